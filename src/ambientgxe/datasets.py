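"""Published contingency tables for the HLA-DRA rs3129882 pyrethroid
interaction analysis in a population-based Parkinson's disease case-control
study (465 patients, 497 controls of European ancestry).

These printed counts are the only individual-free data the analysis can be
checked against: genotype margins by status, genotype x ambient-pyrethroid
exposure counts, and the adjusted odds ratios reported alongside them.
They serve as fixed inputs for arithmetic cross-checks of the model code —
crude odds ratios from the homozygote cells, Hardy-Weinberg tests on the
control margin, and internal-consistency identities of the additive model.
"""

from __future__ import annotations

import pandas as pd

from .genetics import GenotypeCounts

#: genotype counts by case-control status (marginal table)
GENOTYPE_COUNTS = pd.DataFrame(
    [
        ("AA", 142, 175),
        ("AG", 243, 227),
        ("GG", 80, 95),
    ],
    columns=["genotype", "n_cases", "n_controls"],
)

#: genotype x pyrethroid-exposure counts (none vs one-or-more pesticides)
GXE_COUNTS = pd.DataFrame(
    [
        ("none", "AA", 95, 117),
        ("none", "AG", 172, 161),
        ("none", "GG", 50, 81),
        ("exposed", "AA", 47, 58),
        ("exposed", "AG", 71, 66),
        ("exposed", "GG", 30, 14),
    ],
    columns=["exposure", "genotype", "n_cases", "n_controls"],
)

#: adjusted odds ratios printed with the additive-genetic-model table
#: (reference: unexposed AA; adjusted for age, sex, smoking)
GXE_ADDITIVE_ADJUSTED_OR = {
    ("none", "AG"): 0.91,
    ("none", "GG"): 0.82,
    ("exposed", "AA"): 0.83,
    ("exposed", "AG"): 1.25,
    ("exposed", "GG"): 1.87,
}

#: adjusted odds ratios for the homozygote (AA vs GG) contrast
GXE_HOMOZYGOTE_ADJUSTED_OR = {
    ("none", "GG"): 0.73,
    ("exposed", "AA"): 1.04,
    ("exposed", "GG"): 2.48,
}

#: reported Hardy-Weinberg p-value in controls
CONTROL_HWE_P = 0.18


def control_genotype_counts() -> GenotypeCounts:
    """Control-group genotype counts as a GenotypeCounts object."""
    row = GENOTYPE_COUNTS.set_index("genotype")["n_controls"]
    return GenotypeCounts(int(row["AA"]), int(row["AG"]), int(row["GG"]))


def case_genotype_counts() -> GenotypeCounts:
    row = GENOTYPE_COUNTS.set_index("genotype")["n_cases"]
    return GenotypeCounts(int(row["AA"]), int(row["AG"]), int(row["GG"]))


def homozygote_corner_cells() -> dict:
    """The doubly-unexposed and doubly-exposed homozygote cells, the
    ingredients of the crude joint-effect odds ratio."""
    t = GXE_COUNTS.set_index(["exposure", "genotype"])
    return {
        "unexposed_AA": (
            int(t.loc[("none", "AA"), "n_cases"]),
            int(t.loc[("none", "AA"), "n_controls"]),
        ),
        "exposed_GG": (
            int(t.loc[("exposed", "GG"), "n_cases"]),
            int(t.loc[("exposed", "GG"), "n_controls"]),
        ),
    }
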