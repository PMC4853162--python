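"""Case-control association models.

Two model classes follow the familiar fit/Results pattern:

``MarginalGenotypeModel``
    marginal SNP-disease association under an additive, recessive, or
    homozygote-contrast genetic model, adjusted for covariates.

``GxEInteractionModel``
    the gene-environment interaction model
    logit P(case) = b0 + bg*G + be*E + bge*G*E + covariates,
    with E a binary class-level ambient-exposure category, reporting the
    stratified and joint odds ratios (reference: unexposed low-risk
    homozygotes) and the multiplicative-interaction p-value (Wald, with the
    likelihood-ratio p alongside).

Both accept a subjects DataFrame with the standard columns
(subject_id, status, age_years, sex, smoker_ever, genotype) and drop
subjects listwise when genotype, exposure, or a covariate is missing; the
drop counts are kept on the Results object.

Module-level helpers provide the demographic two-sample tests and the
tie-corrected Spearman rank eQTL statistic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateTestError, InestimableError
from .genetics import code_genotypes
from .glm import (
    EffectEstimate,
    LogisticFit,
    fit_logistic,
    likelihood_ratio_p,
    wald_or,
)

DEFAULT_COVARIATES = ("age", "sex", "smoking")

_COVARIATE_COLUMNS = {
    "age": "age_years",
    "sex": "sex",
    "smoking": "smoker_ever",
}


def _covariate_matrix(subjects: pd.DataFrame, covariates):
    """Covariate columns: age continuous, sex/smoking as 0/1 indicators."""
    cols, names = [], []
    for cov in covariates:
        if cov not in _COVARIATE_COLUMNS:
            raise DataError(f"unknown covariate: {cov!r}")
        col = subjects[_COVARIATE_COLUMNS[cov]]
        if cov == "age":
            cols.append(col.to_numpy(dtype=float))
            names.append("age")
        elif cov == "sex":
            cols.append((col == "male").to_numpy(dtype=float))
            names.append("male")
        else:
            cols.append(col.astype(bool).to_numpy(dtype=float))
            names.append("smoker")
    return cols, names


def _outcome(subjects: pd.DataFrame) -> np.ndarray:
    status = subjects["status"]
    bad = set(status.unique()) - {"case", "control"}
    if bad:
        raise DataError(f"unknown status labels: {sorted(bad)}")
    return (status == "case").to_numpy(dtype=float)


@dataclass
class DropLog:
    """Listwise-deletion bookkeeping."""

    n_input: int = 0
    n_analysed: int = 0
    missing_genotype: int = 0
    excluded_genotype_model: int = 0
    missing_exposure: int = 0
    missing_covariate: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# marginal genotype model


class MarginalGenotypeModel:
    """Marginal SNP-disease logistic model under one genetic coding."""

    def __init__(
        self,
        subjects: pd.DataFrame,
        model: str = "additive",
        covariates=DEFAULT_COVARIATES,
    ):
        self.subjects = subjects.reset_index(drop=True)
        self.model = model
        self.covariates = tuple(covariates)

    def fit(self, **fit_kwargs) -> "MarginalResults":
        df = self.subjects
        log = DropLog(n_input=len(df))
        geno_missing = df["genotype"].isna()
        log.missing_genotype = int(geno_missing.sum())
        df = df[~geno_missing]
        g = code_genotypes(df["genotype"], self.model)
        excluded = np.isnan(g)
        log.excluded_genotype_model = int(excluded.sum())
        df, g = df[~excluded], g[~excluded]
        cov_cols, cov_names = _covariate_matrix(df, self.covariates)
        cov_missing = np.zeros(len(df), dtype=bool)
        for c in cov_cols:
            cov_missing |= ~np.isfinite(c)
        log.missing_covariate = int(cov_missing.sum())
        keep = ~cov_missing
        df, g = df[keep], g[keep]
        cov_cols = [c[keep] for c in cov_cols]
        log.n_analysed = len(df)
        y = _outcome(df)
        X = np.column_stack([np.ones(len(df)), g, *cov_cols])
        terms = ["intercept", "genotype", *cov_names]
        fit = fit_logistic(X, y, terms=terms, **fit_kwargs)
        return MarginalResults(
            model=self.model, fit=fit, drop_log=log, subjects=df
        )


@dataclass
class MarginalResults:
    """Fitted marginal genotype model."""

    model: str
    fit: LogisticFit
    drop_log: DropLog
    subjects: pd.DataFrame = field(repr=False, default=None)

    def _contrast(self, k: float) -> np.ndarray:
        c = np.zeros(len(self.fit.terms))
        c[self.fit.terms.index("genotype")] = k
        return c

    def or_per_allele(self) -> EffectEstimate:
        if self.model != "additive":
            raise DataError("per-allele OR only defined for the additive model")
        return wald_or(self.fit, self._contrast(1.0))

    def or_two_alleles(self) -> EffectEstimate:
        if self.model != "additive":
            raise DataError("two-allele OR only defined for the additive model")
        return wald_or(self.fit, self._contrast(2.0))

    def or_genotype(self) -> EffectEstimate:
        """OR for the model's single genotype contrast (recessive / AA-vs-GG)."""
        return wald_or(self.fit, self._contrast(1.0))

    def summary(self) -> pd.DataFrame:
        rows = []
        if self.model == "additive":
            one, two = self.or_per_allele(), self.or_two_alleles()
            rows.append(("AG vs AA (one G allele)", one))
            rows.append(("GG vs AA (two G alleles)", two))
        elif self.model == "recessive":
            rows.append(("GG vs AA+AG", self.or_genotype()))
        else:
            rows.append(("GG vs AA", self.or_genotype()))
        return pd.DataFrame(
            [
                {
                    "contrast": label,
                    "OR": e.OR,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "p": e.p,
                }
                for label, e in rows
            ]
        )


def marginal_genotype_analysis(
    subjects: pd.DataFrame, model: str = "additive", covariates=DEFAULT_COVARIATES
) -> MarginalResults:
    """Convenience wrapper: build the model and fit it."""
    return MarginalGenotypeModel(subjects, model, covariates).fit()


def genotype_table(subjects: pd.DataFrame, covariates=DEFAULT_COVARIATES):
    """Genotype-by-status counts plus all three marginal codings.

    Mirrors the usual marginal-effects table: per-genotype case/control
    counts and column proportions, additive ORs for one and two risk
    alleles, then the homozygote and recessive contrasts.
    """
    rows = []
    for geno in ("AA", "AG", "GG"):
        sub = subjects[subjects["genotype"] == geno]
        n_case = int((sub["status"] == "case").sum())
        n_control = int((sub["status"] == "control").sum())
        rows.append({"genotype": geno, "n_cases": n_case, "n_controls": n_control})
    table = pd.DataFrame(rows)
    for col, n in (
        ("n_cases", table["n_cases"].sum()),
        ("n_controls", table["n_controls"].sum()),
    ):
        table[col.replace("n_", "frac_")] = table[col] / n
    additive = marginal_genotype_analysis(subjects, "additive", covariates)
    homozygote = marginal_genotype_analysis(
        subjects, "homozygote_contrast", covariates
    )
    recessive = marginal_genotype_analysis(subjects, "recessive", covariates)
    estimates = pd.concat(
        [additive.summary(), homozygote.summary(), recessive.summary()],
        ignore_index=True,
    )
    return table, estimates


# ---------------------------------------------------------------------------
# gene-environment interaction model


class GxEInteractionModel:
    """Multiplicative gene-environment interaction logistic model."""

    def __init__(
        self,
        subjects: pd.DataFrame,
        exposed: pd.Series,
        model: str = "additive",
        covariates=DEFAULT_COVARIATES,
        chemical_class: str | None = None,
    ):
        """``exposed`` is a boolean Series indexed by subject_id (the binary
        class-level category: any/none for pyrethroids, high vs low/none
        otherwise)."""
        if model not in ("additive", "homozygote_contrast"):
            raise DataError(
                "interaction model must be additive or homozygote_contrast"
            )
        self.subjects = subjects.reset_index(drop=True)
        self.exposed = exposed
        self.model = model
        self.covariates = tuple(covariates)
        self.chemical_class = chemical_class

    def fit(self, **fit_kwargs) -> "GxEResults":
        df = self.subjects
        log = DropLog(n_input=len(df))
        geno_missing = df["genotype"].isna()
        log.missing_genotype = int(geno_missing.sum())
        df = df[~geno_missing]
        e = df["subject_id"].map(self.exposed)
        log.missing_exposure = int(e.isna().sum())
        df, e = df[~e.isna()], e[~e.isna()].astype(float).to_numpy()
        g = code_genotypes(df["genotype"], self.model)
        excl = np.isnan(g)
        log.excluded_genotype_model = int(excl.sum())
        df, g, e = df[~excl], g[~excl], e[~excl]
        cov_cols, cov_names = _covariate_matrix(df, self.covariates)
        cov_missing = np.zeros(len(df), dtype=bool)
        for c in cov_cols:
            cov_missing |= ~np.isfinite(c)
        log.missing_covariate = int(cov_missing.sum())
        keep = ~cov_missing
        df, g, e = df[keep], g[keep], e[keep]
        cov_cols = [c[keep] for c in cov_cols]
        log.n_analysed = len(df)

        self._check_estimable(df, g, e)
        y = _outcome(df)
        X = np.column_stack([np.ones(len(df)), g, e, g * e, *cov_cols])
        terms = ["intercept", "genotype", "exposed", "genotype_x_exposed", *cov_names]
        fit = fit_logistic(X, y, terms=terms, **fit_kwargs)
        X_red = np.delete(X, terms.index("genotype_x_exposed"), axis=1)
        terms_red = [t for t in terms if t != "genotype_x_exposed"]
        fit_reduced = fit_logistic(X_red, y, terms=terms_red, **fit_kwargs)
        return GxEResults(
            model=self.model,
            chemical_class=self.chemical_class,
            fit=fit,
            interaction_p_lrt=likelihood_ratio_p(fit, fit_reduced),
            drop_log=log,
            subjects=df,
            genotype_code=g,
            exposed=e.astype(bool),
        )

    def _check_estimable(self, df, g, e):
        for e_level, e_name in ((0.0, "unexposed"), (1.0, "exposed")):
            sub_g = g[e == e_level]
            if len(sub_g) == 0:
                raise InestimableError(
                    f"no subjects in the {e_name} stratum",
                    cell=(e_name, "any"),
                )
            if len(np.unique(sub_g)) < 2:
                raise InestimableError(
                    "interaction inestimable: genotype does not vary among "
                    f"{e_name} subjects",
                    cell=(e_name, "genotype"),
                )


@dataclass
class GxEResults:
    """Fitted interaction model with the stratified/joint OR layout."""

    model: str
    chemical_class: str | None
    fit: LogisticFit
    interaction_p_lrt: float
    drop_log: DropLog
    subjects: pd.DataFrame = field(repr=False, default=None)
    genotype_code: np.ndarray = field(repr=False, default=None)
    exposed: np.ndarray = field(repr=False, default=None)

    def _contrast(self, kg=0.0, ke=0.0, kge=0.0) -> np.ndarray:
        c = np.zeros(len(self.fit.terms))
        c[self.fit.terms.index("genotype")] = kg
        c[self.fit.terms.index("exposed")] = ke
        c[self.fit.terms.index("genotype_x_exposed")] = kge
        return c

    def cell_or(self, g_copies: float, exposed: bool) -> EffectEstimate:
        """OR of the (genotype, exposure) cell vs the unexposed reference."""
        ke = 1.0 if exposed else 0.0
        return wald_or(
            self.fit, self._contrast(kg=g_copies, ke=ke, kge=g_copies * ke)
        )

    @property
    def interaction_p_wald(self) -> float:
        return wald_or(self.fit, self._contrast(kge=1.0)).p

    @property
    def interaction_or(self) -> EffectEstimate:
        return wald_or(self.fit, self._contrast(kge=1.0))

    def joint_or(self) -> EffectEstimate:
        """Doubly-exposed cell vs doubly-unexposed reference."""
        k = 2.0 if self.model == "additive" else 1.0
        return self.cell_or(k, True)

    def table(self) -> pd.DataFrame:
        """The genotype x exposure OR table (reference: unexposed AA)."""
        genos = (
            [("AA", 0.0), ("AG", 1.0), ("GG", 2.0)]
            if self.model == "additive"
            else [("AA", 0.0), ("GG", 1.0)]
        )
        labels = (
            self.subjects["genotype"].to_numpy()
            if self.subjects is not None
            else None
        )
        y = _outcome(self.subjects) if self.subjects is not None else None
        rows = []
        for exp_flag, exp_name in ((False, "none"), (True, "exposed")):
            stratum = self.exposed == exp_flag
            n_case_str = (
                int(((y == 1) & stratum).sum()) if y is not None else np.nan
            )
            n_ctrl_str = (
                int(((y == 0) & stratum).sum()) if y is not None else np.nan
            )
            for geno, k in genos:
                row = {
                    "chemical_class": self.chemical_class,
                    "exposure": exp_name,
                    "genotype": geno,
                }
                if labels is not None:
                    in_cell = stratum & (labels == geno)
                    row["n_cases"] = int(((y == 1) & in_cell).sum())
                    row["n_controls"] = int(((y == 0) & in_cell).sum())
                    row["frac_cases"] = (
                        row["n_cases"] / n_case_str if n_case_str else np.nan
                    )
                    row["frac_controls"] = (
                        row["n_controls"] / n_ctrl_str if n_ctrl_str else np.nan
                    )
                if not exp_flag and k == 0.0:
                    row.update(OR=1.0, ci_low=np.nan, ci_high=np.nan, p=np.nan)
                else:
                    est = self.cell_or(k, exp_flag)
                    row.update(
                        OR=est.OR, ci_low=est.ci_low, ci_high=est.ci_high, p=est.p
                    )
                rows.append(row)
        table = pd.DataFrame(rows)
        table.attrs["interaction_p_wald"] = self.interaction_p_wald
        table.attrs["interaction_p_lrt"] = self.interaction_p_lrt
        table.attrs["model"] = self.model
        table.attrs["covariates"] = [
            t for t in self.fit.terms
            if t not in ("intercept", "genotype", "exposed", "genotype_x_exposed")
        ]
        return table

    def summary(self) -> str:
        lines = [
            f"Gene-environment interaction model ({self.model})",
            f"  chemical class: {self.chemical_class}",
            f"  n analysed: {self.drop_log.n_analysed} "
            f"(of {self.drop_log.n_input})",
            f"  converged: {self.fit.converged} "
            f"in {self.fit.n_iterations} iterations",
            "",
            self.table().to_string(index=False, float_format="%.3f"),
            "",
            f"  interaction OR per risk allele: {self.interaction_or.OR:.3f} "
            f"({self.interaction_or.ci_low:.3f}, {self.interaction_or.ci_high:.3f})",
            f"  interaction p (Wald): {self.interaction_p_wald:.4g}",
            f"  interaction p (LRT):  {self.interaction_p_lrt:.4g}",
        ]
        return "\n".join(lines)


def gxe_analysis(
    subjects: pd.DataFrame,
    exposed: pd.Series,
    model: str = "additive",
    covariates=DEFAULT_COVARIATES,
    chemical_class: str | None = None,
) -> GxEResults:
    """Convenience wrapper: build the interaction model and fit it."""
    return GxEInteractionModel(
        subjects, exposed, model, covariates, chemical_class
    ).fit()


# ---------------------------------------------------------------------------
# demographics and eQTL


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    test: str


def demographics_compare(subjects: pd.DataFrame, variable: str) -> TestResult:
    """Case-control comparison of one demographic variable.

    Continuous variables get the two-sided pooled-variance t-test,
    categorical ones the Pearson chi-square (no continuity correction).
    """
    cases = subjects[subjects["status"] == "case"][variable].dropna()
    controls = subjects[subjects["status"] == "control"][variable].dropna()
    if len(cases) < 2 or len(controls) < 2:
        raise DataError("each group needs at least 2 observations")
    if pd.api.types.is_numeric_dtype(subjects[variable]) and not (
        pd.api.types.is_bool_dtype(subjects[variable])
    ):
        res = stats.ttest_ind(cases, controls, equal_var=True)
        return TestResult(
            statistic=float(res.statistic),
            df=float(len(cases) + len(controls) - 2),
            p=float(res.pvalue),
            test="t",
        )
    table = pd.crosstab(subjects["status"], subjects[variable])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateTestError(f"{variable!r} does not vary in both groups")
    chi2, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return TestResult(statistic=float(chi2), df=float(df), p=float(p), test="chi2")


@dataclass(frozen=True)
class EqtlResult:
    rho: float
    p: float
    n: int
    p_permutation: float | None = None


def spearman_eqtl(
    genotype_codes,
    expression,
    permutation: bool = False,
    n_permutations: int | None = None,
    rng=None,
) -> EqtlResult:
    """Tie-corrected Spearman rank correlation of allele count vs expression.

    ``p`` is the usual t-approximation; with ``permutation=True`` an exact
    enumeration p-value is added for n <= 8 (Monte Carlo above that).
    """
    g = np.asarray(genotype_codes, dtype=float)
    x = np.asarray(expression, dtype=float)
    if g.size != x.size:
        raise DataError("genotype and expression vectors differ in length")
    if g.size < 4:
        raise DataError("need at least 4 observations")
    if np.all(g == g[0]) or np.all(x == x[0]):
        raise DegenerateTestError("constant input: correlation undefined")
    rho, p = stats.spearmanr(g, x)
    p_perm = None
    if permutation:
        obs = abs(rho)
        if g.size <= 8 and n_permutations is None:
            count = total = 0
            for perm in itertools.permutations(x):
                r, _ = stats.spearmanr(g, perm)
                count += abs(r) >= obs - 1e-12
                total += 1
            p_perm = count / total
        else:
            if rng is None:
                rng = np.random.default_rng(0)
            n_perm = n_permutations or 2000
            count = 0
            xs = x.copy()
            for _ in range(n_perm):
                rng.shuffle(xs)
                r, _ = stats.spearmanr(g, xs)
                count += abs(r) >= obs - 1e-12
            p_perm = (count + 1) / (n_perm + 1)
    return EqtlResult(rho=float(rho), p=float(p), n=int(g.size), p_permutation=p_perm)
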