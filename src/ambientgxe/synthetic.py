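"""Synthetic inputs for the full pipeline: a pesticide-application record
table, subject address histories with missing-geocode years, genotypes in
Hardy-Weinberg proportions, covariates, and case-control outcomes drawn
from a configurable logistic disease model.

The generator emulates a retrospective case-control design: an oversized
source population is simulated, disease status is drawn from

    logit P(case) = b0 + bg*G + be*E + bge*G*E
                    + bage*(age - 65) + bsex*male + bsmoke*smoker

with G the risk-allele count and E the subject's *true* binary class-level
ambient exposure (assessed with the same buffer/window/median rules the
analysis applies, with thresholds taken from the source population), and
exactly n_cases cases and n_controls controls are then sampled without
replacement.  Everything is reproducible from a single master seed via
fixed per-stage RNG streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import (
    CHEMICAL_CLASSES,
    ExposureConfig,
    SimConfig,
    stage_rng,
)
from .errors import ConfigError
from .exposure import SETTINGS

GENOTYPE_LABELS = np.array(["AA", "AG", "GG"])


def generate_applications(
    config: SimConfig, region=None, rng=None
) -> pd.DataFrame:
    """Simulate the commercial pesticide application record table.

    Events follow a homogeneous Poisson process per chemical class: the
    yearly event count is Poisson(events_per_year), locations are uniform
    over the rectangular region, the pesticide is uniform among the class's
    agents, and pounds/acres are lognormal.  Covers calendar years
    ``config.start_year`` .. ``config.index_year_max``.
    """
    config.validate()
    if region is None:
        region = (config.region_width_m, config.region_height_m)
    width, height = float(region[0]), float(region[1])
    if width <= 0 or height <= 0:
        raise ConfigError("region must have positive area")
    if rng is None:
        rng = stage_rng(config.seed, "applications")
    years = np.arange(config.start_year, config.index_year_max + 1)
    rows = []
    for cls in sorted(config.intensities):
        intensity = config.intensities[cls]
        if intensity.events_per_year == 0:
            continue
        agents = CHEMICAL_CLASSES[cls]
        counts = rng.poisson(intensity.events_per_year, size=len(years))
        total = int(counts.sum())
        if total == 0:
            continue
        year_col = np.repeat(years, counts)
        rows.append(
            pd.DataFrame(
                {
                    "pesticide_id": rng.choice(agents, size=total),
                    "chemical_class": cls,
                    "year": year_col,
                    "x_m": rng.uniform(0.0, width, size=total),
                    "y_m": rng.uniform(0.0, height, size=total),
                    "pounds": np.exp(
                        rng.normal(intensity.pounds_mu, intensity.pounds_sigma, total)
                    ),
                    "acres": np.exp(
                        rng.normal(intensity.acres_mu, intensity.acres_sigma, total)
                    ),
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "pesticide_id",
                "chemical_class",
                "year",
                "x_m",
                "y_m",
                "pounds",
                "acres",
            ]
        )
    return pd.concat(rows, ignore_index=True)


def generate_genotypes(n: int, q: float, rng) -> np.ndarray:
    """Draw n genotypes under Hardy-Weinberg proportions for G frequency q."""
    if not 0.0 <= q <= 1.0:
        raise ConfigError("allele frequency q must lie in [0, 1]")
    if n < 0:
        raise ConfigError("n must be non-negative")
    probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    codes = rng.choice(3, size=n, p=probs)
    return GENOTYPE_LABELS[codes]


@dataclass
class SourcePopulation:
    """Internal array representation of the simulated source population."""

    genotype_code: np.ndarray       # allele counts 0/1/2
    age: np.ndarray
    male: np.ndarray
    smoker: np.ndarray
    index_year: np.ndarray
    home_xy: np.ndarray             # (n, 2)
    has_occ: np.ndarray             # bool
    occ_xy: np.ndarray              # (n, 2); rows for has_occ only are valid
    recorded: dict                  # setting -> (n, n_years) bool mask
    years: np.ndarray
    exposed: np.ndarray             # true binary class exposure
    is_case: np.ndarray
    p_case: np.ndarray
    class_averages: dict = field(default_factory=dict)  # setting -> (n, n_pest)


@dataclass
class Cohort:
    """A sampled case-control cohort plus generation ground truth."""

    subjects: pd.DataFrame
    addresses: pd.DataFrame
    applications: pd.DataFrame
    true_exposed: pd.Series = None
    truth: dict = field(default_factory=dict)


class ApplicationIndex:
    """Precomputed arrays and KD-tree for one chemical class's applications.

    Built once and reused across power-simulation replicates; the
    application landscape is the fixed environment, replicates redraw the
    subjects.
    """

    def __init__(self, applications: pd.DataFrame, chemical_class: str):
        self.chemical_class = chemical_class
        self.agents = list(CHEMICAL_CLASSES[chemical_class])
        apps = applications[applications["chemical_class"] == chemical_class]
        pest_pos = {p: i for i, p in enumerate(self.agents)}
        self.n_apps = len(apps)
        if self.n_apps:
            self.xy = apps[["x_m", "y_m"]].to_numpy(dtype=float)
            self.year = apps["year"].to_numpy(dtype=int)
            self.pest = apps["pesticide_id"].map(pest_pos).to_numpy(dtype=int)
            self.rate = apps["pounds"].to_numpy(float) / apps["acres"].to_numpy(
                float
            )
            self.tree = cKDTree(self.xy)
        else:
            self.tree = None


def class_window_averages(
    index: ApplicationIndex,
    pop_xy: dict,
    recorded: dict,
    years: np.ndarray,
    index_year: np.ndarray,
    cfg: ExposureConfig,
) -> dict:
    """Per-setting (n_subjects, n_pesticides) window-average matrices for
    subjects whose addresses do not move within a setting.

    Exploits the imputation identity: the imputed window average equals the
    mean of the recorded in-window annual buffer sums.  Mirrors
    :func:`ambientgxe.exposure.compute_exposure`; the unit tests pin the
    two implementations together.
    """
    n = len(index_year)
    year0 = int(years[0])
    win_hi = index_year - cfg.lag_years
    avg = {}
    for setting in SETTINGS:
        xy = pop_xy[setting]              # (n, 2) with NaN rows = no address
        present = np.isfinite(xy[:, 0])
        rec = recorded[setting] & present[:, None]
        in_win = (years[None, :] >= cfg.start_year) & (
            years[None, :] <= win_hi[:, None]
        )
        rec_win = rec & in_win
        n_rec = rec_win.sum(axis=1)

        sums = np.zeros((n, len(index.agents)))
        idx_present = np.flatnonzero(present)
        if index.tree is not None and len(idx_present):
            hits = index.tree.query_ball_point(xy[idx_present], r=cfg.radius_m)
            subj_idx = np.fromiter(
                (idx_present[i] for i, h in enumerate(hits) for _ in h),
                dtype=int,
                count=sum(len(h) for h in hits),
            )
            app_idx = np.fromiter(
                (j for h in hits for j in h), dtype=int, count=len(subj_idx)
            )
            if len(subj_idx):
                keep = rec_win[subj_idx, index.year[app_idx] - year0]
                s_k, a_k = subj_idx[keep], app_idx[keep]
                np.add.at(sums, (s_k, index.pest[a_k]), index.rate[a_k])
        with np.errstate(invalid="ignore"):
            w = np.where(
                n_rec[:, None] > 0, sums / np.maximum(n_rec, 1)[:, None], 0.0
            )
        avg[setting] = w
    return avg


def categorize_class_exposure(
    avg: dict,
    cfg: ExposureConfig,
    chemical_class: str,
    threshold_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Binary class-level exposure from per-setting window-average matrices.

    Thresholds (per-pesticide exposed medians, and the class count median)
    are computed over the rows selected by ``threshold_mask`` — the whole
    population for ground truth, the sampled controls for an analysis-style
    assessment — and applied to every row.
    """
    n = len(next(iter(avg.values())))
    if threshold_mask is None:
        threshold_mask = np.ones(n, dtype=bool)
    high = {}
    for setting in SETTINGS:
        w = avg[setting]
        h = np.zeros_like(w, dtype=bool)
        for j in range(w.shape[1]):
            vals = w[:, j]
            pos = vals[threshold_mask & (vals > 0)]
            if len(pos) == 0:
                continue
            thr = np.median(pos)
            h[:, j] = (vals > 0) & (vals >= thr)
        high[setting] = h

    if cfg.count_rule == "any_nonzero":
        flags = {s: avg[s] > 0 for s in SETTINGS}
    else:
        flags = high
    if cfg.combine_settings == "either":
        combined = flags["residential"] | flags["occupational"]
    elif cfg.combine_settings == "both":
        combined = flags["residential"] & flags["occupational"]
    elif cfg.combine_settings == "residential_only":
        combined = flags["residential"]
    else:
        combined = flags["occupational"]

    counts = combined.sum(axis=1)
    if chemical_class in ("pyrethroid", "paraquat"):
        return counts >= 1
    pos_counts = counts[threshold_mask & (counts >= 1)]
    if len(pos_counts) == 0:
        return np.zeros(n, dtype=bool)
    cthr = np.median(pos_counts)
    return (counts >= 1) & (counts >= cthr)


def simulate_source_population(
    config: SimConfig,
    applications: pd.DataFrame,
    exposure_cfg: ExposureConfig | None = None,
    app_index: ApplicationIndex | None = None,
) -> SourcePopulation:
    """Simulate the source population the case-control sample is drawn from."""
    config.validate()
    exposure_cfg = exposure_cfg or ExposureConfig()
    n = int(np.ceil(config.source_multiplier * config.n_subjects))
    seed = config.seed

    geno_rng = stage_rng(seed, "genotypes")
    genotypes = generate_genotypes(n, config.risk_allele_freq, geno_rng)
    gcode = np.searchsorted(GENOTYPE_LABELS, genotypes).astype(float)

    cov_rng = stage_rng(seed, "covariates")
    age = np.clip(
        cov_rng.normal(config.age_mean, config.age_sd, n),
        config.age_min,
        config.age_max,
    )
    male = cov_rng.random(n) < config.male_fraction
    smoker = cov_rng.random(n) < config.smoker_fraction
    index_year = cov_rng.integers(
        config.index_year_min, config.index_year_max + 1, size=n
    )

    addr_rng = stage_rng(seed, "addresses")
    home_xy = np.column_stack(
        [
            addr_rng.uniform(0.0, config.region_width_m, n),
            addr_rng.uniform(0.0, config.region_height_m, n),
        ]
    )
    has_occ = addr_rng.random(n) < config.occupational_fraction
    occ_xy = np.column_stack(
        [
            addr_rng.uniform(0.0, config.region_width_m, n),
            addr_rng.uniform(0.0, config.region_height_m, n),
        ]
    )
    occ_xy[~has_occ] = np.nan
    years = np.arange(config.start_year, config.index_year_max + 1)
    recorded = {}
    for setting in SETTINGS:
        mask = addr_rng.random((n, len(years))) >= config.missing_rate
        # address history only exists up to the subject's index year
        mask &= years[None, :] <= index_year[:, None]
        recorded[setting] = mask
    recorded["occupational"] &= has_occ[:, None]

    pop_xy = {"residential": home_xy, "occupational": occ_xy}
    if app_index is None:
        app_index = ApplicationIndex(applications, config.disease.exposure_class)
    class_averages = class_window_averages(
        app_index, pop_xy, recorded, years, index_year, exposure_cfg
    )

    d = config.disease
    base_logit = (
        d.b0
        + d.bg * gcode
        + d.bage * (age - 65.0)
        + d.bsex * male
        + d.bsmoke * smoker
    )
    out_rng = stage_rng(seed, "outcomes")
    u = out_rng.random(n)

    def draw(exposed_vec):
        logit = base_logit + (d.be + d.bge * gcode) * exposed_vec
        p = 1.0 / (1.0 + np.exp(-logit))
        return u < p, p

    # True exposure is defined the way the analysis defines it: thresholds
    # from exposed *controls*.  Control status itself depends on exposure, so
    # a two-pass draw with common random numbers is used: pass 1 thresholds
    # come from the whole population, pass 2 re-thresholds on the pass-1
    # non-cases and redraws outcomes.  The remaining mismatch with the
    # sampled-control thresholds the analysis uses is pure sampling noise.
    exposed0 = categorize_class_exposure(
        class_averages, exposure_cfg, d.exposure_class
    )
    is_case0, _ = draw(exposed0)
    exposed = categorize_class_exposure(
        class_averages, exposure_cfg, d.exposure_class, threshold_mask=~is_case0
    )
    is_case, p_case = draw(exposed)

    return SourcePopulation(
        genotype_code=gcode,
        age=age,
        male=male,
        smoker=smoker,
        index_year=index_year,
        home_xy=home_xy,
        has_occ=has_occ,
        occ_xy=occ_xy,
        recorded=recorded,
        years=years,
        exposed=exposed,
        is_case=is_case,
        p_case=p_case,
        class_averages=class_averages,
    )


def _sample_cohort_indices(config: SimConfig, pop: SourcePopulation, rng):
    cases = np.flatnonzero(pop.is_case)
    controls = np.flatnonzero(~pop.is_case)
    if len(cases) < config.n_cases:
        raise ConfigError(
            f"source population produced {len(cases)} cases but "
            f"{config.n_cases} requested; increase source_multiplier or b0"
        )
    if len(controls) < config.n_controls:
        raise ConfigError(
            f"source population produced {len(controls)} controls but "
            f"{config.n_controls} requested; increase source_multiplier"
        )
    case_idx = rng.choice(cases, size=config.n_cases, replace=False)
    if not config.match_controls_by_age:
        control_idx = rng.choice(controls, size=config.n_controls, replace=False)
        return case_idx, control_idx
    # frequency-match controls to the case age-decade distribution
    bins = np.arange(30, 101, 10)
    case_bins = np.digitize(pop.age[case_idx], bins)
    control_bins = np.digitize(pop.age[controls], bins)
    want = np.round(
        np.bincount(case_bins, minlength=len(bins) + 1)
        / len(case_idx)
        * config.n_controls
    ).astype(int)
    chosen = []
    for b in range(len(bins) + 1):
        pool = controls[control_bins == b]
        k = min(want[b], len(pool))
        if k > 0:
            chosen.append(rng.choice(pool, size=k, replace=False))
    chosen = np.concatenate(chosen) if chosen else np.array([], dtype=int)
    if len(chosen) < config.n_controls:  # top up from the remainder
        remainder = np.setdiff1d(controls, chosen)
        extra = rng.choice(
            remainder, size=config.n_controls - len(chosen), replace=False
        )
        chosen = np.concatenate([chosen, extra])
    return case_idx, chosen[: config.n_controls]


def cohort_tables(
    config: SimConfig, pop: SourcePopulation, idx: np.ndarray, status: np.ndarray
) -> Cohort:
    """Build the subjects/addresses tables for the selected source rows."""
    subject_ids = np.array([f"S{k:06d}" for k in range(len(idx))])
    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "status": status,
            "age_years": pop.age[idx],
            "sex": np.where(pop.male[idx], "male", "female"),
            "smoker_ever": pop.smoker[idx],
            "index_year": pop.index_year[idx],
            "genotype": GENOTYPE_LABELS[pop.genotype_code[idx].astype(int)],
        }
    )
    frames = []
    years = pop.years
    for setting, xy in (
        ("residential", pop.home_xy),
        ("occupational", pop.occ_xy),
    ):
        rec = pop.recorded[setting][idx]
        present = (
            np.ones(len(idx), dtype=bool)
            if setting == "residential"
            else pop.has_occ[idx]
        )
        # one row per (subject, year <= index_year) for settings the subject has
        year_ok = years[None, :] <= pop.index_year[idx][:, None]
        rows = present[:, None] & year_ok
        subj_rep = np.repeat(np.arange(len(idx)), rows.sum(axis=1))
        year_rep = np.broadcast_to(years, rows.shape)[rows]
        rec_flat = rec[rows]
        x = np.where(rec_flat, xy[idx][subj_rep, 0], np.nan)
        y = np.where(rec_flat, xy[idx][subj_rep, 1], np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject_ids[subj_rep],
                    "year": year_rep,
                    "setting": setting,
                    "x_m": x,
                    "y_m": y,
                }
            )
        )
    addresses = pd.concat(frames, ignore_index=True)
    true_exposed = pd.Series(pop.exposed[idx], index=subject_ids)
    return Cohort(
        subjects=subjects,
        addresses=addresses,
        applications=None,
        true_exposed=true_exposed,
        truth={
            "betas": dataclass_asdict(config.disease),
            "source_case_fraction": float(pop.is_case.mean()),
            "source_exposed_fraction": float(pop.exposed.mean()),
            "source_size": len(pop.is_case),
        },
    )


def dataclass_asdict(obj) -> dict:
    import dataclasses

    return dataclasses.asdict(obj)


def generate_cohort(
    config: SimConfig,
    applications: pd.DataFrame,
    exposure_cfg: ExposureConfig | None = None,
) -> Cohort:
    """Simulate a source population and sample the case-control cohort.

    Returns a :class:`Cohort` with the subjects and addresses tables, the
    applications table passed through, the per-subject true exposure
    indicator, and a ``truth`` dict recording the generating coefficients
    and source-population summaries for parameter-recovery experiments.
    """
    if applications is None or applications.empty:
        d = config.disease
        if d.be != 0.0 or d.bge != 0.0:
            raise ConfigError(
                "applications table is empty but the disease model has "
                "non-zero exposure effects"
            )
        applications = pd.DataFrame(
            columns=[
                "pesticide_id",
                "chemical_class",
                "year",
                "x_m",
                "y_m",
                "pounds",
                "acres",
            ]
        )
    pop = simulate_source_population(config, applications, exposure_cfg)
    samp_rng = stage_rng(config.seed, "sampling")
    case_idx, control_idx = _sample_cohort_indices(config, pop, samp_rng)
    idx = np.concatenate([case_idx, control_idx])
    status = np.array(["case"] * len(case_idx) + ["control"] * len(control_idx))
    cohort = cohort_tables(config, pop, idx, status)
    cohort.applications = applications
    return cohort


def generate_expression(
    genotype_codes, slope: float, noise_sd: float = 1.0, rng=None, seed: int = 0
) -> np.ndarray:
    """Synthetic per-subject expression levels linear in allele count.

    A minimal generative model for exercising the Spearman eQTL statistic:
    expression = slope * G + Normal(0, noise_sd).
    """
    if rng is None:
        rng = stage_rng(seed, "expression")
    g = np.asarray(genotype_codes, dtype=float)
    return slope * g + rng.normal(0.0, noise_sd, size=g.shape)
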