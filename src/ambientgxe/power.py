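"""Simulation-based power and type-I error for the interaction test.

Rather than an analytic approximation, power is estimated by running the
whole generative and analytic machinery end to end: each replicate draws a
fresh source population over a fixed application landscape, samples the
case-control cohort, re-assesses exposure analysis-style (thresholds from
the sampled controls), fits the interaction model, and tests the
interaction coefficient at level alpha.  The rejection fraction comes back
with an exact (Clopper-Pearson) binomial confidence interval; replicates
that fail with separation or an inestimable interaction are counted and
reported separately rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .association import GxEInteractionModel
from .config import PowerSpec, stage_rng
from .errors import ModelError
from .synthetic import (
    ApplicationIndex,
    GENOTYPE_LABELS,
    _sample_cohort_indices,
    categorize_class_exposure,
    generate_applications,
    simulate_source_population,
)


@dataclass(frozen=True)
class PowerResult:
    """Estimated rejection fraction of the interaction test."""

    power: float
    ci_low: float
    ci_high: float
    alpha: float
    n_replicates: int
    n_failed: int
    n_effective: int
    mean_beta_ge: float
    ci_coverage: float      # fraction of replicate CIs covering the true bge
    model: str
    chemical_class: str

    def summary(self) -> str:
        return (
            f"interaction test power at alpha={self.alpha:g}: "
            f"{self.power:.3f} (95% CI {self.ci_low:.3f}, {self.ci_high:.3f}); "
            f"{self.n_effective}/{self.n_replicates} replicates usable, "
            f"{self.n_failed} failed; mean interaction log-OR "
            f"{self.mean_beta_ge:.4f}"
        )


def _clopper_pearson(k: int, n: int, level: float = 0.95):
    from scipy import stats

    alpha = 1.0 - level
    lo = stats.beta.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def simulate_one(
    sim_config,
    applications: pd.DataFrame,
    exposure_cfg,
    model: str,
    chemical_class: str,
    app_index: ApplicationIndex | None = None,
):
    """One generate -> assess -> fit replicate; returns fitted GxEResults.

    Exposure for the analysis is re-assessed with thresholds from the
    sampled controls, exactly as the table pipeline does.
    """
    pop = simulate_source_population(
        sim_config, applications, exposure_cfg, app_index=app_index
    )
    rng = stage_rng(sim_config.seed, "sampling")
    case_idx, control_idx = _sample_cohort_indices(sim_config, pop, rng)
    idx = np.concatenate([case_idx, control_idx])
    status = np.array(
        ["case"] * len(case_idx) + ["control"] * len(control_idx)
    )
    # analysis-style exposure assessment on the sampled cohort
    avg_sub = {s: w[idx] for s, w in pop.class_averages.items()}
    exposed = categorize_class_exposure(
        avg_sub,
        exposure_cfg,
        chemical_class,
        threshold_mask=(status == "control"),
    )
    subject_ids = [f"S{k:06d}" for k in range(len(idx))]
    subjects = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "status": status,
            "age_years": pop.age[idx],
            "sex": np.where(pop.male[idx], "male", "female"),
            "smoker_ever": pop.smoker[idx],
            "genotype": GENOTYPE_LABELS[pop.genotype_code[idx].astype(int)],
        }
    )
    exposed_series = pd.Series(exposed, index=pd.Index(subject_ids))
    return GxEInteractionModel(
        subjects,
        exposed_series,
        model=model,
        chemical_class=chemical_class,
    ).fit()


def estimate_power(spec: PowerSpec) -> PowerResult:
    """Monte-Carlo power of the multiplicative-interaction Wald test."""
    spec.validate()
    applications = generate_applications(spec.sim)
    app_index = ApplicationIndex(applications, spec.chemical_class)
    # analysed class may differ from the class driving the disease model
    if spec.chemical_class != spec.sim.disease.exposure_class:
        gen_index = ApplicationIndex(
            applications, spec.sim.disease.exposure_class
        )
    else:
        gen_index = app_index

    seed_rng = stage_rng(spec.sim.seed, "power")
    child_seeds = seed_rng.integers(0, 2**31 - 1, size=spec.n_replicates)

    # generating model is per-allele; the homozygote contrast (GG=1 vs AA=0)
    # spans two alleles, so its true interaction coefficient is 2*bge
    true_bge = spec.sim.disease.bge
    true_contrast = (
        2.0 * true_bge if spec.model == "homozygote_contrast" else true_bge
    )

    rejections = 0
    n_failed = 0
    betas = []
    covered = 0
    for s in child_seeds:
        cfg = replace(spec.sim, seed=int(s))
        try:
            res = simulate_one(
                cfg,
                applications,
                spec.exposure,
                spec.model,
                spec.chemical_class,
                app_index=gen_index,
            )
        except ModelError:
            n_failed += 1
            continue
        est = res.interaction_or
        betas.append(est.log_or)
        if est.p < spec.alpha:
            rejections += 1
        lo = est.log_or - 1.959963984540054 * est.se
        hi = est.log_or + 1.959963984540054 * est.se
        if lo <= true_contrast <= hi:
            covered += 1
    n_eff = spec.n_replicates - n_failed
    if n_eff == 0 or n_failed > 0.2 * spec.n_replicates:
        raise ModelError(
            f"unstable design: {n_failed}/{spec.n_replicates} replicates "
            "failed (separation or inestimable interaction)"
        )
    power = rejections / n_eff
    lo, hi = _clopper_pearson(rejections, n_eff)
    return PowerResult(
        power=power,
        ci_low=lo,
        ci_high=hi,
        alpha=spec.alpha,
        n_replicates=spec.n_replicates,
        n_failed=n_failed,
        n_effective=n_eff,
        mean_beta_ge=float(np.mean(betas)) if betas else float("nan"),
        ci_coverage=covered / n_eff,
        model=spec.model,
        chemical_class=spec.chemical_class,
    )
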