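"""End-to-end workflow: simulate -> exposure -> genetics -> association.

All tables are plain CSV with fixed headers:

applications.csv   pesticide_id, chemical_class, year, x_m, y_m, pounds, acres
addresses.csv      subject_id, year, setting, x_m, y_m   (empty = missing geocode)
subjects.csv       subject_id, status, age_years, sex, smoker_ever, index_year, genotype
exposure_profiles.csv  subject_id, setting, pesticide_id, window_average, high_flag
class_exposure.csv subject_id, chemical_class, n_pesticides_exposed, category, exposed
thresholds.csv     pesticide_id, setting, threshold, n_exposed_controls
genetics_summary.csv   per-group genotype counts, allele frequency, HWE tests
table1.csv         marginal genotype effects
table2.csv         genotype x exposure ORs for every class x genetic model
manifest.json      seed, config hash, row counts, exclusions per stage

A RunManifest records, for every stage, input/output row counts and every
exclusion with exactly one reason, so counts reconcile across stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    DEFAULT_COVARIATES,
    genotype_table,
    gxe_analysis,
)
from .config import CHEMICAL_CLASSES, ExposureConfig, SimConfig
from .errors import AmbientGxeError, InestimableError, ModelError
from .exposure import class_exposure_vector, compute_exposure
from .genetics import genotype_summary
from .synthetic import generate_applications, generate_cohort

SUBJECT_COLUMNS = [
    "subject_id",
    "status",
    "age_years",
    "sex",
    "smoker_ever",
    "index_year",
    "genotype",
]


@dataclass
class RunManifest:
    """Structured record of one pipeline run."""

    seed: int
    config_hash: str
    version: str = __version__
    stages: dict = field(default_factory=dict)
    exclusions: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def record_stage(self, name: str, **counts) -> None:
        self.stages[name] = counts

    def record_exclusions(self, analysis: str, drop_log: dict) -> None:
        self.exclusions[analysis] = drop_log

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def config_hash(sim: SimConfig, exposure: ExposureConfig) -> str:
    blob = yaml.safe_dump(
        {
            "simulation": dataclasses.asdict(sim),
            "exposure": dataclasses.asdict(exposure),
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_tables(outdir, **tables) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)


def read_inputs(indir):
    """Read the three standard input tables from a directory."""
    indir = Path(indir)
    applications = pd.read_csv(indir / "applications.csv")
    addresses = pd.read_csv(indir / "addresses.csv")
    subjects = pd.read_csv(indir / "subjects.csv")
    return applications, addresses, subjects


def run_pipeline(
    sim: SimConfig | None = None,
    exposure_cfg: ExposureConfig | None = None,
    outdir=None,
    classes=tuple(CHEMICAL_CLASSES),
    models=("additive", "homozygote_contrast"),
    covariates=DEFAULT_COVARIATES,
):
    """One-command end-to-end run on synthetic data.

    Executes simulate -> exposure -> genetics -> association for every
    chemical class crossed with both genetic models, writes all output
    tables plus the manifest when ``outdir`` is given, and returns
    (manifest, dict of tables).  Deterministic given ``sim.seed``.

    An association fit that fails because the interaction is inestimable
    (e.g. an empty exposed cell) is recorded in the manifest and in
    table2 rather than aborting the run.
    """
    sim = sim or SimConfig()
    exposure_cfg = exposure_cfg or ExposureConfig()
    sim.validate()
    exposure_cfg.validate()
    manifest = RunManifest(seed=sim.seed, config_hash=config_hash(sim, exposure_cfg))
    tables: dict[str, pd.DataFrame] = {}

    stage = "simulate"
    try:
        applications = generate_applications(sim)
        cohort = generate_cohort(sim, applications, exposure_cfg)
        tables["applications"] = applications
        tables["addresses"] = cohort.addresses
        tables["subjects"] = cohort.subjects[SUBJECT_COLUMNS]
        manifest.record_stage(
            stage,
            n_applications=len(applications),
            n_subjects=len(cohort.subjects),
            n_address_rows=len(cohort.addresses),
            source_case_fraction=cohort.truth["source_case_fraction"],
            source_exposed_fraction=cohort.truth["source_exposed_fraction"],
        )

        stage = "exposure"
        exp_result = compute_exposure(
            applications, cohort.addresses, cohort.subjects, exposure_cfg
        )
        tables["exposure_profiles"] = exp_result.profiles
        tables["class_exposure"] = exp_result.class_exposure.reset_index(drop=True)
        tables["thresholds"] = exp_result.thresholds
        manifest.record_stage(
            stage,
            n_profiles=len(exp_result.profiles),
            n_excluded_undefined_exposure=len(exp_result.excluded_subjects),
            n_analysed=len(cohort.subjects) - len(exp_result.excluded_subjects),
        )
        manifest.record_exclusions(
            "exposure",
            {"undefined_exposure": list(map(str, exp_result.excluded_subjects))},
        )

        stage = "genetics"
        by_group = {
            status: cohort.subjects.loc[
                cohort.subjects["status"] == status, "genotype"
            ].to_numpy()
            for status in ("case", "control")
        }
        tables["genetics_summary"] = genotype_summary(by_group)
        manifest.record_stage(stage, n_groups=2)

        stage = "association"
        counts, estimates = genotype_table(cohort.subjects, covariates)
        tables["table1_counts"] = counts
        tables["table1"] = estimates
        analysed_ids = set(cohort.subjects["subject_id"]) - set(
            map(str, exp_result.excluded_subjects)
        )
        subjects_analysed = cohort.subjects[
            cohort.subjects["subject_id"].isin(analysed_ids)
        ]
        t2_frames = []
        for cls in classes:
            exposed = class_exposure_vector(exp_result, cls)
            for model in models:
                try:
                    res = gxe_analysis(
                        subjects_analysed,
                        exposed,
                        model=model,
                        covariates=covariates,
                        chemical_class=cls,
                    )
                except (InestimableError, ModelError) as exc:
                    manifest.errors[f"gxe:{cls}:{model}"] = str(exc)
                    t2_frames.append(
                        pd.DataFrame(
                            [
                                {
                                    "chemical_class": cls,
                                    "model": model,
                                    "error": str(exc),
                                }
                            ]
                        )
                    )
                    continue
                t2 = res.table()
                t2["model"] = model
                t2["interaction_p_wald"] = res.interaction_p_wald
                t2["interaction_p_lrt"] = res.interaction_p_lrt
                t2_frames.append(t2)
                manifest.record_exclusions(
                    f"gxe:{cls}:{model}", res.drop_log.as_dict()
                )
        tables["table2"] = pd.concat(t2_frames, ignore_index=True)
        manifest.record_stage(
            stage,
            n_class_model_fits=sum(
                1 for k in manifest.exclusions if k.startswith("gxe:")
            ),
            n_inestimable=len(manifest.errors),
        )
    except AmbientGxeError as exc:
        manifest.errors[stage] = str(exc)
        if outdir is not None:
            write_tables(outdir, **tables)
            manifest.write(Path(outdir) / "manifest.json")
        raise

    if outdir is not None:
        write_tables(outdir, **tables)
        manifest.write(Path(outdir) / "manifest.json")
    return manifest, tables
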