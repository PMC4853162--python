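"""Configuration objects for the simulation and analysis pipeline.

Three dataclasses mirror the pipeline stages: :class:`SimConfig` for the
synthetic cohort generator, :class:`ExposureConfig` for the ambient-exposure
engine, and :class:`PowerSpec` for simulation-based power.  Configs can be
loaded from a YAML file (nested sections ``simulation:``, ``exposure:``,
``power:``) and are validated eagerly; any violation raises
:class:`~ambientgxe.errors.ConfigError`.

Randomness is organised as one RNG stream per generator stage, each derived
from the master seed by a fixed label, so changing one stage's parameters
does not perturb the draws of another.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigError

# Chemical classes examined, and the pesticides in each.  Pyrethroid names
# follow the products recorded in California use reports for this class.
PYRETHROIDS = (
    "fenvalerate",
    "permethrin",
    "phenothrin",
    "resmethrin",
    "flucythrinate",
    "cypermethrin",
    "s-cypermethrin",
    "tau-fluvalinate",
    "fenpropathrin",
    "lambda-cyhalothrin",
    "bifenthrin",
    "esfenvalerate",
    "tralomethrin",
)
ORGANOPHOSPHATES = (
    "chlorpyrifos",
    "malathion",
    "parathion",
    "diazinon",
    "dimethoate",
    "methidathion",
)
DITHIOCARBAMATES = ("maneb", "ziram", "mancozeb", "thiram")
PARAQUAT = ("paraquat",)

CHEMICAL_CLASSES = {
    "pyrethroid": PYRETHROIDS,
    "organophosphate": ORGANOPHOSPHATES,
    "dithiocarbamate": DITHIOCARBAMATES,
    "paraquat": PARAQUAT,
}

# Fixed stage labels -> offsets for per-stage RNG streams.
_STAGE_LABELS = {
    "applications": 0,
    "genotypes": 1,
    "addresses": 2,
    "covariates": 3,
    "outcomes": 4,
    "sampling": 5,
    "power": 6,
    "expression": 7,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return the RNG stream for one generator stage.

    Streams for distinct stages are statistically independent and fixed by
    (seed, stage) alone.
    """
    try:
        offset = _STAGE_LABELS[stage]
    except KeyError:
        raise ConfigError(f"unknown RNG stage label: {stage!r}") from None
    return np.random.default_rng(np.random.SeedSequence([int(seed), offset]))


@dataclass
class ClassIntensity:
    """Application-process parameters for one chemical class.

    events_per_year is the expected number of application events for the
    whole class over the whole region (a homogeneous Poisson process in
    space and time, split uniformly among the class's pesticides).
    pounds and acres are drawn lognormally: ``exp(Normal(mu, sigma))``.
    """

    events_per_year: float = 5.0
    pounds_mu: float = 3.5   # median ~33 lb per application
    pounds_sigma: float = 0.8
    acres_mu: float = 2.8    # median ~16 acres treated
    acres_sigma: float = 0.6

    def validate(self) -> None:
        if self.events_per_year < 0:
            raise ConfigError("events_per_year must be >= 0")
        if self.pounds_sigma < 0 or self.acres_sigma < 0:
            raise ConfigError("lognormal sigma must be >= 0")


def _default_intensities() -> dict:
    # Class totals chosen so that, with the default 10 km x 10 km region and
    # 500-m buffers, the fraction of controls in the "exposed" category is
    # close to the ~28% seen for pyrethroids in the motivating study design.
    return {
        "pyrethroid": ClassIntensity(events_per_year=3.4),
        "organophosphate": ClassIntensity(events_per_year=6.0),
        "dithiocarbamate": ClassIntensity(events_per_year=4.0),
        "paraquat": ClassIntensity(events_per_year=2.0),
    }


@dataclass
class DiseaseModel:
    """Coefficients of the logistic disease model on the log-odds scale.

    logit P(case) = b0 + bg*G + be*E + bge*G*E + bage*(age - 65) + bsex*male
                    + bsmoke*smoker
    with G the risk-allele count (0/1/2) and E the binary class-level
    exposure for ``exposure_class``.
    """

    b0: float = -1.0986      # source-population log-odds; ORs are invariant
    bg: float = 0.0
    be: float = 0.0
    bge: float = 0.5008      # per-allele interaction, exp() ~ 1.65
    bage: float = 0.02
    bsex: float = 0.4        # male vs female
    bsmoke: float = -0.35    # ever- vs never-smoker
    exposure_class: str = "pyrethroid"

    def validate(self) -> None:
        if self.exposure_class not in CHEMICAL_CLASSES:
            raise ConfigError(
                f"unknown exposure_class: {self.exposure_class!r}"
            )


@dataclass
class SimConfig:
    """Full parameterisation of the synthetic cohort generator."""

    n_cases: int = 465
    n_controls: int = 497
    risk_allele_freq: float = 0.42
    seed: int = 0

    region_width_m: float = 10_000.0
    region_height_m: float = 10_000.0
    start_year: int = 1974
    index_year_min: int = 1998
    index_year_max: int = 2007

    missing_rate: float = 0.10
    occupational_fraction: float = 0.6
    source_multiplier: float = 3.0
    match_controls_by_age: bool = False

    age_mean: float = 65.0
    age_sd: float = 10.0
    age_min: float = 35.0
    age_max: float = 90.0
    male_fraction: float = 0.5
    smoker_fraction: float = 0.5

    intensities: dict = field(default_factory=_default_intensities)
    disease: DiseaseModel = field(default_factory=DiseaseModel)

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ConfigError("case and control counts must be positive")
        if not 0.0 <= self.risk_allele_freq <= 1.0:
            raise ConfigError("risk_allele_freq must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.region_width_m <= 0 or self.region_height_m <= 0:
            raise ConfigError("region must have positive area")
        if self.index_year_min < 1984:
            raise ConfigError(
                "index_year_min must be >= 1984 so the exposure window "
                "1974..index-10 is non-empty"
            )
        if self.index_year_max < self.index_year_min:
            raise ConfigError("index_year_max < index_year_min")
        if self.source_multiplier <= 1.0:
            raise ConfigError("source_multiplier must exceed 1")
        for name, intensity in self.intensities.items():
            if name not in CHEMICAL_CLASSES:
                raise ConfigError(f"unknown chemical class: {name!r}")
            intensity.validate()
        self.disease.validate()

    @property
    def n_subjects(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def years(self) -> range:
        return range(self.start_year, self.index_year_max + 1)


@dataclass
class ExposureConfig:
    """Parameters of the ambient-exposure assessment."""

    radius_m: float = 500.0
    start_year: int = 1974
    lag_years: int = 10
    combine_settings: str = "either"   # either | both | residential_only | occupational_only
    count_rule: str = "at_or_above_median"  # or "any_nonzero"

    def validate(self) -> None:
        if self.radius_m <= 0:
            raise ConfigError("radius_m must be positive")
        if self.lag_years < 0:
            raise ConfigError("lag_years must be >= 0")
        if self.combine_settings not in (
            "either",
            "both",
            "residential_only",
            "occupational_only",
        ):
            raise ConfigError(
                f"unknown combine_settings: {self.combine_settings!r}"
            )
        if self.count_rule not in ("at_or_above_median", "any_nonzero"):
            raise ConfigError(f"unknown count_rule: {self.count_rule!r}")


@dataclass
class PowerSpec:
    """Specification of a simulation-based power run."""

    sim: SimConfig = field(default_factory=SimConfig)
    exposure: ExposureConfig = field(default_factory=ExposureConfig)
    alpha: float = 0.05
    n_replicates: int = 500
    model: str = "additive"  # or homozygote_contrast
    chemical_class: str = "pyrethroid"

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie strictly in (0, 1)")
        if self.n_replicates < 100:
            raise ConfigError("n_replicates must be >= 100")
        if self.model not in ("additive", "homozygote_contrast"):
            raise ConfigError(f"unknown model: {self.model!r}")
        if self.chemical_class not in CHEMICAL_CLASSES:
            raise ConfigError(f"unknown chemical class: {self.chemical_class!r}")
        self.sim.validate()
        self.exposure.validate()


def _build(cls, data: dict, path: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"section {path!r} must be a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"unknown keys in {path!r}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        if f.name == "intensities":
            kwargs[key] = {
                cname: _build(ClassIntensity, cval, f"{path}.{key}.{cname}")
                for cname, cval in value.items()
            }
        elif f.name == "disease":
            kwargs[key] = _build(DiseaseModel, value, f"{path}.{key}")
        elif f.name == "sim":
            kwargs[key] = _build(SimConfig, value, f"{path}.{key}")
        elif f.name == "exposure":
            kwargs[key] = _build(ExposureConfig, value, f"{path}.{key}")
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"bad section {path!r}: {exc}") from exc


def load_config(path) -> tuple[SimConfig, ExposureConfig]:
    """Read a YAML config file with ``simulation:`` and ``exposure:`` sections.

    Missing sections fall back to defaults.  Returns a validated
    (SimConfig, ExposureConfig) pair.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping at top level")
    unknown = set(raw) - {"simulation", "exposure", "power"}
    if unknown:
        raise ConfigError(f"unknown top-level sections: {sorted(unknown)}")
    sim = _build(SimConfig, raw.get("simulation", {}), "simulation")
    exposure = _build(ExposureConfig, raw.get("exposure", {}), "exposure")
    sim.validate()
    exposure.validate()
    return sim, exposure


def load_power_spec(path) -> PowerSpec:
    """Read a YAML config, returning a validated PowerSpec."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    power_raw = dict(raw.get("power", {}))
    if "simulation" in raw:
        power_raw.setdefault("sim", raw["simulation"])
    if "exposure" in raw:
        power_raw.setdefault("exposure", raw["exposure"])
    spec = _build(PowerSpec, power_raw, "power")
    spec.validate()
    return spec
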