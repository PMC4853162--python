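"""Ambient pesticide exposure assessment.

The model of exposure is GIS-style: every commercial application event has a
point location; a subject's annual exposure to a pesticide at an address is
the sum of pounds-per-acre over all applications of that pesticide, that
year, within a fixed-radius circular buffer of the address (boundary
inclusive, planar Euclidean distance).  Yearly values are averaged over the
study window [start_year, index_year - lag_years] (both endpoints
inclusive); years whose address could not be geocoded are imputed with the
mean of the subject's recorded years in the window.  Pesticide-level
exposure is dichotomised at the median window average among *exposed*
controls (window average > 0), labelling a subject high when at or above
it.  Class-level exposure then counts high pesticides per chemical class:
organophosphates and dithiocarbamates are split at the median count among
exposed controls, pyrethroids at one-or-more, and paraquat (a single agent)
follows its own pesticide label.

Two code paths compute window averages: a record-level path that follows
the operations above literally, and a vectorised path used by the pipeline
and the power simulator.  Because every missing year is imputed with the
mean of the recorded in-window years, the imputed window average equals the
plain mean of the recorded in-window annual sums; the vectorised path uses
that identity and the tests pin the two paths together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import CHEMICAL_CLASSES, ExposureConfig
from .errors import (
    DataError,
    InvalidWindowError,
    ThresholdUndefinedError,
    UndefinedExposureError,
)

SETTINGS = ("residential", "occupational")

# class-level category labels: (not-exposed label, exposed label)
CLASS_CATEGORIES = {
    "organophosphate": ("low_or_none", "high"),
    "dithiocarbamate": ("low_or_none", "high"),
    "pyrethroid": ("none", "any"),
    "paraquat": ("unexposed", "exposed"),
}


def exposure_window(index_year: int, cfg: ExposureConfig) -> range:
    """Study window [start_year .. index_year - lag_years], inclusive."""
    end = index_year - cfg.lag_years
    if end < cfg.start_year:
        raise InvalidWindowError(
            f"index year {index_year} with lag {cfg.lag_years} leaves an "
            f"empty window before {cfg.start_year}"
        )
    return range(cfg.start_year, end + 1)


# ---------------------------------------------------------------------------
# record-level operations


def annual_buffer_sum(
    applications: pd.DataFrame,
    point,
    year: int,
    pesticide_id: str,
    cfg: ExposureConfig,
) -> float:
    """Sum of pounds/acres over matching applications within the buffer.

    An application matches when its pesticide and calendar year equal the
    query and its location lies within ``cfg.radius_m`` (inclusive) of
    ``point``.  An empty sum is 0.
    """
    x, y = float(point[0]), float(point[1])
    if not (np.isfinite(x) and np.isfinite(y)):
        raise DataError("query point must have finite coordinates")
    df = applications
    mask = (df["pesticide_id"].to_numpy() == pesticide_id) & (
        df["year"].to_numpy() == year
    )
    if not mask.any():
        return 0.0
    dx = df["x_m"].to_numpy()[mask] - x
    dy = df["y_m"].to_numpy()[mask] - y
    within = dx * dx + dy * dy <= cfg.radius_m**2
    rates = df["pounds"].to_numpy()[mask][within] / df["acres"].to_numpy()[mask][
        within
    ]
    return float(rates.sum())


def impute_missing_years(yearly_values: dict, window) -> tuple[dict, set]:
    """Fill missing (None/NaN) years with the mean of recorded years.

    Returns (complete mapping over ``window``, set of imputed years).
    Recorded values pass through unchanged.  Raises UndefinedExposureError
    when no year in the window is recorded.
    """
    window = list(window)
    recorded = {
        yr: float(yearly_values[yr])
        for yr in window
        if yr in yearly_values
        and yearly_values[yr] is not None
        and np.isfinite(yearly_values[yr])
    }
    if not recorded:
        raise UndefinedExposureError(
            "no recorded (geocoded) years in the exposure window"
        )
    mean_recorded = sum(recorded.values()) / len(recorded)
    complete = {}
    imputed = set()
    for yr in window:
        if yr in recorded:
            complete[yr] = recorded[yr]
        else:
            complete[yr] = mean_recorded
            imputed.add(yr)
    return complete, imputed


def window_average(
    yearly_values: dict, index_year: int, cfg: ExposureConfig
) -> float:
    """Arithmetic mean of the (already imputed) yearly values over the window."""
    window = exposure_window(index_year, cfg)
    try:
        vals = [float(yearly_values[yr]) for yr in window]
    except KeyError as exc:
        raise DataError(f"year {exc.args[0]} missing from yearly values") from None
    if any(not np.isfinite(v) for v in vals):
        raise DataError("yearly values contain non-finite entries; impute first")
    return float(np.mean(vals))


def dichotomize_pesticide(
    window_averages: pd.Series, is_control: pd.Series
) -> tuple[pd.Series, float]:
    """Label subjects high at/above the exposed-control median.

    ``window_averages`` maps subject -> window-average exposure for one
    pesticide (one setting, or combined); ``is_control`` is aligned boolean.
    "Exposed" controls are those with a strictly positive window average.
    Returns (boolean high labels, threshold).  A subject with window
    average 0 is never high.
    """
    exposed_controls = window_averages[is_control & (window_averages > 0)]
    if exposed_controls.empty:
        raise ThresholdUndefinedError(
            "no exposed control: median threshold undefined"
        )
    threshold = float(np.median(exposed_controls.to_numpy()))
    high = (window_averages > 0) & (window_averages >= threshold)
    return high, threshold


def classify_class_exposure(
    high_flags: pd.DataFrame,
    chemical_class: str,
    is_control: pd.Series,
) -> pd.DataFrame:
    """Class-level exposure categories from per-pesticide high labels.

    ``high_flags`` is a subjects x pesticides boolean frame (already
    combined across settings); organophosphates/dithiocarbamates are split
    at the median count among controls with count >= 1, pyrethroids at
    one-or-more, paraquat follows its single pesticide.
    """
    if chemical_class not in CLASS_CATEGORIES:
        raise DataError(f"unknown chemical class: {chemical_class!r}")
    counts = high_flags.sum(axis=1).astype(int)
    low_label, high_label = CLASS_CATEGORIES[chemical_class]
    if chemical_class == "pyrethroid":
        exposed = counts >= 1
    elif chemical_class == "paraquat":
        exposed = counts >= 1
    else:
        control_counts = counts[is_control & (counts >= 1)]
        if control_counts.empty:
            if (counts >= 1).any():
                raise ThresholdUndefinedError(
                    f"no control with any high {chemical_class} pesticide: "
                    "count threshold undefined"
                )
            exposed = counts >= 1  # nobody exposed at all: all low/none
        else:
            count_threshold = float(np.median(control_counts.to_numpy()))
            exposed = (counts >= 1) & (counts >= count_threshold)
    return pd.DataFrame(
        {
            "subject_id": high_flags.index,
            "chemical_class": chemical_class,
            "n_pesticides_exposed": counts.to_numpy(),
            "category": np.where(exposed, high_label, low_label),
            "exposed": exposed.to_numpy(),
        }
    ).set_index("subject_id", drop=False)


# ---------------------------------------------------------------------------
# vectorised engine


@dataclass
class ExposureResult:
    """Output of the full exposure-assessment stage."""

    profiles: pd.DataFrame       # subject_id, setting, pesticide_id, window_average, high_flag
    thresholds: pd.DataFrame     # pesticide_id, setting, threshold, n_exposed_controls
    class_exposure: pd.DataFrame  # subject_id, chemical_class, n_pesticides_exposed, category, exposed
    excluded_subjects: list = field(default_factory=list)
    class_count_thresholds: dict = field(default_factory=dict)


def _recorded_window_averages(
    applications: pd.DataFrame,
    addresses: pd.DataFrame,
    windows: dict,
    cfg: ExposureConfig,
):
    """Window averages per (subject, setting, pesticide), vectorised.

    For each recorded address-year a KD-tree query collects applications
    within the buffer; rates of year-matching hits accumulate into
    per-(subject, setting, pesticide) sums, divided by the number of
    recorded in-window years (the imputation identity).

    Returns (avg: dict setting -> DataFrame subjects x pesticides,
    n_recorded: dict setting -> Series, pesticides: Index).
    """
    pest_ids = pd.Index(sorted(applications["pesticide_id"].unique()))
    pest_pos = {p: i for i, p in enumerate(pest_ids)}
    app_xy = applications[["x_m", "y_m"]].to_numpy(dtype=float)
    app_year = applications["year"].to_numpy(dtype=int)
    app_pest = applications["pesticide_id"].map(pest_pos).to_numpy(dtype=int)
    app_rate = (
        applications["pounds"].to_numpy(dtype=float)
        / applications["acres"].to_numpy(dtype=float)
    )
    tree = cKDTree(app_xy) if len(applications) else None

    subj_ids = pd.Index(sorted(windows))
    subj_pos = {s: i for i, s in enumerate(subj_ids)}
    win_lo = np.array([windows[s].start for s in subj_ids])
    win_hi = np.array([windows[s].stop - 1 for s in subj_ids])

    averages, n_recorded = {}, {}
    for setting in SETTINGS:
        rows = addresses[addresses["setting"] == setting]
        rows = rows[rows["subject_id"].isin(subj_pos)]
        sub = rows["subject_id"].map(subj_pos).to_numpy(dtype=int)
        yr = rows["year"].to_numpy(dtype=int)
        xs = rows["x_m"].to_numpy(dtype=float)
        ys = rows["y_m"].to_numpy(dtype=float)
        recorded = np.isfinite(xs) & np.isfinite(ys)
        in_window = (yr >= win_lo[sub]) & (yr <= win_hi[sub])
        keep = recorded & in_window
        sub_k, yr_k = sub[keep], yr[keep]
        pts = np.column_stack([xs[keep], ys[keep]])

        n_rec = np.zeros(len(subj_ids), dtype=int)
        np.add.at(n_rec, sub_k, 1)

        sums = np.zeros((len(subj_ids), len(pest_ids)))
        if tree is not None and len(pts):
            hits = tree.query_ball_point(pts, r=cfg.radius_m)
            addr_idx = np.fromiter(
                (i for i, h in enumerate(hits) for _ in h),
                dtype=int,
                count=sum(len(h) for h in hits),
            )
            app_idx = np.fromiter(
                (j for h in hits for j in h),
                dtype=int,
                count=len(addr_idx),
            )
            if len(addr_idx):
                match = app_year[app_idx] == yr_k[addr_idx]
                a_i, p_i = addr_idx[match], app_idx[match]
                np.add.at(sums, (sub_k[a_i], app_pest[p_i]), app_rate[p_i])

        with np.errstate(invalid="ignore", divide="ignore"):
            avg = np.where(n_rec[:, None] > 0, sums / np.maximum(n_rec, 1)[:, None], np.nan)
        averages[setting] = pd.DataFrame(avg, index=subj_ids, columns=pest_ids)
        n_recorded[setting] = pd.Series(n_rec, index=subj_ids)
    return averages, n_recorded, pest_ids


def _combine_high(high_by_setting: dict, mode: str) -> pd.DataFrame:
    res = high_by_setting["residential"]
    occ = high_by_setting["occupational"]
    if mode == "either":
        return res | occ
    if mode == "both":
        return res & occ
    if mode == "residential_only":
        return res
    if mode == "occupational_only":
        return occ
    raise DataError(f"unknown combine_settings: {mode!r}")


def compute_exposure(
    applications: pd.DataFrame,
    addresses: pd.DataFrame,
    subjects: pd.DataFrame,
    cfg: ExposureConfig | None = None,
    on_undefined_threshold: str = "all_unexposed",
) -> ExposureResult:
    """Run the full exposure-assessment stage for a cohort.

    Parameters
    ----------
    applications, addresses, subjects : the three standard tables
        (see the CSV schemas in :mod:`ambientgxe.pipeline`).
    cfg : exposure parameters; defaults used when None.
    on_undefined_threshold : ``"all_unexposed"`` treats a pesticide (or a
        class count) with no exposed control as exposing nobody;
        ``"raise"`` propagates ThresholdUndefinedError.

    Subjects with zero recorded in-window years across every setting are
    excluded (listed in ``excluded_subjects``) and take no part in
    threshold building.
    """
    cfg = cfg or ExposureConfig()
    cfg.validate()
    if on_undefined_threshold not in ("all_unexposed", "raise"):
        raise DataError(
            f"unknown on_undefined_threshold: {on_undefined_threshold!r}"
        )
    windows = {
        row.subject_id: exposure_window(int(row.index_year), cfg)
        for row in subjects.itertuples()
    }
    averages, n_recorded, pest_ids = _recorded_window_averages(
        applications, addresses, windows, cfg
    )
    subj_ids = averages["residential"].index
    total_recorded = sum(n_recorded[s] for s in SETTINGS)
    excluded = list(subj_ids[total_recorded == 0])
    analysed = subj_ids[total_recorded > 0]

    status = subjects.set_index("subject_id")["status"].reindex(subj_ids)
    is_control = (status == "control") & subj_ids.isin(analysed)

    # per-(pesticide, setting) thresholds and high labels
    high_by_setting = {}
    thr_rows = []
    for setting in SETTINGS:
        avg = averages[setting].fillna(0.0)
        avg.loc[n_recorded[setting] == 0] = 0.0  # absent setting: no exposure
        high = pd.DataFrame(False, index=subj_ids, columns=pest_ids)
        for pest in pest_ids:
            vals = avg[pest]
            try:
                labels, thr = dichotomize_pesticide(vals, is_control)
            except ThresholdUndefinedError:
                if on_undefined_threshold == "raise" and (vals > 0).any():
                    raise
                labels, thr = pd.Series(False, index=subj_ids), np.nan
            high[pest] = labels
            thr_rows.append(
                {
                    "pesticide_id": pest,
                    "setting": setting,
                    "threshold": thr,
                    "n_exposed_controls": int(
                        (is_control & (vals > 0)).sum()
                    ),
                }
            )
        high_by_setting[setting] = high
    thresholds = pd.DataFrame(thr_rows)

    if cfg.count_rule == "any_nonzero":
        flags_by_setting = {
            s: (averages[s].fillna(0.0) > 0) for s in SETTINGS
        }
    else:
        flags_by_setting = high_by_setting
    combined = _combine_high(flags_by_setting, cfg.combine_settings)
    combined = combined.loc[analysed]

    class_to_pests = {
        cls: [p for p in pest_ids if p in set(members)]
        for cls, members in CHEMICAL_CLASSES.items()
    }
    class_frames = []
    count_thresholds = {}
    ctrl_analysed = is_control.loc[analysed]
    for cls, pests in class_to_pests.items():
        flags = combined[pests] if pests else pd.DataFrame(
            False, index=analysed, columns=[]
        )
        try:
            frame = classify_class_exposure(flags, cls, ctrl_analysed)
        except ThresholdUndefinedError:
            if on_undefined_threshold == "raise":
                raise
            low_label, _ = CLASS_CATEGORIES[cls]
            counts = flags.sum(axis=1).astype(int)
            frame = pd.DataFrame(
                {
                    "subject_id": analysed,
                    "chemical_class": cls,
                    "n_pesticides_exposed": counts.to_numpy(),
                    "category": low_label,
                    "exposed": False,
                }
            ).set_index("subject_id", drop=False)
        if cls in ("organophosphate", "dithiocarbamate"):
            cc = frame.loc[ctrl_analysed.to_numpy(), "n_pesticides_exposed"]
            cc = cc[cc >= 1]
            count_thresholds[cls] = float(np.median(cc)) if len(cc) else np.nan
        class_frames.append(frame.reset_index(drop=True))
    class_exposure = pd.concat(class_frames, ignore_index=True)

    # long-format profiles for the pesticides that anybody contacted
    prof_frames = []
    for setting in SETTINGS:
        avg = averages[setting]
        present = n_recorded[setting] > 0
        stacked = avg.loc[present].stack()
        stacked = stacked[stacked > 0]
        if stacked.empty:
            continue
        prof = stacked.rename("window_average").reset_index()
        prof.columns = ["subject_id", "pesticide_id", "window_average"]
        prof["setting"] = setting
        hf = high_by_setting[setting].loc[present].stack().rename("high_flag")
        prof = prof.merge(
            hf.reset_index().rename(
                columns={"level_0": "subject_id", "level_1": "pesticide_id"}
            ),
            on=["subject_id", "pesticide_id"],
            how="left",
        )
        prof_frames.append(
            prof[["subject_id", "setting", "pesticide_id", "window_average", "high_flag"]]
        )
    profiles = (
        pd.concat(prof_frames, ignore_index=True)
        if prof_frames
        else pd.DataFrame(
            columns=["subject_id", "setting", "pesticide_id", "window_average", "high_flag"]
        )
    )
    return ExposureResult(
        profiles=profiles,
        thresholds=thresholds,
        class_exposure=class_exposure,
        excluded_subjects=excluded,
        class_count_thresholds=count_thresholds,
    )


def class_exposure_vector(
    result: ExposureResult, chemical_class: str
) -> pd.Series:
    """Binary exposed indicator for one class, indexed by subject_id."""
    sub = result.class_exposure
    sub = sub[sub["chemical_class"] == chemical_class]
    return sub.set_index("subject_id")["exposed"]
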