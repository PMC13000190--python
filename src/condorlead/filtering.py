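"""Data-preparation rules for condor blood-lead monitoring data.

This module implements every screening and summarisation step applied to the
raw monitoring tables before modelling:

* detection-limit flooring of laboratory blood-lead values,
* the between-sample independence rules (minimum spacing, the rising-exposure
  exception, same-event replacement, and care/pen exclusions),
* behaviour covariates computed over a trailing 180-day window of daily
  detection records,
* GPS fix quality control and foraging-location classification,
* hunt-tag correction for the 2015 deer reporting change, bimonthly smoothing
  and per-series standardisation,
* the pig cull-to-hunt ratio trend regression.

All functions accept and return :class:`pandas.DataFrame` objects with
documented column names; dates are ``datetime64`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

# Laboratory reporting floor (ug/dL) and the substitute value recorded for
# samples at or below it.
DETECTION_FLOOR = 5.0
FLOOR_SUBSTITUTE = 2.5

# Independence-rule constants (days / ug/dL).
MIN_GAP_DAYS = 56
EXCEPTION_MIN_GAP_DAYS = 14
EXCEPTION_RISE = 10.0
MAX_CARE_DAYS = 3
MAX_PEN_DAYS = 21

# Age-class boundaries in years post-fledge: FirstYear [0,1), Juvenile [1,6),
# YoungAdult [6,10), OlderAdult [10, inf).
AGE_CLASS_BOUNDS = {"FirstYear": (0.0, 1.0), "Juvenile": (1.0, 6.0),
                    "YoungAdult": (6.0, 10.0), "OlderAdult": (10.0, np.inf)}


def bioyear(date) -> int:
    """Bioyear label (September–August year, labelled by its starting year).

    A date in Sep–Dec of calendar year Y belongs to Bioyear Y; Jan–Aug
    belongs to Bioyear Y-1.
    """
    ts = pd.Timestamp(date)
    return ts.year if ts.month >= 9 else ts.year - 1


def is_spring_summer(date) -> bool:
    """Season flag: March through August."""
    return 3 <= pd.Timestamp(date).month <= 8


def floor_detection_limit(value: float) -> tuple[float, bool]:
    """Apply the reporting floor to a single blood-lead value.

    Values at or below 5 ug/dL are recorded as 2.5 ug/dL and flagged as
    censored at the floor; values above 5 pass through unchanged.

    Returns ``(recorded_value, censored)``.
    """
    if value < 0:
        raise ValueError(f"blood lead value must be nonnegative, got {value}")
    if value <= DETECTION_FLOOR:
        return FLOOR_SUBSTITUTE, True
    return float(value), False


def apply_detection_floor(samples: pd.DataFrame,
                          value_col: str = "value") -> pd.DataFrame:
    """Vectorised detection-limit flooring over a samples table.

    Adds/overwrites a boolean ``censored`` column and replaces floored
    values with the substitute.
    """
    vals = samples[value_col].to_numpy(dtype=float)
    if (vals < 0).any():
        bad = samples.index[vals < 0][:5].tolist()
        raise ValueError(f"negative blood lead values at rows {bad}")
    out = samples.copy()
    censored = vals <= DETECTION_FLOOR
    out[value_col] = np.where(censored, FLOOR_SUBSTITUTE, vals)
    out["censored"] = censored
    return out


def select_independent_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Apply the between-sample independence rules.

    ``samples`` must be sorted by (ID, date) and carry columns ``ID``,
    ``date``, ``value`` and optionally ``days_in_care`` / ``days_in_pen``.

    Per individual, scanning chronologically against the last *retained*
    sample:

    * gap > 56 days: retain (rule a);
    * 14–56 days (inclusive) and value more than 10 ug/dL higher than the
      last retained value: retain as an independent exposure event (rule b);
    * < 14 days and higher: the later sample replaces the earlier one —
      rising lead from the same exposure event; replacements chain, so the
      replacement becomes the comparator for subsequent samples;
    * otherwise: drop.

    Samples preceded by more than 3 days of veterinary care or 21 days in a
    field pen are dropped before the scan.
    """
    required = {"ID", "date", "value"}
    if not required.issubset(samples.columns):
        raise ValueError(f"samples table needs columns {sorted(required)}")
    idx_sorted = samples.sort_values(["ID", "date"]).index
    if not idx_sorted.equals(samples.index):
        raise ValueError("samples must be sorted by (ID, date)")

    df = samples
    if "days_in_care" in df.columns:
        df = df[df["days_in_care"].fillna(0) <= MAX_CARE_DAYS]
    if "days_in_pen" in df.columns:
        df = df[df["days_in_pen"].fillna(0) <= MAX_PEN_DAYS]

    keep_index: list = []
    for _, grp in df.groupby("ID", sort=False):
        dates = grp["date"].to_numpy()
        values = grp["value"].to_numpy(dtype=float)
        retained: list[int] = []  # positions within grp
        for i in range(len(grp)):
            if not retained:
                retained.append(i)
                continue
            last = retained[-1]
            gap = (dates[i] - dates[last]) / np.timedelta64(1, "D")
            if gap > MIN_GAP_DAYS:
                retained.append(i)
            elif gap >= EXCEPTION_MIN_GAP_DAYS and \
                    values[i] > values[last] + EXCEPTION_RISE:
                retained.append(i)
            elif gap < EXCEPTION_MIN_GAP_DAYS and values[i] > values[last]:
                retained[-1] = i  # same event, rising: replace
            # else: drop
        keep_index.extend(grp.index[retained])
    return samples.loc[keep_index]


@dataclass
class BehaviorCovariates:
    """Foraging/ranging behaviour summaries over the trailing window."""
    proffered: float
    presence: float
    coastal: float
    free_fly: float
    free_flying_days: int


def compute_behavior_metrics(daily: pd.DataFrame, condor_id, as_of_date,
                             window: int = 180) -> BehaviorCovariates | None:
    """Behaviour covariates for one individual at a sampling date.

    The window is the ``window`` days strictly before ``as_of_date``.
    ``daily`` needs columns ``ID``, ``date`` and boolean flags ``free_flying``,
    ``detected``, ``proffered``, ``coastal``.

    Proffered / Presence / Coastal are proportions of *free-flying* days in
    the window on which the bird was (respectively) seen feeding at a
    proffered carcass, detected without a proffered-feeding observation, or
    observed in the coastal zone. FreeFly is the proportion of window days
    free-flying. Returns ``None`` when the bird had no free-flying days in
    the window (metrics undefined; the sample is excluded downstream).
    """
    end = pd.Timestamp(as_of_date)
    start = end - pd.Timedelta(days=window)
    mask = (daily["ID"] == condor_id) & (daily["date"] >= start) & \
        (daily["date"] < end)
    win = daily.loc[mask]
    ff = win["free_flying"].to_numpy(dtype=bool)
    n_ff = int(ff.sum())
    if n_ff == 0:
        return None
    proffered = win["proffered"].to_numpy(dtype=bool) & ff
    detected = win["detected"].to_numpy(dtype=bool) & ff
    coastal = win["coastal"].to_numpy(dtype=bool) & ff
    return BehaviorCovariates(
        proffered=proffered.sum() / n_ff,
        presence=(detected & ~proffered).sum() / n_ff,
        coastal=coastal.sum() / n_ff,
        free_fly=n_ff / window,
        free_flying_days=n_ff,
    )


def age_class(age_years: float) -> str:
    """Age class label for an age in years post-fledge."""
    for label, (lo, hi) in AGE_CLASS_BOUNDS.items():
        if lo <= age_years < hi:
            return label
    raise ValueError(f"age must be nonnegative, got {age_years}")


# ---------------------------------------------------------------------------
# Hunt-tag series
# ---------------------------------------------------------------------------

DEER_CORRECTION = 1.53
DEER_CORRECTION_LAST_YEAR = 2014  # correction applies to years before 2015


def correct_and_smooth_hunts(series: pd.DataFrame) -> pd.DataFrame:
    """Correct, smooth and standardise a monthly hunt-tag series.

    ``series`` needs columns ``region``, ``species`` ('deer'|'pig'),
    ``year``, ``month`` and ``count``, with complete consecutive months per
    (region, species). Deer counts before calendar 2015 are multiplied by
    1.53 to correct for the tag-reporting change; the bimonthly value for a
    month is the mean of the corrected counts for that month and the one
    before (first month: its own value); standardised values divide the
    bimonthly series by its per-(region, species) maximum.
    """
    out = []
    for (region, species), grp in series.groupby(["region", "species"]):
        grp = grp.sort_values(["year", "month"]).copy()
        months = grp["year"] * 12 + (grp["month"] - 1)
        gaps = np.diff(months.to_numpy())
        if (gaps != 1).any():
            where = grp.iloc[1:][gaps != 1][["year", "month"]]
            raise ValueError(
                f"missing months in hunt series {region}/{species} before "
                f"{where.to_records(index=False).tolist()}")
        raw = grp["count"].to_numpy(dtype=float)
        corrected = raw.copy()
        if species == "deer":
            corrected[grp["year"].to_numpy() <= DEER_CORRECTION_LAST_YEAR] \
                *= DEER_CORRECTION
        bimonthly = corrected.copy()
        bimonthly[1:] = 0.5 * (corrected[1:] + corrected[:-1])
        grp["corrected"] = corrected
        grp["bimonthly"] = bimonthly
        peak = bimonthly.max()
        grp["standardized"] = bimonthly / peak if peak > 0 else 0.0
        out.append(grp)
    return pd.concat(out, ignore_index=True)


def cull_hunt_trend(ratios: pd.DataFrame) -> dict:
    """Trend in the annual pig cull-to-hunt ratio.

    ``ratios`` needs columns ``bioyear``, ``cull`` and ``hunt`` (annual
    totals). Returns the simple linear regression of cull/hunt on Bioyear:
    slope, intercept, two-sided p-value and r.

    The caller is responsible for the span convention (Bioyears 2016–2022,
    with Bioyear 2016 totals built from Jan–Aug 2017 only, where cull
    reporting starts mid-span); :func:`truncate_first_cull_bioyear` applies
    that truncation to monthly data.
    """
    hunts = ratios["hunt"].to_numpy(dtype=float)
    if (hunts == 0).any():
        bad = ratios.loc[hunts == 0, "bioyear"].tolist()
        raise ValueError(f"zero hunt count in bioyears {bad}")
    years = ratios["bioyear"].to_numpy(dtype=float)
    ratio = ratios["cull"].to_numpy(dtype=float) / hunts
    fit = stats.linregress(years, ratio)
    return {"slope": fit.slope, "intercept": fit.intercept,
            "p_value": fit.pvalue, "r": fit.rvalue, "ratios": ratio}


def truncate_first_cull_bioyear(monthly: pd.DataFrame,
                                first_bioyear: int = 2016) -> pd.DataFrame:
    """Drop months of the first cull Bioyear that precede reliable reporting.

    Keeps only Jan–Aug of the Bioyear's closing calendar year for
    ``first_bioyear`` (e.g. Jan–Aug 2017 for Bioyear 2016) and all months of
    later Bioyears. ``monthly`` needs ``year`` and ``month`` columns.
    """
    by = monthly.apply(
        lambda r: bioyear(pd.Timestamp(int(r["year"]), int(r["month"]), 1)),
        axis=1)
    keep = (by > first_bioyear) | (
        (by == first_bioyear) & (monthly["month"] <= 8) &
        (monthly["year"] == first_bioyear + 1))
    return monthly[keep]


# ---------------------------------------------------------------------------
# GPS fixes
# ---------------------------------------------------------------------------

def qc_gps_fixes(fixes: pd.DataFrame,
                 subsample_minutes: int = 15) -> pd.DataFrame:
    """Quality-control GPS fixes.

    Drops 2D fixes, HDOP > 10, VDOP > 10 (missing VDOP passes), reported
    altitude > 4000 m and altitude above ground <= -50 m, then subsamples
    each bird's stream to at most one fix per ``subsample_minutes``.

    Columns: ``ID``, ``timestamp``, ``fix_quality`` ('2D'|'3D'), ``hdop``,
    ``vdop`` (optional), ``altitude_m``, ``agl_m``, ``speed_kph``.
    """
    keep = (fixes["fix_quality"] != "2D") & (fixes["hdop"] <= 10) & \
        (fixes["altitude_m"] <= 4000) & (fixes["agl_m"] > -50)
    if "vdop" in fixes.columns:
        keep &= ~(fixes["vdop"] > 10)  # NaN VDOP passes
    out = fixes[keep].sort_values(["ID", "timestamp"])
    rows = []
    for _, grp in out.groupby("ID", sort=False):
        ts = grp["timestamp"].to_numpy()
        last = None
        sel = []
        for i, t in enumerate(ts):
            if last is None or (t - last) / np.timedelta64(1, "m") >= \
                    subsample_minutes:
                sel.append(i)
                last = t
        rows.append(grp.iloc[sel])
    return pd.concat(rows) if rows else out


def classify_foraging(fixes: pd.DataFrame, day_start: int = 6,
                      day_end: int = 20) -> pd.DataFrame:
    """Classify QC-passed fixes as likely foraging locations.

    Foraging = daytime ground locations with speed < 5 kph and altitude
    above ground < 50 m. Dawn/dusk default to 06:00–20:00 local unless the
    caller supplies solar times via ``day_start``/``day_end`` hours.
    """
    hours = pd.DatetimeIndex(fixes["timestamp"]).hour
    keep = (hours >= day_start) & (hours < day_end) & \
        (fixes["speed_kph"] < 5) & (fixes["agl_m"] < 50)
    return fixes[keep]
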