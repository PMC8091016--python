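"""Two-step growth-curve analysis for plate-reader OD traces.

The estimator works on blank-corrected OD traces.  During balanced
exponential growth the specific growth rate mu is constant and equals the
slope of ln(OD) versus time, so the algorithm proceeds in two steps:

1. *Seeding*: scan every candidate 5-h window (anchored at sample times with
   full coverage) and fit ordinary least squares of ln(OD) on time over the
   unmasked points; the window with the maximum slope is the seed.
2. *Expansion*: greedily grow the window one sample point at a time (left
   end tried before right each iteration); a proposed expansion is accepted
   only if the refitted slope stays >= 95% of the seed slope and R^2 stays
   above 0.995.

The lag time is the start of the final exponential window (zero when the
window starts at the first unmasked point).  Diauxic (biphasic) growth is
detected from the rolling-window slope profile and yields an adjusted lag:
the time between the end of the initial growth phase and the beginning of
the main exponential phase.

Quality control is separated from estimation: ``mu``/``lag`` are the
estimator's output whenever a seed window exists, while ``status`` encodes
whether the fit passes the acceptance thresholds (``growth``), fails only
the R^2 gate or another curation rule (``flagged``), or shows no usable
signal (``no_growth``, reported as NA in result files).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .io_formats import PlateLayout, PlateTable

__all__ = [
    "ODTrace",
    "GrowthFit",
    "GrowthParams",
    "ReplicateSummary",
    "blank_correct",
    "find_max_slope_window",
    "expand_window",
    "fit_growth",
    "detect_diauxie",
    "summarize_replicates",
    "fit_plate",
]

#: Default noise floor in OD units: the blank-to-blank standard deviation of
#: the instrument setup this pipeline targets stays below this value.
DEFAULT_NOISE_FLOOR = 0.006


@dataclass
class ODTrace:
    """One well's blank-corrected OD time series.

    ``mask`` is True for points excluded from regression (at or below the
    noise floor, missing, or non-positive after blank subtraction).
    """

    well: str
    times: np.ndarray
    od: np.ndarray
    noise_floor: float = DEFAULT_NOISE_FLOOR
    mask: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.noise_floor <= 0:
            raise ValueError("noise_floor must be > 0")
        if self.mask is None:
            with np.errstate(invalid="ignore"):
                self.mask = ~(self.od > self.noise_floor)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (len(self.times) == len(self.od) == len(self.mask)):
            raise ValueError("times, od and mask must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def usable(self) -> np.ndarray:
        """Points eligible for regression: unmasked, finite, positive OD."""
        with np.errstate(invalid="ignore"):
            return (~self.mask) & np.isfinite(self.od) & (self.od > 0)


@dataclass
class WindowFit:
    """An OLS fit of ln(OD) vs time over a contiguous index window."""

    i_left: int
    i_right: int
    slope: float
    intercept: float
    r2: float
    n: int


@dataclass
class GrowthFit:
    """Result of the two-step fit for one well."""

    well: str
    status: str  # "growth" | "no_growth" | "flagged"
    mu: float = math.nan  # 1/h, slope of ln OD on the final window
    lag: float = math.nan  # h, start of the final exponential window
    t_start: float = math.nan
    t_end: float = math.nan
    r2: float = math.nan
    n_points: int = 0
    seed_slope: float = math.nan
    diauxic: bool = False
    lag_adjusted: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class GrowthParams:
    """Tunable parameters of the growth-curve estimator (units in names)."""

    window_h: float = 5.0
    min_points: int = 30
    ratio: float = 0.95
    r2_min: float = 0.995
    mu_min: float = 0.01
    step_points: int = 1
    peak_ratio: float = 0.2
    trough_ratio: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.r2_min <= 1):
            raise ValueError("r2_min must lie in (0, 1]")
        if not (0 < self.ratio <= 1):
            raise ValueError("ratio must lie in (0, 1]")
        if self.window_h <= 0:
            raise ValueError("window_h must be > 0")


@dataclass
class ReplicateSummary:
    """Mean +/- SD of mu and lag over the growth-status replicates of a group."""

    strain: str
    carbon_source: str
    mu_mean: float
    mu_sd: float
    lag_mean: float
    lag_sd: float
    n_total: int
    n_growth: int

    @property
    def growth_fraction(self) -> float:
        return self.n_growth / self.n_total


# ---------------------------------------------------------------------------
# Blank correction
# ---------------------------------------------------------------------------


def blank_correct(
    plate: PlateTable,
    layout: PlateLayout,
    default_floor: float = DEFAULT_NOISE_FLOOR,
) -> dict[str, ODTrace]:
    """Subtract the per-time-point blank mean from every sample well.

    The noise floor is the larger of ``default_floor`` and the observed
    blank-to-blank scatter (mean over time points of the across-blank SD);
    corrected values at or below the floor are masked, not dropped.  Blanks
    that grow (final blank mean > 3x initial) abort with an error.
    """
    blanks = [w for w in layout.blank_wells if w in plate.wells]
    if not blanks:
        raise ValueError("cannot blank-correct: layout has no blank wells on this plate")
    for well in layout.wells:
        if well not in plate.wells:
            raise ValueError(f"layout well {well} missing from plate table")
    blank_matrix = plate.readings[blanks].to_numpy(dtype=float)
    blank_mean = np.nanmean(blank_matrix, axis=1)
    if blank_mean[-1] > 3.0 * max(blank_mean[0], 1e-12):
        raise ValueError("contaminated blanks: final blank mean exceeds 3x initial")
    if len(blanks) > 1:
        per_time_sd = np.nanstd(blank_matrix, axis=1, ddof=1)
        observed_sd = float(np.nanmean(per_time_sd))
    else:
        observed_sd = 0.0
    noise_floor = max(default_floor, observed_sd)
    flags = ["noisy_blanks"] if observed_sd > default_floor else []

    traces: dict[str, ODTrace] = {}
    for well in layout.sample_wells:
        corrected = plate.series(well) - blank_mean
        with np.errstate(invalid="ignore"):
            mask = ~(corrected > noise_floor)
        traces[well] = ODTrace(
            well=well,
            times=plate.times.copy(),
            od=corrected,
            noise_floor=noise_floor,
            mask=mask,
            flags=list(flags),
        )
    return traces


# ---------------------------------------------------------------------------
# Window regression machinery
# ---------------------------------------------------------------------------


def _ols_ln(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R^2 of OLS of y (= ln OD) on t."""
    n = len(t)
    tbar = t.mean()
    ybar = y.mean()
    dt = t - tbar
    dy = y - ybar
    sxx = float(dt @ dt)
    syy = float(dy @ dy)
    sxy = float(dt @ dy)
    if sxx == 0.0:
        return 0.0, ybar, 0.0
    slope = sxy / sxx
    if syy == 0.0:
        # perfectly flat signal: a horizontal line explains nothing
        return slope, ybar - slope * tbar, 0.0
    r2 = min(1.0, max(0.0, sxy * sxy / (sxx * syy)))
    return slope, ybar - slope * tbar, r2


def _fit_range(trace: ODTrace, lny: np.ndarray, usable: np.ndarray,
               i_left: int, i_right: int) -> WindowFit | None:
    sel = usable[i_left : i_right + 1]
    n = int(sel.sum())
    if n < 2:
        return None
    t = trace.times[i_left : i_right + 1][sel]
    y = lny[i_left : i_right + 1][sel]
    slope, intercept, r2 = _ols_ln(t, y)
    return WindowFit(i_left=i_left, i_right=i_right, slope=slope,
                     intercept=intercept, r2=r2, n=n)


def _prepare(trace: ODTrace) -> tuple[np.ndarray, np.ndarray]:
    usable = trace.usable
    lny = np.full_like(trace.od, np.nan)
    lny[usable] = np.log(trace.od[usable])
    return lny, usable


def _scan_windows(trace: ODTrace, window_h: float, min_points: int):
    """All full-coverage candidate windows with their OLS fits.

    Yields ``(t0, WindowFit | None)`` for every sample time t0 such that the
    window [t0, t0 + window_h] is fully covered by the trace; ``None`` marks
    windows with fewer than ``min_points`` usable points.
    """
    lny, usable = _prepare(trace)
    t = trace.times
    t_last = t[-1]
    results = []
    j = 0
    for i0 in range(len(t)):
        t0 = t[i0]
        if t0 + window_h > t_last + 1e-9:
            break
        j = int(np.searchsorted(t, t0 + window_h + 1e-9, side="right")) - 1
        fit = _fit_range(trace, lny, usable, i0, j)
        if fit is not None and fit.n < min_points:
            fit = None
        results.append((t0, fit))
    return results


def find_max_slope_window(
    trace: ODTrace, window_h: float = 5.0, min_points: int = 30
) -> WindowFit | None:
    """Seed step: the fixed-duration window with the maximum ln-OD slope.

    Ties (slopes within 1e-12) resolve to the earliest start time.  Returns
    ``None`` when no candidate window holds at least ``min_points`` usable
    points, which callers interpret as a no-growth trace.
    """
    best: WindowFit | None = None
    for _t0, fit in _scan_windows(trace, window_h, min_points):
        if fit is None:
            continue
        if best is None or fit.slope > best.slope + 1e-12:
            best = fit
    return best


def expand_window(
    trace: ODTrace,
    seed: WindowFit,
    slope_max: float | None = None,
    ratio: float = 0.95,
    r2_min: float = 0.995,
    step_points: int = 1,
) -> WindowFit:
    """Expansion step: greedily grow the seed window point by point.

    At each iteration the left boundary is tried first, then the right; a
    proposal is accepted only if the refit keeps slope >= ratio * slope_max
    (the *seed* slope, not the running one) and R^2 > r2_min.  The loop
    stops when neither end accepts; the seed itself is always returnable.
    """
    if slope_max is None:
        slope_max = seed.slope
    lny, usable = _prepare(trace)
    current = seed
    n_total = len(trace.times)
    while True:
        moved = False
        if current.i_left - step_points >= 0:
            cand = _fit_range(trace, lny, usable, current.i_left - step_points, current.i_right)
            if cand is not None and cand.slope >= ratio * slope_max and cand.r2 > r2_min:
                current = cand
                moved = True
        if not moved and current.i_right + step_points <= n_total - 1:
            cand = _fit_range(trace, lny, usable, current.i_left, current.i_right + step_points)
            if cand is not None and cand.slope >= ratio * slope_max and cand.r2 > r2_min:
                current = cand
                moved = True
        if not moved:
            return current


# ---------------------------------------------------------------------------
# Full fit
# ---------------------------------------------------------------------------


def fit_growth(trace: ODTrace, params: GrowthParams | None = None) -> GrowthFit:
    """Compose seeding and expansion into a growth/lag estimate for one well.

    Status rules (defaults):

    * ``growth``   — mu >= mu_min, final R^2 > r2_min, and the maximum
      corrected OD reaches at least twice the noise floor;
    * ``no_growth`` — no candidate window, trace shorter than the window,
      mu < mu_min, or the culture never cleared 2x the noise floor; mu and
      lag are reported as NA in result files;
    * ``flagged``  — a usable fit that fails only a curation rule (R^2 gate,
      negative seed slope); estimates are retained for review.
    """
    params = params or GrowthParams()
    flags = list(trace.flags)

    if trace.times[-1] - trace.times[0] < params.window_h:
        return GrowthFit(well=trace.well, status="no_growth",
                         flags=flags + ["short_trace"])

    seed = find_max_slope_window(trace, params.window_h, params.min_points)
    if seed is None:
        return GrowthFit(well=trace.well, status="no_growth",
                         flags=flags + ["no_window"])

    final = expand_window(trace, seed, seed.slope, params.ratio,
                          params.r2_min, params.step_points)
    mu = final.slope
    usable = trace.usable
    usable_idx = np.flatnonzero(usable)
    window_usable = usable_idx[(usable_idx >= final.i_left) & (usable_idx <= final.i_right)]
    t_start = float(trace.times[window_usable[0]])
    t_end = float(trace.times[window_usable[-1]])
    lag = 0.0 if window_usable[0] == usable_idx[0] else t_start
    max_od = float(np.nanmax(trace.od[usable])) if usable.any() else 0.0

    if seed.slope < 0:
        flags.append("negative_seed")
    if 0.990 <= final.r2 <= params.r2_min:
        flags.append("marginal_r2")

    growth_ok = (
        mu >= params.mu_min
        and final.r2 > params.r2_min
        and max_od >= 2.0 * trace.noise_floor
    )
    if growth_ok and "negative_seed" not in flags:
        status = "growth"
    elif mu < params.mu_min or max_od < 2.0 * trace.noise_floor:
        status = "no_growth"
    else:
        status = "flagged"
        if "marginal_r2" not in flags:
            flags.append("low_r2")

    fit = GrowthFit(
        well=trace.well,
        status=status,
        mu=mu,
        lag=lag,
        t_start=t_start,
        t_end=t_end,
        r2=final.r2,
        n_points=final.n,
        seed_slope=seed.slope,
        flags=flags,
    )
    if status == "growth":
        fit = detect_diauxie(trace, fit, params)
    return fit


def detect_diauxie(
    trace: ODTrace,
    fit: GrowthFit,
    params: GrowthParams | None = None,
) -> GrowthFit:
    """Annotate biphasic (diauxic) growth and adjust the lag time.

    The rolling 5-h-window slope profile is scanned for an earlier slope
    peak, wholly before the main (global-max-slope) window, with slope at
    least ``peak_ratio`` times mu, separated from the main phase by a trough
    below ``trough_ratio`` times the smaller peak's slope.  The end of the
    initial phase is the last window start whose slope is still clearly
    above the trough (trough + 10% of the peak-trough gap, a localization
    tolerance); the adjusted lag is the main window start minus that time.
    The main phase is always the global-max-slope phase, so a second phase
    slower than the first never reassigns mu.
    """
    params = params or GrowthParams()
    if fit.status != "growth":
        return fit
    profile = [
        (t0, w.slope) for t0, w in _scan_windows(trace, params.window_h, params.min_points)
        if w is not None
    ]
    main_start = fit.lag if fit.lag > 0 else fit.t_start
    before = [(t0, s) for t0, s in profile if t0 + params.window_h <= main_start + 1e-9]
    if not before:
        return fit
    peak_t0, peak_slope = max(before, key=lambda item: item[1])
    if peak_slope < params.peak_ratio * fit.mu:
        return fit
    between = [(t0, s) for t0, s in profile if peak_t0 <= t0 <= main_start]
    if len(between) < 2:
        return fit
    trough_t0, trough_slope = min(between, key=lambda item: item[1])
    if trough_slope >= params.trough_ratio * min(peak_slope, fit.mu):
        return fit
    threshold = trough_slope + 0.1 * (peak_slope - trough_slope)
    end_initial = peak_t0
    for t0, s in between:
        if t0 > trough_t0:
            break
        if s >= threshold:
            end_initial = t0
    lag_adjusted = max(0.0, main_start - end_initial)
    flags = fit.flags + ["diauxic"] if "diauxic" not in fit.flags else fit.flags
    return replace(fit, diauxic=True, lag_adjusted=lag_adjusted, flags=flags)


# ---------------------------------------------------------------------------
# Replicate summaries and plate-level driver
# ---------------------------------------------------------------------------


def summarize_replicates(
    fits: Sequence[GrowthFit],
    keys: Sequence[tuple[str, str]],
) -> list[ReplicateSummary]:
    """Per-(strain, carbon source) mean +/- SD of mu and lag.

    Only growth-status fits enter the means (sample SD, n-1 denominator);
    groups with no growth-status members report NA means and growth
    fraction 0.  ``keys`` aligns one (strain, carbon_source) pair with each
    fit.
    """
    if len(fits) == 0:
        raise ValueError("no fits to summarize")
    if len(fits) != len(keys):
        raise ValueError("fits and keys must have equal length")
    groups: dict[tuple[str, str], list[GrowthFit]] = {}
    for fit, key in zip(fits, keys):
        groups.setdefault(tuple(key), []).append(fit)
    summaries = []
    for (strain, carbon), members in groups.items():
        grown = [f for f in members if f.status == "growth"]
        if grown:
            mus = np.array([f.mu for f in grown])
            lags = np.array([f.lag for f in grown])
            mu_mean = float(mus.mean())
            lag_mean = float(lags.mean())
            mu_sd = float(mus.std(ddof=1)) if len(grown) > 1 else math.nan
            lag_sd = float(lags.std(ddof=1)) if len(grown) > 1 else math.nan
        else:
            mu_mean = mu_sd = lag_mean = lag_sd = math.nan
        summaries.append(
            ReplicateSummary(
                strain=strain,
                carbon_source=carbon,
                mu_mean=mu_mean,
                mu_sd=mu_sd,
                lag_mean=lag_mean,
                lag_sd=lag_sd,
                n_total=len(members),
                n_growth=len(grown),
            )
        )
    return summaries


def fit_plate(
    plate: PlateTable,
    layout: PlateLayout,
    params: GrowthParams | None = None,
    default_floor: float = DEFAULT_NOISE_FLOOR,
) -> list[GrowthFit]:
    """Blank-correct a plate and fit every sample well."""
    traces = blank_correct(plate, layout, default_floor)
    return [fit_growth(traces[w], params) for w in layout.sample_wells if w in traces]
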