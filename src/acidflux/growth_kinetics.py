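"""Growth-curve kinetics: sliding-window μ_max, spline μ(t), summary metrics.

The maximum specific growth rate is estimated the way micro-cultivation
time series are commonly analysed: OD600 is ln-transformed, an ordinary
least-squares line is fitted in a sliding window of (by default) seven
consecutive points, the exponential phase is the first contiguous run
of windows with R² at or above a threshold (default 0.90), and μ_max is
the steepest slope among those eligible windows.  A smoothing-spline
derivative of ln OD provides the continuous specific growth rate μ(t).
Auxiliary helpers compute the scalar comparisons used when summarising
stress experiments: percent reductions, log10 viability changes, and
the counter-ion load contributed by acid titration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .io_formats import GrowthCurve

__all__ = [
    "WindowFit",
    "GrowthSummary",
    "sliding_window_fits",
    "exponential_phase",
    "mu_max",
    "spline_mu_t",
    "summarize_growth",
    "percent_reduction",
    "log10_change",
    "titration_ion_load",
]


@dataclass(frozen=True)
class WindowFit:
    """OLS fit of ln OD vs time over one sliding window."""

    start_index: int
    slope: float  # specific growth rate over the window, h^-1
    intercept: float  # ln-OD units
    r2: float

    def end_index(self, window_size: int) -> int:
        return self.start_index + window_size - 1


@dataclass(frozen=True)
class GrowthSummary:
    """Derived kinetic metrics for one growth curve."""

    od_max: float
    mu_max: float | None
    mu_max_window: tuple[int, int] | None  # (start, end) point indices
    exp_phase: tuple[int, int] | None  # (first, last) eligible window start
    ph_max: float | None = None
    delta_ph_max: float | None = None
    cfu_log10_change: float | None = None
    multiple_runs: bool = False  # later qualifying runs existed and were ignored


def _window_ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, R² of y on t; R² = 1 when SST = 0 = SSE, else 0."""
    tbar = t.mean()
    ybar = y.mean()
    dt = t - tbar
    dy = y - ybar
    sst = float(dy @ dy)
    sxx = float(dt @ dt)
    slope = float(dt @ dy) / sxx
    intercept = ybar - slope * tbar
    resid = dy - slope * dt
    sse = float(resid @ resid)
    if sst == 0.0:
        r2 = 1.0 if sse == 0.0 else 0.0
    else:
        r2 = 1.0 - sse / sst
    return slope, intercept, min(max(r2, 0.0), 1.0)


def sliding_window_fits(curve: GrowthCurve, window_size: int = 7) -> list[WindowFit]:
    """OLS of ln OD on time over every sliding window (step one point).

    Regression uses the actual sampling times, so irregular series are
    handled correctly.
    """
    if window_size < 3:
        raise ValueError("window_size must be at least 3")
    n = len(curve)
    if n < window_size:
        raise ValueError(f"need at least {window_size} points, got {n}")
    t = curve.time_h
    y = np.log(curve.od)
    fits = []
    for start in range(n - window_size + 1):
        sl = slice(start, start + window_size)
        slope, intercept, r2 = _window_ols(t[sl], y[sl])
        fits.append(WindowFit(start, slope, intercept, r2))
    return fits


def exponential_phase(
    fits: list[WindowFit], r2_threshold: float = 0.90
) -> tuple[tuple[int, int] | None, list[WindowFit], bool]:
    """First contiguous run of windows with R² >= threshold.

    Returns ``(bounds, eligible_windows, later_runs_exist)`` where
    bounds are (first, last) window start indices, or ``(None, [], ...)``
    when no window qualifies.  Only the first qualifying run defines
    the exponential phase; any later runs are flagged, not used.
    """
    if not fits:
        raise ValueError("no window fits supplied")
    ok = [f.r2 >= r2_threshold for f in fits]
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(ok):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(ok) - 1))
    if not runs:
        return None, [], False
    first = runs[0]
    eligible = fits[first[0] : first[1] + 1]
    return first, eligible, len(runs) > 1


def mu_max(
    curve: GrowthCurve, window_size: int = 7, r2_threshold: float = 0.90
) -> GrowthSummary:
    """Full kinetic summary of a growth curve; see :func:`summarize_growth`."""
    return summarize_growth(curve, window_size=window_size, r2_threshold=r2_threshold)


def summarize_growth(
    curve: GrowthCurve, window_size: int = 7, r2_threshold: float = 0.90
) -> GrowthSummary:
    """μ_max via eligible sliding windows, plus OD/pH/CFU summary metrics.

    μ_max is the maximum slope among windows in the exponential phase,
    ties broken by the earliest window.  If no window reaches the R²
    threshold the rate is reported missing (with a warning), never
    raised as an error.
    """
    fits = sliding_window_fits(curve, window_size=window_size)
    bounds, eligible, multiple = exponential_phase(fits, r2_threshold=r2_threshold)

    mu: float | None = None
    mu_window: tuple[int, int] | None = None
    if eligible:
        best = max(eligible, key=lambda f: (f.slope, -f.start_index))
        mu = best.slope
        mu_window = (best.start_index, best.end_index(window_size))
    else:
        warnings.warn(
            f"no window reached R^2 >= {r2_threshold}; mu_max undefined",
            stacklevel=2,
        )

    ph_max = delta_ph = None
    if curve.ph is not None:
        ph_max = float(np.max(curve.ph))
        delta_ph = ph_max - float(curve.ph[0])
    cfu_change = None
    if curve.cfu_per_ml is not None:
        cfu_change = log10_change(float(curve.cfu_per_ml[0]), float(curve.cfu_per_ml[-1]))

    return GrowthSummary(
        od_max=float(np.max(curve.od)),
        mu_max=mu,
        mu_max_window=mu_window,
        exp_phase=bounds,
        ph_max=ph_max,
        delta_ph_max=delta_ph,
        cfu_log10_change=cfu_change,
        multiple_runs=multiple,
    )


def spline_mu_t(curve: GrowthCurve, lam: float | None = None) -> np.ndarray:
    """Specific growth rate μ(t) as the derivative of a smoothing spline.

    A cubic smoothing spline is fitted to ln OD with the penalty chosen
    by generalized cross-validation (``lam=None``); pass ``lam`` to
    override the smoothing parameter.  Returns μ at each input time.
    """
    if len(curve) < 8:
        raise ValueError("need at least 8 points for spline fitting")
    t = curve.time_h
    y = np.log(curve.od)
    spline = make_smoothing_spline(t, y, lam=lam)
    return spline.derivative()(t)


def percent_reduction(reference: float, value: float) -> float:
    """Percent reduction of ``value`` relative to ``reference``."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * (reference - value) / reference


def log10_change(initial: float, final: float) -> float:
    """Signed log10 fold change, e.g. for viable-count (CFU) comparisons."""
    if initial <= 0 or final <= 0:
        raise ValueError("initial and final must be positive")
    return float(np.log10(final / initial))


def titration_ion_load(
    added_volume_uL: float,
    acid_molarity_M: float,
    ions_per_molecule: int,
    medium_volume_mL: float,
) -> float:
    """Counter-ion concentration (mM) contributed by acid titration.

    E.g. 140 µL of 12 M HCl into 250 mL of medium adds ~6.7 mM Cl⁻.
    """
    if added_volume_uL <= 0 or acid_molarity_M <= 0 or medium_volume_mL <= 0:
        raise ValueError("volumes and molarity must be positive")
    if ions_per_molecule < 1 or ions_per_molecule != int(ions_per_molecule):
        raise ValueError("ions_per_molecule must be a positive integer")
    moles = added_volume_uL * 1e-6 * acid_molarity_M * ions_per_molecule
    return moles / (medium_volume_mL * 1e-3) * 1e3
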