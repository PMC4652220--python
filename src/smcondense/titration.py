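"""Ensemble fluorescence titration analytics.

Apparent site size by two-segment breakpoint fitting, plateau-amplitude
tabulation across salts, and salt back-titration midpoint extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass
class TitrationCurve:
    """Fluorescence fold-enhancement vs nucleotide:tetramer ratio."""

    ratio: np.ndarray
    fold_enhancement: np.ndarray
    salt_mM: float = 0.0
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.fold_enhancement = np.asarray(self.fold_enhancement, dtype=float)
        if self.ratio.shape != self.fold_enhancement.shape:
            raise ValueError("ratio and signal arrays must align")
        if np.any(self.ratio < 0):
            raise ValueError("ratios must be non-negative")
        if np.any(np.diff(self.ratio) <= 0):
            raise ValueError("ratios must be strictly increasing")


@dataclass
class SiteSizeFit:
    """Two-segment breakpoint solution of a titration curve."""

    site_size_nt: float
    amplitude_fold: float
    breakpoint_se: float
    residual_ss: float
    salt_mM: float = 0.0
    n_points: int = 0


@dataclass
class BackTitrationResult:
    """Salt back-titration summary: half-dissociation point and context."""

    midpoint_mM: float
    peak_signal: float
    decline_slope: float
    midpoint_se: float = float("nan")


# --------------------------------------------------------------------------
# site-size breakpoint fit
# --------------------------------------------------------------------------

def _segment_rss(ratio: np.ndarray, y: np.ndarray, breakpoint: float) -> tuple[float, float]:
    """Profile RSS for the two-segment model at a fixed breakpoint.

    Model on the baseline-subtracted signal y = fold - 1:
        y = A * min(ratio / breakpoint, 1)
    i.e. a rising segment through the origin meeting a flat plateau of
    height A continuously at the breakpoint.  Returns (rss, A_hat).
    """
    x = np.minimum(ratio / breakpoint, 1.0)
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return float(np.dot(y, y)), 0.0
    a_hat = float(np.dot(x, y)) / denom
    resid = y - a_hat * x
    return float(np.dot(resid, resid)), a_hat


def fit_site_size(
    curve: TitrationCurve,
    n_boot: int = 1000,
    boot_seed: int = 0,
    grid_step_nt: float = 1.0,
) -> SiteSizeFit:
    """Fit the stoichiometric breakpoint of a titration curve.

    The fit operates on the baseline-subtracted signal (fold - 1): the
    rising segment is constrained through the origin, the plateau has
    zero slope, and the two segments join continuously at the
    breakpoint, which is the apparent site size in nucleotides per
    tetramer.  A coarse grid (``grid_step_nt``) seeds a bounded
    continuous refinement; ties break toward the smaller breakpoint.

    Standard error of the breakpoint comes from a case-resampling
    bootstrap (``n_boot`` resamples, seeded); pass ``n_boot=0`` to skip.
    """
    ratio, y = curve.ratio, curve.fold_enhancement - 1.0
    if ratio.size < 6:
        raise ValueError("need at least 6 titration points for a breakpoint fit")
    positive = ratio[ratio > 0]
    if positive.size < 2:
        raise ValueError("need at least two non-zero ratios")

    b_hat, a_hat, rss = _fit_breakpoint(ratio, y, positive, grid_step_nt)

    scale = max(float(np.max(np.abs(y))), 1e-12)
    if a_hat < 0.05 * scale or np.max(np.abs(y)) < 1e-9:
        raise ValueError("breakpoint unidentifiable: no fluorescence enhancement above baseline")
    n_below = int(np.sum(ratio < b_hat))
    n_above = int(np.sum(ratio > b_hat))
    if min(n_below, n_above) < 4:
        warnings.warn(
            f"fewer than 4 points on one side of the breakpoint "
            f"({n_below} below, {n_above} above); estimate may be unstable",
            stacklevel=2,
        )
    if b_hat >= positive.max() - 1e-9:
        raise ValueError("breakpoint not bracketed by the data (plateau not reached)")

    se = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(boot_seed)
        boots = []
        n = ratio.size
        for _ in range(n_boot):
            idx = np.sort(rng.integers(0, n, n))
            r_b, y_b = ratio[idx], y[idx]
            keep = np.concatenate([[True], np.diff(r_b) > 0])
            r_b, y_b = r_b[keep], y_b[keep]
            pos_b = r_b[r_b > 0]
            if pos_b.size < 2:
                continue
            try:
                b_b, _, _ = _fit_breakpoint(r_b, y_b, pos_b, grid_step_nt)
            except ValueError:
                continue
            boots.append(b_b)
        if len(boots) > 1:
            se = float(np.std(boots, ddof=1))

    return SiteSizeFit(
        site_size_nt=b_hat,
        amplitude_fold=a_hat + 1.0,
        breakpoint_se=se,
        residual_ss=rss,
        salt_mM=curve.salt_mM,
        n_points=ratio.size,
    )


def _fit_breakpoint(
    ratio: np.ndarray, y: np.ndarray, positive: np.ndarray, grid_step_nt: float
) -> tuple[float, float, float]:
    lo, hi = float(positive.min()), float(positive.max())
    grid = np.arange(lo, hi + grid_step_nt / 2, grid_step_nt)
    if grid.size < 2:
        grid = np.array([lo, hi])
    rss_grid = np.array([_segment_rss(ratio, y, b)[0] for b in grid])
    i_best = int(np.argmin(rss_grid))  # argmin takes first minimum: smaller breakpoint
    b_lo = grid[max(i_best - 1, 0)]
    b_hi = grid[min(i_best + 1, grid.size - 1)]
    if b_hi > b_lo:
        res = optimize.minimize_scalar(
            lambda b: _segment_rss(ratio, y, b)[0],
            bounds=(b_lo, b_hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        b_hat = float(res.x)
        if _segment_rss(ratio, y, grid[i_best])[0] < res.fun - 1e-12:
            b_hat = float(grid[i_best])
    else:
        b_hat = float(grid[i_best])
    rss, a_hat = _segment_rss(ratio, y, b_hat)
    return b_hat, a_hat, rss


def fit_site_size_grid(
    curve: TitrationCurve, grid_step_nt: float = 0.1
) -> tuple[float, float, float]:
    """Exhaustive breakpoint grid search (oracle for :func:`fit_site_size`).

    Scans breakpoints at ``grid_step_nt`` resolution over the positive
    ratio range and returns ``(breakpoint, amplitude_fold, rss)`` of the
    global RSS minimizer (first minimum on ties).
    """
    ratio, y = curve.ratio, curve.fold_enhancement - 1.0
    positive = ratio[ratio > 0]
    grid = np.arange(positive.min(), positive.max() + grid_step_nt / 2, grid_step_nt)
    rss = np.array([_segment_rss(ratio, y, b)[0] for b in grid])
    i = int(np.argmin(rss))
    r, a = _segment_rss(ratio, y, grid[i])
    return float(grid[i]), a + 1.0, r


# --------------------------------------------------------------------------
# amplitude table and back-titration
# --------------------------------------------------------------------------

def amplitude_vs_salt(fits: list[SiteSizeFit]) -> pd.DataFrame:
    """Tabulate plateau amplitude (fold enhancement) against salt."""
    if not fits:
        raise ValueError("no fits supplied")
    salts = [f.salt_mM for f in fits]
    if len(set(salts)) != len(salts):
        raise ValueError("duplicate salt keys in amplitude table")
    df = pd.DataFrame(
        {
            "salt_mM": salts,
            "amplitude_fold": [f.amplitude_fold for f in fits],
            "site_size_nt": [f.site_size_nt for f in fits],
        }
    )
    return df.sort_values("salt_mM", ignore_index=True)


def find_salt_midpoint(
    salt_mM: np.ndarray, signal: np.ndarray
) -> BackTitrationResult:
    """Locate the half-dissociation salt of a back-titration.

    Only points past the signal maximum enter the fit (the rise and the
    shallow pre-transition decline are excluded); the dissociation limb
    is modelled as a linearly declining envelope times a logistic drop,
    and the midpoint is the logistic inflection.
    """
    salt = np.asarray(salt_mM, dtype=float)
    sig = np.asarray(signal, dtype=float)
    if salt.shape != sig.shape or salt.size < 6:
        raise ValueError("need matching salt/signal arrays with >= 6 points")

    i_peak = int(np.argmax(sig))
    s_t, y_t = salt[i_peak:], sig[i_peak:]
    if s_t.size < 5:
        raise ValueError("no dissociation limb: signal maximum at the end of the table")
    y_peak = float(y_t[0])
    if float(np.min(y_t)) > 0.5 * y_peak:
        raise ValueError(
            "dissociation limb not covered: signal never falls below half its "
            f"maximum (need data beyond {salt.max():.0f} mM)"
        )

    def model(s, p0, p1, mid, width):
        return (p0 + p1 * (s - s_t[0])) / (1.0 + np.exp((s - mid) / width))

    # initial midpoint: first crossing of half-peak
    below = np.flatnonzero(y_t < 0.5 * y_peak)
    mid0 = float(s_t[below[0]]) if below.size else float(s_t[-1])
    span = float(s_t[-1] - s_t[0])
    p0 = (y_peak, 0.0, mid0, max(span / 20.0, 1e-3))
    bounds = (
        [0.0, -np.inf, float(s_t[0]), 1e-6],
        [np.inf, np.inf, float(s_t[-1]), span],
    )
    popt, pcov = optimize.curve_fit(model, s_t, y_t, p0=p0, bounds=bounds, maxfev=20000)
    mid_se = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else float("nan")
    return BackTitrationResult(
        midpoint_mM=float(popt[2]),
        peak_signal=y_peak,
        decline_slope=float(-popt[1]),
        midpoint_se=mid_se,
    )
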