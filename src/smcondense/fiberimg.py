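"""Per-frame fiber length and intensity from kymograph frame stacks.

Conventions: pixel indices are 0-based; the flow axis is the image row
axis; the tether sits at the upstream (low-row) end of the fiber.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FiberTrace:
    """Per-frame length/intensity measurements for one fiber."""

    frame: int
    time_s: float
    length_um: float
    roi_mean_intensity: float
    roi_intensity_sd: float
    normalized_intensity: float = float("nan")


@dataclass
class LengthDistribution:
    """Gaussian summary of a population of per-molecule lengths."""

    condition: str
    lengths_um: np.ndarray
    mu_um: float
    sigma_um: float
    n_molecules: int
    salt_mM: float = float("nan")


def estimate_background(
    frame: np.ndarray, fiber_col: int, margin: int = 3
) -> tuple[float, float]:
    """Background mean/sd from columns at least ``margin`` away from the fiber."""
    cols = np.arange(frame.shape[1])
    mask = np.abs(cols - fiber_col) > margin
    if not mask.any():
        raise ValueError("frame too narrow to estimate background")
    bg = frame[:, mask]
    return float(bg.mean()), float(bg.std())


def measure_fiber_length(
    frame: np.ndarray,
    tether_rc: tuple[int, int],
    pixel_um: float,
    k_sd: float = 3.0,
    background: tuple[float, float] | None = None,
    flow_axis: int = 0,
) -> float:
    """Fiber length from the contiguous above-threshold run at the tether.

    The threshold is background mean + ``k_sd`` background standard
    deviations (background estimated from flanking columns unless
    given).  Length is the contiguous run of above-threshold pixels
    starting at the tether pixel, walked along the flow axis, times the
    pixel size.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if flow_axis == 1:
        frame = frame.T
        tether_rc = (tether_rc[1], tether_rc[0])
    t_row, t_col = tether_rc
    n_rows, n_cols = frame.shape
    if not (0 <= t_row < n_rows and 0 <= t_col < n_cols):
        raise ValueError("tether pixel outside frame")
    if pixel_um <= 0:
        raise ValueError("pixel size must be positive")

    if background is None:
        background = estimate_background(frame, t_col)
    bg_mean, bg_sd = background
    threshold = bg_mean + k_sd * bg_sd

    profile = frame[t_row:, t_col]
    above = profile > threshold
    if not above[0]:
        raise ValueError("fiber not found: no above-threshold pixel at the tether")
    stops = np.flatnonzero(~above)
    run = int(stops[0]) if stops.size else int(above.size)
    return run * pixel_um


def measure_roi_intensity(
    frame: np.ndarray,
    roi: tuple[int, int, int, int],
    background_mean: float = 0.0,
) -> tuple[float, float]:
    """Mean and standard deviation of ROI pixels (rows r0:r1, cols c0:c1).

    ``background_mean`` is subtracted from the mean (the sd is
    unaffected by a constant offset).
    """
    r0, r1, c0, c1 = roi
    patch = np.asarray(frame, dtype=float)[r0:r1, c0:c1]
    if patch.size == 0:
        raise ValueError("empty ROI")
    return float(patch.mean() - background_mean), float(patch.std())


def normalize_intensity(traces: list[FiberTrace], reference_mean: float) -> list[FiberTrace]:
    """Fill ``normalized_intensity`` as roi_mean / reference (0 mM) mean."""
    if reference_mean <= 0:
        raise ValueError("reference intensity must be positive")
    return [
        FiberTrace(
            frame=t.frame,
            time_s=t.time_s,
            length_um=t.length_um,
            roi_mean_intensity=t.roi_mean_intensity,
            roi_intensity_sd=t.roi_intensity_sd,
            normalized_intensity=t.roi_mean_intensity / reference_mean,
        )
        for t in traces
    ]


def analyze_stack(
    stack: np.ndarray,
    tether_rc: tuple[int, int],
    pixel_um: float,
    frame_interval_s: float = 1.0,
    k_sd: float = 3.0,
    roi: tuple[int, int, int, int] | None = None,
    background: tuple[float, float] | None = None,
) -> list[FiberTrace]:
    """Measure length and ROI intensity for every frame of a stack.

    The default ROI is a fixed rectangle around the tether column
    spanning the maximum fiber extent observed across the stack.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, rows, cols)")
    t_row, t_col = tether_rc

    lengths = []
    for frame in stack:
        bg = background if background is not None else estimate_background(frame, t_col)
        lengths.append(
            measure_fiber_length(frame, tether_rc, pixel_um, k_sd=k_sd, background=bg)
        )

    if roi is None:
        max_px = int(np.ceil(max(lengths) / pixel_um))
        c0 = max(t_col - 2, 0)
        c1 = min(t_col + 3, stack.shape[2])
        roi = (t_row, min(t_row + max_px, stack.shape[1]), c0, c1)

    traces = []
    for i, frame in enumerate(stack):
        bg = background if background is not None else estimate_background(frame, t_col)
        mean, sd = measure_roi_intensity(frame, roi, background_mean=bg[0])
        traces.append(
            FiberTrace(
                frame=i,
                time_s=i * frame_interval_s,
                length_um=lengths[i],
                roi_mean_intensity=mean,
                roi_intensity_sd=sd,
            )
        )
    return traces


def fit_length_distribution(
    lengths_um, condition: str = "", salt_mM: float = float("nan")
) -> LengthDistribution:
    """Maximum-likelihood normal fit of a length population.

    The MLE of a normal distribution is the sample mean and the
    population (ddof=0) standard deviation; histogram binning is
    presentation-only and never enters the fit.
    """
    lengths = np.asarray(lengths_um, dtype=float)
    if np.unique(lengths).size < 2:
        raise ValueError("need at least 2 distinct lengths (degenerate variance)")
    if lengths.size < 10:
        warnings.warn(
            f"only {lengths.size} molecules; distribution fit is weakly constrained",
            stacklevel=2,
        )
    return LengthDistribution(
        condition=condition,
        lengths_um=lengths,
        mu_um=float(lengths.mean()),
        sigma_um=float(lengths.std()),  # ddof=0: the MLE
        n_molecules=int(lengths.size),
        salt_mM=salt_mM,
    )


def condensation_series(distributions: list[LengthDistribution]) -> pd.DataFrame:
    """Tabulate mean length vs salt, with L/L0 relative to the 0 mM mean."""
    if not distributions:
        raise ValueError("no distributions supplied")
    df = pd.DataFrame(
        {
            "salt_mM": [d.salt_mM for d in distributions],
            "mu_um": [d.mu_um for d in distributions],
            "sigma_um": [d.sigma_um for d in distributions],
            "n_molecules": [d.n_molecules for d in distributions],
        }
    ).sort_values("salt_mM", ignore_index=True)
    zero = df.loc[df["salt_mM"] == 0, "mu_um"]
    if zero.empty:
        warnings.warn("no 0 mM condition: L/L0 column omitted", stacklevel=2)
    else:
        df["L_over_L0"] = df["mu_um"] / float(zero.iloc[0])
    return df
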