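"""Single-molecule photon-count kinetics: ROI traces, normalization,
single-exponential dissociation fits, and binding waiting times.

A trace is the per-frame mean photon count inside a fixed region of
interest, normalized to its first frame. Dissociation after transfer to a
protein-free channel follows I(t) = A exp(-k t); the fit reports k with its
standard error. Waiting times are detected as the first threshold crossing
that persists for a minimum number of frames (an automated stand-in for
manual event picking; threshold and persistence are configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, ParameterError

__all__ = [
    "IntensityTrace",
    "FitResult",
    "roi_mean_counts",
    "normalize_trace",
    "fit_dissociation_rate",
    "waiting_time",
]


@dataclass
class FitResult:
    k: float  # 1/s
    k_stderr: float
    amplitude: float
    baseline: float
    residuals: np.ndarray


@dataclass
class IntensityTrace:
    """Time-stamped mean photon counts for one ROI."""

    times: np.ndarray  # s, strictly increasing
    mean_counts: np.ndarray
    roi: tuple[int, int, int, int] | None = None  # (x0, y0, w, h)
    normalized: np.ndarray | None = None
    fit: FitResult | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean_counts = np.asarray(self.mean_counts, dtype=float)
        if self.times.shape != self.mean_counts.shape:
            raise ParameterError("times and counts must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")


def roi_mean_counts(
    frames: np.ndarray, roi: tuple[int, int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame arithmetic mean of pixel counts inside a rectangular ROI.

    ``roi`` is (x0, y0, width, height) in pixel coordinates; the same box is
    applied to every frame. Non-finite pixels are excluded from that frame's
    mean and the frame is flagged. Returns ``(means, flagged)``.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise ParameterError("expected a (frames, H, W) stack")
    x0, y0, w, h = roi
    nt, ny, nx = frames.shape
    if w <= 0 or h <= 0 or x0 < 0 or y0 < 0 or x0 + w > nx or y0 + h > ny:
        raise ParameterError(f"roi {roi} outside image bounds ({ny}x{nx})")
    box = frames[:, y0 : y0 + h, x0 : x0 + w].reshape(nt, -1)
    finite = np.isfinite(box)
    flagged = ~finite.all(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(
            finite.any(axis=1),
            np.nansum(np.where(finite, box, 0.0), axis=1) / finite.sum(axis=1),
            np.nan,
        )
    return means, flagged


def normalize_trace(values: np.ndarray) -> np.ndarray:
    """Divide a trace by its first frame so that normalized[0] = 1."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParameterError("empty trace")
    if values[0] <= 0:
        raise ParameterError("first-frame mean must be positive to normalize")
    return values / values[0]


def fit_dissociation_rate(
    times: np.ndarray,
    values: np.ndarray,
    with_baseline: bool = False,
) -> FitResult:
    """Nonlinear least-squares fit of I(t) = A exp(-k t) [+ C].

    The amplitude is free and there is no additive baseline by default
    (traces are background-subtracted upstream); ``with_baseline`` adds one.
    The rate is constrained to k >= 0.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 3:
        raise ParameterError("need at least 3 frames to fit")

    # log-linear initial guess for k, robust to offsets
    pos = values > 0
    if pos.sum() >= 2:
        slope = np.polyfit(times[pos], np.log(values[pos]), 1)[0]
        k0 = max(1e-9, -slope)
    else:
        k0 = 1e-3
    a0 = max(values[0], 1e-9)
    try:
        if with_baseline:
            model = lambda t, a, k, c: a * np.exp(-k * t) + c
            p0 = (a0, k0, 0.0)
            bounds = ([-np.inf, 0.0, -np.inf], [np.inf, np.inf, np.inf])
        else:
            model = lambda t, a, k: a * np.exp(-k * t)
            p0 = (a0, k0)
            bounds = ([-np.inf, 0.0], [np.inf, np.inf])
        popt, pcov = curve_fit(model, times, values, p0=p0, bounds=bounds, maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(
            "single-exponential fit did not converge",
            diagnostics={"k0": k0, "a0": a0, "n": times.size, "cause": str(exc)},
        ) from exc
    if with_baseline:
        a, k, c = popt
    else:
        (a, k), c = popt, 0.0
    k_err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
    residuals = values - model(times, *popt)
    return FitResult(
        k=float(k), k_stderr=k_err, amplitude=float(a), baseline=float(c),
        residuals=residuals,
    )


def waiting_time(
    values: np.ndarray,
    threshold: float,
    dt: float,
    persistence_frames: int = 2,
) -> float | None:
    """First binding time: first frame exceeding ``threshold`` for at least
    ``persistence_frames`` consecutive frames. Returns the time in seconds or
    None if the trace never qualifies.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if persistence_frames < 1:
        raise ParameterError("persistence_frames must be >= 1")
    values = np.asarray(values, dtype=float)
    above = values > threshold
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= persistence_frames:
            return (i - persistence_frames + 1) * dt
    return None
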