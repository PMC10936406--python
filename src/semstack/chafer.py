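"""Charge-artifact suppression by row-wise sigmoid tail fitting ("chafer").

SEM imaging of insulating features (lipid droplets, myelin) accumulates
charge that appears as dark regions elongated along the fast-scan (x)
direction, extending asymmetrically beyond the charging center itself.
Given a segmentation of the charging centers, this filter estimates, row by
row, the clean background from previously corrected rows, models each
artifact tail with a shifted logistic sigmoid, and subtracts the fitted
tails from the unmasked pixels.  The labeled center pixels are never
modified, so the corrected image still shows the charging object.

The tail model on either side of a labeled segment is

    f(x) = a / (1 + exp(s (x - b) / c)),   s = -1 (left), s = +1 (right)

with amplitude ``a`` (signed; charging tails are usually dark, a < 0),
center ``b`` (pixels) and width ``c > 0`` (pixels).  The sign convention
makes the curve saturate to ``a`` approaching the labeled segment and decay
to 0 away from it; the asymmetry of real tails is captured by fitting the
left and right sides independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .io_core import LabelMask

__all__ = [
    "SigmoidTailModel",
    "ChaferParams",
    "RowSegments",
    "extract_row_segments",
    "estimate_row_background",
    "sigmoid_tail",
    "fit_tail_sigmoids",
    "correct_row",
    "chafer_filter",
    "background_std_report",
]

_EXP_CLAMP = 500.0  # exp argument clamp; avoids overflow without changing fits


@dataclass
class SigmoidTailModel:
    """Fitted shifted-logistic tail on one side of a charging segment."""

    side: str  # "left" or "right"
    amplitude: float
    center: float
    width: float

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if not self.width > 0:
            raise ValueError(f"width must be positive, got {self.width}")

    def __call__(self, x) -> np.ndarray:
        return sigmoid_tail(x, self)


@dataclass
class ChaferParams:
    """Filter controls.

    n_lines_average : rows averaged to estimate the clean background.
    passes : "down", "up" or "both" (both passes averaged).
    fit_max_iter / fit_tolerance : nonlinear solver controls.
    clip_output : clamp the result to the input intensity range.
    """

    n_lines_average: int = 5
    passes: str = "both"
    fit_max_iter: int = 200
    fit_tolerance: float = 1e-8
    clip_output: bool = False

    def __post_init__(self) -> None:
        if self.n_lines_average < 1:
            raise ValueError("n_lines_average must be >= 1")
        if self.passes not in ("down", "up", "both"):
            raise ValueError(f"passes must be down/up/both, got {self.passes!r}")


@dataclass
class RowSegments:
    """Labeled intervals [x_start, x_end] (inclusive) of one mask row."""

    intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted((int(a), int(b)) for a, b in self.intervals)
        for (a, b), nxt in zip(self.intervals, self.intervals[1:]):
            if b >= nxt[0]:
                raise ValueError("segments overlap")
        for a, b in self.intervals:
            if a > b:
                raise ValueError(f"segment ({a}, {b}) reversed")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]


def extract_row_segments(mask: LabelMask | np.ndarray, row: int) -> RowSegments:
    """Maximal runs of nonzero mask pixels in one row, sorted by start."""
    data = mask.data if isinstance(mask, LabelMask) else np.asarray(mask)
    line = data[row] > 0
    if not line.any():
        return RowSegments([])
    padded = np.concatenate([[False], line, [False]]).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    return RowSegments(list(zip(starts, ends)))


def estimate_row_background(working_image: np.ndarray, mask: LabelMask | np.ndarray,
                            row: int, n_lines_average: int = 5,
                            direction: str = "down") -> np.ndarray:
    """Per-column mean over preceding (already corrected) rows.

    In a down pass the predecessors are the up-to-``n_lines_average`` rows
    above ``row``; in an up pass, below.  Masked pixels are excluded
    column-wise; a column masked in every contributing row falls back to
    the mean of the valid background values of that row window.
    """
    img = np.asarray(working_image, dtype=np.float64)
    mdata = mask.data if isinstance(mask, LabelMask) else np.asarray(mask)
    h = img.shape[0]
    if direction == "down":
        lo, hi = max(0, row - n_lines_average), row
    elif direction == "up":
        lo, hi = row + 1, min(h, row + 1 + n_lines_average)
    else:
        raise ValueError(f"direction must be 'down' or 'up', got {direction!r}")
    if lo >= hi:
        raise ValueError(f"row {row} has no preceding rows in the {direction} pass")
    block = img[lo:hi]
    valid = mdata[lo:hi] == 0
    counts = valid.sum(axis=0)
    sums = np.where(valid, block, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        profile = sums / counts
    if (counts == 0).any():
        overall = sums.sum() / counts.sum() if counts.sum() else 0.0
        profile = np.where(counts == 0, overall, profile)
    return profile


def sigmoid_tail(x, model: SigmoidTailModel) -> np.ndarray:
    """Evaluate the shifted logistic tail at column coordinate(s) x."""
    x = np.asarray(x, dtype=np.float64)
    s = -1.0 if model.side == "left" else 1.0
    arg = np.clip(s * (x - model.center) / model.width, -_EXP_CLAMP, _EXP_CLAMP)
    return model.amplitude / (1.0 + np.exp(arg))


def _fit_one_side(x: np.ndarray, ydata: np.ndarray, side: str, boundary: float,
                  seg_len: int, max_iter: int, tol: float) -> SigmoidTailModel | None:
    """Deterministic nonlinear least squares for one tail; None on failure."""
    if len(x) < 4:
        return None
    # initial values from segment geometry: amplitude from the 5 valid
    # pixels nearest the boundary, center at the boundary, width ~ seg/4
    order = np.argsort(np.abs(x - boundary))
    a0 = float(np.mean(ydata[order[:5]]))
    b0 = float(boundary)
    c0 = max(2.0, seg_len / 4.0)
    sgn = -1.0 if side == "left" else 1.0

    def residual(p):
        a, b, logc = p
        c = np.exp(logc)
        arg = np.clip(sgn * (x - b) / c, -_EXP_CLAMP, _EXP_CLAMP)
        return a / (1.0 + np.exp(arg)) - ydata

    try:
        res = least_squares(residual, [a0, b0, np.log(c0)], method="lm",
                            max_nfev=max_iter * 4, xtol=tol, ftol=tol, gtol=tol)
    except Exception:
        return None
    if not res.success or not np.all(np.isfinite(res.x)):
        return None
    a, b, logc = res.x
    c = float(np.exp(np.clip(logc, -20, 20)))
    if c <= 0 or not np.isfinite(c):
        return None
    # an amplitude far beyond the observed signal means the plateau was
    # extrapolated, not fitted; treat as non-converged
    if abs(a) > 5.0 * (np.abs(ydata).max() + 1e-12):
        return None
    return SigmoidTailModel(side=side, amplitude=float(a), center=float(b), width=c)


def fit_tail_sigmoids(diff_signal: np.ndarray, segments: RowSegments,
                      segment_index: int, max_iter: int = 200,
                      tolerance: float = 1e-8
                      ) -> tuple[SigmoidTailModel | None, SigmoidTailModel | None]:
    """Fit left/right tails of one labeled segment against a difference row.

    ``diff_signal`` is the current row minus the background estimate with
    invalid (masked) columns set to NaN.  Fit windows are bounded by
    neighbouring segments so tails never overlap another center's window.
    A side with fewer than 4 valid pixels, or a non-converged fit, returns
    None for that side.
    """
    diff = np.asarray(diff_signal, dtype=np.float64)
    width = len(diff)
    x_start, x_end = segments[segment_index]
    seg_len = x_end - x_start + 1
    left_lo = segments[segment_index - 1][1] + 1 if segment_index > 0 else 0
    right_hi = (segments[segment_index + 1][0] - 1
                if segment_index + 1 < len(segments) else width - 1)

    def window_fit(lo, hi, side, boundary):
        if lo > hi:
            return None
        xs = np.arange(lo, hi + 1)
        ys = diff[lo:hi + 1]
        ok = np.isfinite(ys)
        if ok.sum() < 4:
            return None
        return _fit_one_side(xs[ok].astype(float), ys[ok], side, boundary,
                             seg_len, max_iter, tolerance)

    left = window_fit(left_lo, x_start - 1, "left", float(x_start))
    right = window_fit(x_end + 1, right_hi, "right", float(x_end))
    return left, right


def correct_row(row_values: np.ndarray, segments: RowSegments,
                fits: list[tuple[SigmoidTailModel | None, SigmoidTailModel | None]],
                mask_row: np.ndarray | None = None) -> np.ndarray:
    """Subtract fitted tails from the unmasked pixels of one row.

    Each fitted sigmoid is subtracted only over its own window; masked
    pixels are returned unchanged.
    """
    row = np.asarray(row_values, dtype=np.float64).copy()
    width = len(row)
    if mask_row is None:
        mask_row = np.zeros(width, dtype=bool)
    else:
        mask_row = np.asarray(mask_row) > 0
    for i, (x_start, x_end) in enumerate(segments):
        left, right = fits[i]
        left_lo = segments[i - 1][1] + 1 if i > 0 else 0
        right_hi = segments[i + 1][0] - 1 if i + 1 < len(segments) else width - 1
        if left is not None and left_lo <= x_start - 1:
            xs = np.arange(left_lo, x_start)
            sub = sigmoid_tail(xs, left)
            sel = ~mask_row[left_lo:x_start]
            row[left_lo:x_start][sel] -= sub[sel]
        if right is not None and x_end + 1 <= right_hi:
            xs = np.arange(x_end + 1, right_hi + 1)
            sub = sigmoid_tail(xs, right)
            sel = ~mask_row[x_end + 1:right_hi + 1]
            row[x_end + 1:right_hi + 1][sel] -= sub[sel]
    return row


def _single_pass(image: np.ndarray, mdata: np.ndarray, params: ChaferParams,
                 direction: str, stats: dict) -> np.ndarray:
    work = image.astype(np.float64).copy()
    h = image.shape[0]
    rows = range(h) if direction == "down" else range(h - 1, -1, -1)
    first = 0 if direction == "down" else h - 1
    for r in rows:
        segments = extract_row_segments(mdata, r)
        if len(segments) == 0 or r == first:
            continue  # unlabeled rows and the seed row pass through
        background = estimate_row_background(work, mdata, r,
                                             params.n_lines_average, direction)
        diff = work[r] - background
        diff[mdata[r] > 0] = np.nan
        fits = []
        for i in range(len(segments)):
            pair = fit_tail_sigmoids(diff, segments, i,
                                     params.fit_max_iter, params.fit_tolerance)
            for m in pair:
                if m is None:
                    stats["fit_failures"] += 1
                else:
                    stats["fits"] += 1
            fits.append(pair)
        work[r] = correct_row(work[r], segments, fits, mdata[r])
    return work


def chafer_filter(image: np.ndarray, mask: LabelMask | np.ndarray,
                  params: ChaferParams | None = None,
                  return_stats: bool = False):
    """Suppress charging tails around labeled centers in one slice.

    Runs sequential top-to-bottom and bottom-to-top passes (each row's
    background comes from already-corrected predecessor rows of that pass)
    and averages the two results.  An empty mask is a documented no-op.
    """
    params = params or ChaferParams()
    image = np.asarray(image, dtype=np.float64)
    mdata = mask.data if isinstance(mask, LabelMask) else np.asarray(mask)
    if mdata.shape != image.shape:
        raise ValueError(
            f"mask shape {mdata.shape} does not match image shape {image.shape}")
    stats = {"fits": 0, "fit_failures": 0}
    if not (mdata > 0).any():
        out = image.copy()
        return (out, stats) if return_stats else out
    passes = []
    if params.passes in ("down", "both"):
        passes.append(_single_pass(image, mdata, params, "down", stats))
    if params.passes in ("up", "both"):
        passes.append(_single_pass(image, mdata, params, "up", stats))
    out = passes[0] if len(passes) == 1 else (passes[0] + passes[1]) / 2.0
    if params.clip_output:
        out = np.clip(out, image.min(), image.max())
    return (out, stats) if return_stats else out


def background_std_report(before: np.ndarray, after: np.ndarray,
                          mask: LabelMask | np.ndarray,
                          radius_px: int = 50) -> dict:
    """Standard deviation of the unmasked background near charging centers.

    The region is all unmasked pixels within ``radius_px`` (Chebyshev
    distance) of any labeled pixel.  ``percent_reduction`` is
    100 * (1 - std_after / std_before).
    """
    before = np.asarray(before, dtype=np.float64)
    after = np.asarray(after, dtype=np.float64)
    mdata = mask.data if isinstance(mask, LabelMask) else np.asarray(mask)
    if before.shape != after.shape or before.shape != mdata.shape:
        raise ValueError("before/after/mask shapes must match")
    labeled = mdata > 0
    if not labeled.any():
        raise ValueError("mask has no labeled pixels")
    from scipy.ndimage import binary_dilation

    footprint = np.ones((2 * radius_px + 1, 2 * radius_px + 1), dtype=bool)
    near = binary_dilation(labeled, structure=footprint)
    region = near & ~labeled
    std_before = float(before[region].std())
    std_after = float(after[region].std())
    reduction = 100.0 * (1.0 - std_after / std_before) if std_before > 0 else 0.0
    return {
        "std_before": std_before,
        "std_after": std_after,
        "percent_reduction": reduction,
        "n_pixels": int(region.sum()),
    }
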