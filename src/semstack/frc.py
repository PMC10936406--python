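"""Fourier Ring Correlation (FRC) resolution estimation.

Two independently acquired images of the same field of view share signal up
to the frequency where noise dominates; the normalized cross-spectral
correlation over rings of spatial frequency ("Fourier ring correlation")
quantifies this, and the frequency where the curve first falls below a
threshold (1/7 ≈ 0.143 by convention) defines the resolution.  When only a
single image exists, sub-images formed from the checkerboard pixel
parities give a one-image FRC; its systematic bias relative to the
two-image gold standard is absorbed by an instrument calibration fitted on
image pairs acquired at several pixel sizes.  Tiling an image and running
the one-image FRC per tile yields a local resolution map.

Conventions: frequencies are normalized so the outermost computed ring is
1 (a 2-pixel period); ``resolution_px = 2 / f_crossing``.  Checkerboard
sub-images are treated as contiguous grids at the original pixel pitch —
the geometric bias this introduces is part of what the calibration absorbs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .io_core import LabelMask

__all__ = [
    "FRCCurve",
    "ResolutionResult",
    "CalibrationModel",
    "ResolutionMap",
    "compute_frc",
    "resolution_from_curve",
    "checkerboard_split",
    "one_image_frc",
    "fit_power_law",
    "fit_calibration",
    "tiled_resolution",
    "compare_tile_sizes",
    "FRC_THRESHOLD",
]

FRC_THRESHOLD = 1.0 / 7.0


@dataclass
class FRCCurve:
    """Ring correlation versus normalized spatial frequency (0, 1]."""

    freq: np.ndarray
    corr: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=np.float64)
        self.corr = np.asarray(self.corr, dtype=np.float64)
        if self.freq.shape != self.corr.shape:
            raise ValueError("freq and corr lengths differ")
        if len(self.freq) and np.any(np.diff(self.freq) <= 0):
            raise ValueError("freq must be strictly increasing")


@dataclass
class ResolutionResult:
    """Threshold crossing of an FRC curve and the implied resolution."""

    f_crossing: float
    resolution_px: float
    resolution_physical: float | None = None
    threshold: float = FRC_THRESHOLD
    calibrated: bool = False
    flag: str | None = None  # None | "at-limit" | "unresolved"

    def to_dict(self) -> dict:
        return {
            "f_crossing": self.f_crossing,
            "resolution_px": self.resolution_px,
            "resolution_nm": self.resolution_physical,
            "threshold": self.threshold,
            "calibrated": self.calibrated,
            "flag": self.flag,
        }


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def _ring_index(shape: tuple[int, int]) -> tuple[np.ndarray, int]:
    """Integer ring index per (unshifted) DFT bin and the max ring used."""
    fy = np.fft.fftfreq(shape[0]) * shape[0]
    fx = np.fft.fftfreq(shape[1]) * shape[1]
    # radius in units of the smaller axis so rings stay isotropic for
    # non-square inputs (callers are expected to pass squares)
    r = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    rings = np.round(r).astype(int)
    n_rings = min(shape) // 2
    return rings, n_rings


def compute_frc(img1: np.ndarray, img2: np.ndarray, ring_width_bins: int = 1,
                window: str = "hann") -> FRCCurve:
    """FRC between two equally shaped square images.

    A Hann taper (default) suppresses edge leakage; per ring q the
    correlation is Re{sum F1 conj(F2)} / sqrt(sum|F1|^2 sum|F2|^2) over the
    DFT bins whose rounded radius falls in ring q.  Frequencies are
    normalized so the outermost ring is 1.
    """
    img1 = np.asarray(img1, dtype=np.float64)
    img2 = np.asarray(img2, dtype=np.float64)
    if img1.shape != img2.shape:
        raise ValueError(f"image shapes differ: {img1.shape} vs {img2.shape}")
    if img1.ndim != 2:
        raise ValueError("FRC expects 2D images")
    if not img1.any() or not img2.any():
        raise ValueError("all-zero image: FRC normalization undefined")
    if window == "hann":
        w = _hann2d(img1.shape)
        img1 = img1 * w
        img2 = img2 * w
    elif window not in (None, "none"):
        raise ValueError(f"unknown window {window!r}")
    F1 = np.fft.fft2(img1)
    F2 = np.fft.fft2(img2)
    rings, n_rings = _ring_index(img1.shape)
    cross = np.real(F1 * np.conj(F2))
    p1 = np.abs(F1) ** 2
    p2 = np.abs(F2) ** 2
    flat = rings.ravel()
    nbins = n_rings + 1
    num = np.bincount(flat, weights=cross.ravel(), minlength=nbins)[:nbins]
    d1 = np.bincount(flat, weights=p1.ravel(), minlength=nbins)[:nbins]
    d2 = np.bincount(flat, weights=p2.ravel(), minlength=nbins)[:nbins]
    qs = np.arange(1, n_rings + 1)
    if ring_width_bins > 1:
        # aggregate consecutive rings
        edges = np.arange(1, n_rings + 1, ring_width_bins)
        num = np.add.reduceat(num[1:], edges - 1)
        d1 = np.add.reduceat(d1[1:], edges - 1)
        d2 = np.add.reduceat(d2[1:], edges - 1)
        qs = np.minimum(edges + ring_width_bins - 1, n_rings)
    else:
        num, d1, d2 = num[1:], d1[1:], d2[1:]
    denom = np.sqrt(d1 * d2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / denom, 0.0)
    freq = qs / n_rings
    return FRCCurve(freq=freq, corr=corr)


def resolution_from_curve(curve: FRCCurve, threshold: float = FRC_THRESHOLD,
                          pixel_size_nm: float | None = None) -> ResolutionResult:
    """First threshold crossing of an FRC curve, linearly interpolated.

    Never dropping below the threshold flags the result "at-limit"
    (f_crossing = 1); being below already at the first ring flags it
    "unresolved".
    """
    if len(curve.freq) == 0:
        raise ValueError("empty FRC curve")
    below = curve.corr < threshold
    flag = None
    if not below.any():
        f_cross = 1.0
        flag = "at-limit"
    else:
        i = int(np.argmax(below))
        if i == 0:
            f_cross = float(curve.freq[0])
            flag = "unresolved"
        else:
            f0, f1 = curve.freq[i - 1], curve.freq[i]
            c0, c1 = curve.corr[i - 1], curve.corr[i]
            f_cross = float(f0 + (c0 - threshold) * (f1 - f0) / (c0 - c1))
    res_px = 2.0 / f_cross
    res_phys = res_px * pixel_size_nm if pixel_size_nm is not None else None
    return ResolutionResult(f_crossing=f_cross, resolution_px=res_px,
                            resolution_physical=res_phys, threshold=threshold,
                            flag=flag)


def checkerboard_split(image: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Four pixel-parity sub-images (even/odd row x even/odd column).

    Odd dimensions are cropped by one row/column; the four sub-images
    partition the cropped pixels exactly.
    """
    image = np.asarray(image)
    if image.shape[0] < 2 or image.shape[1] < 2:
        raise ValueError("image must be at least 2x2")
    h = image.shape[0] - image.shape[0] % 2
    w = image.shape[1] - image.shape[1] % 2
    img = image[:h, :w]
    sub_ee = img[0::2, 0::2]
    sub_oo = img[1::2, 1::2]
    sub_eo = img[0::2, 1::2]
    sub_oe = img[1::2, 0::2]
    return sub_ee, sub_oo, sub_eo, sub_oe


@dataclass
class CalibrationModel:
    """Power-law map from one-image to two-image FRC resolution.

    d_2img = alpha * d_1img ** beta, fitted in log-log space over the
    observed domain of uncalibrated (one-image) resolutions.
    """

    alpha: float
    beta: float
    domain: tuple[float, float]
    family: str = "power_law"
    pixel_sizes_nm: list[float] = field(default_factory=list)
    n_pairs: int = 0
    monotone: bool = True

    @classmethod
    def identity(cls) -> "CalibrationModel":
        return cls(alpha=1.0, beta=1.0, domain=(0.0, np.inf))

    def apply(self, d_1img: float) -> tuple[float, bool]:
        """Map an uncalibrated resolution; returns (value, in_domain)."""
        in_domain = self.domain[0] <= d_1img <= self.domain[1]
        return self.alpha * d_1img ** self.beta, in_domain

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "alpha": self.alpha,
            "beta": self.beta,
            "domain": list(self.domain),
            "pixel_sizes_nm": self.pixel_sizes_nm,
            "n_pairs": self.n_pairs,
            "monotone": self.monotone,
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(alpha=d["alpha"], beta=d["beta"], domain=tuple(d["domain"]),
                   family=d.get("family", "power_law"),
                   pixel_sizes_nm=d.get("pixel_sizes_nm", []),
                   n_pairs=d.get("n_pairs", 0), monotone=d.get("monotone", True))


def _square_even_crop(image: np.ndarray) -> np.ndarray:
    n = min(image.shape[:2])
    n -= n % 2
    return image[:n, :n]


def one_image_frc(image: np.ndarray, calibration: CalibrationModel | None = None,
                  threshold: float = FRC_THRESHOLD,
                  pixel_size_nm: float | None = None) -> ResolutionResult:
    """Resolution of a single image by checkerboard-subsampled FRC.

    Averages the two diagonal-pair curves (even-even vs odd-odd and
    even-odd vs odd-even), extracts the threshold crossing, then maps the
    resolution through the calibration when one is supplied.
    """
    image = np.asarray(image, dtype=np.float64)
    img = _square_even_crop(image)
    if img.shape[0] < 32:
        raise ValueError("image must provide at least 32x32 pixels")
    ee, oo, eo, oe = checkerboard_split(img)
    c1 = compute_frc(ee, oo)
    c2 = compute_frc(eo, oe)
    curve = FRCCurve(freq=c1.freq, corr=(c1.corr + c2.corr) / 2.0)
    result = resolution_from_curve(curve, threshold=threshold)
    if calibration is not None:
        d_cal, _ = calibration.apply(result.resolution_px)
        result.resolution_px = d_cal
        result.f_crossing = 2.0 / d_cal
        result.calibrated = True
    if pixel_size_nm is not None:
        result.resolution_physical = result.resolution_px * pixel_size_nm
    return result


def fit_power_law(d_1img: np.ndarray, d_2img: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of d_2 = alpha * d_1 ** beta in log-log space."""
    d1 = np.asarray(d_1img, dtype=np.float64)
    d2 = np.asarray(d_2img, dtype=np.float64)
    if len(d1) < 2:
        raise ValueError("need at least 2 points to fit the calibration")
    if np.any(d1 <= 0) or np.any(d2 <= 0):
        raise ValueError("resolutions must be positive for the power-law fit")
    beta, log_alpha = np.polyfit(np.log(d1), np.log(d2), 1)
    return float(np.exp(log_alpha)), float(beta)


def fit_calibration(image_pairs, threshold: float = FRC_THRESHOLD) -> CalibrationModel:
    """Fit the one-image -> two-image resolution calibration.

    ``image_pairs`` is a list of ``(img_a, img_b, pixel_size_nm)`` tuples of
    pre-registered repeat acquisitions at distinct pixel sizes.  For each
    pair, the two-image FRC resolution and the mean of the two one-image
    FRC resolutions (in pixels) give one (d_1img, d_2img) point; a power
    law is fitted through the points.
    """
    if len(image_pairs) < 2:
        raise ValueError("need at least 2 image pairs at distinct pixel sizes")
    d1s, d2s, px_sizes = [], [], []
    for img_a, img_b, px in image_pairs:
        a = _square_even_crop(np.asarray(img_a, dtype=np.float64))
        b = _square_even_crop(np.asarray(img_b, dtype=np.float64))
        d2 = resolution_from_curve(compute_frc(a, b), threshold).resolution_px
        d1 = np.mean([one_image_frc(a, threshold=threshold).resolution_px,
                      one_image_frc(b, threshold=threshold).resolution_px])
        d1s.append(float(d1))
        d2s.append(float(d2))
        px_sizes.append(float(px))
    alpha, beta = fit_power_law(np.array(d1s), np.array(d2s))
    order = np.argsort(d1s)
    monotone = bool(beta > 0 and np.all(np.diff(np.array(d2s)[order]) >= 0))
    return CalibrationModel(alpha=alpha, beta=beta,
                            domain=(min(d1s), max(d1s)),
                            pixel_sizes_nm=px_sizes, n_pairs=len(image_pairs),
                            monotone=monotone)


@dataclass
class ResolutionMap:
    """Per-tile resolution grid with summary statistics over included tiles."""

    tile_px: int
    grid_shape: tuple[int, int]
    results: list[dict]  # tile_row, tile_col, result or excluded flag
    mean_px: float
    std_px: float
    median_px: float
    pixel_size_nm: float | None = None

    @property
    def included_resolutions_px(self) -> np.ndarray:
        return np.array([r["resolution_px"] for r in self.results if r["included"]])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.results)


def tiled_resolution(image: np.ndarray, tile_px: int,
                     calibration: CalibrationModel | None = None,
                     mask: LabelMask | np.ndarray | None = None,
                     threshold: float = FRC_THRESHOLD,
                     pixel_size_nm: float | None = None) -> ResolutionMap:
    """Local resolution map from per-tile one-image FRC.

    Non-overlapping tiles anchored top-left; partial edge tiles are
    dropped; tiles with more than 50% masked pixels are excluded.
    """
    image = np.asarray(image, dtype=np.float64)
    if tile_px < 32:
        raise ValueError("tile_px must be >= 32")
    if tile_px > min(image.shape):
        raise ValueError(
            f"tile_px {tile_px} exceeds image dimensions {image.shape}")
    mdata = None
    if mask is not None:
        mdata = mask.data if isinstance(mask, LabelMask) else np.asarray(mask)
        if mdata.shape != image.shape:
            raise ValueError("mask shape does not match image")
    n_ty = image.shape[0] // tile_px
    n_tx = image.shape[1] // tile_px
    results = []
    for ty in range(n_ty):
        for tx in range(n_tx):
            sl = (slice(ty * tile_px, (ty + 1) * tile_px),
                  slice(tx * tile_px, (tx + 1) * tile_px))
            rec = {"tile_row": ty, "tile_col": tx, "included": True,
                   "f_crossing": np.nan, "resolution_px": np.nan,
                   "resolution_nm": np.nan}
            if mdata is not None and (mdata[sl] > 0).mean() > 0.5:
                rec["included"] = False
            else:
                r = one_image_frc(image[sl], calibration=calibration,
                                  threshold=threshold,
                                  pixel_size_nm=pixel_size_nm)
                rec.update(f_crossing=r.f_crossing,
                           resolution_px=r.resolution_px,
                           resolution_nm=r.resolution_physical)
            results.append(rec)
    included = [r["resolution_px"] for r in results if r["included"]]
    if not included:
        raise ValueError("no tiles included (all masked or image too small)")
    arr = np.array(included)
    return ResolutionMap(tile_px=tile_px, grid_shape=(n_ty, n_tx),
                         results=results, mean_px=float(arr.mean()),
                         std_px=float(arr.std()), median_px=float(np.median(arr)),
                         pixel_size_nm=pixel_size_nm)


def compare_tile_sizes(image: np.ndarray, tile_sizes: list[int],
                       calibration: CalibrationModel | None = None,
                       threshold: float = FRC_THRESHOLD,
                       pixel_size_nm: float | None = None) -> dict:
    """Tile-size robustness of the local resolution distribution.

    Runs :func:`tiled_resolution` per tile size and reports per-size
    min/max/median, the maximum absolute difference between medians (in
    pixels), and the Kruskal-Wallis H statistic and p-value across the
    per-tile resolution samples (null: all group medians equal).
    """
    if len(tile_sizes) < 2:
        raise ValueError("need at least 2 tile sizes to compare")
    per_size = {}
    samples = []
    for ts in tile_sizes:
        m = tiled_resolution(image, ts, calibration=calibration,
                             threshold=threshold, pixel_size_nm=pixel_size_nm)
        vals = m.included_resolutions_px
        samples.append(vals)
        per_size[int(ts)] = {
            "n_tiles": int(len(vals)),
            "min_px": float(vals.min()),
            "max_px": float(vals.max()),
            "median_px": float(np.median(vals)),
            "mean_px": float(vals.mean()),
            "std_px": float(vals.std()),
        }
    medians = [v["median_px"] for v in per_size.values()]
    H, p = sstats.kruskal(*samples)
    return {
        "per_size": per_size,
        "median_max_abs_diff_px": float(max(medians) - min(medians)),
        "kruskal_H": float(H),
        "kruskal_p": float(p),
    }
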