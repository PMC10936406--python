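"""Physically constrained serial-stack alignment.

Serial FIB/SEM stacks accumulate slice-to-slice distortions that are
constrained by the acquisition physics: line-scanned imaging after ion-beam
milling produces translations, shear along the fast-scan (x) axis and
stretch along the slow-scan (y) axis — but not rotation.  Generic affine or
rigid registration of such stacks can therefore introduce nonphysical
rotations that propagate through the stack.  This module fits landmark
correspondences with a user-constrained transformation family so that
disabled degrees of freedom stay at their identity values exactly.

The fitted model maps a source landmark ``r`` to ``r' = A @ r + b`` with
``A`` a 2x2 matrix and ``b`` a translation, both in pixel units with points
as (x, y) = (column, row).  For families without rotation the least-squares
problem is linear in the enabled entries and solved exactly via the normal
equations; rotation families use the closed-form Procrustes (Umeyama)
solution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .io_core import ImageStack

__all__ = [
    "TransformSpec",
    "AffineTransform2D",
    "MatchSet",
    "AlignmentResult",
    "PercentileFilter",
    "RansacFilter",
    "detect_and_match",
    "filter_matches_percentile",
    "filter_matches_ransac",
    "fit_constrained_transform",
    "compose_transforms",
    "apply_transform",
    "align_stack",
]


@dataclass(frozen=True)
class TransformSpec:
    """Boolean flags selecting the degrees of freedom of the fit.

    ``affine`` enables all six parameters and overrides the other flags.
    ``rotate`` may only be combined with ``translate`` and
    ``scale_uniform`` (rigid / similarity); mixing rotation with shear or
    stretch has no closed-form constrained solution and is rejected.
    ``scale_uniform`` excludes ``stretch_x``/``stretch_y``.
    """

    translate: bool = False
    rotate: bool = False
    shear_x: bool = False
    shear_y: bool = False
    stretch_x: bool = False
    stretch_y: bool = False
    scale_uniform: bool = False
    affine: bool = False

    def __post_init__(self) -> None:
        if self.affine:
            return
        if self.rotate and (self.shear_x or self.shear_y or self.stretch_x or self.stretch_y):
            raise ValueError("rotate may only be combined with translate and scale_uniform")
        if self.scale_uniform and (self.stretch_x or self.stretch_y):
            raise ValueError("scale_uniform excludes stretch_x/stretch_y")
        if not any(
            (self.translate, self.rotate, self.shear_x, self.shear_y,
             self.stretch_x, self.stretch_y, self.scale_uniform)
        ):
            raise ValueError("at least one degree of freedom must be enabled")

    @property
    def n_params(self) -> int:
        if self.affine:
            return 6
        n = 0
        n += 2 if self.translate else 0
        n += 1 if self.rotate else 0
        n += sum((self.shear_x, self.shear_y, self.stretch_x,
                  self.stretch_y, self.scale_uniform))
        return n

    @property
    def min_matches(self) -> int:
        if self.affine:
            return 3
        return max(1, math.ceil(self.n_params / 2))

    @classmethod
    def from_names(cls, names) -> "TransformSpec":
        """Build from an iterable of flag names, e.g. ``["translate", "shear_x"]``."""
        if isinstance(names, str):
            names = [n.strip() for n in names.split(",") if n.strip()]
        valid = {f for f in cls.__dataclass_fields__}
        unknown = set(names) - valid
        if unknown:
            raise ValueError(f"unknown transform flags {sorted(unknown)}; valid: {sorted(valid)}")
        return cls(**{n: True for n in names})

    def names(self) -> list[str]:
        return [f for f in self.__dataclass_fields__ if getattr(self, f)]


@dataclass
class AffineTransform2D:
    """A 2x2 matrix plus translation acting on (x, y) points: r' = A r + b."""

    A: np.ndarray = field(default_factory=lambda: np.eye(2))
    b: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64).reshape(2, 2)
        self.b = np.asarray(self.b, dtype=np.float64).reshape(2)
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.b))):
            raise ValueError("transform entries must be finite")

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) points (x, y) through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts @ self.A.T + self.b

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return self ∘ other (``other`` applied first)."""
        return AffineTransform2D(self.A @ other.A, self.A @ other.b + self.b)

    def inverse(self) -> "AffineTransform2D":
        Ainv = np.linalg.inv(self.A)
        return AffineTransform2D(Ainv, -Ainv @ self.b)

    def is_identity(self, atol: float = 0.0) -> bool:
        return bool(
            np.allclose(self.A, np.eye(2), atol=atol, rtol=0)
            and np.allclose(self.b, 0.0, atol=atol, rtol=0)
        )

    def to_dict(self) -> dict:
        return {"A": self.A.tolist(), "b": self.b.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform2D":
        return cls(np.asarray(d["A"]), np.asarray(d["b"]))


@dataclass
class MatchSet:
    """Paired landmark coordinates between two images, as (x, y) points."""

    points_src: np.ndarray
    points_dst: np.ndarray
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points_src = np.asarray(self.points_src, dtype=np.float64).reshape(-1, 2)
        self.points_dst = np.asarray(self.points_dst, dtype=np.float64).reshape(-1, 2)
        if self.points_src.shape != self.points_dst.shape:
            raise ValueError("source and destination point lists differ in length")
        if self.scores is None:
            self.scores = np.ones(len(self.points_src))
        else:
            self.scores = np.asarray(self.scores, dtype=np.float64).reshape(-1)
            if len(self.scores) != len(self.points_src):
                raise ValueError("scores length does not match points")

    def __len__(self) -> int:
        return len(self.points_src)

    @property
    def displacements(self) -> np.ndarray:
        return self.points_dst - self.points_src

    def subset(self, index) -> "MatchSet":
        return MatchSet(self.points_src[index], self.points_dst[index], self.scores[index])


DEFAULT_DETECTOR_PARAMS = {
    "upsampling": 1,
    "n_octaves": 8,
    "n_scales": 3,
    "sigma_min": 1.6,
    "c_dog": 0.009,
    "c_edge": 10.0,
    "lowe_ratio": 0.75,
}


def detect_and_match(img_a: np.ndarray, img_b: np.ndarray,
                     params: dict | None = None) -> MatchSet:
    """SIFT keypoint detection + descriptor matching between two images.

    Nearest-neighbour descriptor matching with cross-checking and a Lowe
    ratio test (default 0.75).  Deterministic for fixed inputs and
    settings.  Returns an empty :class:`MatchSet` when either image yields
    no keypoints.
    """
    from skimage.feature import SIFT, match_descriptors

    img_a = np.asarray(img_a, dtype=np.float64)
    img_b = np.asarray(img_b, dtype=np.float64)
    if img_a.shape != img_b.shape:
        raise ValueError(f"image shapes differ: {img_a.shape} vs {img_b.shape}")
    if not (np.all(np.isfinite(img_a)) and np.all(np.isfinite(img_b))):
        raise ValueError("images must be finite")
    p = dict(DEFAULT_DETECTOR_PARAMS, **(params or {}))
    lowe_ratio = p.pop("lowe_ratio")
    empty = MatchSet(np.empty((0, 2)), np.empty((0, 2)))
    keypoints, descriptors = [], []
    for img in (img_a, img_b):
        det = SIFT(**p)
        try:
            det.detect_and_extract(img)
        except RuntimeError:  # no features found
            return empty
        keypoints.append(det.keypoints)
        descriptors.append(det.descriptors)
    if any(len(k) == 0 for k in keypoints):
        return empty
    pairs = match_descriptors(descriptors[0], descriptors[1],
                              cross_check=True, max_ratio=lowe_ratio)
    if len(pairs) == 0:
        return empty
    # keypoints are (row, col); convert to (x, y)
    src = keypoints[0][pairs[:, 0]][:, ::-1].astype(np.float64)
    dst = keypoints[1][pairs[:, 1]][:, ::-1].astype(np.float64)
    return MatchSet(src, dst)


def filter_matches_percentile(matches: MatchSet, q: float = 5.0) -> MatchSet:
    """Keep matches whose displacement lies in the central percentile band.

    Displacements d_i = r'_i - r_i are filtered component-wise: a match is
    kept when both its x and y displacement fall inside the inclusive
    [q, 100 - q] percentile interval of the respective component
    distribution.  ``q = 0`` returns the input unchanged.
    """
    if len(matches) == 0:
        raise ValueError("no matches to filter")
    if not 0 <= q < 50:
        raise ValueError(f"q must be in [0, 50), got {q}")
    if q == 0:
        return matches
    d = matches.displacements
    keep = np.ones(len(matches), dtype=bool)
    for axis in (0, 1):
        lo, hi = np.percentile(d[:, axis], [q, 100 - q])
        keep &= (d[:, axis] >= lo) & (d[:, axis] <= hi)
    return matches.subset(keep)


def filter_matches_ransac(matches: MatchSet, spec: TransformSpec,
                          inlier_tol_px: float = 2.0, n_iter: int = 1000,
                          seed: int = 0) -> MatchSet:
    """RANSAC outlier rejection under the constrained model family.

    Repeatedly fits the constrained transform on a random minimal sample
    and keeps the largest consensus set (residual below
    ``inlier_tol_px``).  Reproducible for a fixed ``seed``.
    """
    min_sample = max(3, spec.min_matches)
    n = len(matches)
    if n < min_sample:
        raise ValueError(
            f"RANSAC needs at least {min_sample} matches for this spec, got {n} "
            f"(short by {min_sample - n})"
        )
    rng = np.random.default_rng(seed)
    best_inliers = np.zeros(n, dtype=bool)
    for _ in range(n_iter):
        idx = rng.choice(n, size=min_sample, replace=False)
        try:
            t = fit_constrained_transform(matches.subset(idx), spec)
        except (ValueError, np.linalg.LinAlgError):
            continue  # degenerate sample
        resid = np.linalg.norm(t.apply(matches.points_src) - matches.points_dst, axis=1)
        inliers = resid < inlier_tol_px
        if inliers.sum() > best_inliers.sum():
            best_inliers = inliers
    if best_inliers.sum() < min_sample:
        return matches.subset(best_inliers)
    # refine once: refit on the consensus set and re-evaluate membership
    t = fit_constrained_transform(matches.subset(best_inliers), spec)
    resid = np.linalg.norm(t.apply(matches.points_src) - matches.points_dst, axis=1)
    refined = resid < inlier_tol_px
    if refined.sum() >= best_inliers.sum():
        best_inliers = refined
    return matches.subset(best_inliers)


def _fit_linear_family(src: np.ndarray, dst: np.ndarray,
                       spec: TransformSpec) -> AffineTransform2D:
    """Exact least squares for families linear in their parameters."""
    n = len(src)
    x, y = src[:, 0], src[:, 1]
    ones, zeros = np.ones(n), np.zeros(n)
    cols: list[np.ndarray] = []
    names: list[str] = []

    def add(name, col_x, col_y):
        names.append(name)
        cols.append(np.concatenate([col_x, col_y]))

    if spec.affine or spec.stretch_x:
        add("a11", x, zeros)
    if spec.scale_uniform and not spec.affine:
        add("s", x, y)  # shared diagonal
    if spec.affine or spec.shear_x:
        add("a12", y, zeros)
    if spec.affine or spec.shear_y:
        add("a21", zeros, x)
    if spec.affine or spec.stretch_y:
        add("a22", zeros, y)
    if spec.affine or spec.translate:
        add("b1", ones, zeros)
        add("b2", zeros, ones)

    # constant (identity) contribution for entries that are not fitted
    const_x = zeros.copy() if ("a11" in names or "s" in names) else x.copy()
    const_y = zeros.copy() if ("a22" in names or "s" in names) else y.copy()
    target = np.concatenate([dst[:, 0] - const_x, dst[:, 1] - const_y])

    M = np.column_stack(cols)
    if n * 2 < len(names):
        raise ValueError(f"{n} matches cannot determine {len(names)} parameters")
    sol, _, rank, _ = np.linalg.lstsq(M, target, rcond=None)
    if rank < len(names):
        raise ValueError("rank-deficient system: matches do not determine the "
                         "enabled parameters (e.g. collinear points)")
    p = dict(zip(names, sol))
    A = np.eye(2)
    if "s" in p:
        A[0, 0] = A[1, 1] = p["s"]
    A[0, 0] = p.get("a11", A[0, 0])
    A[0, 1] = p.get("a12", 0.0)
    A[1, 0] = p.get("a21", 0.0)
    A[1, 1] = p.get("a22", A[1, 1])
    b = np.array([p.get("b1", 0.0), p.get("b2", 0.0)])
    return AffineTransform2D(A, b)


def _fit_procrustes(src: np.ndarray, dst: np.ndarray,
                    with_scale: bool) -> AffineTransform2D:
    """Closed-form rigid / similarity fit (Umeyama)."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    sc, dc = src - mu_s, dst - mu_d
    cov = dc.T @ sc / len(src)
    U, S, Vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, d])
    R = U @ D @ Vt
    if with_scale:
        var_s = (sc ** 2).sum() / len(src)
        if var_s == 0:
            raise ValueError("degenerate source points (zero variance)")
        scale = float(np.trace(np.diag(S) @ D)) / var_s
    else:
        scale = 1.0
    A = scale * R
    b = mu_d - A @ mu_s
    return AffineTransform2D(A, b)


def fit_constrained_transform(matches: MatchSet, spec: TransformSpec) -> AffineTransform2D:
    """Least-squares transform within the spec's family.

    Minimises sum_i || A r_i + b - r'_i ||^2 over the enabled parameters.
    Matrix entries not enabled by the spec are exactly their identity
    values in the returned transform.
    """
    if len(matches) < spec.min_matches:
        raise ValueError(
            f"need at least {spec.min_matches} matches for this spec, got {len(matches)}"
        )
    src, dst = matches.points_src, matches.points_dst
    if spec.affine or not spec.rotate:
        return _fit_linear_family(src, dst, spec)
    return _fit_procrustes(src, dst, with_scale=spec.scale_uniform)


def compose_transforms(pairwise: list[AffineTransform2D]) -> list[AffineTransform2D]:
    """Cumulative transforms to the reference (slice 0) frame.

    ``pairwise[k]`` is the correcting transform mapping slice ``k+1``
    coordinates into slice ``k``'s frame; ``cumulative[k]`` maps slice
    ``k`` into slice 0's frame.  ``cumulative[0]`` is the identity and
    ``cumulative[k] = pairwise[0] ∘ … ∘ pairwise[k-1]``.
    """
    cumulative = [AffineTransform2D.identity()]
    for t in pairwise:
        cumulative.append(cumulative[-1].compose(t))
    return cumulative


def apply_transform(image: np.ndarray, t: AffineTransform2D,
                    interpolation: str = "bilinear",
                    fill_value: float = 0.0) -> np.ndarray:
    """Warp an image so a feature at r appears at ``t(r)`` in the output.

    Each output pixel is sampled from the input at the inverse-mapped
    location; out-of-bounds samples take ``fill_value``.  Output shape
    equals input shape.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    det = np.linalg.det(t.A)
    if abs(det) < 1e-12:
        raise ValueError("transform matrix is singular")
    order = {"nearest": 0, "bilinear": 1, "bicubic": 3}[interpolation]
    inv = t.inverse()
    # convert (x, y) convention to ndimage's (row, col)
    P = np.array([[0.0, 1.0], [1.0, 0.0]])
    M = P @ inv.A @ P
    offset = P @ inv.b
    return ndimage.affine_transform(image, M, offset=offset, order=order,
                                    mode="constant", cval=fill_value)


@dataclass
class PercentileFilter:
    q: float = 5.0


@dataclass
class RansacFilter:
    inlier_tol_px: float = 2.0
    n_iter: int = 1000
    seed: int = 0


@dataclass
class AlignmentResult:
    """Per-pair transforms, diagnostics, and cumulative maps to slice 0."""

    pairwise: list[AffineTransform2D]
    cumulative: list[AffineTransform2D]
    n_matches_used: list[int]
    residual_rms: list[float]
    fallback_pairs: list[int]
    spec: TransformSpec
    detector_params: dict

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.names(),
            "detector_params": self.detector_params,
            "pairwise": [t.to_dict() for t in self.pairwise],
            "cumulative": [t.to_dict() for t in self.cumulative],
            "n_matches_used": self.n_matches_used,
            "residual_rms": self.residual_rms,
            "fallback_pairs": self.fallback_pairs,
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def align_stack(stack: ImageStack, spec: TransformSpec,
                match_filter: PercentileFilter | RansacFilter | None = None,
                detector_params: dict | None = None,
                interpolation: str = "bilinear") -> tuple[ImageStack, AlignmentResult]:
    """Align a stack slice-by-slice under the constrained model.

    For each consecutive pair, SIFT matches from slice k+1 to slice k are
    filtered and fitted, giving the correcting transform into slice k's
    frame; cumulative transforms to slice 0 are composed and each slice is
    resampled exactly once.  Pairs with too few matches fall back to the
    previous pairwise transform (or identity) and are flagged — alignment
    degradation is reported, never raised.
    """
    if stack.n_slices < 2:
        raise ValueError("need at least 2 slices to align")
    if match_filter is None:
        match_filter = RansacFilter()
    dparams = dict(DEFAULT_DETECTOR_PARAMS, **(detector_params or {}))
    pairwise: list[AffineTransform2D] = []
    n_used: list[int] = []
    rms: list[float] = []
    fallback: list[int] = []
    for k in range(stack.n_slices - 1):
        matches = detect_and_match(stack[k + 1], stack[k], dparams)
        try:
            if len(matches) == 0:
                raise ValueError("no matches")
            if isinstance(match_filter, PercentileFilter):
                matches = filter_matches_percentile(matches, match_filter.q)
            else:
                matches = filter_matches_ransac(
                    matches, spec, match_filter.inlier_tol_px,
                    match_filter.n_iter, match_filter.seed)
            t = fit_constrained_transform(matches, spec)
        except ValueError:
            t = pairwise[-1] if pairwise else AffineTransform2D.identity()
            fallback.append(k)
            n_used.append(0)
            rms.append(float("nan"))
        else:
            resid = np.linalg.norm(
                t.apply(matches.points_src) - matches.points_dst, axis=1)
            n_used.append(len(matches))
            rms.append(float(np.sqrt(np.mean(resid ** 2))))
        pairwise.append(t)
    cumulative = compose_transforms(pairwise)
    aligned = np.empty_like(stack.data)
    for k in range(stack.n_slices):
        t = cumulative[k]
        if t.is_identity():
            aligned[k] = stack[k]
        else:
            aligned[k] = apply_transform(stack[k], t, interpolation=interpolation,
                                         fill_value=float(np.median(stack[k])))
    result = AlignmentResult(pairwise, cumulative, n_used, rms, fallback,
                             spec, dparams)
    return ImageStack(aligned, pixel_size_nm=stack.pixel_size_nm), result
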