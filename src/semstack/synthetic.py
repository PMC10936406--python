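"""Seeded synthetic-data generators with recorded ground truth.

Each generator is a pure function of its parameters and a seed (one
private NumPy Generator per call, no global state), and returns a
:class:`GroundTruthRecord` holding every applied parameter so tests read
ground truth from the record rather than re-deriving it.

The textures emulate the ingredients the algorithms rely on — local
contrast for SIFT landmarks, flat background with parametric charging
tails, band-limited spectra with a known cutoff — not the full physics of
SEM image formation (no Poisson-Gaussian noise mixtures, no curtaining).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .chafer import SigmoidTailModel, sigmoid_tail
from .io_core import ImageStack, LabelMask
from .stack_align import AffineTransform2D, TransformSpec, apply_transform

__all__ = [
    "GroundTruthRecord",
    "make_textured_image",
    "make_misaligned_stack",
    "make_charging_image",
    "make_bandlimited_pair",
]


@dataclass
class GroundTruthRecord:
    """All parameters applied by a generator call, JSON-serializable."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    def record_stats(self, data: np.ndarray) -> None:
        self.stats = {
            "min": float(np.min(data)),
            "max": float(np.max(data)),
            "mean": float(np.mean(data)),
        }

    def to_dict(self) -> dict:
        return {"generator": self.generator, "seed": self.seed,
                "params": self.params, "stats": self.stats}

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GroundTruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def make_textured_image(shape: tuple[int, int] = (512, 512),
                        blob_density: float = 3e-3,
                        noise_sigma: float = 0.02,
                        seed: int = 0) -> np.ndarray:
    """SEM-like texture: multi-scale smoothed random blobs plus noise.

    Values roughly in [0, 1] with enough local contrast that SIFT finds
    hundreds of keypoints on a 512x512 image at the default density.
    """
    if min(shape) < 64:
        raise ValueError("shape must be at least 64x64")
    rng = np.random.default_rng(seed)
    img = np.zeros(shape, dtype=np.float64)
    n_pix = shape[0] * shape[1]
    for sigma, weight in ((2.0, 0.6), (5.0, 1.0), (11.0, 0.8)):
        impulses = np.zeros(n_pix)
        k = max(1, int(blob_density * n_pix))
        idx = rng.choice(n_pix, size=k, replace=False)
        impulses[idx] = rng.normal(size=k)
        layer = ndimage.gaussian_filter(impulses.reshape(shape), sigma)
        layer /= max(layer.std(), 1e-12)
        img += weight * layer
    img /= max(img.std(), 1e-12)
    img = 0.5 + 0.18 * img
    if noise_sigma > 0:
        img = img + rng.normal(scale=noise_sigma, size=shape)
    return img


def _cumulative_transform(params: dict) -> AffineTransform2D:
    """Build a transform from named parameters (identity defaults)."""
    A = np.eye(2)
    A[0, 0] = params.get("stretch_x", params.get("scale", 1.0))
    A[1, 1] = params.get("stretch_y", params.get("scale", 1.0))
    A[0, 1] = params.get("shear_x", 0.0)
    A[1, 0] = params.get("shear_y", 0.0)
    if "rotate" in params:
        th = params["rotate"]
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        A = A @ R
    b = np.array([params.get("tx", 0.0), params.get("ty", 0.0)])
    return AffineTransform2D(A, b)


def make_misaligned_stack(n_slices: int = 10,
                          spec: TransformSpec | None = None,
                          param_schedule=None,
                          shape: tuple[int, int] = (512, 512),
                          evolution_amplitude: float = 0.02,
                          seed: int = 0) -> tuple[ImageStack, GroundTruthRecord]:
    """Textured stack whose slice k is warped by a known cumulative transform.

    ``param_schedule`` maps slice index k to a dict of cumulative transform
    parameters (keys among tx, ty, shear_x, shear_y, stretch_x, stretch_y,
    scale, rotate); it may be a callable, a list of dicts, or None
    (identity).  Consecutive slices also differ by a small smooth intensity
    perturbation (default 2% amplitude) so they resemble serial sections
    rather than copies.
    """
    if n_slices < 2:
        raise ValueError("need at least 2 slices")
    spec = spec or TransformSpec(translate=True)
    rng = np.random.default_rng(seed)
    base = make_textured_image(shape, seed=int(rng.integers(2 ** 31)))
    slices = []
    transforms: list[AffineTransform2D] = []
    schedule_used = []
    texture = base
    for k in range(n_slices):
        if k > 0 and evolution_amplitude > 0:
            perturb = ndimage.gaussian_filter(rng.normal(size=shape), 15.0)
            perturb /= max(perturb.std(), 1e-12)
            texture = texture + evolution_amplitude * texture.std() * perturb
        if param_schedule is None:
            params = {}
        elif callable(param_schedule):
            params = dict(param_schedule(k))
        else:
            params = dict(param_schedule[k])
        _check_params_in_family(params, spec)
        schedule_used.append(params)
        t = _cumulative_transform(params)
        transforms.append(t)
        if t.is_identity():
            slices.append(texture.copy())
        else:
            slices.append(apply_transform(texture, t,
                                          fill_value=float(np.median(texture))))
    data = np.stack(slices)
    record = GroundTruthRecord(
        generator="make_misaligned_stack", seed=seed,
        params={
            "n_slices": n_slices,
            "shape": list(shape),
            "spec": spec.names(),
            "schedule": schedule_used,
            "evolution_amplitude": evolution_amplitude,
            "cumulative_transforms": [t.to_dict() for t in transforms],
        },
    )
    record.record_stats(data)
    return ImageStack(data, pixel_size_nm=1.0), record


_PARAM_FLAGS = {
    "tx": "translate", "ty": "translate", "shear_x": "shear_x",
    "shear_y": "shear_y", "stretch_x": "stretch_x", "stretch_y": "stretch_y",
    "scale": "scale_uniform", "rotate": "rotate",
}


def _check_params_in_family(params: dict, spec: TransformSpec) -> None:
    if spec.affine:
        return
    for key in params:
        flag = _PARAM_FLAGS.get(key)
        if flag is None:
            raise ValueError(f"unknown schedule parameter {key!r}")
        if not getattr(spec, flag):
            raise ValueError(f"parameter {key!r} is outside the spec family "
                             f"{spec.names()}")


def make_charging_image(shape: tuple[int, int] = (256, 384),
                        centers=((190, 128, 28, 14),),
                        tail_params=None,
                        center_depth: float = 55.0,
                        background_level: float = 100.0,
                        noise_sigma: float = 0.0,
                        seed: int = 0
                        ) -> tuple[np.ndarray, LabelMask, GroundTruthRecord]:
    """Flat background + dark elliptical charge centers + sigmoid tails.

    ``centers`` is a list of ellipses ``(x, y, rx, ry)`` in pixels;
    ``tail_params`` gives per-center ``{"left": (amplitude, width),
    "right": (amplitude, width)}`` (defaults: asymmetric dark tails).
    Every row crossing an ellipse receives additive tails of the exact
    shifted-logistic form anchored at the ellipse boundary of that row,
    so a fit against the known background recovers the parameters exactly
    in the noiseless case.  Overlapping ellipses are rejected to keep the
    fitting windows well-defined.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    if tail_params is None:
        tail_params = [{"left": (-30.0, 6.0), "right": (-18.0, 10.0)}
                       for _ in centers]
    image = np.full(shape, background_level, dtype=np.float64)
    mask = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    for label, (cx, cy, rx, ry) in enumerate(centers, start=1):
        if not (0 <= cx - rx and cx + rx < w and 0 <= cy - ry and cy + ry < h):
            raise ValueError(f"center {label} extends outside the image")
        inside = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
        if (mask[inside] > 0).any():
            raise ValueError("overlapping ellipses are not supported")
        mask[inside] = label
        image[inside] = background_level - center_depth
    cols = np.arange(w, dtype=np.float64)
    applied = []
    for label, ((cx, cy, rx, ry), tails) in enumerate(zip(centers, tail_params), 1):
        rows = np.flatnonzero((mask == label).any(axis=1))
        for r in rows:
            seg_cols = np.flatnonzero(mask[r] == label)
            x0, x1 = int(seg_cols[0]), int(seg_cols[-1])
            la, lw = tails.get("left", (0.0, 1.0))
            ra, rw = tails.get("right", (0.0, 1.0))
            if la != 0.0:
                m = SigmoidTailModel("left", la, float(x0), lw)
                image[r, :x0] += sigmoid_tail(cols[:x0], m)
            if ra != 0.0:
                m = SigmoidTailModel("right", ra, float(x1), rw)
                image[r, x1 + 1:] += sigmoid_tail(cols[x1 + 1:], m)
        applied.append({"center": [cx, cy, rx, ry], "tails": tails})
    if noise_sigma > 0:
        image = image + rng.normal(scale=noise_sigma, size=shape)
    record = GroundTruthRecord(
        generator="make_charging_image", seed=seed,
        params={
            "shape": list(shape),
            "centers": applied,
            "center_depth": center_depth,
            "background_level": background_level,
            "noise_sigma": noise_sigma,
        },
    )
    record.record_stats(image)
    return image, LabelMask(mask), record


def make_bandlimited_pair(shape: tuple[int, int] = (512, 512),
                          cutoff_norm: float = 0.5,
                          snr: float = 10.0,
                          seed: int = 0
                          ) -> tuple[np.ndarray, np.ndarray, GroundTruthRecord]:
    """Two noisy realizations of a hard-low-passed white-noise ground truth.

    The ground-truth spectrum is exactly zero above ``cutoff_norm`` (in
    units of the maximum computed ring frequency, i.e. 1 = 2-pixel
    period); both outputs add independent white Gaussian noise with
    standard deviation ``gt_std / snr``.  ``snr = inf`` returns two copies
    of the ground truth.
    """
    if not 0 < cutoff_norm <= 1:
        raise ValueError("cutoff_norm must be in (0, 1]")
    if shape[0] != shape[1]:
        raise ValueError("shape must be square")
    rng = np.random.default_rng(seed)
    n = shape[0]
    white = rng.normal(size=shape)
    F = np.fft.fft2(white)
    fy = np.fft.fftfreq(n) * n
    r = np.sqrt(fy[:, None] ** 2 + fy[None, :] ** 2)
    F[r > cutoff_norm * (n // 2)] = 0.0
    gt = np.real(np.fft.ifft2(F))
    gt /= max(gt.std(), 1e-12)
    if np.isinf(snr):
        img_a, img_b = gt.copy(), gt.copy()
    else:
        noise_sd = 1.0 / snr
        img_a = gt + rng.normal(scale=noise_sd, size=shape)
        img_b = gt + rng.normal(scale=noise_sd, size=shape)
    record = GroundTruthRecord(
        generator="make_bandlimited_pair", seed=seed,
        params={"shape": list(shape), "cutoff_norm": cutoff_norm,
                "snr": None if np.isinf(snr) else snr},
    )
    record.record_stats(np.stack([img_a, img_b]))
    return img_a, img_b, record
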