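"""Synthetic MRI-like phantoms with known tumor masks, areas and curation labels.

The clinical osteosarcoma MRI dataset this pipeline targets is embargoed, so
every downstream stage is exercised on phantoms that emulate a T1-weighted
slice: a bright body region on a dark background containing a tumor blob whose
intensity sits close to the surrounding tissue, with blurred boundaries and
additive Gaussian noise.  The tumor outline is an ellipse with an optional
low-order radial harmonic perturbation, so the ground-truth area is available
in closed form (shoelace formula on a dense analytic polygon) and the
usefulness label (US = useful slice, NS = normal/difficult slice) is known by
construction: a slice is US iff its tumor-pixel fraction reaches a threshold
and its boundary blur stays below a cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as _draw_polygon

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "generate_slice",
    "generate_dataset",
    "augment",
    "polygon_area",
    "write_sample",
]

# Rotation convention used across the package: rotations are counter-clockwise
# in the usual image sense, on row-major arrays with the origin at the top left
# (numpy's rot90).  A pixel at (row r, col c) of an HxW image maps under one
# 90-degree rotation to (W-1-c, r).
ROTATION_CONVENTION = "ccw-rowmajor-origin-topleft"


@dataclass
class PhantomSpec:
    """Generation parameters for one family of synthetic slices.

    Intensities are 8-bit gray levels, geometry is in millimetres.
    ``boundary_blur_sigma`` may be a single value (pixels) or a ``(lo, hi)``
    range sampled per slice; ``tumor_size_range`` bounds the mean tumor radius.
    """

    image_height: int = 128
    image_width: int = 128
    pixel_spacing: float = 0.5  # mm per pixel, isotropic
    body_intensity_mean: float = 170.0
    tumor_intensity_mean: float = 120.0
    background_intensity_mean: float = 25.0
    noise_sigma: float = 8.0
    boundary_blur_sigma: object = (0.6, 2.4)  # pixels; float or (lo, hi)
    tumor_shape: str = "perturbed-ellipse"  # or "ellipse"
    harmonic_amplitude: float = 0.12  # relative radial perturbation bound
    tumor_size_range: tuple = (6.0, 16.0)  # mm, mean tumor radius
    us_area_fraction_threshold: float = 0.08  # near the median for the size range
    ns_blur_cutoff: float = 1.8  # pixels; blur above this forces NS

    def validate(self) -> None:
        for v in (
            self.body_intensity_mean,
            self.tumor_intensity_mean,
            self.background_intensity_mean,
        ):
            if not 0.0 <= v <= 255.0:
                raise ValueError("intensity means must lie in [0, 255]")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.tumor_size_range[0] > self.tumor_size_range[1]:
            raise ValueError("tumor_size_range must be (lo, hi) with lo <= hi")
        body_a, body_b = self._body_semiaxes_mm()
        if self.tumor_size_range[1] * 1.3 > min(body_a, body_b):
            raise ValueError("tumor does not fit inside the body region")

    def _body_semiaxes_mm(self) -> tuple:
        h_mm = self.image_height * self.pixel_spacing
        w_mm = self.image_width * self.pixel_spacing
        return 0.44 * w_mm, 0.40 * h_mm


@dataclass
class PhantomSample:
    image: np.ndarray  # (H, W) uint8
    mask: np.ndarray  # (H, W) uint8, 1 = tumor
    true_area: float  # mm^2, closed-form area of the generating shape
    usefulness_label: str  # "US" or "NS"
    seed: int
    meta: dict = field(default_factory=dict)


def polygon_area(xy: np.ndarray) -> float:
    """Shoelace area of a closed polygon given as (n, 2) xy vertices in mm."""
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def _tumor_polygon(
    rng: np.random.Generator, spec: PhantomSpec, center_mm: np.ndarray, n_vertices: int = 2048
) -> np.ndarray:
    """Dense analytic outline of the tumor in mm coordinates (x, y)."""
    lo, hi = spec.tumor_size_range
    r0 = float(rng.uniform(lo, hi))
    ecc = float(rng.uniform(0.7, 1.0))
    a, b = r0 / np.sqrt(ecc), r0 * np.sqrt(ecc)  # keep pi*a*b ~ pi*r0^2
    tilt = float(rng.uniform(0, np.pi))
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    pert = np.zeros_like(theta)
    if spec.tumor_shape == "perturbed-ellipse" and r0 > 0:
        for k in (3, 4, 5):
            amp = rng.uniform(0.0, spec.harmonic_amplitude / 3.0)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            pert += amp * np.cos(k * theta + phi)
    px = a * np.cos(theta) * (1.0 + pert)
    py = b * np.sin(theta) * (1.0 + pert)
    ct, st = np.cos(tilt), np.sin(tilt)
    xy = np.stack([ct * px - st * py, st * px + ct * py], axis=1) + center_mm
    return xy


def generate_slice(spec: PhantomSpec, seed: int) -> PhantomSample:
    """Generate one phantom slice; deterministic for fixed (spec, seed)."""
    spec.validate()
    rng = np.random.default_rng(seed)
    H, W, sp = spec.image_height, spec.image_width, spec.pixel_spacing
    cy_mm, cx_mm = H * sp / 2.0, W * sp / 2.0
    body_a, body_b = spec._body_semiaxes_mm()

    # body ellipse (x semi-axis body_a, y semi-axis body_b), slight jitter
    ba = body_a * rng.uniform(0.95, 1.0)
    bb = body_b * rng.uniform(0.95, 1.0)

    # tumor center inside the body core so the shape cannot poke out
    max_r = spec.tumor_size_range[1] * (1.0 + spec.harmonic_amplitude)
    reach_x = max(ba - max_r - 2.0 * sp, 0.0)
    reach_y = max(bb - max_r - 2.0 * sp, 0.0)
    ang = rng.uniform(0.0, 2.0 * np.pi)
    rad = np.sqrt(rng.uniform(0.0, 1.0)) * 0.7
    center = np.array([cx_mm + rad * reach_x * np.cos(ang), cy_mm + rad * reach_y * np.sin(ang)])

    poly = _tumor_polygon(rng, spec, center)
    true_area = polygon_area(poly)

    # rasterize tumor polygon (mm -> pixel index; pixel centers at (i+0.5)*sp)
    rows = poly[:, 1] / sp - 0.5
    cols = poly[:, 0] / sp - 0.5
    mask = np.zeros((H, W), dtype=np.uint8)
    if true_area > 0:
        rr, cc = _draw_polygon(rows, cols, shape=(H, W))
        mask[rr, cc] = 1

    # body mask
    yy, xx = np.mgrid[0:H, 0:W]
    x_mm = (xx + 0.5) * sp
    y_mm = (yy + 0.5) * sp
    body = ((x_mm - cx_mm) / ba) ** 2 + ((y_mm - cy_mm) / bb) ** 2 <= 1.0

    img = np.full((H, W), spec.background_intensity_mean)
    img[body] = spec.body_intensity_mean
    img[mask == 1] = spec.tumor_intensity_mean

    blur = spec.boundary_blur_sigma
    if isinstance(blur, (tuple, list)):
        blur = float(rng.uniform(blur[0], blur[1]))
    if blur > 0:
        img = ndimage.gaussian_filter(img, sigma=blur)
    img = img + rng.normal(0.0, spec.noise_sigma, size=(H, W))
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    frac = mask.mean()
    label = (
        "US"
        if (frac >= spec.us_area_fraction_threshold and blur <= spec.ns_blur_cutoff)
        else "NS"
    )
    return PhantomSample(
        image=img,
        mask=mask,
        true_area=float(true_area),
        usefulness_label=label,
        seed=int(seed),
        meta={"tumor_fraction": float(frac), "blur_sigma": float(blur)},
    )


def generate_dataset(spec: PhantomSpec, n: int, seed: int) -> list:
    """Generate ``n`` independent phantom slices with reproducible sub-seeds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(seed)
    sub = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]
    return [generate_slice(spec, s) for s in sub]


_AUG_OPS = ("rotate90", "rotate180", "rotate270", "flip_h", "flip_v", "zoom")


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    ops,
    zoom_factor: float = 0.8,
) -> tuple:
    """Apply the same geometric transform to image and mask.

    ``ops`` is an ordered collection drawn from
    ``rotate90 | rotate180 | rotate270 | flip_h | flip_v | zoom``; rotations are
    counter-clockwise (see ``ROTATION_CONVENTION``).  ``zoom`` shrinks by
    ``zoom_factor`` (nearest-neighbour on the mask, so it stays binary) and pads
    back to the original shape.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask must share a shape")
    img, msk = np.asarray(image), np.asarray(mask)
    for op in ops:
        if op == "rotate90":
            img, msk = np.rot90(img, 1), np.rot90(msk, 1)
        elif op == "rotate180":
            img, msk = np.rot90(img, 2), np.rot90(msk, 2)
        elif op == "rotate270":
            img, msk = np.rot90(img, 3), np.rot90(msk, 3)
        elif op == "flip_h":
            img, msk = img[:, ::-1], msk[:, ::-1]
        elif op == "flip_v":
            img, msk = img[::-1, :], msk[::-1, :]
        elif op == "zoom":
            img = _zoom_keep_shape(img, zoom_factor, order=1)
            msk = _zoom_keep_shape(msk, zoom_factor, order=0)
        else:
            raise ValueError(f"unknown augmentation op: {op!r}")
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


def _zoom_keep_shape(arr: np.ndarray, factor: float, order: int) -> np.ndarray:
    H, W = arr.shape
    small = ndimage.zoom(arr.astype(float), factor, order=order)
    out = np.zeros_like(arr, dtype=float)
    h, w = small.shape
    r0, c0 = (H - h) // 2, (W - w) // 2
    out[max(r0, 0) : max(r0, 0) + min(h, H), max(c0, 0) : max(c0, 0) + min(w, W)] = small[
        : min(h, H), : min(w, W)
    ]
    return out.astype(arr.dtype)


def write_sample(out_dir, stem: str, sample: PhantomSample, spec: PhantomSpec | None = None,
                 nifti: bool = False) -> dict:
    """Write a sample as PNG image + PNG mask + JSON sidecar (optionally NIfTI)."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img_path = out_dir / f"{stem}.png"
    msk_path = out_dir / f"{stem}_mask.png"
    iio.imwrite(img_path, sample.image)
    iio.imwrite(msk_path, (sample.mask * 255).astype(np.uint8))
    sidecar = {
        "true_area_mm2": sample.true_area,
        "usefulness_label": sample.usefulness_label,
        "seed": sample.seed,
        "pixel_spacing_mm": spec.pixel_spacing if spec else None,
        "meta": sample.meta,
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    if nifti:
        import nibabel as nib

        sp = spec.pixel_spacing if spec else 1.0
        affine = np.diag([sp, sp, 1.0, 1.0])
        nib.save(
            nib.Nifti1Image(sample.image[..., None].astype(np.float32), affine),
            out_dir / f"{stem}.nii",
        )
    return sidecar
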