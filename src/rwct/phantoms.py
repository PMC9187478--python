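"""Deterministic synthetic test images with ground truth.

Two generators:

* ``make_ct_phantom`` — a CT-like thorax slice: two dark elliptical lung
  fields in brighter soft tissue, with bright disk nodules and optionally an
  eccentric hollow (an annular cavity wall enclosing a small inner nodule)
  in the upper part of the first lung.  The ground-truth mask marks lesion
  pixels (nodule disks, cavity wall, inner nodule); the hollow's interior is
  background class.  Additive Gaussian noise and a smooth multiplicative-
  style bias field are applied after rasterization.

* ``make_ihc_phantom`` — an immunohistochemistry-like field of view:
  non-overlapping round cells on a pale background, each cell independently
  positive (stained) with probability ``positive_fraction``; a two-channel
  image (stain + counterstain) plus a per-cell table recording the truth.

Both are bit-reproducible given the spec (which carries its own RNG seed);
no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .rw_core import GridImage, SeedMap


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place an object."""


# --- CT-like phantom -------------------------------------------------------

@dataclass(frozen=True)
class CtPhantomSpec:
    shape: tuple[int, int] = (80, 80)
    lung_centers: tuple[tuple[float, float], ...] = ((40.0, 24.0), (40.0, 56.0))
    lung_axes: tuple[tuple[float, float], ...] = ((26.0, 13.0), (26.0, 13.0))
    n_nodules: int = 3
    nodule_radius: tuple[float, float] = (4.0, 7.0)
    cavity: bool = True              # eccentric hollow with an inner nodule
    cavity_outer_radius: float = 9.0
    cavity_wall: float = 3.0
    inner_nodule_radius: float = 2.5
    tissue_level: float = 0.55
    lung_level: float = 0.15
    lesion_level: float = 0.85
    noise_sigma: float = 0.0         # fraction of the [0, 1] dynamic range
    bias_amplitude: float = 0.0      # peak of the smooth additive bias field
    seed: int = 0

    def __post_init__(self):
        if self.nodule_radius[0] < 1 or self.inner_nodule_radius < 1:
            raise ValueError("lesion radii must be >= 1 px")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class PhantomSample:
    image: np.ndarray        # (H, W) or (H, W, C) float
    truth: np.ndarray        # (H, W) integer ground-truth labels
    objects: pd.DataFrame    # one row per generated object
    spec: object

    def grid_image(self, channel: int | None = None) -> GridImage:
        img = self.image if self.image.ndim == 2 else self.image[..., channel or 0]
        return GridImage(img)


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def make_ct_phantom(spec: CtPhantomSpec | None = None) -> PhantomSample:
    """Rasterize a CT-like slice with lesions and return image + truth + table.

    Nodules are rejection-sampled to lie fully inside a lung field without
    touching each other or the cavity; placement failure after bounded
    retries raises :class:`PlacementError`.
    """
    spec = spec or CtPhantomSpec()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    lungs = np.zeros(spec.shape, dtype=bool)
    for c, a in zip(spec.lung_centers, spec.lung_axes):
        lungs |= _ellipse_mask(spec.shape, c, a)
    # distance to the lung boundary: a disk of radius r fits where depth > r
    depth = distance_transform_edt(lungs)

    truth = np.zeros(spec.shape, dtype=np.int64)
    rows = []

    if spec.cavity:
        r_out = spec.cavity_outer_radius
        c0, a0 = spec.lung_centers[0], spec.lung_axes[0]
        for _ in range(500):
            cr = rng.uniform(c0[0] - a0[0] * 0.6, c0[0] - a0[0] * 0.1)  # upper part
            cc_ = rng.uniform(c0[1] - a0[1] * 0.4, c0[1] + a0[1] * 0.4)
            ir, ic = int(round(cr)), int(round(cc_))
            if 0 <= ir < h and 0 <= ic < w and depth[ir, ic] > r_out + 2:
                break
        else:
            raise PlacementError("could not place the cavity inside the lung field")
        outer = _disk_mask(spec.shape, (cr, cc_), r_out)
        inner_cavity = _disk_mask(spec.shape, (cr, cc_), r_out - spec.cavity_wall)
        wall = outer & ~inner_cavity
        # eccentric inner nodule, offset toward a random direction
        ang = rng.uniform(0, 2 * np.pi)
        off = spec.inner_nodule_radius
        ncr, ncc = cr + off * np.sin(ang), cc_ + off * np.cos(ang)
        inner_nod = _disk_mask(spec.shape, (ncr, ncc), spec.inner_nodule_radius)
        truth[wall] = 1
        truth[inner_nod] = 1
        wall_seed = (int(round(cr + (r_out - spec.cavity_wall / 2.0))), int(round(cc_)))
        interior_seed = (int(round(cr - off * np.sin(ang))), int(round(cc_ - off * np.cos(ang))))
        rows.append(dict(kind="cavity_wall", row=cr, col=cc_, radius=r_out,
                         seed_row=wall_seed[0], seed_col=wall_seed[1], lesion=True))
        rows.append(dict(kind="inner_nodule", row=ncr, col=ncc, radius=spec.inner_nodule_radius,
                         seed_row=int(round(ncr)), seed_col=int(round(ncc)), lesion=True))
        rows.append(dict(kind="cavity_interior", row=interior_seed[0], col=interior_seed[1],
                         radius=r_out - spec.cavity_wall, seed_row=interior_seed[0],
                         seed_col=interior_seed[1], lesion=False))

    def clearance() -> np.ndarray:
        if not truth.any():
            return np.full(spec.shape, np.inf)
        return distance_transform_edt(truth == 0)

    lesion_clearance = clearance()
    for _ in range(spec.n_nodules):
        placed = False
        for _ in range(20):  # radius re-draws; centers come from the feasible set
            r = rng.uniform(*spec.nodule_radius)
            feasible = (depth > r + 2) & (lesion_clearance > r + 4)
            choices = np.argwhere(feasible)
            if len(choices) == 0:
                continue
            ir, ic = choices[rng.integers(len(choices))]
            disk = _disk_mask(spec.shape, (float(ir), float(ic)), r)
            truth[disk] = 1
            lesion_clearance = clearance()
            rows.append(dict(kind="nodule", row=float(ir), col=float(ic), radius=r,
                             seed_row=int(ir), seed_col=int(ic), lesion=True))
            placed = True
            break
        if not placed:
            raise PlacementError("no feasible nodule position remains in the lung fields")

    img = np.full(spec.shape, spec.tissue_level)
    img[lungs] = spec.lung_level
    img[truth == 1] = spec.lesion_level
    if spec.bias_amplitude:
        rr, cc = np.mgrid[:h, :w]
        img = img + spec.bias_amplitude * np.sin(np.pi * rr / h) * np.sin(np.pi * cc / w)
    if spec.noise_sigma:
        img = img + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    return PhantomSample(image=img, truth=truth, objects=pd.DataFrame(rows), spec=spec)


def default_ct_seeds(sample: PhantomSample, background_spacing: int = 12,
                     margin: float = 4.0) -> SeedMap:
    """Seed map a user would place on the phantom: label 2 (foreground) at
    each lesion's representative point, label 1 (background) on a sparse grid
    away from lesions plus inside the cavity's hollow interior."""
    points = []
    for _, obj in sample.objects.iterrows():
        label = 2 if obj["lesion"] else 1
        points.append((int(obj["seed_row"]), int(obj["seed_col"]), label))
    clearance = distance_transform_edt(sample.truth == 0)
    h, w = sample.truth.shape
    for r in range(background_spacing // 2, h, background_spacing):
        for c in range(background_spacing // 2, w, background_spacing):
            if clearance[r, c] > margin:
                points.append((r, c, 1))
    return SeedMap.from_points(points)


def packaged_ct_fixture(noise_sigma: float = 0.0, seed: int = 7) -> tuple[PhantomSample, SeedMap]:
    """The standard phantom + seed pair used throughout the test suite."""
    sample = make_ct_phantom(replace(CtPhantomSpec(), noise_sigma=noise_sigma, seed=seed))
    return sample, default_ct_seeds(sample)


# --- IHC-like phantom ------------------------------------------------------

@dataclass(frozen=True)
class IhcPhantomSpec:
    shape: tuple[int, int] = (320, 320)
    cell_count: int = 400
    cell_radius: tuple[float, float] = (3.0, 5.0)
    positive_fraction: float = 0.19
    stain_level: float = 0.75        # DAB-like channel, positive cells
    counterstain_level: float = 0.60  # hematoxylin-like channel, all cells
    negative_stain_level: float = 0.10
    background_level: float = 0.05
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.cell_count < 1:
            raise ValueError("cell_count must be >= 1")


def make_ihc_phantom(spec: IhcPhantomSpec | None = None) -> PhantomSample:
    """Rasterize a stained-cell field of view.

    Cells are rejection-sampled without overlap; each is independently
    positive with probability ``positive_fraction``.  Positive cells get a
    staining-intensity category 1-3 (weak/moderate/strong), negatives 0.
    Channel 0 is the positive stain, channel 1 the counterstain.
    ``truth`` labels pixels 0 background, 1 negative cell, 2 positive cell.
    """
    spec = spec or IhcPhantomSpec()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    max_attempts = 200 * spec.cell_count
    attempts = 0
    while len(centers) < spec.cell_count:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed only {len(centers)}/{spec.cell_count} non-overlapping cells"
            )
        attempts += 1
        r = rng.uniform(*spec.cell_radius)
        cr = rng.uniform(r + 1, h - r - 1)
        cc = rng.uniform(r + 1, w - r - 1)
        if centers:
            d = np.hypot(np.array([c[0] for c in centers]) - cr,
                         np.array([c[1] for c in centers]) - cc)
            if (d <= np.array(radii) + r + 1).any():
                continue
        centers.append((cr, cc))
        radii.append(r)

    positive = rng.random(spec.cell_count) < spec.positive_fraction
    intensity_cat = np.where(positive, rng.integers(1, 4, spec.cell_count), 0)

    stain = np.full(spec.shape, spec.background_level)
    counter = np.full(spec.shape, spec.background_level)
    truth = np.zeros(spec.shape, dtype=np.int64)
    rows = []
    for k, ((cr, cc), r) in enumerate(zip(centers, radii)):
        disk = _disk_mask(spec.shape, (cr, cc), r)
        counter[disk] = spec.counterstain_level
        if positive[k]:
            # stronger categories stain darker/denser
            stain[disk] = spec.negative_stain_level + (
                (spec.stain_level - spec.negative_stain_level) * intensity_cat[k] / 3.0
            )
            truth[disk] = 2
        else:
            stain[disk] = spec.negative_stain_level
            truth[disk] = 1
        rows.append(dict(row=cr, col=cc, radius=r, positive=bool(positive[k]),
                         intensity_cat=int(intensity_cat[k])))
    if spec.noise_sigma:
        stain = stain + rng.normal(0.0, spec.noise_sigma, spec.shape)
        counter = counter + rng.normal(0.0, spec.noise_sigma, spec.shape)
    image = np.stack([stain, counter], axis=-1)
    return PhantomSample(image=image, truth=truth, objects=pd.DataFrame(rows), spec=spec)
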