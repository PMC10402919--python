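"""Synthetic multi-channel spheroid images with pixel-exact ground truth.

Renders the morphology of a collagen-embedded multicellular spheroid as seen
in a projected confocal field: a bright cohesive core carrying all labeled
cell types, filamentous sprouts radiating from the core rim (fibroblast-like
synoviocyte and endothelial channels), and scattered detached single cells
(macrophage channel) in an annulus around the core.  Every rendered image
comes with noiseless per-channel truth images, exact region masks and the
planted cell coordinates, so the whole quantification pipeline can be
validated without real microscopy data.

Ground truth is frozen on the noiseless, quantized composite before any
noise is applied; noise never changes the truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .stacks import ChannelStack

CELL_TYPES = ("FLS", "EC", "MACROPHAGE")

#: cell types whose fluorescence is carried by sprouts (coordinated migration)
SPROUT_CELL_TYPES = ("FLS", "EC")
#: cell type of the detached single cells scattered around the core
DETACHED_CELL_TYPE = "MACROPHAGE"


class PlacementError(RuntimeError):
    """Detached-cell rejection sampling exhausted its attempt budget."""


def _default_assignment() -> dict:
    return {ct: i for i, ct in enumerate(CELL_TYPES)}


def _default_intensity() -> dict:
    return {ct: 200.0 for ct in CELL_TYPES}


@dataclass(frozen=True)
class SpheroidScene:
    """Parameters of one synthetic spheroid field.

    Lengths are in pixels, intensities in arbitrary fluorescence units.
    ``core_center=None`` places the core at the image center.  The defaults
    describe a realistic 10X field: a large cohesive core, sprouts a few
    cell-widths thick reaching roughly one core-diameter outward, and a
    modest number of detached cells in an annulus beyond the sprout tips.
    """

    image_shape: tuple = (256, 256)
    core_center: tuple | None = None
    core_radius: float = 40.0
    n_sprouts: int = 18
    sprout_length_mean: float = 55.0
    sprout_length_sd: float = 10.0
    sprout_width: float = 5.0
    n_detached_cells: int = 12
    detached_cell_radius: float = 3.0
    detached_ring: tuple = (105.0, 122.0)
    channel_assignment: dict = field(default_factory=_default_assignment)
    channel_intensity: dict = field(default_factory=_default_intensity)
    noise_sigma: float = 8.0
    photon_scale: float = 0.0
    n_planes: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.core_center is None:
            h, w = self.image_shape
            object.__setattr__(self, "core_center", ((h - 1) / 2.0, (w - 1) / 2.0))
        if self.core_radius <= 0:
            raise ValueError("core_radius must be > 0")
        inner, outer = self.detached_ring
        if inner < self.core_radius:
            raise ValueError("detached_ring inner radius must be >= core_radius")
        if outer <= inner:
            raise ValueError("detached_ring outer radius must exceed inner radius")
        if self.n_sprouts < 0 or self.n_detached_cells < 0:
            raise ValueError("structure counts must be non-negative")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")
        if set(self.channel_assignment) != set(CELL_TYPES):
            raise ValueError(f"channel_assignment must map exactly {CELL_TYPES}")
        if sorted(self.channel_assignment.values()) != [0, 1, 2]:
            raise ValueError("channel_assignment must use channel indices {0,1,2}")


@dataclass
class SyntheticTruth:
    """Pixel-exact ground truth for one rendered scene."""

    core_mask: np.ndarray
    outgrowth_mask: np.ndarray
    background_mask: np.ndarray
    true_core_area: int
    true_outgrowth_area: int
    detached_cell_centers: list
    per_channel_truth: np.ndarray  # (channel, row, col), noiseless, uint16

    def validate(self) -> None:
        total = (
            self.core_mask.astype(int)
            + self.outgrowth_mask.astype(int)
            + self.background_mask.astype(int)
        )
        if not np.all(total == 1):
            raise AssertionError("truth masks do not partition the image")
        if self.true_core_area != int(self.core_mask.sum()):
            raise AssertionError("true_core_area inconsistent with core_mask")
        if self.true_outgrowth_area != int(self.outgrowth_mask.sum()):
            raise AssertionError("true_outgrowth_area inconsistent with outgrowth_mask")


def _dist_to_segment(rr, cc, p0, p1):
    """Euclidean distance of pixel centers (rr, cc) to segment p0-p1."""
    d = p1 - p0
    lsq = float(d @ d)
    if lsq == 0.0:
        return np.hypot(rr - p0[0], cc - p0[1])
    t = ((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / lsq
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(rr - (p0[0] + t * d[0]), cc - (p0[1] + t * d[1]))


def _paint_capsule(canvas, p0, p1, half_width, value):
    """Max-compose an anti-aliased capsule (thick segment) onto a 2D canvas."""
    h, w = canvas.shape
    pad = half_width + 1.5
    r0 = max(int(np.floor(min(p0[0], p1[0]) - pad)), 0)
    r1 = min(int(np.ceil(max(p0[0], p1[0]) + pad)) + 1, h)
    c0 = max(int(np.floor(min(p0[1], p1[1]) - pad)), 0)
    c1 = min(int(np.ceil(max(p0[1], p1[1]) + pad)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dist = _dist_to_segment(rr.astype(float), cc.astype(float), p0, p1)
    # 1-px soft edge: full value inside half_width, linear falloff outside
    prof = np.clip(half_width + 0.5 - dist, 0.0, 1.0) * value
    np.maximum(canvas[r0:r1, c0:c1], prof, out=canvas[r0:r1, c0:c1])


def _paint_disk(canvas, center, radius, value):
    _paint_capsule(canvas, np.asarray(center, float), np.asarray(center, float), radius, value)


def _place_detached_cells(scene: SpheroidScene, rng) -> list:
    """Rejection-sample non-overlapping cell centers inside the detached ring."""
    inner, outer = scene.detached_ring
    h, w = scene.image_shape
    r_cell = scene.detached_cell_radius
    min_sep = 2.0 * r_cell
    centers: list = []
    max_attempts = max(500, 500 * scene.n_detached_cells)
    attempts = 0
    while len(centers) < scene.n_detached_cells:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {scene.n_detached_cells} detached cells of radius "
                f"{r_cell} in ring {scene.detached_ring} after {max_attempts} attempts"
            )
        attempts += 1
        # area-uniform radius in the annulus
        rad = np.sqrt(rng.uniform(inner**2, outer**2))
        ang = rng.uniform(0.0, 2 * np.pi)
        r = scene.core_center[0] + rad * np.sin(ang)
        c = scene.core_center[1] + rad * np.cos(ang)
        if not (r_cell <= r < h - r_cell and r_cell <= c < w - r_cell):
            continue
        if any(np.hypot(r - pr, c - pc) < min_sep for pr, pc in centers):
            continue
        centers.append((float(r), float(c)))
    return centers


def _sprout_geometry(scene: SpheroidScene, rng) -> list:
    """Stratified sprout angles and lengths: (p0, p1) endpoint pairs.

    Angles are laid on an even grid with bounded jitter so sprouts diverge
    and do not overlap each other at the default densities; this keeps the
    expected outgrowth area linear in n_sprouts.
    """
    segs = []
    n = scene.n_sprouts
    if n == 0:
        return segs
    offset = rng.uniform(0.0, 2 * np.pi)
    slot = 2 * np.pi / n
    cr, cch = scene.core_center
    r0 = max(scene.core_radius - 1.0, 0.0)
    for k in range(n):
        ang = offset + k * slot + rng.uniform(-0.3, 0.3) * slot
        length = max(4.0, rng.normal(scene.sprout_length_mean, scene.sprout_length_sd))
        d = np.array([np.sin(ang), np.cos(ang)])
        p0 = np.array([cr, cch]) + r0 * d
        p1 = p0 + length * d
        segs.append((p0, p1))
    return segs


def render_scene(scene: SpheroidScene) -> tuple:
    """Render a scene into a 3-channel image stack and its exact truth.

    Structures are composed per channel by pixel-wise maximum (fluorescence
    does not add where structures overlap in projection).  Returns
    ``(ChannelStack, SyntheticTruth)``; the stack has ``scene.n_planes``
    planes, with structures distributed over planes when ``n_planes > 1`` so
    that a per-channel max projection reproduces the single-plane render of
    the same scene exactly.
    """
    ss = np.random.SeedSequence(scene.seed)
    rng_geom, rng_plane, rng_noise = (np.random.default_rng(c) for c in ss.spawn(3))
    h, w = scene.image_shape
    n_ch = 3
    by_type = {ct: np.zeros((h, w), dtype=np.float64) for ct in CELL_TYPES}

    # core: filled disk carrying every cell-type channel at nominal intensity
    rr, cc = np.mgrid[0:h, 0:w]
    dist = np.hypot(rr - scene.core_center[0], cc - scene.core_center[1])
    core_mask = dist <= scene.core_radius
    structures = []  # (cell_type, painted 2D layer) for plane distribution
    for ct in CELL_TYPES:
        layer = core_mask * scene.channel_intensity[ct]
        structures.append((ct, layer))

    # sprouts: radiating capsules carrying the FLS and EC channels with
    # independent per-sprout, per-channel intensity jitter
    half_w = scene.sprout_width / 2.0
    for p0, p1 in _sprout_geometry(scene, rng_geom):
        for ct in SPROUT_CELL_TYPES:
            layer = np.zeros((h, w), dtype=np.float64)
            level = scene.channel_intensity[ct] * rng_geom.uniform(0.7, 1.0)
            _paint_capsule(layer, p0, p1, half_w, level)
            structures.append((ct, layer))

    # detached cells: small disks, macrophage channel only
    centers = _place_detached_cells(scene, rng_geom)
    for ctr in centers:
        layer = np.zeros((h, w), dtype=np.float64)
        level = scene.channel_intensity[DETACHED_CELL_TYPE] * rng_geom.uniform(0.8, 1.0)
        _paint_disk(layer, ctr, scene.detached_cell_radius, level)
        structures.append((DETACHED_CELL_TYPE, layer))

    for ct, layer in structures:
        np.maximum(by_type[ct], layer, out=by_type[ct])

    noiseless = np.zeros((n_ch, h, w), dtype=np.float64)
    for ct in CELL_TYPES:
        noiseless[scene.channel_assignment[ct]] = by_type[ct]
    quantized = np.rint(np.clip(noiseless, 0, 65535)).astype(np.uint16)

    # truth is frozen here, before any noise
    composite = quantized.astype(np.int64).sum(axis=0)
    outgrowth_mask = (composite > 0) & ~core_mask
    background_mask = ~core_mask & ~outgrowth_mask
    truth = SyntheticTruth(
        core_mask=core_mask,
        outgrowth_mask=outgrowth_mask,
        background_mask=background_mask,
        true_core_area=int(core_mask.sum()),
        true_outgrowth_area=int(outgrowth_mask.sum()),
        detached_cell_centers=centers,
        per_channel_truth=quantized,
    )

    # distribute structures over planes (core to the middle plane)
    planes = np.zeros((scene.n_planes, n_ch, h, w), dtype=np.float64)
    if scene.n_planes == 1:
        planes[0] = noiseless
    else:
        mid = scene.n_planes // 2
        for i, (ct, layer) in enumerate(structures):
            p = mid if i < n_ch else int(rng_plane.integers(0, scene.n_planes))
            ch = scene.channel_assignment[ct]
            np.maximum(planes[p, ch], layer, out=planes[p, ch])
    planes = np.rint(np.clip(planes, 0, 65535))

    if scene.photon_scale > 0:
        planes = rng_noise.poisson(planes * scene.photon_scale) / scene.photon_scale
    if scene.noise_sigma > 0:
        planes = planes + rng_noise.normal(0.0, scene.noise_sigma, size=planes.shape)
    pixels = np.rint(np.clip(planes, 0, 65535)).astype(np.uint16)

    channel_names = [None] * n_ch
    for ct, idx in scene.channel_assignment.items():
        channel_names[idx] = ct
    stack = ChannelStack(
        pixels=pixels,
        channel_names=list(channel_names),
        pixel_size=None,
        source_path=f"synthetic(seed={scene.seed})",
    )
    return stack, truth


def derived_seeds(seed: int, n: int) -> list:
    """n distinct per-replicate seeds derived from one parent seed (< 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(2 * n, dtype=np.uint32)
    out: list = []
    for s in state:
        v = int(s) % (2**31)
        if v not in out:
            out.append(v)
        if len(out) == n:
            return out
    # astronomically unlikely; fall back to consecutive values
    while len(out) < n:
        v = (out[-1] + 1) % (2**31)
        if v not in out:
            out.append(v)
    return out


def scale_scene(base: SpheroidScene, fold_outgrowth: float, seed: int) -> SpheroidScene:
    """A scene whose expected true outgrowth area is fold x that of base.

    Sprout count is scaled by the fold and the mean sprout length absorbs the
    integer rounding of the count, so the expected sprout-covered area scales
    exactly; the detached-cell count is scaled by the fold and rounded.
    """
    if fold_outgrowth <= 0:
        raise ValueError("fold_outgrowth must be > 0")
    n_spr = base.n_sprouts
    if n_spr > 0:
        n_new = max(1, int(round(fold_outgrowth * n_spr)))
        len_new = base.sprout_length_mean * (fold_outgrowth * n_spr / n_new)
    else:
        n_new, len_new = 0, base.sprout_length_mean
    n_det = int(round(fold_outgrowth * base.n_detached_cells))
    return dataclasses.replace(
        base,
        n_sprouts=n_new,
        sprout_length_mean=len_new,
        n_detached_cells=n_det,
        seed=seed,
    )


def make_condition_set(
    base: SpheroidScene, fold_outgrowth: float, n_replicates: int, seed: int
) -> list:
    """Render biological replicates of one condition.

    Each replicate uses an independent derived seed; the expected true
    outgrowth area of every replicate is ``fold_outgrowth`` times that of the
    base scene.
    """
    if fold_outgrowth <= 0:
        raise ValueError("fold_outgrowth must be > 0")
    if not (2 <= n_replicates <= 16):
        raise ValueError("n_replicates must be in [2, 16]")
    seeds = derived_seeds(seed, n_replicates)
    return [render_scene(scale_scene(base, fold_outgrowth, s)) for s in seeds]


def save_truth(truth: SyntheticTruth, prefix) -> None:
    """Write truth as a label TIFF + per-channel TIFF + scalar JSON sidecar.

    ``prefix`` is a path stem; writes ``<prefix>.labels.tif`` (0=background,
    1=core, 2=outgrowth), ``<prefix>.channels.tif`` and ``<prefix>.json``.
    """
    prefix = Path(prefix)
    labels = np.zeros(truth.core_mask.shape, dtype=np.uint8)
    labels[truth.core_mask] = 1
    labels[truth.outgrowth_mask] = 2
    tifffile.imwrite(str(prefix) + ".labels.tif", labels)
    tifffile.imwrite(
        str(prefix) + ".channels.tif",
        truth.per_channel_truth,
        photometric="minisblack",
        metadata={"axes": "CYX"},
    )
    scalars = {
        "true_core_area": truth.true_core_area,
        "true_outgrowth_area": truth.true_outgrowth_area,
        "detached_cell_centers": [list(c) for c in truth.detached_cell_centers],
    }
    Path(str(prefix) + ".json").write_text(json.dumps(scalars, indent=2))
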