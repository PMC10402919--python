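"""Post-processing of raw pixel labels into coherent core and outgrowth regions.

The outgrowth is defined as everything cell-covered outside the core —
sprouts still attached to it as well as detached single cells.  A field
images one spheroid, so after refinement the core is a single 4-connected
component (or empty, with a QC flag); stray core-labeled islands are
relabeled outgrowth and sub-speckle objects are dropped from the outgrowth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage as ndi
from skimage.morphology import dilation, disk, erosion, opening

LABEL_BACKGROUND = 0
LABEL_CORE = 1
LABEL_OUTGROWTH = 2
CLASS_NAMES = ("background", "core", "outgrowth")

FLAG_EMPTY_CORE = "empty core"
FLAG_MULTI_CORE = "multiple core candidates"
FLAG_CORE_BORDER = "core touching border"

# 4-connectivity: conservative separation of barely-touching sprout tips
_STRUCT4 = ndi.generate_binary_structure(2, 1)


@dataclass
class RegionLabelMap:
    """Per-pixel classification into {0: background, 1: core, 2: outgrowth}."""

    labels: np.ndarray
    provenance: str = ""
    qc_flags: list = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if not np.isin(self.labels, (LABEL_BACKGROUND, LABEL_CORE, LABEL_OUTGROWTH)).all():
            raise ValueError("labels must be in {0, 1, 2}")

    @property
    def core_mask(self) -> np.ndarray:
        return self.labels == LABEL_CORE

    @property
    def outgrowth_mask(self) -> np.ndarray:
        return self.labels == LABEL_OUTGROWTH

    @property
    def background_mask(self) -> np.ndarray:
        return self.labels == LABEL_BACKGROUND

    def area(self, code: int) -> int:
        return int((self.labels == code).sum())


@dataclass(frozen=True)
class RefineConfig:
    """Morphological post-processing parameters (all lengths in pixels).

    ``min_object_area`` is kept small (9 px^2) so single detached cells of
    radius >= 2 px survive speckle removal; ``r_core`` is the erosion radius
    that strips sprouts off a cell mask when the core must be derived
    morphologically rather than classified.
    """

    r_open: int = 3
    min_object_area: int = 9
    r_core: int = 5


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    if min_area <= 1 or not mask.any():
        return mask
    lab, n = ndi.label(mask, structure=_STRUCT4)
    if n == 0:
        return mask
    areas = np.bincount(lab.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[lab]


def _select_core(candidates: np.ndarray, image_shape) -> tuple:
    """Largest 4-connected candidate; ties broken by centroid proximity to
    the image center.  Returns (core mask, n_candidates)."""
    lab, n = ndi.label(candidates, structure=_STRUCT4)
    if n == 0:
        return np.zeros(image_shape, dtype=bool), 0
    areas = np.bincount(lab.ravel())[1:]
    best = areas.max()
    tied = [i + 1 for i, a in enumerate(areas) if a == best]
    if len(tied) == 1:
        chosen = tied[0]
    else:
        center = ((image_shape[0] - 1) / 2.0, (image_shape[1] - 1) / 2.0)
        cents = ndi.center_of_mass(candidates, lab, tied)
        dists = [np.hypot(r - center[0], c - center[1]) for r, c in cents]
        chosen = tied[int(np.argmin(dists))]
    return lab == chosen, n


def _assemble(core: np.ndarray, cellish: np.ndarray, cfg: RefineConfig, provenance: str,
              extra_flags: list | None = None) -> RegionLabelMap:
    outgrowth = _remove_small(cellish & ~core, cfg.min_object_area)
    labels = np.zeros(core.shape, dtype=np.uint8)
    labels[outgrowth] = LABEL_OUTGROWTH
    labels[core] = LABEL_CORE
    flags = list(extra_flags or [])
    if not core.any():
        flags.append(FLAG_EMPTY_CORE)
    elif (
        core[0, :].any() or core[-1, :].any() or core[:, 0].any() or core[:, -1].any()
    ):
        flags.append(FLAG_CORE_BORDER)
    return RegionLabelMap(labels=labels, provenance=provenance, qc_flags=flags)


def refine_regions(raw: RegionLabelMap, config: RefineConfig | None = None) -> RegionLabelMap:
    """Enforce a single coherent core on a raw three-class label map.

    Core candidates are the 4-connected components of the core class after
    morphological opening (radius ``r_open``) and hole filling; the largest
    one is kept (centroid-to-image-center tie-break), every other core-labeled
    pixel is relabeled outgrowth, and outgrowth objects smaller than
    ``min_object_area`` are removed.  Never fatal: an empty core is flagged
    and downstream ratios are reported as missing.
    """
    cfg = config or RefineConfig()
    raw_core = raw.labels == LABEL_CORE
    opened = opening(raw_core, disk(cfg.r_open))
    filled = ndi.binary_fill_holes(opened)
    core, n_cand = _select_core(filled, raw.labels.shape)
    flags = [FLAG_MULTI_CORE] if n_cand > 1 else []
    cellish = (raw.labels != LABEL_BACKGROUND) | core
    out = _assemble(core, cellish, cfg, raw.provenance or "refined", flags)
    return out


def derive_regions_from_cellmask(
    cell_mask: np.ndarray, config: RefineConfig | None = None
) -> RegionLabelMap:
    """Split a binary cell mask into core and outgrowth morphologically.

    The core is recovered as the largest component of the mask after an
    erosion by ``r_core`` (which annihilates thin sprouts), dilated back,
    hole-filled and intersected with the mask; the outgrowth is the rest of
    the mask after speckle removal.
    """
    cfg = config or RefineConfig()
    cell_mask = np.asarray(cell_mask, dtype=bool)
    se = disk(cfg.r_core)
    eroded = erosion(cell_mask, se)
    seed, n_cand = _select_core(eroded, cell_mask.shape)
    core = ndi.binary_fill_holes(dilation(seed, se)) & cell_mask
    flags = [FLAG_MULTI_CORE] if n_cand > 1 else []
    return _assemble(core, cell_mask, cfg, "cellmask", flags)


def read_label_map(path) -> RegionLabelMap:
    """Read a label map written as single-channel 8-bit TIFF ({0,1,2})."""
    labels = tifffile.imread(str(path))
    return RegionLabelMap(labels=labels, provenance=str(path))


def write_label_map(labels: RegionLabelMap, path) -> None:
    tifffile.imwrite(str(path), labels.labels.astype(np.uint8))
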