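"""From raw fluorescence channels to per-cell binary masks.

The chain mirrors a standard single-cell segmentation recipe for isolated
adherent cells: per-channel contrast stretching, pixelwise combination of
the actin and membrane channels (whose union delineates the full cell
footprint), a single 3x3 grayscale erosion to sharpen edges, thresholding
(Otsu by default, fixed value as an override), connected-component
labelling with hole filling, rejection of border-touching and undersized
components, and pairing of each cell with the nucleus whose centroid it
contains.  Only cells with exactly one nucleus survive; everything else is
discarded and logged so the attrition is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=bool)


class ThresholdError(ValueError):
    pass


@dataclass
class ChannelStack:
    """One field of view: nucleus / actin / membrane planes + provenance."""

    nucleus_plane: np.ndarray
    actin_plane: np.ndarray
    membrane_plane: np.ndarray
    pixel_size: float | None = None
    line: str = ""
    surface: str = ""
    image_id: str = ""

    def __post_init__(self) -> None:
        shapes = {
            self.nucleus_plane.shape,
            self.actin_plane.shape,
            self.membrane_plane.shape,
        }
        if len(shapes) != 1:
            raise ValueError("channel planes must share identical dimensions")


@dataclass
class CellInstance:
    """One isolated cell: full-frame masks plus provenance."""

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    bounding_box: tuple[int, int, int, int]  # (row, col, height, width), 0-based
    line: str = ""
    surface: str = ""
    image_id: str = ""
    cell_id: str = ""
    metastatic_class: str = ""
    pixel_size: float | None = None
    threshold: float | None = None


def read_channel_stack(path, channel_order=("nucleus", "actin", "membrane"),
                       **provenance) -> ChannelStack:
    """Load a multi-page TIFF (one page per channel) into a ChannelStack."""
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        raise ValueError("expected a multi-channel TIFF, got a single plane")
    planes = {name: pages[i] for i, name in enumerate(channel_order)}
    return ChannelStack(
        nucleus_plane=planes["nucleus"],
        actin_plane=planes["actin"],
        membrane_plane=planes["membrane"],
        **provenance,
    )


def contrast_stretch(plane: np.ndarray, low_pct: float = 1.0,
                     high_pct: float = 99.9) -> np.ndarray:
    """Linearly map the [low_pct, high_pct] intensity percentiles onto
    [0, 65535], clipping outside; a constant plane maps to all zeros."""
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("require 0 <= low_pct < high_pct <= 100")
    plane = np.asarray(plane, dtype=float)
    lo, hi = np.percentile(plane, [low_pct, high_pct])
    if hi <= lo:
        return np.zeros_like(plane)
    out = (plane - lo) / (hi - lo) * 65535.0
    return np.clip(out, 0.0, 65535.0)


def combine_actin_membrane(actin_plane: np.ndarray,
                           membrane_plane: np.ndarray) -> np.ndarray:
    """Pixelwise maximum of the two (enhanced) planes."""
    actin_plane = np.asarray(actin_plane, dtype=float)
    membrane_plane = np.asarray(membrane_plane, dtype=float)
    if actin_plane.shape != membrane_plane.shape:
        raise ValueError("actin and membrane planes differ in shape")
    return np.maximum(actin_plane, membrane_plane)


def erode(plane: np.ndarray, radius: int = 1) -> np.ndarray:
    """Morphological erosion with a 3x3 square structuring element,
    applied ``radius`` times; grayscale or binary input."""
    if plane.dtype == bool:
        return ndimage.binary_erosion(plane, structure=_EIGHT, iterations=radius)
    return ndimage.grey_erosion(plane, footprint=np.ones((3, 3)), mode="constant",
                                cval=0.0) if radius == 1 else _erode_n(plane, radius)


def _erode_n(plane: np.ndarray, n: int) -> np.ndarray:
    out = np.asarray(plane)
    for _ in range(n):
        out = ndimage.grey_erosion(out, footprint=np.ones((3, 3)), mode="constant",
                                   cval=0.0)
    return out


def binarize(plane: np.ndarray, method: str = "otsu",
             fixed_value: float | None = None) -> tuple[np.ndarray, float]:
    """Threshold a plane; returns (mask, threshold used).

    mask = plane > threshold.  Otsu maximizes between-class variance; a
    constant plane has no Otsu threshold and requires the fixed method.
    """
    plane = np.asarray(plane, dtype=float)
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed method requires fixed_value")
        thr = float(fixed_value)
    elif method == "otsu":
        if np.ptp(plane) == 0:
            raise ThresholdError(
                "all pixels equal: Otsu undefined, use method='fixed'"
            )
        thr = float(threshold_otsu(plane))
    else:
        raise ValueError(f"unknown method {method!r}")
    return plane > thr, thr


@dataclass
class LabelledComponent:
    mask: np.ndarray
    bounding_box: tuple[int, int, int, int]
    label: int
    centroid: tuple[float, float] = (0.0, 0.0)


def segment_and_select(mask: np.ndarray, min_area: int = 200,
                       border_margin: int = 1) -> list[LabelledComponent]:
    """8-connected components of a binary mask, holes filled; components
    touching the border margin or smaller than ``min_area`` are dropped."""
    mask = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return []
    h, w = mask.shape
    # pre-filter tiny components in one pass (a noisy threshold can spawn
    # thousands of specks; per-label full-frame work would dominate)
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    slices = ndimage.find_objects(labels)
    out: list[LabelledComponent] = []
    for lab in range(1, n + 1):
        if areas[lab] < min_area:
            continue
        sl = slices[lab - 1]
        r0, r1 = sl[0].start, sl[0].stop
        c0, c1 = sl[1].start, sl[1].stop
        if (r0 < border_margin or c0 < border_margin
                or r1 > h - border_margin or c1 > w - border_margin):
            continue
        sub = ndimage.binary_fill_holes(labels[sl] == lab)
        if int(sub.sum()) < min_area:
            continue
        comp = np.zeros_like(mask)
        comp[sl] = sub
        cr, cc = ndimage.center_of_mass(sub)
        out.append(LabelledComponent(
            mask=comp,
            bounding_box=(int(r0), int(c0), int(r1 - r0), int(c1 - c0)),
            label=lab,
            centroid=(float(cr + r0), float(cc + c0)),
        ))
    return out


def pair_nuclei(cells: list[LabelledComponent],
                nucleus_mask: np.ndarray,
                stack: ChannelStack | None = None,
                min_nucleus_area: int = 20,
                threshold: float | None = None) -> list[CellInstance]:
    """Assign each nucleus to the cell containing its centroid; keep only
    cells with exactly one nucleus."""
    nuclei = segment_and_select(nucleus_mask, min_area=min_nucleus_area,
                                border_margin=1)
    assigned: dict[int, list[LabelledComponent]] = {i: [] for i in range(len(cells))}
    dropped_nuclei = 0
    for nuc in nuclei:
        r, c = int(round(nuc.centroid[0])), int(round(nuc.centroid[1]))
        owners = [i for i, cell in enumerate(cells) if cell.mask[r, c]]
        if len(owners) == 1:
            assigned[owners[0]].append(nuc)
        else:
            dropped_nuclei += 1
    if dropped_nuclei:
        logger.info("dropped %d nuclei outside any cell", dropped_nuclei)
    instances: list[CellInstance] = []
    discarded = 0
    for i, cell in enumerate(cells):
        if len(assigned[i]) != 1:
            discarded += 1
            continue
        nuc = assigned[i][0]
        nmask = nuc.mask & cell.mask
        prov = {}
        if stack is not None:
            prov = dict(line=stack.line, surface=stack.surface,
                        image_id=stack.image_id, pixel_size=stack.pixel_size)
        instances.append(CellInstance(
            cell_mask=cell.mask,
            nucleus_mask=nmask,
            bounding_box=cell.bounding_box,
            cell_id=f"{prov.get('image_id', '')}_c{cell.label}",
            threshold=threshold,
            **prov,
        ))
    if discarded:
        logger.info("discarded %d cells without exactly one nucleus", discarded)
    return instances


def segment_stack(stack: ChannelStack,
                  low_pct: float = 1.0,
                  high_pct: float = 99.9,
                  method: str = "otsu",
                  fixed_value: float | None = None,
                  min_area: int = 200,
                  border_margin: int = 4) -> list[CellInstance]:
    """Full chain: enhance, combine, erode, threshold, segment, pair."""
    nucleus = contrast_stretch(stack.nucleus_plane, low_pct, high_pct)
    actin = contrast_stretch(stack.actin_plane, low_pct, high_pct)
    membrane = contrast_stretch(stack.membrane_plane, low_pct, high_pct)
    combined = erode(combine_actin_membrane(actin, membrane))
    cell_bin, thr = binarize(combined, method=method, fixed_value=fixed_value)
    nuc_bin, _ = binarize(nucleus, method=method, fixed_value=fixed_value)
    cells = segment_and_select(cell_bin, min_area=min_area,
                               border_margin=border_margin)
    return pair_nuclei(cells, nuc_bin, stack=stack, threshold=thr)
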