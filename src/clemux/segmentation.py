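"""Cell detection in the EM overview from a pixel-class map.

The input is an integer label raster (or per-class probability stack) over the
classes background / well-preserved cell / hole-in-resin / debris, produced by
an external pixel classifier on the blended medium-magnification EM montage.
Cell profiles are recovered by smoothing the cell class, splitting touching
cells with a marker-based watershed on the Euclidean distance transform, and
gating the resulting objects on area and circularity (4*pi*A/P**2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import find_contours, regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

__all__ = [
    "CLASS_BACKGROUND",
    "CLASS_CELL",
    "CLASS_HOLE",
    "CLASS_DEBRIS",
    "CellRecord",
    "SegmentationParams",
    "detect_cells",
    "holes_mask",
    "cells_to_csv",
    "outlines_to_csv",
    "read_cells_csv",
    "read_outlines_csv",
]

# Class-map label values. A probability stack (float, one plane per class in
# this order) is accepted anywhere a label raster is and argmax-converted.
CLASS_BACKGROUND = 0
CLASS_CELL = 1
CLASS_HOLE = 2
CLASS_DEBRIS = 3
_KNOWN_CLASSES = frozenset({CLASS_BACKGROUND, CLASS_CELL, CLASS_HOLE, CLASS_DEBRIS})


@dataclass
class SegmentationParams:
    """Knobs for cell detection.

    Attributes
    ----------
    smoothing_radius_px : int
        Radius of the disk used for binary opening+closing of the raw class map.
    min_area_um2, max_area_um2 : float
        Area gate for accepting a profile (default 3-80 um^2, the range of
        yeast cell cross sections).
    min_circularity : float
        4*pi*A/P^2 threshold; 1 for a perfect circle.
    pixel_size_nm : float
        EM overview pixel size.
    marker_min_distance_um : float
        Minimum separation of watershed markers (distance-transform maxima).
    """

    smoothing_radius_px: int = 2
    min_area_um2: float = 3.0
    max_area_um2: float = 80.0
    min_circularity: float = 0.6
    pixel_size_nm: float = 500.0
    marker_min_distance_um: float = 1.5

    def __post_init__(self) -> None:
        if not self.min_area_um2 < self.max_area_um2:
            raise ValueError("min area must be < max area")
        if not 0 < self.min_circularity <= 1:
            raise ValueError("min circularity must be in (0, 1]")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class CellRecord:
    """One detected cell profile in the EM overview frame.

    ``centroid`` and ``outline`` use (x, y) = (column, row), 0-based pixel
    centers.  ``flags`` is a set drawn from {ok, excluded_size,
    excluded_shape, edge_touching}.
    """

    id: int
    centroid: tuple[float, float]
    outline: np.ndarray  # (N, 2) closed polygon, (x, y)
    area_px: int
    area_um2: float
    circularity: float
    flags: frozenset[str] = field(default_factory=lambda: frozenset({"ok"}))


def _as_labels(class_map: np.ndarray) -> np.ndarray:
    """Accept an integer label raster or a float per-class probability stack."""
    arr = np.asarray(class_map)
    if arr.ndim == 3:
        # (C, H, W) or (H, W, C); channel axis is the smallest
        axis = int(np.argmin(arr.shape))
        return np.argmax(arr, axis=axis).astype(np.int32)
    if arr.ndim != 2:
        raise ValueError(f"class map must be 2D labels or 3D probabilities, got ndim={arr.ndim}")
    if np.issubdtype(arr.dtype, np.floating):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("2D float class map is not integer-valued; pass a per-class stack")
        arr = np.round(arr)
    labels = arr.astype(np.int32)
    unknown = set(np.unique(labels)) - _KNOWN_CLASSES
    if unknown:
        raise ValueError(f"unknown class labels in map: {sorted(unknown)}")
    return labels


def _smooth(mask: np.ndarray, radius_px: int) -> np.ndarray:
    if radius_px <= 0:
        return mask
    selem = disk(radius_px)
    # edge-pad so opening/closing do not shave objects at the image border
    pad = radius_px + 1
    padded = np.pad(mask, pad, mode="edge")
    opened = ndi.binary_opening(padded, structure=selem)
    closed = ndi.binary_closing(opened, structure=selem)
    return closed[pad:-pad, pad:-pad]


def _outline(obj_mask: np.ndarray, origin_rc: tuple[int, int]) -> np.ndarray:
    """Closed (x, y) outline polygon of a binary object (longest 0.5-contour)."""
    padded = np.pad(obj_mask, 1)
    contours = find_contours(padded.astype(float), 0.5)
    contour = max(contours, key=len)  # (row, col) in padded frame
    rc = contour - 1.0 + np.asarray(origin_rc, dtype=float)
    return rc[:, ::-1].copy()  # -> (x, y)


def detect_cells(class_map: np.ndarray, params: SegmentationParams | None = None) -> list[CellRecord]:
    """Detect cell profiles: smooth, watershed-split, gate by size and shape.

    All objects are returned, each carrying flags; only ``ok`` objects pass
    the area gate, the circularity gate and do not touch the image edge.
    Ids are assigned in raster order of the centroids (top-to-bottom, then
    left-to-right), so the output is independent of labelling order.

    An empty cell class yields an empty list; unknown label values raise.
    """
    params = params or SegmentationParams()
    labels = _as_labels(class_map)
    cell_mask = _smooth(labels == CLASS_CELL, params.smoothing_radius_px)
    if not cell_mask.any():
        return []

    px_um = params.pixel_size_nm / 1000.0
    dist = ndi.distance_transform_edt(cell_mask)
    min_dist_px = max(1, int(round(params.marker_min_distance_um / px_um)))
    # seed from regional maxima of the distance transform (connected plateaus
    # count once, so elongated objects are not fragmented), merging maxima
    # closer than the configured separation into a single marker
    # local maxima of the distance transform, plateaus included (a ridge of
    # constant width marks once, so elongated objects are not fragmented)
    maxima = (ndi.maximum_filter(dist, size=3) == dist) & cell_mask
    # grow each maximum by half the separation (via a distance threshold,
    # cheap even for large radii) so nearby maxima merge into one marker
    maxima = ndi.distance_transform_edt(~maxima) <= max(min_dist_px // 2, 1)
    maxima &= cell_mask
    markers, n_markers = ndi.label(maxima)
    if n_markers == 0:  # degenerate: no interior maxima
        markers, _ = ndi.label(cell_mask)
    ws = watershed(-dist, markers, mask=cell_mask)

    h, w = ws.shape
    records: list[CellRecord] = []
    for prop in regionprops(ws):
        area_px = int(prop.area)
        area_um2 = area_px * px_um**2
        perimeter = float(prop.perimeter)
        circ = 4.0 * np.pi * area_px / perimeter**2 if perimeter > 0 else 0.0
        circ = min(circ, 1.0)
        flags: set[str] = set()
        minr, minc, maxr, maxc = prop.bbox
        if minr == 0 or minc == 0 or maxr == h or maxc == w:
            flags.add("edge_touching")
        if not (params.min_area_um2 <= area_um2 <= params.max_area_um2):
            flags.add("excluded_size")
        if circ < params.min_circularity:
            flags.add("excluded_shape")
        if not flags:
            flags.add("ok")
        cy, cx = prop.centroid
        obj = ws[minr:maxr, minc:maxc] == prop.label
        records.append(
            CellRecord(
                id=-1,
                centroid=(float(cx), float(cy)),
                outline=_outline(obj, (minr, minc)),
                area_px=area_px,
                area_um2=float(area_um2),
                circularity=float(circ),
                flags=frozenset(flags),
            )
        )
    records.sort(key=lambda r: (round(r.centroid[1]), round(r.centroid[0])))
    for i, rec in enumerate(records):
        rec.id = i
    return records


def holes_mask(class_map: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Union of the hole and debris classes, smoothed like the cell class.

    Used downstream to subtract defective regions from measurement masks.
    """
    params = params or SegmentationParams()
    labels = _as_labels(class_map)
    raw = (labels == CLASS_HOLE) | (labels == CLASS_DEBRIS)
    return _smooth(raw, params.smoothing_radius_px)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def cells_to_csv(cells: list[CellRecord], path) -> None:
    df = pd.DataFrame(
        {
            "id": [c.id for c in cells],
            "x": [c.centroid[0] for c in cells],
            "y": [c.centroid[1] for c in cells],
            "area_px": [c.area_px for c in cells],
            "area_um2": [c.area_um2 for c in cells],
            "circularity": [c.circularity for c in cells],
            "flags": [";".join(sorted(c.flags)) for c in cells],
        }
    )
    df.to_csv(path, index=False)


def outlines_to_csv(cells: list[CellRecord], path) -> None:
    rows = []
    for c in cells:
        for i, (x, y) in enumerate(c.outline):
            rows.append((c.id, i, x, y))
    pd.DataFrame(rows, columns=["id", "vertex", "x", "y"]).to_csv(path, index=False)


def read_cells_csv(cells_path, outlines_path=None) -> list[CellRecord]:
    df = pd.read_csv(cells_path)
    outlines: dict[int, np.ndarray] = {}
    if outlines_path is not None:
        odf = pd.read_csv(outlines_path)
        for cid, grp in odf.groupby("id"):
            outlines[int(cid)] = grp.sort_values("vertex")[["x", "y"]].to_numpy(float)
    records = []
    for _, row in df.iterrows():
        cid = int(row["id"])
        records.append(
            CellRecord(
                id=cid,
                centroid=(float(row["x"]), float(row["y"])),
                outline=outlines.get(cid, np.empty((0, 2))),
                area_px=int(row["area_px"]),
                area_um2=float(row["area_um2"]),
                circularity=float(row["circularity"]),
                flags=frozenset(str(row["flags"]).split(";")),
            )
        )
    return records


def read_outlines_csv(path) -> dict[int, np.ndarray]:
    odf = pd.read_csv(path)
    return {
        int(cid): grp.sort_values("vertex")[["x", "y"]].to_numpy(float)
        for cid, grp in odf.groupby("id")
    }


def read_class_map(path, h5_dataset: str = "class_map") -> np.ndarray:
    """Load a class map from integer TIFF or an HDF5 dataset.

    HDF5 files (.h5/.hdf5) are read from ``h5_dataset``; anything else goes
    through tifffile.  Probability stacks are accepted as-is (converted at
    detection time).
    """
    import os

    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            return fh[h5_dataset][()]
    import tifffile

    return tifffile.imread(path)
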