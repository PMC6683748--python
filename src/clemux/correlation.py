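"""LM <-> EM correlation: landmark affine registration, measurement masks, intensities.

Coordinate convention throughout: 0-based pixel centers, ``(x, y) = (column, row)``,
x rightward, y downward. Arrays are indexed ``[row, col]`` as usual.

The registration model is a 2D affine map fitted by least squares to 3-10
user-picked control-point pairs; with well-spread landmarks this overlays
EM-derived cell outlines onto the fluorescence data to sub-pixel accuracy.
Outlines are filled, dilated slightly (the lectin ring sits on and just outside
the cell wall, i.e. outside the EM-derived outline), and pixels claimed by more
than one cell -- or falling on holes/debris -- are dropped from every claimant
so that the per-cell median intensities are unbiased by neighbours.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import skimage.transform
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon
from skimage.morphology import disk

from .segmentation import CellRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AffineTransform",
    "MeasurementMask",
    "fit_affine",
    "build_masks",
    "measure_intensities",
    "read_control_points",
    "write_transform",
    "read_transform",
]


# ---------------------------------------------------------------------------
# Affine transform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffineTransform:
    """2D affine map ``p_out = A @ p_in + t`` between pixel frames.

    Parameters
    ----------
    matrix : (2, 3) array
        ``[[a, b, tx], [c, d, ty]]`` acting on column vectors ``(x, y, 1)``.
    direction : str
        Free-text tag, conventionally ``"EM->LM"`` or ``"LM->EM"``.
    """

    matrix: np.ndarray
    direction: str = "EM->LM"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) <= 1e-12:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls, direction: str = "EM->LM") -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]), direction)

    @classmethod
    def from_params(
        cls,
        scale: float = 1.0,
        rotation_deg: float = 0.0,
        translation: tuple[float, float] = (0.0, 0.0),
        direction: str = "LM->EM",
    ) -> "AffineTransform":
        """Similarity transform (uniform scale, rotation, translation)."""
        th = math.radians(rotation_deg)
        a = scale * math.cos(th)
        b = -scale * math.sin(th)
        return cls(
            np.array([[a, b, translation[0]], [-b, a, translation[1]]]),
            direction,
        )

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 2) array of (x, y) points (a single pair also works)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ self.linear.T + self.translation
        return out if np.asarray(points).ndim == 2 else out[0]

    def inverse(self) -> "AffineTransform":
        inv_lin = np.linalg.inv(self.linear)
        inv_t = -inv_lin @ self.translation
        parts = self.direction.split("->")
        direction = "->".join(parts[::-1]) if len(parts) == 2 else f"inv({self.direction})"
        return AffineTransform(np.hstack([inv_lin, inv_t[:, None]]), direction)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return the map ``self after other`` (apply ``other`` first)."""
        lin = self.linear @ other.linear
        t = self.linear @ other.translation + self.translation
        return AffineTransform(np.hstack([lin, t[:, None]]), self.direction)

    def as_skimage(self) -> skimage.transform.AffineTransform:
        h = np.vstack([self.matrix, [0.0, 0.0, 1.0]])
        return skimage.transform.AffineTransform(matrix=h)


def fit_affine(
    points_src: Sequence[tuple[float, float]],
    points_dst: Sequence[tuple[float, float]],
    direction: str = "EM->LM",
    warn_rms_px: float = 5.0,
) -> tuple[AffineTransform, np.ndarray]:
    """Least-squares affine mapping ``points_src`` onto ``points_dst``.

    Minimizes sum ||T(p_src) - p_dst||^2 over the six affine coefficients.
    3-10 well-spread landmark pairs are typically sufficient.

    Returns the fitted transform and the per-point residual norms (px).

    Raises
    ------
    ValueError
        Fewer than 3 pairs, mismatched lengths, or (near-)collinear source points.
    """
    src = np.atleast_2d(np.asarray(points_src, dtype=float))
    dst = np.atleast_2d(np.asarray(points_dst, dtype=float))
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("control points must be matched (N, 2) arrays")
    n = src.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 control-point pairs, got {n}")
    design = np.hstack([src, np.ones((n, 1))])
    # rank < 3 <=> all source points collinear
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(design).max())) < 3:
        raise ValueError("control points are collinear; affine fit is degenerate")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = coef.T  # (2, 3)
    tform = AffineTransform(matrix, direction)
    residuals = np.linalg.norm(tform(src) - dst, axis=1)
    rms = float(np.sqrt(np.mean(residuals**2)))
    if rms > warn_rms_px:
        logger.warning("affine fit rms residual %.2f px exceeds %.2f px", rms, warn_rms_px)
    return tform, residuals


def read_control_points(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a control-point CSV with columns em_x, em_y, lm_x, lm_y."""
    df = pd.read_csv(path)
    missing = {"em_x", "em_y", "lm_x", "lm_y"} - set(df.columns)
    if missing:
        raise ValueError(f"control point CSV missing columns: {sorted(missing)}")
    return df[["em_x", "em_y"]].to_numpy(float), df[["lm_x", "lm_y"]].to_numpy(float)


def write_transform(tform: AffineTransform, path) -> None:
    """Store the six coefficients as a text sidecar with a direction tag."""
    with open(path, "w") as fh:
        fh.write(f"# direction: {tform.direction}\n")
        fh.write(" ".join(repr(float(v)) for v in tform.matrix.ravel()) + "\n")


def read_transform(path) -> AffineTransform:
    direction = "EM->LM"
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# direction:"):
                direction = line.split(":", 1)[1].strip()
            elif line:
                values.extend(float(v) for v in line.split())
    if len(values) != 6:
        raise ValueError(f"expected 6 affine coefficients, got {len(values)}")
    return AffineTransform(np.array(values).reshape(2, 3), direction)


# ---------------------------------------------------------------------------
# Measurement masks
# ---------------------------------------------------------------------------

@dataclass
class MeasurementMask:
    """Pixels measured for one cell, as flat indices into the LM frame.

    Indices are row-major into an image of shape ``shape``; the ``mask``
    property materializes the boolean raster when convenient.
    """

    cell_id: int
    pixels: np.ndarray  # flat indices, int64, sorted
    shape: tuple[int, int]
    excluded: bool = False

    @property
    def n_px(self) -> int:
        return int(self.pixels.size)

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        m.ravel()[self.pixels] = True
        return m


def _cell_pixels(
    outline_lm: np.ndarray, lm_shape: tuple[int, int], selem: np.ndarray | None
) -> np.ndarray:
    """Flat LM-frame indices of the filled (optionally dilated) outline.

    Rasterization happens on a local bounding-box patch so memory scales with
    the cell, not the field of view.
    """
    h, w = lm_shape
    x, y = outline_lm[:, 0], outline_lm[:, 1]
    pad = (selem.shape[0] // 2 + 1) if selem is not None else 1
    x0 = int(np.floor(x.min())) - pad
    y0 = int(np.floor(y.min())) - pad
    x1 = int(np.ceil(x.max())) + pad + 1
    y1 = int(np.ceil(y.max())) + pad + 1
    patch_shape = (y1 - y0, x1 - x0)
    patch = np.zeros(patch_shape, dtype=bool)
    rr, cc = draw_polygon(y - y0, x - x0, shape=patch_shape)
    patch[rr, cc] = True
    if selem is not None and patch.any():
        patch = ndi.binary_dilation(patch, structure=selem)
    pr, pc = np.nonzero(patch)
    gr = pr + y0
    gc = pc + x0
    keep = (gr >= 0) & (gr < h) & (gc >= 0) & (gc < w)
    return np.sort(gr[keep].astype(np.int64) * w + gc[keep])


def build_masks(
    cells: Iterable[CellRecord],
    holes: np.ndarray | None,
    dilation_um: float,
    transform: AffineTransform,
    lm_shape: tuple[int, int],
    lm_pixel_size_nm: float = 100.0,
) -> list[MeasurementMask]:
    """Build disjoint per-cell measurement masks in the LM frame.

    Each ``ok``-flagged cell's EM outline is mapped through ``transform``
    (EM -> LM), filled, and dilated by ``round(dilation_um * 1000 / lm_pixel_size_nm)``
    pixels.  Pixels claimed by more than one cell are removed from *all*
    claimants, and pixels on the (transformed) holes/debris mask are removed,
    so neighbouring cells and defects cannot bias the intensity medians.

    Parameters
    ----------
    holes : bool array or None
        EM-frame holes/debris raster (see :func:`clemux.segmentation.holes_mask`).
    transform : AffineTransform
        EM pixel frame to LM pixel frame.
    lm_shape : (rows, cols)
        Shape of the LM image plane.

    Cells whose outline maps entirely outside the LM image are returned with
    an empty mask and ``excluded=True``.
    """
    if dilation_um < 0:
        raise ValueError("dilation_um must be >= 0")
    dil_px = int(round(dilation_um * 1000.0 / lm_pixel_size_nm))
    selem = disk(dil_px) if dil_px > 0 else None

    masks: list[MeasurementMask] = []
    for cell in cells:
        if "ok" not in cell.flags:
            continue
        pixels = _cell_pixels(transform(cell.outline), lm_shape, selem)
        masks.append(MeasurementMask(cell.id, pixels, lm_shape, excluded=pixels.size == 0))

    if masks:
        coverage = np.zeros(lm_shape[0] * lm_shape[1], dtype=np.uint8)
        for mm in masks:
            coverage[mm.pixels] += 1
        forbidden = coverage >= 2
        if holes is not None and holes.any():
            holes_lm = warp_mask(holes, transform, lm_shape)
            forbidden |= holes_lm.ravel()
        if forbidden.any():
            for mm in masks:
                mm.pixels = mm.pixels[~forbidden[mm.pixels]]
        for mm in masks:
            if not mm.excluded and mm.n_px == 0:
                mm.excluded = True
    return masks


def warp_mask(mask: np.ndarray, transform: AffineTransform, out_shape: tuple[int, int]) -> np.ndarray:
    """Resample a binary raster through an affine map (nearest neighbour).

    ``transform`` maps input-frame (x, y) to output-frame (x, y).
    """
    # skimage.warp wants the output->input map
    inv = transform.inverse().as_skimage()
    out = skimage.transform.warp(
        mask.astype(np.float32), inverse_map=inv, output_shape=out_shape,
        order=0, preserve_range=True, cval=0.0,
    )
    return out > 0.5


# ---------------------------------------------------------------------------
# Intensity measurement
# ---------------------------------------------------------------------------

def measure_intensities(
    lm_stack: np.ndarray,
    masks: Sequence[MeasurementMask],
    channels: Sequence[str],
) -> pd.DataFrame:
    """Median intensity per channel under each cell's measurement mask.

    Parameters
    ----------
    lm_stack : (C, H, W) array
        One 2D plane per fluorescent channel, panel order.
    masks : measurement masks in the same (H, W) frame.
    channels : channel names, one per plane.

    Returns
    -------
    DataFrame with columns ``id``, ``n_px``, then one column per channel
    holding the raw median intensities I_i^c.  Cells with an empty mask get
    NaN medians and ``n_px = 0`` (flagged downstream, not an error).
    """
    stack = np.asarray(lm_stack)
    if stack.ndim != 3:
        raise ValueError("lm_stack must be (channels, rows, cols)")
    if stack.shape[0] != len(channels):
        raise ValueError(
            f"{stack.shape[0]} planes but {len(channels)} channel names"
        )
    flat = stack.reshape(stack.shape[0], -1)
    rows = []
    for mm in masks:
        if mm.shape != stack.shape[1:]:
            raise ValueError("mask shape does not match LM image plane")
        rec: dict[str, float] = {"id": mm.cell_id, "n_px": mm.n_px}
        if mm.n_px == 0:
            rec.update({c: np.nan for c in channels})
        else:
            med = np.median(flat[:, mm.pixels], axis=1)
            rec.update(dict(zip(channels, med)))
        rows.append(rec)
    df = pd.DataFrame(rows, columns=["id", "n_px", *channels])
    df["id"] = df["id"].astype(int)
    df["n_px"] = df["n_px"].astype(int)
    return df
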