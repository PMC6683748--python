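"""Ground-truthed synthetic inputs: barcoded LM/EM image pairs, sliced spheres.

This module replaces the microscope.  It renders a multi-channel fluorescence
plane and a matching EM overview + pixel-class map of the same (virtual)
section, with a known LM->EM affine and a complete ground-truth table, so that
every downstream stage -- segmentation, registration, mask building, intensity
measurement, barcode classification -- can be tested against truth.  A second
generator slices 3D sphere populations to validate the stereological
volume-fraction estimator against the exact 3D fraction.

Model of the section
--------------------
Cells are ellipses carrying a bright wall ring (the lectin conjugates bind the
cell wall).  Each cell draws one log-normal brightness factor shared across
channels -- staining varies a lot between cells but is highly correlated
between channels -- and its ring intensity in channel c is
``brightness * bit_c + background``, plus additive Gaussian noise.  The cell
interior carries a faint echo of the same barcode (default 30% of the wall
brightness), standing for cytoplasmic background labeling; without it a
filled measurement mask over a thin crisp ring would see mostly unstained
interior.  No optics are simulated (no PSF, no chromatic shift).

The EM overview holds the same cells in a frame related by a configurable
affine (default 8x scale, 7 degree rotation: medium-magnification EM pixels of
a few nm vs LM pixels of ~100 nm), plus hole and debris distractors, and the
class map labels every pixel background / cell / hole / debris.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .correlation import AffineTransform
from .morphometry import MorphometryDataset
from .segmentation import (
    CLASS_BACKGROUND,
    CLASS_CELL,
    CLASS_DEBRIS,
    CLASS_HOLE,
    CellRecord,
)

__all__ = [
    "ChannelPanel",
    "BarcodePattern",
    "enumerate_patterns",
    "NoiseConfig",
    "RenderConfig",
    "SyntheticSample",
    "render_sample",
    "truth_cell_records",
    "save_sample",
    "SphereSliceConfig",
    "slice_spheres",
]


# ---------------------------------------------------------------------------
# Channel panels and barcode patterns
# ---------------------------------------------------------------------------

#: The five spectrally separated conjugate channels commonly available on a
#: widefield system (blue / green / orange / far red / near infrared).
DEFAULT_CHANNELS = ("A350", "A488", "TRITC", "A647", "Cy7")


@dataclass(frozen=True)
class ChannelPanel:
    """Ordered set of fluorescent channels used for barcoding.

    The order is fixed for the lifetime of an experiment: bit i of every
    pattern refers to ``names[i]``.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(self.names)
        if not 1 <= len(names) <= 8:
            raise ValueError("panel must have 1..8 channels")
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        object.__setattr__(self, "names", names)

    @property
    def count(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class BarcodePattern:
    """Binary channel-membership vector: bit i = conjugate i present.

    The all-zero combination is excluded (an unstained cell is
    indistinguishable from a false negative).
    """

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        bits = tuple(int(b) for b in self.bits)
        if any(b not in (0, 1) for b in bits):
            raise ValueError("pattern bits must be 0/1")
        if not any(bits):
            raise ValueError("the all-zero pattern is excluded")
        object.__setattr__(self, "bits", bits)

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)

    @classmethod
    def from_string(cls, s: str) -> "BarcodePattern":
        return cls(tuple(int(ch) for ch in s.strip()))

    @property
    def vector(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=float)


def enumerate_patterns(panel: ChannelPanel) -> list[BarcodePattern]:
    """All nonzero binary patterns over the panel, in ascending binary order.

    An n-channel panel yields 2^n - 1 barcodes (7 for three dyes, 15 for
    four, 31 for five); channel 0 is the most significant bit of the code.
    """
    n = panel.count
    return [
        BarcodePattern(tuple((i >> (n - 1 - c)) & 1 for c in range(n)))
        for i in range(1, 2**n)
    ]


# ---------------------------------------------------------------------------
# LM/EM sample rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseConfig:
    """Intensity model of the rendered fluorescence planes.

    ``ring_intensity`` is the nominal wall-ring amplitude (camera units);
    each cell's actual amplitude is ``ring_intensity`` scaled by a log-normal
    factor of sigma ``brightness_sigma`` (median 1), shared across channels.
    Additive Gaussian noise has sd ``gaussian_cv * ring_intensity``; a
    constant ``background`` is added everywhere.
    """

    ring_intensity: float = 100.0
    background: float = 20.0
    gaussian_cv: float = 0.10
    brightness_sigma: float = 0.3


@dataclass(frozen=True)
class RenderConfig:
    """Geometry of the rendered section.

    LM pixels are ~100 nm, cells yeast-sized (radius ~2 um).  The wall ring
    occupies the outer ``ring_width_frac`` of the radius and the interior is
    stained at ``interior_level`` of the wall brightness.  The EM frame is
    related to the LM frame by scale ``em_scale`` and rotation
    ``em_rotation_deg`` (translation is chosen so the transformed field of
    view fits the EM canvas).
    """

    lm_pixel_size_nm: float = 100.0
    cell_radius_um: tuple[float, float] = (1.8, 2.4)  # min/max mean radius
    ellipticity: float = 1.15  # max axis ratio sqrt
    ring_width_frac: float = 0.35
    interior_level: float = 0.3
    em_scale: float = 8.0
    em_rotation_deg: float = 7.0
    n_holes: int = 3
    n_debris: int = 3
    hole_radius_um: tuple[float, float] = (1.0, 2.5)
    n_control_points: int = 6
    control_point_jitter_px: float = 0.5  # EM px
    spacing_margin: float = 1.5  # grid spacing in units of 2*r_max
    lm_shape: tuple[int, int] | None = None  # None: auto-size to fit


@dataclass
class SyntheticSample:
    """One rendered virtual section with complete ground truth.

    ``truth`` columns: id, pattern, brightness, lm_x, lm_y, em_x, em_y,
    r1_px, r2_px, theta_rad (ellipse semi-axes/orientation, LM frame).
    ``control_points`` columns: em_x, em_y, lm_x, lm_y.
    """

    panel: ChannelPanel
    lm_stack: np.ndarray  # (C, H, W) float32
    em_overview: np.ndarray | None  # (H', W') float32
    class_map: np.ndarray | None  # (H', W') uint8
    truth: pd.DataFrame
    lm_to_em: AffineTransform
    control_points: pd.DataFrame
    seed: int

    @property
    def lm_shape(self) -> tuple[int, int]:
        return self.lm_stack.shape[1:]


def _ellipse_quadratic(r1: float, r2: float, theta: float) -> np.ndarray:
    """Shape matrix Q with (p-c)^T Q (p-c) = rho^2 (rho=1 on the boundary)."""
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, s], [-s, c]])
    return rot.T @ np.diag([1.0 / r1**2, 1.0 / r2**2]) @ rot


def _rho_patch(shape: tuple[int, int], center: np.ndarray, q: np.ndarray, rmax: float):
    """Normalized elliptical radius on a bounding-box patch around the ellipse.

    Returns (row slice, col slice, rho array) or None if fully outside.
    """
    # ellipse bbox half-extents from the inverse shape matrix
    qinv = np.linalg.inv(q)
    hx = math.sqrt(max(qinv[0, 0], 0.0))
    hy = math.sqrt(max(qinv[1, 1], 0.0))
    x0 = max(int(math.floor(center[0] - hx)) - 1, 0)
    x1 = min(int(math.ceil(center[0] + hx)) + 2, shape[1])
    y0 = max(int(math.floor(center[1] - hy)) - 1, 0)
    y1 = min(int(math.ceil(center[1] + hy)) + 2, shape[0])
    if x0 >= x1 or y0 >= y1:
        return None
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx = xs - center[0]
    dy = ys - center[1]
    rho2 = q[0, 0] * dx * dx + 2 * q[0, 1] * dx * dy + q[1, 1] * dy * dy
    return slice(y0, y1), slice(x0, x1), np.sqrt(np.maximum(rho2, 0.0))


def render_sample(
    panel: ChannelPanel,
    patterns_in_use: list[BarcodePattern],
    n_cells_per_pattern: int,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    config: RenderConfig | None = None,
    render_em: bool = True,
) -> SyntheticSample:
    """Render a barcoded virtual section with known ground truth.

    Cells (``n_cells_per_pattern`` per pattern) are placed on a jittered grid
    so profiles never touch; holes and debris distractors occupy further grid
    slots.  Identical ``(panel, patterns, n, noise, seed, config)`` reproduce
    the sample bit-for-bit.

    With ``render_em=False`` only the LM stack and truth are produced
    (``em_overview``/``class_map`` are None); useful for large samples where
    only the fluorescence path is needed.

    Raises
    ------
    ValueError
        If patterns are not drawn from the panel, or the requested cells and
        distractors exceed the grid capacity of a caller-fixed ``lm_shape``.
    """
    noise = noise or NoiseConfig()
    cfg = config or RenderConfig()
    valid = set(enumerate_patterns(panel))
    if not patterns_in_use:
        raise ValueError("patterns_in_use is empty")
    if not set(patterns_in_use) <= valid:
        raise ValueError("patterns_in_use must be drawn from the panel")
    if n_cells_per_pattern < 1:
        raise ValueError("n_cells_per_pattern must be >= 1")
    rng = np.random.default_rng(seed)

    px_um = cfg.lm_pixel_size_nm / 1000.0
    r_max_px = cfg.cell_radius_um[1] / px_um * cfg.ellipticity
    spacing = 2.0 * r_max_px * cfg.spacing_margin
    n_cells = len(patterns_in_use) * n_cells_per_pattern
    n_slots = n_cells + cfg.n_holes + cfg.n_debris

    if cfg.lm_shape is not None:
        lm_shape = cfg.lm_shape
        nx = int((lm_shape[1] - spacing) // spacing)
        ny = int((lm_shape[0] - spacing) // spacing)
        if nx * ny < n_slots:
            raise ValueError(
                f"cannot place {n_slots} objects without overlap in {lm_shape} "
                f"at grid capacity {nx * ny}"
            )
    else:
        side = int(math.ceil(math.sqrt(n_slots)))
        nx = ny = side
        dim = int(math.ceil(spacing * (side + 1)))
        lm_shape = (dim, dim)

    # jittered grid placement: overlap-free by construction
    slot_ids = rng.permutation(nx * ny)[:n_slots]
    jitter_max = max(spacing / 2.0 - r_max_px - 1.0, 0.0)
    centers = np.empty((n_slots, 2))
    for i, s in enumerate(slot_ids):
        gx, gy = s % nx, s // nx
        centers[i] = (
            spacing * (gx + 1) + rng.uniform(-jitter_max, jitter_max),
            spacing * (gy + 1) + rng.uniform(-jitter_max, jitter_max),
        )
    cell_centers = centers[:n_cells]
    hole_centers = centers[n_cells : n_cells + cfg.n_holes]
    debris_centers = centers[n_cells + cfg.n_holes :]

    # per-cell geometry and brightness
    patterns = [p for p in patterns_in_use for _ in range(n_cells_per_pattern)]
    order = rng.permutation(n_cells)
    patterns = [patterns[i] for i in order]
    radius = rng.uniform(*cfg.cell_radius_um, size=n_cells) / px_um
    ax_ratio = rng.uniform(1.0, cfg.ellipticity, size=n_cells)
    r1 = radius * ax_ratio
    r2 = radius / ax_ratio
    theta = rng.uniform(0.0, math.pi, size=n_cells)
    brightness = noise.ring_intensity * rng.lognormal(
        mean=0.0, sigma=noise.brightness_sigma, size=n_cells
    )

    # LM->EM transform: similarity, translation centers the field on the EM canvas
    lin = AffineTransform.from_params(cfg.em_scale, cfg.em_rotation_deg, (0.0, 0.0))
    corners = np.array(
        [[0, 0], [lm_shape[1], 0], [0, lm_shape[0]], [lm_shape[1], lm_shape[0]]], float
    )
    mapped = corners @ lin.linear.T
    margin = 4.0
    t = margin - mapped.min(axis=0)
    lm_to_em = AffineTransform(
        np.hstack([lin.linear, t[:, None]]), direction="LM->EM"
    )
    em_extent = mapped.max(axis=0) + t + margin
    em_shape = (int(math.ceil(em_extent[1])), int(math.ceil(em_extent[0])))

    # fluorescence planes
    n_ch = panel.count
    lm = np.zeros((n_ch, *lm_shape), dtype=np.float64)
    for i in range(n_cells):
        q = _ellipse_quadratic(r1[i], r2[i], theta[i])
        patch = _rho_patch(lm_shape, cell_centers[i], q, radius[i])
        if patch is None:
            continue
        sy, sx, rho = patch
        ring = (rho <= 1.0) & (rho >= 1.0 - cfg.ring_width_frac)
        interior = rho < 1.0 - cfg.ring_width_frac
        bits = patterns[i].bits
        for c in range(n_ch):
            if bits[c]:
                lm[c, sy, sx][ring] = brightness[i]
                lm[c, sy, sx][interior] = cfg.interior_level * brightness[i]
    lm += noise.background
    if noise.gaussian_cv > 0:
        lm += rng.normal(
            0.0, noise.gaussian_cv * noise.ring_intensity, size=lm.shape
        )
        np.clip(lm, 0.0, None, out=lm)

    # EM-frame geometry of every cell (exact affine image of the LM ellipse)
    em_centers = lm_to_em(cell_centers)
    a_inv = np.linalg.inv(lm_to_em.linear)

    em_overview = None
    class_map = None
    if render_em:
        class_map = np.zeros(em_shape, dtype=np.uint8)
        em_overview = np.full(em_shape, 120.0, dtype=np.float64)
        for i in range(n_cells):
            q_lm = _ellipse_quadratic(r1[i], r2[i], theta[i])
            q_em = a_inv.T @ q_lm @ a_inv
            patch = _rho_patch(em_shape, em_centers[i], q_em, 0.0)
            if patch is None:
                continue
            sy, sx, rho = patch
            inside = rho <= 1.0
            wall = inside & (rho >= 0.93)
            cm = class_map[sy, sx]
            cm[inside] = CLASS_CELL
            ov = em_overview[sy, sx]
            ov[inside] = 90.0
            ov[wall] = 50.0
        # holes: bright disks where cells detached from the resin
        hole_r = rng.uniform(*cfg.hole_radius_um, size=cfg.n_holes) / px_um
        for i, hc in enumerate(lm_to_em(hole_centers) if cfg.n_holes else []):
            r_em = hole_r[i] * cfg.em_scale
            patch = _rho_patch(em_shape, hc, np.eye(2) / r_em**2, r_em)
            if patch is None:
                continue
            sy, sx, rho = patch
            inside = rho <= 1.0
            class_map[sy, sx][inside] = CLASS_HOLE
            em_overview[sy, sx][inside] = 220.0
        # debris: small irregular dark clumps (union of offset disks)
        for dc in lm_to_em(debris_centers) if cfg.n_debris else []:
            for _ in range(3):
                off = rng.uniform(-0.8, 0.8, size=2) / px_um * cfg.em_scale
                r_em = rng.uniform(0.3, 0.8) / px_um * cfg.em_scale
                patch = _rho_patch(em_shape, dc + off, np.eye(2) / r_em**2, r_em)
                if patch is None:
                    continue
                sy, sx, rho = patch
                inside = rho <= 1.0
                keep = class_map[sy, sx][inside] != CLASS_CELL
                idx = np.where(inside)
                class_map[sy, sx][idx[0][keep], idx[1][keep]] = CLASS_DEBRIS
                em_overview[sy, sx][idx[0][keep], idx[1][keep]] = 30.0
        em_overview += rng.normal(0.0, 5.0, size=em_shape)

    # control points: jittered grid over the LM field, mapped through the truth
    ncp = cfg.n_control_points
    gx = np.linspace(0.1, 0.9, max(2, int(math.ceil(math.sqrt(ncp)))))
    grid = np.array([(x, y) for y in gx for x in gx])[:ncp]
    cp_lm = grid * np.array([lm_shape[1], lm_shape[0]])
    cp_lm += rng.uniform(-2.0, 2.0, size=cp_lm.shape)
    cp_em = lm_to_em(cp_lm)
    if cfg.control_point_jitter_px > 0:
        cp_em = cp_em + rng.normal(0.0, cfg.control_point_jitter_px, size=cp_em.shape)
    control_points = pd.DataFrame(
        {"em_x": cp_em[:, 0], "em_y": cp_em[:, 1], "lm_x": cp_lm[:, 0], "lm_y": cp_lm[:, 1]}
    )

    # ground truth in EM raster order so detection ids line up naturally
    truth = pd.DataFrame(
        {
            "pattern": [str(p) for p in patterns],
            "brightness": brightness,
            "lm_x": cell_centers[:, 0],
            "lm_y": cell_centers[:, 1],
            "em_x": em_centers[:, 0],
            "em_y": em_centers[:, 1],
            "r1_px": r1,
            "r2_px": r2,
            "theta_rad": theta,
        }
    )
    truth = truth.sort_values(
        by=["em_y", "em_x"], key=lambda s: np.round(s)
    ).reset_index(drop=True)
    truth.insert(0, "id", np.arange(len(truth)))

    return SyntheticSample(
        panel=panel,
        lm_stack=lm.astype(np.float32),
        em_overview=None if em_overview is None else em_overview.astype(np.float32),
        class_map=class_map,
        truth=truth,
        lm_to_em=lm_to_em,
        control_points=control_points,
        seed=seed,
    )


def truth_cell_records(sample: SyntheticSample, frame: str = "lm", n_vertices: int = 72) -> list[CellRecord]:
    """Ground-truth cell outlines as CellRecords (ellipse polygons).

    ``frame`` selects the LM or EM pixel frame.  Useful for measuring
    intensities against truth without running the detection stage.
    """
    if frame not in ("lm", "em"):
        raise ValueError("frame must be 'lm' or 'em'")
    phi = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    records = []
    for _, row in sample.truth.iterrows():
        c, s = math.cos(row.theta_rad), math.sin(row.theta_rad)
        xy = np.stack(
            [
                row.r1_px * np.cos(phi) * c - row.r2_px * np.sin(phi) * s,
                row.r1_px * np.cos(phi) * s + row.r2_px * np.sin(phi) * c,
            ],
            axis=1,
        )
        center = np.array([row.lm_x, row.lm_y])
        if frame == "em":
            xy = (xy + center) @ sample.lm_to_em.linear.T + sample.lm_to_em.translation
            center = sample.lm_to_em(center)
        else:
            xy = xy + center
        area = math.pi * row.r1_px * row.r2_px
        records.append(
            CellRecord(
                id=int(row.id),
                centroid=(float(center[0]), float(center[1])),
                outline=np.vstack([xy, xy[:1]]),
                area_px=int(round(area)),
                area_um2=float(area * 0.01),
                circularity=1.0,
                flags=frozenset({"ok"}),
            )
        )
    return records


def save_sample(sample: SyntheticSample, out_dir) -> dict[str, Path]:
    """Write the sample to disk: TIFF images, CSV tables, transform sidecar."""
    import tifffile

    from .correlation import write_transform

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "lm_stack": out / "lm_stack.tif",
        "truth": out / "truth.csv",
        "control_points": out / "control_points.csv",
        "lm_to_em": out / "lm_to_em.txt",
    }
    tifffile.imwrite(paths["lm_stack"], sample.lm_stack, photometric="minisblack")
    sample.truth.to_csv(paths["truth"], index=False)
    sample.control_points.to_csv(paths["control_points"], index=False)
    write_transform(sample.lm_to_em, paths["lm_to_em"])
    if sample.em_overview is not None:
        paths["em_overview"] = out / "em_overview.tif"
        paths["class_map"] = out / "class_map.tif"
        tifffile.imwrite(paths["em_overview"], sample.em_overview)
        tifffile.imwrite(paths["class_map"], sample.class_map)
    return paths


# ---------------------------------------------------------------------------
# Sphere-slicing simulator for stereology validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SphereSliceConfig:
    """Population of spherical cells containing spherical organelles.

    Radii are log-normal with the given mean and coefficient of variation;
    organelle counts are Poisson.  Defaults emulate yeast (cell radius
    ~2 um) containing a couple of ~200-nm-diameter endosomal organelles.
    """

    n_cells: int = 1000
    cell_radius_mean_nm: float = 2000.0
    cell_radius_cv: float = 0.10
    organelle_mean_count: float = 2.0
    organelle_radius_mean_nm: float = 100.0
    organelle_radius_cv: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.cell_radius_mean_nm <= 0 or self.organelle_radius_mean_nm <= 0:
            raise ValueError("radii must be positive")
        if self.organelle_radius_mean_nm >= self.cell_radius_mean_nm:
            raise ValueError("organelle radius must be smaller than cell radius")
        if self.cell_radius_cv < 0 or self.organelle_radius_cv < 0:
            raise ValueError("CV must be non-negative")
        if self.organelle_mean_count < 0:
            raise ValueError("organelle count must be non-negative")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.full(size, mean)
    sigma2 = math.log(1.0 + cv**2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


def slice_spheres(cfg: SphereSliceConfig) -> tuple[MorphometryDataset, float]:
    """Cut each synthetic cell with one random plane; return profiles + truth.

    The cutting plane's offset is uniform over the cell's own diameter
    (-R, R), emulating profile-based sampling of ultrathin sections: every
    cell contributes a cross-section area ``u``; organelles intersected by
    the plane contribute circular profiles summed into ``v`` (v = 0 when the
    plane misses them all).  Also returns the exact 3D volume fraction
    ``sum (4/3) pi r^3 / sum (4/3) pi R^3`` of the generated population.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    big_r = _lognormal(rng, cfg.cell_radius_mean_nm, cfg.cell_radius_cv, n)
    h = big_r * rng.uniform(-1.0, 1.0, size=n)
    u = np.maximum(np.pi * (big_r**2 - h**2), 1e-9)

    counts = rng.poisson(cfg.organelle_mean_count, size=n)
    m = int(counts.sum())
    v = np.zeros(n)
    prof_cell: list[int] = []
    prof_d: list[float] = []
    total_org_vol = 0.0
    if m > 0:
        owner = np.repeat(np.arange(n), counts)
        r = _lognormal(rng, cfg.organelle_radius_mean_nm, cfg.organelle_radius_cv, m)
        r = np.minimum(r, 0.45 * big_r[owner])
        total_org_vol = float((4.0 / 3.0) * np.pi * np.sum(r**3))
        # organelle center z: z-coordinate of a uniform point in the ball of
        # radius (R - r), so the organelle always lies fully inside the cell
        rad = (big_r[owner] - r) * rng.random(m) ** (1.0 / 3.0)
        z = rad * rng.uniform(-1.0, 1.0, size=m)
        rho2 = r**2 - (h[owner] - z) ** 2
        hit = rho2 > 0
        areas = np.pi * rho2[hit]
        np.add.at(v, owner[hit], areas)
        diam = 2.0 * np.sqrt(rho2[hit])
        prof_cell = owner[hit].tolist()
        prof_d = diam.tolist()
    # clip the (vanishingly rare) case of organelle profiles summing past the
    # cell profile in a grazing section
    v = np.minimum(v, u)

    total_cell_vol = float((4.0 / 3.0) * np.pi * np.sum(big_r**3))
    true_fraction = total_org_vol / total_cell_vol
    profiles = pd.DataFrame({"cell_id": prof_cell, "d1": prof_d, "d2": prof_d})
    ds = MorphometryDataset(u, v, profiles=profiles)
    return ds, true_fraction
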