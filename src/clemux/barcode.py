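"""Barcode determination: two-step normalization, k-means, pattern calls.

Raw per-cell per-channel median intensities are first brought onto a common
scale per channel,

    N_i^c = (I_i^c - min_j I_j^c) / (Q3(I^c) - Q1(I^c)),

(the interquartile range characterizes the distribution shape without being
driven by outliers), then normalized per cell by the brightest channel,

    F_i^c = N_i^c / max_c' N_i^c',

which removes the large cell-to-cell variation in total labeling while
preserving the (highly correlated) channel ratios.  In F-space a cell
carrying pattern bits b sits near the vector b itself, so k-means with k =
number of expected color combinations separates the barcodes, and clusters
are mapped one-to-one onto patterns by a Hungarian assignment of centroids
to ideal bit vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .synthetic import BarcodePattern

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_channels",
    "normalize_per_cell",
    "cluster_barcodes",
    "assign_cluster_identities",
    "classify_cells",
    "apply_overrides",
    "read_calls",
    "qc_report",
]


def normalize_channels(
    table: pd.DataFrame, channels: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-channel min/IQR normalization (step 1).

    ``table`` is an intensity table with columns ``id`` and one per channel.
    Quartiles use linear interpolation between order statistics.  Returns the
    normalized table (same shape) and per-channel metadata (min, q1, q3).

    Requires at least 4 cells with finite values; a channel with Q3 = Q1
    carries no information and raises a ValueError naming it.
    """
    vals = table[channels].to_numpy(float)
    finite = np.isfinite(vals).all(axis=1)
    if int(finite.sum()) < 4:
        raise ValueError("need at least 4 measurable cells for quartile normalization")
    meta_rows = {}
    out = table.copy()
    for c in channels:
        col = table.loc[finite, c].to_numpy(float)
        cmin = float(col.min())
        q1, q3 = np.percentile(col, [25.0, 75.0])  # linear interpolation
        if not q3 > q1:
            raise ValueError(f"channel {c!r} has zero interquartile range; uninformative")
        out[c] = (table[c] - cmin) / (q3 - q1)
        meta_rows[c] = {"min": cmin, "q1": float(q1), "q3": float(q3)}
    meta = pd.DataFrame(meta_rows).T
    meta.index.name = "channel"
    return out, meta


def normalize_per_cell(
    table: pd.DataFrame, channels: list[str]
) -> tuple[pd.DataFrame, list[int]]:
    """Per-cell division by the brightest channel (step 2).

    Every classifiable cell's row has max over channels exactly 1.  Cells
    whose maximum normalized intensity is <= 0 (or not finite) cannot be
    scaled and are flagged unclassifiable: returned as a list of ids and
    left NaN in the output.
    """
    out = table.copy()
    vals = table[channels].to_numpy(float)
    with np.errstate(invalid="ignore"):
        maxes = np.nanmax(np.where(np.isfinite(vals), vals, -np.inf), axis=1)
    bad = ~np.isfinite(maxes) | (maxes <= 0) | ~np.isfinite(vals).all(axis=1)
    scale = np.where(bad, np.nan, maxes)
    out[channels] = vals / scale[:, None]
    unclassifiable = table.loc[bad, "id"].astype(int).tolist()
    return out, unclassifiable


def cluster_barcodes(
    final: pd.DataFrame,
    channels: list[str],
    k: int,
    seed: int,
    restarts: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean k-means (k-means++ init, ``restarts`` restarts, fixed seed).

    ``final`` holds the per-cell fully normalized intensities; rows with NaN
    must be dropped by the caller.  Returns (labels, centroids).
    """
    x = final[channels].to_numpy(float)
    if not np.isfinite(x).all():
        raise ValueError("clustering input contains non-finite values")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds the {x.shape[0]} classifiable cells")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        random_state=int(seed) % (2**31),
    ).fit(x)
    return km.labels_.astype(int), km.cluster_centers_


def assign_cluster_identities(
    centroids: np.ndarray, patterns_in_use: list[BarcodePattern]
) -> dict[int, BarcodePattern]:
    """Optimal one-to-one cluster -> pattern map (Hungarian assignment).

    Each pattern's ideal position in F-space is its bit vector (the brightest
    present channel normalizes to 1).  Minimizes total Euclidean
    centroid-ideal distance; ties broken deterministically by the patterns'
    binary order (the assignment problem is solved on the sorted pattern
    list).
    """
    patterns = sorted(patterns_in_use, key=str)
    if len(centroids) != len(patterns):
        raise ValueError(
            f"{len(centroids)} centroids but {len(patterns)} patterns; need a bijection"
        )
    ideals = np.array([p.vector for p in patterns])
    cost = cdist(np.asarray(centroids, float), ideals)
    rows, cols = linear_sum_assignment(cost)
    return {int(r): patterns[c] for r, c in zip(rows, cols)}


def classify_cells(
    intensity: pd.DataFrame,
    channels: list[str],
    patterns_in_use: list[BarcodePattern],
    seed: int,
    k: int | None = None,
    restarts: int = 50,
    low_confidence_quantile: float = 0.95,
) -> pd.DataFrame:
    """Full demultiplexing: normalize twice, cluster, assign patterns.

    Returns a call table with columns ``id``, ``cluster``, ``pattern``,
    ``distance`` (to own centroid in F-space) and ``flags`` (ok /
    unclassifiable / low_confidence).  ``k`` defaults to the number of
    expected color combinations, i.e. ``len(patterns_in_use)``.  A cell is
    flagged low_confidence when its centroid distance exceeds the given
    quantile of distances within its cluster.
    """
    k = len(patterns_in_use) if k is None else k
    norm, _ = normalize_channels(intensity, channels)
    final, unclassifiable = normalize_per_cell(norm, channels)
    good = final[~final["id"].isin(unclassifiable)].reset_index(drop=True)
    labels, centroids = cluster_barcodes(good, channels, k, seed, restarts)
    mapping = assign_cluster_identities(centroids, patterns_in_use)

    x = good[channels].to_numpy(float)
    dist = np.linalg.norm(x - centroids[labels], axis=1)
    low_conf = np.zeros(len(good), dtype=bool)
    for c in range(k):
        in_c = labels == c
        if in_c.sum() >= 2:
            thr = np.quantile(dist[in_c], low_confidence_quantile)
            low_conf |= in_c & (dist > thr)

    rows = []
    for i, cid in enumerate(good["id"].astype(int)):
        flags = "low_confidence" if low_conf[i] else "ok"
        rows.append(
            {
                "id": cid,
                "cluster": int(labels[i]),
                "pattern": str(mapping[int(labels[i])]),
                "distance": float(dist[i]),
                "flags": flags,
            }
        )
    for cid in unclassifiable:
        rows.append(
            {"id": int(cid), "cluster": -1, "pattern": "", "distance": np.nan,
             "flags": "unclassifiable"}
        )
    calls = pd.DataFrame(rows, columns=["id", "cluster", "pattern", "distance", "flags"])
    return calls.sort_values("id").reset_index(drop=True)


def read_calls(path) -> pd.DataFrame:
    """Read a call CSV, keeping patterns as bit strings (leading zeros matter)."""
    calls = pd.read_csv(path, keep_default_na=False, dtype={"pattern": str})
    calls["distance"] = pd.to_numeric(calls["distance"], errors="coerce")
    calls["id"] = calls["id"].astype(int)
    return calls


def apply_overrides(calls: pd.DataFrame, overrides: pd.DataFrame) -> pd.DataFrame:
    """Apply a manual-correction table: id, action in {exclude, reassign:<bits>}.

    Mirrors the interactive validation step non-interactively: affected rows
    gain the ``manual_override`` flag (plus ``excluded`` when excluded).
    """
    out = calls.copy()
    for _, row in overrides.iterrows():
        cid = int(row["id"])
        action = str(row["action"]).strip()
        idx = out.index[out["id"] == cid]
        if len(idx) == 0:
            raise ValueError(f"override for unknown cell id {cid}")
        if action == "exclude":
            out.loc[idx, "flags"] = "excluded;manual_override"
        elif action.startswith("reassign:"):
            pattern = action.split(":", 1)[1]
            BarcodePattern.from_string(pattern)  # validate
            out.loc[idx, "pattern"] = pattern
            out.loc[idx, "flags"] = "manual_override"
        else:
            raise ValueError(f"unknown override action {action!r}")
    return out


# ---------------------------------------------------------------------------
# QC report: thumbnail galleries + call table
# ---------------------------------------------------------------------------

def _to_uint8(img: np.ndarray, lo: float, hi: float) -> np.ndarray:
    scaled = (np.asarray(img, float) - lo) / max(hi - lo, 1e-12)
    return (np.clip(scaled, 0.0, 1.0) * 255).astype(np.uint8)


def _crop(img: np.ndarray, cx: float, cy: float, half: int) -> np.ndarray:
    h, w = img.shape
    y0, y1 = int(round(cy)) - half, int(round(cy)) + half
    x0, x1 = int(round(cx)) - half, int(round(cx)) + half
    out = np.zeros((2 * half, 2 * half), dtype=img.dtype)
    sy0, sy1 = max(y0, 0), min(y1, h)
    sx0, sx1 = max(x0, 0), min(x1, w)
    if sy0 < sy1 and sx0 < sx1:
        out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = img[sy0:sy1, sx0:sx1]
    return out


def qc_report(
    calls: pd.DataFrame,
    lm_stack: np.ndarray,
    cells,
    out_dir,
    em_overview: np.ndarray | None = None,
    em_transform=None,
    overrides: pd.DataFrame | None = None,
    thumb_half_px: int = 32,
    max_cells_per_pattern: int = 24,
) -> pd.DataFrame:
    """Write the non-interactive QC report: call CSV + thumbnail galleries.

    For each assigned pattern a PNG montage is written (one row per cell:
    every LM channel crop, plus an EM crop when ``em_overview`` and the
    EM->LM ``em_transform`` are given), so barcode assignment and EM
    preservation can be assessed together.  ``cells`` supplies the LM- or
    EM-frame centroids (a list of CellRecords keyed by call id).  An
    optional override table is applied first; the (possibly amended) call
    table is returned and written as ``calls.csv``.

    Output is deterministic: rerunning on the same inputs writes
    byte-identical files.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if overrides is not None:
        calls = apply_overrides(calls, overrides)
    calls = calls.sort_values("id").reset_index(drop=True)
    calls.to_csv(out / "calls.csv", index=False, float_format="%.6g")

    centroid_of = {c.id: c.centroid for c in cells}
    lo = float(np.min(lm_stack))
    hi = float(np.max(lm_stack))
    to_lm = None
    if em_overview is not None and em_transform is not None:
        to_lm = em_transform  # EM -> LM
        em_lo, em_hi = float(em_overview.min()), float(em_overview.max())

    for pattern, grp in calls[calls["pattern"] != ""].groupby("pattern"):
        ids = [i for i in grp["id"].astype(int) if i in centroid_of]
        ids = ids[:max_cells_per_pattern]
        if not ids:
            continue
        rows = []
        for cid in ids:
            cx, cy = centroid_of[cid]
            tiles = [
                _to_uint8(_crop(plane, cx, cy, thumb_half_px), lo, hi)
                for plane in lm_stack
            ]
            if to_lm is not None:
                ex, ey = to_lm.inverse()(np.array([cx, cy]))
                scale = abs(np.linalg.det(to_lm.linear)) ** -0.5  # EM px per LM px
                em_half = int(round(thumb_half_px * scale))
                em_crop = _crop(em_overview, ex, ey, max(em_half, 2))
                # downsample to thumbnail size by strided sampling
                step = max(em_crop.shape[0] // (2 * thumb_half_px), 1)
                em_small = em_crop[::step, ::step][: 2 * thumb_half_px, : 2 * thumb_half_px]
                pad = np.zeros((2 * thumb_half_px, 2 * thumb_half_px), np.uint8)
                pad[: em_small.shape[0], : em_small.shape[1]] = _to_uint8(
                    em_small, em_lo, em_hi
                )
                tiles.append(pad)
            rows.append(np.hstack(tiles))
        gallery = np.vstack(rows)
        iio.imwrite(out / f"gallery_{pattern}.png", gallery)
    return calls
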