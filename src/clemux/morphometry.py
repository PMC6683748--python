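"""Stereological organelle morphometry from cross-section profiles.

Organelle profiles (e.g. multivesicular bodies) are approximated by the user
as ellipses on high-resolution micrographs: the major-axis diameter D1 and the
widest perpendicular diameter D2.  From these and the per-cell cross-section
areas the module estimates, per experimental group:

* the organelle volume fraction ``V_r = sum(v) / sum(u)`` by the Delesse
  principle (areal fraction on random sections estimates volume fraction),
  with ``u`` the cell cross-section areas and ``v`` the summed organelle
  profile areas per cell;
* its sampling-theory standard error for a ratio of sums over paired per-cell
  observations;
* the surface-to-volume ratio from summed profile circumferences and areas,
  ``S/V = (4/pi) * sum(C) / sum(A)`` (boundary length per unit area times the
  classical stereological factor 4/pi).

The ellipse circumference uses Ramanujan's first approximation, accurate to
well below 0.1% for the modest aspect ratios of organelle profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProfileMeasurement",
    "MorphometryDataset",
    "StereologySummary",
    "ellipse_area",
    "ellipse_circumference",
    "volume_fraction",
    "volume_fraction_se",
    "surface_to_volume",
    "summarize_groups",
]


# ---------------------------------------------------------------------------
# Ellipse profile geometry
# ---------------------------------------------------------------------------

def ellipse_area(d1, d2):
    """Area of an ellipse from its two diameters: A = pi * D1 * D2 / 4.

    Accepts scalars or arrays; diameters must be positive.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if np.any(d1 <= 0) or np.any(d2 <= 0):
        raise ValueError("diameters must be positive")
    out = np.pi * d1 * d2 / 4.0
    return float(out) if out.ndim == 0 else out


def ellipse_circumference(d1, d2):
    """Ramanujan's approximation to the ellipse circumference.

    With semi-axes a = D1/2, b = D2/2:

        C = pi * [3(a + b) - sqrt((3a + b)(a + 3b))]

    Exact for a circle; relative error < 0.02% up to aspect ratio 5.
    Symmetric in its arguments.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if np.any(d1 <= 0) or np.any(d2 <= 0):
        raise ValueError("diameters must be positive")
    a = d1 / 2.0
    b = d2 / 2.0
    out = np.pi * (3.0 * (a + b) - np.sqrt((3.0 * a + b) * (a + 3.0 * b)))
    return float(out) if out.ndim == 0 else out


@dataclass
class ProfileMeasurement:
    """One organelle cross-section: major/minor diameters and derived A, C."""

    cell_id: int
    d1: float
    d2: float
    group: str | None = None
    area: float = field(init=False)
    circumference: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.d1 >= self.d2 > 0:
            raise ValueError("require D1 >= D2 > 0")
        self.area = ellipse_area(self.d1, self.d2)
        self.circumference = ellipse_circumference(self.d1, self.d2)


# ---------------------------------------------------------------------------
# Ratio estimator
# ---------------------------------------------------------------------------

@dataclass
class MorphometryDataset:
    """Paired per-cell observations feeding the ratio estimator.

    ``u[i]`` is the i-th cell's cross-section area and ``v[i]`` the summed
    organelle cross-section areas in that cell (same units; ``v[i] = 0`` when
    the section missed every organelle).  ``profiles`` optionally carries the
    individual organelle profiles (columns cell_id, d1, d2) for
    surface-to-volume estimation.
    """

    u: np.ndarray
    v: np.ndarray
    group: str = ""
    profiles: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape or self.u.ndim != 1:
            raise ValueError("u and v must be matched 1D vectors")
        if np.any(self.u <= 0):
            raise ValueError("cell cross-section areas must be positive")
        if np.any(self.v < 0):
            raise ValueError("organelle areas must be non-negative")
        if np.any(self.v > self.u):
            raise ValueError("organelle area exceeds its cell's area")

    @property
    def k(self) -> int:
        """Number of cell cross sections."""
        return int(self.u.size)

    def to_csv(self, path) -> None:
        pd.DataFrame({"u": self.u, "v": self.v}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, group: str = "") -> "MorphometryDataset":
        df = pd.read_csv(path)
        return cls(df["u"].to_numpy(float), df["v"].to_numpy(float), group=group)


def volume_fraction(ds: MorphometryDataset) -> float:
    """Delesse ratio estimator of the organelle volume fraction: sum(v)/sum(u)."""
    if ds.k < 1:
        raise ValueError("empty dataset")
    return float(ds.v.sum() / ds.u.sum())


def volume_fraction_se(ds: MorphometryDataset) -> float:
    """Sampling-theory standard error of the ratio-of-sums estimator.

    SE = V_r * sqrt( k/(k-1) * [ sum(u^2)/(sum u)^2 + sum(v^2)/(sum v)^2
                                 - 2*sum(uv)/(sum u * sum v) ] )

    The negative cross term means positive correlation between a cell's area
    and its organelle content *reduces* the uncertainty of the ratio, and the
    bracket vanishes exactly when v is proportional to u.  Defined as 0 when
    every v is 0; the bracket is clamped at 0 against floating-point
    negatives.  Requires k >= 2.
    """
    k = ds.k
    if k < 2:
        raise ValueError("SE requires at least 2 cross sections")
    su = ds.u.sum()
    sv = ds.v.sum()
    if sv == 0:
        return 0.0
    bracket = (
        (ds.u**2).sum() / su**2
        + (ds.v**2).sum() / sv**2
        - 2.0 * (ds.u * ds.v).sum() / (su * sv)
    )
    bracket = max(bracket, 0.0)
    vr = sv / su
    return float(vr * math.sqrt(k / (k - 1) * bracket))


def surface_to_volume(
    profiles: pd.DataFrame,
    cell_areas: np.ndarray | None = None,
    stereology_factor: bool = True,
) -> float:
    """Organelle surface-to-volume ratio from profile circumference and area sums.

    ``profiles`` needs columns ``d1`` and ``d2`` (one row per organelle
    profile).  The default estimator is

        S/V = (4/pi) * sum(C) / sum(A)

    restricting the classical boundary-length stereology relation to the
    organelle phase; for a population of sliced spheres of radius r it
    converges to the true 3/r.  ``stereology_factor=False`` drops the 4/pi
    constant and returns the bare circumference-to-area ratio.
    """
    if len(profiles) < 1:
        raise ValueError("need at least one organelle profile")
    a = ellipse_area(profiles["d1"].to_numpy(float), profiles["d2"].to_numpy(float))
    c = ellipse_circumference(profiles["d1"].to_numpy(float), profiles["d2"].to_numpy(float))
    sa = float(np.sum(a))
    if sa == 0:
        raise ValueError("total profile area is zero")
    ratio = float(np.sum(c)) / sa
    return (4.0 / math.pi) * ratio if stereology_factor else ratio


# ---------------------------------------------------------------------------
# Group summaries
# ---------------------------------------------------------------------------

@dataclass
class StereologySummary:
    group: str
    volume_fraction: float
    se: float
    surface_to_volume: float | None
    k: int


_DROP_FLAGS = {"excluded", "unclassifiable"}


def _group_of(calls: pd.DataFrame) -> dict[int, str | None]:
    """cell id -> group label (assigned pattern), None for dropped cells."""
    out: dict[int, str | None] = {}
    for _, row in calls.iterrows():
        flags = set(str(row.get("flags", "ok")).split(";"))
        dropped = flags & _DROP_FLAGS
        out[int(row["id"])] = None if dropped else str(row["pattern"])
    return out


def summarize_groups(
    profiles: pd.DataFrame,
    cell_areas: pd.DataFrame,
    calls: pd.DataFrame | Mapping[int, str],
    stereology_factor: bool = True,
) -> list[StereologySummary]:
    """Join organelle profiles to barcode groups and summarize per group.

    Parameters
    ----------
    profiles : DataFrame with columns cell_id, d1, d2 (one organelle profile
        per row; a cell may have several or none).
    cell_areas : DataFrame with columns cell_id, area (every analyzed cell,
        including cells without organelle profiles -- they contribute v = 0).
    calls : barcode call table (columns id, pattern, flags) or a plain
        mapping cell id -> group label.  Cells flagged excluded or
        unclassifiable are dropped.

    Raises
    ------
    ValueError
        If any profile's cell id is missing from ``cell_areas`` or has no
        barcode call (orphans are listed in the message).
    """
    if isinstance(calls, pd.DataFrame):
        groups = _group_of(calls)
    else:
        groups = {int(k): str(g) for k, g in calls.items()}

    area_of = dict(zip(cell_areas["cell_id"].astype(int), cell_areas["area"].astype(float)))
    orphans = sorted(
        {int(c) for c in profiles["cell_id"]} - set(area_of)
        | {int(c) for c in profiles["cell_id"]} - set(groups)
        | set(area_of) - set(groups)
    )
    if orphans:
        raise ValueError(f"measurements with no matching call/area: {orphans}")

    a_profile = ellipse_area(profiles["d1"].to_numpy(float), profiles["d2"].to_numpy(float))
    v_of: dict[int, float] = {}
    for cid, a in zip(profiles["cell_id"].astype(int), a_profile):
        v_of[cid] = v_of.get(cid, 0.0) + float(a)

    summaries: list[StereologySummary] = []
    for group in sorted({g for g in groups.values() if g is not None}):
        ids = [cid for cid in area_of if groups.get(cid) == group]
        if not ids:
            continue
        u = np.array([area_of[cid] for cid in ids])
        v = np.array([v_of.get(cid, 0.0) for cid in ids])
        ds = MorphometryDataset(u, v, group=group)
        vr = volume_fraction(ds)
        se = volume_fraction_se(ds) if ds.k >= 2 else 0.0
        gmask = profiles["cell_id"].astype(int).isin(ids)
        sv = (
            surface_to_volume(profiles[gmask], stereology_factor=stereology_factor)
            if gmask.any()
            else None
        )
        summaries.append(StereologySummary(group, vr, se, sv, ds.k))
    return summaries


def summaries_to_csv(summaries: Sequence[StereologySummary], path) -> None:
    pd.DataFrame(
        {
            "group": [s.group for s in summaries],
            "volume_fraction": [s.volume_fraction for s in summaries],
            "se": [s.se for s in summaries],
            "surface_to_volume": [s.surface_to_volume for s in summaries],
            "k": [s.k for s in summaries],
        }
    ).to_csv(path, index=False)
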