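"""SerialEM Navigator (.nav, autodoc) reading, writing, coordinate export.

A Navigator file is a plain-text autodoc: preamble ``Key = value`` lines
(notably ``AdocVersion``), then ``[Item = label]`` sections describing points,
polygons and maps with stage coordinates in micrometres.  This module parses
the minimal subset needed to append acquisition points tied to a registered
map -- everything else passes through verbatim, so the written file remains
usable by the acquisition software.

The canonical serialized form is ``Key = value`` lines with one blank line
before each item section; reading then writing a canonical file reproduces it
byte-for-byte (up to newline normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .segmentation import CellRecord

__all__ = [
    "NavigatorItem",
    "NavigatorDocument",
    "read_navigator",
    "write_navigator",
    "pixel_to_stage",
    "stage_to_pixel",
    "add_acquisition_points",
    "make_map_item",
]

ITEM_TYPE_POINT = 0
ITEM_TYPE_POLYGON = 1
ITEM_TYPE_MAP = 2


@dataclass
class NavigatorItem:
    """One ``[Item = label]`` section: ordered key/value pairs, values verbatim."""

    label: str
    keys: dict[str, str] = field(default_factory=dict)  # insertion-ordered

    # -- typed accessors over the raw strings ------------------------------
    def _floats(self, key: str) -> list[float] | None:
        raw = self.keys.get(key)
        return None if raw is None else [float(v) for v in raw.split()]

    @property
    def item_type(self) -> int | None:
        raw = self.keys.get("Type")
        return None if raw is None else int(raw)

    @property
    def stage_xyz(self) -> tuple[float, float, float] | None:
        v = self._floats("StageXYZ")
        return None if v is None else (v[0], v[1], v[2] if len(v) > 2 else 0.0)

    @property
    def raw_stage_xy(self) -> tuple[float, float] | None:
        v = self._floats("RawStageXY")
        if v is None:
            s = self.stage_xyz
            return None if s is None else (s[0], s[1])
        return (v[0], v[1])

    @property
    def map_scale_mat(self) -> np.ndarray | None:
        """2x2 stage-per-pixel matrix of a map item (um per overview pixel)."""
        v = self._floats("MapScaleMat")
        return None if v is None else np.array(v, float).reshape(2, 2)

    @property
    def map_width_height(self) -> tuple[int, int] | None:
        v = self._floats("MapWidthHeight")
        return None if v is None else (int(v[0]), int(v[1]))

    def set(self, key: str, value) -> None:
        if isinstance(value, (list, tuple, np.ndarray)):
            value = " ".join(_fmt_num(v) for v in np.asarray(value).ravel())
        self.keys[key] = str(value)


def _fmt_num(v) -> str:
    f = float(v)
    return str(int(f)) if f == int(f) and abs(f) < 1e15 else repr(f)


@dataclass
class NavigatorDocument:
    """Ordered Navigator items plus the verbatim preamble (version line etc.)."""

    preamble: list[str] = field(default_factory=lambda: ["AdocVersion = 2.00"])
    items: list[NavigatorItem] = field(default_factory=list)

    def find(self, label: str) -> NavigatorItem:
        for item in self.items:
            if item.label == label:
                return item
        raise KeyError(f"no Navigator item labeled {label!r}")

    @property
    def labels(self) -> list[str]:
        return [i.label for i in self.items]


def read_navigator(path) -> NavigatorDocument:
    """Parse an autodoc Navigator file; unknown keys are preserved verbatim.

    Raises ValueError (with the line number) on malformed section headers or
    duplicate item labels.
    """
    text = Path(path).read_text()
    doc = NavigatorDocument(preamble=[])
    current: NavigatorItem | None = None
    seen: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith("["):
            if not (stripped.endswith("]") and "=" in stripped):
                raise ValueError(f"line {lineno}: malformed section header {line!r}")
            head, _, val = stripped[1:-1].partition("=")
            if head.strip() != "Item":
                raise ValueError(f"line {lineno}: unsupported section {head.strip()!r}")
            label = val.strip()
            if not label:
                raise ValueError(f"line {lineno}: empty item label")
            if label in seen:
                raise ValueError(f"line {lineno}: duplicate item label {label!r}")
            seen.add(label)
            current = NavigatorItem(label=label)
            doc.items.append(current)
        elif "=" in stripped:
            key, _, val = stripped.partition("=")
            key = key.strip()
            val = val.strip()
            if current is None:
                doc.preamble.append(f"{key} = {val}")
            else:
                current.keys[key] = val
        elif stripped:
            raise ValueError(f"line {lineno}: unparseable line {line!r}")
    return doc


def write_navigator(doc: NavigatorDocument, path) -> None:
    """Serialize in canonical autodoc form (LF newlines)."""
    lines: list[str] = list(doc.preamble)
    for item in doc.items:
        lines.append("")
        lines.append(f"[Item = {item.label}]")
        for key, val in item.keys.items():
            lines.append(f"{key} = {val}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pixel <-> stage coordinates
# ---------------------------------------------------------------------------

def _map_geometry(map_item: NavigatorItem):
    m = map_item.map_scale_mat
    if m is None:
        raise ValueError(f"item {map_item.label!r} has no MapScaleMat")
    wh = map_item.map_width_height
    if wh is None:
        raise ValueError(f"item {map_item.label!r} has no MapWidthHeight")
    raw = map_item.raw_stage_xy
    if raw is None:
        raise ValueError(f"item {map_item.label!r} has no stage position")
    center = np.array([wh[0] / 2.0, wh[1] / 2.0])
    return m, center, np.asarray(raw, float)


def pixel_to_stage(
    map_item: NavigatorItem, points_px: np.ndarray, y_inverted: bool = True
) -> np.ndarray:
    """Map overview pixel coordinates to stage micrometres.

    ``stage = raw_stage + M @ (p_px - map_center_px)`` with M the map's
    stage-per-pixel scale matrix.  ``y_inverted=True`` (the default
    convention here: image y runs down, stage y runs up) negates the pixel
    y-offset before applying M; installations differ, so the flag is explicit.
    """
    m, center, raw = _map_geometry(map_item)
    p = np.atleast_2d(np.asarray(points_px, float))
    d = p - center
    if y_inverted:
        d = d * np.array([1.0, -1.0])
    out = d @ m.T + raw
    return out if np.asarray(points_px).ndim == 2 else out[0]


def stage_to_pixel(
    map_item: NavigatorItem, points_um: np.ndarray, y_inverted: bool = True
) -> np.ndarray:
    """Inverse of :func:`pixel_to_stage` for the same map and convention."""
    m, center, raw = _map_geometry(map_item)
    s = np.atleast_2d(np.asarray(points_um, float))
    d = (s - raw) @ np.linalg.inv(m).T
    if y_inverted:
        d = d * np.array([1.0, -1.0])
    out = d + center
    return out if np.asarray(points_um).ndim == 2 else out[0]


# ---------------------------------------------------------------------------
# Acquisition point export
# ---------------------------------------------------------------------------

def make_map_item(
    label: str,
    width_height: tuple[int, int],
    scale_mat: np.ndarray,
    raw_stage_xy: tuple[float, float] = (0.0, 0.0),
    map_id: int = 1,
    z_um: float = 0.0,
) -> NavigatorItem:
    """Construct a minimal Navigator map item for an overview image."""
    item = NavigatorItem(label=label)
    item.set("Color", 0)
    item.set("StageXYZ", (raw_stage_xy[0], raw_stage_xy[1], z_um))
    item.set("Type", ITEM_TYPE_MAP)
    item.set("MapID", map_id)
    item.set("RawStageXY", raw_stage_xy)
    item.set("MapWidthHeight", width_height)
    item.set("MapScaleMat", np.asarray(scale_mat).ravel())
    return item


def add_acquisition_points(
    doc: NavigatorDocument,
    map_label: str,
    cells: list[CellRecord],
    calls=None,
    y_inverted: bool = True,
) -> NavigatorDocument:
    """Append one acquire-flagged point item per selected cell.

    Cells must be ``ok``-flagged; when a call table is given, only cells with
    an ok/low_confidence call are exported and labels read
    ``<pattern>_<id>``.  Stage coordinates come from :func:`pixel_to_stage`
    on the named map item; points reference the map via ``DrawnID``.
    Original items are untouched; the input document is not modified.
    """
    map_item = doc.find(map_label)
    if map_item.item_type != ITEM_TYPE_MAP:
        raise ValueError(f"item {map_label!r} is not a map")
    map_id = map_item.keys.get("MapID", "0")
    z = map_item.stage_xyz[2] if map_item.stage_xyz else 0.0

    pattern_of = {}
    if calls is not None:
        for _, row in calls.iterrows():
            flags = set(str(row["flags"]).split(";"))
            if not flags & {"excluded", "unclassifiable"}:
                pattern_of[int(row["id"])] = str(row["pattern"])

    out = NavigatorDocument(
        preamble=list(doc.preamble),
        items=list(doc.items),
    )
    existing = set(out.labels)
    for cell in cells:
        if "ok" not in cell.flags:
            continue
        if calls is not None and cell.id not in pattern_of:
            continue
        pattern = pattern_of.get(cell.id)
        label = f"{pattern}_{cell.id}" if pattern else f"cell_{cell.id}"
        if label in existing:
            raise ValueError(f"point label {label!r} already present")
        existing.add(label)
        stage = pixel_to_stage(map_item, np.asarray(cell.centroid), y_inverted=y_inverted)
        item = NavigatorItem(label=label)
        item.set("Color", 1)
        item.set("StageXYZ", (stage[0], stage[1], z))
        item.set("Type", ITEM_TYPE_POINT)
        item.set("Acquire", 1)
        item.set("DrawnID", map_id)
        out.items.append(item)
    return out
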