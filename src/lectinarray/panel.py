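"""Lectin panel definition and physical slide layout.

A lectin microarray slide carries several identical *blocks*; each block
holds the full lectin panel spotted in replicate (triplicate by default)
plus control spots: Cy3-labeled BSA as a location marker and plain BSA as
a negative control.  Every downstream stage (simulation, I/O join,
normalization) resolves spot identity through the :class:`SlideLayout`
built here.

The bundled default panel lists the 37 lectins of the serum-glycopattern
study with their glycan-binding annotations.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "Lectin",
    "LectinPanel",
    "SlideLayout",
    "PanelError",
    "load_panel",
    "default_panel",
    "build_layout",
    "write_layout",
    "load_layout",
    "ROLE_LECTIN",
    "ROLE_MARKER",
    "ROLE_NEGATIVE",
]

ROLE_LECTIN = "lectin"
ROLE_MARKER = "marker"
ROLE_NEGATIVE = "negative"

GLYCAN_CLASSES = frozenset({"N-linked", "O-linked", "both", "unspecified"})


class PanelError(ValueError):
    """Raised for invalid panel or layout definitions."""


@dataclass(frozen=True)
class Lectin:
    """One carbohydrate-binding probe on the array."""

    name: str
    specificity: str = ""
    glycan_class: str = "unspecified"

    def __post_init__(self) -> None:
        if not self.name:
            raise PanelError("lectin name must be non-empty")
        if self.glycan_class not in GLYCAN_CLASSES:
            raise PanelError(
                f"unknown glycan_class {self.glycan_class!r} for {self.name}; "
                f"expected one of {sorted(GLYCAN_CLASSES)}"
            )


@dataclass(frozen=True)
class LectinPanel:
    """Ordered, duplicate-free collection of lectins."""

    lectins: tuple[Lectin, ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for lec in self.lectins:
            if lec.name in seen:
                raise PanelError(f"duplicate lectin name: {lec.name!r}")
            seen.add(lec.name)

    @property
    def names(self) -> list[str]:
        return [lec.name for lec in self.lectins]

    @property
    def size(self) -> int:
        return len(self.lectins)

    def __len__(self) -> int:
        return len(self.lectins)

    def __iter__(self):
        return iter(self.lectins)

    def __contains__(self, name: str) -> bool:
        return any(lec.name == name for lec in self.lectins)


def load_panel(path: str | Path) -> LectinPanel:
    """Read a panel CSV with header ``name,specificity,glycan_class``.

    Row order is preserved; duplicate names raise :class:`PanelError`.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise PanelError(f"empty panel file: {path}")
        required = {"name", "specificity", "glycan_class"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise PanelError(f"panel file {path} missing columns: {sorted(missing)}")
        lectins = [
            Lectin(
                name=row["name"].strip(),
                specificity=row["specificity"].strip(),
                glycan_class=row["glycan_class"].strip() or "unspecified",
            )
            for row in reader
        ]
    if not lectins:
        raise PanelError(f"panel file {path} contains no lectins")
    return LectinPanel(tuple(lectins))


def default_panel() -> LectinPanel:
    """The bundled 37-lectin panel covering N- and O-linked glycans."""
    ref = resources.files("lectinarray.data").joinpath("lectin_panel_37.csv")
    with resources.as_file(ref) as path:
        return load_panel(path)


@dataclass(frozen=True)
class SlideLayout:
    """Deterministic mapping from grid coordinates to spot identity.

    ``grid_map`` maps ``(block, row, column)`` (1-based) to a
    ``(role, name)`` pair; controls carry their role as name.  Geometry is
    metadata only — statistics never depend on row/column positions.
    """

    panel: LectinPanel
    blocks_per_slide: int
    spots_per_lectin: int
    grid_map: dict[tuple[int, int, int], tuple[str, str]] = field(repr=False)

    @property
    def marker_positions(self) -> list[tuple[int, int, int]]:
        return [k for k, v in self.grid_map.items() if v[0] == ROLE_MARKER]

    @property
    def negative_positions(self) -> list[tuple[int, int, int]]:
        return [k for k, v in self.grid_map.items() if v[0] == ROLE_NEGATIVE]

    @property
    def n_lectin_spots(self) -> int:
        return sum(1 for v in self.grid_map.values() if v[0] == ROLE_LECTIN)

    def lookup(self, block: int, row: int, column: int) -> tuple[str, str]:
        try:
            return self.grid_map[(block, row, column)]
        except KeyError:
            raise PanelError(
                f"coordinate (block={block}, row={row}, column={column}) "
                "not present in slide layout"
            ) from None


def build_layout(
    panel: LectinPanel,
    blocks_per_slide: int = 3,
    spots_per_lectin: int = 3,
    grid_columns: int = 12,
    n_marker: int = 3,
    n_negative: int = 3,
) -> SlideLayout:
    """Lay the panel out row-major with replicate spots adjacent.

    Row 1 of each block holds the Cy3-BSA markers then the BSA negative
    controls; lectin spots fill subsequent rows left-to-right in panel
    order.  Identical inputs always produce identical layouts.
    """
    if blocks_per_slide < 1 or spots_per_lectin < 1 or grid_columns < 1:
        raise PanelError("blocks_per_slide, spots_per_lectin and grid_columns must be >= 1")
    if n_marker + n_negative > grid_columns:
        raise PanelError("control row does not fit in grid_columns")

    grid_map: dict[tuple[int, int, int], tuple[str, str]] = {}
    for block in range(1, blocks_per_slide + 1):
        col = 1
        for _ in range(n_marker):
            grid_map[(block, 1, col)] = (ROLE_MARKER, "Cy3-BSA")
            col += 1
        for _ in range(n_negative):
            grid_map[(block, 1, col)] = (ROLE_NEGATIVE, "BSA")
            col += 1
        row, col = 2, 1
        for lec in panel:
            for _ in range(spots_per_lectin):
                grid_map[(block, row, col)] = (ROLE_LECTIN, lec.name)
                col += 1
                if col > grid_columns:
                    col = 1
                    row += 1
    return SlideLayout(
        panel=panel,
        blocks_per_slide=blocks_per_slide,
        spots_per_lectin=spots_per_lectin,
        grid_map=grid_map,
    )


def write_layout(layout: SlideLayout, path: str | Path) -> None:
    """Export the layout as CSV ``block,row,column,role,name``."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["block", "row", "column", "role", "name"])
        for (block, row, col), (role, name) in sorted(layout.grid_map.items()):
            writer.writerow([block, row, col, role, name])


def load_layout(path: str | Path, panel: LectinPanel) -> SlideLayout:
    """Read a layout CSV back; validates lectin names against *panel*."""
    path = Path(path)
    grid_map: dict[tuple[int, int, int], tuple[str, str]] = {}
    counts: dict[tuple[int, str], int] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"block", "row", "column", "role", "name"}
        if reader.fieldnames is None or required - set(reader.fieldnames):
            raise PanelError(f"layout file {path} missing required columns")
        for rec in reader:
            key = (int(rec["block"]), int(rec["row"]), int(rec["column"]))
            role, name = rec["role"], rec["name"]
            if role == ROLE_LECTIN:
                if name not in panel:
                    raise PanelError(f"layout references unknown lectin {name!r}")
                counts[(key[0], name)] = counts.get((key[0], name), 0) + 1
            grid_map[key] = (role, name)
    if not grid_map:
        raise PanelError(f"layout file {path} is empty")
    per_lectin = {c for c in counts.values()}
    spots_per_lectin = per_lectin.pop() if len(per_lectin) == 1 else 0
    if spots_per_lectin == 0:
        raise PanelError("layout has unequal spot counts per lectin per block")
    blocks = max(k[0] for k in grid_map)
    return SlideLayout(
        panel=panel,
        blocks_per_slide=blocks,
        spots_per_lectin=spots_per_lectin,
        grid_map=grid_map,
    )
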