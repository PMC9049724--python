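"""Read/write GenePix-results-like spot tables and join them to a layout.

The dialect is a minimal tab-delimited subset of a GenePix results file:
header ``Slide  Block  Row  Column  F532 Median  B532 Median  Flags``
(case-insensitive match, extra columns ignored, lines starting with
``#`` skipped).  Spot identity (lectin name or control role) is not
stored in the file; it is recovered by joining grid coordinates against
the :class:`~lectinarray.panel.SlideLayout`.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .panel import SlideLayout

__all__ = ["FormatError", "JoinError", "read_spot_table", "write_spot_table"]

REQUIRED = ["block", "row", "column", "f532 median", "b532 median", "flags"]
FILE_COLUMNS = ["Slide", "Block", "Row", "Column", "F532 Median", "B532 Median", "Flags"]


class FormatError(ValueError):
    """File does not conform to the spot-table dialect."""


class JoinError(ValueError):
    """Spot coordinates cannot be resolved against the slide layout."""


def read_spot_table(path: str | Path, layout: SlideLayout) -> pd.DataFrame:
    """Read a spot-table TSV and annotate each record via *layout*.

    Returns a DataFrame with columns ``Slide, Block, Row, Column, Role,
    Name, F532 Median, B532 Median, Flags``.  A missing required column
    raises :class:`FormatError` naming it; a coordinate absent from the
    layout raises :class:`JoinError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    lower = {c.lower().strip(): c for c in df.columns}
    missing = [c for c in REQUIRED if c not in lower]
    if missing:
        raise FormatError(f"{path} is missing required column(s): {missing}")
    out = pd.DataFrame(
        {
            "Slide": df[lower["slide"]] if "slide" in lower else 1,
            "Block": df[lower["block"]].astype(int),
            "Row": df[lower["row"]].astype(int),
            "Column": df[lower["column"]].astype(int),
            "F532 Median": df[lower["f532 median"]].astype(float),
            "B532 Median": df[lower["b532 median"]].astype(float),
            "Flags": df[lower["flags"]].astype(int),
        }
    )
    roles, names = [], []
    for block, row, col in zip(out["Block"], out["Row"], out["Column"]):
        key = (block, row, col)
        if key not in layout.grid_map:
            raise JoinError(
                f"coordinate (block={block}, row={row}, column={col}) in {path} "
                "is not present in the slide layout"
            )
        role, name = layout.grid_map[key]
        roles.append(role)
        names.append(name)
    out.insert(4, "Role", roles)
    out.insert(5, "Name", names)
    return out


def write_spot_table(spots: pd.DataFrame, path: str | Path) -> None:
    """Write spots in the dialect, deterministically ordered.

    Only the seven dialect columns are written (identity columns are
    layout-derived and re-attached on read).  Rows are sorted by
    (slide, block, row, column).
    """
    path = Path(path)
    missing = [c for c in FILE_COLUMNS if c not in spots.columns]
    if missing:
        raise FormatError(f"spot table lacks column(s) {missing}; cannot write")
    out = spots[FILE_COLUMNS].sort_values(
        ["Slide", "Block", "Row", "Column"], kind="mergesort"
    )
    out.to_csv(path, sep="\t", index=False)
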