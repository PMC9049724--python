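"""Spot filtering and sum-of-medians NFI normalization.

Procedure, per block:

1. estimate the block background as mean +/- SD of every spot's recorded
   background median (controls included by default);
2. drop scanner/QC-flagged spots (negative flag), then drop spots whose
   foreground fails to clear ``bg_mean + k * bg_sd`` (k = 1.5 for lectin
   arrays) — survivors are the *effective data points*;
3. subtract the block background mean from surviving foregrounds
   (floored at 0), take the per-lectin median, and divide each median by
   the sum of medians over all effective lectins in the block.  The
   resulting Normalized Fluorescence Intensities (NFIs) are
   dimensionless fractions summing to 1 per block.

Group statistics then average each lectin's NFI over the replicate
blocks (9 by default: 3 slides x 3 blocks) and record the sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import ROLE_LECTIN, LectinPanel, SlideLayout

__all__ = [
    "BlockBackground",
    "NFIMatrix",
    "GroupNFI",
    "PreprocessError",
    "DegenerateBlockError",
    "block_background",
    "filter_effective",
    "lectin_block_nfi",
    "blocks_to_nfi",
    "aggregate_group",
]


class PreprocessError(ValueError):
    pass


class DegenerateBlockError(PreprocessError):
    """All lectin signal in a block was filtered out (sum of medians = 0)."""


@dataclass(frozen=True)
class BlockBackground:
    """Block-level background estimate (fluorescence units)."""

    block: object
    bg_mean: float
    bg_sd: float

    def __post_init__(self) -> None:
        if self.bg_sd < 0:
            raise PreprocessError("bg_sd must be >= 0")


@dataclass
class NFIMatrix:
    """Lectin x block NFI fractions plus the effective-lectin mask.

    ``values`` holds NaN where a lectin was non-effective in a block;
    ``mask`` is True where effective.  Each column of ``values`` sums to
    1 over its effective lectins.
    """

    values: pd.DataFrame
    mask: pd.DataFrame


@dataclass
class GroupNFI:
    """Per-group NFI replicates and their mean +/- SD summary.

    ``blocks`` is the lectin x replicate-block NFI table; ``summary``
    has columns ``mean_nfi, sd, n_blocks, usable`` — a lectin is usable
    for testing only when effective in at least two replicate blocks.
    """

    group: str
    blocks: pd.DataFrame
    summary: pd.DataFrame

    def replicates(self, lectin: str) -> np.ndarray:
        """Replicate NFIs for one lectin, NaN (non-effective) dropped."""
        return self.blocks.loc[lectin].dropna().to_numpy()


def block_background(spots: pd.DataFrame, include_controls: bool = True) -> BlockBackground:
    """Mean and sample SD of background medians over one block's spots.

    By default every spot (lectin, marker and negative control)
    contributes, reading "the average background" at block level;
    ``include_controls=False`` restricts to lectin spots.
    """
    if include_controls or "Role" not in spots.columns:
        bg = spots["B532 Median"]
    else:
        bg = spots.loc[spots["Role"] == ROLE_LECTIN, "B532 Median"]
    if len(bg) < 2:
        raise PreprocessError(f"block needs >= 2 spots to estimate background, got {len(bg)}")
    block = spots["Block"].iloc[0] if "Block" in spots.columns else None
    return BlockBackground(block=block, bg_mean=float(bg.mean()), bg_sd=float(bg.std(ddof=1)))


def filter_effective(
    spots: pd.DataFrame,
    bg: BlockBackground,
    k: float = 1.5,
    direction: str = "above",
) -> pd.DataFrame:
    """Keep effective data points: unflagged spots clearing the background.

    The detection-limit reading (default, ``direction="above"``) removes
    spots whose foreground falls below ``bg_mean + k * bg_sd``; the
    threshold is inclusive (foreground exactly at it survives).  The
    alternative literal reading ``direction="below"`` removes only spots
    below ``bg_mean - k * bg_sd`` and is provided for sensitivity
    analysis.  May return an empty frame.
    """
    if k < 0:
        raise PreprocessError("k must be >= 0")
    if direction not in ("above", "below"):
        raise PreprocessError(f"direction must be 'above' or 'below', got {direction!r}")
    ok = spots["Flags"] >= 0
    sign = 1.0 if direction == "above" else -1.0
    threshold = bg.bg_mean + sign * k * bg.bg_sd
    return spots.loc[ok & (spots["F532 Median"] >= threshold)]


def lectin_block_nfi(
    survivors: pd.DataFrame,
    panel: LectinPanel,
    bg: BlockBackground,
) -> tuple[pd.Series, pd.Series]:
    """One block's NFI column from its surviving spots.

    Per lectin: median of background-subtracted foregrounds (floored at
    0), then divided by the sum of medians over effective lectins.
    Lectins with no surviving spot are non-effective (NFI = NaN).
    """
    lec = survivors.loc[survivors["Role"] == ROLE_LECTIN] if "Role" in survivors.columns else survivors
    net = (lec["F532 Median"] - bg.bg_mean).clip(lower=0)
    medians = net.groupby(lec["Name"]).median()
    medians = medians.reindex(panel.names)
    mask = medians.notna()
    total = medians[mask].sum()
    if not total > 0:
        raise DegenerateBlockError(
            f"block {bg.block!r}: sum of effective lectin medians is zero"
        )
    nfi = medians / total
    nfi.index.name = "lectin"
    mask.index.name = "lectin"
    return nfi, mask


def blocks_to_nfi(
    spot_tables: list[pd.DataFrame],
    layout: SlideLayout,
    k: float = 1.5,
    direction: str = "above",
    include_controls: bool = True,
) -> NFIMatrix:
    """Run background -> filter -> normalize over every (slide, block).

    Columns are labelled ``s{slide}b{block}``.  Conservation is asserted
    after every block: effective NFIs sum to 1 within 1e-9.
    """
    cols: dict[str, pd.Series] = {}
    masks: dict[str, pd.Series] = {}
    for table in spot_tables:
        for (slide, block), sub in table.groupby(["Slide", "Block"]):
            bg = block_background(sub, include_controls=include_controls)
            surv = filter_effective(sub, bg, k=k, direction=direction)
            nfi, mask = lectin_block_nfi(surv, layout.panel, bg)
            total = nfi[mask].sum()
            assert abs(total - 1.0) < 1e-9, f"NFI conservation violated: {total}"
            label = f"s{slide}b{block}"
            cols[label] = nfi
            masks[label] = mask
    values = pd.DataFrame(cols)
    values.index.name = "lectin"
    return NFIMatrix(values=values, mask=pd.DataFrame(masks))


def aggregate_group(group: str, nfi: NFIMatrix, min_blocks: int = 2) -> GroupNFI:
    """Average each lectin's NFI over replicate blocks; record sample SD.

    Lectins effective in fewer than *min_blocks* blocks are flagged
    unusable for downstream testing (their mean/SD are still reported
    where defined).
    """
    values = nfi.values
    n_blocks = nfi.mask.sum(axis=1).astype(int)
    summary = pd.DataFrame(
        {
            "mean_nfi": values.mean(axis=1, skipna=True),
            "sd": values.std(axis=1, ddof=1, skipna=True),
            "n_blocks": n_blocks,
            "usable": n_blocks >= min_blocks,
        }
    )
    summary.index.name = "lectin"
    return GroupNFI(group=group, blocks=values, summary=summary)
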