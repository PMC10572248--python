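"""Per-site, per-strand allele-count tables (the pipeline pileup format).

The canonical interchange is a tab-separated table with one row per
(sample, position): ``sample_id, position, ref_base`` followed by the eight
strand-split allele-count columns ``A_plus .. T_minus``. Counts are assumed
to already respect the quality floor (minimum base and alignment quality,
default 20 for both) applied upstream when the table was produced from
alignments; the :class:`QualityPolicy` travels with the table so the floor
is auditable. Optional ``trav_*`` columns carry the subset of counts from
reads traversing an entire homopolymer repeat, and ``in_homopolymer`` flags
sites within or adjacent to a run.

Depth accounting near homopolymers: sequencing errors concentrate in runs
of identical bases, so at sites within or adjacent (+/- 1 position by
default) to a run only reads spanning the whole repeat are trusted.
:func:`homopolymer_adjusted_depth` swaps in the traversing-read counts at
those sites, keeping the raw counts alongside for audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BASES, ReferenceGenome, ValidationError
from .synthetic_data import COUNT_COLUMNS, TRAV_COLUMNS


class DataError(ValueError):
    """Raised for malformed or inconsistent data content."""


@dataclass(frozen=True)
class QualityPolicy:
    """Phred-scaled quality floors applied when counting bases."""

    min_base_quality: int = 20
    min_alignment_quality: int = 20

    def __post_init__(self) -> None:
        if self.min_base_quality < 0 or self.min_alignment_quality < 0:
            raise ValidationError("quality floors must be >= 0")


REQUIRED_COLUMNS = ["sample_id", "position", "ref_base", *COUNT_COLUMNS]


def read_pileup(path: str | Path, policy: QualityPolicy | None = None) -> pd.DataFrame:
    """Read and validate a pileup TSV.

    Raises :class:`DataError` naming the offending line (1-based, counting
    the header as line 1) for unknown bases, negative counts, or duplicate
    (sample, position) records. An empty table with a valid header is fine.
    """
    policy = policy or QualityPolicy()
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing pileup columns {missing}")
    if len(df) == 0:
        df.attrs["policy"] = policy
        return df

    lines = df.index.to_numpy() + 2  # +1 header, +1 one-based
    bad = ~df["ref_base"].isin(list(BASES))
    if bad.any():
        line = lines[bad.to_numpy()][0]
        raise DataError(
            f"{path}, line {line}: unknown base symbol {df['ref_base'][bad].iloc[0]!r}"
        )
    count_cols = [c for c in df.columns if c in COUNT_COLUMNS or c in TRAV_COLUMNS]
    for c in count_cols:
        if not np.issubdtype(df[c].dtype, np.integer):
            coerced = pd.to_numeric(df[c], errors="coerce")
            if coerced.isna().any() or (coerced % 1 != 0).any():
                line = lines[(coerced.isna() | (coerced % 1 != 0)).to_numpy()][0]
                raise DataError(f"{path}, line {line}: non-integer count in {c}")
            df[c] = coerced.astype(np.int64)
        if (df[c] < 0).any():
            line = lines[(df[c] < 0).to_numpy()][0]
            raise DataError(f"{path}, line {line}: negative count in {c}")
    dup = df.duplicated(subset=["sample_id", "position"])
    if dup.any():
        line = lines[dup.to_numpy()][0]
        raise DataError(f"{path}, line {line}: duplicate (sample_id, position) record")
    if (df["position"] < 1).any():
        line = lines[(df["position"] < 1).to_numpy()][0]
        raise DataError(f"{path}, line {line}: position must be >= 1")
    df.attrs["policy"] = policy
    return df


def write_pileup(df: pd.DataFrame, path: str | Path) -> None:
    """Write a pileup table as TSV (UTF-8, Unix newlines)."""
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def site_depth(df: pd.DataFrame) -> pd.Series:
    """Total quality-passing depth per row (sum of the eight count columns)."""
    return df[COUNT_COLUMNS].sum(axis=1)


def homopolymer_adjusted_depth(
    df: pd.DataFrame,
    ref: ReferenceGenome | None = None,
    adjacent_width: int = 1,
) -> pd.DataFrame:
    """Replace counts at homopolymer-context sites with traversing-read counts.

    Context sites are those within or within ``adjacent_width`` positions of
    a homopolymer run, taken from ``ref`` when given, otherwise from the
    table's ``in_homopolymer`` column. The raw counts are preserved in
    ``raw_*`` columns and ``raw_depth``; ``effective_depth`` holds the
    homopolymer-adjusted total and ``homopolymer_adjusted`` marks the table
    as resolved. A flagged site without traversing counts is an error.
    """
    out = df.copy()
    if ref is not None:
        mask = ref.homopolymer_context(adjacent_width)
        positions = out["position"].to_numpy()
        if positions.max(initial=0) > ref.length:
            raise DataError("pileup positions exceed reference length")
        context = mask[positions - 1] if len(out) else np.zeros(0, dtype=bool)
        out["in_homopolymer"] = context.astype(np.int64)
    elif "in_homopolymer" in out.columns:
        context = out["in_homopolymer"].to_numpy().astype(bool)
    else:
        raise DataError(
            "homopolymer context unavailable: pass a reference or provide "
            "an in_homopolymer column"
        )

    have_trav = all(c in out.columns for c in TRAV_COLUMNS)
    if context.any() and not have_trav:
        raise DataError(
            "sites flagged in_homopolymer lack traversing-read counts (trav_* columns)"
        )

    out["raw_depth"] = out[COUNT_COLUMNS].sum(axis=1)
    for c in COUNT_COLUMNS:
        out[f"raw_{c}"] = out[c]
    if have_trav and context.any():
        trav = out.loc[context, TRAV_COLUMNS].to_numpy()
        raw = out.loc[context, COUNT_COLUMNS].to_numpy()
        if (trav > raw).any():
            raise DataError("traversing counts exceed raw counts at a flagged site")
        cols = out.columns.get_indexer(COUNT_COLUMNS)
        out.iloc[np.flatnonzero(context), cols] = trav
    out["effective_depth"] = out[COUNT_COLUMNS].sum(axis=1)
    out["homopolymer_adjusted"] = True
    return out
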