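"""Circular mitochondrial reference genomes.

The mitochondrial genome is a small circular molecule (~16.3 kb in mouse,
16,569 bp in human). Positions are 1-based and inclusive throughout, matching
the mtDNA variant convention (e.g. T9461C = ref T at position 9461, alt C).
Gene intervals may wrap around the origin; a wrapping interval is represented
with start > end and flagged by :attr:`GeneInterval.wraps`.

Homopolymer runs (stretches of a single base) are sequencing-error hotspots;
downstream depth accounting restricts sites within or adjacent to a run to
reads traversing the entire repeat, so the reference records run coordinates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: gene region classes used by the consequence annotator
REGION_CLASSES = ("protein_coding", "tRNA", "rRNA", "noncoding")

#: default minimum length for a stretch of identical bases to count as a
#: homopolymer run (the source protocols leave "run" undefined; 5 is the
#: package default and is configurable everywhere it matters)
DEFAULT_MIN_RUN_LENGTH = 5


class ValidationError(ValueError):
    """Raised for malformed inputs (bad config, bad coordinates, bad schema)."""


@dataclass(frozen=True)
class GeneInterval:
    """A gene interval on the circular reference (1-based, inclusive)."""

    name: str
    start: int
    end: int
    strand: str  # '+' or '-'
    region_class: str = "protein_coding"
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.name}: strand must be '+' or '-'")
        if self.region_class not in REGION_CLASSES:
            raise ValidationError(
                f"gene {self.name}: unknown region_class {self.region_class!r}"
            )
        if self.frame_offset not in (0, 1, 2):
            raise ValidationError(f"gene {self.name}: frame_offset must be 0, 1 or 2")

    @property
    def wraps(self) -> bool:
        """True when the interval crosses the circular origin."""
        return self.start > self.end

    @property
    def is_coding(self) -> bool:
        return self.region_class == "protein_coding"

    def length(self, genome_length: int) -> int:
        if not self.wraps:
            return self.end - self.start + 1
        return (genome_length - self.start + 1) + self.end

    def contains(self, position: int, genome_length: int) -> bool:
        if not self.wraps:
            return self.start <= position <= self.end
        return position >= self.start or position <= self.end


def find_homopolymer_runs(
    sequence: str, min_length: int = DEFAULT_MIN_RUN_LENGTH, circular: bool = True
) -> list[tuple[int, int, str]]:
    """Locate maximal runs of identical bases of at least ``min_length``.

    Returns (start, end, base) tuples, 1-based inclusive. On a circular
    sequence a run crossing the origin is reported once with start > end.
    """
    L = len(sequence)
    if L == 0:
        return []
    runs: list[tuple[int, int, str]] = []
    s = 0
    for i in range(1, L + 1):
        if i == L or sequence[i] != sequence[s]:
            runs.append((s + 1, i, sequence[s]))
            s = i
    if circular and len(runs) > 1 and runs[0][2] == runs[-1][2]:
        # merge the run touching position 1 with the run touching position L
        first, last = runs[0], runs[-1]
        if first[0] == 1 and last[1] == L:
            runs = runs[1:-1] + [(last[0], first[1], first[2])]
    out = []
    for a, b, base in runs:
        run_len = (b - a + 1) if a <= b else (L - a + 1) + b
        if run_len >= min_length:
            out.append((a, b, base))
    return sorted(out)


@dataclass
class ReferenceGenome:
    """A circular reference sequence with gene and homopolymer annotation."""

    name: str
    sequence: str
    genes: list[GeneInterval] = field(default_factory=list)
    homopolymer_runs: list[tuple[int, int, str]] = field(default_factory=list)
    min_run_length: int = DEFAULT_MIN_RUN_LENGTH

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set(BASES)
        if bad:
            raise ValidationError(f"sequence contains non-ACGT symbols: {sorted(bad)}")
        L = self.length
        for g in self.genes:
            if not (1 <= g.start <= L and 1 <= g.end <= L):
                raise ValidationError(
                    f"gene {g.name}: interval ({g.start},{g.end}) outside [1,{L}]"
                )
        for a, b, base in self.homopolymer_runs:
            run_len = (b - a + 1) if a <= b else (L - a + 1) + b
            if run_len < self.min_run_length:
                raise ValidationError(
                    f"homopolymer run ({a},{b}) shorter than {self.min_run_length}"
                )
            if any(self.base_at(p) != base for p in self._run_positions(a, b)):
                raise ValidationError(f"homopolymer run ({a},{b}) is not uniform {base}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int) -> str:
        """Base at a 1-based circular coordinate."""
        return self.sequence[(position - 1) % self.length]

    def fetch(self, start: int, end: int) -> str:
        """Inclusive 1-based slice; start > end wraps through the origin."""
        if start <= end:
            return self.sequence[start - 1 : end]
        return self.sequence[start - 1 :] + self.sequence[:end]

    def _run_positions(self, a: int, b: int) -> Iterable[int]:
        if a <= b:
            return range(a, b + 1)
        return list(range(a, self.length + 1)) + list(range(1, b + 1))

    def detect_homopolymer_runs(self) -> list[tuple[int, int, str]]:
        return find_homopolymer_runs(self.sequence, self.min_run_length)

    def homopolymer_context(self, adjacent_width: int = 1) -> np.ndarray:
        """Boolean mask (index = position - 1) of sites within a homopolymer
        run or within ``adjacent_width`` positions of one, wrap-aware."""
        mask = np.zeros(self.length, dtype=bool)
        for a, b, _ in self.homopolymer_runs:
            for p in self._run_positions(a, b):
                mask[p - 1] = True
            for w in range(1, adjacent_width + 1):
                mask[(a - 1 - w) % self.length] = True
                mask[(b - 1 + w) % self.length] = True
        return mask

    def genes_at(self, position: int) -> list[GeneInterval]:
        return [g for g in self.genes if g.contains(position, self.length)]

    # ------------------------------------------------------------------ IO

    def to_fasta(self, path: str | Path) -> None:
        record = SeqRecord(Seq(self.sequence), id=self.name, description="")
        SeqIO.write([record], str(path), "fasta")

    def write_annotation(self, path: str | Path) -> None:
        rows = [
            {
                "gene_name": g.name,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "region_class": g.region_class,
                "frame_offset": g.frame_offset,
            }
            for g in self.genes
        ]
        pd.DataFrame(
            rows,
            columns=["gene_name", "start", "end", "strand", "region_class", "frame_offset"],
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_fasta(
        cls,
        fasta_path: str | Path,
        annotation_path: str | Path | None = None,
        min_run_length: int = DEFAULT_MIN_RUN_LENGTH,
    ) -> "ReferenceGenome":
        records = list(SeqIO.parse(str(fasta_path), "fasta"))
        if not records:
            raise ValidationError(f"no FASTA record in {fasta_path}")
        rec = records[0]
        genes = read_annotation(annotation_path) if annotation_path else []
        seq = str(rec.seq).upper()
        return cls(
            name=rec.id,
            sequence=seq,
            genes=genes,
            homopolymer_runs=find_homopolymer_runs(seq, min_run_length),
            min_run_length=min_run_length,
        )


def read_annotation(path: str | Path) -> list[GeneInterval]:
    """Read a gene-annotation TSV (gene_name, start, end, strand,
    region_class, frame_offset)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_name", "start", "end", "strand", "region_class", "frame_offset"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"annotation file missing columns: {sorted(missing)}")
    return [
        GeneInterval(
            name=str(r.gene_name),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            region_class=str(r.region_class),
            frame_offset=int(r.frame_offset),
        )
        for r in df.itertuples()
    ]
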