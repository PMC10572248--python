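"""Gene and amino-acid consequence annotation under the vertebrate
mitochondrial genetic code.

Vertebrate mitochondria deviate from the standard code: AGA/AGG are stops,
ATA codes Met, and TGA codes Trp. Gene assignment is by interval
containment on the circular reference (wrap-aware); for protein-coding
genes the affected codon is extracted strand-aware and both reference and
alternate codons are translated to decide synonymy. Positions outside any
annotated gene fall back to the noncoding control region (D-loop) class —
never an error. Variants are named in the compact mtDNA convention, e.g.
T9461C (reference T, position 9461, alternate C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd
from Bio.Data import CodonTable

from .genome import COMPLEMENT, GeneInterval, ReferenceGenome, ValidationError

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial

NONCODING_FALLBACK = "D-loop/noncoding"


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon under the vertebrate mito code
    ('*' for stop)."""
    codon = codon.upper()
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    try:
        return _MITO_TABLE.forward_table[codon]
    except KeyError as exc:
        raise ValidationError(f"not a valid codon: {codon!r}") from exc


def variant_name(ref_base: str, position: int, alt_base: str) -> str:
    """Compact mtDNA variant name, e.g. T9461C."""
    return f"{ref_base}{position}{alt_base}"


@dataclass(frozen=True)
class Consequence:
    """Annotation of one substitution."""

    gene_name: str
    region_class: str  # protein_coding, tRNA, rRNA, noncoding
    codon_ref: Optional[str] = None
    codon_alt: Optional[str] = None
    aa_ref: Optional[str] = None
    aa_alt: Optional[str] = None
    is_nonsynonymous: Optional[bool] = None  # None iff not protein_coding


def _codon_positions(gene: GeneInterval, position: int, L: int) -> tuple[list[int], int]:
    """Genomic positions (5'->3' in gene orientation) of the codon containing
    ``position``, and the in-codon phase of the variant site."""
    if gene.strand == "+":
        offset = (position - gene.start) % L - gene.frame_offset
    else:
        offset = (gene.end - position) % L - gene.frame_offset
    if offset < 0:
        raise ValidationError(
            f"position {position} precedes the coding frame of {gene.name}"
        )
    codon_index, phase = divmod(offset, 3)
    if gene.strand == "+":
        p0 = gene.start + gene.frame_offset + 3 * codon_index
        positions = [(p0 - 1 + k) % L + 1 for k in range(3)]
    else:
        p0 = gene.end - gene.frame_offset - 3 * codon_index
        positions = [(p0 - 1 - k) % L + 1 for k in range(3)]
    return positions, phase


def _coding_consequence(
    gene: GeneInterval, position: int, ref_base: str, alt_base: str, ref: ReferenceGenome
) -> Consequence:
    positions, phase = _codon_positions(gene, position, ref.length)
    if gene.strand == "+":
        bases = [ref.base_at(p) for p in positions]
        var = alt_base
    else:
        bases = [COMPLEMENT[ref.base_at(p)] for p in positions]
        var = COMPLEMENT[alt_base]
    codon_ref = "".join(bases)
    alt_bases = list(bases)
    alt_bases[phase] = var
    codon_alt = "".join(alt_bases)
    aa_ref = translate_codon(codon_ref)
    aa_alt = translate_codon(codon_alt)
    return Consequence(
        gene_name=gene.name,
        region_class="protein_coding",
        codon_ref=codon_ref,
        codon_alt=codon_alt,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        is_nonsynonymous=(aa_ref != aa_alt),
    )


def annotate_call(
    position: int, ref_base: str, alt_base: str, ref: ReferenceGenome
) -> list[Consequence]:
    """All consequences of a substitution; one per overlapping gene, or a
    single noncoding fallback when no gene contains the position."""
    if not 1 <= position <= ref.length:
        raise ValidationError(f"position {position} outside reference [1,{ref.length}]")
    if ref.base_at(position) != ref_base:
        raise ValidationError(
            f"reference base mismatch at {position}: "
            f"expected {ref.base_at(position)}, got {ref_base}"
        )
    genes = ref.genes_at(position)
    if not genes:
        return [Consequence(gene_name=NONCODING_FALLBACK, region_class="noncoding")]
    out = []
    for gene in sorted(genes, key=lambda g: (g.region_class != "protein_coding", g.start)):
        if gene.is_coding:
            out.append(_coding_consequence(gene, position, ref_base, alt_base, ref))
        else:
            out.append(Consequence(gene_name=gene.name, region_class=gene.region_class))
    return out


def primary_consequence(
    position: int, ref_base: str, alt_base: str, ref: ReferenceGenome
) -> Consequence:
    """The single primary consequence (protein-coding genes take priority)."""
    return annotate_call(position, ref_base, alt_base, ref)[0]


def annotate_table(calls: pd.DataFrame, ref: ReferenceGenome) -> pd.DataFrame:
    """Attach primary-consequence columns to a call table."""
    out = calls.copy()
    records = []
    for r in out.itertuples():
        c = primary_consequence(int(r.position), r.ref_base, r.alt_base, ref)
        records.append(
            {
                "variant": variant_name(r.ref_base, int(r.position), r.alt_base),
                "gene_name": c.gene_name,
                "region_class": c.region_class,
                "codon_ref": c.codon_ref,
                "codon_alt": c.codon_alt,
                "aa_ref": c.aa_ref,
                "aa_alt": c.aa_alt,
                "is_nonsynonymous": c.is_nonsynonymous,
            }
        )
    ann = pd.DataFrame(
        records,
        columns=["variant", "gene_name", "region_class", "codon_ref", "codon_alt",
                 "aa_ref", "aa_alt", "is_nonsynonymous"],
    )
    return pd.concat([out.reset_index(drop=True), ann], axis=1)
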