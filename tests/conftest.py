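"""Shared fixtures: small hand-built references and simulated samples."""

import numpy as np
import pandas as pd
import pytest

from mthet import (
    GeneInterval,
    ReferenceGenome,
    TruthSet,
    generate_reference,
    simulate_pileup,
)


def _filler(n: int) -> str:
    return ("ACGT" * (n // 4 + 1))[:n]


@pytest.fixture(scope="session")
def annotated_ref() -> ReferenceGenome:
    """120 bp reference with a plus-strand coding gene whose codons are
    chosen to probe the vertebrate mito code, a minus-strand coding gene,
    and a tRNA interval."""
    seq = list(_filler(120))
    # plus-strand gene, positions 10-39, frame 0; first codons:
    # TGA (Trp in mito), GGA (Gly), ATA (Met in mito), AAA (Lys)
    coding = "TGA" "GGA" "ATA" "AAA" + _filler(18)
    seq[9:39] = list(coding)
    # minus-strand gene, 50-79; genomic 77-79 = TCA reads TGA (Trp) in gene frame
    seq[49:79] = list(_filler(30))
    seq[76:79] = list("TCA")
    genes = [
        GeneInterval("plusGene", 10, 39, "+", "protein_coding", 0),
        GeneInterval("minusGene", 50, 79, "-", "protein_coding", 0),
        GeneInterval("tRNA-Syn", 90, 110, "+", "tRNA", 0),
    ]
    return ReferenceGenome("toy", "".join(seq), genes=genes, homopolymer_runs=[])


@pytest.fixture(scope="session")
def small_ref() -> ReferenceGenome:
    """A 2 kb synthetic reference with genes and homopolymer runs."""
    return generate_reference(length=2000, n_genes=2, homopolymer_spec=(3, 5, 6), seed=11)


@pytest.fixture(scope="session")
def null_truth() -> TruthSet:
    return TruthSet(sample_id="null_sample")


def make_truth(ref: ReferenceGenome, hets, fixed=(), sample_id="s1", **kw) -> TruthSet:
    """Build a TruthSet pulling ref bases from the reference; alt is the
    alphabetically first non-reference base."""
    def alt_of(pos):
        rb = ref.base_at(pos)
        return next(b for b in "ACGT" if b != rb)

    return TruthSet(
        sample_id=sample_id,
        heteroplasmies=[(p, ref.base_at(p), alt_of(p), aaf) for p, aaf in hets],
        fixed_variants=[(p, ref.base_at(p), alt_of(p)) for p in fixed],
        **kw,
    )


@pytest.fixture(scope="session")
def design_2x2x2() -> pd.DataFrame:
    rows = []
    for strain in ("B6", "D2"):
        for treatment in ("PBS", "V2O5"):
            for time in (14, 112):
                for k in range(4):
                    rows.append(
                        {
                            "sample_id": f"{strain}_{treatment}_{time}_{k}",
                            "strain": strain,
                            "treatment": treatment,
                            "time": time,
                        }
                    )
    return pd.DataFrame(rows)
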