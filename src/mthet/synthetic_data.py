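"""Synthetic cohorts for the heteroplasmy and DNA-damage pipeline.

The generators realise exactly the statistical structure the downstream
stages assume, so the whole pipeline is testable without any external data:

* :func:`generate_reference` — a random circular mtDNA-like reference with
  non-overlapping genes and implanted homopolymer runs;
* :func:`simulate_pileup` — per-site, per-allele, per-strand read counts.
  Site depth is Poisson(mean_depth); sequencing/PCR errors hit each read
  independently at ``error_rate`` and substitute uniformly over the three
  non-reference bases; implanted heteroplasmies draw alternate reads
  binomially at their true allele frequency; reads split between strands
  by a per-site plus fraction (default 0.5);
* :func:`simulate_qpcr_plate` — the long-amplicon qPCR forward model:
  lesions block the polymerase, so the relative amplification of a long
  fragment is the Poisson zero class exp(-rate * amplicon/normalisation),
  while a short mitochondrial amplicon is lesion-insensitive and scales
  linearly with mtDNA copy number;
* :func:`simulate_cohort` — a full strain x treatment x time study with
  group-level truth for heteroplasmy, lesion rates and copy numbers.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    BASES,
    DEFAULT_MIN_RUN_LENGTH,
    GeneInterval,
    ReferenceGenome,
    ValidationError,
    find_homopolymer_runs,
)

# indices of the three non-reference bases for each reference base index
_NONREF = np.array([[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]])

COUNT_COLUMNS = [f"{b}_{s}" for b in BASES for s in ("plus", "minus")]
TRAV_COLUMNS = [f"trav_{c}" for c in COUNT_COLUMNS]

#: default qPCR amplicon sizes (bp): 10 kb long mito fragment, small
#: lesion-insensitive mito fragment, 6.5 kb nuclear (beta-polymerase) fragment
DEFAULT_AMPLICON_BP = {"LMITO": 10_000, "SMITO": 117, "BPOL": 6_500}


@dataclass
class TruthSet:
    """Ground truth for one simulated sample.

    Heteroplasmies are (position, ref, alt, true_aaf) with true_aaf in
    [0.01, 0.8); fixed variants (the sample's major sequence differing from
    the reference, 80-100% AAF band) are (position, ref, alt) simulated at
    ``fixed_variant_aaf``. Lesion rates are per 10 kb (mito) and per 6.5 kb
    (nuclear); copy_number is mtDNA copies per DNA input unit.
    """

    sample_id: str
    heteroplasmies: list[tuple[int, str, str, float]] = field(default_factory=list)
    fixed_variants: list[tuple[int, str, str]] = field(default_factory=list)
    lesion_rate_mt: float = 0.0
    lesion_rate_nuc: float = 0.0
    copy_number: float = 0.0
    fixed_variant_aaf: float = 0.99

    def __post_init__(self) -> None:
        positions = [h[0] for h in self.heteroplasmies] + [v[0] for v in self.fixed_variants]
        if len(positions) != len(set(positions)):
            raise ValidationError(f"{self.sample_id}: duplicate truth positions")
        for pos, _, _, aaf in self.heteroplasmies:
            if not 0.01 <= aaf < 0.8:
                raise ValidationError(
                    f"{self.sample_id}: heteroplasmy AAF {aaf} at {pos} outside [0.01, 0.8)"
                )
        if not 0.8 <= self.fixed_variant_aaf <= 1.0:
            raise ValidationError("fixed_variant_aaf must be in [0.8, 1.0]")
        if min(self.lesion_rate_mt, self.lesion_rate_nuc, self.copy_number) < 0:
            raise ValidationError("lesion rates and copy number must be non-negative")

    def all_variants(self) -> list[tuple[int, str, str, float]]:
        return list(self.heteroplasmies) + [
            (p, r, a, self.fixed_variant_aaf) for p, r, a in self.fixed_variants
        ]


def generate_reference(
    length: int = 16_569,
    n_genes: int = 13,
    homopolymer_spec: tuple[int, int, int] = (10, 5, 8),
    seed: int = 0,
    gene_span: tuple[int, int] = (240, 900),
    min_run_length: int = DEFAULT_MIN_RUN_LENGTH,
) -> ReferenceGenome:
    """Generate a random circular reference with genes and homopolymer runs.

    ``homopolymer_spec`` is (count, min_len, max_len) for implanted runs;
    they are placed away from gene boundaries so consequence annotation in
    tests is unambiguous. Deterministic for a fixed seed. Raises
    :class:`ValidationError` when the requested genes or runs cannot be
    packed into the sequence.
    """
    if length < 1000:
        raise ValidationError("length must be >= 1000")
    n_runs, run_min, run_max = homopolymer_spec
    if n_runs < 0 or (n_runs > 0 and not (min_run_length <= run_min <= run_max)):
        raise ValidationError("homopolymer_spec must satisfy min_run_length <= min <= max")
    if n_genes < 0:
        raise ValidationError("n_genes must be >= 0")
    if n_genes * gene_span[1] > length:
        raise ValidationError(
            f"cannot pack {n_genes} genes of up to {gene_span[1]} bp into {length} bp"
        )

    rng = np.random.default_rng(seed)
    seq = rng.choice(list(BASES), size=length)

    genes: list[GeneInterval] = []
    if n_genes > 0:
        block = length // n_genes
        for i in range(n_genes):
            lo = i * block + 1
            span = 3 * int(rng.integers(gene_span[0] // 3, gene_span[1] // 3 + 1))
            span = min(span, block - 6)
            start = lo + int(rng.integers(0, block - span - 2))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneInterval(
                    name=f"synGene{i + 1:02d}",
                    start=start,
                    end=start + span - 1,
                    strand=strand,
                    region_class="protein_coding",
                    frame_offset=0,
                )
            )

    # implant homopolymer runs away from gene boundaries
    boundary = set()
    for g in genes:
        for p in (g.start, g.end):
            boundary.update(range(p - 2, p + 3))
    placed: list[tuple[int, int]] = []
    for _ in range(n_runs):
        for _attempt in range(1000):
            run_len = int(rng.integers(run_min, run_max + 1))
            start = int(rng.integers(1, length - run_len))
            end = start + run_len - 1
            span_ok = not any(a <= end + 1 and start - 1 <= b for a, b in placed)
            if span_ok and not any(p in boundary for p in range(start - 1, end + 2)):
                base = BASES[int(rng.integers(0, 4))]
                seq[start - 1 : end] = base
                placed.append((start, end))
                break
        else:
            raise ValidationError("could not place homopolymer runs; relax the spec")

    sequence = "".join(seq)
    return ReferenceGenome(
        name=f"synthetic_mt_{length}",
        sequence=sequence,
        genes=genes,
        homopolymer_runs=find_homopolymer_runs(sequence, min_run_length),
        min_run_length=min_run_length,
    )


def simulate_pileup(
    ref: ReferenceGenome,
    truth: TruthSet,
    mean_depth: float = 2000.0,
    error_rate: float = 0.01,
    strand_bias: dict[int, float] | None = None,
    seed: int = 0,
    traversal_fraction: float = 0.85,
    adjacent_width: int = 1,
) -> pd.DataFrame:
    """Simulate one sample's per-site per-allele per-strand counts.

    Returns the pipeline pileup table: one row per position with the eight
    strand-split allele-count columns, traversing-read counts (``trav_*``,
    for homopolymer-context depth accounting) and an ``in_homopolymer``
    flag. At homopolymer-context sites a read traverses the whole repeat
    with probability ``traversal_fraction``; elsewhere traversing counts
    equal the full counts.
    """
    if mean_depth <= 0:
        raise ValidationError("mean_depth must be > 0")
    if not 0 <= error_rate < 1:
        raise ValidationError("error_rate must be in [0, 1)")
    strand_bias = strand_bias or {}
    for pos, frac in strand_bias.items():
        if not 0 <= frac <= 1:
            raise ValidationError(f"strand_bias fraction {frac} at {pos} outside [0,1]")

    L = ref.length
    rng = np.random.default_rng(seed)
    base_index = {b: i for i, b in enumerate(BASES)}
    ref_idx = np.fromiter((base_index[b] for b in ref.sequence), dtype=np.int64, count=L)

    depth = rng.poisson(mean_depth, size=L)
    counts = np.zeros((L, 4), dtype=np.int64)

    remaining = depth.copy()
    for pos, ref_base, alt_base, aaf in truth.all_variants():
        if not 1 <= pos <= L:
            raise ValidationError(f"truth position {pos} outside reference [1,{L}]")
        if ref.base_at(pos) != ref_base:
            raise ValidationError(
                f"truth ref base {ref_base} at {pos} does not match reference"
            )
        n_alt = rng.binomial(depth[pos - 1], aaf)
        counts[pos - 1, base_index[alt_base]] += n_alt
        remaining[pos - 1] -= n_alt

    # independent substitution errors, uniform over the three non-ref bases
    n_err = rng.binomial(remaining, error_rate)
    e1 = rng.binomial(n_err, 1.0 / 3.0)
    e2 = rng.binomial(n_err - e1, 0.5)
    e3 = n_err - e1 - e2
    nonref = _NONREF[ref_idx]
    idx = np.arange(L)
    np.add.at(counts, (idx, nonref[:, 0]), e1)
    np.add.at(counts, (idx, nonref[:, 1]), e2)
    np.add.at(counts, (idx, nonref[:, 2]), e3)
    counts[idx, ref_idx] += remaining - n_err

    plus_frac = np.full(L, 0.5)
    for pos, frac in strand_bias.items():
        plus_frac[pos - 1] = frac
    plus = rng.binomial(counts, plus_frac[:, None])
    minus = counts - plus

    context = ref.homopolymer_context(adjacent_width)
    trav_plus = plus.copy()
    trav_minus = minus.copy()
    if context.any():
        trav_plus[context] = rng.binomial(plus[context], traversal_fraction)
        trav_minus[context] = rng.binomial(minus[context], traversal_fraction)

    data: dict[str, object] = {
        "sample_id": truth.sample_id,
        "position": np.arange(1, L + 1),
        "ref_base": list(ref.sequence),
    }
    for i, b in enumerate(BASES):
        data[f"{b}_plus"] = plus[:, i]
        data[f"{b}_minus"] = minus[:, i]
    for i, b in enumerate(BASES):
        data[f"trav_{b}_plus"] = trav_plus[:, i]
        data[f"trav_{b}_minus"] = trav_minus[:, i]
    data["in_homopolymer"] = context.astype(np.int64)
    return pd.DataFrame(data)


def simulate_qpcr_plate(
    truth: TruthSet,
    amplicon_bp: dict[str, int] | None = None,
    noise_cv: float = 0.05,
    seed: int = 0,
    baseline: float = 1000.0,
    background: float = 50.0,
    smito_control_copies: float = 10_000.0,
    replicates: int = 3,
) -> "QpcrPlate":
    """Simulate a qPCR plate for one sample (plus its control wells).

    Long-amplicon signal is ``baseline * exp(-rate * amplicon/normalisation)``
    (mito normalised per 10 kb, nuclear per 6.5 kb); the short mito amplicon
    signal is ``baseline * copy_number / smito_control_copies``. Every well
    reads ``(background + signal) * noise`` with multiplicative lognormal
    noise of coefficient of variation ``noise_cv`` (mean 1; exactly 1 when
    noise_cv == 0). Includes 100% and 50% undamaged controls and no-template
    background wells for each target.
    """
    from .damage import QpcrPlate  # local import to avoid a cycle

    amplicon_bp = dict(amplicon_bp or DEFAULT_AMPLICON_BP)
    for target, bp in amplicon_bp.items():
        if bp <= 0:
            raise ValidationError(f"amplicon length for {target} must be > 0")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)

    def noise(n: int) -> np.ndarray:
        if noise_cv == 0:
            return np.ones(n)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=n)

    signal = {
        "LMITO": baseline * np.exp(-truth.lesion_rate_mt * amplicon_bp["LMITO"] / 10_000.0),
        "BPOL": baseline * np.exp(-truth.lesion_rate_nuc * amplicon_bp["BPOL"] / 6_500.0),
        "SMITO": baseline * truth.copy_number / smito_control_copies,
    }
    rows = []
    well = 0
    for target in ("LMITO", "SMITO", "BPOL"):
        for role, sig in (
            ("experimental", signal[target]),
            ("control_100", baseline),
            ("control_50", baseline / 2.0),
            ("no_template", 0.0),
        ):
            values = (background + sig) * noise(replicates)
            for v in values:
                well += 1
                rows.append(
                    {
                        "well_id": f"W{well:03d}",
                        "sample_id": truth.sample_id,
                        "target": target,
                        "role": role,
                        "fluorescence": float(v),
                    }
                )
    return QpcrPlate(wells=pd.DataFrame(rows), amplicon_bp=amplicon_bp)


# --------------------------------------------------------------------------
# cohort-level generation (study design: strain x treatment x time)
# --------------------------------------------------------------------------

#: per-group heteroplasmic loci (position, true AAF) emulating the magnitudes
#: and group placement of the observed heteroplasmy landscape: 1-30% AAF,
#: shared and group-private sites, at 14 and 112 days
DEFAULT_GROUP_HETEROPLASMIES: dict[tuple[str, str, int], list[tuple[int, float]]] = {
    ("D2", "PBS", 14): [(4405, 0.089), (11879, 0.028)],
    ("D2", "V2O5", 14): [(11879, 0.081)],
    ("B6", "PBS", 14): [(13052, 0.030)],
    ("B6", "V2O5", 14): [(14992, 0.013)],
    ("D2", "V2O5", 112): [(1054, 0.027), (15446, 0.014)],
    ("D2", "PBS", 112): [(2781, 0.103), (11879, 0.202)],
    ("B6", "V2O5", 112): [(5228, 0.072), (9214, 0.041), (9461, 0.26), (13270, 0.011)],
    ("B6", "PBS", 112): [(13052, 0.012)],
}

#: group truth for the damage assays: (lesions/10 kb mito, lesions/6.5 kb
#: nuclear, mtDNA copies). The D2 strain shows a treatment-dependent copy
#: loss and a late lesion burden; nuclear lesions are flat by design.
DEFAULT_GROUP_DAMAGE: dict[tuple[str, str, int], tuple[float, float, float]] = {
    ("B6", "PBS", 14): (0.40, 0.30, 30_000.0),
    ("B6", "V2O5", 14): (0.45, 0.30, 29_000.0),
    ("B6", "PBS", 112): (0.40, 0.30, 30_000.0),
    ("B6", "V2O5", 112): (0.50, 0.30, 28_000.0),
    ("D2", "PBS", 14): (0.50, 0.30, 43_159.0),
    ("D2", "V2O5", 14): (0.60, 0.30, 20_000.0),
    ("D2", "PBS", 112): (0.64, 0.30, 43_159.0),
    ("D2", "V2O5", 112): (2.82, 0.30, 7_064.0),
}

#: strain-private fixed variant: every D2 sample carries a major-sequence
#: difference from the (B6-style) reference at this position
DEFAULT_FIXED_VARIANT_POSITION = 9461


@dataclass
class Cohort:
    """A complete simulated study: reference, design, truths, data."""

    reference: ReferenceGenome
    design: pd.DataFrame  # sample_id, strain, treatment, time
    truths: dict[str, TruthSet]
    pileups: dict[str, pd.DataFrame]
    plates: dict[str, "QpcrPlate"]


def _pick_alt(rng: np.random.Generator, ref_base: str) -> str:
    choices = [b for b in BASES if b != ref_base]
    return choices[int(rng.integers(0, 3))]


def simulate_cohort(
    seed: int = 0,
    n_per_group: int = 4,
    mean_depth: float = 2000.0,
    error_rate: float = 0.01,
    noise_cv: float = 0.1,
    length: int = 16_569,
    n_genes: int = 13,
    group_heteroplasmies: dict | None = None,
    group_damage: dict | None = None,
    with_plates: bool = True,
) -> Cohort:
    """Simulate a full 2-strain x 2-treatment x 2-time cohort.

    Defaults reflect the study conditions the pipeline targets: n=4 samples
    per cell, >=1000x mean depth (2000x), per-base error rate 0.01,
    implanted heteroplasmies at 1-30% AAF, a strain-private fixed variant,
    and group-level lesion/copy truth with a strain-by-treatment copy-number
    deficit and a late mitochondrial lesion burden.
    """
    if n_per_group < 1:
        raise ValidationError("n_per_group must be >= 1")
    het = group_heteroplasmies if group_heteroplasmies is not None else DEFAULT_GROUP_HETEROPLASMIES
    dmg = group_damage if group_damage is not None else DEFAULT_GROUP_DAMAGE

    root = np.random.SeedSequence(seed)
    ref_seed, sample_seed = root.spawn(2)
    ref = generate_reference(length=length, n_genes=n_genes, seed=int(ref_seed.generate_state(1)[0] % 2**31))

    rng = np.random.default_rng(sample_seed.generate_state(2))
    rows = []
    truths: dict[str, TruthSet] = {}
    pileups: dict[str, pd.DataFrame] = {}
    plates: dict[str, object] = {}
    sample_seeds = iter(root.spawn(8 * n_per_group * 2))
    for strain in ("B6", "D2"):
        for treatment in ("PBS", "V2O5"):
            for time in (14, 112):
                group = (strain, treatment, time)
                lesion_mt, lesion_nuc, copies = dmg.get(group, (0.0, 0.0, 10_000.0))
                for k in range(n_per_group):
                    sample_id = f"{strain}_{treatment}_{time}d_{k + 1}"
                    rows.append(
                        {"sample_id": sample_id, "strain": strain,
                         "treatment": treatment, "time": time}
                    )
                    hets = [
                        (pos, ref.base_at(pos), _pick_alt(rng, ref.base_at(pos)), aaf)
                        for pos, aaf in het.get(group, [])
                        if pos <= ref.length
                    ]
                    fixed = []
                    if strain == "D2" and DEFAULT_FIXED_VARIANT_POSITION <= ref.length:
                        fpos = DEFAULT_FIXED_VARIANT_POSITION
                        if all(h[0] != fpos for h in hets):
                            fixed = [(fpos, ref.base_at(fpos), _pick_alt(rng, ref.base_at(fpos)))]
                    truth = TruthSet(
                        sample_id=sample_id,
                        heteroplasmies=hets,
                        fixed_variants=fixed,
                        lesion_rate_mt=lesion_mt,
                        lesion_rate_nuc=lesion_nuc,
                        copy_number=copies,
                    )
                    truths[sample_id] = truth
                    pileups[sample_id] = simulate_pileup(
                        ref, truth, mean_depth=mean_depth, error_rate=error_rate,
                        seed=int(next(sample_seeds).generate_state(1)[0] % 2**31),
                    )
                    if with_plates:
                        plates[sample_id] = simulate_qpcr_plate(
                            truth, noise_cv=noise_cv,
                            seed=int(next(sample_seeds).generate_state(1)[0] % 2**31),
                        )
    design = pd.DataFrame(rows)
    return Cohort(reference=ref, design=design, truths=truths, pileups=pileups, plates=plates)


# ------------------------------------------------------------------ writers

def write_truth(truths: dict[str, TruthSet], path: str | Path) -> None:
    rows = []
    for truth in truths.values():
        for pos, r, a, aaf in truth.all_variants():
            rows.append(
                {"sample_id": truth.sample_id, "position": pos,
                 "ref": r, "alt": a, "true_aaf": aaf}
            )
    pd.DataFrame(rows, columns=["sample_id", "position", "ref", "alt", "true_aaf"]).to_csv(
        path, sep="\t", index=False
    )


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "strain", "treatment", "time"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"design table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValidationError("design table has duplicate sample_ids")
    return df
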