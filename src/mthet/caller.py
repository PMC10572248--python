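"""Low-frequency heteroplasmy calling from strand-split allele counts.

The caller tests, per sample, every non-reference allele against the global
null that all alternate-supporting reads are PCR/sequencing errors. The
filter chain and test are conjunctive:

* depth gate — sites below ``min_depth`` (default 1000x) are not considered;
* frequency gate — the alternate allele frequency (AAF = alt reads /
  effective depth) must be at least ``min_aaf`` (default 1%);
* strand gate — the allele's plus-strand fraction must lie strictly inside
  (``strand_ratio_low``, ``strand_ratio_high``) (default (0.1, 0.9));
* significance — P(X >= alt_count) for X ~ Poisson(error_rate * depth)
  (default per-base error rate 0.01), Benjamini-Hochberg adjusted across
  all tested alternate alleles of the sample, emitted at q <= ``fdr_alpha``
  (default 0.05).

Emitted calls with AAF >= ``fixed_variant_aaf`` (default 0.8) are classified
as fixed variants — the sample's major sequence differing from the
reference — rather than heteroplasmies. Note the frequency gate alone can
never clear the test: an allele at exactly the error rate (AAF 1% at error
rate 0.01) sits at the centre of the null and is insignificant by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import BASES, ValidationError
from .pileup import DataError, site_depth
from .synthetic_data import COUNT_COLUMNS

CALL_COLUMNS = [
    "sample_id", "position", "ref_base", "alt_base", "alt_count", "depth",
    "aaf", "strand_fraction_plus", "p_value", "q_value", "status", "filter_flags",
]

GROUP_FACTORS = ["strain", "treatment", "time"]


@dataclass(frozen=True)
class CallerConfig:
    """Thresholds for the heteroplasmy filter chain (defaults above)."""

    min_depth: int = 1000
    min_aaf: float = 0.01
    strand_ratio_low: float = 0.1
    strand_ratio_high: float = 0.9
    error_rate: float = 0.01
    fdr_alpha: float = 0.05
    fixed_variant_aaf: float = 0.8

    def __post_init__(self) -> None:
        if not 0 <= self.strand_ratio_low < self.strand_ratio_high <= 1:
            raise ValidationError("require 0 <= strand_ratio_low < strand_ratio_high <= 1")
        if not 0 < self.min_aaf < self.fixed_variant_aaf <= 1:
            raise ValidationError("require 0 < min_aaf < fixed_variant_aaf <= 1")
        if not 0 < self.error_rate < 1:
            raise ValidationError("error_rate must be in (0, 1)")
        if not 0 < self.fdr_alpha < 1:
            raise ValidationError("fdr_alpha must be in (0, 1)")
        if self.min_depth < 1:
            raise ValidationError("min_depth must be >= 1")


def poisson_pvalue(
    alt_count: int | np.ndarray, depth: int | np.ndarray, error_rate: float
) -> float | np.ndarray:
    """P(X >= alt_count) for X ~ Poisson(error_rate * depth).

    Computed via the survival function, stable for rates up to 1e4 and
    beyond. ``alt_count == 0`` returns exactly 1.
    """
    alt = np.asarray(alt_count)
    dep = np.asarray(depth)
    if np.any(dep <= 0):
        raise ValidationError("depth must be > 0")
    if np.any(alt < 0) or np.any(alt > dep):
        raise ValidationError("alt_count must be in [0, depth]")
    lam = error_rate * dep
    p = stats.poisson.sf(alt - 1, lam)
    if np.isscalar(alt_count) and np.isscalar(depth):
        return float(p)
    return p


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    Suitable for large families (tens of thousands of p-values per sample).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValidationError("NaN p-value passed to bh_adjust")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def strand_fraction(plus: int, minus: int) -> float:
    """Plus-strand share plus / (plus + minus); errors on zero total."""
    total = plus + minus
    if total <= 0:
        raise DataError("strand_fraction undefined: zero total reads")
    return plus / total


def _long_format(counts: pd.DataFrame) -> pd.DataFrame:
    """One row per (site, non-reference allele) with counts and strand split."""
    depth_col = "effective_depth" if "effective_depth" in counts.columns else None
    frames = []
    for b in BASES:
        sub = counts.loc[counts["ref_base"] != b]
        if len(sub) == 0:
            continue
        plus = sub[f"{b}_plus"].to_numpy()
        minus = sub[f"{b}_minus"].to_numpy()
        depth = (
            sub[depth_col].to_numpy()
            if depth_col
            else sub[COUNT_COLUMNS].sum(axis=1).to_numpy()
        )
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sub["sample_id"].to_numpy(),
                    "position": sub["position"].to_numpy(),
                    "ref_base": sub["ref_base"].to_numpy(),
                    "alt_base": b,
                    "alt_plus": plus,
                    "alt_minus": minus,
                    "alt_count": plus + minus,
                    "depth": depth,
                    "unresolved": (
                        sub["in_homopolymer"].to_numpy().astype(bool)
                        if ("in_homopolymer" in sub.columns
                            and "homopolymer_adjusted" not in sub.columns)
                        else np.zeros(len(sub), dtype=bool)
                    ),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["sample_id", "position", "ref_base", "alt_base", "alt_plus",
                     "alt_minus", "alt_count", "depth", "unresolved"]
        )
    return pd.concat(frames, ignore_index=True)


def call_sites(
    counts: pd.DataFrame,
    config: CallerConfig | None = None,
    audit: bool = False,
) -> pd.DataFrame:
    """Run the filter chain and Poisson test; emit significant calls.

    ``counts`` is a (possibly multi-sample) pileup table, quality-filtered
    and homopolymer-adjusted. BH adjustment is per sample, across all
    alternate alleles that pass the gates. When several alleles at one site
    pass, the maximal-AAF allele is reported (ties: higher count, then
    alphabetical). With ``audit=True`` gated-out candidate alleles (AAF >=
    min_aaf/2 or any reads at a failed site) are returned too, with their
    ``filter_flags`` set; emitted calls always have empty flags.
    """
    config = config or CallerConfig()
    long = _long_format(counts)
    if len(long) == 0:
        return pd.DataFrame(columns=CALL_COLUMNS)

    with np.errstate(invalid="ignore", divide="ignore"):
        depth = long["depth"].to_numpy().astype(float)
        aaf = np.where(depth > 0, long["alt_count"] / depth, 0.0)
        sf = np.where(
            long["alt_count"] > 0,
            long["alt_plus"] / np.maximum(long["alt_count"], 1),
            np.nan,
        )
    long["aaf"] = aaf
    long["strand_fraction_plus"] = sf

    ok_depth = depth >= config.min_depth
    ok_aaf = aaf >= config.min_aaf
    ok_strand = (sf > config.strand_ratio_low) & (sf < config.strand_ratio_high)
    ok_strand = np.where(np.isnan(sf), False, ok_strand)
    resolved = ~long["unresolved"].to_numpy()
    tested = ok_depth & ok_aaf & ok_strand & resolved

    long["p_value"] = np.nan
    long["q_value"] = np.nan
    if tested.any():
        sub = long.loc[tested]
        p = poisson_pvalue(
            sub["alt_count"].to_numpy(), sub["depth"].to_numpy(), config.error_rate
        )
        long.loc[tested, "p_value"] = p
        q = np.full(len(sub), np.nan)
        for _, idx in sub.groupby("sample_id").groups.items():
            loc = sub.index.get_indexer(idx)
            q[loc] = bh_adjust(np.asarray(p)[loc])
        long.loc[tested, "q_value"] = q

    emit = tested & (long["q_value"].to_numpy() <= config.fdr_alpha)
    calls = long.loc[emit].copy()
    if len(calls):
        # one call per site: maximal AAF, then count, then alphabetical allele
        calls = calls.sort_values(
            ["sample_id", "position", "aaf", "alt_count", "alt_base"],
            ascending=[True, True, False, False, True],
        ).drop_duplicates(subset=["sample_id", "position"], keep="first")
    calls["status"] = np.where(
        calls["aaf"] >= config.fixed_variant_aaf, "fixed_variant", "heteroplasmy"
    )
    calls["filter_flags"] = ""

    if audit:
        rejected = long.loc[~emit & (long["alt_count"] > 0) & (long["aaf"] >= config.min_aaf / 2)].copy()
        flags = []
        for _, r in rejected.iterrows():
            f = []
            if r["depth"] < config.min_depth:
                f.append("low_depth")
            if r["aaf"] < config.min_aaf:
                f.append("low_aaf")
            sfp = r["strand_fraction_plus"]
            if not (config.strand_ratio_low < sfp < config.strand_ratio_high):
                f.append("strand_fail")
            if r["unresolved"]:
                f.append("homopolymer_unresolved")
            flags.append(";".join(f) if f else "not_significant")
        rejected["status"] = "rejected"
        rejected["filter_flags"] = flags
        calls = pd.concat([calls, rejected], ignore_index=True)

    calls = calls.sort_values(["sample_id", "position"]).reset_index(drop=True)
    return calls[CALL_COLUMNS]


def informative_positions(
    calls: pd.DataFrame, design: pd.DataFrame
) -> list[int]:
    """Positions whose emitted-call presence differs between design groups.

    A position is informative when at least one strain x treatment x time
    group contains a sample carrying an emitted call there while another
    group does not. Requires >= 2 groups; an expected (full-factorial)
    group with zero samples is an error.
    """
    groups = design.groupby(GROUP_FACTORS)["sample_id"].apply(set)
    levels = [design[f].unique() for f in GROUP_FACTORS]
    from itertools import product

    expected = list(product(*levels))
    if len(expected) < 2:
        raise ValidationError("informative_positions requires >= 2 groups")
    for combo in expected:
        if combo not in groups.index or not groups.loc[combo]:
            raise ValidationError(f"design group {combo} has zero samples")

    merged = calls.merge(design, on="sample_id", how="left")
    if merged[GROUP_FACTORS].isna().any().any():
        raise DataError("call with sample_id absent from the design table")
    out = []
    for position, sub in merged.groupby("position"):
        present = {g: False for g in expected}
        for combo in set(map(tuple, sub[GROUP_FACTORS].itertuples(index=False))):
            present[combo] = True
        if len(set(present.values())) > 1:
            out.append(int(position))
    return sorted(out)


def write_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["filter_flags"] = df.get("filter_flags", pd.Series(dtype=str)).fillna("")
    return df
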