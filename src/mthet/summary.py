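"""Group-level reporting: per-site combined frequencies, per-group mean
percent heteroplasmy, descriptives, and the factorial ANOVA / Tukey layer.

The study design is strain x treatment x time (2 x 2 x 2, n = 3-4 samples
per cell). Two reporting conventions are supported for a group's "combined
heteroplasmy frequency" at a site — the mean AAF over the group's carrier
samples (default) or the sum across carriers — because published group
values are not always uniquely attributable to one convention. Per-group
mean percent heteroplasmy averages each sample's mean AAF over its
heteroplasmic loci (samples with no calls contribute 0%), then averages
over the group's samples.

The ANOVA is a fixed-effects full-factorial model fitted by OLS with
Type-II sums of squares (robust to the mildly unbalanced n = 3-4 cells;
identical to Type I on balanced data). Pairwise group differences use
Tukey's HSD on the studentized range.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .caller import GROUP_FACTORS
from .genome import ValidationError
from .pileup import DataError

TABLE_COLUMNS = [
    "strain", "treatment", "time", "position", "ref_base", "gene_name",
    "combined_frequency_pct", "is_nonsynonymous",
]


def _merge_design(calls: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    merged = calls.merge(design, on="sample_id", how="left")
    if merged[GROUP_FACTORS].isna().any().any():
        missing = merged.loc[merged["strain"].isna(), "sample_id"].unique()
        raise DataError(f"samples absent from design table: {list(missing)}")
    return merged


def group_site_table(
    calls: pd.DataFrame,
    design: pd.DataFrame,
    convention: str = "mean",
) -> pd.DataFrame:
    """Per-(group, position) combined heteroplasmy frequency table.

    Uses emitted heteroplasmy calls only (fixed variants describe the major
    sequence, not heteroplasmy). ``convention`` is 'mean' (average AAF over
    carrier samples, default) or 'sum'. Rows are ordered by time then
    position.
    """
    if convention not in ("mean", "sum"):
        raise ValidationError("convention must be 'mean' or 'sum'")
    het = calls.loc[calls["status"] == "heteroplasmy"].copy()
    if len(het) == 0:
        return pd.DataFrame(columns=TABLE_COLUMNS)
    merged = _merge_design(het, design)
    agg = {"aaf": convention, "ref_base": "first"}
    if "gene_name" in merged.columns:
        agg["gene_name"] = "first"
    if "is_nonsynonymous" in merged.columns:
        agg["is_nonsynonymous"] = lambda s: bool(s.dropna().astype(bool).any())
    grouped = (
        merged.groupby([*GROUP_FACTORS, "position"], as_index=False)
        .agg(agg)
        .rename(columns={"aaf": "combined_frequency_pct"})
    )
    grouped["combined_frequency_pct"] = 100.0 * grouped["combined_frequency_pct"]
    for col in ("gene_name", "is_nonsynonymous"):
        if col not in grouped.columns:
            grouped[col] = None
    grouped = grouped.sort_values(["time", "position"]).reset_index(drop=True)
    return grouped[TABLE_COLUMNS]


@dataclass(frozen=True)
class TableDescriptives:
    n_sites: int
    n_nonsynonymous: int
    min_frequency_pct: float  # NaN when the table is empty
    max_frequency_pct: float


def table_descriptives(table: pd.DataFrame) -> TableDescriptives:
    """Row count, nonsynonymous count, and frequency extremes of a
    group-site table. An empty table yields zero counts and NaN extremes."""
    if len(table) == 0:
        return TableDescriptives(0, 0, float("nan"), float("nan"))
    nonsyn = int(table["is_nonsynonymous"].fillna(False).astype(bool).sum())
    freq = table["combined_frequency_pct"].astype(float)
    return TableDescriptives(
        n_sites=int(len(table)),
        n_nonsynonymous=nonsyn,
        min_frequency_pct=float(freq.min()),
        max_frequency_pct=float(freq.max()),
    )


def load_table1_fixture() -> pd.DataFrame:
    """The packaged worked-example group-site table (13 heteroplasmic sites
    across the strain x exposure x time groups)."""
    with importlib.resources.files("mthet.data").joinpath("table1_fixture.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def sample_mean_heteroplasmy(calls: pd.DataFrame, design: pd.DataFrame) -> pd.Series:
    """Per-sample mean AAF (percent) across that sample's heteroplasmic
    loci; samples with no heteroplasmy calls contribute 0%."""
    het = calls.loc[calls["status"] == "heteroplasmy"]
    per_sample = 100.0 * het.groupby("sample_id")["aaf"].mean()
    return per_sample.reindex(design["sample_id"], fill_value=0.0)


def mean_percent_heteroplasmy(
    calls: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Group mean +/- SE of per-sample mean percent heteroplasmy."""
    values = sample_mean_heteroplasmy(calls, design)
    df = design.copy()
    df["mean_pct"] = values.to_numpy()
    out = (
        df.groupby(GROUP_FACTORS)["mean_pct"]
        .agg(n="size", mean_pct="mean", sd="std")
        .reset_index()
    )
    if (out["n"] == 0).any():
        raise ValidationError("group with zero samples")
    out["se_pct"] = out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")


def _values_frame(values, design: pd.DataFrame) -> pd.DataFrame:
    """Join per-sample measurements (Series indexed by sample_id, or a
    DataFrame with sample_id/value columns) with the design table."""
    if isinstance(values, pd.Series):
        vf = values.rename("value").rename_axis("sample_id").reset_index()
    else:
        vf = values.rename(columns={values.columns[-1]: "value"})[["sample_id", "value"]]
    merged = design.merge(vf, on="sample_id", how="inner")
    if len(merged) == 0:
        raise DataError("no overlap between values and design samples")
    return merged


def three_way_anova(
    values, design: pd.DataFrame, factors: Sequence[str] = tuple(GROUP_FACTORS)
) -> pd.DataFrame:
    """Fixed-effects full-factorial ANOVA (3 mains, 3 two-way, 1 three-way).

    Type-II sums of squares; p-values from the F distribution. Returns a
    tidy table (term, sum_sq, df, F, p_value). A factor with a single
    observed level is an error naming the factor.
    """
    df = _values_frame(values, design)
    for f in factors:
        if df[f].nunique() < 2:
            raise ValidationError(f"factor {f!r} has fewer than 2 levels")
    formula = "value ~ " + " * ".join(f"C({f})" for f in factors)
    model = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.reset_index().rename(
        columns={"index": "term", "F": "F_value", "PR(>F)": "p_value"}
    )
    table["term"] = (
        table["term"].str.replace(r"C\((\w+)\)", r"\1", regex=True)
    )
    return table


def tukey_hsd(
    values, design: pd.DataFrame, term: str | Sequence[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons for the groups defined by ``term``
    (one factor name or a combination). Requires >= 2 samples per group."""
    factors = [term] if isinstance(term, str) else list(term)
    df = _values_frame(values, design)
    groups = df[factors].astype(str).agg("-".join, axis=1)
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValidationError("tukey_hsd requires >= 2 groups")
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise ValidationError(f"singleton group(s) for Tukey HSD: {bad}")
    res = pairwise_tukeyhsd(endog=df["value"].to_numpy(), groups=groups.to_numpy(), alpha=alpha)
    frame = pd.DataFrame(
        data=res._results_table.data[1:], columns=res._results_table.data[0]
    ).rename(columns={"p-adj": "p_adj", "meandiff": "mean_diff"})
    frame["p_adj"] = res.pvalues  # full precision, not the rounded table
    return frame
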