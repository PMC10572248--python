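"""The Poisson error-model caller: test statistics, gates, and calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mthet import (
    CallerConfig,
    DataError,
    ValidationError,
    bh_adjust,
    call_sites,
    homopolymer_adjusted_depth,
    informative_positions,
    poisson_pvalue,
    simulate_pileup,
    strand_fraction,
)
from conftest import make_truth


def _bh_oracle(p):
    """Independent step-up definition: q_(i) = min_{j>=i} (m * p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestPoissonPvalue:
    def test_zero_count_has_probability_one(self):
        assert poisson_pvalue(0, 1000, 0.01) == 1.0

    def test_matches_pmf_partial_sum_to_12_digits(self):
        # brute-force: P(X>=25) = 1 - sum_{k<25} e^-10 10^k / k!
        lam, terms = 10.0, []
        t = math.exp(-lam)
        for k in range(25):
            terms.append(t)
            t *= lam / (k + 1)
        expected = 1.0 - math.fsum(terms)
        assert poisson_pvalue(25, 1000, 0.01) == pytest.approx(expected, rel=1e-12)

    def test_aaf_at_the_error_rate_is_not_significant(self):
        # 1% AAF at error rate 0.01 sits at the null's centre
        assert poisson_pvalue(10, 1000, 0.01) > 0.5

    @given(st.integers(0, 50), st.integers(1, 30))
    @settings(max_examples=40, deadline=None)
    def test_monotone_decreasing_in_alt_count(self, k, extra):
        depth = 2000
        assert poisson_pvalue(k, depth, 0.01) >= poisson_pvalue(k + extra, depth, 0.01)

    def test_preconditions(self):
        with pytest.raises(ValidationError):
            poisson_pvalue(5, 0, 0.01)
        with pytest.raises(ValidationError):
            poisson_pvalue(11, 10, 0.01)


class TestBhAdjust:
    def test_single_pvalue_is_identity(self):
        assert bh_adjust([0.01]) == pytest.approx([0.01])

    def test_step_up_worked_example(self):
        got = bh_adjust([0.001, 0.01, 0.03, 0.04])
        assert got == pytest.approx([0.004, 0.02, 0.04, 0.04])

    def test_ties_are_scale_invariant(self):
        assert bh_adjust([0.5] * 100) == pytest.approx([0.5] * 100)

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, float("nan")])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_matches_independent_step_up_oracle(self, p):
        assert np.allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)


class TestStrandFraction:
    @pytest.mark.parametrize(
        "plus, minus, frac, passes",
        [
            (50, 50, 0.5, True),
            (10, 90, 0.10, False),  # bound is exclusive
            (95, 5, 0.95, False),
            (11, 89, 0.11, True),
        ],
    )
    def test_fraction_and_exclusive_bounds(self, plus, minus, frac, passes):
        cfg = CallerConfig()
        got = strand_fraction(plus, minus)
        assert got == pytest.approx(frac)
        assert (cfg.strand_ratio_low < got < cfg.strand_ratio_high) is passes

    def test_zero_total_is_an_error(self):
        with pytest.raises(DataError):
            strand_fraction(0, 0)


class TestCallerConfig:
    def test_invalid_configs_rejected_before_computation(self):
        with pytest.raises(ValidationError):
            CallerConfig(strand_ratio_low=0.9, strand_ratio_high=0.1)
        with pytest.raises(ValidationError):
            CallerConfig(min_aaf=0.9, fixed_variant_aaf=0.8)
        with pytest.raises(ValidationError):
            CallerConfig(error_rate=0.0)
        with pytest.raises(ValidationError):
            CallerConfig(fdr_alpha=1.0)


class TestCallSites:
    def test_heteroplasmy_recovered_within_3se(self, small_ref):
        aaf, depth = 0.10, 2000
        truth = make_truth(small_ref, [(901, aaf)])
        pile = simulate_pileup(small_ref, truth, mean_depth=depth, error_rate=0.01, seed=21)
        calls = call_sites(homopolymer_adjusted_depth(pile, small_ref))
        row = calls[calls["position"] == 901]
        assert len(row) == 1
        assert row["status"].iloc[0] == "heteroplasmy"
        se = np.sqrt(aaf * (1 - aaf) / depth)
        assert abs(row["aaf"].iloc[0] - aaf) < 3 * se

    def test_major_variant_classified_fixed(self, small_ref):
        truth = make_truth(small_ref, [], fixed=[801], fixed_variant_aaf=0.95)
        pile = simulate_pileup(small_ref, truth, mean_depth=2000, error_rate=0.01, seed=22)
        calls = call_sites(homopolymer_adjusted_depth(pile, small_ref))
        row = calls[calls["position"] == 801]
        assert row["status"].iloc[0] == "fixed_variant"

    def test_emitted_calls_satisfy_every_gate(self, small_ref):
        cfg = CallerConfig()
        truth = make_truth(small_ref, [(301, 0.05), (601, 0.26)], fixed=[1001])
        pile = simulate_pileup(small_ref, truth, mean_depth=2000, error_rate=0.01, seed=23)
        calls = call_sites(homopolymer_adjusted_depth(pile, small_ref), cfg)
        assert len(calls) >= 3
        assert (calls["depth"] >= cfg.min_depth).all()
        assert (calls["aaf"] >= cfg.min_aaf).all()
        assert ((calls["strand_fraction_plus"] > cfg.strand_ratio_low)
                & (calls["strand_fraction_plus"] < cfg.strand_ratio_high)).all()
        assert (calls["q_value"] <= cfg.fdr_alpha).all()
        assert (calls["filter_flags"] == "").all()
        assert np.allclose(calls["aaf"], calls["alt_count"] / calls["depth"])

    def test_strand_biased_site_rejected(self, small_ref):
        truth = make_truth(small_ref, [(451, 0.10)])
        pile = simulate_pileup(
            small_ref, truth, mean_depth=2000, error_rate=0.01,
            strand_bias={451: 0.05}, seed=24,
        )
        calls = call_sites(homopolymer_adjusted_depth(pile, small_ref), audit=True)
        row = calls[calls["position"] == 451]
        assert (row["status"] != "heteroplasmy").all()
        assert row["filter_flags"].str.contains("strand_fail").any()

    def test_low_depth_sites_not_considered(self, small_ref):
        truth = make_truth(small_ref, [(333, 0.20)])
        pile = simulate_pileup(small_ref, truth, mean_depth=500, error_rate=0.01, seed=25)
        calls = call_sites(homopolymer_adjusted_depth(pile, small_ref))
        assert len(calls) == 0

    def test_unresolved_homopolymer_sites_are_not_called(self, small_ref):
        a, _, _ = small_ref.homopolymer_runs[0]
        truth = make_truth(small_ref, [(a, 0.2)])
        pile = simulate_pileup(small_ref, truth, mean_depth=2000, error_rate=0.0, seed=26)
        # without running the adjustment, flagged sites must not be emitted
        calls = call_sites(pile.drop(columns=[]), audit=True)
        row = calls[calls["position"] == a]
        assert (row["status"] == "rejected").all()
        assert row["filter_flags"].str.contains("homopolymer_unresolved").any()


class TestInformativePositions:
    def _calls(self, entries):
        return pd.DataFrame(
            [{"sample_id": s, "position": p, "status": "heteroplasmy"} for s, p in entries]
        )

    def test_shared_calls_are_uninformative(self, design_2x2x2):
        entries = [(s, 100) for s in design_2x2x2["sample_id"]]
        assert informative_positions(self._calls(entries), design_2x2x2) == []

    def test_group_private_call_is_informative(self, design_2x2x2):
        carriers = design_2x2x2.query(
            "strain == 'D2' and treatment == 'V2O5' and time == 112"
        )["sample_id"]
        entries = [(s, 42) for s in carriers]
        assert informative_positions(self._calls(entries), design_2x2x2) == [42]

    def test_matches_permutation_oracle(self, design_2x2x2):
        rng = np.random.default_rng(7)
        samples = design_2x2x2["sample_id"].to_list()
        counts = []
        for _ in range(30):
            entries = [
                (s, p)
                for p in (10, 20, 30)
                for s in rng.choice(samples, size=rng.integers(1, 8), replace=False)
            ]
            calls = self._calls(entries)
            perm = design_2x2x2.copy()
            perm["sample_id"] = rng.permutation(samples)
            got = informative_positions(calls, perm)
            # oracle: brute-force group presence recount under the same labels
            merged = calls.merge(perm, on="sample_id")
            expected = []
            n_groups = 8
            for p, sub in merged.groupby("position"):
                present = len(sub.groupby(["strain", "treatment", "time"]))
                if 0 < present < n_groups:
                    expected.append(int(p))
            assert got == sorted(expected)
            counts.append(len(got))
        assert max(counts) > 0

    def test_empty_design_group_is_an_error(self, design_2x2x2):
        broken = design_2x2x2[~(
            (design_2x2x2["strain"] == "B6")
            & (design_2x2x2["treatment"] == "PBS")
            & (design_2x2x2["time"] == 14)
        )]
        calls = self._calls([(broken["sample_id"].iloc[0], 5)])
        with pytest.raises(ValidationError, match="zero samples"):
            informative_positions(calls, broken)
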