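"""Call-pair statistics, MDCA scores and caller-sequence patterns."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_calls, stationary_gps
from vocalmap import sequence_analysis as sa
from vocalmap import synthetic_data as sd


def mdca_oracle(pairs: pd.DataFrame, cats: list[str] | None = None) -> pd.DataFrame:
    """Exact binomial tail scores by direct pmf summation (math.comb)."""
    if cats is None:
        cats = sorted(set(pairs["first_category"]) | set(pairs["second_category"]))
    n = len(pairs)
    counts = {(a, b): 0 for a in cats for b in cats}
    for a, b in zip(pairs["first_category"], pairs["second_category"]):
        counts[(a, b)] += 1
    n_a = {a: sum(counts[(a, b)] for b in cats) for a in cats}
    n_b = {b: sum(counts[(a, b)] for a in cats) for b in cats}

    def pmf(k, m, p):
        return math.comb(m, k) * p**k * (1 - p) ** (m - k)

    out = pd.DataFrame(np.nan, index=cats, columns=cats)
    for a in cats:
        if n_a[a] == 0:
            continue
        for b in cats:
            p_b = n_b[b] / n
            k, m = counts[(a, b)], n_a[a]
            if k >= m * p_b:
                tail = sum(pmf(i, m, p_b) for i in range(k, m + 1))
                sign = 1.0
            else:
                tail = sum(pmf(i, m, p_b) for i in range(0, k + 1))
                sign = -1.0
            tail = min(max(tail, 1e-300), 1.0)
            out.loc[a, b] = sign * -math.log10(tail) + 0.0
    return out


def pairs_from_counts(counts: dict[tuple[str, str], int]) -> pd.DataFrame:
    rows = []
    for (a, b), k in counts.items():
        for _ in range(k):
            rows.append({"first_category": a, "second_category": b,
                         "first_individual": "x", "second_individual": "y",
                         "gap_s": 0.5, "same_caller": False,
                         "first_event": "e", "second_event": "f"})
    return pd.DataFrame(rows)


class TestIntervalThreshold:
    def test_degenerate_distribution(self):
        calls = make_calls([(f"e{i}", "a", i * 1.0, i * 1.0 + 0.1, "cc")
                            for i in range(5)])
        assert sa.interval_threshold(calls) == pytest.approx(1.0)

    def test_type7_quantile_against_hand_computation(self):
        # 100 calls: 90 gaps of 0.5 s then 9 gaps of 5.0 s (99 gaps total).
        # Type-7 90th percentile: h = 0.9*98 = 88.2 -> between sorted gaps
        # 89 and 90 (1-based), both 0.5 -> 0.5 exactly.
        gaps = [0.5] * 90 + [5.0] * 9
        t = np.concatenate([[0.0], np.cumsum(gaps)])
        calls = make_calls([(f"e{i}", "a", ti, ti + 0.01, "cc")
                            for i, ti in enumerate(t)])
        got = sa.interval_threshold(calls)
        assert got == pytest.approx(np.quantile(np.array(gaps), 0.9))
        assert got == pytest.approx(0.5)

    def test_override_wins(self):
        calls = make_calls([("e0", "a", 0, 0.1, "cc"), ("e1", "a", 9, 9.1, "cc")])
        assert sa.interval_threshold(calls, override=2.31) == 2.31

    def test_fewer_than_two_calls_errors(self):
        with pytest.raises(ValueError):
            sa.interval_threshold(make_calls([("e0", "a", 0, 0.1, "cc")]))


class TestBuildPairs:
    def test_monologue_all_self(self):
        calls = make_calls([(f"e{i}", "a", i * 0.5, i * 0.5 + 0.1, "cc")
                            for i in range(6)])
        pairs = sa.build_pairs(calls, 2.31)
        assert len(pairs) == 5 and pairs["same_caller"].all()

    def test_alternation_all_nonself(self):
        calls = make_calls([(f"e{i}", "ab"[i % 2], i * 0.5, i * 0.5 + 0.1, "cc")
                            for i in range(6)])
        pairs = sa.build_pairs(calls, 2.31)
        assert len(pairs) == 5 and not pairs["same_caller"].any()

    def test_long_gap_breaks_pairing(self):
        # 6 calls, one onset gap of 3 s (> 2.31) -> exactly 4 pairs
        t = [0.0, 0.5, 1.0, 4.0, 4.5, 5.0]
        calls = make_calls([(f"e{i}", "a", ti, ti + 0.1, "cc")
                            for i, ti in enumerate(t)])
        pairs = sa.build_pairs(calls, 2.31)
        assert len(pairs) == 4
        assert pairs["gap_s"].max() <= 2.31

    def test_subset_filters(self):
        calls = make_calls([(f"e{i}", "ab"[i % 2], i * 0.5, i * 0.5 + 0.1, "cc")
                            for i in range(6)])
        assert len(sa.build_pairs(calls, 2.31, "self")) == 0
        assert len(sa.build_pairs(calls, 2.31, "nonself")) == 5


class TestMdca:
    def test_saturated_margin_scores_zero(self):
        pairs = pairs_from_counts({("cc", "cc"): 50})
        tm = sa.mdca(pairs)
        assert tm.pbin.loc["cc", "cc"] == 0.0

    def test_hand_table_matches_exact_oracle(self):
        counts = {("cc", "cc"): 12, ("cc", "sn"): 2, ("cc", "al"): 1,
                  ("sn", "cc"): 3, ("sn", "sn"): 8, ("sn", "al"): 0,
                  ("al", "cc"): 1, ("al", "sn"): 1, ("al", "al"): 6}
        pairs = pairs_from_counts(counts)
        got = sa.mdca(pairs).pbin
        want = mdca_oracle(pairs)
        pd.testing.assert_frame_equal(got, want, atol=1e-9, rtol=0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=8),
                    min_size=9, max_size=9).filter(lambda c: 0 < sum(c) <= 50))
    def test_random_small_tables_match_oracle(self, cells):
        cats = ["agg", "cc", "sn"]
        counts = {(a, b): cells[i * 3 + j]
                  for i, a in enumerate(cats) for j, b in enumerate(cats)}
        pairs = pairs_from_counts(counts)
        got = sa.mdca(pairs, categories=cats).pbin
        want = mdca_oracle(pairs, cats)
        pd.testing.assert_frame_equal(got, want, atol=1e-9, rtol=0)

    def test_empty_rows_are_nan(self):
        pairs = pairs_from_counts({("cc", "sn"): 5})
        tm = sa.mdca(pairs, categories=["cc", "sn", "al"])
        assert tm.pbin.loc["al"].isna().all()
        assert tm.pbin.loc["sn"].isna().all()  # 'sn' never initiates here

    def test_independent_pairs_rarely_significant(self):
        # second category independent of first: per cell, |pbin| crosses the
        # p<0.05 anchor (1.3) at most at the nominal rate, and the p<0.001
        # anchor (3) essentially never
        rng = np.random.default_rng(42)
        cats = np.array(["cc", "sn", "soc"])
        n_exceed = n_cells = n_strong = 0
        n_sets = 40
        for _ in range(n_sets):
            first = rng.choice(cats, size=10_000, p=[0.6, 0.3, 0.1])
            second = rng.choice(cats, size=10_000, p=[0.6, 0.3, 0.1])
            pairs = pd.DataFrame({"first_category": first, "second_category": second})
            pbin = np.abs(sa.mdca(pairs).pbin.to_numpy())
            n_exceed += int((pbin >= 1.3).sum())
            n_strong += int((pbin >= 3.0).sum())
            n_cells += int(np.isfinite(pbin).sum())
        assert n_exceed / n_cells <= 0.06
        assert n_strong == 0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            sa.mdca(pairs_from_counts({}))


class TestNonselfProportions:
    def test_identical_rows_give_zero_statistic(self):
        pairs = pairs_from_counts({("cc", "cc"): 0})
        rows = []
        for cat in ("cc", "sn"):
            for same in (True, False):
                for _ in range(30):
                    rows.append({"first_category": cat, "second_category": cat,
                                 "same_caller": same})
        res = sa.nonself_proportions(pd.DataFrame(rows))
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_2x2_matches_textbook_pearson(self):
        # table [[30, 70], [60, 40]]: chi2 = sum (O-E)^2/E = 18.1818...
        rows = []
        for cat, (n_self, n_nonself) in {"cc": (30, 70), "sn": (60, 40)}.items():
            rows += [{"first_category": cat, "second_category": cat, "same_caller": True}
                     ] * n_self
            rows += [{"first_category": cat, "second_category": cat, "same_caller": False}
                     ] * n_nonself
        res = sa.nonself_proportions(pd.DataFrame(rows))
        # hand oracle: N=200, row sums 100/100, col sums 90/110
        expected = sum((o - e) ** 2 / e for o, e in
                       zip([30, 70, 60, 40], [45, 55, 45, 55]))
        assert res.chi2 == pytest.approx(expected, rel=1e-12)
        assert res.df == 1

    def test_boundary_proportions(self):
        # alternating-caller cc block, then (well separated) a sn monologue
        alternation = make_calls(
            [(f"e{i}", "ab"[i % 2], i * 0.5, i * 0.5 + 0.1, "cc") for i in range(40)]
            + [(f"s{i}", "c", 1000 + i * 0.5, 1000 + i * 0.5 + 0.1, "sn")
               for i in range(40)])
        pairs = sa.build_pairs(alternation, 2.31)
        res = sa.nonself_proportions(pairs)
        tbl = res.table.set_index("category")
        assert tbl.loc["cc", "prop_nonself"] == pytest.approx(1.0)
        assert tbl.loc["sn", "prop_nonself"] == pytest.approx(0.0)
        # self + non-self partition every homogeneous pair
        assert (tbl["n_self"] + tbl["n_nonself"]).tolist() == [39, 39]

    def test_excluded_categories_dropped(self):
        rows = []
        for cat in ("cc", "sn", "mo", "ld"):
            rows += [{"first_category": cat, "second_category": cat, "same_caller": True}
                     ] * 10
            rows += [{"first_category": cat, "second_category": cat, "same_caller": False}
                     ] * 10
        res = sa.nonself_proportions(pd.DataFrame(rows))
        assert set(res.table["category"]) == {"cc", "sn"}


class TestTriplePatterns:
    GPS = {"a": (0.0, 0.0), "b": (3.0, 0.0), "c": (0.0, 4.0), "far": (15.0, 0.0)}

    def test_monologue_gives_AA_patterns_only(self):
        calls = make_calls([(f"e{i}", "a", i * 0.5, i * 0.5 + 0.1, "cc")
                            for i in range(5)])
        trajs = stationary_gps(self.GPS)
        res = {r.pattern: r.observed_prop for r in sa.triple_patterns(calls, trajs, 2.31)}
        # chains from calls 1..3 are A-A-A; call 4's chain is A-A-stop
        assert res["A-A-A"] == pytest.approx(3 / 4)
        assert res["A-A-stop"] == pytest.approx(1 / 4)
        assert sum(res.values()) == pytest.approx(1.0)

    def test_rotation_dominated_by_ABC(self):
        calls = make_calls([(f"e{i}", "abc"[i % 3], i * 0.5, i * 0.5 + 0.1, "cc")
                            for i in range(12)])
        res = {r.pattern: r.observed_prop
               for r in sa.triple_patterns(calls, stationary_gps(self.GPS), 2.31)}
        assert res["A-B-C"] == max(res.values())

    def test_out_of_radius_caller_breaks_chain(self):
        # b replies to a; 'far' (15 m away) would be third but breaks the chain
        calls = make_calls([
            ("e0", "a", 0.0, 0.1, "cc"), ("e1", "b", 0.5, 0.6, "cc"),
            ("e2", "far", 1.0, 1.1, "cc"), ("e3", "c", 10.0, 10.1, "cc"),
            ("e4", "a", 10.5, 10.6, "cc"), ("e5", "c", 11.0, 11.1, "cc"),
        ])
        counts = sa._pattern_counts(calls, stationary_gps(self.GPS), 2.31, 10.0)
        # hand enumeration: e0->e1 then far breaks => A-B-stop
        #   e1 starts: e2 far from b? dist(far,b)=12 => breaks, length 1, dropped
        #   e2 ('far') within its own radius: e3 is 9.0+ s later => no chain
        #   e3->e4->e5: c,a,c = A-B-A;  e4 starts: a,c then end => A-B-stop
        assert counts == {"A-A-stop": 0, "A-A-A": 0, "A-A-B": 0,
                          "A-B-stop": 2, "A-B-A": 1, "A-B-B": 0, "A-B-C": 0}

    def test_proportions_sum_to_one(self, exchange_sim):
        thr = sa.interval_threshold(exchange_sim.calls)
        res = sa.triple_patterns(exchange_sim.calls, exchange_sim.gps, thr)
        assert sum(r.observed_prop for r in res) == pytest.approx(1.0)


class TestPermutationNull:
    def test_fixed_seed_is_bit_identical(self, exchange_sim):
        thr = sa.interval_threshold(exchange_sim.calls)
        kw = dict(category="cc", n_perm=20, seed=5)
        a = sa.permutation_null_patterns(exchange_sim.calls, exchange_sim.gps, thr, **kw)
        b = sa.permutation_null_patterns(exchange_sim.calls, exchange_sim.gps, thr, **kw)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.null_props, rb.null_props)
            assert ra.p_over == rb.p_over

    def test_permutation_preserves_marginals(self, exchange_sim):
        # each permuted dataset keeps per-individual call counts; proportions
        # sum to 1 in every null replicate
        thr = sa.interval_threshold(exchange_sim.calls)
        res = sa.permutation_null_patterns(
            exchange_sim.calls, exchange_sim.gps, thr, category="cc",
            n_perm=10, seed=1)
        null = np.stack([r.null_props for r in res])
        assert np.allclose(null.sum(axis=0), 1.0)

    def test_exchange_data_shows_caller_transitions(self, exchange_sim):
        thr = sa.interval_threshold(exchange_sim.calls)
        res = sa.permutation_null_patterns(
            exchange_sim.calls, exchange_sim.gps, thr, category="cc",
            n_perm=99, seed=2)
        by = {r.pattern: r for r in res}
        # A-B-C over-represented, A-A-A under-represented vs the null
        assert by["A-B-C"].p_over <= 0.01
        assert by["A-A-A"].p_under <= 0.05

    def test_nonself_monotone_in_response_probability(self):
        # overall call rate held matched across p_resp (baseline scaled by
        # 1 - p_resp) so the comparison isolates the exchange structure
        med = []
        for p_resp in (0.0, 0.45, 0.9):
            vals = []
            for seed in range(3):
                cfg = sd.SimConfig(
                    n_individuals=5, session_s=600.0, seed=200 + seed,
                    exchange=sd.ExchangeConfig(p_resp=p_resp,
                                               base_rate=0.1 * (1 - p_resp)))
                sim = sd.simulate_session(cfg, "exchange")
                pairs = sa.build_pairs(sim.calls, sa.interval_threshold(sim.calls))
                vals.append(1.0 - pairs["same_caller"].mean())
            med.append(np.median(vals))
        assert med[0] <= med[1] <= med[2]
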