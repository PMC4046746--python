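"""TPM, Audic-Claverie test, BH correction, DEG calls, phase classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgetag import (
    audic_claverie_p,
    bh_fdr,
    call_degs,
    classify_phase,
    de_table,
    log2_ratio,
    tpm_normalize,
)
from dgetag.mapping import GeneCounts
from dgetag.stats import format_ratio

from oracles import ac_pvalue_exact


class TestTpm:
    def test_zero_count(self):
        assert tpm_normalize(np.array([0]), 1000)[0] == 0.0

    def test_direct_arithmetic(self):
        # 100 tags in a 4,362,459-tag library -> 22.92 per million
        assert tpm_normalize(np.array([100]), 4_362_459)[0] == pytest.approx(22.92, abs=0.005)

    def test_sum_equals_mapped_fraction(self):
        counts = np.array([10, 0, 25, 5])
        total = 1000
        assert tpm_normalize(counts, total).sum() == pytest.approx(
            1e6 * counts.sum() / total
        )

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            tpm_normalize(np.array([1]), 0)
        with pytest.raises(ValueError):
            tpm_normalize(np.array([-1]), 10)


class TestAudicClaverie:
    def test_symmetry_at_equal_counts(self):
        # both tails include the mode, each >= 1/2, doubled and capped
        assert audic_claverie_p(7, 7, 10_000, 10_000) == pytest.approx(1.0, rel=1e-12)

    @settings(max_examples=60, derandomize=True)
    @given(
        st.integers(0, 300), st.integers(0, 300),
        st.integers(1000, 2_000_000), st.integers(1000, 2_000_000),
    )
    def test_exchange_symmetry_up_to_tie_terms(self, x, y, N1, N2):
        # swapping (x, N1) <-> (y, N2) moves the observed value's pmf mass
        # between the tails, so the doubled-tail p is symmetric only up to
        # twice the tie terms (exact at x = y, N1 = N2)
        from dgetag.stats import audic_claverie_pmf

        p1 = audic_claverie_p(x, y, N1, N2)
        p2 = audic_claverie_p(y, x, N2, N1)
        tie = float(audic_claverie_pmf(x, y, N1, N2)) + float(
            audic_claverie_pmf(y, x, N2, N1)
        )
        assert abs(p1 - p2) <= 2 * tie + 1e-9

    def test_against_exact_oracle_spot(self):
        p = audic_claverie_p(0, 20, 10**6, 10**6)
        exact = float(ac_pvalue_exact(0, 20, 10**6, 10**6))
        assert p == pytest.approx(exact, rel=1e-10)

    @pytest.mark.parametrize(
        "x,y,N1,N2",
        [
            (0, 0, 100, 100),
            (3, 15, 10_000, 12_000),
            (50, 48, 500_000, 400_000),
            (120, 60, 10**6, 10**6),
            (1, 0, 4_362_459, 4_395_028),
        ],
    )
    def test_against_exact_oracle_cases(self, x, y, N1, N2):
        assert audic_claverie_p(x, y, N1, N2) == pytest.approx(
            float(ac_pvalue_exact(x, y, N1, N2)), rel=1e-10
        )

    def test_large_counts_stable(self):
        # counts at the 1e5 scale: finite, in (0,1], monotone in |y - x|
        p_near = audic_claverie_p(100_000, 100_500, 5_000_000, 5_000_000)
        p_far = audic_claverie_p(100_000, 110_000, 5_000_000, 5_000_000)
        assert 0.0 <= p_far < p_near <= 1.0

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            audic_claverie_p(-1, 0, 10, 10)
        with pytest.raises(ValueError):
            audic_claverie_p(0, 0, 0, 10)


class TestBH:
    def test_single_p(self):
        assert bh_fdr([0.02]) == pytest.approx([0.02])

    def test_all_equal(self):
        assert bh_fdr([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_hand_computation(self):
        # m * p(i) / i then cumulative minimum from the largest rank
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_order_preserving_and_monotone(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= p) | np.isclose(q, p)).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        p = rng.uniform(size=500) ** 2
        assert bh_fdr(p) == pytest.approx(
            multipletests(p, method="fdr_bh")[1], rel=1e-12
        )

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestLog2Ratio:
    def test_equal_tpm_is_zero(self):
        assert log2_ratio(50, 25, 1_000_000, 500_000) == pytest.approx(0.0)

    def test_both_zero_undefined(self):
        v = log2_ratio(0, 0, 1000, 1000)
        assert np.isnan(v)
        assert format_ratio(v) == "-"

    def test_zero_floor_magnitude(self):
        # 11,500 tags vs a floored zero at equal depth: log2(11500) = 13.49
        assert log2_ratio(11_500, 0, 10**6, 10**6) == pytest.approx(13.49, abs=0.005)


class TestCallDegs:
    def make(self, rows):
        return pd.DataFrame(
            [
                {"gene_id": f"g{i}", "fdr": fdr, "log2_ratio": lr}
                for i, (fdr, lr) in enumerate(rows)
            ]
        )

    def test_threshold_semantics(self):
        table = self.make(
            [
                (0.0005, 1.2),   # passes both -> up
                (0.01, 3.0),     # fails FDR
                (0.0001, 0.5),   # fails ratio
                (0.001, 1.0),    # exactly on both thresholds -> up (<=, >=)
                (0.0005, -1.2),  # down
                (0.0005, np.nan),  # undefined ratio: never significant
            ]
        )
        up, down = call_degs(table)
        assert up == ["g0", "g3"]
        assert down == ["g4"]

    def test_custom_thresholds(self):
        table = self.make([(0.04, 0.8)])
        up, down = call_degs(table, fdr_max=0.05, min_abs_log2=0.5)
        assert up == ["g0"]


class TestDeTable:
    def test_columns_and_consistency(self):
        idx = ["a", "b", "c", "d"]
        ctrl = GeneCounts("c", pd.Series([100, 0, 50, 0], index=idx), 100_000)
        treat = GeneCounts("t", pd.Series([800, 40, 52, 0], index=idx), 100_000)
        t = de_table(ctrl, treat)
        assert list(t["gene_id"]) == idx
        assert t["tpm1"].tolist() == pytest.approx((t["x"] / 100_000 * 1e6).tolist())
        # gene a: 8-fold, huge counts -> significant up
        row = t.set_index("gene_id").loc["a"]
        assert row["significant"] and row["log2_ratio"] == pytest.approx(3.0)
        # gene d: zero in both -> undefined, not significant
        row_d = t.set_index("gene_id").loc["d"]
        assert np.isnan(row_d["log2_ratio"]) and not row_d["significant"]

    def test_mismatched_indexes_rejected(self):
        a = GeneCounts("a", pd.Series([1], index=["x"]), 10)
        b = GeneCounts("b", pd.Series([1], index=["y"]), 10)
        with pytest.raises(ValueError):
            de_table(a, b)


class TestPhase:
    def test_earliest_timepoint_wins(self):
        calls = {c.gene_id: c.phase for c in classify_phase(
            up_1h={"a"}, up_5h={"a", "b"}, up_24h={"a", "b", "c"},
        )}
        assert calls == {"a": "phase1", "b": "phase2", "c": "phase3"}

    def test_never_up_is_none(self):
        (call,) = classify_phase(set(), set(), set(), genes=["g"])
        assert call.phase == "none" and call.up_flags == (False, False, False)

    def test_up_only_at_24h_is_late_response(self):
        (call,) = classify_phase(set(), set(), {"g"})
        assert call.phase == "phase3"
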