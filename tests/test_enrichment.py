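import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import nbinom

from ventflow.enrichment import (
    audic_claverie_pvalue,
    fold_change,
    group_compare,
    subtract_background,
    test_otu,
    two_proportion_test,
)
from ventflow.errors import ConfigurationError, VentflowError
from ventflow.io_model import OtuTable, SampleMetadata

from oracles import ac_pvalue_exact, two_proportion_exact, welch_t_exact


class TestAudicClaverie:
    def test_no_counts_no_evidence(self):
        assert audic_claverie_pvalue(0, 1000, 0, 1000) == 1.0

    @pytest.mark.parametrize("x,y", [(0, 3), (5, 0), (12, 40), (50, 49)])
    def test_equal_depth_pairs_match_oracle(self, x, y):
        # the conditional test is not exchangeable in (x, y); both orientations
        # must instead agree with the exact rational oracle
        N = 1000
        for a, bb in ((x, y), (y, x)):
            got = audic_claverie_pvalue(a, N, bb, N)
            assert got == pytest.approx(ac_pvalue_exact(a, N, bb, N), abs=1e-10)

    def test_matches_exact_rational_oracle_worked_example(self):
        p = audic_claverie_pvalue(5, 1000, 0, 1000)
        assert p == pytest.approx(ac_pvalue_exact(5, 1000, 0, 1000), abs=1e-10)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        x=st.integers(0, 200),
        y=st.integers(0, 200),
        N1=st.integers(200, 100_000),
        N2=st.integers(200, 100_000),
        tail=st.sampled_from(["two_sided", "enriched_in_1", "enriched_in_2"]),
    )
    def test_matches_exact_rational_oracle(self, x, y, N1, N2, tail):
        got = audic_claverie_pvalue(x, N1, y, N2, tail)
        want = ac_pvalue_exact(x, N1, y, N2, tail)
        assert got == pytest.approx(want, abs=1e-10)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(x=st.integers(0, 150), y=st.integers(0, 150),
           N1=st.integers(500, 50_000), N2=st.integers(500, 50_000))
    def test_conditional_is_negative_binomial(self, x, y, N1, N2):
        """Independent library route: the conditional law is NB(x+1, N1/(N1+N2))."""
        p_success = N1 / (N1 + N2)
        lower = nbinom.cdf(y, x + 1, p_success)
        upper = nbinom.sf(y - 1, x + 1, p_success)
        want = min(1.0, 2.0 * min(lower, upper))
        assert audic_claverie_pvalue(x, N1, y, N2) == pytest.approx(want, abs=1e-9)

    def test_enriched_tail_monotone_in_x(self):
        N1 = N2 = 10_000
        y = 5
        ps = [audic_claverie_pvalue(x, N1, y, N2, "enriched_in_1") for x in range(0, 120)]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            audic_claverie_pvalue(11, 10, 0, 10)
        with pytest.raises(ValueError):
            audic_claverie_pvalue(1, 0, 0, 10)


class TestTwoProportion:
    def test_equal_proportions_give_null(self):
        z, p = two_proportion_test(10, 100, 100, 1000)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_antisymmetry(self):
        z1, p1 = two_proportion_test(30, 1000, 10, 1000)
        z2, p2 = two_proportion_test(10, 1000, 30, 1000)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    @pytest.mark.parametrize("x1,N1,x2,N2", [
        (30, 1000, 10, 1000), (1, 500, 0, 700), (250, 2000, 100, 3000),
    ])
    def test_matches_closed_form_oracle(self, x1, N1, x2, N2):
        z, p = two_proportion_test(x1, N1, x2, N2)
        z0, p0 = two_proportion_exact(x1, N1, x2, N2)
        assert z == pytest.approx(z0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)

    def test_degenerate_pooled_proportion(self):
        assert two_proportion_test(0, 100, 0, 100) == (0.0, 1.0)
        assert two_proportion_test(100, 100, 50, 50) == (0.0, 1.0)


class TestFoldChange:
    def test_basic_ratio(self):
        assert fold_change(20, 1000, 10, 1000) == pytest.approx(2.0)

    def test_conventions(self):
        assert fold_change(3, 100, 0, 100) == np.inf
        assert fold_change(0, 100, 5, 100) == 0.0
        assert fold_change(0, 100, 0, 100) == 1.0


class TestTestOtu:
    def test_clearly_enriched(self):
        r = test_otu("o", 100, 10_000, 1, 10_000)
        assert r.enriched and r.fold == pytest.approx(100.0)
        assert r.p_ac < 0.01 and r.p_z < 0.01

    def test_fold_threshold_is_strict(self):
        r = test_otu("o", 20, 10_000, 10, 10_000)
        assert r.fold == pytest.approx(2.0)
        assert not r.enriched

    def test_depleted_direction_never_enriched(self):
        r = test_otu("o", 3, 10_000, 30, 10_000)
        assert not r.enriched and r.fold < 1

    def test_rule_variants(self):
        # marginal case where AC is significant but z barely not (or vice versa)
        base = dict(x=100, N1=10_000, y=1, N2=10_000)
        for rule in ("both", "either", "ac_only", "z_only"):
            assert test_otu("o", **base, rule=rule).enriched

    def test_untestable_double_zero(self):
        r = test_otu("o", 0, 100, 0, 100)
        assert not r.enriched and r.p_ac == 1.0


def _planted_tables(rng, n_background=500, n_planted=50, depth=30_000, fold=8.0):
    """One region: off-axis from a lognormal background, one vent sample with
    planted OTUs at a fixed fold; planted expected vent count >= 30 reads."""
    base = rng.lognormal(0, 1, size=n_background)
    base /= base.sum()
    planted_idx = rng.choice(n_background, size=n_planted, replace=False)
    floor = 30.0 / depth  # expected vent count >= 30 reads
    vent = base.copy()
    vent[planted_idx] = np.maximum(base[planted_idx] * fold, floor)
    vent /= vent.sum()
    otus = [f"Otu{i}" for i in range(n_background)]
    counts = np.vstack([
        rng.multinomial(depth, vent),
        rng.multinomial(depth, base),
    ])
    table = OtuTable(counts, ["V1", "OA"], otus)
    meta = SampleMetadata(pd.DataFrame({
        "sample_id": ["V1", "OA"],
        "region": ["EPR", "EPR"],
        "habitat": ["diffuse_flow", "off_axis"],
    }))
    return table, meta, {otus[i] for i in planted_idx}


class TestSubtractBackground:
    def test_planted_recovery_and_false_positives(self, rng):
        table, meta, planted = _planted_tables(rng)
        vsets, frame = subtract_background(table, meta)
        enriched = vsets["EPR"].per_sample["V1"]
        recall = len(enriched & planted) / len(planted)
        assert recall >= 0.95
        # false positives bounded by ~alpha * number tested (99% binomial bound)
        n_tested = len(frame)
        fp = len(enriched - planted)
        bound = 0.01 * n_tested + 3 * np.sqrt(0.01 * n_tested)
        assert fp <= bound

    def test_identical_composition_yields_empty_set(self, rng):
        base = rng.dirichlet(np.ones(50))
        counts = np.vstack([rng.multinomial(5000, base), rng.multinomial(5000, base)])
        table = OtuTable(counts, ["V1", "OA"], [f"Otu{i}" for i in range(50)])
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": ["V1", "OA"], "region": ["EPR"] * 2,
            "habitat": ["diffuse_flow", "off_axis"],
        }))
        vsets, _ = subtract_background(table, meta)
        # a handful of chance calls are possible but the set should be ~empty
        assert len(vsets["EPR"].per_sample["V1"]) <= 2

    def test_percent_of_library_bookkeeping(self):
        # OTU_A is the only enriched OTU: 900/3000 vent vs 1/3000 off axis
        table = OtuTable(
            [[900, 700, 700, 700], [1, 1000, 1000, 999]],
            ["V1", "OA"], ["OtuA", "OtuB", "OtuC", "OtuD"],
        )
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": ["V1", "OA"], "region": ["EPR"] * 2,
            "habitat": ["diffuse_flow", "off_axis"],
        }))
        vsets, _ = subtract_background(table, meta)
        vset = vsets["EPR"]
        assert vset.per_sample["V1"] == {"OtuA"}
        assert vset.per_sample_seq_count["V1"] == 900
        assert vset.per_sample_percent["V1"] == pytest.approx(30.0)

    def test_invariant_under_column_and_sample_permutation(self, rng):
        table, meta, _ = _planted_tables(rng, n_background=80, n_planted=10)
        vsets1, _ = subtract_background(table, meta)
        perm = rng.permutation(table.otu_ids)
        table2 = OtuTable(table.data[list(perm)], drop_empty_otus=False)
        vsets2, _ = subtract_background(table2, meta)
        assert vsets1["EPR"].per_sample == vsets2["EPR"].per_sample

    def test_missing_off_axis_is_configuration_error(self, rng):
        table = OtuTable([[5, 5]], ["V1"], ["OtuA", "OtuB"])
        meta = SampleMetadata(pd.DataFrame({
            "sample_id": ["V1"], "region": ["EPR"], "habitat": ["diffuse_flow"],
        }))
        with pytest.raises(ConfigurationError):
            subtract_background(table, meta)


class TestGroupCompare:
    def _meta(self, epr_vals, guay_vals):
        rows = []
        for i, v in enumerate(epr_vals):
            rows.append({"sample_id": f"E{i}", "region": "EPR",
                         "habitat": "diffuse_flow", "Co": v})
        for i, v in enumerate(guay_vals):
            rows.append({"sample_id": f"G{i}", "region": "GUAYMAS",
                         "habitat": "diffuse_flow", "Co": v})
        return SampleMetadata(pd.DataFrame(rows))

    def test_identical_groups_null(self):
        meta = self._meta([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        t, df, p = group_compare(meta, "Co")
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_welch_oracle(self):
        a, b = [1.0, 2.0, 3.0], [11.0, 12.0, 13.0]
        meta = self._meta(a, b)
        t, df, p = group_compare(meta, "Co")
        t0, df0 = welch_t_exact(a, b)
        assert t == pytest.approx(t0, abs=1e-10)
        assert df == pytest.approx(df0, abs=1e-10)
        from scipy.stats import t as tdist
        assert p == pytest.approx(2 * tdist.sf(abs(t0), df0), abs=1e-10)

    def test_single_observation_rejected(self):
        meta = self._meta([1.0], [1.0, 2.0, 3.0])
        with pytest.raises(VentflowError):
            group_compare(meta, "Co")
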