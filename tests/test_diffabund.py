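"""Differential abundance: size factors, dispersion, exact test, BH, table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from riboscreen.counting import CountMatrix
from riboscreen.diffabund import (
    _exact_test_sums,
    bh_adjust,
    differential_table,
    estimate_dispersion,
    nb_exact_test,
    spike_size_factors,
)
from riboscreen.simulate import SimConfig, make_truth, simulate_counts


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_conditional_p(sum_a, n_a, sum_b, n_b, phi, mu=7.3):
    """Brute-force conditional exact test via explicit pmf products.

    Sums scipy pmf terms over every split of the pooled total; the choice
    of mu is arbitrary (it cancels in the conditional).
    """
    total = sum_a + sum_b
    k = np.arange(total + 1)
    if phi == 0:
        fa = sps.poisson.pmf(k, n_a * mu)
        fb = sps.poisson.pmf(total - k, n_b * mu)
    else:
        ra, rb = n_a / phi, n_b / phi
        pa = ra / (ra + n_a * mu)
        pb = rb / (rb + n_b * mu)
        fa = sps.nbinom.pmf(k, ra, pa)
        fb = sps.nbinom.pmf(total - k, rb, pb)
    w = fa * fb
    w = w / w.sum()
    return w[w <= w[sum_a] * (1 + 1e-9)].sum()


def oracle_bh(p):
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = min(prev, 1.0)
    return q


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

class TestSpikeSizeFactors:
    def _matrix(self, spike):
        idx = ["lib|AAA", "lib|CCC", "spike|sp"]
        data = {f"s{i}": [100, 200, v] for i, v in enumerate(spike)}
        return CountMatrix(pd.DataFrame(data, index=idx))

    def test_equal_spike_gives_unit_factors(self):
        f = spike_size_factors(self._matrix([50, 50, 50]))
        assert np.allclose(f, 1.0)

    def test_doubled_spike_halves_normalized_counts(self):
        m = self._matrix([50, 100])
        f = spike_size_factors(m)
        norm = m.counts / f
        assert norm.loc["lib|AAA", "s1"] == pytest.approx(
            norm.loc["lib|AAA", "s0"] / 2
        )

    def test_geometric_mean_is_one(self):
        f = spike_size_factors(self._matrix([13, 99, 255, 7]))
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0)

    def test_zero_spike_names_sample(self):
        with pytest.raises(ValueError, match="s1"):
            spike_size_factors(self._matrix([50, 0]))


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

class TestDispersion:
    def _estimate(self, phi, n_variants=1000, n=8, mu=50.0, seed=0):
        rng = np.random.default_rng(seed)
        if phi == 0:
            counts = rng.poisson(mu, size=(n_variants, 2 * n))
        else:
            r = 1 / phi
            counts = rng.negative_binomial(r, r / (r + mu), size=(n_variants, 2 * n))
        df = pd.DataFrame(counts, columns=[f"s{i}" for i in range(2 * n)])
        groups = pd.Series(["a"] * n + ["b"] * n, index=df.columns)
        return estimate_dispersion(df, groups)

    def test_poisson_gives_near_zero_dispersion(self):
        model = self._estimate(phi=0)
        assert model.phi_common < 0.005

    def test_nb_dispersion_recovered(self):
        model = self._estimate(phi=0.1)
        assert 0.07 <= model.phi_common <= 0.13  # within +-30%

    def test_shrinkage_limit(self):
        df = pd.DataFrame(
            [[10, 12, 9, 11, 30, 29, 31, 28]],
            columns=[f"s{i}" for i in range(8)],
        )
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=df.columns)
        model = estimate_dispersion(df, groups, n_prior=1e9)
        assert model.phi.iloc[0] == pytest.approx(model.phi_common, rel=1e-6)

    def test_no_replication_warns_and_floors(self):
        df = pd.DataFrame([[10, 20]], columns=["s0", "s1"])
        groups = pd.Series(["a", "b"], index=df.columns)
        with pytest.warns(UserWarning, match="dispersion"):
            model = estimate_dispersion(df, groups)
        assert model.phi_common == pytest.approx(1e-8)


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

class TestExactTest:
    def test_identical_group_sums_give_p_one(self):
        assert nb_exact_test([5, 5, 5], [5, 5, 5], phi=0.1) == 1.0

    @pytest.mark.parametrize("phi", [0.0, 0.2])
    @pytest.mark.parametrize("n_a,n_b", [(8, 8), (3, 5)])
    def test_matches_bruteforce_oracle_small_totals(self, phi, n_a, n_b):
        for total in range(0, 51, 5):
            for sum_a in range(total + 1):
                p = _exact_test_sums(sum_a, n_a, total - sum_a, n_b, phi)
                expected = oracle_conditional_p(sum_a, n_a, total - sum_a, n_b, phi)
                assert p == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_symmetric_under_group_swap(self):
        p1 = _exact_test_sums(40, 8, 10, 8, 0.1)
        p2 = _exact_test_sums(10, 8, 40, 8, 0.1)
        assert p1 == pytest.approx(p2)

    def test_p_in_unit_interval(self):
        for sum_a, sum_b in [(0, 0), (0, 100), (1000, 10)]:
            p = _exact_test_sums(sum_a, 8, sum_b, 8, 0.05)
            assert 0 < p <= 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test([-1, 2], [3, 4], phi=0.1)

    def test_uniform_conservative_under_null(self):
        """Fraction of null p-values below alpha stays near/below alpha."""
        rng = np.random.default_rng(7)
        phi, n, mu = 0.1, 8, 40.0
        r = 1 / phi
        draws = rng.negative_binomial(r, r / (r + mu), size=(2000, 2 * n))
        pvals = np.array(
            [
                _exact_test_sums(row[:n].sum(), n, row[n:].sum(), n, phi)
                for row in draws
            ]
        )
        for alpha in (0.01, 0.05):
            frac = (pvals < alpha).mean()
            assert frac <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / len(pvals))


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

class TestBH:
    def test_single_p(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            p = rng.uniform(1e-8, 1.0, size=rng.integers(1, 60))
            assert np.allclose(bh_adjust(p), oracle_bh(p))

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=30))
    @settings(max_examples=100, derandomize=True)
    def test_order_preserving_and_bounded(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# full table
# ---------------------------------------------------------------------------

def _screen(toy_design, samplesheet_factory, seed=5, n_switches=0, **cfg_kw):
    cfg = SimConfig(
        doses=cfg_kw.pop("doses", (0.0, 300.0)),
        replicates=cfg_kw.pop("replicates", 4),
        reads_per_sample=cfg_kw.pop("reads_per_sample", 20_000),
        phi=0.05,
        seed=seed,
        **cfg_kw,
    )
    truth = make_truth(toy_design, n_switches=n_switches, seed=seed)
    counts = simulate_counts(truth, cfg)
    return counts, cfg.samples(), truth


class TestDifferentialTable:
    def test_null_screen_flat(self, toy_design, samplesheet_factory):
        counts, sheet, _ = _screen(toy_design, samplesheet_factory, n_switches=0)
        table = differential_table(counts, sheet)
        assert table.table["log2fc"].abs().median() < 0.3
        assert (table.table["fdr"] > 0.2).mean() > 0.9

    def test_deterministic(self, toy_design, samplesheet_factory):
        counts, sheet, _ = _screen(toy_design, samplesheet_factory)
        t1 = differential_table(counts, sheet).table
        t2 = differential_table(counts, sheet).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_label_shuffle_within_group_invariant(self, toy_design, samplesheet_factory):
        counts, sheet, _ = _screen(toy_design, samplesheet_factory)
        shuffled = sheet.copy()
        g0 = shuffled["dose_uM"] == 0.0
        shuffled.loc[g0, "sample"] = shuffled.loc[g0, "sample"].to_numpy()[::-1]
        t1 = differential_table(counts, sheet).table
        t2 = differential_table(counts, shuffled).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_log2fc_antisymmetric_under_contrast_swap(
        self, toy_design, samplesheet_factory
    ):
        counts, sheet, _ = _screen(toy_design, samplesheet_factory)
        swapped = sheet.copy()
        swapped["dose_uM"] = swapped["dose_uM"].map({0.0: 300.0, 300.0: 0.0})
        t1 = differential_table(counts, sheet).table.set_index("variant")
        t2 = differential_table(counts, swapped).table.set_index("variant")
        assert np.allclose(t1["log2fc"], -t2["log2fc"])
        assert np.allclose(t1["pvalue"], t2["pvalue"])

    def test_missing_control_group_rejected(self, toy_design, samplesheet_factory):
        counts, sheet, _ = _screen(toy_design, samplesheet_factory)
        sheet = sheet.copy()
        sheet["dose_uM"] = sheet["dose_uM"].replace({0.0: 100.0})
        with pytest.raises(ValueError, match="dose-0|control"):
            differential_table(counts, sheet)

    def test_planted_off_switches_rank_top_by_fdr(self):
        """20 planted 2.8-fold OFF-switches dominate the FDR ranking."""
        from riboscreen.design import builtin_design

        design = builtin_design("gua-hdv")
        cfg = SimConfig(
            doses=(0.0, 300.0), replicates=8, reads_per_sample=200_000,
            phi=0.05, seed=17,
        )
        truth = make_truth(
            design, n_switches=20, delta_range=(1.5, 1.5), direction="off", seed=17
        )
        counts = simulate_counts(truth, cfg)
        table = differential_table(counts, cfg.samples())
        ranked = table.contrast(300.0).sort_values(["fdr", "pvalue"]).head(30)
        truths_in_top30 = set(ranked["variant"]) & set(truth.switches["variant"])
        assert len(truths_in_top30) >= 18  # >= 90% of the 20 planted
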