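"""Dispersion statistic, permutation null and empirical p-value behaviour."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_freq_table
from vadpop.differentiation import (
    empirical_p,
    freq_matrix,
    panel_statistic,
    per_snp_dispersion,
    permutation_null,
    run_differentiation,
)
from vadpop.simulate import FrequencyModelConfig, gen_background_frequencies

ALFA_RS10882272 = (0.620, 0.617, 0.383, 0.106)


def sd_oracle(values):
    """Sample SD by direct arithmetic, independent of numpy reductions."""
    m = sum(values) / len(values)
    return math.sqrt(sum((v - m) ** 2 for v in values) / (len(values) - 1))


class TestDispersion:
    def test_constant_vector_is_zero(self):
        assert per_snp_dispersion([0.3, 0.3, 0.3, 0.3]) == 0.0

    def test_alfa_rs10882272_matches_arithmetic_oracle(self):
        s = per_snp_dispersion(ALFA_RS10882272)
        assert s == pytest.approx(sd_oracle(ALFA_RS10882272), abs=1e-12)
        assert s == pytest.approx(0.2437, abs=5e-4)

    def test_population_convention(self):
        v = ALFA_RS10882272
        s_pop = per_snp_dispersion(v, convention="population")
        assert s_pop == pytest.approx(sd_oracle(v) * math.sqrt(3 / 4), abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=8)
    )
    def test_allele_complement_invariance(self, freqs):
        f = np.array(freqs)
        assert per_snp_dispersion(f) == pytest.approx(
            per_snp_dispersion(1 - f), abs=1e-12
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            per_snp_dispersion([0.5])
        with pytest.raises(ValueError):
            per_snp_dispersion([0.5, 1.2])
        with pytest.raises(ValueError):
            per_snp_dispersion([0.3, 0.4], convention="bogus")


class TestPanelStatistic:
    def test_singleton_panel(self):
        table = make_freq_table([ALFA_RS10882272], snp_ids=["rs10882272"])
        s = panel_statistic(table, ["rs10882272"])
        assert s == pytest.approx(per_snp_dispersion(ALFA_RS10882272), abs=1e-15)

    def test_mean_of_two(self):
        table = make_freq_table([[0.5, 0.5], [0.4, 0.4 + 0.2 * math.sqrt(2)]])
        assert panel_statistic(table, ["snp0", "snp1"]) == pytest.approx(0.1, abs=1e-12)

    def test_missing_ids_listed(self):
        table = make_freq_table([[0.5, 0.5]])
        with pytest.raises(KeyError, match="nope"):
            panel_statistic(table, ["snp0", "nope"])

    def test_matches_monte_carlo_expectation(self):
        # panel at F=0.2, K=5: mean SD close to the model's MC expectation
        cfg = FrequencyModelConfig(
            n_groups=5, fst_background=0.2, n_background=39, seed=17
        )
        table = gen_background_frequencies(cfg)
        s = panel_statistic(table, list(table["snp_id"]))
        rng = np.random.default_rng(99)  # independent MC oracle
        p = rng.uniform(0.05, 0.95, 20_000)
        a, b = p * 4, (1 - p) * 4  # (1-F)/F = 4 at F = 0.2
        draws = rng.beta(a[:, None], b[:, None], (20_000, 5))
        expected = draws.std(axis=1, ddof=1).mean()
        assert abs(s - expected) / expected < 0.15


class TestPermutationNull:
    def test_background_of_exactly_m(self, small_background):
        bg = small_background.head(10)
        s = panel_statistic(bg, list(bg["snp_id"]))
        null = permutation_null(bg, m=10, B=50, seed=0)
        assert np.allclose(null, s, atol=1e-12)

    def test_identical_rows_give_constant_null(self):
        table = make_freq_table([[0.2, 0.8, 0.5]] * 30)
        null = permutation_null(table, m=5, B=100, seed=1)
        assert np.allclose(null, null[0], atol=1e-12)

    def test_null_mean_near_background_mean(self, small_background):
        disp = per_snp_dispersion(freq_matrix(small_background))
        null = permutation_null(small_background, m=10, B=1000, seed=3)
        # each draw has expectation disp.mean(); only MC error remains
        se = null.std(ddof=1) / math.sqrt(1000)
        assert abs(null.mean() - disp.mean()) < 3 * se
        # reproducible under seed
        assert np.array_equal(null, permutation_null(small_background, 10, 1000, 3))

    def test_oversized_panel_rejected(self, small_background):
        with pytest.raises(ValueError):
            permutation_null(small_background, m=10_000, B=10, seed=0)

    def test_exact_enumeration_oracle(self):
        # full C(12,3) enumeration vs Monte-Carlo null: mean and variance
        rng = np.random.default_rng(5)
        table = make_freq_table(rng.uniform(0, 1, (12, 4)))
        disp = per_snp_dispersion(freq_matrix(table))
        exact = np.array(
            [disp[list(c)].mean() for c in combinations(range(12), 3)]
        )
        B = 4000
        null = permutation_null(table, m=3, B=B, seed=11)
        se_mean = exact.std(ddof=1) / math.sqrt(B)
        assert abs(null.mean() - exact.mean()) < 3 * se_mean
        centred4 = ((exact - exact.mean()) ** 2).var()
        se_var = math.sqrt(centred4 / B)
        assert abs(null.var() - exact.var()) < 3 * se_var


class TestEmpiricalP:
    def test_extreme_observation(self):
        null = np.linspace(0, 1, 1000)
        assert empirical_p(1.5, null) == 0.0
        assert empirical_p(1.5, null, "add_one") == pytest.approx(1 / 1001)
        assert empirical_p(-1.0, null) == 1.0

    def test_median_observation(self):
        null = np.arange(1, 1001) / 1000
        assert empirical_p(0.5, null) == pytest.approx(0.5, abs=0.01)

    def test_ties_count_toward_tail(self):
        assert empirical_p(0.5, [0.5, 0.5, 0.1, 0.9]) == 0.75

    def test_p_uniform_under_exchangeability(self):
        # S_obs drawn by the same scheme as the null -> p uniform on its grid
        rng = np.random.default_rng(42)
        B, reps = 100, 500
        draws = rng.normal(size=(reps, B + 1))
        ps = np.array([empirical_p(d[0], d[1:]) for d in draws])
        # exact discrete CDF: P(p <= k/B) = (k+1)/(B+1)
        ks = np.arange(B + 1)
        ecdf = np.array([(ps <= k / B).mean() for k in ks])
        cdf = (ks + 1) / (B + 1)
        band = math.sqrt(math.log(2 / 0.01) / (2 * reps))
        assert np.abs(ecdf - cdf).max() < band

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            empirical_p(0.5, [])


class TestRunDifferentiation:
    def test_null_panel_rarely_significant(self, small_background):
        hits = 0
        reps = 100
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            panel_ids = rng.choice(small_background["snp_id"], 10, replace=False)
            panel = small_background[small_background["snp_id"].isin(panel_ids)]
            res = run_differentiation(small_background, panel, B=200, seed=seed)
            hits += res.p_value <= 0.05
        assert hits / reps <= 0.10

    def test_deterministic_rerun(self, small_background):
        panel = small_background.head(10)
        a = run_differentiation(small_background, panel, B=100, seed=8)
        b = run_differentiation(small_background, panel, B=100, seed=8)
        assert a.p_value == b.p_value
        assert np.array_equal(a.null_values, b.null_values)

    def test_panel_excluded_from_background(self, small_background):
        panel = small_background.head(10)
        res = run_differentiation(small_background, panel, B=50, seed=0)
        assert res.excluded_from_background == 10
        assert res.background_size == len(small_background) - 10

    def test_group_mismatch_names_groups(self, small_background):
        panel = small_background.head(5).rename(columns={"freq_AFR": "freq_XXX"})
        with pytest.raises(ValueError, match="XXX"):
            run_differentiation(small_background, panel, B=10, seed=0)

    def test_complement_invariance_of_statistic_and_p(self, small_background):
        panel = small_background.head(10)
        flipped_bg = small_background.copy()
        flipped_panel = panel.copy()
        fcols = [c for c in panel.columns if c.startswith("freq_")]
        # flip the tabulated allele for a subset of SNPs in both tables
        flip_rows = flipped_bg.index[::3]
        flipped_bg.loc[flip_rows, fcols] = 1 - flipped_bg.loc[flip_rows, fcols]
        flipped_panel.loc[flipped_panel.index[::2], fcols] = (
            1 - flipped_panel.loc[flipped_panel.index[::2], fcols]
        )
        a = run_differentiation(small_background, panel, B=200, seed=4)
        b = run_differentiation(flipped_bg, flipped_panel, B=200, seed=4)
        assert b.panel_statistic == pytest.approx(a.panel_statistic, abs=1e-12)
        assert b.p_value == pytest.approx(a.p_value, abs=1e-12)

    def test_monotonic_in_panel_fst(self):
        # median S_obs never decreases as fst_panel grows
        medians = []
        for fst in (0.05, 0.1, 0.2, 0.3):
            stats_ = []
            for seed in range(20):
                cfg = FrequencyModelConfig(
                    n_groups=5, fst_background=0.05, fst_panel=fst,
                    n_background=60, panel_size=39, seed=seed,
                )
                from vadpop.simulate import gen_panel_frequencies

                panel = gen_panel_frequencies(cfg)
                stats_.append(
                    panel_statistic(panel, list(panel["snp_id"]))
                )
            medians.append(np.median(stats_))
        assert all(b >= a for a, b in zip(medians, medians[1:]))

    def test_maf_matched_null_absorbs_frequency_confound(self):
        # a common-variant panel over a mixed rare/common background looks
        # inflated against the plain null; matching on the folded frequency
        # spectrum removes that confound
        from vadpop.simulate import gen_background_frequencies

        def bn_table(p_range, n, seed, prefix):
            cfg = FrequencyModelConfig(
                n_groups=5, fst_background=0.1, n_background=n, seed=seed,
                ancestral_freq_range=p_range, panel_size=1,
            )
            t = gen_background_frequencies(cfg)
            t["snp_id"] = [f"{prefix}_{i}" for i in range(n)]
            return t

        for seed in range(5):
            bg = pd.concat(
                [
                    bn_table((0.05, 0.15), 200, seed, "low"),
                    bn_table((0.4, 0.6), 200, seed + 100, "high"),
                ],
                ignore_index=True,
            )
            panel = bn_table((0.4, 0.6), 20, seed + 200, "panel")
            un = run_differentiation(bg, panel, B=500, seed=seed + 300)
            ma = run_differentiation(
                bg, panel, B=500, seed=seed + 300, maf_match_bins=5
            )
            assert ma.p_value > un.p_value

    def test_matched_null_insufficient_bin_raises(self, small_background):
        from vadpop.differentiation import matched_permutation_null

        # demand more SNPs per bin than the background holds
        with pytest.raises(ValueError, match="bin"):
            matched_permutation_null(
                small_background.head(40), small_background, B=10, seed=0, bins=10
            )

    def test_null_frame_export(self, small_background):
        res = run_differentiation(small_background, small_background.head(5), B=50, seed=1)
        frame = res.null_frame()
        assert (frame["kind"] == "null").sum() == 50
        assert (frame["kind"] == "observed").sum() == 1
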