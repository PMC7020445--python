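"""Statistical utilities: rank-test arithmetic against hand-derived and
permutation oracles, normality-test calibration, box summaries, and the
two plate computations with their invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fluopop import (
    box_summary,
    fold_change_ddct,
    jarque_bera,
    kruskal_wallis,
    simulate_qpcr,
    simulate_viability,
    viability_percent,
)


class TestKruskalWallis:
    def test_hand_derived_example(self):
        # ranks 1..6, R1=6, R2=15: H = 12/(6*7)*(36/3+225/3) - 21 = 3.857...
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_all_values_identical_degenerate(self):
        assert kruskal_wallis([[5, 5], [5, 5, 5]]) == (0.0, 1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.integers(0, 6, size=rng.integers(3, 9)) for _ in range(3)]
        if len(np.unique(np.concatenate(groups))) == 1:
            pytest.skip("degenerate draw")
        h, p = kruskal_wallis(groups)
        h_sp, p_sp = stats.kruskal(*groups)
        assert h == pytest.approx(h_sp, rel=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_permutation_p_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(3, 9, size=2)
        groups = [list(rng.normal(size=s)) for s in sizes]
        h, p_impl = kruskal_wallis(
            groups, p_method="permutation", n_permutations=100_000, seed=123
        )
        # independent oracle: literal re-shuffling of the pooled sample
        pooled = np.concatenate([np.asarray(g, float) for g in groups])
        n_draws = 20_000
        rng_o = np.random.default_rng(seed + 999)
        count = 0
        for _ in range(n_draws):
            perm = rng_o.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            h_perm, _ = stats.kruskal(*parts)
            if h_perm >= h - 1e-12:
                count += 1
        p_oracle = (count + 1) / (n_draws + 1)
        mc_err = 4 * np.sqrt(p_oracle * (1 - p_oracle) / n_draws)
        assert abs(p_impl - p_oracle) <= max(mc_err, 0.02)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(size=5), rng.normal(0.5, size=6)]
        h1, p1 = kruskal_wallis(groups)
        h2, p2 = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2], []])


class TestJarqueBera:
    def test_zero_skew_kurtosis_three_gives_zero(self):
        # 8 zeros with +/-1 and +/-a chosen so sample kurtosis is exactly 3:
        # values {0 x8, +b x2, -b x2} give K = 1/(2p) with p = 2/12
        sample = [0.0] * 8 + [1.0, 1.0, -1.0, -1.0]
        jb, p = jarque_bera(sample)
        assert jb == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        jb, p = jarque_bera(x)
        res = stats.jarque_bera(x)
        assert jb == pytest.approx(res.statistic, rel=1e-9)
        assert p == pytest.approx(res.pvalue, rel=1e-9)

    def test_calibrated_on_normal_samples(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=5000)
            _, p = jarque_bera(x)
            hits += p > 0.05
        assert hits >= 90

    def test_rejects_heavy_tails(self):
        hits = 0
        for seed in range(40):
            x = np.random.default_rng(seed).standard_t(df=2, size=500)
            _, p = jarque_bera(x)
            hits += p < 0.05
        assert hits >= 38  # >= 95%

    def test_small_or_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            jarque_bera([1, 2, 3])
        with pytest.raises(ValueError):
            jarque_bera([2.0] * 20)


class TestBoxSummary:
    def test_one_to_eleven(self):
        s = box_summary(range(1, 12))
        assert s.median == 6.0
        assert s.q1 == 3.5
        assert s.q3 == 8.5
        assert s.p10 == 2.0
        assert s.p90 == 10.0

    def test_constant_sample(self):
        s = box_summary([4.2] * 7)
        assert s.median == s.q1 == s.q3 == s.p10 == s.p90 == 4.2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        shift=st.floats(min_value=-100, max_value=100, allow_nan=False),
        seed=st.integers(min_value=0, max_value=1000),
    )
    def test_translation_equivariance(self, shift, seed):
        x = np.random.default_rng(seed).normal(size=30)
        a, b = box_summary(x), box_summary(x + shift)
        for field in ("median", "q1", "q3", "p10", "p90"):
            assert getattr(b, field) == pytest.approx(getattr(a, field) + shift, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            box_summary([])


class TestFoldChange:
    def _table(self, dct_control, dct_treated, ref_ct=17.0):
        rows = []
        for cond, dcts in (("control", dct_control), ("hypoxia", dct_treated)):
            for i, d in enumerate(dcts, start=1):
                rows.append({"gene": "REF", "condition": cond, "replicate": i, "ct": ref_ct})
                rows.append({"gene": "TGT", "condition": cond, "replicate": i,
                             "ct": ref_ct + d})
        return pd.DataFrame(rows)

    def test_equal_dct_gives_fold_one(self):
        ct = self._table([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        r = fold_change_ddct(ct, "TGT", "REF", "control", "hypoxia")
        assert r.fold == pytest.approx(1.0)
        assert r.sem == 0.0

    def test_ddct_minus_one_gives_fold_two(self):
        ct = self._table([5.0, 5.0, 5.0], [4.0, 4.0, 4.0])
        r = fold_change_ddct(ct, "TGT", "REF", "control", "hypoxia")
        assert r.fold == pytest.approx(2.0)
        assert r.sem == 0.0

    @pytest.mark.parametrize("fold", [1.0, 2.0, 6.89])
    def test_simulator_round_trip_noiseless(self, fold):
        ct = simulate_qpcr({"G": fold}, n_replicates=3, ct_noise_sd=0.0)
        r = fold_change_ddct(ct, "G", "ACTB", "control", "hypoxia")
        assert abs(r.fold - fold) < 1e-9

    def test_invariant_to_per_replicate_ct_shift(self):
        ct = self._table([5.0, 5.2, 4.9], [3.8, 4.1, 4.0])
        r0 = fold_change_ddct(ct, "TGT", "REF", "control", "hypoxia")
        shifted = ct.copy()
        # plate-position offset: shift every Ct of one replicate
        sel = (shifted["condition"] == "hypoxia") & (shifted["replicate"] == 2)
        shifted.loc[sel, "ct"] += 3.3
        r1 = fold_change_ddct(shifted, "TGT", "REF", "control", "hypoxia")
        assert r1.fold == pytest.approx(r0.fold, rel=1e-12)

    def test_missing_reference_pairing_named(self):
        ct = self._table([5.0, 5.0], [5.0, 5.0])
        ct = ct.drop(ct[(ct.gene == "REF") & (ct.condition == "hypoxia")
                        & (ct.replicate == 2)].index)
        with pytest.raises(ValueError, match="replicate"):
            fold_change_ddct(ct, "TGT", "REF", "control", "hypoxia")


class TestViability:
    def test_control_level_is_100(self):
        plate = pd.DataFrame(
            [
                {"well": "b", "dose_um": 0, "absorbance": 0.1, "role": "blank"},
                {"well": "c", "dose_um": 0, "absorbance": 1.1, "role": "control"},
                {"well": "t", "dose_um": 50, "absorbance": 1.1, "role": "treated"},
            ]
        )
        out = viability_percent(plate)
        assert out["percent"].iloc[0] == pytest.approx(100.0)

    def test_half_signal_is_50(self):
        plate = pd.DataFrame(
            [
                {"well": "b", "dose_um": 0, "absorbance": 0.2, "role": "blank"},
                {"well": "c", "dose_um": 0, "absorbance": 1.2, "role": "control"},
                {"well": "t", "dose_um": 50, "absorbance": 0.7, "role": "treated"},
            ]
        )
        assert viability_percent(plate)["percent"].iloc[0] == pytest.approx(50.0)

    def test_simulator_round_trip(self):
        plate = simulate_viability({150.0: 62.33}, noise_sd=0.0)
        out = viability_percent(plate)
        assert abs(out["percent"].iloc[0] - 62.33) < 1e-9

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        gain=st.floats(min_value=0.1, max_value=10, allow_nan=False),
        offset=st.floats(min_value=-0.5, max_value=0.5, allow_nan=False),
    )
    def test_invariant_to_affine_rescaling(self, gain, offset):
        plate = simulate_viability({100.0: 80.0, 150.0: 62.33}, noise_sd=0.01, seed=5)
        out0 = viability_percent(plate)
        scaled = plate.copy()
        scaled["absorbance"] = scaled["absorbance"] * gain + offset
        out1 = viability_percent(scaled)
        assert np.allclose(out1["percent"], out0["percent"], atol=1e-8)

    def test_control_not_above_blank_rejected(self):
        plate = pd.DataFrame(
            [
                {"well": "b", "dose_um": 0, "absorbance": 1.0, "role": "blank"},
                {"well": "c", "dose_um": 0, "absorbance": 0.9, "role": "control"},
                {"well": "t", "dose_um": 50, "absorbance": 0.5, "role": "treated"},
            ]
        )
        with pytest.raises(ValueError):
            viability_percent(plate)
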