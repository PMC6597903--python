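"""TMT normalization, moderated t, and the BH procedure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import dualomics as d


def bh_oracle(p):
    """Brute-force BH: sorted p * m / rank, cumulative min from the right."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    terms = [p[order[r]] * m / (r + 1) for r in range(m)]
    out = np.empty(m)
    for r, i in enumerate(order):
        out[i] = min(min(terms[r:]), 1.0)
    return out


class TestChannelMedianNormalize:
    def test_hand_example(self, make_intensity_matrix):
        m = make_intensity_matrix([[10, 20], [30, 40]], [d.CONTROL, d.MUTANT])
        out = d.channel_median_normalize(m)
        # channel medians (20, 30), grand mean 25
        np.testing.assert_allclose(
            out.intensities.to_numpy(), [[12.5, 50 / 3], [37.5, 100 / 3]], rtol=1e-12
        )

    def test_equal_medians_is_fixed_point(self, make_intensity_matrix):
        vals = np.array([[10.0, 10.0], [30.0, 30.0], [20.0, 20.0]])
        m = make_intensity_matrix(vals, [d.CONTROL, d.MUTANT])
        out = d.channel_median_normalize(m)
        np.testing.assert_allclose(out.intensities.to_numpy(), vals, rtol=1e-12)

    def test_post_normalization_medians_equal(self, make_intensity_matrix):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(3, 1, size=(51, 4))
        m = make_intensity_matrix(vals, [d.CONTROL, d.CONTROL, d.MUTANT, d.MUTANT])
        med = d.channel_median_normalize(m).intensities.median(axis=0)
        np.testing.assert_allclose(med, med.iloc[0], rtol=1e-9)

    def test_row_permutation_commutes(self, make_intensity_matrix):
        rng = np.random.default_rng(6)
        vals = rng.lognormal(3, 1, size=(20, 4))
        perm = rng.permutation(20)
        m = make_intensity_matrix(vals, [d.CONTROL, d.CONTROL, d.MUTANT, d.MUTANT])
        mp = make_intensity_matrix(vals[perm], [d.CONTROL, d.CONTROL, d.MUTANT, d.MUTANT])
        a = d.channel_median_normalize(m).intensities.to_numpy()[perm]
        b = d.channel_median_normalize(mp).intensities.to_numpy()
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_empty_channel_named_in_error(self, make_intensity_matrix):
        m = make_intensity_matrix([[1.0, 2.0], [3.0, 4.0]], [d.CONTROL, d.MUTANT])
        m.intensities.iloc[:, 1] = np.nan
        with pytest.raises(d.EstimationError, match="ch2"):
            d.channel_median_normalize(m)


class TestRelativeRatio:
    def test_direct_arithmetic(self, make_intensity_matrix):
        m = make_intensity_matrix([[2.0, 4.0, 6.0]], [d.CONTROL, d.CONTROL, d.MUTANT])
        np.testing.assert_allclose(
            d.relative_ratio(m).to_numpy(), [[0.5, 1.0, 1.5]], rtol=1e-12
        )

    def test_constant_row_is_all_ones(self, make_intensity_matrix):
        m = make_intensity_matrix([[7.0, 7.0, 7.0]], [d.CONTROL, d.CONTROL, d.MUTANT])
        np.testing.assert_allclose(d.relative_ratio(m).to_numpy(), 1.0)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_row_scale_invariance(self, c):
        vals = np.array([[2.0, 4.0, 6.0, 8.0]])
        idx = pd.Index(["P1"], name="protein_id")
        chans = pd.Index([f"ch{i}" for i in range(1, 5)], name="channel_id")
        base = d.IntensityMatrix(
            pd.DataFrame(vals, index=idx, columns=chans),
            pd.Series(["G1"], index=idx),
            pd.DataFrame({"genotype": [d.CONTROL] * 2 + [d.MUTANT] * 2,
                          "timepoint": 35, "tmt_set": "TMT35"}, index=chans),
        )
        scaled = d.IntensityMatrix(
            pd.DataFrame(vals * c, index=idx, columns=chans),
            pd.Series(["G1"], index=idx),
            base.channels.copy(),
        )
        np.testing.assert_allclose(
            d.relative_ratio(base).to_numpy(), d.relative_ratio(scaled).to_numpy(),
            rtol=1e-9,
        )

    def test_row_means_are_one_and_idempotent(self, make_intensity_matrix):
        rng = np.random.default_rng(8)
        vals = rng.lognormal(3, 1, size=(30, 6))
        m = make_intensity_matrix(vals, [d.CONTROL] * 3 + [d.MUTANT] * 3)
        r = d.relative_ratio(d.channel_median_normalize(m))
        np.testing.assert_allclose(r.mean(axis=1), 1.0, rtol=1e-12)
        # re-applying the row-mean division is the identity on its own output
        np.testing.assert_allclose(
            r.div(r.mean(axis=1), axis=0).to_numpy(), r.to_numpy(), rtol=1e-12
        )


class TestModeratedT:
    @staticmethod
    def _random_ratios(n_prot=60, n_per_group=4, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(0, 0.3, size=(n_prot, 2 * n_per_group))
        cols = pd.Index([f"ch{i}" for i in range(2 * n_per_group)], name="channel_id")
        ratios = pd.DataFrame(x, index=[f"P{i}" for i in range(n_prot)], columns=cols)
        design = pd.Series([d.CONTROL] * n_per_group + [d.MUTANT] * n_per_group, index=cols)
        return ratios, design

    def test_equal_group_means_null(self):
        cols = pd.Index([f"ch{i}" for i in range(6)], name="channel_id")
        vals = np.tile([1.0, 2.0, 3.0], (10, 2))  # mutant repeats control exactly
        ratios = pd.DataFrame(vals, index=[f"P{i}" for i in range(10)], columns=cols)
        design = pd.Series([d.CONTROL] * 3 + [d.MUTANT] * 3, index=cols)
        fit = d.moderated_t(ratios, design)
        np.testing.assert_allclose(fit["t_mod"], 0.0, atol=1e-12)
        np.testing.assert_allclose(fit["p_raw"], 1.0, atol=1e-12)

    def test_d0_zero_reduces_to_pooled_t(self):
        """With no shrinkage the statistic is the textbook two-sample pooled t."""
        ratios, design = self._random_ratios(seed=3)
        fit = d.moderated_t(ratios, design, d0_override=0)
        x = np.log2(ratios.to_numpy())
        t_ref, p_ref = stats.ttest_ind(x[:, 4:], x[:, :4], axis=1, equal_var=True)
        np.testing.assert_allclose(fit["t_mod"], t_ref, rtol=1e-10)
        np.testing.assert_allclose(fit["p_raw"], p_ref, rtol=1e-10)

    def test_posterior_variance_between_s2_and_prior(self):
        ratios, design = self._random_ratios(n_prot=200, seed=7)
        fit = d.moderated_t(ratios, design)
        lo = np.minimum(fit["s2"], fit["s2_0"])
        hi = np.maximum(fit["s2"], fit["s2_0"])
        assert ((fit["s2_post"] >= lo - 1e-15) & (fit["s2_post"] <= hi + 1e-15)).all()

    def test_shrinkage_direction(self):
        """Below-prior variances are inflated (|t| drops), above-prior deflated."""
        ratios, design = self._random_ratios(n_prot=300, seed=11)
        mod = d.moderated_t(ratios, design)
        ord_ = d.moderated_t(ratios, design, d0_override=0)
        if not np.isfinite(mod["d0"].iloc[0]):
            pytest.skip("prior degenerate on this draw; no shrinkage to compare")
        below = mod["s2"] < mod["s2_0"]
        assert (np.abs(mod.loc[below, "t_mod"]) <= np.abs(ord_.loc[below, "t_mod"]) + 1e-12).all()
        assert (np.abs(mod.loc[~below, "t_mod"]) >= np.abs(ord_.loc[~below, "t_mod"]) - 1e-12).all()

    def test_low_coverage_proteins_excluded(self):
        ratios, design = self._random_ratios(n_prot=5, seed=13)
        ratios.iloc[0, [0, 1, 2]] = np.nan  # only 1 control channel left
        fit = d.moderated_t(ratios, design)
        assert "P0" not in fit.index
        assert len(fit) == 4

    def test_too_few_channels_rejected(self):
        cols = pd.Index(["a", "b", "c"], name="channel_id")
        ratios = pd.DataFrame(np.ones((3, 3)), columns=cols)
        design = pd.Series([d.CONTROL, d.CONTROL, d.MUTANT], index=cols)
        with pytest.raises(d.EstimationError):
            d.moderated_t(ratios, design)


class TestGeneLevelTable:
    def test_duplicate_gene_keeps_highest_mean_intensity(self, make_intensity_matrix):
        rng = np.random.default_rng(3)
        vals = rng.lognormal(10, 0.2, size=(6, 10))
        vals[2] *= 50  # dominant isoform for the duplicated gene
        genes = ["GA", "GB", "GC", "GC", "GD", "GE"]
        m = make_intensity_matrix(
            vals, [d.CONTROL] * 5 + [d.MUTANT] * 5, gene_symbols=genes
        )
        table = d.protein_differential(m, 35)
        assert table["feature"].tolist() == sorted(set(g.upper() for g in genes))
        assert len(table) == 5


class TestBhAdjust:
    def test_single_p_identity(self):
        np.testing.assert_allclose(d.bh_adjust([0.03]), [0.03])

    def test_step_through_example(self):
        # sorted (0.01,0.02,0.03,0.04) * 4/(1..4) = (.04,.04,.04,.04)
        np.testing.assert_allclose(
            d.bh_adjust([0.01, 0.04, 0.03, 0.02]), [0.04, 0.04, 0.04, 0.04], rtol=1e-12
        )

    def test_all_ones(self):
        np.testing.assert_allclose(d.bh_adjust(np.ones(5)), np.ones(5))

    @pytest.mark.parametrize("bad", [[-0.1], [1.1], [np.nan]])
    def test_invalid_p_rejected(self, bad):
        with pytest.raises(d.ValidationError):
            d.bh_adjust(bad)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_matches_bruteforce_oracle(self, p):
        np.testing.assert_allclose(d.bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(17)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 200))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(d.bh_adjust(p), ref, atol=1e-12)

    def test_monotone_in_input_ranks(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(size=100)
        adj = d.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
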