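import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import null_dataset, two_group_dataset
from oracles import pooled_t_oracle
from regscreen.diffexpr import (
    call_differential,
    fit_contrasts,
    fit_variance_prior,
    induction_breadth,
    moderated_t,
    trigamma_inverse,
)

TOY_INDUCED = [8.1, 8.4, 7.9, 8.6]
TOY_CONTROL = [7.2, 7.5, 7.3, 7.1]


class TestFitContrasts:
    def test_identical_groups_give_exact_null(self):
        data = two_group_dataset(
            {"flat": [8.0, 8.1, 7.9, 8.0], "moved": TOY_INDUCED},
            {"flat": [8.0, 8.1, 7.9, 8.0], "moved": TOY_CONTROL},
        )
        table = fit_contrasts(data).table.set_index("gene_id")
        assert table.loc["flat", "log2fc"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["flat", "t"] == pytest.approx(0.0, abs=1e-12)
        assert table.loc["flat", "p"] == pytest.approx(1.0, abs=1e-12)

    def test_zero_prior_df_recovers_textbook_pooled_t(self):
        data = two_group_dataset(
            {"toy": TOY_INDUCED, "other": [6.5, 6.9, 6.8, 7.0]},
            {"toy": TOY_CONTROL, "other": [7.0, 7.1, 6.6, 6.8]},
        )
        table = fit_contrasts(data, d0_override=0).table.set_index("gene_id")
        for gene, xi, xc in [
            ("toy", TOY_INDUCED, TOY_CONTROL),
            ("other", [6.5, 6.9, 6.8, 7.0], [7.0, 7.1, 6.6, 6.8]),
        ]:
            assert table.loc[gene, "t"] == pytest.approx(pooled_t_oracle(xi, xc), abs=1e-10)

    def test_shift_invariance_of_fc_and_t(self):
        base = two_group_dataset({"g": TOY_INDUCED}, {"g": TOY_CONTROL})
        shifted = two_group_dataset(
            {"g": [x + 5.0 for x in TOY_INDUCED]},
            {"g": [x + 5.0 for x in TOY_CONTROL]},
        )
        a = fit_contrasts(base, d0_override=0).table
        b = fit_contrasts(shifted, d0_override=0).table
        assert a["log2fc"].iloc[0] == pytest.approx(b["log2fc"].iloc[0], abs=1e-12)
        assert a["t"].iloc[0] == pytest.approx(b["t"].iloc[0], abs=1e-12)

    def test_underreplicated_cell_marked_unavailable(self):
        data = two_group_dataset({"g": TOY_INDUCED}, {"g": TOY_CONTROL})
        # drop controls down to one replicate
        keep = [c for c in data.matrix.columns if not c.startswith("control")] + ["control_t6_r1"]
        data.matrix = data.matrix[keep]
        data.design = data.design.loc[keep]
        table = fit_contrasts(data).table
        assert np.isnan(table["p"]).all()
        assert (table["call"] == 0).all()

    def test_null_p_values_calibrated(self):
        table = fit_contrasts(null_dataset(4000, noise_sd=0.3, seed=42)).table
        frac = float((table["p"] < 0.05).mean())
        # 99.9% binomial band around 0.05 at n=4000
        assert abs(frac - 0.05) < 3.29 * np.sqrt(0.05 * 0.95 / 4000)

    def test_shrinkage_limit_large_prior_df(self):
        data = null_dataset(200, noise_sd=0.4, seed=3)
        big = fit_contrasts(data, d0_override=1e12).table
        # with an overwhelming prior, every gene shares the prior variance:
        # t is proportional to log2fc
        ratio = big["t"] / big["log2fc"]
        assert np.allclose(ratio, ratio.iloc[0], rtol=1e-6)


class TestVariancePrior:
    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for x in (0.3, 1.0, 4.0, 25.0):
            y = float(polygamma(1, x))
            assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)

    def test_prior_recovers_scaled_f_parameters(self):
        # variances drawn as s0^2 * chi2_d / d scaled by gene factors from an
        # inverse-chi2 with known prior df
        rng = np.random.default_rng(0)
        d, d0, s0 = 6, 10.0, 0.25
        gene_var = s0 * d0 / rng.chisquare(d0, size=20000)
        s2 = gene_var * rng.chisquare(d, size=20000) / d
        d0_hat, s0_hat = fit_variance_prior(s2, d)
        assert d0_hat == pytest.approx(d0, rel=0.15)
        assert s0_hat == pytest.approx(s0, rel=0.05)

    def test_homoscedastic_variances_shrink_heavily(self):
        rng = np.random.default_rng(1)
        s2 = 0.09 * rng.chisquare(6, size=5000) / 6
        d0, s0 = fit_variance_prior(s2, 6)
        assert d0 > 50  # near-complete shrinkage toward the common variance
        assert s0 == pytest.approx(0.09, rel=0.05)

    def test_infinite_prior_gives_pooled_variance_z(self):
        # degenerate log-variance spread drives the prior df to infinity;
        # the statistic then reduces to the pooled-variance z with normal p
        d0, s0 = fit_variance_prior(np.full(100, 0.25), 6)
        assert np.isinf(d0)
        t, p = moderated_t(np.array([0.3]), np.array([0.25]), 6, 4, 4, d0, s0)
        se = np.sqrt(s0 * 0.5)
        assert t[0] == pytest.approx(0.3 / se, abs=1e-12)
        assert p[0] == pytest.approx(2 * stats.norm.sf(abs(t[0])), abs=1e-12)


class TestCalls:
    @pytest.mark.parametrize(
        "p,log2fc,expected",
        [
            (0.005, 0.5, 1),  # passes both cutoffs
            (0.005, 0.3, 0),  # fails the fold-change cutoff
            (0.5, 3.0, 0),  # fails the significance cutoff
            (0.005, -0.5, -1),  # repression
        ],
    )
    def test_cutoff_rules(self, p, log2fc, expected):
        from regscreen.diffexpr import ContrastTable

        table = pd.DataFrame(
            {
                "gene_id": ["g"],
                "substrate": ["avicel"],
                "time_h": [6.0],
                "log2fc": [log2fc],
                "p": [p],
            }
        )
        ct = ContrastTable(table=table)
        call_differential(ct)
        assert ct.table["call"].iloc[0] == expected

    def test_nonpositive_cutoffs_rejected(self):
        from regscreen.diffexpr import ContrastTable

        ct = ContrastTable(table=pd.DataFrame(
            {"gene_id": [], "substrate": [], "time_h": [], "log2fc": [], "p": []}
        ))
        with pytest.raises(ValueError):
            call_differential(ct, p_cut=0.0)
        with pytest.raises(ValueError):
            call_differential(ct, lfc_cut=-1.0)

    def test_relaxing_cutoffs_never_reduces_calls(self):
        data = null_dataset(500, noise_sd=0.4, seed=9)
        ct = fit_contrasts(data)
        call_differential(ct, p_cut=0.01, lfc_cut=0.4)
        strict = int((ct.table["call"] != 0).sum())
        call_differential(ct, p_cut=0.05, lfc_cut=0.4)
        looser_p = int((ct.table["call"] != 0).sum())
        call_differential(ct, p_cut=0.05, lfc_cut=0.2)
        looser_both = int((ct.table["call"] != 0).sum())
        assert strict <= looser_p <= looser_both


class TestInductionBreadth:
    def _table(self, rows):
        from regscreen.diffexpr import ContrastTable

        return ContrastTable(table=pd.DataFrame(
            rows, columns=["gene_id", "substrate", "time_h", "call"]
        ))

    def test_counts_substrates_not_time_points(self):
        ct = self._table(
            [
                ("g", "avicel", 6.0, 1),
                ("g", "avicel", 17.0, 1),  # same substrate counted once
                ("g", "wheat", 6.0, 1),
                ("g", "spruce", 17.0, 1),
                ("g", "sophorose", 6.0, 0),
            ]
        )
        assert induction_breadth(ct)["g"] == 3

    def test_repression_does_not_count(self):
        ct = self._table([("g", "avicel", 6.0, -1), ("g", "wheat", 6.0, -1)])
        assert induction_breadth(ct)["g"] == 0

    def test_planted_breadth_on_zero_noise_data(self, tiny_zero_noise):
        ds = tiny_zero_noise
        ct = fit_contrasts(ds.expression)
        call_differential(ct)
        breadth = induction_breadth(ct)
        members = ds.truth.cluster_labels[ds.truth.cluster_labels == 0].index
        # the single planted cluster is induced on all four substrates
        assert (breadth[members] == 4).all()
        background = ds.truth.cluster_labels[ds.truth.cluster_labels == -1].index
        assert (breadth[background] == 0).all()
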