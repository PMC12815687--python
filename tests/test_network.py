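"""Perturbation covariance networks: partial correlations, perturbed
networks, z-scores, jackknife and edge summaries."""

import numpy as np
import pandas as pd
import pytest

import petcovnet as pcn
from petcovnet.network import InfiniteVarianceError, zmatrices_to_long


def toy_tables(n=12, r=4, seed=0, rho=0.5):
    rng = np.random.default_rng(seed)
    cov = np.full((r, r), rho) + (1 - rho) * np.eye(r)
    cols = ["hippocampus"] + [f"roi{j}" for j in range(1, r)]
    vt = pd.DataFrame(rng.multivariate_normal(np.zeros(r), cov, size=n) + 5.0,
                      index=[f"s{i}" for i in range(n)], columns=cols)
    cov_df = pd.DataFrame({"age": rng.normal(0, 4, n), "sex": rng.integers(0, 2, n)},
                          index=vt.index, dtype=float)
    return vt, cov_df


def pairwise_partial_oracle(x, y, covs):
    """Independent inverse-covariance oracle for one edge: partial corr of
    (x, y) given the covariates from the precision matrix of [x, y, covs]."""
    m = np.column_stack([x, y, covs])
    omega = np.linalg.inv(np.cov(m, rowvar=False))
    return -omega[0, 1] / np.sqrt(omega[0, 0] * omega[1, 1])


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self):
        vt, _ = toy_tables()
        out = pcn.partial_correlation_matrix(vt)
        np.testing.assert_allclose(out.to_numpy(), np.corrcoef(vt.to_numpy(), rowvar=False),
                                   atol=1e-12)

    def test_duplicated_roi_gives_unit_edge(self):
        vt, cov = toy_tables()
        vt = vt.assign(copy=vt["hippocampus"])
        out = pcn.partial_correlation_matrix(vt, cov)
        assert out.loc["hippocampus", "copy"] == pytest.approx(1.0)

    def test_matches_precision_matrix_oracle(self):
        vt, cov = toy_tables(n=6, r=3, seed=3)
        out = pcn.partial_correlation_matrix(vt, cov[["age"]])
        for i in range(3):
            for j in range(i):
                oracle = pairwise_partial_oracle(vt.iloc[:, i], vt.iloc[:, j],
                                                 cov[["age"]].to_numpy())
                assert out.iloc[i, j] == pytest.approx(oracle, abs=1e-10)

    def test_symmetric_unit_diagonal_bounded(self):
        vt, cov = toy_tables(n=30, r=6, seed=9)
        out = pcn.partial_correlation_matrix(vt, cov).to_numpy()
        np.testing.assert_allclose(out, out.T, atol=1e-14)
        np.testing.assert_allclose(np.diag(out), 1.0)
        assert np.all(np.abs(out) <= 1.0)

    def test_missing_values_rejected(self):
        vt, _ = toy_tables()
        vt.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            pcn.partial_correlation_matrix(vt)

    def test_rank_deficient_covariates_rejected(self):
        vt, cov = toy_tables()
        cov["age2"] = cov["age"]
        with pytest.raises(np.linalg.LinAlgError):
            pcn.partial_correlation_matrix(vt, cov)


class TestReferenceNetwork:
    def test_row_order_and_scale_invariance(self):
        vt, cov = toy_tables(n=25)
        with pytest.warns(UserWarning, match="guideline"):
            base = pcn.build_reference_network(vt, cov)
        shuffled = vt.sample(frac=1.0, random_state=1)
        with pytest.warns(UserWarning):
            perm = pcn.build_reference_network(shuffled, cov.loc[shuffled.index])
        np.testing.assert_allclose(base.pcc.to_numpy(), perm.pcc.to_numpy(), atol=1e-12)
        scaled = vt.assign(hippocampus=vt["hippocampus"] * 10.0)
        with pytest.warns(UserWarning):
            scl = pcn.build_reference_network(scaled, cov)
        np.testing.assert_allclose(base.pcc.to_numpy(), scl.pcc.to_numpy(), atol=1e-12)

    def test_too_small_reference_rejected(self):
        vt, cov = toy_tables(n=4)
        with pytest.raises(ValueError, match="n >= 5"):
            pcn.build_reference_network(vt, cov)


class TestPerturbedNetwork:
    def test_matches_from_scratch_recomputation(self):
        """Oracle: residualise the stacked table column-by-column with an
        independent OLS and correlate."""
        import statsmodels.api as sm

        vt, cov = toy_tables(n=5, r=3, seed=7)
        extra_vt, extra_cov = toy_tables(n=1, r=3, seed=8)
        row, crow = extra_vt.iloc[0].rename("new"), extra_cov.iloc[0].rename("new")
        pert = pcn.perturbed_network(vt, row, cov, crow)

        stacked = pd.concat([vt, row.to_frame().T])
        covs = pd.concat([cov, crow.to_frame().T])
        x = sm.add_constant(covs.to_numpy())
        resid = np.column_stack([
            sm.OLS(stacked[c].to_numpy(), x).fit().resid for c in stacked.columns
        ])
        oracle = np.corrcoef(resid, rowvar=False)
        np.testing.assert_allclose(pert.to_numpy(), oracle, atol=1e-12)

    def test_average_participant_barely_perturbs(self):
        vt, cov = toy_tables(n=40, r=4, seed=2)
        ref = pcn.partial_correlation_matrix(vt)
        pert = pcn.perturbed_network(vt, vt.mean().rename("avg"))
        off = ~np.eye(4, dtype=bool)
        assert np.max(np.abs((pert - ref).to_numpy()[off])) < 0.02

    def test_add_then_drop_recovers_reference(self):
        vt, cov = toy_tables(n=10, r=4)
        row, crow = vt.iloc[0].rename("dup"), cov.iloc[0].rename("dup")
        stacked = pd.concat([vt, row.to_frame().T])
        covs = pd.concat([cov, crow.to_frame().T])
        back = pcn.partial_correlation_matrix(stacked.drop(index="dup"), covs.drop(index="dup"))
        ref = pcn.partial_correlation_matrix(vt, cov)
        np.testing.assert_allclose(back.to_numpy(), ref.to_numpy(), atol=1e-14)

    def test_missing_roi_rejected(self):
        vt, cov = toy_tables()
        with pytest.raises(ValueError, match="missing ROI"):
            pcn.perturbed_network(vt, pd.Series({"hippocampus": 5.0}), cov, cov.iloc[0])


def make_reference(pcc_value: float, n: int, r: int = 3) -> pcn.ReferenceNetwork:
    cols = ["hippocampus", "amygdala", "thalamus"][:r]
    pcc = np.full((r, r), pcc_value)
    np.fill_diagonal(pcc, 1.0)
    return pcn.ReferenceNetwork(pcc=pd.DataFrame(pcc, index=cols, columns=cols), n=n)


def make_delta(value: float, ref: pcn.ReferenceNetwork) -> pcn.DeltaNetwork:
    d = np.full(ref.pcc.shape, value)
    np.fill_diagonal(d, 0.0)
    return pcn.DeltaNetwork(dpcc=pd.DataFrame(d, index=ref.pcc.index, columns=ref.pcc.columns),
                            participant_id="x")


class TestZScore:
    def test_zero_delta_zero_z(self):
        ref = make_reference(0.4, 23)
        z = pcn.zscore_network(make_delta(0.0, ref), ref)
        np.testing.assert_array_equal(z.z.to_numpy(), 0.0)

    def test_printed_formula_uncorrelated_reference(self):
        # sigma = (1 - 0^2)/22, so Z = 0.1 * 22 = 2.2
        ref = make_reference(0.0, 23)
        z = pcn.zscore_network(make_delta(0.1, ref), ref)
        assert z.z.iloc[1, 0] == pytest.approx(2.2)

    def test_printed_formula_correlated_reference(self):
        # sigma = 0.75/22, Z = -0.05/sigma = -1.4667
        ref = make_reference(0.5, 23)
        z = pcn.zscore_network(make_delta(-0.05, ref), ref)
        assert z.z.iloc[1, 0] == pytest.approx(-0.05 * 22 / 0.75)

    def test_saturated_reference_edge_raises(self):
        ref = make_reference(1.0, 23)
        with pytest.raises(InfiniteVarianceError, match="hippocampus"):
            pcn.zscore_network(make_delta(0.1, ref), ref)

    def test_edge_pvalues_two_sided_normal(self):
        ref = make_reference(0.0, 23)
        z = pcn.zscore_network(make_delta(0.1, ref), ref)
        from scipy.stats import norm
        assert z.edge_pvalues().iloc[1, 0] == pytest.approx(2 * norm.sf(2.2))


class TestJackknife:
    def test_one_zmatrix_per_control_with_symmetry(self):
        vt, cov = toy_tables(n=10)
        zms = pcn.jackknife_reference_z(vt, cov)
        assert len(zms) == 10
        for zm in zms:
            arr = zm.z.to_numpy()
            np.testing.assert_allclose(arr, arr.T, atol=1e-10)
            np.testing.assert_array_equal(np.diag(arr), 0.0)
            assert zm.reference_n == 9

    def test_duplicated_participants_get_identical_z(self):
        vt, cov = toy_tables(n=8)
        vt.iloc[1] = vt.iloc[0].to_numpy()
        cov.iloc[1] = cov.iloc[0].to_numpy()
        zms = pcn.jackknife_reference_z(vt, cov)
        np.testing.assert_allclose(zms[0].z.to_numpy(), zms[1].z.to_numpy(), atol=1e-12)

    def test_needs_six_controls(self):
        vt, cov = toy_tables(n=5)
        with pytest.raises(ValueError, match="at least 6"):
            pcn.jackknife_reference_z(vt, cov)


class TestParticipantZscores:
    def test_chain_preserves_symmetry_and_zero_diagonal(self):
        vt, cov = toy_tables(n=30, r=5, seed=4)
        hc, pat = vt.iloc[:20], vt.iloc[20:]
        hcc, patc = cov.iloc[:20], cov.iloc[20:]
        with pytest.warns(UserWarning):
            zms = pcn.participant_zscores(hc, pat, hcc, patc)
        assert len(zms) == 10
        for zm in zms:
            arr = zm.z.to_numpy()
            np.testing.assert_allclose(arr, arr.T, atol=1e-10)
            np.testing.assert_array_equal(np.diag(arr), 0.0)
            assert np.isfinite(arr).all()
            assert zm.reference_n == 20


class TestEdgeSummaries:
    def test_extreme_proportion_counts_incident_edges(self):
        cols = list(pcn.ROI_NAMES)
        z = pd.DataFrame(0.0, index=cols, columns=cols)
        z.loc["hippocampus", "amygdala"] = 3.0
        z.loc["amygdala", "hippocampus"] = 3.0
        zm = pcn.ZMatrix(z=z, participant_id="x", reference_n=23)
        prop = pcn.extreme_deviation_proportion(zm, z_crit=1.96)
        assert prop["hippocampus"] == pytest.approx(1 / 22)
        assert prop["amygdala"] == pytest.approx(1 / 22)
        assert prop.drop(["hippocampus", "amygdala"]).eq(0).all()

    def test_extreme_proportion_limits(self):
        cols = list(pcn.ROI_NAMES)
        zeros = pcn.ZMatrix(pd.DataFrame(0.0, index=cols, columns=cols), "a", 23)
        assert pcn.extreme_deviation_proportion(zeros).eq(0).all()
        big = pd.DataFrame(5.0, index=cols, columns=cols)
        np.fill_diagonal(big.to_numpy(), 0.0)
        allbig = pcn.ZMatrix(big, "b", 23)
        assert pcn.extreme_deviation_proportion(allbig).eq(1.0).all()

    def test_edge_subset_lengths_and_transpose_invariance(self):
        rng = np.random.default_rng(0)
        cols = list(pcn.ROI_NAMES)
        a = rng.normal(size=(23, 23))
        sym = a + a.T
        np.fill_diagonal(sym, 0.0)
        zm = pcn.ZMatrix(pd.DataFrame(sym, index=cols, columns=cols), "x", 23)
        whole = pcn.edge_subset(zm, "whole_brain")
        assert whole.shape == (253,)  # 23 * 22 / 2
        hip = pcn.edge_subset(zm, "hippocampus")
        assert hip.shape == (22,)
        zt = pcn.ZMatrix(pd.DataFrame(sym.T, index=cols, columns=cols), "x", 23)
        np.testing.assert_allclose(np.sort(whole), np.sort(pcn.edge_subset(zt, "whole_brain")))

    def test_edge_subset_unknown_mode(self):
        cols = list(pcn.ROI_NAMES)
        zm = pcn.ZMatrix(pd.DataFrame(0.0, index=cols, columns=cols), "x", 23)
        with pytest.raises(ValueError, match="mode"):
            pcn.edge_subset(zm, "cerebellum_only")

    def test_long_format_has_unique_edges(self):
        vt, cov = toy_tables(n=10, r=4)
        zms = pcn.jackknife_reference_z(vt, cov)
        long = zmatrices_to_long(zms, {zm.participant_id: "HC" for zm in zms})
        assert len(long) == 10 * 6  # 4*3/2 edges per participant
        assert set(long.columns) >= {"participant_id", "group", "roi_i", "roi_j", "z", "p_edge"}
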