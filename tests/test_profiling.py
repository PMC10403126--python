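"""Well aggregation, grit, binning, sphering, mAP and batch diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ortho_group

from moascreen import profiling
from moascreen.profiling import (aggregate_sites_to_wells,
                                 average_precision_from_ranking,
                                 bin_accuracy_by_grit, cosine_within_across,
                                 fit_sphering, grit, mean_average_precision,
                                 plate_correlation_matrix)
import oracles

F2 = ["f0", "f1"]


def profile_frame(vectors, compounds, moas=None, plates=None):
    vectors = np.asarray(vectors, dtype=float)
    n, d = vectors.shape
    frame = pd.DataFrame(vectors, columns=[f"f{j}" for j in range(d)])
    frame.insert(0, "plate_id", plates if plates is not None else "P01")
    frame.insert(1, "well", [f"A{i:02d}" for i in range(n)])
    frame.insert(2, "compound_id", compounds)
    frame.insert(3, "moa_label", moas if moas is not None else compounds)
    return frame


class TestWellAggregation:
    def test_two_site_mean(self):
        sites = pd.DataFrame({
            "plate_id": "P01", "well": ["A01", "A01"],
            "compound_id": "c1", "moa_label": "A",
            "f0": [1.0, 3.0], "f1": [3.0, 5.0]})
        wells = aggregate_sites_to_wells(sites, F2)
        assert wells[F2].iloc[0].tolist() == [2.0, 4.0]

    def test_single_site_identity(self):
        sites = pd.DataFrame({"plate_id": "P01", "well": ["A01"],
                              "f0": [1.5], "f1": [-2.0]})
        wells = aggregate_sites_to_wells(sites, F2)
        assert wells[F2].iloc[0].tolist() == [1.5, -2.0]

    def test_matches_groupby_oracle_on_shuffled_input(self, rng):
        n = 60
        sites = pd.DataFrame({
            "plate_id": rng.choice(["P01", "P02"], n),
            "well": rng.choice(["A01", "B02", "C03"], n),
            "f0": rng.standard_normal(n), "f1": rng.standard_normal(n)})
        wells = aggregate_sites_to_wells(sites, F2)
        ref = oracles.well_mean_bf(sites.to_dict("records"), F2)
        for row in wells.itertuples():
            expected = ref[(row.plate_id, row.well)]
            assert row.f0 == pytest.approx(expected["f0"])
            assert row.f1 == pytest.approx(expected["f1"])

    def test_missing_keys_rejected(self):
        with pytest.raises(ValueError, match="well keys"):
            aggregate_sites_to_wells(pd.DataFrame({"f0": [1.0]}), ["f0"])


class TestGrit:
    def _replicated(self, rng, d=8, reps=3, n_ctrl=6, signal=None):
        rows, compounds = [], []
        for c in range(2):
            mean = signal if signal is not None else rng.standard_normal(d)
            for r in range(reps):
                rows.append(mean + 0.01 * rng.standard_normal(d))
                compounds.append(f"c{c}")
        for k in range(n_ctrl):
            rows.append(rng.standard_normal(d))
            compounds.append("DMSO")
        return profile_frame(rows, compounds)

    def test_direct_formula_oracle(self, rng):
        frame = self._replicated(rng)
        fcols = [c for c in frame.columns if c.startswith("f")]
        scores = grit(frame, fcols).scores
        x = frame[fcols].to_numpy()
        corr = np.corrcoef(x)
        ctrl = np.array([c == "DMSO" for c in frame.compound_id])
        for i, row in scores.iterrows():
            if row.compound_id == "DMSO":
                assert np.isnan(row.grit)
                continue
            mates = [j for j in range(len(frame))
                     if frame.compound_id[j] == row.compound_id and j != i]
            c_i = corr[i, ctrl]
            expected = np.mean((corr[i, mates] - c_i.mean()) / c_i.std())
            assert row.grit == pytest.approx(expected)
            assert row.grit > 1.5  # tight replicates vs noise controls

    def test_centered_z_hand_cases(self):
        """Grit is zero when the replicate correlation equals the mean
        control correlation, and equals the plain z-score otherwise."""
        u = np.array([1.0, -1.0, 1.0, -1.0])
        v = np.array([1.0, -1.0, -1.0, 1.0])  # corr(u, v) = 0
        fcols = [f"f{j}" for j in range(4)]
        # controls at correlations +1 and -1 to u: mean 0, sd 1
        frame = profile_frame([u, v, u * 2.0, -u], ["c1", "c1",
                                                    "DMSO", "DMSO"])
        scores = grit(frame, fcols).scores
        g = scores[scores.compound_id == "c1"].grit.to_numpy()
        assert g[0] == pytest.approx((0 - 0) / 1.0)   # profile u
        # profile v: replicate corr 0, control corrs both 0 -> sd 0 -> NaN
        assert np.isnan(g[1])
        # replicate corr 1 instead: grit = (1 - 0) / 1
        frame2 = profile_frame([u, u * 3.0, u * 2.0, -u],
                               ["c1", "c1", "DMSO", "DMSO"])
        g2 = grit(frame2, fcols).scores
        assert g2[g2.compound_id == "c1"].grit.iloc[0] == pytest.approx(1.0)

    def test_affine_rescaling_invariance(self, rng):
        frame = self._replicated(rng)
        fcols = [c for c in frame.columns if c.startswith("f")]
        scaled = frame.copy()
        scaled[fcols] = frame[fcols] * 3.7 - 1.2
        a = grit(frame, fcols).scores
        b = grit(scaled, fcols).scores
        np.testing.assert_allclose(a.grit.to_numpy(), b.grit.to_numpy(),
                                   equal_nan=True)

    def test_singleton_group_missing_with_reason(self, rng):
        frame = profile_frame(rng.standard_normal((4, 5)),
                              ["c1", "DMSO", "DMSO", "DMSO"])
        scores = grit(frame, [f"f{j}" for j in range(5)]).scores
        row = scores[scores.compound_id == "c1"].iloc[0]
        assert np.isnan(row.grit)
        assert row.reason == "singleton group"

    def test_pooled_control_strategy(self, rng):
        frame = self._replicated(rng)
        fcols = [c for c in frame.columns if c.startswith("f")]
        pooled = grit(frame, fcols, control_stats="pooled").scores
        per = grit(frame, fcols, control_stats="per_profile").scores
        ok = np.isfinite(pooled.grit)
        assert ok.sum() == np.isfinite(per.grit).sum() > 0

    def test_requires_two_controls(self, rng):
        frame = profile_frame(rng.standard_normal((3, 5)),
                              ["c1", "c1", "DMSO"])
        with pytest.raises(ValueError, match="two control"):
            grit(frame, [f"f{j}" for j in range(5)])


class TestGritBinning:
    def test_ten_samples_ten_bins(self, rng):
        grits = rng.standard_normal(10)
        correct = rng.random(10) < 0.5
        table = bin_accuracy_by_grit(correct, grits, n_bins=10)
        np.testing.assert_allclose(table.mean_grit, np.sort(grits))
        assert (table.n == 1).all()

    def test_remainder_goes_to_lowest_bins(self, rng):
        table = bin_accuracy_by_grit(rng.random(23) < 0.5,
                                     rng.standard_normal(23), n_bins=10)
        assert table.n.tolist() == [3, 3, 3, 2, 2, 2, 2, 2, 2, 2]
        assert table.n.sum() == 23
        assert table.accuracy.between(0, 1).all()

    def test_fewer_samples_than_bins_rejected(self, rng):
        with pytest.raises(ValueError, match="bins"):
            bin_accuracy_by_grit(np.ones(5), rng.standard_normal(5),
                                 n_bins=10)


class TestSphering:
    def test_small_lambda_whitens_controls(self, rng):
        d = 6
        cov = np.diag(rng.random(d) + 0.5)
        x = rng.multivariate_normal(np.zeros(d), cov, size=4000)
        t = fit_sphering(x, 1e-6)
        xt = t(x)
        np.testing.assert_allclose(np.cov(xt, rowvar=False), np.eye(d),
                                   atol=0.05)

    def test_large_lambda_reduces_to_uniform_scaling(self, rng):
        x = rng.standard_normal((200, 5)) * [5, 1, 1, 1, 0.2]
        t = fit_sphering(x, 1e6)
        xt = t(x)
        centered = x - x.mean(axis=0)
        # cosine similarities among centered profiles are preserved
        def cosines(a):
            an = a / np.linalg.norm(a, axis=1, keepdims=True)
            return (an @ an.T)[np.triu_indices(len(a), 1)]
        np.testing.assert_allclose(cosines(xt), cosines(centered), atol=1e-4)

    def test_whitening_matrix_symmetric_positive_definite(self, rng):
        x = rng.standard_normal((50, 8))
        for lam in (1e-3, 1e-1, 1.0, 10.0):
            w = fit_sphering(x, lam).whitening
            np.testing.assert_allclose(w, w.T, atol=1e-10)
            assert np.linalg.eigvalsh(w).min() > 0

    def test_invalid_inputs_rejected(self, rng):
        x = rng.standard_normal((10, 3))
        with pytest.raises(ValueError, match="lambda"):
            fit_sphering(x, 0.0)
        bad = x.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_sphering(bad, 0.1)


class TestAveragePrecision:
    def test_hit_miss_hit_example(self):
        assert average_precision_from_ranking([True, False, True]) \
            == pytest.approx(5 / 6)

    def test_matches_bruteforce_on_random_rankings(self, rng):
        for _ in range(50):
            hits = rng.random(20) < 0.3
            assert average_precision_from_ranking(hits) == pytest.approx(
                oracles.average_precision_bf(list(hits)))

    def test_perfect_clusters_give_map_one(self):
        vec = np.repeat(np.eye(3), 3, axis=0)
        frame = profile_frame(vec + 0, [f"c{i}" for i in range(9)],
                              moas=["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        score, table = mean_average_precision(frame,
                                              [f"f{j}" for j in range(3)])
        assert score == pytest.approx(1.0)
        assert len(table) == 9

    def test_random_features_match_permutation_null(self, rng):
        from moascreen.experiments import map_permutation_null
        n, d = 40, 6
        frame = profile_frame(rng.standard_normal((n, d)),
                              [f"c{i}" for i in range(n)],
                              moas=list(rng.choice(["A", "B", "C", "D"], n)))
        fcols = [f"f{j}" for j in range(d)]
        score, _ = mean_average_precision(frame, fcols)
        null = map_permutation_null(frame, fcols, 300, rng)
        z = (score - null.mean()) / null.std()
        assert abs(z) < 3.5

    def test_rotation_invariance_about_origin(self, rng):
        n, d = 24, 5
        frame = profile_frame(rng.standard_normal((n, d)),
                              [f"c{i}" for i in range(n)],
                              moas=list(rng.choice(["A", "B"], n)))
        fcols = [f"f{j}" for j in range(d)]
        q = ortho_group.rvs(d, random_state=4)
        rotated = frame.copy()
        rotated[fcols] = frame[fcols].to_numpy() @ q
        a, _ = mean_average_precision(frame, fcols)
        b, _ = mean_average_precision(rotated, fcols)
        assert a == pytest.approx(b)

    def test_controls_excluded_and_singletons_warned(self, rng):
        frame = profile_frame(
            rng.standard_normal((6, 4)),
            ["c1", "c2", "c3", "c4", "c5", "DMSO"],
            moas=["A", "A", "B", "B", "C", "DMSO"])
        with pytest.warns(UserWarning, match="single well"):
            _, table = mean_average_precision(frame,
                                              [f"f{j}" for j in range(4)])
        assert "DMSO" not in set(table.moa_label)
        assert "C" not in set(table.moa_label)

    def test_matches_per_query_bruteforce(self, rng):
        n, d = 18, 4
        moas = list(rng.choice(["A", "B", "C"], n))
        vec = rng.standard_normal((n, d))
        frame = profile_frame(vec, [f"c{i}" for i in range(n)], moas=moas)
        fcols = [f"f{j}" for j in range(d)]
        _, table = mean_average_precision(frame, fcols)
        ref = oracles.mean_ap_bf(vec, moas, list(range(n)))
        for i, row in table.iterrows():
            assert row.average_precision == pytest.approx(ref[i])


class TestCosineWithinAcross:
    def test_identical_vectors_all_one(self):
        x = np.tile([1.0, 2.0], (6, 1))
        res = cosine_within_across(x, np.array(["A"] * 3 + ["B"] * 3))
        np.testing.assert_allclose(res.within, 1.0)
        np.testing.assert_allclose(res.across, 1.0)

    def test_orthogonal_classes_separate(self):
        x = np.repeat(np.eye(2), 3, axis=0)
        res = cosine_within_across(x, np.array(["A"] * 3 + ["B"] * 3))
        np.testing.assert_allclose(res.within, 1.0)
        np.testing.assert_allclose(res.across, 0.0, atol=1e-12)
        assert res.separation == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.standard_normal((50, 7))
        labels = rng.choice(["A", "B", "C"], 50)
        res = cosine_within_across(x, labels)
        w, a = oracles.cosine_pairs_bf(x, list(labels))
        np.testing.assert_allclose(np.sort(res.within), np.sort(w))
        np.testing.assert_allclose(np.sort(res.across), np.sort(a))

    def test_zero_vector_rejected(self):
        x = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.5, 1.0]])
        with pytest.raises(ValueError, match="zero vector"):
            cosine_within_across(x, np.array(["A", "A", "B", "B"]))


class TestPlateCorrelation:
    def _frame(self, vectors, plates):
        frame = pd.DataFrame(vectors, columns=[f"f{j}" for j in
                                               range(vectors.shape[1])])
        frame.insert(0, "plate_id", plates)
        return frame

    def test_identical_plates_all_ones(self, rng):
        v = rng.standard_normal(5)
        frame = self._frame(np.tile(v, (6, 1)),
                            ["P01", "P01", "P02", "P02", "P03", "P03"])
        m = plate_correlation_matrix(frame, [f"f{j}" for j in range(5)])
        np.testing.assert_allclose(m.to_numpy(), 1.0)

    def test_anticorrelated_plates(self):
        v = np.array([1.0, -1.0, 2.0, -2.0])
        frame = self._frame(np.vstack([v, -v]), ["P01", "P02"])
        m = plate_correlation_matrix(frame, [f"f{j}" for j in range(4)])
        assert m.loc["P01", "P02"] == pytest.approx(-1.0)
        assert m.loc["P01", "P01"] == 1.0

    def test_injected_offsets_widen_offdiagonal_spread(self):
        """Paired simulation: plate offsets increase the variance of the
        off-diagonal correlation entries."""
        from moascreen.synthetic import (feature_columns,
                                         generate_feature_table)
        from conftest import small_screen

        def offdiag_sd(offset_sd):
            cfg = small_screen(n_plates=6, plate_offset_sd=offset_sd,
                               dmso_wells_per_plate=12, seed=13)
            table = generate_feature_table(cfg)
            fcols = feature_columns(table)
            ctrl = table[table.compound_id == "DMSO"]
            m = plate_correlation_matrix(ctrl, fcols).to_numpy()
            return m[np.triu_indices(len(m), 1)].std()

        assert offdiag_sd(3.0) > offdiag_sd(0.0)
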