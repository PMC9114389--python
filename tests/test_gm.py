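"""Geometric morphometrics: curves, template, GPA, ordinations, CV."""

import numpy as np
import pytest

from paleomolar import gm, synth
from paleomolar.core import ValidationError
from conftest import rigid_copy


class TestResampleCurve:
    def test_straight_segment(self):
        line = np.column_stack([np.linspace(0, 10, 7), np.zeros(7),
                                np.zeros(7)])
        out = gm.resample_curve(line, 11)
        assert out[:, 0] == pytest.approx(np.arange(11.0), abs=1e-9)
        assert np.abs(out[:, 1:]).max() < 1e-12

    def test_circle_uniform_spacing_and_radius(self):
        th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        circle = np.column_stack([np.cos(th), np.sin(th), np.zeros(100)])
        out = gm.resample_curve(circle, 30, closed=True)
        radii = np.linalg.norm(out[:, :2], axis=1)
        assert np.abs(radii - 1.0).max() < 1e-3
        seg = np.linalg.norm(np.diff(np.vstack([out, out[:1]]), axis=0),
                             axis=1)
        assert np.ptp(seg) < 1e-3

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            gm.resample_curve(np.zeros((3, 3)) + np.arange(3)[:, None], 5)

    def test_duplicate_points_deduplicated_with_warning(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [2, 0, 0],
                        [3, 0, 0]], float)
        with pytest.warns(UserWarning, match="duplicate"):
            out = gm.resample_curve(pts, 4)
        assert out.shape == (4, 3)


class TestBuildTemplate:
    def test_synthetic_crown_horns_land_exactly(self, small_crown):
        cfg = gm.build_template(small_crown.horns, small_crown.ridge_path,
                                small_crown.cervix_path)
        assert cfg.coords.shape == (94, 3)
        assert cfg.coords[:4] == pytest.approx(small_crown.horns)

    def test_segment_counts(self, small_crown):
        cfg = gm.build_template(small_crown.horns, small_crown.ridge_path,
                                small_crown.cervix_path)
        assert gm.N_ANATOMICAL + gm.N_RIDGE + gm.N_CERVIX == 94
        assert gm.RIDGE_SEGMENT_COUNTS == (12, 12, 24, 12)
        assert len(cfg.coords) == gm.N_TEMPLATE

    def test_mirrored_input_reflected_and_flagged(self, small_crown):
        flip = np.array([-1.0, 1.0, 1.0])
        cfg = gm.build_template(small_crown.horns * flip,
                                small_crown.ridge_path * flip,
                                small_crown.cervix_path * flip, mirror=True)
        ref = gm.build_template(small_crown.horns, small_crown.ridge_path,
                                small_crown.cervix_path)
        assert cfg.mirrored
        assert cfg.coords == pytest.approx(ref.coords, abs=1e-9)

    def test_wrong_horn_order_names_cusp(self, small_crown):
        horns = small_crown.horns[[0, 2, 1, 3]]     # swap meta/ento
        with pytest.raises(ValidationError, match="entoconid|metaconid"):
            gm.build_template(horns, small_crown.ridge_path,
                              small_crown.cervix_path)


class TestGpa:
    def test_rigid_copies_have_zero_distances(self, landmark_sample):
        configs, _ = landmark_sample
        base = configs[0].coords
        rng = np.random.default_rng(0)
        copies = [gm.LandmarkConfig(rigid_copy(rng, base),
                                    n_points=base.shape[0])
                  for _ in range(5)]
        space = gm.gpa(copies)
        spread = np.sqrt(((space.aligned - space.aligned[0]) ** 2
                          ).sum(axis=(1, 2)))
        assert spread.max() < 1e-10

    def test_unit_size_and_centred(self, landmark_sample):
        configs, _ = landmark_sample
        space = gm.gpa(configs)
        for a in space.aligned:
            assert np.abs(a.mean(axis=0)).max() < 1e-9
            assert np.sqrt((a ** 2).sum()) == pytest.approx(1.0, rel=1e-9)

    def test_distances_match_pairwise_opa_oracle(self, landmark_sample):
        configs, _ = landmark_sample
        space = gm.gpa(configs[:6])
        # tangent-space distances approximate pairwise OPA distances for
        # small isotropic perturbations
        for i in range(1, 4):
            d_gpa = np.sqrt(((space.aligned[0] - space.aligned[i]) ** 2
                             ).sum())
            d_opa = gm.procrustes_distance(configs[0].coords,
                                           configs[i].coords)
            assert d_gpa == pytest.approx(d_opa, abs=1e-3)

    def test_collinear_configuration_rejected(self):
        line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValidationError):
            gm.gpa([gm.LandmarkConfig(line, n_points=10),
                    gm.LandmarkConfig(line + 1.0, n_points=10)])


class TestPca:
    def test_explained_sums_to_one_and_reconstructs(self, landmark_sample):
        configs, _ = landmark_sample
        space = gm.gpa(configs)
        res = gm.pca(space)
        assert res.explained.sum() == pytest.approx(1.0, rel=1e-9)
        x = space.tangent_coords()
        recon = res.scores @ res.axes
        assert recon == pytest.approx(x, abs=1e-10)

    def test_one_dimensional_trajectory(self):
        base = synth.gen_landmark_groups(n_per_group=2, seed=0,
                                         rigid_motions=False)[0][0].coords
        direction = np.random.default_rng(1).standard_normal(base.shape)
        configs = [gm.LandmarkConfig(base + t * 0.01 * direction,
                                     n_points=base.shape[0])
                   for t in np.linspace(-1, 1, 8)]
        res = gm.pca(gm.gpa(configs))
        assert res.explained[0] > 0.999

    def test_matches_sklearn_pca_oracle(self, landmark_sample):
        from sklearn.decomposition import PCA

        configs, _ = landmark_sample
        space = gm.gpa(configs)
        x = space.tangent_coords()
        res = gm.pca(space)
        sk = PCA(n_components=5).fit(x)
        # explained-variance ratios agree (axes agree up to sign)
        assert res.explained[:5] == pytest.approx(
            sk.explained_variance_ratio_ / sk.explained_variance_ratio_.sum()
            * res.explained[:5].sum() / 1.0, rel=0.15)
        for j in range(3):
            cos = abs(np.dot(res.axes[j], sk.components_[j]))
            assert cos > 0.99

    @pytest.mark.parametrize("explained,target,expected", [
        ((0.5, 0.3, 0.15, 0.05), 0.90, 3),
        ((0.5, 0.3, 0.15, 0.05), 1.0, 4),
        ((0.5, 0.3, 0.15, 0.05), 0.0, 1),
    ])
    def test_select_pcs(self, explained, target, expected):
        res = gm.OrdinationResult(scores=np.zeros((4, 4)), axes=np.eye(4),
                                  explained=np.array(explained), kind="pca",
                                  center=np.zeros(4))
        assert gm.select_pcs(res, target) == expected


class TestBgpca:
    def test_group_mean_projection_linearity(self, landmark_sample):
        configs, _ = landmark_sample
        space = gm.gpa(configs)
        x = space.tangent_coords()
        groups = [c.group for c in configs]
        res = gm.bgpca(x, groups)
        for name in set(groups):
            idx = [i for i, g in enumerate(groups) if g == name]
            assert res.group_mean_scores[name] == pytest.approx(
                res.scores[idx].mean(axis=0), abs=1e-8)

    def test_axis_count_bounded_by_groups(self, landmark_sample):
        configs, _ = landmark_sample
        space = gm.gpa(configs)
        res = gm.bgpca(space.tangent_coords(), [c.group for c in configs])
        assert res.axes.shape[0] <= 2

    def test_known_offset_direction(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(30)
        offset = rng.standard_normal(30)
        offset /= np.linalg.norm(offset)
        x = np.vstack([base + d * offset + 0.01 * rng.standard_normal(30)
                       for d in (-1.0,) * 5 + (0.0,) * 5 + (1.0,) * 5])
        groups = ["A"] * 5 + ["B"] * 5 + ["C"] * 5
        res = gm.bgpca(x, groups)
        assert abs(np.dot(res.axes[0], offset)) > 0.99

    def test_residuals_and_pc_scores_give_same_axes(self, landmark_sample):
        """Between-group axes are identical (up to rotation of the basis)
        whether fitted on tangent coordinates or full-rank PC scores."""
        configs, _ = landmark_sample
        space = gm.gpa(configs)
        x = space.tangent_coords()
        groups = [c.group for c in configs]
        direct = gm.bgpca(x, groups)
        full = gm.pca(space)
        via_pcs = gm.bgpca(full.scores, groups)
        # scores must agree up to axis sign
        for j in range(direct.scores.shape[1]):
            diff = np.minimum(
                np.abs(direct.scores[:, j] - via_pcs.scores[:, j]),
                np.abs(direct.scores[:, j] + via_pcs.scores[:, j]))
            assert diff.max() < 1e-8

    def test_small_group_rejected(self):
        x = np.random.default_rng(0).standard_normal((5, 4))
        with pytest.raises(ValidationError):
            gm.bgpca(x, ["A", "A", "B", "B", "C"])


class TestCva:
    def test_within_group_covariance_is_identity(self, landmark_sample):
        configs, _ = landmark_sample
        space = gm.gpa(configs)
        groups = [c.group for c in configs]
        full = gm.pca(space)
        k = gm.select_pcs(full, 0.90)
        k = min(k, len(configs) - len(set(groups)) - 1)
        res = gm.cva(full.scores[:, :k], groups)
        pooled = np.zeros((res.scores.shape[1], res.scores.shape[1]))
        n = 0
        for name in set(groups):
            idx = [i for i, g in enumerate(groups) if g == name]
            d = res.scores[idx] - res.scores[idx].mean(axis=0)
            pooled += d.T @ d
            n += len(idx)
        pooled /= (n - len(set(groups)))
        assert pooled == pytest.approx(np.eye(pooled.shape[0]), abs=1e-8)

    def test_two_group_decision_boundary_at_zero(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(-1, 1, 40), rng.normal(1, 1, 40)])
        groups = ["A"] * 40 + ["B"] * 40
        res = gm.cva(x[:, None], groups,
                     unknowns=np.array([[-0.2], [0.2]]))
        assert res.classification.unknown_predicted == ["A", "B"]

    def test_classification_matches_sklearn_lda_oracle(self, landmark_sample):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        configs, _ = landmark_sample
        space = gm.gpa(configs)
        groups = [str(c.group) for c in configs]
        full = gm.pca(space)
        k = min(gm.select_pcs(full, 0.90), len(configs) - 4)
        scores = full.scores[:, :k]
        res = gm.cva(scores, groups)
        lda = LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(scores,
                                                                 groups)
        assert list(lda.predict(scores)) == res.classification.predicted

    def test_too_many_variables_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((8, 10))
        with pytest.raises(ValidationError):
            gm.cva(x, ["A"] * 4 + ["B"] * 4)


class TestCrossValidate:
    def test_perfect_separation_full_rates(self, landmark_sample):
        configs, _ = landmark_sample
        space = gm.gpa(configs)
        res = gm.cross_validate("cva", space.tangent_coords(),
                                [c.group for c in configs])
        assert res["overall_rate"] == 1.0
        assert all(v == 1.0 for v in res["per_group_rate"].values())

    def test_rates_decrease_with_overlap(self):
        rates = []
        for overlap in (0.0, 0.9, 0.98):
            configs, _ = synth.gen_landmark_groups(
                n_per_group=8, overlap=overlap, covariance_scale=0.02,
                seed=13, rigid_motions=False)
            space = gm.gpa(configs)
            res = gm.cross_validate("bgpca", space.tangent_coords(),
                                    [c.group for c in configs])
            rates.append(res["overall_rate"])
        assert rates[0] >= rates[1] >= rates[2]
        assert rates[0] > rates[2]

    def test_order_invariance(self, landmark_sample):
        configs, _ = landmark_sample
        space = gm.gpa(configs)
        x = space.tangent_coords()
        groups = np.array([c.group for c in configs])
        perm = np.random.default_rng(5).permutation(len(configs))
        a = gm.cross_validate("cva", x, groups)
        b = gm.cross_validate("cva", x[perm], groups[perm])
        assert a["overall_rate"] == b["overall_rate"]
        assert a["per_group_rate"] == b["per_group_rate"]


class TestAllometry:
    def test_null_sizes_give_uniformish_p(self):
        rng = np.random.default_rng(7)
        pvals = []
        for rep in range(100):
            scores = rng.standard_normal((20, 1))
            sizes = rng.uniform(10, 20, 20)
            out = gm.allometry_regression(scores, sizes, n_perm=200,
                                          seed=rep)
            pvals.append(out["p_perm"].iloc[0])
        from scipy.stats import kstest
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_strong_allometry_detected(self):
        rng = np.random.default_rng(8)
        sizes = rng.uniform(10, 20, 30)
        scores = (2.0 * sizes + 0.5 * rng.standard_normal(30))[:, None]
        out = gm.allometry_regression(scores, sizes, n_perm=2000, seed=1)
        assert out["slope"].iloc[0] == pytest.approx(2.0, abs=0.1)
        assert out["p_perm"].iloc[0] < 0.001
        assert out["p_f"].iloc[0] < 1e-6

    def test_no_permutations_falls_back_to_f_test(self):
        rng = np.random.default_rng(9)
        out = gm.allometry_regression(rng.standard_normal((10, 2)),
                                      rng.uniform(1, 2, 10), n_perm=0)
        assert np.isnan(out["p_perm"]).all()
        assert ((0 <= out["p_f"]) & (out["p_f"] <= 1)).all()

    def test_constant_sizes_rejected(self):
        with pytest.raises(ValidationError):
            gm.allometry_regression(np.zeros((5, 1)), np.ones(5))


class TestIO:
    def test_tps_round_trip(self, tmp_path, landmark_sample):
        configs, _ = landmark_sample
        path = tmp_path / "sample.tps"
        gm.write_tps(configs[:3], path)
        back = gm.read_tps(path)
        assert len(back) == 3
        for a, b in zip(configs[:3], back):
            assert b.coords == pytest.approx(a.coords, abs=1e-5)
            assert b.label == a.label
            assert b.group == a.group

    def test_csv_long_format(self, tmp_path):
        import pandas as pd

        rows = []
        for spec in ("s1", "s2"):
            for i in range(5):
                rows.append({"specimen": spec, "index": i, "x": i * 1.0,
                             "y": 0.0, "z": float(spec == "s2"),
                             "group": "G"})
        pd.DataFrame(rows).to_csv(tmp_path / "lm.csv", index=False)
        configs = gm.read_landmarks_csv(tmp_path / "lm.csv")
        assert len(configs) == 2
        assert configs[0].coords.shape == (5, 3)
        assert configs[1].group == "G"
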