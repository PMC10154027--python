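"""PCA projection, smoothness ratios and paired comparisons."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy import stats as sps

from metapom.representations import RepresentationTable
from metapom.smoothness import (
    PCAConfig,
    paired_t_test,
    pca_project,
    explained_variance_fractions,
    plot_pathway,
    score_pathways,
    smoothness_ratio,
    view_coordinates,
)
from metapom.synthetic import GeneratorConfig, make_embedding_table, make_metabolome, smooth_table_along_pathways


def random_table(rng, n=12, width=16):
    return RepresentationTable(
        "t", "correlation_centered", {f"k{i}": rng.normal(size=width) for i in range(n)}
    )


class TestPCAProject:
    def test_rank_one_data_on_first_component(self):
        rng = np.random.default_rng(0)
        direction = rng.normal(size=256)
        table = RepresentationTable(
            "t", "correlation_centered",
            {f"k{i}": (i * 1.0) * direction for i in range(6)},
        )
        keys = sorted(table.vectors)
        fractions = explained_variance_fractions(table, keys, PCAConfig(n_components=4))
        assert fractions[0] == pytest.approx(1.0)
        proj = pca_project(table, keys, PCAConfig(n_components=4))
        for k in keys:
            assert np.allclose(proj[k][1:], 0.0, atol=1e-9)

    def test_distances_preserved_at_full_rank(self):
        rng = np.random.default_rng(1)
        table = random_table(rng, n=10, width=16)
        keys = sorted(table.vectors)
        proj = pca_project(table, keys, PCAConfig(n_components=9))  # n-1 >= rank of centered data
        mat = np.vstack([table.vectors[k] for k in keys])
        pmat = np.vstack([proj[k] for k in keys])
        for i in range(len(keys)):
            for j in range(len(keys)):
                orig = np.linalg.norm(mat[i] - mat[j])
                compressed = np.linalg.norm(pmat[i] - pmat[j])
                assert compressed == pytest.approx(orig, rel=1e-9)

    def test_explained_variance_monotone(self):
        rng = np.random.default_rng(2)
        table = random_table(rng, n=20, width=10)
        fr = explained_variance_fractions(table, sorted(table.vectors), PCAConfig(n_components=8))
        assert fr.sum() <= 1.0 + 1e-12
        assert np.all(np.diff(fr) <= 1e-12)

    def test_too_few_keys(self):
        table = random_table(np.random.default_rng(0), n=5)
        with pytest.raises(ValueError):
            pca_project(table, ["k0", "k1"])


class TestSmoothnessRatio:
    def test_collinear_is_one(self):
        assert smoothness_ratio((0, 0), (1, 0), (2, 0)) == pytest.approx(1.0)

    def test_right_angle_detour(self):
        assert smoothness_ratio((0, 0), (1, 1), (2, 0)) == pytest.approx(1 / np.sqrt(2))

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pts = rng.normal(size=(3, 3))
            base = smoothness_ratio(*pts)
            rot = Rotation.random(rng=rng).as_matrix()
            shift = rng.normal(size=3)
            moved = pts @ rot.T + shift
            assert abs(smoothness_ratio(*moved) - base) < 1e-9

    def test_bounded_by_one_on_random_triplets(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            a, b, c = rng.normal(size=(3, 4))
            assert smoothness_ratio(a, b, c) <= 1.0 + 1e-12

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            smoothness_ratio((1, 1), (0, 0), (1, 1))


class TestScorePathways:
    def test_record_count_endpoint_mode(self):
        rng = np.random.default_rng(5)
        table = random_table(rng, n=5)
        path = sorted(table.vectors)
        records = score_pathways({"p": path}, table)
        assert len(records) == 3
        assert all(r.start == path[0] and r.end == path[-1] for r in records)

    def test_consecutive_mode_triplets(self):
        rng = np.random.default_rng(5)
        table = random_table(rng, n=5)
        path = sorted(table.vectors)
        records = score_pathways({"p": path}, table, mode="consecutive")
        assert len(records) == 3
        assert records[0].start == path[0] and records[0].end == path[2]

    def test_collinear_ordered_pathway_scores_one(self):
        direction = np.linspace(1, 2, 16)
        offset = np.random.default_rng(0).normal(size=16)
        table = RepresentationTable(
            "t", "correlation_centered",
            {f"k{i}": offset + i * direction for i in range(5)},
        )
        records = score_pathways({"p": sorted(table.vectors)}, table)
        for r in records:
            assert r.smoothness == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_from_projection(self):
        rng = np.random.default_rng(6)
        table = random_table(rng, n=8)
        keys = sorted(table.vectors)
        pathways = {"p1": keys[:4], "p2": keys[4:]}
        cfg = PCAConfig(n_components=4)
        records = score_pathways(pathways, table, cfg)
        proj = pca_project(table, sorted(keys), cfg)
        for rec in records:
            a, x, z = proj[rec.start], proj[rec.intermediate], proj[rec.end]
            direct = np.linalg.norm(z - a)
            through = np.linalg.norm(x - a) + np.linalg.norm(z - x)
            assert rec.smoothness == pytest.approx(direct / through)

    def test_missing_member_named(self):
        table = random_table(np.random.default_rng(0), n=4)
        with pytest.raises(KeyError, match="ghost"):
            score_pathways({"p": ["k0", "ghost", "k1"]}, table)

    def test_whole_pipeline_rotation_invariance(self):
        rng = np.random.default_rng(7)
        table = random_table(rng, n=10, width=6)
        keys = sorted(table.vectors)
        pathways = {"p": keys[:6]}
        base = [r.smoothness for r in score_pathways(pathways, table, PCAConfig(n_components=5))]
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        shift = rng.normal(size=6)
        rotated = RepresentationTable(
            "t", "correlation_centered", {k: v @ q.T + shift for k, v in table.vectors.items()}
        )
        moved = [r.smoothness for r in score_pathways(pathways, rotated, PCAConfig(n_components=5))]
        assert np.allclose(base, moved, atol=1e-9)

    def test_smoothed_table_discrimination(self):
        cfg = GeneratorConfig(seed=1, n_metabolites=150, rho=1.0, noise_sd=0.0)
        met = make_metabolome(cfg)
        table = make_embedding_table(met, cfg)
        pathways = {f"p{i}": p for i, p in enumerate(met.pathways) if len(p) >= 4}
        smoothed = smooth_table_along_pathways(table, list(pathways.values()), weight=0.9)
        rec_r = score_pathways(pathways, table)
        rec_s = score_pathways(pathways, smoothed)
        assert len(rec_r) >= 30
        res = paired_t_test(
            [r.smoothness for r in rec_s], [r.smoothness for r in rec_r], sided="greater"
        )
        assert res.mean_diff > 0
        assert res.p_value < 0.01


class TestPairedTTest:
    def test_closed_form_example(self):
        b = np.zeros(3)
        a = np.array([1.0, 2.0, 3.0])
        res = paired_t_test(a, b)
        assert res.t_statistic == pytest.approx(2 / (1 / np.sqrt(3)))
        assert res.n == 3

    def test_matches_scipy_two_sided(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=(2, 20))
        res = paired_t_test(a, b)
        ref = sps.ttest_rel(a, b)
        assert res.t_statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_constant_shift_degenerate(self):
        b = np.arange(10.0)
        with pytest.raises(ValueError):
            paired_t_test(b + 1.0, b)

    def test_single_perturbation_well_defined(self):
        b = np.arange(10.0)
        a = b.copy()
        a[3] += 0.5
        res = paired_t_test(a, b)
        assert np.isfinite(res.t_statistic)
        assert 0 < res.p_value < 1


class TestViewCoordinates:
    def test_matches_projection_columns(self):
        rng = np.random.default_rng(9)
        table = random_table(rng, n=6)
        keys = sorted(table.vectors)
        proj = pca_project(table, keys, PCAConfig(n_components=4))
        coords = view_coordinates(proj, keys)
        assert len(coords) == 6
        for (k, x, y) in coords:
            assert x == proj[k][0] and y == proj[k][1]

    def test_plot_smoke(self, tmp_path):
        rng = np.random.default_rng(10)
        table = random_table(rng, n=6)
        keys = sorted(table.vectors)
        proj = pca_project(table, keys, PCAConfig(n_components=2))
        out = tmp_path / "traj.png"
        plot_pathway(proj, keys, out)
        assert out.stat().st_size > 0
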