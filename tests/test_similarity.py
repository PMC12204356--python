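"""GDT-TS / TM-score behaviour and pool similarity matrices."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from foldpool import (
    ModelPool,
    ScoreParams,
    gdt_ts,
    make_pool,
    make_reference,
    pairwise_matrix,
    tm_score,
)
from foldpool.similarity import (
    SimilarityMatrix,
    gdt_ts_components,
    tm_d0,
    tm_score_from_distances,
)

from conftest import build_model, straight_trace


def gdt_enumeration_oracle(mob: np.ndarray, ref: np.ndarray,
                           thresholds=(1.0, 2.0, 4.0, 8.0)) -> dict[float, float]:
    """Independent GDT oracle: superimpose on every subset of size >= 3 with
    scipy's align_vectors and count residues within each threshold."""
    n = len(ref)
    out = {}
    dists = []
    for k in range(3, n + 1):
        for c in combinations(range(n), k):
            s = np.array(c)
            ca, cb = ref[s].mean(0), mob[s].mean(0)
            rot, _ = Rotation.align_vectors(ref[s] - ca, mob[s] - cb)
            moved = rot.apply(mob - cb) + ca
            dists.append(np.linalg.norm(moved - ref, axis=1))
    D = np.array(dists)
    for d in thresholds:
        out[d] = int((D <= d).sum(axis=1).max()) / n
    return out


class TestGdtTs:
    def test_identical_models_score_one(self):
        ref = make_reference(24, 0)
        assert gdt_ts(ref, ref) == 1.0

    def test_rigid_motion_invariance(self):
        ref = make_reference(30, 1)
        rot = Rotation.from_euler("xyz", [0.3, -1.2, 2.0]).as_matrix()
        moved = ref.transformed(rot, np.array([10.0, -4.0, 7.0]))
        assert abs(gdt_ts(moved, ref) - 1.0) < 1e-6

    def test_split_straight_trace_matches_oracle(self):
        """Half-displaced collinear trace: enumeration oracle gives the truth."""
        ref_c = straight_trace(10)
        mob_c = ref_c.copy()
        mob_c[5:, 1] += 20.0
        a = build_model("a", ref_c)
        b = build_model("b", mob_c)
        comp = gdt_ts_components(b, a)
        oracle = gdt_enumeration_oracle(mob_c, ref_c)
        for d in (1.0, 2.0, 4.0, 8.0):
            assert comp[d] == pytest.approx(oracle[d], abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 5, 11])
    def test_small_instance_oracle_parity(self, seed):
        ref = make_reference(8, seed)
        mob = ref.ca_coords + np.random.default_rng(1000 + seed).normal(scale=1.0, size=(8, 3))
        b = build_model("b", mob, sequence=ref.sequence)
        comp = gdt_ts_components(b, ref)
        oracle = gdt_enumeration_oracle(mob, ref.ca_coords)
        for d in (1.0, 2.0, 4.0, 8.0):
            assert comp[d] == pytest.approx(oracle[d], abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_threshold_fractions_monotone(self, seed):
        ref = make_reference(20, seed)
        mob = ref.ca_coords + np.random.default_rng(200 + seed).normal(scale=2.0, size=(20, 3))
        comp = gdt_ts_components(build_model("b", mob, sequence=ref.sequence), ref)
        vals = [comp[d] for d in (1.0, 2.0, 4.0, 8.0)]
        assert all(x <= y + 1e-12 for x, y in zip(vals, vals[1:]))

    def test_strictly_below_one_when_displaced(self):
        ref = make_reference(20, 3)
        mob = ref.ca_coords.copy()
        mob[-1] += 30.0  # far beyond the largest threshold
        assert gdt_ts(build_model("b", mob, sequence=ref.sequence), ref) < 1.0


class TestTmScore:
    def test_identical_models_score_one(self):
        ref = make_reference(40, 2)
        assert tm_score(ref, ref) == pytest.approx(1.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        ref = make_reference(40, 2)
        rot = Rotation.from_euler("zxz", [1.0, 0.5, -0.7]).as_matrix()
        moved = ref.transformed(rot, np.array([-3.0, 8.0, 1.0]))
        assert abs(tm_score(moved, ref) - 1.0) < 1e-6

    def test_d0_floor_at_short_lengths(self):
        # raw d0 = 1.24 * (15-15)^(1/3) - 1.8 = -1.8 -> floored
        assert tm_d0(15) == 0.5
        assert tm_d0(200) > 0.5

    def test_all_distances_at_d0_give_half(self):
        L = 16
        assert tm_score_from_distances(np.full(L, tm_d0(L)), L) == pytest.approx(0.5)

    def test_constructed_d0_displacement_reaches_half(self):
        """Paired planar points displaced +/- d0 along z: the identity is the
        least-squares superposition, under which every distance equals d0."""
        L = 16
        d0 = tm_d0(L)
        rng = np.random.default_rng(5)
        half = rng.normal(scale=6, size=(L // 2, 3))
        half[:, 2] = 0.0
        ref_c = np.vstack([half, -half])
        disp = np.concatenate([np.repeat(d0, L // 4), np.repeat(-d0, L // 4)] * 2)
        mob_c = ref_c.copy()
        mob_c[:, 2] += disp
        score = tm_score(build_model("b", mob_c), build_model("a", ref_c))
        assert score >= 0.5 - 1e-9

    def test_missing_residues_contribute_zero(self):
        ref = make_reference(30, 7)
        partial = build_model(
            "p",
            ref.ca_coords[:20],
            sequence=ref.sequence[:20],
            residue_numbers=np.arange(1, 21),
        )
        assert tm_score(partial, ref, lref=30) == pytest.approx(20 / 30, abs=1e-9)

    def test_noise_degrades_score_monotonically(self):
        """Mean TM over replicates decreases as coordinate noise grows."""
        ref = make_reference(30, 11)
        sigmas = [0.5, 1.0, 2.0, 4.0]
        means = []
        for si, sigma in enumerate(sigmas):
            scores = []
            for rep in range(50):
                rng = np.random.default_rng(10_000 + 97 * si + rep)
                mob = ref.ca_coords + rng.normal(scale=sigma, size=ref.ca_coords.shape)
                scores.append(tm_score(build_model("b", mob, sequence=ref.sequence), ref))
            means.append(np.mean(scores))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestPairwiseMatrix:
    def test_identical_pool_gives_ones(self):
        ref = make_reference(20, 0)
        models = [build_model(f"m{i}", ref.ca_coords, sequence=ref.sequence) for i in range(3)]
        pool = ModelPool(target_id="SYN", models=models, reference_length=20)
        mat = pairwise_matrix(pool, metric="tm")
        np.testing.assert_allclose(mat.values, 1.0, atol=1e-9)

    def test_two_model_offdiagonal_equals_pair_score(self):
        ref = make_reference(24, 4)
        mob = ref.ca_coords + np.random.default_rng(9).normal(scale=1.0, size=(24, 3))
        m0 = build_model("m0", ref.ca_coords, sequence=ref.sequence)
        m1 = build_model("m1", mob, sequence=ref.sequence)
        pool = ModelPool(target_id="SYN", models=[m0, m1], reference_length=24)
        mat = pairwise_matrix(pool, metric="tm")
        assert mat.values[0, 1] == pytest.approx(tm_score(m0, m1, lref=24), abs=1e-9)

    def test_two_cluster_pool_separates(self):
        pool, truth = make_pool_with_two_clusters()
        mat = pairwise_matrix(pool, metric="tm")
        labels = truth.labels
        within = [mat.values[i, j] for i in range(len(labels)) for j in range(i + 1, len(labels))
                  if labels[i] == labels[j]]
        between = [mat.values[i, j] for i in range(len(labels)) for j in range(i + 1, len(labels))
                   if labels[i] != labels[j]]
        assert min(within) > max(between)

    def test_single_model_pool_rejected(self):
        ref = make_reference(20, 0)
        pool = ModelPool(target_id="SYN", models=[ref], reference_length=20)
        with pytest.raises(ValueError, match=">= 2"):
            pairwise_matrix(pool)

    def test_matrix_roundtrip(self, tmp_path):
        pool, _ = make_pool_with_two_clusters()
        mat = pairwise_matrix(pool, metric="tm")
        path = tmp_path / "sim.tsv"
        mat.write(path)
        back = SimilarityMatrix.read(path)
        assert back.model_ids == mat.model_ids
        np.testing.assert_allclose(back.values, mat.values, atol=1e-5)


def make_pool_with_two_clusters():
    from foldpool import PoolRecipe

    recipe = PoolRecipe(L=30, n_models=6, cluster_fractions=(0.5, 0.5),
                        cluster_displacement=10.0, noise_sigma=0.3, seed=21)
    return make_pool(recipe)
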