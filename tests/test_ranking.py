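"""PSS, score combination, K-means clustering, and top-5 selection strategies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from foldpool import (
    ModelPool,
    PoolRecipe,
    QAScoreTable,
    SelectOptions,
    cluster_models,
    combine,
    make_pool,
    make_reference,
    normalize,
    pairwise_matrix,
    pss,
    select_top5,
)
from foldpool.similarity import SimilarityMatrix

from conftest import build_model


def sim_matrix(ids: list[str], offdiag: dict[tuple[str, str], float]) -> SimilarityMatrix:
    n = len(ids)
    vals = np.eye(n)
    for (a, b), v in offdiag.items():
        i, j = ids.index(a), ids.index(b)
        vals[i, j] = vals[j, i] = v
    return SimilarityMatrix(model_ids=ids, values=vals)


def dummy_pool(ids: list[str], generators: dict[str, str] | None = None) -> ModelPool:
    ref = make_reference(20, 0)
    models = [
        build_model(i, ref.ca_coords, sequence=ref.sequence,
                    generator=(generators or {}).get(i, "AF2"))
        for i in ids
    ]
    return ModelPool(target_id="SYN", models=models, reference_length=20)


class TestPss:
    def test_identical_pool_all_ones(self):
        mat = sim_matrix(["a", "b", "c"], {("a", "b"): 1.0, ("a", "c"): 1.0, ("b", "c"): 1.0})
        assert pss(mat).tolist() == [1.0, 1.0, 1.0]

    def test_three_model_arithmetic(self):
        mat = sim_matrix(["m1", "m2", "m3"],
                         {("m1", "m2"): 0.8, ("m1", "m3"): 0.2, ("m2", "m3"): 0.4})
        np.testing.assert_allclose(pss(mat).to_numpy(), [0.5, 0.6, 0.3])

    def test_two_models_share_the_pair_value(self):
        mat = sim_matrix(["a", "b"], {("a", "b"): 0.7})
        assert pss(mat).tolist() == [0.7, 0.7]


class TestNormalizeCombine:
    def test_plddt_rescaled_others_passed_through(self):
        t = QAScoreTable(df=pd.DataFrame({"plddt": [90.0], "gate": [0.8]}, index=["m"]))
        n = normalize(t)
        assert n.df.loc["m", "plddt"] == pytest.approx(0.9)
        assert n.df.loc["m", "gate"] == pytest.approx(0.8)
        assert normalize(n).df.loc["m", "plddt"] == pytest.approx(0.9)  # idempotent

    def test_empty_column_warns(self):
        t = QAScoreTable(df=pd.DataFrame({"plddt": [np.nan], "gate": [0.5]}, index=["m"]))
        with pytest.warns(UserWarning, match="empty"):
            normalize(t)

    def test_equal_weight_mean(self):
        t = normalize(QAScoreTable(df=pd.DataFrame(
            {"plddt": [90.0], "gate": [0.8]}, index=["m"])))
        assert combine(t, ["gate", "plddt"]).loc["m"] == pytest.approx(0.85)

    def test_degenerate_weights(self):
        t = QAScoreTable(df=pd.DataFrame({"a": [0.3, 0.6], "b": [0.9, 0.1]},
                                         index=["m1", "m2"]), normalized=True)
        np.testing.assert_allclose(combine(t, ["a", "b"], [1.0, 0.0]).to_numpy(), [0.3, 0.6])
        np.testing.assert_allclose(combine(t, ["a"]).to_numpy(), [0.3, 0.6])

    def test_missing_scores_become_nan(self):
        t = QAScoreTable(df=pd.DataFrame({"a": [0.3, np.nan], "b": [0.9, 0.1]},
                                         index=["m1", "m2"]), normalized=True)
        out = combine(t, ["a", "b"])
        assert np.isnan(out.loc["m2"]) and out.loc["m1"] == pytest.approx(0.6)

    def test_unknown_column_rejected(self):
        t = QAScoreTable(df=pd.DataFrame({"a": [0.3]}, index=["m"]), normalized=True)
        with pytest.raises(ValueError, match="nope"):
            combine(t, ["nope"])


class TestClustering:
    def test_two_identical_groups_recovered(self):
        ids = ["a", "b", "c", "d"]
        mat = sim_matrix(ids, {("a", "b"): 1.0, ("c", "d"): 1.0,
                               ("a", "c"): 0.2, ("a", "d"): 0.2,
                               ("b", "c"): 0.2, ("b", "d"): 0.2})
        cl = cluster_models(mat, k=2, seed=0)
        assert cl.labels[0] == cl.labels[1] and cl.labels[2] == cl.labels[3]
        assert cl.labels[0] != cl.labels[2]

    def test_all_identical_degenerates_to_one_cluster(self):
        ids = ["a", "b", "c"]
        mat = sim_matrix(ids, {(x, y): 1.0 for x in ids for y in ids if x < y})
        with pytest.warns(UserWarning):
            cl = cluster_models(mat, k="auto", seed=0)
        assert cl.k == 1

    def test_silhouette_finds_three_generated_clusters(self):
        recipe = PoolRecipe(L=30, n_models=12, cluster_fractions=(0.34, 0.33, 0.33),
                            cluster_displacement=10.0, noise_sigma=0.3, seed=5)
        pool, truth = make_pool(recipe)
        mat = pairwise_matrix(pool, metric="tm")
        cl = cluster_models(mat, k="auto", seed=0)
        assert cl.k == 3
        assert adjusted_rand_score(truth.labels, cl.labels) == 1.0

    def test_deterministic_given_seed(self):
        recipe = PoolRecipe(L=30, n_models=8, cluster_fractions=(0.5, 0.5), seed=6)
        pool, _ = make_pool(recipe)
        mat = pairwise_matrix(pool, metric="tm")
        a = cluster_models(mat, k=2, seed=3)
        b = cluster_models(mat, k=2, seed=3)
        assert np.array_equal(a.labels, b.labels)


def six_model_setup(af3_id: str):
    ids = [f"m{i}" for i in range(1, 7)]
    generators = {i: "AF2" for i in ids}
    generators[af3_id] = "AF3"
    pool = dummy_pool(ids, generators)
    table = QAScoreTable(df=pd.DataFrame(
        {"plddt": [95.0, 94.0, 93.0, 92.0, 91.0, 90.0]}, index=ids))
    mat = sim_matrix(ids, {("m1", "m2"): 0.9, **{(a, b): 0.5 for a in ids for b in ids
                                                 if a < b and (a, b) != ("m1", "m2")}})
    return pool, table, mat


class TestSelectTop5:
    def test_plddt_diverse_skips_similar_model(self):
        pool, table, mat = six_model_setup(af3_id="m6")
        res = select_top5("plddt_diverse", pool, table, mat)
        assert res.top5 == ["m1", "m3", "m4", "m5", "m6"]
        assert res.top1 == "m1"

    def test_forced_af3_replacement_fires(self):
        pool, table, mat = six_model_setup(af3_id="m2")
        res = select_top5("plddt_diverse", pool, table, mat)
        assert res.top5 == ["m1", "m3", "m4", "m5", "m2"]
        assert "forced AF3" in res.rationale[-1]

    def test_combined_llm_slot_order(self):
        ids = ["m1", "m2", "m3", "m4"]
        pool = dummy_pool(ids)
        table = QAScoreTable(df=pd.DataFrame(
            {
                "af3_ranking": [0.9, 0.5, 0.4, 0.3],
                # mean(gate, plddt/100) ordering: m2 > m3 > m1 > m4
                "gate": [0.50, 0.90, 0.80, 0.30],
                "plddt": [50.0, 90.0, 80.0, 30.0],
            },
            index=ids,
        ))
        mat = sim_matrix(ids, {(a, b): 0.5 for a in ids for b in ids if a < b})
        res = select_top5("combined_llm", pool, table, mat)
        assert res.top5 == ["m1", "m2", "m3", "m4"]

    def test_gate_cluster_takes_cluster_representatives(self):
        ids = ["a1", "a2", "b1", "b2"]
        pool = dummy_pool(ids, {"b2": "AF3"})
        table = QAScoreTable(df=pd.DataFrame(
            {"gate": [0.9, 0.8, 0.7, 0.6]}, index=ids))
        mat = sim_matrix(ids, {("a1", "a2"): 0.95, ("b1", "b2"): 0.95,
                               ("a1", "b1"): 0.2, ("a1", "b2"): 0.2,
                               ("a2", "b1"): 0.2, ("a2", "b2"): 0.2})
        cl = cluster_models(mat, k=2, seed=0)
        res = select_top5("gate_cluster", pool, table, mat, clustering=cl)
        # best of each cluster first (cluster order by best gate), then cycle
        assert res.top5[:2] == ["a1", "b1"]
        assert set(res.top5) == set(ids)

    def test_multicom_ensemble_slot_metrics(self):
        ids = ["m1", "m2", "m3", "m4", "m5", "m6"]
        pool = dummy_pool(ids, {"m6": "AF3"})
        table = QAScoreTable(df=pd.DataFrame(
            {
                "af3_ranking": [0.9, 0.1, 0.1, 0.1, 0.1, 0.8],
                "gate": [0.5, 0.9, 0.6, 0.6, 0.7, 0.5],
                "plddt": [50.0, 90.0, 95.0, 60.0, 70.0, 50.0],
                "gcpnet": [0.1, 0.2, 0.3, 0.9, 0.4, 0.1],
                "pss": [0.2, 0.3, 0.4, 0.5, 0.9, 0.1],
            },
            index=ids,
        ))
        mat = sim_matrix(ids, {(a, b): 0.5 for a in ids for b in ids if a < b})
        res = select_top5("multicom_ensemble", pool, table, mat)
        # slot1 mean(af3,gate): m1=0.7 highest; slot2 mean(gate,plddt): m2=0.9;
        # slot3 gate: m2 taken -> m5? gate ranks m2(0.9), m5(0.7) -> m5;
        # slot4 gcpnet: m4; slot5 pss: m5 taken -> back-fill by blend: m3
        assert res.top5 == ["m1", "m2", "m5", "m4", "m3"]

    def test_missing_required_column_is_error(self):
        pool, table, mat = six_model_setup(af3_id="m6")
        with pytest.raises(ValueError, match="gate"):
            select_top5("gate_cluster", pool, table, mat)

    def test_determinism_byte_identical(self):
        pool, table, mat = six_model_setup(af3_id="m2")
        a = select_top5("plddt_diverse", pool, table, mat)
        b = select_top5("plddt_diverse", pool, table, mat)
        assert a.top5 == b.top5 and a.rationale == b.rationale

    def test_unknown_strategy_rejected(self):
        pool, table, mat = six_model_setup(af3_id="m6")
        with pytest.raises(ValueError, match="unknown strategy"):
            select_top5("bogus", pool, table, mat)

    def test_diversity_holds_except_forced_slot(self):
        pool, table, mat = six_model_setup(af3_id="m2")
        res = select_top5("plddt_diverse", pool, table, mat,
                          opts=SelectOptions(tm_diversity_threshold=0.8))
        non_forced = res.top5[:-1]
        for i, a in enumerate(non_forced):
            for b in non_forced[i + 1:]:
                ia, ib = mat.model_ids.index(a), mat.model_ids.index(b)
                assert mat.values[ia, ib] < 0.8
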