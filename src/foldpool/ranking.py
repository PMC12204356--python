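"""Consensus scoring (PSS), QA-score combination, K-means model clustering, and
the four algorithmic top-5 selection strategies used by CASP16-style predictors.

Strategies (names follow what each ranks by, not who ran it):

* ``plddt_diverse`` — rank by global plDDT, enforce pairwise structural
  diversity (TM-score < 0.8) among the picks, force at least one AF3 model in.
* ``gate_cluster`` — rank by the GATE consensus score, pick the best-scoring
  model of each K-means structure cluster, force an AF3 model in.
* ``combined_llm`` — top-1 by the AF3 ranking score, remaining slots by the
  mean of GATE and normalized plDDT.
* ``multicom_ensemble`` — top-1 by the mean of AF3 ranking and GATE; remaining
  slots by a fixed rota of metrics (GATE+plDDT mean, GATE, GCPNet-EMA with
  EnQA fallback, PSS), back-filled from the GATE+plDDT ranking.

All ties break by lexicographic model id so results are deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .similarity import SimilarityMatrix
from .struct_model import Generator, ModelPool

logger = logging.getLogger(__name__)

__all__ = [
    "QAScoreTable",
    "Clustering",
    "SelectionResult",
    "SelectOptions",
    "STRATEGIES",
    "pss",
    "normalize",
    "combine",
    "cluster_models",
    "select_top5",
]


@dataclass
class QAScoreTable:
    """Model x method score matrix (pandas-backed); missing values allowed.

    Raw plDDT lives on [0, 100]; every other method is assumed to already be
    on [0, 1]. ``normalized`` records whether plDDT has been rescaled.
    """

    df: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        self.df = self.df.copy()
        self.df.index = self.df.index.astype(str)
        if "plddt" in self.df.columns and not self.normalized:
            col = self.df["plddt"].dropna()
            if len(col) and (col.min() < 0 or col.max() > 100):
                raise ValueError("raw plddt column must lie in [0, 100]")

    @property
    def model_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def methods(self) -> list[str]:
        return list(self.df.columns)

    def write(self, path: str | Path) -> None:
        out = self.df.copy()
        out.index.name = "model_id"
        out.to_csv(path, sep="\t", float_format="%.6f")

    @classmethod
    def read(cls, path: str | Path, *, normalized: bool = False) -> "QAScoreTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df=df, normalized=normalized)


@dataclass
class Clustering:
    """K-means labels over a pool's models."""

    model_ids: list[str]
    labels: np.ndarray
    k: int
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.model_ids),):
            raise ValueError("one label per model required")
        present = set(self.labels.tolist())
        if present != set(range(self.k)):
            raise ValueError(f"labels must cover 0..{self.k - 1} with no empty cluster")

    def members(self, label: int) -> list[str]:
        return [m for m, l in zip(self.model_ids, self.labels) if l == label]


@dataclass
class SelectionResult:
    """Top-5 pick of one strategy with per-slot provenance."""

    strategy: str
    top5: list[str]
    rationale: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.top5)) != len(self.top5):
            raise ValueError("top5 contains duplicate model ids")
        if not self.top5:
            raise ValueError("empty selection")

    @property
    def top1(self) -> str:
        return self.top5[0]

    def to_json_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "top1": self.top1,
            "top5": self.top5,
            "rationale": self.rationale,
        }


@dataclass(frozen=True)
class SelectOptions:
    """Strategy options: the TM diversity cutoff and the forced-AF3 rule."""

    tm_diversity_threshold: float = 0.8
    enforce_af3: bool = True
    n_select: int = 5


def pss(matrix: SimilarityMatrix) -> pd.Series:
    """Average pairwise similarity score: each model's mean similarity to the
    rest of the pool — the consensus quality estimate."""
    n = len(matrix.model_ids)
    if n < 2:
        raise ValueError("PSS needs at least 2 models")
    vals = (matrix.values.sum(axis=1) - np.diag(matrix.values)) / (n - 1)
    return pd.Series(vals, index=matrix.model_ids, name="pss")


def normalize(table: QAScoreTable) -> QAScoreTable:
    """Bring every column to the [0, 1] scale (plDDT divided by 100)."""
    if table.normalized:
        return table
    df = table.df.copy()
    for col in df.columns:
        if df[col].dropna().empty:
            warnings.warn(f"QA column {col!r} is empty")
    if "plddt" in df.columns:
        df["plddt"] = df["plddt"] / 100.0
    return QAScoreTable(df=df, normalized=True)


def combine(
    table: QAScoreTable,
    columns: list[str],
    weights: list[float] | None = None,
) -> pd.Series:
    """Weighted mean of named (normalized) columns per model.

    Models missing any named column get NaN and thus drop out of rankings by
    the combined score.
    """
    missing = [c for c in columns if c not in table.df.columns]
    if missing:
        raise ValueError(f"columns not in table: {missing}")
    if weights is None:
        weights = [1.0] * len(columns)
    w = np.asarray(weights, dtype=float)
    if len(w) != len(columns) or w.sum() <= 0:
        raise ValueError("weights must match columns and sum to > 0")
    sub = table.df[columns]
    vals = (sub.to_numpy(dtype=float) * w).sum(axis=1) / w.sum()
    out = pd.Series(vals, index=table.df.index, name="+".join(columns))
    out[sub.isna().any(axis=1)] = np.nan
    return out


def cluster_models(
    matrix: SimilarityMatrix,
    k: int | str = "auto",
    seed: int = 0,
) -> Clustering:
    """K-means over models embedded by their dissimilarity profiles.

    Feature vector of model i = row i of (1 - similarity matrix). With
    ``k="auto"`` the k in [2, min(10, n-1)] maximizing mean silhouette is
    chosen; a pool of (near-)identical models degenerates to k=1.
    """
    n = len(matrix.model_ids)
    if n < 2:
        raise ValueError("clustering needs >= 2 models")
    X = 1.0 - matrix.values
    if np.allclose(X, 0.0, atol=1e-9):
        warnings.warn("all models identical; returning a single cluster")
        return Clustering(model_ids=matrix.model_ids, labels=np.zeros(n, dtype=int), k=1, seed=seed)
    if k == "auto":
        best_k, best_s, best_labels = 1, -np.inf, np.zeros(n, dtype=int)
        for kk in range(2, min(10, n - 1) + 1):
            km = KMeans(n_clusters=kk, random_state=seed, n_init=10).fit(X)
            if len(set(km.labels_.tolist())) < 2:
                continue
            s = silhouette_score(X, km.labels_)
            if s > best_s:
                best_k, best_s, best_labels = kk, s, km.labels_
        if best_k == 1:
            warnings.warn("silhouette selection degenerated; returning k=1")
            return Clustering(model_ids=matrix.model_ids, labels=best_labels, k=1, seed=seed)
        labels, kk = best_labels, best_k
    else:
        kk = int(k)
        if not (1 <= kk <= n):
            raise ValueError(f"k={kk} out of range for n={n}")
        if kk == 1:
            return Clustering(model_ids=matrix.model_ids, labels=np.zeros(n, dtype=int), k=1, seed=seed)
        labels = KMeans(n_clusters=kk, random_state=seed, n_init=10).fit(X).labels_
        if len(set(labels.tolist())) < kk:
            raise ValueError("K-means produced an empty cluster; reduce k")
    # relabel clusters in order of first appearance for determinism
    remap: dict[int, int] = {}
    for l in labels:
        if int(l) not in remap:
            remap[int(l)] = len(remap)
    labels = np.array([remap[int(l)] for l in labels])
    return Clustering(model_ids=matrix.model_ids, labels=labels, k=kk, seed=seed)


def _ranked(series: pd.Series) -> list[str]:
    """Model ids by descending score; ties and NaN-exclusion deterministic."""
    s = series.dropna()
    return sorted(s.index, key=lambda m: (-s[m], m))


def _tm(matrix: SimilarityMatrix, a: str, b: str) -> float:
    ia, ib = matrix.model_ids.index(a), matrix.model_ids.index(b)
    return float(matrix.values[ia, ib])


def _force_af3(
    selected: list[str],
    rationale: list[str],
    pool: ModelPool,
    score: pd.Series,
    opts: SelectOptions,
    score_name: str,
) -> None:
    """Replace the last slot by the best-scoring AF3 model if none selected."""
    if not opts.enforce_af3:
        return
    gen = {m.model_id: m.generator for m in pool.models}
    if any(gen.get(m) == Generator.AF3 for m in selected):
        return
    af3 = [m for m in score.dropna().index if gen.get(m) == Generator.AF3 and m not in selected]
    if not af3:
        logger.info("no AF3 model available; forced-inclusion rule cannot fire")
        return
    best = sorted(af3, key=lambda m: (-score[m], m))[0]
    if len(selected) >= opts.n_select:
        dropped = selected[-1]
        selected[-1] = best
        note = f"slot{len(selected)}: {best} forced AF3 inclusion (by {score_name}), replacing {dropped}"
    else:
        selected.append(best)
        note = f"slot{len(selected)}: {best} forced AF3 inclusion (by {score_name})"
    logger.info(note)
    if len(rationale) >= len(selected):
        rationale[len(selected) - 1] = note
    else:
        rationale.append(note)


def _select_plddt_diverse(
    pool: ModelPool, table: QAScoreTable, matrix: SimilarityMatrix, opts: SelectOptions
) -> SelectionResult:
    ranked = _ranked(table.df["plddt"])
    if not ranked:
        raise ValueError("plddt column has no usable scores")
    selected = [ranked[0]]
    rationale = [f"slot1: {ranked[0]} top plddt"]
    for m in ranked[1:]:
        if len(selected) >= opts.n_select:
            break
        tms = [_tm(matrix, m, s) for s in selected]
        if all(t < opts.tm_diversity_threshold for t in tms):
            selected.append(m)
            rationale.append(
                f"slot{len(selected)}: {m} next plddt with TM<"
                f"{opts.tm_diversity_threshold} to all selected"
            )
        else:
            logger.info("diversity skip: %s (max TM %.3f)", m, max(tms))
    _force_af3(selected, rationale, pool, table.df["plddt"], opts, "plddt")
    return SelectionResult(strategy="plddt_diverse", top5=selected, rationale=rationale)


def _select_gate_cluster(
    pool: ModelPool,
    table: QAScoreTable,
    matrix: SimilarityMatrix,
    clustering: Clustering,
    opts: SelectOptions,
) -> SelectionResult:
    gate = table.df["gate"]
    per_cluster = {c: _ranked(gate[gate.index.isin(clustering.members(c))]) for c in range(clustering.k)}
    order = sorted(
        (c for c in per_cluster if per_cluster[c]),
        key=lambda c: (-gate[per_cluster[c][0]], per_cluster[c][0]),
    )
    selected: list[str] = []
    rationale: list[str] = []
    depth = 0
    while len(selected) < opts.n_select:
        added = False
        for c in order:
            if len(selected) >= opts.n_select:
                break
            members = per_cluster[c]
            if depth < len(members):
                m = members[depth]
                selected.append(m)
                rationale.append(
                    f"slot{len(selected)}: {m} rank-{depth + 1} gate in cluster {c}"
                )
                added = True
        if not added:
            break
        depth += 1
    if not selected:
        raise ValueError("gate column has no usable scores")
    _force_af3(selected, rationale, pool, gate, opts, "gate")
    return SelectionResult(strategy="gate_cluster", top5=selected, rationale=rationale)


def _fill_slots(
    selected: list[str],
    rationale: list[str],
    ranking: list[str],
    note: str,
    limit: int,
) -> None:
    for m in ranking:
        if len(selected) >= limit:
            return
        if m not in selected:
            selected.append(m)
            rationale.append(f"slot{len(selected)}: {m} {note}")
            return


def _select_combined_llm(
    pool: ModelPool, table: QAScoreTable, matrix: SimilarityMatrix, opts: SelectOptions
) -> SelectionResult:
    af3_rank = _ranked(table.df["af3_ranking"])
    if not af3_rank:
        raise ValueError("af3_ranking column has no usable scores")
    selected = [af3_rank[0]]
    rationale = [f"slot1: {af3_rank[0]} top af3_ranking"]
    blend = _ranked(combine(table, ["gate", "plddt"]))
    while len(selected) < opts.n_select and any(m not in selected for m in blend):
        _fill_slots(selected, rationale, blend, "by mean(gate, plddt)", opts.n_select)
    return SelectionResult(strategy="combined_llm", top5=selected, rationale=rationale)


def _select_multicom_ensemble(
    pool: ModelPool, table: QAScoreTable, matrix: SimilarityMatrix, opts: SelectOptions
) -> SelectionResult:
    head = _ranked(combine(table, ["af3_ranking", "gate"]))
    if not head:
        raise ValueError("af3_ranking/gate columns have no jointly usable scores")
    selected = [head[0]]
    rationale = [f"slot1: {head[0]} top mean(af3_ranking, gate)"]
    blend = _ranked(combine(table, ["gate", "plddt"]))
    slot_metrics: list[tuple[list[str], str]] = [(blend, "by mean(gate, plddt)")]
    slot_metrics.append((_ranked(table.df["gate"]), "by gate"))
    if "gcpnet" in table.df.columns and table.df["gcpnet"].notna().any():
        slot_metrics.append((_ranked(table.df["gcpnet"]), "by gcpnet"))
    elif "enqa" in table.df.columns:
        slot_metrics.append((_ranked(table.df["enqa"]), "by enqa (gcpnet fallback)"))
    if "pss" in table.df.columns:
        slot_metrics.append((_ranked(table.df["pss"]), "by pss"))
    for ranking, note in slot_metrics:
        if len(selected) >= opts.n_select:
            break
        _fill_slots(selected, rationale, ranking, note, opts.n_select)
    while len(selected) < opts.n_select and any(m not in selected for m in blend):
        _fill_slots(selected, rationale, blend, "back-fill by mean(gate, plddt)", opts.n_select)
    return SelectionResult(strategy="multicom_ensemble", top5=selected, rationale=rationale)


STRATEGIES = ("plddt_diverse", "gate_cluster", "combined_llm", "multicom_ensemble")

_REQUIRED_COLUMNS = {
    "plddt_diverse": ("plddt",),
    "gate_cluster": ("gate",),
    "combined_llm": ("af3_ranking", "gate", "plddt"),
    "multicom_ensemble": ("af3_ranking", "gate", "plddt"),
}


def select_top5(
    strategy: str,
    pool: ModelPool,
    table: QAScoreTable,
    matrix: SimilarityMatrix,
    clustering: Clustering | None = None,
    opts: SelectOptions = SelectOptions(),
) -> SelectionResult:
    """Run one selection strategy; see the module docstring for the rules.

    ``table`` may be raw or normalized; normalization is applied here so that
    plDDT blends with [0, 1]-scale scores meaningfully.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    for col in _REQUIRED_COLUMNS[strategy]:
        if col not in table.df.columns:
            raise ValueError(f"strategy {strategy!r} requires missing column {col!r}")
    table = normalize(table)
    if strategy == "plddt_diverse":
        return _select_plddt_diverse(pool, table, matrix, opts)
    if strategy == "gate_cluster":
        if clustering is None:
            clustering = cluster_models(matrix, k="auto", seed=0)
        return _select_gate_cluster(pool, table, matrix, clustering, opts)
    if strategy == "combined_llm":
        return _select_combined_llm(pool, table, matrix, opts)
    return _select_multicom_ensemble(pool, table, matrix, opts)
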