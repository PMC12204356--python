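"""Deterministic generators for model pools, MSAs, and score panels.

Every generator is a pure function of its parameters plus a seed, so every
stage of the toolkit is testable with known ground truth and no external data.

The pool generator emulates the structure of real decoy pools: clusters of
models that agree internally but differ by an internal hinge deformation
(rigid motions alone are invisible to superposition-based similarity), with
per-model coordinate noise, and synthetic QA scores tied to each model's true
TM-score to the reference through additive Gaussian noise. Setting a minority
cluster as the correct one reproduces the consensus-failure regime where the
best models hide in a small cluster and average-similarity ranking prefers the
dominant wrong fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .casp_eval import ScorePanel
from .ranking import QAScoreTable
from .similarity import ScoreParams, tm_score
from .struct_model import Generator, ModelPool, StructureModel

__all__ = ["PoolRecipe", "PoolGroundTruth", "make_reference", "make_pool", "make_msa", "make_panel"]

CA_SPACING = 3.8  # Å, consecutive alpha-carbon distance
HINGE_DEG_PER_ANGSTROM = 6.0  # hinge angle scale vs cluster displacement
RIGID_DEG_PER_ANGSTROM = 4.0  # rigid rotation scale vs cluster displacement


@dataclass(frozen=True)
class PoolRecipe:
    """Conditions for one synthetic model pool.

    cluster_displacement sets both the per-cluster rigid motion (rotation of
    4°/Å x displacement, translation of displacement Å) and the internal hinge
    rotation of the C-terminal half (6°/Å x displacement; the default 10 Å
    yields a 60° hinge). ``correct_cluster`` names the undeformed cluster that
    matches the reference; every other cluster gets its own hinge axis.
    qa_noise is the sd of the additive noise linking each synthetic QA column
    to the model's true TM-score to the reference.
    """

    L: int = 60
    n_models: int = 20
    cluster_fractions: tuple[float, ...] = (1.0,)
    cluster_displacement: float = 10.0
    noise_sigma: float = 0.5
    qa_noise: float = 0.05
    seed: int = 0
    correct_cluster: int = 0
    target_id: str = "SYN"

    def __post_init__(self) -> None:
        if abs(sum(self.cluster_fractions) - 1.0) > 1e-9:
            raise ValueError("cluster_fractions must sum to 1")
        if self.L < 16:
            raise ValueError("L must be >= 16")
        if not (0 <= self.correct_cluster < len(self.cluster_fractions)):
            raise ValueError("correct_cluster out of range")


@dataclass
class PoolGroundTruth:
    """What the generator knows: cluster labels, true quality, QA scores."""

    labels: np.ndarray
    true_tm: np.ndarray
    qa_table: QAScoreTable
    correct_cluster: int


def make_reference(L: int, seed: int = 0) -> StructureModel:
    """Random helix-like CA trace with exact 3.8 Å consecutive spacing."""
    if L < 4:
        raise ValueError("L must be >= 4")
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    pos = np.zeros(3)
    coords = [pos.copy()]
    for _ in range(L - 1):
        direction = direction + 0.45 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = pos + CA_SPACING * direction
        coords.append(pos.copy())
    aas = "ACDEFGHIKLMNPQRSTVWY"
    seq = "".join(aas[i] for i in rng.integers(0, len(aas), size=L))
    return StructureModel(
        model_id="reference",
        target_id="SYN",
        sequence=seq,
        residue_numbers=np.arange(1, L + 1),
        ca_coords=np.array(coords),
        generator=Generator.other,
    )


def _random_rotation(rng: np.random.Generator, angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()


def _hinge(coords: np.ndarray, rng: np.random.Generator, angle_deg: float) -> np.ndarray:
    """Rotate the C-terminal half about a random axis through the hinge CA."""
    h = len(coords) // 2
    pivot = coords[h]
    rot = _random_rotation(rng, angle_deg)
    out = coords.copy()
    out[h + 1 :] = (coords[h + 1 :] - pivot) @ rot.T + pivot
    return out


def make_pool(
    recipe: PoolRecipe,
    params: ScoreParams | None = None,
) -> tuple[ModelPool, PoolGroundTruth]:
    """Generate a clustered pool plus its ground truth.

    Cluster sizes follow cluster_fractions (largest remainders rounding, every
    declared cluster non-empty). Generator tags alternate AF2/AF3 round-robin.
    QA columns: plddt (x100), gate, enqa, gcpnet for all models; af3_ranking
    only for AF3-tagged models, as in a real mixed pool.
    """
    rng = np.random.default_rng(recipe.seed)
    ref = make_reference(recipe.L, recipe.seed)
    ref = StructureModel(
        model_id="reference",
        target_id=recipe.target_id,
        sequence=ref.sequence,
        residue_numbers=ref.residue_numbers,
        ca_coords=ref.ca_coords,
    )
    params = params or ScoreParams()

    # per-cluster sizes by largest remainders
    raw = np.array(recipe.cluster_fractions) * recipe.n_models
    sizes = np.floor(raw).astype(int)
    while sizes.sum() < recipe.n_models:
        sizes[int(np.argmax(raw - sizes))] += 1
    if np.any(sizes == 0):
        raise ValueError("every declared cluster must receive at least one model")

    # cluster-specific deformed templates
    templates: list[np.ndarray] = []
    for c in range(len(sizes)):
        if c == recipe.correct_cluster:
            templates.append(ref.ca_coords.copy())
            continue
        deformed = _hinge(ref.ca_coords, rng, HINGE_DEG_PER_ANGSTROM * recipe.cluster_displacement)
        rot = _random_rotation(rng, RIGID_DEG_PER_ANGSTROM * recipe.cluster_displacement)
        shift = rng.normal(size=3)
        shift *= recipe.cluster_displacement / np.linalg.norm(shift)
        templates.append(deformed @ rot.T + shift)

    models: list[StructureModel] = []
    labels: list[int] = []
    gens = [Generator.AF2, Generator.AF3]
    idx = 0
    for c, size in enumerate(sizes):
        for _ in range(size):
            coords = templates[c] + rng.normal(scale=recipe.noise_sigma, size=(recipe.L, 3))
            models.append(
                StructureModel(
                    model_id=f"m{idx:03d}",
                    target_id=recipe.target_id,
                    sequence=ref.sequence,
                    residue_numbers=np.arange(1, recipe.L + 1),
                    ca_coords=coords,
                    generator=gens[idx % 2],
                )
            )
            labels.append(c)
            idx += 1
    pool = ModelPool(target_id=recipe.target_id, models=models, reference_length=recipe.L)

    true_tm = np.array([tm_score(m, ref, params, lref=recipe.L) for m in models])

    def qa_col(scale: float = 1.0) -> np.ndarray:
        noisy = true_tm + rng.normal(scale=recipe.qa_noise, size=len(models))
        return np.clip(noisy, 0.0, 1.0) * scale

    df = pd.DataFrame(
        {
            "plddt": qa_col(100.0),
            "gate": qa_col(),
            "enqa": qa_col(),
            "gcpnet": qa_col(),
            "af3_ranking": qa_col(),
        },
        index=pool.model_ids,
    )
    af2_mask = [m.generator != Generator.AF3 for m in models]
    df.loc[af2_mask, "af3_ranking"] = np.nan
    for m, p in zip(models, df["plddt"]):
        m.plddt = np.full(recipe.L, float(p))

    truth = PoolGroundTruth(
        labels=np.array(labels),
        true_tm=true_tm,
        qa_table=QAScoreTable(df=df),
        correct_cluster=recipe.correct_cluster,
    )
    return pool, truth


_AAS = "ACDEFGHIKLMNPQRSTVWY"


def _mutate(seq: str, rng: np.random.Generator, rate: float = 0.3) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = _AAS[int(rng.integers(0, len(_AAS)))]
    return out


def make_msa(
    L: int,
    depths_per_region: list[tuple[tuple[int, int], int]],
    id_overlap: float = 0.5,
    seed: int = 0,
    rows_per_domain: int = 10,
    query: str | None = None,
) -> tuple["Msa", list["Msa"]]:
    """Synthetic full-length MSA with controlled per-region depth, plus one
    domain MSA per region with a controlled identifier overlap.

    Full-MSA rows each cover exactly one region, so the query-inclusive depth
    profile equals 1 + (depth_target - 1) inside each region (exact, within
    the ±1 the rounding of depth targets allows) and 1 elsewhere. Domain MSAs
    hold ``rows_per_domain`` rows each; a fraction ``id_overlap`` of their
    identifiers is shared across all domain MSAs (those rows pair during
    domain-based MSA construction), the rest are unique (they gap-pad).
    Pass ``query`` to emulate several MSA sources for one target.
    """
    from .msa import Msa  # local import to avoid a cycle at module load

    if not (0.0 <= id_overlap <= 1.0):
        raise ValueError("id_overlap must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if query is None:
        query = "".join(_AAS[i] for i in rng.integers(0, len(_AAS), size=L))
    elif len(query) != L:
        raise ValueError("query length must equal L")

    rows: list[tuple[str, str]] = []
    for ri, ((s, e), depth) in enumerate(depths_per_region):
        if depth < 0:
            raise ValueError("depths must be >= 0")
        if not (1 <= s <= e <= L):
            raise ValueError(f"region ({s}, {e}) outside [1, {L}]")
        for j in range(max(depth - 1, 0)):  # query itself supplies depth 1
            body = "".join(_mutate(query[s - 1 : e], rng))
            aligned = "-" * (s - 1) + body + "-" * (L - e)
            rows.append((f"r{ri}_full{j:03d}", aligned))
    full = Msa(query_id="query", query_seq=query, rows=rows)

    n_shared = int(round(id_overlap * rows_per_domain))
    domain_msas: list[Msa] = []
    for ri, ((s, e), _) in enumerate(depths_per_region):
        dquery = query[s - 1 : e]
        drows: list[tuple[str, str]] = []
        for j in range(rows_per_domain):
            ident = f"shared{j:03d}" if j < n_shared else f"d{ri}_seq{j:03d}"
            drows.append((ident, "".join(_mutate(dquery, rng))))
        domain_msas.append(Msa(query_id="query", query_seq=dquery, rows=drows))
    return full, domain_msas


def make_panel(
    n_domains: int,
    n_predictors: int,
    outlier_spec: list[tuple[int, int, float]] | None = None,
    seed: int = 0,
) -> ScorePanel:
    """Beta-distributed GDT-TS panel with optional injected outliers.

    Scores per domain are a Beta(8, 3)-drawn domain difficulty plus small
    per-predictor jitter, clipped to [0, 1]. ``outlier_spec`` entries are
    (domain index, predictor index, score).
    """
    if n_predictors < 2:
        raise ValueError("need >= 2 predictors")
    rng = np.random.default_rng(seed)
    base = rng.beta(8, 3, size=n_domains)
    vals = np.clip(
        base[:, None] + rng.normal(scale=0.05, size=(n_domains, n_predictors)), 0.0, 1.0
    )
    for d, p, score in outlier_spec or []:
        vals[d, p] = score
    df = pd.DataFrame(
        vals,
        index=[f"T{1000 + i}-D1" for i in range(n_domains)],
        columns=[f"pred{j:02d}" for j in range(n_predictors)],
    )
    return ScorePanel(df=df)
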