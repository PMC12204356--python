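"""Shared fixtures: hand-built models and the large consensus-failure pool."""

from __future__ import annotations

import numpy as np
import pytest

from foldpool import ModelPool, PoolRecipe, StructureModel, make_pool, pairwise_matrix


def build_model(
    model_id: str,
    coords: np.ndarray,
    *,
    sequence: str | None = None,
    residue_numbers: np.ndarray | None = None,
    target_id: str = "SYN",
    generator: str = "other",
    plddt: np.ndarray | None = None,
) -> StructureModel:
    """Construct a StructureModel from bare coordinates (poly-alanine default)."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return StructureModel(
        model_id=model_id,
        target_id=target_id,
        sequence=sequence if sequence is not None else "A" * n,
        residue_numbers=residue_numbers if residue_numbers is not None else np.arange(1, n + 1),
        ca_coords=coords,
        plddt=plddt,
        generator=generator,
    )


def straight_trace(n: int, spacing: float = 3.8) -> np.ndarray:
    """Collinear CA trace along x."""
    coords = np.zeros((n, 3))
    coords[:, 0] = spacing * np.arange(n)
    return coords


@pytest.fixture(scope="session")
def consensus_setup():
    """100-model pool, 90% in a deformed (wrong-fold) cluster and 10% matching
    the reference, with QA scores tracking true quality closely — the regime
    where consensus ranking prefers the dominant wrong cluster."""
    recipe = PoolRecipe(
        L=60,
        n_models=100,
        cluster_fractions=(0.9, 0.1),
        correct_cluster=1,
        cluster_displacement=10.0,
        noise_sigma=0.5,
        qa_noise=0.02,
        seed=16,
    )
    pool, truth = make_pool(recipe)
    matrix = pairwise_matrix(pool, metric="tm")
    return pool, truth, matrix
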