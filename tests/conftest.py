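"""Shared fixtures: the frozen synthetic study dataset and helper builders."""

from __future__ import annotations

import numpy as np
import pytest

from coilmrf import (
    CvConfig,
    HydropathyScale,
    RegressionModel,
    SyntheticSpec,
    build_state_space,
    leave_family_out,
    sample_dataset,
)
from coilmrf.evaluation import _tally
from coilmrf.frequencies import BackgroundTables, N_AA, PairTable, SingleTable

STUDY_SEED = 1


@pytest.fixture(scope="session")
def space():
    return build_state_space()


@pytest.fixture(scope="session")
def scale():
    return HydropathyScale.eisenberg_consensus()


@pytest.fixture(scope="session")
def dataset():
    """The default-condition synthetic dataset used across the suite."""
    return sample_dataset(SyntheticSpec(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def tables(dataset):
    families, negatives = dataset
    records = [r for recs in families.values() for r in recs]
    return _tally(records, negatives, 1.0)


@pytest.fixture(scope="session")
def cv_result(dataset):
    """Nested leave-family-out run on the study dataset (shared: it is the
    expensive end-to-end computation)."""
    families, negatives = dataset
    return leave_family_out(families, negatives, CvConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def full_model(cv_result):
    return cv_result.final_model


def random_model(rng: np.random.Generator, coef_scale: float = 0.5) -> RegressionModel:
    """A random small regression model for oracle-equivalence trials."""
    return RegressionModel(
        alpha=rng.normal(0, coef_scale, 8),
        beta=rng.normal(0, coef_scale, 8),
        c_dimer=float(rng.normal(0, 2)),
        c_trimer=float(rng.normal(0, 2)),
    )


def random_tables(rng: np.random.Generator) -> tuple[SingleTable, PairTable]:
    """Random strictly positive frequency tables with a shared background."""
    bg = BackgroundTables(rng.gamma(2.0, size=N_AA) * 50,
                          rng.gamma(2.0, size=(7, N_AA, N_AA)) * 5, 1.0)
    single = SingleTable(rng.gamma(2.0, size=(2, 7, N_AA)) * 50, 1.0, bg)
    pairs = PairTable(rng.gamma(2.0, size=(2, 7, 7, N_AA, N_AA)) * 5, 1.0, bg)
    return single, pairs


def uniform_tables() -> tuple[SingleTable, PairTable]:
    """All-uniform tables: every single probability 1/20, pair joints 1/400."""
    bg = BackgroundTables(np.zeros(N_AA), np.zeros((7, N_AA, N_AA)), 1.0)
    single = SingleTable(np.zeros((2, 7, N_AA)), 1.0, bg)
    pairs = PairTable(np.zeros((2, 7, 7, N_AA, N_AA)), 1.0, bg)
    return single, pairs


def independent_pair_tables(
    rng: np.random.Generator,
) -> tuple[SingleTable, PairTable]:
    """Non-uniform tables whose pair joints are exactly the products of the
    single-table marginals (zero correlation by construction)."""
    single_counts = rng.gamma(2.0, size=(2, 7, N_AA)) * 1000
    bg_single = rng.gamma(2.0, size=N_AA) * 1000
    bg = BackgroundTables(bg_single, np.zeros((7, N_AA, N_AA)), 0.0)
    single = SingleTable(single_counts, 0.0, bg)
    p = single.p[:, :, :N_AA]
    pbg = bg.pbg[:N_AA]
    pair_counts = np.zeros((2, 7, 7, N_AA, N_AA))
    for c in range(2):
        for k in range(1, 8):
            for h in range(7):
                pair_counts[c, k - 1, h] = np.outer(p[c, (h - k) % 7], p[c, h]) * 1e6
    bg.pair_counts = np.stack([np.outer(pbg, pbg) * 1e6] * 7)
    bg.__post_init__()
    pairs = PairTable(pair_counts, 0.0, bg)
    return single, pairs
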