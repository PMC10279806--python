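"""Shared fixtures: tiny cohorts and layer builders used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from multinet.cohort_io import CohortLabels, CovariateTable, ModalityTable
from multinet.similarity import SimilarityLayer

SMALL_FEATURES = {"mri": 10, "pet": 8, "csf": 3, "cognition": 6, "genetics": 3}


def make_table(values, modality_id="mri", preprocessed=False, subject_ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, p = values.shape
    return ModalityTable(
        modality_id=modality_id,
        subject_ids=subject_ids or [f"s{i}" for i in range(n)],
        features=[f"f{j}" for j in range(p)],
        values=values,
        preprocessed=preprocessed,
    )


def make_covs(n, age=None, sex=None, icv=None, subject_ids=None):
    return CovariateTable(
        subject_ids=subject_ids or [f"s{i}" for i in range(n)],
        age=np.asarray(age if age is not None else np.linspace(60, 80, n)),
        sex=np.asarray(sex if sex is not None else np.arange(n) % 2),
        icv=None if icv is None else np.asarray(icv),
    )


def make_layer(weights, modality_id="mri", subject_ids=None):
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    return SimilarityLayer(
        modality_id=modality_id,
        subject_ids=subject_ids or [f"s{i}" for i in range(n)],
        weights=weights,
    )


def random_layer(rng, n, modality_id="mri", signed=True, subject_ids=None):
    w = rng.normal(size=(n, n)) if signed else rng.random((n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return make_layer(w, modality_id, subject_ids=subject_ids)


def make_labels(subject_ids, baseline, final=None, suvr=None):
    n = len(subject_ids)
    return CohortLabels(
        subject_ids=list(subject_ids),
        baseline_dx=list(baseline),
        final_dx=list(final) if final is not None else [None] * n,
        amyloid_suvr=np.asarray(suvr if suvr is not None else [1.0] * n, dtype=float),
        follow_up_years=np.full(n, 4.0),
    )


@pytest.fixture
def small_cohort():
    """Generated 40-subject, 5-modality cohort with strong planted structure."""
    from multinet.synthetic import SyntheticConfig, generate_cohort

    cfg = SyntheticConfig(
        n_subjects=40,
        feature_counts=dict(SMALL_FEATURES),
        effect_size=2.0,
        rho=1.0,
        label_noise=0.0,
        seed=42,
    )
    return generate_cohort(cfg)


def set_partitions(n):
    """All set partitions of range(n) as label vectors (restricted growth)."""
    labels = np.zeros(n, dtype=int)

    def rec(i, kmax):
        if i == n:
            yield labels.copy()
            return
        for c in range(kmax + 1):
            labels[i] = c
            yield from rec(i + 1, max(kmax, c + 1))

    yield from rec(0, 0)
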