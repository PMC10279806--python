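"""Subject-by-subject similarity layers from pairwise correlations.

Each preprocessed modality table becomes one network layer whose nodes are
subjects and whose edge weights are the correlation between the two
subjects' feature vectors within that modality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .cohort_io import CohortError, ModalityTable


@dataclass
class SimilarityLayer:
    """Symmetric subjects x subjects edge-weight matrix with zero diagonal."""

    modality_id: str
    subject_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.subject_ids)
        if self.weights.shape != (n, n):
            raise CohortError("weight matrix shape does not match subject count")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise CohortError("weight matrix must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise CohortError("diagonal must be exactly zero")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def build_similarity_layer(
    table: ModalityTable, method: str = "pearson"
) -> SimilarityLayer:
    """Correlate every pair of subjects across the modality's features.

    Requires a table flagged as preprocessed (correlating features of mixed
    units is not meaningful otherwise) and at least 2 features.  A subject
    whose feature vector has zero variance has no defined correlation and is
    reported by ID.
    """
    if not table.preprocessed:
        raise CohortError(
            f"{table.modality_id} table has not been preprocessed; "
            "run preprocess_modality first"
        )
    if table.n_features < 2:
        raise CohortError(
            f"{table.modality_id}: need >= 2 features to correlate subjects"
        )
    if table.n_features < 3:
        warnings.warn(
            f"{table.modality_id}: only {table.n_features} features; pairwise "
            "correlations are degenerate (r = +/-1)",
            stacklevel=2,
        )
    v = table.values
    if method == "spearman":
        v = rankdata(v, axis=1)
    elif method != "pearson":
        raise CohortError(f"unknown correlation method {method!r}")
    sd = v.std(axis=1)
    if np.any(sd == 0):
        bad = [table.subject_ids[i] for i in np.where(sd == 0)[0]]
        raise CohortError(
            f"{table.modality_id}: zero-variance feature vector for subject(s) {bad}; "
            "correlation undefined"
        )
    w = np.corrcoef(v)
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return SimilarityLayer(table.modality_id, list(table.subject_ids), w)


def sanitize_layer(layer: SimilarityLayer, mode: str = "keep_signed") -> SimilarityLayer:
    """Optionally map signed correlations onto a nonnegative edge scale.

    ``keep_signed`` is the identity (the modularity core accepts signed
    weights); ``clip_negative`` zeroes negative edges; ``shift_rescale``
    maps [-1, 1] onto [0, 1] off-diagonal.
    """
    w = layer.weights
    if mode == "keep_signed":
        out = w.copy()
    elif mode == "clip_negative":
        out = np.maximum(w, 0.0)
    elif mode == "shift_rescale":
        out = (w + 1.0) / 2.0
        np.fill_diagonal(out, 0.0)
    else:
        raise CohortError(f"unknown sanitize mode {mode!r}")
    return SimilarityLayer(layer.modality_id, list(layer.subject_ids), out)
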