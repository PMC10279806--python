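"""Per-modality preprocessing: mean centering, covariate residualization,
normalization.

The covariate set is modality-specific: structural volumes and amyloid-PET
SUVRs are adjusted for age, sex and total intracranial volume; CSF analytes
and cognitive scores for age and sex; genetics for sex only.  Normalization
is min-max to [0, 1] by default, z-scoring for genetics; ``max_divide``
(divide by the maximum absolute value) is kept as an alternative reading of
"max normalization".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort_io import CohortError, CovariateTable, ModalityTable

DEFAULT_COVARIATES: dict[str, list[str]] = {
    "mri": ["age", "sex", "icv"],
    "pet": ["age", "sex", "icv"],
    "csf": ["age", "sex"],
    "cognition": ["age", "sex"],
    "genetics": ["sex"],
}

DEFAULT_NORMALIZATION: dict[str, str] = {
    "mri": "unit_interval",
    "pet": "unit_interval",
    "csf": "unit_interval",
    "cognition": "unit_interval",
    "genetics": "zscore",
}

_NORMALIZERS = ("unit_interval", "max_divide", "zscore", "none")


@dataclass
class PreprocessSpec:
    """Covariate sets and normalization modes per modality (both overridable)."""

    covariates: dict[str, list[str]] | None = None
    normalization: dict[str, str] | None = None

    def __post_init__(self) -> None:
        cov = dict(DEFAULT_COVARIATES)
        cov.update(self.covariates or {})
        self.covariates = cov
        norm = dict(DEFAULT_NORMALIZATION)
        norm.update(self.normalization or {})
        for mode in norm.values():
            if mode not in _NORMALIZERS:
                raise CohortError(f"unknown normalization mode {mode!r}")
        self.normalization = norm


def _warn_constant(table: ModalityTable, mask: np.ndarray, what: str) -> None:
    if mask.any():
        names = [table.features[j] for j in np.where(mask)[0]]
        warnings.warn(
            f"{table.modality_id}: constant feature(s) {names} during {what}",
            stacklevel=3,
        )


def mean_center(table: ModalityTable) -> ModalityTable:
    """Subtract each feature's across-subject mean."""
    centered = table.values - table.values.mean(axis=0, keepdims=True)
    _warn_constant(table, np.ptp(table.values, axis=0) == 0, "mean centering")
    return replace(table, values=centered)


def residualize(
    table: ModalityTable, covs: CovariateTable, which: list[str]
) -> ModalityTable:
    """Replace each feature by its OLS residual on [intercept, covariates].

    With an empty covariate set this is intercept-only regression, i.e. mean
    centering.  A rank-deficient design raises, naming the collinear columns.
    """
    if covs.subject_ids != table.subject_ids:
        raise CohortError("covariates are not aligned with the modality table")
    n = table.n_subjects
    X = np.column_stack([np.ones(n)] + [covs.column(c) for c in which])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise CohortError(
            f"rank-deficient covariate design for {table.modality_id}: "
            f"collinear among intercept + {which}"
        )
    beta, *_ = np.linalg.lstsq(X, table.values, rcond=None)
    resid = table.values - X @ beta
    return replace(table, values=resid)


def scale_unit_interval(table: ModalityTable, mode: str = "unit_interval") -> ModalityTable:
    """Map each feature into [0, 1] (min-max) or divide by max |value|.

    Constant columns become 0.5 (min-max) or stay 0 (max_divide), with a
    warning either way.
    """
    v = table.values
    lo, hi = v.min(axis=0), v.max(axis=0)
    const = hi == lo
    _warn_constant(table, const, "scaling")
    if mode == "unit_interval":
        span = np.where(const, 1.0, hi - lo)
        out = (v - lo) / span
        out[:, const] = 0.5
    elif mode == "max_divide":
        m = np.abs(v).max(axis=0)
        out = v / np.where(m == 0, 1.0, m)
    else:
        raise CohortError(f"unknown scaling mode {mode!r}")
    return replace(table, values=out)


def zscore(table: ModalityTable) -> ModalityTable:
    """Standardize each feature to mean 0, sample SD 1 (ddof=1)."""
    v = table.values
    mu = v.mean(axis=0)
    sd = v.std(axis=0, ddof=1)
    const = sd == 0
    _warn_constant(table, const, "z-scoring")
    out = (v - mu) / np.where(const, 1.0, sd)
    out[:, const] = 0.0
    return replace(table, values=out)


def preprocess_modality(
    table: ModalityTable, covs: CovariateTable, spec: PreprocessSpec | None = None
) -> ModalityTable:
    """Apply center -> residualize -> normalize for one modality.

    The output is flagged ``preprocessed``; feeding an already-flagged table
    back in raises, because min-max scaling is not idempotent.
    """
    if table.preprocessed:
        raise CohortError(
            f"{table.modality_id} table is already preprocessed; refusing to repeat"
        )
    spec = spec or PreprocessSpec()
    which = spec.covariates.get(table.modality_id, [])
    mode = spec.normalization.get(table.modality_id, "unit_interval")

    out = mean_center(table)
    out = residualize(out, covs, which)
    if mode in ("unit_interval", "max_divide"):
        out = scale_unit_interval(out, mode)
    elif mode == "zscore":
        out = zscore(out)
    # mode == "none": leave residuals untouched
    return replace(out, preprocessed=True)
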