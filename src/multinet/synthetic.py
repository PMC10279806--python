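"""Synthetic multimodal cohort with planted subtypes.

The generator emulates the statistical structure the multilayer analysis
assumes: a latent subtype shared across modalities (a planted partition)
expressed in each layer with probability ``rho``, modality-specific
Gaussian noise, linear age/sex/ICV confounds, diagnosis labels tied to the
subtype with flip noise ``label_noise``, longitudinal conversion/reversion,
and an amyloid SUVR distribution straddling the 1.11 positivity cutoff.

Subtype 0 is the "healthy-like" extreme and subtype ``n_subtypes - 1`` the
"AD-like" extreme; intermediate subtypes interpolate linearly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cohort_io import CohortError, CohortLabels, CovariateTable, ModalityTable

DEFAULT_FEATURE_COUNTS = {"mri": 90, "pet": 68, "csf": 3, "cognition": 6, "genetics": 3}


@dataclass
class SyntheticConfig:
    """Knobs of the planted-subtype simulator.

    ``effect_size`` is the mean shift (in noise-SD units) an affected
    feature receives per unit of subtype code; ``rho`` the probability that
    a subject's subtype expresses in a given layer; ``label_noise`` the rate
    at which the baseline diagnosis is drawn from the wrong subtype's
    distribution.
    """

    n_subjects: int = 200
    n_subtypes: int = 2
    feature_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_COUNTS)
    )
    effect_size: float = 1.0
    affected_fraction: float = 0.5
    rho: float = 0.9
    noise_sd: float = 1.0
    age_slope: float = 0.03       # per year, in noise-SD units
    sex_effect: float = 0.5
    icv_slope: float = 5e-7       # per mm^3, imaging layers only
    label_noise: float = 0.1
    conversion_prob: float = 0.4
    reversion_prob: float = 0.3
    followup_missing: float = 0.0
    suvr_means: tuple[float, float] = (1.02, 1.30)
    suvr_sds: tuple[float, float] = (0.06, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rho <= 1 and 0 <= self.label_noise <= 1):
            raise CohortError("rho and label_noise must lie in [0, 1]")
        if self.effect_size < 0:
            raise CohortError("effect_size must be non-negative")
        if self.n_subjects < 2 * self.n_subtypes:
            raise CohortError("need at least 2 subjects per subtype")
        if not (0 <= self.affected_fraction <= 1):
            raise CohortError("affected_fraction must lie in [0, 1]")


# baseline diagnosis distribution per subtype pole, loosely matching a
# CN/MCI/AD mix of roughly 30/60/10 in a memory-clinic research cohort
_BASE_DX_HEALTHY = {"CN": 0.60, "MCI": 0.40, "AD": 0.00}
_BASE_DX_AD = {"CN": 0.00, "MCI": 0.65, "AD": 0.35}


def _interp_dx(code: float) -> dict[str, float]:
    return {
        k: (1 - code) * _BASE_DX_HEALTHY[k] + code * _BASE_DX_AD[k]
        for k in ("CN", "MCI", "AD")
    }


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[ModalityTable], CovariateTable, CohortLabels, pd.DataFrame]:
    """Draw one cohort.

    Returns the five modality tables (raw, pre-preprocessing scale), the
    covariate table, the label table, and a ground-truth frame with the
    latent subtype, whether the baseline label was flipped, and per-layer
    expression indicators.  Deterministic given ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, K = cfg.n_subjects, cfg.n_subtypes
    sids = [f"s{i:04d}" for i in range(n)]

    z = rng.integers(0, K, size=n)
    code = z / max(K - 1, 1)  # 0 = healthy-like, 1 = AD-like

    age = np.clip(rng.normal(72.0, 7.0, size=n), 55.0, 90.0)
    sex = rng.integers(0, 2, size=n).astype(float)
    icv = rng.normal(1.5e6, 1.5e5, size=n)
    covs = CovariateTable(subject_ids=sids, age=age, sex=sex, icv=icv)

    modalities = list(cfg.feature_counts)
    expressed = rng.random((n, len(modalities))) < cfg.rho

    tables: list[ModalityTable] = []
    for li, m in enumerate(modalities):
        p = cfg.feature_counts[m]
        n_aff = int(np.ceil(cfg.affected_fraction * p))
        affected = np.zeros(p, dtype=bool)
        affected[rng.choice(p, size=n_aff, replace=False)] = True

        shift = cfg.effect_size * code * expressed[:, li]  # (n,)
        confound = cfg.age_slope * (age - age.mean()) + cfg.sex_effect * sex
        if m in ("mri", "pet"):
            confound = confound + cfg.icv_slope * (icv - icv.mean())

        if m == "genetics":
            # feature 0: risk-allele count 0-2 with subtype-dependent frequency
            expr_code = code * expressed[:, li]
            freq = np.clip(
                0.15 + 0.25 * min(cfg.effect_size, 1.0) * expr_code, 0.0, 0.9
            )
            vals = np.empty((n, p))
            vals[:, 0] = rng.binomial(2, freq)
            # remaining features: continuous polygenic-style scores
            for j in range(1, p):
                vals[:, j] = shift + confound + cfg.noise_sd * rng.normal(size=n)
        else:
            vals = cfg.noise_sd * rng.normal(size=(n, p))
            vals += confound[:, None]
            vals[:, affected] += shift[:, None]
        tables.append(
            ModalityTable(
                modality_id=m,
                subject_ids=list(sids),
                features=[f"{m}_f{j}" for j in range(p)],
                values=vals,
            )
        )

    # --- baseline diagnosis with flip noise ---------------------------------
    flipped = rng.random(n) < cfg.label_noise
    label_code = np.where(flipped, 1.0 - code, code)
    baseline = []
    for c in label_code:
        probs = _interp_dx(c)
        baseline.append(rng.choice(["CN", "MCI", "AD"], p=list(probs.values())))
    baseline = np.array(baseline, dtype=object)

    # split MCI into early/late by a severity score (label code + noise)
    severity = label_code + rng.normal(0, 0.3, size=n)
    mci = baseline == "MCI"
    if mci.any():
        med = np.median(severity[mci])
        for i in np.where(mci)[0]:
            baseline[i] = "LMCI" if severity[i] > med else "EMCI"

    # --- final diagnosis: conversion / reversion driven by the TRUE subtype --
    ad_like = code > 0.5
    final: list[str | None] = []
    for i in range(n):
        b = "MCI" if baseline[i] in ("EMCI", "LMCI") else baseline[i]
        if ad_like[i]:
            f = "AD" if (b == "AD" or rng.random() < cfg.conversion_prob) else b
        else:
            if b == "MCI" and rng.random() < cfg.reversion_prob:
                f = "CN"
            else:
                f = b
        final.append(f)
    if cfg.followup_missing > 0:
        lost = rng.random(n) < cfg.followup_missing
        final = [None if lost[i] else final[i] for i in range(n)]

    suvr_mu = (1 - code) * cfg.suvr_means[0] + code * cfg.suvr_means[1]
    suvr_sd = (1 - code) * cfg.suvr_sds[0] + code * cfg.suvr_sds[1]
    suvr = np.clip(rng.normal(suvr_mu, suvr_sd), 0.6, None)
    follow_up = np.clip(rng.normal(4.5, 2.5, size=n), 0.5, 11.0)

    labels = CohortLabels(
        subject_ids=list(sids),
        baseline_dx=[str(b) for b in baseline],
        final_dx=final,
        amyloid_suvr=suvr,
        follow_up_years=follow_up,
    )
    truth = pd.DataFrame(
        {
            "subtype": z,
            "flipped": flipped,
            **{f"expressed_{m}": expressed[:, li] for li, m in enumerate(modalities)},
        },
        index=sids,
    )
    return tables, covs, labels, truth


def recovery_score(consensus: np.ndarray, truth: np.ndarray | pd.Series) -> float:
    """Adjusted Rand index between detected communities and planted subtypes."""
    truth_arr = np.asarray(truth.to_numpy() if hasattr(truth, "to_numpy") else truth)
    consensus = np.asarray(consensus)
    if len(consensus) != len(truth_arr):
        raise CohortError(
            f"length mismatch: {len(consensus)} consensus labels vs {len(truth_arr)} truths"
        )
    return float(adjusted_rand_score(truth_arr, consensus))
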