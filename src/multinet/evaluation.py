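"""Diagnosis-based evaluation of detected communities.

Communities are cross-tabulated against clinical diagnosis (CN / MCI / AD),
labelled CN-dominant / AD-dominant / intermediate by composition, and scored
with sensitivity and specificity plus exact (Clopper-Pearson) binomial 95%
confidence intervals.  Longitudinal transitions (converters, reverters,
stable groups) are broken down per community, and per-feature group
differences are summarized as scaled Mann-Whitney U maps with family-wise
error control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import beta, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .cohort_io import CohortLabels, ModalityTable

logger = logging.getLogger(__name__)

DX_ORDER = ["CN", "MCI", "AD"]

TRANSITION_CATEGORIES = [
    "stable CN",
    "CN to MCI",
    "CN to AD",
    "stable MCI",
    "MCI to AD",
    "MCI to CN",
    "stable AD",
]


class EvaluationError(ValueError):
    """Raised when contingency metrics cannot be computed."""


@dataclass
class ContingencySummary:
    counts: pd.DataFrame
    community_labels: dict[int, str]
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    denominator_type: str


def collapse_baseline(dx: str) -> str:
    """Collapse the four baseline codes onto CN / MCI / AD."""
    return "MCI" if dx in ("EMCI", "LMCI") else dx


def crosstab(
    consensus: np.ndarray,
    labels: CohortLabels,
    denominator: str = "final",
) -> pd.DataFrame:
    """Integer community x {CN, MCI, AD} table.

    ``denominator="baseline"`` uses the (collapsed) baseline diagnosis;
    ``"final"`` uses the final diagnosis and drops subjects without one (the
    dropped count is logged).
    """
    consensus = np.asarray(consensus, dtype=int)
    if len(consensus) != len(labels.subject_ids):
        raise EvaluationError("consensus labels do not cover the cohort")
    if denominator == "baseline":
        dx = [collapse_baseline(d) for d in labels.baseline_dx]
        keep = np.ones(len(dx), dtype=bool)
    elif denominator == "final":
        keep = np.array([d is not None for d in labels.final_dx])
        dropped = int((~keep).sum())
        if dropped:
            logger.info("crosstab: dropping %d subject(s) without final diagnosis", dropped)
        dx = [d for d in labels.final_dx if d is not None]
    else:
        raise EvaluationError(f"unknown denominator type {denominator!r}")
    for d in dx:
        if d not in DX_ORDER:
            raise EvaluationError(f"unknown diagnosis code {d!r}")
    comm = consensus[keep]
    table = pd.crosstab(pd.Series(comm, name="community"), pd.Series(dx, name="dx"))
    table = table.reindex(columns=DX_ORDER, fill_value=0)
    table = table.reindex(index=sorted(np.unique(comm)), fill_value=0)
    return table.astype(int)


def crosstab_mci_subtypes(consensus: np.ndarray, labels: CohortLabels) -> pd.DataFrame:
    """Auxiliary community x {CN, EMCI, LMCI, AD} table (baseline codes kept)."""
    consensus = np.asarray(consensus, dtype=int)
    table = pd.crosstab(
        pd.Series(consensus, name="community"),
        pd.Series(list(labels.baseline_dx), name="dx"),
    )
    return table.reindex(columns=["CN", "EMCI", "LMCI", "AD"], fill_value=0).astype(int)


def label_communities(counts: pd.DataFrame) -> dict[int, str]:
    """Name communities by composition.

    AD-dominant holds the largest share of all AD subjects, CN-dominant the
    largest share of all CN; everything else is intermediate.  The two roles
    must land on different communities.
    """
    if counts.shape[0] < 2:
        raise EvaluationError("need at least 2 communities to label")
    ad_share = counts["AD"] / max(int(counts["AD"].sum()), 1)
    cn_share = counts["CN"] / max(int(counts["CN"].sum()), 1)
    ad_dom = int(ad_share.idxmax())
    cn_dom = int(cn_share.idxmax())
    if ad_dom == cn_dom:
        raise EvaluationError(
            "AD-dominant and CN-dominant coincide; assign labels manually"
        )
    out: dict[int, str] = {}
    for c in counts.index:
        c = int(c)
        if c == ad_dom:
            out[c] = "AD-dominant"
        elif c == cn_dom:
            out[c] = "CN-dominant"
        else:
            out[c] = "intermediate"
    return out


def sensitivity_specificity(
    counts: pd.DataFrame, community_labels: dict[int, str] | None = None
) -> tuple[float, float]:
    """Percent of AD subjects in the AD-dominant community and of CN subjects
    in the CN-dominant community.  MCI subjects enter neither metric; with
    more than two communities, intermediate communities count as misses.
    """
    community_labels = community_labels or label_communities(counts)
    ad_dom = next(c for c, v in community_labels.items() if v == "AD-dominant")
    cn_dom = next(c for c, v in community_labels.items() if v == "CN-dominant")
    n_ad = int(counts["AD"].sum())
    n_cn = int(counts["CN"].sum())
    if n_ad == 0 or n_cn == 0:
        raise EvaluationError("zero AD or CN subjects; metrics undefined")
    sens = 100.0 * int(counts.loc[ad_dom, "AD"]) / n_ad
    spec = 100.0 * int(counts.loc[cn_dom, "CN"]) / n_cn
    return sens, spec


def clopper_pearson_ci(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial confidence interval, returned in percent.

    Lower bound is the (1-level)/2 quantile of Beta(x, n-x+1) (0 when x=0);
    upper bound the 1-(1-level)/2 quantile of Beta(x+1, n-x) (100 when x=n).
    """
    if not (0 <= successes <= n) or n <= 0:
        raise EvaluationError(f"invalid counts: {successes}/{n}")
    if not (0 < level < 1):
        raise EvaluationError(f"invalid confidence level {level}")
    alpha = 1.0 - level
    low = 0.0 if successes == 0 else 100.0 * beta.ppf(alpha / 2, successes, n - successes + 1)
    high = 100.0 if successes == n else 100.0 * beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    return float(low), float(high)


def summarize_contingency(
    consensus: np.ndarray,
    labels: CohortLabels,
    denominator: str = "final",
    level: float = 0.95,
) -> ContingencySummary:
    """Full contingency evaluation: counts, labels, metrics and exact CIs."""
    counts = crosstab(consensus, labels, denominator)
    community_labels = label_communities(counts)
    sens, spec = sensitivity_specificity(counts, community_labels)
    ad_dom = next(c for c, v in community_labels.items() if v == "AD-dominant")
    cn_dom = next(c for c, v in community_labels.items() if v == "CN-dominant")
    sens_ci = clopper_pearson_ci(int(counts.loc[ad_dom, "AD"]), int(counts["AD"].sum()), level)
    spec_ci = clopper_pearson_ci(int(counts.loc[cn_dom, "CN"]), int(counts["CN"].sum()), level)
    return ContingencySummary(
        counts=counts,
        community_labels=community_labels,
        sensitivity=sens,
        specificity=spec,
        sensitivity_ci=sens_ci,
        specificity_ci=spec_ci,
        denominator_type=denominator,
    )


def contingency_frame(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts plus within-diagnosis percentages, one row per community."""
    out = counts.copy().astype(float)
    pct = 100.0 * counts / counts.sum(axis=0).replace(0, np.nan)
    for col in counts.columns:
        out[f"{col}_pct_within_dx"] = pct[col].round(1)
    return out


def amyloid_split(
    labels: CohortLabels, cutoff: float = 1.11
) -> tuple[list[str], list[str]]:
    """Partition subjects into amyloid positive (SUVR >= cutoff) and negative.

    Subjects without a SUVR are excluded and logged.
    """
    pos, neg = [], []
    missing = 0
    for sid, suvr in zip(labels.subject_ids, labels.amyloid_suvr):
        if np.isnan(suvr):
            missing += 1
            continue
        (pos if suvr >= cutoff else neg).append(sid)
    if missing:
        logger.info("amyloid_split: %d subject(s) without SUVR excluded", missing)
    return pos, neg


def transition_category(baseline_dx: str, final_dx: str) -> str | None:
    b = collapse_baseline(baseline_dx)
    f = final_dx
    if b == "CN":
        return {"CN": "stable CN", "MCI": "CN to MCI", "AD": "CN to AD"}[f]
    if b == "MCI":
        return {"MCI": "stable MCI", "AD": "MCI to AD", "CN": "MCI to CN"}[f]
    if b == "AD":
        # clinical AD diagnoses are not revised downward in this breakdown
        return "stable AD" if f == "AD" else None
    return None


def transition_breakdown(
    consensus: np.ndarray, labels: CohortLabels
) -> pd.DataFrame:
    """Counts and within-category percentages of each transition category per
    community.  Categories with no subjects keep zero counts and NaN
    percentages.  Subjects without a final diagnosis are skipped.
    """
    consensus = np.asarray(consensus, dtype=int)
    comms = sorted(np.unique(consensus))
    counts = pd.DataFrame(0, index=TRANSITION_CATEGORIES, columns=comms)
    for i, sid in enumerate(labels.subject_ids):
        f = labels.final_dx[i]
        if f is None:
            continue
        cat = transition_category(labels.baseline_dx[i], f)
        if cat is None:
            continue
        counts.loc[cat, consensus[i]] += 1
    totals = counts.sum(axis=1)
    pct = 100.0 * counts.div(totals.replace(0, np.nan), axis=0)
    out = counts.copy().astype(float)
    for c in comms:
        out[f"pct_community_{c}"] = pct[c]
    out.insert(0, "total", totals)
    return out


def scaled_u_map(
    feature_table: ModalityTable,
    group_a: list[str],
    group_b: list[str],
    correction: str = "bonferroni",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature two-sided Mann-Whitney U comparison between two groups.

    The reported statistic is ``min(U_a, U_b)`` scaled by the maximum U
    across features (so the feature with the largest U maps to 1).
    Significance uses Bonferroni or Benjamini-Hochberg control at
    ``alpha`` over the features tested in this call.
    """
    idx = {s: i for i, s in enumerate(feature_table.subject_ids)}
    missing = [s for s in list(group_a) + list(group_b) if s not in idx]
    if missing:
        raise EvaluationError(f"subjects absent from feature table: {missing[:5]}")
    ia = [idx[s] for s in group_a]
    ib = [idx[s] for s in group_b]
    if len(ia) < 2 or len(ib) < 2:
        raise EvaluationError("both groups need at least 2 subjects")
    va = feature_table.values[ia]
    vb = feature_table.values[ib]
    us, ps = [], []
    for j in range(feature_table.n_features):
        res = mannwhitneyu(va[:, j], vb[:, j], alternative="two-sided")
        u_a = float(res.statistic)
        u_b = len(ia) * len(ib) - u_a
        us.append(min(u_a, u_b))
        ps.append(float(res.pvalue))
    us = np.asarray(us)
    ps = np.asarray(ps)
    method = {"bonferroni": "bonferroni", "fdr": "fdr_bh"}.get(correction)
    if method is None:
        raise EvaluationError(f"unknown correction {correction!r}")
    reject, p_adj, *_ = multipletests(ps, alpha=alpha, method=method)
    u_max = us.max()
    scaled = us / u_max if u_max > 0 else np.zeros_like(us)
    return pd.DataFrame(
        {
            "feature": feature_table.features,
            "u": us,
            "scaled_u": scaled,
            "p": ps,
            "p_adjusted": p_adj,
            "significant": reject,
        }
    ).set_index("feature")
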