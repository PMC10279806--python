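"""Tabular I/O, cohort containers, run configuration and pipeline orchestration.

All on-disk formats are comma-separated UTF-8 with a header row and the
subject identifier in the first column.  Converters from other dialects are
deliberately out of scope.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Recognised modality identifiers, in canonical layer order.
MODALITIES = ("mri", "pet", "csf", "cognition", "genetics")

DX_BASELINE = ("CN", "EMCI", "LMCI", "AD")
DX_FINAL = ("CN", "MCI", "AD")


class CohortError(ValueError):
    """Raised for malformed or inconsistent cohort inputs."""


@dataclass
class ModalityTable:
    """Subjects x features matrix for one modality.

    Parameters
    ----------
    modality_id
        One of :data:`MODALITIES`.
    subject_ids
        Ordered, unique subject identifiers (row labels of ``values``).
    features
        Ordered feature names (column labels of ``values``).
    values
        Real matrix of shape ``(n_subjects, n_features)``.
    preprocessed
        Set by :func:`multinet.preprocess.preprocess_modality`; similarity
        construction refuses tables that are not flagged.
    """

    modality_id: str
    subject_ids: list[str]
    features: list[str]
    values: np.ndarray
    preprocessed: bool = False

    def __post_init__(self) -> None:
        if self.modality_id not in MODALITIES:
            raise CohortError(
                f"unknown modality {self.modality_id!r}; expected one of {MODALITIES}"
            )
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.features = [str(f) for f in self.features]
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if len(self.subject_ids) != n or len(self.features) != p:
            raise CohortError("label lengths do not match value matrix shape")
        if len(set(self.subject_ids)) != n:
            dupes = sorted({s for s in self.subject_ids if self.subject_ids.count(s) > 1})
            raise CohortError(f"duplicate subject IDs: {dupes}")
        if n < 2:
            raise CohortError(f"need at least 2 subjects, got {n}")
        if p < 1:
            raise CohortError("need at least 1 feature")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))
            locs = [(self.subject_ids[i], self.features[j]) for i, j in bad[:5]]
            raise CohortError(f"missing or non-finite values at (subject, feature): {locs}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.features)


@dataclass
class CovariateTable:
    """Per-subject nuisance covariates: age (years), sex (0/1), ICV (mm^3)."""

    subject_ids: list[str]
    age: np.ndarray
    sex: np.ndarray
    icv: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=float)
        if self.icv is not None:
            self.icv = np.asarray(self.icv, dtype=float)
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            raise CohortError("duplicate subject IDs in covariate table")
        if self.age.shape != (n,) or self.sex.shape != (n,):
            raise CohortError("covariate column lengths do not match subject count")
        if np.any(self.age <= 0):
            raise CohortError("ages must be positive")
        if not np.isin(self.sex, (0.0, 1.0)).all():
            raise CohortError("sex must be coded 0/1")

    def column(self, name: str) -> np.ndarray:
        if name == "age":
            return self.age
        if name == "sex":
            return self.sex
        if name == "icv":
            if self.icv is None:
                raise CohortError("ICV requested but absent from covariate table")
            return self.icv
        raise CohortError(f"unknown covariate {name!r}")

    def to_frame(self) -> pd.DataFrame:
        data = {"age": self.age, "sex": self.sex}
        if self.icv is not None:
            data["icv"] = self.icv
        return pd.DataFrame(data, index=self.subject_ids)


@dataclass
class CohortLabels:
    """Diagnostic labels: baseline/final diagnosis, amyloid SUVR, follow-up.

    ``final_dx`` entries may be ``None`` for subjects lost to follow-up;
    ``amyloid_suvr`` may contain NaN where PET is unavailable.
    """

    subject_ids: list[str]
    baseline_dx: list[str]
    final_dx: list[str | None]
    amyloid_suvr: np.ndarray
    follow_up_years: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            raise CohortError("duplicate subject IDs in label table")
        self.amyloid_suvr = np.asarray(self.amyloid_suvr, dtype=float)
        self.follow_up_years = np.asarray(self.follow_up_years, dtype=float)
        if not (len(self.baseline_dx) == len(self.final_dx) == n):
            raise CohortError("label column lengths do not match subject count")
        for dx in self.baseline_dx:
            if dx not in DX_BASELINE:
                raise CohortError(f"unknown baseline diagnosis {dx!r}")
        for dx in self.final_dx:
            if dx is not None and dx not in DX_FINAL:
                raise CohortError(f"unknown final diagnosis {dx!r}")
        with np.errstate(invalid="ignore"):
            if np.any(self.amyloid_suvr[~np.isnan(self.amyloid_suvr)] <= 0):
                raise CohortError("amyloid SUVR must be positive where present")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "baseline_dx": self.baseline_dx,
                "final_dx": [dx if dx is not None else "" for dx in self.final_dx],
                "amyloid_suvr": self.amyloid_suvr,
                "follow_up_years": self.follow_up_years,
            },
            index=self.subject_ids,
        )


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end run.

    ``gamma`` is the per-layer structural resolution; ``omega`` the uniform
    categorical interlayer coupling.  All stochastic steps draw from ``seed``.
    """

    modalities: list[str] = field(default_factory=lambda: list(MODALITIES))
    covariates: dict[str, list[str]] | None = None
    normalization: dict[str, str] | None = None
    similarity_method: str = "pearson"
    sanitize_mode: str = "keep_signed"
    gamma: dict[str, float] | float = 1.0
    omega: float = 1.0
    coupling: str = "categorical"
    restarts: int = 20
    seed: int = 0
    tol: float = 1e-10
    amyloid_cutoff: float = 1.11
    denominator: str = "final"

    def __post_init__(self) -> None:
        if isinstance(self.gamma, (int, float)):
            self.gamma = {m: float(self.gamma) for m in self.modalities}
        if any(g <= 0 for g in self.gamma.values()):
            raise CohortError("gamma must be positive for every layer")
        if self.omega < 0:
            raise CohortError("omega must be non-negative")
        if self.restarts < 1:
            raise CohortError("restarts must be >= 1")
        if self.amyloid_cutoff <= 0:
            raise CohortError("amyloid cutoff must be positive")

    def gamma_list(self) -> list[float]:
        return [float(self.gamma[m]) for m in self.modalities]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Readers / writers


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CohortError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise CohortError(f"empty input file: {path}") from exc
    if df.shape[0] == 0:
        raise CohortError(f"no data rows in {path}")
    df.index = df.index.map(str)
    return df


def read_modality_table(path: str | Path, modality_id: str) -> ModalityTable:
    """Load one modality's subjects x features CSV.

    The first column is the subject ID; every other cell must be numeric and
    non-missing.  Duplicate IDs and blank cells are hard errors.
    """
    df = _read_csv(path)
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise CohortError(f"duplicate subject IDs in {path}: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = list(zip(*np.where(numeric.isna().to_numpy())))
        locs = [(df.index[i], df.columns[j]) for i, j in bad[:5]]
        raise CohortError(f"missing or non-numeric cells in {path} at (row, column): {locs}")
    if df.shape[0] < 3:
        raise CohortError(f"{path}: need at least 3 subjects, got {df.shape[0]}")
    return ModalityTable(
        modality_id=modality_id,
        subject_ids=list(df.index),
        features=list(df.columns),
        values=numeric.to_numpy(dtype=float),
    )


def read_covariates(path: str | Path) -> CovariateTable:
    df = _read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for required in ("age", "sex"):
        if required not in cols:
            raise CohortError(f"covariate file {path} lacks column {required!r}")
    icv = df[cols["icv"]].to_numpy(float) if "icv" in cols else None
    return CovariateTable(
        subject_ids=list(df.index),
        age=df[cols["age"]].to_numpy(float),
        sex=df[cols["sex"]].to_numpy(float),
        icv=icv,
    )


def read_labels(path: str | Path) -> CohortLabels:
    df = _read_csv(path)
    final = [
        None if (isinstance(v, float) and np.isnan(v)) or v in ("", None) else str(v)
        for v in df["final_dx"]
    ]
    suvr = (
        df["amyloid_suvr"].to_numpy(float)
        if "amyloid_suvr" in df.columns
        else np.full(len(df), np.nan)
    )
    fup = (
        df["follow_up_years"].to_numpy(float)
        if "follow_up_years" in df.columns
        else np.full(len(df), np.nan)
    )
    return CohortLabels(
        subject_ids=list(df.index),
        baseline_dx=[str(v) for v in df["baseline_dx"]],
        final_dx=final,
        amyloid_suvr=suvr,
        follow_up_years=fup,
    )


def write_frame(df: pd.DataFrame, path: str | Path) -> None:
    """Write a frame as CSV with 12 significant digits (round-trip safe)."""
    df.to_csv(path, float_format="%.12g")


def write_modality_table(table: ModalityTable, path: str | Path) -> None:
    write_frame(table.to_frame(), path)


# ---------------------------------------------------------------------------
# Complete-case alignment


def align_complete_cases(
    tables: list[ModalityTable],
    covs: CovariateTable,
    labels: CohortLabels,
) -> tuple[list[ModalityTable], CovariateTable, CohortLabels]:
    """Restrict every input to the subjects present in all of them.

    The intersection keeps the subject order of the first modality table.
    Every dropped subject is logged together with the input(s) that lacked
    it; an empty intersection is an error.
    """
    if not tables:
        raise CohortError("need at least one modality table")
    sources: list[tuple[str, set[str]]] = [
        (t.modality_id, set(t.subject_ids)) for t in tables
    ]
    sources.append(("covariates", set(covs.subject_ids)))
    sources.append(("labels", set(labels.subject_ids)))
    common = set.intersection(*(s for _, s in sources))
    if not common:
        raise CohortError("no subject is present in every input (empty intersection)")

    everyone = set.union(*(s for _, s in sources))
    for sid in sorted(everyone - common):
        missing_from = [name for name, s in sources if sid not in s]
        logger.info("dropping subject %s: absent from %s", sid, ", ".join(missing_from))

    order = [s for s in tables[0].subject_ids if s in common]

    def _take_table(t: ModalityTable) -> ModalityTable:
        idx = [t.subject_ids.index(s) for s in order]
        return replace(t, subject_ids=list(order), values=t.values[idx])

    cidx = [covs.subject_ids.index(s) for s in order]
    new_covs = CovariateTable(
        subject_ids=list(order),
        age=covs.age[cidx],
        sex=covs.sex[cidx],
        icv=None if covs.icv is None else covs.icv[cidx],
    )
    lidx = [labels.subject_ids.index(s) for s in order]
    new_labels = CohortLabels(
        subject_ids=list(order),
        baseline_dx=[labels.baseline_dx[i] for i in lidx],
        final_dx=[labels.final_dx[i] for i in lidx],
        amyloid_suvr=labels.amyloid_suvr[lidx],
        follow_up_years=labels.follow_up_years[lidx],
    )
    return [_take_table(t) for t in tables], new_covs, new_labels


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineResult:
    partition: "object"          # multinet.multilayer.Partition
    consensus: np.ndarray
    contingency: pd.DataFrame
    metrics: dict


def run_pipeline(
    config: RunConfig,
    modality_paths: dict[str, str | Path],
    covariates_path: str | Path,
    labels_path: str | Path,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full analysis: load, preprocess, build layers, detect
    communities, evaluate against diagnoses, and (optionally) write results.

    Deterministic given ``config.seed``.  Stage failures are re-raised with
    the stage name prefixed.
    """
    from . import evaluation, multilayer, preprocess, similarity

    def _stage(name, fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    tables = []
    for m in config.modalities:
        if m not in modality_paths:
            raise CohortError(f"config lists modality {m!r} but no input path was given")
        tables.append(_stage(f"read:{m}", read_modality_table, modality_paths[m], m))
    covs = _stage("read:covariates", read_covariates, covariates_path)
    labels = _stage("read:labels", read_labels, labels_path)

    tables, covs, labels = _stage("align", align_complete_cases, tables, covs, labels)

    spec = preprocess.PreprocessSpec(
        covariates=config.covariates, normalization=config.normalization
    )
    tables = [
        _stage(f"preprocess:{t.modality_id}", preprocess.preprocess_modality, t, covs, spec)
        for t in tables
    ]
    layers = [
        _stage(
            f"similarity:{t.modality_id}",
            similarity.build_similarity_layer,
            t,
            config.similarity_method,
        )
        for t in tables
    ]
    layers = [similarity.sanitize_layer(l, config.sanitize_mode) for l in layers]

    net = _stage(
        "assemble",
        multilayer.assemble_multilayer,
        layers,
        config.gamma_list(),
        config.omega,
        coupling=config.coupling,
    )
    part = _stage(
        "genlouvain",
        multilayer.genlouvain,
        net,
        restarts=config.restarts,
        seed=config.seed,
        tol=config.tol,
    )
    consensus, split = multilayer.consensus_node_labels(part)

    counts = _stage("crosstab", evaluation.crosstab, consensus, labels, config.denominator)
    metrics: dict = {
        "q": part.q,
        "n_communities": int(part.n_communities),
        "n_subjects": len(labels.subject_ids),
        "any_subject_split": bool(split.any()),
        "seed": config.seed,
        "omega": config.omega,
        "gamma": config.gamma_list(),
    }
    try:
        comm_labels = evaluation.label_communities(counts)
        sens, spec_ = evaluation.sensitivity_specificity(counts, comm_labels)
        n_ad = int(counts["AD"].sum())
        n_cn = int(counts["CN"].sum())
        ad_dom = next(c for c, v in comm_labels.items() if v == "AD-dominant")
        cn_dom = next(c for c, v in comm_labels.items() if v == "CN-dominant")
        sens_ci = evaluation.clopper_pearson_ci(int(counts.loc[ad_dom, "AD"]), n_ad)
        spec_ci = evaluation.clopper_pearson_ci(int(counts.loc[cn_dom, "CN"]), n_cn)
        metrics.update(
            {
                "community_labels": {int(k): v for k, v in comm_labels.items()},
                "sensitivity": sens,
                "specificity": spec_,
                "sensitivity_ci": list(sens_ci),
                "specificity_ci": list(spec_ci),
            }
        )
    except evaluation.EvaluationError as exc:
        logger.warning("contingency metrics unavailable: %s", exc)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        n, L = part.g.shape
        rows = []
        for l, layer_id in enumerate(part.layer_ids):
            for i, sid in enumerate(part.subject_ids):
                rows.append((sid, layer_id, int(part.g[i, l]), int(consensus[i])))
        pd.DataFrame(
            rows, columns=["subject_id", "layer", "community", "consensus_community"]
        ).to_csv(out / "partition.csv", index=False)
        evaluation.contingency_frame(counts).to_csv(out / "contingency.csv")
        with open(out / "metrics.json", "w", encoding="utf-8") as fh:
            json.dump(metrics, fh, indent=2)

    return PipelineResult(
        partition=part, consensus=consensus, contingency=counts, metrics=metrics
    )
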