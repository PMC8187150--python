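"""Core domain containers.

The universal substrate is the beta-value matrix: per-probe methylation
fractions in [0, 1] with probes in rows and samples in columns (the usual
array-export orientation).  Around it sit the sample sheet (cohort roles),
the probe annotation table, and the knowledge-database objects: episignatures
(a disorder's selected probe set with reference means), trained classifiers
(linear weights plus Platt calibration), and the versioned database itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    BetaRangeError,
    EpisigError,
    IntegrityError,
    SchemaError,
)

MISSING = np.nan

SHEET_COLUMNS = [
    "sample_id",
    "sex",
    "age",
    "batch",
    "role",
    "replicate_of",
    "disorder_label",
    "cohort",
]

ROLES = {"reference_case", "reference_control", "test", "replicate"}
SEXES = {"M", "F", "unknown"}
COHORTS = {"targeted", "screening", "validation", "simulated"}

ANNOTATION_COLUMNS = ["probe_id", "chrom", "pos", "gene", "region_tag", "on_chrX"]


class BetaMatrix:
    """Probe x sample matrix of methylation beta fractions.

    Wraps a :class:`pandas.DataFrame` whose index holds unique probe ids and
    whose columns hold unique sample ids.  Missing values are NaN; every
    non-missing entry must lie in [0, 1].
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate probe ids: {dupes[:5]}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].unique().tolist()
            raise SchemaError(f"duplicate sample ids: {dupes[:5]}")
        values = data.to_numpy(dtype=float, copy=False)
        bad = (values < 0) | (values > 1)
        if np.any(bad):
            i, j = map(int, np.argwhere(bad)[0])
            raise BetaRangeError(
                f"beta value out of [0,1]: probe={data.index[i]!r} "
                f"sample={data.columns[j]!r} value={values[i, j]!r}"
            )
        self._data = data.astype(float)
        self._data.index.name = "probe_id"

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def probe_ids(self) -> list[str]:
        return self._data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self._data.shape

    def sample(self, sample_id: str) -> pd.Series:
        """Per-probe beta profile of one sample."""
        if sample_id not in self._data.columns:
            raise KeyError(sample_id)
        return self._data[sample_id]

    def restrict(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        """Sub-matrix over ``probe_ids`` (missing probes become NaN rows)."""
        return BetaMatrix(self._data.reindex(index=list(probe_ids)))

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(self._data.loc[:, list(sample_ids)])

    def equals(self, other: "BetaMatrix", tol: float = 1e-9) -> bool:
        if self.probe_ids != other.probe_ids or self.sample_ids != other.sample_ids:
            return False
        a, b = self._data.to_numpy(), other._data.to_numpy()
        both_nan = np.isnan(a) & np.isnan(b)
        close = np.isclose(a, b, atol=tol, equal_nan=False)
        return bool(np.all(both_nan | close))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        p, s = self.shape
        return f"BetaMatrix({p} probes x {s} samples)"


class SampleSheet:
    """Per-sample metadata: sex, age, batch, cohort role and disorder label.

    Invariants enforced at construction:

    * ``disorder_label`` is non-empty iff ``role == "reference_case"``;
    * ``replicate_of`` is non-empty iff ``role == "replicate"`` and names an
      existing sample in the sheet.
    """

    def __init__(self, data: pd.DataFrame):
        missing_cols = [c for c in SHEET_COLUMNS if c not in data.columns]
        if missing_cols:
            raise SchemaError(f"sample sheet missing columns: {missing_cols}")
        df = data.loc[:, SHEET_COLUMNS].copy()
        for col in ("sample_id", "sex", "batch", "role", "replicate_of",
                    "disorder_label", "cohort"):
            df[col] = df[col].fillna("").astype(str)
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
        if df["sample_id"].duplicated().any():
            raise SchemaError("duplicate sample ids in sheet")
        bad_roles = sorted(set(df["role"]) - ROLES)
        if bad_roles:
            raise SchemaError(f"unknown roles: {bad_roles}")
        bad_sex = sorted(set(df["sex"]) - SEXES)
        if bad_sex:
            raise SchemaError(f"unknown sex values: {bad_sex}")
        ids = set(df["sample_id"])
        for _, row in df.iterrows():
            is_case = row["role"] == "reference_case"
            if is_case != bool(row["disorder_label"]):
                raise SchemaError(
                    f"sample {row['sample_id']!r}: disorder_label must be set "
                    "iff role is reference_case"
                )
            is_rep = row["role"] == "replicate"
            if is_rep != bool(row["replicate_of"]):
                raise SchemaError(
                    f"sample {row['sample_id']!r}: replicate_of must be set "
                    "iff role is replicate"
                )
            if is_rep and row["replicate_of"] not in ids:
                raise SchemaError(
                    f"sample {row['sample_id']!r}: replicate_of "
                    f"{row['replicate_of']!r} not in sheet"
                )
        self._data = df.reset_index(drop=True)

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def sample_ids(self) -> list[str]:
        return self._data["sample_id"].tolist()

    def role_ids(self, role: str) -> list[str]:
        df = self._data
        return df.loc[df["role"] == role, "sample_id"].tolist()

    def case_ids(self, disorder_id: str) -> list[str]:
        df = self._data
        mask = (df["role"] == "reference_case") & (df["disorder_label"] == disorder_id)
        return df.loc[mask, "sample_id"].tolist()

    def control_ids(self) -> list[str]:
        return self.role_ids("reference_control")

    def disorders(self) -> list[str]:
        df = self._data
        labels = df.loc[df["role"] == "reference_case", "disorder_label"]
        return sorted(labels.unique())

    def sex_of(self, sample_id: str) -> str:
        df = self._data
        row = df.loc[df["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return str(row["sex"].iloc[0])

    def __len__(self) -> int:
        return len(self._data)


class ProbeAnnotation:
    """Probe genomic annotation with locus tags.

    ``region_tag`` is either ``""``/``"none"`` or ``"imprinted_dmr:<name>"`` /
    ``"repeat_locus:<name>"`` pointing into the locus registry.
    """

    def __init__(self, data: pd.DataFrame):
        missing_cols = [c for c in ANNOTATION_COLUMNS if c not in data.columns]
        if missing_cols:
            raise SchemaError(f"annotation missing columns: {missing_cols}")
        df = data.loc[:, ANNOTATION_COLUMNS].copy()
        for col in ("probe_id", "chrom", "gene", "region_tag"):
            df[col] = df[col].fillna("").astype(str)
        df["region_tag"] = df["region_tag"].replace("none", "")
        df["pos"] = pd.to_numeric(df["pos"]).astype(int)
        df["on_chrX"] = df["on_chrX"].astype(bool)
        if (df["pos"] < 1).any():
            raise SchemaError("positions are 1-based; found pos < 1")
        bad = df["region_tag"][
            (df["region_tag"] != "")
            & ~df["region_tag"].str.match(r"^(imprinted_dmr|repeat_locus):.+$")
        ]
        if len(bad):
            raise SchemaError(f"malformed region tags: {bad.unique()[:5].tolist()}")
        if df["probe_id"].duplicated().any():
            raise SchemaError("duplicate probe ids in annotation")
        self._data = df.reset_index(drop=True)

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    def locus_probes(self, name: str) -> list[str]:
        """Probe ids tagged with locus ``name`` (either locus type)."""
        df = self._data
        tag_suffix = ":" + name
        mask = df["region_tag"].str.endswith(tag_suffix) & (df["region_tag"] != "")
        return df.loc[mask, "probe_id"].tolist()

    def locus_names(self) -> dict[str, str]:
        """Map locus name -> locus type for every tagged locus."""
        out: dict[str, str] = {}
        for tag in self._data["region_tag"].unique():
            if not tag:
                continue
            locus_type, name = tag.split(":", 1)
            out[name] = locus_type
        return out


@dataclass(frozen=True)
class ThresholdConfig:
    """MVP-score decision bands: >t_pos positive, <t_neg negative, the closed
    band [t_neg, t_pos] inconclusive; replicate_tol is the concordance bound."""

    t_pos: float = 0.5
    t_neg: float = 0.1
    replicate_tol: float = 0.05

    def __post_init__(self):
        if not (0 <= self.t_neg < self.t_pos <= 1):
            raise EpisigError(
                f"thresholds must satisfy 0 <= t_neg < t_pos <= 1, "
                f"got t_neg={self.t_neg}, t_pos={self.t_pos}"
            )
        if self.replicate_tol <= 0:
            raise EpisigError("replicate_tol must be positive")


@dataclass(frozen=True)
class PlattParams:
    """Logistic link of Platt scaling: P(f) = 1 / (1 + exp(A*f + B)).

    A is negative whenever the positive class has the larger decision values,
    so the mapped probability increases with the decision value f.
    """

    A: float
    B: float


@dataclass
class Episignature:
    """A disorder's selected probe set with reference methylation means.

    ``delta`` is case_mean - control_mean per probe; ``selection_stat`` is the
    ranking statistic used at discovery time.  ``n_cases``/``n_controls``
    record the reference sample counts the means were computed on (needed for
    pooled re-averaging when signatures are merged).
    """

    disorder_id: str
    version: str
    probe_ids: list[str]
    control_mean: np.ndarray
    case_mean: np.ndarray
    delta: np.ndarray
    selection_stat: np.ndarray
    granularity: str = "gene"
    sensitivity_class: str = "robust"
    n_cases: int = 0
    n_controls: int = 0

    def __post_init__(self):
        self.probe_ids = list(self.probe_ids)
        if len(self.probe_ids) < 1:
            raise EpisigError("an episignature needs at least one probe")
        for name in ("control_mean", "case_mean", "delta", "selection_stat"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (len(self.probe_ids),):
                raise EpisigError(f"{name} length does not match probe_ids")
        for name in ("control_mean", "case_mean"):
            arr = getattr(self, name)
            if np.any((arr < 0) | (arr > 1)):
                raise BetaRangeError(f"{name} outside [0,1]")
        if np.max(np.abs(self.delta - (self.case_mean - self.control_mean))) > 1e-12:
            raise EpisigError("delta must equal case_mean - control_mean")
        if self.granularity not in {"gene", "gene_domain", "complex", "region"}:
            raise EpisigError(f"unknown granularity {self.granularity!r}")
        if self.sensitivity_class not in {"robust", "moderate"}:
            raise EpisigError(f"unknown sensitivity class {self.sensitivity_class!r}")

    def __len__(self) -> int:
        return len(self.probe_ids)


@dataclass
class TrainedClassifier:
    """Per-disorder linear margin classifier with Platt calibration.

    The decision value of a sample is ``weights . beta[signature probes] +
    bias``; the MVP score is the Platt-mapped probability of that decision.
    """

    disorder_id: str
    signature: Episignature
    weights: np.ndarray
    bias: float
    platt: PlattParams
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.signature.probe_ids),):
            raise EpisigError("weights length does not match signature probes")

    @property
    def probe_ids(self) -> list[str]:
        return self.signature.probe_ids


@dataclass
class LocusDefinition:
    """Registry entry for a screened locus with its control reference range."""

    name: str
    locus_type: str  # imprinted_dmr | repeat_locus
    control_mean: float
    control_sd: float

    def __post_init__(self):
        if self.locus_type not in {"imprinted_dmr", "repeat_locus"}:
            raise EpisigError(f"unknown locus type {self.locus_type!r}")


@dataclass
class KnowledgeDatabase:
    """Versioned store of episignatures, classifiers and control references.

    ``control_reference`` is a DataFrame indexed by probe_id with columns
    ``mean``/``sd`` covering all signature probes and registered locus probes.
    """

    version: str
    signatures: dict[str, Episignature] = field(default_factory=dict)
    classifiers: dict[str, TrainedClassifier] = field(default_factory=dict)
    control_reference: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["mean", "sd"])
    )
    locus_registry: list[LocusDefinition] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for disorder_id, clf in self.classifiers.items():
            if disorder_id not in self.signatures:
                raise IntegrityError(
                    f"classifier {disorder_id!r} references a signature "
                    "absent from the database"
                )
            if clf.signature.version != self.version:
                raise IntegrityError(
                    f"classifier {disorder_id!r} was trained on signature "
                    f"version {clf.signature.version!r}, store is {self.version!r}"
                )
        for sig in self.signatures.values():
            if sig.version != self.version:
                raise IntegrityError(
                    f"signature {sig.disorder_id!r} version {sig.version!r} "
                    f"does not match store version {self.version!r}"
                )


@dataclass
class ValidatedCohort:
    """A beta matrix and sample sheet known to describe the same samples."""

    beta: BetaMatrix
    sheet: SampleSheet
    missing_fraction: pd.Series  # per sample, fraction of NaN probes


def sheet_from_records(records: Iterable[Mapping]) -> SampleSheet:
    """Build a :class:`SampleSheet` from dict-like rows, filling defaults."""
    rows = []
    for rec in records:
        row = {c: "" for c in SHEET_COLUMNS}
        row["age"] = np.nan
        row.update(rec)
        rows.append(row)
    return SampleSheet(pd.DataFrame(rows, columns=SHEET_COLUMNS))
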