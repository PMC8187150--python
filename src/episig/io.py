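"""Readers, writers and the on-disk knowledge database.

All formats are plain UTF-8 text: beta matrices as TSV/CSV with a
``probe_id`` first column, sample sheets and probe annotations as CSV, and
the knowledge database as a directory of JSON files (one manifest, one
signature file and one classifier file per disorder) plus a CSV control
reference — diffable and versionable.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    BetaRangeError,
    CorruptStoreError,
    FormatError,
    ReconciliationError,
)
from .types import (
    ANNOTATION_COLUMNS,
    SHEET_COLUMNS,
    BetaMatrix,
    Episignature,
    KnowledgeDatabase,
    LocusDefinition,
    PlattParams,
    ProbeAnnotation,
    SampleSheet,
    ThresholdConfig,
    TrainedClassifier,
    ValidatedCohort,
)

_SEPS = {"tsv": "\t", "csv": ","}


def _dialect_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in _SEPS:
            raise FormatError(f"unknown dialect {dialect!r}")
        return dialect
    return "csv" if path.suffix.lower() == ".csv" else "tsv"


def read_beta_matrix(path, dialect: str | None = None) -> BetaMatrix:
    """Read a probe x sample beta matrix from TSV/CSV.

    The first column must be headed ``probe_id``; remaining header cells are
    sample ids.  Empty cells become missing values; any value outside [0, 1]
    raises :class:`BetaRangeError` naming the offending cell.
    """
    path = Path(path)
    sep = _SEPS[_dialect_for(path, dialect)]
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except Exception as exc:  # pandas parse failure
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.index.name != "probe_id":
        raise FormatError(
            f"{path}: first header cell must be 'probe_id', got {df.index.name!r}"
        )
    if len(df.columns) == 0:
        raise FormatError(f"{path}: no sample columns")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad_text = numeric.isna() & df.notna()  # empty cells parse to NaN already
    if bad_text.to_numpy().any():
        i, j = map(int, np.argwhere(bad_text.to_numpy())[0])
        raise FormatError(
            f"{path}: non-numeric beta value {df.iat[i, j]!r} at "
            f"probe={df.index[i]!r} sample={df.columns[j]!r}"
        )
    return BetaMatrix(numeric)


def write_beta_matrix(beta: BetaMatrix, path, dialect: str | None = None) -> None:
    path = Path(path)
    sep = _SEPS[_dialect_for(path, dialect)]
    beta.data.to_csv(path, sep=sep, float_format="%.10g", na_rep="")


def read_sample_sheet(path) -> SampleSheet:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {missing}")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, index=False)


def read_probe_annotation(path) -> ProbeAnnotation:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation missing columns {missing}")
    df["on_chrX"] = df["on_chrX"].map(
        {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}
    )
    return ProbeAnnotation(df)


def write_probe_annotation(annotation: ProbeAnnotation, path) -> None:
    annotation.data.to_csv(path, index=False)


def validate_cohort(beta: BetaMatrix, sheet: SampleSheet) -> ValidatedCohort:
    """Check that a beta matrix and sample sheet describe the same samples.

    Returns the pair together with a per-sample missing-probe fraction.
    Idempotent: validating the components of a validated cohort returns an
    identical result.
    """
    beta_ids = set(beta.sample_ids)
    sheet_ids = set(sheet.sample_ids)
    only_sheet = sorted(sheet_ids - beta_ids)
    only_beta = sorted(beta_ids - sheet_ids)
    if only_sheet or only_beta:
        raise ReconciliationError(
            f"sample mismatch: in sheet only {only_sheet[:10]}, "
            f"in matrix only {only_beta[:10]}"
        )
    # order samples as in the sheet for a canonical layout
    ordered = beta.subset_samples(sheet.sample_ids)
    missing = ordered.data.isna().mean(axis=0)
    missing.name = "missing_fraction"
    return ValidatedCohort(beta=ordered, sheet=sheet, missing_fraction=missing)


# ---------------------------------------------------------------------------
# knowledge database store
# ---------------------------------------------------------------------------

def _signature_to_dict(sig: Episignature) -> dict:
    return {
        "disorder_id": sig.disorder_id,
        "version": sig.version,
        "probe_ids": sig.probe_ids,
        "control_mean": sig.control_mean.tolist(),
        "case_mean": sig.case_mean.tolist(),
        "delta": sig.delta.tolist(),
        "selection_stat": sig.selection_stat.tolist(),
        "granularity": sig.granularity,
        "sensitivity_class": sig.sensitivity_class,
        "n_cases": sig.n_cases,
        "n_controls": sig.n_controls,
    }


def _signature_from_dict(d: dict) -> Episignature:
    return Episignature(
        disorder_id=d["disorder_id"],
        version=d["version"],
        probe_ids=d["probe_ids"],
        control_mean=np.asarray(d["control_mean"]),
        case_mean=np.asarray(d["case_mean"]),
        delta=np.asarray(d["delta"]),
        selection_stat=np.asarray(d["selection_stat"]),
        granularity=d["granularity"],
        sensitivity_class=d["sensitivity_class"],
        n_cases=d.get("n_cases", 0),
        n_controls=d.get("n_controls", 0),
    )


def _classifier_to_dict(clf: TrainedClassifier) -> dict:
    return {
        "disorder_id": clf.disorder_id,
        "weights": clf.weights.tolist(),
        "bias": clf.bias,
        "platt": {"A": clf.platt.A, "B": clf.platt.B},
        "thresholds": asdict(clf.thresholds),
        "training_meta": clf.training_meta,
    }


def persist_kdb(kdb: KnowledgeDatabase, path) -> str:
    """Write a knowledge database to ``path`` and return its version string.

    Layout: ``manifest.json`` (version, disorder list, locus registry),
    ``control_reference.csv``, and per-disorder files under ``signatures/``
    and ``classifiers/``.  JSON floats round-trip exactly.
    """
    kdb.validate()
    root = Path(path)
    (root / "signatures").mkdir(parents=True, exist_ok=True)
    (root / "classifiers").mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": kdb.version,
        "signatures": sorted(kdb.signatures),
        "classifiers": sorted(kdb.classifiers),
        "locus_registry": [asdict(ld) for ld in kdb.locus_registry],
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    kdb.control_reference.to_csv(
        root / "control_reference.csv", index_label="probe_id", float_format="%.17g"
    )
    for disorder_id, sig in kdb.signatures.items():
        (root / "signatures" / f"{disorder_id}.json").write_text(
            json.dumps(_signature_to_dict(sig))
        )
    for disorder_id, clf in kdb.classifiers.items():
        (root / "classifiers" / f"{disorder_id}.json").write_text(
            json.dumps(_classifier_to_dict(clf))
        )
    return kdb.version


def load_kdb(path) -> KnowledgeDatabase:
    """Load a knowledge database written by :func:`persist_kdb`."""
    root = Path(path)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise CorruptStoreError(f"missing manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    version = manifest["version"]

    ref_path = root / "control_reference.csv"
    if not ref_path.exists():
        raise CorruptStoreError(f"missing control reference: {ref_path}")
    control_reference = pd.read_csv(ref_path, index_col="probe_id")

    signatures: dict[str, Episignature] = {}
    for disorder_id in manifest["signatures"]:
        sig_path = root / "signatures" / f"{disorder_id}.json"
        if not sig_path.exists():
            raise CorruptStoreError(f"missing signature file: {sig_path}")
        signatures[disorder_id] = _signature_from_dict(json.loads(sig_path.read_text()))

    classifiers: dict[str, TrainedClassifier] = {}
    for disorder_id in manifest["classifiers"]:
        clf_path = root / "classifiers" / f"{disorder_id}.json"
        if not clf_path.exists():
            raise CorruptStoreError(f"missing classifier file: {clf_path}")
        d = json.loads(clf_path.read_text())
        if disorder_id not in signatures:
            raise CorruptStoreError(
                f"classifier {disorder_id!r} has no signature file in the store"
            )
        classifiers[disorder_id] = TrainedClassifier(
            disorder_id=d["disorder_id"],
            signature=signatures[disorder_id],
            weights=np.asarray(d["weights"]),
            bias=d["bias"],
            platt=PlattParams(**d["platt"]),
            thresholds=ThresholdConfig(**d["thresholds"]),
            training_meta=d["training_meta"],
        )

    registry = [LocusDefinition(**ld) for ld in manifest["locus_registry"]]
    return KnowledgeDatabase(
        version=version,
        signatures=signatures,
        classifiers=classifiers,
        control_reference=control_reference,
        locus_registry=registry,
    )
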