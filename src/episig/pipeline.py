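"""End-to-end orchestration: cohort -> knowledge database -> sample reports.

Thin glue over the module-level operations; everything here can also be done
step by step (see examples/).
"""

from __future__ import annotations

import pandas as pd

from .classify import score_sample, train_classifiers
from .evidence import ClusterEvidence, cluster_assign
from .io import validate_cohort
from .loci import LocusParams, build_locus_registry, screen_sample
from .report import EpisignatureReport, compose_report
from .signature import SelectionParams, select_signature_probes
from .types import (
    BetaMatrix,
    KnowledgeDatabase,
    ProbeAnnotation,
    SampleSheet,
    ThresholdConfig,
)


def build_kdb(
    beta: BetaMatrix,
    sheet: SampleSheet,
    disorder_ids: list[str] | None = None,
    annotation: ProbeAnnotation | None = None,
    params: SelectionParams = SelectionParams(),
    cv_folds: int = 10,
    seed: int = 0,
    version: str = "1",
    thresholds: ThresholdConfig = ThresholdConfig(),
) -> KnowledgeDatabase:
    """Discover signatures, train classifiers and assemble a database.

    ``disorder_ids`` defaults to every disorder with reference cases in the
    sheet.  When ``annotation`` is given, locus reference ranges are
    estimated from the reference controls and added to the registry.
    """
    cohort = validate_cohort(beta, sheet)
    disorder_ids = disorder_ids or sheet.disorders()
    signatures = {
        d: select_signature_probes(cohort.beta, sheet, d, params, version=version)
        for d in disorder_ids
    }
    classifiers = train_classifiers(
        cohort.beta, sheet, signatures, cv_folds=cv_folds, seed=seed,
        thresholds=thresholds, kdb_version=version,
    )

    control_ids = sheet.control_ids()
    ref_probes: list[str] = []
    for sig in signatures.values():
        ref_probes.extend(sig.probe_ids)
    registry = []
    if annotation is not None:
        registry = build_locus_registry(cohort.beta, sheet, annotation)
        for name in annotation.locus_names():
            ref_probes.extend(annotation.locus_probes(name))
    ref_probes = list(dict.fromkeys(ref_probes))
    ctrl = cohort.beta.restrict(ref_probes).data[control_ids]
    control_reference = pd.DataFrame(
        {"mean": ctrl.mean(axis=1), "sd": ctrl.std(axis=1, ddof=1)}
    )
    return KnowledgeDatabase(
        version=version,
        signatures=signatures,
        classifiers=classifiers,
        control_reference=control_reference,
        locus_registry=registry,
    )


def analyze_sample(
    beta: BetaMatrix,
    sheet: SampleSheet,
    kdb: KnowledgeDatabase,
    sample_id: str,
    annotation: ProbeAnnotation | None = None,
    margin_floor: float = 0.2,
    locus_params: LocusParams = LocusParams(),
    max_missing: float = 0.10,
    timestamp: str | None = None,
) -> EpisignatureReport:
    """Score one sample, gather secondary evidence, and compose its report.

    Cluster/MDS evidence is computed for every disorder whose MVP score is
    above the negative threshold (the disorders worth reviewing); locus
    screening runs whenever an annotation and registry are available.
    """
    thresholds = next(
        (c.thresholds for c in kdb.classifiers.values()), ThresholdConfig()
    )
    mvp = score_sample(kdb.classifiers, beta.sample(sample_id), sample_id,
                       max_missing=max_missing)

    evidence: dict[str, ClusterEvidence] = {}
    for disorder_id, score in mvp.scores.items():
        if score < thresholds.t_neg:
            continue
        sig = kdb.signatures[disorder_id]
        case_ids = sheet.case_ids(disorder_id)
        control_ids = sheet.control_ids()
        if len(case_ids) < 3 or len(control_ids) < 3:
            continue
        evidence[disorder_id] = cluster_assign(
            beta.restrict(sig.probe_ids),
            case_ids, control_ids, sample_id,
            disorder_id=disorder_id, margin_floor=margin_floor,
        )

    locus_results = []
    if annotation is not None and kdb.locus_registry:
        try:
            sex = sheet.sex_of(sample_id)
        except KeyError:
            sex = "unknown"
        locus_results = screen_sample(
            beta.sample(sample_id), annotation, kdb.locus_registry,
            sex=sex, params=locus_params,
        )

    return compose_report(
        mvp, evidence, locus_results, thresholds=thresholds,
        kdb_version=kdb.version, timestamp=timestamp,
    )
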