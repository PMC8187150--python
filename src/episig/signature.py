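"""Episignature discovery: probe selection from reference cases vs controls.

Selection is a Welch two-sample test per probe on the beta scale, Benjamini-
Hochberg corrected, combined with an absolute effect-size floor on the
case-control mean difference.  Surviving probes are ranked by
``|delta| * (-log10 p)`` with a lexicographic probe-id tie-break, making the
truncation at ``max_probes`` fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import CohortSizeError, EmptySignatureError, EpisigError, MergeError
from .types import BetaMatrix, Episignature, SampleSheet

_P_FLOOR = 1e-300  # guards -log10 against zero p-values


@dataclass(frozen=True)
class SelectionParams:
    """Tunable probe-selection criteria.

    min_abs_delta: minimum |case mean - control mean| on the beta scale.
    alpha: BH-adjusted two-sided significance level.
    max_probes: cap on signature size after ranking.
    min_cases / min_controls: smallest usable reference cohorts.
    """

    min_abs_delta: float = 0.10
    alpha: float = 0.01
    max_probes: int = 500
    min_cases: int = 5
    min_controls: int = 10

    def __post_init__(self):
        if not 0 < self.min_abs_delta < 1:
            raise EpisigError("min_abs_delta must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise EpisigError("alpha must be in (0, 1)")
        if self.max_probes < 1:
            raise EpisigError("max_probes must be >= 1")


def select_signature_probes(
    beta: BetaMatrix,
    sheet: SampleSheet,
    disorder_id: str,
    params: SelectionParams = SelectionParams(),
    version: str = "1",
) -> Episignature:
    """Derive the episignature of ``disorder_id`` from a reference cohort.

    Raises :class:`CohortSizeError` when reference cases or controls are too
    few, and :class:`EmptySignatureError` when no probe survives selection
    (an empty signature is never returned silently).
    """
    case_ids = sheet.case_ids(disorder_id)
    control_ids = sheet.control_ids()
    if len(case_ids) < params.min_cases:
        raise CohortSizeError(
            f"{disorder_id}: {len(case_ids)} reference cases "
            f"< min_cases={params.min_cases}"
        )
    if len(control_ids) < params.min_controls:
        raise CohortSizeError(
            f"{len(control_ids)} reference controls "
            f"< min_controls={params.min_controls}"
        )

    case_vals = beta.data[case_ids].to_numpy()
    ctrl_vals = beta.data[control_ids].to_numpy()
    case_mean = np.nanmean(case_vals, axis=1)
    ctrl_mean = np.nanmean(ctrl_vals, axis=1)
    delta = case_mean - ctrl_mean

    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(
            case_vals, ctrl_vals, axis=1, equal_var=False, nan_policy="omit"
        )
    pvals = np.asarray(pvals, dtype=float)
    pvals[~np.isfinite(pvals)] = 1.0  # degenerate probes (zero variance etc.)

    _, p_adj, _, _ = multipletests(pvals, alpha=params.alpha, method="fdr_bh")
    keep = (np.abs(delta) >= params.min_abs_delta) & (p_adj <= params.alpha)
    if not np.any(keep):
        raise EmptySignatureError(
            f"{disorder_id}: no probe passed |delta| >= {params.min_abs_delta} "
            f"and BH p <= {params.alpha}"
        )

    score = np.abs(delta) * (-np.log10(np.clip(pvals, _P_FLOOR, 1.0)))
    probe_ids = np.asarray(beta.probe_ids, dtype=object)
    kept = np.flatnonzero(keep)
    # rank by score descending, probe id ascending for ties
    order = kept[np.lexsort((probe_ids[kept], -score[kept]))]
    order = order[: params.max_probes]

    n_cases, n_controls = len(case_ids), len(control_ids)
    sensitivity = "moderate" if (len(order) < 50 or n_cases < 10) else "robust"
    return Episignature(
        disorder_id=disorder_id,
        version=version,
        probe_ids=probe_ids[order].tolist(),
        control_mean=ctrl_mean[order],
        case_mean=case_mean[order],
        delta=delta[order],
        selection_stat=score[order],
        granularity="gene",
        sensitivity_class=sensitivity,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def merge_signatures(
    parts: list[Episignature],
    granularity: str = "complex",
    disorder_id: str | None = None,
) -> Episignature:
    """Union of several signatures with pooled reference means.

    Per-probe means are the sample-count-weighted average of the contributing
    parts, which equals recomputing the means on the pooled reference samples
    when the parts came from disjoint cohorts.  Probe order is first
    appearance across the parts, so merging a signature with itself is the
    identity.
    """
    if not parts:
        raise MergeError("nothing to merge")
    versions = {p.version for p in parts}
    if len(versions) > 1:
        raise MergeError(f"signature versions differ: {sorted(versions)}")
    for p in parts:
        if p.n_cases <= 0 or p.n_controls <= 0:
            raise MergeError(
                f"{p.disorder_id}: sample counts unknown; cannot pool means"
            )

    order: list[str] = []
    seen: dict[str, list[tuple[Episignature, int]]] = {}
    for part in parts:
        for i, pid in enumerate(part.probe_ids):
            if pid not in seen:
                seen[pid] = []
                order.append(pid)
            seen[pid].append((part, i))

    control_mean = np.empty(len(order))
    case_mean = np.empty(len(order))
    stat = np.empty(len(order))
    for j, pid in enumerate(order):
        contribs = seen[pid]
        w_ctrl = np.array([p.n_controls for p, _ in contribs], dtype=float)
        w_case = np.array([p.n_cases for p, _ in contribs], dtype=float)
        cm = np.array([p.control_mean[i] for p, i in contribs])
        am = np.array([p.case_mean[i] for p, i in contribs])
        control_mean[j] = np.average(cm, weights=w_ctrl)
        case_mean[j] = np.average(am, weights=w_case)
        stat[j] = max(p.selection_stat[i] for p, i in contribs)

    n_cases = sum(p.n_cases for p in parts) if len(parts) > 1 else parts[0].n_cases
    n_controls = (sum(p.n_controls for p in parts) if len(parts) > 1
                  else parts[0].n_controls)
    if disorder_id is None:
        ids = sorted({p.disorder_id for p in parts})
        disorder_id = ids[0] if len(ids) == 1 else "+".join(ids)
    sensitivity = "moderate" if (len(order) < 50 or n_cases < 10) else "robust"
    return Episignature(
        disorder_id=disorder_id,
        version=parts[0].version,
        probe_ids=order,
        control_mean=control_mean,
        case_mean=case_mean,
        delta=case_mean - control_mean,
        selection_stat=stat,
        granularity=granularity,
        sensitivity_class=sensitivity,
        n_cases=n_cases,
        n_controls=n_controls,
    )
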