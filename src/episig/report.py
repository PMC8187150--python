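"""Final report composition, replicate concordance, cohort summaries.

A sample's evidence bundle — MVP scores per disorder, cluster/MDS evidence,
and locus screening results — collapses to a three-way status through an
ordered rule list (first match decides):

1. a positive-score disorder confirmed by clustering          -> positive
2. a positive-score disorder contradicted (or not confirmed)
   by clustering                                              -> inconclusive
3. all scores negative but cluster evidence intermediate and
   trending case-ward                                         -> inconclusive
4. any score in the inconclusive band                         -> inconclusive
5. a non-normal imprinted/repeat locus call                   -> positive
6. otherwise                                                  -> negative

Every non-trivial decision surfaces a human-readable review flag naming the
evidence item it came from; expert phenotype reasoning is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .classify import MVPResult
from .errors import ComparisonError, CompositionError
from .evidence import ClusterEvidence
from .loci import LocusResult
from .types import SampleSheet, ThresholdConfig


@dataclass
class EpisignatureReport:
    """Final three-way call for one sample with its evidence bundle."""

    sample_id: str
    kdb_version: str
    final_status: str  # positive | negative | inconclusive
    matched_disorders: list[str]
    mvp: MVPResult
    cluster_evidence: dict[str, ClusterEvidence]
    locus_results: list[LocusResult]
    review_flags: list[str] = field(default_factory=list)
    timestamp: str = ""

    def __post_init__(self):
        if (self.final_status == "positive") != bool(self.matched_disorders):
            raise CompositionError(
                "final_status is positive iff matched_disorders is non-empty"
            )


def compose_report(
    mvp: MVPResult,
    evidence: Mapping[str, ClusterEvidence] | None = None,
    loci: Sequence[LocusResult] = (),
    thresholds: ThresholdConfig = ThresholdConfig(),
    kdb_version: str = "",
    timestamp: str | None = None,
) -> EpisignatureReport:
    """Combine one sample's evidence into a final report (rules above)."""
    evidence = dict(evidence or {})
    for disorder_id, ev in evidence.items():
        if ev.sample_id != mvp.sample_id:
            raise CompositionError(
                f"cluster evidence for {ev.sample_id!r} does not match "
                f"sample {mvp.sample_id!r} (disorder {disorder_id})"
            )

    flags: list[str] = []
    status: str | None = None
    matched: list[str] = []

    positive_scores = [d for d, c in mvp.categories.items() if c == "positive"]
    inconclusive_scores = [d for d, c in mvp.categories.items()
                           if c == "inconclusive"]
    for disorder_id, message in sorted(mvp.coverage_errors.items()):
        flags.append(f"{disorder_id}: not scored, {message}")

    # rule 1: positive score confirmed by clustering
    confirmed = []
    for d in sorted(positive_scores):
        ev = evidence.get(d)
        if ev is None:
            confirmed.append(d)
            flags.append(f"{d}: positive MVP score without cluster evidence")
        elif ev.call == "with_cases":
            confirmed.append(d)
    if confirmed:
        status = "positive"
        matched = confirmed
        if len(confirmed) > 1:
            flags.append(
                "multiple simultaneous positive episignatures: "
                + ", ".join(confirmed)
            )

    # rule 2: positive score contradicted / not confirmed by clustering
    if status is None and positive_scores:
        status = "inconclusive"
        for d in sorted(positive_scores):
            call = evidence[d].call
            if call == "with_controls":
                flags.append(f"{d}: score/cluster discordant "
                             "(positive MVP, clusters with controls)")
            else:
                flags.append(f"{d}: positive MVP but cluster evidence "
                             f"{call}, not confirmatory")

    # rule 3: all scores negative, cluster evidence trending case-ward
    if status is None and not inconclusive_scores:
        trending = [d for d, ev in sorted(evidence.items())
                    if ev.call == "intermediate" and ev.margin > 0]
        if trending:
            status = "inconclusive"
            for d in trending:
                flags.append(
                    f"{d}: MVP negative but sample plots between cases and "
                    f"controls (margin {evidence[d].margin:+.2f})"
                )

    # rule 4: inconclusive-band scores
    if status is None and inconclusive_scores:
        status = "inconclusive"
        for d in sorted(inconclusive_scores):
            flags.append(
                f"{d}: MVP score {mvp.scores[d]:.2f} in the inconclusive band "
                f"[{thresholds.t_neg}, {thresholds.t_pos}]"
            )

    # rule 5: locus screening positives
    if status is None:
        aberrant = [lr for lr in loci
                    if lr.call in ("hypermethylated", "hypomethylated")]
        if aberrant:
            status = "positive"
            matched = [lr.locus for lr in aberrant]
            for lr in aberrant:
                frac = ("" if lr.estimated_aberrant_fraction is None else
                        f", estimated aberrant fraction "
                        f"{lr.estimated_aberrant_fraction:.2f}")
                flags.append(f"{lr.locus}: {lr.call} (z {lr.z:+.1f}{frac})")

    # rule 6: nothing matched
    if status is None:
        status = "negative"

    for lr in loci:
        if lr.call == "indeterminate":
            flags.append(f"{lr.locus}: indeterminate locus screen (z {lr.z:+.1f})")

    return EpisignatureReport(
        sample_id=mvp.sample_id,
        kdb_version=kdb_version,
        final_status=status,
        matched_disorders=matched,
        mvp=mvp,
        cluster_evidence=evidence,
        locus_results=list(loci),
        review_flags=flags,
        timestamp=timestamp if timestamp is not None
        else datetime.now(timezone.utc).isoformat(),
    )


@dataclass
class ConcordanceResult:
    concordant: bool
    max_delta: float
    discordant_disorders: list[str] = field(default_factory=list)


def check_replicate_concordance(
    r1: MVPResult, r2: MVPResult, tol: float = 0.05
) -> ConcordanceResult:
    """Compare two replicate score sets: concordant iff every disorder's
    scores agree within ``tol`` AND categories agree everywhere."""
    if set(r1.disorders()) != set(r2.disorders()):
        raise ComparisonError(
            f"disorder panels differ: {sorted(r1.disorders())} vs "
            f"{sorted(r2.disorders())}"
        )
    offenders = []
    max_delta = 0.0
    for d in sorted(set(r1.scores) | set(r2.scores)):
        if d not in r1.scores or d not in r2.scores:
            offenders.append(d)  # scored in one replicate only
            continue
        delta = abs(r1.scores[d] - r2.scores[d])
        max_delta = max(max_delta, delta)
        if delta > tol or r1.categories[d] != r2.categories[d]:
            offenders.append(d)
    return ConcordanceResult(
        concordant=not offenders,
        max_delta=max_delta,
        discordant_disorders=offenders,
    )


def percent(k: int, n: int) -> float:
    """k/n as a percentage, half-up rounded to one decimal."""
    if n == 0:
        return float("nan")
    return float(
        (Decimal(k) * 100 / Decimal(n)).quantize(Decimal("0.1"), ROUND_HALF_UP)
    )


def summarize_counts(positive: int, negative: int, inconclusive: int) -> dict:
    """Summary percentages from raw outcome counts."""
    n = positive + negative + inconclusive
    return {
        "n": n,
        "positive": positive,
        "negative": negative,
        "inconclusive": inconclusive,
        "pct_positive": percent(positive, n),
        "pct_negative": percent(negative, n),
        "pct_inconclusive": percent(inconclusive, n),
        "pct_conclusive": percent(positive + negative, n),
    }


def summarize_cohort(
    reports: Sequence[EpisignatureReport],
    sheet: SampleSheet | None = None,
) -> pd.DataFrame:
    """Outcome counts and percentages, overall and per cohort tag."""
    if not reports:
        return pd.DataFrame(
            columns=["cohort", "n", "positive", "negative", "inconclusive",
                     "pct_positive", "pct_negative", "pct_inconclusive",
                     "pct_conclusive"]
        )
    statuses = {r.sample_id: r.final_status for r in reports}
    cohorts = {}
    if sheet is not None:
        cohorts = dict(zip(sheet.data["sample_id"], sheet.data["cohort"]))

    def tally(sample_ids):
        counts = {"positive": 0, "negative": 0, "inconclusive": 0}
        for sid in sample_ids:
            counts[statuses[sid]] += 1
        return summarize_counts(**counts)

    rows = [{"cohort": "all", **tally(statuses)}]
    for tag in sorted(set(cohorts.get(sid, "") for sid in statuses) - {""}):
        ids = [sid for sid in statuses if cohorts.get(sid) == tag]
        rows.append({"cohort": tag, **tally(ids)})
    return pd.DataFrame(rows)


def render_text(report: EpisignatureReport) -> str:
    """Plain-text rendering of a report for log files and stdout."""
    lines = [
        f"sample:      {report.sample_id}",
        f"kdb version: {report.kdb_version}",
        f"status:      {report.final_status.upper()}",
    ]
    if report.matched_disorders:
        lines.append("matched:     " + ", ".join(report.matched_disorders))
    if report.mvp.scores:
        lines.append("MVP scores:")
        for d in sorted(report.mvp.scores):
            lines.append(f"  {d:<20s} {report.mvp.scores[d]:.3f} "
                         f"({report.mvp.categories[d]})")
    for lr in report.locus_results:
        lines.append(f"locus {lr.locus:<14s} mean {lr.observed_mean:.3f} "
                     f"z {lr.z:+.1f} -> {lr.call}")
    for flag in report.review_flags:
        lines.append(f"flag: {flag}")
    return "\n".join(lines)
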