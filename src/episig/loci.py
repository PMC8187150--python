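"""Concurrent screening of imprinted DMRs and repeat-expansion loci.

Imprinted differentially methylated regions sit near 50% methylation in
blood; loss or gain of methylation (and its mosaic dilution) moves the
locus mean toward 0 or 1.  Repeat-expansion promoter loci (fragile-X-like)
are normally unmethylated and become hypermethylated on full expansion in
males; in females the unaffected X masks the signal, so elevated female
repeat loci are reported indeterminate rather than called.

Calls compare the observed locus mean to the control reference range with a
combined z-score and absolute-difference guard, and estimate the aberrant
cell fraction under the same linear two-population mixture used by the
simulator.  Deviations whose implied fraction is below ``min_fraction``
(default 0.2 — the practical detection floor set by normal control
variability) are reported indeterminate, not called.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ControlReferenceError, LocusCoverageError
from .types import BetaMatrix, LocusDefinition, ProbeAnnotation, SampleSheet


@dataclass(frozen=True)
class LocusParams:
    z_cut: float = 3.0
    delta_cut: float = 0.10
    min_fraction: float = 0.2
    min_probes: int = 3


@dataclass
class LocusResult:
    """Outcome of screening one locus in one sample."""

    locus: str
    locus_type: str
    observed_mean: float
    control_mean: float
    control_sd: float
    z: float
    estimated_aberrant_fraction: float | None
    call: str  # normal | hypermethylated | hypomethylated | indeterminate


def summarize_locus(
    sample: pd.Series,
    annotation: ProbeAnnotation,
    locus: str,
    min_probes: int = 3,
) -> float:
    """Mean beta of the sample's non-missing probes tagged with ``locus``."""
    probes = annotation.locus_probes(locus)
    values = sample.reindex(probes).dropna()
    if len(values) < min_probes:
        raise LocusCoverageError(
            f"{locus}: {len(values)} usable probes < required {min_probes}"
        )
    return float(values.mean())


def assess_locus(
    locus: str,
    locus_type: str,
    observed_mean: float,
    control_mean: float,
    control_sd: float,
    sex: str = "unknown",
    params: LocusParams = LocusParams(),
) -> LocusResult:
    """Call one locus from its observed mean and control reference range.

    hyper/hypo requires |z| > z_cut AND |delta| > delta_cut AND an estimated
    aberrant fraction of at least ``min_fraction``; the fraction estimate is
    |observed - control| / |target - control| with target 1 (hyper) or 0
    (hypo), clipped to [0, 1].  Female samples at repeat loci are always
    indeterminate (heterozygote masking).
    """
    if control_sd <= 0:
        raise ControlReferenceError(
            f"{locus}: control_sd must be positive, got {control_sd}"
        )
    delta = observed_mean - control_mean
    z = delta / control_sd

    target = 1.0 if delta >= 0 else 0.0
    denom = abs(target - control_mean)
    fraction = None if denom == 0 else float(np.clip(abs(delta) / denom, 0.0, 1.0))

    if locus_type == "repeat_locus" and sex == "F":
        call = "indeterminate"
        fraction = None
    elif abs(z) <= params.z_cut and abs(delta) <= params.delta_cut:
        call = "normal"
    elif (abs(z) > params.z_cut and abs(delta) > params.delta_cut
          and fraction is not None and fraction >= params.min_fraction):
        call = "hypermethylated" if delta > 0 else "hypomethylated"
    else:
        call = "indeterminate"

    return LocusResult(
        locus=locus,
        locus_type=locus_type,
        observed_mean=float(observed_mean),
        control_mean=float(control_mean),
        control_sd=float(control_sd),
        z=float(z),
        estimated_aberrant_fraction=fraction,
        call=call,
    )


def build_locus_registry(
    beta: BetaMatrix,
    sheet: SampleSheet,
    annotation: ProbeAnnotation,
    min_probes: int = 3,
) -> list[LocusDefinition]:
    """Estimate control reference ranges for every annotated locus.

    The control mean and SD are computed over the locus means of the
    reference controls.
    """
    controls = sheet.control_ids()
    registry = []
    for name, locus_type in sorted(annotation.locus_names().items()):
        means = [
            summarize_locus(beta.sample(sid), annotation, name, min_probes)
            for sid in controls
        ]
        registry.append(LocusDefinition(
            name=name,
            locus_type=locus_type,
            control_mean=float(np.mean(means)),
            control_sd=float(np.std(means, ddof=1)),
        ))
    return registry


def screen_sample(
    sample: pd.Series,
    annotation: ProbeAnnotation,
    registry: list[LocusDefinition],
    sex: str = "unknown",
    params: LocusParams = LocusParams(),
) -> list[LocusResult]:
    """Screen one sample across every registered locus."""
    results = []
    for locus_def in registry:
        observed = summarize_locus(sample, annotation, locus_def.name,
                                   params.min_probes)
        results.append(assess_locus(
            locus=locus_def.name,
            locus_type=locus_def.locus_type,
            observed_mean=observed,
            control_mean=locus_def.control_mean,
            control_sd=locus_def.control_sd,
            sex=sex,
            params=params,
        ))
    return results
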