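"""Synthetic methylation cohorts with known ground truth.

The generator emulates the features of peripheral-blood array data that the
rest of the package depends on: a genome-wide bimodal beta-value landscape
(most probes near 0 or 1, a minor intermediate component), disorder-specific
signature probes shifted by a mean beta delta in cases, imprinted DMRs
centred at 0.5, repeat-expansion promoter loci near 0 that become
hypermethylated in affected males, linear mosaic mixtures, X-linked dosage
dilution, additive batch offsets, and technical replicate pairs that share
biology and differ only by Gaussian technical noise.

Determinism contract: identical (config, seed) yields bitwise-identical
output, and each sample's noise stream is derived by stable hashing of its
id, so adding a sample never perturbs existing ones.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import BetaRangeError, EpisigError
from .types import BetaMatrix, ProbeAnnotation, SampleSheet, sheet_from_records

log = logging.getLogger(__name__)

#: Beta-mixture parameters of the genome-wide background: weights and
#: (a, b) shapes of the near-0 / near-1 / intermediate components.
BACKGROUND_MIXTURE = (
    (0.45, (2.0, 18.0)),
    (0.45, (18.0, 2.0)),
    (0.10, (5.0, 5.0)),
)

IMPRINTED_BASELINE = 0.5
REPEAT_BASELINE = 0.05
REPEAT_ABERRANT_MEAN = 0.9


@dataclass(frozen=True)
class DisorderSim:
    """One simulated disorder: its signature size, shift and cohort sizes."""

    disorder_id: str
    n_signature_probes: int = 200
    delta: float = 0.15
    n_cases: int = 20
    n_test: int = 10

    def __post_init__(self):
        if not -1 < self.delta < 1:
            raise BetaRangeError(f"delta must be in (-1, 1), got {self.delta}")
        if min(self.n_signature_probes, self.n_cases, self.n_test) < 0:
            raise EpisigError("counts must be non-negative")


@dataclass(frozen=True)
class AberrantSim:
    direction: str  # hyper | hypo
    fraction: float  # aberrant cell fraction in (0, 1]

    def __post_init__(self):
        if self.direction not in {"hyper", "hypo"}:
            raise EpisigError(f"unknown direction {self.direction!r}")
        if not 0 < self.fraction <= 1:
            raise BetaRangeError(f"fraction must be in (0, 1], got {self.fraction}")


@dataclass(frozen=True)
class LocusSim:
    """A simulated imprinted DMR or repeat locus with optional aberrant samples."""

    name: str
    locus_type: str  # imprinted_dmr | repeat_locus
    n_probes: int = 10
    aberrant_samples: tuple[AberrantSim, ...] = ()

    def __post_init__(self):
        if self.locus_type not in {"imprinted_dmr", "repeat_locus"}:
            raise EpisigError(f"unknown locus type {self.locus_type!r}")
        object.__setattr__(self, "aberrant_samples", tuple(self.aberrant_samples))


@dataclass(frozen=True)
class MosaicSim:
    disorder_id: str
    fraction: float

    def __post_init__(self):
        if not 0 <= self.fraction <= 1:
            raise BetaRangeError(f"fraction must be in [0, 1], got {self.fraction}")


@dataclass(frozen=True)
class DilutionSim:
    disorder_id: str
    dosage_factor: float

    def __post_init__(self):
        if not 0 <= self.dosage_factor <= 1:
            raise BetaRangeError(
                f"dosage_factor must be in [0, 1], got {self.dosage_factor}"
            )


def _default_disorders() -> tuple[DisorderSim, ...]:
    return (
        DisorderSim("SYND_A"),
        DisorderSim("SYND_B"),
        DisorderSim("SYND_C"),
    )


def _default_imprinted() -> tuple[LocusSim, ...]:
    return (
        LocusSim("ICR_A", "imprinted_dmr"),
        LocusSim("ICR_B", "imprinted_dmr"),
    )


def _default_repeat() -> tuple[LocusSim, ...]:
    return (LocusSim("TNR_X", "repeat_locus"),)


@dataclass(frozen=True)
class SimulationConfig:
    """Full recipe for a synthetic cohort.

    Defaults define the standard simulated panel used throughout the test
    suite: three disorders with 200 signature probes each shifted by 0.15,
    20 reference cases and 10 held-out test cases per disorder, 100 reference
    controls, 30 held-out test controls, 20,000 background probes and
    technical noise of SD 0.01 on the beta scale.
    """

    n_background_probes: int = 20_000
    disorders: tuple[DisorderSim, ...] = field(default_factory=_default_disorders)
    n_controls: int = 100
    n_test_controls: int = 30
    technical_sd: float = 0.01
    batch_effects: tuple[float, ...] = ()
    mosaic_samples: tuple[MosaicSim, ...] = ()
    dilution_samples: tuple[DilutionSim, ...] = ()
    imprinted_loci: tuple[LocusSim, ...] = field(default_factory=_default_imprinted)
    repeat_loci: tuple[LocusSim, ...] = field(default_factory=_default_repeat)
    locus_biological_sd: float = 0.02
    replicate_pairs: int = 0
    seed: int = 42

    def __post_init__(self):
        for name in ("disorders", "batch_effects", "mosaic_samples",
                     "dilution_samples", "imprinted_loci", "repeat_loci"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        if self.technical_sd < 0:
            raise BetaRangeError("technical_sd must be >= 0")
        if min(self.n_background_probes, self.n_controls,
               self.n_test_controls, self.replicate_pairs) < 0:
            raise EpisigError("counts must be non-negative")


def default_config(seed: int = 42, **overrides) -> SimulationConfig:
    """The standard simulated panel, optionally with field overrides."""
    return SimulationConfig(seed=seed, **overrides)


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from plain dicts/lists (e.g. parsed YAML)."""
    d = dict(d)
    if "disorders" in d:
        d["disorders"] = tuple(DisorderSim(**x) for x in d["disorders"])
    for key in ("imprinted_loci", "repeat_loci"):
        if key in d:
            loci = []
            for x in d[key]:
                x = dict(x)
                x["aberrant_samples"] = tuple(
                    AberrantSim(**a) for a in x.get("aberrant_samples", [])
                )
                loci.append(LocusSim(**x))
            d[key] = tuple(loci)
    if "mosaic_samples" in d:
        d["mosaic_samples"] = tuple(MosaicSim(**x) for x in d["mosaic_samples"])
    if "dilution_samples" in d:
        d["dilution_samples"] = tuple(DilutionSim(**x) for x in d["dilution_samples"])
    if "batch_effects" in d:
        d["batch_effects"] = tuple(float(x) for x in d["batch_effects"])
    return SimulationConfig(**d)


@dataclass
class SimulatedCohort:
    """Simulation output: data, metadata, annotation and the ground truth.

    ``baseline`` is the noise-free control biology per probe;
    ``case_profiles`` maps disorder id to the noise-free affected biology.
    """

    beta: BetaMatrix
    sheet: SampleSheet
    annotation: ProbeAnnotation
    truth: pd.DataFrame
    baseline: pd.Series
    case_profiles: dict[str, pd.Series]
    config: SimulationConfig


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def mix_mosaic(case_profile, control_profile, fraction: float) -> np.ndarray:
    """Linear allele-dosage mixture of affected and unaffected biology.

    beta_mix = fraction * beta_case + (1 - fraction) * beta_control, so the
    displacement of the mixture from the control profile is exactly
    proportional to the aberrant cell fraction.
    """
    if not 0 <= fraction <= 1:
        raise BetaRangeError(f"fraction must be in [0, 1], got {fraction}")
    case = np.asarray(case_profile, dtype=float)
    control = np.asarray(control_profile, dtype=float)
    if case.shape != control.shape:
        raise EpisigError("case and control profiles must cover the same probes")
    return fraction * case + (1.0 - fraction) * control


def apply_technical_noise(profile, sd: float, seed) -> np.ndarray:
    """Additive Gaussian technical noise, clipped to [0, 1].

    ``seed`` may be an int or a :class:`numpy.random.Generator`.
    """
    if sd < 0:
        raise BetaRangeError(f"sd must be >= 0, got {sd}")
    values = np.asarray(profile, dtype=float)
    if sd == 0:
        return values.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.clip(values + rng.normal(0.0, sd, size=values.shape), 0.0, 1.0)


def _sample_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-sample stream from the global seed and a stable hash."""
    digest = hashlib.blake2b(
        f"{seed}:{label}".encode(), digest_size=8
    ).digest()
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, int.from_bytes(digest, "big")])
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _draw_background(rng: np.random.Generator, n: int) -> np.ndarray:
    weights = np.array([w for w, _ in BACKGROUND_MIXTURE])
    comps = rng.choice(len(BACKGROUND_MIXTURE), size=n, p=weights / weights.sum())
    out = np.empty(n)
    for k, (_, (a, b)) in enumerate(BACKGROUND_MIXTURE):
        mask = comps == k
        out[mask] = rng.beta(a, b, size=int(mask.sum()))
    return out


def _signature_baselines(rng: np.random.Generator, n: int, delta: float) -> np.ndarray:
    # leave room for the shift so case means stay inside [0, 1] without clipping
    lo = max(0.10, 0.02 - delta)
    hi = min(0.90, 0.98 - delta)
    if hi <= lo:  # extreme shifts cannot avoid clipping; keep a valid interval
        hi = lo + 0.01
    return rng.uniform(lo, hi, size=n)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a full synthetic cohort from ``config``.

    Returns the beta matrix (probes x samples), sample sheet, probe
    annotation, a per-sample truth table, and the noise-free biology
    profiles the samples were built from.
    """
    master = np.random.default_rng(config.seed)

    # ---- probe panel -------------------------------------------------------
    probe_ids: list[str] = []
    annotation_rows: list[dict] = []
    baseline_parts: list[np.ndarray] = []

    n_bg = config.n_background_probes
    bg_ids = [f"bg_{i:06d}" for i in range(n_bg)]
    probe_ids.extend(bg_ids)
    baseline_parts.append(_draw_background(master, n_bg))
    for i, pid in enumerate(bg_ids):
        annotation_rows.append({
            "probe_id": pid, "chrom": f"chr{(i % 22) + 1}", "pos": 1000 + 100 * i,
            "gene": "", "region_tag": "", "on_chrX": False,
        })

    sig_index: dict[str, np.ndarray] = {}
    for d_i, dis in enumerate(config.disorders):
        ids = [f"sig_{dis.disorder_id}_{i:04d}" for i in range(dis.n_signature_probes)]
        start = len(probe_ids)
        probe_ids.extend(ids)
        sig_index[dis.disorder_id] = np.arange(start, start + len(ids))
        baseline_parts.append(
            _signature_baselines(master, dis.n_signature_probes, dis.delta)
        )
        for i, pid in enumerate(ids):
            annotation_rows.append({
                "probe_id": pid, "chrom": f"chr{(d_i % 22) + 1}",
                "pos": 5_000_000 + 100 * i, "gene": dis.disorder_id,
                "region_tag": "", "on_chrX": False,
            })

    locus_index: dict[str, np.ndarray] = {}
    for locus in config.imprinted_loci + config.repeat_loci:
        ids = [f"{locus.name}_{i:03d}" for i in range(locus.n_probes)]
        start = len(probe_ids)
        probe_ids.extend(ids)
        locus_index[locus.name] = np.arange(start, start + len(ids))
        base = (IMPRINTED_BASELINE if locus.locus_type == "imprinted_dmr"
                else REPEAT_BASELINE)
        baseline_parts.append(np.full(locus.n_probes, base))
        on_x = locus.locus_type == "repeat_locus"
        for i, pid in enumerate(ids):
            annotation_rows.append({
                "probe_id": pid, "chrom": "chrX" if on_x else "chr15",
                "pos": 9_000_000 + 100 * i, "gene": locus.name,
                "region_tag": f"{locus.locus_type}:{locus.name}", "on_chrX": on_x,
            })

    baseline = np.concatenate(baseline_parts) if baseline_parts else np.empty(0)
    n_probes = len(probe_ids)

    # ---- noise-free disorder profiles --------------------------------------
    case_profiles: dict[str, np.ndarray] = {}
    for dis in config.disorders:
        profile = baseline.copy()
        idx = sig_index[dis.disorder_id]
        shifted = profile[idx] + dis.delta
        n_clip = int(np.sum((shifted < 0) | (shifted > 1)))
        if n_clip:
            log.warning(
                "disorder %s: delta %.3f clips %d signature probe means",
                dis.disorder_id, dis.delta, n_clip,
            )
        profile[idx] = np.clip(shifted, 0.0, 1.0)
        case_profiles[dis.disorder_id] = profile

    # ---- enumerate samples --------------------------------------------------
    # each entry: (sample_id, biology_label, role, disorder_label, truth row)
    all_loci = {locus.name: locus for locus in
                config.imprinted_loci + config.repeat_loci}

    samples: list[dict] = []

    def add(sample_id: str, role: str, *, disorder_label: str = "",
            replicate_of: str = "", sex: str | None = None, truth: dict | None = None,
            biology_of: str | None = None):
        samples.append({
            "sample_id": sample_id,
            "role": role,
            "disorder_label": disorder_label,
            "replicate_of": replicate_of,
            "sex": sex,
            "truth": truth or {},
            "biology_of": biology_of or sample_id,
        })

    for i in range(config.n_controls):
        add(f"ctrl_{i:04d}", "reference_control",
            truth={"group": "control"})
    for dis in config.disorders:
        for i in range(dis.n_cases):
            add(f"case_{dis.disorder_id}_{i:04d}", "reference_case",
                disorder_label=dis.disorder_id,
                truth={"group": "case", "disorder_id": dis.disorder_id})
        for i in range(dis.n_test):
            add(f"test_{dis.disorder_id}_{i:04d}", "test",
                truth={"group": "test_case", "disorder_id": dis.disorder_id})
    for i in range(config.n_test_controls):
        add(f"testctrl_{i:04d}", "test", truth={"group": "test_control"})
    for i, mos in enumerate(config.mosaic_samples):
        add(f"mosaic_{mos.disorder_id}_{i:03d}", "test",
            truth={"group": "mosaic", "disorder_id": mos.disorder_id,
                   "mosaic_fraction": mos.fraction})
    for i, dil in enumerate(config.dilution_samples):
        add(f"dilution_{dil.disorder_id}_{i:03d}", "test",
            truth={"group": "dilution", "disorder_id": dil.disorder_id,
                   "dosage_factor": dil.dosage_factor})
    for locus in all_loci.values():
        for i, ab in enumerate(locus.aberrant_samples):
            sex = "M" if locus.locus_type == "repeat_locus" else None
            add(f"aberrant_{locus.name}_{i:03d}", "test", sex=sex,
                truth={"group": "locus_aberrant", "locus": locus.name,
                       "locus_direction": ab.direction,
                       "locus_fraction": ab.fraction})

    # replicate pairs: duplicate the first k reference samples (biology shared)
    reference = [s for s in samples
                 if s["role"] in ("reference_control", "reference_case")]
    for i in range(config.replicate_pairs):
        base = reference[i % len(reference)]
        add(base["sample_id"] + "_rep", "replicate",
            replicate_of=base["sample_id"],
            truth={"group": "replicate", "replicate_of": base["sample_id"]},
            biology_of=base["sample_id"])

    # ---- realise biology + noise -------------------------------------------
    n_batches = max(1, len(config.batch_effects))
    batch_offsets = config.batch_effects or (0.0,)

    def biology_for(entry: dict) -> np.ndarray:
        t = entry["truth"]
        group = t.get("group", "control")
        if group in ("case", "test_case"):
            bio = case_profiles[t["disorder_id"]].copy()
        elif group == "mosaic":
            bio = mix_mosaic(case_profiles[t["disorder_id"]], baseline,
                             t["mosaic_fraction"])
        elif group == "dilution":
            dis = next(d for d in config.disorders
                       if d.disorder_id == t["disorder_id"])
            bio = baseline.copy()
            idx = sig_index[t["disorder_id"]]
            bio[idx] = np.clip(bio[idx] + dis.delta * t["dosage_factor"], 0, 1)
        else:
            bio = baseline.copy()
        # per-sample locus-level biological wobble (normal control variability)
        brng = _sample_rng(config.seed, "bio:" + entry["biology_of"])
        for name, idx in locus_index.items():
            bio[idx] = bio[idx] + brng.normal(0.0, config.locus_biological_sd)
        if group == "locus_aberrant":
            locus = all_loci[t["locus"]]
            idx = locus_index[t["locus"]]
            if locus.locus_type == "imprinted_dmr":
                target = 1.0 if t["locus_direction"] == "hyper" else 0.0
            else:
                target = (REPEAT_ABERRANT_MEAN if t["locus_direction"] == "hyper"
                          else 0.0)
            bio[idx] = mix_mosaic(np.full(idx.size, target), bio[idx],
                                  t["locus_fraction"])
        return np.clip(bio, 0.0, 1.0)

    columns = {}
    sheet_rows = []
    truth_rows = []
    for order, entry in enumerate(samples):
        sid = entry["sample_id"]
        bio = biology_for(entry)
        batch_i = order % n_batches
        bio = bio + batch_offsets[batch_i]
        nrng = _sample_rng(config.seed, "noise:" + sid)
        columns[sid] = apply_technical_noise(np.clip(bio, 0, 1),
                                             config.technical_sd, nrng)
        sex = entry["sex"] or ("M" if order % 2 == 0 else "F")
        sheet_rows.append({
            "sample_id": sid,
            "sex": sex,
            "age": float(3 + order % 35),
            "batch": f"batch{batch_i}",
            "role": entry["role"],
            "replicate_of": entry["replicate_of"],
            "disorder_label": entry["disorder_label"],
            "cohort": "simulated",
        })
        t = entry["truth"]
        truth_rows.append({
            "sample_id": sid,
            "group": t.get("group", ""),
            "disorder_id": t.get("disorder_id", ""),
            "mosaic_fraction": t.get("mosaic_fraction", np.nan),
            "dosage_factor": t.get("dosage_factor", np.nan),
            "locus": t.get("locus", ""),
            "locus_direction": t.get("locus_direction", ""),
            "locus_fraction": t.get("locus_fraction", np.nan),
            "seed": config.seed,
        })

    beta = BetaMatrix(pd.DataFrame(columns, index=pd.Index(probe_ids, name="probe_id")))
    sheet = sheet_from_records(sheet_rows)
    annotation = ProbeAnnotation(pd.DataFrame(annotation_rows))
    truth = pd.DataFrame(truth_rows)
    probe_index = pd.Index(probe_ids, name="probe_id")
    return SimulatedCohort(
        beta=beta,
        sheet=sheet,
        annotation=annotation,
        truth=truth,
        baseline=pd.Series(baseline, index=probe_index, name="baseline"),
        case_profiles={
            k: pd.Series(v, index=probe_index, name=k)
            for k, v in case_profiles.items()
        },
        config=config,
    )


def planted_probes(cohort: SimulatedCohort, disorder_id: str) -> list[str]:
    """Probe ids whose means were truly shifted for ``disorder_id``."""
    prefix = f"sig_{disorder_id}_"
    return [p for p in cohort.beta.probe_ids if p.startswith(prefix)]
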