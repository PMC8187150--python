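"""One-vs-rest margin classifiers with Platt-calibrated MVP scores.

For each disorder a linear maximum-margin classifier is trained on that
disorder's signature probes: positive class = the disorder's reference
cases, negative class = all other disorders' reference cases plus controls.
Decision values are mapped to Methylation Variant Pathogenicity (MVP)
scores in [0, 1] through the Platt logistic link

    P(f) = 1 / (1 + exp(A * f + B)),

with (A, B) fitted by maximising the Bernoulli likelihood of Platt's
smoothed targets on *out-of-fold* decision values from stratified
cross-validation, which avoids the calibration optimism of in-sample
decisions.  Scores map to categories with a general threshold of > t_pos
positive, < t_neg negative, and the closed band [t_neg, t_pos] inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import (
    BetaRangeError,
    CalibrationError,
    FoldError,
    TrainingError,
)
from .types import (
    BetaMatrix,
    Episignature,
    PlattParams,
    SampleSheet,
    ThresholdConfig,
    TrainedClassifier,
)

_SCORE_EPS = 1e-16  # keeps MVP scores inside the open interval (0, 1)


@dataclass
class MVPResult:
    """Per-sample MVP scores and threshold categories across the panel.

    ``coverage_errors`` records disorders that could not be scored because
    too many signature probes were missing; they carry no score entry.
    """

    sample_id: str
    scores: dict[str, float] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)
    coverage_errors: dict[str, str] = field(default_factory=dict)

    def disorders(self) -> list[str]:
        return sorted(set(self.scores) | set(self.coverage_errors))


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def fit_platt(decisions, labels) -> PlattParams:
    """Fit the Platt logistic link to decision values.

    ``labels`` are truthy for the positive class.  The fit maximises the
    (lightly ridge-regularised) Bernoulli likelihood with Platt's smoothed
    targets t+ = (N+ + 1)/(N+ + 2) and t- = 1/(N- + 2); the smoothing keeps
    the optimum finite even for perfectly separated decisions.
    """
    f = np.asarray(decisions, dtype=float)
    y = np.asarray(labels).astype(bool)
    if f.shape != y.shape or f.ndim != 1:
        raise CalibrationError("decisions and labels must be equal-length vectors")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise CalibrationError(
            f"both classes required for calibration (pos={n_pos}, neg={n_neg})"
        )
    t = np.where(y, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    ridge = 1e-8

    def objective(params):
        A, B = params
        z = A * f + B
        # P = sigmoid(-z); -log P = softplus(z); -log(1 - P) = softplus(-z)
        nll = np.sum(t * _softplus(z) + (1.0 - t) * _softplus(-z))
        g = t * expit(z) - (1.0 - t) * expit(-z)
        grad = np.array([np.sum(g * f), np.sum(g)])
        return (
            nll + ridge * (A * A + B * B),
            grad + 2.0 * ridge * np.array([A, B]),
        )

    b0 = np.log((n_neg + 1.0) / (n_pos + 1.0))
    res = optimize.minimize(
        objective, x0=np.array([0.0, b0]), jac=True, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    A, B = map(float, res.x)
    return PlattParams(A=A, B=B)


def mvp_from_decision(f, platt: PlattParams):
    """MVP score for decision value(s) ``f``: 1 / (1 + exp(A*f + B)).

    Evaluated through the numerically stable logistic, so arbitrarily large
    |f| saturates to the asymptotes instead of overflowing; results are
    clipped to the open interval (0, 1).
    """
    z = platt.A * np.asarray(f, dtype=float) + platt.B
    score = expit(-z)
    return np.clip(score, _SCORE_EPS, 1.0 - _SCORE_EPS)


def call_category(score: float, thresholds: ThresholdConfig = ThresholdConfig()) -> str:
    """Map an MVP score to positive / negative / inconclusive.

    Strict thresholds: score > t_pos is positive, score < t_neg negative,
    and the closed band [t_neg, t_pos] inconclusive.
    """
    if not 0 <= score <= 1:
        raise BetaRangeError(f"MVP score must be in [0, 1], got {score}")
    if score > thresholds.t_pos:
        return "positive"
    if score < thresholds.t_neg:
        return "negative"
    return "inconclusive"


def decision_value(clf: TrainedClassifier, profile: np.ndarray) -> float:
    """Linear decision value w . beta + b over the classifier's probes."""
    return float(np.dot(clf.weights, np.asarray(profile, dtype=float)) + clf.bias)


def train_classifiers(
    beta: BetaMatrix,
    sheet: SampleSheet,
    signatures: dict[str, Episignature] | list[Episignature],
    cv_folds: int = 10,
    seed: int = 0,
    thresholds: ThresholdConfig = ThresholdConfig(),
    kdb_version: str | None = None,
) -> dict[str, TrainedClassifier]:
    """Train one calibrated one-vs-rest classifier per signature.

    Training samples are all reference cases (any disorder) plus reference
    controls.  Per disorder: linear SVM (C = 1, balanced class weights) on
    the signature's probes; Platt parameters fitted on out-of-fold decision
    values from ``cv_folds``-fold stratified CV; final weights refitted on
    all training data.
    """
    if isinstance(signatures, list):
        signatures = {s.disorder_id: s for s in signatures}
    ref_ids = [
        sid for sid in sheet.sample_ids
        if sid in set(sheet.role_ids("reference_case"))
        | set(sheet.role_ids("reference_control"))
    ]
    if not ref_ids:
        raise TrainingError("no reference samples in sheet")
    labels = dict(zip(sheet.data["sample_id"], sheet.data["disorder_label"]))

    out: dict[str, TrainedClassifier] = {}
    for disorder_id, sig in signatures.items():
        X = beta.restrict(sig.probe_ids).data[ref_ids].to_numpy().T
        # mean-impute missing entries from the signature's control reference
        nan_mask = np.isnan(X)
        if nan_mask.any():
            X = np.where(nan_mask, np.broadcast_to(sig.control_mean, X.shape), X)
        y = np.array([labels[sid] == disorder_id for sid in ref_ids], dtype=int)
        n_pos = int(y.sum())
        n_neg = int(len(y) - n_pos)
        if n_pos == 0 or n_neg == 0:
            raise TrainingError(
                f"{disorder_id}: both classes required "
                f"(positives={n_pos}, negatives={n_neg})"
            )
        if cv_folds > n_pos:
            raise FoldError(
                f"{disorder_id}: cv_folds={cv_folds} exceeds "
                f"positive-class size {n_pos}"
            )
        if cv_folds < 2:
            raise FoldError("cv_folds must be >= 2")

        def make_svm():
            return SVC(kernel="linear", C=1.0, class_weight="balanced")

        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        oof = np.empty(len(y))
        for train_idx, test_idx in skf.split(X, y):
            fold_svm = make_svm().fit(X[train_idx], y[train_idx])
            oof[test_idx] = fold_svm.decision_function(X[test_idx])
        platt = fit_platt(oof, y.astype(bool))

        final = make_svm().fit(X, y)
        weights = np.asarray(final.coef_).ravel()
        bias = float(final.intercept_[0])
        out[disorder_id] = TrainedClassifier(
            disorder_id=disorder_id,
            signature=sig,
            weights=weights,
            bias=bias,
            platt=platt,
            thresholds=thresholds,
            training_meta={
                "n_cases": n_pos,
                "n_others": int(sum(1 for sid in ref_ids
                                    if labels[sid] not in ("", disorder_id))),
                "n_controls": int(sum(1 for sid in ref_ids if labels[sid] == "")),
                "cv_folds": cv_folds,
                "seed": seed,
                "kdb_version": kdb_version or sig.version,
            },
        )
    return out


def score_sample(
    classifiers: dict[str, TrainedClassifier],
    sample: pd.Series,
    sample_id: str | None = None,
    max_missing: float = 0.10,
) -> MVPResult:
    """Score one per-probe beta profile against every trained classifier.

    A disorder whose signature has more than ``max_missing`` of its probes
    absent from ``sample`` is recorded as a coverage error in the result
    (never a crash); remaining missing probes are mean-imputed from the
    signature's control reference.
    """
    sid = sample_id or str(getattr(sample, "name", "") or "sample")
    result = MVPResult(sample_id=sid)
    for disorder_id, clf in classifiers.items():
        probes = clf.probe_ids
        values = sample.reindex(probes).to_numpy(dtype=float)
        missing = np.isnan(values)
        frac_missing = float(missing.mean())
        if frac_missing > max_missing:
            result.coverage_errors[disorder_id] = (
                f"{frac_missing:.0%} of signature probes missing "
                f"(> {max_missing:.0%} allowed)"
            )
            continue
        if missing.any():
            values = np.where(missing, clf.signature.control_mean, values)
        f = decision_value(clf, values)
        score = float(mvp_from_decision(f, clf.platt))
        result.scores[disorder_id] = score
        result.categories[disorder_id] = call_category(score, clf.thresholds)
    return result


def score_matrix(
    classifiers: dict[str, TrainedClassifier],
    beta: BetaMatrix,
    sample_ids: list[str] | None = None,
    max_missing: float = 0.10,
) -> pd.DataFrame:
    """Score many samples; long-format table of (sample, disorder, mvp, category)."""
    rows = []
    for sid in sample_ids or beta.sample_ids:
        res = score_sample(classifiers, beta.sample(sid), sid, max_missing)
        for disorder_id in sorted(classifiers):
            if disorder_id in res.scores:
                rows.append({
                    "sample_id": sid, "disorder_id": disorder_id,
                    "mvp": res.scores[disorder_id],
                    "category": res.categories[disorder_id],
                    "coverage_flag": "",
                })
            else:
                rows.append({
                    "sample_id": sid, "disorder_id": disorder_id,
                    "mvp": np.nan, "category": "coverage_error",
                    "coverage_flag": res.coverage_errors[disorder_id],
                })
    return pd.DataFrame(rows)
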