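"""Secondary evidence: hierarchical clustering and MDS against references.

Clinical review of a candidate episignature match looks at where the test
sample falls relative to the disorder's reference cases and controls.  This
module quantifies that inspection: a classical-MDS (principal coordinate)
embedding over the signature probes for display, a Ward-linkage tree cut at
k = 2 for the side assignment, and a centroid-margin statistic

    margin = (d_control - d_case) / max(d_control, d_case)  in [-1, 1]

that is positive when the test sample sits nearer the case centroid.  Calls:
``with_cases`` / ``with_controls`` when the tree side and a margin of at
least ``margin_floor`` agree, ``intermediate`` otherwise — the borderline
pattern that clinical review treats as inconclusive evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa

from .errors import CohortSizeError, EmbeddingError, SeparabilityError
from .types import BetaMatrix


@dataclass
class ClusterEvidence:
    """Clustering/MDS evidence for one (sample, disorder) pair."""

    disorder_id: str
    sample_id: str
    embedding: pd.DataFrame  # index sample_id, columns dim1/dim2
    assignment: str  # case_side | control_side
    margin: float  # in [-1, 1]; positive is case-ward
    call: str  # with_cases | with_controls | intermediate
    margin_floor: float = 0.2


def _feature_matrix(beta: BetaMatrix) -> np.ndarray:
    X = beta.data.to_numpy(dtype=float).T  # samples x probes
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean, X)
    return X


def mds_embed(beta: BetaMatrix, case_ids: list[str] | None = None) -> pd.DataFrame:
    """Classical metric MDS (PCoA) on Euclidean distances over the probes.

    Returns the first two principal coordinates per sample.  The embedding
    is deterministic up to axis sign; the sign of each axis is fixed by
    forcing the case centroid (when ``case_ids`` is given) to non-negative
    first coordinate.
    """
    sample_ids = beta.sample_ids
    if len(sample_ids) < 3:
        raise EmbeddingError(f"need >= 3 samples to embed, got {len(sample_ids)}")
    X = _feature_matrix(beta)
    dm = DistanceMatrix(squareform(pdist(X)), ids=sample_ids)
    ordination = pcoa(dm, method="eigh", number_of_dimensions=2)
    coords = ordination.samples.iloc[:, :2].to_numpy()
    if coords.shape[1] < 2:  # degenerate one-dimensional configurations
        coords = np.column_stack([coords, np.zeros(len(sample_ids))])
    out = pd.DataFrame(coords, index=pd.Index(sample_ids, name="sample_id"),
                       columns=["dim1", "dim2"])
    if case_ids:
        centroid = out.loc[[c for c in case_ids if c in out.index], "dim1"].mean()
        if centroid < 0:
            out["dim1"] *= -1
    return out


def cluster_assign(
    beta: BetaMatrix,
    case_ids: list[str],
    control_ids: list[str],
    test_id: str,
    disorder_id: str = "",
    margin_floor: float = 0.2,
) -> ClusterEvidence:
    """Ward/Euclidean clustering of references plus the test sample, cut at k=2.

    The test sample is assigned to the tree side holding the majority of
    reference cases (case_side) or controls (control_side); the centroid
    margin then yields the call.  Raises :class:`SeparabilityError` when both
    reference groups land on the same side of the k = 2 cut (the signature
    does not separate them).
    """
    if len(case_ids) < 3 or len(control_ids) < 3:
        raise CohortSizeError(
            f"need >= 3 reference cases and controls, got "
            f"{len(case_ids)}/{len(control_ids)}"
        )
    ordered = list(case_ids) + list(control_ids) + [test_id]
    sub = beta.subset_samples(ordered)
    X = _feature_matrix(sub)
    Z = linkage(X, method="ward", metric="euclidean")
    sides = fcluster(Z, t=2, criterion="maxclust")

    n_case = len(case_ids)
    case_sides = sides[:n_case]
    ctrl_sides = sides[n_case:n_case + len(control_ids)]
    case_major = int(np.bincount(case_sides).argmax())
    ctrl_major = int(np.bincount(ctrl_sides).argmax())
    if case_major == ctrl_major:
        raise SeparabilityError(
            f"{disorder_id or 'signature'}: reference cases and controls do "
            "not separate at the k=2 tree cut"
        )
    assignment = "case_side" if sides[-1] == case_major else "control_side"

    test_vec = X[-1]
    case_centroid = X[:n_case].mean(axis=0)
    ctrl_centroid = X[n_case:n_case + len(control_ids)].mean(axis=0)
    d_case = float(np.linalg.norm(test_vec - case_centroid))
    d_ctrl = float(np.linalg.norm(test_vec - ctrl_centroid))
    denom = max(d_case, d_ctrl)
    margin = 0.0 if denom == 0 else (d_ctrl - d_case) / denom

    if abs(margin) < margin_floor:
        call = "intermediate"
    elif margin >= margin_floor and assignment == "case_side":
        call = "with_cases"
    elif margin <= -margin_floor and assignment == "control_side":
        call = "with_controls"
    else:  # tree side and centroid margin disagree: not confident evidence
        call = "intermediate"

    embedding = mds_embed(sub, case_ids=list(case_ids))
    return ClusterEvidence(
        disorder_id=disorder_id,
        sample_id=test_id,
        embedding=embedding,
        assignment=assignment,
        margin=float(margin),
        call=call,
        margin_floor=margin_floor,
    )


def plot_embedding(evidence: ClusterEvidence, case_ids, control_ids, path) -> None:
    """Scatter the 2-D embedding with references and the test sample marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    emb = evidence.embedding
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(emb.loc[case_ids, "dim1"], emb.loc[case_ids, "dim2"],
               c="firebrick", label="reference cases", s=22)
    ax.scatter(emb.loc[control_ids, "dim1"], emb.loc[control_ids, "dim2"],
               c="steelblue", label="controls", s=22)
    ax.scatter(emb.loc[[evidence.sample_id], "dim1"],
               emb.loc[[evidence.sample_id], "dim2"],
               c="black", marker="*", s=140, label=evidence.sample_id)
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    ax.set_title(f"{evidence.disorder_id}: {evidence.call} "
                 f"(margin {evidence.margin:+.2f})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
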