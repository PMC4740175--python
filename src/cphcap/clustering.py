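"""Unsupervised hierarchical clustering of lines on significant probes.

Lines are clustered on their beta profiles over a probe subset (typically
the significant non-CG MVPs) with agglomerative linkage; the tree is cut at
k clusters and agreement with phenotype labels is quantified by per-class
purity, overall majority-vote agreement, and the adjusted Rand index.
Columns are sorted lexicographically by line id before linkage so ties in
the merge order break deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from .datatypes import BetaMatrix

__all__ = ["ClusterResult", "cluster_lines", "clade_purity"]

_SUPPORTED_DISTANCES = {"euclidean", "cityblock", "correlation", "cosine"}
_SUPPORTED_LINKAGES = {"average", "complete", "single", "ward"}


@dataclass
class ClusterResult:
    """Agglomerative merge tree over lines."""

    linkage_matrix: np.ndarray
    line_ids: list[str]  # order used for linkage (lexicographic)
    distance: str
    method: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.line_ids[i] for i in leaves_list(self.linkage_matrix)]

    def cut(self, k: int) -> pd.Series:
        if k > len(self.line_ids):
            raise ValueError(f"k={k} exceeds {len(self.line_ids)} lines")
        labels = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.line_ids, name="cluster")

    def summary(self) -> dict:
        return {
            "n_lines": len(self.line_ids),
            "distance": self.distance,
            "method": self.method,
            "leaf_order": self.leaf_order,
            "merge_heights": [float(h) for h in self.linkage_matrix[:, 2]],
        }


def cluster_lines(line_beta, probe_subset: Iterable[str] | None = None,
                  distance: str = "euclidean", method: str = "average",
                  ) -> ClusterResult:
    """Hierarchical clustering of lines on beta over a probe subset."""
    if distance not in _SUPPORTED_DISTANCES:
        raise ValueError(f"distance {distance!r} not in {sorted(_SUPPORTED_DISTANCES)}")
    if method not in _SUPPORTED_LINKAGES:
        raise ValueError(f"linkage {method!r} not in {sorted(_SUPPORTED_LINKAGES)}")
    frame = line_beta.values if isinstance(line_beta, BetaMatrix) else line_beta
    if probe_subset is not None:
        wanted = set(probe_subset)
        keep = [p for p in frame.index if p in wanted]
        if not keep:
            raise ValueError("probe subset is empty after intersection")
        frame = frame.loc[keep]
    if frame.shape[1] < 3:
        raise ValueError("need >= 3 lines to cluster")
    line_ids = sorted(frame.columns)
    x = frame[line_ids].to_numpy(dtype=float).T
    z = linkage(pdist(x, metric=distance), method=method)
    return ClusterResult(linkage_matrix=z, line_ids=line_ids,
                         distance=distance, method=method)


def clade_purity(result: ClusterResult, labels: Mapping[str, str],
                 k: int = 3) -> dict:
    """Cut the tree at k and score agreement with the given labels.

    Per class: the fraction of its members falling in the class's majority
    cluster. Overall agreement assigns each cluster its majority label and
    counts matches. ARI compares the k-cut against the labels directly.
    """
    assignments = result.cut(k)
    labelled = [l for l in assignments.index if labels.get(l) is not None]
    if len(set(labels[l] for l in labelled)) < 2:
        raise ValueError("need labels from >= 2 classes")
    clusters = assignments.loc[labelled]
    truth = pd.Series({l: labels[l] for l in labelled})

    purity = {}
    for cls in sorted(truth.unique()):
        members = clusters[truth == cls]
        purity[cls] = float(members.value_counts().iloc[0] / len(members))

    majority_label = {c: truth[clusters == c].mode().iloc[0]
                      for c in clusters.unique()}
    agreement = float(np.mean([majority_label[clusters[l]] == truth[l]
                               for l in labelled]))
    ari = float(adjusted_rand_score(truth.to_numpy(), clusters.to_numpy()))
    return {
        "k": k,
        "purity": purity,
        "agreement": agreement,
        "ari": ari,
        "assignments": assignments.to_dict(),
    }
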