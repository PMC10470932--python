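"""Multisource feature fusion.

The disease similarities are merged into DS (semantic average where the
ontology covers both diseases, GIP kernel otherwise) and the circRNA
similarities into CS (expression/GIP average where profiled, GIP otherwise).
DS is concatenated with the disease Jaccard matrix into DM, CS with the
circRNA Jaccard matrix into CM; both are reduced with PCA.  A pair's
feature vector FV is the reduced CM row of the circRNA followed by the
reduced DM row of the disease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .core_io import LabeledPairSet
from .similarity import SimilarityBundle


@dataclass
class FusedFeatures:
    DS: np.ndarray  # n x n fused disease similarity
    CS: np.ndarray  # m x m fused circRNA similarity
    DM: np.ndarray  # n x r_d reduced [DS, JD]
    CM: np.ndarray  # m x r_c reduced [CS, JC]

    @property
    def r_d(self) -> int:
        return self.DM.shape[1]

    @property
    def r_c(self) -> int:
        return self.CM.shape[1]


def fuse_disease(DSS1: np.ndarray, DSS2: np.ndarray, GD: np.ndarray, semantic_mask: np.ndarray) -> np.ndarray:
    """DS(i,j) = mean of the two semantic similarities where both diseases
    are covered by the ontology, else the disease GIP kernel value."""
    if not (DSS1.shape == DSS2.shape == GD.shape):
        raise ValueError("similarity matrix shapes disagree")
    mask = np.asarray(semantic_mask, dtype=bool)
    both = mask[:, None] & mask[None, :]
    return np.where(both, (DSS1 + DSS2) / 2.0, GD)


def fuse_circrna(SE: np.ndarray, GC: np.ndarray, expression_mask: np.ndarray) -> np.ndarray:
    """CS(i,j) = mean of expression correlation and circRNA GIP kernel where
    both circRNAs are profiled, else the GIP kernel value."""
    if SE.shape != GC.shape:
        raise ValueError("similarity matrix shapes disagree")
    mask = np.asarray(expression_mask, dtype=bool)
    both = mask[:, None] & mask[None, :]
    return np.where(both, (SE + GC) / 2.0, GC)


def reduce(X: np.ndarray, variance_kept: float = 0.95, r: int | None = None, max_r: int = 128) -> np.ndarray:
    """Mean-centered PCA scores keeping ``variance_kept`` of the variance.

    With ``r`` given, exactly r components are kept.  Component signs are
    fixed by forcing the largest-magnitude loading of each component to be
    positive, so the reduction is fully deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows for PCA")
    full = min(X.shape)
    if r is None:
        if not (0 < variance_kept <= 1):
            raise ValueError("variance_kept must be in (0, 1]")
        pca = PCA(n_components=full, svd_solver="full")
        scores = pca.fit_transform(X)
        ratios = pca.explained_variance_ratio_
        csum = np.cumsum(ratios)
        if variance_kept >= 1.0 - 1e-12:
            r_eff = int(np.sum(pca.explained_variance_ > 1e-12 * max(pca.explained_variance_[0], 1)))
            r_eff = max(r_eff, 1)
        else:
            r_eff = int(np.searchsorted(csum, variance_kept) + 1)
        r_eff = min(r_eff, max_r)
    else:
        if not (1 <= r <= full):
            raise ValueError(f"r must be in [1, {full}]")
        pca = PCA(n_components=r, svd_solver="full")
        scores = pca.fit_transform(X)
        r_eff = r
    comps = pca.components_[:r_eff]
    scores = scores[:, :r_eff].copy()
    # sign convention: largest-|loading| entry of each component positive
    for c in range(r_eff):
        k = np.argmax(np.abs(comps[c]))
        if comps[c, k] < 0:
            scores[:, c] *= -1.0
    return scores


def fuse(bundle: SimilarityBundle, variance_kept: float = 0.95, r_d: int | None = None, r_c: int | None = None) -> FusedFeatures:
    """Run the full fusion: DS/CS, concatenation with Jaccard, PCA."""
    ds = fuse_disease(bundle.DSS1, bundle.DSS2, bundle.GD, bundle.semantic_mask)
    cs = fuse_circrna(bundle.SE, bundle.GC, bundle.expression_mask)
    dm = reduce(np.hstack([ds, bundle.JD]), variance_kept, r_d)
    cm = reduce(np.hstack([cs, bundle.JC]), variance_kept, r_c)
    return FusedFeatures(ds, cs, dm, cm)


def pair_features(CM_reduced: np.ndarray, DM_reduced: np.ndarray, pairs: LabeledPairSet) -> np.ndarray:
    """FV matrix: one row per labeled pair, [CM row of circ, DM row of disease]."""
    idx_c = np.array([i for i, _, _ in pairs.pairs], dtype=int)
    idx_d = np.array([j for _, j, _ in pairs.pairs], dtype=int)
    return np.hstack([CM_reduced[idx_c], DM_reduced[idx_d]])
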