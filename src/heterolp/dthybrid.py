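"""Degree-tuned bipartite projection baseline (DT-Hybrid style).

A recommendation method built on two-phase resource allocation over a
bipartite association layer, blended multiplicatively with an a-priori
similarity matrix.  For rows i, j of an association matrix A with row
degrees G(i) and column degrees G'(l), the transfer weight is

    w_ij = 1 / (G(i)^(1-lambda) * G(j)^lambda) * sum_l a_il * a_jl / G'(l)

and the similarity-blended weight

    w'_ij = w_ij * (alpha * s_ij + (1 - alpha)),

after which recommendations are R = W' @ A.  lambda tunes how strongly
high-degree rows are penalized; alpha in [0, 1] is the weight of the
a-priori similarity (alpha = 0 recovers pure structural network-based
inference).  The projection is undefined for degree-0 nodes, so the method
requires a harmonized network (every entity active in all of its layers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .network_model import (
    AssociationMatrix,
    EntityCatalog,
    HeterogeneousNetwork,
    SimilarityMatrix,
)


@dataclass(frozen=True)
class RecommendationMatrix:
    """Nonnegative recommendation scores over a bipartite relation."""

    row_catalog: EntityCatalog
    col_catalog: EntityCatalog
    values: np.ndarray

    @property
    def relation(self) -> str:
        return f"{self.row_catalog.kind}_{self.col_catalog.kind}"

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def toarray(self) -> np.ndarray:
        return np.asarray(self.values)

    def as_association(self) -> AssociationMatrix:
        vals = self.values
        top = vals.max() if vals.size else 0.0
        if top > 1.0:
            raise ValueError("scores exceed 1; rescale before converting to associations")
        return AssociationMatrix(self.row_catalog, self.col_catalog, sp.csr_array(vals))


def dthybrid_weights(
    assoc: AssociationMatrix,
    similarity: SimilarityMatrix | None = None,
    lam: float = 0.5,
    alpha: float = 0.5,
) -> np.ndarray:
    """Row-side transfer weights of the degree-tuned resource allocation.

    Raises if any row or column of the association layer has zero degree:
    that indicates harmonization was bypassed.
    """
    if not 0.0 <= lam <= 1.0 or not 0.0 <= alpha <= 1.0:
        raise ValueError("lambda and alpha must lie in [0, 1]")
    A = assoc.toarray()
    row_deg = A.sum(axis=1)
    col_deg = A.sum(axis=0)
    if (row_deg == 0).any() or (col_deg == 0).any():
        raise ValueError(
            f"{assoc.relation}: zero-degree rows/columns present; run "
            f"harmonize_common_entities first (projection undefined at degree 0)"
        )
    # resource allocation: A diag(1/G') A^T, degree-tuned by the lambda split
    shared = (A / col_deg) @ A.T
    scale = 1.0 / (row_deg[:, None] ** (1.0 - lam) * row_deg[None, :] ** lam)
    W = scale * shared
    if alpha > 0.0:
        if similarity is None:
            raise ValueError("alpha > 0 requires a row-side similarity matrix")
        if similarity.catalog.ids != assoc.row_catalog.ids:
            raise ValueError("similarity catalog does not match association rows")
        W = W * (alpha * similarity.toarray() + (1.0 - alpha))
    return W


def dthybrid_recommend(
    W: np.ndarray, assoc: AssociationMatrix, rescale: bool = True
) -> RecommendationMatrix:
    """Recommendation scores R = W @ A, optionally min-max rescaled to [0, 1].

    Rescaling makes the scores comparable with a probability-style weight
    threshold.
    """
    W = np.asarray(W, dtype=np.float64)
    A = assoc.toarray()
    if W.shape[1] != A.shape[0]:
        raise ValueError(f"shape mismatch: W {W.shape} vs A {A.shape}")
    R = W @ A
    if rescale and R.size:
        lo, hi = R.min(), R.max()
        if hi > lo:
            R = (R - lo) / (hi - lo)
        elif hi > 0:
            R = R / hi
    return RecommendationMatrix(assoc.row_catalog, assoc.col_catalog, R)


#: relation -> which side's similarity blends into the projection
_SIMILARITY_SIDE = {
    "drug_disease": "drug",
    "drug_target": "drug",
    "disease_target": "disease",
}


def dthybrid_predict(
    network: HeterogeneousNetwork,
    relation: str,
    lam: float = 0.5,
    alpha: float = 0.5,
    rescale: bool = True,
) -> RecommendationMatrix:
    """Run the full DT-Hybrid projection for one relation of a harmonized network.

    Drug-side similarity drives the drug-disease and drug-target relations;
    disease-side similarity drives disease-target.
    """
    assoc = network.association(relation)
    sim = network.similarity(_SIMILARITY_SIDE[relation])
    W = dthybrid_weights(assoc, sim, lam=lam, alpha=alpha)
    return dthybrid_recommend(W, assoc, rescale=rescale)
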