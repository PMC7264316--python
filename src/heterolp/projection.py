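"""Topological similarity from bipartite layers and fusion with intrinsic similarity.

Two same-type nodes are topologically similar when they connect to the
opposite side of a bipartite association layer in the same way.  We measure
this with the weighted Jaccard index of neighbor profiles,

    T_ij = sum_k min(a_ik, a_jk) / sum_k max(a_ik, a_jk),

which is bounded in [0, 1], reduces to the set Jaccard index on binary
associations, and is robust to degree differences.  Each entity type draws
topological similarity from both bipartite layers that touch it; these are
fused with the intrinsic similarity matrix by an element-wise maximum
(strongest evidence wins) or, optionally, an element-wise mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .network_model import (
    AssociationMatrix,
    EntityCatalog,
    HeterogeneousNetwork,
    NetworkFormatError,
    SimilarityMatrix,
)

_CHUNK = 256  # rows of the pairwise min computed at a time


@dataclass(frozen=True)
class FusedSimilarity:
    """Similarity matrix combining intrinsic and topological evidence."""

    catalog: EntityCatalog
    values: sp.csr_array
    provenance: tuple[str, ...] = ("intrinsic",)

    def as_similarity(self) -> SimilarityMatrix:
        return SimilarityMatrix(self.catalog, self.values)


def topological_similarity(assoc: AssociationMatrix, side: str = "rows") -> SimilarityMatrix:
    """Weighted Jaccard similarity between neighbor profiles of one side.

    Parameters
    ----------
    assoc : AssociationMatrix
        Bipartite layer; profiles are its rows (``side="rows"``) or columns.
    side : {"rows", "cols"}

    Pairs where both profiles are all-zero get similarity 0 (no evidence),
    and the diagonal is 0 by the similarity-matrix contract.
    """
    if side not in ("rows", "cols"):
        raise ValueError(f"side must be 'rows' or 'cols'; got {side!r}")
    if side == "rows":
        profiles, catalog = assoc.values, assoc.row_catalog
    else:
        profiles, catalog = assoc.values.T.tocsr(), assoc.col_catalog

    n = profiles.shape[0]
    dense = profiles.toarray()
    row_sums = dense.sum(axis=1)
    out = np.zeros((n, n))
    # sum min(a_ik, a_jk) chunked over i; sum max = r_i + r_j - sum min
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        mins = np.minimum(dense[start:stop, None, :], dense[None, :, :]).sum(axis=2)
        maxs = row_sums[start:stop, None] + row_sums[None, :] - mins
        with np.errstate(invalid="ignore", divide="ignore"):
            out[start:stop] = np.where(maxs > 0, mins / np.maximum(maxs, 1e-300), 0.0)
    np.fill_diagonal(out, 0.0)
    return SimilarityMatrix(catalog, sp.csr_array(out))


def fuse_similarities(
    intrinsic: SimilarityMatrix,
    topo1: SimilarityMatrix,
    topo2: SimilarityMatrix,
    method: str = "max",
) -> FusedSimilarity:
    """Combine intrinsic similarity with two layer-derived topological similarities.

    ``method="max"`` takes the element-wise maximum (parameter-free, keeps
    [0, 1], idempotent); ``method="mean"`` averages the three matrices.
    """
    mats = (intrinsic, topo1, topo2)
    for m in mats[1:]:
        if m.catalog.ids != intrinsic.catalog.ids or m.catalog.kind != intrinsic.catalog.kind:
            raise NetworkFormatError("fuse_similarities: catalogs differ across inputs")
    if method == "max":
        fused = mats[0].values.maximum(mats[1].values).maximum(mats[2].values)
    elif method == "mean":
        fused = (mats[0].values + mats[1].values + mats[2].values) / 3.0
    else:
        raise ValueError(f"unknown fusion method {method!r}")
    return FusedSimilarity(
        intrinsic.catalog,
        sp.csr_array(fused),
        provenance=("intrinsic", "topological-layer-1", "topological-layer-2"),
    )


def fuse_network(network: HeterogeneousNetwork, method: str = "max") -> dict[str, FusedSimilarity]:
    """Fused similarity for every entity type of a network.

    Drugs draw topological similarity from the drug-disease and drug-target
    layers; diseases from drug-disease and disease-target; targets from
    drug-target and disease-target.
    """
    return {
        "drug": fuse_similarities(
            network.S_drug,
            topological_similarity(network.A_drug_disease, "rows"),
            topological_similarity(network.A_drug_target, "rows"),
            method,
        ),
        "disease": fuse_similarities(
            network.S_disease,
            topological_similarity(network.A_drug_disease, "cols"),
            topological_similarity(network.A_disease_target, "rows"),
            method,
        ),
        "target": fuse_similarities(
            network.S_target,
            topological_similarity(network.A_drug_target, "cols"),
            topological_similarity(network.A_disease_target, "cols"),
            method,
        ),
    }
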