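import numpy as np
import pytest
import scipy.sparse as sp

from heterolp import (
    AssociationMatrix,
    EntityCatalog,
    HeterogeneousNetwork,
    SimilarityMatrix,
)


def catalog(kind: str, *ids: str) -> EntityCatalog:
    return EntityCatalog(kind, tuple(ids))


def similarity(cat: EntityCatalog, values) -> SimilarityMatrix:
    return SimilarityMatrix(cat, sp.csr_array(np.asarray(values, dtype=float)))


def association(row_cat, col_cat, values) -> AssociationMatrix:
    return AssociationMatrix(row_cat, col_cat, sp.csr_array(np.asarray(values, dtype=float)))


@pytest.fixture
def tiny_network() -> HeterogeneousNetwork:
    """3 drugs x 2 diseases x 2 targets; drug A and B are similar, A treats x.

    Drug B shares similarity with the labeled drug A, drug C is unrelated —
    the canonical setup where propagation should rank B's link to disease x
    above C's.
    """
    drugs = catalog("drug", "A", "B", "C")
    diseases = catalog("disease", "x", "y")
    targets = catalog("target", "t1", "t2")
    return HeterogeneousNetwork(
        drugs=drugs,
        diseases=diseases,
        targets=targets,
        S_drug=similarity(drugs, [[0, 0.9, 0], [0.9, 0, 0], [0, 0, 0]]),
        S_disease=similarity(diseases, [[0, 0.5], [0.5, 0]]),
        S_target=similarity(targets, [[0, 0.4], [0.4, 0]]),
        A_drug_disease=association(drugs, diseases, [[1, 0], [0, 0], [0, 0]]),
        A_drug_target=association(drugs, targets, [[1, 0], [0, 1], [0, 0]]),
        A_disease_target=association(diseases, targets, [[1, 0], [0, 0]]),
    )


def random_normalized_graph(rng: np.random.Generator, n: int):
    """Random symmetric similarity, symmetrically normalized (test instances)."""
    from heterolp import normalize_symmetric

    S = rng.random((n, n))
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 0.0)
    # sparsify a bit so isolated nodes occur
    S[S < 0.3] = 0.0
    return normalize_symmetric(sp.csr_array(S))
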