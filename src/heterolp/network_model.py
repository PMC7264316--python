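"""Data model for heterogeneous drug-disease-target networks.

The network is a six-matrix bundle: three homogeneous similarity matrices
(drug-drug, disease-disease, target-target) and three bipartite association
matrices (drug-disease, drug-target, disease-target), all indexed by entity
catalogs.  Matrices are stored sparse (CSR) because real datasets in this
domain have ~10^4 entities per type with very sparse edges.

Readers accept tab-separated edge lists (``id1  id2  weight``) or labeled
square matrices; writers emit deterministic edge lists so a load -> write ->
load round trip is exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import yaml

ENTITY_KINDS = ("drug", "disease", "target")

#: relation name -> (row entity kind, column entity kind)
RELATIONS: dict[str, tuple[str, str]] = {
    "drug_disease": ("drug", "disease"),
    "drug_target": ("drug", "target"),
    "disease_target": ("disease", "target"),
}

_SYMMETRY_TOL = 1e-9


class NetworkFormatError(ValueError):
    """Raised when an input file or matrix violates the data-model contract."""


@dataclass(frozen=True)
class EntityCatalog:
    """Ordered, deduplicated identifier list for one entity type.

    The catalog is the coordinate system for every matrix touching its
    entity type: position ``index[id]`` is the row/column of ``id``.
    """

    kind: str
    ids: tuple[str, ...]
    index: Mapping[str, int] = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.kind not in ENTITY_KINDS:
            raise NetworkFormatError(
                f"unknown entity kind {self.kind!r}; expected one of {ENTITY_KINDS}"
            )
        ids = tuple(self.ids)
        if any(not i for i in ids):
            raise NetworkFormatError(f"{self.kind} catalog contains an empty identifier")
        index = {s: k for k, s in enumerate(ids)}
        if len(index) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise NetworkFormatError(f"duplicate {self.kind} identifier {dup!r}")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "index", index)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self.index

    def positions(self, identifiers: Iterable[str]) -> np.ndarray:
        return np.array([self.index[i] for i in identifiers], dtype=np.intp)


def _as_csr(values) -> sp.csr_array:
    mat = sp.csr_array(values, dtype=np.float64)
    mat.eliminate_zeros()
    return mat


def _check_unit_interval(mat: sp.csr_array, what: str) -> None:
    if mat.nnz == 0:
        return
    lo, hi = mat.data.min(), mat.data.max()
    if lo < 0.0 or hi > 1.0 + 1e-12:
        raise NetworkFormatError(f"{what}: entries must lie in [0, 1]; found range [{lo}, {hi}]")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity matrix over one catalog.

    Entries are in [0, 1]; the diagonal is zeroed on construction because
    self-similarity carries no information for propagation.
    """

    catalog: EntityCatalog
    values: sp.csr_array

    def __post_init__(self) -> None:
        mat = _as_csr(self.values)
        n = len(self.catalog)
        if mat.shape != (n, n):
            raise NetworkFormatError(
                f"{self.catalog.kind} similarity shape {mat.shape} does not match "
                f"catalog size {n}"
            )
        asym = abs(mat - mat.T)
        if asym.nnz and asym.data.max() > _SYMMETRY_TOL:
            raise NetworkFormatError(
                f"{self.catalog.kind} similarity is not symmetric "
                f"(max |S - S^T| = {asym.data.max():.3g})"
            )
        mat.setdiag(0.0)
        mat.eliminate_zeros()
        _check_unit_interval(mat, f"{self.catalog.kind} similarity")
        object.__setattr__(self, "values", mat)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def toarray(self) -> np.ndarray:
        return self.values.toarray()


@dataclass(frozen=True)
class AssociationMatrix:
    """Rectangular association matrix linking two catalogs (bipartite layer)."""

    row_catalog: EntityCatalog
    col_catalog: EntityCatalog
    values: sp.csr_array

    def __post_init__(self) -> None:
        mat = _as_csr(self.values)
        expect = (len(self.row_catalog), len(self.col_catalog))
        if mat.shape != expect:
            raise NetworkFormatError(
                f"{self.relation} association shape {mat.shape} != catalogs {expect}"
            )
        _check_unit_interval(mat, f"{self.relation} association")
        object.__setattr__(self, "values", mat)

    @property
    def relation(self) -> str:
        return f"{self.row_catalog.kind}_{self.col_catalog.kind}"

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def toarray(self) -> np.ndarray:
        return self.values.toarray()

    def transpose(self) -> "AssociationMatrix":
        return AssociationMatrix(self.col_catalog, self.row_catalog, self.values.T.tocsr())


@dataclass(frozen=True)
class HeterogeneousNetwork:
    """The six-matrix bundle over three entity catalogs."""

    drugs: EntityCatalog
    diseases: EntityCatalog
    targets: EntityCatalog
    S_drug: SimilarityMatrix
    S_disease: SimilarityMatrix
    S_target: SimilarityMatrix
    A_drug_disease: AssociationMatrix
    A_drug_target: AssociationMatrix
    A_disease_target: AssociationMatrix

    def __post_init__(self) -> None:
        cats = {"drug": self.drugs, "disease": self.diseases, "target": self.targets}
        for kind, cat in cats.items():
            if cat.kind != kind:
                raise NetworkFormatError(f"catalog in {kind} slot has kind {cat.kind!r}")
        for sim in (self.S_drug, self.S_disease, self.S_target):
            if cats[sim.catalog.kind].ids != sim.catalog.ids:
                raise NetworkFormatError(
                    f"{sim.catalog.kind} similarity catalog differs from network catalog"
                )
        for assoc in (self.A_drug_disease, self.A_drug_target, self.A_disease_target):
            for cat in (assoc.row_catalog, assoc.col_catalog):
                if cats[cat.kind].ids != cat.ids:
                    raise NetworkFormatError(
                        f"{assoc.relation} association {cat.kind} catalog differs "
                        f"from network catalog"
                    )

    def catalog(self, kind: str) -> EntityCatalog:
        return {"drug": self.drugs, "disease": self.diseases, "target": self.targets}[kind]

    def similarity(self, kind: str) -> SimilarityMatrix:
        return {"drug": self.S_drug, "disease": self.S_disease, "target": self.S_target}[kind]

    def association(self, relation: str) -> AssociationMatrix:
        return {
            "drug_disease": self.A_drug_disease,
            "drug_target": self.A_drug_target,
            "disease_target": self.A_disease_target,
        }[relation]

    def with_association(self, relation: str, assoc: AssociationMatrix) -> "HeterogeneousNetwork":
        """Return a copy of the network with one association layer replaced."""
        slot = {
            "drug_disease": "A_drug_disease",
            "drug_target": "A_drug_target",
            "disease_target": "A_disease_target",
        }[relation]
        return replace(self, **{slot: assoc})


@dataclass
class Config:
    """Run configuration for the full pipeline.

    alpha
        Label-propagation mixing parameter in (0, 1): fraction of each score
        diffused from neighbors vs. retained from the original labels.
    tol, max_iter
        Convergence tolerance (max absolute score change) and iteration cap.
    tau
        Prediction weight threshold; predicted links with weight >= tau are
        reported, the field's conventional cutoff being 0.005.
    fusion
        How topological and intrinsic similarities are combined: "max" | "mean".
    dthybrid_lambda, dthybrid_alpha
        Degree-tuning exponent and similarity-blending weight of the
        DT-Hybrid baseline.
    dthybrid_rescale
        Min-max rescale DT-Hybrid scores to [0, 1] so tau applies.
    seed
        Seed for synthetic generation only; inference is deterministic.
    """

    alpha: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1000
    tau: float = 0.005
    fusion: str = "max"
    dthybrid_lambda: float = 0.5
    dthybrid_alpha: float = 0.5
    dthybrid_rescale: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be strictly inside (0, 1); got {self.alpha}")
        if self.tau < 0:
            raise ValueError(f"tau must be nonnegative; got {self.tau}")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be positive and max_iter >= 1")
        if self.fusion not in ("max", "mean"):
            raise ValueError(f"fusion must be 'max' or 'mean'; got {self.fusion!r}")
        for name in ("dthybrid_lambda", "dthybrid_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]; got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# TSV readers / writers


def _read_rows(path: str | Path) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            rows.append((lineno, line.split("\t")))
    return rows


def _parse_weight(text: str, path, lineno: int) -> float:
    try:
        w = float(text)
    except ValueError:
        raise NetworkFormatError(f"{path}:{lineno}: weight {text!r} is not a number") from None
    if not np.isfinite(w) or w < 0.0 or w > 1.0:
        raise NetworkFormatError(f"{path}:{lineno}: weight {w} outside [0, 1]")
    return w


def _looks_like_matrix(rows: list[tuple[int, list[str]]]) -> bool:
    """Distinguish a labeled square matrix from an edge list.

    A labeled matrix of n entities has n+1 columns (corner cell plus n
    headers) and its row labels equal its column headers.  Edge lists have
    2-3 columns; the ambiguous 3-column case is resolved by the row-label /
    header correspondence.
    """
    if not rows:
        return False
    header = rows[0][1]
    if len(header) > 3:
        return True
    if len(header) < 3:
        return False
    col_ids = [h for h in header[1:] if h]
    row_ids = [fields[0] for _, fields in rows[1:]]
    return bool(col_ids) and set(col_ids) == set(row_ids) and len(rows) == len(col_ids) + 1


def _maybe_skip_header(rows, expect_cols: int):
    """Drop an optional header row (last column not numeric)."""
    if rows and len(rows[0][1]) == expect_cols:
        try:
            float(rows[0][1][-1])
        except ValueError:
            return rows[1:]
    return rows


def load_similarity(path: str | Path, kind: str) -> SimilarityMatrix:
    """Load a homogeneous similarity matrix from a TSV file.

    The file may be a 3-column edge list (``id1  id2  weight``) or a labeled
    square matrix; the format is auto-detected.  Edge lists are symmetrized
    by taking ``max(w_ij, w_ji)`` (strongest evidence wins), self-edges are
    dropped, and the catalog follows first appearance in the file.
    """
    path = Path(path)
    rows = _read_rows(path)
    if _looks_like_matrix(rows):
        return _similarity_from_labeled(rows, kind, path)
    rows = _maybe_skip_header(rows, 3)

    order: dict[str, None] = {}
    cells: dict[tuple[str, str], float] = {}
    cell_lines: dict[tuple[str, str], int] = {}
    for lineno, fields in rows:
        if len(fields) != 3:
            raise NetworkFormatError(
                f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}"
            )
        a, b, wtext = fields
        if not a or not b:
            raise NetworkFormatError(f"{path}:{lineno}: empty identifier")
        w = _parse_weight(wtext, path, lineno)
        order.setdefault(a)
        order.setdefault(b)
        if a == b:
            continue  # self-similarity carries no propagation information
        key = (a, b)
        if key in cells and cells[key] != w:
            raise NetworkFormatError(
                f"{path}:{lineno}: conflicting weights for pair ({a!r}, {b!r}): "
                f"{cells[key]} at line {cell_lines[key]} vs {w}"
            )
        cells[key] = w
        cell_lines[key] = lineno

    catalog = EntityCatalog(kind, tuple(order))
    n = len(catalog)
    mat = sp.dok_array((n, n), dtype=np.float64)
    for (a, b), w in cells.items():
        i, j = catalog.index[a], catalog.index[b]
        w = max(w, mat[i, j], mat[j, i])
        mat[i, j] = w
        mat[j, i] = w
    return SimilarityMatrix(catalog, mat.tocsr())


def _similarity_from_labeled(rows, kind: str, path: Path) -> SimilarityMatrix:
    header = rows[0][1]
    col_ids = [h for h in header[1:] if h]
    catalog = EntityCatalog(kind, tuple(col_ids))
    n = len(catalog)
    dense = np.zeros((n, n))
    seen: set[str] = set()
    for lineno, fields in rows[1:]:
        rid = fields[0]
        if rid in seen:
            raise NetworkFormatError(f"{path}:{lineno}: duplicate row label {rid!r}")
        seen.add(rid)
        if rid not in catalog.index:
            raise NetworkFormatError(f"{path}:{lineno}: row label {rid!r} not in header")
        if len(fields) != n + 1:
            raise NetworkFormatError(
                f"{path}:{lineno}: expected {n + 1} columns, got {len(fields)}"
            )
        dense[catalog.index[rid]] = [_parse_weight(t, path, lineno) for t in fields[1:]]
    if len(seen) != n:
        raise NetworkFormatError(f"{path}: matrix has {len(seen)} rows but {n} columns")
    asym = np.abs(dense - dense.T).max() if n else 0.0
    if asym > _SYMMETRY_TOL:
        raise NetworkFormatError(f"{path}: labeled matrix not symmetric (max dev {asym:.3g})")
    return SimilarityMatrix(catalog, sp.csr_array(dense))


def load_association(path: str | Path, row_kind: str, col_kind: str) -> AssociationMatrix:
    """Load a bipartite association layer from a TSV edge list.

    Rows are ``row_id  col_id  weight``; a 2-column file defaults every
    weight to 1.0 (binary associations).  Missing pairs are zero.
    """
    path = Path(path)
    rows = _read_rows(path)
    rows = _maybe_skip_header(rows, 3)
    if not rows:
        warnings.warn(f"{path}: empty association file; returning 0x0 matrix", stacklevel=2)
        empty = EntityCatalog(row_kind, ()), EntityCatalog(col_kind, ())
        return AssociationMatrix(*empty, sp.csr_array((0, 0)))

    row_order: dict[str, None] = {}
    col_order: dict[str, None] = {}
    cells: dict[tuple[str, str], float] = {}
    for lineno, fields in rows:
        if len(fields) == 2:
            rid, cid, w = fields[0], fields[1], 1.0
        elif len(fields) == 3:
            rid, cid = fields[0], fields[1]
            w = _parse_weight(fields[2], path, lineno)
        else:
            raise NetworkFormatError(
                f"{path}:{lineno}: expected 2 or 3 tab-separated columns, got {len(fields)}"
            )
        if not rid or not cid:
            raise NetworkFormatError(f"{path}:{lineno}: empty identifier")
        key = (rid, cid)
        if key in cells and cells[key] != w:
            raise NetworkFormatError(
                f"{path}:{lineno}: conflicting weights for pair {key!r}"
            )
        row_order.setdefault(rid)
        col_order.setdefault(cid)
        cells[key] = w

    row_cat = EntityCatalog(row_kind, tuple(row_order))
    col_cat = EntityCatalog(col_kind, tuple(col_order))
    mat = sp.dok_array((len(row_cat), len(col_cat)), dtype=np.float64)
    for (rid, cid), w in cells.items():
        mat[row_cat.index[rid], col_cat.index[cid]] = w
    return AssociationMatrix(row_cat, col_cat, mat.tocsr())


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    """Write the upper triangle as a deterministic ``id1 id2 weight`` edge list."""
    coo = sp.triu(sp.coo_array(sim.values))
    triples = sorted(
        (sim.catalog.ids[i], sim.catalog.ids[j], float(w))
        for i, j, w in zip(coo.row, coo.col, coo.data)
    )
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, w in triples:
            fh.write(f"{a}\t{b}\t{w!r}\n")


def write_association(assoc: AssociationMatrix, path: str | Path) -> None:
    coo = sp.coo_array(assoc.values)
    triples = sorted(
        (assoc.row_catalog.ids[i], assoc.col_catalog.ids[j], float(w))
        for i, j, w in zip(coo.row, coo.col, coo.data)
    )
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, w in triples:
            fh.write(f"{a}\t{b}\t{w!r}\n")


# ---------------------------------------------------------------------------
# Alignment & harmonization


def _union_catalog(kind: str, id_lists: Sequence[Sequence[str]]) -> EntityCatalog:
    order: dict[str, None] = {}
    for ids in id_lists:
        for i in ids:
            order.setdefault(i)
    return EntityCatalog(kind, tuple(order))


def _reindex_square(sim: SimilarityMatrix, catalog: EntityCatalog) -> SimilarityMatrix:
    pos = catalog.positions(sim.catalog.ids)
    coo = sp.coo_array(sim.values)
    n = len(catalog)
    mat = sp.coo_array((coo.data, (pos[coo.row], pos[coo.col])), shape=(n, n))
    return SimilarityMatrix(catalog, mat.tocsr())


def _reindex_rect(
    assoc: AssociationMatrix, row_cat: EntityCatalog, col_cat: EntityCatalog
) -> AssociationMatrix:
    rpos = row_cat.positions(assoc.row_catalog.ids)
    cpos = col_cat.positions(assoc.col_catalog.ids)
    coo = sp.coo_array(assoc.values)
    mat = sp.coo_array(
        (coo.data, (rpos[coo.row], cpos[coo.col])), shape=(len(row_cat), len(col_cat))
    )
    return AssociationMatrix(row_cat, col_cat, mat.tocsr())


def align_network(
    S_drug: SimilarityMatrix,
    S_disease: SimilarityMatrix,
    S_target: SimilarityMatrix,
    A_drug_disease: AssociationMatrix,
    A_drug_target: AssociationMatrix,
    A_disease_target: AssociationMatrix,
) -> HeterogeneousNetwork:
    """Integrate six independently loaded matrices into one network.

    Per entity type the catalog is the UNION of ids seen in any matrix
    mentioning that type; matrices are re-indexed onto the union with absent
    rows/columns zero-filled.  Identifier lists need not overlap across
    layers.  An identifier used under two different entity kinds is an error:
    kind namespaces are disjoint.
    """
    by_kind = {
        "drug": [S_drug.catalog.ids, A_drug_disease.row_catalog.ids, A_drug_target.row_catalog.ids],
        "disease": [
            S_disease.catalog.ids,
            A_drug_disease.col_catalog.ids,
            A_disease_target.row_catalog.ids,
        ],
        "target": [
            S_target.catalog.ids,
            A_drug_target.col_catalog.ids,
            A_disease_target.col_catalog.ids,
        ],
    }
    cats = {kind: _union_catalog(kind, lists) for kind, lists in by_kind.items()}
    for k1, k2 in (("drug", "disease"), ("drug", "target"), ("disease", "target")):
        clash = set(cats[k1].ids) & set(cats[k2].ids)
        if clash:
            raise NetworkFormatError(
                f"identifier(s) {sorted(clash)[:5]} appear as both {k1} and {k2}; "
                f"entity namespaces must be disjoint"
            )
    return HeterogeneousNetwork(
        drugs=cats["drug"],
        diseases=cats["disease"],
        targets=cats["target"],
        S_drug=_reindex_square(S_drug, cats["drug"]),
        S_disease=_reindex_square(S_disease, cats["disease"]),
        S_target=_reindex_square(S_target, cats["target"]),
        A_drug_disease=_reindex_rect(A_drug_disease, cats["drug"], cats["disease"]),
        A_drug_target=_reindex_rect(A_drug_target, cats["drug"], cats["target"]),
        A_disease_target=_reindex_rect(A_disease_target, cats["disease"], cats["target"]),
    )


def _active_mask(mat: sp.csr_array, axis: int) -> np.ndarray:
    """Nodes with >= 1 nonzero entry along the given axis (off-diagonal for square)."""
    return np.asarray(abs(mat).sum(axis=1 - axis)).ravel() > 0


def harmonize_common_entities(network: HeterogeneousNetwork) -> HeterogeneousNetwork:
    """Restrict the network to entities active in every layer touching their type.

    Methods that project bipartite layers (DT-Hybrid style) are undefined for
    degree-0 nodes and require consistent item lists across sub-networks, so
    each entity must carry at least one nonzero entry in its similarity matrix
    AND in both of its association layers.  Catalog order is preserved.
    """
    masks = {
        "drug": (
            _active_mask(network.S_drug.values, 0)
            & _active_mask(network.A_drug_disease.values, 0)
            & _active_mask(network.A_drug_target.values, 0)
        ),
        "disease": (
            _active_mask(network.S_disease.values, 0)
            & _active_mask(network.A_drug_disease.values, 1)
            & _active_mask(network.A_disease_target.values, 0)
        ),
        "target": (
            _active_mask(network.S_target.values, 0)
            & _active_mask(network.A_drug_target.values, 1)
            & _active_mask(network.A_disease_target.values, 1)
        ),
    }
    for kind, mask in masks.items():
        if not mask.any():
            raise NetworkFormatError(
                f"no {kind} is active in all three {kind} layers; the network has no "
                f"consistent common entity set and projection baselines are inapplicable"
            )
    cats = {
        kind: EntityCatalog(
            kind, tuple(np.array(network.catalog(kind).ids, dtype=object)[mask])
        )
        for kind, mask in masks.items()
    }
    idx = {kind: np.flatnonzero(mask) for kind, mask in masks.items()}

    def sq(sim: SimilarityMatrix, kind: str) -> SimilarityMatrix:
        sub = sim.values[np.ix_(idx[kind], idx[kind])]
        return SimilarityMatrix(cats[kind], sp.csr_array(sub))

    def rect(assoc: AssociationMatrix, rk: str, ck: str) -> AssociationMatrix:
        sub = assoc.values[np.ix_(idx[rk], idx[ck])]
        return AssociationMatrix(cats[rk], cats[ck], sp.csr_array(sub))

    return HeterogeneousNetwork(
        drugs=cats["drug"],
        diseases=cats["disease"],
        targets=cats["target"],
        S_drug=sq(network.S_drug, "drug"),
        S_disease=sq(network.S_disease, "disease"),
        S_target=sq(network.S_target, "target"),
        A_drug_disease=rect(network.A_drug_disease, "drug", "disease"),
        A_drug_target=rect(network.A_drug_target, "drug", "target"),
        A_disease_target=rect(network.A_disease_target, "disease", "target"),
    )


_LAYER_FILES = {
    "drug_similarity.tsv": ("similarity", "drug"),
    "disease_similarity.tsv": ("similarity", "disease"),
    "target_similarity.tsv": ("similarity", "target"),
    "drug_disease.tsv": ("association", ("drug", "disease")),
    "drug_target.tsv": ("association", ("drug", "target")),
    "disease_target.tsv": ("association", ("disease", "target")),
}


def load_network(directory: str | Path) -> HeterogeneousNetwork:
    """Load and align the six TSVs of a dataset directory (standard file names)."""
    directory = Path(directory)
    missing = [name for name in _LAYER_FILES if not (directory / name).exists()]
    if missing:
        raise FileNotFoundError(f"dataset directory {directory} is missing: {missing}")
    return align_network(
        load_similarity(directory / "drug_similarity.tsv", "drug"),
        load_similarity(directory / "disease_similarity.tsv", "disease"),
        load_similarity(directory / "target_similarity.tsv", "target"),
        load_association(directory / "drug_disease.tsv", "drug", "disease"),
        load_association(directory / "drug_target.tsv", "drug", "target"),
        load_association(directory / "disease_target.tsv", "disease", "target"),
    )


def write_network(network: HeterogeneousNetwork, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_similarity(network.S_drug, directory / "drug_similarity.tsv")
    write_similarity(network.S_disease, directory / "disease_similarity.tsv")
    write_similarity(network.S_target, directory / "target_similarity.tsv")
    write_association(network.A_drug_disease, directory / "drug_disease.tsv")
    write_association(network.A_drug_target, directory / "drug_target.tsv")
    write_association(network.A_disease_target, directory / "disease_target.tsv")
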