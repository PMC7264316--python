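"""Ranked novel predictions from score matrices: threshold + novelty semantics.

A predicted link is reported when its weight reaches the threshold tau
(default 0.005, the conventional cutoff for these probability-style weights)
AND it is absent from the input association layer — any nonzero input
weight, including partial-confidence weights, counts as already known.
Ordering is weight-descending with lexicographic tie-breaks so reports are
reproducible byte for byte.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import scipy.sparse as sp

from .network_model import AssociationMatrix


@dataclass(frozen=True)
class PredictionSet:
    """Scored, ranked (row_id, col_id, weight) triples for one relation."""

    relation: str
    triples: tuple[tuple[str, str, float], ...]
    tau: float
    novel_only: bool = True

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self):
        return iter(self.triples)


def _sorted_triples(entries: Iterable[tuple[str, str, float]]):
    return tuple(sorted(entries, key=lambda t: (-t[2], t[0], t[1])))


def novel_predictions(
    scores: AssociationMatrix, known: AssociationMatrix, tau: float = 0.005
) -> PredictionSet:
    """Extract novel links: score >= tau and not present in the input layer."""
    if tau < 0:
        raise ValueError(f"tau must be nonnegative; got {tau}")
    if scores.shape != known.shape:
        raise ValueError(f"scores {scores.shape} and known {known.shape} differ in shape")
    S = scores.toarray()
    K = known.toarray()
    rows, cols = np.nonzero((S >= tau) & (S > 0) & (K == 0))
    triples = _sorted_triples(
        (scores.row_catalog.ids[i], scores.col_catalog.ids[j], float(S[i, j]))
        for i, j in zip(rows, cols)
    )
    return PredictionSet(scores.relation, triples, tau, novel_only=True)


def all_predictions(scores: AssociationMatrix, tau: float = 0.0) -> PredictionSet:
    """All scored links at or above tau, known or not (diagnostic view)."""
    if tau < 0:
        raise ValueError(f"tau must be nonnegative; got {tau}")
    coo = sp.coo_array(scores.values)
    triples = _sorted_triples(
        (scores.row_catalog.ids[i], scores.col_catalog.ids[j], float(w))
        for i, j, w in zip(coo.row, coo.col, coo.data)
        if w >= tau
    )
    return PredictionSet(scores.relation, triples, tau, novel_only=False)


def query_entity(
    predictions: dict[str, PredictionSet], entity_id: str, known_ids: Iterable[str]
) -> dict[str, list[tuple[str, str, float]]]:
    """All novel triples involving one entity, grouped by relation, ranked.

    Querying a disease returns its candidate drugs (drug_disease rows) and
    candidate targets (disease_target columns); analogous for drugs/targets.
    Raises KeyError with nearest-match suggestions for unknown ids.
    """
    known_ids = list(known_ids)
    if entity_id not in set(known_ids):
        hints = difflib.get_close_matches(entity_id, known_ids, n=5, cutoff=0.4)
        raise KeyError(
            f"unknown entity {entity_id!r}" + (f"; nearest matches: {hints}" if hints else "")
        )
    report: dict[str, list[tuple[str, str, float]]] = {}
    for relation, pset in sorted(predictions.items()):
        hits = [t for t in pset.triples if entity_id in (t[0], t[1])]
        if hits:
            report[relation] = hits
    return report


def write_predictions(predictions: dict[str, PredictionSet], path: str | Path) -> None:
    """TSV report: ``relation  id1  id2  weight  novel`` (one file, all relations)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("relation\tid1\tid2\tweight\tnovel\n")
        for relation in sorted(predictions):
            pset = predictions[relation]
            for a, b, w in pset.triples:
                fh.write(f"{relation}\t{a}\t{b}\t{w!r}\t{int(pset.novel_only)}\n")


def report_to_json(report: dict[str, list[tuple[str, str, float]]]) -> str:
    return json.dumps(
        {
            rel: [{"id1": a, "id2": b, "weight": w} for a, b, w in triples]
            for rel, triples in report.items()
        },
        indent=2,
    )
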