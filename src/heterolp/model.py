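"""Estimator-style front ends for the two link predictors.

`HeterLP` and `DTHybrid` follow the scikit-learn estimator protocol
(constructor stores hyperparameters, ``fit`` takes the data and sets
trailing-underscore attributes, ``get_params``/``set_params`` work with
``sklearn.base.clone`` and model selection).  Both are transductive: ``fit``
scores every pair of the network it is given, and ``predict`` returns score
matrices or thresholded novel-prediction sets for one relation.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .dthybrid import dthybrid_predict
from .label_propagation import predict_relation
from .network_model import (
    AssociationMatrix,
    HeterogeneousNetwork,
    RELATIONS,
    harmonize_common_entities,
)
from .prediction import PredictionSet, novel_predictions
from .projection import fuse_network


class HeterLP(BaseEstimator):
    """Heterogeneous label propagation over a drug-disease-target network.

    The three-stage pipeline: (1) the six-matrix network is the input data
    model; (2) topological similarities are projected from each bipartite
    layer and fused with the intrinsic similarities; (3) known associations
    are diffused over each fused network by label spreading, and each
    relation is scored from both of its sides.

    Parameters
    ----------
    alpha : float, default 0.5
        Mixing parameter in (0, 1): diffusion weight vs. label retention.
    tol : float, default 1e-6
        Convergence tolerance on the max absolute score change.
    max_iter : int, default 1000
        Iteration cap per propagation.
    fusion : {"max", "mean"}, default "max"
        How intrinsic and topological similarities are combined.
    tau : float, default 0.005
        Weight threshold for reported novel predictions.

    Attributes
    ----------
    network_ : HeterogeneousNetwork
        The fitted (input) network.
    fused_ : dict of str -> FusedSimilarity
        Fused similarity per entity type.
    scores_ : dict of str -> AssociationMatrix
        Score matrix per relation, entries in [0, 1].
    diagnostics_ : dict
        Per-relation, per-side PropagationResult (iterations, residuals).
    converged_ : bool
        True when every propagation met the tolerance.

    Examples
    --------
    >>> from heterolp import HeterLP, SyntheticSpec, generate
    >>> net = generate(SyntheticSpec(seed=7))
    >>> model = HeterLP(alpha=0.5).fit(net)
    >>> model.predict("drug_disease").shape
    (50, 40)
    """

    def __init__(
        self,
        alpha: float = 0.5,
        tol: float = 1e-6,
        max_iter: int = 1000,
        fusion: str = "max",
        tau: float = 0.005,
    ):
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter
        self.fusion = fusion
        self.tau = tau

    def fit(self, X: HeterogeneousNetwork, y=None) -> "HeterLP":
        """Project, fuse, and propagate every relation of the network ``X``."""
        if not isinstance(X, HeterogeneousNetwork):
            raise TypeError(f"X must be a HeterogeneousNetwork; got {type(X).__name__}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1); got {self.alpha}")
        self.network_ = X
        self.fused_ = fuse_network(X, method=self.fusion)
        self.scores_ = {}
        self.diagnostics_ = {}
        for relation in RELATIONS:
            scores, diag = predict_relation(
                X, self.fused_, relation, alpha=self.alpha, tol=self.tol, max_iter=self.max_iter
            )
            self.scores_[relation] = scores
            self.diagnostics_[relation] = diag
        self.converged_ = all(
            res.converged for diag in self.diagnostics_.values() for res in diag.values()
        )
        return self

    def predict(self, relation: str = "drug_disease") -> AssociationMatrix:
        """Score matrix for one relation of the fitted network."""
        check_is_fitted(self, "scores_")
        return self.scores_[relation]

    def predict_novel(self, relation: str = "drug_disease", tau: float | None = None) -> PredictionSet:
        """Thresholded novel predictions (score >= tau, absent from input)."""
        check_is_fitted(self, "scores_")
        tau = self.tau if tau is None else tau
        return novel_predictions(
            self.scores_[relation], self.network_.association(relation), tau
        )

    def predict_all_novel(self, tau: float | None = None) -> dict[str, PredictionSet]:
        check_is_fitted(self, "scores_")
        return {rel: self.predict_novel(rel, tau) for rel in RELATIONS}


class DTHybrid(BaseEstimator):
    """Degree-tuned bipartite projection baseline with similarity blending.

    Requires a harmonized network (entities active in every layer of their
    type); ``fit`` harmonizes automatically when needed.

    Parameters
    ----------
    lam : float, default 0.5
        Degree-tuning exponent of the resource-allocation weights.
    alpha : float, default 0.5
        Weight of the a-priori similarity blend; 0 is pure structural NBI.
    rescale : bool, default True
        Min-max rescale scores to [0, 1] so the tau threshold applies.
    tau : float, default 0.005
        Weight threshold for reported novel predictions.
    harmonize : bool, default True
        Restrict the input network to its common entity set before fitting.
    """

    def __init__(
        self,
        lam: float = 0.5,
        alpha: float = 0.5,
        rescale: bool = True,
        tau: float = 0.005,
        harmonize: bool = True,
    ):
        self.lam = lam
        self.alpha = alpha
        self.rescale = rescale
        self.tau = tau
        self.harmonize = harmonize

    def fit(self, X: HeterogeneousNetwork, y=None) -> "DTHybrid":
        if not isinstance(X, HeterogeneousNetwork):
            raise TypeError(f"X must be a HeterogeneousNetwork; got {type(X).__name__}")
        net = harmonize_common_entities(X) if self.harmonize else X
        self.network_ = net
        self.scores_ = {}
        for relation in RELATIONS:
            rec = dthybrid_predict(
                net, relation, lam=self.lam, alpha=self.alpha, rescale=self.rescale
            )
            if self.rescale:
                self.scores_[relation] = AssociationMatrix(
                    rec.row_catalog, rec.col_catalog, np.clip(rec.values, 0.0, 1.0)
                )
            else:
                self.scores_[relation] = rec  # raw scores may exceed 1
        return self

    def predict(self, relation: str = "drug_target") -> AssociationMatrix:
        check_is_fitted(self, "scores_")
        return self.scores_[relation]

    def predict_novel(self, relation: str = "drug_target", tau: float | None = None) -> PredictionSet:
        check_is_fitted(self, "scores_")
        tau = self.tau if tau is None else tau
        return novel_predictions(
            self.scores_[relation], self.network_.association(relation), tau
        )
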