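"""Hybrid scorers combining the dense and convolutional Siamese models.

Two fusion families:

* **Decision fusion (max)** — the two component models are trained
  independently; the hybrid score of a pair is the maximum of their
  final scores.  With two measures per component this is the
  Hybrid-D-Max2 design, with three (Jaccard for the dense model,
  Russel for the convolutional one) Hybrid-D-Max3.

* **Feature fusion (sum / max)** — one end-to-end model.  Each trunk
  runs its twin branch, three similarity measures and the fusion
  layer; the dense trunk is reduced through a 1024-512 ReLU stack to a
  512-vector, the convolutional trunk's fused vector is 512-long
  already.  The two 512-vectors are combined elementwise (sum for
  Hybrid-F-Sum, maximum for Hybrid-F-Max) and a single sigmoid unit
  produces the score.  Trained from scratch with RMSprop + binary
  cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor
from .fingerprint_data import DEFAULT_LENGTH
from .siamese_models import (
    SimilarityScorer,
    TrainSpec,
    _NeuralScorer,
    _dense,
    _fused_measures,
    _init,
)
from .synthetic_data import PairBatch

__all__ = [
    "DecisionHybridScorer",
    "TrainableDecisionHybrid",
    "decision_fuse_max",
    "FeatureHybridConfig",
    "FeatureHybridScorer",
    "build_feature_hybrid",
    "train_feature_hybrid",
]


# -- decision fusion -------------------------------------------------------


class DecisionHybridScorer(SimilarityScorer):
    """Maximum of two independently trained component scorers."""

    kind = "decision-hybrid"
    needs_training = False  # components arrive trained

    def __init__(self, model_a: SimilarityScorer, model_b: SimilarityScorer):
        for m in (model_a, model_b):
            if not getattr(m, "trained", False):
                raise ValueError(
                    "decision fusion needs trained component scorers"
                )
        self.model_a = model_a
        self.model_b = model_b
        self.trained = True

    def score_pairs(self, A, B):
        return np.maximum(
            self.model_a.score_pairs(A, B), self.model_b.score_pairs(A, B)
        )


def decision_fuse_max(hybrid: DecisionHybridScorer, a, b) -> float:
    """Score one pair with a decision-fusion hybrid (max of components)."""
    return hybrid.score_pair(a, b)


class TrainableDecisionHybrid(SimilarityScorer):
    """Decision-fusion hybrid whose components are still untrained.

    Fitting trains both components independently on the same pair
    batch; afterwards the scorer behaves as the max of their outputs.
    Used by the cross-validation pipeline, where training happens
    inside each fold.
    """

    kind = "decision-hybrid"
    needs_training = True

    def __init__(self, model_a: SimilarityScorer, model_b: SimilarityScorer):
        self.model_a = model_a
        self.model_b = model_b
        self.trained = False
        self.loss_trace: list[float] = []

    def fit(self, pairs: PairBatch, spec: TrainSpec) -> list[float]:
        trace_a = self.model_a.fit(pairs, spec)
        trace_b = self.model_b.fit(pairs, spec)
        self.trained = True
        # component traces interleaved as (a, b) per epoch
        self.loss_trace = [v for ab in zip(trace_a, trace_b) for v in ab]
        return self.loss_trace

    def score_pairs(self, A, B):
        if not self.trained:
            raise ValueError("decision hybrid scored before training")
        return np.maximum(
            self.model_a.score_pairs(A, B), self.model_b.score_pairs(A, B)
        )


# -- feature fusion --------------------------------------------------------


@dataclass(frozen=True)
class FeatureHybridConfig:
    """End-to-end feature-fusion hybrid architecture.

    Both trunks must meet at the same width (default 512) for the
    elementwise combination; ``combine`` is ``"sum"`` or ``"max"``.
    """

    combine: str = "sum"
    input_length: int = DEFAULT_LENGTH
    smlp_branch_width: int = 1024
    smlp_head_widths: tuple[int, ...] = (1024, 512)
    n_filters: int = 64
    kernel_size: int = 3
    pool_size: int = 2
    feature_width: int = 512

    def __post_init__(self):
        if self.combine not in ("sum", "max"):
            raise ValueError("combine must be 'sum' or 'max'")
        if self.smlp_head_widths[-1] != self.feature_width:
            raise ValueError(
                "dense-trunk output width must equal the convolutional "
                "trunk width for elementwise fusion"
            )
        if self.input_length % (self.pool_size**2) != 0:
            raise ValueError(
                f"input length {self.input_length} must be divisible by "
                f"{self.pool_size ** 2}"
            )


class FeatureHybridScorer(_NeuralScorer):
    """One trainable model: both trunks plus the shared output head."""

    kind = "feature-hybrid"

    def __init__(self, cfg: FeatureHybridConfig = FeatureHybridConfig(),
                 seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        L = cfg.input_length
        # dense trunk
        self.params["m_Wb"] = _init(rng, (L, cfg.smlp_branch_width), L)
        self.params["m_bb"] = Tensor(np.zeros(cfg.smlp_branch_width),
                                     requires_grad=True)
        prev = cfg.smlp_branch_width
        for i, w in enumerate(cfg.smlp_head_widths):
            self.params[f"m_Wh{i}"] = _init(rng, (prev, w), prev)
            self.params[f"m_bh{i}"] = Tensor(np.zeros(w), requires_grad=True)
            prev = w
        # convolutional trunk
        K, F = cfg.kernel_size, cfg.n_filters
        self.params["c_K1"] = _init(rng, (K, 1, F), K)
        self.params["c_c1"] = Tensor(np.zeros(F), requires_grad=True)
        self.params["c_K2"] = _init(rng, (K, F, F), K * F)
        self.params["c_c2"] = Tensor(np.zeros(F), requires_grad=True)
        flat = (L // cfg.pool_size**2) * F
        self.params["c_Wd"] = _init(rng, (flat, cfg.feature_width), flat)
        self.params["c_bd"] = Tensor(np.zeros(cfg.feature_width),
                                     requires_grad=True)
        # shared output head
        self.params["Wo"] = _init(rng, (cfg.feature_width, 1),
                                  cfg.feature_width)
        self.params["bo"] = Tensor(np.zeros(1), requires_grad=True)

    # trunk forward passes -------------------------------------------------

    def _smlp_trunk(self, xa: Tensor, xb: Tensor) -> Tensor:
        fA = _dense(xa, self.params["m_Wb"], self.params["m_bb"]).relu()
        fB = _dense(xb, self.params["m_Wb"], self.params["m_bb"]).relu()
        h = _fused_measures(fA, fB, "jaccard")
        for i in range(len(self.cfg.smlp_head_widths)):
            h = _dense(h, self.params[f"m_Wh{i}"], self.params[f"m_bh{i}"]).relu()
        return h

    def _conv_branch(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        h = x.reshape(x.shape[0], cfg.input_length, 1)
        h = (h.conv1d_same(self.params["c_K1"]) + self.params["c_c1"]).relu()
        h = h.maxpool1d(cfg.pool_size)
        h = (h.conv1d_same(self.params["c_K2"]) + self.params["c_c2"]).relu()
        h = h.maxpool1d(cfg.pool_size)
        h = h.reshape(h.shape[0], h.shape[1] * h.shape[2])
        return _dense(h, self.params["c_Wd"], self.params["c_bd"]).sigmoid()

    def _scnn_trunk(self, xa: Tensor, xb: Tensor) -> Tensor:
        fA = self._conv_branch(xa)
        fB = self._conv_branch(xb)
        return _fused_measures(fA, fB, "russel")

    def _forward(self, A, B):
        xa, xb = Tensor(A), Tensor(B)
        va = self._smlp_trunk(xa, xb)
        vb = self._scnn_trunk(xa, xb)
        combined = va + vb if self.cfg.combine == "sum" else va.maximum(vb)
        return _dense(combined, self.params["Wo"], self.params["bo"]).sigmoid()


def build_feature_hybrid(combine: str, seed: int = 0,
                         cfg: FeatureHybridConfig | None = None
                         ) -> FeatureHybridScorer:
    """Construct an untrained feature-fusion hybrid (``combine``: sum|max)."""
    if cfg is None:
        cfg = FeatureHybridConfig(combine=combine)
    elif cfg.combine != combine:
        raise ValueError("combine argument disagrees with the config")
    return FeatureHybridScorer(cfg, seed=seed)


def train_feature_hybrid(scorer: FeatureHybridScorer, pairs: PairBatch,
                         spec: TrainSpec) -> list[float]:
    """Train a feature-fusion hybrid end-to-end; returns the loss trace."""
    return scorer.fit(pairs, spec)
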