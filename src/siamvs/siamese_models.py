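"""Enhanced Siamese similarity scorers.

Two twin networks with one shared parameter set map each fingerprint of
a pair to a feature vector.  The pair of feature vectors is compared by
explicit similarity-measure layers — the elementwise absolute
difference (a vector), the exponential Manhattan similarity (a scalar)
and optionally a third scalar measure (continuous Jaccard for the
dense-branch model, Russel for the convolutional model).  A fusion
layer broadcasts the scalar measures onto the difference vector, and a
dense head ends in a single sigmoid unit producing a similarity score
in [0, 1]: 1 means complete similarity, 0 complete dissimilarity.

Because every measure layer is symmetric in its two inputs and the
twins share weights structurally, ``score(a, b) == score(b, a)`` for
any parameter values.

Training minimises binary cross-entropy on same-activity-class pair
labels with RMSprop, exactly the supervision the scorers are screened
with afterwards.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from dataclasses import asdict, dataclass

import numpy as np

from ._autodiff import RMSProp, Tensor
from .fingerprint_data import DEFAULT_LENGTH, CountFingerprint
from .similarity_measures import tanimoto_score
from .synthetic_data import PairBatch

__all__ = [
    "MeasureSet",
    "measure_fusion",
    "SmlpConfig",
    "Scnn1dConfig",
    "TrainSpec",
    "SimilarityScorer",
    "TanimotoScorer",
    "SmlpScorer",
    "Scnn1dScorer",
    "build_siamese",
    "train",
    "score_pair",
    "save_checkpoint",
    "load_checkpoint",
]


# -- measure fusion (reference, outside the autodiff graph) ----------------


@dataclass(frozen=True)
class MeasureSet:
    """Output of the measure layers for one pair: a vector plus scalars."""

    vector_measure: np.ndarray
    scalar_measures: tuple[float, ...]

    def __post_init__(self):
        if not 1 <= len(self.scalar_measures) <= 2:
            raise ValueError("expected one or two scalar measures")


def measure_fusion(ms: MeasureSet) -> np.ndarray:
    """Broadcast-add the scalar measures onto the vector measure.

    With scalars ``s2`` (and ``s3``): ``out_j = vector_j + s2 (+ s3)``.
    """
    if len(ms.scalar_measures) == 0:
        raise ValueError("measure fusion needs at least one scalar measure")
    return np.asarray(ms.vector_measure, dtype=np.float64) + float(
        sum(ms.scalar_measures)
    )


# -- configuration ---------------------------------------------------------


@dataclass(frozen=True)
class SmlpConfig:
    """Dense-branch ("SMLP") architecture.

    One 1024-unit ReLU layer per twin, a 1024-wide measure-fusion
    vector, then a 1024-512-256-128-64 ReLU head and a sigmoid output
    unit.  ``n_measures=3`` adds continuous Jaccard on the twin
    feature vectors as a third scalar measure.
    """

    input_length: int = DEFAULT_LENGTH
    branch_width: int = 1024
    head_widths: tuple[int, ...] = (1024, 512, 256, 128, 64)
    n_measures: int = 2

    def __post_init__(self):
        if self.n_measures not in (2, 3):
            raise ValueError("n_measures must be 2 or 3")
        if self.input_length < 1 or self.branch_width < 1:
            raise ValueError("widths must be positive")


@dataclass(frozen=True)
class Scnn1dConfig:
    """Convolutional-branch ("SCNN1D") architecture.

    Per twin: two 1-D convolutions (64 filters, kernel 3, ReLU), each
    followed by max-pooling of size 2, a flatten, and a sigmoid dense
    layer onto a 512-long feature vector.  The fused measure vector
    feeds a single sigmoid output unit.  ``n_measures=3`` adds the
    Russel coefficient on the twin feature vectors.
    """

    input_length: int = DEFAULT_LENGTH
    n_filters: int = 64
    kernel_size: int = 3
    pool_size: int = 2
    feature_width: int = 512
    n_measures: int = 2

    def __post_init__(self):
        if self.n_measures not in (2, 3):
            raise ValueError("n_measures must be 2 or 3")
        if self.input_length % (self.pool_size**2) != 0:
            raise ValueError(
                f"input length {self.input_length} must be divisible by "
                f"{self.pool_size ** 2} (two pooling stages)"
            )


@dataclass(frozen=True)
class TrainSpec:
    """Optimisation settings: RMSprop + binary cross-entropy."""

    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


# -- scorer contract -------------------------------------------------------


class SimilarityScorer(ABC):
    """Maps a fingerprint pair to a similarity score in [0, 1]."""

    needs_training: bool = True

    @abstractmethod
    def score_pairs(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        """Score aligned ``(n, L)`` fingerprint batches; returns ``(n,)``."""

    def score_pair(self, a, b) -> float:
        a = a.values if isinstance(a, CountFingerprint) else np.asarray(a)
        b = b.values if isinstance(b, CountFingerprint) else np.asarray(b)
        if a.shape != b.shape:
            raise ValueError("fingerprint length mismatch")
        return float(self.score_pairs(a[None, :], b[None, :])[0])

    def fit(self, pairs: PairBatch, spec: TrainSpec) -> list[float]:
        raise NotImplementedError(f"{type(self).__name__} is not trainable")


class TanimotoScorer(SimilarityScorer):
    """The classical continuous-Tanimoto baseline; needs no training."""

    needs_training = False
    trained = True

    def score_pairs(self, A, B):
        A = np.asarray(A, dtype=np.float64)
        B = np.asarray(B, dtype=np.float64)
        return np.asarray(tanimoto_score(A, B), dtype=np.float64).reshape(-1)


# -- shared neural machinery ----------------------------------------------


def _init(rng: np.random.Generator, shape: tuple[int, ...],
          fan_in: int) -> Tensor:
    """Seeded uniform fan-in initialisation."""
    bound = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


def _dense(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    return x @ W + b


def _fused_measures(fA: Tensor, fB: Tensor, third: str | None) -> Tensor:
    """Measure layers + fusion inside the autodiff graph.

    ``third`` selects the optional scalar measure: ``"jaccard"``,
    ``"russel"`` or ``None``.  The in-graph Jaccard guards the 0/0 case
    with a tiny additive constant in the denominator so that a pair of
    all-zero feature vectors scores 0 instead of poisoning training.
    """
    v = (fA - fB).abs()
    s = (-v.sum(axis=1, keepdims=True)).exp()  # exponential Manhattan
    if third == "jaccard":
        num = (fA * fB).sum(axis=1, keepdims=True)
        den = (fA * fA).sum(axis=1, keepdims=True) + (fB * fB).sum(
            axis=1, keepdims=True
        ) - num
        s = s + num / (den + 1e-12)
    elif third == "russel":
        n = fA.shape[1]
        s = s + (fA * fB).sum(axis=1, keepdims=True) * (1.0 / n)
    elif third is not None:
        raise ValueError(f"unknown third measure {third!r}")
    return v + s  # broadcast (n, F) + (n, 1)


def _bce(p: Tensor, y: np.ndarray) -> Tensor:
    yt = Tensor(y.astype(np.float64).reshape(p.shape))
    one = Tensor(np.ones_like(p.data))
    eps = 1e-12
    return -(
        yt * (p + eps).log() + (one - yt) * (one - p + eps).log()
    ).mean()


class _NeuralScorer(SimilarityScorer):
    """Common training loop and bookkeeping for the neural scorers."""

    def __init__(self):
        self.params: dict[str, Tensor] = {}
        self.trained = False
        self.loss_trace: list[float] = []

    # subclasses implement the differentiable forward pass
    def _forward(self, A: np.ndarray, B: np.ndarray) -> Tensor:
        raise NotImplementedError

    def score_pairs(self, A, B):
        A = np.asarray(A, dtype=np.float64)
        B = np.asarray(B, dtype=np.float64)
        if A.shape != B.shape:
            raise ValueError("fingerprint batch shape mismatch")
        return self._forward(A, B).data.reshape(-1)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def fit(self, pairs: PairBatch, spec: TrainSpec) -> list[float]:
        y = np.asarray(pairs.labels)
        if len(pairs) == 0:
            raise ValueError("empty pair batch")
        if len(np.unique(y)) < 2:
            raise ValueError(
                "degenerate supervision: both pair labels must be present"
            )
        opt = RMSProp(self.parameters(), lr=spec.learning_rate)
        rng = np.random.default_rng(spec.seed)
        n = len(pairs)
        A = np.asarray(pairs.a, dtype=np.float64)
        B = np.asarray(pairs.b, dtype=np.float64)
        trace = []
        for _ in range(spec.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, spec.batch_size):
                idx = order[start : start + spec.batch_size]
                opt.zero_grad()
                p = self._forward(A[idx], B[idx])
                loss = _bce(p, y[idx])
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            trace.append(epoch_loss / n)
        self.trained = True
        self.loss_trace = trace
        return trace


class SmlpScorer(_NeuralScorer):
    """Enhanced Siamese multi-layer-perceptron scorer."""

    kind = "smlp"

    def __init__(self, cfg: SmlpConfig = SmlpConfig(), seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        L, Bw = cfg.input_length, cfg.branch_width
        self.params["Wb"] = _init(rng, (L, Bw), L)
        self.params["bb"] = Tensor(np.zeros(Bw), requires_grad=True)
        prev = Bw
        for i, w in enumerate(cfg.head_widths):
            self.params[f"Wh{i}"] = _init(rng, (prev, w), prev)
            self.params[f"bh{i}"] = Tensor(np.zeros(w), requires_grad=True)
            prev = w
        self.params["Wo"] = _init(rng, (prev, 1), prev)
        self.params["bo"] = Tensor(np.zeros(1), requires_grad=True)

    def _branch(self, x: Tensor) -> Tensor:
        return _dense(x, self.params["Wb"], self.params["bb"]).relu()

    def _head(self, fused: Tensor) -> Tensor:
        h = fused
        for i in range(len(self.cfg.head_widths)):
            h = _dense(h, self.params[f"Wh{i}"], self.params[f"bh{i}"]).relu()
        return _dense(h, self.params["Wo"], self.params["bo"]).sigmoid()

    def _forward(self, A, B):
        fA = self._branch(Tensor(A))
        fB = self._branch(Tensor(B))
        third = "jaccard" if self.cfg.n_measures == 3 else None
        return self._head(_fused_measures(fA, fB, third))


class Scnn1dScorer(_NeuralScorer):
    """Enhanced Siamese 1-D convolutional scorer."""

    kind = "scnn1d"

    def __init__(self, cfg: Scnn1dConfig = Scnn1dConfig(), seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        K, F = cfg.kernel_size, cfg.n_filters
        self.params["K1"] = _init(rng, (K, 1, F), K)
        self.params["c1"] = Tensor(np.zeros(F), requires_grad=True)
        self.params["K2"] = _init(rng, (K, F, F), K * F)
        self.params["c2"] = Tensor(np.zeros(F), requires_grad=True)
        flat = (cfg.input_length // cfg.pool_size**2) * F
        self.params["Wd"] = _init(rng, (flat, cfg.feature_width), flat)
        self.params["bd"] = Tensor(np.zeros(cfg.feature_width), requires_grad=True)
        self.params["Wo"] = _init(rng, (cfg.feature_width, 1), cfg.feature_width)
        self.params["bo"] = Tensor(np.zeros(1), requires_grad=True)

    def _branch(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        h = x.reshape(x.shape[0], cfg.input_length, 1)
        h = (h.conv1d_same(self.params["K1"]) + self.params["c1"]).relu()
        h = h.maxpool1d(cfg.pool_size)
        h = (h.conv1d_same(self.params["K2"]) + self.params["c2"]).relu()
        h = h.maxpool1d(cfg.pool_size)
        h = h.reshape(h.shape[0], h.shape[1] * h.shape[2])
        return _dense(h, self.params["Wd"], self.params["bd"]).sigmoid()

    def _forward(self, A, B):
        fA = self._branch(Tensor(A))
        fB = self._branch(Tensor(B))
        third = "russel" if self.cfg.n_measures == 3 else None
        fused = _fused_measures(fA, fB, third)
        return _dense(fused, self.params["Wo"], self.params["bo"]).sigmoid()


# -- functional facade -----------------------------------------------------


def build_siamese(cfg: SmlpConfig | Scnn1dConfig, seed: int = 0) -> SimilarityScorer:
    """Construct an untrained Siamese scorer from its configuration."""
    if isinstance(cfg, SmlpConfig):
        return SmlpScorer(cfg, seed=seed)
    if isinstance(cfg, Scnn1dConfig):
        return Scnn1dScorer(cfg, seed=seed)
    raise TypeError(f"unsupported config type {type(cfg).__name__}")


def train(scorer: SimilarityScorer, pairs: PairBatch,
          spec: TrainSpec) -> list[float]:
    """Train a scorer in place; returns the per-epoch loss trace."""
    return scorer.fit(pairs, spec)


def score_pair(scorer: SimilarityScorer, a, b) -> float:
    """Score one fingerprint pair with a (trained) scorer."""
    return scorer.score_pair(a, b)


# -- checkpointing ---------------------------------------------------------


def save_checkpoint(scorer, path) -> None:
    """Persist a neural scorer (config + parameters) to an .npz container."""
    header = {
        "kind": scorer.kind,
        "config": asdict(scorer.cfg),
        "trained": bool(scorer.trained),
        "loss_trace": list(scorer.loss_trace),
    }
    arrays = {name: t.data for name, t in scorer.params.items()}
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Rebuild a scorer saved by :func:`save_checkpoint`."""
    from .hybrid_models import FeatureHybridScorer, FeatureHybridConfig

    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        arrays = {k: data[k] for k in data.files if k != "__header__"}
    kind = header["kind"]
    if kind == "smlp":
        cfg = SmlpConfig(**{**header["config"],
                            "head_widths": tuple(header["config"]["head_widths"])})
        scorer = SmlpScorer(cfg)
    elif kind == "scnn1d":
        scorer = Scnn1dScorer(Scnn1dConfig(**header["config"]))
    elif kind == "feature-hybrid":
        cfg_d = dict(header["config"])
        cfg_d["smlp_head_widths"] = tuple(cfg_d["smlp_head_widths"])
        scorer = FeatureHybridScorer(FeatureHybridConfig(**cfg_d))
    else:
        raise ValueError(f"unknown checkpoint kind {kind!r}")
    for name, arr in arrays.items():
        scorer.params[name].data = arr.astype(np.float64)
    scorer.trained = header["trained"]
    scorer.loss_trace = list(header["loss_trace"])
    return scorer
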