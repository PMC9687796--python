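"""Virtual-screening protocol: ranking, recall@top-n%, cross-validation.

A query (reference structure) is an active molecule; the database is
ranked by descending similarity score and recall@n% is the fraction of
the query's same-class actives retrieved within the top ``n`` percent
of the ranked set.  The cross-validated protocol splits the library
into k stratified folds, trains the scorer on k-1 folds (from sampled
pairs), draws a fixed number of random queries per activity class from
the held-out fold, screens them against the remaining held-out
molecules, and averages recall over queries and folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .fingerprint_data import INACTIVE_LABEL, CountFingerprint, ScreeningLibrary
from .siamese_models import SimilarityScorer, TrainSpec
from .synthetic_data import generate_pairs

__all__ = [
    "RankedList",
    "RecallTable",
    "CvProtocol",
    "rank_database",
    "recall_at",
    "run_cv",
    "summarize",
    "load_published_table",
    "PUBLISHED_TABLES",
]


@dataclass(frozen=True)
class RankedList:
    """Database molecules ordered by descending similarity to a query."""

    query_id: str
    query_class: str
    molecule_ids: np.ndarray
    labels: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")
        if self.query_id in set(self.molecule_ids):
            raise ValueError("query must be excluded from its ranked list")

    def __len__(self) -> int:
        return len(self.molecule_ids)


class RecallTable:
    """Activity-class x method matrix of recall percentages."""

    def __init__(self, df: pd.DataFrame):
        if df.empty:
            raise ValueError("empty recall table")
        self.df = df.astype(np.float64)
        self.df.index = self.df.index.astype(str)
        self.df.index.name = "class"

    @classmethod
    def from_columns(cls, columns: dict[str, "pd.Series | dict"]) -> "RecallTable":
        return cls(pd.DataFrame(columns))

    def mean_row(self) -> pd.Series:
        """Per-method arithmetic mean over activity classes."""
        return self.df.mean(axis=0)

    def shaded_counts(self) -> pd.Series:
        """Per-method count of classes where the method attains the row
        maximum (all tied maxima are counted)."""
        mx = self.df.max(axis=1)
        return (self.df.ge(mx - 1e-9, axis=0)).sum(axis=0)

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "RecallTable":
        df = pd.read_csv(path, sep="\t", dtype={"class": str},
                         float_precision="round_trip")
        if "class" not in df.columns:
            raise ValueError("recall table lacks the 'class' index column")
        return cls(df.set_index("class"))

    def __eq__(self, other):
        return isinstance(other, RecallTable) and self.df.equals(other.df)


def summarize(table: RecallTable) -> tuple[pd.Series, pd.Series]:
    """The Mean row and the shaded-cell counts of a recall table."""
    return table.mean_row(), table.shaded_counts()


@dataclass(frozen=True)
class CvProtocol:
    """Cross-validated screening settings."""

    k_folds: int = 5
    queries_per_class: int = 10
    cutoffs: tuple[float, ...] = (1.0, 5.0)
    seed: int = 0
    n_train_pairs: int = 2000
    pos_fraction: float = 0.5

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.queries_per_class < 1:
            raise ValueError("queries_per_class must be >= 1")
        for pct in self.cutoffs:
            if not 0.0 < pct <= 100.0:
                raise ValueError("cutoffs must lie in (0, 100]")


# -- ranking ---------------------------------------------------------------


def rank_database(scorer: SimilarityScorer, query: CountFingerprint,
                  lib: ScreeningLibrary) -> RankedList:
    """Score and sort every non-query molecule, descending.

    Score ties are broken by ascending molecule id so rankings are
    reproducible.
    """
    if lib.n_molecules == 0:
        raise ValueError("empty library")
    keep = np.asarray(
        [str(m) != query.molecule_id for m in lib.molecule_ids], dtype=bool
    )
    if not keep.any():
        raise ValueError("library contains only the query")
    ids = lib.molecule_ids[keep].astype(str)
    labels = lib.labels[keep]
    fps = lib.fingerprints[keep]
    Q = np.broadcast_to(query.values, fps.shape)
    scores = np.asarray(scorer.score_pairs(Q, fps), dtype=np.float64)
    order = np.lexsort((ids, -scores))
    qlabel = None
    hit = np.flatnonzero(lib.molecule_ids.astype(str) == query.molecule_id)
    if hit.size:
        qlabel = str(lib.labels[hit[0]])
    return RankedList(
        query_id=query.molecule_id,
        query_class=qlabel if qlabel is not None else "",
        molecule_ids=ids[order],
        labels=labels[order].astype(str),
        scores=scores[order],
    )


def recall_at(ranked: RankedList, pct: float,
              query_class: str | None = None) -> float:
    """Recall percentage of the query's class within the top ``pct``%.

    The cutoff keeps ``ceil(pct/100 * N)`` molecules; the denominator
    is the number of same-class actives present in the ranked list.
    """
    if not 0.0 < pct <= 100.0:
        raise ValueError("pct must lie in (0, 100]")
    cls = query_class if query_class is not None else ranked.query_class
    if not cls or cls == INACTIVE_LABEL:
        raise ValueError("recall needs an active query class")
    is_active = ranked.labels == cls
    total = int(is_active.sum())
    if total == 0:
        raise ValueError(
            f"no same-class active of {cls!r} present in the ranked list"
        )
    n_top = math.ceil(pct / 100.0 * len(ranked))
    found = int(is_active[:n_top].sum())
    return 100.0 * found / total


# -- cross-validated evaluation -------------------------------------------


def _stratified_folds(lib: ScreeningLibrary, k: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Round-robin fold assignment within each label stratum."""
    fold = np.empty(lib.n_molecules, dtype=np.intp)
    for lbl in list(lib.class_labels()) + [INACTIVE_LABEL]:
        idx = np.flatnonzero(lib.labels == lbl)
        if idx.size == 0:
            continue
        idx = rng.permutation(idx)
        fold[idx] = np.arange(idx.size) % k
    return fold


def run_cv(scorer_factory, lib: ScreeningLibrary, protocol: CvProtocol,
           train_spec: TrainSpec | None = None,
           method_name: str = "method") -> dict[float, RecallTable]:
    """Cross-validated recall evaluation of one scoring method.

    ``scorer_factory(seed)`` must return a fresh scorer; scorers with
    ``needs_training`` are fitted on pairs sampled from the training
    folds.  Returns one single-column :class:`RecallTable` per cutoff.
    """
    classes = lib.class_labels()
    if not classes:
        raise ValueError("library has no activity classes")
    for lbl in classes:
        n_cls = lib.class_members(lbl).size
        if n_cls / protocol.k_folds < protocol.queries_per_class:
            raise ValueError(
                f"class {lbl!r} has {n_cls} members: fewer than "
                f"{protocol.queries_per_class} per fold on average with "
                f"k={protocol.k_folds}"
            )
    root = np.random.SeedSequence(protocol.seed)
    ss_folds, ss_rest = root.spawn(2)
    rng = np.random.default_rng(ss_folds)
    fold = _stratified_folds(lib, protocol.k_folds, rng)
    # per cutoff: class -> list of per-fold means
    acc: dict[float, dict[str, list[float]]] = {
        pct: {lbl: [] for lbl in classes} for pct in protocol.cutoffs
    }
    fold_seeds = ss_rest.spawn(protocol.k_folds)
    for f in range(protocol.k_folds):
        ss_train, ss_query = fold_seeds[f].spawn(2)
        test_lib = lib.subset(np.flatnonzero(fold == f))
        train_lib = lib.subset(np.flatnonzero(fold != f))
        seed_int = int(ss_train.generate_state(1)[0] % (2**31))
        scorer = scorer_factory(seed_int)
        if scorer.needs_training:
            spec = train_spec if train_spec is not None else TrainSpec()
            pairs = generate_pairs(
                train_lib, protocol.n_train_pairs,
                pos_fraction=protocol.pos_fraction, seed=seed_int,
            )
            scorer.fit(pairs, spec)
        qrng = np.random.default_rng(ss_query)
        for lbl in classes:
            members = np.flatnonzero(test_lib.labels == lbl)
            if members.size < 2:
                continue  # cannot rank same-class actives
            n_q = min(protocol.queries_per_class, members.size)
            queries = qrng.choice(members, size=n_q, replace=False)
            per_pct = {pct: [] for pct in protocol.cutoffs}
            for qi in queries:
                ranked = rank_database(scorer, test_lib.fingerprint(qi),
                                       test_lib)
                for pct in protocol.cutoffs:
                    per_pct[pct].append(recall_at(ranked, pct))
            for pct in protocol.cutoffs:
                acc[pct][lbl].append(float(np.mean(per_pct[pct])))
    out = {}
    for pct in protocol.cutoffs:
        col = {
            lbl: float(np.mean(vals)) for lbl, vals in acc[pct].items() if vals
        }
        out[pct] = RecallTable(pd.DataFrame({method_name: col}))
    return out


# -- bundled published recall tables --------------------------------------

#: Names of the bundled published recall tables: four benchmark
#: collections at the two ranking cutoffs.
PUBLISHED_TABLES = (
    "mddr_ds1_top1", "mddr_ds1_top5",
    "mddr_ds2_top1", "mddr_ds2_top5",
    "mddr_ds3_top1", "mddr_ds3_top5",
    "muv_top1", "muv_top5",
)


def load_published_table(name: str) -> RecallTable:
    """Load one of the bundled published recall tables."""
    if name not in PUBLISHED_TABLES:
        raise KeyError(
            f"unknown table {name!r}; choose from {PUBLISHED_TABLES}"
        )
    ref = resources.files("siamvs").joinpath(f"data/published/{name}.tsv")
    with resources.as_file(ref) as path:
        return RecallTable.read(path)
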