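"""Count-fingerprint data model and I/O.

A screening library is a table of molecules, each represented by a
fixed-length vector of nonnegative integer substructure counts (an
ECFC-style *count fingerprint*) plus an activity-class label.  Inactive
background molecules carry the reserved label ``"INACTIVE"``; they take
part in screening but are never used as queries.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "INACTIVE_LABEL",
    "DEFAULT_LENGTH",
    "CountFingerprint",
    "ActivityClassInfo",
    "ScreeningLibrary",
    "read_library",
    "write_library",
    "fold_counts",
    "class_mean_pairwise_similarity",
]

#: Reserved class label for background (inactive) molecules.
INACTIVE_LABEL = "INACTIVE"

#: Default folded fingerprint length; matches the width of the dense
#: branch of the Siamese multi-layer-perceptron scorer.
DEFAULT_LENGTH = 1024


class LibraryFormatError(ValueError):
    """Raised for malformed library files."""


@dataclass(frozen=True)
class CountFingerprint:
    """A single molecule's folded count fingerprint."""

    molecule_id: str
    values: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.int64)
        if values.ndim != 1:
            raise ValueError("fingerprint values must be a 1-D vector")
        if (values < 0).any():
            raise ValueError(
                f"fingerprint {self.molecule_id!r} has negative counts"
            )
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ActivityClassInfo:
    """Summary statistics for one activity class."""

    class_index: str
    n_active: int
    mean_pairwise_similarity: float | None = None

    def __post_init__(self):
        if self.mean_pairwise_similarity is not None:
            if self.n_active < 2:
                raise ValueError(
                    "mean pairwise similarity is undefined for classes "
                    "with fewer than 2 members"
                )
            if not 0.0 <= self.mean_pairwise_similarity <= 1.0:
                raise ValueError("mean pairwise similarity must lie in [0, 1]")


@dataclass
class ScreeningLibrary:
    """Fingerprint matrix plus activity labels and a class registry.

    Parameters
    ----------
    fingerprints
        ``(N, L)`` matrix of nonnegative integer counts, one row per
        molecule, in library order.
    labels
        Length-``N`` sequence of class labels; inactives use
        :data:`INACTIVE_LABEL`.
    molecule_ids
        Length-``N`` unique molecule identifiers.
    classes
        Optional registry of :class:`ActivityClassInfo`; filled in from
        the labels when omitted.
    """

    fingerprints: np.ndarray
    labels: np.ndarray
    molecule_ids: np.ndarray
    classes: list[ActivityClassInfo] = field(default_factory=list)

    def __post_init__(self):
        self.fingerprints = np.asarray(self.fingerprints, dtype=np.int64)
        if self.fingerprints.ndim != 2:
            raise ValueError("fingerprints must be an (N, L) matrix")
        if self.fingerprints.shape[0] == 0:
            raise ValueError("no molecules: a library must be nonempty")
        if (self.fingerprints < 0).any():
            raise ValueError("negative count in fingerprint matrix")
        self.labels = np.asarray(self.labels, dtype=object)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=object)
        n = self.fingerprints.shape[0]
        if len(self.labels) != n or len(self.molecule_ids) != n:
            raise ValueError("labels/ids length does not match matrix rows")
        if len(set(self.molecule_ids)) != n:
            raise ValueError("molecule ids must be unique")
        if not self.classes:
            self.classes = [
                ActivityClassInfo(str(lbl), int((self.labels == lbl).sum()))
                for lbl in self.class_labels()
            ]
        registered = {c.class_index for c in self.classes}
        missing = set(self.class_labels()) - registered
        if missing:
            raise ValueError(f"labels not in class registry: {sorted(missing)}")

    # -- basic accessors -------------------------------------------------

    @property
    def n_molecules(self) -> int:
        return self.fingerprints.shape[0]

    @property
    def length(self) -> int:
        return self.fingerprints.shape[1]

    def class_labels(self) -> list[str]:
        """Distinct activity-class labels, excluding the inactive token."""
        seen: dict[str, None] = {}
        for lbl in self.labels:
            if lbl != INACTIVE_LABEL:
                seen.setdefault(str(lbl), None)
        return list(seen)

    def class_members(self, class_label: str) -> np.ndarray:
        """Row indices of the members of ``class_label``."""
        idx = np.flatnonzero(self.labels == class_label)
        if idx.size == 0:
            raise KeyError(f"unknown activity class {class_label!r}")
        return idx

    def fingerprint(self, i: int) -> CountFingerprint:
        return CountFingerprint(str(self.molecule_ids[i]), self.fingerprints[i])

    def subset(self, indices: np.ndarray) -> "ScreeningLibrary":
        """A new library restricted to the given row indices (order kept)."""
        indices = np.asarray(indices, dtype=np.intp)
        return ScreeningLibrary(
            self.fingerprints[indices],
            self.labels[indices],
            self.molecule_ids[indices],
        )


# -- delimited-text I/O ---------------------------------------------------


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_library(path, length: int | None = None) -> ScreeningLibrary:
    """Read a screening library from a delimited text file.

    Rows are ``molecule_id, class_label, v1..vL`` with a mandatory
    header; comma and tab separators are auto-detected.  ``length``
    optionally asserts the expected fingerprint length.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        text = fh.read()
    buf = io.StringIO(text)
    first = buf.readline()
    if not first.strip():
        raise LibraryFormatError("no molecules: empty file")
    delim = _sniff_delimiter(first)
    reader = csv.reader(buf, delimiter=delim)
    ids, labels, rows = [], [], []
    ncols = None
    for lineno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) < 3:
            raise LibraryFormatError(
                f"row {lineno}: expected id, label and counts, got {len(row)} fields"
            )
        if ncols is None:
            ncols = len(row)
        elif len(row) != ncols:
            raise LibraryFormatError(
                f"row {lineno}: inconsistent length ({len(row)} != {ncols})"
            )
        ids.append(row[0])
        labels.append(row[1])
        try:
            counts = [int(v) for v in row[2:]]
        except ValueError as exc:
            raise LibraryFormatError(f"row {lineno}: non-integer count ({exc})")
        if any(v < 0 for v in counts):
            raise LibraryFormatError(f"row {lineno}: negative count")
        rows.append(counts)
    if not rows:
        raise LibraryFormatError("no molecules: header-only file")
    matrix = np.asarray(rows, dtype=np.int64)
    if length is not None and matrix.shape[1] != length:
        raise LibraryFormatError(
            f"fingerprint length {matrix.shape[1]} != declared {length}"
        )
    return ScreeningLibrary(matrix, np.asarray(labels, dtype=object),
                            np.asarray(ids, dtype=object))


def write_library(lib: ScreeningLibrary, path, delimiter: str = "\t") -> None:
    """Write a library so that :func:`read_library` reproduces it exactly."""
    if lib.n_molecules == 0:
        raise ValueError("refusing to write an empty library")
    header = ["molecule_id", "class_label"] + [
        f"v{j + 1}" for j in range(lib.length)
    ]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(header)
        for i in range(lib.n_molecules):
            writer.writerow(
                [str(lib.molecule_ids[i]), str(lib.labels[i])]
                + [int(v) for v in lib.fingerprints[i]]
            )


# -- folding and class statistics -----------------------------------------


def fold_counts(raw: dict[int, int], length: int = DEFAULT_LENGTH) -> np.ndarray:
    """Fold a sparse ``{feature_hash: count}`` map onto ``length`` bins.

    Position ``j`` accumulates every count whose hash satisfies
    ``h % length == j``; the total count is conserved, so hash
    collisions sum rather than overwrite.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    out = np.zeros(length, dtype=np.int64)
    for h, c in raw.items():
        if c < 0:
            raise ValueError(f"negative count for feature hash {h}")
        out[int(h) % length] += int(c)
    return out


def class_mean_pairwise_similarity(lib: ScreeningLibrary, class_label: str) -> float:
    """Mean continuous-Tanimoto similarity over all unordered member pairs.

    This is the within-class homogeneity statistic used to profile the
    benchmark collections: near 0.3 for structurally homogeneous
    classes, near 0.1 for heterogeneous ones.
    """
    idx = lib.class_members(class_label)
    if idx.size < 2:
        raise ValueError(
            f"class {class_label!r} has {idx.size} member(s); need >= 2"
        )
    X = lib.fingerprints[idx].astype(np.float64)
    # Pairwise continuous Tanimoto via the Gram matrix:
    # s_ij = <xi, xj> / (|xi|^2 + |xj|^2 - <xi, xj>)
    G = X @ X.T
    sq = np.diag(G)
    denom = sq[:, None] + sq[None, :] - G
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(denom > 0, G / denom, 0.0)
    iu = np.triu_indices(idx.size, k=1)
    return float(S[iu].mean())
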