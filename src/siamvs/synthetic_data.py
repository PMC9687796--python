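"""Synthetic screening libraries with controllable class structure.

Licensed/external benchmark collections are emulated, not reproduced:
a library is characterised only by its activity-class sizes and their
mean pairwise continuous-Tanimoto similarity, the two statistics the
benchmark profiles publish.  Each class is built from a template count
fingerprint; members copy a calibrated fraction of template positions
and redraw the rest from the sparse background distribution, which
moves the realised within-class similarity onto the requested target.
Inactive background molecules are drawn wholly from the background and
therefore share no template with any class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .fingerprint_data import (
    DEFAULT_LENGTH,
    INACTIVE_LABEL,
    ActivityClassInfo,
    ScreeningLibrary,
    class_mean_pairwise_similarity,
)

__all__ = [
    "ClassSpec",
    "GeneratorConfig",
    "PairBatch",
    "CalibrationError",
    "generate_library",
    "generate_pairs",
    "load_profile",
    "profile_to_config",
]


class CalibrationError(RuntimeError):
    """Raised when no copy-fraction realises the requested similarity."""


@dataclass(frozen=True)
class ClassSpec:
    """Target shape of one synthetic activity class."""

    label: str
    n_active: int
    target_similarity: float

    def __post_init__(self):
        if self.n_active < 2:
            raise ValueError("a class needs at least 2 members")
        if not 0.0 < self.target_similarity <= 1.0:
            raise ValueError("target similarity must lie in (0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full recipe for one synthetic screening library.

    ``density`` is the expected fraction of nonzero fingerprint
    positions and ``count_scale`` the mean nonzero count; the defaults
    (0.05, 2.0) give the sparse low-count vectors typical of
    extended-connectivity count fingerprints folded to 1024 bins.
    """

    class_specs: tuple[ClassSpec, ...]
    n_inactive: int = 0
    length: int = DEFAULT_LENGTH
    count_scale: float = 2.0
    density: float = 0.05
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "class_specs", tuple(self.class_specs))
        if not self.class_specs:
            raise ValueError("need at least one class spec")
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must lie in (0, 1)")
        if self.count_scale < 1.0:
            raise ValueError("count_scale must be >= 1")
        if self.n_inactive < 0:
            raise ValueError("n_inactive must be >= 0")


@dataclass(frozen=True)
class PairBatch:
    """Aligned fingerprint pairs with same-activity-class labels."""

    a: np.ndarray
    b: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        if not (self.a.shape == self.b.shape and len(self.labels) == len(self.a)):
            raise ValueError("misaligned pair batch")

    def __len__(self) -> int:
        return len(self.labels)


# -- generative model ------------------------------------------------------


def _background(rng: np.random.Generator, n: int, cfg: GeneratorConfig) -> np.ndarray:
    """Draw ``n`` background fingerprints: Bernoulli support, shifted-Poisson counts."""
    support = rng.random((n, cfg.length)) < cfg.density
    counts = 1 + rng.poisson(cfg.count_scale - 1.0, size=(n, cfg.length))
    return np.where(support, counts, 0).astype(np.int64)


def _ensure_nonzero(rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A valid fingerprint needs one nonzero entry; patch all-zero draws."""
    empty = ~(rows != 0).any(axis=1)
    for i in np.flatnonzero(empty):
        rows[i, rng.integers(rows.shape[1])] = 1
    return rows


def _members(rng, template: np.ndarray, n: int, rho: float,
             cfg: GeneratorConfig) -> np.ndarray:
    """Draw ``n`` class members copying a ``rho`` fraction of the template."""
    keep = rng.random((n, cfg.length)) < rho
    fresh = _background(rng, n, cfg)
    rows = np.where(keep, template[None, :], fresh)
    return _ensure_nonzero(rows, rng)


def _mean_pairwise_tanimoto(X: np.ndarray) -> float:
    X = X.astype(np.float64)
    G = X @ X.T
    sq = np.diag(G)
    denom = sq[:, None] + sq[None, :] - G
    S = np.where(denom > 0, G / np.where(denom > 0, denom, 1.0), 0.0)
    iu = np.triu_indices(len(X), k=1)
    return float(S[iu].mean())


def _calibrate_rho(template: np.ndarray, spec: ClassSpec, cfg: GeneratorConfig,
                   seed_seq: np.random.SeedSequence,
                   tol: float = 0.03, n_pilot: int = 20,
                   max_iter: int = 30) -> float:
    """Bisect the template copy-fraction against measured pilot similarity."""

    def realized(rho: float) -> float:
        rng = np.random.default_rng(seed_seq)  # same pilot stream every probe
        return _mean_pairwise_tanimoto(_members(rng, template, n_pilot, rho, cfg))

    lo, hi = 0.0, 1.0
    f_lo, f_hi = realized(lo), realized(hi)
    target = spec.target_similarity
    if target < f_lo - tol:
        raise CalibrationError(
            f"class {spec.label!r}: target similarity {target:.3f} is below "
            f"the background level {f_lo:.3f}; lower density or raise the target"
        )
    if target > f_hi + tol:
        raise CalibrationError(
            f"class {spec.label!r}: target similarity {target:.3f} exceeds the "
            f"maximum {f_hi:.3f} attainable by template copying"
        )
    rho = 0.5
    for _ in range(max_iter):
        rho = 0.5 * (lo + hi)
        f = realized(rho)
        if abs(f - target) <= tol:
            return rho
        if f < target:
            lo = rho
        else:
            hi = rho
    raise CalibrationError(
        f"class {spec.label!r}: copy-fraction bisection did not reach the "
        f"target {target:.3f} within +/-{tol}"
    )


def generate_library(cfg: GeneratorConfig) -> ScreeningLibrary:
    """Generate a screening library matching the configured class profile.

    Deterministic under ``cfg.seed``.  The returned library's class
    registry records the *realised* mean pairwise similarity of each
    generated class.
    """
    root = np.random.SeedSequence(cfg.seed)
    ss_classes = root.spawn(len(cfg.class_specs))
    rows, labels, ids = [], [], []
    infos = []
    for spec, ss in zip(cfg.class_specs, ss_classes):
        ss_template, ss_pilot, ss_draw = ss.spawn(3)
        t_rng = np.random.default_rng(ss_template)
        template = _ensure_nonzero(_background(t_rng, 1, cfg), t_rng)[0]
        rho = _calibrate_rho(template, spec, cfg, ss_pilot)
        draw_rng = np.random.default_rng(ss_draw)
        members = _members(draw_rng, template, spec.n_active, rho, cfg)
        rows.append(members)
        labels.extend([spec.label] * spec.n_active)
        ids.extend(f"{spec.label}_{k:05d}" for k in range(spec.n_active))
        infos.append(spec)
    if cfg.n_inactive:
        bg_rng = np.random.default_rng(root.spawn(1)[0])
        bg = _ensure_nonzero(_background(bg_rng, cfg.n_inactive, cfg), bg_rng)
        rows.append(bg)
        labels.extend([INACTIVE_LABEL] * cfg.n_inactive)
        ids.extend(f"BG_{k:05d}" for k in range(cfg.n_inactive))
    lib = ScreeningLibrary(
        np.vstack(rows),
        np.asarray(labels, dtype=object),
        np.asarray(ids, dtype=object),
    )
    lib.classes = [
        ActivityClassInfo(
            spec.label,
            spec.n_active,
            round(class_mean_pairwise_similarity(lib, spec.label), 6),
        )
        for spec in infos
    ]
    return lib


# -- pair sampling ---------------------------------------------------------


def generate_pairs(lib: ScreeningLibrary, n_pairs: int,
                   pos_fraction: float = 0.5, seed: int = 0) -> PairBatch:
    """Sample supervised fingerprint pairs from a library.

    Label 1 marks two molecules sharing an activity class (inactives
    never share one), label 0 anything else; the positive fraction is
    ``pos_fraction`` up to rounding and no molecule is paired with
    itself.  Deterministic under ``seed``.
    """
    if not 0.0 < pos_fraction < 1.0:
        raise ValueError("pos_fraction must lie strictly between 0 and 1")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    eligible = [
        lbl for lbl in lib.class_labels() if lib.class_members(lbl).size >= 2
    ]
    if len(eligible) < 2:
        raise ValueError("need >= 2 activity classes with >= 2 members each")
    rng = np.random.default_rng(seed)
    n_pos = int(round(n_pairs * pos_fraction))
    n_neg = n_pairs - n_pos
    ia, ib, lab = [], [], []
    for _ in range(n_pos):
        lbl = eligible[rng.integers(len(eligible))]
        members = lib.class_members(lbl)
        i, j = rng.choice(members, size=2, replace=False)
        ia.append(i)
        ib.append(j)
        lab.append(1)
    n = lib.n_molecules
    drawn = 0
    while drawn < n_neg:
        i, j = rng.integers(n, size=2)
        if i == j:
            continue
        same_activity = (
            lib.labels[i] == lib.labels[j] and lib.labels[i] != INACTIVE_LABEL
        )
        if same_activity:
            continue
        ia.append(i)
        ib.append(j)
        lab.append(0)
        drawn += 1
    order = rng.permutation(n_pairs)
    ia = np.asarray(ia)[order]
    ib = np.asarray(ib)[order]
    lab = np.asarray(lab, dtype=np.int8)[order]
    return PairBatch(lib.fingerprints[ia], lib.fingerprints[ib], lab)


# -- bundled benchmark profiles -------------------------------------------

_PROFILES = {"mddr_ds1", "mddr_ds2", "mddr_ds3", "muv"}


def load_profile(name: str) -> pd.DataFrame:
    """Load a bundled benchmark profile (class sizes and similarities)."""
    if name not in _PROFILES:
        raise KeyError(f"unknown profile {name!r}; choose from {sorted(_PROFILES)}")
    ref = resources.files("siamvs").joinpath(f"data/profiles/{name}.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"class": str})


def profile_to_config(name: str, scale: float = 1.0, n_inactive: int = 0,
                      length: int = DEFAULT_LENGTH, seed: int = 0,
                      **kwargs) -> GeneratorConfig:
    """Build a generator config from a bundled profile.

    ``scale`` shrinks every class size (floored at 2 members) so the
    statistical shape of a benchmark collection can be emulated at a
    fraction of its size.
    """
    prof = load_profile(name)
    specs = tuple(
        ClassSpec(str(r["class"]), max(2, int(round(r["n_active"] * scale))),
                  float(r["pairwise_similarity"]))
        for _, r in prof.iterrows()
    )
    return GeneratorConfig(specs, n_inactive=n_inactive, length=length,
                           seed=seed, **kwargs)
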