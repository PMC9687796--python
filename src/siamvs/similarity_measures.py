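"""Similarity measures used inside and alongside the Siamese scorers.

Four measures enter the enhanced Siamese architectures — the
elementwise absolute difference of the twin feature vectors, the
exponential Manhattan similarity, the continuous Jaccard coefficient
and the Russel coefficient — and the continuous Tanimoto coefficient
(the same formula as continuous Jaccard, applied to raw count
fingerprints) serves as the classical screening baseline.

All functions are pure, symmetric in their two arguments, and accept
1-D vectors or ``(batch, F)`` matrices (batched over rows).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "abs_difference",
    "exp_manhattan",
    "jaccard_continuous",
    "russel",
    "tanimoto_score",
]


def _pair(fa, fb):
    fa = np.asarray(fa, dtype=np.float64)
    fb = np.asarray(fb, dtype=np.float64)
    if fa.shape != fb.shape:
        raise ValueError(f"length mismatch: {fa.shape} vs {fb.shape}")
    return fa, fb


def abs_difference(fa, fb) -> np.ndarray:
    """Elementwise ``|fa - fb|`` — the vector-valued measure.

    Zero exactly where the two feature vectors agree, so the zero
    vector identifies identical inputs.
    """
    fa, fb = _pair(fa, fb)
    return np.abs(fa - fb)


def exp_manhattan(fa, fb):
    """Exponential Manhattan similarity ``exp(-sum |fa - fb|)`` in (0, 1].

    Equals 1 iff the vectors coincide and decays toward 0 as they move
    apart in L1 distance.
    """
    fa, fb = _pair(fa, fb)
    d = np.abs(fa - fb).sum(axis=-1)
    out = np.exp(-d)
    return float(out) if out.ndim == 0 else out


def jaccard_continuous(fa, fb):
    """Continuous Jaccard coefficient on real vectors.

    ``sum(a*b) / (sum(a^2) + sum(b^2) - sum(a*b))``; 1 iff the vectors
    are equal and nonzero, and within [0, 1] for nonnegative inputs.
    Undefined (raises) when both vectors are zero.
    """
    fa, fb = _pair(fa, fb)
    num = (fa * fb).sum(axis=-1)
    denom = (fa * fa).sum(axis=-1) + (fb * fb).sum(axis=-1) - num
    # denom == 0 iff both vectors are zero (Cauchy-Schwarz).
    if np.any(denom == 0):
        raise ValueError("Jaccard is undefined for a pair of zero vectors")
    out = num / denom
    return float(out) if out.ndim == 0 else out


def russel(fa, fb):
    """Russel coefficient ``sum(a*b) / n`` on real vectors.

    A binary-heritage association coefficient applied to continuous
    features: the raw product sum normalised by the vector length, zero
    whenever supports are disjoint.
    """
    fa, fb = _pair(fa, fb)
    n = fa.shape[-1]
    if n == 0:
        raise ValueError("Russel is undefined for empty vectors")
    out = (fa * fb).sum(axis=-1) / n
    return float(out) if out.ndim == 0 else out


def tanimoto_score(a, b):
    """Continuous Tanimoto similarity of two raw count fingerprints.

    Identical in form to :func:`jaccard_continuous`; this is the TAN
    baseline scorer of ligand-based virtual screening.
    """
    return jaccard_continuous(a, b)
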