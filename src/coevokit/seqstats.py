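"""Weighted frequency estimation and positional conservation.

Single-site frequencies ``f_i(A)`` and joint frequencies ``f_ij(A, B)`` are
weighted empirical counts, optionally smoothed with a pseudocount mixed
against the uniform distribution. Positional conservation is the binary
Kullback-Leibler relative entropy of the observed frequency of a residue
against a background probability:

    D_i(A) = f ln(f / p) + (1 - f) ln((1 - f) / (1 - p)),   f = f_i(A), p = p(A)

with the convention 0 ln 0 = 0. ``D_i(A)`` is zero iff ``f = p`` and grows as
residue A at position i becomes more over- or under-represented relative to
background. The scalar per-position profile ``D_pos[i]`` is D evaluated at
the query sequence's own residue, and the threshold sigma selects conserved
positions for the filtered coupling energy downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa import MSA, SequenceWeights


class BackgroundDegeneracyError(ValueError):
    """A background probability of exactly 0 or 1 makes D_i undefined."""


@dataclass
class FrequencyModel:
    """Smoothed one- and two-site frequencies of an alignment."""

    f_i: np.ndarray  # (L, q)
    f_ij: np.ndarray  # (L, L, q, q); diagonal blocks hold f_ii(A,A)=f_i(A)
    pseudocount: float
    background: np.ndarray  # (q,)
    query: np.ndarray  # encoded query sequence, length L

    @property
    def length(self) -> int:
        return self.f_i.shape[0]

    @property
    def q(self) -> int:
        return self.f_i.shape[1]


def compute_frequencies(
    msa: MSA,
    weights: SequenceWeights | None = None,
    pseudocount: float = 0.5,
) -> FrequencyModel:
    """Weighted, pseudocount-smoothed frequencies.

    Raw weighted counts are normalised by Neff, then mixed with the uniform
    distribution: ``f <- (1 - c) f_raw + c / q`` with ``c = lam / (lam + Neff)``,
    applied consistently to single-site and joint frequencies (the joint gets
    ``c / q^2`` so that smoothed marginals stay coherent in the lam -> 0 limit).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    q = msa.alphabet.q
    n, length = msa.matrix.shape
    w = np.ones(n) if weights is None else np.asarray(weights.w, dtype=float)
    neff = w.sum()
    # one-hot encode once: (N, L, q)
    onehot = np.zeros((n, length, q))
    rows = np.arange(n)[:, None]
    cols = np.arange(length)[None, :]
    onehot[rows, cols, msa.matrix] = 1.0
    f_i = np.einsum("k,kia->ia", w, onehot) / neff
    f_ij = np.einsum("k,kia,kjb->ijab", w, onehot, onehot) / neff
    c = pseudocount / (pseudocount + neff)
    f_i = (1.0 - c) * f_i + c / q
    f_ij = (1.0 - c) * f_ij + c / q**2
    # default background carried on the model: the alignment-wide mean
    # composition (self-contained; no external residue table needed)
    return FrequencyModel(f_i, f_ij, pseudocount, f_i.mean(axis=0),
                          msa.query.copy())


def background_distribution(
    msa: MSA,
    mode: str = "msa_mean",
    weights: SequenceWeights | None = None,
    user: np.ndarray | None = None,
    pseudocount: float = 0.5,
) -> np.ndarray:
    """Background probability vector p(A) used by the relative entropy.

    ``msa_mean`` averages the (weighted, smoothed) single-site frequencies
    over positions, ``uniform`` returns 1/q, ``user`` validates and returns a
    caller-supplied vector.
    """
    q = msa.alphabet.q
    if mode == "uniform":
        return np.full(q, 1.0 / q)
    if mode == "user":
        if user is None:
            raise ValueError("mode='user' requires a probability vector")
        p = np.asarray(user, dtype=float)
        if p.shape != (q,) or abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
            raise ValueError("user background must be a length-q probability vector")
        return p
    if mode == "msa_mean":
        freq = compute_frequencies(msa, weights, pseudocount)
        return freq.f_i.mean(axis=0)
    raise ValueError(f"unknown background mode {mode!r}")


@dataclass
class EntropyProfile:
    """Per-position relative-entropy conservation profile."""

    D: np.ndarray  # (L, q) relative entropies D_i(A)
    D_pos: np.ndarray  # (L,) D at the query's own residue
    background: np.ndarray  # the p(A) used
    query: np.ndarray
    sigma: float | None = None  # conservation threshold, set downstream

    @property
    def length(self) -> int:
        return self.D.shape[0]


def _binary_kl(f: np.ndarray, p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(f > 0, f * np.log(f / p), 0.0)
        t2 = np.where(f < 1, (1 - f) * np.log((1 - f) / (1 - p)), 0.0)
    return t1 + t2


def relative_entropy(
    freq: FrequencyModel,
    background: np.ndarray | None = None,
    aggregate: str = "query",
) -> EntropyProfile:
    """Binary KL conservation of every residue at every position.

    ``aggregate`` controls the scalar per-position profile: ``query`` (the
    default) evaluates D at the query's residue; ``max`` and ``sum`` take the
    maximum / sum over the 20 canonical residues.
    """
    p = freq.background if background is None else np.asarray(background, float)
    if ((p <= 0) | (p >= 1)).any():
        raise BackgroundDegeneracyError(
            "background probabilities must lie strictly inside (0, 1)"
        )
    D = _binary_kl(freq.f_i, p[None, :])
    if aggregate == "query":
        d_pos = D[np.arange(freq.length), freq.query]
    elif aggregate == "max":
        d_pos = D[:, :-1].max(axis=1)  # canonical residues only, no gap
    elif aggregate == "sum":
        d_pos = D[:, :-1].sum(axis=1)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return EntropyProfile(D, d_pos, p, freq.query.copy())


def conservation_threshold(
    profile: EntropyProfile, rule: str = "percentile", value: float = 50.0
) -> float:
    """Set and return the conservation threshold sigma on a profile."""
    if profile.D_pos.size == 0:
        raise ValueError("empty conservation profile")
    if rule == "percentile":
        if not 0.0 <= value <= 100.0:
            raise ValueError("percentile must be in [0, 100]")
        sigma = float(np.percentile(profile.D_pos, value))
    elif rule == "absolute":
        sigma = float(value)
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    profile.sigma = sigma
    return sigma
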