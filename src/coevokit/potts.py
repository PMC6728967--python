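"""Maximum-entropy Potts model of an alignment.

The model assigns every length-L sequence the probability

    P(A_1..A_L) = (1/Z) exp( sum_{i<j} e_ij(A_i, A_j) + sum_i h_i(A_i) )

with site biases ``h_i`` and pairwise couplings ``e_ij`` chosen so that the
model's one- and two-site marginals agree with the (reweighted) alignment
frequencies. Fitting goes through regularised maximum pseudolikelihood: each
site's conditional distribution given the rest of the sequence is a
multinomial logistic regression, which sidesteps the partition constant Z
entirely. The fitted couplings are symmetrised and shifted to the zero-sum
gauge.

Sequence scores follow the exponent's sign convention: HIGHER score = more
probable sequence. The positionally-conserved-coupling (PCC) energy is the
same sum restricted to positions whose conservation exceeds a threshold
sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.sparse

from .alphabet import DEFAULT, Alphabet
from .msa import MSA, SequenceWeights
from .seqstats import EntropyProfile


class OptimizationError(RuntimeError):
    """The pseudolikelihood objective became non-finite."""


@dataclass
class PottsModel:
    """Site biases and pairwise couplings with gauge metadata.

    ``e`` is stored as a full ``(L, L, q, q)`` array with the symmetry
    ``e[i, j] == e[j, i].T`` and zero diagonal blocks. Z is never computed;
    every downstream quantity is a score difference or a conditional.
    """

    h: np.ndarray  # (L, q)
    e: np.ndarray  # (L, L, q, q)
    gauge: str = "zero_sum"
    reg_h: float = 0.0
    reg_e: float = 0.0
    converged: bool = True
    alphabet: Alphabet = field(default_factory=lambda: DEFAULT)

    @property
    def length(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=np.float64)
        self.e = np.asarray(self.e, dtype=np.float64)
        L, q = self.h.shape
        if self.e.shape != (L, L, q, q):
            raise ValueError("coupling tensor shape does not match h")
        if not np.isfinite(self.h).all() or not np.isfinite(self.e).all():
            raise ValueError("model parameters must be finite")


def zero_sum_gauge(h: np.ndarray, e: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shift parameters to the zero-sum (Ising) gauge.

    Score differences between sequences are unchanged; only the additive
    constant absorbed into log Z moves.
    """
    mean_b = e.mean(axis=3, keepdims=True)      # (L,L,q,1)
    mean_a = e.mean(axis=2, keepdims=True)      # (L,L,1,q)
    mean_ab = e.mean(axis=(2, 3), keepdims=True)
    e_new = e - mean_a - mean_b + mean_ab
    # fields absorb the row means of every coupling block touching site i
    shift = (mean_b - mean_ab)[:, :, :, 0]      # (L, L, q)
    h_new = h + shift.sum(axis=1)
    h_new = h_new - h_new.mean(axis=1, keepdims=True)
    L = h.shape[0]
    e_new[np.arange(L), np.arange(L)] = 0.0
    return h_new, e_new


def _site_onehot(matrix: np.ndarray, q: int) -> scipy.sparse.csr_matrix:
    n, length = matrix.shape
    cols = (np.arange(length)[None, :] * q + matrix).ravel()
    rows = np.repeat(np.arange(n), length)
    data = np.ones(n * length)
    return scipy.sparse.csr_matrix(
        (data, (rows, cols)), shape=(n, length * q)
    )


def fit_plm(
    msa: MSA,
    weights: SequenceWeights | None = None,
    reg_h: float = 0.01,
    reg_e: float = 0.05,
    max_iter: int = 500,
    gtol: float = 1e-5,
) -> PottsModel:
    """Fit the Potts model by asymmetric pseudolikelihood.

    Each site is a ridge-regularised multinomial logistic regression of its
    residue on all other columns (L-BFGS with analytic gradients); the
    resulting directed couplings are symmetrised ``e_ij <- (e_ij + e_ji^T)/2``
    and the model is shifted to the zero-sum gauge. Deterministic given
    identical inputs and settings.
    """
    if reg_h <= 0 or reg_e <= 0:
        raise ValueError("regularisation strengths must be positive")
    q = msa.alphabet.q
    n, length = msa.matrix.shape
    w = np.ones(n) if weights is None else np.asarray(weights.w, dtype=float)
    neff = w.sum()
    if neff <= q:
        import warnings

        warnings.warn(
            f"effective sequence count {neff:.1f} <= q={q}; "
            "couplings will be dominated by the regulariser",
            stacklevel=2,
        )
    onehot = _site_onehot(msa.matrix, q)
    wn = w / neff
    h_all = np.zeros((length, q))
    J_all = np.zeros((length, length, q, q))  # J_all[i, j, a, b]: directed
    converged = True

    for i in range(length):
        yi = msa.matrix[:, i].astype(np.int64)
        blk = slice(i * q, (i + 1) * q)

        def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
            hi = x[:q]
            Ji = x[q:].reshape(length * q, q).copy()
            Ji[blk] = 0.0  # no self-coupling
            logits = onehot @ Ji + hi[None, :]
            logits -= logits.max(axis=1, keepdims=True)
            expl = np.exp(logits)
            norm = expl.sum(axis=1)
            p = expl / norm[:, None]
            nll = -np.dot(wn, logits[np.arange(n), yi] - np.log(norm))
            if not np.isfinite(nll):
                raise OptimizationError(
                    f"non-finite pseudolikelihood at site {i}"
                )
            resid = p * wn[:, None]
            resid[np.arange(n), yi] -= wn
            g_h = resid.sum(axis=0) + 2.0 * reg_h * hi
            g_J = (onehot.T @ resid) + 2.0 * reg_e * Ji
            g_J[blk] = 0.0
            loss = nll + reg_h * np.dot(hi, hi) + reg_e * np.dot(
                Ji.ravel(), Ji.ravel()
            )
            return loss, np.concatenate([g_h, g_J.ravel()])

        x0 = np.zeros(q + length * q * q)
        res = scipy.optimize.minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
        )
        converged &= bool(res.success)
        h_all[i] = res.x[:q]
        Ji = res.x[q:].reshape(length, q, q)
        Ji[i] = 0.0
        J_all[i] = Ji.transpose(0, 2, 1)  # store as e[i, j, a_i, a_j]

    # symmetrise the two directed estimates of every coupling block
    e = 0.5 * (J_all + J_all.transpose(1, 0, 3, 2))
    h, e = zero_sum_gauge(h_all, e)
    return PottsModel(
        h, e, gauge="zero_sum", reg_h=reg_h, reg_e=reg_e,
        converged=converged, alphabet=msa.alphabet,
    )


@dataclass
class SequenceEnergies:
    """Component scores of one sequence under a Potts model."""

    E_s: float  # site-bias energy sum_i h_i(tau_i)
    E_c: float  # coupling energy sum_{i<j} e_ij(tau_i, tau_j)
    E_pcc: float | None = None  # sigma-filtered energy, if computed
    alpha: float | None = None

    @property
    def E_total(self) -> float:
        """Weighted stability score E_s + alpha * E_c (alpha defaults to 1)."""
        a = 1.0 if self.alpha is None else self.alpha
        return self.E_s + a * self.E_c


def _check_seq(model: PottsModel, seq: np.ndarray) -> np.ndarray:
    seq = np.asarray(seq)
    if seq.shape != (model.length,):
        raise ValueError(
            f"sequence length {seq.shape} does not match model L={model.length}"
        )
    if seq.min() < 0 or seq.max() >= model.q:
        raise ValueError("sequence contains out-of-alphabet codes")
    return seq.astype(np.int64)


def potts_score(model: PottsModel, seq: np.ndarray) -> SequenceEnergies:
    """Site-bias and coupling scores; higher = more probable sequence."""
    s = _check_seq(model, seq)
    L = model.length
    e_s = float(model.h[np.arange(L), s].sum())
    iu, ju = np.triu_indices(L, k=1)
    e_c = float(model.e[iu, ju, s[iu], s[ju]].sum())
    return SequenceEnergies(E_s=e_s, E_c=e_c)


def pcc_energy(
    model: PottsModel,
    profile: EntropyProfile,
    seq: np.ndarray,
    sigma: float | None = None,
    pair_rule: str = "both",
) -> float:
    """Positionally-conserved-coupling energy.

    Field terms are summed only over positions with ``D_pos[i] > sigma``;
    coupling terms require conserved endpoints — both (default) or either,
    depending on ``pair_rule``.
    """
    s = _check_seq(model, seq)
    if profile.length != model.length:
        raise ValueError("conservation profile and model have different L")
    if sigma is None:
        if profile.sigma is None:
            raise ValueError("no sigma given and profile.sigma unset")
        sigma = profile.sigma
    keep = profile.D_pos > sigma
    L = model.length
    e_s = float(model.h[np.arange(L), s][keep].sum())
    iu, ju = np.triu_indices(L, k=1)
    if pair_rule == "both":
        pair_keep = keep[iu] & keep[ju]
    elif pair_rule == "either":
        pair_keep = keep[iu] | keep[ju]
    else:
        raise ValueError(f"unknown pair_rule {pair_rule!r}")
    e_c = float(model.e[iu[pair_keep], ju[pair_keep],
                        s[iu[pair_keep]], s[ju[pair_keep]]].sum())
    return e_s + e_c


@dataclass
class ContactScores:
    """Coupling-strength contact map with average-product correction."""

    raw: np.ndarray  # (L, L) Frobenius norms of non-gap coupling blocks
    apc: np.ndarray  # (L, L) APC-corrected scores
    min_separation: int = 5

    def top_pairs(self, k: int | None = None, corrected: bool = True
                  ) -> list[tuple[int, int, float]]:
        """Pairs ranked by score, excluding |i-j| < min_separation."""
        mat = self.apc if corrected else self.raw
        L = mat.shape[0]
        iu, ju = np.triu_indices(L, k=max(1, self.min_separation))
        order = np.argsort(mat[iu, ju])[::-1]
        pairs = [(int(iu[o]), int(ju[o]), float(mat[iu[o], ju[o]]))
                 for o in order]
        return pairs if k is None else pairs[:k]


def contact_scores(model: PottsModel, min_separation: int = 5) -> ContactScores:
    """Frobenius-norm coupling strengths with average-product correction.

    The gap state is excluded from the norms (its couplings reflect
    alignment coverage, not structure). APC removes the background
    row/column signal: ``apc_ij = raw_ij - mean_i * mean_j / mean_all``.
    """
    nres = model.q - 1  # drop the gap state
    blocks = model.e[:, :, :nres, :nres]
    raw = np.sqrt((blocks**2).sum(axis=(2, 3)))
    np.fill_diagonal(raw, 0.0)
    row_mean = raw.mean(axis=1)
    total = raw.mean()
    if total > 0:
        apc = raw - np.outer(row_mean, row_mean) / total
    else:
        apc = raw.copy()
    np.fill_diagonal(apc, 0.0)
    return ContactScores(raw=raw, apc=apc, min_separation=min_separation)


def save_model(model: PottsModel, path) -> None:
    """Serialise a model to a single .npz archive (versioned)."""
    np.savez_compressed(
        path,
        format_version=np.array(1),
        h=model.h,
        e=model.e,
        gauge=np.array(model.gauge),
        reg_h=np.array(model.reg_h),
        reg_e=np.array(model.reg_e),
        converged=np.array(model.converged),
        symbols=np.array(model.alphabet.symbols),
    )


def load_model(path) -> PottsModel:
    with np.load(path, allow_pickle=False) as npz:
        return PottsModel(
            h=npz["h"],
            e=npz["e"],
            gauge=str(npz["gauge"]),
            reg_h=float(npz["reg_h"]),
            reg_e=float(npz["reg_e"]),
            converged=bool(npz["converged"]),
            alphabet=Alphabet(symbols=str(npz["symbols"])),
        )


def contacts_to_tsv(scores: ContactScores, path, k: int | None = None) -> None:
    """Write ranked contacts as 3-column TSV (i, j, score; 1-based)."""
    import pandas as pd

    pairs = scores.top_pairs(k)
    pd.DataFrame(
        [(i + 1, j + 1, s) for i, j, s in pairs],
        columns=["i", "j", "score"],
    ).to_csv(path, sep="\t", index=False)


def sample_potts(
    model: PottsModel,
    n: int,
    burn_in: int | None = None,
    thin: int | None = None,
    seed: int = 0,
    n_chains: int | None = None,
) -> MSA:
    """Draw n sequences from the model by Gibbs sampling.

    Runs ``n_chains`` independent chains in parallel (default: one chain per
    requested sample, so every returned row is an independent draw after
    ``burn_in`` systematic sweeps). ``thin`` sweeps separate consecutive
    samples taken from the same chain when ``n_chains < n``. Deterministic
    given the seed; the first returned row is designated the query.
    """
    if n < 1:
        raise ValueError("need n >= 1 samples")
    L, q = model.length, model.q
    if burn_in is None:
        burn_in = 100 * L
    if thin is None:
        thin = L
    if n_chains is None:
        n_chains = n
    n_chains = min(n_chains, n)
    per_chain = -(-n // n_chains)  # ceil
    rng = np.random.default_rng(seed)
    X = rng.integers(0, q, size=(n_chains, L), dtype=np.int64)
    # e indexed as [i, j, a_i, a_j]; transpose once for row-gather updates
    e_t = np.ascontiguousarray(model.e.transpose(0, 1, 3, 2))  # [i,j,a_j,a_i]

    def sweep() -> None:
        for i in range(L):
            logits = np.broadcast_to(model.h[i], (n_chains, q)).copy()
            for j in range(L):
                if j != i:
                    logits += e_t[i, j][X[:, j]]
            # inverse-CDF categorical draw: one uniform per chain
            logits -= logits.max(axis=1, keepdims=True)
            np.exp(logits, out=logits)
            np.cumsum(logits, axis=1, out=logits)
            u = rng.random(n_chains) * logits[:, -1]
            X[:, i] = (logits < u[:, None]).sum(axis=1)

    for _ in range(burn_in):
        sweep()
    samples = [X.copy()]
    for _ in range(per_chain - 1):
        for _ in range(thin):
            sweep()
        samples.append(X.copy())
    matrix = np.concatenate(samples, axis=0)[:n].astype(np.int8)
    ids = [f"sample_{k}" for k in range(n)]
    return MSA(matrix, ids, query_index=0, alphabet=model.alphabet)
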