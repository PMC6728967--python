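"""Statistical-energy-guided sequence analysis and design.

All routines share one orientation: the Potts score is a log-probability up
to a constant, so design MAXIMISES it. A mutation with negative delta-score
is predicted deleterious, one with positive delta-score tolerated. The
stability score ``E = E_s + alpha * E_c`` weighs the coupling contribution
against the site-bias contribution; ``alpha`` is calibrated against measured
quantities (e.g. transition temperatures) by maximising the absolute Pearson
correlation over a grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .potts import PottsModel, potts_score
from .seqstats import EntropyProfile


class UndefinedCorrelationError(ValueError):
    """Correlation is undefined (constant inputs or too few rows)."""


# ---------------------------------------------------------------------------
# masked parameters: one machinery for full-Potts and sigma-filtered scoring


def _masked_params(
    model: PottsModel,
    profile: EntropyProfile | None,
    sigma: float | None,
    pair_rule: str = "both",
) -> tuple[np.ndarray, np.ndarray]:
    """Return (h', e') equal to the model's parameters with non-conserved
    positions zeroed out when a conservation filter is requested."""
    if profile is None or sigma is None:
        return model.h, model.e
    keep = profile.D_pos > sigma
    if pair_rule == "both":
        pair = np.outer(keep, keep)
    elif pair_rule == "either":
        pair = keep[:, None] | keep[None, :]
    else:
        raise ValueError(f"unknown pair_rule {pair_rule!r}")
    h = model.h * keep[:, None]
    e = model.e * pair[:, :, None, None]
    return h, e


def _coupling_field(e: np.ndarray, seq: np.ndarray) -> np.ndarray:
    """contrib[i, a] = sum_j e_ij(a, seq_j); the local field each position
    feels from the rest of the sequence (diagonal blocks are zero)."""
    L = e.shape[0]
    contrib = np.zeros((L, e.shape[2]))
    for j in range(L):
        contrib += e[:, j, :, seq[j]]
    return contrib


# ---------------------------------------------------------------------------
# point-mutation scan


@dataclass
class MutationScan:
    """Delta-scores of every single substitution of a sequence."""

    delta: np.ndarray  # (L, q); delta[i, A] = score(tau_i -> A) - score(tau)
    wild_type: np.ndarray
    scored_with: str = "full"  # "full" Potts score or "pcc" filtered score

    def to_frame(self, alphabet) -> pd.DataFrame:
        """L x q table with 1-based positions and residue-letter columns."""
        df = pd.DataFrame(self.delta, columns=list(alphabet.symbols))
        df.insert(0, "position", np.arange(1, self.delta.shape[0] + 1))
        df.insert(1, "wt", [alphabet.symbols[a] for a in self.wild_type])
        return df


def mutation_scan(
    model: PottsModel,
    seq: np.ndarray,
    profile: EntropyProfile | None = None,
    sigma: float | None = None,
    pair_rule: str = "both",
) -> MutationScan:
    """Incremental delta-score of every point mutation.

    Each entry is computed as a field difference plus coupling-field
    difference (never by full rescoring) but equals full rescoring exactly.
    """
    seq = np.asarray(seq, dtype=np.int64)
    if seq.shape != (model.length,):
        raise ValueError("sequence length does not match model")
    h, e = _masked_params(model, profile, sigma, pair_rule)
    contrib = _coupling_field(e, seq)
    local = h + contrib  # (L, q): score change landscape around seq
    L = model.length
    wt_local = local[np.arange(L), seq]
    delta = local - wt_local[:, None]
    delta[np.arange(L), seq] = 0.0  # exact zero for self-substitution
    return MutationScan(
        delta=delta,
        wild_type=seq.copy(),
        scored_with="full" if sigma is None or profile is None else "pcc",
    )


# ---------------------------------------------------------------------------
# stability table and alpha calibration


def stability_table(
    ids: list[str],
    E_s: np.ndarray,
    E_c: np.ndarray,
    measured: np.ndarray | None = None,
    family: list[str] | None = None,
    label: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-sequence energy table used by alpha calibration and
    thermostability classification."""
    df = pd.DataFrame({"id": ids, "E_s": np.asarray(E_s, float),
                       "E_c": np.asarray(E_c, float)})
    if measured is not None:
        df["measured"] = np.asarray(measured, float)
    if family is not None:
        df["family"] = family
    if label is not None:
        df["label"] = label
    return df


def optimize_alpha(
    table: pd.DataFrame,
    alpha_grid: np.ndarray | None = None,
) -> tuple[float, float]:
    """Grid-search the coupling weight alpha maximising |corr(E_total, measured)|.

    Returns ``(alpha_star, signed_correlation_at_alpha_star)``. Ties are
    broken toward smaller |alpha|.
    """
    if alpha_grid is None:
        alpha_grid = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 10)
    if "measured" not in table.columns:
        raise UndefinedCorrelationError("table has no measured values")
    sub = table.dropna(subset=["measured"])
    if len(sub) < 3:
        raise UndefinedCorrelationError("need at least 3 measured rows")
    es = sub["E_s"].to_numpy()
    ec = sub["E_c"].to_numpy()
    y = sub["measured"].to_numpy()
    if np.ptp(y) == 0:
        raise UndefinedCorrelationError("measured values are constant")
    if np.ptp(es) == 0 and np.ptp(ec) == 0:
        raise UndefinedCorrelationError("energies are constant")
    yc = y - y.mean()
    ynorm = np.sqrt((yc**2).sum())
    corrs = np.full(len(alpha_grid), np.nan)
    for idx, a in enumerate(alpha_grid):
        tot = es + a * ec
        tc = tot - tot.mean()
        denom = np.sqrt((tc**2).sum()) * ynorm
        if denom > 0:
            corrs[idx] = float(np.dot(tc, yc) / denom)
    if np.isnan(corrs).all():
        raise UndefinedCorrelationError("correlation undefined on entire grid")
    best = np.nanmax(np.abs(corrs))
    candidates = np.flatnonzero(np.abs(corrs) >= best - 1e-15)
    pick = candidates[np.abs(alpha_grid[candidates]).argmin()]
    return float(alpha_grid[pick]), float(corrs[pick])


def classify_thermostability(
    table: pd.DataFrame,
    alpha: float,
    expect: str = "thermophilic_higher",
) -> pd.DataFrame:
    """Per-family mesophilic-vs-thermophilic score comparison.

    For each family with both class labels, reports the mean E_total
    difference (mesophilic - thermophilic) and whether its sign matches the
    configured expectation. The returned frame carries the aggregate
    ``fraction_distinguished`` in ``df.attrs``.
    """
    if expect not in {"thermophilic_higher", "thermophilic_lower"}:
        raise ValueError(f"unknown expectation {expect!r}")
    required = {"family", "label", "E_s", "E_c"}
    if not required <= set(table.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    rows = []
    for fam, grp in table.groupby("family", sort=True):
        labels = set(grp["label"])
        if not {"mesophilic", "thermophilic"} <= labels:
            import warnings

            warnings.warn(f"family {fam!r} lacks both classes; skipped",
                          stacklevel=2)
            continue
        etot = grp["E_s"] + alpha * grp["E_c"]
        meso = etot[grp["label"] == "mesophilic"].mean()
        thermo = etot[grp["label"] == "thermophilic"].mean()
        diff = meso - thermo
        distinguished = diff < 0 if expect == "thermophilic_higher" else diff > 0
        rows.append({"family": fam, "delta_E": diff,
                     "distinguished": bool(distinguished)})
    report = pd.DataFrame(rows, columns=["family", "delta_E", "distinguished"])
    report.attrs["fraction_distinguished"] = (
        float(report["distinguished"].mean()) if len(report) else float("nan")
    )
    return report


# ---------------------------------------------------------------------------
# dead-end elimination


def dee_eliminate(
    model: PottsModel,
    allowed: list[list[int]] | None = None,
) -> list[list[int]]:
    """Goldstein singles dead-end elimination under score maximisation.

    Candidate A at position i is eliminated when some competitor B at i
    satisfies ``h_i(B) - h_i(A) + sum_j min_C [e_ij(B,C) - e_ij(A,C)] > 0``
    — i.e. B beats A no matter what the rest of the sequence does, so A can
    never be part of the global optimum. Iterates to a fixed point.
    """
    L, q = model.length, model.q
    if allowed is None:
        allowed = [list(range(q)) for _ in range(L)]
    allowed = [sorted(set(a)) for a in allowed]
    for i, cands in enumerate(allowed):
        if not cands:
            raise ValueError(f"empty candidate set at position {i}")
        if any(c < 0 or c >= q for c in cands):
            raise ValueError(f"out-of-alphabet candidate at position {i}")
    changed = True
    while changed:
        changed = False
        for i in range(L):
            cands = allowed[i]
            if len(cands) == 1:
                continue
            survivors = []
            for a in cands:
                dominated = False
                for b in cands:
                    if b == a:
                        continue
                    gap = model.h[i, b] - model.h[i, a]
                    for j in range(L):
                        if j == i:
                            continue
                        cj = allowed[j]
                        gap += (model.e[i, j, b, cj]
                                - model.e[i, j, a, cj]).min()
                    if gap > 0:
                        dominated = True
                        break
                if not dominated:
                    survivors.append(a)
            if not survivors:  # defensive; Goldstein cannot empty a position
                survivors = [max(cands, key=lambda a: model.h[i, a])]
            if len(survivors) < len(cands):
                allowed[i] = survivors
                changed = True
    return allowed


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo design


@dataclass
class DesignState:
    """One design trajectory's outcome (maximisation convention)."""

    seq: np.ndarray
    score: float
    best_seq: np.ndarray
    best_score: float
    fixed_positions: frozenset = frozenset()
    trajectory: list = field(default_factory=list)
    n_accepted: int = 0
    n_steps: int = 0


def metropolis_design(
    model: PottsModel,
    wt: np.ndarray,
    profile: EntropyProfile | None = None,
    sigma: float | None = None,
    iterations: int = 100_000,
    temperature: float = 1.0,
    n_trials: int = 500,
    seed: int = 0,
    fixed_positions: set[int] | frozenset[int] = frozenset(),
    allowed: list[list[int]] | None = None,
    record_trajectory: bool = False,
    anneal: tuple[float, float] | None = None,
) -> DesignState:
    """Metropolis Monte Carlo sequence design; returns the best state found.

    Each trial starts from the wild type and proposes a uniform random
    substitution at a uniform random mutable position, accepting with
    probability ``min(1, exp(delta/T))``. With ``anneal=(T_hi, T_lo)`` the
    temperature decays geometrically over the trial. Fully reproducible
    given the seed.
    """
    wt = np.asarray(wt, dtype=np.int64)
    if wt.shape != (model.length,):
        raise ValueError("wild-type length does not match model")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    L, q = model.length, model.q
    if allowed is None:
        allowed = [list(range(q)) for _ in range(L)]
    fixed = frozenset(int(i) for i in fixed_positions)
    mutable = [i for i in range(L) if i not in fixed and len(allowed[i]) > 1]
    if not mutable:
        raise ValueError("no mutable positions")
    h, e = _masked_params(model, profile, sigma)
    allowed_arr = [np.asarray(allowed[i], dtype=np.int64) for i in range(L)]

    def score_of(s: np.ndarray) -> float:
        iu, ju = np.triu_indices(L, k=1)
        return float(h[np.arange(L), s].sum()
                     + e[iu, ju, s[iu], s[ju]].sum())

    root = np.random.default_rng(seed)
    trial_seeds = root.integers(0, 2**31 - 1, size=n_trials)
    best_state: DesignState | None = None
    for trial in range(n_trials):
        rng = np.random.default_rng(int(trial_seeds[trial]))
        s = wt.copy()
        contrib = _coupling_field(e, s)
        score = score_of(s)
        best_seq, best_score = s.copy(), score
        traj: list = []
        n_acc = 0
        if anneal is not None:
            t_hi, t_lo = anneal
            decay = (t_lo / t_hi) ** (1.0 / max(1, iterations - 1))
        positions = rng.choice(mutable, size=iterations)
        unif = rng.random(iterations)
        pick = rng.random(iterations)
        for it in range(iterations):
            i = int(positions[it])
            cands = allowed_arr[i]
            b = int(cands[int(pick[it] * len(cands))])
            a = int(s[i])
            if b == a:
                continue
            delta = h[i, b] - h[i, a] + contrib[i, b] - contrib[i, a]
            temp = (temperature if anneal is None
                    else t_hi * decay**it)
            accept = delta >= 0 or unif[it] < math.exp(delta / temp)
            if record_trajectory:
                traj.append((it, i, a, b, float(delta), bool(accept)))
            if accept:
                s[i] = b
                contrib += e[:, i, :, b] - e[:, i, :, a]
                score += delta
                n_acc += 1
                if score > best_score:
                    best_score = score
                    best_seq = s.copy()
        if best_state is None or best_score > best_state.best_score:
            best_state = DesignState(
                seq=s, score=score, best_seq=best_seq,
                best_score=float(best_score), fixed_positions=fixed,
                trajectory=traj, n_accepted=n_acc, n_steps=iterations,
            )
    assert best_state is not None
    return best_state


def exhaustive_optimum(
    model: PottsModel,
    allowed: list[list[int]] | None = None,
) -> tuple[np.ndarray, float]:
    """Brute-force global score maximum; only feasible at tiny L and q.

    Serves as the independent check for DEE soundness and design optimality.
    """
    import itertools

    L, q = model.length, model.q
    if allowed is None:
        allowed = [list(range(q)) for _ in range(L)]
    n_states = math.prod(len(a) for a in allowed)
    if n_states > 2_000_000:
        raise ValueError(f"{n_states} sequences is too many to enumerate")
    iu, ju = np.triu_indices(L, k=1)
    best_seq, best = None, -np.inf
    for combo in itertools.product(*allowed):
        s = np.asarray(combo, dtype=np.int64)
        val = (model.h[np.arange(L), s].sum()
               + model.e[iu, ju, s[iu], s[ju]].sum())
        if val > best:
            best, best_seq = float(val), s
    return best_seq, best
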