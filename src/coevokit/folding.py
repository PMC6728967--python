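"""Coarse-grained torsion-space Monte Carlo folding.

A chain is represented by its backbone torsions (phi, psi) per residue with
the peptide bond fixed planar-trans (omega = 180 degrees); Cartesian
coordinates for the N, C-alpha, C backbone are rebuilt deterministically
from ideal bond lengths and angles, and only the C-alpha trace is kept.

Folding minimises a simple non-negative energy by simulated annealing:

* flat-bottom contact restraints  sum w_ij max(0, d_ij - d0)^2
* torsion-window penalties        quadratic outside a square (phi, psi)
  window of half-width w degrees around per-residue predictions
* steric clashes                  sum max(0, d_clash - d_ij)^2 over
  non-adjacent C-alpha pairs

The iterative protocol runs many independent trajectories from the extended
chain, keeps the lowest-energy elite fraction, averages their contact maps,
and feeds high-frequency consensus contacts back as restraints for the next
round.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

# ideal backbone internal coordinates (lengths in Angstrom, angles degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0

DEFAULT_CONTACT_D0 = 8.0  # Angstrom, C-alpha contact threshold
DEFAULT_CLASH_D = 4.0  # Angstrom, C-alpha steric floor


def wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Map angle(s) in degrees to the interval (-180, 180]."""
    out = -((-np.asarray(a) + 180.0) % 360.0 - 180.0)
    return float(out) if np.isscalar(a) else out


@dataclass
class TorsionConstraint:
    """Per-residue predicted (phi, psi) with a square tolerance window."""

    phi: np.ndarray  # degrees, length L
    psi: np.ndarray
    half_width: float = 25.0

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.half_width <= 0:
            raise ValueError("window half-width must be positive")

    @classmethod
    def from_tsv(cls, path: str | Path, half_width: float = 25.0
                 ) -> "TorsionConstraint":
        df = pd.read_csv(path, sep="\t")
        df = df.sort_values("position")
        return cls(df["phi"].to_numpy(), df["psi"].to_numpy(), half_width)


@dataclass
class ContactRestraints:
    """Flat-bottom C-alpha distance restraints."""

    pairs: list[tuple[int, int, float]]  # (i, j, weight), 0-based, i < j
    d0: float = DEFAULT_CONTACT_D0
    min_separation: int = 5

    def __post_init__(self) -> None:
        seen = set()
        norm = []
        for i, j, w in self.pairs:
            i, j = (int(i), int(j)) if i < j else (int(j), int(i))
            if w < 0:
                raise ValueError("restraint weights must be nonnegative")
            if (i, j) in seen:
                raise ValueError(f"duplicate restraint pair ({i}, {j})")
            seen.add((i, j))
            norm.append((i, j, float(w)))
        self.pairs = norm

    @classmethod
    def from_tsv(cls, path: str | Path, **kw) -> "ContactRestraints":
        df = pd.read_csv(path, sep="\t")
        pairs = [(int(r.i) - 1, int(r.j) - 1, float(r.weight))
                 for r in df.itertuples()]
        return cls(pairs, **kw)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(i + 1, j + 1, w) for i, j, w in self.pairs],
            columns=["i", "j", "weight"],
        ).to_csv(path, sep="\t", index=False)


@dataclass
class EnergyTerms:
    restraint: float
    torsion: float
    clash: float
    total: float


@dataclass
class Conformation:
    """Backbone torsions plus the derived C-alpha trace."""

    torsions: np.ndarray  # (L, 2) degrees
    coords: np.ndarray  # (L, 3) C-alpha positions
    energy: EnergyTerms | None = None

    @property
    def length(self) -> int:
        return self.torsions.shape[0]

    def radius_of_gyration(self) -> float:
        centred = self.coords - self.coords.mean(axis=0)
        return float(np.sqrt((centred**2).sum(axis=1).mean()))


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Natural extension: position of the atom bonded to c given internal
    coordinates in the a-b-c frame. Scalar arithmetic on 3-tuples — this is
    the innermost call of every Monte Carlo move."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    inv = 1.0 / math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx * inv, bcy * inv, bcz * inv
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    inv = 1.0 / math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx * inv, ny * inv, nz * inv
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -bond * math.cos(angle)
    sa = bond * math.sin(angle)
    d1 = sa * math.cos(torsion)
    d2 = sa * math.sin(torsion)
    return (c[0] + d0 * bcx + d1 * mx + d2 * nx,
            c[1] + d0 * bcy + d1 * my + d2 * ny,
            c[2] + d0 * bcz + d1 * mz + d2 * nz)


_C1_SEED = (BOND_N_CA + BOND_CA_C * -math.cos(math.radians(ANGLE_N_CA_C)),
            BOND_CA_C * math.sin(math.radians(ANGLE_N_CA_C)), 0.0)


def build_coordinates(torsions: np.ndarray) -> Conformation:
    """Deterministic C-alpha trace from per-residue (phi, psi).

    Ideal bond lengths/angles, omega fixed at 180 degrees. phi of the first
    residue and psi of the last do not affect the trace but are kept so the
    torsion array round-trips.
    """
    torsions = np.asarray(torsions, dtype=float)
    if torsions.ndim != 2 or torsions.shape[1] != 2:
        raise ValueError("torsions must be an (L, 2) array of (phi, psi)")
    L = torsions.shape[0]
    if L < 2:
        raise ValueError("chain needs at least 2 residues")
    # first residue's N, CA, C seeded in a canonical frame
    prev_n, prev_ca, prev_c = (0.0, 0.0, 0.0), (BOND_N_CA, 0.0, 0.0), _C1_SEED
    cas = [prev_ca]
    for i in range(1, L):
        n_i = _place_atom(prev_n, prev_ca, prev_c,
                          BOND_C_N, ANGLE_CA_C_N, torsions[i - 1, 1])
        ca_i = _place_atom(prev_ca, prev_c, n_i,
                           BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = _place_atom(prev_c, n_i, ca_i,
                          BOND_CA_C, ANGLE_N_CA_C, torsions[i, 0])
        cas.append(ca_i)
        prev_n, prev_ca, prev_c = n_i, ca_i, c_i
    return Conformation(torsions=torsions.copy(), coords=np.array(cas))


@dataclass
class EnergyWeights:
    restraint: float = 1.0
    torsion: float = 0.01  # degrees^2 are large; keep terms commensurate
    clash: float = 1.0


def folding_energy(
    conf: Conformation,
    restraints: ContactRestraints | None = None,
    torsion: TorsionConstraint | None = None,
    weights: EnergyWeights | None = None,
    clash_distance: float = DEFAULT_CLASH_D,
) -> EnergyTerms:
    """Non-negative restraint + torsion-window + clash energy."""
    weights = weights or EnergyWeights()
    coords = conf.coords
    L = conf.length
    e_rest = 0.0
    if restraints is not None:
        for i, j, w in restraints.pairs:
            d = float(np.linalg.norm(coords[i] - coords[j]))
            e_rest += w * max(0.0, d - restraints.d0) ** 2
    e_tors = 0.0
    if torsion is not None:
        dphi = np.abs(wrap_angle(conf.torsions[:, 0] - torsion.phi))
        dpsi = np.abs(wrap_angle(conf.torsions[:, 1] - torsion.psi))
        excess = np.maximum(0.0, dphi - torsion.half_width) ** 2
        excess += np.maximum(0.0, dpsi - torsion.half_width) ** 2
        e_tors = float(excess.sum())
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    iu, ju = np.triu_indices(L, k=2)  # non-adjacent pairs only
    viol = np.maximum(0.0, clash_distance - dist[iu, ju])
    e_clash = float((viol**2).sum())
    total = (weights.restraint * e_rest + weights.torsion * e_tors
             + weights.clash * e_clash)
    return EnergyTerms(restraint=e_rest, torsion=e_tors, clash=e_clash,
                       total=total)


def extended_chain(L: int) -> Conformation:
    """Fully extended conformation: every (phi, psi) = (180, 180)."""
    return build_coordinates(np.full((L, 2), 180.0))


def fold_once(
    seq_length: int,
    restraints: ContactRestraints | None = None,
    torsion: TorsionConstraint | None = None,
    n_moves: int = 500,
    temperature: tuple[float, float] = (2.0, 0.2),
    move_scale: float = 30.0,
    weights: EnergyWeights | None = None,
    seed: int = 0,
) -> Conformation:
    """One annealed Metropolis trajectory from the extended chain.

    Each move perturbs a single residue's (phi, psi) by Gaussian noise of
    scale ``move_scale`` degrees, or — when torsion windows are supplied —
    resamples them uniformly inside the residue's window half the time.
    The temperature anneals geometrically between the given endpoints.
    """
    if n_moves < 1:
        raise ValueError("need at least one move")
    weights = weights or EnergyWeights()
    rng = np.random.default_rng(seed)
    conf = extended_chain(seq_length)
    energy = folding_energy(conf, restraints, torsion, weights)
    t_hi, t_lo = temperature
    decay = (t_lo / t_hi) ** (1.0 / max(1, n_moves - 1))
    tors = conf.torsions.copy()
    for move in range(n_moves):
        temp = t_hi * decay**move
        i = int(rng.integers(seq_length))
        old = tors[i].copy()
        if torsion is not None and rng.random() < 0.5:
            tors[i, 0] = wrap_angle(
                torsion.phi[i]
                + rng.uniform(-torsion.half_width, torsion.half_width))
            tors[i, 1] = wrap_angle(
                torsion.psi[i]
                + rng.uniform(-torsion.half_width, torsion.half_width))
        else:
            tors[i] = wrap_angle(tors[i] + rng.normal(0, move_scale, 2))
        cand = build_coordinates(tors)
        cand_energy = folding_energy(cand, restraints, torsion, weights)
        delta = cand_energy.total - energy.total
        if delta <= 0 or rng.random() < math.exp(-delta / temp):
            conf, energy = cand, cand_energy
        else:
            tors[i] = old
    conf.energy = energy
    return conf


def contact_map(conf: Conformation, d0: float = DEFAULT_CONTACT_D0,
                min_separation: int = 5) -> np.ndarray:
    """Binary symmetric C-alpha contact map with a sequence-separation cut."""
    diff = conf.coords[:, None, :] - conf.coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    sep = np.abs(np.subtract.outer(np.arange(conf.length),
                                   np.arange(conf.length)))
    return (dist < d0) & (sep >= min_separation)


@dataclass
class FoldingRound:
    """Record of one elite-averaging round."""

    index: int
    n_conformations: int
    elite_fraction: float
    elite_energy: float  # median restraint energy of the elite, measured
    # against the round's incoming restraint set
    elite_initial_energy: float  # same, measured against the *initial*
    # restraints only (comparable across rounds)
    consensus: np.ndarray  # (L, L) elite contact frequencies in [0, 1]
    n_restraints: int


def iterative_fold(
    seq_length: int,
    initial_restraints: ContactRestraints | None = None,
    torsion: TorsionConstraint | None = None,
    n_conformations: int = 500,
    elite_fraction: float = 0.20,
    rounds: int = 3,
    n_moves: int = 500,
    merge_threshold: float = 0.5,
    update_torsions: bool = False,
    weights: EnergyWeights | None = None,
    seed: int = 0,
) -> tuple[Conformation, list[FoldingRound]]:
    """Iterative elite-biased folding.

    Each round runs ``n_conformations`` independent trajectories from the
    extended chain (distinct derived seeds), keeps the lowest-total-energy
    elite, averages their contact maps, and adds consensus contacts seen in
    at least ``merge_threshold`` of the elite to the restraint set for the
    next round. Returns the overall best conformation and per-round records.
    """
    if rounds < 1:
        raise ValueError("need at least one round")
    elite_size = math.ceil(elite_fraction * n_conformations)
    if elite_size < 1:
        raise ValueError("elite set is empty; raise n or elite_fraction")
    weights = weights or EnergyWeights()
    restraints = initial_restraints or ContactRestraints([], )
    ss = np.random.SeedSequence(seed)
    history: list[FoldingRound] = []
    best: Conformation | None = None
    for rnd in range(rounds):
        seeds = ss.spawn(1)[0].generate_state(n_conformations)
        confs = [
            fold_once(seq_length, restraints, torsion, n_moves=n_moves,
                      weights=weights, seed=int(s) % (2**31))
            for s in seeds
        ]
        confs.sort(key=lambda c: c.energy.total)
        elite = confs[:elite_size]
        if best is None or elite[0].energy.total < best.energy.total:
            best = elite[0]
        consensus = np.mean(
            [contact_map(c, restraints.d0, restraints.min_separation)
             for c in elite], axis=0)
        existing = {(i, j) for i, j, _ in restraints.pairs}
        new_pairs = list(restraints.pairs)
        iu, ju = np.nonzero(np.triu(consensus >= merge_threshold, k=1))
        for i, j in zip(iu.tolist(), ju.tolist()):
            if (i, j) not in existing and j - i >= restraints.min_separation:
                new_pairs.append((i, j, float(consensus[i, j])))
        if update_torsions and torsion is not None:
            # circular mean of the elite's torsions recentres the windows
            ang = np.stack([c.torsions for c in elite])  # (E, L, 2)
            rad = np.deg2rad(ang)
            mean = np.rad2deg(np.arctan2(np.sin(rad).mean(axis=0),
                                         np.cos(rad).mean(axis=0)))
            torsion = replace(torsion, phi=mean[:, 0], psi=mean[:, 1])
        median_rest = float(np.median([c.energy.restraint for c in elite]))
        median_init = float(np.median([
            folding_energy(c, initial_restraints, None, weights).restraint
            for c in elite
        ])) if initial_restraints is not None else 0.0
        history.append(FoldingRound(
            index=rnd, n_conformations=n_conformations,
            elite_fraction=elite_fraction, elite_energy=median_rest,
            elite_initial_energy=median_init,
            consensus=consensus, n_restraints=len(new_pairs),
        ))
        restraints = ContactRestraints(new_pairs, d0=restraints.d0,
                                       min_separation=restraints.min_separation)
    assert best is not None
    return best, history


def write_ca_pdb(conf: Conformation, path: str | Path,
                 sequence: str | None = None) -> None:
    """Write the C-alpha trace as PDB ATOM records (chain A, 1-based)."""
    three = {"A": "ALA"}  # default residue name when no sequence given
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(conf.coords, start=1):
            resname = "GLY" if sequence is None else three.get(
                sequence[i - 1], "UNK")
            fh.write(
                f"ATOM  {i:5d}  CA  {resname:>3s} A{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")
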