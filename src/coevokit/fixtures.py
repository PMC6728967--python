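"""Planted-truth synthetic inputs for every recovery analysis.

Each generator returns a scenario object that stores its own generating
parameters, so tests of contact recovery, alpha calibration, block
extraction and folding can compare inferred quantities against the planted
ground truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import reduced_alphabet
from .folding import ContactRestraints, build_coordinates, contact_map
from .msa import MSA
from .potts import PottsModel, sample_potts, zero_sum_gauge


@dataclass
class CoupledMSAScenario:
    """A Potts-sampled alignment with a known planted contact graph."""

    model: PottsModel
    msa: MSA
    contacts: list[tuple[int, int]]  # planted coupled pairs, i < j
    coupling_strength: float
    seed: int

    @property
    def true_norms(self) -> np.ndarray:
        """(L, L) Frobenius norms of the planted (gauged) coupling blocks."""
        L, q = self.model.length, self.model.q
        blocks = self.model.e[:, :, : q - 1, : q - 1]
        return np.sqrt((blocks**2).sum(axis=(2, 3)))


def make_coupled_msa(
    L: int = 25,
    q: int = 5,
    n_contacts: int = 12,
    coupling_strength: float = 1.0,
    N: int = 5000,
    seed: int = 0,
    min_separation: int = 5,
    burn_in: int = 200,
) -> CoupledMSAScenario:
    """Sample an MSA from a sparse planted Potts model.

    Couplings sit on ``n_contacts`` random pairs with ``|i - j| >=
    min_separation``; each coupled block has i.i.d. normal entries of scale
    ``coupling_strength`` on the non-gap states. Fields are zero, so every
    signal in the alignment comes from the planted couplings. Sparse weak
    models like these mix quickly under systematic-sweep Gibbs updates, so
    200 burn-in sweeps per chain equilibrate the sampler; the agreement of
    sampled marginals with the generating model is property-tested.
    """
    rng = np.random.default_rng(seed)
    candidates = [(i, j) for i in range(L) for j in range(i + 1, L)
                  if j - i >= min_separation]
    if n_contacts > len(candidates):
        raise ValueError(
            f"cannot place {n_contacts} contacts with separation >= "
            f"{min_separation} in L={L}")
    idx = rng.choice(len(candidates), size=n_contacts, replace=False)
    contacts = sorted(candidates[i] for i in idx)
    alphabet = reduced_alphabet(q)
    h = np.zeros((L, q))
    e = np.zeros((L, L, q, q))
    for i, j in contacts:
        block = np.zeros((q, q))
        block[: q - 1, : q - 1] = (
            coupling_strength * rng.standard_normal((q - 1, q - 1)))
        e[i, j] = block
        e[j, i] = block.T
    h, e = zero_sum_gauge(h, e)
    model = PottsModel(h, e, gauge="zero_sum", alphabet=alphabet)
    msa = sample_potts(model, n=N, seed=int(rng.integers(2**31)),
                       burn_in=burn_in)
    return CoupledMSAScenario(model=model, msa=msa, contacts=contacts,
                              coupling_strength=coupling_strength, seed=seed)


@dataclass
class StabilityScenario:
    """Energy table with a planted coupling weight alpha."""

    table: pd.DataFrame
    planted_alpha: float
    noise_sd: float
    seed: int


def make_stability_table(
    n_families: int = 10,
    seqs_per_family: int = 8,
    planted_alpha: float = -0.43,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> StabilityScenario:
    """Stability fixture: measured = E_s + alpha * E_c + noise.

    Component energies are drawn with unit spread (the scale cancels in the
    correlation); class labels split each family at its median measured
    value, thermophilic above.
    """
    if n_families < 1:
        raise ValueError("need at least one family")
    rng = np.random.default_rng(seed)
    rows = []
    for fam in range(n_families):
        es = rng.normal(0.0, 1.0, seqs_per_family)
        ec = rng.normal(0.0, 1.0, seqs_per_family)
        measured = (es + planted_alpha * ec
                    + rng.normal(0.0, noise_sd, seqs_per_family))
        med = np.median(measured)
        for s in range(seqs_per_family):
            rows.append({
                "id": f"fam{fam}_seq{s}",
                "E_s": es[s],
                "E_c": ec[s],
                "measured": measured[s],
                "family": f"fam{fam}",
                "label": ("thermophilic" if measured[s] > med
                          else "mesophilic"),
            })
    return StabilityScenario(pd.DataFrame(rows), planted_alpha, noise_sd, seed)


# canonical motif torsions, degrees
HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-120.0, 120.0)


@dataclass
class ToyFoldScenario:
    """A small chain with native torsions and sampled native contacts."""

    native_torsions: np.ndarray  # (L, 2)
    restraints: ContactRestraints
    all_native_contacts: list[tuple[int, int]]
    motif: str
    seed: int


def make_toy_fold(
    L: int = 15,
    motif: str = "hairpin",
    n_native_contacts: int = 5,
    seed: int = 0,
    d0: float = 8.0,
    min_separation: int = 5,
) -> ToyFoldScenario:
    """Native torsions for a canonical motif plus sampled native contacts.

    ``helix`` uses ideal alpha-helical torsions throughout; ``hairpin``
    builds two extended strands around a tight two-residue turn, which puts
    the strands in register and creates long-range contacts.
    """
    if L < 8:
        raise ValueError("toy folds need L >= 8")
    torsions = np.zeros((L, 2))
    if motif == "helix":
        torsions[:] = HELIX_PHI_PSI
    elif motif == "hairpin":
        torsions[:] = STRAND_PHI_PSI
        mid = L // 2
        # two-residue turn with the positive-phi flip of a type-II' beta
        # turn; brings the strands into contact register
        torsions[mid - 1] = (60.0, -90.0)
        torsions[mid] = (-90.0, -30.0)
    else:
        raise ValueError(f"unknown motif {motif!r}")
    native = build_coordinates(torsions)
    cmap = contact_map(native, d0=d0, min_separation=min_separation)
    pairs = [(i, j) for i in range(L) for j in range(i + 1, L) if cmap[i, j]]
    if len(pairs) < n_native_contacts:
        raise ValueError(
            f"{motif} motif at L={L} has only {len(pairs)} contacts with "
            f"separation >= {min_separation}; asked for {n_native_contacts}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pairs), size=n_native_contacts, replace=False)
    chosen = sorted(pairs[i] for i in idx)
    restraints = ContactRestraints(
        [(i, j, 1.0) for i, j in chosen], d0=d0,
        min_separation=min_separation)
    return ToyFoldScenario(
        native_torsions=torsions, restraints=restraints,
        all_native_contacts=pairs, motif=motif, seed=seed)
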