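import numpy as np
import pytest

from coevokit.alphabet import reduced_alphabet
from coevokit.msa import MSA
from coevokit.potts import PottsModel, zero_sum_gauge


def random_potts(L: int, q: int, rng: np.random.Generator,
                 scale: float = 1.0, gauge: bool = True) -> PottsModel:
    """A dense random Potts model in zero-sum gauge (test helper)."""
    h = rng.normal(0.0, scale, (L, q))
    e = rng.normal(0.0, scale, (L, L, q, q))
    e = 0.5 * (e + e.transpose(1, 0, 3, 2))
    for i in range(L):
        e[i, i] = 0.0
    if gauge:
        h, e = zero_sum_gauge(h, e)
    return PottsModel(h, e, gauge="zero_sum" if gauge else "none",
                      alphabet=reduced_alphabet(q))


def random_msa(N: int, L: int, q: int, rng: np.random.Generator,
               gap_fraction: float = 0.0) -> MSA:
    """Uniform random integer alignment (test helper)."""
    alphabet = reduced_alphabet(q)
    matrix = rng.integers(0, q - 1 if gap_fraction == 0 else q,
                          size=(N, L), dtype=np.int8)
    if gap_fraction > 0:
        mask = rng.random((N, L)) < gap_fraction
        matrix[mask] = alphabet.gap_index
        matrix[0] = rng.integers(0, q - 1, size=L)  # keep query gap-free
    return MSA(matrix, [f"s{k}" for k in range(N)], alphabet=alphabet)


@pytest.fixture(scope="session")
def planted_scenario():
    """The shared planted-contact alignment used by recovery tests."""
    from coevokit.fixtures import make_coupled_msa

    return make_coupled_msa(L=25, q=5, n_contacts=12, coupling_strength=1.0,
                            N=5000, seed=11)


@pytest.fixture(scope="session")
def planted_fit(planted_scenario):
    from coevokit.msa import compute_weights
    from coevokit.potts import fit_plm

    weights = compute_weights(planted_scenario.msa)
    return fit_plm(planted_scenario.msa, weights)
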