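"""Amino-acid alphabet with an explicit gap state.

The whole package works on integer-encoded alignments: the 20 canonical
residues in a fixed order followed by the gap symbol ``-`` (index 20), giving
``q = 21`` states. Non-canonical letters (B, Z, X, J, U, O) carry essentially
no positional information at the resolution of a Potts model, so by default
they are encoded as gap; a strict mode raises instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: letters that are legal in real alignments but not canonical residues
AMBIGUOUS = set("BZXJUO")


class EncodingError(ValueError):
    """An alignment contains a symbol the alphabet cannot encode."""


@dataclass(frozen=True)
class Alphabet:
    """Ordered residue alphabet; gap is always the last state.

    Parameters
    ----------
    symbols:
        The ordered state letters. Default: 20 canonical residues + gap.
    strict:
        If True, ambiguous residue codes raise :class:`EncodingError`
        instead of mapping to gap.
    """

    symbols: str = CANONICAL + GAP
    strict: bool = False
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        object.__setattr__(
            self, "_index", {s: i for i, s in enumerate(self.symbols)}
        )

    @property
    def q(self) -> int:
        return len(self.symbols)

    @property
    def gap_index(self) -> int:
        return len(self.symbols) - 1

    def encode_symbol(self, ch: str) -> int:
        ch = ch.upper() if ch.islower() else ch
        if ch == ".":
            ch = GAP
        try:
            return self._index[ch]
        except KeyError:
            if ch in AMBIGUOUS and not self.strict:
                return self.gap_index
            raise EncodingError(f"cannot encode symbol {ch!r}") from None

    def encode(self, seq: str) -> np.ndarray:
        """Encode a string into an int8 vector of state indices."""
        return np.fromiter(
            (self.encode_symbol(c) for c in seq), dtype=np.int8, count=len(seq)
        )

    def decode(self, codes: np.ndarray) -> str:
        return "".join(self.symbols[int(c)] for c in codes)


#: module-level default alphabet (20 residues + gap, lenient encoding)
DEFAULT = Alphabet()


def reduced_alphabet(q: int) -> Alphabet:
    """A small test alphabet with ``q - 1`` residue letters plus gap.

    Used by synthetic fixtures where a full 21-state model would only slow
    the inference down without changing what is being tested.
    """
    if not 2 <= q <= 21:
        raise ValueError("reduced alphabet needs 2 <= q <= 21")
    return Alphabet(symbols=CANONICAL[: q - 1] + GAP)
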