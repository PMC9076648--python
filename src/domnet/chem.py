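"""Elemental composition arithmetic for CHNOS sum formulas.

Dissolved organic matter measured by negative-mode ESI is dominated by
singly deprotonated [M-H]- ions, so peak m/z and neutral monoisotopic
mass differ by one proton mass. Formulas are restricted to C, H, N, O, S,
which covers the vast majority of DOM assignments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

# IUPAC monoisotopic atomic masses (u) of the most abundant isotopes.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
}

#: Mass of the proton (u); removed when forming the [M-H]- ion.
PROTON_MASS: float = 1.007276466

# Hill order for carbon-containing compounds: C, H, then alphabetical.
_HILL_ORDER = ("C", "H", "N", "O", "S")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True, order=True)
class SumFormula:
    """An elemental composition (sum formula) over C, H, N, O, S.

    Isomers share a single sum formula; exact-mass measurements can
    therefore identify the composition but never the structure.
    """

    c: int
    h: int
    n: int = 0
    o: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative element count {name!r} in formula")

    @property
    def counts(self) -> dict[str, int]:
        return {"C": self.c, "H": self.h, "N": self.n, "O": self.o, "S": self.s}

    @property
    def mass(self) -> float:
        """Monoisotopic neutral mass (u)."""
        m = MONOISOTOPIC_MASS
        return (
            self.c * m["C"]
            + self.h * m["H"]
            + self.n * m["N"]
            + self.o * m["O"]
            + self.s * m["S"]
        )

    @property
    def mz_deprotonated(self) -> float:
        """m/z of the singly charged [M-H]- ion."""
        return self.mass - PROTON_MASS

    @property
    def dbe(self) -> float:
        """Rings plus double bonds (double-bond equivalents)."""
        return self.c - self.h / 2.0 + self.n / 2.0 + 1.0

    def __str__(self) -> str:
        parts = []
        for el in _HILL_ORDER:
            cnt = self.counts[el]
            if cnt == 0:
                continue
            parts.append(el if cnt == 1 else f"{el}{cnt}")
        return "".join(parts) or ""

    @classmethod
    def parse(cls, text: str) -> "SumFormula":
        """Parse a Hill-notation CHNOS formula string (e.g. ``C6H12O6``)."""
        counts = {el: 0 for el in _HILL_ORDER}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos or not match.group(0):
                break
            el, num = match.group(1), match.group(2)
            if el not in counts:
                raise ValueError(f"unsupported element {el!r} in formula {text!r}")
            counts[el] += int(num) if num else 1
            pos = match.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula string {text!r}")
        return cls(c=counts["C"], h=counts["H"], n=counts["N"], o=counts["O"], s=counts["S"])


def neutral_mass_from_mz(mz: float) -> float:
    """Neutral monoisotopic mass of a singly deprotonated ion at ``mz``."""
    return mz + PROTON_MASS


def ppm_error(observed_mass: float, candidate_mass: float) -> float:
    """Relative mass error in parts per million, signed."""
    return 1e6 * (observed_mass - candidate_mass) / candidate_mass
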