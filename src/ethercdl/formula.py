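"""Exact elemental-formula arithmetic for positive-ion lipid mass spectrometry.

All mass bookkeeping in the package runs through :class:`ElementalFormula`:
an immutable element→count mapping with Hill-order rendering, monoisotopic
mass evaluation (electron-corrected for cations), signed ppm errors, and the
first-isotopologue (M+1) intensity ratio used for the ¹³C quantification
policy of cardiolipins.

Conventions
-----------
* Ion compositions *include* the adduct atoms: the protonated species of a
  neutral M with formula F is written F+H and its m/z is the monoisotopic
  mass of F+H minus one electron mass.  This matches how high-resolution
  instruments report ion compositions (e.g. C73H151O13P2 for an [M+H]+).
* ppm error is signed, (observed − theoretical) / theoretical × 1e6.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "ElementalFormula",
    "Adduct",
    "MassMatch",
    "ADDUCTS",
    "parse_formula",
    "monoisotopic_mass",
    "ppm_error",
    "m1_ratio",
    "ELECTRON_MASS",
    "PROTON_MZ",
]

# Monoisotopic atomic masses (Da), CODATA/NIST.  Six or more decimals are
# required: low-ppm error annotations on kDa ions do not reproduce otherwise.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "Na": 22.9897692809,
}

ELECTRON_MASS = 0.00054857991  # Da

# Minor/major abundance ratio of the +1 Da isotope of each element
# (13C/12C, 2H/1H, 15N/14N, 17O/16O); P and Na are monoisotopic.
M1_ABUNDANCE_RATIO: dict[str, float] = {
    "C": 0.010816,
    "H": 0.000156,
    "N": 0.003676,
    "O": 0.000380,
    "P": 0.0,
    "Na": 0.0,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalFormula(Mapping):
    """Immutable element→count mapping supporting +/− arithmetic.

    Counts are non-negative integers; zero-count elements are dropped so
    that equality is element-wise.  Rendering follows Hill order (C, H,
    then remaining elements alphabetically).
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kw:
            for el, n in src.items():
                if el not in MONOISOTOPIC_MASS:
                    raise ValueError(f"unknown element symbol: {el!r}")
                if n != int(n):
                    raise ValueError(f"non-integer count for {el}: {n!r}")
                merged[el] = merged.get(el, 0) + int(n)
        if any(n < 0 for n in merged.values()):
            neg = {el: n for el, n in merged.items() if n < 0}
            raise ValueError(f"negative element counts: {neg}")
        self._counts = {el: n for el, n in merged.items() if n > 0}
        self._hash = hash(frozenset(self._counts.items()))

    # Mapping protocol -------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self._counts[el]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, el: str, default: int = 0) -> int:
        return self._counts.get(el, default)

    def __hash__(self) -> int:
        return self._hash

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalFormula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == dict(other)
        return NotImplemented

    # Arithmetic -------------------------------------------------------
    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = dict(self._counts)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return ElementalFormula(out)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        out = dict(self._counts)
        for el, n in other.items():
            out[el] = out.get(el, 0) - n
            if out[el] < 0:
                raise ValueError(
                    f"impossible neutral loss: {other} not contained in {self} "
                    f"({el} deficit)"
                )
        return ElementalFormula(out)

    def __mul__(self, k: int) -> "ElementalFormula":
        if k < 0:
            raise ValueError("negative multiplier")
        return ElementalFormula({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def contains(self, other: "ElementalFormula") -> bool:
        """True if ``other`` is element-wise ≤ ``self``."""
        return all(self.get(el) >= n for el, n in other.items())

    def __bool__(self) -> bool:
        return bool(self._counts)

    # Rendering --------------------------------------------------------
    def hill(self) -> str:
        """Hill-order text: C, H, then alphabetical; '' for the empty formula."""
        order = []
        for el in ("C", "H"):
            if el in self._counts:
                order.append(el)
        order.extend(sorted(el for el in self._counts if el not in ("C", "H")))
        return "".join(
            f"{el}{self._counts[el] if self._counts[el] != 1 else ''}" for el in order
        )

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"ElementalFormula({self.hill()!r})"


def parse_formula(text: str) -> ElementalFormula:
    """Parse a Hill-order formula string, e.g. ``"C34H70O3"``.

    Repeated element symbols accumulate.  Raises ``ValueError`` on unknown
    symbols or malformed text.
    """
    if not text or not text.strip():
        return ElementalFormula()
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalFormula(counts)


def monoisotopic_mass(f: ElementalFormula | Mapping[str, int], charge: int = 0) -> float:
    """Monoisotopic mass (charge 0) or m/z (charge +1) of a formula.

    For charge +1 the formula is taken to be the full ion composition
    (adduct atoms included) and one electron mass is subtracted.
    """
    if charge not in (0, 1):
        raise ValueError("only charge 0 and +1 are supported")
    if not f:
        raise ValueError("empty formula has no mass")
    mass = sum(MONOISOTOPIC_MASS[el] * n for el, n in f.items())
    return mass - charge * ELECTRON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in ppm: (obs − theo)/theo × 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (observed - theoretical) / theoretical * 1e6


def m1_ratio(f: ElementalFormula | Mapping[str, int]) -> float:
    """Expected M+1/M intensity ratio of the first isotopologue.

    Linear single-substitution approximation: Σ_E n_E·r_E over the +1 Da
    isotopes (¹³C, ²H, ¹⁵N, ¹⁷O); exact for the one-substitution peak and
    accurate to <1% for lipid-sized formulas.
    """
    if not f:
        raise ValueError("empty formula")
    return sum(M1_ABUNDANCE_RATIO[el] * n for el, n in f.items())


@dataclass(frozen=True)
class Adduct:
    """Positive-mode ionizing addition, applied as a formula delta.

    ``delta_add`` is added to and ``delta_sub`` subtracted from the neutral
    formula (subtraction is needed for in-source water loss).
    """

    name: str
    delta_add: ElementalFormula
    delta_sub: ElementalFormula
    charge: int = 1

    def ion_formula(self, neutral: ElementalFormula) -> ElementalFormula:
        return (neutral + self.delta_add) - self.delta_sub

    def mz(self, neutral: ElementalFormula) -> float:
        return monoisotopic_mass(self.ion_formula(neutral), self.charge)


_EMPTY = ElementalFormula()

ADDUCTS: dict[str, Adduct] = {
    "[M+H]+": Adduct("[M+H]+", ElementalFormula(H=1), _EMPTY),
    "[M+H-H2O]+": Adduct(
        "[M+H-H2O]+", ElementalFormula(H=1), ElementalFormula(H=2, O=1)
    ),
    "[M+NH4]+": Adduct("[M+NH4]+", ElementalFormula(N=1, H=4), _EMPTY),
    "[M+Na]+": Adduct("[M+Na]+", ElementalFormula(Na=1), _EMPTY),
}

PROTON_MZ = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS


@dataclass(frozen=True)
class MassMatch:
    """An observed/theoretical mass pair with its signed ppm deviation."""

    observed_mz: float
    theoretical_mz: float

    @property
    def delta_ppm(self) -> float:
        return ppm_error(self.observed_mz, self.theoretical_mz)
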