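"""Elemental-formula algebra and ESI adduct mass arithmetic.

This module is the numerical foundation of the package: element-count
vectors over {C, H, N, O, S, Na}, monoisotopic masses, ring-double-bond
equivalents (RDB), singly-charged adduct-ion m/z values with electron-mass
correction, signed ppm mass errors, and nominal (nearest-integer) mass
shifts.

Conventions
-----------
* Monoisotopic masses (Da): H 1.0078250319, C 12 (exact), N 14.0030740052,
  O 15.9949146221, S 31.97207069, Na 22.98976928; electron 0.00054858.
* Ion masses carry the electron correction: a protonated ion adds a proton
  (H minus an electron, 1.00727646 Da), a sodiated ion adds Na minus an
  electron (22.98922070 Da), a deprotonated ion loses a proton.
* ppm error is signed as 1e6 * (measured - theoretical) / theoretical, so a
  measurement above theory is positive.
* RDB counts Na as monovalent (like H) and is evaluated on neutral
  compositions: RDB = C + 1 - (H + Na)/2 + N/2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterator, Mapping, Union

__all__ = [
    "ELEMENTS",
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "Formula",
    "FormulaError",
    "AdductSpec",
    "ADDUCTS",
    "get_adduct",
    "monoisotopic_mass",
    "rdbe",
    "adduct_mz",
    "neutral_mass_from_adduct",
    "ion_composition",
    "ppm_error",
    "nominal_shift",
]

#: Supported element symbols, in canonical storage order.
ELEMENTS = ("C", "H", "N", "Na", "O", "S")

#: Monoisotopic masses of the most abundant isotopes, Da.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "Na": 22.98976928,
}

#: Electron rest mass, Da.
ELECTRON_MASS = 0.00054858

#: Proton mass = H minus one electron, Da.
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

# Hill order: carbon, hydrogen, then remaining elements alphabetically.
_HILL_ORDER = ("C", "H", "N", "Na", "O", "S")
_ELEMENT_INDEX = {el: i for i, el in enumerate(ELEMENTS)}
_MASS_VECTOR = tuple(MONOISOTOPIC_MASS[el] for el in ELEMENTS)

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparseable text, unsupported elements, or negative counts."""


@dataclass(frozen=True)
class Formula:
    """Immutable elemental composition over {C, H, N, O, S, Na}.

    Counts are non-negative integers.  Addition and subtraction are
    element-wise; subtraction that would drive any count negative raises
    :class:`FormulaError`.
    """

    _counts: tuple[int, ...]

    def __init__(self, counts: Union[Mapping[str, int], None] = None, **kw: int):
        merged = dict(counts or {})
        merged.update(kw)
        vec = [0] * len(ELEMENTS)
        for el, n in merged.items():
            if el not in _ELEMENT_INDEX:
                raise FormulaError(f"unsupported element symbol: {el!r}")
            if int(n) != n or n < 0:
                raise FormulaError(f"count for {el} must be a non-negative integer, got {n!r}")
            vec[_ELEMENT_INDEX[el]] = int(n)
        object.__setattr__(self, "_counts", tuple(vec))

    # -- construction -------------------------------------------------

    @classmethod
    def from_vector(cls, vec: tuple[int, ...]) -> "Formula":
        if len(vec) != len(ELEMENTS) or any(v < 0 for v in vec):
            raise FormulaError(f"invalid count vector: {vec!r}")
        obj = object.__new__(cls)
        object.__setattr__(obj, "_counts", tuple(int(v) for v in vec))
        return obj

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse Hill-like notation, e.g. ``"C34H42O19"`` or ``"CH4"``.

        An empty string parses to the all-zero formula.  Unsupported element
        symbols raise :class:`FormulaError` naming the symbol.
        """
        text = text.strip()
        vec = [0] * len(ELEMENTS)
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if not m or not m.group(1):
                raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
            sym, digits = m.group(1), m.group(2)
            if sym not in _ELEMENT_INDEX:
                raise FormulaError(f"unsupported element symbol: {sym!r} in {text!r}")
            vec[_ELEMENT_INDEX[sym]] += int(digits) if digits else 1
            pos = m.end()
        return cls.from_vector(tuple(vec))

    # -- mapping-ish access -------------------------------------------

    def __getitem__(self, el: str) -> int:
        try:
            return self._counts[_ELEMENT_INDEX[el]]
        except KeyError:
            raise FormulaError(f"unsupported element symbol: {el!r}") from None

    @property
    def counts(self) -> dict[str, int]:
        """Non-zero counts as a plain dict."""
        return {el: n for el, n in zip(ELEMENTS, self._counts) if n}

    @property
    def vector(self) -> tuple[int, ...]:
        """Raw count tuple in :data:`ELEMENTS` order."""
        return self._counts

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts.items())

    def is_empty(self) -> bool:
        return not any(self._counts)

    # -- algebra -------------------------------------------------------

    def __add__(self, other: "Formula") -> "Formula":
        return Formula.from_vector(tuple(a + b for a, b in zip(self._counts, other._counts)))

    def __sub__(self, other: "Formula") -> "Formula":
        vec = tuple(a - b for a, b in zip(self._counts, other._counts))
        if any(v < 0 for v in vec):
            raise FormulaError(f"subtraction {self} - {other} yields a negative count")
        return Formula.from_vector(vec)

    def contains(self, other: "Formula") -> bool:
        """Element-wise containment: ``other`` is a sub-formula of ``self``."""
        return all(a >= b for a, b in zip(self._counts, other._counts))

    def __le__(self, other: "Formula") -> bool:
        return other.contains(self)

    # -- formatting ----------------------------------------------------

    def hill(self) -> str:
        """Canonical Hill notation (C, H, then alphabetical)."""
        parts = []
        for el in _HILL_ORDER:
            n = self[el]
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - thin alias
        return self.hill()

    def __repr__(self) -> str:
        return f"Formula({self.hill()!r})"


def parse_formula(text: str) -> Formula:
    """Module-level alias for :meth:`Formula.parse`."""
    return Formula.parse(text)


def format_formula(f: Formula) -> str:
    """Canonical Hill-notation string for ``f``."""
    return f.hill()


def monoisotopic_mass(f: Formula) -> float:
    """Monoisotopic mass of a composition in Da (additive over elements)."""
    return sum(n * m for n, m in zip(f.vector, _MASS_VECTOR))


def rdbe(f: Formula) -> float:
    """Ring-double-bond equivalents of a neutral composition.

    RDB = C + 1 - (H + Na)/2 + N/2; oxygen and sulfur contribute nothing.
    Sodium is treated as monovalent, like hydrogen.
    """
    return f["C"] + 1.0 - (f["H"] + f["Na"]) / 2.0 + f["N"] / 2.0


@dataclass(frozen=True)
class AdductSpec:
    """A singly-charged ESI adduct: atoms gained/lost plus electrons gained.

    ``delta`` maps element symbols to signed atom changes relative to the
    neutral molecule; ``electron_delta`` is the number of electrons gained
    (-1 for cations, +1 for anions), so charge = -electron_delta.
    """

    name: str
    charge: int
    delta: Mapping[str, int]
    electron_delta: int

    def __post_init__(self):
        if self.charge != -self.electron_delta:
            raise ValueError(f"{self.name}: charge must equal -(electrons gained)")
        if abs(self.charge) != 1:
            raise ValueError(f"{self.name}: only singly charged adducts are supported")

    @property
    def delta_mass(self) -> float:
        """Mass added to the neutral molecule, electrons included, Da."""
        atoms = sum(n * MONOISOTOPIC_MASS[el] for el, n in self.delta.items())
        return atoms + self.electron_delta * ELECTRON_MASS

    @property
    def polarity(self) -> str:
        return "+" if self.charge > 0 else "-"


ADDUCTS: Mapping[str, AdductSpec] = {
    "[M+H]+": AdductSpec("[M+H]+", charge=+1, delta={"H": +1}, electron_delta=-1),
    "[M-H]-": AdductSpec("[M-H]-", charge=-1, delta={"H": -1}, electron_delta=+1),
    "[M+Na]+": AdductSpec("[M+Na]+", charge=+1, delta={"Na": +1}, electron_delta=-1),
}

_ADDUCT_NORMALIZE = str.maketrans({"−": "-", " ": None, " ": None})


def get_adduct(adduct: Union[str, AdductSpec]) -> AdductSpec:
    """Resolve an adduct by name, tolerating spaces and Unicode minus signs."""
    if isinstance(adduct, AdductSpec):
        return adduct
    key = adduct.translate(_ADDUCT_NORMALIZE)
    try:
        return ADDUCTS[key]
    except KeyError:
        supported = ", ".join(ADDUCTS)
        raise KeyError(f"unknown adduct {adduct!r}; supported adducts: {supported}") from None


def adduct_mz(neutral_mass: float, adduct: Union[str, AdductSpec]) -> float:
    """Theoretical ion m/z for a neutral mass under a singly-charged adduct."""
    spec = get_adduct(adduct)
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    return (neutral_mass + spec.delta_mass) / abs(spec.charge)


def neutral_mass_from_adduct(mz: float, adduct: Union[str, AdductSpec]) -> float:
    """Exact inverse of :func:`adduct_mz` for singly-charged ions."""
    spec = get_adduct(adduct)
    if mz <= 0:
        raise ValueError(f"m/z must be positive, got {mz}")
    return mz * abs(spec.charge) - spec.delta_mass


def ion_composition(neutral: Formula, adduct: Union[str, AdductSpec]) -> Formula:
    """Atomic composition of the adduct ion (charge carried implicitly)."""
    spec = get_adduct(adduct)
    vec = list(neutral.vector)
    for el, n in spec.delta.items():
        vec[_ELEMENT_INDEX[el]] += n
        if vec[_ELEMENT_INDEX[el]] < 0:
            raise FormulaError(f"adduct {spec.name} removes more {el} than {neutral} has")
    return Formula.from_vector(tuple(vec))


def ppm_error(measured: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million.

    Positive when the measurement sits above theory.
    """
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return 1e6 * (measured - theoretical) / theoretical


def nominal_shift(mz_a: float, mz_b: float) -> int:
    """Nearest-integer mass difference between two m/z values, Da."""
    return round(mz_a - mz_b)
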