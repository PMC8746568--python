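"""Candidate molecular formulas: bounded enumeration and biotransformation closure.

Two generators of candidate compositions live here.

``enumerate_formulas`` exhaustively lists every formula over the bounded
C/H/N/O/S/Na lattice whose monoisotopic mass falls within a ppm tolerance
of a target neutral mass and whose ring-double-bond equivalents fall in a
configured range.  The defaults mirror a typical high-resolution formula
predictor: C 0-50, H 0-100, O 0-50, N 0-5, S 0-5, RDB 0-15, 5 ppm.

``rule_closure`` performs a breadth-first closure of a parent compound
under a catalog of biotransformation rules (demethylation, reduction,
ester/glycosidic cleavage, ...), each expressed as a signed element-count
delta.  The closure is deduplicated by formula, keeping the shortest path
(ties broken by the lexicographically earliest rule-name sequence), and is
bounded by per-element ceilings so that gain rules cannot chain forever.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .chem import (
    ELEMENTS,
    MONOISOTOPIC_MASS,
    Formula,
    FormulaError,
    monoisotopic_mass,
    ppm_error,
    rdbe,
)

__all__ = [
    "ElementBounds",
    "BiotransformationRule",
    "CandidatePath",
    "enumerate_formulas",
    "rule_closure",
    "label_reaction",
    "parse_delta",
    "load_rules",
    "default_rules",
]


@dataclass(frozen=True)
class ElementBounds:
    """Per-element count ranges plus RDB window and mass tolerance.

    The defaults are the element ranges of a standard small-molecule
    formula predictor (sodium excluded from neutral formulas).
    """

    bounds: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "C": (0, 50),
            "H": (0, 100),
            "N": (0, 5),
            "Na": (0, 0),
            "O": (0, 50),
            "S": (0, 5),
        }
    )
    rdb_min: float = 0.0
    rdb_max: float = 15.0
    tolerance_ppm: float = 5.0

    def __post_init__(self):
        for el, (lo, hi) in self.bounds.items():
            if el not in ELEMENTS:
                raise FormulaError(f"unsupported element symbol in bounds: {el!r}")
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid bounds for {el}: ({lo}, {hi})")

    def range(self, el: str) -> tuple[int, int]:
        return self.bounds.get(el, (0, 0))

    def admits(self, f: Formula) -> bool:
        """True when every count and the RDB value fall inside the windows."""
        for el in ELEMENTS:
            lo, hi = self.range(el)
            if not lo <= f[el] <= hi:
                return False
        return self.rdb_min <= rdbe(f) <= self.rdb_max


def enumerate_formulas(
    target_neutral_mass: float,
    bounds: Optional[ElementBounds] = None,
) -> list[tuple[Formula, float]]:
    """All formulas within ``bounds`` whose mass matches the target.

    Returns ``(formula, signed ppm)`` pairs sorted by absolute ppm error,
    ties broken by Hill-notation lexicographic order.  The signed ppm
    treats the target as the measured quantity.  A non-positive target
    yields an empty list; a non-positive tolerance raises ``ValueError``.
    """
    bounds = bounds or ElementBounds()
    if bounds.tolerance_ppm <= 0:
        raise ValueError(f"tolerance must be positive, got {bounds.tolerance_ppm}")
    if target_neutral_mass <= 0:
        return []

    lo = target_neutral_mass * (1.0 - bounds.tolerance_ppm * 1e-6)
    hi = target_neutral_mass * (1.0 + bounds.tolerance_ppm * 1e-6)
    mC, mH, mN, mNa, mO, mS = (MONOISOTOPIC_MASS[el] for el in ("C", "H", "N", "Na", "O", "S"))
    cLo, cHi = bounds.range("C")
    hLo, hHi = bounds.range("H")
    nLo, nHi = bounds.range("N")
    naLo, naHi = bounds.range("Na")
    oLo, oHi = bounds.range("O")
    sLo, sHi = bounds.range("S")

    out: list[tuple[Formula, float]] = []
    for na in range(naLo, naHi + 1):
        m_na = na * mNa
        if m_na > hi:
            break
        for s in range(sLo, sHi + 1):
            m_s = m_na + s * mS
            if m_s > hi:
                break
            for n in range(nLo, nHi + 1):
                m_n = m_s + n * mN
                if m_n > hi:
                    break
                for c in range(cLo, cHi + 1):
                    m_c = m_n + c * mC
                    if m_c > hi:
                        break
                    for h in range(hLo, hHi + 1):
                        m_h = m_c + h * mH
                        if m_h > hi:
                            break
                        o_min = max(oLo, math.ceil((lo - m_h) / mO))
                        o_max = min(oHi, math.floor((hi - m_h) / mO))
                        for o in range(o_min, o_max + 1):
                            total = m_h + o * mO
                            if total < lo or total > hi:
                                continue
                            rdb = c + 1.0 - (h + na) / 2.0 + n / 2.0
                            if not bounds.rdb_min <= rdb <= bounds.rdb_max:
                                continue
                            f = Formula.from_vector((c, h, n, na, o, s))
                            out.append((f, ppm_error(target_neutral_mass, total)))
    out.sort(key=lambda pair: (abs(pair[1]), pair[0].hill()))
    return out


@dataclass(frozen=True)
class BiotransformationRule:
    """A named biotransformation expressed as a signed element-count delta."""

    name: str
    delta: Mapping[str, int]
    klass: str = ""

    @property
    def direction(self) -> str:
        """'loss', 'gain', or 'mixed' according to the delta signs."""
        signs = {1 if v > 0 else -1 for v in self.delta.values() if v}
        if signs == {-1}:
            return "loss"
        if signs == {1}:
            return "gain"
        return "mixed" if signs else "identity"

    def apply(self, f: Formula) -> Optional[Formula]:
        """Apply the delta; ``None`` when any count would go negative."""
        vec = list(f.vector)
        for el, n in self.delta.items():
            i = ELEMENTS.index(el)
            vec[i] += n
            if vec[i] < 0:
                return None
        return Formula.from_vector(tuple(vec))

    def delta_string(self) -> str:
        """Signed-term representation, e.g. ``-CH2`` or ``+H2O``."""
        gains = {el: v for el, v in self.delta.items() if v > 0}
        losses = {el: -v for el, v in self.delta.items() if v < 0}
        text = ""
        if gains:
            text += "+" + Formula(gains).hill()
        if losses:
            text += "-" + Formula(losses).hill()
        return text or "+"


def parse_delta(text: str) -> dict[str, int]:
    """Parse a signed delta such as ``-CH2``, ``+H2O`` or ``+O-CH2``."""
    text = text.strip().replace("−", "-")
    if not text:
        raise FormulaError("empty delta string")
    delta: dict[str, int] = {}
    i = 0
    sign = +1
    if text[0] not in "+-":
        text = "+" + text
    while i < len(text):
        sign = +1 if text[i] == "+" else -1
        i += 1
        j = i
        while j < len(text) and text[j] not in "+-":
            j += 1
        part = Formula.parse(text[i:j])
        for el, n in part.items():
            delta[el] = delta.get(el, 0) + sign * n
        i = j
    return {el: v for el, v in delta.items() if v}


_DEFAULT_RULE_FILE = "default_rules.tsv"


def load_rules(path: Union[str, Path, None] = None) -> list[BiotransformationRule]:
    """Load a rule catalog from columnar text (name, signed delta, class).

    With no path, the bundled default catalog is returned.
    """
    if path is None:
        source = resources.files("dissmet").joinpath("data", _DEFAULT_RULE_FILE)
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    rules = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"rule catalog line {lineno}: expected name<TAB>delta[<TAB>class]")
        name, delta = parts[0].strip(), parts[1].strip()
        klass = parts[2].strip() if len(parts) > 2 else ""
        rules.append(BiotransformationRule(name, parse_delta(delta), klass))
    return rules


def default_rules() -> list[BiotransformationRule]:
    """The bundled biotransformation catalog."""
    return load_rules(None)


@dataclass(frozen=True)
class CandidatePath:
    """An ordered rule sequence from the parent to a candidate formula."""

    rules: tuple[str, ...]
    formula: Formula
    depth: int

    def __post_init__(self):
        if self.depth != len(self.rules):
            raise ValueError("depth must equal the number of rule applications")

    def replay(self, parent: Formula, catalog: Sequence[BiotransformationRule]) -> Formula:
        """Re-apply the rule sequence to ``parent``; raises if invalid."""
        by_name = {r.name: r for r in catalog}
        f = parent
        for name in self.rules:
            nxt = by_name[name].apply(f)
            if nxt is None:
                raise FormulaError(f"rule {name!r} not applicable to {f}")
            f = nxt
        return f


def rule_closure(
    parent: Formula,
    rules: Sequence[BiotransformationRule],
    max_depth: int,
    ceilings: Optional[Mapping[str, int]] = None,
    ceiling_slack: int = 2,
    rdb_floor: float = 0.0,
) -> dict[Formula, CandidatePath]:
    """Breadth-first closure of ``parent`` under ``rules`` up to ``max_depth``.

    Returns a mapping formula -> shortest :class:`CandidatePath`; ties at
    equal depth keep the lexicographically earliest rule-name sequence.

    Heavy-atom ceilings default to the parent count plus ``ceiling_slack``
    so that gain rules cannot wander off the metabolically plausible
    lattice.  Hydrogen is bounded by valence rather than by a fixed
    ceiling: successive reductions raise the H count well above the
    parent's (hydrogenated metabolites), but RDB must stay at or above
    ``rdb_floor``, which terminates every +H2 chain.  The parent is always
    a member (empty path, depth 0).
    """
    if max_depth < 0:
        raise ValueError(f"max_depth must be >= 0, got {max_depth}")
    if not rules and max_depth > 0:
        warnings.warn("empty rule catalog: closure contains only the parent", stacklevel=2)
    if ceilings is None:
        ceilings = {el: parent[el] + ceiling_slack for el in ELEMENTS if el != "H"}

    paths: dict[Formula, CandidatePath] = {parent: CandidatePath((), parent, 0)}
    ordered_rules = sorted(rules, key=lambda r: r.name)
    frontier = [parent]
    for depth in range(1, max_depth + 1):
        discovered: dict[Formula, tuple[str, ...]] = {}
        for f in sorted(frontier, key=lambda g: paths[g].rules):
            base = paths[f].rules
            for rule in ordered_rules:
                g = rule.apply(f)
                if g is None or g in paths:
                    continue
                if any(g[el] > hi for el, hi in ceilings.items()):
                    continue
                if rdbe(g) < rdb_floor:
                    continue
                cand = base + (rule.name,)
                prev = discovered.get(g)
                if prev is None or cand < prev:
                    discovered[g] = cand
        if not discovered:
            break
        for g, seq in discovered.items():
            paths[g] = CandidatePath(seq, g, depth)
        frontier = list(discovered)
    return paths


def label_reaction(
    parent: Formula,
    child: Formula,
    rules: Sequence[BiotransformationRule],
    max_depth: int = 8,
    ceilings: Optional[Mapping[str, int]] = None,
) -> Optional[CandidatePath]:
    """Shortest rule path linking ``parent`` to ``child``.

    Returns ``None`` when the child is unreachable within ``max_depth``
    (reported downstream as "unexplained").
    """
    closure = rule_closure(parent, rules, max_depth, ceilings=ceilings)
    return closure.get(child)
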