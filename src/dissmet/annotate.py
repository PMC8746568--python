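"""MS1 feature grouping, formula assignment, MS2 fragment annotation, network export.

The pipeline stages here take measured adduct ions (with optional MS2 peak
lists) through to an identification table:

1. :func:`group_features` merges dual-polarity detections of the same
   metabolite by deduced neutral mass and retention time (single linkage).
2. :func:`assign_candidates` matches each group against a
   biotransformation closure of the parent compound, ranking candidates by
   reaction-path depth then mean absolute ppm error.
3. :func:`annotate_fragments` explains MS2 peaks as element-wise
   sub-formulas of the precursor ion, labelling canonical neutral losses.
4. :func:`build_network` lays the identified reaction paths out as a
   directed metabolic network (unobserved intermediates marked virtual).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import networkx as nx
import numpy as np

from .chem import (
    ELECTRON_MASS,
    ELEMENTS,
    MONOISOTOPIC_MASS,
    AdductSpec,
    Formula,
    adduct_mz,
    get_adduct,
    ion_composition,
    monoisotopic_mass,
    neutral_mass_from_adduct,
    ppm_error,
)
from .inference import BiotransformationRule, CandidatePath, ElementBounds

__all__ = [
    "Ms1Feature",
    "Ms2Peak",
    "FragmentAssignment",
    "IdentificationRecord",
    "MetaboliteGroup",
    "ClosureIndex",
    "group_features",
    "assign_candidates",
    "annotate_fragments",
    "sequential_losses",
    "validate_printed_fragments",
    "build_network",
    "identify",
]

#: Canonical neutral-loss dictionary: composition -> label.
NEUTRAL_LOSSES: Mapping[str, str] = {
    "H2O": "water",
    "CO": "carbon monoxide",
    "CO2": "carbon dioxide",
    "CH3": "methyl radical",
    "CH2O": "formaldehyde",
    "CH4O": "methanol",
    "C6H10O5": "anhydrohexose",
    "C11H10O4": "sinapoyl",
}


@dataclass(frozen=True)
class Ms2Peak:
    """One MS2 fragment peak: m/z and relative intensity (base peak = 100)."""

    mz: float
    intensity: float
    printed_formula: Optional[str] = None

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"fragment m/z must be positive, got {self.mz}")
        if not 0 < self.intensity <= 100:
            raise ValueError(f"relative intensity must be in (0, 100], got {self.intensity}")


@dataclass
class Ms1Feature:
    """One measured adduct ion with retention time and optional MS2 peaks."""

    feature_id: str
    rt_min: float
    polarity: str
    adduct: str
    mz: float
    metabolite: Optional[str] = None
    sham_matrices: frozenset[int] = frozenset()
    model_matrices: frozenset[int] = frozenset()
    ms2: tuple[Ms2Peak, ...] = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"{self.feature_id}: m/z must be positive, got {self.mz}")
        if self.rt_min < 0:
            raise ValueError(f"{self.feature_id}: retention time must be >= 0")
        spec = get_adduct(self.adduct)
        if spec.polarity != self.polarity:
            raise ValueError(
                f"{self.feature_id}: adduct {self.adduct} does not match polarity {self.polarity}"
            )
        self.adduct = spec.name

    @property
    def neutral_mass(self) -> float:
        return neutral_mass_from_adduct(self.mz, self.adduct)


@dataclass(frozen=True)
class FragmentAssignment:
    """A fragment peak explained (or not) as a precursor sub-formula ion."""

    peak: Ms2Peak
    formula: Optional[Formula]
    ppm: Optional[float]
    neutral_loss: Optional[Formula]
    loss_label: Optional[str]
    status: str  # "sub-formula-valid" | "unassigned"


@dataclass
class MetaboliteGroup:
    """Features grouped into one putative metabolite."""

    group_id: str
    features: tuple[Ms1Feature, ...]

    @property
    def consensus_rt(self) -> float:
        return float(np.mean([f.rt_min for f in self.features]))

    @property
    def mean_neutral_mass(self) -> float:
        return float(np.mean([f.neutral_mass for f in self.features]))

    @property
    def sham_matrices(self) -> frozenset[int]:
        out: frozenset[int] = frozenset()
        for f in self.features:
            out |= f.sham_matrices
        return out

    @property
    def model_matrices(self) -> frozenset[int]:
        out: frozenset[int] = frozenset()
        for f in self.features:
            out |= f.model_matrices
        return out


@dataclass
class IdentificationRecord:
    """One identified (or unidentified) metabolite group."""

    metabolite_id: str
    rt_min: float
    formula: Optional[Formula]
    path: Optional[tuple[str, ...]]
    adducts: tuple[tuple[str, float, float], ...]  # (adduct name, measured m/z, signed ppm)
    sham_matrices: frozenset[int] = frozenset()
    model_matrices: frozenset[int] = frozenset()
    reaction_label: str = "unexplained"
    fragments: tuple[FragmentAssignment, ...] = ()
    source_labels: tuple[str, ...] = ()

    @property
    def identified(self) -> bool:
        return self.formula is not None

    @property
    def neutral_mass(self) -> Optional[float]:
        return monoisotopic_mass(self.formula) if self.formula else None

    @property
    def depth(self) -> Optional[int]:
        return len(self.path) if self.path is not None else None


def group_features(
    features: Sequence[Ms1Feature],
    mass_tol_ppm: float = 10.0,
    rt_tol_min: float = 0.2,
) -> list[MetaboliteGroup]:
    """Single-linkage partition of features into metabolite groups.

    Two features link when their retention times agree within
    ``rt_tol_min`` AND their deduced neutral masses agree within
    ``mass_tol_ppm`` (relative to the mean of the pair).  The result is a
    partition: every feature lands in exactly one group.  Groups are
    ordered by (consensus RT, lowest m/z) and the output is independent of
    the input ordering.
    """
    if mass_tol_ppm <= 0 or rt_tol_min <= 0:
        raise ValueError("grouping tolerances must be positive")
    g = nx.Graph()
    indexed = sorted(features, key=lambda f: (f.rt_min, f.mz, f.feature_id))
    g.add_nodes_from(range(len(indexed)))
    neutral = [f.neutral_mass for f in indexed]
    for i in range(len(indexed)):
        for j in range(i + 1, len(indexed)):
            if abs(indexed[i].rt_min - indexed[j].rt_min) > rt_tol_min:
                continue
            mean = 0.5 * (neutral[i] + neutral[j])
            if abs(neutral[i] - neutral[j]) / mean * 1e6 <= mass_tol_ppm:
                g.add_edge(i, j)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (min(indexed[i].rt_min for i in c), min(indexed[i].mz for i in c)))
    width = max(2, len(str(len(comps))))
    return [
        MetaboliteGroup(f"G{k:0{width}d}", tuple(indexed[i] for i in comp))
        for k, comp in enumerate(comps, start=1)
    ]


class ClosureIndex:
    """Mass-sorted view of a rule closure for fast candidate lookup."""

    def __init__(self, closure: Mapping[Formula, CandidatePath]):
        items = sorted(closure.items(), key=lambda kv: monoisotopic_mass(kv[0]))
        self.formulas = [f for f, _ in items]
        self.paths = [p for _, p in items]
        self.masses = np.array([monoisotopic_mass(f) for f in self.formulas])

    def window(self, mass: float, tol_ppm: float) -> range:
        pad = mass * tol_ppm * 1e-6 * 2.0  # generous: ion vs neutral ppm differ slightly
        lo = int(np.searchsorted(self.masses, mass - pad, side="left"))
        hi = int(np.searchsorted(self.masses, mass + pad, side="right"))
        return range(lo, hi)


@dataclass(frozen=True)
class Candidate:
    """A closure member consistent with every feature in a group."""

    formula: Formula
    path: CandidatePath
    ppms: tuple[float, ...]

    @property
    def mean_abs_ppm(self) -> float:
        return float(np.mean([abs(p) for p in self.ppms]))


def assign_candidates(
    group: MetaboliteGroup,
    closure: Union[Mapping[Formula, CandidatePath], ClosureIndex],
    tol_ppm: float = 5.0,
) -> list[Candidate]:
    """Rank closure formulas consistent with *every* feature of a group.

    A candidate passes when, for each member feature, the theoretical m/z
    of the candidate under that feature's adduct is within ``tol_ppm`` of
    the measured m/z.  Ranking: reaction-path depth ascending, then mean
    absolute ppm, then Hill notation.  An empty list means unidentified.
    """
    if not isinstance(closure, ClosureIndex):
        if not closure:
            raise ValueError("closure must be non-empty")
        closure = ClosureIndex(closure)
    out = []
    for i in closure.window(group.mean_neutral_mass, tol_ppm):
        f = closure.formulas[i]
        mass = closure.masses[i]
        ppms = []
        for feat in group.features:
            err = ppm_error(feat.mz, adduct_mz(mass, feat.adduct))
            if abs(err) > tol_ppm:
                break
            ppms.append(err)
        else:
            out.append(Candidate(f, closure.paths[i], tuple(ppms)))
    out.sort(key=lambda c: (c.path.depth, c.mean_abs_ppm, c.formula.hill()))
    return out


_MASS_VEC = np.array([MONOISOTOPIC_MASS[el] for el in ELEMENTS])


def _subformula_table(ion: Formula) -> tuple[np.ndarray, np.ndarray]:
    """All element-wise sub-compositions of an ion with their masses."""
    axes = [np.arange(ion[el] + 1) for el in ELEMENTS]
    grids = np.meshgrid(*axes, indexing="ij")
    counts = np.stack([g.ravel() for g in grids], axis=1)
    masses = counts @ _MASS_VEC
    return counts, masses


def annotate_fragments(
    neutral: Formula,
    adduct: Union[str, AdductSpec],
    peaks: Sequence[Ms2Peak],
    frag_tol_ppm: float = 10.0,
    allow_radical: bool = True,
) -> list[FragmentAssignment]:
    """Explain MS2 peaks as sub-formula ions of the precursor ion.

    Candidate fragment ions are element-wise sub-compositions of the
    precursor ion composition carrying the precursor's charge; fragment
    m/z = mass -/+ electron for cations/anions.  Even-electron ions
    (half-integer RDB) are assumed; compositions with integer RDB are
    admitted only as methyl-radical losses when ``allow_radical`` is set.
    For each peak the best candidate (smallest absolute ppm within
    ``frag_tol_ppm``) is reported together with the complementary neutral
    loss; peaks with no candidate are flagged unassigned.
    """
    if frag_tol_ppm <= 0:
        raise ValueError("fragment tolerance must be positive")
    spec = get_adduct(adduct)
    ion = ion_composition(neutral, spec)
    counts, masses = _subformula_table(ion)
    mz = masses - spec.charge * ELECTRON_MASS
    iC, iH, iN, iNa = (ELEMENTS.index(el) for el in ("C", "H", "N", "Na"))
    rdb = counts[:, iC] + 1.0 - (counts[:, iH] + counts[:, iNa]) / 2.0 + counts[:, iN] / 2.0
    half_integer = np.mod(rdb * 2, 2) == 1
    ion_vec = np.array(ion.vector)
    loss = ion_vec[None, :] - counts
    radical_ok = (loss[:, iC] >= 1) & (loss[:, iH] >= 3)
    ok = (rdb >= -0.5) & (half_integer | (allow_radical & radical_ok))

    out = []
    for peak in peaks:
        with np.errstate(divide="ignore"):
            ppm = (peak.mz - mz) / mz * 1e6
        cand = np.where(ok & (np.abs(ppm) <= frag_tol_ppm) & (mz > 0))[0]
        if len(cand) == 0:
            out.append(FragmentAssignment(peak, None, None, None, None, "unassigned"))
            continue
        best = cand[np.argmin(np.abs(ppm[cand]))]
        f = Formula.from_vector(tuple(int(v) for v in counts[best]))
        nl = ion - f
        label = NEUTRAL_LOSSES.get(nl.hill()) if not nl.is_empty() else None
        out.append(
            FragmentAssignment(peak, f, float(ppm[best]), nl, label, "sub-formula-valid")
        )
    return out


def sequential_losses(
    assignments: Sequence[FragmentAssignment],
) -> list[tuple[FragmentAssignment, FragmentAssignment, Formula, Optional[str]]]:
    """Pairwise neutral losses along the assigned-fragment ladder.

    Assigned fragments are ordered by descending m/z; for each consecutive
    pair whose compositions nest, the step loss and its canonical label (if
    dictionary-known) are reported.  Captures chains such as precursor ->
    -H2O -> -CH3.
    """
    assigned = sorted(
        (a for a in assignments if a.formula is not None),
        key=lambda a: -a.peak.mz,
    )
    steps = []
    for hi, lo in zip(assigned, assigned[1:]):
        if hi.formula.contains(lo.formula):
            step = hi.formula - lo.formula
            steps.append((hi, lo, step, NEUTRAL_LOSSES.get(step.hill())))
    return steps


def validate_printed_fragments(
    features: Sequence[Ms1Feature],
    neutral_formulas: Mapping[str, Formula],
    mass_tol_ppm: float = 10.0,
) -> list[dict]:
    """Audit printed fragment-formula assignments against their precursors.

    For every MS2 peak carrying a printed ion composition, reports whether
    that composition is an element-wise sub-formula of the precursor ion
    and whether its theoretical m/z sits within ``mass_tol_ppm`` of the
    printed fragment m/z.  Violations are listed, never corrected.
    """
    report = []
    for feat in features:
        neutral = neutral_formulas.get(feat.feature_id)
        if neutral is None:
            continue
        spec = get_adduct(feat.adduct)
        ion = ion_composition(neutral, spec)
        for peak in feat.ms2:
            if not peak.printed_formula:
                continue
            frag = Formula.parse(peak.printed_formula)
            theo = monoisotopic_mass(frag) - spec.charge * ELECTRON_MASS
            err = ppm_error(peak.mz, theo)
            report.append(
                {
                    "feature_id": feat.feature_id,
                    "fragment_mz": peak.mz,
                    "printed_formula": frag.hill(),
                    "subformula_ok": ion.contains(frag),
                    "mass_ok": abs(err) <= mass_tol_ppm,
                    "ppm": err,
                }
            )
    return report


def identify(
    groups: Sequence[MetaboliteGroup],
    closure: Union[Mapping[Formula, CandidatePath], ClosureIndex],
    tol_ppm: float = 5.0,
    frag_tol_ppm: float = 10.0,
    spectra: Optional[Mapping[str, Sequence[Ms2Peak]]] = None,
) -> list[IdentificationRecord]:
    """Full per-group identification: candidates, fragments, isomer labels.

    Metabolite ids are assigned in RT order; groups sharing a top-candidate
    formula (positional isomers) are distinguished only by retention time,
    earlier RT receiving the lower id.
    """
    if not isinstance(closure, ClosureIndex):
        closure = ClosureIndex(closure)
    records = []
    ordered = sorted(groups, key=lambda g: (g.consensus_rt, g.mean_neutral_mass))
    for k, group in enumerate(ordered, start=1):
        candidates = assign_candidates(group, closure, tol_ppm)
        top = candidates[0] if candidates else None
        adducts = []
        fragments: tuple[FragmentAssignment, ...] = ()
        if top is not None:
            mass = monoisotopic_mass(top.formula)
            adducts = [
                (f.adduct, f.mz, ppm_error(f.mz, adduct_mz(mass, f.adduct)))
                for f in group.features
            ]
            frags = []
            for f in group.features:
                peaks = list(f.ms2)
                if spectra and f.feature_id in spectra:
                    peaks.extend(spectra[f.feature_id])
                if peaks:
                    frags.extend(
                        annotate_fragments(top.formula, f.adduct, peaks, frag_tol_ppm)
                    )
            fragments = tuple(frags)
        else:
            adducts = [(f.adduct, f.mz, float("nan")) for f in group.features]
        label = "unidentified"
        if top is not None:
            label = " > ".join(top.path.rules) if top.path.rules else "parent"
        records.append(
            IdentificationRecord(
                metabolite_id=f"MET{k:02d}",
                rt_min=group.consensus_rt,
                formula=top.formula if top else None,
                path=top.path.rules if top else None,
                adducts=tuple(adducts),
                sham_matrices=group.sham_matrices,
                model_matrices=group.model_matrices,
                reaction_label=label,
                fragments=fragments,
                source_labels=tuple(
                    sorted({f.metabolite for f in group.features if f.metabolite})
                ),
            )
        )
    # isomer suffixing by RT rank among records sharing a formula
    by_formula: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        if rec.formula is not None:
            by_formula.setdefault(rec.formula.hill(), []).append(i)
    for hill, idxs in by_formula.items():
        if len(idxs) > 1:
            for rank, i in enumerate(sorted(idxs, key=lambda i: records[i].rt_min), start=1):
                records[i] = replace(
                    records[i],
                    reaction_label=f"{records[i].reaction_label} [isomer {rank}]",
                )
    return records


def build_network(
    records: Sequence[IdentificationRecord],
    rules: Sequence[BiotransformationRule],
    parent: Formula,
) -> nx.DiGraph:
    """Directed metabolic network from identified reaction paths.

    Nodes are metabolite ids for observed formulas (the record with the
    earliest RT when isomers share a composition is used for path
    intermediates) and virtual formula nodes, marked ``observed=False``,
    for intermediates nobody detected.  Each edge carries the rule name
    that converts its source composition into its target.
    """
    by_name = {r.name: r for r in rules}
    observed: dict[str, IdentificationRecord] = {}
    for rec in sorted(records, key=lambda r: r.rt_min):
        if rec.formula is not None:
            observed.setdefault(rec.formula.hill(), rec)

    g = nx.DiGraph()

    def node_for(formula: Formula, terminal: Optional[IdentificationRecord]) -> str:
        hill = formula.hill()
        if terminal is not None and terminal.formula is not None and terminal.formula.hill() == hill:
            name = terminal.metabolite_id
            g.add_node(name, formula=hill, observed=True)
            return name
        if hill in observed:
            name = observed[hill].metabolite_id
            g.add_node(name, formula=hill, observed=True)
            return name
        name = f"[{hill}]"
        g.add_node(name, formula=hill, observed=False)
        return name

    for rec in records:
        if rec.path is None or rec.formula is None:
            continue
        current = parent
        src = node_for(parent, None)
        for step_i, rule_name in enumerate(rec.path):
            rule = by_name[rule_name]
            nxt = rule.apply(current)
            if nxt is None:
                raise ValueError(
                    f"{rec.metabolite_id}: rule {rule_name!r} not applicable to {current}"
                )
            terminal = rec if step_i == len(rec.path) - 1 else None
            dst = node_for(nxt, terminal)
            g.add_edge(src, dst, rule=rule_name, delta=rule.delta_string())
            current, src = nxt, dst
    return g
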