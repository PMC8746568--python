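"""Synthetic metabolomes, noisy feature tables, and the packaged fixture.

The simulator emulates the measurement model the annotation pipeline
assumes: a ground-truth metabolome drawn from the biotransformation
closure of a parent compound, adduct ions observed with multiplicative
Gaussian mass noise (in ppm, matching how Orbitrap error scales), decoy
peaks at random masses, per-matrix detection in two study groups, and MS2
spectra produced by random neutral-loss cuts.  Everything is driven by a
single seed, so identical configurations yield identical artifacts.

`load_table1_fixture` returns the packaged transcription of the published
metabolite summary table (27 adduct-ion rows for metabolites M0-M19,
digest-guarded), which serves as the canonical real-data input.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np

from .annotate import (
    NEUTRAL_LOSSES,
    ClosureIndex,
    Ms1Feature,
    Ms2Peak,
    assign_candidates,
    group_features,
    ion_composition,
)
from .chem import ELECTRON_MASS, Formula, adduct_mz, get_adduct, monoisotopic_mass
from .inference import BiotransformationRule, CandidatePath, default_rules, rule_closure
from .io import Spectrum, read_feature_table

__all__ = [
    "SimulationConfig",
    "TrueMetabolite",
    "simulate_metabolome",
    "simulate_features",
    "recovery_experiment",
    "Table1Fixture",
    "load_table1_fixture",
    "FixtureIntegrityError",
]

_MATRICES = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic metabolome.

    Defaults mirror the design of the mouse distribution study: a parent
    disinapoyl-sucrose compound, 20 true metabolites from the default
    biotransformation closure, sub-2-ppm Orbitrap-like mass noise, decoy
    features across the observed mass range, and per-matrix detection in a
    sham and a model group.
    """

    seed: int = 0
    parent: str = "C34H42O19"
    max_depth: int = 8
    n_true: int = 20
    noise_sd_ppm: float = 1.0
    n_decoys: int = 50
    decoy_mass_range: tuple[float, float] = (150.0, 800.0)
    detect_prob: float = 0.6
    adduct_probs: Mapping[str, float] = field(
        default_factory=lambda: {"[M+H]+": 0.6, "[M+Na]+": 0.35, "[M-H]-": 0.5}
    )
    rt_range_min: tuple[float, float] = (5.0, 24.0)
    ms2_max_losses: int = 4

    def __post_init__(self):
        if self.noise_sd_ppm < 0:
            raise ValueError("noise SD must be >= 0")
        if not all(0 <= p <= 1 for p in self.adduct_probs.values()):
            raise ValueError("adduct emission probabilities must be in [0, 1]")
        if not 0 <= self.detect_prob <= 1:
            raise ValueError("detection probability must be in [0, 1]")


@dataclass(frozen=True)
class TrueMetabolite:
    """Ground truth for one simulated metabolite."""

    truth_id: str
    formula: Formula
    path: CandidatePath
    rt_min: float
    sham_matrices: frozenset[int]
    model_matrices: frozenset[int]


def simulate_metabolome(
    cfg: SimulationConfig,
    rules: Optional[Sequence[BiotransformationRule]] = None,
    closure: Optional[Mapping[Formula, CandidatePath]] = None,
) -> list[TrueMetabolite]:
    """Seeded sample of distinct closure members, parent always included."""
    rules = list(rules) if rules is not None else default_rules()
    parent = Formula.parse(cfg.parent)
    if closure is None:
        closure = rule_closure(parent, rules, cfg.max_depth)
    if cfg.n_true < 1:
        raise ValueError("n_true must be >= 1")
    if cfg.n_true > len(closure):
        raise ValueError(
            f"requested {cfg.n_true} metabolites but the closure holds only {len(closure)}"
        )
    rng = np.random.default_rng(cfg.seed)
    others = sorted((f for f in closure if f != parent), key=lambda f: f.hill())
    chosen = [parent]
    if cfg.n_true > 1:
        idx = rng.choice(len(others), size=cfg.n_true - 1, replace=False)
        chosen.extend(others[i] for i in sorted(idx))
    out = []
    lo, hi = cfg.rt_range_min
    for i, f in enumerate(chosen):
        rt = float(rng.uniform(lo, hi))
        sham = frozenset(m for m in _MATRICES if rng.random() < cfg.detect_prob)
        model = frozenset(m for m in _MATRICES if rng.random() < cfg.detect_prob)
        out.append(TrueMetabolite(f"T{i:02d}", f, closure[f], rt, sham, model))
    return out


_LOSS_FORMULAS = tuple(Formula.parse(text) for text in NEUTRAL_LOSSES)


def _simulate_ms2(
    rng: np.random.Generator,
    neutral: Formula,
    adduct: str,
    precursor_mz: float,
    noise_sd_ppm: float,
    max_losses: int,
) -> tuple[Ms2Peak, ...]:
    """Random neutral-loss cuts from the precursor ion composition."""
    spec = get_adduct(adduct)
    current = ion_composition(neutral, spec)
    comps = []
    for _ in range(max_losses):
        applicable = [nl for nl in _LOSS_FORMULAS if current.contains(nl)]
        if not applicable:
            break
        nl = applicable[int(rng.integers(len(applicable)))]
        current = current - nl
        comps.append(current)
    if not comps:
        return ()
    intensities = rng.uniform(5.0, 100.0, size=len(comps))
    intensities = intensities / intensities.max() * 100.0
    peaks = []
    for comp, inten in zip(comps, intensities):
        theo = monoisotopic_mass(comp) - spec.charge * ELECTRON_MASS
        mz = theo * (1.0 + rng.normal(0.0, noise_sd_ppm) * 1e-6)
        peaks.append(Ms2Peak(mz, float(inten)))
    return tuple(sorted(peaks, key=lambda p: p.mz))


def simulate_features(
    truth: Sequence[TrueMetabolite],
    cfg: SimulationConfig,
) -> tuple[list[Ms1Feature], dict[str, Spectrum]]:
    """Emit noisy adduct-ion features plus decoys and MS2 spectra.

    Measured m/z = theoretical * (1 + eps * 1e-6) with eps ~ N(0, noise SD
    in ppm).  Decoys are formula-free masses drawn uniformly over the decoy
    range.  The feature/spectrum streams are fully determined by the seed
    (a sub-seed distinct from the metabolome sampler's).
    """
    rng = np.random.default_rng((cfg.seed, 1))
    features: list[Ms1Feature] = []
    spectra: dict[str, Spectrum] = {}
    suffix = {"[M+H]+": "h", "[M+Na]+": "na", "[M-H]-": "n"}
    for met in truth:
        mass = monoisotopic_mass(met.formula)
        emitted = [a for a, p in sorted(cfg.adduct_probs.items()) if rng.random() < p]
        # deprotonation needs an abstractable hydrogen on the molecule
        emitted = [
            a for a in emitted
            if get_adduct(a).delta.get("H", 0) >= 0 or met.formula["H"] > 0
        ]
        if not emitted:
            emitted = ["[M+H]+"]
        for adduct in emitted:
            spec = get_adduct(adduct)
            theo = adduct_mz(mass, adduct)
            mz = theo * (1.0 + rng.normal(0.0, cfg.noise_sd_ppm) * 1e-6)
            fid = f"{met.truth_id}{suffix[adduct]}"
            peaks = _simulate_ms2(
                rng, met.formula, adduct, mz, cfg.noise_sd_ppm, cfg.ms2_max_losses
            )
            features.append(
                Ms1Feature(
                    feature_id=fid,
                    rt_min=met.rt_min,
                    polarity=spec.polarity,
                    adduct=adduct,
                    mz=mz,
                    metabolite=met.truth_id,
                    sham_matrices=met.sham_matrices,
                    model_matrices=met.model_matrices,
                    ms2=peaks,
                )
            )
            if peaks:
                spectra[fid] = Spectrum(fid, mz, spec.charge, peaks)
    lo, hi = cfg.decoy_mass_range
    for i in range(cfg.n_decoys):
        mz = float(rng.uniform(lo, hi))
        rt = float(rng.uniform(*cfg.rt_range_min))
        negative = rng.random() < 0.5
        features.append(
            Ms1Feature(
                feature_id=f"D{i:03d}",
                rt_min=rt,
                polarity="-" if negative else "+",
                adduct="[M-H]-" if negative else "[M+H]+",
                mz=mz,
            )
        )
    return features, spectra


def recovery_experiment(
    cfg: SimulationConfig,
    tol_ppm: float = 5.0,
    group_tol_ppm: float = 10.0,
    rt_tol_min: float = 0.2,
    rules: Optional[Sequence[BiotransformationRule]] = None,
    closure: Optional[Mapping[Formula, CandidatePath]] = None,
) -> dict:
    """Simulate, annotate, and score the pipeline against ground truth.

    Recall: fraction of true metabolites for which some group containing
    their features receives the true formula as top candidate.  Precision:
    fraction of identified groups whose top candidate matches the (single)
    truth behind their features; groups built purely from decoys or mixing
    several truths count as incorrect when identified.
    """
    rules = list(rules) if rules is not None else default_rules()
    parent = Formula.parse(cfg.parent)
    if closure is None:
        closure = rule_closure(parent, rules, cfg.max_depth)
    truth = simulate_metabolome(cfg, rules, closure)
    features, _ = simulate_features(truth, cfg)
    groups = group_features(features, group_tol_ppm, rt_tol_min)
    index = ClosureIndex(closure)
    truth_by_id = {m.truth_id: m for m in truth}

    recalled: set[str] = set()
    n_identified = 0
    n_correct = 0
    for group in groups:
        candidates = assign_candidates(group, index, tol_ppm)
        if not candidates:
            continue
        n_identified += 1
        top = candidates[0].formula
        sources = {f.metabolite for f in group.features}
        if len(sources) == 1 and None not in sources:
            met = truth_by_id[next(iter(sources))]
            if met.formula == top:
                n_correct += 1
                recalled.add(met.truth_id)
    return {
        "n_true": len(truth),
        "n_groups": len(groups),
        "n_identified": n_identified,
        "recall": len(recalled) / len(truth),
        "precision": (n_correct / n_identified) if n_identified else float("nan"),
    }


class FixtureIntegrityError(RuntimeError):
    """The packaged fixture does not match its stored digest."""


@dataclass
class Table1Fixture:
    """The packaged adduct-ion table: 27 rows covering metabolites M0-M19."""

    features: list[Ms1Feature]
    neutral_formulas: dict[str, Formula]
    printed_ppm: dict[str, float]
    printed_formulas: dict[str, str]

    @property
    def metabolites(self) -> list[str]:
        seen: list[str] = []
        for f in self.features:
            if f.metabolite and f.metabolite not in seen:
                seen.append(f.metabolite)
        return seen

    def distribution_records(self):
        """Per-metabolite matrix sets, unioned over polarity rows."""
        from .distribution import DistributionRecord

        sham: dict[str, frozenset[int]] = {}
        model: dict[str, frozenset[int]] = {}
        for f in self.features:
            mid = f.metabolite
            sham[mid] = sham.get(mid, frozenset()) | f.sham_matrices
            model[mid] = model.get(mid, frozenset()) | f.model_matrices
        return [DistributionRecord(mid, sham[mid], model[mid]) for mid in self.metabolites]


def _fixture_text(name: str) -> str:
    return resources.files("dissmet").joinpath("data", name).read_text(encoding="utf-8")


def load_table1_fixture(verify: bool = True) -> Table1Fixture:
    """Load the packaged adduct-ion fixture with its MS2 peak lists.

    The two data files are digest-guarded; ``verify=False`` skips the
    check (useful only when regenerating the digest).
    """
    if verify:
        digests = json.loads(_fixture_text("table1_digest.json"))
        for name, expected in digests.items():
            actual = hashlib.sha256(_fixture_text(name).encode("utf-8")).hexdigest()
            if actual != expected:
                raise FixtureIntegrityError(
                    f"fixture file {name} digest mismatch: {actual} != {expected}"
                )
    with resources.as_file(
        resources.files("dissmet").joinpath("data", "table1_features.tsv")
    ) as path:
        features = read_feature_table(path)

    fragments: dict[str, list[Ms2Peak]] = {}
    lines = _fixture_text("table1_fragments.tsv").splitlines()
    header: Optional[list[str]] = None
    for line in lines:
        if not line.strip() or line.startswith("#"):
            continue
        if header is None:
            header = line.split("\t")
            continue
        row = dict(zip(header, line.split("\t")))
        fragments.setdefault(row["feature_id"], []).append(
            Ms2Peak(
                float(row["mz"]),
                float(row["rel_intensity"]),
                printed_formula=row["formula"] or None,
            )
        )

    neutral: dict[str, Formula] = {}
    printed_ppm: dict[str, float] = {}
    printed_formula: dict[str, str] = {}
    out = []
    for f in features:
        f.ms2 = tuple(fragments.get(f.feature_id, ()))
        neutral[f.feature_id] = Formula.parse(f.provenance["formula"])
        printed_ppm[f.feature_id] = float(f.provenance["printed_ppm"])
        printed_formula[f.feature_id] = f.provenance["printed_formula"]
        out.append(f)
    return Table1Fixture(out, neutral, printed_ppm, printed_formula)
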