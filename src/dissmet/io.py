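"""Readers, writers, run configuration, and the end-to-end pipeline driver.

All tables are UTF-8, tab-delimited, with ``#``-prefixed comment lines;
m/z values serialize to 5 decimals and ppm errors to 3.  MS2 spectra use
MGF (``BEGIN IONS``/``PEPMASS``/``CHARGE 1+|1-``/``TITLE``) with peak
intensities normalized so the base peak reads 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import networkx as nx
import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from .annotate import (
    FragmentAssignment,
    IdentificationRecord,
    Ms1Feature,
    Ms2Peak,
    ClosureIndex,
    build_network,
    group_features,
    identify,
)
from .chem import Formula, adduct_mz, monoisotopic_mass, ppm_error
from .distribution import DistributionRecord, differential_report
from .inference import BiotransformationRule, default_rules, load_rules, rule_closure

__all__ = [
    "InputError",
    "read_feature_table",
    "write_feature_table",
    "Spectrum",
    "read_mgf",
    "write_mgf",
    "attach_spectra",
    "write_identification_table",
    "read_identification_table",
    "write_network",
    "write_differential_report",
    "read_distribution_table",
    "RunConfig",
    "load_config",
    "PipelineResult",
    "run_full_pipeline",
]

logger = logging.getLogger("dissmet")

_FEATURE_COLUMNS = ("feature_id", "rt_min", "polarity", "adduct", "mz")


class InputError(ValueError):
    """Malformed or missing input data; maps to CLI exit code 1."""


def _parse_codes(text: str) -> frozenset[int]:
    text = (text or "").strip()
    if not text or text == "-":
        return frozenset()
    return frozenset(int(tok) for tok in text.replace(" ", "").split(",") if tok)


def read_feature_table(path: Union[str, Path]) -> list[Ms1Feature]:
    """Read an MS1 feature table (tab-delimited, '#' comments allowed).

    Required columns: feature_id, rt_min, polarity, adduct, mz.  Optional:
    metabolite, sham_matrices, model_matrices (comma-separated codes).
    Malformed rows are rejected with their line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"feature table not found: {path}")
    features = []
    header: Optional[list[str]] = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = [c.strip() for c in cells]
                missing = [c for c in _FEATURE_COLUMNS if c not in header]
                if missing:
                    raise InputError(f"{path}: missing required column(s): {', '.join(missing)}")
                continue
            row = dict(zip(header, cells))
            try:
                features.append(
                    Ms1Feature(
                        feature_id=row["feature_id"].strip(),
                        rt_min=float(row["rt_min"]),
                        polarity=row["polarity"].strip(),
                        adduct=row["adduct"].strip(),
                        mz=float(row["mz"]),
                        metabolite=(row.get("metabolite") or "").strip() or None,
                        sham_matrices=_parse_codes(row.get("sham_matrices", "")),
                        model_matrices=_parse_codes(row.get("model_matrices", "")),
                        provenance={
                            k: row[k]
                            for k in ("formula", "printed_formula", "printed_exact_mass",
                                      "printed_ppm", "identification")
                            if k in row
                        },
                    )
                )
            except (KeyError, ValueError) as exc:
                raise InputError(f"{path}, line {lineno}: {exc}") from exc
    if header is None:
        raise InputError(f"{path}: no header line found")
    return features


def write_feature_table(features: Sequence[Ms1Feature], path: Union[str, Path]) -> None:
    path = Path(path)
    rows = []
    for f in features:
        rows.append(
            {
                "feature_id": f.feature_id,
                "metabolite": f.metabolite or "",
                "rt_min": f"{f.rt_min:.2f}",
                "polarity": f.polarity,
                "adduct": f.adduct,
                "mz": f"{f.mz:.5f}",
                "sham_matrices": ",".join(str(c) for c in sorted(f.sham_matrices)),
                "model_matrices": ",".join(str(c) for c in sorted(f.model_matrices)),
            }
        )
    columns = ["feature_id", "metabolite", "rt_min", "polarity", "adduct", "mz",
               "sham_matrices", "model_matrices"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


@dataclass
class Spectrum:
    """One MS2 spectrum keyed by its parent feature id."""

    feature_id: str
    pepmass: float
    charge: int
    peaks: tuple[Ms2Peak, ...]


def read_mgf(path: Union[str, Path]) -> dict[str, Spectrum]:
    """Read an MGF file into spectra keyed by TITLE (feature id).

    Peaks are normalized so the base peak equals 100.  Structural problems
    (unbalanced BEGIN/END IONS, missing PEPMASS) raise :class:`InputError`
    with the offending block index.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"MGF file not found: {path}")
    text = path.read_text(encoding="utf-8")
    begins = text.count("BEGIN IONS")
    ends = text.count("END IONS")
    if begins != ends:
        raise InputError(f"{path}: unterminated MGF block (block {min(begins, ends) + 1})")
    spectra: dict[str, Spectrum] = {}
    if begins == 0:
        return spectra
    with _mgf.MGF(str(path)) as reader:
        for index, spec in enumerate(reader, start=1):
            params = spec.get("params", {})
            title = str(params.get("title", "")).strip()
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise InputError(f"{path}: MGF block {index} lacks PEPMASS")
            if not title:
                raise InputError(f"{path}: MGF block {index} lacks TITLE")
            charges = params.get("charge")
            charge = int(charges[0]) if charges else 1
            mzs = spec["m/z array"]
            intens = spec["intensity array"]
            if len(mzs):
                base = float(max(intens))
                peaks = tuple(
                    Ms2Peak(float(m), float(i) / base * 100.0)
                    for m, i in zip(mzs, intens)
                    if i > 0
                )
            else:
                peaks = ()
            spectra[title] = Spectrum(title, float(params["pepmass"][0]), charge, peaks)
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for spec in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={spec.feature_id}\n")
            fh.write(f"PEPMASS={spec.pepmass:.5f}\n")
            fh.write(f"CHARGE={abs(spec.charge)}{'+' if spec.charge > 0 else '-'}\n")
            for peak in spec.peaks:
                fh.write(f"{peak.mz:.5f} {peak.intensity:.4f}\n")
            fh.write("END IONS\n")


def attach_spectra(
    features: Sequence[Ms1Feature], spectra: Mapping[str, Spectrum]
) -> list[Ms1Feature]:
    """Return features with MS2 peak lists attached by feature id."""
    out = []
    for f in features:
        spec = spectra.get(f.feature_id)
        out.append(replace(f, ms2=spec.peaks) if spec is not None else f)
    return out


def _codes(codes: frozenset[int]) -> str:
    return ",".join(str(c) for c in sorted(codes))


def write_identification_table(
    records: Sequence[IdentificationRecord], path: Union[str, Path]
) -> None:
    """Write the identification table (rows ordered by RT then id)."""
    rows = []
    for rec in sorted(records, key=lambda r: (r.rt_min, r.metabolite_id)):
        adducts = ";".join(
            f"{name}:{mz:.5f}:{ppm:.3f}" for name, mz, ppm in rec.adducts
        )
        top = sorted(
            (a for a in rec.fragments if a.formula is not None),
            key=lambda a: -a.peak.intensity,
        )[:3]
        rows.append(
            {
                "metabolite_id": rec.metabolite_id,
                "rt_min": f"{rec.rt_min:.2f}",
                "formula": rec.formula.hill() if rec.formula else "",
                "neutral_mass": f"{rec.neutral_mass:.5f}" if rec.formula else "",
                "adducts": adducts,
                "path": ">".join(rec.path) if rec.path is not None else "",
                "reaction_label": rec.reaction_label,
                "top_fragments": ";".join(
                    f"{a.peak.mz:.5f}({a.formula.hill()},{a.peak.intensity:.2f})" for a in top
                ),
                "sham_matrices": _codes(rec.sham_matrices),
                "model_matrices": _codes(rec.model_matrices),
                "source_labels": ",".join(rec.source_labels),
            }
        )
    columns = [
        "metabolite_id", "rt_min", "formula", "neutral_mass", "adducts", "path",
        "reaction_label", "top_fragments", "sham_matrices", "model_matrices",
        "source_labels",
    ]
    try:
        pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
    except OSError as exc:  # surface the file path on I/O failure
        raise InputError(f"cannot write identification table to {path}: {exc}") from exc


def read_identification_table(path: Union[str, Path]) -> list[IdentificationRecord]:
    """Read back an identification table written by this package.

    Adduct ppm errors are recomputed from the stored masses rather than
    parsed, so a write/read cycle reproduces the in-memory records (the
    fragment annotations travel in a display column and are not
    reconstructed).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"identification table not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False, dtype=str)
    records = []
    for _, row in df.iterrows():
        formula = Formula.parse(row["formula"]) if row["formula"] else None
        identified = formula is not None and not formula.is_empty()
        formula = formula if identified else None
        adducts = []
        for chunk in filter(None, row["adducts"].split(";")):
            name, mz_text, _ = chunk.rsplit(":", 2)
            mz = float(mz_text)
            if identified:
                ppm = ppm_error(mz, adduct_mz(monoisotopic_mass(formula), name))
            else:
                ppm = float("nan")
            adducts.append((name, mz, ppm))
        if row["path"]:
            path_rules: Optional[tuple[str, ...]] = tuple(row["path"].split(">"))
        else:
            path_rules = () if identified else None
        records.append(
            IdentificationRecord(
                metabolite_id=row["metabolite_id"],
                rt_min=float(row["rt_min"]),
                formula=formula,
                path=path_rules,
                adducts=tuple(adducts),
                sham_matrices=_parse_codes(row.get("sham_matrices", "")),
                model_matrices=_parse_codes(row.get("model_matrices", "")),
                reaction_label=row["reaction_label"],
                source_labels=tuple(filter(None, row.get("source_labels", "").split(","))),
            )
        )
    return records


def write_network(g: nx.DiGraph, path: Union[str, Path]) -> None:
    """Export a metabolic network as a labeled edge-list table."""
    rows = [
        {
            "source": u,
            "target": v,
            "rule": data.get("rule", ""),
            "delta": data.get("delta", ""),
            "source_observed": g.nodes[u].get("observed", False),
            "target_observed": g.nodes[v].get("observed", False),
        }
        for u, v, data in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["source", "target", "rule", "delta",
                                "source_observed", "target_observed"]).to_csv(
        path, sep="\t", index=False
    )


def write_differential_report(results, path: Union[str, Path]) -> None:
    rows = [
        {
            "metabolite_id": r.metabolite_id,
            "sham_only": _codes(r.sham_only),
            "model_only": _codes(r.model_only),
            "status": "concordant" if r.concordant else "differential",
        }
        for r in results
    ]
    pd.DataFrame(rows, columns=["metabolite_id", "sham_only", "model_only", "status"]).to_csv(
        path, sep="\t", index=False
    )


def read_distribution_table(path: Union[str, Path]) -> list[DistributionRecord]:
    """Read (metabolite id, group, comma-separated matrix codes) rows."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"distribution table not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False, dtype=str)
    required = {"metabolite_id", "group", "matrices"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: need columns {sorted(required)}")
    sham: dict[str, frozenset[int]] = {}
    model: dict[str, frozenset[int]] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        mid, grp = row["metabolite_id"], row["group"].strip().lower()
        if mid not in order:
            order.append(mid)
        codes = _parse_codes(row["matrices"])
        if grp == "sham":
            sham[mid] = sham.get(mid, frozenset()) | codes
        elif grp == "model":
            model[mid] = model.get(mid, frozenset()) | codes
        else:
            raise InputError(f"{path}: unknown group {row['group']!r} (expected sham/model)")
    return [
        DistributionRecord(mid, sham.get(mid, frozenset()), model.get(mid, frozenset()))
        for mid in order
    ]


@dataclass
class RunConfig:
    """Tolerances and catalog settings for a pipeline run.

    Defaults: 5 ppm MS1 candidate gate, 10 ppm MS2 fragment tolerance,
    10 ppm / 0.2 min cross-polarity grouping, rule-closure depth 8.
    """

    ms1_tol_ppm: float = 5.0
    frag_tol_ppm: float = 10.0
    rt_tol_min: float = 0.2
    group_tol_ppm: float = 10.0
    parent: str = "C34H42O19"
    rules_path: Optional[str] = None
    max_depth: int = 8
    out_dir: Optional[str] = None
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self):
        for name in ("ms1_tol_ppm", "frag_tol_ppm", "rt_tol_min", "group_tol_ppm"):
            if getattr(self, name) <= 0:
                raise InputError(f"config: {name} must be positive")
        if self.max_depth < 0:
            raise InputError("config: max_depth must be >= 0")
        Formula.parse(self.parent)  # validate early

    def rules(self) -> list[BiotransformationRule]:
        return load_rules(self.rules_path) if self.rules_path else default_rules()


def load_config(path: Union[str, Path]) -> RunConfig:
    """Load a YAML config whose keys override :class:`RunConfig` defaults."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise InputError(f"{path}: unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**data)


@dataclass
class PipelineResult:
    records: list[IdentificationRecord]
    network: nx.DiGraph
    differential: list
    log: list[str]


def run_full_pipeline(
    cfg: RunConfig,
    features: Sequence[Ms1Feature],
    spectra: Optional[Mapping[str, Spectrum]] = None,
) -> PipelineResult:
    """Group, identify, annotate, and difference a feature table end to end."""
    log: list[str] = []

    def stage(msg: str) -> None:
        log.append(msg)
        logger.info(msg)

    parent = Formula.parse(cfg.parent)
    rules = cfg.rules()
    stage(f"closure: parent={parent} rules={len(rules)} max_depth={cfg.max_depth}")
    closure = rule_closure(parent, rules, cfg.max_depth)
    index = ClosureIndex(closure)
    stage(f"closure: {len(closure)} candidate formulas")

    if spectra:
        features = attach_spectra(features, spectra)
    groups = group_features(features, cfg.group_tol_ppm, cfg.rt_tol_min)
    stage(
        f"grouping: {len(features)} features -> {len(groups)} groups "
        f"(tol {cfg.group_tol_ppm} ppm, {cfg.rt_tol_min} min)"
    )
    records = identify(
        groups, index, tol_ppm=cfg.ms1_tol_ppm, frag_tol_ppm=cfg.frag_tol_ppm
    )
    n_id = sum(1 for r in records if r.identified)
    stage(f"identification: {n_id}/{len(records)} groups identified at {cfg.ms1_tol_ppm} ppm")

    network = build_network([r for r in records if r.identified], rules, parent)
    stage(f"network: {network.number_of_nodes()} nodes, {network.number_of_edges()} edges")

    dist_records = [
        DistributionRecord(r.metabolite_id, r.sham_matrices, r.model_matrices)
        for r in records
        if r.sham_matrices or r.model_matrices
    ]
    differential = differential_report(dist_records)
    stage(f"distribution: {sum(1 for d in differential if not d.concordant)} differential")
    return PipelineResult(records, network, differential, log)


def write_pipeline_outputs(result: PipelineResult, out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write the standard output bundle into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "identifications": out_dir / "identifications.tsv",
        "network": out_dir / "network_edges.tsv",
        "differential": out_dir / "differential.tsv",
        "log": out_dir / "pipeline.log",
    }
    write_identification_table(result.records, paths["identifications"])
    write_network(result.network, paths["network"])
    write_differential_report(result.differential, paths["differential"])
    paths["log"].write_text("\n".join(result.log) + "\n", encoding="utf-8")
    return paths
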