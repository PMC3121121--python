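"""End-to-end pipeline: structure -> SASA -> burial graph -> features -> SVM.

:func:`run_pipeline` wires the stages together for one complex and one
mutation table, producing a feature CSV and (when both classes are present)
a cross-validated evaluation report.  Stage failures carry the stage name so
a batch driver can report where a complex went wrong.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .burial import atom_burial_levels, build_contact_graph
from .features import AC_COLUMNS, DBAC_COLUMNS, feature_vector, interface_residues
from .model import DDG_THRESHOLD, HotspotSVM, label_hotspots
from .sasa import DEFAULT_PROBE, EXPOSURE_THRESHOLD, solvate_and_label
from .structure import ChemistryTables, read_pdb

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run (defaults are the published protocol)."""

    pdb_path: str
    side_a: tuple[str, ...]
    side_b: tuple[str, ...]
    mutations_path: str | None = None
    out_dir: str = "."
    probe_radius: float = DEFAULT_PROBE
    exposure_threshold: float = EXPOSURE_THRESHOLD
    contact_pad: float = 2.75
    ddg_threshold: float = DDG_THRESHOLD
    mode: str = "DBAC"
    protocol: str = "loocv"
    leave_n: int = 1
    seed: int = 0
    radius_table: str | None = None
    class_table: str | None = None

    def __post_init__(self) -> None:
        for name in ("probe_radius", "exposure_threshold", "contact_pad"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mode.upper() not in ("DBAC", "AC"):
            raise ValueError(f"unknown feature mode {self.mode!r}")
        if self.protocol not in ("loocv", "leave-n-out"):
            raise ValueError(f"unknown protocol {self.protocol!r}")


def config_from_file(path: str | Path, **overrides) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file.

    Recognised keys mirror the RunConfig fields; ``side_a``/``side_b`` are
    lists of chain ids.  Keyword overrides win over file values.
    """
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    raw.update(overrides)
    raw["side_a"] = tuple(raw.get("side_a", ()))
    raw["side_b"] = tuple(raw.get("side_b", ()))
    return RunConfig(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def read_mutations(path: str | Path) -> pd.DataFrame:
    """Mutation table CSV/TSV: complex, chain, resnum, wt_aa, ddG columns."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"chain", "resnum", "ddG"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns {sorted(missing)}")
    return df


def complex_features(config: RunConfig) -> pd.DataFrame:
    """Feature vectors for the interface residues of one complex."""
    tables = ChemistryTables(config.radius_table, config.class_table)

    def stage(name, fn, *args, **kw):
        t0 = time.time()
        try:
            out = fn(*args, **kw)
        except Exception as exc:
            raise StageError(name, exc) from exc
        log.info("stage %-10s %.2fs", name, time.time() - t0)
        return out

    structure = stage("parse", read_pdb, config.pdb_path,
                      side_a=config.side_a, side_b=config.side_b,
                      tables=tables)
    log.info("parsed %d atoms (%d waters)", len(structure),
             int(structure.water_mask().sum()))
    pruned, flags, _ = stage("sasa", solvate_and_label, structure,
                             probe_radius=config.probe_radius,
                             threshold=config.exposure_threshold)
    log.info("pruned to %d atoms (%d buried waters kept)", len(pruned),
             int(pruned.water_mask().sum()))
    graph = stage("graph", build_contact_graph, pruned, flags,
                  pad=config.contact_pad)
    log.info("%d contact edges", len(graph.edges))
    assignment = stage("burial", atom_burial_levels, graph)

    def _features():
        rows = []
        for rid in interface_residues(pruned, graph):
            fv = feature_vector(pruned, assignment, rid, mode=config.mode)
            chain, resnum, icode = rid
            atoms = pruned.residue_atoms(rid)
            rows.append({"chain": chain, "resnum": resnum, "icode": icode,
                         "resname": pruned.atoms[atoms[0]].residue_name,
                         **fv.to_dict()})
        return pd.DataFrame(rows)

    return stage("features", _features)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline; write features CSV, report JSON and manifest.

    Returns a dict with the output paths and, if a mutation table with both
    classes was supplied, the evaluation summary.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    feats = complex_features(config)

    result: dict = {}
    if config.mutations_path:
        muts = read_mutations(config.mutations_path)
        merged = feats.merge(muts, on=["chain", "resnum"], how="inner")
        if len(merged) == 0:
            raise StageError("merge", ValueError(
                "no mutation rows matched interface residues"))
        merged["label"] = label_hotspots(merged["ddG"], config.ddg_threshold)
        feats = merged
    cols = DBAC_COLUMNS if config.mode.upper() == "DBAC" else AC_COLUMNS
    features_csv = out / "features.csv"
    feats.to_csv(features_csv, index=False)
    result["features_csv"] = str(features_csv)

    if config.mutations_path and feats["label"].nunique() == 2:
        try:
            model = HotspotSVM(feats[cols], ddg=feats["ddG"],
                               threshold=config.ddg_threshold)
            res = model.fit(protocol=config.protocol,
                            leave_n=config.leave_n, seed=config.seed)
        except Exception as exc:
            raise StageError("train-eval", exc) from exc
        report = res.report.as_series().to_dict()
        report["mann_whitney_p"] = res.mann_whitney_p if \
            (res.predictions.any() and not res.predictions.all()) else None
        report["fold_params"] = [list(p) for p in res.fold_params]
        report_json = out / "report.json"
        report_json.write_text(json.dumps(report, indent=2, default=float))
        result["report_json"] = str(report_json)
        result["report"] = report

    manifest = {"config": dataclasses.asdict(config), "version": __version__,
                "n_feature_rows": int(len(feats))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    result["manifest_json"] = str(out / "manifest.json")
    return result
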