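"""End-to-end orchestration: budgets -> mapping -> satisfaction ->
pose scoring/filtering/clustering, with every intermediate written out.

A run is driven by a :class:`RunConfig` (flat key=value file or keyword
construction).  Reports are deterministic: identical config + inputs
reproduce byte-identical output files (timings go to the log, never into
report files).
"""
from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .structio import Assembly, read_structure
from .transforms import RigidTransform
from .xlink import (DEFAULT_REGISTRY, LinkerChemistry, evaluate_satisfaction,
                    map_crosslinks, read_crosslink_table,
                    write_satisfaction_report)
from .pose import (ScoreParams, featurize_poses, filter_poses, read_pose_list,
                   score_poses, scores_frame, truncate_pose_list, ward_cluster)

__all__ = ["RunConfig", "RunReport", "StageError", "run_xl_eval", "load_config"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Configuration of one evaluation run.

    Defaults follow the reference workflow: at least three satisfied
    restraints per pose, zero core clashes, three clusters, and a pose list
    cut to 30 structures.
    """

    receptor_pdb: str = ""
    ligand_pdb: str = ""
    core_pdb: str = ""
    crosslink_table: str = ""
    pose_list: str = ""
    receptor_proteins: tuple[str, ...] = ("receptor",)
    ligand_proteins: tuple[str, ...] = ("ligand",)
    offsets: dict = field(default_factory=dict)
    linker_overrides: dict = field(default_factory=dict)
    min_satisfied: int = 3
    max_clash: int = 0
    clash_cutoff: float = 3.0
    k_clusters: int = 3
    n_keep: int = 30
    count_unmappable: bool = False
    outdir: str = "xlassembly_out"
    seed: int = 0


def load_config(path) -> RunConfig:
    """Parse a flat ``key = value`` config file into a RunConfig."""
    kw: dict = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected key = value")
        key, val = (s.strip() for s in line.split("=", 1))
        if key in ("min_satisfied", "max_clash", "k_clusters", "n_keep", "seed"):
            kw[key] = int(val)
        elif key == "clash_cutoff":
            kw[key] = float(val)
        elif key == "count_unmappable":
            kw[key] = val.lower() in ("1", "true", "yes")
        elif key in ("receptor_proteins", "ligand_proteins"):
            kw[key] = tuple(v.strip() for v in val.split(",") if v.strip())
        elif key == "offsets":  # e.g. "hE2o:-3,hE1o:0"
            kw[key] = {p.split(":")[0].strip(): int(p.split(":")[1])
                       for p in val.split(",") if p.strip()}
        elif key == "linker_overrides":  # e.g. "XL1:spacer=10.0"
            ov = {}
            for part in val.split(","):
                name, spec = part.split(":", 1)
                k2, v2 = spec.split("=", 1)
                ov.setdefault(name.strip(), {})[k2.strip()] = float(v2)
            kw[key] = ov
        else:
            kw[key] = val
    unknown = set(kw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**kw)


@dataclass
class RunReport:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"version": self.version, "config": self.config,
                           "stages": self.stages}, indent=2, sort_keys=True)


def _registry_with_overrides(overrides: dict) -> dict:
    registry = dict(DEFAULT_REGISTRY)
    for name, fields_ in overrides.items():
        base = registry.get(name, LinkerChemistry(name, 0.0))
        registry[name] = LinkerChemistry(
            name,
            spacer_length=fields_.get("spacer", base.spacer_length),
            sidechain_allowance=fields_.get("sidechain", base.sidechain_allowance),
            dynamics_allowance=fields_.get("dynamics", base.dynamics_allowance),
        )
    return registry


def run_xl_eval(cfg: RunConfig, log=None) -> RunReport:
    """Run the cross-link evaluation pipeline described by *cfg*.

    Stages: read inputs -> map cross-links on the receptor+ligand complex
    (per pose when a pose list is given) -> satisfaction report -> pose
    scoring, filtering, truncation and Ward clustering.  Every intermediate
    table is written under ``cfg.outdir``; a structured summary lands in
    ``summary.json``.  Raises :class:`StageError` on the first failing
    stage, leaving earlier outputs in place.
    """
    log = log or sys.stderr
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=_jsonable(asdict(cfg)), version=__version__)
    registry = _registry_with_overrides(cfg.linker_overrides)

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
            print(f"[{name}] done in {time.perf_counter() - t0:.2f}s", file=log)
            return result
        return wrap

    # --- inputs ---------------------------------------------------------
    def load_inputs():
        if not cfg.receptor_pdb:
            raise ValueError("receptor_pdb is required")
        receptor = Assembly.from_structure(read_structure(cfg.receptor_pdb), "r")
        ligand = (Assembly.from_structure(read_structure(cfg.ligand_pdb), "l")
                  if cfg.ligand_pdb else None)
        core = (Assembly.from_structure(read_structure(cfg.core_pdb), "k")
                if cfg.core_pdb else None)
        if not cfg.crosslink_table:
            raise ValueError("crosslink_table is required")
        links = read_crosslink_table(cfg.crosslink_table)
        poses = read_pose_list(cfg.pose_list) if cfg.pose_list else []
        return receptor, ligand, core, links, poses

    receptor, ligand, core, links, poses = stage("inputs")(load_inputs)

    report.stages["inputs"] = {
        "n_links": len(links),
        "n_poses": len(poses),
        "budgets": {name: registry[name].budget
                    for name in sorted({l.linker for l in links})},
    }

    # --- static satisfaction audit (receptor [+ ligand at identity]) ----
    def audit():
        assembly = receptor if ligand is None else Assembly.merge(receptor, ligand)
        assignment = {p: None for p in (*cfg.receptor_proteins, *cfg.ligand_proteins)}
        if ligand is not None:
            rec_labels = receptor.chain_labels
            lig_labels = ligand.chain_labels
            assignment = {**{p: rec_labels for p in cfg.receptor_proteins},
                          **{p: lig_labels for p in cfg.ligand_proteins}}
        mappings = map_crosslinks(assembly, links, assignment,
                                  offsets=cfg.offsets, registry=registry)
        rep = evaluate_satisfaction(mappings, count_unmappable=cfg.count_unmappable)
        write_satisfaction_report(rep, outdir / "satisfaction.tsv")
        return rep

    sat = stage("satisfaction")(audit)
    report.stages["satisfaction"] = {"n_total": sat.n_total,
                                     "n_mappable": sat.n_mappable,
                                     "n_satisfied": sat.n_satisfied}

    # --- pose evaluation -------------------------------------------------
    if poses:
        if ligand is None:
            raise StageError("poses", "pose scoring needs ligand_pdb")
        params = ScoreParams(cfg.min_satisfied, cfg.max_clash, cfg.clash_cutoff)

        def do_scores():
            return score_poses(poses, receptor, ligand, links,
                               receptor_proteins=cfg.receptor_proteins,
                               ligand_proteins=cfg.ligand_proteins,
                               core=core, params=params,
                               offsets=cfg.offsets, registry=registry)

        scores = stage("score-poses")(do_scores)
        passed = filter_poses(scores, cfg.min_satisfied, cfg.max_clash)
        kept = truncate_pose_list([s for s in scores if s.pose_id in set(passed)],
                                  cfg.n_keep)

        def do_cluster():
            if len(kept) < 1:
                return None
            keep_poses = [p for p in poses if p.pose_id in set(kept)]
            feats = featurize_poses(keep_poses, ligand)
            k = min(cfg.k_clusters, len(keep_poses))
            return ward_cluster(feats, k, [p.pose_id for p in keep_poses])

        clusters = stage("cluster")(do_cluster)
        scores_frame(scores, clusters).to_csv(outdir / "pose_scores.tsv",
                                              sep="\t", index=False)
        report.stages["poses"] = {
            "n_scored": len(scores),
            "n_passed": len(passed),
            "n_kept": len(kept),
            "passed_ids": passed,
            "ranked_kept": kept,
        }
        if clusters is not None:
            report.stages["cluster"] = {
                "k": clusters.k,
                "labels": clusters.labels,
                "representatives": {str(c): p for c, p in
                                    sorted(clusters.representatives.items())},
            }

    (outdir / "summary.json").write_text(report.to_json() + "\n")
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj
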