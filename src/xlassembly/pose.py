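"""Docking-pose evaluation: restraint satisfaction, clash screening,
filtering, Ward clustering and representative selection.

Poses are rigid placements of a ligand assembly (e.g. an E1 dimer) relative
to a receptor assembly (e.g. an E2 trimer), produced externally by a docking
engine or synthetically.  Each pose is scored by (i) how many cross-link
distance restraints it satisfies (minimum over symmetry copies, via
:mod:`xlassembly.xlink`) and (ii) how many steric collisions it makes with
the receptor or with a larger core assembly.  Passing poses are
hierarchically clustered (Ward linkage) on their ligand Calpha coordinates
in the receptor frame, and each cluster is represented by its medoid.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform, pdist

from .structio import Assembly, Selection, select_atoms
from .transforms import RigidTransform
from .xlink import (ConfigurationError, CrossLink, DEFAULT_REGISTRY,
                    LinkerChemistry, evaluate_satisfaction, map_crosslinks)

__all__ = [
    "Pose",
    "PoseScore",
    "ScoreParams",
    "ClusterAssignment",
    "score_pose",
    "score_poses",
    "filter_poses",
    "featurize_poses",
    "ward_cluster",
    "truncate_pose_list",
    "read_pose_list",
    "write_pose_list",
    "scores_frame",
]


@dataclass(frozen=True)
class Pose:
    """A rigid placement of the ligand assembly in the receptor frame."""

    pose_id: str
    transform: RigidTransform
    provenance: str = ""

    def __post_init__(self):
        self.transform.require_proper()


@dataclass(frozen=True)
class ScoreParams:
    """Pose acceptance thresholds.

    ``min_satisfied`` defaults to 3 restraints, ``max_clash`` to 0 collisions
    with the core, and a collision is an inter-assembly Calpha pair closer
    than ``clash_cutoff`` (A).
    """

    min_satisfied: int = 3
    max_clash: int = 0
    clash_cutoff: float = 3.0


@dataclass
class PoseScore:
    pose_id: str
    n_satisfied: int
    n_mappable: int
    clash_count: int
    passed: bool


@dataclass
class ClusterAssignment:
    """Ward clustering of poses cut at k clusters.

    ``labels`` maps pose_id to a 0-based cluster index (indices ordered by
    first occurrence in pose order); ``merge_tree`` lists the merges applied
    to reach the cut as (member_a, member_b, ward_height, new_size);
    ``representatives`` maps cluster index to its medoid pose_id.
    """

    labels: dict[str, int]
    merge_tree: list[tuple[int, int, float, int]]
    k: int
    representatives: dict[int, str] = field(default_factory=dict)


def score_pose(
    pose: Pose,
    receptor: Assembly,
    ligand: Assembly,
    links: Sequence[CrossLink],
    *,
    receptor_proteins,
    ligand_proteins,
    core: Assembly | None = None,
    params: ScoreParams = ScoreParams(),
    offsets: Mapping[str, int] | None = None,
    registry: Mapping[str, LinkerChemistry] = DEFAULT_REGISTRY,
) -> PoseScore:
    """Score one pose against cross-link restraints and core clashes.

    *receptor_proteins* / *ligand_proteins* name the link proteins living on
    each side, either as an iterable (all chains of that side) or a mapping
    protein -> chain labels.  Clashes are counted between the posed ligand
    Calphas and the *core* assembly if given, else the receptor.
    """
    posed = ligand.transformed(pose.transform)
    merged = Assembly.merge(receptor.relabeled("R/"), posed.relabeled("L/"))
    rec_side = {p: ([f"R/{c.copy_id}.{ch.chain_id}" for c in receptor.copies
                     for ch in c.structure.chains(0)] if chains is None else
                    [f"R/{c}" for c in chains])
                for p, chains in _as_mapping(receptor_proteins).items()}
    lig_side = {p: ([f"L/{c.copy_id}.{ch.chain_id}" for c in ligand.copies
                     for ch in c.structure.chains(0)] if chains is None else
                    [f"L/{c}" for c in chains])
                for p, chains in _as_mapping(ligand_proteins).items()}
    overlap = set(rec_side) & set(lig_side)
    if overlap:
        raise ConfigurationError(f"proteins assigned to both sides: {sorted(overlap)}")
    assignment = {**rec_side, **lig_side}
    for link in links:
        for prot in (link.protein_a, link.protein_b):
            if prot not in assignment:
                raise ConfigurationError(f"protein {prot!r} not assigned to receptor or ligand")
    mappings = map_crosslinks(merged, links, assignment, offsets=offsets, registry=registry)
    report = evaluate_satisfaction(mappings)

    clash_ref = core if core is not None else receptor
    lig_ca = posed.coords()[select_atoms(posed, Selection(element_class="ca"))]
    ref_ca = clash_ref.coords()[select_atoms(clash_ref, Selection(element_class="ca"))]
    clash_count = 0
    if len(lig_ca) and len(ref_ca):
        tree = cKDTree(ref_ca)
        for idxs, pt in zip(tree.query_ball_point(lig_ca, params.clash_cutoff), lig_ca):
            for j in idxs:
                if float(np.linalg.norm(ref_ca[j] - pt)) < params.clash_cutoff:
                    clash_count += 1
    passed = report.n_satisfied >= params.min_satisfied and clash_count <= params.max_clash
    return PoseScore(pose.pose_id, report.n_satisfied, report.n_mappable, clash_count, passed)


def _as_mapping(proteins) -> Mapping:
    return proteins if isinstance(proteins, Mapping) else {p: None for p in proteins}


def score_poses(poses: Sequence[Pose], receptor: Assembly, ligand: Assembly,
                links: Sequence[CrossLink], **kwargs) -> list[PoseScore]:
    return [score_pose(p, receptor, ligand, links, **kwargs) for p in poses]


def filter_poses(scores: Sequence[PoseScore], min_satisfied: int = 3,
                 max_clash: int = 0) -> list[str]:
    """Pose ids meeting both thresholds, input order preserved."""
    return [s.pose_id for s in scores
            if s.n_satisfied >= min_satisfied and s.clash_count <= max_clash]


def featurize_poses(poses: Sequence[Pose], ligand: Assembly,
                    selection: Selection | None = None) -> np.ndarray:
    """One row per pose: flattened ligand Calpha coordinates in the receptor
    frame (clustering on this feature makes Ward distance a rigid-motion-
    meaningful quantity)."""
    if not poses:
        raise ValueError("need at least one pose")
    sel = selection if selection is not None else Selection(element_class="ca")
    idx = select_atoms(ligand, sel)
    if idx.size == 0:
        raise ValueError("pose featurization selection is empty")
    base = ligand.coords()[idx]
    return np.stack([p.transform.apply(base).ravel() for p in poses])


def ward_cluster(features: np.ndarray, k: int,
                 pose_ids: Sequence[str] | None = None) -> ClusterAssignment:
    """Agglomerative Ward clustering of pose features, cut at *k* clusters.

    Representatives are medoids (minimum summed within-cluster Euclidean
    distance; ties broken by lowest pose index).
    """
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if pose_ids is None:
        pose_ids = [str(i) for i in range(n)]
    if len(pose_ids) != n:
        raise ValueError("pose_ids length mismatch")

    if n == 1:
        raw = np.array([0])
        Z = np.zeros((0, 4))
    else:
        Z = linkage(features, method="ward")
        raw = fcluster(Z, t=k, criterion="maxclust") - 1
    # relabel clusters by first occurrence so output is row-order deterministic
    remap: dict[int, int] = {}
    labels_arr = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        if c not in remap:
            remap[c] = len(remap)
        labels_arr[i] = remap[c]

    merge_tree = [(int(a), int(b), float(h), int(sz))
                  for a, b, h, sz in Z[: n - k]]

    dist = squareform(pdist(features)) if n > 1 else np.zeros((1, 1))
    representatives: dict[int, str] = {}
    for c in range(labels_arr.max() + 1):
        members = np.flatnonzero(labels_arr == c)
        sums = dist[np.ix_(members, members)].sum(axis=1)
        representatives[c] = pose_ids[members[int(np.argmin(sums))]]

    return ClusterAssignment(
        labels={pid: int(lb) for pid, lb in zip(pose_ids, labels_arr)},
        merge_tree=merge_tree,
        k=int(labels_arr.max() + 1),
        representatives=representatives,
    )


def truncate_pose_list(scores: Sequence[PoseScore], n_keep: int = 30) -> list[str]:
    """Keep the best *n_keep* poses under the fixed total order
    (n_satisfied desc, clash_count asc, pose_id asc) — reproducible cut."""
    ranked = sorted(scores, key=lambda s: (-s.n_satisfied, s.clash_count, s.pose_id))
    return [s.pose_id for s in ranked[:n_keep]]


# ---------------------------------------------------------------------------
# I/O: pose lists and score reports


def write_pose_list(poses: Sequence[Pose], path) -> None:
    lines = []
    for p in poses:
        nums = " ".join(f"{v:.17g}" for v in p.transform.to_flat())
        lines.append(f"{p.pose_id} {nums}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pose_list(path) -> list[Pose]:
    poses = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 13:
            raise ValueError(f"{path}:{ln}: expected pose_id + 12 numbers")
        poses.append(Pose(parts[0], RigidTransform.from_flat([float(v) for v in parts[1:]]),
                          provenance=f"{Path(path).name}:{ln}"))
    return poses


def scores_frame(scores: Sequence[PoseScore],
                 clusters: ClusterAssignment | None = None) -> pd.DataFrame:
    rows = []
    for s in scores:
        row = {"pose_id": s.pose_id, "n_satisfied": s.n_satisfied,
               "n_mappable": s.n_mappable, "clash_count": s.clash_count,
               "passed": s.passed}
        if clusters is not None:
            row["cluster"] = clusters.labels.get(s.pose_id, -1)
        rows.append(row)
    return pd.DataFrame(rows)
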