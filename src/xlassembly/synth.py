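"""Seeded generators of toy assemblies, planted poses with consistent
cross-link sets, decoy poses, and noise trajectories with known fluctuation
structure.

These stand in for the real inputs of the pipeline — homo-oligomeric
protein assemblies, docking pose lists, and MD trajectories — with planted
ground truth so every downstream stage can be tested for recovery.  All
generators are pure functions of (spec, seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .pose import Pose
from .structio import Assembly, Atom, Chain, Residue, Structure, build_assembly
from .transforms import RigidTransform
from .xlink import CrossLink, DSBU, LinkerChemistry

__all__ = [
    "SynthSpec",
    "GenerationError",
    "make_toy_chain",
    "make_toy_assembly",
    "plant_pose_and_links",
    "generate_decoy_poses",
    "simulate_noise_trajectory",
    "random_rigid_transform",
    "write_synthetic_fixture",
    "anchor_residues",
    "DEFAULT_PLANTED_TRANSFORM",
]

ANCHOR_PERIOD = 10  # every 10th residue is a Lys-like cross-linkable anchor


class GenerationError(RuntimeError):
    """A generator could not satisfy its construction constraints."""


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic study conditions.

    Defaults mirror the scale of the real problem within desk-scale reach:
    multi-chain assemblies with periodic Lys anchors, a handful of true
    cross-links plus a couple of false positives, twenty decoy poses
    displaced by at least 50 A, and Gaussian-fluctuation trajectories.
    """

    seed: int = 0
    chain_length: int = 100
    n_chains: int = 3
    geometry: str = "helix"  # extended | helix | bead-spring
    noise_sigma: float = 0.5
    n_frames: int = 2000
    n_true_links: int = 5
    n_false_links: int = 2
    decoy_count: int = 20
    min_displacement: float = 50.0

    def __post_init__(self):
        if self.chain_length < 5:
            raise ValueError("chain_length must be >= 5")
        for attr in ("n_chains", "n_frames", "n_true_links", "n_false_links",
                     "decoy_count"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.geometry not in ("extended", "helix", "bead-spring"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _ca_trace(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.chain_length
    if spec.geometry == "extended":
        # straight trace at the canonical 3.8 A Calpha spacing
        return np.stack([3.8 * np.arange(n), np.zeros(n), np.zeros(n)], axis=1)
    if spec.geometry == "helix":
        # ideal alpha-helix Calpha geometry: radius 2.3 A, rise 1.5 A, 100 deg/res
        theta = np.deg2rad(100.0) * np.arange(n)
        return np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta),
                         1.5 * np.arange(n)], axis=1)
    # bead-spring: random walk with fixed 3.8 A steps, mild self-avoidance bias
    pts = [np.zeros(3)]
    direction = np.array([1.0, 0.0, 0.0])
    for _ in range(n - 1):
        step = direction + 0.8 * rng.standard_normal(3)
        direction = step / np.linalg.norm(step)
        pts.append(pts[-1] + 3.8 * direction)
    return np.array(pts)


def make_toy_chain(spec: SynthSpec, chain_id: str = "A") -> Structure:
    """One poly-alanine-like chain with Lys-like anchors every 10th residue.

    Residues carry a minimal backbone (N, CA, C, O) placed at small fixed
    offsets from the Calpha trace; residues at positions 10, 20, ... are
    named LYS so linker chemistries recognise them as reactive anchors.
    """
    rng = np.random.default_rng(spec.seed)
    trace = _ca_trace(spec, rng)
    chain = Chain(chain_id=chain_id)
    serial = 0
    offsets = {"N": np.array([-0.5, 0.9, 0.0]), "C": np.array([0.9, -0.6, 0.3]),
               "O": np.array([1.1, -1.1, 1.2])}
    for i, ca in enumerate(trace):
        seq = i + 1
        res_name = "LYS" if seq % ANCHOR_PERIOD == 0 else "ALA"
        res = Residue(chain_id, seq, "", res_name)
        for name in ("N", "CA", "C", "O"):
            serial += 1
            pos = ca if name == "CA" else ca + offsets[name]
            element = "C" if name in ("CA", "C") else name
            res.atoms.append(Atom(serial, name, element, pos))
        chain.residues.append(res)
    return Structure(models=[[chain]], title=f"toy-{spec.geometry}")


def make_toy_assembly(spec: SynthSpec, spacing: float = 20.0) -> Assembly:
    """A homo-oligomer of ``n_chains`` toy chains related by rigid transforms.

    Copies are arranged on a ring of radius *spacing* about the z axis
    (one copy sits at the origin untransformed when n_chains == 1), so
    inter-copy geometry is non-trivial but clash-free.
    """
    chain = make_toy_chain(spec)
    transforms = []
    for k in range(spec.n_chains):
        ang = 2 * math.pi * k / max(spec.n_chains, 1)
        R = Rotation.from_euler("z", ang).as_matrix()
        t = spacing * np.array([math.cos(ang), math.sin(ang), 0.0]) if spec.n_chains > 1 \
            else np.zeros(3)
        transforms.append(RigidTransform(R, t))
    return build_assembly(chain, transforms)


def anchor_residues(assembly: Assembly) -> list[tuple[str, int]]:
    """(chain_label, seq_num) of every Lys-like anchor with a Calpha."""
    out = []
    seen = set()
    for fa in assembly.flat_atoms():
        if fa.res_name == "LYS" and fa.atom_name == "CA":
            key = (fa.chain_label, fa.seq_num)
            if key not in seen:
                seen.add(key)
                out.append(key)
    return out


def plant_pose_and_links(
    receptor: Assembly,
    ligand: Assembly,
    transform: RigidTransform,
    linker: LinkerChemistry = DSBU,
    n_true: int = 5,
    n_false: int = 2,
    seed: int = 0,
    receptor_protein: str = "receptor",
    ligand_protein: str = "ligand",
    false_margin: float = 10.0,
) -> tuple[Pose, list[CrossLink]]:
    """Plant a pose and sample geometrically consistent + false cross-links.

    True links are anchor pairs whose minimum-over-copies Calpha distance at
    the planted pose is within the linker budget; false links are pairs
    whose minimum distance exceeds budget + *false_margin* (so they stay
    unsatisfied even under the inclusive comparison).
    """
    rng = np.random.default_rng(seed)
    posed = ligand.transformed(transform)
    rec_anchors = anchor_residues(receptor)
    lig_anchors = anchor_residues(posed)
    budget = linker.budget

    # minimum-over-copies distance per residue-number pair (homo-oligomer
    # ambiguity: mapping sees only residue numbers, not copies)
    rec_by_res: dict[int, list[np.ndarray]] = {}
    for label, seq in rec_anchors:
        rec_by_res.setdefault(seq, []).append(receptor.ca_coord(label, seq))
    lig_by_res: dict[int, list[np.ndarray]] = {}
    for label, seq in lig_anchors:
        lig_by_res.setdefault(seq, []).append(posed.ca_coord(label, seq))

    true_pool, false_pool = [], []
    for ra, pa in rec_by_res.items():
        for rb, pb in lig_by_res.items():
            dmin = min(float(np.linalg.norm(x - y)) for x in pa for y in pb)
            if dmin <= budget:
                true_pool.append((ra, rb))
            elif dmin > budget + false_margin:
                false_pool.append((ra, rb))
    if len(true_pool) < n_true:
        raise GenerationError(
            f"only {len(true_pool)} anchor pairs under the {budget:.1f} A budget "
            f"at the planted pose; need {n_true}")
    if len(false_pool) < n_false:
        raise GenerationError(
            f"only {len(false_pool)} anchor pairs beyond budget+{false_margin:.0f} A; "
            f"need {n_false}")

    links: list[CrossLink] = []
    for ra, rb in map(tuple, rng.permutation(np.array(true_pool))[:n_true]):
        links.append(CrossLink(receptor_protein, int(ra), ligand_protein, int(rb),
                               linker.name, source_row="planted:true"))
    for ra, rb in map(tuple, rng.permutation(np.array(false_pool))[:n_false]):
        links.append(CrossLink(receptor_protein, int(ra), ligand_protein, int(rb),
                               linker.name, source_row="planted:false"))
    return Pose("planted", transform, provenance="synthetic planted pose"), links


def random_rigid_transform(rng: np.random.Generator,
                           max_translation: float = 0.0) -> RigidTransform:
    """Uniform random rotation (quaternion sampling) + uniform-in-ball
    translation of magnitude <= max_translation."""
    R = Rotation.from_quat(_uniform_quaternion(rng)).as_matrix()
    if max_translation > 0:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        t = direction * max_translation * rng.uniform() ** (1 / 3)
    else:
        t = np.zeros(3)
    return RigidTransform(R, t)


def _uniform_quaternion(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    return q / np.linalg.norm(q)


def _count_satisfied_at(receptor: Assembly, posed_ligand: Assembly,
                        links, registry=None) -> int:
    """Satisfied-link count for links running receptor(res_a) -> ligand(res_b),
    with minimum-over-copies ambiguity resolution."""
    from .xlink import DEFAULT_REGISTRY

    registry = registry or DEFAULT_REGISTRY
    rec_by_res: dict[int, list[np.ndarray]] = {}
    for label, seq in anchor_residues(receptor):
        rec_by_res.setdefault(seq, []).append(receptor.ca_coord(label, seq))
    lig_by_res: dict[int, list[np.ndarray]] = {}
    for label, seq in anchor_residues(posed_ligand):
        lig_by_res.setdefault(seq, []).append(posed_ligand.ca_coord(label, seq))
    n_sat = 0
    for link in links:
        pa = rec_by_res.get(link.res_a, [])
        pb = lig_by_res.get(link.res_b, [])
        if not pa or not pb:
            continue
        dmin = min(float(np.linalg.norm(x - y)) for x in pa for y in pb)
        if dmin <= registry[link.linker].budget:
            n_sat += 1
    return n_sat


def generate_decoy_poses(receptor: Assembly, ligand: Assembly, n: int,
                         min_displacement: float = 50.0, seed: int = 0,
                         reference: RigidTransform | None = None,
                         links=None, max_satisfied: int = 2,
                         max_attempts: int = 200) -> list[Pose]:
    """Random decoy poses displaced >= *min_displacement* from a reference.

    Rotations are uniform (quaternion sampling); translations point in a
    uniform random direction with magnitude uniform in
    [min_displacement, 2 x min_displacement] from the reference translation.

    When *links* (planted ground truth) is given, each decoy is additionally
    required to satisfy at most *max_satisfied* of them — a decoy is by
    definition inconsistent with the planted truth, and for an extended
    ligand a large displacement alone cannot guarantee that.  Candidates
    violating the bound are redrawn from the same seeded stream, keeping the
    output a pure function of the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ref = reference if reference is not None else RigidTransform.identity()
    poses = []
    for i in range(n):
        for _ in range(max_attempts):
            R = Rotation.from_quat(_uniform_quaternion(rng)).as_matrix()
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            mag = rng.uniform(min_displacement, 2.0 * min_displacement)
            t = ref.translation + mag * direction
            transform = RigidTransform(R, t)
            if links is not None and _count_satisfied_at(
                    receptor, ligand.transformed(transform), links) > max_satisfied:
                continue
            break
        else:
            raise GenerationError(
                f"could not draw a decoy inconsistent with the planted links "
                f"in {max_attempts} attempts")
        poses.append(Pose(f"decoy{i:03d}", transform,
                          provenance=f"synthetic decoy (seed={seed})"))
    return poses


def simulate_noise_trajectory(s: Structure, sigma_profile, n_frames: int,
                              seed: int = 0, rigid_wobble: bool = False,
                              wobble_angle_deg: float = 5.0,
                              wobble_translation: float = 2.0) -> "Trajectory":
    """Equilibrium structure + iid per-axis Gaussian displacement per frame.

    *sigma_profile* is a scalar or per-atom array of per-axis standard
    deviations (A), so the expected per-atom RMSF is sigma * sqrt(3).  With
    *rigid_wobble* each frame additionally receives a random global rigid
    motion, exercising superposition in downstream statistics.
    """
    from .dynamics import Trajectory

    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    base = s.coords(0)
    n_atoms = base.shape[0]
    sigma = np.broadcast_to(np.asarray(sigma_profile, dtype=float), (n_atoms,)).copy()
    if np.any(sigma < 0):
        raise ValueError("sigma_profile must be non-negative")
    rng = np.random.default_rng(seed)
    frames = base[None, :, :] + rng.standard_normal((n_frames, n_atoms, 3)) * sigma[None, :, None]
    if rigid_wobble:
        for f in range(n_frames):
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            ang = np.deg2rad(rng.uniform(-wobble_angle_deg, wobble_angle_deg))
            R = Rotation.from_rotvec(ang * axis).as_matrix()
            t = rng.uniform(-wobble_translation, wobble_translation, size=3)
            frames[f] = frames[f] @ R.T + t
    topo = Structure(models=[s.models[0]], title=s.title)
    return Trajectory(topo, frames)


DEFAULT_PLANTED_TRANSFORM = RigidTransform(np.eye(3), np.array([48.0, 0.0, 0.0]))
"""Planted placement used by the packaged fixture: the ligand oligomer sits
beside the receptor ring, close enough for abundant under-budget anchor
pairs but clash-free at the Calpha level."""


def write_synthetic_fixture(outdir, seed: int = 0, chain_length: int = 100,
                            n_true: int = 5, n_false: int = 2,
                            n_decoys: int = 20,
                            min_displacement: float = 50.0) -> dict[str, str]:
    """Write a complete on-disk fixture for the end-to-end pipeline.

    Produces receptor (trimer) and ligand (dimer) PDBs, a pose list with the
    planted pose first followed by decoys, a cross-link table with ``n_true``
    consistent plus ``n_false`` false-positive DSBU links, and a ready-to-run
    flat config file.  Returns the path of each artefact.
    """
    from pathlib import Path

    from .pose import write_pose_list
    from .structio import write_structure
    from .xlink import write_crosslink_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    receptor = make_toy_assembly(SynthSpec(seed=seed, chain_length=chain_length,
                                           n_chains=3))
    ligand = make_toy_assembly(SynthSpec(seed=seed + 1, chain_length=chain_length,
                                         n_chains=2))
    planted, links = plant_pose_and_links(receptor, ligand,
                                          DEFAULT_PLANTED_TRANSFORM,
                                          n_true=n_true, n_false=n_false,
                                          seed=seed)
    decoys = generate_decoy_poses(receptor, ligand, n_decoys,
                                  min_displacement=min_displacement, seed=seed,
                                  reference=planted.transform, links=links)
    paths = {
        "receptor_pdb": str(outdir / "receptor.pdb"),
        "ligand_pdb": str(outdir / "ligand.pdb"),
        "pose_list": str(outdir / "poses.txt"),
        "crosslink_table": str(outdir / "links.tsv"),
        "config": str(outdir / "run.cfg"),
    }
    write_structure(receptor.to_structure(title="synthetic receptor trimer"),
                    paths["receptor_pdb"])
    write_structure(ligand.to_structure(title="synthetic ligand dimer"),
                    paths["ligand_pdb"])
    write_pose_list([planted, *decoys], paths["pose_list"])
    write_crosslink_table(links, paths["crosslink_table"])
    Path(paths["config"]).write_text(
        "\n".join([
            f"receptor_pdb = {paths['receptor_pdb']}",
            f"ligand_pdb = {paths['ligand_pdb']}",
            f"pose_list = {paths['pose_list']}",
            f"crosslink_table = {paths['crosslink_table']}",
            "receptor_proteins = receptor",
            "ligand_proteins = ligand",
            f"seed = {seed}",
            f"outdir = {outdir / 'run'}",
        ]) + "\n")
    return paths
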