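"""Trajectory and elastic-network analyses.

Implements the dynamics observables used to characterise assembly models:
least-squares (Kabsch) superposition and RMSD series, per-atom RMSF about
the mean structure, fraction of native contacts Q, inter-group contact
frequency maps, hydrogen-bond occupancy, anisotropic-network-model (ANM)
normal modes with mode animation, and PCA of the positional covariance.

A trajectory is an ordered set of frames over one topology; multi-model PDB
is the canonical interchange format.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structio import (Chain, FlatAtom, Residue, Selection, Structure,
                       StructureError, select_atoms)
from .transforms import RigidTransform

__all__ = [
    "Trajectory",
    "ContactSet",
    "ModeSet",
    "HBondRecord",
    "PCAResult",
    "DegenerateGeometryError",
    "superpose",
    "rmsd_series",
    "rmsf",
    "native_contacts",
    "q_series",
    "contact_map",
    "hbond_census",
    "anm_modes",
    "mode_trajectory",
    "pca_projection",
]


class DegenerateGeometryError(ValueError):
    """Too few or collinear points for a unique superposition."""


@dataclass
class Trajectory:
    """Ordered frames sharing one topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in Angstrom; the topology is
    a single-model reference Structure.  ``frame_interval`` is metadata only.
    """

    topology: Structure
    frames: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms(0):
            raise StructureError(
                f"frames carry {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms(0)}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def flat_atoms(self) -> list[FlatAtom]:
        return self.topology.flat_atoms(0)

    @classmethod
    def from_structure(cls, s: Structure, frame_interval: float = 1.0) -> "Trajectory":
        """Build from a multi-model Structure (models = frames)."""
        s.validate_shared_topology()
        frames = np.stack([s.coords(m) for m in range(s.n_models)])
        topo = Structure(models=[s.models[0]], title=s.title)
        return cls(topo, frames, frame_interval)

    def to_structure(self) -> Structure:
        """Flatten back to a multi-model Structure for PDB writing."""
        models = []
        for f in range(self.n_frames):
            chains = []
            i = 0
            for chain in self.topology.chains(0):
                new = Chain(chain.chain_id)
                for res in chain.residues:
                    nr = Residue(res.chain_id, res.seq_num, res.icode, res.res_name)
                    for atom in res.atoms:
                        a = type(atom)(atom.serial, atom.name, atom.element,
                                       self.frames[f, i], atom.occupancy,
                                       atom.bfactor, atom.is_hetero)
                        nr.atoms.append(a)
                        i += 1
                    new.residues.append(nr)
                chains.append(new)
            models.append(chains)
        return Structure(models=models, title=self.topology.title)


# ---------------------------------------------------------------------------
# Superposition (Kabsch)


def superpose(mobile: np.ndarray, reference: np.ndarray,
              weights: np.ndarray | None = None) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of *mobile* onto *reference*.

    Returns the proper rigid transform (reflections excluded) minimising the
    weighted squared deviation, and the post-fit RMSD (A).  Requires >= 3
    non-collinear points.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and reference must both be (N, 3)")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 points to superpose")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cP = (w[:, None] * P).sum(axis=0)
    cQ = (w[:, None] * Q).sum(axis=0)
    P0, Q0 = P - cP, Q - cQ
    if np.linalg.matrix_rank(Q0, tol=1e-9) < 2:
        raise DegenerateGeometryError("reference points are collinear")
    H = (w[:, None] * P0).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cQ - R @ cP
    moved = P @ R.T + t
    rmsd = float(np.sqrt((w * ((moved - Q) ** 2).sum(axis=1)).sum()))
    return RigidTransform(R, t), rmsd


def rmsd_series(t: Trajectory, reference: int = 0,
                sel: Selection | str | None = None) -> np.ndarray:
    """Per-frame RMSD to a reference frame after per-frame superposition
    over the selection."""
    idx = select_atoms(t, sel)
    if idx.size == 0:
        raise ValueError("rmsd_series selection is empty")
    ref = t.frames[reference][idx]
    out = np.empty(t.n_frames)
    for f in range(t.n_frames):
        _, out[f] = superpose(t.frames[f][idx], ref)
    return out


def _superpose_frames(frames: np.ndarray) -> np.ndarray:
    """Two-pass superposition: fit all frames to frame 0, then re-fit to the
    mean structure (the standard fluctuation reference)."""
    aligned = np.empty_like(frames)
    ref = frames[0]
    for f in range(frames.shape[0]):
        tr, _ = superpose(frames[f], ref)
        aligned[f] = tr.apply(frames[f])
    mean = aligned.mean(axis=0)
    for f in range(frames.shape[0]):
        tr, _ = superpose(frames[f], mean)
        aligned[f] = tr.apply(frames[f])
    return aligned


def rmsf(t: Trajectory, sel: Selection | str | None = None,
         reference: str = "mean") -> np.ndarray:
    """Per-atom root-mean-square fluctuation (A) over the trajectory.

    Frames are superposed over the selection onto the mean structure
    (two-pass) or onto frame 0 (``reference="frame0"``); the fluctuation is
    then measured about the per-atom mean position.
    """
    if t.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = select_atoms(t, sel)
    if idx.size == 0:
        raise ValueError("rmsf selection is empty")
    sub = t.frames[:, idx, :]
    if reference == "mean":
        aligned = _superpose_frames(sub)
    elif reference == "frame0":
        aligned = np.empty_like(sub)
        for f in range(sub.shape[0]):
            tr, _ = superpose(sub[f], sub[0])
            aligned[f] = tr.apply(sub[f])
    else:
        raise ValueError(f"unknown RMSF reference {reference!r}")
    mean = aligned.mean(axis=0)
    return np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))


# ---------------------------------------------------------------------------
# Native contacts and contact maps


@dataclass
class ContactSet:
    """Residue pairs in contact in the native (reference) frame.

    ``pairs`` holds (i, j, native minimum heavy-atom distance) with i < j in
    global residue order; intra-chain pairs respect ``min_seq_sep`` measured
    in residue positions along the chain.
    """

    pairs: list[tuple[int, int, float]]
    cutoff: float
    min_seq_sep: int
    residue_keys: list[tuple[str, int, str]] = field(default_factory=list)


def _residue_heavy_groups(flat: Sequence[FlatAtom]):
    """Group heavy-atom indices by residue, preserving flat order.

    Returns (keys, groups, chain_pos) where chain_pos[i] = (chain, position
    along chain) for sequence-separation tests.
    """
    keys: list[tuple[str, int, str]] = []
    groups: list[list[int]] = []
    chain_pos: list[tuple[str, int]] = []
    pos_in_chain: dict[str, int] = {}
    seen: dict[tuple[str, int, str], int] = {}
    for fa in flat:
        if fa.element == "H":
            continue
        key = (fa.chain_label, fa.seq_num, fa.icode)
        if key not in seen:
            seen[key] = len(keys)
            keys.append(key)
            groups.append([])
            p = pos_in_chain.get(fa.chain_label, 0)
            chain_pos.append((fa.chain_label, p))
            pos_in_chain[fa.chain_label] = p + 1
        groups[seen[key]].append(fa.index)
    return keys, groups, chain_pos


def native_contacts(source, frame: int = 0, cutoff: float = 4.5,
                    min_seq_sep: int = 3, scope: str = "both") -> ContactSet:
    """Residue contacts of the native (reference) frame.

    *source* is a Trajectory or a single-model Structure.  A pair (i, j) is
    a contact iff its minimum heavy-atom distance is <= *cutoff* and, within
    a chain, the residues are at least *min_seq_sep* positions apart.
    *scope* restricts pairs to ``intra``-chain, ``inter``-chain, or ``both``.
    """
    if scope not in ("intra", "inter", "both"):
        raise ValueError(f"unknown scope {scope!r}")
    flat, coords = _flat_and_coords(source, frame)
    keys, groups, chain_pos = _residue_heavy_groups(flat)
    atom2res = {}
    for ri, grp in enumerate(groups):
        for ai in grp:
            atom2res[ai] = ri
    heavy_idx = np.array(sorted(atom2res), dtype=int)
    if heavy_idx.size == 0:
        return ContactSet([], cutoff, min_seq_sep, keys)
    tree = cKDTree(coords[heavy_idx])
    best: dict[tuple[int, int], float] = {}
    for a, b in tree.query_pairs(cutoff):
        ia, ib = int(heavy_idx[a]), int(heavy_idx[b])
        ri, rj = atom2res[ia], atom2res[ib]
        if ri == rj:
            continue
        if ri > rj:
            ri, rj = rj, ri
        d = float(np.linalg.norm(coords[ia] - coords[ib]))
        if d < best.get((ri, rj), math.inf):
            best[(ri, rj)] = d
    pairs = []
    for (ri, rj), d in sorted(best.items()):
        ca, pa = chain_pos[ri]
        cb, pb = chain_pos[rj]
        same_chain = ca == cb
        if same_chain and abs(pa - pb) < min_seq_sep:
            continue
        if scope == "intra" and not same_chain:
            continue
        if scope == "inter" and same_chain:
            continue
        pairs.append((ri, rj, d))
    return ContactSet(pairs, cutoff, min_seq_sep, keys)


def _flat_and_coords(source, frame: int):
    if isinstance(source, Trajectory):
        return source.flat_atoms(), source.frames[frame]
    if isinstance(source, Structure):
        return source.flat_atoms(frame), source.coords(frame)
    # Assembly quacks the same way
    return source.flat_atoms(), source.coords()


def q_series(t: Trajectory, contacts: ContactSet, tolerance: float = 1.0) -> np.ndarray:
    """Fraction of native contacts preserved per frame.

    Q(f) is the fraction of native pairs whose frame-f minimum heavy-atom
    distance is <= tolerance x cutoff.  With contacts built from frame 0,
    Q(0) = 1 by construction (tolerance >= 1).
    """
    if not contacts.pairs:
        raise ValueError("empty contact set")
    flat = t.flat_atoms()
    keys, groups, _ = _residue_heavy_groups(flat)
    key2group = dict(zip(keys, groups))
    if contacts.residue_keys:
        grp = [np.array(key2group[contacts.residue_keys[i]], dtype=int)
               for i in range(len(contacts.residue_keys))]
    else:
        grp = [np.array(g, dtype=int) for g in groups]
    thresh = tolerance * contacts.cutoff
    out = np.empty(t.n_frames)
    for f in range(t.n_frames):
        coords = t.frames[f]
        kept = 0
        for i, j, _ in contacts.pairs:
            if cdist(coords[grp[i]], coords[grp[j]]).min() <= thresh:
                kept += 1
        out[f] = kept / len(contacts.pairs)
    return out


def contact_map(t: Trajectory, group_a: Selection | str, group_b: Selection | str,
                cutoff: float = 4.5):
    """Residue x residue contact frequency over the trajectory.

    Entry (i, j) is the fraction of frames in which the minimum heavy-atom
    distance between residue i of group_a and residue j of group_b is
    <= cutoff.  Returns (matrix, labels_a, labels_b); symmetric when the
    groups coincide.
    """
    flat = t.flat_atoms()
    res_a = _selected_residues(flat, group_a)
    res_b = _selected_residues(flat, group_b)
    if not res_a or not res_b:
        raise ValueError("contact_map selection is empty")
    mat = np.zeros((len(res_a), len(res_b)))
    for f in range(t.n_frames):
        coords = t.frames[f]
        for i, (_, gi) in enumerate(res_a):
            di = cdist(coords[gi], coords[np.concatenate([g for _, g in res_b])])
            # split columns back per residue of group b
            start = 0
            for j, (_, gj) in enumerate(res_b):
                if di[:, start:start + len(gj)].min() <= cutoff:
                    mat[i, j] += 1
                start += len(gj)
    mat /= t.n_frames
    return mat, [k for k, _ in res_a], [k for k, _ in res_b]


def _selected_residues(flat: Sequence[FlatAtom], sel: Selection | str):
    if isinstance(sel, str):
        sel = Selection.parse(sel)
    chosen = {fa.index for fa in flat if sel.matches(fa)}
    keys, groups, _ = _residue_heavy_groups(flat)
    out = []
    for key, grp in zip(keys, groups):
        g = [i for i in grp if i in chosen]
        if g:
            out.append((key, np.array(g, dtype=int)))
    return out


# ---------------------------------------------------------------------------
# Hydrogen bonds


@dataclass
class HBondRecord:
    donor: tuple[str, int, str, str]      # (chain, seq, res_name, atom_name)
    acceptor: tuple[str, int, str, str]
    occupancy: float
    mean_distance: float
    mean_angle: float | None = None


def hbond_census(t: Trajectory, dist_cutoff: float = 3.5,
                 angle_cutoff: float = 120.0,
                 partition: tuple[Selection | str, Selection | str] | None = None,
                 ) -> list[HBondRecord]:
    """Hydrogen-bond occupancy across the trajectory.

    Donors and acceptors are N/O atoms.  When a covalent hydrogen (<= 1.2 A
    from the donor in frame 0, same residue) is present the D-H...A angle
    must be >= *angle_cutoff*; otherwise the census runs hydrogen-free on
    the donor-acceptor distance alone.  *partition* restricts pairs to one
    atom in each selection (default: all vs all, different residues).
    Records are sorted by occupancy descending.
    """
    flat = t.flat_atoms()
    coords0 = t.frames[0]
    polar = [fa for fa in flat if fa.element in ("N", "O")]
    if partition is not None:
        sa, sb = partition
        sa = Selection.parse(sa) if isinstance(sa, str) else sa
        sb = Selection.parse(sb) if isinstance(sb, str) else sb
        side_a = [fa for fa in polar if sa.matches(fa)]
        side_b = [fa for fa in polar if sb.matches(fa)]
    else:
        side_a = side_b = polar

    # attach hydrogens (by proximity within the residue in frame 0)
    hydrogens: dict[int, list[int]] = {}
    hs = [fa for fa in flat if fa.element == "H"]
    for fa in polar:
        attached = [h.index for h in hs
                    if (h.chain_label, h.seq_num, h.icode) == (fa.chain_label, fa.seq_num, fa.icode)
                    and np.linalg.norm(coords0[h.index] - coords0[fa.index]) <= 1.2]
        if attached:
            hydrogens[fa.index] = attached
    use_angles = bool(hydrogens)

    def res_key(fa):
        return (fa.chain_label, fa.seq_num, fa.icode)

    candidates: dict[tuple[int, int], list] = {}
    for fa in side_a:
        for fb in side_b:
            if fa.index == fb.index or res_key(fa) == res_key(fb):
                continue
            if use_angles and fa.index not in hydrogens:
                continue  # donor must carry an H when hydrogens are present
            key = (fa.index, fb.index) if use_angles else tuple(sorted((fa.index, fb.index)))
            candidates.setdefault(key, [fa, fb])

    id_of = {fa.index: (fa.chain_label, fa.seq_num, fa.res_name, fa.atom_name) for fa in flat}
    records = []
    for (di, ai), _ in candidates.items():
        hits = 0
        dsum = 0.0
        asum = 0.0
        for f in range(t.n_frames):
            d = float(np.linalg.norm(t.frames[f][di] - t.frames[f][ai]))
            if d > dist_cutoff:
                continue
            if use_angles:
                ok = False
                best_angle = 0.0
                for hi in hydrogens.get(di, []):
                    v1 = t.frames[f][di] - t.frames[f][hi]
                    v2 = t.frames[f][ai] - t.frames[f][hi]
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                    if ang >= angle_cutoff:
                        ok = True
                        best_angle = max(best_angle, ang)
                if not ok:
                    continue
                asum += best_angle
            hits += 1
            dsum += d
        if hits:
            records.append(HBondRecord(
                donor=id_of[di], acceptor=id_of[ai],
                occupancy=hits / t.n_frames,
                mean_distance=dsum / hits,
                mean_angle=(asum / hits) if use_angles else None,
            ))
    records.sort(key=lambda r: (-r.occupancy, r.donor, r.acceptor))
    return records


# ---------------------------------------------------------------------------
# Anisotropic network model


@dataclass
class ModeSet:
    """ANM eigenvalues/eigenvectors with rigid-body null space flagged.

    Eigenvalues ascend; eigenvectors are orthonormal columns of shape
    (3N, n_modes); the first ``n_zero`` modes are rigid-body (near-zero
    eigenvalue).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero: int
    cutoff: float
    gamma: float
    n_atoms: int


def anm_hessian(coords: np.ndarray, cutoff: float = 15.0, gamma: float = 1.0) -> np.ndarray:
    """Dense 3N x 3N ANM Hessian: uniform springs between node pairs within
    the cutoff; off-diagonal block for pair (i, j) is -gamma d d^T / |d|^2."""
    X = np.asarray(coords, dtype=float)
    n = X.shape[0]
    H = np.zeros((3 * n, 3 * n))
    tree = cKDTree(X)
    for i, j in tree.query_pairs(cutoff):
        d = X[j] - X[i]
        r2 = float(d @ d)
        if r2 == 0.0:
            continue
        block = -gamma * np.outer(d, d) / r2
        H[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
        H[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block
        H[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        H[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return H


def anm_modes(source, cutoff: float = 15.0, n_modes: int | None = None,
              gamma: float = 1.0, sel: Selection | str | None = None) -> ModeSet:
    """ANM normal modes of the Calpha network of *source*.

    Builds the dense Hessian over Calpha nodes (uniform spring constant
    *gamma*, interaction *cutoff* in A) and eigendecomposes it.  Eigenvalues
    below 1e-8 x the largest are flagged rigid-body (6 for any connected,
    non-degenerate 3-D structure); a disconnected network triggers a warning
    and the extra zero modes are reported honestly.  *n_modes* limits the
    number of non-rigid modes kept.
    """
    flat, coords = _flat_and_coords(source, 0)
    ca_sel = sel if sel is not None else Selection(element_class="ca")
    if isinstance(ca_sel, str):
        ca_sel = Selection.parse(ca_sel)
    idx = np.array([fa.index for fa in flat if ca_sel.matches(fa)], dtype=int)
    X = coords[idx]
    n = X.shape[0]
    if n < 3 or np.linalg.matrix_rank(X - X.mean(axis=0), tol=1e-9) < 2:
        raise DegenerateGeometryError("ANM needs >= 3 non-collinear Calpha atoms")
    tree = cKDTree(X)
    degrees = np.array([len(tree.query_ball_point(x, cutoff)) - 1 for x in X])
    if np.any(degrees == 0):
        warnings.warn(f"ANM network disconnected: {int((degrees == 0).sum())} isolated "
                      "node(s); extra zero modes will appear", stacklevel=2)
    H = anm_hessian(X, cutoff=cutoff, gamma=gamma)
    evals, evecs = scipy.linalg.eigh(H)
    scale = max(float(evals[-1]), 1.0)
    n_zero = int(np.sum(np.abs(evals) < 1e-8 * scale))
    if n_modes is not None:
        keep = n_zero + int(n_modes)
        evals, evecs = evals[:keep], evecs[:, :keep]
    return ModeSet(evals, evecs, n_zero, cutoff, gamma, n)


def mode_trajectory(source, modes: ModeSet, mode_index: int, amplitude: float,
                    n_frames: int = 20, sel: Selection | str | None = None) -> Trajectory:
    """Animate one non-rigid ANM mode as a sinusoidal oscillation.

    Frame k displaces the network nodes by
    ``amplitude * sin(2 pi k / n_frames) * eigenvector``.
    """
    if mode_index < modes.n_zero:
        raise ValueError(f"mode {mode_index} is a rigid-body mode (n_zero={modes.n_zero})")
    if isinstance(source, Trajectory):
        topo = source.topology
    elif isinstance(source, Structure):
        topo = Structure(models=[source.models[0]], title=source.title)
    else:
        topo = source.to_structure()
    flat = topo.flat_atoms(0)
    ca_sel = sel if sel is not None else Selection(element_class="ca")
    if isinstance(ca_sel, str):
        ca_sel = Selection.parse(ca_sel)
    idx = np.array([fa.index for fa in flat if ca_sel.matches(fa)], dtype=int)
    if idx.size != modes.n_atoms:
        raise ValueError("mode set does not match the structure's Calpha count")
    base = topo.coords(0)
    vec = modes.eigenvectors[:, mode_index].reshape(-1, 3)
    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    for k in range(n_frames):
        frames[k, idx, :] = base[idx] + amplitude * math.sin(2 * math.pi * k / n_frames) * vec
    return Trajectory(topo, frames)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    """Principal components of the superposed positional covariance.

    ``components`` rows are orthonormal 3N-vectors; ``explained_variance``
    is non-increasing; ``projections`` is frames x n_components;
    ``total_variance`` is the full superposed positional variance.
    """

    components: np.ndarray
    explained_variance: np.ndarray
    projections: np.ndarray
    mean: np.ndarray
    total_variance: float


def pca_projection(t: Trajectory, sel: Selection | str | None = None,
                   n_components: int = 3) -> PCAResult:
    """PCA of the trajectory's positional covariance after superposition.

    Frames are superposed onto the mean structure (two-pass), flattened to
    3N-vectors, centred, and decomposed by SVD.  Components carry a
    deterministic sign (largest-magnitude coefficient positive).
    """
    if t.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    idx = select_atoms(t, sel)
    if idx.size == 0:
        raise ValueError("pca selection is empty")
    aligned = _superpose_frames(t.frames[:, idx, :])
    X = aligned.reshape(t.n_frames, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S ** 2 / (t.n_frames - 1)
    total = float(Xc.var(axis=0, ddof=1).sum())
    k = min(n_components, Vt.shape[0])
    comps = Vt[:k].copy()
    proj = Xc @ comps.T
    for c in range(k):
        imax = int(np.argmax(np.abs(comps[c])))
        if comps[c, imax] < 0:
            comps[c] = -comps[c]
            proj[:, c] = -proj[:, c]
    return PCAResult(comps, var[:k].copy(), proj, mean, total)
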