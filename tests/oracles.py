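"""Independent brute-force oracles used to cross-check the implementation.

Each oracle deliberately takes a different algorithmic route from the code
under test: quaternion (Horn) superposition vs SVD Kabsch, Lance-Williams
agglomeration vs scipy's Ward linkage, naive per-pair Hessian assembly +
numpy eigensolver vs the vectorized ANM path, and exhaustive all-pairs
scans vs KD-tree searches.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def quaternion_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimum RMSD of P onto Q via Horn's quaternion eigenvalue method."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    n = P.shape[0]
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    S = P0.T @ Q0
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam_max = np.linalg.eigvalsh(K)[-1]
    e0 = (P0 ** 2).sum() + (Q0 ** 2).sum()
    return math.sqrt(max(0.0, (e0 - 2.0 * lam_max) / n))


def ward_oracle(X: np.ndarray, k: int):
    """Exhaustive Ward agglomeration via the Lance-Williams update.

    Starts from Euclidean distances between singletons and repeatedly merges
    the closest pair, updating distances with the Ward formula.  Returns
    (labels at cut k as 0-based array ordered by first occurrence,
    sorted merge heights applied to reach the cut).
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    members = {i: [i] for i in range(n)}
    size = {i: 1 for i in range(n)}
    D = {}
    for i, j in itertools.combinations(range(n), 2):
        D[(i, j)] = float(np.linalg.norm(X[i] - X[j]))
    active = set(range(n))
    next_id = n
    heights = []
    while len(active) > k:
        (s, t), h = min(((pair, d) for pair, d in D.items()
                         if pair[0] in active and pair[1] in active),
                        key=lambda kv: (kv[1], kv[0]))
        heights.append(h)
        u = next_id
        next_id += 1
        members[u] = members[s] + members[t]
        size[u] = size[s] + size[t]
        active -= {s, t}
        for v in active:
            dvs = D[tuple(sorted((v, s)))]
            dvt = D[tuple(sorted((v, t)))]
            dst = h
            nv, ns, nt = size[v], size[s], size[t]
            d2 = ((nv + ns) * dvs ** 2 + (nv + nt) * dvt ** 2 - nv * dst ** 2) / (nv + ns + nt)
            D[tuple(sorted((v, u)))] = math.sqrt(max(0.0, d2))
        active.add(u)
    labels = np.empty(n, dtype=int)
    remap = {}
    cluster_of = {}
    for cid in active:
        for m in members[cid]:
            cluster_of[m] = cid
    for i in range(n):
        c = cluster_of[i]
        if c not in remap:
            remap[c] = len(remap)
        labels[i] = remap[c]
    return labels, sorted(heights)


def anm_hessian_naive(coords: np.ndarray, cutoff: float, gamma: float = 1.0) -> np.ndarray:
    """3N x 3N ANM Hessian assembled per pair with explicit 3x3 blocks."""
    X = np.asarray(coords, float)
    n = X.shape[0]
    H = np.zeros((3 * n, 3 * n))
    for i in range(n):
        for j in range(i + 1, n):
            d = X[j] - X[i]
            r = float(np.linalg.norm(d))
            if r > cutoff or r == 0.0:
                continue
            for a in range(3):
                for b in range(3):
                    v = gamma * d[a] * d[b] / (r * r)
                    H[3 * i + a, 3 * j + b] -= v
                    H[3 * j + a, 3 * i + b] -= v
                    H[3 * i + a, 3 * i + b] += v
                    H[3 * j + a, 3 * j + b] += v
    return H


def anm_energy_gradient(coords_flat: np.ndarray, ref: np.ndarray, cutoff: float,
                        gamma: float = 1.0) -> np.ndarray:
    """Gradient of the ANM potential E = sum gamma/2 (|rij| - |rij0|)^2 over
    pairs within the cutoff in the reference geometry."""
    X = coords_flat.reshape(-1, 3)
    n = X.shape[0]
    g = np.zeros_like(X)
    for i in range(n):
        for j in range(i + 1, n):
            r0 = float(np.linalg.norm(ref[j] - ref[i]))
            if r0 > cutoff or r0 == 0.0:
                continue
            d = X[j] - X[i]
            r = float(np.linalg.norm(d))
            if r == 0.0:
                continue
            f = gamma * (r - r0) / r
            g[i] -= f * d
            g[j] += f * d
    return g.ravel()


def brute_force_contacts(flat_atoms, coords, cutoff: float, min_seq_sep: int,
                         scope: str = "both"):
    """Exhaustive residue-pair minimum heavy-atom distance scan."""
    residues = []  # (key, chain, pos_in_chain, [atom indices])
    seen = {}
    pos_counter = {}
    for fa in flat_atoms:
        if fa.element == "H":
            continue
        key = (fa.chain_label, fa.seq_num, fa.icode)
        if key not in seen:
            p = pos_counter.get(fa.chain_label, 0)
            pos_counter[fa.chain_label] = p + 1
            seen[key] = len(residues)
            residues.append([key, fa.chain_label, p, []])
        residues[seen[key]][3].append(fa.index)
    pairs = []
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            _, ci, pi, ai = residues[i]
            _, cj, pj, aj = residues[j]
            same = ci == cj
            if same and abs(pi - pj) < min_seq_sep:
                continue
            if scope == "intra" and not same:
                continue
            if scope == "inter" and same:
                continue
            dmin = min(float(np.linalg.norm(coords[a] - coords[b]))
                       for a in ai for b in aj)
            if dmin <= cutoff:
                pairs.append((i, j, dmin))
    return pairs


def brute_force_min_distance(assembly, link, chains_a, chains_b, seq_a, seq_b):
    """Exhaustive min-over-copies Calpha distance for one cross-link."""
    best = math.inf
    for la in chains_a:
        for lb in chains_b:
            if la == lb and seq_a == seq_b:
                continue
            xa = assembly.ca_coord(la, seq_a)
            xb = assembly.ca_coord(lb, seq_b)
            if xa is None or xb is None:
                continue
            best = min(best, float(np.linalg.norm(xa - xb)))
    return best
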