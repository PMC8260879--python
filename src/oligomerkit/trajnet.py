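"""Trajectory post-processing: superposition, RMSF, SASA, dynamical networks.

The dynamical-network construction follows the standard protein-dynamics
convention: α-carbons are the nodes; an edge joins two non-consecutive
residues whose nodes stay within a distance cutoff (default 4.5 Å) for at
least a persistence fraction (default 75%) of the analyzed frames.  Edges
carry the normalized cross-correlation of the node displacements,

    C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩),

and a path-length weight w_ij = −log|C_ij| so that strongly correlated
pairs are "close".  Communities of coordinated residues are found with the
Girvan–Newman edge-betweenness algorithm, keeping the partition of maximal
weighted modularity along the removal sequence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    NumericalDegeneracyError,
)
from .structures import Structure, TrajectoryBundle

__all__ = [
    "DEFAULT_RADII",
    "DynamicNetwork",
    "CommunityPartition",
    "superpose",
    "superpose_coords",
    "rmsf",
    "analysis_frame_count",
    "sasa",
    "build_network",
    "communities",
    "interface_residues",
]

#: Van der Waals radii (Å) used for SASA.
DEFAULT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
DEFAULT_BURN_IN = 1.0 / 6.0  # e.g. 50 ns of a 300 ns run


# ---------------------------------------------------------------------------
# Superposition / RMSD / RMSF
# ---------------------------------------------------------------------------


def _kabsch(mobile_sel: np.ndarray, ref_sel: np.ndarray):
    """Optimal rotation+translation of mobile onto reference (selections only).

    Returns (rotation, mobile_centroid, ref_centroid).  Guards against
    reflections via the determinant sign and against (near-)collinear
    selections, where the rotation is not determined.
    """
    if mobile_sel.shape != ref_sel.shape:
        raise InvalidInputError(
            f"selection size mismatch: {mobile_sel.shape[0]} vs {ref_sel.shape[0]} atoms"
        )
    if mobile_sel.shape[0] < 3:
        raise InvalidInputError("superposition needs at least 3 selected atoms")
    cm = mobile_sel.mean(axis=0)
    cr = ref_sel.mean(axis=0)
    p = mobile_sel - cm
    q = ref_sel - cr
    sv = np.linalg.svd(p, compute_uv=False)
    scale = sv[0] if sv[0] > 0 else 1.0
    if sv[1] / scale < 1e-8:
        raise NumericalDegeneracyError("selected atoms are collinear; rotation is undetermined")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return rot, cm, cr


def superpose_coords(mobile: np.ndarray, reference: np.ndarray, selection=None):
    """Superpose coordinate arrays; returns (aligned coords, RMSD over selection)."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape[0] != reference.shape[0]:
        raise InvalidInputError(
            f"atom count mismatch: {mobile.shape[0]} vs {reference.shape[0]}"
        )
    sel = np.arange(mobile.shape[0]) if selection is None else np.asarray(selection)
    rot, cm, cr = _kabsch(mobile[sel], reference[sel])
    aligned = (mobile - cm) @ rot.T + cr
    rmsd = float(np.sqrt(np.mean(np.sum((aligned[sel] - reference[sel]) ** 2, axis=1))))
    return aligned, rmsd


def superpose(mobile: Structure, reference: Structure, selection=None):
    """Least-squares rigid-body superposition of two structures.

    ``selection`` indexes/masks atoms used for the fit (all atoms by
    default); the returned structure has *all* atoms transformed.  The RMSD
    is the minimized value over the selection, invariant to the initial
    pose.
    """
    aligned, rmsd = superpose_coords(mobile.coords, reference.coords, selection)
    return mobile.with_coords(aligned), rmsd


def _burned(coords: np.ndarray, burn_in_fraction: float) -> np.ndarray:
    f = coords.shape[0]
    start = int(math.floor(f * burn_in_fraction))
    return coords[start:]


def rmsf(bundle: TrajectoryBundle, burn_in_fraction: float = DEFAULT_BURN_IN) -> pd.DataFrame:
    """Per-residue RMSF (Å) about the reference, averaged over replicates.

    Each post-burn-in frame is superposed onto the reference on backbone
    atoms; RMSF_i = √⟨|r_i − r_i,ref|²⟩ over frames for each α-carbon,
    computed per replicate and then averaged.
    """
    ref = bundle.reference
    bb = np.where(ref.backbone_mask())[0]
    ca = np.where(ref.ca_mask())[0]
    if ca.size == 0:
        ca = np.arange(ref.n_atoms)
    per_rep = []
    for traj in bundle.replicates:
        frames = _burned(traj.coords, burn_in_fraction)
        if frames.shape[0] < 2:
            raise InsufficientDataError("need at least 2 frames after burn-in for RMSF")
        sq = np.zeros(ca.size)
        for fr in frames:
            aligned, _ = superpose_coords(fr, ref.coords, bb)
            sq += np.sum((aligned[ca] - ref.coords[ca]) ** 2, axis=1)
        per_rep.append(np.sqrt(sq / frames.shape[0]))
    vals = np.mean(per_rep, axis=0)
    tab = ref.atoms.iloc[ca]
    return pd.DataFrame(
        {"chain": tab["chain"].to_numpy(), "res_id": tab["res_id"].to_numpy(), "rmsf": vals}
    )


def analysis_frame_count(
    replicates: int = 3,
    total_ns: float = 300.0,
    burn_in_ns: float = 50.0,
    sampling_ps: float = 50.0,
) -> int:
    """Number of analysis frames: replicates × (total − burn-in) / sampling."""
    per_rep = (total_ns - burn_in_ns) * 1000.0 / sampling_ps
    return int(round(replicates * per_rep))


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley)
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    sphere_points: int = 960,
    radii: dict[str, float] | None = None,
    default_radius: float = 1.70,
    per_atom: bool = False,
):
    """Shrake–Rupley solvent-accessible surface area (Å²).

    For each atom, ``sphere_points`` quasi-uniform test points on the
    solvent-expanded sphere of radius r_i + probe are checked for burial in
    any neighbor's expanded sphere; the accessible fraction times
    4π(r_i+probe)² is the atom's SASA.  Residue SASA sums its atoms.
    Unknown elements fall back to ``default_radius`` with a warning.
    """
    rad_table = DEFAULT_RADII if radii is None else radii
    elements = structure.atoms["element"].to_numpy()
    unknown = sorted({e for e in elements if e not in rad_table})
    if unknown:
        warnings.warn(
            f"unknown element(s) {unknown}; using default radius {default_radius} Å", stacklevel=2
        )
    r = np.array([rad_table.get(e, default_radius) for e in elements]) + probe_radius
    xyz = structure.coords
    pts = _fibonacci_sphere(int(sphere_points))

    tree = cKDTree(xyz)
    rmax = float(r.max())
    atom_area = np.zeros(len(r))
    for i in range(len(r)):
        nb = [j for j in tree.query_ball_point(xyz[i], r[i] + rmax) if j != i]
        sphere = xyz[i] + r[i] * pts
        if nb:
            d2 = cdist(sphere, xyz[nb], "sqeuclidean")
            buried = (d2 < (r[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        atom_area[i] = frac * 4.0 * math.pi * r[i] ** 2
    if per_atom:
        return atom_area
    df = structure.atoms[["chain", "res_id"]].copy()
    df["sasa"] = atom_area
    out = df.groupby(["chain", "res_id"], sort=True, as_index=False)["sasa"].sum()
    return out


# ---------------------------------------------------------------------------
# Dynamical network + communities
# ---------------------------------------------------------------------------


@dataclass
class DynamicNetwork:
    """Contact-persistence correlation network over α-carbon nodes."""

    graph: nx.Graph
    nodes: pd.DataFrame  # node index -> chain, res_id
    cutoff: float
    persistence_threshold: float
    contact_atoms: str = "ca"

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {
                "i": i,
                "j": j,
                "correlation": d["correlation"],
                "weight": d["weight"],
                "persistence": d["persistence"],
            }
            for i, j, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["i", "j", "correlation", "weight", "persistence"])


@dataclass
class CommunityPartition:
    assignment: dict[int, int]  # node -> community id
    modularity: float
    n_communities: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_communities = len(set(self.assignment.values()))


def _pooled_ca_frames(bundle: TrajectoryBundle, burn_in_fraction: float) -> np.ndarray:
    """Post-burn-in Cα coordinates, superposed to the reference, pooled."""
    ref = bundle.reference
    bb = np.where(ref.backbone_mask())[0]
    ca = np.where(ref.ca_mask())[0]
    if ca.size == 0:
        ca = np.arange(ref.n_atoms)
    pooled = []
    for traj in bundle.replicates:
        for fr in _burned(traj.coords, burn_in_fraction):
            aligned, _ = superpose_coords(fr, ref.coords, bb)
            pooled.append(aligned[ca])
    if len(pooled) < 2:
        raise InsufficientDataError("need at least 2 pooled frames to build a network")
    return np.asarray(pooled)  # (F, n_ca, 3)


def build_network(
    bundle: TrajectoryBundle,
    cutoff: float = 4.5,
    persistence: float = 0.75,
    burn_in_fraction: float = DEFAULT_BURN_IN,
    contact_atoms: str = "ca",
    weight_cap: float = 10.0,
) -> DynamicNetwork:
    """Build the dynamical network from pooled post-burn-in frames.

    An edge joins residues i, j when their contact distance stays ≤
    ``cutoff`` in at least ``persistence`` (inclusive) of the pooled frames
    and the residues are not consecutive within a chain.  ``contact_atoms``
    selects the distance criterion: ``"ca"`` (node-to-node, default) or
    ``"heavy"`` (minimum over non-hydrogen atom pairs).  Correlations are
    computed on Cα displacements about their pooled mean; weights are
    −log|C_ij| capped at ``weight_cap``.
    """
    if contact_atoms not in ("ca", "heavy"):
        raise InvalidInputError("contact_atoms must be 'ca' or 'heavy'")
    frames = _pooled_ca_frames(bundle, burn_in_fraction)
    nfr, n_ca, _ = frames.shape
    ref = bundle.reference
    ca_idx = np.where(ref.ca_mask())[0]
    if ca_idx.size == 0:
        ca_idx = np.arange(ref.n_atoms)
    tab = ref.atoms.iloc[ca_idx].reset_index(drop=True)
    chains = tab["chain"].to_numpy()
    res_ids = tab["res_id"].to_numpy()

    # contact persistence
    if contact_atoms == "ca":
        hits = np.zeros((n_ca, n_ca))
        for fr in frames:
            d = cdist(fr, fr)
            hits += d <= cutoff
        pers = hits / nfr
    else:
        pers = _heavy_contact_persistence(bundle, burn_in_fraction, cutoff, chains, res_ids)

    # displacement correlations on Cα
    mean = frames.mean(axis=0)
    delta = frames - mean[None]
    cov = np.einsum("fik,fjk->ij", delta, delta) / nfr
    var = np.clip(np.diag(cov), 1e-300, None)
    corr = cov / np.sqrt(np.outer(var, var))
    corr = np.clip(corr, -1.0, 1.0)

    g = nx.Graph()
    node_df = pd.DataFrame({"node": np.arange(n_ca), "chain": chains, "res_id": res_ids})
    for i in range(n_ca):
        g.add_node(i, chain=chains[i], res_id=int(res_ids[i]))
    for i in range(n_ca):
        for j in range(i + 1, n_ca):
            if chains[i] == chains[j] and abs(int(res_ids[i]) - int(res_ids[j])) <= 1:
                continue  # bonded (consecutive) residues never form edges
            if pers[i, j] < persistence:
                continue
            c = float(corr[i, j])
            w = weight_cap if abs(c) <= math.exp(-weight_cap) else min(-math.log(abs(c)), weight_cap)
            g.add_edge(
                i,
                j,
                correlation=c,
                abs_correlation=abs(c),
                weight=float(w),
                persistence=float(pers[i, j]),
            )
    return DynamicNetwork(
        graph=g, nodes=node_df, cutoff=cutoff, persistence_threshold=persistence, contact_atoms=contact_atoms
    )


def _heavy_contact_persistence(bundle, burn_in_fraction, cutoff, chains, res_ids):
    """Per-residue-pair persistence of any-heavy-atom contact (O(N²) per frame)."""
    ref = bundle.reference
    heavy = np.where((ref.atoms["element"] != "H").to_numpy())[0]
    ca_idx = np.where(ref.ca_mask())[0]
    if ca_idx.size == 0:
        ca_idx = np.arange(ref.n_atoms)
    key = list(zip(ref.atoms["chain"].to_numpy(), ref.atoms["res_id"].to_numpy()))
    res_of_node = {(c, r): k for k, (c, r) in enumerate(zip(chains, res_ids))}
    atom_node = np.array([res_of_node.get(key[a], -1) for a in heavy])
    bb = np.where(ref.backbone_mask())[0]
    n = len(chains)
    hits = np.zeros((n, n))
    nfr = 0
    for traj in bundle.replicates:
        for fr in _burned(traj.coords, burn_in_fraction):
            aligned, _ = superpose_coords(fr, ref.coords, bb)
            d = cdist(aligned[heavy], aligned[heavy])
            close = d <= cutoff
            contact = np.zeros((n, n), dtype=bool)
            ii, jj = np.where(close)
            contact[atom_node[ii], atom_node[jj]] = True
            hits += contact
            nfr += 1
    return hits / nfr


def _betweenness_edge(graph: nx.Graph):
    """Most valuable edge: max weighted edge betweenness, ties lexicographic."""
    bet = nx.edge_betweenness_centrality(graph, weight="weight")
    best = max(bet.values())
    cands = sorted(tuple(sorted(e)) for e, v in bet.items() if v >= best - 1e-15)
    return cands[0]


def communities(network: DynamicNetwork, k: int | None = None) -> CommunityPartition:
    """Girvan–Newman community detection on the dynamical network.

    Edges of maximal weighted betweenness (path weights w = −log|C|) are
    removed iteratively; among the partitions along the removal sequence
    (including the initial connected components) the one maximizing
    modularity — computed with |C_ij| as the affinity weight — is returned.
    Passing ``k`` instead selects the first partition with exactly k
    communities.  Deterministic: betweenness ties break toward the
    lexicographically smallest edge.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise InvalidInputError("cannot cluster an empty network")

    def as_partition(comm_sets: Iterable[frozenset]) -> list[set]:
        return sorted((set(c) for c in comm_sets), key=min)

    candidates = [as_partition(nx.connected_components(g))]
    if g.number_of_edges() > 0:
        for part in nx.community.girvan_newman(g, most_valuable_edge=_betweenness_edge):
            candidates.append(as_partition(part))

    def score(part) -> float:
        return nx.community.modularity(g, part, weight="abs_correlation") if g.number_of_edges() else 0.0

    if k is not None:
        matching = [p for p in candidates if len(p) == k]
        chosen = matching[0] if matching else min(candidates, key=lambda p: abs(len(p) - k))
    else:
        chosen = max(candidates, key=score)

    assignment = {node: ci for ci, comm in enumerate(chosen) for node in sorted(comm)}
    return CommunityPartition(assignment=assignment, modularity=float(score(chosen)))


# ---------------------------------------------------------------------------
# Interface residues
# ---------------------------------------------------------------------------


def interface_residues(
    structure: Structure, chain_a: str, chain_b: str, cutoff: float = 4.0
) -> list[tuple[int, int]]:
    """Residue pairs across two chains with any interatomic distance ≤ cutoff.

    Returns sorted (res_id_a, res_id_b) pairs.
    """
    chains = structure.atoms["chain"].to_numpy()
    for c in (chain_a, chain_b):
        if c not in chains:
            raise InvalidInputError(f"chain {c!r} not present in the structure")
    a = np.where(chains == chain_a)[0]
    b = np.where(chains == chain_b)[0]
    res_a = structure.atoms["res_id"].to_numpy()[a]
    res_b = structure.atoms["res_id"].to_numpy()[b]
    d = cdist(structure.coords[a], structure.coords[b])
    ii, jj = np.where(d <= cutoff)
    pairs = sorted({(int(res_a[i]), int(res_b[j])) for i, j in zip(ii, jj)})
    return pairs
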