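"""Atomistic elastic network models and rotation-translation-block NMA.

Each residue contributes 3–5 heavy-atom nodes (N, Cα, C plus up to two
side-chain representatives from a fixed per-residue table); springs connect
node pairs with a distance-dependent stiffness.  The Hessian of the harmonic
network is projected onto per-residue rigid-body coordinates (RTB: each
residue moves as a rigid block with ≤6 degrees of freedom), eigendecomposed,
and the six rigid-body modes removed.  Residue fluctuations (variance of
atomic positions, Å² on an arbitrary common unit-temperature scale) follow
from the inverse eigenvalues.  Ensemble NMA runs this over a phosphosite
group on a shared residue core after a redundancy filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.sparse import coo_matrix

from .structures import PhosphositeGroup, StructureRecord, align_residue_pair

#: side-chain representative atoms (≤2), chosen by size / distance to Cα
SIDECHAIN_ATOMS: Dict[str, Tuple[str, ...]] = {
    "GLY": (),
    "ALA": ("CB",),
    "SER": ("CB", "OG"),
    "CYS": ("CB", "SG"),
    "THR": ("CB", "OG1"),
    "VAL": ("CB", "CG1"),
    "PRO": ("CB", "CG"),
    "LEU": ("CG", "CD1"),
    "ILE": ("CG1", "CD1"),
    "MET": ("CG", "SD"),
    "ASP": ("CB", "CG"),
    "ASN": ("CB", "CG"),
    "GLU": ("CB", "CD"),
    "GLN": ("CB", "CD"),
    "LYS": ("CG", "NZ"),
    "ARG": ("CG", "CZ"),
    "HIS": ("CB", "NE2"),
    "PHE": ("CB", "CZ"),
    "TYR": ("CB", "OH"),
    "TRP": ("CB", "CZ2"),
}

CHAIN_BREAK_DISTANCE = 4.5  # Å, Cα–Cα between consecutive retained residues


@dataclass
class ElasticNetwork:
    coords: np.ndarray             # (n_nodes, 3)
    node_residue: np.ndarray       # node -> residue position (0-based)
    node_names: List[str]
    springs: List[Tuple[int, int, float]]   # (i, j, stiffness), i < j
    residue_positions: List[int]   # retained residue positions in the record

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_residues(self) -> int:
        return len(self.residue_positions)

    def n_components(self) -> int:
        n = self.n_nodes
        if not self.springs:
            return n
        i = [s[0] for s in self.springs]
        j = [s[1] for s in self.springs]
        adj = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
        return int(connected_components(adj, directed=False)[0])


@dataclass
class ModeSet:
    """Non-trivial normal modes plus per-residue fluctuations.

    ``eigenvectors`` columns are unit-norm; in the full node space they are
    mutually orthonormal, after restriction to a residue core they are only
    renormalised (``component_weight`` keeps the restriction norms so that
    covariances can be reconstructed).
    """

    eigenvalues: np.ndarray        # ascending, > 0
    eigenvectors: np.ndarray       # (3*n_nodes, k), unit columns
    node_residue: np.ndarray
    residue_fluctuations: np.ndarray   # per retained residue, Å²
    residue_positions: List[int]
    component_weight: Optional[np.ndarray] = None  # per-mode restriction norm
    structure_id: str = ""

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)


# ---------------------------------------------------------------------------
# network construction


def inverse_sixth_stiffness(r: np.ndarray) -> np.ndarray:
    """Distance-dependent spring constant k(r) = (r0/r)^6 with r0 = 4 Å."""
    return (4.0 / r) ** 6


def build_atomistic_enm(structure: StructureRecord,
                        cutoff: Optional[float] = None,
                        stiffness_fn: Callable = inverse_sixth_stiffness,
                        model: int = 0) -> ElasticNetwork:
    """Build the 3–5-node-per-residue elastic network.

    Residues missing any backbone atom (N, Cα, C) are excluded and logged in
    the returned network's residue list.  With ``cutoff=None`` all node pairs
    are connected (the distance-dependent stiffness decays as r^-6); with a
    cutoff, only pairs within it.
    """
    coords, node_res, names, res_positions = [], [], [], []
    for pos, res in enumerate(structure.models[model]):
        if not all(a in res.atoms for a in ("N", "CA", "C")):
            continue
        ridx = len(res_positions)
        res_positions.append(pos)
        for a in ("N", "CA", "C"):
            coords.append(res.atoms[a])
            node_res.append(ridx)
            names.append(a)
        for a in SIDECHAIN_ATOMS.get(res.aa3, ("CB",)):
            if a in res.atoms:
                coords.append(res.atoms[a])
                node_res.append(ridx)
                names.append(a)
    if not coords:
        raise ValueError("no residues with complete backbone")
    coords = np.asarray(coords, float)

    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    n = len(coords)
    iu, ju = np.triu_indices(n, k=1)
    r = d[iu, ju]
    keep = r > 1e-6
    if cutoff is not None:
        keep &= r <= cutoff
    iu, ju, r = iu[keep], ju[keep], r[keep]
    springs = list(zip(iu.tolist(), ju.tolist(),
                       np.asarray(stiffness_fn(r), float).tolist()))
    return ElasticNetwork(coords, np.asarray(node_res), names, springs,
                          res_positions)


def check_ensemble_eligibility(structure: StructureRecord,
                               break_distance: float = CHAIN_BREAK_DISTANCE,
                               cutoff: Optional[float] = 10.0,
                               ) -> Tuple[bool, str]:
    """Chain-continuity and network-connectivity gate for ensemble NMA."""
    cas = [r.atoms["CA"] for r in structure.residues if "CA" in r.atoms]
    if len(cas) < 3:
        return False, "too few residues with Calpha"
    for a, b in zip(cas[:-1], cas[1:]):
        if np.linalg.norm(a - b) > break_distance:
            return False, "chain break"
    net = build_atomistic_enm(structure, cutoff=cutoff,
                              stiffness_fn=lambda r: np.ones_like(r))
    if net.n_components() > 1:
        return False, "disconnected network"
    return True, "ok"


# ---------------------------------------------------------------------------
# Hessian and RTB projection


def enm_hessian(network: ElasticNetwork) -> np.ndarray:
    """Dense 3N×3N Hessian of the pair-potential network."""
    n = network.n_nodes
    if not network.springs:
        return np.zeros((3 * n, 3 * n))
    iv = np.array([s[0] for s in network.springs])
    jv = np.array([s[1] for s in network.springs])
    kv = np.array([s[2] for s in network.springs])
    dv = network.coords[jv] - network.coords[iv]
    r2 = (dv ** 2).sum(axis=1)
    blk = -(kv / r2)[:, None, None] * dv[:, :, None] * dv[:, None, :]
    H4 = np.zeros((n, 3, n, 3))
    np.add.at(H4, (iv, slice(None), jv, slice(None)), blk)
    np.add.at(H4, (jv, slice(None), iv, slice(None)), blk)
    np.add.at(H4, (iv, slice(None), iv, slice(None)), -blk)
    np.add.at(H4, (jv, slice(None), jv, slice(None)), -blk)
    return H4.reshape(3 * n, 3 * n)


def _rtb_projection(network: ElasticNetwork) -> np.ndarray:
    """Orthonormal block basis: ≤6 rigid-body DOF per residue.

    Collinear 3-atom and 2-atom blocks reduce to 5 DOF, single atoms to 3
    (degenerate rotations are dropped by rank truncation of the SVD).
    """
    n = network.n_nodes
    cols = []
    for b in range(network.n_residues):
        nodes = np.where(network.node_residue == b)[0]
        m = len(nodes)
        x = network.coords[nodes]
        c = x.mean(axis=0)
        basis = np.zeros((3 * n, 6))
        for ax in range(3):
            basis[3 * nodes + ax, ax] = 1.0          # translations
        rel = x - c
        for ax in range(3):                           # rotations about axes
            e = np.zeros(3)
            e[ax] = 1.0
            rot = np.cross(e, rel)                    # (m, 3)
            for local, node in enumerate(nodes):
                basis[3 * node:3 * node + 3, 3 + ax] = rot[local]
        # orthonormalise within the block; drop rank-deficient directions
        sub = basis[np.repeat(3 * nodes, 3) + np.tile([0, 1, 2], m)]
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        keep = s > 1e-8 * s[0]
        block = np.zeros((3 * n, int(keep.sum())))
        block[np.repeat(3 * nodes, 3) + np.tile([0, 1, 2], m)] = u[:, keep]
        cols.append(block)
    return np.hstack(cols)


def rtb_modes(network: ElasticNetwork,
              n_modes: Optional[int] = None,
              rtb: bool = True,
              structure_id: str = "") -> ModeSet:
    """Normal modes of the network; RTB-projected by default.

    Exactly six near-zero (rigid-body) eigenvalues are removed; a network
    with more near-zero modes is disconnected and rejected.  Eigenvectors are
    returned in the full 3N node space (back-projected for RTB), orthonormal,
    eigenvalues ascending.
    """
    H = enm_hessian(network)
    if rtb:
        P = _rtb_projection(network)
        Hr = P.T @ H @ P
        w, v = np.linalg.eigh(Hr)
        vecs = P @ v
    else:
        w, v = np.linalg.eigh(H)
        vecs = v
    # rigid-body zeros sit at ~1e-14 of the top eigenvalue; the softest
    # genuine modes of long floppy chains can reach ~1e-9, so the cut
    # separating them must be far below the usual 1e-8
    scale = max(w.max(), 1.0)
    trivial = w < 3e-12 * scale
    n_trivial = int(trivial.sum())
    if n_trivial > 6:
        raise ValueError(
            f"{n_trivial} near-zero modes: disconnected network")
    keep = ~trivial
    w, vecs = w[keep], vecs[:, keep]
    order = np.argsort(w)
    w, vecs = w[order], vecs[:, order]
    if n_modes is not None:
        w, vecs = w[:n_modes], vecs[:, :n_modes]
    ms = ModeSet(w, vecs, network.node_residue,
                 residue_fluctuations=np.zeros(network.n_residues),
                 residue_positions=list(network.residue_positions),
                 structure_id=structure_id)
    ms.residue_fluctuations = residue_fluctuations(ms)
    return ms


def count_near_zero_modes(network: ElasticNetwork) -> int:
    """Number of near-zero Hessian eigenvalues (6 iff connected)."""
    w = np.linalg.eigvalsh(enm_hessian(network))
    return int((w < 1e-8 * max(w.max(), 1.0)).sum())


def residue_fluctuations(modes: ModeSet) -> np.ndarray:
    """Per-residue positional variance from the mode spectrum.

    fluct(r) = mean over r's nodes of Σ_k (w_k²/λ_k)·|mode_k on node|²,
    i.e. the per-node diagonal of the pseudo-inverse Hessian averaged within
    each residue (unit temperature).
    """
    if np.any(modes.eigenvalues <= 0):
        raise ValueError("trivial modes must be removed first")
    wts = (modes.component_weight ** 2
           if modes.component_weight is not None else 1.0)
    inv = wts / modes.eigenvalues
    v2 = modes.eigenvectors ** 2               # (3N, k)
    node_var = (v2 * inv).sum(axis=1).reshape(-1, 3).sum(axis=1)
    n_res = int(modes.node_residue.max()) + 1
    out = np.zeros(n_res)
    for r in range(n_res):
        out[r] = node_var[modes.node_residue == r].mean()
    return out


# ---------------------------------------------------------------------------
# ensemble NMA


def _redundancy_filter(records: Sequence[StructureRecord],
                       cutoff: float) -> List[StructureRecord]:
    """Greedy filter: keep first, drop structures within ``cutoff`` RMSD."""
    from .backbone import pairwise_backbone_rmsd
    kept: List[StructureRecord] = []
    for rec in records:
        close = False
        for k in kept:
            m = align_residue_pair(k, rec)
            if m.pairs and pairwise_backbone_rmsd(k, rec, m).rmsd < cutoff:
                close = True
                break
        if not close:
            kept.append(rec)
    return kept


@dataclass
class EnsembleNMA:
    group: PhosphositeGroup
    mode_sets: Dict[str, ModeSet]           # structure_id -> core-space modes
    core_positions: Dict[str, List[int]]    # structure_id -> residue positions
    phospho_ids: List[str]
    nonphospho_ids: List[str]
    excluded: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def n_core(self) -> int:
        first = next(iter(self.mode_sets.values()))
        return len(first.residue_positions)


def ensemble_nma(group: PhosphositeGroup,
                 redundancy_rmsd: float = 0.2,
                 n_modes: Optional[int] = None,
                 cutoff: Optional[float] = None,
                 stiffness_fn: Callable = inverse_sixth_stiffness,
                 ) -> EnsembleNMA:
    """Ensemble NMA of a phosphosite group on a shared residue core.

    Eligibility (chain breaks, connectivity) is checked per structure, the
    0.2 Å redundancy filter applied within each state separately, the common
    core defined as residues aligned across all retained structures, and
    RTB modes computed per structure then restricted to core Cα components
    (unit-renormalised, restriction norms retained).
    """
    excluded: List[Tuple[str, str]] = []

    def eligible(recs):
        out = []
        for r in recs:
            ok, reason = check_ensemble_eligibility(r)
            if ok:
                out.append(r)
            else:
                excluded.append((r.structure_id, reason))
        return out

    phos = _redundancy_filter(eligible(group.phospho_structures),
                              redundancy_rmsd)
    non = _redundancy_filter(eligible(group.nonphospho_structures),
                             redundancy_rmsd)
    if not phos or not non:
        raise ValueError("no eligible structure in one of the states")

    records = phos + non
    anchor = records[0]
    # core via the anchor: positions of the anchor matched in every structure
    maps = {anchor.structure_id: {i: i for i in range(len(anchor.residues))}}
    core_anchor = set(range(len(anchor.residues)))
    for rec in records[1:]:
        m = align_residue_pair(anchor, rec)
        maps[rec.structure_id] = dict(m.pairs)
        core_anchor &= {i for i, _ in m.pairs}
    core_anchor = sorted(core_anchor)
    if not core_anchor:
        raise ValueError("empty shared residue core")

    mode_sets: Dict[str, ModeSet] = {}
    core_positions: Dict[str, List[int]] = {}
    for rec in records:
        positions = [maps[rec.structure_id][i] for i in core_anchor]
        net = build_atomistic_enm(rec, cutoff=cutoff,
                                  stiffness_fn=stiffness_fn)
        ms = rtb_modes(net, n_modes=n_modes, structure_id=rec.structure_id)
        restricted = _restrict_to_core_ca(ms, net, positions)
        mode_sets[rec.structure_id] = restricted
        core_positions[rec.structure_id] = positions

    return EnsembleNMA(group, mode_sets, core_positions,
                       [r.structure_id for r in phos],
                       [r.structure_id for r in non],
                       excluded)


def _restrict_to_core_ca(ms: ModeSet, net: ElasticNetwork,
                         core_positions: List[int]) -> ModeSet:
    """Restrict a mode set to core Cα components; renormalise columns."""
    pos_to_retained = {p: i for i, p in enumerate(net.residue_positions)}
    ca_nodes = []
    for p in core_positions:
        if p not in pos_to_retained:
            raise ValueError(f"core residue {p} missing from network")
        ridx = pos_to_retained[p]
        node = next(n for n in np.where(net.node_residue == ridx)[0]
                    if net.node_names[n] == "CA")
        ca_nodes.append(node)
    dof = np.concatenate([[3 * n, 3 * n + 1, 3 * n + 2] for n in ca_nodes])
    sub = ms.eigenvectors[dof]
    norms = np.linalg.norm(sub, axis=0)
    norms[norms == 0] = 1.0
    flucts = ms.residue_fluctuations[[pos_to_retained[p]
                                      for p in core_positions]]
    return ModeSet(ms.eigenvalues.copy(), sub / norms,
                   node_residue=np.arange(len(core_positions)),
                   residue_fluctuations=flucts,
                   residue_positions=list(core_positions),
                   component_weight=norms,
                   structure_id=ms.structure_id)


# ---------------------------------------------------------------------------
# serialization


def save_modes(path, ms: ModeSet) -> None:
    np.savez(path,
             eigenvalues=ms.eigenvalues,
             eigenvectors=ms.eigenvectors,
             node_residue=ms.node_residue,
             residue_fluctuations=ms.residue_fluctuations,
             residue_positions=np.asarray(ms.residue_positions),
             component_weight=(ms.component_weight
                               if ms.component_weight is not None
                               else np.zeros(0)),
             structure_id=np.array(ms.structure_id))


def load_modes(path) -> ModeSet:
    z = np.load(path, allow_pickle=False)
    cw = z["component_weight"]
    return ModeSet(z["eigenvalues"], z["eigenvectors"], z["node_residue"],
                   z["residue_fluctuations"],
                   list(z["residue_positions"]),
                   component_weight=cw if cw.size else None,
                   structure_id=str(z["structure_id"]))
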