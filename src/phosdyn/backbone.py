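"""Backbone conformational comparison between structure sets.

Pairwise Cα RMSD after optimal superposition (Kabsch/SVD), a
superposition-free lDDT check, buried-surface-area interaction calls for the
protein-interaction confound, a robust regression confound model, and the
per-group three-way comparison (P-vs-NP, P-vs-P, NP-vs-NP) with optional
exclusion of same-last-author pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm

from .structures import PhosphositeGroup, ResidueMap, StructureRecord


@dataclass
class ComparisonResult:
    id_a: str
    id_b: str
    comparison_class: str  # "P_vs_NP" | "NP_vs_NP" | "P_vs_P"
    rmsd: float            # Å
    n_matched: int
    lddt: Optional[float] = None
    same_last_author: bool = False


# ---------------------------------------------------------------------------
# superposition


def superpose_kabsch(coords_a: np.ndarray, coords_b: np.ndarray
                     ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of b onto a (SVD / Kabsch).

    Returns (rotation, translation, rmsd); the rotation is proper
    (determinant +1, reflection branch corrected).
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape or a.shape[0] < 3:
        raise ValueError("need two equal coordinate sets of >= 3 points")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite coordinates")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    u, s, vt = np.linalg.svd(b0.T @ a0)
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    rot = u @ corr @ vt          # maps b-frame -> a-frame
    t = ca - cb @ rot
    diff = b0 @ rot - a0
    rmsd = float(np.sqrt((diff ** 2).sum() / len(a)))
    return rot, t, rmsd


def _comparison_class(a: StructureRecord, b: StructureRecord,
                      sites: frozenset) -> str:
    pa = bool(a.phospho_sites & sites) or a.phospho_sites == sites
    pb = bool(b.phospho_sites & sites) or b.phospho_sites == sites
    if pa and pb:
        return "P_vs_P"
    if not pa and not pb:
        return "NP_vs_NP"
    return "P_vs_NP"


def pairwise_backbone_rmsd(a: StructureRecord, b: StructureRecord,
                           residue_map: ResidueMap,
                           comparison_class: str = "") -> ComparisonResult:
    """Cα RMSD over matched residues; median over model pairs for NMR."""
    pairs = [(i, j) for i, j in residue_map.pairs
             if "CA" in a.residues[i].atoms and "CA" in b.residues[j].atoms]
    if not pairs:
        raise ValueError("no matched residues with Calpha in both structures")
    ia = [i for i, _ in pairs]
    ib = [j for _, j in pairs]
    rmsds = []
    for ma in range(a.n_models):
        ca = a.ca_coords(ia, model=ma)
        for mb in range(b.n_models):
            cb = b.ca_coords(ib, model=mb)
            rmsds.append(superpose_kabsch(ca, cb)[2])
    same_author = (a.last_author is not None
                   and a.last_author == b.last_author)
    return ComparisonResult(a.structure_id, b.structure_id, comparison_class,
                            float(np.median(rmsds)), len(pairs),
                            same_last_author=same_author)


def group_rmsd_summary(group: PhosphositeGroup,
                       exclude_same_author: bool = False,
                       with_lddt: bool = False,
                       ) -> Tuple[Dict[str, Optional[float]],
                                  List[ComparisonResult]]:
    """All pairwise comparisons in the three classes and their medians.

    Classes without any comparison (or emptied by the same-last-author
    exclusion) report a median of None.
    """
    from .structures import align_residue_pair

    comparisons: List[ComparisonResult] = []

    def compare(a, b, cls):
        m = align_residue_pair(a, b)
        res = pairwise_backbone_rmsd(a, b, m, cls)
        if with_lddt:
            res.lddt = lddt_score(a, b, m)
        comparisons.append(res)

    for a, b in itertools.combinations(group.phospho_structures, 2):
        compare(a, b, "P_vs_P")
    for a, b in itertools.combinations(group.nonphospho_structures, 2):
        compare(a, b, "NP_vs_NP")
    for a in group.phospho_structures:
        for b in group.nonphospho_structures:
            compare(a, b, "P_vs_NP")

    usable = [c for c in comparisons
              if not (exclude_same_author and c.same_last_author)]
    medians: Dict[str, Optional[float]] = {}
    for cls in ("P_vs_NP", "P_vs_P", "NP_vs_NP"):
        vals = [c.rmsd for c in usable if c.comparison_class == cls]
        medians[cls] = float(np.median(vals)) if vals else None
    return medians, comparisons


# ---------------------------------------------------------------------------
# lDDT

_LDDT_THRESHOLDS = (0.5, 1.0, 2.0, 4.0)
_LDDT_RADIUS = 15.0


def _lddt_one_way(ref: np.ndarray, mod: np.ndarray) -> float:
    d_ref = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
    d_mod = np.linalg.norm(mod[:, None] - mod[None, :], axis=-1)
    n = len(ref)
    iu = np.triu_indices(n, k=1)
    mask = d_ref[iu] < _LDDT_RADIUS
    if not mask.any():
        raise ValueError("no residue pairs within the lDDT inclusion radius")
    dd = np.abs(d_ref[iu][mask] - d_mod[iu][mask])
    return float(np.mean([(dd < t).mean() for t in _LDDT_THRESHOLDS]))


def lddt_score(a: StructureRecord, b: StructureRecord,
               residue_map: ResidueMap) -> float:
    """Symmetrised Cα lDDT over matched residues.

    Standard definition: pairs within 15 Å in the reference, preserved-distance
    fractions at 0.5/1/2/4 Å averaged; reported as the mean of both
    reference choices (superposition-free).
    """
    pairs = [(i, j) for i, j in residue_map.pairs
             if "CA" in a.residues[i].atoms and "CA" in b.residues[j].atoms]
    if len(pairs) < 2:
        raise ValueError("need >= 2 matched residues")
    ca = a.ca_coords([i for i, _ in pairs])
    cb = b.ca_coords([j for _, j in pairs])
    return 0.5 * (_lddt_one_way(ca, cb) + _lddt_one_way(cb, ca))


# ---------------------------------------------------------------------------
# buried surface area

BSA_INTERACTION_THRESHOLD = 250.0  # Å²


def _to_atom_array(recs: Sequence[StructureRecord], chain_ids=None):
    import biotite.structure as struc
    rows = []
    for ci, rec in enumerate(recs):
        cid = chain_ids[ci] if chain_ids else chr(ord("A") + ci)
        for res in rec.residues:
            for name, xyz in res.atoms.items():
                rows.append((cid, res.author_index, res.aa3, name,
                             name[0], xyz))
    arr = struc.AtomArray(len(rows))
    arr.chain_id = np.array([r[0] for r in rows])
    arr.res_id = np.array([r[1] for r in rows])
    arr.res_name = np.array([r[2] for r in rows])
    arr.atom_name = np.array([r[3] for r in rows])
    arr.element = np.array([r[4] for r in rows])
    arr.coord = np.array([r[5] for r in rows], dtype=np.float32)
    return arr


def _total_sasa(arr, n_points: int) -> float:
    import biotite.structure as struc
    vals = struc.sasa(arr, point_number=n_points, vdw_radii="Single")
    return float(np.nansum(vals))


def chain_interaction_bsa(chains: Dict[str, StructureRecord],
                          chain: str,
                          n_points: int = 200) -> Tuple[float, bool]:
    """Buried surface area of one chain against the rest of the complex.

    BSA = SASA(chain alone) + SASA(rest alone) − SASA(complex), with SASA
    from Shrake–Rupley sampling (element van-der-Waals radii, 1.4 Å probe);
    the chain is deemed interacting when BSA ≥ 250 Å².  A single-chain
    complex has BSA 0.
    """
    if chain not in chains:
        raise KeyError(chain)
    rest_ids = [c for c in chains if c != chain]
    if not rest_ids:
        return 0.0, False
    sel = _to_atom_array([chains[chain]], [chain])
    rest = _to_atom_array([chains[c] for c in rest_ids], rest_ids)
    both = sel + rest
    bsa = (_total_sasa(sel, n_points) + _total_sasa(rest, n_points)
           - _total_sasa(both, n_points))
    return bsa, bsa >= BSA_INTERACTION_THRESHOLD


# ---------------------------------------------------------------------------
# PPI confound model


@dataclass
class RobustFit:
    params: np.ndarray     # intercept, n_partners_P, n_partners_NP, n_shared
    bse: np.ndarray
    pseudo_r2: float
    meta: dict


def ppi_confound_model(n_partners_p: Sequence[int],
                       n_partners_np: Sequence[int],
                       n_shared: Sequence[int],
                       median_rmsd: Sequence[float]) -> RobustFit:
    """Huber M-estimator regression of median RMSD on partner counts.

    pseudo-R² = 1 − Σρ(residual/s) / Σρ(null residual/s) with the Huber loss
    (c = 1.345) and the fitted model's scale s; an intercept-only robust fit
    is the null.  May be negative when predictors carry no signal.
    """
    X = np.column_stack([np.asarray(n_partners_p, float),
                         np.asarray(n_partners_np, float),
                         np.asarray(n_shared, float)])
    y = np.asarray(median_rmsd, float)
    if len(y) < 5:
        raise ValueError("need >= 5 observations")
    Xc = sm.add_constant(X)
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("rank-deficient design matrix")
    norm = sm.robust.norms.HuberT(t=1.345)
    fit = sm.RLM(y, Xc, M=norm).fit()
    null = sm.RLM(y, np.ones((len(y), 1)), M=norm).fit()
    s = fit.scale if fit.scale > 0 else 1.0
    rho = norm.rho((y - fit.fittedvalues) / s).sum()
    rho0 = norm.rho((y - null.fittedvalues) / s).sum()
    pseudo_r2 = 1.0 - rho / rho0 if rho0 > 0 else 0.0
    return RobustFit(fit.params, fit.bse, float(pseudo_r2),
                     meta={"loss": "HuberT", "tuning_c": 1.345,
                           "pseudo_r2": "1 - sum(rho)/sum(rho_null)"})
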