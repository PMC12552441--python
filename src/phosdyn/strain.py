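"""Finite-strain analysis of conformational change.

For each Cα a local deformation gradient F is fitted by least squares over
the relative positions of its 12 Å neighborhood (reference and deformed
neighborhoods intersected), and summarised by the principal stretches
λ1 ≤ λ2 ≤ λ3 — the square roots of the eigenvalues of the Cauchy tensor
FᵀF.  λ3 (the extensive stretch) is the working deformation measure.
Site-level strain aggregates geometric means per comparison then arithmetic
means across comparisons, with significance from site-relocation bootstrap
(mean + 3σ criterion, n = 50).  The high-strain manifold is the set of
top-strained residues of minimal correlation dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .structures import PhosphositeGroup, ResidueMap, StructureRecord, \
    align_residue_pair

STRAIN_RADIUS = 12.0       # Å neighborhood for the deformation gradient
MIN_NEIGHBORS = 4
BOOTSTRAP_N = 50


def principal_stretches(F: np.ndarray) -> Tuple[float, float, float]:
    """Principal stretches λ1 ≤ λ2 ≤ λ3 of a deformation gradient.

    λ_i are the square roots of the eigenvalues of the Cauchy tensor FᵀF;
    any proper rotation gives (1, 1, 1).  Raises on a singular F.
    """
    F = np.asarray(F, float)
    if abs(np.linalg.det(F)) < 1e-12:
        raise ValueError("singular deformation gradient")
    w = np.linalg.eigvalsh(F.T @ F)
    lam = np.sqrt(np.clip(w, 0.0, None))
    return tuple(float(x) for x in np.sort(lam))


@dataclass
class StrainField:
    reference_id: str
    deformed_id: str
    lambdas: np.ndarray            # (n_mapped, 3), NaN rows = unscored
    neighbor_count: np.ndarray
    author_indices: List[int]      # of the reference structure's residues

    @property
    def lambda3(self) -> np.ndarray:
        return self.lambdas[:, 2]

    def scored(self) -> np.ndarray:
        return ~np.isnan(self.lambdas[:, 2])


def strain_field(reference: StructureRecord, deformed: StructureRecord,
                 residue_map: Optional[ResidueMap] = None,
                 radius: float = STRAIN_RADIUS) -> StrainField:
    """Per-residue principal stretches between two structures.

    Neighborhoods: mapped Cα within ``radius`` of residue i in the reference,
    intersected with the deformed-state 12 Å neighborhood.  F_i minimises
    Σ_j ‖F·d⁰_ij − d_ij‖² over relative positions; residues with fewer than
    4 usable or near-coplanar neighbors are left unscored (NaN).
    """
    if residue_map is None:
        residue_map = align_residue_pair(reference, deformed)
    pairs = [(i, j) for i, j in residue_map.pairs
             if "CA" in reference.residues[i].atoms
             and "CA" in deformed.residues[j].atoms]
    if not pairs:
        raise ValueError("no mapped residues with Calpha")
    ref_xyz = reference.ca_coords([i for i, _ in pairs])
    def_xyz = deformed.ca_coords([j for _, j in pairs])
    n = len(pairs)
    d_ref = np.linalg.norm(ref_xyz[:, None] - ref_xyz[None], axis=-1)
    d_def = np.linalg.norm(def_xyz[:, None] - def_xyz[None], axis=-1)

    lambdas = np.full((n, 3), np.nan)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        neigh = np.where((d_ref[i] <= radius) & (d_def[i] <= radius))[0]
        neigh = neigh[neigh != i]
        counts[i] = len(neigh)
        if len(neigh) < MIN_NEIGHBORS:
            continue
        D0 = ref_xyz[neigh] - ref_xyz[i]       # (m, 3)
        D1 = def_xyz[neigh] - def_xyz[i]
        s = np.linalg.svd(D0 - D0.mean(axis=0), compute_uv=False)
        if s[-1] <= 1e-6:
            continue                            # near-coplanar neighborhood
        # F = argmin Σ ||F d0 - d||²  ->  F = (D1ᵀ D0)(D0ᵀ D0)⁻¹
        A = D0.T @ D0
        B = D1.T @ D0
        F = B @ np.linalg.inv(A)
        try:
            lambdas[i] = principal_stretches(F)
        except ValueError:
            continue
    if not np.any(~np.isnan(lambdas[:, 2])):
        raise ValueError("no residue with a sufficient neighborhood")
    return StrainField(reference.structure_id, deformed.structure_id,
                       lambdas, counts,
                       [reference.residues[i].author_index for i, _ in pairs])


def group_strain_fields(group: PhosphositeGroup,
                        radius: float = STRAIN_RADIUS) -> List[StrainField]:
    """All cross-state strain fields (non-phospho reference → phospho)."""
    fields = []
    for ref in group.nonphospho_structures:
        for dfm in group.phospho_structures:
            fields.append(strain_field(ref, dfm, radius=radius))
    return fields


# ---------------------------------------------------------------------------
# site-level strain


def _field_site_geomean(field: StrainField, site: Sequence[int]) -> float:
    """Geometric mean of λ3 over the site's author indices in one field."""
    pos = {a: i for i, a in enumerate(field.author_indices)}
    vals = [field.lambda3[pos[a]] for a in site
            if a in pos and not np.isnan(field.lambda3[pos[a]])]
    if not vals:
        return float("nan")
    return float(np.exp(np.mean(np.log(vals))))


def site_mean_strain(fields: Sequence[StrainField],
                     site: Sequence[int]) -> float:
    """⟨λ3⟩: geometric mean per comparison, arithmetic mean across them."""
    means = [_field_site_geomean(f, site) for f in fields]
    means = [m for m in means if m == m]
    if not means:
        raise ValueError("site absent from every strain field")
    return float(np.mean(means))


@dataclass
class SiteStrainResult:
    site: List[int]
    mean_extensive_stretch: float
    bootstrap_mean: float
    bootstrap_sd: float
    significant: bool
    n_bootstrap: int


def bootstrap_site_significance(fields: Sequence[StrainField],
                                site: Sequence[int],
                                n: int = BOOTSTRAP_N,
                                seed: int = 0,
                                contiguous: bool = True) -> SiteStrainResult:
    """Site-relocation bootstrap of ⟨λ3⟩ with the mean + 3σ criterion.

    Each draw relocates the site to a random position preserving its size
    (a contiguous window for contiguous sites, a random subset otherwise);
    the site is significantly strained when the observed ⟨λ3⟩ exceeds the
    bootstrap mean plus three bootstrap standard deviations.
    """
    if n < 2:
        raise ValueError("need at least 2 bootstrap draws")
    rng = np.random.default_rng(seed)
    observed = site_mean_strain(fields, site)
    all_authors = sorted(set().union(*[set(f.author_indices)
                                       for f in fields]))
    size = len(site)
    if size >= len(all_authors):
        raise ValueError("site covers the whole protein")
    draws = []
    for _ in range(n):
        while True:
            if contiguous:
                start = rng.integers(0, len(all_authors) - size + 1)
                fake = all_authors[start:start + size]
            else:
                fake = list(rng.choice(all_authors, size=size,
                                       replace=False))
            try:
                draws.append(site_mean_strain(fields, fake))
                break
            except ValueError:
                continue
    mu, sd = float(np.mean(draws)), float(np.std(draws))
    return SiteStrainResult(list(site), observed, mu, sd,
                            significant=observed > mu + 3.0 * sd,
                            n_bootstrap=n)


@dataclass
class CoStrainingResult:
    phosphosite: List[int]
    functional_site: List[int]
    phospho_significant: bool
    functional_significant: bool
    co_strained: bool
    distance: Optional[float]
    overlap: bool


def co_straining_classification(phospho_result: SiteStrainResult,
                                functional_result: SiteStrainResult,
                                structure: Optional[StructureRecord] = None,
                                ) -> CoStrainingResult:
    """Pairwise co-straining call plus minimal Cα–Cα site distance.

    A pair is co-strained when both sites are significantly strained; the
    distance is the minimum Euclidean Cα distance between the phosphosite
    and the functional-site residues (None when unmodelled), and overlapping
    sites are flagged.
    """
    psite = set(phospho_result.site)
    fsite = set(functional_result.site)
    distance = None
    if structure is not None:
        by_author = {r.author_index: r for r in structure.residues}
        d = []
        for a in psite:
            for b in fsite:
                ra, rb = by_author.get(a), by_author.get(b)
                if ra and rb and "CA" in ra.atoms and "CA" in rb.atoms:
                    d.append(np.linalg.norm(ra.atoms["CA"] - rb.atoms["CA"]))
        distance = float(min(d)) if d else None
    return CoStrainingResult(
        sorted(psite), sorted(fsite),
        phospho_result.significant, functional_result.significant,
        co_strained=phospho_result.significant
        and functional_result.significant,
        distance=distance,
        overlap=bool(psite & fsite))


# ---------------------------------------------------------------------------
# correlation dimension and the high-strain manifold


def correlation_dimension(points: np.ndarray,
                          fit_range: Tuple[float, float] = (1.0, 20.0),
                          n_radii: int = 24) -> float:
    """Grassberger–Procaccia estimate of the correlation dimension ν.

    The correlation integral C(r) (fraction of point pairs within r) is
    evaluated on log-spaced radii between the ``fit_range`` percentiles of
    the pairwise-distance distribution (small radii: the power-law scaling
    regime; wider windows run into boundary saturation and bias ν low), and
    ν is the slope of log C(r) vs log r.  Identical points give ν = 0.
    """
    pts = np.asarray(points, float)
    if len(pts) < 10:
        raise ValueError("need at least 10 points")
    d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
    iu = np.triu_indices(len(pts), k=1)
    dists = d[iu]
    positive = dists[dists > 0]
    if positive.size == 0:
        return 0.0
    lo, hi = np.percentile(positive, fit_range)
    if hi <= lo:
        return 0.0
    radii = np.geomspace(lo, hi, n_radii)
    c = np.array([(dists <= r).mean() for r in radii])
    ok = c > 0
    slope = np.polyfit(np.log(radii[ok]), np.log(c[ok]), 1)[0]
    return float(max(slope, 0.0))


@dataclass
class ManifoldResult:
    residues: List[int]            # author indices of the manifold
    size: int
    nu: float
    scan: List[Tuple[int, float]] = field(default_factory=list)


def high_strain_manifold(field: StrainField, coords: np.ndarray,
                         scan_fractions: Optional[np.ndarray] = None
                         ) -> ManifoldResult:
    """Top-strained residue set of minimal correlation dimension.

    Scans manifold sizes N over 5%–60% of scored residues (5% steps), takes
    the N residues of largest λ3 for each, and returns the set minimising ν
    (ties → smallest N).  ``coords`` are Cα coordinates aligned with the
    field's residues.
    """
    scored = np.where(field.scored())[0]
    if len(scored) < 20:
        raise ValueError("need >= 20 scored residues")
    if scan_fractions is None:
        scan_fractions = np.arange(0.05, 0.601, 0.05)
    lam = field.lambda3[scored]
    order = scored[np.argsort(-lam)]           # descending λ3
    best = None
    scan = []
    for frac in scan_fractions:
        N = max(int(round(frac * len(scored))), 10)
        if N > len(scored):
            continue
        subset = order[:N]
        nu = correlation_dimension(coords[subset])
        scan.append((N, nu))
        if best is None or nu < best[1] - 1e-12:
            best = (N, nu, subset)
    if best is None:
        raise ValueError("empty manifold scan range")
    N, nu, subset = best
    residues = sorted(field.author_indices[i] for i in subset)
    return ManifoldResult(residues, N, nu, scan)


def manifold_representation(site: Sequence[int],
                            manifolds: Sequence[ManifoldResult]) -> float:
    """Mean fraction of site residues inside the manifold across comparisons."""
    if not site:
        raise ValueError("empty site")
    if not manifolds:
        raise ValueError("no manifolds")
    fracs = [len(set(site) & set(m.residues)) / len(site) for m in manifolds]
    return float(np.mean(fracs))


def lambda3_bfactor_lines(structure: StructureRecord,
                          field: StrainField) -> List[str]:
    """Cα PDB lines with λ3 written to the B-factor column (visualisation)."""
    pos = {a: i for i, a in enumerate(field.author_indices)}
    lines = []
    serial = 1
    for res in structure.residues:
        if "CA" not in res.atoms or res.author_index not in pos:
            continue
        lam = field.lambda3[pos[res.author_index]]
        if np.isnan(lam):
            continue
        x, y, z = res.atoms["CA"]
        lines.append(
            f"ATOM  {serial:5d}  CA  {res.aa3:<3s} A{res.author_index:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{lam:6.2f}"
            f"           C")
        serial += 1
    return lines
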