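"""Comparison of intrinsic dynamics between phospho-states.

Covers: Pearson correlation of residue-fluctuation profiles per comparison
class; global flexibility change (two-sample KS on per-residue state
medians); the data-driven peak-significance cutoff (local maxima of
|Δfluctuation| profiles, 1.5×IQR outlier removal, median + 6·SD) and the
combined local-change call; the 12 Å Cβ phosphosite-neighborhood test; mode
matching by Hungarian assignment on 1−RMSIP costs with frequency-window
summaries; and residue-residue coupling analysis via linear mutual
information matrices compared with the RV2 coefficient, classified as
relaxation / tensioning / rewiring.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .enm import EnsembleNMA, ModeSet
from .stats import TestResult, ks_two_sample, wilcoxon_signed_rank

MODE_WINDOWS = {"global": (1, 3), "LF": (4, 20), "LTIF": (21, 60)}
NEIGHBORHOOD_RADIUS = 12.0       # Å, Cβ rule
REWIRING_RV2_THRESHOLD = 0.90


# ---------------------------------------------------------------------------
# fluctuation profiles


def _state_profiles(ens: EnsembleNMA) -> Tuple[np.ndarray, np.ndarray]:
    """(n_phospho, n_core) and (n_nonphospho, n_core) fluctuation arrays."""
    p = np.array([ens.mode_sets[i].residue_fluctuations
                  for i in ens.phospho_ids])
    n = np.array([ens.mode_sets[i].residue_fluctuations
                  for i in ens.nonphospho_ids])
    return p, n


def fluctuation_correlations(ens: EnsembleNMA) -> Dict[str, List[float]]:
    """Pearson r of core fluctuation profiles per comparison class."""
    p, n = _state_profiles(ens)
    if p.shape[1] < 3:
        raise ValueError("need >= 3 core residues")

    def corr(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    out = {"P_vs_P": [corr(a, b) for a, b in itertools.combinations(p, 2)],
           "NP_vs_NP": [corr(a, b) for a, b in itertools.combinations(n, 2)],
           "P_vs_NP": [corr(a, b) for a in p for b in n]}
    return out


def global_flexibility_test(ens: EnsembleNMA) -> TestResult:
    """Two-sample KS between per-residue median fluctuations of each state."""
    p, n = _state_profiles(ens)
    if p.shape[1] < 3:
        raise ValueError("need >= 3 core residues")
    med_p = np.median(p, axis=0)
    med_n = np.median(n, axis=0)
    res = ks_two_sample(med_p, med_n)
    res.label = "increase" if np.median(med_p) > np.median(med_n) \
        else "decrease"
    return res


# ---------------------------------------------------------------------------
# peak significance


def find_peaks_1d(profile: np.ndarray) -> List[Tuple[int, float]]:
    """Interior local maxima of a profile; plateau ties go to the leftmost.

    Endpoints are never peaks (a maximum must fall off on both sides), so a
    constant profile has none.
    """
    peaks = []
    n = len(profile)
    for i in range(1, n - 1):
        left, right = profile[i - 1], profile[i + 1]
        if profile[i] > left and profile[i] > right:
            peaks.append((i, float(profile[i])))
        elif profile[i] > left and profile[i] == right:
            # leftmost point of a plateau that falls off before the boundary
            j = i
            while j < n - 1 and profile[j + 1] == profile[i]:
                j += 1
            if j < n - 1 and profile[i] > profile[j + 1]:
                peaks.append((i, float(profile[i])))
    return peaks


def abs_difference_profiles(ens: EnsembleNMA) -> List[np.ndarray]:
    """|Δfluctuation| profiles for every cross-state structure pair."""
    p, n = _state_profiles(ens)
    return [np.abs(a - b) for a in p for b in n]


def derive_peak_cutoff(profiles: Sequence[np.ndarray]) -> float:
    """Significance cutoff for |Δfluctuation| peaks.

    Pools the heights of all local maxima across profiles, removes
    1.5×IQR outliers, and returns median + 6·SD of the remainder.
    """
    heights = []
    for prof in profiles:
        heights.extend(h for _, h in find_peaks_1d(np.asarray(prof, float)))
    if not heights:
        raise ValueError("no local maxima in any profile")
    h = np.asarray(heights, float)
    q1, q3 = np.percentile(h, [25, 75])
    iqr = q3 - q1
    keep = h[(h >= q1 - 1.5 * iqr) & (h <= q3 + 1.5 * iqr)]
    return float(np.median(keep) + 6.0 * np.std(keep))


@dataclass
class FluctuationComparison:
    median_p: np.ndarray
    median_np: np.ndarray
    difference: np.ndarray              # median_p - median_np
    peaks: List[Tuple[int, float]] = field(default_factory=list)
    significant_peaks: List[Tuple[int, float]] = field(default_factory=list)
    wilcoxon: Optional[TestResult] = None
    combined_call: bool = False
    direction: str = "mixed"


def compare_fluctuations(ens: EnsembleNMA) -> FluctuationComparison:
    """Median-per-state fluctuation difference profile with Wilcoxon test."""
    p, n = _state_profiles(ens)
    med_p, med_n = np.median(p, axis=0), np.median(n, axis=0)
    diff = med_p - med_n
    comp = FluctuationComparison(med_p, med_n, diff)
    comp.peaks = find_peaks_1d(np.abs(diff))
    comp.wilcoxon = wilcoxon_signed_rank(med_p, med_n)
    return comp


def local_fluctuation_calls(comp: FluctuationComparison,
                            cutoff: float) -> FluctuationComparison:
    """Apply the peak cutoff (strictly exceeds) and the combined criterion."""
    comp.significant_peaks = [(i, h) for i, h in comp.peaks if h > cutoff]
    padj = comp.wilcoxon.p_adjusted if comp.wilcoxon and \
        comp.wilcoxon.p_adjusted is not None else \
        (comp.wilcoxon.p_value if comp.wilcoxon else float("nan"))
    comp.combined_call = bool(comp.significant_peaks) and \
        (padj == padj and padj <= 0.05)
    if comp.significant_peaks:
        signs = np.sign([comp.difference[i] for i, _ in
                         comp.significant_peaks])
        if np.all(signs > 0):
            comp.direction = "increase"
        elif np.all(signs < 0):
            comp.direction = "decrease"
        else:
            comp.direction = "mixed"
    return comp


def phosphosite_neighborhood(ens: EnsembleNMA, site_author_index: int
                             ) -> Optional[set]:
    """Core indices of residues in the 12 Å Cβ neighborhood of the site.

    A residue belongs to the neighborhood when its Cβ (Cα for glycine) lies
    within 12 Å of the phosphosite's Cβ (Cα for glycine) in *any* relevant
    structure.  Returns None when the site is unmodelled in one of the
    states (no reference point).
    """
    group = ens.group

    def anchor_atom(res):
        return res.atoms.get("CB") if res.aa3 != "GLY" else res.atoms.get("CA")

    neighborhood: set = set()
    seen_in = {"P": False, "NP": False}
    for state, recs in (("P", group.phospho_structures),
                        ("NP", group.nonphospho_structures)):
        for rec in recs:
            if rec.structure_id not in ens.core_positions:
                continue
            positions = ens.core_positions[rec.structure_id]
            by_author = {rec.residues[p].author_index: (ci, rec.residues[p])
                         for ci, p in enumerate(positions)}
            if site_author_index not in by_author:
                continue
            seen_in[state] = True
            _, site_res = by_author[site_author_index]
            ref = anchor_atom(site_res)
            if ref is None:
                continue
            for ci, p in enumerate(positions):
                a = anchor_atom(rec.residues[p])
                if a is not None and np.linalg.norm(a - ref) <= \
                        NEIGHBORHOOD_RADIUS:
                    neighborhood.add(ci)
    if not (seen_in["P"] and seen_in["NP"]):
        return None
    return neighborhood


def neighborhood_fluctuation_test(ens: EnsembleNMA,
                                  site_author_index: int
                                  ) -> Optional[TestResult]:
    """KS of median fluctuation differences: site neighborhood vs background.

    Returns None (skipped) when the phosphosite is unmodelled in some state
    or the neighborhood/background is too small.  Note that fluctuation
    differences scale with local flexibility, so this statistic partly
    reflects where the site sits on the flexibility profile, not only the
    designed perturbation.
    """
    neighborhood = phosphosite_neighborhood(ens, site_author_index)
    if neighborhood is None:
        return None  # no reference point in one state
    p, n = _state_profiles(ens)
    diff = np.median(p, axis=0) - np.median(n, axis=0)
    neigh = sorted(neighborhood)
    background = [i for i in range(len(diff)) if i not in neighborhood]
    if len(neigh) < 3 or len(background) < 3:
        return None
    res = ks_two_sample(diff[neigh], diff[background])
    res.label = f"site_{site_author_index}"
    return res


# ---------------------------------------------------------------------------
# mode matching


def rmsip(modes_a: np.ndarray, modes_b: np.ndarray) -> float:
    """Root mean squared inner product between two mode subspaces.

    Columns are mode vectors of equal dimension; RMSIP =
    sqrt((1/k) Σ_i Σ_j (a_i · b_j)²) with k the subset size of A.
    """
    a = np.asarray(modes_a, float)
    b = np.asarray(modes_b, float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[0] != b.shape[0]:
        raise ValueError("mode vector dimensions differ")
    k = a.shape[1]
    ip = a.T @ b
    return float(np.sqrt((ip ** 2).sum() / k))


@dataclass
class ModeMatch:
    permutation: np.ndarray              # index in A -> matched index in B
    pair_similarity: np.ndarray          # |v_i . u_perm(i)| in [0, 1]
    window_summary: Dict[str, float] = field(default_factory=dict)


def match_modes(a: ModeSet, b: ModeSet, k: int = 20) -> ModeMatch:
    """Optimal mode pairing by the Hungarian algorithm.

    Cost(i, j) = 1 − |v_i · u_j| (the k=1 RMSIP; absolute value handles the
    eigenvector sign ambiguity).  If fewer than k modes are available, k is
    reduced.  Ties resolve to the lexicographically smallest assignment.
    """
    k = min(k, a.n_modes, b.n_modes)
    va = a.eigenvectors[:, :k]
    vb = b.eigenvectors[:, :k]
    sim = np.abs(va.T @ vb)
    # tiny index-dependent perturbation steers equal-cost optima to the
    # lowest-index pairing, keeping the result deterministic
    eps = 1e-12 * (np.arange(k)[:, None] + np.arange(k)[None, :])
    rows, cols = linear_sum_assignment(1.0 - sim + eps)
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    return ModeMatch(perm, sim[rows, perm[rows]])


def window_mode_similarity(matches: Sequence[ModeMatch],
                           n_modes: int) -> Dict[str, float]:
    """Median matched-pair similarity per frequency window across matches.

    Windows: global k=1–3, LF k=4–20, LTIF k=21–60, HF k>60 (1-based mode
    ranks in structure A); the HF upper bound is the number of available
    modes.
    """
    windows = dict(MODE_WINDOWS)
    windows["HF"] = (61, n_modes)
    out = {}
    for name, (lo, hi) in windows.items():
        vals = []
        for m in matches:
            idx = np.arange(len(m.permutation))
            sel = (idx + 1 >= lo) & (idx + 1 <= hi)
            vals.extend(m.pair_similarity[sel])
        out[name] = float(np.median(vals)) if vals else float("nan")
    return out


def rmsip_stratum(median_rmsip_20: float) -> str:
    if median_rmsip_20 >= 0.90:
        return ">=0.90"
    if median_rmsip_20 >= 0.80:
        return "0.80-0.90"
    return "<0.80"


def group_mode_comparison(ens: EnsembleNMA, k: int = 20) -> dict:
    """Cross-state mode matching summary for one phosphosite group."""
    matches, rmsips = [], []
    n_modes = min(ens.mode_sets[i].n_modes
                  for i in ens.phospho_ids + ens.nonphospho_ids)
    for pid in ens.phospho_ids:
        for nid in ens.nonphospho_ids:
            a, b = ens.mode_sets[pid], ens.mode_sets[nid]
            m = match_modes(a, b, k=min(n_modes, max(k, 80)))
            matches.append(m)
            kk = min(k, len(m.pair_similarity))
            rmsips.append(float(np.median(m.pair_similarity[:kk])))
    med = float(np.median(rmsips))
    return {"median_rmsip_20": med,
            "stratum": rmsip_stratum(med),
            "window_summary": window_mode_similarity(matches, n_modes),
            "matches": matches}


# ---------------------------------------------------------------------------
# linear mutual information and RV2


def lmi_matrix(modes: ModeSet) -> np.ndarray:
    """Generalized-correlation matrix from linear (Gaussian) mutual information.

    The residue-residue displacement covariance is assembled from the modes
    weighted by inverse eigenvalues; for each pair, the Gaussian MI
    I = ½(ln det Ci + ln det Cj − ln det Cij) is mapped to
    r_MI = sqrt(1 − exp(−2I/3)) ∈ [0, 1].  Diagonal is 1; singular marginals
    give 0.
    """
    wts = (modes.component_weight ** 2
           if modes.component_weight is not None else
           np.ones_like(modes.eigenvalues))
    V = modes.eigenvectors * np.sqrt(wts / modes.eigenvalues)
    n_res = int(modes.node_residue.max()) + 1
    if len(V) != 3 * n_res:
        raise ValueError("LMI requires one Calpha node per residue")
    C = V @ V.T                                    # (3n, 3n)
    out = np.eye(n_res)
    logdets = np.empty(n_res)
    for i in range(n_res):
        ci = C[3 * i:3 * i + 3, 3 * i:3 * i + 3]
        sign, ld = np.linalg.slogdet(ci)
        logdets[i] = ld if sign > 0 else -np.inf
    for i in range(n_res):
        for j in range(i + 1, n_res):
            if not np.isfinite(logdets[i]) or not np.isfinite(logdets[j]):
                continue
            idx = np.r_[3 * i:3 * i + 3, 3 * j:3 * j + 3]
            sign, ld = np.linalg.slogdet(C[np.ix_(idx, idx)])
            if sign <= 0:
                # numerically perfect dependence: joint covariance singular
                r = 1.0
            else:
                mi = max(0.0, 0.5 * (logdets[i] + logdets[j] - ld))
                r = np.sqrt(1.0 - np.exp(-2.0 * mi / 3.0))
            out[i, j] = out[j, i] = r
    return out


def rv2_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """Diagonal-corrected matrix correlation (RV2) in [−1, 1].

    X̃ = XXᵀ with zeroed diagonal (same for Y);
    RV2 = tr(X̃Ỹ) / sqrt(tr(X̃X̃)·tr(ỸỸ)).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape:
        raise ValueError("matrices must share a shape")
    xt = X @ X.T
    yt = Y @ Y.T
    np.fill_diagonal(xt, 0.0)
    np.fill_diagonal(yt, 0.0)
    denom = np.sqrt((xt * xt).sum() * (yt * yt).sum())
    if denom == 0:
        raise ValueError("zero matrix has undefined RV2")
    return float((xt * yt).sum() / denom)


@dataclass
class CouplingComparison:
    mi_by_structure: Dict[str, np.ndarray]
    median_mi_p: np.ndarray
    median_mi_np: np.ndarray
    delta_mi_overall: float          # mean off-diagonal (P − NP)
    rv2_between: float               # median RV2 over cross-state pairs
    classification: str = ""


def compare_couplings(ens: EnsembleNMA) -> CouplingComparison:
    """LMI matrices per structure; state medians; ΔMI and cross-state RV2."""
    mi = {sid: lmi_matrix(ms) for sid, ms in ens.mode_sets.items()}
    mp = np.median([mi[i] for i in ens.phospho_ids], axis=0)
    mn = np.median([mi[i] for i in ens.nonphospho_ids], axis=0)
    off = ~np.eye(len(mp), dtype=bool)
    delta = float((mp - mn)[off].mean())
    rv2s = [rv2_coefficient(mi[p], mi[n])
            for p in ens.phospho_ids for n in ens.nonphospho_ids]
    return CouplingComparison(mi, mp, mn, delta, float(np.median(rv2s)))


def classify_coupling_change(delta_mi: float, rv2_between: float,
                             dataset_deltas: Sequence[float],
                             rewiring_threshold: float =
                             REWIRING_RV2_THRESHOLD) -> str:
    """Relaxation / tensioning / rewiring / unchanged call.

    Bounds are the dataset median ± one SD of the overall ΔMI distribution:
    above → tensioning, below → relaxation; within bounds the call is
    rewiring when the cross-state RV2 falls under the threshold, else
    unchanged.
    """
    d = np.asarray(dataset_deltas, float)
    if d.size == 0:
        raise ValueError("dataset context required")
    lo = float(np.median(d) - np.std(d))
    hi = float(np.median(d) + np.std(d))
    if delta_mi > hi:
        return "tensioning"
    if delta_mi < lo:
        return "relaxation"
    if rv2_between < rewiring_threshold:
        return "rewiring"
    return "unchanged"


def residue_communities(mi: np.ndarray, min_cluster_size: int = 2,
                        min_samples: int = 5) -> np.ndarray:
    """Density clustering of residues with (1 − MI) as dissimilarity.

    Returns per-residue labels; −1 marks unclustered (noise) residues.
    """
    from sklearn.cluster import HDBSCAN
    dist = 1.0 - np.asarray(mi, float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    n = len(dist)
    if n < 3:
        return np.zeros(n, dtype=int)
    ms = min(min_samples, n - 1)
    h = HDBSCAN(min_cluster_size=min_cluster_size, min_samples=ms,
                metric="precomputed", copy=True)
    return h.fit(dist).labels_
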