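"""Synthetic structure ensembles with known ground truth.

Generates groups of homologous structures of one protein in two labelled
states (phosphorylated / non-phosphorylated) with a controllable
conformational shift (location, magnitude, state populations), per-atom
Gaussian coordinate noise, designed localized affine deformations with
known principal stretches, and the curation metadata (resolution, R-free,
last author) the quality filters consume.  Everything is deterministic
under a seed; ground truth is serialised beside the corpus.

Geometry is idealised (helix: 1.5 Å rise, 100°/residue; strand: 3.3 Å rise;
self-avoiding coil walk) with N, Cα, C, Cβ atoms (plus OG on serines) —
sufficient for the 3–5-node elastic networks and the Cβ neighborhood rule,
with no claim of side-chain realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .structures import PhosphositeGroup, ResidueRecord, \
    StructureRecord, THREE_TO_ONE

_AA_POOL = "ADEFGHIKLMNQRSTVWY"
_ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: taper width (residues) per Å of shift; keeps Cα steps below the
#: chain-break threshold for any shift magnitude
SHIFT_RAMP_PER_ANGSTROM = 2.4
MIN_SHIFT_RAMP = 4


def shift_ramp_width(vector) -> int:
    """Taper width used when a region shift of this vector is applied."""
    norm = float(np.linalg.norm(np.asarray(vector, float)))
    return max(MIN_SHIFT_RAMP,
               int(np.ceil(SHIFT_RAMP_PER_ANGSTROM * norm)))


@dataclass
class SyntheticSpec:
    uniprot_id: str = "PSYN1"
    n_residues: int = 60
    n_phospho: int = 4
    n_nonphospho: int = 6
    noise_sigma: float = 0.3           # Å RMS per-structure displacement
    noise_model: str = "smooth"        # "smooth" (low-mode) | "isotropic"
    geometry: str = "helix"
    phosphosite: int = 30              # author residue number, SEP
    # two-state conformational shift
    shift_region: Optional[Tuple[int, int]] = None   # author numbers, incl.
    shift_vector: Tuple[float, float, float] = (0.0, 0.0, 5.0)
    populations: Tuple[float, float] = (0.5, 0.5)    # non-phospho (A, B)
    # localized affine deformation applied to state B
    deform_region: Optional[Tuple[int, int]] = None
    deform_F: Optional[np.ndarray] = None
    resolution_range: Tuple[float, float] = (1.5, 2.5)
    r_free_range: Tuple[float, float] = (0.18, 0.28)
    author_pool: Tuple[str, ...] = ("A.AUSTEN", "B.BRONTE", "C.CATHER",
                                    "D.DICKENS")
    seed: int = 0


# ---------------------------------------------------------------------------
# backbone generation


def _ca_trace(n: int, geometry: str, rng: np.random.Generator) -> np.ndarray:
    if geometry == "helix":
        theta = np.radians(100.0) * np.arange(n)
        return np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta),
                         1.5 * np.arange(n)], axis=1)
    if geometry == "strand":
        z = 3.3 * np.arange(n)
        y = 0.95 * (-1.0) ** np.arange(n)
        return np.stack([np.zeros(n), y, z], axis=1)
    if geometry == "coil":
        pts = [np.zeros(3)]
        while len(pts) < n:
            for _ in range(200):
                step = rng.normal(size=3)
                step *= 3.8 / np.linalg.norm(step)
                cand = pts[-1] + step
                if all(np.linalg.norm(cand - p) >= 2.0 for p in pts[:-1]):
                    pts.append(cand)
                    break
            else:
                raise RuntimeError("self-avoiding walk stuck")
        return np.array(pts)
    raise ValueError(f"unknown geometry {geometry!r}")


def _decorate_backbone(ca: np.ndarray) -> List[Dict[str, np.ndarray]]:
    """Place N, C, Cβ around each Cα with locally rigid ideal offsets."""
    n = len(ca)
    out = []
    for i in range(n):
        prev = ca[i - 1] if i > 0 else 2 * ca[i] - ca[i + 1]
        nxt = ca[i + 1] if i < n - 1 else 2 * ca[i] - ca[i - 1]
        t = nxt - prev
        t /= np.linalg.norm(t)
        m = ca[i] - 0.5 * (prev + nxt)
        if np.linalg.norm(m) < 1e-6:
            m = np.cross(t, [0.0, 0.0, 1.0])
            if np.linalg.norm(m) < 1e-6:
                m = np.cross(t, [0.0, 1.0, 0.0])
        m /= np.linalg.norm(m)
        b = np.cross(t, m)
        out.append({
            "N": ca[i] - 1.20 * t + 0.60 * m,
            "CA": ca[i].copy(),
            "C": ca[i] + 1.25 * t + 0.55 * b,
            "CB": ca[i] + 0.70 * m - 1.25 * b,
        })
    return out


def generate_backbone(n_residues: int, geometry: str = "helix",
                      seed: int = 0,
                      sequence: Optional[str] = None,
                      uniprot_id: str = "PSYN1",
                      structure_id: str = "SYN1_A") -> StructureRecord:
    """Ideal-geometry backbone with N, Cα, C, Cβ (OG on serines)."""
    if n_residues < 5:
        raise ValueError("need >= 5 residues")
    rng = np.random.default_rng(seed)
    ca = _ca_trace(n_residues, geometry, rng)
    if sequence is None:
        sequence = "".join(rng.choice(list(_AA_POOL), size=n_residues))
    atoms = _decorate_backbone(ca)
    residues = []
    for i, (c, aa1) in enumerate(zip(atoms, sequence)):
        aa3 = _ONE_TO_THREE.get(aa1, "ALA")
        d = dict(c)
        if aa3 == "GLY":
            d.pop("CB")
        if aa3 == "SER":
            d["OG"] = d["CB"] + np.array([0.0, 0.0, 1.2])
        residues.append(ResidueRecord(i + 1, aa3, d))
    return StructureRecord(structure_id, uniprot_id, [residues])


# ---------------------------------------------------------------------------
# perturbations


def _copy_structure(rec: StructureRecord, structure_id: str
                    ) -> StructureRecord:
    models = [[ResidueRecord(r.author_index, r.aa3,
                             {k: v.copy() for k, v in r.atoms.items()},
                             r.phospho_code)
               for r in model] for model in rec.models]
    return StructureRecord(structure_id, rec.uniprot_id, models,
                           rec.method, rec.resolution, rec.r_free,
                           rec.last_author)


def perturb_ensemble(base: StructureRecord, n: int, sigma: float,
                     seed: int = 0) -> List[StructureRecord]:
    """n copies with isotropic per-atom Gaussian noise of scale sigma."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        rec = _copy_structure(base, f"{base.structure_id}_p{i}")
        for res in rec.residues:
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + rng.normal(0.0, sigma, 3)
        out.append(rec)
    return out


def smooth_perturb_ensemble(base: StructureRecord, n: int, sigma: float,
                            seed: int = 0,
                            n_waves: int = 6) -> List[StructureRecord]:
    """n copies perturbed by smooth low-mode displacement fields.

    Each structure gets a displacement field that varies sinusoidally along
    the sequence (a superposition of the ``n_waves`` lowest standing waves
    with random amplitudes and directions, RMS amplitude ``sigma``); all
    atoms of a residue move together.  This emulates the spatially
    correlated variation of real homologous structures without stretching
    bonds, so perturbed ensembles keep chain continuity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    n_res = len(base.residues)
    t = np.arange(n_res)
    out = []
    for i in range(n):
        rec = _copy_structure(base, f"{base.structure_id}_s{i}")
        disp = np.zeros((n_res, 3))
        for m in range(1, n_waves + 1):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            phase = rng.uniform(0, 2 * np.pi)
            amp = rng.normal(0.0, 1.0) / m
            disp += amp * np.sin(np.pi * m * t / n_res + phase)[:, None] \
                * direction
        rms = np.sqrt((disp ** 2).sum(axis=1).mean())
        if rms > 0 and sigma > 0:
            disp *= sigma / rms
        else:
            disp[:] = 0.0
        for ri, res in enumerate(rec.residues):
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + disp[ri]
        out.append(rec)
    return out


def _shift_weights(rec: StructureRecord, region: Tuple[int, int],
                   ramp: int) -> Dict[int, float]:
    """Per-residue shift weight: 1 inside the region, cosine taper outside.

    Tapering keeps consecutive Cα steps under the chain-break threshold so
    shifted ensembles stay eligible for ensemble NMA.
    """
    lo, hi = region
    w = {}
    for res in rec.residues:
        a = res.author_index
        if lo <= a <= hi:
            w[a] = 1.0
        elif lo - ramp <= a < lo:
            w[a] = 0.5 * (1 + np.cos(np.pi * (lo - a) / ramp))
        elif hi < a <= hi + ramp:
            w[a] = 0.5 * (1 + np.cos(np.pi * (a - hi) / ramp))
    return w


def apply_region_shift(rec: StructureRecord, region: Tuple[int, int],
                       vector: Sequence[float]) -> StructureRecord:
    out = _copy_structure(rec, rec.structure_id)
    v = np.asarray(vector, float)
    w = _shift_weights(out, region, shift_ramp_width(v))
    for res in out.residues:
        weight = w.get(res.author_index, 0.0)
        if weight:
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + weight * v
    return out


def apply_region_deformation(rec: StructureRecord,
                             region: Tuple[int, int],
                             F: np.ndarray) -> StructureRecord:
    """Affine map x → F·(x − centroid) + centroid on the region's atoms."""
    F = np.asarray(F, float)
    if abs(np.linalg.det(F)) < 1e-12:
        raise ValueError("singular deformation gradient")
    out = _copy_structure(rec, rec.structure_id)
    lo, hi = region
    coords = [a for res in out.residues if lo <= res.author_index <= hi
              for a in res.atoms.values()]
    if not coords:
        return out
    centroid = np.mean(coords, axis=0)
    for res in out.residues:
        if lo <= res.author_index <= hi:
            for name in res.atoms:
                res.atoms[name] = F @ (res.atoms[name] - centroid) + centroid
    return out


# ---------------------------------------------------------------------------
# two-state ensembles


def _attach_metadata(rec: StructureRecord, spec: SyntheticSpec,
                     rng: np.random.Generator) -> None:
    rec.method = "xray"
    rec.resolution = float(rng.uniform(*spec.resolution_range))
    rec.r_free = float(rng.uniform(*spec.r_free_range))
    rec.last_author = str(rng.choice(spec.author_pool))


def _tag_phospho(rec: StructureRecord, site: int) -> None:
    for model in rec.models:
        for res in model:
            if res.author_index == site:
                res.aa3 = "SER"
                res.phospho_code = "SEP"
                if "CB" in res.atoms and "OG" not in res.atoms:
                    res.atoms["OG"] = res.atoms["CB"] + \
                        np.array([0.0, 0.0, 1.2])


def two_state_ensemble(spec: SyntheticSpec) -> PhosphositeGroup:
    """Two-state conformational-selection ensemble with ground-truth labels.

    State B is state A with the shift region displaced along the shift
    vector (cosine-tapered).  Non-phosphorylated structures are drawn from
    both states per the population weights; phosphorylated structures come
    from state B only (the pre-existing-conformation scenario) and carry
    SEP at the phosphosite.  The optional affine deformation is applied to
    the phosphorylated structures only — it models a localized mechanical
    response to phosphorylation on top of the selected conformation.
    """
    if spec.shift_region is None:
        raise ValueError("two-state ensemble requires a shift region")
    rng = np.random.default_rng(spec.seed)
    base = generate_backbone(spec.n_residues, spec.geometry,
                             seed=spec.seed, uniprot_id=spec.uniprot_id,
                             structure_id=f"{spec.uniprot_id}S")
    state_b = apply_region_shift(base, spec.shift_region, spec.shift_vector)
    phospho_src = state_b
    if spec.deform_region is not None and spec.deform_F is not None:
        phospho_src = apply_region_deformation(state_b, spec.deform_region,
                                               spec.deform_F)

    group = PhosphositeGroup(spec.uniprot_id, frozenset({spec.phosphosite}))
    perturb = smooth_perturb_ensemble if spec.noise_model == "smooth" \
        else perturb_ensemble
    n_state_a = int(round(spec.populations[0] * spec.n_nonphospho))
    for i in range(spec.n_nonphospho):
        src = base if i < n_state_a else state_b
        rec = perturb(src, 1, spec.noise_sigma,
                      seed=int(rng.integers(2 ** 31)))[0]
        rec.structure_id = f"{spec.uniprot_id}_NP{i}_A"
        _attach_metadata(rec, spec, rng)
        group.nonphospho_structures.append(rec)
    for i in range(spec.n_phospho):
        rec = perturb(phospho_src, 1, spec.noise_sigma,
                      seed=int(rng.integers(2 ** 31)))[0]
        rec.structure_id = f"{spec.uniprot_id}_P{i}_A"
        _attach_metadata(rec, spec, rng)
        _tag_phospho(rec, spec.phosphosite)
        group.phospho_structures.append(rec)
    return group


def ground_truth(spec: SyntheticSpec) -> dict:
    gt = {"uniprot_id": spec.uniprot_id,
          "phosphosite": spec.phosphosite,
          "shift_region": list(spec.shift_region)
          if spec.shift_region else None,
          "shift_ramp": shift_ramp_width(spec.shift_vector)
          if spec.shift_region else None,
          "shift_vector": list(spec.shift_vector),
          "populations": list(spec.populations),
          "noise_sigma": spec.noise_sigma,
          "noise_model": spec.noise_model,
          "seed": spec.seed}
    if spec.deform_region is not None and spec.deform_F is not None:
        lam = np.sqrt(np.linalg.eigvalsh(
            np.asarray(spec.deform_F).T @ np.asarray(spec.deform_F)))
        gt["deform_region"] = list(spec.deform_region)
        gt["true_stretches"] = sorted(float(x) for x in lam)
    return gt


# ---------------------------------------------------------------------------
# PDB output


def write_pdb(rec: StructureRecord, path) -> None:
    """Write a fixed-width PDB with the curation metadata in the header."""
    path = Path(path)
    lines = [f"HEADER    SYNTHETIC STRUCTURE                     01-JAN-00   "
             f"{rec.structure_id[:4].upper():<4s}"]
    if rec.method:
        text = {"xray": "X-RAY DIFFRACTION", "em": "ELECTRON MICROSCOPY",
                "nmr": "SOLUTION NMR"}[rec.method]
        lines.append(f"EXPDTA    {text}")
    if rec.last_author:
        lines.append(f"AUTHOR    {rec.last_author}")
    if rec.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION.    {rec.resolution:.2f} "
                     f"ANGSTROMS.")
    if rec.r_free is not None:
        lines.append(f"REMARK   3   FREE R VALUE                     : "
                     f"{rec.r_free:.3f}")
    multi = rec.n_models > 1
    for mi, model in enumerate(rec.models):
        if multi:
            lines.append(f"MODEL     {mi + 1:4d}")
        serial = 1
        for res in model:
            name3 = res.phospho_code if res.is_phospho else res.aa3
            for aname, xyz in res.atoms.items():
                pad = f" {aname:<3s}" if len(aname) < 4 else aname
                lines.append(
                    f"ATOM  {serial:5d} {pad}{'':1s}{name3:<3s} A"
                    f"{res.author_index:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          "
                    f"{aname[0]:>2s}")
                serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# corpus generation


def generate_dataset(specs: Sequence[SyntheticSpec], out_dir) -> Path:
    """Write a PDB corpus plus the annotation tables the pipeline consumes.

    Produces structures/<id>.pdb, metadata.tsv (structure_id, uniprot_id,
    chain, state), phosphosites.tsv, functional_sites.tsv, domains.tsv,
    functional_scores.tsv and ground_truth.json.  Deterministic per spec
    seed.
    """
    out = Path(out_dir)
    (out / "structures").mkdir(parents=True, exist_ok=True)
    meta_rows, site_rows, func_rows, dom_rows, score_rows = \
        [], [], [], [], []
    truth = {}
    for spec in specs:
        group = two_state_ensemble(spec)
        truth[spec.uniprot_id] = ground_truth(spec)
        for state, recs in (("P", group.phospho_structures),
                            ("NP", group.nonphospho_structures)):
            for rec in recs:
                write_pdb(rec, out / "structures" /
                          f"{rec.structure_id.rsplit('_', 1)[0]}.pdb")
                meta_rows.append((rec.structure_id.rsplit('_', 1)[0],
                                  spec.uniprot_id, "A", state))
        site_rows.append((spec.uniprot_id, spec.phosphosite, "SER"))
        score_rows.append((spec.uniprot_id, spec.phosphosite,
                           round(0.3 + 0.6 * (spec.seed % 2), 2)))
        dom_rows.append((spec.uniprot_id, 1, spec.n_residues))
        lo = max(2, spec.n_residues - 12)
        func_rows.append((spec.uniprot_id, "site1", "binding site",
                          ";".join(str(i) for i in range(lo, lo + 4))))

    def tsv(name, header, rows):
        with open(out / name, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for r in rows:
                fh.write("\t".join(str(x) for x in r) + "\n")

    tsv("metadata.tsv", ["file_stem", "uniprot_id", "chain", "state"],
        meta_rows)
    tsv("phosphosites.tsv", ["uniprot_id", "site", "residue"], site_rows)
    tsv("functional_scores.tsv", ["uniprot_id", "site", "score"], score_rows)
    tsv("domains.tsv", ["uniprot_id", "start", "end"], dom_rows)
    tsv("functional_sites.tsv",
        ["uniprot_id", "site_name", "category", "residues"], func_rows)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return out
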