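"""End-to-end orchestration: corpus → curation → analyses → summary table.

Stages run in dependency order (curation, backbone, landscape, dynamics,
strain); each stage's statistical family is Benjamini–Hochberg adjusted
within the run.  The per-phosphosite summary row collects the median RMSDs
per comparison class, lDDT, cluster-share fractions, fluctuation-comparison
calls, mode-similarity windows and stratum, coupling change (ΔMI, RV2,
classification), and site-level strain with bootstrap significance,
co-straining and manifold representation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from . import backbone as bb
from . import dynamics as dyn
from . import landscape as ls
from . import strain as st
from .enm import ensemble_nma
from .stats import adjust_family
from .structures import CurationThresholds, PhosphositeGroup, \
    build_phosphosite_groups, curate_group, curation_report_rows, \
    read_structure

log = logging.getLogger("phosdyn")


@dataclass
class PipelineConfig:
    input_dir: str = "."
    output_dir: str = "phosdyn_out"
    seed: int = 0
    stages: tuple = ("backbone", "landscape", "dynamics", "strain")
    thresholds: CurationThresholds = field(default_factory=CurationThresholds)
    redundancy_rmsd: float = 0.2
    strain_radius: float = st.STRAIN_RADIUS
    n_bootstrap: int = st.BOOTSTRAP_N
    with_lddt: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def load_corpus(input_dir) -> List:
    """Read all structures listed in metadata.tsv under input_dir."""
    input_dir = Path(input_dir)
    meta = pd.read_csv(input_dir / "metadata.tsv", sep="\t")
    records = []
    for _, row in meta.iterrows():
        path = input_dir / "structures" / f"{row.file_stem}.pdb"
        records.append(read_structure(path, str(row.chain),
                                      uniprot_id=str(row.uniprot_id)))
    return records


def _read_sites(input_dir) -> Dict[str, List[dict]]:
    path = Path(input_dir) / "functional_sites.tsv"
    if not path.exists():
        return {}
    df = pd.read_csv(path, sep="\t")
    out: Dict[str, List[dict]] = {}
    for _, row in df.iterrows():
        residues = [int(x) for x in str(row.residues).split(";")]
        out.setdefault(str(row.uniprot_id), []).append(
            {"name": row.site_name, "category": row.category,
             "residues": residues})
    return out


def run_pipeline(config: PipelineConfig) -> Dict[str, pd.DataFrame]:
    """Run all enabled stages and write the summary tables.

    Returns the tables as DataFrames; TSV/JSON copies go to the output
    directory with the config hash embedded in a header comment.
    """
    t0 = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    records = load_corpus(config.input_dir)
    raw_groups = build_phosphosite_groups(records)
    groups: List[PhosphositeGroup] = []
    curation_rows = []
    for g in raw_groups:
        curated, rejections = curate_group(g, config.thresholds)
        curation_rows.extend(curation_report_rows(g, curated, rejections))
        if curated is not None:
            groups.append(curated)
    log.info("curation: %d/%d groups retained", len(groups), len(raw_groups))

    functional_sites = _read_sites(config.input_dir)
    summary: Dict[tuple, dict] = {}
    for g in groups:
        key = (g.uniprot_id, tuple(sorted(g.site_indices)))
        summary[key] = {"uniprot_id": g.uniprot_id,
                        "sites": ";".join(map(str, sorted(g.site_indices))),
                        "is_multisite": g.is_multisite,
                        "n_phospho": len(g.phospho_structures),
                        "n_nonphospho": len(g.nonphospho_structures)}

    sidecars: Dict[str, dict] = {}

    if "backbone" in config.stages:
        for g in groups:
            key = (g.uniprot_id, tuple(sorted(g.site_indices)))
            medians, _ = bb.group_rmsd_summary(g, with_lddt=config.with_lddt)
            row = summary[key]
            for cls, v in medians.items():
                row[f"median_rmsd_{cls}"] = v
            if config.with_lddt:
                _, comps = bb.group_rmsd_summary(g, with_lddt=True)
                lddts = [c.lddt for c in comps
                         if c.comparison_class == "P_vs_NP"
                         and c.lddt is not None]
                row["median_lddt_P_vs_NP"] = (float(np.median(lddts))
                                              if lddts else None)

    if "landscape" in config.stages:
        for g in groups:
            key = (g.uniprot_id, tuple(sorted(g.site_indices)))
            structures = g.structures
            flags = [True] * len(g.phospho_structures) + \
                    [False] * len(g.nonphospho_structures)
            if not ls.embedding_gate(len(structures),
                                     len(g.phospho_structures)):
                summary[key]["cluster_share"] = None
                continue
            emb = ls.embed_shapemers(structures)
            coords, _ = ls.pca_reduce(emb, 2)
            assign = ls.cluster_landscape(coords, "density2d")
            share = ls.phospho_cluster_share(assign, flags)
            summary[key].update(
                cluster_share=share["fraction_shared"],
                cluster_phospho_only=share["fraction_phospho_only"],
                cluster_noise=share["fraction_noise"],
                n_clusters=assign.n_clusters)

    if "dynamics" in config.stages:
        ensembles = {}
        for g in groups:
            key = (g.uniprot_id, tuple(sorted(g.site_indices)))
            try:
                ensembles[key] = ensemble_nma(
                    g, redundancy_rmsd=config.redundancy_rmsd)
            except ValueError as e:
                log.warning("dynamics skipped for %s: %s", key, e)

        # dataset-level peak cutoff over every cross-state pair
        all_profiles = []
        for ens in ensembles.values():
            all_profiles.extend(dyn.abs_difference_profiles(ens))
        cutoff = dyn.derive_peak_cutoff(all_profiles) if all_profiles else None

        ks_family, wil_family, neigh_family = [], [], []
        comps = {}
        for key, ens in ensembles.items():
            corr = dyn.fluctuation_correlations(ens)
            summary[key]["median_fluct_corr_P_vs_NP"] = float(
                np.nanmedian(corr["P_vs_NP"]))
            ks = dyn.global_flexibility_test(ens)
            summary[key]["global_direction"] = ks.label
            ks.label = str(key)
            ks_family.append(ks)
            comp = dyn.compare_fluctuations(ens)
            wil_family.append(comp.wilcoxon)
            site = sorted(ens.group.site_indices)[0]
            if not ens.group.is_multisite:
                nt = dyn.neighborhood_fluctuation_test(ens, site)
                if nt is not None:
                    nt.label = str(key)
                    neigh_family.append(nt)
            mode_cmp = dyn.group_mode_comparison(ens)
            summary[key]["median_rmsip_20"] = mode_cmp["median_rmsip_20"]
            summary[key]["rmsip_stratum"] = mode_cmp["stratum"]
            for w, v in mode_cmp["window_summary"].items():
                summary[key][f"rmsip_{w}"] = v
            coup = dyn.compare_couplings(ens)
            summary[key]["delta_mi"] = coup.delta_mi_overall
            summary[key]["rv2_between"] = coup.rv2_between
            comps[key] = (comp, coup)
        adjust_family(ks_family)
        adjust_family([w for w in wil_family if w is not None])
        adjust_family(neigh_family)
        neigh_by_key = {t.label: t for t in neigh_family}
        deltas = [summary[k]["delta_mi"] for k in ensembles]
        for key, ens in ensembles.items():
            comp, coup = comps[key]
            if cutoff is not None:
                comp = dyn.local_fluctuation_calls(comp, cutoff)
            anchor_id = ens.phospho_ids[0]
            anchor = next(r for r in ens.group.phospho_structures
                          if r.structure_id == anchor_id)
            positions = ens.core_positions[anchor_id]
            peak_authors = [anchor.residues[positions[ci]].author_index
                            for ci, _ in comp.significant_peaks]
            summary[key].update(
                peak_cutoff=cutoff,
                n_significant_peaks=len(comp.significant_peaks),
                significant_peak_residues=";".join(map(str, peak_authors)),
                fluct_combined_call=comp.combined_call,
                fluct_direction=comp.direction,
                coupling_class=dyn.classify_coupling_change(
                    coup.delta_mi_overall, coup.rv2_between, deltas))
            nt = neigh_by_key.get(str(key))
            if nt is not None:
                summary[key]["neighborhood_ks_p_adj"] = nt.p_adjusted
        for t in ks_family:
            for key in ensembles:
                if t.label == str(key):
                    summary[key]["global_ks_p_adj"] = t.p_adjusted

    if "strain" in config.stages:
        for g in groups:
            key = (g.uniprot_id, tuple(sorted(g.site_indices)))
            try:
                fields = st.group_strain_fields(g,
                                                radius=config.strain_radius)
            except ValueError as e:
                log.warning("strain skipped for %s: %s", key, e)
                continue
            site = sorted(g.site_indices)[0]
            vicinity = list(range(site - 2, site + 3))
            seed = int(rng.integers(2 ** 31))
            res = st.bootstrap_site_significance(
                fields, vicinity, n=config.n_bootstrap, seed=seed)
            summary[key].update(
                site_lambda3=res.mean_extensive_stretch,
                site_strain_significant=res.significant,
                strain_bootstrap_mean=res.bootstrap_mean,
                strain_bootstrap_sd=res.bootstrap_sd)
            fsites = functional_sites.get(g.uniprot_id, [])
            ref = g.nonphospho_structures[0]
            co_rows = []
            for fs in fsites:
                fres = st.bootstrap_site_significance(
                    fields, fs["residues"], n=config.n_bootstrap,
                    seed=int(rng.integers(2 ** 31)), contiguous=False)
                co = st.co_straining_classification(res, fres, ref)
                co_rows.append({"functional_site": fs["name"],
                                "co_strained": co.co_strained,
                                "functional_significant":
                                    co.functional_significant,
                                "distance": co.distance,
                                "overlap": co.overlap})
            if co_rows:
                summary[key]["co_strained_any"] = any(
                    r["co_strained"] for r in co_rows)
                summary[key]["n_functional_sites_significant"] = sum(
                    r["functional_significant"] for r in co_rows)
                dists = [r["distance"] for r in co_rows
                         if r["distance"] is not None]
                summary[key]["min_site_distance"] = (min(dists)
                                                     if dists else None)
            try:
                manifolds = []
                for f in fields:
                    refrec = next(r for r in g.nonphospho_structures
                                  if r.structure_id == f.reference_id)
                    pos = {r.author_index: i for i, r in
                           enumerate(refrec.residues)}
                    coords = refrec.ca_coords(
                        [pos[a] for a in f.author_indices])
                    manifolds.append(st.high_strain_manifold(f, coords))
                summary[key]["manifold_representation"] = \
                    st.manifold_representation(vicinity, manifolds)
                sidecars[f"manifold_{g.uniprot_id}"] = {
                    "sizes": [m.size for m in manifolds],
                    "nus": [m.nu for m in manifolds]}
            except ValueError as e:
                log.warning("manifold skipped for %s: %s", key, e)

    # ----- outputs
    header = f"# phosdyn config={config.hash()} seed={config.seed}\n"
    summary_df = pd.DataFrame(list(summary.values()))
    curation_df = pd.DataFrame(curation_rows)
    for name, df in (("summary.tsv", summary_df),
                     ("curation.tsv", curation_df)):
        with open(out_dir / name, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)
    with open(out_dir / "sidecars.json", "w") as fh:
        json.dump({"config": config.to_dict(), **sidecars}, fh, indent=1,
                  default=str)
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return {"summary": summary_df, "curation": curation_df}
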