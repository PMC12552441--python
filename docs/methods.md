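# Methods

This note records the models implemented in `phosdyn`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical decisions taken where the underlying procedures
were open.

## Curation and pairing

Structures are paired into phosphosite groups by protein accession and
exact phosphosite set: a structure phosphorylated at {A, B} belongs to the
multisite group {A, B} only, so a multisite event is one data point. The
non-phosphorylated partners of a group are the same-protein structures
carrying no phosphate at any of the group's sites.

Quality filters: resolution ≤ 3 Å and R-free ≤ 0.3 for X-ray/EM (NMR is
exempt — the fields are undefined for it; all models are kept and pairwise
RMSDs to NMR structures are medians over model pairs). Coverage ≥ 0.25 of
the reference sequence and median pairwise sequence similarity ≥ 0.75.
Alignment is global Needleman–Wunsch with BLOSUM62, gap open −10, gap
extend −0.5 (Biopython `PairwiseAligner`). Two choices are this package's
own, made because the procedure they replace needs external services:

* the coverage reference defaults to the longest structure-derived
  sequence of the group when no full-length sequence is supplied;
* all-vs-all pairwise alignments replace a per-protein multiple alignment;
  "similarity" is the fraction of aligned (non-gap) columns with a
  positive BLOSUM62 score.

## Backbone comparison

Cα RMSD after SVD (Kabsch) superposition with the reflection branch
corrected. lDDT is the published Cα definition — 15 Å inclusion radius in
the reference, preserved-distance fractions at 0.5/1/2/4 Å averaged — and
is reported symmetrised (mean of both reference choices). Buried surface
area uses Shrake–Rupley SASA (biotite, element van-der-Waals radii, 1.4 Å
probe, 200 sphere points) with the ≥ 250 Å² interaction threshold. The
protein-interaction confound model is a Huber M-estimator regression
(tuning constant 1.345) of the median P-vs-NP RMSD on partner counts;
pseudo-R² = 1 − Σρ(residual/s)/Σρ(null residual/s) with the fitted scale
s, recorded in the fit metadata because several robust pseudo-R²
definitions exist. It may be negative.

## Landscape embedding

Each structure yields one fragment per residue for each fragmenting scheme
(sequence window of k = 20 Cα, and all Cα within 15 Å). A fragment is
summarised by four translation/rotation-invariant moments of the centered
coordinates: the second-moment trace, the third and fourth radial moments,
and a third-order Gram-matrix invariant (mean of the cubed pairwise inner
products). They are deliberately not scale-invariant — conformational
expansion is signal. Keys are formed by signed-log1p rescaling and
rounding at resolution 2; this stabilises the dynamic range of the
higher-order moments before discretisation.

Density clustering of the first two principal components uses the HDBSCAN
implementation in scikit-learn with `min_cluster_size=2, min_samples=5`;
with `min_samples` left at its default (equal to `min_cluster_size`) the
algorithm fragments tight conformational clusters into two-point
subclusters, so the density requirement is set independently of the
minimum cluster size. The hierarchical robustness check clusters the full
count matrix with cosine distance and average linkage at the
silhouette-maximising cut (2 … min(10, n−1) clusters). Groups enter the
embedding only with ≥ 10 structures of which ≥ 4 phosphorylated.

## Elastic networks and RTB normal modes

Nodes: N, Cα, C plus up to two side-chain heavy atoms from a fixed
per-residue table (e.g. Ser → Cβ+Oγ, Leu → Cγ+Cδ1, Trp → Cβ+Cζ2); glycine
contributes 3 nodes, alanine 4. The default spring law is a
distance-dependent stiffness k(r) = (4 Å / r)⁶ between all node pairs (no
cutoff); a uniform-stiffness variant with a distance cutoff is available
in configuration. Because all downstream statistics are comparative
(correlations, RMSIP, RV₂, medians across states on a common scale), the
absolute stiffness calibration is irrelevant by construction; the spring
law is recorded in outputs.

The RTB reduction treats each residue as a rigid block: the per-block
basis holds 3 translations and 3 rotations about the block centroid,
orthonormalised by SVD with rank truncation (collinear or 2-atom blocks
keep 5 degrees of freedom, single atoms 3). Eigenvectors of the projected
Hessian are back-projected to the atom space, where they remain
orthonormal. Exactly six near-zero eigenvalues are removed; the cut is
placed at 3 × 10⁻¹² of the top eigenvalue because the rigid-body zeros sit
at ~10⁻¹⁴ relative while the softest genuine bending modes of long chains
reach ~10⁻⁹ relative — a conventional 10⁻⁸ cut misclassifies them. More
than six near-zeros means a disconnected network and is an error.

Eligibility for ensemble NMA: no consecutive-residue Cα–Cα distance above
4.5 Å and a connected network. Within each state, near-duplicate
structures (pairwise RMSD < 0.2 Å, greedy keep-first) are removed. The
shared residue core is the set of anchor-structure residues aligned in
every retained structure; modes are restricted to core Cα components and
unit-renormalised, with the restriction norms kept so covariances can be
reconstructed exactly. Fluctuations are computed in the full node space
(pseudo-inverse Hessian diagonal contracted per residue, unit temperature,
unit masses) and then restricted, so a residue's reported variance does
not depend on the core choice.

## Dynamics comparison

Fluctuation profiles are compared by Pearson correlation per comparison
class and by a two-sample KS test on the per-residue state medians
(BH-adjusted across phosphosites). The local-change cutoff is derived at
dataset level: all |Δfluctuation| profiles over every cross-state pair are
scanned for interior local maxima (endpoints are never peaks; plateau ties
go to the leftmost residue), heights outside 1.5 × IQR are discarded, and
the cutoff is the median plus six standard deviations of the remainder. A
peak is significant only if it strictly exceeds the cutoff; the combined
call additionally requires an adjusted Wilcoxon p ≤ 0.05 on the paired
per-residue state medians.

The 12 Å Cβ neighborhood test (Cα for glycine; sites unmodelled in one
state are skipped) compares the distribution of median fluctuation
differences inside the phosphosite neighborhood against the background by
KS. A caution, observed systematically on synthetic ensembles: fluctuation
differences scale with local flexibility, and elastic-network stiffness
changes propagate through global modes, so this statistic partly reads
*where the site sits on the flexibility profile* rather than purely local
perturbation. Its p-values should be interpreted comparatively, not as
calibrated error rates.

Modes are matched as a linear assignment problem with cost
1 − |vᵢ·uⱼ| (the absolute inner product handles eigenvector sign
ambiguity) solved by the Hungarian algorithm, with an index-ordered
tie-break for determinism. Window summaries report the median matched-pair
similarity in the global/LF/LTIF/HF bands and the stratum from the median
RMSIP over the first 20 modes (≥ 0.90 / 0.80–0.90 / < 0.80).

Linear mutual information: residue-pair covariances are assembled from the
modes weighted by inverse eigenvalues; the Gaussian MI
I = ½(ln det Cᵢ + ln det Cⱼ − ln det Cᵢⱼ) is mapped to the generalized
correlation coefficient r = √(1 − e^(−2I/3)) so entries lie in [0, 1] with
unit diagonal. RV₂ compares matrices after zeroing the diagonal of XXᵀ,
removing the inflation of the classical RV coefficient. The overall
coupling difference ΔMI is the mean over off-diagonal entries of the
state-median matrices (the aggregation level was open; the choice is
recorded in output metadata). Classification: tensioning above the dataset
median + 1 SD of ΔMI, relaxation below median − 1 SD, otherwise rewiring
if the cross-state RV₂ falls below 0.90 (configurable), else unchanged.
Residue communities come from density clustering of 1 − MI.

## Strain

The deformation gradient at residue i minimises Σⱼ‖F·d⁰ᵢⱼ − dᵢⱼ‖² over the
relative positions of mapped Cα neighbors within 12 Å of i in the
reference, intersected with the deformed-state neighborhood; the fit is
unweighted and exact for affine deformations. Residues with fewer than 4
neighbors, or whose centered neighbor matrix has smallest singular value
≤ 10⁻⁶ (near-coplanar), are unscored. Site strain ⟨λ₃⟩ is the geometric
mean over the site per comparison, then the arithmetic mean across
comparisons; phosphosite vicinity is the site ± 2 residues.

Significance uses a site-relocation bootstrap (n = 50): each draw moves
the site to a uniformly random contiguous window of the same size (a
same-size random subset for non-contiguous functional sites), and the site
is called strained when the observed ⟨λ₃⟩ exceeds the bootstrap
mean + 3 SD. The criterion is deliberately stringent; under a homogeneous
strain field its false-positive rate measures ≤ 5% (it is usually ≪ 1%).
A pair of sites is co-strained when both pass; the phosphosite–functional
site distance is the minimal Cα–Cα distance, with overlapping sites
flagged.

The correlation dimension ν of a residue set is the slope of
log C(r) vs log r, with C(r) the fraction of point pairs within r,
evaluated on log-spaced radii between the 1st and 20th percentile of the
pairwise distances. This window sits in the small-r power-law regime;
wider windows (extending toward the median distance) run into boundary
saturation of the correlation integral and bias ν low by ~0.3–0.5 on
uniform test sets. The high-strain manifold scans N over 5%–60% of scored
residues in 5% steps (minimum 10), takes the N top-λ₃ residues, and keeps
the set of minimal ν, smallest N on ties. Representation of a site is the
mean fraction of its residues inside the manifold across comparisons.

## Synthetic study conditions

The generator emulates groups of homologous structures of one protein in
two labelled states. Geometry is an ideal helix (rise 1.5 Å,
100°/residue; strand and self-avoiding coil variants exist) decorated with
N, C and Cβ at locally rigid ideal offsets, plus Oγ on serines — enough
for the 3–5-node elastic networks, the Cβ neighborhood rule and shapemer
fragments, with no claim of side-chain realism.

Two-state ensembles displace a residue window along a shift vector,
cosine-tapered over ⌈2.4 × |shift|⌉ residues so consecutive Cα steps stay
under the 4.5 Å chain-continuity threshold. Ensemble noise is, by
default, a superposition of low-order standing waves along the sequence
with RMS amplitude σ = 0.2–0.3 Å and rigid per-residue motion — the
spatially correlated variation real homologous structures show — because
independent per-atom noise of realistic amplitude stretches bonds past
the continuity filter and adds white noise real ensembles do not have.
Isotropic per-atom noise remains available. Designed affine deformations
(known principal stretches) are applied to the phosphorylated structures
only, modelling a localized mechanical response on top of the selected
conformation. Metadata is drawn as resolution ∈ [1.5, 2.5] Å, R-free ∈
[0.18, 0.28], authors from a fixed pool.

The standard study corpora (used by the end-to-end tests and
`scripts/acceptance.py`) were chosen once as conditions a desk-scale study
can support:

* **Dynamics corpus** — three 100-residue groups: PSYNA (shift 5 Å on
  residues 45–55, unmodified structures split 50/50 across states,
  6 P + 10 NP) carries the conformational-selection signature; PSYNC
  (all unmodified structures in the reference state, 4 P + 6 NP) carries
  the local fluctuation signal; PSYNN (no shift) anchors the
  dataset-level peak cutoff with null comparisons, as the cutoff
  derivation presumes a pool dominated by unperturbed variation.
* **Strain corpus** — one 300-residue group, no state shift, axial
  stretch diag(1, 1, 1.35) on residues 145–155 of the phosphorylated
  structures, 3 P + 5 NP. The chain length keeps the strained zone a
  small fraction of the protein; the mean + 3σ relocation bootstrap is
  only sensitive when random site placements rarely overlap genuinely
  strained residues, which is also the regime of real proteins.

What passing these tests shows: the estimators recover designed geometry,
dynamics and strain ground truth end-to-end through PDB round trips,
curation, alignment and core construction. What they do not show:
behaviour on real side-chain packing, crystal contacts, missing residues
beyond simple truncation, or corpus-scale statistics of the PDB — all
dataset-level fractions reported by studies of real corpora are outside
what a synthetic desk-scale corpus can reproduce.

## Known limitations

* The elastic-network stiffness law is a generic distance-dependent form,
  not a force-field calibration; absolute fluctuation magnitudes are in
  arbitrary units and only cross-state comparisons are meaningful.
* The phosphosite-neighborhood KS statistic is location-confounded (see
  above).
* RTB approximation quality is verified on small networks (low-mode
  subspace overlap RMSIP ≥ 0.9 against the full Hessian); very soft,
  nearly-degenerate mode pairs can still swap order between states, which
  the Hungarian matching absorbs but window boundaries do not.
* The bootstrap relocation scheme preserves site size and contiguity but
  not secondary-structure context; on proteins whose strain background is
  strongly structured, the null may be conservative.
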