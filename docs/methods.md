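# Methods

This note documents the models, algorithms and numerical choices behind
`bonemsi`, and what the synthetic phantom does and does not emulate.

## Exact-mass chemistry

Monoisotopic masses are summed from a fixed table of IUPAC atomic masses
restricted to C, H, N, O, P, S, K, Na, Cl — the elements occurring in small
endogenous metabolites and in negative-mode adducts.  Ion m/z bookkeeping
includes the electron mass (0.00054858 Da): a singly charged anion carries
one extra electron, so the deprotonated ion is `M − 1.00727646`.  This is
required to reproduce the 9-aminoacridine matrix lock mass (C₁₃H₁₀N₂,
[M−H]⁻ = 193.0771) at four decimal places.

Five negative adducts are modeled: M−H, M−H₂O, M+K−2H, M+Na−2H, M+Cl.
"M−H₂O" is interpreted as the deprotonated water-loss ion [M−H₂O−H]⁻ — a
bare neutral water loss carries no charge and would not be detected in
negative mode.  Degenerate ions (e.g. water losing water plus a proton) are
rejected.

Glycan fragments are handled at composition level only: a residue is the
monosaccharide minus one water (e.g. Hex = C₆H₁₀O₅), modifications are net
elemental additions (sulfate +SO₃, phosphate +HPO₃, acetyl +C₂H₂O), and a
free reducing end adds one water.  Composition labels use residue-count
nomenclature (HexNAc1S1, HexA1HexNAc1S1).  Note that compositions can be
elementally isobaric (HexN + Ac ≡ HexNAc); accurate mass alone cannot
distinguish them and both candidates are reported.

## Reference table

The bundled metabolite table (≈190 records) is a desk-scale, hand-curated
emulation of the KEGG/HMDB records relevant to bone metabolism: glycolysis,
the pentose phosphate pathway, purine/pyrimidine and nucleotide-sugar
metabolism, the CDP-choline/CDP-ethanolamine branches, cysteine/methionine,
galactose, inositol, arginine, ascorbate/aldarate and TCA intermediates,
free fatty acids, cofactors, plus eleven exogenous decoys (drugs,
pesticides, the 9-AA matrix) that exercise the exogenous-annotation filter.
Every stored mass is recomputable from its formula to 10⁻⁶ Da (a loader
invariant).  Pathway memberships use short descriptive identifiers; chemical
classes follow HMDB-style taxonomy labels.

## Preprocessing

**Normalization.** Each spectrum is divided by its root-mean-square
intensity; the operation is idempotent and all-zero spectra are left
untouched with a warning.  RMS normalization assumes the total ion current
is comparable across pixels; pixels dominated by a single changing species
violate this and shift apparent fold changes of all other ions (see the
phantom design below).

**Noise.** Per-bin noise is the median absolute deviation in a sliding m/z
window (default 1 Da), scaled by 1.4826 for consistency with the Gaussian
standard deviation.  The MAD is insensitive to sparse peaks inside the
window, which is what makes an S/N threshold on profile data meaningful.

**Peak picking** operates on the overall mean spectrum — one shared feature
space for the whole experiment — keeping local maxima with apex/noise ≥ 3
(apex m/z, no centroid fitting).  Maxima closer than `min_separation_ppm`
(pipeline default 50 ppm) are merged keeping the strongest apex; without
this, shoulder samples of profile peaks yield spurious duplicates.  The
threshold is monotone: the S/N-4 peak set is a subset of the S/N-3 set.

**Datacube.** Ion images integrate intensities within `center × (1 ± 4
ppm)`, half-open at the upper edge; bins claimed by two overlapping windows
go to the nearest center.  Sum aggregation is the default (robust for
profile data); max is available.

## pLSA segmentation

The aspect model factorizes the pixel × peak matrix, treated as
pseudo-counts, as `P(d, w) = Σ_z P(z) P(d|z) P(w|z)`.  EM updates are the
standard multiplicative form; the log-likelihood is asserted non-decreasing
and all probability vectors stay normalized to 1e-9.  Initialization is
seeded random Dirichlet; because EM is only locally convergent, `fit_plsa`
runs a small number of restarts (default 3, seeds derived deterministically
from the user seed) and keeps the best final log-likelihood.  Convergence is
declared at a relative log-likelihood change below 1e-6 or 500 iterations.

The number of components is chosen a priori as tissue compartments + 1
(e.g. 4 for mineralized bone / osteoid / marrow / background).  The
background component is the one whose pixel distribution `P(d|z)`
concentrates the most mass on mask-labeled off-tissue pixels (ties break to
the lowest index); it is excluded from peak association.  Peaks are
associated to the non-background component maximizing `P(w|z)`; pixels are
segmented by the posterior argmax `P(z|d)`.  Component order is arbitrary,
so evaluation against ground truth uses Hungarian matching on the confusion
matrix.  PCA (column-mean-centered SVD, deterministic sign convention:
largest-magnitude loading positive) serves as the unsupervised cross-check.

## ROI statistics

The statistical unit question — pixels versus animals — is resolved by
computing both: pixel-wise Mann-Whitney tests pooling ROI pixels per group
(the primary readout, matching how MSI studies report "pixel-wise intensity
distributions" with n animals per group) and a per-section-mean test
(`p_section`) that is immune to pseudoreplication.  Fold changes are always
computed from per-section ROI means — `log2(mean_B / mean_A)` over section
means — which is robust to unequal section sizes.

Mann-Whitney p-values are exact for `n_a + n_b ≤ 16`, obtained by
enumerating all `C(n, n_a)` group labelings of the pooled midranks; the
null U distribution is symmetric about `n_a·n_b/2` under rank reversal, so
the two-sided p is the `|U − mean|` tail.  The enumeration handles ties
naturally (identical samples give p = 1 exactly).  Larger samples use the
normal approximation with tie and continuity corrections.  Kruskal-Wallis
uses the chi-square reference; Dunn's pairwise z statistics are computed on
pooled midranks with the tie correction `Σ(t³−t)/(12(N−1))` and adjusted by
Benjamini-Hochberg across pairs.  Volcano classification is `up` iff
log₂FC ≥ 1 and p < 0.05, `down` iff ≤ −1 and p < 0.05 (cutoffs inclusive on
the fold change, exclusive on alpha).

Pathway over-representation uses the upper-tail hypergeometric probability
of at least the observed overlap; the enrichment ratio is observed/expected
(`hits / (size × |hits|/|background|)`).  The background is the set of
annotated endogenous metabolites detected in the experiment.  Peaks with
several isobaric candidates contribute their top-ranked (smallest |ppm|)
annotation to class and pathway summaries; all candidates remain in the
annotation table.

## Correlation networks

Spatial Spearman correlation (midranks; t-approximation p) is computed over
mask pixels of ion-image pairs.  Candidate edges are annotated peak pairs
sharing at least one pathway; edges are kept regardless of ρ magnitude
(an optional |ρ| floor exists, default 0), and a node survives only with at
least one correlation at p ≤ alpha (default 0.05, unadjusted — with
thousands of pixels nearly all correlations are significant, which is why
the |ρ| floor is exposed).  Nodes carry name, log₂FC and a label flag at
|log₂FC| ≥ 1; edges carry ρ, p, |ρ| (the layout weight used by compound
spring-embedder layouts) and the shared pathway ids.  Layout itself is out
of scope; the GraphML export is consumable by Cytoscape-style tools.

## The synthetic phantom

Each section is a 64×64 grid (50 μm notional spacing) with concentric
compartments: a mineralized cortical ring (outer radius 28 px, width 8), an
osteoid seam (width 3), a marrow core, and off-tissue background; per-section
seeded jitter (±1 px) varies the geometry between sections.  Two groups
(WT-like and Hyp-like, 5 sections each) are generated.

The peak list derives deterministically from the bundled table: [M−H]⁻ and
[M+Cl]⁻ ions of all endogenous records within m/z 75–1100, deduplicated at
500 ppm, truncated to ~300 (the defaults yield 258).  Each peak has a "home"
compartment where its base intensity is 100 a.u. versus 2–10 elsewhere;
pyrophosphate is always homed in the osteoid (its biological site of
accumulation in hypomineralized bone).  A 9-AA matrix ion is included at
base 500 off tissue and 50 on tissue: realistic (matrix signal is strongest
off tissue), it anchors the pLSA background component, exercises the
exogenous filter, and — critically — gives background pixels enough signal
that RMS normalization does not amplify pure noise into a pedestal that
would defeat S/N thresholding of the mean spectrum.

Group effects multiply intensities of 20 upregulated and 15 downregulated
peaks by 2^±3 in the Hyp-like group.  Planted peaks are assigned
trace-level abundance (home 8–12 a.u.) so that the planted effects leave
the total ion current approximately unchanged — the assumption under which
per-pixel RMS normalization preserves fold-change interpretability.  With
full-abundance planting the normalization itself would induce a spurious
−1.3 log₂ shift on every null peak; at trace abundance the residual bias is
below 0.1.  The lock-mass region (±2 Da around 193.077) and pyrophosphate
are never planted.

Per-pixel noise is multiplicative log-normal with mean 1 and CV 0.2
(`σ² = ln(1 + CV²)`, mean-corrected), reflecting the positive, right-skewed
intensity distributions of MSI.  Spectra are synthesized on a sparse shared
axis — each peak contributes samples at its (jittered) center and ±3.5σ
with σ = 10 ppm — plus additive Gaussian baseline noise (σ = 0.1 a.u.)
clipped at zero.  Sparse sampling keeps a section at ~800 axis points; dense
profile sampling at 1 ppm over 75–1100 would need ~10⁷ points per pixel.  A
per-section calibration jitter (uniform, ≤0.3 ppm) shifts the axis; apexes
stay within 1 ppm of the intended adduct m/z.  All randomness flows from
seeded, spawned substreams, so a spec+seed pair reproduces the spectral
payload byte-identically (the imzML ibd begins with a per-file UUID required
by the standard; determinism is over everything after it).

**What the phantom does not emulate:** isotope envelopes, matrix cluster
peaks beyond the single 9-AA ion, detector saturation, mass-resolution
decay with m/z, spatial intensity gradients within a compartment, chemical
noise, or section-to-section biological variability beyond mask-geometry
jitter.  Passing the recovery tests therefore demonstrates correctness of
the analysis chain under the stated noise model — not performance on real
FTICR data, where peak density, isobaric interference and baseline
structure are far harsher.

**Null calibration scenario.** The type-I error check (fraction of raw
p < 0.05 under no planted effects ∈ [0.02, 0.09]) uses a phantom with
identical masks across sections (`mask_perturb = 0`) and tests within the
homogeneous mineralized compartment.  Both choices are required for a valid
calibration check, not relaxations: geometry jitter is a real
between-section difference that pixel-pooled tests legitimately detect
(pseudoreplication), and pooling two compartments makes all peaks co-vary
through the mixture composition so the rejection fraction across peaks no
longer concentrates around its mean.

## Problem sizes

The test suite runs a 32×32 / 60-peak / 2×2-section phantom for unit tests
and the full 64×64 / ~300-peak / 2×5-section default for the end-to-end
recovery checks; the acceptance script uses the default phantom, a
32×32 / 200-peak null phantom, and a 32×32 / 60-peak pipeline rerun for the
determinism check.  These sizes are the package's chosen desk-scale study
conditions; recovery results at larger grids behave identically because all
estimators sharpen with pixel count.

## Known limitations

- Annotation is MS1-only; isobars and isomers are not resolved (all
  candidates within tolerance are reported, ranked by |ppm|).
- The exact peak-picking behavior of vendor software (e.g. SCiLS) is not
  reproduced; counts such as "peaks per compartment" are definition-
  dependent.
- pLSA assumes non-negative pseudo-count intensities; no spatial smoothing
  prior is applied, so single-pixel label noise is expected at compartment
  boundaries on real data.
- Pixel-wise p-values with thousands of pixels are essentially zero for any
  real effect; interpret them jointly with the fold-change cutoff, or use
  the per-section test for animal-level inference.
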