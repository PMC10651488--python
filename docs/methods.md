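# Methods

## Scope

`fbrmech` models the mechanical micro-environment around soft-tissue
implants and the transcriptomic readout of the foreign-body response (FBR)
that this environment drives.  Three computational stages share a common
package: (i) a small-strain linear-elastic finite-element solver for
layered tissue domains containing a disc implant, reporting the extrema of
the horizontal normal stress Sx at the implant–tissue interface; (ii) a
negative-binomial differential-expression pipeline for two-group biomarker
count panels (mild vs severe capsular-contracture grades) producing
ordered top-k gene signatures; and (iii) a single-cell workflow that
scores those signatures on clustered UMI data and quantifies which
clusters and conditions carry them.

## Mechanical model

**Geometry.** A rectangular box with a square footprint
(`lateral_extent`, mm) holds tissue layers stacked along z; the bottom
face of the lowest (muscle/bone) layer is fully clamped.  The implant is a
disc (radius, height) embedded in a host layer, centred laterally and
vertically.  Loads act along +x ("horizontal").

**Discretisation.** A structured grid, laterally uniform and vertically
conforming to layer interfaces, is subdivided into six tetrahedra per cell
by the Kuhn scheme; the subdivision is translation-invariant, so the mesh
is conforming.  All elements — including the implant — are linear
(constant-strain) tetrahedra with exact one-point integration.  The disc
is approximated by relabelling cells whose centres fall inside it; the
geometric error is controlled by the edge length (the disc volume error is
below 5% at the resolutions used here, and a refinement check is part of
the standard run).  Implant–tissue bonding is through shared nodes, the
conforming-mesh equivalent of a tied contact.  There is no sliding,
friction or separation.

**Materials and solve.** Each region carries an isotropic Hookean
material (E in Pa, ν in [0, 0.5), density in kg/m³).  The global
stiffness is assembled vectorised over elements and solved by sparse LU
after symmetric Jacobi equilibration, with iterative refinement; the
accepted solution must have normwise backward error
‖Ku−f‖/(‖K‖‖u‖+‖f‖) ≤ 1e-8 (the conditioning-independent quality
measure — stiffness contrasts reach ~10⁷ when a metal implant sits in
fat).  A solution whose norm grows by more than 10¹⁴ relative to the load
is reported as an insufficiently constrained (singular) system rather
than silently regularised.  Uniform-strain patch tests reproduce the
closed-form stress and displacement to machine precision, the standard
correctness oracle for this element.

**Loads.** Three kinds:

- `static_force` (N): total horizontal force spread over the implant's
  nodes with lumped-volume weights.  Species values derive from measured
  resting tissue tensions and are configuration inputs (mouse default
  0.025 N, human 40 N; order-of-magnitude provenance is documented in the
  preset files — the original study's supplementary tables were not
  available, so these are literature-scale placeholders, and downstream
  absolute stresses inherit that status).
- `vibration` (amplitude in multiples of g, frequency in Hz): treated as
  its quasi-static peak, a body force of `amplitude_g × 9.8` N/kg acting
  on the implant mass (material density plus a lumped motor mass).
  g is fixed at 9.8 m/s² so that 1.38 g ↦ 13.524 ≈ 13.5 N/kg, the
  vibrating-implant operating point (1.38 g, 203 Hz).  An undamped
  harmonic solve `(K − ω²M)u = F` with lumped mass is available as an
  explicitly optional mode; it reduces to the static solve at 0 Hz.
  Quasi-static peak loading of the vibrating implant produces interface
  stresses of the same order as the static mouse model — the package
  makes no claim about dynamic amplification, for which no damping or
  resonance parameters are configured.
- `body_force` (N/kg): the explicit form of the same mechanism.

**Stress reporting.** Per-element constant stress σ = C:ε (compression
negative).  The interface summary takes extrema of Sx over tissue-side
elements adjacent to interface nodes and reports kPa.  Whether the
published "maximal stress" is the tensile, compressive or absolute
extremum is not defined anywhere we could check; the absolute extremum is
used and all three are reported.

**Allometric scaling.** `allometric_force_scale` maps a reference force
across body masses as F·(m/m_ref)^a with a = 2/3 by default (force
proportional to load-bearing cross-sectional area).  The exponent is a
declared modelling choice, configurable, and nothing downstream depends
on a particular value: the species presets carry configured loads rather
than loads derived from this function.

**Implant stiffness testing.** The Young's modulus of a fabricated
implant is the least-squares slope of its compression stress–strain curve
restricted to strain ∈ [0, 0.10], exact on noiseless linear data.

## Panel differential expression

**Model.** Counts y_gj ~ NB(s_j·m_g, φ_g) with variance μ + φμ².
Size factors s_j are TMM-style: trimmed mean (30% log-ratio trim, 5%
abundance trim) of log ratios against the per-gene geometric-mean
pseudo-reference, multiplied by the raw library size and centred to
geometric mean 1 — so a sample with all counts doubled gets twice the
factor of its peers.

**Dispersion.** Per-gene method-of-moments on normalised counts using the
pooled within-group variance, floored at 0, then shrunk toward the common
(median) dispersion with weight w = 0.7: φ ← w·φ_common + (1−w)·φ_g.
The weight was fixed a priori; at n = 10 per group the per-gene moment
estimate is far too noisy to use unshrunken.

**Test.** Likelihood-ratio statistic for equal NB means between groups
(one mean vs two, shared dispersion, log size-factor offsets; means fitted
by a vectorised Newton iteration in log-mean).  The statistic is referred
to F(1, df) with df = residual df/(1−w) = 18/0.3 = 60, i.e. the residual
df plus the prior df implied by the dispersion shrinkage — the
quasi-likelihood small-sample convention.  The chi-square(1) asymptote
(available via `shrink_weight=1`) is measurably anticonservative in the
deep tail at this sample size (empirical type-I ≈ 0.055 at α = 0.05, up
to 2× inflation at p ≈ 10⁻³), which breaks the Benjamini–Hochberg FDR
guarantee downstream; the F reference restores it (measured type-I
0.047–0.056 across seeds at 10,000 genes; mean false-discovery
proportion ≈ π₀·α at q < 0.05).  All-zero genes get p = 1 and logFC = 0.
log2 fold changes use fitted group means with a half-count-at-average-
depth pseudo-fraction added to both.

**Multiplicity and signatures.** BH step-up q-values (tested against a
brute-force implementation of the definition).  Signatures take genes
with the requested fold-change sign and unadjusted p < 0.05 (the
eligibility rule used for the published top-100/top-25 lists; q-values
are reported alongside), ranked by ascending p with ties broken by
descending |logFC| then gene id, truncated to k.

## Single-cell workflow

QC keeps cells with ≥ 200 detected genes (inclusive) and mitochondrial
fraction < 10% (strict).  Kept cells are depth-normalised to 10,000
counts and transformed ln(1 + x) (zeros preserved).  The mitochondrial
fraction is regressed out gene-wise by OLS; residuals are standardised
per gene (flat genes set to 0, with a roundoff-aware zero-variance
threshold).  The embedding is the top 15 principal components by exact
SVD, signs fixed so each component's largest-magnitude loading is
positive.  Clustering is seeded k-means on that embedding — a fully
specified, dependency-light stand-in for graph-based clustering; it is
adequate for planted-structure recovery and is not claimed to reproduce
any published cluster count.  Markers are one-vs-rest: natural-log ratio
of mean expm1 expression (pseudocount 1 on both means), gated at
|lnFC| ≥ 0.25, scored by the Mann–Whitney AUC (midranks; equal to pair
enumeration) and ranked by AUC.  Signature scores are the per-cell
arithmetic mean of log-normalised (pre-regression) expression over the
mapped signature genes; cross-species mapping is by case-insensitive
symbol match unless an explicit two-column ortholog table is supplied.
Composition tables give cluster fractions per condition, rows summing
to 1.

## Synthetic data

The generators are pure functions of (parameters, seed) and emulate the
statistical structure the pipelines assume, not full assay realism.

- Panel: lognormal baseline means (median ≈ e⁴ ≈ 55 counts, sd 1.5 on
  the log scale — placeholders; the real panel's depth profile is not
  published), lognormal(0, 0.2) library factors, NB counts, an exactly
  `round(frac_de·n_genes)` subset multiplied by 2^lfc in group 2.
  Defaults mirror the study design: 2,549 genes, 10 samples per group.
- UMI: two or more populations with shared lognormal baseline profiles,
  per-population random marker genes (5% of genes, e^1.5 uplift), one
  signature-high population (multiplicative e^uplift on the signature
  genes) preferentially assigned the "MSI" condition (0.8 vs 0.45),
  per-cell lognormal library sizes (median 2,500), and a per-cell
  mitochondrial fraction drawn uniformly from the requested interval and
  imposed exactly in expectation.  Counts are Poisson around the cell's
  expected profile; library-size mixing makes the marginal overdispersed.
  Not modelled: doublets, ambient RNA, batch chemistry.

Passing tests on these fixtures therefore demonstrate that the pipeline
recovers planted structure under its own model assumptions; they say
nothing about robustness to the artefacts real droplet data add.

## Problem sizes and numerical choices

Preset stress runs use edge lengths of 1.2 mm (mouse, ≈ 38k elements)
and 3.4 mm (human, ≈ 111k elements), with a refinement sequence
1.4/1.2/0.9 mm on the mouse model; these sizes put the disc-volume error
under 5% and the refinement change of max |Sx| under ~25% while keeping a
full run on one CPU in minutes.  DE calibration uses 10,000 null genes
for the type-I rate and 15 replicates of 3,000 genes (2% planted DE,
4-fold effect) for the false-discovery proportion, which estimates the
FDR to a standard error of ~0.01.  The single-cell fixture uses 650
cells × 600 genes.  Ties in ranking are broken deterministically
(documented above); k-means uses 10 seeded restarts.

## Known limitations

- Absolute interface stresses depend on preset loads and moduli that are
  literature-order configuration values, not the original supplementary
  tables; the package's validated claims are the orderings and
  monotonicities, not the absolute kPa values.
- Linear kinematics: reported tissue strains at the human load are within
  the small-strain regime, but no geometric nonlinearity or hyperelastic
  behaviour is modelled.
- The vibrating-implant stress is its quasi-static peak; resonance
  effects at 203 Hz are out of scope (the undamped harmonic mode exists
  but has no damping model, so it diverges at resonance by construction).
- k-means on 15 PCs will split or merge populations whose geometry
  violates its isotropic-cluster assumption; cluster counts are a user
  parameter, not an inference.
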