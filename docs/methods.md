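# Methods

This note documents the models and procedures implemented in
`sporesigma`, the parameters that matter, the design of the synthetic
generators, and the numerical choices made where the design was open.

## Homology classification

Proteins are classified against a catalog of sigma-factor family
profiles. The rule is best-hit by smallest *sequence* E-value; per-domain
rows in the tabular input are collapsed to the best sequence-level
E-value per (protein, family) at load time. Two families are *general*
umbrellas (`sigma70-ECF`, `SigBFG`) that almost any sigma factor matches:
when the best hit is general and a non-general hit exists, the best
non-general family is assigned instead and `fallback_used` is set. A
protein with only general hits keeps the general assignment and is never
spore-like. E-value ties are broken by higher bit score, then
lexicographic family id, so classification is deterministic and invariant
to hit order.

The spore-like family set is configuration. The shipped default names
forespore (sigF, sigG) and mother-cell (sigE, sigK) cascade families plus
a primary-sigma family; surveys against a real profile database should
supply their own catalog CSV with the accessions actually searched.
Genome summaries bin genomes by 0/1/2/3+ sigma factors and flag a genome
spore-like when *any* of its proteins is; host phyla with fewer than 10
genomes (configurable) are flagged `low_count` but never dropped.

## Percent identity on profile alignments

Pairwise identity follows the alignment-statistics convention
`100 · matches / min(n_a, n_b)`, where matches are columns in which both
sequences carry the same non-gap residue and `n_x` counts non-gap
residues of sequence `x` over the compared columns. With
`trim_to_reference` (default), columns strictly before the first and
strictly after the last profile reference column are removed first,
emulating termini trimming against the profile. The reference mask is
read from a companion `RF` record ('x' = reference column) or, with the
case convention, from upper/lower-case column usage. Identity–phenotype
association uses Spearman's rank correlation with average ranks; for
n ≤ 8 shared genes the two-sided p-value is exact (all n! rank
permutations), otherwise the t approximation is used.

## Phylogenetic clade calls

Trees are consumed as newick plus a tip-metadata table (source =
phage/bacterial, family for references). All clade operations are
set-wise on a **rooted** tree: unrooted inputs (basal multifurcation)
must come with an explicit outgroup or a midpoint-rooting request; the
package never roots silently. The sporulation clade is the tip set of the
MRCA of the sporulation reference tips; the excluded subclade is the MRCA
tip set of the sigB references (sigB and relatives sit inside the
sporulation clade on real trees but regulate general stress, not
sporulation). Membership = phage tips in the clade minus the excluded
set; if the sigB MRCA is not nested inside the sporulation clade the
exclusion still applies set-wise, with a warning. Reference tip choice is
the caller's: which bacterial tips delimit the clades is a property of
the reference set, not of the algorithm. Branch supports are carried
through but never influence calls. Phage-only clades are the maximal
nodes whose descendant tips are all phage-encoded; they are returned in a
canonical order, so results are invariant to child rotation of the same
topology.

## Virulence index

For one strain, each replicate carries a dilution series over MOI plus
its own MOI = 0 control. Per well, the trapezoidal area under OD₆₀₀ is
taken on [0, t_end] with t_end = 6 h by default (the window from
infection to the uninfected culture's entry into stationary phase;
configurable), interpolating the boundary value linearly when t_end is
not sampled. Local virulence `v = 1 − A_inf/A_ctl` is clamped to [0, 1]:
an infected culture outgrowing its control carries no information about
lysis in this index, and clamping keeps Vp a fraction of the theoretical
maximum. No blank subtraction is applied by default (raw areas); Vp is
invariant to uniform rescaling of all ODs regardless. Replicates are
averaged on the local-virulence scale per MOI before integrating over
log10 MOI; per-replicate Vp values are also emitted and are the unit for
Welch comparisons between strains. At least two distinct nonzero MOIs are
required (otherwise the log-MOI span is empty).

## Statistics

Welch's two-sample t-test uses the Welch–Satterthwaite degrees of
freedom; two groups with zero variance and equal means return p = 1 (the
test is vacuous), zero variance otherwise is an error rather than a
silent infinity. The one-sample paired test on induced-minus-control
density differences follows the same conventions. Multiple-testing
adjustment delegates to standard step-down Holm (default for cross-strain
comparisons, conservative under any dependence) and step-up BH/BY.
Hypergeometric enrichment is exact upper-tail, p = P(X ≥ k), with the
universe defined as the genes present in the strain's own DE table; the
enrichment direction defaults to the up-regulated set. DEG thresholds are
adjusted p < 0.05 and |log2fc| > 1 exactly (boundary excluded); a flag
switches to raw-p thresholding for upstream tables that report both.

## Flow-cytometry gating

All channels are transformed x → asinh(x / cofactor) with cofactor 1 by
default (configurable per call); the transform is monotone, so gates and
mixture labels are unaffected by its scale except through cluster shape.
Gates run in the order singlet → noise, then the mixture:

- **Singlet gate**: Theil–Sen robust line of transformed FSC-H on FSC-A;
  events within k = 2.5 robust scales (1.4826·MAD) of the line are
  singlets. Doublets — two coincident cells — double the area signal at
  singlet height and fall far below the line. Theil–Sen is quadratic in
  the number of points, so the line is fitted on at most 2,000 events
  picked evenly along the sorted (FSC-A, FSC-H) order — deterministic and
  order-invariant — and the residual band is applied to every event.
- **Noise gate**: Gaussian KDE (Silverman bandwidth) of transformed
  FSC-A on a 512-point grid; the threshold is the deepest density minimum
  below the global mode. With no such minimum (clean unimodal sample) the
  0.5% quantile is used as a fallback; disabling the fallback retains
  everything with a warning. The threshold is translation-equivariant.
- **Mixture**: two-component full-covariance Gaussian mixture over
  transformed (FSC-A, fluorescence area), EM with 5 seeded restarts
  keeping the best log-likelihood, trained on the gated non-induced
  control(s) of each strain × run and then applied to all samples of that
  strain/run (strain/run mismatch is an error unless overridden). The
  component with lower mean fluorescence is the spore population — the
  nucleic-acid stain cannot cross the spore coat. A component weight
  below 0.1% triggers a degenerate-split warning. Training requires at
  least 1,000 gated events (configurable floor).

Spore yield is pct-spores(induced) / pct-spores(paired control), paired
by explicit pair ids; clone-level yield is the mean over pairs with its
SEM. Strain effects are Welch tests of clone yields against the
empty-vector control, Holm-adjusted across strains by default.

## Synthetic generators

All generators take an integer seed and are byte-reproducible; each emits
a truth sidecar sufficient to score the downstream stage directly.

- **Hit tables**: each protein's planted (non-general) family receives an
  E-value log-uniform in [1e-40, 1e-10]; decoys are ≥ margin× larger
  (margin 10 by default); with a configurable rate, an umbrella hit
  smaller than all others is planted to exercise the fallback branch.
- **Trees**: a rooted topology with the sporulation clade (references,
  planted phage members, and a nested sigB subclade that may itself carry
  phage tips the exclusion rule must drop), a sister clade of
  out-of-clade phage tips and non-sporulation references, and a bacterial
  outgroup. One reference tip is placed on each side of the relevant
  clade roots so the references' MRCA spans exactly the planted clade.
  Branch lengths are uniform (0.05–0.5) and carry no signal. Planting
  phage tips inside the sigB subclade requires ≥ 2 sigB references,
  because a single reference's MRCA is a leaf and could never exclude
  them.
- **Growth curves**: the control is logistic (r = 1.4 h⁻¹, K = 1.2 OD,
  OD₀ = 0.05, i.e. a fast-growing *Bacillus*-like culture saturating
  around 4 h); infected wells multiply the control by
  exp(−θ·(t − t_on)⁺) with onset t_on = max(0, 3 h − 0.75·log10(MOI/MOI_min))
  — lysis starts earlier at higher phage load — and lysis strength θ.
  This is phenomenological: the virulence index consumes only integrated
  areas, so any family monotone in θ supports recovery tests. The grid is
  0–16 h at 0.25 h with 8 replicate series; measurement noise is Gaussian
  (sd 0.01 OD), floored at 0.
- **Flow events**: cells are Gaussian on the asinh scale — spores at
  (FSC-A 4.0, FL 2.5), vegetative at (4.6, 7.5), sd 0.35 — and raw
  intensities are the sinh back-transform, so the pipeline's modeling
  assumption holds by construction on the transformed scale. Singlet
  FSC-H tracks 0.98·FSC-A with bounded uniform jitter (±0.05), so a pure
  singlet cloud lies entirely inside the default k = 2.5 band; doublets
  double raw areas at singlet height; noise sits at low scatter
  (transformed FSC-A ≈ 1). Default contamination is 5% doublets + 5%
  noise. Paired samples are generated by planting two spore fractions.
- **DE tables**: 4,000 genes with 500 sporulation-annotated by default;
  sporulation genes go up with probability 0.6 versus 0.05 background
  (and 0.05 down anywhere). Up genes draw log2fc ∈ U(1.2, 4) with
  p_adj < 0.04; null genes draw log2fc ~ N(0, 0.3) with uniform p_adj.
  Re-using a previous truth table as `base` keeps the class draws and
  baseline effects and adds fresh N(0, 0.1) noise, emulating a second
  strain with the same underlying transcriptional response.

### What the generators do and do not emulate

They reproduce the *decision structure* each stage faces — E-value
margins and umbrella hits, clade nesting, MOI-dependent growth
suppression, overlapping event clouds with contamination, and class-mixed
DE tables — under the pipeline's own modeling assumptions. They do not
emulate sequence evolution, profile-score correlations between related
families, realistic branch lengths, mechanistic lysis kinetics,
instrument-specific scatter distributions, spectral spillover, or
count-based DE noise. Passing recovery tests therefore demonstrates
correctness of the rules and estimators under their stated assumptions,
not robustness to every way real instruments and genomes violate them.

## Problem sizes used in checks

Recovery checks run at 1,000 proteins for classification, 200 random
trees of ≤ 64 tips plus planted fixtures for clade calls, 20,000 events
per flow sample, and 200 null tables of 4,000 genes for type-I control of
the enrichment test — sizes at which the planted effects are comfortably
identified while the whole suite runs in well under a minute.

## Known limitations

- The classification stage consumes homology-search tabular output; it
  does not run the search, so E-value calibration differences between
  profile databases are the caller's concern.
- Clade calls depend entirely on the caller's reference tip sets; no
  attempt is made to infer which bacterial tips delimit the sporulation
  clade.
- The virulence index assumes the MOI = 0 control grows (positive area);
  wells where the control fails are errors, not imputed.
- The mixture model is fixed at two components with full covariance;
  samples with genuine sub-populations (germinating spores, damaged
  cells) will fold them into the nearest component.
- The exact-permutation Spearman p is factorial in n and capped at n ≤ 8
  by default.
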