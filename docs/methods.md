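# Methods

## Scope and design

`miromics` re-implements, as a tested library, a candidate-based
multi-omics association design: miRNA-related genomic regions define a
candidate SNP/CpG universe; GWAS summary statistics provide the discovery
layer; population-scale methylation and plasma expression data provide two
confirmation layers; external me-QTL and miR-eQTM catalogs are
cross-referenced; and the three layers are intersected per miRNA. The
original cohort-scale inputs (consortium GWAS files, array methylation,
HTG EdgeSeq counts) are not redistributable, so the package ships a
synthetic-cohort generator with planted truth plus the published
worked-example tables as fixtures.

## Coordinates and region construction

All 1-based inclusive inputs (GFF3, manifests, catalogs, VCF) are converted
once at read time to 0-based half-open intervals; writers convert back.
This single conversion boundary is deliberate — every interval comparison
in the package uses one convention.

Regions per miRNA: a flank interval `[precursor.start − f, precursor.end + f)`
(default f = 2,000 bp, symmetric and strand-agnostic, clipped at zero), the
precursor itself, and each mature interval. When a site falls in several
classes of one miRNA the most specific wins (mature > precursor > flank).
A site exactly on a flank's outer end is excluded (half-open); a site on
the start is included. eQTL-catalog SNPs map to miRNAs directly (most
miR-eQTLs are distal regulators, so no distance constraint applies) and
carry the class `eqtl`.

Catalog union is keyed by rsID; a SNP found by both the region scan and
the eQTL catalog is counted once and keeps both source tags. Conflicting
positions for one rsID abort the merge by name.

## SNP layer

Independent-test counts come from greedy position-ordered sliding-window
LD pruning (window 250 kb, step half a window): within a window, while any
surviving pair has r² above the cut (0.7), the worst pair's member with the
larger position-order index is dropped. Ties on r² resolve to the first
pair in row-major order — the procedure is fully deterministic, its output
preserves input order, and re-pruning its own output is a no-op. Missing
pairwise values count as independence (r² = 0) with a log line.

The Bonferroni threshold α/m is computed per imputation panel on the
pruned count of candidate SNPs present in that panel's GWAS (not on the
full candidate set). Allele harmonization: a summary-stat row whose
effect/other alleles are swapped relative to the catalog has its beta sign
flipped; A/T and C/G sites with any allele discordance are dropped because
a swap is indistinguishable from a strand flip. SNPs absent from a GWAS
are untested for that trait, never "failed". p = 0 inputs are floored at
1×10⁻³⁰⁰ for −log₁₀ plotting only; significance always uses the raw value.

Per-(miRNA, trait) locus summaries keep the minimum-p SNP, breaking ties
by position then rsID.

## Methylation layer (EWAS)

Model orientation: methylation is the dependent variable — the technical
random effects act on the measurement, so `beta ~ trait + covariates +
(1 | batch)` fitted by REML. The expression layer uses the opposite
orientation because there the disease-prevalence models force the trait to
the left-hand side; the two orientations are an explicit design choice.

Covariates: base set age, sex, current smoking and measured blood cell
fractions (monocytes, granulocytes, lymphocytes); group additions are BMI
for WC/WHR (a trait never adjusts for itself), BMI + diabetic medication
for glycemic traits, BMI + lipid medication for lipids, and BMI +
blood-pressure-lowering + lipid medication for cardiovascular traits.
Fitting is complete-case per (probe, trait), with a 30-sample floor.
Beta-values are used untransformed, so coefficients are on the methylation
fraction scale (an M-value switch is deliberately absent: the layer's
published effect sizes are beta-scale).

When the REML batch-variance estimate is degenerate (< 10⁻⁸) or the
optimizer fails, the fit falls back to OLS with batch as a fixed factor and
records the fallback; with a single batch the plain OLS limit applies. The
two technical grouping factors of a real array experiment (plate, array
row) are collapsed into one batch label — a single random intercept is all
the generator emulates.

## Expression layer

CPM = counts / library-size × 10⁶; the log transform is log₂(CPM + 1), so
zero counts map to 0 and the "mean log₂ CPM < 1 means not expressed" floor
is meaningful. The floor and the LLOQ filter are two independent,
sequential criteria.

LLOQ: per-miRNA mean and SD of log₂ CPM; antitonic regression (decreasing
isotonic fit, scikit-learn PAVA) of SD on mean, lightly smoothed with a
centered moving average (which preserves monotonicity); the LLOQ is the
smallest mean whose fitted SD is at or below a cut. The cut defaults to
the midpoint of the fitted SD range — a scale-free, reproducible choice the
source design left open — and is exposed as `sd_cut`. Fewer than 10 finite
points is an error; a flat profile returns the minimum mean with a logged
warning. Well-expressed: strictly more than `min_frac` (default 0.5) of
samples strictly above the LLOQ. Housekeeping probes are normalized
alongside but excluded from the LLOQ fit and from testing.

Associations: continuous traits by OLS, T2D/CHD prevalence by logistic
regression (coefficients on the log-odds scale), covariates as in the EWAS
minus cell counts (plasma, not whole blood). Complete separation yields a
flagged record with missing p rather than a crash. Target-gene lookup
reuses the region-mapping and GWAS machinery on gene intervals (supplied
as BED; database retrieval is out of scope) with a per-miRNA Bonferroni
denominator equal to the SNPs tested in that miRNA's target genes.

## Cross-referencing and integration

me-QTLs are cis iff same chromosome and |SNP − CpG| ≤ 250,000 bp (boundary
inclusive, "no further than"); anything else is trans. Reference FDR
values are trusted as reported; eQTM pairs are pre-filtered at FDR < 0.01.
Joins never invent keys, and a trait-associated SNP whose me-QTL CpG has
no trait association is retained with a flag rather than dropped.

Integration is candidate-based: evidence entries exist only for miRNAs the
SNP layer identified (significant at the panel threshold). A downstream
layer that never tested a miRNA is recorded as `unavailable`, distinct
from "tested, null" — this keeps tested/supported counts reproducible.
The trait-compatibility rule is the weakest rule consistent with the
published integrated table: the CpG-matched and expression-matched traits
must each lie inside the SNP trait set but need not equal each other.
Prioritization requires the `eqtl_evidence` flag, supplied as input
(its derivation — eQTL portals, tissue atlases, RNA secondary structure —
is outside the package's scope). Output ordering is ascending best
SNP-layer p with the miRNA id as a deterministic tie-break.

## Synthetic cohort generator

The generator emulates the study conditions, not any particular dataset:

- **Layout**: precursors of ~80 bp spaced 50 kb apart on four chromosomes,
  one mature form each; per-miRNA blocks of SNPs and CpGs placed uniformly
  inside the ±2 kb window.
- **Genotypes**: latent AR(1) Gaussians per block (ρ = 0.97) thresholded
  at Hardy–Weinberg genotype frequencies into dosages {0,1,2}. One shared
  minor-allele frequency per block (drawn U(0.05, 0.5)) reflects that
  tight-LD SNPs ride a common haplotype; thresholding attenuates the
  latent correlation, so ρ = 0.97 yields adjacent dosage r² around 0.75.
  Blocks are mutually independent.
- **Summary statistics** are *computed*, not drawn: per-SNP simple linear
  regression of each trait on dosage over the GWAS cohort (closed-form
  least squares; an independent regression routine reproduces the stored
  betas to 10⁻⁸). Traits carry planted dosage effects (β = 0.4 per allele
  on a unit-variance trait) for the planted miRNAs' lead SNPs.
- **Methylation**: probe baseline U(0.2, 0.8) + batch intercepts
  (10 plates, SD 0.02) + N(0, 0.02) noise, clipped to (0, 1); planted
  probes add an effect of 2× the residual SD per SD of trait.
- **Counts**: per-miRNA latent log₂ means (well-expressed U(4, 11), rest
  U(−2, 1)) with log-scale SD following 2·exp(−mean/3) + 0.2 — the
  decreasing mean–SD relation the LLOQ stage assumes — converted to
  Poisson counts at a 5×10⁶ library size. Realized log₂ CPM is shifted
  from the latent scale by the library composition, as CPM genuinely is;
  the shift is common to all miRNAs, so ordering, SD structure and the
  planted separation survive.
- **Phenotypes**: age, sex, smoking, noisy cell fractions, BMI and
  medication flags per cohort; disease prevalence via a logistic link
  (T2D 0.15, CHD 0.10). The three omics cohorts are disjoint sample sets,
  as in the emulated design.
- **Planted miRNAs** carry effects for the same trait in all three layers
  and appear in the me-QTL/eQTM reference tables and the functional-flag
  table; everything else is pure noise.

What the generator does *not* emulate: real allele-frequency spectra,
probe chemistry and cross-reactivity, count over-dispersion beyond
Poisson, trait correlations, relatedness, or population structure. Tests
passing on this generator therefore demonstrate the estimators' internal
correctness and calibration, not robustness to those real-data features.

Determinism: one `numpy` Generator seeded from the config; identical
config + seed gives byte-identical outputs on any platform.

## Problem sizes used in the shipped runs

The default generator (300 miRNAs, 4,800 SNPs, 5,000/700/1,000 samples) is
sized so a full pipeline run completes in minutes on one CPU. The test
suite uses a 60-miRNA cohort (2,000/300/500 samples), 2,000-fit null
batches for the calibration checks (EWAS nulls at n = 700, the methylation
sub-cohort scale), and the acceptance script a 150-miRNA cohort
(4,000/500/800 samples). These are the package's own choices of
desk-scale defaults.

## Known limitations

- The mixed model uses normal-approximation Wald p-values (statsmodels
  MixedLM); at small n they are mildly anticonservative, which is why the
  calibration checks run at the cohort scale the generator emulates.
- LD pruning guarantees no surviving pair with r² above the cut within
  half a window of each other; pairs between half and one full window
  apart are only checked when a window happens to contain both.
- The LLOQ cut is a convention (midpoint of the fitted SD range); with a
  bimodal expression profile the LLOQ lands between the modes, which is
  the intended behaviour but means its absolute value tracks the profile,
  not an assay property.
- Binary-trait summary statistics in the generator come from linear
  (not logistic) single-variant regressions; for candidate lookup this
  affects effect-size units only, not calibration.
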