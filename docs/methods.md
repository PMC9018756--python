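# Methods

## The measurement model

A two-channel SILAC comparison yields, for every quantified protein group
and every GG-remnant (diGly) site, a normalized heavy/light ratio per
biological replicate. All analysis happens on log2(H/L). Three confounded
effects drive a site's ratio: the abundance change of its parent protein,
the ubiquitination change at that lysine, and measurement noise. The
pipeline's central quantity is the site-to-protein relative ratio
Δ = log2(H/L)_site − log2(H/L)_protein, in which the abundance component
cancels; sites are classified at a fold threshold T (default 3) with the
boundary |Δ| = log2 T counted as affected. The threshold is inclusive and
configurable because "3-fold" vs "over 3-fold" is ambiguous in common
usage; inclusivity changes at most the measure-zero boundary.

Sites whose protein lacks pre-enrichment quantification are labelled
`unmatched` and reported, never dropped silently, so summary counts always
conserve the total.

## Row exclusion

Contaminant and reversed-database rows (MaxQuant "+" flags) are removed
first. A GG remnant on a peptide C-terminal lysine is a tryptic artifact
when confidently localized, so sites flagged C-terminal with localization
probability strictly greater than 0.5 are excluded; at exactly 0.5 the
site is retained (the rule excludes *better than* 50%). Retained sites
must sit on lysine. The filter is idempotent.

Where several peptides support one (protein, position) site, the reader
keys records by site and the collapse to the best-localized peptide is the
table producer's concern; the synthetic generator emits one row per site.

## Replicate structure and merging

Each protein carries a latent log2 ratio θ ~ N(μ_p, √ρ·σ_p); replicate r
observes θ + ε_r with ε_r ~ N(0, √(1−ρ)·σ_p). This makes the per-replicate
marginal exactly N(μ_p, σ_p) and the inter-replicate Pearson correlation
exactly ρ, matching the observed high replicate agreement without
modelling MS noise mechanistically. Replicates are merged by the
arithmetic mean of available log2 ratios (median available as an option);
testing happens on merged values. Missingness is MCAR, independent per
replicate per row — the simplest mechanism consistent with the many
single-replicate quantifications such experiments show.

Defaults: μ_p = −0.07, σ_p = 0.596 (the observed pre-enrichment
distribution), ρ = 0.9, missing rate 0.15.

## Site model in the generator

Non-target sites inherit their protein's latent θ plus an offset drawn
from a two-component normal mixture; the offset component means are
mix_means − μ_p so the *marginal* site component means sit at the observed
peaks (−1.15, −0.35). Because the protein latent enters site and protein
identically it cancels exactly in Δ, which is why the caller's operating
characteristics have closed forms (`implied_delta_mixture`,
`analytic_reduced_rate`, `analytic_sensitivity`). The price of full
inheritance is that the marginal site distribution is the mixture
convolved with the protein latent (component sd
√(ρσ_p² + ρσ_j² + (1−ρ)σ̄²) ≈ 0.59 at defaults), so the bundle's marginal
is broader than the offset mixture and not visibly bimodal; the
distributional-fidelity test therefore checks the Kolmogorov–Smirnov
distance against this exact implied marginal (`marginal_site_cdf`), and
bimodality recovery is exercised on direct mixture draws. This is a
deliberate trade: the package's inference object is Δ, not the marginal.

Planted targets draw their offset as −log2 3 − Exponential(scale 0.5), so
every planted site's true relative shift is at least 3-fold down and the
excess has mean 0.5 log2 units. Free parameters (the data report no
ground-truth fraction or effect-size distribution) were fixed once:
mixture weights (0.4, 0.6) — a "large subset" shifted left; component sds
(0.18, 0.18); target fraction 0.10. Under these conditions the closed-form
operating point of the 3-fold caller is a false-positive rate ≈ 0.006
(specificity ≈ 0.994) and sensitivity ≈ 0.90 — the analytic values the
recovery tests compare against, not tuned quantities.

The generator also emits: ubiquitin (canonical 76-aa monomer, accession
`UBIQ`) as a protein group at log2 H/L 0.068 with GG sites at its seven
lysines carrying planted linkage shifts (default −1.0 on K48 and K63); an
IP-enrichment table in which planted interactors (30% of target proteins
plus 5% of the rest) exceed 1.5-fold bait/IgG enrichment; an expression
table correlated with the protein latent at ρ ≈ 0.46 (squared rank
correlation ≈ 0.21) with a BH step-up p column; and a FASTA proteome with
lysines forced at site positions. What the generator does **not** emulate:
peptide-level evidence, intensity-dependent ratio variance, shared-peptide
protein inference, isotope-incorporation or fractionation effects. Tests
passing on this data certify the pipeline's arithmetic and operating
characteristics under the stated model, not performance on real MS data.

## Abundance significance

The intensity-binned robust outlier statistic sorts proteins by summed MS
intensity into equal-occupancy bins (default: as many bins as leave ≥ 300
proteins each; 1 bin for small sets; bins of < 10 raise an error). Within
a bin, z = (ratio − median) / s_side, where s_side is the distance from
the median to the 15.87th (left) or 84.13th (right) percentile — the
one-sigma quantiles — giving asymmetric robustness. p = erfc(|z|/√2)
two-sided (both directions of change are of interest), then BH across all
records with significance at q < 0.05. On single-Gaussian nulls the
p < 0.05 rate is nominal to within Monte-Carlo and percentile-estimation
error (checked at n = 5000).

## Mixture fit and bimodality

EM on a two-component univariate normal mixture: quantile-split
initialization (components seeded below/above the median) plus seeded
random restarts (default 5), best final log-likelihood wins;
tol 1e-8 on the log-likelihood increment, max 500 iterations, component-sd
floor 1e-4 with a warning. The log-likelihood trace is retained and is
non-decreasing by construction. Bimodality is operationalized as
Ashman's D = |μ₂−μ₁|/√((σ₁²+σ₂²)/2) > 2 with both weights > 0.05, a
standard two-Gaussian separability criterion adopted because visual
bimodality is not a test.

## Linkage profiling

GG sites on ubiquitin accessions are remapped onto the monomer by
position → ((position−1) mod 76) + 1 (polyubiquitin precursors are exact
76-aa repeats). Exactly seven slots are reported; unmappable positions are
excluded with a warning. Each slot reports mean ± SEM over the available
experiment values — in the synthetic bundle these are the two SILAC
replicates, a deliberately small problem size; real studies would supply
three or more independent experiments.

## Enrichment and motifs

Fisher over-representation uses the one-sided hypergeometric upper tail
P(X ≥ k) per term, fold enrichment (k/K)/(n/N), Bonferroni min(1, m·p) and
BH (reported as both the Benjamini column and the FDR, which coincide
here). Motif classes are the literal patterns `[LP]P.Y` (PY) and `[SV]P.F`
(PY-like, the natural reading of "generally S/VPXF"); all match starts are
reported 1-based, overlaps included, and both patterns are configurable at
the module level.

## Radial mean intensity

Each mask pixel maps to r = d_centroid/(d_centroid + d_edge) with the
centroid at the mask's center of mass and d_edge from the Euclidean
distance transform of the mask — the natural reading of "distance of the
pixel to the centroid and the closest edge"; whether the original custom
code normalized along rays instead is not recoverable, so the formula is
declared rather than asserted identical. Pixels fall into bin
⌈r·n_bins⌉ (bin 1 at r = 0; outermost bin right-closed), so counts
conserve the mask area and bin means are affine-equivariant in the
intensity. On a disk this r equals the Euclidean normalized radius up to
one pixel of discretization, and the I(r) = r profile matches the analytic
annulus means (2/3)(b³−a³)/(b²−a²) to 1e-2 at 512². Masks must be a single
connected component (one cell per call).

Migration is summarized as m/d (furthest migrated cell over a reference
landmark distance, unitless). F:G densitometry converts band signals to
load units through a least-squares line over ≥ 2 known-load standards
before forming the ratio; non-positive converted loads raise an error
pointing at background/saturation problems.

## Pipeline and reproducibility

`run-all` executes filter → stats → call_targets → mixture → linkages →
integration, writing every stage's output plus a manifest of input SHA-256
hashes, parameters and package version. All randomness is routed through
one seed; identical inputs and seed reproduce byte-identical outputs.
Problem sizes in the tests and the acceptance script (2000-protein
bundles, 5000-draw mixture and null calibrations, 4000-protein null
bundle, 512² images) were chosen as the smallest sizes at which the
Monte-Carlo error bands in the checks are decisively narrower than the
effects being verified.

## Known limitations

- The free generator parameters (mixture weights/sds, target fraction,
  replicate correlation, missingness) are documented choices, not
  estimates from deposited data.
- The marginal-vs-Δ tension described above: marginal site bimodality at
  the observed peak separation is not reproducible under full protein
  inheritance with σ_p = 0.596.
- Exact Perseus internals of the outlier statistic are not public; the
  percentile construction here is a documented reimplementation.
- No peptide-to-site collapse logic beyond best-localization keying; no
  protein inference; no spectrum-level processing.
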