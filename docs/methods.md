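# Methods

## Study design being modelled

Eight sampled conditions cross maturation stage (IM, PM, M), sex (F, M;
immature animals are unsexed) and circalunar phase (NM, FRFM): `IM_NM`,
`IM_FRFM`, `PM_NM_F`, `PM_NM_M`, `PM_FRFM_F`, `PM_FRFM_M`, `M_NM_F`,
`M_NM_M` — mature animals are sampled only at new moon. Each condition has
three biological replicates (pools of heads). Fourteen pairwise comparisons
are pre-configured (8 maturation, 3 sex, 3 lunar contrasts); the exact set
is a reconstruction from the sampled conditions and is fully configurable
(`design.DEFAULT_COMPARISON_SPECS`). "Maturation DETs" etc. are pooled as
the union of significant consensus calls over that factor's comparisons;
the pooling rule is exposed in the consensus layer.

## Synthetic data generator

The generator emulates the data-generating process the analysis assumes;
it is the package's test bed, not a model of any particular real dataset.

**Counts.** Per transcript a lognormal baseline (meanlog 4, sdlog 1.5 —
a realistic bulk-RNA dynamic range); truly regulated features get
multiplicative effects: lunar features ±`effect_log2fc` (default 2, i.e.
4-fold) in FRFM samples, sex features in male samples, maturation features
a monotone stage gradient with log2 multipliers 0 / 1 / 1.5 × log2FC for
IM / PM / M (consecutive stages differ, while the full IM→M span stays
within ~1.5× the stated effect size). Regulated fractions default to the
observed study-scale rates (transcripts 16.52 / 1.23 / 0.12 %; proteins
65.13 / 1.60 / 24.53 % for maturation / sex / lunar). Counts are drawn
NB(mean = baseline × effect × library-size factor, dispersion 0.05);
per-sample depths are uniform in 0.8–1.2 M. Technical lanes are
**multinomial thinnings** of each biological replicate's counts, so
collapsing lanes by sum recovers the replicate draw exactly — this is what
makes the TR-collapse contract testable to equality.

**TMT intensities.** Per protein a lognormal abundance (meanlog 7.6,
sdlog 1.2), per peptide a lognormal ionisation efficiency (sdlog 0.5) and a
unique-mapping flag (p = 0.9); protein effects as above but with
`protein_effect_log2fc` defaulting to 1 (2-fold): protein fold-changes are
buffered relative to transcript changes, and (see *Limitations*) the
normalization cascade's residual bias grows with the aggregate asymmetry of
regulation, so 2-fold is both the more realistic and the more diagnostic
default. Observed intensity = abundance × efficiency × channel loading
(CV 10%) × run effect (sd 0.05) × lognormal measurement noise (sd 0.2);
values below a fixed detection floor (100) are missing —
**left-censoring**, i.e. missing-not-at-random, which is exactly the
regime the quantifiable-protein filter exists for. NM sets are 5-plex (the
five NM conditions); FRFM sets carry the three FRFM conditions plus one
spike channel replaying the protein abundances of `PM_NM_F` BR1 — with
only three FRFM conditions sampled, FRFM sets are 4-plex (set validation
accepts 4–6 channels). Five technical MS runs per set.

**Randomness contract.** One root seed expands via `SeedSequence.spawn`
into independent child streams (counts, TMT, ontology, qPCR); consuming
one stream never perturbs another, and identical configuration + seed is
bit-reproducible.

## Count differential expression

Both NB tests share the dispersion machinery but are deliberately distinct
pipelines so the rank-sum consensus merges genuinely different evidence:

* **Wald route** — median-of-ratios size factors (median over features
  positive in all samples of count / geometric-mean reference).
* **LRT route** — TMM composition factors (trimmed weighted mean of
  log-ratios, 30% trim on M, 5% on A, precision weights, factors rescaled
  to geometric mean 1; cross-checked against an independent reference
  implementation at 2% tolerance) times library size.

**Dispersions.** Per feature, method of moments on size-factor-normalized
counts pooled within groups: `(var − shot_noise) / mean²`, where the shot
noise term is `mean × avg(1/size factor)` (the exact Poisson contribution
of normalized counts). A lowess trend of raw dispersion vs log mean is
fitted **non-robustly** (robust iterations chase the median of a
right-skewed estimator and bias the trend low); the working value is
`0.5 × trend + 0.5 × raw` (weight configurable; always between raw and
trend). All-zero features are excluded and reported NA.

**Tests.** Group log-means are fitted by vectorized Newton–Raphson on the
NB score with log size-factor offsets (Poisson closed form at dispersion
0). The Wald statistic is `(β_A − β_B) / SE` with SE from the summed
inverse Fisher informations; the LRT compares separate-means vs pooled-mean
likelihoods. Both statistics are referred to a **Student t with the
residual degrees of freedom** (equivalently F(1, n−2) for the LR statistic)
rather than their asymptotic normal/χ²(1) references: with three replicates
and estimated dispersions the asymptotic tails are anticonservative enough
to violate BH FDR control on full-null simulations, while the t reference
restores calibration (0 spurious BH-10% discoveries over 100 null
replicates × 2,000 features) at a negligible power cost (median |log2FC|
recovery error 0.17–0.20 at 4-fold effects, n = 5). Asymptotically the two
references coincide. Fold changes are reported as A relative to B; a
group with zero mean gets a +0.5 pseudo-count fold change for display
only, never for testing.

**BH adjustment** is a direct step-up implementation (`p·m/i` with a
running minimum), NA-aware (NAs excluded from m, reinserted), and verified
bitwise against an independent brute-force oracle.

## TMT normalization cascade

Order is enforced and recorded on the matrix
(`raw_mean → channel_norm → [filter] → median_norm → interrep_norm →
crossset_norm`); calling a step out of order raises. All steps operate on
the linear intensity scale; tests run on log2 values. No step imputes:
missingness propagates, except that a protein with a missing spike value
in a set is invalidated in that set (logged).

Channel sum normalization computes the equalizing factors on the proteins
present in **every** channel of the set, so the equal-sum contract holds
exactly on shared proteins despite missingness. Inter-replicate conversion
factors use one median per replicate set (reference BR1 for NM, BR3 for
FRFM, as in the study's scheme). Cross-set calibration is **per protein**
by default (each protein's factor is its own reference/spike ratio), with
a set-wide median-factor mode as an option — the per-protein reading
matches the "intensity / intensity value recorded for this sample"
phrasing; the text is ambiguous between the two.

## Protein tests

**Moderated t.** Two-group available-case model on log2 intensities;
pooled per-feature variance with df = n_A + n_B − 2 (features with < 2
present values per group are NA and excluded from BH's m). The prior
(d₀, s₀²) comes from method of moments on log sample variances
(digamma/trigamma inversion); d₀ is capped at 10⁶ and, when the observed
log-variance spread is at or below pure sampling noise, the prior collapses
to a point mass on the mean sample variance (so the moderated t equals the
ordinary t when all sample variances coincide). Posterior variance
`(d₀s₀² + d_g s_g²)/(d₀ + d_g)`, t with d₀ + d_g df. Cross-checked against
an independent reference implementation on a tiny fixture.

**Reproducibility-optimised statistic.** Family
`d_α(g) = |mean_A − mean_B| / (α₁ + α₂·s_g)` with s_g the pooled standard
error; α₁ grid 0–5 in steps of 0.05 for α₂ = 1, plus the scale-free
member (α₂ = 0, plain |Δmean|). For each member and top-list size k
(default grid 10–300), B bootstrap pairs (resampling within groups) give
the observed top-k overlap R_k and group-label-permuted pairs a null
overlap; the member maximising `(R_k − R_k^null)/sd(R_k)` is selected.
p-values come from a pooled permutation null of the selected statistic with
a **two-pass purification**: first-pass detections (p < 0.05) are removed
from the null pool and p recomputed. With 3v3 groups and a large regulated
fraction, label permutations retain part of the regulated features'
signal; without purification the pooled null tail floors every p-value
above the BH threshold even when the ranking is perfect. B defaults to 500
(100 in the orchestrated pipeline); everything is seeded.

## Consensus and bookkeeping

Each method's features are ranked by adjusted p (ascending, ties →
average ranks); rank sums sorted ascending with final ties broken by
feature ID. Features untested (NA) in either method are excluded from the
merge and reported separately. Significance defaults to BH 10% in **both**
methods (intersection; union available, and the choice is recorded in
every report) — on synthetic truth the intersection's false-discovery
proportion is never materially above the union's. Unisex calls require
significance in the same direction in both the male and female version of
a stage contrast. Percentages are rendered round-half-up to two decimals;
stratified enrichment folds divide the two-decimal percentages and report
one decimal — this reproduces the printed bookkeeping chains exactly
(e.g. 0.40 / 0.12 → 3.3). One printed maturation fold does not survive
recomputation (48.70 / 16.52 = 2.9, not 3.3); the reporting operations
emit the recomputed value.

## Soft clustering

Profiles are per-feature z-scores of condition means (zero-variance
features dropped, logged). The fuzziness exponent defaults to the
dimension-based estimate
`m = 1 + (1418/N + 22.05)·D⁻² + (12.33/N + 0.243)·D^(−0.0406·ln N − 0.1134)`
(> 1 always; manual override available). Fuzzy c-means uses k-means++
seeding from the given seed, membership updates computed relative to each
feature's nearest centroid (numerically safe down to m = 1.01), and stops
when the largest membership change is below 1e-8; the weighted objective
is non-increasing. Cluster number defaults to the average-linkage
dendrogram elbow (largest relative merge-height drop within the candidate
range; deterministic), replacing interactive dendrogram inspection; the
study-scale cluster counts (transcripts 5/5/4, proteins 5/5/3 for
maturation/sex/lunar) are treated as reference presets, not assertions.

## Term enrichment

Annotations propagate to all ancestors before testing. Over- and
under-representation are independent hypergeometric passes
(P(X ≥ x) / P(X ≤ x)). The conditional procedure tests terms in reverse
topological order (same-depth ties by term ID) and removes genes of
already-significant descendants (α = 0.05) from a parent's gene set; the
universe itself is unchanged. Output is ranked by raw p ascending; **no
multiple-testing correction is applied to enrichment p-values** — callers
should treat the ranking, not the absolute p, as the result.

## qPCR and correlation

Technical duplicate Ct values are averaged arithmetically before
ΔCt = Ct_target − mean(Ct_ref1, Ct_ref2); relative expression is 2^−ΔCt
(shift-invariant in Ct by construction). Group testing: Shapiro–Wilk per
group (n ≥ 3), Welch two-sided t, BH across the assay batch via the same
adjustment code as the DE tests. Transcript–protein agreement is Pearson r
on log10 values (scale-invariant); in the orchestrated pipeline, transcript
values are size-factor-normalized mean counts and protein values normalized
mean intensities, matched positionally as a synthetic stand-in for an
ORF-to-transcript map.

## Problem sizes

The orchestrated demo and the acceptance script run at 2,000 transcripts ×
400 proteins with 100 ROTS bootstraps — large enough for stable rates
(≈ 330 true maturation transcripts, ≈ 90 true lunar proteins) while a full
run completes in well under a minute; the generator scales to the
study-size defaults (52,059 × 2,290) unchanged. Calibration simulations
use 100 replicates × 2,000 features.

## Known limitations

* The cascade's sum-normalize → median-normalize → spike-calibrate chain
  couples channel scale to the composition of regulated proteins: when a
  large fraction of proteins is regulated with asymmetric aggregate effect
  (upward shifts inflate sums more than medians), null proteins acquire a
  systematic log2 offset between experiments (~0.08 at 2-fold effects on
  25% of proteins, ~0.25 at 4-fold). This is a property of the cascade
  itself, visible in the pipeline's residual protein-level FDP (~0.2 for
  lunar contrasts); it is not corrected because the cascade's definition is
  the object being implemented.
* Pooling a factor's calls as the union over its comparisons (each at
  BH 10%) controls FDR per comparison, not for the pooled set.
* The generator draws effect sizes as a single magnitude per feature and
  technical noise as lognormal; real data have heavy-tailed effect and
  noise distributions, batch structure beyond run/loading effects, and
  correlated features. Passing tests demonstrate correctness of the
  implemented operations under the stated model, not performance on real
  libraries.
* Permutation p-values at 3v3 have coarse granularity even after null
  purification; the moderated t carries most of the small-sample power in
  the consensus.
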