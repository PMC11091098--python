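# Methods

## The measurements being modeled

`vampseq` scores three multiplexed assays of variant effect on one shared
computational backbone:

1. **Abundance (FACS sort-seq).** Cells carrying one barcoded protein variant
   each are sorted by the GFP-fusion:mCherry fluorescence ratio into four
   equal-occupancy bins, and barcodes in each bin are sequenced. For variant
   *i* with per-bin frequencies *f*<sub>*i*,*g*</sub> the protein stability
   index is the frequency-weighted mean bin index

   PSI<sub>*i*</sub> = Σ<sub>*g*</sub> *g*·*f*<sub>*i*,*g*</sub> / Σ<sub>*g*</sub> *f*<sub>*i*,*g*</sub>,

   and the abundance score is the anchor-normalized form
   (PSI<sub>*i*</sub> − PSI<sub>stop</sub>) / (PSI<sub>WT</sub> − PSI<sub>stop</sub>),
   so the wild-type amino-acid sequence scores 1 and premature-stop variants
   score 0. PSI<sub>stop</sub> is the per-replicate median over nonsense
   variants and PSI<sub>WT</sub> the wild-type PSI, both averaged over
   replicates before the transform is applied to every replicate (a
   per-replicate anchoring variant is available as an option). Scores are not
   clamped; hyper-stable variants legitimately exceed 1.

2. **Toxicity (competitive growth).** Without sorting, the pool is sampled on
   days 0, 5, 7 and 9. Each variant's frequency trajectory is normalized to
   sum to one over days (the sequenced pools contain the same number of
   cells, so nothing else is normalized), and summarized by the ordinary
   least-squares slope α against day. Weighted least squares is deliberately
   not used: a frequency's Poisson uncertainty is correlated with the
   frequency itself, so weighting would systematically discount the late,
   informative time points of exactly the toxic variants. Days with zero
   observed count enter as zeros — no pseudocounts anywhere in the package.
   Scores are anchored per replicate as (α<sub>*i*</sub> − α<sub>WT</sub>) /
   (α<sub>toxic</sub> − α<sub>WT</sub>), so the neutral reference scores 0
   and the designated toxic reference scores 1 in every replicate.

3. **Degron tiles.** The protein is split into 24-residue tiles stepping by
   12; a C-terminal tile covering the last 24 residues closes the tiling.
   Tiles go into Odds/Evens/CT pools by serial parity (overlapping oligos
   never share a tube), each pool carrying three control peptides with
   C-terminal degron strengths strong (−RLLL) / mild (−RAAA) / none (−DAAA).
   The tile stability index (TSI) has the same weighted-mean-bin form as PSI.
   Because pools are sorted separately, the Evens and CT replicate TSIs are
   mapped onto the Odds scale by the unique affine map interpolating the
   shared RLLL and DAAA controls; renormalization happens per replicate, then
   tiles are averaged.

Upstream of all three sits the **subassembly** of the barcode → variant map
from long reads of the barcode+CDS construct: reads are decomposed by exact
constant flanks, compared globally against the reference CDS, and rejected on
any length difference (indel), ten or more nucleotide substitutions, or more
than one encoded amino-acid change. Barcodes map to a variant under a strict
majority (>50 %) of their reads; ties are dropped. Downstream counting is
exact-match only — no error-tolerant barcode matching — and the score of a
variant in a replicate is computed only when it has at least 20 reads summed
over bins (or days) in that replicate, so a variant can be scored in some
replicates and not others.

## The synthetic-data generator

The generator reproduces the statistical structure the estimators assume, at
the experiment's design scale: a 313-residue protein (6260-entry universe of
19·L missense + (L−1) nonsense + wild type), Poisson(21) random 18-nt
barcodes per entry, five million sorted cells, four bins of 25 % occupancy
sequenced to 10⁶ reads each across 11 replicates, and a four-replicate
day-0/5/7/9 time course at 10⁶ reads per day.

* **Latent abundance** lives on [0, 1] as a two-mode mixture on the
  fluorescence log-ratio: a WT-like mode N(1, 0.08) and a stop-like mode
  N(0, 0.10), clipped to the unit interval. Nonsense variants always join the
  low mode and the wild type the high mode. A missense variant joins the high
  mode with a *position-specific* probability drawn once per position from a
  Beta distribution with marginal mean 0.5 and concentration 0.8. The
  hierarchy is what makes mutational tolerance predominantly a property of
  position, so per-position medians capture roughly half of the score
  variance — the qualitative behavior of real variant-effect maps — while a
  flat Bernoulli would make positional medians uninformative by construction.
* **Sorting** draws each cell's fluorescence as N(latent, 0.25), splits cells
  at the empirical occupancy quantiles of the pooled mixture (estimated from
  a 200 000-cell subsample), assigns each barcode's cells to bins through the
  exact Gaussian bin probabilities, and sequences each bin with a multinomial
  of fixed depth. There is no PCR-duplicate or instrument-noise model beyond
  the Gaussian ratio spread; counts are exactly multinomial conditional on
  bin totals, which is the assumption the frequency normalization encodes.
* **Toxicity** acts multiplicatively on growth rate, not on sorting (the two
  screens are separate experiments). Only variants with latent abundance
  below 0.3 can be toxic; their per-day deficit is max-deficit 0.4 scaled by
  the shortfall below the threshold and jittered by U(0.6, 1), so toxicity is
  coupled to, but not determined by, low abundance. A designated toxic
  reference (C152W by default; the random reference protein is forced to
  carry Cys at the anchor position) receives a deficit of exactly 0.35/day.
  Cell fractions then evolve as exponential depletion; because frequencies
  renormalize each day, neutral variants drift slightly upward as the library
  loses complexity — the slight enrichment the slope estimator expects.
* **Predictor tracks** (a ΔΔG-like stability column on 0–5 kcal/mol, a
  conservation column on [−8, 0]) are rank-coupled to the latent abundance
  through a Gaussian copula at configurable Spearman targets (defaults −0.47
  and +0.45). Clipping the latent abundance creates tie blocks that attenuate
  rank correlations, so the generator applies two fixed-point corrections to
  land the realized coefficient on the target (within ±0.05 at full universe
  size); a target of ±1 produces an exactly monotone, noise-free track.
* **Determinism.** One seed drives everything through `numpy.SeedSequence`
  spawning, in fixed order: library, FACS, time course, predictors, tiles.
  Identical configurations produce byte-identical outputs.

What the generator does **not** emulate: sequencing errors at the read level
(reads are abstracted to barcode observations), PCR jackpotting and UMI
structure, FACS gate drift between replicates, within-bin expression
structure beyond the Gaussian ratio model, and any biochemical relationship
between a variant's identity and its latent abundance (positions are
exchangeable). Passing recovery tests therefore demonstrates that the
estimators invert the generative model they assume — not that the assay
itself is unbiased on real cells.

## Numerical choices and edge cases

* PSI/TSI are undefined (variant unscored) when all bin frequencies are zero;
  trajectories with zero total frequency are unscored rather than scored 0.
* Anchor degeneracy (PSI_WT = PSI_stop, or equal anchor slopes, or coincident
  control TSIs) raises an error instead of returning infinities.
* The ≥20-read filter applies to counts summed within a replicate across
  bins/days, interpreting the per-replica rule in its natural reading.
* Synonymous barcodes encode the wild-type protein and merge into the WT
  entry by default, so PSI_WT reflects the wild-type amino-acid sequence
  regardless of codon usage; an option keeps them as a separate track.
* Reverse translation uses one fixed high-usage human codon per amino acid
  (nucleotide sequences only matter for length accounting and exact
  matching); synonymous variants use a fixed alternate codon, which exists
  for every amino acid except Met and Trp.
* The weighted contact number uses Cα representatives and 1/r² weights with
  no cutoff, summed over all chains present, so subunit-interface residues
  gain contacts on a multimer. Unresolved residues are absent, not zero.
  Alternative WCN weight functions exist in the literature; comparisons
  against numbers computed with a different kernel must account for this.
* ΔΔG post-processing divides by 2.9 (model energy units → kcal/mol) and
  truncates to [0, 5]. The MSA gap filter removes sequences with strictly
  more than 50 % gaps; exactly half is retained.
* Variance explained by position is reported twice — as the squared Pearson
  correlation between scores and their positional medians, and as
  1 − SSE/SST with the medians as point predictions — because the two
  estimators genuinely differ when medians are not a least-squares fit.
* Bootstrap confidence intervals are percentile-based, seeded, and
  reproducible; resamples with zero variance become NaN and are excluded.

## Problem sizes

The acceptance script and the full-scale tests run the complete default
configuration (6260-entry universe, ~131 000 barcodes, 11 FACS replicates at
10⁶ reads per bin, four time-course replicates at 10⁶ reads per day); one run
takes a few seconds on a single CPU because sorting and sequencing are
vectorized multinomials rather than per-cell loops. Unit and property tests
use a 40-residue, three-replicate configuration (`small_config`) with
50 000 reads per bin/day.

## Known limitations

* The control peptides, Gibson adapters, default reference protein and
  test-globule coordinates are synthetic stand-ins, labeled as such where
  they are defined; they preserve lengths, orderings and statistical roles
  but not real sequences or structures.
* The slope estimator is linear, not an exponential fit; it is the assay's
  published estimator and is reproduced as such, but its scores are only
  rank-faithful, not proportional to growth-rate deficits.
* Replicate variation in the simulator comes from sampling alone (cells and
  reads); there is no replicate-level batch effect, so simulated replicate
  correlations sit near the top of the range observed in real screens.
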