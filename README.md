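# vampseq

Scoring pipeline for multiplexed assays of variant effect on protein
abundance and cell fitness, plus degron-scanning peptide tiles — the analysis
stack behind FACS-sort-seq ("VAMP-seq"-style) deep mutational scans, written
for people who need the published estimators as tested, reusable code rather
than one-off analysis scripts.

## What it computes

For a site-saturated library of single amino-acid variants, each marked by
random 18-nt barcodes:

* **Subassembly** — builds the barcode → variant map from long reads of the
  barcode+CDS construct. Reads with any indel, ten or more nucleotide
  substitutions, or more than one encoded amino-acid change are rejected;
  barcodes map to their strict-majority variant with full filter accounting.
* **Abundance scores** — the protein stability index
  PSI*ᵢ* = Σ*g* *g*·*f*ᵢ,*g* / Σ*g* *f*ᵢ,*g* over FACS bins *g*, anchored so
  the wild-type protein scores 1 and premature-stop variants score 0. No
  pseudocounts; variants are scored per replicate only at ≥ 20 reads.
* **Toxicity scores** — the unweighted OLS slope α of each variant's
  time-normalized frequency over culture days (0, 5, 7, 9), anchored so the
  wild type scores 0 and a toxic reference variant scores 1.
* **Degron tiles** — designs the 24-residue / 12-step tile library
  (Odds/Evens/CT pools with degron control peptides, 132-nt oligos), scores
  tiles by the same weighted-mean-bin index (TSI), and renormalizes pools
  onto a common scale through the shared RLLL/DAAA controls.
* **Residue-level context** — weighted contact numbers (Σ 1/r² over Cα
  pairs) from a structure, predicted-stability (ΔΔG) rescaling/truncation,
  MSA gap filtering, per-position medians, variance explained by position,
  bootstrap-CI correlations, clinical-class summaries and replicate
  statistics.
* **Synthetic data** — a seeded generator producing barcode maps, FACS-bin
  counts and time courses with the statistical structure these estimators
  assume (bimodal latent abundance, equal-occupancy sorting, multinomial
  sequencing, exponential depletion confined to low-abundance variants), so
  the whole pipeline is testable end to end with no sequencing data.

The scoring steps are sklearn-style estimators (`AbundanceScorer`,
`ToxicityScorer`, `TileRenormalizer`) with `fit`/`transform` and fitted
anchor attributes; everything is also reachable through plain functions and
a `vampseq` command-line interface (`simulate`, `subassemble`, `count`,
`normalize`, `abundance`, `toxicity`, `tiles`, `structmet`, `analyze`,
`pipeline`).

## Worked example

```python
from vampseq import AbundanceScorer, ToxicityScorer, small_config
from vampseq.simulate import simulate_library, simulate_facs_counts, simulate_timecourse
from vampseq.quantify import merge_and_normalize, apply_read_threshold
from vampseq.analyze import correlate

cfg = small_config(seed=1)                      # 40-residue protein, 3 replicates
barcode_map, truth = simulate_library(cfg)

counts = simulate_facs_counts(truth, barcode_map, cfg)
freq = apply_read_threshold(merge_and_normalize(counts, unit="bin"), "bin", 20)
scores = AbundanceScorer().fit(freq).score_table(freq)

rec = correlate(scores.set_index("variant")["score"], truth.latent_of(),
                "spearman", seed=1)
print(f"abundance recovery: spearman {rec.coefficient:.3f} "
      f"[95% CI {rec.ci_low:.3f}, {rec.ci_high:.3f}], n={rec.n}")

tc = simulate_timecourse(truth, barcode_map, cfg)
tfreq = apply_read_threshold(merge_and_normalize(tc, unit="day"), "day", 20)
tox = ToxicityScorer(toxic_anchor=truth.toxic_anchor).fit(tfreq).score_table()
print(tox.set_index("variant").loc[["WT", truth.toxic_anchor]].round(3))
```

prints

```
abundance recovery: spearman 0.961 [95% CI 0.954, 0.968], n=800
         score   sd  n_replicates
variant
WT         0.0  0.0             3
C20W       1.0  0.0             3
```

The recovery line says the abundance scores computed from simulated bin
counts rank-match the latent truth the counts were generated from; the
toxicity table shows the anchor contract — the wild type scores exactly 0
and the toxic reference exactly 1 in every replicate, with other variants
falling on that scale according to their growth deficit. A score table row
carries the replicate-mean score, its standard deviation over replicates,
and how many replicates passed the 20-read filter for that variant.

The same run from a shell:

```bash
vampseq pipeline --seed 1 --small --outdir out/
```

writes the barcode map, per-replicate and aggregated abundance/toxicity
score tables, the tile design and TSI scores, residue metrics, a summary
JSON of the headline statistics, and a manifest recording the seed,
configuration and package versions. Omit `--small` for the full design
scale: a 313-residue protein, ~21 barcodes per variant (~131 000 barcodes),
four bins at 10⁶ reads over 11 replicates, and a 4-replicate time course at
10⁶ reads per day.

## Layout

```
src/vampseq/
  variants.py     variant grammar, universe enumeration
  subassembly.py  long-read extraction, variant calling, majority-rule map
  quantify.py     exact-match counting, merging, frequency normalization
  abundance.py    PSI and anchored abundance scores (AbundanceScorer)
  toxicity.py     trajectory slopes and anchored toxicity scores (ToxicityScorer)
  tiles.py        tile design, TSI, control renormalization (TileRenormalizer)
  structure.py    weighted contact number, ΔΔG post-processing, MSA filter
  analyze.py      medians, variance explained, correlations, replicate stats
  simulate.py     the synthetic-data generator
  pipeline.py     the end-to-end runner
  cli.py          command-line interface
docs/methods.md   model assumptions, parameter choices, limitations
```
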