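# Methods

## Scope and model

`methylseg` analyses cytosine-level bisulfite count data from multiple
cohorts (generations) of the same tissue. The statistical unit is the 2×2
contingency table of a single cytosine: replicate counts are pooled within
each cohort, giving (methylated, unmethylated) counts per cohort. All
coordinates are held 0-based half-open internally; the 1-based cytosine
report dialect and 0-based BED are converted only at the I/O boundary.

### Per-site test

The per-site test is the two-sided Fisher exact test on pooled counts. It is
implemented as a vectorized log-gamma enumeration of the hypergeometric
support, summing point probabilities not exceeding the observed one with a
1 + 10⁻⁷ relative tie tolerance (the convention of the R ecosystem this
field predominantly reports with). The test suite checks it against an exact
integer/rational enumeration on every table with margins ≤ 30 (< 10⁻¹²
absolute) and against an independent library implementation on random
tables. Pooling replicates and testing with Fisher is the standard
no-replicate-model default for this assay; regression models with
per-replicate terms or covariates are deliberately out of scope.

Multiple testing uses Benjamini–Hochberg, applied genome-wide across all
tested sites (whether the original analyses corrected per chromosome is
unknowable from the outside; genome-wide is the stricter and simpler
choice). A site is differential when q < `q_max` AND |Δm| ≥ `min_diff`
percentage points, with both cohorts at pooled coverage ≥ `min_coverage`.

Defaults, with rationale:

| parameter | default | meaning |
|---|---|---|
| `q_max` | 0.01 (0.05 in the gametic profile) | corrected-p cutoff |
| `min_diff` | 15 pp, inclusive | minimum methylation difference |
| `min_coverage` | 10 per cohort | pooled-coverage filter (common ERRBS practice; not dictated by the method) |
| `min_sites` | 4 | minimum differential sites per region |
| `max_gap` | 1000 bp | maximum gap between consecutive differential sites |

One documented ambiguity: the source analyses state the corrected-p rule
once as "≥ 0.01" and once as "q < 0.01"; the latter is the only reading
consistent with calling *significant* sites and is what is implemented.

### DMR calling

Differential sites are chained by single linkage: a region is a maximal run
of consecutive differential sites with inter-site gaps ≤ `max_gap`,
measured between site start coordinates; runs shorter than `min_sites` are
dropped. Non-differential sites are invisible to the gap rule — the
definition is purely in terms of the called sites, which avoids committing
to an arbitrary window size. CpG and CpH sites are both eligible. Runs are
kept whole; mixed-direction regions are retained and flagged rather than
discarded, and a region is *unidirectional* when all member differences
share a sign. Region boundaries are [first site, last site + 1).

### Feature annotation and enrichment

From gene models, the package derives: promoter = TSS ± 2 kb (an absolute
window; strand only determines which gene end is the TSS), exons by
reference, introns = gene body minus exons, upstream = 50 kb beyond the
promoter edge, downstream = 50 kb beyond the TES, both strand-aware and
clipped at chromosome ends. CpG-island overlap is an independent flag, never
a primary label. A query's primary label is the highest-precedence feature
overlapping it (region queries use the midpoint); the default precedence
promoter > exon > intron > downstream > upstream > intergenic privileges
proximal regulatory context and is configurable.

Enrichment divides the percentage of differential sites assigned to a
feature by the percentage of genomic space the feature occupies after the
same precedence flattens overlaps into a partition. Because observed and
expected percentages are computed over one partition, Σ observed = 100 and
Σ fold·expected = 100 exactly; a feature with zero flattened space reports a
missing fold. The formula is scale-invariant, so conclusions do not depend
on genome size.

### Segregation, overlap significance and propagation

Cohort DMR sets are matched by genomic overlap, ≥ 1 bp by default
(half-open: touching regions do not overlap). The matching rule between
generations is a genuine design choice — exact coordinate equality is too
brittle for boundary jitter — and a gene-level mode (shared assigned gene)
is provided because generation-intersection figures are often drawn at the
gene level. `trait_segregation` returns the regions of the first "present"
cohort supported by every other "present" cohort and absent from all
"absent" cohorts; with a single present cohort and no exclusions it is the
identity, which the tests assert.

Overlap significance between two cohort sets uses a Fisher exact test on
the 2×2 membership table over a *universe* of candidate regions, built by
clustering **all tested sites** (no significance filter) with the same
`min_sites`/`max_gap` rule. Published overlap tests rarely state their
universe; this choice makes the test self-contained, reproducible and
conservative (the universe contains every region that could in principle
have been called). The odds ratio is the unconditional cross-product ratio
(both·neither)/(A-only·B-only), flagged infinite when a denominator cell is
zero; the conditional MLE variant is not used because the cross-product is
what overlap analyses conventionally report.

Germ-cell (PGC) DMRs are checked for propagation by restricting a
downstream cohort pair to the sites inside each region and re-running the
identical test/threshold/cluster machinery there; a region with no covered
sites is *untestable*, which is reported distinctly from *non-propagating*.

## The synthetic-data generator

The generator emulates the statistical structure the inference assumes, not
the sequencing process.

* **Genome**: chromosomes with non-overlapping slot-placed genes (first and
  last exon anchored at the gene ends), CpG islands preferentially centred
  on TSSs (70%), and cytosine sites laid out in covered *fragments* —
  Poisson-sized runs (mean 20 sites) with geometric ~50 bp internal spacing,
  separated by 800 bp + exponential(250 bp) gaps. This reproduces the
  reduced-representation geometry in which dense covered fragments alternate
  with uncovered gaps, gives an overall density of 1 site / 100 bp, and is
  what makes a gap-bounded candidate universe meaningful. Sites are CpG with
  probability 0.97 (CpH otherwise).
* **Baseline methylation**: class means 0.10 inside CpG islands, 0.80 at
  non-island CpGs, 0.03 at CpHs — a deliberate caricature of a mammalian
  brain methylome — jittered per site by a Beta with concentration 50.
* **Planted DMRs**: runs of ~6 sites spaced 40–60 bp (span ≈ 200–300 bp), a
  signed effect Δ (default |Δ| = 0.30), and a 55/45 hypo/hyper mix; each
  planted region lists the cohorts it affects, and placement keeps a 2 kb
  buffer so neighbouring regions cannot chain. Planted-site baselines are
  pinned to |Δ| (hypo) or 1 − |Δ| (hyper), so the affected cohort saturates
  at the fully unmethylated/methylated state and the realized contrast is
  exactly Δ. This models the switch-like, two-state behaviour typical of
  regions that differ between cohorts; naively shifting the 0.80 background
  baseline would be truncated by the [0, 1] clip and silently shrink the
  planted effect.
* **Counts**: coverage is negative-binomial per site and sample (mean 30,
  dispersion 5 — the method's usual working depth; the noise model is not
  prescribed by the analysis itself). Methylated counts are beta-binomial:
  each replicate draws its methylation fraction from a Beta around the
  cohort mean with intraclass correlation ρ = 0.005, within the replicate
  concordance range reported for this assay. Degenerate means (0 or 1)
  bypass the Beta draw.
* **Seeding**: one master seed fans out through CRC-tagged named substreams
  (genome, placement, baseline, per-sample counts), so each stage is
  independently reproducible and byte-identical across runs; the `TruthSet`
  records the genome recipe, planted regions, baselines and seed, and can
  regenerate the identical data after a JSON round trip.

What the generator does **not** model: reads, bisulfite-conversion errors,
mapping bias, strand asymmetries, allele-specific methylation, spatial
autocorrelation of baseline methylation beyond the island/non-island split,
coverage correlation between neighbouring sites, or batch effects. Passing
tests therefore demonstrate that the inference chain is correct and
well-calibrated *under its own assumptions*; they do not certify power or
FDR on real data, where replicate overdispersion and covariate structure
can be larger and a regression-based per-site model may be preferable.

## Numerical and degenerate-input choices

* Fisher p-values are clipped to [0, 1]; ties use the 1 + 10⁻⁷ relative
  rule; computation is chunked (4096 tables) to bound memory.
* A zero methylation difference cannot occur in a called site (|Δm| ≥ 15),
  so a zero member difference inside a region triggers an assertion, not a
  silent class.
* Empty inputs: an empty site table yields an empty call table (warning
  logged); an empty DMR list summarizes as n = 0 with missing fractions and
  writes a valid header-only BED; enrichment with zero differential sites
  raises, instructing the caller to skip.
* Validation reports all missing config keys at once; thresholds are
  validated jointly (e.g. `min_diff` > 100 is rejected).
* Problem sizes used in the shipped checks — a 2 Mb/~20,000-site recovery
  benchmark, a 1 Mb/~10,000-site null, and the 1 Mb six-cohort demo — were
  chosen as the smallest sizes at which the multiple-testing landscape and
  fragment structure behave like the genome-scale setting.

## Known limitations

* Pooling replicates discards between-replicate variance; the beta-binomial
  simulator deliberately keeps ρ small so the pooled Fisher test stays
  valid. On real data with strong replicate effects the test can be
  anticonservative.
* DMR boundaries are site-defined; uncovered flanks of a true region are
  invisible.
* The midpoint rule for a region's primary feature can misclassify regions
  straddling a feature boundary (member sites are unaffected).
* Gene-level matching treats any shared gene as support, which is generous
  for very long genes.
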