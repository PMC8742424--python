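# Methods

## Problem and model

A mixed animal-tissue sample is shotgun-sequenced; a small fraction of the
library (order 0.3–0.5% in real meat mixes) derives from mitochondrial
genomes.  Mitogenomes are ideal quantification targets: present in many
copies per cell, small (~16–17 kb, circular in mammals and birds),
structurally conserved but sequence-diverse across species (pairwise
p-distances of roughly 0.14–0.49 across common food species), and densely
represented in public databases.

The pipeline estimates, for each species in a reference panel, the number
of reads that can be attributed to that species *and no other*.  Because
mitogenomes are partially conserved, a large share of mitochondrial reads
(half or more in practice) maps to several species; total mapped counts
therefore overestimate every species, and only uniquely mapped reads are
used for presence calls and biomass.

## Pipeline stages and parameters

**S1 — extraction.**  Reads are queried (forward and reverse complement)
against a forward-strand k-mer index of the panel.  For every candidate
(species, diagonal) holding at least `min_seed_hits` exact seeds, the read
is extended ungapped along the diagonal under +1/−1 scoring; the read is
mitochondrial when some extension reaches `min_span` bases at
`min_identity`.

* `k = 21` (odd so a seed is never its own reverse complement; 4²¹ ≫ panel
  size makes random collisions negligible).
* `min_identity = 0.80`, `min_span = 60`: for 150 bp reads against a
  ~0.24 Mb panel this is a permissive operating point comparable to a
  nucleotide-BLAST search at a lenient e-value.  This stage *partitions*
  reads (mitochondrial vs not); it never assigns species.
* Reads shorter than k are counted and left unclassified.

With single 21-mer seeding the classifier is effectively exhaustive at
sequencing error rates (a 150 bp read at a 0.002 substitution rate almost
surely contains an error-free 21-mer), but heavily mutated reads (~10%
substitutions) lose their seeds roughly 8% of the time even though an
exhaustive alignment would still accept them.  At default conditions the
classifier agrees with an exhaustive all-diagonal oracle on >99.5% of
reads; the stress-case shortfall is a known property of seeded search.

**S2 — consensus assembly.**  Public references come from single
individuals; sampled animals differ by intra-specific variation.  Each
species' reference is therefore polished into a sample-specific consensus:
reads are seeded against that single reference, placed by banded
end-to-end alignment in a window around each seeded diagonal (band =
`ceil(0.1 · read_length)`; the band bounds both the explored diagonals and
the accepted edit distance), and aligned bases are counted per reference
position, modulo length on the circle.

* The band is the contamination guard: at ~20% panel divergence a foreign
  species' read needs ~30 edits to align, far beyond a 15-edit band, so a
  species absent from the sample keeps its reference rather than being
  rewritten toward a contaminant.  An explicit identity filter
  (`min_identity = 0.80`) applies on top and becomes active only if a user
  widens the band.
* Consensus: majority base where coverage ≥ `min_cov = 3`, the top base
  holds ≥ half the coverage, and the top base is unique; otherwise the
  reference base.  `min_cov = 3` stops a lone sequencing error from
  flipping a site; the reference fallback keeps uncovered regions usable.
* The model is substitution-only: the consensus keeps the reference length
  and coordinate system, and indels are out of scope.  For the same reason
  an ungapped placement is preferred whenever it achieves the banded edit
  distance — unit-cost alignment otherwise breaks ties between two
  substitutions and an indel pair arbitrarily, punching spurious holes in
  coverage.
* With error-free coverage ≥ 3 everywhere, the consensus equals the
  sample's true genome exactly (parameter-recovery property, tested).

**S3 — mapping.**  Every mitochondrial read is screened against every
assembled genome independently: accepted when its best end-to-end
alignment (either orientation, circular target) has edit distance ≤
`floor(0.1 · read_length)`.  The rule is deterministic and
tool-independent, at a stringency comparable to a short-read mapper's
end-to-end defaults for 150 bp reads.  A read aligning at several loci of
one genome counts once (set semantics on read ids).

**S4 — unique assignment and quantification.**  Reads in exactly one
species' mapped set are unique to it; reads in two or more sets are
ambiguous and discarded; reads in none are unassigned.  These three classes
partition the mitochondrial reads exactly (asserted on every run).
Presence: `unique/total_mito > threshold`, strict inequality, threshold
0.02 by default (set at the spike-simulation detection limit).  Across
replicates a species is present when present in at least one replicate.

**Correction factors.**  Species differ in mitochondrial DNA per gram of
tissue, so equal masses give unequal read counts.  From an equal-mass
mixture sequenced in replicates, `factor[s]` = mean over replicates of
`unique[s]/unique[baseline]` (pig baseline by convention).  The mean of
per-replicate ratios is used rather than the ratio of sums: replicate
libraries differ in depth, and the per-replicate ratio cancels depth while
the ratio of sums does not (on the bundled 15-species table the two
estimators visibly disagree, e.g. 1.94 vs 1.77 for fox).  Relative biomass
is then `mass[s] ∝ unique[s]/factor[s]`, normalised to sum to one over the
species with factors; species lacking a factor are excluded and flagged.
The proportional combination rule is this package's own reading — factors
are defined by construction only up to the claim that corrected counts are
mass-proportional.

**Sensitivity (spike-in) study.**  Minor-species reads are mixed into a
major background at a grid of percentages (defaults mirror the reference
experiment: 30,000 reads per dataset; levels 0.01–100%; five replicates;
minor count = round(total·level/100), half away from zero, so 0.01% of
30,000 is 3 reads).  Detected = unique reads assigned to the minor species
after S4.  Relative error = |detected − true|/true; per level the mean and
the *population* SD (divisor n) over replicates are reported — the divisor
is pinned by cross-checking the bundled published table, whose printed ±SD
values only reproduce with divisor n.  The detection limit is the smallest
level whose mean relative error is strictly below the tolerance (default
5%).  `simulated_spike_study()` packages the self-contained rerun used by
the acceptance script: 16 kb two-species panel at ~20% expected divergence,
150 bp reads at 0.002 substitution rate, 10,000-read datasets, levels
{2, 3, 5, 10, 20, 50, 100}%, three replicates — sizes chosen to keep a full
study to a few minutes on one CPU while leaving per-level counts large
enough for the error statistic to be meaningful (200 minor reads at the 2%
level).

## Synthetic data generator

`simdata` emulates the study conditions end to end:

* **Panels** are star phylogenies: a uniform-random ancestor and one
  independent mutant per species with exactly `round(m·L)` substituted
  sites (uniform over the three alternative bases).  Expected pairwise
  p-distance is `2m(1−m) + (2/3)m²`; `divergence_to_mutation` inverts this
  so panels are parameterised by their expected divergence.  The default
  target of ~20% sits inside the range real food-species panels span.
* **Reads** are single-end, uniform start on the circle (reads may span
  the origin), Bernoulli(½) strand, per-base substitution probability
  0.002 (the right order for post-QC Illumina data), constant Q30
  qualities, truth-labelled with their source species.
* **Mixtures and spike series** sample without replacement from per-species
  pools and shuffle deterministically; replicate r of a spike design uses
  seed `seed + r`.  Truth-label counts in any mixture equal the design
  exactly.
* **Off-target background** reads are uniform random; a random 150-mer
  essentially never shares a 21-mer with a 16 kb panel.

What the generator does **not** model: indels, quality-score error
profiles, PCR duplicates, GC bias, paired-end structure, real phylogenetic
tree shape (star topology only), nuclear mitochondrial pseudogenes (NUMTs),
or within-species polymorphism beyond a single sample genome.  Passing
tests therefore demonstrate the counting machinery and its thresholds under
a clean substitution-only error model, not robustness to real library
artefacts; on real data the extraction and mapping identities would absorb
some of these effects, and NUMTs in particular could inflate apparent
mitochondrial fractions.

## Numerical and design choices

* All pairwise genome alignments go through unique-k-mer anchoring (k = 15,
  anchors thinned to ~1 per 200 bp) with edit-distance alignment of
  inter-anchor segments; pairs with no colinear anchor chain raise an
  error advising external alignment rather than returning a garbage
  alignment.  Distances are p-distances over columns where both symbols
  are plain bases; no multiple-substitution correction is applied.
* Distances between reference/assembled genome pairs use pairwise (not
  joint multiple) alignment.
* Consensus ties (two bases at equal top count) fall back to the reference
  base; majority requires ≥ half the coverage.
* Percentages are carried at full precision internally and rounded to two
  decimals only when writing reports; correction factors print at two
  decimals.
* Classifier ties across species at equal identity resolve to the
  lexicographically smaller species id (deterministic output).
* All randomness flows from one seed; pipeline stages derive seeds by
  hashing the stage name with the base seed, so a run is byte-reproducible
  from (inputs, config, seed).
* The k-mer index accepts any odd k ≤ 31; k below ~11 is only sensible for
  toy panels and the default stays 21.

## Known limitations

* Substitution-only consensus cannot represent structural or length
  variation between the sample and the reference individual.
* Presence calling is threshold-based on unique-read share; a species whose
  mitogenome has few unique regions relative to the panel (e.g. closely
  related bovids) loses most reads to ambiguity and can stay below the
  threshold even when present — the bundled 15-species table shows cattle
  at ~80% non-specific reads for exactly this reason.
* Correction factors are tissue- and protocol-specific: they fold together
  mitochondrial copy number, DNA extraction efficiency and library
  behaviour, and transfer to other tissues or kits only approximately.
* The unmapped-read fraction is exported for external taxonomic profiling
  but not classified here.
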