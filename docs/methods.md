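# Methods

## Scope and coordinate conventions

All analyses run in a single coordinate frame: 0-based, half-open
intervals on the plus strand of a named reference. Read positions are
1-based 5′→3′ on the read's own strand. A dipyrimidine site is identified
by the plus-strand coordinate of the base that is 5′ *on its own strand*
(`pos5`); a minus-strand site of kind K therefore appears on the plus
strand as `revcomp(K)` with `pos5` at the rightmost of the two plus-strand
positions. The dimer coordinate of an aligned read is the plus-strand
position of the dimer's 5′ base: `start + p − 1` (plus strand) or
`start + length − p` (minus strand, mirrored), with `p` the 1-based dimer
offset within the read.

Circular references (plasmids) are handled by virtual extension: the
dinucleotide spanning the origin is enumerated, the exact-match index
finds origin-spanning occurrences, and all reported coordinates are
reduced modulo the length. N bases never form dipyrimidines and abort
exact matches.

## Generative model of an excision-product library

One simulated molecule is produced by:

1. **Site draw.** Every dipyrimidine site of the configured kinds gets a
   weight: the kind's damage propensity (default TT 0.95, TC 0.03,
   CT 0.01, CC 0.01 — CPDs in these libraries are overwhelmingly at TT)
   multiplied, for sites on a gene's transcribed strand inside the gene
   interval, by that gene's TCR enrichment factor *e*. Weights are
   normalized and the site is drawn from the resulting categorical
   distribution. Because the enrichment multiplies every TS site by the
   same factor, the expected TS/NTS count ratio within a gene is *e*
   times the composition baseline, and *e* itself is what the downstream
   ratio-of-ratios estimates.
2. **Length and placement.** A product length is drawn from the length
   distribution (prokaryote default 12:0.05, 13:0.85, 14:0.10 with dimer
   offsets 8, 8, 9; eukaryote default 24–30 peaked at 26–27 with the
   dimer a fixed 7 nt from the 3′ end, i.e. offset 19 for 26-mers). The
   read is placed so the dimer's 5′ base sits at the offset and extracted
   5′→3′ on the damaged strand. On linear references, draws whose
   footprint leaves the sequence are rejected and redrawn (counted); on
   circular references placement wraps.
3. **Degradation tail.** With probability `degradation_fraction`
   (default 0.05) the product is 5′-truncated to a uniform length of
   4–11 nt, emulating the nucleolytic degradation products seen below
   12 nt. Truncation keeps the 3′ end; for the shortest truncations this
   can clip into the dimer itself, which is acceptable because degraded
   products are removed by the length filter downstream in any case.
4. **Library structure.** The raw read is `UMI + insert + 3′ adapter`
   (default 8-nt uniform-random UMI, TruSeq small-RNA 3′ adapter as a
   configurable stand-in for the real library chemistry, which is not
   modeled further). Each molecule then gains k ~ Poisson(`pcr_dup_mean`,
   default 1.0) byte-identical PCR duplicate copies. FASTQ qualities are
   a constant Q40 placeholder.

A matched experiment is two such libraries (mfd+ with enrichment, mfd−
without) generated from independent child seeds spawned from one parent
seed. Read ids are anonymous serial numbers; all ground truth lives in a
separate truth table (site, strand, length, gene, dimer coordinate,
duplicate parentage, degradation flag).

**What the generator does not emulate:** sequencing errors (real reads
with mismatches are discarded by the exact-match policy anyway; a
mismatch-tolerant trimmer flag exists for testing), ligation and
immunoprecipitation biases, UV dose–response, (6-4) photoproducts, and
damage-formation sequence context beyond the kind weights. Passing tests
therefore demonstrate correctness of the analysis chain and calibration
of the TCR estimator under the stated generative model — not robustness
to real-library artifacts.

## Processing chain

* **Deduplication before trimming** (default): byte-identical raw reads
  collapse to their first occurrence. Since the UMI is part of the raw
  sequence, genuine repeated repair events at one site survive (distinct
  UMIs) while PCR duplicates do not. A post-alignment UMI-aware mode
  (key = start, strand, length, UMI) is provided as an alternative
  (`dedup_mode: umi_aligned | both`), since duplicate removal can sit at
  either stage depending on library type.
* **Trimming:** first `umi_length` bases are the UMI; the insert runs to
  the leftmost adapter occurrence (prefix match, ≥ 5 bases overlap so the
  adapter may run off the read end, 0 mismatches by default for bitwise
  reproducibility; a mismatch tolerance is a flag). Reads without an
  adapter hit are kept whole if they are short enough to be a plain
  insert, otherwise discarded as `no_adapter`. Inserts under 4 nt are
  `too_short`, above the configured maximum `too_long`. Stats satisfy
  input = kept + Σ discarded exactly, asserted on every run.
* **Alignment:** exact full-length matching on both strands via a
  per-length substring hash; this is the whole alignment problem here
  because any mismatched or gapped read would be discarded anyway.
  Ambiguous placements (e.g. homopolymer inserts, short degraded
  fragments) are discarded by default (`random_one` optional). The
  leftmost plus-strand coordinate is reported regardless of strand (BED
  convention). Correctness is tested against a naive all-position scan.
* **Damage filter:** keep reads of exactly the canonical length with a
  qualifying dipyrimidine at the expected positions, checked on the
  read's own sequence (identical to the reference under exact alignment,
  and usable pre-alignment). Defaults: 13 nt with dimer at 8–9
  (prokaryote preset) or 26 nt at 19–20 (eukaryote preset); all four
  dipyrimidines by default, TT-only as a switch.
* **Subsampling:** uniform without replacement to a fixed depth (default
  200,000) after filtering, preserving input order; a request larger than
  the input returns everything with a warning.

## TCR estimation

Reads are assigned to genes by dimer coordinate in `[start, end)` — a
single-position rule that avoids double counting at gene edges (the
footprint-overlap alternative is deliberately not used; reads may still
count toward multiple *overlapping* genes). TS/NTS ratios and the TCR
ratio-of-ratios follow the definitions in the README; zero denominators
propagate as NA through the report. Display rounding is 2 decimals; full
precision is kept internally. A percentile bootstrap (binomial resampling
of strand counts per library) is available for TCR confidence intervals;
no significance testing is attached by default.

The eukaryote dimer offset deserves one note: 26-mers are filtered with
the dimer at positions 19–20, which places it 7–8 nt from the 3′ end
counting inclusively; descriptions of such products sometimes put the
dimer "5–6 nt from the 3′ end". Both conventions are expressible through
`DamageFilterSpec`; 19–20 is the default.

## Problem sizes, tolerances, and determinism

* Enrichment-recovery runs use a 7 kb circular synthetic plasmid, one
  1 kb gene, and 200,000 molecules per library; planted enrichments of
  2.5 and 6 are recovered within ±0.3 and ±0.6 (≈3 SE at these depths).
  The null calibration averages 20 replicate pairs of 50,000 molecules
  each — at that depth the standard error of the replicate mean is well
  under 0.01, so the [0.95, 1.05] band is a sharp unbiasedness check at
  a fraction of the cost of full-depth replicates.
* Stochastic checks use 3-standard-error bands with fixed seeds
  throughout; chi-square goodness-of-fit tests use α = 0.01.
* All randomness flows through `numpy.random.Generator` objects seeded
  from explicit integers (child seeds via `SeedSequence.spawn`), so a
  rerun with the same config is byte-identical across FASTQ, BED,
  bedGraph, and TSV outputs; the pipeline manifest records seeds and
  input SHA-256 digests and contains no timestamps.

## Known limitations

* Exact matching only; references with repeats longer than the product
  length will shed reads as multimappers (counted, not rescued).
* The trimmer is a layout-specific prefix/suffix matcher, not a general
  alignment-based adapter finder; it assumes the simulator's read layout.
* TT composition baselines (`tt_strand_ratio`, `flank_background`) count
  TT dinucleotides only, matching their use as CPD-site proxies.
* Single-reference pipelines: multi-contig references are parsed but the
  orchestrated pipeline operates on the first record.
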