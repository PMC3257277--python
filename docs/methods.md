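# Methods

This note documents the models, parameters, numerical choices and known
limitations of `motifswitch`, in the spirit of a statistical methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and unification rules

Coordinates are 1-based inclusive everywhere. Evidence comes in two
tiers: `LTP` (low-throughput, targeted experiments such as
phospho-specific antibodies or mutagenesis — treated as highly reliable)
and `HTP` (high-throughput surveys, mostly mass spectrometry or protein
arrays). When the same phosphorylation event is reported several times,
the records are unified: sources are unioned and the stronger tier (LTP)
wins. Rows that contradict the protein sequence (wrong residue letter,
out-of-range position, unknown accession) are never fatal; they are
dropped into a structured rejects log so large merges survive dirty
input.

Motifs longer than 30 residues are discarded as not narrowed down to the
binding element. Duplicate records of the same (domain protein, motif
protein, family) triple whose intervals overlap in more than 80% of the
residues are collapsed to one instance — the shorter, or on equal length
the left-most. Two choices here were genuinely open:

* *Overlap denominator.* "More than 80% of the residues" needs a
  denominator; we use the shorter motif's length (configurable). The
  worked 30–42 / 32–43 example collapses under either convention.
* *Chained duplicates.* Records duplicated across more than two sources
  can overlap pairwise without all pairs exceeding the threshold. We take
  the transitive closure of the >80% relation and keep one instance per
  connected component, which makes deduplication idempotent (kept
  instances never share an above-threshold overlap).
* *Tier of the kept instance.* The survivor takes the strongest tier in
  its component, mirroring the phosphosite rule.

## The disorder-matched permutation test

For a motif set of one family we count motifs with at least one
phosphosite inside (`intra`) and motifs with at least one site in the
N/C-terminal flanking windows (`near`, default window 20 residues,
boundary inclusive; a motif with both kinds of site contributes to both
counters). Significance comes from replacing every motif, in each of `B`
replicates (default 10,000), by a random same-length interval on the same
protein that

1. does not overlap the actual motif,
2. contains at least one Ser/Thr/Tyr, and
3. has a mean disorder score within ±0.1 of the actual motif's mean
   (motifs live in intrinsically disordered context; an unmatched null
   would be wildly anticonservative because phosphosites concentrate in
   disordered regions too).

The tolerance 0.1 is a package default (no established value exists) and
is configurable. The empirical p-value uses add-one smoothing and an
inclusive comparison, `p = (1 + #{b : k_b ≥ k})/(B + 1)`, so p is never
0 and the test is valid under ties; a literal strict-exceed variant
(`>`) is available behind a flag. Bonferroni correction is applied over
the (family × tier × intra/near) tests of a run.

Two robustness choices: a motif for which no interval satisfies all
three constraints is excluded from both the observed and the randomized
counts of that test (keeping the comparison balanced) and logged; and
each motif draws its replicate intervals from its own generator, seeded
by a stable hash of the motif identity mixed with the run seed, so
results are independent of input order.

*Known property.* The non-overlap constraint (1) makes the null counts
slightly anti-correlated with the observed event (an interval overlapping
the real motif would share its sites), which produces a mild
anticonservative drift of the rejection rate at large motif counts —
about 0.06–0.08 at nominal 0.05 in the calibration experiment below.
Dropping constraint (1) restores ~0.04, but the constraint is part of the
randomization design this package implements, so it stays.

## Dual patterns and the double-switch scan

Patterns are ordered residue classes (`.`/`x` wildcard, `[ABC]` sets),
optionally carrying a `phospho_index` — the position whose
phosphorylation the family requires (SH2, class IV WW) or blocks (the
class I WW tyrosine). Merging two patterns at an offset intersects the
classes position by position; an empty intersection means the offset is
incompatible. Merging is symmetric, and duplicates (identical merged
class lists) are collapsed.

The strict scheme keeps only offsets where the SH2 phospho-tyrosine
coincides with a partner position whose class is exactly `{Y}` — the
phosphorylated residue is then vital for both interactions. The
permissive scheme keeps all compatible overlaps and additionally requires
the SH2 phospho-tyrosine inside the merged span (our reading of "any
overlapping patterns": without the shared phospho-residue the notion of
a dual motif is empty). Proteome hits are reported only where a
documented phosphosite sits at the switch position; overlapping matches
are all reported, and every hit is cross-checked against both component
patterns, not just the merged one.

The shipped pattern library contains caption-verified patterns plus
ELM-style defaults and is explicitly replaceable (`--patterns`); the
network over-representation test uses the hypergeometric upper tail over
the network's protein universe (the underlying publication reports
p-values without naming a test).

## PDZ specificity switches

Peptides are aligned at the C-terminus (position −1 is the last
residue); the last three positions dominate PDZ specificity, and the
default position weights are 4/2/1 for −1/−2/−3 with 0.5 elsewhere.
"Highly similar" residues are defined by *both* a PAM30 log-odds score
≥ 0 and a biophysical distance ≤ 60 on the classic
composition/polarity/volume scale; the distance matrix is computed from
the published residue properties (`D = ρ√(αΔc² + βΔp² + γΔv²)`, mean
scaled to 100) and reproduces the published values (S–T = 58, V–F = 50).
All three thresholds are configurable; none is quantified in the source
analysis.

A binding matrix holds calls in {binds, no-bind, missing}; numeric
affinities (dissociation constants) convert via a configurable cutoff.
Missing calls always mean skip-and-log, never no-bind. For one peptide
pair and two domains there are 2⁴ = 16 labeled call configurations; the
domains are exchangeable, so by Burnside's count (16 + 4)/2 = 10
canonical scenarios remain — the package enumerates this rather than
assuming it. Switch over-representation is a two-sided Fisher test of
the observed (switch, other) counts against the configuration-uniform
expectation 2/16; the exact null of the original analysis is not
recoverable from its published description, so the uniform-configuration
null is declared as an interpretation.

## Evolutionary tracing

The lineage is the ordered 16-taxon list HUMAN, CHIMP, MOUSE, RATUS,
BOVIN, CHICK, XENTR, DANRE, CIONA, DROME, ANOGA, CAEEL, YEAST, DICDI,
ARATH, PLAFA (XENTR before DANRE, matching the distance ranking used for
the origin matrix); only the linear ranking enters the procedure, not
the branching topology. Orthology inference is out of scope: ortholog
sets arrive as multi-FASTA files with `TAXON|accession` headers.

Pairwise global alignment (Needleman-Wunsch with affine gaps; BLOSUM62,
gap open 11 / extend 1 — standard protein defaults, none are given by
the source analysis) yields a strictly increasing partial mapping of
human positions. The phospho origin is the most distant taxon whose
aligned position carries any of S/T/Y (phospho-potential, not residue
identity); the motif origin is the most distant taxon with a
family-pattern match (subtypes unified) within ±20 residues of the
aligned motif start. Deliberately, there is **no** continuity
requirement across intermediate taxa — the most distant presence wins
even if intermediate taxa lost the element; this is the literal reading
of the procedure and makes both origins monotone under ortholog
deletion. For SH2 / class IV WW units the binding-essential phosphosite
is excluded upstream; only additional sites form units.

The null model multiplies the empirical per-taxon motif-origin and
phospho-origin frequencies, sums the products over the diagonal
(co-appearance), lower triangle (motif-first) and upper triangle
(phospho-first), and compares observed 3-class counts to these expected
fractions by χ² with 2 degrees of freedom, Bonferroni-corrected over
domain families. Classes with expected counts below 5 set a warning flag
rather than failing.

## Synthetic data: what it emulates, and what it does not

The generators are first-class, tested code. Defaults were chosen once
as typical study conditions:

* Proteome: 200 proteins, gamma-distributed lengths (mean 400, minimum
  120), UniProt-like background residue frequencies (shipped as a static
  fixture, not a claim about any particular proteome).
* Disorder: alternating blocks (geometric lengths, mean ~50 residues)
  around 0.8 (disordered) and 0.2 (ordered) with per-residue sd 0.05 —
  enough structure that the disorder-matched sampler has non-trivial
  work.
* Motifs: Poisson(0.4) per protein, clipped-normal lengths (mean 12, sd
  4, range 5–25, matching the ~14-residue average of curated motifs),
  placed uniformly among intervals wholly inside disordered blocks that
  contain ≥1 S/T/Y; family mix SH3 0.40 / PDZ 0.25 / WW 0.20 / SH2 0.15,
  LTP fraction 0.45.
* Phosphosites: Bernoulli per S/T/Y residue at density 0.03, multiplied
  by the coupling enrichment factor inside motifs and their 20-residue
  flanks (factor 1 = the null; the enrichment is exact by construction),
  LTP fraction 0.15.
* PDZ matrices: peptide pairs differing by one S/T/Y↔D/E swap in the
  last three positions (remaining last-three positions identical, so all
  pairs satisfy the pairing defaults); planted couples receive the
  inverse-binding pattern; background calls are Bernoulli at the
  configured density.
* Ortholog families: substitutions only, no indels — alignment is then
  exact and noise-free planted stagings are recovered with certainty.
  Flanks and scrambled segments are drawn from an alphabet without
  P/R/K/Y so no spurious family-pattern hit can arise near the planted
  unit, and the residues following a planted tyrosine are neutralized so
  the tyrosine alone cannot complete an SH2 pattern.

What the generators do **not** emulate: kinase sequence specificity,
realistic affinity distributions, indel evolution, correlated
disorder/composition biases, and database-specific curation artifacts.
Passing tests on synthetic data therefore demonstrate the correctness
and calibration of the statistics under the stated generative
assumptions, not the biological conclusions one would draw from real
compendia.

## Problem sizes used by the packaged experiments

The calibration experiment runs 200 seeded replicates of 500-protein
null proteomes at 1,000 randomizations per test. 500 proteins (~200
motifs per replicate) is a count-resolution choice: with many fewer
motifs the intra/near counts are small integers, their heavy ties make
the empirical p-value distribution visibly super-uniform, and the
Kolmogorov–Smirnov distance to uniform cannot reach the ~0.05–0.08 this
size achieves. The power experiment plants 3× near-motif enrichment in
50 seeded 500-protein runs. Oracle-agreement checks cover every 2×2
table with row margins ≤ 30 (Fisher vs exact tail summation) and 50
random ≤12-residue pairs (alignment score vs brute-force Gotoh DP).

## Known limitations

* The permutation test treats motifs as independent; overlapping random
  intervals of different motifs on one protein can share sites, which
  slightly overdisperses null counts on motif-dense proteins.
* The PDZ "highly similar" thresholds and position weights are package
  defaults, not fitted quantities; conclusions can be sensitive to them.
* Pattern libraries are inherently incomplete; motif-origin calls are
  lower bounds with respect to the library used.
* The trace null conditions on the empirical marginals; with few units
  per family the χ² approximation is weak (flagged, not rejected).
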