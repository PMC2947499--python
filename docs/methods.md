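# Methods

This note documents the models and procedures `bsmira` implements, the
parameters that matter, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and containers

All internal coordinates are 0-based, half-open; BED input/output passes
through unchanged. A CpG site is recorded once, at the forward-strand C;
reverse-strand evidence (the paired G) is projected onto the same
coordinate, so a site's methylation level pools both strands. Positions
containing N never match a seed and never produce a methylation call.

## Library simulation

The simulator walks the enrichment protocol stage by stage and logs
everything into a ground-truth record.

**Genome synthesis.** Background sequence is drawn i.i.d. at 40% GC.
CpG islands (default 20 per 200 kb, 500–1,500 bp) are drawn at 65% GC
with one CG dinucleotide explicitly planted per ~12 bp; an i.i.d. draw at
island GC alone would leave the absolute CpG density too close to
background, while the planted islands reach roughly 4× background density
with observed/expected above 1, which is what makes island-targeted
capture meaningful. Half the genes (default 20) get their TSS at an
island center. The repeat track is positional annotation only — no
literal sequence copies are planted — so unique mapping remains
well-defined at this scale; consequences: repeat-overlap statistics are
exercised, but mappability in real repeat space is not.

**Methylation assignment.** Every CpG receives a level drawn from a
[0, 1]-truncated normal around its region target (default SD 0.05). The
default, tumor-like profile sets islands to 0.9 and background to 0.05;
a normal-like profile can instead raise repeat/gene-body targets. Region
precedence is island > repeat > gene body > background.

**Digestion and size selection.** Each enzyme (MseI `T^TAA`, BfaI
`C^TAG`, Csp6I `G^TAC`; all cut after base 1, leaving TA overhangs)
digests every chromosome to completion separately; the three fragment
pools are merged, mirroring the protocol's parallel digests. Fragments
outside 200–800 bp are dropped before capture. Enzymes are data, not
code, so toy enzymes can exercise the digest engine.

**Capture.** The true affinity curve of methyl-CpG-binding capture is
not known; any monotone function of methyl-CpG content produces
enrichment. We use the saturating form p = m/(m + k) with m the sum of
CpG levels over the fragment and k = 3 (the methyl-CpG count at
half-maximal capture), floored at 0.01 to model background carry-over.

**Bisulfite conversion.** Per molecule, each CpG cytosine is first drawn
methylated with probability equal to its level; methylated cytosines
never convert; unmethylated and non-CpG cytosines convert with
efficiency ε = 0.97. The residual 3% of unconverted non-CpG cytosines is
what the conversion-rate estimator measures; the residual unconverted
*CpG* cytosines inflate apparent methylation by about (1 − ℓ)(1 − ε) per
site — a bias inherent to the assay and deliberately left in.

**Reads and orientation.** Bisulfite conversion makes the two strands of
a fragment non-complementary; after PCR, four read classes exist, of
which two align to the forward reference under the mapper's two collapse
phases and two are their reverse complements. The simulator emits every
read pre-oriented along forward coordinates: each read comes from a "CT"
molecule (C→T conversions) or a "GA" molecule (G→A conversions — the
bottom strand's conversions viewed from the top), chosen uniformly, and
starts at the left or right template end (uniformly), mimicking
sequencing into the fragment from either adapter. Reads representing the
two reverse-complement classes are thus emitted already flipped; this
keeps the mapper free of a reverse-complement phase without losing
coverage of either fragment end. Read lengths follow a log-normal with
fixed shape (σ = 0.35) whose location is set to the target mean (FLX:
143 bp, truncated to [20, 444]; Titanium preset: 218, [20, 692]).
Substitution errors are injected at a configurable per-base rate
(default 10⁻³, a plausible substitution floor for the emulated
chemistry; homopolymer indel errors are out of scope). Adapter bases are
unmethylated and convert like any non-CpG cytosine.

## Two-phase mapping

The CT phase collapses T into C in both read and reference (forward
conversions); the GA phase collapses A into G (bottom-strand conversions
on forward coordinates). Per phase, the collapsed genome is indexed with
a suffix array (prefix doubling, numpy-backed) supporting exact lookup of
any collapsed substring.

Seeds (default length 20, stride 10, plus one end-anchored seed) found in
the index are discarded if any position pairs reference T with read C (CT
phase) or reference A with read G (GA phase) — those collapses are not
bisulfite conversions. Surviving seeds chain when they share phase and
chromosome, sit within 5 of a common diagonal, and are within 50 bp on
both axes.

Each chain is extended by an affine-gap alignment (match +1, mismatch
−2, gap open −3, extend −1; insertions and deletions never abut) over a
reference window spanning the chain's diagonals ± a 16-bp band, global
in the read, free at both reference ends. Scoring happens in the
original alphabet: an allowed bisulfite pairing is a match, an asymmetric
pairing is a mismatch. A chain whose gap-free placement is already
perfect skips the dynamic program.

The best candidate across both phases wins. Reads scoring below 0.9 ×
read length are unmapped; a read is unique only if the runner-up at any
other locus trails by ≥ 1 score unit (candidates at identical coordinates
found in both phases — e.g. reads without any C or G — are deduplicated
rather than treated as competitors). Ambiguous reads are excluded from
all downstream calling. None of these numeric values is canonical; all
are exposed in `MapperParams`.

`reference_dp.exhaustive_best_score` re-derives the optimal score with a
full-width dynamic program over every reference position and both
phases, sharing the scoring model but none of the code; the test suite
additionally checks both implementations against a scalar per-cell
program written independently inside the tests. For the oracle-agreement
benchmark the mapper runs with dense seeds (length 12, stride 2): under
the 0.9 score threshold a reportable alignment admits at most one error
event per ~30 bp, and that seed layout guarantees an intact seed between
adjacent events, so the heuristic provably sees every reportable locus.

## Methylation and conversion-rate calling

At each aligned M-column: a CT-phase read reports a reference-CpG C as
methylated (read C) or unmethylated (read T); a GA-phase read reports the
CpG's G one base downstream (read G / read A), projected onto the C.
Other read bases give no call; inserted/deleted bases give no call.
Non-CpG cytosines (forward: C not followed by G; reverse: G not preceded
by C; neighbors containing N are skipped) accumulate converted/unconverted
counts on both strands. The conversion rate is reported as the converted
fraction, with the unconverted fraction alongside — the two complementary
conventions both appear in the literature, so both numbers are labeled
explicitly. Division-by-zero states are flagged as undefined rather than
silently returned as 0 or 1.

## Clusters, methylation index, MRIs

Clusters are maximal runs of overlapping or exactly abutting unique
alignments; any positive gap splits (the merge gap is configurable for
sensitivity analysis). The methylation index is the unweighted mean of
per-site levels over the CpG sites inside the cluster — unweighted
because each site's level is already a read-pooled estimate; a
coverage-weighted variant exists but is off by default. Clusters without
any CpG have no index and are excluded. An MRI is a cluster ≥ 50 bp with
≥ 5 reads and index strictly greater than 0.20 (a cluster at exactly 20%
is not an MRI); called MRIs are re-checked against all three thresholds
after every run. Read-count and length thresholds are inclusive
("at least").

## Permutation test

Cluster geometry and the site-to-cluster assignment are frozen; each
permutation shuffles the level triple (level, methylated count, total
count) uniformly across all covered CpG rows, recomputes every cluster
index, re-calls MRIs, and runs a two-sample Student t-test (equal
variances by default — the two samples have equal size by construction;
Welch available) between the original and permuted index distributions
of proper clusters (those passing the read/length thresholds). Child
seeds derive deterministically from the master seed, so any single
permutation is reproducible alone.

Two calibration caveats are worth recording. First, within one dataset
the original sample is frozen across permutations, so permutation
p-values are only *marginally* uniform under a no-structure null;
assessing calibration requires pooling permutations across independent
null datasets, which is how the benchmark does it. Second, the permuted
sample reuses the observed level multiset: when the tested clusters hold
most of the shuffle pool, the two t-test samples are strongly dependent
and the test is conservative even marginally. In practice (and in the
benchmark's null geometry) proper clusters hold a minority of covered
CpGs — most covered loci have fewer than the threshold number of reads —
which keeps the dependence small.

On structured (capture-enriched) data the test is powered by two effects:
shuffling pulls every cluster index toward the pool mean, collapsing the
variance of the distribution, and because CpG-dense methylated clusters
dominate the pool, the permuted mean shifts away from the original
unweighted cluster mean.

## Annotation

Gene-context windows are strand-aware, computed in transcription
orientation: 5′ end [TSS − 2,200, TSS + 500), gene body
[TSS + 500, TES − 500), 3′ end [TES − 500, TES + 500), clamped at
chromosome bounds; genes shorter than 1 kb have no body window. An MRI
overlapping ≥ 1 bp of a window takes its label with precedence 5′ end >
3′ end > gene body (promoter methylation is the phenomenon of interest,
and the narrow 3′ window would otherwise be unreachable); no overlap
means intergenic. The four categories partition every MRI set by
construction. CGI/repeat overlap is plain ≥ 1-bp interval overlap; an MRI
counts once per repeat class and once toward the "contains repeats"
total. Between samples, MRI overlap counts A-side regions sharing ≥ 1 bp
with any B-side region, and the CpG-level Pearson correlation is computed
over sites covered in both samples (minimum coverage configurable;
undefined under 3 shared sites).

## Problem sizes and limits

The benchmark runs use a 200 kb genome (4 chromosomes), 20,000 reads,
ε = 0.97 and the default capture model — small enough to run the whole
stack in about a minute while leaving hundreds of clusters and thousands
of covered CpGs to measure on. What passing these checks shows: the
mapper is score-optimal against exhaustive search, and every pipeline
stage recovers what the simulator planted, at the simulator's noise
model. What it cannot show: behavior under real 454 homopolymer errors,
PCR duplicates, repeat-space mappability, or genome-scale contiguity —
none of which the simulator models. The aligner is quadratic in the read
× window size and pure Python/numpy; it is built for method validation
at kilobase-to-megabase scale, not production alignment of full
sequencing runs.
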