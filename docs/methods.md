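# Methods

This note documents the models, conventions and design choices behind
`xenoscan`, and what the synthetic-data validation does and does not show
about real data.

## The detection problem

A horizontally acquired gene in a parasite transcriptome is distinguished
from vertical inheritance and from host contamination by a conjunction of
signals: homology pattern (closest matches in the distant donor clade, none
in the parasite's close relatives), phylogeny (the parasite sequences form a
clade *nested within* the donor clade rather than sister to it), age (the
transfer node dates to a plausible window of host–parasite contact),
constraint (ω = dN/dS well below 1, indicating a functional protein),
structure (intron position and splice sites conserved with the donor
lineage; the protein fold's diagnostic residues intact), and expression
(stage-structured transcription in the parasite). The package computes each
signal separately so their evidence can be weighed explicitly.

## Screening cascade

The translated search scores the best local alignment over all 36 frame
pairs of query and subject under BLOSUM62 with affine gaps (a gap of length
k costs 11 + (k−1)). Raw scores S become bitscores
S′ = (λS − ln K)/ln 2 with the standard gapped-BLOSUM62 constants
λ = 0.267, K = 0.041, and e-values E = m·n·2^(−S′) with m the query and n
the database amino-acid lengths. These e-values are a ranking and cutoff
device (default cutoff 1e−10), not calibrated significance — the engine
makes no attempt to reproduce a production search tool's heuristics. A
shared-word prefilter (word size 5 by default) skips frame pairs
that cannot align well; at the identity levels the cascade accepts
(≥ 60 %), a shared 5-mer exists with probability ≈ 1.

Cascade conventions, fixed here: identity bounds are inclusive [60, 95] %;
contig length is strictly > 500 nt; the aligned-length rule uses the top
donor hit's query nucleotide span (single alignment, not summed segments);
stage 4's "much weaker close-relative hit" is quantified as a bitscore ratio
(best donor / best close relative, default ≥ 1.2) because bitscores are
length-normalized and monotone in e-value. Hits are ordered by bitscore
desc, e-value asc, subject id — a deterministic tiebreak. The report's
"initial" funnel count combines stages 1+2, mirroring how such screens are
conventionally reported.

## Phylogenetics

Distances: JC (d = −¾ ln(1 − 4p/3)) or K2P, pairwise deletion of gap/N
columns; p ≥ ¾ is flagged saturated rather than extrapolated.
Neighbor-joining uses the standard Q-criterion with negative branch
estimates clamped to 0 and ties broken by the lexicographically smallest
label pair, so reruns are identical. Likelihoods use Felsenstein pruning
under GTR (exchangeabilities + frequencies, rate matrix normalized to one
substitution per site per unit branch length), with gaps/N as missing data;
an optional 4-category discrete-gamma model (mean-normalized category rates)
sits behind a flag and defaults off. The pruning implementation is verified
against exhaustive summation over internal-node states on small trees.

Topology tests are RELL: per-site log-likelihoods are resampled with
replacement without re-optimizing branch lengths. KH compares each topology
with the ML topology through the centered bootstrap distribution of the
log-likelihood difference (one-sided); SH compares against each replicate's
maximum over per-topology centered sums. Site columns are put in a canonical
(lexicographic) order before resampling, which makes the p-values exactly
invariant to input site order. Defaults: 1000 replicates, seed-controlled.

Dating is strict-clock mean-path-length: each node's depth is the mean path
to its descendant tips, a single calibration node (default 39 My, the donor
clade crown) sets the global rate, and ages are depth/rate. The calibration
is used as a point value; its published uncertainty (±2.4 My) is carried in
configuration but not propagated. Parent-younger-than-child conflicts are
clamped with a warning, and the coefficient of variation of root-to-tip
distances is reported as a clocklikeness diagnostic. This is a deliberately
deterministic, oracle-checkable surrogate for Bayesian relaxed-clock
dating; no topology search or MCMC is performed anywhere in the package.

## Selection

NG86 counting: each codon position contributes a synonymous-site fraction
equal to the fraction of its non-stop single-nucleotide mutations that
preserve the amino acid (mutations to stops are excluded from both the
denominator and the numerators — one of the standard conventions, fixed
here), so S + N = 3 per codon. Multi-difference codon pairs are averaged
over all orderings of the minimal mutational pathway that avoid stop
codons; if every ordering hits a stop the codon pair is skipped with a
warning. Proportions pN = Nd/N and pS = Sd/S are Jukes–Cantor corrected;
ω is undefined when dS = 0 or a proportion is saturated.

Two estimator properties worth knowing. First, pathway averaging can
attribute fractional nonsynonymous counts to codon pairs whose true history
was purely synonymous (e.g. TTA→CTC has one all-synonymous and one
all-nonsynonymous ordering), so Nd > 0 does not by itself prove an amino
acid ever changed; under a frozen protein the resulting ω stays ≈ 0.
Second, NG86's equal-opportunity site counting ignores the
transition/transversion bias; with κ = 2 the method underestimates ω by
roughly 15 %, which is why parameter-recovery checks are run at the
generator's κ and judged at ±25 %, while the exact-consistency check is run
at κ = 1.

Per-branch counts reconstruct ancestral states position-wise by parsimony
with *exact* averaging over all maximally parsimonious reconstructions: an
inside–outside pass over unit-cost Sankoff tables yields, for every branch,
the joint distribution of (parent, child) states under uniform weighting of
optimal reconstructions; the three positions are independent under that
weighting, so codon-level expected (Nd, Sd) follow by enumerating the
product support with the same pathway-averaging classifier. Pools sum branch
counts (double assignment is an error); pooled rates use alignment-mean
NG86 site counts.

The per-site constraint score is this package's own statistic:
ln(expected_N / (observed_N + ½)), with the expectation proportional to the
column's nonsynonymous opportunity and the alignment-wide nonsynonymous
rate, and a consensus-cysteine flag. It is a counting analogue of site-wise
constraint analysis, not an empirical-Bayes posterior: it ranks constrained
columns when the background tolerates nonsynonymous change, and loses
discrimination when the whole alignment is strongly conserved (then most
columns have observed_N = 0 and differ only by opportunity).

## Gene structure and the scaffold score

Intron inference assumes the single-intron gene model (the case this
pipeline targets): it enumerates all splits cds = prefix + suffix with
genomic = prefix·intron·suffix (up to a configurable number of exonic
mismatches), preferring GT..AG-canonical solutions and then the longest
prefix. Shift-ambiguous boundaries therefore resolve to a canonical intron
whenever one exists. Coordinates are 0-based half-open internally and
1-based inclusive in GFF3 output, with CDS phase per the GFF3 convention.

The cysteine scaffold score is an original rule-based statistic for the
six-cysteine KNOTTIN-style fold: subscores for the exact cysteine count
(weight 10), each of the five inter-cysteine loop lengths inside windows
derived from a packaged profile alignment (weight 2 each, windows = profile
min/max ± 2), and the absence of a terminal cysteine (weight 1); the pass
threshold of 18 requires the full count plus at least four loops in window.
The packaged profile (`data/albumin1_synthetic.faa`) is a synthetic
albumin-1-like sequence set with family-typical spacing, not curated data,
and the score's numeric scale is not comparable to any external predictor.
Calibration is by permutation control: shuffling a passing sequence
preserves its cysteine count but destroys the spacing, and ≥ 95 % of
shuffles must fail.

## Expression

RPKM = 10⁹ · count / (gene length · library size), with the library size
taken as *mapped* reads per stage. The naive mapper counts a read for a gene
if it matches a window on either strand within the mismatch budget
(default 0, implemented as window hashing); reads tied across genes are
discarded as ambiguous rather than fractionally assigned, and the ambiguous
count is reported. Fold summaries flag zero-minimum profiles as infinite
rather than dividing.

One composition effect matters when validating fold recovery: libraries
sample a fixed number of reads, so a gene's count share is its fraction of
the whole transcriptome pool. A 1000:1 RPKM profile is recovered in counts
only if the gene stays a minor share of every library; otherwise the
changing denominator compresses the realized fold. The default scenario
therefore gives the 50 background families a flat 100-RPKM expression so the
two-copy xenolog family stays a small fraction at all stages — emulating a
two-contig family inside a whole-transcriptome library — and even so the
realized fold (~600–900 across seeds) modestly undershoots the 1040:1
profile ratio; the validation checks agreement within the binomial
sampling envelope, not a point value.

## Synthetic data: what it does and does not emulate

The generator builds random ultrametric (pure-birth-shaped) donor and
parasite clades, attaches the parasite gene clade inside the donor clade on
a designated donor lineage at the transfer age (default 16 My), adds one
duplication (5 My) in the first parasite subclade, and roots with an
outgroup (50 My). Sequences evolve by per-branch transition matrices
(matrix exponentials) — exact and fast, no event-level simulation — under
HKY (nucleotide) or an MG94-style codon model whose instantaneous rate is
π_target · κ^[transition] · ω^[nonsynonymous] for single-nucleotide codon
changes and 0 otherwise, so simulated CDSs never gain internal stops. All
ω-class matrices share one scale (neutral class = 3 substitutions per codon
per unit), so constrained classes genuinely evolve more slowly. Defaults:
rate 0.006 subs/site/My, κ = 2, uniform base frequencies, ω classes
(0.1: 60 %, 0.5: 30 %, 1.0: 10 %) plus a pinned ω = 0 class for the six
designated cysteine codons. Background families get a close-relative
ortholog at 5 % divergence and a donor homolog at 35 %, so they fail the
cascade by construction; contig lengths (240–1500 nt) deliberately include
sub-500-nt contigs to exercise the length filter.

What passing on this fixture does **not** show: robustness to assembly
artifacts, chimeric contigs, indels and alignment error (no indel
evolution), host contamination (no contamination model), heterotachy or
rate variation across lineages, multi-intron genes, or read errors and
quality scores (reads are exact substrings unless a mismatch fraction is
configured). Results on real transcriptomes depend on those factors and on
reference-panel composition.

## Reproducibility and problem sizes

All randomness flows from one integer seed through named substreams
(seed × CRC32(name)), so stages cannot perturb each other and identical
seeds give byte-identical reports. Default validation sizes, chosen to keep
the full suite in the low minutes on one core: 50 background families + 1
planted xenolog (screen), 10 kb alignments for dating and ω recovery,
2000 codons for pooled counts, 200 simulated datasets × 500 RELL replicates
for topology-test calibration, 200–500 intron round-trips, 1000 scaffold
permutations, and 50 000-read stage libraries.
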