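# Methods

## Scope and data model

The package characterizes a pair of annotated, circular mitochondrial
genomes. Coordinates are 1-based and inclusive throughout, exactly as
annotation tables print them; no annotated feature wraps the origin, but the
molecule is circular wherever that matters (region extraction, gap
inference, gene-order adjacency). Annotations enter as a nine-column TSV
(Type, Name, Starts, Stops, Length, Strand, Anticodon, StartCodon,
StopCodon), as a GenBank flat file restricted to simple single-interval
locations (`join()` raises an explicit error rather than guessing), or as
the packaged transcriptions of the published *M. senhousia* tables. The
genetic code defaults to NCBI translation table 5 (invertebrate
mitochondrial) and is configurable everywhere it is used.

Codon counting includes the terminal complete stop codon — the published
per-gene residue counts equal span/3 with the stop included — and a span of
3n+1 or 3n+2 nucleotides ends in an incomplete stop codon (tokenized `T--`)
that is excluded from the codon list; this reproduces the printed 588/583
residue counts for the two nad5 genes from their 1,765/1,750 nt spans. An
`exclude_stops` switch restores stop-free counts.

## Unassigned regions

URs are maximal runs of positions covered by no gene, tRNA or rRNA,
computed on the circular genome; the run spanning the origin is one region,
numbering restarts after the feature covering position 1, and the single
longest region (ties to the smaller start) is the LUR. The minimum reported
gap defaults to 2 nt: both published genomes leave exactly one 1-nt gap
(between trnR and trnS(AGN)) unannotated while annotating every gap of 4 nt
and above, so single-nucleotide gaps are treated as annotation slack. With
this default the inference reproduces the printed censuses exactly
(29 + LUR regions / 6,798 nt in F; 27 + LUR / 4,296 nt in M); `min_gap=1`
is available and is what the coverage-conservation identity
(spans + gaps − overlaps = genome length) holds under.

tRNA clusters are maximal circular runs of ≥ 2 tRNAs interrupted only by
(non-LUR) URs; any gene, rRNA or the LUR breaks a run. Tolerating
arbitrarily long URs inside a run while letting the LUR break it is the only
reading consistent with both published cluster censuses (20-in-5 for F,
19-in-5 for M, with trnE stranded beside the male LUR).

For the upstream-hairpin survey, a protein gene qualifies when the nearest
upstream gene-like feature — skipping small URs, with the LUR acting as a
non-tRNA breaker — is not a tRNA, and non-coding sequence actually precedes
the start codon. Applied to the packaged annotations this yields exactly the
seven genes per genome the publication lists as hairpin-preceded. The scan
window covers the intervening non-coding stretch up to `window` nt (default
60) before the start and 20 nt into the gene, so structures containing the
initiation codon are caught and flagged.

## Composition and skew

Strand statistics follow the H-strand convention: GC skew = (G−C)/(G+C),
AT skew = (A−T)/(A+T). IUPAC ambiguity symbols are excluded from numerators
and denominators. Profiles built from printed percentage rows keep the
printed values as percentages (they are already normalized, up to printed
rounding) rather than renormalizing by their imperfect sum; the accepted
drift from 100 is 0.75, since published rows sum to anywhere between 99.4
and 100.1. Reported rounding is 1 decimal for percentages and 2 for skews;
the objects retain full precision.

## Codon-usage statistics

All statistics derive from a stop-inclusive 64-codon count table (the
published totals, 3,792 and 4,098, are stop-inclusive). The NNT:NNC ratio is
computed over families whose U-ending and C-ending codons are synonymous
under the configured code — all 16 under table 5 — with percentages of the
full codon total, matching the published 44.7%/9.3% convention. Degeneracy
classes (2FD/4FD/mixed) derive purely from the code. Anticodon matching is
deliberately wobble-free: each tRNA's anticodon is reverse-complemented to
the codon it reads exactly, and that codon is compared with the modal codon
of its synonymous set; ties break lexicographically and are flagged.

## Divergence estimation

p-distances use pairwise deletion of gap columns and a site-bootstrap
standard error (default B = 1000 column resamples; the replicate count the
original analyses used is unstated, so 1000 is the documented default). The
seed is a mandatory argument: there is no hidden global randomness.

Ks/Ka uses the modified Nei–Gojobori method. Potential sites: at each codon
position the transitional change carries weight R/(R+2) and each
transversional change 1/(R+2); changes creating stops are removed and the
remaining weights renormalized, so each codon contributes exactly 3 sites
split between synonymous and nonsynonymous. R defaults to 2.0 — the value
the original analyses used is unprinted, so no test asserts an R-sensitive
published number. Observed differences: codon pairs differing at k
positions are averaged over all k! minimal substitution pathways with equal
weight; pathways through stop codons are excluded, and a pair with no
surviving pathway is dropped from both difference and site totals (and
counted). Codons containing gaps, ambiguity symbols or stops in either
sequence are excluded pairwise. Proportions are corrected with
d = −(3/4)·ln(1 − (4/3)p); p ≥ 0.75 is reported as a saturation marker
(None), and Ka/Ks is defined only when Ks > 0. At R = 1 the site counting
reduces to the classic unweighted method, which is how the tests
cross-check it against a brute-force enumerator.

Alignment is an input, not a service: homologous genes are paired by name
(plus an explicit map for duplicated copies, e.g. male cox2b against cox2),
and genes with unequal codon counts are listed as needing an external
alignment rather than silently aligned. For synthetic data the true
alignment is known by construction.

## Non-coding structure

Hairpin detection is purely complementarity-based (no free-energy model): a
hairpin is a pair of arms, each the reverse complement of the other under
Watson–Crick pairing (G·U and an arm-mismatch budget are opt-in), flanking
a loop. Defaults: stem ≥ 5 bp, loop 3–30 nt, no mismatches. All maximal
structures are reported — maximality means the stem cannot be extended
outward — and "length" in reports means the full span 2·stem + loop, with
stem and loop also emitted. The finder is exhaustive over loop placements
and is tested for exact agreement with an independent triple-enumeration
oracle.

Tandem repeats are found by self-comparison: exact 13-mer matches propose
candidate periods d; each is extended while the running mismatch fraction
stays within `max_divergence` (default 0.05, so 0.4%-diverged repeat copies
merge while ~45%-diverged subregions do not). Because the running-ratio
budget accumulates slack over a long low-divergence array, the raw
extension ends can wander into flanking sequence; both boundaries are
therefore refined by a maximum-likelihood change point contrasting match
densities of ~0.95 inside the array versus 0.25 outside (30 nt windows,
expectation-padded at sequence edges). Among candidate arrays, the longest
span wins, with the fundamental period preferred over its harmonics within
a 25 nt span tolerance and remaining ties going leftmost. The refined span
is cut into full units of length d plus a trailing truncated unit of
≥ 10 nt. Unit p-distance matrices require pre-aligned (equal-length) units;
truncated units are excluded from the matrix. Subregion labelling across
genomes is by user-supplied motif anchors, not automatic synteny, since the
reference decomposition was defined by inspection.

## Synthetic paired genomes

The generator emulates the study system's statistical structure: the
F-genome feature skeleton (gene order, UR layout, tRNA anticodons) scaled
1/4 by default for fast tests (scale 1 mirrors real lengths), target
composition (39.3, 12.0, 27.2, 21.4)% (T, C, A, G), whole-proteome
divergence targets Ks 0.716 / Ka 0.143, a control region with two 540 nt
repeat units at 0.4% divergence plus a 17 nt truncated unit and two planted
8/5 stem/loop hairpins, a duplicated male cox2 copy extended by 123 nt
in-frame, and an incomplete `T--` stop on nad5. All values are configurable.

Coding sequences are sampled codon-wise from a distribution over sense
codons fitted by iterative proportional fitting so that each codon
position's base marginals equal the target composition; start codons are
ATG/ATA and stops TAA/TAG, as annotated in the real pair. Divergence is
planted on the estimator's own scale: targets are Jukes–Cantor-inverted to
per-site proportions of the modified Nei–Gojobori site counts (R = 2), and
single-base codon changes — proposal bases drawn from the target
composition, at most one hit per site, never creating stops or
stop-locked pathway pairs — are accepted while the pathway-averaged
difference counts against the original sequence move toward those targets.
Scoring realized divergence with the method's own pathway averaging is what
makes recovery tests calibration tests rather than circular identities: the
estimator still has to redo site counting and pathway averaging from raw
sequence, and measured bias at Ks ∈ {0.3, 0.7, 0.9} stays below 0.01
against a 0.05 acceptance band. The planted changes are then split between
the lineages a whole codon at a time (coin flip per codon), so each lineage
carries about half the divergence while the pairwise difference set equals
the planted set exactly — independent half-rate evolution of the two
lineages would collide at the same sites often enough at deep Ks to bias
pairwise divergence measurably low.

What the generator does not emulate: indels and rearrangements (the true
alignment is ungapped by construction), transcription/replication
asymmetries beyond composition, heteroplasmy or population sampling, tRNA
secondary structure (tRNA spans are composition-matched random sequence),
and realistic rRNA content. Passing recovery tests therefore demonstrates
estimator correctness and calibration under substitution-only divergence
with known homology — not robustness to alignment error or structural
variation in real data.

## Numerical and reproducibility choices

Every stochastic operation takes an explicit seed; one `numpy` generator
drives a simulation, and identical configurations yield byte-identical
outputs. Ranking ties break lexicographically and are flagged. Reporting
rounds at the reporting layer only. Problem sizes in the test suite —
40 random 160 nt sequences for the hairpin oracle, 50 random tables for the
occupancy oracle, 20 seeds per divergence regime at 300 codons, 100 planted
arrays for the recovery rate — were chosen as the smallest sizes at which
the checks are statistically meaningful, and the suite runs in well under a
minute.

## Known limitations

The gene-boundary comparison treats orders as circular by default (a flag
forces linear); whether the reference comparison did is unstated. The
published rrnS lengths disagree between running text (819/1,087 bp) and the
annotation tables (818/900 bp); the fixtures follow the tables and the
discrepancy is surfaced here rather than resolved. The published F codon
total likewise appears both as 3,792 (table sum) and 3,794 (text); fixtures
carry the table counts and the annotation-derived total is 3,794, with each
test asserting against its own source. Anticodon matching ignores wobble by
design and says so in its output; repeat decomposition assumes ungapped
arrays (no indel drift between units); hairpin calls are complementarity
statements, not stability predictions.
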