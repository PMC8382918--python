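# Methods

`htt` detects horizontal transfer (HT) of transposable elements (TEs)
between diverged plant lineages from low-depth "sample sequence" data:
unassembled single-end shotgun reads (~151 bp, ≥100 bp after trimming,
~2.3× coverage) from candidate donor lineages, compared against assembled
recipient genomes. The governing idea is a divergence contrast: sequences
inherited vertically from the donor/recipient common ancestor sit near the
speciation-level identity (here ~86%), while a recently transferred element
is far more similar (>97%) in both lineages. Everything in the package
serves to measure that contrast reliably and to turn raw high-identity
matches into a defensible count of independent transfer events.

## Detection model and thresholds

**Targeted track (LTR-retrotransposons).** Reads carrying a reverse
transcriptase (RT) domain are isolated by profile scanning, clustered by
sequence similarity, and each cluster representative is searched against
the recipient genomes. The top 3 homologies per genome with >85% identity
over ≥140 bp seed a 10-kb-flanked window; all sample reads are mapped onto
the window and pruned to best-nonoverlapping hits (≥100 bp matched, ≤75 bp
overlap, overlap boundary inclusive). The window is structurally annotated
(domains + LTR pair), and an HT is called iff ≥10 distinct reads hit
within the element at an unweighted mean identity >97.0%. Hits wholly
outside the element must not show elevated identity; windows that do are
flagged (`elevated_flank_identity`), since a transfer moves the element,
not its flanks.

**Nontargeted track (any sequence).** Reads are chopped to 50-bp pieces
and placed end-to-end with ≤3 mismatches — an exact 94% identity floor.
Mapped intervals chain into dense regions (gaps <150 bp, union of covered
bases >500 bp, both inequalities strict as stated); regions matching
organelle/rRNA/conserved-gene exclusion sets (≥50% of bases at >85%
identity) or ≥50% low-complexity windows (mononucleotide entropy <1.5 bits
or dinucleotide entropy <2.5 bits) are removed. Full-length reads are then
re-mapped onto each 20-kb-flanked candidate window, and a call requires
reads above the identity threshold (default 97%) to cover >500 bp of the
region's neighbourhood (±2 kb; high-identity sequence elsewhere in the
window does not accrue). `threshold_sweep` re-counts calls computed at the
loosest threshold at 94/97/100%, and is nonincreasing by construction.

**Identity semantics.** Local alignment reports the maximal-scoring
segment, which trims mismatch-dense read ends and therefore overstates
identity on diverged sequence by ~2 points at 14% divergence (the same
bias affects BLAST HSPs; we verified it with blastn on simulated reads).
Where identity is a *divergence estimate* — the CDS calibration histogram
and the nontargeted ≥97% read screen — the package therefore scores
identity over the full read span (`align.full_span_identity`), extending
the placement ungapped to the read ends. Where identity is part of the
published hit-selection arithmetic (targeted mean-identity rule, the
85%/140-bp seeding rule), the HSP identity is used as is.

## Alignment engines

`local_align` is a seed-and-extend local aligner: exact 11-mer seeds are
grouped into diagonal bands; single-diagonal bands get an exact
maximal-scoring-segment (Kadane) ungapped extension, and bands whose seeds
straddle diagonals — the signature of an indel — get a full gapped local
DP on the candidate subwindow (Biopython's PairwiseAligner with the same
scoring). Scoring is +1/−2 with BLAST-style affine gaps 5+2g, chosen so a
score of 60 ≈ 60 bp of matched sequence, consistent with the 100–140 bp
matched-length floors. E-values follow Karlin–Altschul with λ solved
numerically for the score scheme, K = 0.3 (conventional; at score >60 the
e-value cut of 1e−8 is far from binding), and the effective search space
frozen to the supplied target set. `single_hsp` keeps the best HSP per
query–target pair (used for read mapping); genome-scale homology searches
run multi-HSP so each element copy on one contig surfaces as its own hit.
`map_kmismatch` uses pigeonhole seeding (k+1 exact pieces) with vectorized
verification and reports every qualifying placement on both strands.

## Domain profiles

Domain models are ungapped position-specific score matrices (log2-odds
against a uniform amino-acid background, additive pseudocount, >50%-gap
columns dropped) scanned over all six reading frames — a deliberate
simplification of profile HMMs that costs little on ≤50-aa read
translations; HMMER domain tables can be imported instead. Stop codons
score −∞ in read scanning, where they discriminate the coding frame, but 0
(like X) in contig annotation, where aged elements legitimately accumulate
nonsense substitutions and one stop must not erase a domain. Each profile
carries two thresholds calibrated on random sequences to ≤0.1% FPR, with a
floor at 0.35 of the attainable consensus score — needed because a 20-kb
window offers tens of thousands of candidate positions, where a per-window
quantile alone produces spurious blocks. The shipped profiles for
gag/AP/IN/RT/RH are *synthetic* stand-ins built from simulated variants of
fixed random consensus proteins (the RT consensus carries the conserved
YXDD motif); they match the simulator's planted elements and must be
replaced by curated profiles for biological work.

TE annotation chains domain occurrences into blocks (gaps ≤3 kb) and
delimits the element by the best pair of flanking direct repeats (≥100 bp
at ≥85% identity within 2.5 kb of the block) — the two LTRs. A block
without a detectable LTR pair is still reported, flagged incomplete.

## Event inference

Elements are clustered by explicit single-linkage over identity/coverage
edges (≥90% identity over ≥55% of the shorter sequence; thresholds mirror
documented similarity-based read-clustering defaults and are exposed).
Calls in one cluster merge into one event iff they share the donor taxon
and their recipients group in one clade of the cluster tree, or share the
recipient taxon and their donors form one clade; a clade is any
bipartition side whose taxa are exactly the focal pair, so recipients
nested inside the donors' subtree still leave the donor pair as the
complement side. The relation closes transitively. Without a tree the rule
degrades to same-cluster + shared-taxon and events are flagged unverified.
The minimum event count is one event per HT cluster plus one per
singleton.

Transfer direction comes from the nesting test: recipients nested in
donors iff the recipient leaves form one side of an edge while donor
diversity straddles its attachment point (an internal edge of the
complement with donors on both sides). When the structural reading holds
in both directions, the deeper lineage (larger within-set patristic
distance, ratio ≥1.5) is taken as the surrounding one — a relative
molecular clock: a recent transfer leaves the recipient family shallow.
Balanced splits stay `not_nested`.

Activity histories run UPGMA on identity distances (d = 100 − %identity);
node height = merge distance / 2 (per-lineage divergence; the raw merge
distances are kept alongside since the halving convention is a choice),
histogrammed at 1% bins — n−1 nodes, heights monotone by average-linkage
reducibility.

## Junction verification

An integrated LTR element begins TG and ends CA; integration duplicates
4–6 bp of target site (TSD, default search window 4–6 bp — the
LTR-retrotransposon norm; assigned to the flanks, not the element).
`junction_support` counts reads spanning each junction with ≥20 aligned bp
on both sides. `ortholog_presence` anchors the element's 1-kb flanks in
other genomes (>80% identity), calling the element present (aligns between
anchors at >85% over >50% of its length), absent (anchors adjoin with <10%
of the element length between them; small anchor overlaps up to 50 bp are
tolerated — both anchors cover the single target site when the carrier has
a TSD), or unresolved. This is flank-anchored pairwise comparison, not
whole-genome synteny.

## Synthetic data: what it does and does not emulate

`build_ht_scenario` plants ground truth exactly: an ancestor background
(default 100 kb) carries a structurally canonical 5-kb element (300-bp
identical LTRs, coding domains); the recipient background diverges by
exactly 14% (substitution-only, exact counts, so orthologous identity is
86% by construction); one element copy crosses at 1.5% divergence and two
amplified copies add 0.5% each — emulating post-transfer amplification
with 98.9–100% homolog identity. Reads are ~2.3× single-end, 151 bp with
40% quality-trimmed to 100–150 bp: fully fixed-length reads place identity
values on a ⅔%-lattice that destabilizes the histogram's modal bin, and
length variation is what real trimmed data shows. `build_vertical_scenario`
is the matched no-transfer control (the same element inherited vertically,
or donor-only).

Not emulated: sequencing error, indel mutation (parameter exists, default
0), paired ends, realistic repeat landscapes, assembly artifacts, or
multi-contig genomes. Passing the planted-recovery study therefore shows
the detection logic and thresholds behave as designed under the stated
divergence contrast — not that the pipeline is robust to assembly noise or
repeat-rich backgrounds; on real data the exclusion filters and curated
profiles carry that weight.

## Numerical choices

Deterministic tie-breaks throughout: NJ pairs and UPGMA merges by smallest
contained leaf label; best-nonoverlapping hits by score, then length, then
start, then query id; cluster ids by descending size then smallest member.
Negative NJ branch lengths clamp to 0 with a warning. Histogram peak ties
resolve to the lowest-identity bin (conservative, older divergence).
Windows truncated at contig edges proceed with a warning. All simulation
randomness flows from `numpy.random.default_rng` seeded per stage; the CLI
fans one global seed out by stable hashing.

## Test-suite problem sizes

The planted-recovery study runs 20 seeds of the default 100-kb scenario
(60 planted copies) for both tracks plus CDS calibration, with the
calibration peak and tail computed on hits pooled across seeds (~5,400
hits; single-seed modal bins wobble by a bin or two at ~270 hits). The
vertical-only false-positive control runs 50 simulations at 30 kb. The
whole suite completes in a few minutes on one CPU.
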