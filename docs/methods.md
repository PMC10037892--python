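# Methods

This document describes the models and algorithms implemented in
`karyopaint`, the default parameter values with their rationale, and the
numerical and design decisions that are open to revision.

## 1. Oligo mining (`karyopaint.mining`)

Probe homology segments are 39-mers mined greedily left-to-right along each
scaffold. A candidate is accepted if it passes all of:

| constraint | default | units | rationale |
|---|---|---|---|
| melting temperature | 42–47 | °C | hybridisation temperature window for 39-mers in the standard formamide buffer |
| GC fraction | 0.20–0.80 | — | excludes composition extremes with unreliable thermodynamics |
| k-mer uniqueness | max count 5 for k = 18 | — | removes repeat-derived segments; counts are over canonical (strand-collapsed) 18-mers of the whole genome |
| hairpin ΔG | ≥ 0 at 42 °C | kcal/mol | no favourable secondary structure at the hybridisation temperature |
| masking | none | — | candidates may not contain N or softmasked (lowercase) bases |

Mining is greedy leftmost-first with a minimum spacing (default 0) between
accepted candidates; after a masked base the scan resumes past the mask.
Runs of N break k-mers during genome counting; softmasked bases still count
(masking states repeat *annotation*, not absence of sequence).

## 2. Thermodynamics (`karyopaint.thermo`)

Nearest-neighbour duplex thermodynamics use the unified DNA NN parameter set
(ΔH in kcal/mol, ΔS in cal/mol/K) with terminal initiation terms for
G·C and A·T ends. Melting temperature:

* Tm = ΔH / (ΔS' + R ln(CT/4)) − 273.15, with R = 1.987 cal/mol/K;
* salt-corrected entropy ΔS' = ΔS + 0.368 (N−1) ln[Na⁺] (N = sequence
  length); defaults [Na⁺] = 390 mM, each strand at 25 nM (CT/4 for
  non-self-complementary duplexes);
* formamide lowers Tm linearly, 0.72 °C per percent (coefficient
  configurable).

The implementation reproduces Biopython's `Tm_NN` (same parameter set and
salt correction) to ≈1e-13 °C; the tests use Biopython as an independent
oracle but the package computes Tm itself so that duplex and hairpin ΔG use
the identical tables.

Dimer ΔG (`duplex_dg`) scores every gapless antiparallel pairing of two
strands: for each alignment offset, every maximal complementary run of
length ≥ 2 is evaluated with both-terminal initiation, at the evaluation
temperature (entropic terms scaled by T/310.15). Hairpin ΔG enumerates all
stem pairs (i, j), extends the stem maximally, adds one open-end initiation
and an entropic loop penalty from a tabulated loop-size table
(Jacobson–Stockmayer extrapolation beyond 30 nt). Both are exact
brute-force evaluations — pool sizes are small enough that no heuristic is
needed, and the tests hold them equal to independent oracles.

## 3. Probe allocation and window placement (`karyopaint.design`)

Each probe is a window of `n_oligo` (default 1500) mined 39-mers.
Allocation assigns probe counts per scaffold under per-library capacity
(default 92,000 oligos, 3 libraries):

* the longest scaffold gets `max_count` (default 5) probes, capped so the
  rest remain feasible;
* scaffolds suspected of mis-assembly get 4 (extra probes localise the
  breakpoint);
* remaining scaffolds get tiered counts — either an explicit
  `tier_sizes = (n₃, n₂, n₁)` or the lexicographically maximal
  (total, n₃, n₂) filling of the budget. Tier sizes are accepted
  explicitly because a desired tiering is generally *not* the max-fill
  solution: max-fill can produce totals that cannot be packed into the
  per-library pools (the partitioner then raises).
* scaffolds are partitioned into libraries greedily, longest first onto the
  least-loaded pool.

Windows are placed by dynamic programming: candidate windows are all runs
of `n_oligo` consecutive candidates; the DP picks one window per probe
minimising, lexicographically, (sum of squared deviations from ideal
evenly-spaced centres, total spacing variance within windows), subject to a
minimum inter-window gap and a minimum distance from scaffold termini.
If the terminus constraint makes placement infeasible it is relaxed to 0
with a logged warning (a probe near an end is better than no probe). A
prefix-minimum formulation keeps the DP O(probes × windows).

`scaled_geometry` shrinks the default gap/terminus distances for short
scaffolds (gap capped at L/(3·n_probes), terminus at L/20) so toy-scale
inputs remain feasible with the same code path.

## 4. Orthogonal barcodes, roles, colours, assembly

Barcodes start as synthetic 25-mers (pool generator enforces uniqueness and
GC 0.2–0.8); each 25-mer yields six 20-mers by sliding a 20 nt window
(offsets 0–5), so 240,000 25-mers give 1,440,000 candidate 20-mers.

**Genome homology screen.** Each 20-mer is scored against the genome with a
seeded ungapped aligner (match +1, mismatch −2, both strands; seed word
size 6 by default). Significance uses Karlin–Altschul statistics:
E = K·m·n·exp(−λS) with λ solved from Σ pᵢpⱼ exp(λ sᵢⱼ) = 1 (brentq) and
K = 0.621. Sequences with E **below** the cutoff (default 25) are removed —
more significant than the threshold means too genome-like. Two exactness
bounds justify the seeding: a 20-mer alignment scoring ≥ 12 must contain a
6-base exact run, and one scoring ≥ 8 must contain a 4-base run; so word
size 6 is exact above score 12 and word size 4 above score 8. The default
cutoff is calibrated to genome scale; against toy genomes every random
20-mer is "significant" at 25, so toy-scale runs must pass a
scale-appropriate cutoff (e.g. 1e-2).

**Dimer filter.** Greedy in input order: a sequence is kept if its
self-dimer ΔG and its cross-dimer ΔG against every already-kept sequence
are ≥ `dg_min` (default −9 kcal/mol at the working temperature).
Self-complementary 20-mers always fail (perfect self-duplex). Greedy
rather than maximum-independent-set: deterministic, order-stable, and the
pool is large relative to demand.

**Roles.** Surviving barcodes become reverse primers (preferring a 5′ GC
clamp — ≥ 2 G/C among the three terminal bases), colour adapters
(preferring clamps at both ends) and forward primers (preferring a 3′
clamp). Reverse primers are unique within a library and reused across
libraries (they index scaffolds within an amplification pool). Detection
oligos are the reverse complements of the adapters.

**Colours.** Three fluorophores give six colours (three singles, three
pairwise combinations). Each scaffold in a pool receives a distinct ordered
colour pattern along its probes (capacity 6ⁿ for n probes); repeats across
pools are permitted but reported.

**Assembly.** Each library oligo is
`reverse(20) | homolog(39) | forward(20)` = 79 nt. For two-fluorophore
probes the two forward primers alternate oligo-by-oligo so both colours
tile the window evenly. Amplification primers: reverse = T7 promoter
(33 nt) + reverse complement of the reverse 20-mer (53 nt total);
forward = adapter + forward 20-mer (40 nt); detection oligo = reverse
complement of the adapter (20 nt).

## 5. FISH-guided curation (`karyopaint.curation`)

Observations are per-spread records: probe id, chromosome label, rank from
the centromere along an arm, arm side (p/q), colour. Curation proceeds:

1. **Assignment** — probes vote across spreads; a probe needs `min_spreads`
   (default 2) concordant spreads; observations whose colour contradicts
   the design are discarded with a warning; a probe's order is the median
   rank.
2. **Anomaly detection** — within each scaffold, probe placements are
   compared against design order on a per-arm linearised axis: p-arm ranks
   map to (0, −rank), q-arm/unknown to (1, rank), because ranks restart at
   the centromere on each arm. Statuses: `clean`, `reversed` (whole
   scaffold descending), `reordered` (non-monotone), `chimeric` (probes on
   ≥ 2 chromosomes).
3. **Breakpoints** — for a chimeric scaffold the flanking probes are the
   adjacent designed probes assigned to different chromosomes. Bounds
   default to the inter-probe interval (midpoint fallback); with
   scaffold-to-reference alignments the interval is narrowed to the last
   position supported by the left chromosome and the first supported by
   the right (`evidence="synteny"`); equal bounds are a point estimate
   when alignment blocks abut exactly.
4. **Split and orient** — chimeric scaffolds split at the breakpoint
   midpoint; each part is oriented by the sign of rank differences along
   the arm axis (`+`, `−`, or undetermined with a warning if mixed;
   single-probe parts are `+` with `low_confidence`).
5. **Build and number** — parts are ordered per chromosome (arm-linearised
   median order); chromosomes are numbered by morphology group
   (acrocentric, submetacentric, metacentric) and decreasing physical
   length, with the X labelled last. Output is AGP v2.1 with U gap rows
   (100 nt, evidence "map") and `scaffold/part` component ids; orientation
   `?` encodes undetermined.

## 6. Synthetic data (`karyopaint.synthetic`)

The generator exists to provide ground truth for parameter-recovery tests,
not to imitate real genomes: uniform base composition, optional exact-copy
repeat families (5–20% of the genome), chosen centromere morphologies
(acrocentric centromeres within 5% of an end). `fragment_into_scaffolds`
cuts chromosomes into scaffolds named by decreasing length, plants chimeras
(one scaffold joining slices of two chromosomes, junction recorded) and
inversions (interval reverse-complemented, strand recorded), and the same
seed reproduces the same cuts so an inverted set differs from its base set
only by the inversion. `simulate_hybridization` is zero-noise by default
(every probe observed on its true chromosome with its true rank), with
optional dropout; `simulate_reference_alignments` emits tiled PAF rows
matching the truth.

## 7. Metrics and synteny (`karyopaint.metrics`, `karyopaint.synteny`)

N50 is the largest length x such that sequences ≥ x sum to ≥ half the
total; L-fraction(f) is the minimal number of sequences covering fraction f
(L90 at f = 0.9). Both are O(n log n) and tested against quadratic
oracles. `relative_lengths` removes per-spread compaction by expressing
chromosome lengths as ratios to the X within each spread, scaled by the
grand-mean X length.

`chain_blocks` merges co-linear PAF records (same query, target and strand,
gap-bounded, target-monotone) into synteny blocks; `classify_rearrangements`
finds all minimal event sequences (inversion, fission, fusion,
translocation) transforming the reference block arrangement into the query
by breadth-first search over canonicalised states (a chromosome equals its
reversed sign-flipped self), refuses instances above 10 blocks, enumerates
scenarios as distinct event-kind sequences, marks chronology as determined
only when a single scenario exists, and flags inversions spanning a
centromere block as pericentric.

## 8. Numerical and design choices, open decisions

* **Hand-rolled aligner instead of blastn.** An external blastn cannot be
  assumed at runtime and its gapped statistics are not reproducible
  in-process; the seeded ungapped aligner with Karlin–Altschul statistics
  is exact for the score ranges the filter acts on (bounds above). Open:
  scores near the seeding bound with word size 6 can be underestimated —
  use word size 4 where exactness matters.
* **E-value filter direction.** "Removed if E < cutoff" is read literally
  (more significant = removed). Open: at toy scale the published default
  removes everything; callers must scale the cutoff.
* **Greedy dimer filter** rather than optimal subset selection: stable and
  sufficient. Open: a pool barely larger than demand could benefit from
  smarter selection.
* **GC clamp** defined as ≥ 2 G/C among the three terminal bases.
* **Explicit `tier_sizes`** because the desired tiering is not in general
  derivable from a max-fill rule under pool capacity.
* **Reverse amplification primer** takes the reverse *complement* of the
  oligo's 5′ 20-mer after the T7 promoter (53 nt total), consistent with
  the stated primer lengths.
* **Gapless alignment** throughout; real scaffold-to-reference alignments
  contain indels, but breakpoint narrowing only uses block boundaries, so
  gapped detail is unnecessary at the resolution FISH provides.
* **AGP gap policy**: U gaps of 100 nt, linkage evidence "map" — the joins
  are evidenced by hybridisation order, not sequence overlap.
* **Midpoint-fallback breakpoints** cannot contain a junction that falls
  *inside* a probe window (rare; ≈ 0.3% per junction at toy geometry);
  synteny narrowing does not have this limitation.
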