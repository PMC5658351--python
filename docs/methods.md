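# Methods

This note documents the models, thresholds and design choices behind
`alfwalk`, the way one would document a simulation or analysis package:
what is computed, under which assumptions, and what the bundled synthetic
data can and cannot show.

## The classification model

A read produced by linear enrichment from a known element is, ideally, the
known element followed by progressively less-known sequence: construct
interior, then the construct/genome junction, then host flank.  The cascade
orders the evidence accordingly and stops at the strongest claim:

1. **Event search.**  A read *confirms an event* when it aligns to an
   event-specific sequence with identity ≥ 95% and the alignment covers
   ≥ 97% of the event sequence.  Coverage is alignment columns over event
   length, so insertions in the read can push it above 100% — intentional,
   since a read carrying the whole event region plus a one-base insertion
   still covers the event.  All qualifying hits are recorded; two disjoint
   hits to the same event sequence are the signature of a tandem ligation
   artifact and are kept, flagged, rather than discarded.
2. **Construct search.**  A read whose best CAF hit covers ≥ 97% of the
   *read* contains only known information; the covered interval is
   annotated with every element feature it overlaps by at least one base.
   The published workflow asks for "complete" alignment; 97% rather than
   100% tolerates a clipped terminal base or two, and the value is
   configurable up to 100.
3. **Element search.**  Remaining reads either contain element homology
   (`unknown_parts` — the UGMO signal) or nothing beyond the primer
   (`only_unknown_information`).  Element hits need identity ≥ 80% over
   ≥ 30 columns: loose enough for residual consensus error and for element
   variants that differ between transgenic lines, tight enough to exclude
   micro-hits.  Overlapping hits are resolved longest-alignment-first
   (a bit-score ranking is available as an option, off by default);
   surviving hits are ordered 5′→3′ and any unaligned stretch of ≥ 1 nt
   between neighbours becomes an `nnn` gap token.  The 1-nt gap floor is
   deliberately conservative: every unexplained base between elements is
   surfaced rather than smoothed over.

Bins partition the representatives: each read is claimed by exactly one
step.  Precedence means an event-confirming read is never re-examined for
construct or element content.

## Alignment engine

All homology decisions use an exhaustive affine-gap local alignment
(match +1, mismatch −2, gap of length k costing 2.5 + 0.5k, minimum
reportable score 20) over both query strands, with coordinates reported on
forward strands plus a strand flag.  N never counts as a match.  Ties are
broken toward the smallest query start, then subject start, then the plus
strand.  The scheme favours long, high-identity hits, which is what the
tiered thresholds consume; the thresholds, not the score scheme, are the
contract, and the test suite pins the engine to an independent
dynamic-programming oracle on hundreds of random sequence pairs.

Multi-hit extraction is iterative: the best hit over all subjects is
claimed, its query span masked with N, and the search repeats, so reported
query spans are pairwise disjoint.  Element-order reconstruction instead
queries each element separately and resolves overlaps by alignment length,
because two element variants may legitimately claim overlapping read
regions and the longer explanation should win.

Tandem repeats (ligation artifacts: the same molecule ligated twice between
sequencing adaptors) are detected by shift autocorrelation: for each
candidate unit length `u`, the read minus its last `u` bases is globally
aligned against the read minus its first `u` bases, with the edit distance
capped at the identity budget.  Shifts small enough that un-shifting the
alignment back onto the main diagonal (cost `2u` indels) would fit inside
the budget are excluded, so a reported repeat is always genuine off-diagonal
self-similarity, and an inverted repeat (a read followed by its reverse
complement) is never reported.  This is equivalent to an off-diagonal
self-alignment at a fraction of the cost.

## Preprocessing

Trimming removes an anchor-adaptor match (20% edit tolerance) anchored at
either read end, together with an adjacent homopolymer run of the tailing
base or its complement when the run is at least 8 nt — long enough to
distinguish the synthetic tail from natural homopolymers.  The 3′ end is
handled by applying the 5′ rule to the reverse complement.  Trimming is
idempotent and never touches interior sequence; emptied reads are left for
the length filter.

The length filter keeps reads strictly longer than 50 nt — shorter reads
cannot be informative when the shortest element in the database is longer.
The Phred ≥ 33 over ≥ 90% quality filter exists for reference-validation
workflows; the main cascade omits it because multi-pass consensus reads are
already high quality.

Primer assignment searches both strands for every nested enrichment primer
within an edit budget of 20% of primer length.  Matches anchored within
10 nt of a read end outrank interior matches before edit distance is
compared: the enrichment primer primes the molecule and therefore sits at an
extremity, whereas a fragment long enough to run through the other target
element contains that element's primer site internally — and tail trimming
can clip a leading base off a primer that begins with the tail base, which
would otherwise let the interior impostor win on edit distance.  Reads whose
primer lies on the minus strand are reverse complemented, so clustering can
compare plus/plus only.

## Clustering

Reads are dereplicated exactly, sorted by abundance (ties: longer first,
then smallest id), and scanned greedily: a sequence joins the first cluster
whose *founding* sequence it matches at global identity ≥ 0.97, computed as
matches over alignment columns of an end-to-end alignment, which penalises
length differences — two nested fragments of very different lengths do not
cluster, by design, because they carry different walking depth.  The value
0.97 is sometimes called a cluster "radius" in the clustering literature
even though it is a minimum identity; it is treated as minimum identity
here.  The read carried into classification is the longest member
(smallest id on ties), not the centroid: the longest read has walked
furthest and is the most informative representative.

## qPCR arithmetic

Relative Cq is `Cq(starting material) − Cq(after step)`; a d-fold
pre-measurement dilution shifts Cq by `log_E d` cycles (E = 2 by default, a
perfect doubling), which is subtracted before comparison.  Rounding follows
the reporting chain conventional in this setting: log-dilution shifts to two
decimals (100-fold → 6.64 cycles), ΔCq to one decimal before
exponentiation, fold changes to three significant figures — so
30.3 / 9.6 / 100-fold gives 2.96, ΔCq 27.3 and 1.65 × 10⁸.  "Beyond
detection" is an explicit state, not a number; it poisons every downstream
value computed from it.  Copy numbers are
`mass_ng · 1000 · fraction / 1C_pg · zygosity`, rounded to the nearest
integer; with 200 ng, 1C values of 2.725 pg (maize) and 2.33 pg (cotton)
and a 0.5 hemizygous factor this yields 35596 copies at 97% and 367/429
copies at 1%.

## The simulator

The generator emulates the whole enrichment + sequencing stack and labels
every read with its provenance, so each pipeline decision can be scored
against truth.

* **Constructs** are host flanks around ordered element tokens (minus-strand
  tokens reverse complemented), with one annotation per token.  The bundled
  scenario has nine synthetic elements (the two enrichment targets carry
  their primer sites internally, downstream sites forward and upstream
  sites reverse complemented) and four constructs: a dominant fully-known
  event identified at its 5′ junction, two minor known events identified at
  their 3′ junctions, and a model UGMO ordered `tNOS – nptII – p35S` with
  20-nt spacers, present only in the element database.
* **The mixture** mirrors an uneven reference set: 97/1/1/1 by mass,
  35596/367/367/429 haploid copies in 200 ng, 411 consensus reads of which
  18 are primer-free background and one is a ligation artifact, read shares
  368:15 between p35S and tNOS and 7:1 upstream:downstream.  Fragment
  counts are apportioned *deterministically* (largest-remainder) across
  reactions by share and across constructs by copy number: counts
  proportional to copies times share is the model, and deterministic
  apportionment keeps 1% components represented at realistic run sizes.
* **Fragments** start at the nested-primer site and extend in the
  enrichment direction with per-base stop probability 0.001 (geometric
  lengths, mean ≈ 1 kb, matching typical subread lengths and reproducing
  the size-dependent enrichment seen by qPCR: targets close to the start
  are covered by many more fragments than distant ones).  Each fragment is
  dressed with the anchor adaptor and a 10–20 nt tail homopolymer — exactly
  what trimming must remove.
* **Subreads** apply independent per-base errors: 10% insertion, 5%
  deletion and 1% substitution (the substitution rate is a package choice;
  published platform characterisations emphasise the indel rates).  This
  gives single-pass identities in the low-to-mid 80s.  Expected subread
  length is 1.05× the template.
* **Consensus** requires ≥ 4 passes.  The subread with the smallest total
  edit distance to the others scaffolds a column-wise majority vote
  (insertions between scaffold columns need a strict majority; ties keep
  the scaffold base).  Residual consensus error therefore *emerges* from
  voting rather than being modelled separately.  Positions with unanimous
  agreement get Phred 40, all others Phred 20 — a deliberately simple
  quality model, sufficient to exercise the quality filter.
* **Seeding.**  Scenario construction and read generation use child seeds
  derived from one master seed via a seed sequence; sharing a raw seed
  between the two would let a background read reproduce construct sequence
  verbatim (both would consume the same underlying draws).  A fixed master
  seed reproduces a run bit for bit.

What the simulator does *not* model: polymerase kinetics, sequence-dependent
error profiles, chimeras other than exact tandem duplication, element
sequence variation between transgenic lines, and host-genome homology to
construct elements (background is uniform random sequence).  Passing the
zero-error recovery tests therefore shows that the workflow logic is
correct, not that the thresholds are optimal for real instrument data; the
noisy-mode tests show the thresholds tolerate the stated error rates, no
more.

## Numerical and procedural choices

* Problem sizes in the test suite and acceptance script: 411-read
  zero-error runs for end-to-end recovery, 60-read noisy runs for the
  clustering contract, 50 replicates of 8-pass consensus on 400-nt
  templates, 500 random pairs (≤ 30 nt) for oracle equivalence.  These
  sizes give stable, reproducible statistics at interactive runtimes.
* Reference merging (suffix/prefix overlap) allows substitutions but no
  indels in the junction and defaults to zero mismatches, configurable;
  two references that genuinely derive from the same construct agree over
  their overlap.
* Equal-length duplicates in element deduplication keep the first
  occurrence; all orderings and tie-breaks in the package are total, so
  every output is byte-reproducible.
* Event templates render unknown runs as N; N scores as a mismatch
  everywhere and never as a match.
* The CLI is a thin layer over the library: `build-db`, `simulate`, `run`,
  `qpcr`, all plain-text in and out, with per-step read counts logged as a
  ledger from input through bins.

## Known limitations

* The element-order string reports one winning hit per read region; nested
  or overlapping element annotations (e.g. a promoter inside a larger
  cassette annotation) are resolved by length, which may hide the shorter
  feature.
* Event coverage is evaluated per hit, not summed across split hits, so an
  event region interrupted by a large insertion will not confirm.
* `only_unknown_information` reads are set aside for manual follow-up; the
  package does not escalate them to external sequence databases.
* The exhaustive aligner is meant for reads against small curated
  databases; genome-scale subjects would need a seeded fast path.
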