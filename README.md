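# alfwalk

Detection and identification of unauthorized GMOs (UGMOs) from
linearly-enriched long reads.

## The problem

Routine GMO screening tests a sample for common transgenic *elements* — the
CaMV 35S promoter (p35S), the nopaline synthase terminator (tNOS), marker
genes such as *nptII* — and compares the detected elements against the
element composition of the GMOs identified in the same sample (the matrix
approach).  Elements that no identified GMO explains point to a potential
unauthorized GMO, possibly one with no published sequence.  Genome walking
from a known element, coupled to long-read sequencing, can recover the
unknown adjacent sequence: single-primer linear enrichment (LE) from p35S or
tNOS produces fragments of various lengths, a homopolymer tail plus anchor
adaptor makes them amplifiable, and circular-consensus sequencing yields
accurate long reads that may run from the known element across the construct
into the host-genome flank.

`alfwalk` implements the desk side of that strategy for analysts who need to
triage such reads quickly:

* **Reference databases** — an *event* database of event-specific junction
  amplicons (assembled from public primer/probe segments with runs of
  unknown nucleotides between them), a *Constructs-And-Flanks* (CAF)
  database of full inserts plus genomic flanks with GFF3 element
  annotations, and an *element* database deduplicated to the longest
  sequence per element.
* **A six-step workflow** — adaptor/tail trimming, a >50 nt length filter,
  an enrichment-primer filter, read orientation, dereplication and greedy
  clustering at 0.97 global identity with longest-read representatives
  (crCCS reads), and a tiered homology cascade that places every
  representative in exactly one of four bins:
  `confirmed_event` (≥95% identity over ≥97% of an event sequence),
  `only_known_information` (complete alignment to a CAF reference),
  `unknown_parts` (element evidence with unexplained sequence — the UGMO
  signal, reported as a 5′→3′ element-order string such as
  `tNOS - nnn - nptII - nnn - p35S`), and `only_unknown_information`.
* **qPCR enrichment arithmetic** — relative Cq, dilution correction
  (ΔCq<sub>dil</sub> = log<sub>E</sub> d), fold change E<sup>ΔCq</sup>, and
  genome copy numbers from DNA mass, 1C value and zygosity.
* **A seeded simulator** — annotated constructs, enrichment fragments with
  geometric length decay, subreads at long-read error rates (10% insertion,
  5% deletion, 1% substitution), ≥4-pass majority consensus, plus
  primer-free background and tandem-duplication ligation artifacts, all with
  per-read ground-truth provenance.

## Worked example

Simulate a small error-free run of the bundled four-component mixture (one
dominant fully-known event at 97% of the DNA mass, two minor known events,
and a model UGMO carrying `tNOS – nptII – p35S` that is present only in the
element database), then classify it:

```
$ alfwalk simulate --out demo --seed 11 --n-reads 120 --zero-errors
$ alfwalk run --reads demo/reads.fastq --db-dir demo/db \
              --config demo/config.yaml --out demo/results
120 reads -> 10 clusters; bins: confirmed_event=2, only_known_information=5,
unknown_parts=3, only_unknown_information=0
$ cat demo/results/steps.log
input reads     120
after trimming  120
after length filter (>50 nt)    120
after primer filter     102
  p35S_down     12
  p35S_up       86
  tNOS_down     1
  tNOS_up       3
unique sequences        10
clusters        10
bin confirmed_event     2
bin only_known_information      5
bin unknown_parts       3
bin only_unknown_information    0
```

The 18 primer-free background reads are removed by the primer filter; the
read shares mirror the strong p35S-over-tNOS and upstream-over-downstream
imbalance of real enrichment runs.  The UGMO leaves its signature in
`unknown_parts`:

```
$ cat demo/results/bins/unknown_parts.tsv
crccs_id  cluster_size  bin            best_subject  identity_pct  coverage_pct  element_order                             flags
S000084   1             unknown_parts  p35S          100.00        9.17          p35S(-) - nnn - nptII(-) - nnn - tNOS(-)  NA
S000099   1             unknown_parts  tNOS          100.00        19.35         tNOS(-)                                   NA
S000100   1             unknown_parts  tNOS          100.00        10.36         tNOS - nnn - nptII - nnn - p35S           NA
```

`S000100` is a tNOS-downstream read walking through the model UGMO:
terminator, gap, *nptII* marker, gap, promoter — an element order no
construct in the CAF database explains, exactly the evidence an analyst
would escalate.  The dominant event lands in `confirmed_event` with 100%
identity over 100% of its event sequence (cluster of 82 reads), including a
ligation-artifact read that carries the event twice and is flagged
`tandem_repeat`.

The qPCR side reproduces the enrichment bookkeeping: a target measured at
Cq 30.3 in the starting material and 9.6 after a 100-fold-diluted
semi-nested PCR is corrected by log₂100 = 6.64 cycles to 2.96, giving
ΔCq = 27.3 and a fold change of 2²⁷·³ ≈ 1.65 × 10⁸:

```
$ alfwalk qpcr --table cq.tsv
target     distance_nt  relative_cq_le  fold_change_le  relative_cq_snpcr  fold_change_snpcr
Cp4-epsps  303          2.2             4.59            27.3               165000000.0
```

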