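"""Read preprocessing: artifact trimming, length/quality filters, primer
assignment, and read orientation.

The enrichment chemistry leaves two artificial fixtures on each sequenced
fragment: the homopolymer tail appended by terminal transferase (poly-dC on
the fragment, read as poly-G on the opposite strand) and the anchor adaptor
that primes off that tail.  Trimming removes both from either read end.
Reads are then filtered by length (the shortest informative transgenic
element sets the bar), searched on both strands for a nested enrichment
primer, and reverse-complemented where needed so the primer lies at the 5'
end — the orientation the downstream plus/plus clustering expects.

The quality filter (Phred >= q_min over at least a fraction of positions)
belongs to the reference-merging validation path, not the main cascade: the
consensus reads entering the cascade are already high quality.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import edlib
from Bio import SeqIO

from .seqcore import NucSequence, SequenceError, reverse_complement, revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

TARGETS = ("p35S", "tNOS")
DIRECTIONS = ("up", "down")

# A primer match counts as anchored at a read end when it starts or ends
# within this many bases of the extremity.
_END_ANCHOR_SLACK = 10


class PrimerError(ValueError):
    pass


@dataclass(frozen=True)
class PrimerPair:
    """Linear-enrichment primer and its nested counterpart for one target."""

    le_primer: str
    nested_primer: str

    def __post_init__(self) -> None:
        if not self.le_primer or not self.nested_primer:
            raise PrimerError("empty primer sequence")


@dataclass(frozen=True)
class PrimerSet:
    """Primers per (target element, direction), plus the anchor adaptor.

    ``tail_base`` is the base added by the tailing reaction (C for poly-dC);
    the read may show the tail as either that base or its complement
    depending on which strand was sequenced.
    """

    primers: dict[tuple[str, str], PrimerPair]  # (target, direction) -> pair
    anchor_adaptor: str
    tail_base: str = "C"

    def __post_init__(self) -> None:
        if self.tail_base not in ("C", "G"):
            raise PrimerError("tail_base must be C or G")
        if not self.anchor_adaptor:
            raise PrimerError("empty anchor adaptor")

    def nested(self, target: str, direction: str) -> str:
        return self.primers[(target, direction)].nested_primer


@dataclass(frozen=True)
class ReadAssignment:
    """The enrichment primer found on a read, and where."""

    read_id: str
    target_element: str
    direction: str
    strand_found: str  # '+' or '-'
    primer_span: tuple[int, int]  # 1-based inclusive on the read as given
    edit_distance: int


# ---------------------------------------------------------------------------
# Step 1: trimming and filters
# ---------------------------------------------------------------------------

def _find_adaptor_at_start(
    bases: str, adaptor: str, max_edits: int
) -> Optional[int]:
    """End index (exclusive) of an adaptor match anchored at the 5' end."""
    window = bases[: len(adaptor) + max_edits + 8]
    if not window:
        return None
    res = edlib.align(adaptor, window, mode="HW", task="locations")
    if res["editDistance"] < 0 or res["editDistance"] > max_edits:
        return None
    start, end = res["locations"][0]
    if start > max_edits + 2:  # not actually at the read end
        return None
    return end + 1


def _trim_5p(
    bases: str, adaptor: str, tail_base: str, min_tail_run: int, max_edits: int
) -> int:
    """Number of bases to cut from the 5' end (0 when nothing to trim)."""
    cut = _find_adaptor_at_start(bases, adaptor, max_edits)
    if cut is None:
        return 0
    run_chars = (tail_base, _COMP[tail_base])
    if cut < len(bases) and bases[cut] in run_chars:
        ch = bases[cut]
        run_end = cut
        while run_end < len(bases) and bases[run_end] == ch:
            run_end += 1
        if run_end - cut >= min_tail_run:
            cut = run_end
    return cut


def trim_artificial(
    read: NucSequence,
    primers: PrimerSet,
    min_tail_run: int = 8,
    max_edit_fraction: float = 0.2,
) -> NucSequence:
    """Remove the anchor adaptor and adjacent homopolymer tail from read ends.

    Either end is handled: the 3' end is trimmed by applying the 5' rule to
    the reverse complement.  The tail run (of ``tail_base`` or its
    complement) is only removed when adjacent to an adaptor match and at
    least ``min_tail_run`` long.  Interior sequence is never touched, and the
    operation is idempotent.  Reads that become empty are passed through (the
    length filter removes them).
    """
    adaptor = primers.anchor_adaptor.upper()
    max_edits = int(max_edit_fraction * len(adaptor))
    bases = read.bases
    quals = list(read.qualities) if read.qualities is not None else None

    cut5 = _trim_5p(bases, adaptor, primers.tail_base, min_tail_run, max_edits)
    bases = bases[cut5:]
    if quals is not None:
        quals = quals[cut5:]

    cut3 = _trim_5p(revcomp(bases), adaptor, primers.tail_base, min_tail_run, max_edits)
    if cut3:
        bases = bases[: len(bases) - cut3]
        if quals is not None:
            quals = quals[: len(quals) - cut3]

    return NucSequence(read.id, bases, tuple(quals) if quals is not None else None)


def length_filter(
    reads: Iterable[NucSequence], min_exclusive: int = 50
) -> list[NucSequence]:
    """Keep reads strictly longer than ``min_exclusive`` nucleotides."""
    return [r for r in reads if len(r) > min_exclusive]


def quality_filter(
    read: NucSequence, q_min: int = 33, min_fraction: float = 0.90
) -> bool:
    """True when at least ``min_fraction`` of positions have Phred >= q_min."""
    if read.qualities is None:
        raise SequenceError(f"{read.id}: quality filter needs per-base qualities")
    if len(read) == 0:
        return False
    good = sum(1 for q in read.qualities if q >= q_min)
    return good / len(read) >= min_fraction


# ---------------------------------------------------------------------------
# Step 2: primer assignment; step 3 orientation
# ---------------------------------------------------------------------------

def assign_primer(
    read: NucSequence,
    primers: PrimerSet,
    max_edit_fraction: float = 0.2,
) -> Optional[ReadAssignment]:
    """Locate the best nested enrichment primer match on either strand.

    Matches anchored at a read end outrank interior matches: the enrichment
    primer primes the molecule and therefore sits at one extremity, while a
    fragment long enough to run through the other target element carries
    that element's primer site internally (and tail trimming can nibble a
    base off the true primer, so an interior copy may even score a lower
    edit distance).  Within the same class the winner has the lowest edit
    distance, then sits closest to an end, then earliest, then '+' before
    '-'.  ``None`` when no primer matches within ``max_edit_fraction`` of
    its length.
    """
    if len(read) == 0:
        return None
    best: Optional[tuple] = None
    for (target, direction), pair in sorted(primers.primers.items()):
        primer = pair.nested_primer.upper()
        max_edits = int(max_edit_fraction * len(primer))
        for strand, probe in (("+", primer), ("-", revcomp(primer))):
            res = edlib.align(probe, read.bases, mode="HW", task="locations")
            dist = res["editDistance"]
            if dist < 0 or dist > max_edits:
                continue
            start, end = res["locations"][0]
            end_distance = min(start, len(read) - 1 - end)
            cand = ReadAssignment(
                read_id=read.id,
                target_element=target,
                direction=direction,
                strand_found=strand,
                primer_span=(start + 1, end + 1),
                edit_distance=dist,
            )
            key = (end_distance > _END_ANCHOR_SLACK, dist, end_distance, start, strand)
            if best is None or key < best[0]:
                best = (key, cand)
    return best[1] if best is not None else None


def orient_read(read: NucSequence, assignment: ReadAssignment) -> NucSequence:
    """Reverse-complement the read when its primer was found on the '-' strand.

    After orientation the enrichment primer lies on the plus strand toward
    the 5' end, the precondition for plus/plus clustering.  Applying the
    operation twice equals applying it once.
    """
    if assignment.read_id != read.id:
        raise SequenceError(
            f"assignment for {assignment.read_id!r} applied to read {read.id!r}"
        )
    if assignment.strand_found == "-":
        return reverse_complement(read)
    return read


# ---------------------------------------------------------------------------
# FASTQ/FASTA input
# ---------------------------------------------------------------------------

def read_reads(path: Union[str, Path]) -> list[NucSequence]:
    """Load reads from FASTQ (Phred+33) or FASTA, by file extension."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        quals = (
            tuple(rec.letter_annotations["phred_quality"])
            if "phred_quality" in rec.letter_annotations
            else None
        )
        reads.append(NucSequence(rec.id, str(rec.seq).upper(), quals))
    return reads


def write_fastq(reads: Iterable[NucSequence], path: Union[str, Path]) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(
            r.qualities if r.qualities is not None else [40] * len(r)
        )
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")
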