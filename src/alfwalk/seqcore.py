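"""Sequence primitives and the local-alignment engine used throughout the cascade.

Every read and reference in the pipeline is a :class:`NucSequence`; every
homology decision (event confirmation, construct coverage, element hits) is a
:class:`LocalAlignment` produced by :func:`local_align` or
:func:`find_all_hits`.  The aligner is an exhaustive affine-gap local
(Smith-Waterman) alignment with megablast-like scoring that strongly favours
long, high-identity hits; this is adequate at the scale of this pipeline
(hundreds of kilobase-sized reads against small curated databases).

Coordinates are 1-based inclusive on the forward strand of each sequence,
with a strand flag for hits found on the reverse complement of the query.
Internally everything is 0-based half-open.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import edlib
from Bio import Align
from Bio.Align import substitution_matrices

ALPHABET = "ACGTN"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised for malformed sequences or invalid alignment requests."""


# ---------------------------------------------------------------------------
# Sequence container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NucSequence:
    """A nucleotide sequence with optional per-base Phred qualities.

    Parameters
    ----------
    id : str
        Sequence label (read name or reference accession).
    bases : str
        Uppercase string over ``ACGTN``.
    qualities : tuple of int, optional
        Per-base Phred scores; must match ``bases`` in length when present.
    """

    id: str
    bases: str
    qualities: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        for pos, ch in enumerate(self.bases):
            if ch not in ALPHABET:
                raise SequenceError(
                    f"{self.id}: invalid character {ch!r} at position {pos + 1}"
                )
        if self.qualities is not None:
            object.__setattr__(self, "qualities", tuple(self.qualities))
            if len(self.qualities) != len(self.bases):
                raise SequenceError(
                    f"{self.id}: {len(self.qualities)} qualities for "
                    f"{len(self.bases)} bases"
                )
            if any(q < 0 for q in self.qualities):
                raise SequenceError(f"{self.id}: negative quality score")

    def __len__(self) -> int:
        return len(self.bases)


def reverse_complement(seq: NucSequence) -> NucSequence:
    """Watson-Crick reverse complement; N maps to N, qualities are reversed."""
    quals = None if seq.qualities is None else tuple(reversed(seq.qualities))
    return NucSequence(seq.id, seq.bases.translate(_COMPLEMENT)[::-1], quals)


def revcomp(bases: str) -> str:
    """Reverse complement of a bare base string."""
    return bases.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Alignment containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringScheme:
    """Megablast-like local alignment scoring.

    A gap of length k costs ``gap_open + k * gap_extend`` (so the first gap
    column costs 3.0 under the defaults).  ``min_score`` is the smallest
    reportable alignment score; N never scores as a match.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -2.5
    gap_extend: float = -0.5
    min_score: float = 20.0


@dataclass(frozen=True)
class LocalAlignment:
    """One local hit, coordinates 1-based inclusive on forward strands."""

    query_id: str
    subject_id: str
    strand: str  # '+' or '-'
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    n_columns: int
    n_matches: int
    n_mismatches: int
    n_gap_opens: int
    score: float
    query_length: int
    subject_length: int

    def __post_init__(self) -> None:
        if not (1 <= self.q_start <= self.q_end <= self.query_length):
            raise SequenceError("query span out of bounds")
        if not (1 <= self.s_start <= self.s_end <= self.subject_length):
            raise SequenceError("subject span out of bounds")
        if self.n_matches > self.n_columns:
            raise SequenceError("more matches than alignment columns")

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.n_matches / self.n_columns

    @property
    def subject_coverage_pct(self) -> float:
        # Alignment columns over subject length: insertions in the query can
        # push this above 100, matching how tabular alignment length behaves.
        return 100.0 * self.n_columns / self.subject_length

    @property
    def query_coverage_pct(self) -> float:
        return 100.0 * (self.q_end - self.q_start + 1) / self.query_length

    def query_span(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)


# ---------------------------------------------------------------------------
# Local alignment
# ---------------------------------------------------------------------------

def _make_aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    matrix = substitution_matrices.Array(ALPHABET, dims=2)
    for a in ALPHABET:
        for b in ALPHABET:
            is_match = a == b and a != "N"
            matrix[a, b] = scoring.match if is_match else scoring.mismatch
    aligner.substitution_matrix = matrix
    # Biopython charges open_gap_score for the first gap column and
    # extend_gap_score for each further one; fold our per-column extend cost
    # into the opening column so a k-gap costs gap_open + k*gap_extend.
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    return aligner

# Enumerating every co-optimal alignment can explode on repetitive input;
# ties are broken over at most this many candidates.
_MAX_TIE_CANDIDATES = 32


def _alignment_stats(aln, query: str, subject: str) -> tuple[int, int, int, int, int, int, int]:
    """(q0, q1, s0, s1, columns, matches, mismatches) from a biopython alignment.

    Spans are 0-based half-open on the aligned (local) region; gap columns
    between aligned blocks are counted in ``columns``.
    """
    q_blocks, s_blocks = aln.aligned  # target=query was passed first
    q0, q1 = int(q_blocks[0][0]), int(q_blocks[-1][1])
    s0, s1 = int(s_blocks[0][0]), int(s_blocks[-1][1])
    columns = 0
    matches = 0
    mismatches = 0
    gap_opens = 0
    for i, ((qa, qb), (sa, sb)) in enumerate(zip(q_blocks, s_blocks)):
        columns += qb - qa
        for cq, cs in zip(query[qa:qb], subject[sa:sb]):
            if cq == cs and cq != "N":
                matches += 1
            else:
                mismatches += 1
        if i + 1 < len(q_blocks):
            gq = q_blocks[i + 1][0] - qb
            gs = s_blocks[i + 1][0] - sb
            columns += gq + gs
            gap_opens += (gq > 0) + (gs > 0)
    return q0, q1, s0, s1, columns, matches, mismatches, gap_opens


def _best_local(query: str, subject: str, aligner) -> Optional[tuple]:
    alignments = aligner.align(query, subject)
    try:
        best_score = alignments.score
    except (ValueError, AttributeError):
        return None
    if best_score <= 0:
        return None
    candidates = list(itertools.islice(alignments, _MAX_TIE_CANDIDATES))
    stats = [_alignment_stats(a, query, subject) for a in candidates]
    stats.sort(key=lambda t: (t[0], t[2]))  # smallest q_start, then s_start
    return (best_score, stats[0])


def local_align(
    query: NucSequence,
    subject: NucSequence,
    scoring: ScoringScheme = ScoringScheme(),
) -> Optional[LocalAlignment]:
    """Best local alignment of ``query`` against ``subject`` on either strand.

    Returns ``None`` when the best score falls below ``scoring.min_score``.
    Minus-strand hits report forward-strand coordinates on both sequences
    together with ``strand='-'``.  Ties are broken toward the smallest query
    start, then smallest subject start, with '+' preferred over '-'.
    """
    if not query.bases or not subject.bases:
        raise SequenceError("cannot align an empty sequence")
    aligner = _make_aligner(scoring)
    best = None
    for strand, qbases in (("+", query.bases), ("-", revcomp(query.bases))):
        hit = _best_local(qbases, subject.bases, aligner)
        if hit is None:
            continue
        score, stats = hit
        if best is None or score > best[0]:
            best = (score, strand, stats)
    if best is None or best[0] < scoring.min_score:
        return None
    score, strand, (q0, q1, s0, s1, cols, matches, mismatches, gap_opens) = best
    if strand == "-":
        q0, q1 = len(query) - q1, len(query) - q0
    return LocalAlignment(
        query_id=query.id,
        subject_id=subject.id,
        strand=strand,
        q_start=q0 + 1,
        q_end=q1,
        s_start=s0 + 1,
        s_end=s1,
        n_columns=cols,
        n_matches=matches,
        n_mismatches=mismatches,
        n_gap_opens=gap_opens,
        score=score,
        query_length=len(query),
        subject_length=len(subject),
    )


def find_all_hits(
    query: NucSequence,
    db: Sequence[NucSequence],
    min_identity_pct: float = 0.0,
    min_score: Optional[float] = None,
    scoring: ScoringScheme = ScoringScheme(),
) -> list[LocalAlignment]:
    """All above-threshold hits of ``query`` against a database.

    Hits are extracted iteratively: the best-scoring hit over all subjects is
    claimed, its query span is masked with N, and the search repeats until no
    subject reaches the thresholds.  Query spans of the returned hits are
    therefore pairwise disjoint; the list is sorted by descending score.
    """
    if min_score is not None:
        scoring = replace(scoring, min_score=min_score)
    if not db:
        return []
    hits: list[LocalAlignment] = []
    masked = query.bases
    while True:
        working = NucSequence(query.id, masked)
        best: Optional[LocalAlignment] = None
        for subject in db:
            hit = local_align(working, subject, scoring)
            if hit is None or hit.identity_pct < min_identity_pct:
                continue
            if best is None or (hit.score, -hit.q_start) > (best.score, -best.q_start):
                best = hit
        if best is None:
            break
        # An optimal local alignment never starts or ends on masked (all-N)
        # columns, and crossing a claimed span costs at least two mismatches
        # per masked column; guard anyway so spans stay pairwise disjoint.
        if any(not (best.q_end < h.q_start or best.q_start > h.q_end) for h in hits):
            break
        hits.append(best)
        a, b = best.q_start - 1, best.q_end
        masked = masked[:a] + "N" * (b - a) + masked[b:]
    hits.sort(key=lambda h: (-h.score, h.q_start))
    return hits


# ---------------------------------------------------------------------------
# Tandem-repeat (ligation artifact) detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TandemRepeat:
    """Same-strand self-similarity of a read, evidence for a ligation artifact."""

    unit_length: int
    identity_pct: float
    first_span: tuple[int, int]  # 1-based inclusive
    second_span: tuple[int, int]


def detect_tandem_repeat(
    seq: NucSequence,
    min_unit: int = 50,
    min_identity_pct: float = 90.0,
) -> Optional[TandemRepeat]:
    """Detect a same-strand tandem repetition within a read.

    The read is compared against itself at every shift ``u`` (the candidate
    unit length): a tandem repeat of unit ``u`` makes ``seq[:-u]`` and
    ``seq[u:]`` near-identical.  Global edit distance over the overlap,
    capped at the identity budget ``k``, gives the identity; the best
    qualifying shift is reported.  Shifts small enough that the comparison
    could trivially re-align the read with itself on the main diagonal
    (un-shifting costs ``2u`` indels, which must exceed ``k``) are excluded,
    so a reported repeat is always genuinely off-diagonal.  A read shorter
    than ``2 * min_unit``, or one whose only self-similarity is to its own
    reverse complement, yields ``None``.
    """
    n = len(seq)
    if n < 2 * min_unit:
        return None
    best: Optional[TandemRepeat] = None
    budget_fraction = 1.0 - min_identity_pct / 100.0
    for unit in range(min_unit, n - min_unit + 1):
        overlap = n - unit
        k = int(overlap * budget_fraction)
        if 2 * unit <= k:
            continue  # an un-shift alignment alone would pass the threshold
        dist = edlib.align(
            seq.bases[: n - unit], seq.bases[unit:], mode="NW", task="distance", k=k
        )["editDistance"]
        if dist < 0:
            continue
        identity = 100.0 * max(0, overlap - dist) / overlap
        if identity < min_identity_pct:
            continue
        if best is None or identity > best.identity_pct:
            best = TandemRepeat(
                unit_length=unit,
                identity_pct=identity,
                first_span=(1, overlap),
                second_span=(unit + 1, n),
            )
    return best


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def hits_to_tabular(hits: Iterable[LocalAlignment]) -> str:
    """Render hits in the conventional 12-column tabular alignment layout.

    Columns: query, subject, % identity, alignment length, mismatches, gap
    opens, q.start, q.end, s.start, s.end, e-value placeholder, score.
    Minus-strand hits follow the convention of swapped subject coordinates.
    """
    lines = []
    for h in hits:
        s_start, s_end = (h.s_start, h.s_end) if h.strand == "+" else (h.s_end, h.s_start)
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    h.query_id,
                    h.subject_id,
                    f"{h.identity_pct:.2f}",
                    h.n_columns,
                    h.n_mismatches,
                    h.n_gap_opens,
                    h.q_start,
                    h.q_end,
                    s_start,
                    s_end,
                    "NA",
                    f"{h.score:g}",
                )
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Global identity (shared by clustering and the simulator)
# ---------------------------------------------------------------------------

def global_identity(a: str, b: str) -> float:
    """Identity of an end-to-end alignment as matches / alignment columns."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    cigar = res["cigar"]
    matches = columns = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        k = int(num)
        num = ""
        columns += k
        if ch == "=":
            matches += k
    return matches / columns if columns else 0.0
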