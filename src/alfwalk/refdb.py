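"""Construction of the three reference databases used by the cascade.

The cascade consults, in order:

* an **event database** of event-specific amplicon sequences, assembled from
  primer/probe segments with runs of unknown nucleotides between them, then
  replaced by externally resolved sequences supplied as FASTA;
* a **Constructs-And-Flanks (CAF) database** of full insert sequences plus
  flanking host-genome sequence, each carrying element annotations (GFF3);
* an **element database** of individual transgenic building blocks
  (promoters, terminators, coding sequences, ...), extracted from annotated
  references and deduplicated to the longest sequence per element name.

This module also merges two overlapping references into one (suffix/prefix
overlap with substitutions only), the operation behind combining a 5'-flank
reference with an insert reference into a single construct sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcore import NucSequence, SequenceError, revcomp

#: Element class codes: promoter, intron, coding sequence, vector, left
#: border, leader, terminator, right border, transit peptide.
ELEMENT_CLASSES = ("P", "I", "CS", "V", "LB", "L", "T", "RB", "TP")


class DatabaseError(ValueError):
    """Raised for malformed database inputs."""


# ---------------------------------------------------------------------------
# Event search templates
# ---------------------------------------------------------------------------

Segment = Union[str, int]  # known bases, or a run of that many unknown bases


@dataclass(frozen=True)
class EventTemplate:
    """An event-specific search template assembled from primer/probe segments.

    ``segments`` alternates known base strings with integer lengths of
    unknown runs; the assembled query renders unknown runs as N.  When the
    template has been resolved against an external sequence database, the
    resolved top hit replaces the template for classification.
    """

    event_name: str
    segments: tuple[Segment, ...]
    assembled_query: str
    resolved_sequence: Optional[str] = None

    def __len__(self) -> int:
        return len(self.assembled_query)


#: Search-template segments for four widely used reference events, taken
#: from the public primer/probe sequences of their validated event-specific
#: qPCR detection methods; integers are the numbers of unknown nucleotides
#: between the published segments.
BUNDLED_EVENT_TEMPLATES: dict[str, tuple[Segment, ...]] = {
    "MON810": (
        "TCGAAGGACGAAGGACTCTAACGT", 2,
        "AACATCCTTTGCCATTGCCCAGC", 19,
        "AAGATAGTGGAAAAGGAAGGTGGC",
    ),
    "MON89034": (
        "TTCTCCATATTGACCATCATACTCATT", 2,
        "ATCCCCGGAAATTATGTT", 2,
        "TTTAAAAACCACGGTATTATAGATACCG",
    ),
    "MON88017": (
        "GAGCAGGACCTGCAGAAGCT", 26,
        "TCCCGCCTTCAGTTTAAACAGAGTCGGGT", 1,
        "TGGATGGTCAACTCCGGCA",
    ),
    "MON15985": (
        "GTTACTAGATCGGGGATATCC", 9,
        "CCGCTCTAGAACTAGTGGATCTGCACTGAA", 1,
        "TCCCATCCATTTAGCAACCTT",
    ),
}


def build_event_query(event_name: str, segments: Sequence[Segment]) -> EventTemplate:
    """Assemble an event search template from ordered segments.

    Parameters
    ----------
    segments : sequence of str or int
        Known base strings and unknown-run lengths, in template order.
    """
    known = [s for s in segments if isinstance(s, str)]
    if not known:
        raise DatabaseError(f"{event_name}: template needs at least one known segment")
    parts = []
    for seg in segments:
        if isinstance(seg, str):
            if not seg:
                raise DatabaseError(f"{event_name}: zero-length known segment")
            parts.append(seg.upper())
        else:
            if seg < 0:
                raise DatabaseError(f"{event_name}: negative unknown-run length")
            parts.append("N" * seg)
    return EventTemplate(event_name, tuple(segments), "".join(parts))


# ---------------------------------------------------------------------------
# Annotated references and elements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Feature:
    """One annotated element on a reference, 1-based inclusive coordinates."""

    name: str
    class_code: str
    start: int
    end: int
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class AnnotatedReference:
    id: str
    bases: str
    features: tuple[Feature, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))
        for f in self.features:
            if not (1 <= f.start <= f.end <= len(self.bases)):
                raise DatabaseError(
                    f"{self.id}: feature {f.name} [{f.start},{f.end}] outside "
                    f"sequence of length {len(self.bases)}"
                )

    def __len__(self) -> int:
        return len(self.bases)

    def as_sequence(self) -> NucSequence:
        return NucSequence(self.id, self.bases)


@dataclass(frozen=True)
class ElementRecord:
    """A single transgenic element: name, class code, bases, and origin."""

    element_name: str
    class_code: str
    bases: str
    source: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise DatabaseError(f"{self.element_name}: empty element sequence")

    def __len__(self) -> int:
        return len(self.bases)

    def as_sequence(self) -> NucSequence:
        return NucSequence(self.element_name, self.bases)


def extract_elements(ref: AnnotatedReference) -> list[ElementRecord]:
    """Cut an annotated reference into one element record per feature.

    Minus-strand features yield the reverse complement of the slice, so every
    record reads 5'->3' in the element's own orientation.
    """
    records = []
    for f in ref.features:
        piece = ref.bases[f.start - 1 : f.end]
        if f.strand == "-":
            piece = revcomp(piece)
        records.append(ElementRecord(f.name, f.class_code, piece, ref.id))
    return records


def dedupe_elements(records: Iterable[ElementRecord]) -> list[ElementRecord]:
    """Keep the longest record per element name (first wins on equal length).

    Input order is otherwise preserved: each name appears at the position of
    its first occurrence.
    """
    best: dict[str, ElementRecord] = {}
    order: list[str] = []
    for rec in records:
        if rec.element_name not in best:
            best[rec.element_name] = rec
            order.append(rec.element_name)
        elif len(rec) > len(best[rec.element_name]):
            best[rec.element_name] = rec
    return [best[name] for name in order]


# ---------------------------------------------------------------------------
# Reference merging
# ---------------------------------------------------------------------------

def merge_references(
    a: NucSequence,
    b: NucSequence,
    min_overlap: int,
    max_mismatches: int = 0,
) -> NucSequence:
    """Merge two references across a suffix/prefix overlap.

    Finds the longest suffix of ``a`` matching a prefix of ``b`` with at
    least ``min_overlap`` columns and at most ``max_mismatches``
    substitutions (no indels), and returns ``a`` followed by the
    non-overlapping remainder of ``b``; bases of ``a`` win inside the
    overlap.  Raises :class:`DatabaseError`, reporting the best overlap seen,
    when no junction qualifies.
    """
    if not a.bases or not b.bases:
        raise SequenceError("cannot merge an empty sequence")
    limit = min(len(a), len(b))
    best_seen = (0, 0)  # (overlap, mismatches) for the error message
    for overlap in range(limit, min_overlap - 1, -1):
        suffix = a.bases[len(a) - overlap :]
        prefix = b.bases[:overlap]
        mism = sum(1 for x, y in zip(suffix, prefix) if x != y)
        if mism <= max_mismatches:
            merged = a.bases + b.bases[overlap:]
            return NucSequence(f"{a.id}+{b.id}", merged)
        if overlap > best_seen[0] and mism <= max_mismatches + 5:
            best_seen = (overlap, mism)
    raise DatabaseError(
        f"no overlap of >= {min_overlap} columns with <= {max_mismatches} "
        f"mismatches between {a.id} and {b.id} "
        f"(best candidate: {best_seen[0]} columns, {best_seen[1]} mismatches)"
    )


# ---------------------------------------------------------------------------
# The database set and its on-disk form
# ---------------------------------------------------------------------------

@dataclass
class DatabaseSet:
    """The event, CAF, and element databases used by the cascade."""

    event_db: list[NucSequence] = field(default_factory=list)
    caf_db: list[AnnotatedReference] = field(default_factory=list)
    element_db: list[ElementRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for label, ids in (
            ("event", [s.id for s in self.event_db]),
            ("CAF", [r.id for r in self.caf_db]),
            ("element", [e.element_name for e in self.element_db]),
        ):
            if len(ids) != len(set(ids)):
                raise DatabaseError(f"duplicate ids in {label} database")

    def element_sequences(self) -> list[NucSequence]:
        return [e.as_sequence() for e in self.element_db]

    def caf_sequences(self) -> list[NucSequence]:
        return [r.as_sequence() for r in self.caf_db]


# --- FASTA -----------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> list[NucSequence]:
    return [
        NucSequence(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(seqs: Iterable[NucSequence], path: Union[str, Path]) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


# --- GFF3 ------------------------------------------------------------------
# The CAF feature files are tiny, hand-curated GFF3 (version directive,
# 1-based inclusive coordinates, Name= attribute carrying the element name,
# feature type carrying the element class code).

def write_gff3(refs: Iterable[AnnotatedReference], path: Union[str, Path]) -> None:
    lines = ["##gff-version 3"]
    for ref in refs:
        lines.append(f"##sequence-region {ref.id} 1 {len(ref)}")
        for f in ref.features:
            lines.append(
                "\t".join(
                    (
                        ref.id,
                        "alfwalk",
                        f.class_code,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"Name={f.name}",
                    )
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3_features(path: Union[str, Path]) -> dict[str, list[Feature]]:
    """Features per seqid from a GFF3 file; only Name= rows are kept."""
    features: dict[str, list[Feature]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise DatabaseError(f"malformed GFF3 line: {line!r}")
        seqid, _source, ftype, start, end, _score, strand, _frame, attrs = cols[:9]
        name = None
        for item in attrs.split(";"):
            key, _, value = item.partition("=")
            if key.strip() == "Name":
                name = value.strip()
        if name is None:
            continue
        features.setdefault(seqid, []).append(
            Feature(name, ftype, int(start), int(end), strand if strand in "+-" else "+")
        )
    return features


def annotate_fasta(
    fasta_path: Union[str, Path], gff_path: Union[str, Path]
) -> list[AnnotatedReference]:
    feats = read_gff3_features(gff_path)
    refs = []
    for seq in read_fasta(fasta_path):
        refs.append(AnnotatedReference(seq.id, seq.bases, tuple(feats.get(seq.id, ()))))
    return refs


# --- manifest / directory layout -------------------------------------------

MANIFEST_NAME = "manifest.txt"
_DB_FILES = {
    "event_fasta": "event.fasta",
    "caf_fasta": "caf.fasta",
    "caf_gff3": "caf.gff3",
    "element_fasta": "elements.fasta",
}


def write_database_set(dbs: DatabaseSet, out_dir: Union[str, Path]) -> Path:
    """Write a database set as FASTA/GFF3 plus a flat key-value manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(dbs.event_db, out / _DB_FILES["event_fasta"])
    write_fasta(dbs.caf_sequences(), out / _DB_FILES["caf_fasta"])
    write_gff3(dbs.caf_db, out / _DB_FILES["caf_gff3"])
    write_fasta(
        [e.as_sequence() for e in dbs.element_db], out / _DB_FILES["element_fasta"]
    )
    classes = ",".join(f"{e.element_name}:{e.class_code}" for e in dbs.element_db)
    manifest = "\n".join(
        [f"{key} = {value}" for key, value in _DB_FILES.items()]
        + [f"element_classes = {classes}"]
    )
    (out / MANIFEST_NAME).write_text(manifest + "\n")
    return out / MANIFEST_NAME


def load_database_set(db_dir: Union[str, Path]) -> DatabaseSet:
    """Load a database set from a directory holding a manifest."""
    root = Path(db_dir)
    manifest_path = root / MANIFEST_NAME
    if not manifest_path.exists():
        raise DatabaseError(f"no {MANIFEST_NAME} in {root}")
    entries: dict[str, str] = {}
    for line in manifest_path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        entries[key.strip()] = value.strip()
    class_of: dict[str, str] = {}
    for item in entries.get("element_classes", "").split(","):
        if ":" in item:
            name, _, code = item.partition(":")
            class_of[name] = code
    event_db = read_fasta(root / entries["event_fasta"])
    caf_db = annotate_fasta(root / entries["caf_fasta"], root / entries["caf_gff3"])
    element_db = [
        ElementRecord(s.id, class_of.get(s.id, "CS"), s.bases, "db")
        for s in read_fasta(root / entries["element_fasta"])
    ]
    return DatabaseSet(event_db=event_db, caf_db=caf_db, element_db=element_db)
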