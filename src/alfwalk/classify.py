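"""The tiered homology cascade binning cluster representatives.

Each cluster-representative read (crCCS read) is pushed through three
database searches in strict order, landing in exactly one of four bins:

1. **confirmed_event** — a hit to an event-specific sequence at >= 95%
   identity covering >= 97% of the event sequence (coverage measured as
   alignment columns over event-sequence length, so insertions can push it
   above 100).  Such reads carry a confirmed, known GMO event.
2. **only_known_information** — the read aligns (nearly) completely to a
   Constructs-And-Flanks reference: everything on it is already known.  The
   hit interval is annotated with the overlapping element features.
3. **unknown_parts** — at least one transgenic element is recognized but the
   read is not explained by any known construct; the reconstructed element
   order (with ``nnn`` gap markers) is the evidence a potential unauthorized
   GMO leaves behind.
4. **only_unknown_information** — nothing beyond the enrichment primer is
   recognized.

Reads that align to themselves off-diagonal (tandem repetitions, the
signature of a ligation artifact) are binned normally but flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from . import cluster as _cluster
from . import preprocess as _pre
from .refdb import AnnotatedReference, DatabaseSet, Feature
from .seqcore import (
    LocalAlignment,
    NucSequence,
    ScoringScheme,
    detect_tandem_repeat,
    find_all_hits,
    local_align,
)

BIN_LABELS = (
    "confirmed_event",
    "only_known_information",
    "unknown_parts",
    "only_unknown_information",
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of the workflow, with their published defaults."""

    min_len: int = 50                          # length filter, exclusive
    cluster_min_identity: float = 0.97         # greedy clustering radius
    event_min_identity_pct: float = 95.0       # step 4
    event_min_subject_coverage_pct: float = 97.0
    caf_min_query_coverage_pct: float = 97.0   # step 5 "full query coverage"
    element_min_identity_pct: float = 80.0     # step 6
    element_min_hit_length: int = 30
    gap_min: int = 1                           # unaligned nt before an "nnn"
    primer_max_edit_fraction: float = 0.2
    min_tail_run: int = 8
    tandem_min_unit: int = 50
    tandem_min_identity_pct: float = 90.0
    rank_by_score: bool = False                # optional bit-score-style ranking
    seed: int = 0
    scoring: ScoringScheme = field(default_factory=ScoringScheme)

    def __post_init__(self) -> None:
        if self.min_len < 0:
            raise ConfigError("min_len must be >= 0")
        if not (0.0 < self.cluster_min_identity <= 1.0):
            raise ConfigError("cluster_min_identity must be in (0, 1]")
        for name in (
            "event_min_identity_pct",
            "event_min_subject_coverage_pct",
            "caf_min_query_coverage_pct",
            "element_min_identity_pct",
            "tandem_min_identity_pct",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 110.0):
                raise ConfigError(f"{name} out of range: {value}")
        if self.gap_min < 1:
            raise ConfigError("gap_min must be >= 1")


# ---------------------------------------------------------------------------
# Element order strings
# ---------------------------------------------------------------------------

GAP_TOKEN = "nnn"


@dataclass(frozen=True)
class ElementOrderString:
    """Element names with strands, 5'->3' along the read, gaps as ``nnn``."""

    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.tokens, self.tokens[1:]):
            if a == GAP_TOKEN and b == GAP_TOKEN:
                raise ValueError("consecutive gap tokens")

    def __str__(self) -> str:
        return " - ".join(self.tokens)

    def __bool__(self) -> bool:
        return bool(self.tokens)


def _token(name: str, strand: str) -> str:
    return name if strand == "+" else f"{name}(-)"


@dataclass
class ClassificationRecord:
    """One crCCS read, its bin, and the evidence that put it there."""

    crccs_id: str
    bin: str
    hits: list[LocalAlignment] = field(default_factory=list)
    element_order: Optional[ElementOrderString] = None
    annotations: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    cluster_size: int = 1

    def __post_init__(self) -> None:
        if self.bin not in BIN_LABELS:
            raise ValueError(f"unknown bin {self.bin!r}")


# ---------------------------------------------------------------------------
# Step 4: event classification
# ---------------------------------------------------------------------------

def classify_event(
    read: NucSequence,
    event_db: Sequence[NucSequence],
    config: PipelineConfig = PipelineConfig(),
) -> Optional[ClassificationRecord]:
    """confirmed_event when an event sequence is covered >= 97% at >= 95% identity.

    All qualifying hits are recorded, including multiple disjoint hits to the
    same event sequence (a read can carry the same event twice, the tandem
    ligation-artifact case).  ``None`` passes the read down the cascade.
    """
    qualifying: list[LocalAlignment] = []
    for event in event_db:
        hits = find_all_hits(
            read, [event], min_identity_pct=config.event_min_identity_pct,
            scoring=config.scoring,
        )
        for hit in hits:
            if (
                hit.identity_pct >= config.event_min_identity_pct
                and hit.subject_coverage_pct >= config.event_min_subject_coverage_pct
            ):
                qualifying.append(hit)
    if not qualifying:
        return None
    qualifying.sort(key=lambda h: (-h.score, h.subject_id, h.q_start))
    return ClassificationRecord(read.id, "confirmed_event", hits=qualifying)


# ---------------------------------------------------------------------------
# Step 5: CAF classification
# ---------------------------------------------------------------------------

def annotate_intervals(
    hit: LocalAlignment, ref: AnnotatedReference
) -> list[tuple[Feature, tuple[int, int]]]:
    """Features overlapping the subject span of a hit by >= 1 base.

    Returned in genomic order with the overlap span (1-based inclusive,
    reference coordinates).
    """
    if hit.subject_id != ref.id:
        raise ValueError(f"hit subject {hit.subject_id!r} is not {ref.id!r}")
    out = []
    for f in sorted(ref.features, key=lambda f: (f.start, f.end)):
        lo = max(hit.s_start, f.start)
        hi = min(hit.s_end, f.end)
        if lo <= hi:
            out.append((f, (lo, hi)))
    return out


def classify_caf(
    read: NucSequence,
    caf_db: Sequence[AnnotatedReference],
    config: PipelineConfig = PipelineConfig(),
) -> Optional[ClassificationRecord]:
    """only_known_information when the read aligns (nearly) completely to a CAF reference.

    "Completely" is query coverage >= ``caf_min_query_coverage_pct``; the
    record carries the element annotations of the covered interval.
    """
    best: Optional[LocalAlignment] = None
    best_ref: Optional[AnnotatedReference] = None
    for ref in caf_db:
        hit = local_align(read, ref.as_sequence(), config.scoring)
        if hit is None:
            continue
        if best is None or hit.score > best.score:
            best, best_ref = hit, ref
    if best is None or best.query_coverage_pct < config.caf_min_query_coverage_pct:
        return None
    annotated = annotate_intervals(best, best_ref)
    names = [f.name for f, _span in annotated]
    if best.strand == "-":
        names = names[::-1]
    return ClassificationRecord(
        read.id, "only_known_information", hits=[best], annotations=names
    )


# ---------------------------------------------------------------------------
# Step 6: element classification and order reconstruction
# ---------------------------------------------------------------------------

def _element_hits(
    read: NucSequence,
    element_db: Sequence[NucSequence],
    config: PipelineConfig,
) -> list[LocalAlignment]:
    """Per-element hit lists, overlaps on the read resolved longest-first.

    Each element is queried separately (so two similar elements may both
    claim hits); a query region is then awarded to the hit with the longest
    alignment, the paper's top-hit rule, or to the highest score when
    ``rank_by_score`` is enabled.
    """
    pooled: list[LocalAlignment] = []
    for element in element_db:
        pooled.extend(
            find_all_hits(
                read,
                [element],
                min_identity_pct=config.element_min_identity_pct,
                scoring=config.scoring,
            )
        )
    pooled = [h for h in pooled if h.n_columns >= config.element_min_hit_length]
    if config.rank_by_score:
        pooled.sort(key=lambda h: (-h.score, h.q_start, h.subject_id))
    else:
        pooled.sort(key=lambda h: (-h.n_columns, h.q_start, h.subject_id))
    accepted: list[LocalAlignment] = []
    for hit in pooled:
        if all(hit.q_end < a.q_start or hit.q_start > a.q_end for a in accepted):
            accepted.append(hit)
    return accepted


def element_order(
    read: NucSequence,
    element_db: Sequence[NucSequence],
    gap_min: int = 1,
    config: PipelineConfig = PipelineConfig(),
) -> ElementOrderString:
    """Reconstruct the order of recognized elements along a read, 5'->3'.

    Consecutive hits separated by at least ``gap_min`` unaligned query bases
    are joined by the ``nnn`` gap marker; abutting hits are not.
    """
    if gap_min != config.gap_min:
        config = replace(config, gap_min=gap_min)
    accepted = sorted(_element_hits(read, element_db, config), key=lambda h: h.q_start)
    tokens: list[str] = []
    prev_end = None
    for hit in accepted:
        if prev_end is not None and hit.q_start - prev_end - 1 >= config.gap_min:
            tokens.append(GAP_TOKEN)
        tokens.append(_token(hit.subject_id, hit.strand))
        prev_end = hit.q_end
    return ElementOrderString(tuple(tokens))


def classify_elements(
    read: NucSequence,
    element_db: Sequence[NucSequence],
    config: PipelineConfig = PipelineConfig(),
) -> ClassificationRecord:
    """Split the remaining reads into unknown_parts / only_unknown_information."""
    accepted = _element_hits(read, element_db, config)
    if not accepted:
        return ClassificationRecord(read.id, "only_unknown_information")
    ordered = sorted(accepted, key=lambda h: h.q_start)
    tokens: list[str] = []
    prev_end = None
    for hit in ordered:
        if prev_end is not None and hit.q_start - prev_end - 1 >= config.gap_min:
            tokens.append(GAP_TOKEN)
        tokens.append(_token(hit.subject_id, hit.strand))
        prev_end = hit.q_end
    return ClassificationRecord(
        read.id,
        "unknown_parts",
        hits=ordered,
        element_order=ElementOrderString(tuple(tokens)),
    )


# ---------------------------------------------------------------------------
# The full workflow
# ---------------------------------------------------------------------------

@dataclass
class RunReport:
    """Per-step read ledger plus the classification records of one run."""

    n_input: int = 0
    n_after_trim: int = 0
    n_after_length: int = 0
    n_after_primer: int = 0
    primer_breakdown: dict[str, int] = field(default_factory=dict)
    n_unique: int = 0
    n_clusters: int = 0
    bin_counts: dict[str, int] = field(default_factory=dict)
    records: list[ClassificationRecord] = field(default_factory=list)
    clusters: list[_cluster.Cluster] = field(default_factory=list)
    representatives: list[NucSequence] = field(default_factory=list)
    membership_tsv: str = ""
    discarded: dict[str, list[str]] = field(default_factory=dict)
    config: Optional[PipelineConfig] = None

    def validate(self) -> None:
        if not (self.n_input >= self.n_after_length >= self.n_after_primer):
            raise ValueError("filter chain counts must be non-increasing")
        if sum(self.bin_counts.values()) != self.n_clusters:
            raise ValueError("bin counts must sum to the cluster count")


def classify_read(
    read: NucSequence, dbs: DatabaseSet, config: PipelineConfig
) -> ClassificationRecord:
    """Run one read through steps 4-6 of the cascade."""
    record = classify_event(read, dbs.event_db, config)
    if record is None:
        record = classify_caf(read, dbs.caf_db, config)
    if record is None:
        record = classify_elements(read, dbs.element_sequences(), config)
    repeat = detect_tandem_repeat(
        read, config.tandem_min_unit, config.tandem_min_identity_pct
    )
    if repeat is not None:
        record.flags.append("tandem_repeat")
    return record


def run_pipeline(
    reads: Sequence[NucSequence],
    dbs: DatabaseSet,
    config: PipelineConfig = PipelineConfig(),
    primers: Optional[_pre.PrimerSet] = None,
) -> RunReport:
    """Execute the whole workflow: trim, filter, orient, cluster, classify.

    Deterministic for fixed inputs and configuration.  ``primers`` may be
    omitted only when the reads are already trimmed and oriented; the primer
    filter then passes everything through.
    """
    if not isinstance(dbs, DatabaseSet):
        raise ConfigError("dbs must be a DatabaseSet")
    report = RunReport(config=config)
    report.n_input = len(reads)

    # Step 1: trimming and length filter
    if primers is not None:
        trimmed = [
            _pre.trim_artificial(
                r, primers, config.min_tail_run, config.primer_max_edit_fraction
            )
            for r in reads
        ]
    else:
        trimmed = list(reads)
    report.n_after_trim = len(trimmed)
    report.discarded["empty_after_trim"] = [r.id for r in trimmed if len(r) == 0]
    kept = length_kept = _pre.length_filter(trimmed, config.min_len)
    report.n_after_length = len(kept)
    report.discarded["too_short"] = [
        r.id for r in trimmed if len(r) > 0 and r.id not in {k.id for k in kept}
    ]

    # Step 2: primer filter; step 3 orientation
    oriented: list[NucSequence] = []
    breakdown: dict[str, int] = {}
    no_primer: list[str] = []
    if primers is not None:
        for read in length_kept:
            assignment = _pre.assign_primer(
                read, primers, config.primer_max_edit_fraction
            )
            if assignment is None:
                no_primer.append(read.id)
                continue
            key = f"{assignment.target_element}_{assignment.direction}"
            breakdown[key] = breakdown.get(key, 0) + 1
            oriented.append(_pre.orient_read(read, assignment))
    else:
        oriented = list(length_kept)
    report.n_after_primer = len(oriented)
    report.primer_breakdown = breakdown
    report.discarded["no_primer"] = no_primer

    # Step 3: dereplicate and cluster
    uniques = _cluster.dereplicate(oriented)
    report.n_unique = len(uniques)
    clusters = _cluster.greedy_cluster(uniques, config.cluster_min_identity)
    report.clusters = clusters
    report.n_clusters = len(clusters)
    reads_by_id = {r.id: r for r in oriented}
    report.membership_tsv = (
        _cluster.membership_table(clusters, reads_by_id) if clusters else
        "cluster_id\tread_id\trole\tidentity_to_centroid\n"
    )

    # Steps 4-6: the cascade, one record per representative
    report.bin_counts = {label: 0 for label in BIN_LABELS}
    for cl in clusters:
        rep = _cluster.representative(cl, reads_by_id)
        record = classify_read(rep, dbs, config)
        record.cluster_size = cl.read_count
        report.records.append(record)
        report.representatives.append(rep)
        report.bin_counts[record.bin] += 1

    report.validate()
    return report
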