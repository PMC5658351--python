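"""Seeded synthetic-data generator for the whole enrichment + sequencing stack.

The generator emulates, end to end, what the wet protocol and the sequencer
hand to the analysis pipeline:

* annotated GMO **constructs** — host flanks around an ordered series of
  transgenic elements, with matching feature annotations;
* **enrichment fragments** — single-stranded molecules starting at a nested
  enrichment-primer site and extending in the enrichment direction for a
  geometric length (per-base continuation probability ``1 - stop_prob``),
  then dressed with the anchor adaptor and a homopolymer tail, exactly the
  fixtures the trimming step must remove;
* **subreads** — per-base independent errors at long-read rates (defaults:
  10% insertions, 5% deletions, 1% substitutions, giving the familiar
  low-to-mid-80s single-pass accuracy);
* **consensus reads** — a position-wise majority consensus over >= 4 passes,
  whose residual error emerges from the voting rather than from a separate
  error model.

Every emitted read carries provenance (source construct, target, direction,
true fragment coordinates, pass count), sufficient to score every decision
the pipeline makes.  A fixed seed reproduces the run bit for bit.

The default mixture mirrors an uneven four-component reference set: one
dominant event at 97% of the DNA mass and three at 1% each (roughly
35600/370/370/430 haploid copies in 200 ng), read shares of 368:15 between
the two enrichment targets and 7:1 between upstream and downstream
reactions, 411 consensus reads of which 18 are primer-free background.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import edlib
import numpy as np
import pandas as pd

from .preprocess import DIRECTIONS, TARGETS, PrimerPair, PrimerSet
from .refdb import (
    AnnotatedReference,
    DatabaseSet,
    DatabaseError,
    ElementRecord,
    Feature,
    dedupe_elements,
)
from .seqcore import NucSequence, revcomp, reverse_complement

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    pass


def derive_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` uncorrelated child seeds (< 2**31) from one master seed.

    Scenario construction and read generation must never share a generator
    stream: with a shared seed, a background read can reproduce construct
    sequence verbatim because both consumed the same underlying draws.
    """
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s % (2**31 - 1)) for s in state]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstructSpec:
    """Ordered element tokens plus host flanks defining one construct."""

    name: str
    elements: tuple[tuple[str, str], ...]  # (element_name, strand)
    flank5: int = 300
    flank3: int = 300
    spacer: int = 0  # intervening host-derived bases between elements
    host: str = "host"

    def __post_init__(self) -> None:
        if not self.elements:
            raise SimulationError(f"{self.name}: construct needs >= 1 element")
        if self.flank5 < 0 or self.flank3 < 0 or self.spacer < 0:
            raise SimulationError(f"{self.name}: negative flank or spacer length")


@dataclass(frozen=True)
class MixtureSpec:
    """Mixture composition and read-share structure of a simulated run."""

    components: tuple[tuple[ConstructSpec, int], ...]  # (construct, copy count)
    background_read_count: int = 18
    # read share per (target, direction); must sum to 1
    target_shares: tuple[tuple[tuple[str, str], float], ...] = (
        (("p35S", "up"), (368 / 383) * (7 / 8)),
        (("p35S", "down"), (368 / 383) * (1 / 8)),
        (("tNOS", "up"), (15 / 383) * (7 / 8)),
        (("tNOS", "down"), (15 / 383) * (1 / 8)),
    )

    def __post_init__(self) -> None:
        if any(c < 0 for _, c in self.components):
            raise SimulationError("negative copy count")
        total = sum(share for _, share in self.target_shares)
        if not np.isclose(total, 1.0):
            raise SimulationError(f"target shares sum to {total}, expected 1")

    def shares(self) -> dict[tuple[str, str], float]:
        return dict(self.target_shares)


@dataclass(frozen=True)
class ErrorModel:
    """Per-base independent subread error rates."""

    insertion_rate: float = 0.10
    deletion_rate: float = 0.05
    substitution_rate: float = 0.01

    def __post_init__(self) -> None:
        rates = (self.insertion_rate, self.deletion_rate, self.substitution_rate)
        if any(not (0.0 <= r < 1.0) for r in rates):
            raise SimulationError("error rates must lie in [0, 1)")
        if self.deletion_rate + self.substitution_rate >= 1.0:
            raise SimulationError("deletion + substitution rates must be < 1")


ZERO_ERRORS = ErrorModel(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class Fragment:
    """One enrichment fragment, already dressed with adaptor and tail."""

    sequence: str          # adaptor + tail + fragment, 5'->3'
    insert: str            # the fragment proper (starts with the nested primer)
    construct: str
    target: str
    direction: str
    frag_start: int        # 1-based inclusive span on the construct reference
    frag_end: int
    is_rc: bool            # True when the insert is the reverse complement
                           # of the forward reference span (upstream reads)


# ---------------------------------------------------------------------------
# Construct assembly
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n)) if n else ""


def build_construct(
    spec: ConstructSpec,
    element_db: Sequence[ElementRecord],
    rng: np.random.Generator,
) -> AnnotatedReference:
    """Assemble a construct reference: flank + elements (+ spacers) + flank.

    Minus-strand tokens are inserted as the reverse complement of the
    element; one feature is emitted per token.  Deterministic for a fixed
    generator state.
    """
    by_name = {e.element_name: e for e in element_db}
    parts: list[str] = [_random_bases(rng, spec.flank5)]
    features: list[Feature] = []
    pos = spec.flank5
    for i, (name, strand) in enumerate(spec.elements):
        if name not in by_name:
            raise SimulationError(f"{spec.name}: unknown element token {name!r}")
        if i and spec.spacer:
            parts.append(_random_bases(rng, spec.spacer))
            pos += spec.spacer
        element = by_name[name]
        bases = element.bases if strand == "+" else revcomp(element.bases)
        parts.append(bases)
        features.append(
            Feature(name, element.class_code, pos + 1, pos + len(bases), strand)
        )
        pos += len(bases)
    parts.append(_random_bases(rng, spec.flank3))
    return AnnotatedReference(spec.name, "".join(parts), tuple(features))


# ---------------------------------------------------------------------------
# Fragment sampling
# ---------------------------------------------------------------------------

def _largest_remainder(weights: Sequence[float], total: int) -> list[int]:
    """Apportion ``total`` items proportionally to ``weights`` (deterministic)."""
    weights = np.asarray(weights, dtype=float)
    if total == 0 or weights.sum() == 0:
        return [0] * len(weights)
    quotas = weights / weights.sum() * total
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    for idx in order[:remainder]:
        counts[idx] += 1
    return counts.tolist()


def _nested_site(
    ref: AnnotatedReference, primers: PrimerSet, target: str, direction: str
) -> tuple[int, int]:
    """0-based half-open span of the nested primer site on the forward strand.

    Downstream reactions extend rightward from a forward occurrence of the
    primer; upstream reactions extend leftward from a reverse-complement
    occurrence.
    """
    primer = primers.nested(target, direction)
    probe = primer if direction == "down" else revcomp(primer)
    at = ref.bases.find(probe)
    if at < 0:
        raise SimulationError(
            f"nested {target} {direction} primer not found in {ref.id}"
        )
    return at, at + len(probe)


def has_target(ref: AnnotatedReference, primers: PrimerSet, target: str,
               direction: str) -> bool:
    try:
        _nested_site(ref, primers, target, direction)
        return True
    except SimulationError:
        return False


def _draw_fragment(
    ref: AnnotatedReference,
    primers: PrimerSet,
    target: str,
    direction: str,
    stop_prob: float,
    rng: np.random.Generator,
    tail_len_range: tuple[int, int] = (10, 20),
) -> Fragment:
    a, b = _nested_site(ref, primers, target, direction)
    if stop_prob > 0:
        extension = int(rng.geometric(stop_prob))
    else:
        extension = len(ref)  # runs off the reference end
    if direction == "down":
        end = min(len(ref.bases), b + extension)
        span = (a, end)
        insert = ref.bases[a:end]
        is_rc = False
    else:
        start = max(0, a - extension)
        span = (start, b)
        insert = revcomp(ref.bases[start:b])
        is_rc = True
    tail_len = int(rng.integers(tail_len_range[0], tail_len_range[1] + 1))
    tail_char = "G" if primers.tail_base == "C" else "C"
    sequence = primers.anchor_adaptor + tail_char * tail_len + insert
    return Fragment(
        sequence=sequence,
        insert=insert,
        construct=ref.id,
        target=target,
        direction=direction,
        frag_start=span[0] + 1,
        frag_end=span[1],
        is_rc=is_rc,
    )


def sample_fragments(
    refs: Sequence[AnnotatedReference],
    mixture: MixtureSpec,
    primers: PrimerSet,
    n_fragments: int,
    stop_prob: float,
    rng: np.random.Generator,
) -> list[Fragment]:
    """Draw enrichment fragments for a mixture.

    Counts are apportioned deterministically: first across the four
    (target, direction) reactions by their read shares, then across the
    constructs carrying that target in proportion to copy number.  Only the
    fragment lengths (and tail lengths) are random.
    """
    by_name = {r.id: r for r in refs}
    copies = {spec.name: count for spec, count in mixture.components}
    for name in copies:
        if name not in by_name:
            raise SimulationError(f"no reference for mixture component {name}")
    reaction_items = list(mixture.shares().items())
    reaction_counts = _largest_remainder([s for _, s in reaction_items], n_fragments)
    fragments: list[Fragment] = []
    for ((target, direction), _share), n_reaction in zip(reaction_items, reaction_counts):
        eligible = [
            name for name in copies
            if has_target(by_name[name], primers, target, direction)
        ]
        if not eligible or n_reaction == 0:
            continue
        construct_counts = _largest_remainder(
            [copies[name] for name in eligible], n_reaction
        )
        for name, n_construct in zip(eligible, construct_counts):
            for _ in range(n_construct):
                fragments.append(
                    _draw_fragment(
                        by_name[name], primers, target, direction, stop_prob, rng
                    )
                )
    return fragments


# ---------------------------------------------------------------------------
# Subread errors and consensus
# ---------------------------------------------------------------------------

def corrupt_subread(
    seq: str, model: ErrorModel, rng: np.random.Generator
) -> str:
    """Apply per-base independent insertion/deletion/substitution errors.

    Before each template base an extra random base is inserted with the
    insertion rate; the base itself is dropped with the deletion rate or
    replaced with a different base with the substitution rate.  Expected
    output length is ``len(seq) * (1 + i - d)``.
    """
    n = len(seq)
    if n == 0:
        return seq
    ins = rng.random(n) < model.insertion_rate
    dele = rng.random(n) < model.deletion_rate
    sub = rng.random(n) < model.substitution_rate
    ins_bases = rng.choice(_BASES, size=int(ins.sum()))
    sub_shift = rng.integers(1, 4, size=n)  # substitute with a *different* base
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    out: list[str] = []
    ins_i = 0
    for i, ch in enumerate(seq):
        if ins[i]:
            out.append(str(ins_bases[ins_i]))
            ins_i += 1
        if dele[i]:
            continue
        if sub[i] and ch in base_index:
            out.append(str(_BASES[(base_index[ch] + sub_shift[i]) % 4]))
        else:
            out.append(ch)
    return "".join(out)


def _nice_alignment(query: str, target: str) -> tuple[str, str]:
    res = edlib.align(query, target, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, query, target)
    return nice["query_aligned"], nice["target_aligned"]


def ccs_consensus(
    subreads: Sequence[str], min_passes: int = 4
) -> Optional[NucSequence]:
    """Position-wise majority consensus of subreads from one template.

    ``None`` when fewer than ``min_passes`` subreads are available.  The
    subread closest to all others (smallest total edit distance, first on
    ties) serves as the scaffold; every subread is aligned to it end to end
    and votes per scaffold column (base or deletion) and per inter-column
    junction (insertion).  Majority wins; ties keep the scaffold base.
    Positions where every subread agrees get Phred 40, all others Phred 20.
    """
    subreads = [s for s in subreads if s]
    k = len(subreads)
    if k < min_passes:
        return None
    if k == 1 or len(set(subreads)) == 1:
        return NucSequence("consensus", subreads[0], (40,) * len(subreads[0]))

    totals = [0] * k
    for i in range(k):
        for j in range(i + 1, k):
            d = edlib.align(subreads[i], subreads[j], mode="NW",
                            task="distance")["editDistance"]
            totals[i] += d
            totals[j] += d
    scaffold = subreads[min(range(k), key=lambda i: (totals[i], i))]
    n = len(scaffold)

    votes: list[collections.Counter] = [collections.Counter() for _ in range(n)]
    inserts: list[dict[int, str]] = []
    for sub in subreads:
        q_aln, t_aln = _nice_alignment(sub, scaffold)
        pos = 0
        my_inserts: dict[int, str] = {}
        pending = ""
        for qc, tc in zip(q_aln, t_aln):
            if tc == "-":
                pending += qc
                continue
            if pending:
                my_inserts[pos] = pending
                pending = ""
            votes[pos][qc] += 1  # qc may be '-', a deletion vote
            pos += 1
        if pending:
            my_inserts[pos] = pending
        inserts.append(my_inserts)

    consensus: list[str] = []
    quals: list[int] = []
    majority = k // 2 + 1

    def emit_insertion(position: int) -> None:
        strings = [m[position] for m in inserts if position in m]
        if len(strings) >= majority:
            counter = collections.Counter(strings)
            top = max(counter.items(), key=lambda kv: (kv[1], kv[0]))
            best = min(s for s, c in counter.items() if c == counter[top[0]])
            unanimous = len(strings) == k and len(counter) == 1
            for ch in best:
                consensus.append(ch)
                quals.append(40 if unanimous else 20)

    for pos in range(n):
        emit_insertion(pos)
        counter = votes[pos]
        top_count = max(counter.values())
        winners = sorted(c for c, cnt in counter.items() if cnt == top_count)
        choice = scaffold[pos] if scaffold[pos] in winners else winners[0]
        if choice == "-":
            continue
        consensus.append(choice)
        quals.append(40 if counter.get(choice, 0) == k else 20)
    emit_insertion(n)

    return NucSequence("consensus", "".join(consensus), tuple(quals))


# ---------------------------------------------------------------------------
# End-to-end run
# ---------------------------------------------------------------------------

PassesDistribution = Union[tuple[int, int], Callable[[np.random.Generator], int]]


def _draw_passes(dist: PassesDistribution, rng: np.random.Generator) -> int:
    if callable(dist):
        return int(dist(rng))
    lo, hi = dist
    return int(rng.integers(lo, hi + 1))


PROVENANCE_COLUMNS = [
    "read_id", "construct", "target", "direction", "frag_start", "frag_end",
    "is_rc", "n_passes", "is_background", "is_artifact", "flipped", "read_len",
]


def simulate_run(
    refs: Sequence[AnnotatedReference],
    mixture: MixtureSpec,
    primers: PrimerSet,
    error_model: ErrorModel = ErrorModel(),
    n_reads: int = 411,
    passes_distribution: PassesDistribution = (4, 12),
    stop_prob: float = 0.001,
    artifact_count: int = 1,
    seed: int = 0,
) -> tuple[list[NucSequence], pd.DataFrame]:
    """Generate a full synthetic sequencing run with per-read provenance.

    ``n_reads`` counts all emitted consensus reads, including
    ``mixture.background_read_count`` primer-free host fragments and
    ``artifact_count`` tandem-duplication (ligation artifact) reads built
    from the most abundant component.  Reads whose pass count falls below
    the consensus minimum are not emitted.  Bitwise reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    n_background = mixture.background_read_count
    n_enriched = n_reads - n_background - artifact_count
    if n_enriched < 0:
        raise SimulationError("n_reads smaller than background + artifact counts")

    fragments = sample_fragments(refs, mixture, primers, n_enriched, stop_prob, rng)

    templates: list[tuple[str, dict]] = []
    for frag in fragments:
        templates.append(
            (
                frag.sequence,
                dict(
                    construct=frag.construct,
                    target=frag.target,
                    direction=frag.direction,
                    frag_start=frag.frag_start,
                    frag_end=frag.frag_end,
                    is_rc=frag.is_rc,
                    is_background=False,
                    is_artifact=False,
                ),
            )
        )

    # Ligation artifacts: the same molecule ligated twice in a row, so the
    # raw read shows adaptor + tail + insert repeated head to tail.
    if artifact_count and mixture.components:
        donor = max(mixture.components, key=lambda item: item[1])[0]
        ref = next(r for r in refs if r.id == donor.name)
        for _ in range(artifact_count):
            frag = _draw_fragment(ref, primers, "p35S", "up", stop_prob, rng)
            templates.append(
                (
                    frag.sequence + frag.sequence,
                    dict(
                        construct=frag.construct,
                        target=frag.target,
                        direction=frag.direction,
                        frag_start=frag.frag_start,
                        frag_end=frag.frag_end,
                        is_rc=frag.is_rc,
                        is_background=False,
                        is_artifact=True,
                    ),
                )
            )

    tail_char = "G" if primers.tail_base == "C" else "C"
    for _ in range(n_background):
        insert = _random_bases(rng, int(rng.integers(300, 1500)))
        tail = tail_char * int(rng.integers(10, 21))
        templates.append(
            (
                primers.anchor_adaptor + tail + insert,
                dict(
                    construct="background",
                    target="none",
                    direction="none",
                    frag_start=0,
                    frag_end=0,
                    is_rc=False,
                    is_background=True,
                    is_artifact=False,
                ),
            )
        )

    reads: list[NucSequence] = []
    rows: list[dict] = []
    for serial, (template, meta) in enumerate(templates):
        n_passes = _draw_passes(passes_distribution, rng)
        subreads = [corrupt_subread(template, error_model, rng)
                    for _ in range(n_passes)]
        consensus = ccs_consensus(subreads, min_passes=4)
        if consensus is None:
            continue
        flipped = bool(rng.random() < 0.5)
        read_id = f"S{serial:06d}"
        read = NucSequence(read_id, consensus.bases, consensus.qualities)
        if flipped:
            read = reverse_complement(read)
        reads.append(read)
        rows.append(
            dict(
                read_id=read_id,
                n_passes=n_passes,
                flipped=flipped,
                read_len=len(read),
                **meta,
            )
        )
    provenance = pd.DataFrame(rows, columns=PROVENANCE_COLUMNS)
    return reads, provenance


# ---------------------------------------------------------------------------
# The bundled demonstration scenario
# ---------------------------------------------------------------------------

EVENT_WINDOW = 92  # junction window length of the event-specific sequences


@dataclass
class Scenario:
    """A complete simulated study: primers, references, databases, mixture."""

    primers: PrimerSet
    refs: list[AnnotatedReference]          # all constructs, incl. the model UGMO
    dbs: DatabaseSet                        # event + CAF + element databases
    mixture: MixtureSpec
    event_windows: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    # event id -> (construct, start, end), 1-based inclusive

    def construct(self, name: str) -> AnnotatedReference:
        return next(r for r in self.refs if r.id == name)


def _planted_element(
    rng: np.random.Generator,
    length: int,
    plants: Sequence[tuple[int, str]] = (),
) -> str:
    bases = list(_random_bases(rng, length))
    for at, piece in plants:
        bases[at : at + len(piece)] = list(piece)
    return "".join(bases)


def default_primer_set(rng: np.random.Generator) -> PrimerSet:
    """Synthetic 24-nt LE/nested primer pairs for both targets and directions."""
    def primer() -> str:
        return _random_bases(rng, 24)

    primers = {
        (target, direction): PrimerPair(le_primer=primer(), nested_primer=primer())
        for target in TARGETS
        for direction in DIRECTIONS
    }
    adaptor = _random_bases(rng, 36)
    return PrimerSet(primers=primers, anchor_adaptor=adaptor, tail_base="C")


def make_demo_scenario(seed: int = 0) -> Scenario:
    """Build the bundled four-component study: one dominant fully-known event,
    two minor known events, and one model UGMO present only in the element
    database, mixed 97/1/1/1 by mass.

    The known constructs have CAF references and event-specific junction
    windows (the 5' junction for the dominant event, the 3' junction for the
    minor ones); the UGMO carries the order tNOS - nptII - p35S with short
    unannotated spacers, so its reads can only be explained element by
    element.
    """
    rng = np.random.default_rng(seed)
    primers = default_primer_set(rng)

    # Enrichment target elements with the primer sites planted inside:
    # downstream sites read forward, upstream sites appear reverse
    # complemented (the upstream primer extends leftward along the construct).
    p35s = _planted_element(
        rng,
        350,
        [
            (76, revcomp(primers.nested("p35S", "up"))),
            (100, revcomp(primers.primers[("p35S", "up")].le_primer)),
            (126, primers.primers[("p35S", "down")].le_primer),
            (150, primers.nested("p35S", "down")),
        ],
    )
    tnos = _planted_element(
        rng,
        250,
        [
            (48, revcomp(primers.nested("tNOS", "up"))),
            (72, revcomp(primers.primers[("tNOS", "up")].le_primer)),
            (100, primers.primers[("tNOS", "down")].le_primer),
            (124, primers.nested("tNOS", "down")),
        ],
    )
    catalog = [
        ElementRecord("p35S", "P", p35s, "synthetic"),
        ElementRecord("tNOS", "T", tnos, "synthetic"),
        ElementRecord("hsp70", "I", _random_bases(rng, 200), "synthetic"),
        ElementRecord("cry1Ab", "CS", _random_bases(rng, 550), "synthetic"),
        ElementRecord("cry2Ab2", "CS", _random_bases(rng, 500), "synthetic"),
        ElementRecord("cp4epsps", "CS", _random_bases(rng, 600), "synthetic"),
        ElementRecord("nptII", "CS", _random_bases(rng, 400), "synthetic"),
        ElementRecord("uidA", "CS", _random_bases(rng, 450), "synthetic"),
        ElementRecord("ctp", "TP", _random_bases(rng, 150), "synthetic"),
    ]

    specs = [
        ConstructSpec(
            "MAIZE-A",
            (("p35S", "+"), ("hsp70", "+"), ("cry1Ab", "+")),
            flank5=400, flank3=400, host="maize",
        ),
        ConstructSpec(
            "MAIZE-B",
            (("p35S", "+"), ("cry2Ab2", "+"), ("tNOS", "+")),
            flank5=350, flank3=350, host="maize",
        ),
        ConstructSpec(
            "MAIZE-C",
            (("cp4epsps", "+"), ("tNOS", "+"), ("p35S", "+"), ("cry1Ab", "+")),
            flank5=300, flank3=300, host="maize",
        ),
        ConstructSpec(
            "COTTON-U",
            (("tNOS", "+"), ("nptII", "+"), ("p35S", "+")),
            flank5=300, flank3=300, spacer=20, host="cotton",
        ),
    ]
    refs = [build_construct(spec, catalog, rng) for spec in specs]

    # Event-specific junction windows: insert/flank boundaries no construct
    # shares.  The dominant event is identified at its 5' junction (reached
    # by upstream enrichment), the minor known events at their 3' junctions.
    event_db: list[NucSequence] = []
    event_windows: dict[str, tuple[str, int, int]] = {}
    half = EVENT_WINDOW // 2
    for ref, side in (("MAIZE-A", "5p"), ("MAIZE-B", "3p"), ("MAIZE-C", "3p")):
        reference = next(r for r in refs if r.id == ref)
        spec = next(s for s in specs if s.name == ref)
        if side == "5p":
            junction = spec.flank5
        else:
            junction = len(reference) - spec.flank3
        start, end = junction - half, junction + half  # 0-based half-open
        window = reference.bases[start:end]
        event_id = f"EVENT-{ref}"
        event_db.append(NucSequence(event_id, window))
        event_windows[event_id] = (ref, start + 1, end)

    caf_db = [r for r in refs if r.id != "COTTON-U"]
    element_db = dedupe_elements(catalog)
    dbs = DatabaseSet(event_db=event_db, caf_db=caf_db, element_db=element_db)

    copies = {"MAIZE-A": 35596, "MAIZE-B": 367, "MAIZE-C": 367, "COTTON-U": 429}
    mixture = MixtureSpec(
        components=tuple((spec, copies[spec.name]) for spec in specs)
    )
    return Scenario(
        primers=primers,
        refs=refs,
        dbs=dbs,
        mixture=mixture,
        event_windows=event_windows,
    )


# ---------------------------------------------------------------------------
# Ground-truth helpers for scoring pipeline output against provenance
# ---------------------------------------------------------------------------

def score_zero_error_run(scenario: "Scenario", provenance: pd.DataFrame, report):
    """Score a zero-error pipeline run against the simulator's provenance.

    Returns recovery metrics: the fraction of event-window-covering reads
    confirmed as events, the fraction of model-UGMO reads binned as
    unknown_parts, the fraction of those whose planted element order was
    reconstructed exactly, and the number of background reads that slipped
    through the primer filter.  Each read inherits the bin of its cluster
    representative.
    """
    record_of_read: dict[str, object] = {}
    for cl, record in zip(report.clusters, report.records):
        for rid in cl.member_read_ids():
            record_of_read[rid] = record

    caf_names = {ref.id for ref in scenario.dbs.caf_db}
    event_expected = event_correct = 0
    ugmo_total = ugmo_bin_correct = ugmo_order_correct = 0
    background_passed = 0
    for _, row in provenance.iterrows():
        record = record_of_read.get(row["read_id"])
        if row["is_background"]:
            background_passed += record is not None
            continue
        expected = expected_bin(scenario, row)
        if expected == "confirmed_event":
            event_expected += 1
            event_correct += record is not None and record.bin == "confirmed_event"
        is_ugmo = row["construct"] not in caf_names and not row["is_artifact"]
        if is_ugmo:
            ugmo_total += 1
            if record is not None and record.bin == "unknown_parts":
                ugmo_bin_correct += 1
                got = tuple(record.element_order.tokens)
                if got == expected_element_tokens(scenario, row):
                    ugmo_order_correct += 1
    return {
        "event_reads_expected": event_expected,
        "event_recovery_pct": 100.0 * event_correct / event_expected
        if event_expected else float("nan"),
        "ugmo_reads": ugmo_total,
        "ugmo_bin_pct": 100.0 * ugmo_bin_correct / ugmo_total
        if ugmo_total else float("nan"),
        "ugmo_order_pct": 100.0 * ugmo_order_correct / ugmo_total
        if ugmo_total else float("nan"),
        "background_reads_passing_primer_filter": background_passed,
    }

def expected_bin(
    scenario: Scenario,
    row: pd.Series,
    min_overlap_columns: int = 90,  # ceil(0.97 * 92)
) -> Optional[str]:
    """The bin a zero-error read must land in, from its provenance alone.

    Returns ``None`` for background reads (they never reach a bin) and for
    reads close to a threshold boundary, where the outcome legitimately
    depends on alignment details.
    """
    if row["is_background"]:
        return None
    construct = row["construct"]
    span = (int(row["frag_start"]), int(row["frag_end"]))
    for _eid, (ref_name, w_start, w_end) in scenario.event_windows.items():
        if ref_name != construct:
            continue
        overlap = min(span[1], w_end) - max(span[0], w_start) + 1
        if overlap >= min_overlap_columns:
            return "confirmed_event"
        if overlap > min_overlap_columns - 10:
            return None  # too close to the coverage boundary to call
    if any(ref.id == construct for ref in scenario.dbs.caf_db):
        return "only_known_information"
    return "unknown_parts"


def expected_element_tokens(
    scenario: Scenario,
    row: pd.Series,
    min_hit_length: int = 30,
    gap_min: int = 1,
) -> tuple[str, ...]:
    """The element-order tokens a zero-error read must reconstruct.

    Elements of the source construct overlapping the true fragment span by
    at least ``min_hit_length`` bases, ordered along the read (reversed with
    flipped strands for upstream fragments), with ``nnn`` between
    non-abutting neighbours.
    """
    ref = scenario.construct(row["construct"])
    span = (int(row["frag_start"]), int(row["frag_end"]))
    overlapped = []
    for f in sorted(ref.features, key=lambda f: f.start):
        lo, hi = max(span[0], f.start), min(span[1], f.end)
        if hi - lo + 1 >= min_hit_length:
            overlapped.append((f, lo, hi))
    if row["is_rc"]:
        overlapped = [
            (f, lo, hi) for f, lo, hi in reversed(overlapped)
        ]
        flip = {"+": "-", "-": "+"}
        items = [(f.name, flip[f.strand], span[1] - hi + 1, span[1] - lo + 1)
                 for f, lo, hi in overlapped]
    else:
        items = [(f.name, f.strand, lo, hi) for f, lo, hi in overlapped]
    tokens: list[str] = []
    prev_end = None
    for name, strand, lo, hi in items:
        if prev_end is not None and lo - prev_end - 1 >= gap_min:
            tokens.append("nnn")
        tokens.append(name if strand == "+" else f"{name}(-)")
        prev_end = hi
    return tuple(tokens)
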