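from __future__ import annotations

import numpy as np
import pytest

from alfwalk.refdb import (
    AnnotatedReference,
    BUNDLED_EVENT_TEMPLATES,
    DatabaseError,
    DatabaseSet,
    ElementRecord,
    Feature,
    annotate_fasta,
    build_event_query,
    dedupe_elements,
    extract_elements,
    load_database_set,
    merge_references,
    read_gff3_features,
    write_database_set,
    write_fasta,
    write_gff3,
)
from alfwalk.seqcore import NucSequence, revcomp
from conftest import random_bases
from oracles import best_suffix_prefix_overlap


class TestEventTemplates:
    @pytest.mark.parametrize(
        "event,expected_length",
        [("MON810", 92), ("MON89034", 77), ("MON88017", 95), ("MON15985", 82)],
    )
    def test_bundled_template_lengths(self, event, expected_length):
        template = build_event_query(event, BUNDLED_EVENT_TEMPLATES[event])
        assert len(template) == expected_length

    def test_unknown_runs_rendered_as_n(self):
        template = build_event_query("X", ("ACGT", 3, "GGTT"))
        assert template.assembled_query == "ACGTNNNGGTT"
        assert len(template) == sum(
            len(s) if isinstance(s, str) else s for s in template.segments
        )

    def test_single_known_segment(self):
        assert build_event_query("X", ("ACGTAC",)).assembled_query == "ACGTAC"

    def test_zero_length_segment_rejected(self):
        with pytest.raises(DatabaseError):
            build_event_query("X", ("ACGT", 2, ""))
        with pytest.raises(DatabaseError):
            build_event_query("X", (4, 2))


class TestExtractElements:
    def test_full_span_feature(self, rng):
        bases = random_bases(rng, 40)
        ref = AnnotatedReference("r", bases, (Feature("e", "P", 1, 40, "+"),))
        (rec,) = extract_elements(ref)
        assert rec.bases == bases
        assert rec.source == "r"

    def test_minus_strand_feature_reverse_complemented(self, rng):
        bases = random_bases(rng, 40)
        ref = AnnotatedReference("r", bases, (Feature("e", "T", 11, 30, "-"),))
        (rec,) = extract_elements(ref)
        assert rec.bases == revcomp(bases[10:30])

    def test_adjacent_features_reconstruct_span(self, rng):
        bases = random_bases(rng, 20)
        ref = AnnotatedReference(
            "r", bases, (Feature("a", "P", 1, 10, "+"), Feature("b", "T", 11, 20, "+"))
        )
        rec_a, rec_b = extract_elements(ref)
        assert rec_a.bases + rec_b.bases == bases[:20]

    def test_out_of_bounds_feature_rejected(self):
        with pytest.raises(DatabaseError, match="bad"):
            AnnotatedReference("r", "ACGTACGT", (Feature("bad", "P", 5, 20, "+"),))

    def test_reinsertion_roundtrip(self, rng):
        # cutting elements out and pasting them back at their coordinates
        # reconstructs the annotated spans exactly
        bases = random_bases(rng, 100)
        feats = (Feature("a", "P", 6, 35, "+"), Feature("b", "CS", 41, 90, "-"))
        ref = AnnotatedReference("r", bases, feats)
        for feat, rec in zip(feats, extract_elements(ref)):
            piece = rec.bases if feat.strand == "+" else revcomp(rec.bases)
            assert bases[feat.start - 1 : feat.end] == piece


class TestDedupeElements:
    def test_longest_kept(self, rng):
        short = ElementRecord("p35S", "P", random_bases(rng, 300), "a")
        long = ElementRecord("p35S", "P", random_bases(rng, 350), "b")
        assert dedupe_elements([short, long]) == [long]

    def test_unique_names_untouched(self, rng):
        records = [
            ElementRecord(f"e{i}", "CS", random_bases(rng, 50), "a") for i in range(4)
        ]
        assert dedupe_elements(records) == records

    def test_equal_length_keeps_first(self, rng):
        first = ElementRecord("x", "P", random_bases(rng, 50), "a")
        second = ElementRecord("x", "P", random_bases(rng, 50), "b")
        assert dedupe_elements([first, second]) == [first]

    def test_output_size_is_distinct_name_count(self, rng):
        records = [
            ElementRecord(f"e{i % 3}", "CS", random_bases(rng, int(rng.integers(30, 90))), "a")
            for i in range(9)
        ]
        assert len(dedupe_elements(records)) == 3


class TestMergeReferences:
    def test_exact_four_base_overlap(self):
        merged = merge_references(
            NucSequence("a", "AAAATTTT"), NucSequence("b", "TTTTGGGG"), min_overlap=4
        )
        assert merged.bases == "AAAATTTTGGGG"

    def test_no_overlap_rejected_with_diagnostics(self):
        with pytest.raises(DatabaseError, match="best candidate"):
            merge_references(
                NucSequence("a", "AAAACCCC"), NucSequence("b", "GGGGTTTT"), min_overlap=4
            )

    def test_planted_75nt_junction(self, rng):
        # the classic two-reference case: a 75-nt exact overlap at the junction
        junction = random_bases(rng, 75)
        a = NucSequence("a", random_bases(rng, 125) + junction)
        b = NucSequence("b", junction + random_bases(rng, 125))
        oracle = best_suffix_prefix_overlap(a.bases, b.bases, 20, 0)
        assert oracle == 75
        merged = merge_references(a, b, min_overlap=20, max_mismatches=0)
        assert len(merged) == 200 + 200 - 75

    def test_mismatch_budget(self, rng):
        junction = random_bases(rng, 50)
        damaged = list(junction)
        damaged[25] = {"A": "C", "C": "G", "G": "T", "T": "A"}[damaged[25]]
        a = NucSequence("a", random_bases(rng, 100) + junction)
        b = NucSequence("b", "".join(damaged) + random_bases(rng, 100))
        with pytest.raises(DatabaseError):
            merge_references(a, b, min_overlap=40, max_mismatches=0)
        merged = merge_references(a, b, min_overlap=40, max_mismatches=1)
        assert len(merged) == 150 + 150 - 50
        # bases of the first sequence win inside the overlap
        assert merged.bases[100:150] == junction


class TestDatabaseIO:
    def test_gff3_roundtrip(self, rng, tmp_path):
        ref = AnnotatedReference(
            "ref1",
            random_bases(rng, 120),
            (Feature("p35S", "P", 11, 60, "+"), Feature("tNOS", "T", 71, 110, "-")),
        )
        gff = tmp_path / "x.gff3"
        write_gff3([ref], gff)
        assert gff.read_text().startswith("##gff-version 3")
        feats = read_gff3_features(gff)
        assert feats["ref1"] == list(ref.features)

    def test_database_set_roundtrip(self, rng, tmp_path):
        ref = AnnotatedReference(
            "caf1", random_bases(rng, 200), (Feature("p35S", "P", 21, 120, "+"),)
        )
        dbs = DatabaseSet(
            event_db=[NucSequence("ev1", random_bases(rng, 92))],
            caf_db=[ref],
            element_db=[ElementRecord("p35S", "P", random_bases(rng, 100), "caf1")],
        )
        write_database_set(dbs, tmp_path / "db")
        loaded = load_database_set(tmp_path / "db")
        assert [s.id for s in loaded.event_db] == ["ev1"]
        assert loaded.caf_db[0].features == ref.features
        assert loaded.element_db[0].element_name == "p35S"
        assert loaded.element_db[0].class_code == "P"

    def test_duplicate_ids_rejected(self, rng):
        seq = NucSequence("dup", random_bases(rng, 50))
        with pytest.raises(DatabaseError, match="event"):
            DatabaseSet(event_db=[seq, seq])

    def test_annotate_fasta(self, rng, tmp_path):
        ref = AnnotatedReference(
            "r1", random_bases(rng, 80), (Feature("e", "CS", 1, 50, "+"),)
        )
        write_fasta([ref.as_sequence()], tmp_path / "r.fasta")
        write_gff3([ref], tmp_path / "r.gff3")
        (loaded,) = annotate_fasta(tmp_path / "r.fasta", tmp_path / "r.gff3")
        assert loaded.bases == ref.bases
        assert loaded.features == ref.features
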