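from __future__ import annotations

import numpy as np
import pytest

from alfwalk.classify import (
    BIN_LABELS,
    ConfigError,
    PipelineConfig,
    annotate_intervals,
    classify_caf,
    classify_elements,
    classify_event,
    element_order,
    run_pipeline,
)
from alfwalk.refdb import AnnotatedReference, DatabaseSet, ElementRecord, Feature
from alfwalk.seqcore import NucSequence, revcomp, reverse_complement
from conftest import random_bases


def _mutate(bases: str, positions, rng=None) -> str:
    out = list(bases)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


@pytest.fixture
def event(rng) -> NucSequence:
    return NucSequence("EV", random_bases(rng, 92))


class TestClassifyEvent:
    def test_exact_embedded_event_confirms(self, rng, event):
        read = NucSequence(
            "r", random_bases(rng, 150) + event.bases + random_bases(rng, 150)
        )
        record = classify_event(read, [event])
        assert record is not None and record.bin == "confirmed_event"
        hit = record.hits[0]
        assert hit.identity_pct == pytest.approx(100.0)
        assert hit.subject_coverage_pct == pytest.approx(100.0)

    def test_six_substitutions_fall_below_identity(self, rng, event):
        positions = rng.choice(92, size=6, replace=False)
        damaged = _mutate(event.bases, positions)
        read = NucSequence("r", random_bases(rng, 100) + damaged + random_bases(rng, 100))
        assert classify_event(read, [event]) is None  # 86/92 = 93.5% < 95%

    def test_half_coverage_passes_through(self, rng, event):
        read = NucSequence("r", random_bases(rng, 100) + event.bases[:46] + random_bases(rng, 100))
        assert classify_event(read, [event]) is None

    def test_duplicated_event_recorded_twice(self, rng, event):
        unit = random_bases(rng, 60) + event.bases + random_bases(rng, 60)
        record = classify_event(NucSequence("r", unit + unit), [event])
        assert record is not None
        assert len(record.hits) == 2
        spans = sorted(h.query_span() for h in record.hits)
        assert spans[0][1] < spans[1][0]


class TestClassifyCaf:
    def test_exact_substring_fully_covered(self, rng):
        ref = AnnotatedReference("C1", random_bases(rng, 1200),
                                 (Feature("p35S", "P", 101, 400, "+"),))
        read = NucSequence("r", ref.bases[200:900])
        record = classify_caf(read, [ref])
        assert record is not None and record.bin == "only_known_information"
        assert record.hits[0].query_coverage_pct == pytest.approx(100.0)
        assert record.annotations == ["p35S"]

    def test_half_foreign_read_passes_through(self, rng):
        ref = AnnotatedReference("C1", random_bases(rng, 1000))
        read = NucSequence("r", ref.bases[:400] + random_bases(rng, 400))
        assert classify_caf(read, [ref]) is None

    def test_no_hit_passes_through(self, rng):
        ref = AnnotatedReference("C1", random_bases(rng, 500))
        assert classify_caf(NucSequence("r", random_bases(rng, 300)), [ref]) is None


class TestAnnotateIntervals:
    def _ref(self, rng):
        return AnnotatedReference(
            "R", random_bases(rng, 300),
            (Feature("a", "P", 1, 100, "+"), Feature("b", "T", 101, 200, "+")),
        )

    def _hit(self, rng, ref, s_start, s_end):
        from alfwalk.seqcore import LocalAlignment
        return LocalAlignment(
            "q", ref.id, "+", 1, s_end - s_start + 1, s_start, s_end,
            s_end - s_start + 1, s_end - s_start + 1, 0, 0, 50.0,
            s_end - s_start + 1, len(ref),
        )

    def test_spanning_hit_reports_both_in_order(self, rng):
        ref = self._ref(rng)
        names = [f.name for f, _ in annotate_intervals(self._hit(rng, ref, 50, 150), ref)]
        assert names == ["a", "b"]

    def test_unannotated_gap_is_empty(self, rng):
        ref = self._ref(rng)
        assert annotate_intervals(self._hit(rng, ref, 250, 280), ref) == []

    def test_single_base_overlap_included(self, rng):
        ref = self._ref(rng)
        out = annotate_intervals(self._hit(rng, ref, 100, 120), ref)
        assert [f.name for f, _ in out] == ["a", "b"]
        assert out[0][1] == (100, 100)


class TestElementOrder:
    @pytest.fixture
    def elements(self, rng):
        return [
            NucSequence("tNOS", random_bases(rng, 250)),
            NucSequence("nptII", random_bases(rng, 400)),
            NucSequence("p35S", random_bases(rng, 350)),
        ]

    def test_planted_order_with_gaps(self, rng, elements):
        tnos, nptii, p35s = (e.bases for e in elements)
        read = NucSequence(
            "r", tnos + random_bases(rng, 20) + nptii + random_bases(rng, 20) + p35s
        )
        order = element_order(read, elements)
        assert order.tokens == ("tNOS", "nnn", "nptII", "nnn", "p35S")
        assert str(order) == "tNOS - nnn - nptII - nnn - p35S"

    def test_abutting_elements_have_no_gap(self, rng, elements):
        tnos, nptii, _ = (e.bases for e in elements)
        order = element_order(NucSequence("r", tnos + nptii), elements)
        assert order.tokens == ("tNOS", "nptII")

    def test_reverse_complement_reverses_order_and_strands(self, rng, elements):
        tnos, nptii, p35s = (e.bases for e in elements)
        read = NucSequence(
            "r", tnos + random_bases(rng, 20) + nptii + random_bases(rng, 20) + p35s
        )
        order = element_order(reverse_complement(read), elements)
        assert order.tokens == ("p35S(-)", "nnn", "nptII(-)", "nnn", "tNOS(-)")


class TestClassifyElements:
    def test_partial_element_evidence_is_unknown_parts(self, rng):
        element = NucSequence("cry", random_bases(rng, 200))
        read = NucSequence("r", element.bases + random_bases(rng, 400))
        record = classify_elements(read, [element])
        assert record.bin == "unknown_parts"
        assert record.element_order.tokens[0] == "cry"

    def test_pure_random_read_is_only_unknown(self, rng):
        element = NucSequence("cry", random_bases(rng, 200))
        record = classify_elements(NucSequence("r", random_bases(rng, 500)), [element])
        assert record.bin == "only_unknown_information"
        assert not record.hits

    def test_fully_element_covered_read_is_unknown_parts(self, rng):
        a, b = NucSequence("ea", random_bases(rng, 300)), NucSequence("eb", random_bases(rng, 300))
        record = classify_elements(NucSequence("r", a.bases + b.bases), [a, b])
        assert record.bin == "unknown_parts"
        assert record.element_order.tokens == ("ea", "eb")


class TestRunPipeline:
    def test_empty_read_set(self, rng):
        dbs = DatabaseSet(
            event_db=[NucSequence("e", random_bases(rng, 92))],
            caf_db=[AnnotatedReference("c", random_bases(rng, 500))],
            element_db=[ElementRecord("x", "CS", random_bases(rng, 100), "c")],
        )
        report = run_pipeline([], dbs)
        assert report.n_input == 0
        assert report.n_clusters == 0
        assert all(report.bin_counts[label] == 0 for label in BIN_LABELS)

    def test_malformed_config_rejected_before_processing(self):
        with pytest.raises(ConfigError):
            PipelineConfig(cluster_min_identity=1.5)

    def test_bins_partition_representatives(self, zero_error_run):
        _reads, _prov, report = zero_error_run
        assert sum(report.bin_counts.values()) == report.n_clusters
        assert len(report.records) == report.n_clusters
        assert {r.bin for r in report.records} <= set(BIN_LABELS)

    def test_cluster_members_conserve_primer_passing_reads(self, zero_error_run):
        _reads, _prov, report = zero_error_run
        member_total = sum(c.read_count for c in report.clusters)
        assert member_total == report.n_after_primer

    def test_event_threshold_monotonicity(self, rng, scenario, zero_error_run):
        # lowering the event coverage bar can only add confirmed events
        from dataclasses import replace
        reads, _prov, report = zero_error_run
        relaxed_config = PipelineConfig(event_min_subject_coverage_pct=50.0, seed=7)
        relaxed = run_pipeline(reads, scenario.dbs, relaxed_config, scenario.primers)
        assert (
            relaxed.bin_counts["confirmed_event"]
            >= report.bin_counts["confirmed_event"]
        )
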