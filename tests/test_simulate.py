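from __future__ import annotations

import numpy as np
import pytest

from alfwalk.preprocess import trim_artificial
from alfwalk.refdb import ElementRecord
from alfwalk.seqcore import NucSequence, detect_tandem_repeat, global_identity
from alfwalk.simulate import (
    ZERO_ERRORS,
    ConstructSpec,
    ErrorModel,
    MixtureSpec,
    SimulationError,
    build_construct,
    ccs_consensus,
    corrupt_subread,
    default_primer_set,
    make_demo_scenario,
    sample_fragments,
    simulate_run,
)
from conftest import random_bases


@pytest.fixture
def catalog(rng):
    return [
        ElementRecord("p35S", "P", random_bases(rng, 200), "syn"),
        ElementRecord("tNOS", "T", random_bases(rng, 150), "syn"),
        ElementRecord("nptII", "CS", random_bases(rng, 300), "syn"),
    ]


class TestBuildConstruct:
    def test_length_and_features(self, rng, catalog):
        spec = ConstructSpec(
            "X", (("p35S", "+"), ("nptII", "+"), ("tNOS", "+")), flank5=100, flank3=100
        )
        ref = build_construct(spec, catalog, rng)
        assert len(ref) == 200 + 200 + 300 + 150
        assert [f.name for f in ref.features] == ["p35S", "nptII", "tNOS"]
        assert ref.features[0].start == 101

    def test_minus_strand_token_reverse_complemented(self, rng, catalog):
        from alfwalk.seqcore import revcomp

        spec = ConstructSpec("X", (("nptII", "-"),), flank5=10, flank3=10)
        ref = build_construct(spec, catalog, rng)
        element = next(e for e in catalog if e.element_name == "nptII")
        assert ref.bases[10:310] == revcomp(element.bases)

    def test_unknown_token_rejected(self, rng, catalog):
        spec = ConstructSpec("X", (("nosuch", "+"),))
        with pytest.raises(SimulationError, match="nosuch"):
            build_construct(spec, catalog, rng)

    def test_empty_token_list_rejected(self):
        with pytest.raises(SimulationError):
            ConstructSpec("X", ())

    def test_deterministic_per_seed(self, catalog):
        spec = ConstructSpec("X", (("p35S", "+"),), flank5=50, flank3=50)
        a = build_construct(spec, catalog, np.random.default_rng(5))
        b = build_construct(spec, catalog, np.random.default_rng(5))
        assert a.bases == b.bases


class TestSampleFragments:
    def test_zero_stop_prob_runs_to_reference_end(self, scenario, rng):
        frags = sample_fragments(
            scenario.refs, scenario.mixture, scenario.primers, 40, 0.0, rng
        )
        assert frags
        for frag in frags:
            ref = scenario.construct(frag.construct)
            if frag.direction == "down":
                assert frag.frag_end == len(ref)
            else:
                assert frag.frag_start == 1

    def test_fragments_begin_with_nested_primer_after_trim(self, scenario, rng):
        frags = sample_fragments(
            scenario.refs, scenario.mixture, scenario.primers, 40, 0.002, rng
        )
        for frag in frags:
            nested = scenario.primers.nested(frag.target, frag.direction)
            assert frag.insert.startswith(nested)
            trimmed = trim_artificial(NucSequence("f", frag.sequence), scenario.primers)
            # trimming recovers the insert, except that a primer starting
            # with tail-like bases may lose those to the tail trim
            assert frag.insert.endswith(trimmed.bases)
            clipped = len(frag.insert) - len(trimmed.bases)
            leading_tail = len(nested) - len(nested.lstrip("G"))
            assert clipped <= leading_tail

    def test_mean_length_decreases_with_stop_prob(self, scenario):
        means = []
        for stop_prob in (0.001, 0.005, 0.02):
            rng = np.random.default_rng(11)
            frags = sample_fragments(
                scenario.refs, scenario.mixture, scenario.primers, 400, stop_prob, rng
            )
            means.append(np.mean([len(f.insert) for f in frags]))
        assert means[0] > means[1] > means[2]


class TestCorruptSubread:
    def test_zero_rates_identity(self, rng):
        seq = random_bases(rng, 500)
        assert corrupt_subread(seq, ZERO_ERRORS, rng) == seq

    def test_expected_length_inflation(self, rng):
        # E[len out] = len * (1 + ins - del) = 1.05 * len at published rates
        model = ErrorModel(0.10, 0.05, 0.0)
        n, reps = 5000, 100
        seq = random_bases(rng, n)
        lengths = [len(corrupt_subread(seq, model, rng)) for _ in range(reps)]
        assert np.mean(lengths) == pytest.approx(1.05 * n, abs=20)

    def test_subread_accuracy_low_to_mid_eighties(self, rng):
        model = ErrorModel()  # 10% ins, 5% del, 1% sub
        seq = random_bases(rng, 1000)
        idents = [
            global_identity(seq, corrupt_subread(seq, model, rng)) for _ in range(20)
        ]
        assert 0.78 < np.mean(idents) < 0.90

    def test_invalid_rates_rejected(self):
        with pytest.raises(SimulationError):
            ErrorModel(insertion_rate=1.2)


class TestCcsConsensus:
    def test_three_subreads_no_consensus(self, rng):
        seq = random_bases(rng, 300)
        assert ccs_consensus([seq] * 3) is None

    def test_four_identical_error_free_subreads_exact(self, rng):
        seq = random_bases(rng, 300)
        consensus = ccs_consensus([seq] * 4)
        assert consensus.bases == seq
        assert set(consensus.qualities) == {40}

    def test_noisy_consensus_beats_single_subreads(self, rng):
        template = random_bases(rng, 500)
        model = ErrorModel()
        subreads = [corrupt_subread(template, model, rng) for _ in range(8)]
        consensus = ccs_consensus(subreads)
        consensus_identity = global_identity(template, consensus.bases)
        mean_subread = np.mean([global_identity(template, s) for s in subreads])
        assert consensus_identity > mean_subread
        assert consensus_identity > 0.97


class TestSimulateRun:
    def test_zero_reads(self, scenario):
        reads, provenance = simulate_run(
            scenario.refs, scenario.mixture, scenario.primers,
            n_reads=19, seed=3,  # background (18) + artifact (1) only
        )
        assert len(reads) == 19
        assert provenance["is_background"].sum() == 18

    def test_same_seed_bitwise_identical(self, scenario):
        kwargs = dict(error_model=ErrorModel(), n_reads=40, seed=12)
        reads_a, prov_a = simulate_run(
            scenario.refs, scenario.mixture, scenario.primers, **kwargs
        )
        reads_b, prov_b = simulate_run(
            scenario.refs, scenario.mixture, scenario.primers, **kwargs
        )
        assert [(r.id, r.bases, r.qualities) for r in reads_a] == [
            (r.id, r.bases, r.qualities) for r in reads_b
        ]
        assert prov_a.equals(prov_b)

    def test_artifact_reads_flagged_at_zero_error(self, scenario):
        reads, provenance = simulate_run(
            scenario.refs, scenario.mixture, scenario.primers,
            error_model=ZERO_ERRORS, n_reads=60, stop_prob=0.0,
            artifact_count=2, seed=4,
        )
        artifact_ids = set(provenance.loc[provenance["is_artifact"], "read_id"])
        assert len(artifact_ids) == 2
        for read in reads:
            report = detect_tandem_repeat(read)
            if read.id in artifact_ids:
                assert report is not None
            else:
                assert report is None

    def test_provenance_spans_lie_within_references(self, scenario, zero_error_run):
        _reads, provenance, _report = zero_error_run
        for _, row in provenance[~provenance["is_background"]].iterrows():
            ref = scenario.construct(row["construct"])
            assert 1 <= row["frag_start"] <= row["frag_end"] <= len(ref)


def test_mixture_spec_validation():
    spec = ConstructSpec("X", (("p35S", "+"),))
    with pytest.raises(SimulationError):
        MixtureSpec(components=((spec, -1),))
    with pytest.raises(SimulationError):
        MixtureSpec(
            components=((spec, 10),),
            target_shares=((("p35S", "up"), 0.5),),
        )


def test_default_primer_set_structure():
    primers = default_primer_set(np.random.default_rng(0))
    assert set(primers.primers) == {
        (t, d) for t in ("p35S", "tNOS") for d in ("up", "down")
    }
    assert primers.tail_base == "C"
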