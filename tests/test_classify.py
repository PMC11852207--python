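import numpy as np
import pytest

from shufflon.classify import (ExhaustiveDecoder, ReadRecord, build_marker_index,
                               classify_read, classify_read_exhaustive,
                               classify_reads, size_filter, summarize,
                               STATUS_CLASSIFIED, STATUS_SIZE_FILTERED,
                               STATUS_UNCLASSIFIED)
from shufflon.design import (Configuration, DesignError, ModuleSpec,
                             ShufflonDesign, build_sequence, default_design)
from shufflon.sequtil import revcomp
from shufflon.simulate import ErrorModel, LibrarySpec, simulate_library, simulate_reads


class TestSizeFilter:
    def test_exact_length_passes(self):
        reads = [ReadRecord("a", "A" * 1000)]
        passed, rejected = size_filter(reads, 1000, 0.15)
        assert len(passed) == 1 and not rejected

    def test_half_length_filtered(self):
        reads = [ReadRecord("a", "A" * 500)]
        passed, rejected = size_filter(reads, 1000, 0.15)
        assert not passed
        assert rejected[0].status == STATUS_SIZE_FILTERED

    def test_tolerance_validated(self):
        with pytest.raises(DesignError):
            size_filter([], 1000, 1.5)

    def test_simulated_error_free_reads_pass(self, design5):
        seq = build_sequence(design5, Configuration.reference(5))
        reads = [ReadRecord(r.id, r.sequence) for r in
                 simulate_reads([("ref", seq)], ErrorModel(0, 0, 0), depth=100, seed=1)]
        passed, rejected = size_filter(reads, design5.total_length, 0.15)
        assert len(passed) == 100 and not rejected


class TestMarkerIndex:
    def test_marker_density(self, marker_index):
        assert all(c >= 20 for c in marker_index.per_module_counts.values())

    def test_identical_modules_rejected(self, design5):
        m1 = design5.modules[0]
        modules = (m1, ModuleSpec(2, m1.sequence[:-1] + "A")) \
            if m1.sequence[-1] != "A" else (m1, ModuleSpec(2, m1.sequence[:-1] + "C"))
        # near-identical modules share almost all k-mers -> too few markers
        design = ShufflonDesign(modules, design5.site, design5.anchor_left,
                                design5.anchor_right)
        with pytest.raises(DesignError):
            build_marker_index(design)

    def test_forward_markers_are_module_substrings(self, design5, marker_index):
        by_module = {m.id: m.sequence for m in design5.modules}
        for kmer, (mid, off, strand) in marker_index.module_markers.items():
            if strand == "+":
                assert by_module[mid][off:off + marker_index.k] == kmer


class TestMarkerDecoder:
    def test_reference_read(self, design5, marker_index):
        seq = build_sequence(design5, Configuration.reference(5))
        res = classify_read(ReadRecord("ref", seq), marker_index, design5)
        assert res.status == STATUS_CLASSIFIED
        assert res.configuration.to_string() == "+1+2+3+4+5"
        assert res.score == 1.0
        assert res.global_strand == "+"

    def test_minus_strand_read(self, design5, marker_index):
        cfg = Configuration.from_string("-3-2-1+4+5")
        seq = revcomp(build_sequence(design5, cfg))
        res = classify_read(ReadRecord("rc", seq), marker_index, design5)
        assert res.status == STATUS_CLASSIFIED
        assert res.configuration == cfg
        assert res.global_strand == "-"

    def test_strand_invariance(self, design5, marker_index):
        cfg = Configuration.from_string("+5-2+3+4+1")
        seq = build_sequence(design5, cfg)
        fwd = classify_read(ReadRecord("f", seq), marker_index, design5)
        rev = classify_read(ReadRecord("r", revcomp(seq)), marker_index, design5)
        assert fwd.configuration == rev.configuration == cfg

    def test_anchor_only_read_unclassified(self, design5, marker_index):
        res = classify_read(ReadRecord("a", design5.anchor_left), marker_index, design5)
        assert res.status == STATUS_UNCLASSIFIED

    def test_foreign_read_unclassified(self, design5, marker_index):
        # NB seed must differ from the design seed, or the "foreign" read
        # would reproduce the design's own base stream
        rng = np.random.default_rng(987654)
        from shufflon.sequtil import random_dna
        res = classify_read(ReadRecord("x", random_dna(rng, 4000)), marker_index, design5)
        assert res.status == STATUS_UNCLASSIFIED

    def test_no_phantom_configurations(self, design5, marker_index):
        from shufflon.combinatorics import enumerate_configurations
        lib = simulate_library(design5, LibrarySpec(60, event_rate=3.0, seed=31))
        sources = [(c.to_string(), build_sequence(design5, c)) for c in lib]
        valid = set(enumerate_configurations(5))
        for r in simulate_reads(sources, ErrorModel(), depth=1, seed=32):
            res = classify_read(ReadRecord(r.id, r.sequence), marker_index, design5)
            if res.status == STATUS_CLASSIFIED:
                assert res.configuration in valid


class TestExhaustiveDecoder:
    def test_error_free_read_distance_zero(self, design5, exhaustive_decoder):
        cfg = Configuration.from_string("+3-2+1-4+5")
        seq = build_sequence(design5, cfg)
        res = exhaustive_decoder.classify(ReadRecord("e", seq))
        assert res.status == STATUS_CLASSIFIED
        assert res.configuration == cfg
        assert res.score == 1.0

    def test_minus_strand(self, design5, exhaustive_decoder):
        cfg = Configuration.from_string("-1+2+3+4+5")
        res = exhaustive_decoder.classify(ReadRecord("e", revcomp(build_sequence(design5, cfg))))
        assert res.status == STATUS_CLASSIFIED
        assert res.configuration == cfg
        assert res.global_strand == "-"

    def test_equidistant_read_is_tie(self, design1):
        # a core holding only the two sites is |M1| away from both references
        decoder = ExhaustiveDecoder(design1, identity_floor=0.0)
        site = design1.site.sequence
        read = design1.anchor_left + site + revcomp(site) + design1.anchor_right
        res = decoder.classify(ReadRecord("tie", read))
        assert res.status == STATUS_UNCLASSIFIED
        assert "tie" in res.reason

    def test_low_identity_unclassified(self, design5, exhaustive_decoder):
        rng = np.random.default_rng(1)
        from shufflon.sequtil import random_dna
        junk = design5.anchor_left + random_dna(rng, 1845) + design5.anchor_right
        res = exhaustive_decoder.classify(ReadRecord("junk", junk))
        assert res.status == STATUS_UNCLASSIFIED

    def test_functional_wrapper(self, design5, reference_set):
        seq = build_sequence(design5, Configuration.reference(5))
        res = classify_read_exhaustive(ReadRecord("w", seq), design5, reference_set)
        assert res.configuration == Configuration.reference(5)


class TestBatchAndSummary:
    def test_classify_reads_and_summarize(self, design5, marker_index):
        lib = simulate_library(design5, LibrarySpec(40, event_rate=2.0, seed=51))
        sources = [(c.to_string(), build_sequence(design5, c)) for c in lib]
        reads = [ReadRecord(r.id, r.sequence) for r in
                 simulate_reads(sources, ErrorModel(), depth=1, seed=52)]
        reads.append(ReadRecord("short", "ACGT" * 10))
        results = classify_reads(reads, marker_index, design5)
        assert len(results) == 41
        statuses = {r.status for r in results}
        assert STATUS_SIZE_FILTERED in statuses
        summary = summarize(results)
        assert summary.n_classified + summary.n_unclassified == 41
        truth = {}
        for r in reads[:-1]:
            truth[r.id] = r.id.split("|", 1)[1]
        by_id = {r.read_id: r for r in results}
        correct = sum(1 for rid, cfg in truth.items()
                      if by_id[rid].status == STATUS_CLASSIFIED
                      and by_id[rid].configuration.to_string() == cfg)
        assert correct >= 38  # default error rates barely dent marker decoding

    def test_result_invariant(self):
        with pytest.raises(DesignError):
            from shufflon.classify import ClassificationResult
            ClassificationResult("r", STATUS_CLASSIFIED, configuration=None)
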