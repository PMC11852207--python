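import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shufflon.design import DesignError
from shufflon.mine import (CandidateSite, FlankRecord, RepeatHit, classify_locus,
                           find_repeats, mine_fasta, novelty_filter,
                           pick_representative_site, reconstruct_sites,
                           write_mine_outputs,
                           CATEGORY_BOTH, CATEGORY_DIRECT, CATEGORY_NONE)
from shufflon.sequtil import canonical_kmer, random_dna, revcomp
from shufflon.simulate import plant_repeats


def brute_force_hits(seq, k=13):
    """Naive all-pairs comparison of every k-mer window (oracle)."""
    wins = [seq[i:i + k] for i in range(len(seq) - k + 1)]
    reported = set()
    for i in range(len(wins)):
        if "N" in wins[i]:
            continue
        for j in range(i + 1, len(wins)):
            if wins[i] == wins[j] or wins[i] == revcomp(wins[j]):
                reported.add(canonical_kmer(wins[i]))
    occurrences = {}
    for canon in reported:
        rc = revcomp(canon)
        occurrences[canon] = tuple(
            (i, "+" if wins[i] == canon else "-")
            for i in range(len(wins)) if wins[i] in (canon, rc))
    return occurrences


class TestFindRepeats:
    def test_planted_direct(self):
        seq, kmer = plant_repeats(2000, positions=[100, 800], strands=["+", "+"], seed=1)
        hits = find_repeats(FlankRecord("L", seq))
        assert len(hits) == 1
        (h,) = hits
        assert h.canonical_kmer == canonical_kmer(kmer)
        assert h.n_direct == 2 and h.n_inverted_pairs == 0
        assert [p for p, _ in h.occurrences] == [100, 800]

    def test_planted_inverted(self):
        seq, kmer = plant_repeats(2000, positions=[150, 1200], strands=["+", "-"], seed=2)
        hits = find_repeats(FlankRecord("L", seq))
        assert len(hits) == 1
        assert hits[0].n_inverted_pairs == 1

    def test_zero_plants_clean(self):
        seq, _ = plant_repeats(5000, seed=3)
        assert find_repeats(FlankRecord("L", seq)) == []

    def test_tandem_repeat_phases(self):
        # (ACGT)*10: every 13-mer recurs every 4 bases; brute force agrees
        seq = "ACGT" * 10
        hits = find_repeats(FlankRecord("T", seq))
        oracle = brute_force_hits(seq)
        assert {h.canonical_kmer for h in hits} == set(oracle)
        for h in hits:
            assert h.occurrences == oracle[h.canonical_kmer]

    def test_n_windows_excluded(self):
        core = "ACGTACGTACGTA"
        seq = core + "NNNN" + core.replace("A", "N", 1) + "TT" + core
        hits = find_repeats(FlankRecord("N", seq))
        assert any(h.canonical_kmer == canonical_kmer(core) for h in hits)
        for h in hits:
            assert "N" not in h.canonical_kmer

    def test_short_sequence_warns_empty(self):
        with pytest.warns(UserWarning):
            assert find_repeats(FlankRecord("S", "ACGTACGT")) == []

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_on_random(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 400)
        hits = {h.canonical_kmer: h.occurrences for h in find_repeats(FlankRecord("R", seq))}
        oracle = brute_force_hits(seq)
        assert hits == oracle

    def test_strand_symmetry(self):
        rng = np.random.default_rng(11)
        seq, kmer = plant_repeats(1500, positions=[200, 900], strands=["+", "-"], seed=4)
        fwd = find_repeats(FlankRecord("F", seq))
        rev = find_repeats(FlankRecord("R", revcomp(seq)))
        assert {h.canonical_kmer for h in fwd} == {h.canonical_kmer for h in rev}
        L = len(seq)
        for hf, hr in zip(fwd, rev):
            mirrored = sorted((L - 13 - p, "-" if s == "+" else "+")
                              for p, s in hf.occurrences)
            assert sorted(hr.occurrences) == mirrored


class TestClassifyLocus:
    def test_empty(self):
        assert classify_locus([]) == CATEGORY_NONE

    def test_direct_only(self):
        h = RepeatHit("A" * 13, ((0, "+"), (50, "+"), (90, "+")), 3, 0)
        assert classify_locus([h]) == CATEGORY_DIRECT

    def test_direct_and_inverted(self):
        h = RepeatHit("A" * 12 + "C", ((0, "+"), (50, "-")), 1, 1)
        assert classify_locus([h]) == CATEGORY_BOTH


class TestNovelty:
    KMER = "ACGTACGTACGTA"

    def _hit(self):
        return RepeatHit(canonical_kmer(self.KMER), ((0, "+"), (40, "+")), 2, 0)

    def test_known_flagged(self):
        (h,) = novelty_filter([self._hit()], [self.KMER])
        assert h.novel is False

    def test_known_by_revcomp(self):
        (h,) = novelty_filter([self._hit()], [revcomp(self.KMER)])
        assert h.novel is False

    def test_one_mismatch_is_novel(self):
        (h,) = novelty_filter([self._hit()], ["CCGTACGTACGTA"])
        assert h.novel is True


class TestReconstructSites:
    def test_plus_strand_window_arithmetic(self):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 300)
        kmer = seq[100:113]
        hit = RepeatHit(canonical_kmer(kmer), ((100, "+" if kmer == canonical_kmer(kmer) else "-"),), 1, 0)
        # use the strand recorded for the forward window
        strand = "+" if kmer == canonical_kmer(kmer) else "-"
        sites = reconstruct_sites(FlankRecord("L", seq), hit, offset=18)
        assert len(sites) == 1
        if strand == "+":
            assert sites[0].window == seq[82:113]
        else:
            assert sites[0].window == revcomp(seq[100:131])

    def test_truncated_windows_dropped(self):
        rng = np.random.default_rng(6)
        seq = random_dna(rng, 40)
        hit = RepeatHit(canonical_kmer(seq[:13]), ((0, "+"),), 1, 0)
        with pytest.warns(UserWarning):
            assert reconstruct_sites(FlankRecord("L", seq), hit, offset=18) == []

    def test_palindromic_arms_score_one(self):
        left = "ACGTTGCAACGT"
        window = left + "TTTTTTT" + revcomp(left)
        site = CandidateSite(window, 0, "+", 1.0)
        assert site.left_arm == left and site.right_arm == revcomp(left)
        rec = FlankRecord("P", window + "G" * 20)
        hit = RepeatHit(canonical_kmer(window[18:31]), ((18, "+"),), 1, 0)
        sites = reconstruct_sites(rec, hit, offset=18)
        # offset 18 places the k-mer flush right, so the window is recovered
        assert sites and sites[0].palindromy_score == 1.0

    def test_minus_strand_right_arm_content(self):
        rng = np.random.default_rng(7)
        fwd31 = random_dna(rng, 31)
        seq = random_dna(rng, 60) + revcomp(fwd31) + random_dna(rng, 60)
        kmer = fwd31[18:31]
        pos = 60 + (31 - 13 - 18)  # the k-mer's revcomp sits at the window start
        strand = "+" if seq[pos:pos + 13] == canonical_kmer(kmer) else "-"
        hit = RepeatHit(canonical_kmer(kmer), ((pos, strand),), 1, 0)
        sites = reconstruct_sites(FlankRecord("M", seq), hit, offset=18)
        assert len(sites) == 1

    def test_offset_validated(self):
        hit = RepeatHit("A" * 13, ((0, "+"),), 1, 0)
        with pytest.raises(DesignError):
            reconstruct_sites(FlankRecord("L", "ACGT" * 20), hit, offset=19)


class TestRepresentative:
    def _site(self, left, score=0.0):
        return CandidateSite(left + "TTTTTTT" + "ACGTACGTACGT", 0, "+", score)

    def test_modal_left_arm(self):
        x, y = "AAAACCCCGGGG", "TTTTAAAACCCC"
        sites = [self._site(x), self._site(x), self._site(y)]
        assert pick_representative_site(sites).left_arm == x

    def test_singleton(self):
        s = self._site("AAAACCCCGGGG")
        assert pick_representative_site([s]) == s

    def test_tie_is_seeded_deterministic(self):
        sites = [self._site("AAAACCCCGGGG"), self._site("TTTTAAAACCCC")]
        picks = {pick_representative_site(sites, seed=42).left_arm for _ in range(5)}
        assert len(picks) == 1

    def test_all_palindromic_rejected(self):
        with pytest.raises(DesignError):
            pick_representative_site([self._site("AAAACCCCGGGG", score=0.9)])


class TestDriver:
    def test_mine_fasta_end_to_end(self, tmp_path):
        direct, km_d = plant_repeats(2000, positions=[300, 1200], strands=["+", "+"], seed=21)
        inverted, km_i = plant_repeats(2000, positions=[400, 1300], strands=["+", "-"], seed=22)
        clean, _ = plant_repeats(2000, seed=23)
        fasta = tmp_path / "flanks.fasta"
        fasta.write_text(f">direct\n{direct}\n>inverted\n{inverted}\n>clean\n{clean}\n")
        per_locus, reps, summary = mine_fasta(fasta)
        assert per_locus["direct"][0] == CATEGORY_DIRECT
        assert per_locus["inverted"][0] == CATEGORY_BOTH
        assert per_locus["clean"][0] == CATEGORY_NONE
        assert summary[CATEGORY_BOTH] == 1 and summary["representative_sites"] == 1
        assert "inverted" in reps
        write_mine_outputs(per_locus, reps, summary, tmp_path / "out")
        assert (tmp_path / "out" / "loci.tsv").exists()
        assert (tmp_path / "out" / "candidate_sites.fasta").read_text().startswith(">inverted")

    def test_known_kmer_suppresses_site(self, tmp_path):
        seq, kmer = plant_repeats(2000, positions=[400, 1300], strands=["+", "-"], seed=25)
        fasta = tmp_path / "f.fasta"
        fasta.write_text(f">L\n{seq}\n")
        _, reps, _ = mine_fasta(fasta, known_kmers=[kmer])
        assert reps == {}
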