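"""Two-phase mapper: collapsing, indexing, seeding, extension, mapping."""

import numpy as np
import pytest

from bsmira import bsalign
from bsmira.bsalign import (
    Mapper,
    MapperParams,
    banded_align,
    build_index,
    collapse_alphabet,
    filter_asymmetric,
    merge_seeds,
    SeedHit,
    trim_adapters,
)
from bsmira.refdata import ReferenceGenome
from bsmira.reference_dp import exhaustive_best_score
from bsmira.simseq import BSP_PRIMER_FWD


def scalar_dp_best(read: str, ref: str, phase: str, params: MapperParams) -> int:
    """Per-cell scalar affine DP, written independently of the package DPs.

    Global in the read, free reference ends; gaps open from match state
    only (insertions and deletions never abut), matching the package's
    scoring model.
    """
    NEG = -(10**9)
    L, W = len(read), len(ref)

    def score(r, q):
        if r == "N" or q == "N":
            return params.mismatch
        if r == q:
            return params.match
        if phase == "CT" and r == "C" and q == "T":
            return params.match
        if phase == "GA" and r == "G" and q == "A":
            return params.match
        return params.mismatch

    M = [[NEG] * (W + 1) for _ in range(L + 1)]
    X = [[NEG] * (W + 1) for _ in range(L + 1)]
    Y = [[NEG] * (W + 1) for _ in range(L + 1)]
    for j in range(W + 1):
        M[0][j] = 0
    for i in range(1, L + 1):
        X[i][0] = max(M[i - 1][0] + params.gap_open, X[i - 1][0] + params.gap_extend)
        for j in range(1, W + 1):
            s = score(ref[j - 1], read[i - 1])
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + params.gap_open, X[i - 1][j] + params.gap_extend)
            Y[i][j] = max(M[i][j - 1] + params.gap_open, Y[i][j - 1] + params.gap_extend)
    return max(max(M[L]), max(X[L]))


class TestCollapse:
    @pytest.mark.parametrize(
        "seq,phase,expected",
        [
            ("TTACGT", "CT", "CCACGC"),
            ("TTACGT", "GA", "TTGCGT"),
            ("CCGG", "CT", "CCGG"),
        ],
    )
    def test_examples(self, seq, phase, expected):
        assert collapse_alphabet(seq, phase) == expected

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGTN"), size=50))
            for phase in ("CT", "GA"):
                once = collapse_alphabet(seq, phase)
                assert collapse_alphabet(once, phase) == once


class TestIndex:
    def test_short_query_hand_example(self):
        g = ReferenceGenome({"c1": "ACGT"})
        idx = build_index(g, "CT")  # collapsed text "ACGC"
        assert ("c1", 0) in idx.lookup("ACG")

    def test_absent_kmer_empty(self):
        g = ReferenceGenome({"c1": "AAAAAAAA"})
        idx = build_index(g, "CT")
        assert idx.lookup("GGG") == []

    def test_matches_naive_scan_all_15mers(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=5_000))
        g = ReferenceGenome({"c1": seq})
        for phase in ("CT", "GA"):
            idx = build_index(g, phase)
            collapsed = collapse_alphabet(seq, phase)
            # exhaustive over every distinct 15-mer of the sequence
            kmers = {collapsed[i : i + 15] for i in range(0, len(seq) - 15, 7)}
            for kmer in kmers:
                naive = [
                    i
                    for i in range(len(collapsed) - 14)
                    if collapsed[i : i + 15] == kmer
                ]
                got = sorted(p for _, p in idx.lookup(kmer))
                assert got == naive

    def test_multi_chromosome_positions(self):
        g = ReferenceGenome({"c1": "AACCGGTT", "c2": "CCGGTTAA"})
        idx = build_index(g, "CT")
        hits = idx.lookup("GG")
        assert ("c1", 4) in hits and ("c2", 2) in hits

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            build_index(ReferenceGenome({"c1": ""}), "CT")


class TestAsymmetricFilter:
    @pytest.mark.parametrize(
        "ref,read,phase,keep",
        [
            ("ACGA", "ATGA", "CT", True),   # ref C ↔ read T: conversion
            ("ATGA", "ACGA", "CT", False),  # ref T ↔ read C: unallowed
            ("ACGA", "ACGA", "CT", True),
            ("AGGA", "AAGA", "GA", True),   # ref G ↔ read A: conversion
            ("AAGA", "AGGA", "GA", False),  # ref A ↔ read G: unallowed
            ("ANGA", "ANGA", "CT", False),  # N never matches
        ],
    )
    def test_rules(self, ref, read, phase, keep):
        assert filter_asymmetric(ref, read, phase) is keep

    def test_invariant_under_appended_matches(self):
        ref, read = "ACGA", "ATGA"
        for tail in ("", "G", "GGT", "ACGT"):
            assert filter_asymmetric(ref + tail, read + tail, "CT")


class TestMergeSeeds:
    def _hit(self, ref_pos, read_pos, length=20, chrom="c1", phase="CT"):
        return SeedHit(phase, chrom, ref_pos, read_pos, length)

    def test_codiagonal_seeds_merge(self):
        params = MapperParams()
        chains = merge_seeds([self._hit(100, 0), self._hit(150, 50)], params)
        assert len(chains) == 1 and len(chains[0]) == 2

    def test_different_chromosomes_split(self):
        params = MapperParams()
        chains = merge_seeds(
            [self._hit(100, 0), self._hit(100, 0, chrom="c2")], params
        )
        assert len(chains) == 2

    def test_off_diagonal_not_merged(self):
        params = MapperParams()
        chains = merge_seeds([self._hit(100, 0), self._hit(200, 10)], params)
        assert len(chains) == 2

    def test_far_apart_not_merged(self):
        params = MapperParams()
        chains = merge_seeds([self._hit(100, 0), self._hit(400, 300)], params)
        assert len(chains) == 2


class TestExtension:
    def test_perfect_read_scores_match_times_length(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        params = MapperParams()
        read = seq[100:160].replace("C", "T")  # fully converted
        res = banded_align(read, seq, 80, 200, "CT", params)
        score, start, end, cigar, n_mm = res
        assert score == params.match * len(read)
        assert (start, end, n_mm) == (100, 160, 0)
        assert cigar == f"{len(read)}M"

    def test_single_substitution_arithmetic(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        params = MapperParams()
        read = list(seq[100:160].replace("C", "T"))
        orig = read[30]
        read[30] = {"A": "G", "G": "A", "T": "G", "C": "A"}[orig]
        read = "".join(read)
        res = banded_align(read, seq, 80, 200, "CT", params)
        score = res[0]
        assert score == params.match * 59 + params.mismatch

    @pytest.mark.parametrize("phase", ["CT", "GA"])
    def test_matches_scalar_dp(self, phase):
        rng = np.random.default_rng(6)
        params = MapperParams()
        for _ in range(15):
            ref = "".join(rng.choice(list("ACGT"), size=200))
            start = int(rng.integers(0, 150))
            read = list(ref[start : start + 40])
            src, dst = ("C", "T") if phase == "CT" else ("G", "A")
            read = [dst if (c == src and rng.random() < 0.7) else c for c in read]
            for _ in range(rng.integers(0, 3)):
                i = int(rng.integers(len(read)))
                read[i] = "ACGT"[int(rng.integers(4))]
            read = "".join(read)
            banded = banded_align(read, ref, 0, len(ref), phase, params)
            assert banded is not None
            assert banded[0] == scalar_dp_best(read, ref, phase, params)

    def test_exhaustive_oracle_matches_scalar_dp(self):
        # triple check: the vectorized full-width oracle equals the naive
        # per-cell DP on small instances
        rng = np.random.default_rng(7)
        params = MapperParams()
        for _ in range(10):
            ref = "".join(rng.choice(list("ACGT"), size=300))
            g = ReferenceGenome({"c1": ref})
            read = "".join(rng.choice(list("ACGT"), size=30))
            expected = max(
                scalar_dp_best(read, ref, "CT", params),
                scalar_dp_best(read, ref, "GA", params),
            )
            assert exhaustive_best_score(read, g, params) == expected


class TestTrimming:
    def test_exact_primer_prefix_removed(self):
        insert = "GATTTGGAGTAGTTGGTAGAGTTTGGGATTAGGTAT"
        read = BSP_PRIMER_FWD + insert
        assert trim_adapters(read) == insert

    def test_no_overlap_unchanged(self):
        read = "GATTTGGAGTAGTTGGTAGAGTTTGGGATTAGGTAT"
        assert trim_adapters(read) == read

    def test_short_insert_discarded(self):
        primer = list(BSP_PRIMER_FWD)
        primer[5] = "C" if primer[5] != "C" else "G"  # one mismatch
        read = "".join(primer) + "GATTTGGAGTAGTTGGTAG"  # 19 bp insert
        assert trim_adapters(read) is None

    def test_converted_adapter_still_recognized(self):
        from bsmira.simseq import ADAPTER_TOP

        converted = ADAPTER_TOP.replace("C", "T")  # fully bisulfite-converted
        insert = "GATTTGGAGTAGTTGGTAGAGTTTGGGATTAGGTAT"
        assert trim_adapters(converted + insert) == insert


class TestMapping:
    def test_unique_read_recovered_at_origin(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=20_000))
        g = ReferenceGenome({"c1": seq})
        mapper = Mapper(g)
        read = seq[5_000:5_080].replace("C", "T")
        res = mapper.map_read("r1", read)
        assert res.status == "unique"
        assert (res.alignment.chrom, res.alignment.start) == ("c1", 5_000)
        assert res.alignment.phase == "CT"

    def test_ga_phase_read_recovered(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=20_000))
        g = ReferenceGenome({"c1": seq})
        mapper = Mapper(g)
        read = seq[7_000:7_080].replace("G", "A")
        res = mapper.map_read("r1", read)
        assert res.status == "unique"
        assert res.alignment.start == 7_000
        assert res.alignment.phase == "GA"

    def test_duplicated_segment_ambiguous(self):
        rng = np.random.default_rng(10)
        block = "".join(rng.choice(list("ACGT"), size=1_000))
        filler = "".join(rng.choice(list("ACGT"), size=2_000))
        g = ReferenceGenome({"c1": block + filler + block})
        mapper = Mapper(g)
        read = block[100:170].replace("C", "T")
        res = mapper.map_read("r1", read)
        assert res.status == "ambiguous"

    def test_random_read_unmapped(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=20_000))
        g = ReferenceGenome({"c1": seq})
        mapper = Mapper(g)
        read = "".join(np.random.default_rng(999).choice(list("ACGT"), size=30))
        res = mapper.map_read("r1", read)
        # a random 30-mer may occur by chance in collapsed space, but a
        # full-score placement of an unrelated read is effectively impossible
        assert res.status in ("unmapped", "ambiguous")

    def test_phase_recovery_on_simulated_reads(self, mini_mapped):
        lib = mini_mapped["library"]
        truth = lib.truth.reads
        alns = mini_mapped["alignments"]
        agree = sum(1 for a in alns if a.phase == truth[a.read_id].phase)
        assert agree / len(alns) >= 0.99

    def test_simulated_mapping_rate(self, mini_mapped):
        counts = mini_mapped["counts"]
        total = sum(counts.values())
        assert counts["unique"] / total >= 0.90

    def test_mapped_positions_match_truth(self, mini_mapped):
        lib = mini_mapped["library"]
        truth = lib.truth.reads
        ok = 0
        for a in mini_mapped["alignments"]:
            rt = truth[a.read_id]
            overlap = max(0, min(a.end, rt.end) - max(a.start, rt.start))
            if a.chrom == rt.chrom and overlap >= 0.8 * (a.end - a.start):
                ok += 1
        assert ok / len(mini_mapped["alignments"]) >= 0.95


class TestAlignmentIO:
    def test_round_trip(self, tmp_path, mini_mapped):
        path = tmp_path / "aln.tsv"
        alns = mini_mapped["alignments"][:100]
        bsalign.write_alignments(alns, path)
        again = bsalign.read_alignments(path)
        assert [(a.read_id, a.chrom, a.start, a.end, a.score) for a in again] == [
            (a.read_id, a.chrom, a.start, a.end, a.score) for a in alns
        ]
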