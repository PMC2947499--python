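"""Two-phase bisulfite-aware read mapping.

The mapper aligns bisulfite-converted reads against the forward reference
in two collapsed alphabets: the CT phase merges T into C (forward-strand
conversions) and the GA phase merges A into G (reverse-strand conversions
viewed on the forward coordinates).  For each phase the collapsed reference
is indexed with a suffix array; exact seed hits are post-filtered to reject
asymmetric pairings (reference T against read C in the CT phase, reference
A against read G in the GA phase — collapses that do not correspond to a
bisulfite conversion), merged into diagonal-consistent chains, and extended
by a banded affine-gap alignment scored in the original alphabet where an
allowed bisulfite pairing counts as a match.  The best-scoring candidate
across both phases wins; a read is "unique" only when the runner-up at a
different locus trails by at least the uniqueness margin, and only unique
alignments feed methylation calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .refdata import ReferenceGenome
from .simseq import (
    ADAPTER_BOTTOM,
    ADAPTER_TOP,
    BSP_PRIMER_FWD,
    BSP_PRIMER_REV,
)
from .refdata import reverse_complement

_CT_TABLE = str.maketrans("T", "C")
_GA_TABLE = str.maketrans("A", "G")

NEG_INF = np.iinfo(np.int32).min // 4


@dataclass
class MapperParams:
    """Free parameters of the seed-and-extend mapper.

    The two-phase architecture is fixed; everything numeric is tunable.
    ``min_score_fraction`` is the fraction of the perfect score
    (match × read length) below which a read is reported unmapped.
    """

    seed_length: int = 20
    seed_stride: int | None = None  # default: seed_length // 2
    max_seed_hits: int = 100
    match: int = 1
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1
    merge_gap: int = 50
    diag_tolerance: int = 5
    band: int = 16
    min_score_fraction: float = 0.9
    uniqueness_margin: int = 1
    max_candidates: int = 30

    def __post_init__(self) -> None:
        if self.seed_length < 8:
            raise ValueError("seed_length must be ≥ 8")
        if self.match <= 0 or self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("require match > 0 and penalties ≤ 0")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be ≥ 0")

    @property
    def stride(self) -> int:
        return self.seed_stride if self.seed_stride is not None else max(1, self.seed_length // 2)


@dataclass(frozen=True)
class SeedHit:
    phase: str
    chrom: str
    ref_pos: int
    read_pos: int
    length: int

    @property
    def diag(self) -> int:
        return self.ref_pos - self.read_pos


@dataclass
class AlignmentResult:
    read_id: str
    chrom: str
    start: int
    end: int
    phase: str
    score: int
    cigar: str
    n_mismatch: int
    unique: bool = False

    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class MapResult:
    """Outcome of mapping one read: 'unique', 'ambiguous' or 'unmapped'."""

    status: str
    alignment: AlignmentResult | None = None
    best_score: int | None = None
    second_score: int | None = None


def collapse_alphabet(seq: str, phase: str) -> str:
    """CT phase: every T→C; GA phase: every A→G; other bases unchanged."""
    if phase == "CT":
        return seq.translate(_CT_TABLE)
    if phase == "GA":
        return seq.translate(_GA_TABLE)
    raise ValueError(f"unknown phase {phase!r}")


# ---------------------------------------------------------------------------
# suffix-array index
# ---------------------------------------------------------------------------


def build_suffix_array(text: str) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), numpy-backed)."""
    n = len(text)
    if n == 0:
        raise ValueError("cannot index an empty sequence")
    rank = np.frombuffer(text.encode("ascii"), dtype=np.uint8).astype(np.int64)
    k = 1
    order = np.argsort(rank, kind="stable")
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        newrank = np.empty(n, dtype=np.int64)
        diff = np.ones(n, dtype=bool)
        r_o = rank[order]
        k_o = key2[order]
        diff[1:] = (r_o[1:] != r_o[:-1]) | (k_o[1:] != k_o[:-1])
        newrank[order] = np.cumsum(diff) - 1
        rank = newrank
        if rank[order[-1]] == n - 1 or k >= n:
            break
        k *= 2
    return order


class GenomeIndex:
    """Suffix-array index over one collapse phase of a genome.

    Chromosomes are concatenated with sentinel separators; lookups return
    (chromosome, position) pairs for every exact occurrence of a collapsed
    query, via binary search on the suffix array.
    """

    SENTINEL = "#"  # sorts below A/C/G/T and cannot match any query base

    def __init__(self, genome: ReferenceGenome, phase: str):
        if genome.total_length == 0:
            raise ValueError("cannot index an empty genome")
        self.phase = phase
        self.names = genome.names()
        parts = []
        starts = []
        cursor = 0
        for name in self.names:
            starts.append(cursor)
            parts.append(collapse_alphabet(genome[name], phase))
            cursor += genome.lengths[name] + 1
            parts.append(self.SENTINEL)
        self.text = "".join(parts)
        self.starts = np.array(starts, dtype=np.int64)
        self.lengths = [genome.lengths[name] for name in self.names]
        self.sa = build_suffix_array(self.text)

    def _compare(self, pos: int, query: str) -> int:
        chunk = self.text[pos : pos + len(query)]
        if chunk == query:
            return 0
        return -1 if chunk < query else 1

    def lookup(self, query: str) -> list[tuple[str, int]]:
        """All exact occurrences of a collapsed query (any length ≥ 1)."""
        if not query:
            raise ValueError("empty query")
        sa, text = self.sa, self.text
        n = len(sa)
        # lower bound: first suffix with prefix ≥ query
        lo, hi = 0, n
        while lo < hi:
            mid = (lo + hi) // 2
            if text[sa[mid] : sa[mid] + len(query)] < query:
                lo = mid + 1
            else:
                hi = mid
        first = lo
        # upper bound: first suffix with prefix > query
        hi = n
        while lo < hi:
            mid = (lo + hi) // 2
            if text[sa[mid] : sa[mid] + len(query)] <= query:
                lo = mid + 1
            else:
                hi = mid
        out = []
        for idx in sa[first:lo]:
            ci = int(np.searchsorted(self.starts, idx, side="right")) - 1
            offset = int(idx) - int(self.starts[ci])
            if offset + len(query) <= self.lengths[ci]:
                out.append((self.names[ci], offset))
        out.sort()
        return out


def build_index(genome: ReferenceGenome, phase: str) -> GenomeIndex:
    return GenomeIndex(genome, phase)


# ---------------------------------------------------------------------------
# adapter trimming
# ---------------------------------------------------------------------------


def default_trim_sequences() -> list[str]:
    """Adapter/primer sequences searched at read ends, both orientations."""
    seqs = [
        ADAPTER_TOP,
        reverse_complement(ADAPTER_BOTTOM),
        ADAPTER_BOTTOM,
        reverse_complement(ADAPTER_TOP),
        BSP_PRIMER_FWD,
        reverse_complement(BSP_PRIMER_FWD),
        BSP_PRIMER_REV,
        reverse_complement(BSP_PRIMER_REV),
    ]
    seen: list[str] = []
    for s in seqs:
        if s not in seen:
            seen.append(s)
    return seen


def _collapsed_bytes(seq: str, phase: str) -> np.ndarray:
    return np.frombuffer(collapse_alphabet(seq, phase).encode("ascii"), dtype=np.uint8)


def trim_adapters(
    read: str,
    sequences: list[str] | None = None,
    min_overlap: int = 10,
    max_mismatch: int = 1,
    min_length: int = 20,
) -> str | None:
    """Trim adapter/primer overlap from both read ends.

    Comparison happens in bisulfite-collapsed space (both CT and GA, so a
    converted adapter still matches its unconverted sequence).  The longest
    end overlap of ≥ ``min_overlap`` bases with ≤ ``max_mismatch``
    mismatches is removed from each end; reads shorter than ``min_length``
    afterwards are discarded (returns None).  Untrimmable reads pass
    through unchanged.
    """
    if sequences is None:
        sequences = default_trim_sequences()
    cand = [
        (phase, _collapsed_bytes(s, phase))
        for phase in ("CT", "GA")
        for s in sequences
    ]

    def longest_5p(r: str) -> int:
        arrs = {p: _collapsed_bytes(r, p) for p in ("CT", "GA")}
        best = 0
        for phase, s in cand:
            rb = arrs[phase]
            top = min(len(s), len(rb))
            for ell in range(top, min_overlap - 1, -1):
                if ell <= best:
                    break
                if np.count_nonzero(s[-ell:] != rb[:ell]) <= max_mismatch:
                    best = ell
                    break
        return best

    def longest_3p(r: str) -> int:
        arrs = {p: _collapsed_bytes(r, p) for p in ("CT", "GA")}
        best = 0
        for phase, s in cand:
            rb = arrs[phase]
            top = min(len(s), len(rb))
            for ell in range(top, min_overlap - 1, -1):
                if ell <= best:
                    break
                if np.count_nonzero(s[:ell] != rb[-ell:]) <= max_mismatch:
                    best = ell
                    break
        return best

    cut5 = longest_5p(read)
    read = read[cut5:]
    if read:
        cut3 = longest_3p(read)
        if cut3:
            read = read[:-cut3]
    if len(read) < min_length:
        return None
    return read


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------


def filter_asymmetric(ref_seq: str, read_seq: str, phase: str) -> bool:
    """Keep a collapsed-space exact seed only if no asymmetric pairing occurs.

    CT phase: reference T paired with read C is not a bisulfite event and
    kills the seed (reference C with read T is allowed).  GA phase is the
    mirror: reference A with read G is disallowed.  Any N kills the seed.
    """
    if len(ref_seq) != len(read_seq):
        raise ValueError("seed sequences differ in length")
    if "N" in ref_seq or "N" in read_seq:
        return False
    if phase == "CT":
        bad = ("T", "C")
    elif phase == "GA":
        bad = ("A", "G")
    else:
        raise ValueError(f"unknown phase {phase!r}")
    return not any(r == bad[0] and q == bad[1] for r, q in zip(ref_seq, read_seq))


def seed_read(
    read: str, index: GenomeIndex, genome: ReferenceGenome, params: MapperParams
) -> list[SeedHit]:
    """Exact collapsed seeds of the read in one phase, asymmetric-filtered."""
    phase = index.phase
    L = len(read)
    k = min(params.seed_length, L)
    offsets = sorted(set(range(0, L - k + 1, params.stride)) | {L - k})
    collapsed = collapse_alphabet(read, phase)
    hits: list[SeedHit] = []
    for off in offsets:
        query = collapsed[off : off + k]
        if "N" in query:
            continue
        occ = index.lookup(query)
        if len(occ) > params.max_seed_hits:
            continue
        for chrom, pos in occ:
            ref = genome[chrom][pos : pos + k]
            if filter_asymmetric(ref, read[off : off + k], phase):
                hits.append(SeedHit(phase, chrom, pos, off, k))
    return hits


def merge_seeds(hits: list[SeedHit], params: MapperParams) -> list[list[SeedHit]]:
    """Chain seeds that are near in both reference and read.

    Two hits join the same chain iff they share phase and chromosome, sit
    within ``diag_tolerance`` of a common diagonal, and are within
    ``merge_gap`` on both the reference and read axes.  Chains are maximal
    under transitive closure of that relation along the diagonal ordering.
    """
    chains: list[list[SeedHit]] = []
    ordered = sorted(hits, key=lambda h: (h.phase, h.chrom, h.diag, h.ref_pos))
    for hit in ordered:
        last = chains[-1] if chains else None
        if last is not None:
            prev = last[-1]
            same = prev.phase == hit.phase and prev.chrom == hit.chrom
            if (
                same
                and abs(hit.diag - prev.diag) <= params.diag_tolerance
                and hit.ref_pos - (prev.ref_pos + prev.length) <= params.merge_gap
                and abs(hit.read_pos - prev.read_pos) <= params.merge_gap + prev.length
            ):
                last.append(hit)
                continue
        chains.append([hit])
    return chains


# ---------------------------------------------------------------------------
# extension (banded Gotoh in collapsed space, scored in original space)
# ---------------------------------------------------------------------------


def _pair_allowed(ref: np.ndarray, q: int, phase: str) -> np.ndarray:
    """Vectorized match test for one read base against a reference window."""
    ok = ref == q
    if phase == "CT" and q == ord("T"):
        ok = ok | (ref == ord("C"))
    elif phase == "GA" and q == ord("A"):
        ok = ok | (ref == ord("G"))
    if q == ord("N"):
        ok[:] = False
    else:
        ok = ok & (ref != ord("N"))
    return ok


def _gapless_score(
    read: str, chrom_seq: str, start: int, phase: str, params: MapperParams
) -> tuple[int, int] | None:
    """Score of the gap-free alignment placing the read at ``start``."""
    L = len(read)
    if start < 0 or start + L > len(chrom_seq):
        return None
    ref = np.frombuffer(chrom_seq[start : start + L].encode("ascii"), dtype=np.uint8)
    q = np.frombuffer(read.encode("ascii"), dtype=np.uint8)
    ok = ref == q
    if phase == "CT":
        ok = ok | ((ref == ord("C")) & (q == ord("T")))
    else:
        ok = ok | ((ref == ord("G")) & (q == ord("A")))
    ok = ok & (ref != ord("N")) & (q != ord("N"))
    n_match = int(np.count_nonzero(ok))
    n_mm = L - n_match
    return n_match * params.match + n_mm * params.mismatch, n_mm


def banded_align(
    read: str,
    chrom_seq: str,
    window_start: int,
    window_end: int,
    phase: str,
    params: MapperParams,
) -> tuple[int, int, int, str, int] | None:
    """Affine-gap alignment of the whole read against a reference window.

    Global in the read, free at both reference ends (the window plays the
    band).  Returns (score, ref_start, ref_end, cigar, n_mismatch) with
    coordinates on the chromosome, or None for an empty window.  Gap-open
    applies to the first base of a gap, gap-extend to each further base;
    insertions and deletions never abut.
    """
    window_start = max(0, window_start)
    window_end = min(len(chrom_seq), window_end)
    W = window_end - window_start
    L = len(read)
    if W <= 0 or L == 0:
        return None
    ref = np.frombuffer(
        chrom_seq[window_start:window_end].encode("ascii"), dtype=np.uint8
    )
    q = np.frombuffer(read.encode("ascii"), dtype=np.uint8)
    mt, mm = params.match, params.mismatch
    go, ge = params.gap_open, params.gap_extend

    M = np.full((L + 1, W + 1), NEG_INF, dtype=np.int32)
    Ix = np.full((L + 1, W + 1), NEG_INF, dtype=np.int32)  # gap in ref (read insert)
    Iy = np.full((L + 1, W + 1), NEG_INF, dtype=np.int32)  # gap in read (deletion)
    M[0, :] = 0  # free reference start
    for i in range(1, L + 1):
        ok = _pair_allowed(ref, int(q[i - 1]), phase)
        s_row = np.where(ok, mt, mm).astype(np.int32)
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = s_row + prev_best[:-1]
        M[i, 0] = NEG_INF
        Ix[i] = np.maximum(M[i - 1] + go, Ix[i - 1] + ge)
        # Iy chains horizontally from M in the same row: closed form via
        # running max of (M[i, j'] + go - ge*(j'+1)).
        d = M[i, :-1].astype(np.int64) + go - ge * (np.arange(W) + 1)
        acc = np.maximum.accumulate(d)
        Iy[i, 1:] = (acc + ge * (np.arange(1, W + 1))).astype(np.int32)
        Iy[i, 0] = NEG_INF

    final = np.maximum(M[L], Ix[L])
    j_end = int(np.argmax(final))
    score = int(final[j_end])
    if score <= NEG_INF // 2:
        return None

    # traceback
    state = "M" if M[L, j_end] >= Ix[L, j_end] else "X"
    i, j = L, j_end
    ops: list[str] = []
    n_mm = 0
    while i > 0:
        if state == "M":
            ok = _pair_allowed(ref[j - 1 : j], int(q[i - 1]), phase)[0]
            if not ok:
                n_mm += 1
            ops.append("M")
            prev = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            state = "MXY"[int(np.argmax(prev))]
            i, j = i - 1, j - 1
        elif state == "X":  # insertion: consume read base
            ops.append("I")
            opened = M[i - 1, j] + go
            extended = Ix[i - 1, j] + ge
            state = "M" if opened >= extended else "X"
            i -= 1
        else:  # Y: deletion: consume reference base
            ops.append("D")
            opened = M[i, j - 1] + go
            extended = Iy[i, j - 1] + ge
            state = "M" if opened >= extended else "Y"
            j -= 1
    ref_start = window_start + j
    ref_end = window_start + j_end
    ops.reverse()
    cigar = _run_length_cigar(ops)
    return score, ref_start, ref_end, cigar, n_mm


def _run_length_cigar(ops: list[str]) -> str:
    out = []
    i = 0
    while i < len(ops):
        j = i
        while j < len(ops) and ops[j] == ops[i]:
            j += 1
        out.append(f"{j - i}{ops[i]}")
        i = j
    return "".join(out)


def extend_alignment(
    chain: list[SeedHit],
    read_id: str,
    read: str,
    genome: ReferenceGenome,
    params: MapperParams,
) -> AlignmentResult | None:
    """Extend one seed chain to a full-read alignment.

    When the chain is single-diagonal and the gap-free placement is
    perfect, the alignment is emitted directly; otherwise a banded
    affine-gap alignment over the chain's diagonal window decides.
    """
    if not chain:
        return None
    phase = chain[0].phase
    chrom = chain[0].chrom
    seq = genome[chrom]
    L = len(read)
    diags = [h.diag for h in chain]
    lo_d, hi_d = min(diags), max(diags)

    if lo_d == hi_d:
        gl = _gapless_score(read, seq, lo_d, phase, params)
        if gl is not None and gl[0] == params.match * L:
            return AlignmentResult(
                read_id, chrom, lo_d, lo_d + L, phase, gl[0], f"{L}M", 0
            )
    res = banded_align(
        read,
        seq,
        lo_d - params.band,
        hi_d + L + params.band,
        phase,
        params,
    )
    if res is None:
        return None
    score, start, end, cigar, n_mm = res
    if end <= start:
        return None
    return AlignmentResult(read_id, chrom, start, end, phase, score, cigar, n_mm)


# ---------------------------------------------------------------------------
# whole-read mapping
# ---------------------------------------------------------------------------


class Mapper:
    """Both phase indices over one genome, plus the mapping loop."""

    def __init__(self, genome: ReferenceGenome, params: MapperParams | None = None):
        self.genome = genome
        self.params = params if params is not None else MapperParams()
        self.indices = {
            "CT": build_index(genome, "CT"),
            "GA": build_index(genome, "GA"),
        }

    def map_read(self, read_id: str, read: str) -> MapResult:
        params = self.params
        L = len(read)
        if L == 0:
            return MapResult("unmapped")
        candidates: dict[tuple[str, int, int], AlignmentResult] = {}
        for phase in ("CT", "GA"):
            hits = seed_read(read, self.indices[phase], self.genome, params)
            chains = merge_seeds(hits, params)
            chains.sort(key=lambda c: -sum(h.length for h in c))
            for chain in chains[: params.max_candidates]:
                aln = extend_alignment(chain, read_id, read, self.genome, params)
                if aln is None:
                    continue
                key = aln.key()
                prev = candidates.get(key)
                if prev is None or aln.score > prev.score:
                    candidates[key] = aln
        if not candidates:
            return MapResult("unmapped")
        ranked = sorted(
            candidates.values(), key=lambda a: (-a.score, a.phase, a.chrom, a.start)
        )
        best = ranked[0]
        second = ranked[1].score if len(ranked) > 1 else None
        threshold = params.min_score_fraction * params.match * L
        if best.score < threshold:
            return MapResult("unmapped", best_score=best.score, second_score=second)
        if second is not None and best.score - second < params.uniqueness_margin:
            best.unique = False
            return MapResult("ambiguous", best, best.score, second)
        best.unique = True
        return MapResult("unique", best, best.score, second)

    def map_reads(
        self, reads: list[tuple[str, str]]
    ) -> tuple[list[AlignmentResult], dict[str, int]]:
        """Map many reads; returns unique alignments and status counters."""
        alignments: list[AlignmentResult] = []
        counts = {"unique": 0, "ambiguous": 0, "unmapped": 0}
        for read_id, seq in reads:
            res = self.map_read(read_id, seq)
            counts[res.status] += 1
            if res.status == "unique":
                alignments.append(res.alignment)
        return alignments, counts


# ---------------------------------------------------------------------------
# alignment I/O
# ---------------------------------------------------------------------------

ALN_COLUMNS = [
    "read_id",
    "chrom",
    "start",
    "end",
    "phase",
    "score",
    "n_mismatch",
    "unique",
    "cigar",
]


def write_alignments(alignments: list[AlignmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ALN_COLUMNS) + "\n")
        for a in alignments:
            fh.write(
                f"{a.read_id}\t{a.chrom}\t{a.start}\t{a.end}\t{a.phase}\t"
                f"{a.score}\t{a.n_mismatch}\t{int(a.unique)}\t{a.cigar}\n"
            )


def read_alignments(path) -> list[AlignmentResult]:
    out: list[AlignmentResult] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ALN_COLUMNS:
            raise ValueError(f"unexpected alignment columns in {path}")
        for line in fh:
            c = line.rstrip("\n").split("\t")
            out.append(
                AlignmentResult(
                    c[0], c[1], int(c[2]), int(c[3]), c[4], int(c[5]), c[8],
                    int(c[6]), bool(int(c[7])),
                )
            )
    return out


def write_sam(
    alignments: list[AlignmentResult],
    genome: ReferenceGenome,
    reads: dict[str, str],
    path,
) -> None:
    """Minimal SAM export (MAPQ fixed at 30; GA-phase reads flagged reverse)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, length in genome.lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for a in alignments:
            flag = 16 if a.phase == "GA" else 0
            seq = reads.get(a.read_id, "*")
            fh.write(
                f"{a.read_id}\t{flag}\t{a.chrom}\t{a.start + 1}\t30\t{a.cigar}\t"
                f"*\t0\t0\t{seq}\t*\n"
            )
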