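"""In-silico emulation of a MIRA-enriched 454 bisulfite sequencing library.

The generator walks the wet protocol end to end: restriction digestion with
three TA-overhang enzymes (MseI, BfaI, Csp6I, digested separately and
pooled), size selection, adapter ligation, affinity capture biased toward
methyl-CpG-dense fragments, stochastic bisulfite conversion with imperfect
efficiency, and 454-like single-end reads taken from the template ends.
Everything it does is recorded in a :class:`TruthSet`, so downstream stages
(alignment, methylation calling, region calling) can be scored against
ground truth.

Orientation model
-----------------
Bisulfite conversion makes the two strands of a fragment non-complementary,
and after PCR four read classes exist.  Only two of them align to the
forward reference under the mapper's two collapse phases (C→T and G→A);
the other two are their reverse complements.  The simulator therefore
emits every read pre-oriented along forward coordinates: "CT" molecules
carry C→T conversions, "GA" molecules carry G→A conversions (the bottom
strand's conversions viewed from the top), and a read is a prefix (left
template end) or suffix (right template end) of its molecule, chosen
uniformly.  This covers both fragment ends and exercises both mapper
phases without requiring a reverse-complement phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .refdata import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    ReferenceGenome,
    find_cpg_sites,
    reverse_complement,
)

# Adapter oligos of the linker-ligated library (space-stripped, 5'→3').
ADAPTER_TOP = "AGTTATTCTGGACTGTCGAAGCTGAATGCCATGG"
ADAPTER_BOTTOM = "TACCATGGCATTCAGCTTCGACAGTCCAGAAT"

# Bisulfite-PCR primers matching the converted linker sequences.
BSP_PRIMER_FWD = "TTGGATTGTTGAAGTTGAATG"
BSP_PRIMER_REV = "AAACTATCAAAACTAAATACCATAATA"

# Restriction enzymes: recognition sequence and cut offset from the site
# start (all three cut after base 1, leaving TA overhangs).  Encoded as
# data so the digest engine can be exercised with toy enzymes.
DEFAULT_ENZYMES: dict[str, tuple[str, int]] = {
    "MseI": ("TTAA", 1),
    "BfaI": ("CTAG", 1),
    "Csp6I": ("GTAC", 1),
}


class ConfigError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass
class SimulationConfig:
    """Study conditions for the library emulation.

    Defaults follow the protocol being emulated: three-enzyme digestion,
    200–800 bp size selection, conversion efficiency 0.97, and FLX read
    lengths (mean 143 bp, range 20–444).  ``titanium()`` switches the read
    length model to the longer-read chemistry (mean 218, range 20–692).
    """

    genome_length: int = 200_000
    n_chroms: int = 4
    cgi_count: int = 20
    cgi_length_range: tuple[int, int] = (500, 1500)
    gene_count: int = 20
    gene_length_range: tuple[int, int] = (2_000, 8_000)
    promoter_cgi_fraction: float = 0.5
    repeat_count: int = 30
    repeat_length_range: tuple[int, int] = (150, 500)
    background_gc: float = 0.40
    cgi_gc: float = 0.65

    # methylation profile: per-region target level and draw SD
    methylation_profile: dict[str, float] = field(
        default_factory=lambda: {"cgi": 0.9, "background": 0.05}
    )
    level_sd: float = 0.05

    enzymes: dict[str, tuple[str, int]] = field(
        default_factory=lambda: dict(DEFAULT_ENZYMES)
    )
    size_range: tuple[int, int] = (200, 800)

    conversion_efficiency: float = 0.97
    capture_k_half: float = 3.0
    capture_floor: float = 0.01

    read_length_mean: float = 143.0
    read_length_min: int = 20
    read_length_max: int = 444
    error_rate: float = 0.001
    n_reads: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.conversion_efficiency <= 1.0:
            raise ConfigError("conversion_efficiency must lie in [0, 1]")
        if not (
            self.read_length_min <= self.read_length_mean <= self.read_length_max
        ):
            raise ConfigError("read length model requires min ≤ mean ≤ max")
        for name, (site, offset) in self.enzymes.items():
            if set(site) - set("ACGT"):
                raise ConfigError(f"enzyme {name}: recognition sequence not over ACGT")
            if not 0 <= offset <= len(site):
                raise ConfigError(f"enzyme {name}: cut offset outside site")
        for region, target in self.methylation_profile.items():
            if not 0.0 <= target <= 1.0:
                raise ConfigError(f"profile target for {region!r} outside [0, 1]")
        if self.cgi_count * self.cgi_length_range[1] > self.genome_length:
            raise ConfigError("CGIs cannot fit in the genome")
        if self.n_reads <= 0:
            raise ConfigError("n_reads must be positive")

    def titanium(self) -> "SimulationConfig":
        return replace(
            self, read_length_mean=218.0, read_length_min=20, read_length_max=692
        )


@dataclass(frozen=True)
class ReadTruth:
    """Ground truth for one simulated read."""

    chrom: str
    start: int  # genomic span covered by the read's insert portion
    end: int
    phase: str  # "CT" or "GA"
    fragment: GenomicInterval
    n_cpg_methylated: int
    n_errors: int


@dataclass
class TruthSet:
    """Complete simulator ground truth."""

    cpg_levels: dict[tuple[str, int], float]
    fragments: list[GenomicInterval]
    captured: list[GenomicInterval]
    reads: dict[str, ReadTruth] = field(default_factory=dict)


@dataclass
class SimulatedLibrary:
    """Everything one simulation run produces."""

    genome: ReferenceGenome
    annotation: AnnotationSet
    truth: TruthSet
    reads: list[tuple[str, str]]  # (read_id, sequence)
    config: SimulationConfig


# ---------------------------------------------------------------------------
# genome synthesis
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    return _BASES[rng.choice(4, size=n, p=p)]


def _island_seq(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """CpG-island-like sequence: GC-rich with explicitly planted CpGs.

    An i.i.d. draw at island GC alone leaves the CpG observed/expected
    ratio at 1 but the absolute density too close to background; planting
    one CG dinucleotide per ~12 bp pushes the density to island-like
    levels while leaving GC content near the target.
    """
    seq = _random_seq(n, gc, rng)
    if n >= 2:
        n_plant = n // 12
        pos = rng.integers(0, n - 1, size=n_plant)
        seq[pos] = ord("C")
        seq[pos + 1] = ord("G")
    return seq


def synthesize_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[ReferenceGenome, AnnotationSet]:
    """Random genome with planted CpG islands, genes and a repeat track.

    Background base composition is ~40% GC; islands are i.i.d. draws at
    ~65% GC, which makes their CpG density both absolutely high and high
    relative to expectation (observed/expected ≈ 1).  Roughly half the
    genes get a planted island centered on their TSS.  The repeat track is
    positional annotation only — no literal sequence copies are planted,
    so unique mapping remains well-defined at this scale.
    """
    chrom_len = config.genome_length // config.n_chroms
    names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    seqs = {name: _random_seq(chrom_len, config.background_gc, rng) for name in names}

    # place CGIs without overlap, round-robin across chromosomes
    cgis: list[GenomicInterval] = []
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}

    def _place(name: str, length: int) -> int | None:
        for _ in range(200):
            start = int(rng.integers(0, chrom_len - length))
            if all(
                start + length <= s or start >= e for s, e in occupied[name]
            ):
                occupied[name].append((start, start + length))
                return start
        return None

    for i in range(config.cgi_count):
        name = names[i % len(names)]
        length = int(rng.integers(*config.cgi_length_range, endpoint=True))
        start = _place(name, length)
        if start is None:
            raise ConfigError("could not place CGIs without overlap")
        seqs[name][start : start + length] = _island_seq(length, config.cgi_gc, rng)
        cgis.append(GenomicInterval(name, start, start + length, name=f"CGI{i + 1}"))

    # genes: a configurable fraction get a CGI promoter (TSS at island center)
    genes: list[GeneModel] = []
    n_promoter = int(round(config.gene_count * config.promoter_cgi_fraction))
    for i in range(config.gene_count):
        length = int(rng.integers(*config.gene_length_range, endpoint=True))
        strand = "+" if rng.random() < 0.5 else "-"
        if i < n_promoter and i < len(cgis):
            island = cgis[i]
            tss = (island.start + island.end) // 2
            if strand == "+":
                start, end = tss, min(tss + length, chrom_len)
            else:
                start, end = max(tss - length, 0), tss
            name = island.chrom
        else:
            name = names[int(rng.integers(len(names)))]
            start = int(rng.integers(0, max(chrom_len - length, 1)))
            end = min(start + length, chrom_len)
        if end - start < 2:
            continue
        genes.append(GeneModel(f"gene{i + 1}", name, strand, start, end))

    repeat_classes = ["SINE", "LINE", "LTR", "Simple_repeat"]
    repeats: list[tuple[GenomicInterval, str]] = []
    for i in range(config.repeat_count):
        name = names[int(rng.integers(len(names)))]
        length = int(rng.integers(*config.repeat_length_range, endpoint=True))
        start = int(rng.integers(0, chrom_len - length))
        cls = repeat_classes[i % len(repeat_classes)]
        repeats.append(
            (GenomicInterval(name, start, start + length, name=cls), cls)
        )

    genome = ReferenceGenome(
        {name: seqs[name].tobytes().decode("ascii") for name in names}
    )
    return genome, AnnotationSet(genes=genes, cgis=cgis, repeats=repeats)


# ---------------------------------------------------------------------------
# methylation assignment
# ---------------------------------------------------------------------------


def assign_methylation(
    genome: ReferenceGenome,
    annotation: AnnotationSet,
    profile: dict[str, float],
    rng: np.random.Generator,
    level_sd: float = 0.05,
) -> dict[tuple[str, int], float]:
    """Assign a true methylation level to every CpG site.

    Each site gets a draw from a [0, 1]-truncated normal around its
    region's target.  Recognized profile keys, by precedence: ``cgi``,
    ``repeat``, ``gene_body``, ``background`` (``background`` is the
    fallback and defaults to 0 if absent).  A tumor-like profile sets
    ``cgi`` high; a normal-like profile sets ``repeat``/``gene_body``
    high instead.
    """
    for region, target in profile.items():
        if not 0.0 <= target <= 1.0:
            raise ConfigError(f"profile target for {region!r} outside [0, 1]")
    sites = find_cpg_sites(genome)

    from .refdata import IntervalIndex

    cgi_idx = IntervalIndex.from_intervals(annotation.cgis)
    rep_idx = IntervalIndex((iv, cls) for iv, cls in annotation.repeats)
    body_idx = IntervalIndex(
        (GenomicInterval(g.chrom, g.tx_start, g.tx_end), g) for g in annotation.genes
    )

    def target_for(chrom: str, pos: int) -> float:
        if "cgi" in profile and cgi_idx.overlaps(chrom, pos, pos + 1):
            return profile["cgi"]
        if "repeat" in profile and rep_idx.overlaps(chrom, pos, pos + 1):
            return profile["repeat"]
        if "gene_body" in profile and body_idx.overlaps(chrom, pos, pos + 1):
            return profile["gene_body"]
        return profile.get("background", 0.0)

    targets = np.array([target_for(c, p) for c, p in sites])
    if level_sd <= 0.0:
        levels = targets
    else:
        a = (0.0 - targets) / level_sd
        b = (1.0 - targets) / level_sd
        levels = stats.truncnorm.rvs(
            a, b, loc=targets, scale=level_sd, random_state=rng
        )
    return {site: float(level) for site, level in zip(sites, levels)}


# ---------------------------------------------------------------------------
# digestion, ligation, capture
# ---------------------------------------------------------------------------


def digest_sequence(seq: str, site: str, cut_offset: int) -> list[tuple[int, int]]:
    """Fragment boundaries for one enzyme on one sequence.

    Cuts at ``occurrence_start + cut_offset`` for every occurrence of the
    recognition sequence; fragments tile [0, len(seq)) exactly.
    """
    cuts = []
    start = seq.find(site)
    while start != -1:
        cuts.append(start + cut_offset)
        start = seq.find(site, start + 1)
    bounds = [0] + [c for c in cuts if 0 < c < len(seq)] + [len(seq)]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


def digest(
    genome: ReferenceGenome, enzymes: dict[str, tuple[str, int]] | None = None
) -> list[GenomicInterval]:
    """Pooled single-enzyme digests of the whole genome.

    Each enzyme digests every chromosome to completion separately; the
    returned list is the union of the per-enzyme fragment pools (fragments
    carry the enzyme name).
    """
    enzymes = dict(DEFAULT_ENZYMES) if enzymes is None else enzymes
    fragments: list[GenomicInterval] = []
    for enzyme, (site, offset) in enzymes.items():
        for chrom, seq in genome.chromosomes.items():
            if not seq:
                continue
            for start, end in digest_sequence(seq, site, offset):
                fragments.append(GenomicInterval(chrom, start, end, name=enzyme))
    return fragments


def size_select(
    fragments: list[GenomicInterval], size_range: tuple[int, int]
) -> list[GenomicInterval]:
    lo, hi = size_range
    return [f for f in fragments if lo <= len(f) <= hi]


def ligate_adapters(fragment_seq: str) -> str:
    """Top strand of the adapter-ligated template.

    template = top adapter oligo + fragment + reverse complement of the
    bottom adapter oligo, per the shared TA-overhang geometry.
    """
    if len(fragment_seq) < 1:
        raise ConfigError("cannot ligate an empty fragment")
    return ADAPTER_TOP + fragment_seq + reverse_complement(ADAPTER_BOTTOM)


def capture_probability(m: float, k_half: float, floor: float) -> float:
    """Saturating capture model: p = m / (m + k_half), floored at ``floor``.

    ``m`` is the fragment's expected methylated-CpG count (sum of site
    levels).  The true affinity curve of the capture step is unknown; any
    monotone model yields enrichment of methylated fragments, and this
    one saturates with a configurable half-maximal count.
    """
    if m <= 0.0:
        return floor
    return max(m / (m + k_half), floor)


def mira_capture(
    fragments: list[GenomicInterval],
    cpg_levels: dict[tuple[str, int], float],
    rng: np.random.Generator,
    k_half: float = 3.0,
    floor: float = 0.01,
) -> list[GenomicInterval]:
    """Methylation-density-biased fragment capture."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {f.chrom for f in fragments}:
        pairs = sorted(
            (pos, lvl) for (c, pos), lvl in cpg_levels.items() if c == chrom
        )
        pos = np.array([p for p, _ in pairs], dtype=np.int64)
        lvl = np.array([l for _, l in pairs])
        by_chrom[chrom] = (pos, np.concatenate([[0.0], np.cumsum(lvl)]))

    captured = []
    for frag in fragments:
        pos, cum = by_chrom[frag.chrom]
        i = np.searchsorted(pos, frag.start, side="left")
        j = np.searchsorted(pos, frag.end, side="left")
        m = float(cum[j] - cum[i])
        if rng.random() < capture_probability(m, k_half, floor):
            captured.append(frag)
    return captured


# ---------------------------------------------------------------------------
# bisulfite conversion
# ---------------------------------------------------------------------------


def bisulfite_convert(
    template: str,
    is_cpg: np.ndarray,
    levels: np.ndarray,
    efficiency: float,
    rng: np.random.Generator,
    phase: str = "CT",
) -> tuple[str, int, int]:
    """Stochastic bisulfite conversion of one molecule.

    ``is_cpg``/``levels`` flag, per template position, the cytosines (CT
    phase) or guanines (GA phase) that sit in a CpG context and give their
    true methylation level.  A flagged base is first drawn methylated with
    probability ``level``; methylated bases never convert, unmethylated
    ones convert with probability ``efficiency`` (C→T or G→A).  Every
    unflagged C (resp. G) converts with probability ``efficiency``.

    Returns (converted sequence, number of CpG bases drawn methylated,
    number of CpG bases eligible), the per-molecule conversion record.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ConfigError("efficiency must lie in [0, 1]")
    if phase not in ("CT", "GA"):
        raise ConfigError(f"unknown phase {phase!r}")
    src, dst = ("C", "T") if phase == "CT" else ("G", "A")
    arr = np.frombuffer(template.encode("ascii"), dtype=np.uint8).copy()
    is_src = arr == ord(src)
    u = rng.random(arr.size)
    meth = is_cpg & is_src & (u < levels)
    n_cpg = int(np.count_nonzero(is_cpg & is_src))
    n_meth = int(np.count_nonzero(meth))
    convert = is_src & ~meth & (rng.random(arr.size) < efficiency)
    arr[convert] = ord(dst)
    return arr.tobytes().decode("ascii"), n_meth, n_cpg


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------


def draw_read_lengths(
    n: int,
    mean: float,
    lo: int,
    hi: int,
    rng: np.random.Generator,
    sigma: float = 0.35,
) -> np.ndarray:
    """454-like read lengths: log-normal with fixed shape, truncated to [lo, hi].

    ``mu`` is set so the untruncated mean equals ``mean``; at the default
    shape the [lo, hi] truncation moves the mean by well under a base.
    """
    mu = np.log(mean) - sigma**2 / 2.0
    lengths = rng.lognormal(mu, sigma, size=n)
    bad = (lengths < lo) | (lengths > hi)
    while np.any(bad):
        lengths[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
        bad = (lengths < lo) | (lengths > hi)
    return np.round(lengths).astype(np.int64)


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate <= 0.0:
        return seq, 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode("ascii"), len(hit)


def simulate(config: SimulationConfig) -> SimulatedLibrary:
    """Run the full library emulation and return reads plus ground truth."""
    rng = np.random.default_rng(config.seed)
    genome, annotation = synthesize_genome(config, rng)
    cpg_levels = assign_methylation(
        genome, annotation, config.methylation_profile, rng, config.level_sd
    )
    fragments = size_select(digest(genome, config.enzymes), config.size_range)
    captured = mira_capture(
        fragments, cpg_levels, rng, config.capture_k_half, config.capture_floor
    )
    if not captured:
        raise ConfigError("no fragments captured; check capture parameters")

    n_adapt_l = len(ADAPTER_TOP)
    lengths = draw_read_lengths(
        config.n_reads,
        config.read_length_mean,
        config.read_length_min,
        config.read_length_max,
        rng,
    )
    frag_choice = rng.integers(len(captured), size=config.n_reads)
    phase_choice = rng.random(config.n_reads) < 0.5
    end_choice = rng.random(config.n_reads) < 0.5

    # Per-chromosome CpG masks and levels, used to annotate templates fast:
    # cpg_c flags the C of every CpG, cpg_g the G; level arrays carry the
    # site's truth level at those positions.
    chrom_ann: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, seq in genome.chromosomes.items():
        n = len(seq)
        cpg_c = np.zeros(n, dtype=bool)
        cpg_g = np.zeros(n, dtype=bool)
        lvl_c = np.zeros(n)
        lvl_g = np.zeros(n)
        for (c, pos), level in cpg_levels.items():
            if c != chrom:
                continue
            cpg_c[pos] = True
            lvl_c[pos] = level
            cpg_g[pos + 1] = True
            lvl_g[pos + 1] = level
        chrom_ann[chrom] = (cpg_c, lvl_c, cpg_g, lvl_g)

    # fragment -> (template, CT mask/levels, GA mask/levels), built lazily
    frag_cache: dict[tuple[str, int, int], tuple] = {}

    def _template_for(frag: GenomicInterval):
        key = (frag.chrom, frag.start, frag.end)
        if key not in frag_cache:
            frag_seq = genome[frag.chrom][frag.start : frag.end]
            template = ligate_adapters(frag_seq)
            t_len = len(template)
            cpg_c, lvl_c, cpg_g, lvl_g = chrom_ann[frag.chrom]
            ct_mask = np.zeros(t_len, dtype=bool)
            ct_lvl = np.zeros(t_len)
            ga_mask = np.zeros(t_len, dtype=bool)
            ga_lvl = np.zeros(t_len)
            sl = slice(n_adapt_l, n_adapt_l + len(frag))
            ct_mask[sl] = cpg_c[frag.start : frag.end]
            ct_lvl[sl] = lvl_c[frag.start : frag.end]
            ga_mask[sl] = cpg_g[frag.start : frag.end]
            ga_lvl[sl] = lvl_g[frag.start : frag.end]
            frag_cache[key] = (template, ct_mask, ct_lvl, ga_mask, ga_lvl)
        return frag_cache[key]

    truth = TruthSet(cpg_levels=cpg_levels, fragments=fragments, captured=captured)
    reads: list[tuple[str, str]] = []
    pad = len(str(config.n_reads))
    for i in range(config.n_reads):
        frag = captured[int(frag_choice[i])]
        phase = "CT" if phase_choice[i] else "GA"
        template, ct_mask, ct_lvl, ga_mask, ga_lvl = _template_for(frag)
        t_len = len(template)
        is_cpg, levels = (ct_mask, ct_lvl) if phase == "CT" else (ga_mask, ga_lvl)

        converted, n_meth, _ = bisulfite_convert(
            template, is_cpg, levels, config.conversion_efficiency, rng, phase
        )
        length = min(int(lengths[i]), t_len)
        if end_choice[i]:
            t_start = 0
        else:
            t_start = t_len - length
        read_seq = converted[t_start : t_start + length]
        read_seq, n_err = _inject_errors(read_seq, config.error_rate, rng)

        # genomic span of the insert portion covered by the read
        ins_lo = max(t_start, n_adapt_l) - n_adapt_l + frag.start
        ins_hi = min(t_start + length, n_adapt_l + len(frag)) - n_adapt_l + frag.start
        read_id = f"read{i:0{pad}d}"
        truth.reads[read_id] = ReadTruth(
            chrom=frag.chrom,
            start=min(ins_lo, ins_hi),
            end=max(ins_lo, ins_hi),
            phase=phase,
            fragment=frag,
            n_cpg_methylated=n_meth,
            n_errors=n_err,
        )
        reads.append((read_id, read_seq))

    return SimulatedLibrary(genome, annotation, truth, reads, config)


# ---------------------------------------------------------------------------
# output files
# ---------------------------------------------------------------------------


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth(truth: TruthSet, levels_path, reads_path) -> None:
    with open(levels_path, "w") as fh:
        fh.write("chrom\tpos\tlevel\n")
        for (chrom, pos), level in sorted(truth.cpg_levels.items()):
            fh.write(f"{chrom}\t{pos}\t{level:.6f}\n")
    with open(reads_path, "w") as fh:
        fh.write("read_id\tchrom\tstart\tend\tphase\n")
        for read_id, rt in truth.reads.items():
            fh.write(f"{read_id}\t{rt.chrom}\t{rt.start}\t{rt.end}\t{rt.phase}\n")
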