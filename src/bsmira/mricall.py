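"""Read clusters, methylation indices, and methylated regions of interest.

A cluster is a maximal run of overlapping or abutting unique alignments
(any positive gap splits).  Its methylation index is the unweighted mean
of the per-site methylation levels of the CpG sites inside it; clusters
without a CpG site have no index and are excluded.  A methylated region
of interest (MRI) is a cluster at least 50 bp long, with at least 5
reads, whose index strictly exceeds 20% — all three thresholds are
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .bsalign import AlignmentResult
from .refdata import GenomicInterval, ReferenceGenome


@dataclass
class MRIParams:
    min_reads: int = 5
    min_length: int = 50
    min_index: float = 0.20  # exclusive threshold
    require_cpg: bool = True

    def __post_init__(self) -> None:
        if self.min_reads < 1 or self.min_length < 1 or self.min_index < 0:
            raise ValueError("MRI thresholds must be positive")


@dataclass
class Cluster:
    interval: GenomicInterval
    n_reads: int
    cpg_positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    cpg_levels: np.ndarray = field(default_factory=lambda: np.empty(0))
    cpg_totals: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def methylation_index(self) -> float | None:
        """Unweighted mean of site levels; None when the cluster has no CpG."""
        if self.cpg_levels.size == 0:
            return None
        return float(np.mean(self.cpg_levels))

    @property
    def n_cpg(self) -> int:
        return int(self.cpg_positions.size)


def build_clusters(
    alignments: list[AlignmentResult], merge_gap: int = 0
) -> list[Cluster]:
    """Merge alignments into maximal overlapping-or-abutting clusters.

    Input order is irrelevant (sorted internally).  With the default
    ``merge_gap`` of 0 bp, reads merge when they overlap or abut exactly;
    a 1-bp gap starts a new cluster.
    """
    by_chrom: dict[str, list[AlignmentResult]] = {}
    for aln in alignments:
        by_chrom.setdefault(aln.chrom, []).append(aln)
    clusters: list[Cluster] = []
    for chrom in sorted(by_chrom):
        alns = sorted(by_chrom[chrom], key=lambda a: (a.start, a.end))
        cur_start, cur_end, cur_n = None, None, 0
        for aln in alns:
            if cur_start is None:
                cur_start, cur_end, cur_n = aln.start, aln.end, 1
            elif aln.start <= cur_end + merge_gap:
                cur_end = max(cur_end, aln.end)
                cur_n += 1
            else:
                clusters.append(
                    Cluster(GenomicInterval(chrom, cur_start, cur_end), cur_n)
                )
                cur_start, cur_end, cur_n = aln.start, aln.end, 1
        if cur_start is not None:
            clusters.append(
                Cluster(GenomicInterval(chrom, cur_start, cur_end), cur_n)
            )
    return clusters


def attach_cpg_sites(clusters: list[Cluster], site_table: pd.DataFrame) -> None:
    """Fill each cluster with the covered CpG sites inside its interval."""
    by_chrom = {
        chrom: grp.sort_values("pos")
        for chrom, grp in site_table.groupby("chrom", sort=False)
    }
    for cl in clusters:
        grp = by_chrom.get(cl.interval.chrom)
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        i = np.searchsorted(pos, cl.interval.start, side="left")
        j = np.searchsorted(pos, cl.interval.end, side="left")
        cl.cpg_positions = pos[i:j]
        cl.cpg_levels = grp["level"].to_numpy()[i:j]
        cl.cpg_totals = grp["n_total"].to_numpy()[i:j]


def filter_clusters(clusters: list[Cluster], params: MRIParams) -> list[Cluster]:
    """Length and read-count filters (both inclusive: "at least")."""
    return [
        c
        for c in clusters
        if len(c.interval) >= params.min_length and c.n_reads >= params.min_reads
    ]


def methylation_index(cluster: Cluster, site_table: pd.DataFrame) -> float | None:
    """Convenience single-cluster index (attaches sites, then averages)."""
    attach_cpg_sites([cluster], site_table)
    return cluster.methylation_index


def call_mris(clusters: list[Cluster], params: MRIParams | None = None) -> list[Cluster]:
    """MRIs: clusters passing all filters with index strictly above threshold.

    Clusters with no CpG site have no index and are excluded (they cannot
    be assessed for methylation).
    """
    params = params if params is not None else MRIParams()
    kept = []
    for cl in filter_clusters(clusters, params):
        idx = cl.methylation_index
        if idx is None:
            if not params.require_cpg:
                continue
            continue
        if idx > params.min_index:
            kept.append(cl)
    return kept


def assert_mri_thresholds(mris: list[Cluster], params: MRIParams) -> None:
    """Post-hoc guard: every called MRI satisfies all printed thresholds."""
    for cl in mris:
        idx = cl.methylation_index
        assert len(cl.interval) >= params.min_length
        assert cl.n_reads >= params.min_reads
        assert idx is not None and idx > params.min_index


def chromosome_summary(
    mris: list[Cluster], genome: ReferenceGenome
) -> tuple[pd.DataFrame, float | None]:
    """Per-chromosome MRI counts and the count-vs-length Pearson r.

    The correlation is reported as None with fewer than 3 chromosomes.
    """
    counts = {name: 0 for name in genome.names()}
    for cl in mris:
        counts[cl.interval.chrom] += 1
    rows = [
        {
            "chrom": name,
            "length_bp": genome.lengths[name],
            "n_mri": counts[name],
            "mri_per_mb": counts[name] / (genome.lengths[name] / 1e6),
        }
        for name in genome.names()
    ]
    table = pd.DataFrame(rows)
    if len(rows) < 3:
        return table, None
    lengths = table["length_bp"].to_numpy(dtype=float)
    n = table["n_mri"].to_numpy(dtype=float)
    if np.std(lengths) == 0 or np.std(n) == 0:
        return table, None
    r = float(_sps.pearsonr(n, lengths).statistic)
    return table, r


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_clusters_bed(clusters: list[Cluster], path, prefix: str = "cluster") -> None:
    """BED: name = cluster id, score = read count."""
    with open(path, "w") as fh:
        for i, cl in enumerate(clusters, 1):
            iv = cl.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{prefix}{i}\t{cl.n_reads}\n")


def write_mris_bed(mris: list[Cluster], path) -> None:
    """BED: name = MRI id, score = round(index × 1000)."""
    with open(path, "w") as fh:
        for i, cl in enumerate(mris, 1):
            iv = cl.interval
            score = int(round((cl.methylation_index or 0.0) * 1000))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tMRI{i}\t{score}\n")
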