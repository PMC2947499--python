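"""Permutation test of the cluster methylation-index distribution.

Cluster geometry and the CpG-to-cluster assignment are frozen; each
permutation shuffles the per-site methylation levels (counts travel with
the level) uniformly across all covered CpG rows, recomputes every
cluster's index, re-calls MRIs with the standard thresholds, and runs a
two-sample Student t-test between the original and permuted index
distributions.  If clustered methylation structure is real, shuffling
mixes levels toward the global mean, and the permuted distributions are
systematically different from the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mricall import Cluster, MRIParams


@dataclass
class PermutationResult:
    n_perm: int
    original_indices: np.ndarray
    original_mri_count: int
    mri_counts: np.ndarray
    t_stats: np.ndarray  # NaN where undefined (zero variance)
    p_values: np.ndarray
    perm_index_means: np.ndarray
    seed: int


def permute_cpg_levels(
    site_table: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Shuffle methylation levels across CpG rows (positions stay put).

    The (n_meth, n_total, level) triple moves as a unit, sampling without
    replacement, so the level multiset is preserved exactly.
    """
    perm = rng.permutation(len(site_table))
    out = site_table.reset_index(drop=True).copy()
    for col in ("n_meth", "n_total", "level"):
        out[col] = out[col].to_numpy()[perm]
    return out


def _cluster_site_assignment(
    clusters: list[Cluster], site_table: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map each site row to its cluster (clusters never overlap).

    Returns (site_cluster_id with -1 for unclustered sites, cluster CpG
    counts, cluster eligibility mask for the length/read filters).
    """
    chroms = site_table["chrom"].to_numpy()
    pos = site_table["pos"].to_numpy(dtype=np.int64)
    assign = np.full(len(site_table), -1, dtype=np.int64)
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for ci, cl in enumerate(clusters):
        by_chrom.setdefault(cl.interval.chrom, []).append(
            (cl.interval.start, cl.interval.end, ci)
        )
    for chrom, entries in by_chrom.items():
        entries.sort()
        starts = np.array([e[0] for e in entries], dtype=np.int64)
        ends = np.array([e[1] for e in entries], dtype=np.int64)
        ids = np.array([e[2] for e in entries], dtype=np.int64)
        sel = np.nonzero(chroms == chrom)[0]
        if sel.size == 0:
            continue
        slot = np.searchsorted(starts, pos[sel], side="right") - 1
        ok = (slot >= 0) & (pos[sel] < ends[np.maximum(slot, 0)])
        assign[sel[ok]] = ids[slot[ok]]
    counts = np.bincount(assign[assign >= 0], minlength=len(clusters))
    return assign, counts, None


def cluster_indices_from_levels(
    assign: np.ndarray, counts: np.ndarray, levels: np.ndarray
) -> np.ndarray:
    """Unweighted mean level per cluster; NaN for zero-CpG clusters."""
    mask = assign >= 0
    sums = np.bincount(assign[mask], weights=levels[mask], minlength=counts.size)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def permutation_run(
    clusters: list[Cluster],
    site_table: pd.DataFrame,
    n_perm: int,
    seed: int,
    params: MRIParams | None = None,
    equal_var: bool = True,
) -> PermutationResult:
    """Run the full shuffle–recompute–test procedure.

    Child seeds for individual permutations derive deterministically from
    the master seed, so any single permutation is reproducible alone.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")
    params = params if params is not None else MRIParams()
    table = site_table.reset_index(drop=True)
    levels = table["level"].to_numpy()
    assign, counts, _ = _cluster_site_assignment(clusters, table)

    lengths = np.array([len(c.interval) for c in clusters])
    reads = np.array([c.n_reads for c in clusters])
    eligible = (lengths >= params.min_length) & (reads >= params.min_reads)
    has_cpg = counts > 0

    # The index distributions entering the t-test are those of proper
    # clusters (read/length thresholds met, ≥1 CpG); the shuffle itself
    # moves levels across the entire site table, most of which lies in
    # sub-threshold clusters.
    in_test = eligible & has_cpg
    orig = cluster_indices_from_levels(assign, counts, levels)
    orig_defined = orig[in_test]
    original_mri_count = int(
        np.sum(eligible & has_cpg & (np.nan_to_num(orig, nan=-1.0) > params.min_index))
    )

    master = np.random.SeedSequence(seed)
    children = master.spawn(n_perm)
    mri_counts = np.empty(n_perm, dtype=np.int64)
    t_stats = np.full(n_perm, np.nan)
    p_values = np.full(n_perm, np.nan)
    means = np.empty(n_perm)
    for i in range(n_perm):
        rng = np.random.default_rng(children[i])
        perm_levels = levels[rng.permutation(levels.size)]
        perm_idx = cluster_indices_from_levels(assign, counts, perm_levels)
        perm_defined = perm_idx[in_test]
        mri_counts[i] = int(
            np.sum(
                eligible
                & has_cpg
                & (np.nan_to_num(perm_idx, nan=-1.0) > params.min_index)
            )
        )
        means[i] = float(np.mean(perm_defined)) if perm_defined.size else np.nan
        if (
            orig_defined.size >= 2
            and perm_defined.size >= 2
            and (np.std(orig_defined) > 0 or np.std(perm_defined) > 0)
        ):
            t, p = stats.ttest_ind(orig_defined, perm_defined, equal_var=equal_var)
            t_stats[i] = t
            p_values[i] = p
    return PermutationResult(
        n_perm=n_perm,
        original_indices=orig_defined,
        original_mri_count=original_mri_count,
        mri_counts=mri_counts,
        t_stats=t_stats,
        p_values=p_values,
        perm_index_means=means,
        seed=seed,
    )


def summarize_permutations(
    result: PermutationResult,
    p_threshold: float = 0.05,
    n_bins: int = 20,
) -> dict:
    """Min/mean/max MRI counts, p-value histogram, fraction below threshold.

    Degenerate runs (zero-variance indices) leave p undefined; the
    fraction of undefined tests is reported rather than silently folded
    into either tail.
    """
    p = result.p_values
    defined = p[~np.isnan(p)]
    hist, edges = np.histogram(defined, bins=n_bins, range=(0.0, 1.0))
    mean_hist, mean_edges = np.histogram(
        result.perm_index_means[~np.isnan(result.perm_index_means)],
        bins=n_bins,
        range=(0.0, 1.0),
    )
    return {
        "n_perm": result.n_perm,
        "original_mri_count": result.original_mri_count,
        "mri_count_min": int(result.mri_counts.min()),
        "mri_count_mean": float(result.mri_counts.mean()),
        "mri_count_max": int(result.mri_counts.max()),
        "p_defined_fraction": float(defined.size / result.n_perm),
        "p_below_threshold_fraction": (
            float(np.mean(defined < p_threshold)) if defined.size else float("nan")
        ),
        "p_threshold": p_threshold,
        "p_histogram": hist.tolist(),
        "p_bin_edges": edges.tolist(),
        "index_mean_histogram": mean_hist.tolist(),
        "index_mean_bin_edges": mean_edges.tolist(),
    }


def write_permutations(result: PermutationResult, path) -> None:
    df = pd.DataFrame(
        {
            "perm_id": np.arange(result.n_perm),
            "mri_count": result.mri_counts,
            "t": result.t_stats,
            "p": result.p_values,
            "mean_index": result.perm_index_means,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        for key, value in summary.items():
            fh.write(f"{key}\t{value}\n")
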