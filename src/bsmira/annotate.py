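"""Genomic-context annotation of MRIs and between-sample comparison.

Each MRI receives exactly one of four categories from strand-aware gene
windows: the 5' end (promoter) window runs from 2,200 bp upstream to 500
bp downstream of the TSS, the gene body from TSS+500 to TES−500, and the
3' end ±500 bp around the TES (all in transcription orientation); an MRI
touching no window is intergenic.  When an MRI overlaps several windows,
precedence is 5' end > 3' end > gene body — promoter methylation is the
phenomenon of interest, and the narrow 3' window would otherwise be
unreachable.  CGI and repeat overlap use plain ≥1-bp interval overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mricall import Cluster
from .refdata import GeneModel, GenomicInterval, IntervalIndex

CATEGORIES = ("five_prime", "gene_body", "three_prime", "intergenic")

PROMOTER_UPSTREAM = 2200
PROMOTER_DOWNSTREAM = 500
BODY_MARGIN = 500
THREE_PRIME_FLANK = 500


@dataclass
class MRIAnnotation:
    mri: Cluster
    category: str
    cgi_overlap: bool = False
    repeat_classes: tuple[str, ...] = ()
    nearest_gene: str | None = None


def gene_windows(gene: GeneModel) -> dict[str, tuple[int, int] | None]:
    """Half-open five_prime / gene_body / three_prime windows of one gene.

    Windows are computed in transcription orientation and may be clamped
    to non-negative coordinates; a gene shorter than the two body margins
    has no body window (None).
    """
    if gene.strand == "+":
        five = (gene.tx_start - PROMOTER_UPSTREAM, gene.tx_start + PROMOTER_DOWNSTREAM)
        body = (gene.tx_start + BODY_MARGIN, gene.tx_end - BODY_MARGIN)
        three = (gene.tx_end - THREE_PRIME_FLANK, gene.tx_end + THREE_PRIME_FLANK)
    else:
        five = (gene.tx_end - PROMOTER_DOWNSTREAM, gene.tx_end + PROMOTER_UPSTREAM)
        body = (gene.tx_start + BODY_MARGIN, gene.tx_end - BODY_MARGIN)
        three = (gene.tx_start - THREE_PRIME_FLANK, gene.tx_start + THREE_PRIME_FLANK)

    def clamp(win: tuple[int, int]) -> tuple[int, int] | None:
        lo, hi = max(win[0], 0), win[1]
        return (lo, hi) if lo < hi else None

    return {"five_prime": clamp(five), "gene_body": clamp(body), "three_prime": clamp(three)}


def classify_mri(mri: Cluster, genes: list[GeneModel]) -> tuple[str, str | None]:
    """(category, gene name or None) for one MRI.

    Deduplicated gene records and gene-list order never change the result:
    within each precedence tier the overlapping gene with the smallest
    (name) label is reported.
    """
    iv = mri.interval
    hits: dict[str, list[str]] = {"five_prime": [], "gene_body": [], "three_prime": []}
    for gene in genes:
        if gene.chrom != iv.chrom:
            continue
        for label, win in gene_windows(gene).items():
            if win is None:
                continue
            if iv.start < win[1] and win[0] < iv.end:
                hits[label].append(gene.name)
    for label in ("five_prime", "three_prime", "gene_body"):
        if hits[label]:
            return label, sorted(hits[label])[0]
    return "intergenic", None


def classify_mris(
    mris: list[Cluster], genes: list[GeneModel]
) -> list[MRIAnnotation]:
    out = []
    for mri in mris:
        category, gene = classify_mri(mri, genes)
        out.append(MRIAnnotation(mri, category, nearest_gene=gene))
    return out


def category_summary(annotations: list[MRIAnnotation]) -> pd.DataFrame:
    counts = {cat: 0 for cat in CATEGORIES}
    for ann in annotations:
        counts[ann.category] += 1
    total = len(annotations)
    return pd.DataFrame(
        {
            "category": list(counts),
            "count": list(counts.values()),
            "percent": [
                100.0 * c / total if total else 0.0 for c in counts.values()
            ],
        }
    )


def overlap_cgi(
    mris: list[Cluster], cgis: list[GenomicInterval]
) -> tuple[list[bool], dict]:
    """Flag MRIs overlapping any CGI by ≥1 bp; count distinct CGIs hit."""
    idx = IntervalIndex((iv, i) for i, iv in enumerate(cgis))
    flags: list[bool] = []
    hit_cgis: set[int] = set()
    for mri in mris:
        iv = mri.interval
        found = idx.query(iv.chrom, iv.start, iv.end)
        flags.append(bool(found))
        hit_cgis.update(found)
    summary = {
        "n_mris": len(mris),
        "n_overlapping": sum(flags),
        "fraction_overlapping": (sum(flags) / len(mris)) if mris else float("nan"),
        "n_distinct_cgis_hit": len(hit_cgis),
    }
    return flags, summary


def overlap_repeats(
    mris: list[Cluster], repeats: list[tuple[GenomicInterval, str]]
) -> tuple[list[tuple[str, ...]], pd.DataFrame, dict]:
    """Per-MRI repeat classes and a per-class breakdown.

    An MRI overlapping several repeats of several classes contributes to
    each class once, and once to the "contains repeats" total.
    """
    idx = IntervalIndex((iv, cls) for iv, cls in repeats)
    per_mri: list[tuple[str, ...]] = []
    class_counts: dict[str, int] = {}
    n_with = 0
    for mri in mris:
        iv = mri.interval
        classes = tuple(sorted(set(idx.query(iv.chrom, iv.start, iv.end))))
        per_mri.append(classes)
        if classes:
            n_with += 1
        for cls in classes:
            class_counts[cls] = class_counts.get(cls, 0) + 1
    breakdown = pd.DataFrame(
        {
            "repeat_class": sorted(class_counts),
            "n_mris": [class_counts[c] for c in sorted(class_counts)],
        }
    )
    summary = {
        "n_mris": len(mris),
        "n_with_repeats": n_with,
        "fraction_with_repeats": (n_with / len(mris)) if mris else float("nan"),
    }
    return per_mri, breakdown, summary


def compare_samples(
    mris_a: list[Cluster],
    mris_b: list[Cluster],
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    min_coverage: int = 1,
) -> dict:
    """Cross-sample MRI overlap and shared-CpG methylation correlation.

    The MRI overlap counts A-side regions sharing ≥1 bp with any B-side
    region.  The Pearson correlation is computed over the per-site levels
    of CpGs covered at ``min_coverage`` or more reads in both samples,
    and is None with fewer than 3 shared sites.
    """
    idx_b = IntervalIndex((m.interval, i) for i, m in enumerate(mris_b))
    n_overlap = sum(
        1
        for m in mris_a
        if idx_b.overlaps(m.interval.chrom, m.interval.start, m.interval.end)
    )
    a = sites_a[sites_a["n_total"] >= min_coverage][["chrom", "pos", "level"]]
    b = sites_b[sites_b["n_total"] >= min_coverage][["chrom", "pos", "level"]]
    merged = a.merge(b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    if len(merged) < 3:
        r = None
    else:
        la = merged["level_a"].to_numpy()
        lb = merged["level_b"].to_numpy()
        if np.std(la) == 0 or np.std(lb) == 0:
            r = None
        else:
            r = float(stats.pearsonr(la, lb).statistic)
    return {
        "n_mris_a": len(mris_a),
        "n_mris_b": len(mris_b),
        "n_a_overlapping_b": n_overlap,
        "n_shared_cpgs": int(len(merged)),
        "pearson_r": r,
    }


def write_annotations(annotations: list[MRIAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcategory\tcgi_overlap\trepeat_classes\tgene\n")
        for ann in annotations:
            iv = ann.mri.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{ann.category}\t"
                f"{int(ann.cgi_overlap)}\t{','.join(ann.repeat_classes) or '.'}\t"
                f"{ann.nearest_gene or '.'}\n"
            )
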