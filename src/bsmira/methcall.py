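"""Per-CpG methylation calling from unique alignments.

A CpG site is recorded once, at its forward-strand C.  A CT-phase read
reports the site through its C (read C = methylated, read T = converted,
i.e. unmethylated); a GA-phase read reports the same site through the G at
the next position (read G = methylated, read A = unmethylated) and the
call is projected onto the C coordinate.  Cytosines outside a CpG context
(CpH) estimate the bisulfite conversion rate: on the forward strand these
are reference Cs not followed by G, on the reverse strand reference Gs not
preceded by C.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bsalign import AlignmentResult
from .refdata import ReferenceGenome

_CIGAR_RE = re.compile(r"(\d+)([MID])")


class IntegrityError(ValueError):
    pass


@dataclass
class CpHStats:
    """Non-CpG cytosine conversion bookkeeping."""

    n_unconverted: int = 0
    n_total: int = 0

    def __add__(self, other: "CpHStats") -> "CpHStats":
        return CpHStats(
            self.n_unconverted + other.n_unconverted, self.n_total + other.n_total
        )

    @property
    def defined(self) -> bool:
        return self.n_total > 0

    @property
    def converted_fraction(self) -> float:
        """The conversion rate as usually reported (converted / total)."""
        if not self.defined:
            return float("nan")
        return (self.n_total - self.n_unconverted) / self.n_total

    @property
    def unconverted_fraction(self) -> float:
        if not self.defined:
            return float("nan")
        return self.n_unconverted / self.n_total


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


def call_read_methylation(
    alignment: AlignmentResult,
    read: str,
    genome: ReferenceGenome,
) -> tuple[list[tuple[str, int, bool]], CpHStats]:
    """Methylation calls and CpH conversion counts from one alignment.

    Only M-op columns yield calls (inserted/deleted bases have no
    reference partner).  Returns a list of (chrom, site_pos, methylated)
    with site_pos the forward-strand C, plus the read's CpH statistics.
    """
    chrom = alignment.chrom
    seq = genome[chrom]
    if alignment.start < 0 or alignment.end > len(seq):
        raise IntegrityError("alignment outside the genome")
    calls: list[tuple[str, int, bool]] = []
    cph = CpHStats()
    ref_pos = alignment.start
    read_pos = 0
    phase = alignment.phase
    for length, op in parse_cigar(alignment.cigar):
        if op == "I":
            read_pos += length
            continue
        if op == "D":
            ref_pos += length
            continue
        ref_block = seq[ref_pos : ref_pos + length]
        read_block = read[read_pos : read_pos + length]
        if phase == "CT":
            for k, (r, q) in enumerate(zip(ref_block, read_block)):
                if r != "C":
                    continue
                p = ref_pos + k
                nxt = seq[p + 1] if p + 1 < len(seq) else "N"
                if nxt == "G":
                    if q == "C":
                        calls.append((chrom, p, True))
                    elif q == "T":
                        calls.append((chrom, p, False))
                elif nxt != "N":
                    if q == "C":
                        cph.n_unconverted += 1
                        cph.n_total += 1
                    elif q == "T":
                        cph.n_total += 1
        else:  # GA phase: reverse-strand evidence projected onto the C
            for k, (r, q) in enumerate(zip(ref_block, read_block)):
                if r != "G":
                    continue
                p = ref_pos + k
                prv = seq[p - 1] if p >= 1 else "N"
                if prv == "C":
                    if q == "G":
                        calls.append((chrom, p - 1, True))
                    elif q == "A":
                        calls.append((chrom, p - 1, False))
                elif prv != "N":
                    if q == "G":
                        cph.n_unconverted += 1
                        cph.n_total += 1
                    elif q == "A":
                        cph.n_total += 1
        ref_pos += length
        read_pos += length
    return calls, cph


def aggregate_calls(
    all_calls: list[tuple[str, int, bool]]
) -> pd.DataFrame:
    """Per-site counts from pooled read calls.

    Returns the CpG site table: columns chrom, pos, n_meth, n_total,
    level; one row per covered site, sorted; sites never covered are
    absent.
    """
    if not all_calls:
        return pd.DataFrame(
            columns=["chrom", "pos", "n_meth", "n_total", "level"]
        ).astype({"pos": int, "n_meth": int, "n_total": int, "level": float})
    df = pd.DataFrame(all_calls, columns=["chrom", "pos", "meth"])
    grouped = df.groupby(["chrom", "pos"], sort=True)["meth"].agg(["sum", "count"])
    out = grouped.reset_index().rename(columns={"sum": "n_meth", "count": "n_total"})
    out["n_meth"] = out["n_meth"].astype(int)
    out["level"] = out["n_meth"] / out["n_total"]
    return out[["chrom", "pos", "n_meth", "n_total", "level"]]


def call_sample(
    alignments: list[AlignmentResult],
    reads: dict[str, str],
    genome: ReferenceGenome,
) -> tuple[pd.DataFrame, CpHStats]:
    """Run calling over all unique alignments of a sample."""
    pooled: list[tuple[str, int, bool]] = []
    cph = CpHStats()
    for aln in alignments:
        if not aln.unique:
            raise IntegrityError(
                f"non-unique alignment {aln.read_id} passed to methylation calling"
            )
        calls, stats = call_read_methylation(aln, reads[aln.read_id], genome)
        pooled.extend(calls)
        cph = cph + stats
    return aggregate_calls(pooled), cph


def conversion_rate(stats: CpHStats) -> tuple[float, float]:
    """(converted fraction, unconverted fraction); NaNs when undefined."""
    return stats.converted_fraction, stats.unconverted_fraction


def write_site_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_site_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cph_stats(stats: CpHStats, path) -> None:
    with open(path, "w") as fh:
        fh.write("n_unconverted\tn_total\tconverted_fraction\tunconverted_fraction\n")
        fh.write(
            f"{stats.n_unconverted}\t{stats.n_total}\t"
            f"{stats.converted_fraction:.6f}\t{stats.unconverted_fraction:.6f}\n"
        )


def write_tracks(table: pd.DataFrame, level_path, coverage_path) -> None:
    """bedGraph tracks: per-CpG methylation level and read coverage."""
    ordered = table.sort_values(["chrom", "pos"])
    with open(level_path, "w") as lv, open(coverage_path, "w") as cv:
        for row in ordered.itertuples(index=False):
            lv.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.level:g}\n")
            cv.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.n_total}\n")


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "value"], header=None
    )
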