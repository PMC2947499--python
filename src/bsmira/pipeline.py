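"""End-to-end orchestration: simulate → trim → map → call → mri → permute → annotate.

One config object drives all stages; every output is written under an
output directory and listed, with its SHA-256 checksum, in a manifest so
identical config+seed reruns are verifiable byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

from . import annotate as annotate_mod
from . import bsalign, methcall, mricall, permtest, simseq
from .refdata import write_bed, write_fasta, write_gene_table

log = logging.getLogger("bsmira")


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str = "bsmira_out"
    seed: int = 0
    n_permutations: int = 200
    simulation: simseq.SimulationConfig = dataclasses.field(
        default_factory=simseq.SimulationConfig
    )
    mapper: bsalign.MapperParams = dataclasses.field(
        default_factory=bsalign.MapperParams
    )
    mri: mricall.MRIParams = dataclasses.field(default_factory=mricall.MRIParams)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        sim = simseq.SimulationConfig(**data.get("simulation", {}))
        mapper = bsalign.MapperParams(**data.get("mapper", {}))
        mri = mricall.MRIParams(**data.get("mri", {}))
        top = {
            k: v
            for k, v in data.items()
            if k in ("out_dir", "seed", "n_permutations")
        }
        return cls(simulation=sim, mapper=mapper, mri=mri, **top)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns the output manifest.

    The simulation seed is taken from the pipeline seed so one integer
    reproduces the whole run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)

    log.info("simulating library (%d reads)", sim_cfg.n_reads)
    lib = simseq.simulate(sim_cfg)
    write_fasta(lib.genome, out / "genome.fasta")
    write_bed(lib.annotation.cgis, out / "cgis.bed")
    write_bed([iv for iv, _ in lib.annotation.repeats], out / "repeats.bed")
    write_gene_table(lib.annotation.genes, out / "genes.tsv")
    simseq.write_fastq(lib.reads, out / "reads.fastq")
    simseq.write_truth(
        lib.truth, out / "truth_cpg_levels.tsv", out / "truth_reads.tsv"
    )

    log.info("trimming adapters")
    trimmed = []
    for read_id, seq in lib.reads:
        t = bsalign.trim_adapters(seq)
        if t is not None:
            trimmed.append((read_id, t))
    log.info("reads surviving trimming: %d / %d", len(trimmed), len(lib.reads))

    log.info("mapping")
    mapper = bsalign.Mapper(lib.genome, config.mapper)
    alignments, counts = mapper.map_reads(trimmed)
    log.info("mapping counts: %s", counts)
    bsalign.write_alignments(alignments, out / "alignments.tsv")

    log.info("calling methylation")
    reads_by_id = dict(trimmed)
    site_table, cph = methcall.call_sample(alignments, reads_by_id, lib.genome)
    methcall.write_site_table(site_table, out / "cpg_sites.tsv")
    methcall.write_cph_stats(cph, out / "cph_stats.tsv")
    methcall.write_tracks(
        site_table, out / "methylation.bedGraph", out / "coverage.bedGraph"
    )

    log.info("building clusters and MRIs")
    clusters = mricall.build_clusters(alignments)
    mricall.attach_cpg_sites(clusters, site_table)
    mris = mricall.call_mris(clusters, config.mri)
    mricall.assert_mri_thresholds(mris, config.mri)
    mricall.write_clusters_bed(clusters, out / "clusters.bed")
    mricall.write_mris_bed(mris, out / "mris.bed")
    summary_table, pearson = mricall.chromosome_summary(mris, lib.genome)
    summary_table.to_csv(out / "chromosome_summary.tsv", sep="\t", index=False)

    log.info("permutation test (%d permutations)", config.n_permutations)
    perm = permtest.permutation_run(
        clusters, site_table, config.n_permutations, config.seed, config.mri
    )
    permtest.write_permutations(perm, out / "permutations.tsv")
    permtest.write_summary(
        permtest.summarize_permutations(perm), out / "perm_summary.tsv"
    )

    log.info("annotating MRIs")
    annotations = annotate_mod.classify_mris(mris, lib.annotation.genes)
    cgi_flags, cgi_summary = annotate_mod.overlap_cgi(mris, lib.annotation.cgis)
    rep_classes, rep_breakdown, rep_summary = annotate_mod.overlap_repeats(
        mris, lib.annotation.repeats
    )
    for ann, flag, classes in zip(annotations, cgi_flags, rep_classes):
        ann.cgi_overlap = flag
        ann.repeat_classes = classes
    annotate_mod.write_annotations(annotations, out / "mri_annotations.tsv")
    annotate_mod.category_summary(annotations).to_csv(
        out / "category_summary.tsv", sep="\t", index=False
    )
    rep_breakdown.to_csv(out / "repeat_breakdown.tsv", sep="\t", index=False)

    stats = {
        "n_reads": len(lib.reads),
        "n_trimmed": len(trimmed),
        "mapping": counts,
        "n_cpg_covered": int(len(site_table)),
        "n_mcpg": int((site_table["n_meth"] > 0).sum()) if len(site_table) else 0,
        "conversion_rate": cph.converted_fraction,
        "n_clusters": len(clusters),
        "n_mris": len(mris),
        "mri_chrom_pearson_r": pearson,
        "cgi_overlap": cgi_summary,
        "repeat_overlap": rep_summary,
    }
    with open(out / "run_stats.json", "w") as fh:
        json.dump(stats, fh, indent=2)

    manifest = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
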