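"""End-to-end driver chaining simulate -> filter -> segments -> merge ->
hotspots -> fst-scan -> enrich -> te-tag -> saturation.

Stages communicate through files under one output directory; the run
manifest records every stage's parameters and the SHA-256 of every output,
so two runs with the same config and seed are byte-identical. The single
global seed is fanned out to per-stage child seeds by stable hashing of the
stage name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import sys
import time
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as pio
from .depth_pav import (
    call_depth_segments,
    ecotype_specific_genes,
    gene_pav_matrix,
    SegmentCall,
)
from .enrichment import association_tests, ecotype_representation, saturation_curve
from .hotspots import call_hotspots, subgenome_asymmetry_test, window_event_counts
from .merge import (
    export_binary_matrix,
    genes_with_sv_in_cds_utr,
    locus_frequencies,
    merge_cohort,
)
from .selection import annotate_regions, candidate_regions, windowed_fst, zscore_windows
from .sv_filter import (
    FilterThresholds,
    apply_homozygous_precise_filter,
    apply_quality_filter,
    consensus_two_callers,
    min_support,
    remove_svs_in_deleted_segments,
)
from .synthetic import CohortConfig, simulate_cohort, simulate_reference, write_cohort
from .te import TELibraryIndex, annotate_sv_te, te_family_summary

STAGES = (
    "simulate",
    "filter",
    "segments",
    "merge",
    "hotspots",
    "fst_scan",
    "enrich",
    "te_tag",
    "saturation",
)


@dataclass
class RunConfig:
    """Pipeline parameters; the defaults are the workflow's published ones."""

    outdir: str
    seed: int = 0
    stages: Tuple[str, ...] = STAGES
    cohort: Optional[CohortConfig] = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    merge_max_dist: int = 1000
    merge_min_seq_id: float = 0.9
    segment_min_len: int = 10_000
    segment_max_cov: float = 150.0
    bin_size: int = 1000
    hotspot_window: int = 200_000
    hotspot_top_frac: float = 0.30
    fst_window: int = 50_000
    z_crit: float = 1.645
    ecotype_hi: float = 0.70
    ecotype_lo: float = 0.30
    te_min_identity: float = 0.99
    te_min_match: int = 30
    te_flank: int = 100
    saturation_iterations: int = 1000
    comparisons: Tuple[Tuple[str, str], ...] = (("swede_vs_nonswede", "SWEDE"),)


def stage_seed(seed: int, name: str) -> int:
    return (seed * 1_000_003 + zlib.crc32(name.encode())) & 0x7FFFFFFF


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(cfg: RunConfig, rel: str, stage: str, needed_by: str) -> str:
    path = os.path.join(cfg.outdir, rel)
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"stage '{needed_by}' requires '{rel}' — run the '{stage}' stage first"
        )
    return path


def _panel(cfg: RunConfig):
    return pio.read_panel(
        _require(cfg, "cohort/panel.tsv", "simulate", "pipeline"),
        os.path.join(cfg.outdir, "cohort/chromosomes.tsv"),
    )


def _accessions(cfg: RunConfig) -> List[str]:
    return list(_panel(cfg).ecotype_of)


def _stage_simulate(cfg: RunConfig) -> List[str]:
    seed = stage_seed(cfg.seed, "simulate")
    cc = cfg.cohort if cfg.cohort is not None else CohortConfig(seed=seed)
    ref = simulate_reference(cc, seed)
    cohort = simulate_cohort(ref, cc, seed)
    write_cohort(cohort, os.path.join(cfg.outdir, "cohort"), force=True)
    outputs = []
    for root, _, files in os.walk(os.path.join(cfg.outdir, "cohort")):
        for f in sorted(files):
            outputs.append(os.path.relpath(os.path.join(root, f), cfg.outdir))
    return sorted(outputs)


def _filtered_one(cfg: RunConfig, acc: str) -> List:
    base = os.path.join(cfg.outdir, "cohort")
    track = pio.read_coverage_bedgraph(
        os.path.join(base, f"coverage/{acc}.bedgraph"), cfg.bin_size, acc
    )
    support = min_support(track.mean_depth(), cfg.thresholds.support_fraction)
    out = []
    for caller in ("A", "B"):
        recs = pio.read_sv_vcf(os.path.join(base, f"vcf/{acc}.caller{caller}.vcf"))
        recs = apply_homozygous_precise_filter(recs, cfg.thresholds)
        recs = [r for r in recs if r.dv >= support]
        out.append(recs)
    cons = consensus_two_callers(out[0], out[1], cfg.merge_max_dist)
    return apply_quality_filter(cons, cfg.thresholds)


def _stage_filter(cfg: RunConfig) -> List[str]:
    _require(cfg, "cohort/manifest.json", "simulate", "filter")
    panel = _panel(cfg)
    os.makedirs(os.path.join(cfg.outdir, "filtered"), exist_ok=True)
    outputs = []
    for acc in panel.ecotype_of:
        recs = _filtered_one(cfg, acc)
        rel = f"filtered/{acc}.vcf"
        pio.write_sv_vcf(
            recs, os.path.join(cfg.outdir, rel), acc, panel.chrom_lengths
        )
        outputs.append(rel)
    return outputs


def _stage_segments(cfg: RunConfig) -> List[str]:
    panel = _panel(cfg)
    os.makedirs(os.path.join(cfg.outdir, "segments"), exist_ok=True)
    os.makedirs(os.path.join(cfg.outdir, "filtered_nodel"), exist_ok=True)
    outputs = []
    seg_rows = []
    segments_by_acc: Dict[str, List[SegmentCall]] = {}
    for acc in panel.ecotype_of:
        track = pio.read_coverage_bedgraph(
            os.path.join(cfg.outdir, f"cohort/coverage/{acc}.bedgraph"),
            cfg.bin_size,
            acc,
        )
        segs = call_depth_segments(track, cfg.segment_min_len, cfg.segment_max_cov)
        segments_by_acc[acc] = segs
        rel = f"segments/{acc}.bed"
        with open(os.path.join(cfg.outdir, rel), "w") as fh:
            for s in segs:
                fh.write(
                    f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}\t"
                    f"{s.segment_class}\t{s.mean_depth:.4f}\t{s.deviation_sd:.4f}\n"
                )
        outputs.append(rel)
        for s in segs:
            seg_rows.append(
                {
                    "accession_id": acc,
                    "chrom": s.interval.chrom,
                    "start": s.interval.start,
                    "end": s.interval.end,
                    "segment_class": s.segment_class,
                    "mean_depth": round(s.mean_depth, 4),
                    "deviation_sd": round(s.deviation_sd, 4),
                }
            )
        # remove SVs in this accession's deleted segments
        vcf_in = _require(cfg, f"filtered/{acc}.vcf", "filter", "segments")
        recs = remove_svs_in_deleted_segments(pio.read_sv_vcf(vcf_in), segs)
        rel2 = f"filtered_nodel/{acc}.vcf"
        pio.write_sv_vcf(recs, os.path.join(cfg.outdir, rel2), acc, panel.chrom_lengths)
        outputs.append(rel2)
    pd.DataFrame(
        seg_rows,
        columns=[
            "accession_id",
            "chrom",
            "start",
            "end",
            "segment_class",
            "mean_depth",
            "deviation_sd",
        ],
    ).to_csv(os.path.join(cfg.outdir, "segments/segments.tsv"), sep="\t", index=False)
    outputs.append("segments/segments.tsv")
    genes = pio.read_gene_models(os.path.join(cfg.outdir, "cohort/genes.gff3"))
    pav = gene_pav_matrix(segments_by_acc, genes)
    pav.to_csv(
        os.path.join(cfg.outdir, "segments/gene_pav.tsv"),
        sep="\t",
        index_label="gene_id",
    )
    outputs.append("segments/gene_pav.tsv")
    eco = ecotype_specific_genes(pav, panel, cfg.ecotype_hi, cfg.ecotype_lo)
    eco.to_csv(
        os.path.join(cfg.outdir, "segments/ecotype_genes.tsv"),
        sep="\t",
        index=False,
        float_format="%.4f",
    )
    outputs.append("segments/ecotype_genes.tsv")
    return outputs


def _stage_merge(cfg: RunConfig) -> List[str]:
    panel = _panel(cfg)
    callsets = {}
    for acc in panel.ecotype_of:
        vcf = _require(cfg, f"filtered_nodel/{acc}.vcf", "segments", "merge")
        recs = pio.read_sv_vcf(vcf)
        for r in recs:
            r.accession_id = acc
        callsets[acc] = recs
    loci = merge_cohort(
        callsets,
        max_dist=cfg.merge_max_dist,
        min_seq_id=cfg.merge_min_seq_id,
        accessions=list(panel.ecotype_of),
    )
    os.makedirs(os.path.join(cfg.outdir, "merged"), exist_ok=True)
    pio.write_merged_vcf(
        loci,
        list(panel.ecotype_of),
        os.path.join(cfg.outdir, "merged/merged.vcf"),
        panel.chrom_lengths,
    )
    freqs = locus_frequencies(loci, panel)
    freqs.to_csv(
        os.path.join(cfg.outdir, "merged/frequencies.tsv"),
        sep="\t",
        index=False,
        float_format="%.4f",
    )
    genes = pio.read_gene_models(os.path.join(cfg.outdir, "cohort/genes.gff3"))
    hits = genes_with_sv_in_cds_utr(loci, genes)
    hits.to_csv(
        os.path.join(cfg.outdir, "merged/cds_utr_genes.tsv"), sep="\t", index=False
    )
    export_binary_matrix(
        loci, panel, "binary-alignment", os.path.join(cfg.outdir, "merged/binary.phy")
    )
    export_binary_matrix(
        loci, panel, "treemix-counts", os.path.join(cfg.outdir, "merged/treemix.txt")
    )
    return [
        "merged/merged.vcf",
        "merged/frequencies.tsv",
        "merged/cds_utr_genes.tsv",
        "merged/binary.phy",
        "merged/treemix.txt",
    ]


def _loci(cfg: RunConfig, needed_by: str):
    return pio.read_merged_vcf(
        _require(cfg, "merged/merged.vcf", "merge", needed_by)
    )


def _stage_hotspots(cfg: RunConfig) -> List[str]:
    panel = _panel(cfg)
    loci = _loci(cfg, "hotspots")
    windows = window_event_counts(loci, panel, cfg.hotspot_window)
    os.makedirs(os.path.join(cfg.outdir, "hotspots"), exist_ok=True)
    with open(os.path.join(cfg.outdir, "hotspots/window_counts.tsv"), "w") as fh:
        fh.write("chrom\tstart\tend\tsubgenome\tcount\n")
        for w in windows:
            fh.write(
                f"{w.interval.chrom}\t{w.interval.start}\t{w.interval.end}\t"
                f"{w.subgenome}\t{int(w.value)}\n"
            )
    flagged = call_hotspots(windows, cfg.hotspot_top_frac)
    with open(os.path.join(cfg.outdir, "hotspots/hotspots.bed"), "w") as fh:
        for w in flagged:
            fh.write(
                f"{w.interval.chrom}\t{w.interval.start}\t{w.interval.end}\t"
                f"hotspot_{w.subgenome}\t{int(w.value)}\n"
            )
    res = subgenome_asymmetry_test(windows)
    with open(os.path.join(cfg.outdir, "hotspots/asymmetry.tsv"), "w") as fh:
        fh.write("t\tp_one_tailed\tmean_a\tsd_a\tmean_c\tsd_c\tn_a\tn_c\n")
        fh.write(
            f"{res.t:.6g}\t{res.p_one_tailed:.6g}\t{res.mean_a:.6g}\t{res.sd_a:.6g}\t"
            f"{res.mean_c:.6g}\t{res.sd_c:.6g}\t{res.n_a}\t{res.n_c}\n"
        )
    return [
        "hotspots/window_counts.tsv",
        "hotspots/hotspots.bed",
        "hotspots/asymmetry.tsv",
    ]


def _stage_fst_scan(cfg: RunConfig) -> List[str]:
    panel = _panel(cfg)
    loci = _loci(cfg, "fst_scan")
    genes = pio.read_gene_models(os.path.join(cfg.outdir, "cohort/genes.gff3"))
    os.makedirs(os.path.join(cfg.outdir, "fst"), exist_ok=True)
    outputs = []
    for label, target in cfg.comparisons:
        pop1 = panel.group(target)
        pop2 = [a for a in panel.ecotype_of if panel.ecotype_of[a] != target]
        windows = windowed_fst(loci, (pop1, pop2), cfg.fst_window)
        windows = zscore_windows(windows)
        windows["flagged"] = windows["z"] >= cfg.z_crit
        rel = f"fst/{label}_windows.tsv"
        windows.to_csv(
            os.path.join(cfg.outdir, rel), sep="\t", index=False, float_format="%.6g"
        )
        outputs.append(rel)
        regions = annotate_regions(
            candidate_regions(windows, cfg.z_crit, label=label), genes
        )
        rel2 = f"fst/{label}_regions.bed"
        with open(os.path.join(cfg.outdir, rel2), "w") as fh:
            for r in regions:
                fh.write(
                    f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t"
                    f"{label}\t{r.peak_z:.4f}\t{','.join(r.genes)}\n"
                )
        outputs.append(rel2)
    return outputs


def _stage_enrich(cfg: RunConfig) -> List[str]:
    panel = _panel(cfg)
    loci = _loci(cfg, "enrich")
    os.makedirs(os.path.join(cfg.outdir, "enrich"), exist_ok=True)
    rep = ecotype_representation(loci, panel, cfg.ecotype_hi, cfg.ecotype_lo)
    rep.to_csv(
        os.path.join(cfg.outdir, "enrich/representation.tsv"),
        sep="\t",
        index=False,
        float_format="%.4f",
    )
    assoc = association_tests(loci, panel)
    assoc.to_csv(
        os.path.join(cfg.outdir, "enrich/associations.tsv"),
        sep="\t",
        index=False,
        float_format="%.6g",
    )
    return ["enrich/representation.tsv", "enrich/associations.tsv"]


def _stage_te_tag(cfg: RunConfig) -> List[str]:
    # the TE procedure applies to insertions and inversions
    loci = [l for l in _loci(cfg, "te_tag") if l.sv_type in ("INS", "INV")]
    te_lib = pio.read_fasta(os.path.join(cfg.outdir, "cohort/te_library.fa"))
    reference = dict(pio.read_fasta(os.path.join(cfg.outdir, "cohort/reference.fa")))
    index = TELibraryIndex(te_lib)
    anns = annotate_sv_te(
        loci,
        reference,
        index,
        flank=cfg.te_flank,
        min_identity=cfg.te_min_identity,
        min_match=cfg.te_min_match,
    )
    os.makedirs(os.path.join(cfg.outdir, "te"), exist_ok=True)
    with open(os.path.join(cfg.outdir, "te/annotations.tsv"), "w") as fh:
        fh.write("locus_id\tzone\tte_family\tidentity\tmatch_length\tstrand\n")
        for a in anns:
            fh.write(
                f"{a.locus_id}\t{a.zone}\t{a.te_family}\t{a.identity:.4f}\t"
                f"{a.match_length}\t{a.strand}\n"
            )
    summary = te_family_summary(anns)
    summary.to_csv(
        os.path.join(cfg.outdir, "te/family_summary.tsv"),
        sep="\t",
        index=False,
        float_format="%.6g",
    )
    return ["te/annotations.tsv", "te/family_summary.tsv"]


def _stage_saturation(cfg: RunConfig) -> List[str]:
    pav_path = _require(cfg, "segments/gene_pav.tsv", "segments", "saturation")
    pav = pd.read_csv(pav_path, sep="\t", index_col="gene_id")
    presence = pav != "DELETED"
    curve = saturation_curve(
        presence,
        iterations=cfg.saturation_iterations,
        seed=stage_seed(cfg.seed, "saturation"),
    )
    os.makedirs(os.path.join(cfg.outdir, "saturation"), exist_ok=True)
    with open(os.path.join(cfg.outdir, "saturation/curve.tsv"), "w") as fh:
        fh.write("k\tmean_genes\tsd_genes\n")
        for k, m, s in zip(curve.k, curve.mean_genes, curve.sd_genes):
            fh.write(f"{k}\t{m:.4f}\t{s:.4f}\n")
    return ["saturation/curve.tsv"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "segments": _stage_segments,
    "merge": _stage_merge,
    "hotspots": _stage_hotspots,
    "fst_scan": _stage_fst_scan,
    "enrich": _stage_enrich,
    "te_tag": _stage_te_tag,
    "saturation": _stage_saturation,
}


def run_pipeline(config: RunConfig, log=sys.stderr) -> Dict:
    """Run the enabled stages in dependency order and write the manifest."""
    os.makedirs(config.outdir, exist_ok=True)
    manifest: Dict = {"seed": config.seed, "stages": []}
    for name in STAGES:
        if name not in config.stages:
            continue
        t0 = time.time()
        outputs = _STAGE_FN[name](config)
        elapsed = time.time() - t0
        if log is not None:
            print(f"[pansv-atlas] stage {name}: {elapsed:.1f}s", file=log)
        manifest["stages"].append(
            {
                "name": name,
                "seed": stage_seed(config.seed, name),
                "elapsed_s": round(elapsed, 2),
                "outputs": {rel: _sha256(os.path.join(config.outdir, rel)) for rel in outputs},
            }
        )
    params = dataclasses.asdict(config)
    params.pop("outdir", None)
    manifest["params"] = json.loads(json.dumps(params, default=str))
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
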