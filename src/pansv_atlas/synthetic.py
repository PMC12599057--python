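"""Synthetic cohorts with planted truth.

The generator emulates the statistical structure the analyses assume: a
two-subgenome chromosome plan, ecotype groups in the proportions of a
94-accession rapeseed panel scaled down, shared/ecotype-specific/private SV
loci placed on a spaced grid, SV hotspot windows with excess locus density,
an A-subgenome density bias, TE-derived insertion alleles, >=10-kbp coverage
deletion/duplication segments mirrored between coverage tracks and spurious
in-segment calls, and two pseudo-callers with independent breakpoint jitter
and false positives. Every planted feature is recorded in a machine-readable
truth table. All randomness flows from one seed through named child streams
(slots, loci, segments, per-accession coverage, per-accession call sets, in
that order), so outputs are byte-identical across reruns.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import (
    ChromBins,
    CoverageTrack,
    EcotypePanel,
    GeneModel,
    GenomicInterval,
    SVRecord,
)
from .merge import PangenomeLocus
from . import io as pio

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_TE_CLASSES = [
    "LTR/Copia",
    "LTR/Gypsy",
    "DNA/MuDR",
    "DNA/CACTA",
    "LINE/L1",
    "SINE/tRNA",
    "RC/Helitron",
    "DNA/hAT",
    "LTR/unknown",
    "DNA/Harbinger",
    "LINE/unknown",
    "MITE/Tourist",
]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def _mutate(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    protect: Optional[Tuple[int, int]],
    cap_frac: float = 0.025,
) -> str:
    """Substitute bases at `rate`, never inside the protected span.

    The substitution count is capped at ``cap_frac`` of the length so that any
    two copies of one allele stay within 2 x cap_frac pairwise divergence.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    if protect is not None:
        hit[protect[0] : protect[1]] = False
    cap = int(cap_frac * len(arr))
    for i in np.flatnonzero(hit)[:cap]:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


@dataclass
class CohortConfig:
    """Generator parameters; defaults are the package's standard study cohort.

    The default cohort is 22 accessions in four ecotype groups (the
    94-accession panel's 22/23/22/17 proportions scaled by ~1/4) on two
    10-Mbp chromosomes, one per subgenome, with ~7200 planted loci giving
    roughly 4-5 thousand calls per accession.
    """

    ecotype_sizes: Dict[str, int] = field(
        default_factory=lambda: {"WOSR": 6, "SOSR": 6, "EA_OSR": 6, "SWEDE": 4}
    )
    chromosomes: Tuple[Tuple[str, int, str], ...] = (
        ("A01", 10_000_000, "A"),
        ("C01", 10_000_000, "C"),
    )
    # planted locus counts
    n_shared: int = 4800
    n_ecotype_specific: int = 1200
    n_private: int = 1200
    n_differentiated: int = 0
    shared_freq_range: Tuple[float, float] = (0.7, 1.0)
    ecotype_hi: float = 0.8
    ecotype_lo: float = 0.05
    diff_freqs: Tuple[float, float] = (0.9, 0.1)
    diff_target: str = "SWEDE"
    # spatial structure
    min_locus_spacing: int = 2200
    edge_margin: int = 50_000
    n_hotspot_windows: int = 6
    hotspot_window: int = 200_000
    hotspot_excess: float = 4.0
    subgenome_weight: Dict[str, float] = field(
        default_factory=lambda: {"A": 1.3, "C": 1.0}
    )
    # SV properties
    sv_type_weights: Dict[str, float] = field(
        default_factory=lambda: {"INS": 0.55, "DEL": 0.40, "INV": 0.04, "TRA": 0.01}
    )
    ins_len_range: Tuple[int, int] = (30, 3000)
    del_len_range: Tuple[int, int] = (30, 5000)
    inv_len_range: Tuple[int, int] = (100, 10_000)
    allele_divergence: float = 0.01
    jitter: int = 50
    te_fraction: float = 0.3
    # coverage segments
    n_deletion_segments: int = 8
    n_duplication_segments: int = 4
    segment_len_range: Tuple[int, int] = (12_000, 30_000)
    del_depth_factor: float = 0.1
    dup_depth_factor: float = 2.5
    segment_ecotype_fraction: float = 0.5
    spurious_per_segment: int = 3
    depth_mean: float = 40.0
    depth_sd: float = 8.0
    bin_size: int = 1000
    n_outlier_bins: int = 20
    outlier_depth: float = 500.0
    # caller behaviour
    n_false_positives: int = 150
    degraded_fraction: float = 0.06
    # reference
    n_genes: int = 2000
    gene_len_range: Tuple[int, int] = (2000, 6000)
    n_te_families: int = 12
    te_len_range: Tuple[int, int] = (200, 5000)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_shared,
            self.n_ecotype_specific,
            self.n_private,
            self.n_differentiated,
            self.n_deletion_segments,
            self.n_duplication_segments,
            self.n_false_positives,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        for f in (
            *self.shared_freq_range,
            self.ecotype_hi,
            self.ecotype_lo,
            *self.diff_freqs,
            self.te_fraction,
            self.degraded_fraction,
        ):
            if not 0.0 <= f <= 1.0:
                raise ValueError("frequencies must lie in [0, 1]")
        if self.segment_len_range[0] < 10_000:
            raise ValueError("planted segments must be >= 10 kbp")

    @property
    def n_loci(self) -> int:
        return (
            self.n_shared
            + self.n_ecotype_specific
            + self.n_private
            + self.n_differentiated
        )


@dataclass
class Reference:
    chromosomes: Tuple[Tuple[str, int, str], ...]
    sequences: Dict[str, str]
    genes: List[GeneModel]
    te_library: List[Tuple[str, str]]


@dataclass
class Cohort:
    reference: Reference
    config: CohortConfig
    panel: EcotypePanel
    accessions: List[str]
    callsets: Dict[str, Dict[str, List[SVRecord]]]  # acc -> caller -> records
    coverage: Dict[str, CoverageTrack]
    truth: Dict
    seed: int


def _child(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def simulate_reference(config: CohortConfig, seed: int) -> Reference:
    """Reference sequences, tiled gene models with CDS/UTRs, and a TE library."""
    rng = _child(seed, 0)
    sequences = {
        name: _random_seq(rng, length) for name, length, _ in config.chromosomes
    }
    total_len = sum(l for _, l, _ in config.chromosomes)
    genes: List[GeneModel] = []
    max_gene = config.gene_len_range[1]
    for name, length, _ in config.chromosomes:
        n_chrom = max(1, round(config.n_genes * length / total_len))
        spacing = length // (n_chrom + 1)
        if spacing < max_gene + 200:
            raise ValueError(
                f"gene density infeasible on {name}: spacing {spacing} < "
                f"max gene length {max_gene} + 200"
            )
        for i in range(n_chrom):
            start = (i + 1) * spacing
            glen = int(rng.integers(config.gene_len_range[0], max_gene + 1))
            s = start
            gene_iv = GenomicInterval(name, s, s + glen)
            d = glen // 10
            utr = [
                GenomicInterval(name, s, s + d),
                GenomicInterval(name, s + 9 * d, s + glen),
            ]
            cds = [
                GenomicInterval(name, s + d, s + 4 * d),
                GenomicInterval(name, s + 5 * d, s + 8 * d),
            ]
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"{name}g{i + 1:05d}", gene_iv, strand, cds, utr))
    te_library = []
    for i in range(config.n_te_families):
        cls = _TE_CLASSES[i % len(_TE_CLASSES)]
        length = int(rng.integers(config.te_len_range[0], config.te_len_range[1] + 1))
        te_library.append((f"TEfam{i + 1:02d}#{cls}", _random_seq(rng, length)))
    return Reference(config.chromosomes, sequences, genes, te_library)


def _make_panel(config: CohortConfig) -> Tuple[EcotypePanel, List[str]]:
    ecotype_of: Dict[str, str] = {}
    for eco, n in config.ecotype_sizes.items():
        for i in range(n):
            ecotype_of[f"{eco}{i + 1:02d}"] = eco
    panel = EcotypePanel(
        ecotype_of=ecotype_of,
        subgenome_of={name: sg for name, _, sg in config.chromosomes},
        chrom_lengths={name: length for name, length, _ in config.chromosomes},
    )
    return panel, list(ecotype_of)


def _locus_slots(
    config: CohortConfig, rng: np.random.Generator
) -> Tuple[List[Tuple[str, int]], List[Dict]]:
    """Spaced candidate positions plus planted hotspot windows with weights."""
    slots: List[Tuple[str, int]] = []
    weights: List[float] = []
    # choose hotspot windows genome-wide
    all_windows = []
    for name, length, _ in config.chromosomes:
        for wstart in range(0, length, config.hotspot_window):
            all_windows.append((name, wstart))
    n_hot = min(config.n_hotspot_windows, len(all_windows))
    hot_idx = sorted(rng.choice(len(all_windows), size=n_hot, replace=False))
    hotspots = [
        {
            "chrom": all_windows[i][0],
            "start": all_windows[i][1],
            "end": all_windows[i][1] + config.hotspot_window,
            "excess": config.hotspot_excess,
        }
        for i in hot_idx
    ]
    hot_set = {(h["chrom"], h["start"]) for h in hotspots}
    sg_of = {name: sg for name, _, sg in config.chromosomes}
    for name, length, _ in config.chromosomes:
        pos = config.edge_margin
        while pos < length - config.edge_margin:
            w = config.subgenome_weight.get(sg_of[name], 1.0)
            wstart = (pos // config.hotspot_window) * config.hotspot_window
            if (name, wstart) in hot_set:
                w *= config.hotspot_excess
            slots.append((name, pos))
            weights.append(w)
            pos += config.min_locus_spacing
    if config.n_loci > len(slots):
        raise ValueError(
            f"cannot place {config.n_loci} loci on {len(slots)} spaced slots; "
            "reduce counts or enlarge chromosomes"
        )
    p = np.asarray(weights) / np.sum(weights)
    chosen = rng.choice(len(slots), size=config.n_loci, replace=False, p=p)
    chosen = np.sort(chosen)
    return [slots[i] for i in chosen], hotspots


def _draw_type_and_length(
    config: CohortConfig, rng: np.random.Generator
) -> Tuple[str, int]:
    types = list(config.sv_type_weights)
    w = np.array([config.sv_type_weights[t] for t in types], dtype=float)
    sv_type = types[rng.choice(len(types), p=w / w.sum())]
    if sv_type == "TRA":
        return sv_type, 1
    lo, hi = {
        "INS": config.ins_len_range,
        "DEL": config.del_len_range,
        "INV": config.inv_len_range,
    }[sv_type]
    length = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
    return sv_type, min(max(length, lo), hi)


def simulate_cohort(reference: Reference, config: CohortConfig, seed: int) -> Cohort:
    """Per-accession dual-caller call sets, coverage tracks, panel, and truth."""
    panel, accessions = _make_panel(config)
    acc_index = {a: i for i, a in enumerate(accessions)}
    n_acc = len(accessions)
    eco_members = {eco: panel.group(eco) for eco in panel.ecotypes}

    rng_slots = _child(seed, 1)
    rng_loci = _child(seed, 2)
    rng_seg = _child(seed, 3)

    slots, hotspots = _locus_slots(config, rng_slots)

    # kinds randomly interleaved over the chosen slots
    kinds = (
        ["shared"] * config.n_shared
        + ["ecotype"] * config.n_ecotype_specific
        + ["private"] * config.n_private
        + ["differentiated"] * config.n_differentiated
    )
    rng_loci.shuffle(kinds)

    te_lib = reference.te_library
    ecotypes = list(config.ecotype_sizes)
    diff_in = set(eco_members.get(config.diff_target, []))

    loci: List[Dict] = []
    for idx, ((chrom, pos), kind) in enumerate(zip(slots, kinds)):
        sv_type, length = _draw_type_and_length(config, rng_loci)
        presence = np.zeros(n_acc, dtype=bool)
        target_eco = None
        if kind == "shared":
            f = rng_loci.uniform(*config.shared_freq_range)
            presence = rng_loci.random(n_acc) < f
        elif kind == "ecotype":
            target_eco = ecotypes[int(rng_loci.integers(0, len(ecotypes)))]
            for a, i in acc_index.items():
                p = (
                    config.ecotype_hi
                    if panel.ecotype_of[a] == target_eco
                    else config.ecotype_lo
                )
                presence[i] = rng_loci.random() < p
        elif kind == "private":
            presence[int(rng_loci.integers(0, n_acc))] = True
        else:  # differentiated
            for a, i in acc_index.items():
                p = config.diff_freqs[0] if a in diff_in else config.diff_freqs[1]
                presence[i] = rng_loci.random() < p
        if not presence.any():
            presence[int(rng_loci.integers(0, n_acc))] = True
        allele = None
        te_family = None
        te_span = None
        if sv_type == "INS":
            allele = _random_seq(rng_loci, length)
            if length >= 150 and te_lib and rng_loci.random() < config.te_fraction:
                fam_i = int(rng_loci.integers(0, len(te_lib)))
                fam_name, fam_seq = te_lib[fam_i]
                sub_len = min(len(fam_seq), max(50, int(0.8 * length)))
                te_start = int(rng_loci.integers(0, len(fam_seq) - sub_len + 1))
                te_sub = fam_seq[te_start : te_start + sub_len]
                offset = int(rng_loci.integers(0, length - sub_len + 1))
                allele = allele[:offset] + te_sub + allele[offset + sub_len :]
                te_family = fam_name
                te_span = (offset, offset + sub_len)
        loci.append(
            {
                "locus_id": f"L{idx + 1:05d}",
                "chrom": chrom,
                "pos": int(pos),
                "sv_type": sv_type,
                "length": int(length),
                "kind": kind,
                "target_ecotype": target_eco,
                "carriers": [accessions[i] for i in np.flatnonzero(presence)],
                "te_family": te_family,
                "te_span": te_span,
                "allele": allele,
            }
        )

    # ------------------------------------------------------------- segments
    segments: List[Dict] = []
    chrom_lengths = {name: length for name, length, _ in config.chromosomes}
    chrom_names = list(chrom_lengths)
    chrom_w = np.array([chrom_lengths[c] for c in chrom_names], dtype=float)
    n_seg = config.n_deletion_segments + config.n_duplication_segments
    placed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_names}
    B = config.bin_size
    for si in range(n_seg):
        seg_class = "DELETION" if si < config.n_deletion_segments else "DUPLICATION"
        for attempt in range(1000):
            chrom = chrom_names[rng_seg.choice(len(chrom_names), p=chrom_w / chrom_w.sum())]
            seg_len = (
                int(rng_seg.integers(*config.segment_len_range)) // B * B
            )
            seg_len = max(seg_len, ((config.segment_len_range[0] + B - 1) // B) * B)
            max_start = chrom_lengths[chrom] - config.edge_margin - seg_len
            start = (
                int(rng_seg.integers(config.edge_margin, max_start)) // B * B
            )
            end = start + seg_len
            if all(
                end + B <= s or e + B <= start for s, e in placed[chrom]
            ):
                placed[chrom].append((start, end))
                break
        else:
            raise ValueError("segment placement exceeded retry budget")
        if rng_seg.random() < config.segment_ecotype_fraction:
            eco = ecotypes[int(rng_seg.integers(0, len(ecotypes)))]
            carriers = list(eco_members[eco])
        else:
            mask = rng_seg.random(n_acc) < 0.3
            if not mask.any():
                mask[int(rng_seg.integers(0, n_acc))] = True
            carriers = [accessions[i] for i in np.flatnonzero(mask)]
        factor = (
            config.del_depth_factor
            if seg_class == "DELETION"
            else config.dup_depth_factor
        )
        segments.append(
            {
                "segment_id": f"S{si + 1:03d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "segment_class": seg_class,
                "depth_factor": factor,
                "carriers": carriers,
            }
        )

    # spurious calls planted inside deletion segments (both callers see them)
    spurious: List[Dict] = []
    for seg in segments:
        if seg["segment_class"] != "DELETION":
            continue
        for k in range(config.spurious_per_segment):
            pos = int(rng_seg.integers(seg["start"] + 100, seg["end"] - 600))
            length = int(rng_seg.integers(30, 500))
            sv_type = "DEL" if rng_seg.random() < 0.5 else "INS"
            spurious.append(
                {
                    "locus_id": f"{seg['segment_id']}sp{k + 1}",
                    "chrom": seg["chrom"],
                    "pos": pos,
                    "sv_type": sv_type,
                    "length": length,
                    "kind": "spurious_in_segment",
                    "carriers": list(seg["carriers"]),
                    "allele": _random_seq(rng_seg, length) if sv_type == "INS" else None,
                    "te_family": None,
                    "te_span": None,
                    "target_ecotype": None,
                }
            )

    # ------------------------------------------------------------- coverage
    coverage: Dict[str, CoverageTrack] = {}
    seg_by_acc: Dict[str, List[Dict]] = {a: [] for a in accessions}
    for seg in segments:
        for a in seg["carriers"]:
            seg_by_acc[a].append(seg)
    for ai, acc in enumerate(accessions):
        rng_cov = _child(seed, 4, ai)
        track = CoverageTrack(accession_id=acc, bin_size=B)
        for chrom, length in chrom_lengths.items():
            nbins = -(-length // B)
            depths = rng_cov.normal(config.depth_mean, config.depth_sd, nbins)
            seg_mask = np.zeros(nbins, dtype=bool)
            for seg in seg_by_acc[acc]:
                if seg["chrom"] != chrom:
                    continue
                b0, b1 = seg["start"] // B, seg["end"] // B
                depths[b0:b1] = rng_cov.normal(
                    config.depth_mean * seg["depth_factor"], config.depth_sd, b1 - b0
                )
                seg_mask[b0:b1] = True
            n_out = config.n_outlier_bins
            if n_out > 0:
                free = np.flatnonzero(~seg_mask)
                pick = rng_cov.choice(len(free), size=min(n_out, len(free)), replace=False)
                depths[free[pick]] = config.outlier_depth
            depths = np.clip(depths, 0.0, None)
            widths = np.full(nbins, B, dtype=np.int64)
            widths[-1] = length - (nbins - 1) * B
            track.bins[chrom] = ChromBins(
                np.arange(nbins, dtype=np.int64) * B, depths, widths
            )
        coverage[acc] = track

    # ------------------------------------------------------------- call sets
    callsets: Dict[str, Dict[str, List[SVRecord]]] = {}
    fp_truth: Dict[str, Dict[str, List[Tuple[str, int, str]]]] = {}
    carried_by: Dict[str, List[Dict]] = {a: [] for a in accessions}
    for entry in loci + spurious:
        for a in entry["carriers"]:
            carried_by[a].append(entry)

    for ai, acc in enumerate(accessions):
        rng_call = _child(seed, 5, ai)
        per_caller: Dict[str, List[SVRecord]] = {"A": [], "B": []}
        for entry in carried_by[acc]:
            allele_acc = entry["allele"]
            if allele_acc is not None and config.allele_divergence > 0:
                allele_acc = _mutate(
                    rng_call, allele_acc, config.allele_divergence, entry["te_span"]
                )
            for caller in ("A", "B"):
                start = entry["pos"] + int(
                    rng_call.integers(-config.jitter, config.jitter + 1)
                )
                start = max(1, start)
                rec = _emit_record(
                    rng_call, config, entry, start, allele_acc, acc
                )
                per_caller[caller].append(rec)
        for caller in ("A", "B"):
            fps: List[Tuple[str, int, str]] = []
            for _ in range(config.n_false_positives):
                chrom = chrom_names[
                    rng_call.choice(len(chrom_names), p=chrom_w / chrom_w.sum())
                ]
                pos = int(
                    rng_call.integers(
                        config.edge_margin, chrom_lengths[chrom] - config.edge_margin
                    )
                )
                sv_type, length = _draw_type_and_length(config, rng_call)
                entry = {
                    "sv_type": sv_type,
                    "length": length,
                    "chrom": chrom,
                    "allele": _random_seq(rng_call, length)
                    if sv_type == "INS"
                    else None,
                }
                rec = _emit_record(rng_call, config, entry, pos, entry["allele"], acc)
                per_caller[caller].append(rec)
                fps.append((chrom, pos, sv_type))
            per_caller[caller].sort(key=lambda r: (r.chrom, r.start, r.sv_type))
            fp_truth.setdefault(acc, {})[caller] = fps
        callsets[acc] = per_caller

    truth = {
        "seed": seed,
        "accessions": accessions,
        "loci": [
            {k: v for k, v in entry.items() if k != "allele"} for entry in loci
        ],
        "spurious_in_segments": [
            {k: v for k, v in entry.items() if k != "allele"} for entry in spurious
        ],
        "hotspot_windows": hotspots,
        "segments": segments,
        "false_positives": fp_truth,
    }
    return Cohort(
        reference=reference,
        config=config,
        panel=panel,
        accessions=accessions,
        callsets=callsets,
        coverage=coverage,
        truth=truth,
        seed=seed,
    )


def _emit_record(
    rng: np.random.Generator,
    config: CohortConfig,
    entry: Mapping,
    start: int,
    allele: Optional[str],
    acc: str,
) -> SVRecord:
    sv_type = entry["sv_type"]
    length = entry["length"]
    chrom = entry["chrom"]
    if sv_type in ("DEL", "INV"):
        interval = GenomicInterval(chrom, start, start + length)
    else:
        interval = GenomicInterval(chrom, start, start + 1)
    qual = round(55.0 + 40.0 * rng.random(), 1)
    gq = int(rng.integers(55, 100))
    dv = max(1, int(rng.poisson(0.8 * config.depth_mean)))
    dr = int(rng.poisson(0.3))
    precise = True
    genotype = "hom_alt"
    filter_status = "PASS"
    if rng.random() < config.degraded_fraction:
        mode = int(rng.integers(0, 4))
        if mode == 0:
            qual = round(10.0 + 39.0 * rng.random(), 1)
            filter_status = "LowQual"
        elif mode == 1:
            genotype = "het"
            dr = max(dv - int(rng.integers(0, 3)), 1)
        elif mode == 2:
            precise = False
        else:
            dv = int(rng.integers(1, 12))
    af = dv / (dr + dv) if (dr + dv) > 0 else None
    return SVRecord(
        interval=interval,
        sv_type=sv_type,
        length=length,
        accession_id=acc,
        alt_sequence=allele if sv_type == "INS" else None,
        qual=qual,
        filter_status=filter_status,
        precise=precise,
        genotype=genotype,
        gq=gq,
        dr=dr,
        dv=dv,
        allele_frequency=round(af, 6) if af is not None else None,
    )


# ---------------------------------------------------------------------------
# direct presence-matrix simulation (selection-scan calibration and power)
# ---------------------------------------------------------------------------

def simulate_presence_loci(
    n_windows: int,
    loci_per_window: int,
    group_sizes: Tuple[int, int] = (20, 20),
    n_diff_windows: int = 0,
    diff_freqs: Tuple[float, float] = (0.9, 0.1),
    null_freq_range: Tuple[float, float] = (0.1, 0.9),
    window: int = 50_000,
    seed: int = 0,
) -> Tuple[List[PangenomeLocus], Tuple[List[str], List[str]], List[int]]:
    """Binary loci tiled into windows, with optional differentiated windows.

    Null loci draw one carrier frequency per locus from ``null_freq_range``
    and apply it to both populations; the first ``n_diff_windows`` windows
    instead use ``diff_freqs`` (population 1 vs 2). Returns the loci, the two
    population accession lists, and the planted window start positions.
    """
    rng = np.random.default_rng(seed)
    n1, n2 = group_sizes
    pop1 = [f"P1_{i:03d}" for i in range(n1)]
    pop2 = [f"P2_{i:03d}" for i in range(n2)]
    accessions = tuple(pop1 + pop2)
    n_loci = n_windows * loci_per_window
    wi = np.repeat(np.arange(n_windows), loci_per_window)
    offsets = rng.integers(0, window, n_loci)
    starts = wi * window + offsets
    is_diff = wi < n_diff_windows
    p_null = rng.uniform(*null_freq_range, n_loci)
    p1 = np.where(is_diff, diff_freqs[0], p_null)
    p2 = np.where(is_diff, diff_freqs[1], p_null)
    pres1 = rng.random((n_loci, n1)) < p1[:, None]
    pres2 = rng.random((n_loci, n2)) < p2[:, None]
    presence = np.hstack([pres1, pres2])
    loci: List[PangenomeLocus] = []
    for i in range(n_loci):
        rec = SVRecord(
            interval=GenomicInterval("A01", int(starts[i]), int(starts[i]) + 100),
            sv_type="DEL",
            length=100,
            accession_id=pop1[0],
        )
        freq = 100.0 * presence[i].sum() / (n1 + n2)
        loci.append(
            PangenomeLocus(
                locus_id=f"SIM{i + 1:06d}",
                representative=rec,
                sv_type="DEL",
                presence=presence[i].copy(),
                accessions=accessions,
                frequency_pct=freq,
            )
        )
    planted = [int(w) * window for w in range(n_diff_windows)]
    return loci, (pop1, pop2), planted


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_gff3(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tpansv\tgene\t{iv.start + 1}\t{iv.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{iv.chrom}\tpansv\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for c in g.cds:
                fh.write(
                    f"{c.chrom}\tpansv\tCDS\t{c.start + 1}\t{c.end}\t.\t{g.strand}\t0\t"
                    f"ID={mrna}.cds;Parent={mrna}\n"
                )
            for j, u in enumerate(g.utr):
                utype = "five_prime_UTR" if j == 0 else "three_prime_UTR"
                fh.write(
                    f"{u.chrom}\tpansv\t{utype}\t{u.start + 1}\t{u.end}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.utr{j};Parent={mrna}\n"
                )


def write_cohort(cohort: Cohort, outdir: str, force: bool = False) -> str:
    """Write the cohort's VCFs, bedgraphs, panel, reference, and truth JSON.

    Returns the manifest path. Refuses a non-empty output directory unless
    ``force`` is set.
    """
    outdir = str(outdir)
    if os.path.isdir(outdir) and os.listdir(outdir) and not force:
        raise FileExistsError(f"{outdir} is not empty (use force=True to overwrite)")
    os.makedirs(outdir, exist_ok=True)
    os.makedirs(os.path.join(outdir, "vcf"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "coverage"), exist_ok=True)
    chrom_lengths = cohort.panel.chrom_lengths
    paths: Dict[str, object] = {}
    pio.write_panel(
        cohort.panel,
        os.path.join(outdir, "panel.tsv"),
        os.path.join(outdir, "chromosomes.tsv"),
    )
    paths["panel"] = "panel.tsv"
    paths["chromosomes"] = "chromosomes.tsv"
    pio.write_fasta(
        cohort.reference.sequences.items(), os.path.join(outdir, "reference.fa")
    )
    paths["reference"] = "reference.fa"
    pio.write_fasta(cohort.reference.te_library, os.path.join(outdir, "te_library.fa"))
    paths["te_library"] = "te_library.fa"
    write_gff3(cohort.reference.genes, os.path.join(outdir, "genes.gff3"))
    paths["genes"] = "genes.gff3"
    vcfs: Dict[str, Dict[str, str]] = {}
    for acc in cohort.accessions:
        vcfs[acc] = {}
        for caller, records in cohort.callsets[acc].items():
            rel = f"vcf/{acc}.caller{caller}.vcf"
            pio.write_sv_vcf(records, os.path.join(outdir, rel), acc, chrom_lengths)
            vcfs[acc][caller] = rel
    paths["vcf"] = vcfs
    bedgraphs: Dict[str, str] = {}
    for acc in cohort.accessions:
        rel = f"coverage/{acc}.bedgraph"
        pio.write_bedgraph(cohort.coverage[acc], os.path.join(outdir, rel))
        bedgraphs[acc] = rel
    paths["coverage"] = bedgraphs
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["truth"] = "truth.json"
    manifest = {"seed": cohort.seed, "paths": paths}
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest_path
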