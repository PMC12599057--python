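"""Readers and writers for the standard formats (VCF, GFF3, bedgraph, TSV, FASTA).

VCF and GFF3 are 1-based on disk; everything returned here is 0-based
half-open. Reading goes through pysam / gffutils; writing emits plain text so
that output bytes are exactly reproducible.
"""

from __future__ import annotations

import os
import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    ChromBins,
    CoverageTrack,
    EcotypePanel,
    GeneModel,
    GenomicInterval,
    SVRecord,
    SV_TYPES,
)

_GT_TO_CODE = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}


def _fmt(x: float) -> str:
    """Floats at 6 significant digits (the package's on-disk float contract)."""
    return format(float(x), ".6g")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _classify_gt(gt) -> str:
    if gt is None or all(a is None for a in gt):
        return "missing"
    alleles = [a for a in gt if a is not None]
    if not alleles:
        return "missing"
    if all(a == 0 for a in alleles):
        return "hom_ref"
    if all(a >= 1 for a in alleles):
        return "hom_alt"
    return "het"


def _scalar(value):
    if isinstance(value, (tuple, list)):
        return value[0] if value else None
    return value


def _info_get(rec, *keys):
    for key in keys:
        try:
            value = rec.info.get(key)
        except ValueError:  # key not declared in this header
            value = None
        if value is not None:
            return value
    return None


def read_sv_vcf(path: str) -> List[SVRecord]:
    """Read one accession's SV call set.

    POS is converted to a 0-based start; symbolic ALTs use INFO END for the
    span; INS spans are 1 bp. ``allele_frequency`` is taken from INFO AF/VAF
    when present, else computed as dv/(dr+dv) (None when dr+dv = 0). Records
    with an SVTYPE outside INS/DEL/INV/TRA are skipped with a single warning.
    """
    vf = pysam.VariantFile(str(path))
    header_lines = 0
    with open(path) as fh:  # count the file's own header lines for messages
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
    sample = list(vf.header.samples)
    records: List[SVRecord] = []
    skipped = 0
    lineno = header_lines
    it = iter(vf)
    while True:
        lineno += 1
        try:
            rec = next(it)
        except StopIteration:
            break
        except Exception as exc:  # pragma: no cover - depends on htslib message
            raise ValueError(f"malformed VCF record at line {lineno} of {path}: {exc}")
        try:
            sv_type = _scalar(rec.info.get("SVTYPE"))
            if sv_type not in SV_TYPES:
                skipped += 1
                continue
            pos0 = rec.pos - 1  # pysam .pos is 1-based
            svlen = _scalar(_info_get(rec, "SVLEN"))
            alt = rec.alts[0] if rec.alts else None
            alt_seq: Optional[str] = None
            if sv_type == "INS":
                if alt and not alt.startswith("<"):
                    alt_seq = alt[len(rec.ref):] or None
                if svlen is not None:
                    length = abs(int(svlen))
                elif alt_seq is not None:
                    length = len(alt_seq)
                else:
                    raise ValueError("INS without SVLEN or sequence ALT")
                interval = GenomicInterval(rec.chrom, pos0, pos0 + 1)
            elif sv_type == "TRA":
                length = abs(int(svlen)) if svlen is not None else 1
                interval = GenomicInterval(rec.chrom, pos0, pos0 + 1)
            else:  # DEL / INV span the reference starting at POS
                # htslib absorbs INFO END into rec.stop but, when SVLEN is
                # present, re-derives the end as POS + |SVLEN| under the
                # base-before convention; prefer SVLEN so POS stays the first
                # affected base (END alone round-trips via rec.stop)
                if svlen is not None:
                    end = pos0 + abs(int(svlen))
                elif rec.stop is not None and rec.stop > pos0 + 1:
                    end = rec.stop
                else:
                    raise ValueError(f"{sv_type} without END or SVLEN")
                interval = GenomicInterval(rec.chrom, pos0, int(end))
                length = interval.length
            precise = "IMPRECISE" not in rec.info
            af = _scalar(_info_get(rec, "AF", "VAF"))
            qual = float(format(rec.qual, ".6g")) if rec.qual is not None else 0.0
            filters = list(rec.filter.keys())
            filter_status = filters[0] if filters else "PASS"
            gq = dr = dv = 0
            genotype = "missing"
            if sample:
                s = rec.samples[sample[0]]
                genotype = _classify_gt(s.get("GT"))
                gq = int(s.get("GQ") or 0)
                dr = int(s.get("DR") or 0)
                dv = int(s.get("DV") or 0)
            if af is None:
                af = dv / (dr + dv) if (dr + dv) > 0 else None
            records.append(
                SVRecord(
                    interval=interval,
                    sv_type=sv_type,
                    length=int(length),
                    accession_id=sample[0] if sample else "",
                    alt_sequence=alt_seq,
                    qual=qual,
                    filter_status=filter_status,
                    precise=precise,
                    genotype=genotype,
                    gq=gq,
                    dr=dr,
                    dv=dv,
                    allele_frequency=float(af) if af is not None else None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"malformed VCF record at line {lineno} of {path}: {exc}")
    vf.close()
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} records with unsupported SVTYPE")
    return records


_VCF_META = """##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of structural variant">
##INFO=<ID=PRECISE,Number=0,Type=Flag,Description="Precise breakpoints">
##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise breakpoints">
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
##FILTER=<ID=LowQual,Description="Low quality call">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=DR,Number=1,Type=Integer,Description="Reference-supporting reads">
##FORMAT=<ID=DV,Number=1,Type=Integer,Description="Variant-supporting reads">
"""


def _vcf_header(
    sample_ids: Sequence[str], chrom_lengths: Optional[Dict[str, int]]
) -> str:
    lines = ["##fileformat=VCFv4.2"]
    if chrom_lengths:
        for chrom, ln in chrom_lengths.items():
            lines.append(f"##contig=<ID={chrom},length={ln}>")
    lines.append(_VCF_META.rstrip("\n"))
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    cols.extend(sample_ids)
    lines.append("\t".join(cols))
    return "\n".join(lines) + "\n"


def _record_line(rec: SVRecord, rec_id: str) -> str:
    if rec.sv_type == "INS" and rec.alt_sequence is not None:
        ref, alt = "N", "N" + rec.alt_sequence
        end = rec.start + 1
    else:
        ref, alt = "N", f"<{rec.sv_type}>"
        end = rec.interval.end
    svlen = -rec.length if rec.sv_type == "DEL" else rec.length
    info = [
        f"SVTYPE={rec.sv_type}",
        f"SVLEN={svlen}",
        f"END={end}",
        "PRECISE" if rec.precise else "IMPRECISE",
    ]
    if rec.allele_frequency is not None:
        info.append(f"AF={_fmt(rec.allele_frequency)}")
    fmt = f"{_GT_TO_CODE[rec.genotype]}:{rec.gq}:{rec.dr}:{rec.dv}"
    return "\t".join(
        [
            rec.chrom,
            str(rec.start + 1),
            rec_id,
            ref,
            alt,
            _fmt(rec.qual),
            rec.filter_status,
            ";".join(info),
            "GT:GQ:DR:DV",
            fmt,
        ]
    )


def write_sv_vcf(
    records: Sequence[SVRecord],
    path: str,
    sample_id: str,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> None:
    """Write a single-sample VCF 4.2 (records emitted in input order)."""
    with open(path, "w") as fh:
        fh.write(_vcf_header([sample_id], chrom_lengths))
        for i, rec in enumerate(records):
            fh.write(_record_line(rec, f"sv{i + 1}") + "\n")


def write_merged_vcf(
    loci,
    accessions: Sequence[str],
    path: str,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> None:
    """Multi-sample VCF of merged pangenome loci: GT 1/1 carriers, ./. absent."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(list(accessions), chrom_lengths))
        for locus in loci:
            rep = locus.representative
            base = _record_line(rep, locus.locus_id).split("\t")[:9]
            base[8] = "GT"
            gts = ["1/1" if p else "./." for p in locus.presence]
            fh.write("\t".join(base + gts) + "\n")


def read_merged_vcf(path: str):
    """Read a multi-sample merged VCF back into PangenomeLocus objects."""
    from .merge import PangenomeLocus
    import numpy as np

    vf = pysam.VariantFile(str(path))
    samples = tuple(vf.header.samples)
    loci = []
    for rec in vf:
        sv_type = _scalar(rec.info.get("SVTYPE"))
        if sv_type not in SV_TYPES:
            continue
        pos0 = rec.pos - 1
        svlen = _scalar(_info_get(rec, "SVLEN"))
        alt = rec.alts[0] if rec.alts else None
        alt_seq = None
        if sv_type == "INS" and alt and not alt.startswith("<"):
            alt_seq = alt[len(rec.ref):] or None
        if sv_type in ("INS", "TRA"):
            interval = GenomicInterval(rec.chrom, pos0, pos0 + 1)
            length = abs(int(svlen)) if svlen is not None else (
                len(alt_seq) if alt_seq else 1
            )
        else:
            end = pos0 + abs(int(svlen)) if svlen is not None else rec.stop
            interval = GenomicInterval(rec.chrom, pos0, int(end))
            length = interval.length
        presence = np.array(
            [_classify_gt(rec.samples[s].get("GT")) == "hom_alt" for s in samples]
        )
        rep = SVRecord(
            interval=interval,
            sv_type=sv_type,
            length=int(length),
            accession_id="",
            alt_sequence=alt_seq,
            qual=float(rec.qual) if rec.qual is not None else 0.0,
            precise="IMPRECISE" not in rec.info,
        )
        loci.append(
            PangenomeLocus(
                locus_id=rec.id or f"PSV{len(loci) + 1:06d}",
                representative=rep,
                sv_type=sv_type,
                presence=presence,
                accessions=samples,
                frequency_pct=100.0 * presence.sum() / len(samples),
            )
        )
    vf.close()
    return loci


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gene_models(path: str) -> List[GeneModel]:
    """Parse gene/CDS/UTR features from GFF3 into GeneModels.

    CDS or UTR rows without a resolvable parent gene are grouped by their
    Parent attribute and attached to a synthetic singleton gene (with a
    warning).
    """
    import gffutils

    with open(path) as fh:
        has_features = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_features:
        return []
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        force=True,
    )
    utr_types = [
        t
        for t in ("five_prime_UTR", "three_prime_UTR", "UTR")
        if t in set(db.featuretypes())
    ]
    genes: List[GeneModel] = []
    claimed: set = set()

    def _iv(feat) -> GenomicInterval:
        return GenomicInterval(feat.seqid, feat.start - 1, feat.end)

    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        cds, utr = [], []
        for child in db.children(g, featuretype="CDS", order_by="start"):
            cds.append(_iv(child))
            claimed.add(id_key(child))
        for ut in utr_types:
            for child in db.children(g, featuretype=ut, order_by="start"):
                utr.append(_iv(child))
                claimed.add(id_key(child))
        genes.append(GeneModel(g.id, _iv(g), g.strand or "+", cds, utr))

    orphans: Dict[str, List] = {}
    for ftype in ["CDS"] + utr_types:
        for feat in db.features_of_type(ftype):
            if id_key(feat) in claimed:
                continue
            parent = feat.attributes.get("Parent", [feat.id])[0]
            orphans.setdefault(parent, []).append(feat)
    if orphans:
        warnings.warn(
            f"{path}: {sum(len(v) for v in orphans.values())} CDS/UTR rows without "
            f"a resolvable gene parent; attached to synthetic singleton genes"
        )
        for parent, feats in sorted(orphans.items()):
            span = GenomicInterval(
                feats[0].seqid,
                min(f.start for f in feats) - 1,
                max(f.end for f in feats),
            )
            cds = [_iv(f) for f in feats if f.featuretype == "CDS"]
            utr = [_iv(f) for f in feats if f.featuretype != "CDS"]
            genes.append(
                GeneModel(f"orphan:{parent}", span, feats[0].strand or "+", cds, utr)
            )
    return genes


def id_key(feat) -> Tuple[str, str, int, int]:
    return (feat.featuretype, feat.seqid, feat.start, feat.end)


# ---------------------------------------------------------------------------
# bedgraph
# ---------------------------------------------------------------------------

def read_coverage_bedgraph(
    path: str, bin_size: int, accession_id: Optional[str] = None
) -> CoverageTrack:
    """Average a sorted bedgraph into fixed-width bins (length-weighted mean).

    The trailing partial bin keeps its true width. Overlapping or unsorted
    input intervals raise ``ValueError``.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "depth"],
        comment="#",
        dtype={"chrom": str},
    )
    if accession_id is None:
        accession_id = os.path.splitext(os.path.basename(str(path)))[0]
    track = CoverageTrack(accession_id=accession_id, bin_size=int(bin_size))
    if df.empty:
        return track
    if (df["depth"] < 0).any():
        raise ValueError(f"{path}: negative depth")
    for chrom, grp in df.groupby("chrom", sort=False):
        s = grp["start"].to_numpy(np.int64)
        e = grp["end"].to_numpy(np.int64)
        d = grp["depth"].to_numpy(np.float64)
        if (e <= s).any():
            raise ValueError(f"{path}: empty interval on {chrom}")
        if len(s) > 1 and (s[1:] < e[:-1]).any():
            raise ValueError(f"{path}: overlapping or unsorted intervals on {chrom}")
        chrom_len = int(e[-1])
        nbins = -(-chrom_len // bin_size)
        wsum = np.zeros(nbins, dtype=np.float64)
        b0 = s // bin_size
        b1 = (e - 1) // bin_size
        within = b0 == b1
        np.add.at(wsum, b0[within], d[within] * (e[within] - s[within]))
        for i in np.flatnonzero(~within):  # intervals spanning bin boundaries
            for b in range(int(b0[i]), int(b1[i]) + 1):
                lo = max(int(s[i]), b * bin_size)
                hi = min(int(e[i]), (b + 1) * bin_size)
                wsum[b] += d[i] * (hi - lo)
        widths = np.full(nbins, bin_size, dtype=np.int64)
        widths[-1] = chrom_len - (nbins - 1) * bin_size
        starts = np.arange(nbins, dtype=np.int64) * bin_size
        track.bins[str(chrom)] = ChromBins(starts, wsum / widths, widths)
    return track


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, cb in track.bins.items():
            ends = cb.starts + cb.widths
            for s, e, d in zip(cb.starts, ends, cb.depths):
                fh.write(f"{chrom}\t{s}\t{e}\t{_fmt(d)}\n")


# ---------------------------------------------------------------------------
# panel / chromosome tables, FASTA
# ---------------------------------------------------------------------------

def write_panel(panel: EcotypePanel, panel_path: str, chrom_path: str) -> None:
    with open(panel_path, "w") as fh:
        fh.write("accession_id\tecotype\n")
        for acc, eco in panel.ecotype_of.items():
            fh.write(f"{acc}\t{eco}\n")
    with open(chrom_path, "w") as fh:
        fh.write("chrom\tlength\tsubgenome\n")
        for chrom, ln in panel.chrom_lengths.items():
            fh.write(f"{chrom}\t{ln}\t{panel.subgenome_of[chrom]}\n")


def read_panel(panel_path: str, chrom_path: str) -> EcotypePanel:
    pdf = pd.read_csv(panel_path, sep="\t", dtype=str)
    cdf = pd.read_csv(chrom_path, sep="\t", dtype={"chrom": str, "subgenome": str})
    return EcotypePanel(
        ecotype_of=dict(zip(pdf["accession_id"], pdf["ecotype"])),
        subgenome_of=dict(zip(cdf["chrom"], cdf["subgenome"])),
        chrom_lengths=dict(zip(cdf["chrom"], cdf["length"].astype(int))),
    )


def read_fasta(path: str) -> List[Tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[Tuple[str, str]], path: str) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path),
        "fasta",
    )
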