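"""Readers and writers for the interchange formats.

Internal coordinates are 0-based half-open; SEG and VCF files use 1-based
inclusive coordinates as is standard. Chromosome names are "chr"-prefixed
everywhere; readers normalise bare names. All writers produce canonical,
byte-stable output for a given input (floats at fixed precision).
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import pandas as pd
import pysam

from .complexity import CaseFeatures
from .genome import Breakend, CNProfile, CNSegment, GenomeSpec, SVCall
from .promoter_swap import GeneModel

__all__ = [
    "read_seg", "write_seg",
    "read_sv", "write_sv_tsv", "write_sv_vcf", "read_sv_tsv", "read_sv_vcf",
    "read_expression", "write_expression",
    "read_gene_model", "write_gene_model",
    "read_case_features", "write_case_features",
]

log = logging.getLogger(__name__)

SEG_COLUMNS = ["sample", "chrom", "start", "end", "cn", "log2ratio"]
SV_COLUMNS = ["chrom1", "pos1", "chrom2", "pos2", "orientation", "caller",
              "qual", "side1", "side2"]


def _norm_chrom(name: str) -> str:
    name = str(name)
    return name if name.startswith("chr") else f"chr{name}"


# ---------------------------------------------------------------------------
# SEG-like copy-number tables
# ---------------------------------------------------------------------------

def write_seg(profiles: list[CNProfile], path: str | Path) -> None:
    rows = []
    for profile in profiles:
        for seg in profile.all_segments():
            rows.append((profile.sample_id, seg.chrom, seg.start + 1,
                         seg.end, seg.cn, f"{seg.log2ratio:.4f}"))
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t",
                                                   index=False)


def read_seg(path: str | Path, genome: GenomeSpec) -> list[CNProfile]:
    """Read a SEG-like TSV into per-sample profiles (validated against the
    genome: full chromosome coverage required)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        log.warning("%s: empty SEG file", path)
        return []
    missing = set(SEG_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing SEG columns {sorted(missing)}")
    profiles = []
    for sample, sub in df.groupby("sample", sort=True):
        segs = []
        for idx, row in sub.iterrows():
            chrom = _norm_chrom(row["chrom"])
            try:
                segs.append(CNSegment(chrom, int(row["start"]) - 1,
                                      int(row["end"]), int(row["cn"]),
                                      float(row.get("log2ratio", 0.0))))
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{idx + 2}: {exc}") from exc
        profiles.append(CNProfile(str(sample), genome, segs))
    return profiles


# ---------------------------------------------------------------------------
# structural variants: simple TSV dialect and VCF BND
# ---------------------------------------------------------------------------

_SIDES_FROM_ORIENTATION = {
    "D": ("right", "left"), "TD": ("left", "right"),
    "HH": ("right", "right"), "TT": ("left", "left"),
}


def write_sv_tsv(calls: list[SVCall], path: str | Path) -> None:
    rows = [(c.bnd1.chrom, c.bnd1.pos + 1, c.bnd2.chrom, c.bnd2.pos + 1,
             c.orientation, c.caller_id, f"{c.quality:.1f}",
             c.bnd1.side, c.bnd2.side) for c in calls]
    pd.DataFrame(rows, columns=SV_COLUMNS).to_csv(path, sep="\t",
                                                  index=False)


def read_sv_tsv(path: str | Path) -> list[SVCall]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        log.warning("%s: empty SV file", path)
        return []
    calls = []
    has_sides = "side1" in df.columns and "side2" in df.columns
    for idx, row in df.iterrows():
        try:
            ori = str(row["orientation"])
            if has_sides:
                s1, s2 = str(row["side1"]), str(row["side2"])
            elif ori in _SIDES_FROM_ORIENTATION:
                s1, s2 = _SIDES_FROM_ORIENTATION[ori]
            else:  # interchromosomal without explicit sides
                s1, s2 = "right", "left"
            calls.append(SVCall.make(
                Breakend(_norm_chrom(row["chrom1"]), int(row["pos1"]) - 1, s1),
                Breakend(_norm_chrom(row["chrom2"]), int(row["pos2"]) - 1, s2),
                caller_id=str(row["caller"]),
                quality=float(row["qual"])))
        except (ValueError, TypeError, KeyError) as exc:
            raise ValueError(f"{path}:{idx + 2}: {exc}") from exc
    return calls


def _bnd_alt(own: Breakend, mate: Breakend) -> str:
    """VCF BND bracket notation for one breakend of a junction.

    A breakend whose junction faces right keeps its left flank, hence the
    reference base precedes the bracket; the bracket direction encodes the
    mate's facing flank.
    """
    mate_ref = f"{mate.chrom}:{mate.pos + 1}"
    bracket = "[" if mate.side == "left" else "]"
    body = f"{bracket}{mate_ref}{bracket}"
    return f"N{body}" if own.side == "right" else f"{body}N"


_ALT_RE = re.compile(
    r"^(?P<pre>[ACGTN]*)(?P<b1>[\[\]])(?P<chrom>[^\[\]:]+):(?P<pos>\d+)"
    r"(?P<b2>[\[\]])(?P<post>[ACGTN]*)$")


def _parse_bnd_alt(alt: str, own_chrom: str, own_pos: int
                   ) -> tuple[Breakend, Breakend]:
    m = _ALT_RE.match(alt)
    if not m or m.group("b1") != m.group("b2"):
        raise ValueError(f"malformed BND ALT {alt!r}")
    own_side = "right" if m.group("pre") else "left"
    mate_side = "left" if m.group("b1") == "[" else "right"
    own = Breakend(own_chrom, own_pos, own_side)
    mate = Breakend(_norm_chrom(m.group("chrom")),
                    int(m.group("pos")) - 1, mate_side)
    return own, mate


def write_sv_vcf(calls: list[SVCall], genome: GenomeSpec,
                 path: str | Path) -> None:
    """Write paired BND records (bracket notation), one pair per call."""
    header = pysam.VariantHeader()
    header.add_line('##fileformat=VCFv4.2')
    for chrom, length in genome.chromosomes:
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,'
                    'Description="Type of structural variant">')
    header.add_line('##INFO=<ID=MATEID,Number=1,Type=String,'
                    'Description="ID of mate breakend">')
    header.add_line('##INFO=<ID=CALLER,Number=1,Type=String,'
                    'Description="Originating caller">')
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, call in enumerate(calls):
            ids = (f"bnd_{i}_1", f"bnd_{i}_2")
            for (own, mate), own_id, mate_id in (
                    ((call.bnd1, call.bnd2), ids[0], ids[1]),
                    ((call.bnd2, call.bnd1), ids[1], ids[0])):
                rec = vcf.new_record()
                rec.contig = own.chrom
                rec.start = own.pos
                rec.id = own_id
                rec.ref = "N"
                rec.alts = (_bnd_alt(own, mate),)
                rec.stop = own.pos + 1
                rec.qual = call.quality
                rec.info["SVTYPE"] = "BND"
                rec.info["MATEID"] = mate_id
                rec.info["CALLER"] = call.caller_id
                vcf.write(rec)


def read_sv_vcf(path: str | Path) -> list[SVCall]:
    """Read paired BND records; each mate pair yields one call."""
    calls = []
    seen: set[str] = set()
    with pysam.VariantFile(str(path)) as vcf:
        records = {rec.id: rec for rec in vcf}
    if not records:
        log.warning("%s: empty VCF", path)
        return []
    for rec_id, rec in records.items():
        if rec_id in seen:
            continue
        info = dict(rec.info)
        if info.get("SVTYPE") != "BND":
            continue
        mate_id = info.get("MATEID")
        if mate_id is not None:
            seen.add(str(mate_id))
        seen.add(rec_id)
        own, mate = _parse_bnd_alt(rec.alts[0], _norm_chrom(rec.contig),
                                   rec.start)
        calls.append(SVCall.make(own, mate,
                                 caller_id=str(info.get("CALLER", "vcf")),
                                 quality=float(rec.qual or 0.0)))
    return calls


def read_sv(path: str | Path) -> list[SVCall]:
    """Dispatch on file content: VCF BND or the simple TSV dialect."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF"):
        return read_sv_vcf(path)
    return read_sv_tsv(path)


# ---------------------------------------------------------------------------
# expression, gene models, case features
# ---------------------------------------------------------------------------

def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.round(4).to_csv(path, sep="\t", index_label="feature")


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        log.warning("%s: empty expression matrix", path)
    return df


def write_gene_model(genes: dict[str, GeneModel], path: str | Path) -> None:
    """BED12-like TSV: one row per gene with comma-separated exon bounds."""
    rows = []
    for name in sorted(genes):
        g = genes[name]
        rows.append((g.name, g.chrom, g.strand, g.promoter[0], g.promoter[1],
                     g.cds_start,
                     ",".join(str(s) for s, _ in g.exons),
                     ",".join(str(e) for _, e in g.exons)))
    pd.DataFrame(rows, columns=["gene", "chrom", "strand", "promoter_start",
                                "promoter_end", "cds_start", "exon_starts",
                                "exon_ends"]).to_csv(path, sep="\t",
                                                     index=False)


def read_gene_model(path: str | Path) -> dict[str, GeneModel]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    genes = {}
    for idx, row in df.iterrows():
        try:
            starts = [int(x) for x in str(row["exon_starts"]).split(",")]
            ends = [int(x) for x in str(row["exon_ends"]).split(",")]
            genes[str(row["gene"])] = GeneModel(
                name=str(row["gene"]), chrom=_norm_chrom(row["chrom"]),
                strand=str(row["strand"]),
                promoter=(int(row["promoter_start"]),
                          int(row["promoter_end"])),
                exons=tuple(zip(starts, ends)),
                cds_start=int(row["cds_start"]))
        except (ValueError, TypeError, KeyError) as exc:
            raise ValueError(f"{path}:{idx + 2}: {exc}") from exc
    return genes


def write_case_features(cases: list[CaseFeatures], path: str | Path) -> None:
    payload = [{k: v for k, v in vars(c).items()} for c in cases]
    with open(path, "w") as fh:
        json.dump({"cases": payload}, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_case_features(path: str | Path) -> list[CaseFeatures]:
    with open(path) as fh:
        payload = json.load(fh)
    rows = payload["cases"] if isinstance(payload, dict) else payload
    return [CaseFeatures(**{k: v for k, v in row.items() if k != "notes"})
            for row in rows]
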