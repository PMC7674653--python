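"""Readers/writers for the standard formats and the packaged table fixtures.

Internal coordinates are 1-based inclusive (GFF3/VCF convention); BED output
is converted to 0-based half-open at the boundary.  FASTA/FASTQ go through
Biopython, GFF3 reading through gffutils, SAM through pysam; VCF is written
by a plain emitter and can be re-read with either our reader or pysam.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    Alignment,
    CnvCall,
    GeneFeature,
    GenomeRecord,
    LongChange,
    ReadPair,
    VariantCall,
)

_GFF_TYPE_TO_KIND = {
    "CDS": "cds",
    "pseudogene": "pseudogene",
    "rRNA": "rrna",
    "tRNA": "trna",
}
_KIND_TO_GFF_TYPE = {v: k for k, v in _GFF_TYPE_TO_KIND.items()}


# ---------------------------------------------------------------- FASTA

def write_fasta(genome: GenomeRecord, path) -> None:
    SeqIO.write([SeqRecord(Seq(genome.sequence), id=genome.id, description="")], str(path), "fasta")


def read_fasta(path) -> GenomeRecord:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    rec = records[0]
    return GenomeRecord(id=rec.id, sequence=str(rec.seq).upper())


# ---------------------------------------------------------------- FASTQ

def write_fastq_pairs(pairs: list[ReadPair], path1, path2) -> None:
    """Write mates to two Phred+33 FASTQ files."""

    def records(mate: int):
        for p in pairs:
            seq = p.mate1_seq if mate == 1 else p.mate2_seq
            qual = p.mate1_qual if mate == 1 else p.mate2_qual
            rec = SeqRecord(Seq(seq), id=f"{p.pair_id}/{mate}", description="")
            rec.letter_annotations["phred_quality"] = [int(q) for q in qual]
            yield rec

    SeqIO.write(records(1), str(path1), "fastq")
    SeqIO.write(records(2), str(path2), "fastq")


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    pairs = []
    for r1, r2 in zip(it1, it2, strict=True):
        pid1 = r1.id.rsplit("/", 1)[0]
        pid2 = r2.id.rsplit("/", 1)[0]
        if pid1 != pid2:
            raise ValueError(f"paired FASTQ out of sync: {r1.id} vs {r2.id}")
        pairs.append(
            ReadPair(
                pair_id=pid1,
                mate1_seq=str(r1.seq).upper(),
                mate2_seq=str(r2.seq).upper(),
                mate1_qual=np.array(r1.letter_annotations["phred_quality"]),
                mate2_qual=np.array(r2.letter_annotations["phred_quality"]),
            )
        )
    return pairs


# ---------------------------------------------------------------- GFF3

def write_gff3(features: list[GeneFeature], genome: GenomeRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for i, f in enumerate(sorted(features, key=lambda f: f.start), start=1):
            attrs = [f"ID=feat{i}", f"locus_tag={f.locus_tag}", f"product={f.product}"]
            if f.feature_kind == "pseudogene":
                attrs.append("pseudo=true")
            fh.write(
                "\t".join(
                    [
                        genome.id,
                        "clonalvar",
                        _KIND_TO_GFF_TYPE[f.feature_kind],
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[GeneFeature]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    features = []
    for f in db.all_features():
        kind = _GFF_TYPE_TO_KIND.get(f.featuretype)
        if kind is None:
            continue
        features.append(
            GeneFeature(
                locus_tag=f.attributes.get("locus_tag", [f.id])[0],
                product=f.attributes.get("product", [""])[0],
                start=f.start,
                end=f.end,
                strand=f.strand,
                feature_kind=kind,
            )
        )
    features.sort(key=lambda f: f.start)
    return features


# ---------------------------------------------------------------- SAM

def write_sam(alignments: list[Alignment], reference: GenomeRecord, path,
              read_sequences: dict[str, str] | None = None) -> None:
    """Minimal valid SAM: @SQ header plus POS/CIGAR/FLAG per record."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": reference.id, "LN": reference.length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in alignments:
            rec = pysam.AlignedSegment()
            rec.query_name = a.read_id
            rec.reference_id = 0
            rec.reference_start = a.ref_start - 1
            rec.cigarstring = "".join(f"{n}{op}" for op, n in a.cigar)
            flag = 0
            if a.strand == "-":
                flag |= 0x10
            if a.is_duplicate:
                flag |= 0x400
            rec.flag = flag
            rec.mapping_quality = 0 if a.is_ambiguous else 60
            if read_sequences and a.read_id in read_sequences:
                seq = read_sequences[a.read_id]
                if a.strand == "-":
                    from .models import revcomp

                    seq = revcomp(seq)
                rec.query_sequence = seq
            rec.set_tag("NM", a.n_mismatches)
            out.write(rec)


def read_sam(path) -> tuple[list[Alignment], str, int]:
    """Read a SAM file back into alignments; returns (alignments,
    reference_name, reference_length)."""
    import pysam

    alignments = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        ref_name = fh.references[0] if fh.references else ""
        ref_len = fh.lengths[0] if fh.lengths else 0
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            cigar = []
            for op_code, n in rec.cigartuples or []:
                op = {0: "M", 1: "I", 2: "D"}.get(op_code)
                if op is None:
                    raise ValueError(f"{path}: unsupported CIGAR op code {op_code} in {rec.query_name}")
                cigar.append((op, n))
            name = rec.query_name
            pair_id, _, mate_s = name.rpartition("/")
            alignments.append(
                Alignment(
                    read_id=name,
                    pair_id=pair_id or name,
                    mate=int(mate_s) if mate_s.isdigit() else 1,
                    ref_start=rec.reference_start + 1,
                    cigar=cigar,
                    strand="-" if rec.is_reverse else "+",
                    n_mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                    query_length=sum(n for op, n in cigar if op in ("M", "I")),
                    is_duplicate=rec.is_duplicate,
                    is_ambiguous=rec.mapping_quality == 0,
                )
            )
    return alignments, ref_name, ref_len


# ---------------------------------------------------------------- VCF

_FILTER_CODES = {
    "raw": ".",
    "pass": "PASS",
    "shared_with_wt": "SharedWithWT",
    "low_relcov": "LowRelCov",
    "low_fraction": "LowFraction",
}
_FILTER_DECODE = {v: k for k, v in _FILTER_CODES.items()}


def write_vcf(calls: list[VariantCall], reference: GenomeRecord, path,
              thresholds=None) -> None:
    """VCF 4.2 with DP/AC/AF/RC INFO fields; calibrated thresholds echoed in
    the header when given."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={reference.id},length={reference.length}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Site depth">\n')
        fh.write('##INFO=<ID=AC,Number=1,Type=Integer,Description="Alternate allele read count">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele read fraction">\n')
        fh.write('##INFO=<ID=RC,Number=1,Type=Float,Description="Depth relative to genome mean">\n')
        fh.write('##FILTER=<ID=SharedWithWT,Description="Also called in the wild-type sample">\n')
        fh.write('##FILTER=<ID=LowRelCov,Description="Relative coverage at or below rel_cov_min">\n')
        fh.write('##FILTER=<ID=LowFraction,Description="Supporting read fraction below pop_fraction_min">\n')
        if thresholds is not None:
            fh.write(f"##clonalvar_rel_cov_min={thresholds.rel_cov_min}\n")
            fh.write(f"##clonalvar_pop_fraction_min={thresholds.pop_fraction_min}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: c.position):
            info = f"DP={c.depth};AC={c.alt_count};AF={c.alt_fraction:.6g};RC={c.rel_coverage:.6g}"
            fh.write(
                f"{reference.id}\t{c.position}\t.\t{c.ref_allele}\t{c.alt_allele}\t.\t"
                f"{_FILTER_CODES[c.filter_status]}\t{info}\n"
            )


def read_vcf(path) -> list[VariantCall]:
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}:{lineno}: malformed VCF record ({len(parts)} columns)")
            _, pos, _, ref, alt, _, filt, info = parts[:8]
            fields = dict(kv.split("=", 1) for kv in info.split(";") if "=" in kv)
            try:
                depth = int(fields["DP"])
                alt_count = int(fields["AC"])
                rel_cov = float(fields.get("RC", 0.0))
            except KeyError as e:
                raise ValueError(f"{path}:{lineno}: missing INFO field {e}") from None
            calls.append(
                VariantCall(
                    position=int(pos),
                    ref_allele=ref,
                    alt_allele=alt,
                    depth=depth,
                    alt_count=alt_count,
                    rel_coverage=rel_cov,
                    filter_status=_FILTER_DECODE.get(filt, "raw"),
                )
            )
    return calls


# ---------------------------------------------------------------- BED / TSV

def write_bed(calls: list[CnvCall], reference_id: str, path) -> None:
    """CNV calls as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda c: c.start):
            fh.write(f"{reference_id}\t{c.start - 1}\t{c.end}\t{c.kind}\t{c.copy_ratio:.3f}\n")


def write_cnv_tsv(calls: list[CnvCall], path) -> None:
    rows = [
        {
            "position": f"{c.start}-{c.end}",
            "size": c.size,
            "kind": c.kind,
            "copy_ratio": round(c.copy_ratio, 3),
            "loci": ";".join(c.loci),
        }
        for c in sorted(calls, key=lambda c: c.start)
    ]
    pd.DataFrame(rows, columns=["position", "size", "kind", "copy_ratio", "loci"]).to_csv(
        path, sep="\t", index=False
    )


def write_annotated_tsv(annotated, path) -> None:
    """Variant-table-shaped TSV (Position..Aa_alt plus Effect)."""
    rows = []
    for av in annotated:
        rows.append(
            {
                "Position": av.call.position,
                "Ref": av.call.ref_allele,
                "Alt": av.call.alt_allele,
                "Locus": av.locus_tag,
                "Product": av.product,
                "Start": av.feature_start or "",
                "End": av.feature_end or "",
                "Strand": av.strand,
                "Feature": av.feature_kind if av.feature_kind not in ("cds", "intergenic") else "",
                "Aa_ref": av.aa_ref,
                "Aa_alt": av.aa_alt,
                "Effect": av.effect,
            }
        )
    cols = ["Position", "Ref", "Alt", "Locus", "Product", "Start", "End", "Strand",
            "Feature", "Aa_ref", "Aa_alt", "Effect"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_truth_tsv(truth, path) -> None:
    rows = [
        {"kind": t.kind, "position": t.position, "ref": t.ref_allele, "alt": t.alt_allele,
         "size": t.size}
        for t in truth
    ]
    pd.DataFrame(rows, columns=["kind", "position", "ref", "alt", "size"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------- fixtures

def _fixture_path(name: str) -> Path:
    return Path(importlib.resources.files("clonalvar") / "fixtures" / name)


def load_table3_variants() -> pd.DataFrame:
    """Published per-strain variant table (one row per variant record).

    Columns: strain, position, ref, alt, locus, product, start, end, strand,
    feature, aa_ref, aa_alt.  Missing locus means a non-coding (intergenic)
    record; the minus sign is normalised to ASCII.
    """
    path = _fixture_path("table3_variants.tsv")
    df = pd.read_csv(path, sep="\t", dtype={"position": int}, keep_default_na=False)
    df = df.fillna("")
    if df.shape[1] != 12:
        raise ValueError(f"{path}: expected 12 columns, found {df.shape[1]}")
    df["strand"] = df["strand"].str.replace("−", "-", regex=False)
    return df


def load_table4_long_changes() -> list[tuple[str, LongChange]]:
    """Published longer genome changes as (strain, record) tuples."""
    path = _fixture_path("table4_long_changes.tsv")
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        lc = LongChange(start=int(row.start), end=int(row.end), note=str(row.note))
        if lc.size != int(row.size_bp):
            raise ValueError(
                f"{path}: size mismatch for {row.strain} {row.start}-{row.end}: "
                f"end-start+1={lc.size} but table prints {row.size_bp}"
            )
        out.append((str(row.strain), lc))
    return out


def load_table5_cnv() -> list[tuple[str, CnvCall]]:
    """Published copy-number variants as (strain, record) tuples; the gain
    copy ratio is not printed in the source table and is recorded as 2.0."""
    path = _fixture_path("table5_cnv.tsv")
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        call = CnvCall(
            start=int(row.start),
            end=int(row.end),
            kind="gain",
            copy_ratio=2.0,
            loci=[t for t in str(row.loci).split(";") if t],
        )
        out.append((str(row.strain), call))
    return out
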