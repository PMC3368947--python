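"""File-format adapters: FASTA, VCF, transcript tables (TSV/BED12), TSV, JSON.

All genomic coordinates are 0-based half-open internally; VCF's 1-based
positions are converted at this boundary.  Everything this package emits is
plain text and round-trips losslessly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO

from .annotation import AnnotatedSnv, Snv, TranscriptModel
from .code_sites import BASES, CodingSequence, SiteCounts

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- FASTA

def read_cds_fasta(path: str, delimiter: str = "|") -> List[CodingSequence]:
    """In-frame CDS records; header convention ``>gene_id|transcript_id``."""
    records = []
    for rec in SeqIO.parse(path, "fasta"):
        parts = rec.id.split(delimiter, 1)
        gene_id = parts[0]
        transcript_id = parts[1] if len(parts) > 1 else parts[0]
        records.append(CodingSequence(gene_id, transcript_id, str(rec.seq).upper()))
    return records


def write_fasta(records: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_cds_fasta(cds_list: Iterable[CodingSequence], path: str, delimiter: str = "|") -> None:
    write_fasta(
        {f"{c.gene_id}{delimiter}{c.transcript_id}": c.sequence for c in cds_list}, path
    )


def read_genome_fasta(path: str) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ------------------------------------------------------- transcript models

def write_transcript_table(models: Iterable[TranscriptModel], path: str) -> None:
    """TSV: gene_id, transcript_id, chrom, strand, comma-separated intervals."""
    with open(path, "w") as fh:
        fh.write("gene_id\ttranscript_id\tchrom\tstrand\tcds_intervals\n")
        for m in models:
            ivals = ",".join(f"{s}-{e}" for s, e in m.cds_intervals)
            fh.write(f"{m.gene_id}\t{m.transcript_id}\t{m.chrom}\t{m.strand}\t{ivals}\n")


def read_transcript_table(path: str) -> List[TranscriptModel]:
    models = []
    with open(path) as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        expected = ["gene_id", "transcript_id", "chrom", "strand", "cds_intervals"]
        if header != expected:
            raise ValueError(f"{path}:1: expected columns {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
            gene, transcript, chrom, strand, ivals = fields
            intervals = []
            for token in ivals.split(","):
                start, _, end = token.partition("-")
                intervals.append((int(start), int(end)))
            models.append(
                TranscriptModel(gene, transcript, chrom, strand, tuple(intervals))
            )
    return models


def read_bed12(path: str) -> List[TranscriptModel]:
    """BED12 transcript models; CDS = blocks intersected with the thick region.

    The name field supplies both gene and transcript id (``gene|transcript``
    or a single id used for both).
    """
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 fields")
            chrom = fields[0]
            chrom_start = int(fields[1])
            name = fields[3]
            strand = fields[5]
            thick_start, thick_end = int(fields[6]), int(fields[7])
            n_blocks = int(fields[9])
            sizes = [int(v) for v in fields[10].rstrip(",").split(",")]
            starts = [int(v) for v in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            intervals = []
            for size, rel in zip(sizes, starts):
                s = chrom_start + rel
                e = s + size
                cs, ce = max(s, thick_start), min(e, thick_end)
                if cs < ce:
                    intervals.append((cs, ce))
            if not intervals:
                logger.warning("%s:%d: %s has no CDS blocks; skipped", path, lineno, name)
                continue
            gene, _, transcript = name.partition("|")
            models.append(
                TranscriptModel(gene, transcript or gene, chrom, strand, tuple(intervals))
            )
    return models


def read_transcript_models(path: str) -> List[TranscriptModel]:
    """Dispatch on extension: .bed/.bed12 -> BED12, otherwise the TSV format."""
    if str(path).endswith((".bed", ".bed12")):
        return read_bed12(path)
    return read_transcript_table(path)


# ----------------------------------------------------------------- VCF

def write_vcf(
    snvs: Sequence[Snv],
    contig_lengths: Mapping[str, int],
    path: str,
    source: str = "rdnsv-simulate",
) -> None:
    """Plain VCF 4.2 with AA/AC/AN INFO fields; records sorted by contig order."""
    order = {c: i for i, c in enumerate(contig_lengths)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##INFO=<ID=AC,Number=A,Type=Integer,Description="Alternate allele count">\n')
        fh.write('##INFO=<ID=AN,Number=1,Type=Integer,Description="Total allele number">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for snv in sorted(snvs, key=lambda v: (order.get(v.chrom, len(order)), v.pos)):
            info = f"AC={snv.alt_count};AN={snv.allele_number}"
            if snv.ancestral:
                info = f"AA={snv.ancestral};" + info
            fh.write(
                f"{snv.chrom}\t{snv.pos + 1}\t.\t{snv.ref}\t{snv.alt}\t.\tPASS\t{info}\n"
            )


def read_ancestral_sidecar(path: str) -> Dict[Tuple[str, int], str]:
    """TSV of (chrom, 1-based pos, ancestral base); ``#`` comments allowed."""
    table: Dict[Tuple[str, int], str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected chrom, pos, base")
            table[(fields[0], int(fields[1]) - 1)] = fields[2].upper()
    return table


def read_vcf_snvs(
    path: str,
    ancestral: Optional[Mapping[Tuple[str, int], str]] = None,
    pass_only: bool = False,
) -> List[Snv]:
    """Strict biallelic SNVs from a VCF; multi-allelic records are split.

    Allele counts come from AC/AN INFO when present, otherwise from
    genotypes (missing genotypes reduce AN).  The ancestral base comes from
    the AA INFO key (case-insensitive; lowercase = low confidence but used),
    else from the sidecar mapping.
    """
    from cyvcf2 import VCF

    snvs: List[Snv] = []
    vcf = VCF(str(path))
    for variant in vcf:
        if pass_only and variant.FILTER is not None:
            continue
        ref = variant.REF.upper()
        if len(ref) != 1 or ref not in BASES:
            continue
        an = variant.INFO.get("AN")
        ac_info = variant.INFO.get("AC")
        if an is None or ac_info is None:
            gts = variant.genotypes  # [[a, b, phased], ...]
            alleles = [a for gt in gts for a in gt[:-1] if a >= 0]
            an = len(alleles)
            ac_list = [alleles.count(i + 1) for i in range(len(variant.ALT))]
        else:
            ac_list = list(ac_info) if isinstance(ac_info, (tuple, list)) else [ac_info]
        if an is None or an < 2:
            logger.warning("%s:%d: no usable allele number; skipped", variant.CHROM, variant.POS)
            continue
        aa = variant.INFO.get("AA")
        if aa is not None:
            aa = str(aa).upper()
            if aa not in BASES:
                aa = None
        if aa is None and ancestral is not None:
            aa = ancestral.get((variant.CHROM, variant.POS - 1))
        for alt, ac in zip(variant.ALT, ac_list):
            alt = alt.upper()
            if len(alt) != 1 or alt not in BASES:
                continue
            snvs.append(
                Snv(
                    chrom=variant.CHROM, pos=variant.POS - 1, ref=ref, alt=alt,
                    alt_count=int(ac), allele_number=int(an), ancestral=aa,
                )
            )
    return snvs


# ----------------------------------------------------------- TSV outputs

def site_counts_frame(per_gene: Mapping[str, SiteCounts]) -> pd.DataFrame:
    rows = []
    for gene, sc in per_gene.items():
        rows.append(
            {
                "gene_id": gene,
                "n_basepairs": int(sc.total),
                "sSite": float(sc.s_site),
                "nsSite": float(sc.ns_site),
                "sSite_ts": float(sc.s_site_ts),
                "sSite_tv": float(sc.s_site_tv),
                "nsSite_ts": float(sc.ns_site_ts),
                "nsSite_tv": float(sc.ns_site_tv),
            }
        )
    return pd.DataFrame(rows)


def annotated_frame(annotated: Iterable[AnnotatedSnv]) -> pd.DataFrame:
    rows = []
    for a in annotated:
        rows.append(
            {
                "chrom": a.snv.chrom,
                "pos": a.snv.pos,
                "ref": a.snv.ref,
                "alt": a.snv.alt,
                "gene_id": a.gene_id,
                "effect": a.effect,
                "channel": a.channel,
                "derived": a.derived,
                "p": a.p,
                "source": a.source,
            }
        )
    return pd.DataFrame(rows)


def write_tsv(frame: pd.DataFrame, path: str, float_format: str = "%.6g") -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=float_format)


def write_manifest(path: str, command: str, config: Mapping[str, object]) -> None:
    from . import __version__

    manifest = {"tool": "rdnsv", "version": __version__, "command": command,
                "config": dict(config)}
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")


def read_gene_list(path: str) -> List[str]:
    genes = []
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                genes.append(token)
    return genes


def read_expression_matrix(path: str) -> pd.DataFrame:
    """Genes x tissues TSV with gene ids in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_tissue_groups(path: str) -> Dict[str, str]:
    """TSV mapping tissue -> group in {target, other, excluded}."""
    groups: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or fields[1] not in ("target", "other", "excluded"):
                raise ValueError(
                    f"{path}:{lineno}: expected 'tissue<TAB>target|other|excluded'"
                )
            groups[fields[0]] = fields[1]
    return groups
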