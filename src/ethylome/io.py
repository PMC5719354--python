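"""Readers and writers for the file formats the pipeline touches.

Coordinate convention: everything in memory is 0-based half-open; GFF3/GTF
are written/read as 1-based inclusive; BED and the per-cytosine methylation
table are 0-based. FASTA is wrapped at 60 columns.
"""

from __future__ import annotations

import os
from typing import Iterable

import gffutils
import pandas as pd
from pyfaidx import Fasta

from .types import Annotation, Gene, TranscriptModel

METH_COLUMNS = ["chrom", "pos0", "strand", "context", "m_count", "total_count"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    """Load a FASTA file into a plain {name: sequence} dict."""
    fa = Fasta(path, as_raw=True, sequence_always_upper=True, rebuild=True)
    out = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    # drop the .fai side file created for random access; we read eagerly
    fai = path + ".fai"
    if os.path.exists(fai):
        os.unlink(fai)
    return out


# ---------------------------------------------------------------------------
# GFF3 annotation
# ---------------------------------------------------------------------------

def write_gff3(annotation: Annotation, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in annotation:
            fh.write(
                f"{gene.chrom}\tethylome\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.id}\n"
            )
            for t in gene.transcripts:
                fh.write(
                    f"{gene.chrom}\tethylome\tmRNA\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\tID={t.id};Parent={gene.id}\n"
                )
                for i, (s, e) in enumerate(t.exons, 1):
                    fh.write(
                        f"{gene.chrom}\tethylome\texon\t{s + 1}\t{e}\t.\t{t.strand}"
                        f"\t.\tID={t.id}.exon{i};Parent={t.id}\n"
                    )


def read_gff3(path: str) -> Annotation:
    """Parse a GFF3 annotation into :class:`Annotation` via gffutils."""
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[Gene] = []
    for g in db.features_of_type("gene"):
        gene = Gene(id=g.id, chrom=g.seqid, strand=g.strand,
                    start=g.start - 1, end=g.end)
        for t in db.children(g, featuretype=("mRNA", "transcript"), order_by="start"):
            exons = sorted((e.start - 1, e.end) for e in db.children(t, featuretype="exon"))
            if not exons:
                raise ValueError(f"annotation transcript {t.id} of gene {g.id} has no exon features")
            gene.transcripts.append(
                TranscriptModel(id=t.id, chrom=g.seqid, strand=t.strand, exons=tuple(exons))
            )
        if not gene.transcripts:
            raise ValueError(f"annotation gene {g.id} has no transcripts with exon features")
        genes.append(gene)
    return Annotation(genes)


# ---------------------------------------------------------------------------
# transcript-model GTF / BED12
# ---------------------------------------------------------------------------

def write_transcript_gtf(models: Iterable[TranscriptModel], path: str) -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = f'transcript_id "{m.id}"; gene_id "{m.id}";'
            if m.source_condition:
                attrs += f' condition "{m.source_condition}";'
            fh.write(
                f"{m.chrom}\tethylome\ttranscript\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tethylome\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def read_transcript_gtf(path: str) -> list[TranscriptModel]:
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    models = []
    for t in db.features_of_type("transcript"):
        exons = sorted((e.start - 1, e.end) for e in db.children(t, featuretype="exon"))
        cond = t.attributes.get("condition", [None])[0]
        tid = t.attributes.get("transcript_id", [t.id])[0]
        models.append(
            TranscriptModel(id=tid, chrom=t.seqid, strand=t.strand,
                            exons=tuple(exons), source_condition=cond)
        )
    models.sort(key=lambda m: (m.chrom, m.start, m.id))
    return models


def read_bed12(path: str) -> list[TranscriptModel]:
    """Read transcript models from 12-column BED (one transcript per line)."""
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError("BED12 requires 12 columns")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            models.append(TranscriptModel(id=name, chrom=chrom, strand=strand, exons=exons))
    return models


# ---------------------------------------------------------------------------
# per-cytosine methylation table (CGmap-like, 0-based)
# ---------------------------------------------------------------------------

def write_methylation(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, columns=METH_COLUMNS)


def read_methylation(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"chrom": str, "pos0": "int64", "strand": str, "context": str,
               "m_count": "int64", "total_count": "int64"},
    )
    missing = [c for c in METH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"methylation table missing columns: {missing}")
    if (df["m_count"] > df["total_count"]).any():
        raise ValueError("m_count exceeds total_count in methylation table")
    return df


# ---------------------------------------------------------------------------
# expression matrix / BED tracks
# ---------------------------------------------------------------------------

def write_expression(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_expression(path: str) -> pd.DataFrame:
    """FPKM matrix: rows are genes/isoforms, columns are samples 'COND_rep'."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("expression matrix contains negative values")
    return df


def read_bed(path: str) -> list[tuple[str, int, int]]:
    """Minimal BED3 reader (TE track)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_dmr_bed(dmrs, path: str) -> None:
    """DMRs as BED6+ with delta/levels/counts in extra columns."""
    import math

    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\t"
                 "direction\tlevel_a\tlevel_b\tdelta\tp_value\tq_value\tn_cytosines\tannotation\n")
        for d in dmrs:
            score = -math.log10(d.q_value) if d.q_value > 0 else 300.0
            name = f"{d.context}:{d.pair[0]}_vs_{d.pair[1]}"
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{name}\t{score:.3f}\t.\t"
                f"{d.direction}\t{d.level_a:.4f}\t{d.level_b:.4f}\t{d.delta:.4f}\t"
                f"{d.p_value:.4g}\t{d.q_value:.4g}\t{d.n_cytosines}\t{d.annotation or '.'}\n"
            )
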