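"""Readers and writers for the standard formats the pipeline touches.

FASTA and FASTQ go through Biopython, GFF3 parsing through gffutils; the
GFF3 and BedGraph writers are plain text emitters. Annotation coordinates
are 1-based closed; BedGraph output is 0-based half-open.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import SPECIES, GenomeSet, ReadRecord, TranscriptModel


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(path: str | Path, models: Iterable[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in models:
            attrs = (
                f"ID={t.transcript_id};gene_id={t.gene_id};biotype={t.biotype}"
            )
            if t.orf is not None:
                attrs += f";orf={t.orf[0]}-{t.orf[1]}"
            fh.write(
                f"{t.chrom}\tmobilnc\ttranscript\t{t.start}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(t.exons, 1):
                fh.write(
                    f"{t.chrom}\tmobilnc\texon\t{s}\t{e}\t.\t{t.strand}\t.\t"
                    f"ID={t.transcript_id}.exon{i};Parent={t.transcript_id}\n"
                )


def read_gff3(path: str | Path, species: str) -> list[TranscriptModel]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for tr in db.features_of_type("transcript"):
        exons = sorted(
            (f.start, f.end) for f in db.children(tr, featuretype="exon")
        )
        orf = None
        if "orf" in tr.attributes:
            a, b = tr.attributes["orf"][0].split("-")
            orf = (int(a), int(b))
        models.append(
            TranscriptModel(
                transcript_id=tr.id,
                gene_id=tr.attributes.get("gene_id", [tr.id])[0],
                species=species,
                chrom=tr.seqid,
                strand=tr.strand,
                exons=exons,
                biotype=tr.attributes.get("biotype", ["candidate"])[0],
                orf=orf,
            )
        )
    return models


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def write_fastq_pair(
    prefix: str | Path, reads: Iterable[ReadRecord], gzipped: bool = False
) -> tuple[Path, Path]:
    prefix = Path(prefix)
    suffix = ".fastq.gz" if gzipped else ".fastq"
    p1 = prefix.with_name(prefix.name + "_R1" + suffix)
    p2 = prefix.with_name(prefix.name + "_R2" + suffix)
    op = gzip.open if gzipped else open
    with op(p1, "wt") as f1, op(p2, "wt") as f2:
        for r in reads:
            f1.write(f"@{r.read_id}/1\n{r.seq1}\n+\n{r.qual}\n")
            f2.write(f"@{r.read_id}/2\n{r.seq2}\n+\n{r.qual}\n")
    return p1, p2


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """(read_id, sequence, quality) tuples."""
    op = gzip.open if str(path).endswith(".gz") else open
    with op(path, "rt") as handle:
        return [
            (rec.id, str(rec.seq), "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]))
            for rec in SeqIO.parse(handle, "fastq")
        ]


# ---------------------------------------------------------------------------
# tables and tracks
# ---------------------------------------------------------------------------

def write_truth_table(path: str | Path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bedgraph(
    path: str | Path, chrom: str, span_start_1based: int, depth
) -> None:
    """Write a per-base depth vector as BedGraph (0-based half-open),
    run-length collapsed."""
    with open(path, "w") as fh:
        i = 0
        n = len(depth)
        while i < n:
            j = i
            while j < n and depth[j] == depth[i]:
                j += 1
            if depth[i] != 0:
                start0 = span_start_1based - 1 + i
                fh.write(f"{chrom}\t{start0}\t{start0 + (j - i)}\t{int(depth[i])}\n")
            i = j


def write_simulation(outdir: str | Path, genomes: GenomeSet, libraries) -> None:
    """Write the full synthetic dataset: per-species FASTA + GFF3, per-tissue
    paired FASTQ, and the ground-truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for species in SPECIES:
        write_fasta(outdir / f"{species}.fasta", genomes.sequences[species])
        write_gff3(outdir / f"{species}.gff3", genomes.transcripts[species])
    for tissue, reads in libraries.reads.items():
        write_fastq_pair(outdir / tissue, reads)
    write_truth_table(outdir / "truth.tsv", libraries.truth_table())
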