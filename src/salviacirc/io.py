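"""Reading and writing of the standard formats used by the pipeline.

FASTA/FASTQ go through Biopython; GFF3 is the minimal gene/exon subset the
annotation model needs; tables are tab-separated with a header row.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import BackspliceJunction, GeneModel, GenomeModel, ReadRecord


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genome: GenomeModel, path: str | Path) -> None:
    """Write gene/exon features, one gene line and one line per exon."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in genome.scaffolds.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for g in genome.genes:
            fh.write(
                f"{g.scaffold}\tsalviacirc\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.scaffold}\tsalviacirc\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Parse the gene/exon subset written by :func:`write_gff3`."""
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            scaffold, _, ftype, start, end, _, strand, _, attrs = fields[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                meta[attr["ID"]] = (scaffold, strand)
            elif ftype == "exon":
                exons.setdefault(attr["Parent"], []).append((int(start), int(end)))
    genes = []
    for gid, (scaffold, strand) in meta.items():
        ex = tuple(sorted(exons.get(gid, [])))
        genes.append(GeneModel(gene_id=gid, scaffold=scaffold, strand=strand, exons=ex))
    return genes


def phred_string(qualities: Iterable[int]) -> str:
    return "".join(chr(q + 33) for q in qualities)


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}/{r.mate}\n{r.sequence}\n+\n{phred_string(r.qualities)}\n")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            rid = rec.id
            mate = 0
            if rid.endswith("/1") or rid.endswith("/2"):
                mate = int(rid[-1])
                rid = rid[:-2]
            yield ReadRecord(
                id=rid,
                mate=mate,
                sequence=str(rec.seq).upper(),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
            )


def junction_table(junctions: Iterable[BackspliceJunction], sample_ids: list[str] | None = None) -> pd.DataFrame:
    """One row per junction; one count column per sample."""
    junctions = list(junctions)
    if sample_ids is None:
        seen: list[str] = []
        for j in junctions:
            for s in j.junction_reads:
                if s not in seen:
                    seen.append(s)
        sample_ids = seen
    rows = []
    for j in junctions:
        row = {
            "circ_id": j.id,
            "scaffold": j.scaffold,
            "start": j.start,
            "end": j.end,
            "strand": j.strand,
            "callers": ",".join(sorted(j.callers)) or ".",
        }
        for s in sample_ids:
            row[s] = j.junction_reads.get(s, 0)
        rows.append(row)
    cols = ["circ_id", "scaffold", "start", "end", "strand", "callers"] + list(sample_ids)
    return pd.DataFrame(rows, columns=cols)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def junctions_to_bed(junctions: Iterable[BackspliceJunction], path: str | Path) -> None:
    """BED6 export: converts 1-based inclusive to 0-based half-open."""
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                f"{j.scaffold}\t{j.start - 1}\t{j.end}\t{j.id}\t{j.total_reads()}\t{j.strand}\n"
            )
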