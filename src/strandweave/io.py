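"""Readers and writers for the standard interchange formats.

Strand-seq read placements use a documented TSV dialect with header
``contig  position  strand  cell  mapq  dup`` (plus ``read_id``); allele
observations travel in a companion TSV ``read_id  snv_id  allele  baseq``.
FASTA goes through Biopython, VCF through pysam, intervals through BED.
All coordinates are 0-based half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def write_fasta(records: dict[str, str], path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        path, "fasta",
    )


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_snv_vcf(genome, path: str, sample: str = "sample") -> None:
    """Unphased het SNV calls for a simulated genome."""
    import pysam

    header = pysam.VariantHeader()
    for c in genome.chrom_names:
        header.contigs.add(c, length=genome.chrom_lengths[c])
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for sid, row in genome.snvs.iterrows():
            rec = vf.new_record(contig=row["chrom"], start=int(row["pos"]),
                                stop=int(row["pos"]) + 1,
                                alleles=(row["ref"], row["alt"]), id=str(sid))
            rec.samples[sample]["GT"] = (0, 1)
            rec.samples[sample].phased = False
            vf.write(rec)


def write_bed(intervals: pd.DataFrame, path: str, cols=("chrom", "start", "end")) -> None:
    extra = [c for c in intervals.columns if c not in cols]
    intervals[list(cols) + extra].to_csv(path, sep="\t", header=False, index=False)


READ_COLUMNS = ["contig", "position", "strand", "cell", "mapq", "dup", "read_id"]


def write_reads_tsv(reads: pd.DataFrame, path: str) -> None:
    df = reads.rename(columns={"pos": "position"})
    df[READ_COLUMNS].to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"position": "pos"})
    df["dup"] = df["dup"].astype(bool)
    return df


def write_alleles_tsv(alleles: pd.DataFrame, path: str) -> None:
    alleles.to_csv(path, sep="\t", index=False)


def read_alleles_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_paf(path: str) -> pd.DataFrame:
    """Minimal PAF reader: query/target names, coordinates and strand."""
    names = ["query", "qlen", "qstart", "qend", "strand",
             "chrom", "tlen", "start", "end", "matches", "alnlen", "mapq"]
    return pd.read_csv(path, sep="\t", header=None, usecols=range(12), names=names)


def write_cluster_fasta(cluster_contigs: dict, sequences: dict[str, str],
                        orientations: dict[str, str], path: str,
                        gap: int = 100) -> None:
    """One concatenated record per cluster with an N-gap spacer between
    ordered, re-oriented contigs."""
    from .simdata import revcomp

    records = {}
    spacer = "N" * gap
    for cluster, contigs in cluster_contigs.items():
        parts = []
        for c in contigs:
            seq = sequences[c]
            if orientations.get(c) == "-":
                seq = revcomp(seq)
            parts.append(seq)
        records[f"cluster{cluster}"] = spacer.join(parts)
    write_fasta(records, path)
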