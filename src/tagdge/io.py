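"""Plain-text readers/writers: FASTA/FASTQ via Biopython, tables as TSV."""

from __future__ import annotations

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .enrichment import AnnotationMap
from .preprocess import TagCountTable
from .simulate import RawReadSet, ReferenceSet

_FASTQ_QUALITY = 40  # constant 'I'; the protocol filters on sequence, not quality


def write_reference_fasta(reference: ReferenceSet, path) -> None:
    records = [SeqRecord(Seq(seq), id=gid, description="") for gid, seq in reference.genes]
    SeqIO.write(records, str(path), "fasta")


def write_genome_fasta(reference: ReferenceSet, path) -> None:
    if reference.genome is None:
        raise ValueError("reference has no genome sequence")
    SeqIO.write([SeqRecord(Seq(reference.genome), id="genome", description="")], str(path), "fasta")


def read_reference_fasta(path, genome_path=None) -> ReferenceSet:
    genes = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    genome = None
    if genome_path is not None:
        genome = str(next(SeqIO.parse(str(genome_path), "fasta")).seq).upper()
    return ReferenceSet(genes, genome)


def write_reads_fastq(reads: RawReadSet, path) -> None:
    records = []
    for i, read in enumerate(reads.reads):
        rec = SeqRecord(Seq(read), id=f"read{i + 1}", description="")
        rec.letter_annotations["phred_quality"] = [_FASTQ_QUALITY] * len(read)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_reads_fastq(path) -> RawReadSet:
    reads = [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]
    return RawReadSet(reads, [("unknown", "")] * len(reads))


def write_tag_table(table: TagCountTable, path) -> None:
    df = pd.DataFrame(sorted(table.counts.items()), columns=["tag", "count"])
    df.to_csv(path, sep="\t", index=False)


def read_tag_table(path, label: str = "") -> TagCountTable:
    df = pd.read_csv(path, sep="\t", dtype={"tag": str, "count": int})
    return TagCountTable(dict(zip(df["tag"], df["count"])), label=label)


def write_truth(truth_table: pd.DataFrame, path) -> None:
    truth_table.to_csv(path, sep="\t")


def write_annotations(annotation: AnnotationMap, path) -> None:
    annotation.to_frame().to_csv(path, sep="\t", index=False)


def read_annotations(path) -> AnnotationMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    gene_terms: dict[str, set[str]] = {}
    gene_pathways: dict[str, set[str]] = {}
    term_ontology: dict[str, str] = {}
    for gene, ident, kind in df.itertuples(index=False):
        gene_terms.setdefault(gene, set())
        gene_pathways.setdefault(gene, set())
        if kind == "pathway":
            gene_pathways[gene].add(ident)
        else:
            gene_terms[gene].add(ident)
            term_ontology[ident] = kind
    return AnnotationMap(gene_terms, gene_pathways, term_ontology)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_ct_table(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, sep="\t", index=False)


def read_ct_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
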