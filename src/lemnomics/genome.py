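"""Coding-sequence extraction and translation.

Reads a genome FASTA together with a GTF annotation, assembles the coding
sequence of each gene (one representative transcript per gene), translates
it with the standard genetic code and writes the proteins as FASTA queries
for downstream homology search.

Coordinates are GTF-style throughout: 1-based, inclusive on both ends.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = dict(_STANDARD.forward_table)
_STOPS = set(_STANDARD.stop_codons)


@dataclass
class GeneModel:
    """A gene's representative coding model.

    ``cds_intervals`` are 1-based inclusive genomic (start, end) pairs sorted
    by genomic position; for minus-strand genes the assembled nucleotide
    sequence is the reverse complement of the concatenated intervals, so it
    always reads 5'->3' in coding orientation.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    nt_sequence: str
    aa_sequence: str
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand {self.strand!r} for {self.gene_id}")
        for start, end in self.cds_intervals:
            if start > end:
                raise ValueError(
                    f"interval ({start}, {end}) of {self.gene_id} has start > end"
                )


def translate(nt_sequence: str) -> str:
    """Translate a coding nucleotide sequence to protein.

    Standard genetic code; translation terminates at the first stop codon;
    any codon containing ``N`` yields ``X``; a trailing incomplete codon is
    dropped with a warning.

    Raises
    ------
    ValueError
        If the sequence is shorter than one codon.
    """
    seq = nt_sequence.upper()
    if len(seq) < 3:
        raise ValueError("sequence too short to translate")
    if len(seq) % 3:
        warnings.warn(
            f"trailing incomplete codon of {len(seq) % 3} nt dropped", stacklevel=2
        )
        seq = seq[: len(seq) - len(seq) % 3]
    aa: list[str] = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            aa.append("X")
            continue
        if codon in _STOPS:
            break
        try:
            aa.append(_FORWARD[codon])
        except KeyError:
            aa.append("X")
    return "".join(aa)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_cds(genome_fasta: str | Path, gtf: str | Path) -> list[GeneModel]:
    """Assemble one coding model per gene from a genome FASTA and a GTF.

    For multi-isoform genes the representative transcript is the one with the
    longest total CDS length (ties broken by transcript id). Minus-strand
    sequences are reverse-complemented into coding orientation. The phase
    (frame) of the first coding segment is honoured: leading out-of-frame
    bases are trimmed before translation.

    Raises
    ------
    ValueError
        If a CDS feature references a chromosome absent from the FASTA.
    """
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    db = gffutils.create_db(
        str(gtf),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    # transcript-level grouping: (gene, transcript) -> list of CDS features
    by_tx: dict[tuple[str, str], list] = {}
    genes_seen: set[str] = set()
    for feat in db.features_of_type("CDS"):
        gene_id = feat.attributes.get("gene_id", [None])[0]
        if gene_id is None:
            raise ValueError(f"CDS feature at {feat.seqid}:{feat.start} lacks gene_id")
        tx_id = feat.attributes.get("transcript_id", [gene_id])[0]
        if feat.seqid not in contigs:
            raise ValueError(
                f"CDS of gene {gene_id!r} (transcript {tx_id!r}) references "
                f"chromosome {feat.seqid!r} absent from the genome FASTA"
            )
        by_tx.setdefault((gene_id, tx_id), []).append(feat)
        genes_seen.add(gene_id)

    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("gene_id", [None])[0]
        if gid is not None and gid not in genes_seen:
            logger.warning("gene %s has no CDS features; skipped", gid)

    # longest total CDS per gene, ties by transcript id
    best_tx: dict[str, tuple[int, str]] = {}
    for (gene_id, tx_id), feats in by_tx.items():
        total = sum(f.end - f.start + 1 for f in feats)
        key = (-total, tx_id)
        cur = best_tx.get(gene_id)
        if cur is None or key < cur:
            best_tx[gene_id] = key

    models: list[GeneModel] = []
    for gene_id in sorted(best_tx):
        _, tx_id = best_tx[gene_id]
        feats = sorted(by_tx[(gene_id, tx_id)], key=lambda f: f.start)
        chrom = feats[0].seqid
        strand = feats[0].strand if feats[0].strand in {"+", "-"} else "+"
        intervals = [(f.start, f.end) for f in feats]
        nt = "".join(contigs[chrom][s - 1 : e] for s, e in intervals)
        if strand == "-":
            nt = _revcomp(nt)
            first = feats[-1]  # highest coordinates = first in coding order
        else:
            first = feats[0]
        phase = first.frame if first.frame in {"0", "1", "2"} else "0"
        if phase != "0":
            nt = nt[int(phase) :]
        aa = translate(nt)
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                cds_intervals=intervals,
                nt_sequence=nt,
                aa_sequence=aa,
                transcript_id=tx_id,
            )
        )
    return models


def write_protein_fasta(models: Iterable[GeneModel], path: str | Path) -> int:
    """Write gene models as a protein multi-FASTA; returns record count."""
    records = [
        SeqRecord(Seq(m.aa_sequence), id=m.gene_id, description="")
        for m in models
        if m.aa_sequence
    ]
    return SeqIO.write(records, str(path), "fasta")


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an id -> sequence map."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
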