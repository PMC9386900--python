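"""Protein homology search against an annotated reference database.

Desk-scale replacement for an external BLASTP stage: an exact local
aligner (Smith-Waterman with affine gaps, Gotoh algorithm) scores every
query against every reference record, and per-hit metrics (identity,
similarity, alignment length, query coverage) are derived from the
traceback. Precomputed tabular search output in the 12-column BLAST
outfmt-6 dialect can be imported instead.

Gap penalties follow the BLAST convention: a gap of length L costs
``gap_open + L * gap_extend``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

logger = logging.getLogger(__name__)

TAXON_GROUPS = ("plant", "bacteria", "fungi", "other")

#: column order of the tabular hit dialect (BLAST ``-outfmt 6``)
OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

_UNKNOWN = "?"  # sentinel residue: scores -1 against everything


@dataclass(frozen=True)
class ProteinRecord:
    """One reference protein with taxon metadata and GO annotations."""

    record_id: str
    species: str
    taxon_group: str
    aa_sequence: str
    go_terms: frozenset[str] = frozenset()
    descriptor: str = ""

    def __post_init__(self) -> None:
        if not self.aa_sequence:
            raise ValueError(f"record {self.record_id} has an empty sequence")
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(
                f"record {self.record_id}: unknown taxon group {self.taxon_group!r}"
            )
        for go in self.go_terms:
            if not (go.startswith("GO:") and len(go) == 10 and go[3:].isdigit()):
                raise ValueError(f"record {self.record_id}: malformed GO id {go!r}")


@dataclass
class HomologyHit:
    """One query-subject local alignment with derived metrics.

    ``percent_query_alignment`` is the share of the query covered by the
    alignment span (the "% alignment" used to rank best hits);
    ``percent_similarity`` counts aligned columns that are identical or have
    a positive substitution score (BLAST "positives").
    """

    query_id: str
    subject_id: str
    subject_species: str
    subject_taxon_group: str
    percent_identity: float
    percent_similarity: float
    alignment_length: int
    percent_query_alignment: float
    score: float
    evalue: float | None = None
    similarity_is_identity: bool = False


_matrix_cache: dict[str, object] = {}


def _extended_matrix(name_or_matrix):
    """Substitution matrix extended with a sentinel symbol scoring -1."""
    if isinstance(name_or_matrix, str) and name_or_matrix in _matrix_cache:
        return _matrix_cache[name_or_matrix]
    m = (
        substitution_matrices.load(name_or_matrix)
        if isinstance(name_or_matrix, str)
        else name_or_matrix
    )
    if _UNKNOWN in m.alphabet:
        return m
    alphabet = m.alphabet + _UNKNOWN
    ext = substitution_matrices.Array(alphabet=alphabet, dims=2)
    n = len(m.alphabet)
    view = np.asarray(ext)
    view[:n, :n] = np.asarray(m)
    view[n, :] = -1.0
    view[:, n] = -1.0
    if isinstance(name_or_matrix, str):
        _matrix_cache[name_or_matrix] = ext
    return ext


_warned_unknown = False


def _sanitize(seq: str, alphabet: str) -> str:
    """Map residues outside the matrix alphabet to the sentinel symbol."""
    global _warned_unknown
    up = seq.upper()
    if all(c in alphabet for c in up):
        return up
    if not _warned_unknown:
        logger.warning(
            "unknown residue symbol(s) encountered; scored -1 against everything"
        )
        _warned_unknown = True
    return "".join(c if c in alphabet else _UNKNOWN for c in up)


def _make_aligner(matrix, gap_open: float, gap_extend: float) -> PairwiseAligner:
    if gap_open < 0 or gap_extend < 0:
        raise ValueError("gap penalties must be >= 0")
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = matrix
    # BLAST convention: gap of length L costs gap_open + L*gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(
    query: str,
    subject: str,
    matrix: str | object = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    query_id: str = "query",
    subject_id: str = "subject",
    subject_species: str = "",
    subject_taxon_group: str = "other",
) -> HomologyHit | None:
    """Optimal local alignment of two proteins; ``None`` if no positive score.

    Metrics are computed from the traceback of one optimal alignment:
    identity and similarity are percentages of all alignment columns
    (including gap columns), and query coverage is the aligned query span
    over the full query length.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    mat = _extended_matrix(matrix)
    alphabet = str(mat.alphabet)
    q = _sanitize(query, alphabet)
    s = _sanitize(subject, alphabet)
    aligner = _make_aligner(mat, gap_open, gap_extend)
    alignments = aligner.align(q, s)
    score = alignments.score
    if score <= 0:
        return None
    aln = alignments[0]
    identities = 0
    positives = 0
    q_first, q_last = None, None
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        if q_first is None:
            q_first = qs
        q_last = qe
        for a, b in zip(q[qs:qe], s[ss:se]):
            if a == b:
                identities += 1
                positives += 1
            elif mat[a, b] > 0:
                positives += 1
    length = int(aln.length)
    coverage = float(100.0 * (q_last - q_first) / len(q))
    return HomologyHit(
        query_id=query_id,
        subject_id=subject_id,
        subject_species=subject_species,
        subject_taxon_group=subject_taxon_group,
        percent_identity=100.0 * identities / length,
        percent_similarity=100.0 * positives / length,
        alignment_length=length,
        percent_query_alignment=coverage,
        score=float(score),
    )


def search(
    queries: Mapping[str, str],
    db: Sequence[ProteinRecord],
    matrix: str | object = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[HomologyHit]:
    """Align every query against every database record.

    Returns all positive-scoring hits carrying subject species/taxon
    metadata, ordered by query id, then score descending, then subject id.
    """
    if not db:
        raise ValueError("reference database is empty")
    if not queries:
        logger.warning("empty query collection; no hits produced")
        return []
    mat = _extended_matrix(matrix)
    alphabet = str(mat.alphabet)
    sanitized_db = [(rec, _sanitize(rec.aa_sequence, alphabet)) for rec in db]
    hits: list[HomologyHit] = []
    for query_id in sorted(queries):
        q = _sanitize(queries[query_id], alphabet)
        if not q:
            continue
        per_query: list[HomologyHit] = []
        for rec, s in sanitized_db:
            hit = local_align(
                q, s, mat, gap_open, gap_extend,
                query_id=query_id,
                subject_id=rec.record_id,
                subject_species=rec.species,
                subject_taxon_group=rec.taxon_group,
            )
            if hit is not None:
                per_query.append(hit)
        per_query.sort(key=lambda h: (-h.score, h.subject_id))
        hits.extend(per_query)
    return hits


class TabularImport(NamedTuple):
    hits: list[HomologyHit]
    n_dropped: int


def read_tabular_hits(
    path: str | Path,
    db_metadata: Mapping[str, ProteinRecord],
    query_lengths: Mapping[str, int],
) -> TabularImport:
    """Import hits from 12-column tabular search output (BLAST outfmt 6).

    The dialect does not report positives, so ``percent_similarity`` falls
    back to ``percent_identity`` and the hit is flagged
    (``similarity_is_identity``). Hits whose subject is absent from
    ``db_metadata`` are dropped and counted.
    """
    hits: list[HomologyHit] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(OUTFMT6_COLUMNS):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(OUTFMT6_COLUMNS)} "
                    f"columns, found {len(fields)}"
                )
            row = dict(zip(OUTFMT6_COLUMNS, fields))
            subject = db_metadata.get(row["sseqid"])
            if subject is None:
                dropped += 1
                continue
            qlen = query_lengths.get(row["qseqid"])
            if qlen is None:
                raise ValueError(
                    f"{path}: line {lineno}: unknown query {row['qseqid']!r}"
                )
            qstart, qend = int(row["qstart"]), int(row["qend"])
            pident = float(row["pident"])
            hits.append(
                HomologyHit(
                    query_id=row["qseqid"],
                    subject_id=row["sseqid"],
                    subject_species=subject.species,
                    subject_taxon_group=subject.taxon_group,
                    percent_identity=pident,
                    percent_similarity=pident,
                    alignment_length=int(row["length"]),
                    percent_query_alignment=100.0 * (qend - qstart + 1) / qlen,
                    score=float(row["bitscore"]),
                    evalue=float(row["evalue"]),
                    similarity_is_identity=True,
                )
            )
    if dropped:
        logger.warning("%d hit(s) dropped: subject absent from db metadata", dropped)
    return TabularImport(hits=hits, n_dropped=dropped)


def read_db_metadata(path: str | Path, fasta: str | Path | None = None) -> dict[str, ProteinRecord]:
    """Load reference records from a metadata TSV (and optionally sequences).

    The TSV has columns record_id, species, taxon_group, go_terms
    (comma-separated, empty or ``-`` for none), descriptor.
    """
    seqs: dict[str, str] = {}
    if fasta is not None:
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
    records: dict[str, ProteinRecord] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for name in ("record_id", "species", "taxon_group", "go_terms"):
            if name not in idx:
                raise ValueError(f"{path}: missing column {name!r}")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            rid = fields[idx["record_id"]]
            go_cell = fields[idx["go_terms"]]
            gos = frozenset(
                t for t in go_cell.split(",") if t and t != "-"
            )
            records[rid] = ProteinRecord(
                record_id=rid,
                species=fields[idx["species"]],
                taxon_group=fields[idx["taxon_group"]],
                aa_sequence=seqs.get(rid, "X"),
                go_terms=gos,
                descriptor=fields[idx["descriptor"]] if "descriptor" in idx else "",
            )
    return records


def write_hits_tsv(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Persist hits as TSV with the HomologyHit fields as columns."""
    cols = (
        "query_id", "subject_id", "subject_species", "subject_taxon_group",
        "percent_identity", "percent_similarity", "alignment_length",
        "percent_query_alignment", "score", "evalue", "similarity_is_identity",
    )
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        h.subject_species,
                        h.subject_taxon_group,
                        repr(float(h.percent_identity)),
                        repr(float(h.percent_similarity)),
                        str(int(h.alignment_length)),
                        repr(float(h.percent_query_alignment)),
                        repr(float(h.score)),
                        "" if h.evalue is None else repr(float(h.evalue)),
                        "1" if h.similarity_is_identity else "0",
                    ]
                )
                + "\n"
            )


def read_hits_tsv(path: str | Path) -> list[HomologyHit]:
    """Read hits written by :func:`write_hits_tsv`."""
    hits: list[HomologyHit] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            hits.append(
                HomologyHit(
                    query_id=f[idx["query_id"]],
                    subject_id=f[idx["subject_id"]],
                    subject_species=f[idx["subject_species"]],
                    subject_taxon_group=f[idx["subject_taxon_group"]],
                    percent_identity=float(f[idx["percent_identity"]]),
                    percent_similarity=float(f[idx["percent_similarity"]]),
                    alignment_length=int(f[idx["alignment_length"]]),
                    percent_query_alignment=float(f[idx["percent_query_alignment"]]),
                    score=float(f[idx["score"]]),
                    evalue=float(f[idx["evalue"]]) if f[idx["evalue"]] else None,
                    similarity_is_identity=f[idx["similarity_is_identity"]] == "1",
                )
            )
    return hits
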