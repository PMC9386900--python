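"""Homology-based GO annotation transfer.

Implements the cleaning-and-transfer scheme used to annotate a poorly
annotated plant genome from reference proteomes: raw hits are cleaned for
short or weak alignments and for queries whose top hit is not plant-related,
the best hit per reference species (ranked by query coverage) is selected,
and each gene receives the union of the GO terms of its matched plant
reference proteins. An eggNOG-mapper annotations file can be merged in as a
second, complementary source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lemnomics.homology import HomologyHit, ProteinRecord

logger = logging.getLogger(__name__)


@dataclass
class GeneAnnotation:
    """Annotation of a single gene."""

    gene_id: str
    go_terms: set[str] = field(default_factory=set)
    descriptor: str = ""
    sources: set[str] = field(default_factory=set)
    best_hits: dict[str, str] = field(default_factory=dict)  # species -> subject
    go_sources: dict[str, set[str]] = field(default_factory=dict)
    best_hit_species: str = ""
    best_hit_taxon: str = ""


@dataclass
class AnnotationDB:
    """Gene -> {GO terms, descriptor, evidence sources} map."""

    genes: dict[str, GeneAnnotation] = field(default_factory=dict)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __len__(self) -> int:
        return len(self.genes)

    def get(self, gene_id: str) -> GeneAnnotation | None:
        return self.genes.get(gene_id)

    def gene_to_go(self) -> dict[str, set[str]]:
        return {g: set(a.go_terms) for g, a in self.genes.items()}

    def write(self, outdir: str | Path) -> None:
        """Persist as two TSVs: gene2go and gene_info."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "gene2go.tsv", "w") as fh:
            fh.write("gene_id\tgo_id\tsource\n")
            for gene_id in sorted(self.genes):
                anno = self.genes[gene_id]
                for go in sorted(anno.go_terms):
                    for src in sorted(anno.go_sources.get(go, {"homology"})):
                        fh.write(f"{gene_id}\t{go}\t{src}\n")
        with open(outdir / "gene_info.tsv", "w") as fh:
            fh.write("gene_id\tdescriptor\tbest_hit\tspecies\ttaxon_group\tsources\n")
            for gene_id in sorted(self.genes):
                anno = self.genes[gene_id]
                best = ""
                if anno.best_hit_species and anno.best_hit_species in anno.best_hits:
                    best = anno.best_hits[anno.best_hit_species]
                fh.write(
                    f"{gene_id}\t{anno.descriptor}\t{best}\t"
                    f"{anno.best_hit_species}\t{anno.best_hit_taxon}\t"
                    f"{','.join(sorted(anno.sources))}\n"
                )

    @classmethod
    def read(cls, indir: str | Path) -> "AnnotationDB":
        indir = Path(indir)
        db = cls()
        with open(indir / "gene2go.tsv") as fh:
            fh.readline()
            for line in fh:
                gene_id, go, src = line.rstrip("\n").split("\t")
                anno = db.genes.setdefault(gene_id, GeneAnnotation(gene_id=gene_id))
                anno.go_terms.add(go)
                anno.go_sources.setdefault(go, set()).add(src)
                anno.sources.add(src)
        info = indir / "gene_info.tsv"
        if info.exists():
            with open(info) as fh:
                fh.readline()
                for line in fh:
                    f = line.rstrip("\n").split("\t")
                    gene_id = f[0]
                    anno = db.genes.setdefault(gene_id, GeneAnnotation(gene_id=gene_id))
                    anno.descriptor = f[1]
                    if f[3]:
                        anno.best_hits.setdefault(f[3], f[2])
                        anno.best_hit_species = f[3]
                        anno.best_hit_taxon = f[4]
                    anno.sources.update(s for s in f[5].split(",") if s)
        return db


@dataclass
class TaxonSummary:
    """Distribution of genes over the taxon group of their top hit."""

    counts: dict[str, int] = field(default_factory=dict)
    fractions: dict[str, float] = field(default_factory=dict)

    @property
    def percents(self) -> dict[str, float]:
        """Percentages rounded to 0.1 (reporting precision)."""
        return {k: round(100.0 * v, 1) for k, v in self.fractions.items()}

    @property
    def n_genes(self) -> int:
        return sum(self.counts.values())


def _top_hit_key(h: HomologyHit) -> tuple[float, str]:
    return (-h.score, h.subject_id)


def _group_by_query(hits: Iterable[HomologyHit]) -> dict[str, list[HomologyHit]]:
    grouped: dict[str, list[HomologyHit]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    return grouped


def filter_hits(
    hits: Sequence[HomologyHit],
    min_len: int = 20,
    min_similarity: float = 35.0,
) -> list[HomologyHit]:
    """Clean raw hits before GO transfer.

    Removes, in order: every hit of any query whose top-scoring hit is not
    plant-related (the whole gene is distrusted), remaining non-plant hits
    (transfer draws on plant-related matches only), hits with alignment
    length below ``min_len`` amino acids, and hits with percent similarity
    below ``min_similarity``. Surviving hits are returned unchanged, in
    input order. Idempotent.
    """
    grouped = _group_by_query(hits)
    plant_top = {
        q: min(qh, key=_top_hit_key).subject_taxon_group == "plant"
        for q, qh in grouped.items()
    }
    out = []
    for h in hits:
        if not plant_top[h.query_id]:
            continue
        if h.subject_taxon_group != "plant":
            continue
        if h.alignment_length < min_len:
            continue
        if h.percent_similarity < min_similarity:
            continue
        out.append(h)
    n_removed = len(hits) - len(out)
    if n_removed:
        logger.info("filter_hits: %d of %d hits removed", n_removed, len(hits))
    return out


def best_hit_per_species(
    hits: Sequence[HomologyHit],
) -> dict[tuple[str, str], HomologyHit]:
    """Best hit per (gene, reference species), ranked by query coverage.

    Ties are broken by higher score, then lexicographically smaller
    subject id, so selection is deterministic.
    """
    best: dict[tuple[str, str], HomologyHit] = {}
    for h in hits:
        key = (h.query_id, h.subject_species)
        cur = best.get(key)
        if cur is None:
            best[key] = h
            continue
        a = (-h.percent_query_alignment, -h.score, h.subject_id)
        b = (-cur.percent_query_alignment, -cur.score, cur.subject_id)
        if a < b:
            best[key] = h
    return best


def transfer_go(
    best_hits: Mapping[tuple[str, str], HomologyHit],
    db_records: Mapping[str, ProteinRecord],
) -> AnnotationDB:
    """Annotate each gene with the union of its best hits' GO term sets.

    The gene descriptor is taken from the overall best hit (same ranking as
    per-species selection, across species).
    """
    db = AnnotationDB()
    per_gene: dict[str, list[HomologyHit]] = {}
    for (gene_id, _species), hit in best_hits.items():
        per_gene.setdefault(gene_id, []).append(hit)
    for gene_id in sorted(per_gene):
        anno = GeneAnnotation(gene_id=gene_id, sources={"homology"})
        overall = min(
            per_gene[gene_id],
            key=lambda h: (-h.percent_query_alignment, -h.score, h.subject_id),
        )
        for hit in per_gene[gene_id]:
            anno.best_hits[hit.subject_species] = hit.subject_id
            rec = db_records.get(hit.subject_id)
            if rec is None:
                continue
            for go in rec.go_terms:
                anno.go_terms.add(go)
                anno.go_sources.setdefault(go, set()).add("homology")
        best_rec = db_records.get(overall.subject_id)
        anno.descriptor = best_rec.descriptor if best_rec is not None else ""
        anno.best_hit_species = overall.subject_species
        anno.best_hit_taxon = overall.subject_taxon_group
        db.genes[gene_id] = anno
    return db


def _parse_eggnog(path: str | Path) -> dict[str, dict[str, str]]:
    """Parse an eggNOG-mapper annotations file into query -> column map."""
    rows: dict[str, dict[str, str]] = {}
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#"):
                header = line.lstrip("#").split("\t")
                continue
            if header is None:
                header = line.split("\t")
                if header and header[0] in {"query", "query_name"}:
                    continue
                raise ValueError(f"{path}: no header line found before data")
            fields = line.split("\t")
            row = dict(zip(header, fields))
            qcol = "query" if "query" in row else "query_name"
            rows[row[qcol]] = row
    return rows


def merge_eggnog(
    anno: AnnotationDB,
    eggnog_tsv: str | Path,
    db_metadata: Mapping[str, ProteinRecord] | None = None,
) -> AnnotationDB:
    """Merge eggNOG-mapper annotations into a homology-derived AnnotationDB.

    Per gene the GO set becomes the union of both sources; genes present
    only in the eggNOG file are added with source ``eggnog``. ``-`` or empty
    GO cells contribute nothing. When ``db_metadata`` is given, rows whose
    seed ortholog maps to a non-plant record are skipped (plant-related
    matches only).
    """
    merged = AnnotationDB(genes={g: a for g, a in anno.genes.items()})
    for query, row in sorted(_parse_eggnog(eggnog_tsv).items()):
        if db_metadata is not None:
            seed = row.get("seed_ortholog", "")
            rec = db_metadata.get(seed)
            if rec is not None and rec.taxon_group != "plant":
                continue
        go_cell = row.get("GOs", "-")
        terms = {t for t in go_cell.split(",") if t and t != "-"}
        gene = merged.genes.get(query)
        if gene is None:
            gene = GeneAnnotation(gene_id=query)
            merged.genes[query] = gene
        gene.sources.add("eggnog")
        for go in terms:
            gene.go_terms.add(go)
            gene.go_sources.setdefault(go, set()).add("eggnog")
        if not gene.descriptor:
            gene.descriptor = row.get("Description", "") or ""
    return merged


def taxon_summary(hits: Sequence[HomologyHit]) -> TaxonSummary:
    """Taxon-group distribution of top hits, computed on pre-cleaning hits.

    Each gene is assigned the taxon group of its single top-scoring hit;
    fractions are over genes having at least one hit.
    """
    grouped = _group_by_query(hits)
    counts: dict[str, int] = {}
    for qh in grouped.values():
        taxon = min(qh, key=_top_hit_key).subject_taxon_group
        counts[taxon] = counts.get(taxon, 0) + 1
    total = sum(counts.values())
    fractions = {k: v / total for k, v in counts.items()} if total else {}
    return TaxonSummary(counts=counts, fractions=fractions)
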