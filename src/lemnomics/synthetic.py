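"""Seeded generators for every input the pipeline consumes.

Produces a toy genome (FASTA + GTF with known multi-exon CDS on both
strands), a reference protein database at a controlled identity to the
translated queries (with taxon labels, planted GO terms and non-homologous
decoys), and differential-expression tables with planted DEGs, planted
direction asymmetry and planted cross-level concordance. Every generator is
a pure function of its parameters and a seed, and the planted ground truth
is serialized alongside the generated files so end-to-end tests can score
recovery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from lemnomics.genome import translate
from lemnomics.ora import bh_adjust

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_STOPS = ["TAA", "TAG", "TGA"]
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SyntheticTruth:
    """Planted ground truth, fully determined by (parameters, seed)."""

    proteins: dict[str, str] = field(default_factory=dict)
    homologs: dict[str, dict] = field(default_factory=dict)  # gene -> subject info
    gene_go: dict[str, list[str]] = field(default_factory=dict)
    taxon_counts: dict[str, int] = field(default_factory=dict)
    de_status: dict[str, str] = field(default_factory=dict)  # null | up | down
    true_lfc: dict[str, float] = field(default_factory=dict)
    enriched_terms: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = rng.choice(list(AMINO_ACIDS), size=length - 1)
    return "M" + "".join(body)


def _back_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein
    ]
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def make_genome(
    n_genes: int,
    mean_cds_len: int = 300,
    strand_mix: float = 0.5,
    seed: int = 0,
    max_exons: int = 3,
    genes_per_contig: int = 25,
    outdir: str | Path | None = None,
) -> tuple[dict[str, str], list[str], SyntheticTruth]:
    """Toy genome: contigs with embedded multi-exon CDS on both strands.

    Returns (contig sequences, GTF lines, truth). CDS lengths are multiples
    of three (a start codon, the back-translated protein body, one stop
    codon); introns and intergenic spacers are random nucleotides. With
    ``outdir`` set, writes ``genome.fa``, ``genes.gtf`` and
    ``genome_truth.json``; identical seeds give byte-identical files.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(
        params={
            "n_genes": n_genes, "mean_cds_len": mean_cds_len,
            "strand_mix": strand_mix, "seed": int(seed), "max_exons": max_exons,
        }
    )
    width = max(4, len(str(n_genes)))
    contigs: dict[str, str] = {}
    gtf_lines: list[str] = []
    nt = "ACGT"
    contig_parts: list[str] = []
    contig_idx, pos = 1, 0

    def _spacer() -> str:
        return "".join(rng.choice(list(nt), size=int(rng.integers(50, 150))))

    for i in range(n_genes):
        if i and i % genes_per_contig == 0:
            contigs[f"contig{contig_idx}"] = "".join(contig_parts)
            contig_parts, pos, contig_idx = [], 0, contig_idx + 1
        chrom = f"contig{contig_idx}"
        gene_id = f"g{i + 1:0{width}d}"
        aa_len = max(30, int(round(rng.normal(mean_cds_len / 3, mean_cds_len / 15))))
        protein = _random_protein(rng, aa_len)
        cds = _back_translate(rng, protein)
        strand = "-" if rng.random() < strand_mix else "+"
        n_exons = int(rng.integers(1, max_exons + 1))
        # split the CDS at random interior nucleotide positions
        if n_exons > 1:
            cuts = np.sort(rng.choice(np.arange(1, len(cds)), size=n_exons - 1, replace=False))
            bounds = [0, *cuts.tolist(), len(cds)]
        else:
            bounds = [0, len(cds)]
        exons = [cds[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
        introns = [
            "".join(rng.choice(list(nt), size=int(rng.integers(20, 80))))
            for _ in range(n_exons - 1)
        ]
        sense_parts: list[str] = []
        exon_offsets: list[tuple[int, int]] = []  # [a, b) in the sense locus
        off = 0
        for j, exon in enumerate(exons):
            exon_offsets.append((off, off + len(exon)))
            sense_parts.append(exon)
            off += len(exon)
            if j < len(introns):
                sense_parts.append(introns[j])
                off += len(introns[j])
        sense = "".join(sense_parts)
        spacer = _spacer()
        contig_parts.append(spacer)
        locus_start = pos + len(spacer)  # 0-based
        locus_seq = sense if strand == "+" else _revcomp(sense)
        contig_parts.append(locus_seq)
        pos = locus_start + len(sense)

        # genomic intervals (1-based inclusive) and frames in coding order
        records: list[tuple[int, int, int]] = []  # (start, end, frame)
        cum = 0
        for a, b in exon_offsets:
            frame = (3 - cum % 3) % 3
            if strand == "+":
                start, end = locus_start + a + 1, locus_start + b
            else:
                start = locus_start + len(sense) - b + 1
                end = locus_start + len(sense) - a
            records.append((start, end, frame))
            cum += b - a
        gene_start = min(r[0] for r in records)
        gene_end = max(r[1] for r in records)
        attrs = f'gene_id "{gene_id}"; transcript_id "{gene_id}.t1";'
        gtf_lines.append(
            f"{chrom}\tsynthetic\tgene\t{gene_start}\t{gene_end}\t.\t{strand}\t.\t"
            f'gene_id "{gene_id}";'
        )
        for start, end, frame in sorted(records):
            gtf_lines.append(
                f"{chrom}\tsynthetic\tCDS\t{start}\t{end}\t.\t{strand}\t{frame}\t{attrs}"
            )
        truth.proteins[gene_id] = protein
    contig_parts.append(_spacer())
    contigs[f"contig{contig_idx}"] = "".join(contig_parts)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fa", "w") as fh:
            for name in contigs:
                fh.write(f">{name}\n")
                seq = contigs[name]
                for j in range(0, len(seq), 60):
                    fh.write(seq[j : j + 60] + "\n")
        with open(outdir / "genes.gtf", "w") as fh:
            fh.write("\n".join(gtf_lines) + "\n")
        truth.to_json(outdir / "genome_truth.json")
    return contigs, gtf_lines, truth


def _allocate_taxa(
    n: int, taxa_mix: Mapping[str, float], rng: np.random.Generator
) -> list[str]:
    """Largest-remainder allocation of n genes to taxa, order shuffled."""
    items = sorted(taxa_mix.items())
    raw = [(name, n * frac) for name, frac in items]
    counts = {name: int(np.floor(x)) for name, x in raw}
    remainder = n - sum(counts.values())
    by_frac = sorted(raw, key=lambda t: (-(t[1] - np.floor(t[1])), t[0]))
    for name, _ in by_frac[:remainder]:
        counts[name] += 1
    labels = [name for name, c in sorted(counts.items()) for _ in range(c)]
    return [labels[i] for i in rng.permutation(n)]


def _mutate_protein(
    rng: np.random.Generator, protein: str, identity_target: float
) -> str:
    n_sub = int(round((1.0 - identity_target / 100.0) * len(protein)))
    if n_sub == 0:
        return protein
    positions = rng.choice(len(protein), size=n_sub, replace=False)
    chars = list(protein)
    for p in positions:
        choices = [a for a in AMINO_ACIDS if a != chars[p]]
        chars[p] = choices[rng.integers(len(choices))]
    return "".join(chars)


def default_go_pool(n_terms: int = 25) -> list[str]:
    return [f"GO:{i + 1:07d}" for i in range(n_terms)]


def make_reference_db(
    truth: SyntheticTruth | Mapping[str, str],
    identity_target: float = 90.0,
    taxa_mix: Mapping[str, float] | None = None,
    go_pool: Sequence[str] | None = None,
    seed: int = 0,
    decoy_fraction: float = 0.2,
    n_plant_species: int = 3,
    enriched_term: str | None = None,
    enriched_genes: Sequence[str] = (),
    outdir: str | Path | None = None,
) -> tuple[list[dict], SyntheticTruth]:
    """Reference protein database with homologs at a controlled identity.

    Per gene, one homolog mutated to about ``identity_target`` percent
    identity (point substitutions, no indels), with a species label drawn
    from ``taxa_mix`` (largest-remainder allocation, so a 0.5% bacterial
    fraction over 200 genes yields exactly one bacterial homolog) and 1-3
    planted GO terms from ``go_pool``. ``enriched_term`` is additionally
    planted on the listed genes. Non-homologous decoy records are appended.

    Returns (records, truth); records are dicts with the ProteinRecord
    fields. With ``outdir``, writes ``db.faa``, ``db_meta.tsv`` and
    ``db_truth.json``.
    """
    if not 0 < identity_target <= 100:
        raise ValueError("identity_target must be in (0, 100]")
    proteins = truth.proteins if isinstance(truth, SyntheticTruth) else dict(truth)
    taxa_mix = dict(taxa_mix) if taxa_mix else {"plant": 0.995, "bacteria": 0.005}
    go_pool = list(go_pool) if go_pool is not None else default_go_pool()
    rng = np.random.default_rng(seed)
    genes = sorted(proteins)
    taxa = _allocate_taxa(len(genes), taxa_mix, rng)
    enriched = set(enriched_genes)

    out = SyntheticTruth(
        proteins=dict(proteins),
        params={
            "identity_target": identity_target, "taxa_mix": taxa_mix,
            "decoy_fraction": decoy_fraction, "seed": int(seed),
            "enriched_term": enriched_term,
        },
        enriched_terms=[enriched_term] if enriched_term else [],
    )
    records: list[dict] = []
    for gene, taxon in zip(genes, taxa):
        if taxon == "plant":
            species = f"plant_sp{int(rng.integers(n_plant_species)) + 1}"
        else:
            species = f"{taxon}_sp1"
        homolog = _mutate_protein(rng, proteins[gene], identity_target)
        n_go = int(rng.integers(1, 4))
        gos = sorted(
            str(g) for g in rng.choice(go_pool, size=min(n_go, len(go_pool)), replace=False)
        )
        if enriched_term and gene in enriched:
            gos = sorted(set(gos) | {enriched_term})
        rid = f"REF_{gene}"
        records.append(
            {
                "record_id": rid,
                "species": species,
                "taxon_group": taxon,
                "aa_sequence": homolog,
                "go_terms": gos,
                "descriptor": f"homolog of {gene}",
            }
        )
        out.homologs[gene] = {
            "subject_id": rid, "species": species, "taxon_group": taxon,
            "identity_target": identity_target,
        }
        out.gene_go[gene] = gos
        out.taxon_counts[taxon] = out.taxon_counts.get(taxon, 0) + 1

    mean_len = int(np.mean([len(p) for p in proteins.values()])) if proteins else 100
    n_decoys = int(round(decoy_fraction * len(genes)))
    for d in range(n_decoys):
        taxon = ("fungi", "other")[int(rng.integers(2))]
        length = max(30, int(round(rng.normal(mean_len, mean_len / 5))))
        n_go = int(rng.integers(1, 4))
        gos = sorted(
            str(g) for g in rng.choice(go_pool, size=min(n_go, len(go_pool)), replace=False)
        )
        records.append(
            {
                "record_id": f"DECOY_{d + 1:04d}",
                "species": f"{taxon}_sp1",
                "taxon_group": taxon,
                "aa_sequence": _random_protein(rng, length),
                "go_terms": gos,
                "descriptor": "decoy protein",
            }
        )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "db.faa", "w") as fh:
            for rec in records:
                fh.write(f">{rec['record_id']}\n")
                seq = rec["aa_sequence"]
                for j in range(0, len(seq), 60):
                    fh.write(seq[j : j + 60] + "\n")
        with open(outdir / "db_meta.tsv", "w") as fh:
            fh.write("record_id\tspecies\ttaxon_group\tgo_terms\tdescriptor\n")
            for rec in records:
                fh.write(
                    f"{rec['record_id']}\t{rec['species']}\t{rec['taxon_group']}\t"
                    f"{','.join(rec['go_terms'])}\t{rec['descriptor']}\n"
                )
        out.to_json(outdir / "db_truth.json")
    return records, out


def make_dge_tables(
    n_genes: int = 1000,
    n_de: int = 100,
    effect_lfc: float = 2.0,
    dispersion: float = 0.3,
    concordance: float = 0.8,
    frac_up: float = 0.5,
    amplify: float = 1.5,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
    de_genes: Sequence[str] | None = None,
    outdir: str | Path | None = None,
) -> tuple[dict[str, "object"], SyntheticTruth]:
    """DE tables for a two-concentration, two-level (RNA/protein) design.

    Null genes receive raw fold changes drawn from N(0, dispersion) and, by
    construction, uniform p-values (two-sided normal test of the observed
    fold change); planted DEGs receive |true lfc| >= ``effect_lfc`` with the
    high-concentration (EC20-like) effects amplified by ``amplify``. Shrunk
    fold changes moderate small estimates toward zero. Proteome tables share
    the planted direction with probability ``concordance`` at half the
    magnitude. padj is the BH adjustment of the p-values.

    Returns ({contrast name -> DataFrame}, truth); contrasts are
    ``rna_ec5``, ``rna_ec20``, ``protein_ec5``, ``protein_ec20``. With
    ``outdir``, each table is written as ``<contrast>.tsv``.
    """
    import pandas as pd

    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        width = max(4, len(str(n_genes)))
        gene_ids = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    else:
        gene_ids = list(gene_ids)
        if len(gene_ids) != n_genes:
            raise ValueError("gene_ids length must equal n_genes")
    if de_genes is None:
        de_genes = [gene_ids[i] for i in sorted(rng.choice(n_genes, size=n_de, replace=False))]
    de_set = set(de_genes)

    truth = SyntheticTruth(
        params={
            "n_genes": n_genes, "n_de": n_de, "effect_lfc": effect_lfc,
            "dispersion": dispersion, "concordance": concordance,
            "frac_up": frac_up, "amplify": amplify, "seed": int(seed),
        }
    )
    mean_expr = np.exp(rng.normal(3.0, 1.2, size=n_genes))
    sign = np.zeros(n_genes)
    true5 = np.zeros(n_genes)
    for i, g in enumerate(gene_ids):
        if g in de_set:
            s = 1.0 if rng.random() < frac_up else -1.0
            mag = effect_lfc + rng.exponential(0.5)
            sign[i] = s
            true5[i] = s * mag
            truth.de_status[g] = "up" if s > 0 else "down"
        else:
            truth.de_status[g] = "null"
        truth.true_lfc[g] = float(true5[i])

    # proteome direction agreement is drawn once per gene
    prot_sign = sign.copy()
    for i in range(n_genes):
        if sign[i] != 0 and rng.random() > concordance:
            prot_sign[i] = -sign[i]

    def _table(true_vec: np.ndarray, noise_sd: float, sub_rng: np.random.Generator):
        raw = true_vec + sub_rng.normal(0.0, noise_sd, size=n_genes)
        z = raw / noise_sd
        pval = 2.0 * stats.norm.sf(np.abs(z))
        shrunk = raw * raw**2 / (raw**2 + 4.0 * noise_sd**2)
        padj = bh_adjust(pval)
        return pd.DataFrame(
            {
                "gene_id": gene_ids,
                "mean_expression": np.round(mean_expr, 4),
                "lfc_raw": np.round(raw, 6),
                "lfc_shrunk": np.round(shrunk, 6),
                "pvalue": pval,
                "padj": padj,
            }
        )

    tables = {
        "rna_ec5": _table(true5, dispersion, np.random.default_rng(rng.integers(2**31))),
        "rna_ec20": _table(true5 * amplify, dispersion, np.random.default_rng(rng.integers(2**31))),
        "protein_ec5": _table(
            prot_sign * np.abs(true5) * 0.5, dispersion, np.random.default_rng(rng.integers(2**31))
        ),
        "protein_ec20": _table(
            prot_sign * np.abs(true5) * 0.5 * amplify, dispersion,
            np.random.default_rng(rng.integers(2**31)),
        ),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        truth.to_json(outdir / "dge_truth.json")
    return tables, truth


#: simulation presets: problem sizes for desk-scale end-to-end runs
PRESETS = {
    "tiny": {"n_genes": 20, "n_de": 6},
    "small": {"n_genes": 50, "n_de": 12},
    "e2e": {"n_genes": 200, "n_de": 30},
}


def simulate(
    preset: str = "small",
    seed: int = 0,
    outdir: str | Path | None = None,
    identity_target: float = 90.0,
    decoy_fraction: float = 0.2,
    taxa_mix: Mapping[str, float] | None = None,
) -> SyntheticTruth:
    """Generate a complete, coupled synthetic study.

    Genome, reference database (with the enriched GO term planted on the
    DE genes plus a background margin) and DE tables all share the same gene
    universe; the combined truth is returned and, with ``outdir``, written
    as ``truth.json`` beside the generated inputs.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[preset]
    rng = np.random.default_rng(seed)
    g_seed, db_seed, dge_seed = (int(x) for x in rng.integers(2**31, size=3))

    _, _, genome_truth = make_genome(p["n_genes"], seed=g_seed, outdir=outdir)
    gene_ids = sorted(genome_truth.proteins)
    de_genes = [gene_ids[i] for i in sorted(rng.choice(len(gene_ids), size=p["n_de"], replace=False))]
    enriched_term = "GO:0099999"
    # margin of non-DE genes carrying the enriched term keeps K realistic
    margin = [g for g in gene_ids if g not in set(de_genes)][: max(5, p["n_de"] // 3)]
    _, db_truth = make_reference_db(
        genome_truth,
        identity_target=identity_target,
        taxa_mix=taxa_mix,
        seed=db_seed,
        decoy_fraction=decoy_fraction,
        enriched_term=enriched_term,
        enriched_genes=list(de_genes) + margin,
        outdir=outdir,
    )
    _, dge_truth = make_dge_tables(
        n_genes=p["n_genes"],
        n_de=p["n_de"],
        seed=dge_seed,
        gene_ids=gene_ids,
        de_genes=de_genes,
        outdir=outdir,
    )
    combined = SyntheticTruth(
        proteins=genome_truth.proteins,
        homologs=db_truth.homologs,
        gene_go=db_truth.gene_go,
        taxon_counts=db_truth.taxon_counts,
        de_status=dge_truth.de_status,
        true_lfc=dge_truth.true_lfc,
        enriched_terms=[enriched_term],
        params={
            "preset": preset, "seed": int(seed),
            "identity_target": identity_target,
            "decoy_fraction": decoy_fraction,
            **{f"genome_{k}": v for k, v in genome_truth.params.items()},
            **{f"dge_{k}": v for k, v in dge_truth.params.items()},
        },
    )
    if outdir is not None:
        combined.to_json(Path(outdir) / "truth.json")
    return combined
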