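"""End-to-end orchestration: config validation, staged runs, run manifest.

The pipeline reproduces the full annotation-to-fingerprint flow: extract and
translate coding sequences, search them against the reference database,
clean hits and transfer GO terms (optionally merging eggNOG annotations),
call DEGs per contrast with the adaptive threshold, intersect them into
core fingerprints, compare compounds, and test each fingerprint for GO
overrepresentation. All outputs are TSV/JSON; reruns with an unchanged
config and inputs are byte-identical, which the manifest's checksums make
auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from lemnomics import __version__
from lemnomics.annotation import (
    best_hit_per_species,
    filter_hits,
    merge_eggnog,
    taxon_summary,
    transfer_go,
)
from lemnomics.dge import (
    call_degs,
    compare_compounds,
    core_set,
    direction_summary,
    pearson,
    quadrant_concordance,
    read_dge_table,
    select_top_expressed,
)
from lemnomics.genome import extract_cds, write_protein_fasta
from lemnomics.homology import read_db_metadata, search, write_hits_tsv
from lemnomics.ora import run_ora, write_ora_tsv

logger = logging.getLogger(__name__)


class ConfigError(Exception):
    """Invalid or incomplete pipeline configuration (exit code 2)."""


class DataError(Exception):
    """Malformed or missing input data (exit code 3)."""


@dataclass
class Thresholds:
    """All tunable cut-offs, surfaced as named keys.

    Defaults are the study conditions: hits shorter than 20 aligned amino
    acids or below 35% similarity are discarded, DEGs require padj <= 0.05
    and |shrunk lfc| above the 0.75 quantile of the absolute raw fold
    changes, and ORA tests terms annotating 10-500 universe genes.
    """

    min_len: int = 20
    min_similarity: float = 35.0
    alpha: float = 0.05
    lfcut_quantile: float = 0.75
    ora_min_size: int = 10
    ora_max_size: int = 500
    top_k_markers: int = 50


@dataclass
class PipelineConfig:
    genome: str = ""
    gtf: str = ""
    reference_db: str = ""
    db_meta: str = ""
    eggnog: str | None = None
    obo: str | None = None
    propagate: bool = False
    compounds: dict[str, dict[str, dict[str, str]]] = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    _TOP_KEYS = {
        "genome", "gtf", "reference_db", "db_meta", "eggnog", "obo",
        "propagate", "compounds", "thresholds", "seed",
    }

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        unknown = set(raw) - cls._TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        thr_raw = dict(raw.get("thresholds") or {})
        thr_unknown = set(thr_raw) - set(Thresholds.__dataclass_fields__)
        if thr_unknown:
            raise ConfigError(f"unknown threshold key(s): {sorted(thr_unknown)}")
        cfg = cls(
            genome=str(raw.get("genome", "")),
            gtf=str(raw.get("gtf", "")),
            reference_db=str(raw.get("reference_db", "")),
            db_meta=str(raw.get("db_meta", "")),
            eggnog=raw.get("eggnog"),
            obo=raw.get("obo"),
            propagate=bool(raw.get("propagate", False)),
            compounds=dict(raw.get("compounds") or {}),
            thresholds=Thresholds(**thr_raw),
            seed=int(raw.get("seed", 0)),
        )
        for name in ("genome", "gtf", "reference_db", "db_meta"):
            if not getattr(cfg, name):
                raise ConfigError(f"config key {name!r} is required")
        if not cfg.compounds:
            raise ConfigError("config must define at least one compound")
        for comp, levels in cfg.compounds.items():
            if not isinstance(levels, Mapping) or not levels:
                raise ConfigError(f"compound {comp!r}: expected level -> table map")
            for level, tables in levels.items():
                if not isinstance(tables, Mapping) or set(tables) != {"low", "high"}:
                    raise ConfigError(
                        f"compound {comp!r} level {level!r}: needs 'low' and 'high' tables"
                    )
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh)
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        except yaml.YAMLError as exc:
            raise ConfigError(f"config file {path} is not valid YAML: {exc}") from exc
        if not isinstance(raw, Mapping):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw)

    def input_paths(self) -> dict[str, str]:
        paths = {
            "genome": self.genome,
            "gtf": self.gtf,
            "reference_db": self.reference_db,
            "db_meta": self.db_meta,
        }
        if self.eggnog:
            paths["eggnog"] = self.eggnog
        if self.obo:
            paths["obo"] = self.obo
        for comp, levels in self.compounds.items():
            for level, tables in levels.items():
                for which, p in tables.items():
                    paths[f"{comp}.{level}.{which}"] = p
        return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _check_inputs(config: PipelineConfig) -> None:
    for name, p in config.input_paths().items():
        if not Path(p).exists():
            raise DataError(f"input {name!r} not found: {p}")


def run_pipeline(config: PipelineConfig | str | Path, outdir: str | Path) -> dict:
    """Run all stages; returns the manifest (also written as manifest.json).

    Any stage failure aborts with an error naming the stage and the
    offending input. The manifest records the package version, parameters,
    input checksums and per-stage output checksums; it contains no
    timestamps, so identical runs produce identical manifests.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    _check_inputs(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    manifest: dict = {
        "tool": "lemnomics",
        "version": __version__,
        "parameters": {
            **{k: getattr(thr, k) for k in Thresholds.__dataclass_fields__},
            "propagate": config.propagate,
            "seed": config.seed,
        },
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in sorted(config.input_paths().items())
        },
        "stages": [],
    }

    def _stage(name: str, outputs: list[Path], counts: dict | None = None) -> None:
        manifest["stages"].append(
            {
                "name": name,
                "outputs": {
                    str(p.relative_to(out)): _sha256(p) for p in sorted(outputs)
                },
                "counts": counts or {},
            }
        )

    # --- extract ---------------------------------------------------------
    stage = "extract"
    try:
        models = extract_cds(config.genome, config.gtf)
        (out / "proteins").mkdir(exist_ok=True)
        proteins_faa = out / "proteins" / "proteins.faa"
        n_written = write_protein_fasta(models, proteins_faa)
        _stage(stage, [proteins_faa], {"genes": len(models), "proteins": n_written})
    except DataError:
        raise
    except Exception as exc:
        raise DataError(f"stage {stage!r} failed on {config.gtf}: {exc}") from exc

    # --- search ----------------------------------------------------------
    stage = "search"
    try:
        db_records = read_db_metadata(config.db_meta, fasta=config.reference_db)
        queries = {m.gene_id: m.aa_sequence for m in models if m.aa_sequence}
        hits = search(queries, sorted(db_records.values(), key=lambda r: r.record_id))
        (out / "hits").mkdir(exist_ok=True)
        hits_tsv = out / "hits" / "hits.tsv"
        write_hits_tsv(hits, hits_tsv)
        summary = taxon_summary(hits)
        taxon_tsv = out / "hits" / "taxon_summary.tsv"
        with open(taxon_tsv, "w") as fh:
            fh.write("taxon_group\tn_genes\tpercent\n")
            for taxon in sorted(summary.counts):
                fh.write(f"{taxon}\t{summary.counts[taxon]}\t{summary.percents[taxon]}\n")
        _stage(stage, [hits_tsv, taxon_tsv], {"hits": len(hits), "genes_with_hits": summary.n_genes})
    except DataError:
        raise
    except Exception as exc:
        raise DataError(f"stage {stage!r} failed on {config.db_meta}: {exc}") from exc

    # --- annotate --------------------------------------------------------
    stage = "annotate"
    try:
        cleaned = filter_hits(hits, min_len=thr.min_len, min_similarity=thr.min_similarity)
        best = best_hit_per_species(cleaned)
        annodb = transfer_go(best, db_records)
        if config.eggnog:
            annodb = merge_eggnog(annodb, config.eggnog, db_metadata=db_records)
        annodir = out / "annodb"
        annodb.write(annodir)
        _stage(
            stage,
            [annodir / "gene2go.tsv", annodir / "gene_info.tsv"],
            {
                "hits_after_cleaning": len(cleaned),
                "annotated_genes": len(annodb),
            },
        )
    except Exception as exc:
        raise DataError(f"stage {stage!r} failed: {exc}") from exc

    # --- fingerprint -----------------------------------------------------
    stage = "fingerprint"
    fp_dir = out / "fingerprint"
    fp_dir.mkdir(exist_ok=True)
    cores: dict[tuple[str, str], set[str]] = {}
    universes: dict[str, set[str]] = {}
    fp_outputs: list[Path] = []
    fp_counts: dict = {}
    try:
        for comp in sorted(config.compounds):
            for level in sorted(config.compounds[comp]):
                tables = config.compounds[comp][level]
                low = read_dge_table(tables["low"])
                high = read_dge_table(tables["high"])
                degs_low = call_degs(low, alpha=thr.alpha, label=f"{comp}_{level}_low",
                                     lfcut_quantile=thr.lfcut_quantile)
                degs_high = call_degs(high, alpha=thr.alpha, label=f"{comp}_{level}_high",
                                      lfcut_quantile=thr.lfcut_quantile)
                core = core_set(degs_low, degs_high, label=f"{comp}_{level}")
                cores[(comp, level)] = core.genes
                if level == "rna":
                    universes[comp] = set(low["gene_id"].astype(str))
                prefix = f"{comp}_{level}"
                degs_tsv = fp_dir / f"{prefix}_degs.tsv"
                with open(degs_tsv, "w") as fh:
                    fh.write("gene_id\tcontrast\tdirection\tin_core\n")
                    for label, degs in (("low", degs_low), ("high", degs_high)):
                        for g in sorted(degs.genes):
                            fh.write(
                                f"{g}\t{label}\t{degs.genes[g]}\t"
                                f"{'1' if g in core.genes else '0'}\n"
                            )
                low_idx = low.set_index("gene_id")
                high_idx = high.set_index("gene_id")
                core_sorted = sorted(core.genes)
                summary_tsv = fp_dir / f"{prefix}_summary.tsv"
                d_low, d_high = direction_summary(degs_low), direction_summary(degs_high)
                corr = None
                if len(core_sorted) >= 3:
                    a = low_idx.loc[core_sorted, "lfc_shrunk"].to_numpy()
                    b = high_idx.loc[core_sorted, "lfc_shrunk"].to_numpy()
                    try:
                        corr = pearson(a, b)
                    except ValueError:
                        corr = None
                with open(summary_tsv, "w") as fh:
                    fh.write("metric\tvalue\n")
                    fh.write(f"lfcut_low\t{degs_low.lfcut:.6g}\n")
                    fh.write(f"lfcut_high\t{degs_high.lfcut:.6g}\n")
                    fh.write(f"n_degs_low\t{len(degs_low)}\n")
                    fh.write(f"n_degs_high\t{len(degs_high)}\n")
                    fh.write(f"pct_down_low\t{d_low.pct_down}\n")
                    fh.write(f"pct_down_high\t{d_high.pct_down}\n")
                    fh.write(f"n_core\t{len(core.genes)}\n")
                    fh.write(f"core_pct_of_low\t{core.pct_of_low}\n")
                    fh.write(f"core_pct_of_high\t{core.pct_of_high}\n")
                    if corr is not None:
                        fh.write(f"core_pearson_r\t{corr.r:.6g}\n")
                        fh.write(f"core_pearson_p\t{corr.pvalue:.6g}\n")
                fp_outputs += [degs_tsv, summary_tsv]
                fp_counts[prefix] = {
                    "n_low": len(degs_low), "n_high": len(degs_high),
                    "n_core": len(core.genes),
                }
            # cross-level concordance and top-expressed markers per compound
            levels = config.compounds[comp]
            if "rna" in levels:
                rna_low = read_dge_table(levels["rna"]["low"])
                mean_expr = dict(
                    zip(rna_low["gene_id"].astype(str), rna_low["mean_expression"])
                )
                core_rna = cores.get((comp, "rna"), set())
                markers = select_top_expressed(
                    sorted(g for g in core_rna if g in mean_expr),
                    mean_expr,
                    k=thr.top_k_markers,
                )
                markers_tsv = fp_dir / f"{comp}_markers.tsv"
                with open(markers_tsv, "w") as fh:
                    fh.write("rank\tgene_id\tmean_expression\n")
                    for rank, g in enumerate(markers, start=1):
                        fh.write(f"{rank}\t{g}\t{mean_expr[g]:.6g}\n")
                fp_outputs.append(markers_tsv)
            if "rna" in levels and "protein" in levels:
                conc_tsv = fp_dir / f"{comp}_concordance.tsv"
                rows = []
                for which in ("low", "high"):
                    rna = read_dge_table(levels["rna"][which]).set_index("gene_id")
                    prot = read_dge_table(levels["protein"][which]).set_index("gene_id")
                    degs_rna = call_degs(
                        rna.reset_index(), alpha=thr.alpha,
                        lfcut_quantile=thr.lfcut_quantile,
                    )
                    shared = sorted(degs_rna.gene_ids & set(prot.index.astype(str)))
                    if shared:
                        qcr = quadrant_concordance(
                            rna.loc[shared, "lfc_shrunk"].to_numpy(),
                            prot.loc[shared, "lfc_shrunk"].to_numpy(),
                        )
                        rows.append((which, len(shared), qcr))
                with open(conc_tsv, "w") as fh:
                    fh.write("contrast\tn_pairs\tqcr\n")
                    for which, n_pairs, qcr in rows:
                        fh.write(f"{which}\t{n_pairs}\t{qcr:.4f}\n")
                fp_outputs.append(conc_tsv)
        _stage(stage, fp_outputs, fp_counts)
    except DataError:
        raise
    except Exception as exc:
        raise DataError(f"stage {stage!r} failed: {exc}") from exc

    # --- compare (only with >= 2 compounds) ------------------------------
    comp_names = sorted(config.compounds)
    if len(comp_names) >= 2:
        stage = "compare"
        try:
            cmp_dir = out / "compare"
            cmp_dir.mkdir(exist_ok=True)
            outputs = []
            for i, a in enumerate(comp_names):
                for b in comp_names[i + 1 :]:
                    for level in ("rna", "protein"):
                        if (a, level) not in cores or (b, level) not in cores:
                            continue
                        res = compare_compounds(cores[(a, level)], cores[(b, level)])
                        path = cmp_dir / f"{a}_vs_{b}_{level}.tsv"
                        with open(path, "w") as fh:
                            fh.write("gene_id\tmembership\n")
                            for g in sorted(res.intersection):
                                fh.write(f"{g}\tshared\n")
                            for g in sorted(res.only_a):
                                fh.write(f"{g}\t{a}_specific\n")
                            for g in sorted(res.only_b):
                                fh.write(f"{g}\t{b}_specific\n")
                        summary = cmp_dir / f"{a}_vs_{b}_{level}_summary.tsv"
                        with open(summary, "w") as fh:
                            fh.write("metric\tvalue\n")
                            fh.write(f"n_shared\t{len(res.intersection)}\n")
                            fh.write(f"pct_of_{a}\t{res.pct_of_a}\n")
                            fh.write(f"pct_of_{b}\t{res.pct_of_b}\n")
                        outputs += [path, summary]
            _stage(stage, outputs)
        except Exception as exc:
            raise DataError(f"stage {stage!r} failed: {exc}") from exc

    # --- ora -------------------------------------------------------------
    stage = "ora"
    try:
        ora_dir = out / "ora"
        ora_dir.mkdir(exist_ok=True)
        outputs = []
        counts = {}
        for comp in comp_names:
            core_rna = cores.get((comp, "rna"))
            if core_rna is None:
                continue
            universe = universes[comp]
            result = run_ora(
                sorted(core_rna & universe),
                sorted(universe),
                annodb,
                min_size=thr.ora_min_size,
                max_size=thr.ora_max_size,
                propagate=config.propagate,
                obo=config.obo,
            )
            path = ora_dir / f"{comp}_core_ora.tsv"
            write_ora_tsv(result, path)
            outputs.append(path)
            counts[comp] = {"terms_tested": int(len(result))}
        _stage(stage, outputs, counts)
    except Exception as exc:
        raise DataError(f"stage {stage!r} failed: {exc}") from exc

    # --- report ----------------------------------------------------------
    stage = "report"
    report = out / "report.json"
    summary_payload = {
        "n_genes": len(models),
        "n_annotated": len(annodb),
        "taxon_percents": taxon_summary(hits).percents,
        "fingerprints": fp_counts,
    }
    with open(report, "w") as fh:
        json.dump(summary_payload, fh, indent=1, sort_keys=True)
    _stage(stage, [report])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %d stages", len(manifest["stages"]))
    return manifest
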