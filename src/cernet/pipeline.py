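"""End-to-end orchestration: DE -> duplex prediction -> triplets -> network ->
enrichment -> GSEA, from a single declarative config, with a machine-readable
run report.

Outputs are written to stage-numbered subdirectories of the run directory
with ``report.json`` at the root.  A rerun with identical inputs, config and
seed is bit-identical; wall-clock timestamps therefore go to the log only,
never into the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import diffexpr, duplex, enrichment, gsea, network, triplets

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline, with the study defaults."""

    counts: str | None = None  # counts TSV; alternatively a precomputed DE table
    de_table: str | None = None
    mirna_fasta: str | None = None
    lncrna_fasta: str | None = None
    interaction_db: str | None = None
    genesets_gmt: str | None = None

    fc_thresholds: dict = field(
        default_factory=lambda: dict(diffexpr.DEFAULT_FC_THRESHOLDS)
    )
    p_threshold: float = 0.001
    mfe_threshold: float = -20.0  # kcal/mol; the duplex energy cutoff
    duplex_window: int = 75
    kappa_threshold: float = 0.4
    p_adj_cutoff: float = 0.05
    gsea_n_perm: int = 1000
    gsea_fdr_cutoff: float = 0.01
    gsea_weight: float = 1.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.counts is None and self.de_table is None:
            raise ValueError("config needs either a counts table or a DE table")
        if self.p_threshold < 0 or self.p_threshold > 1:
            raise ValueError("p_threshold must be in [0, 1]")
        if self.mfe_threshold > 0:
            raise ValueError("mfe_threshold must be <= 0 kcal/mol")
        if self.gsea_n_perm < 100:
            raise ValueError("gsea_n_perm must be >= 100")
        for key in ("counts", "de_table", "mirna_fasta", "lncrna_fasta",
                    "interaction_db", "genesets_gmt"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{key}: {val} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_inputs(config: PipelineConfig) -> list[dict]:
    """Severity-tagged findings about the input files; never raises."""
    findings: list[dict] = []

    def add(severity: str, message: str) -> None:
        findings.append({"severity": severity, "message": message})

    for key in ("counts", "de_table", "mirna_fasta", "lncrna_fasta",
                "interaction_db", "genesets_gmt"):
        val = getattr(config, key)
        if val is not None and not Path(val).exists():
            add("error", f"{key}: file {val} does not exist")

    expr_ids: set[str] = set()
    if config.counts and Path(config.counts).exists():
        try:
            matrix = diffexpr.read_counts(config.counts)
            expr_ids = set(matrix.counts.index)
        except Exception as exc:
            add("error", f"counts table unreadable: {exc}")
    elif config.de_table and Path(config.de_table).exists():
        try:
            expr_ids = {r.id for r in diffexpr.read_de_table(config.de_table)}
        except Exception as exc:
            add("error", f"DE table unreadable: {exc}")

    for key in ("mirna_fasta", "lncrna_fasta"):
        val = getattr(config, key)
        if not val or not Path(val).exists():
            continue
        raw = Path(val).read_text()
        seen: set[str] = set()
        for block in raw.split(">")[1:]:
            header, _, body = block.partition("\n")
            rid = header.split()[0]
            if rid in seen:
                add("warning", f"{key}: duplicate record id {rid}")
            seen.add(rid)
            seq = body.replace("\n", "").upper()
            if "T" in seq:
                add("info", f"{key}: record {rid} contains DNA 'T'; will be read as U")
            bad = set(seq) - set("ACGUT")
            if bad:
                add("error", f"{key}: record {rid} has non-RNA characters {sorted(bad)}")
            if expr_ids and rid not in expr_ids:
                add("warning", f"{key}: record {rid} absent from the expression table")

    if config.interaction_db and Path(config.interaction_db).exists() and expr_ids:
        try:
            df = pd.read_csv(config.interaction_db, sep="\t")
            for col in ("mirna_id", "mrna_id"):
                if col not in df.columns:
                    add("error", f"interaction_db: missing column {col}")
                    break
            else:
                for rid in pd.unique(df[["mirna_id", "mrna_id"]].values.ravel()):
                    if rid not in expr_ids:
                        add("warning", f"interaction_db references unknown id {rid}")
        except Exception as exc:
            add("error", f"interaction_db unreadable: {exc}")
    return findings


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage in order and return the run report (also written
    to ``<outdir>/report.json``).  Any stage error aborts the run, leaving
    partial outputs plus a FAILED marker naming the stage."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": config.to_dict(),
        "seed": config.rng_seed,
        "version": __version__,
        "stages": {},
    }
    current = "setup"
    try:
        # ---- stage 1: differential expression -------------------------------
        current = "diffexpr"
        d1 = outdir / "01_de"
        d1.mkdir(exist_ok=True)
        if config.counts:
            matrix = diffexpr.read_counts(config.counts)
            records = diffexpr.compute_de(matrix)
        else:
            records = diffexpr.read_de_table(config.de_table)
        de = diffexpr.filter_de(records, config.fc_thresholds, config.p_threshold)
        diffexpr.write_de_table(records, d1 / "de_all.tsv")
        diffexpr.write_de_table(de, d1 / "de_filtered.tsv")
        by_class = {c: [r for r in de if r.rna_class == c] for c in diffexpr.RNA_CLASSES}
        report["stages"]["diffexpr"] = {
            "n_tested": len(records),
            "n_DEL": len(by_class["lncRNA"]),
            "n_DEMi": len(by_class["miRNA"]),
            "n_DEM": len(by_class["mRNA"]),
        }
        logger.info("diffexpr: %d tested, %d DELs / %d DEMis / %d DEMs",
                    len(records), len(by_class["lncRNA"]),
                    len(by_class["miRNA"]), len(by_class["mRNA"]))

        # ---- stage 2: miRNA-lncRNA duplex prediction ------------------------
        current = "duplex"
        d2 = outdir / "02_duplex"
        d2.mkdir(exist_ok=True)
        predicted_rows: list[dict] = []
        if config.mirna_fasta and config.lncrna_fasta:
            de_mir = {r.id for r in by_class["miRNA"]}
            de_lnc = {r.id for r in by_class["lncRNA"]}
            mirnas = [r for r in duplex.read_fasta(config.mirna_fasta, "miRNA") if r.id in de_mir]
            lncrnas = [r for r in duplex.read_fasta(config.lncrna_fasta, "lncRNA") if r.id in de_lnc]
            predicted_rows = duplex.predict_lncrna_targets(
                mirnas, lncrnas, mfe_threshold=config.mfe_threshold,
                window=config.duplex_window,
            )
        pd.DataFrame(predicted_rows,
                     columns=["mirna_id", "target_id", "mfe", "n_seed_sites", "best_site_start"]
                     ).to_csv(d2 / "mirna_lncrna_pairs.tsv", sep="\t", index=False)
        report["stages"]["duplex"] = {"n_predicted_pairs": len(predicted_rows)}

        # ---- stage 3: triplets ---------------------------------------------
        current = "triplets"
        d3 = outdir / "03_triplets"
        d3.mkdir(exist_ok=True)
        db_pairs: list[triplets.InteractionPair] = []
        if config.interaction_db:
            db_pairs = triplets.load_interaction_db(
                config.interaction_db,
                de_mirnas={r.id for r in by_class["miRNA"]},
                de_mrnas={r.id for r in by_class["mRNA"]},
            )
        predicted_pairs = [
            triplets.InteractionPair(
                mirna_id=row["mirna_id"], partner_id=row["target_id"],
                partner_class="lncRNA", source="predicted", mfe=row["mfe"],
            )
            for row in predicted_rows
        ]
        trips = triplets.build_triplets(predicted_pairs, db_pairs)
        triplets.write_triplets(trips, d3 / "triplets.tsv")
        co_lnc, co_mir, co_mrna = triplets.coexpression_sets(trips)
        report["stages"]["triplets"] = {
            "n_db_pairs": len(db_pairs),
            "n_predicted_pairs": len(predicted_pairs),
            "n_triplets": len(trips),
            "n_coexpression_lncRNA": len(co_lnc),
            "n_coexpression_miRNA": len(co_mir),
            "n_coexpression_mRNA": len(co_mrna),
        }

        # ---- stage 4: network ----------------------------------------------
        current = "network"
        d4 = outdir / "04_network"
        d4.mkdir(exist_ok=True)
        net = network.build_network(trips, records)
        stage4: dict = {"n_nodes": net.number_of_nodes(), "n_edges": net.number_of_edges()}
        if net.number_of_nodes():
            table = network.centrality_table(net)
            network.export_network(net, d4 / "network.sif", "sif")
            network.export_network(net, d4 / "network.graphml", "graphml", table=table)
            network.export_network(net, d4 / "node_attributes.tsv", "tsv", table=table)
            network.degree_histogram(net).to_csv(d4 / "degree_histogram.tsv", sep="\t", index=False)
            try:
                fit = network.fit_power_law(net)
                stage4["power_law"] = {"slope": fit.slope, "r_squared": fit.r_squared,
                                       "n_points": fit.n_points}
            except ValueError as exc:
                stage4["power_law"] = None
                logger.info("power-law fit skipped: %s", exc)
            try:
                kw = network.compare_centrality(table)
                stage4["kruskal_wallis"] = {
                    r.metric: {"h": r.h_statistic, "df": r.df, "p": r.pvalue} for r in kw
                }
            except ValueError as exc:
                stage4["kruskal_wallis"] = None
                logger.info("centrality comparison skipped: %s", exc)
        else:
            stage4["power_law"] = None
            stage4["kruskal_wallis"] = None
            logger.info("network stage: empty network, downstream stats skipped")
        report["stages"]["network"] = stage4

        # ---- stage 5: enrichment -------------------------------------------
        current = "enrichment"
        d5 = outdir / "05_enrichment"
        d5.mkdir(exist_ok=True)
        stage5: dict = {"n_enriched_terms": 0, "n_groups": 0}
        if config.genesets_gmt and co_mrna:
            coll = enrichment.GeneSetCollection.from_gmt(config.genesets_gmt)
            res = enrichment.enrich(set(co_mrna), coll,
                                    p_adj_cutoff=config.p_adj_cutoff,
                                    kappa_threshold=config.kappa_threshold)
            enrichment.write_enrichment(res, d5 / "enrichment.tsv")
            ann = enrichment.annotate_lncrnas(trips, res)
            enrichment.write_lncrna_annotation(ann, d5 / "lncrna_annotation.tsv")
            stage5 = {
                "n_enriched_terms": len(res),
                "n_groups": len({r.group_id for r in res}),
            }
        report["stages"]["enrichment"] = stage5

        # ---- stage 6: GSEA --------------------------------------------------
        current = "gsea"
        d6 = outdir / "06_gsea"
        d6.mkdir(exist_ok=True)
        stage6: dict = {"n_sets_tested": 0, "n_significant": 0}
        mrna_records = [r for r in records if r.rna_class == "mRNA"]
        if config.genesets_gmt and mrna_records:
            ranked = gsea.rank_genes(mrna_records)
            coll = enrichment.GeneSetCollection.from_gmt(config.genesets_gmt)
            res = gsea.significance(
                ranked, {k: v for k, v in coll.sets.items()},
                n_perm=config.gsea_n_perm, rng_seed=config.rng_seed,
                weight=config.gsea_weight,
            )
            gsea.write_gsea_results(res, d6 / "gsea.tsv")
            stage6 = {
                "n_sets_tested": len(res),
                "n_significant": sum(r.fdr_q < config.gsea_fdr_cutoff for r in res),
            }
        report["stages"]["gsea"] = stage6

    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {current}\nerror: {exc}\n")
        raise StageError(current, exc) from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: report at %s", outdir / "report.json")
    return report
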