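"""End-to-end orchestration of the three-step biomarker pipeline.

``run_pipeline`` executes discovery (paired testing + FDR + separation
filter), survival validation (Cox screen, gene mapping, gene-set
over-representation, gene-frequency ranking) and threshold search
(constrained minimal-p log-rank cutpoint per final probe) from one
configuration mapping, writes every intermediate table as TSV, and
returns a machine-readable run report with the stage funnel, seed,
version and output checksums.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from . import discovery as disc
from . import simulate as sim
from . import survival as surv
from . import threshold as thr
from .io import (
    BetaMatrix,
    ClinicalTable,
    GeneSetCollection,
    ProbeAnnotation,
    ValidationError,
    build_matched_pairs,
    read_beta_matrix,
    read_clinical,
    read_gene_sets,
    read_probe_annotation,
    write_beta_matrix,
    write_clinical,
    write_gene_sets,
    write_probe_annotation,
)

logger = logging.getLogger(__name__)

__all__ = ["RunReport", "run_pipeline", "summarize", "DEFAULTS"]

DEFAULTS: dict[str, Any] = {
    "q": 0.01,                  # FDR level of the discovery step
    "correction": "bh",         # or "bonferroni"
    "separation_filter": True,
    "cox_alpha": 0.01,          # marker-level survival screen
    "enrich_p": 0.05,
    "enrich_method": "hypergeometric",
    "min_overlap": 2,
    "blacklist": [],            # term ids excluded from ranking
    "top_k": 3,
    "min_group_abs": 2,
    "min_group_frac": 0.01,
    "permutations": 0,          # opt-in permutation correction of scan p
    "seed": 0,
}


@dataclass
class RunReport:
    """Structured record of one pipeline run."""

    config: dict
    seed: int
    version: str
    counts: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)     # name -> sha256
    final_genes: list = field(default_factory=list)
    thresholds: list = field(default_factory=list)

    def to_json(self, include_timings: bool = True) -> str:
        payload = dataclasses.asdict(self)
        if not include_timings:
            payload.pop("timings_s")
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if len(out) and isinstance(out[col].iloc[0], tuple):
            out[col] = out[col].map(lambda t: ";".join(map(str, t)))
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> RunReport:
    """Run discover -> validate -> threshold and write all outputs.

    ``config`` either sets ``simulate: true`` (with optional
    ``simulation`` keys forwarded to :class:`~methmark.simulate.SimulationConfig`)
    or names input paths: ``pairs_matrix`` + ``sample_meta`` (TSV),
    ``validation_matrix``, ``clinical``, ``annotation``, ``gene_sets``.
    Analysis knobs default to :data:`DEFAULTS`.
    """
    cfg = {**DEFAULTS, **dict(config)}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={k: v for k, v in cfg.items() if k != "simulation"},
                       seed=int(cfg["seed"]), version=__version__)
    t_start = time.perf_counter()

    # ---- inputs -----------------------------------------------------------
    if cfg.get("simulate"):
        sim_kwargs = dict(cfg.get("simulation", {}))
        sim_kwargs.setdefault("seed", cfg["seed"])
        for key in ("planted_cutpoints", "planted_risk_high", "gene_set_size_range"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        sim_config = sim.SimulationConfig(**sim_kwargs)
        pairs, truth = sim.simulate_matched_cohort(sim_config)
        validation, clinical = sim.simulate_validation_cohort(sim_config, truth)
        annotation, gene_sets = sim.simulate_gene_universe(sim_config, truth)
        sim.write_truth(truth, outdir / "truth.tsv")
        write_beta_matrix(validation, outdir / "validation_matrix.tsv")
        write_clinical(clinical, outdir / "clinical.tsv")
        write_probe_annotation(annotation, outdir / "annotation.tsv")
        write_gene_sets(gene_sets, outdir / "gene_sets.gmt")
        (outdir / "config_echo.json").write_text(
            json.dumps(dataclasses.asdict(sim_config), indent=2, sort_keys=True))
    else:
        matrix = read_beta_matrix(cfg["pairs_matrix"])
        sample_meta = pd.read_csv(cfg["sample_meta"], sep="\t", dtype=str)
        pairs = build_matched_pairs(matrix, sample_meta)
        validation = read_beta_matrix(cfg["validation_matrix"])
        clinical = read_clinical(cfg["clinical"])
        annotation = read_probe_annotation(cfg["annotation"])
        gene_sets = read_gene_sets(cfg["gene_sets"])

    # ---- step 1: discovery ------------------------------------------------
    t0 = time.perf_counter()
    records = disc.run_discovery(pairs, q=cfg["q"], correction=cfg["correction"],
                                 separation=cfg["separation_filter"])
    candidates = disc.select_candidates(records, q_threshold=cfg["q"])
    manhattan, _ = disc.manhattan_table(records, annotation)
    _write(records, outdir / "discovery.tsv")
    _write(candidates, outdir / "candidates.tsv")
    _write(manhattan, outdir / "manhattan.tsv")
    report.timings_s["discovery"] = round(time.perf_counter() - t0, 3)
    report.counts.update(
        probes_tested=int(records["p_value"].notna().sum()),
        fdr_significant=int(records["rejected"].sum()),
        candidates=len(candidates),
    )

    # ---- step 2: survival validation -------------------------------------
    t0 = time.perf_counter()
    if not len(candidates):
        raise ValidationError("stage discovery produced no candidate probes")
    cand_matrix = validation.select_probes(candidates["probe_id"].tolist())
    cox = surv.cox_screen(cand_matrix, clinical)
    survivors = surv.filter_by_p(cox, alpha=cfg["cox_alpha"])
    genes, probe_gene_table, _ = surv.map_to_genes(survivors["probe_id"], annotation)
    universe = annotation.all_genes()
    enrichment = surv.enrich(genes, gene_sets, universe,
                             method=cfg["enrich_method"], alpha=cfg["enrich_p"],
                             min_overlap=cfg["min_overlap"])
    n_enriched_pre = int(enrichment["enriched"].sum())
    enrichment_kept = surv.apply_term_blacklist(enrichment, cfg["blacklist"])
    frequency = surv.gene_frequency_rank(enrichment_kept)
    final_genes, final_probes = surv.select_final_genes(
        frequency, probe_gene_table, top_k=cfg["top_k"])
    _write(cox, outdir / "cox.tsv")
    _write(enrichment_kept, outdir / "enrichment.tsv")
    _write(frequency, outdir / "gene_frequency.tsv")
    _write(final_probes, outdir / "final_candidates.tsv")
    report.timings_s["validation"] = round(time.perf_counter() - t0, 3)
    report.counts.update(
        cox_tested=len(cox),
        cox_significant=len(survivors),
        genes_mapped=len(genes),
        enriched_terms=n_enriched_pre,
        enriched_terms_after_blacklist=int(enrichment_kept["enriched"].sum()),
        final_genes=len(final_genes),
        final_probes=len(final_probes),
    )
    report.final_genes = list(final_genes)

    # ---- step 3: threshold search ----------------------------------------
    t0 = time.perf_counter()
    threshold_rows = []
    km_tables = []
    for probe in final_probes["probe_id"].drop_duplicates():
        beta = cand_matrix.data.loc[probe]
        beta.index = cand_matrix.sample_ids
        result = thr.threshold_scan(beta, clinical,
                                    min_group_frac=cfg["min_group_frac"],
                                    min_group_abs=cfg["min_group_abs"],
                                    probe_id=probe)
        row = {
            "probe_id": probe,
            "threshold": result.threshold,
            "n_low": result.n_low,
            "n_high": result.n_high,
            "deaths_low": result.deaths_low,
            "deaths_high": result.deaths_high,
            "logrank_chi2": result.logrank_chi2,
            "logrank_p": result.logrank_p,
            "n_excluded_missing": result.n_excluded_missing,
        }
        if cfg["permutations"]:
            row["adjusted_p"] = thr.permutation_adjusted_p(
                beta, clinical, result, n_permutations=int(cfg["permutations"]),
                seed=int(cfg["seed"]))
        threshold_rows.append(row)
        _, _, km_table = thr.km_plot_table(result, clinical, beta)
        km_tables.append(km_table)
    thresholds = pd.DataFrame(threshold_rows)
    _write(thresholds, outdir / "thresholds.tsv")
    if km_tables:
        _write(pd.concat(km_tables, ignore_index=True), outdir / "km_curves.tsv")
    report.timings_s["threshold"] = round(time.perf_counter() - t0, 3)
    report.counts["thresholds"] = len(thresholds)
    report.thresholds = threshold_rows
    report.timings_s["total"] = round(time.perf_counter() - t_start, 3)

    for path in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.gmt")):
        report.files[path.name] = _sha256(path)
    (outdir / "report.json").write_text(report.to_json())
    return report


def summarize(report: RunReport) -> str:
    """Human-readable funnel summary of a run report."""
    c = report.counts
    lines = [
        f"methmark {report.version} (seed {report.seed})",
        "",
        "stage funnel:",
        f"  probes tested          {c.get('probes_tested', 0):>8}",
        f"  FDR-significant        {c.get('fdr_significant', 0):>8}",
        f"  candidates             {c.get('candidates', 0):>8}",
        f"  Cox-significant        {c.get('cox_significant', 0):>8}",
        f"  genes mapped           {c.get('genes_mapped', 0):>8}",
        f"  enriched terms (kept)  {c.get('enriched_terms_after_blacklist', 0):>8}",
        f"  final genes            {c.get('final_genes', 0):>8}",
        f"  final probes           {c.get('final_probes', 0):>8}",
        "",
    ]
    if report.thresholds:
        lines.append("thresholds:")
        for row in report.thresholds:
            lines.append(
                f"  {row['probe_id']}: cut {row['threshold']:.4g}  "
                f"low n={row['n_low']} deaths={row['deaths_low']}  "
                f"high n={row['n_high']} deaths={row['deaths_high']}  "
                f"log-rank p={row['logrank_p']:.3g}"
            )
    else:
        lines.append("thresholds: none (empty final set)")
    return "\n".join(lines)
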