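"""Step 2: survival screening and gene-set over-representation.

Each candidate probe is screened with a univariate Cox proportional-
hazards model (continuous beta as the sole covariate, Breslow tie
handling, Wald p); survivors of the 1% filter are mapped to genes and
tested for over-representation in user-supplied gene sets with the
hypergeometric upper tail (or DAVID's EASE variant).  Genes are then
ranked by how many enriched terms contain them and the top-k genes,
with their probes, become the final biomarker candidates.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy.stats import hypergeom

from .io import BetaMatrix, ClinicalTable, GeneSetCollection, ProbeAnnotation, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "cox_screen",
    "filter_by_p",
    "map_to_genes",
    "enrich",
    "apply_term_blacklist",
    "gene_frequency_rank",
    "select_final_genes",
]

FLAG_OK = ""
FLAG_DEGENERATE = "degenerate: constant covariate"
FLAG_NO_CONVERGE = "non-convergent fit"


def cox_screen(matrix: BetaMatrix, clinical: ClinicalTable) -> pd.DataFrame:
    """Univariate Cox fit per probe against the survival endpoint.

    Matrix columns are matched to clinical patient ids (the
    intersection is used; mismatches are logged).  Per probe, samples
    missing that probe's beta are dropped.  Returns one row per probe:
    probe_id, n_used, n_events, log_hazard_ratio (per unit beta),
    standard_error, wald_p, flag.  Constant covariates are flagged with
    p = 1 by convention; non-convergent fits are flagged and carry NaN
    estimates.
    """
    shared = [s for s in matrix.sample_ids if s in clinical.data.index]
    if not shared:
        raise ValidationError("no overlap between matrix samples and clinical patients")
    if len(shared) < matrix.n_samples:
        logger.warning("cox screen: %d samples lack clinical data",
                       matrix.n_samples - len(shared))
    sub = matrix.data[shared]
    clin = clinical.data.loc[shared, ["time", "event"]].astype(float)

    rows = []
    for probe_id, betas in sub.iterrows():
        ok = betas.notna()
        n_used = int(ok.sum())
        frame = clin[ok.to_numpy()].copy()
        n_events = int(frame["event"].sum())
        x = betas[ok].to_numpy(dtype=float)
        if n_used < 2 or np.ptp(x) == 0.0:
            rows.append((probe_id, n_used, n_events, np.nan, np.nan, 1.0, FLAG_DEGENERATE))
            continue
        frame["beta"] = x
        try:
            cph = CoxPHFitter()
            cph.fit(frame, duration_col="time", event_col="event")
            rows.append((
                probe_id, n_used, n_events,
                float(cph.params_["beta"]),
                float(cph.standard_errors_["beta"]),
                float(cph.summary.loc["beta", "p"]),
                FLAG_OK,
            ))
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("cox screen: probe %s did not converge (%s)", probe_id, exc)
            rows.append((probe_id, n_used, n_events, np.nan, np.nan, np.nan, FLAG_NO_CONVERGE))
    return pd.DataFrame(
        rows,
        columns=["probe_id", "n_used", "n_events", "log_hazard_ratio",
                 "standard_error", "wald_p", "flag"],
    )


def filter_by_p(records: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Keep unflagged probes with Wald p strictly below ``alpha``, sorted by p."""
    mask = (records["flag"] == FLAG_OK) & (records["wald_p"] < alpha)
    out = records[mask].sort_values(["wald_p", "probe_id"], kind="mergesort")
    return out.reset_index(drop=True)


def map_to_genes(
    probes: Sequence[str], annotation: ProbeAnnotation
) -> tuple[list[str], pd.DataFrame, list[str]]:
    """Map probes to gene symbols via the annotation.

    Returns (sorted unique gene symbols, probe->gene long table,
    probes with no annotated gene).
    """
    rows = []
    unmapped = []
    for probe in probes:
        genes = annotation.genes_for(probe)
        if not genes:
            unmapped.append(probe)
            continue
        rows.extend((probe, g) for g in genes)
    table = pd.DataFrame(rows, columns=["probe_id", "gene"])
    genes = sorted(table["gene"].unique()) if len(table) else []
    if unmapped:
        logger.info("map_to_genes: %d probes without a gene", len(unmapped))
    return genes, table, unmapped


def enrich(
    query_genes: Iterable[str],
    sets: GeneSetCollection,
    universe_genes: Iterable[str],
    method: str = "hypergeometric",
    alpha: float = 0.05,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """Over-representation of the query in each gene set.

    The p-value is the hypergeometric upper tail P(X >= overlap) with
    population = |universe|, successes = |set ∩ universe| and draws =
    |query|; ``method="ease"`` applies DAVID's EASE penalty (the overlap
    is reduced by one before taking the tail).  A term is flagged
    ``enriched`` when p < alpha and overlap >= ``min_overlap``.  Query
    genes outside the universe are dropped with a warning; sets are
    intersected with the universe.
    """
    universe = set(universe_genes)
    if not universe:
        raise ValidationError("enrichment universe is empty")
    if method not in ("hypergeometric", "ease"):
        raise ValidationError(f"unknown enrichment method {method!r}")
    query = set(query_genes)
    outside = query - universe
    if outside:
        logger.warning("enrich: %d query genes outside the universe dropped", len(outside))
        query &= universe

    N, n = len(universe), len(query)
    rows = []
    for gs in sets:
        members = gs.genes & universe
        if not members:
            continue
        overlap = sorted(query & members)
        k = len(overlap)
        shift = 1 if method == "hypergeometric" else 2
        p = float(hypergeom.sf(k - shift, N, len(members), n)) if k else 1.0
        p = min(p, 1.0)
        rows.append((
            gs.term_id, gs.term_name, k, len(members), n, N, p,
            bool(p < alpha and k >= min_overlap), tuple(overlap),
        ))
    out = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "overlap", "set_size", "query_size",
                 "universe_size", "p_value", "enriched", "genes"],
    )
    return out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)


def apply_term_blacklist(records: pd.DataFrame, blacklist: Iterable[str]) -> pd.DataFrame:
    """Drop blacklisted term ids (e.g. processes ubiquitous across cell
    types that a user has chosen to exclude); ids not present are a
    warning, not an error."""
    blacklist = set(blacklist)
    absent = blacklist - set(records["term_id"])
    if absent:
        logger.warning("blacklist ids not in enrichment results: %s", sorted(absent))
    removed = int(records["term_id"].isin(blacklist).sum())
    if removed:
        logger.info("blacklist removed %d terms", removed)
    return records[~records["term_id"].isin(blacklist)].reset_index(drop=True)


def gene_frequency_rank(records: pd.DataFrame) -> pd.DataFrame:
    """Rank genes by how many enriched terms contain them.

    Input rows must carry ``term_id`` and a ``genes`` tuple (only rows
    flagged ``enriched`` are counted when the column is present).
    Output: gene, count, term_ids — sorted by count descending, then
    gene symbol.
    """
    rows = records[records["enriched"]] if "enriched" in records.columns else records
    counts: dict[str, list[str]] = {}
    for row in rows.itertuples(index=False):
        for gene in row.genes:
            counts.setdefault(gene, []).append(row.term_id)
    table = pd.DataFrame(
        [(g, len(t), tuple(sorted(t))) for g, t in counts.items()],
        columns=["gene", "count", "term_ids"],
    )
    table = table.sort_values(["count", "gene"], ascending=[False, True],
                              kind="mergesort")
    return table.reset_index(drop=True)


def select_final_genes(
    frequency: pd.DataFrame,
    probe_gene_table: pd.DataFrame,
    top_k: int = 3,
) -> tuple[list[str], pd.DataFrame]:
    """Top-k genes by enriched-term frequency, with their candidate probes.

    Ties at the cut are broken lexicographically (already encoded in the
    frequency ordering) and logged.  ``probe_gene_table`` is the long
    probe->gene table of the surviving candidates; the returned probe
    table keeps only probes mapping to a selected gene.
    """
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    chosen = frequency.head(top_k)
    if len(frequency) > top_k and len(chosen) and \
            frequency.iloc[top_k]["count"] == chosen.iloc[-1]["count"]:
        logger.warning("gene frequency tie at rank %d broken lexicographically", top_k)
    genes = chosen["gene"].tolist()
    probes = probe_gene_table[probe_gene_table["gene"].isin(genes)]
    probes = probes.sort_values(["gene", "probe_id"], kind="mergesort").reset_index(drop=True)
    return genes, probes
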