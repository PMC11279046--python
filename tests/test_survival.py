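import math

import numpy as np
import pandas as pd
import pytest

from methmark.io import (
    BetaMatrix,
    GeneSet,
    GeneSetCollection,
    ProbeAnnotation,
    ValidationError,
)
from methmark.survival import (
    FLAG_DEGENERATE,
    apply_term_blacklist,
    cox_screen,
    enrich,
    filter_by_p,
    gene_frequency_rank,
    map_to_genes,
    select_final_genes,
)

from conftest import bp_enrichment_records, make_clinical


# ---------------------------------------------------------------------------
# Cox screen
# ---------------------------------------------------------------------------

def _survival_data(rng, n, hazard):
    death = rng.exponential(1.0 / hazard)
    censor = rng.uniform(0, 2000, size=n)
    return np.minimum(death, censor), (death <= censor).astype(int)


def test_cox_detects_binary_like_risk_covariate():
    """Beta 0.1 vs 0.9 groups with a 3x hazard ratio, n=300: the screen
    should find a positive log-HR at p < 0.01 in every one of a few
    seeded replicates (a scaled-down power check)."""
    for seed in range(5):
        rng = np.random.default_rng(seed)
        n = 300
        beta = np.repeat([0.1, 0.9], n // 2)
        hazard = np.where(beta > 0.5, 3e-3, 1e-3)
        time, event = _survival_data(rng, n, hazard)
        patients = [f"V{i}" for i in range(n)]
        matrix = BetaMatrix(pd.DataFrame([beta], index=["cgX"], columns=patients))
        clinical = make_clinical(time, event, patients)
        rec = cox_screen(matrix, clinical).iloc[0]
        assert rec["log_hazard_ratio"] > 0
        assert rec["wald_p"] < 0.01


def test_cox_constant_covariate_flagged():
    n = 40
    rng = np.random.default_rng(1)
    time, event = _survival_data(rng, n, 1e-3)
    patients = [f"V{i}" for i in range(n)]
    matrix = BetaMatrix(pd.DataFrame([[0.5] * n], index=["cgX"], columns=patients))
    rec = cox_screen(matrix, make_clinical(time, event, patients)).iloc[0]
    assert rec["flag"] == FLAG_DEGENERATE
    assert rec["wald_p"] == 1.0


def test_cox_counts_events_and_samples():
    rng = np.random.default_rng(2)
    n = 50
    time, event = _survival_data(rng, n, 1e-3)
    beta = rng.uniform(0, 1, n)
    beta[:5] = np.nan  # per-probe complete-case
    patients = [f"V{i}" for i in range(n)]
    matrix = BetaMatrix(pd.DataFrame([beta], index=["cgX"], columns=patients))
    rec = cox_screen(matrix, make_clinical(time, event, patients)).iloc[0]
    assert rec["n_used"] == n - 5
    assert rec["n_events"] == int(event[5:].sum())
    assert rec["n_events"] <= rec["n_used"]


def test_filter_by_p_threshold_and_flags():
    records = pd.DataFrame({
        "probe_id": ["a", "b", "c"],
        "wald_p": [0.009, 0.011, 0.001],
        "flag": ["", "", FLAG_DEGENERATE],
    })
    kept = filter_by_p(records, alpha=0.01)
    assert kept["probe_id"].tolist() == ["a"]


# ---------------------------------------------------------------------------
# gene mapping
# ---------------------------------------------------------------------------

def _annotation(mapping):
    return ProbeAnnotation(pd.DataFrame(
        {"gene_symbols": list(mapping.values()),
         "chromosome": ["1"] * len(mapping),
         "position": np.arange(1, len(mapping) + 1, dtype=float)},
        index=pd.Index(list(mapping), name="probe_id"),
    ))


def test_two_probes_one_gene():
    ann = _annotation({"cg11304234": ("IL18",), "cg26534425": ("IL18",)})
    genes, table, unmapped = map_to_genes(["cg11304234", "cg26534425"], ann)
    assert genes == ["IL18"]
    assert len(table) == 2
    assert unmapped == []


def test_multi_gene_probe_and_unmapped():
    ann = _annotation({"cgA": ("G1", "G2"), "cgB": ()})
    genes, table, unmapped = map_to_genes(["cgA", "cgB", "cgC"], ann)
    assert genes == ["G1", "G2"]
    assert unmapped == ["cgB", "cgC"]


def test_all_unmapped():
    ann = _annotation({"cgA": ()})
    genes, table, unmapped = map_to_genes(["cgA"], ann)
    assert genes == [] and len(table) == 0 and unmapped == ["cgA"]


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def _collection(sets):
    return GeneSetCollection({tid: GeneSet(tid, tid, frozenset(genes))
                              for tid, genes in sets.items()})


def test_hypergeometric_worked_example():
    """Universe 20, set 5, query 5, overlap 4:
    p = [C(5,4)C(15,1) + C(5,5)C(15,0)] / C(20,5)."""
    universe = [f"g{i}" for i in range(20)]
    sets = _collection({"T": universe[:5]})
    query = universe[1:5] + [universe[10]]  # overlap 4
    rec = enrich(query, sets, universe).iloc[0]
    expected = (math.comb(5, 4) * math.comb(15, 1) + math.comb(5, 5)) / math.comb(20, 5)
    assert rec["overlap"] == 4
    assert rec["p_value"] == pytest.approx(expected, rel=1e-12)
    assert rec["p_value"] == pytest.approx(0.00490, abs=5e-5)


def test_zero_overlap_p_is_one():
    universe = [f"g{i}" for i in range(20)]
    sets = _collection({"T": universe[:5]})
    rec = enrich(universe[10:12], sets, universe).iloc[0]
    assert rec["p_value"] == 1.0
    assert not rec["enriched"]


def test_ease_penalizes_overlap():
    universe = [f"g{i}" for i in range(30)]
    sets = _collection({"T": universe[:6]})
    query = universe[:4] + universe[20:22]
    p_hyper = enrich(query, sets, universe, method="hypergeometric").iloc[0]["p_value"]
    p_ease = enrich(query, sets, universe, method="ease").iloc[0]["p_value"]
    assert p_ease > p_hyper


def brute_force_tail(N, K, n, k):
    """Exhaustive hypergeometric upper tail P(X >= k)."""
    total = math.comb(N, n)
    return sum(math.comb(K, x) * math.comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / total


def test_enrich_matches_enumeration_small_universes():
    rng = np.random.default_rng(8)
    for _ in range(60):
        N = int(rng.integers(4, 26))
        universe = [f"g{i}" for i in range(N)]
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        members = list(rng.choice(universe, size=K, replace=False))
        query = list(rng.choice(universe, size=n, replace=False))
        rec = enrich(query, _collection({"T": members}), universe,
                     min_overlap=0).iloc[0]
        k = len(set(members) & set(query))
        expected = brute_force_tail(N, K, n, k) if k else 1.0
        assert rec["p_value"] == pytest.approx(expected, rel=1e-10)


def test_query_outside_universe_dropped():
    universe = [f"g{i}" for i in range(10)]
    sets = _collection({"T": universe[:4]})
    rec = enrich(universe[:3] + ["alien"], sets, universe).iloc[0]
    assert rec["query_size"] == 3


def test_empty_universe_is_error():
    with pytest.raises(ValidationError):
        enrich(["a"], _collection({"T": ["a"]}), [])


def test_enrich_invariant_to_input_order():
    rng = np.random.default_rng(3)
    universe = [f"g{i}" for i in range(40)]
    sets = _collection({"A": universe[:10], "B": universe[5:20]})
    query = universe[2:12]
    a = enrich(query, sets, universe)
    b = enrich(list(reversed(query)), sets, list(reversed(universe)))
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# blacklist, frequency ranking, final selection
# ---------------------------------------------------------------------------

def test_blacklist_19_minus_5_leaves_14():
    records = pd.DataFrame({
        "term_id": [f"T{i}" for i in range(19)],
        "genes": [("G",)] * 19,
        "enriched": [True] * 19,
    })
    kept = apply_term_blacklist(records, [f"T{i}" for i in range(5)])
    assert len(kept) == 14


def test_blacklist_empty_and_absent_ids():
    records = pd.DataFrame({"term_id": ["T1"], "genes": [("G",)], "enriched": [True]})
    pd.testing.assert_frame_equal(apply_term_blacklist(records, []), records)
    kept = apply_term_blacklist(records, ["NOPE"])
    assert len(kept) == 1


def test_gene_frequency_on_published_term_table():
    """The 14-term worked example ranks PRKCZ (7), PTK2 (6), IL18 (4) on top."""
    freq = gene_frequency_rank(bp_enrichment_records())
    top = freq.set_index("gene")["count"]
    assert top["PRKCZ"] == 7
    assert top["PTK2"] == 6
    assert top["IL18"] == 4
    assert freq["gene"].tolist()[:3] == ["PRKCZ", "PTK2", "IL18"]
    # conservation: counts sum to total gene-list length over terms
    total = sum(len(row.genes) for row in bp_enrichment_records().itertuples())
    assert freq["count"].sum() == total


def test_gene_frequency_counts_match_contributing_terms():
    records = pd.DataFrame({
        "term_id": ["T1", "T2"],
        "genes": [("A", "B"), ("A",)],
        "enriched": [True, True],
    })
    freq = gene_frequency_rank(records)
    assert freq.iloc[0]["gene"] == "A" and freq.iloc[0]["count"] == 2
    assert freq.iloc[0]["term_ids"] == ("T1", "T2")
    assert freq.iloc[1]["gene"] == "B" and freq.iloc[1]["count"] == 1


def test_select_final_genes_worked_example():
    freq = gene_frequency_rank(bp_enrichment_records())
    probe_gene = pd.DataFrame({
        "probe_id": ["cg16269144", "cg16624272", "cg11304234", "cg26534425"],
        "gene": ["PRKCZ", "PTK2", "IL18", "IL18"],
    })
    genes, probes = select_final_genes(freq, probe_gene, top_k=3)
    assert genes == ["PRKCZ", "PTK2", "IL18"]
    assert sorted(probes["probe_id"]) == sorted(
        ["cg16269144", "cg16624272", "cg11304234", "cg26534425"])


def test_select_final_genes_top_k_larger_than_table():
    freq = pd.DataFrame({"gene": ["A", "B"], "count": [2, 1],
                         "term_ids": [("T1", "T2"), ("T1",)]})
    genes, _ = select_final_genes(freq, pd.DataFrame(columns=["probe_id", "gene"]),
                                  top_k=10)
    assert genes == ["A", "B"]


def test_select_final_genes_tie_is_lexicographic(caplog):
    freq = gene_frequency_rank(pd.DataFrame({
        "term_id": ["T1"], "genes": [("B", "A", "C")], "enriched": [True]}))
    genes, _ = select_final_genes(freq, pd.DataFrame(columns=["probe_id", "gene"]),
                                  top_k=2)
    assert genes == ["A", "B"]
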