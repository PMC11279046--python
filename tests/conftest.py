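import numpy as np
import pandas as pd
import pytest

from methmark.io import BetaMatrix, ClinicalTable, MatchedPairSet
from methmark.simulate import (
    SimulationConfig,
    simulate_gene_universe,
    simulate_matched_cohort,
    simulate_validation_cohort,
)


def make_pair_set(normal: np.ndarray, tumor: np.ndarray,
                  probe_ids=None) -> MatchedPairSet:
    """Build a MatchedPairSet from probes x patients arrays."""
    normal = np.atleast_2d(np.asarray(normal, dtype=float))
    tumor = np.atleast_2d(np.asarray(tumor, dtype=float))
    n_probes, n_pairs = normal.shape
    probes = probe_ids or [f"cg{i:05d}" for i in range(n_probes)]
    patients = tuple(f"P{i}" for i in range(n_pairs))
    nid = [f"{p}-N" for p in patients]
    tid = [f"{p}-T" for p in patients]
    return MatchedPairSet(
        patient_ids=patients,
        normal=BetaMatrix(pd.DataFrame(normal, index=probes, columns=nid)),
        tumor=BetaMatrix(pd.DataFrame(tumor, index=probes, columns=tid)),
        pairing={p: (a, b) for p, a, b in zip(patients, nid, tid)},
    )


def make_clinical(times, events, patient_ids=None) -> ClinicalTable:
    times = np.asarray(times, dtype=float)
    patients = patient_ids or [f"V{i:03d}" for i in range(times.size)]
    return ClinicalTable(pd.DataFrame(
        {"event": np.asarray(events, dtype=int), "time": times},
        index=pd.Index(patients, name="patient_id"),
    ))


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A scaled-down synthetic world for fast end-to-end tests."""
    return SimulationConfig(
        n_pairs=10, n_validation=200, n_probes=400,
        n_separated_hyper=8, n_separated_hypo=8,
        n_prognostic=3, planted_cutpoints=(0.7, 0.3, 0.35),
        planted_risk_high=(False, True, True),
        n_prognostic_genes=2, n_genes=300, n_gene_sets=30, n_enriched_sets=3,
        baseline_hazard=5e-5,  # fewer markers than the default world: keep
        seed=7,                # the event fraction comparable
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    pairs, truth = simulate_matched_cohort(small_config)
    validation, clinical = simulate_validation_cohort(small_config, truth)
    annotation, gene_sets = simulate_gene_universe(small_config, truth)
    return dict(config=small_config, pairs=pairs, truth=truth,
                validation=validation, clinical=clinical,
                annotation=annotation, gene_sets=gene_sets)


# The published enrichment table used as a worked example for the
# gene-frequency ranking: 14 biological-process terms with their member
# genes from the screen's survivor list.
BP_TABLE = [
    ("GO:0010744", "positive regulation of macrophage-derived foam cell differentiation",
     ("PRKCH", "IL18", "NFKB1")),
    ("GO:0031032", "actomyosin structure organization",
     ("EPB41L1", "CDC42BPG", "MYO18A")),
    ("GO:0030010", "establishment of cell polarity", ("PRKCZ", "PTK2", "MARK2")),
    ("GO:0030036", "actin cytoskeleton organization",
     ("CAPZB", "PTK7", "CDC42BPG", "FHL3", "ANTXR1")),
    ("GO:0035556", "intracellular signal transduction",
     ("PRKCH", "ASB13", "TGFA", "PRKCZ", "MARK2", "MAP4K4")),
    ("GO:0030155", "regulation of cell adhesion", ("IL18", "CYTH1", "PTK2")),
    ("GO:0060463", "lung lobe morphogenesis", ("LIF", "GRHL2")),
    ("GO:0045630", "positive regulation of T-helper 2 cell differentiation",
     ("IL18", "PRKCZ")),
    ("GO:0008284", "positive regulation of cell proliferation",
     ("LIF", "GCNT2", "TGFA", "PRKCZ", "PTK2", "TRPM4")),
    ("GO:0043066", "negative regulation of apoptotic process",
     ("MYO18A", "PRKCZ", "PTK2", "NFKB1", "LIMS2", "MAP4K4")),
    ("GO:0090179", "planar cell polarity pathway involved in neural tube closure",
     ("PTK7", "GRHL3")),
    ("GO:0007179", "transforming growth factor beta receptor signaling pathway",
     ("ZMIZ1", "GCNT2", "PTK2")),
    ("GO:0016477", "cell migration", ("PTK7", "MYO18A", "PRKCZ", "PTK2")),
    ("GO:0032736", "positive regulation of interleukin-13 production",
     ("IL18", "PRKCZ")),
]


def bp_enrichment_records() -> pd.DataFrame:
    """The worked-example table in the shape gene_frequency_rank expects."""
    return pd.DataFrame(
        [(tid, name, len(genes), len(genes), 78, 500, 0.01, True, genes)
         for tid, name, genes in BP_TABLE],
        columns=["term_id", "term_name", "overlap", "set_size", "query_size",
                 "universe_size", "p_value", "enriched", "genes"],
    )
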