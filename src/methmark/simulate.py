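"""Synthetic matched-cohort and validation-cohort generator.

Emulates the data the three-step biomarker pipeline consumes: a small
discovery cohort of matched tumor/adjacent-normal beta-value pairs, a
larger independent tumor-only validation cohort with right-censored
survival, and a probe/gene annotation universe with one or more planted
over-represented gene sets.

Null probes draw both tissues from the same per-probe Beta distribution
and add a shared per-patient shift on the logit scale, so pairs are
correlated while tumor-normal differences stay centered at zero.
Planted differential probes draw normal and tumor values from disjoint
intervals separated by at least ``separation_gap``, which makes the
complete-separation effect-size filter succeed by construction.  A
subset of planted probes is prognostic: in the validation cohort the
event hazard is multiplied by ``exp(planted_log_hr)`` whenever the
probe's beta lies on the risky side of its planted cutpoint.

All randomness flows from one root seed through named
:class:`numpy.random.SeedSequence` children, in this fixed order:
probe parameters, matched cohort, validation cohort, gene universe.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import (
    BetaMatrix,
    ClinicalTable,
    GeneSet,
    GeneSetCollection,
    MatchedPairSet,
    ProbeAnnotation,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "PlantedProbe",
    "SyntheticTruth",
    "simulate_matched_cohort",
    "simulate_validation_cohort",
    "simulate_gene_universe",
    "write_truth",
    "read_truth",
]

# margin kept between planted intervals and the (0, 1) boundary
_EDGE = 0.02


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic world.

    Defaults mirror the study design the pipeline targets: 10 matched
    discovery pairs, 275 independent validation tumors, four prognostic
    CpGs on three genes with cutpoints 0.74 / 0.14 / 0.29 / 0.321, and
    an event-time scale giving deaths around one year.
    """

    n_pairs: int = 10
    n_validation: int = 275
    n_probes: int = 2000
    n_separated_hyper: int = 20
    n_separated_hypo: int = 20
    n_prognostic: int = 4
    separation_gap: float = 0.2
    patient_effect_sd: float = 0.4
    baseline_hazard: float = 1e-5
    planted_log_hr: float = 1.5
    planted_cutpoints: tuple[float, ...] = (0.74, 0.14, 0.29, 0.321)
    planted_risk_high: tuple[bool, ...] = (False, True, True, True)
    censor_time_max: float = 1200.0
    # gene universe
    n_genes: int = 500
    n_prognostic_genes: int = 3
    n_gene_sets: int = 50
    n_enriched_sets: int = 3
    gene_set_size_range: tuple[int, int] = (5, 30)
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 2:
            raise ValidationError("n_pairs must be >= 2")
        n_planted = self.n_separated_hyper + self.n_separated_hypo
        if min(self.n_separated_hyper, self.n_separated_hypo, self.n_prognostic) < 0:
            raise ValidationError("planted counts must be >= 0")
        if n_planted > self.n_probes:
            raise ValidationError("more planted probes than probes")
        if self.n_prognostic > n_planted:
            raise ValidationError("prognostic probes must be a subset of separated probes")
        if not 0 < self.separation_gap < 1:
            raise ValidationError("separation_gap must be in (0, 1)")
        if len(self.planted_cutpoints) != self.n_prognostic:
            raise ValidationError("need one cutpoint per prognostic probe")
        if len(self.planted_risk_high) != self.n_prognostic:
            raise ValidationError("need one risk side per prognostic probe")
        if any(not 0 < c < 1 for c in self.planted_cutpoints):
            raise ValidationError("cutpoints must be in (0, 1)")
        if self.censor_time_max < 0 or self.baseline_hazard <= 0:
            raise ValidationError("hazard must be positive, censoring horizon non-negative")
        if self.n_prognostic and not 1 <= self.n_prognostic_genes <= self.n_prognostic:
            raise ValidationError("n_prognostic_genes must be in [1, n_prognostic]")


@dataclass(frozen=True)
class PlantedProbe:
    probe_id: str
    direction: str                 # "hyper" or "hypo" (tumor vs normal)
    normal_low: float
    normal_high: float
    tumor_low: float
    tumor_high: float
    is_prognostic: bool
    cutpoint: float | None = None
    log_hr: float | None = None
    risk_high: bool | None = None  # True: beta > cutpoint is the risk group


@dataclass
class SyntheticTruth:
    """Planted-marker ledger for recovery testing."""

    planted: list[PlantedProbe]
    seed: int
    config: SimulationConfig
    prognostic_genes: tuple[str, ...] = ()
    enriched_term_ids: tuple[str, ...] = ()
    probe_gene_map: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def planted_ids(self) -> list[str]:
        return [p.probe_id for p in self.planted]

    @property
    def prognostic(self) -> list[PlantedProbe]:
        return [p for p in self.planted if p.is_prognostic]


def _streams(config: SimulationConfig) -> list[np.random.SeedSequence]:
    """Fixed stream order: probe params, matched, validation, genes."""
    return np.random.SeedSequence(config.seed).spawn(4)


def _probe_baselines(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe Beta(a, b) baselines shared by both cohorts.

    Means uniform on [0.15, 0.85] and concentrations on [20, 100]:
    unimodal, moderately dispersed probes for which the paired t test's
    normality assumption is reasonable.
    """
    rng = np.random.default_rng(_streams(config)[0])
    mean = rng.uniform(0.15, 0.85, size=config.n_probes)
    conc = rng.uniform(20.0, 100.0, size=config.n_probes)
    return mean * conc, (1.0 - mean) * conc


def _planted_layout(config: SimulationConfig) -> list[PlantedProbe]:
    """Deterministic interval layout for planted probes (ids assigned later).

    Prognostic probes get tumor intervals centered on their cutpoint so
    the validation betas straddle it; the discovery direction is chosen
    to leave room for the disjoint normal interval (tumor-high = hyper
    for cutpoints >= 0.5, tumor-low = hypo otherwise).
    """
    gap = config.separation_gap
    probes: list[PlantedProbe] = []

    directions = (["hyper"] * config.n_separated_hyper
                  + ["hypo"] * config.n_separated_hypo)
    # carve out prognostic slots by required direction
    prognostic: list[tuple[float, bool, str]] = []
    for cut, risk_high in zip(config.planted_cutpoints, config.planted_risk_high):
        direction = "hyper" if cut >= 0.5 else "hypo"
        prognostic.append((cut, risk_high, direction))
        try:
            directions.remove(direction)
        except ValueError:
            raise ValidationError(
                f"not enough separated probes of direction {direction!r} for "
                f"cutpoint {cut}"
            ) from None

    for cut, risk_high, direction in prognostic:
        if direction == "hyper":
            half = min(0.2, cut - _EDGE, (1 - _EDGE) - cut, cut - (gap + 2 * _EDGE))
        else:
            half = min(0.2, cut - _EDGE, (1 - _EDGE) - cut, (1 - gap - 2 * _EDGE) - cut)
        if half < _EDGE:
            raise ValidationError(
                f"separation gap {gap} leaves no room for a tumor interval "
                f"around cutpoint {cut}"
            )
        t_lo, t_hi = cut - half, cut + half
        if direction == "hyper":
            n_lo, n_hi = _EDGE, t_lo - gap
        else:
            n_lo, n_hi = t_hi + gap, 1 - _EDGE
        probes.append(PlantedProbe(
            probe_id="", direction=direction,
            normal_low=n_lo, normal_high=n_hi, tumor_low=t_lo, tumor_high=t_hi,
            is_prognostic=True, cutpoint=cut, log_hr=config.planted_log_hr,
            risk_high=risk_high,
        ))

    for direction in directions:
        lo_band = (_EDGE + 0.03, 0.30)           # interval away from the cutoff side
        hi_band = (lo_band[1] + gap, min(1 - _EDGE, lo_band[1] + gap + 0.35))
        if hi_band[0] >= hi_band[1]:
            raise ValidationError(f"separation gap {gap} too large for planted intervals")
        if direction == "hyper":
            n_lo, n_hi = lo_band
            t_lo, t_hi = hi_band
        else:
            t_lo, t_hi = lo_band
            n_lo, n_hi = hi_band
        probes.append(PlantedProbe(
            probe_id="", direction=direction,
            normal_low=n_lo, normal_high=n_hi, tumor_low=t_lo, tumor_high=t_hi,
            is_prognostic=False,
        ))
    return probes


def _probe_ids(n: int) -> list[str]:
    return [f"cg{i:07d}" for i in range(n)]


def simulate_matched_cohort(config: SimulationConfig) -> tuple[MatchedPairSet, SyntheticTruth]:
    """Generate the matched tumor/normal discovery cohort plus truth ledger."""
    config.validate()
    a, b = _probe_baselines(config)
    rng = np.random.default_rng(_streams(config)[1])
    n_probes, n_pairs = config.n_probes, config.n_pairs

    layout = _planted_layout(config)
    planted_idx = rng.choice(n_probes, size=len(layout), replace=False)
    probe_ids = _probe_ids(n_probes)
    planted = [dataclasses.replace(p, probe_id=probe_ids[i])
               for p, i in zip(layout, planted_idx)]

    # null model: shared per-patient logit shift on top of per-probe Beta draws
    u = rng.normal(0.0, config.patient_effect_sd, size=n_pairs)
    normal = expit(logit(rng.beta(a[:, None], b[:, None], size=(n_probes, n_pairs))) + u)
    tumor = expit(logit(rng.beta(a[:, None], b[:, None], size=(n_probes, n_pairs))) + u)

    for probe, i in zip(planted, planted_idx):
        normal[i] = rng.uniform(probe.normal_low, probe.normal_high, size=n_pairs)
        tumor[i] = rng.uniform(probe.tumor_low, probe.tumor_high, size=n_pairs)

    # re-verify planted separation after generation
    for probe, i in zip(planted, planted_idx):
        if probe.direction == "hyper":
            assert tumor[i].min() > normal[i].max()
        else:
            assert tumor[i].max() < normal[i].min()

    patients = tuple(f"P{i:03d}" for i in range(n_pairs))
    normal_ids = [f"{p}-N" for p in patients]
    tumor_ids = [f"{p}-T" for p in patients]
    pairs = MatchedPairSet(
        patient_ids=patients,
        normal=BetaMatrix(pd.DataFrame(normal, index=probe_ids, columns=normal_ids)),
        tumor=BetaMatrix(pd.DataFrame(tumor, index=probe_ids, columns=tumor_ids)),
        pairing={p: (n, t) for p, n, t in zip(patients, normal_ids, tumor_ids)},
    )
    truth = SyntheticTruth(planted=planted, seed=config.seed, config=config)
    return pairs, truth


def simulate_validation_cohort(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[BetaMatrix, ClinicalTable]:
    """Generate the independent tumor-only cohort with survival endpoints.

    Event times are exponential with per-patient hazard
    ``baseline_hazard * exp(sum of planted log-HRs whose risk indicator
    fires)``; censoring is the minimum of the administrative horizon
    ``censor_time_max`` and a uniform draw on (0, 2 * censor_time_max).
    """
    config.validate()
    a, b = _probe_baselines(config)
    rng = np.random.default_rng(_streams(config)[2])
    n_probes, n = config.n_probes, config.n_validation
    probe_ids = _probe_ids(n_probes)
    index = pd.Index(probe_ids)

    u = rng.normal(0.0, config.patient_effect_sd, size=n)
    betas = expit(logit(rng.beta(a[:, None], b[:, None], size=(n_probes, n))) + u)
    for probe in truth.planted:
        i = index.get_loc(probe.probe_id)
        betas[i] = rng.uniform(probe.tumor_low, probe.tumor_high, size=n)

    log_hazard = np.full(n, np.log(config.baseline_hazard))
    for probe in truth.prognostic:
        i = index.get_loc(probe.probe_id)
        risky = betas[i] > probe.cutpoint if probe.risk_high else betas[i] < probe.cutpoint
        log_hazard += probe.log_hr * risky
    death = rng.exponential(1.0 / np.exp(log_hazard))
    censor = np.minimum(config.censor_time_max,
                        rng.uniform(0.0, 2.0 * max(config.censor_time_max, 1e-12), size=n))
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    # survival times must be positive; nudge exact zeros from a zero horizon
    time = np.maximum(time, 1e-9)

    patients = [f"V{i:03d}" for i in range(n)]
    matrix = BetaMatrix(pd.DataFrame(betas, index=probe_ids, columns=patients))
    clinical = ClinicalTable(pd.DataFrame({"event": event, "time": time},
                                          index=pd.Index(patients, name="patient_id")))
    return matrix, clinical


def simulate_gene_universe(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[ProbeAnnotation, GeneSetCollection]:
    """Assign probes to genes and build gene sets with planted enrichment.

    Each probe maps to 0-2 gene symbols.  Prognostic probes are forced
    onto ``n_prognostic_genes`` distinct genes (round-robin, so several
    probes may share a gene, as CpGs on one promoter do).  Each of the
    ``n_enriched_sets`` planted sets contains every prognostic gene plus
    disjoint filler genes; the remaining sets are random draws from the
    universe.  Updates ``truth.prognostic_genes`` and
    ``truth.enriched_term_ids`` in place.
    """
    config.validate()
    rng = np.random.default_rng(_streams(config)[3])
    genes = np.array([f"GENE{i:04d}" for i in range(config.n_genes)])
    probe_ids = _probe_ids(config.n_probes)
    prognostic_ids = [p.probe_id for p in truth.prognostic]

    n_genes_per_probe = rng.choice([0, 1, 2], size=config.n_probes, p=[0.25, 0.55, 0.20])
    gene_lists: list[tuple[str, ...]] = [
        tuple(rng.choice(genes, size=k, replace=False)) for k in n_genes_per_probe
    ]

    prog_genes = tuple(rng.choice(genes, size=config.n_prognostic_genes, replace=False)) \
        if prognostic_ids else ()
    index = pd.Index(probe_ids)
    for j, pid in enumerate(prognostic_ids):
        gene_lists[index.get_loc(pid)] = (prog_genes[j % len(prog_genes)],)

    annotation = ProbeAnnotation(pd.DataFrame(
        {
            "gene_symbols": gene_lists,
            "chromosome": [str(c) for c in rng.integers(1, 23, size=config.n_probes)],
            "position": rng.integers(1, 100_000_000, size=config.n_probes).astype(float),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    ))

    sets: dict[str, GeneSet] = {}
    filler_pool = [g for g in genes if g not in prog_genes]
    rng.shuffle(filler_pool)
    cursor = 0
    for j in range(config.n_enriched_sets if prognostic_ids else 0):
        n_fill = int(rng.integers(3, 8))
        members = frozenset(prog_genes) | frozenset(filler_pool[cursor:cursor + n_fill])
        cursor += n_fill
        term = f"ENR{j:04d}"
        sets[term] = GeneSet(term, f"planted enriched set {j}", members)
    lo, hi = config.gene_set_size_range
    for j in range(config.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        term = f"SET{j:04d}"
        sets[term] = GeneSet(term, f"random background set {j}",
                             frozenset(rng.choice(genes, size=size, replace=False)))

    truth.prognostic_genes = prog_genes
    truth.enriched_term_ids = tuple(t for t in sets if t.startswith("ENR"))
    truth.probe_gene_map = {pid: gl for pid, gl in zip(probe_ids, gene_lists)}
    return annotation, GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# truth ledger I/O
# ---------------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Write the planted-marker ledger as TSV with a JSON config header."""
    header = {
        "seed": truth.seed,
        "config": dataclasses.asdict(truth.config),
        "prognostic_genes": list(truth.prognostic_genes),
        "enriched_term_ids": list(truth.enriched_term_ids),
    }
    rows = pd.DataFrame([dataclasses.asdict(p) for p in truth.planted])
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("# " + json.dumps(header) + "\n")
        rows.to_csv(handle, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_truth(path: str | Path) -> SyntheticTruth:
    with open(path, encoding="utf-8") as handle:
        header = json.loads(handle.readline().lstrip("# "))
        rows = pd.read_csv(handle, sep="\t", na_values=["NA"], keep_default_na=False,
                           float_precision="round_trip")
    cfg_dict = header["config"]
    for key in ("planted_cutpoints", "planted_risk_high", "gene_set_size_range"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = SimulationConfig(**cfg_dict)
    planted = []
    for row in rows.itertuples(index=False):
        planted.append(PlantedProbe(
            probe_id=row.probe_id, direction=row.direction,
            normal_low=row.normal_low, normal_high=row.normal_high,
            tumor_low=row.tumor_low, tumor_high=row.tumor_high,
            is_prognostic=bool(row.is_prognostic),
            cutpoint=None if pd.isna(row.cutpoint) else float(row.cutpoint),
            log_hr=None if pd.isna(row.log_hr) else float(row.log_hr),
            risk_high=None if pd.isna(row.risk_high) else bool(row.risk_high),
        ))
    return SyntheticTruth(
        planted=planted, seed=header["seed"], config=config,
        prognostic_genes=tuple(header["prognostic_genes"]),
        enriched_term_ids=tuple(header["enriched_term_ids"]),
    )
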