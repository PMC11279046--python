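"""Domain containers and on-disk formats.

The pipeline works with five kinds of tabular data: beta-value matrices
(CpG probes x samples, methylated fraction in [0, 1]), matched
tumor/normal pair sets, clinical survival tables, probe-to-gene
annotation, and gene-set collections (GMT).  Everything on disk is
UTF-8, tab-delimited text with ``NA`` for missing values; beta values
are validated on read, never clamped.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"

__all__ = [
    "FormatError",
    "ValidationError",
    "BetaMatrix",
    "MatchedPairSet",
    "ClinicalTable",
    "ProbeAnnotation",
    "GeneSet",
    "GeneSetCollection",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_tcga_sample_files",
    "build_matched_pairs",
    "read_clinical",
    "write_clinical",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_gene_sets",
    "write_gene_sets",
]


class FormatError(ValueError):
    """A file violates the structural contract of its format."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant (e.g. beta outside [0, 1])."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaMatrix:
    """Probes x samples matrix of methylation beta values.

    ``data`` is a float DataFrame indexed by probe id with sample ids as
    columns; ``NaN`` marks a missing measurement.  All non-missing values
    must lie in [0, 1].
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy(dtype=float)
        bad = (values < 0.0) | (values > 1.0)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value out of [0, 1]: probe {self.data.index[i]!r}, "
                f"sample {self.data.columns[j]!r}, value {values[i, j]!r}"
            )
        object.__setattr__(self, "data", self.data.astype(float))

    @property
    def probe_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_probes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def select_probes(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        missing = [p for p in probe_ids if p not in self.data.index]
        if missing:
            raise KeyError(f"probes not in matrix: {missing[:5]}")
        return BetaMatrix(self.data.loc[list(probe_ids)])

    def select_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return BetaMatrix(self.data[list(sample_ids)])


@dataclass(frozen=True)
class MatchedPairSet:
    """Per-probe aligned normal/tumor beta values for n matched patients.

    ``normal`` and ``tumor`` carry identical probe ids in identical order;
    their columns are aligned to ``patient_ids`` (column i of each matrix
    belongs to patient i).  ``pairing`` maps each patient to its
    (normal sample id, tumor sample id).
    """

    patient_ids: tuple[str, ...]
    normal: BetaMatrix
    tumor: BetaMatrix
    pairing: Mapping[str, tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.patient_ids) < 2:
            raise ValidationError("a matched pair set needs at least 2 patients")
        if self.normal.probe_ids != self.tumor.probe_ids:
            raise ValidationError("normal and tumor matrices disagree on probes")
        if self.normal.n_samples != len(self.patient_ids) or self.tumor.n_samples != len(self.patient_ids):
            raise ValidationError("matrices not aligned to patients")
        for pid in self.patient_ids:
            if pid not in self.pairing:
                raise ValidationError(f"patient {pid!r} missing from pairing")

    @property
    def n_pairs(self) -> int:
        return len(self.patient_ids)

    @property
    def probe_ids(self) -> list[str]:
        return self.normal.probe_ids

    @property
    def normal_values(self) -> np.ndarray:
        """Probes x patients array of normal-tissue betas."""
        return self.normal.values

    @property
    def tumor_values(self) -> np.ndarray:
        """Probes x patients array of tumor-tissue betas."""
        return self.tumor.values


@dataclass(frozen=True)
class ClinicalTable:
    """Per-patient survival endpoint: event indicator and time in days.

    ``data`` is indexed by patient id with an int ``event`` column
    (1 = dead, 0 = alive/censored), a positive float ``time`` column
    (days), plus any extra covariate columns (carried, not modeled).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate patient ids in clinical table")
        for col in ("event", "time"):
            if col not in self.data.columns:
                raise FormatError(f"clinical table missing column {col!r}")
        ev = self.data["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValidationError("event indicator must be 0 or 1")
        t = self.data["time"].to_numpy(dtype=float)
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            bad = self.data.index[(~np.isfinite(t)) | (t <= 0)][0]
            raise ValidationError(f"non-positive or missing survival time for patient {bad!r}")

    @property
    def patient_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    def subset(self, patient_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(patient_ids)])


@dataclass(frozen=True)
class ProbeAnnotation:
    """Probe -> (gene symbols, chromosome, position) lookup.

    ``data`` is indexed by probe id with columns ``gene_symbols`` (tuple
    of symbols, possibly empty), ``chromosome`` (label) and ``position``
    (1-based bp, NaN when unknown).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate probe ids in annotation")
        pos = pd.to_numeric(self.data["position"], errors="coerce")
        if (pos.dropna() < 1).any():
            raise ValidationError("annotation positions must be >= 1")

    @property
    def probe_ids(self) -> list[str]:
        return self.data.index.tolist()

    def genes_for(self, probe_id: str) -> tuple[str, ...]:
        if probe_id not in self.data.index:
            return ()
        return tuple(self.data.loc[probe_id, "gene_symbols"])

    def all_genes(self) -> list[str]:
        """Sorted unique gene symbols over the whole annotation (the
        default over-representation universe)."""
        genes: set[str] = set()
        for syms in self.data["gene_symbols"]:
            genes.update(syms)
        return sorted(genes)


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.term_id!r} is empty")
        if any(not g for g in self.genes):
            raise ValidationError(f"gene set {self.term_id!r} has empty gene symbols")


@dataclass(frozen=True)
class GeneSetCollection:
    sets: Mapping[str, GeneSet] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.sets[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.sets


# ---------------------------------------------------------------------------
# beta matrix I/O
# ---------------------------------------------------------------------------

def read_beta_matrix(path: str | Path, missing_token: str = MISSING_TOKEN) -> BetaMatrix:
    """Read a probes-in-rows TSV beta matrix.

    First column holds probe ids, header row holds sample ids; cells are
    numeric or ``missing_token``.  Out-of-range values raise
    :class:`ValidationError` naming the offending probe, sample and value.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[missing_token], keep_default_na=False
    )
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df)


def write_beta_matrix(matrix: BetaMatrix, path: str | Path,
                      missing_token: str = MISSING_TOKEN) -> None:
    matrix.data.to_csv(path, sep="\t", na_rep=missing_token, index_label="probe_id")


def read_tcga_sample_files(
    directory: str | Path,
    manifest: pd.DataFrame,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Assemble portal-style per-sample two-column files into one matrix.

    ``manifest`` needs columns ``file`` (name relative to ``directory``),
    ``sample_id`` and ``sample_type`` ("tumor"/"normal"); an optional
    ``patient_id`` column is passed through.  Probes are restricted to
    the intersection present in every file and sorted by probe id.
    Returns the matrix and the per-sample metadata table (one row per
    matrix column, in column order).
    """
    directory = Path(directory)
    for col in ("file", "sample_id", "sample_type"):
        if col not in manifest.columns:
            raise FormatError(f"manifest missing column {col!r}")
    bad_type = set(manifest["sample_type"]) - {"tumor", "normal"}
    if bad_type:
        raise FormatError(f"unknown sample types in manifest: {sorted(bad_type)}")
    if manifest["sample_id"].duplicated().any():
        raise FormatError("duplicate sample ids in manifest")

    columns: dict[str, pd.Series] = {}
    for row in manifest.itertuples(index=False):
        fpath = directory / row.file
        raw = pd.read_csv(
            fpath, sep="\t", header=None, na_values=[MISSING_TOKEN],
            keep_default_na=False, comment="#",
        )
        if raw.shape[1] < 2:
            raise FormatError(f"{fpath}: expected two tab-separated columns")
        raw = raw.iloc[:, :2]
        raw.columns = ["probe", "beta"]
        # tolerate a single header line ("probe\tbeta" style)
        first = raw.iloc[0]["beta"]
        if isinstance(first, str):
            raw = raw.iloc[1:]
        series = pd.Series(
            pd.to_numeric(raw["beta"], errors="raise").to_numpy(),
            index=raw["probe"].astype(str),
        )
        if series.index.has_duplicates:
            grouped = series.groupby(level=0)
            conflicting = grouped.nunique(dropna=False) > 1
            if conflicting.any():
                probe = conflicting.index[conflicting][0]
                raise FormatError(
                    f"{fpath}: probe {probe!r} listed twice with different values"
                )
            series = grouped.first()
        columns[row.sample_id] = series

    common: set[str] | None = None
    for series in columns.values():
        common = set(series.index) if common is None else common & set(series.index)
    if not common:
        raise FormatError("no probe is present in every sample file")
    probes = sorted(common)
    data = pd.DataFrame({sid: s.loc[probes] for sid, s in columns.items()}, index=probes)
    meta = manifest.drop(columns=["file"]).reset_index(drop=True)
    return BetaMatrix(data), meta


def build_matched_pairs(matrix: BetaMatrix, sample_meta: pd.DataFrame) -> MatchedPairSet:
    """Pair each patient's single tumor and single normal sample.

    ``sample_meta`` needs columns ``sample_id``, ``patient_id`` and
    ``sample_type``.  Patients lacking one of the two tissue types are
    dropped (logged); a patient with more than one sample of a type is
    an error — pairing would be ambiguous.  Patient order follows first
    appearance in ``sample_meta`` so results are order-stable.
    """
    for col in ("sample_id", "patient_id", "sample_type"):
        if col not in sample_meta.columns:
            raise FormatError(f"sample metadata missing column {col!r}")
    uncovered = set(matrix.sample_ids) - set(sample_meta["sample_id"])
    if uncovered:
        raise FormatError(f"sample metadata does not cover samples: {sorted(uncovered)[:5]}")

    meta = sample_meta[sample_meta["sample_id"].isin(matrix.sample_ids)]
    pairing: dict[str, tuple[str, str]] = {}
    dropped = []
    for pid in meta["patient_id"].drop_duplicates():
        rows = meta[meta["patient_id"] == pid]
        normals = rows.loc[rows["sample_type"] == "normal", "sample_id"].tolist()
        tumors = rows.loc[rows["sample_type"] == "tumor", "sample_id"].tolist()
        if len(normals) > 1 or len(tumors) > 1:
            raise ValidationError(
                f"patient {pid!r} has {len(tumors)} tumor / {len(normals)} normal "
                "samples; pairing is ambiguous"
            )
        if len(normals) == 1 and len(tumors) == 1:
            pairing[pid] = (normals[0], tumors[0])
        else:
            dropped.append(pid)
    if dropped:
        logger.warning("dropped %d patients without a complete pair: %s",
                       len(dropped), dropped[:10])
    if not pairing:
        raise ValidationError("no patient has a complete tumor/normal pair")
    patients = tuple(pairing)
    logger.info("retained %d matched pairs", len(patients))
    normal = matrix.select_samples([pairing[p][0] for p in patients])
    tumor = matrix.select_samples([pairing[p][1] for p in patients])
    return MatchedPairSet(patient_ids=patients, normal=normal, tumor=tumor,
                          pairing=pairing)


# ---------------------------------------------------------------------------
# clinical table I/O
# ---------------------------------------------------------------------------

_DEAD_LABELS = {"dead", "deceased", "1"}
_ALIVE_LABELS = {"alive", "living", "0"}


def read_clinical(path: str | Path, missing_token: str = MISSING_TOKEN) -> ClinicalTable:
    """Read a portal-style clinical TSV into event/time form.

    Expects columns ``patient_id``, ``vital_status``, ``days_to_death``
    and ``days_to_last_follow_up``.  Deceased patients contribute
    event = 1 with time = days_to_death; the rest contribute event = 0
    with time = days_to_last_follow_up.  Rows with no usable time are
    dropped with a warning; non-positive times are a validation error.
    """
    df = pd.read_csv(path, sep="\t", na_values=[missing_token], keep_default_na=False,
                     dtype={"patient_id": str})
    for col in ("patient_id", "vital_status", "days_to_death", "days_to_last_follow_up"):
        if col not in df.columns:
            raise FormatError(f"clinical file missing column {col!r}")
    records = []
    dropped = []
    for row in df.itertuples(index=False):
        status = str(row.vital_status).strip().lower()
        dead = status in _DEAD_LABELS
        time = row.days_to_death if dead else row.days_to_last_follow_up
        if pd.isna(time):
            dropped.append(row.patient_id)
            continue
        time = float(time)
        if time <= 0:
            raise ValidationError(
                f"non-positive survival time {time!r} for patient {row.patient_id!r}"
            )
        records.append((row.patient_id, int(dead), time))
    if dropped:
        logger.warning("dropped %d clinical rows without an endpoint time: %s",
                       len(dropped), dropped[:10])
    out = pd.DataFrame(records, columns=["patient_id", "event", "time"])
    out = out.set_index("patient_id")
    return ClinicalTable(out)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    """Write event/time back out in the portal-style four-column layout."""
    df = table.data
    out = pd.DataFrame(
        {
            "patient_id": df.index,
            "vital_status": np.where(df["event"] == 1, "Dead", "Alive"),
            "days_to_death": np.where(df["event"] == 1, df["time"], np.nan),
            "days_to_last_follow_up": np.where(df["event"] == 0, df["time"], np.nan),
        }
    )
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


# ---------------------------------------------------------------------------
# annotation and gene sets
# ---------------------------------------------------------------------------

def read_probe_annotation(path: str | Path, missing_token: str = MISSING_TOKEN) -> ProbeAnnotation:
    """Read a 4-column probe annotation TSV.

    Columns: ``probe_id``, ``gene_symbols`` (';'-separated, may be
    empty/NA), ``chromosome``, ``position``.
    """
    df = pd.read_csv(path, sep="\t", na_values=[missing_token], keep_default_na=False,
                     dtype={"probe_id": str, "chromosome": str})
    for col in ("probe_id", "gene_symbols", "chromosome", "position"):
        if col not in df.columns:
            raise FormatError(f"annotation missing column {col!r}")

    def _split(cell) -> tuple[str, ...]:
        if pd.isna(cell) or str(cell).strip() == "":
            return ()
        return tuple(s for s in str(cell).split(";") if s)

    df = df.assign(gene_symbols=df["gene_symbols"].map(_split),
                   position=pd.to_numeric(df["position"], errors="coerce"))
    return ProbeAnnotation(df.set_index("probe_id"))


def write_probe_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    df = annotation.data
    out = pd.DataFrame(
        {
            "probe_id": df.index,
            "gene_symbols": [";".join(s) for s in df["gene_symbols"]],
            "chromosome": df["chromosome"],
            "position": df["position"],
        }
    )
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``term<TAB>description<TAB>gene1<TAB>gene2...``.

    Lines without member genes are skipped with a warning; a duplicated
    term id is an error.
    """
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: GMT line needs term and description")
            term_id, term_name, *genes = parts
            genes = [g for g in genes if g.strip()]
            if not genes:
                logger.warning("%s:%d: gene set %r has no genes; skipped",
                               path, lineno, term_id)
                continue
            if term_id in sets:
                raise FormatError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            sets[term_id] = GeneSet(term_id, term_name, frozenset(genes))
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for gs in collection:
            handle.write("\t".join([gs.term_id, gs.term_name, *sorted(gs.genes)]) + "\n")
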