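"""Readers and writers for quantification report tables.

All dialects are parsed into one canonical long table (`QuantTable`): one
row per (setup, sample, replicate run, protein group) with intensity,
peptide count, optional q-value gates and retention time, and decoy /
contaminant flags.  Zero or empty raw intensities become NaN ("absent") on
read — quantification software writes 0 for non-detections, and a literal
zero would corrupt CV and missingness statistics downstream.

Supported dialects:

* generic    — tidy long TSV with canonical column names (also the writer
               format; round-trips losslessly),
* maxquant   — proteinGroups-style wide TSV with per-run "LFQ intensity"
               columns and "+" marker columns for reverse hits and
               potential contaminants,
* diann      — report-style long TSV with one row per precursor, aggregated
               here to protein-per-run records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "QuantTable",
    "RunMetadata",
    "QuantIOError",
    "CANONICAL_COLUMNS",
    "Q_GATE_COLUMNS",
    "read_generic",
    "write_generic",
    "read_maxquant_proteingroups",
    "read_diann_report",
    "annotate_species",
    "species_map_from_fasta",
    "DEFAULT_SUFFIX_RULES",
]


class QuantIOError(ValueError):
    """Raised for malformed or inconsistent report tables."""


Q_GATE_COLUMNS = ("q_value", "pg_q_value", "lib_q_value", "lib_pg_q_value")

KEY_COLUMNS = ("setup_id", "sample_id", "replicate", "protein_group")

CANONICAL_COLUMNS = (
    "setup_id",
    "sample_id",
    "replicate",
    "protein_group",
    "species",
    "intensity",
    "n_peptides",
    *Q_GATE_COLUMNS,
    "rt",
    "is_decoy",
    "is_contaminant",
)

MANDATORY_GENERIC = ("setup_id", "sample_id", "replicate", "protein_group", "intensity")


def _exact_float(s: pd.Series) -> pd.Series:
    """String -> float via Python's shortest-round-trip parser (pd.to_numeric
    can be off by one ulp, breaking bitwise round-trips)."""
    if s.dtype != object:
        return s.astype(float)

    def conv(v):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return np.nan
        if isinstance(v, str) and not v.strip():
            return np.nan
        try:
            return float(v)
        except (TypeError, ValueError):
            return np.nan

    return s.map(conv).astype(float)


@dataclass(frozen=True)
class RunMetadata:
    """Acquisition descriptors for one LC-MS setup."""

    setup_id: str
    acquisition_mode: str  # "DDA" | "DIA"
    gradient_length: float  # minutes
    flow_regime: str = "nano"  # "nano" | "micro"
    instrument_label: str = ""
    cycle_time_s: float | None = None  # MS cycle time, seconds
    peak_fwhm_min: float | None = None  # mean chromatographic peak FWHM, minutes

    def __post_init__(self) -> None:
        if self.acquisition_mode not in ("DDA", "DIA"):
            raise QuantIOError(f"acquisition_mode must be DDA or DIA, got {self.acquisition_mode!r}")
        if self.gradient_length <= 0:
            raise QuantIOError("gradient_length must be > 0")


@dataclass
class QuantTable:
    """Canonical long table of protein-per-run measurements plus run metadata."""

    data: pd.DataFrame
    metadata: dict[str, RunMetadata] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                if col == "species":
                    df[col] = "unknown"
                elif col == "n_peptides":
                    df[col] = 0
                elif col in ("is_decoy", "is_contaminant"):
                    df[col] = False
                else:
                    df[col] = np.nan
        df = df.loc[:, list(CANONICAL_COLUMNS)]
        df["replicate"] = df["replicate"].astype(int)
        df["n_peptides"] = df["n_peptides"].astype(int)
        for col in ("intensity", "rt", *Q_GATE_COLUMNS):
            df[col] = _exact_float(df[col])
        for col in ("is_decoy", "is_contaminant"):
            s = df[col]
            if s.dtype == object:
                s = s.map(lambda v: str(v).strip().lower() in ("true", "1", "+", "yes"))
            df[col] = s.astype(bool)
        # absent, not zero: software writes 0 for non-detections
        df.loc[df["intensity"] <= 0, "intensity"] = np.nan
        dup = df.duplicated(subset=list(KEY_COLUMNS))
        if dup.any():
            first = df.loc[dup, list(KEY_COLUMNS)].iloc[0].tolist()
            raise QuantIOError(f"duplicate record key {tuple(first)}")
        missing_meta = set(df["setup_id"].unique()) - set(self.metadata)
        if missing_meta:
            raise QuantIOError(f"setups without metadata: {sorted(missing_meta)}")
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def setups(self) -> tuple[str, ...]:
        return tuple(sorted(self.data["setup_id"].unique()))

    def for_setup(self, setup_id: str) -> "QuantTable":
        sub = self.data[self.data["setup_id"] == setup_id]
        if sub.empty:
            raise QuantIOError(f"no records for setup {setup_id!r}")
        return QuantTable(sub, {setup_id: self.metadata[setup_id]})

    def with_data(self, df: pd.DataFrame) -> "QuantTable":
        meta = {s: self.metadata[s] for s in df["setup_id"].unique()}
        return QuantTable(df, meta)

    def detected(self) -> pd.DataFrame:
        """Rows with a quantified (non-absent) intensity."""
        return self.data[self.data["intensity"].notna()]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, na_values=[""],
        float_precision="round_trip",
    )


def read_generic(path: str | Path, metadata: Mapping[str, RunMetadata]) -> QuantTable:
    """Read the canonical tidy TSV dialect."""
    df = _read_tsv(path)
    missing = [c for c in MANDATORY_GENERIC if c not in df.columns]
    if missing:
        raise QuantIOError(f"generic table missing mandatory columns: {missing}")
    return QuantTable(df, dict(metadata))


def write_generic(table: QuantTable, path: str | Path) -> None:
    """Write the canonical dialect with fixed column order (lossless round-trip)."""
    df = table.data.loc[:, list(CANONICAL_COLUMNS)].copy()
    for col in ("is_decoy", "is_contaminant"):
        df[col] = df[col].map({True: "true", False: "false"})
    df.to_csv(path, sep="\t", index=False, na_rep="")


def _normalize_run_map(
    run_to_sample_map: Mapping[str, tuple | Mapping],
) -> dict[str, tuple[str, str, int]]:
    out: dict[str, tuple[str, str, int]] = {}
    for run, entry in run_to_sample_map.items():
        if isinstance(entry, Mapping):
            out[str(run)] = (str(entry["setup_id"]), str(entry["sample_id"]), int(entry["replicate"]))
        else:
            setup, sample, rep = entry
            out[str(run)] = (str(setup), str(sample), int(rep))
    return out


MAXQUANT_SCHEMA = {
    "protein_group": "Protein IDs",
    "n_peptides": "Peptides",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "lfq_prefix": "LFQ intensity ",
}


def read_maxquant_proteingroups(
    path: str | Path,
    run_to_sample_map: Mapping[str, tuple | Mapping],
    metadata: Mapping[str, RunMetadata],
    schema: Mapping[str, str] | None = None,
) -> QuantTable:
    """Melt a proteinGroups-style wide TSV into canonical long records.

    Per-run "LFQ intensity <run>" columns are melted using `run_to_sample_map`
    (run label -> (setup_id, sample_id, replicate)); "+" marks in the reverse /
    contaminant columns set the corresponding flags; LFQ 0 becomes absent.
    """
    sch = {**MAXQUANT_SCHEMA, **(schema or {})}
    run_map = _normalize_run_map(run_to_sample_map)
    df = _read_tsv(path)
    if sch["protein_group"] not in df.columns:
        raise QuantIOError(f"missing protein-group column {sch['protein_group']!r}")
    prefix = sch["lfq_prefix"]
    lfq_cols = [c for c in df.columns if c.startswith(prefix)]
    if not lfq_cols:
        raise QuantIOError(f"no per-run {prefix!r} columns found")
    records = []
    for col in lfq_cols:
        run = col[len(prefix):]
        if run not in run_map:
            raise QuantIOError(f"run {run!r} not present in run-to-sample map")
        setup, sample, rep = run_map[run]
        sub = pd.DataFrame(
            {
                "setup_id": setup,
                "sample_id": sample,
                "replicate": rep,
                "protein_group": df[sch["protein_group"]],
                "intensity": _exact_float(df[col]),
                "n_peptides": pd.to_numeric(df.get(sch["n_peptides"], 0), errors="coerce")
                .fillna(0)
                .astype(int),
                "is_decoy": df.get(sch["reverse"], "").astype(str).str.strip() == "+",
                "is_contaminant": df.get(sch["contaminant"], "").astype(str).str.strip() == "+",
            }
        )
        records.append(sub)
    long = pd.concat(records, ignore_index=True)
    return QuantTable(long, dict(metadata))


DIANN_SCHEMA = {
    "run": "Run",
    "protein_group": "Protein.Group",
    "quantity": "PG.MaxLFQ",
    "rt": "RT",
    "sequence": "Stripped.Sequence",
    "q_value": "Q.Value",
    "pg_q_value": "PG.Q.Value",
    "lib_q_value": "Lib.Q.Value",
    "lib_pg_q_value": "Lib.PG.Q.Value",
}


def read_diann_report(
    path: str | Path,
    run_to_sample_map: Mapping[str, tuple | Mapping],
    metadata: Mapping[str, RunMetadata],
    schema: Mapping[str, str] | None = None,
) -> QuantTable:
    """Aggregate a precursor-level report-style long TSV to protein-per-run records.

    Intensity is the reported protein-group quantity (repeated across the
    precursor rows of one protein; taken once, never summed).  RT is the
    median precursor RT in the run; n_peptides counts distinct stripped
    sequences; each q-value gate is the minimum across precursors (the
    protein is identified if its best precursor passes).  Reading never
    filters — q-values above a gate threshold are retained for the filter
    stage.
    """
    sch = {**DIANN_SCHEMA, **(schema or {})}
    run_map = _normalize_run_map(run_to_sample_map)
    df = _read_tsv(path)
    for key in ("run", "protein_group", "quantity"):
        if sch[key] not in df.columns:
            raise QuantIOError(f"missing column {sch[key]!r}")
    unknown = set(df[sch["run"]].unique()) - set(run_map)
    if unknown:
        raise QuantIOError(f"runs not present in run-to-sample map: {sorted(unknown)}")
    df = df.copy()
    df["_quant"] = _exact_float(df[sch["quantity"]])
    df["_rt"] = _exact_float(df[sch["rt"]]) if sch["rt"] in df.columns else np.nan
    for gate in Q_GATE_COLUMNS:
        col = sch[gate]
        df[f"_{gate}"] = _exact_float(df[col]) if col in df.columns else np.nan
    seq_col = sch["sequence"] if sch["sequence"] in df.columns else None

    grouped = df.groupby([sch["run"], sch["protein_group"]], sort=False)
    agg = grouped.agg(
        intensity=("_quant", "first"),
        rt=("_rt", "median"),
        **{gate: (f"_{gate}", "min") for gate in Q_GATE_COLUMNS},
    )
    if seq_col is not None:
        agg["n_peptides"] = grouped[seq_col].nunique()
    else:
        agg["n_peptides"] = grouped.size()
    agg = agg.reset_index().rename(columns={sch["protein_group"]: "protein_group"})
    keys = agg[sch["run"]].map(run_map)
    agg["setup_id"] = keys.str[0]
    agg["sample_id"] = keys.str[1]
    agg["replicate"] = keys.str[2]
    agg = agg.drop(columns=[sch["run"]])
    return QuantTable(agg, dict(metadata))


DEFAULT_SUFFIX_RULES: dict[str, str] = {
    r"_HUMAN$": "human",
    r"_YEAST$": "yeast",
    r"_ECOLI$": "ecoli",
}


def species_map_from_fasta(
    path: str | Path,
    organism_to_label: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Build an accession -> species-label map from FASTA headers.

    UniProt-style headers (``>db|ACCESSION|ENTRY_NAME ... OS=Organism ...``)
    are parsed with pyteomics; the ``OS=`` organism field is matched against
    `organism_to_label` by substring (default: Homo sapiens -> human,
    Saccharomyces -> yeast, Escherichia coli -> ecoli).  Both the accession
    and the entry name are mapped.
    """
    from pyteomics import fasta as pyt_fasta

    org_map = dict(
        organism_to_label
        or {"Homo sapiens": "human", "Saccharomyces": "yeast", "Escherichia coli": "ecoli"}
    )
    out: dict[str, str] = {}
    with pyt_fasta.read(str(path)) as reader:
        for description, _seq in reader:
            header = description if isinstance(description, str) else description.get("description", "")
            first = header.split()[0] if header.split() else ""
            parts = first.split("|")
            # UniProt "db|ACCESSION|ENTRY_NAME"; otherwise the bare identifier
            ids = [p for p in (parts[1:] if len(parts) >= 2 else parts) if p]
            os_match = re.search(r"OS=(.+?)(?:\s\w\w=|$)", header)
            organism = os_match.group(1).strip() if os_match else ""
            label = next((lab for org, lab in org_map.items() if org in organism), None)
            if label:
                for ident in ids:
                    out[ident] = label
    return out


def annotate_species(
    table: QuantTable,
    rules: Mapping[str, str] | None = None,
    accession_map: Mapping[str, str] | None = None,
) -> QuantTable:
    """Assign one species label to every protein group.

    `accession_map` (exact member -> label, e.g. from a FASTA) takes
    precedence; `rules` is an ordered mapping of identifier regex patterns
    to labels (default: entry-name suffix conventions _HUMAN/_YEAST/_ECOLI).
    Groups whose member accessions match more than one species are labelled
    "mixed"; unmatched groups are "unknown".
    """
    if not rules and not accession_map:
        raise QuantIOError("species annotation needs non-empty rules or an accession map")
    pattern_rules = [(re.compile(p), lab) for p, lab in (rules or {}).items()]
    acc_map = dict(accession_map or {})

    def classify(group: str) -> str:
        labels = set()
        for member in str(group).split(";"):
            member = member.strip()
            if not member:
                continue
            if member in acc_map:
                labels.add(acc_map[member])
                continue
            for pat, lab in pattern_rules:
                if pat.search(member):
                    labels.add(lab)
                    break
        if not labels:
            return "unknown"
        if len(labels) > 1:
            return "mixed"
        return labels.pop()

    df = table.data.copy()
    mapping = {g: classify(g) for g in df["protein_group"].unique()}
    df["species"] = df["protein_group"].map(mapping)
    return QuantTable(df, table.metadata)
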