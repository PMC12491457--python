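"""Machine-readable reporting: metric TSV writers and the JSON summary.

The evaluation of one or more report tables produces a fixed set of TSV
files (one per metric family) plus a JSON summary aggregating the headline
numbers per setup x dilution level.  The summary is validated against a
pydantic model; the equivalent JSON schema is shipped in
``pyebench/schemas/summary.schema.json``.  All writers are deterministic
given identical inputs (the timestamp field can be disabled).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel

from pyebench import __version__ as _pkg_version
from pyebench import metrics as m
from pyebench.composition import DilutionSeries
from pyebench.filtering import (
    FilterPolicy,
    apply_identification_filters,
    restrict_for_ratio_metrics,
)
from pyebench.quant_io import QuantTable

logger = logging.getLogger(__name__)

__all__ = ["LevelSummary", "SetupSummary", "EvaluationSummary", "evaluate_table", "EvaluationResult"]


class LevelSummary(BaseModel):
    level: str
    n_runs: int
    ids_total: int
    ids_by_species: dict[str, int]
    completeness: dict[str, int]  # complete / ge50 / sparse / unique
    ids_per_minute: float
    median_cv_percent: Optional[float] = None
    median_rt_cv_percent: Optional[float] = None
    accuracy: dict[str, float] = {}
    precision: dict[str, float] = {}
    missingness_crossing_rank: Optional[int] = None


class SetupSummary(BaseModel):
    setup_id: str
    acquisition_mode: str
    gradient_length: float
    levels: list[LevelSummary]


class EvaluationSummary(BaseModel):
    schema_version: int = 1
    package_version: str = _pkg_version
    generated_at: Optional[str] = None
    design_levels: list[str]
    filter_audit: dict[str, dict[str, int]]
    setups: list[SetupSummary]


@dataclass
class EvaluationResult:
    """All per-setup metric tables plus the validated JSON summary."""

    summary: EvaluationSummary
    completeness: pd.DataFrame
    cv: pd.DataFrame
    accuracy_precision: pd.DataFrame
    missingness: pd.DataFrame
    bins: pd.DataFrame
    correlations: pd.DataFrame | None = None

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.completeness.to_csv(out / "completeness.tsv", sep="\t", index=False)
        self.cv.to_csv(out / "cv.tsv", sep="\t", index=False)
        self.accuracy_precision.to_csv(out / "accuracy_precision.tsv", sep="\t", index=False)
        self.missingness.to_csv(out / "missingness.tsv", sep="\t", index=False)
        self.bins.to_csv(out / "bins.tsv", sep="\t", index=False)
        if self.correlations is not None:
            self.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            fh.write(self.summary.model_dump_json(indent=2))
            fh.write("\n")


def _maybe_timestamp(timestamps: bool) -> str | None:
    return datetime.now(timezone.utc).isoformat() if timestamps else None


def evaluate_table(
    table: QuantTable,
    series: DilutionSeries,
    policy: FilterPolicy | None = None,
    timestamps: bool = True,
) -> EvaluationResult:
    """Run the filter cascade and the full metric panel on a canonical table.

    Metrics that the inputs cannot support (RT CVs without an RT column,
    cross-setup correlations with fewer than three setups) are skipped with
    a logged warning.
    """
    policy = policy or FilterPolicy()
    audit_all: dict[str, dict[str, int]] = {}
    comp_rows, cv_rows, ap_rows, miss_rows, bin_rows = [], [], [], [], []
    setup_summaries = []
    corr_inputs = []

    for setup in table.setups:
        sub = table.for_setup(setup)
        meta = sub.metadata[setup]
        filtered, audit = apply_identification_filters(sub, policy)
        audit_all[setup] = audit
        ratio_table = restrict_for_ratio_metrics(filtered, policy)
        level_summaries = []
        for level in series.levels:
            a, b = series.pair_labels[level]
            level_df = filtered.data[filtered.data["sample_id"].isin([a, b])]
            if level_df.empty:
                logger.warning("setup %s: no records at level %s; skipped", setup, level)
                continue
            level_table = filtered.with_data(level_df)
            comp = m.completeness(level_table, series, level)
            comp_rows.append(
                {"setup_id": setup, "level": level, "n_runs": comp.n_runs, **comp.counts(),
                 "total": comp.total, "ids_per_minute": comp.ids_per_minute}
            )
            det = level_table.detected()
            ids_by_species = det.groupby("species")["protein_group"].nunique().to_dict()
            ids_total = det["protein_group"].nunique()

            cv = m.protein_cv(level_table, a)
            cv_rows.append({"setup_id": setup, "level": level, "kind": "protein", "sample": a,
                            "n": cv.n, "median": cv.median, "q25": cv.q25, "q75": cv.q75,
                            "p5": cv.p5, "p90": cv.p90})
            median_rt = None
            if level_table.data["rt"].notna().any():
                rcv = m.rt_cv(level_table, series, level)
                median_rt = rcv.median
                cv_rows.append({"setup_id": setup, "level": level, "kind": "rt", "sample": f"{a}+{b}",
                                "n": rcv.n, "median": rcv.median, "q25": rcv.q25, "q75": rcv.q75,
                                "p5": rcv.p5, "p90": rcv.p90})
            else:
                logger.warning("setup %s: no RT values at level %s; RT CVs skipped", setup, level)

            acc: dict[str, float] = {}
            prec: dict[str, float] = {}
            rl_df = ratio_table.data[ratio_table.data["sample_id"].isin([a, b])]
            if not rl_df.empty:
                rl_table = ratio_table.with_data(rl_df)
                for sp in sorted(set(rl_df["species"])):
                    for tertile in ("all", "low", "mid", "high"):
                        try:
                            ap = m.accuracy_precision(rl_table, series, level, sp, tertile, policy)
                        except Exception as exc:  # no eligible proteins
                            logger.warning("accuracy skipped for %s/%s/%s: %s", setup, level, sp, exc)
                            continue
                        ap_rows.append(
                            {"setup_id": setup, "level": level, "species": sp, "tertile": tertile,
                             "n_proteins": ap.n_proteins, "q25": ap.q25, "q50": ap.q50,
                             "q75": ap.q75, "expected_log2": ap.expected_log2,
                             "accuracy": ap.accuracy, "precision": ap.precision,
                             "stable": ap.stable}
                        )
                        if tertile == "all" and ap.n_proteins:
                            acc[sp] = ap.accuracy
                            prec[sp] = ap.precision

            crossing = None
            try:
                mc = m.missingness_curve(level_table, level_table)
                crossing = mc.crossing_rank
                pts = mc.points.copy()
                pts.insert(0, "level", level)
                pts.insert(0, "setup_id", setup)
                miss_rows.append(pts)
            except Exception as exc:
                logger.warning("missingness skipped for %s/%s: %s", setup, level, exc)

            level_summaries.append(
                LevelSummary(
                    level=level, n_runs=comp.n_runs, ids_total=ids_total,
                    ids_by_species={k: int(v) for k, v in sorted(ids_by_species.items())},
                    completeness=comp.counts(), ids_per_minute=comp.ids_per_minute,
                    median_cv_percent=None if np.isnan(cv.median) else cv.median,
                    median_rt_cv_percent=median_rt,
                    accuracy=acc, precision=prec,
                    missingness_crossing_rank=crossing,
                )
            )

        base_level = series.levels[0]
        ref_sample = series.pair_labels[base_level][0]
        for sp in series.spike_species:
            try:
                rb = m.response_bins(ratio_table, series, sp, ref_sample)
            except Exception as exc:
                logger.warning("response bins skipped for %s/%s: %s", setup, sp, exc)
                continue
            med = rb.medians.reset_index().melt(id_vars="bin", var_name="sample_id",
                                                value_name="median_intensity")
            lod = rb.below_lod.reset_index().melt(id_vars="bin", var_name="sample_id",
                                                  value_name="below_lod")
            merged = med.merge(lod, on=["bin", "sample_id"])
            merged.insert(0, "species", sp)
            merged.insert(0, "setup_id", setup)
            bin_rows.append(merged)

        setup_summaries.append(
            SetupSummary(setup_id=setup, acquisition_mode=meta.acquisition_mode,
                         gradient_length=meta.gradient_length, levels=level_summaries)
        )
        if level_summaries:
            first = level_summaries[0]
            spike = series.spike_species[0] if series.spike_species else None
            corr_inputs.append(
                {"setup_id": setup,
                 "accuracy": first.accuracy.get(spike, np.nan) if spike else np.nan,
                 "ids": first.ids_total,
                 "median_cv": first.median_cv_percent,
                 "peak_capacity": (
                     m.peak_capacity(meta.gradient_length, meta.peak_fwhm_min)
                     if meta.peak_fwhm_min else np.nan),
                 "data_points_per_peak": (
                     m.data_points_per_peak(meta.peak_fwhm_min, meta.cycle_time_s)
                     if meta.peak_fwhm_min and meta.cycle_time_s else np.nan)}
            )

    correlations = None
    if len(corr_inputs) >= 3:
        corr_df = pd.DataFrame(corr_inputs).set_index("setup_id")
        correlations = m.metric_correlation(corr_df)
    else:
        logger.warning("metric correlations skipped: %d setups (need >= 3)", len(corr_inputs))

    summary = EvaluationSummary(
        generated_at=_maybe_timestamp(timestamps),
        design_levels=list(series.levels),
        filter_audit=audit_all,
        setups=setup_summaries,
    )
    empty = pd.DataFrame()
    return EvaluationResult(
        summary=summary,
        completeness=pd.DataFrame(comp_rows),
        cv=pd.DataFrame(cv_rows),
        accuracy_precision=pd.DataFrame(ap_rows),
        missingness=pd.concat(miss_rows, ignore_index=True) if miss_rows else empty,
        bins=pd.concat(bin_rows, ignore_index=True) if bin_rows else empty,
        correlations=correlations,
    )


def summary_json_schema() -> dict:
    """The JSON schema of the evaluation summary (derived from the model)."""
    return EvaluationSummary.model_json_schema()
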