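"""The benchmark metric panel.

Given a filtered canonical table and the composition ground truth, this
module computes the quantities a spike-in benchmark is scored on:

* identification completeness per setup and dilution level (complete /
  >=50% of runs / sparse / single-run categories, IDs per gradient minute),
* protein-abundance and retention-time CV distributions,
* chromatographic peak capacity and data points per peak,
* accuracy and precision of log2(A/B) protein ratios against the design
  ratios (median deviation and interquartile range), optionally restricted
  to an intensity tertile,
* missingness curves over abundance rank and their 50%-crossing rank,
* integrated dynamic-range profiles and cross-dilution correlation,
* decile response curves across the dilution series with below-LOD flags,
* correlation of per-setup accuracy with other panel metrics.

Quantiles use linear interpolation between closest ranks throughout (the
numpy default).  CVs are computed on raw, not log, intensities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pyebench.composition import DilutionSeries, spike_fold, expected_log2_ratio
from pyebench.filtering import FilterPolicy, quantification_eligibility
from pyebench.quant_io import QuantIOError, QuantTable

__all__ = [
    "CompletenessSummary",
    "CVSummary",
    "AccuracyPrecision",
    "MissingnessCurve",
    "ResponseBins",
    "completeness",
    "protein_cv",
    "rt_cv",
    "peak_capacity",
    "data_points_per_peak",
    "accuracy_precision",
    "missingness_curve",
    "dynamic_range",
    "cross_dilution_correlation",
    "response_bins",
    "metric_correlation",
]

logger = logging.getLogger(__name__)

# Gaussian FWHM -> 4-sigma base width: 4 / (2*sqrt(2*ln 2)) = 1.699
FWHM_TO_4SIGMA = 4.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def _single_setup(table: QuantTable) -> str:
    setups = table.setups
    if len(setups) != 1:
        raise QuantIOError(f"expected a single-setup table, got setups {setups}")
    return setups[0]


# ---------------------------------------------------------------------------
# completeness


@dataclass(frozen=True)
class CompletenessSummary:
    """Detection-completeness categories for one setup x dilution level."""

    setup_id: str
    level: str
    n_runs: int
    complete: int  # detected in all runs
    ge50: int      # detected in >=50% of runs (but not all)
    sparse: int    # detected in <50% of runs (more than once)
    unique: int    # detected in exactly one run
    ids_per_minute: float  # complete count / gradient minutes

    @property
    def total(self) -> int:
        return self.complete + self.ge50 + self.sparse + self.unique

    def counts(self) -> dict[str, int]:
        return {
            "complete": self.complete,
            "ge50": self.ge50,
            "sparse": self.sparse,
            "unique": self.unique,
        }


def completeness(table: QuantTable, series: DilutionSeries, level: str) -> CompletenessSummary:
    """Categorise proteins of one setup by detection count over a level's runs."""
    setup = _single_setup(table)
    a, b = series.pair_labels[level] if level in series.pair_labels else (None, None)
    if a is None:
        raise QuantIOError(f"unknown dilution level {level!r}")
    df = table.data[table.data["sample_id"].isin([a, b])]
    runs = df[["sample_id", "replicate"]].drop_duplicates()
    n_runs = len(runs)
    if n_runs == 0:
        raise QuantIOError(f"no runs for level {level!r} in setup {setup!r}")
    det = df[df["intensity"].notna()].groupby("protein_group").size()
    half = n_runs / 2.0
    complete = int((det == n_runs).sum())
    unique = int(((det == 1) & (det != n_runs)).sum())
    ge50 = int(((det >= half) & (det < n_runs) & (det > 1)).sum())
    sparse = int(((det < half) & (det > 1)).sum())
    gradient = table.metadata[setup].gradient_length
    return CompletenessSummary(
        setup_id=setup,
        level=level,
        n_runs=n_runs,
        complete=complete,
        ge50=ge50,
        sparse=sparse,
        unique=unique,
        ids_per_minute=complete / gradient,
    )


# ---------------------------------------------------------------------------
# coefficients of variation


@dataclass(frozen=True)
class CVSummary:
    """Distribution of per-protein CVs (percent) with order-statistic summary."""

    values: pd.Series  # per-protein CV, percent, indexed by protein group
    median: float
    q25: float
    q75: float
    p5: float
    p90: float

    @property
    def n(self) -> int:
        return len(self.values)


def _summarize_cv(per_protein: pd.Series) -> CVSummary:
    vals = per_protein.to_numpy(dtype=float)
    if vals.size == 0:
        nan = float("nan")
        return CVSummary(per_protein, nan, nan, nan, nan, nan)
    p5, q25, med, q75, p90 = np.percentile(vals, [5, 25, 50, 75, 90])
    return CVSummary(per_protein, float(med), float(q25), float(q75), float(p5), float(p90))


def protein_cv(table: QuantTable, sample: str) -> CVSummary:
    """Per-protein CV of raw intensities across replicate runs of one sample.

    CV = sample standard deviation / mean x 100; proteins with fewer than
    two detected replicates are skipped.
    """
    _single_setup(table)
    det = table.detected()
    det = det[det["sample_id"] == sample]
    g = det.groupby("protein_group")["intensity"]
    agg = g.agg(["count", "mean", "std"])
    agg = agg[agg["count"] >= 2]
    cv = (agg["std"] / agg["mean"] * 100.0).rename("cv_percent")
    return _summarize_cv(cv.sort_index())


def rt_cv(table: QuantTable, series: DilutionSeries, level: str) -> CVSummary:
    """Per-protein retention-time CV (percent), pooled over the A and B runs of a level."""
    _single_setup(table)
    a, b = series.pair_labels[level]
    df = table.data
    df = df[df["sample_id"].isin([a, b]) & df["rt"].notna() & df["intensity"].notna()]
    g = df.groupby("protein_group")["rt"]
    agg = g.agg(["count", "mean", "std"])
    agg = agg[agg["count"] >= 2]
    cv = (agg["std"] / agg["mean"] * 100.0).rename("rt_cv_percent")
    return _summarize_cv(cv.sort_index())


# ---------------------------------------------------------------------------
# chromatography descriptors


def peak_capacity(gradient_minutes: float, peak_fwhm_values: Sequence[float] | float) -> float:
    """Chromatographic peak capacity from gradient length and peak FWHM.

    Uses 4-sigma base widths from Gaussian FWHM:
    capacity = 1 + gradient / (mean FWHM x 1.699).
    """
    if gradient_minutes <= 0:
        raise ValueError("gradient length must be > 0")
    fwhm = np.atleast_1d(np.asarray(peak_fwhm_values, dtype=float))
    if fwhm.size == 0 or np.any(fwhm <= 0):
        raise ValueError("peak FWHM values must be positive and non-empty")
    return 1.0 + gradient_minutes / (float(fwhm.mean()) * FWHM_TO_4SIGMA)


def data_points_per_peak(peak_fwhm_minutes: float, cycle_time_s: float) -> float:
    """MS data points acquired across one chromatographic peak (FWHM / cycle time)."""
    if peak_fwhm_minutes <= 0 or cycle_time_s <= 0:
        raise ValueError("FWHM and cycle time must be positive")
    return peak_fwhm_minutes * 60.0 / cycle_time_s


# ---------------------------------------------------------------------------
# accuracy / precision


@dataclass(frozen=True)
class AccuracyPrecision:
    """Quartile summary of per-protein log2(A/B) against the design ratio.

    accuracy = Q50 - expected log2 ratio (median deviation);
    precision = Q75 - Q25 (interquartile range).
    """

    setup_id: str
    level: str
    species: str
    tertile: str
    q25: float
    q50: float
    q75: float
    expected_log2: float
    n_proteins: int
    stable: bool
    ratios: pd.Series  # per-protein log2(A/B), indexed by protein group

    @property
    def accuracy(self) -> float:
        return self.q50 - self.expected_log2

    @property
    def precision(self) -> float:
        return self.q75 - self.q25


def _tertile_membership(pooled_log10: pd.Series) -> pd.Series:
    """Assign 'low'/'mid'/'high' thirds by mean log10 intensity (ties by id)."""
    order = pooled_log10.loc[sorted(pooled_log10.index)].sort_values(kind="mergesort")
    chunks = np.array_split(order.index.to_numpy(), 3)
    labels = pd.Series(index=pooled_log10.index, dtype=object)
    for name, idx in zip(("low", "mid", "high"), chunks):
        labels.loc[idx] = name
    return labels


def accuracy_precision(
    table: QuantTable,
    series: DilutionSeries,
    level: str,
    species: str,
    tertile: str = "all",
    policy: FilterPolicy | None = None,
) -> AccuracyPrecision:
    """Accuracy and precision of one species' log2(A/B) ratios at one level.

    Per eligible protein (quantified in >= min_reps_per_condition replicates
    of both A and B) the ratio is log2 of the mean detected intensity in A
    over the mean in B.  Quartiles are taken over proteins; tertiles split
    the eligible proteins into thirds by mean log10 intensity pooled over
    the A and B runs.
    """
    if species in ("mixed", "unknown"):
        raise QuantIOError("ratio metrics are undefined for mixed/unknown species")
    if tertile not in ("all", "low", "mid", "high"):
        raise ValueError(f"tertile must be all/low/mid/high, got {tertile!r}")
    setup = _single_setup(table)
    policy = policy or FilterPolicy()
    a, b = series.pair_labels[level]
    sub = table.with_data(table.data[table.data["species"] == species])
    if sub.data.empty:
        raise QuantIOError(f"no records for species {species!r}")
    eligible = quantification_eligibility(sub, policy, pair=(a, b))
    det = sub.detected()
    det = det[det["sample_id"].isin([a, b])]
    det = det[det["protein_group"].map(eligible).fillna(False)]
    means = det.groupby(["protein_group", "sample_id"])["intensity"].mean().unstack()
    means = means.dropna(subset=[a, b])
    ratios = np.log2(means[a] / means[b]).rename("log2_ab")

    if tertile != "all":
        pooled = det.groupby("protein_group")["intensity"].apply(
            lambda x: float(np.log10(x).mean())
        )
        membership = _tertile_membership(pooled.loc[ratios.index])
        ratios = ratios[membership == tertile]

    n = len(ratios)
    stable = n >= 3
    if not stable:
        logger.warning(
            "accuracy_precision unstable: %d eligible proteins for %s/%s/%s", n, setup, level, species
        )
    if n == 0:
        q25 = q50 = q75 = float("nan")
    else:
        q25, q50, q75 = (float(v) for v in np.percentile(ratios.to_numpy(), [25, 50, 75]))
    expected = expected_log2_ratio(series, level, species)
    return AccuracyPrecision(
        setup_id=setup,
        level=level,
        species=species,
        tertile=tertile,
        q25=q25,
        q50=q50,
        q75=q75,
        expected_log2=expected,
        n_proteins=n,
        stable=stable,
        ratios=ratios.sort_index(),
    )


# ---------------------------------------------------------------------------
# missingness


@dataclass(frozen=True)
class MissingnessCurve:
    """Missingness (1 - detections/runs) over abundance rank.

    Ranks (1..n, descending reference abundance) come from the reference
    table; detections are counted over all runs of the query table.
    `crossing_rank` is the first rank at which the centred rolling-mean
    missingness reaches 0.5 (None if never).
    """

    points: pd.DataFrame  # columns: rank, protein_group, norm_intensity, missingness, smoothed
    crossing_rank: int | None
    window: int
    n_query_runs: int


def _reference_ranking(reference_table: QuantTable) -> pd.Series:
    """Average per-setup max-normalized mean intensity, per protein."""
    det = reference_table.detected()
    if det.empty:
        raise QuantIOError("reference table has no detected intensities")
    per_setup = det.groupby(["setup_id", "protein_group"])["intensity"].mean()
    normed = per_setup / per_setup.groupby(level="setup_id").transform("max")
    return normed.groupby(level="protein_group").mean()


def missingness_curve(
    reference_table: QuantTable,
    query_table: QuantTable,
    window: int = 51,
) -> MissingnessCurve:
    """Missingness of query detections over the reference abundance ranking.

    The reference defines the protein set and the ranking (mean of per-setup
    max-normalized intensities, descending; ties broken by identifier).
    Missingness per protein is 1 - detections/runs over all runs of the
    query; reference proteins absent from the query score 1.
    """
    ranking = _reference_ranking(reference_table)
    order = ranking.rename_axis(None).to_frame("norm_intensity")
    order["protein_group"] = order.index
    order = order.sort_values(
        ["norm_intensity", "protein_group"], ascending=[False, True], kind="mergesort"
    )
    qdf = query_table.data
    n_runs = len(qdf[["setup_id", "sample_id", "replicate"]].drop_duplicates())
    if n_runs == 0:
        raise QuantIOError("query table has no runs")
    det_counts = query_table.detected().groupby("protein_group").size()
    miss = 1.0 - order["protein_group"].map(det_counts).fillna(0.0) / n_runs
    points = pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "protein_group": order["protein_group"].to_numpy(),
            "norm_intensity": order["norm_intensity"].to_numpy(),
            "missingness": miss.to_numpy(),
        }
    )
    points["smoothed"] = (
        points["missingness"].rolling(window, center=True, min_periods=1).mean()
    )
    crossed = points.index[points["smoothed"] >= 0.5]
    crossing = int(points.loc[crossed[0], "rank"]) if len(crossed) else None
    return MissingnessCurve(points=points, crossing_rank=crossing, window=window, n_query_runs=n_runs)


# ---------------------------------------------------------------------------
# dynamic range & cross-dilution correlation


def dynamic_range(
    tables: QuantTable | Iterable[QuantTable],
    series: DilutionSeries,
    level: str,
    species: str | None = None,
) -> pd.DataFrame:
    """Integrated normalized-abundance profile across setups at one level.

    Per setup, each protein's mean detected intensity over the level's runs
    is divided by the setup's maximum (=100%); setups are combined as the
    mean of available normalized values per protein.  Returns a DataFrame
    sorted descending with columns protein_group, species, percent,
    log10_percent, rank.
    """
    if isinstance(tables, QuantTable):
        tables = [tables]
    a, b = series.pair_labels[level]
    frames = []
    for t in tables:
        det = t.detected()
        det = det[det["sample_id"].isin([a, b])]
        if species is not None:
            det = det[det["species"] == species]
        if det.empty:
            continue
        per = det.groupby(["setup_id", "protein_group"]).agg(
            intensity=("intensity", "mean"), species=("species", "first")
        )
        per["percent"] = (
            per["intensity"] / per.groupby(level="setup_id")["intensity"].transform("max") * 100.0
        )
        frames.append(per.reset_index())
    if not frames:
        raise QuantIOError(f"no detected records at level {level!r}")
    allp = pd.concat(frames, ignore_index=True)
    combined = allp.groupby("protein_group").agg(
        percent=("percent", "mean"), species=("species", "first")
    )
    combined = combined.sort_values(
        ["percent", "protein_group"], ascending=[False, True], kind="mergesort"
    ).reset_index()
    combined["log10_percent"] = np.log10(combined["percent"])
    combined["rank"] = np.arange(1, len(combined) + 1)
    return combined


def cross_dilution_correlation(
    table: QuantTable,
    series: DilutionSeries,
    levels: tuple[str, str],
    species_list: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-species R^2 of log10 normalized abundances between two dilution levels.

    For each level, per-protein mean intensities over the level's pooled A/B
    runs are normalized to the setup maximum (x100).  The expected offset of
    the identity line is 0 for the background species and log10 of the spike
    dilution fold for spike species.
    """
    _single_setup(table)
    if species_list is None:
        species_list = [sp for sp in sorted(set(table.data["species"])) if sp in series.species]
    lvl1, lvl2 = levels
    per_level = {}
    for lvl in levels:
        a, b = series.pair_labels[lvl]
        det = table.detected()
        det = det[det["sample_id"].isin([a, b])]
        means = det.groupby("protein_group").agg(
            intensity=("intensity", "mean"), species=("species", "first")
        )
        means["percent"] = means["intensity"] / means["intensity"].max() * 100.0
        per_level[lvl] = means
    joined = per_level[lvl1].join(per_level[lvl2], lsuffix="_1", rsuffix="_2", how="inner")
    rows = []
    for sp in species_list:
        sub = joined[joined["species_1"] == sp]
        n = len(sub)
        if n >= 2 and sub["percent_1"].nunique() > 1 and sub["percent_2"].nunique() > 1:
            r, _ = stats.pearsonr(np.log10(sub["percent_1"]), np.log10(sub["percent_2"]))
            r2 = float(r**2)
        else:
            r2 = float("nan")
        a1, _ = series.pair_labels[lvl1]
        a2, _ = series.pair_labels[lvl2]
        offset = (
            0.0
            if sp == series.background_species
            else math.log10(spike_fold(series, sp, a1, a2))
        )
        rows.append({"species": sp, "n": n, "r2": r2, "expected_offset_log10": offset})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# response bins (LOD / linearity)


@dataclass(frozen=True)
class ResponseBins:
    """Decile response curves across the dilution series.

    Proteins are ranked by mean abundance in the reference sample and split
    into `n_bins` equal-sized bins (bin 1 = lowest abundance; any remainder
    goes to the lowest bins; ties broken by identifier).  For each bin and
    sample the median of member mean abundances over detected replicates is
    reported; a bin x sample is flagged below the limit of detection when
    more than half its members are undetected in that sample.
    """

    assignments: pd.Series  # protein_group -> bin number (1 = lowest abundance)
    medians: pd.DataFrame   # bins x samples, median abundance (NaN if none detected)
    below_lod: pd.DataFrame  # bins x samples, bool


def response_bins(
    table: QuantTable,
    series: DilutionSeries,
    species: str,
    reference_sample: str,
    n_bins: int = 10,
) -> ResponseBins:
    """Bin species proteins by reference-sample abundance; median response per sample."""
    _single_setup(table)
    det = table.detected()
    det = det[det["species"] == species]
    ref = det[det["sample_id"] == reference_sample]
    if ref.empty:
        raise QuantIOError(
            f"no detected {species!r} proteins in reference sample {reference_sample!r}"
        )
    ref_means = ref.groupby("protein_group")["intensity"].mean()
    order = ref_means.rename_axis(None).to_frame("mean_intensity")
    order["protein_group"] = order.index
    order = order.sort_values(
        ["mean_intensity", "protein_group"], ascending=[True, True], kind="mergesort"
    )
    chunks = np.array_split(order["protein_group"].to_numpy(), n_bins)
    assignments = pd.Series(
        {p: i + 1 for i, chunk in enumerate(chunks) for p in chunk}, name="bin"
    )

    sample_ids = list(series.sample_ids)
    per_sample_means = (
        det[det["protein_group"].isin(assignments.index)]
        .groupby(["protein_group", "sample_id"])["intensity"]
        .mean()
        .unstack()
        .reindex(columns=sample_ids)
        .reindex(assignments.index)
    )
    bins = sorted(assignments.unique())
    medians = pd.DataFrame(index=bins, columns=sample_ids, dtype=float)
    below = pd.DataFrame(index=bins, columns=sample_ids, dtype=bool)
    for b in bins:
        members = assignments.index[assignments == b]
        vals = per_sample_means.loc[members]
        medians.loc[b] = vals.median()
        below.loc[b] = vals.isna().sum() > len(members) / 2.0
    medians.index.name = below.index.name = "bin"
    return ResponseBins(assignments=assignments, medians=medians, below_lod=below)


# ---------------------------------------------------------------------------
# cross-metric correlation


def metric_correlation(
    metric_table: pd.DataFrame,
    accuracy_col: str = "accuracy",
    use_absolute: bool = True,
) -> pd.DataFrame:
    """Pearson and Spearman correlation of per-setup accuracy with other metrics.

    `metric_table` holds one row per setup and columns for the accuracy plus
    any of: ID count, median CV, data points per peak, peak capacity.
    Constant vectors yield an undefined correlation, reported as NaN with a
    logged warning.  Requires at least three setups.
    """
    if len(metric_table) < 3:
        raise QuantIOError("metric_correlation needs >= 3 setups")
    if accuracy_col not in metric_table.columns:
        raise QuantIOError(f"missing accuracy column {accuracy_col!r}")
    acc = metric_table[accuracy_col].astype(float)
    if use_absolute:
        acc = acc.abs()
    rows = []
    for col in metric_table.columns:
        if col == accuracy_col:
            continue
        vec = metric_table[col].astype(float)
        mask = acc.notna() & vec.notna()
        x, y = acc[mask], vec[mask]
        if len(x) < 3 or x.nunique() <= 1 or y.nunique() <= 1:
            logger.warning("correlation undefined for metric %r (constant or too short)", col)
            pearson = spearman = float("nan")
        else:
            pearson = float(stats.pearsonr(x, y)[0])
            spearman = float(stats.spearmanr(x, y)[0])
        rows.append({"metric": col, "pearson": pearson, "spearman": spearman, "n": int(len(x))})
    return pd.DataFrame(rows)
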