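"""Post-design functional analyses.

Spike-in-calibrated mRNA decay kinetics (log-log calibration per
timepoint, trapezoidal integrated abundance as a protein-output proxy),
single-exponential misfit diagnosis for biphasic decay, the ribosome-free
to total abundance ratio, and gene-editing efficiency summarization with
strong-Kozak normalization.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "SpikeInSet",
    "SpikeCalibration",
    "AbundanceSeries",
    "fit_spikein_calibration",
    "normalize_series",
    "integrate_abundance",
    "ExponentialDecayModel",
    "ExponentialDecayResults",
    "fit_single_exponential",
    "free_to_total_ratio",
    "editing_efficiency",
    "kozak_normalize",
    "indel_table_from_sam",
]


@dataclass(frozen=True)
class SpikeInSet:
    """Known-concentration controls; counts has shape (n_controls, n_timepoints)."""

    ids: tuple[str, ...]
    concentrations: tuple[float, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        conc = np.asarray(self.concentrations, dtype=float)
        if not (np.diff(conc) > 0).all():
            raise ValueError("spike-in concentrations must be strictly increasing")
        if (self.counts < 0).any():
            raise ValueError("spike-in counts must be non-negative")
        if self.counts.shape[0] != len(self.ids) or len(self.ids) != len(conc):
            raise ValueError("ids, concentrations and count rows must align")

    @classmethod
    def standard(cls, counts: np.ndarray,
                 concentrations: Sequence[float] = (1, 10, 100, 1000, 10000)) -> "SpikeInSet":
        ids = tuple(f"spike{int(c)}" for c in concentrations)
        return cls(ids, tuple(float(c) for c in concentrations), counts)


@dataclass(frozen=True)
class SpikeCalibration:
    """log10(concentration) = intercept + slope * log10(count), anchored so
    the most abundant control maps to relative abundance 1."""

    slope: float
    intercept: float
    top_count: float

    def __call__(self, count: float | np.ndarray) -> np.ndarray:
        count = np.asarray(count, dtype=float)
        out = np.zeros_like(count)
        pos = count > 0
        out[pos] = 10.0 ** (self.slope * (np.log10(count[pos]) - np.log10(self.top_count)))
        return out


def fit_spikein_calibration(spikes: SpikeInSet, timepoint: int) -> SpikeCalibration:
    """Least-squares line in (log10 count, log10 concentration) at one timepoint."""
    counts = spikes.counts[:, timepoint]
    conc = np.asarray(spikes.concentrations, dtype=float)
    ok = counts > 0
    if ok.sum() < 2:
        raise ValueError(
            f"timepoint {timepoint}: need >= 2 spike-ins with nonzero counts, got {int(ok.sum())}"
        )
    slope, intercept = np.polyfit(np.log10(counts[ok]), np.log10(conc[ok]), 1)
    top = counts[ok][np.argmax(conc[ok])]
    return SpikeCalibration(slope=float(slope), intercept=float(intercept), top_count=float(top))


@dataclass
class AbundanceSeries:
    variant: str
    timepoints_h: np.ndarray
    abundance: np.ndarray
    input_normalizer: float = 1.0

    def __post_init__(self) -> None:
        self.timepoints_h = np.asarray(self.timepoints_h, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if not (np.diff(self.timepoints_h) > 0).all():
            raise ValueError("timepoints must be strictly increasing")
        if (self.abundance < 0).any():
            raise ValueError("abundances must be >= 0")


def normalize_series(
    variant: str,
    raw_counts: Sequence[float],
    spikes: SpikeInSet,
    input_library_count: float,
    input_library_total: float,
    timepoints_h: Sequence[float] = (0.5, 1, 2, 4, 8, 24),
) -> AbundanceSeries:
    """Spike-calibrated abundances, normalized to the IVT input loading.

    abundance(t) = calibration_t(raw count at t) / (input count / input
    total); a missing/zero input-library count is an error (the caller
    excludes such variants with a warning).
    """
    if input_library_count <= 0:
        raise ValueError(f"variant {variant}: no input-library representation")
    raw = np.asarray(raw_counts, dtype=float)
    t = np.asarray(timepoints_h, dtype=float)
    if raw.shape != t.shape:
        raise ValueError("raw_counts and timepoints length mismatch")
    calibrated = np.array([
        fit_spikein_calibration(spikes, j)(raw[j : j + 1])[0] for j in range(len(t))
    ])
    normalizer = input_library_count / input_library_total
    return AbundanceSeries(variant, t, calibrated / normalizer, input_normalizer=normalizer)


def integrate_abundance(series: AbundanceSeries) -> float:
    """Trapezoidal integral of abundance from the first to the last
    timepoint (hours x abundance units); a protein-output proxy under
    d(protein)/dt = r * mRNA."""
    if len(series.timepoints_h) < 2:
        raise ValueError("integration needs >= 2 timepoints")
    return float(np.trapezoid(series.abundance, series.timepoints_h))


# ---------------------------------------------------------------------------
# single-exponential decay


class ExponentialDecayModel:
    """Single-exponential decay A*exp(-k t) fitted to an abundance series;
    a large residual is the diagnostic for biphasic decay."""

    def __init__(self, series: AbundanceSeries):
        if len(series.timepoints_h) < 3:
            raise ValueError("exponential fit needs >= 3 timepoints")
        self.series = series

    def fit(self, misfit_threshold: float = 0.05) -> "ExponentialDecayResults":
        t = self.series.timepoints_h
        y = self.series.abundance
        pos = y > 0
        if pos.sum() >= 2:
            # log-linear initialization on the positive points
            k0, logA0 = np.polyfit(t[pos], np.log(y[pos]), 1)
            p0 = (float(np.exp(logA0)), float(max(-k0, 1e-6)))
        else:
            p0 = (max(float(y.max()), 1e-6), 0.1)
        converged = True
        try:
            popt, _ = curve_fit(
                lambda tt, A, k: A * np.exp(-k * tt), t, y, p0=p0,
                bounds=([0, 0], [np.inf, np.inf]), maxfev=10_000,
            )
            A, k = float(popt[0]), float(popt[1])
        except RuntimeError:
            converged = False
            A, k = p0
        resid = y - A * np.exp(-k * t)
        rmse = float(np.sqrt(np.mean(resid**2)))
        scale = float(np.mean(y)) if np.mean(y) > 0 else 1.0
        return ExponentialDecayResults(
            series=self.series, amplitude=A, rate=k, rmse=rmse,
            relative_rmse=rmse / scale, converged=converged,
            misfit_flag=(not converged) or (rmse / scale > misfit_threshold),
        )


@dataclass
class ExponentialDecayResults:
    series: AbundanceSeries
    amplitude: float
    rate: float
    rmse: float
    relative_rmse: float
    converged: bool
    misfit_flag: bool

    @property
    def half_life_h(self) -> float:
        return np.log(2) / self.rate if self.rate > 0 else np.inf

    def summary(self) -> str:
        return (
            f"Single-exponential decay fit for {self.series.variant}\n"
            f"  A = {self.amplitude:.4g}, k = {self.rate:.4g} /h "
            f"(half-life {self.half_life_h:.3g} h)\n"
            f"  RMSE {self.rmse:.4g} ({100 * self.relative_rmse:.2f}% of mean); "
            f"{'POOR FIT - biphasic behaviour suspected' if self.misfit_flag else 'adequate fit'}\n"
        )


def fit_single_exponential(series: AbundanceSeries,
                           misfit_threshold: float = 0.05) -> ExponentialDecayResults:
    """Functional wrapper: fit A*exp(-k t) and report the misfit diagnostic."""
    return ExponentialDecayModel(series).fit(misfit_threshold=misfit_threshold)


# ---------------------------------------------------------------------------
# free-to-total ratio


def free_to_total_ratio(free_count: float, total_count: float,
                        free_depth: float | None = None,
                        total_depth: float | None = None) -> float:
    """Ribosome-free over total-RNA abundance, after per-library depth
    normalization (depths default to 1, i.e. already normalized counts)."""
    if total_count <= 0:
        raise ValueError("total count must be > 0")
    free = free_count / (free_depth if free_depth else 1.0)
    total = total_count / (total_depth if total_depth else 1.0)
    return float(free / total)


# ---------------------------------------------------------------------------
# gene editing


def editing_efficiency(
    aligned_reads: pd.DataFrame,
    breakpoint: int,
    window_half: int = 5,
    min_mapq: float = 20.0,
    min_mean_q: float = 30.0,
) -> float:
    """Percentage of quality-passing reads with an indel touching the
    breakpoint window.

    ``aligned_reads`` columns: ``mapq``, ``mean_q`` and
    ``indel_intervals`` (list of half-open [start, end) amplicon
    intervals).  Denominator: reads with mapq > 20 and mean q > 30;
    numerator: those with any indel interval intersecting
    [breakpoint - window_half, breakpoint + window_half].
    """
    passing = aligned_reads[
        (aligned_reads["mapq"] > min_mapq) & (aligned_reads["mean_q"] > min_mean_q)
    ]
    if len(passing) == 0:
        raise ValueError("no reads pass the MAPQ/quality filters")
    lo, hi = breakpoint - window_half, breakpoint + window_half
    def hits(intervals) -> bool:
        return any(start < hi + 1 and end > lo for start, end in intervals)
    n_edited = int(passing["indel_intervals"].map(hits).sum())
    return 100.0 * n_edited / len(passing)


def indel_table_from_sam(path) -> pd.DataFrame:
    """Thin reader turning an aligned SAM into the editing-efficiency
    input table (mapq, mean_q, CIGAR-derived indel intervals in
    reference coordinates)."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            intervals = []
            ref = read.reference_start
            for op, length in read.cigartuples or []:
                if op in (0, 7, 8):      # M, =, X consume both
                    ref += length
                elif op == 2:            # deletion: occupies reference span
                    intervals.append((ref, ref + length))
                    ref += length
                elif op == 1:            # insertion: zero-width at ref point
                    intervals.append((ref, ref + 1))
                elif op == 3:            # N skip
                    ref += length
            quals = read.query_qualities
            mean_q = float(np.mean(quals)) if quals is not None else 0.0
            rows.append({"read": read.query_name, "mapq": read.mapping_quality,
                         "mean_q": mean_q, "indel_intervals": intervals})
    return pd.DataFrame(rows)


def kozak_normalize(
    records: pd.DataFrame,
    control_id: str = "StrongKozak",
    exclusions: Iterable[tuple[str, float]] = (),
) -> pd.DataFrame:
    """Per-UTR mean and SD of efficiencies relative to the strong-Kozak
    control at the matched (dosage, replicate).

    ``records`` columns: ``utr``, ``dosage_pmol``, ``replicate``,
    ``efficiency_percent``.  ``exclusions`` lists (utr, dosage) points
    flagged as experimental failures; exclusions are explicit and never
    auto-detected.
    """
    required = {"utr", "dosage_pmol", "replicate", "efficiency_percent"}
    if not required <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    controls = records[records["utr"] == control_id].set_index(["dosage_pmol", "replicate"])
    df = records.copy()
    for utr, dosage in exclusions:
        df = df[~((df["utr"] == utr) & (df["dosage_pmol"] == dosage))]
    def normalize(row):
        key = (row["dosage_pmol"], row["replicate"])
        if key not in controls.index:
            raise ValueError(
                f"control {control_id!r} missing at dosage {key[0]} pmol, replicate {key[1]}"
            )
        return row["efficiency_percent"] / controls.loc[key, "efficiency_percent"]
    df = df.assign(normalized=df.apply(normalize, axis=1))
    out = df.groupby("utr")["normalized"].agg(["mean", "std", "count"])
    out.columns = ["normalized_mean", "normalized_sd", "n"]
    return out
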