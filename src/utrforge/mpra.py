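"""Polysome-profiling MPRA processing: reads -> UMI counts -> MRL tables.

The mean ribosome load (MRL) of a variant is the ribosome-number-weighted
average over polysome fractions after depth normalization:

    MRL_v = sum_f (c_vf / N_f) * r_f  /  sum_f (c_vf / N_f)

where c_vf is the UMI count of variant v in fraction f, N_f the fraction's
total count, and r_f the number of ribosomes in fraction f.  Only loaded
fractions (r_f >= 1) enter the sums; the ribosome-free fraction is carried
alongside for the free-to-total analyses.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .seqcore import edit_distance

logger = logging.getLogger(__name__)

__all__ = [
    "FractionSpec",
    "FractionCountMatrix",
    "MRLRecord",
    "ReadRecord",
    "default_fractions",
    "read_paired_fastq",
    "write_paired_fastq",
    "parse_and_filter_reads",
    "collapse_umis",
    "cluster_umis",
    "compute_mrl",
    "filter_and_average_replicates",
    "positional_median_effect",
]


@dataclass(frozen=True)
class FractionSpec:
    fraction_id: str
    ribosome_load: float
    is_free: bool = False

    def __post_init__(self) -> None:
        if self.is_free and self.ribosome_load != 0:
            raise ValueError("free fraction must have ribosome_load 0")
        if not self.is_free and self.ribosome_load < 1:
            raise ValueError("loaded fractions must have ribosome_load >= 1")


def default_fractions(n_loaded: int = 8, heaviest_load: float | None = None,
                      include_free: bool = True) -> list[FractionSpec]:
    """Fractions with loads 1..n; the heaviest pools everything above it.

    The number of collected fractions and the nominal load of the heaviest
    one are instrument configuration, not constants; defaults are 8 loaded
    fractions plus a ribosome-free fraction.
    """
    specs = []
    if include_free:
        specs.append(FractionSpec("free", 0.0, is_free=True))
    for r in range(1, n_loaded + 1):
        load = heaviest_load if (heaviest_load is not None and r == n_loaded) else float(r)
        specs.append(FractionSpec(f"poly{r}", load))
    return specs


@dataclass
class FractionCountMatrix:
    variants: list[str]
    fractions: list[FractionSpec]
    counts: np.ndarray  # (n_variants, n_fractions) non-negative ints
    replicate_id: str = "rep1"
    cell_type: str = "synthetic"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.variants), len(self.fractions)):
            raise ValueError("counts shape does not match variants x fractions")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        ids = [f.fraction_id for f in self.fractions]
        if len(set(ids)) != len(ids):
            raise ValueError("fraction ids must be unique")

    @property
    def loaded_mask(self) -> np.ndarray:
        return np.array([not f.is_free for f in self.fractions])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.variants,
                          columns=[f.fraction_id for f in self.fractions])
        df.index.name = "variant"
        return df


@dataclass(frozen=True)
class MRLRecord:
    variant: str
    mrl: float
    total_reads: int
    replicate_id: str = "rep1"


@dataclass(frozen=True)
class ReadRecord:
    variable_region: str
    umi: str
    mean_q: float
    fraction_id: str
    ts_suffix: str = ""
    variant: str | None = None  # assigned id when the region maps to a known variant


# ---------------------------------------------------------------------------
# FASTQ I/O: read 1 carries the variable region followed by the
# template-switch-adjacent bases; read 2 carries the UMI.


def read_paired_fastq(
    r1_path,
    r2_path,
    fraction_id: str,
    variable_length: int,
    umi_length: int = 10,
) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a read-1/read-2 FASTQ pair.

    The first ``variable_length`` bases of read 1 are the variable
    region (already oriented 5'->3'), the remainder its template-switch
    suffix; ``mean_q`` is the mean Phred quality of read 1.  Read 2
    supplies the first ``umi_length`` bases as the UMI.
    """
    from Bio import SeqIO

    r1_iter = SeqIO.parse(str(r1_path), "fastq")
    r2_iter = SeqIO.parse(str(r2_path), "fastq")
    for r1, r2 in zip(r1_iter, r2_iter):
        if r1.id != r2.id:
            raise ValueError(f"FASTQ pair out of sync: {r1.id} vs {r2.id}")
        seq1 = str(r1.seq).upper()
        quals = r1.letter_annotations["phred_quality"]
        yield ReadRecord(
            variable_region=seq1[:variable_length],
            umi=str(r2.seq)[:umi_length].upper(),
            mean_q=float(np.mean(quals)) if quals else 0.0,
            fraction_id=fraction_id,
            ts_suffix=seq1[variable_length:],
        )
    if next(r1_iter, None) is not None or next(r2_iter, None) is not None:
        raise ValueError("FASTQ pair has unequal read counts")


def write_paired_fastq(reads: Iterable[ReadRecord], r1_path, r2_path) -> None:
    """Write ReadRecords as a read-1/read-2 FASTQ pair (inverse of
    :func:`read_paired_fastq`; qualities are flat at each read's mean)."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for i, read in enumerate(reads):
            name = f"read{i:09d}"
            seq1 = read.variable_region + read.ts_suffix
            q1 = chr(min(int(round(read.mean_q)), 60) + 33) * len(seq1)
            q2 = "I" * len(read.umi)
            f1.write(f"@{name}\n{seq1}\n+\n{q1}\n")
            f2.write(f"@{name}\n{read.umi}\n+\n{q2}\n")


# ---------------------------------------------------------------------------
# read filtering


def parse_and_filter_reads(
    reads: Iterable[ReadRecord],
    ts_oligo: str | None,
    q_min: float = 25.0,
    max_edit: int = 5,
) -> Iterator[ReadRecord]:
    """Keep reads with mean q-score > q_min whose template-switch suffix is
    within ``max_edit`` edits of the expected oligo.

    ``ts_oligo=None`` disables the template-switch check (fixed-end
    libraries).  Drop counts are logged by reason.
    """
    n_in = n_q = n_ts = n_kept = 0
    for read in reads:
        n_in += 1
        if not (read.mean_q > q_min):
            n_q += 1
            continue
        if ts_oligo and edit_distance(read.ts_suffix, ts_oligo) > max_edit:
            n_ts += 1
            continue
        n_kept += 1
        yield read
    if n_in == 0:
        logger.warning("parse_and_filter_reads: empty input")
    logger.info(
        "parse_and_filter_reads: %d in, %d kept, %d dropped (q<=%.3g), %d dropped (TS edit>%d)",
        n_in, n_kept, n_q, q_min, n_ts, max_edit,
    )


# ---------------------------------------------------------------------------
# UMI collapse


def cluster_umis(umi_counts: Counter | dict[str, int]) -> int:
    """Number of UMI clusters under greedy directional Hamming-1 merging.

    Exact duplicates are merged first; then, visiting UMIs in descending
    count (ties broken lexicographically), any UMI within Hamming distance
    1 of an already-accepted, more-abundant UMI is merged into it.
    """
    if not umi_counts:
        return 0
    lengths = {len(u) for u in umi_counts}
    if len(lengths) != 1:
        raise ValueError(f"ragged UMI lengths: {sorted(lengths)}")
    order = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    rank = {u: i for i, u in enumerate(order)}
    cluster_of: dict[str, int] = {}
    alphabet = "ACGTN"
    n_clusters = 0
    for umi in order:
        best: str | None = None
        for i, base in enumerate(umi):
            for b in alphabet:
                if b == base:
                    continue
                neighbour = umi[:i] + b + umi[i + 1 :]
                if neighbour in cluster_of and (best is None or rank[neighbour] < rank[best]):
                    best = neighbour
        if best is not None:
            cluster_of[umi] = cluster_of[best]
        else:
            cluster_of[umi] = n_clusters
            n_clusters += 1
    return n_clusters


def collapse_umis(
    reads: Iterable[ReadRecord],
    fractions: Sequence[FractionSpec],
    replicate_id: str = "rep1",
    cell_type: str = "synthetic",
) -> FractionCountMatrix:
    """Group reads by (variant, fraction) and count UMI clusters."""
    groups: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for read in reads:
        variant = read.variant if read.variant is not None else read.variable_region
        groups[(variant, read.fraction_id)][read.umi] += 1
    fraction_index = {f.fraction_id: j for j, f in enumerate(fractions)}
    variants = sorted({v for v, _ in groups})
    counts = np.zeros((len(variants), len(fractions)), dtype=np.int64)
    vindex = {v: i for i, v in enumerate(variants)}
    for (variant, fraction_id), umis in groups.items():
        if fraction_id not in fraction_index:
            raise KeyError(f"read fraction {fraction_id!r} not in fraction specs")
        counts[vindex[variant], fraction_index[fraction_id]] = cluster_umis(umis)
    return FractionCountMatrix(variants, list(fractions), counts,
                               replicate_id=replicate_id, cell_type=cell_type)


# ---------------------------------------------------------------------------
# MRL


def compute_mrl(matrix: FractionCountMatrix) -> list[MRLRecord]:
    """Three-step MRL: depth-normalize fractions, ribosome-weight, renormalize.

    Free fractions are excluded from both sums.  Variants with zero counts
    across all loaded fractions are excluded from the output; total_reads
    is the raw UMI count across all fractions (free included).
    """
    loaded = matrix.loaded_mask
    counts = matrix.counts[:, loaded].astype(float)
    loads = np.array([f.ribosome_load for f in matrix.fractions])[loaded]
    totals = counts.sum(axis=0)
    zero = totals == 0
    if zero.any():
        names = np.array([f.fraction_id for f in matrix.fractions])[loaded][zero]
        raise ValueError(f"fractions with zero total count: {list(names)}")
    normalized = counts / totals
    denom = normalized.sum(axis=1)
    keep = denom > 0
    mrl = np.full(len(matrix.variants), np.nan)
    mrl[keep] = (normalized[keep] * loads).sum(axis=1) / denom[keep]
    all_reads = matrix.counts.sum(axis=1)
    return [
        MRLRecord(v, float(mrl[i]), int(all_reads[i]), matrix.replicate_id)
        for i, v in enumerate(matrix.variants)
        if keep[i]
    ]


def filter_and_average_replicates(
    tables: Sequence[Sequence[MRLRecord]],
    min_reads: int = 100,
) -> pd.DataFrame:
    """Read-depth filter across replicates plus depth-weighted MRL averaging.

    A variant is kept only if its per-replicate total read count is at
    least ``min_reads`` in *every* replicate.  The averaged MRL weights
    each replicate by its total UMI reads; combined depth is the sum.
    Returns a DataFrame indexed by variant with columns (mrl, reads,
    n_replicates).
    """
    if not tables:
        raise ValueError("at least one replicate required")
    frames = []
    for i, table in enumerate(tables):
        frames.append(pd.DataFrame(
            {"variant": [r.variant for r in table],
             "mrl": [r.mrl for r in table],
             "reads": [r.total_reads for r in table],
             "rep": i}))
    long = pd.concat(frames, ignore_index=True)
    ok = long[long["reads"] >= min_reads]
    present = ok.groupby("variant")["rep"].nunique()
    keep = present[present == len(tables)].index
    if len(keep) == 0:
        logger.warning("filter_and_average_replicates: no variant passes in all replicates")
    sub = ok[ok["variant"].isin(keep)]
    grouped = sub.groupby("variant", sort=True)
    weighted = grouped.apply(
        lambda g: np.average(g["mrl"], weights=g["reads"]), include_groups=False
    )
    out = pd.DataFrame({
        "mrl": weighted,
        "reads": grouped["reads"].sum(),
        "n_replicates": grouped["rep"].nunique(),
    })
    out.index.name = "variant"
    return out


# ---------------------------------------------------------------------------
# positional motif effects


def positional_median_effect(
    table: pd.DataFrame,
    motif_predicate: Callable[[str, int], bool],
    positions: Iterable[int],
    min_matches: int = 50,
    with_pvalues: bool = False,
) -> pd.DataFrame:
    """Median MRL of sequences with a motif at each position, normalized
    to the library-wide median.

    ``table`` must carry ``sequence`` and ``mrl`` columns; positions are
    0-based from the transcript start and the predicate receives the full
    transcript-coordinate sequence.  Positions with fewer than
    ``min_matches`` matching sequences get NaN (count still reported).
    A two-sided Mann-Whitney U p-value against the non-matching set is
    optional.
    """
    if not {"sequence", "mrl"} <= set(table.columns):
        raise ValueError("table must have 'sequence' and 'mrl' columns")
    sequences = table["sequence"].to_numpy()
    mrl = table["mrl"].to_numpy(dtype=float)
    library_median = float(np.median(mrl))
    rows = []
    for p in positions:
        mask = np.fromiter((motif_predicate(s, p) for s in sequences),
                           dtype=bool, count=len(sequences))
        n = int(mask.sum())
        row = {"position": p, "n": n, "normalized_median": np.nan, "pvalue": np.nan}
        if n >= min_matches:
            row["normalized_median"] = float(np.median(mrl[mask])) / library_median
            if with_pvalues and n < len(sequences):
                row["pvalue"] = float(mannwhitneyu(mrl[mask], mrl[~mask],
                                                  alternative="two-sided").pvalue)
        else:
            logger.info("position %d: only %d matches (< %d), omitted", p, n, min_matches)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("position")
    if not with_pvalues:
        out = out.drop(columns="pvalue")
    return out
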