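"""Seeded generators for every input the toolkit consumes.

A planted ground-truth sequence->MRL model drives all simulations: the
baseline MRL is perturbed by position- and frame-dependent upstream-AUG
penalties and a 5'-proximal oligopyrimidine bonus, and a monotone link
maps the MRL deficit to the probability of being ribosome-free.  From
there, polysome-fraction UMI counts, raw reads (with UMI duplication and
sequencing errors) and biphasic decay time series with spike-in controls
are generated, so the whole analysis stack can be exercised and validated
without any external data.  Every generator is a pure function of its
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .mpra import FractionCountMatrix, FractionSpec, ReadRecord, default_fractions
from .seqcore import ALPHABET, Architecture, Frame, UTRRecord, find_pyrimidine_tracts, scan_start_codons

__all__ = [
    "GroundTruthParams",
    "FractionSimSpec",
    "generate_library",
    "ground_truth_mrl",
    "ground_truth_mrl_batch",
    "simulate_fraction_counts",
    "simulate_reads",
    "simulate_decay",
    "mpra_scenario",
]


@dataclass(frozen=True)
class GroundTruthParams:
    """Planted sequence->MRL model.

    MRL = mu0 - sum(uAUG penalties) + sum(pyrimidine-tract bonuses),
    clipped below at ``clip_min``; penalties saturate with distance from
    the 5' end (attenuated 5'-proximally), out-of-frame uAUGs are
    penalized more than in-frame ones, and the pyrimidine bonus decays
    with position.  ``free_link`` maps MRL to the probability that a
    molecule sits in the ribosome-free fraction.
    """

    mu0: float = 5.0
    oof_penalty_max: float = 3.0
    if_penalty_max: float = 1.2
    penalty_halfway: float = 6.0
    pyr_boost0: float = 0.5
    pyr_decay: float = 10.0
    tract_length: int = 5
    noise_sigma: float = 0.3
    clip_min: float = 0.1
    phi_min: float = 0.02
    phi_max: float = 0.6
    phi_midpoint: float = 3.0
    phi_steepness: float = 1.0

    def penalty_oof(self, p: int) -> float:
        return self.oof_penalty_max * p / (p + self.penalty_halfway)

    def penalty_if(self, p: int) -> float:
        return self.if_penalty_max * p / (p + self.penalty_halfway)

    def pyr_boost(self, p: int) -> float:
        return self.pyr_boost0 * np.exp(-p / self.pyr_decay)

    def free_link(self, mrl: float | np.ndarray) -> float | np.ndarray:
        z = (self.phi_midpoint - np.asarray(mrl, dtype=float)) / self.phi_steepness
        return self.phi_min + (self.phi_max - self.phi_min) / (1.0 + np.exp(-z))


def generate_library(
    n: int,
    architecture: Architecture | str = Architecture.RANDOM_END_25,
    seed: int = 0,
    gc_bias: float | None = None,
    id_prefix: str = "utr",
) -> list[UTRRecord]:
    """Seeded i.i.d. random library with unique ids.

    ``gc_bias`` is the target G+C fraction (None = uniform 0.25 each);
    G and C (and A and T) are kept equiprobable within their class.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    arch = Architecture(architecture)
    rng = np.random.default_rng(seed)
    if gc_bias is None:
        probs = np.full(4, 0.25)
    else:
        if not 0 < gc_bias < 1:
            raise ValueError("gc_bias must be in (0, 1)")
        probs = np.array([(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2])
    codes = rng.choice(4, size=(n, arch.variable_length), p=probs)
    width = len(str(n))
    return [
        UTRRecord(
            id=f"{id_prefix}_{i:0{width}d}",
            sequence="".join(ALPHABET[c] for c in row),
            architecture=arch,
        )
        for i, row in enumerate(codes)
    ]


def ground_truth_mrl(
    record: UTRRecord,
    params: GroundTruthParams = GroundTruthParams(),
    with_noise: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """Planted MRL of one record (see GroundTruthParams)."""
    value = params.mu0
    for hit in scan_start_codons(record, {"ATG"}):
        if hit.frame is Frame.OUT_OF_FRAME:
            value -= params.penalty_oof(hit.position)
        else:
            value -= params.penalty_if(hit.position)
    for p in find_pyrimidine_tracts(record, params.tract_length):
        value += params.pyr_boost(p)
    value = max(value, params.clip_min)
    if with_noise:
        if rng is None:
            raise ValueError("with_noise=True requires an rng")
        value += rng.normal(0.0, params.noise_sigma)
    return float(value)


def ground_truth_mrl_batch(
    records: Sequence[UTRRecord],
    params: GroundTruthParams = GroundTruthParams(),
    noise_seed: int | None = None,
) -> np.ndarray:
    """Vector of planted MRLs; Gaussian noise added when a seed is given."""
    values = np.array([ground_truth_mrl(r, params) for r in records])
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        values = values + rng.normal(0.0, params.noise_sigma, size=len(values))
    return values


# ---------------------------------------------------------------------------
# fraction counts


@dataclass(frozen=True)
class FractionSimSpec:
    """Count-generating process for one polysome-profiling replicate.

    The occupancy family over loads {1..F} is a truncated Poisson whose
    parameter is matched per variant by monotone bisection.  With
    ``calibration='assay'`` (default) the matched statistic is the
    depth-normalized weighted mean the MRL formula measures, so the
    planted truth is exactly what the assay reports at infinite depth;
    ``'occupancy'`` matches the plain conditional-on-loaded mean instead.
    """

    n_fractions: int = 8
    depth_per_fraction: int = 200_000
    free_depth: int | None = None
    total_depth: int | None = None
    seed: int = 0
    calibration: str = "assay"

    @property
    def loads(self) -> np.ndarray:
        return np.arange(1, self.n_fractions + 1, dtype=float)


def _truncated_poisson_pmf(lam: np.ndarray, loads: np.ndarray) -> np.ndarray:
    """Poisson pmf restricted to the given loads, renormalized; (n, F)."""
    lam = np.asarray(lam, dtype=float)[:, None]
    logp = loads * np.log(lam) - lam - gammaln(loads + 1)
    p = np.exp(logp - logp.max(axis=1, keepdims=True))
    return p / p.sum(axis=1, keepdims=True)


def _match_weighted_mean(targets: np.ndarray, loads: np.ndarray,
                         weights: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Bisection for lambda s.t. the weights-reweighted truncated-Poisson
    mean of the loads equals each target (monotone in lambda)."""
    lo = np.full_like(targets, 1e-9)
    hi = np.full_like(targets, 500.0)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        q = _truncated_poisson_pmf(mid, loads) * weights
        mean = (q * loads).sum(axis=1) / q.sum(axis=1)
        too_low = mean < targets
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
        if (hi - lo).max() < tol:
            break
    return 0.5 * (lo + hi)


def occupancy_for_mrl(
    true_mrls: np.ndarray,
    spec: FractionSimSpec,
    loaded_weight: np.ndarray | None = None,
) -> np.ndarray:
    """Per-variant occupancy over loads {1..F} matching the target MRLs.

    ``loaded_weight`` is each variant's share of material that is loaded
    at all (1 - free probability); it scales the library totals the assay
    normalizes by and therefore enters the 'assay' calibration fixed
    point.
    """
    loads = spec.loads
    targets = np.asarray(true_mrls, dtype=float)
    lw = np.ones_like(targets) if loaded_weight is None else np.asarray(loaded_weight, dtype=float)
    eps = 1e-3
    if ((targets <= 1 + eps) | (targets >= spec.n_fractions - eps)).any():
        raise ValueError(
            f"target MRLs must lie in ({1 + eps}, {spec.n_fractions - eps}): "
            "a truncated-Poisson occupancy over loads 1..F cannot reach further"
        )
    weights = np.ones_like(loads)
    if spec.calibration == "occupancy":
        lam = _match_weighted_mean(targets, loads, weights)
        return _truncated_poisson_pmf(lam, loads)
    if spec.calibration != "assay":
        raise ValueError(f"unknown calibration {spec.calibration!r}")
    # fixed point: the assay reweights fraction f by 1 / (library total in f)
    q = None
    for _ in range(25):
        lam = _match_weighted_mean(targets, loads, weights)
        q = _truncated_poisson_pmf(lam, loads)
        new_weights = 1.0 / (lw[:, None] * q).sum(axis=0)
        new_weights = new_weights / new_weights.sum()
        if np.abs(new_weights - weights / weights.sum()).max() < 1e-12:
            weights = new_weights
            break
        weights = new_weights
    return q


def simulate_fraction_counts(
    records: Sequence[UTRRecord] | Sequence[str],
    true_mrls: Sequence[float],
    spec: FractionSimSpec = FractionSimSpec(),
    free_probs: Sequence[float] | None = None,
    params: GroundTruthParams = GroundTruthParams(),
    replicate_id: str = "rep1",
) -> tuple[FractionCountMatrix, np.ndarray]:
    """Multinomial UMI counts per fraction plus a total-RNA library.

    Returns ``(matrix, total_rna_counts)``; the matrix includes the
    ribosome-free fraction (flagged, excluded from MRL by compute_mrl).
    ``free_probs`` defaults to the ground-truth free link applied to the
    true MRLs.
    """
    ids = [r.id if isinstance(r, UTRRecord) else str(r) for r in records]
    m = np.asarray(true_mrls, dtype=float)
    if len(ids) != len(m):
        raise ValueError("records and true_mrls length mismatch")
    phi = params.free_link(m) if free_probs is None else np.asarray(free_probs, dtype=float)
    if ((phi <= 0) | (phi >= 1)).any() and not np.allclose(phi, np.clip(phi, 0, 1)):
        raise ValueError("free probabilities must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    q_loaded = occupancy_for_mrl(m, spec, loaded_weight=1 - phi)   # (n, F)
    occupancy = np.concatenate([phi[:, None], (1 - phi)[:, None] * q_loaded], axis=1)
    fractions = default_fractions(spec.n_fractions, include_free=True)
    counts = np.zeros((len(ids), len(fractions)), dtype=np.int64)
    free_depth = spec.free_depth or spec.depth_per_fraction
    for j, frac in enumerate(fractions):
        mass = occupancy[:, j]
        if mass.sum() == 0:
            continue
        depth = free_depth if frac.is_free else spec.depth_per_fraction
        counts[:, j] = rng.multinomial(depth, mass / mass.sum())
    total_depth = spec.total_depth or spec.depth_per_fraction
    total_rna = rng.multinomial(total_depth, np.full(len(ids), 1.0 / len(ids)))
    return (
        FractionCountMatrix(ids, fractions, counts, replicate_id=replicate_id),
        total_rna,
    )


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    matrix: FractionCountMatrix,
    umi_length: int = 10,
    duplication_rate: float = 0.0,
    error_rate: float = 0.0,
    ts_oligo: str = "ATTGGCCTGCGA",
    q_fail_fraction: float = 0.0,
    seed: int = 0,
    sequences: dict[str, str] | None = None,
) -> list[ReadRecord]:
    """Expand UMI counts into raw reads.

    Each counted molecule receives a random UMI and 1 + Geometric extra
    PCR duplicates (mean extra = duplication_rate / (1 - duplication_rate));
    sequencing errors hit UMI and template-switch suffix bases at
    ``error_rate`` per base per read, and a ``q_fail_fraction`` of reads
    draws a mean q-score below the q>25 filter.
    """
    if not (0 <= duplication_rate < 1 and 0 <= error_rate < 1):
        raise ValueError("rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    reads: list[ReadRecord] = []

    def mutate(s: str) -> str:
        if error_rate == 0.0:
            return s
        chars = list(s)
        for i in range(len(chars)):
            if rng.random() < error_rate:
                chars[i] = ALPHABET[rng.integers(4)]
        return "".join(chars)

    for i, variant in enumerate(matrix.variants):
        region = sequences.get(variant, variant) if sequences else variant
        for j, frac in enumerate(matrix.fractions):
            count = int(matrix.counts[i, j])
            # keep molecule UMIs >= 2 edits apart within a group (UMI space
            # far from saturated), so clustering merges only error copies
            taken: set[str] = set()
            separate = count * 31 * 10 < 4**umi_length
            for _ in range(count):
                while True:
                    umi = "".join(ALPHABET[c] for c in rng.integers(0, 4, size=umi_length))
                    if not separate or umi not in taken:
                        break
                if separate:
                    taken.add(umi)
                    for pos in range(umi_length):
                        for b in ALPHABET:
                            if b != umi[pos]:
                                taken.add(umi[:pos] + b + umi[pos + 1 :])
                n_copies = 1 + (rng.geometric(1 - duplication_rate) - 1 if duplication_rate > 0 else 0)
                for _ in range(n_copies):
                    fail = rng.random() < q_fail_fraction
                    mean_q = rng.uniform(15.0, 24.9) if fail else rng.uniform(28.0, 38.0)
                    reads.append(ReadRecord(
                        variable_region=region,
                        umi=mutate(umi),
                        mean_q=float(mean_q),
                        fraction_id=frac.fraction_id,
                        ts_suffix=mutate(ts_oligo),
                        variant=variant,
                    ))
    return reads


# ---------------------------------------------------------------------------
# decay kinetics


def simulate_decay(
    variants: Sequence[str],
    amplitudes: Sequence[float],
    k_fast: Sequence[float] | float,
    k_slow: Sequence[float] | float,
    fast_weight: Sequence[float] | float,
    timepoints_h: Sequence[float] = (0.5, 1, 2, 4, 8, 24),
    spike_concentrations: Sequence[float] = (1, 10, 100, 1000, 10000),
    depth: int = 1_000_000,
    loading: Sequence[float] | None = None,
    spike_share: float = 0.2,
    seed: int = 0,
    poisson_noise: bool = True,
) -> dict:
    """Biphasic decay count tables plus spike-ins and an input library.

    abundance_v(t) = A_v * (w_v e^{-k_fast t} + (1-w_v) e^{-k_slow t});
    at each timepoint a library of variant material plus a fixed spike-in
    mix (a ``spike_share`` of total material at t=0) is sequenced to
    ``depth`` reads.  Returns a dict with 'counts' (n_variants x T),
    'spikes' (5 x T), 'input_counts', 'timepoints_h', 'true_abundance'.
    """
    n = len(variants)
    t = np.asarray(timepoints_h, dtype=float)
    A = np.asarray(amplitudes, dtype=float)
    kf = np.broadcast_to(np.asarray(k_fast, dtype=float), (n,))
    ks = np.broadcast_to(np.asarray(k_slow, dtype=float), (n,))
    w = np.broadcast_to(np.asarray(fast_weight, dtype=float), (n,))
    if (kf <= 0).any() or (ks <= 0).any():
        raise ValueError("decay rates must be positive")
    if ((w < 0) | (w > 1)).any():
        raise ValueError("fast-phase weights must lie in [0, 1]")
    load = np.ones(n) if loading is None else np.asarray(loading, dtype=float)
    rng = np.random.default_rng(seed)

    true_abund = A[:, None] * (
        w[:, None] * np.exp(-kf[:, None] * t[None, :])
        + (1 - w[:, None]) * np.exp(-ks[:, None] * t[None, :])
    )  # (n, T)
    conc = np.asarray(spike_concentrations, dtype=float)
    spike_material = conc / conc.sum() * spike_share * (load * A).sum()

    counts = np.zeros((n, len(t)))
    spikes = np.zeros((len(conc), len(t)))
    for j in range(len(t)):
        material = np.concatenate([load * true_abund[:, j], spike_material])
        expected = depth * material / material.sum()
        drawn = rng.poisson(expected) if poisson_noise else expected
        counts[:, j] = drawn[:n]
        spikes[:, j] = drawn[n:]
    input_material = load / load.sum()
    input_expected = depth * input_material
    input_counts = rng.poisson(input_expected) if poisson_noise else input_expected
    return {
        "variants": list(variants),
        "timepoints_h": t,
        "counts": counts,
        "spikes": spikes,
        "spike_concentrations": conc,
        "input_counts": np.asarray(input_counts, dtype=float),
        "true_abundance": true_abund,
    }


# ---------------------------------------------------------------------------
# end-to-end MPRA scenario


def mpra_scenario(
    n_variants: int,
    n_replicates: int = 1,
    architecture: Architecture | str = Architecture.RANDOM_END_25,
    params: GroundTruthParams = GroundTruthParams(),
    sim: FractionSimSpec = FractionSimSpec(),
    seed: int = 0,
) -> dict:
    """Library + planted MRLs + per-replicate count matrices.

    True MRLs are clipped into the occupancy-achievable band
    (1+1e-3, F-1e-3) before count simulation; the clipped value is the
    recorded truth.  Replicate r uses seed ``seed*1000 + r``.
    """
    records = generate_library(n_variants, architecture, seed=seed)
    truth = ground_truth_mrl_batch(records, params)
    eps = 2e-3
    truth = np.clip(truth, 1 + eps, sim.n_fractions - eps)
    matrices = []
    totals = []
    for rep in range(n_replicates):
        rep_spec = replace(sim, seed=seed * 1000 + rep)
        matrix, total_rna = simulate_fraction_counts(
            records, truth, rep_spec, params=params, replicate_id=f"rep{rep + 1}"
        )
        matrices.append(matrix)
        totals.append(total_rna)
    return {
        "records": records,
        "true_mrl": truth,
        "matrices": matrices,
        "total_rna": totals,
        "params": params,
        "sim": sim,
    }
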