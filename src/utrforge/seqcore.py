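"""Sequence primitives shared across the toolkit.

Coordinates are 0-based from the transcript 5' end (the first G of the
IVT "GGG" for random-end libraries) and intervals are half-open.  The
internal alphabet is DNA; ``U`` is accepted on input and mapped to ``T``.
One-hot channel order is fixed to (A, C, G, T) everywhere.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

import edlib
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
CHANNEL_ORDER = {b: i for i, b in enumerate(ALPHABET)}

__all__ = [
    "Architecture",
    "UTRRecord",
    "OneHotMatrix",
    "Frame",
    "StartCodonHit",
    "AlphabetError",
    "SequenceLengthError",
    "clean_sequence",
    "one_hot_encode",
    "one_hot_decode",
    "encode_batch",
    "scan_start_codons",
    "find_pyrimidine_tracts",
    "kmer_log_features",
    "kmer_feature_names",
    "positional_3mer_features",
    "positional_3mer_dim",
    "edit_distance",
    "read_fasta",
    "write_fasta",
    "read_sequence_table",
]


class AlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T, U}."""


class SequenceLengthError(ValueError):
    """A sequence length is incompatible with the requested operation."""


class Architecture(str, Enum):
    """Library architecture of the variable 5'UTR region."""

    FIXED_END_50 = "fixed_end_50"
    RANDOM_END_25 = "random_end_25"
    RANDOM_END_50 = "random_end_50"

    @property
    def variable_length(self) -> int:
        return 25 if self is Architecture.RANDOM_END_25 else 50

    @property
    def default_prefix(self) -> str:
        # Random-end transcripts start with only the IVT G-triplet; the
        # fixed-end constant 25nt segment is configuration (not printed in
        # any primary source), so a placeholder ending in A is used, which
        # preserves the "initial UG creates a uAUG" hazard.
        if self is Architecture.FIXED_END_50:
            return "GGGACATTTGCTTCTGACACAACTA"
        return "GGG"


def clean_sequence(sequence: str, *, context: str = "sequence") -> str:
    """Uppercase, map U->T and validate the alphabet."""
    seq = sequence.strip().upper().replace("U", "T")
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise AlphabetError(
            f"{context} contains non-ACGT characters: {sorted(bad)!r}"
        )
    return seq


@dataclass(frozen=True)
class UTRRecord:
    """A variable 5'UTR region plus its transcript context.

    ``cds_offset`` is the 0-based transcript position of the A of the
    main-ORF AUG; for all supported architectures the main AUG starts
    immediately after the variable region, so
    ``cds_offset == len(prefix) + len(sequence)``.
    """

    id: str
    sequence: str
    architecture: Architecture = Architecture.RANDOM_END_25
    prefix: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", clean_sequence(self.sequence, context=f"record {self.id}"))
        arch = Architecture(self.architecture)
        object.__setattr__(self, "architecture", arch)
        prefix = arch.default_prefix if self.prefix is None else clean_sequence(self.prefix, context=f"prefix of {self.id}")
        object.__setattr__(self, "prefix", prefix)
        if len(self.sequence) != arch.variable_length:
            raise SequenceLengthError(
                f"record {self.id}: architecture {arch.value} requires a "
                f"{arch.variable_length}nt variable region, got {len(self.sequence)}nt"
            )
        if arch is not Architecture.FIXED_END_50 and prefix != "GGG":
            raise ValueError(f"record {self.id}: random-end architectures use the 'GGG' prefix")

    @property
    def transcript(self) -> str:
        """Prefix plus variable region, i.e. the full 5'UTR."""
        return self.prefix + self.sequence

    @property
    def cds_offset(self) -> int:
        return len(self.prefix) + len(self.sequence)


class Frame(str, Enum):
    IN_FRAME = "in_frame"
    OUT_OF_FRAME = "out_of_frame"


@dataclass(frozen=True)
class StartCodonHit:
    position: int
    codon: str
    frame: Frame


@dataclass
class OneHotMatrix:
    """L x 4 encoding with (A, C, G, T) channels, zero-padded on the left."""

    values: np.ndarray
    pad_columns: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 4:
            raise ValueError("one-hot matrix must have shape (L, 4)")


def one_hot_encode(record: UTRRecord | str, model_input_length: int | None = None) -> OneHotMatrix:
    """One-hot encode the variable region, left zero-padded to the model input length."""
    seq = record.sequence if isinstance(record, UTRRecord) else clean_sequence(record)
    length = len(seq) if model_input_length is None else int(model_input_length)
    if len(seq) > length:
        raise SequenceLengthError(
            f"sequence of length {len(seq)} exceeds model input length {length}"
        )
    pad = length - len(seq)
    out = np.zeros((length, 4), dtype=float)
    idx = np.fromiter((CHANNEL_ORDER[b] for b in seq), dtype=np.int64, count=len(seq))
    out[np.arange(pad, length), idx] = 1.0
    return OneHotMatrix(out, pad_columns=pad)


def one_hot_decode(matrix: OneHotMatrix | np.ndarray) -> str:
    values = matrix.values if isinstance(matrix, OneHotMatrix) else np.asarray(matrix)
    keep = values.sum(axis=1) > 0
    return "".join(ALPHABET[i] for i in values[keep].argmax(axis=1))


def encode_batch(sequences: Iterable[str], model_input_length: int) -> np.ndarray:
    """Stack one-hot encodings into an (N, L, 4) array."""
    mats = [one_hot_encode(s if isinstance(s, str) else s, model_input_length).values for s in sequences]
    return np.stack(mats) if mats else np.zeros((0, model_input_length, 4))


def scan_start_codons(
    record: UTRRecord | str,
    codon_set: Iterable[str] = ("ATG",),
    cds_offset: int | None = None,
) -> list[StartCodonHit]:
    """Find upstream start codons in the 5'UTR (prefix + variable region).

    Hits never overlap the main-ORF AUG: every reported position ``p``
    satisfies ``p + 3 <= cds_offset``.  Frame is classified relative to
    the main ORF: in-frame iff ``(cds_offset - p) % 3 == 0``.
    """
    codons = {clean_sequence(c, context="codon") for c in codon_set}
    if not codons:
        raise ValueError("codon_set must be non-empty")
    if isinstance(record, UTRRecord):
        transcript = record.transcript
        offset = record.cds_offset
    else:
        transcript = clean_sequence(record)
        offset = len(transcript) if cds_offset is None else int(cds_offset)
    hits = []
    for p in range(0, offset - 2):
        codon = transcript[p : p + 3]
        if codon in codons:
            frame = Frame.IN_FRAME if (offset - p) % 3 == 0 else Frame.OUT_OF_FRAME
            hits.append(StartCodonHit(position=p, codon=codon, frame=frame))
    return hits


def find_pyrimidine_tracts(record: UTRRecord | str, tract_length: int = 5) -> list[int]:
    """Positions of all (overlapping) runs of >= tract_length pyrimidines (C/T)."""
    if tract_length < 1:
        raise ValueError("tract_length must be >= 1")
    transcript = record.transcript if isinstance(record, UTRRecord) else clean_sequence(record)
    is_pyr = np.frombuffer(transcript.encode(), dtype=np.uint8)
    is_pyr = (is_pyr == ord("C")) | (is_pyr == ord("T"))
    if len(transcript) < tract_length:
        return []
    window = np.lib.stride_tricks.sliding_window_view(is_pyr, tract_length)
    return np.flatnonzero(window.all(axis=1)).tolist()


def _all_kmers(k: int) -> list[str]:
    return ["".join(t) for t in itertools.product(ALPHABET, repeat=k)]


def kmer_feature_names(k_min: int = 2, k_max: int = 6) -> list[str]:
    """Feature ordering: ascending k, lexicographic within each k."""
    names: list[str] = []
    for k in range(k_min, k_max + 1):
        names.extend(_all_kmers(k))
    return names


def _codes(sequence: str) -> np.ndarray:
    return np.fromiter((CHANNEL_ORDER[b] for b in sequence), dtype=np.int64, count=len(sequence))


def kmer_log_features(
    sequence: str | Sequence[str], k_min: int = 2, k_max: int = 6
) -> np.ndarray:
    """log2(1 + k-mer count) features for k = k_min..k_max.

    Dimension is sum_k 4^k (5,456 for k = 2..6).  Accepts a single
    sequence (returns a vector) or a list of equal-length sequences
    (returns an (N, D) float32 matrix).
    """
    if k_min > k_max or k_min < 1:
        raise ValueError("require 1 <= k_min <= k_max")
    single = isinstance(sequence, str)
    seqs = [sequence] if single else list(sequence)
    if not seqs:
        return np.zeros((0, sum(4**k for k in range(k_min, k_max + 1))), dtype=np.float32)
    for s in seqs:
        if len(s) < k_max:
            raise SequenceLengthError(f"sequence shorter than k_max={k_max}")
    codes = np.stack([_codes(clean_sequence(s)) for s in seqs])
    n, L = codes.shape
    blocks = []
    for k in range(k_min, k_max + 1):
        weights = 4 ** np.arange(k - 1, -1, -1)
        ids = np.zeros((n, L - k + 1), dtype=np.int64)
        for j in range(k):
            ids += codes[:, j : L - k + 1 + j] * weights[j]
        counts = np.zeros((n, 4**k), dtype=np.float32)
        np.add.at(counts, (np.repeat(np.arange(n), ids.shape[1]), ids.ravel()), 1.0)
        blocks.append(np.log2(1.0 + counts))
    out = np.concatenate(blocks, axis=1)
    return out[0] if single else out


def positional_3mer_dim(length: int) -> int:
    return (length - 2) * 64


def positional_3mer_features(sequence: str | Sequence[str]) -> np.ndarray:
    """Binary indicator per (offset, 3-mer); exactly L-2 ones per sequence."""
    single = isinstance(sequence, str)
    seqs = [sequence] if single else list(sequence)
    if not seqs:
        raise ValueError("no sequences given")
    codes = np.stack([_codes(clean_sequence(s)) for s in seqs])
    n, L = codes.shape
    if L < 3:
        raise SequenceLengthError("positional 3-mer features require length >= 3")
    ids = codes[:, :-2] * 16 + codes[:, 1:-1] * 4 + codes[:, 2:]
    cols = np.arange(L - 2) * 64 + ids
    out = np.zeros((n, (L - 2) * 64), dtype=np.float32)
    out[np.repeat(np.arange(n), L - 2), cols.ravel()] = 1.0
    return out[0] if single else out


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance (substitution/insertion/deletion)."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return int(edlib.align(a, b, task="distance")["editDistance"])


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path, architecture: Architecture | str | None = None) -> list[UTRRecord]:
    arch = Architecture(architecture) if architecture is not None else None
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = clean_sequence(str(rec.seq), context=f"FASTA record {rec.id}")
        a = arch or _infer_architecture(seq)
        records.append(UTRRecord(id=rec.id, sequence=seq, architecture=a))
    return records


def write_fasta(path, records: Iterable[UTRRecord]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description=r.architecture.value) for r in records),
        str(path),
        "fasta",
    )


def _infer_architecture(seq: str) -> Architecture:
    if len(seq) == 25:
        return Architecture.RANDOM_END_25
    if len(seq) == 50:
        return Architecture.RANDOM_END_50
    raise SequenceLengthError(f"cannot infer architecture for length {len(seq)}")


def read_sequence_table(path) -> list[UTRRecord]:
    """Read a TSV of (id, sequence, architecture) with strict validation."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in {"id", "variant", "name"}:
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            try:
                records.append(UTRRecord(id=parts[0], sequence=parts[1], architecture=Architecture(parts[2])))
            except (ValueError, AlphabetError, SequenceLengthError) as exc:
                raise type(exc)(f"{path}:{lineno}: {exc}") from exc
    return records
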