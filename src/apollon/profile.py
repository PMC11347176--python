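"""Per-position conservation analysis of a selected pool.

Builds position x base count matrices (read-weighted or unique-sequence
weighted), computes information content in bits for sequence-logo export,
extracts the consensus and high-information "core" ranges, and estimates
the synthesis doping rate from an unselected pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import UniqueSequenceTable

__all__ = [
    "PositionProfile",
    "build_profile",
    "information_content",
    "consensus_and_core",
    "ConsensusResult",
    "estimate_doping_rate",
    "DopingEstimate",
    "encode_table",
]

_BASE_INDEX = {b: k for k, b in enumerate("ACGT")}
BASES = "ACGT"


def encode_table(table: UniqueSequenceTable) -> tuple[np.ndarray, np.ndarray]:
    """Encode a uniform-length table as (codes[n_unique, L] int8, counts)."""
    if len(table) == 0:
        raise ValueError("empty table")
    seqs = list(table.entries)
    codes = np.frombuffer(
        "".join(seqs).encode("ascii"), dtype=np.uint8
    ).reshape(len(seqs), table.length)
    lut = np.full(256, -1, dtype=np.int8)
    for b, k in _BASE_INDEX.items():
        lut[ord(b)] = k
    enc = lut[codes]
    if (enc < 0).any():
        raise ValueError("table contains non-ACGT characters")
    counts = np.array([table.entries[s] for s in seqs], dtype=np.int64)
    return enc, counts


@dataclass(frozen=True)
class PositionProfile:
    """Counts matrix [position x {A,C,G,T}] with its weighting mode."""

    counts: np.ndarray  # float, shape (L, 4)
    weighting: str  # "reads" | "unique"

    def __post_init__(self) -> None:
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must have shape (L, 4)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        row_sums = self.counts.sum(axis=1)
        if not np.allclose(row_sums, row_sums[0]):
            raise ValueError("every position must have the same total weight")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.counts[0].sum())

    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(BASES))
        df.insert(0, "position", np.arange(1, self.length + 1))
        return df

    def to_tsv(self, path: str | Path) -> None:
        """TSV export (position, A, C, G, T, IC, consensus) for logo plotters."""
        df = self.to_frame()
        df["IC"] = information_content(self)
        df["consensus"] = [BASES[k] for k in np.argmax(self.counts, axis=1)]
        df.to_csv(path, sep="\t", index=False)


def build_profile(
    table: UniqueSequenceTable, weighting: str = "reads"
) -> PositionProfile:
    """Accumulate per-position base counts from a uniform-length table.

    Read-weighted mode adds each sequence's read count to its base cells
    (abundance reflects activity after selection); unique mode adds 1 per
    distinct sequence.
    """
    if weighting not in ("reads", "unique"):
        raise ValueError(f"unknown weighting {weighting!r}")
    enc, counts = encode_table(table)
    if weighting == "unique":
        counts = np.ones_like(counts)
    L = enc.shape[1]
    prof = np.zeros((L, 4))
    for b in range(4):
        prof[:, b] = np.where(enc == b, counts[:, None], 0).sum(axis=0)
    return PositionProfile(prof.astype(float), weighting)


def information_content(profile: PositionProfile) -> np.ndarray:
    """Per-position information content IC = 2 - H, H in bits over ACGT.

    No small-sample correction is applied; bounds are 0 <= IC <= 2 with
    IC = 2 exactly when a column is single-base.
    """
    freqs = profile.frequencies()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -terms.sum(axis=1)
    return 2.0 - entropy


def _merged_ranges(positions: np.ndarray) -> list[tuple[int, int]]:
    """Collapse sorted 1-based positions into closed ranges."""
    ranges: list[tuple[int, int]] = []
    for p in positions:
        if ranges and p == ranges[-1][1] + 1:
            ranges[-1] = (ranges[-1][0], int(p))
        else:
            ranges.append((int(p), int(p)))
    return ranges


@dataclass(frozen=True)
class ConsensusResult:
    consensus: str
    core_positions: tuple[int, ...]  # 1-based
    core_ranges: tuple[tuple[int, int], ...]
    tied_positions: tuple[int, ...]  # consensus ties broken by fixed A<C<G<T order


def consensus_and_core(
    profile: PositionProfile, ic_threshold: float = 1.0
) -> ConsensusResult:
    """Consensus string and merged 1-based ranges of high-information positions."""
    if not 0.0 < ic_threshold <= 2.0:
        raise ValueError("ic_threshold must be in (0, 2]")
    ic = information_content(profile)
    consensus_idx = np.argmax(profile.counts, axis=1)  # ties -> lowest index (A<C<G<T)
    maxima = profile.counts.max(axis=1, keepdims=True)
    ties = (profile.counts == maxima).sum(axis=1) > 1
    core = np.flatnonzero(ic >= ic_threshold) + 1
    return ConsensusResult(
        consensus="".join(BASES[k] for k in consensus_idx),
        core_positions=tuple(int(p) for p in core),
        core_ranges=tuple(_merged_ranges(core)),
        tied_positions=tuple(int(p) for p in np.flatnonzero(ties) + 1),
    )


@dataclass(frozen=True)
class DopingEstimate:
    rate: float
    se: float
    per_position: np.ndarray


def estimate_doping_rate(
    profile: PositionProfile, reference: str
) -> DopingEstimate:
    """Estimate the per-position mutagenesis rate of an unselected pool.

    The per-position estimate is 1 minus the frequency of the reference
    base; the reported rate is the mean over positions and the standard
    error comes from the across-position variance. Unbiased only on
    unselected pools: selection depletes non-reference bases at constrained
    positions.
    """
    if len(reference) != profile.length:
        raise ValueError(
            f"reference length {len(reference)} != profile length {profile.length}"
        )
    freqs = profile.frequencies()
    ref_idx = np.array([_BASE_INDEX[b] for b in reference])
    per_pos = 1.0 - freqs[np.arange(profile.length), ref_idx]
    se = float(per_pos.std(ddof=1) / np.sqrt(profile.length)) if profile.length > 1 else 0.0
    return DopingEstimate(rate=float(per_pos.mean()), se=se, per_position=per_pos)
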