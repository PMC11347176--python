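"""Synthetic-data engine: doped libraries and in vitro selection rounds.

A doped library is synthesized from a reference sequence with a fixed
per-position probability of substituting one of the three non-reference
bases (here 21% per position over an 85-nt region, as in the reselection
that optimized the deoxyribozyme). Selection is modeled as per-molecule
Bernoulli survival with probability equal to the molecule's activity,
followed by unbiased (multinomial) amplification back to the working pool
size; sequencing of each round draws a fixed number of reads from the
survivors. Incubation-time stringency is abstracted into the activity scale.

Pool complexity in a real selection (~1e14 molecules) is far beyond desk
scale; ``pool_size`` is an explicitly scaled-down knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import UniqueSequenceTable
from .structmodel import StructureModel, formable_pairs

__all__ = [
    "DopingModel",
    "FitnessModel",
    "SelectionConfig",
    "ConstructLayout",
    "SelectionResult",
    "PoolExtinctionError",
    "sample_pool",
    "variant_activity",
    "run_selection",
    "ligated_length",
    "simulate_kinetics",
]

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: k for k, b in enumerate("ACGT")}


@dataclass(frozen=True)
class DopingModel:
    """Reference sequence + per-position mutation rate + alternative-base mix.

    ``alt_dist`` gives the probabilities of the three non-reference bases in
    alphabetical order of the alternatives; the default synthesis mixture is
    uniform (1/3 each).
    """

    reference: str
    rate: float = 0.21
    alt_dist: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if not self.reference:
            raise ValueError("reference must be non-empty")
        if set(self.reference) - set("ACGT"):
            raise ValueError("reference must be over ACGT")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("doping rate must be in [0, 1]")
        if abs(sum(self.alt_dist) - 1.0) > 1e-9 or any(p < 0 for p in self.alt_dist):
            raise ValueError("alt_dist must be a distribution over 3 bases")

    @property
    def length(self) -> int:
        return len(self.reference)


@dataclass(frozen=True)
class FitnessModel:
    """Generative fitness: conserved-core and stem-formation requirements.

    A variant is fully active (``active_level``) iff it mismatches the core
    consensus at no more than ``core_tolerance`` positions AND can form at
    least the required number of pairs in every listed stem; otherwise it
    sits at ``background_level``. ``mode='graded'`` instead scales activity
    by the fraction of satisfied constraints (for power studies).
    """

    core: dict[int, str] = field(default_factory=dict)  # 1-based pos -> consensus base
    core_tolerance: int = 0
    stems: tuple[tuple[str, int], ...] = ()  # (stem name, min formable pairs)
    active_level: float = 1.0
    background_level: float = 0.01
    mode: str = "binary"  # "binary" | "graded"

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_level <= self.active_level <= 1.0:
            raise ValueError("need 0 <= background_level <= active_level <= 1")
        if self.mode not in ("binary", "graded"):
            raise ValueError(f"unknown fitness mode {self.mode!r}")


@dataclass(frozen=True)
class SelectionConfig:
    pool_size: int
    rounds: int
    reads_per_round: int
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.pool_size, self.rounds, self.reads_per_round) < 1:
            raise ValueError("pool_size, rounds and reads_per_round must be positive")


@dataclass(frozen=True)
class ConstructLayout:
    """Length bookkeeping through the round protocol (insert + primer site + tag)."""

    insert_length: int
    primer_site_length: int
    tag_length: int

    def __post_init__(self) -> None:
        if min(self.insert_length, self.primer_site_length, self.tag_length) < 0:
            raise ValueError("lengths must be >= 0")


def ligated_length(layout: ConstructLayout) -> int:
    """Total construct length after ligation of the tag.

    An 85-nt mutagenized insert with a 20-nt primer-binding site runs as a
    105-nt pool molecule, and as a 125-nt product once the 20-nt ligation
    tag is attached.
    """
    return layout.insert_length + layout.primer_site_length + layout.tag_length


class PoolExtinctionError(RuntimeError):
    """No molecule survived a selection round."""

    def __init__(self, round_index: int):
        self.round_index = round_index
        super().__init__(f"pool went extinct in selection round {round_index}")


def _decode(rows: np.ndarray) -> list[str]:
    return ["".join(s) for s in _BASES[rows]]


def sample_pool_codes(
    model: DopingModel, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``n`` doped molecules as an (n, L) int8 base-code matrix."""
    L = model.length
    ref_codes = np.array([_BASE_INDEX[b] for b in model.reference], dtype=np.int8)
    rows = np.tile(ref_codes, (n, 1))
    mutate = rng.random((n, L)) < model.rate
    # alternatives of base r, in alphabetical order: the 3 codes != r
    alt_table = np.array(
        [[c for c in range(4) if c != r] for r in range(4)], dtype=np.int8
    )
    alt_idx = rng.choice(3, size=(n, L), p=np.asarray(model.alt_dist))
    rows[mutate] = alt_table[rows[mutate], alt_idx[mutate]]
    return rows


def sample_pool(model: DopingModel, n: int, seed: int) -> UniqueSequenceTable:
    """Draw ``n`` i.i.d. doped-library molecules.

    Each position independently mutates with probability ``model.rate`` to a
    base drawn from ``model.alt_dist`` over the three non-reference bases.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows = sample_pool_codes(model, n, rng)
    return UniqueSequenceTable.from_sequences(_decode(rows))


def variant_activity(
    seq: str, fitness: FitnessModel, structure: StructureModel | None = None
) -> float:
    """Activity in [0, 1] of one variant under the generative fitness."""
    if structure is not None and len(seq) != structure.sequence_length:
        raise ValueError(
            f"sequence length {len(seq)} != model length {structure.sequence_length}"
        )
    checks: list[bool] = []
    if fitness.core:
        mismatches = sum(seq[pos - 1] != base for pos, base in fitness.core.items())
        checks.append(mismatches <= fitness.core_tolerance)
    for stem_name, min_pairs in fitness.stems:
        if structure is None:
            raise ValueError("fitness lists stems but no structure model given")
        k = formable_pairs(seq, structure.stem(stem_name)).formable
        checks.append(k >= min_pairs)
    if not checks:
        return fitness.active_level
    if fitness.mode == "graded":
        frac = sum(checks) / len(checks)
        return fitness.background_level + (
            fitness.active_level - fitness.background_level
        ) * frac
    return fitness.active_level if all(checks) else fitness.background_level


@dataclass
class SelectionResult:
    """Per-round sequencing tables and survival fractions."""

    round_tables: list[UniqueSequenceTable]
    survival_fractions: list[float]
    final_pool: UniqueSequenceTable

    @property
    def rounds(self) -> int:
        return len(self.round_tables)


def _sample_table(
    seqs: list[str], weights: np.ndarray, n: int, rng: np.random.Generator
) -> UniqueSequenceTable:
    counts = rng.multinomial(n, weights / weights.sum())
    entries = {s: int(c) for s, c in zip(seqs, counts) if c > 0}
    return UniqueSequenceTable(entries)


def run_selection(
    model: DopingModel,
    fitness: FitnessModel,
    structure: StructureModel | None,
    cfg: SelectionConfig,
) -> SelectionResult:
    """Simulate selection rounds over a doped pool.

    Round r+1's pool is a multinomial resample (size ``pool_size``, i.e.
    unbiased PCR amplification) of round r's survivors, where each molecule
    survives with probability equal to its activity. ``reads_per_round``
    sequencing reads are drawn from the survivors of each round.
    """
    rng = np.random.default_rng(cfg.seed)
    pool = sample_pool(model, cfg.pool_size, seed=int(rng.integers(2**31)))

    activity_cache: dict[str, float] = {}

    def activity(seq: str) -> float:
        if seq not in activity_cache:
            activity_cache[seq] = variant_activity(seq, fitness, structure)
        return activity_cache[seq]

    round_tables: list[UniqueSequenceTable] = []
    survival_fractions: list[float] = []
    for r in range(1, cfg.rounds + 1):
        seqs = list(pool.entries)
        counts = np.array([pool.entries[s] for s in seqs], dtype=np.int64)
        acts = np.array([activity(s) for s in seqs])
        survivors = rng.binomial(counts, acts)
        total_in, total_out = counts.sum(), survivors.sum()
        survival_fractions.append(total_out / total_in)
        if total_out == 0:
            raise PoolExtinctionError(r)
        keep = survivors > 0
        surv_seqs = [s for s, k in zip(seqs, keep) if k]
        surv_counts = survivors[keep].astype(float)
        round_tables.append(
            _sample_table(surv_seqs, surv_counts, cfg.reads_per_round, rng)
        )
        pool = _sample_table(surv_seqs, surv_counts, cfg.pool_size, rng)
    return SelectionResult(round_tables, survival_fractions, pool)


def simulate_kinetics(
    preset,
    concentrations: Sequence[float],
    noise_sd_frac: float = 0.05,
    seed: int = 0,
):
    """Draw noisy initial rates from a Michaelis-Menten preset.

    Rates are ``v(S) * (1 + N(0, noise_sd_frac))`` truncated at zero, one
    per substrate concentration; see :mod:`apollon.kinetics` for presets
    and fitting.
    """
    from .kinetics import KineticDataset, mm_v0

    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("substrate concentrations must be positive")
    if noise_sd_frac < 0:
        raise ValueError("noise_sd_frac must be >= 0")
    rng = np.random.default_rng(seed)
    v_true = mm_v0(preset.vmax, preset.km, conc)
    v = v_true * (1.0 + rng.normal(0.0, noise_sd_frac, size=conc.shape))
    v = np.clip(v, 0.0, None)
    return KineticDataset(
        substrate=conc, rate=v, enzyme_conc=preset.enzyme_conc,
        conc_unit="M", rate_unit="M/min",
    )
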