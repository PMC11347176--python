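"""Secondary-structure models, stem-pairing statistics, and imino-signal bookkeeping.

A :class:`StructureModel` lists base pairs (typed canonical or wobble) grouped
into named stems. Operations score the pairing potential of sequence variants
against a stem, compute the exact chance distribution of that potential under
a doped-synthesis null (Poisson binomial over per-pair complementarity
probabilities), and count the distinct imino-proton NMR signals a model
predicts: one per canonical pair, two per G-T/T-G wobble pair (the two
tautomeric forms of guanine and thymine each give a resonance in the
12-15 ppm window).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .seqio import UniqueSequenceTable

if TYPE_CHECKING:  # pragma: no cover
    from .doped_pool import DopingModel

__all__ = [
    "BasePair",
    "StructureModel",
    "PairingPotential",
    "pair_complementary",
    "formable_pairs",
    "stem_statistic",
    "StemStatistic",
    "pair_probability",
    "null_pairing_distribution",
    "PairingNull",
    "expected_imino_signals",
    "delete_stem",
    "apollon_reference",
    "apollon_structure",
]

_BASES = frozenset("ACGT")
_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class BasePair:
    """One base pair: 1-based positions i < j, typed canonical or wobble."""

    i: int
    j: int
    kind: str = "canonical"  # "canonical" | "wobble"

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValueError(f"pair positions must satisfy i < j, got ({self.i}, {self.j})")
        if self.kind not in ("canonical", "wobble"):
            raise ValueError(f"unknown pair kind {self.kind!r}")


@dataclass(frozen=True)
class StructureModel:
    """Named stems of typed base pairs on a sequence of fixed length."""

    stems: dict[str, tuple[BasePair, ...]]
    sequence_length: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for name, pairs in self.stems.items():
            for p in pairs:
                for pos in (p.i, p.j):
                    if not 1 <= pos <= self.sequence_length:
                        raise ValueError(
                            f"stem {name!r}: position {pos} outside 1..{self.sequence_length}"
                        )
                    if pos in seen:
                        raise ValueError(f"position {pos} appears in two pairs")
                    seen.add(pos)

    @property
    def pairs(self) -> tuple[BasePair, ...]:
        return tuple(p for pairs in self.stems.values() for p in pairs)

    def n_canonical(self) -> int:
        return sum(p.kind == "canonical" for p in self.pairs)

    def n_wobble(self) -> int:
        return sum(p.kind == "wobble" for p in self.pairs)

    def stem(self, name: str) -> tuple[BasePair, ...]:
        if name not in self.stems:
            raise KeyError(f"unknown stem {name!r}; have {sorted(self.stems)}")
        return self.stems[name]

    def to_dot_bracket(self) -> str:
        chars = ["."] * self.sequence_length
        for p in self.pairs:
            chars[p.i - 1] = "("
            chars[p.j - 1] = ")"
        return "".join(chars)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("i\tj\ttype\tstem\n")
            for name, pairs in self.stems.items():
                for p in pairs:
                    fh.write(f"{p.i}\t{p.j}\t{p.kind}\t{name}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, sequence_length: int) -> "StructureModel":
        from .seqio import read_tsv_lines

        stems: dict[str, list[BasePair]] = {}
        lines = read_tsv_lines(path)
        if not lines or not lines[0].startswith("i\t"):
            raise ValueError(f"{path}: missing 'i\\tj\\ttype\\tstem' header")
        for line in lines[1:]:
            i, j, kind, stem = line.split("\t")
            stems.setdefault(stem, []).append(BasePair(int(i), int(j), kind))
        return cls({k: tuple(v) for k, v in stems.items()}, sequence_length)


@dataclass(frozen=True)
class PairingPotential:
    """How many of a stem's pairs a variant can form."""

    per_pair: tuple[bool, ...]

    @property
    def formable(self) -> int:
        return sum(self.per_pair)

    @property
    def total(self) -> int:
        return len(self.per_pair)


def pair_complementary(a: str, b: str, allow_gu: bool = True) -> bool:
    """True if (a, b) can base-pair: Watson-Crick, plus G-T/T-G if allow_gu."""
    if a not in _BASES or b not in _BASES:
        raise ValueError(f"bases must be in ACGT, got ({a!r}, {b!r})")
    return (a, b) in _WC or (allow_gu and (a, b) in _WOBBLE)


def formable_pairs(
    seq: str, stem: Sequence[BasePair], allow_gu: bool = True
) -> PairingPotential:
    """Evaluate a variant's bases at each stem pair for complementarity."""
    max_pos = max((p.j for p in stem), default=0)
    if len(seq) < max_pos:
        raise ValueError(
            f"sequence length {len(seq)} shorter than stem extent {max_pos}"
        )
    per_pair = tuple(
        pair_complementary(seq[p.i - 1], seq[p.j - 1], allow_gu) for p in stem
    )
    return PairingPotential(per_pair)


@dataclass(frozen=True)
class StemStatistic:
    """Pairing potential across the high-count variants of a pool."""

    min_k: int | None
    histogram: dict[int, int]  # k -> number of qualifying variants
    variants: tuple[tuple[str, int, int], ...]  # (sequence, count, k)

    @property
    def empty(self) -> bool:
        return self.min_k is None


def stem_statistic(
    table: UniqueSequenceTable,
    stem: Sequence[BasePair],
    read_floor: int = 1,
    allow_gu: bool = True,
) -> StemStatistic:
    """Distribution of formable-pair counts among variants with count >= floor."""
    variants: list[tuple[str, int, int]] = []
    hist: dict[int, int] = {}
    for seq, count in table:
        if count < read_floor:
            continue
        k = formable_pairs(seq, stem, allow_gu).formable
        variants.append((seq, count, k))
        hist[k] = hist.get(k, 0) + 1
    if not variants:
        return StemStatistic(None, {}, ())
    return StemStatistic(
        min(k for _, _, k in variants), hist, tuple(sorted(variants, key=lambda v: -v[1]))
    )


@dataclass(frozen=True)
class PairingNull:
    """Exact Poisson-binomial null for a stem's formable-pair count.

    ``pmf[k]`` is the chance a single doped-library molecule can form
    exactly k of the stem's pairs; ``tail(t)`` gives P(k >= t).
    """

    per_pair_prob: tuple[float, ...]
    pmf: np.ndarray

    def tail(self, t: int) -> float:
        if t <= 0:
            return 1.0
        return float(self.pmf[t:].sum())

    def joint_tail(self, t: int, m: int) -> float:
        """P(m independent doped molecules ALL form >= t pairs) = tail(t)^m."""
        return self.tail(t) ** m


def _position_base_probs(model: "DopingModel", pos: int) -> dict[str, float]:
    """Base distribution at a 1-based position under the doping model."""
    ref = model.reference[pos - 1]
    probs = {b: 0.0 for b in "ACGT"}
    probs[ref] = 1.0 - model.rate
    alts = [b for b in "ACGT" if b != ref]
    for b, p in zip(alts, model.alt_dist):
        probs[b] += model.rate * p
    return probs


def pair_probability(
    model: "DopingModel", pair: BasePair, allow_gu: bool = True
) -> float:
    """Exact complementarity probability of one pair under doped synthesis.

    Enumerates the 16 dinucleotide outcomes at the pair's two positions
    (mutations at distinct positions are independent).
    """
    pi = _position_base_probs(model, pair.i)
    pj = _position_base_probs(model, pair.j)
    return sum(
        pi[a] * pj[b]
        for a in "ACGT"
        for b in "ACGT"
        if pair_complementary(a, b, allow_gu)
    )


def null_pairing_distribution(
    model: "DopingModel", stem: Sequence[BasePair], allow_gu: bool = True
) -> PairingNull:
    """Exact chance distribution of formable pairs in an unselected pool.

    Each pair forms independently with its own probability, so the count of
    formable pairs is Poisson-binomial; the pmf is built by convolution.
    """
    probs = tuple(pair_probability(model, p, allow_gu) for p in stem)
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return PairingNull(probs, pmf)


def expected_imino_signals(model: StructureModel) -> int:
    """Distinct imino-proton signals predicted: 1 per canonical, 2 per wobble pair."""
    return model.n_canonical() + 2 * model.n_wobble()


def delete_stem(model: StructureModel, stem_name: str) -> StructureModel:
    """Return the model without the named stem's pairs."""
    if stem_name not in model.stems:
        raise KeyError(f"unknown stem {stem_name!r}; have {sorted(model.stems)}")
    stems = {k: v for k, v in model.stems.items() if k != stem_name}
    return replace(model, stems=stems)


# ---------------------------------------------------------------------------
# Packaged reconstruction of the Apollon secondary-structure fixture.
#
# The reported structure facts are: an 85-nt mutagenized region; conserved
# catalytic core at positions 1-8 and 34-64; three stems; position 3 pairing
# with position 22 (Stem 1, supported by a double mutant cycle); Stem 2 made
# of four deletable canonical pairs; Stem 3 of eight pairs in the
# near-invariant G-rich core; 12 canonical plus 4 G-T/T-G pairs in total.
# Exact pair coordinates are not reported anywhere, so the fixture below is a
# SYNTHETIC reconstruction consistent with all of the above; analyses that
# depend only on pair composition (imino-signal counts) are coordinate-free.
# ---------------------------------------------------------------------------

_STEM1 = tuple(BasePair(i, 25 - i) for i in (1, 2, 3, 4))  # includes (3, 22)
# Stem 2 avoids the 34-64 core: a hairpin closing 9..18
_STEM2 = tuple(BasePair(i, 27 - i) for i in (9, 10, 11, 12))  # (9,18)...(12,15)
_STEM3 = tuple(
    BasePair(i, 104 - i, kind=("wobble" if i % 2 == 0 else "canonical"))
    for i in range(40, 48)
)  # (40,64)...(47,57): 4 canonical + 4 wobble, inside core 34-64


def apollon_structure() -> StructureModel:
    """Reconstructed three-stem model: 12 canonical + 4 wobble pairs, L=85."""
    return StructureModel(
        {"Stem1": _STEM1, "Stem2": _STEM2, "Stem3": _STEM3}, sequence_length=85
    )


def apollon_reference(seed: int = 20240613) -> str:
    """Synthetic 85-nt reference sequence consistent with the packaged model.

    Unpaired positions are filled deterministically from ``seed``; paired
    positions are made complementary (G-T at wobble pairs, Watson-Crick at
    canonical pairs) so the reference forms every stem by construction.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=85))
    partner = {"A": "T", "T": "A", "G": "C", "C": "G"}
    for p in apollon_structure().pairs:
        if p.kind == "wobble":
            seq[p.i - 1], seq[p.j - 1] = "G", "T"
        else:
            if seq[p.i - 1] not in partner:  # pragma: no cover
                seq[p.i - 1] = "G"
            seq[p.j - 1] = partner[seq[p.i - 1]]
    return "".join(seq)
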