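"""Pairwise covariation analysis for base-pair inference, plus mutant cycles.

Covarying position pairs whose joint changes are complementary are evidence
of base pairing. The statistic is mutual information (MI) of the joint base
distribution at two positions, reported with a pairing-consistency fraction
(among sequences deviating from the reference at both positions, the
weighted fraction whose bases can pair) and a Monte-Carlo p-value against a
doped-synthesis null: unselected pools of matched size generated from the
doping model. Benjamini-Hochberg q-values are reported across the
L(L-1)/2 pairs.

Double and triple mutant cycles score interaction between positions from an
activity table: a double mutant much more active than the multiplicative
expectation from the single mutants indicates a restored interaction
(compensatory base pair).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .doped_pool import DopingModel, sample_pool_codes
from .profile import encode_table
from .seqio import UniqueSequenceTable
from .structmodel import pair_complementary

__all__ = [
    "CovariationResult",
    "ActivityTable",
    "MutantCycleResult",
    "PairingConsistency",
    "mutual_information",
    "pairing_consistency",
    "covariation_scan",
    "mutant_cycle",
]


def _pair_indices(L: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(L, k=1)
    return iu[0], iu[1]


def _joint_counts(
    enc: np.ndarray, counts: np.ndarray, ii: np.ndarray, jj: np.ndarray
) -> np.ndarray:
    """Weighted 16-bin joint base histograms for each requested pair.

    Computes the full (4, 4, L, L) cross tabulation with one matrix product
    per base combination (BLAS does the heavy lifting), then gathers the
    requested (i, j) pairs. Returns shape (n_pairs, 16) with bin 4*a+b
    counting weight with base code a at position i and b at position j.
    """
    onehot = [(enc == a).astype(np.float64) for a in range(4)]
    weighted = [counts[:, None] * oh for oh in onehot]
    L = enc.shape[1]
    joint = np.empty((4, 4, L, L))
    for a in range(4):
        for b in range(4):
            joint[a, b] = weighted[a].T @ onehot[b]
    return joint[:, :, ii, jj].reshape(16, len(ii)).T


def _mi_from_joint(joint: np.ndarray) -> np.ndarray:
    """MI in bits from (n_pairs, 16) joint histograms."""
    totals = joint.sum(axis=1, keepdims=True)
    p = joint / totals
    p4 = p.reshape(-1, 4, 4)
    pi = p4.sum(axis=2)  # marginal at i
    pj = p4.sum(axis=1)  # marginal at j
    indep = pi[:, :, None] * pj[:, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p4 > 0, p4 * np.log2(p4 / indep), 0.0)
    return np.clip(terms.sum(axis=(1, 2)), 0.0, None)


def mutual_information(
    table: UniqueSequenceTable, i: int, j: int, weighting: str = "reads"
) -> float:
    """Mutual information in bits between the bases at 1-based positions i, j."""
    if i == j:
        raise ValueError("positions must differ")
    for pos in (i, j):
        if not 1 <= pos <= table.length:
            raise ValueError(f"position {pos} outside 1..{table.length}")
    enc, counts = encode_table(table)
    if weighting == "unique":
        counts = np.ones_like(counts)
    elif weighting != "reads":
        raise ValueError(f"unknown weighting {weighting!r}")
    a, b = min(i, j) - 1, max(i, j) - 1
    joint = _joint_counts(enc, counts.astype(float), np.array([a]), np.array([b]))
    return float(_mi_from_joint(joint)[0])


@dataclass(frozen=True)
class PairingConsistency:
    """Complementarity among double-deviant sequences at a position pair."""

    fraction: float | None  # None when no double-deviant exists (undefined)
    n_double_deviant_reads: int

    @property
    def defined(self) -> bool:
        return self.fraction is not None


def pairing_consistency(
    table: UniqueSequenceTable,
    i: int,
    j: int,
    reference: str,
    allow_gu: bool = True,
) -> PairingConsistency:
    """Read-weighted complementary fraction among sequences deviating at both i and j."""
    if i == j:
        raise ValueError("positions must differ")
    comp_w = 0
    total_w = 0
    ri, rj = reference[i - 1], reference[j - 1]
    for seq, count in table:
        a, b = seq[i - 1], seq[j - 1]
        if a == ri or b == rj:
            continue
        total_w += count
        if pair_complementary(a, b, allow_gu):
            comp_w += count
    if total_w == 0:
        return PairingConsistency(None, 0)
    return PairingConsistency(comp_w / total_w, total_w)


@dataclass(frozen=True)
class CovariationResult:
    i: int
    j: int
    mi: float
    pairing_consistency: float | None
    null_p: float
    q: float


def covariation_scan(
    table: UniqueSequenceTable,
    model: DopingModel,
    n_null: int = 200,
    seed: int = 0,
    allow_gu: bool = True,
    weighting: str = "reads",
) -> list[CovariationResult]:
    """Scan all position pairs for covariation against a doping-model null.

    For each pair i<j the observed MI is compared to the MI of the same pair
    in ``n_null`` unselected pools sampled from the doping model at matched
    read depth; ``null_p`` is the fraction of null pools with MI at least as
    large (add-one Monte-Carlo estimator). Results carry BH q-values and are
    sorted by null_p, then MI descending.
    """
    if n_null < 100:
        raise ValueError("n_null must be >= 100 for usable p-values")
    if table.length != model.length:
        raise ValueError("table length != doping-model reference length")
    enc, counts = encode_table(table)
    if weighting == "unique":
        counts = np.ones_like(counts)
    ii, jj = _pair_indices(table.length)
    obs_mi = _mi_from_joint(_joint_counts(enc, counts.astype(float), ii, jj))

    rng = np.random.default_rng(seed)
    depth = int(counts.sum())
    exceed = np.zeros_like(obs_mi)
    ones = np.ones(depth)
    for _ in range(n_null):
        nenc = sample_pool_codes(model, depth, rng)
        null_mi = _mi_from_joint(_joint_counts(nenc, ones, ii, jj))
        exceed += null_mi >= obs_mi
    null_p = (1.0 + exceed) / (n_null + 1.0)
    q = false_discovery_control(null_p, method="bh")

    ref = model.reference
    results = []
    for k in range(len(ii)):
        pc = pairing_consistency(
            table, int(ii[k]) + 1, int(jj[k]) + 1, ref, allow_gu
        )
        results.append(
            CovariationResult(
                i=int(ii[k]) + 1,
                j=int(jj[k]) + 1,
                mi=float(obs_mi[k]),
                pairing_consistency=pc.fraction,
                null_p=float(null_p[k]),
                q=float(q[k]),
            )
        )
    results.sort(key=lambda r: (r.null_p, -r.mi))
    return results


def scan_to_frame(results: list[CovariationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "i": [r.i for r in results],
            "j": [r.j for r in results],
            "mi": [r.mi for r in results],
            "pairing_consistency": [r.pairing_consistency for r in results],
            "null_p": [r.null_p for r in results],
            "q": [r.q for r in results],
        }
    )


def scan_to_tsv(results: list[CovariationResult], path: str | Path) -> None:
    scan_to_frame(results).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ActivityTable:
    """Labeled relative activities of a mutant-cycle experiment.

    Labels follow the cube convention: ``wt``, singles ``m1``/``m2`` (and
    ``m3``), doubles ``m12``/``m13``/``m23``, triple ``m123``. Zero or
    negative activities are floored at ``floor_frac * wt`` so ratios stay
    defined; floored labels are recorded.
    """

    activities: dict[str, float]
    floor_frac: float = 0.001

    def floored(self) -> tuple[dict[str, float], tuple[str, ...]]:
        wt = self.activities.get("wt")
        if wt is None or wt <= 0:
            raise ValueError("activity table requires wt > 0")
        floor = self.floor_frac * wt
        out, flagged = {}, []
        for label, a in self.activities.items():
            if a < floor:
                out[label] = floor
                flagged.append(label)
            else:
                out[label] = a
        return out, tuple(flagged)

    @classmethod
    def from_tsv(cls, path: str | Path, floor_frac: float = 0.001) -> "ActivityTable":
        from .seqio import read_tsv_lines

        acts: dict[str, float] = {}
        lines = read_tsv_lines(path)
        if not lines or not lines[0].startswith("label"):
            raise ValueError(f"{path}: missing 'label\\tactivity' header")
        for line in lines[1:]:
            label, value = line.split("\t")
            acts[label] = float(value)
        return cls(acts, floor_frac)


@dataclass(frozen=True)
class MutantCycleResult:
    ratio: float
    verdict: str  # "rescue" | "independent" | "aggravating"
    order: int  # 2 or 3
    floored_labels: tuple[str, ...]


def _verdict(ratio: float, rescue_threshold: float) -> str:
    if ratio >= rescue_threshold:
        return "rescue"
    if ratio < 1.0:
        return "aggravating"
    return "independent"


def mutant_cycle(
    acts: ActivityTable, rescue_threshold: float = 5.0
) -> MutantCycleResult:
    """Interaction ratio of a double (or triple) mutant cycle.

    Double: R = (A_m12 * A_wt) / (A_m1 * A_m2). Under multiplicative
    independence R = 1; R >= ``rescue_threshold`` is called a rescue
    (disrupt-and-restore pattern of a base pair); R < 1 aggravating.
    Triple (when the m3 family is present): the third-order ratio over the
    2^3 cube, R = (A_m123 * A_m1 * A_m2 * A_m3) / (A_m12 * A_m13 * A_m23 *
    A_wt), which is 1 under pairwise multiplicativity. Both are invariant
    to rescaling all activities by a common factor.
    """
    a, floored = acts.floored()
    triple = any(k in acts.activities for k in ("m3", "m13", "m23", "m123"))
    required = (
        ("wt", "m1", "m2", "m3", "m12", "m13", "m23", "m123")
        if triple
        else ("wt", "m1", "m2", "m12")
    )
    missing = [k for k in required if k not in a]
    if missing:
        raise ValueError(f"activity table missing corner(s): {', '.join(missing)}")
    if triple:
        ratio = (a["m123"] * a["m1"] * a["m2"] * a["m3"]) / (
            a["m12"] * a["m13"] * a["m23"] * a["wt"]
        )
        order = 3
    else:
        ratio = (a["m12"] * a["wt"]) / (a["m1"] * a["m2"])
        order = 2
    return MutantCycleResult(float(ratio), _verdict(ratio, rescue_threshold), order, floored)
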