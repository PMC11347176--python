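"""Structure models: pairing potential, exact chance nulls, imino-signal counts."""

import numpy as np
import pytest

from apollon.doped_pool import DopingModel
from apollon.structmodel import (
    BasePair,
    StructureModel,
    apollon_reference,
    apollon_structure,
    delete_stem,
    expected_imino_signals,
    formable_pairs,
    null_pairing_distribution,
    pair_complementary,
    pair_probability,
    stem_statistic,
)
from apollon.seqio import UniqueSequenceTable


class TestPairComplementary:
    @pytest.mark.parametrize(
        "a, b, gu, expected",
        [
            ("G", "C", False, True),
            ("A", "T", False, True),
            ("G", "T", True, True),
            ("T", "G", True, True),
            ("G", "T", False, False),
            ("A", "C", True, False),
        ],
    )
    def test_pairing_rules(self, a, b, gu, expected):
        assert pair_complementary(a, b, allow_gu=gu) is expected

    def test_non_base_rejected(self):
        with pytest.raises(ValueError):
            pair_complementary("G", "U")


class TestFormablePairs:
    def test_reference_forms_every_stem(self, reference, structure):
        for name in structure.stems:
            fp = formable_pairs(reference, structure.stem(name))
            assert fp.formable == fp.total

    def test_single_break_and_compensation(self, reference, structure):
        stem3 = structure.stem("Stem3")
        pair = stem3[1]  # a canonical pair
        broken = list(reference)
        broken[pair.i - 1] = {"A": "C", "C": "A", "G": "A", "T": "C"}[
            reference[pair.i - 1]
        ]
        assert formable_pairs("".join(broken), stem3).formable == 7
        # compensatory change at the partner restores complementarity
        partner = {"A": "T", "T": "A", "G": "C", "C": "G"}[broken[pair.i - 1]]
        broken[pair.j - 1] = partner
        assert formable_pairs("".join(broken), stem3).formable == 8

    def test_length_mismatch_raises(self, structure):
        with pytest.raises(ValueError):
            formable_pairs("ACGT", structure.stem("Stem3"))


class TestStemStatistic:
    def test_histogram_and_min(self, reference, structure):
        stem1 = structure.stem("Stem1")
        broken = "C" * 4 + reference[4:]  # kills all 4 Stem 1 pairs? no: breaks (1..4)
        table = UniqueSequenceTable({reference: 10, broken: 3})
        stat = stem_statistic(table, stem1, read_floor=1)
        assert stat.min_k == formable_pairs(broken, stem1).formable
        assert stat.histogram[4] == 1

    def test_read_floor_excludes_rare_variants(self, reference, structure):
        broken = "C" * 4 + reference[4:]
        table = UniqueSequenceTable({reference: 10, broken: 3})
        stat = stem_statistic(table, structure.stem("Stem1"), read_floor=5)
        assert stat.min_k == 4
        assert len(stat.variants) == 1

    def test_floor_above_all_counts_is_empty(self, reference, structure):
        table = UniqueSequenceTable({reference: 2})
        stat = stem_statistic(table, structure.stem("Stem1"), read_floor=100)
        assert stat.empty


def _brute_force_pair_probability(model, pair, allow_gu=True):
    """Independent oracle: enumerate the 16 dinucleotide outcomes directly."""
    probs = {}
    for pos in (pair.i, pair.j):
        ref = model.reference[pos - 1]
        dist = {b: 0.0 for b in "ACGT"}
        dist[ref] = 1 - model.rate
        for b, p in zip([x for x in "ACGT" if x != ref], model.alt_dist):
            dist[b] += model.rate * p
        probs[pos] = dist
    total = 0.0
    for a in "ACGT":
        for b in "ACGT":
            if pair_complementary(a, b, allow_gu):
                total += probs[pair.i][a] * probs[pair.j][b]
    return total


class TestNullPairingDistribution:
    def test_zero_doping_concentrates_at_full_pairing(self, reference, structure):
        model = DopingModel(reference, 0.0)
        null = null_pairing_distribution(model, structure.stem("Stem3"))
        assert null.pmf[-1] == pytest.approx(1.0)
        assert null.tail(8) == pytest.approx(1.0)

    def test_gc_pair_probability_enumeration(self):
        # reference G-C pair at 21% doping, uniform alternatives, G.T allowed
        model = DopingModel("GC", 0.21)
        pair = BasePair(1, 2)
        p = pair_probability(model, pair, allow_gu=True)
        assert p == pytest.approx(_brute_force_pair_probability(model, pair))
        assert p == pytest.approx(0.699, abs=5e-4)

    def test_at_pair_probability_matches_enumeration(self):
        # one wobble outcome involves a reference base, exactly as for G-C
        model = DopingModel("AT", 0.21)
        pair = BasePair(1, 2)
        p = pair_probability(model, pair, allow_gu=True)
        assert p == pytest.approx(_brute_force_pair_probability(model, pair))
        assert p == pytest.approx(0.699, abs=5e-4)

    def test_pmf_sums_to_one(self, doping_model, structure):
        for name in structure.stems:
            null = null_pairing_distribution(doping_model, structure.stem(name))
            assert null.pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_exact_tail_matches_monte_carlo(self, doping_model, structure):
        from apollon.doped_pool import sample_pool_codes

        stem = structure.stem("Stem3")
        null = null_pairing_distribution(doping_model, stem)
        rng = np.random.default_rng(8)
        n = 100_000
        rows = sample_pool_codes(doping_model, n, rng)
        bases = np.array(list("ACGT"))
        ks = np.zeros(n, dtype=int)
        for p in stem:
            a = bases[rows[:, p.i - 1]]
            b = bases[rows[:, p.j - 1]]
            ok = np.zeros(n, dtype=bool)
            for x, y in [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")]:
                ok |= (a == x) & (b == y)
            ks += ok
        for t in range(len(stem) + 1):
            exact = null.tail(t)
            mc = (ks >= t).mean()
            se = np.sqrt(max(exact * (1 - exact), 1e-12) / n)
            assert abs(mc - exact) <= max(3 * se, 2e-3)

    def test_joint_chance_is_tail_power(self, doping_model, structure):
        null = null_pairing_distribution(doping_model, structure.stem("Stem3"))
        t = 7
        for m in (2, 5, 10):
            assert null.joint_tail(t, m) == pytest.approx(null.tail(t) ** m)
        # ten independent high-count variants all pairing >= 7/8 is a rare event
        assert null.joint_tail(7, 10) < 1e-4


class TestIminoSignals:
    def test_full_model_signal_count(self, structure):
        assert structure.n_canonical() == 12
        assert structure.n_wobble() == 4
        assert expected_imino_signals(structure) == 20

    def test_stem2_deletion_signal_count(self, structure):
        reduced = delete_stem(structure, "Stem2")
        assert expected_imino_signals(reduced) == 16

    def test_empty_model_is_zero(self):
        assert expected_imino_signals(StructureModel({}, 10)) == 0

    def test_additive_over_disjoint_stems(self, structure):
        total = sum(
            expected_imino_signals(StructureModel({n: structure.stems[n]}, 85))
            for n in structure.stems
        )
        assert total == expected_imino_signals(structure)

    def test_unknown_stem_rejected(self, structure):
        with pytest.raises(KeyError):
            delete_stem(structure, "Stem9")


class TestStructureModelInvariants:
    def test_position_in_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            StructureModel({"S": (BasePair(1, 5), BasePair(5, 9))}, 10)

    def test_pair_order_enforced(self):
        with pytest.raises(ValueError):
            BasePair(7, 3)

    def test_tsv_round_trip(self, structure, tmp_path):
        path = tmp_path / "structure.tsv"
        structure.to_tsv(path)
        back = StructureModel.from_tsv(path, structure.sequence_length)
        assert set(back.pairs) == set(structure.pairs)

    def test_dot_bracket_is_balanced(self, structure):
        db = structure.to_dot_bracket()
        assert len(db) == 85
        assert db.count("(") == db.count(")") == 16
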