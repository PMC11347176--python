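"""Doped-pool sampling, generative fitness, and selection dynamics."""

import numpy as np
import pytest

from apollon.doped_pool import (
    ConstructLayout,
    DopingModel,
    FitnessModel,
    PoolExtinctionError,
    SelectionConfig,
    ligated_length,
    run_selection,
    sample_pool,
    simulate_kinetics,
    variant_activity,
)
from apollon.kinetics import APOLLON_2, fit_mm, mm_v0
from apollon.structmodel import BasePair, StructureModel


class TestSamplePool:
    def test_zero_doping_reproduces_reference(self, reference):
        table = sample_pool(DopingModel(reference, 0.0), 100, seed=1)
        assert table.entries == {reference: 100}

    def test_same_seed_is_deterministic(self, doping_model):
        t1 = sample_pool(doping_model, 2000, seed=5)
        t2 = sample_pool(doping_model, 2000, seed=5)
        assert t1.entries == t2.entries

    def test_per_position_mutation_rate_unbiased(self, doping_model, reference):
        # estimator within 3 standard errors of the 21% synthesis rate
        n = 50_000
        table = sample_pool(doping_model, n, seed=11)
        ref = np.frombuffer(reference.encode(), dtype=np.uint8)
        mismatch = 0
        for seq, count in table:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            mismatch += count * int((arr != ref).sum())
        est = mismatch / (n * len(reference))
        se = np.sqrt(0.21 * 0.79 / (n * len(reference)))
        assert abs(est - 0.21) < 3 * se

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            DopingModel("ACGT", 1.5)


class TestVariantActivity:
    @pytest.fixture()
    def toy(self):
        # 10-nt reference with a single 3-pair stem: (1,10) (2,9) (3,8)
        structure = StructureModel(
            {"S": (BasePair(1, 10), BasePair(2, 9), BasePair(3, 8))}, 10
        )
        reference = "GGGAATTCCC"
        fitness = FitnessModel(
            core={4: "A", 5: "A"},
            core_tolerance=0,
            stems=(("S", 3),),
            active_level=1.0,
            background_level=0.01,
        )
        return reference, structure, fitness

    def test_reference_is_active(self, toy):
        ref, structure, fitness = toy
        assert variant_activity(ref, fitness, structure) == 1.0

    def test_core_mutation_beyond_tolerance_is_background(self, toy):
        ref, structure, fitness = toy
        mutated = ref[:3] + "C" + ref[4:]
        assert variant_activity(mutated, fitness, structure) == 0.01

    def test_single_stem_break_is_background(self, toy):
        ref, structure, fitness = toy
        broken = "C" + ref[1:]  # (1,10) becomes C-C
        assert variant_activity(broken, fitness, structure) == 0.01

    def test_compensatory_double_mutant_is_active(self, toy):
        ref, structure, fitness = toy
        # G-C pair at (1,10) replaced by A-T: still complementary
        swapped = "A" + ref[1:9] + "T"
        assert variant_activity(swapped, fitness, structure) == 1.0

    def test_length_mismatch_raises(self, toy):
        ref, structure, fitness = toy
        with pytest.raises(ValueError):
            variant_activity(ref + "A", fitness, structure)

    def test_graded_mode_interpolates(self, toy):
        ref, structure, _ = toy
        fitness = FitnessModel(
            core={4: "A"},
            stems=(("S", 3),),
            active_level=1.0,
            background_level=0.0,
            mode="graded",
        )
        broken = "C" + ref[1:]  # stem fails, core holds: 1 of 2 constraints
        assert variant_activity(broken, fitness, structure) == pytest.approx(0.5)


class TestLigatedLength:
    @pytest.mark.parametrize(
        "layout, expected",
        [
            ((85, 20, 20), 125),  # full ligated construct
            ((85, 20, 0), 105),  # pool molecule before tagging
            ((0, 0, 0), 0),
        ],
    )
    def test_construct_length_bookkeeping(self, layout, expected):
        assert ligated_length(ConstructLayout(*layout)) == expected


class TestRunSelection:
    def _config(self, **kw):
        defaults = dict(pool_size=5000, rounds=3, reads_per_round=2000, seed=3)
        defaults.update(kw)
        return SelectionConfig(**defaults)

    def test_round_tables_conserve_read_depth(self, doping_model, structure):
        fitness = FitnessModel(stems=(("Stem1", 4),))
        res = run_selection(doping_model, fitness, structure, self._config())
        assert all(t.total_reads == 2000 for t in res.round_tables)

    def test_neutral_fitness_survival_matches_activity(self, doping_model):
        fitness = FitnessModel(active_level=0.5, background_level=0.5)
        res = run_selection(doping_model, fitness, None, self._config(pool_size=20000))
        se = np.sqrt(0.5 * 0.5 / 20000)
        assert abs(res.survival_fractions[0] - 0.5) < 4 * se

    def test_first_round_survival_equals_mean_pool_activity(self, doping_model, structure):
        fitness = FitnessModel(
            stems=(("Stem1", 4),), active_level=1.0, background_level=0.01
        )
        cfg = self._config(pool_size=30000)
        res = run_selection(doping_model, fitness, structure, cfg)
        # expected mean activity: P(all 4 Stem 1 pairs formable) under doping
        from apollon.structmodel import null_pairing_distribution

        null = null_pairing_distribution(doping_model, structure.stem("Stem1"))
        p_active = null.tail(4)
        expected = p_active * 1.0 + (1 - p_active) * 0.01
        assert res.survival_fractions[0] == pytest.approx(expected, rel=0.1)

    def test_fit_variant_dominates_after_selection(self, reference, doping_model):
        # activity 1.0 iff position 1 keeps the reference base, else 0.01:
        # expected frequency follows f' = f/(f + (1-f)*0.01) each round
        fitness = FitnessModel(
            core={1: reference[0]}, active_level=1.0, background_level=0.01
        )
        res = run_selection(doping_model, fitness, None, self._config(pool_size=30000))
        f = 0.79
        for table in res.round_tables:
            f = f / (f + (1 - f) * 0.01)
            observed = (
                sum(c for s, c in table if s[0] == reference[0]) / table.total_reads
            )
            assert observed == pytest.approx(f, abs=0.02)
        assert observed > 0.99

    def test_extinction_raises_naming_round(self, doping_model):
        fitness = FitnessModel(active_level=0.0, background_level=0.0)
        with pytest.raises(PoolExtinctionError, match="round 1"):
            run_selection(doping_model, fitness, None, self._config())

    def test_seeded_determinism(self, doping_model, structure):
        fitness = FitnessModel(stems=(("Stem1", 4),))
        r1 = run_selection(doping_model, fitness, structure, self._config())
        r2 = run_selection(doping_model, fitness, structure, self._config())
        assert r1.survival_fractions == r2.survival_fractions
        assert all(
            a.entries == b.entries for a, b in zip(r1.round_tables, r2.round_tables)
        )


class TestSimulateKinetics:
    conc = np.geomspace(1e-6, 1.5e-3, 8)

    def test_noiseless_rates_on_curve(self):
        ds = simulate_kinetics(APOLLON_2, self.conc, 0.0, seed=0)
        np.testing.assert_allclose(
            ds.rate, mm_v0(APOLLON_2.vmax, APOLLON_2.km, self.conc)
        )

    def test_rate_at_km_is_half_vmax(self):
        ds = simulate_kinetics(APOLLON_2, [APOLLON_2.km], 0.0, seed=0)
        assert ds.rate[0] == pytest.approx(APOLLON_2.vmax / 2)

    def test_noiseless_refit_recovers_preset_exactly(self):
        ds = simulate_kinetics(APOLLON_2, self.conc, 0.0, seed=0)
        fit = fit_mm(ds)
        assert fit.vmax == pytest.approx(APOLLON_2.vmax, rel=1e-6)
        assert fit.km == pytest.approx(APOLLON_2.km, rel=1e-6)

    def test_seeded_determinism(self):
        a = simulate_kinetics(APOLLON_2, self.conc, 0.05, seed=9)
        b = simulate_kinetics(APOLLON_2, self.conc, 0.05, seed=9)
        np.testing.assert_array_equal(a.rate, b.rate)
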