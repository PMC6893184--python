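"""Selection-engine primitives and the Fn / DH scheme runners."""

import numpy as np
import pytest

from recgain.errors import (
    DegenerateTraitError,
    InvalidCountError,
    PanelMismatchError,
)
from recgain.meiosis import cross, founder
from recgain.selection import (
    GSModel,
    LociLayout,
    SchemeConfig,
    calibrate_VE,
    gebv,
    genotype_matrix,
    genotypic_value,
    phenotype,
    run_dh_scheme,
    run_fn_scheme,
    run_scheme,
    truncation_select,
)
from recgain.selection import _f1_origins, _values_from_origins
from recgain.meiosis import meiosis_batch


def small_layout(genome, trait, scenario="normal", markers=50):
    return LociLayout.build(genome.spec.landscapes[scenario], trait, markers)


class TestGenotypicValue:
    def test_founders_are_opposite(self, small_genome, small_trait, rng):
        lsc = small_genome.spec.landscapes["normal"]
        p1, p2 = founder(lsc, 0), founder(lsc, 1)
        g1 = genotypic_value(p1, small_trait)
        g2 = genotypic_value(p2, small_trait)
        expect = sum(
            float(np.sum(s * a))
            for s, a in zip(small_trait.sign_p1["normal"], small_trait.amplitude)
        )
        assert g1 == pytest.approx(expect)
        assert g2 == pytest.approx(-expect)

    def test_f1_is_zero(self, small_genome, small_trait, rng):
        lsc = small_genome.spec.landscapes["normal"]
        f1 = cross(founder(lsc, 0), founder(lsc, 1), lsc, rng)
        assert genotypic_value(f1, small_trait) == pytest.approx(0.0)

    def test_engine_agrees_with_segment_api(self, small_genome, small_trait):
        """Dual-route check: array engine vs per-individual segment sums."""
        layout = small_layout(small_genome, small_trait)
        lsc = small_genome.spec.landscapes["normal"]
        for which, expect_sign in ((0, 1.0), (1, -1.0)):
            origins = np.full((1, 2, layout.n_loci), which, dtype=np.uint8)
            v = _values_from_origins(origins, layout)[0]
            assert v == pytest.approx(
                expect_sign * genotypic_value(founder(lsc, 0), small_trait)
            )


class TestTraitState:
    def test_ve_from_h2(self):
        vals = np.array([0.0, 4.0, -4.0, 2.0, -2.0])
        vg = np.var(vals, ddof=1)
        st = calibrate_VE(vals, 0.5)
        assert st.V_E == pytest.approx(vg)
        st = calibrate_VE(vals, 0.2)
        assert st.V_E == pytest.approx(vg * 4.0)

    def test_h2_one_means_no_noise(self, rng):
        st = calibrate_VE(np.array([1.0, 2.0, 3.0]), 1.0)
        assert st.V_E == 0.0
        p = phenotype(np.array([5.0, 6.0]), st, rng)
        assert p == pytest.approx([5.0, 6.0])

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateTraitError):
            calibrate_VE(np.ones(10), 0.5)

    def test_noise_variance(self, rng):
        st = calibrate_VE(np.array([0.0, 2.0, -2.0, 1.0]), 0.5)
        g = np.zeros(10**5)
        p = phenotype(g, st, rng)
        assert np.var(p) == pytest.approx(st.V_E, rel=0.03)

    def test_realized_f2_heritability(self, small_genome, small_trait):
        rng = np.random.default_rng(0)
        layout = small_layout(small_genome, small_trait)
        f1 = _f1_origins(layout.n_loci)
        idx = np.zeros(10**4, dtype=np.intp)
        origins = np.stack(
            [
                meiosis_batch(f1[idx], layout.chrom_pos, layout.GL, None, rng),
                meiosis_batch(f1[idx], layout.chrom_pos, layout.GL, None, rng),
            ],
            axis=1,
        )
        g = _values_from_origins(origins, layout)
        st = calibrate_VE(g, 0.5)
        p = phenotype(g, st, rng)
        assert np.var(g) / np.var(p) == pytest.approx(0.5, abs=0.02)


class TestGenotypeMatrix:
    def test_founder_coding(self, small_genome, small_trait):
        layout = small_layout(small_genome, small_trait)
        p1 = np.zeros((1, 2, layout.n_loci), np.uint8)
        p2 = np.ones((1, 2, layout.n_loci), np.uint8)
        f1 = _f1_origins(layout.n_loci)
        assert np.all(genotype_matrix(p1, layout) == -1)
        assert np.all(genotype_matrix(p2, layout) == 1)
        assert np.all(genotype_matrix(f1, layout) == 0)

    def test_f2_column_moments(self, small_genome, small_trait):
        rng = np.random.default_rng(1)
        layout = small_layout(small_genome, small_trait)
        f1 = _f1_origins(layout.n_loci)
        idx = np.zeros(5000, dtype=np.intp)
        origins = np.stack(
            [
                meiosis_batch(f1[idx], layout.chrom_pos, layout.GL, None, rng),
                meiosis_batch(f1[idx], layout.chrom_pos, layout.GL, None, rng),
            ],
            axis=1,
        )
        Z = genotype_matrix(origins, layout).astype(float)
        se = 3 * np.sqrt(0.5 / 5000)
        assert np.all(np.abs(Z.mean(axis=0)) < se + 0.02)
        assert Z.var(axis=0).mean() == pytest.approx(0.5, abs=0.02)

    def test_dh_population_has_no_heterozygotes(self, small_genome, small_trait):
        rng = np.random.default_rng(2)
        layout = small_layout(small_genome, small_trait)
        f1 = _f1_origins(layout.n_loci)
        idx = np.zeros(200, dtype=np.intp)
        gam = meiosis_batch(f1[idx], layout.chrom_pos, layout.GL, None, rng)
        Z = genotype_matrix(np.stack([gam, gam], axis=1), layout)
        assert not np.any(Z == 0)


class TestGebvAndSelect:
    def test_gebv_formula(self):
        model = GSModel(beta=2.0, u=np.array([1.0, -1.0]), trained_at=2)
        Z = np.array([[1, 0], [-1, 1]])
        assert gebv(Z, model) == pytest.approx([3.0, 0.0])

    def test_gebv_zero_effects(self):
        model = GSModel(beta=0.5, u=np.zeros(3), trained_at=2)
        assert gebv(np.zeros((4, 3), int), model) == pytest.approx([0.5] * 4)

    def test_panel_mismatch(self):
        model = GSModel(beta=0.0, u=np.zeros(3), trained_at=2)
        with pytest.raises(PanelMismatchError):
            gebv(np.zeros((2, 4), int), model)

    def test_select_top(self, rng):
        vals = np.arange(1, 251, dtype=float)
        sel = truncation_select(vals, 5, rng)
        assert sorted(vals[sel]) == [246, 247, 248, 249, 250]

    def test_select_all(self, rng):
        sel = truncation_select(np.zeros(7), 7, rng)
        assert sorted(sel) == list(range(7))

    def test_tie_break_uniform(self):
        rng = np.random.default_rng(0)
        counts = np.zeros(6)
        for _ in range(3000):
            sel = truncation_select(np.zeros(6), 2, rng)
            counts[sel] += 1
        freq = counts / 6000
        assert np.all(np.abs(freq - 1 / 6) < 3 * np.sqrt((1 / 6) * (5 / 6) / 6000))

    def test_select_too_many(self, rng):
        with pytest.raises(InvalidCountError):
            truncation_select(np.zeros(3), 4, rng)


def _quick_cfg(**kw):
    base = dict(pop_size=60, n_selected=5, n_generations=8, markers_per_chrom=40)
    base.update(kw)
    return SchemeConfig(**base)


class TestFnScheme:
    def test_gain_zero_at_g2_and_shapes(self, small_genome, small_trait):
        traj = run_fn_scheme(
            _quick_cfg(),
            small_genome.spec.landscapes["normal"],
            small_trait,
            np.random.default_rng(0),
        )
        assert traj.generations[0] == 2
        assert traj.generations[-1] == 8
        assert traj.gain(2) == 0.0
        assert len(traj.mean_G) == 7

    def test_training_schedule_flags(self, small_genome, small_trait):
        traj = run_fn_scheme(
            _quick_cfg(n_generations=10, recalibration="every_4"),
            small_genome.spec.landscapes["normal"],
            small_trait,
            np.random.default_rng(0),
        )
        trained_gens = traj.generations[traj.gs_trained]
        assert list(trained_gens) == [2, 6, 10]

    def test_fixation_with_strong_selection(self, small_genome):
        from recgain.synth import build_trait

        trait = build_trait(small_genome, 1, np.random.default_rng(8))
        traj = run_fn_scheme(
            _quick_cfg(
                pop_size=100, n_selected=2, n_generations=16,
                selection_mode="phenotypic", h2=1.0,
            ),
            small_genome.spec.landscapes["normal"],
            trait,
            np.random.default_rng(0),
        )
        assert traj.var_G[-1] == pytest.approx(0.0, abs=1e-12)
        assert traj.mean_G[-1] == pytest.approx(trait.gain_ceiling())

    def test_drift_is_martingale_without_selection(self, small_genome, small_trait):
        changes = []
        for rep in range(60):
            traj = run_fn_scheme(
                _quick_cfg(
                    pop_size=40, n_selected=40, n_generations=6,
                    selection_mode="phenotypic", h2=1.0,
                ),
                small_genome.spec.landscapes["normal"],
                small_trait,
                np.random.default_rng(rep),
            )
            changes.append(traj.gain(6))
        changes = np.asarray(changes)
        se = changes.std(ddof=1) / np.sqrt(len(changes))
        assert abs(changes.mean()) < 3 * se

    def test_bulmer_variance_drop(self, small_genome):
        from recgain.synth import build_trait

        drops = []
        for rep in range(25):
            trait = build_trait(small_genome, 20, np.random.default_rng(100 + rep))
            traj = run_fn_scheme(
                _quick_cfg(selection_mode="phenotypic", h2=1.0, n_generations=4),
                small_genome.spec.landscapes["normal"],
                trait,
                np.random.default_rng(rep),
            )
            drops.append(traj.var_G[1] - traj.var_G[0])
        drops = np.asarray(drops)
        assert drops.mean() < 0
        assert abs(drops.mean()) > 3 * drops.std(ddof=1) / np.sqrt(len(drops))

    def test_gain_ceiling_never_exceeded(self, small_genome, small_trait):
        for rep in range(5):
            traj = run_fn_scheme(
                _quick_cfg(n_generations=12),
                small_genome.spec.landscapes["boosted"],
                small_trait,
                np.random.default_rng(rep),
            )
            assert np.all(traj.mean_G <= small_trait.gain_ceiling() + 1e-9)

    def test_absorption_is_permanent(self, small_genome):
        from recgain.synth import build_trait

        trait = build_trait(small_genome, 1, np.random.default_rng(8))
        traj = run_fn_scheme(
            _quick_cfg(
                pop_size=100, n_selected=2, n_generations=20,
                selection_mode="phenotypic", h2=1.0,
            ),
            small_genome.spec.landscapes["normal"],
            trait,
            np.random.default_rng(0),
        )
        fixed = np.flatnonzero(traj.var_G == 0)
        assert fixed.size > 0
        i = fixed[0]
        assert np.all(traj.var_G[i:] == 0)
        assert np.allclose(traj.mean_G[i:], traj.mean_G[i])


class TestDhScheme:
    def test_even_generations_fully_homozygous(self, small_genome, small_trait):
        traj = run_dh_scheme(
            _quick_cfg(scheme="DH", n_generations=8),
            small_genome.spec.landscapes["normal"],
            small_trait,
            np.random.default_rng(0),
        )
        assert list(traj.generations) == [2, 3, 4, 5, 6, 7, 8]

    def test_dh_variance_twice_f2_variance(self, small_genome, small_trait):
        rng = np.random.default_rng(0)
        layout = small_layout(small_genome, small_trait)
        f1 = _f1_origins(layout.n_loci)
        idx = np.zeros(3 * 10**4, dtype=np.intp)
        gam1 = meiosis_batch(f1[idx], layout.chrom_pos, layout.GL, None, rng)
        gam2 = meiosis_batch(f1[idx], layout.chrom_pos, layout.GL, None, rng)
        v_f2 = np.var(_values_from_origins(np.stack([gam1, gam2], 1), layout))
        v_dh = np.var(_values_from_origins(np.stack([gam1, gam1], 1), layout))
        assert v_dh / v_f2 == pytest.approx(2.0, abs=0.15)

    def test_scheme_dispatch(self, small_genome, small_trait):
        traj = run_scheme(
            _quick_cfg(scheme="DH"),
            small_genome.spec.landscapes["normal"],
            small_trait,
            np.random.default_rng(0),
        )
        assert traj.scheme == "DH"

    def test_h2_one_phenotypic_ranks_on_true_values(self, small_genome, small_trait):
        # with V_E = 0 the selection criterion equals G exactly
        from recgain.selection import TraitState, _criterion

        layout = small_layout(small_genome, small_trait)
        rng = np.random.default_rng(0)
        origins = np.random.default_rng(1).integers(
            0, 2, (30, 2, layout.n_loci)
        ).astype(np.uint8)
        vals = _values_from_origins(origins, layout)
        crit = _criterion(
            _quick_cfg(selection_mode="phenotypic", h2=1.0),
            vals, origins, layout, TraitState(0.0, 1.0, 1.0), None, rng,
        )
        assert crit == pytest.approx(vals)
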