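"""Copolymer MC: templates, transforms, determinism, observables, physics."""

import numpy as np
import pytest
from scipy.integrate import quad

from chromarch.polymer import (
    BeadTypeSequence,
    ConfinementSpec,
    Ensemble,
    FREE_SPACE,
    SimulationConfig,
    TypeEnergyTable,
    build_genome_template,
    ensemble_contact_map,
    ensemble_distance_map,
    merge_ensembles,
    mutant_transform,
    run_mc,
    template_from_labels,
)

ZERO = TypeEnergyTable(0, 0, 0, 0, 0, 0, 0)


class TestTemplates:
    def test_bead_counting(self):
        seq = build_genome_template(2, arm_beads=50, centromere_beads=5, telomere_beads=5)
        # per chromosome: 5C + 50 + 5C + 50 + 5C = 115
        assert seq.n_beads == 230
        assert all(len(c) == 115 for c in seq.chains)

    def test_pure_b_arm_allowed(self):
        seq = build_genome_template(1, arm_beads=20, centromere_beads=2,
                                    telomere_beads=1, arm_pattern="B")
        assert set(seq.chains[0]) == {"B", "C"}

    def test_pattern_run_length_preserved(self):
        pattern = "AAABBBBBAA"
        seq = build_genome_template(1, arm_beads=10, centromere_beads=2,
                                    telomere_beads=1, arm_pattern=pattern)
        chain = seq.chains[0]
        arm1 = chain[1:11]
        assert arm1 == pattern

    def test_pattern_too_long_rejected(self):
        with pytest.raises(ValueError, match="longer than"):
            build_genome_template(1, arm_beads=5, centromere_beads=1,
                                  telomere_beads=1, arm_pattern="ABABABAB")

    def test_template_from_labels(self):
        seq = template_from_labels(["A", "A", "B"], bead_size=40_000)
        assert seq.chains == ("AAB",)
        assert seq.bead_size == 40_000

    def test_invalid_type_rejected(self):
        with pytest.raises(ValueError):
            BeadTypeSequence(chains=("AXB",))


class TestMutantTransform:
    def test_identity(self):
        en = TypeEnergyTable()
        assert mutant_transform(en, 1.0) == en

    def test_zero_factor(self):
        en = TypeEnergyTable()
        mut = mutant_transform(en, 0.0)
        assert mut.CC == 0 and mut.surf_C == 0
        assert (mut.AA, mut.BB, mut.AB) == (en.AA, en.BB, en.AB)

    def test_half_factor_fieldwise(self):
        en = TypeEnergyTable(AA=0.1, BB=0.3, CC=0.6, AB=0.05, AC=0.05, BC=0.05, surf_C=1.0)
        mut = mutant_transform(en, 0.5)
        assert mut.CC == pytest.approx(0.3)
        assert mut.surf_C == pytest.approx(0.5)
        for field in ("AA", "BB", "AB", "AC", "BC"):
            assert getattr(mut, field) == getattr(en, field)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mutant_transform(TypeEnergyTable(), 1.5)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            TypeEnergyTable(AA=-0.1)


@pytest.fixture(scope="module")
def small_run():
    seq = template_from_labels("A" * 10 + "B" * 10)
    cfg = SimulationConfig(seed=5, n_sweeps=1200, equilibration_sweeps=200, sample_interval=10)
    conf = ConfinementSpec.auto(seq.n_beads)
    return seq, cfg, conf, run_mc(seq, TypeEnergyTable(), conf, cfg)


class TestRunMC:
    def test_seed_determinism(self, small_run):
        seq, cfg, conf, ens = small_run
        again = run_mc(seq, TypeEnergyTable(), conf, cfg)
        np.testing.assert_array_equal(ens.configurations, again.configurations)

    def test_different_seed_differs(self, small_run):
        seq, cfg, conf, ens = small_run
        from dataclasses import replace

        other = run_mc(seq, TypeEnergyTable(), conf, replace(cfg, seed=6))
        assert not np.array_equal(ens.configurations, other.configurations)

    def test_bond_limits_in_samples(self, small_run):
        _, cfg, _, ens = small_run
        for conf in ens.configurations:
            bl = np.linalg.norm(np.diff(conf, axis=0), axis=1)
            assert bl.min() >= 0.7 * cfg.bond_length - 1e-9
            assert bl.max() <= 1.3 * cfg.bond_length + 1e-9

    def test_confinement_respected(self, small_run):
        _, _, conf, ens = small_run
        xyz = ens.configurations.reshape(-1, 3)
        assert (xyz[:, 2] >= 0).all() and (xyz[:, 2] <= conf.height).all()
        assert (xyz[:, 0] ** 2 + xyz[:, 1] ** 2 <= conf.radius**2 + 1e-9).all()

    def test_provenance_records_seed(self, small_run):
        _, cfg, _, ens = small_run
        assert ens.provenance["seed"] == cfg.seed
        assert len(ens.provenance["config_hash"]) == 16

    def test_two_bead_bond_distribution_matches_quadrature(self):
        """Bond-length histogram against direct integration of the
        Boltzmann weight r^2 exp(-k/2 (r - l0)^2) on the allowed range."""
        seq = BeadTypeSequence(chains=("AA",))
        cfg = SimulationConfig(
            seed=9, n_sweeps=60_000, equilibration_sweeps=5_000, sample_interval=5
        )
        ens = run_mc(seq, ZERO, FREE_SPACE, cfg)
        r = np.linalg.norm(
            ens.configurations[:, 1] - ens.configurations[:, 0], axis=1
        )
        k = cfg.bond_k
        w = lambda x: x**2 * np.exp(-0.5 * k * (x - 1.0) ** 2)
        z = quad(w, 0.7, 1.3)[0]
        mean_exp = quad(lambda x: x * w(x), 0.7, 1.3)[0] / z
        var_exp = quad(lambda x: (x - mean_exp) ** 2 * w(x), 0.7, 1.3)[0] / z
        assert r.mean() == pytest.approx(mean_exp, abs=0.01)
        assert r.var() == pytest.approx(var_exp, rel=0.15)

    def test_free_beads_fill_box_uniformly(self):
        """Detailed-balance smoke test: non-interacting single-bead chains
        in a cylinder occupy equal-volume height slices uniformly."""
        from scipy.stats import chisquare

        seq = BeadTypeSequence(chains=("A",) * 30)
        conf = ConfinementSpec(radius=4.0, height=12.0)
        # wide sampling interval: chi-square needs decorrelated samples
        cfg = SimulationConfig(
            seed=2, n_sweeps=112_000, equilibration_sweeps=12_000, sample_interval=500
        )
        ens = run_mc(seq, ZERO, conf, cfg)
        z = ens.configurations[:, :, 2].ravel()
        counts, _ = np.histogram(z, bins=6, range=(0, conf.height))
        assert chisquare(counts).pvalue > 0.01


class TestObservables:
    def _toy_ensemble(self):
        # 3 configurations of 3 beads on a line with known distances
        confs = np.array(
            [
                [[0, 0, 0], [1, 0, 0], [2, 0, 0]],
                [[0, 0, 0], [1, 0, 0], [5, 0, 0]],
                [[0, 0, 0], [1, 0, 0], [2.5, 0, 0]],
            ],
            dtype=float,
        )
        return Ensemble(confs, np.zeros(3, np.int8), np.zeros(3, np.int64), 0.5, {})

    def test_contact_map_brute_force(self):
        ens = self._toy_ensemble()
        cmap = ensemble_contact_map(ens, contact_radius=2.0, min_samples=1)
        assert cmap.counts[0, 1] == 1.0  # bonded pair always within 2
        assert cmap.counts[0, 2] == pytest.approx(0.0)  # 2, 5, 2.5 all >= 2
        assert cmap.counts[1, 2] == pytest.approx(2 / 3)  # 1, 4, 1.5
        assert np.allclose(np.diag(cmap.counts), 1.0)

    def test_contact_map_requires_samples(self):
        ens = self._toy_ensemble()
        with pytest.raises(ValueError, match="samples"):
            ensemble_contact_map(ens, min_samples=50)

    def test_distance_map_brute_force(self):
        ens = self._toy_ensemble()
        dmap = ensemble_distance_map(ens)
        assert dmap[0, 0] == 0.0
        np.testing.assert_allclose(dmap, dmap.T)
        assert dmap[1, 2] == pytest.approx((1 + 4 + 1.5) / 3)

    def test_ensemble_round_trip(self, small_run, tmp_path):
        from chromarch.polymer import load_ensemble, save_ensemble

        *_, ens = small_run
        p = tmp_path / "ens.h5"
        save_ensemble(ens, p)
        back = load_ensemble(p)
        np.testing.assert_array_equal(back.configurations, ens.configurations)
        assert back.provenance["config_hash"] == ens.provenance["config_hash"]

    def test_merge_rejects_mismatched(self, small_run):
        *_, ens = small_run
        other = Ensemble(
            np.zeros((1, 3, 3)), np.zeros(3, np.int8), np.zeros(3, np.int64), 0.5, {}
        )
        with pytest.raises(ValueError):
            merge_ensembles([ens, other])


class TestConfinement:
    def test_auto_packing_fraction(self):
        for n in (100, 1000):
            spec = ConfinementSpec.auto(n, packing=0.1, aspect=3.0)
            v_beads = n * np.pi / 6
            v_cyl = np.pi * spec.radius**2 * spec.height
            assert v_beads / v_cyl == pytest.approx(0.1, rel=1e-6)
            assert spec.height == pytest.approx(3.0 * spec.radius)
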