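"""Compartment eigenvector, saddle strength, switching and insulation."""

import numpy as np
import pandas as pd
import pytest

from chromarch.compartments import (
    CompartmentTrack,
    SaddleMatrix,
    compartment_score,
    differential_saddle,
    insulation,
    saddle,
    switching,
)
from chromarch.maps import ContactMap, balance
from chromarch.synthetic import SyntheticMapSpec, make_map


def _scored_map(n_bins=200, contrast=2.0, beta=1.0, block=20, noise=False, seed=0, layout="random"):
    spec = SyntheticMapSpec(
        n_bins=n_bins,
        checkerboard_contrast=contrast,
        b_weakening=beta,
        block_bins=block,
        block_layout=layout,
        noise=noise,
        seed=seed,
    )
    cmap, truth = make_map(spec)
    return balance(cmap, method="none"), truth


class TestCompartmentScore:
    def test_checkerboard_sign_pattern(self):
        cmap, truth = _scored_map()
        track = compartment_score(cmap, orientation=truth.scores)
        assert np.array_equal(np.sign(track.scores), np.sign(truth.scores))

    @pytest.mark.parametrize("n_blocks", [2, 4, 6])
    def test_label_recovery_varied_blocks(self, n_blocks):
        n = 240
        cmap, truth = _scored_map(n_bins=n, block=n // n_blocks, noise=True, seed=1, layout="alternating")
        track = compartment_score(cmap, orientation=truth.scores)
        agree = (np.sign(track.scores) == np.sign(truth.scores)).mean()
        assert agree >= 0.99

    def test_uniform_map_degenerate(self):
        cmap, _ = _scored_map(contrast=1.0)
        with pytest.warns(UserWarning, match="degenerate"):
            track = compartment_score(cmap)
        # a featureless map must not produce confident labels
        assert (track.labels == "undefined").all() or np.nanstd(track.scores) < 1e-6

    def test_orientation_flip_swaps_labels(self):
        cmap, truth = _scored_map()
        a = compartment_score(cmap, orientation=truth.scores)
        b = compartment_score(cmap, orientation=-truth.scores)
        np.testing.assert_allclose(a.scores, -b.scores)
        ok = a.labels != "undefined"
        assert (a.labels[ok] != b.labels[ok]).all()


class TestSaddle:
    def test_uniform_oe_all_ones(self):
        cmap, _ = _scored_map(contrast=1.0)
        scores = np.tile([1.0, -1.0], cmap.n_bins // 2)
        track = CompartmentTrack(cmap.resolution, scores, cmap.bins)
        sad = saddle(cmap, track, n_quantiles=10)
        assert np.allclose(sad.values[np.isfinite(sad.values)], 1.0, atol=1e-9)
        rep = sad.strength()
        assert rep.strength_overall == pytest.approx(1.0, abs=1e-9)

    def test_corner_ratio_construction(self):
        # planted contrast c=2 means AA and BB corners enrich twofold over
        # AB once pairs within the block scale are filtered out
        cmap, truth = _scored_map(n_bins=300, contrast=2.0)
        sad = saddle(cmap, truth, n_quantiles=20, min_separation=500_000)
        rep = sad.strength()
        assert rep.strength_overall == pytest.approx(2.0, rel=0.05)

    def test_b_weakening_moves_only_strength_b(self):
        _, truth = _scored_map()
        strengths = {}
        for beta in (1.0, 0.9, 0.8, 0.7):
            cmap, _ = _scored_map(beta=beta)
            sad = saddle(cmap, truth, n_quantiles=20, min_separation=500_000)
            strengths[beta] = sad.strength()
        sb = [strengths[b].strength_B for b in (1.0, 0.9, 0.8, 0.7)]
        assert sb == sorted(sb, reverse=True), "strength_B must fall with B-B weakening"
        for beta in (0.9, 0.8, 0.7):
            ratio_a = strengths[beta].strength_A / strengths[1.0].strength_A
            assert abs(ratio_a - 1) < 0.02, "strength_A must stay put"

    @pytest.mark.parametrize("corner_fraction", [0.1, 0.2, 0.25])
    def test_planted_ratio_across_corner_fractions(self, corner_fraction):
        _, truth = _scored_map()
        cmap1, _ = _scored_map(beta=1.0)
        cmap2, _ = _scored_map(beta=0.8)
        s1 = saddle(cmap1, truth, n_quantiles=20, corner_fraction=corner_fraction).strength()
        s2 = saddle(cmap2, truth, n_quantiles=20, corner_fraction=corner_fraction).strength()
        assert s2.strength_B / s1.strength_B == pytest.approx(0.8, abs=0.03)

    @pytest.mark.parametrize("min_sep", [0, 500_000, 3_000_000])
    def test_strength_ordering_separation_invariant(self, min_sep):
        # the planted compartment signal is separation-independent, so the
        # B-weakened map must rank below control at every distance filter
        c1, truth = _scored_map(n_bins=600, beta=1.0, noise=True, seed=8)
        c2, _ = _scored_map(n_bins=600, beta=0.8, noise=True, seed=9)
        t1 = compartment_score(c1, orientation=truth.scores)
        t2 = compartment_score(c2, orientation=truth.scores)
        s1 = saddle(c1, t1, n_quantiles=20, min_separation=min_sep).strength()
        s2 = saddle(c2, t2, n_quantiles=20, min_separation=min_sep).strength()
        assert s2.strength_B < s1.strength_B

    def test_differential_saddle(self):
        cmap, truth = _scored_map()
        sad = saddle(cmap, truth, n_quantiles=10)
        zero = differential_saddle(sad, sad)
        assert np.allclose(zero[np.isfinite(zero)], 0.0)
        doubled = SaddleMatrix(10, sad.values * 2)
        assert np.allclose(
            differential_saddle(doubled, sad)[np.isfinite(sad.values)], 1.0
        )
        with pytest.raises(ValueError):
            differential_saddle(sad, SaddleMatrix(5, np.ones((5, 5))))


class TestSwitching:
    def _track(self, scores):
        bins = pd.DataFrame({"chrom": "c", "start": np.arange(len(scores)) * 10})
        return CompartmentTrack(10, np.asarray(scores, float), bins)

    def test_identical_zero(self):
        t = self._track([1, -1, 1, -1])
        assert switching(t, t) == 0.0

    def test_full_flip_one(self):
        t = self._track([1, -1, 1, -1])
        assert switching(t, t.flipped()) == 1.0

    def test_half_flip(self):
        a = self._track([1, 1, -1, -1])
        b = self._track([1, -1, -1, 1])
        assert switching(a, b) == 0.5

    def test_undefined_bins_excluded(self):
        a = self._track([1, np.nan, -1, -1])
        b = self._track([-1, 1, -1, np.nan])
        assert switching(a, b) == 0.5  # bins 0 and 2 defined in both; one flips


class TestInsulation:
    def _domain_map(self, boundary=50, n=100, cross=0.05):
        spec = SyntheticMapSpec(
            n_bins=n,
            checkerboard_contrast=1.0,
            tad_boundaries=(boundary,),
            tad_enrichment=1.0 / max(cross, 1e-9),
            noise=False,
        )
        cmap, _ = make_map(spec)
        return balance(cmap, method="none")

    def test_planted_boundary_is_global_minimum(self):
        cmap = self._domain_map()
        track = insulation(cmap, window=100_000)
        ok = np.isfinite(track.values)
        assert np.nanargmin(track.values) == 50
        assert 50 in track.boundaries

    def test_uniform_map_flat(self):
        spec = SyntheticMapSpec(n_bins=80, checkerboard_contrast=1.0, noise=False)
        cmap = balance(make_map(spec)[0], method="none")
        track = insulation(cmap, window=100_000)
        assert len(track.boundaries) == 0

    def test_cross_boundary_contacts_raise_insulation(self):
        values = []
        for cross in (0.05, 0.2, 0.6):
            track = insulation(self._domain_map(cross=cross), window=100_000)
            values.append(track.values[50])
        assert values[0] < values[1] < values[2]

    def test_window_edges_undefined(self):
        cmap = self._domain_map()
        track = insulation(cmap, window=100_000)
        w = 100_000 // cmap.resolution
        assert np.isnan(track.values[:w]).all()
        assert np.isnan(track.values[-(w - 1) :]).all()
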