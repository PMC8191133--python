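"""Spot detection, axis counting, ring scores and phenotype rules."""

import numpy as np
import pytest

from hydrapattern.model import SPECIES, SPECIES_INDEX, FieldState
from hydrapattern.pattern_analysis import (SpotSet, Spot, classify_phenotype,
                                           count_axes, detect_spots,
                                           ring_score, summarize_state)


def state_with(mesh, species, values):
    arr = np.zeros((len(SPECIES), mesh.n_vertices))
    arr[SPECIES_INDEX[species]] = values
    return FieldState(arr)


def gaussian_bump(mesh, center_vertex, sigma=0.3, height=1.0):
    d = np.linalg.norm(mesh.vertices - mesh.vertices[center_vertex], axis=1)
    return height * np.exp(-(d / sigma) ** 2)


class TestDetectSpots:
    def test_single_bump_single_spot(self, sphere_l4):
        apex = int(np.argmax(sphere_l4.sphere_coords[:, 2]))
        state = state_with(sphere_l4, "wnt3", gaussian_bump(sphere_l4, apex))
        spots = detect_spots(state, "wnt3", sphere_l4)
        assert len(spots) == 1
        assert spots.spots[0].seed_vertex == apex

    def test_two_antipodal_bumps(self, sphere_l4):
        top = int(np.argmax(sphere_l4.sphere_coords[:, 2]))
        bottom = int(np.argmin(sphere_l4.sphere_coords[:, 2]))
        f = gaussian_bump(sphere_l4, top) + gaussian_bump(sphere_l4, bottom)
        spots = detect_spots(state_with(sphere_l4, "wnt3", f), "wnt3",
                             sphere_l4)
        assert len(spots) == 2
        assert {s.seed_vertex for s in spots.spots} == {top, bottom}

    def test_uniform_field_yields_no_spots(self, sphere_l4):
        state = state_with(sphere_l4, "wnt3",
                           np.full(sphere_l4.n_vertices, 3.3))
        spots = detect_spots(state, "wnt3", sphere_l4)
        assert len(spots) == 0
        assert spots.cv < 1e-12

    def test_scale_invariance(self, sphere_l4):
        apex = int(np.argmax(sphere_l4.sphere_coords[:, 2]))
        f = gaussian_bump(sphere_l4, apex)
        a = detect_spots(state_with(sphere_l4, "wnt3", f), "wnt3", sphere_l4)
        b = detect_spots(state_with(sphere_l4, "wnt3", 73.0 * f), "wnt3",
                         sphere_l4)
        assert [s.seed_vertex for s in a.spots] == \
            [s.seed_vertex for s in b.spots]
        assert a.spots[0].area == pytest.approx(b.spots[0].area)

    def test_azimuthal_position_invariance(self, sphere_l4):
        # same latitude, different azimuth: identical spot structure
        s = sphere_l4.sphere_coords
        lat = np.abs(s[:, 2] - 0.5)
        v1 = int(np.argmin(lat + np.abs(np.arctan2(s[:, 1], s[:, 0]))))
        v2 = int(np.argmin(lat + np.abs(np.arctan2(s[:, 1], s[:, 0]) - 1.7)))
        a = detect_spots(state_with(sphere_l4, "tent",
                                    gaussian_bump(sphere_l4, v1)),
                         "tent", sphere_l4)
        b = detect_spots(state_with(sphere_l4, "tent",
                                    gaussian_bump(sphere_l4, v2)),
                         "tent", sphere_l4)
        assert len(a) == len(b) == 1
        assert a.spots[0].area == pytest.approx(b.spots[0].area, rel=0.1)

    def test_unknown_species_rejected(self, sphere_l2):
        state = FieldState(np.zeros((9, sphere_l2.n_vertices)))
        with pytest.raises(KeyError):
            detect_spots(state, "gsk3", sphere_l2)


class TestCountAxes:
    @staticmethod
    def spotset(vertices):
        spots = [Spot(seed_vertex=v, members=np.array([v]), peak_value=1.0,
                      area=0.01) for v in vertices]
        return SpotSet(species="wnt3", spots=spots, rel_threshold=0.5, cv=1.0)

    def test_empty(self, sphere_l3):
        assert count_axes(self.spotset([]), sphere_l3) == 0

    def test_single_spot(self, sphere_l3):
        assert count_axes(self.spotset([0]), sphere_l3) == 1

    def test_single_linkage_clustering(self, sphere_l3):
        top = int(np.argmax(sphere_l3.sphere_coords[:, 2]))
        bottom = int(np.argmin(sphere_l3.sphere_coords[:, 2]))
        # a vertex adjacent to the top pole: same cluster as top
        neighbor = sphere_l3.edge_graph()[top].indices[0]
        spots = self.spotset([top, int(neighbor), bottom])
        assert count_axes(spots, sphere_l3) == 2


class TestRingScore:
    def test_ideal_band_indicator(self, sphere_l4):
        s3 = sphere_l4.sphere_coords[:, 2]
        f = ((s3 > 0.4) & (s3 < 0.7)).astype(float)
        state = state_with(sphere_l4, "has", f)
        score = ring_score(state, "has", sphere_l4, band_center_s3=0.55,
                           band_width=0.3)
        assert score >= 0.95

    def test_off_band_bump_scores_low(self, sphere_l4):
        bottom = int(np.argmin(sphere_l4.sphere_coords[:, 2]))
        state = state_with(sphere_l4, "has",
                           gaussian_bump(sphere_l4, bottom, sigma=0.2))
        score = ring_score(state, "has", sphere_l4, band_center_s3=0.55,
                           band_width=0.3)
        assert score < 0.2

    def test_uniform_field_scores_area_fraction(self, sphere_l4):
        state = state_with(sphere_l4, "has",
                           np.ones(sphere_l4.n_vertices))
        s3 = sphere_l4.sphere_coords[:, 2]
        lo, hi = 0.3, 0.7
        in_band = (s3 >= lo) & (s3 <= hi)
        frac = sphere_l4.vertex_areas[in_band].sum() / sphere_l4.total_area
        score = ring_score(state, "has", sphere_l4, band_center_s3=0.5,
                           band_width=0.4)
        assert score == pytest.approx(frac, rel=0.15)

    def test_empty_band_rejected(self, sphere_l2):
        state = state_with(sphere_l2, "has", np.ones(sphere_l2.n_vertices))
        with pytest.raises(ValueError):
            ring_score(state, "has", sphere_l2, band_center_s3=5.0,
                       band_width=0.01)


class TestClassifyPhenotype:
    @pytest.mark.parametrize(
        "wnt3_spots,axes,tent_spots,body_tent,area,ref,expected",
        [
            (0, 0, 0, 0, 0.0, None, "no-pattern"),
            (1, 1, 5, 0, 0.3, 0.3, "single-organizer"),
            (1, 1, 6, 6, 0.3, 0.3, "ectopic-tentacles"),
            (2, 2, 0, 0, 0.3, 0.3, "secondary-axis"),
            (3, 2, 4, 4, 0.3, 0.3, "secondary-axis-with-tentacles"),
            (1, 1, 0, 0, 0.9, 0.3, "broadened-organizer"),
            (1, 1, 0, 0, 0.9, None, "single-organizer"),  # no reference
            (0, 0, 3, 3, 0.0, None, "ectopic-tentacles"),
        ])
    def test_rule_table(self, wnt3_spots, axes, tent_spots, body_tent, area,
                        ref, expected):
        label = classify_phenotype(
            wnt3_spot_count=wnt3_spots, axis_count=axes,
            tentacle_spot_count=tent_spots,
            body_tentacle_spot_count=body_tent, wnt3_spot_area=area,
            reference_spot_area=ref)
        assert label == expected

    def test_deterministic(self):
        args = dict(wnt3_spot_count=2, axis_count=2, tentacle_spot_count=1,
                    body_tentacle_spot_count=1, wnt3_spot_area=0.5,
                    reference_spot_area=0.3)
        assert classify_phenotype(**args) == classify_phenotype(**args)


class TestSummarize:
    def test_axis_count_bounded_by_spot_count(self, sphere_l3, rng):
        values = rng.uniform(0, 1, (9, sphere_l3.n_vertices))
        state = FieldState(values)
        summary = summarize_state(state, sphere_l3)
        assert summary.axis_count <= max(summary.wnt3_spot_count, 0)
        assert 0.0 <= summary.tentacle_ring_score <= 1.0
        assert 0.0 <= summary.has_ring_score <= 1.0
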