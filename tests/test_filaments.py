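"""Filament tracing: masks, contour lengths, classification, clustering,
inter-puncta spacing and colocalization."""

import numpy as np
import pytest

from condensekit import filaments as fil
from condensekit import synthetic as syn
from condensekit.loctable import LocalizationTable


def _table_from_nm(xy_nm, pixel_size_nm=130.0):
    xy_nm = np.asarray(xy_nm, dtype=float).reshape(-1, 2)
    n = len(xy_nm)
    return LocalizationTable.from_arrays(
        frame=np.arange(n), x=xy_nm[:, 0] / pixel_size_nm, y=xy_nm[:, 1] / pixel_size_nm,
        photons=np.full(n, 1000.0), sx=np.full(n, 1.2), sy=np.full(n, 1.2),
        precision_nm=np.full(n, 15.0), pixel_size_nm=pixel_size_nm,
    )


class TestDensityMask:
    def test_empty_table_gives_empty_mask(self):
        m = fil.density_mask(LocalizationTable.empty())
        assert not m.mask.any()

    def test_straight_filament_single_component(self):
        spec = syn.FilamentSceneSpec(geometry="line", seed=1)
        table, _, truth = syn.make_filament_localizations(spec)
        m = fil.density_mask(table)
        from skimage import measure

        assert measure.label(m.mask, connectivity=2).max() == 1
        # mask covers ≥ 90% of the true curve
        pts = truth.filaments[0]["points"]
        r = ((pts[:, 1] - m.origin_nm[1]) / m.sr_pixel_nm).round().astype(int)
        c = ((pts[:, 0] - m.origin_nm[0]) / m.sr_pixel_nm).round().astype(int)
        inside = (r >= 0) & (r < m.mask.shape[0]) & (c >= 0) & (c < m.mask.shape[1])
        assert m.mask[r[inside], c[inside]].mean() >= 0.9

    def test_parallel_filaments_stay_separate(self):
        # two straight filaments 5x the smoothing width apart -> 2 components
        s = np.linspace(0.0, 2000.0, 200)
        sep = 5 * fil.DEFAULT_SMOOTH_NM
        rng = np.random.default_rng(2)
        a = np.column_stack([s, np.zeros_like(s)]) + rng.normal(0, 10, (200, 2))
        b = np.column_stack([s, np.full_like(s, sep)]) + rng.normal(0, 10, (200, 2))
        # resolving nearby parallel filaments needs the higher threshold;
        # the permissive tracing default favours continuity over separation
        m = fil.density_mask(_table_from_nm(np.vstack([a, b])), min_density=0.05)
        from skimage import measure

        assert measure.label(m.mask, connectivity=2).max() == 2


class TestTraceFilaments:
    def test_empty_mask_gives_no_traces(self):
        m = fil.DensityMask(np.zeros((16, 16), dtype=bool), 10.0, (0.0, 0.0))
        assert fil.trace_filaments(m) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_circle_closed_and_length_within_5pct(self, seed):
        spec = syn.FilamentSceneSpec(
            geometry="circle", unit_contour_length_nm=4000.0,
            localization_sigma_nm=1e-6, seed=600 + seed,
        )
        table, _, _ = syn.make_filament_localizations(spec)
        traces = fil.trace_filaments(fil.density_mask(table))
        assert len(traces) == 1 and traces[0].closed
        assert traces[0].contour_length_nm == pytest.approx(4000.0, rel=0.05)

    @pytest.mark.parametrize("seed", range(10))
    def test_line_open_and_length_within_5pct(self, seed):
        spec = syn.FilamentSceneSpec(
            geometry="line", localization_sigma_nm=1e-6, seed=700 + seed
        )
        table, _, _ = syn.make_filament_localizations(spec)
        traces = fil.trace_filaments(fil.density_mask(table))
        assert len(traces) == 1 and not traces[0].closed
        assert traces[0].contour_length_nm == pytest.approx(2100.0, rel=0.05)

    def test_tether_length_additivity_within_10pct(self):
        # k units traced as one filament of ~k x unit length at the default
        # jitter (15 nm) and density (1 per 10 nm)
        for k in (2, 4):
            spec = syn.FilamentSceneSpec(
                geometry="line", n_units_tethered=k, field_extent_nm=30_000, seed=13
            )
            table, _, truth = syn.make_filament_localizations(spec)
            traces = fil.trace_filaments(fil.density_mask(table))
            assert len(traces) == 1
            assert traces[0].contour_length_nm == pytest.approx(
                k * spec.unit_contour_length_nm, rel=0.10
            )


class TestPopulationStats:
    def test_arithmetic(self):
        def tr(lnm):
            return fil.FilamentTrace(
                points_nm=np.array([[0.0, 0.0], [lnm, 0.0]]),
                closed=False, contour_length_nm=lnm,
            )

        s = fil.population_stats([tr(2e3)] * 3, threshold_um=5.0)
        assert (s.mean_um, s.sd_um, s.fraction_above_threshold) == (2.0, 0.0, 0.0)
        s2 = fil.population_stats([tr(2e3), tr(10e3)], threshold_um=5.0)
        assert s2.fraction_above_threshold == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fil.population_stats([])

    def test_single_filament_preset_recovery(self):
        # population of 50 single filaments (10 fields of 5), unit 2.1 um
        # with 0.4 um spread: traced mean recovers the preset within 0.2 um,
        # SD within 2 SE
        traces = []
        for seed in range(10):
            spec = syn.FilamentSceneSpec(
                geometry="line", unit_length_sd_nm=400.0, n_filaments=5,
                field_extent_nm=30_000, seed=170 + seed,
            )
            table, _, _ = syn.make_filament_localizations(spec)
            traces.extend(fil.trace_filaments(fil.density_mask(table)))
        stats = fil.population_stats(traces, threshold_um=5.0)
        assert len(traces) >= 48
        assert abs(stats.mean_um - 2.1) < 0.2
        se_sd = 0.4 / np.sqrt(2 * (len(traces) - 1))
        assert abs(stats.sd_um - 0.4) < 2 * se_sd + 0.05


class TestDetectClusters:
    def test_separated_singles_are_unclustered(self):
        spec = syn.FilamentSceneSpec(
            geometry="line", n_filaments=10, field_extent_nm=60_000, seed=22
        )
        table, _, _ = syn.make_filament_localizations(spec)
        traces = fil.trace_filaments(fil.density_mask(table))
        report = fil.detect_clusters(traces)
        assert report.n_clusters == 0
        assert all(t.cluster_id == -1 for t in traces)

    def test_crossing_bundle_forms_one_cluster(self):
        spec = syn.FilamentSceneSpec(
            geometry="line", bundle_multiplicity=3, field_extent_nm=15_000, seed=21
        )
        table, _, _ = syn.make_filament_localizations(spec)
        traces = fil.trace_filaments(fil.density_mask(table))
        report = fil.detect_clusters(traces)
        assert report.n_clusters >= 1
        assert max(len(c["trace_indices"]) for c in report.clusters) >= 3

    def test_single_circle_is_not_a_cluster(self):
        spec = syn.FilamentSceneSpec(geometry="circle", unit_contour_length_nm=4000, seed=8)
        table, _, _ = syn.make_filament_localizations(spec)
        traces = fil.trace_filaments(fil.density_mask(table))
        assert fil.detect_clusters(traces).n_clusters == 0


class TestInterPunctaSpacing:
    def _straight_trace(self, length_nm):
        s = np.linspace(0.0, length_nm, 200)
        return fil.FilamentTrace(
            points_nm=np.column_stack([s, np.zeros_like(s)]),
            closed=False, contour_length_nm=length_nm,
        )

    def _puncta_at(self, centers_nm, n_per=50, sigma=20.0, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.concatenate(
            [c + rng.normal(0, sigma, (n_per, 2)) for c in np.atleast_2d(centers_nm)]
        )
        return _table_from_nm(pts)

    def test_single_punctum_gives_no_spacing(self):
        rep = fil.inter_puncta_spacing(
            self._straight_trace(2000.0), self._puncta_at([[1000.0, 0.0]])
        )
        assert rep.n_puncta == 1 and rep.spacings_nm == []

    def test_end_puncta_spacing_equals_length(self):
        L = 3000.0
        rep = fil.inter_puncta_spacing(
            self._straight_trace(L), self._puncta_at([[0.0, 0.0], [L, 0.0]])
        )
        assert len(rep.spacings_nm) == 1
        assert rep.spacings_nm[0] == pytest.approx(L, abs=fil.DEFAULT_ASSIGN_RADIUS_NM)

    def test_far_puncta_reported_unassigned(self):
        rep = fil.inter_puncta_spacing(
            self._straight_trace(2000.0), self._puncta_at([[1000.0, 5000.0]])
        )
        assert rep.n_unassigned == 1 and rep.n_puncta == 0

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_tether_spacings_recover_unit_length(self, k):
        spec = syn.FilamentSceneSpec(
            geometry="line", n_units_tethered=k, puncta_at_junctions=True,
            field_extent_nm=30_000, seed=40 + k,
        )
        table, puncta, truth = syn.make_filament_localizations(spec)
        traces = fil.trace_filaments(fil.density_mask(table))
        assert len(traces) == 1
        rep = fil.inter_puncta_spacing(traces[0], puncta)
        assert len(rep.spacings_nm) == max(k - 2, 0)  # k-1 puncta -> k-2 gaps
        mean, _ = fil.pool_spacings([rep])
        if k > 2:
            assert mean == pytest.approx(spec.unit_contour_length_nm, rel=0.10)


class TestColocalization:
    def test_identical_tables_fully_colocalize(self):
        t = _table_from_nm(np.random.default_rng(0).uniform(0, 1000, (100, 2)))
        r = fil.colocalization_fraction(t, t, radius_nm=50.0)
        assert r.frac_a_near_b == 1.0 and r.frac_b_near_a == 1.0

    def test_distant_tables_do_not_colocalize(self):
        a = _table_from_nm(np.random.default_rng(1).uniform(0, 500, (50, 2)))
        b = _table_from_nm(np.random.default_rng(2).uniform(0, 500, (50, 2)) + 50_000)
        r = fil.colocalization_fraction(a, b, radius_nm=100.0)
        assert r.frac_a_near_b == 0.0 and r.symmetric == 0.0

    def test_uniform_poisson_matches_closed_form(self):
        # P(≥1 neighbour within r) = 1 - exp(-rho * pi * r^2)
        rng = np.random.default_rng(3)
        box = 20_000.0
        n_b = 4000
        rho = n_b / box**2
        radius = 150.0
        a = _table_from_nm(rng.uniform(2000, box - 2000, (600, 2)))
        b = _table_from_nm(rng.uniform(0, box, (n_b, 2)))
        expected = 1.0 - np.exp(-rho * np.pi * radius**2)
        r = fil.colocalization_fraction(a, b, radius_nm=radius)
        se = np.sqrt(expected * (1 - expected) / 600)
        assert abs(r.frac_a_near_b - expected) < 4 * se

    def test_bad_radius_rejected(self):
        t = _table_from_nm([[0.0, 0.0]])
        with pytest.raises(ValueError):
            fil.colocalization_fraction(t, t, radius_nm=0.0)
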