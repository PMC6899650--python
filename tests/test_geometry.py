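"""Data model, I/O round trips, strain corrections and filters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sppa import (
    BedSurfaceMap,
    ObservationWindow,
    SpecimenRecord,
    StrainEstimate,
    estimate_strain,
    extract_rect_subwindow,
    filter_analysis_taxa,
    largest_inscribed_rectangle,
    read_surface_map,
    retrodeform,
    write_surface_map,
)
from sppa.errors import FormatError, InsufficientDataError, ParseError
from sppa.synthetic import apply_tectonic_strain

from conftest import make_map


class TestDataModel:
    def test_window_area_matches_polygon(self):
        w = ObservationWindow.rectangle(0, 0, 13.0, 8.858)
        assert w.area == pytest.approx(115.154, rel=1e-9)

    def test_invalid_records_rejected(self):
        with pytest.raises(ValueError):
            SpecimenRecord("a", "", 0, 0)
        with pytest.raises(ValueError):
            SpecimenRecord("a", "t", float("nan"), 0)
        with pytest.raises(ValueError):
            SpecimenRecord("a", "t", 0, 0, disc_width=-0.1)
        with pytest.raises(ValueError):
            SpecimenRecord("a", "t", 0, 0, group_class="weird")

    def test_duplicate_ids_rejected(self, unit_window):
        recs = [SpecimenRecord("a", "t", 0.5, 0.5), SpecimenRecord("a", "t", 0.2, 0.2)]
        with pytest.raises(ValueError, match="unique"):
            BedSurfaceMap("m", recs, unit_window)

    def test_record_outside_window_rejected(self, unit_window):
        with pytest.raises(ValueError, match="outside"):
            BedSurfaceMap("m", [SpecimenRecord("a", "t", 2.0, 0.5)], unit_window)


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path, rng):
        pts = rng.uniform(0, 5, (30, 2))
        m = make_map(
            pts,
            taxa=["A"] * 10 + ["B"] * 20,
            window=ObservationWindow.rectangle(0, 0, 5, 5),
            disc_width=0.02,
            disc_length=0.03,
        )
        path = tmp_path / "m.csv"
        write_surface_map(m, path)
        back = read_surface_map(path)
        assert back == m

    def test_empty_map_roundtrip(self, tmp_path, unit_window):
        m = BedSurfaceMap("empty", [], unit_window)
        path = tmp_path / "empty.csv"
        write_surface_map(m, path)
        back = read_surface_map(path)
        assert len(back) == 0
        assert back.window == unit_window

    def test_absent_morphometrics_omitted(self, tmp_path, unit_window):
        m = BedSurfaceMap("m", [SpecimenRecord("a", "t", 0.5, 0.5)], unit_window)
        path = tmp_path / "m.csv"
        write_surface_map(m, path)
        assert "disc_width_m" not in path.read_text()
        assert read_surface_map(path) == m

    def test_fixture_dimensions_preserved(self, tmp_path, rng):
        # a synthetic surface at the scale of the largest mapped bed:
        # 115.16 m² window carrying 761 specimens
        w = ObservationWindow.rectangle(0, 0, 13.0, 115.16 / 13.0)
        pts = w.sample_uniform(761, rng)
        m = make_map(pts, window=w, name="bed_b_fixture")
        path = tmp_path / "bed_b.csv"
        write_surface_map(m, path)
        back = read_surface_map(path)
        assert len(back) == 761
        assert back.window.area == pytest.approx(115.16, rel=1e-9)

    def test_missing_column_is_format_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("specimen_id,x_m\n1,0.5\n")
        with pytest.raises(FormatError, match="taxon"):
            read_surface_map(path)

    def test_non_numeric_coordinate_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("specimen_id,taxon,x_m,y_m\n1,t,0.5,0.5\n2,t,oops,0.5\n")
        with pytest.raises(ParseError, match="row 1"):
            read_surface_map(path)

    def test_outside_records_not_silently_dropped(self, tmp_path, unit_window):
        path = tmp_path / "m.csv"
        path.write_text("specimen_id,taxon,x_m,y_m\n1,t,0.5,0.5\n2,t,3.0,0.5\n")
        with pytest.raises(ValueError, match="outside"):
            read_surface_map(path, window=unit_window)
        with pytest.warns(UserWarning, match="dropped"):
            m = read_surface_map(path, window=unit_window, outside="drop")
        assert len(m) == 1


class TestStrain:
    def test_circular_discs_give_unit_ratio(self):
        s = estimate_strain([(1.0, 1.0, 0.3), (2.0, 2.0, 1.0), (0.5, 0.5, 2.0)])
        assert s.ratio == pytest.approx(1.0)

    def test_median_ratio(self):
        discs = [(1.4, 1.0, 0.5), (1.5, 1.0, 0.5), (1.6, 1.0, 0.5)]
        assert estimate_strain(discs).ratio == pytest.approx(1.5)

    def test_too_few_discs(self):
        with pytest.raises(InsufficientDataError):
            estimate_strain([(1.0, 1.0, 0.0), (1.0, 1.0, 0.0)])

    def test_stretched_circles_recover_strain(self, rng):
        # forward-transform oracle: stretch circles x1.5 along 30 degrees
        theta = math.radians(30)
        radii = rng.uniform(0.01, 0.05, 50)
        discs = [(r * math.sqrt(1.5), r / math.sqrt(1.5), theta) for r in radii]
        s = estimate_strain(discs)
        assert s.ratio == pytest.approx(1.5, abs=1e-9)
        assert math.degrees(s.orientation) == pytest.approx(30, abs=2)

    @pytest.mark.parametrize("area_preserving", [True, False])
    def test_strain_then_retrodeform_is_identity(self, rng, big_window, area_preserving):
        pts = big_window.sample_uniform(50, rng)
        m = make_map(pts, window=big_window, disc_width=0.03, disc_length=0.03)
        strain = StrainEstimate(ratio=1.7, orientation=0.6)
        distorted = apply_tectonic_strain(m, strain, area_preserving)
        restored = retrodeform(distorted, strain, area_preserving)
        orig = m.coords()
        rest = restored.coords()
        assert np.max(np.abs(orig - rest)) < 1e-9

    def test_identity_strain_is_noop(self, small_map):
        s = StrainEstimate(ratio=1.0, orientation=0.0)
        out = retrodeform(small_map, s)
        assert np.allclose(out.coords(), small_map.coords(), atol=1e-12)

    def test_retrodeformed_discs_circular(self, rng, big_window):
        pts = big_window.sample_uniform(40, rng)
        m = make_map(pts, window=big_window, disc_width=0.04, disc_length=0.04)
        strain = StrainEstimate(ratio=1.5, orientation=0.3)
        distorted = apply_tectonic_strain(m, strain)
        ratios = [r.disc_length / r.disc_width for r in distorted.records]
        assert np.mean(ratios) == pytest.approx(1.5, abs=1e-9)
        restored = retrodeform(distorted, strain)
        ratios = [r.disc_length / r.disc_width for r in restored.records]
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)


class TestFilters:
    def _mixed_map(self):
        recs = []
        k = 0

        def add(taxon, n, group="described_taxon"):
            nonlocal k
            for i in range(n):
                recs.append(
                    SpecimenRecord(f"s{k}", taxon, 0.1 + 0.001 * k, 0.5, group_class=group)
                )
                k += 1

        add("Abundant", 33)
        add("Borderline", 29)
        add("Sparse", 18)
        add("Hiemalora_like", 40, "organ_taxon")
        add("ivesheadiomorph", 50, "taphomorph")
        add("holdfast_disc", 35, "bin_group")
        return make_map(
            np.array([(r.x, r.y) for r in recs]),
            taxa=[r.taxon for r in recs],
            window=ObservationWindow.rectangle(0, 0, 1, 1),
        ).subset(recs, ObservationWindow.rectangle(0, 0, 1, 1))

    def test_default_threshold_30(self):
        m = self._mixed_map()
        out, report = filter_analysis_taxa(m, 30)
        counts = out.taxon_counts()
        assert counts == {"Abundant": 33}
        assert report.low_abundance == {"Borderline": 29, "Sparse": 18}
        assert report.taphomorphs == 50
        assert report.organ_taxa == 40
        assert report.bin_groups == 35

    def test_sparse_surface_threshold_16(self):
        # low-abundance override: taxa with more than 15 specimens retained
        m = self._mixed_map()
        out, _ = filter_analysis_taxa(m, 16)
        assert set(out.taxon_counts()) == {"Abundant", "Borderline", "Sparse"}

    def test_only_taphomorphs_gives_empty_map(self, unit_window):
        recs = [
            SpecimenRecord(f"s{i}", "iv", 0.5, 0.5 + i * 1e-4, group_class="taphomorph")
            for i in range(5)
        ]
        m = BedSurfaceMap("m", recs, unit_window)
        out, _ = filter_analysis_taxa(m)
        assert len(out) == 0

    def test_idempotent(self):
        m = self._mixed_map()
        once, _ = filter_analysis_taxa(m, 30)
        twice, rep = filter_analysis_taxa(once, 30)
        assert twice == once
        assert not rep.low_abundance


class TestSubwindow:
    def test_full_rect_is_identity(self, small_map):
        out = extract_rect_subwindow(small_map, small_map.window.bounds)
        assert out.records == small_map.records

    def test_left_half_counts(self, rng, unit_window):
        pts = rng.uniform(0, 1, (100, 2))
        m = make_map(pts, window=unit_window)
        out = extract_rect_subwindow(m, (0, 0, 0.5, 1.0))
        assert len(out) == int((pts[:, 0] <= 0.5).sum())
        assert all(r.x <= 0.5 for r in out.records)

    def test_empty_rect(self, small_map):
        out = extract_rect_subwindow(small_map, (100.0, 100.0, 101.0, 102.0))
        assert len(out) == 0
        assert out.window.area == pytest.approx(2.0)

    @given(
        x0=st.floats(0, 0.5), y0=st.floats(0, 0.5),
        wdt=st.floats(0.1, 0.5), hgt=st.floats(0.1, 0.5),
    )
    @settings(max_examples=25, deadline=None)
    def test_never_returns_point_outside_rect(self, x0, y0, wdt, hgt):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 1, (60, 2))
        m = make_map(pts, window=ObservationWindow.rectangle(0, 0, 1, 1))
        rect = (x0, y0, x0 + wdt, y0 + hgt)
        out = extract_rect_subwindow(m, rect)
        for r in out.records:
            assert rect[0] <= r.x <= rect[2] and rect[1] <= r.y <= rect[3]


class TestInscribedRectangle:
    def test_rectangle_window_returns_bounds(self, big_window):
        assert largest_inscribed_rectangle(big_window) == big_window.bounds

    def test_l_shaped_window(self):
        # L-shape: 2x2 square minus its upper-right 1x1 quadrant
        w = ObservationWindow([(0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2)])
        rect = largest_inscribed_rectangle(w, resolution=0.05)
        x0, y0, x1, y1 = rect
        area = (x1 - x0) * (y1 - y0)
        assert area == pytest.approx(2.0, rel=0.15)
        # the rectangle must sit inside the L
        assert w.contains([x0 + 1e-3, x1 - 1e-3], [y0 + 1e-3, y1 - 1e-3]).all()
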