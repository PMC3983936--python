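import random
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from featuretracks import (
    Feature,
    GlyphKind,
    LayoutConfig,
    RenderStyle,
    WindowError,
    assign_color,
    assign_rows,
    assign_tracks,
    build_layout,
    build_legend,
    compute_ruler,
    default_glyph,
    derive_geometry,
    place_features,
    position_to_pixel,
    region_width,
    zoom,
)
from featuretracks.layout import PALETTE, round_half_up

from conftest import random_intervals, residue_depth


class TestDeriveGeometry:
    def test_reference_view_700px_96_residues(self, q8lax3_config):
        d = derive_geometry(q8lax3_config)
        assert d.ruler_length == 660
        assert d.unitsize == 6.875

    def test_unit_scale(self):
        cfg = LayoutConfig(sequence_length=100, size_x=140)
        assert derive_geometry(cfg).unitsize == 1.0

    def test_zoomed_window_fractional_unitsize(self):
        cfg = LayoutConfig(sequence_length=96, requested_start=54,
                           requested_stop=96)
        assert derive_geometry(cfg).unitsize == pytest.approx(660 / 43)


class TestPixelMapping:
    def test_residue_74_maps_to_529(self, q8lax3_config):
        d = derive_geometry(q8lax3_config)
        # 20 + 74 * 6.875 = 528.75 -> 529
        assert position_to_pixel(74, q8lax3_config, d) == 529

    def test_window_stop_maps_to_ruler_end(self, q8lax3_config):
        d = derive_geometry(q8lax3_config)
        assert position_to_pixel(96, q8lax3_config, d) == 680

    def test_window_origin_maps_to_left_margin(self, q8lax3_config):
        d = derive_geometry(q8lax3_config)
        assert position_to_pixel(0, q8lax3_config, d) == 20

    def test_out_of_window_position_rejected(self, q8lax3_config):
        d = derive_geometry(q8lax3_config)
        with pytest.raises(WindowError):
            position_to_pixel(97, q8lax3_config, d)

    @given(st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_monotone_and_endpoint_consistent(self, data):
        length = data.draw(st.integers(5, 2000))
        start = data.draw(st.integers(1, length))
        stop = data.draw(st.integers(start, length))
        size_x = data.draw(st.integers(100, 1200))
        cfg = LayoutConfig(sequence_length=length, requested_start=start,
                           requested_stop=stop, size_x=size_x)
        d = derive_geometry(cfg)
        pixels = [position_to_pixel(p, cfg, d) for p in range(start - 1, stop + 1)]
        assert pixels == sorted(pixels)
        span = pixels[-1] - pixels[0]
        assert abs(span - d.ruler_length) <= 1
        if (d.unitsize * cfg.window_length).is_integer():
            assert span == d.ruler_length


class TestRegionWidth:
    @pytest.mark.parametrize(
        "start,end,unitsize,expected",
        [
            (74, 96, 6.875, 151),  # 22 * 6.875 = 151.25 -> 151
            (10, 10, 6.875, 0),
            (1, 97, 1.0, 96),
            (75, 96, 6.875, 144),  # 21 * 6.875 = 144.375 -> 144
        ],
    )
    def test_width_rounds_half_up(self, start, end, unitsize, expected):
        assert region_width(start, end, unitsize) == expected

    def test_half_up_tie_break(self):
        assert round_half_up(2.5) == 3
        assert round_half_up(2.4999) == 2


def _regions(*spans):
    return [Feature(feature_id=f"f{i}", start=s, end=e, type_label="Region")
            for i, (s, e) in enumerate(spans)]


class TestAssignTracks:
    def test_three_mutually_overlapping_features_need_three_tracks(
            self, three_listing_features):
        tracks = assign_tracks(three_listing_features)
        assert sorted(tracks.values()) == [0, 1, 2]

    def test_disjoint_features_share_track_zero(self):
        tracks = assign_tracks(_regions((1, 10), (20, 30)))
        assert set(tracks.values()) == {0}

    def test_touching_closed_intervals_overlap(self):
        tracks = assign_tracks(_regions((1, 10), (10, 20)))
        assert sorted(tracks.values()) == [0, 1]

    def test_track_count_matches_depth_oracle_on_random_sets(self):
        rng = random.Random(20140409)
        for _ in range(40):
            feats = random_intervals(rng, n_max=200, length=400)
            tracks = assign_tracks(feats)
            n_tracks = max(tracks.values(), default=-1) + 1
            assert n_tracks == residue_depth(feats, 400)

    def test_no_two_features_on_one_track_overlap(self):
        rng = random.Random(7)
        feats = random_intervals(rng, n_max=200, length=500)
        tracks = assign_tracks(feats)
        by_track = {}
        for f in feats:
            by_track.setdefault(tracks[f.feature_id], []).append(f)
        for members in by_track.values():
            members.sort(key=lambda f: f.start)
            for a, b in zip(members, members[1:]):
                assert a.end < b.start


class TestAssignRows:
    def test_rows_ordered_by_category_then_label(self):
        feats = [
            Feature(feature_id="a", start=1, end=5, type_label="Peptide",
                    type_category="Molecule processing"),
            Feature(feature_id="b", start=2, end=6, type_label="Active Site",
                    type_category="Molecule processing"),
        ]
        rows = assign_rows(feats)
        assert rows == {"b": 0, "a": 1}  # alphabetical within one category

    def test_single_type_single_row(self):
        rows = assign_rows(_regions((1, 5), (2, 8), (3, 9)))
        assert set(rows.values()) == {0}

    def test_k_types_k_rows(self):
        feats = [
            Feature(feature_id=f"f{i}", start=1, end=5,
                    type_label=f"Type{i}") for i in range(7)
        ]
        assert sorted(assign_rows(feats).values()) == list(range(7))


class TestDefaultGlyph:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("Metal ion binding", GlyphKind.CIRCLE),
            ("Active Site", GlyphKind.DIAMOND),
            ("Lipidation", GlyphKind.WAVE),
            ("Glycosylation site", GlyphKind.HEXAGON),
            ("Modified residue", GlyphKind.TRIANGLE),
            ("PTM", GlyphKind.TRIANGLE),
            ("Disulfide bond", GlyphKind.BRIDGE),
        ],
    )
    def test_field_conventions(self, label, expected):
        assert default_glyph(label) is expected

    def test_unmatched_region_is_rect(self):
        assert default_glyph("Peptide") is GlyphKind.RECT

    def test_unmatched_site_is_line(self):
        assert default_glyph("Chain", single_residue=True) is GlyphKind.LINE


class TestAssignColor:
    def test_explicit_color_wins_verbatim(self):
        assert assign_color("SO:0001064", "#33FF66") == "#33FF66"

    def test_same_code_same_color(self):
        assert assign_color("SO:0001064") == assign_color("SO:0001064")

    def test_palette_spread_over_vocabulary(self):
        codes = [f"SO:000{i:04d}" for i in range(40)]
        colors = {assign_color(c) for c in codes}
        assert len(colors) > 1
        assert colors <= set(PALETTE)


class TestComputeRuler:
    def test_fifteen_ticks_for_660px_at_division_50(self, q8lax3_config):
        d = derive_geometry(q8lax3_config)
        ticks = compute_ruler(q8lax3_config, d)
        assert len(ticks) == 15
        assert [t.x_px for t in ticks] == list(range(20, 671, 50)) + [680]
        assert ticks[0].label == 1
        assert ticks[-1].label == 96

    def test_huge_division_leaves_both_ends(self):
        cfg = LayoutConfig(sequence_length=96, pixels_division=10000)
        ticks = compute_ruler(cfg, derive_geometry(cfg))
        assert len(ticks) == 2
        assert ticks[0].x_px == 20 and ticks[-1].x_px == 680

    @given(st.data())
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_ticks_strictly_increasing_with_unique_labels(self, data):
        length = data.draw(st.integers(1, 3000))
        start = data.draw(st.integers(1, length))
        stop = data.draw(st.integers(start, length))
        division = data.draw(st.integers(5, 200))
        cfg = LayoutConfig(sequence_length=length, requested_start=start,
                           requested_stop=stop, pixels_division=division)
        d = derive_geometry(cfg)
        ticks = compute_ruler(cfg, d)
        xs = [t.x_px for t in ticks]
        assert xs == sorted(set(xs))
        assert xs[0] == cfg.left_margin
        assert xs[-1] == cfg.left_margin + d.ruler_length
        labels = [t.label for t in ticks]
        if cfg.window_length > 1:
            assert len(labels) == len(set(labels))
        assert all(start <= lab <= stop for lab in labels)


class TestPlaceFeatures:
    def test_centered_style_straddles_sequence_line(self, peptide_feature):
        cfg = LayoutConfig(sequence_length=96, style="centered")
        d = derive_geometry(cfg)
        placed = place_features([peptide_feature], cfg, d)
        assert placed[0].y == 75  # 95 - 40/2
        assert placed[0].track_index == 0

    def test_reference_rect_geometry(self, peptide_feature, q8lax3_config):
        d = derive_geometry(q8lax3_config)
        p = place_features([peptide_feature], q8lax3_config, d)[0]
        assert (p.x, p.width) == (529, 151)
        assert p.glyph is GlyphKind.RECT
        assert p.fill == "#7DBAA4"

    def test_first_track_sits_gap_below_sequence_line(
            self, peptide_feature, q8lax3_config):
        d = derive_geometry(q8lax3_config)
        p = place_features([peptide_feature], q8lax3_config, d)[0]
        assert p.y == 54 + 2

    def test_empty_input_empty_output(self, q8lax3_config):
        d = derive_geometry(q8lax3_config)
        assert place_features([], q8lax3_config, d) == []

    def test_style_blocks_cover_all_three_styles(
            self, peptide_feature, q8lax3_config):
        d = derive_geometry(q8lax3_config)
        p = place_features([peptide_feature], q8lax3_config, d)[0]
        assert set(p.style_blocks) == {"nonOverlapping", "centered", "rows"}
        assert p.style_blocks["centered"] == {"heightOrRadius": 40, "y": 75}


class TestLegend:
    def test_distinct_types_counted_once(self, three_listing_features,
                                         q8lax3_config):
        cfg = LayoutConfig(sequence_length=770)
        d = derive_geometry(cfg)
        placed = place_features(three_listing_features, cfg, d)
        legend = build_legend(placed)
        # Peptide/blue/rect, Active Site/diamond, Active Site/#33FF66/bridge
        assert len(legend) == 3
        labels = [e.type_label for e in legend]
        assert labels == sorted(labels)

    def test_empty_legend(self):
        assert build_legend([]) == []


class TestZoom:
    def test_zoom_to_full_window_is_identity(self, peptide_feature,
                                             q8lax3_config):
        base = build_layout("Q8LAx3", [peptide_feature], q8lax3_config)
        zoomed = zoom([peptide_feature], q8lax3_config, 1, 96,
                      segment_id="Q8LAx3")
        assert zoomed == base

    def test_zoom_is_idempotent(self, three_listing_features):
        cfg = LayoutConfig(sequence_length=770)
        once = zoom(three_listing_features, cfg, 50, 120, segment_id="a4")
        twice = zoom(three_listing_features, once.config, 50, 120,
                     segment_id="a4")
        assert once == twice

    def test_zoom_grows_unitsize(self, peptide_feature, q8lax3_config):
        doc = zoom([peptide_feature], q8lax3_config, 74, 96)
        assert doc.derived.unitsize == pytest.approx(660 / 23)

    def test_partially_visible_feature_clipped_and_flagged(self):
        cfg = LayoutConfig(sequence_length=96)
        f = Feature(feature_id="pep", start=54, end=96, type_label="Peptide")
        doc = zoom([f], cfg, 74, 96)
        p = doc.placed[0]
        assert (p.feature.start, p.feature.end) == (74, 96)
        assert p.clipped_left and not p.clipped_right

    def test_feature_outside_window_dropped(self):
        cfg = LayoutConfig(sequence_length=200)
        f = Feature(feature_id="far", start=150, end=180)
        assert zoom([f], cfg, 1, 100).placed == []

    def test_invalid_window_rejected(self, q8lax3_config):
        with pytest.raises(WindowError):
            zoom([], q8lax3_config, 50, 10)
        with pytest.raises(WindowError):
            zoom([], q8lax3_config, 1, 500)


class TestBuildLayout:
    def test_reference_document_geometry(self, q8lax3_doc):
        assert q8lax3_doc.derived.unitsize == 6.875
        assert q8lax3_doc.derived.ruler_length == 660
        p = q8lax3_doc.placed[0]
        assert (p.x, p.width) == (529, 151)

    def test_empty_feature_set_keeps_ruler_and_margins(self, q8lax3_config):
        doc = build_layout("empty", [], q8lax3_config)
        assert doc.placed == [] and doc.legend == []
        assert len(doc.ticks) == 15
        assert doc.derived.size_y == 54 + 30  # sequence line + below_ruler

    def test_documents_are_deterministic(self, three_listing_features):
        cfg = LayoutConfig(sequence_length=770)
        a = build_layout("a4_human", three_listing_features, cfg)
        b = build_layout("a4_human", list(three_listing_features), cfg)
        assert a == b

    def test_placed_sorted_by_track_then_x(self, three_listing_features):
        cfg = LayoutConfig(sequence_length=770)
        doc = build_layout("a4_human", three_listing_features, cfg)
        keys = [(p.track_index, p.x) for p in doc.placed]
        assert keys == sorted(keys)

    def test_large_fixture_respects_canvas_bounds(self):
        from featuretracks import generate_fixture

        feats = generate_fixture(100, 800, max_depth=6, seed=3)
        cfg = LayoutConfig(sequence_length=800)
        doc = build_layout("syn", feats, cfg)
        lo, hi = cfg.left_margin, cfg.left_margin + doc.derived.ruler_length
        for p in doc.placed:
            assert lo <= p.x <= p.x + p.width <= hi
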