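"""Standard/vertical layout engine: geometry, colors, glyphs, tracks."""

import json
import math

import pytest

from phewas_view import (
    AssociationRecord,
    ConfigurationError,
    CorrelationMatrix,
    DEFAULT_GROUP_STYLES,
    EmptyResultError,
    PheWASDataset,
    PlotConfig,
    SignificanceClass,
    assign_axis_positions,
    build_group_glyph_layout,
    build_heatmap_panel,
    build_standard_layout,
    build_tracks,
    build_vertical_layout,
    classify_dataset,
    heatmap_color,
    generate_dataset,
    paper_like_spec,
)


def rec(snp="rs1", phen="PhenA", p=0.5, idx=0, **kw):
    return AssociationRecord(snp, phen, p, idx, **kw)


class TestAxisPositions:
    def test_first_appearance_order(self):
        ds = PheWASDataset.from_records(
            [rec(phen="PhenB", idx=0), rec(phen="PhenA", idx=1),
             rec(phen="PhenB", idx=2)]
        )
        assert assign_axis_positions(ds) == [("PhenB", 0), ("PhenA", 1)]

    def test_presorted_input_keeps_sorted_order(self):
        """A file pre-sorted by p-value yields an axis in that order."""
        records = [
            rec(phen=f"Phen{i}", p=p, idx=i)
            for i, p in enumerate([1e-6, 1e-4, 0.01, 0.5])
        ]
        ds = PheWASDataset.from_records(records)
        axis = assign_axis_positions(ds)
        assert [phen for phen, _ in axis] == [
            "Phen0", "Phen1", "Phen2", "Phen3"
        ]

    def test_single_phenotype(self):
        ds = PheWASDataset.from_records([rec()])
        assert assign_axis_positions(ds) == [("PhenA", 0)]


class TestStandardLayout:
    def test_points_at_neg_log10_heights(self):
        ds = PheWASDataset.from_records(
            [rec(p=0.01, idx=0), rec(p=0.1, idx=1)]
        )
        layout = build_standard_layout(ds, PlotConfig())
        assert len(layout.points) == 2
        assert {p.position for p in layout.points} == {0}
        assert sorted(p.value for p in layout.points) == pytest.approx(
            [1.0, 2.0]
        )

    def test_redline_height(self):
        ds = PheWASDataset.from_records([rec()])
        layout = build_standard_layout(ds, PlotConfig(redline_p=0.01))
        assert layout.redline == pytest.approx(2.0)

    def test_color_roles_follow_classes(self):
        ds = PheWASDataset.from_records(
            [rec(p=0.001, idx=0), rec(p=0.5, idx=1),
             rec(snp="rs9", p=0.001, idx=2)]
        )
        classes = [
            SignificanceClass.HIGHLIGHT,
            SignificanceClass.BACKGROUND,
            SignificanceClass.NOVEL,
        ]
        layout = build_standard_layout(ds, PlotConfig(), classes)
        assert [p.color for p in layout.points] == ["blue", "grey", "purple"]

    def test_default_color_is_blue(self):
        ds = PheWASDataset.from_records([rec()])
        layout = build_standard_layout(ds, PlotConfig())
        assert layout.points[0].color == "blue"

    def test_empty_dataset_raises_empty_result(self):
        ds = PheWASDataset.from_records([rec()]).subset([])
        with pytest.raises(EmptyResultError, match="relax"):
            build_standard_layout(ds, PlotConfig())

    def test_point_count_equals_record_count(self, demo_dataset):
        layout = build_standard_layout(demo_dataset, PlotConfig())
        assert len(layout.points) == len(demo_dataset)

    def test_long_description_used_for_axis_labels(self):
        ds = PheWASDataset.from_records(
            [rec(phenotype_long="Phenotype A, long form")]
        )
        layout = build_standard_layout(ds, PlotConfig())
        assert layout.phenotype_axis == (("Phenotype A, long form", 0),)

    def test_deterministic_serialization(self, demo_dataset):
        config = PlotConfig(redline_p=0.01)
        classes = classify_dataset(demo_dataset, highlight_p=0.01)
        a = build_standard_layout(demo_dataset, config, classes)
        b = build_standard_layout(demo_dataset, config, classes)
        assert json.dumps(a.to_dict(), sort_keys=True) == json.dumps(
            b.to_dict(), sort_keys=True
        )


class TestVerticalLayout:
    def test_transposition_preserves_point_multiset(self, demo_dataset):
        h = build_standard_layout(demo_dataset, PlotConfig())
        v = build_vertical_layout(
            demo_dataset, PlotConfig(orientation="vertical")
        )
        assert h.orientation == "horizontal" and v.orientation == "vertical"
        assert sorted((p.position, p.value) for p in h.points) == sorted(
            (p.position, p.value) for p in v.points
        )

    def test_best_annotation_content(self):
        ds = PheWASDataset.from_records(
            [
                rec("rs673548", "PhenA", 0.001, 0, gene="GENE1", effect=-0.2),
                rec("rs999", "PhenA", 0.5, 1, gene="GENE2", effect=0.4),
            ]
        )
        layout = build_vertical_layout(
            ds,
            PlotConfig(orientation="vertical", show_best_annotations=True),
        )
        assert layout.annotations == ((0, "rs673548 GENE1 -"),)

    def test_annotation_degrades_without_gene_and_effect(self, caplog):
        ds = PheWASDataset.from_records([rec("rs1", "PhenA", 0.01, 0)])
        with caplog.at_level("WARNING", logger="phewas_view"):
            layout = build_vertical_layout(
                ds,
                PlotConfig(
                    orientation="vertical", show_best_annotations=True
                ),
            )
        assert layout.annotations == ((0, "rs1"),)
        assert any("SNP id only" in m for m in caplog.messages)


class TestGroupGlyphLayout:
    def _ds(self):
        return PheWASDataset.from_records(
            [
                rec("rs1", "PhenA", 0.01, 0, group="AA", effect=0.3),
                rec("rs1", "PhenA", 0.02, 1, group="EA", effect=-0.1),
                rec("rs1", "PhenB", 0.03, 2, group="AA", effect=0.0),
            ]
        )

    def test_triangles_and_group_colors(self):
        layout = build_group_glyph_layout(self._ds(), PlotConfig())
        pts = layout.points
        assert (pts[0].color, pts[0].glyph) == ("blue", "triangle_up")
        assert (pts[1].color, pts[1].glyph) == ("red", "triangle_down")

    def test_zero_effect_points_up(self):
        layout = build_group_glyph_layout(self._ds(), PlotConfig())
        assert layout.points[2].glyph == "triangle_up"

    def test_unmapped_group_label_names_it(self):
        ds = PheWASDataset.from_records(
            [rec(group="XX", effect=0.1)]
        )
        with pytest.raises(ConfigurationError, match="XX"):
            build_group_glyph_layout(ds, PlotConfig())

    def test_requires_group_and_effect_columns(self):
        no_effect = PheWASDataset.from_records([rec(group="AA")])
        with pytest.raises(ConfigurationError):
            build_group_glyph_layout(no_effect, PlotConfig())
        no_group = PheWASDataset.from_records([rec(effect=0.1)])
        with pytest.raises(ConfigurationError):
            build_group_glyph_layout(no_group, PlotConfig())


class TestTracks:
    def test_tracks_align_with_axis_positions(self):
        ds = PheWASDataset.from_records(
            [rec(effect=-0.4, sample_size=1200)]
        )
        effect, sizes = build_tracks(
            ds,
            PlotConfig(show_effect_track=True, show_sample_size_track=True),
        )
        assert effect == ((0, -0.4),)
        assert sizes == ((0, 1200),)

    def test_missing_columns_are_configuration_errors(self):
        ds = PheWASDataset.from_records([rec()])
        with pytest.raises(ConfigurationError, match="ES"):
            build_tracks(ds, PlotConfig(show_effect_track=True))
        with pytest.raises(ConfigurationError, match="sample-size"):
            build_tracks(ds, PlotConfig(show_sample_size_track=True))

    def test_all_positive_effects_stay_positive(self, demo_spec):
        ds = generate_dataset(demo_spec)
        positives = ds.subset(r for r in ds if r.effect >= 0)
        effect, _ = build_tracks(
            positives, PlotConfig(show_effect_track=True)
        )
        assert min(v for _, v in effect) >= 0


class TestHeatmap:
    def test_endpoint_colors(self):
        assert heatmap_color(1.0) == "#ffff00"  # yellow
        assert heatmap_color(0.0) == "#0000ff"  # blue
        assert heatmap_color(-1.0) == "#ffff00"

    def test_midpoint_is_linear(self):
        # each channel at 127.5, the exact midpoint, rounds to 0x80
        assert heatmap_color(0.5) == "#808080"

    def test_invariant_under_sign_flip(self):
        for r in (0.1, 0.35, 0.8):
            assert heatmap_color(r) == heatmap_color(-r)

    def test_monotone_in_abs_r_per_channel(self):
        rs = [i / 20 for i in range(21)]
        colors = [heatmap_color(r) for r in rs]
        reds = [int(c[1:3], 16) for c in colors]
        greens = [int(c[3:5], 16) for c in colors]
        blues = [int(c[5:7], 16) for c in colors]
        assert reds == sorted(reds)
        assert greens == sorted(greens)
        assert blues == sorted(blues, reverse=True)

    def test_panel_aligned_to_axis(self):
        matrix = CorrelationMatrix(
            labels=("PhenA", "PhenB"),
            values=((1.0, -0.8), (-0.8, 1.0)),
        )
        ds = PheWASDataset.from_records(
            [rec(phen="PhenA", idx=0), rec(phen="PhenB", idx=1)]
        )
        cells = build_heatmap_panel(matrix, assign_axis_positions(ds))
        grid = {(r, c): color for r, c, color in cells}
        assert grid[(0, 0)] == "#ffff00"
        assert grid[(0, 1)] == grid[(1, 0)] == heatmap_color(0.8)

    def test_missing_phenotype_named_in_error(self):
        matrix = CorrelationMatrix(labels=("PhenA",), values=((1.0,),))
        ds = PheWASDataset.from_records([rec(phen="PhenZ")])
        with pytest.raises(Exception, match="PhenZ"):
            build_heatmap_panel(matrix, assign_axis_positions(ds))
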