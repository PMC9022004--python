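"""Bulk-assignment tables and synthetic-CT construction."""

import numpy as np
import pytest

from sctdosim import (
    GridSpec,
    build_phantom,
    build_sct,
    hu_to_red,
    make_assignment_table,
    summarize_roi_red,
)
from sctdosim.errors import ConfigError
from sctdosim.sct import AssignmentEntry, AssignmentTable
from sctdosim.structures import StructureSet

from conftest import coarse_spec


@pytest.fixture(scope="module")
def phantom_summary(coarse_phantom, coarse_structures):
    red = hu_to_red(coarse_phantom.ct)
    return red, summarize_roi_red(red, coarse_structures)


class TestAssignmentTable:
    def test_homogeneity_single_body_entry_at_one(self, phantom_summary):
        _, summary = phantom_summary
        table = make_assignment_table("homogeneity", summary)
        assert len(table.entries) == 1
        assert table.entries[0].roi == "body"
        assert table.entries[0].red == 1.0

    def test_icru_bone_and_air_values(self, phantom_summary):
        _, summary = phantom_summary
        table = make_assignment_table("icru", summary)
        assert table.value_of("cranium") == 1.61
        assert table.value_of("air_cavity") == 0.001
        # everything else keeps its patient-specific mean
        assert table.value_of("ptv_nx") == pytest.approx(summary.mean_red("ptv_nx"))
        assert table.value_of("body") == pytest.approx(summary.mean_red("body"))

    def test_tailor_is_summary_passthrough(self, phantom_summary):
        _, summary = phantom_summary
        table = make_assignment_table("tailor", summary)
        for name in summary.names:
            assert table.value_of(name) == pytest.approx(summary.mean_red(name))

    def test_missing_required_roi_raises_with_name(self, phantom_summary):
        red, _ = phantom_summary
        ss = StructureSet(red.grid)
        ss.add("body", "body", np.ones(red.shape, dtype=bool))
        summary = summarize_roi_red(red, ss)
        with pytest.raises(ConfigError, match="bone"):
            make_assignment_table("icru", summary)

    def test_duplicate_ranks_rejected(self):
        with pytest.raises(ConfigError):
            AssignmentTable(
                "tailor",
                [AssignmentEntry("body", 1.0, 0), AssignmentEntry("a", 0.5, 0)],
            )

    def test_homogeneity_body_must_be_water(self):
        with pytest.raises(ConfigError):
            AssignmentTable("homogeneity", [AssignmentEntry("body", 1.1, 0)])

    def test_yaml_round_trip(self, tmp_path, phantom_summary):
        _, summary = phantom_summary
        table = make_assignment_table("icru", summary)
        path = tmp_path / "table.yaml"
        table.to_yaml(path)
        back = AssignmentTable.from_yaml(path)
        assert back.strategy == table.strategy
        assert [(e.roi, e.red, e.rank) for e in back.entries] == [
            (e.roi, e.red, e.rank) for e in table.entries
        ]


class TestBuildSct:
    def test_disjoint_rois_take_their_own_values(self):
        grid = GridSpec((4, 4, 4), (0, 0, 0), (2, 2, 2))
        ss = StructureSet(grid)
        body = np.ones((4, 4, 4), dtype=bool)
        left = np.zeros_like(body)
        left[:2] = True
        ss.add("body", "body", body)
        ss.add("left", "oar", left)
        table = AssignmentTable(
            "tailor",
            [AssignmentEntry("body", 1.0, 0), AssignmentEntry("left", 0.5, 1)],
        )
        sct = build_sct(ss, table)
        assert np.all(sct.red_map.values[:2] == 0.5)
        assert np.all(sct.red_map.values[2:] == 1.0)

    def test_air_cavity_wins_inside_target(self, coarse_structures, phantom_summary):
        """An air cavity inside the primary target keeps the air value
        under the default precedence."""
        _, summary = phantom_summary
        table = make_assignment_table("icru", summary)
        sct = build_sct(coarse_structures, table)
        overlap = (
            coarse_structures["ptv_nx"].mask & coarse_structures["air_cavity"].mask
        )
        assert overlap.any()
        assert np.all(sct.red_map.values[overlap] == 0.001)

    def test_background_outside_body(self, coarse_structures, phantom_summary):
        _, summary = phantom_summary
        sct = build_sct(coarse_structures, make_assignment_table("tailor", summary))
        outside = ~coarse_structures.body.mask
        # outside voxels not covered by any ROI carry the air background
        covered = np.zeros_like(outside)
        for roi in coarse_structures.rois:
            covered |= roi.mask
        assert np.all(sct.red_map.values[outside & ~covered] == 0.001)

    def test_tailor_conserves_roi_means_identity_registration(
        self, coarse_structures, phantom_summary
    ):
        """With identity registration the per-ROI mean of the tailored
        sCT equals the planning-CT ROI mean to 1e-12 wherever the ROI is
        not overwritten by a higher-precedence one."""
        red, summary = phantom_summary
        table = make_assignment_table("tailor", summary)
        sct = build_sct(coarse_structures, table)
        ranks = {e.roi: e.rank for e in table.entries}
        for roi in coarse_structures.rois:
            higher = np.zeros(red.shape, dtype=bool)
            for other in coarse_structures.rois:
                if ranks[other.name] > ranks[roi.name]:
                    higher |= other.mask
            clean = roi.mask & ~higher
            if not clean.any() or not np.array_equal(clean, roi.mask):
                continue
            assert sct.red_map.values[roi.mask].mean() == pytest.approx(
                summary.mean_red(roi.name), abs=1e-12
            )

    def test_distinct_values_bounded_by_entries(self, coarse_structures, phantom_summary):
        _, summary = phantom_summary
        for strategy in ("homogeneity", "icru", "tailor"):
            table = make_assignment_table(strategy, summary)
            sct = build_sct(coarse_structures, table)
            body_vals = np.unique(sct.red_map.values[coarse_structures.body.mask])
            assert body_vals.size <= len(table.entries)

    def test_equal_value_disjoint_entries_order_independent(self):
        grid = GridSpec((4, 4, 4), (0, 0, 0), (2, 2, 2))
        body = np.ones((4, 4, 4), dtype=bool)
        a = np.zeros_like(body); a[0] = True
        b = np.zeros_like(body); b[3] = True
        ss = StructureSet(grid)
        ss.add("body", "body", body)
        ss.add("a", "oar", a)
        ss.add("b", "oar", b)
        t1 = AssignmentTable("tailor", [AssignmentEntry("body", 1.0, 0),
                                        AssignmentEntry("a", 0.5, 1),
                                        AssignmentEntry("b", 0.7, 2)])
        t2 = AssignmentTable("tailor", [AssignmentEntry("body", 1.0, 0),
                                        AssignmentEntry("b", 0.7, 1),
                                        AssignmentEntry("a", 0.5, 2)])
        assert np.array_equal(build_sct(ss, t1).red_map.values,
                              build_sct(ss, t2).red_map.values)

    def test_missing_roi_in_structures_rejected(self, coarse_structures):
        table = AssignmentTable("tailor", [AssignmentEntry("body", 1.0, 0),
                                           AssignmentEntry("nope", 0.5, 1)])
        with pytest.raises(ConfigError, match="nope"):
            build_sct(coarse_structures, table)

    def test_tailor_minimizes_mean_absolute_density_error(self):
        """Across seeds, the tailored sCT tracks the true density map
        more closely (body-wide mean |error|) than ICRU or water."""
        from sctdosim.pipeline import StudyConfig, build_reference_structures

        wins = 0
        for seed in range(5):
            ph = build_phantom(coarse_spec(seed))
            structures = build_reference_structures(ph, StudyConfig(seeds=(seed,)))
            red = hu_to_red(ph.ct)
            summary = summarize_roi_red(red, structures)
            errors = {}
            for strategy in ("homogeneity", "icru", "tailor"):
                sct = build_sct(structures, make_assignment_table(strategy, summary))
                body = structures.body.mask
                errors[strategy] = np.abs(
                    sct.red_map.values[body] - red.values[body]
                ).mean()
            if errors["tailor"] <= min(errors.values()):
                wins += 1
        assert wins == 5
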