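"""Plate model: registry inheritance, subsetting, pipeline orchestration."""

import warnings

import numpy as np
import pandas as pd
import pytest

import dropgate as dg
from dropgate.errors import InputError, RegistryError, SelectionError
from dropgate.plate_model import (
    AssayType,
    STEP_CLASSIFY_PNPP,
    analyze,
    new_plate,
    next_step,
    plates_equal,
    resolve_assay,
    set_params,
    subset_plate,
    well_table,
)

GENERIC_STEPS = ("initialize", "remove_failures", "remove_outliers", "remove_empty")


class TestRegistry:
    def test_generic_resolves_to_four_steps_without_gating(self):
        steps, params, pos = resolve_assay("generic")
        assert steps == GENERIC_STEPS
        assert pos is None
        assert "pnpp" not in params

    @pytest.mark.parametrize("name,channel", [("fam_positive_pnpp", 1), ("hex_positive_pnpp", 2)])
    def test_pnpp_types_add_gating_steps(self, name, channel):
        steps, params, pos = resolve_assay(name)
        assert steps == GENERIC_STEPS + ("classify_pnpp", "reclassify_pnpp")
        assert pos == channel
        assert "pnpp" in params

    def test_root_steps_are_prefix_of_every_type(self):
        from dropgate.plate_model import registered_assays

        for name in registered_assays():
            steps, _, _ = resolve_assay(name)
            assert steps[: len(GENERIC_STEPS)] == GENERIC_STEPS

    def test_child_override_changes_only_that_entry(self):
        registry = {
            "generic": AssayType("generic", None, GENERIC_STEPS, {"gate": {"outlier_k": 5.0, "min_total_droplets": 5000}}),
            "child": AssayType("child", "generic", None, {"gate": {"outlier_k": 9.0}}),
        }
        _, parent_params, _ = resolve_assay("generic", registry)
        _, child_params, _ = resolve_assay("child", registry)
        assert child_params["gate"]["outlier_k"] == 9.0
        assert child_params["gate"]["min_total_droplets"] == parent_params["gate"]["min_total_droplets"]

    def test_transitive_inheritance_through_grandparent(self):
        registry = {
            "generic": AssayType("generic", None, GENERIC_STEPS, {"gate": {"outlier_k": 5.0}}),
            "mid": AssayType("mid", "generic", None, {"gate": {"outlier_k": 7.0}}),
            "leaf": AssayType("leaf", "mid", None, {}),
        }
        _, params, _ = resolve_assay("leaf", registry)
        assert params["gate"]["outlier_k"] == 7.0

    def test_cycle_detected(self):
        registry = {
            "a": AssayType("a", "b"),
            "b": AssayType("b", "a"),
        }
        with pytest.raises(RegistryError, match="cycle"):
            resolve_assay("a", registry)

    def test_unknown_type_rejected(self):
        with pytest.raises(RegistryError):
            resolve_assay("no_such_assay")


class TestNewPlate:
    def test_simulated_bundle_loads_with_known_counts(self, sim_bundle, fresh_plate):
        _, specs = sim_bundle
        counts = fresh_plate.plate_data.groupby("well").size()
        for well, sp in specs.items():
            assert counts[well] == sp.n_droplets
        assert (fresh_plate.plate_data["label"] == "UNDEFINED").all()
        assert fresh_plate.status.cursor == 0
        assert fresh_plate.steps[0] == "initialize"

    def test_unknown_assay_type(self, sim_bundle):
        directory, _ = sim_bundle
        with pytest.raises(RegistryError):
            new_plate(directory, assay_type="bogus")

    def test_empty_directory_rejected(self, tmp_path):
        with pytest.raises(InputError):
            new_plate(tmp_path, assay_type="generic")

    def test_metadata_only_wells_kept_as_unused(self, tmp_path):
        dg.simulate_plate_bundle({"A01": dg.SimParams(seed=1, n_droplets=6000)}, tmp_path, prefix="M")
        meta = tmp_path / "M_metadata.csv"
        meta.write_text(meta.read_text() + "H12,ghost_sample,MUT\n")
        plate = new_plate(tmp_path, assay_type="generic")
        assert "H12" in plate.plate_meta.index
        assert not plate.plate_meta.loc["H12", "used"]
        assert plate.plate_meta.loc["H12", "sample"] == "ghost_sample"
        assert plate.used_wells() == ["A01"]


class TestSubset:
    def test_single_well(self, fresh_plate):
        sub = subset_plate(fresh_plate, "A02")
        assert sub.wells() == ["A02"]
        assert set(sub.plate_data["well"]) == {"A02"}

    def test_rectangular_block(self, fresh_plate):
        sub = subset_plate(fresh_plate, "A01:B02")
        assert sub.wells() == ["A01", "A02", "B01"]  # B02 absent from plate

    def test_identity_subset_differs_only_in_name(self, fresh_plate):
        sub = subset_plate(fresh_plate, "A01,A02,B01")
        clone = sub.copy()
        clone.name = fresh_plate.name
        assert plates_equal(clone, fresh_plate)

    def test_no_match_raises(self, fresh_plate):
        with pytest.raises(SelectionError):
            subset_plate(fresh_plate, "H12")


class TestAnalyze:
    def test_all_droplets_labeled_and_partition_holds(self, analyzed_plate):
        wt = well_table(analyzed_plate)
        for _, row in wt.iterrows():
            droplets = analyzed_plate.plate_data[
                analyzed_plate.plate_data["well"] == row.well
            ]
            assert not (droplets["label"] == "UNDEFINED").any()
            if row.success:
                parts = (
                    row.n_outlier + row.n_empty + row.n_rain
                    + row.n_single_pos + row.n_double_pos
                )
                assert parts == row.n_total == len(droplets)
            else:
                assert (droplets["label"] == "FAILED").all()

    def test_idempotent(self, analyzed_plate):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = analyze(analyzed_plate)
        assert plates_equal(analyzed_plate, again)

    def test_next_step_composition_equals_analyze(self, fresh_plate, analyzed_plate):
        stepped = fresh_plate
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(len(fresh_plate.steps) - 1):
                stepped = next_step(stepped)
        assert plates_equal(stepped, analyzed_plate)

    def test_next_step_past_end_warns_and_is_noop(self, analyzed_plate):
        with pytest.warns(UserWarning, match="complete"):
            after = next_step(analyzed_plate)
        assert plates_equal(after, analyzed_plate)

    def test_first_step_only_assigns_failure_labels(self, fresh_plate):
        one = next_step(fresh_plate)
        assert one.status.cursor == 1
        labels = set(one.plate_data["label"].unique())
        assert labels <= {"UNDEFINED", "FAILED"}
        assert (one.plate_data.loc[one.plate_data["well"] == "B01", "label"] == "FAILED").all()

    def test_generic_pipeline_stops_after_empty_removal(self, sim_bundle):
        directory, _ = sim_bundle
        plate = analyze(new_plate(directory, assay_type="generic"))
        assert plate.status.cursor == len(plate.steps) - 1
        labels = set(plate.plate_data["label"].unique())
        assert "SINGLE_POS" not in labels and "DOUBLE_POS" not in labels
        assert "UNDEFINED" in labels  # filled droplets remain ungated

    def test_failed_step_leaves_input_plate_unchanged(self, fresh_plate, monkeypatch):
        from dropgate import plate_model

        def boom(plate):
            raise RuntimeError("synthetic step failure")

        monkeypatch.setitem(plate_model.STEP_FUNCTIONS, "remove_outliers", boom)
        before = fresh_plate.copy()
        with pytest.raises(RuntimeError):
            analyze(fresh_plate)
        assert plates_equal(before, fresh_plate)


class TestDirtyRecompute:
    def test_param_edit_marks_dirty_and_rerun_matches_fresh(self, sim_bundle):
        directory, _ = sim_bundle
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plate = analyze(new_plate(directory, assay_type="fam_positive_pnpp"))
            edited = set_params(plate, "pnpp", rain_sd_multiplier=5.0)
            assert edited.dirty
            assert edited.status.restart_from == edited.steps.index(STEP_CLASSIFY_PNPP)
            rerun = analyze(edited)

            fresh = new_plate(directory, assay_type="fam_positive_pnpp")
            fresh = set_params(fresh, "pnpp", rain_sd_multiplier=5.0)
            reference = analyze(fresh)
        rerun2 = rerun.copy()
        rerun2.name = reference.name
        assert not rerun.dirty
        assert plates_equal(rerun2, reference)

    def test_edit_before_running_does_not_mark_dirty(self, fresh_plate):
        edited = set_params(fresh_plate, "pnpp", rain_sd_multiplier=5.0)
        assert not edited.dirty

    def test_unknown_parameter_rejected(self, fresh_plate):
        with pytest.raises(KeyError):
            set_params(fresh_plate, "gate", no_such_knob=1)


class TestWellTable:
    def test_unanalyzed_plate_has_counts_but_no_concentrations(self, fresh_plate):
        wt = well_table(fresh_plate)
        assert (wt["n_total"] > 0).all()
        assert wt["conc_total"].isna().all()
        assert wt["mutant_freq"].isna().all()

    def test_counts_match_droplet_label_tallies(self, analyzed_plate):
        wt = well_table(analyzed_plate).set_index("well")
        for well, group in analyzed_plate.plate_data.groupby("well"):
            tally = group["label"].value_counts()
            assert wt.loc[well, "n_empty"] == tally.get("EMPTY", 0)
            assert wt.loc[well, "n_single_pos"] == tally.get("SINGLE_POS", 0)
            assert wt.loc[well, "n_double_pos"] == tally.get("DOUBLE_POS", 0)
            assert wt.loc[well, "n_rain"] == tally.get("RAIN", 0)
            assert wt.loc[well, "n_outlier"] == tally.get("OUTLIER", 0)

    def test_rows_sorted_row_major(self, analyzed_plate):
        wt = well_table(analyzed_plate)
        assert list(wt["well"]) == sorted(wt["well"])

    def test_failed_well_row(self, analyzed_plate):
        row = well_table(analyzed_plate).set_index("well").loc["B01"]
        assert not row["success"]
        assert "too few" in row["failure_reason"]
        assert pd.isna(row["conc_total"]) and pd.isna(row["mutant_freq"])


class TestCommutation:
    def test_subset_then_analyze_equals_analyze_then_subset(self, tmp_path):
        # both wells confident, so the cross-well re-gate is inert
        specs = {
            "C01": dg.SimParams(seed=51, lambda_wt=0.5, lambda_mut=0.1, n_droplets=8000),
            "C02": dg.SimParams(seed=52, lambda_wt=0.6, lambda_mut=0.15, n_droplets=8000),
        }
        dg.simulate_plate_bundle(specs, tmp_path, prefix="CM")
        plate = new_plate(tmp_path, assay_type="fam_positive_pnpp")
        a = analyze(subset_plate(plate, "C01"))
        b = subset_plate(analyze(plate), "C01")
        pd.testing.assert_frame_equal(
            a.plate_data.reset_index(drop=True), b.plate_data.reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(
            well_table(a), well_table(b), check_dtype=False
        )
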