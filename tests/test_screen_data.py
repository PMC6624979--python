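"""Parsing, validation and log-fold-change computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from giscreen import ScreenError, accept_external_lfc, compute_lfc, load_screen, pair_key
from giscreen.screen_data import CountMatrix

from .conftest import make_design, make_lfc


class TestLoadScreen:
    def test_toy_round_trip(self, toy_screen_files):
        design, counts = load_screen(
            toy_screen_files["counts"],
            toy_screen_files["annotation"],
            toy_screen_files["samples"],
            negative_control_genes=["NC"],
        )
        assert len(design.construct_ids) == 3
        assert design.sample_ids == ["s1"]
        assert design.samples[0].n_replicates == 2
        assert design.samples[0].replicates[0].early_columns == ("early",)
        assert counts.values.loc["c2", "s1_r1"] == 200

    def test_unannotated_construct_is_an_error_naming_it(self, toy_screen_files, tmp_path):
        counts = tmp_path / "extra.tsv"
        counts.write_text(
            toy_screen_files["counts"].read_text() + "c4\t10\t10\t10\n"
        )
        with pytest.raises(ScreenError, match="c4"):
            load_screen(counts, toy_screen_files["annotation"], toy_screen_files["samples"])

    def test_sample_without_late_timepoint_rejected(self, toy_screen_files, tmp_path):
        sheet = tmp_path / "bad_sheet.tsv"
        sheet.write_text(
            "column\tsample\treplicate\ttimepoint\n"
            "early\ts1\t1\tearly\n"
            "s1_r1\ts1\t1\tearly\n"
            "s1_r2\ts1\t2\tearly\n"
        )
        with pytest.raises(ScreenError, match="late"):
            load_screen(toy_screen_files["counts"], toy_screen_files["annotation"], sheet)

    def test_duplicate_construct_ids_rejected(self, toy_screen_files, tmp_path):
        ann = tmp_path / "dup.tsv"
        ann.write_text(
            "construct_id\tguide_i\tguide_j\tgene_g\tgene_h\n"
            "c1\tA_1\tN_1\tA\tNC\n"
            "c1\tB_1\tN_1\tB\tNC\n"
            "c2\tB_1\tN_1\tB\tNC\n"
            "c3\tA_1\tB_1\tA\tB\n"
        )
        with pytest.raises(ScreenError, match="duplicate"):
            load_screen(toy_screen_files["counts"], ann, toy_screen_files["samples"])

    def test_guide_paired_with_itself_rejected(self):
        with pytest.raises(ScreenError, match="itself"):
            make_design([("c1", "A_1", "A_1", "A", "A")])


class TestPairKey:
    def test_orientation_free(self):
        assert pair_key("MAPK1", "MAPK3") == pair_key("MAPK3", "MAPK1")

    def test_swapped_annotation_orientations_aggregate_together(self):
        design = make_design(
            [("c1", "A_1", "B_1", "A", "B"), ("c2", "B_2", "A_2", "B", "A")]
        )
        keys = design.pair_keys()
        assert keys["c1"] == keys["c2"] == ("A", "B")

    @given(st.text(min_size=1, max_size=8), st.text(min_size=1, max_size=8))
    def test_symmetric_and_sorted(self, g, h):
        assert pair_key(g, h) == pair_key(h, g) == tuple(sorted((g, h)))


class TestComputeLfc:
    def _counts(self, design, table):
        return CountMatrix(values=pd.DataFrame(table, index=design.construct_ids))

    def test_identical_late_and_early_gives_zero(self):
        design = make_design(
            [("c1", "A_1", "N_1", "A", "NC"), ("c2", "B_1", "N_1", "B", "NC")]
        )
        counts = self._counts(
            design, {"early": [100, 300], "s1_r1": [100, 300], "s1_r2": [100, 300]}
        )
        lfc = compute_lfc(counts, design)
        assert np.allclose(lfc.D.to_numpy(), 0.0)

    def test_hand_computed_example(self):
        # early (100,100), late (100,400), pseudocount 0:
        # D = (log2(0.2/0.5), log2(0.8/0.5)) ~= (-1.3219, 0.6781)
        design = make_design(
            [("c1", "A_1", "N_1", "A", "NC"), ("c2", "B_1", "N_1", "B", "NC")],
            n_reps=1,
        )
        counts = self._counts(design, {"early": [100, 100], "s1_r1": [100, 400]})
        lfc = compute_lfc(counts, design, pseudocount=0)
        np.testing.assert_allclose(
            lfc.D["s1"].to_numpy(), [np.log2(0.2 / 0.5), np.log2(0.8 / 0.5)], atol=1e-4
        )

    def test_single_replicate_flags_variance_undefined(self):
        design = make_design([("c1", "A_1", "N_1", "A", "NC")], n_reps=1)
        counts = self._counts(design, {"early": [100], "s1_r1": [50]})
        lfc = compute_lfc(counts, design)
        assert np.isnan(lfc.rep_var.to_numpy()).all()
        assert np.allclose(lfc.D.to_numpy(), lfc.D_rep[:, :, 0])

    def test_zero_total_column_rejected(self):
        design = make_design([("c1", "A_1", "N_1", "A", "NC")], n_reps=1)
        counts = pd.DataFrame({"early": [0], "s1_r1": [50]}, index=design.construct_ids)
        with pytest.raises(ScreenError, match="zero total"):
            compute_lfc(CountMatrix(values=counts), design, pseudocount=0)

    @pytest.mark.parametrize("scale", [3, 10, 250])
    def test_depth_invariance_without_pseudocount(self, scale):
        design = make_design(
            [("c1", "A_1", "N_1", "A", "NC"), ("c2", "B_1", "N_1", "B", "NC")],
            n_reps=1,
        )
        base = {"early": [120, 80], "s1_r1": [30, 170]}
        lfc1 = compute_lfc(self._counts(design, base), design, pseudocount=0)
        scaled = {k: [v * scale for v in vals] for k, vals in base.items()}
        lfc2 = compute_lfc(self._counts(design, scaled), design, pseudocount=0)
        np.testing.assert_allclose(lfc1.D.to_numpy(), lfc2.D.to_numpy(), atol=1e-12)


class TestExternalLfc:
    def test_round_trip_of_written_lfc(self, tmp_path, small_sim):
        path = tmp_path / "lfc.tsv"
        small_sim.lfc.to_tsv(path)
        lfc2 = accept_external_lfc(path, small_sim.design)
        np.testing.assert_allclose(lfc2.D.to_numpy(), small_sim.lfc.D.to_numpy(), atol=1e-9)
        np.testing.assert_allclose(
            lfc2.rep_var.to_numpy(), small_sim.lfc.rep_var.to_numpy(), atol=1e-9
        )

    def test_replicate_table_mean_recomputed(self, tmp_path):
        design = make_design([("c1", "A_1", "N_1", "A", "NC")])
        path = tmp_path / "lfc.tsv"
        path.write_text("construct_id\ts1.1\ts1.2\nc1\t-1.0\t-3.0\n")
        lfc = accept_external_lfc(path, design)
        assert lfc.D.loc["c1", "s1"] == -2.0
        assert lfc.rep_var.loc["c1", "s1"] == pytest.approx(2.0)

    def test_missing_sample_listed(self, tmp_path):
        design = make_design([("c1", "A_1", "N_1", "A", "NC")], samples=("s1", "s2"))
        path = tmp_path / "lfc.tsv"
        path.write_text("construct_id\ts1.1\ts1.2\nc1\t-1.0\t-3.0\n")
        with pytest.raises(ScreenError, match="s2"):
            accept_external_lfc(path, design)
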