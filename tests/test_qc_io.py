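"""Viability/damage QC and file/config round-trips."""

import numpy as np
import pandas as pd
import pytest
import yaml

from phoswell import (
    DamageRecord,
    ViabilityRecord,
    ldh_flag,
    mtt_viability,
    paper_like_design,
    generate_timeseries,
)
from phoswell.io import (
    design_from_config,
    geometry_from_config,
    papp_unit_scale,
    read_counts,
    read_series_csv,
    series_from_frame,
    write_counts,
    write_series_csv,
)
from phoswell.qc import CYTOTOXICITY_SIGNAL, NO_CYTOTOXICITY


class TestMtt:
    def control(self):
        return ViabilityRecord(1.0, 0.10, "control", is_control=True)

    def test_treatment_equal_to_control_is_hundred(self):
        v = mtt_viability([self.control(), ViabilityRecord(1.0, 0.10, "2 mM P")])
        assert v["2 mM P"] == pytest.approx(100.0)

    def test_zero_signal_is_zero(self):
        v = mtt_viability([self.control(), ViabilityRecord(0.10, 0.10, "8 mM P")])
        assert v["8 mM P"] == 0.0

    def test_half_signal_is_fifty(self):
        v = mtt_viability([self.control(), ViabilityRecord(0.55, 0.10, "t")])
        assert v["t"] == pytest.approx(50.0)

    def test_stimulation_above_hundred_not_capped(self):
        v = mtt_viability([self.control(), ViabilityRecord(1.30, 0.10, "1 mM P")])
        assert v["1 mM P"] == pytest.approx(400 / 3, rel=1e-9)

    def test_missing_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            mtt_viability([ViabilityRecord(1.0, 0.1, "t")])

    def test_non_positive_control_signal_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            mtt_viability([ViabilityRecord(0.1, 0.1, "c", is_control=True),
                           ViabilityRecord(1.0, 0.1, "t")])


class TestLdh:
    def test_below_limit_is_clean(self):
        assert ldh_flag(DamageRecord(ldh_u_l=10.0)) == NO_CYTOTOXICITY

    def test_boundary_reads_as_detectable(self):
        assert ldh_flag(DamageRecord(ldh_u_l=14.0)) == CYTOTOXICITY_SIGNAL

    def test_censored_marker_is_clean(self):
        assert ldh_flag(DamageRecord(below_limit=True)) == NO_CYTOTOXICITY

    def test_value_or_marker_required(self):
        with pytest.raises(ValueError):
            DamageRecord()


class TestSeriesCsv:
    def test_round_trip_identical(self, tmp_path, make_noiseless_series):
        series = [make_noiseless_series(7.74e-6), make_noiseless_series(1.8e-5, c_b0=0.0)]
        series[1].replicate_id = "w2"
        path = tmp_path / "assay.csv"
        write_series_csv(series, path)
        back = read_series_csv(path)
        assert len(back) == len(series)
        for orig, rt in zip(series, back):
            np.testing.assert_array_equal(orig.times_s, rt.times_s)
            np.testing.assert_array_equal(orig.apical_mm, rt.apical_mm)
            np.testing.assert_array_equal(orig.basolateral_mm, rt.basolateral_mm)
            assert rt.condition.layout == orig.condition.layout

    def test_inhibitors_recovered_from_condition_id(self, tmp_path):
        design = paper_like_design(replicates=1, noise_sd=0.0)
        study = generate_timeseries(design)
        path = tmp_path / "study.csv"
        write_series_csv(study.series, path)
        back = {s.condition.condition_id: s for s in read_series_csv(path)}
        pfa_arm = back["meso_basolateral+PFA+Tenapanor"]
        assert len(pfa_arm.condition.inhibitors) == 2

    def test_malformed_rows_reported_with_line_numbers(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "condition_id,layout,replicate,time_s,compartment,conc_mM\n"
            "c1,blank,w1,0,apical,1.0\n"
            "c1,blank,w1,0,sideways,0.1\n"
            "c1,blank,w1,oops,basolateral,0.1\n"
        )
        with pytest.raises(ValueError) as exc:
            read_series_csv(path)
        assert "line 3" in str(exc.value) and "sideways" in str(exc.value)
        assert "line 4" in str(exc.value)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing required columns"):
            series_from_frame(pd.DataFrame({"condition_id": []}))

    def test_unpaired_samples_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "condition_id,layout,replicate,time_s,compartment,conc_mM\n"
            "c1,blank,w1,0,apical,1.0\n"
            "c1,blank,w1,0,basolateral,0.1\n"
            "c1,blank,w1,3600,apical,0.9\n"
        )
        with pytest.raises(ValueError, match="paired"):
            read_series_csv(path)


class TestCountsIo:
    def test_tsv_round_trip(self, tmp_path):
        from phoswell import cell_line_count_config, generate_count_matrix

        counts, meta = generate_count_matrix(cell_line_count_config(), seed=0)
        write_counts(counts, meta, tmp_path / "c.tsv", tmp_path / "m.csv")
        back_counts, back_meta = read_counts(tmp_path / "c.tsv", tmp_path / "m.csv")
        pd.testing.assert_frame_equal(counts, back_counts)
        pd.testing.assert_frame_equal(meta, back_meta)

    def test_metadata_must_cover_samples(self, tmp_path):
        pd.DataFrame({"s1": [1]}, index=["g"]).to_csv(tmp_path / "c.csv")
        pd.DataFrame({"group": ["A"]}, index=pd.Index(["other"], name="sample")).to_csv(tmp_path / "m.csv")
        with pytest.raises(ValueError, match="without metadata"):
            read_counts(tmp_path / "c.csv", tmp_path / "m.csv")


class TestConfig:
    def test_partial_geometry_block_takes_defaults(self):
        g = geometry_from_config({"geometry": {"apical_volume_ul": 100.0}})
        assert g.apical_volume_ul == 100.0
        assert g.basolateral_volume_ul == 1000.0

    def test_absent_block_is_default(self):
        g = geometry_from_config(None)
        assert g.membrane_area_cm2 == 0.33

    def test_design_preset(self):
        d = design_from_config({"design": {"preset": "paper_like", "replicates": 3, "seed": 9}})
        assert d.replicates == 3 and d.seed == 9

    def test_design_explicit_arms(self):
        cfg = {
            "design": {
                "replicates": 2,
                "noise_sd": 0.05,
                "arms": [
                    {"layout": "blank", "model": {"p_filter": 1.8e-5, "layers": 0}},
                    {"layout": "meso_apical", "inhibitors": ["PFA"],
                     "model": {"p_filter": 1.8e-5, "p_trans": 5e-6, "p_para": 5e-6,
                               "efficacy_pfa": 0.2, "layers": 1}},
                ],
            }
        }
        d = design_from_config(cfg)
        assert len(d.arms) == 2
        assert d.arms[0].true_papp() == 1.8e-5
        assert d.arms[1].true_papp() < 1e-5

    @pytest.mark.parametrize(
        "unit, scale",
        [("cm/s", 1.0), ("1e-6 cm/s", 1e-6), ("x10^-6 cm/s", 1e-6), ("×10^-6 cm/s", 1e-6)],
    )
    def test_papp_unit_scale(self, unit, scale):
        assert papp_unit_scale(unit) == scale

    def test_positive_exponent_interpreted_as_negative_with_warning(self):
        with pytest.warns(UserWarning, match="positive exponent"):
            assert papp_unit_scale("x10^6 cm/s") == 1e-6

    def test_garbage_unit_rejected(self):
        with pytest.raises(ValueError):
            papp_unit_scale("furlongs/fortnight")
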