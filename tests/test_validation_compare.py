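"""Paired comparison arithmetic, error statistics, detection scoring, I/O."""

import numpy as np
import pytest

from hipsim.mesh_core import ValidationError
from hipsim.rom_engine import STANDARD_MOTIONS
from hipsim.validation_compare import (
    ErrorStats,
    ROMRecord,
    compare_conditions,
    detection_confusion,
    error_stats,
    error_vs_reference,
    read_rom_csv,
    write_report,
    write_rom_csv,
)

# measured endpoints of one cadaveric hip (simulation arm), used as the
# worked example throughout; rows whose printed arithmetic is
# self-consistent: max flexion 105/93, max internal rotation 60/60,
# max internal rotation at 90 degrees of flexion 20/1
HIP5_SIM_NATIVE = {
    "max_flexion": 105.0, "max_abduction": 29.0, "max_ir_0": 60.0,
    "max_ir_30": 34.0, "max_ir_60": 27.0, "max_ir_90": 20.0,
}
HIP5_SIM_CAM = {
    "max_flexion": 93.0, "max_abduction": 31.0, "max_ir_0": 60.0,
    "max_ir_30": 34.0, "max_ir_60": 26.0, "max_ir_90": 1.0,
}
# reference (tracker) reductions for the same self-consistent rows
HIP5_REF_DIFF = {"max_flexion": 16.0, "max_ir_0": 1.0, "max_ir_90": 14.0}


def _records(subject="hip5", source="simulation"):
    return (
        ROMRecord(subject, source, "native", HIP5_SIM_NATIVE),
        ROMRecord(subject, source, "cam", HIP5_SIM_CAM),
    )


class TestCompareConditions:
    def test_hip5_worked_example(self):
        native, cam = _records()
        cmp_ = compare_conditions(native, cam)
        assert cmp_.difference["max_flexion"] == 12.0
        assert cmp_.difference["max_ir_0"] == 0.0
        assert cmp_.difference["max_ir_90"] == 19.0
        assert cmp_.limited["max_flexion"] is True
        assert cmp_.limited["max_ir_0"] is False
        assert cmp_.limited["max_ir_90"] is True

    def test_identical_records_no_flags(self):
        native = ROMRecord("s", "simulation", "native", HIP5_SIM_NATIVE)
        cam = ROMRecord("s", "simulation", "cam", HIP5_SIM_NATIVE)
        cmp_ = compare_conditions(native, cam)
        assert all(d == 0.0 for d in cmp_.difference.values())
        assert not any(cmp_.limited.values())

    def test_threshold_is_strict(self):
        """A reduction of exactly the threshold does not count as limited."""
        native = ROMRecord("s", "simulation", "native", HIP5_SIM_NATIVE)
        shifted = {m: v - 5.0 for m, v in HIP5_SIM_NATIVE.items()}
        cam = ROMRecord("s", "simulation", "cam", shifted)
        cmp_ = compare_conditions(native, cam, threshold=5.0)
        assert not any(cmp_.limited.values())
        cam2 = ROMRecord(
            "s", "simulation", "cam", {m: v - 5.0001 for m, v in HIP5_SIM_NATIVE.items()}
        )
        assert all(compare_conditions(native, cam2).limited.values())

    def test_subject_mismatch_rejected(self):
        native, _ = _records("a")
        _, cam = _records("b")
        with pytest.raises(ValidationError):
            compare_conditions(native, cam)

    def test_incomplete_motion_set_rejected(self):
        angles = dict(HIP5_SIM_NATIVE)
        angles.pop("max_flexion")
        with pytest.raises(ValidationError):
            ROMRecord("s", "simulation", "native", angles)


class TestErrorVsReference:
    def test_hip5_difference_of_differences(self):
        sim = compare_conditions(*_records())
        ref_native = {m: 50.0 for m in STANDARD_MOTIONS}
        ref_cam = {m: 50.0 - HIP5_REF_DIFF.get(m, sim.difference[m]) for m in STANDARD_MOTIONS}
        ref = compare_conditions(
            ROMRecord("hip5", "reference", "native", ref_native),
            ROMRecord("hip5", "reference", "cam", ref_cam),
        )
        err = error_vs_reference(sim, ref)
        assert err["max_flexion"] == pytest.approx(-4.0)
        assert err["max_ir_0"] == pytest.approx(-1.0)
        assert err["max_ir_90"] == pytest.approx(5.0)

    def test_self_comparison_zero(self):
        sim = compare_conditions(*_records())
        assert all(v == 0.0 for v in error_vs_reference(sim, sim).values())


class TestErrorStats:
    def test_single_value(self):
        s = error_stats([0.0])
        assert s.median == 0.0 and s.iqr == (0.0, 0.0) and s.max_abs == 0.0

    def test_hand_computable_order_statistics(self):
        s = error_stats([1.0, -2.0, 3.0, -4.0, 5.0])
        assert s.median == 1.0
        assert s.max_abs == 5.0

    def test_even_length_median_averages_middle_two(self):
        assert error_stats([1.0, 2.0, 3.0, 4.0]).median == 2.5

    def test_matches_independent_percentile_oracle(self):
        """Linear-interpolation percentiles, re-derived from sorted order
        statistics by hand."""
        rng = np.random.default_rng(9)
        for _ in range(200):
            x = rng.normal(scale=5, size=rng.integers(2, 40))
            s = error_stats(x)
            xs = np.sort(x)
            n = len(xs)

            def pct(q):
                h = (n - 1) * q
                lo = int(np.floor(h))
                hi = min(lo + 1, n - 1)
                return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

            assert s.iqr[0] == pytest.approx(pct(0.25), abs=1e-12)
            assert s.iqr[1] == pytest.approx(pct(0.75), abs=1e-12)
            assert s.median == pytest.approx(pct(0.5), abs=1e-12)
            assert s.max_abs == pytest.approx(np.abs(x).max())

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            error_stats([])


class TestDetectionConfusion:
    def test_perfect_agreement(self):
        sim = [compare_conditions(*_records())]
        counts = detection_confusion(sim, sim)
        k = sum(sim[0].limited.values())
        assert counts == {"tp": k, "fp": 0, "fn": 0, "tn": 6 - k}

    def test_all_flags_vs_none(self):
        native = ROMRecord("s", "simulation", "native", HIP5_SIM_NATIVE)
        big_drop = ROMRecord(
            "s", "simulation", "cam", {m: v - 30 for m, v in HIP5_SIM_NATIVE.items()}
        )
        same = ROMRecord("s", "simulation", "cam", HIP5_SIM_NATIVE)
        sim = [compare_conditions(native, big_drop)]
        ref = [compare_conditions(native, same)]
        counts = detection_confusion(sim, ref)
        assert counts == {"tp": 0, "fp": 6, "fn": 0, "tn": 0}

    def test_counts_sum_to_cohort_size(self):
        rng = np.random.default_rng(10)
        sim, ref = [], []
        for i in range(7):
            nat = {m: rng.uniform(20, 120) for m in STANDARD_MOTIONS}
            sim.append(compare_conditions(
                ROMRecord(f"s{i}", "simulation", "native", nat),
                ROMRecord(f"s{i}", "simulation", "cam",
                          {m: v - rng.uniform(0, 12) for m, v in nat.items()}),
            ))
            ref.append(compare_conditions(
                ROMRecord(f"s{i}", "reference", "native", nat),
                ROMRecord(f"s{i}", "reference", "cam",
                          {m: v - rng.uniform(0, 12) for m, v in nat.items()}),
            ))
        counts = detection_confusion(sim, ref)
        assert sum(counts.values()) == 7 * 6


class TestFileIO:
    def test_rom_csv_roundtrip(self, tmp_path):
        records = list(_records()) + list(_records("hip6", "reference"))
        path = tmp_path / "rom.csv"
        write_rom_csv(records, path)
        back = read_rom_csv(path)
        assert len(back) == 4
        by_key = {(r.subject, r.source, r.condition): r for r in back}
        orig = {(r.subject, r.source, r.condition): r for r in records}
        assert by_key.keys() == orig.keys()
        for k in orig:
            assert by_key[k].angles == orig[k].angles

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "subject,source,condition,motion,angle_deg\n"
            "h1,simulation,native,max_flexion,105\n"
            "h1,simulation,native,max_abduction,not_a_number\n"
        )
        with pytest.raises(ValidationError, match=":3:"):
            read_rom_csv(path)

    def test_report_has_seven_numeric_columns_per_motion(self, tmp_path):
        import pandas as pd

        sim = compare_conditions(*_records())
        write_report([(sim, sim)], error_stats([0.0]), tmp_path / "rep.csv",
                     tmp_path / "rep.json")
        df = pd.read_csv(tmp_path / "rep.csv")
        numeric = df.select_dtypes("number")
        assert len(df) == 6
        assert numeric.shape[1] == 7
        import json

        summary = json.loads((tmp_path / "rep.json").read_text())
        assert summary["confusion"]["fp"] == 0
        assert summary["n_endpoints"] == 6
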