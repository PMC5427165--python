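"""SSMD, plate QC, fold-change normalization, and well filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from appscreen.errors import (InputError, NormalizationError, QCError,
                              SSMDUndefinedError)
from appscreen.plate_stats import (compute_ssmd, filter_wells,
                                   normalize_wells, qc_plate, qc_screen)
from appscreen.synth_screen import (ROLE_NT, ROLE_SAMPLE, ROLE_SIAPP,
                                    ROLE_SIPSEN1)


def _plate(nt=None, siapp=None, sipsen1=None, samples=None, counts=800,
           plate_id="P001", replicate=1):
    rows = []
    groups = {
        ROLE_NT: nt if nt is not None else [100.0] * 4,
        ROLE_SIAPP: siapp if siapp is not None else [],
        ROLE_SIPSEN1: sipsen1 if sipsen1 is not None else [],
        ROLE_SAMPLE: samples if samples is not None else [],
    }
    i = 0
    for role, values in groups.items():
        for v in values:
            i += 1
            rows.append({
                "plate_id": plate_id, "well": f"W{i}", "replicate": replicate,
                "sirna_id": role if role != ROLE_SAMPLE else f"G{i}",
                "role": role, "cell_count": counts,
                "mcherry_mean": float(v), "yfp_mean": float(v),
            })
    return pd.DataFrame(rows)


class TestSSMD:
    def test_hand_computed_oracle(self):
        # (14 - 6) / sqrt(10 + 2.5), unbiased variances
        value = compute_ssmd([10, 12, 14, 16, 18], [4, 5, 6, 7, 8])
        assert value == pytest.approx(8 / np.sqrt(12.5), abs=1e-12)
        assert value == pytest.approx(2.2627, abs=1e-4)

    def test_identical_groups_give_zero(self):
        assert compute_ssmd([1, 2, 3], [1, 2, 3]) == 0.0

    def test_sign_preserved(self):
        assert compute_ssmd([4, 5, 6, 7, 8], [10, 12, 14, 16, 18]) < 0

    def test_zero_variance_is_an_error_not_a_number(self):
        with pytest.raises(SSMDUndefinedError):
            compute_ssmd([5.0, 5.0], [7.0, 7.0])

    def test_small_groups_rejected(self):
        with pytest.raises(InputError):
            compute_ssmd([1.0], [1.0, 2.0])

    @given(
        a=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=10),
        b=st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=10),
        scale=st.floats(0.01, 100.0),
        shift=st.floats(-1e3, 1e3),
    )
    def test_affine_invariance(self, a, b, scale, shift):
        a, b = np.asarray(a), np.asarray(b)
        if a.var(ddof=1) + b.var(ddof=1) == 0:
            return
        base = compute_ssmd(a, b)
        moved = compute_ssmd(a * scale + shift, b * scale + shift)
        assert moved == pytest.approx(base, rel=1e-7, abs=1e-9)


class TestQC:
    def test_strong_controls_pass(self):
        plate = _plate(nt=[100, 101, 99, 100],
                       siapp=[40, 41, 39, 40],
                       sipsen1=[220, 221, 219, 222])
        report = qc_plate(plate)
        assert report.passed
        assert report.beta_siAPP_mcherry <= -3

    def test_null_controls_fail(self):
        plate = _plate(nt=[100, 101, 99, 100],
                       siapp=[100, 102, 98, 101],
                       sipsen1=[99, 100, 102, 100])
        assert not qc_plate(plate).passed

    def test_missing_control_group_named(self):
        plate = _plate(nt=[100, 101], siapp=[40, 41], sipsen1=[])
        with pytest.raises(QCError, match="siPSEN1"):
            qc_plate(plate)

    def test_failing_plate_excludes_sample_wells(self):
        good = _plate(nt=[100, 101, 99], siapp=[40, 41, 39],
                      sipsen1=[220, 222, 219], samples=[150, 90],
                      plate_id="P001")
        bad = _plate(nt=[100, 101, 99], siapp=[100, 99, 101],
                     sipsen1=[100, 102, 98], samples=[150, 90],
                     plate_id="P002")
        wells = pd.concat([good, bad], ignore_index=True)
        qc = qc_screen(wells)
        assert qc.set_index("plate_id")["passed"].to_dict() == {
            "P001": True, "P002": False}
        flagged = filter_wells(wells, qc, min_cells=300)
        by_plate = flagged.groupby("plate_id")["included"].any()
        assert by_plate["P001"]
        assert not by_plate["P002"]


class TestNormalization:
    def test_closed_form_fold_change(self):
        wells = _plate(nt=[100.0, 100.0], samples=[150.0])
        out = normalize_wells(filter_wells(wells, min_cells=0))
        sample = out[out["role"] == ROLE_SAMPLE]
        assert sample["mcherry_fc"].iloc[0] == pytest.approx(1.5, rel=1e-12)
        assert np.log2(sample["mcherry_fc"].iloc[0]) == pytest.approx(
            0.584962500721, abs=1e-9)

    def test_nt_mean_fold_change_is_one_exactly(self, rng):
        nt = list(rng.uniform(80, 120, size=6))
        wells = _plate(nt=nt, samples=[150.0, 60.0])
        out = normalize_wells(filter_wells(wells, min_cells=0))
        nt_fc = out.loc[out["role"] == ROLE_NT, "mcherry_fc"]
        assert nt_fc.mean() == pytest.approx(1.0, rel=1e-12)

    def test_sample_at_nt_mean_has_unit_fold_change(self):
        wells = _plate(nt=[90.0, 110.0], samples=[100.0])
        out = normalize_wells(filter_wells(wells, min_cells=0))
        assert out.loc[out["role"] == ROLE_SAMPLE, "mcherry_fc"].iloc[0] \
            == pytest.approx(1.0, rel=1e-12)

    def test_excluded_nt_wells_with_included_samples_raise(self):
        wells = _plate(nt=[100.0, 100.0], samples=[150.0])
        wells.loc[wells["role"] == ROLE_NT, "cell_count"] = 100
        flagged = filter_wells(wells, min_cells=300)
        with pytest.raises(NormalizationError):
            normalize_wells(flagged)


class TestFiltering:
    @pytest.mark.parametrize("count,included", [(299, False), (300, True)])
    def test_cell_count_boundary(self, count, included):
        wells = _plate(nt=[100.0, 100.0], samples=[150.0], counts=count)
        out = filter_wells(wells, min_cells=300)
        assert bool(out["included"].iloc[-1]) is included

    def test_min_cells_zero_includes_everything(self):
        wells = _plate(nt=[100.0, 100.0], samples=[150.0], counts=1)
        assert filter_wells(wells, min_cells=0)["included"].all()

    @given(st.integers(0, 2000), st.integers(0, 2000))
    def test_exclusion_monotone_in_min_cells(self, lo, hi, ):
        lo, hi = min(lo, hi), max(lo, hi)
        rng = np.random.default_rng(99)
        wells = _plate(nt=[100.0] * 3,
                       samples=list(rng.uniform(50, 200, size=20)))
        wells["cell_count"] = rng.integers(0, 1500, size=len(wells))
        inc_lo = filter_wells(wells, min_cells=lo)["included"]
        inc_hi = filter_wells(wells, min_cells=hi)["included"]
        assert (inc_hi <= inc_lo).all()
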