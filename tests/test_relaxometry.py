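"""Forward-model unit and property tests: alpha table, blood/tissue R2,
two-compartment and coronary-sinus signals."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from myooef import (
    AcquisitionProtocol,
    AlphaTable,
    DataError,
    SignalSeries,
    TissueState,
    blood_r2,
    cs_signal,
    tissue_r2,
    voxel_signal,
)

# the shipped 1.5 T coefficient table, frozen entry for entry (1/s)
EXPECTED_ALPHAS = {
    "coronary_sinus": {
        24: (2.42, 4.25, 3.94),
        36: (4.78, 5.27, 4.05),
        48: (7.25, 6.33, 4.17),
        60: (9.55, 7.32, 4.28),
        72: (11.54, 8.18, 4.37),
    },
    "myocardium": {
        24: (2.52, 2.69, 2.83),
        36: (3.76, 3.22, 2.89),
        48: (4.57, 3.57, 2.93),
        60: (5.09, 3.80, 2.95),
        72: (5.45, 3.95, 2.97),
    },
}

TAB_TES = (24, 36, 48, 60, 72)


class TestAlphaTable:
    def test_default_table_matches_reference_values(self, table):
        for comp, rows in EXPECTED_ALPHAS.items():
            for te, expected in rows.items():
                assert table.coefficients(te, comp) == pytest.approx(expected, abs=1e-12)

    def test_default_hematocrits(self, table):
        assert table.hematocrit_cs == 0.40
        assert table.hematocrit_myo == pytest.approx(table.hematocrit_cs / 2)

    def test_interpolation_between_tabulated_tes(self, table):
        lo = np.array(table.coefficients(24, "myocardium"))
        hi = np.array(table.coefficients(36, "myocardium"))
        mid = np.array(table.coefficients(30, "myocardium"))
        assert mid == pytest.approx((lo + hi) / 2)

    def test_extrapolation_disabled_by_default(self, table):
        with pytest.raises(ValueError, match="outside tabulated range"):
            table.coefficients(100, "coronary_sinus")
        # opt-in flag extends the end segment linearly
        a = table.coefficients(100, "coronary_sinus", extrapolate=True)
        assert a[0] > EXPECTED_ALPHAS["coronary_sinus"][72][0]

    def test_unknown_compartment_rejected(self, table):
        with pytest.raises(ValueError, match="compartment"):
            table.coefficients(24, "liver")

    def test_invalid_tables_rejected(self, table):
        df = table.entries.copy()
        df.loc[df.index[0], "alpha1"] = -1.0
        with pytest.raises(DataError, match="positive"):
            AlphaTable(entries=df)
        df2 = table.entries.copy()
        # break monotonicity in TE
        df2.loc[df2.index[1], "alpha2"] = 0.01
        with pytest.raises(DataError):
            AlphaTable(entries=df2)

    def test_csv_round_trip(self, table, tmp_path):
        p = tmp_path / "alphas.csv"
        table.to_csv(p)
        again = AlphaTable.from_csv(p)
        assert np.allclose(
            again.entries[["alpha1", "alpha2", "alpha3"]].to_numpy(),
            table.entries[["alpha1", "alpha2", "alpha3"]].to_numpy(),
        )


class TestBloodR2:
    @pytest.mark.parametrize(
        "oef, te, comp, expected",
        [
            (0.0, 24, "coronary_sinus", 2.42),  # alpha1 alone
            (1.0, 24, "coronary_sinus", 10.61),  # 2.42 + 4.25 + 3.94
            (0.73, 48, "coronary_sinus", 14.093093),  # 7.25 + 6.33*.73 + 4.17*.73^2
        ],
    )
    def test_hand_computed_values(self, table, oef, te, comp, expected):
        assert blood_r2(oef, te, comp, table) == pytest.approx(expected, abs=1e-9)

    @given(
        oef_pair=st.tuples(
            st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
        ),
        te=st.sampled_from(TAB_TES),
        comp=st.sampled_from(["coronary_sinus", "myocardium"]),
    )
    def test_strictly_increasing_in_oef(self, table, oef_pair, te, comp):
        lo, hi = sorted(oef_pair)
        if hi > lo:
            assert blood_r2(hi, te, comp, table) > blood_r2(lo, te, comp, table)

    def test_oef_domain_enforced(self, table):
        with pytest.raises(ValueError):
            blood_r2(1.2, 24, "coronary_sinus", table)


class TestTissueR2:
    def test_diffusion_term_vanishes_at_zero_oef(self):
        s = TissueState(oef=0.0, mbv=0.06, r20t=24.5, r21t=1.06e5)
        assert tissue_r2(s, 0.016) == 24.5

    def test_hand_computed_value(self):
        # 24.5 + 1.06e5 * (0.37 * 0.10 * 0.024)^2 = 24.5 + 0.0835857
        s = TissueState(oef=0.37, mbv=0.10, r20t=24.5, r21t=1.06e5)
        assert tissue_r2(s, 0.024) == pytest.approx(24.58358566, abs=1e-6)

    def test_doubling_tau_quadruples_excess(self):
        s = TissueState(oef=0.5, mbv=0.08, r20t=20.0, r21t=2e5)
        e1 = tissue_r2(s, 0.01) - s.r20t
        e2 = tissue_r2(s, 0.02) - s.r20t
        assert e2 == pytest.approx(4 * e1, rel=1e-12)

    def test_reduces_to_r20t_when_r21t_zero(self):
        s = TissueState(oef=0.9, mbv=0.2, r20t=30.0, r21t=0.0)
        assert tissue_r2(s, 0.5) == 30.0

    @given(
        oef=st.floats(0, 1), mbv=st.floats(0, 0.5), tau=st.floats(0.001, 0.05)
    )
    def test_monotone_in_each_argument(self, oef, mbv, tau):
        base = TissueState(oef=oef, mbv=mbv, r20t=24.5, r21t=1.06e5)
        bumped = TissueState(
            oef=min(oef + 0.1, 1.0), mbv=min(mbv + 0.1, 0.6), r20t=24.5, r21t=1.06e5
        )
        assert tissue_r2(base, tau) <= tissue_r2(bumped, tau)
        assert tissue_r2(base, tau) <= tissue_r2(base, tau * 1.5)

    def test_negative_tau_rejected(self):
        s = TissueState(oef=0.5, mbv=0.1, r20t=20.0, r21t=1e5)
        with pytest.raises(ValueError):
            tissue_r2(s, -0.01)


class TestVoxelSignal:
    def test_mbv_zero_is_monoexponential_to_machine_precision(self, protocol, table):
        s = TissueState(oef=0.5, mbv=0.0, r20t=24.5, r21t=1.06e5)
        sig = voxel_signal(s, protocol, 100.0, table)
        te_s = sig.te_s
        tau_s = protocol.tau_s
        expected = 100.0 * np.exp(-te_s * np.array([tissue_r2(s, t) for t in tau_s]))
        np.testing.assert_allclose(sig.intensity, expected, rtol=1e-15)

    def test_mbv_one_would_be_pure_blood(self, protocol, table):
        # mbv -> 1 limit approached: tissue term weight vanishes
        s = TissueState(oef=0.4, mbv=1 - 1e-12, r20t=24.5, r21t=1.06e5)
        sig = voxel_signal(s, protocol, 1.0, table)
        r2b = np.array([blood_r2(0.4, te, "myocardium", table) for te in sig.te_ms])
        np.testing.assert_allclose(sig.intensity, np.exp(-sig.te_s * r2b), rtol=1e-9)

    def test_signal_decreases_with_te(self, rest_state, protocol, table):
        sig = voxel_signal(rest_state, protocol, 100.0, table)
        assert np.all(np.diff(sig.intensity) < 0)
        assert sig.intensity[0] > sig.intensity[-1]  # TE=24 vs TE=72

    def test_linear_in_s0(self, rest_state, protocol, table):
        a = voxel_signal(rest_state, protocol, 1.0, table).intensity
        b = voxel_signal(rest_state, protocol, 250.0, table).intensity
        np.testing.assert_allclose(b, 250.0 * a, rtol=1e-14)


class TestCsSignal:
    def test_known_point_value(self, protocol, table):
        # exp(-0.048 * 14.093093) at TE = 48 ms, OEF = 0.73
        sig = cs_signal(0.73, protocol, 1.0, table)
        i48 = sig.intensity[list(sig.te_ms).index(48.0)]
        assert i48 == pytest.approx(np.exp(-0.048 * 14.093093), rel=1e-9)
        assert i48 == pytest.approx(0.5085, abs=5e-4)

    def test_oef_zero_decay_uses_alpha1_only(self, protocol, table):
        sig = cs_signal(0.0, protocol, 1.0, table)
        a1 = np.array([table.coefficients(te, "coronary_sinus")[0] for te in sig.te_ms])
        np.testing.assert_allclose(sig.intensity, np.exp(-sig.te_s * a1), rtol=1e-12)

    @given(oefs=st.tuples(st.floats(0, 1), st.floats(0, 1)))
    def test_signal_decreasing_in_oef_at_fixed_te(self, protocol, table, oefs):
        lo, hi = sorted(oefs)
        if hi - lo > 1e-12:
            s_lo = cs_signal(lo, protocol, 1.0, table).intensity
            s_hi = cs_signal(hi, protocol, 1.0, table).intensity
            assert np.all(s_hi < s_lo)

    def test_not_globally_monoexponential(self, protocol, table):
        # TE-dependent alphas bend the log-decay: log-signal is convex/concave,
        # not affine, in TE
        sig = cs_signal(0.73, protocol, 1.0, table)
        slopes = np.diff(np.log(sig.intensity)) / np.diff(sig.te_s)
        assert np.ptp(slopes) > 1.0  # effective R2 varies by > 1 1/s across echoes


class TestProtocolAndSeries:
    def test_t2prep_tau_is_te_over_n(self):
        p = AcquisitionProtocol.t2prep_default()
        assert p.tau_for(48.0) == pytest.approx(16.0)

    def test_tse_requires_explicit_tau(self):
        with pytest.raises(DataError, match="tau_ms"):
            AcquisitionProtocol(family="tse", te_list=(24.0, 48.0, 72.0))
        p = AcquisitionProtocol(family="tse", te_list=(24.0, 48.0, 72.0), tau_ms=8.0)
        assert p.tau_for(72.0) == 8.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(te_ms=[24, 24, 48], intensity=[3, 2, 1]),  # non-increasing TE
            dict(te_ms=[24, 48], intensity=[1, -2]),  # negative intensity
            dict(te_ms=[24], intensity=[1]),  # too short
            dict(te_ms=[24, 48, 72], intensity=[3, 2]),  # length mismatch
        ],
    )
    def test_invalid_series_rejected(self, kwargs):
        with pytest.raises(DataError):
            SignalSeries(
                te_ms=np.asarray(kwargs["te_ms"], dtype=float),
                intensity=np.asarray(kwargs["intensity"], dtype=float),
            )
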