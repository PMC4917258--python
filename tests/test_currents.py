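"""Membrane currents: reversal conditions, printed-formula values,
scaling laws, and kernel/API consistency."""

import numpy as np
import pytest

from nram import currents as cur
from nram.cell import CellState, initial_state, total_current
from nram.constants import CURRENT_FIELDS
from nram.params import CellParams


@pytest.fixture(scope="module")
def p():
    return CellParams()


# ---------------------------------------------------------------------------
# Nernst potentials
# ---------------------------------------------------------------------------

def test_nernst_zero_for_equal_concentrations():
    assert cur.nernst_potential(1, 5.4, 5.4) == pytest.approx(0.0)


def test_nernst_potassium_standard_value():
    """E_K for 5.4/140 mM at 295 K is about -82.8 mV."""
    ek = cur.nernst_potential(1, 5.4, 140.0, 295.0)
    assert ek == pytest.approx(-82.8, abs=0.2)


def test_nernst_valence_halves_magnitude():
    e1 = cur.nernst_potential(1, 10.0, 1.0)
    e2 = cur.nernst_potential(2, 10.0, 1.0)
    assert e2 == pytest.approx(e1 / 2.0)


def test_nernst_rejects_nonpositive():
    with pytest.raises(ValueError):
        cur.nernst_potential(1, 0.0, 5.4)
    with pytest.raises(ValueError):
        cur.nernst_potential(1, 5.4, -1.0)


# ---------------------------------------------------------------------------
# reversal / zero conditions per current
# ---------------------------------------------------------------------------

def test_i_na_zero_at_reversal_and_with_closed_gates(p):
    e_na = cur.nernst_potential(1, p.na_o, p.na_i, p.temperature)
    assert cur.i_na(e_na, 1.0, 1.0, 1.0, p) == pytest.approx(0.0, abs=1e-12)
    assert cur.i_na(-20.0, 0.0, 0.0, 0.0, p) == 0.0
    # direct substitution: fully open, 10 mV above reversal
    assert cur.i_na(e_na + 10.0, 1.0, 1.0, 1.0, p) == \
        pytest.approx(10.0 * p.g_na)


def test_i_na_inward_below_reversal(p):
    e_na = cur.nernst_potential(1, p.na_o, p.na_i, p.temperature)
    assert cur.i_na(e_na - 50.0, 0.5, 0.5, 0.5, p) < 0


def test_i_cat_zero_at_shifted_reversal(p):
    ca_i = 2e-4
    e_ca = cur.nernst_potential(2, p.ca_o, ca_i, p.temperature)
    assert cur.i_cat(e_ca - 106.5, 1.0, 1.0, ca_i, p) == \
        pytest.approx(0.0, abs=1e-12)
    assert cur.i_cat(e_ca - 106.5 + 1.0, 1.0, 1.0, ca_i, p) == \
        pytest.approx(p.g_cat)


def test_i_to_zero_at_ek_and_weights(p):
    e_k = cur.nernst_potential(1, p.k_o, p.k_i, p.temperature)
    assert cur.i_to(e_k, 1.0, 1.0, 1.0, p) == pytest.approx(0.0, abs=1e-12)
    fast = cur.i_to(e_k + 50.0, 1.0, 1.0, 0.0, p)
    slow = cur.i_to(e_k + 50.0, 1.0, 0.0, 1.0, p)
    assert fast / slow == pytest.approx(0.706 / 0.294)
    assert cur.i_to(e_k + 100.0, 1.0, 1.0, 1.0, p) == \
        pytest.approx(100.0 * p.g_to)


def test_i_ksus_is_016_times_components(p):
    """The sustained current is exactly k_ksus x (I_Kur + I_Kr + I_Ks)."""
    v, gates = 20.0, (0.7, 0.8, 0.5, 0.4, 0.3)
    base = cur.i_ksus(v, *gates, p.replace(k_ksus=1.0))
    scaled = cur.i_ksus(v, *gates, p)
    assert scaled == pytest.approx(0.16 * base)
    assert cur.i_ksus(v, 0.0, 0.0, 0.0, 0.0, 0.0, p) == 0.0


def test_i_k1bar_leak_only_at_shifted_reversal(p):
    """At V = E_K + 10 the rectifier vanishes; the leak contributes
    0.01 * 10 = 0.1 pA/pF."""
    e_k = cur.nernst_potential(1, p.k_o, p.k_i, p.temperature)
    assert cur.i_k1bar(e_k + 10.0, p) == pytest.approx(0.1, abs=1e-9)


def test_i_k1bar_rectifier_only_at_ek(p):
    """At V = E_K the leak vanishes; the rectifier term equals its printed
    closed form."""
    e_k = cur.nernst_potential(1, p.k_o, p.k_i, p.temperature)
    expected = (p.g_k1 * p.k_o / (p.k_o + 210.0) * (-10.0)
                / (1.0 + np.exp(0.041 * -10.0)))
    assert cur.i_k1bar(e_k, p) == pytest.approx(expected, rel=1e-12)


def test_i_k1bar_strong_depolarization_is_leak(p):
    """Far above E_K the rectifier term decays; the linear leak remains."""
    e_k = cur.nernst_potential(1, p.k_o, p.k_i, p.temperature)
    v = e_k + 200.0
    assert cur.i_k1bar(v, p) == pytest.approx(p.g_kleak * 200.0, rel=1e-2)


def test_i_kach_zeros_and_direct_value():
    p1 = CellParams(g_kach=1.0)
    e_k = cur.nernst_potential(1, p1.k_o, p1.k_i, p1.temperature)
    assert cur.i_kach(e_k + 10.0, 1.0, p1) == pytest.approx(0.0, abs=1e-12)
    assert cur.i_kach(-100.0, 0.0, p1) == 0.0
    # independent transcription of the dose/voltage law at 1 uM, -100 mV
    dose = 3.5 / (1.0 + 9.13652 / 1.0 ** 0.477811)
    fac = 0.04 + 0.23 / (1.0 + np.exp((-100.0 + 102.0) / 10.0))
    expected = dose * fac * (-100.0 - e_k - 10.0)
    assert cur.i_kach(-100.0, 1.0, p1) == pytest.approx(expected, rel=1e-12)


def test_i_kach_monotone_in_dose():
    p1 = CellParams(g_kach=1.0)
    doses = [0.01, 0.1, 1.0, 10.0]
    vals = [abs(cur.i_kach(-100.0, d, p1)) for d in doses]
    assert np.all(np.diff(vals) > 0)


def test_i_kach_c_printed_form():
    p1 = CellParams(g_kach=1.0)
    e_k = cur.nernst_potential(1, p1.k_o, p1.k_i, p1.temperature)
    assert cur.i_kach_c(e_k + 10.0, p1) == pytest.approx(0.0, abs=1e-12)
    # at V = -102 the gating sigmoid is 1/2: conductance factor 0.25
    slope = cur.i_kach_c(-102.0, p1) / (-102.0 - e_k - 10.0)
    assert slope == pytest.approx(0.37488 * 0.25, rel=1e-9)
    # hyperpolarized limit of the conductance factor
    slope_lo = cur.i_kach_c(-300.0, p1) / (-300.0 - e_k - 10.0)
    assert slope_lo == pytest.approx(0.37488 * 0.425, rel=1e-3)


def test_constitutive_form_independent_of_dose(p):
    a = cur.i_kach_c(-80.0, p.replace(ach=0.001))
    b = cur.i_kach_c(-80.0, p.replace(ach=100.0))
    assert a == b


def test_i_f_closed_gate_zero(p):
    assert cur.i_f(-100.0, 0.0, p) == 0.0


# ---------------------------------------------------------------------------
# GHK L-type current
# ---------------------------------------------------------------------------

def test_i_cal_closed_gate_zero(p):
    assert cur.i_cal(0.0, 0.0, 1.0, 1.0, 2e-4, p) == 0.0


def test_i_cal_removable_singularity(p):
    """The analytic V=0 limit is continuous with V = +-1e-6 mV."""
    at0 = cur.i_cal(0.0, 1.0, 1.0, 1.0, 2e-4, p)
    lo = cur.i_cal(-1e-6, 1.0, 1.0, 1.0, 2e-4, p)
    hi = cur.i_cal(1e-6, 1.0, 1.0, 1.0, 2e-4, p)
    assert np.isfinite(at0)
    assert at0 == pytest.approx(lo, rel=1e-6)
    assert at0 == pytest.approx(hi, rel=1e-6)


def test_i_cal_ghk_reversal(p):
    """The current reverses where Ca_i e^{2VF/RT} = 0.341 Ca_o."""
    ca_i = 2e-4
    rt = 1000.0 * 8.31446 * p.temperature / 96485.33212
    v_rev = rt / 2.0 * np.log(0.341 * p.ca_o / ca_i)
    assert cur.i_cal(v_rev, 1.0, 1.0, 1.0, ca_i, p) == \
        pytest.approx(0.0, abs=1e-9)
    assert cur.i_cal(v_rev - 20.0, 1.0, 1.0, 1.0, ca_i, p) < 0


def test_i_cal_rejects_nonpositive_calcium(p):
    with pytest.raises(ValueError):
        cur.i_cal(0.0, 1.0, 1.0, 1.0, 0.0, p)


# ---------------------------------------------------------------------------
# pumps and backgrounds
# ---------------------------------------------------------------------------

def test_backgrounds_zero_at_their_reversals(p):
    e_na = cur.nernst_potential(1, p.na_o, p.na_i, p.temperature)
    ca_i = 2e-4
    e_ca = cur.nernst_potential(2, p.ca_o, ca_i, p.temperature)
    inak, incx, inab, icab = cur.pumps_and_backgrounds(e_na, ca_i, p)
    assert inab == pytest.approx(0.0, abs=1e-12)
    _, _, _, icab = cur.pumps_and_backgrounds(e_ca, ca_i, p)
    assert icab == pytest.approx(0.0, abs=1e-12)


def test_nak_pump_properties(p):
    inak, _, _, _ = cur.pumps_and_backgrounds(-70.0, 2e-4, p)
    assert inak >= 0.0
    starved = p.replace(na_i=1e-3)
    inak0, _, _, _ = cur.pumps_and_backgrounds(-70.0, 2e-4, starved)
    assert inak0 < 0.01 * inak


def test_ncx_sign_follows_calcium(p):
    """High cytosolic Ca drives forward-mode (inward) exchange current."""
    _, lo, _, _ = cur.pumps_and_backgrounds(-70.0, 1e-5, p)
    _, hi, _, _ = cur.pumps_and_backgrounds(-70.0, 5e-3, p)
    assert hi < lo
    assert hi < 0


# ---------------------------------------------------------------------------
# total current and kernel/API consistency
# ---------------------------------------------------------------------------

def test_total_is_sum_of_components(p, rest_single):
    cs = total_current(rest_single, p, "single_cell")
    parts = [getattr(cs, k) for k in CURRENT_FIELDS
             if k.startswith("i") and k != "i_total"]
    assert cs.i_total == pytest.approx(sum(parts), abs=1e-12)


def test_block_removes_component(p, rest_single):
    blocked = p.with_block("i_kach", 1.0)
    cs = total_current(rest_single, blocked, "constitutive")
    assert cs.i_kach == 0.0
    half = p.with_block("i_kach", 0.5)
    full = total_current(rest_single, p, "constitutive")
    cs2 = total_current(rest_single, half, "constitutive")
    assert cs2.i_kach == pytest.approx(0.5 * full.i_kach)


def test_modes_differ_only_in_kach(p, rest_single):
    a = total_current(rest_single, p, "single_cell")
    b = total_current(rest_single, p, "constitutive")
    for k in CURRENT_FIELDS:
        if k in ("i_kach", "i_total"):
            continue
        assert getattr(a, k) == pytest.approx(getattr(b, k), abs=1e-12)
    assert a.i_total - b.i_total == pytest.approx(a.i_kach - b.i_kach,
                                                 abs=1e-12)


def test_kernel_matches_public_current_functions(p, rest_single):
    """The compiled evaluation agrees with the NumPy current wrappers."""
    st = rest_single
    cs = total_current(st, p, "single_cell")
    assert cs.i_na == pytest.approx(
        cur.i_na(st.v, st.m, st.h, st.j, p), rel=1e-12, abs=1e-15)
    assert cs.i_to == pytest.approx(
        cur.i_to(st.v, st.r, st.s, st.s_slow, p), rel=1e-12, abs=1e-15)
    assert cs.i_k1 == pytest.approx(cur.i_k1bar(st.v, p), rel=1e-12)
    assert cs.i_kach == pytest.approx(cur.i_kach(st.v, p.ach, p), rel=1e-12)
    inak, incx, inab, icab = cur.pumps_and_backgrounds(st.v, st.ca_i, p)
    assert cs.i_nak == pytest.approx(inak, rel=1e-12)
    assert cs.i_ncx == pytest.approx(incx, rel=1e-12)
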