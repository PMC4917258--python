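"""Index layouts shared by the public API and the compiled integration kernels.

The cell model is evaluated structure-of-fields: the state of N cells is a
``(NVAR, N)`` float64 array, parameters are packed into a flat vector ordered
as :data:`PARAM_FIELDS`, and per-cell conductance variability is a
``(NMULT, N)`` array ordered as :data:`MULT_FIELDS`.  The integer constants
below are resolved at numba compile time, so their values must never change
between releases without recompiling everything that embeds them.
"""

# ---------------------------------------------------------------------------
# physical constants
# ---------------------------------------------------------------------------
FARADAY = 96485.33212  # C/mol
GAS_R = 8.31446        # J/(mol K)

# ---------------------------------------------------------------------------
# state vector
# ---------------------------------------------------------------------------
STATE_FIELDS = (
    "v",                      # membrane potential, mV
    "m", "h", "j",            # fast Na+ current gates
    "d", "f", "fca",          # L-type Ca2+ current gates
    "b", "g",                 # T-type Ca2+ current gates
    "r", "s", "s_slow",       # transient outward K+ gates
    "ua", "ui",               # ultra-rapid K+ gates
    "xr",                     # rapid delayed rectifier gate
    "xs1", "xs2",             # slow delayed rectifier gates
    "y",                      # funny current gate
    "ca_i", "ca_nsr", "ca_jsr",   # free Ca2+, mM
    "ryr_r", "ryr_o", "ryr_i",    # RyR closed/open/inactivated fractions
    "b_trpn", "b_cmdn",           # Ca2+ bound to troponin / calmodulin, mM
    "b_csqn",                     # Ca2+ bound to calsequestrin (JSR), mM
)
NVAR = len(STATE_FIELDS)

# gate indices (gates occupy a contiguous block 1..17)
GATE_SLICE = slice(1, 18)
GATE_FIELDS = STATE_FIELDS[GATE_SLICE]

# ---------------------------------------------------------------------------
# parameter vector
# ---------------------------------------------------------------------------
PARAM_FIELDS = (
    # maximal conductances / scale factors (nS/pF unless noted)
    "g_na", "g_cal", "g_cat", "g_to", "g_kur", "g_kr", "g_ks",
    "k_ksus",          # dimensionless 0.16 scale on I_Kur + I_Kr + I_Ks
    "g_k1",            # composite inward-rectifier prefactor (0.048925)
    "g_kleak",         # linear K+ leak slope (0.01 nS/pF)
    "g_kach",          # dimensionless scale on the printed I_KACh forms
    "g_f", "g_nab", "g_cab",
    "i_nak_max",       # pA/pF
    "k_ncx", "d_ncx", "gamma_ncx", "km_nai", "km_ko",
    # ion concentrations (mM), ACh (uM), temperature (K)
    "na_o", "na_i", "k_o", "k_i", "ca_o", "ach", "temperature",
    # capacitance bookkeeping
    "cm",              # uF/cm^2 (per-area; 1 makes pA/pF == uA/cm^2)
    "c_cell",          # pF; converts absolute pA stimulus to pA/pF
    # Ca2+ subsystem geometry and membrane-flux conversion
    "ca_conv",         # mM/ms of cytosolic Ca per pA/pF of Ca current
    "r_nsr",           # V_NSR / V_cyto
    "r_jsr",           # V_JSR / V_cyto  (= r_nsr/9 when JSR is 10% of SR)
    # SERCA (Shannon-type reversible pump) and SR transfer/leak
    "vmax_up", "kmf_up", "kmr_up", "h_up", "tau_tr", "k_leak_sr",
    # RyR (Shannon-type with luminal regulation, local-trigger proxy)
    "ko_ca", "kom", "ki_ca", "kim", "ec50_sr", "max_sr", "min_sr",
    "ks_rel", "k_local",
    # buffers: totals (mM), dissociation constants (mM), on-rates (1/mM/ms)
    "trpn_tot", "kd_trpn", "kon_trpn",
    "cmdn_tot", "kd_cmdn", "kon_cmdn",
    "csqn_tot", "kd_csqn", "kon_csqn",
    # named modification hooks
    "k_temp_na",       # room-temperature slowing of the Na+ time constants
    "tau_d_shift",     # +10 ms correction to the L-type activation tau
)
NPAR = len(PARAM_FIELDS)

# ---------------------------------------------------------------------------
# per-cell variability multipliers: the 19 scaled conductances/fluxes
# ---------------------------------------------------------------------------
MULT_FIELDS = (
    "g_na", "g_cal", "g_cat", "g_to", "g_kur", "g_kr", "g_ks",
    "g_k1", "g_kleak", "g_kach", "g_f", "g_nab", "g_cab",
    "i_nak_max", "k_ncx", "vmax_up", "ks_rel", "k_leak_sr", "j_tr",
)
NMULT = len(MULT_FIELDS)
assert NMULT == 19

# ---------------------------------------------------------------------------
# block targets (fraction in [0, 1]; 1 = full block)
# ---------------------------------------------------------------------------
BLOCK_FIELDS = (
    "i_na", "i_cal", "i_cat", "i_to", "i_ksus", "i_k1", "i_kach",
    "i_f", "i_nak", "i_ncx", "i_nab", "i_cab",
)
NBLOCK = len(BLOCK_FIELDS)

# ---------------------------------------------------------------------------
# diagnostic current/flux output order
# ---------------------------------------------------------------------------
CURRENT_FIELDS = BLOCK_FIELDS + ("j_up", "j_rel", "j_leak", "j_tr", "i_total")
NOUT = len(CURRENT_FIELDS)

# I_KACh operating modes
MODE_SINGLE_CELL = 0   # dose-dependent single-cell form
MODE_CONSTITUTIVE = 1  # agonist-independent tissue form


def _make_index_constants(namespace):
    """Expose S_*, P_*, M_*, B_*, C_* integer index constants."""
    for i, name in enumerate(STATE_FIELDS):
        namespace["S_" + name.upper()] = i
    for i, name in enumerate(PARAM_FIELDS):
        namespace["P_" + name.upper()] = i
    for i, name in enumerate(MULT_FIELDS):
        namespace["M_" + name.upper()] = i
    for i, name in enumerate(BLOCK_FIELDS):
        namespace["B_" + name.upper()] = i
    for i, name in enumerate(CURRENT_FIELDS):
        namespace["C_" + name.upper()] = i


_make_index_constants(globals())
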