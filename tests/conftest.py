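import numpy as np
import pytest

from porespace import (FixedParams, PoreSpaceState, RecoverySpec,
                       RootParams, WormParams)

# Pore-class rows for a long-term ley/arable rotation trial (treatment A: 5-year ley; D: mostly arable),
# phi_min = 0.3, psi_mic/mes = -100 cm, macroporosity assumed zero.
TABLE1 = {
    "A": dict(phi_t_mic=0.295, phi_t_mes=0.005, phi_t=0.3,
              phi_s_mic=0.120, phi_s_mes=0.168, phi_s=0.288,
              phi_mic=0.415, phi_mes=0.173, phi_mat=0.588),
    "D": dict(phi_t_mic=0.295, phi_t_mes=0.005, phi_t=0.3,
              phi_s_mic=0.118, phi_s_mes=0.147, phi_s=0.265,
              phi_mic=0.413, phi_mes=0.152, phi_mat=0.565),
}

# Scenario-simulation parameter set (high root production, high
# bioturbation unless overridden).
SCENARIO = dict(phi=0.4, phi_min=0.3, f_t_mic=0.8, gamma_s=2.7,
                gamma_r=1.2, f_r_c=0.2, R_g=0.0012, tau_s=0.12,
                f_casts_mic=0.8, eps_casts=0.6)


@pytest.fixture
def scenario_roots():
    return RootParams.from_production(SCENARIO["R_g"],
                                      gamma_r=SCENARIO["gamma_r"],
                                      f_r_c=SCENARIO["f_r_c"])


@pytest.fixture
def scenario_worms():
    return WormParams(eps_casts=SCENARIO["eps_casts"],
                      f_casts_mic=SCENARIO["f_casts_mic"],
                      tau_s=SCENARIO["tau_s"])


@pytest.fixture
def table1_state_a():
    """Layer state reproducing the treatment-A pore-class row."""
    r = TABLE1["A"]
    return PoreSpaceState(A_xs=1.0, V_s_mineral=1.0 - r["phi_mat"],
                          V_p_textural=r["phi_t"],
                          V_ps_mic=r["phi_s_mic"], V_ps_mes=r["phi_s_mes"],
                          V_mac=0.0, f_t_mic=r["phi_t_mic"] / r["phi_t"])


@pytest.fixture
def recovery_spec():
    """Noiseless 4-year synthetic recovery series spec."""
    return RecoverySpec()
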