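import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings
from scipy.integrate import cumulative_trapezoid, solve_ivp

import dopakin as dk

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def study2():
    return dk.get_preset("study2_32f")


@pytest.fixture(scope="session")
def study1():
    return dk.get_preset("study1_26f")


@pytest.fixture(scope="session")
def noiseless_curves(study2):
    """Noiseless striatal and cerebellar TACs at the default kinetics."""
    striatum = dk.simulate_region(dk.DEFAULT_STRIATUM, dk.DEFAULT_PLASMA, study2, 0.0,
                                  region_label="striatum")
    reference = dk.simulate_region(dk.DEFAULT_REFERENCE, dk.DEFAULT_PLASMA, study2, 0.0,
                                   region_label="cerebellum")
    return striatum, reference


def ode_tissue_curve(kin, input_params, t_end_min, pts_per_min=60, rtol=1e-8):
    """Independent oracle: two-tissue ODE solved with scipy's adaptive RK.

    Deliberately a different numerical route (stiff-safe initial-value
    solver on the differential form) from the package's convolution
    integrator.
    """

    def rhs(t, y):
        cp = dk.plasma_input(input_params, t)
        return [kin.K1 * cp - (kin.k2 + kin.k3) * y[0], kin.k3 * y[0]]

    t = np.linspace(0.0, t_end_min, int(t_end_min * pts_per_min) + 1)
    sol = solve_ivp(rhs, (0.0, t_end_min), [0.0, 0.0], t_eval=t,
                    rtol=rtol, atol=1e-12, max_step=0.5)
    return t, sol.y[0] + sol.y[1]


def fine_grid_patlak_slope(target_curve, ref_curve, t, t_star):
    """Patlak slope straight off instantaneous fine-grid curves."""
    integral = cumulative_trapezoid(ref_curve, t, initial=0.0)
    m = t >= t_star
    x = integral[m] / ref_curve[m]
    y = target_curve[m] / ref_curve[m]
    return float(np.polyfit(x, y, 1)[0])


@pytest.fixture(scope="session")
def oracle_slope_extended():
    """Asymptotic reference-Patlak slope: 1 s grid, 180 min, late window."""
    t, tar = ode_tissue_curve(dk.DEFAULT_STRIATUM, dk.DEFAULT_PLASMA, 180.0)
    _, ref = ode_tissue_curve(dk.DEFAULT_REFERENCE, dk.DEFAULT_PLASMA, 180.0)
    return fine_grid_patlak_slope(tar, ref, t, 120.0)
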