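"""Gating kinetics of the cochlear-nucleus conductance family.

Steady states and time constants (at 22 degrees C) for the fast sodium
current (gates m, h), the high-threshold potassium current (n, p) and the
low-threshold potassium current (w, z) of the Rothman & Manis ventral
cochlear nucleus neuron models, transcribed as closed-form rate tables.
Voltages in mV, times in ms.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["GATE_NAMES", "steady_states", "time_constants"]

GATE_NAMES = ("m", "h", "n", "p", "w", "z", "r_s", "r_f")


@njit(cache=True)
def _inf_tau(v):
    """All six K/Na gate steady states and time constants at voltage v."""
    m_inf = 1.0 / (1.0 + np.exp(-(v + 38.0) / 7.0))
    tau_m = 10.0 / (5.0 * np.exp((v + 60.0) / 18.0)
                    + 36.0 * np.exp(-(v + 60.0) / 25.0)) + 0.04
    h_inf = 1.0 / (1.0 + np.exp((v + 65.0) / 6.0))
    tau_h = 100.0 / (7.0 * np.exp((v + 60.0) / 11.0)
                     + 10.0 * np.exp(-(v + 60.0) / 25.0)) + 0.6
    n_inf = (1.0 + np.exp(-(v + 15.0) / 5.0)) ** -0.5
    tau_n = 100.0 / (11.0 * np.exp((v + 60.0) / 24.0)
                     + 21.0 * np.exp(-(v + 60.0) / 23.0)) + 0.7
    p_inf = 1.0 / (1.0 + np.exp(-(v + 23.0) / 6.0))
    tau_p = 100.0 / (4.0 * np.exp((v + 60.0) / 32.0)
                     + 5.0 * np.exp(-(v + 60.0) / 22.0)) + 5.0
    w_inf = (1.0 + np.exp(-(v + 48.0) / 6.0)) ** -0.25
    tau_w = 100.0 / (6.0 * np.exp((v + 60.0) / 6.0)
                     + 16.0 * np.exp(-(v + 60.0) / 45.0)) + 1.5
    z_inf = 0.5 + 0.5 / (1.0 + np.exp((v + 71.0) / 10.0))
    tau_z = 1000.0 / (np.exp((v + 60.0) / 20.0)
                      + np.exp(-(v + 60.0) / 8.0)) + 50.0
    return (m_inf, tau_m, h_inf, tau_h, n_inf, tau_n,
            p_inf, tau_p, w_inf, tau_w, z_inf, tau_z)


def steady_states(v: float) -> np.ndarray:
    """Steady-state values of the six K/Na gates (m, h, n, p, w, z) at v."""
    vals = _inf_tau(float(v))
    return np.array(vals[0::2])


def time_constants(v: float) -> np.ndarray:
    """Time constants (ms, 22 degrees C) of the six K/Na gates at v."""
    vals = _inf_tau(float(v))
    return np.array(vals[1::2])
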