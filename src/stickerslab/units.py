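"""Unit conventions.

Internal units: length in nm, energy in kBT0 (T0 = 300 K reference),
time in ns, temperature in K.  The derived mass unit is kBT0*ns^2/nm^2.
Surface tension converts as 1 kBT0/nm^2 = kB*T0/1e-18 N/m.
"""

KB_SI = 1.380649e-23  # J/K, exact

T0_DEFAULT = 300.0  # K, reference temperature of the energy unit


def energy_unit_joules(t0: float = T0_DEFAULT) -> float:
    """Joules per kBT0."""
    return KB_SI * t0


def gamma_sim_to_si(gamma_sim: float, t0: float = T0_DEFAULT) -> float:
    """Convert surface tension from kBT0/nm^2 to N/m."""
    return gamma_sim * energy_unit_joules(t0) / 1e-18


def gamma_si_to_sim(gamma_si: float, t0: float = T0_DEFAULT) -> float:
    """Convert surface tension from N/m to kBT0/nm^2."""
    return gamma_si * 1e-18 / energy_unit_joules(t0)


def thermal_energy(temperature: float, t0: float = T0_DEFAULT) -> float:
    """kBT in internal energy units (kBT0), i.e. T/T0."""
    return temperature / t0
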