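"""Physical constants and coarse-grained model defaults.

All quantities in the package use the unit system of molecular simulation
practice: lengths in nm, energies in kJ/mol, charges in units of the
elementary charge e, temperatures in K.
"""

#: Avogadro constant, 1/mol (2019 SI exact value).
AVOGADRO = 6.02214076e23

#: Molar gas constant, kJ mol^-1 K^-1 (2019 SI exact value).
R_GAS = 8.31446261815324e-3

#: Bjerrum length of water at 300 K, nm.
BJERRUM_LENGTH_WATER = 0.7

#: B-DNA rise per base pair, nm.
BDNA_RISE = 0.338

#: Coarse-grained bead radius, nm (B-DNA diameter ~ 2 nm).
BEAD_RADIUS = 1.0

#: Charge per coarse-grained bead: both strands' phosphates of one bp, e.
BEAD_CHARGE = -2.0

#: Reference temperature, K.
TEMPERATURE = 300.0


def kT(temperature: float = TEMPERATURE) -> float:
    """Thermal energy R*T in kJ/mol (2.494 kJ/mol at 300 K)."""
    return R_GAS * temperature
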