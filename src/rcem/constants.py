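"""Physical constants and unit conversions.

Internal energy unit is kcal/mol, length unit Angstrom, charge unit e.
Stated once here and pinned by tests.
"""

#: Coulomb constant e^2/(4 pi eps0), kcal*A/(mol*e^2)
K_COULOMB = 332.0636

#: Gas constant, kcal/(mol*K)
R_GAS = 1.9872041e-3

#: 1 eV in kcal/mol
EV_TO_KCAL = 23.061

#: 1 mV (per unit charge) in kcal/mol
MV_TO_KCAL = EV_TO_KCAL / 1000.0

#: Avogadro's number, 1/mol
N_AVOGADRO = 6.02214076e23


def kt_kcal(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol at *temperature* (K)."""
    return R_GAS * temperature


def debye_kappa2(ionic_strength: float, eps_solvent: float, temperature: float) -> float:
    """Squared inverse Debye length, A^-2.

    kappa^2 = 8*pi*k_e*c / (eps_w * k_B*T) with c the ion number density
    (from *ionic_strength* in mol/L) and k_e the Coulomb constant in the
    internal unit system.
    """
    import math

    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    # mol/L -> ions/A^3
    c = ionic_strength * N_AVOGADRO * 1e-27
    return 8.0 * math.pi * K_COULOMB * c / (eps_solvent * kt_kcal(temperature))


def debye_length(ionic_strength: float, eps_solvent: float = 80.0,
                 temperature: float = 300.0) -> float:
    """Debye screening length in A (inf at zero ionic strength)."""
    import math

    k2 = debye_kappa2(ionic_strength, eps_solvent, temperature)
    return math.inf if k2 == 0.0 else 1.0 / math.sqrt(k2)
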