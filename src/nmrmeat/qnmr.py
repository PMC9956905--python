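"""Internal-standard qNMR quantification.

The purity equation relates an analyte signal to the internal-standard
signal through their integrals I, proton counts N, molar masses M, weighed
masses m and the standard's purity P:

    P_analyte = (I_a/I_s) · (N_s/N_a) · (M_a/M_s) · (m_s/m_a) · P_s

Rearranged for an unknown amount, the moles of analyte in the tube follow
from the standard's known moles:

    n_a [µmol] = (I_a/I_s) · (N_s/N_a) · n_s [µmol]

and the tissue concentration divides by the wet sample mass times the
declared extract-transfer fraction.  Both forms are invariant under any
common rescaling of the two integrals, so normalization never affects them.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .panel import MALEIC_ACID
from .spectra import SignalDefinition, Spectrum, integrate

__all__ = [
    "QuantSignal",
    "StandardSpec",
    "purity_vs_standard",
    "amount_umol",
    "concentration_umol_per_g",
    "quantify_spectrum",
    "quantify_spectra",
    "default_standard",
]


@dataclass(frozen=True)
class QuantSignal:
    """One measured signal with its qNMR constants.

    integral: intensity·ppm; n_protons: protons in the signal; molar_mass:
    g/mol; mass_mg: weighed mass (standard, or analyte for purity
    determination); purity: mass fraction of the pure compound.
    """

    integral: float
    n_protons: int
    molar_mass: float
    mass_mg: float = float("nan")
    purity: float = 1.0

    def __post_init__(self) -> None:
        if self.integral < 0:
            raise ValueError("integral must be >= 0")
        if self.n_protons < 1:
            raise ValueError("n_protons must be >= 1")
        if not self.molar_mass > 0:
            raise ValueError("molar_mass must be > 0")
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")


@dataclass(frozen=True)
class StandardSpec:
    """Internal standard: identity, weighed amount and integration window."""

    molar_mass: float = MALEIC_ACID["molar_mass"]
    n_protons: int = MALEIC_ACID["n_protons"]
    mass_mg: float = MALEIC_ACID["mass_mg"]
    purity: float = MALEIC_ACID["purity"]
    ppm_lo: float = MALEIC_ACID["ppm_lo"]
    ppm_hi: float = MALEIC_ACID["ppm_hi"]

    @property
    def amount_umol(self) -> float:
        # mg / (g/mol) = mmol; ×1000 → µmol
        return self.mass_mg / self.molar_mass * self.purity * 1000.0


def default_standard() -> StandardSpec:
    return StandardSpec()


def purity_vs_standard(analyte: QuantSignal, standard: QuantSignal) -> float:
    """Purity of a weighed analyte relative to the internal standard."""
    if standard.integral <= 0:
        raise ValueError("standard integral must be > 0")
    if not analyte.mass_mg > 0:
        raise ValueError("analyte mass must be > 0 for the purity form")
    if not standard.mass_mg > 0:
        raise ValueError("standard mass must be > 0")
    return (
        (analyte.integral / standard.integral)
        * (standard.n_protons / analyte.n_protons)
        * (analyte.molar_mass / standard.molar_mass)
        * (standard.mass_mg / analyte.mass_mg)
        * standard.purity
    )


def amount_umol(
    analyte_integral: float,
    analyte_n_protons: int,
    standard: StandardSpec,
    standard_integral: float,
) -> float:
    """Moles of analyte in the tube (µmol), linear in the analyte integral."""
    if standard_integral <= 0:
        raise ValueError("standard integral must be > 0")
    if analyte_integral < 0:
        raise ValueError("analyte integral must be >= 0")
    if analyte_n_protons < 1:
        raise ValueError("n_protons must be >= 1")
    return (
        (analyte_integral / standard_integral)
        * (standard.n_protons / analyte_n_protons)
        * standard.amount_umol
    )


def concentration_umol_per_g(
    amount: float, sample_mass_mg: float, extract_fraction: float = 1.0
) -> float:
    """Convert a tube amount (µmol) to µmol per g wet tissue."""
    if not sample_mass_mg > 0:
        raise ValueError("sample_mass_mg must be > 0")
    if not 0 < extract_fraction <= 1:
        raise ValueError("extract_fraction must be in (0, 1]")
    return amount / (sample_mass_mg / 1000.0 * extract_fraction)


def quantify_spectrum(
    spectrum: Spectrum,
    signals: list[SignalDefinition],
    standard: StandardSpec | None = None,
    sample_mass_mg: float = 200.0,
    extract_fraction: float = 1.0,
) -> dict[str, float]:
    """Quantify every signal-table metabolite in one spectrum (µmol/g)."""
    standard = standard if standard is not None else default_standard()
    i_std = integrate(spectrum, standard.ppm_lo, standard.ppm_hi, baseline="linear")
    if i_std <= 0:
        raise ValueError("internal-standard integral is non-positive")
    out: dict[str, float] = {}
    for sig in signals:
        i_a = max(integrate(spectrum, sig.ppm_lo, sig.ppm_hi, baseline="linear"), 0.0)
        amt = amount_umol(i_a, sig.n_protons, standard, i_std)
        out[sig.metabolite] = concentration_umol_per_g(amt, sample_mass_mg, extract_fraction)
    return out


def quantify_spectra(
    spectra: list[Spectrum],
    signals: list[SignalDefinition],
    standard: StandardSpec | None = None,
    sample_mass_mg: float = 200.0,
    extract_fraction: float = 1.0,
) -> pd.DataFrame:
    """Quantify a list of spectra into a samples × metabolites table."""
    rows = []
    ids = []
    for sp in spectra:
        rows.append(
            quantify_spectrum(sp, signals, standard, sample_mass_mg, extract_fraction)
        )
        ids.append(str(sp.metadata.get("sample_id", f"S{len(ids) + 1}")))
    return pd.DataFrame(rows, index=ids).rename_axis("sample_id")
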