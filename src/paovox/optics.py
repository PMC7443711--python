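"""Wavelength-dependent optical properties of the skin layers and blood.

All closed-form property models used to build a tissue phantom live here:
the melanin-fraction epidermis absorption, the blood-fraction dermis
absorption, whole-blood absorption as a linear mix of oxy-/deoxyhemoglobin,
power-law reduced scattering for each tissue, and the refractive-index /
anisotropy defaults.  Coefficients are returned in cm^-1 (the unit the
source compilations use); the phantom module converts to mm^-1 at its
boundary because the simulation grid is specified in mm.

The oxy/deoxy whole-blood absorption values at the four excitation
wavelengths (784, 796, 808, 820 nm) are embedded as a small constant table
derived from the standard compiled hemoglobin extinction spectra at a total
hemoglobin concentration of 150 g/L; they can be overridden through
:class:`ChromophoreTable` for sensitivity studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "WAVELENGTHS_NM",
    "OpticalProperties",
    "ChromophoreTable",
    "DEFAULT_BLOOD_TABLE",
    "LayerSample",
    "skin_baseline_mu_a",
    "melanin_mu_a",
    "epidermis_mu_a",
    "epidermis_mu_s_prime",
    "dermis_mu_a",
    "dermis_mu_s_prime",
    "blood_mu_a",
    "blood_mu_s_prime",
    "hypodermis_props",
    "dermis_refractive_index",
    "soft_tissue_anisotropy",
    "mu_s_from_reduced",
    "layer_optical_properties",
]

#: Default excitation wavelength set, nm (near-infrared, ascending).
WAVELENGTHS_NM: tuple[float, ...] = (784.0, 796.0, 808.0, 820.0)

#: Validity window of the embedded spectra, nm.
LAMBDA_MIN_NM = 400.0
LAMBDA_MAX_NM = 1100.0

# Fixed scalar defaults (dimensionless).
BLOOD_G = 0.994
BLOOD_N = 1.36
EPIDERMIS_N = 1.43  # midpoint of the reported 1.42-1.44 (700-900 nm) range
HYPODERMIS_N = 1.44
HYPODERMIS_G = 0.8


@dataclass(frozen=True)
class OpticalProperties:
    """Single-tissue optical properties at one wavelength.

    mu_a and mu_s in cm^-1; g (anisotropy) and n (refractive index)
    dimensionless.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if not 0.0 <= self.g < 1.0:
            raise ValueError("anisotropy g must lie in [0, 1)")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient mu_s * (1 - g), cm^-1."""
        return self.mu_s * (1.0 - self.g)


# Whole-blood absorption coefficients, cm^-1, at 150 g/L total hemoglobin,
# for fully deoxygenated (Hb) and fully oxygenated (HbO2) blood.  Derived
# from the standard compiled molar extinction spectra via
# mu_a = ln(10) * eps * C_Hb / M_Hb with C_Hb = 150 g/L, M_Hb = 64500 g/mol.
_ALPHA_HB_CM = {784.0: 5.22, 796.0: 4.55, 808.0: 4.10, 820.0: 3.80}
_ALPHA_HBO2_CM = {784.0: 3.96, 796.0: 4.28, 808.0: 4.55, 820.0: 4.85}


@dataclass(frozen=True)
class ChromophoreTable:
    """Volumetric absorption of whole blood's two hemoglobin states.

    ``alpha_hb[lambda]`` / ``alpha_hbo2[lambda]`` give the absorption
    coefficient (cm^-1) of fully deoxygenated / oxygenated whole blood at the
    reference total hemoglobin concentration.  Wavelengths not present in
    the table raise a lookup error rather than being silently interpolated.
    """

    alpha_hb: Mapping[float, float] = field(
        default_factory=lambda: dict(_ALPHA_HB_CM)
    )
    alpha_hbo2: Mapping[float, float] = field(
        default_factory=lambda: dict(_ALPHA_HBO2_CM)
    )

    def __post_init__(self) -> None:
        if set(self.alpha_hb) != set(self.alpha_hbo2):
            raise ValueError("alpha_hb and alpha_hbo2 must share wavelengths")
        for lam in self.alpha_hb:
            if self.alpha_hb[lam] <= 0 or self.alpha_hbo2[lam] <= 0:
                raise ValueError("chromophore absorption must be positive")

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(sorted(self.alpha_hb))

    def lookup(self, lambda_nm: float) -> tuple[float, float]:
        """Return ``(alpha_Hb, alpha_HbO2)`` at ``lambda_nm`` (cm^-1)."""
        lam = float(lambda_nm)
        try:
            return self.alpha_hb[lam], self.alpha_hbo2[lam]
        except KeyError:
            raise KeyError(
                f"wavelength {lam} nm not in chromophore table "
                f"{self.wavelengths}"
            ) from None


DEFAULT_BLOOD_TABLE = ChromophoreTable()


@dataclass(frozen=True)
class LayerSample:
    """One random draw of the per-phantom skin-layer parameters.

    C_M: melanosome volume fraction of the epidermis (0.06 light skin to
    0.40 strongly pigmented); C_B: dermal blood volume fraction; dermis_so2:
    oxygen saturation of the dermal blood pool; thicknesses in mm.
    """

    c_m: float
    c_b: float
    dermis_so2: float
    thickness_epi_mm: float
    thickness_derm_mm: float
    thickness_hypo_mm: float

    def __post_init__(self) -> None:
        if not 0.06 <= self.c_m <= 0.40:
            raise ValueError("C_M outside physiological range [0.06, 0.40]")
        if not 0.002 <= self.c_b <= 0.07:
            raise ValueError("C_B outside physiological range [0.002, 0.07]")
        if not 0.40 <= self.dermis_so2 <= 1.00:
            raise ValueError("dermis sO2 outside [0.40, 1.00]")
        if not 0.1 <= self.thickness_epi_mm <= 0.3:
            raise ValueError("epidermis thickness outside [0.1, 0.3] mm")
        if not 1.3 <= self.thickness_derm_mm <= 2.9:
            raise ValueError("dermis thickness outside [1.3, 2.9] mm")
        if not 0.8 <= self.thickness_hypo_mm <= 2.6:
            raise ValueError("hypodermis thickness outside [0.8, 2.6] mm")


def _check_wavelength(lambda_nm: float) -> float:
    lam = float(lambda_nm)
    if not LAMBDA_MIN_NM <= lam <= LAMBDA_MAX_NM:
        raise ValueError(
            f"wavelength {lam} nm outside the validity window "
            f"[{LAMBDA_MIN_NM}, {LAMBDA_MAX_NM}] nm"
        )
    return lam


def skin_baseline_mu_a(lambda_nm):
    """Blood- and melanin-free skin baseline absorption, cm^-1.

    0.244 + 85.3 * exp(-(lambda - 154) / 66.2), lambda in nm.  Exposed
    separately (without the wavelength-window guard) because both the
    epidermis and dermis absorption models share it.
    """
    lam = np.asarray(lambda_nm, dtype=float)
    return 0.244 + 85.3 * np.exp(-(lam - 154.0) / 66.2)


def melanin_mu_a(lambda_nm):
    """Absorption of a pure melanosome volume, cm^-1: 6.6e11 * lambda^-3.33."""
    lam = np.asarray(lambda_nm, dtype=float)
    return 6.6e11 * lam ** -3.33


def epidermis_mu_a(lambda_nm: float, c_m: float) -> float:
    """Epidermis absorption coefficient, cm^-1.

    mu_a,epi = C_M * 6.6e11 * lambda^-3.33
             + (1 - C_M) * [0.244 + 85.3 * exp(-(lambda - 154)/66.2)]
    with C_M the melanosome volume fraction.
    """
    lam = _check_wavelength(lambda_nm)
    if not 0.0 <= c_m <= 1.0:
        raise ValueError("melanosome fraction C_M must lie in [0, 1]")
    return float(c_m * melanin_mu_a(lam) + (1.0 - c_m) * skin_baseline_mu_a(lam))


def _power_law_mu_s_prime(lambda_nm: float, a_500: float, b: float) -> float:
    lam = float(lambda_nm)
    if lam <= 0:
        raise ValueError("wavelength must be positive")
    return a_500 * (lam / 500.0) ** (-b)


def epidermis_mu_s_prime(lambda_nm: float) -> float:
    """Epidermis reduced scattering, cm^-1: 68.7 * (lambda/500)^-1.16."""
    return _power_law_mu_s_prime(lambda_nm, 68.7, 1.16)


def dermis_mu_s_prime(lambda_nm: float) -> float:
    """Dermis reduced scattering, cm^-1: 45.3 * (lambda/500)^-1.292."""
    return _power_law_mu_s_prime(lambda_nm, 45.3, 1.292)


def blood_mu_s_prime(lambda_nm: float) -> float:
    """Whole-blood reduced scattering, cm^-1: 22 * (lambda/500)^-0.66."""
    return _power_law_mu_s_prime(lambda_nm, 22.0, 0.66)


def blood_mu_a(
    lambda_nm: float,
    so2: float,
    table: ChromophoreTable = DEFAULT_BLOOD_TABLE,
) -> float:
    """Whole-blood absorption, cm^-1, linear in the oxygen saturation.

    mu_a,blood = C_Hb * alpha_Hb + C_HbO2 * alpha_HbO2 with the hemoglobin
    split C_Hb = (1 - sO2), C_HbO2 = sO2 of the table's reference total
    concentration.
    """
    if not 0.0 <= so2 <= 1.0:
        raise ValueError("sO2 must lie in [0, 1]")
    a_hb, a_hbo2 = table.lookup(lambda_nm)
    return (1.0 - so2) * a_hb + so2 * a_hbo2


def dermis_mu_a(
    lambda_nm: float,
    c_b: float,
    dermis_so2: float,
    table: ChromophoreTable = DEFAULT_BLOOD_TABLE,
) -> float:
    """Dermis absorption, cm^-1: a blood/baseline volume mix.

    mu_a,derm = C_B * mu_a,blood(sO2) + (1 - C_B) * baseline(lambda) with
    C_B the dermal blood volume fraction.
    """
    lam = _check_wavelength(lambda_nm)
    if not 0.0 <= c_b <= 1.0:
        raise ValueError("blood volume fraction C_B must lie in [0, 1]")
    return float(
        c_b * blood_mu_a(lam, dermis_so2, table)
        + (1.0 - c_b) * skin_baseline_mu_a(lam)
    )


# Hypodermis anchors: (mu_a, mu_s') measured at 770 and 830 nm, cm^-1.
_HYPO_ANCHORS = {770.0: (1.1, 20.7), 830.0: (1.0, 19.6)}


def hypodermis_props(lambda_nm: float) -> OpticalProperties:
    """Hypodermis properties by linear interpolation between the two anchors.

    Anchored at mu_a = 1.1 / mu_s' = 20.7 cm^-1 (770 nm) and 1.0 / 19.6
    cm^-1 (830 nm).  Wavelengths outside [770, 830] nm are clamped to the
    nearest anchor with a warning.
    """
    lam = float(lambda_nm)
    if lam < 770.0 or lam > 830.0:
        warnings.warn(
            f"hypodermis properties extrapolated: {lam} nm clamped to "
            "[770, 830] nm",
            stacklevel=2,
        )
        lam = min(max(lam, 770.0), 830.0)
    frac = (lam - 770.0) / 60.0
    mu_a = 1.1 + frac * (1.0 - 1.1)
    mu_s_prime = 20.7 + frac * (19.6 - 20.7)
    return OpticalProperties(
        mu_a=mu_a,
        mu_s=mu_s_prime / (1.0 - HYPODERMIS_G),
        g=HYPODERMIS_G,
        n=HYPODERMIS_N,
    )


def dermis_refractive_index(lambda_nm: float) -> float:
    """Dermis refractive index Cauchy fit: n = A + B/l^2 + C/l^4 (l in nm)."""
    lam = float(lambda_nm)
    if lam <= 0:
        raise ValueError("wavelength must be positive")
    return 1.3696 + 3.9168e3 / lam**2 + 2.5588e3 / lam**4


def soft_tissue_anisotropy(lambda_nm: float) -> float:
    """Epidermis/dermis anisotropy: linear 0.95 at 700 nm to 0.8 at 1500 nm."""
    lam = float(lambda_nm)
    lam = min(max(lam, 700.0), 1500.0)
    return 0.95 + (lam - 700.0) / (1500.0 - 700.0) * (0.8 - 0.95)


def mu_s_from_reduced(mu_s_prime: float, g: float) -> float:
    """Recover mu_s = mu_s' / (1 - g) for the photon-transport engine."""
    if not 0.0 <= g < 1.0:
        raise ValueError("anisotropy g must lie in [0, 1)")
    if mu_s_prime < 0:
        raise ValueError("mu_s_prime must be non-negative")
    return mu_s_prime / (1.0 - g)


def layer_optical_properties(
    tissue: str,
    lambda_nm: float,
    sample: LayerSample,
    vessel_so2: float = 1.0,
    table: ChromophoreTable = DEFAULT_BLOOD_TABLE,
) -> OpticalProperties:
    """Full optical properties of one tissue class at one wavelength.

    ``tissue`` is one of ``epidermis``, ``dermis``, ``hypodermis``,
    ``vessel``; ``vessel_so2`` is only used for the vessel class.
    """
    if tissue == "epidermis":
        g = soft_tissue_anisotropy(lambda_nm)
        return OpticalProperties(
            mu_a=epidermis_mu_a(lambda_nm, sample.c_m),
            mu_s=mu_s_from_reduced(epidermis_mu_s_prime(lambda_nm), g),
            g=g,
            n=EPIDERMIS_N,
        )
    if tissue == "dermis":
        g = soft_tissue_anisotropy(lambda_nm)
        return OpticalProperties(
            mu_a=dermis_mu_a(lambda_nm, sample.c_b, sample.dermis_so2, table),
            mu_s=mu_s_from_reduced(dermis_mu_s_prime(lambda_nm), g),
            g=g,
            n=dermis_refractive_index(lambda_nm),
        )
    if tissue == "hypodermis":
        return hypodermis_props(lambda_nm)
    if tissue == "vessel":
        return OpticalProperties(
            mu_a=blood_mu_a(lambda_nm, vessel_so2, table),
            mu_s=mu_s_from_reduced(blood_mu_s_prime(lambda_nm), BLOOD_G),
            g=BLOOD_G,
            n=BLOOD_N,
        )
    raise ValueError(f"unknown tissue class {tissue!r}")
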