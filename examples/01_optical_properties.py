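"""Tissue optical properties at the four excitation wavelengths.

Prints absorption and reduced scattering (cm^-1) for each skin layer and
for whole blood at two oxygenation levels.  The spectral contrast between
oxy- and deoxyhemoglobin across 784-820 nm is what makes sO2 estimation
from multiwavelength photoacoustic images possible.
"""

from paovox import optics

sample = optics.LayerSample(
    c_m=0.2, c_b=0.03, dermis_so2=0.8,
    thickness_epi_mm=0.2, thickness_derm_mm=2.0, thickness_hypo_mm=1.5,
)

print(f"{'lambda (nm)':>12} {'tissue':>12} {'mu_a':>8} {'mu_s_prime':>11}")
for lam in optics.WAVELENGTHS_NM:
    for tissue in ("epidermis", "dermis", "hypodermis", "vessel"):
        p = optics.layer_optical_properties(tissue, lam, sample, vessel_so2=0.75)
        print(f"{lam:12.0f} {tissue:>12} {p.mu_a:8.3f} {p.mu_s_prime:11.2f}")

print("\nwhole blood mu_a (cm^-1), deoxygenated vs fully oxygenated:")
for lam in optics.WAVELENGTHS_NM:
    lo = optics.blood_mu_a(lam, 0.0)
    hi = optics.blood_mu_a(lam, 1.0)
    print(f"  {lam:.0f} nm: Hb {lo:.2f}  HbO2 {hi:.2f}  ratio {hi / lo:.2f}")
print("the Hb/HbO2 ratio flips across ~800 nm: that sign change encodes sO2")
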