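"""Quantitative assay computations: metal content, TMPD kinetics, NADI.

Recomputes three worked examples: Cu atoms per cell from an AAS reading,
cytochrome c oxidase activity from a ΔA520 pair, and NADI phenotype
calls from colony staining times.
"""

from fixiscan import (
    AASMeasurement,
    NadiObservation,
    StainIntensity,
    TMPDKinetics,
    atoms_per_cell,
    classify_nadi,
    tmpd_activity,
)

# 63.55 mg/L Cu (= 1 mmol) in 1 L over 1e9 cells
cu = AASMeasurement(
    metal="Cu",
    concentration_mg_per_l=63.55,
    sample_volume_l=1.0,
    molar_mass_g_per_mol=63.55,
    cell_count=1e9,
)
print(f"Cu atoms per cell: {atoms_per_cell(cu):.4e}")
# 6.0221e+11 — one millimole of Cu is 6.022e20 atoms, shared by 1e9 cells.

# A520 rises by 0.305 over 5 min in a 100 ul reaction, 1 cm path
k = TMPDKinetics(
    a520_t0=0.0,
    a520_t5=0.305,
    interval_min=5.0,
    epsilon_mm_cm=6.1,
    path_length_cm=1.0,
    reaction_volume_l=1e-4,
)
print(f"TMPD oxidase activity: {tmpd_activity(k):.4e} umol/min per well")
# 1.0000e-03 — Beer-Lambert: 0.305/6.1 = 0.05 mM oxidized; x 0.1 mL; / 5 min.

for onset, intensity in [(30.0, StainIntensity.DARK),
                         (600.0, StainIntensity.LIGHT),
                         (None, StainIntensity.NONE)]:
    obs = NadiObservation(onset, intensity, observation_window_s=1800.0)
    label = "never" if onset is None else f"{onset:.0f} s"
    print(f"staining {intensity.value.lower():5s} at {label:6s} -> {classify_nadi(obs).value}")
# Dark staining within 60 s is NADI+, light staining within 15 min is
# NADIslow, and no staining over a 30-min watch is NADI-.
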