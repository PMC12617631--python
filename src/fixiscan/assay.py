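"""Quantitative assay computations.

Three measurements are implemented:

* **atoms per cell** from atomic absorption spectroscopy (AAS):
  ``atoms/cell = (c [mg/L] × V [L] / 1000 / M [g/mol]) × N_A / N_cells``
  with Avogadro's constant ``N_A = 6.02214076e23`` (2019 SI value).
* **TMPD oxidase activity** from ΔA520 Beer–Lambert kinetics:
  TMPD oxidation forms an indophenol product absorbing at 520 nm with
  ε = 6.1 mM⁻¹ cm⁻¹; activity is expressed as μmol TMPD oxidized per
  minute per aliquot of cells (default 2.4e4 cells), using the
  absorbance increase between 0 and 5 minutes.
* **NADI phenotype** classification by colony staining speed: dark blue
  within the fast cutoff (default 60 s) is NADI+, any staining within
  the slow cutoff (default 900 s, i.e. 15 min) is NADIslow, no staining
  within the slow cutoff is NADI−.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23  # mol^-1

#: default optical path for 100 μl in a flat-bottom 96-well plate (cm).
#: This is an assumption of the implementation, not a measured value.
DEFAULT_PATH_LENGTH_CM = 0.29

DEFAULT_EPSILON_TMPD = 6.1  # mM^-1 cm^-1, indophenol product at 520 nm
DEFAULT_CELLS_PER_WELL = 2.4e4


@dataclass(frozen=True)
class AASMeasurement:
    """One AAS reading, dilution-corrected."""

    metal: str
    concentration_mg_per_l: float
    sample_volume_l: float
    molar_mass_g_per_mol: float
    cell_count: float

    def __post_init__(self) -> None:
        if self.concentration_mg_per_l < 0:
            raise ValueError("concentration must be >= 0")
        if self.molar_mass_g_per_mol <= 0:
            raise ValueError("molar mass must be > 0")
        if self.cell_count <= 0:
            raise ValueError("cell count must be > 0")
        if self.sample_volume_l <= 0:
            raise ValueError("sample volume must be > 0")


@dataclass(frozen=True)
class TMPDKinetics:
    """Endpoint absorbance pair for the TMPD oxidase assay."""

    a520_t0: float
    a520_t5: float
    interval_min: float = 5.0
    epsilon_mm_cm: float = DEFAULT_EPSILON_TMPD
    path_length_cm: float = DEFAULT_PATH_LENGTH_CM
    reaction_volume_l: float = 1e-4
    cells_per_well: float = DEFAULT_CELLS_PER_WELL

    def __post_init__(self) -> None:
        if self.epsilon_mm_cm <= 0:
            raise ValueError("epsilon must be > 0")
        if self.path_length_cm <= 0:
            raise ValueError("path length must be > 0")
        if self.interval_min <= 0:
            raise ValueError("interval must be > 0")
        if self.cells_per_well <= 0:
            raise ValueError("cells per well must be > 0")


class StainIntensity(Enum):
    DARK = "DARK"
    LIGHT = "LIGHT"
    NONE = "NONE"


class NadiPhenotype(Enum):
    NADI_PLUS = "NADI_PLUS"
    NADI_SLOW = "NADI_SLOW"
    NADI_MINUS = "NADI_MINUS"
    #: observation stopped before the slow cutoff with no staining seen —
    #: cannot distinguish NADI_SLOW from NADI_MINUS
    NADI_INDETERMINATE = "NADI_INDETERMINATE"


@dataclass(frozen=True)
class NadiObservation:
    """Colony staining record: onset in seconds (None = never stained
    within the observation window)."""

    stain_onset_s: float | None
    intensity: StainIntensity
    observation_window_s: float

    def __post_init__(self) -> None:
        if self.stain_onset_s is not None and (
            self.stain_onset_s > self.observation_window_s
        ):
            raise ValueError("stain onset beyond the observation window")
        if self.stain_onset_s is None and self.intensity is not StainIntensity.NONE:
            raise ValueError("staining reported without an onset time")


def atoms_per_cell(m: AASMeasurement) -> float:
    """Metal atoms per cell from an AAS concentration.

    Linear in concentration, inversely proportional to cell count.
    """
    grams = m.concentration_mg_per_l * m.sample_volume_l / 1000.0
    moles = grams / m.molar_mass_g_per_mol
    return moles * AVOGADRO / m.cell_count


def tmpd_activity(k: TMPDKinetics) -> float:
    """μmol TMPD oxidized per minute per ``cells_per_well`` cells.

    ΔA/(ε·l) gives the concentration change in mM; times the reaction
    volume (L) and 1000 that is μmol; divided by the interval, a rate.
    Negative ΔA (blank drift) is returned as-is with a warning.
    """
    delta_a = k.a520_t5 - k.a520_t0
    if delta_a < 0:
        logger.warning(
            "negative ΔA520 (%.4f): blank drift or mis-ordered timepoints", delta_a
        )
    delta_c_mm = delta_a / (k.epsilon_mm_cm * k.path_length_cm)
    amount_umol = delta_c_mm * k.reaction_volume_l * 1000.0
    return amount_umol / k.interval_min


def classify_nadi(
    obs: NadiObservation,
    fast_cutoff_s: float = 60.0,
    slow_cutoff_s: float = 900.0,
) -> NadiPhenotype:
    """Map a staining observation to NADI+/NADIslow/NADI−.

    Dark staining within the fast cutoff is NADI+; any staining within
    the slow cutoff (not already NADI+) is NADIslow; staining later than
    the slow cutoff, or none at all over a window covering the slow
    cutoff, is NADI−. A window shorter than the slow cutoff with no
    staining is indeterminate.
    """
    if fast_cutoff_s <= 0 or slow_cutoff_s <= 0 or fast_cutoff_s >= slow_cutoff_s:
        raise ValueError("need 0 < fast_cutoff < slow_cutoff")
    onset = obs.stain_onset_s
    if onset is None:
        if obs.observation_window_s < slow_cutoff_s:
            return NadiPhenotype.NADI_INDETERMINATE
        return NadiPhenotype.NADI_MINUS
    if obs.intensity is StainIntensity.DARK and onset <= fast_cutoff_s:
        return NadiPhenotype.NADI_PLUS
    if onset <= slow_cutoff_s:
        return NadiPhenotype.NADI_SLOW
    return NadiPhenotype.NADI_MINUS
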