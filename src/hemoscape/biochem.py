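"""Deterministic unit conversions for the biochemical readouts.

TBARS absorbance → malondialdehyde (MDA) concentration via Beer–Lambert
with the standard TBA–MDA adduct molar absorptivity ε = 156 mM⁻¹ cm⁻¹,
protein normalization, control centring, and LDH percent-of-lysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: TBA-MDA adduct molar absorptivity at 532 nm, mM^-1 cm^-1.
EPSILON_MDA = 156.0

#: Assay dilution implied by 100 μL homogenate in a 1000 μL reaction.
DEFAULT_DILUTION = 10.0


@dataclass(frozen=True)
class TbarsMeasurement:
    """One TBARS assay read: 532 nm absorbance with 600 nm background.

    ``protein_g`` is total protein (g) in the assayed homogenate volume,
    used for normalization downstream.  ``dilution_factor`` defaults to the
    protocol's 10× homogenate dilution in the reaction mix.
    """

    a532: float
    a600: float = 0.0
    path_length: float = 1.0  # cm
    dilution_factor: float = DEFAULT_DILUTION
    protein_g: float | None = None
    epsilon: float = EPSILON_MDA  # mM^-1 cm^-1

    def __post_init__(self) -> None:
        if self.path_length <= 0:
            raise ValueError("path_length must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


def mda_concentration(m: TbarsMeasurement) -> float:
    """MDA-equivalent concentration in μM from background-corrected absorbance.

    ΔA / (ε · l) gives mM; ×1000 converts to μM; the dilution factor maps
    the reaction-mix concentration back to the homogenate.  A negative ΔA
    passes through as a negative concentration (control-centred readouts are
    legitimately negative).
    """
    delta_a = m.a532 - m.a600
    return delta_a / (m.epsilon * m.path_length) * 1000.0 * m.dilution_factor


def normalize_to_protein(conc_um: float, protein_g: float) -> float:
    """Normalize a μM concentration to total protein: μM g⁻¹."""
    if protein_g <= 0:
        raise ValueError("protein_g must be > 0")
    return conc_um / protein_g


def center_to_control(values, control_mean: float):
    """Subtract the batch control mean (the normalization that yields the
    negative control-level MDA values reported for unexposed slices)."""
    return np.asarray(values, dtype=float) - control_mean


def ldh_percent_of_max(sample_rfu: float, triton_max_rfu: float) -> float:
    """LDH release as percent of the full-lysis (Triton X-100) signal."""
    if triton_max_rfu <= 0:
        raise ValueError("triton_max_rfu must be > 0")
    return 100.0 * sample_rfu / triton_max_rfu
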