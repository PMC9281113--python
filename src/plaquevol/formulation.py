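"""Closed-form nanoparticle formulation arithmetic.

Loading rate (drug mass per nanoparticle mass), encapsulation rate (drug
mass retained per drug mass fed), hemolysis ratio against negative/positive
absorbance controls, and the theoretical mass fraction of one component of
a formulation given its mole-ratio parts.  All results are percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FormulationInputs",
    "HemolysisInputs",
    "HemolysisResult",
    "loading_rate",
    "encapsulation_rate",
    "hemolysis_ratio",
    "theoretical_fraction",
]


@dataclass(frozen=True)
class FormulationInputs:
    """Masses (mg) entering the loading/encapsulation-rate formulas."""

    mass_cur_in_np: float  # drug measured inside the nanoparticles
    total_mass_np: float  # nanoparticle mass
    total_mass_cur_fed: float  # drug fed during preparation

    def __post_init__(self) -> None:
        if min(self.mass_cur_in_np, self.total_mass_np, self.total_mass_cur_fed) < 0:
            raise ValueError("masses must be >= 0")
        if self.total_mass_np and self.mass_cur_in_np > self.total_mass_np:
            raise ValueError("loaded drug mass cannot exceed the nanoparticle mass")
        if self.total_mass_cur_fed and self.mass_cur_in_np > self.total_mass_cur_fed:
            raise ValueError("loaded drug mass cannot exceed the mass fed")


@dataclass(frozen=True)
class HemolysisInputs:
    """Absorbances of sample (As), negative (An) and positive (Ap) controls."""

    a_sample: float
    a_negative: float
    a_positive: float

    def __post_init__(self) -> None:
        if self.a_positive <= self.a_negative:
            raise ValueError("positive-control absorbance must exceed the negative control")


@dataclass(frozen=True)
class HemolysisResult:
    percent: float
    out_of_range: bool  # outside [0, 100]: pathological inputs, reported unclipped


def loading_rate(inputs: FormulationInputs) -> float:
    """Loading rate (%) = 100 x drug mass in nanoparticles / nanoparticle mass."""
    if inputs.total_mass_np <= 0:
        raise ValueError("total nanoparticle mass must be > 0")
    return 100.0 * inputs.mass_cur_in_np / inputs.total_mass_np


def encapsulation_rate(inputs: FormulationInputs) -> float:
    """Encapsulation rate (%) = 100 x drug mass in nanoparticles / drug mass fed."""
    if inputs.total_mass_cur_fed <= 0:
        raise ValueError("total drug mass fed must be > 0")
    return 100.0 * inputs.mass_cur_in_np / inputs.total_mass_cur_fed


def hemolysis_ratio(inputs: HemolysisInputs) -> HemolysisResult:
    """Hemolysis (%) = 100 x (As - An) / (Ap - An), unclipped but flagged."""
    pct = 100.0 * (inputs.a_sample - inputs.a_negative) / (inputs.a_positive - inputs.a_negative)
    return HemolysisResult(percent=pct, out_of_range=not 0.0 <= pct <= 100.0)


def theoretical_fraction(parts, target_index: int) -> float:
    """Theoretical fraction (%) of one component from formulation ratio parts.

    E.g. an iron-oxide : polymer ratio of 1:1 gives a theoretical 50% core
    fraction; 2:2:2:1:1 gives 25% for the first component.
    """
    parts = list(parts)
    if not parts or any(p <= 0 for p in parts):
        raise ValueError("parts must be non-empty and all > 0")
    if not 0 <= target_index < len(parts):
        raise ValueError(f"target_index {target_index} out of range for {len(parts)} parts")
    return 100.0 * parts[target_index] / sum(parts)
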