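"""Treatment effects: how medication exposure and adherence modify hazards.

Beneficial effects (statin, antihypertensive and antiplatelet relative
risks on CVD; antihypertensive relative risk on heart failure) and adverse
effects (treatment-emergent diabetes, aspirin GI bleeding, ACE-inhibitor
cough) apply only while a person is adherent. Relative risks combine
multiplicatively across drug classes. ``itt_adjustment`` exponentiates the
log relative risks, exposing the intention-to-treat vs per-protocol
sensitivity analysis as a single dial (1 = ITT estimates as supplied).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, ContractError
from .population import Individual, MedicationProfile


@dataclass
class TreatmentEffects:
    rr_cvd_statin: float = 0.75
    rr_cvd_aht: float = 0.80          # antihypertensive class effect on CVD
    rr_cvd_aspirin: float = 0.90
    rr_diabetes_tx: float = 1.10      # statin/AHT effect on new-onset diabetes
    rr_gi_bleed_aspirin: float = 1.60
    p_cough_acei: float = 0.05        # placebo-adjusted, per initiation
    rr_hf_aht: float = 0.72           # AHT effect on heart failure
    itt_adjustment: float = 1.0       # exponent on log-RRs (per-protocol dial)

    def validate(self) -> None:
        problems = []
        for name in ("rr_cvd_statin", "rr_cvd_aht", "rr_cvd_aspirin",
                     "rr_diabetes_tx", "rr_gi_bleed_aspirin", "rr_hf_aht",
                     "itt_adjustment"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.p_cough_acei <= 1.0:
            problems.append(f"p_cough_acei must be in [0,1], got {self.p_cough_acei}")
        if problems:
            raise ConfigurationError("; ".join(problems))


def adjusted_cvd_hazard(baseline: float, meds: MedicationProfile,
                        adherent: bool, fx: TreatmentEffects) -> float:
    """CVD hazard after treatment modification.

    Non-adherent (or untreated) people keep the baseline hazard exactly;
    adherent people get the product of class relative risks, each raised
    to ``itt_adjustment``, over the classes they take.
    """
    if baseline < 0:
        raise ContractError("baseline hazard must be >= 0")
    if not adherent:
        return baseline
    h = baseline
    a = fx.itt_adjustment
    if meds.statin:
        h *= fx.rr_cvd_statin ** a
    if meds.n_antihypertensives >= 1:
        h *= fx.rr_cvd_aht ** a
    if meds.aspirin:
        h *= fx.rr_cvd_aspirin ** a
    return h


def adverse_event_hazards(meds: MedicationProfile, adherent: bool,
                          baseline_diabetes: float, baseline_gi: float,
                          fx: TreatmentEffects) -> dict:
    """Treatment-modified diabetes and GI-bleed hazards plus the one-shot
    cough probability (nonzero only for adherent ACE-inhibitor users)."""
    if baseline_diabetes < 0 or baseline_gi < 0:
        raise ContractError("baseline hazards must be >= 0")
    dm = baseline_diabetes
    gi = baseline_gi
    cough = 0.0
    if adherent:
        if meds.statin or meds.n_antihypertensives >= 1:
            dm *= fx.rr_diabetes_tx
        if meds.aspirin:
            gi *= fx.rr_gi_bleed_aspirin
        if meds.acei:
            cough = fx.p_cough_acei
    return {"diabetes": dm, "gi_bleed": gi, "cough_probability": cough}


@dataclass(frozen=True)
class AgeRateTable:
    """Piecewise-linear yearly rate by age (e.g. heart-failure incidence)."""

    ages: tuple = field(default_factory=tuple)
    rates: tuple = field(default_factory=tuple)

    def validate(self) -> None:
        if len(self.ages) != len(self.rates) or len(self.ages) < 2:
            raise ConfigurationError(
                "age/rate table needs >= 2 matching age and rate entries")
        if any(b <= a for a, b in zip(self.ages, self.ages[1:])):
            raise ConfigurationError("table ages must be strictly increasing")
        if any(r < 0 for r in self.rates):
            raise ConfigurationError("table rates must be >= 0")

    def rate_at(self, age: float) -> float:
        if age < self.ages[0] or age > self.ages[-1]:
            warnings.warn(
                f"age {age:.1f} outside rate table range "
                f"[{self.ages[0]}, {self.ages[-1]}]; clamping to boundary",
                stacklevel=2)
        return float(np.interp(age, self.ages, self.rates))


def heart_failure_hazard(age: float, baseline_hf_by_age: AgeRateTable,
                         adherent_aht: bool, fx: TreatmentEffects) -> float:
    """Age-interpolated heart-failure incidence, reduced by the AHT
    relative risk while adherent to an antihypertensive."""
    h = baseline_hf_by_age.rate_at(age)
    if adherent_aht:
        h *= fx.rr_hf_aht ** fx.itt_adjustment
    return h
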