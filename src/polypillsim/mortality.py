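"""Other-cause mortality (life table) and acute case fatality.

The life table holds annual probabilities of death q(age, sex) in the
national-life-table layout (CSV columns ``age, sex, qx``). Death times are
sampled from the implied piecewise-exponential survival: within each year
of age the hazard is constant at ``-ln(1 - qx)``, so the table's annual
probabilities are reproduced exactly at integer ages.

Case fatality covers the two acute events the model treats as potentially
fatal: stroke (60-day window) and MI (30-day window), with probabilities
by age band. Band edges are closed on the left (74.99 falls in the <75
band, 75.0 in the >=75 band).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError

_Q_CAP = 1.0 - 1e-12   # q = 1 maps to a huge but finite hazard

#: case-fatality windows, in years
STROKE_FATALITY_WINDOW = 60.0 / 365.25
MI_FATALITY_WINDOW = 30.0 / 365.25

MI_BAND_EDGES = (30.0, 55.0, 65.0, 75.0, 85.0)   # lower bounds, closed left


class LifeTable:
    """Annual death probabilities by single year of age and sex.

    ``qx`` maps sex -> sequence of annual probabilities for ages
    ``age_min .. age_min + len - 1`` with no gaps; the table must reach at
    least age 100 to cover the model's age cap.
    """

    def __init__(self, age_min: int, qx: dict):
        self.age_min = int(age_min)
        self.qx = {sex: tuple(float(q) for q in qs) for sex, qs in qx.items()}
        self._validate()
        # per-sex constant-within-year hazards and cumulative hazard at
        # integer-age boundaries (cum[0] = 0 at age_min)
        self._hazard = {}
        self._cumhaz = {}
        for sex, qs in self.qx.items():
            h = np.array([-math.log1p(-min(q, _Q_CAP)) for q in qs])
            self._hazard[sex] = h
            self._cumhaz[sex] = np.concatenate([[0.0], np.cumsum(h)])

    def _validate(self) -> None:
        problems = []
        if not self.qx:
            problems.append("life table has no sexes")
        for sex, qs in self.qx.items():
            if self.age_min + len(qs) - 1 < 100:
                problems.append(
                    f"life table for {sex!r} must cover ages up to >= 100 "
                    f"(covers {self.age_min}..{self.age_min + len(qs) - 1})")
            if any(not 0.0 <= q <= 1.0 for q in qs):
                problems.append(f"life table for {sex!r} has q outside [0,1]")
        if problems:
            raise ConfigurationError("; ".join(problems))

    @property
    def age_max(self) -> int:
        return self.age_min + len(next(iter(self.qx.values()))) - 1

    def annual_q(self, age: int, sex: str) -> float:
        qs = self.qx[sex]
        i = int(age) - self.age_min
        if not 0 <= i < len(qs):
            raise ConfigurationError(
                f"age {age} outside life table range for {sex!r}")
        return qs[i]

    def survival_from(self, start_age: float, target_age: float,
                      sex: str) -> float:
        """P(alive at target_age | alive at start_age), other causes only."""
        return math.exp(-(self._cum_at(target_age, sex)
                          - self._cum_at(start_age, sex)))

    def _cum_at(self, age: float, sex: str) -> float:
        """Cumulative hazard from age_min to (possibly fractional) age."""
        x = age - self.age_min
        if x <= 0:
            return 0.0
        h = self._hazard[sex]
        cum = self._cumhaz[sex]
        i = int(x)
        if i >= len(h):
            # beyond the table: extrapolate with the last year's hazard
            return float(cum[-1] + (x - len(h)) * h[-1])
        return float(cum[i] + (x - i) * h[i])

    def sample_death_time(self, age: float, sex: str,
                          rng: np.random.Generator) -> float:
        """Years until other-cause death for someone alive at ``age``.

        Inverse-transform sampling on the piecewise-constant hazard;
        consumes exactly one exponential draw.
        """
        if sex not in self.qx:
            raise ConfigurationError(f"no life table for sex {sex!r}")
        h = self._hazard[sex]
        cum = self._cumhaz[sex]
        target = self._cum_at(age, sex) + rng.exponential()
        if target >= cum[-1]:
            # past the table end; continue at the final hazard (the age cap
            # normally intervenes first)
            death_age = self.age_min + len(h) + (target - cum[-1]) / h[-1] \
                if h[-1] > 0 else math.inf
            return death_age - age
        j = int(np.searchsorted(cum, target, side="right")) - 1
        death_age = self.age_min + j + (target - cum[j]) / h[j]
        return death_age - age

    # -- CSV round trip ----------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        out = {}
        age_min = None
        for sex, g in df.groupby("sex"):
            g = g.sort_values("age")
            ages = g["age"].to_numpy(dtype=int)
            if not np.all(np.diff(ages) == 1):
                raise ConfigurationError(
                    f"life table for {sex!r} has gaps or duplicate ages")
            if age_min is None:
                age_min = int(ages[0])
            elif int(ages[0]) != age_min:
                raise ConfigurationError("sexes cover different age ranges")
            out[str(sex)] = g["qx"].to_list()
        if age_min is None:
            raise ConfigurationError("empty life table")
        return cls(age_min, out)

    def to_csv(self, path) -> None:
        rows = [{"age": self.age_min + i, "sex": sex, "qx": q}
                for sex, qs in self.qx.items() for i, q in enumerate(qs)]
        pd.DataFrame(rows).to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {"age_min": self.age_min,
                "qx": {sex: list(qs) for sex, qs in self.qx.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "LifeTable":
        return cls(d["age_min"], d["qx"])

    def __eq__(self, other) -> bool:
        return isinstance(other, LifeTable) and self.to_dict() == other.to_dict()


@dataclass
class CaseFatality:
    """Acute fatality probabilities by age band.

    Stroke uses two bands (<75, >=75) over a 60-day window; MI uses five
    bands (30-54, 55-64, 65-74, 75-84, 85+) over a 30-day window.
    """

    stroke_lt75: float = 0.15
    stroke_ge75: float = 0.30
    #: MI fatality by band lower bound, aligned with MI_BAND_EDGES
    mi_bands: tuple = (0.02, 0.05, 0.12, 0.25, 0.40)

    def validate(self) -> None:
        probs = [self.stroke_lt75, self.stroke_ge75, *self.mi_bands]
        if len(self.mi_bands) != len(MI_BAND_EDGES):
            raise ConfigurationError(
                f"mi_bands needs {len(MI_BAND_EDGES)} entries")
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ConfigurationError("case-fatality probabilities must be in [0,1]")

    def probability(self, event: str, age: float) -> float:
        if event == "stroke":
            return self.stroke_lt75 if age < 75.0 else self.stroke_ge75
        if event == "mi":
            i = int(np.searchsorted(MI_BAND_EDGES, age, side="right")) - 1
            return self.mi_bands[max(i, 0)]
        raise ContractError(
            f"case fatality defined only for stroke and MI, got {event!r}")

    def window(self, event: str) -> float:
        if event == "stroke":
            return STROKE_FATALITY_WINDOW
        if event == "mi":
            return MI_FATALITY_WINDOW
        raise ContractError(f"no fatality window for {event!r}")
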