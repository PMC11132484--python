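"""Annual CVD event probability.

The ten-year baseline risk follows the survival form used by QRISK-style
scores, ``risk = 1 - s0 ** exp(lp)``, where the linear predictor ``lp`` is
built from age terms only (sex enters through separate coefficient sets,
and default clinical values for BMI, cholesterol ratio and blood pressure
are folded into the coefficients).  The baseline is multiplied by one
user-supplied factor per behaviour -- keyed by level, age band and sex --
and divided by 10 to give the probability of an event in the current year.
Risk is accrued only in the validity window ages 25-84.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .parameters import (
    AGE_MAX,
    AGE_MIN,
    BEHAVIOURS,
    ConfigurationError,
    SEXES,
)
from .population import Agent, Population

RISK_AGE_MIN = 25
RISK_AGE_MAX = 84

_TERMS = ("intercept", "age_centered", "age_centered_sq")


class BaselineRiskModel:
    """Per-sex baseline survival constant and age-term coefficients."""

    def __init__(self, s0: dict[str, float], coefficients: dict[str, dict[str, float]]):
        self.s0 = dict(s0)
        self.coefficients = {sex: dict(c) for sex, c in coefficients.items()}

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BaselineRiskModel":
        s0, coeffs = {}, {}
        for sex in SEXES:
            sub = df[df["sex"] == sex].set_index("term")["coefficient"]
            if "s0" not in sub.index:
                raise ConfigurationError(f"baseline_risk: missing s0 for {sex}")
            s0[sex] = float(sub["s0"])
            coeffs[sex] = {t: float(sub.get(t, 0.0)) for t in _TERMS}
        return cls(s0, coeffs)

    def linear_predictor(self, age, sex: str):
        age = np.asarray(age, dtype=float)
        c = self.coefficients[sex]
        a = age - 60.0
        return c["intercept"] + c["age_centered"] * a + c["age_centered_sq"] * a * a / 100.0

    def ten_year_risk(self, age, sex: str):
        """10-year CVD probability, ``1 - s0 ** exp(lp)``, clipped to [0, 1]."""
        lp = self.linear_predictor(age, sex)
        risk = 1.0 - np.power(self.s0[sex], np.exp(lp))
        return np.clip(risk, 0.0, 1.0)


def baseline_ten_year_risk(age: int, sex: str, model: BaselineRiskModel) -> float:
    """Scalar convenience wrapper; valid for ages 25-84 (caller-enforced)."""
    return float(model.ten_year_risk(age, sex))


class RiskMultiplierTable:
    """Multiplier per (behaviour, level, age band, sex), gridded by year of age.

    Age bands are half-open ``[age_lo, age_hi)`` as given in the table; ages
    not covered by any band hold NaN and raise on lookup.
    """

    def __init__(self, grid: np.ndarray):
        # grid shape: (behaviour, level, sex, age index from AGE_MIN)
        self.grid = grid

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RiskMultiplierTable":
        n_ages = AGE_MAX - AGE_MIN + 1
        grid = np.full((len(BEHAVIOURS), 3, len(SEXES), n_ages), np.nan)
        for _, row in df.iterrows():
            b = BEHAVIOURS.index(row["behaviour"])
            s = SEXES.index(row["sex"])
            lo = max(int(row["age_lo"]), AGE_MIN) - AGE_MIN
            hi = min(int(row["age_hi"]), AGE_MAX + 1) - AGE_MIN
            grid[b, int(row["level"]), s, lo:hi] = float(row["multiplier"])
        return cls(grid)

    def lookup(self, behaviour: str, level: int, age: int, sex: str) -> float:
        m = self.grid[BEHAVIOURS.index(behaviour), level, SEXES.index(sex), age - AGE_MIN]
        if np.isnan(m):
            raise ConfigurationError(
                f"no risk multiplier for ({behaviour}, level {level}, age {age}, {sex})"
            )
        return float(m)


def combined_multiplier(agent: Agent, table: RiskMultiplierTable) -> float:
    """Product of the four behaviour-level multipliers for one agent."""
    m = 1.0
    for beh in BEHAVIOURS:
        m *= table.lookup(beh, agent.level[beh], agent.age, agent.sex)
    return m


def annual_event_probability(ten_year_risk: float, multiplier: float):
    """Behaviour-adjusted annual probability: clamp(risk * multiplier / 10)."""
    return np.clip(np.asarray(ten_year_risk) * np.asarray(multiplier) / 10.0, 0.0, 1.0)


def annual_probabilities(
    population: Population, model: BaselineRiskModel, table: RiskMultiplierTable
) -> np.ndarray:
    """Vectorised annual event probability for every agent.

    Agents outside the 25-84 validity window get probability 0 and accrue
    no risk (and, in the engine, no person-years).
    """
    n = population.n
    p = np.zeros(n)
    in_window = (population.age >= RISK_AGE_MIN) & (population.age <= RISK_AGE_MAX)
    if not in_window.any():
        return p
    age_idx = population.age - AGE_MIN
    for s, sex in enumerate(SEXES):
        mask = in_window & (population.sex == s)
        if not mask.any():
            continue
        base = model.ten_year_risk(population.age[mask], sex)
        mult = np.ones(int(mask.sum()))
        for b in range(len(BEHAVIOURS)):
            m = table.grid[b, population.levels[mask, b], s, age_idx[mask]]
            if np.isnan(m).any():
                bad_age = int(population.age[mask][np.isnan(m)][0])
                raise ConfigurationError(
                    f"no risk multiplier covering ({BEHAVIOURS[b]}, age {bad_age}, {sex})"
                )
            mult *= m
        p[mask] = annual_event_probability(base, mult)
    return p
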