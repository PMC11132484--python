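"""Parameter sets configuring a simulation.

Every quantity that drives a run -- demographic distributions, network
parameters, behaviour prevalence, risk multipliers, baseline risk
coefficients and relationship influence strengths -- lives in a
:class:`ParameterSet`, which round-trips to a directory of plain CSV files.
A synthetic fixture generator produces a complete, schema-valid parameter
set so the simulator can be built and tested without any external data.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BEHAVIOURS = ("smoking", "alcohol", "diet", "inactivity")
RELATIONSHIPS = ("marriage", "household", "friendship", "workplace")
SEXES = ("female", "male")
LEVELS = (0, 1, 2)
AGE_MIN = 18
AGE_MAX = 89
WORKPLACE_CATEGORIES = ("<10", "<50", "<250", "250+")

#: Default relationship influence strengths per (relationship, behaviour),
#: as (level0, level1, level2).  These are the calibrated values shipped as
#: the model's defaults; workplace strengths default to zero and are only
#: activated by interventions.
DEFAULT_INFLUENCE = {
    ("marriage", "smoking"): (0.554, 0.691, 0.635),
    ("marriage", "alcohol"): (0.316, 0.525, 0.755),
    ("marriage", "diet"): (0.331, 0.659, 0.773),
    ("marriage", "inactivity"): (0.472, 0.959, 0.255),
    ("household", "smoking"): (0.193, 0.099, 0.497),
    ("household", "alcohol"): (0.252, 0.46, 0.785),
    ("household", "diet"): (0.266, 0.192, 0.522),
    ("household", "inactivity"): (0.037, 0.589, 0.373),
    ("friendship", "smoking"): (0.276, 0.104, 0.359),
    ("friendship", "alcohol"): (0.229, 0.371, 0.749),
    ("friendship", "diet"): (0.169, 0.53, 0.594),
    ("friendship", "inactivity"): (0.124, 0.487, 0.496),
}

#: Observed fatal-CVD incidence rates per 1,000 person-years by five-year
#: age group and sex, from the QRISK derivation cohort (Hippisley-Cox et
#: al.).  Used as the calibration reference.
OBSERVED_RATES = {
    "25-29": (0.24, 0.40),
    "30-34": (0.49, 0.99),
    "35-39": (1.02, 2.12),
    "40-44": (1.90, 3.99),
    "45-49": (3.20, 6.65),
    "50-54": (4.83, 9.86),
    "55-59": (7.47, 14.18),
    "60-64": (11.36, 19.69),
    "65-69": (17.13, 26.55),
    "70-74": (25.08, 35.48),
    "75-79": (35.11, 45.16),
    "80-84": (48.02, 58.29),
}

AGE_GROUPS = tuple(OBSERVED_RATES)

_PROB_TOL = 1e-9


class ConfigurationError(Exception):
    """A parameter directory or value cannot configure a simulation."""


class ValidationError(Exception):
    """A parameter set violates its invariants."""

    def __init__(self, issues: list[str]):
        self.issues = issues
        super().__init__("invalid parameter set:\n  " + "\n  ".join(issues))


class InfluenceMatrix:
    """Strengths in [0, 1] indexed by (relationship, behaviour, level).

    Marriage, household and friendship rows carry the 36 free strengths;
    the workplace row defaults to zero and is excluded from calibration.
    """

    shape = (len(RELATIONSHIPS), len(BEHAVIOURS), len(LEVELS))

    def __init__(self, data: np.ndarray | None = None):
        if data is None:
            data = np.zeros(self.shape)
        data = np.asarray(data, dtype=float)
        if data.shape != self.shape:
            raise ValueError(f"expected shape {self.shape}, got {data.shape}")
        self.data = data

    @classmethod
    def from_dict(cls, strengths: Mapping[tuple[str, str], Iterable[float]]) -> "InfluenceMatrix":
        m = cls()
        for (rel, beh), levels in strengths.items():
            m.data[RELATIONSHIPS.index(rel), BEHAVIOURS.index(beh), :] = list(levels)
        return m

    @classmethod
    def default(cls) -> "InfluenceMatrix":
        return cls.from_dict(DEFAULT_INFLUENCE)

    def strength(self, relationship: str, behaviour: str, level: int) -> float:
        return float(
            self.data[RELATIONSHIPS.index(relationship), BEHAVIOURS.index(behaviour), level]
        )

    def set_strength(self, relationship: str, behaviour: str, level: int, value: float) -> None:
        self.data[RELATIONSHIPS.index(relationship), BEHAVIOURS.index(behaviour), level] = value

    @property
    def free_vector(self) -> np.ndarray:
        """The 36 non-workplace strengths, flattened (rel-major)."""
        return self.data[:3].ravel().copy()

    @classmethod
    def from_free_vector(cls, vec: np.ndarray) -> "InfluenceMatrix":
        vec = np.asarray(vec, dtype=float)
        if vec.size != 36:
            raise ValueError("free vector must have 36 entries")
        m = cls()
        m.data[:3] = vec.reshape(3, len(BEHAVIOURS), len(LEVELS))
        return m

    def copy(self) -> "InfluenceMatrix":
        return InfluenceMatrix(self.data.copy())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, rel in enumerate(RELATIONSHIPS):
            for b, beh in enumerate(BEHAVIOURS):
                rows.append(
                    {
                        "relationship": rel,
                        "behaviour": beh,
                        "level0": self.data[r, b, 0],
                        "level1": self.data[r, b, 1],
                        "level2": self.data[r, b, 2],
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "InfluenceMatrix":
        m = cls()
        for _, row in df.iterrows():
            r = RELATIONSHIPS.index(row["relationship"])
            b = BEHAVIOURS.index(row["behaviour"])
            m.data[r, b, :] = [row["level0"], row["level1"], row["level2"]]
        return m

    def __eq__(self, other) -> bool:
        return isinstance(other, InfluenceMatrix) and np.array_equal(self.data, other.data)


@dataclass
class ParameterSet:
    """All distributions and coefficients driving one simulation."""

    age_sex: pd.DataFrame          # age, sex, probability (joint, sums to 1)
    marriage: pd.DataFrame         # age, sex, probability (of being married)
    spouse: pd.DataFrame           # proband_age, proband_sex, spouse_age, spouse_sex, probability
    household_size: pd.DataFrame   # size, probability (adult household sizes >= 1)
    imd: pd.DataFrame              # age, sex, decile, probability (sums to 1 per age/sex)
    employment: pd.DataFrame       # age, sex, decile, probability (Bernoulli)
    workplace: pd.DataFrame        # category, probability, contact_mean
    prevalence: pd.DataFrame       # behaviour, age, sex, level, probability
    multipliers: pd.DataFrame      # behaviour, level, age_lo, age_hi, sex, multiplier
    baseline_risk: pd.DataFrame    # sex, term, coefficient (terms: s0, intercept,
                                   #   age_centered = age - 60, age_centered_sq = (age-60)^2/100)
    influence: InfluenceMatrix = field(default_factory=InfluenceMatrix.default)
    observed_rates: pd.DataFrame | None = None  # age_group, sex, rate

    same_sex_marriage_fraction: float = 0.01
    threshold_mean: float = 0.8
    threshold_sd: float = 0.05
    friendship_generator: str = "NWS"
    friendship_mean_degree: float = 6.0
    friendship_exclusion_fraction: float = 0.07
    nws_shortcut_probability: float = 0.01
    contact_group_sd: float | None = None  # None -> mean/4 per category

    def copy(self) -> "ParameterSet":
        kwargs = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, pd.DataFrame):
                v = v.copy()
            elif isinstance(v, InfluenceMatrix):
                v = v.copy()
            kwargs[f.name] = v
        return ParameterSet(**kwargs)


_FILES = {
    "age_sex": "age_sex.csv",
    "marriage": "marriage.csv",
    "spouse": "spouse.csv",
    "household_size": "household_size.csv",
    "imd": "imd.csv",
    "employment": "employment.csv",
    "workplace": "workplace.csv",
    "prevalence": "prevalence.csv",
    "multipliers": "multipliers.csv",
    "baseline_risk": "baseline_risk.csv",
}

_SCALAR_KEYS = (
    "same_sex_marriage_fraction",
    "threshold_mean",
    "threshold_sd",
    "friendship_generator",
    "friendship_mean_degree",
    "friendship_exclusion_fraction",
    "nws_shortcut_probability",
    "contact_group_sd",
)

_SORT_KEYS = {
    "age_sex": ["age", "sex"],
    "marriage": ["age", "sex"],
    "spouse": ["proband_age", "proband_sex", "spouse_age", "spouse_sex"],
    "household_size": ["size"],
    "imd": ["age", "sex", "decile"],
    "employment": ["age", "sex", "decile"],
    "workplace": [],
    "prevalence": ["behaviour", "age", "sex", "level"],
    "multipliers": ["behaviour", "level", "age_lo", "sex"],
    "baseline_risk": ["sex", "term"],
}


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    # default float formatting is shortest round-trip repr, i.e. exact reload
    buf = io.StringIO()
    df.to_csv(buf, index=False, lineterminator="\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def write_parameter_set(params: ParameterSet, directory: str | os.PathLike) -> None:
    """Write a parameter set to a directory of CSV files (deterministic layout)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, fname in _FILES.items():
        df = getattr(params, name)
        keys = _SORT_KEYS[name]
        if keys:
            df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)
        _write_csv(df, directory / fname)
    _write_csv(params.influence.to_frame(), directory / "influence.csv")
    if params.observed_rates is not None:
        _write_csv(params.observed_rates, directory / "observed_rates.csv")
    cfg = pd.DataFrame(
        {"key": list(_SCALAR_KEYS), "value": [getattr(params, k) for k in _SCALAR_KEYS]}
    )
    _write_csv(cfg, directory / "config.csv")


def load_parameter_set(directory: str | os.PathLike) -> ParameterSet:
    """Load and validate a parameter set from a CSV directory.

    Missing optional files fall back to defaults: an ``influence.csv``
    without a workplace row (or absent entirely) yields zero workplace
    strengths; ``observed_rates.csv`` and ``config.csv`` are optional.
    """
    directory = Path(directory)
    frames = {}
    for name, fname in _FILES.items():
        path = directory / fname
        if not path.exists():
            raise ConfigurationError(f"missing mandatory parameter file: {fname}")
        frames[name] = pd.read_csv(path)

    infl_path = directory / "influence.csv"
    if infl_path.exists():
        influence = InfluenceMatrix.from_frame(pd.read_csv(infl_path))
    else:
        influence = InfluenceMatrix()  # all zeros

    obs_path = directory / "observed_rates.csv"
    observed = pd.read_csv(obs_path) if obs_path.exists() else None

    scalars: dict[str, object] = {}
    cfg_path = directory / "config.csv"
    if cfg_path.exists():
        cfg = pd.read_csv(cfg_path)
        for _, row in cfg.iterrows():
            key = row["key"]
            if key not in _SCALAR_KEYS:
                raise ConfigurationError(f"unknown config key in config.csv: {key}")
            val = row["value"]
            if key == "friendship_generator":
                scalars[key] = str(val)
            elif key == "contact_group_sd":
                scalars[key] = None if pd.isna(val) else float(val)
            else:
                scalars[key] = float(val)

    params = ParameterSet(influence=influence, observed_rates=observed, **frames, **scalars)
    issues = validate_parameter_set(params)
    if issues:
        raise ValidationError(issues)
    return params


def _check_dist(df: pd.DataFrame, group: list[str], name: str, issues: list[str]) -> None:
    if group:
        sums = df.groupby(group)["probability"].sum()
        bad = sums[(sums - 1.0).abs() > _PROB_TOL]
        for idx, s in bad.items():
            issues.append(f"{name}: distribution over cell {idx} sums to {s:.12g}, not 1")
    else:
        s = df["probability"].sum()
        if abs(s - 1.0) > _PROB_TOL:
            issues.append(f"{name}: distribution sums to {s:.12g}, not 1")
    if (df["probability"] < 0).any():
        issues.append(f"{name}: negative probability entries")


def validate_parameter_set(params: ParameterSet) -> list[str]:
    """Return a list of invariant violations (empty list means valid)."""
    issues: list[str] = []

    for df_name, age_col in (("age_sex", "age"), ("marriage", "age"),
                             ("imd", "age"), ("employment", "age")):
        df = getattr(params, df_name)
        ages = df[age_col]
        if ages.min() < AGE_MIN or ages.max() > AGE_MAX:
            issues.append(f"{df_name}: ages outside [{AGE_MIN}, {AGE_MAX}]")

    _check_dist(params.age_sex, [], "age_sex", issues)
    _check_dist(params.spouse, ["proband_age", "proband_sex"], "spouse", issues)
    _check_dist(params.household_size, [], "household_size", issues)
    _check_dist(params.imd, ["age", "sex"], "imd", issues)
    _check_dist(params.workplace, [], "workplace", issues)
    _check_dist(params.prevalence, ["behaviour", "age", "sex"], "prevalence", issues)

    for df_name in ("marriage", "employment"):
        p = getattr(params, df_name)["probability"]
        if (p < 0).any() or (p > 1).any():
            issues.append(f"{df_name}: probabilities outside [0, 1]")

    if (params.household_size["size"] < 1).any():
        issues.append("household_size: sizes below 1")
    if not params.imd["decile"].isin(range(1, 11)).all():
        issues.append("imd: deciles outside 1-10")
    if (params.workplace["contact_mean"] <= 0).any():
        issues.append("workplace: non-positive contact_mean")

    bad = params.multipliers[params.multipliers["multiplier"] <= 0]
    for _, row in bad.iterrows():
        issues.append(
            "multipliers: non-positive multiplier for "
            f"({row['behaviour']}, level {row['level']}, "
            f"ages [{row['age_lo']}, {row['age_hi']}), {row['sex']})"
        )

    d = params.influence.data
    if (d < 0).any() or (d > 1).any():
        locs = np.argwhere((d < 0) | (d > 1))
        for r, b, l in locs:
            issues.append(
                f"influence: strength {d[r, b, l]:.6g} for "
                f"({RELATIONSHIPS[r]}, {BEHAVIOURS[b]}, level {l}) outside [0, 1]"
            )

    for sex in SEXES:
        sub = params.baseline_risk[params.baseline_risk["sex"] == sex]
        terms = set(sub["term"])
        if "s0" not in terms:
            issues.append(f"baseline_risk: missing s0 term for {sex}")
        else:
            s0 = float(sub[sub["term"] == "s0"]["coefficient"].iloc[0])
            if not (0 < s0 <= 1):
                issues.append(f"baseline_risk: s0 for {sex} outside (0, 1]")

    if params.threshold_sd <= 0:
        issues.append("config: threshold_sd must be > 0")
    if not (0 <= params.same_sex_marriage_fraction <= 1):
        issues.append("config: same_sex_marriage_fraction outside [0, 1]")
    if not (0 <= params.friendship_exclusion_fraction <= 1):
        issues.append("config: friendship_exclusion_fraction outside [0, 1]")
    if params.friendship_generator not in ("NWS", "BA"):
        issues.append("config: friendship_generator must be NWS or BA")

    if params.observed_rates is not None and (params.observed_rates["rate"] < 0).any():
        issues.append("observed_rates: negative rates")

    return issues


# ---------------------------------------------------------------------------
# Synthetic fixture generation
# ---------------------------------------------------------------------------

_OVERRIDE_KEYS = _SCALAR_KEYS + (
    "marriage_probability",      # scalar replacing the whole marriage table
    "household_size_distribution",  # dict size -> probability
    "employment_probability",    # scalar replacing the whole employment table
    "contact_mean",              # scalar contact-group mean for all categories
    "influence",                 # InfluenceMatrix replacing the default
)

_AGES = np.arange(AGE_MIN, AGE_MAX + 1)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _fixture_prevalence(rng: np.random.Generator) -> pd.DataFrame:
    """Plausible behaviour-level prevalence by (behaviour, age, sex).

    Shapes emulate broad English patterns: never-smoking declines with age
    while ex-smoking rises; heavy drinking is more common in men; poor diet
    and inactivity worsen with age.  A small seeded jitter varies the mix.
    """
    rows = []
    a = (_AGES - AGE_MIN) / (AGE_MAX - AGE_MIN)  # 0..1
    for sex_i, sex in enumerate(SEXES):
        jit = {b: rng.uniform(-0.02, 0.02, size=3) for b in BEHAVIOURS}
        male = sex_i  # 0 female, 1 male
        weights = {
            "smoking": np.stack(
                [0.75 - 0.35 * a, 0.05 + 0.38 * a, 0.20 - 0.03 * a + 0.04 * male], axis=1
            ),
            "alcohol": np.stack(
                [0.72 + 0.08 * a - 0.06 * male,
                 0.22 - 0.05 * a + 0.03 * male,
                 0.06 - 0.03 * a + 0.03 * male], axis=1
            ),
            "diet": np.stack(
                [0.22 + 0.10 * a - 0.04 * male,
                 0.56 + 0.0 * a,
                 0.22 - 0.10 * a + 0.04 * male], axis=1
            ),
            "inactivity": np.stack(
                [0.62 - 0.25 * a, 0.23 + 0.08 * a, 0.15 + 0.17 * a], axis=1
            ),
        }
        for beh in BEHAVIOURS:
            w = np.clip(weights[beh] + jit[beh][None, :], 0.01, None)
            w /= w.sum(axis=1, keepdims=True)
            for i, age in enumerate(_AGES):
                for lvl in LEVELS:
                    rows.append(
                        {"behaviour": beh, "age": age, "sex": sex,
                         "level": lvl, "probability": w[i, lvl]}
                    )
    return pd.DataFrame(rows)


def _fixture_multipliers() -> pd.DataFrame:
    bands = ((25, 45), (45, 65), (65, 85))
    # level-2 relative risks shrink with age, as published behaviour-specific
    # relative risks for CVD do
    level12 = {
        "smoking": ((1.25, 1.18, 1.10), (2.20, 1.80, 1.45)),
        "alcohol": ((1.05, 1.04, 1.03), (1.35, 1.25, 1.15)),
        "diet": ((1.10, 1.08, 1.05), (1.45, 1.30, 1.20)),
        "inactivity": ((1.15, 1.10, 1.08), (1.55, 1.40, 1.25)),
    }
    rows = []
    for beh in BEHAVIOURS:
        for lvl in LEVELS:
            for bi, (lo, hi) in enumerate(bands):
                for sex in SEXES:
                    if lvl == 0:
                        m = 1.0
                    else:
                        m = level12[beh][lvl - 1][bi]
                    rows.append(
                        {"behaviour": beh, "level": lvl, "age_lo": lo,
                         "age_hi": hi, "sex": sex, "multiplier": m}
                    )
    return pd.DataFrame(rows)


def generate_fixture_parameters(
    seed: int = 0,
    overrides: Mapping[str, object] | None = None,
    directory: str | os.PathLike | None = None,
) -> ParameterSet:
    """Generate a complete synthetic parameter set (pure function of inputs).

    The fixture emulates broad English demographic shapes -- a declining
    adult age pyramid, marriage probability rising through the thirties,
    UK-like household sizes -- without transcribing any real dataset.
    ``overrides`` may replace the scalar configuration values or a few
    whole-table defaults; ``directory``, if given, also writes the CSVs.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - set(_OVERRIDE_KEYS)
    if unknown:
        raise ValueError(
            f"unknown override keys {sorted(unknown)}; valid keys: {sorted(_OVERRIDE_KEYS)}"
        )
    rng = np.random.default_rng(seed)

    # age/sex joint distribution: gently declining pyramid, near-even sexes
    slope = 0.008 + rng.uniform(-0.001, 0.001)
    age_w = np.clip(1.2 - slope * (_AGES - AGE_MIN) ** 1.05, 0.2, None)
    sex_share = {"female": 0.505, "male": 0.495}
    rows = [
        {"age": int(age), "sex": sex, "probability": age_w[i] * sex_share[sex]}
        for i, age in enumerate(_AGES) for sex in SEXES
    ]
    age_sex = pd.DataFrame(rows)
    age_sex["probability"] /= age_sex["probability"].sum()

    # marriage probability rising with age, slightly later for men
    if "marriage_probability" in overrides:
        p_scalar = float(overrides.pop("marriage_probability"))
        marriage = pd.DataFrame(
            [{"age": int(a), "sex": s, "probability": p_scalar} for a in _AGES for s in SEXES]
        )
    else:
        rows = []
        for sex in SEXES:
            centre = 31.0 + (2.0 if sex == "male" else 0.0)
            p = 0.72 * _sigmoid((_AGES - centre) / 4.5)
            rows += [
                {"age": int(a), "sex": sex, "probability": float(p[i])}
                for i, a in enumerate(_AGES)
            ]
        marriage = pd.DataFrame(rows)

    # spouse (age, sex) conditional on proband: Gaussian age assortativity
    # with a +/-2-year mean offset by spouse sex
    rows = []
    for p_age in _AGES:
        lo, hi = max(AGE_MIN, p_age - 12), min(AGE_MAX, p_age + 12)
        s_ages = np.arange(lo, hi + 1)
        for p_sex in SEXES:
            for s_sex in SEXES:
                mu = p_age + (2.0 if s_sex == "male" else -2.0)
                w = np.exp(-0.5 * ((s_ages - mu) / 3.5) ** 2)
                w /= w.sum()
                for j, s_age in enumerate(s_ages):
                    rows.append(
                        {"proband_age": int(p_age), "proband_sex": p_sex,
                         "spouse_age": int(s_age), "spouse_sex": s_sex,
                         "probability": float(w[j]), "_same": int(s_sex == p_sex)}
                    )
    spouse = pd.DataFrame(rows)
    f_same = float(overrides.get("same_sex_marriage_fraction", 0.01))
    spouse["probability"] *= np.where(spouse["_same"] == 1, f_same, 1.0 - f_same)
    spouse = spouse.drop(columns="_same")

    hh = overrides.pop("household_size_distribution", None)
    if hh is None:
        hh = {1: 0.30, 2: 0.40, 3: 0.17, 4: 0.09, 5: 0.03, 6: 0.01}
    household_size = pd.DataFrame(
        [{"size": int(k), "probability": float(v)} for k, v in sorted(hh.items())]
    )

    # IMD deciles: near-uniform with a mild age tilt
    rows = []
    for age in _AGES:
        for sex in SEXES:
            d = np.arange(1, 11)
            w = 1.0 + 0.015 * (d - 5.5) * ((age - 50) / 35.0)
            w /= w.sum()
            rows += [
                {"age": int(age), "sex": sex, "decile": int(d[i]), "probability": float(w[i])}
                for i in range(10)
            ]
    imd = pd.DataFrame(rows)

    # employment probability by (age, sex, decile)
    if "employment_probability" in overrides:
        e_scalar = float(overrides.pop("employment_probability"))
        employment = pd.DataFrame(
            [{"age": int(a), "sex": s, "decile": d, "probability": e_scalar}
             for a in _AGES for s in SEXES for d in range(1, 11)]
        )
    else:
        rows = []
        base = 0.84 * _sigmoid((_AGES - 17.5) / 1.5) * (1 - _sigmoid((_AGES - 64.5) / 1.5)) + 0.03
        for sex in SEXES:
            sex_f = 1.04 if sex == "male" else 1.0
            for d in range(1, 11):
                dec_f = 0.85 + 0.03 * (d - 1)
                p = np.clip(base * sex_f * dec_f, 0.0, 0.97)
                rows += [
                    {"age": int(a), "sex": sex, "decile": d, "probability": float(p[i])}
                    for i, a in enumerate(_AGES)
                ]
        employment = pd.DataFrame(rows)

    cm = overrides.pop("contact_mean", None)
    means = [cm] * 4 if cm is not None else [4.0, 8.0, 15.0, 21.0]
    workplace = pd.DataFrame(
        {
            "category": list(WORKPLACE_CATEGORIES),
            "probability": [0.2, 0.3, 0.3, 0.2],
            "contact_mean": [float(m) for m in means],
        }
    )

    prevalence = _fixture_prevalence(rng)
    multipliers = _fixture_multipliers()

    # simplified ten-year baseline risk: risk = 1 - s0 ** exp(lp),
    # lp = intercept + c_age * (age - 60) + c_age2 * (age - 60)^2 / 100
    baseline_risk = pd.DataFrame(
        [
            {"sex": "female", "term": "s0", "coefficient": 0.93},
            {"sex": "female", "term": "intercept", "coefficient": 0.0},
            {"sex": "female", "term": "age_centered", "coefficient": 0.089},
            {"sex": "female", "term": "age_centered_sq", "coefficient": 0.0},
            {"sex": "male", "term": "s0", "coefficient": 0.88},
            {"sex": "male", "term": "intercept", "coefficient": 0.05},
            {"sex": "male", "term": "age_centered", "coefficient": 0.091},
            {"sex": "male", "term": "age_centered_sq", "coefficient": 0.0},
        ]
    )

    influence = overrides.pop("influence", None)
    if influence is None:
        influence = InfluenceMatrix.default()
    elif not isinstance(influence, InfluenceMatrix):
        raise ValueError("influence override must be an InfluenceMatrix")

    observed = pd.DataFrame(
        [
            {"age_group": g, "sex": sex, "rate": OBSERVED_RATES[g][i]}
            for g in AGE_GROUPS for i, sex in enumerate(SEXES)
        ]
    )

    scalar_overrides = {k: overrides[k] for k in _SCALAR_KEYS if k in overrides}
    params = ParameterSet(
        age_sex=age_sex,
        marriage=marriage,
        spouse=spouse,
        household_size=household_size,
        imd=imd,
        employment=employment,
        workplace=workplace,
        prevalence=prevalence,
        multipliers=multipliers,
        baseline_risk=baseline_risk,
        influence=influence,
        observed_rates=observed,
        **scalar_overrides,
    )
    if directory is not None:
        write_parameter_set(params, directory)
    return params
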