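"""Synthetic age- and sex-specific epidemiological tables.

Provides the two rate tables the cohort engine consumes -- annual background
mortality probabilities and annual gastric-cancer incidence rates per
100,000 -- together with a CSV loader/writer and the starting-age
distribution of the target population (ages 50-69, both sexes).

The generators are deliberately minimal: a Gompertz-Makeham life table and
an exponential-in-age incidence curve. Any CSV with columns ``age,sex,value``
can override them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "SEXES",
    "RateTable",
    "PopulationWeights",
    "generate_life_table",
    "generate_incidence_table",
    "read_rate_table",
    "write_rate_table",
    "expand_age_bands",
    "default_population_weights",
    "MAKEHAM_DEFAULTS",
    "INCIDENCE_DEFAULTS",
    "INCIDENCE_CAP_PER_100K",
]

SEXES = ("male", "female")

#: Gompertz-Makeham (a, b, c) per sex; chosen to give a life expectancy in
#: the mid-80s with female mortality below male at every age.
MAKEHAM_DEFAULTS = {
    "male": (0.0005, 3.0e-5, 0.095),
    "female": (0.0004, 2.0e-5, 0.095),
}

#: (base rate per 100,000 at age 50, annual relative growth) per sex.
#: Male incidence is twice female incidence at the default settings; the
#: level is chosen to land in the intermediate-risk band where focused
#: surveillance of premalignancy carriers is worthwhile but mass screening
#: is borderline.
INCIDENCE_DEFAULTS = {
    "male": (80.0, 0.08),
    "female": (40.0, 0.08),
}

INCIDENCE_CAP_PER_100K = 2000.0


@dataclass
class RateTable:
    """Age x sex annual rates.

    ``kind`` is either ``"mortality"`` (values are annual probabilities in
    [0, 1]) or ``"incidence"`` (values are annual rates per 100,000,
    non-negative). Entries are keyed by ``(age, sex)``.
    """

    kind: str
    entries: dict[tuple[int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("mortality", "incidence"):
            raise ValueError(f"unknown rate-table kind {self.kind!r}")

    def value(self, age: int, sex: str) -> float:
        try:
            return self.entries[(age, sex)]
        except KeyError:
            raise KeyError(
                f"{self.kind} table has no entry for age={age}, sex={sex!r}"
            ) from None

    def annual_probability(self, age: int, sex: str) -> float:
        """Value converted to an annual probability (incidence / 100,000)."""
        v = self.value(age, sex)
        return v if self.kind == "mortality" else v / 100_000.0

    def ages(self, sex: str) -> list[int]:
        return sorted(a for a, s in self.entries if s == sex)

    def max_age(self, sex: str) -> int:
        ages = self.ages(sex)
        if not ages:
            raise ValueError(f"no entries for sex {sex!r}")
        return ages[-1]

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        for (age, sex), v in self.entries.items():
            if not math.isfinite(v):
                problems.append(f"({age},{sex}): non-finite value {v}")
            elif self.kind == "mortality" and not 0.0 <= v <= 1.0:
                problems.append(f"({age},{sex}): probability {v} outside [0,1]")
            elif self.kind == "incidence" and v < 0.0:
                problems.append(f"({age},{sex}): negative rate {v}")
            if sex not in SEXES:
                problems.append(f"({age},{sex}): unknown sex {sex!r}")
        for sex in SEXES:
            ages = self.ages(sex)
            if ages and ages != list(range(ages[0], ages[-1] + 1)):
                problems.append(f"ages not contiguous for sex {sex!r}")
        return problems

    def update(self, other: "RateTable") -> "RateTable":
        if other.kind != self.kind:
            raise ValueError("cannot merge tables of different kinds")
        merged = dict(self.entries)
        merged.update(other.entries)
        return RateTable(self.kind, merged)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"age": age, "sex": sex, "value": v}
            for (age, sex), v in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["age", "sex", "value"])


def generate_life_table(
    sex: str,
    makeham_a: float | None = None,
    makeham_b: float | None = None,
    makeham_c: float | None = None,
    max_age: int = 110,
    seed: int | None = None,  # reserved; generation is deterministic
) -> RateTable:
    """Gompertz-Makeham annual death probabilities.

    q(age) = 1 - exp(-(a + b * exp(c * age))), clamped to [0, 1].
    """
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}")
    defaults = MAKEHAM_DEFAULTS[sex]
    a = defaults[0] if makeham_a is None else makeham_a
    b = defaults[1] if makeham_b is None else makeham_b
    c = defaults[2] if makeham_c is None else makeham_c
    for name, v in (("makeham_a", a), ("makeham_b", b), ("makeham_c", c)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    if c < 0 and b != 0:
        raise ValueError("makeham_c < 0 yields a decreasing hazard; rejected")
    if max_age > 110:
        raise ValueError("max_age must be <= 110")
    entries: dict[tuple[int, str], float] = {}
    for age in range(0, max_age + 1):
        q = 1.0 - math.exp(-(a + b * math.exp(c * age)))
        q = min(max(q, 0.0), 1.0)
        if q >= 1.0 and age < 60:
            raise ValueError(
                f"implausible parameters: q(age={age}) >= 1 before age 60"
            )
        entries[(age, sex)] = q
    return RateTable("mortality", entries)


def generate_incidence_table(
    sex: str,
    base_rate_per100k_at50: float | None = None,
    annual_growth: float | None = None,
    max_age: int = 110,
) -> RateTable:
    """Exponential-in-age incidence, per 100,000, capped at 2,000/100k.

    I(age) = base * (1 + growth) ** (age - 50); ages below 50 carry the
    (small) extrapolated value.
    """
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}")
    defaults = INCIDENCE_DEFAULTS[sex]
    base = defaults[0] if base_rate_per100k_at50 is None else base_rate_per100k_at50
    growth = defaults[1] if annual_growth is None else annual_growth
    if base < 0:
        raise ValueError(f"base rate must be >= 0, got {base}")
    if growth < 0:
        raise ValueError(f"annual growth must be >= 0, got {growth}")
    entries = {
        (age, sex): min(base * (1.0 + growth) ** (age - 50), INCIDENCE_CAP_PER_100K)
        for age in range(0, max_age + 1)
    }
    return RateTable("incidence", entries)


def read_rate_table(path: str | Path, kind: str) -> RateTable:
    """Load a rate table from a CSV with columns ``age,sex,value``."""
    df = pd.read_csv(path)
    missing = {"age", "sex", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"rate-table CSV missing columns: {sorted(missing)}")
    if df.duplicated(subset=["age", "sex"]).any():
        dupes = df[df.duplicated(subset=["age", "sex"])][["age", "sex"]]
        first = dupes.iloc[0]
        raise ValueError(
            f"duplicate (age, sex) rows, e.g. ({first['age']}, {first['sex']})"
        )
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        bad = df.loc[values.isna(), "value"].iloc[0]
        raise ValueError(f"non-numeric value in rate-table CSV: {bad!r}")
    entries = {
        (int(age), str(sex)): float(v)
        for age, sex, v in zip(df["age"], df["sex"], values)
    }
    table = RateTable(kind, entries)
    problems = table.validate()
    if problems:
        raise ValueError("invalid rate table: " + "; ".join(problems))
    return table


def write_rate_table(table: RateTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False, float_format="%.12g")


def expand_age_bands(df: pd.DataFrame) -> pd.DataFrame:
    """Expand banded rows (age_start, age_end, sex, value) to per-year rows.

    Every year inside a band receives the band's value. Helper for sources
    that publish 5-year bands rather than single-year ages.
    """
    missing = {"age_start", "age_end", "sex", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"banded table missing columns: {sorted(missing)}")
    rows = []
    for rec in df.itertuples(index=False):
        if rec.age_end < rec.age_start:
            raise ValueError(f"band end {rec.age_end} < start {rec.age_start}")
        for age in range(int(rec.age_start), int(rec.age_end) + 1):
            rows.append({"age": age, "sex": rec.sex, "value": float(rec.value)})
    out = pd.DataFrame(rows, columns=["age", "sex", "value"])
    if out.duplicated(subset=["age", "sex"]).any():
        raise ValueError("overlapping age bands")
    return out


@dataclass
class PopulationWeights:
    """Proportions over (starting age, sex) cells of the target population."""

    weights: dict[tuple[int, str], float]

    def __post_init__(self) -> None:
        for (age, sex), w in self.weights.items():
            if sex not in SEXES:
                raise ValueError(f"unknown sex {sex!r}")
            if w < 0:
                raise ValueError(f"negative weight for ({age}, {sex}): {w}")
        total = sum(self.weights.values())
        if total <= 0:
            raise ValueError("weights must have positive total")
        # renormalize so user edits keep the sum-to-one invariant
        self.weights = {k: w / total for k, w in self.weights.items()}

    def items(self):
        return sorted(self.weights.items())

    def restrict(self, keys) -> "PopulationWeights":
        keys = set(keys)
        sub = {k: w for k, w in self.weights.items() if k in keys}
        if not sub:
            raise ValueError("restriction leaves no population cells")
        return PopulationWeights(sub)


def default_population_weights(
    age_min: int = 50, age_max: int = 69
) -> PopulationWeights:
    """Uniform starting-age distribution over ages x sexes."""
    n = (age_max - age_min + 1) * len(SEXES)
    return PopulationWeights(
        {
            (age, sex): 1.0 / n
            for age in range(age_min, age_max + 1)
            for sex in SEXES
        }
    )
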