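"""Background mortality from an age-indexed life table.

Mortality is treatment-independent: the disease is not life-threatening, so
both arms share one survival curve. Annual death probabilities (qx) are
converted to the model's sub-annual cycle assuming a constant hazard within
each year of age, and looked up at the floor of the cohort's current age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LifeTable:
    """Contiguous ages with annual death probabilities; closed at ``max_age``."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or ages.size == 0 or ages.size != qx.size:
            raise ValueError("life table needs matching 1-d age and qx columns")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("life table ages must be contiguous with step 1")
        if np.any((qx < 0) | (qx > 1)):
            raise ValueError("life table qx values must lie in [0, 1]")
        if qx[-1] != 1.0:
            raise ValueError("life table must close with qx = 1 at max_age")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def annual_q(self, age: float) -> float:
        """Annual death probability at floor(age); 1 at or beyond max_age."""
        if age >= self.max_age:
            return 1.0
        idx = math.floor(age) - self.min_age
        if idx < 0:
            raise ValueError(f"age {age} below life-table minimum {self.min_age}")
        return float(self.qx[idx])


def annual_mortality(lt: LifeTable, age: float) -> float:
    return lt.annual_q(age)


def per_cycle_probability(annual_p: float, cycle_years: float) -> float:
    """Convert an annual probability to a shorter cycle (constant hazard)."""
    if not 0.0 <= annual_p <= 1.0:
        raise ValueError(f"annual probability {annual_p} outside [0, 1]")
    if cycle_years <= 0:
        raise ValueError("cycle length must be positive")
    return 1.0 - (1.0 - annual_p) ** cycle_years


def life_expectancy(lt: LifeTable, start_age: float,
                    cycle_length_years: float = 0.5,
                    timing: str = "mid") -> float:
    """Undiscounted expected years lived from ``start_age``.

    Computed on the model's own cycle grid with half-cycle-corrected
    accrual (``timing="mid"``); ``"begin"``/``"end"`` accrue full cycles at
    the start-of-cycle / end-of-cycle survivor share and exist to bracket
    the half-cycle-corrected value.
    """
    alive = 1.0
    total = 0.0
    t = 0.0
    while alive > 1e-15:
        age = start_age + t
        d = per_cycle_probability(lt.annual_q(age), cycle_length_years)
        alive_end = alive * (1.0 - d)
        if timing == "mid":
            w = 0.5 * (alive + alive_end)
        elif timing == "begin":
            w = alive
        elif timing == "end":
            w = alive_end
        else:
            raise ValueError(f"unknown accrual timing: {timing}")
        total += w * cycle_length_years
        alive = alive_end
        t += cycle_length_years
        if age >= lt.max_age:
            break
    return total


def load_life_table(path: str | Path) -> LifeTable:
    """Read a two-column (age, qx) delimited text file; header optional.

    The terminal row is forced closed (qx = 1) so the cohort cannot outlive
    the table.
    """
    path = Path(path)
    first = path.open().readline()
    header: int | None = 0
    token = first.split(",")[0].split()[0] if first.strip() else ""
    try:
        float(token)
        header = None
    except ValueError:
        header = 0
    df = pd.read_csv(path, sep=None, engine="python", header=header)
    if df.shape[1] < 2:
        raise ValueError(f"life table {path} must have age and qx columns")
    ages = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(ages != np.floor(ages)):
        raise ValueError("life table ages must be integers")
    qx = df.iloc[:, 1].to_numpy(dtype=float).copy()
    qx[-1] = 1.0
    return LifeTable(ages=ages.astype(int), qx=qx)


def save_life_table(lt: LifeTable, path: str | Path) -> None:
    pd.DataFrame({"age": lt.ages, "qx": lt.qx}).to_csv(path, index=False)
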