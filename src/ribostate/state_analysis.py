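"""Open/middle/closed conformational states and summary statistics.

The aptamer's junction geometry is reduced to a single mass-center
distance (D1).  Frames with D1 above the open threshold are labelled
``open``, below the closed threshold ``closed``, and ``middle`` in
between; both comparisons are strict, so a frame exactly at a threshold
is ``middle``.  Thresholds can be configured directly or derived as
trailing-window means of a ligand-bound series (closed bound) and an
apo series (open bound).

Also houses the small statistics used to connect geometry, energetics
and experiment: Pearson correlation, the coefficient of determination
r^2, and the dissociation-constant conversion dG_exp = RT ln Kd
(equivalently -RT ln Ka; negative for sub-molar Kd).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "R_KCAL",
    "OPEN",
    "MIDDLE",
    "CLOSED",
    "StateThresholds",
    "StateSeries",
    "AffinityRecord",
    "derive_thresholds",
    "classify_states",
    "state_percentages",
    "pearson_r",
    "coefficient_of_determination",
    "kd_to_dg",
]

#: gas constant, kcal/(mol*K)
R_KCAL = 0.0019872

OPEN = "open"
MIDDLE = "middle"
CLOSED = "closed"


@dataclass(frozen=True)
class StateThresholds:
    """Distance thresholds (A) separating the three states.

    ``closed_max``: frames strictly below it are closed.
    ``open_min``: frames strictly above it are open.
    """

    closed_max: float
    open_min: float
    source: str = "configured"  # or "derived"

    def __post_init__(self) -> None:
        if not self.closed_max < self.open_min:
            raise ValueError(
                f"closed_max ({self.closed_max}) must be < open_min ({self.open_min})"
            )


@dataclass
class StateSeries:
    labels: np.ndarray  # dtype=object/str, per frame
    thresholds: StateThresholds
    pct_open: float = field(init=False)
    pct_middle: float = field(init=False)
    pct_closed: float = field(init=False)

    def __post_init__(self) -> None:
        self.pct_open, self.pct_middle, self.pct_closed = state_percentages(self.labels)


@dataclass(frozen=True)
class AffinityRecord:
    """Experimental dissociation constant converted to a free energy."""

    ligand: str
    kd: float | None  # molar
    temperature: float = 298.15  # K
    dg_exp: float = field(init=False, default=None)

    def __post_init__(self) -> None:
        if self.kd is not None:
            object.__setattr__(self, "dg_exp", kd_to_dg(self.kd, self.temperature))


def derive_thresholds(
    bound_series: Sequence[float],
    apo_series: Sequence[float],
    window_fraction: float = 0.5,
) -> StateThresholds:
    """Thresholds from trailing-window means of bound and apo series.

    The mean D1 of the ligand-bound trajectory's trailing window sets
    ``closed_max``; the apo trajectory's sets ``open_min``.
    """
    bound = np.asarray(bound_series, dtype=float)
    apo = np.asarray(apo_series, dtype=float)
    if bound.size == 0 or apo.size == 0:
        raise ValueError("empty input series")
    if not 0.0 < window_fraction <= 1.0:
        raise ValueError("window_fraction must be in (0, 1]")
    nb = max(1, int(round(window_fraction * bound.size)))
    na = max(1, int(round(window_fraction * apo.size)))
    closed_max = float(bound[-nb:].mean())
    open_min = float(apo[-na:].mean())
    if closed_max >= open_min:
        raise ValueError(
            f"bound trailing mean ({closed_max:.3f}) must fall below apo "
            f"trailing mean ({open_min:.3f})"
        )
    return StateThresholds(closed_max=closed_max, open_min=open_min, source="derived")


def classify_states(series: Sequence[float], thresholds: StateThresholds) -> StateSeries:
    """Label each frame open/middle/closed by strict threshold comparison."""
    d = np.asarray(series, dtype=float)
    labels = np.full(d.shape, MIDDLE, dtype=object)
    labels[d > thresholds.open_min] = OPEN
    labels[d < thresholds.closed_max] = CLOSED
    return StateSeries(labels=labels, thresholds=thresholds)


def state_percentages(labels: Sequence[str]) -> tuple[float, float, float]:
    """Exact percentages (open, middle, closed) from a label sequence."""
    labels = np.asarray(labels, dtype=object)
    n = labels.size
    if n == 0:
        raise ValueError("no labels")
    return (
        100.0 * int((labels == OPEN).sum()) / n,
        100.0 * int((labels == MIDDLE).sum()) / n,
        100.0 * int((labels == CLOSED).sum()) / n,
    )


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length series of at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def coefficient_of_determination(pred: Sequence[float], exp: Sequence[float]) -> float:
    """r^2: squared Pearson correlation of predictions vs experiment."""
    return pearson_r(pred, exp) ** 2


def kd_to_dg(kd: float, temperature: float = 298.15) -> float:
    """Binding free energy from a dissociation constant, kcal/mol.

    dG_exp = -RT ln Ka = RT ln Kd (Kd in molar, standard state 1 M), so
    a 1 uM binder at 298.15 K gives about -8.2 kcal/mol; every tenfold
    drop in Kd strengthens binding by RT ln 10 ~ 1.36 kcal/mol.
    """
    if kd <= 0:
        raise ValueError("Kd must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL * temperature * math.log(kd)
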