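"""Small-sample wet-lab assay statistics used by the validation figures.

Covers three standard computations:

* qPCR relative expression of a small RNA against a housekeeping
  reference (U6) via ``2**(-(Ct_target - Ct_reference))``;
* dual-luciferase reporter normalization — per-well firefly/renilla
  ratios, with the condition mean expressed as a percentage of the
  control mean (the renilla signal normalizes for transfection
  efficiency in the pmirGLO design);
* two-tailed unpaired t-tests, both Welch (unequal variances,
  Welch–Satterthwaite degrees of freedom) and Student (pooled variance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ValidationError


@dataclass(frozen=True)
class QpcrMeasurement:
    """Threshold cycles of a target and its housekeeping reference."""

    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(f"{name}={v} must be a finite positive cycle count")


@dataclass(frozen=True)
class LuciferaseWell:
    """One well's firefly/renilla luminescence under a named condition."""

    firefly: float
    renilla: float
    condition: str  # "mimic" or "control"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.firefly) and math.isfinite(self.renilla)):
            raise ValidationError("non-finite luminescence reading")
        if self.renilla <= 0:
            raise ValidationError("renilla luminescence must be positive (it is the normalizer)")

    @property
    def ratio(self) -> float:
        return self.firefly / self.renilla


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


def relative_expression(m: QpcrMeasurement | None = None, *, ct_target: float | None = None,
                        ct_reference: float | None = None) -> float:
    """qPCR relative expression ``2**(-dCt)`` with dCt = Ct_target - Ct_reference."""
    if m is None:
        m = QpcrMeasurement(ct_target=ct_target, ct_reference=ct_reference)
    return float(2.0 ** (-(m.ct_target - m.ct_reference)))


def luciferase_percent_of_control(wells: Iterable[LuciferaseWell]) -> float:
    """Mean mimic firefly/renilla ratio as a percentage of the mean control ratio."""
    wells = list(wells)
    mimic = [w.ratio for w in wells if w.condition == "mimic"]
    control = [w.ratio for w in wells if w.condition == "control"]
    if not mimic or not control:
        raise ValidationError("need at least one well in each of the mimic and control conditions")
    mean_control = float(np.mean(control))
    if mean_control == 0.0:
        raise ValidationError("control mean ratio is zero; percent-of-control undefined")
    return float(100.0 * np.mean(mimic) / mean_control)


def _check_groups(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs n >= 2")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in t-test input")
    return x, y


def _degenerate(x: np.ndarray, y: np.ndarray) -> TTestResult | None:
    """Zero-variance contract: equal means -> t=0, p=1; unequal means -> error."""
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return TTestResult(t=0.0, df=float(x.size + y.size - 2), p=1.0)
        raise DegenerateInputError("zero variance with unequal means; t statistic unbounded")
    return None


def welch_t_test(x, y) -> TTestResult:
    """Two-tailed unpaired t-test with Welch's correction (unequal variances)."""
    x, y = _check_groups(x, y)
    deg = _degenerate(x, y)
    if deg is not None:
        return deg
    res = stats.ttest_ind(x, y, equal_var=False)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def student_t_test(x, y) -> TTestResult:
    """Two-tailed unpaired Student's t-test (pooled variance)."""
    x, y = _check_groups(x, y)
    deg = _degenerate(x, y)
    if deg is not None:
        return deg
    res = stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(t=float(res.statistic), df=float(x.size + y.size - 2), p=float(res.pvalue))
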