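"""Solenoid reward calibration.

Liquid rewards are metered by how long a solenoid valve is held open.  The
dispensed volume is, to excellent approximation, linear in open time, with a
small negative intercept reflecting the valve's opening dead time.  The
default line (slope 0.156 ml/s, intercept -0.00134 ml) was fit empirically
for a syringe-fed three-port box; on that line a 72-ms opening dispenses
about 10 ul of water.

Public interfaces use microliters for volumes and seconds for open time.
The model itself stores slope and intercept in ml and seconds, the units of
the fitted line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["CalibrationModel", "DEFAULT_CALIBRATION"]

_ML_TO_UL = 1000.0


@dataclass(frozen=True)
class CalibrationModel:
    """Linear open-time -> dispensed-volume model for one solenoid valve.

    Parameters
    ----------
    slope:
        Dispense rate in ml per second of open time.  Must be positive.
    intercept:
        Volume offset in ml (typically slightly negative: very short
        openings dispense nothing).
    cv:
        Fractional coefficient of variation of repeated dispenses.
        Informational metadata; not used in the deterministic conversions.
    r_squared:
        Goodness of fit of the calibration line.  Informational only.
    """

    slope: float = 0.156
    intercept: float = -0.00134
    cv: float = 0.034
    r_squared: float = 0.999

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"calibration slope must be > 0, got {self.slope}")

    @property
    def min_open_time(self) -> float:
        """Open time (s) at which predicted volume crosses zero."""
        return -self.intercept / self.slope

    def volume_for_time(self, t: float) -> float:
        """Volume (ul) dispensed by holding the valve open for ``t`` seconds.

        Raises
        ------
        ValueError
            If ``t`` is below the valve's effective minimum open time, i.e.
            the line predicts a negative volume.
        """
        v_ml = self.slope * t + self.intercept
        if v_ml < 0:
            raise ValueError(
                f"open time {t:.6g} s is below the valve's effective minimum "
                f"({self.min_open_time:.6g} s); predicted volume is negative"
            )
        return v_ml * _ML_TO_UL

    def time_for_volume(self, v: float) -> float:
        """Open time (s) required to dispense ``v`` microliters.

        Exact algebraic inverse of :meth:`volume_for_time`; round trips are
        exact to floating-point precision.
        """
        if v < 0:
            raise ValueError(f"target volume must be >= 0 ul, got {v}")
        return (v / _ML_TO_UL - self.intercept) / self.slope

    def solenoid_ms_for_volume(self, v: float) -> int:
        """Whole-millisecond open time used by the box firmware for ``v`` ul.

        Rounded down so the dispensed volume never exceeds the target; with
        the default line a 10-ul target maps to 72 ms.
        """
        return int(math.floor(self.time_for_volume(v) * 1000.0 + 1e-9))


DEFAULT_CALIBRATION = CalibrationModel()
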