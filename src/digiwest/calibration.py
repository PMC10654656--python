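"""Molecular-weight calibration of the 96-fraction lane coordinate.

Protein migration distance in SDS-PAGE is, to a good approximation,
linear in log10 of the molecular weight, so the mapping between fraction
index (migration position) and MW is fitted as a piecewise-linear
interpolation of ``log10(MW)`` against fraction index through the ladder
anchor points.  Beyond the outermost anchors the edge segments are
extended linearly and the result is clamped to the physically sensible
range [1, 500] kDa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import N_FRACTIONS, DigiWestError

MW_CLAMP_KDA = (1.0, 500.0)


def _interp_linear_extrap(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """np.interp with linear (edge-slope) extrapolation instead of clamping."""
    y = np.interp(x, xp, fp)
    lo = x < xp[0]
    hi = x > xp[-1]
    if np.any(lo):
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y = np.where(lo, fp[0] + (x - xp[0]) * slope, y)
    if np.any(hi):
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y = np.where(hi, fp[-1] + (x - xp[-1]) * slope, y)
    return y


@dataclass(frozen=True)
class MWCalibration:
    """Monotone mapping between fraction index and molecular weight (kDa).

    Parameters
    ----------
    anchors
        Ladder anchor points ``(fraction_index, mw_kda)``.  Indices must be
        strictly increasing and MWs strictly decreasing (heavier proteins
        migrate less, i.e. sit at lower fraction indices).
    """

    anchors: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        anchors = tuple((float(i), float(m)) for i, m in self.anchors)
        if len(anchors) < 2:
            raise DigiWestError(
                f"calibration requires >= 2 ladder anchors, got {len(anchors)}"
            )
        idx = np.array([a[0] for a in anchors])
        mw = np.array([a[1] for a in anchors])
        if np.any(np.diff(idx) <= 0):
            raise DigiWestError("ladder anchor fraction indices must be strictly increasing")
        if np.any(np.diff(mw) >= 0):
            raise DigiWestError(
                "ladder anchor MWs must be strictly decreasing with fraction index"
            )
        if np.any(mw <= 0):
            raise DigiWestError("ladder anchor MWs must be > 0 kDa")
        object.__setattr__(self, "anchors", anchors)

    @property
    def valid_range(self) -> tuple[float, float]:
        """Fraction-index span covered by the anchors."""
        return (self.anchors[0][0], self.anchors[-1][0])

    @property
    def mw_range(self) -> tuple[float, float]:
        """(lowest, highest) anchor MW in kDa."""
        return (self.anchors[-1][1], self.anchors[0][1])

    def _xp_logmw(self) -> tuple[np.ndarray, np.ndarray]:
        idx = np.array([a[0] for a in self.anchors])
        logmw = np.log10([a[1] for a in self.anchors])
        return idx, logmw

    def fraction_to_mw(self, index) -> np.ndarray | float:
        """MW in kDa at a (possibly fractional) fraction index."""
        x = np.asarray(index, dtype=float)
        if not np.all(np.isfinite(x)):
            raise DigiWestError("fraction index must be finite")
        xp, fp = self._xp_logmw()
        mw = 10.0 ** _interp_linear_extrap(x, xp, fp)
        mw = np.clip(mw, *MW_CLAMP_KDA)
        return float(mw) if np.isscalar(index) else mw

    def mw_to_fraction(self, mw_kda) -> np.ndarray | float:
        """Fraction index (real-valued) at which a given MW migrates."""
        m = np.asarray(mw_kda, dtype=float)
        if not np.all(np.isfinite(m)) or np.any(m <= 0):
            raise DigiWestError("MW must be a finite positive number of kDa")
        lo, hi = MW_CLAMP_KDA
        if np.any(m < lo) or np.any(m > hi):
            raise DigiWestError(
                f"MW outside the calibrated clamp range [{lo:g}, {hi:g}] kDa"
            )
        xp, fp = self._xp_logmw()
        # invert the piecewise-linear log-MW map: log-MW is strictly
        # decreasing in index, so reverse both arrays for np.interp
        x = _interp_linear_extrap(np.log10(m), fp[::-1], xp[::-1])
        return float(x) if np.isscalar(mw_kda) else x

    def fraction_mw_table(self) -> pd.DataFrame:
        """Fitted MW for each of the 96 integer fractions."""
        idx = np.arange(N_FRACTIONS)
        return pd.DataFrame(
            {"fraction_index": idx, "mw_kda": self.fraction_to_mw(idx)}
        )

    def fraction_span_kda(self, index: int) -> float:
        """MW width of one fraction at a given index (local resolution)."""
        lo = max(0, index - 1)
        hi = min(N_FRACTIONS - 1, index + 1)
        return abs(
            float(self.fraction_to_mw(lo)) - float(self.fraction_to_mw(hi))
        ) / (hi - lo)


def fit_calibration(anchors) -> MWCalibration:
    """Fit the fraction-index <-> MW mapping from ladder anchors.

    Anchors may arrive in any order; they are sorted by fraction index.
    Raises :class:`DigiWestError` for fewer than 2 anchors or a
    non-monotone ladder.
    """
    anchors = sorted(((float(i), float(m)) for i, m in anchors), key=lambda a: a[0])
    return MWCalibration(tuple(anchors))


def default_ladder(n_anchors: int = 8) -> list[tuple[int, float]]:
    """A log-linear reference ladder from 250 kDa (fraction 2) to 10 kDa
    (fraction 93), qualitatively mirroring a 4-12% Bis-Tris gradient gel."""
    idx = np.linspace(2, 93, n_anchors)
    mw = 10.0 ** np.linspace(np.log10(250.0), np.log10(10.0), n_anchors)
    return [(int(round(i)), float(round(m, 3))) for i, m in zip(idx, mw)]
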