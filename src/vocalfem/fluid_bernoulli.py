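"""Bernoulli glottal flow with an imposed flow-separation ratio.

The intraglottal pressure is p = p_sub - (p_sub - p_sup) (A_sep / A)^2 up to
the separation point and p = p_sup beyond it, with A_sep = r_sep * A_min and
the separation point located at the first station at or downstream of the
minimum area where A >= A_sep.  Stations upstream of the minimum always carry
the Bernoulli branch.  Pressure depends only on area ratios, so the 2D
width-to-area convention cancels.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .geometry import ChannelProfile

#: gaps below this (mm) count as glottal closure
CLOSED_GAP_TOL = 1e-6


@dataclass
class BernoulliParams:
    """Driving pressures (kPa) and separation ratio (A_sep / A_min >= 1)."""

    p_sub: float = 1.092
    p_sup: float = 0.0
    r_sep: float = 1.2

    def __post_init__(self):
        if self.r_sep < 1.0:
            raise ConfigurationError("separation ratio must be >= 1")
        if self.p_sub < self.p_sup:
            raise ConfigurationError("p_sub must be >= p_sup")


@dataclass
class PressureProfile:
    """Station pressures in kPa, with closure flag and separation index."""

    p: np.ndarray
    closed: bool = False
    i_sep: int | None = None


def closed_glottis_pressure(gap: np.ndarray, p_sub: float, p_sup: float,
                            closed_tol: float = CLOSED_GAP_TOL) -> np.ndarray:
    """Pressure assignment when the glottis is (partly) closed.

    p_sub upstream of the first closed station, zero in the contact zone, and
    p_sup downstream of the last closed station; the structure is driven by
    the subglottal loading during closure.
    """
    closed = gap <= closed_tol
    first = int(np.argmax(closed))
    last = int(len(gap) - 1 - np.argmax(closed[::-1]))
    p = np.zeros_like(gap)
    p[:first] = p_sub
    p[last + 1:] = p_sup
    return p


def bernoulli_pressure(channel: ChannelProfile, params: BernoulliParams) -> PressureProfile:
    """Intraglottal pressure (kPa) at every channel station.

    A fully (or partly) closed glottis returns the closed-glottis assignment,
    flagged via ``closed``.
    """
    gap = channel.gap
    if np.any(gap <= CLOSED_GAP_TOL):
        return PressureProfile(
            p=closed_glottis_pressure(gap, params.p_sub, params.p_sup),
            closed=True)
    area = channel.area
    i_min = channel.i_min
    a_sep = params.r_sep * area[i_min]
    # first station at/after the minimum with A >= A_sep
    after = np.flatnonzero(area[i_min:] >= a_sep - 1e-300)
    i_sep = int(i_min + after[0]) if after.size else len(area)
    p = np.full(area.shape, params.p_sup)
    up = slice(0, i_sep)
    dp = params.p_sub - params.p_sup
    p[up] = params.p_sub - dp * (a_sep / area[up]) ** 2
    return PressureProfile(p=p, closed=False,
                           i_sep=i_sep if i_sep < len(area) else None)
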