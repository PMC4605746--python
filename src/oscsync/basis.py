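"""Spline bases for the log-intensity terms.

Two families are provided:

* ordinary B-splines (via :class:`scipy.interpolate.BSpline`) for the stimulus
  effect f1(t) and the auto-history effect f2(t - t*);
* periodic "circular" splines for the phase-modulation effect f3(phi), built
  from a truncated cosine series around equally spaced knots on [-pi, pi].

Each circular basis function has the form

    r_k(phi) = sum_{m=1}^{m_max} w_m * cos(m * (phi - phi_k)),   w_m = 2/(2 pi m)^4

which is smooth, 2*pi-periodic, and decays quickly in m (the m_max = 4
truncation changes values by less than the m = 5 term bound).  An alternative
``literal`` convention uses cos(2*pi*m*(phi - phi_k)) inside the cosine; it is
retained for fidelity comparisons but has period 1 in radian phase, so the
2*pi-periodic ``radian`` convention is the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "BasisSet",
    "bspline_basis",
    "circular_basis",
    "bspline_knots",
    "circular_knots",
]

TWO_PI = 2.0 * np.pi


def bspline_knots(lo: float, hi: float, n_interior: int, *, log_spaced: bool = False,
                  order: int = 4) -> np.ndarray:
    """Clamped knot vector on [lo, hi] with `n_interior` interior knots.

    `order` is the spline order (number of coefficients per segment); cubic
    splines have order 4.  With ``log_spaced`` the interior knots are placed
    geometrically between lo and hi (useful for history lags, which need
    resolution near zero); lo must then be positive.
    """
    if n_interior < 0:
        raise ValueError("n_interior must be >= 0")
    if hi <= lo:
        raise ValueError("need hi > lo")
    if log_spaced:
        if lo <= 0:
            raise ValueError("log-spaced knots require lo > 0")
        interior = np.geomspace(lo, hi, n_interior + 2)[1:-1]
    else:
        interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    return np.concatenate([np.full(order, lo), interior, np.full(order, hi)])


def circular_knots(n_knots: int) -> np.ndarray:
    """`n_knots` equally spaced phase knots covering [-pi, pi)."""
    if n_knots < 2:
        raise ValueError("need at least 2 circular knots")
    return -np.pi + TWO_PI * np.arange(n_knots) / n_knots


def bspline_basis(knots: np.ndarray, order: int, points: np.ndarray) -> np.ndarray:
    """Evaluate the B-spline basis at `points`.

    Returns a (len(points), n_basis) matrix; rows sum to 1 inside the knot
    span (partition of unity).  Points outside [knots[0], knots[-1]] raise.
    """
    knots = np.asarray(knots, dtype=float)
    points = np.atleast_1d(np.asarray(points, dtype=float))
    lo, hi = knots[0], knots[-1]
    bad = (points < lo) | (points > hi)
    if bad.any():
        raise ValueError(
            f"point {points[bad][0]:g} outside the B-spline span [{lo:g}, {hi:g}]"
        )
    n_basis = len(knots) - order
    if n_basis < 1:
        raise ValueError("knot vector too short for this order")
    eye = np.eye(n_basis)
    spl = BSpline(knots, eye, order - 1, extrapolate=False)
    out = spl(np.clip(points, lo, hi))
    # BSpline returns NaN exactly at the right endpoint for some versions;
    # clamp by evaluating a hair inside.
    nan_rows = ~np.isfinite(out).all(axis=1)
    if nan_rows.any():
        eps = 1e-12 * max(1.0, abs(hi))
        out[nan_rows] = spl(np.clip(points[nan_rows], lo, hi - eps))
    return out


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to [-pi, pi)."""
    return np.mod(np.asarray(phi, dtype=float) + np.pi, TWO_PI) - np.pi


def circular_basis(knots: np.ndarray, points: np.ndarray, m_max: int = 4,
                   convention: str = "radian") -> np.ndarray:
    """Evaluate the circular (periodic cosine-series) basis at `points`.

    Entry (p, k) = sum_{m=1..m_max} 2/(2 pi m)^4 * cos(arg), with
    arg = m*(phi_p - phi_k) under the default ``radian`` convention and
    arg = 2*pi*m*(phi_p - phi_k) under ``literal``.
    """
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    if convention not in ("radian", "literal"):
        raise ValueError(f"unknown convention {convention!r}")
    knots = np.asarray(knots, dtype=float)
    phi = wrap_phase(np.atleast_1d(points))
    diff = phi[:, None] - knots[None, :]
    scale = 1.0 if convention == "radian" else TWO_PI
    out = np.zeros_like(diff)
    for m in range(1, m_max + 1):
        out += 2.0 / (TWO_PI * m) ** 4 * np.cos(scale * m * diff)
    return out


@dataclass
class BasisSet:
    """A serializable basis description with an `evaluate` method.

    kind is "bspline" or "circular".  For B-splines, `knots` is the full
    clamped knot vector and `order` the spline order (4 = cubic); for circular
    bases, `knots` are the equally spaced phase knots and `m_max` the harmonic
    cutoff.
    """

    kind: str
    knots: np.ndarray
    order: int = 4
    m_max: int = 4
    convention: str = "radian"
    normalize: bool = True

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        if self.kind not in ("bspline", "circular"):
            raise ValueError(f"unknown basis kind {self.kind!r}")

    @property
    def _circular_peak(self) -> float:
        """Peak value of one circular basis function (at its knot); used to
        rescale the basis to unit peak so the ridge penalty acts on a
        comparable coefficient scale across terms."""
        m = np.arange(1, self.m_max + 1)
        return float(np.sum(2.0 / (TWO_PI * m) ** 4))

    @property
    def n_basis(self) -> int:
        if self.kind == "bspline":
            return len(self.knots) - self.order
        return len(self.knots)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        if self.kind == "bspline":
            return bspline_basis(self.knots, self.order, points)
        out = circular_basis(self.knots, points, self.m_max, self.convention)
        if self.normalize:
            out = out / self._circular_peak
        return out

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "knots": self.knots.tolist()}
        if self.kind == "bspline":
            d["order"] = self.order
        else:
            d["m_max"] = self.m_max
            d["convention"] = self.convention
            d["normalize"] = self.normalize
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSet":
        return cls(
            kind=d["kind"],
            knots=np.asarray(d["knots"], dtype=float),
            order=int(d.get("order", 4)),
            m_max=int(d.get("m_max", 4)),
            convention=d.get("convention", "radian"),
            normalize=bool(d.get("normalize", True)),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "BasisSet":
        return cls.from_dict(json.loads(s))


def default_stimulus_basis(trial_length: float, n_knots: int = 10) -> BasisSet:
    """Cubic B-spline basis over trial time [0, T]."""
    return BasisSet("bspline", bspline_knots(0.0, trial_length, n_knots - 2))


def default_history_basis(span: float = 0.2, n_knots: int = 8,
                          lag_min: float = 1e-3) -> BasisSet:
    """Cubic B-spline basis over history lags, log-spaced on (0, span]."""
    return BasisSet("bspline", bspline_knots(lag_min, span, n_knots - 2,
                                             log_spaced=True))


def default_phase_basis(n_knots: int = 6, m_max: int = 4,
                        convention: str = "radian") -> BasisSet:
    """Circular basis with equally spaced knots on [-pi, pi)."""
    return BasisSet("circular", circular_knots(n_knots), m_max=m_max,
                    convention=convention)
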