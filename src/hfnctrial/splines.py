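"""M-spline and I-spline bases for the baseline hazard.

An M-spline of degree ``d`` is a nonnegative polynomial spline normalized to
integrate to one over its support; a mixture of M-splines with simplex weights
is therefore a density, and — scaled by a positive intercept — a flexible
nonnegative hazard function.  The I-spline is the running integral of the
M-spline and supplies the matching cumulative hazard.

M-splines are obtained from the ordinary B-spline basis by rescaling: with
knot vector ``t`` and degree ``d``, ``M_j = (d + 1) / (t[j + d + 1] - t[j]) * B_j``,
since each B-spline integrates to ``(t[j+d+1] - t[j]) / (d + 1)`` over its
support.  Boundary knots are repeated with multiplicity ``d + 1`` so the basis
spans the full interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


class DegenerateDurationsError(ValueError):
    """Raised when uncensored durations cannot support distinct internal knots."""


@dataclass(frozen=True)
class MSplineBasis:
    """A fixed M-spline basis on ``[lower, upper]``.

    Parameters
    ----------
    degree : int
        Polynomial degree (3 for the cubic basis used in the trial design;
        0 gives the constant-hazard stub used for exponential reductions).
    boundary_knots : (float, float)
        Lower and upper boundary ``(L, U)`` in hours.
    internal_knots : tuple of float
        Strictly increasing knots inside ``(L, U)``; two for the trial design.
    """

    degree: int
    boundary_knots: tuple[float, float]
    internal_knots: tuple[float, ...] = ()
    _splines: tuple = field(init=False, repr=False, compare=False)
    _isplines: tuple = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        lo, hi = self.boundary_knots
        if not np.isfinite([lo, hi]).all() or not lo < hi:
            raise ValueError(f"boundary knots must satisfy L < U, got ({lo}, {hi})")
        ik = np.asarray(self.internal_knots, dtype=float)
        if ik.size and (np.any(np.diff(ik) <= 0) or ik[0] <= lo or ik[-1] >= hi):
            raise ValueError("internal knots must be strictly increasing inside (L, U)")
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        knots = np.concatenate(
            [np.repeat(lo, self.degree + 1), ik, np.repeat(hi, self.degree + 1)]
        )
        span = knots[self.degree + 1 :] - knots[: -(self.degree + 1)]
        scale = (self.degree + 1) / span  # unit-integral normalization
        splines, isplines = [], []
        for j in range(self.n_basis):
            coef = np.zeros(self.n_basis)
            coef[j] = scale[j]
            bj = BSpline(knots, coef, self.degree, extrapolate=False)
            splines.append(bj)
            isplines.append(bj.antiderivative())
        object.__setattr__(self, "_splines", tuple(splines))
        object.__setattr__(self, "_isplines", tuple(isplines))

    @property
    def n_basis(self) -> int:
        return len(self.internal_knots) + self.degree + 1

    @property
    def lower(self) -> float:
        return float(self.boundary_knots[0])

    @property
    def upper(self) -> float:
        return float(self.boundary_knots[1])

    # -- evaluation -----------------------------------------------------

    def mspline(self, t) -> np.ndarray:
        """Evaluate all M-spline basis functions at time(s) ``t`` (hours).

        Returns an array of shape ``(n_basis,)`` for scalar ``t`` or
        ``(len(t), n_basis)``; zero outside ``[L, U]``.  Negative times are
        rejected.
        """
        t_arr, scalar = _as_time_array(t)
        out = np.zeros((t_arr.size, self.n_basis))
        inside = (t_arr >= self.lower) & (t_arr <= self.upper)
        if inside.any():
            tt = t_arr[inside]
            for j, s in enumerate(self._splines):
                v = s(tt)
                out[inside, j] = np.nan_to_num(v, nan=0.0)
        # right-continuity at U: B-splines vanish at the closed right end
        return out[0] if scalar else out

    def ispline(self, t) -> np.ndarray:
        """Integrated basis: componentwise integral of :meth:`mspline` from L.

        Each component is nondecreasing, 0 at ``t <= L`` and 1 at ``t >= U``.
        """
        t_arr, scalar = _as_time_array(t)
        tt = np.clip(t_arr, self.lower, self.upper)
        out = np.empty((t_arr.size, self.n_basis))
        for j, s in enumerate(self._isplines):
            lo_val = s(self.lower)
            out[:, j] = np.nan_to_num(s(tt) - lo_val, nan=0.0)
        np.clip(out, 0.0, 1.0, out=out)
        out[t_arr >= self.upper] = 1.0
        return out[0] if scalar else out

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "degree": self.degree,
            "boundary_knots": list(self.boundary_knots),
            "internal_knots": list(self.internal_knots),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "MSplineBasis":
        return cls(
            degree=int(d["degree"]),
            boundary_knots=tuple(float(x) for x in d["boundary_knots"]),
            internal_knots=tuple(float(x) for x in d.get("internal_knots", ())),
        )

    @classmethod
    def from_json(cls, s: str) -> "MSplineBasis":
        return cls.from_dict(json.loads(s))


def _as_time_array(t):
    arr = np.atleast_1d(np.asarray(t, dtype=float))
    if not np.isfinite(arr).all():
        raise ValueError("times must be finite")
    if (arr < 0).any():
        raise ValueError("times must be nonnegative (hours)")
    return arr.ravel(), np.isscalar(t) or (np.ndim(t) == 0)


def build_basis(uncensored_durations, degree: int = 3) -> MSplineBasis:
    """Build the trial's cubic basis from observed uncensored durations.

    Internal knots sit at the 33 1/3rd and 66 2/3rd percentiles of the
    uncensored durations (equally spaced percentiles for two knots), computed
    with linear interpolation between order statistics.  Boundary knots are 0
    and the maximum observed duration, so the cumulative hazard is defined at
    every observation.
    """
    d = np.asarray(uncensored_durations, dtype=float)
    if d.size == 0 or not np.isfinite(d).all():
        raise ValueError("durations must be a non-empty finite array")
    if (d <= 0).any():
        raise ValueError("durations must be positive hours")
    if np.unique(d).size < 3:
        raise DegenerateDurationsError(
            "need at least 3 distinct uncensored durations to place internal knots"
        )
    k1, k2 = np.percentile(d, [100 / 3, 200 / 3], method="linear")
    if not (0 < k1 < k2 < d.max()):
        raise DegenerateDurationsError(
            "internal knots would coincide with each other or a boundary"
        )
    return MSplineBasis(degree=degree, boundary_knots=(0.0, float(d.max())),
                        internal_knots=(float(k1), float(k2)))


def constant_basis(upper: float) -> MSplineBasis:
    """Degree-0, single-function basis: M(t) = 1/U on [0, U].

    A mixture over this basis is a constant hazard, so the proportional-
    hazards model reduces to the exponential model — the stub used by the
    grid-integration cross-checks.
    """
    return MSplineBasis(degree=0, boundary_knots=(0.0, float(upper)))


def mspline_eval(basis: MSplineBasis, t):
    """Functional alias for :meth:`MSplineBasis.mspline`."""
    return basis.mspline(t)


def ispline_eval(basis: MSplineBasis, t):
    """Functional alias for :meth:`MSplineBasis.ispline`."""
    return basis.ispline(t)
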