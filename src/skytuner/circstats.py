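"""Circular and axial descriptive statistics and significance tests.

Implements the statistics used to characterise angular tuning of a neuron:
the mean direction and resultant length *r* of a sample of angles, the
preferred stimulus angle Φ_max, a mean-angular-deviation "circular SD", the
95% confidence arc of a mean direction, the linear-circular correlation
between firing rate and stimulus angle (with its coefficient of
determination R²), and a Rayleigh uniformity test.

Axial data — angles defined only modulo 180°, such as the E-vector
orientation of linearly polarized light — are handled by the classical
angle-doubling device: double the angles, apply ordinary circular
statistics, and halve the resulting direction at the very end.

All angles are degrees.  Statistics are computed in radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DirectionalStats",
    "UndefinedStatisticError",
    "NoPreferredAngleError",
    "CHI2_95_DF1",
    "resultant",
    "axial_double",
    "axial_halve",
    "phi_max",
    "circ_sd_from_r",
    "ci95_mean_direction",
    "linear_circular_corr",
    "rayleigh_test",
    "circular_distance",
]

#: upper 5% quantile of chi-square with 1 df, used by the mean-direction CI
CHI2_95_DF1 = float(stats.chi2.ppf(0.95, df=1))  # 3.8415


class UndefinedStatisticError(ValueError):
    """A statistic was requested on input where it is not defined."""


class NoPreferredAngleError(UndefinedStatisticError):
    """The resultant vector vanishes: no preferred angle exists.

    Callers report this as a non-significant, untuned outcome rather than
    inventing an arbitrary direction.
    """


@dataclass(frozen=True)
class DirectionalStats:
    """Descriptive circular statistics of one angular sample.

    ``mean_direction`` lies in [0, periodicity); ``ci95_halfarc`` is the
    half-width of the 95% confidence arc around it, or ``None`` when the
    sample is too dispersed for the arc to be defined.
    """

    mean_direction: float
    r: float
    circ_sd: float
    ci95_halfarc: float | None
    n: int
    periodicity: int = 360


def _to_rad(angles_deg) -> np.ndarray:
    return np.deg2rad(np.asarray(angles_deg, dtype=float).ravel())


def resultant(
    angles,
    weights=None,
) -> tuple[float, float]:
    """Mean direction (degrees in [0, 360)) and resultant length r in [0, 1].

    Each angle contributes a unit vector (scaled by its weight, if given);
    the mean direction is the direction of the vector sum and r is its
    length divided by the total weight.  r is invariant under a global
    rotation of all angles.

    Raises
    ------
    UndefinedStatisticError
        On empty input or all-zero weights.

    Notes
    -----
    A vanishing resultant (e.g. four angles 90° apart) returns ``(nan, 0.0)``
    — the mean direction is undefined but r = 0 is a valid statistic.
    """
    a = _to_rad(angles)
    if a.size == 0:
        raise UndefinedStatisticError("resultant of an empty angle sample")
    if weights is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.shape != a.shape:
            raise ValueError("weights must match angles in length")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if not np.any(w > 0):
            raise UndefinedStatisticError("all weights are zero")
    z = np.sum(w * np.exp(1j * a)) / np.sum(w)
    r = float(np.abs(z))
    if r < 1e-12:
        return (float("nan"), 0.0)
    mean = float(np.mod(np.rad2deg(np.angle(z)), 360.0))
    return (mean, min(r, 1.0))


def axial_double(angles) -> np.ndarray:
    """Double angles modulo 360°, mapping an axial (180°-periodic) sample
    onto the full circle so ordinary circular statistics apply."""
    return np.mod(2.0 * np.asarray(angles, dtype=float), 360.0)


def axial_halve(direction: float) -> float:
    """Halve a direction obtained on doubled angles, back to [0, 180)."""
    return float(np.mod(np.asarray(direction, dtype=float) / 2.0, 180.0))


def phi_max(angles, periodicity: int = 360, weights=None) -> float:
    """Preferred angle Φ_max of an angular sample, in [0, periodicity).

    For 360°-periodic data this is the mean direction of the sample (the
    unimodal-sample method).  For axial 180°-periodic data the angles are
    doubled, the mean direction computed, and the result halved.

    Raises
    ------
    NoPreferredAngleError
        If the (doubled) resultant vanishes — no preferred angle exists.
    """
    a = np.asarray(angles, dtype=float).ravel()
    if a.size < 1:
        raise UndefinedStatisticError("phi_max of an empty sample")
    if periodicity == 180:
        a = axial_double(a)
    elif periodicity != 360:
        raise ValueError("periodicity must be 180 or 360")
    mean, r = resultant(a, weights)
    if not math.isfinite(mean):
        raise NoPreferredAngleError(
            "resultant vector vanishes; no preferred angle"
        )
    return axial_halve(mean) if periodicity == 180 else mean


def circ_sd_from_r(r: float, convention: str = "angular_deviation") -> float:
    """Angular spread (degrees) implied by a resultant length r ∈ [0, 1].

    ``angular_deviation`` (default) is the mean angular deviation
    (180/π)·√(2(1−r)), bounded by ≈81.03° at r=0; ``circular_sd`` is the
    unbounded alternative (180/π)·√(−2·ln r).  Both are 0 at r=1 and
    monotone decreasing in r.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r={r} outside [0, 1]")
    if convention == "angular_deviation":
        return math.degrees(math.sqrt(2.0 * (1.0 - r)))
    if convention == "circular_sd":
        if r == 0.0:
            return float("inf")
        return math.degrees(math.sqrt(-2.0 * math.log(r)))
    raise ValueError(f"unknown convention {convention!r}")


def ci95_mean_direction(
    n: int, r: float, periodicity: int = 360
) -> float | None:
    """Half-arc (degrees) of the 95% confidence interval of a mean direction.

    Uses the two-regime large-sample arc for a mean direction with
    χ²₀.₀₅,₁ ≈ 3.841 and R = n·r:

    * r ≤ 0.9:  d = arccos( √( 2n·(2R² − n·χ²) / (4n − χ²) ) / R )
    * r > 0.9:  d = arccos( √( n² − (n² − R²)·e^{χ²/n} ) / R )

    For axial data (``periodicity=180``) r is assumed to come from doubled
    angles and the arc is halved before returning.  Returns ``None`` when
    the sample is too dispersed for the arc to be defined (the arccos
    argument leaves [0, 1]).
    """
    if n < 2:
        raise UndefinedStatisticError("confidence arc requires n >= 2")
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r={r} outside [0, 1]")
    if r == 0.0:
        return None
    chi2 = CHI2_95_DF1
    R = n * r
    if r <= 0.9:
        num = 2.0 * n * (2.0 * R * R - n * chi2)
        den = 4.0 * n - chi2
        if num <= 0:
            return None
        arg = math.sqrt(num / den) / R
    else:
        inner = n * n - (n * n - R * R) * math.exp(chi2 / n)
        if inner < 0:
            return None
        arg = math.sqrt(inner) / R
    if arg > 1.0:
        if arg > 1.0 + 1e-12:
            return None
        arg = 1.0
    d = math.degrees(math.acos(arg))
    return d / 2.0 if periodicity == 180 else d


def linear_circular_corr(
    values, angles, periodicity: int = 360
) -> tuple[float, float]:
    """Linear-circular correlation of a linear variable with an angle.

    Correlates ``values`` (e.g. per-bin firing rates) with the sine and
    cosine components of the angles (doubled first when ``periodicity`` is
    180).  With r_xc = corr(x, cos φ), r_xs = corr(x, sin φ) and
    r_cs = corr(cos φ, sin φ):

        R² = (r_xc² + r_xs² − 2·r_xc·r_xs·r_cs) / (1 − r_cs²)

    reported clipped to [0, 1].  Under the null of no association n·R²
    follows a χ² distribution with 2 df, giving the p-value (computed on
    the unclipped statistic).

    Returns ``(R², p)``.

    Raises
    ------
    UndefinedStatisticError
        If ``values`` is constant (correlation undefined).
    ValueError
        On fewer than 4 paired observations or mismatched lengths.
    """
    x = np.asarray(values, dtype=float).ravel()
    a = np.asarray(angles, dtype=float).ravel()
    if x.shape != a.shape:
        raise ValueError("values and angles must have equal length")
    n = x.size
    if n < 4:
        raise ValueError("linear-circular correlation requires n >= 4")
    if periodicity == 180:
        a = axial_double(a)
    elif periodicity != 360:
        raise ValueError("periodicity must be 180 or 360")
    if np.ptp(x) == 0.0:
        raise UndefinedStatisticError(
            "values are constant; correlation undefined"
        )
    phi = np.deg2rad(a)
    c, s = np.cos(phi), np.sin(phi)

    def _corr(u, v):
        du, dv = u - u.mean(), v - v.mean()
        denom = math.sqrt(float(du @ du) * float(dv @ dv))
        if denom == 0.0:
            return 0.0
        return float(du @ dv) / denom

    r_xc = _corr(x, c)
    r_xs = _corr(x, s)
    r_cs = _corr(c, s)
    denom = 1.0 - r_cs * r_cs
    if denom <= 1e-15:
        raise UndefinedStatisticError("degenerate angular design (cos ∝ sin)")
    r2 = (r_xc * r_xc + r_xs * r_xs - 2.0 * r_xc * r_xs * r_cs) / denom
    p = float(stats.chi2.sf(n * r2, df=2))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return (float(np.clip(r2, 0.0, 1.0)), p)


def rayleigh_test(angles, periodicity: int = 360) -> tuple[float, float]:
    """Rayleigh test of circular uniformity; returns ``(z, p)``.

    z = n·r² on the (doubled, if axial) angles; the p-value uses the
    standard series approximation
    p ≈ e^{−z}·(1 + (2z − z²)/(4n) − (24z − 132z² + 76z³ − 9z⁴)/(288n²)).
    Requires n ≥ 5 (the approximation is poor below that).
    """
    a = np.asarray(angles, dtype=float).ravel()
    n = a.size
    if n < 5:
        raise ValueError("Rayleigh test requires n >= 5")
    if periodicity == 180:
        a = axial_double(a)
    _, r = resultant(a)
    z = n * r * r
    p = math.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4)
        / (288.0 * n * n)
    )
    return (float(z), float(min(max(p, 0.0), 1.0)))


def circular_distance(a: float, b: float, periodicity: int = 360) -> float:
    """Smallest angular distance between two directions under a given
    periodicity, in [0, periodicity/2].  With ``periodicity=180`` this is
    the axial distance used for polarization-angle comparisons."""
    d = abs(float(a) - float(b)) % periodicity
    return min(d, periodicity - d)
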