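"""Circular statistics: means, dispersion, and tests on phase angles.

All public functions take and return phases in **degrees**, wrapped to
``(-180, 180]``. Internally angles are handled as unit vectors, so every
statistic is invariant under adding multiples of 360 to the input.

The implementations follow the standard directional-statistics literature
(Fisher 1993; Zar, Biostatistical Analysis ch. 26-27), i.e. the same
formulae as the widely used MATLAB circular-statistics toolbox:

* mean direction = angle of the mean resultant vector;
* angular deviation ``s = sqrt(2 (1 - Rbar))`` (reported in degrees);
* Rayleigh test of uniformity with the finite-n corrected p approximation;
* Watson-Williams high-concentration F test for equality of mean directions;
* a sign (binomial) test of the circular median against a fixed direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError

__all__ = [
    "wrap_deg",
    "circ_diff_deg",
    "CircMean",
    "circ_mean",
    "circ_median",
    "CircularTestResult",
    "rayleigh_test",
    "watson_williams",
    "circ_median_test",
    "mean_ci_valid",
]


def wrap_deg(angles: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) in degrees to the interval ``(-180, 180]``."""
    a = np.asarray(angles, dtype=float)
    w = (a + 180.0) % 360.0 - 180.0
    w = np.where(w == -180.0, 180.0, w)
    return float(w) if np.isscalar(angles) or a.ndim == 0 else w


def circ_diff_deg(a: np.ndarray | float, b: np.ndarray | float):
    """Signed circular difference ``a - b`` wrapped to ``(-180, 180]`` degrees."""
    return wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


@dataclass
class CircMean:
    """Mean direction of a circular sample."""

    mean_deg: float
    resultant: float  # mean resultant length Rbar in [0, 1]
    angular_sd_deg: float  # angular deviation sqrt(2(1-Rbar)), degrees
    n: int

    @property
    def mean_defined(self) -> bool:
        """False for (near-)uniform samples where the mean direction is arbitrary."""
        return self.resultant > 1e-9


def circ_mean(phases_deg: np.ndarray) -> CircMean:
    """Circular mean as the angle of the mean resultant vector."""
    p = np.asarray(phases_deg, dtype=float)
    if p.size == 0:
        raise InsufficientDataError("circ_mean of an empty sample is undefined")
    z = np.exp(1j * np.radians(p))
    m = z.mean()
    rbar = float(np.abs(m))
    mean = float(wrap_deg(np.degrees(np.angle(m))))
    sd = float(np.degrees(np.sqrt(max(0.0, 2.0 * (1.0 - rbar)))))
    return CircMean(mean_deg=mean, resultant=rbar, angular_sd_deg=sd, n=int(p.size))


def circ_median(phases_deg: np.ndarray) -> float:
    """Circular median: the sample direction minimising mean circular distance.

    Evaluated over the sample points (and antipodal midpoints for even n),
    which is sufficient for the aggregate statistics used here.
    """
    p = np.asarray(phases_deg, dtype=float)
    if p.size == 0:
        raise InsufficientDataError("circ_median of an empty sample is undefined")
    rad = np.radians(p)
    candidates = rad
    # mean absolute circular deviation from each candidate
    dev = np.abs(np.pi - np.abs(np.pi - np.abs(rad[None, :] - candidates[:, None])))
    cost = dev.mean(axis=1)
    best = np.flatnonzero(np.isclose(cost, cost.min()))
    # average tied minimisers on the circle for a deterministic answer
    m = np.angle(np.exp(1j * rad[best]).mean())
    return float(wrap_deg(np.degrees(m)))


@dataclass
class CircularTestResult:
    statistic: float
    p_value: float
    df: tuple[int, int] | None = None
    n_per_group: tuple[int, ...] = ()


def rayleigh_test(phases_deg: np.ndarray) -> CircularTestResult:
    """Rayleigh test of circular uniformity.

    Uses Z = n * Rbar^2 with the corrected p-value approximation
    ``p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n))`` (Zar eq. 27.4).
    """
    p = np.asarray(phases_deg, dtype=float)
    n = p.size
    if n < 5:
        raise InsufficientDataError(f"Rayleigh test needs n >= 5, got {n}")
    rbar = circ_mean(p).resultant
    rn = n * rbar
    z = rn**2 / n
    pval = float(np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - rn**2)) - (1.0 + 2.0 * n)))
    return CircularTestResult(statistic=float(z), p_value=min(1.0, pval), n_per_group=(n,))


def _kappa_from_rbar(rbar: float) -> float:
    """Maximum-likelihood-ish estimate of von Mises kappa (Fisher 1993, eq. 4.40)."""
    rbar = min(rbar, 1.0 - 1e-10)  # perfectly concentrated samples -> huge kappa
    if rbar < 0.53:
        return 2.0 * rbar + rbar**3 + 5.0 * rbar**5 / 6.0
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1.0 - rbar)
    return 1.0 / (rbar**3 - 4.0 * rbar**2 + 3.0 * rbar)


def watson_williams(*groups: np.ndarray) -> CircularTestResult:
    """Watson-Williams test for equality of k mean directions.

    High-concentration F approximation with the ``1 + 3/(8 kappa)``
    correction factor; degrees of freedom ``(k-1, N-k)``. A warning is
    issued when the pooled concentration is low enough (mean resultant
    < 0.45) that the approximation is unreliable.
    """
    if len(groups) < 2:
        raise InsufficientDataError("Watson-Williams needs at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    ns = [a.size for a in arrs]
    if any(n < 5 for n in ns):
        raise InsufficientDataError(f"every group needs n >= 5 (got {ns})")
    k = len(arrs)
    n_total = int(sum(ns))
    rs = [a.size * circ_mean(a).resultant for a in arrs]  # per-group resultants Rj
    pooled = np.concatenate(arrs)
    r_all = pooled.size * circ_mean(pooled).resultant
    rw = sum(rs) / n_total  # weighted mean resultant length
    if rw < 0.45:
        warnings.warn(
            "Watson-Williams assumptions doubtful: pooled mean resultant "
            f"{rw:.2f} < 0.45",
            stacklevel=2,
        )
    kappa = _kappa_from_rbar(rw)
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    num = (n_total - k) * (sum(rs) - r_all)
    den = (k - 1) * (n_total - sum(rs))
    if den <= 0:
        # perfectly concentrated groups: F unbounded, decide by resultant equality
        f = np.inf if num > 1e-12 else 0.0
        pval = 0.0 if num > 1e-12 else 1.0
        return CircularTestResult(f, pval, df=(k - 1, n_total - k), n_per_group=tuple(ns))
    f = float(correction * num / den)
    pval = float(stats.f.sf(f, k - 1, n_total - k))
    return CircularTestResult(f, pval, df=(k - 1, n_total - k), n_per_group=tuple(ns))


def circ_median_test(phases_deg: np.ndarray, mu_deg: float = 0.0) -> CircularTestResult:
    """Sign (binomial) test that the circular median equals ``mu_deg``.

    Counts observations falling on either side of the direction ``mu_deg``
    (signed wrapped difference), discards exact ties, and evaluates a
    two-sided binomial test at p = 1/2.
    """
    d = circ_diff_deg(np.asarray(phases_deg, dtype=float), mu_deg)
    pos = int(np.sum(d > 0))
    neg = int(np.sum(d < 0))
    n = pos + neg
    if n == 0:
        raise InsufficientDataError("all observations tie with mu; sign test undefined")
    res = stats.binomtest(min(pos, neg), n, 0.5, alternative="two-sided")
    return CircularTestResult(statistic=float(pos - neg), p_value=float(res.pvalue), n_per_group=(n,))


def mean_ci_valid(n: int, rbar: float, conf: float = 0.95) -> bool:
    """Whether the standard confidence interval for a mean direction exists.

    The textbook interval for the mean of n angles with mean resultant
    length ``Rbar`` (Zar eq. 26.24) requires ``n * Rbar^2 > chi2(conf, 1) / 2``;
    below that the sample is too dispersed for confidence limits.
    """
    if n < 2:
        return False
    chi2 = stats.chi2.ppf(conf, 1)
    return bool(n * rbar**2 > chi2 / 2.0)
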