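"""Independent oracles used by the test suite.

Each routine here is deliberately written by a different method than the
library code it checks: brute-force double loops, generic numerical
optimisation, and a different solar ephemeris, so that agreement is
evidence rather than tautology.
"""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
from scipy import optimize


def moran_brute_force(values, w):
    """Moran's I and its randomisation-test moments by literal double loops."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    z = x - x.mean()
    s0 = 0.0
    num = 0.0
    for i in range(n):
        for j in range(n):
            s0 += w[i, j]
            num += w[i, j] * z[i] * z[j]
    I = (n / s0) * num / sum(zi * zi for zi in z)

    e_i = -1.0 / (n - 1)
    s1 = 0.0
    for i in range(n):
        for j in range(n):
            s1 += 0.5 * (w[i, j] + w[j, i]) ** 2
    s2 = 0.0
    for i in range(n):
        wi_out = sum(w[i, j] for j in range(n))
        wi_in = sum(w[j, i] for j in range(n))
        s2 += (wi_out + wi_in) ** 2
    m2 = sum(zi ** 2 for zi in z) / n
    m4 = sum(zi ** 4 for zi in z) / n
    b2 = m4 / m2 ** 2
    num_v = (n * ((n ** 2 - 3 * n + 3) * s1 - n * s2 + 3 * s0 ** 2)
             - b2 * ((n ** 2 - n) * s1 - 2 * n * s2 + 6 * s0 ** 2))
    den_v = (n - 1) * (n - 2) * (n - 3) * s0 ** 2
    var_i = num_v / den_v - e_i ** 2
    sd = (I - e_i) / math.sqrt(var_i) if var_i > 0 else float("nan")
    return I, e_i, var_i, sd


def poisson_mle_scipy(y, X):
    """Poisson log-link MLE via generic Nelder-Mead/BFGS optimisation."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)

    def negll(beta):
        eta = X @ beta
        return float(np.sum(np.exp(eta)) - y @ eta)

    beta0 = np.zeros(X.shape[1])
    beta0[0] = math.log(max(y.mean(), 0.1))
    res = optimize.minimize(negll, beta0, method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 2000})
    res = optimize.minimize(negll, res.x, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 20000})
    return res.x


_J2000 = 2451545.0


def solar_elevation_almanac(t_utc: dt.datetime, lon: float, lat: float) -> float:
    """Solar elevation by the Astronomical Almanac low-precision formulas.

    Independent of the NOAA fractional-year expansion: mean longitude and
    anomaly from the Julian date, ecliptic longitude, right ascension and
    declination, and the hour angle from GMST.
    """
    jd = (t_utc - dt.datetime(2000, 1, 1, 12, tzinfo=dt.timezone.utc)
          ).total_seconds() / 86400.0
    L = math.radians((280.460 + 0.9856474 * jd) % 360.0)
    g = math.radians((357.528 + 0.9856003 * jd) % 360.0)
    lam = L + math.radians(1.915) * math.sin(g) + math.radians(0.020) * math.sin(2 * g)
    eps = math.radians(23.439 - 0.0000004 * jd)
    ra = math.atan2(math.cos(eps) * math.sin(lam), math.cos(lam))
    dec = math.asin(math.sin(eps) * math.sin(lam))
    gmst_h = (18.697374558 + 24.06570982441908 * jd) % 24.0
    lst = math.radians(gmst_h * 15.0 + lon)
    ha = lst - ra
    phi = math.radians(lat)
    sin_el = (math.sin(phi) * math.sin(dec)
              + math.cos(phi) * math.cos(dec) * math.cos(ha))
    return math.degrees(math.asin(max(-1.0, min(1.0, sin_el))))
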