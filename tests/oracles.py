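"""Independent brute-force oracles shared by unit and acceptance tests.

Deliberately naive O(N^2) re-statements of the published definitions,
written from the definitions (not from the package code) so that agreement
is evidence of correctness rather than of shared bugs.
"""

import numpy as np
from scipy import integrate
from scipy.stats import t as t_dist


def oracle_sampen(x: np.ndarray, m: int, r: float, sd_ref: float | None = None) -> float:
    """SampEn by direct enumeration: -ln(A/B), Chebyshev distance,
    self-matches excluded, both template sets of size N-m."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = np.std(x) if sd_ref is None else sd_ref
    tol = r * sd
    nt = n - m
    b = a = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if np.max(np.abs(x[i : i + m] - x[j : j + m])) <= tol:
                b += 1
                if abs(x[i + m] - x[j + m]) <= tol:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def oracle_apen(x: np.ndarray, m: int, r: float) -> float:
    """ApEn = Phi(m) - Phi(m+1), self-matches included."""
    x = np.asarray(x, dtype=float)
    tol = r * np.std(x)

    def phi(mm: int) -> float:
        nm = x.size - mm + 1
        logs = []
        for i in range(nm):
            c = sum(
                np.max(np.abs(x[i : i + mm] - x[j : j + mm])) <= tol
                for j in range(nm)
            )
            logs.append(np.log(c / nm))
        return float(np.mean(logs))

    return phi(m) - phi(m + 1)


def oracle_coarse(x: np.ndarray, scale: int) -> np.ndarray:
    n = x.size // scale
    return np.array([x[i * scale : (i + 1) * scale].mean() for i in range(n)])


def oracle_pearson_p(r: float, n: int) -> float:
    """Two-sided p by numerical quadrature of the t density at df = n-2."""
    df = n - 2
    t = abs(r) * np.sqrt(df / (1 - r**2))
    tail, _ = integrate.quad(lambda u: t_dist.pdf(u, df), t, np.inf)
    return 2 * tail


def oracle_partial(x, y, group):
    """Partial correlation controlling a categorical covariate: residualize
    both variables on group dummies (with intercept), correlate residuals,
    test with df = N - k - 1.  Singleton groups are dropped."""
    labels, counts = np.unique(group, return_counts=True)
    keep = np.isin(group, labels[counts > 1])
    x, y, group = x[keep], y[keep], group[keep]
    labels = np.unique(group)
    dummies = (group[:, None] == labels[None, :]).astype(float)
    rx = x - dummies @ np.linalg.lstsq(dummies, x, rcond=None)[0]
    ry = y - dummies @ np.linalg.lstsq(dummies, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = len(x) - len(labels) - 1
    t = abs(r) * np.sqrt(df / (1 - r**2))
    return r, 2 * t_dist.sf(t, df)


def oracle_ols(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    """Polynomial least squares by the normal equations; returns coefficients
    ordered (intercept, slope, ...)."""
    X = np.column_stack([x**k for k in range(degree + 1)])
    return np.linalg.solve(X.T @ X, X.T @ y)
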