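"""Profile REML for a single random effect with an intercept.

Model: y = mu*1 + Z u + e with u ~ N(0, sigma2_u I_q) and
e ~ N(0, sigma2_e I_n).  Writing lambda = sigma2_e / sigma2_u and
M(lambda) = Z'Z + lambda I, the Woodbury identity reduces every quantity
in the restricted likelihood to sparse solves against M, so the problem
becomes a 1-D search over log(lambda) with mu and sigma2_e profiled out
analytically.  BLUPs at the optimum are u_hat = M^-1 Z'(y - mu_hat).

This is deliberately restricted to the two designs used here (sire
incidence; pooled sire-dam incidence) — one variance ratio, intercept
only — which keeps the optimization 1-D and robust.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import minimize_scalar
from scipy.sparse.linalg import splu

__all__ = ["RemlFit", "reml_fit"]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class RemlFit:
    """REML variance components, fitted mean, and BLUPs."""

    sigma2_u: float
    sigma2_e: float
    mu: float
    loglik: float
    blup: np.ndarray
    converged: bool


def _profile(log_lam: float, y, Z, ZtZ, Zty, Zt1, n, q):
    """-2 * restricted log-likelihood at a given log variance ratio,
    with mu and sigma2_e profiled out.  Returns the criterion plus the
    profiled (mu, sigma2_e, u_hat-solve pieces) for reuse."""
    lam = np.exp(log_lam)
    M = (ZtZ + lam * sparse.eye(q, format="csc")).tocsc()
    lu = splu(M)
    a = lu.solve(Zty)  # M^-1 Z'y
    c = lu.solve(Zt1)  # M^-1 Z'1
    # H = I + Z Z' / lam;  H^-1 v = v - Z M^-1 Z'v
    yHy = float(y @ y - Zty @ a)
    oHo = float(n - Zt1 @ c)
    oHy = float(np.sum(y) - Zt1 @ a)
    mu = oHy / oHo
    rHr = yHy - oHy**2 / oHo  # (y - mu)' H^-1 (y - mu)
    dof = n - 1
    sigma2_e = rHr / dof
    # log|M| from the sparse LU factors; M is SPD so the determinant is
    # positive and the permutation sign cancels in the absolute values.
    logdet_M = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
    logdet_H = logdet_M - q * np.log(lam)
    crit = dof * (_LOG_2PI + np.log(sigma2_e) + 1.0) + logdet_H + np.log(oHo)
    return crit, mu, sigma2_e, lam, lu


def reml_fit(
    y: np.ndarray,
    Z: sparse.spmatrix,
    lam_bounds: tuple[float, float] = (1e-8, 1e10),
    xatol: float = 1e-10,
) -> RemlFit:
    """Fit the one-random-effect mixed model by profile REML.

    Parameters
    ----------
    y
        Response vector, length n.
    Z
        Sparse incidence matrix (n, q) linking records to effect levels.
    lam_bounds
        Search interval for the variance ratio lambda = sigma2_e/sigma2_u.
        If the boundary fit (sigma2_u = 0) beats the interior optimum,
        the estimate is truncated at zero and BLUPs are zero.
    """
    y = np.asarray(y, dtype=float)
    Z = sparse.csr_matrix(Z)
    n, q = Z.shape
    if n < 3:
        raise ValueError("need at least 3 records")
    if q < 2:
        raise ValueError("need at least 2 random-effect levels")
    ZtZ = (Z.T @ Z).tocsc()
    Zty = Z.T @ y
    Zt1 = np.asarray(Z.sum(axis=0)).ravel()

    args = (y, Z, ZtZ, Zty, Zt1, n, q)
    res = minimize_scalar(
        lambda x: _profile(x, *args)[0],
        bounds=(np.log(lam_bounds[0]), np.log(lam_bounds[1])),
        method="bounded",
        options={"xatol": xatol},
    )
    crit, mu, sigma2_e, lam, lu = _profile(res.x, *args)

    # Boundary comparison: sigma2_u -> 0 is ordinary least squares.
    r0 = y - y.mean()
    s2_ols = float(r0 @ r0) / (n - 1)
    crit0 = (n - 1) * (_LOG_2PI + np.log(s2_ols) + 1.0) + np.log(float(n))
    if crit0 <= crit:
        return RemlFit(
            sigma2_u=0.0,
            sigma2_e=s2_ols,
            mu=float(y.mean()),
            loglik=-0.5 * crit0,
            blup=np.zeros(q),
            converged=True,
        )

    u_hat = lu.solve(Zty - mu * Zt1)
    return RemlFit(
        sigma2_u=sigma2_e / lam,
        sigma2_e=sigma2_e,
        mu=mu,
        loglik=-0.5 * crit,
        blup=np.asarray(u_hat),
        converged=bool(res.success),
    )
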