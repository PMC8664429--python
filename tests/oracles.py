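"""Independent brute-force oracles used to validate the REML engine.

These evaluate the restricted likelihood directly from the n x n marginal
covariance matrix V — a completely separate computational path from the
mixed-model-equations engine they check.
"""

from __future__ import annotations

import numpy as np


def direct_reml_loglik(y, x, z_list, k_list, resid_group, theta) -> float:
    """Restricted log-likelihood via the marginal covariance.

    ``theta`` = (variances of the random terms..., residual variance per
    group).  ``k_list[i]`` is the kernel of term i (None = identity).
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n, p = x.shape
    k = len(z_list)
    v = np.zeros((n, n))
    for i, z in enumerate(z_list):
        zz = np.asarray(z.todense()) if hasattr(z, "todense") else np.asarray(z)
        kern = k_list[i]
        if kern is None:
            v += theta[i] * zz @ zz.T
        else:
            v += theta[i] * zz @ kern @ zz.T
    groups = np.asarray(resid_group, int)
    v[np.diag_indices(n)] += np.asarray(theta)[k + groups]
    vi = np.linalg.inv(v)
    xvx = x.T @ vi @ x
    beta = np.linalg.solve(xvx, x.T @ vi @ y)
    r = y - x @ beta
    _, ld_v = np.linalg.slogdet(v)
    _, ld_x = np.linalg.slogdet(xvx)
    return float(
        -0.5 * ((n - p) * np.log(2 * np.pi) + ld_v + ld_x + r @ vi @ r)
    )


def engine_loglik_grid(engine, grids) -> float:
    """Max direct logREML over a cartesian grid of variance components."""
    import itertools

    z_list = [t.z for t in engine.terms]
    k_list = []
    for t in engine.terms:
        if t.kinv is None:
            k_list.append(None)
        else:
            k_list.append(np.linalg.inv(t.kinv))
    best = -np.inf
    for theta in itertools.product(*grids):
        ll = direct_reml_loglik(
            engine.y, engine.x, z_list, k_list, engine.resid_group,
            np.asarray(theta),
        )
        best = max(best, ll)
    return best


def pearson_by_hand(a, b) -> float:
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    return float(np.sum(a * b) / np.sqrt(np.sum(a * a) * np.sum(b * b)))
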