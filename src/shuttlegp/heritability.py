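"""Broad-sense heritability on an entry-mean basis.

Two forms are used for two-site progeny-testing trials:

* trial-level repeatability, from the single-site model:

      H2 = s2_g / (s2_g + s2_e / NR)

* global two-site heritability, from the two-site model with per-site
  genotype-by-site and residual variances:

      H2 = s2_g / (s2_g + (s2_gs_a + s2_gs_b)/NE + (s2_e_a + s2_e_b)/NR)

``NR`` is the harmonic-mean number of plots per genotype (6 for a balanced
two-site, three-replicate design) and ``NE`` the harmonic-mean number of
sites per genotype (2 when every genotype is tested at both sites).  Both
are computed from the realised design, never hard-coded.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "harmonic_mean",
    "h2_trial",
    "h2_global",
    "variance_proportions",
    "round_half_up",
]


def harmonic_mean(counts) -> float:
    """Harmonic mean ``n / sum(1/c_i)`` of positive counts."""
    c = np.asarray(list(counts), dtype=float)
    if c.size == 0:
        raise ValueError("harmonic mean of an empty collection")
    if (c <= 0).any():
        raise ValueError("harmonic mean requires strictly positive counts")
    return c.size / float(np.sum(1.0 / c))


def _check_nonneg(**kwargs) -> None:
    for name, v in kwargs.items():
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")


def h2_trial(sigma2_g: float, sigma2_e: float, nr: float) -> float:
    """Trial-level repeatability ``s2_g / (s2_g + s2_e/NR)``."""
    _check_nonneg(sigma2_g=sigma2_g, sigma2_e=sigma2_e)
    if nr < 1:
        raise ValueError("NR must be >= 1")
    denom = sigma2_g + sigma2_e / nr
    if denom == 0:
        raise ValueError("all variance components are zero")
    return sigma2_g / denom


def h2_global(
    sigma2_g: float,
    sigma2_gs_a: float,
    sigma2_gs_b: float,
    sigma2_e_a: float,
    sigma2_e_b: float,
    ne: float,
    nr: float,
) -> float:
    """Global two-site heritability from the two-site model components.

    ``a`` / ``b`` index the two sites; the interaction variances are
    averaged through ``NE`` and the residual variances through ``NR``.
    """
    _check_nonneg(
        sigma2_g=sigma2_g, sigma2_gs_a=sigma2_gs_a, sigma2_gs_b=sigma2_gs_b,
        sigma2_e_a=sigma2_e_a, sigma2_e_b=sigma2_e_b,
    )
    if not 1 <= ne <= 2:
        raise ValueError("NE must lie in [1, 2] for a two-site design")
    if nr < 1:
        raise ValueError("NR must be >= 1")
    denom = (
        sigma2_g
        + (sigma2_gs_a + sigma2_gs_b) / ne
        + (sigma2_e_a + sigma2_e_b) / nr
    )
    if denom == 0:
        raise ValueError("all variance components are zero")
    return sigma2_g / denom


def variance_proportions(variances: pd.Series | dict) -> pd.DataFrame:
    """Variance-decomposition table: each component over the total.

    Accepts a Series/dict of named variance components (genotype, per-site
    GxS, block, per-site residual) and returns a frame with ``variance``
    and ``proportion`` columns; the proportions sum to 1.
    """
    v = pd.Series(variances, dtype=float)
    if (v < 0).any():
        raise ValueError("variance components must be >= 0")
    total = float(v.sum())
    if total == 0:
        raise ValueError("total variance is zero")
    return pd.DataFrame(
        {"variance": v, "proportion": v / total}
    ).rename_axis("component")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Half-up rounding, for comparisons against printed tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
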