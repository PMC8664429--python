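"""Attribution of predictive-ability variation to calibration factors.

A fixed-effects ANOVA is fitted to the per-iteration predictive abilities
with the calibration parameters (year, genomic-prediction method, CV
scheme, training-set size — all treated as categorical) as factors, plus
their interactions up to a configurable order.  Each effect's share of the
outcome variation is reported as

    Eta2 = SSq_effect / SSq_total

where ``SSq_total`` is the total sum of squares over all effects,
interactions and the residual, so the Eta2 column plus the residual share
sums to one.  Sums of squares are sequential (type I) in the given factor
order; in the balanced grids produced by the CV driver (equal iteration
counts per cell) sequential and marginal sums of squares coincide, which
is asserted on the fly.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = ["fit_anova_eta2"]


def _term_label(combo: tuple[str, ...]) -> str:
    return ":".join(combo)


def fit_anova_eta2(
    results: pd.DataFrame,
    response: str = "pa",
    factors: tuple[str, ...] = ("year", "gp_method", "scheme", "set_size"),
    max_order: int = 3,
) -> pd.DataFrame:
    """Sequential ANOVA with Eta2 per effect.

    Parameters
    ----------
    results : per-iteration table (e.g. ``CVResult.results``) with the
        response column and one column per factor.
    factors : factor columns, in the order sums of squares are assigned.
    max_order : include interactions up to this order (1 = main effects
        only).

    Returns a frame indexed by effect (plus ``Residual``) with columns
    ``sum_sq``, ``df``, ``eta2``; ``attrs`` carry ``r_squared``, ``n`` and
    the factor order.  Raises on empty factor cells (rank-deficient
    design), naming the first missing cell.
    """
    df = results.dropna(subset=[response]).copy()
    if df.empty:
        raise ValueError("no observations with a response value")
    for f in factors:
        if f not in df.columns:
            raise ValueError(f"factor column {f!r} missing from results")
        if df[f].nunique() < 2:
            raise ValueError(
                f"factor {f!r} has a single level; drop it from `factors`"
            )
    levels = {f: sorted(df[f].unique().tolist()) for f in factors}
    counts = df.groupby(list(factors)).size()
    observed = (
        set(counts.index) if len(factors) > 1 else {(i,) for i in counts.index}
    )
    for cell in itertools.product(*(levels[f] for f in factors)):
        if cell not in observed:
            raise ValueError(
                "empty factor cell "
                + ", ".join(f"{f}={v}" for f, v in zip(factors, cell))
            )

    # safe column names for the formula interface
    safe = {f: f"f{i}" for i, f in enumerate(factors)}
    work = pd.DataFrame({"resp": df[response].to_numpy(dtype=float)})
    for f in factors:
        work[safe[f]] = pd.Categorical(df[f].astype(str).to_numpy())

    terms = []
    order = min(max_order, len(factors))
    for k in range(1, order + 1):
        for combo in itertools.combinations(factors, k):
            terms.append(combo)
    formula = "resp ~ " + " + ".join(
        ":".join(f"C({safe[f]})" for f in combo) for combo in terms
    )
    model = smf.ols(formula, data=work).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = sm.stats.anova_lm(model, typ=1)

    rename = {}
    for combo in terms:
        rename[":".join(f"C({safe[f]})" for f in combo)] = _term_label(combo)
    tab = tab.rename(index=rename)

    ss_total = float(tab["sum_sq"].sum())
    out = pd.DataFrame(
        {
            "sum_sq": tab["sum_sq"],
            "df": tab["df"].astype(int),
            "eta2": tab["sum_sq"] / ss_total,
        }
    ).rename_axis("effect")
    resid_ss = float(tab.loc["Residual", "sum_sq"])
    out.attrs["r_squared"] = 1.0 - resid_ss / ss_total
    out.attrs["n"] = int(len(work))
    out.attrs["factor_order"] = tuple(factors)

    balanced = counts.nunique() == 1
    out.attrs["balanced"] = bool(balanced)
    if balanced and order >= len(factors):
        # sequential vs marginal SSq must agree in a balanced full design
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab2 = sm.stats.anova_lm(model, typ=2).rename(index=rename)
        shared = [i for i in out.index if i != "Residual" and i in tab2.index]
        if not np.allclose(
            out.loc[shared, "sum_sq"], tab2.loc[shared, "sum_sq"],
            rtol=1e-8, atol=1e-8 * max(ss_total, 1.0),
        ):
            warnings.warn(
                "sequential and marginal sums of squares disagree on a "
                "balanced design; check the factor coding", UserWarning,
                stacklevel=2,
            )
    return out
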