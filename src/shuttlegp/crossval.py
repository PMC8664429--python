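"""Sparse-testing cross-validation schemes and predictive ability.

Four calibration scenarios are scored for their ability to predict
genotype merit at a target site (all validation genotypes lack target-site
phenotypes during training; the validation set is fixed at 100 predictions
for comparability across schemes):

* ``SIN``  — single-site: ``s`` genotypes phenotyped at the target site
  only; the single-site model is fitted.
* ``BAL1`` — balanced, 100% overlap: the same ``s`` genotypes phenotyped
  at both sites; two-site model.
* ``BAL2`` — balanced, 50% overlap: ``s`` genotypes observed per site of
  which half are shared, so ``3s/2`` distinct genotypes enter the
  calibration; two-site model.  With 334 genotypes and ``s = 200`` only 34
  remain for validation.
* ``IMB``  — imbalanced / sparse testing: the whole population phenotyped
  at the other site, only ``s`` at the target site; two-site model.  Here
  validation genotypes are phenotyped at the non-target site.

Predictive ability (PA) is the Pearson correlation between the reference
BLUP-adjusted phenotypes (single-site model, identity kernel, complete
target-site data) and the GEBVs of the validation genotypes.  Each
scenario is repeated over seeded random partitions (default 100) and the
per-cell mean and SD of PA are reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kernels import (
    BandwidthPrior,
    GenomicKernel,
    MarkerMatrix,
    estimate_bandwidth,
    linear_kernel,
    scaled_gaussian_kernel,
)
from .mixedlm import GenomicMixedModel, blup_adjusted_means

logger = logging.getLogger(__name__)

__all__ = [
    "SCHEMES",
    "CVConfig",
    "Partition",
    "make_partition",
    "predictive_ability",
    "run_cv",
    "run_cv_grid",
    "CVResult",
]

SCHEMES = ("SIN", "BAL1", "BAL2", "IMB")


@dataclass
class CVConfig:
    """One cross-validation cell: scheme x training size x method."""

    scheme: str
    set_size: int
    trait: str
    target_site: str
    year: object = None
    n_iterations: int = 100
    validation_size: int = 100
    gp_method: str = "gblup"  # gblup | rkhs | oracle (diagnostic)
    master_seed: int = 0
    include_interaction: bool = True
    bandwidth_prior: BandwidthPrior = field(default_factory=BandwidthPrior)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.set_size < 3:
            raise ValueError("set_size must be >= 3")
        if self.gp_method not in ("gblup", "rkhs", "oracle"):
            raise ValueError("gp_method must be 'gblup', 'rkhs' or 'oracle'")


@dataclass
class Partition:
    """Genotype sets for one CV iteration.

    ``train_target`` are observed at the target site, ``train_other`` at
    the other site; ``validation`` genotypes have no target-site phenotype
    in training.
    """

    scheme: str
    train_target: list[str]
    train_other: list[str]
    validation: list[str]

    def __post_init__(self) -> None:
        tt, to, va = map(set, (self.train_target, self.train_other, self.validation))
        if va & tt:
            raise ValueError("validation genotypes must not be trained at the target site")
        if self.scheme in ("SIN", "BAL1", "BAL2") and va & to:
            raise ValueError(
                f"{self.scheme}: validation genotypes must be unphenotyped at both sites"
            )
        if self.scheme == "IMB" and not va <= to:
            raise ValueError("IMB: validation genotypes must be phenotyped at the other site")
        if self.scheme == "SIN" and to:
            raise ValueError("SIN uses no other-site phenotypes")


def make_partition(
    scheme: str,
    s: int,
    population: list[str],
    validation_size: int = 100,
    seed: int | np.random.Generator = 0,
) -> Partition:
    """Sample one training/validation partition for a scheme.

    BAL2 targets a 50% overlap between the two sites' calibration sets:
    ``s`` genotypes observed per site, ``floor(s/2)`` shared, hence
    ``2s - floor(s/2)`` distinct genotypes in the calibration.  When fewer
    than ``validation_size`` genotypes remain unphenotyped the validation
    set shrinks to the remainder with a warning (the ``s = 200`` case on a
    334-genotype population leaves 34).
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop = list(population)
    npop = len(pop)

    def sample(pool, k):
        return [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]

    if scheme == "SIN":
        need = s
    elif scheme == "BAL1":
        need = s
    elif scheme == "BAL2":
        if s % 2:
            warnings.warn(
                f"BAL2 with odd s={s}: overlap rounded down to {s // 2}",
                UserWarning, stacklevel=2,
            )
        need = 2 * s - s // 2
    else:  # IMB
        need = s
    if need > npop:
        raise ValueError(
            f"{scheme} with s={s} needs {need} genotypes but the population has {npop}"
        )

    if scheme == "SIN":
        train_target = sample(pop, s)
        train_other: list[str] = []
        remainder = [g for g in pop if g not in set(train_target)]
    elif scheme == "BAL1":
        train_target = sample(pop, s)
        train_other = list(train_target)
        remainder = [g for g in pop if g not in set(train_target)]
    elif scheme == "BAL2":
        overlap = s // 2
        distinct = sample(pop, 2 * s - overlap)
        both = distinct[:overlap]
        target_only = distinct[overlap:s]
        other_only = distinct[s:]
        train_target = both + target_only
        train_other = both + other_only
        remainder = [g for g in pop if g not in set(distinct)]
    else:  # IMB
        train_other = list(pop)
        train_target = sample(pop, s)
        remainder = [g for g in pop if g not in set(train_target)]

    k = min(validation_size, len(remainder))
    if k < 3:
        raise ValueError(
            f"{scheme} with s={s}: only {len(remainder)} genotypes left for validation"
        )
    if k < validation_size:
        warnings.warn(
            f"{scheme} with s={s}: validation set reduced to {k} genotypes",
            UserWarning, stacklevel=2,
        )
    validation = sample(remainder, k)
    return Partition(scheme, train_target, train_other, validation)


def predictive_ability(reference: pd.Series, gebv: pd.Series) -> float:
    """Pearson correlation between reference adjusted phenotypes and GEBVs.

    Returns ``nan`` (with a warning) when either vector has zero variance.
    """
    shared = reference.index.intersection(gebv.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 genotypes to compute predictive ability")
    a = reference.loc[shared].to_numpy(dtype=float)
    b = gebv.loc[shared].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero variance: predictive ability undefined", UserWarning,
                      stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(a, b)[0])


@dataclass
class CVResult:
    """Per-iteration predictive abilities plus bookkeeping."""

    results: pd.DataFrame
    n_failed: int = 0

    def summary(self) -> pd.DataFrame:
        """Mean and SD of PA per scheme x size x year x method x trait cell
        (non-converged iterations excluded)."""
        ok = self.results[self.results["converged"]]
        return (
            ok.groupby(["scheme", "set_size", "year", "gp_method", "trait"],
                       dropna=False)["pa"]
            .agg(mean_pa="mean", sd_pa="std", n="count")
            .reset_index()
        )


def _subset_kernel(kernel: GenomicKernel, ids: list[str]) -> GenomicKernel:
    pos = {g: i for i, g in enumerate(kernel.genotype_ids)}
    idx = np.array([pos[g] for g in ids])
    return GenomicKernel(
        kernel.matrix[np.ix_(idx, idx)], ids, kind=kernel.kind,
        bandwidth=kernel.bandwidth, site_label=kernel.site_label,
    )


def _subset_markers(markers: MarkerMatrix, ids: list[str]) -> MarkerMatrix:
    pos = {g: i for i, g in enumerate(markers.genotype_ids)}
    idx = np.array([pos[g] for g in ids])
    return MarkerMatrix(markers.values[idx], ids, markers.marker_ids,
                        positions=markers.positions, imputed=markers.imputed)


def run_cv(
    data: pd.DataFrame,
    markers: MarkerMatrix | None,
    config: CVConfig,
) -> CVResult:
    """Run one CV cell: repeated partitions, masking, fitting, scoring.

    Per iteration: draw a partition with an iteration-specific seed spawned
    from ``master_seed`` (iterations share sampling streams across schemes,
    enabling paired comparisons); keep only the phenotypes the scheme
    allows; fit the single-site model (SIN) or the two-site model
    (otherwise) with the configured kernel(s); predict GEBVs for the
    validation genotypes; PA = cor(reference, GEBV).  RKHS bandwidths are
    re-estimated each iteration from the training set's BLUP-adjusted
    phenotypes.  Non-convergent iterations are flagged and excluded from
    summaries, never re-sampled.
    """
    sub = data if config.year is None else data[data["year"] == config.year]
    sites = sorted(sub["site"].unique().tolist())
    if config.target_site not in sites:
        raise ValueError(f"target site {config.target_site!r} not in data {sites}")
    target = config.target_site
    others = [s for s in sites if s != target]
    if config.scheme != "SIN":
        if len(others) != 1:
            raise ValueError("two-site schemes need exactly two sites in the data")
    other = others[0] if others else None

    target_rows = sub[sub["site"] == target].dropna(subset=[config.trait])
    population = sorted(target_rows["genotype"].astype(str).unique().tolist())
    reference = blup_adjusted_means(sub, config.trait, site=target)

    if config.gp_method == "gblup":
        if markers is None:
            raise ValueError("gblup needs a marker matrix")
        full_kernel = linear_kernel(markers)
    else:
        full_kernel = None

    rows = []
    n_failed = 0
    warm: np.ndarray | None = None
    for it in range(config.n_iterations):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.master_seed, spawn_key=(it,))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            part = make_partition(
                config.scheme, config.set_size, population,
                config.validation_size, rng,
            )
        involved = sorted(set(part.train_target) | set(part.train_other)
                          | set(part.validation))
        tt = set(part.train_target)
        to = set(part.train_other)
        if config.scheme == "SIN":
            train = sub[(sub["site"] == target)
                        & sub["genotype"].astype(str).isin(tt)]
        else:
            train = sub[
                ((sub["site"] == target) & sub["genotype"].astype(str).isin(tt))
                | ((sub["site"] == other) & sub["genotype"].astype(str).isin(to))
            ]
        pa = np.nan
        converged = False
        try:
            if config.gp_method == "oracle":
                gebv = reference.reindex(part.validation)
                pa = predictive_ability(reference, gebv)
                converged = True
            else:
                gebv_df, res = _fit_and_predict(
                    train, involved, part, config, target, other,
                    full_kernel, markers, warm,
                )
                converged = res.converged
                if converged:
                    warm = res.varcomp.to_numpy()
                    pa = predictive_ability(reference, gebv_df["gebv"])
                else:
                    n_failed += 1
        except np.linalg.LinAlgError:
            n_failed += 1
        rows.append(
            {
                "iteration": it,
                "scheme": config.scheme,
                "set_size": config.set_size,
                "year": config.year,
                "gp_method": config.gp_method,
                "trait": config.trait,
                "pa": pa,
                "converged": converged,
            }
        )
    if n_failed:
        logger.warning(
            "%s s=%d: %d / %d iterations did not converge and were excluded",
            config.scheme, config.set_size, n_failed, config.n_iterations,
        )
    return CVResult(pd.DataFrame(rows), n_failed=n_failed)


def _fit_and_predict(train, involved, part, config, target, other,
                     full_kernel, markers, warm):
    """Fit the scheme's model on the masked data; return validation GEBVs."""
    fit_kwargs = dict(rtol=1e-6, ltol=1e-8, max_iter=100, compute_se=False)
    if warm is not None:
        fit_kwargs["start"] = warm
        fit_kwargs["n_em"] = 1  # warm-started: go to AI updates quickly
    if config.scheme == "SIN":
        kernel = _scheme_kernel_single(train, involved, config, full_kernel, markers)
        model = GenomicMixedModel(train, config.trait, design="single",
                                  kernel=kernel, site=target)
        res = model.fit(**fit_kwargs)
        gebv = res.predict_gebv(part.validation)
    else:
        kernels = _scheme_kernels_two_site(
            train, involved, config, full_kernel, markers, target, other
        )
        model = GenomicMixedModel(train, config.trait, design="two_site",
                                  kernel=kernels)
        res = model.fit(**fit_kwargs)
        gebv = res.predict_gebv(
            part.validation, target_site=target,
            include_interaction=config.include_interaction,
        )
    return gebv, res


def _scheme_kernel_single(train, involved, config, full_kernel, markers):
    if config.gp_method == "gblup":
        return _subset_kernel(full_kernel, involved)
    sub_markers = _subset_markers(markers, involved)
    adj = blup_adjusted_means(train, config.trait)
    h = estimate_bandwidth(sub_markers, adj, config.bandwidth_prior)
    return scaled_gaussian_kernel(sub_markers, h)


def _scheme_kernels_two_site(train, involved, config, full_kernel, markers,
                             target, other):
    if config.gp_method == "gblup":
        k = _subset_kernel(full_kernel, involved)
        return {"M0": k, target: k, other: k}
    sub_markers = _subset_markers(markers, involved)
    adj = {}
    for s in (target, other):
        site_rows = train[train["site"] == s]
        adj[s] = blup_adjusted_means(site_rows, config.trait, site=s)
    pooled = pd.concat(adj.values(), axis=1).mean(axis=1)
    kernels = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        h0 = estimate_bandwidth(sub_markers, pooled, config.bandwidth_prior)
        kernels["M0"] = scaled_gaussian_kernel(sub_markers, h0)
        for s in (target, other):
            h = estimate_bandwidth(sub_markers, adj[s], config.bandwidth_prior)
            kernels[s] = scaled_gaussian_kernel(sub_markers, h)
    return kernels


def run_cv_grid(
    data: pd.DataFrame,
    markers: MarkerMatrix | None,
    trait: str,
    target_site: str,
    schemes=("SIN", "BAL1", "BAL2", "IMB"),
    set_sizes=(25, 50, 100, 200),
    years=None,
    gp_methods=("gblup",),
    n_iterations: int = 100,
    validation_size: int = 100,
    master_seed: int = 0,
    include_interaction: bool = True,
) -> CVResult:
    """Run a grid of CV cells and concatenate the per-iteration results."""
    if years is None:
        years = sorted(data["year"].unique().tolist())
    frames = []
    n_failed = 0
    for year in years:
        for method in gp_methods:
            for scheme in schemes:
                for s in set_sizes:
                    cfg = CVConfig(
                        scheme=scheme, set_size=s, trait=trait,
                        target_site=target_site, year=year,
                        n_iterations=n_iterations,
                        validation_size=validation_size,
                        gp_method=method, master_seed=master_seed,
                        include_interaction=include_interaction,
                    )
                    out = run_cv(data, markers, cfg)
                    frames.append(out.results)
                    n_failed += out.n_failed
    return CVResult(pd.concat(frames, ignore_index=True), n_failed=n_failed)


def plot_pa_vs_size(summary: pd.DataFrame, ax=None):
    """Mean PA against training-set size, one line per scheme (simple
    diagnostic plot; requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for scheme, grp in summary.groupby("scheme"):
        grp = grp.sort_values("set_size")
        ax.errorbar(grp["set_size"], grp["mean_pa"], yerr=grp["sd_pa"],
                    marker="o", capsize=3, label=str(scheme))
    ax.set_xlabel("training set size s")
    ax.set_ylabel("predictive ability")
    ax.legend(title="scheme")
    return ax
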