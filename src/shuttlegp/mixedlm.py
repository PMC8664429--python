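"""Kernel mixed models for single-site and two-site trial analysis.

Two model layouts are supported, mirroring how multi-environment rice
trials are analysed:

* single-site (``design="single"``): ``Y_ijk = mu + r_i + b(r)_ij + g_k +
  e_ijk`` — fixed intercept and replicate, random block-within-replicate
  (``s2_b``), random genotype with a genomic kernel (``s2_g``), one
  residual variance.
* two-site (``design="two_site"``): ``Y_ijkl = mu + s_i + rs_ij + b(rs)_ijk
  + g_l + gs_il + e_ijkl`` — adds a fixed site effect and replicate within
  site, a genotype-by-site interaction per site (each with its own kernel
  and variance ``s2_gs.site``), and site-specific residual variances.

``GenomicMixedModel`` is built from a plot-level phenotype DataFrame plus
kernels; ``fit()`` runs REML (see :mod:`shuttlegp.reml`) and returns a
:class:`MixedModelResults` carrying estimates, BLUPs and GEBVs.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.linalg import cho_factor, cho_solve

from .kernels import GenomicKernel
from .reml import RandomTerm, REMLResult, VarianceComponentModel

logger = logging.getLogger(__name__)

__all__ = [
    "REQUIRED_COLUMNS",
    "GenomicMixedModel",
    "MixedModelResults",
    "fit_model1",
    "fit_model2",
    "blup_adjusted_means",
    "site_correlation",
    "descriptive_stats",
    "harmonic_mean_plots",
    "harmonic_mean_sites",
]

#: columns every plot-level phenotype table must carry (plus >=1 trait column)
REQUIRED_COLUMNS = ("genotype", "site", "year", "rep", "block")

_KERNEL_RIDGE = 1e-8


def _kernel_inverse(kernel: GenomicKernel) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of a kernel, ridged for stability.

    A ridge of ``1e-8 * mean(diag)`` is always added before factorisation
    (logged); the result is cached on the kernel object so cross-validation
    loops that reuse one kernel pay the cost once.
    """
    cached = getattr(kernel, "_inv_cache", None)
    if cached is not None:
        return cached
    k = kernel.matrix
    ridge = _KERNEL_RIDGE * float(np.mean(np.diag(k)))
    if ridge <= 0:
        ridge = _KERNEL_RIDGE
    logger.debug("adding ridge %.3e to %s kernel before inversion", ridge, kernel.kind)
    km = k + ridge * np.eye(k.shape[0])
    cf = cho_factor(km, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    kinv = cho_solve(cf, np.eye(k.shape[0]))
    kinv = (kinv + kinv.T) / 2.0
    kernel._inv_cache = (kinv, logdet)
    return kernel._inv_cache


def validate_phenotypes(data: pd.DataFrame, traits: list[str] | None = None) -> list[str]:
    """Check the plot-table schema; return the trait column names."""
    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"phenotype table is missing required columns: {missing}")
    trait_cols = traits or [c for c in data.columns if c not in REQUIRED_COLUMNS]
    if not trait_cols:
        raise ValueError("phenotype table has no trait columns")
    key = data.duplicated(subset=["genotype", "site", "year", "rep"])
    if key.any():
        offenders = data.loc[key, ["genotype", "site", "year", "rep"]].head(5)
        raise ValueError(
            "duplicate (genotype, site, year, rep) records:\n"
            f"{offenders.to_string(index=False)}"
        )
    return trait_cols


def _incidence(codes: np.ndarray, q: int) -> sparse.csr_matrix:
    n = codes.size
    return sparse.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, q)
    )


def _site_incidence(codes: np.ndarray, mask: np.ndarray, q: int) -> sparse.csr_matrix:
    rows = np.where(mask)[0]
    return sparse.csr_matrix(
        (np.ones(rows.size), (rows, codes[rows])), shape=(codes.size, q)
    )


class GenomicMixedModel:
    """Kernel mixed model for a single trait of a plot-level trial table.

    Parameters
    ----------
    data : DataFrame with columns genotype/site/year/rep/block + traits.
        Rows with a missing value for ``trait`` are dropped.
    trait : trait column to analyse.
    design : ``"single"`` (one site) or ``"two_site"``.
    kernel : genotype covariance.  For ``"single"``: a GenomicKernel or
        ``None`` (identity over phenotyped genotypes).  For ``"two_site"``:
        a dict ``{"M0": K, site_a: K_a, site_b: K_b}`` (as produced by
        :func:`shuttlegp.kernels.site_kernels`), a single kernel reused for
        all three terms, or ``None``.
    site, year : optional subsetting before the design is built.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        trait: str,
        design: str = "single",
        kernel=None,
        site=None,
        year=None,
    ) -> None:
        validate_phenotypes(data, traits=[trait])
        if design not in ("single", "two_site"):
            raise ValueError("design must be 'single' or 'two_site'")
        sub = data
        if site is not None:
            sub = sub[sub["site"] == site]
        if year is not None:
            sub = sub[sub["year"] == year]
        sub = sub.dropna(subset=[trait])
        if sub.empty:
            raise ValueError("no records left after subsetting / dropping missing values")
        self.data = sub.reset_index(drop=True)
        self.trait = trait
        self.design = design
        self.sites = sorted(self.data["site"].unique().tolist())
        if design == "single" and len(self.sites) != 1:
            raise ValueError(
                f"single-site model needs exactly one site, found {self.sites}; "
                "pass site=..."
            )
        if design == "two_site" and len(self.sites) != 2:
            raise ValueError(
                f"two-site model needs exactly two sites, found {self.sites}"
            )
        if self.data["genotype"].nunique() < 3:
            raise ValueError("need at least 3 genotypes with records")
        self.kernel = kernel
        self._build()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, trait: str, **kwargs) -> "GenomicMixedModel":
        return cls(data, trait, **kwargs)

    # ------------------------------------------------------------------
    def _genotype_kernels(self):
        geno_in_data = sorted(self.data["genotype"].astype(str).unique().tolist())
        k = self.kernel
        if self.design == "single":
            main = k if isinstance(k, GenomicKernel) else None
            if main is None:
                main = GenomicKernel.identity(geno_in_data)
            inter = {}
        else:
            if k is None:
                main = GenomicKernel.identity(geno_in_data)
                inter = {s: main for s in self.sites}
            elif isinstance(k, GenomicKernel):
                main = k
                inter = {s: k for s in self.sites}
            elif isinstance(k, dict):
                if "M0" not in k:
                    raise ValueError("two-site kernel dict must contain 'M0'")
                missing = [s for s in self.sites if s not in k]
                if missing:
                    raise ValueError(f"no interaction kernel for site(s) {missing}")
                main, inter = k["M0"], {s: k[s] for s in self.sites}
            else:
                raise TypeError("kernel must be GenomicKernel, dict or None")
        absent = set(geno_in_data) - set(main.genotype_ids)
        if absent:
            raise ValueError(
                f"{len(absent)} genotypes have records but are absent from the "
                f"kernel (e.g. {sorted(absent)[:3]})"
            )
        return main, inter

    def _build(self) -> None:
        df = self.data
        self.y = df[self.trait].to_numpy(dtype=float)
        n = len(df)

        main, inter = self._genotype_kernels()
        self.kernel_main = main
        self.kernel_inter = inter
        gid = {g: i for i, g in enumerate(main.genotype_ids)}
        geno_codes = df["genotype"].astype(str).map(gid).to_numpy()

        # fixed effects, reference-level (first level dropped) coding
        cols = [np.ones(n)]
        names = ["mu"]
        if self.design == "single":
            reps = sorted(df["rep"].unique().tolist())
            for r in reps[1:]:
                cols.append((df["rep"] == r).to_numpy(float))
                names.append(f"rep[{r}]")
            block_lab = df["rep"].astype(str) + ":" + df["block"].astype(str)
            resid_group, resid_labels = None, None
        else:
            site_a, site_b = self.sites
            cols.append((df["site"] == site_b).to_numpy(float))
            names.append(f"site[{site_b}]")
            for s in self.sites:
                reps = sorted(df.loc[df["site"] == s, "rep"].unique().tolist())
                for r in reps[1:]:
                    cols.append(((df["site"] == s) & (df["rep"] == r)).to_numpy(float))
                    names.append(f"rep[{s}:{r}]")
            block_lab = (
                df["site"].astype(str) + ":" + df["rep"].astype(str)
                + ":" + df["block"].astype(str)
            )
            resid_group = (df["site"] == site_b).to_numpy(int)
            resid_labels = [site_a, site_b]
        x = np.column_stack(cols)

        terms: list[RandomTerm] = []
        blocks = sorted(block_lab.unique().tolist())
        # a single block per replicate is fully confounded with the fixed
        # replicate effect: no block term to estimate
        n_rep_cells = (
            df.groupby(["site", "rep"]).ngroups
            if self.design == "two_site"
            else df.groupby("rep").ngroups
        )
        if len(blocks) > n_rep_cells:
            bcode = block_lab.map({b: i for i, b in enumerate(blocks)}).to_numpy()
            terms.append(RandomTerm("block", _incidence(bcode, len(blocks)), blocks))
        if main.kind == "identity":
            kinv_main, logdet_main = None, 0.0
        else:
            kinv_main, logdet_main = _kernel_inverse(main)
        terms.append(
            RandomTerm(
                "genotype",
                _incidence(geno_codes, main.n),
                list(main.genotype_ids),
                kinv=kinv_main,
                logdet_k=logdet_main,
            )
        )
        if self.design == "two_site":
            for s in self.sites:
                ks = inter[s]
                if list(ks.genotype_ids) != list(main.genotype_ids):
                    raise ValueError(
                        f"interaction kernel for site {s!r} must index the same "
                        "genotypes as the main kernel"
                    )
                if ks.kind == "identity":
                    kinv_s, logdet_s = None, 0.0
                else:
                    kinv_s, logdet_s = _kernel_inverse(ks)
                mask = (df["site"] == s).to_numpy()
                terms.append(
                    RandomTerm(
                        f"gs_{s}",
                        _site_incidence(geno_codes, mask, ks.n),
                        list(ks.genotype_ids),
                        kinv=kinv_s,
                        logdet_k=logdet_s,
                    )
                )
        self._engine = VarianceComponentModel(
            self.y, x, names, terms, resid_group, resid_labels
        )

    # ------------------------------------------------------------------
    def fit(self, **kwargs) -> "MixedModelResults":
        """REML fit.  Keyword arguments are passed to the engine
        (``start``, ``max_iter``, ``rtol``, ``fixed_varcomp``, ...)."""
        res = self._engine.fit(**kwargs)
        return MixedModelResults(self, res)


class MixedModelResults:
    """REML estimates, BLUPs and predictions for a fitted model.

    Attributes of note: ``varcomp`` (variance components, floored at
    ~0 rather than negative), ``fe_params`` (fixed effects under the
    reference-level constraint recorded in the index), ``blups`` (dict of
    BLUP Series per random term), ``llf`` (restricted log-likelihood).
    """

    def __init__(self, model: GenomicMixedModel, res: REMLResult) -> None:
        self.model = model
        self._res = res
        self.varcomp = res.varcomp
        self.fe_params = res.fixed_effects
        self.blups = res.blups
        self.llf = res.loglik
        self.converged = res.converged
        self.n_iter = res.n_iter
        self.n_records = res.n_records
        self.varcomp_cov = res.varcomp_cov

    # -- conventional names ------------------------------------------------
    @property
    def mu(self) -> float:
        return float(self.fe_params["mu"])

    def fe_se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self._res.fe_cov)), index=self.fe_params.index
        )

    def varcomp_se(self) -> pd.Series | None:
        if self.varcomp_cov is None:
            return None
        return pd.Series(
            np.sqrt(np.maximum(np.diag(self.varcomp_cov.to_numpy()), 0.0)),
            index=self.varcomp.index,
        )

    def site_effect(self, site: str) -> float:
        """Fixed site effect under reference coding (0 for the first site)."""
        key = f"site[{site}]"
        if key in self.fe_params.index:
            return float(self.fe_params[key])
        if site not in self.model.sites:
            raise KeyError(f"unknown site {site!r}")
        return 0.0

    # -- predictions -------------------------------------------------------
    def predict_gebv(
        self,
        genotypes=None,
        target_site: str | None = None,
        include_interaction: bool = True,
    ) -> pd.DataFrame:
        """Genomic estimated breeding values.

        Single-site model: ``GEBV = mu + g``.  Two-site model: ``GEBV = mu
        + s_target + g`` plus, when ``include_interaction`` (default), the
        site-specific interaction BLUP ``gs_target``.  Genotypes without
        phenotypes receive BLUPs through the kernel covariances (zero under
        an identity kernel).
        """
        g = self.blups["genotype"]
        if genotypes is None:
            genotypes = list(g.index)
        missing = [x for x in genotypes if x not in g.index]
        if missing:
            raise KeyError(
                f"{len(missing)} genotypes absent from the fitted kernel "
                f"(e.g. {missing[:3]})"
            )
        out = pd.DataFrame(index=pd.Index(genotypes, name="genotype"))
        out["g"] = g.reindex(genotypes)
        gebv = self.mu + out["g"]
        components = ["mu", "g"]
        if self.model.design == "two_site":
            if target_site is None:
                raise ValueError("target_site is required for a two-site model")
            gebv = gebv + self.site_effect(target_site)
            out["site_effect"] = self.site_effect(target_site)
            components.append(f"s_{target_site}")
            if include_interaction:
                gs = self.blups[f"gs_{target_site}"].reindex(genotypes)
                out["gs"] = gs
                gebv = gebv + gs
                components.append(f"gs_{target_site}")
        out["gebv"] = gebv
        out.attrs["components"] = components
        out.attrs["model"] = self.model.design
        return out

    def variance_proportions(self) -> pd.DataFrame:
        """Each variance component as a proportion of their sum (sums to 1)."""
        v = self.varcomp
        total = float(v.sum())
        return pd.DataFrame(
            {"variance": v, "proportion": v / total}
        ).rename_axis("component")

    # -- heritability ------------------------------------------------------
    def harmonic_means(self) -> tuple[float, float]:
        """(NR, NE): harmonic-mean plots per genotype and sites per genotype,
        counted from the records actually fitted."""
        df = self.model.data
        plots = df.groupby("genotype").size()
        sites = df.groupby("genotype")["site"].nunique()
        return _harmonic(plots.to_numpy()), _harmonic(sites.to_numpy())

    def h2(self) -> float:
        """Broad-sense heritability on an entry-mean basis.

        Single-site: trial repeatability ``s2_g / (s2_g + s2_e/NR)``.
        Two-site: the across-site form with the mean interaction and mean
        residual variance (see :func:`shuttlegp.heritability.h2_global`).
        """
        from . import heritability as h

        nr, ne = self.harmonic_means()
        v = self.varcomp
        if self.model.design == "single":
            return h.h2_trial(v["genotype"], v["residual"], nr)
        sa, sb = self.model.sites
        return h.h2_global(
            v["genotype"],
            v[f"gs_{sa}"], v[f"gs_{sb}"],
            v[f"residual_{sa}"], v[f"residual_{sb}"],
            ne, nr,
        )

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = []
        m = self.model
        title = "Kernel mixed model (REML)"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(f"design:        {m.design}   trait: {m.trait}")
        lines.append(f"sites:         {', '.join(map(str, m.sites))}")
        lines.append(f"records:       {self.n_records}")
        lines.append(f"genotypes:     {m.data['genotype'].nunique()} phenotyped, "
                      f"{m.kernel_main.n} in kernel ({m.kernel_main.kind})")
        lines.append(f"logREML:       {self.llf:.4f}")
        lines.append(f"converged:     {self.converged} ({self.n_iter} iterations)")
        lines.append("")
        lines.append("Fixed effects (reference-level constraint)")
        fe = pd.DataFrame({"estimate": self.fe_params, "se": self.fe_se()})
        lines.append(fe.to_string(float_format=lambda v: f"{v:.4f}"))
        lines.append("")
        lines.append("Variance components")
        vc = pd.DataFrame({"variance": self.varcomp})
        se = self.varcomp_se()
        if se is not None:
            vc["se"] = se
        vc["proportion"] = self.varcomp / self.varcomp.sum()
        lines.append(vc.to_string(float_format=lambda v: f"{v:.4f}"))
        lines.append("")
        lines.append(f"H2 (entry-mean basis): {self.h2():.4f}")
        return "\n".join(lines)


def _harmonic(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or (counts <= 0).any():
        raise ValueError("harmonic mean requires positive counts")
    return counts.size / float(np.sum(1.0 / counts))


def harmonic_mean_plots(data: pd.DataFrame, trait: str) -> float:
    """NR: harmonic-mean number of plots per genotype with a trait record."""
    sub = data.dropna(subset=[trait])
    return _harmonic(sub.groupby("genotype").size().to_numpy())


def harmonic_mean_sites(data: pd.DataFrame, trait: str) -> float:
    """NE: harmonic-mean number of sites per genotype with a trait record."""
    sub = data.dropna(subset=[trait])
    return _harmonic(sub.groupby("genotype")["site"].nunique().to_numpy())


# ---------------------------------------------------------------------------
# convenience pipeline functions
# ---------------------------------------------------------------------------

def fit_model1(
    data: pd.DataFrame,
    trait: str,
    site=None,
    year=None,
    kernel: GenomicKernel | None = None,
    **fit_kwargs,
) -> MixedModelResults:
    """Single-site model: fixed intercept + replicate; random block and
    genotype (kernel); one residual variance."""
    return GenomicMixedModel(
        data, trait, design="single", kernel=kernel, site=site, year=year
    ).fit(**fit_kwargs)


def fit_model2(
    data: pd.DataFrame,
    trait: str,
    year=None,
    kernel=None,
    **fit_kwargs,
) -> MixedModelResults:
    """Two-site model: adds the fixed site effect, per-site genotype-by-site
    interactions and site-specific residual variances."""
    return GenomicMixedModel(
        data, trait, design="two_site", kernel=kernel, year=year
    ).fit(**fit_kwargs)


def blup_adjusted_means(
    data: pd.DataFrame,
    trait: str,
    site=None,
    year=None,
    **fit_kwargs,
) -> pd.Series:
    """Per-genotype BLUP-adjusted phenotypes ``mu + g_hat`` from the
    single-site model with an identity kernel.

    This is the reference against which predictive abilities are scored,
    and the phenotype input for Gaussian-kernel bandwidth estimation.
    """
    res = fit_model1(data, trait, site=site, year=year, kernel=None, **fit_kwargs)
    out = res.mu + res.blups["genotype"]
    out.name = f"{trait}_adjusted"
    return out


def site_correlation(
    data: pd.DataFrame,
    trait: str,
    year=None,
    **fit_kwargs,
) -> tuple[float, float]:
    """Pearson correlation (and two-sided p-value) between the per-site
    BLUP-adjusted phenotypes over shared genotypes."""
    sub = data if year is None else data[data["year"] == year]
    sites = sorted(sub["site"].unique().tolist())
    if len(sites) != 2:
        raise ValueError(f"site correlation needs exactly two sites, found {sites}")
    means = [
        blup_adjusted_means(sub, trait, site=s, **fit_kwargs) for s in sites
    ]
    shared = means[0].index.intersection(means[1].index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 genotypes shared between the sites")
    r, p = stats.pearsonr(means[0].loc[shared], means[1].loc[shared])
    return float(r), float(p)


def descriptive_stats(
    data: pd.DataFrame, trait: str, site=None, year=None
) -> pd.Series:
    """Plot-level mean, SE of the mean, min, max and CV (percent)."""
    sub = data
    if site is not None:
        sub = sub[sub["site"] == site]
    if year is not None:
        sub = sub[sub["year"] == year]
    v = sub[trait].dropna().to_numpy(dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 records for descriptive statistics")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    if mean == 0.0:
        warnings.warn("zero mean: coefficient of variation undefined", UserWarning,
                      stacklevel=2)
        cv = np.nan
    else:
        cv = 100.0 * sd / abs(mean)
    return pd.Series(
        {
            "mean": mean,
            "se": sd / np.sqrt(v.size),
            "min": float(np.min(v)),
            "max": float(np.max(v)),
            "c_var": cv,
            "n": float(v.size),
        }
    )
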