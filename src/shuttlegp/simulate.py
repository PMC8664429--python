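"""Synthetic genotypes and two-site lattice-trial phenotypes.

The generator emulates the data structure of an early-generation rice
recurrent-selection experiment: a few hundred partially inbred genotypes
scored by SNP markers on 12 chromosomes, progeny-tested at two contrasting
sites in incomplete-block lattices (16 blocks x 3 replicates per site),
optionally over two years.  It produces the exact generative mirror of the
two-site mixed model — site means, fixed replicate shifts, random block
effects, genotypic site effects ``u_site = g + gs_site`` built from marker
effects, and site-specific residuals — together with the known truth, so
model recovery can be tested.

Genotypes are coded -1/0/1.  Each individual carries two haplotype chains
per chromosome (first-order Markov dependence between adjacent markers
mimics LD); heterozygotes arise naturally at rate 2p(1-p) and are then
partially collapsed toward one of the individual's own haplotypes — as
selfing would, preserving allele frequencies and LD — to reach the
configured residual heterozygosity.  Genotypic site effects are sums of
marker effects
``X beta``; for a nonnegative between-site genetic correlation ``r_g`` the
marker effects decompose exactly as shared + site-specific, so the implied
(kernel-scale) variance components are known in closed form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import MarkerMatrix

__all__ = [
    "SiteConfig",
    "SimulationConfig",
    "TrueValues",
    "simulate_genotypes",
    "simulate_true_values",
    "simulate_trial",
    "simulate_dataset",
]


@dataclass
class SiteConfig:
    """Per-site trial parameters.

    ``target_h2_trial`` is the intended single-site, entry-mean
    repeatability; together with ``sigma2_residual`` and the replicate
    count it fixes the genotypic variance at the site.
    """

    name: str
    trait_mean: float
    sigma2_block: float = 0.9
    sigma2_residual: float = 5.0
    target_h2_trial: float = 0.8

    def __post_init__(self) -> None:
        if self.sigma2_block < 0 or self.sigma2_residual < 0:
            raise ValueError("variances must be >= 0")
        if not 0.0 < self.target_h2_trial <= 1.0:
            raise ValueError("target_h2_trial must be in (0, 1]")


def _default_sites() -> list[SiteConfig]:
    # an irrigated high-mean site and a rainfed lower-mean site, flowering-like
    return [
        SiteConfig("PAL", trait_mean=88.2, sigma2_block=0.9,
                   sigma2_residual=5.6, target_h2_trial=0.69),
        SiteConfig("SRO", trait_mean=82.2, sigma2_block=0.9,
                   sigma2_residual=4.9, target_h2_trial=0.96),
    ]


@dataclass
class SimulationConfig:
    """Study design + genetic architecture for the synthetic experiment."""

    n_genotypes: int = 334
    n_markers: int = 992
    n_chromosomes: int = 12
    maf_beta: tuple[float, float] = (1.0, 3.0)
    residual_heterozygosity: float = 0.25
    ld_rho: float = 0.6
    sites: list[SiteConfig] = field(default_factory=_default_sites)
    n_replicates: int = 3
    n_blocks: int = 16
    genetic_correlation: float = 0.55
    trait_name: str = "trait"
    years: list = field(default_factory=lambda: [2017])
    year_effects: dict | None = None  # {site: [shift per year]}, default zeros
    sigma2_rep: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers < 1 or self.n_genotypes < 2:
            raise ValueError("need >= 1 marker and >= 2 genotypes")
        if self.n_chromosomes < 1:
            raise ValueError("need >= 1 chromosome")
        if not 0.0 <= self.residual_heterozygosity <= 1.0:
            raise ValueError("residual_heterozygosity must be in [0, 1]")
        if not -1.0 <= self.genetic_correlation <= 1.0:
            raise ValueError("genetic correlation must be in [-1, 1]")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if len(self.sites) != 2:
            raise ValueError("the two-site design requires exactly 2 sites")
        if len({s.name for s in self.sites}) != 2:
            raise ValueError("site names must be distinct")
        plots_per_block = math.ceil(self.n_genotypes / self.n_blocks)
        if self.n_blocks * plots_per_block < self.n_genotypes:
            raise ValueError("blocks cannot hold all genotypes in a replicate")

    @property
    def site_names(self) -> list[str]:
        return [s.name for s in self.sites]

    def genotype_ids(self) -> list[str]:
        width = len(str(self.n_genotypes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genotypes)]


@dataclass
class TrueValues:
    """Ground truth behind a simulated experiment.

    ``true_main_effect`` is the genotype main effect ``g``;
    ``true_site_effects`` holds ``u_site = g + gs_site`` per genotype and
    site (the quantity whose between-site correlation is ``r_g``);
    ``variance_components_truth`` records the generating variances on the
    scale of the realised GBLUP kernel, keyed like the fitted model
    (``genotype``, ``gs_<site>``, ``block``, ``residual_<site>``).
    """

    true_main_effect: pd.Series
    true_site_effects: pd.DataFrame
    variance_components_truth: dict[str, float]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def _chromosome_sizes(n_markers: int, n_chrom: int) -> list[int]:
    base = n_markers // n_chrom
    sizes = [base] * n_chrom
    for i in range(n_markers - base * n_chrom):
        sizes[i] += 1
    return [s for s in sizes if s > 0]


def simulate_genotypes(config: SimulationConfig) -> MarkerMatrix:
    """Draw the -1/0/1 marker matrix.

    Per-marker allele frequencies come from ``Beta(*maf_beta)``; within a
    chromosome adjacent markers are correlated with first-order coefficient
    ``ld_rho``.  Heterozygous (0) calls arise from the two haplotypes and
    are collapsed marker-wise i.i.d. toward a per-individual donor
    haplotype until their overall rate matches
    ``residual_heterozygosity``.  Monomorphic markers are kept (they carry
    no signal but count toward the marker number)."""
    rng = _rng(config, 0)
    n, m = config.n_genotypes, config.n_markers
    a, b = config.maf_beta
    freqs = rng.beta(a, b, size=m)
    sizes = _chromosome_sizes(m, config.n_chromosomes)

    # two haplotypes per individual, each a first-order Markov chain along
    # the chromosome; heterozygosity then arises naturally at rate 2p(1-p)
    haplotypes = np.empty((2, n, m), dtype=float)
    for hap in range(2):
        col = 0
        for size in sizes:
            p = freqs[col:col + size]
            sd = np.sqrt(np.maximum(p * (1 - p), 1e-12))
            x = (rng.random(n) < p[0]).astype(float)
            haplotypes[hap, :, col] = x
            for j in range(1, size):
                cond = p[j] + config.ld_rho * (sd[j] / sd[j - 1]) * (x - p[j - 1])
                np.clip(cond, 0.0, 1.0, out=cond)
                x = (rng.random(n) < cond).astype(float)
                haplotypes[hap, :, col + j] = x
            col += size

    codes = haplotypes[0] + haplotypes[1] - 1.0
    # collapse excess heterozygotes to one of the individual's own
    # haplotypes (as selfing would), which preserves allele frequencies;
    # retention is tuned marker-wise i.i.d. to the configured het fraction
    het = codes == 0.0
    exp_het = float(np.mean(2.0 * freqs * (1.0 - freqs)))
    target = config.residual_heterozygosity
    if exp_het > 0 and target < exp_het:
        retain = target / exp_het
        collapse = het & (rng.random((n, m)) >= retain)
        # one donor haplotype per individual so the collapsed calls keep
        # the chain's marker-to-marker correlation
        pick = rng.integers(0, 2, size=(n, 1))
        collapsed_allele = np.where(pick == 0, haplotypes[0], haplotypes[1])
        codes[collapse] = 2.0 * collapsed_allele[collapse] - 1.0
    elif target > exp_het:
        warnings.warn(
            f"requested heterozygosity {target:.2f} exceeds the panmictic "
            f"expectation {exp_het:.2f} for this allele-frequency "
            "distribution; leaving heterozygotes as drawn", UserWarning,
            stacklevel=2,
        )

    chroms = np.concatenate(
        [np.full(s, i + 1) for i, s in enumerate(sizes)]
    )
    pos = np.concatenate([40_000 * (np.arange(s) + 1) for s in sizes])
    positions = pd.DataFrame({"chrom": chroms.astype(int), "pos": pos.astype(int)})
    marker_ids = [f"chr{c}_{p}" for c, p in zip(positions["chrom"], positions["pos"])]
    mm = MarkerMatrix(codes, config.genotype_ids(), marker_ids, positions=positions,
                      imputed=True)
    mono = int(mm.monomorphic().sum())
    if mono:
        warnings.warn(
            f"{mono} monomorphic markers retained (flagged)", UserWarning,
            stacklevel=2,
        )
    return mm


def _site_genetic_variances(config: SimulationConfig) -> list[float]:
    """Per-site genotypic variance implied by target H2, residual variance
    and replicate count: V = H2/(1-H2) * s2_e / n_rep (V -> large as H2 -> 1)."""
    out = []
    for sc in config.sites:
        h2 = sc.target_h2_trial
        if h2 >= 1.0:
            # perfect repeatability only possible with no residual variance
            out.append(sc.sigma2_residual if sc.sigma2_residual > 0 else 1.0)
            if sc.sigma2_residual > 0:
                warnings.warn(
                    f"site {sc.name}: target_h2_trial=1 with nonzero residual "
                    "variance is unreachable; using V = s2_e", UserWarning,
                    stacklevel=3,
                )
        else:
            out.append(h2 / (1.0 - h2) * sc.sigma2_residual / config.n_replicates)
    return out


def simulate_true_values(markers: MarkerMatrix, config: SimulationConfig) -> TrueValues:
    """Draw genotypic site effects from marker effects with the configured
    between-site correlation and per-site variances.

    For ``r_g >= 0`` the construction is the exact generative mirror of the
    two-site model: a shared marker-effect vector gives ``g`` with
    kernel-scale variance ``r_g * sqrt(V_a V_b)`` and independent
    site-specific vectors give ``gs_site``.  For ``r_g < 0`` a signed-shared
    construction is used and the model-scale ``sigma2_g`` truth is recorded
    as 0 (the two-site model cannot represent negative main-effect
    variance)."""
    if markers.n_genotypes != config.n_genotypes:
        raise ValueError("marker matrix and config disagree on genotype count")
    rng = _rng(config, 1)
    x = markers.values
    if not np.isfinite(x).all():
        raise ValueError("marker matrix must be complete")
    nmk = markers.n_markers
    # column-centred markers: the population mean of X beta is then exactly
    # zero (no random displacement of the trait mean), and REML with the
    # uncentred GBLUP kernel is equivalent because error contrasts are
    # orthogonal to the intercept
    x = x - x.mean(axis=0)
    # expected between-genotype variance of X beta per unit kernel-scale
    # variance: sum_j var(x_j) / N
    mean_diag = realised_gblup_scale(markers)
    if mean_diag <= 0:
        # monomorphic matrix: marker effects cannot separate genotypes
        warnings.warn(
            "markers carry no between-genotype variation: genotypic effects "
            "are zero and the H2 targets are unreachable", UserWarning,
            stacklevel=2,
        )
        mean_diag = np.nan

    v_model = _site_genetic_variances(config)  # realised-effect scale
    vk = [v / mean_diag if np.isfinite(mean_diag) else 0.0 for v in v_model]
    r = config.genetic_correlation
    names = config.site_names

    s2g_target = r * math.sqrt(vk[0] * vk[1])
    feasible = 0.0 <= s2g_target <= min(vk) + 1e-12
    if np.isnan(mean_diag) or max(vk) == 0.0:
        zero = np.zeros(config.n_genotypes)
        effects = {s: zero.copy() for s in names}
        g = zero.copy()
        s2g, s2gs = 0.0, [0.0, 0.0]
    elif feasible:
        # exact generative mirror of the two-site model
        s2g = s2g_target
        s2gs = [max(vk[i] - s2g, 0.0) for i in range(2)]
        beta0 = rng.normal(0.0, math.sqrt(s2g / nmk) if s2g > 0 else 0.0, size=nmk)
        g = x @ beta0
        effects = {}
        for i, s in enumerate(names):
            eta = rng.normal(0.0, math.sqrt(s2gs[i] / nmk) if s2gs[i] > 0 else 0.0,
                             size=nmk)
            effects[s] = g + x @ eta
    else:
        # correlation-exact bivariate construction for r_g < 0 or r_g above
        # the ratio the main+interaction decomposition can represent
        warnings.warn(
            "genetic correlation not representable as a nonnegative main + "
            "site-specific decomposition for these per-site variances; "
            "recorded truth components are the boundary projection",
            UserWarning, stacklevel=2,
        )
        b1 = rng.normal(0.0, math.sqrt(vk[0] / nmk), size=nmk)
        eta = rng.normal(0.0, 1.0, size=nmk)
        b2 = (
            r * math.sqrt(vk[1] / vk[0]) * b1
            + math.sqrt((1.0 - r * r) * vk[1] / nmk) * eta
        )
        effects = {names[0]: x @ b1, names[1]: x @ b2}
        g = 0.5 * (effects[names[0]] + effects[names[1]])
        s2g = float(np.clip(s2g_target, 0.0, min(vk)))
        s2gs = [max(vk[i] - s2g, 0.0) for i in range(2)]

    ids = markers.genotype_ids
    site_effects = pd.DataFrame(effects, index=pd.Index(ids, name="genotype"))
    if site_effects.to_numpy().std() == 0:
        warnings.warn(
            "true genotypic effects are all zero; heritability targets are "
            "unreachable", UserWarning, stacklevel=2,
        )
    truth_vc = {
        "genotype": s2g,
        f"gs_{names[0]}": s2gs[0],
        f"gs_{names[1]}": s2gs[1],
        "block": float(np.mean([sc.sigma2_block for sc in config.sites])),
        f"residual_{names[0]}": config.sites[0].sigma2_residual,
        f"residual_{names[1]}": config.sites[1].sigma2_residual,
    }
    return TrueValues(
        true_main_effect=pd.Series(g, index=site_effects.index, name="g"),
        true_site_effects=site_effects,
        variance_components_truth=truth_vc,
    )


def simulate_trial(truth: TrueValues, config: SimulationConfig) -> pd.DataFrame:
    """Plot-level phenotypes: one record per genotype x replicate x site x
    year.

    ``Y = site mean (+ year shift) + replicate shift + block effect +
    u_site + residual``; blocks follow the incomplete-block lattice (a
    fresh randomisation per site x year x replicate), and a second year
    redraws blocks and residuals with the same genotypic effects
    (generation effect zero)."""
    if len(truth.true_site_effects) != config.n_genotypes:
        raise ValueError("truth and config disagree on genotype count")
    rng = _rng(config, 2)
    ids = list(truth.true_site_effects.index)
    n = len(ids)
    per_block = math.ceil(n / config.n_blocks)
    if n % config.n_blocks:
        warnings.warn(
            f"{n} genotypes do not divide into {config.n_blocks} equal blocks; "
            "allowing unbalanced blocks", UserWarning, stacklevel=2,
        )
    year_effects = config.year_effects or {
        s.name: [0.0] * len(config.years) for s in config.sites
    }
    records = []
    for yi, year in enumerate(config.years):
        for sc in config.sites:
            u = truth.true_site_effects[sc.name].to_numpy()
            shift = year_effects[sc.name][yi]
            for rep in range(1, config.n_replicates + 1):
                rep_eff = rng.normal(0.0, math.sqrt(config.sigma2_rep))
                order = rng.permutation(n)
                block_of = np.empty(n, dtype=int)
                for bi, chunk in enumerate(np.array_split(order, config.n_blocks)):
                    block_of[chunk] = bi + 1
                blocks = rng.normal(
                    0.0, math.sqrt(sc.sigma2_block), size=config.n_blocks
                )
                resid = rng.normal(0.0, math.sqrt(sc.sigma2_residual), size=n)
                y = (
                    sc.trait_mean + shift + rep_eff
                    + blocks[block_of - 1] + u + resid
                )
                records.append(
                    pd.DataFrame(
                        {
                            "genotype": ids,
                            "site": sc.name,
                            "year": year,
                            "rep": rep,
                            "block": block_of,
                            config.trait_name: y,
                        }
                    )
                )
    return pd.concat(records, ignore_index=True)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[MarkerMatrix, TrueValues, pd.DataFrame]:
    """Genotypes, truth and phenotypes in one call (shared seed streams)."""
    markers = simulate_genotypes(config)
    truth = simulate_true_values(markers, config)
    pheno = simulate_trial(truth, config)
    return markers, truth, pheno


def realised_gblup_scale(markers: MarkerMatrix) -> float:
    """Expected between-genotype variance of ``X beta`` per unit of
    kernel-scale variance: ``sum_j var(x_j) / N`` (equals the mean diagonal
    of the GBLUP kernel after column-centring).  Converts kernel-scale
    variance components to realised genotypic variance."""
    x = np.asarray(markers.values, dtype=float)
    return float(np.sum(np.var(x, axis=0)) / markers.n_markers)
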