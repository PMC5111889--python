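"""Monte Carlo propagation of fecundity/fertilization uncertainty.

Fecundity and fertilization success are the two weakest links of the larval
budget, so their pooled means are replaced by independent normal draws
(n = 20,000 by default) and pushed through the deterministic chain

    larvae_i = N × p_mature × a·d̄^b × f_i × φ_i .

Negative draws are kept by default: with untruncated independent draws the
Monte Carlo mean converges exactly to the deterministic product of means,
which keeps the stochastic and deterministic chains mutually checkable.
Truncation at zero is available (``truncate_negative``) and biases the mean
upward.

Diagnostics follow the conventions of the classic moment estimators:
central moments with 1/n normalisation, skewness m₃/m₂^{3/2}, kurtosis
m₄/m₂² (normal reference 3, not excess), and a one-sample Kolmogorov–
Smirnov statistic against a normal with the sample's own mean and SD (the
p-value is asymptotic and approximate because the parameters are
estimated).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .reproduction import AllometryModel, PooledDistribution, tissue_area


@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo settings: draw count, seed, input distributions."""

    fecundity_dist: PooledDistribution
    fertilization_dist: PooledDistribution
    n_draws: int = 20_000
    seed: int | None = None
    truncate_negative: bool = False

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        for dist in (self.fecundity_dist, self.fertilization_dist):
            if dist.sd_defined and dist.sd < 0:
                raise ValueError("distribution SDs must be >= 0")


@dataclass(frozen=True)
class MCSummary:
    """Summary of one Monte Carlo draw vector."""

    mean: float
    sd: float
    skewness: float
    kurtosis: float
    ks_statistic: float
    ks_p: float
    n_draws: int

    def __post_init__(self) -> None:
        if not math.isnan(self.sd) and self.sd < 0:
            raise ValueError("sd must be >= 0")


def sample_skewness(draws: Sequence[float]) -> float:
    """Moment skewness m₃ / m₂^{3/2} with 1/n central moments."""
    x = np.asarray(draws, dtype=float)
    if x.size < 3:
        raise ValueError("skewness requires at least 3 draws")
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 == 0:
        raise ValueError("skewness undefined for zero-variance sample")
    m3 = np.mean((x - m) ** 3)
    return float(m3 / m2 ** 1.5)


def sample_kurtosis(draws: Sequence[float]) -> float:
    """Moment kurtosis m₄ / m₂² (Pearson; normal reference value 3)."""
    x = np.asarray(draws, dtype=float)
    if x.size < 4:
        raise ValueError("kurtosis requires at least 4 draws")
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 == 0:
        raise ValueError("kurtosis undefined for zero-variance sample")
    m4 = np.mean((x - m) ** 4)
    return float(m4 / m2 ** 2)


def ks_normality(draws: Sequence[float]) -> tuple[float, float]:
    """One-sample KS statistic against N(sample mean, sample SD).

    Returns ``(D, p)`` where ``D = sup |F̂(x) − Φ((x−m)/s)|`` and ``p`` comes
    from the asymptotic Kolmogorov distribution.  The p-value is approximate
    (anticonservative) because location and scale are estimated from the
    same sample.
    """
    x = np.asarray(draws, dtype=float)
    if x.size < 5:
        raise ValueError("ks_normality requires at least 5 draws")
    m, s = float(x.mean()), float(x.std(ddof=1))
    if s == 0:
        raise ValueError("ks_normality undefined for zero-variance sample")
    d = float(stats.kstest(x, "norm", args=(m, s)).statistic)
    p = float(stats.kstwobign.sf(d * math.sqrt(x.size)))
    return d, min(max(p, 0.0), 1.0)


def summarize_draws(draws: np.ndarray) -> MCSummary:
    """Full diagnostic summary of a draw vector.

    Moment and KS diagnostics are NaN for degenerate (zero-variance)
    vectors, which arise legitimately when both input SDs are zero or the
    propagated population has no mature colonies.
    """
    x = np.asarray(draws, dtype=float)
    if x.size < 2:
        raise ValueError("summary diagnostics require at least 2 draws")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        nan = float("nan")
        return MCSummary(mean, 0.0, nan, nan, nan, nan, x.size)
    d, p = ks_normality(x)
    return MCSummary(mean, sd, sample_skewness(x), sample_kurtosis(x), d, p, x.size)


def propagate_larval_production(colony_abundance: float, prop_mature: float,
                                mean_mature_diameter_cm: float,
                                allometry: AllometryModel, config: MCConfig,
                                rng: np.random.Generator | None = None,
                                ) -> tuple[MCSummary, np.ndarray]:
    """Propagate input uncertainty through the larval-production chain.

    Each draw samples fecundity and fertilization independently and computes
    ``abundance × prop_mature × a·d^b × f × φ``.  A fixed seed (in ``config``
    or via an explicit ``rng``) makes the draw vector bit-reproducible.
    Returns the summary and the raw draw vector.
    """
    if config.n_draws < 2:
        raise ValueError("diagnostics undefined for n_draws < 2")
    if colony_abundance < 0 or not (0.0 <= prop_mature <= 1.0):
        raise ValueError("invalid abundance or maturity fraction")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    fec, fert = config.fecundity_dist, config.fertilization_dist
    f = rng.normal(fec.mean, fec.sd if fec.sd_defined else 0.0, config.n_draws)
    phi = rng.normal(fert.mean, fert.sd if fert.sd_defined else 0.0, config.n_draws)
    if config.truncate_negative:
        f = np.clip(f, 0.0, None)
        phi = np.clip(phi, 0.0, None)

    if prop_mature == 0 or colony_abundance == 0:
        base = 0.0
    else:
        base = colony_abundance * prop_mature * tissue_area(mean_mature_diameter_cm, allometry)
    draws = base * f * phi
    return summarize_draws(draws), draws
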