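"""Synthetic survey generator with known ground truth.

Every pipeline stage can be exercised against data whose true densities,
cover fractions, size distribution and allometry are known exactly:

* tile and quadrat counts are Poisson (counts of rare settlers/colonies in
  small fixed areas); juvenile counts are binomial thinnings of the colony
  count in the same quadrat, so juveniles ≤ colonies per quadrat while each
  remains marginally Poisson at its own truth;
* point counts are multinomial over the true cover fractions, with an
  implicit "other" remainder category; grid scores likewise over cells;
* colony diameters are lognormal, so the mature fraction above any
  threshold has the closed form P(D ≥ t) = Φ((ln(median) − ln t)/σ);
* allometry calibration pairs are a·d^b with multiplicative lognormal
  noise.

A negative-binomial overdispersion hook exists for counts but is off by
default.  All draws flow through one seeded generator per table, so a
scenario with a fixed seed reproduces its data set bit for bit.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import (ColonyRecord, GridScoreRecord, HabitatSpec, PointCountRecord,
                 QuadratCensusRecord, SamplerSpec, SurveyDataset, TileCensusRecord)

logger = logging.getLogger(__name__)

# fixed per-table offsets so each table has an independent, reproducible stream
_STREAM = {"tiles": 1, "quadrats": 2, "colonies": 3, "points": 4, "grids": 5,
           "allometry": 6}


@dataclass(frozen=True)
class HabitatYearTruth:
    """Ground truth for one habitat-year.

    Densities are per sampler unit: recruit densities per tile scoring area
    and per deployment period; juvenile/colony densities per quadrat.
    ``size_median_cm``/``size_log_sd`` parameterise the lognormal diameter
    distribution; ``cover`` maps benthic category to true cover fraction
    (an ``other`` remainder absorbs the rest).
    """

    habitat: str
    year: int
    recruit_density_per_period: dict = field(default_factory=lambda: {"early": 0.2, "late": 1.0})
    juvenile_density: float = 0.5
    colony_density: float = 1.0
    size_median_cm: float = 8.0
    size_log_sd: float = 0.5
    cover: dict = field(default_factory=dict)
    sites: tuple[str, ...] = ("LTER_1", "LTER_2")
    depths_m: tuple[float, ...] = (10.0,)
    n_tiles: int = 15
    n_quadrats: int = 40
    n_images: int = 40
    n_colonies: int = 100

    def __post_init__(self) -> None:
        if self.juvenile_density > self.colony_density:
            raise ValueError("juvenile density cannot exceed all-colony density")
        for v in (*self.recruit_density_per_period.values(), self.juvenile_density,
                  self.colony_density):
            if v < 0:
                raise ValueError("densities must be >= 0")
        if sum(self.cover.values()) > 1.0 + 1e-12:
            raise ValueError("cover fractions sum above 1")

    def mature_fraction(self, threshold_cm: float) -> float:
        """Closed-form lognormal tail P(D >= threshold)."""
        from scipy.stats import norm
        if self.size_log_sd == 0:
            return float(self.size_median_cm >= threshold_cm)
        z = (np.log(threshold_cm) - np.log(self.size_median_cm)) / self.size_log_sd
        return float(norm.sf(z))


@dataclass(frozen=True)
class SimulationScenario:
    """A full synthetic-survey scenario: truths, geometry, and noise levels."""

    seed: int
    habitats: tuple[HabitatSpec, ...]
    truths: tuple[HabitatYearTruth, ...]
    sampler: SamplerSpec = SamplerSpec()
    allometry_a: float = 2.493
    allometry_b: float = 2.312
    allometry_noise_log_sd: float = 0.0
    n_allometry_pairs: int = 50
    overdispersion: float | None = None  # negative-binomial size; None = Poisson

    def __post_init__(self) -> None:
        names = {h.name for h in self.habitats}
        for t in self.truths:
            if t.habitat not in names:
                raise ValueError(f"truth references unknown habitat {t.habitat!r}")
        for t in self.truths:
            if min(t.n_tiles, t.n_quadrats, t.n_images) < 1:
                raise ValueError("sampling efforts must be >= 1")


def _rng(scenario: SimulationScenario, table: str) -> np.random.Generator:
    return np.random.default_rng([scenario.seed, _STREAM[table]])


def _counts(rng: np.random.Generator, mean: float, size: int,
            overdispersion: float | None) -> np.ndarray:
    if mean == 0:
        return np.zeros(size, dtype=int)
    if overdispersion is None:
        return rng.poisson(mean, size)
    # NB with mean `mean` and size parameter k: p = k / (k + mean)
    k = overdispersion
    return rng.negative_binomial(k, k / (k + mean), size)


def simulate_tiles(scenario: SimulationScenario) -> list[TileCensusRecord]:
    """Poisson recruit counts per tile, period, site and depth."""
    rng = _rng(scenario, "tiles")
    out: list[TileCensusRecord] = []
    for t in scenario.truths:
        for site in t.sites:
            for depth in t.depths_m:
                for period, dens in sorted(t.recruit_density_per_period.items()):
                    counts = _counts(rng, dens, t.n_tiles, scenario.overdispersion)
                    for i, c in enumerate(counts, start=1):
                        out.append(TileCensusRecord(
                            site, t.habitat, depth, t.year, period,
                            f"{site}_{depth:g}m_{period}_{i:03d}", int(c)))
    return out


def simulate_quadrats(scenario: SimulationScenario) -> list[QuadratCensusRecord]:
    """Colony counts (Poisson) with nested juvenile counts (binomial thinning)."""
    rng = _rng(scenario, "quadrats")
    out: list[QuadratCensusRecord] = []
    for t in scenario.truths:
        p_juv = t.juvenile_density / t.colony_density if t.colony_density > 0 else 0.0
        for site in t.sites:
            for depth in t.depths_m:
                colonies = _counts(rng, t.colony_density, t.n_quadrats,
                                   scenario.overdispersion)
                juveniles = rng.binomial(colonies, p_juv)
                for i, (c, j) in enumerate(zip(colonies, juveniles), start=1):
                    qid = f"{site}_{depth:g}m_{i:03d}"
                    out.append(QuadratCensusRecord(site, t.habitat, depth, t.year,
                                                   qid, "all", int(c)))
                    out.append(QuadratCensusRecord(site, t.habitat, depth, t.year,
                                                   qid, "juvenile", int(j)))
    return out


def simulate_colony_sizes(scenario: SimulationScenario) -> list[ColonyRecord]:
    """Lognormal colony diameters (median/log-SD per habitat-year truth)."""
    rng = _rng(scenario, "colonies")
    out: list[ColonyRecord] = []
    for t in scenario.truths:
        if t.n_colonies == 0:
            logger.warning("truth %s %s requests zero colony sizes", t.habitat, t.year)
            continue
        d = np.exp(rng.normal(np.log(t.size_median_cm), t.size_log_sd, t.n_colonies))
        site = t.sites[0]
        out.extend(ColonyRecord(site, t.habitat, t.year, float(x)) for x in d)
    return out


def simulate_point_counts(scenario: SimulationScenario) -> list[PointCountRecord]:
    """Multinomial per-image point counts from true cover fractions."""
    rng = _rng(scenario, "points")
    out: list[PointCountRecord] = []
    n_pts = scenario.sampler.points_per_image
    for t in scenario.truths:
        cats = sorted(t.cover)
        probs = [t.cover[c] for c in cats]
        rest = 1.0 - sum(probs)
        labels = cats + (["other"] if rest > 1e-12 else [])
        if rest > 1e-12:
            probs = probs + [rest]
        for site in t.sites:
            for depth in t.depths_m:
                draws = rng.multinomial(n_pts, probs, size=t.n_images)
                for i, row in enumerate(draws, start=1):
                    counts = {lab: int(n) for lab, n in zip(labels, row)}
                    out.append(PointCountRecord(
                        f"{t.habitat}_{t.year}_{site}_{depth:g}m_{i:03d}",
                        site, t.habitat, depth, t.year, counts))
    return out


def simulate_grid_scores(scenario: SimulationScenario) -> list[GridScoreRecord]:
    """Multinomial dominant-occupant cell counts from true cover fractions."""
    rng = _rng(scenario, "grids")
    out: list[GridScoreRecord] = []
    n_cells = scenario.sampler.grid_cells
    for t in scenario.truths:
        cats = sorted(t.cover)
        probs = [t.cover[c] for c in cats]
        rest = 1.0 - sum(probs)
        labels = cats + (["other"] if rest > 1e-12 else [])
        if rest > 1e-12:
            probs = probs + [rest]
        for site in t.sites:
            draws = rng.multinomial(n_cells, probs, size=t.n_images)
            for i, row in enumerate(draws, start=1):
                counts = {lab: int(n) for lab, n in zip(labels, row)}
                out.append(GridScoreRecord(
                    f"{t.habitat}_{t.year}_{site}_g{i:03d}", site, t.habitat,
                    t.year, counts))
    return out


def simulate_allometry_pairs(scenario: SimulationScenario,
                             d_range: tuple[float, float] = (2.0, 30.0),
                             ) -> list[tuple[float, float]]:
    """(diameter, tissue area) pairs: a·d^b times multiplicative lognormal noise."""
    rng = _rng(scenario, "allometry")
    d = rng.uniform(*d_range, scenario.n_allometry_pairs)
    noise = np.exp(rng.normal(0.0, scenario.allometry_noise_log_sd,
                              scenario.n_allometry_pairs))
    area = scenario.allometry_a * d ** scenario.allometry_b * noise
    return [(float(x), float(y)) for x, y in zip(d, area)]


def simulate_survey(scenario: SimulationScenario) -> SurveyDataset:
    """Generate the complete survey data set for a scenario."""
    ds = SurveyDataset(
        habitats=list(scenario.habitats),
        sampler=scenario.sampler,
        tiles=simulate_tiles(scenario),
        quadrats=simulate_quadrats(scenario),
        colonies=simulate_colony_sizes(scenario),
        points=simulate_point_counts(scenario),
        grids=simulate_grid_scores(scenario),
    )
    return ds.validate()


def default_scenario(seed: int = 0, **overrides) -> SimulationScenario:
    """A two-habitat, two-year scenario at magnitudes typical of a recovering
    Indo-Pacific reef shore (sparse 2010 populations, dense 2014 outer reef)."""
    habitats = (
        HabitatSpec("back_reef", 4.58, (2.0, 5.0), 16.0),
        HabitatSpec("outer_reef", 3.15, (0.0, 17.0), 16.0),
    )
    truths = (
        HabitatYearTruth("back_reef", 2010,
                         recruit_density_per_period={"early": 0.08, "late": 0.30},
                         juvenile_density=0.025, colony_density=0.10,
                         size_median_cm=9.0, size_log_sd=0.45,
                         cover={"scleractinian": 0.20, "pocillopora": 0.002},
                         sites=("BR_1", "BR_2", "BR_3"), depths_m=(2.5,)),
        HabitatYearTruth("back_reef", 2014,
                         recruit_density_per_period={"early": 0.10, "late": 0.37},
                         juvenile_density=0.60, colony_density=0.80,
                         size_median_cm=9.0, size_log_sd=0.55,
                         cover={"scleractinian": 0.10, "pocillopora": 0.001},
                         sites=("BR_1", "BR_2", "BR_3"), depths_m=(2.5,)),
        HabitatYearTruth("outer_reef", 2010,
                         recruit_density_per_period={"early": 0.57, "late": 2.72},
                         juvenile_density=0.26, colony_density=0.30,
                         size_median_cm=6.0, size_log_sd=0.5,
                         cover={"scleractinian": 0.02, "pocillopora": 0.002},
                         depths_m=(10.0, 17.0)),
        HabitatYearTruth("outer_reef", 2014,
                         recruit_density_per_period={"early": 0.20, "late": 0.68},
                         juvenile_density=4.75, colony_density=9.08,
                         size_median_cm=5.0, size_log_sd=0.4,
                         cover={"scleractinian": 0.27, "pocillopora": 0.18},
                         depths_m=(10.0, 17.0)),
    )
    kwargs = {"seed": seed, "habitats": habitats, "truths": truths}
    kwargs.update(overrides)
    return SimulationScenario(**kwargs)
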