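"""Published survey inputs for the north shore of Moorea, French Polynesia.

This module carries the printed values of the 2010–2014/15 *Pocillopora*
spp. census of Moorea's north shore — habitat areas, per-sampler densities,
maturity summaries, and the literature fecundity/fertilization studies —
and recomputes the full larval budget from them with the package's own
operations.  Printed values are inputs here, never expected outputs: the
scaling, pooling, allometry and Monte Carlo arithmetic is all done at run
time.

Two documented bookkeeping choices:

* The back-reef surveys of January 2015 are labelled year 2014 so that
  habitat-year keys align across habitats, matching how the source pairs
  "2014/2015" surveys with the April/May 2014 outer-reef census.
* Where a printed shore-wide abundance is irreconcilable with its own
  printed density (the density having been rounded harder, or the
  arithmetic being internally inconsistent), the printed abundance is
  treated as data and used with a flag, per
  :func:`published_abundances`.

The 2010 maturity proportions as printed (21 % outer reef, 50 % back reef)
do not reproduce either habitat's printed 2010 egg or zygote totals, while
the swapped assignment (50 % outer, 21 % back) reproduces both habitats'
zygote totals and the outer-reef egg total.  Both variants are available
via ``maturity_2010``; the reproducing ("transposed") variant is the
default.  Neither is silently preferred for anything beyond the default.
"""
from __future__ import annotations

import numpy as np

from .abundance import AbundanceEstimate, DensityEstimate, scale_to_habitat
from .io import HabitatSpec, SamplerSpec, TileCensusRecord
from .mc import MCConfig, MCSummary, propagate_larval_production
from .reproduction import (AllometryModel, FecundityStudy, MaturitySummary,
                           PooledDistribution, ReproductionParams,
                           colony_egg_output, pooled_fecundity,
                           population_egg_output, zygote_production)
from .selfseed import SelfSeedingReport, SelfSeedingScenario, build_report

BACK, OUTER = "back_reef", "outer_reef"

#: shore geometry: ~16 km of north shore; hard-bottom areas from satellite imagery
HABITATS = (
    HabitatSpec(BACK, 4.58, (2.0, 5.0), 16.0),
    HabitatSpec(OUTER, 3.15, (0.0, 17.0), 16.0),
)

SAMPLER = SamplerSpec()  # 225 cm² tiles, 0.25 m² quadrats, 200 points, 25 cells

#: published diameter→tissue-area calibration for P. verrucosa (wax dipping)
ALLOMETRY = AllometryModel(coefficient_a=2.493, exponent_b=2.312, r_squared=0.986)

#: the three literature fecundity studies pooled into eggs cm⁻² yr⁻¹
FECUNDITY_STUDIES = (
    FecundityStudy("Maldives_P_verrucosa", 7300.0, "eggs_per_cm2_per_yr", "P. verrucosa"),
    FecundityStudy("RedSea_P_verrucosa", 63.0, "eggs_per_polyp", "P. verrucosa"),
    FecundityStudy("Hawaii_P_meandrina", 114.0, "eggs_per_polyp", "P. meandrina"),
)

#: pooled fertilization success of broadcast spawners (given as mean ± SD;
#: the underlying per-assay observations were not published)
FERTILIZATION = PooledDistribution(mean=0.15, sd=0.21, n_studies=2)

#: printed per-sampler densities: (habitat, year, life_stage) -> density.
#: Recruits are per 225 cm² tile-year; juveniles/colonies per 0.25 m² quadrat.
#: back_reef 2010 juveniles: site means 0.02 and 0.03 print as "0.02", but the
#: printed abundance 4.58e5 pins the unrounded mean 0.025 used here.
DENSITIES = {
    (BACK, 2010, "recruit"): 0.38,
    (OUTER, 2010, "recruit"): 3.29,
    (BACK, 2014, "recruit"): 0.47,
    (OUTER, 2014, "recruit"): 0.88,
    (BACK, 2010, "juvenile"): 0.025,
    (OUTER, 2010, "juvenile"): 0.26,
    (BACK, 2014, "juvenile"): 0.60,
    (OUTER, 2014, "juvenile"): 4.75,
    (BACK, 2010, "all_colonies"): 0.10,
    (OUTER, 2010, "all_colonies"): 0.01,
    (BACK, 2014, "all_colonies"): 0.80,
    (OUTER, 2014, "all_colonies"): 9.08,
}

#: printed shore-wide abundances (the same keys as DENSITIES)
PRINTED_ABUNDANCES = {
    (BACK, 2010, "recruit"): 7.74e7,
    (OUTER, 2010, "recruit"): 4.27e8,
    (BACK, 2014, "recruit"): 9.51e7,
    (OUTER, 2014, "recruit"): 1.23e8,
    (BACK, 2010, "juvenile"): 4.58e5,
    (OUTER, 2010, "juvenile"): 3.21e6,
    (BACK, 2014, "juvenile"): 1.10e7,
    (OUTER, 2014, "juvenile"): 5.98e7,
    (BACK, 2010, "all_colonies"): 1.83e6,
    (OUTER, 2010, "all_colonies"): 9.45e4,
    (BACK, 2014, "all_colonies"): 1.47e7,
    (OUTER, 2014, "all_colonies"): 1.78e8,
}

#: published per-period recruit densities (already site-averaged) for the
#: outer reef in 2010, by depth; early = Jan/Feb, late = Aug/Sep
OUTER_2010_PERIOD_DENSITIES = {
    10.0: {"early": 0.21, "late": 3.37},
    17.0: {"early": 0.93, "late": 2.06},
}

#: published per-site annual recruit densities, back reef 2010
BACK_2010_SITE_DENSITIES = {"BR_1": 0.27, "BR_2": 0.80, "BR_3": 0.07}

#: published maturity summaries as printed: (prop_mature, n_colonies, mean
#: mature diameter cm).  NaN diameter where no colony reached 14 cm.
_MATURITY_PRINTED = {
    (OUTER, 2010): (0.21, 19, 17.1),
    (BACK, 2010): (0.50, 2, 19.1),
    (OUTER, 2014): (0.00, 2245, float("nan")),
    (BACK, 2014): (0.10, 191, 22.3),
}


def habitat(name: str) -> HabitatSpec:
    for h in HABITATS:
        if h.name == name:
            return h
    raise KeyError(name)


def default_params() -> ReproductionParams:
    """Reproduction constants with fecundity pooled from the study table."""
    return ReproductionParams(
        fecundity=pooled_fecundity(FECUNDITY_STUDIES, polyp_density_per_cm2=66.0),
        fertilization=FERTILIZATION,
        allometry=ALLOMETRY,
        maturity_threshold_cm=14.0,
        polyp_density_per_cm2=66.0,
    )


def maturity(maturity_2010: str = "transposed") -> dict[tuple[str, int], MaturitySummary]:
    """Maturity summaries per habitat-year.

    ``maturity_2010="as_printed"`` keeps the 2010 proportions with the
    habitats they are printed against; ``"transposed"`` (default) swaps the
    two 2010 proportions, which is the assignment under which the printed
    2010 egg/zygote totals reproduce.  Mean mature diameters stay with
    their habitats in both variants.
    """
    if maturity_2010 not in ("as_printed", "transposed"):
        raise ValueError(f"unknown maturity_2010 variant {maturity_2010!r}")
    table = dict(_MATURITY_PRINTED)
    if maturity_2010 == "transposed":
        p_outer, n_outer, d_outer = table[(OUTER, 2010)]
        p_back, n_back, d_back = table[(BACK, 2010)]
        table[(OUTER, 2010)] = (p_back, n_outer, d_outer)
        table[(BACK, 2010)] = (p_outer, n_back, d_back)
    out = {}
    for key, (prop, n, d) in table.items():
        n_mat = int(round(prop * n))
        out[key] = MaturitySummary(n_colonies=n, n_mature=min(n_mat, n),
                                   prop_mature=prop, mean_mature_diameter_cm=d)
    return out


def published_densities() -> dict[tuple[str, int, str], DensityEstimate]:
    """The printed densities as :class:`DensityEstimate` objects."""
    out = {}
    for (hab, year, stage), dens in DENSITIES.items():
        area = SAMPLER.tile_scoring_area_cm2 if stage == "recruit" else SAMPLER.quadrat_area_cm2
        out[(hab, year, stage)] = DensityEstimate(hab, year, stage, dens, area)
    return out


def published_abundances(prefer_printed_when_inconsistent: bool = True,
                         rel_tol: float = 0.02) -> list[AbundanceEstimate]:
    """Shore-wide abundances scaled from the printed densities.

    Each printed density is scaled to its habitat's hard-bottom area.  When
    the result disagrees with the printed abundance by more than ``rel_tol``
    (the printed density having been rounded harder than the printed
    abundance, or the two being genuinely inconsistent), the printed
    abundance is substituted and the estimate flagged
    ``printed_abundance_used`` — printed totals are data, not checks.
    """
    out = []
    for key, dens in sorted(published_densities().items()):
        hab, year, stage = key
        est = scale_to_habitat(dens, habitat(hab))
        printed = PRINTED_ABUNDANCES[key]
        rel = abs(est.abundance - printed) / printed
        if prefer_printed_when_inconsistent and rel > rel_tol:
            est = AbundanceEstimate(hab, year, stage, printed, dens,
                                    flags=("printed_abundance_used",))
        out.append(est)
    return out


def outer_reef_2010_tiles(n_tiles_per_group: int = 100) -> list[TileCensusRecord]:
    """Integer tile records whose period means equal the printed outer-reef
    2010 per-depth densities exactly (for exercising the aggregation chain)."""
    recs = []
    for depth, by_period in OUTER_2010_PERIOD_DENSITIES.items():
        for period, mean in by_period.items():
            recs.extend(_tiles_with_mean("LTER_avg", OUTER, depth, 2010, period,
                                         mean, n_tiles_per_group))
    return recs


def back_reef_2010_tiles(n_tiles_per_group: int = 100) -> list[TileCensusRecord]:
    """Tile records reproducing the printed per-site back-reef 2010 annual
    densities (all counts placed in the late period; early period zero)."""
    recs = []
    for site, mean in BACK_2010_SITE_DENSITIES.items():
        recs.extend(_tiles_with_mean(site, BACK, 2.5, 2010, "late", mean,
                                     n_tiles_per_group))
        recs.extend(_tiles_with_mean(site, BACK, 2.5, 2010, "early", 0.0,
                                     n_tiles_per_group))
    return recs


def _tiles_with_mean(site: str, hab: str, depth: float, year: int, period: str,
                     mean: float, n: int) -> list[TileCensusRecord]:
    total = int(round(mean * n))
    if abs(total - mean * n) > 1e-9:
        raise ValueError(f"mean {mean} not representable with {n} integer tiles")
    base, rem = divmod(total, n)
    counts = [base + 1] * rem + [base] * (n - rem)
    return [TileCensusRecord(site, hab, depth, year, period,
                             f"{site}_{depth:g}m_{period}_{i:03d}", c)
            for i, c in enumerate(counts, start=1)]


def reproduction_chains(params: ReproductionParams | None = None,
                        maturity_2010: str = "transposed",
                        abundances: list[AbundanceEstimate] | None = None,
                        ) -> dict[tuple[str, int], dict]:
    """Egg and zygote chains per habitat-year from the published inputs."""
    params = params or default_params()
    abundances = abundances if abundances is not None else published_abundances()
    colonies = {(a.habitat, a.year): a for a in abundances
                if a.life_stage == "all_colonies"}
    mats = maturity(maturity_2010)
    chains = {}
    for key in sorted(colonies):
        mat = mats[key]
        eggs = population_egg_output(colonies[key], mat, params)
        chains[key] = {
            "n_colonies": colonies[key].abundance,
            "prop_mature": mat.prop_mature,
            "mean_mature_diameter_cm": mat.mean_mature_diameter_cm,
            "eggs_per_year": eggs,
            "zygotes_per_year": zygote_production(eggs, params),
        }
    return chains


def larval_budget(seed: int | None = None, loss: float = 0.999,
                  n_draws: int = 20_000, maturity_2010: str = "transposed",
                  params: ReproductionParams | None = None,
                  ) -> tuple[SelfSeedingReport, dict[tuple[str, int], np.ndarray]]:
    """Recompute the whole-shore larval budget from the published inputs.

    Runs density→abundance scaling, the egg/zygote chains, the 20,000-draw
    Monte Carlo per habitat-year, and the self-seeding assessment.  Returns
    the report and the raw Monte Carlo draw vectors keyed by habitat-year.
    """
    params = params or default_params()
    abundances = published_abundances()
    chains = reproduction_chains(params, maturity_2010, abundances)
    mats = maturity(maturity_2010)
    colonies = {(a.habitat, a.year): a for a in abundances
                if a.life_stage == "all_colonies"}

    master = np.random.default_rng(seed)
    mc_summaries: dict[tuple[str, int], MCSummary] = {}
    draws: dict[tuple[str, int], np.ndarray] = {}
    for key in sorted(chains):
        sub_seed = int(master.integers(0, 2**31 - 1))
        cfg = MCConfig(fecundity_dist=params.fecundity,
                       fertilization_dist=params.fertilization,
                       n_draws=n_draws, seed=sub_seed)
        mat = mats[key]
        d = mat.mean_mature_diameter_cm
        summary, vec = propagate_larval_production(
            colonies[key].abundance, mat.prop_mature,
            1.0 if mat.prop_mature == 0 else d, params.allometry, cfg)
        mc_summaries[key] = summary
        draws[key] = vec

    scenario = SelfSeedingScenario(larval_loss_fraction=loss)
    report = build_report(abundances, chains, scenario, mc_summaries, mc_seed=seed)
    return report, draws


def per_colony_egg_outputs(params: ReproductionParams | None = None) -> dict[float, float]:
    """Annual egg output of the mean mature colony for each surveyed mean
    diameter (19.1 cm back reef 2010, 22.3 cm back reef 2014, 17.1 cm outer
    reef 2010)."""
    params = params or default_params()
    return {d: colony_egg_output(d, params) for d in (19.1, 22.3, 17.1)}
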