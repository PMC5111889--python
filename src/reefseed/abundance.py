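"""Sampler densities and shore-wide abundance scaling.

Settlement-tile and quadrat counts are turned into densities per sampler
area, then scaled proportionately to the hard-bottom area of a habitat:

    abundance = (density / sampler_area_cm2) * habitat_area_cm2

Annual recruit density sums the two deployment-period means (Jan/Feb and
Aug/Sep deployments) and then averages across sites and across depths, in
that order.  The alternative ``pooled`` weighting divides total counts by
total sampler effort, which matters when sites contribute unequal numbers
of tiles or quadrats.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import (HabitatSpec, QuadratCensusRecord, SamplerSpec,
                 TileCensusRecord, VALID_PERIODS, ValidationError)

Weighting = Literal["simple", "pooled"]

#: life-stage labels used on density/abundance estimates
LIFE_STAGES = ("recruit", "juvenile", "all_colonies")

_STAGE_FROM_QUADRAT = {"juvenile": "juvenile", "all": "all_colonies"}


@dataclass
class DensityEstimate:
    """A density per sampler area with its aggregation trace.

    ``averaging_trace`` records each aggregation level (tile/period means,
    period sums, site means, depth means) so any printed chain can be audited.
    ``partial`` marks an annual recruit density built from fewer than two
    deployment periods.
    """

    habitat: str
    year: int
    life_stage: str
    density: float
    sampler_area_cm2: float
    averaging_trace: list = field(default_factory=list)
    partial: bool = False

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.sampler_area_cm2 <= 0:
            raise ValueError("sampler_area_cm2 must be > 0")

    @property
    def per_cm2(self) -> float:
        return self.density / self.sampler_area_cm2


@dataclass
class AbundanceEstimate:
    """A shore-wide abundance and the density it was scaled from."""

    habitat: str
    year: int
    life_stage: str
    abundance: float
    source_density: DensityEstimate | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ValueError("abundance must be >= 0")


def _single_habitat_year(df: pd.DataFrame, what: str) -> tuple[str, int]:
    habs, years = df["habitat"].unique(), df["year"].unique()
    if len(habs) != 1 or len(years) != 1:
        raise ValidationError(
            f"{what} must cover exactly one habitat-year "
            f"(got habitats {sorted(habs)}, years {sorted(years)})")
    return str(habs[0]), int(years[0])


def annual_recruit_density(tiles: Sequence[TileCensusRecord], sampler: SamplerSpec,
                           weighting: Weighting = "simple") -> DensityEstimate:
    """Annual recruit density for one habitat-year.

    Simple weighting: mean tile count per (site, depth, period); sum over
    the (at most two) periods per (site, depth); mean across sites within
    each depth; mean across depths.  Pooled weighting: per-period mean over
    all tiles regardless of site/depth, summed over periods.
    """
    if not tiles:
        raise ValidationError("no tile records supplied")
    df = pd.DataFrame(
        [(t.site, t.habitat, t.depth_m, t.year, t.period, t.recruit_count) for t in tiles],
        columns=["site", "habitat", "depth_m", "year", "period", "count"])
    habitat, year = _single_habitat_year(df, "annual_recruit_density")

    periods = sorted(df["period"].unique())
    partial = len(periods) < len(VALID_PERIODS)
    trace: list = []

    if weighting == "pooled":
        period_means = df.groupby("period")["count"].mean()
        trace.append(("period_pooled_mean", period_means.to_dict()))
        density = float(period_means.sum())
    elif weighting == "simple":
        per_sdp = df.groupby(["site", "depth_m", "period"])["count"].mean()
        trace.append(("tile_period_mean", {str(k): float(v) for k, v in per_sdp.items()}))
        annual_sd = per_sdp.groupby(["site", "depth_m"]).sum()
        trace.append(("period_sum", {str(k): float(v) for k, v in annual_sd.items()}))
        per_depth = annual_sd.groupby("depth_m").mean()
        trace.append(("site_mean_by_depth", {float(k): float(v) for k, v in per_depth.items()}))
        density = float(per_depth.mean())
        trace.append(("depth_mean", density))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    return DensityEstimate(habitat, year, "recruit", density,
                           sampler.tile_scoring_area_cm2, trace, partial)


def mean_quadrat_density(quadrats: Sequence[QuadratCensusRecord], sampler: SamplerSpec,
                         weighting: Weighting = "simple") -> DensityEstimate:
    """Mean colony density per quadrat for one habitat-year-stage.

    Simple weighting averages depth means within sites then site means;
    pooled weighting is total colonies over total quadrats.
    """
    if not quadrats:
        raise ValidationError("no quadrat records supplied")
    stages = {q.life_stage for q in quadrats}
    if len(stages) != 1:
        raise ValidationError(f"quadrat records mix life stages {sorted(stages)}")
    df = pd.DataFrame(
        [(q.site, q.habitat, q.depth_m, q.year, q.colony_count) for q in quadrats],
        columns=["site", "habitat", "depth_m", "year", "count"])
    habitat, year = _single_habitat_year(df, "mean_quadrat_density")
    trace: list = []

    if weighting == "pooled":
        density = float(df["count"].sum() / len(df))
        trace.append(("pooled", {"total": int(df["count"].sum()), "n_quadrats": len(df)}))
    elif weighting == "simple":
        per_sd = df.groupby(["site", "depth_m"])["count"].mean()
        trace.append(("quadrat_mean", {str(k): float(v) for k, v in per_sd.items()}))
        per_site = per_sd.groupby("site").mean()
        trace.append(("depth_mean_by_site", {str(k): float(v) for k, v in per_site.items()}))
        density = float(per_site.mean())
        trace.append(("site_mean", density))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    stage = _STAGE_FROM_QUADRAT[stages.pop()]
    return DensityEstimate(habitat, year, stage, density, sampler.quadrat_area_cm2, trace)


def scale_to_habitat(density: DensityEstimate, habitat: HabitatSpec) -> AbundanceEstimate:
    """Scale a per-sampler density to the habitat's hard-bottom area."""
    if habitat.hard_bottom_area_cm2 <= 0:
        raise ValueError("habitat area must be > 0")
    if density.habitat != habitat.name:
        raise ValidationError(
            f"density is for habitat {density.habitat!r}, not {habitat.name!r}")
    abundance = density.per_cm2 * habitat.hard_bottom_area_cm2
    flags = ("partial_year",) if density.partial else ()
    return AbundanceEstimate(density.habitat, density.year, density.life_stage,
                             abundance, density, flags)


def fold_change(later: DensityEstimate | AbundanceEstimate,
                earlier: DensityEstimate | AbundanceEstimate) -> float:
    """Ratio later/earlier for two estimates of the same kind and stage."""
    if type(later) is not type(earlier):
        raise ValidationError("fold_change requires two estimates of the same kind")
    if later.life_stage != earlier.life_stage:
        raise ValidationError(
            f"life-stage mismatch: {later.life_stage!r} vs {earlier.life_stage!r}")
    if later.habitat != earlier.habitat:
        raise ValidationError(f"habitat mismatch: {later.habitat!r} vs {earlier.habitat!r}")
    if isinstance(later, DensityEstimate):
        if not np.isclose(later.sampler_area_cm2, earlier.sampler_area_cm2):
            raise ValidationError("sampler-area (unit) mismatch between densities")
        a, b = later.density, earlier.density
    else:
        a, b = later.abundance, earlier.abundance
    if b <= 0:
        raise ValidationError("fold change undefined for zero baseline")
    return a / b
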