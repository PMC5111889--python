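"""Self-seeding sufficiency assessment.

Combines larval production (zygotes, taken as the best available estimate
of larvae), observed recruit abundances, and juvenile abundances into a
feasibility verdict: could the shore's own populations have produced the
larvae behind the recruitment that was observed?  The key scenario
parameter is the fraction of larvae assumed lost (died, exported, or failed
to settle) — an assumption, not an estimate — so the assessment is swept
over a grid of loss fractions rather than pinned to one.

    larvae_required = recruits / (1 − loss)
    sufficiency    = larvae_produced / larvae_required   (> 1 ⇒ excess)
    survival       = juveniles / recruits                (fraction needed)

A survival fraction above 1 is reported with an implausibility flag, never
clamped.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import AbundanceEstimate
from .io import sig3
from .mc import MCSummary


@dataclass(frozen=True)
class SelfSeedingScenario:
    """Assumptions of the assessment.

    ``larval_loss_fraction`` is the headline assumption (default 0.999,
    i.e. ~99.9 % of larvae never recruit locally); ``loss_grid`` is the
    sensitivity sweep.  ``lag_years`` shifts which recruitment year a
    production year is compared against (0 = same year).
    """

    larval_loss_fraction: float = 0.999
    loss_grid: tuple[float, ...] = (0.9, 0.99, 0.999)
    lag_years: int = 0

    def __post_init__(self) -> None:
        for loss in (self.larval_loss_fraction, *self.loss_grid):
            if not (0.0 <= loss < 1.0):
                raise ValueError(f"loss fraction must be in [0, 1) (got {loss})")


class ReconciliationError(ValueError):
    """Component tables disagree on habitat/year keys."""


def required_larvae(recruits: float, scenario: SelfSeedingScenario,
                    loss: float | None = None) -> float:
    """Larvae needed to yield ``recruits`` under the assumed loss fraction."""
    if recruits < 0:
        raise ValueError("recruits must be >= 0")
    loss = scenario.larval_loss_fraction if loss is None else loss
    if not (0.0 <= loss < 1.0):
        raise ValueError("loss fraction of 1 would require infinite larvae")
    return recruits / (1.0 - loss)


def sufficiency_ratio(produced: float, required: float) -> float:
    """Produced/required larvae; > 1 means production exceeds requirement."""
    if required <= 0:
        raise ValueError("sufficiency undefined when no larvae are required")
    if produced < 0:
        raise ValueError("produced must be >= 0")
    return produced / required


def recruit_to_juvenile_survival(juveniles: float, recruits: float) -> float:
    """Fraction of recruits that must survive to yield the observed juveniles."""
    if recruits <= 0:
        raise ValueError("survival undefined for zero recruits")
    if juveniles < 0:
        raise ValueError("juveniles must be >= 0")
    return juveniles / recruits


@dataclass
class SelfSeedingReport:
    """Assembled assessment with full provenance.

    ``table`` holds one row per habitat-year plus ``all``-habitat totals;
    ``abundance_table``, ``reproduction_table`` and ``mc_table`` carry the
    upstream components; ``gaps`` lists inputs that were explicitly absent
    (never silently zeroed) and ``flags`` lists plausibility warnings.
    """

    table: pd.DataFrame
    abundance_table: pd.DataFrame
    reproduction_table: pd.DataFrame
    mc_table: pd.DataFrame
    loss_sweep: pd.DataFrame
    scenario: SelfSeedingScenario
    gaps: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def render_text(self) -> str:
        """Human-readable summary; numbers shown at 3 significant figures."""
        lines = ["Self-seeding sufficiency assessment",
                 "=" * 37,
                 f"Assumed larval loss fraction: {self.scenario.larval_loss_fraction}",
                 ""]
        for _, r in self.table.iterrows():
            lines.append(
                f"{r['habitat']:>10s} {int(r['year'])}: produced {sig3(r['larvae_produced'])} "
                f"larvae, required {sig3(r['larvae_required'])} "
                f"(sufficiency {sig3(r['sufficiency_ratio'])}), "
                f"recruit->juvenile survival {sig3(r['recruit_to_juvenile_survival'])}")
        if self.gaps:
            lines += ["", "Missing inputs:"] + [f"  - {g}" for g in self.gaps]
        if self.flags:
            lines += ["", "Flags:"] + [f"  - {f}" for f in self.flags]
        lines.append("")
        return "\n".join(lines)


def _stage_map(abundances: Sequence[AbundanceEstimate], stage: str) -> dict:
    return {(a.habitat, a.year): a for a in abundances if a.life_stage == stage}


def build_report(abundances: Sequence[AbundanceEstimate],
                 chains: Mapping[tuple[str, int], Mapping[str, float]],
                 scenario: SelfSeedingScenario,
                 mc_summaries: Mapping[tuple[str, int], MCSummary] | None = None,
                 mc_seed: int | None = None) -> SelfSeedingReport:
    """Assemble the full assessment.

    Parameters
    ----------
    abundances : sequence of AbundanceEstimate
        Shore-wide abundances for recruits, juveniles and all colonies.
    chains : mapping
        (habitat, year) → reproduction chain dict with keys ``n_colonies``,
        ``prop_mature``, ``mean_mature_diameter_cm``, ``eggs_per_year``,
        ``zygotes_per_year``.
    scenario : SelfSeedingScenario
    mc_summaries : mapping, optional
        (habitat, year) → :class:`MCSummary` for the zygote chain.
    """
    recruits = _stage_map(abundances, "recruit")
    juveniles = _stage_map(abundances, "juvenile")
    colonies = _stage_map(abundances, "all_colonies")

    for key in chains:
        if key not in colonies:
            raise ReconciliationError(
                f"reproduction chain for {key} has no matching all-colonies abundance")

    gaps: list[str] = []
    flags: list[str] = []
    habitats = sorted({a.habitat for a in abundances})
    years = sorted({a.year for a in abundances})

    abundance_rows = []
    for a in sorted(abundances, key=lambda a: (a.habitat, a.year, a.life_stage)):
        d = a.source_density
        abundance_rows.append({
            "habitat": a.habitat, "year": a.year, "life_stage": a.life_stage,
            "density": d.density if d else float("nan"),
            "sampler_area_cm2": d.sampler_area_cm2 if d else float("nan"),
            "abundance": a.abundance, "flags": ";".join(a.flags)})
        flags.extend(f"{a.habitat} {a.year} {a.life_stage}: {f}" for f in a.flags)
    abundance_table = pd.DataFrame(abundance_rows, columns=[
        "habitat", "year", "life_stage", "density", "sampler_area_cm2",
        "abundance", "flags"])

    repro_rows = []
    for (hab, year), ch in sorted(chains.items()):
        repro_rows.append({
            "habitat": hab, "year": year,
            "n_colonies": ch.get("n_colonies", float("nan")),
            "prop_mature": ch.get("prop_mature", float("nan")),
            "mean_mature_diameter_cm": ch.get("mean_mature_diameter_cm", float("nan")),
            "eggs_per_year": ch.get("eggs_per_year", float("nan")),
            "zygotes_per_year": ch.get("zygotes_per_year", float("nan"))})
    reproduction_table = pd.DataFrame(repro_rows, columns=[
        "habitat", "year", "n_colonies", "prop_mature", "mean_mature_diameter_cm",
        "eggs_per_year", "zygotes_per_year"])

    mc_rows = []
    for (hab, year), s in sorted((mc_summaries or {}).items()):
        mc_rows.append({"habitat": hab, "year": year, "n_draws": s.n_draws,
                        "seed": mc_seed, "mean": s.mean, "sd": s.sd,
                        "skewness": s.skewness, "kurtosis": s.kurtosis,
                        "ks_statistic": s.ks_statistic, "ks_p": s.ks_p})
    mc_table = pd.DataFrame(mc_rows, columns=[
        "habitat", "year", "n_draws", "seed", "mean", "sd", "skewness",
        "kurtosis", "ks_statistic", "ks_p"])

    nan = float("nan")

    def assess(hab_label: str, year: int, produced: float | None,
               recr: float | None, juv: float | None) -> dict:
        row = {"habitat": hab_label, "year": year,
               "larvae_produced": nan if produced is None else produced,
               "recruits_observed": nan if recr is None else recr,
               "larvae_required": nan, "sufficiency_ratio": nan,
               "recruit_to_juvenile_survival": nan}
        if recr is not None and recr > 0:
            req = required_larvae(recr, scenario)
            row["larvae_required"] = req
            if produced is not None:
                row["sufficiency_ratio"] = sufficiency_ratio(produced, req)
            if juv is not None:
                surv = recruit_to_juvenile_survival(juv, recr)
                row["recruit_to_juvenile_survival"] = surv
                if surv > 1:
                    flags.append(f"{hab_label} {year}: implausible survival fraction "
                                 f"{surv:.3g} > 1")
        return row

    rows = []
    for year in years:
        recr_year = year + scenario.lag_years
        produced_total = 0.0
        produced_all_present = True
        recr_total = 0.0
        recr_all_present = True
        juv_total = 0.0
        juv_all_present = True
        for hab in habitats:
            ch = chains.get((hab, year))
            produced = ch["zygotes_per_year"] if ch else None
            if produced is None:
                produced_all_present = False
                gaps.append(f"{hab} {year}: larval production missing")
            else:
                produced_total += produced
            ra = recruits.get((hab, recr_year))
            recr = ra.abundance if ra else None
            if recr is None:
                recr_all_present = False
                gaps.append(f"{hab} {recr_year}: recruit abundance missing")
            else:
                recr_total += recr
            ja = juveniles.get((hab, recr_year))
            juv = ja.abundance if ja else None
            if juv is None:
                juv_all_present = False
            else:
                juv_total += juv
            rows.append(assess(hab, year, produced, recr, juv))
        rows.append(assess("all", year,
                           produced_total if produced_all_present else None,
                           recr_total if recr_all_present else None,
                           juv_total if juv_all_present else None))

    table = pd.DataFrame(rows, columns=[
        "habitat", "year", "larvae_produced", "recruits_observed",
        "larvae_required", "sufficiency_ratio", "recruit_to_juvenile_survival"])

    sweep_rows = []
    for loss in scenario.loss_grid:
        for _, r in table[table["habitat"] == "all"].iterrows():
            if math.isnan(r["recruits_observed"]) or r["recruits_observed"] <= 0 \
                    or math.isnan(r["larvae_produced"]):
                continue
            req = required_larvae(r["recruits_observed"], scenario, loss=loss)
            sweep_rows.append({"year": int(r["year"]), "larval_loss_fraction": loss,
                               "larvae_required": req,
                               "sufficiency_ratio": sufficiency_ratio(
                                   r["larvae_produced"], req)})
    loss_sweep = pd.DataFrame(sweep_rows, columns=[
        "year", "larval_loss_fraction", "larvae_required", "sufficiency_ratio"])

    return SelfSeedingReport(table, abundance_table, reproduction_table, mc_table,
                             loss_sweep, scenario, gaps, flags)
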