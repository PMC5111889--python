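"""Model/Results facade over the larval-budget pipeline.

:class:`LarvalBudgetModel` is constructed from a :class:`~reefseed.io.SurveyDataset`
plus reproduction/Monte-Carlo/scenario settings; :meth:`LarvalBudgetModel.fit`
runs the stage sequence

    cover → densities → abundances → maturity → egg/zygote chains
          → Monte Carlo → self-seeding assessment

and returns a :class:`LarvalBudgetResults` carrying every intermediate
estimate, the Monte Carlo diagnostics, and a ``summary()`` table.  Any stage
failure aborts with the stage name attached.
"""
from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import moorea
from .abundance import (AbundanceEstimate, DensityEstimate, annual_recruit_density,
                        mean_quadrat_density, scale_to_habitat)
from .cover import CoverEstimate, summarize_cover
from .io import (SurveyDataset, config_hash, load_config, read_dataset, sig3,
                 write_report_tables)
from .mc import MCConfig, MCSummary, propagate_larval_production
from .reproduction import (AllometryModel, FecundityStudy, MaturitySummary,
                           PooledDistribution, ReproductionParams,
                           classify_maturity, pooled_fecundity,
                           population_egg_output, zygote_production)
from .selfseed import SelfSeedingReport, SelfSeedingScenario, build_report


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def params_from_config(cfg: Mapping[str, Any]) -> ReproductionParams:
    """Build :class:`ReproductionParams` from a config mapping.

    Fecundity can be given either as a ``fecundity_studies`` list (pooled at
    build time) or as a pre-pooled ``fecundity: {mean, sd, n_studies}``.
    Missing sections fall back to the published study constants.
    """
    rep = dict(cfg.get("reproduction") or {})
    polyps = float(rep.get("polyp_density_per_cm2", 66.0))

    if "fecundity_studies" in rep:
        studies = [FecundityStudy(str(s["study"]), float(s["value"]), str(s["unit"]),
                                  str(s.get("taxon", ""))) for s in rep["fecundity_studies"]]
        fec = pooled_fecundity(studies, polyps)
    elif "fecundity" in rep:
        f = rep["fecundity"]
        fec = PooledDistribution(float(f["mean"]), float(f.get("sd", float("nan"))),
                                 int(f.get("n_studies", 1)))
    else:
        fec = pooled_fecundity(moorea.FECUNDITY_STUDIES, polyps)

    if "fertilization" in rep:
        f = rep["fertilization"]
        fert = PooledDistribution(float(f["mean"]), float(f.get("sd", float("nan"))),
                                  int(f.get("n_studies", 1)))
    else:
        fert = moorea.FERTILIZATION

    if "allometry" in rep:
        a = rep["allometry"]
        allo = AllometryModel(float(a["coefficient_a"]), float(a["exponent_b"]),
                              float(a.get("r_squared", float("nan"))))
    else:
        allo = moorea.ALLOMETRY

    return ReproductionParams(
        fecundity=fec, fertilization=fert, allometry=allo,
        maturity_threshold_cm=float(rep.get("maturity_threshold_cm", 14.0)),
        polyp_density_per_cm2=polyps)


def scenario_from_config(cfg: Mapping[str, Any]) -> SelfSeedingScenario:
    sc = dict(cfg.get("scenario") or {})
    return SelfSeedingScenario(
        larval_loss_fraction=float(sc.get("larval_loss_fraction", 0.999)),
        loss_grid=tuple(sc.get("loss_grid", (0.9, 0.99, 0.999))),
        lag_years=int(sc.get("lag_years", 0)))


class LarvalBudgetModel:
    """Whole-shore larval budget for a broadcast-spawning coral population.

    Parameters
    ----------
    dataset : SurveyDataset
        Census tables plus habitat/sampler metadata.
    params : ReproductionParams, optional
        Reproduction constants; defaults to the published study constants.
    scenario : SelfSeedingScenario, optional
        Larval-loss assumptions for the assessment.
    n_draws : int
        Monte Carlo draws per habitat-year chain (default 20,000).
    truncate_negative : bool
        Clip negative fecundity/fertilization draws at zero (off by default;
        see :mod:`reefseed.mc`).
    coral_category : str
        Benthic category whose cover is summarised alongside total coral.
    weighting : {"simple", "pooled"}
        Density aggregation weighting across sites/depths.
    """

    def __init__(self, dataset: SurveyDataset,
                 params: ReproductionParams | None = None,
                 scenario: SelfSeedingScenario | None = None,
                 n_draws: int = 20_000, truncate_negative: bool = False,
                 coral_category: str = "pocillopora",
                 weighting: str = "simple"):
        self.dataset = dataset.validate()
        self.params = params or moorea.default_params()
        self.scenario = scenario or SelfSeedingScenario()
        self.n_draws = n_draws
        self.truncate_negative = truncate_negative
        self.coral_category = coral_category
        self.weighting = weighting
        self.config_hash_: str | None = None

    @classmethod
    def from_config(cls, config: str | Path | Mapping[str, Any]) -> "LarvalBudgetModel":
        """Build a model (and its data set) from a YAML pipeline config."""
        base = Path(config).parent if isinstance(config, (str, Path)) else Path(".")
        cfg = load_config(config)
        paths = {k: (base / v if not Path(v).is_absolute() else Path(v))
                 for k, v in (cfg.get("paths") or {}).items()}
        dataset = read_dataset(paths, cfg)
        mc_cfg = dict(cfg.get("mc") or {})
        model = cls(dataset,
                    params=params_from_config(cfg),
                    scenario=scenario_from_config(cfg),
                    n_draws=int(mc_cfg.get("n_draws", 20_000)),
                    truncate_negative=bool(mc_cfg.get("truncate_negative", False)),
                    coral_category=str(cfg.get("coral_category", "pocillopora")),
                    weighting=str(cfg.get("weighting", "simple")))
        model.config_hash_ = config_hash(cfg)
        return model

    # -- stages -----------------------------------------------------------

    def _cover_stage(self) -> pd.DataFrame:
        rows: list[CoverEstimate] = []
        records = list(self.dataset.points) + list(self.dataset.grids)
        categories = sorted({c for r in self.dataset.points for c in r.label_counts}
                            | {c for r in self.dataset.grids for c in r.dominant_counts})
        for cat in categories:
            rows.extend(summarize_cover(self.dataset.points, cat, self.dataset.sampler))
            rows.extend(summarize_cover(self.dataset.grids, cat, self.dataset.sampler))
        return pd.DataFrame(
            [(e.site, e.habitat, e.depth_m, e.year, e.category, e.mean_cover,
              e.se_cover, e.n_images) for e in rows],
            columns=["site", "habitat", "depth_m", "year", "category",
                     "mean_cover", "se_cover", "n_images"])

    def _abundance_stage(self) -> tuple[dict, list[AbundanceEstimate]]:
        sampler = self.dataset.sampler
        densities: dict[tuple[str, int, str], DensityEstimate] = {}

        by_hy: dict[tuple[str, int], list] = {}
        for t in self.dataset.tiles:
            by_hy.setdefault((t.habitat, t.year), []).append(t)
        for (hab, year), recs in sorted(by_hy.items()):
            d = annual_recruit_density(recs, sampler, self.weighting)
            densities[(hab, year, "recruit")] = d

        by_hys: dict[tuple[str, int, str], list] = {}
        for q in self.dataset.quadrats:
            by_hys.setdefault((q.habitat, q.year, q.life_stage), []).append(q)
        for (hab, year, stage), recs in sorted(by_hys.items()):
            d = mean_quadrat_density(recs, sampler, self.weighting)
            densities[(hab, year, d.life_stage)] = d

        abundances = [scale_to_habitat(d, self.dataset.habitat(d.habitat))
                      for d in densities.values()]
        return densities, abundances

    def _maturity_stage(self) -> dict[tuple[str, int], MaturitySummary]:
        by_hy: dict[tuple[str, int], list] = {}
        for c in self.dataset.colonies:
            by_hy.setdefault((c.habitat, c.year), []).append(c)
        return {key: classify_maturity(recs, self.params)
                for key, recs in sorted(by_hy.items())}

    def fit(self, seed: int | None = None) -> "LarvalBudgetResults":
        """Run the full pipeline; ``seed`` drives all Monte Carlo draws."""
        try:
            cover = self._cover_stage()
        except Exception as exc:
            raise StageError("cover", exc) from exc
        try:
            densities, abundances = self._abundance_stage()
        except Exception as exc:
            raise StageError("abundance", exc) from exc
        try:
            maturity = self._maturity_stage()
            chains: dict[tuple[str, int], dict] = {}
            colony_ab = {(a.habitat, a.year): a for a in abundances
                         if a.life_stage == "all_colonies"}
            for key in sorted(colony_ab):
                if key not in maturity:
                    continue  # no size survey: chain reported as a gap downstream
                mat = maturity[key]
                eggs = population_egg_output(colony_ab[key], mat, self.params)
                chains[key] = {
                    "n_colonies": colony_ab[key].abundance,
                    "prop_mature": mat.prop_mature,
                    "mean_mature_diameter_cm": mat.mean_mature_diameter_cm,
                    "eggs_per_year": eggs,
                    "zygotes_per_year": zygote_production(eggs, self.params)}
        except Exception as exc:
            raise StageError("reproduction", exc) from exc
        try:
            master = np.random.default_rng(seed)
            mc_summaries: dict[tuple[str, int], MCSummary] = {}
            draws: dict[tuple[str, int], np.ndarray] = {}
            for key in sorted(chains):
                cfg = MCConfig(fecundity_dist=self.params.fecundity,
                               fertilization_dist=self.params.fertilization,
                               n_draws=self.n_draws,
                               seed=int(master.integers(0, 2**31 - 1)),
                               truncate_negative=self.truncate_negative)
                mat = maturity[key]
                d = mat.mean_mature_diameter_cm
                summary, vec = propagate_larval_production(
                    colony_ab[key].abundance, mat.prop_mature,
                    1.0 if mat.prop_mature == 0 else d, self.params.allometry, cfg)
                mc_summaries[key] = summary
                draws[key] = vec
        except Exception as exc:
            raise StageError("mc", exc) from exc
        try:
            report = build_report(abundances, chains, self.scenario,
                                  mc_summaries, mc_seed=seed)
        except Exception as exc:
            raise StageError("assess", exc) from exc

        return LarvalBudgetResults(self, seed, cover, densities, abundances,
                                   maturity, chains, mc_summaries, draws, report)


class LarvalBudgetResults:
    """Fitted larval budget: estimates, uncertainties, diagnostics."""

    def __init__(self, model: LarvalBudgetModel, seed: int | None,
                 cover: pd.DataFrame, densities: dict,
                 abundances: list[AbundanceEstimate], maturity: dict,
                 chains: dict, mc: dict, draws: dict,
                 report: SelfSeedingReport):
        self.model = model
        self.seed = seed
        self.cover = cover
        self.densities = densities
        self.abundances = abundances
        self.maturity = maturity
        self.chains = chains
        self.mc = mc
        self.draws = draws
        self.report = report

    @property
    def abundance_table(self) -> pd.DataFrame:
        return self.report.abundance_table

    @property
    def assessment(self) -> pd.DataFrame:
        return self.report.table

    def summary(self) -> str:
        """Plain-text summary of the fitted budget."""
        p = self.model.params
        lines = [
            "Larval budget summary",
            "=" * 60,
            f"Seed: {self.seed}   MC draws per chain: {self.model.n_draws}",
            f"Fecundity: {sig3(p.fecundity.mean)} ± {sig3(p.fecundity.sd)} eggs cm⁻² yr⁻¹ "
            f"(n={p.fecundity.n_studies} studies)",
            f"Fertilization: {p.fertilization.mean:.2f} ± {p.fertilization.sd:.2f}",
            f"Allometry: area = {p.allometry.coefficient_a} · d^{p.allometry.exponent_b}",
            f"Maturity threshold: ≥ {p.maturity_threshold_cm} cm",
            "",
            "Shore-wide abundances",
            "-" * 60,
        ]
        for a in sorted(self.abundances, key=lambda a: (a.habitat, a.year, a.life_stage)):
            lines.append(f"  {a.habitat:>10s} {a.year} {a.life_stage:>12s}: "
                         f"{sig3(a.abundance)}" + (f"  [{';'.join(a.flags)}]" if a.flags else ""))
        lines += ["", "Egg/zygote chains", "-" * 60]
        for (hab, year), ch in sorted(self.chains.items()):
            mc = self.mc.get((hab, year))
            mc_txt = (f"  MC mean {sig3(mc.mean)} ± {sig3(mc.sd)}" if mc else "")
            lines.append(f"  {hab:>10s} {year}: eggs {sig3(ch['eggs_per_year'])}, "
                         f"zygotes {sig3(ch['zygotes_per_year'])}{mc_txt}")
        lines += ["", self.report.render_text()]
        return "\n".join(lines)

    def to_csv(self, out_dir: str | Path) -> list[Path]:
        """Write all report tables (plus the cover summary) to ``out_dir``."""
        written = write_report_tables(self.report, out_dir)
        if not self.cover.empty:
            p = Path(out_dir) / "cover_summary.csv"
            self.cover.to_csv(p, index=False)
            written.append(p)
        return written

    def plot_chain(self, ax=None):
        """Bar chart of the four-stage abundance chain per habitat-year."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        stages = ["zygotes", "recruit", "juvenile", "all_colonies"]
        ab = {(a.habitat, a.year, a.life_stage): a.abundance for a in self.abundances}
        keys = sorted({(a.habitat, a.year) for a in self.abundances})
        width = 0.8 / max(len(keys), 1)
        x = np.arange(len(stages))
        for i, (hab, year) in enumerate(keys):
            vals = [self.chains.get((hab, year), {}).get("zygotes_per_year", np.nan),
                    ab.get((hab, year, "recruit"), np.nan),
                    ab.get((hab, year, "juvenile"), np.nan),
                    ab.get((hab, year, "all_colonies"), np.nan)]
            ax.bar(x + i * width, vals, width, label=f"{hab} {year}")
        ax.set_yscale("log")
        ax.set_xticks(x + width * (len(keys) - 1) / 2)
        ax.set_xticklabels(stages)
        ax.set_ylabel("individuals (log scale)")
        ax.legend(fontsize=8)
        return ax
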