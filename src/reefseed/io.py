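"""Survey data model, CSV readers/writers, and configuration.

All census inputs are plain CSV (comma-separated, UTF-8, header row, "."
decimal separator); the run configuration is YAML.  Areas are stored in the
units surveyors use (km² for habitats, m² or cm² for samplers) but every
scaling computation goes through cm² — one unit system internally avoids
silent km²/m² slips.

The container types are frozen dataclasses with invariant checks in
``__post_init__``; readers translate those checks into errors that cite the
offending table and 1-based data-row number.
"""
from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

KM2_TO_CM2 = 1e10
M2_TO_CM2 = 1e4

VALID_PERIODS = ("early", "late")  # early = Jan/Feb deployment, late = Aug/Sep
VALID_QUADRAT_STAGES = ("juvenile", "all")  # juvenile: colonies <= 4 cm diameter

#: canonical file name for each table of a survey data set
TABLE_FILES = {
    "tiles": "tile_census.csv",
    "quadrats": "quadrat_census.csv",
    "colonies": "colony_sizes.csv",
    "points": "point_counts.csv",
    "grids": "grid_scores.csv",
}

TABLE_COLUMNS = {
    "tiles": ["site", "habitat", "depth_m", "year", "period", "tile_id", "recruit_count"],
    "quadrats": ["site", "habitat", "depth_m", "year", "quadrat_id", "life_stage", "colony_count"],
    "colonies": ["site", "habitat", "year", "diameter_cm"],
    "points": ["image_id", "site", "habitat", "depth_m", "year", "category", "points"],
    "grids": ["image_id", "site", "habitat", "year", "category", "cells"],
}


class SchemaError(ValueError):
    """A table is missing a required column."""


class ValidationError(ValueError):
    """A row violates a record invariant; the message cites table and row."""


class UnknownHabitatError(ValidationError):
    """A record references a habitat absent from the configuration."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HabitatSpec:
    """A reef habitat with a known hard-bottom area.

    Parameters
    ----------
    name : str
        Habitat label, e.g. ``"back_reef"`` or ``"outer_reef"``.
    hard_bottom_area_km2 : float
        Planar hard-bottom area available for settlement, km².
    depth_range_m : tuple of float
        (shallow, deep) depth limits in metres, informational.
    shore_length_km : float, optional
        Length of shore the habitat spans, informational.
    """

    name: str
    hard_bottom_area_km2: float
    depth_range_m: tuple[float, float] = (0.0, 0.0)
    shore_length_km: float | None = None

    def __post_init__(self) -> None:
        if self.hard_bottom_area_km2 <= 0:
            raise ValueError(f"hard_bottom_area_km2 must be > 0 (got {self.hard_bottom_area_km2})")
        lo, hi = self.depth_range_m
        if lo > hi:
            raise ValueError(f"depth_range_m must be ascending (got {self.depth_range_m})")
        object.__setattr__(self, "depth_range_m", (float(lo), float(hi)))

    @property
    def hard_bottom_area_cm2(self) -> float:
        return self.hard_bottom_area_km2 * KM2_TO_CM2


@dataclass(frozen=True)
class SamplerSpec:
    """Geometry of the sampling devices.

    Defaults follow common reef-survey practice: settlement tiles scored on
    their 225 cm² lower surface, 0.5 × 0.5 m quadrats, 200 random points per
    photoquadrat image, and a 25-cell dominance grid (4 % cover resolution).
    """

    tile_scoring_area_cm2: float = 225.0
    quadrat_area_m2: float = 0.25
    points_per_image: int = 200
    grid_cells: int = 25

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be > 0")

    @property
    def quadrat_area_cm2(self) -> float:
        return self.quadrat_area_m2 * M2_TO_CM2


@dataclass(frozen=True)
class TileCensusRecord:
    """Recruit count on one settlement tile for one deployment period."""

    site: str
    habitat: str
    depth_m: float
    year: int
    period: str
    tile_id: str
    recruit_count: int

    def __post_init__(self) -> None:
        if self.period not in VALID_PERIODS:
            raise ValueError(f"period must be one of {VALID_PERIODS} (got {self.period!r})")
        if self.recruit_count < 0:
            raise ValueError(f"recruit_count must be >= 0 (got {self.recruit_count})")


@dataclass(frozen=True)
class QuadratCensusRecord:
    """Colony count in one quadrat for one life stage."""

    site: str
    habitat: str
    depth_m: float
    year: int
    quadrat_id: str
    life_stage: str
    colony_count: int

    def __post_init__(self) -> None:
        if self.life_stage not in VALID_QUADRAT_STAGES:
            raise ValueError(
                f"life_stage must be one of {VALID_QUADRAT_STAGES} (got {self.life_stage!r})"
            )
        if self.colony_count < 0:
            raise ValueError(f"colony_count must be >= 0 (got {self.colony_count})")


@dataclass(frozen=True)
class ColonyRecord:
    """A single colony diameter measurement."""

    site: str
    habitat: str
    year: int
    diameter_cm: float

    def __post_init__(self) -> None:
        if self.diameter_cm <= 0:
            raise ValueError(f"diameter_cm must be > 0 (got {self.diameter_cm})")


@dataclass(frozen=True)
class PointCountRecord:
    """Per-image benthic category point counts from random-point scoring."""

    image_id: str
    site: str
    habitat: str
    depth_m: float
    year: int
    label_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for cat, n in self.label_counts.items():
            if n < 0:
                raise ValueError(f"negative point count for category {cat!r}")

    def total_points(self) -> int:
        return int(sum(self.label_counts.values()))


@dataclass(frozen=True)
class GridScoreRecord:
    """Per-image dominant-occupant cell counts from grid scoring."""

    image_id: str
    site: str
    habitat: str
    year: int
    dominant_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        for cat, n in self.dominant_counts.items():
            if n < 0:
                raise ValueError(f"negative cell count for category {cat!r}")

    def total_cells(self) -> int:
        return int(sum(self.dominant_counts.values()))


@dataclass
class SurveyDataset:
    """All census tables for one shore, plus habitat and sampler metadata."""

    habitats: list[HabitatSpec]
    sampler: SamplerSpec
    tiles: list[TileCensusRecord] = field(default_factory=list)
    quadrats: list[QuadratCensusRecord] = field(default_factory=list)
    colonies: list[ColonyRecord] = field(default_factory=list)
    points: list[PointCountRecord] = field(default_factory=list)
    grids: list[GridScoreRecord] = field(default_factory=list)

    def habitat(self, name: str) -> HabitatSpec:
        for h in self.habitats:
            if h.name == name:
                return h
        raise UnknownHabitatError(f"habitat {name!r} not defined in configuration")

    def validate(self) -> "SurveyDataset":
        names = {h.name for h in self.habitats}
        for kind in ("tiles", "quadrats", "colonies", "points", "grids"):
            for i, rec in enumerate(getattr(self, kind), start=1):
                if rec.habitat not in names:
                    raise UnknownHabitatError(
                        f"{kind} record {i}: habitat {rec.habitat!r} not in config ({sorted(names)})"
                    )
        for i, rec in enumerate(self.points, start=1):
            if rec.total_points() != self.sampler.points_per_image:
                raise ValidationError(
                    f"points record {i} (image {rec.image_id!r}): counts sum to "
                    f"{rec.total_points()}, expected {self.sampler.points_per_image}"
                )
        for i, rec in enumerate(self.grids, start=1):
            if rec.total_cells() != self.sampler.grid_cells:
                raise ValidationError(
                    f"grids record {i} (image {rec.image_id!r}): cells sum to "
                    f"{rec.total_cells()}, expected {self.sampler.grid_cells}"
                )
        return self


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def parse_habitats(entries: Sequence[Mapping[str, Any]]) -> list[HabitatSpec]:
    out = []
    for e in entries:
        out.append(
            HabitatSpec(
                name=str(e["name"]),
                hard_bottom_area_km2=float(e["hard_bottom_area_km2"]),
                depth_range_m=tuple(e.get("depth_range_m", (0.0, 0.0))),
                shore_length_km=e.get("shore_length_km"),
            )
        )
    return out


def parse_sampler(entry: Mapping[str, Any] | None) -> SamplerSpec:
    entry = dict(entry or {})
    return SamplerSpec(
        tile_scoring_area_cm2=float(entry.get("tile_scoring_area_cm2", 225.0)),
        quadrat_area_m2=float(entry.get("quadrat_area_m2", 0.25)),
        points_per_image=int(entry.get("points_per_image", 200)),
        grid_cells=int(entry.get("grid_cells", 25)),
    )


def load_config(config: Mapping[str, Any] | str | Path) -> dict[str, Any]:
    """Load a pipeline configuration from a YAML file or pass a dict through."""
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise SchemaError("configuration must be a mapping")
    if "habitats" not in config:
        raise SchemaError("configuration missing required key 'habitats'")
    return dict(config)


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable short hash of a configuration, for stamping outputs."""
    canon = yaml.safe_dump(_plain(config), sort_keys=True)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:12]


def _plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _plain(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, table: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{table} table not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TABLE_COLUMNS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    return df


def _build_rows(df: pd.DataFrame, table: str, builder) -> list:
    """Build one record per row, wrapping invariant failures with row numbers."""
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(builder(row))
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{TABLE_FILES.get(table, table)} row {i}: {exc}") from exc
    return out


def read_dataset(paths: Mapping[str, str | Path],
                 config: Mapping[str, Any] | str | Path) -> SurveyDataset:
    """Read and validate a full survey data set.

    Parameters
    ----------
    paths : mapping
        Table name (``tiles``, ``quadrats``, ``colonies``, ``points``,
        ``grids``) to CSV path.  Absent tables are simply empty.
    config : mapping or path
        Pipeline configuration carrying at least ``habitats`` and, optionally,
        ``sampler``.
    """
    cfg = load_config(config)
    habitats = parse_habitats(cfg["habitats"])
    sampler = parse_sampler(cfg.get("sampler"))
    ds = SurveyDataset(habitats=habitats, sampler=sampler)

    if "tiles" in paths:
        df = _read_table(paths["tiles"], "tiles")
        ds.tiles = _build_rows(df, "tiles", lambda r: TileCensusRecord(
            str(r.site), str(r.habitat), float(r.depth_m), int(r.year),
            str(r.period), str(r.tile_id), int(r.recruit_count)))
    if "quadrats" in paths:
        df = _read_table(paths["quadrats"], "quadrats")
        ds.quadrats = _build_rows(df, "quadrats", lambda r: QuadratCensusRecord(
            str(r.site), str(r.habitat), float(r.depth_m), int(r.year),
            str(r.quadrat_id), str(r.life_stage), int(r.colony_count)))
    if "colonies" in paths:
        df = _read_table(paths["colonies"], "colonies")
        ds.colonies = _build_rows(df, "colonies", lambda r: ColonyRecord(
            str(r.site), str(r.habitat), int(r.year), float(r.diameter_cm)))
    if "points" in paths:
        df = _read_table(paths["points"], "points")
        ds.points = _group_images(df, "points")
    if "grids" in paths:
        df = _read_table(paths["grids"], "grids")
        ds.grids = _group_images(df, "grids")

    return ds.validate()


def _group_images(df: pd.DataFrame, table: str) -> list:
    recs: list = []
    if table == "points":
        keys = ["image_id", "site", "habitat", "depth_m", "year"]
        for key, grp in df.groupby(keys, sort=True):
            counts = {str(c): int(n) for c, n in zip(grp["category"], grp["points"])}
            img, site, hab, depth, year = key
            recs.append(PointCountRecord(str(img), str(site), str(hab),
                                         float(depth), int(year), counts))
    else:
        keys = ["image_id", "site", "habitat", "year"]
        for key, grp in df.groupby(keys, sort=True):
            counts = {str(c): int(n) for c, n in zip(grp["category"], grp["cells"])}
            img, site, hab, year = key
            recs.append(GridScoreRecord(str(img), str(site), str(hab), int(year), counts))
    return recs


def read_fecundity_studies(path: str | Path) -> pd.DataFrame:
    """Read a literature fecundity table (study, taxon, value, unit)."""
    df = pd.read_csv(path)
    missing = [c for c in ("study", "value", "unit") if c not in df.columns]
    if missing:
        raise SchemaError(f"fecundity_studies: missing column(s) {missing}")
    return df


def read_fertilization_studies(path: str | Path) -> pd.DataFrame:
    """Read a literature fertilization table (study, taxon, n, success_fraction)."""
    df = pd.read_csv(path)
    missing = [c for c in ("study", "success_fraction") if c not in df.columns]
    if missing:
        raise SchemaError(f"fertilization_studies: missing column(s) {missing}")
    return df


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_dataset(ds: SurveyDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a data set to the canonical CSV files plus a ``config.yaml``.

    Returns the paths mapping accepted by :func:`read_dataset`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    frames: dict[str, pd.DataFrame] = {}
    frames["tiles"] = pd.DataFrame(
        [(r.site, r.habitat, r.depth_m, r.year, r.period, r.tile_id, r.recruit_count)
         for r in ds.tiles], columns=TABLE_COLUMNS["tiles"])
    frames["quadrats"] = pd.DataFrame(
        [(r.site, r.habitat, r.depth_m, r.year, r.quadrat_id, r.life_stage, r.colony_count)
         for r in ds.quadrats], columns=TABLE_COLUMNS["quadrats"])
    frames["colonies"] = pd.DataFrame(
        [(r.site, r.habitat, r.year, r.diameter_cm) for r in ds.colonies],
        columns=TABLE_COLUMNS["colonies"])
    frames["points"] = pd.DataFrame(
        [(r.image_id, r.site, r.habitat, r.depth_m, r.year, cat, n)
         for r in ds.points for cat, n in sorted(r.label_counts.items())],
        columns=TABLE_COLUMNS["points"])
    frames["grids"] = pd.DataFrame(
        [(r.image_id, r.site, r.habitat, r.year, cat, n)
         for r in ds.grids for cat, n in sorted(r.dominant_counts.items())],
        columns=TABLE_COLUMNS["grids"])

    for table, df in frames.items():
        if df.empty:
            continue
        p = out / TABLE_FILES[table]
        df.to_csv(p, index=False, float_format="%.17g")  # lossless round trip
        paths[table] = p

    cfg = {
        "habitats": [
            {"name": h.name, "hard_bottom_area_km2": h.hard_bottom_area_km2,
             "depth_range_m": list(h.depth_range_m), "shore_length_km": h.shore_length_km}
            for h in ds.habitats
        ],
        "sampler": dataclasses.asdict(ds.sampler),
    }
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return paths


def sig3(x: float) -> str:
    """Render a number at 3 significant figures (report text only)."""
    try:
        if x != x:  # NaN
            return "-"
    except TypeError:
        return str(x)
    return f"{float(x):.3g}"


def write_report_tables(report, out_dir: str | Path) -> list[Path]:
    """Write all report tables for a self-seeding assessment.

    ``report`` is a :class:`reefseed.selfseed.SelfSeedingReport`.  Emits full
    precision CSVs (abundances, reproduction chains, Monte Carlo summaries,
    the assessment table) plus a human-readable ``summary.txt``; output is
    deterministic for a fixed report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    tables = {
        "abundance_summary.csv": report.abundance_table,
        "reproduction_summary.csv": report.reproduction_table,
        "mc_summary.csv": report.mc_table,
        "self_seeding_report.csv": report.table,
    }
    for name, df in tables.items():
        if df is None or df.empty:
            continue
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)

    p = out / "summary.txt"
    with open(p, "w", encoding="utf-8") as fh:
        fh.write(report.render_text())
    written.append(p)
    return written
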