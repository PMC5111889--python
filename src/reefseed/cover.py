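"""Percent-cover estimation from photoquadrat scoring.

Two scoring schemes are supported: random-point counts (e.g. 200 points per
image) and categorical dominance grids (e.g. 25 cells per image, giving 4 %
resolution).  Per-image covers are summarised as mean ± SE across images
within a site/habitat/depth/year group.  A category that was never scored on
an image is 0 % cover on that image, not missing — both schemes score the
whole image exhaustively.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import GridScoreRecord, PointCountRecord, SamplerSpec, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoverEstimate:
    """Mean ± SE percent cover of one category in one survey group."""

    site: str
    habitat: str
    depth_m: float | None
    year: int
    category: str
    mean_cover: float
    se_cover: float
    n_images: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_cover <= 100.0):
            raise ValueError(f"mean_cover out of [0, 100]: {self.mean_cover}")
        if self.se_cover < 0:
            raise ValueError("se_cover must be >= 0")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")


def cover_from_points(record: PointCountRecord, category: str,
                      sampler: SamplerSpec) -> float:
    """Percent cover of ``category`` on one point-scored image."""
    total = record.total_points()
    if total != sampler.points_per_image:
        raise ValidationError(
            f"image {record.image_id!r}: point counts sum to {total}, "
            f"expected {sampler.points_per_image}")
    return 100.0 * record.label_counts.get(category, 0) / total


def cover_from_grid(record: GridScoreRecord, category: str,
                    sampler: SamplerSpec) -> float:
    """Percent cover of ``category`` on one grid-scored image.

    Output is quantized to ``100 / grid_cells`` steps (4 % with the default
    25-cell grid).
    """
    total = record.total_cells()
    if total != sampler.grid_cells:
        raise ValidationError(
            f"image {record.image_id!r}: cell counts sum to {total}, "
            f"expected {sampler.grid_cells}")
    return 100.0 * record.dominant_counts.get(category, 0) / total


def _group_key(rec) -> tuple:
    depth = getattr(rec, "depth_m", None)
    return (rec.site, rec.habitat, depth, rec.year)


def summarize_cover(records: Sequence[PointCountRecord | GridScoreRecord],
                    category: str, sampler: SamplerSpec) -> list[CoverEstimate]:
    """Mean ± SE percent cover per site/habitat/depth/year group.

    SE is sample SD (n−1 denominator) over per-image covers divided by √n;
    a single-image group gets SE 0 by convention (flagged in the log).
    """
    groups: dict[tuple, list[float]] = {}
    for rec in records:
        if isinstance(rec, PointCountRecord):
            c = cover_from_points(rec, category, sampler)
        else:
            c = cover_from_grid(rec, category, sampler)
        groups.setdefault(_group_key(rec), []).append(c)

    out: list[CoverEstimate] = []
    for key in sorted(groups, key=lambda k: tuple(str(x) for x in k)):
        covers = np.asarray(groups[key], dtype=float)
        n = covers.size
        if n == 0:  # defensive; cannot arise from the loop above
            logger.warning("empty cover group %s excluded", key)
            continue
        mean = float(covers.mean())
        se = float(covers.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        if n == 1:
            logger.warning("cover group %s has a single image; SE set to 0", key)
        site, habitat, depth, year = key
        out.append(CoverEstimate(site, habitat, depth, int(year), category, mean, se, n))
    return out
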