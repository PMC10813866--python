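"""Directional co-occurrence matrices and Haralick texture features.

Cell-density maps are treated as small gray-level images (levels
0..Ng-1).  For each map, four symmetric, normalized gray-level
co-occurrence matrices (GLCMs) are computed at offset distance 1 —
horizontal (D1), vertical (D2), minor diagonal / 45 deg (D3) and main
diagonal / 135 deg (D4) — and each GLCM is reduced to the 13 classic
Haralick statistics.  Per patch that is 13 x 4 x 3 scales = 156
features; per slide, five summary statistics over patches give 260
named attributes per scale.

Conventions (the original formulation leaves several open):

* gray levels are 0-based, so sum-distribution indices run 0..2(Ng-1);
* logarithms are base 2 and zero-probability terms are skipped
  (0 * log 0 := 0);
* ``variance`` is the marginal variance of the symmetric GLCM;
  ``sum_variance`` is the variance of the (i+j) distribution about the
  sum average;
* for a degenerate single-cell GLCM (constant map) ``correlation``,
  ``IMC1`` and ``IMC2`` are defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .density import DensityMap

__all__ = [
    "DIRECTIONS",
    "HARALICK_FEATURES",
    "SLIDE_STATS",
    "SCALE_TAGS",
    "CooccurrenceMatrix",
    "cooccurrence",
    "haralick",
    "patch_features",
    "aggregate_slide",
    "enumerate_pathomics_schema",
    "PathomicsFeatureTable",
]

# (row offset, col offset) at distance 1
DIRECTIONS: dict[str, tuple[int, int]] = {
    "D1": (0, 1),    # horizontal, 0 deg
    "D2": (1, 0),    # vertical, 90 deg
    "D3": (-1, 1),   # minor diagonal, 45 deg
    "D4": (1, 1),    # main diagonal, 135 deg
}

HARALICK_FEATURES: tuple[str, ...] = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "IMC1",
    "IMC2",
)

SLIDE_STATS: tuple[str, ...] = ("mean", "median", "var", "kurtosis", "skewness")

# scale tag -> bin size in px
SCALE_TAGS: dict[str, int] = {"S1": 16, "S2": 32, "S3": 64}


@dataclass
class CooccurrenceMatrix:
    direction: str
    distance: int
    matrix: np.ndarray  # Ng x Ng, symmetric, sums to 1


def cooccurrence(dm: DensityMap | np.ndarray, direction: str,
                 n_gray: int | None = None) -> CooccurrenceMatrix:
    """Symmetric normalized GLCM of a quantized map at offset distance 1.

    Counts every ordered pixel pair at the direction's offset in both
    orders (symmetrization) and normalizes the matrix to total mass 1.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}; expected one of {list(DIRECTIONS)}")
    if isinstance(dm, DensityMap):
        levels, ng = dm.levels, dm.n_gray
    else:
        levels = np.asarray(dm)
        ng = int(n_gray) if n_gray is not None else int(levels.max()) + 1
    dr, dc = DIRECTIONS[direction]
    h, w = levels.shape
    if h - abs(dr) < 1 or w - abs(dc) < 1 or (h - abs(dr)) * (w - abs(dc)) == 0:
        raise ValueError(f"map of shape {levels.shape} too small for direction {direction}")

    rs = slice(max(dr, 0), h + min(dr, 0))
    cs = slice(max(dc, 0), w + min(dc, 0))
    rs0 = slice(max(-dr, 0), h + min(-dr, 0))
    cs0 = slice(max(-dc, 0), w + min(-dc, 0))
    a = levels[rs0, cs0].ravel()
    b = levels[rs, cs].ravel()
    mat = np.zeros((ng, ng), dtype=float)
    np.add.at(mat, (a, b), 1.0)
    mat = mat + mat.T  # count both orders
    mat /= mat.sum()
    return CooccurrenceMatrix(direction=direction, distance=1, matrix=mat)


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def haralick(glcm: CooccurrenceMatrix | np.ndarray) -> dict[str, float]:
    """The 13 classic Haralick statistics of a normalized symmetric GLCM.

    The 14th statistic (maximal correlation coefficient) is excluded; it
    is numerically unstable on small matrices and unused downstream.
    """
    p = glcm.matrix if isinstance(glcm, CooccurrenceMatrix) else np.asarray(glcm, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("GLCM must be square")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalized to total mass 1")
    ng = p.shape[0]
    i = np.arange(ng, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sd_x = float(np.sqrt(((i - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((i - mu_y) ** 2) @ py))

    ii, jj = np.meshgrid(i, i, indexing="ij")
    # sum and difference distributions
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2 * ng - 1, dtype=float)
    k_diff = np.arange(ng, dtype=float)

    out: dict[str, float] = {}
    out["energy"] = float((p ** 2).sum())
    out["contrast"] = float((((ii - jj) ** 2) * p).sum())
    if sd_x > 0 and sd_y > 0:
        out["correlation"] = float(((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        out["correlation"] = 0.0
    out["variance"] = float((((ii - mu_x) ** 2) * p).sum())
    out["inverse_difference_moment"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float(k_sum @ p_sum)
    out["sum_average"] = sum_avg
    out["sum_variance"] = float(((k_sum - sum_avg) ** 2) @ p_sum)
    out["sum_entropy"] = _entropy2(p_sum)
    hxy = _entropy2(p.ravel())
    out["entropy"] = hxy
    mu_d = float(k_diff @ p_diff)
    out["difference_variance"] = float(((k_diff - mu_d) ** 2) @ p_diff)
    out["difference_entropy"] = _entropy2(p_diff)

    hx = _entropy2(px)
    hy = _entropy2(py)
    pxy = np.outer(px, py)
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxy[nz])).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())
    denom = max(hx, hy)
    out["IMC1"] = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    out["IMC2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    return out


def patch_features(dms: Mapping[str, DensityMap]) -> pd.Series:
    """156 named texture features for one patch (13 x 4 directions x 3 scales).

    ``dms`` maps scale tags S1/S2/S3 to that patch's density maps.  Names
    are ``{feature}_{direction}_{scale}``, e.g. ``sum_average_D1_S1``.
    """
    missing = [s for s in SCALE_TAGS if s not in dms]
    if missing:
        raise ValueError(f"missing density maps for scales: {missing}")
    values: dict[str, float] = {}
    for stag in SCALE_TAGS:
        dm = dms[stag]
        for d in DIRECTIONS:
            feats = haralick(cooccurrence(dm, d))
            for fname in HARALICK_FEATURES:
                values[f"{fname}_{d}_{stag}"] = feats[fname]
    return pd.Series(values)


def _slide_stat_names(scale: str | None = None) -> list[str]:
    suffix = f"_{scale}" if scale else ""
    return [
        f"{stat}_{feat}_{d}{suffix}"
        for stat in SLIDE_STATS
        for feat in HARALICK_FEATURES
        for d in DIRECTIONS
    ]


def aggregate_slide(patch_table: pd.DataFrame, scale: str) -> pd.Series:
    """Slide-level summary of one scale's patch features: 260 named values.

    For each (feature, direction), five statistics over the slide's
    retained patches — mean, median, sample variance (n-1), excess
    kurtosis and bias-corrected skewness — named ``{stat}_{feature}_{direction}``
    in the reporting style of the association tables (e.g.
    ``var_sum_average_D1``, ``kurtosis_IMC1_D3``).  With fewer than 4
    patches, kurtosis and skewness are undefined (NaN) with a warning.
    """
    import warnings

    if scale not in SCALE_TAGS:
        raise ValueError(f"unknown scale tag {scale!r}")
    cols = [c for c in patch_table.columns if c.endswith(f"_{scale}")]
    if patch_table.empty or not cols:
        raise ValueError("no patch features to aggregate")
    n = len(patch_table)
    if n < 4:
        warnings.warn(f"only {n} patches: kurtosis and skewness are undefined (NaN)")
    out: dict[str, float] = {}
    for col in cols:
        base = col[: -(len(scale) + 1)]  # strip _Sx -> {feature}_{direction}
        x = patch_table[col].to_numpy(dtype=float)
        out[f"mean_{base}"] = float(np.mean(x))
        out[f"median_{base}"] = float(np.median(x))
        out[f"var_{base}"] = float(np.var(x, ddof=1)) if n > 1 else 0.0
        out[f"kurtosis_{base}"] = (
            float(sstats.kurtosis(x, fisher=True, bias=False)) if n >= 4 else np.nan)
        out[f"skewness_{base}"] = (
            float(sstats.skew(x, bias=False)) if n >= 4 else np.nan)
    return pd.Series(out).reindex(_slide_stat_names())


def enumerate_pathomics_schema(scales: Sequence[str] = ("S1", "S2", "S3")) -> list[str]:
    """Deterministic ordered slide-level feature names.

    One scale yields the 260 bare names (reporting style); several scales
    yield unique names suffixed with the scale tag (260 per scale).
    """
    for s in scales:
        if s not in SCALE_TAGS:
            raise ValueError(f"unknown scale tag {s!r}")
    if len(scales) == 1:
        return _slide_stat_names()
    names: list[str] = []
    for s in scales:
        names.extend(_slide_stat_names(s))
    return names


class PathomicsFeatureTable:
    """Per-scale slide-level feature tables: scale tag -> patients x 260."""

    def __init__(self, per_scale: Mapping[str, pd.DataFrame]):
        for s, df in per_scale.items():
            if s not in SCALE_TAGS:
                raise ValueError(f"unknown scale tag {s!r}")
            if list(df.columns) != _slide_stat_names():
                raise ValueError(f"scale {s}: columns do not match the 260-name schema")
        self.per_scale = dict(per_scale)

    @property
    def scales(self) -> list[str]:
        return list(self.per_scale)

    def __getitem__(self, scale: str) -> pd.DataFrame:
        return self.per_scale[scale]

    def flat(self) -> pd.DataFrame:
        """Single table with scale-suffixed column names (for CSV export)."""
        parts = [df.add_suffix(f"_{s}") for s, df in self.per_scale.items()]
        return pd.concat(parts, axis=1)
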