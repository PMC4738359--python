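"""Averaging multifunctionality index.

Six ecosystem functions — ammonium, nitrate, potential net N
mineralization, available P, DNA concentration and NDVI (plant
productivity) — are normalized (log-transform when it tames strong
skew), Z-scored across sites, and averaged into a single per-site index
M.  Upstream corrections: soil functions can be put on a per-volume
basis with bulk density, and microsite (vegetated / bare) measurements
are cover-weighted into site-level values before any standardization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FUNCTION_COLUMNS = [
    "ammonium",
    "nitrate",
    "net_n_mineralization",
    "available_p",
    "dna_concentration",
    "ndvi",
]
#: functions measured per unit soil mass, hence subject to bulk-density
#: correction; NDVI is an area-based satellite proxy and is left untouched
SOIL_FUNCTIONS = [c for c in FUNCTION_COLUMNS if c != "ndvi"]


def bulk_density_correct(
    functions: pd.DataFrame,
    sites: pd.DataFrame,
    soil_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Convert per-mass soil functions to a per-volume basis.

    Each soil function value is multiplied by the site's bulk density
    (g cm^-3), so that sites with very light organic soils are not
    overweighted per gram.
    """
    if "bulk_density" not in sites.columns:
        raise ValueError("sites table has no bulk_density column")
    bd = sites["bulk_density"].reindex(functions.index)
    if bd.isna().any():
        missing = bd.index[bd.isna()].tolist()
        raise ValueError(f"missing bulk density for sites: {missing}")
    if soil_columns is None:
        soil_columns = [c for c in SOIL_FUNCTIONS if c in functions.columns]
    out = functions.copy()
    for c in soil_columns:
        out[c] = out[c] * bd
    return out


def microsite_weighted_average(values_veg, values_bare, cover_veg, cover_bare):
    """Cover-weighted mean of vegetated and bare-ground measurements.

    v = (cover_veg * veg + cover_bare * bare) / (cover_veg + cover_bare)
    """
    values_veg = np.asarray(values_veg, dtype=float)
    values_bare = np.asarray(values_bare, dtype=float)
    cover_veg = np.asarray(cover_veg, dtype=float)
    cover_bare = np.asarray(cover_bare, dtype=float)
    if np.any(cover_veg < 0) or np.any(cover_bare < 0):
        raise ValueError("covers must be >= 0")
    total = cover_veg + cover_bare
    if np.any(total <= 0):
        raise ValueError("cover_veg + cover_bare must be > 0 at every site")
    return (cover_veg * values_veg + cover_bare * values_bare) / total


def normalize_function(values, skew_threshold: float = 1.0):
    """Normality-improving transform ahead of Z-scoring.

    Applies the natural log when all values are strictly positive, the
    sample skewness exceeds ``skew_threshold`` in magnitude, and logging
    actually reduces that magnitude; otherwise returns the data unchanged.
    Returns ``(transformed, transform_used)`` with transform_used in
    {"log", "none"}.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("need at least 3 finite values to assess skewness")
    xf = x[finite]
    if np.all(xf > 0) and xf.std() > 0:
        sk = stats.skew(xf, bias=False)
        if abs(sk) > skew_threshold:
            logged = np.log(xf)
            if abs(stats.skew(logged, bias=False)) < abs(sk):
                out = np.full_like(x, np.nan)
                out[finite] = logged
                return out, "log"
    return x.copy(), "none"


def zscore(values) -> np.ndarray:
    """(x - mean) / sd with the n-1 denominator; NaN-tolerant."""
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    mu = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot z-score a constant vector")
    out = np.full_like(x, np.nan)
    out[finite] = (x[finite] - mu) / sd
    return out


@dataclass
class MultifunctionalityIndex:
    """Per-site averaging index M with bookkeeping."""

    table: pd.DataFrame  # columns: M, n_functions_used
    transforms: dict
    standardized: pd.DataFrame

    @property
    def M(self) -> pd.Series:
        return self.table["M"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="site_id")


def averaging_index(
    functions: pd.DataFrame,
    columns: list[str] | None = None,
    transforms: dict | None = None,
) -> MultifunctionalityIndex:
    """Mean of Z-scored (post-normalization) functions, per site.

    ``transforms`` overrides the automatic skewness rule per function
    ("log", "square" or "none").  Missing values are complete-case per
    function: a site is excluded from a function's z-scoring only where
    it is missing there, and M averages whatever standardized functions
    the site has (n_functions_used records how many).
    """
    if columns is None:
        columns = [c for c in FUNCTION_COLUMNS if c in functions.columns]
        if not columns:
            columns = list(functions.columns)
    if functions.shape[0] < 2:
        raise ValueError("need at least 2 sites")
    used_transforms = {}
    std = pd.DataFrame(index=functions.index)
    for c in columns:
        x = functions[c].to_numpy(dtype=float)
        if transforms and c in transforms and transforms[c] is not None:
            t = transforms[c]
            if t == "log":
                if np.any(x[np.isfinite(x)] <= 0):
                    raise ValueError(f"log transform on non-positive values: {c}")
                x, tag = np.where(np.isfinite(x), np.log(x), np.nan), "log"
            elif t == "square":
                x, tag = x**2, "square"
            elif t == "none":
                tag = "none"
            else:
                raise ValueError(f"unknown transform {t!r} for {c}")
        else:
            x, tag = normalize_function(x)
        try:
            std[c] = zscore(x)
        except ValueError as err:
            raise ValueError(f"function {c!r}: {err}") from err
        used_transforms[c] = tag
    M = std.mean(axis=1, skipna=True)
    n_used = std.notna().sum(axis=1)
    out = pd.DataFrame({"M": M, "n_functions_used": n_used})
    return MultifunctionalityIndex(out, used_transforms, std)


def load_dataset_manifest(path) -> dict:
    """Read a per-data-set YAML manifest.

    Recognized keys: ``functions`` (column names entering the index),
    ``transforms`` (per-function override: log / square / none),
    ``cover_columns`` (vegetated and bare cover column names) and
    ``soil_functions`` (columns subject to bulk-density correction).
    Unknown keys are rejected to catch typos early.
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    allowed = {"functions", "transforms", "cover_columns", "soil_functions"}
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"unknown manifest keys: {sorted(unknown)}")
    doc.setdefault("functions", None)
    doc.setdefault("transforms", {})
    doc.setdefault("cover_columns", None)
    doc.setdefault("soil_functions", None)
    return doc


def site_level_functions(
    functions_veg: pd.DataFrame,
    functions_bare: pd.DataFrame,
    sites: pd.DataFrame,
    bulk_density: bool = True,
    soil_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Microsite aggregation then bulk-density correction, in that order.

    Vegetated and bare-ground measurements are cover-weighted into
    site-level values first; the per-mass soil functions are then put on
    a per-volume basis.  Normalization and z-scoring happen downstream in
    :func:`averaging_index`, keeping the pipeline order fixed.
    """
    if list(functions_veg.columns) != list(functions_bare.columns):
        raise ValueError("vegetated and bare tables must share columns")
    cv = sites["cover_vegetated"].reindex(functions_veg.index).to_numpy(dtype=float)
    cb = sites["cover_bare"].reindex(functions_veg.index).to_numpy(dtype=float)
    out = pd.DataFrame(index=functions_veg.index)
    for c in functions_veg.columns:
        out[c] = microsite_weighted_average(
            functions_veg[c].to_numpy(dtype=float),
            functions_bare[c].to_numpy(dtype=float),
            cv,
            cb,
        )
    if bulk_density:
        out = bulk_density_correct(out, sites, soil_columns=soil_columns)
    return out


def compare_indices(index_a: pd.Series, index_b: pd.Series):
    """Spearman rank correlation between two indices on shared sites."""
    shared = index_a.index.intersection(index_b.index)
    if len(shared) < 5:
        raise ValueError(f"only {len(shared)} shared sites; need >= 5")
    rho, p = stats.spearmanr(index_a.loc[shared], index_b.loc[shared])
    return float(rho), float(p)
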