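"""Synthetic landscapes with known ground truth.

Emulates the statistical structure of a large-scale soil survey: sites
scattered over a rectangle carry spatially autocorrelated climate and
soil covariates; a latent microbial-diversity value responds linearly to
those covariates; six ecosystem functions respond to diversity and
covariates with configurable effect sizes on top of SAR-structured noise;
an OTU table whose per-site evenness tracks the latent diversity; and a
random pure-birth phylogeny over the taxa.  Every downstream stage of the
package can therefore be tested against known coefficients.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import yaml

from .regression import SpatialWeights, build_spatial_weights

COVARIATES = ["distance_from_equator", "altitude", "MAT", "MAP", "soil_pH"]
FUNCTIONS = [
    "ammonium",
    "nitrate",
    "net_n_mineralization",
    "available_p",
    "dna_concentration",
    "ndvi",
]

# plausible field scales (mean, sd) used to place functions on raw units;
# affine placement is irrelevant to every z-score-based downstream stage
_FUNCTION_SCALES = {
    "ammonium": (8.0, 3.0),
    "nitrate": (12.0, 5.0),
    "net_n_mineralization": (1.5, 0.8),
    "available_p": (15.0, 6.0),
    "dna_concentration": (10.0, 4.0),
    "ndvi": (0.35, 0.12),
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic landscape.

    Effect sizes are on the standardized scale (per-unit-SD of the
    predictor).  ``evenness_range`` is the (low, high) log-normal sigma of
    taxon abundances per site; higher sigma means a more uneven community
    and hence lower expected Shannon diversity.
    """

    n_sites: int = 78
    n_taxa: int = 300
    read_depth: int = 2000
    effect_diversity_on_functions: tuple = (0.4,) * 6
    effect_covariates_on_diversity: tuple = (-0.1, -0.1, -0.2, 0.3, -0.3)
    effect_covariates_on_functions: tuple = (0.0, 0.0, -0.1, 0.2, -0.1)
    spatial_lambda: float = 0.5
    noise_sd: float = 1.0
    evenness_range: tuple = (0.5, 2.0)
    knn: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        vals = np.concatenate(
            [
                np.atleast_1d(np.asarray(v, dtype=float))
                for v in (
                    self.n_sites,
                    self.n_taxa,
                    self.read_depth,
                    self.effect_diversity_on_functions,
                    self.effect_covariates_on_diversity,
                    self.effect_covariates_on_functions,
                    self.spatial_lambda,
                    self.noise_sd,
                    self.evenness_range,
                )
            ]
        )
        if not np.all(np.isfinite(vals)):
            raise ValueError("SimulationConfig contains non-finite values")
        if self.n_sites < 4:
            raise ValueError("n_sites must be >= 4")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if not (-1.0 < self.spatial_lambda < 1.0):
            raise ValueError("spatial_lambda must lie strictly inside (-1, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if len(self.effect_diversity_on_functions) != len(FUNCTIONS):
            raise ValueError(f"need one diversity effect per function ({len(FUNCTIONS)})")
        if len(self.effect_covariates_on_diversity) != len(COVARIATES):
            raise ValueError(f"need one effect per covariate ({len(COVARIATES)})")
        if len(self.effect_covariates_on_functions) != len(COVARIATES):
            raise ValueError(f"need one effect per covariate ({len(COVARIATES)})")
        lo, hi = self.evenness_range
        if not (0 < lo <= hi):
            raise ValueError("evenness_range must be 0 < low <= high")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        for key in (
            "effect_diversity_on_functions",
            "effect_covariates_on_diversity",
            "effect_covariates_on_functions",
            "evenness_range",
        ):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass
class GroundTruth:
    """True coefficients and latent states behind a simulated landscape."""

    effect_diversity_on_functions: np.ndarray
    effect_covariates_on_diversity: np.ndarray
    effect_covariates_on_functions: np.ndarray
    spatial_lambda: float
    latent_diversity: np.ndarray
    evenness_sigma: np.ndarray = field(default=None)


def sar_noise(
    weights: SpatialWeights, lam: float, sigma: float, n: int, seed: int
) -> np.ndarray:
    """Draw u = (I - lambda W)^-1 eps with eps ~ N(0, sigma^2)."""
    if weights.n != n:
        raise ValueError(f"weights are {weights.n}x{weights.n}, expected n={n}")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, size=n)
    if lam == 0.0:
        return eps
    A = np.eye(n) - lam * weights.matrix
    if abs(np.linalg.det(A)) < 1e-300:
        raise ValueError(f"I - lambda W is singular at lambda={lam}")
    return np.linalg.solve(A, eps)


def _std(x: np.ndarray) -> np.ndarray:
    s = x.std(ddof=1)
    return (x - x.mean()) / s if s > 0 else x - x.mean()


def evenness_from_diversity(
    latent: np.ndarray, evenness_range: tuple
) -> np.ndarray:
    """Map latent diversity to per-site log-normal sigma, inversely by rank.

    The most diverse site gets the lowest sigma (most even community).
    """
    lo, hi = evenness_range
    n = len(latent)
    ranks = np.argsort(np.argsort(latent))
    pct = ranks / max(n - 1, 1)
    return hi - (hi - lo) * pct


def simulate_landscape(config: SimulationConfig):
    """Generate (SiteTable, FunctionMatrix, GroundTruth) for one landscape.

    Returns two DataFrames indexed by site id plus the ground truth.
    Sub-streams of the master seed drive coordinates, covariates,
    diversity noise and function noise independently.
    """
    n = config.n_sites
    ss = np.random.SeedSequence(config.seed)
    s_coord, s_cov, s_div, s_fun, s_site = ss.spawn(5)
    rng_coord = np.random.default_rng(s_coord)
    rng_div = np.random.default_rng(s_div)
    rng_site = np.random.default_rng(s_site)

    lat = rng_coord.uniform(36.0, 44.0, n)
    lon = rng_coord.uniform(-8.0, 4.0, n)
    coords = np.column_stack([lat, lon])
    k = min(config.knn, n - 1)
    W = build_spatial_weights(coords, k=k)

    # spatially autocorrelated standard fields, one per covariate
    cov_seeds = s_cov.spawn(len(COVARIATES))
    fields = {}
    for name, sub in zip(COVARIATES, cov_seeds):
        u = sar_noise(W, config.spatial_lambda, 1.0, n, sub)
        fields[name] = _std(u)

    sites = pd.DataFrame(index=[f"S{i + 1:03d}" for i in range(n)])
    sites.index.name = "site_id"
    sites["latitude"] = lat
    sites["longitude"] = lon
    sites["distance_from_equator"] = np.abs(lat) + 0.5 * fields["distance_from_equator"]
    sites["altitude"] = np.clip(800 + 400 * fields["altitude"], 0, None)
    sites["MAT"] = 18.0 + 5.0 * fields["MAT"]
    sites["MAP"] = np.clip(400 + 150 * fields["MAP"], 30, None)
    sites["soil_pH"] = np.clip(7.8 + 0.6 * fields["soil_pH"], 4.0, 9.5)
    sites["aridity_index"] = rng_site.uniform(0.05, 0.65, n)
    sites["ecosystem_type"] = rng_site.choice(
        ["grassland", "mixed", "woodland"], size=n
    )
    sites["bulk_density"] = rng_site.uniform(0.9, 1.3, n)
    cover_veg = rng_site.uniform(0.2, 0.8, n)
    sites["cover_vegetated"] = cover_veg
    sites["cover_bare"] = 1.0 - cover_veg

    Z = np.column_stack([_std(sites[c].to_numpy()) for c in COVARIATES])
    b_div = np.asarray(config.effect_covariates_on_diversity, dtype=float)
    latent = Z @ b_div + rng_div.normal(0.0, config.noise_sd, n)
    latent_std = _std(latent)

    e_fun = np.asarray(config.effect_diversity_on_functions, dtype=float)
    b_fun = np.asarray(config.effect_covariates_on_functions, dtype=float)
    fun_seeds = s_fun.spawn(len(FUNCTIONS))
    functions = pd.DataFrame(index=sites.index)
    for j, (name, sub) in enumerate(zip(FUNCTIONS, fun_seeds)):
        noise = sar_noise(W, config.spatial_lambda, config.noise_sd, n, sub)
        signal = e_fun[j] * latent_std + Z @ b_fun + noise
        mean, sd = _FUNCTION_SCALES[name]
        functions[name] = mean + sd * signal
    if not np.all(np.isfinite(functions.to_numpy())):
        raise AssertionError("simulated functions contain non-finite values")

    truth = GroundTruth(
        effect_diversity_on_functions=e_fun,
        effect_covariates_on_diversity=b_div,
        effect_covariates_on_functions=b_fun,
        spatial_lambda=config.spatial_lambda,
        latent_diversity=latent_std,
        evenness_sigma=evenness_from_diversity(latent_std, config.evenness_range),
    )
    return sites, functions, truth


def simulate_otu_table(
    n_sites: int, n_taxa: int, evenness: np.ndarray, depth: int, seed: int
):
    """Multinomial OTU counts with per-site log-normal abundance sigma.

    Relative abundances at site i are drawn log-normal(0, evenness[i]^2)
    and normalized; counts are multinomial(depth, abundances), so every
    column sums to exactly ``depth``.
    """
    from .diversity import OtuTable

    evenness = np.broadcast_to(np.asarray(evenness, dtype=float), (n_sites,))
    if np.any(evenness <= 0):
        raise ValueError("evenness sigma values must be > 0")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_taxa, n_sites), dtype=np.int64)
    for i in range(n_sites):
        logs = rng.normal(0.0, evenness[i], n_taxa)
        p = np.exp(logs - logs.max())
        p /= p.sum()
        counts[:, i] = rng.multinomial(depth, p)
    taxa = [f"OTU_{t + 1:04d}" for t in range(n_taxa)]
    samples = [f"S{i + 1:03d}" for i in range(n_sites)]
    return OtuTable(pd.DataFrame(counts, index=taxa, columns=samples))


def simulate_phylogeny(n_taxa: int, seed: int, birth_rate: float = 1.0) -> str:
    """Pure-birth (Yule) tree over n_taxa labelled tips, as newick text.

    Tip labels OTU_0001..OTU_nnnn match :func:`simulate_otu_table`.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=random.Random(seed),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        if leaf.taxon is None:
            leaf.taxon = tree.taxon_namespace.new_taxon(label="")
        leaf.taxon.label = f"OTU_{i + 1:04d}"
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length <= 0:
            edge.length = 1e-9
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def write_landscape(outdir, sites: pd.DataFrame, functions: pd.DataFrame) -> None:
    """Write SiteTable and FunctionMatrix CSVs keyed by site id."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites.to_csv(outdir / "sites.csv")
    functions.to_csv(outdir / "functions.csv")
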