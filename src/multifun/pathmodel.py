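"""Recursive observed-variable path models.

A path model here is a directed acyclic graph over observed (or
composite) variables.  All variables are standardized after any declared
normality transforms, each endogenous variable is regressed by OLS on
its parents — exact maximum likelihood for recursive models with
unconstrained exogenous covariances — and the resulting standardized
path coefficients support:

* model-implied correlation matrix Sigma = (I-B)^-1 Psi (I-B)^-T,
* the ML discrepancy chi-square, df and RMSEA,
* nonparametric bootstrap p-values for each path coefficient,
* the Bollen-Stine bootstrap test of overall fit, and
* standardized direct / indirect / total effects (sums over all
  directed paths, i.e. the geometric series of B).

Composite variables (e.g. bacterial + fungal diversity entering as one
"microbial diversity" predictor) are fixed linear combinations of
standardized indicators, weighted by their OLS coefficients against the
composite's anchoring endogenous target and rescaled to unit variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class PathModelSpec:
    """Directed edges, composites and per-variable transforms."""

    edges: list
    composites: dict = field(default_factory=dict)
    transforms: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = [tuple(e) for e in self.edges]
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"path model must be acyclic; found cycle {cycle}")
        for name, spec in self.composites.items():
            if not spec.get("indicators"):
                raise ValueError(f"composite {name!r} needs >= 1 indicator")
            if "target" not in spec:
                raise ValueError(f"composite {name!r} needs an anchoring target")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_edges_from(self.edges)
        return g

    @property
    def variables(self) -> list[str]:
        """Model variables in topological order."""
        return list(nx.topological_sort(self.graph()))

    @property
    def endogenous(self) -> list[str]:
        g = self.graph()
        return [v for v in self.variables if g.in_degree(v) > 0]

    @property
    def exogenous(self) -> list[str]:
        g = self.graph()
        return [v for v in self.variables if g.in_degree(v) == 0]

    def observed_columns(self) -> list[str]:
        """Data columns required: non-composite variables plus indicators."""
        cols = [v for v in self.variables if v not in self.composites]
        for c in self.composites.values():
            cols.extend(c["indicators"])
        return list(dict.fromkeys(cols))

    @classmethod
    def from_yaml(cls, path) -> "PathModelSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            edges=[tuple(e) for e in doc["edges"]],
            composites=doc.get("composites", {}) or {},
            transforms=doc.get("transforms", {}) or {},
        )

    def to_yaml(self, path) -> None:
        doc = {
            "edges": [list(e) for e in self.edges],
            "composites": self.composites,
            "transforms": self.transforms,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant variable cannot be standardized")
    return (x - x.mean()) / sd


def _apply_transform(x: np.ndarray, tag: str, name: str) -> np.ndarray:
    if tag in (None, "none"):
        return x
    if tag == "log":
        if np.any(x <= 0):
            raise ValueError(f"log transform on non-positive values: {name}")
        return np.log(x)
    if tag == "square":
        return x**2
    raise ValueError(f"unknown transform {tag!r} for {name}")


def build_composite(data: pd.DataFrame, indicators: list[str], target: str):
    """Composite scores and weights anchored on an endogenous target.

    Weights are the OLS coefficients of the standardized target on the
    standardized indicators; the weighted sum is rescaled to unit
    variance.  Returns ``(scores, weights)``.
    """
    Z = np.column_stack(
        [_standardize(data[c].to_numpy(dtype=float)) for c in indicators]
    )
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError(f"collinear composite indicators: {indicators}")
    yt = _standardize(data[target].to_numpy(dtype=float))
    w, *_ = np.linalg.lstsq(Z, yt, rcond=None)
    scores = Z @ w
    sd = scores.std(ddof=1)
    if sd == 0:
        raise ValueError("composite has zero variance")
    scores = scores / sd
    return (
        pd.Series(scores, index=data.index, name="composite"),
        pd.Series(w, index=indicators, name="weight"),
    )


@dataclass
class PathModelFit:
    """Standardized path coefficients and everything derived from them."""

    spec: PathModelSpec
    variables: list
    B: pd.DataFrame  # B.loc[i, j] = effect of j on i
    psi: pd.DataFrame
    r2: dict
    n: int
    data: pd.DataFrame  # standardized model variables (post-composite)
    composite_weights: dict = field(default_factory=dict)

    def path_coefficient(self, source: str, target: str) -> float:
        return float(self.B.loc[target, source])

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "coefficients": {
                f"{s}->{t}": self.path_coefficient(s, t) for s, t in self.spec.edges
            },
            "r2": self.r2,
            "n": self.n,
            "composite_weights": {
                k: v.to_dict() for k, v in self.composite_weights.items()
            },
        }


def _prepare_data(data: pd.DataFrame, spec: PathModelSpec):
    cols = spec.observed_columns()
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks columns: {missing}")
    work = data[cols].dropna()
    std = pd.DataFrame(index=work.index)
    for c in cols:
        x = work[c].to_numpy(dtype=float)
        x = _apply_transform(x, spec.transforms.get(c), c)
        std[c] = _standardize(x)
    weights = {}
    for name, cspec in spec.composites.items():
        scores, w = build_composite(std, cspec["indicators"], cspec["target"])
        std[name] = scores
        weights[name] = w
    return std[spec.variables], weights


def fit_path_model(data: pd.DataFrame, spec: PathModelSpec) -> PathModelFit:
    """OLS-per-equation fit of a recursive path model on standardized data."""
    g = spec.graph()
    std, weights = _prepare_data(data, spec)
    n = std.shape[0]
    n_params = len(spec.edges) + len(spec.endogenous)
    if n < 10 + n_params:
        raise ValueError(
            f"too few complete cases: n={n} < 10 + {n_params} parameters"
        )
    variables = spec.variables
    B = pd.DataFrame(0.0, index=variables, columns=variables)
    r2 = {}
    Y = std.to_numpy(dtype=float)
    col = {v: i for i, v in enumerate(variables)}
    for v in spec.endogenous:
        parents = sorted(g.predecessors(v), key=col.get)
        Xp = Y[:, [col[p] for p in parents]]
        if np.linalg.matrix_rank(Xp) < Xp.shape[1]:
            raise ValueError(f"rank-deficient parent set for {v!r}: {parents}")
        beta, *_ = np.linalg.lstsq(Xp, Y[:, col[v]], rcond=None)
        B.loc[v, parents] = beta
        resid = Y[:, col[v]] - Xp @ beta
        r2[v] = float(1.0 - resid.var(ddof=0) / Y[:, col[v]].var(ddof=0))
    psi = pd.DataFrame(0.0, index=variables, columns=variables)
    exo = spec.exogenous
    if exo:
        S_exo = np.cov(Y[:, [col[v] for v in exo]], rowvar=False, ddof=1)
        S_exo = np.atleast_2d(S_exo)
        for a, va in enumerate(exo):
            for b, vb in enumerate(exo):
                psi.loc[va, vb] = S_exo[a, b]
    for v in spec.endogenous:
        psi.loc[v, v] = 1.0 - r2[v]
    return PathModelFit(
        spec=spec, variables=variables, B=B, psi=psi, r2=r2, n=n,
        data=std, composite_weights=weights,
    )


def implied_covariance(fit: PathModelFit) -> pd.DataFrame:
    """Model-implied correlation matrix Sigma = (I-B)^-1 Psi (I-B)^-T."""
    B = fit.B.to_numpy()
    inv = np.linalg.inv(np.eye(len(fit.variables)) - B)
    sigma = inv @ fit.psi.to_numpy() @ inv.T
    return pd.DataFrame(sigma, index=fit.variables, columns=fit.variables)


def _free_parameters(spec: PathModelSpec) -> int:
    q = len(spec.exogenous)
    return len(spec.edges) + q * (q + 1) // 2 + len(spec.endogenous)


def fit_statistics(
    fit: PathModelFit, sample_corr: pd.DataFrame | None = None, n: int | None = None
) -> dict:
    """ML discrepancy chi-square, df, p and RMSEA for a fitted model.

    F = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p;  chi2 = (n-1) F;
    df = p(p+1)/2 - free parameters;  RMSEA = sqrt(max(chi2-df,0)/(df(n-1))).
    A saturated model (df = 0) reports chi2 ~ 0, RMSEA 0 and p 1 with a
    saturation flag.
    """
    n = fit.n if n is None else n
    p = len(fit.variables)
    if n <= p:
        raise ValueError("need n > number of variables")
    if sample_corr is None:
        S = np.cov(fit.data.to_numpy(), rowvar=False, ddof=1)
    else:
        S = sample_corr.loc[fit.variables, fit.variables].to_numpy()
    sigma = implied_covariance(fit).to_numpy()
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise ValueError("sample or implied matrix is not positive definite")
    F = logdet_m - logdet_s + float(np.trace(S @ np.linalg.inv(sigma))) - p
    F = max(F, 0.0)
    df = p * (p + 1) // 2 - _free_parameters(fit.spec)
    if df < 0:
        raise ValueError(f"over-parameterized model: df={df}")
    chi2 = (n - 1) * F
    saturated = df == 0
    if saturated:
        pval, rmsea = 1.0, 0.0
    else:
        pval = float(stats.chi2.sf(chi2, df))
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    return {
        "chi2": float(chi2),
        "df": int(df),
        "p": pval,
        "rmsea": rmsea,
        "saturated": saturated,
        "n": n,
    }


class _CompiledSpec:
    """Index-based fitting plan for fast repeated refits on row resamples.

    Mirrors fit_path_model exactly (same standardization, composite and
    per-equation OLS steps) but works on raw numpy arrays; agreement
    with the reference implementation is pinned by tests.
    """

    def __init__(self, data: pd.DataFrame, spec: PathModelSpec):
        cols = spec.observed_columns()
        work = data[cols].dropna()
        raw = np.empty((work.shape[0], len(cols)))
        for j, c in enumerate(cols):
            raw[:, j] = _apply_transform(work[c].to_numpy(dtype=float),
                                         spec.transforms.get(c), c)
        self.raw = raw
        self.n = raw.shape[0]
        col_idx = {c: j for j, c in enumerate(cols)}
        self.variables = spec.variables
        self.composites = [
            (name,
             [col_idx[i] for i in cspec["indicators"]],
             col_idx[cspec["target"]])
            for name, cspec in spec.composites.items()
        ]
        g = spec.graph()
        vpos = {v: i for i, v in enumerate(self.variables)}
        self.var_source = [
            ("composite", name) if v in spec.composites else ("observed", col_idx[v])
            for v in self.variables
            for name in [v]
        ]
        self.endog = [
            (vpos[v], sorted(vpos[p] for p in g.predecessors(v)))
            for v in spec.endogenous
        ]
        self.exog_idx = [vpos[v] for v in spec.exogenous]
        self.edge_pos = [(vpos[t], vpos[s]) for s, t in spec.edges]
        p = len(self.variables)
        self.df = p * (p + 1) // 2 - _free_parameters(spec)

    def fit_arrays(self, idx: np.ndarray | None = None):
        """Standardize, build composites, OLS per equation; returns (B, psi, V)."""
        raw = self.raw if idx is None else self.raw[idx]
        mu = raw.mean(axis=0)
        sd = raw.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant column in resample")
        Z = (raw - mu) / sd
        comp_scores = {}
        for name, ind, tgt in self.composites:
            Zi = Z[:, ind]
            w, *_ = np.linalg.lstsq(Zi, Z[:, tgt], rcond=None)
            s = Zi @ w
            s_sd = s.std(ddof=1)
            if s_sd == 0:
                raise ValueError("degenerate composite in resample")
            comp_scores[name] = s / s_sd
        V = np.column_stack([
            comp_scores[tag] if kind == "composite" else Z[:, tag]
            for kind, tag in self.var_source
        ])
        p = V.shape[1]
        B = np.zeros((p, p))
        psi = np.zeros((p, p))
        for v, parents in self.endog:
            Xp = V[:, parents]
            beta, _, rank, _ = np.linalg.lstsq(Xp, V[:, v], rcond=None)
            if rank < len(parents):
                raise ValueError("rank-deficient parent set in resample")
            B[v, parents] = beta
            resid = V[:, v] - Xp @ beta
            psi[v, v] = resid.var(ddof=0) / V[:, v].var(ddof=0)
        if self.exog_idx:
            E = np.atleast_2d(np.cov(V[:, self.exog_idx], rowvar=False, ddof=1))
            for a, ia in enumerate(self.exog_idx):
                for b, ib in enumerate(self.exog_idx):
                    psi[ia, ib] = E[a, b]
        return B, psi, V

    def chi2(self, idx: np.ndarray | None = None) -> float:
        B, psi, V = self.fit_arrays(idx)
        p = V.shape[1]
        inv = np.linalg.inv(np.eye(p) - B)
        sigma = inv @ psi @ inv.T
        S = np.cov(V, rowvar=False, ddof=1)
        sign_s, logdet_s = np.linalg.slogdet(S)
        sign_m, logdet_m = np.linalg.slogdet(sigma)
        if sign_s <= 0 or sign_m <= 0:
            raise ValueError("non-positive-definite matrix in resample")
        F = logdet_m - logdet_s + float(np.trace(S @ np.linalg.inv(sigma))) - p
        return (V.shape[0] - 1) * max(F, 0.0)


def bootstrap_pvalues(
    data: pd.DataFrame, spec: PathModelSpec, n_boot: int = 2000, seed: int = 0
) -> pd.Series:
    """Two-sided percentile bootstrap p per path coefficient (+1 smoothed).

    Case resampling with replacement; the whole pipeline (transforms,
    standardization, composites, per-equation OLS) is refit on every
    replicate.  Replicates that fail (rank deficiency after resampling)
    are dropped and counted.
    """
    if n_boot < 199:
        raise ValueError("use at least 199 bootstrap replicates")
    rng = np.random.default_rng(seed)
    plan = _CompiledSpec(data, spec)
    n = plan.n
    draws = {e: [] for e in spec.edges}
    dropped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            B, _, _ = plan.fit_arrays(idx)
        except (ValueError, np.linalg.LinAlgError):
            dropped += 1
            continue
        for e, (t, s) in zip(spec.edges, plan.edge_pos):
            draws[e].append(B[t, s])
    kept = n_boot - dropped
    if dropped:
        msg = f"bootstrap_pvalues: dropped {dropped}/{n_boot} replicates"
        logger.warning(msg)
        if dropped > 0.01 * n_boot:
            warnings.warn(msg, stacklevel=2)
    if kept == 0:
        raise RuntimeError("every bootstrap replicate failed")
    out = {}
    for e, vals in draws.items():
        v = np.asarray(vals)
        p_lo = (1 + np.sum(v <= 0)) / (1 + kept)
        p_hi = (1 + np.sum(v >= 0)) / (1 + kept)
        out[f"{e[0]}->{e[1]}"] = min(1.0, 2.0 * min(p_lo, p_hi))
    return pd.Series(out, name="bootstrap_p")


def bollen_stine(
    data: pd.DataFrame, spec: PathModelSpec, n_boot: int = 2000, seed: int = 0
) -> float:
    """Bollen-Stine bootstrap p for overall model fit.

    The standardized model-variable matrix is rotated as
    Y* = Y S^(-1/2) Sigma-hat^(1/2) so the fitted model holds exactly in
    the transformed data; the p-value is the fraction of bootstrap
    chi-squares (from resampling Y*) at or above the observed chi-square.
    """
    fit = fit_path_model(data, spec)
    stats_obs = fit_statistics(fit)
    if stats_obs["df"] < 1:
        raise ValueError("Bollen-Stine test undefined for a saturated model (df=0)")
    Y = fit.data.to_numpy()
    Yc = Y - Y.mean(axis=0)
    S = np.cov(Yc, rowvar=False, ddof=1)
    sigma = implied_covariance(fit).to_numpy()
    S_inv_half = _matrix_power_sym(S, -0.5)
    sig_half = _matrix_power_sym(sigma, 0.5)
    Ystar = Yc @ S_inv_half @ sig_half
    star = pd.DataFrame(Ystar, columns=fit.variables)
    # composites are already columns of Y*; refits treat them as observed
    flat_spec = PathModelSpec(edges=spec.edges, composites={}, transforms={})
    plan = _CompiledSpec(star, flat_spec)
    rng = np.random.default_rng(seed)
    n = star.shape[0]
    count_ge = 0
    kept = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            chi2_b = plan.chi2(idx)
        except (ValueError, np.linalg.LinAlgError):
            continue
        kept += 1
        if chi2_b >= stats_obs["chi2"]:
            count_ge += 1
    if kept == 0:
        raise RuntimeError("every Bollen-Stine replicate failed")
    return count_ge / kept


def _matrix_power_sym(A: np.ndarray, power: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(A)
    if np.any(vals <= 0):
        raise ValueError("matrix is not positive definite")
    return vecs @ np.diag(vals**power) @ vecs.T


def total_effects(fit: PathModelFit):
    """Standardized direct, indirect and total effect matrices.

    total = (I - B)^-1 - I = B + B^2 + ... (finite for acyclic B);
    indirect = total - direct.  Entry [i, j] is the effect of j on i.
    """
    B = fit.B.to_numpy()
    total = np.linalg.inv(np.eye(len(fit.variables)) - B) - np.eye(len(fit.variables))
    direct = fit.B.copy()
    total = pd.DataFrame(total, index=fit.variables, columns=fit.variables)
    indirect = total - direct
    return direct, indirect, total


def total_effects_on(fit: PathModelFit, outcome: str) -> pd.Series:
    """Standardized total effect of every other variable on ``outcome``.

    For composite predictors the effect is also split over indicators in
    proportion to their standardized weights.
    """
    _, _, total = total_effects(fit)
    eff = total.loc[outcome].drop(outcome)
    extra = {}
    for name, w in fit.composite_weights.items():
        if name in eff.index:
            share = w / w.abs().sum()
            for ind, frac in share.items():
                extra[f"{name}:{ind}"] = float(eff[name] * frac)
    return pd.concat([eff, pd.Series(extra)]) if extra else eff
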