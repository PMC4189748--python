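"""Approximate Bayesian Computation over the IM model.

The inference stage follows the classic rejection + local-linear
regression recipe: draw parameters from their priors, simulate a dataset
per draw and reduce it to summary statistics, retain the draws whose
standardized statistics lie closest (Euclidean distance) to the observed
ones — 1% by default — and sharpen the retained sample with an
Epanechnikov-weighted local-linear regression of (transformed) parameters
on the statistic discrepancies.  Posterior point estimates are reported
as the mode of a weighted kernel density with a highest-posterior-density
interval.

Standardization uses the median absolute deviation of each statistic over
the whole simulation table (SD fallback when the MAD vanishes), a robust
choice in the ABCToolBox tradition.  Parameters are log-transformed
(logit for the founding fraction s) before regression and back-transformed
afterwards, so adjusted draws always respect the prior support.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .data_model import StudyDesign
from .scaling import RateModel, to_demographic
from .simulate import ScaledIMParams
from .simulate import simulate_dataset as _simulate_dataset
from .sustats import DEFAULT_ABC_STATS, SUST_NAMES, compute_sustats

__all__ = [
    "PriorSpec",
    "SimTable",
    "PosteriorSample",
    "PosteriorSummary",
    "sample_prior",
    "run_simulations",
    "abc_reject",
    "regression_adjust",
    "posterior_summary",
    "infer",
]

SCALED_PARAM_NAMES = ("theta_A", "theta1", "theta2", "T", "M1", "M2", "s")


@dataclasses.dataclass(frozen=True)
class _Prior:
    low: float
    high: float
    scale: str = "natural"  # sampling scale: natural | log
    transform: str = "log"  # regression transform: log | logit | none

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"invalid bounds ({self.low}, {self.high})")
        if self.scale not in ("natural", "log"):
            raise ValueError(f"unknown sampling scale {self.scale!r}")
        if self.transform not in ("log", "logit", "none"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.scale == "log" and self.low <= 0:
            raise ValueError("log sampling scale needs a positive lower bound")


class PriorSpec:
    """Independent uniform priors, one per parameter.

    ``bounds`` maps parameter name to (low, high) or (low, high, scale)
    where scale is "natural" (uniform) or "log" (log-uniform).
    """

    def __init__(self, bounds: Mapping):
        self.priors: dict[str, _Prior] = {}
        for name, spec in bounds.items():
            spec = tuple(spec)
            low, high = float(spec[0]), float(spec[1])
            scale = spec[2] if len(spec) > 2 else "natural"
            # interval-logit keeps regression-adjusted draws inside BOTH
            # prior bounds (a plain log would only guard the lower one)
            transform = "logit" if math.isfinite(high) else "log"
            if low < 0 or (name == "s" and (low < 0 or high > 1)):
                raise ValueError(f"{name}: bounds must respect the parameter support")
            self.priors[name] = _Prior(low, high, scale, transform)

    @property
    def names(self) -> tuple:
        return tuple(self.priors)

    def range(self, name: str) -> tuple:
        p = self.priors[name]
        return p.low, p.high

    @classmethod
    def default_im(cls, recombination: bool = False,
                   rho_bounds: tuple = (1e-8, 1e-2)) -> "PriorSpec":
        """Default mutation-scaled IM priors: theta_i in (0, 5),
        T in (0, 0.05), M_i in (0, 10), s in (0, 1); with recombination a
        log-uniform per-locus rate is added."""
        bounds = {
            "theta_A": (0.0, 5.0),
            "theta1": (0.0, 5.0),
            "theta2": (0.0, 5.0),
            "T": (0.0, 0.05),
            "M1": (0.0, 10.0),
            "M2": (0.0, 10.0),
            "s": (0.0, 1.0),
        }
        if recombination:
            bounds["rho_per_locus"] = (*rho_bounds, "log")
        return cls(bounds)


def sample_prior(priors: PriorSpec, n: int, seed) -> pd.DataFrame:
    """n i.i.d. draws from the prior; deterministic given the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = {}
    for name, p in priors.priors.items():
        if p.scale == "log":
            cols[name] = np.exp(rng.uniform(math.log(p.low), math.log(p.high), n))
        else:
            cols[name] = rng.uniform(p.low, p.high, n)
    return pd.DataFrame(cols)


@dataclasses.dataclass
class SimTable:
    """Joint record of sampled parameters and their simulated statistics."""

    params: pd.DataFrame
    stats: pd.DataFrame
    root_seed: int | None = None

    def __len__(self):
        return len(self.params)

    def to_tsv(self, path) -> None:
        joined = pd.concat(
            [self.params.add_prefix("param."), self.stats.add_prefix("stat.")], axis=1)
        joined.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SimTable":
        joined = pd.read_csv(path, sep="\t")
        params = joined[[c for c in joined if c.startswith("param.")]].rename(
            columns=lambda c: c[len("param."):])
        stats = joined[[c for c in joined if c.startswith("stat.")]].rename(
            columns=lambda c: c[len("stat."):])
        return cls(params, stats)


def _draw_to_scaled(row: Mapping) -> ScaledIMParams:
    return ScaledIMParams(
        theta_A=row["theta_A"], theta1=row["theta1"], theta2=row["theta2"],
        T=row["T"], M1=row["M1"], M2=row["M2"], s=row["s"],
        rho_per_locus=row.get("rho_per_locus", 0.0) if hasattr(row, "get")
        else row["rho_per_locus"] if "rho_per_locus" in row else 0.0,
    )


def simulate_draw(row: Mapping, design: StudyDesign, seed):
    """One dataset for one scaled-parameter draw (helper for the mass
    simulation and for posterior predictive sampling)."""
    rm = RateModel.from_design(design)
    params = to_demographic(_draw_to_scaled(row), rm)
    return _simulate_dataset(params, design, seed)


def run_simulations(draws: pd.DataFrame, design: StudyDesign, seed) -> SimTable:
    """Simulate a dataset per prior draw and tabulate its statistics.

    Each row gets its own substream spawned from the root seed, so the
    table is reproducible row by row and extendable in batches.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(len(draws))
    rm = RateModel.from_design(design)
    rows = []
    for i, (_, draw) in enumerate(draws.iterrows()):
        try:
            params = to_demographic(_draw_to_scaled(draw), rm)
            ds = _simulate_dataset(params, design, children[i])
            st = compute_sustats(ds, on_all_undefined="nan")
        except Exception as exc:
            raise RuntimeError(f"simulation failed at row {i}: {exc}") from exc
        st.pop("_exclusions", None)
        rows.append(st)
    stats = pd.DataFrame(rows, columns=list(SUST_NAMES))
    entropy = root.entropy
    return SimTable(draws.reset_index(drop=True), stats,
                    root_seed=int(entropy) if isinstance(entropy, int) and entropy < 2**63 else None)


@dataclasses.dataclass
class PosteriorSample:
    """Retained draws before and after regression adjustment."""

    params: pd.DataFrame        # retained raw draws
    adjusted: pd.DataFrame      # regression-adjusted draws (= params before adjust)
    weights: np.ndarray
    distances: np.ndarray       # distances of the retained rows
    threshold: float            # largest retained distance (regression bandwidth)
    stats_used: tuple
    retained_stats_std: np.ndarray
    obs_std: np.ndarray
    retained_index: np.ndarray
    priors: PriorSpec | None = None
    adjusted_flag: bool = False


def _standardize(table_stats: pd.DataFrame, obs: Mapping, stat_names=None):
    """Robust-standardize statistics; returns (names, sim_std, obs_std).
    Statistics with NaN observed value or zero spread are dropped."""
    if stat_names is None:
        stat_names = [n for n in table_stats.columns if n in obs]
    missing = [n for n in stat_names if n not in table_stats.columns]
    if missing:
        raise ValueError(f"statistics missing from the simulation table: {missing}")
    names, sim_cols, obs_vals = [], [], []
    for n in stat_names:
        o = obs.get(n, math.nan) if hasattr(obs, "get") else obs[n]
        if o is None or (isinstance(o, float) and math.isnan(o)):
            continue
        col = table_stats[n].to_numpy(dtype=float)
        scale = median_abs_deviation(col, nan_policy="omit", scale="normal")
        if not np.isfinite(scale) or scale == 0:
            scale = np.nanstd(col)
        if not np.isfinite(scale) or scale == 0:
            continue  # statistic carries no information across the table
        names.append(n)
        sim_cols.append(col / scale)
        obs_vals.append(o / scale)
    if not names:
        raise ValueError("no usable statistics shared between obs and table")
    return tuple(names), np.column_stack(sim_cols), np.asarray(obs_vals)


def abc_reject(obs: Mapping, table: SimTable, retention: float = 0.01,
               priors: PriorSpec | None = None,
               stats: Sequence[str] | None = None) -> PosteriorSample:
    """Retain the ceil(retention * n) draws with the smallest standardized
    Euclidean distance to the observed statistics (ties broken by row
    order).  Simulated rows with undefined entries in a used statistic can
    never be retained.

    ``stats`` selects the statistic set for the distance; by default the
    14-component :data:`imabc.sustats.DEFAULT_ABC_STATS` (intersected with
    the keys present in ``obs``) is used.
    """
    if not 0 < retention <= 1:
        raise ValueError("retention must be in (0, 1]")
    if stats is None:
        stats = [n for n in DEFAULT_ABC_STATS if n in obs]
        if not stats:  # caller supplied a custom statistic vector
            stats = [n for n in obs if not str(n).startswith("_")]
    names, sim_std, obs_std = _standardize(table.stats, obs, stat_names=list(stats))
    diff = sim_std - obs_std
    dist = np.sqrt(np.sum(diff * diff, axis=1))
    dist = np.where(np.isnan(dist), np.inf, dist)
    k = math.ceil(retention * len(table))
    order = np.argsort(dist, kind="stable")[:k]
    retained = table.params.iloc[order].reset_index(drop=True)
    return PosteriorSample(
        params=retained,
        adjusted=retained.copy(),
        weights=np.ones(k),
        distances=dist[order],
        threshold=float(dist[order].max()) if k else 0.0,
        stats_used=names,
        retained_stats_std=sim_std[order],
        obs_std=obs_std,
        retained_index=order,
        priors=priors,
    )


def _transform(y: np.ndarray, prior: _Prior | None, name: str):
    """Support-respecting transform for regression: log above the prior's
    lower bound, logit inside the s bounds, identity when no prior is
    attached (the caller then owns support safety)."""
    eps = 1e-300
    if prior is not None:
        kind, lo, hi = prior.transform, prior.low, prior.high
    else:
        kind, lo, hi = "none", 0.0, np.inf
    if kind == "none":
        return y.copy(), lambda z: z
    if kind == "log":
        yt = np.log(np.maximum(y - lo, eps))
        return yt, lambda z: np.exp(z) + lo
    span = hi - lo
    u = np.clip((y - lo) / span, 1e-12, 1 - 1e-12)
    yt = np.log(u / (1 - u))
    return yt, lambda z: lo + span / (1.0 + np.exp(-z))


def regression_adjust(post: PosteriorSample) -> PosteriorSample:
    """Beaumont-style weighted local-linear regression adjustment.

    Epanechnikov weights on distance (bandwidth = largest retained
    distance) and a weighted least-squares fit of each transformed
    parameter on the standardized statistic discrepancies; the adjusted
    draw is the fitted value at the observed statistics plus the residual.
    A singular fit falls back to the unadjusted draws with a warning.
    """
    k, p = post.retained_stats_std.shape
    if k < p + 2:
        raise ValueError(f"need >= {p + 2} retained draws for {p} statistics, got {k}")
    delta = post.threshold
    d = post.distances
    w = np.ones(k) if delta == 0 else np.maximum(1.0 - (d / delta) ** 2, 0.0)
    if w.sum() == 0:  # all retained at the bandwidth edge
        w = np.ones(k)
    x = post.retained_stats_std - post.obs_std
    design = np.column_stack([np.ones(k), x])
    sw = np.sqrt(w)
    adjusted = {}
    ok = True
    for name in post.params.columns:
        y = post.params[name].to_numpy(dtype=float)
        prior = post.priors.priors.get(name) if post.priors else None
        yt, back = _transform(y, prior, name)
        beta, *_ = np.linalg.lstsq(design * sw[:, None], yt * sw, rcond=None)
        adj_t = yt - x @ beta[1:]
        if not np.all(np.isfinite(adj_t)):
            ok = False
            break
        adjusted[name] = back(adj_t)
    if not ok:
        warnings.warn("singular regression design; returning unadjusted draws")
        adjusted_df = post.params.copy()
    else:
        adjusted_df = pd.DataFrame(adjusted, columns=post.params.columns)
    return dataclasses.replace(post, adjusted=adjusted_df, weights=w, adjusted_flag=ok)


@dataclasses.dataclass
class PosteriorSummary:
    """Mode and HPD interval of one marginal posterior."""

    param: str
    mode: float
    hpd_low: float
    hpd_high: float
    hpd_mass: float
    boundary_flag: bool
    grid: np.ndarray | None = None
    density: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {"param": self.param, "mode": self.mode, "hpd_low": self.hpd_low,
                "hpd_high": self.hpd_high, "hpd_mass": self.hpd_mass,
                "boundary_flag": self.boundary_flag}


def _weighted_quantile(x, w, q):
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return float(np.interp(q * cw[-1], cw, x[order]))


def posterior_summary(post: PosteriorSample | None, param: str,
                      draws: np.ndarray | None = None,
                      weights: np.ndarray | None = None,
                      support: tuple | None = None,
                      hpd_mass: float = 0.90, grid_size: int = 512,
                      keep_density: bool = False) -> PosteriorSummary:
    """Weighted-KDE posterior summary: grid mode, HPD interval (smallest
    density-ordered cell set of the requested mass, reported as its
    enclosing interval) and a flag raised when the density has not
    vanished at a support boundary.

    ``draws``/``weights`` may be passed directly instead of a
    :class:`PosteriorSample`; ``support`` defaults to the prior range when
    the sample carries priors, otherwise to the data range padded by three
    bandwidths.
    """
    if draws is None:
        draws = post.adjusted[param].to_numpy(dtype=float)
        weights = post.weights
        if support is None and post.priors and param in post.priors.priors:
            support = post.priors.range(param)
    x = np.asarray(draws, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    keep = np.isfinite(x) & (w > 0)
    x, w = x[keep], w[keep]
    if x.size == 0:
        raise ValueError("no finite draws with positive weight")
    if np.ptp(x) == 0.0:
        v = float(x[0])
        return PosteriorSummary(param, v, v, v, hpd_mass, False)

    wsum = w.sum()
    mean = np.sum(w * x) / wsum
    sigma = math.sqrt(np.sum(w * (x - mean) ** 2) / wsum)
    iqr = _weighted_quantile(x, w, 0.75) - _weighted_quantile(x, w, 0.25)
    neff = wsum ** 2 / np.sum(w ** 2)
    spread = min(sigma, iqr / 1.34) if iqr > 0 else sigma
    h = 0.9 * spread * neff ** (-0.2)  # Silverman on the weighted sample
    if h <= 0:
        h = sigma * neff ** (-0.2) or 1e-12

    bounded = support is not None
    if support is None:
        support = (float(x.min() - 3 * h), float(x.max() + 3 * h))
    grid = np.linspace(support[0], support[1], grid_size)

    def kde(bandwidth):
        # reflect the sample at finite support bounds so the estimate does
        # not lose mass (and bias the HPD inward) at hard prior boundaries
        pts, wts = [x], [w]
        if bounded:
            pts += [2 * support[0] - x, 2 * support[1] - x]
            wts += [w, w]
        dens = np.zeros_like(grid)
        for p, ww in zip(pts, wts):
            z = (grid[:, None] - p[None, :]) / bandwidth
            dens += np.exp(-0.5 * z * z) @ ww
        return dens / (wsum * bandwidth * math.sqrt(2 * math.pi))

    density = kde(h)
    dx = grid[1] - grid[0]
    total = density.sum() * dx
    if total <= 0:
        raise ValueError("degenerate density")
    # the argmax of a density estimate is noisier than the density itself;
    # the mode-optimal bandwidth scales as n^(-1/7), not Silverman's n^(-1/5)
    h_mode = 1.5 * spread * neff ** (-1.0 / 7.0)
    mode = float(grid[int(np.argmax(kde(h_mode)))]) if h_mode > 0 else \
        float(grid[int(np.argmax(density))])
    order = np.argsort(density)[::-1]
    cum = np.cumsum(density[order]) * dx / total
    n_cells = int(np.searchsorted(cum, hpd_mass)) + 1
    chosen = order[:n_cells]
    hpd_low, hpd_high = float(grid[chosen].min()), float(grid[chosen].max())
    hpd_low, hpd_high = min(hpd_low, mode), max(hpd_high, mode)
    dmax = density.max()
    boundary = bool(density[0] > 0.01 * dmax or density[-1] > 0.01 * dmax)
    return PosteriorSummary(param, mode, hpd_low, hpd_high, hpd_mass, boundary,
                            grid if keep_density else None,
                            density if keep_density else None)


def infer(obs: Mapping, design: StudyDesign, priors: PriorSpec, nsim: int,
          seed, retention: float = 0.01, adjust: bool = True,
          table: SimTable | None = None):
    """End-to-end ABC: prior sampling, mass simulation, rejection,
    regression adjustment and per-parameter summaries.

    Returns (PosteriorSample, {param: PosteriorSummary}, SimTable).  Pass a
    precomputed ``table`` to reuse simulations (nsim is then ignored).
    """
    root = np.random.SeedSequence(seed)
    if table is None:
        ss_prior, ss_sim = root.spawn(2)
        draws = sample_prior(priors, nsim, np.random.default_rng(ss_prior))
        table = run_simulations(draws, design, ss_sim)
    post = abc_reject(obs, table, retention=retention, priors=priors)
    if adjust:
        post = regression_adjust(post)
    summaries = {name: posterior_summary(post, name) for name in post.params.columns}
    return post, summaries, table
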