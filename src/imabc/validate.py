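"""Statistical validation of the ABC pipeline.

Three layers, mirroring standard ABC practice:

* **Posterior predictive tests** — simulate datasets from the fitted
  posterior and ask, statistic by statistic, whether the observed value is
  typical of the predictive distribution (two-tailed empirical p-value).
* **Pseudo-observed datasets (PODs)** — run the full inference on data
  simulated at known parameters drawn from the prior and measure 90% HPD
  coverage, signed bias of the mode and RMSE per parameter.
* **Summary-statistic informativeness** — the determination coefficient
  R^2 of each (transformed) parameter regressed on all standardized
  statistics over the simulation table: the fraction of prior parameter
  variance the statistics can explain at all.

POD calibration supports two budgets: a fresh reference table per POD
(faithful but expensive) and a shared-table leave-one-out mode in which a
single prior-predictive table provides both the PODs and, minus the
held-out row, the reference simulations — the standard cross-validation
device of ABC toolkits.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abc import (PosteriorSample, PriorSpec, SimTable, _transform,
                  abc_reject, posterior_summary, regression_adjust,
                  run_simulations, sample_prior, simulate_draw)
from .data_model import StudyDesign
from .sustats import compute_sustats

__all__ = [
    "empirical_two_tailed_p",
    "posterior_predictive_test",
    "pod_validation",
    "sust_r2",
]


def empirical_two_tailed_p(sample: np.ndarray, obs: float) -> float:
    """Doubled one-sided empirical tail probability, capped at 1.

    p = min(1, 2 * min(P(sample <= obs), P(sample >= obs))); NaN when the
    sample is empty after dropping undefined values.
    """
    x = np.asarray(sample, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return math.nan
    lo = float(np.mean(x <= obs))
    hi = float(np.mean(x >= obs))
    return min(1.0, 2.0 * min(lo, hi))


def posterior_predictive_test(post: PosteriorSample, obs: Mapping,
                              design: StudyDesign, n_rep: int, seed) -> dict:
    """Two-tailed posterior predictive p-value per summary statistic.

    Parameters are resampled from the (weighted, adjusted) posterior,
    ``n_rep`` datasets are simulated and p = min(1, 2 * min(P(sim <= obs),
    P(sim >= obs))) is computed against the predictive sample (undefined
    replicate entries are dropped per statistic).
    """
    if n_rep < 100:
        raise ValueError("n_rep must be >= 100")
    root = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    rng = np.random.default_rng(root.spawn(1)[0])
    w = np.asarray(post.weights, dtype=float)
    if w.sum() <= 0 or len(post.adjusted) < 2:
        import warnings
        warnings.warn("degenerate posterior; resampling uniformly")
        w = np.ones(len(post.adjusted))
    p_idx = rng.choice(len(post.adjusted), size=n_rep, p=w / w.sum())
    children = root.spawn(n_rep)
    rows = []
    for r, i in enumerate(p_idx):
        ds = simulate_draw(post.adjusted.iloc[i], design, children[r])
        st = compute_sustats(ds, on_all_undefined="nan")
        st.pop("_exclusions", None)
        rows.append(st)
    pred = pd.DataFrame(rows)
    pvals = {}
    for name, o in obs.items():
        if name.startswith("_") or name not in pred.columns:
            continue
        if o is None or (isinstance(o, float) and math.isnan(o)):
            continue
        pvals[name] = empirical_two_tailed_p(pred[name].to_numpy(dtype=float), o)
    return pvals


def _default_estimator(retention: float, adjust: bool, hpd_mass: float):
    def run(obs, table, truth, priors):
        post = abc_reject(obs, table, retention=retention, priors=priors)
        if adjust:
            post = regression_adjust(post)
        out = {}
        for name in post.params.columns:
            s = posterior_summary(post, name, hpd_mass=hpd_mass)
            out[name] = (s.mode, s.hpd_low, s.hpd_high)
        return out
    return run


def pod_validation(priors: PriorSpec, design: StudyDesign, n_pods: int,
                   budget: int, seed, retention: float = 0.01,
                   adjust: bool = True, hpd_mass: float = 0.90,
                   shared_table: bool = True, params: Sequence[str] | None = None,
                   estimator=None, table: SimTable | None = None) -> dict:
    """Coverage / bias / RMSE calibration on pseudo-observed datasets.

    With ``shared_table=True`` (default) one ``budget``-row
    prior-predictive table is simulated; ``n_pods`` of its rows serve as
    PODs (their parameters are the truths, their statistics the
    observations) and the inference for each POD uses the table minus that
    row.  With ``shared_table=False`` each POD gets a fresh table of
    ``budget`` rows.  ``params`` restricts which parameters are scored.
    ``estimator(obs, table, truth, priors)`` may replace the inference; it
    must return ``{param: (mode, hpd_low, hpd_high)}`` (the truth argument
    exists so harness self-tests can inject an oracle).
    """
    if n_pods < 1:
        raise ValueError("n_pods must be >= 1")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    est = estimator or _default_estimator(retention, adjust, hpd_mass)

    tracked = tuple(params) if params is not None else priors.names
    records = {name: {"cover": [], "err": []} for name in tracked}
    n_failed = 0

    if shared_table:
        ss_prior, ss_sim, ss_pick = root.spawn(3)
        if table is None:
            draws = sample_prior(priors, budget, np.random.default_rng(ss_prior))
            table = run_simulations(draws, design, ss_sim)
        if n_pods > len(table):
            raise ValueError("n_pods exceeds the table size")
        pick = np.random.default_rng(ss_pick).choice(len(table), n_pods, replace=False)
        for i in pick:
            truth = table.params.iloc[i]
            obs = table.stats.iloc[i].to_dict()
            rest = SimTable(table.params.drop(index=i).reset_index(drop=True),
                            table.stats.drop(index=i).reset_index(drop=True))
            try:
                result = est(obs, rest, truth, priors)
            except Exception as exc:
                logging.getLogger(__name__).warning("POD %d failed: %s", i, exc)
                n_failed += 1
                continue
            _record(records, result, truth)
    else:
        pod_streams = root.spawn(n_pods)
        for k in range(n_pods):
            ss_truth, ss_obs, ss_prior, ss_sim = pod_streams[k].spawn(4)
            truth = sample_prior(priors, 1, np.random.default_rng(ss_truth)).iloc[0]
            obs_ds = simulate_draw(truth, design, ss_obs)
            obs = compute_sustats(obs_ds, on_all_undefined="nan")
            obs.pop("_exclusions", None)
            draws = sample_prior(priors, budget, np.random.default_rng(ss_prior))
            tab = run_simulations(draws, design, ss_sim)
            try:
                result = est(obs, tab, truth, priors)
            except Exception as exc:
                logging.getLogger(__name__).warning("POD %d failed: %s", k, exc)
                n_failed += 1
                continue
            _record(records, result, truth)

    per_param = {}
    for name, rec in records.items():
        if not rec["err"]:
            continue
        err = np.asarray(rec["err"], dtype=float)
        per_param[name] = {
            "coverage": float(np.mean(rec["cover"])),
            "mean_error": float(err.mean()),
            "rmse": float(np.sqrt(np.mean(err ** 2))),
            "n": int(err.size),
        }
    return {
        "per_param": per_param,
        "n_pods": n_pods,
        "n_failed": n_failed,
        "hpd_mass": hpd_mass,
        "budget": budget,
        "shared_table": shared_table,
    }


def _record(records, result, truth):
    for name, (mode, lo, hi) in result.items():
        if name not in records:
            continue
        t = float(truth[name])
        records[name]["cover"].append(lo <= t <= hi)
        records[name]["err"].append(mode - t)


def sust_r2(table: SimTable, param: str, priors: PriorSpec | None = None) -> float:
    """R^2 of the (transformed) parameter on all standardized statistics.

    Ordinary least squares over the full simulation table; rows with any
    undefined statistic are dropped, constant statistics are skipped and
    collinear ones are handled by the pseudoinverse.  Requires at least
    10 rows per statistic.
    """
    stats = table.stats
    y_raw = table.params[param].to_numpy(dtype=float)
    cols, names = [], []
    for n in stats.columns:
        col = stats[n].to_numpy(dtype=float)
        sd = np.nanstd(col)
        if np.isfinite(sd) and sd > 0:
            names.append(n)
            cols.append(col)
    x = np.column_stack(cols)
    keep = np.all(np.isfinite(x), axis=1) & np.isfinite(y_raw)
    x, y_raw = x[keep], y_raw[keep]
    if x.shape[0] < 10 * x.shape[1]:
        raise ValueError(f"need >= {10 * x.shape[1]} usable rows, have {x.shape[0]}")
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    prior = priors.priors.get(param) if priors else None
    y, _ = _transform(y_raw, prior, param)
    design = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return float(max(0.0, 1.0 - np.sum(resid ** 2) / ss_tot))
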