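"""Descriptive statistics and end-to-end orchestration.

Direct numerosity estimates are summarised per condition by linear fits
``f(x) = p1 * x + p2`` against the true visible count, by the coefficient
of variation (sd / mean), and — for the night-sky task — by comparing
estimates of hidden stars against the objectively and subjectively
expected counts.  :func:`run_pipeline` wires design -> simulation ->
fitting -> summaries into one reproducible run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import geometry
from .bayes import UrnSpec, compare_models, fit_prior
from .geometry import OcclusionGeometry, enumerate_trials, expected_hidden
from .psychofit import fit_confidence, fit_psychometric
from .simulate import (ConfidenceParams, PsychometricParams,
                       simulate_bayesian_estimates, simulate_confidence,
                       simulate_linear_estimates, simulate_selection)
from .bayes import GaussianPrior

#: hidden-to-visible area ratios as printed for the two mesh occluders
#: (ratio_source: published); computed geometry is available via
#: occlusion_geometry for parameterized meshes.
PUBLISHED_RATIOS = {"small_occluder": 0.27, "large_occluder": 1.05,
                     "mesh_40_60": 0.27, "mesh_30_45": 1.05}


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line fit ``y = p1 * x + p2``."""

    p1: float
    p2: float
    r_squared: float
    n: int
    clamped: bool = False


def fit_linear(x, y) -> LinearFit:
    """OLS fit of a line; R^2 is 1 - RSS/TSS, clamped at 0 (flagged)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate fit: x is constant")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum((y - pred) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    clamped = r2 < 0
    return LinearFit(p1=float(res.slope), p2=float(res.intercept),
                     r_squared=max(r2, 0.0), n=int(x.size), clamped=clamped)


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1 denominator) over the mean."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mean = v.mean()
    if mean == 0:
        raise ZeroDivisionError("CV undefined for zero mean")
    return float(v.std(ddof=1) / mean)


def exp3_proportion(max_count: float, board=None) -> float:
    """Convert a maximum-hidden-pieces report to a proportion of the
    board (slider maximum = total cell count)."""
    n_cells = board.n_cells if board is not None else 117
    if not 0 <= max_count <= n_cells:
        raise ValueError(f"max_count must lie in [0, {n_cells}]")
    return float(max_count) / n_cells


def subjective_expectation(est_visible: float, est_proportion: float) -> float:
    """Expected hidden count from *perceived* quantities.

    The reported cover fraction is read as hidden area over total area,
    so the hidden/visible ratio is ``p / (1 - p)`` and the constant-density
    rule gives ``est_visible * p / (1 - p)``.
    """
    if not 0 <= est_proportion < 1:
        raise ValueError("est_proportion must lie in [0, 1)")
    if est_visible < 0:
        raise ValueError("est_visible must be non-negative")
    return est_visible * est_proportion / (1.0 - est_proportion)


def condition_summary(responses: pd.DataFrame) -> pd.DataFrame:
    """Per-condition, per-numerosity mean/sd of estimates plus CV and a
    linear fit of mean estimate against the true visible count."""
    est = responses[responses["response_type"].isin(
        ["estimate", "hidden_estimate"])]
    rows = []
    for (cond, rtype), grp in est.groupby(["condition", "response_type"]):
        per_n = grp.groupby("n_visible")["response"].agg(["mean", "std", "count"])
        fit = None
        if len(per_n) >= 2 and per_n.index.nunique() >= 2:
            fit = fit_linear(per_n.index.to_numpy(dtype=float),
                             per_n["mean"].to_numpy())
        for n_v, r in per_n.iterrows():
            cv = float(r["std"] / r["mean"]) if r["mean"] else np.nan
            rows.append(dict(condition=cond, response_type=rtype,
                             n_visible=n_v, mean=r["mean"], sd=r["std"],
                             n=int(r["count"]), cv=cv,
                             slope=fit.p1 if fit else np.nan,
                             intercept=fit.p2 if fit else np.nan,
                             r_squared=fit.r_squared if fit else np.nan))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration

DEFAULT_CONFIG = {
    "experiment": 1,
    "seed": 0,
    "observer": {
        "psychometric": {"alpha": -1.45, "beta": 3.0, "gamma": 0.02,
                         "lam": 0.02},
        "confidence": {"mu": -1.99, "sigma": 4.0, "a": 0.73},
        "linear": {"slope": 0.81, "intercept": 1.31, "noise_sd": 1.5},
        "bayesian": {"kind": "constant_hidden", "mean": 2.48, "sd": 1.45,
                     "noise_sd": 0.0},
    },
    "ratio_source": "published",
}


def _urns_for_exp2(ratio_source: str = "published") -> dict[str, UrnSpec]:
    """Urn geometries for the two mesh occluders of the estimation task."""
    urns = {}
    for label in ("mesh_40_60", "mesh_30_45"):
        if ratio_source == "published":
            geom = OcclusionGeometry.from_ratio(PUBLISHED_RATIOS[label])
        else:
            small, large = (int(p) for p in label.split("_")[1:])
            board = geometry.make_board()
            occ = geometry.make_mesh_occluder(small, large)
            geom = geometry.occlusion_geometry(board, occ)
        urns[label] = UrnSpec(N_v=geom.N_v, N_h=geom.N_h)
    return urns


def run_pipeline(config: dict | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Run design -> simulate -> fit -> summarize for one experiment.

    Returns a result bundle (trial table, response tables, fits,
    summaries, report lines) and, when ``out_dir`` is given, writes the
    CSVs, a manifest, and a plain-text report there.  Fully deterministic
    for a fixed config + seed.
    """
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if config:
        for key, val in config.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    exp = int(cfg["experiment"])
    seed = int(cfg["seed"])
    trials = enumerate_trials(exp)
    bundle: dict = {"config": cfg, "trials": trials, "responses": {},
                    "fits": {}, "report": []}
    rep = bundle["report"].append

    if exp == 1:
        pp = PsychometricParams(**cfg["observer"]["psychometric"])
        cp = ConfidenceParams(**cfg["observer"]["confidence"])
        choices = simulate_selection(trials, pp, seed)
        confid = simulate_confidence(trials, cp, seed + 1)
        bundle["responses"] = {"choice": choices, "confidence": confid}
        for cond, grp in choices.groupby("condition"):
            per = grp.groupby("delta_n")["response"].mean()
            fit = fit_psychometric(per.index.to_numpy(), per.to_numpy())
            bundle["fits"][f"psychometric/{cond}"] = fit
            rep(f"exp1 {cond}: PSE = {fit.params['alpha']:.3f} "
                f"(beta = {fit.params['beta']:.3f}, "
                f"lapse = {fit.params['lambda']:.4f})")
        for cond, grp in confid.groupby("condition"):
            per = grp.groupby("delta_n")["response"].mean()
            fit = fit_confidence(per.index.to_numpy(), per.to_numpy())
            bundle["fits"][f"confidence/{cond}"] = fit
            rep(f"exp1 {cond}: min-confidence point = "
                f"{fit.params['mu']:.3f} (amplitude a = {fit.params['a']:.3f})")

    elif exp == 2:
        bc = cfg["observer"]["bayesian"]
        urns = _urns_for_exp2(cfg.get("ratio_source", "published"))
        prior = GaussianPrior(bc["kind"], bc["mean"], bc["sd"])
        occluded = trials[trials["occluder"].isin(urns)]
        est = simulate_bayesian_estimates(occluded, urns, prior,
                                          noise_sd=bc.get("noise_sd", 0.0),
                                          rng_seed=seed)
        lin = cfg["observer"]["linear"]
        visible = simulate_linear_estimates(trials, lin["slope"],
                                            lin["intercept"],
                                            lin["noise_sd"], seed + 1)
        bundle["responses"] = {"hidden_estimate": est,
                               "visible_estimate": visible}
        means = est.groupby(["occluder", "n_visible"])["response"].mean()
        cells = [(int(n_v), urns[occ]) for (occ, n_v) in means.index]
        y = means.to_numpy()
        rss_by = {}
        for kind in ("constant_hidden", "constant_total"):
            prior_fit, rss = fit_prior(cells, y, kind)
            rss_by[kind] = rss
            bundle["fits"][f"prior/{kind}"] = prior_fit
            rep(f"exp2 {kind}: prior mean = {prior_fit.mean:.3f}, "
                f"sd = {prior_fit.sd:.3f}, RSS = {rss:.4f}")
        comp = compare_models(rss_by, n_points=len(cells))
        bundle["fits"]["model_comparison"] = comp
        for label, b, w in zip(comp.labels, comp.bic, comp.weights):
            rep(f"exp2 {label}: BIC = {b:.2f}, weight = {w:.3f}")
        rep(f"exp2 winner: {comp.winner}")
        bundle["summary"] = condition_summary(pd.concat([est, visible]))

    elif exp in (3, 4, 5):
        lin = cfg["observer"]["linear"]
        est = simulate_linear_estimates(trials, lin["slope"], lin["intercept"],
                                        lin["noise_sd"], seed)
        bundle["responses"] = {"estimate": est}
        bundle["summary"] = condition_summary(est)
        fit = fit_linear(est["n_visible"].to_numpy(dtype=float),
                         est["response"].to_numpy(dtype=float))
        bundle["fits"]["linear"] = fit
        rep(f"exp{exp} linear fit: slope = {fit.p1:.3f}, "
            f"intercept = {fit.p2:.3f}, R^2 = {fit.r_squared:.3f}")

    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle["trials"].to_csv(out_dir / "trials.csv", index=False)
    for name, df in bundle["responses"].items():
        df.to_csv(out_dir / f"responses_{name}.csv", index=False)
    if "summary" in bundle and isinstance(bundle.get("summary"), pd.DataFrame):
        bundle["summary"].to_csv(out_dir / "summary.csv", index=False)
    (out_dir / "report.txt").write_text("\n".join(bundle["report"]) + "\n")
    cfg_text = json.dumps(bundle["config"], sort_keys=True)
    manifest = {
        "config": bundle["config"],
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": bundle["config"]["seed"],
        "package": "hiddenum",
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
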