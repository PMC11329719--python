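"""Longitudinal trajectories of motor and cognitive scores per cluster.

Outcomes (UPDRS-III, MoCA) are modelled over up to six annual visits with a
linear mixed-effects model: fixed effects are the full factorial of time,
cluster and (mean-centered) baseline age; each subject gets a random
intercept; estimation is REML.  The omnibus time-by-cluster interaction is
a Wald chi-square over every fixed term containing both time and cluster;
pairwise per-cluster slope differences (at the mean age) use the Tukey
studentized-range adjustment.  Estimated marginal means are predictions at
the sample mean age with delta-method standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import studentized_range
import statsmodels.formula.api as smf


@dataclass
class TrajectoryFit:
    """REML fit of one outcome's cluster trajectories."""

    outcome: str
    params: pd.Series
    cov_params: pd.DataFrame
    clusters: list[int]
    slopes: pd.DataFrame          # cluster, slope, se (at mean age)
    omnibus: dict                 # statistic, df, p for time x cluster
    contrasts: pd.DataFrame       # pair, estimate, se, q, p_tukey, significant
    random_intercept_var: float
    residual_var: float
    mean_age: float
    converged: bool
    n_subjects: int
    n_obs: int
    result: object = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [f"Trajectory model: {self.outcome} ~ time * cluster * age_c "
                 f"+ (1 | subject), REML",
                 f"subjects={self.n_subjects}  observations={self.n_obs}  "
                 f"converged={self.converged}",
                 f"random intercept var={self.random_intercept_var:.3f}  "
                 f"residual var={self.residual_var:.3f}",
                 f"time x cluster omnibus: chi2={self.omnibus['statistic']:.3f} "
                 f"(df={self.omnibus['df']}), p={self.omnibus['p']:.4f}",
                 "per-cluster slopes (points/year at mean age):"]
        for _, r in self.slopes.iterrows():
            lines.append(f"  cluster {int(r['cluster'])}: "
                         f"{r['slope']:+.3f} (se {r['se']:.3f})")
        sig = self.contrasts[self.contrasts["significant"]]
        if len(sig):
            lines.append("Tukey-significant slope contrasts: "
                         + ", ".join(f"{a} vs {b}" for a, b in sig["pair"]))
        return "\n".join(lines)


def _slope_vector(params_index, cluster, clusters):
    """Contrast vector extracting d(outcome)/d(time) for a cluster at age_c=0."""
    c = np.zeros(len(params_index))
    for i, name in enumerate(params_index):
        if name == "time":
            c[i] = 1.0
        elif name == f"time:C(cluster)[T.{cluster}]":
            c[i] = 1.0
    return c


def fit_trajectory(visits: pd.DataFrame, baseline: pd.DataFrame,
                   labels: np.ndarray, outcome: str = "updrs3",
                   min_subjects_per_cluster: int = 5) -> TrajectoryFit:
    """Fit the mixed model of one outcome's trajectories across clusters.

    ``visits`` has one row per (subject, visit) with ``time`` in years;
    ``baseline`` supplies age; ``labels`` aligns with ``baseline`` rows
    (0 = excluded, dropped).  Clusters with fewer than
    ``min_subjects_per_cluster`` longitudinal subjects are excluded with a
    warning.  Non-convergence is reported on the fit, never silently
    replaced.
    """
    labels = np.asarray(labels)
    meta = baseline[["subject_id", "age"]].copy()
    meta["cluster"] = labels
    meta = meta[meta["cluster"] != 0]
    d = visits.merge(meta, on="subject_id", how="inner")
    d = d.dropna(subset=[outcome, "time", "age"])

    counts = d.groupby("cluster")["subject_id"].nunique()
    small = counts[counts < min_subjects_per_cluster].index.tolist()
    if small:
        warnings.warn(f"cluster(s) {small} have < {min_subjects_per_cluster} "
                      "longitudinal subjects; excluded from the trajectory model")
        d = d[~d["cluster"].isin(small)]
    if d["subject_id"].nunique() < 30 or (d.groupby("subject_id").size() < 2).all():
        raise ValueError("need >= 30 subjects with >= 2 visits")

    mean_age = float(d.groupby("subject_id")["age"].first().mean())
    d = d.assign(age_c=d["age"] - mean_age)
    clusters = sorted(int(c) for c in d["cluster"].unique())

    formula = f"{outcome} ~ time * C(cluster) * age_c"
    model = smf.mixedlm(formula, data=d, groups=d["subject_id"], re_formula="1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    converged = bool(getattr(res, "converged", True))

    params = res.fe_params
    cov = pd.DataFrame(np.asarray(res.cov_params())[:len(params), :len(params)],
                       index=params.index, columns=params.index)

    # omnibus Wald test: every fixed term containing both time and cluster
    inter = [n for n in params.index if "time" in n and "C(cluster)" in n]
    if inter:
        R = np.zeros((len(inter), len(params)))
        for i, name in enumerate(inter):
            R[i, params.index.get_loc(name)] = 1.0
        wald = res.wald_test(np.hstack([R, np.zeros((len(inter),
                             res.params.shape[0] - len(params)))]),
                             use_f=False, scalar=True)
        omnibus = {"statistic": float(wald.statistic), "df": len(inter),
                   "p": float(wald.pvalue)}
    else:
        omnibus = {"statistic": np.nan, "df": 0, "p": np.nan}

    # per-cluster slopes at the mean age
    slope_rows, vectors = [], {}
    for c in clusters:
        v = _slope_vector(params.index, c, clusters)
        vectors[c] = v
        est = float(v @ params.to_numpy())
        se = float(np.sqrt(v @ cov.to_numpy() @ v))
        slope_rows.append({"cluster": c, "slope": est, "se": se})
    slopes = pd.DataFrame(slope_rows)

    # Tukey-adjusted pairwise slope contrasts
    k = len(clusters)
    df_resid = max(int(d.shape[0] - len(params)), 2)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = clusters[i], clusters[j]
            v = vectors[a] - vectors[b]
            est = float(v @ params.to_numpy())
            se = float(np.sqrt(v @ cov.to_numpy() @ v))
            q = abs(est) / se * np.sqrt(2.0) if se > 0 else np.inf
            p = float(studentized_range.sf(q, k, df_resid)) if k > 1 else 1.0
            rows.append({"pair": (a, b), "estimate": est, "se": se,
                         "q": q, "p_tukey": p, "significant": p < 0.05})
    contrasts = pd.DataFrame(rows)

    return TrajectoryFit(
        outcome=outcome, params=params, cov_params=cov, clusters=clusters,
        slopes=slopes, omnibus=omnibus, contrasts=contrasts,
        random_intercept_var=float(np.asarray(res.cov_re)[0, 0]),
        residual_var=float(res.scale), mean_age=mean_age,
        converged=converged,
        n_subjects=int(d["subject_id"].nunique()), n_obs=int(len(d)),
        result=res,
    )


def marginal_means(fit: TrajectoryFit, times=range(0, 7)) -> pd.DataFrame:
    """Estimated marginal means per cluster and visit time at the mean age.

    Delta-method standard errors from the fixed-effect covariance.  Times
    outside the fitted range trigger an extrapolation warning.
    """
    if not np.isfinite(fit.params.to_numpy()).all():
        raise ValueError("marginal means require finite fixed-effect estimates")
    if not fit.converged:
        # zero-variance (noise-free) fits hit the boundary and are flagged
        # non-converged even when the fixed effects are exact
        warnings.warn("trajectory fit did not formally converge; "
                      "marginal means use the reported estimates")
    params = fit.params.to_numpy()
    cov = fit.cov_params.to_numpy()
    names = list(fit.params.index)
    tmax = None
    if fit.result is not None:
        tmax = float(fit.result.model.data.frame["time"].max())
    rows = []
    for c in fit.clusters:
        base = np.zeros(len(names))
        base[names.index("Intercept")] = 1.0
        if f"C(cluster)[T.{c}]" in names:
            base[names.index(f"C(cluster)[T.{c}]")] = 1.0
        slope = _slope_vector(names, c, fit.clusters)
        for t in times:
            if tmax is not None and t > tmax:
                warnings.warn(f"time {t} lies beyond the fitted range "
                              f"(max {tmax:g}); extrapolating")
            v = base + float(t) * slope
            rows.append({"cluster": c, "time": float(t),
                         "mean": float(v @ params),
                         "se": float(np.sqrt(v @ cov @ v))})
    return pd.DataFrame(rows)
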