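"""Statistical characterization of clusters.

Continuous variables are compared across clusters with the Kruskal-Wallis
test (tie-corrected, chi-square approximation) and Dunn-type rank post-hocs
with Holm adjustment; categorical variables with plain Pearson chi-square
(no continuity correction) and Holm-adjusted pairwise sub-tables.  Atrophy
versus controls is mapped per ROI with an ANCOVA (measure ~ group +
covariates), Benjamini-Hochberg correction across the 41 ROIs, and Cohen's
d on age-adjusted measures, the sign oriented so positive d means more
atrophy in the cluster.  All tests are two-sided at alpha = 0.05, with
per-variable pairwise deletion of missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats as st
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .io import ROIMatrix

ALPHA = 0.05


# ---------------------------------------------------------------------------
# omnibus tests
# ---------------------------------------------------------------------------

def kruskal_wallis(*groups) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H across >= 2 samples.

    Returns (H, df, p).  When every value is identical in every group the
    statistic is defined as 0 with p = 1 (degenerate case).
    """
    groups = [np.asarray(g, float) for g in groups]
    groups = [g[np.isfinite(g)] for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups after pairwise deletion")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, df, 1.0
    H, p = st.kruskal(*groups)
    return float(H), df, float(p)


def chi_square_table(counts) -> tuple[float, int, float]:
    """Plain Pearson chi-square of independence on an r x c count table.

    No continuity correction.  Returns (chi2, df, p).
    """
    obs = np.asarray(counts, float)
    if (obs < 0).any():
        raise ValueError("negative counts")
    if obs.sum() == 0 or (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin; expected counts undefined")
    chi2, p, dof, _ = st.chi2_contingency(obs, correction=False)
    return float(chi2), int(dof), float(p)


# ---------------------------------------------------------------------------
# post-hoc pairwise comparisons
# ---------------------------------------------------------------------------

def _dunn_pairwise(groups: dict) -> dict:
    """Dunn-type rank comparisons on the pooled ranking, tie-corrected."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = st.rankdata(pooled)
    n = len(pooled)
    # tie correction for the rank variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    mean_ranks, sizes = {}, {}
    pos = 0
    for g in names:
        m = len(groups[g])
        mean_ranks[g] = ranks[pos:pos + m].mean()
        sizes[g] = m
        pos += m
    out = {}
    for a, b in combinations(names, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                     * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        out[(a, b)] = 2.0 * st.norm.sf(abs(z))
    return out


def posthoc_pairwise(groups: dict, omnibus_p: float,
                     kind: str = "continuous") -> list[tuple]:
    """Holm-adjusted pairwise comparisons, gated on a significant omnibus.

    ``groups`` maps group name to a value array (continuous) or a count
    vector over categories (categorical).  Returns the pairs whose adjusted
    p falls below 0.05; an empty list (with no computation) when the
    omnibus was not significant.
    """
    if omnibus_p >= ALPHA:
        return []
    names = list(groups)
    if len(names) < 2:
        return []
    if kind == "continuous":
        clean = {g: np.asarray(groups[g], float) for g in names}
        clean = {g: v[np.isfinite(v)] for g, v in clean.items()}
        raw = _dunn_pairwise(clean)
    else:
        raw = {}
        for a, b in combinations(names, 2):
            tab = np.vstack([groups[a], groups[b]])
            tab = tab[:, tab.sum(axis=0) > 0]
            try:
                _, _, p = chi_square_table(tab)
            except ValueError:
                p = np.nan
            raw[(a, b)] = p
    pairs = [pq for pq in raw.items() if np.isfinite(pq[1])]
    if not pairs:
        return []
    rej, adj, _, _ = multipletests([p for _, p in pairs], alpha=ALPHA, method="holm")
    return [(pair, float(q)) for (pair, _), r, q in zip(pairs, rej, adj) if r]


# ---------------------------------------------------------------------------
# FDR and effect-size maps
# ---------------------------------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values (monotone)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled-sd Cohen's d of mean(x) - mean(y), unequal-n weighting."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = (((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
           / (nx + ny - 2))
    if sp2 == 0:
        return 0.0
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


@dataclass
class EffectSizeMap:
    """Per-ROI atrophy of one cluster relative to HC."""

    table: pd.DataFrame          # roi, kind, d, p, q, significant, estimable
    cluster_n: int
    hc_n: int
    covariates: list[str] = field(default_factory=list)

    @property
    def significant_rois(self) -> list[str]:
        t = self.table
        return t.loc[t["significant"], "roi"].tolist()


def effect_size_map(matrix: ROIMatrix, table: pd.DataFrame,
                    cluster_mask, hc_mask,
                    covariates=("age", "field_strength", "cohort")) -> EffectSizeMap:
    """ANCOVA + FDR + Cohen's d map of one cluster versus the HC group.

    Per ROI, fits ``measure ~ group + covariates`` (eTIV added for volume
    features) on cluster + HC subjects, collects the group p over the 41
    ROIs, applies Benjamini-Hochberg, and computes pooled-sd Cohen's d on
    age-adjusted measures.  d is reported (unmasked) only where q < 0.05;
    its sign is positive when the cluster is more atrophic (lower
    thickness/volume) than HC.
    """
    import statsmodels.formula.api as smf

    cmask = np.asarray(cluster_mask, bool)
    hmask = np.asarray(hc_mask, bool)
    if not hmask.any():
        raise ValueError("HC group is empty")
    sel = cmask | hmask
    sub = table.loc[sel].reset_index(drop=True)
    sub["is_cluster"] = cmask[sel].astype(int)
    vals = matrix.values[sel]

    rows = []
    for j, (roi, kind) in enumerate(zip(matrix.features, matrix.kinds)):
        sub["y"] = vals[:, j]
        terms = ["is_cluster"]
        for c in covariates:
            if c not in sub.columns:
                continue
            terms.append(f"C({c})" if sub[c].dtype == object or c in
                         ("cohort", "field_strength", "sex") else c)
        if kind == "volume" and "etiv" in sub.columns:
            terms.append("etiv")
        formula = "y ~ " + " + ".join(terms)
        try:
            fit = smf.ols(formula, data=sub).fit()
            p = float(fit.pvalues["is_cluster"])
            estimable = np.isfinite(p)
        except Exception:
            p, estimable = np.nan, False
        # Cohen's d on age-adjusted measures, pooled over cluster + HC
        age = sub["age"].to_numpy(float)
        y = vals[:, j]
        ac = age - age.mean()
        beta = (ac @ y) / (ac @ ac) if (ac @ ac) > 0 else 0.0
        yadj = y - beta * ac
        d = cohens_d(yadj[sub["is_cluster"] == 0], yadj[sub["is_cluster"] == 1])
        rows.append({"roi": roi, "kind": kind, "d": d, "p": p,
                     "estimable": estimable})

    out = pd.DataFrame(rows)
    finite = out["p"].notna()
    q = np.full(len(out), np.nan)
    if finite.any():
        q[finite] = bh_fdr(out.loc[finite, "p"].to_numpy())
    out["q"] = q
    out["significant"] = (out["q"] < ALPHA).fillna(False)
    out.loc[~out["significant"], "d"] = np.nan   # mask non-significant effects
    return EffectSizeMap(table=out, cluster_n=int(cmask.sum()),
                         hc_n=int(hmask.sum()), covariates=list(covariates))


# ---------------------------------------------------------------------------
# cross-solution transitions
# ---------------------------------------------------------------------------

def transition_table(labels_a, labels_b, subjects_a=None, subjects_b=None):
    """Cross-tabulate two cluster solutions on their shared subjects.

    Accepts aligned label arrays, or unaligned ones with subject id lists
    (the intersection is used; excluded subjects, label 0, are dropped).
    Returns (crosstab DataFrame, chi2, df, p, adjusted Rand index).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if subjects_a is not None and subjects_b is not None:
        sa = pd.Series(a, index=subjects_a)
        sb = pd.Series(b, index=subjects_b)
        common = sa.index.intersection(sb.index)
        a, b = sa.loc[common].to_numpy(), sb.loc[common].to_numpy()
    elif len(a) != len(b):
        raise ValueError("label arrays differ in length and no subject ids given")
    keep = (a != 0) & (b != 0)
    a, b = a[keep], b[keep]
    if len(a) == 0:
        raise ValueError("no shared labeled subjects")
    tab = pd.crosstab(pd.Series(a, name="solution_a"),
                      pd.Series(b, name="solution_b"))
    if tab.shape[0] > 1 and tab.shape[1] > 1:
        chi2, dof, p = chi_square_table(tab.to_numpy())
    else:
        chi2, dof, p = 0.0, 0, 1.0
    ari = float(adjusted_rand_score(a, b))
    return tab, chi2, dof, p, ari


# ---------------------------------------------------------------------------
# cluster characterization report
# ---------------------------------------------------------------------------

CONTINUOUS_VARS = ("age", "disease_duration", "education", "updrs3", "moca",
                   "wm_hypo_ratio")
CATEGORICAL_VARS = ("sex", "hy_stage", "medicated", "mci", "depression",
                    "rbd", "pigd", "cohort")


@dataclass
class CharacterizationReport:
    """Per-variable cluster comparison statistics."""

    entries: pd.DataFrame        # variable, test, statistic, df, p, n, posthoc
    cluster_sizes: dict

    def significant(self) -> pd.DataFrame:
        return self.entries[self.entries["p"] < ALPHA]


def characterize_clusters(table: pd.DataFrame, labels: np.ndarray,
                          continuous=CONTINUOUS_VARS,
                          categorical=CATEGORICAL_VARS) -> CharacterizationReport:
    """Kruskal-Wallis / chi-square comparison of clusters on clinical data.

    ``labels`` is aligned with ``table`` rows; label 0 (excluded) subjects
    are dropped.  Missing values are deleted per variable.
    """
    labels = np.asarray(labels)
    if "wm_hypo_ratio" not in table.columns and {"wm_hypo", "etiv"} <= set(table.columns):
        table = table.assign(wm_hypo_ratio=table["wm_hypo"] / table["etiv"])
    sel = labels != 0
    sub = table.loc[sel]
    lab = labels[sel]
    clusters = sorted(int(u) for u in np.unique(lab))

    rows = []
    for var in continuous:
        if var not in sub.columns:
            continue
        groups = {c: sub.loc[lab == c, var].dropna().to_numpy(float)
                  for c in clusters}
        groups = {c: g for c, g in groups.items() if len(g) > 0}
        if len(groups) < 2:
            continue
        H, df, p = kruskal_wallis(*groups.values())
        pairs = posthoc_pairwise(groups, p, kind="continuous")
        rows.append({"variable": var, "test": "kruskal-wallis", "statistic": H,
                     "df": df, "p": p, "n": int(sum(len(g) for g in groups.values())),
                     "posthoc": [pr for pr, _ in pairs]})
    for var in categorical:
        if var not in sub.columns:
            continue
        v = sub[var]
        ok = v.notna()
        if ok.sum() == 0:
            continue
        cats = sorted(v[ok].unique(), key=str)
        counts = {c: np.array([(v[(lab == c) & ok.to_numpy()] == cat).sum()
                               for cat in cats]) for c in clusters}
        counts = {c: arr for c, arr in counts.items() if arr.sum() > 0}
        tab = np.vstack(list(counts.values()))
        tab = tab[:, tab.sum(axis=0) > 0]
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            continue
        chi2, df, p = chi_square_table(tab)
        pairs = posthoc_pairwise(counts, p, kind="categorical")
        rows.append({"variable": var, "test": "chi-square", "statistic": chi2,
                     "df": df, "p": p, "n": int(tab.sum()),
                     "posthoc": [pr for pr, _ in pairs]})
    sizes = {int(c): int((lab == c).sum()) for c in clusters}
    return CharacterizationReport(entries=pd.DataFrame(rows), cluster_sizes=sizes)
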