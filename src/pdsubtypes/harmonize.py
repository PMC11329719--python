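"""Reference-group residual harmonization and global-atrophy normalization.

Multi-site morphometry carries systematic offsets from scanner field
strength and cohort, and volumes scale with head size (eTIV).  Each
nuisance is removed with the residual method: coefficients are estimated in
a designated reference group and the fitted effect is subtracted from every
subject.  Continuous covariates use per-feature OLS slopes and subtract
``slope * (x - x̄_ref)``; categorical covariates subtract per-level mean
offsets relative to a reference level.  Both conventions preserve the
feature level, so the per-subject normalizers of the severity step stay
positive.

The severity (global atrophy) normalization divides, per subject, each
cortical thickness by the subject's mean thickness over the 34 cortical
ROIs and each gray-matter volume by the subject's total (eTIV-adjusted)
subcortical GM volume — removing the global-atrophy dimension so clustering
sees only the *pattern* of atrophy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ROIMatrix


@dataclass
class AdjustmentModel:
    """Fitted coefficients of one residual-adjustment step.

    ``kind`` is "continuous" (per-feature ``slopes`` plus the reference-group
    covariate mean) or "categorical" (per-level per-feature ``offsets``
    relative to ``reference_level``).  ``feature_index`` lists the columns
    the step applies to.
    """

    covariate: str
    kind: str
    reference: str
    feature_index: list[int]
    slopes: list[float] | None = None
    ref_mean: float | None = None
    offsets: dict = field(default_factory=dict)   # level(str) -> list of floats
    reference_level: str | None = None
    n_reference: int = 0

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def fit_residual_adjustment(matrix: ROIMatrix, covariate, reference_mask,
                            *, name: str = "covariate",
                            feature_mask=None,
                            reference_level=None) -> AdjustmentModel:
    """Fit a residual-adjustment model on the reference subset.

    Numeric covariates get a per-feature OLS line fit on the reference
    subjects; categorical covariates get per-level mean offsets relative to
    ``reference_level`` (default: the modal level among reference subjects),
    estimated on the reference subjects.
    """
    cov = np.asarray(covariate)
    ref = np.asarray(reference_mask, dtype=bool)
    if cov.shape[0] != matrix.n_subjects:
        raise ValueError("covariate length must match subject count")
    if ref.sum() < 3:
        raise ValueError(f"reference subset has {int(ref.sum())} subjects; need >= 3")
    fmask = np.ones(len(matrix.features), bool) if feature_mask is None \
        else np.asarray(feature_mask, bool)
    cols = np.flatnonzero(fmask)
    X = matrix.values[:, cols]

    numeric = np.issubdtype(cov.dtype, np.number)
    if numeric:
        x = cov[ref].astype(float)
        if np.ptp(x) == 0:
            raise ValueError(f"covariate {name!r} is constant in the reference group")
        xc = x - x.mean()
        slopes = (xc @ X[ref]) / (xc @ xc)
        return AdjustmentModel(
            covariate=name, kind="continuous", reference="reference subset",
            feature_index=cols.tolist(), slopes=slopes.tolist(),
            ref_mean=float(x.mean()), n_reference=int(ref.sum()),
        )

    levels = [str(v) for v in cov]
    ref_levels = np.array(levels)[ref]
    if reference_level is None:
        uniq, counts = np.unique(ref_levels, return_counts=True)
        reference_level = str(uniq[np.argmax(counts)])
    else:
        reference_level = str(reference_level)
    if reference_level not in set(ref_levels):
        raise ValueError(f"reference level {reference_level!r} absent from reference subset")
    base = X[ref & (np.array(levels) == reference_level)].mean(axis=0)
    offsets = {}
    for lev in sorted(set(np.array(levels)[ref])):
        sel = ref & (np.array(levels) == lev)
        offsets[lev] = (X[sel].mean(axis=0) - base).tolist()
    return AdjustmentModel(
        covariate=name, kind="categorical", reference="reference subset",
        feature_index=cols.tolist(), offsets=offsets,
        reference_level=reference_level, n_reference=int(ref.sum()),
    )


def apply_residual_adjustment(matrix: ROIMatrix, model: AdjustmentModel,
                              covariate) -> ROIMatrix:
    """Subtract the fitted covariate effect from every subject (PD and HC)."""
    cov = np.asarray(covariate)
    if cov.shape[0] != matrix.n_subjects:
        raise ValueError("covariate length must match subject count")
    cols = np.asarray(model.feature_index, int)
    if cols.max(initial=-1) >= len(matrix.features):
        raise ValueError("model feature index exceeds matrix width")
    out = matrix.values.copy()
    if model.kind == "continuous":
        slopes = np.asarray(model.slopes, float)
        out[:, cols] -= np.outer(cov.astype(float) - model.ref_mean, slopes)
    else:
        for i, lev in enumerate(str(v) for v in cov):
            off = model.offsets.get(lev)
            if off is not None:
                out[i, cols] -= np.asarray(off, float)
    return matrix.with_adjustment(out, f"residual:{model.covariate}")


def severity_adjust(matrix: ROIMatrix) -> ROIMatrix:
    """Normalize away each subject's global atrophy.

    Thickness features are divided by the subject's mean thickness; volume
    features by the subject's total GM volume.  The output's per-subject
    mean thickness ratio is exactly 1, so any global (severity) gradient is
    removed and only relative regional patterns remain.
    """
    tmask, vmask = matrix.thickness_mask, matrix.volume_mask
    if not tmask.any() or not vmask.any():
        raise ValueError("severity adjustment needs both thickness and volume features")
    out = matrix.values.copy()
    mean_thick = out[:, tmask].mean(axis=1)
    total_gm = out[:, vmask].sum(axis=1)
    bad = (mean_thick <= 0) | (total_gm <= 0)
    if bad.any():
        raise ValueError(
            f"non-positive severity normalizer for subject(s) "
            f"{[matrix.subjects[i] for i in np.flatnonzero(bad)[:5]]}")
    out[:, tmask] /= mean_thick[:, None]
    out[:, vmask] /= total_gm[:, None]
    return matrix.with_adjustment(out, "severity")


def build_clustering_input(matrix: ROIMatrix, table: pd.DataFrame,
                           mode: str = "unadjusted",
                           reference_cohort: str | None = None,
                           ) -> tuple[ROIMatrix, list[AdjustmentModel]]:
    """Run the full harmonization chain that defines the clustering input.

    Order: field-strength residual (HC reference) → eTIV residual on volume
    features (HC reference) → cohort offsets (largest cohort as reference
    level, estimated on all subjects since not every cohort has HC) → in
    ``adjusted`` mode, the severity normalization.  Rows stay aligned with
    ``table``; both PD and HC are adjusted.
    """
    if mode not in ("unadjusted", "adjusted"):
        raise ValueError(f"mode must be 'unadjusted' or 'adjusted', got {mode!r}")
    if list(table["subject_id"].astype(str)) != list(matrix.subjects):
        raise ValueError("subject table and ROI matrix are not aligned")
    hc = (table["group"] == "HC").to_numpy()
    if not hc.any():
        raise ValueError("no HC subjects available as the reference group")
    if table["etiv"].isna().any():
        raise ValueError("missing eTIV values")

    chain: list[AdjustmentModel] = []
    m = matrix

    fs = table["field_strength"].astype(float).map(lambda v: f"{v:g}T")
    if fs[hc].nunique() > 1:
        # identify the scanner contrast within cohorts whose HC span both
        # field strengths; estimating across cohorts would confound the
        # scanner offset with site offsets when scanner mix differs by site
        mixed = [c for c in table.loc[hc, "cohort"].unique()
                 if fs[hc & (table["cohort"] == c).to_numpy()].nunique() > 1]
        est_mask = hc & table["cohort"].isin(mixed).to_numpy() if mixed else hc
        mod = fit_residual_adjustment(m, fs.to_numpy(), est_mask,
                                      name="field_strength",
                                      reference_level=sorted(fs[hc].unique())[0])
        m = apply_residual_adjustment(m, mod, fs.to_numpy())
        chain.append(mod)

    mod = fit_residual_adjustment(m, table["etiv"].to_numpy(float), hc,
                                  name="etiv", feature_mask=m.volume_mask)
    m = apply_residual_adjustment(m, mod, table["etiv"].to_numpy(float))
    chain.append(mod)

    cohorts = table["cohort"].astype(str)
    if cohorts.nunique() > 1:
        if reference_cohort is None:
            reference_cohort = cohorts.value_counts().idxmax()
        mod = fit_residual_adjustment(m, cohorts.to_numpy(),
                                      np.ones(len(table), bool), name="cohort",
                                      reference_level=reference_cohort)
        m = apply_residual_adjustment(m, mod, cohorts.to_numpy())
        chain.append(mod)

    if mode == "adjusted":
        m = severity_adjust(m)
    return m, chain


def adjust_wm_hypo(table: pd.DataFrame) -> np.ndarray:
    """eTIV-residualized WM-hypo volume (HC reference), for harmonized use.

    Characterization tables instead report the plain WM-hypo/eTIV ratio.
    """
    hc = (table["group"] == "HC").to_numpy()
    if hc.sum() < 3:
        raise ValueError("need >= 3 HC subjects to fit the eTIV residual")
    wm = table["wm_hypo"].to_numpy(float)
    tiv = table["etiv"].to_numpy(float)
    x = tiv[hc] - tiv[hc].mean()
    slope = (x @ wm[hc]) / (x @ x)
    return wm - slope * (tiv - tiv[hc].mean())


def chain_to_json(chain: list[AdjustmentModel], path: str | Path) -> None:
    Path(path).write_text(json.dumps([m.to_dict() for m in chain], indent=1))
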