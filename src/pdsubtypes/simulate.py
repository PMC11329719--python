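"""Synthetic multi-cohort PD/HC morphometry generator.

Emulates the structure of a pooled multi-site Parkinson's disease sample:
several cohorts of stated sizes (one without healthy controls), additive
per-cohort and field-strength offsets on every feature, eTIV-coupled
subcortical volumes, and PD subtypes planted along two designs —

* **severity**: subtypes differ by a multiplicative global atrophy factor
  applied to all 41 features (a gradient of overall neurodegeneration);
* **typicality**: subtypes share the same global factor but each carries
  extra atrophy in a distinct set of regions (distinct patterns at matched
  global atrophy).

Each subject additionally receives a multiplicative global-atrophy jitter
(``subject_scale_sd``): the within-subtype severity nuisance that global
atrophy adjustment is designed to remove.  Longitudinal UPDRS-III / MoCA
visits follow per-subtype linear slopes with subject random intercepts and
monotone attrition.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import ROIMatrix
from .rois import ALL_ROIS, CORTICAL_ROIS, SUBCORTICAL_ROIS

# ---------------------------------------------------------------------------
# reference (healthy-control) feature distributions
# ---------------------------------------------------------------------------

#: mean cortical thickness (mm) and sd for every Desikan-Killiany ROI
THICKNESS_MEAN, THICKNESS_SD = 2.5, 0.15

#: plausible unilateral subcortical gray-matter volumes (mm^3); sd = 10%
SUBCORTICAL_MEANS = {
    "thalamus": 7500.0,
    "caudate": 3700.0,
    "putamen": 4800.0,
    "pallidum": 1800.0,
    "hippocampus": 4200.0,
    "amygdala": 1700.0,
    "accumbens": 600.0,
}

ETIV_MEAN, ETIV_SD = 1.5e6, 1.5e5
#: fraction of a volume's mean scaling proportionally with eTIV
ETIV_COUPLING = 0.8


def hc_reference() -> tuple[np.ndarray, np.ndarray]:
    """Per-feature healthy-control means and standard deviations (41,)."""
    means = np.array(
        [THICKNESS_MEAN] * len(CORTICAL_ROIS)
        + [SUBCORTICAL_MEANS[r] for r in SUBCORTICAL_ROIS]
    )
    sds = np.array(
        [THICKNESS_SD] * len(CORTICAL_ROIS)
        + [0.10 * SUBCORTICAL_MEANS[r] for r in SUBCORTICAL_ROIS]
    )
    return means, sds


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class SubtypeSpec:
    """A planted PD subtype.

    ``global_scale`` multiplies every feature (1.0 = no global atrophy);
    ``pattern_rois``/``pattern_effect`` subtract ``pattern_effect`` HC
    standard deviations from the named ROIs; ``age_shift`` moves the age
    distribution mean; slopes are points/year for the longitudinal scores.
    """

    name: str
    prevalence: float
    global_scale: float = 1.0
    pattern_rois: tuple[str, ...] = ()
    pattern_effect: float = 0.0
    age_shift: float = 0.0
    updrs_slope: float = 1.5
    moca_slope: float = -0.3

    def __post_init__(self):
        if self.global_scale <= 0:
            raise ValueError("global_scale must be > 0")
        unknown = [r for r in self.pattern_rois if r not in ALL_ROIS]
        if unknown:
            raise ValueError(f"unknown ROI name(s) in pattern_rois: {unknown}")


@dataclass
class CohortSpec:
    """One acquisition cohort: sizes, scanner mix, site offset, follow-up."""

    name: str
    n_pd: int
    n_hc: int = 0
    field_strength_mix: float = 1.0      # fraction of subjects scanned at 3 T
    offset_sd: float = 0.3               # per-feature additive offset, HC-sd units
    medicated_frac: float = 0.5
    has_longitudinal: bool = False
    n_visits: int = 7
    visit_interval: float = 1.0          # years

    def __post_init__(self):
        if self.n_pd < 0 or self.n_hc < 0:
            raise ValueError("cohort sizes must be >= 0")
        if not 0 <= self.field_strength_mix <= 1:
            raise ValueError("field_strength_mix must lie in [0, 1]")
        if self.visit_interval < 0:
            raise ValueError("visit interval must be >= 0")


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset."""

    subtype_of: dict                      # subject_id -> subtype name (PD only)
    cohort_offsets: dict                  # cohort -> list of 41 offsets
    field_strength_offset: list           # 41 offsets added at 3 T
    hc_means: list
    hc_sds: list
    subject_scale: dict                   # subject_id -> global atrophy factor

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))

    def labels_for(self, subject_ids) -> np.ndarray:
        return np.array([self.subtype_of[s] for s in subject_ids])


# ---------------------------------------------------------------------------
# presets mirroring the study's cohort structure
# ---------------------------------------------------------------------------

def default_cohorts(scale: float = 1.0) -> list[CohortSpec]:
    """Four cohorts with the pooled study's PD/HC sizes and scanner mixes.

    ``scale`` < 1 shrinks every cohort proportionally (minimum 10 PD) for
    faster runs.
    """
    def s(n):
        if n == 0:
            return 0
        return max(int(round(n * scale)), 10)

    return [
        CohortSpec("COHORT-A", n_pd=s(315), n_hc=s(151), field_strength_mix=215 / 315,
                   offset_sd=0.0, medicated_frac=0.0, has_longitudinal=True),
        CohortSpec("COHORT-B", n_pd=s(107), n_hc=s(44), field_strength_mix=1.0,
                   offset_sd=0.3, medicated_frac=1.0, has_longitudinal=True),
        CohortSpec("COHORT-C", n_pd=s(136), n_hc=0, field_strength_mix=43 / 136,
                   offset_sd=0.3, medicated_frac=0.57),
        CohortSpec("COHORT-D", n_pd=s(75), n_hc=s(38), field_strength_mix=1.0,
                   offset_sd=0.3, medicated_frac=0.99),
    ]


def severity_subtypes() -> list[SubtypeSpec]:
    """Three subtypes on a global-atrophy (severity) gradient.

    Scales 1.0 / 0.85 / 0.70 give between-subtype gaps comfortably above the
    per-subject global jitter; older age accompanies more atrophy.
    """
    return [
        SubtypeSpec("mild", 0.35, global_scale=1.00, age_shift=-3.0,
                    updrs_slope=1.0, moca_slope=-0.1),
        SubtypeSpec("intermediate", 0.40, global_scale=0.85, age_shift=0.0,
                    updrs_slope=1.8, moca_slope=-0.3),
        SubtypeSpec("severe", 0.25, global_scale=0.70, age_shift=4.0,
                    updrs_slope=2.5, moca_slope=-0.6),
    ]


def typicality_subtypes(global_scale: float = 0.9,
                        pattern_effect: float = 2.0) -> list[SubtypeSpec]:
    """Three subtypes with distinct regional patterns at matched global atrophy."""
    cingulate = ("caudalanteriorcingulate", "rostralanteriorcingulate",
                 "posteriorcingulate", "medialorbitofrontal", "caudate", "putamen")
    mediotemporal = ("entorhinal", "parahippocampal", "fusiform",
                     "temporalpole", "hippocampus", "amygdala")
    parietooccipital = ("superiorparietal", "inferiorparietal", "precuneus",
                        "lateraloccipital", "cuneus", "lingual")
    kw = dict(global_scale=global_scale, pattern_effect=pattern_effect)
    return [
        SubtypeSpec("cingulate", 0.34, pattern_rois=cingulate, updrs_slope=2.2, **kw),
        SubtypeSpec("mediotemporal", 0.33, pattern_rois=mediotemporal, moca_slope=-0.5, **kw),
        SubtypeSpec("parieto-occipital", 0.33, pattern_rois=parietooccipital,
                    updrs_slope=2.0, moca_slope=-0.7, **kw),
    ]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _check_prevalences(subtypes):
    total = sum(s.prevalence for s in subtypes)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"subtype prevalences must sum to 1, got {total}")


def generate_dataset(cohorts: list[CohortSpec], subtypes: list[SubtypeSpec],
                     seed: int, *, noise_sd: float = 1.0,
                     subject_scale_sd: float = 0.03,
                     fs_offset_sd: float = 0.3,
                     ) -> tuple[pd.DataFrame, ROIMatrix, GroundTruth]:
    """Generate a pooled multi-cohort baseline dataset.

    Parameters
    ----------
    noise_sd : measurement noise, in units of the HC per-feature sd.
    subject_scale_sd : sd of the per-subject multiplicative global-atrophy
        jitter (severity nuisance within subtype).
    fs_offset_sd : additive 3 T-vs-1.5 T offset per feature, HC-sd units
        (drawn once, shared by all cohorts).

    Returns the subject covariate table, the 41-feature ROI matrix (rows
    aligned with the table) and the planted :class:`GroundTruth`.
    """
    if not cohorts:
        raise ValueError("at least one cohort required")
    if not subtypes:
        raise ValueError("at least one subtype required")
    _check_prevalences(subtypes)

    rng = np.random.default_rng(seed)
    means, sds = hc_reference()
    vol = np.array([r in SUBCORTICAL_ROIS for r in ALL_ROIS])
    fs_offset = rng.normal(0.0, fs_offset_sd, size=len(ALL_ROIS)) * sds

    cohort_offsets = {c.name: rng.normal(0.0, c.offset_sd, size=len(ALL_ROIS)) * sds
                      for c in cohorts}

    prev = np.array([s.prevalence for s in subtypes])
    rows, feats = [], []
    truth_labels, truth_scale = {}, {}
    counter = 0
    for c in cohorts:
        for group, n in (("PD", c.n_pd), ("HC", c.n_hc)):
            if n == 0:
                continue
            sub_idx = rng.choice(len(subtypes), size=n, p=prev) if group == "PD" else None
            for i in range(n):
                sid = f"{c.name}-{group}-{counter:04d}"
                counter += 1
                st = subtypes[sub_idx[i]] if group == "PD" else None
                jitter = max(rng.normal(1.0, subject_scale_sd), 0.5)
                scale = (st.global_scale if st else 1.0) * jitter
                etiv = rng.normal(ETIV_MEAN, ETIV_SD)
                at3t = rng.random() < c.field_strength_mix

                base = means.copy()
                base[vol] = means[vol] * (1 + ETIV_COUPLING * (etiv / ETIV_MEAN - 1))
                values = base * scale
                if st is not None and st.pattern_effect:
                    for roi in st.pattern_rois:
                        j = ALL_ROIS.index(roi)
                        values[j] -= st.pattern_effect * sds[j]
                values += cohort_offsets[c.name]
                if at3t:
                    values += fs_offset
                values += rng.normal(0.0, noise_sd, size=len(ALL_ROIS)) * sds

                age_mu = 63.0 + (st.age_shift if st else 1.0)
                age = float(np.clip(rng.normal(age_mu, 9.0), 40, 90))
                deficit = max(0.0, 1.0 - scale)
                wm_hypo = float(np.exp(rng.normal(np.log(1000.0), 0.5))
                                * (1 + 6.0 * deficit) * (etiv / ETIV_MEAN))
                row = {
                    "subject_id": sid, "group": group, "cohort": c.name,
                    "field_strength": 3.0 if at3t else 1.5,
                    "age": age, "sex": "M" if rng.random() < 0.63 else "F",
                    "etiv": etiv, "wm_hypo": wm_hypo,
                    "education": float(np.clip(rng.normal(15.5, 3.0), 6, 24)),
                    "has_longitudinal": c.has_longitudinal,
                    "n_visits": c.n_visits, "visit_interval": c.visit_interval,
                }
                if group == "PD":
                    row.update({
                        "true_subtype": st.name,
                        "disease_duration": float(rng.exponential(3.0)),
                        "medicated": int(rng.random() < c.medicated_frac),
                        "hy_stage": float(rng.choice(
                            [1, 1.5, 2, 2.5, 3, 4],
                            p=_hy_probs(deficit))),
                        "updrs3": float(np.clip(rng.normal(18.0, 8.0) + 25.0 * deficit, 0, None)),
                        "moca": float(np.clip(rng.normal(27.0, 2.2) - 12.0 * deficit, 0, 30)),
                        "mci": int(rng.random() < np.clip(0.08 + 0.8 * deficit, 0, 0.6)),
                        "depression": int(rng.random() < 0.2),
                        "rbd": int(rng.random() < np.clip(0.3 + 0.4 * deficit, 0, 0.8)),
                        "pigd": int(rng.random() < 0.25),
                    })
                    truth_labels[sid] = st.name
                    truth_scale[sid] = scale
                else:
                    row.update({"moca": float(np.clip(rng.normal(27.8, 1.8), 0, 30)),
                                "mci": int(rng.random() < 0.06)})
                rows.append(row)
                feats.append(values)

    table = pd.DataFrame(rows)
    matrix = ROIMatrix(np.vstack(feats), table["subject_id"].tolist(), list(ALL_ROIS))
    truth = GroundTruth(
        subtype_of=truth_labels,
        cohort_offsets={k: v.tolist() for k, v in cohort_offsets.items()},
        field_strength_offset=fs_offset.tolist(),
        hc_means=means.tolist(), hc_sds=sds.tolist(),
        subject_scale=truth_scale,
    )
    return table, matrix, truth


def _hy_probs(deficit: float) -> np.ndarray:
    """Hoehn & Yahr stage probabilities drifting upward with atrophy burden."""
    w = np.array([0.30, 0.01, 0.55, 0.02, 0.10, 0.02])
    shift = np.clip(deficit, 0, 0.4)
    w = w + shift * np.array([-0.5, 0.0, -0.1, 0.05, 0.45, 0.10])
    w = np.clip(w, 0.001, None)
    return w / w.sum()


# ---------------------------------------------------------------------------
# longitudinal visits
# ---------------------------------------------------------------------------

def generate_longitudinal(table: pd.DataFrame, subtypes: list[SubtypeSpec],
                          seed: int, *, noise_sd: float = 3.0,
                          intercept_sd: float = 2.0,
                          dropout: float = 0.08) -> pd.DataFrame:
    """Generate annual-visit UPDRS-III and MoCA trajectories for PD subjects.

    Scores follow ``baseline + slope * time + subject intercept + noise``
    with subtype-specific slopes; attrition is monotone with per-visit
    probability ``dropout``.  Only PD subjects in cohorts flagged
    ``has_longitudinal`` contribute.
    """
    if (table.get("visit_interval", pd.Series(dtype=float)) < 0).any():
        raise ValueError("negative visit interval")
    rng = np.random.default_rng(seed)
    slopes = {s.name: (s.updrs_slope, s.moca_slope) for s in subtypes}
    rows = []
    pd_long = table[(table["group"] == "PD") & table["has_longitudinal"].astype(bool)]
    for _, r in pd_long.iterrows():
        u_slope, m_slope = slopes[r["true_subtype"]]
        b_u = rng.normal(0.0, intercept_sd)
        b_m = rng.normal(0.0, intercept_sd / 2.0)
        n_visits, dt = int(r["n_visits"]), float(r["visit_interval"])
        for v in range(n_visits):
            if v > 0 and rng.random() < dropout:
                break
            t = v * dt
            updrs = r["updrs3"] + u_slope * t + b_u + rng.normal(0.0, noise_sd)
            moca = r["moca"] + m_slope * t + b_m + rng.normal(0.0, noise_sd / 2.0)
            rows.append({
                "subject_id": r["subject_id"], "cohort": r["cohort"], "visit": v,
                "time": t, "updrs3": max(updrs, 0.0),
                "moca": float(np.clip(moca, 0, 30)),
            })
    return pd.DataFrame(rows, columns=["subject_id", "cohort", "visit", "time",
                                       "updrs3", "moca"])


# ---------------------------------------------------------------------------
# config & serialization
# ---------------------------------------------------------------------------

def specs_from_config(cfg: dict) -> tuple[list[CohortSpec], list[SubtypeSpec]]:
    """Build cohort/subtype specs from a YAML/JSON-style mapping."""
    cohorts = [CohortSpec(**c) for c in cfg.get("cohorts", [])]
    subtypes = [SubtypeSpec(**{**s, "pattern_rois": tuple(s.get("pattern_rois", ()))})
                for s in cfg.get("subtypes", [])]
    return cohorts, subtypes


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    return yaml.safe_load(text)


def write_dataset(outdir: str | Path, table: pd.DataFrame, matrix: ROIMatrix,
                  truth: GroundTruth, visits: pd.DataFrame | None = None) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "subjects.csv", index=False)
    matrix.to_frame().to_csv(out / "roi_matrix.csv")
    truth.to_json(out / "ground_truth.json")
    if visits is not None:
        visits.to_csv(out / "visits.csv", index=False)
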