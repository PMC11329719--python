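"""Reading, validation and normalization of subject and morphometry tables.

Input is a subject-level CSV/TSV (comma vs tab auto-detected from the file
extension) with one row per subject and, for morphometry, one column per
hemisphere-resolved ROI using FreeSurfer-style ``lh_``/``rh_`` prefixes.
Hemispheres are averaged on ingestion; all downstream code works on the
41-feature hemisphere-averaged :class:`ROIMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .rois import ALL_ROIS, roi_kinds

REQUIRED_COLUMNS = ("subject_id", "group", "cohort", "field_strength", "age", "sex", "etiv")

#: optional clinical covariates retained when present (missing stays missing;
#: statistics use per-variable pairwise deletion)
OPTIONAL_COLUMNS = (
    "education",
    "disease_duration",
    "medicated",
    "hy_stage",
    "updrs3",
    "moca",
    "mci",
    "depression",
    "rbd",
    "pigd",
    "wm_hypo",
)

_FIELD_STRENGTH_ALIASES = {
    "1.5": 1.5, "1.5t": 1.5, "1,5t": 1.5, "1.5 t": 1.5,
    "3": 3.0, "3.0": 3.0, "3t": 3.0, "3.0t": 3.0, "3 t": 3.0,
}


@dataclass
class SubjectRecord:
    """Typed view of one subject row (clinical covariates optional)."""

    subject_id: str
    group: str                      # "PD" or "HC"
    cohort: str
    field_strength: float           # tesla, 1.5 or 3.0
    age: float                      # years
    sex: str                        # "M" or "F"
    etiv: float                     # mm^3, > 0
    wm_hypo: float | None = None    # mm^3, >= 0
    extras: dict = field(default_factory=dict)


@dataclass
class ValidationReport:
    """Per-row issues found while reading a subject table."""

    dropped: list[tuple[str, str]] = field(default_factory=list)  # (subject_id, reason)
    notes: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def __bool__(self) -> bool:  # truthy when anything was flagged
        return bool(self.dropped or self.notes)


class ROIMatrix:
    """Subjects x features morphometry matrix with per-feature kind tags.

    Parameters
    ----------
    values : (n_subjects, n_features) array
    subjects : subject identifiers, row order
    features : ROI names, column order
    kinds : "thickness" / "volume" per column; inferred from the canonical
        ROI list when omitted.
    adjustments : provenance — names of adjustment steps already applied.
    """

    def __init__(self, values, subjects, features, kinds=None, adjustments=None):
        self.values = np.asarray(values, dtype=float)
        self.subjects = list(subjects)
        self.features = list(features)
        if self.values.shape != (len(self.subjects), len(self.features)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.subjects)} subjects x {len(self.features)} features"
            )
        self.kinds = list(kinds) if kinds is not None else roi_kinds(self.features)
        self.adjustments: list[str] = list(adjustments or [])

    # -- views -----------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def thickness_mask(self) -> np.ndarray:
        return np.array([k == "thickness" for k in self.kinds])

    @property
    def volume_mask(self) -> np.ndarray:
        return np.array([k == "volume" for k in self.kinds])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.subjects, name="subject_id"),
                            columns=self.features)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, kinds=None, adjustments=None) -> "ROIMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns),
                   kinds=kinds, adjustments=adjustments)

    def copy(self, values=None, adjustments=None) -> "ROIMatrix":
        return ROIMatrix(
            self.values.copy() if values is None else values,
            self.subjects, self.features, self.kinds,
            self.adjustments if adjustments is None else adjustments,
        )

    def with_adjustment(self, values: np.ndarray, step: str) -> "ROIMatrix":
        return self.copy(values=np.asarray(values, float), adjustments=self.adjustments + [step])

    def __repr__(self) -> str:  # pragma: no cover
        return (f"ROIMatrix({self.n_subjects} subjects x {len(self.features)} features, "
                f"adjustments={self.adjustments})")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab", ".txt")) else ","


def parse_field_strength(value) -> float:
    """Normalize field-strength notations ("1.5T", "3T", 3, "3.0") to tesla."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        v = float(value)
    else:
        key = str(value).strip().lower()
        if key not in _FIELD_STRENGTH_ALIASES:
            raise ValueError(f"unrecognized field strength: {value!r}")
        v = _FIELD_STRENGTH_ALIASES[key]
    if v not in (1.5, 3.0):
        raise ValueError(f"field strength must be 1.5 or 3.0 T, got {v}")
    return v


def read_subject_table(path: str | Path) -> tuple[pd.DataFrame, ValidationReport]:
    """Read and validate a subject covariate table.

    Returns the validated table (invalid rows dropped) and a report listing
    every dropped row with the invariant it violated.  Unparseable *optional*
    values become missing; missing/invalid *required* values drop the row.

    Raises
    ------
    ValueError
        if a required column is absent or subject_id values are duplicated.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject table is missing required column(s): {missing}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id values: {dupes}")

    report = ValidationReport()
    keep = np.ones(len(df), dtype=bool)
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)

    fs = []
    for i, row in df.iterrows():
        sid = row["subject_id"]
        try:
            fs.append(parse_field_strength(row["field_strength"]))
        except ValueError as e:
            fs.append(np.nan)
            keep[df.index.get_loc(i)] = False
            report.dropped.append((sid, str(e)))
            continue
        group = str(row["group"]).strip().upper()
        if group not in ("PD", "HC"):
            keep[df.index.get_loc(i)] = False
            report.dropped.append((sid, f"group must be PD or HC, got {row['group']!r}"))
            continue
        etiv = pd.to_numeric(row["etiv"], errors="coerce")
        if not np.isfinite(etiv) or etiv <= 0:
            keep[df.index.get_loc(i)] = False
            report.dropped.append((sid, f"etiv must be > 0, got {row['etiv']!r}"))
            continue
        moca = pd.to_numeric(row.get("moca", np.nan), errors="coerce")
        if np.isfinite(moca) and not (0 <= moca <= 30):
            keep[df.index.get_loc(i)] = False
            report.dropped.append((sid, f"moca out of [0, 30]: {moca}"))
    df["field_strength"] = fs
    df["group"] = df["group"].astype(str).str.strip().str.upper()
    df["sex"] = df["sex"].astype(str).str.strip().str.upper().str[0]

    for col in ("age", "etiv"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in OPTIONAL_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")

    out = df.loc[keep].reset_index(drop=True)
    if report.n_dropped:
        report.notes.append(f"dropped {report.n_dropped} of {len(df)} rows")
    return out, report


def subject_records(table: pd.DataFrame) -> list[SubjectRecord]:
    """Convert a validated subject table to typed records."""
    recs = []
    known = set(REQUIRED_COLUMNS) | {"wm_hypo"}
    for _, row in table.iterrows():
        extras = {k: row[k] for k in table.columns if k not in known}
        recs.append(SubjectRecord(
            subject_id=str(row["subject_id"]), group=row["group"], cohort=str(row["cohort"]),
            field_strength=float(row["field_strength"]), age=float(row["age"]),
            sex=str(row["sex"]), etiv=float(row["etiv"]),
            wm_hypo=float(row["wm_hypo"]) if "wm_hypo" in row and np.isfinite(row.get("wm_hypo", np.nan)) else None,
            extras=extras,
        ))
    return recs


def average_hemispheres(wide: pd.DataFrame, rois: Sequence[str] = ALL_ROIS) -> ROIMatrix:
    """Average ``lh_<roi>``/``rh_<roi>`` column pairs into one column per ROI.

    The wide table must be indexed by subject_id (or carry a subject_id
    column) and contain both hemisphere columns for every requested ROI.
    """
    df = wide
    if "subject_id" in df.columns:
        df = df.set_index("subject_id")
    values = np.empty((len(df), len(rois)), dtype=float)
    for j, roi in enumerate(rois):
        lh, rh = f"lh_{roi}", f"rh_{roi}"
        present = [c for c in (lh, rh) if c in df.columns]
        if len(present) != 2:
            raise ValueError(f"ROI {roi!r}: missing hemisphere column(s) "
                             f"{sorted({lh, rh} - set(present))}")
        values[:, j] = (df[lh].to_numpy(float) + df[rh].to_numpy(float)) / 2.0
    if not np.isfinite(values).all():
        bad = [rois[j] for j in np.unique(np.argwhere(~np.isfinite(values))[:, 1])]
        raise ValueError(f"non-finite morphometry values in ROI(s): {bad}")
    return ROIMatrix(values, list(df.index.astype(str)), list(rois))


def wm_hypo_ratio(wm_hypo, etiv):
    """White-matter-hypointensity burden as the dimensionless WM-hypo/eTIV ratio.

    Accepts scalars or aligned arrays; eTIV must be strictly positive.
    """
    wm = np.asarray(wm_hypo, dtype=float)
    tiv = np.asarray(etiv, dtype=float)
    if np.any(tiv <= 0):
        raise ValueError("etiv must be > 0")
    out = wm / tiv
    return float(out) if out.ndim == 0 else out
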