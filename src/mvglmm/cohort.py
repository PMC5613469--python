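"""Long-format cohort data: parsing, outcome coding and covariate scaling.

A cohort is one row per subject-visit.  Three modelling outcomes are derived
from the raw clinical columns:

* ``Y1`` — MDS-UPDRS part II total (motor aspects of daily living, 0-52),
* ``Y2`` — MDS-UPDRS part I total (non-motor aspects of daily living, 0-52),
* ``Y3`` — binary imbalance indicator: 1 when the Hoehn & Yahr stage or
  MDS-UPDRS item 2.12 (walking/balance) reaches 3.

Covariate preparation follows common clinical-scale conventions: MoCA gets a
one-point education adjustment below 13 years of schooling (capped at the
instrument maximum of 30); HAMD and LEDD are z-scored with constants
estimated on the training subjects only, so external prediction never sees
test-set information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortError",
    "ConfigurationError",
    "DataError",
    "CohortDataset",
    "VISIT_COLUMNS",
    "SUBJECT_COLUMNS",
    "read_long_csv",
    "derive_imbalance",
    "adjust_moca",
    "standardize_covariates",
    "split_train_test",
]


class CohortError(Exception):
    """Base class for cohort-data problems."""


class ConfigurationError(CohortError):
    """A configuration (column mapping, split size, ...) is invalid."""


class DataError(CohortError):
    """The data violate an invariant (duplicates, out-of-range scores, ...)."""


#: semantic visit-level columns (raw clinical inputs)
VISIT_COLUMNS = [
    "subject_id", "visit_time", "mds_updrs_1", "mds_updrs_2",
    "hy_scale", "item_2_12", "hamd_raw", "moca_raw", "ledd_raw",
]

#: semantic subject-level (baseline) columns
SUBJECT_COLUMNS = ["subject_id", "age_baseline", "gender", "education", "doi"]

#: columns added by preprocessing
DERIVED_COLUMNS = ["Y1", "Y2", "Y3", "hamd_std", "ledd_std", "moca_adj"]


@dataclass
class CohortDataset:
    """A split-aware long-format cohort.

    Parameters
    ----------
    subjects
        One row per subject: ``subject_id, age_baseline, gender, education,
        doi`` and optionally a ``role`` column (``train``/``test``).
    visits
        One row per subject-visit with the raw clinical columns and, after
        preprocessing, the derived outcome/covariate columns.
    constants
        Standardization constants ``{"hamd": {"mean":..., "sd":...},
        "ledd": {...}}`` once :func:`standardize_covariates` has run.
    """

    subjects: pd.DataFrame
    visits: pd.DataFrame
    constants: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    # -- validation ---------------------------------------------------------
    def _validate(self) -> None:
        dup = self.visits.duplicated(subset=["subject_id", "visit_time"])
        if dup.any():
            bad = self.visits.loc[dup, ["subject_id", "visit_time"]].iloc[0]
            raise DataError(
                f"duplicate visit for subject {bad['subject_id']!r} "
                f"at time {bad['visit_time']}"
            )
        if (self.visits["visit_time"] < 0).any():
            raise DataError("negative visit_time")
        for col, hi in [("mds_updrs_1", 52), ("mds_updrs_2", 52),
                        ("hy_scale", 5), ("item_2_12", 4)]:
            if col in self.visits:
                v = self.visits[col].dropna()
                if ((v < 0) | (v > hi)).any():
                    raise DataError(f"{col} outside [0, {hi}]")
        if "role" in self.subjects:
            roles = set(self.subjects["role"].dropna())
            if not roles <= {"train", "test"}:
                raise DataError(f"unknown subject roles: {roles}")

    # -- convenience accessors ---------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def subject_ids(self, role: str | None = None) -> list:
        subj = self.subjects
        if role is not None:
            if "role" not in subj:
                raise ConfigurationError("dataset has no train/test split yet")
            subj = subj[subj["role"] == role]
        return list(subj["subject_id"])

    def frame(self, role: str | None = None) -> pd.DataFrame:
        """Merged subject+visit table, optionally restricted to one role."""
        df = self.visits.merge(self.subjects, on="subject_id", how="left")
        if role is not None:
            df = df[df["role"] == role]
        return df.sort_values(["subject_id", "visit_time"]).reset_index(drop=True)

    def subset(self, subject_ids) -> "CohortDataset":
        ids = set(subject_ids)
        return replace(
            self,
            subjects=self.subjects[self.subjects["subject_id"].isin(ids)].reset_index(drop=True),
            visits=self.visits[self.visits["subject_id"].isin(ids)].reset_index(drop=True),
        )

    # -- I/O ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write the merged long table; constants go to a JSON sidecar."""
        path = Path(path)
        self.frame().to_csv(path, index=False)
        if self.constants:
            sidecar = path.with_suffix(path.suffix + ".constants.json")
            sidecar.write_text(json.dumps(self.constants, indent=2))


def _to_float(series: pd.Series) -> pd.Series:
    """Coerce to float; unparseable or blank cells become NaN, never 0."""
    return pd.to_numeric(series, errors="coerce")


def read_long_csv(path: str | Path, column_map: dict[str, str] | None = None) -> CohortDataset:
    """Read a long-format CSV (one row per subject-visit) into a cohort.

    ``column_map`` maps semantic names (see :data:`VISIT_COLUMNS` and
    :data:`SUBJECT_COLUMNS`) to the CSV's header names; identity by default.
    Derived columns (``Y1`` ...) present in the file are carried through.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"no such file: {path}")
    raw = pd.read_csv(path, dtype={0: str})
    column_map = dict(column_map or {})

    semantic = VISIT_COLUMNS + SUBJECT_COLUMNS[1:]
    optional = DERIVED_COLUMNS + ["role"]
    rename = {}
    for name in semantic + optional:
        src = column_map.get(name, name)
        if src in raw.columns:
            rename[src] = name
        elif name in semantic:
            raise ConfigurationError(f"mapped column {src!r} (for {name!r}) missing from {path}")
    df = raw.rename(columns=rename)
    df["subject_id"] = df["subject_id"].astype(str)
    for col in df.columns:
        if col not in ("subject_id", "role"):
            df[col] = _to_float(df[col])

    subj_cols = [c for c in SUBJECT_COLUMNS + ["role"] if c in df.columns]
    subjects = df[subj_cols].drop_duplicates("subject_id").reset_index(drop=True)
    visit_cols = [c for c in VISIT_COLUMNS + DERIVED_COLUMNS if c in df.columns]
    visits = df[visit_cols].reset_index(drop=True)
    return CohortDataset(subjects=subjects, visits=visits)


def derive_imbalance(hy_scale, item_2_12):
    """Binary imbalance indicator from H&Y stage and MDS-UPDRS item 2.12.

    Returns 1 if either available input is >= 3, 0 if every available input
    is < 3, and NaN when both are missing.  A single available component
    decides alone, which keeps visits with one missing component usable.
    Accepts scalars or aligned array-likes.
    """
    hy = np.asarray(hy_scale, dtype=float)
    item = np.asarray(item_2_12, dtype=float)
    if np.any((~np.isnan(hy)) & ((hy < 0) | (hy > 5))):
        raise DataError("hy_scale outside [0, 5]")
    if np.any((~np.isnan(item)) & ((item < 0) | (item > 4))):
        raise DataError("item_2_12 outside [0, 4]")
    any_high = (np.nan_to_num(hy, nan=-np.inf) >= 3) | (np.nan_to_num(item, nan=-np.inf) >= 3)
    both_missing = np.isnan(hy) & np.isnan(item)
    out = np.where(any_high, 1.0, 0.0)
    out = np.where(both_missing, np.nan, out)
    if out.ndim == 0:
        return float(out)
    return out


def adjust_moca(moca_raw, education):
    """Education-adjusted MoCA: +1 point below 13 years of schooling.

    Capped at the instrument maximum of 30.  Accepts scalars or arrays;
    missing MoCA stays missing.
    """
    moca = np.asarray(moca_raw, dtype=float)
    edu = np.asarray(education, dtype=float)
    if np.any((~np.isnan(moca)) & ((moca < 0) | (moca > 30))):
        raise DataError("moca_raw outside [0, 30]")
    adj = np.where(edu < 13, np.minimum(moca + 1, 30.0), moca)
    adj = np.where(np.isnan(moca), np.nan, adj)
    if adj.ndim == 0:
        return float(adj)
    return adj


def standardize_covariates(
    dataset: CohortDataset,
    *,
    ddof: int = 0,
    subset: str = "all_visits",
) -> CohortDataset:
    """Derive Y1/Y2/Y3, moca_adj, and z-score HAMD and LEDD.

    Standardization constants come from training-subject rows only
    (``role == 'train'`` if a split exists, otherwise every subject) and are
    applied unchanged to test rows.  ``subset`` selects which training rows
    feed the constants (``"all_visits"`` pools every visit, ``"baseline"``
    uses time-0 rows only); ``ddof=0`` gives the population-SD denominator.
    """
    visits = dataset.visits.copy()
    merged = visits.merge(dataset.subjects, on="subject_id", how="left")

    visits["Y1"] = merged["mds_updrs_2"].to_numpy(float)
    visits["Y2"] = merged["mds_updrs_1"].to_numpy(float)
    visits["Y3"] = derive_imbalance(merged["hy_scale"], merged["item_2_12"])
    visits["moca_adj"] = adjust_moca(merged["moca_raw"], merged["education"])

    if "role" in dataset.subjects:
        train_mask = (merged["role"] == "train").to_numpy()
    else:
        train_mask = np.ones(len(merged), dtype=bool)
    if subset == "baseline":
        train_mask = train_mask & (merged["visit_time"].to_numpy(float) == 0.0)
    elif subset != "all_visits":
        raise ConfigurationError(f"unknown standardization subset {subset!r}")
    if not train_mask.any():
        raise DataError("no training rows available for standardization")

    constants = dict(dataset.constants)
    for name, col in [("hamd", "hamd_raw"), ("ledd", "ledd_raw")]:
        ref = merged.loc[train_mask, col].dropna().to_numpy(float)
        if ref.size == 0:
            raise DataError(f"no non-missing {col} in the standardization subset")
        mean, sd = float(ref.mean()), float(ref.std(ddof=ddof))
        if sd == 0.0:
            raise DataError(f"{col} has zero SD on the standardization subset")
        visits[f"{name}_std"] = (merged[col].to_numpy(float) - mean) / sd
        constants[name] = {"mean": mean, "sd": sd, "ddof": ddof, "subset": subset}

    return replace(dataset, visits=visits, constants=constants)


def split_train_test(dataset: CohortDataset, n_test: int, seed: int) -> CohortDataset:
    """Random subject-level split into ``n_test`` test / rest train subjects."""
    n = dataset.n_subjects
    if not 0 < n_test < n:
        raise ConfigurationError(f"n_test must be in (0, {n}); got {n_test}")
    rng = np.random.default_rng(seed)
    ids = np.asarray(sorted(dataset.subjects["subject_id"].astype(str)))
    test_ids = set(rng.choice(ids, size=n_test, replace=False))
    subjects = dataset.subjects.copy()
    subjects["role"] = [
        "test" if sid in test_ids else "train" for sid in subjects["subject_id"].astype(str)
    ]
    return replace(dataset, subjects=subjects)
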