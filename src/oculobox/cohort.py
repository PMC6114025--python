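"""Cohort records, concussion case labeling, and sample balancing."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SSS_RANGE = (0, 132)
SAC_RANGE = (0, 30)

COHORT_COLUMNS = ["subject_id", "age", "sex", "group", "ct_status", "sss", "sac"]


@dataclass
class SubjectRecord:
    """Demographics and clinical scores for one subject.

    ``group`` is the recruitment stream ({control, trauma}); the concussion
    case label is derived, never stored raw.  ``ct_status`` is one of
    {positive, negative, none} — 'none' means no CT was indicated/recorded.
    """

    subject_id: str
    age: float
    sex: str
    group: str
    ct_status: str = "none"
    sss: float | None = None
    sac: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.group not in ("control", "trauma"):
            raise ValueError("group must be 'control' or 'trauma'")
        if self.ct_status not in ("positive", "negative", "none"):
            raise ValueError("ct_status must be positive/negative/none")
        if self.sss is not None and not np.isnan(self.sss):
            if not SSS_RANGE[0] <= self.sss <= SSS_RANGE[1]:
                raise ValueError("sss outside scale range")
        if self.sac is not None and not np.isnan(self.sac):
            if not SAC_RANGE[0] <= self.sac <= SAC_RANGE[1]:
                raise ValueError("sac outside scale range")


def label_concussion(subject: SubjectRecord) -> bool | None:
    """Concussion 'true positive' rule: CT-negative AND SSS > 40 AND SAC <= 24.

    Returns None (not labelable) when CT status or either score is missing —
    deliberately distinct from False.
    """
    if subject.ct_status == "none":
        return None
    if subject.sss is None or subject.sac is None:
        return None
    if np.isnan(subject.sss) or np.isnan(subject.sac):
        return None
    return (subject.ct_status == "negative"
            and subject.sss > 40 and subject.sac <= 24)


def case_label(subject: SubjectRecord) -> str:
    """Three-state label column value: case / control / unlabeled."""
    if subject.group == "control":
        return "control"
    lab = label_concussion(subject)
    if lab is None:
        return "unlabeled"
    return "case" if lab else "unlabeled"


def balance_sample(cases: list[SubjectRecord], controls: list[SubjectRecord],
                   match_sex: str | None = None, seed: int = 0,
                   ) -> tuple[list[SubjectRecord], list[SubjectRecord], float]:
    """1:1 age matching of controls to cases, optionally within one sex.

    Nearest-neighbor on age without replacement, randomized tie-break under
    ``seed``.  Returns (cases, matched controls, age rank-sum p-value) and
    raises if the matched cohort still shows a significant age difference.
    """
    if match_sex is not None:
        cases = [s for s in cases if s.sex == match_sex]
        controls = [s for s in controls if s.sex == match_sex]
    if not cases:
        raise ValueError("no cases to match")
    if len(controls) < len(cases):
        raise ValueError(
            f"not enough controls to match: {len(controls)} < {len(cases)}")

    rng = np.random.default_rng(seed)
    pool = list(controls)
    matched: list[SubjectRecord] = []
    # match hardest-to-match (extreme age) cases first
    order = sorted(cases, key=lambda s: abs(s.age - np.median([c.age for c in controls])),
                   reverse=True)
    for case in order:
        gaps = np.array([abs(c.age - case.age) for c in pool])
        best = np.flatnonzero(gaps == gaps.min())
        pick = int(rng.choice(best))
        matched.append(pool.pop(pick))

    case_ages = [s.age for s in cases]
    ctl_ages = [s.age for s in matched]
    if len(set(case_ages + ctl_ages)) == 1:
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(case_ages, ctl_ages,
                                     alternative="two-sided").pvalue)
    if p <= 0.05:
        raise ValueError(
            f"matching failed: matched cohort age rank-sum p = {p:.4f} <= 0.05")
    return list(cases), matched, p


def filter_ct(cohort: list[SubjectRecord], keep: str = "all") -> list[SubjectRecord]:
    """Restrict trauma subjects by CT status; controls pass through unchanged."""
    if keep == "all":
        return list(cohort)
    if keep != "ct_negative_only":
        raise ValueError("keep must be 'all' or 'ct_negative_only'")
    out = [s for s in cohort
           if s.group == "control" or s.ct_status == "negative"]
    if not any(s.group == "trauma" for s in out):
        warnings.warn("no CT-negative trauma subjects remain after filtering")
    return out


def cohort_to_frame(cohort: list[SubjectRecord], labeled: bool = True) -> pd.DataFrame:
    df = pd.DataFrame([{
        "subject_id": s.subject_id, "age": s.age, "sex": s.sex,
        "group": s.group, "ct_status": s.ct_status,
        "sss": s.sss, "sac": s.sac} for s in cohort])
    if labeled:
        df["case_label"] = [case_label(s) for s in cohort]
    return df


def write_cohort_csv(cohort: list[SubjectRecord], path, labeled: bool = True) -> None:
    cohort_to_frame(cohort, labeled=labeled).to_csv(path, index=False)


def read_cohort_csv(path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        sss = row["sss"] if pd.notna(row["sss"]) else None
        sac = row["sac"] if pd.notna(row["sac"]) else None
        out.append(SubjectRecord(
            subject_id=str(row["subject_id"]), age=float(row["age"]),
            sex=str(row["sex"]), group=str(row["group"]),
            ct_status=str(row["ct_status"]), sss=sss, sac=sac))
    return out
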