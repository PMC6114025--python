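"""Univariate biomarker screening.

Group contrasts use Wilcoxon rank-sum tests with a Bonferroni family-wise
threshold; candidate metrics significantly associated with sex or age in
the full control sample are excluded; mutually correlated survivors are
deduplicated to one representative.
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb

EXACT_MAX_GROUP = 8          # exact enumeration when min group size <= this
EXACT_MAX_COMBINATIONS = 500_000

P_SEX_CUT = 0.01
P_AGE_CUT = 0.05
DEFAULT_R_CUT = 0.8


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided rank-sum p-value with midrank tie handling.

    Exact enumeration of all group assignments when the smaller group has
    <= 8 members (and the combination count is tractable); otherwise the
    normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    ranks = stats.rankdata(pooled)
    n1, n2 = len(a), len(b)
    w = float(np.sum(ranks[:n1]))
    mu = n1 * (n1 + n2 + 1) / 2.0

    small = min(n1, n2)
    if small <= EXACT_MAX_GROUP and comb(n1 + n2, small) <= EXACT_MAX_COMBINATIONS:
        # enumerate rank-sum of the smaller group over all assignments
        if n1 <= n2:
            target = abs(w - mu)
            k, m = n1, mu
        else:
            w2 = float(np.sum(ranks[n1:]))
            m = n2 * (n1 + n2 + 1) / 2.0
            target = abs(w2 - m)
            k = n2
        count = 0
        total = 0
        for idx in combinations(range(n1 + n2), k):
            total += 1
            if abs(ranks[list(idx)].sum() - m) >= target - 1e-9:
                count += 1
        return count / total

    # normal approximation with tie correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(sigma2)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha/m controlling the family-wise error rate."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    return alpha / m


def metric_auc(case_values, control_values) -> float:
    """P(random case > random control), ties counted 1/2 (rank-sum identity)."""
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    n1 = len(cases)
    u = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * len(controls)))


def covariate_screen(control_metrics: pd.DataFrame, age, sex,
                     p_sex_cut: float = P_SEX_CUT,
                     p_age_cut: float = P_AGE_CUT) -> pd.DataFrame:
    """Flag metrics associated with sex or age in the full control sample.

    Sex: rank-sum test male vs female.  Age: Spearman rank correlation.
    A metric is excluded iff p_sex <= p_sex_cut or p_age <= p_age_cut
    (inclusive thresholds).
    """
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    male = sex == "male"
    single_sex = male.all() or (~male).all()
    if single_sex:
        warnings.warn("single-sex control sample: sex screen skipped")

    rows = []
    for name in control_metrics.columns:
        v = control_metrics[name].to_numpy(float)
        ok = np.isfinite(v)
        if single_sex or ok[male].sum() < 2 or ok[~male].sum() < 2:
            p_sex = math.nan
        else:
            p_sex = wilcoxon_rank_sum(v[male & ok], v[~male & ok])
        ok_age = ok & np.isfinite(age)
        if ok_age.sum() < 3 or np.all(v[ok_age] == v[ok_age][0]):
            p_age = math.nan
        else:
            p_age = float(stats.spearmanr(v[ok_age], age[ok_age]).pvalue)
        excluded = ((not math.isnan(p_sex) and p_sex <= p_sex_cut)
                    or (not math.isnan(p_age) and p_age <= p_age_cut))
        rows.append({"metric": name, "p_sex": p_sex, "p_age": p_age,
                     "excluded_by_covariate": excluded})
    return pd.DataFrame(rows).set_index("metric")


def dedup_correlated(candidates: pd.DataFrame, p_group: pd.Series,
                     r_cut: float = DEFAULT_R_CUT) -> list[str]:
    """Keep one representative per cluster of |Spearman r| > r_cut metrics.

    Clusters are connected components of the pairwise-correlation graph;
    the representative has the smallest group-contrast p-value, ties broken
    lexicographically.
    """
    names = list(candidates.columns)
    if not names:
        return []
    if len(names) == 1:
        return names
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corr = candidates.corr(method="spearman").abs().to_numpy()
    # union-find over the correlation graph
    parent = list(range(len(names)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if np.isfinite(corr[i, j]) and corr[i, j] > r_cut:
                parent[find(i)] = find(j)

    kept = []
    clusters: dict[int, list[str]] = {}
    for i, name in enumerate(names):
        clusters.setdefault(find(i), []).append(name)
    for members in clusters.values():
        members.sort(key=lambda m: (p_group.get(m, math.inf), m))
        kept.append(members[0])
    return sorted(kept, key=names.index)


def screening_table(metric_table: pd.DataFrame, labels,
                    control_metrics: pd.DataFrame, control_age, control_sex,
                    alpha: float = 0.05,
                    p_sex_cut: float = P_SEX_CUT, p_age_cut: float = P_AGE_CUT,
                    r_cut: float = DEFAULT_R_CUT) -> pd.DataFrame:
    """Full screening report over a balanced case/control metric table.

    ``labels`` is a boolean case indicator aligned with ``metric_table``
    rows; ``control_metrics``/``control_age``/``control_sex`` describe the
    full control sample used for the covariate screen.  Output mirrors the
    candidate-biomarker table: p_group, p_sex, p_age, auc and flags.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("need both cases and controls")
    m = metric_table.shape[1]
    threshold = bonferroni_threshold(alpha, m)
    cov = covariate_screen(control_metrics, control_age, control_sex,
                           p_sex_cut, p_age_cut)

    rows = []
    for name in metric_table.columns:
        v = metric_table[name].to_numpy(float)
        ok = np.isfinite(v)
        cases = v[labels & ok]
        controls = v[~labels & ok]
        if len(cases) < 2 or len(controls) < 2:
            p_group, auc = math.nan, math.nan
        else:
            p_group = wilcoxon_rank_sum(cases, controls)
            auc = metric_auc(cases, controls)
        rows.append({
            "metric": name, "p_group": p_group,
            "p_sex": cov.loc[name, "p_sex"], "p_age": cov.loc[name, "p_age"],
            "auc": auc,
            "pass_bonferroni": bool(not math.isnan(p_group) and p_group < threshold),
            "excluded_by_covariate": bool(cov.loc[name, "excluded_by_covariate"]),
        })
    table = pd.DataFrame(rows).set_index("metric")

    # deduplicate among unexcluded nominally significant candidates
    candidates = [n for n in table.index
                  if not table.loc[n, "excluded_by_covariate"]
                  and math.isfinite(table.loc[n, "p_group"])
                  and table.loc[n, "p_group"] < alpha]
    kept = dedup_correlated(metric_table[candidates], table["p_group"], r_cut)
    table["dropped_as_duplicate"] = [
        (n in candidates and n not in kept) for n in table.index]
    table["candidate"] = [n in kept for n in table.index]
    return table


def write_screening_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")
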