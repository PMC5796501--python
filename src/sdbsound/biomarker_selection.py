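"""Severity-group discriminator selection and biomarker assembly.

A feature is a discriminator for group G when its Tukey HSD pairwise test
is significant between G and each of the other three severity groups; the
acoustic biomarker is the deduplicated union of the four groups'
discriminator sets. A linear-SVM recursive-elimination ranking is provided
as an optional second-stage feature selector.
"""

from __future__ import annotations

import importlib.resources
import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from sdbsound.io_audio import SEVERITY_GROUPS

@dataclass
class DiscriminatorSets:
    """Per-group lists of discriminating feature names (sets may be empty)."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __getitem__(self, group: str) -> list[str]:
        return self.sets.get(group, [])

    def total_entries(self) -> int:
        return sum(len(v) for v in self.sets.values())


def _group_arrays(values: np.ndarray, groups: np.ndarray) -> list[np.ndarray]:
    labels = [g for g in SEVERITY_GROUPS if g in set(groups)]
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = [values[groups == g] for g in labels]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every represented group needs at least two subjects")
    return arrays


def _anova_components(arrays: list[np.ndarray]):
    """Between/within sums of squares and degrees of freedom for one-way ANOVA."""
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)
    return ss_between, ss_within, df_between, df_within


def one_way_anova(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA F statistic and p-value.

    Degenerate variance conventions: all-equal data gives (0, 1); zero
    within-group variance with separated means gives (inf, 0).
    """
    arrays = _group_arrays(np.asarray(values, dtype=np.float64), np.asarray(groups))
    ssb, ssw, dfb, dfw = _anova_components(arrays)
    if ssw <= 0:
        if ssb <= 0:
            return 0.0, 1.0
        return np.inf, 0.0
    f_stat = (ssb / dfb) / (ssw / dfw)
    return float(f_stat), float(f_dist.sf(f_stat, dfb, dfw))


def anova_screen(
    table: pd.DataFrame, groups: np.ndarray | pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA per feature column; pass iff p < alpha."""
    groups = np.asarray(groups)
    rows = []
    for feat in table.columns:
        f_stat, p = one_way_anova(table[feat].to_numpy(), groups)
        rows.append({"feature": feat, "F": f_stat, "p": p, "passed": bool(p < alpha)})
    return pd.DataFrame(rows).set_index("feature")


def tukey_pairwise(
    values: np.ndarray, groups: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Tukey-Kramer HSD p-values for every pair of severity groups.

    Uses the studentized-range distribution on the pooled within-group
    variance; unequal group sizes use the Kramer adjustment. Features with
    zero pooled variance are flagged with p = 1 (or p = 0 when group means
    still differ, mirroring the ANOVA convention).
    """
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    labels = [g for g in SEVERITY_GROUPS if g in set(groups)]
    arrays = {g: values[groups == g] for g in labels}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("every represented group needs at least two subjects")
    k = len(labels)
    df_within = sum(a.size for a in arrays.values()) - k
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_within
    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        a, b = arrays[g1], arrays[g2]
        diff = abs(a.mean() - b.mean())
        if msw <= 0:
            p = 0.0 if diff > 0 else 1.0
            q = np.inf if diff > 0 else 0.0
        else:
            se = np.sqrt(msw / 2.0 * (1.0 / a.size + 1.0 / b.size))
            q = diff / se
            p = float(studentized_range.sf(q, k, df_within))
        rows.append(
            {"group1": g1, "group2": g2, "q": q, "p": p, "significant": bool(p < alpha)}
        )
    return pd.DataFrame(rows)


def select_discriminators(
    table: pd.DataFrame,
    groups: np.ndarray | pd.Series,
    alpha: float = 0.05,
    require_anova: bool = True,
) -> DiscriminatorSets:
    """Assign each feature to the severity groups it discriminates.

    Feature f belongs to group G's set iff its Tukey HSD p-value is below
    alpha for all three (G, other) pairs. By default only features passing
    the one-way ANOVA screen are Tukey-tested.
    """
    groups = np.asarray(groups)
    present = [g for g in SEVERITY_GROUPS if g in set(groups)]
    if len(present) != 4:
        raise ValueError("discriminator selection requires all four severity groups")
    candidates = list(table.columns)
    if require_anova:
        screen = anova_screen(table, groups, alpha)
        candidates = [f for f in candidates if screen.loc[f, "passed"]]
    sets: dict[str, list[str]] = {g: [] for g in SEVERITY_GROUPS}
    for feat in candidates:
        pairwise = tukey_pairwise(table[feat].to_numpy(), groups, alpha)
        for g in SEVERITY_GROUPS:
            mask = (pairwise["group1"] == g) | (pairwise["group2"] == g)
            if bool(pairwise.loc[mask, "significant"].all()):
                sets[g].append(feat)
    return DiscriminatorSets(sets=sets)


def assemble_biomarker(sets: DiscriminatorSets) -> list[str]:
    """Stable-order deduplicated union of all groups' discriminator names."""
    seen: dict[str, None] = {}
    for g in SEVERITY_GROUPS:
        for feat in sets[g]:
            seen.setdefault(feat, None)
    union = list(seen)
    if not union:
        warnings.warn(
            "biomarker union is empty; downstream classification should fall "
            "back to all features",
            stacklevel=2,
        )
    return union


def svm_rank_features(
    table: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    top_k: int,
    C: float = 1.0,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Rank features by linear-SVM recursive elimination; return (ranking, top-k).

    At each step a one-vs-rest linear SVM is fit on the standardized
    surviving features and the feature with the smallest summed squared
    weight across classes is eliminated; ties break by column order. The
    ranking lists features from strongest to weakest.
    """
    labels = np.asarray(labels)
    features = list(table.columns)
    if len(set(labels)) < 2:
        raise ValueError("need at least two classes")
    if top_k > len(features):
        warnings.warn(
            f"top_k={top_k} exceeds the {len(features)} available features; returning all",
            stacklevel=2,
        )
        top_k = len(features)
    X_full = StandardScaler().fit_transform(table.to_numpy(dtype=np.float64))
    surviving = list(range(len(features)))
    eliminated: list[int] = []
    while len(surviving) > 1:
        svm = LinearSVC(C=C, dual=False, random_state=seed, max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            svm.fit(X_full[:, surviving], labels)
        weight2 = (np.atleast_2d(svm.coef_) ** 2).sum(axis=0)
        weakest = int(np.argmin(weight2))  # argmin takes the first (column-order) tie
        eliminated.append(surviving.pop(weakest))
    eliminated.extend(surviving)
    ranking = [features[i] for i in reversed(eliminated)]
    return ranking, ranking[:top_k]


def _expand_indices(spec: str) -> list[int]:
    out: list[int] = []
    for part in spec.split(","):
        part = part.strip()
        if "-" in part:
            lo, hi = part.split("-")
            out.extend(range(int(lo), int(hi) + 1))
        else:
            out.append(int(part))
    return out


def _fixture_column(feature: str, index: int | None, statistic: str, derivative: bool) -> str:
    if index is None:
        base = feature
    elif feature == "sb":
        base = f"sb{index}"
    else:
        base = f"{feature}_{index}"
    return f"{base}_d1_{statistic}" if derivative else f"{base}_{statistic}"


def load_reference_discriminators() -> pd.DataFrame:
    """Load the bundled reference discriminator fixture, expanding index ranges.

    One row per (group, feature, statistic, derivative) entry, with the
    resolved per-subject column name; 132 rows in total (62 normal, 7
    moderate, 63 severe).
    """
    resource = importlib.resources.files("sdbsound.data") / "reference_discriminators.csv"
    with importlib.resources.as_file(resource) as path:
        compact = pd.read_csv(path, dtype={"indices": str}, keep_default_na=False)
    rows = []
    for rec in compact.itertuples(index=False):
        indices = _expand_indices(rec.indices) if rec.indices else [None]
        for idx in indices:
            rows.append(
                {
                    "group": rec.group,
                    "feature": rec.feature if idx is None else f"{rec.feature} {idx}",
                    "statistic": rec.statistic,
                    "derivative": bool(rec.derivative),
                    "column": _fixture_column(rec.feature, idx, rec.statistic, bool(rec.derivative)),
                }
            )
    return pd.DataFrame(rows)
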