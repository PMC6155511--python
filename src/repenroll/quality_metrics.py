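"""Per-respondent careless-responding indicators and group-wise summaries.

These adapt the consistency / outlier / patterning / timing metrics of the
careless-responding literature (Meade & Craig) to questionnaire data:

1. completion time (minutes; summarized by the median, as it is heavily
   skewed in both directions — bots finish fast, abandoned sessions slow);
2. correlation of synonyms: within a respondent, the correlation across the
   item pairs that are most strongly correlated in the whole sample;
3. even-odd consistency: correlate a respondent's even-position and
   odd-position half-scale means across unidimensional scales, with the
   Spearman-Brown step-up correction 2 rho / (1 + rho);
4. distance from average: unstandardized Euclidean distance between the
   respondent's responses and the column means (outlier measure);
5. runs of identical responses: per page with many items, the longest run
   of identical consecutive responses scaled to [0, 1] as
   (run - 1) / (items - 1), averaged over qualifying pages.

Boolean flags collected during study conduct (inconsistent state/climate,
non-US phone, fake name, ...) pass through untouched and are summarized as
percentages. Latent-class model fitting is out of scope: class labels come
from outside and are only cross-tabulated / summarized here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "ScaleDefinition",
    "select_synonym_pairs",
    "synonym_correlation",
    "even_odd_consistency",
    "distance_from_average",
    "run_statistic",
    "quality_profiles",
    "summarize_by_group",
    "cross_tabulate",
]


@dataclass(frozen=True)
class ScaleDefinition:
    """An ordered list of items forming one unidimensional scale."""

    name: str
    items: tuple

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(self.items))
        if len(self.items) < 4:
            raise ValueError(
                f"scale {self.name!r}: need at least 4 items for even-odd splitting"
            )


def _pearson(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def select_synonym_pairs(responses: pd.DataFrame, q: int) -> list[tuple[str, str]]:
    """The q disjoint item pairs with highest absolute sample correlation.

    Greedy by descending |correlation|: take the strongest pair, drop its
    items, repeat.
    """
    cols = list(responses.columns)
    if len(cols) < 2 * q:
        raise ValueError(f"need at least {2 * q} items for q={q} pairs")
    corr = responses.corr().abs()
    candidates = sorted(
        combinations(cols, 2), key=lambda p: corr.loc[p[0], p[1]], reverse=True
    )
    used: set = set()
    pairs = []
    for a, b in candidates:
        if a in used or b in used:
            continue
        pairs.append((a, b))
        used.update((a, b))
        if len(pairs) == q:
            break
    return pairs


def synonym_correlation(row, pairs) -> float:
    """Within-respondent correlation of first vs second elements across item pairs."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for a within-person correlation")
    firsts = [row[a] for a, _ in pairs]
    seconds = [row[b] for _, b in pairs]
    return _pearson(firsts, seconds)


def even_odd_consistency(row, scales: list[ScaleDefinition]) -> float:
    """Spearman-Brown-corrected correlation of even vs odd half-scale means."""
    if len(scales) < 3:
        raise ValueError("need at least 3 scales for an even-odd correlation")
    odd_means, even_means = [], []
    for sc in scales:
        vals = np.asarray([row[i] for i in sc.items], float)
        odd_means.append(np.nanmean(vals[0::2]))
        even_means.append(np.nanmean(vals[1::2]))
    rho = _pearson(odd_means, even_means)
    if np.isnan(rho) or rho <= -1:
        return float("nan")
    return 2 * rho / (1 + rho)


def distance_from_average(responses: pd.DataFrame) -> pd.Series:
    """Unstandardized Euclidean distance of each row from the column means."""
    x = responses.to_numpy(dtype=float)
    dev = x - np.nanmean(x, axis=0)
    return pd.Series(np.sqrt(np.nansum(dev**2, axis=1)), index=responses.index)


def _longest_run(values: np.ndarray) -> int:
    best = run = 1
    for prev, cur in zip(values, values[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


def run_statistic(row, pages: dict, page_min: int = 5) -> float:
    """Mean normalized longest run of identical responses over long pages.

    For each page with at least ``page_min`` items, the longest run of
    identical consecutive responses is scaled as (run - 1) / (items - 1),
    so an all-identical page scores 1 and strict alternation scores 0.
    """
    per_page = []
    for items in pages.values():
        if len(items) < page_min:
            continue
        vals = np.asarray([row[i] for i in items], float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            continue
        per_page.append((_longest_run(vals) - 1) / (vals.size - 1))
    return float(np.mean(per_page)) if per_page else float("nan")


def quality_profiles(
    df: pd.DataFrame,
    scales: list[ScaleDefinition] | None = None,
    pages: dict | None = None,
    synonym_items: list[str] | None = None,
    q_pairs: int = 10,
    time_col: str = "completion_minutes",
    flag_cols: list[str] | None = None,
    page_min: int = 5,
) -> pd.DataFrame:
    """Assemble the per-respondent quality profile table.

    Continuous metrics are computed from the questionnaire responses in
    ``df``; boolean flag columns pass through unchanged.
    """
    out = pd.DataFrame(index=df.index)
    if time_col in df.columns:
        out[time_col] = df[time_col]
    if synonym_items:
        sub = df[synonym_items]
        pairs = select_synonym_pairs(sub, q_pairs)
        out["synonym_corr"] = sub.apply(lambda r: synonym_correlation(r, pairs), axis=1)
    if scales:
        all_items = [i for sc in scales for i in sc.items]
        out["even_odd_corr"] = df[all_items].apply(
            lambda r: even_odd_consistency(r, scales), axis=1
        )
    resp_cols = synonym_items or (
        [i for sc in scales for i in sc.items] if scales else None
    )
    if resp_cols:
        out["distance_from_average"] = distance_from_average(df[resp_cols])
    if pages:
        page_items = [i for items in pages.values() for i in items]
        out["mean_run_statistic"] = df[page_items].apply(
            lambda r: run_statistic(r, pages, page_min=page_min), axis=1
        )
    for c in flag_cols or []:
        out[c] = df[c].astype(bool)
    return out


def summarize_by_group(
    profiles: pd.DataFrame,
    groups,
    median_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Group-wise summary: medians for timing, means for continuous, % for flags.

    Returns one column per group plus a full-sample column. For mean-type
    metrics the full-sample value is the size-weighted mean of group means.
    """
    groups = pd.Series(np.asarray(groups), index=profiles.index, name="group")
    if groups.isna().any():
        raise ValueError("group labels must cover all respondents")
    median_cols = median_cols or [
        c for c in profiles.columns if "minute" in c or "time" in c
    ]

    def _agg(sub: pd.DataFrame) -> pd.Series:
        rec = {}
        for c in sub.columns:
            if sub[c].dtype == bool:
                rec[c] = 100.0 * sub[c].mean()
            elif c in median_cols:
                rec[c] = sub[c].median()
            else:
                rec[c] = sub[c].mean()
        return pd.Series(rec)

    cols = {"full_sample": _agg(profiles)}
    for g in pd.unique(groups):
        cols[g] = _agg(profiles.loc[groups == g])
    return pd.DataFrame(cols)


def cross_tabulate(labels_a, labels_b, names=("cluster", "class")) -> pd.DataFrame:
    """Cross-tabulation of two partitions of the respondents, with margins."""
    a = pd.Series(np.asarray(labels_a), name=names[0])
    b = pd.Series(np.asarray(labels_b), name=names[1])
    return pd.crosstab(a, b, margins=True, margins_name="Total")
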