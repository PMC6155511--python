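"""The SSW statistic, its simulated null reference, and cluster flagging.

For each cluster c in a height-h partition, the size-and-silhouette-width
statistic combines cluster size N_c and average silhouette width ASW_c on a
common scale:

    SSW_c = N_c / max_j N_j + ASW_c / max_j ASW_j.

A cluster attaining both maxima scores 2; large, unusually tight clusters
score high. The null reference is built by simulating M cohorts of
independent eligible completers, re-running the identical clustering at the
same height, and computing each simulated cluster's SSW*_c *normalized by
the observed data's maxima* so the scales match. The observed cluster's
evidence is the exceedance probability: the fraction of the M simulations
whose largest SSW* falls strictly below SSW_c. Clusters whose exceedance
probability exceeds a threshold tau (default 0.95) are flagged as likely
non-independent enrollments. This is not a formal p-value — no multiplicity
adjustment is attempted — but calibration under the null is close to 1-tau
at the dataset level.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .clustering import (
    ClusterSummary,
    cluster_summaries,
    complete_linkage,
    cut_at_height,
    pairwise_distances,
    silhouette_widths,
)
from .null_simulation import NullModel, rejection_sample_cohort
from .survey_data import SurveyMatrix, standardize

__all__ = [
    "SSWTable",
    "NullDistribution",
    "DetectionResult",
    "compute_ssw",
    "exceedance_probability",
    "flag_clusters",
    "simulate_null_distribution",
    "run_detection",
]


@dataclass
class SSWTable:
    """SSW per cluster plus the normalization constants used."""

    cluster_ids: np.ndarray
    sizes: np.ndarray
    asws: np.ndarray
    ssw: np.ndarray
    size_ref: float
    asw_ref: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": self.cluster_ids,
                "size": self.sizes,
                "asw": self.asws,
                "ssw": self.ssw,
            }
        )


@dataclass
class NullDistribution:
    """max_c SSW*_c from each of M independent-cohort simulations."""

    max_ssw_star: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        self.max_ssw_star = np.asarray(self.max_ssw_star, dtype=float)
        if self.max_ssw_star.size == 0:
            raise ValueError("null distribution is empty")
        if not np.isfinite(self.max_ssw_star).all():
            raise ValueError("null distribution contains non-finite values")

    @property
    def m(self) -> int:
        return self.max_ssw_star.size


@dataclass
class DetectionResult:
    """Flagged clusters and per-cluster exceedance probabilities."""

    ssw_table: SSWTable
    exceedance: np.ndarray
    flagged: np.ndarray
    tau: float
    null: NullDistribution
    members: dict = dc_field(default_factory=dict)  # cluster id -> row indices

    @property
    def flagged_cluster_ids(self) -> np.ndarray:
        return self.ssw_table.cluster_ids[self.flagged]

    @property
    def flagged_rows(self) -> np.ndarray:
        ids = self.flagged_cluster_ids
        if ids.size == 0:
            return np.array([], dtype=int)
        return np.sort(np.concatenate([self.members[int(c)] for c in ids]))

    def to_frame(self) -> pd.DataFrame:
        df = self.ssw_table.to_frame()
        df["exceedance_prob"] = self.exceedance
        df["flagged"] = self.flagged
        return df


def compute_ssw(
    summaries: list[ClusterSummary],
    size_ref: float | None = None,
    asw_ref: float | None = None,
) -> SSWTable:
    """SSW_c = N_c/size_ref + ASW_c/asw_ref for every cluster.

    When the references are omitted they default to the maxima over the
    supplied summaries (observed-data mode). Simulated clusters must be
    normalized with the *observed* maxima so both statistics share a scale;
    pass those via ``size_ref``/``asw_ref``.
    """
    sizes = np.array([c.size for c in summaries], dtype=float)
    asws = np.array([c.asw for c in summaries], dtype=float)
    if size_ref is None:
        size_ref = float(sizes.max())
    if asw_ref is None:
        asw_ref = float(asws.max())
    if asw_ref <= 0:
        raise ValueError(
            "maximum cluster ASW is not positive: every cluster at this height is "
            "poorly separated, so the SSW normalization is undefined. Choose a "
            "different cut height (see height_diagnostics)."
        )
    if size_ref <= 0:
        raise ValueError("size reference must be positive")
    return SSWTable(
        cluster_ids=np.array([c.cluster_id for c in summaries]),
        sizes=sizes,
        asws=asws,
        ssw=sizes / size_ref + asws / asw_ref,
        size_ref=float(size_ref),
        asw_ref=float(asw_ref),
    )


def exceedance_probability(ssw_c: float, null: NullDistribution) -> float:
    """Fraction of simulations whose max SSW* lies strictly below ssw_c."""
    return float((ssw_c > null.max_ssw_star).mean())


def flag_clusters(
    ssw_table: SSWTable,
    null: NullDistribution,
    tau: float = 0.95,
    members: dict | None = None,
) -> DetectionResult:
    """Flag clusters whose exceedance probability strictly exceeds tau."""
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    probs = np.array([exceedance_probability(v, null) for v in ssw_table.ssw])
    return DetectionResult(
        ssw_table=ssw_table,
        exceedance=probs,
        flagged=probs > tau,
        tau=float(tau),
        null=null,
        members=members or {},
    )


def _cluster_pipeline(m: SurveyMatrix, h: float, sd_mode: str):
    std = standardize(m, sd_mode=sd_mode)
    d = pairwise_distances(std)
    dend = complete_linkage(d)
    assign = cut_at_height(dend, h)
    sil = silhouette_widths(d, assign)
    return d, dend, assign, sil, cluster_summaries(assign, sil)


def simulate_null_distribution(
    null_model: NullModel,
    n: int,
    h: float,
    m_sims: int,
    size_ref: float,
    asw_ref: float,
    seed,
    sd_mode: str = "sample",
) -> NullDistribution:
    """Simulate M cohorts, recluster each identically, and collect max SSW*.

    Each simulation draws its own substream from the master seed, so results
    for the first simulations are unchanged when M grows. Only sizes and
    ASWs of the simulated clusters are retained.
    """
    if m_sims < 1:
        raise ValueError("need at least one simulation")
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    children = ss.spawn(m_sims)
    maxima = np.empty(m_sims)
    for i, child in enumerate(children):
        cohort = rejection_sample_cohort(null_model, n, np.random.default_rng(child))
        _, _, _, _, summ = _cluster_pipeline(cohort.matrix, h, sd_mode)
        table = compute_ssw(summ, size_ref=size_ref, asw_ref=asw_ref)
        maxima[i] = table.ssw.max()
    return NullDistribution(max_ssw_star=maxima)


def run_detection(
    m: SurveyMatrix,
    h: float,
    m_sims: int,
    null_model: NullModel,
    seed,
    tau: float = 0.95,
    sd_mode: str = "sample",
) -> DetectionResult:
    """Full pipeline: cluster the observed cohort, reference it against the null.

    standardize -> distances -> complete linkage -> cut at h -> silhouettes
    -> SSW -> M null simulations (re-clustered identically at the same h,
    normalized by the observed maxima) -> exceedance probabilities -> flags.
    Reproducible given the seed.
    """
    _, _, assign, sil, summ = _cluster_pipeline(m, h, sd_mode)
    table = compute_ssw(summ)
    null = simulate_null_distribution(
        null_model, m.n, h, m_sims, table.size_ref, table.asw_ref, seed, sd_mode
    )
    members = {c.cluster_id: c.members for c in summ}
    return flag_clusters(table, null, tau=tau, members=members)
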