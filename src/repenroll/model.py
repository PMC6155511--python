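"""Model/Results interface over the detection pipeline.

`EnrollmentClusterModel` is built from a survey cohort (and, optionally, a
null model describing the independent-respondent population); `fit()` runs
the complete-linkage clustering at a chosen height, simulates the null
reference of the SSW statistic, and returns an
`EnrollmentClusterResults` carrying the per-cluster estimates, their null
exceedance probabilities, the flags, and plotting / export helpers.

    >>> model = EnrollmentClusterModel(survey, null_model=nm)
    >>> model.height_diagnostics([4.0, 4.5, 5.0])       # choose the cut
    >>> res = model.fit(height=4.5, n_sims=1000, seed=7)
    >>> print(res.summary())
    >>> res.flagged_respondents
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import clustering as cl
from .detection import (
    DetectionResult,
    NullDistribution,
    compute_ssw,
    flag_clusters,
    simulate_null_distribution,
)
from .null_simulation import NullModel
from .survey_data import FieldSchema, SurveyMatrix, standardize

__all__ = ["EnrollmentClusterModel", "EnrollmentClusterResults"]


class EnrollmentClusterModel:
    """Hierarchical-clustering outlier model for repeat-enrollment detection.

    Parameters
    ----------
    survey : SurveyMatrix
        The analyzed cohort (clustering fields complete, enrollment order
        included).
    null_model : NullModel, optional
        The independent-respondent population used to simulate the SSW null
        reference. Required for :meth:`fit`; diagnostics work without it.
    sd_mode : {"sample", "population"}
        Denominator convention for the per-field standard deviations.
    """

    def __init__(self, survey: SurveyMatrix, null_model: NullModel | None = None,
                 sd_mode: str = "sample"):
        self.survey = survey
        self.null_model = null_model
        self.sd_mode = sd_mode
        self._distances = None
        self._dendrogram = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schemas: list[FieldSchema],
                       null_model: NullModel | None = None,
                       sd_mode: str = "sample") -> "EnrollmentClusterModel":
        return cls(SurveyMatrix.from_frame(df, schemas), null_model, sd_mode)

    # -- cached clustering geometry ---------------------------------------
    @property
    def distances(self) -> cl.DistanceMatrix:
        if self._distances is None:
            self._distances = cl.pairwise_distances(
                standardize(self.survey, sd_mode=self.sd_mode)
            )
        return self._distances

    @property
    def dendrogram(self) -> cl.Dendrogram:
        if self._dendrogram is None:
            self._dendrogram = cl.complete_linkage(self.distances)
        return self._dendrogram

    def height_diagnostics(self, candidate_heights) -> pd.DataFrame:
        """ASW diagnostics over candidate cut heights (to choose ``height``)."""
        return cl.height_diagnostics(self.dendrogram, self.distances, candidate_heights)

    def fit(self, height: float, n_sims: int = 1000, tau: float = 0.95,
            seed=None) -> "EnrollmentClusterResults":
        """Cut at ``height``, simulate ``n_sims`` null cohorts, flag clusters.

        The observed clusters' SSW uses the observed maxima as normalizers;
        every simulated cohort is re-clustered identically at the same
        height and normalized by those same observed maxima.
        """
        if self.null_model is None:
            raise ValueError("fit requires a null_model (see estimate_null_model)")
        assign = cl.cut_at_height(self.dendrogram, height)
        sil = cl.silhouette_widths(self.distances, assign)
        summaries = cl.cluster_summaries(assign, sil)
        table = compute_ssw(summaries)
        null = simulate_null_distribution(
            self.null_model, self.survey.n, height, n_sims,
            table.size_ref, table.asw_ref, seed, self.sd_mode,
        )
        members = {c.cluster_id: c.members for c in summaries}
        detection = flag_clusters(table, null, tau=tau, members=members)
        return EnrollmentClusterResults(self, height, assign, sil, detection, seed)


@dataclass
class EnrollmentClusterResults:
    """Fitted detection results: per-cluster SSW, exceedance, flags."""

    model: EnrollmentClusterModel
    height: float
    assignment: cl.ClusterAssignment
    silhouettes: cl.SilhouetteResult
    detection: DetectionResult
    seed: object = None

    # -- accessors ---------------------------------------------------------
    @property
    def cluster_table(self) -> pd.DataFrame:
        return self.detection.to_frame().sort_values("ssw", ascending=False,
                                                     ignore_index=True)

    @property
    def null_distribution(self) -> NullDistribution:
        return self.detection.null

    @property
    def flagged_rows(self) -> np.ndarray:
        return self.detection.flagged_rows

    @property
    def flagged_respondents(self) -> list:
        ids = self.model.survey.respondent_ids
        return [ids[i] for i in self.flagged_rows]

    def assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "respondent_id": self.model.survey.respondent_ids,
                "cluster": self.assignment.labels,
                "silhouette": self.silhouettes.s,
            }
        )

    def reflag(self, tau: float) -> DetectionResult:
        """Re-threshold the existing exceedance probabilities at another tau."""
        return flag_clusters(
            self.detection.ssw_table, self.detection.null, tau=tau,
            members=self.detection.members,
        )

    def summary(self) -> str:
        """Human-readable report of the fit and the flagged clusters."""
        t = self.cluster_table
        n_flag = int(t["flagged"].sum())
        head = [
            "Repeat-enrollment cluster detection",
            "===================================",
            f"Respondents:            {self.model.survey.n}",
            f"Clustering fields:      {self.model.survey.k}",
            f"Cut height:             {self.height}",
            f"Clusters:               {len(t)} (sizes {int(t['size'].min())}-{int(t['size'].max())})",
            f"ASW range:              {t['asw'].min():.3f} to {t['asw'].max():.3f}",
            f"Null simulations (M):   {self.null_distribution.m}",
            f"Flag threshold (tau):   {self.detection.tau}",
            f"Flagged clusters:       {n_flag} "
            f"({int(t.loc[t['flagged'], 'size'].sum())} respondents)",
            "",
            "Top clusters by SSW:",
        ]
        top = t.head(max(n_flag + 3, 5)).copy()
        top["size"] = top["size"].astype(int)
        top["asw"] = top["asw"].round(3)
        top["ssw"] = top["ssw"].round(3)
        top["exceedance_prob"] = top["exceedance_prob"].round(3)
        return "\n".join(head) + "\n" + top.to_string(index=False)

    # -- plots -------------------------------------------------------------
    def plot_dendrogram(self, ax=None, **kwargs):
        """Dendrogram of the complete-linkage tree with the cut height marked."""
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        scipy_dendrogram(self.model.dendrogram.z, ax=ax, no_labels=True,
                         color_threshold=self.height, **kwargs)
        ax.axhline(self.height, ls="--", lw=1, color="gray")
        ax.set_ylabel("merge height")
        return ax

    def plot_ssw(self, ax=None):
        """Observed max-SSW evidence against the simulated null distribution."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.null_distribution.max_ssw_star, bins=30, color="0.7",
                label="simulated max SSW*")
        t = self.cluster_table
        for _, row in t.head(3).iterrows():
            ax.axvline(row["ssw"], color="red" if row["flagged"] else "black",
                       ls="-" if row["flagged"] else ":",
                       label=f"cluster {int(row['cluster'])} (N={int(row['size'])})")
        ax.set_xlabel("max SSW")
        ax.set_ylabel("simulations")
        ax.legend(fontsize=8)
        return ax
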