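"""Synthetic datasets with a planted correlated cluster; sensitivity/specificity.

A validation dataset consists of a large background of independently
simulated eligible completers plus a much smaller *clustered* group meant to
mimic one person enrolling repeatedly. The clustered group's latent Gaussian
draw uses a block covariance

    Sigma = [(1 - r) I_m + r J_m] (x) S,

whose diagonal blocks S give each pseudo-person the same within-person item
correlation as the background and whose off-diagonal blocks rS (0 <= r < 1)
induce correlation *between* the m cluster members. At r = 0 the cluster is
indistinguishable from background; as r -> 1 the members become near-copies.
Clustered draws face the same eligibility screen and completion model as the
background, so the realized cluster size varies around its expectation. The
planted cluster occupies a contiguous run of enrollment order by default
(repeat enrollers act in bursts).

Detection performance over many replicate datasets is summarized by
 - detection rate: fraction of datasets flagging at least one cluster,
 - conditional identification rate: fraction of truly clustered rows flagged
   among the detecting datasets,
 - sensitivity: fraction of truly clustered rows flagged overall,
 - specificity: fraction of background rows not flagged.
Sensitivity factors exactly as detection_rate x conditional_id_rate when the
realized cluster size is constant across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .detection import run_detection
from .null_simulation import NullModel, _discretize, rejection_sample_cohort
from .survey_data import FieldSchema, SurveyMatrix

__all__ = [
    "SyntheticScenario",
    "TruthLabels",
    "ConfusionSummary",
    "build_block_sigma",
    "generate_clustered_dataset",
    "evaluate_detection",
]


@dataclass
class SyntheticScenario:
    """One validation condition: background size, planted-cluster draw, thresholds."""

    null_model: NullModel
    n_background: int = 1296
    n_cluster_draws: int = 125
    r: float = 0.8
    height: float = 4.5
    tau: float = 0.95
    m_sims: int = 1000
    reps: int = 100
    sd_mode: str = "sample"
    screen_cluster: bool = True
    placement: str = "contiguous"  # or "scattered"

    def __post_init__(self):
        if not 0 <= self.r < 1:
            raise ValueError("between-person factor r must lie in [0, 1)")
        if self.placement not in ("contiguous", "scattered"):
            raise ValueError(f"unknown placement {self.placement!r}")


@dataclass
class TruthLabels:
    is_clustered: np.ndarray

    @property
    def n_clustered(self) -> int:
        return int(self.is_clustered.sum())


@dataclass
class ConfusionSummary:
    detection_rate: float
    conditional_id_rate: float
    sensitivity: float
    specificity: float
    reps: int
    per_rep: pd.DataFrame = dc_field(default_factory=pd.DataFrame, repr=False)


def build_block_sigma(s: np.ndarray, r: float, m: int) -> np.ndarray:
    """Block covariance [(1-r) I_m + r J_m] (x) S for m correlated individuals."""
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("S must be square")
    if np.linalg.eigvalsh(s).min() <= 0:
        raise ValueError("S must be positive definite")
    if not 0 <= r < 1:
        raise ValueError("r must lie in [0, 1); r = 1 makes Sigma rank-deficient")
    if m < 1:
        raise ValueError("m must be at least 1")
    between = (1 - r) * np.eye(m) + r * np.ones((m, m))
    return np.kron(between, s)


def _draw_cluster_rows(model: NullModel, scn: SyntheticScenario, rng) -> np.ndarray:
    """Draw the planted cluster and push it through the same screens as background."""
    k = len(model.schemas)
    sigma = build_block_sigma(model.intermediate_corr, scn.r, scn.n_cluster_draws)
    chol = np.linalg.cholesky(sigma)
    z = (chol @ rng.standard_normal(scn.n_cluster_draws * k)).reshape(
        scn.n_cluster_draws, k
    )
    values = _discretize(model, z)
    if not scn.screen_cluster:
        return values
    from .null_simulation import _score_matrix

    eligible = _score_matrix(values, model.schemas) >= model.cutoff
    complete = rng.random(values.shape[0]) < model.completion_probability(values)
    return values[eligible & complete]


def generate_clustered_dataset(
    scn: SyntheticScenario, seed
) -> tuple[SurveyMatrix, TruthLabels]:
    """Background cohort plus a planted correlated cluster, with enrollment order.

    Background rows are independent eligible completers from the null model.
    Clustered rows come from one joint block-Sigma draw, discretized with the
    same thresholds and (by default) passed through the same eligibility and
    completion screens. Enrollment order is a permutation 1..N in which the
    clustered rows occupy a contiguous random window (configurable).
    """
    model = scn.null_model
    if model.intermediate_corr is None:
        from .null_simulation import build_intermediate_matrix

        build_intermediate_matrix(model)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_bg, rng_cl, rng_order = (np.random.default_rng(c) for c in ss.spawn(3))

    background = rejection_sample_cohort(model, scn.n_background, rng_bg).matrix
    bg_values = background.values[:, :-1]  # drop its order column; reassigned below
    cl_values = _draw_cluster_rows(model, scn, rng_cl)
    nb, nc = bg_values.shape[0], cl_values.shape[0]
    n = nb + nc

    order = np.empty(n)
    if scn.placement == "contiguous" and nc > 0:
        start = int(rng_order.integers(0, nb + 1))
        window = np.arange(start + 1, start + nc + 1, dtype=float)
        rest = np.concatenate(
            [np.arange(1, start + 1), np.arange(start + nc + 1, n + 1)]
        ).astype(float)
        order[:nb] = rng_order.permutation(rest)
        order[nb:] = rng_order.permutation(window)
    else:
        order[:] = rng_order.permutation(n) + 1.0

    values = np.column_stack([np.vstack([bg_values, cl_values]), order])
    schemas = list(model.schemas) + [
        FieldSchema(name=model.order_field, kind="order", categories=())
    ]
    labels = np.zeros(n, dtype=bool)
    labels[nb:] = True
    return SurveyMatrix(values, schemas), TruthLabels(is_clustered=labels)


def evaluate_detection(
    scn: SyntheticScenario, seed=0, taus: list[float] | None = None
) -> ConfusionSummary | dict[float, ConfusionSummary]:
    """Run detection on ``scn.reps`` synthetic datasets and aggregate the rates.

    A truly clustered row counts as identified when it belongs to *any*
    flagged cluster, and a dataset counts as detecting when it flags at
    least one cluster. When ``taus`` is given, each replicate's exceedance
    probabilities are re-thresholded at every tau on shared simulations, and
    a summary per tau is returned.
    """
    tau_list = [scn.tau] if taus is None else list(taus)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    records: dict[float, list[dict]] = {t: [] for t in tau_list}
    for rep, child in enumerate(ss.spawn(scn.reps)):
        gen_seed, det_seed = child.spawn(2)
        data, truth = generate_clustered_dataset(scn, gen_seed)
        result = run_detection(
            data,
            h=scn.height,
            m_sims=scn.m_sims,
            null_model=scn.null_model,
            seed=det_seed,
            tau=scn.tau,
            sd_mode=scn.sd_mode,
        )
        clustered = truth.is_clustered
        for tau in tau_list:
            flagged_ids = result.ssw_table.cluster_ids[result.exceedance > tau]
            if flagged_ids.size:
                rows = np.concatenate([result.members[int(c)] for c in flagged_ids])
            else:
                rows = np.array([], dtype=int)
            flagged_mask = np.zeros(data.n, dtype=bool)
            flagged_mask[rows] = True
            records[tau].append(
                {
                    "rep": rep,
                    "n_clustered": int(clustered.sum()),
                    "n_background": int((~clustered).sum()),
                    "detected": bool(flagged_ids.size > 0),
                    "tp": int((flagged_mask & clustered).sum()),
                    "fp": int((flagged_mask & ~clustered).sum()),
                }
            )
    out = {t: _summarize(pd.DataFrame(rows)) for t, rows in records.items()}
    return out if taus is not None else out[scn.tau]


def _summarize(df: pd.DataFrame) -> ConfusionSummary:
    detecting = df[df["detected"]]
    n_clustered = df["n_clustered"].sum()
    n_background = df["n_background"].sum()
    cond_clustered = detecting["n_clustered"].sum()
    return ConfusionSummary(
        detection_rate=float(df["detected"].mean()),
        conditional_id_rate=float(detecting["tp"].sum() / cond_clustered)
        if cond_clustered
        else float("nan"),
        sensitivity=float(df["tp"].sum() / n_clustered) if n_clustered else float("nan"),
        specificity=float(1.0 - df["fp"].sum() / n_background),
        reps=len(df),
        per_rep=df,
    )
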