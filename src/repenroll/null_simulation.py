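"""Empirical null model and simulation of independent eligible completers.

The null hypothesis is that all enrollments are independent draws from the
screener-response population. Because the analyzed cohort is restricted to
score-eligible respondents who completed the baseline questionnaire, the
null model is estimated from the *unrestricted* screener pool and the
restriction is re-imposed by simulation:

1. ordinal fields are simulated with a Gaussian copula: draw multivariate
   normal deviates with an *intermediate* correlation matrix, then cut them
   at the standard-normal quantiles of the empirical category proportions so
   the simulated ordinal codes reproduce both the marginals and the Pearson
   correlations of the observed pool (the GenOrd construction);
2. each simulated respondent is scored with the screener's item weights and
   kept only if the score meets the eligibility cutoff;
3. completion of the baseline questionnaire is drawn from a logistic model
   (fit on eligible pool respondents) and non-completers are rejected;
4. rejection sampling continues until exactly N accepted rows exist, and a
   uniformly random permutation is appended as enrollment order (enrollment
   characteristics are stable over time under independence).

The intermediate correlation for a field pair is found by monotone
root-finding: the Pearson correlation of the two discretized variables is an
increasing function of the latent Gaussian correlation, and closed-form
rectangle probabilities of the bivariate normal give the discretized
correlation exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import multivariate_normal, norm

from .survey_data import FieldSchema, SurveyMatrix, append_enrollment_order

__all__ = [
    "NullModel",
    "SimulatedCohort",
    "estimate_null_model",
    "intermediate_correlation",
    "discretized_correlation",
    "build_intermediate_matrix",
    "simulate_ordinal",
    "score",
    "rejection_sample_cohort",
    "nearest_positive_definite",
]

_RHO_LIMIT = 0.999


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class NullModel:
    """Empirical distribution of independent screener responses.

    Parameters
    ----------
    schemas : list of FieldSchema
        The simulated fields (screener items and age; not enrollment order).
    marginals : list of ndarray
        Category probabilities per field, aligned with each schema's
        ``categories``.
    target_corr : ndarray
        Pearson correlation of the fields' numeric codes in the pool.
    cutoff : float
        Minimum weighted screener score for eligibility (non-strict).
    completion_coefs : dict
        Logistic-regression coefficients for the probability of completing
        the baseline questionnaire: ``{"intercept": b0, field_name: b_k}``.
    intermediate_corr : ndarray or None
        Latent-Gaussian correlation; built lazily by
        :func:`build_intermediate_matrix`.
    """

    schemas: list[FieldSchema]
    marginals: list[np.ndarray]
    target_corr: np.ndarray
    cutoff: float
    completion_coefs: dict = dc_field(default_factory=dict)
    intermediate_corr: np.ndarray | None = None
    repair_delta: float = 0.0
    order_field: str = "order"

    def __post_init__(self):
        self.marginals = [np.asarray(p, dtype=float) for p in self.marginals]
        for sch, p in zip(self.schemas, self.marginals):
            if len(p) != len(sch.categories):
                raise ValueError(f"field {sch.name!r}: marginal length mismatch")
            if abs(p.sum() - 1.0) > 1e-8 or (p < 0).any():
                raise ValueError(f"field {sch.name!r}: marginals must sum to 1")
        self.target_corr = np.asarray(self.target_corr, dtype=float)
        k = len(self.schemas)
        if self.target_corr.shape != (k, k):
            raise ValueError("target_corr shape mismatch")
        if not np.allclose(self.target_corr, self.target_corr.T) or not np.allclose(
            np.diag(self.target_corr), 1.0
        ):
            raise ValueError("target_corr must be symmetric with unit diagonal")

    @property
    def field_names(self) -> list[str]:
        return [s.name for s in self.schemas]

    def completion_probability(self, values: np.ndarray) -> np.ndarray:
        """P(complete baseline questionnaire) for rows of simulated field values."""
        if not self.completion_coefs:
            return np.ones(values.shape[0])
        eta = np.full(values.shape[0], self.completion_coefs.get("intercept", 0.0))
        for j, name in enumerate(self.field_names):
            b = self.completion_coefs.get(name, 0.0)
            if b:
                eta = eta + b * values[:, j]
        return expit(eta)

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "fields": [
                {
                    "name": s.name,
                    "kind": s.kind,
                    "categories": list(s.categories),
                    "weights": s.weights,
                    "marginal": p.tolist(),
                }
                for s, p in zip(self.schemas, self.marginals)
            ],
            "target_corr": self.target_corr.tolist(),
            "cutoff": self.cutoff,
            "completion_coefs": self.completion_coefs,
            "intermediate_corr": None
            if self.intermediate_corr is None
            else self.intermediate_corr.tolist(),
            "order_field": self.order_field,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "NullModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        schemas, marginals = [], []
        for f in payload["fields"]:
            schemas.append(
                FieldSchema(
                    name=f["name"],
                    kind=f["kind"],
                    categories=tuple(f["categories"]),
                    weights=f["weights"],
                )
            )
            marginals.append(np.asarray(f["marginal"]))
        ic = payload.get("intermediate_corr")
        return cls(
            schemas=schemas,
            marginals=marginals,
            target_corr=np.asarray(payload["target_corr"]),
            cutoff=payload["cutoff"],
            completion_coefs=payload.get("completion_coefs", {}),
            intermediate_corr=None if ic is None else np.asarray(ic),
            order_field=payload.get("order_field", "order"),
        )


@dataclass
class SimulatedCohort:
    """Exactly N simulated eligible completers with permuted enrollment order."""

    matrix: SurveyMatrix
    acceptance_rate: float


def _score_matrix(values: np.ndarray, schemas, field_names=None) -> np.ndarray:
    """Vectorized weighted scores for an (n, k) grid of field values."""
    names = field_names or [s.name for s in schemas]
    total = np.zeros(values.shape[0])
    for j, sch in enumerate(schemas):
        if sch.weights is None:
            continue
        cats = np.asarray(sch.categories)
        w = np.asarray([sch.weights[c] for c in sch.categories])
        idx = np.searchsorted(cats, values[:, j])
        bad = (idx >= cats.size) | (cats[np.minimum(idx, cats.size - 1)] != values[:, j])
        if bad.any():
            raise ValueError(
                f"field {sch.name!r}: level(s) {np.unique(values[bad, j])} "
                "missing from weight map"
            )
        total += w[idx]
    return total


def score(row, schemas, cutoff: float) -> tuple[float, bool]:
    """Weighted screener score and eligibility of one respondent row.

    Only fields carrying a weight map contribute. Eligibility is non-strict:
    a score equal to the cutoff qualifies.
    """
    s = float(_score_matrix(np.asarray(row, dtype=float)[None, :], schemas)[0])
    return s, s >= cutoff


def estimate_null_model(
    pool: SurveyMatrix,
    completion_indicator,
    cutoff: float,
    completion_covariates: list[str] | None = None,
) -> NullModel:
    """Estimate the null model from the unrestricted screener pool.

    Marginals are observed category proportions, the target correlation is
    the Pearson correlation of the numeric codes, and the completion model
    is a logistic regression fit on the score-eligible subset.

    Parameters
    ----------
    pool : SurveyMatrix
        All screener responses before the score cutoff (order field excluded).
    completion_indicator : array-like of bool
        Whether each pool row completed the baseline questionnaire (only the
        eligible rows enter the completion fit).
    cutoff : float
        Eligibility score cutoff.
    completion_covariates : list of str, optional
        Field names entering the completion model (default: all fields,
        linear in their numeric codes). An empty list fits intercept-only.
    """
    completion = np.asarray(completion_indicator, dtype=float)
    if completion.shape[0] != pool.n:
        raise ValueError("completion indicator length mismatch")
    schemas = [s for s in pool.schemas if s.kind != "order"]
    cols = [pool.field_names.index(s.name) for s in schemas]
    values = pool.values[:, cols]

    marginals = []
    for j, sch in enumerate(schemas):
        cats = np.asarray(sch.categories)
        counts = (values[:, j][:, None] == cats[None, :]).sum(axis=0)
        if (counts > 0).sum() < 2:
            raise ValueError(
                f"field {sch.name!r} has a single observed category; "
                "it cannot be simulated"
            )
        marginals.append(counts / counts.sum())

    target_corr = np.atleast_2d(np.corrcoef(values.T))  # K = 1 degenerates to ()

    scores = _score_matrix(values, schemas)
    eligible = scores >= cutoff
    if completion_covariates is None:
        completion_covariates = [s.name for s in schemas]
    names = [s.name for s in schemas]
    xcols = [names.index(c) for c in completion_covariates]
    exog = sm.add_constant(values[eligible][:, xcols], has_constant="add")
    y = completion[eligible]
    if len(np.unique(y)) < 2:
        # degenerate completion pattern: fall back to the observed rate
        p = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
        coefs = {"intercept": float(logit(p))}
    else:
        fit = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        coefs = {"intercept": float(fit.params[0])}
        for c, b in zip(completion_covariates, fit.params[1:]):
            coefs[c] = float(b)
    return NullModel(
        schemas=schemas,
        marginals=marginals,
        target_corr=target_corr,
        cutoff=cutoff,
        completion_coefs=coefs,
    )


# -- intermediate correlation ---------------------------------------------

def _thresholds(probs: np.ndarray) -> np.ndarray:
    return norm.ppf(np.cumsum(probs)[:-1])


def _moments(codes: np.ndarray, probs: np.ndarray) -> tuple[float, float]:
    mu = float(codes @ probs)
    var = float((codes - mu) ** 2 @ probs)
    return mu, var


def discretized_correlation(
    probs_i, probs_j, rho_z: float, codes_i=None, codes_j=None
) -> float:
    """Pearson correlation of two ordinal codes after cutting a bivariate normal.

    With X = c_1 + sum_a (c_{a+1}-c_a) 1{Z1 > t_a} (and likewise Y), the
    covariance reduces to a sum of upper-orthant probabilities:

        cov(X, Y) = sum_a sum_b D_a D_b [Phi2(t_a, t_b; rho) - Phi(t_a) Phi(t_b)].
    """
    probs_i = np.asarray(probs_i, float)
    probs_j = np.asarray(probs_j, float)
    ci = np.arange(1.0, probs_i.size + 1) if codes_i is None else np.asarray(codes_i, float)
    cj = np.arange(1.0, probs_j.size + 1) if codes_j is None else np.asarray(codes_j, float)
    ti, tj = _thresholds(probs_i), _thresholds(probs_j)
    di, dj = np.diff(ci), np.diff(cj)
    if rho_z == 0.0:
        return 0.0
    grid = np.stack(np.meshgrid(ti, tj, indexing="ij"), axis=-1).reshape(-1, 2)
    phi2 = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho_z], [rho_z, 1.0]]).cdf(grid)
    phi2 = np.atleast_1d(phi2).reshape(ti.size, tj.size)
    indep = norm.cdf(ti)[:, None] * norm.cdf(tj)[None, :]
    cov = float(di @ (phi2 - indep) @ dj)
    _, vi = _moments(ci, probs_i)
    _, vj = _moments(cj, probs_j)
    return cov / np.sqrt(vi * vj)


def intermediate_correlation(
    probs_i, probs_j, rho_target: float, codes_i=None, codes_j=None, tol: float = 1e-4
) -> float:
    """Latent-Gaussian correlation whose discretization attains ``rho_target``.

    Solved by monotone root-finding (Brent) on the exact discretized
    correlation. Raises with the attainable range when the target lies
    outside the Frechet-type bounds of the discretized pair.
    """
    if not -1 < rho_target < 1:
        raise ValueError("target correlation must lie in (-1, 1)")
    if rho_target == 0.0:
        return 0.0

    def f(r):
        return discretized_correlation(probs_i, probs_j, r, codes_i, codes_j) - rho_target

    lo, hi = f(-_RHO_LIMIT), f(_RHO_LIMIT)
    if not (lo <= 0.0 <= hi):
        raise ValueError(
            f"target correlation {rho_target:.4f} unattainable for these marginals; "
            f"attainable range is [{lo + rho_target:.4f}, {hi + rho_target:.4f}]"
        )
    root = brentq(f, -_RHO_LIMIT, _RHO_LIMIT, xtol=1e-6)
    achieved = discretized_correlation(probs_i, probs_j, root, codes_i, codes_j)
    if abs(achieved - rho_target) > tol:
        raise RuntimeError("intermediate-correlation root finding failed to converge")
    return float(root)


def nearest_positive_definite(a: np.ndarray, eig_floor: float = 1e-8) -> tuple[np.ndarray, float]:
    """Clip eigenvalues at ``eig_floor`` and rescale to unit diagonal.

    Returns the repaired correlation matrix and the Frobenius norm of the
    adjustment (0.0 when the input was already positive definite).
    """
    a = np.asarray(a, float)
    w, v = np.linalg.eigh(a)
    if w.min() > eig_floor:
        return a, 0.0
    w = np.clip(w, eig_floor, None)
    b = (v * w) @ v.T
    d = np.sqrt(np.diag(b))
    b = b / np.outer(d, d)
    b = (b + b.T) / 2
    np.fill_diagonal(b, 1.0)
    return b, float(np.linalg.norm(b - a))


def build_intermediate_matrix(model: NullModel, strict: bool = False) -> NullModel:
    """Assemble the pairwise intermediate correlations for a null model.

    If the assembled matrix is not positive definite it is repaired by
    eigenvalue clipping; a repair moving any entry by more than 0.05 raises
    under ``strict`` mode.
    """
    k = len(model.schemas)
    codes = [np.asarray(s.categories) for s in model.schemas]
    inter = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            inter[i, j] = inter[j, i] = intermediate_correlation(
                model.marginals[i],
                model.marginals[j],
                float(model.target_corr[i, j]),
                codes[i],
                codes[j],
            )
    repaired, delta = nearest_positive_definite(inter)
    max_move = float(np.abs(repaired - inter).max())
    if strict and max_move > 0.05:
        raise ValueError(
            f"positive-definite repair moved an entry by {max_move:.3f} (> 0.05)"
        )
    model.intermediate_corr = repaired
    model.repair_delta = delta
    return model


def simulate_ordinal(model: NullModel, n: int, seed) -> SurveyMatrix:
    """Draw n independent respondents (no eligibility screen, no order field)."""
    values = _simulate_values(model, n, _as_rng(seed))
    return SurveyMatrix(values, list(model.schemas))


def _simulate_values(model: NullModel, n: int, rng: np.random.Generator) -> np.ndarray:
    if model.intermediate_corr is None:
        build_intermediate_matrix(model)
    chol = np.linalg.cholesky(model.intermediate_corr)
    z = rng.standard_normal((n, len(model.schemas))) @ chol.T
    return _discretize(model, z)


def _discretize(model: NullModel, z: np.ndarray) -> np.ndarray:
    values = np.empty_like(z)
    for j, (sch, probs) in enumerate(zip(model.schemas, model.marginals)):
        thr = _thresholds(probs)
        cats = np.asarray(sch.categories)
        values[:, j] = cats[np.searchsorted(thr, z[:, j])]
    return values


def rejection_sample_cohort(
    model: NullModel,
    n: int,
    seed,
    batch_size: int | None = None,
    max_batches: int = 1000,
) -> SimulatedCohort:
    """Simulate independent respondents until exactly n eligible completers exist.

    Rows survive when their weighted screener score meets the cutoff and a
    Bernoulli draw from the logistic completion model marks them as baseline
    completers. A uniformly random permutation 1..n is appended as the
    enrollment-order field.
    """
    if n < 2:
        raise ValueError("cohort size must be at least 2")
    rng = _as_rng(seed)
    batch = batch_size or max(4 * n, 1000)
    kept: list[np.ndarray] = []
    total_kept = 0
    total_drawn = 0
    for b in range(max_batches):
        values = _simulate_values(model, batch, rng)
        scores = _score_matrix(values, model.schemas)
        p = model.completion_probability(values)
        accept = (scores >= model.cutoff) & (rng.random(batch) < p)
        total_drawn += batch
        if accept.any():
            kept.append(values[accept])
            total_kept += int(accept.sum())
        if total_kept >= n:
            break
        rate = total_kept / total_drawn
        if b >= 2 and rate < 1e-4:
            raise RuntimeError(
                f"acceptance rate {rate:.2e} after {total_drawn} draws; the null "
                "model's eligibility/completion specification looks inconsistent"
            )
        batch = min(2 * batch, 10 * n + 10000)  # geometric growth on low acceptance
    else:
        raise RuntimeError(f"failed to collect {n} eligible completers in {max_batches} batches")
    values = np.concatenate(kept)[:n]
    m = SurveyMatrix(values, list(model.schemas))
    m = append_enrollment_order(m, name=model.order_field)
    perm_order = rng.permutation(n) + 1.0
    m.values[:, -1] = perm_order
    return SimulatedCohort(matrix=m, acceptance_rate=total_kept / total_drawn)
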