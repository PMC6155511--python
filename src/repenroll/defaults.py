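"""Packaged default screener emulation.

A synthetic 8-item skin-cancer risk screener plus self-reported age,
emulating the structure of a weighted Likert-type eligibility instrument:
each item's levels carry risk points, the per-item maxima sum to 89, and
respondents are eligible at a total score of 27 or more. Ages span 18-25.
The item weights, marginal proportions, inter-item correlations and the
baseline-questionnaire completion model below are this package's own
synthetic population — they mimic the shape of a real screener pool
(moderate positive correlation among sun-sensitivity items, weaker links to
family history and mole count, age essentially independent) but are not
estimates from any study dataset.
"""

from __future__ import annotations

import numpy as np

from .null_simulation import NullModel, build_intermediate_matrix
from .survey_data import FieldSchema

__all__ = [
    "DEFAULT_CUTOFF",
    "default_schemas",
    "default_marginals",
    "default_target_corr",
    "default_null_model",
]

DEFAULT_CUTOFF = 27.0

# item name -> (level weights for codes 1..4, marginal proportions)
_ITEMS = {
    "sunburn_tendency": ([0, 5, 10, 14], [0.22, 0.34, 0.28, 0.16]),
    "tan_ability":      ([0, 4, 9, 12],  [0.25, 0.35, 0.25, 0.15]),
    "hair_color":       ([0, 4, 8, 12],  [0.30, 0.30, 0.25, 0.15]),
    "eye_color":        ([0, 3, 7, 11],  [0.28, 0.32, 0.24, 0.16]),
    "freckles":         ([0, 4, 8, 11],  [0.26, 0.34, 0.25, 0.15]),
    "past_sunburns":    ([0, 3, 7, 10],  [0.24, 0.36, 0.26, 0.14]),
    "family_history":   ([0, 3, 6, 10],  [0.40, 0.30, 0.20, 0.10]),
    "mole_count":       ([0, 3, 6, 9],   [0.30, 0.35, 0.22, 0.13]),
}
# per-item maxima: 14+12+12+11+11+10+10+9 = 89

_AGES = tuple(range(18, 26))
_AGE_MARGINAL = [0.16, 0.15, 0.14, 0.13, 0.12, 0.11, 0.10, 0.09]

# first six items form a sun-sensitivity block; family history and mole
# count are more weakly related; age is nearly independent of everything.
_R_BLOCK = 0.28
_R_WEAK = 0.15
_R_AGE = 0.02

_COMPLETION_INTERCEPT = -1.0
_COMPLETION_AGE = 0.04
_COMPLETION_ITEM = 0.03


def default_schemas() -> list[FieldSchema]:
    """Schemas of the simulated fields (8 weighted items + age)."""
    out = [
        FieldSchema(
            name=name,
            kind="ordinal",
            categories=(1, 2, 3, 4),
            weights={c: w for c, w in zip((1, 2, 3, 4), weights)},
        )
        for name, (weights, _) in _ITEMS.items()
    ]
    out.append(FieldSchema(name="age", kind="integer", categories=_AGES))
    return out


def default_marginals() -> list[np.ndarray]:
    out = [np.asarray(m, dtype=float) for _, (_, m) in _ITEMS.items()]
    out.append(np.asarray(_AGE_MARGINAL))
    return out


def default_target_corr() -> np.ndarray:
    k = len(_ITEMS) + 1
    r = np.full((k, k), _R_WEAK)
    r[:6, :6] = _R_BLOCK
    r[-1, :] = r[:, -1] = _R_AGE
    np.fill_diagonal(r, 1.0)
    return r


def default_completion_coefs() -> dict:
    coefs = {"intercept": _COMPLETION_INTERCEPT, "age": _COMPLETION_AGE}
    for name in _ITEMS:
        coefs[name] = _COMPLETION_ITEM
    return coefs


def default_null_model(build: bool = True) -> NullModel:
    """The packaged synthetic screener population as a ready-to-use null model."""
    model = NullModel(
        schemas=default_schemas(),
        marginals=default_marginals(),
        target_corr=default_target_corr(),
        cutoff=DEFAULT_CUTOFF,
        completion_coefs=default_completion_coefs(),
    )
    if build:
        build_intermediate_matrix(model)
    return model
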