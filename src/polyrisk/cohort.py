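"""Synthetic cohort generation from a factor-table's prevalences.

Stands in for self-administered questionnaires or record-extracted inputs:
individuals draw one level per factor independently with the configured
prevalences, and assignments can be masked missing at a fixed rate to
exercise the partial-profile scoring policies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .factors import FactorTable
from .scoring import IndividualProfile

__all__ = ["CohortSpec", "generate_cohort"]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort draw.

    ``overrides`` optionally forces a prevalence vector for named factors
    (level-order vectors summing to one), e.g. to emulate an enriched
    referral stream instead of the general population.
    """

    n_individuals: int
    seed: int
    missingness_rate: float = 0.0
    overrides: Mapping[str, Sequence[float]] | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValidationError(
                f"n_individuals must be >= 1, got {self.n_individuals}"
            )
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ValidationError(
                f"missingness_rate must be in [0, 1), got {self.missingness_rate}"
            )


def generate_cohort(table: FactorTable, spec: CohortSpec) -> list[IndividualProfile]:
    """Draw ``spec.n_individuals`` profiles from the table's prevalences.

    Levels are drawn independently per factor, in declared factor order,
    from one generator seeded with ``spec.seed``; each assignment is then
    independently masked missing with probability ``spec.missingness_rate``.
    Reproducible bit for bit for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    overrides = dict(spec.overrides or {})
    unknown = set(overrides) - set(table.names)
    if unknown:
        raise ValidationError(f"overrides name unknown factor(s) {sorted(unknown)}")

    columns: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    for f in table:
        if f.name in overrides:
            probs = np.asarray(overrides[f.name], dtype=float)
            if len(probs) != len(f.levels):
                raise ValidationError(
                    f"override for {f.name!r} has {len(probs)} entries, "
                    f"factor has {len(f.levels)} levels"
                )
            if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-6:
                raise ValidationError(
                    f"override for {f.name!r} is not a probability vector "
                    f"(sum {probs.sum():.6g})"
                )
        else:
            probs = np.array([lv.prevalence for lv in f.levels])
        cum = np.cumsum(probs)
        cum[-1] = 1.0
        columns[f.name] = np.searchsorted(cum, rng.random(n), side="right")
        masks[f.name] = (
            rng.random(n) < spec.missingness_rate
            if spec.missingness_rate > 0
            else np.zeros(n, dtype=bool)
        )

    width = len(str(n - 1))
    profiles = []
    labels = {f.name: f.labels for f in table}
    for i in range(n):
        assignments = {
            name: labels[name][columns[name][i]]
            for name in table.names
            if not masks[name][i]
        }
        profiles.append(
            IndividualProfile(id=f"ind-{i:0{width}d}", assignments=assignments)
        )
    return profiles
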