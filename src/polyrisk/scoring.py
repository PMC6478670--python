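"""Score individual factor profiles and convert totals to equivalent RRs.

An individual's total score is the sum of the final scores of the levels
they hold, one per factor.  Because scores are 10·log10(RR) shifted to a
zero population mean, a total S is interpretable as an equivalent relative
risk 10^(S/10) against the population average: S = 0 means average risk
(RR 1), S = 5 roughly triples it, S = 10 is a ten-fold relative risk.

Partial profiles are supported by design — self-reported factors can be
scored first and clinical factors added later — with a configurable policy
for the factors not yet observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd

from .construction import ScoringTable
from .errors import DomainError, ValidationError

__all__ = [
    "IndividualProfile",
    "ScoreResult",
    "MissingPolicy",
    "score_individual",
    "score_cohort",
    "pps_to_rr",
    "rr_to_pps",
    "read_profiles",
    "write_profiles",
    "results_to_frame",
]

MissingPolicy = Literal["population_average", "error", "omit"]


@dataclass(frozen=True)
class IndividualProfile:
    """A person's observed factor levels; factors may be missing.

    ``assignments`` maps factor name → level label, at most one level per
    factor (guaranteed by the mapping type).
    """

    id: str
    assignments: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignments", dict(self.assignments))


@dataclass(frozen=True)
class ScoreResult:
    """Total score with per-factor contributions.

    ``total_pps`` is the sum of the per-factor contributions; missing
    factors contribute their population-average final score, zero, or raise,
    depending on the policy used.  ``equivalent_rr`` is 10^(total/scale).
    """

    id: str
    total_pps: float
    per_factor: dict[str, float]
    n_missing: int
    equivalent_rr: float


def pps_to_rr(total_pps: float, scale: float = 10.0) -> float:
    """Equivalent relative risk of a total score: 10^(total/scale)."""
    return 10.0 ** (total_pps / scale)


def rr_to_pps(rr: float, scale: float = 10.0) -> float:
    """Total score equivalent to a relative risk: scale·log10(rr)."""
    if not rr > 0:
        raise DomainError(f"relative risk must be > 0, got {rr}")
    import math

    return scale * math.log10(rr)


def score_individual(
    table: ScoringTable,
    profile: IndividualProfile | Mapping[str, str],
    missing_policy: MissingPolicy = "population_average",
) -> ScoreResult:
    """Score one profile against a scoring table.

    Missing factors are handled per ``missing_policy``:

    - ``population_average`` (default): substitute the factor's
      prevalence-weighted mean final score — the zero-information value
      under the centering construction (near zero, up to rounding);
    - ``omit``: contribute 0;
    - ``error``: raise :class:`ValidationError`.

    ``n_missing`` counts the unassigned factors under any policy.
    """
    if not isinstance(profile, IndividualProfile):
        profile = IndividualProfile(id="", assignments=profile)
    if missing_policy not in ("population_average", "error", "omit"):
        raise ValidationError(f"unknown missing_policy {missing_policy!r}")
    known = set(table.names)
    unknown = set(profile.assignments) - known
    if unknown:
        raise ValidationError(
            f"profile {profile.id!r}: unknown factor(s) {sorted(unknown)}"
        )
    per_factor: dict[str, float] = {}
    n_missing = 0
    for f in table:
        label = profile.assignments.get(f.name)
        if label is None:
            n_missing += 1
            if missing_policy == "error":
                raise ValidationError(
                    f"profile {profile.id!r}: factor {f.name!r} missing "
                    f"under missing_policy='error'"
                )
            contribution = (
                f.population_mean_final
                if missing_policy == "population_average"
                else 0.0
            )
        else:
            try:
                contribution = f.level(label).final_score
            except KeyError:
                raise ValidationError(
                    f"profile {profile.id!r}: unknown level {label!r} for "
                    f"factor {f.name!r} (known: {list(f.labels)})"
                ) from None
        per_factor[f.name] = contribution
    total = sum(per_factor.values())
    return ScoreResult(
        id=profile.id,
        total_pps=total,
        per_factor=per_factor,
        n_missing=n_missing,
        equivalent_rr=pps_to_rr(total, table.scale),
    )


def score_cohort(
    table: ScoringTable,
    profiles: Iterable[IndividualProfile],
    missing_policy: MissingPolicy = "population_average",
) -> list[ScoreResult]:
    """Score an iterable of profiles; see :func:`score_individual`."""
    return [score_individual(table, p, missing_policy) for p in profiles]


# ---------------------------------------------------------------------------
# profile / result I/O
# ---------------------------------------------------------------------------


def read_profiles(path: str | Path) -> list[IndividualProfile]:
    """Read profiles from CSV (one row per individual, one column per
    factor, empty cell = missing) or JSON records with the same shape.

    An optional ``id`` column names individuals; otherwise row order is used.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        import json

        records = json.loads(path.read_text(encoding="utf-8"))
        return [
            IndividualProfile(
                id=str(rec.get("id", i)),
                assignments={
                    k: v for k, v in rec.items() if k != "id" and v is not None
                },
            )
            for i, rec in enumerate(records)
        ]
    frame = pd.read_csv(path, dtype=str)
    if frame.empty:
        raise ValidationError(f"{path}: profile file contains no individuals")
    ids = (
        frame["id"].astype(str).tolist()
        if "id" in frame.columns
        else [str(i) for i in range(len(frame))]
    )
    factor_cols = [c for c in frame.columns if c != "id"]
    profiles = []
    for ident, (_, row) in zip(ids, frame.iterrows()):
        assignments = {
            c: row[c] for c in factor_cols if isinstance(row[c], str) and row[c] != ""
        }
        profiles.append(IndividualProfile(id=ident, assignments=assignments))
    return profiles


def write_profiles(
    profiles: Iterable[IndividualProfile],
    path: str | Path,
    factor_order: Iterable[str] | None = None,
) -> None:
    """Write profiles as CSV with one column per factor, empty = missing."""
    profiles = list(profiles)
    if factor_order is None:
        seen: dict[str, None] = {}
        for p in profiles:
            for f in p.assignments:
                seen.setdefault(f)
        factor_order = list(seen)
    rows = [
        {"id": p.id, **{f: p.assignments.get(f, "") for f in factor_order}}
        for p in profiles
    ]
    pd.DataFrame(rows, columns=["id", *factor_order]).to_csv(path, index=False)


def results_to_frame(
    results: Iterable[ScoreResult], per_factor: bool = False
) -> pd.DataFrame:
    """Tabulate score results; optionally one column per factor contribution."""
    rows = []
    for r in results:
        row = {
            "id": r.id,
            "total_pps": r.total_pps,
            "equivalent_rr": r.equivalent_rr,
            "n_missing": r.n_missing,
        }
        if per_factor:
            row.update({f"score[{k}]": v for k, v in r.per_factor.items()})
        rows.append(row)
    return pd.DataFrame(rows)
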