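"""Build the half-integer scoring system from relative risks and prevalences.

The construction, per factor:

1. raw score  r = log10(RR) for each level (reference levels have RR 1, r 0);
2. centered score  c = r − m, where m = Σ p·r is the prevalence-weighted
   population mean of the raw scores, so the population mean of c is zero
   and exposed individuals get positive scores;
3. final score  s = round(scale·c) to the nearest multiple of the grid
   (default scale 10, grid 0.5), ties rounded away from zero.

The worked reference case: urban residence with RR 2.2 and prevalence 73.6%
gives r = log10(2.2) = 0.342, m = 0.736×0.342 = 0.252, and final scores
+1 (urban) and −2.5 (rural).

``invert_published_scores`` goes the other way: from a published pair of
final scores it recovers the implied RR and the interval of prevalences
consistent with both scores under the ±grid/2 rounding slack.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ConfigParseError, DomainError, ValidationError
from .factors import PREVALENCE_TOL, FactorTable

__all__ = [
    "ScoredLevel",
    "ScoredFactor",
    "ScoringTable",
    "raw_score",
    "population_mean_raw",
    "round_to_half",
    "round_to_grid",
    "build_scoring_table",
    "invert_published_scores",
    "load_scoring_table",
    "save_scoring_table",
]

DEFAULT_SCALE = 10.0
DEFAULT_GRID = 0.5


def raw_score(relative_risk: float) -> float:
    """Raw score of a level: the base-10 logarithm of its relative risk."""
    if not relative_risk > 0:
        raise DomainError(f"relative_risk must be > 0, got {relative_risk}")
    return math.log10(relative_risk)


def population_mean_raw(levels: Iterable[tuple[float, float]]) -> float:
    """Prevalence-weighted mean Σ pᵢ·rᵢ of raw scores.

    ``levels`` is an iterable of ``(raw_score, prevalence)`` pairs whose
    prevalences must sum to one.
    """
    pairs = list(levels)
    total_p = sum(p for _, p in pairs)
    if abs(total_p - 1.0) > PREVALENCE_TOL:
        raise ValidationError(f"prevalences sum to {total_p:.6g}, not 1")
    return sum(r * p for r, p in pairs)


def round_to_grid(x: float, grid: float = DEFAULT_GRID) -> float:
    """Round to the nearest multiple of ``grid``; ties go away from zero.

    Tie detection is at float precision: an argument that lands exactly
    midway between grid points (e.g. 0.25 on the default 0.5 grid) rounds
    away from zero, so 0.25 → 0.5 and −0.25 → −0.5.
    """
    if not math.isfinite(x):
        raise DomainError(f"cannot round non-finite value {x}")
    if not grid > 0:
        raise DomainError(f"grid must be > 0, got {grid}")
    return math.copysign(math.floor(abs(x) / grid + 0.5) * grid, x)


def round_to_half(x: float) -> float:
    """Round to the nearest half integer, ties away from zero."""
    return round_to_grid(x, 0.5)


@dataclass(frozen=True)
class ScoredLevel:
    """A factor level with its raw, centered, and final scores.

    ``final_score`` lies on the half-integer grid and differs from
    ``scale × centered_score`` by at most half the grid spacing.
    """

    label: str
    relative_risk: float
    prevalence: float
    raw_score: float
    centered_score: float
    final_score: float


@dataclass(frozen=True)
class ScoredFactor:
    name: str
    levels: tuple[ScoredLevel, ...]
    baseline_label: str

    def level(self, label: str) -> ScoredLevel:
        for lv in self.levels:
            if lv.label == label:
                return lv
        raise KeyError(f"factor {self.name!r} has no level {label!r}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lv.label for lv in self.levels)

    @property
    def min_final(self) -> float:
        return min(lv.final_score for lv in self.levels)

    @property
    def max_final(self) -> float:
        return max(lv.final_score for lv in self.levels)

    @property
    def population_mean_final(self) -> float:
        """Prevalence-weighted mean of the final (rounded) scores.

        Zero only up to rounding error; the unrounded centered scores
        average to exactly zero by construction.
        """
        return sum(lv.prevalence * lv.final_score for lv in self.levels)


@dataclass(frozen=True)
class ScoringTable:
    """Per-factor scored levels plus the construction parameters."""

    factors: tuple[ScoredFactor, ...]
    scale: float = DEFAULT_SCALE
    grid: float = DEFAULT_GRID
    provenance: str = ""

    def __iter__(self):
        return iter(self.factors)

    def __len__(self) -> int:
        return len(self.factors)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def factor(self, name: str) -> ScoredFactor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(f"no factor named {name!r}")

    @property
    def min_total(self) -> float:
        """Sum of per-factor minimum final scores (least-risk profile)."""
        return sum(f.min_final for f in self.factors)

    @property
    def max_total(self) -> float:
        """Sum of per-factor maximum final scores (greatest-risk profile)."""
        return sum(f.max_final for f in self.factors)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.factors:
            for lv in f.levels:
                rows.append(
                    {
                        "factor": f.name,
                        "level": lv.label,
                        "relative_risk": lv.relative_risk,
                        "prevalence": lv.prevalence,
                        "baseline": lv.label == f.baseline_label,
                        "raw_score": lv.raw_score,
                        "centered_score": lv.centered_score,
                        "final_score": lv.final_score,
                    }
                )
        return pd.DataFrame(rows)

    def format_table(self) -> str:
        """Pretty print mirroring the published scoring-table layout."""
        fw = max(12, *(len(f.name) for f in self.factors)) + 2
        lw = max(12, *(len(lv.label) for f in self.factors for lv in f.levels)) + 2
        lines = [f"{'Factor':<{fw}}{'Level':<{lw}}{'Score':>6}"]
        lines.append("-" * (fw + lw + 6))
        for f in self.factors:
            first = True
            for lv in f.levels:
                score = (
                    f"{lv.final_score:g}"
                    if lv.final_score % 1
                    else f"{int(lv.final_score)}"
                )
                lines.append(
                    f"{f.name if first else '':<{fw}}{lv.label:<{lw}}{score:>6}"
                )
                first = False
        lines.append("-" * (fw + lw + 6))
        lines.append(
            f"{'Total range':<{fw}}{'':<{lw}}"
            f"{self.min_total:g} to {self.max_total:g}"
        )
        return "\n".join(lines)


def build_scoring_table(
    table: FactorTable,
    scale: float = DEFAULT_SCALE,
    grid: float = DEFAULT_GRID,
) -> ScoringTable:
    """Construct the scoring system from a validated :class:`FactorTable`.

    For each level: raw = log10(RR); centered = raw − Σ p·raw over the
    factor's levels; final = round(scale × centered) to the nearest grid
    multiple.  The prevalence-weighted mean of the centered scores is zero
    for every factor by construction.
    """
    scored = []
    for f in table:
        raws = [raw_score(lv.relative_risk) for lv in f.levels]
        mean = population_mean_raw(
            (r, lv.prevalence) for r, lv in zip(raws, f.levels)
        )
        levels = tuple(
            ScoredLevel(
                label=lv.label,
                relative_risk=lv.relative_risk,
                prevalence=lv.prevalence,
                raw_score=r,
                centered_score=r - mean,
                final_score=round_to_grid(scale * (r - mean), grid),
            )
            for r, lv in zip(raws, f.levels)
        )
        scored.append(
            ScoredFactor(name=f.name, levels=levels, baseline_label=f.baseline_label)
        )
    return ScoringTable(
        factors=tuple(scored), scale=scale, grid=grid, provenance=table.provenance
    )


def invert_published_scores(
    score_present: float,
    score_absent: float,
    scale: float = DEFAULT_SCALE,
    grid: float = DEFAULT_GRID,
) -> tuple[float, tuple[float, float]]:
    """Recover the implied RR and prevalence interval from two final scores.

    For a two-level factor with published scores for the exposed
    (``score_present``) and unexposed (``score_absent``) levels, the implied
    relative risk is ``10^((score_present − score_absent)/scale)``, and the
    returned interval contains every prevalence for which the forward
    construction reproduces both published scores under the ±grid/2
    rounding slack (clamped to [0, 1]).
    """
    if not score_present > score_absent:
        raise DomainError(
            f"score_present ({score_present}) must exceed score_absent "
            f"({score_absent})"
        )
    log_rr = (score_present - score_absent) / scale
    implied_rr = 10.0**log_rr
    half = grid / 2.0
    # unexposed level: round(-scale·p·log_rr) = score_absent  ⇒
    # scale·p·log_rr ∈ [-score_absent − half, -score_absent + half]
    lo = (-score_absent - half) / (scale * log_rr)
    hi = (-score_absent + half) / (scale * log_rr)
    return implied_rr, (max(0.0, lo), min(1.0, hi))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_scoring_table(
    table: ScoringTable, path: str | Path, format: str | None = None
) -> None:
    """Write a scoring table as CSV, JSON, or the pretty ``table2`` format."""
    path = Path(path)
    fmt = format or path.suffix.lower().lstrip(".") or "csv"
    if fmt == "csv":
        table.to_frame().to_csv(path, index=False)
    elif fmt == "json":
        data = {
            "scale": table.scale,
            "grid": table.grid,
            "provenance": table.provenance,
            "factors": [
                {
                    "name": f.name,
                    "baseline": f.baseline_label,
                    "levels": [
                        {
                            "label": lv.label,
                            "relative_risk": lv.relative_risk,
                            "prevalence": lv.prevalence,
                            "raw_score": lv.raw_score,
                            "centered_score": lv.centered_score,
                            "final_score": lv.final_score,
                        }
                        for lv in f.levels
                    ],
                }
                for f in table
            ],
        }
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    elif fmt in ("table2", "txt"):
        path.write_text(table.format_table() + "\n", encoding="utf-8")
    else:
        raise ConfigParseError(
            f"unknown scoring-table format {fmt!r}; expected csv, json, or table2"
        )


def load_scoring_table(path: str | Path, format: str | None = None) -> ScoringTable:
    """Read a scoring table previously written by :func:`save_scoring_table`."""
    path = Path(path)
    fmt = format or path.suffix.lower().lstrip(".")
    if not path.exists():
        raise ConfigParseError(f"{path}: file not found")
    if fmt == "json":
        data = json.loads(path.read_text(encoding="utf-8"))
        factors = tuple(
            ScoredFactor(
                name=fd["name"],
                baseline_label=fd["baseline"],
                levels=tuple(
                    ScoredLevel(
                        label=ld["label"],
                        relative_risk=float(ld["relative_risk"]),
                        prevalence=float(ld["prevalence"]),
                        raw_score=float(ld["raw_score"]),
                        centered_score=float(ld["centered_score"]),
                        final_score=float(ld["final_score"]),
                    )
                    for ld in fd["levels"]
                ),
            )
            for fd in data["factors"]
        )
        return ScoringTable(
            factors=factors,
            scale=float(data.get("scale", DEFAULT_SCALE)),
            grid=float(data.get("grid", DEFAULT_GRID)),
            provenance=data.get("provenance", ""),
        )
    if fmt == "csv":
        frame = pd.read_csv(path, dtype={"factor": str, "level": str})
        needed = [
            "factor",
            "level",
            "relative_risk",
            "prevalence",
            "baseline",
            "raw_score",
            "centered_score",
            "final_score",
        ]
        missing = [c for c in needed if c not in frame.columns]
        if missing:
            raise ConfigParseError(f"{path}: missing required columns {missing}")
        factors = []
        for name in frame["factor"].drop_duplicates():
            sub = frame[frame["factor"] == name]
            levels = tuple(
                ScoredLevel(
                    label=str(row["level"]),
                    relative_risk=float(row["relative_risk"]),
                    prevalence=float(row["prevalence"]),
                    raw_score=float(row["raw_score"]),
                    centered_score=float(row["centered_score"]),
                    final_score=float(row["final_score"]),
                )
                for _, row in sub.iterrows()
            )
            base = sub[sub["baseline"].astype(bool)]
            if len(base) != 1:
                raise ValidationError(
                    f"factor {name!r}: expected exactly one baseline row"
                )
            factors.append(
                ScoredFactor(
                    name=str(name),
                    levels=levels,
                    baseline_label=str(base.iloc[0]["level"]),
                )
            )
        return ScoringTable(factors=tuple(factors))
    raise ConfigParseError(f"unknown scoring-table format {fmt!r}")
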