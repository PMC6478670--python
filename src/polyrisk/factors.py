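"""Risk-factor configuration: levels, factors, tables, and composite factors.

A polyrisk score is built from a table of risk factors.  Each factor has a
small set of mutually exclusive levels (e.g. urban / rural residence); each
level carries a relative risk (odds ratios from umbrella-review evidence are
used in this role) and a population prevalence.  Prevalences across a
factor's levels sum to one, so an individual holds exactly one level per
factor.

Logically dependent exposures (e.g. immigrant generation and region of
origin) are merged into a single composite factor whose levels are the
admissible label combinations; on the log scale the composite relative risk
is the sum of its component log-RRs.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import ConfigParseError, ValidationError

__all__ = [
    "FactorLevel",
    "RiskFactor",
    "FactorTable",
    "load_factor_table",
    "save_factor_table",
    "build_composite_factor",
    "validate_profile_support",
]

EVIDENCE_CLASSES = ("I", "II", "III", "IV", "ns")

#: absolute tolerance for prevalences summing to one within a factor
PREVALENCE_TOL = 1e-6
#: absolute tolerance for a composite RR matching the product of its components
COMPONENT_RR_TOL = 1e-9


@dataclass(frozen=True)
class FactorLevel:
    """One level of a risk factor.

    Parameters
    ----------
    label
        Level name, unique within its factor.
    relative_risk
        Relative risk of the outcome at this level versus the factor's
        reference; dimensionless and strictly positive.
    prevalence
        Population proportion holding this level, in [0, 1].
    components
        For composite levels, the ``(component_name, component_rr)`` pairs
        whose product equals ``relative_risk``; ``None`` for simple levels.
    """

    label: str
    relative_risk: float
    prevalence: float
    components: tuple[tuple[str, float], ...] | None = None

    def __post_init__(self) -> None:
        if not self.relative_risk > 0:
            raise ValidationError(
                f"level {self.label!r}: relative_risk must be > 0, "
                f"got {self.relative_risk}"
            )
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValidationError(
                f"level {self.label!r}: prevalence must be in [0, 1], "
                f"got {self.prevalence}"
            )
        if self.components is not None:
            object.__setattr__(
                self, "components", tuple((str(n), float(r)) for n, r in self.components)
            )
            prod = math.prod(r for _, r in self.components)
            if abs(prod - self.relative_risk) > COMPONENT_RR_TOL:
                raise ValidationError(
                    f"level {self.label!r}: relative_risk {self.relative_risk} "
                    f"does not equal the product of component RRs ({prod})"
                )


@dataclass(frozen=True)
class RiskFactor:
    """A risk factor with mutually exclusive levels.

    Exactly one level is the baseline (unexposed / reference) level.  The
    ``evidence_class``, ``instrument`` and ``cutoff`` fields are descriptive
    metadata (strength of umbrella-review evidence, measurement tool, and
    operational cut-off); no logic is keyed on them.
    """

    name: str
    levels: tuple[FactorLevel, ...]
    baseline_label: str
    evidence_class: str = "ns"
    instrument: str = ""
    cutoff: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(self.levels))
        labels = [lv.label for lv in self.levels]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"factor {self.name!r}: duplicate level labels")
        total = sum(lv.prevalence for lv in self.levels)
        if abs(total - 1.0) > PREVALENCE_TOL:
            raise ValidationError(
                f"factor {self.name!r}: level prevalences sum to {total:.6g}, not 1"
            )
        if self.baseline_label not in labels:
            raise ValidationError(
                f"factor {self.name!r}: baseline level {self.baseline_label!r} "
                f"is not among levels {labels}"
            )
        if self.evidence_class not in EVIDENCE_CLASSES:
            raise ValidationError(
                f"factor {self.name!r}: evidence_class must be one of "
                f"{EVIDENCE_CLASSES}, got {self.evidence_class!r}"
            )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lv.label for lv in self.levels)

    @property
    def baseline(self) -> FactorLevel:
        return self.level(self.baseline_label)

    def level(self, label: str) -> FactorLevel:
        for lv in self.levels:
            if lv.label == label:
                return lv
        raise KeyError(f"factor {self.name!r} has no level {label!r}")


@dataclass(frozen=True)
class FactorTable:
    """An ordered collection of risk factors plus a provenance tag."""

    factors: tuple[RiskFactor, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValidationError("factor names must be unique")

    def __iter__(self) -> Iterator[RiskFactor]:
        return iter(self.factors)

    def __len__(self) -> int:
        return len(self.factors)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def factor(self, name: str) -> RiskFactor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(f"no factor named {name!r}")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_CSV_REQUIRED = ["factor", "level", "relative_risk", "prevalence", "baseline"]
_CSV_OPTIONAL = ["evidence_class", "instrument", "cutoff", "components"]


def _encode_components(components: tuple[tuple[str, float], ...] | None) -> str:
    if not components:
        return ""
    return "|".join(f"{name}={rr!r}" for name, rr in components)


def _decode_components(text: str) -> tuple[tuple[str, float], ...] | None:
    if not text or (isinstance(text, float) and math.isnan(text)):
        return None
    pairs = []
    for chunk in str(text).split("|"):
        name, _, rr = chunk.rpartition("=")
        pairs.append((name, float(rr)))
    return tuple(pairs)


def table_to_frame(table: FactorTable) -> pd.DataFrame:
    """Flatten a :class:`FactorTable` to one row per level."""
    rows = []
    for f in table:
        for lv in f.levels:
            rows.append(
                {
                    "factor": f.name,
                    "level": lv.label,
                    "relative_risk": lv.relative_risk,
                    "prevalence": lv.prevalence,
                    "baseline": lv.label == f.baseline_label,
                    "evidence_class": f.evidence_class,
                    "instrument": f.instrument,
                    "cutoff": f.cutoff,
                    "components": _encode_components(lv.components),
                }
            )
    return pd.DataFrame(rows)


def _table_to_dict(table: FactorTable) -> dict:
    return {
        "provenance": table.provenance,
        "factors": [
            {
                "name": f.name,
                "baseline": f.baseline_label,
                "evidence_class": f.evidence_class,
                "instrument": f.instrument,
                "cutoff": f.cutoff,
                "levels": [
                    {
                        "label": lv.label,
                        "relative_risk": lv.relative_risk,
                        "prevalence": lv.prevalence,
                        **(
                            {"components": [[n, r] for n, r in lv.components]}
                            if lv.components
                            else {}
                        ),
                    }
                    for lv in f.levels
                ],
            }
            for f in table
        ],
    }


def _table_from_dict(data: dict, source: str = "<dict>") -> FactorTable:
    try:
        factors = []
        for fd in data["factors"]:
            levels = tuple(
                FactorLevel(
                    label=ld["label"],
                    relative_risk=float(ld["relative_risk"]),
                    prevalence=float(ld["prevalence"]),
                    components=(
                        tuple((n, float(r)) for n, r in ld["components"])
                        if ld.get("components")
                        else None
                    ),
                )
                for ld in fd["levels"]
            )
            factors.append(
                RiskFactor(
                    name=fd["name"],
                    levels=levels,
                    baseline_label=fd["baseline"],
                    evidence_class=fd.get("evidence_class", "ns"),
                    instrument=fd.get("instrument", ""),
                    cutoff=fd.get("cutoff", ""),
                )
            )
    except KeyError as exc:
        raise ConfigParseError(f"{source}: missing required key {exc}") from exc
    return FactorTable(factors=tuple(factors), provenance=data.get("provenance", ""))


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise ConfigParseError(
        f"{path}: cannot infer format from suffix {path.suffix!r}; pass format="
    )


def load_factor_table(path: str | Path, format: str | None = None) -> FactorTable:
    """Load and validate a :class:`FactorTable` from CSV or JSON.

    CSV files have one row per level with columns
    ``factor,level,relative_risk,prevalence,baseline`` (plus optional
    ``evidence_class,instrument,cutoff,components``).  JSON uses a nested
    factors→levels schema.  All type invariants are enforced on load.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise ConfigParseError(f"{path}: file not found")
    if fmt == "json":
        try:
            data = json.loads(path.read_text(encoding="utf-8"))
        except json.JSONDecodeError as exc:
            raise ConfigParseError(f"{path}: invalid JSON ({exc})") from exc
        return _table_from_dict(data, source=str(path))
    if fmt == "csv":
        try:
            frame = pd.read_csv(path, dtype={"factor": str, "level": str})
        except Exception as exc:  # pandas raises a zoo of parse errors
            raise ConfigParseError(f"{path}: cannot parse CSV ({exc})") from exc
        missing = [c for c in _CSV_REQUIRED if c not in frame.columns]
        if missing:
            raise ConfigParseError(f"{path}: missing required columns {missing}")
        factors = []
        for name in frame["factor"].drop_duplicates():
            sub = frame[frame["factor"] == name]
            levels = []
            baseline = None
            for idx, row in sub.iterrows():
                try:
                    levels.append(
                        FactorLevel(
                            label=str(row["level"]),
                            relative_risk=float(row["relative_risk"]),
                            prevalence=float(row["prevalence"]),
                            components=_decode_components(row.get("components", "")),
                        )
                    )
                except (TypeError, ValueError) as exc:
                    raise ConfigParseError(
                        f"{path}: row {idx + 2}: {exc}"
                    ) from exc
                if bool(row["baseline"]):
                    baseline = str(row["level"])
            if baseline is None:
                raise ValidationError(
                    f"factor {name!r}: no level marked baseline"
                )
            first = sub.iloc[0]
            factors.append(
                RiskFactor(
                    name=str(name),
                    levels=tuple(levels),
                    baseline_label=baseline,
                    evidence_class=str(first.get("evidence_class", "ns")),
                    instrument=_nan_to_empty(first.get("instrument", "")),
                    cutoff=_nan_to_empty(first.get("cutoff", "")),
                )
            )
        return FactorTable(factors=tuple(factors), provenance=f"loaded from {path.name}")
    raise ConfigParseError(f"unknown format {fmt!r}; expected 'csv' or 'json'")


def _nan_to_empty(value: object) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return str(value)


def save_factor_table(
    table: FactorTable, path: str | Path, format: str | None = None
) -> None:
    """Write a :class:`FactorTable` to CSV or JSON (lossless round trip)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        path.write_text(
            json.dumps(_table_to_dict(table), indent=2) + "\n", encoding="utf-8"
        )
    elif fmt == "csv":
        table_to_frame(table).to_csv(path, index=False)
    else:
        raise ConfigParseError(f"unknown format {fmt!r}; expected 'csv' or 'json'")


# ---------------------------------------------------------------------------
# composite factors
# ---------------------------------------------------------------------------


def build_composite_factor(
    name: str,
    component_factors: Sequence[RiskFactor],
    joint_prevalences: Mapping[tuple[str, ...] | str, float],
    *,
    collapse: Iterable[str] = (),
    baseline_label: str | None = None,
    labels: Mapping[tuple[str, ...], str] | None = None,
    separator: str = ", ",
    evidence_class: str = "ns",
    instrument: str = "",
    cutoff: str = "",
) -> RiskFactor:
    """Merge logically dependent factors into one composite factor.

    The admissible levels are the cross product of the component levels,
    except that any component level named in ``collapse`` absorbs the whole
    combination: e.g. a "not immigrant" level makes the region-of-origin
    component meaningless, so it stands alone as a single composite level.
    Each admissible combination gets ``relative_risk`` equal to the product
    of its component RRs (the equal-extra-risk assumption: on the log scale
    the component effects add) and the supplied joint prevalence.

    Parameters
    ----------
    joint_prevalences
        Maps each admissible label combination (tuple of component labels in
        component order; a bare string is accepted for collapsed singletons)
        to its population prevalence.  Prevalences must cover exactly the
        admissible combinations and sum to one.
    collapse
        Component level labels that absorb their combination.
    labels
        Optional display labels for combinations; defaults to joining the
        component labels with ``separator``.
    """
    if not component_factors:
        raise ValidationError("build_composite_factor: no component factors given")
    all_labels = [lab for f in component_factors for lab in f.labels]
    if len(set(all_labels)) != len(all_labels):
        raise ValidationError(
            f"composite {name!r}: component factors have overlapping level labels"
        )
    collapse = set(collapse)
    unknown = collapse - set(all_labels)
    if unknown:
        raise ValidationError(
            f"composite {name!r}: collapse labels {sorted(unknown)} not found "
            f"among component levels"
        )

    # admissible keys: collapsed singletons, plus the product of non-collapse levels
    keys: list[tuple[str, ...]] = []
    for f in component_factors:
        for lab in f.labels:
            if lab in collapse:
                keys.append((lab,))
    cross = [
        [lab for lab in f.labels if lab not in collapse] for f in component_factors
    ]
    if all(cross):
        keys.extend(itertools.product(*cross))

    norm_joint = {
        ((k,) if isinstance(k, str) else tuple(k)): float(p)
        for k, p in joint_prevalences.items()
    }
    missing = [k for k in keys if k not in norm_joint]
    if missing:
        raise ValidationError(
            f"composite {name!r}: joint prevalence missing for admissible "
            f"combination(s) {missing}"
        )
    extra = [k for k in norm_joint if k not in keys]
    if extra:
        raise ValidationError(
            f"composite {name!r}: prevalence supplied for excluded "
            f"combination(s) {extra}"
        )

    single = len(component_factors) == 1
    by_label = {
        lab: (f.name, f.level(lab)) for f in component_factors for lab in f.labels
    }
    levels = []
    for key in keys:
        parts = [by_label[lab] for lab in key]
        rr = math.prod(lv.relative_risk for _, lv in parts)
        display = (labels or {}).get(key, separator.join(key))
        levels.append(
            FactorLevel(
                label=display,
                relative_risk=rr,
                prevalence=norm_joint[key],
                components=(
                    None
                    if single
                    else tuple(
                        (f"{fname}:{lv.label}", lv.relative_risk) for fname, lv in parts
                    )
                ),
            )
        )

    if baseline_label is None:
        if len(collapse) == 1:
            baseline_label = next(iter(collapse))
        elif single:
            baseline_label = component_factors[0].baseline_label
        else:
            raise ValidationError(
                f"composite {name!r}: baseline_label required when there is "
                f"not exactly one collapse label"
            )
    return RiskFactor(
        name=name,
        levels=tuple(levels),
        baseline_label=baseline_label,
        evidence_class=evidence_class,
        instrument=instrument,
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# profile support diagnostics
# ---------------------------------------------------------------------------


def validate_profile_support(table: FactorTable, profile) -> list[str]:
    """List the problems preventing ``profile`` from being scored.

    Accepts an ``IndividualProfile`` or any mapping of factor name to level
    label.  Returns an empty list iff every assignment refers to a known
    factor and a known level of that factor.
    """
    assignments = getattr(profile, "assignments", profile)
    problems = []
    for fname, label in assignments.items():
        try:
            f = table.factor(fname)
        except KeyError:
            problems.append(f"unknown factor: {fname}")
            continue
        if label not in f.labels:
            problems.append(
                f"unknown level {label!r} for factor {fname!r} "
                f"(known: {list(f.labels)})"
            )
    return problems
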