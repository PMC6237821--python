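"""Rule-based CMT2A clinical severity scale.

CMT2A patients reported in the literature were examined under heterogeneous
schemes, so standard neuropathy scales (CMTNS, FDS) are unusable across
reports.  The scale implemented here treats CMT2A as a systemic
mitochondrial disorder: a base term for age at onset (earlier onset is a
severity marker) plus additive points for central-nervous-system and
cranial-nerve involvement and half a point for each additional
mitochondrial-disease symptom.

Point values:

==============================  ======  ========
feature                         points  category
==============================  ======  ========
onset before age 6              1.5     onset
onset between 6 and 20          1.0     onset
onset after 20                  0.5     onset
pyramidal signs /
extensor plantar responses      2.0     major
mild pyramidal signs            1.5     major
sudden visual loss              1.5     major
optic nerve atrophy             1.0     major
mental retardation /
developmental delay             1.0     major
wheelchair-bound                1.0     major
subcortical lesions in MRI      0.5     major
each other symptom              0.5     minor
==============================  ======  ========

Minor ("other") symptoms comprise hearing impairment/deafness,
sensorineural hearing loss, cerebellar ataxia, vasomotor troubles, tremor,
cataracts, learning difficulties, mitochondrial myopathy, microcephaly,
periventricular leukomalacia, proximal weakness and markedly reduced motor
nerve conduction velocity.

When a report is compatible with more than one onset category ("early or
classical"), the score is an interval over the alternatives.  A genetically
confirmed but clinically unaffected carrier scores 0 via the
``asymptomatic`` flag, which suppresses the onset base term.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from mfn2sev.errors import ValidationError

__all__ = [
    "ScoreRule",
    "ClinicalRecord",
    "SeverityScore",
    "ONSET_CATEGORIES",
    "DEFAULT_RULES",
    "MINOR_FEATURES",
    "MAJOR_FEATURES",
    "onset_category",
    "score_record",
    "score_table",
    "read_clinical_records",
    "read_rules",
    "write_scores",
]

ONSET_CATEGORIES = ("early", "classical", "late")


@dataclass(frozen=True)
class ScoreRule:
    """One scored feature: symbolic key, point value, category."""

    feature_id: str
    points: float
    category: str  # "onset" | "major" | "minor"

    def __post_init__(self) -> None:
        if self.points not in (0.5, 1.0, 1.5, 2.0):
            raise ValidationError(f"points must be in {{0.5,1,1.5,2}}: {self.points}")
        if self.category not in ("onset", "major", "minor"):
            raise ValidationError(f"unknown rule category {self.category!r}")


def _default_rules() -> dict[str, ScoreRule]:
    onset = [("early", 1.5), ("classical", 1.0), ("late", 0.5)]
    major = [
        ("pyramidal_signs", 2.0),
        ("mild_pyramidal_signs", 1.5),
        ("sudden_visual_loss", 1.5),
        ("optic_atrophy", 1.0),
        ("mental_retardation", 1.0),
        ("wheelchair_bound", 1.0),
        ("subcortical_mri_lesions", 0.5),
    ]
    minor = [
        "hearing_impairment",
        "sensorineural_hearing_loss",
        "cerebellar_ataxia",
        "vasomotor_troubles",
        "tremor",
        "cataracts",
        "learning_difficulties",
        "mitochondrial_myopathy",
        "microcephaly",
        "periventricular_leukomalacia",
        "proximal_weakness",
        "reduced_motor_ncv",
        "other_minor",
    ]
    rules = {k: ScoreRule(k, p, "onset") for k, p in onset}
    rules.update({k: ScoreRule(k, p, "major") for k, p in major})
    rules.update({k: ScoreRule(k, 0.5, "minor") for k in minor})
    return rules


DEFAULT_RULES: dict[str, ScoreRule] = _default_rules()
MAJOR_FEATURES = tuple(k for k, r in DEFAULT_RULES.items() if r.category == "major")
MINOR_FEATURES = tuple(k for k, r in DEFAULT_RULES.items() if r.category == "minor")


@dataclass(frozen=True)
class ClinicalRecord:
    """Structured phenotype of one patient/mutation report.

    ``onset_categories`` lists the onset classes compatible with the report
    (several when the literature is ambiguous); ``asymptomatic`` marks an
    unaffected carrier, which scores 0 regardless of other fields.
    """

    mutation_label: str
    onset_categories: tuple[str, ...] = ()
    major_features: frozenset[str] = frozenset()
    minor_features: frozenset[str] = frozenset()
    asymptomatic: bool = False
    onset_age: str | None = None
    cmap_mV: tuple[float, ...] = ()
    cmtns: int | None = None
    fds: int | None = None

    def __post_init__(self) -> None:
        if not self.asymptomatic and not self.onset_categories:
            raise ValidationError(
                f"{self.mutation_label}: onset category required for symptomatic record"
            )
        for cat in self.onset_categories:
            if cat not in ONSET_CATEGORIES:
                raise ValidationError(
                    f"{self.mutation_label}: unknown onset category {cat!r}"
                )


@dataclass(frozen=True)
class SeverityScore:
    """Closed interval of points; degenerate (min == max) for a point score."""

    min_points: float
    max_points: float

    def __post_init__(self) -> None:
        if self.min_points < 0 or self.min_points > self.max_points:
            raise ValidationError(
                f"invalid score interval [{self.min_points}, {self.max_points}]"
            )
        for v in (self.min_points, self.max_points):
            if not math.isclose(v * 2, round(v * 2)):
                raise ValidationError(f"score {v} is not a multiple of 0.5")

    @property
    def is_point(self) -> bool:
        return self.min_points == self.max_points

    @property
    def midpoint(self) -> float:
        return (self.min_points + self.max_points) / 2

    def hull(self, other: "SeverityScore") -> "SeverityScore":
        return SeverityScore(
            min(self.min_points, other.min_points),
            max(self.max_points, other.max_points),
        )

    def __str__(self) -> str:
        if self.is_point:
            return f"{self.min_points:g}"
        return f"{self.min_points:g}-{self.max_points:g}"


def onset_category(age_or_range: float | tuple[float, float]) -> set[str]:
    """Onset categories spanned by an age (years) or inclusive age range.

    Early onset is age < 6, classical 6-20, late > 20.  A range spanning a
    boundary returns the union of the spanned categories.
    """
    if isinstance(age_or_range, tuple):
        lo, hi = age_or_range
    else:
        lo = hi = float(age_or_range)
    if lo < 0 or hi < lo:
        raise ValidationError(f"invalid onset age {age_or_range!r}")
    cats: set[str] = set()
    if lo < 6:
        cats.add("early")
    if lo <= 20 and hi >= 6:
        cats.add("classical")
    if hi > 20:
        cats.add("late")
    return cats


def _check_features(record: ClinicalRecord, rules: Mapping[str, ScoreRule]) -> None:
    for feat in (*record.major_features, *record.minor_features):
        if feat not in rules:
            raise ValidationError(
                f"{record.mutation_label}: unknown feature {feat!r}; "
                f"valid keys: {', '.join(sorted(rules))}"
            )


def score_record(
    record: ClinicalRecord, rules: Mapping[str, ScoreRule] = DEFAULT_RULES
) -> SeverityScore:
    """Score one clinical record on the internal severity scale.

    The onset base term contributes its interval over the record's onset
    alternatives; major and minor features add fixed points on top.  Each
    distinct minor feature counts once, with no cap.  Pure function.
    """
    _check_features(record, rules)
    if record.asymptomatic:
        base_lo = base_hi = 0.0
    else:
        bases = [rules[cat].points for cat in record.onset_categories]
        base_lo, base_hi = min(bases), max(bases)
    fixed = sum(rules[f].points for f in record.major_features)
    fixed += sum(rules[f].points for f in record.minor_features)
    return SeverityScore(base_lo + fixed, base_hi + fixed)


def score_table(
    records: Sequence[ClinicalRecord],
    rules: Mapping[str, ScoreRule] = DEFAULT_RULES,
) -> dict[str, SeverityScore]:
    """Score per mutation; several reports of one mutation give the interval hull."""
    out: dict[str, SeverityScore] = {}
    for record in records:
        s = score_record(record, rules)
        if record.mutation_label in out:
            s = out[record.mutation_label].hull(s)
        out[record.mutation_label] = s
    return out


def _split(cell: str) -> tuple[str, ...]:
    return tuple(tok.strip() for tok in cell.split(";") if tok.strip())


def read_clinical_records(path: str | Path) -> list[ClinicalRecord]:
    """Read tab-delimited clinical records.

    Columns: ``mutation, onset_categories, major_features, minor_features``
    (``;``-joined controlled-vocabulary keys) plus optional ``onset_age``.
    ``onset_categories == "asymptomatic"`` marks an unaffected carrier.
    """
    records: list[ClinicalRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            cats = _split(row.get("onset_categories") or "")
            asymptomatic = cats == ("asymptomatic",)
            records.append(
                ClinicalRecord(
                    mutation_label=row["mutation"].strip(),
                    onset_categories=() if asymptomatic else cats,
                    major_features=frozenset(_split(row.get("major_features") or "")),
                    minor_features=frozenset(_split(row.get("minor_features") or "")),
                    asymptomatic=asymptomatic,
                    onset_age=(row.get("onset_age") or "").strip() or None,
                )
            )
    return records


def read_rules(path: str | Path) -> dict[str, ScoreRule]:
    """Read a rule-table override: tab-delimited ``feature_id, points, category``."""
    rules: dict[str, ScoreRule] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            key = row["feature_id"].strip()
            if key in rules:
                raise ValidationError(f"duplicate rule {key!r}")
            rules[key] = ScoreRule(key, float(row["points"]), row["category"].strip())
    return rules


def write_scores(scores: Mapping[str, SeverityScore], path: str | Path) -> None:
    """Write tab-delimited ``mutation, score_min, score_max``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["mutation", "score_min", "score_max"])
        for label, s in scores.items():
            writer.writerow([label, f"{s.min_points:g}", f"{s.max_points:g}"])
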