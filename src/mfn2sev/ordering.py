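"""Per-position severity orderings and clinical-vs-structural concordance.

At each residue position carrying several alternative substitutions, the
alternatives are ranked by severity.  A ranking is an *ordering chain*:
amino-acid labels joined by relations from ``{>, ≥, =}``, e.g.
``Asp > Arg > Leu = Tyr``.  The clinical chain is derived from rule-based
severity scores; the structural chain is an annotation summarising the
molecular-modelling assessment of the same substitutions.  Comparing the
two chains position by position yields a concordance statistic: the
fraction of positions whose chains fully agree.

Comparison semantics: a clinical ``≥`` is compatible with a structural
``>`` or ``=`` (it claims no strict order); a strictness disagreement
between ``>`` and ``=`` makes the position *partial* (incomplete but not
discordant); an actual rank reversal makes it *discordant*.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from mfn2sev.errors import ParseError, ValidationError
from mfn2sev.scoring import SeverityScore

__all__ = [
    "OrderingChain",
    "GroupComparison",
    "ConcordanceSummary",
    "parse_chain",
    "derive_clinical_chain",
    "compare_chains",
    "concordance_summary",
    "predictor_compatibility",
    "read_chain_table",
    "write_comparisons",
]

RELATIONS = (">", "≥", "=")  # >, ≥, =
_GEQ = "≥"


@dataclass(frozen=True)
class OrderingChain:
    """Severity ranking of substitutions at one position.

    ``labels`` are distinct amino-acid codes in decreasing severity;
    ``relations`` (one per adjacent pair) are drawn from ``{>, ≥, =}``.
    """

    labels: tuple[str, ...]
    relations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValidationError("chain needs at least one label")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError(f"repeated label in chain {self.labels}")
        if len(self.relations) != len(self.labels) - 1:
            raise ValidationError(
                f"{len(self.labels)} labels need {len(self.labels) - 1} relations"
            )
        for rel in self.relations:
            if rel not in RELATIONS:
                raise ValidationError(f"unknown relation {rel!r}")

    def serialize(self) -> str:
        parts = [self.labels[0]]
        for rel, label in zip(self.relations, self.labels[1:]):
            parts += [rel, label]
        return " ".join(parts)

    def __str__(self) -> str:
        return self.serialize()

    def relation_between(self, a: str, b: str) -> str:
        """Composed relation between two labels, signed from ``a`` to ``b``.

        Returns one of ``>``, ``≥``, ``=`` when ``a`` ranks at or above
        ``b`` in this chain, or ``<``, ``≤`` when it ranks below.
        """
        ia, ib = self.labels.index(a), self.labels.index(b)
        if ia == ib:
            return "="
        lo, hi = min(ia, ib), max(ia, ib)
        span = self.relations[lo:hi]
        if ">" in span:
            rel = ">"
        elif _GEQ in span:
            rel = _GEQ
        else:
            rel = "="
        if ia > ib and rel != "=":
            rel = "<" if rel == ">" else "≤"
        return rel


def parse_chain(text: str) -> OrderingChain:
    """Parse ``"Asp > Arg > Leu = Tyr"``; ``>=`` is accepted for ``≥``."""
    s = str(text).replace(">=", _GEQ)
    for sym in RELATIONS:
        s = s.replace(sym, f" {sym} ")
    toks = s.split()
    labels: list[str] = []
    relations: list[str] = []
    expect_label = True
    for tok in toks:
        if expect_label:
            if tok in RELATIONS:
                raise ParseError(f"expected label, found {tok!r} in {text!r}")
            labels.append(tok)
        else:
            if tok not in RELATIONS:
                raise ParseError(f"expected relation, found {tok!r} in {text!r}")
            relations.append(tok)
        expect_label = not expect_label
    if expect_label:
        raise ParseError(f"dangling relation in {text!r}")
    try:
        return OrderingChain(tuple(labels), tuple(relations))
    except ValidationError as exc:
        raise ParseError(f"{text!r}: {exc}") from None


def derive_clinical_chain(group_scores: Mapping[str, SeverityScore]) -> OrderingChain:
    """Derive the clinical ordering chain from per-substitution severity scores.

    Labels are sorted by decreasing interval midpoint (ties alphabetical).
    Adjacent relations: equal midpoints give ``=``; two point (degenerate)
    scores exactly 0.5 apart give ``≥`` — the scale's resolution limit, a
    tendency rather than a strict order; anything else gives ``>``.
    """
    if not group_scores:
        raise ValidationError("empty score mapping")
    labels = sorted(group_scores, key=lambda k: (-group_scores[k].midpoint, k))
    relations: list[str] = []
    for a, b in zip(labels, labels[1:]):
        sa, sb = group_scores[a], group_scores[b]
        delta = sa.midpoint - sb.midpoint
        if delta == 0:
            relations.append("=")
        elif sa.is_point and sb.is_point and delta == 0.5:
            relations.append(_GEQ)
        else:
            relations.append(">")
    return OrderingChain(tuple(labels), tuple(relations))


@dataclass(frozen=True)
class GroupComparison:
    """Outcome of comparing the clinical and structural chains at one position."""

    position: int
    clinical: OrderingChain
    structural: OrderingChain
    status: str  # "concordant" | "partial" | "discordant"
    mismatched_pairs: tuple[tuple[str, str, str, str], ...] = ()

    def __post_init__(self) -> None:
        if (self.status == "concordant") != (not self.mismatched_pairs):
            raise ValidationError("status inconsistent with mismatched_pairs")


def compare_chains(
    clinical: OrderingChain, structural: OrderingChain, position: int = 0
) -> GroupComparison:
    """Compare a clinical chain against the structural chain for one position.

    For every adjacent pair of the clinical chain, the (composed) relation
    between the same two labels in the structural chain is checked:

    * equal relations, or clinical ``≥`` vs structural ``>``/``=``, agree;
    * a strictness disagreement (``>`` vs ``=`` in either direction, or a
      ``≥`` on the structural side against a strict clinical claim) marks
      the pair mismatched → status ``partial``;
    * a rank reversal (structural strictly orders the pair the other way
      while the clinical chain ranks it) → status ``discordant``.
    """
    if set(clinical.labels) != set(structural.labels):
        raise ValidationError(
            f"label sets differ: {sorted(clinical.labels)} vs {sorted(structural.labels)}"
        )
    mism: list[tuple[str, str, str, str]] = []
    reversal = False
    for (a, b), c_rel in zip(zip(clinical.labels, clinical.labels[1:]),
                             clinical.relations):
        s_rel = structural.relation_between(a, b)
        if c_rel == s_rel:
            continue
        if c_rel == _GEQ and s_rel in (">", "="):
            continue
        if s_rel in ("<", "≤") and c_rel in (">", _GEQ):
            reversal = True
        mism.append((a, b, c_rel, s_rel))
    status = "discordant" if reversal else ("partial" if mism else "concordant")
    return GroupComparison(position, clinical, structural, status, tuple(mism))


@dataclass(frozen=True)
class ConcordanceSummary:
    """Count of fully concordant positions and the agreement percentage."""

    n_groups: int
    n_concordant: int
    agreement_percent: int
    n_partial: int = 0
    n_discordant: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_concordant <= self.n_groups:
            raise ValidationError("inconsistent concordance counts")


def _round_half_up(x: float) -> int:
    return int(x + 0.5)


def concordance_summary(comparisons: Sequence[GroupComparison]) -> ConcordanceSummary:
    """Summarise comparisons; only fully concordant groups enter the numerator."""
    if not comparisons:
        raise ValidationError("no comparisons to summarise")
    n = len(comparisons)
    n_conc = sum(c.status == "concordant" for c in comparisons)
    n_part = sum(c.status == "partial" for c in comparisons)
    n_disc = sum(c.status == "discordant" for c in comparisons)
    return ConcordanceSummary(n, n_conc, _round_half_up(100 * n_conc / n),
                              n_part, n_disc)


def chain_from_scores(scores: Mapping[str, float]) -> OrderingChain:
    """Rank labels by a plain numeric score (descending); exact ties give ``=``."""
    if not scores:
        raise ValidationError("empty score mapping")
    labels = sorted(scores, key=lambda k: (-scores[k], k))
    relations = tuple(
        "=" if scores[a] == scores[b] else ">" for a, b in zip(labels, labels[1:])
    )
    return OrderingChain(tuple(labels), relations)


def predictor_compatibility(
    predictor_scores: Mapping[str, Mapping[str, float]],
    groups: Sequence,
    clinical_chains: Mapping[int, OrderingChain],
) -> dict[str, int]:
    """Concordance of external variant-effect-predictor rankings with the clinic.

    ``predictor_scores`` maps tool name → mutation label → numeric score
    (higher = more severe).  Per tool, each group's mutations are ranked by
    score into a structural-style chain (exact ties → ``=``) and compared
    with the clinical chain; the returned percentage counts fully
    concordant groups.  The procedure mirrors the in-house comparison and
    is methodology-dependent: predictors ignore residue position, so their
    rankings are not calibrated within positions.
    """
    out: dict[str, int] = {}
    for tool, scores in predictor_scores.items():
        comparisons = []
        for g in groups:
            group_scores: dict[str, float] = {}
            for alt, label in zip(g.alts, g.labels):
                if label not in scores:
                    raise ValidationError(f"{tool}: missing score for {label}")
                group_scores[alt] = scores[label]
            chain = chain_from_scores(group_scores)
            comparisons.append(compare_chains(clinical_chains[g.position], chain,
                                              position=g.position))
        out[tool] = concordance_summary(comparisons).agreement_percent
    return out


def read_chain_table(path: str | Path) -> list[dict]:
    """Read tab-delimited ``position, wt, clinical_chain, structural_chain``."""
    rows: list[dict] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                {
                    "position": int(row["position"]),
                    "wt": row["wt"].strip(),
                    "clinical": parse_chain(row["clinical_chain"]),
                    "structural": parse_chain(row["structural_chain"]),
                }
            )
    return rows


def write_comparisons(
    comparisons: Sequence[GroupComparison], path: str | Path
) -> None:
    """Write per-position comparison report as tab-delimited text."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["position", "clinical", "structural", "status",
                         "mismatched_pairs"])
        for c in comparisons:
            pairs = ";".join(f"{a}{cr}{b}|{sr}" for a, b, cr, sr in c.mismatched_pairs)
            writer.writerow([c.position, c.clinical, c.structural, c.status, pairs])
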