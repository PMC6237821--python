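"""Missense-mutation catalogue: parsing, filtering and per-position grouping.

A catalogue is a flat list of protein-level substitutions (e.g.
``p.Arg274Trp``).  The analysis keeps only mutations inside the MFN2
GTPase domain (residues 95-339 by default), drops variants without usable
clinical data, and groups the remainder by residue position, retaining
positions at which the wild-type amino acid is replaced by at least two
distinct alternatives.  Only such multi-substitution positions support a
within-position severity comparison.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from mfn2sev._aa import canonical_aa
from mfn2sev.errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MutationRecord",
    "DomainRange",
    "MutationGroup",
    "ExclusionList",
    "DEFAULT_DOMAIN",
    "DEFAULT_EXCLUSIONS",
    "parse_protein_change",
    "filter_domain",
    "apply_exclusions",
    "dedupe_records",
    "group_by_position",
    "read_catalog",
    "write_groups",
]


@dataclass(frozen=True)
class MutationRecord:
    """A single protein-level missense substitution.

    ``position`` is the 1-based residue index in protein coordinates,
    ``wt`` and ``alt`` are title-case 3-letter amino-acid codes.
    ``annotations`` carries non-missense components of a compound label
    (e.g. an in-trans nonsense allele); they are recorded but never scored.
    """

    position: int
    wt: str
    alt: str
    nt_change: str | None = None
    annotations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if self.wt == self.alt:
            raise ValidationError(
                f"silent substitution at {self.position}: wt == alt == {self.wt}"
            )

    @property
    def label(self) -> str:
        """Canonical ``p.<Wt3><pos><Alt3>`` label."""
        return f"p.{self.wt}{self.position}{self.alt}"


@dataclass(frozen=True)
class DomainRange:
    """Inclusive 1-based residue range of a protein domain."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"invalid range {self.start}..{self.end}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


#: The MFN2 GTPase domain.
DEFAULT_DOMAIN = DomainRange(95, 339)


@dataclass(frozen=True)
class MutationGroup:
    """All alternative substitutions observed at one residue position."""

    position: int
    wt: str
    alts: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.alts) < 2:
            raise ValidationError(
                f"group at {self.position} needs >= 2 alternatives, got {self.alts}"
            )
        if len(set(self.alts)) != len(self.alts) or self.wt in self.alts:
            raise ValidationError(f"invalid alternatives at {self.position}: {self.alts}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"p.{self.wt}{self.position}{alt}" for alt in self.alts)

    @property
    def size(self) -> int:
        return len(self.alts)


@dataclass(frozen=True)
class ExclusionList:
    """Canonical labels dropped before grouping, with a reason per label."""

    reasons: dict[str, str] = field(default_factory=dict)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(self.reasons)


#: Variants dropped by default: two for missing clinical data and one
#: compound in-cis double mutation.
DEFAULT_EXCLUSIONS = ExclusionList(
    {
        "p.Arg104Leu": "no clinical data",
        "p.Thr105Ala": "no clinical data",
        "p.Thr105LeufsX2+p.Phe223Tyr": "double mutation in cis",
    }
)


_MISSENSE_RE = re.compile(
    r"^p\.(?P<wt>[A-Za-z]{3}|[A-Z])(?P<pos>\d+)(?P<alt>[A-Za-z]{3}|[A-Z*])$"
)
_NON_MISSENSE = re.compile(r"(fs|del|dup|ins|ext|Ter$|\*$|X\d*$)", re.IGNORECASE)


def _parse_single(token: str, nt_change: str | None) -> MutationRecord:
    token = token.strip()
    if _NON_MISSENSE.search(token):
        raise ParseError(f"not a missense substitution: {token!r}")
    m = _MISSENSE_RE.match(token)
    if m is None:
        raise ParseError(f"malformed protein change: {token!r}")
    try:
        wt = canonical_aa(m.group("wt"))
        alt = canonical_aa(m.group("alt"))
    except ValueError as exc:
        raise ValidationError(f"{token!r}: {exc}") from None
    return MutationRecord(int(m.group("pos")), wt, alt, nt_change=nt_change)


def parse_protein_change(text: str, nt_change: str | None = None) -> MutationRecord:
    """Parse an HGVS-like protein change into a :class:`MutationRecord`.

    Both 1- and 3-letter amino-acid codes are accepted (case-insensitive
    for 3-letter codes); the canonical label always uses 3-letter codes.
    Frameshift and nonsense notations are rejected as non-missense.

    Compound labels joined by ``+`` (e.g. a missense allele reported
    together with in-trans stop variants, or a co-occurring diagnosis) are
    parsed as their first missense component; the remaining components are
    kept verbatim in ``annotations``.
    """
    parts = [p.strip() for p in str(text).split("+") if p.strip()]
    if not parts:
        raise ParseError(f"empty protein change: {text!r}")
    record = _parse_single(parts[0], nt_change)
    if len(parts) > 1:
        record = MutationRecord(
            record.position,
            record.wt,
            record.alt,
            nt_change=nt_change,
            annotations=tuple(parts[1:]),
        )
        logger.info("compound variant %r: scoring %s, annotations %s",
                    text, record.label, record.annotations)
    return record


def filter_domain(
    records: Sequence[MutationRecord], domain: DomainRange = DEFAULT_DOMAIN
) -> list[MutationRecord]:
    """Keep records whose position lies inside ``domain`` (inclusive)."""
    kept = [r for r in records if r.position in domain]
    for r in records:
        if r.position not in domain:
            logger.info("dropped %s: outside domain %d-%d",
                        r.label, domain.start, domain.end)
    return kept


def apply_exclusions(
    records: Sequence[MutationRecord],
    exclusions: ExclusionList = DEFAULT_EXCLUSIONS,
) -> tuple[list[MutationRecord], list[tuple[str, str]]]:
    """Drop records whose canonical label is excluded.

    Returns ``(kept, removal_log)`` where the log holds ``(label, reason)``
    pairs for every removed record.
    """
    kept: list[MutationRecord] = []
    removed: list[tuple[str, str]] = []
    for r in records:
        if r.label in exclusions.labels:
            reason = exclusions.reasons[r.label]
            removed.append((r.label, reason))
            logger.info("excluded %s: %s", r.label, reason)
        else:
            kept.append(r)
    return kept, removed


def dedupe_records(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Collapse repeated reports of the same substitution, keeping the first."""
    seen: set[str] = set()
    out: list[MutationRecord] = []
    for r in records:
        if r.label in seen:
            logger.warning("duplicate record %s dropped", r.label)
            continue
        seen.add(r.label)
        out.append(r)
    return out


def group_by_position(
    records: Sequence[MutationRecord], min_alts: int = 2
) -> list[MutationGroup]:
    """Group substitutions by residue position, keeping multi-substitution sites.

    Positions with fewer than ``min_alts`` distinct alternative residues are
    dropped (and logged): a single substitution offers nothing to rank
    within its position.  Alternatives keep first-appearance order.
    Conflicting wild-type residues at one position raise
    :class:`~mfn2sev.errors.ValidationError`.
    """
    buckets: dict[int, tuple[str, list[str]]] = {}
    for r in records:
        if r.position not in buckets:
            buckets[r.position] = (r.wt, [])
        wt, alts = buckets[r.position]
        if r.wt != wt:
            raise ValidationError(
                f"conflicting wild-type at {r.position}: {wt} vs {r.wt}"
            )
        if r.alt not in alts:
            alts.append(r.alt)
    groups: list[MutationGroup] = []
    for pos in sorted(buckets):
        wt, alts = buckets[pos]
        if len(alts) >= min_alts:
            groups.append(MutationGroup(pos, wt, tuple(alts)))
        else:
            logger.info("position %d dropped: single substitution %s%d%s",
                        pos, wt, pos, alts[0])
    return groups


def read_catalog(path: str | Path) -> list[MutationRecord]:
    """Read a delimited catalogue with columns ``protein_change[,nt_change,refs]``.

    The delimiter (comma or tab) is sniffed from the header line.
    """
    path = Path(path)
    text = path.read_text()
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    records: list[MutationRecord] = []
    reader = csv.DictReader(text.splitlines(), delimiter=delimiter)
    if reader.fieldnames is None or "protein_change" not in reader.fieldnames:
        raise ParseError(f"{path}: missing 'protein_change' column")
    for row in reader:
        nt = (row.get("nt_change") or "").strip() or None
        records.append(parse_protein_change(row["protein_change"], nt_change=nt))
    return records


def write_groups(groups: Iterable[MutationGroup], path: str | Path) -> None:
    """Write groups as tab-delimited ``position, wt, alts`` (``;``-joined alts)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["position", "wt", "alts"])
        for g in groups:
            writer.writerow([g.position, g.wt, ";".join(g.alts)])
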