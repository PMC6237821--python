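"""Seed-controlled synthetic inputs for every pipeline stage.

Everything here is generated, never downloaded: mutation catalogues with a
chosen per-position group structure, clinical cohorts whose rule-based
score equals a known target (the inverse of the scoring scale), coordinate
fixtures with interactions placed at exact distances and orientations, and
concordance scenarios with known per-group truth statuses.

Side-chain geometry is idealized: each residue template carries the atoms
the interaction detectors inspect, laid out along a contact axis with
canonical-ish bond lengths.  No backbone realism is attempted beyond a
clash limit — the detectors only consume atom positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from mfn2sev._aa import CANONICAL_3
from mfn2sev.catalog import MutationRecord
from mfn2sev.errors import ValidationError
from mfn2sev.ordering import OrderingChain, RELATIONS
from mfn2sev.scoring import (
    DEFAULT_RULES,
    ClinicalRecord,
    MAJOR_FEATURES,
    MINOR_FEATURES,
    SeverityScore,
)
from mfn2sev.structure import Residue, Structure, write_structure

__all__ = [
    "CohortSpec",
    "FixtureSpec",
    "PlacedInteraction",
    "gen_catalog",
    "compose_record",
    "gen_cohort",
    "gen_structure_fixture",
    "gen_random_structure",
    "closure_network_spec",
    "gen_concordance_scenario",
    "rigid_transform",
]

_CLASH_LIMIT = 1.5  # Å; minimum allowed inter-residue atom distance


# ---------------------------------------------------------------------------
# mutation catalogues

@dataclass(frozen=True)
class CohortSpec:
    """Shape of a synthetic catalogue/cohort.

    ``n_positions`` multi-substitution positions with 2-4 alternatives
    each mirror the structure of the reference 26-mutation catalogue
    (11 positions, group sizes 2-4); target severity scores default to the
    0.5-7 range the internal scale actually produces.
    """

    n_positions: int = 11
    alts_range: tuple[int, int] = (2, 4)
    n_singletons: int = 0
    domain: tuple[int, int] = (95, 339)
    target_scores: tuple[float, ...] = tuple(x / 2 for x in range(1, 15))
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.alts_range
        if not 2 <= lo <= hi:
            raise ValidationError(f"alts_range must satisfy 2 <= lo <= hi: {self.alts_range}")
        if hi > 19:
            raise ValidationError("at most 19 alternatives per position")
        for t in self.target_scores:
            if t < 0.5 or (2 * t) != round(2 * t):
                raise ValidationError(f"target score {t} not a positive multiple of 0.5")


_AA = tuple(sorted(CANONICAL_3))


def gen_catalog(spec: CohortSpec) -> list[MutationRecord]:
    """Generate a catalogue whose grouping yields exactly ``spec.n_positions`` groups.

    Deterministic for a given seed.  Optional singleton positions (one
    substitution only) exercise the grouping filter.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.domain
    total = spec.n_positions + spec.n_singletons
    if total > hi - lo + 1:
        raise ValidationError("more positions requested than the domain holds")
    positions = rng.choice(np.arange(lo, hi + 1), size=total, replace=False)
    records: list[MutationRecord] = []
    for i, pos in enumerate(sorted(int(p) for p in positions)):
        wt = _AA[rng.integers(len(_AA))]
        n_alts = 1 if i >= spec.n_positions else int(
            rng.integers(spec.alts_range[0], spec.alts_range[1] + 1)
        )
        pool = [a for a in _AA if a != wt]
        alts = rng.choice(len(pool), size=n_alts, replace=False)
        for j in alts:
            records.append(MutationRecord(pos, wt, pool[int(j)]))
    return records


# ---------------------------------------------------------------------------
# clinical cohorts (inverse of the scoring scale)

_ONSET_FOR_BASE = {1.5: "early", 1.0: "classical", 0.5: "late"}


def compose_record(
    label: str,
    target: float,
    rng: np.random.Generator | None = None,
) -> ClinicalRecord:
    """Build a clinical record whose severity score equals ``target`` exactly.

    Greedy-deterministic by default: the onset category fixes the base
    term, major features are added in decreasing point order while they
    fit, and the remainder is padded with 0.5-point minor symptoms.  With
    ``rng`` given, feature order is shuffled (sampled mode) while the
    target is still met exactly.
    """
    if target == 0:
        return ClinicalRecord(label, asymptomatic=True)
    if target < 0.5 or 2 * target != round(2 * target):
        raise ValidationError(f"target {target} not representable on the scale")
    base = min(1.5, target) if target != 1.0 else 1.0
    if target == 0.5:
        base = 0.5
    remainder = round(target - base, 1)
    majors = [(k, DEFAULT_RULES[k].points) for k in MAJOR_FEATURES]
    minors = list(MINOR_FEATURES)
    if rng is not None:
        rng.shuffle(majors)
        majors.sort(key=lambda kv: -kv[1])  # keep greedy order stable by points
        rng.shuffle(minors)
    chosen_major: list[str] = []
    for key, points in majors:
        if points <= remainder:
            chosen_major.append(key)
            remainder = round(remainder - points, 1)
    n_minor = int(round(remainder / 0.5))
    if n_minor > len(minors):
        raise ValidationError(
            f"target {target} unreachable: needs {n_minor} minor symptoms, "
            f"vocabulary has {len(minors)}"
        )
    return ClinicalRecord(
        label,
        onset_categories=(_ONSET_FOR_BASE[base],),
        major_features=frozenset(chosen_major),
        minor_features=frozenset(minors[:n_minor]),
    )


def gen_cohort(
    records: Sequence[MutationRecord],
    spec: CohortSpec,
    sampled: bool = False,
) -> tuple[list[ClinicalRecord], dict[str, SeverityScore]]:
    """Generate one clinical record per mutation plus the truth score table."""
    rng = np.random.default_rng(spec.seed + 1)
    cohort: list[ClinicalRecord] = []
    truth: dict[str, SeverityScore] = {}
    for rec in records:
        target = float(spec.target_scores[rng.integers(len(spec.target_scores))])
        cohort.append(compose_record(rec.label, target, rng if sampled else None))
        truth[rec.label] = SeverityScore(target, target)
    return cohort, truth


# ---------------------------------------------------------------------------
# coordinate fixtures

def _hexagon(center_x: float, radius: float = 1.39) -> list[np.ndarray]:
    return [
        np.array([center_x + radius * math.cos(a), radius * math.sin(a), 0.0])
        for a in (np.arange(6) * math.pi / 3)
    ]


def _pentagon(center_x: float, radius: float = 1.17) -> list[np.ndarray]:
    return [
        np.array([center_x + radius * math.cos(a), radius * math.sin(a), 0.0])
        for a in (np.arange(5) * 2 * math.pi / 5)
    ]


def _chain_template(names: Sequence[str], spacing: float = 1.5) -> dict[str, np.ndarray]:
    atoms = {"CA": np.array([-1.2, 0.9, 0.0])}
    for i, name in enumerate(names):
        atoms[name] = np.array([i * spacing, 0.0, 0.0])
    return atoms


def _template(code: str) -> tuple[dict[str, np.ndarray], str]:
    """Idealized side-chain template and the name of its +x contact atom."""
    if code == "Asp":
        atoms = _chain_template(["CB", "CG"])
        atoms["OD1"] = np.array([2.75, 0.0, 0.0])
        atoms["OD2"] = np.array([1.9, -1.2, 0.0])
        return atoms, "OD1"
    if code == "Glu":
        atoms = _chain_template(["CB", "CG", "CD"])
        atoms["OE1"] = np.array([4.25, 0.0, 0.0])
        atoms["OE2"] = np.array([3.4, -1.2, 0.0])
        return atoms, "OE1"
    if code == "Arg":
        atoms = _chain_template(["CB", "CG", "CD"])
        atoms.update({
            "NE": np.array([4.4, 0.0, 0.0]),
            "CZ": np.array([5.7, 0.0, 0.0]),
            "NH1": np.array([6.95, 0.0, 0.0]),
            "NH2": np.array([6.1, -1.15, 0.0]),
        })
        return atoms, "NH1"
    if code == "Lys":
        atoms = _chain_template(["CB", "CG", "CD", "CE"])
        atoms["NZ"] = np.array([5.99, 0.0, 0.0])
        return atoms, "NZ"
    if code == "His":
        ring = _pentagon(2.3)
        names = ["NE2", "CE1", "ND1", "CG", "CD2"]  # NE2 at +x tip
        atoms = {"CA": np.array([-1.2, 0.9, 0.0]), "CB": np.array([0.0, 0.0, 0.0])}
        atoms.update(dict(zip(names, ring)))
        return atoms, "NE2"
    if code in ("Phe", "Tyr"):
        ring = _hexagon(2.7)
        names = ["CZ", "CE1", "CD1", "CG", "CD2", "CE2"]  # CZ at +x tip
        atoms = {"CA": np.array([-1.2, 0.9, 0.0]), "CB": np.array([0.0, 0.0, 0.0])}
        atoms.update(dict(zip(names, ring)))
        return atoms, "CZ"
    if code == "Trp":
        ring = _hexagon(2.8)
        names = ["CH2", "CZ2", "CE2", "CD2", "CE3", "CZ3"]  # CH2 at +x tip
        atoms = {"CA": np.array([-1.2, 0.9, 0.0]), "CB": np.array([0.0, 0.0, 0.0]),
                 "CG": np.array([1.0, -0.9, 0.0])}
        atoms.update(dict(zip(names, ring)))
        return atoms, "CH2"
    if code == "Leu":
        atoms = _chain_template(["CB", "CG"])
        atoms["CD1"] = np.array([2.9, 0.0, 0.0])
        atoms["CD2"] = np.array([1.9, -1.3, 0.4])
        return atoms, "CD1"
    if code == "Ile":
        atoms = _chain_template(["CB", "CG1"])
        atoms["CD1"] = np.array([2.9, 0.0, 0.0])
        atoms["CG2"] = np.array([0.3, -1.4, 0.0])
        return atoms, "CD1"
    if code == "Val":
        atoms = _chain_template(["CB"])
        atoms["CG1"] = np.array([1.53, 0.0, 0.0])
        atoms["CG2"] = np.array([0.3, -1.4, 0.0])
        return atoms, "CG1"
    if code == "Met":
        atoms = _chain_template(["CB", "CG"])
        atoms["SD"] = np.array([3.0, 0.0, 0.0])
        atoms["CE"] = np.array([4.4, 0.0, 0.0])
        return atoms, "CE"
    if code == "Pro":
        atoms = {"CA": np.array([-1.2, 0.9, 0.0]), "CB": np.array([0.0, 0.0, 0.0]),
                 "CG": np.array([1.5, 0.0, 0.0]), "CD": np.array([0.8, -1.3, 0.0])}
        return atoms, "CG"
    if code == "Ala":
        return {"CA": np.array([-1.4, 0.6, 0.0]), "CB": np.array([0.0, 0.0, 0.0])}, "CB"
    if code == "Gly":
        return {"N": np.array([-1.3, 0.8, 0.0]), "CA": np.array([0.0, 0.0, 0.0]),
                "C": np.array([1.0, 1.0, 0.0]), "O": np.array([2.2, 1.0, 0.0])}, "CA"
    if code == "Ser":
        atoms = _chain_template(["CB"])
        atoms["OG"] = np.array([1.42, 0.0, 0.0])
        return atoms, "OG"
    if code == "Cys":
        atoms = _chain_template(["CB"])
        atoms["SG"] = np.array([1.8, 0.0, 0.0])
        return atoms, "SG"
    if code == "Asn":
        atoms = _chain_template(["CB", "CG"])
        atoms["OD1"] = np.array([2.7, 0.0, 0.0])
        atoms["ND2"] = np.array([1.9, -1.2, 0.0])
        return atoms, "OD1"
    if code == "Gln":
        atoms = _chain_template(["CB", "CG", "CD"])
        atoms["OE1"] = np.array([4.2, 0.0, 0.0])
        atoms["NE2"] = np.array([3.4, -1.2, 0.0])
        return atoms, "OE1"
    if code == "Thr":
        atoms = _chain_template(["CB"])
        atoms["OG1"] = np.array([1.42, 0.0, 0.0])
        atoms["CG2"] = np.array([0.3, -1.4, 0.0])
        return atoms, "OG1"
    raise ValidationError(f"no template for residue code {code!r}")


_RING_NAMES = {
    "Trp": ["CH2", "CZ2", "CE2", "CD2", "CE3", "CZ3"],
    "Phe": ["CZ", "CE1", "CD1", "CG", "CD2", "CE2"],
    "Tyr": ["CZ", "CE1", "CD1", "CG", "CD2", "CE2"],
    "His": ["NE2", "CE1", "ND1", "CG", "CD2"],
}


def _ring_template(code: str) -> dict[str, np.ndarray]:
    """Ring-only template centred at the origin in the xy-plane."""
    pts = _pentagon(0.0) if code == "His" else _hexagon(0.0)
    atoms = dict(zip(_RING_NAMES[code], pts))
    atoms["CB"] = np.array([2.6, 0.0, 0.0])
    return atoms


@dataclass(frozen=True)
class PlacedInteraction:
    """One interaction to realise in a coordinate fixture."""

    kind: str  # salt_bridge | stacking | hydrophobic | contact
    code_a: str
    code_b: str
    distance: float
    chain_a: str = "A"
    chain_b: str = "A"
    index_a: int = 1
    index_b: int = 2
    orientation: str = "parallel"  # stacking only: parallel | perpendicular

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValidationError("requested distance must be positive")
        if (self.chain_a, self.index_a) == (self.chain_b, self.index_b):
            raise ValidationError("interaction needs two distinct residues")


@dataclass(frozen=True)
class FixtureSpec:
    """Layout of a synthetic coordinate fixture (one slot per interaction)."""

    interactions: tuple[PlacedInteraction, ...]
    slot_spacing: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.interactions:
            if p.distance < _CLASH_LIMIT:
                raise ValidationError(
                    f"distance {p.distance} below clash limit {_CLASH_LIMIT}"
                )
        keys = [(p.chain_a, p.index_a) for p in self.interactions]
        keys += [(p.chain_b, p.index_b) for p in self.interactions]
        if len(set(keys)) != len(keys):
            raise ValidationError("residue (chain, index) pairs must be unique")


def _place(atoms: Mapping[str, np.ndarray], rotation: np.ndarray,
           translation: np.ndarray) -> dict[str, np.ndarray]:
    return {n: rotation @ p + translation for n, p in atoms.items()}


_FLIP_Z = np.diag([-1.0, -1.0, 1.0])  # rotation by pi about z
_IDENTITY = np.eye(3)


def gen_structure_fixture(
    spec: FixtureSpec, path: str | Path | None = None
) -> Structure:
    """Build a structure realising each requested interaction exactly.

    Interactions occupy well-separated slots so they cannot interfere.
    Distance-type interactions place the two contact atoms exactly
    ``distance`` apart along the slot axis; stacking places the two ring
    centroids ``distance`` apart, parallel or perpendicular.  If ``path``
    is given a PDB file is written; re-reading reproduces coordinates to
    the 0.001 Å format precision.
    """
    structure = Structure()
    for slot, inter in enumerate(spec.interactions):
        offset = np.array([0.0, spec.slot_spacing * slot, 0.0])
        if inter.kind == "stacking":
            atoms_a = _ring_template(inter.code_a)
            atoms_b = _ring_template(inter.code_b)
            rot_b = _IDENTITY
            if inter.orientation == "perpendicular":
                rot_b = Rotation.from_euler("x", 90, degrees=True).as_matrix()
            elif inter.orientation != "parallel":
                raise ValidationError(f"unknown orientation {inter.orientation!r}")
            placed_a = _place(atoms_a, _IDENTITY, offset)
            placed_b = _place(atoms_b, rot_b,
                              offset + np.array([0.0, 0.0, inter.distance]))
        else:
            atoms_a, tip_a = _template(inter.code_a)
            atoms_b, tip_b = _template(inter.code_b)
            shift = atoms_a[tip_a][0] + inter.distance + atoms_b[tip_b][0]
            placed_a = _place(atoms_a, _IDENTITY, offset)
            placed_b = _place(atoms_b, _FLIP_Z, offset + np.array([shift, 0.0, 0.0]))
        ra = Residue(inter.chain_a, inter.index_a, inter.code_a, placed_a)
        rb = Residue(inter.chain_b, inter.index_b, inter.code_b, placed_b)
        structure.add(ra)
        structure.add(rb)
    if path is not None:
        write_structure(structure, path)
    return structure


def gen_random_structure(
    n_residues: int, seed: int, box: float = 15.0, chains: Sequence[str] = ("A",)
) -> Structure:
    """Randomly place idealized residues in a box (clash-avoiding, seeded)."""
    rng = np.random.default_rng(seed)
    codes = [c for c in _AA]
    structure = Structure()
    existing: list[np.ndarray] = []
    for i in range(n_residues):
        code = codes[rng.integers(len(codes))]
        atoms, _ = _template(code)
        for _attempt in range(200):
            rot = Rotation.random(rng=rng).as_matrix()
            trans = rng.uniform(0, box, size=3)
            placed = {n: rot @ p + trans for n, p in atoms.items()}
            pts = np.array(list(placed.values()))
            if existing:
                d = np.sqrt(((pts[:, None, :] - np.array(existing)[None, :, :]) ** 2)
                            .sum(-1)).min()
                if d < _CLASH_LIMIT:
                    continue
            chain = chains[int(rng.integers(len(chains)))]
            structure.add(Residue(chain, i + 1, code, placed))
            existing.extend(pts)
            break
        else:
            raise ValidationError("could not place residue without clashes")
    return structure


def closure_network_spec(tyr210: bool = False) -> FixtureSpec:
    """Fixture spec realising the six closure salt-bridge pairs.

    With ``tyr210=True`` position 210 gets a tyrosine side chain instead of
    aspartate: the geometry is unchanged but the carboxylate is gone, so
    the 210-476 pair is no longer a salt bridge.
    """
    pairs = [
        ("Tyr" if tyr210 else "Asp", 210, "Arg", 476),
        ("Asp", 480, "Lys", 243),
        ("Glu", 598, "Arg", 250),
        ("Glu", 542, "Lys", 732),
        ("Asp", 377, "Arg", 564),
        ("Glu", 359, "Arg", 575),
    ]
    return FixtureSpec(
        tuple(
            PlacedInteraction("salt_bridge", ca, cb, 3.5,
                              index_a=ia, index_b=ib)
            for ca, ia, cb, ib in pairs
        )
    )


def rigid_transform(structure: Structure, seed: int) -> Structure:
    """Apply a seeded random rigid rotation + translation to all atoms."""
    rng = np.random.default_rng(seed)
    rot = Rotation.random(rng=rng).as_matrix()
    trans = rng.uniform(-50, 50, size=3)
    out = Structure()
    for res in structure.residues.values():
        out.add(Residue(res.chain, res.index, res.code,
                        {n: rot @ p + trans for n, p in res.atoms.items()}))
    return out


# ---------------------------------------------------------------------------
# concordance scenarios

def gen_concordance_scenario(
    n_groups: int,
    p_concordant: float,
    p_partial: float,
    seed: int,
) -> tuple[list[OrderingChain], list[OrderingChain], list[str]]:
    """Generate clinical/structural chain pairs with known comparison status.

    Statuses are drawn with the given probabilities (remainder discordant).
    A partial pair differs by one strictness flip (``>`` vs ``=``); a
    discordant pair swaps two adjacent labels across a strict relation.
    Returns ``(clinical_chains, structural_chains, truth_statuses)``.
    """
    if p_concordant < 0 or p_partial < 0 or p_concordant + p_partial > 1:
        raise ValidationError("probabilities must be non-negative and sum <= 1")
    rng = np.random.default_rng(seed)
    clinical: list[OrderingChain] = []
    structural: list[OrderingChain] = []
    truth: list[str] = []
    for _ in range(n_groups):
        u = rng.random()
        status = ("concordant" if u < p_concordant
                  else "partial" if u < p_concordant + p_partial
                  else "discordant")
        n_labels = int(rng.integers(2, 5))
        labels = tuple(_AA[int(i)] for i in rng.choice(len(_AA), n_labels, replace=False))
        relations = list(RELATIONS[int(i)] for i in rng.integers(0, 3, n_labels - 1))
        if status == "partial":
            # need a strict/equal link to flip; "≥" cannot mismatch alone
            if all(r == "≥" for r in relations):
                relations[0] = ">"
        if status == "discordant":
            if ">" not in relations:
                relations[int(rng.integers(len(relations)))] = ">"
        chain = OrderingChain(labels, tuple(relations))
        clinical.append(chain)
        if status == "concordant":
            rels = tuple(
                RELATIONS[int(rng.integers(3))] if r == "≥" else r for r in relations
            )
            structural.append(OrderingChain(labels, rels))
        elif status == "partial":
            idx = [i for i, r in enumerate(relations) if r in (">", "=")]
            k = idx[int(rng.integers(len(idx)))]
            rels = list(relations)
            rels[k] = "=" if rels[k] == ">" else ">"
            structural.append(OrderingChain(labels, tuple(rels)))
        else:
            idx = [i for i, r in enumerate(relations) if r == ">"]
            k = idx[int(rng.integers(len(idx)))]
            swapped = list(labels)
            swapped[k], swapped[k + 1] = swapped[k + 1], swapped[k]
            structural.append(OrderingChain(tuple(swapped), tuple(relations)))
        truth.append(status)
    return clinical, structural, truth
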