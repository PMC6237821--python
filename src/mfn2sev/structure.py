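"""Static residue-interaction analysis of MFN2 coordinate models.

The molecular-modelling assessment of mutation severity rests on
interactions the mutated side chains make or break: the Trp104-Trp104
aromatic stacking that over-stabilises the mutant dimer, the
His165-Glu268 / His168-Glu272 / Lys120-Glu266 dimer-interface contacts,
the long-range electrostatic pairs that hold the closed diamond-shaped
conformation together, and the hydrophobic packing around Val244/Pro251.
This module provides the static, geometry-only counterpart: it detects
salt bridges, aromatic (π) stacking and hydrophobic contacts in a PDB
coordinate file, audits the curated closure-pair network, and maps each
analysed position to its proposed pathomechanism.  It deliberately
computes no dynamics and no energies; structural severity orderings remain
user-supplied annotations that this module can support with evidence.

Default cutoffs (heavy-atom distances; models carry no hydrogens):
salt bridge 4.0 Å minimum N-O distance, stacking 5.5 Å ring-centroid
distance with interplanar angle <= 30°, hydrophobic 4.5 Å minimum
side-chain carbon-carbon distance.  Histidine counts as protonatable
(cationic) in salt-bridge detection — an approximation required by the
His165/His168 interface contacts.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np

from mfn2sev.errors import StructureError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Residue",
    "Structure",
    "InteractionEdge",
    "MechanismMap",
    "ClosurePair",
    "DEFAULT_MECHANISM_MAP",
    "DEFAULT_CLOSURE_PAIRS",
    "read_structure",
    "write_structure",
    "detect_salt_bridges",
    "detect_stacking",
    "detect_hydrophobic",
    "detect_all",
    "residue_profile",
    "check_closure_network",
    "classify_mechanism",
    "diff_profiles",
    "write_edges",
]

# ---------------------------------------------------------------------------
# containers

@dataclass
class Residue:
    """One residue: 3-letter title-case code, 1-based index, named atoms (Å)."""

    chain: str
    index: int
    code: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.index, self.code)


@dataclass
class Structure:
    """Chains of residues indexed by (chain id, residue sequence number)."""

    residues: dict[tuple[str, int], Residue] = field(default_factory=dict)

    def add(self, residue: Residue) -> None:
        key = (residue.chain, residue.index)
        if key in self.residues:
            raise StructureError(f"duplicate residue {key}")
        self.residues[key] = residue

    def get(self, chain: str, index: int) -> Residue | None:
        return self.residues.get((chain, index))

    def find_by_index(self, index: int) -> list[Residue]:
        return [r for r in self.residues.values() if r.index == index]

    def __len__(self) -> int:
        return len(self.residues)


_THREE_UPPER = {
    "ALA": "Ala", "ARG": "Arg", "ASN": "Asn", "ASP": "Asp", "CYS": "Cys",
    "GLN": "Gln", "GLU": "Glu", "GLY": "Gly", "HIS": "His", "ILE": "Ile",
    "LEU": "Leu", "LYS": "Lys", "MET": "Met", "PHE": "Phe", "PRO": "Pro",
    "SER": "Ser", "THR": "Thr", "TRP": "Trp", "TYR": "Tyr", "VAL": "Val",
}
_UPPER_THREE = {v: k for k, v in _THREE_UPPER.items()}


def read_structure(path: str | Path) -> Structure:
    """Read a single-model PDB file into a :class:`Structure`.

    Multi-model files use the first model (with a warning).  Insertion
    codes are rejected; alternate locations resolve to the highest
    occupancy, ties broken toward altloc ``A``.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot read {path}: {exc}") from None
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    if len(st) > 1:
        logger.warning("%s: %d models, using the first", path, len(st))
    model = st[0]
    out = Structure()
    n_atoms = 0
    for chain in model:
        for res in chain:
            if res.seqid.icode not in (" ", "", "\x00"):
                raise StructureError(
                    f"{path}: insertion code {res.seqid.icode!r} at "
                    f"{chain.name}{res.seqid.num} not supported"
                )
            code = _THREE_UPPER.get(res.name.upper(), res.name.capitalize())
            residue = out.get(chain.name, res.seqid.num)
            if residue is None:
                residue = Residue(chain.name, res.seqid.num, code)
                out.add(residue)
            best: dict[str, tuple[float, str, np.ndarray]] = {}
            for atom in res:
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if not np.all(np.isfinite(pos)):
                    raise StructureError(f"{path}: non-finite coordinates")
                prev = best.get(atom.name)
                cand = (atom.occ, atom.altloc or "A", pos)
                if prev is None or (cand[0], -ord(cand[1])) > (prev[0], -ord(prev[1])):
                    best[atom.name] = cand
            for name, (_, _, pos) in best.items():
                if name in residue.atoms:
                    raise StructureError(
                        f"{path}: duplicate atom {chain.name}/{res.seqid.num}/{name}"
                    )
                residue.atoms[name] = pos
                n_atoms += 1
    if n_atoms == 0:
        raise StructureError(f"{path}: no ATOM records")
    return out


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as a PDB file (coordinates to 0.001 Å)."""
    st = gemmi.Structure()
    st.name = "mfn2sev"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for (chain_id, index) in sorted(structure.residues):
        residue = structure.residues[(chain_id, index)]
        if chain_id not in chains:
            chains[chain_id] = gemmi.Chain(chain_id)
        res = gemmi.Residue()
        res.name = _UPPER_THREE.get(residue.code, residue.code.upper())
        res.seqid = gemmi.SeqId(index, " ")
        res.het_flag = "A"
        for name, pos in residue.atoms.items():
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(name[0])
            atom.pos = gemmi.Position(*map(float, pos))
            atom.occ = 1.0
            res.add_atom(atom)
        chains[chain_id].add_residue(res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# interaction detection

@dataclass(frozen=True)
class InteractionEdge:
    """A detected residue-residue interaction.

    ``residue_a``/``residue_b`` are ``(chain, index, code)`` triples in
    canonical order (sorted by chain then index), so each pair is reported
    once regardless of query direction.
    """

    kind: str  # salt_bridge | stacking | hydrophobic | hbond_proxy
    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    distance: float
    geometry: tuple[tuple[str, float], ...] = ()
    intra_or_inter: str = "intra"

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValidationError("distance must be positive")
        if self.residue_a[:2] == self.residue_b[:2]:
            raise ValidationError("self-interaction")

    def touches(self, chain: str, index: int) -> bool:
        return (chain, index) in (self.residue_a[:2], self.residue_b[:2])

    def partner(self, chain: str, index: int) -> tuple[str, int, str]:
        return self.residue_b if self.residue_a[:2] == (chain, index) else self.residue_a


def _edge(kind: str, ra: Residue, rb: Residue, distance: float,
          geometry: tuple[tuple[str, float], ...] = ()) -> InteractionEdge:
    a, b = sorted((ra.key, rb.key))
    return InteractionEdge(
        kind, a, b, float(distance), geometry,
        "intra" if ra.chain == rb.chain else "inter",
    )


#: side-chain atoms carrying the formal charge
ACIDIC_ATOMS = {"Asp": ("OD1", "OD2"), "Glu": ("OE1", "OE2")}
BASIC_ATOMS = {
    "Arg": ("NE", "NH1", "NH2"),
    "Lys": ("NZ",),
    "His": ("ND1", "NE2"),  # protonatable approximation
}

#: ring atoms; Trp uses its 6-membered ring for the centroid
RING_ATOMS = {
    "Phe": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "Tyr": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "Trp": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "His": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

APOLAR_RESIDUES = frozenset({"Ala", "Val", "Leu", "Ile", "Met", "Pro", "Phe", "Trp"})
_BACKBONE = frozenset({"N", "CA", "C", "O", "OXT"})


def _group_atoms(res: Residue, names: Sequence[str]) -> np.ndarray | None:
    coords = [res.atoms[n] for n in names if n in res.atoms]
    if not coords:
        return None
    return np.array(coords)


def _min_distance(a: np.ndarray, b: np.ndarray) -> float:
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).min())


def detect_salt_bridges(structure: Structure, cutoff: float = 4.0) -> list[InteractionEdge]:
    """Salt bridges: closest carboxylate-O to side-chain-N distance <= cutoff."""
    acids, bases = [], []
    for res in structure.residues.values():
        if res.code in ACIDIC_ATOMS:
            pts = _group_atoms(res, ACIDIC_ATOMS[res.code])
            if pts is None:
                logger.warning("%s%d %s: carboxylate atoms missing, skipped",
                               res.chain, res.index, res.code)
            else:
                acids.append((res, pts))
        if res.code in BASIC_ATOMS:
            pts = _group_atoms(res, BASIC_ATOMS[res.code])
            if pts is None:
                logger.warning("%s%d %s: basic side-chain atoms missing, skipped",
                               res.chain, res.index, res.code)
            else:
                bases.append((res, pts))
    edges = []
    for ra, pa in acids:
        for rb, pb in bases:
            if ra.key[:2] == rb.key[:2]:
                continue
            d = _min_distance(pa, pb)
            if d <= cutoff:
                edges.append(_edge("salt_bridge", ra, rb, d))
    return sorted(edges, key=lambda e: (e.residue_a, e.residue_b))


def _ring_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - centroid)
    return centroid, vt[2]  # smallest-variance direction = plane normal


def detect_stacking(
    structure: Structure, centroid_cutoff: float = 5.5, angle_max: float = 30.0
) -> list[InteractionEdge]:
    """Parallel aromatic stacking between Phe/Tyr/Trp/His rings.

    An edge requires ring-centroid distance <= ``centroid_cutoff`` and
    interplanar angle <= ``angle_max`` degrees.  Residues with incomplete
    ring atoms are skipped with a warning.
    """
    rings = []
    for res in structure.residues.values():
        if res.code not in RING_ATOMS:
            continue
        names = RING_ATOMS[res.code]
        if any(n not in res.atoms for n in names):
            logger.warning("%s%d %s: incomplete ring, skipped",
                           res.chain, res.index, res.code)
            continue
        pts = np.array([res.atoms[n] for n in names])
        rings.append((res, *_ring_plane(pts)))
    edges = []
    for i, (ra, ca, na) in enumerate(rings):
        for rb, cb, nb in rings[i + 1:]:
            d = float(np.linalg.norm(ca - cb))
            if d > centroid_cutoff:
                continue
            cosang = min(1.0, abs(float(np.dot(na, nb))))
            angle = math.degrees(math.acos(cosang))
            if angle <= angle_max:
                edges.append(_edge("stacking", ra, rb, d,
                                   (("interplanar_angle", round(angle, 3)),)))
    return sorted(edges, key=lambda e: (e.residue_a, e.residue_b))


def detect_hydrophobic(structure: Structure, cutoff: float = 4.5) -> list[InteractionEdge]:
    """Apolar side-chain carbon contacts within ``cutoff`` (one edge per pair)."""
    apolar = []
    for res in structure.residues.values():
        if res.code not in APOLAR_RESIDUES:
            continue
        pts = [p for n, p in res.atoms.items()
               if n not in _BACKBONE and n.startswith("C")]
        if pts:
            apolar.append((res, np.array(pts)))
    edges = []
    for i, (ra, pa) in enumerate(apolar):
        for rb, pb in apolar[i + 1:]:
            d = _min_distance(pa, pb)
            if d <= cutoff:
                edges.append(_edge("hydrophobic", ra, rb, d))
    return sorted(edges, key=lambda e: (e.residue_a, e.residue_b))


def detect_all(
    structure: Structure,
    salt_bridge_cutoff: float = 4.0,
    stacking_cutoff: float = 5.5,
    stacking_angle_max: float = 30.0,
    hydrophobic_cutoff: float = 4.5,
) -> list[InteractionEdge]:
    """All detectors combined, deterministically ordered."""
    edges = (
        detect_salt_bridges(structure, salt_bridge_cutoff)
        + detect_stacking(structure, stacking_cutoff, stacking_angle_max)
        + detect_hydrophobic(structure, hydrophobic_cutoff)
    )
    return sorted(edges, key=lambda e: (e.kind, e.residue_a, e.residue_b))


def residue_profile(
    structure: Structure, chain: str, position: int, **cutoffs
) -> list[InteractionEdge]:
    """All detected interactions touching one residue.

    Ordering is deterministic by (kind, partner chain, partner index);
    unknown residues raise :class:`~mfn2sev.errors.ValidationError`.
    """
    if structure.get(chain, position) is None:
        raise ValidationError(f"no residue {chain}:{position}")
    edges = [e for e in detect_all(structure, **cutoffs) if e.touches(chain, position)]
    return sorted(edges, key=lambda e: (e.kind, e.partner(chain, position)[:2]))


# ---------------------------------------------------------------------------
# curated networks

@dataclass(frozen=True)
class ClosurePair:
    """One long-range electrostatic pair maintaining the closed conformation.

    ``acidic`` may list alternative acidic partners for one basic residue
    (Asp377/Glu370 both reach Arg564); the pair is present if any of them
    bridges it.
    """

    acidic: tuple[tuple[int, str], ...]  # (position, code)
    basic: tuple[int, str]
    domains: str
    note: str = ""


#: The long-range electrostatic pairs driving MFN2 closure.
DEFAULT_CLOSURE_PAIRS: tuple[ClosurePair, ...] = (
    ClosurePair(((210, "Asp"),), (476, "Arg"), "GTPase-HR2", "tightens paddle"),
    ClosurePair(((480, "Asp"),), (243, "Lys"), "GTPase-HR2", "tightens paddle"),
    ClosurePair(((598, "Glu"),), (250, "Arg"), "GTPase-HR2", "tightens HR2"),
    ClosurePair(((542, "Glu"),), (732, "Lys"), "HR2-HR1", "tightens HR2"),
    ClosurePair(((377, "Asp"), (370, "Glu")), (564, "Arg"), "HR1-HR2", "tightens HR1"),
    ClosurePair(((359, "Glu"),), (575, "Arg"), "HR1-HR2", "tightens HR1"),
)


@dataclass(frozen=True)
class ClosureReport:
    """Per-pair presence of the closure network in one structure."""

    statuses: tuple[tuple[ClosurePair, str], ...]  # present | absent | missing_residue
    n_present: int
    n_pairs: int

    @property
    def fraction_present(self) -> float:
        return self.n_present / self.n_pairs


def check_closure_network(
    structure: Structure,
    pairs: Sequence[ClosurePair] = DEFAULT_CLOSURE_PAIRS,
    cutoff: float = 4.0,
) -> ClosureReport:
    """Audit the closure-pair network: which pairs are bridged in ``structure``.

    A pair is *present* when a salt-bridge edge links (any of) its acidic
    position(s) to its basic position; *missing_residue* when neither
    endpoint combination exists in the structure; *absent* otherwise —
    including when the residue exists but carries no carboxylate (the
    Asp210Tyr situation, which breaks the Asp210-Arg476 contact).
    """
    edges = detect_salt_bridges(structure, cutoff)
    bridged = {frozenset((e.residue_a[1], e.residue_b[1])) for e in edges}
    statuses: list[tuple[ClosurePair, str]] = []
    n_present = 0
    for pair in pairs:
        base_here = bool(structure.find_by_index(pair.basic[0]))
        acid_here = any(structure.find_by_index(p) for p, _ in pair.acidic)
        if not (base_here and acid_here):
            statuses.append((pair, "missing_residue"))
            continue
        present = any(
            frozenset((p, pair.basic[0])) in bridged for p, _ in pair.acidic
        )
        statuses.append((pair, "present" if present else "absent"))
        n_present += present
    return ClosureReport(tuple(statuses), n_present, len(pairs))


@dataclass(frozen=True)
class MechanismMap:
    """Position → pathomechanism category, with supporting evidence pairs."""

    categories: Mapping[int, str]
    evidence: Mapping[str, tuple[tuple[str, str, str], ...]] = field(
        default_factory=dict
    )  # category -> (kind, residue_a, residue_b) templates


MECHANISM_CATEGORIES = (
    "gtp_site_rearrangement",
    "dimerization",
    "hydrolysis",
    "closure",
    "unknown",
)

#: Mechanism assignment for the 11 analysed GTPase-domain positions.
DEFAULT_MECHANISM_MAP = MechanismMap(
    categories={
        277: "gtp_site_rearrangement",
        104: "dimerization",
        165: "dimerization",
        259: "dimerization",
        274: "dimerization",
        276: "dimerization",
        127: "hydrolysis",
        210: "closure",
        250: "closure",
        244: "unknown",
        251: "unknown",
    },
    evidence={
        # intramolecular cascade rearranging the GTP site after binding
        "gtp_site_rearrangement": (
            ("hbond_proxy", "His277", "Asn257"),
            ("hbond_proxy", "His277", "Cys281"),
            ("hbond_proxy", "His277", "Ser229"),
        ),
        # cross-subunit contacts formed on dimer tightening, plus the
        # mutant Trp104-Trp104 stacking that hinders dimer decomposition
        "dimerization": (
            ("salt_bridge", "His165", "Glu268"),
            ("salt_bridge", "His168", "Glu272"),
            ("salt_bridge", "Lys120", "Glu266"),
            ("stacking", "Trp104", "Trp104"),
        ),
        # Gly127 positions His128, which holds the catalytic water
        "hydrolysis": (("hbond_proxy", "Gly127", "His128"),),
        "closure": tuple(
            ("salt_bridge", f"{ac}{ap}", f"{pair.basic[1]}{pair.basic[0]}")
            for pair in DEFAULT_CLOSURE_PAIRS[:3]
            for ap, ac in pair.acidic
        ),
        # hydrophobic-core packing around Val244/Pro251
        "unknown": (("hydrophobic", "Val244", "Pro251"),),
    },
)


@dataclass(frozen=True)
class MechanismCall:
    position: int
    category: str
    mapped: bool


def classify_mechanism(
    position: int, mechanism_map: MechanismMap = DEFAULT_MECHANISM_MAP
) -> MechanismCall:
    """Look up the proposed pathomechanism for a residue position.

    Positions outside the curated map return category ``unknown`` with
    ``mapped=False`` so they are distinguishable from the curated
    unknown-mechanism positions (Val244, Pro251).
    """
    if position in mechanism_map.categories:
        return MechanismCall(position, mechanism_map.categories[position], True)
    return MechanismCall(position, "unknown", False)


def diff_profiles(
    wild: Structure, mutant: Structure, chain: str, position: int, **cutoffs
) -> tuple[list[InteractionEdge], list[InteractionEdge]]:
    """Interactions lost and gained at one residue between two structures.

    The structures must share residue numbering and residue identity at
    every position except the mutated one.  Edges are matched by
    (kind, partner chain, partner index); returns ``(lost, gained)`` where
    *lost* edges exist only in ``wild`` and *gained* only in ``mutant``.
    """
    for key, res in wild.residues.items():
        other = mutant.residues.get(key)
        if other is None or (key != (chain, position) and other.code != res.code):
            raise ValidationError(
                f"numbering/identity mismatch at {key} beyond mutated "
                f"{chain}:{position}"
            )
    for key in mutant.residues:
        if key not in wild.residues:
            raise ValidationError(f"extra residue {key} in mutant")

    def keyed(structure: Structure) -> dict[tuple, InteractionEdge]:
        return {
            (e.kind, e.partner(chain, position)[:2]): e
            for e in residue_profile(structure, chain, position, **cutoffs)
        }

    w, m = keyed(wild), keyed(mutant)
    lost = [w[k] for k in sorted(set(w) - set(m))]
    gained = [m[k] for k in sorted(set(m) - set(w))]
    return lost, gained


def write_edges(edges: Iterable[InteractionEdge], path: str | Path) -> None:
    """Write an edge table as tab-delimited text."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["kind", "chain_a", "res_a", "code_a", "chain_b", "res_b",
                         "code_b", "distance", "span", "geometry"])
        for e in edges:
            geo = ";".join(f"{k}={v:g}" for k, v in e.geometry)
            writer.writerow([e.kind, e.residue_a[0], e.residue_a[1], e.residue_a[2],
                             e.residue_b[0], e.residue_b[1], e.residue_b[2],
                             f"{e.distance:.3f}", e.intra_or_inter, geo])
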