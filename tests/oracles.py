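"""Independent brute-force oracles used by the property and acceptance tests.

These re-derive expected results from first principles (exhaustive loops,
hand-coded chemical definitions) without calling the implementation paths
they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# --- grouping ---------------------------------------------------------------

def bucket_groups(records):
    """All-pairs position bucketing: position -> (wt, sorted distinct alts)."""
    buckets = {}
    for r in records:
        buckets.setdefault(r.position, []).append(r)
    out = {}
    for pos, recs in buckets.items():
        alts = []
        for r in recs:
            if r.alt not in alts:
                alts.append(r.alt)
        if len(alts) >= 2:
            out[pos] = (recs[0].wt, tuple(alts))
    return out


# --- chain comparison -------------------------------------------------------

def chain_pair_relation(chain, a, b):
    """Composed relation from a to b by scanning the serialized chain."""
    ia, ib = chain.labels.index(a), chain.labels.index(b)
    lo, hi = min(ia, ib), max(ia, ib)
    span = chain.relations[lo:hi]
    rel = ">" if ">" in span else ("≥" if "≥" in span else "=")
    if ia > ib and rel != "=":
        rel = {"<": ">", ">": "<", "≥": "≤"}[rel] if rel == ">" else "≤"
    return rel


def compare_status_oracle(clinical, structural):
    """Status by enumerating every adjacent clinical pair independently."""
    reversal = False
    mismatch = False
    for i in range(len(clinical.labels) - 1):
        a, b = clinical.labels[i], clinical.labels[i + 1]
        c = clinical.relations[i]
        s = chain_pair_relation(structural, a, b)
        ok = (c == s) or (c == "≥" and s in (">", "="))
        if not ok:
            mismatch = True
            if s in ("<", "≤") and c in (">", "≥"):
                reversal = True
    if reversal:
        return "discordant"
    return "partial" if mismatch else "concordant"


# --- interaction detectors --------------------------------------------------

_ACID = {"Asp": {"OD1", "OD2"}, "Glu": {"OE1", "OE2"}}
_BASE = {"Arg": {"NE", "NH1", "NH2"}, "Lys": {"NZ"}, "His": {"ND1", "NE2"}}
_RING = {
    "Phe": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "Tyr": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "Trp": ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "His": ["CG", "ND1", "CD2", "CE1", "NE2"],
}
_APOLAR = {"Ala", "Val", "Leu", "Ile", "Met", "Pro", "Phe", "Trp"}
_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def _residues(structure):
    return list(structure.residues.values())


def salt_bridge_oracle(structure, cutoff=4.0):
    """Exhaustive all-atom-pair scan for carboxylate-O to basic-N contacts."""
    found = set()
    for ra, rb in itertools.permutations(_residues(structure), 2):
        if ra.code not in _ACID or rb.code not in _BASE:
            continue
        best = math.inf
        for na, pa in ra.atoms.items():
            if na not in _ACID[ra.code]:
                continue
            for nb, pb in rb.atoms.items():
                if nb not in _BASE[rb.code]:
                    continue
                best = min(best, float(np.linalg.norm(pa - pb)))
        if best <= cutoff:
            pair = tuple(sorted((ra.key, rb.key)))
            found.add((pair, round(best, 6)))
    return found


def _plane_normal(points):
    c = points.mean(axis=0)
    # normal from cross products of ring spokes, averaged
    n = np.zeros(3)
    for i in range(len(points)):
        v1 = points[i] - c
        v2 = points[(i + 1) % len(points)] - c
        n += np.cross(v1, v2)
    return n / np.linalg.norm(n)


def stacking_oracle(structure, centroid_cutoff=5.5, angle_max=30.0):
    """Exhaustive ring-pair scan with an explicit normal-vector computation."""
    rings = []
    for r in _residues(structure):
        if r.code in _RING and all(n in r.atoms for n in _RING[r.code]):
            pts = np.array([r.atoms[n] for n in _RING[r.code]])
            rings.append((r, pts.mean(axis=0), _plane_normal(pts)))
    found = set()
    for (ra, ca, na), (rb, cb, nb) in itertools.combinations(rings, 2):
        d = float(np.linalg.norm(ca - cb))
        ang = math.degrees(math.acos(min(1.0, abs(float(np.dot(na, nb))))))
        if d <= centroid_cutoff and ang <= angle_max:
            found.add((tuple(sorted((ra.key, rb.key))), round(d, 6)))
    return found


def hydrophobic_oracle(structure, cutoff=4.5):
    """Exhaustive apolar side-chain carbon-carbon scan."""
    found = set()
    for ra, rb in itertools.combinations(_residues(structure), 2):
        if ra.code not in _APOLAR or rb.code not in _APOLAR:
            continue
        best = math.inf
        for na, pa in ra.atoms.items():
            if na in _BACKBONE or not na.startswith("C"):
                continue
            for nb, pb in rb.atoms.items():
                if nb in _BACKBONE or not nb.startswith("C"):
                    continue
                best = min(best, float(np.linalg.norm(pa - pb)))
        if best <= cutoff:
            found.add((tuple(sorted((ra.key, rb.key))), round(best, 6)))
    return found


def edge_set(edges):
    """Canonical comparable form of a detector's edge list."""
    return {((e.residue_a, e.residue_b), round(e.distance, 6)) for e in edges}
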