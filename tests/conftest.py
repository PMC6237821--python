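import numpy as np
import pytest

from mfn2sev.catalog import MutationRecord
from mfn2sev.pipeline import run_paper_reproduction

#: reference severity scores for all 26 bundled mutations (points, min/max)
REFERENCE_SCORES = {
    "p.Arg104Gln": (0.0, 0.0),
    "p.Arg104Trp": (5.5, 6.0),
    "p.Gly127Asp": (3.0, 3.0),
    "p.Gly127Val": (0.5, 1.0),
    "p.His165Arg": (2.0, 2.0),
    "p.His165Asp": (3.0, 3.5),
    "p.His165Leu": (1.0, 1.0),
    "p.His165Tyr": (1.0, 1.0),
    "p.Asp210Val": (7.0, 7.0),
    "p.Asp210Tyr": (7.0, 7.0),
    "p.Val244Leu": (2.0, 2.0),
    "p.Val244Met": (1.5, 1.5),
    "p.Arg250Gln": (0.5, 1.0),
    "p.Arg250Trp": (1.0, 1.5),
    "p.Pro251Ala": (1.5, 1.5),
    "p.Pro251Arg": (2.5, 2.5),
    "p.Pro251Leu": (0.5, 0.5),
    "p.Arg259Cys": (2.0, 2.0),
    "p.Arg259Leu": (2.5, 2.5),
    "p.Arg259His": (1.0, 1.0),
    "p.Arg274Gln": (1.0, 1.0),
    "p.Arg274Trp": (3.0, 3.0),
    "p.Gln276Arg": (2.0, 2.0),
    "p.Gln276His": (2.0, 2.0),
    "p.His277Arg": (1.0, 1.0),
    "p.His277Tyr": (3.5, 3.5),
}

#: reference per-position clinical severity chains
REFERENCE_CHAINS = {
    104: "Trp > Gln",
    127: "Asp > Val",
    165: "Asp > Arg > Leu = Tyr",
    210: "Tyr = Val",
    244: "Leu ≥ Met",
    250: "Trp > Gln",
    251: "Arg > Ala > Leu",
    259: "Leu ≥ Cys > His",
    274: "Trp > Gln",
    276: "Arg = His",
    277: "Tyr > Arg",
}

#: expected group sizes per residue position
REFERENCE_GROUP_SIZES = {
    104: 2, 127: 2, 165: 4, 210: 2, 244: 2, 250: 2,
    251: 3, 259: 3, 274: 2, 276: 2, 277: 2,
}


@pytest.fixture(scope="session")
def reproduction_report():
    return run_paper_reproduction()


def random_catalog(rng: np.random.Generator, max_records: int = 50):
    """Random well-formed catalogue: consistent wild type per position."""
    from mfn2sev._aa import CANONICAL_3

    aa = sorted(CANONICAL_3)
    n = int(rng.integers(0, max_records + 1))
    wt_at: dict[int, str] = {}
    records = []
    for _ in range(n):
        pos = int(rng.integers(1, 40))
        wt = wt_at.setdefault(pos, aa[int(rng.integers(20))])
        alt = aa[int(rng.integers(20))]
        if alt == wt:
            continue
        records.append(MutationRecord(pos, wt, alt))
    return records
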