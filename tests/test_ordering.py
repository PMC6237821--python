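"""Ordering chains: parsing, derivation from scores, comparison, concordance."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import compare_status_oracle

from mfn2sev._aa import CANONICAL_3
from mfn2sev.catalog import MutationGroup
from mfn2sev.errors import ParseError, ValidationError
from mfn2sev.ordering import (
    OrderingChain,
    chain_from_scores,
    compare_chains,
    concordance_summary,
    derive_clinical_chain,
    parse_chain,
    predictor_compatibility,
    read_chain_table,
)
from mfn2sev.pipeline import _data_path
from mfn2sev.scoring import SeverityScore

AA = sorted(CANONICAL_3)

chains = st.lists(
    st.sampled_from(AA), min_size=1, max_size=6, unique=True
).flatmap(
    lambda labels: st.lists(
        st.sampled_from((">", "≥", "=")),
        min_size=len(labels) - 1, max_size=len(labels) - 1,
    ).map(lambda rels: OrderingChain(tuple(labels), tuple(rels)))
)


class TestParseChain:
    @pytest.mark.parametrize(
        "text,labels,relations",
        [
            ("Asp > Arg > Leu = Tyr", ("Asp", "Arg", "Leu", "Tyr"), (">", ">", "=")),
            ("Trp", ("Trp",), ()),
            ("Leu ≥ Met", ("Leu", "Met"), ("≥",)),
            ("Leu >= Met", ("Leu", "Met"), ("≥",)),
            ("Trp>Gln", ("Trp", "Gln"), (">",)),
        ],
    )
    def test_valid(self, text, labels, relations):
        c = parse_chain(text)
        assert c.labels == labels and c.relations == relations

    @pytest.mark.parametrize("text", ["Trp > Trp", "Trp >", "> Gln", "A > > B", ""])
    def test_rejects(self, text):
        with pytest.raises(ParseError):
            parse_chain(text)

    @given(chains)
    def test_round_trip(self, chain):
        assert parse_chain(chain.serialize()) == chain


def _scores(**kw):
    return {k: SeverityScore(lo, hi) for k, (lo, hi) in kw.items()}


class TestDeriveClinicalChain:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            (_scores(Asp=(3, 3.5), Arg=(2, 2), Leu=(1, 1), Tyr=(1, 1)),
             "Asp > Arg > Leu = Tyr"),
            (_scores(Leu=(2, 2), Met=(1.5, 1.5)), "Leu ≥ Met"),
            (_scores(Trp=(1, 1.5), Gln=(0.5, 1)), "Trp > Gln"),
            (_scores(Tyr=(7, 7), Val=(7, 7)), "Tyr = Val"),
            (_scores(Xaa=(2, 2)), "Xaa"),
        ],
    )
    def test_examples(self, scores, expected):
        assert derive_clinical_chain(scores).serialize() == expected

    def test_interval_gap_of_half_point_stays_strict(self):
        # only two *point* scores 0.5 apart soften to ">="
        chain = derive_clinical_chain(_scores(Trp=(1, 1.5), Gln=(0.5, 1)))
        assert chain.relations == (">",)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            derive_clinical_chain({})


class TestCompareChains:
    @pytest.mark.parametrize(
        "clinical,structural,status",
        [
            ("Tyr = Val", "Tyr > Val", "partial"),
            ("Trp > Gln", "Trp > Gln", "concordant"),
            ("Leu ≥ Met", "Leu = Met", "concordant"),
            ("Leu ≥ Met", "Leu > Met", "concordant"),
            ("Ala > Val", "Val > Ala", "discordant"),
            ("Arg > Ala > Leu", "Arg > Ala = Leu", "partial"),
            ("Leu ≥ Cys > His", "Leu = Cys > His", "concordant"),
        ],
    )
    def test_examples(self, clinical, structural, status):
        cmp = compare_chains(parse_chain(clinical), parse_chain(structural))
        assert cmp.status == status
        assert (cmp.status == "concordant") == (not cmp.mismatched_pairs)

    def test_label_set_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compare_chains(parse_chain("Ala > Val"), parse_chain("Ala > Gly"))

    @given(chains)
    def test_self_comparison_is_concordant(self, chain):
        assert compare_chains(chain, chain).status == "concordant"

    def test_matches_pairwise_relation_oracle(self):
        rng = np.random.default_rng(31)
        rels = (">", "≥", "=")
        for _ in range(500):
            n = int(rng.integers(2, 6))
            labels = [AA[i] for i in rng.choice(20, n, replace=False)]
            perm = list(rng.permutation(n))
            c = OrderingChain(tuple(labels),
                              tuple(rels[i] for i in rng.integers(0, 3, n - 1)))
            s = OrderingChain(tuple(labels[i] for i in perm),
                              tuple(rels[i] for i in rng.integers(0, 3, n - 1)))
            assert compare_chains(c, s).status == compare_status_oracle(c, s)


class TestConcordanceSummary:
    def test_bundled_chain_table(self):
        rows = read_chain_table(_data_path("table2_chains.tsv"))
        comparisons = [
            compare_chains(r["clinical"], r["structural"], position=r["position"])
            for r in rows
        ]
        s = concordance_summary(comparisons)
        assert (s.n_groups, s.n_concordant, s.agreement_percent) == (11, 8, 73)
        mismatched = {c.position for c in comparisons if c.status != "concordant"}
        assert mismatched == {210, 251, 277}
        assert all(c.status == "partial" for c in comparisons
                   if c.position in mismatched)

    def test_all_concordant(self):
        c = parse_chain("Ala > Val")
        s = concordance_summary([compare_chains(c, c)] * 3)
        assert (s.n_groups, s.n_concordant, s.agreement_percent) == (3, 3, 100)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            concordance_summary([])

    def test_invariant_to_group_order(self):
        rows = read_chain_table(_data_path("table2_chains.tsv"))
        comparisons = [compare_chains(r["clinical"], r["structural"]) for r in rows]
        rng = np.random.default_rng(1)
        shuffled = [comparisons[i] for i in rng.permutation(len(comparisons))]
        assert concordance_summary(shuffled) == concordance_summary(comparisons)


class TestPredictorCompatibility:
    def _setup(self):
        groups = [MutationGroup(1, "Ala", ("Val", "Gly")),
                  MutationGroup(2, "Ser", ("Leu", "Thr"))]
        clinical = {1: parse_chain("Val > Gly"), 2: parse_chain("Leu > Thr")}
        return groups, clinical

    def test_identical_scores_give_zero_unless_all_equal(self):
        groups, clinical = self._setup()
        scores = {"tool": {lbl: 1.0 for g in groups for lbl in g.labels}}
        assert predictor_compatibility(scores, groups, clinical) == {"tool": 0}

    def test_one_concordant_one_reversed(self):
        groups, clinical = self._setup()
        scores = {"tool": {"p.Ala1Val": 2, "p.Ala1Gly": 1,
                           "p.Ser2Leu": 1, "p.Ser2Thr": 2}}
        assert predictor_compatibility(scores, groups, clinical) == {"tool": 50}

    def test_scores_replicating_structural_chains_give_73_percent(self):
        from mfn2sev.pipeline import run_paper_reproduction

        report = run_paper_reproduction()
        rows = {r["position"]: r["structural"]
                for r in read_chain_table(_data_path("table2_chains.tsv"))}
        # turn each structural chain into numeric ranks (ties equal)
        scores: dict[str, float] = {}
        for g in report.groups:
            chain = rows[g.position]
            rank = float(len(chain.labels))
            value = {chain.labels[0]: rank}
            for rel, label in zip(chain.relations, chain.labels[1:]):
                if rel != "=":
                    rank -= 1.0
                value[label] = rank
            for alt, lbl in zip(g.alts, g.labels):
                scores[lbl] = value[alt]
        result = predictor_compatibility({"synthetic_tool": scores},
                                         report.groups, report.clinical_chains)
        assert result == {"synthetic_tool": 73}

    def test_missing_score_raises(self):
        groups, clinical = self._setup()
        with pytest.raises(ValidationError, match="p.Ala1Gly"):
            predictor_compatibility({"t": {"p.Ala1Val": 1.0, "p.Ser2Leu": 1,
                                           "p.Ser2Thr": 0}}, groups, clinical)

    def test_ties_give_equals_in_chain(self):
        assert chain_from_scores({"Ala": 1.0, "Val": 1.0}).serialize() == "Ala = Val"
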