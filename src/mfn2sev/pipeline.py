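"""End-to-end orchestration: catalogue → scores → orderings → concordance.

The reference run (:func:`run_paper_reproduction`) works entirely from
fixtures bundled with the package: the 26-mutation GTPase-domain
catalogue, the matching structured clinical records, and the per-position
structural severity annotations.  Custom runs take the same inputs from
user files and may skip the concordance stage when no structural
annotations are provided.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from mfn2sev._version import __version__ as _version
from mfn2sev import catalog as cat
from mfn2sev import ordering as ordmod
from mfn2sev import scoring as sco
from mfn2sev.errors import Mfn2sevError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_paper_reproduction", "run_custom"]

_DATA = resources.files("mfn2sev") / "data"


def _data_path(name: str) -> Path:
    return Path(str(_DATA / name))


def verify_checksums() -> None:
    """Check bundled fixtures against their recorded SHA-256 digests."""
    sums = json.loads(_data_path("checksums.json").read_text())
    for name, expected in sums.items():
        digest = hashlib.sha256(_data_path(name).read_bytes()).hexdigest()
        if digest != expected:
            raise Mfn2sevError(f"fixture {name} corrupted: checksum mismatch")


@dataclass
class RunConfig:
    """Inputs and options of a custom pipeline run."""

    catalog_path: str | Path
    clinical_path: str | Path
    structural_path: str | Path | None = None
    domain: cat.DomainRange = cat.DEFAULT_DOMAIN
    exclusions: cat.ExclusionList = field(default_factory=lambda: cat.DEFAULT_EXCLUSIONS)
    rules: dict[str, sco.ScoreRule] = field(default_factory=lambda: dict(sco.DEFAULT_RULES))
    output_dir: str | Path | None = None

    def validate(self) -> None:
        for p in (self.catalog_path, self.clinical_path, self.structural_path):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")


@dataclass
class RunReport:
    """Everything one pipeline run produced, with per-stage counts."""

    n_input: int
    n_in_domain: int
    n_after_exclusions: int
    groups: list[cat.MutationGroup]
    removal_log: list[tuple[str, str]]
    scores: dict[str, sco.SeverityScore]
    clinical_chains: dict[int, ordmod.OrderingChain]
    comparisons: list[ordmod.GroupComparison]
    summary: ordmod.ConcordanceSummary | None
    version: str = _version
    notes: list[str] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_grouped_mutations(self) -> int:
        return sum(g.size for g in self.groups)


def _run(
    records: list[cat.MutationRecord],
    clinical: list[sco.ClinicalRecord],
    structural: list[dict] | None,
    domain: cat.DomainRange,
    exclusions: cat.ExclusionList,
    rules,
) -> RunReport:
    n_input = len(records)
    records = cat.dedupe_records(records)
    in_domain = cat.filter_domain(records, domain)
    kept, removal_log = cat.apply_exclusions(in_domain, exclusions)
    groups = cat.group_by_position(kept)

    scores = sco.score_table(clinical, rules)

    chains: dict[int, ordmod.OrderingChain] = {}
    notes: list[str] = []
    for g in groups:
        group_scores = {}
        for alt, label in zip(g.alts, g.labels):
            if label not in scores:
                raise ValidationError(f"no clinical record for {label}")
            group_scores[alt] = scores[label]
        chains[g.position] = ordmod.derive_clinical_chain(group_scores)

    comparisons: list[ordmod.GroupComparison] = []
    summary = None
    if structural is not None:
        by_pos = {row["position"]: row["structural"] for row in structural}
        for g in groups:
            if g.position not in by_pos:
                raise ValidationError(f"no structural chain for position {g.position}")
            comparisons.append(
                ordmod.compare_chains(chains[g.position], by_pos[g.position],
                                      position=g.position)
            )
        summary = ordmod.concordance_summary(comparisons) if comparisons else None
    else:
        notes.append("no structural annotations: concordance stage skipped")

    report = RunReport(
        n_input=n_input,
        n_in_domain=len(in_domain),
        n_after_exclusions=len(kept),
        groups=groups,
        removal_log=removal_log,
        scores=scores,
        clinical_chains=chains,
        comparisons=comparisons,
        summary=summary,
        notes=notes,
    )
    logger.info("pipeline: %d records in, %d in domain, %d after exclusions, "
                "%d groups", n_input, len(in_domain), len(kept), len(groups))
    return report


def run_paper_reproduction() -> RunReport:
    """Run the pipeline on the bundled reference fixtures.

    Deterministic; expected outcome: 26 mutations in 11 groups, the
    reference severity scores (including the five interval scores), 11
    derived clinical chains, and a concordance summary of 8/11 fully
    concordant positions (73%), the remaining three (210, 251, 277)
    partial.
    """
    verify_checksums()
    records = cat.read_catalog(_data_path("table1_catalog.tsv"))
    clinical = sco.read_clinical_records(_data_path("table1_clinical.tsv"))
    structural = ordmod.read_chain_table(_data_path("table2_chains.tsv"))
    return _run(records, clinical, structural,
                cat.DEFAULT_DOMAIN, cat.DEFAULT_EXCLUSIONS, sco.DEFAULT_RULES)


def run_custom(config: RunConfig) -> RunReport:
    """Run the pipeline on user inputs; writes stage outputs if requested.

    With no structural-chain file the concordance stage is skipped with a
    notice.  An empty catalogue yields a graceful empty report.
    """
    config.validate()
    records = cat.read_catalog(config.catalog_path)
    clinical = sco.read_clinical_records(config.clinical_path)
    structural = (
        ordmod.read_chain_table(config.structural_path)
        if config.structural_path is not None
        else None
    )
    report = _run(records, clinical, structural,
                  config.domain, config.exclusions, config.rules)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        cat.write_groups(report.groups, out / "groups.tsv")
        sco.write_scores(report.scores, out / "scores.tsv")
        ordmod.write_comparisons(report.comparisons, out / "comparisons.tsv")
        (out / "summary.json").write_text(json.dumps(report_summary(report), indent=2))
    return report


def report_summary(report: RunReport) -> dict:
    """JSON-serializable digest of a run report."""
    return {
        "version": report.version,
        "n_input": report.n_input,
        "n_in_domain": report.n_in_domain,
        "n_after_exclusions": report.n_after_exclusions,
        "n_groups": report.n_groups,
        "n_grouped_mutations": report.n_grouped_mutations,
        "scores": {k: str(v) for k, v in report.scores.items()},
        "clinical_chains": {p: str(c) for p, c in report.clinical_chains.items()},
        "statuses": {c.position: c.status for c in report.comparisons},
        "concordance": (
            None
            if report.summary is None
            else {
                "n_groups": report.summary.n_groups,
                "n_concordant": report.summary.n_concordant,
                "n_partial": report.summary.n_partial,
                "n_discordant": report.summary.n_discordant,
                "agreement_percent": report.summary.agreement_percent,
            }
        ),
        "notes": report.notes,
    }
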