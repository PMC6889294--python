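"""Hierarchical assignment of samples to the four prognostic biotypes.

The hierarchy mirrors clinical precedence: a retained POLE
exonuclease-domain mutation assigns POLE (ultramutated, best prognosis)
regardless of MSI status; otherwise MSI-High assigns MSI (hypermutated);
everything else is split into copy-number low (CNL) vs copy-number high
(CNH) by the 12-gene random-forest surrogate.  The result is always a
partition — every sample lands in exactly one group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .panel import MutationProfile, VariantRecord, protein_residue

logger = logging.getLogger(__name__)

Group = Literal["POLE", "MSI", "CNL", "CNH"]
GROUPS: tuple[Group, ...] = ("POLE", "MSI", "CNL", "CNH")

#: exonuclease (proofreading) domain of DNA polymerase epsilon, protein
#: residues — the standard literature convention; configurable
DEFAULT_DOMAIN = (268, 471)
DEFAULT_HOTSPOTS = frozenset({"p.P286R", "p.V411L"})


@dataclass(frozen=True)
class PoleRule:
    """Residue bounds and hotspot set defining a POLE-driving mutation."""

    domain_start: int = DEFAULT_DOMAIN[0]
    domain_end: int = DEFAULT_DOMAIN[1]
    hotspots: frozenset[str] = DEFAULT_HOTSPOTS
    #: when True, any retained POLE mutation (not only exonuclease-domain)
    #: triggers the POLE branch — sensitivity-analysis mode
    any_pole: bool = False

    def __post_init__(self) -> None:
        if not self.domain_start < self.domain_end:
            raise ValueError("domain_start must be < domain_end")
        for h in self.hotspots:
            res = protein_residue(h)
            if res is None or not self.domain_start <= res <= self.domain_end:
                raise ValueError(f"hotspot {h} outside exonuclease domain")


@dataclass
class SubgroupAssignment:
    sample_id: str
    group: Group
    rule_fired: Literal["pole_domain", "msi_high", "rf_cnl", "rf_cnh"]
    rf_vote_fraction: float | None = None

    def __post_init__(self) -> None:
        if (self.group == "POLE") != (self.rule_fired == "pole_domain"):
            raise ValueError("POLE group iff pole_domain rule")
        if self.group in ("CNL", "CNH") and self.rf_vote_fraction is None:
            raise ValueError("CN assignments must record the forest vote")


def detect_pole_domain_mutation(
    variants: Sequence[VariantRecord],
    rule: PoleRule | None = None,
) -> tuple[bool, bool]:
    """(domain_mutated, hotspot) from a sample's *retained* variants.

    POLE variants without a parseable HGVS-p residue are excluded from the
    domain test (logged), so a malformed annotation can never assign POLE.
    """
    rule = rule or PoleRule()
    domain = hotspot = False
    for v in variants:
        if v.gene != "POLE":
            continue
        res = protein_residue(v.protein_change)
        if res is None:
            if v.protein_change:
                logger.warning("unparseable POLE HGVS-p %r for %s; excluded "
                               "from domain test", v.protein_change, v.sample_id)
            if rule.any_pole:
                domain = True
            continue
        if rule.domain_start <= res <= rule.domain_end or rule.any_pole:
            domain = True
            if v.protein_change.strip() in rule.hotspots:
                hotspot = True
    return domain, hotspot


def assign_subgroup(
    profile: MutationProfile,
    msi_status: str,
    rf=None,
) -> SubgroupAssignment:
    """Assign one sample by the POLE -> MSI -> forest hierarchy.

    ``rf`` is a trained :class:`~ecsubtype.rf.RfModel`; it is consulted only
    when neither rule branch fires.  MSI-indeterminate samples fall through
    to the forest branch with a warning (keeps the partition total).
    """
    if profile.pole_exonuclease_mutated:
        return SubgroupAssignment(profile.sample_id, "POLE", "pole_domain")
    if msi_status == "MSI-H":
        return SubgroupAssignment(profile.sample_id, "MSI", "msi_high")
    if msi_status == "indeterminate":
        logger.warning("sample %s has indeterminate MSI status; falling "
                       "through to the copy-number branch", profile.sample_id)
    if rf is None:
        raise ValueError(
            f"sample {profile.sample_id} reaches the copy-number branch but "
            "no trained forest was supplied"
        )
    label, vote = rf.predict_one(profile.gene_status)
    rule = "rf_cnh" if label == "CNH" else "rf_cnl"
    return SubgroupAssignment(profile.sample_id, label, rule, rf_vote_fraction=vote)


@dataclass
class CohortClassification:
    assignments: list[SubgroupAssignment]
    summary: dict = field(default_factory=dict)

    def group_of(self, sample_id: str) -> Group:
        for a in self.assignments:
            if a.sample_id == sample_id:
                return a.group
        raise KeyError(sample_id)


def classify_cohort(
    profiles: Mapping[str, MutationProfile],
    msi_status: Mapping[str, str],
    rf=None,
) -> CohortClassification:
    """Classify every sample; raises a named-sample error on missing MSI.

    The summary reports n, exact fraction and 1-decimal percent per group
    (exact fractions avoid rounding ambiguity in small cohorts).
    """
    assignments: list[SubgroupAssignment] = []
    for sid in sorted(profiles):
        if sid not in msi_status:
            raise ValueError(f"sample {sid} lacks an MSI status")
        assignments.append(assign_subgroup(profiles[sid], msi_status[sid], rf))
    extra = set(msi_status) - set(profiles)
    if extra:
        raise ValueError(f"samples with MSI status but no profile: {sorted(extra)}")

    n = len(assignments)
    summary = {"n": n, "groups": {}}
    for g in GROUPS:
        k = sum(1 for a in assignments if a.group == g)
        summary["groups"][g] = {
            "n": k, "fraction": k / n if n else 0.0,
            "percent": round(100.0 * k / n, 1) if n else 0.0,
        }
    return CohortClassification(assignments=assignments, summary=summary)


def write_assignments(result: CohortClassification, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "group", "rule_fired", "rf_vote_fraction"])
        for a in result.assignments:
            w.writerow([a.sample_id, a.group, a.rule_fired,
                        "" if a.rf_vote_fraction is None else f"{a.rf_vote_fraction:.4f}"])


__all__ = [
    "Group", "GROUPS", "PoleRule", "SubgroupAssignment",
    "detect_pole_domain_mutation", "assign_subgroup", "classify_cohort",
    "CohortClassification", "write_assignments",
]
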