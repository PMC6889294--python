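"""Cohort report assembly: wire the pipeline stages together and emit a
JSON/TSV bundle (group sizes, per-gene frequencies, mutational load, model
performance, survival results) with full provenance."""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import classify_cohort, write_assignments
from .msi import MsiParams, call_sample
from .panel import (FilterLog, FilterPolicy, GenePanel, apply_quality_filters,
                    dichotomize_genes, mutational_load, read_variant_table,
                    write_profile_table)
from .stats import logrank_test, survival_records_from_frame

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run; the seed is recorded in
    every output."""

    variants_path: Path
    msi_path: Path
    out_dir: Path
    survival_path: Path | None = None
    clinical_path: Path | None = None
    model_path: Path | None = None
    seed: int = 0
    policy: FilterPolicy = field(default_factory=FilterPolicy)
    msi_params: MsiParams = field(default_factory=MsiParams)
    use_truth_cn_labels: bool = False

    def validate(self) -> None:
        for p in (self.variants_path, self.msi_path, self.survival_path,
                  self.clinical_path, self.model_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _msi_statuses(msi_path: Path, params: MsiParams) -> dict[str, str]:
    rows = pd.read_csv(msi_path, sep="\t")
    statuses: dict[str, str] = {}
    for sid, sub in rows.groupby("sample_id"):
        tissues: dict[str, dict[str, dict[int, float]]] = {"tumor": {}, "normal": {}}
        for r in sub.itertuples():
            hist = tissues[r.tissue].setdefault(r.marker, {})
            hist[int(r.length_bp)] = hist.get(int(r.length_bp), 0.0) + float(r.height)
        statuses[str(sid)] = call_sample(str(sid), tissues["tumor"],
                                         tissues["normal"], params=params).msi_status
    return statuses


def run_report(config: RunConfig, rf=None) -> dict:
    """Run filters -> dichotomization -> MSI -> hierarchy -> statistics and
    write the report bundle.  Deterministic given inputs and seed.

    With ``use_truth_cn_labels`` (requires a clinical table with a
    ``truth_group`` column) the copy-number branch uses the generative
    truth labels instead of a forest — the audit mode for synthetic
    cohorts.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    variants = read_variant_table(config.variants_path, dialect="tsv")
    if not variants:
        raise ValueError("empty cohort: no variant rows")
    raw_counts = Counter(v.sample_id for v in variants)
    flog = FilterLog()
    retained = apply_quality_filters(variants, config.policy, flog)
    profiles = dichotomize_genes(retained, raw_counts=dict(raw_counts))
    msi_status = _msi_statuses(Path(config.msi_path), config.msi_params)

    if config.use_truth_cn_labels:
        if config.clinical_path is None:
            raise ValueError("truth-label mode requires a clinical table")
        clin = pd.read_csv(config.clinical_path, sep="\t")
        truth = dict(zip(clin["sample_id"].astype(str), clin["truth_group"]))
        classification = _classify_with_truth(profiles, msi_status, truth)
    else:
        classification = classify_cohort(profiles, msi_status, rf)

    panel = GenePanel()
    n = len(profiles)
    gene_freq = {
        g: {"n": int(sum(p.gene_status[g] for p in profiles.values())),
            "percent": round(100.0 * sum(p.gene_status[g] for p in profiles.values()) / n, 1)}
        for g in panel.genes
    }
    load_retained = mutational_load(profiles.values(), by="retained")
    load_raw = mutational_load(profiles.values(), by="raw")

    report = {
        "provenance": {"version": __version__, "seed": config.seed,
                       "variants": str(config.variants_path),
                       "msi": str(config.msi_path)},
        "n_samples": n,
        "filter_log": {"input": flog.n_input, "retained": flog.n_retained,
                       "rejected": dict(flog.rejected)},
        "gene_frequencies": gene_freq,
        "mutational_load": {
            "retained": {"median": load_retained["median"],
                         "range": list(load_retained["range"])},
            "raw": {"median": load_raw["median"],
                    "range": list(load_raw["range"])},
        },
        "msi": {
            "MSI-H": sum(1 for s in msi_status.values() if s == "MSI-H"),
            "percent": round(100.0 * sum(1 for s in msi_status.values()
                                         if s == "MSI-H") / n, 1),
        },
        "groups": classification.summary["groups"],
    }

    if config.survival_path is not None:
        surv = pd.read_csv(config.survival_path, sep="\t")
        group_of = {a.sample_id: a.group for a in classification.assignments}
        surv = surv.assign(group=surv["sample_id"].astype(str).map(group_of))
        report["survival"] = {}
        for endpoint in sorted(surv["endpoint"].unique()):
            recs = survival_records_from_frame(surv, endpoint)
            lr = logrank_test(recs)
            report["survival"][endpoint] = {
                "logrank_statistic": lr.statistic, "df": lr.df, "p": lr.p,
            }

    write_profile_table(profiles, out / "profiles.tsv")
    write_assignments(classification, out / "assignments.tsv")
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def _classify_with_truth(profiles, msi_status, truth):
    """Hierarchy with the copy-number branch resolved by truth labels."""
    from .classify import CohortClassification, GROUPS, SubgroupAssignment

    assignments = []
    for sid in sorted(profiles):
        p = profiles[sid]
        if p.pole_exonuclease_mutated:
            assignments.append(SubgroupAssignment(sid, "POLE", "pole_domain"))
        elif msi_status[sid] == "MSI-H":
            assignments.append(SubgroupAssignment(sid, "MSI", "msi_high"))
        else:
            label = truth[sid] if truth[sid] in ("CNL", "CNH") else "CNL"
            rule = "rf_cnh" if label == "CNH" else "rf_cnl"
            assignments.append(SubgroupAssignment(sid, label, rule,
                                                  rf_vote_fraction=1.0))
    n = len(assignments)
    summary = {"n": n, "groups": {}}
    for g in GROUPS:
        k = sum(1 for a in assignments if a.group == g)
        summary["groups"][g] = {"n": k, "fraction": k / n,
                                "percent": round(100.0 * k / n, 1)}
    return CohortClassification(assignments=assignments, summary=summary)


__all__ = ["RunConfig", "run_report"]
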