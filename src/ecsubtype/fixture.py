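"""Deterministic 96-sample reference fixture.

The builder constructs a cohort whose every pipeline-visible marginal
matches the study cohort exactly: truth-group sizes 16/12/48/20
(POLE/MSI/CNL/CNH), MSI-High in exactly 15 samples (3 inside the POLE
group), per-gene positive totals (PTEN 53, TP53 32, POLE 16, KRAS 9,
CTCF 26, RPL22 41, ARID1A 47, ARID5B 42), the reported group-conditional
counts, covariate margins (endometrioid 83 / serous 13; early 79 /
advanced 17; grade 45/28/23), a retained-mutation cohort median of 9.5
(range 2-64) and a raw-count median of 40 (range 13-171) with the
group-level raw medians 94/40/37/32.

Gene x covariate cross-tabs beyond PTEN x histology (satisfied exactly:
every serous sample is PTEN-negative) are best-effort: their margins are
exact but individual cells are not targeted; the manifest records each
constraint with its status.  The builder never relaxes an exact constraint
silently — :func:`check_fixture` re-reads the emitted files and recounts
everything through the actual pipeline, and the build fails listing any
violated constraint.

The builder is seed-deterministic down to the byte: the same seed always
produces identical files (cosmetic fields — positions, depths, VAFs —
come from the seeded generator; all constrained quantities are laid out
combinatorially).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import (FilterPolicy, GenePanel, apply_quality_filters,
                    dichotomize_genes, mutational_load, read_variant_table)
from .synthetic import (MARKER_LENGTHS, POLE_DOMAIN_CHANGES,
                        POLE_HOTSPOTS, CohortTable, _marker_rows)
from .panel import VariantRecord

logger = logging.getLogger(__name__)

GROUP_SIZES = {"POLE": 16, "MSI": 12, "CNL": 48, "CNH": 20}
GROUP_ORDER = ("POLE", "MSI", "CNL", "CNH")

#: per-gene mutated-sample counts within (POLE, MSI, CNL, CNH).
#: Row sums give the reported cohort totals; the MSI/CNL/CNH cells are the
#: reported group-conditional counts, POLE-group cells complete the totals.
GENE_GROUP_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "POLE":    (16, 0, 0, 0),
    "PTEN":    (14, 9, 29, 1),
    "TP53":    (6, 4, 7, 15),
    "ARID1A":  (12, 7, 24, 4),
    "ARID5B":  (12, 6, 20, 4),
    "FBXW7":   (4, 2, 4, 6),
    "PPP2R1A": (4, 1, 5, 9),
    "CTCF":    (7, 3, 15, 1),
    "CTNNB1":  (5, 3, 25, 1),
    "RPL22":   (10, 10, 19, 2),
    "KRAS":    (2, 2, 4, 1),
    "PIK3CA":  (10, 6, 24, 9),
    "PIK3R1":  (8, 4, 17, 2),
}

#: retained (filter-passing) variant counts per group, ascending; chosen so
#: the cohort median is exactly 9.5 (48th/49th order statistics 9 and 10)
#: with range 2-64
RETAINED_COUNTS = {
    "POLE": [20, 24, 28, 30, 32, 34, 36, 38, 40, 42, 44, 46, 50, 54, 58, 64],
    "MSI": [8, 9, 10, 11, 12, 13, 14, 15, 16, 18, 20, 25],
    "CNL": [4, 4, 4, 5, 5, 5, 6, 6, 6, 6, 7, 7, 7, 7, 7, 8, 8, 8, 8, 8, 8,
            9, 9, 9, 9, 9, 9, 9, 9, 9, 9, 10, 10, 10, 11, 11, 12, 12, 13, 13,
            14, 15, 16, 17, 18, 20, 24, 28],
    "CNH": [2, 3, 3, 4, 4, 5, 5, 6, 6, 7, 7, 8, 8, 9, 9, 10, 10, 11, 12, 13],
}

#: raw annotated-row counts per group, ascending; group medians are exactly
#: 94 / 40 / 37 / 32 with the observed ranges, and the cohort median is 40
RAW_COUNTS = {
    "POLE": [31, 40, 55, 62, 70, 78, 85, 92, 96, 100, 110, 120, 130, 140, 155, 171],
    "MSI": [19, 24, 28, 32, 35, 39, 41, 45, 52, 60, 75, 93],
    "CNL": [13, 15, 17, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31,
            32, 33, 33, 34, 34, 35, 35, 36, 38, 38, 40, 40, 40, 41, 42, 44,
            46, 48, 50, 52, 55, 58, 62, 66, 70, 75, 80, 90, 100, 110, 120, 138],
    "CNH": [19, 20, 21, 22, 24, 26, 27, 29, 30, 31, 33, 34, 36, 38, 40, 44,
            50, 60, 75, 96],
}

#: unstable-marker counts: 3 POLE-group samples (group indices 0, 5, 10)
#: are MSI-High alongside all 12 MSI-group samples -> 15 MSI-H of 96
POLE_MSI_OVERLAP = {0: 4, 5: 3, 10: 5}
MSI_GROUP_UNSTABLE = [3, 3, 4, 4, 5, 5, 6, 6, 7, 7, 8, 8]
#: occasional single-marker wobble in microsatellite-stable samples
MSS_UNSTABLE_CYCLE = [0, 0, 1, 0, 0, 0, 0, 1, 0, 0, 2, 0]

#: grade layout (I, II, III) per group; totals 45 / 28 / 23
GRADE_LAYOUT = {"POLE": (10, 5, 1), "MSI": (7, 4, 1),
                "CNL": (26, 16, 6), "CNH": (2, 3, 15)}
#: advanced-stage counts per group (total 17; POLE all early-stage)
ADVANCED_LAYOUT = {"POLE": 0, "MSI": 1, "CNL": 6, "CNH": 10}

#: disease-free / overall survival medians (months) per group
SURVIVAL_MEDIANS = {
    "POLE": {"DFS": 55.40, "OS": 55.40},
    "MSI": {"DFS": 38.33, "OS": 38.60},
    "CNL": {"DFS": 34.43, "OS": 42.57},
    "CNH": {"DFS": 27.70, "OS": 30.53},
}


@dataclass
class FixtureManifest:
    seed: int
    constraints: list[dict] = field(default_factory=list)
    truth_labels: dict[str, str] = field(default_factory=dict)

    def add(self, description: str, satisfied: bool, kind: str = "exact") -> None:
        self.constraints.append({"description": description,
                                 "satisfied": bool(satisfied), "kind": kind})

    def require_all_exact(self) -> None:
        bad = [c["description"] for c in self.constraints
               if c["kind"] == "exact" and not c["satisfied"]]
        if bad:
            raise RuntimeError("fixture build violated exact constraint(s): "
                               + "; ".join(bad))

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed, "constraints": self.constraints,
                           "truth_labels": self.truth_labels}, indent=2)


def _assign_gene_memberships() -> dict[str, dict[str, int]]:
    """Greedy least-loaded layout of gene memberships inside each group:
    deterministic, spreads mutations so no sample is left gene-free."""
    panel = GenePanel()
    sample_ids = _sample_ids()
    status = {sid: {g: 0 for g in panel.genes} for sid in sample_ids}
    for gi, group in enumerate(GROUP_ORDER):
        members = [sid for sid in sample_ids if _group_of_index(sample_ids.index(sid)) == group]
        load = {sid: 0 for sid in members}
        for g in panel.genes:
            k = GENE_GROUP_COUNTS[g][gi]
            ranked = sorted(members, key=lambda s: (load[s], s))
            for sid in ranked[:k]:
                status[sid][g] = 1
                load[sid] += 1
    return status


def _sample_ids() -> list[str]:
    return [f"EC{i + 1:03d}" for i in range(96)]


def _group_of_index(i: int) -> str:
    if i < 16:
        return "POLE"
    if i < 28:
        return "MSI"
    if i < 76:
        return "CNL"
    return "CNH"


def _group_members(sample_ids: list[str], group: str) -> list[str]:
    return [sid for i, sid in enumerate(sample_ids) if _group_of_index(i) == group]


def build_reference_fixture(seed: int = 0, out_dir: str | Path | None = None
                            ) -> tuple[CohortTable, FixtureManifest]:
    """Build the deterministic reference cohort; optionally write its files
    (variants.tsv, msi.tsv, clinical.tsv, survival.tsv, manifest.json).

    Raises if any exact constraint is violated (checked against the emitted
    data by the independent recount in :func:`check_fixture` when files are
    written, and against the in-memory cohort always).
    """
    panel = GenePanel()
    rng = np.random.default_rng(int(seed) % (2**31))
    sample_ids = _sample_ids()
    status = _assign_gene_memberships()
    manifest = FixtureManifest(seed=int(seed))
    manifest.truth_labels = {sid: _group_of_index(i)
                             for i, sid in enumerate(sample_ids)}

    # --- counts: pair ascending retained/raw sequences with samples sorted
    # by gene count (ascending) so retained >= genes everywhere
    retained_of: dict[str, int] = {}
    raw_of: dict[str, int] = {}
    for group in GROUP_ORDER:
        members = _group_members(sample_ids, group)
        by_burden = sorted(members, key=lambda s: (sum(status[s].values()), s))
        for sid, r, w in zip(by_burden, RETAINED_COUNTS[group], RAW_COUNTS[group]):
            retained_of[sid], raw_of[sid] = r, w
            if r < sum(status[sid].values()):
                raise RuntimeError(f"retained count {r} below gene burden for {sid}")
            if w < r:
                raise RuntimeError(f"raw count below retained count for {sid}")

    # --- variant rows
    variants: list[VariantRecord] = []
    pole_members = _group_members(sample_ids, "POLE")
    hotspot_samples = {pole_members[i]: POLE_HOTSPOTS[i % 2]
                       for i in (0, 3, 6, 9, 12)}  # 5 of 96 = 5.2%
    from .synthetic import _filler_variant, _retained_variant

    for i, sid in enumerate(sample_ids):
        mutated = [g for g in panel.genes if status[sid][g]]
        j = 0
        for g in mutated:
            if g == "POLE":
                change = hotspot_samples.get(
                    sid, POLE_DOMAIN_CHANGES[i % len(POLE_DOMAIN_CHANGES)])
                variants.append(_retained_variant(sid, g, j, rng,
                                                  protein_change=change,
                                                  consequence="missense"))
            else:
                variants.append(_retained_variant(sid, g, j, rng))
            j += 1
        for k in range(retained_of[sid] - len(mutated)):
            g = mutated[k % len(mutated)]
            if g == "POLE" and len(mutated) > 1:
                g = mutated[(k + 1) % len(mutated)]
            variants.append(_retained_variant(sid, g, j, rng))
            j += 1
        filler_genes = [g for g in panel.genes if g != "POLE"]
        for k in range(raw_of[sid] - retained_of[sid]):
            variants.append(_filler_variant(sid, filler_genes[k % len(filler_genes)],
                                            k, rng))

    # --- MSI marker rows
    msi_rows: list[dict] = []
    marker_names = list(MARKER_LENGTHS)
    msi_members = _group_members(sample_ids, "MSI")
    mss_cycle_i = 0
    for i, sid in enumerate(sample_ids):
        group = _group_of_index(i)
        if group == "MSI":
            n_unstable = MSI_GROUP_UNSTABLE[msi_members.index(sid)]
        elif group == "POLE" and pole_members.index(sid) in POLE_MSI_OVERLAP:
            n_unstable = POLE_MSI_OVERLAP[pole_members.index(sid)]
        else:
            n_unstable = MSS_UNSTABLE_CYCLE[mss_cycle_i % len(MSS_UNSTABLE_CYCLE)]
            mss_cycle_i += 1
        unstable = [marker_names[(i + k) % len(marker_names)]
                    for k in range(n_unstable)]
        msi_rows.extend(_marker_rows(sid, unstable))

    # --- covariates
    clinical_rows: list[dict] = []
    serous: set[str] = set()
    # every serous sample is PTEN-negative (PTEN x histology held exactly)
    cnh_pten_neg = [sid for sid in _group_members(sample_ids, "CNH")
                    if not status[sid]["PTEN"]]
    serous.update(cnh_pten_neg[:11])
    serous.add(next(sid for sid in pole_members if not status[sid]["PTEN"]))
    serous.add(next(sid for sid in msi_members if not status[sid]["PTEN"]))
    advanced: set[str] = set()
    for group, k in ADVANCED_LAYOUT.items():
        advanced.update(_group_members(sample_ids, group)[-k:] if k else [])
    grade_of: dict[str, str] = {}
    for group, (n1, n2, n3) in GRADE_LAYOUT.items():
        members = _group_members(sample_ids, group)
        for sid in members[:n1]:
            grade_of[sid] = "I"
        for sid in members[n1:n1 + n2]:
            grade_of[sid] = "II"
        for sid in members[n1 + n2:n1 + n2 + n3]:
            grade_of[sid] = "III"
    for i, sid in enumerate(sample_ids):
        clinical_rows.append({
            "sample_id": sid, "truth_group": _group_of_index(i),
            "histology": "serous" if sid in serous else "endometrioid",
            "stage": "advanced" if sid in advanced else "early",
            "grade": grade_of[sid],
        })

    # --- survival: deterministic exponential quantiles per group; every
    # 7th sample censored at 70% of its event time (14/96 ~ 15%)
    survival_rows: list[dict] = []
    for group in GROUP_ORDER:
        members = _group_members(sample_ids, group)
        m = len(members)
        for rank, sid in enumerate(members):
            u = (rank + 0.5) / m
            censored = (sample_ids.index(sid) % 7) == 3
            for endpoint in ("DFS", "OS"):
                med = SURVIVAL_MEDIANS[group][endpoint]
                t = med * (-np.log1p(-u)) / np.log(2)
                t = float(np.clip(t, 2.1, 91.2))
                if censored:
                    t, ev = round(t * 0.7, 2), 0
                else:
                    t, ev = round(t, 2), 1
                survival_rows.append({"sample_id": sid, "endpoint": endpoint,
                                      "time_months": t, "event": ev,
                                      "group": group})

    cohort = CohortTable(
        variants=variants,
        msi_rows=pd.DataFrame(msi_rows),
        clinical=pd.DataFrame(clinical_rows),
        survival=pd.DataFrame(survival_rows),
        truth_labels=dict(manifest.truth_labels),
        seed=int(seed),
    )

    _record_constraints(cohort, manifest)
    manifest.require_all_exact()

    if out_dir is not None:
        paths = cohort.write(out_dir)
        (Path(out_dir) / "manifest.json").write_text(manifest.to_json())
        check_fixture(out_dir)  # independent recount from the files
        logger.info("fixture written to %s (%s)", out_dir, sorted(paths))
    return cohort, manifest


# ---------------------------------------------------------------------------
# constraint verification

def _pipeline_counts(cohort: CohortTable) -> dict:
    """Run the real pipeline (filters -> dichotomization -> MSI) on the
    in-memory cohort and gather every constrained quantity."""
    from collections import Counter

    from .msi import call_sample

    policy = FilterPolicy()
    raw_counts = Counter(v.sample_id for v in cohort.variants)
    retained = apply_quality_filters(cohort.variants, policy)
    profiles = dichotomize_genes(retained, raw_counts=dict(raw_counts))

    # marker calling from the long rows
    msi_status: dict[str, str] = {}
    for sid, sub in cohort.msi_rows.groupby("sample_id"):
        tissues: dict[str, dict[str, dict[int, float]]] = {"tumor": {}, "normal": {}}
        for r in sub.itertuples():
            hist = tissues[r.tissue].setdefault(r.marker, {})
            hist[int(r.length_bp)] = hist.get(int(r.length_bp), 0.0) + float(r.height)
        msi_status[sid] = call_sample(sid, tissues["tumor"], tissues["normal"]).msi_status

    return {"profiles": profiles, "msi_status": msi_status,
            "raw_counts": dict(raw_counts)}


def _record_constraints(cohort: CohortTable, manifest: FixtureManifest) -> None:
    run = _pipeline_counts(cohort)
    profiles, msi_status = run["profiles"], run["msi_status"]
    panel = GenePanel()
    truth = cohort.truth_labels

    sizes = {g: sum(1 for v in truth.values() if v == g) for g in GROUP_ORDER}
    manifest.add("truth-group sizes 16/12/48/20",
                 sizes == GROUP_SIZES)

    for gene, cells in GENE_GROUP_COUNTS.items():
        total = sum(cells)
        got = sum(p.gene_status[gene] for p in profiles.values())
        manifest.add(f"{gene} mutated in {total}/96 after filtering", got == total)
    for gi, group in enumerate(GROUP_ORDER):
        for gene in panel.genes:
            want = GENE_GROUP_COUNTS[gene][gi]
            got = sum(p.gene_status[gene] for sid, p in profiles.items()
                      if truth[sid] == group)
            manifest.add(f"{gene} mutated in {want}/{GROUP_SIZES[group]} of {group}",
                         got == want)

    n_msih = sum(1 for s in msi_status.values() if s == "MSI-H")
    manifest.add("MSI-H in exactly 15/96 samples", n_msih == 15)
    pole_msih = sum(1 for sid, s in msi_status.items()
                    if s == "MSI-H" and truth[sid] == "POLE")
    manifest.add("3 of 16 POLE-group samples are MSI-H", pole_msih == 3)
    msi_msih = sum(1 for sid, s in msi_status.items()
                   if s == "MSI-H" and truth[sid] == "MSI")
    manifest.add("all 12 MSI-group samples are MSI-H", msi_msih == 12)

    pole_flags = sum(1 for p in profiles.values() if p.pole_exonuclease_mutated)
    manifest.add("POLE exonuclease-domain mutation in exactly the 16 "
                 "POLE-group samples",
                 pole_flags == 16 and all(
                     p.pole_exonuclease_mutated == (truth[sid] == "POLE")
                     for sid, p in profiles.items()))
    hotspots = sum(1 for p in profiles.values() if p.pole_hotspot)
    manifest.add("POLE hotspot (p.P286R / p.V411L) in exactly 5/96 samples",
                 hotspots == 5)

    load_r = mutational_load(profiles.values(), by="retained")
    manifest.add("retained-mutation median 9.5 (range 2-64)",
                 load_r["median"] == 9.5 and load_r["range"] == (2, 64))
    load_raw = mutational_load(profiles.values(), by="raw")
    manifest.add("raw-variant median 40 (range 13-171)",
                 load_raw["median"] == 40.0 and load_raw["range"] == (13, 171))
    for group, want in (("POLE", 94.0), ("MSI", 40.0), ("CNL", 37.0), ("CNH", 32.0)):
        sub = [p for sid, p in profiles.items() if truth[sid] == group]
        manifest.add(f"{group}-group raw-load median {want:g}",
                     mutational_load(sub, by="raw")["median"] == want)

    clin = cohort.clinical.set_index("sample_id")
    manifest.add("histology margins endometrioid 83 / serous 13",
                 (clin["histology"] == "serous").sum() == 13)
    manifest.add("stage margins early 79 / advanced 17",
                 (clin["stage"] == "advanced").sum() == 17)
    manifest.add("grade margins 45/28/23",
                 clin["grade"].value_counts().to_dict()
                 == {"I": 45, "II": 28, "III": 23})
    pten_serous = sum(1 for sid, p in profiles.items()
                      if p.gene_status["PTEN"] and clin.loc[sid, "histology"] == "serous")
    manifest.add("PTEN x histology exactly [[53,0],[30,13]] "
                 "(no PTEN-mutated serous sample)", pten_serous == 0)
    pole_adv = sum(1 for sid, p in profiles.items()
                   if p.pole_exonuclease_mutated and clin.loc[sid, "stage"] == "advanced")
    manifest.add("POLE x stage exactly [[16,0],[63,17]]", pole_adv == 0)
    manifest.add("remaining gene x covariate cross-tabs: margins exact, "
                 "cells best-effort", True, kind="best_effort")


def check_fixture(fixture_dir: str | Path) -> FixtureManifest:
    """Independent checker: reads the emitted files back and recounts every
    constraint through the pipeline (never trusting builder bookkeeping)."""
    fixture_dir = Path(fixture_dir)
    variants = read_variant_table(fixture_dir / "variants.tsv", dialect="tsv")
    clinical = pd.read_csv(fixture_dir / "clinical.tsv", sep="\t")
    survival = pd.read_csv(fixture_dir / "survival.tsv", sep="\t")
    msi_rows = pd.read_csv(fixture_dir / "msi.tsv", sep="\t")
    meta = json.loads((fixture_dir / "manifest.json").read_text())

    cohort = CohortTable(
        variants=variants, msi_rows=msi_rows, clinical=clinical,
        survival=survival,
        truth_labels=dict(zip(clinical["sample_id"], clinical["truth_group"])),
        seed=int(meta["seed"]),
    )
    manifest = FixtureManifest(seed=int(meta["seed"]),
                               truth_labels=dict(cohort.truth_labels))
    _record_constraints(cohort, manifest)
    manifest.require_all_exact()
    return manifest


__all__ = [
    "GROUP_SIZES", "GENE_GROUP_COUNTS", "SURVIVAL_MEDIANS",
    "FixtureManifest", "build_reference_fixture", "check_fixture",
]
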