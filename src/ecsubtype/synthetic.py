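"""Stochastic cohort generators emulating the study conditions.

Two generators:

* :func:`simulate_training_set` — TCGA-like labeled CNL/CNH matrices
  (default n = 148) with group-specific Bernoulli gene-mutation
  frequencies, for exercising the random-forest protocol.
* :func:`simulate_cohort` — full synthetic endometrial-cancer cohorts
  (default n = 96) with group-specific mutation frequencies, mutational
  loads (discretized log-normal matched to each group's median, clipped to
  the observed ranges), paired tumor/normal STR fragment profiles, clinical
  covariates and exponential survival with censoring, emitted in the exact
  input dialects of the panel and MSI modules.

Group-conditional frequencies observed in the study cohort are used as the
generative probabilities; frequencies the study does not report are filled
once with values typical of TCGA endometrial series (see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import GenePanel, VariantRecord
from .rf import TrainingSet

logger = logging.getLogger(__name__)

#: canonical fragment lengths (bp) of the 8 STR loci
MARKER_LENGTHS: dict[str, int] = {
    "NR27": 87, "NR21": 103, "NR24": 131, "BAT26": 120,
    "BAT25": 124, "D5S346": 110, "D2S123": 170, "D17S250": 150,
}

#: per-group gene-mutation probabilities.  Bold values are the study's
#: reported group-conditional frequencies; the rest are TCGA-typical fills.
GROUP_GENE_PROBS: dict[str, dict[str, float]] = {
    "POLE": {
        "POLE": 1.0, "PTEN": 0.875, "TP53": 0.375, "ARID1A": 0.75,
        "ARID5B": 0.75, "FBXW7": 0.25, "PPP2R1A": 0.25, "CTCF": 0.44,
        "CTNNB1": 0.31, "RPL22": 0.625, "KRAS": 0.125, "PIK3CA": 0.625,
        "PIK3R1": 0.50,
    },
    "MSI": {
        "POLE": 0.30,  # non-exonuclease-domain passengers only
        "PTEN": 0.75, "TP53": 0.25, "ARID1A": 0.583, "ARID5B": 0.50,
        "FBXW7": 0.15, "PPP2R1A": 0.10, "CTCF": 0.25, "CTNNB1": 0.25,
        "RPL22": 0.833, "KRAS": 0.25, "PIK3CA": 0.50, "PIK3R1": 0.35,
    },
    "CNL": {
        "POLE": 0.10,
        "PTEN": 0.604, "TP53": 0.146, "ARID1A": 0.45, "ARID5B": 0.417,
        "FBXW7": 0.08, "PPP2R1A": 0.06, "CTCF": 0.313, "CTNNB1": 0.50,
        "RPL22": 0.396, "KRAS": 0.20, "PIK3CA": 0.50, "PIK3R1": 0.354,
    },
    "CNH": {
        "POLE": 0.05,
        "PTEN": 0.05, "TP53": 0.75, "ARID1A": 0.06, "ARID5B": 0.02,
        "FBXW7": 0.22, "PPP2R1A": 0.45, "CTCF": 0.02, "CTNNB1": 0.03,
        "RPL22": 0.02, "KRAS": 0.04, "PIK3CA": 0.45, "PIK3R1": 0.13,
    },
}

#: reference chromosome per panel gene (annotation metadata only)
GENE_CHROM: dict[str, str] = {
    "POLE": "chr12", "PTEN": "chr10", "TP53": "chr17", "ARID1A": "chr1",
    "ARID5B": "chr10", "FBXW7": "chr4", "PPP2R1A": "chr19", "CTCF": "chr16",
    "CTNNB1": "chr3", "RPL22": "chr1", "KRAS": "chr12", "PIK3CA": "chr3",
    "PIK3R1": "chr5",
}
GENE_BASE_POS: dict[str, int] = {
    "POLE": 133200000, "PTEN": 89620000, "TP53": 7570000, "ARID1A": 27020000,
    "ARID5B": 63660000, "FBXW7": 153240000, "PPP2R1A": 52190000,
    "CTCF": 67590000, "CTNNB1": 41240000, "RPL22": 6250000,
    "KRAS": 25360000, "PIK3CA": 178860000, "PIK3R1": 67510000,
}

#: non-hotspot exonuclease-domain substitutions used for POLE-group samples
POLE_DOMAIN_CHANGES = (
    "p.S297F", "p.A456P", "p.L424V", "p.F367S", "p.M295R", "p.D368Y",
    "p.P436R", "p.S459F",
)
POLE_HOTSPOTS = ("p.P286R", "p.V411L")
#: outside-domain substitutions for POLE passengers in non-POLE groups
POLE_NONDOMAIN_CHANGES = ("p.S500F", "p.K777N", "p.R1826W", "p.T2245M")


@dataclass(frozen=True)
class GroupSpec:
    """Generative description of one prognostic group."""

    name: str
    proportion: float
    gene_probs: Mapping[str, float]
    load_median: float            # raw annotated variants per case
    load_range: tuple[int, int]
    dfs_median: float             # months
    os_median: float              # months
    censoring: float = 0.15
    load_sigma: float = 0.45      # log-normal shape for the load draw

    def __post_init__(self) -> None:
        if not 0 <= self.proportion <= 1:
            raise ValueError("proportion outside [0, 1]")
        for g, p in self.gene_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {g} outside [0, 1]")
        if self.load_median <= 0 or self.dfs_median <= 0 or self.os_median <= 0:
            raise ValueError("medians must be positive")
        if not 0 <= self.censoring <= 1:
            raise ValueError("censoring fraction outside [0, 1]")


def default_group_specs() -> dict[str, GroupSpec]:
    """The study conditions: group proportions 16/12/48/20 of 96, observed
    load medians and ranges, and disease-free / overall survival medians."""
    return {
        "POLE": GroupSpec("POLE", 16 / 96, GROUP_GENE_PROBS["POLE"],
                          94, (31, 171), 55.40, 55.40),
        "MSI": GroupSpec("MSI", 12 / 96, GROUP_GENE_PROBS["MSI"],
                         40, (19, 93), 38.33, 38.60),
        "CNL": GroupSpec("CNL", 48 / 96, GROUP_GENE_PROBS["CNL"],
                         37, (13, 138), 34.43, 42.57),
        "CNH": GroupSpec("CNH", 20 / 96, GROUP_GENE_PROBS["CNH"],
                         32, (19, 96), 27.70, 30.53),
    }


# ---------------------------------------------------------------------------
# TCGA-like training matrices

def simulate_training_set(
    n: int = 148,
    cnh_fraction: float = 0.395,
    specs: Mapping[str, GroupSpec] | None = None,
    seed: int = 0,
    panel: GenePanel | None = None,
) -> TrainingSet:
    """Labeled CNL/CNH feature matrix: independent Bernoulli draws per gene
    per sample from the group's probability.  Reproducible per seed."""
    if n <= 0:
        raise ValueError("n must be positive")
    panel = panel or GenePanel()
    specs = specs or default_group_specs()
    rng = np.random.default_rng(int(seed) % (2**31))
    n_cnh = int(round(n * cnh_fraction))
    n_cnl = n - n_cnh
    if n_cnh == 0 or n_cnl == 0:
        raise ValueError("both classes must be represented")
    rows, labels = [], []
    for label, count in (("CNL", n_cnl), ("CNH", n_cnh)):
        probs = np.array([specs[label].gene_probs[g] for g in panel.rf_genes])
        draws = (rng.random((count, len(probs))) < probs).astype(int)
        rows.append(draws)
        labels.extend([label] * count)
    X = pd.DataFrame(np.vstack(rows), columns=list(panel.rf_genes))
    y = pd.Series(labels, name="label")
    perm = rng.permutation(n)
    return TrainingSet(X.iloc[perm].reset_index(drop=True),
                       y.iloc[perm].reset_index(drop=True))


# ---------------------------------------------------------------------------
# full synthetic cohorts

@dataclass
class CohortTable:
    """Everything a full pipeline run consumes, in memory, plus writers
    emitting the exact TSV dialects of the panel and MSI modules."""

    variants: list[VariantRecord]
    msi_rows: pd.DataFrame          # sample_id, marker, tissue, length_bp, height
    clinical: pd.DataFrame          # sample_id, truth_group, histology, stage, grade
    survival: pd.DataFrame          # sample_id, endpoint, time_months, event, group
    truth_labels: dict[str, str]
    seed: int

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "variants": out / "variants.tsv",
            "msi": out / "msi.tsv",
            "clinical": out / "clinical.tsv",
            "survival": out / "survival.tsv",
        }
        var_frame = pd.DataFrame([{
            "sample_id": v.sample_id, "gene": v.gene, "chrom": v.chrom,
            "pos": v.pos, "ref": v.ref, "alt": v.alt, "hgvs_p": v.protein_change,
            "consequence": v.consequence, "depth": v.depth,
            "vaf": f"{v.vaf:.4f}", "clinvar": v.clinvar_class,
            "polyphen": v.polyphen_call, "sift": v.sift_call,
        } for v in self.variants])
        var_frame.to_csv(paths["variants"], sep="\t", index=False, lineterminator="\n")
        self.msi_rows.to_csv(paths["msi"], sep="\t", index=False, lineterminator="\n")
        self.clinical.to_csv(paths["clinical"], sep="\t", index=False, lineterminator="\n")
        self.survival.to_csv(paths["survival"], sep="\t", index=False, lineterminator="\n")
        return paths


def _normal_histogram(length: int) -> list[tuple[int, float]]:
    # main allele plus a one-repeat stutter shoulder, as in capillary traces
    return [(length, 1000.0), (length - 1, 400.0)]


def _unstable_tumor_histogram(length: int, shift: int = 5) -> list[tuple[int, float]]:
    # retains the germline allele but gains a novel dominant shorter allele
    return [(length, 700.0), (length - 1, 300.0), (length - shift, 800.0)]


def _marker_rows(sample_id: str, unstable_markers: Sequence[str]) -> list[dict]:
    rows = []
    for marker, length in MARKER_LENGTHS.items():
        for bp, h in _normal_histogram(length):
            rows.append({"sample_id": sample_id, "marker": marker,
                         "tissue": "normal", "length_bp": bp, "height": h})
        tumor = (_unstable_tumor_histogram(length) if marker in unstable_markers
                 else _normal_histogram(length))
        for bp, h in tumor:
            rows.append({"sample_id": sample_id, "marker": marker,
                         "tissue": "tumor", "length_bp": bp, "height": h})
    return rows


def _retained_variant(sample_id: str, gene: str, j: int, rng: np.random.Generator,
                      protein_change: str | None = None,
                      consequence: str | None = None) -> VariantRecord:
    bases = ("A", "C", "G", "T")
    ref = bases[int(rng.integers(4))]
    alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
    if protein_change is None:
        residue = 100 + j * 7 + int(rng.integers(5))
        protein_change = f"p.A{residue}T"
    if consequence is None:
        consequence = ("missense", "nonsense", "frameshift", "missense",
                       "splicing", "missense")[j % 6]
    clinvar = ("vus", "pathogenic", "vus", "likely_pathogenic")[j % 4]
    return VariantRecord(
        sample_id=sample_id, gene=gene, chrom=GENE_CHROM[gene],
        pos=GENE_BASE_POS[gene] + 50 * j + int(rng.integers(40)),
        ref=ref, alt=alt, protein_change=protein_change,
        consequence=consequence,
        depth=600 + int(rng.integers(1400)),
        vaf=round(0.05 + 0.55 * float(rng.random()), 4),
        clinvar_class=clinvar,
    )


def _filler_variant(sample_id: str, gene: str, j: int,
                    rng: np.random.Generator) -> VariantRecord:
    """A row guaranteed to be removed by the quality/pathogenicity filter;
    filler mode cycles through every rejection reason."""
    mode = j % 5
    depth = 600 + int(rng.integers(1400))
    vaf = round(0.05 + 0.4 * float(rng.random()), 4)
    clinvar, polyphen, sift, consequence = "unreported", "unknown", "unknown", "missense"
    if mode == 0:
        depth = int(rng.integers(50, 599))          # below coverage floor
    elif mode == 1:
        vaf = round(0.001 + 0.048 * float(rng.random()), 4)  # below VAF floor
    elif mode == 2:
        clinvar = "benign"
    elif mode == 3:
        clinvar = "likely_benign"
    else:
        consequence = ("synonymous", "intronic")[j % 2]  # non-protein-altering VUS
    bases = ("A", "C", "G", "T")
    ref = bases[int(rng.integers(4))]
    alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
    return VariantRecord(
        sample_id=sample_id, gene=gene, chrom=GENE_CHROM[gene],
        pos=GENE_BASE_POS[gene] + 100000 + 50 * j + int(rng.integers(40)),
        ref=ref, alt=alt, protein_change="",
        consequence=consequence, depth=depth, vaf=vaf,
        clinvar_class=clinvar, polyphen_call=polyphen, sift_call=sift,
    )


def draw_load(spec: GroupSpec, rng: np.random.Generator) -> int:
    """Discretized log-normal matched to the group's median raw load,
    clipped to the observed range."""
    x = rng.lognormal(mean=np.log(spec.load_median), sigma=spec.load_sigma)
    return int(np.clip(round(x), spec.load_range[0], spec.load_range[1]))


def draw_survival(median: float, censoring: float,
                  rng: np.random.Generator) -> tuple[float, int]:
    """Exponential event time (median-parameterized) with random censoring;
    censored subjects report a uniformly earlier follow-up time."""
    t = rng.exponential(scale=median / np.log(2))
    t = float(np.clip(t, 0.5, 120.0))
    if rng.random() < censoring:
        return round(t * float(rng.uniform(0.3, 1.0)), 2), 0
    return round(t, 2), 1


def simulate_cohort(
    n: int = 96,
    specs: Mapping[str, GroupSpec] | None = None,
    seed: int = 0,
    panel: GenePanel | None = None,
) -> CohortTable:
    """Full synthetic cohort with the group-specific structure.

    Per sample: the group is drawn from the configured proportions; gene
    mutations are Bernoulli; the raw variant count follows the group's load
    distribution; every mutated gene is realized as >= 1 retained-grade
    variant row (depth >= 600, VAF >= 0.05, non-benign) with filler rows
    below threshold making up the raw count.  POLE-group samples carry an
    exonuclease-domain variant (hotspot w.p. 5/16) and POLE passengers in
    other groups are outside-domain.  MSI markers are forced unstable
    (>= 3/8) for MSI-group samples and for a 3/16 fraction of POLE-group
    samples; survival is exponential per group with censoring.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    panel = panel or GenePanel()
    specs = specs or default_group_specs()
    names = list(specs)
    props = np.array([specs[g].proportion for g in names], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("group proportions must sum to 1")
    rng = np.random.default_rng(int(seed) % (2**31))

    variants: list[VariantRecord] = []
    msi_rows: list[dict] = []
    clinical_rows: list[dict] = []
    survival_rows: list[dict] = []
    truth: dict[str, str] = {}

    groups = rng.choice(names, size=n, p=props)
    for i in range(n):
        sid = f"SYN{i + 1:04d}"
        group = str(groups[i])
        spec = specs[group]
        truth[sid] = group

        mutated = [g for g in panel.genes if rng.random() < spec.gene_probs.get(g, 0.0)]
        if group == "POLE" and "POLE" not in mutated:
            mutated.insert(0, "POLE")

        raw_n = draw_load(spec, rng)
        # roughly a quarter of annotated rows survive the filters (9.5 of 40
        # at the cohort level), but never fewer than one per mutated gene
        retained_n = max(len(mutated), int(round(raw_n * 0.24))) if mutated else 0
        raw_n = max(raw_n, retained_n)

        j = 0
        for g in mutated:
            if g == "POLE":
                if group == "POLE":
                    if rng.random() < 5 / 16:
                        change = POLE_HOTSPOTS[int(rng.integers(2))]
                    else:
                        change = POLE_DOMAIN_CHANGES[int(rng.integers(len(POLE_DOMAIN_CHANGES)))]
                else:
                    change = POLE_NONDOMAIN_CHANGES[int(rng.integers(len(POLE_NONDOMAIN_CHANGES)))]
                variants.append(_retained_variant(sid, g, j, rng,
                                                  protein_change=change,
                                                  consequence="missense"))
            else:
                variants.append(_retained_variant(sid, g, j, rng))
            j += 1
        extra = retained_n - len(mutated)
        for k in range(extra):
            g = mutated[k % len(mutated)] if mutated else panel.genes[1]
            if g == "POLE":
                g = mutated[(k + 1) % len(mutated)] if len(mutated) > 1 else "PTEN"
            variants.append(_retained_variant(sid, g, j, rng))
            j += 1
        filler_genes = [g for g in panel.genes if g != "POLE"]
        for k in range(raw_n - retained_n):
            variants.append(_filler_variant(sid, filler_genes[k % len(filler_genes)], k, rng))

        if group == "MSI":
            n_unstable = int(rng.integers(3, 9))
        elif group == "POLE" and rng.random() < 3 / 16:
            n_unstable = int(rng.integers(3, 6))
        else:
            n_unstable = int(rng.choice([0, 0, 0, 0, 0, 0, 1, 1, 2]))
        marker_names = list(MARKER_LENGTHS)
        unstable = list(rng.choice(marker_names, size=n_unstable, replace=False))
        msi_rows.extend(_marker_rows(sid, unstable))

        if group == "CNH":
            histology = "serous" if rng.random() < 0.55 else "endometrioid"
        else:
            histology = "serous" if rng.random() < 0.04 else "endometrioid"
        adv_p = {"POLE": 0.0, "MSI": 0.08, "CNL": 0.125, "CNH": 0.5}[group]
        stage = "advanced" if rng.random() < adv_p else "early"
        grade_p = {"POLE": (0.6, 0.3, 0.1), "MSI": (0.55, 0.35, 0.1),
                   "CNL": (0.55, 0.33, 0.12), "CNH": (0.1, 0.15, 0.75)}[group]
        grade = str(rng.choice(["I", "II", "III"], p=grade_p))
        clinical_rows.append({"sample_id": sid, "truth_group": group,
                              "histology": histology, "stage": stage, "grade": grade})

        for endpoint, median in (("DFS", spec.dfs_median), ("OS", spec.os_median)):
            t, ev = draw_survival(median, spec.censoring, rng)
            survival_rows.append({"sample_id": sid, "endpoint": endpoint,
                                  "time_months": t, "event": ev, "group": group})

    return CohortTable(
        variants=variants,
        msi_rows=pd.DataFrame(msi_rows),
        clinical=pd.DataFrame(clinical_rows),
        survival=pd.DataFrame(survival_rows),
        truth_labels=truth,
        seed=int(seed),
    )


__all__ = [
    "MARKER_LENGTHS", "GROUP_GENE_PROBS", "GENE_CHROM", "GroupSpec",
    "default_group_specs", "simulate_training_set", "simulate_cohort",
    "CohortTable", "draw_load", "draw_survival",
    "POLE_HOTSPOTS", "POLE_DOMAIN_CHANGES", "POLE_NONDOMAIN_CHANGES",
]
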