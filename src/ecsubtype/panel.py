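"""Gene-panel variant handling: ingestion, quality/pathogenicity filters,
gene-level dichotomization and mutational-load summaries.

The targeted NGS panel covers the coding regions of 13 genes chosen for
their differential mutation frequencies across the four prognostic groups
of endometrial cancer (POLE ultramutated, MSI hypermutated, copy-number
low, copy-number high).  Downstream classification consumes only a binary
mutated/non-mutated indicator per gene per sample, so the whole module
reduces annotated variant tables to per-sample
:class:`MutationProfile` objects.

Filtering follows the clinical pipeline: a variant is kept when it has
sequencing support (depth >= 600 reads, variant allele fraction >= 5%) and
is not (likely) benign — ClinVar assertions take precedence; unreported
variants fall back to PolyPhen/SIFT predictions, and when those too are
unknown, any protein-altering consequence is retained as a VUS.
"""

from __future__ import annotations

import csv
import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# domain types

PANEL_GENES: tuple[str, ...] = (
    "POLE", "PTEN", "TP53", "ARID1A", "ARID5B", "FBXW7", "PPP2R1A",
    "CTCF", "CTNNB1", "RPL22", "KRAS", "PIK3CA", "PIK3R1",
)

CONSEQUENCES = frozenset({
    "missense", "nonsense", "frameshift", "inframe", "splicing",
    "synonymous", "intronic", "regulatory",
})
#: consequences that alter the protein product; used as the VUS fallback
#: when ClinVar has no assertion and both in-silico predictors are unknown
PROTEIN_ALTERING = frozenset({
    "missense", "nonsense", "frameshift", "inframe", "splicing",
})

CLINVAR_CLASSES = frozenset({
    "pathogenic", "likely_pathogenic", "vus", "benign", "likely_benign",
    "unreported",
})


@dataclass(frozen=True)
class GenePanel:
    """Ordered 13-gene panel; ``rf_genes`` is the 12-gene subset (no POLE)
    used as the feature vector of the copy-number classifier."""

    genes: tuple[str, ...] = PANEL_GENES

    def __post_init__(self) -> None:
        if len(self.genes) != 13:
            raise ValueError(f"panel must contain 13 genes, got {len(self.genes)}")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel genes must be unique")
        if any(g != g.upper() for g in self.genes):
            raise ValueError("panel gene symbols must be uppercase")
        if "POLE" not in self.genes:
            raise ValueError("panel must include POLE")

    @property
    def rf_genes(self) -> tuple[str, ...]:
        return tuple(g for g in self.genes if g != "POLE")


@dataclass(frozen=True)
class VariantRecord:
    """One annotated somatic variant row.

    ``gene`` need not belong to the panel: off-panel records are ignored
    (with a logged count) at dichotomization time, never at parse time.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int                      # 1-based, as in VCF
    ref: str
    alt: str
    protein_change: str = ""      # HGVS-p or empty
    consequence: str = "missense"
    depth: int = 0
    vaf: float = 0.0
    clinvar_class: str = "unreported"
    polyphen_call: str = "unknown"   # {damaging, benign, unknown}
    sift_call: str = "unknown"       # {deleterious, tolerated, unknown}

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"negative depth for {self.sample_id}:{self.gene}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")


@dataclass(frozen=True)
class FilterPolicy:
    """Variant retention thresholds.  Bounds are inclusive ("minimum
    coverage of 600X" is read as depth >= 600, VAF >= 0.05)."""

    min_depth: int = 600
    min_vaf: float = 0.05
    retained_classes: frozenset[str] = frozenset(
        {"pathogenic", "likely_pathogenic", "vus"}
    )

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0.0 <= self.min_vaf <= 1.0:
            raise ValueError("min_vaf must lie in [0, 1]")
        if not self.retained_classes:
            raise ValueError("retained_classes must be non-empty")


@dataclass
class MutationProfile:
    """Per-sample binary mutation status over the 13-gene panel."""

    sample_id: str
    gene_status: dict[str, int]
    pole_exonuclease_mutated: bool = False
    pole_hotspot: bool = False
    raw_variant_count: int = 0
    retained_variant_count: int = 0

    def __post_init__(self) -> None:
        if self.pole_hotspot and not self.pole_exonuclease_mutated:
            raise ValueError("hotspot implies exonuclease-domain mutation")
        if self.pole_exonuclease_mutated and not self.gene_status.get("POLE"):
            raise ValueError("POLE domain mutation implies POLE gene status 1")
        if self.retained_variant_count > self.raw_variant_count:
            raise ValueError("retained count exceeds raw count")

    @property
    def n_mutated_genes(self) -> int:
        return sum(self.gene_status.values())


@dataclass
class FilterLog:
    """Structured audit of filter rejections, so samples filtered to zero
    remain distinguishable from samples with no variant rows at all."""

    n_input: int = 0
    n_retained: int = 0
    rejected: Counter = field(default_factory=Counter)

    def reject(self, reason: str) -> None:
        self.rejected[reason] += 1


# ---------------------------------------------------------------------------
# pathogenicity + quality filters

def classify_pathogenicity(v: VariantRecord) -> Literal["retain", "discard"]:
    """Decide retention of a variant from its annotations.

    ClinVar takes precedence: (likely) pathogenic and VUS assertions are
    retained, (likely) benign discarded regardless of predictors.  For
    ClinVar-unreported variants, a damaging PolyPhen or deleterious SIFT
    call retains; if both predictors are unknown the variant is kept as a
    VUS when its consequence is protein-altering, otherwise discarded.
    Total function: every record maps to retain or discard.
    """
    c = v.clinvar_class
    if c in ("pathogenic", "likely_pathogenic", "vus"):
        return "retain"
    if c in ("benign", "likely_benign"):
        return "discard"
    # unreported (or unknown-equivalent): fall back to in-silico predictors
    if v.polyphen_call == "damaging" or v.sift_call == "deleterious":
        return "retain"
    if v.polyphen_call == "unknown" and v.sift_call == "unknown":
        return "retain" if v.consequence in PROTEIN_ALTERING else "discard"
    return "discard"


def apply_quality_filters(
    variants: Sequence[VariantRecord],
    policy: FilterPolicy | None = None,
    log: FilterLog | None = None,
) -> list[VariantRecord]:
    """Retain records with depth >= min_depth, VAF >= min_vaf and a
    retain-grade pathogenicity call.  Order-stable and idempotent."""
    policy = policy or FilterPolicy()
    log = log if log is not None else FilterLog()
    kept: list[VariantRecord] = []
    for v in variants:
        log.n_input += 1
        if v.depth < policy.min_depth:
            log.reject("low_depth")
        elif v.vaf < policy.min_vaf:
            log.reject("low_vaf")
        elif v.clinvar_class in ("benign", "likely_benign") or (
            classify_pathogenicity(v) == "discard"
        ):
            log.reject("benign_or_nonpathogenic")
        else:
            kept.append(v)
            log.n_retained += 1
    if log.rejected:
        logger.info("filter rejections: %s", dict(log.rejected))
    return kept


# ---------------------------------------------------------------------------
# dichotomization

_HGVS_P_RESIDUE = re.compile(r"p\.\(?(?:[A-Z][a-z]{2}|[A-Z*])(\d+)")


def protein_residue(protein_change: str) -> int | None:
    """Residue number of an HGVS-p string (``p.P286R`` -> 286); None when
    absent or unparseable."""
    m = _HGVS_P_RESIDUE.match(protein_change.strip())
    return int(m.group(1)) if m else None


def dichotomize_genes(
    variants: Sequence[VariantRecord],
    panel: GenePanel | None = None,
    *,
    raw_counts: Mapping[str, int] | None = None,
    pole_rule: "object | None" = None,
) -> dict[str, MutationProfile]:
    """Reduce *filtered* variants to one binary profile per sample.

    ``gene_status[g] = 1`` iff the sample carries >= 1 retained variant in
    gene ``g``; off-panel genes are ignored with a logged count.  Samples
    appearing in ``raw_counts`` but with every variant filtered out yield
    an all-zero profile (still classifiable downstream).

    ``raw_counts`` maps sample_id -> pre-filter row count; when omitted the
    retained count doubles as the raw count.
    """
    from .classify import PoleRule, detect_pole_domain_mutation  # lazy: no cycle

    panel = panel or GenePanel()
    rule = pole_rule or PoleRule()
    by_sample: dict[str, list[VariantRecord]] = {}
    off_panel = 0
    for v in variants:
        by_sample.setdefault(v.sample_id, []).append(v)
        if v.gene not in panel.genes:
            off_panel += 1
    if off_panel:
        logger.info("ignored %d off-panel variant records", off_panel)

    sample_ids = list(by_sample)
    if raw_counts is not None:
        for sid in raw_counts:
            if sid not in by_sample:
                logger.warning("sample %s has no retained variants", sid)
                by_sample[sid] = []
                sample_ids.append(sid)

    profiles: dict[str, MutationProfile] = {}
    for sid in sample_ids:
        rows = by_sample[sid]
        on_panel = [v for v in rows if v.gene in panel.genes]
        status = {g: 0 for g in panel.genes}
        for v in on_panel:
            status[v.gene] = 1
        domain, hotspot = detect_pole_domain_mutation(on_panel, rule)
        retained_n = len(rows)
        raw_n = retained_n if raw_counts is None else raw_counts.get(sid, retained_n)
        profiles[sid] = MutationProfile(
            sample_id=sid,
            gene_status=status,
            pole_exonuclease_mutated=domain,
            pole_hotspot=hotspot,
            raw_variant_count=max(raw_n, retained_n),
            retained_variant_count=retained_n,
        )
    return profiles


def mutational_load(
    profiles: Iterable[MutationProfile],
    by: Literal["raw", "retained"] = "retained",
) -> dict:
    """Per-sample variant counts with cohort median and range.

    The median is the mean of the two central order statistics for even n,
    so half-integral medians (e.g. 9.5 mutations/patient) are exact.
    """
    counts = {
        p.sample_id: (p.raw_variant_count if by == "raw" else p.retained_variant_count)
        for p in profiles
    }
    if not counts:
        raise ValueError("mutational_load requires a non-empty cohort")
    values = sorted(counts.values())
    n = len(values)
    mid = n // 2
    median = float(values[mid]) if n % 2 else (values[mid - 1] + values[mid]) / 2.0
    return {
        "counts": counts,
        "median": median,
        "range": (values[0], values[-1]),
        "n": n,
    }


# ---------------------------------------------------------------------------
# I/O

TSV_COLUMNS = (
    "sample_id", "gene", "chrom", "pos", "ref", "alt", "hgvs_p",
    "consequence", "depth", "vaf", "clinvar", "polyphen", "sift",
)

_NORMALIZE = {
    "clinvar": {
        "": "unreported", ".": "unreported", "na": "unreported",
        "unknown": "unreported", "not_reported": "unreported",
        "uncertain_significance": "vus",
    },
    "polyphen": {
        "": "unknown", ".": "unknown", "na": "unknown",
        "probably_damaging": "damaging", "possibly_damaging": "damaging",
        "tolerated": "benign",
    },
    "sift": {
        "": "unknown", ".": "unknown", "na": "unknown",
        "damaging": "deleterious", "benign": "tolerated",
    },
}


def _norm(kind: str, value: str, allowed: frozenset[str], default: str) -> str:
    v = value.strip().lower().replace(" ", "_")
    v = _NORMALIZE[kind].get(v, v)
    if v not in allowed:
        logger.debug("unrecognized %s value %r mapped to %r", kind, value, default)
        return default
    return v


class VariantTableError(ValueError):
    """Raised on malformed variant input (names the file, line and column)."""


def _record_from_row(row: Mapping[str, str], path: str, lineno: int) -> VariantRecord:
    try:
        consequence = row["consequence"].strip().lower() or "missense"
        if consequence not in CONSEQUENCES:
            consequence = "missense"
        return VariantRecord(
            sample_id=row["sample_id"].strip(),
            gene=row["gene"].strip().upper(),
            chrom=row["chrom"].strip(),
            pos=int(row["pos"]),
            ref=row["ref"].strip(),
            alt=row["alt"].strip(),
            protein_change=row.get("hgvs_p", "").strip(),
            consequence=consequence,
            depth=int(float(row["depth"])),
            vaf=float(row["vaf"]),
            clinvar_class=_norm("clinvar", row.get("clinvar", ""), CLINVAR_CLASSES, "unreported"),
            polyphen_call=_norm("polyphen", row.get("polyphen", ""),
                                frozenset({"damaging", "benign", "unknown"}), "unknown"),
            sift_call=_norm("sift", row.get("sift", ""),
                            frozenset({"deleterious", "tolerated", "unknown"}), "unknown"),
        )
    except (KeyError, ValueError) as exc:
        raise VariantTableError(f"{path}:{lineno}: malformed variant row ({exc})") from exc


def _read_tsv(path: Path) -> list[VariantRecord]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in TSV_COLUMNS if c not in header and c not in
                   ("hgvs_p", "consequence", "clinvar", "polyphen", "sift")]
        if missing:
            raise VariantTableError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        return [_record_from_row(row, str(path), i) for i, row in enumerate(reader, start=2)]


#: default INFO-key mapping for the VCF dialect
VCF_INFO_KEYS = {
    "gene": "GENE",
    "hgvs_p": "HGVSP",
    "consequence": "CSQ",
    "clinvar": "CLNSIG",
    "polyphen": "POLYPHEN",
    "sift": "SIFT",
}


def _read_vcf(path: Path, info_keys: Mapping[str, str] | None = None) -> list[VariantRecord]:
    """Read an annotated single- or multi-sample VCF.  Multi-allelic rows
    are split into one record per ALT with per-allele VAF (lossless for
    gene-level dichotomization).  Depth/VAF come from FORMAT DP/AF when
    present, else INFO DP/AF."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional extra
        raise VariantTableError(
            "VCF dialect requires the cyvcf2 optional dependency"
        ) from exc

    keys = dict(VCF_INFO_KEYS)
    if info_keys:
        keys.update(info_keys)
    records: list[VariantRecord] = []
    vcf = VCF(str(path))
    samples = vcf.samples or ["sample"]

    def info_str(variant, key: str, alt_index: int) -> str:
        raw = variant.INFO.get(key)
        if raw is None:
            return ""
        parts = str(raw).split(",")
        return parts[alt_index] if alt_index < len(parts) else parts[0]

    for variant in vcf:
        gene_field = variant.INFO.get(keys["gene"])
        if gene_field is None:
            raise VariantTableError(
                f"{path}: VCF record at {variant.CHROM}:{variant.POS} lacks "
                f"required INFO key {keys['gene']}"
            )
        n_alt = len(variant.ALT)
        for ai, alt in enumerate(variant.ALT):
            for si, sample in enumerate(samples):
                if variant.format("DP") is not None:
                    depth = int(variant.format("DP")[si][0])
                else:
                    depth = int(variant.INFO.get("DP", 0))
                af = variant.format("AF")
                if af is not None:
                    row_af = af[si]
                    vaf = float(row_af[ai] if ai < len(row_af) else row_af[0])
                else:
                    raw = variant.INFO.get("AF", 0.0)
                    parts = str(raw).split(",")
                    vaf = float(parts[ai] if ai < len(parts) else parts[0])
                row = {
                    "sample_id": sample,
                    "gene": info_str(variant, keys["gene"], ai) or str(gene_field),
                    "chrom": variant.CHROM,
                    "pos": str(variant.POS),
                    "ref": variant.REF,
                    "alt": alt,
                    "hgvs_p": info_str(variant, keys["hgvs_p"], ai),
                    "consequence": info_str(variant, keys["consequence"], ai),
                    "depth": str(depth),
                    "vaf": str(vaf),
                    "clinvar": info_str(variant, keys["clinvar"], ai),
                    "polyphen": info_str(variant, keys["polyphen"], ai),
                    "sift": info_str(variant, keys["sift"], ai),
                }
                records.append(_record_from_row(row, str(path), variant.POS))
        del n_alt
    return records


def read_variant_table(
    path: str | Path,
    dialect: Literal["tsv", "vcf"] = "tsv",
    info_keys: Mapping[str, str] | None = None,
) -> list[VariantRecord]:
    """Read an annotated somatic-variant table.

    ``tsv`` expects the documented header (see :data:`TSV_COLUMNS`); ``vcf``
    reads VCF 4.x with annotations in INFO keys (:data:`VCF_INFO_KEYS`,
    overridable).  Unknown annotation values map to unknown/unreported and
    are never dropped silently; a per-file summary is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        records = _read_tsv(path)
    elif dialect == "vcf":
        records = _read_vcf(path, info_keys)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    logger.info("%s: read %d variant records (%d samples)",
                path, len(records), len({r.sample_id for r in records}))
    return records


def write_profile_table(
    profiles: Mapping[str, MutationProfile],
    path: str | Path,
    panel: GenePanel | None = None,
) -> None:
    """Write the per-sample binary profile table (TSV)."""
    panel = panel or GenePanel()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", *panel.genes, "pole_domain", "pole_hotspot",
                    "raw_n", "retained_n"])
        for sid in sorted(profiles):
            p = profiles[sid]
            w.writerow([
                sid, *(p.gene_status[g] for g in panel.genes),
                int(p.pole_exonuclease_mutated), int(p.pole_hotspot),
                p.raw_variant_count, p.retained_variant_count,
            ])


__all__ = [
    "PANEL_GENES", "GenePanel", "VariantRecord", "FilterPolicy",
    "MutationProfile", "FilterLog", "classify_pathogenicity",
    "apply_quality_filters", "dichotomize_genes", "mutational_load",
    "protein_residue", "read_variant_table", "write_profile_table",
    "VariantTableError", "TSV_COLUMNS",
]
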