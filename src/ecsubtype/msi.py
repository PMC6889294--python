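"""Microsatellite-instability calling from paired tumor/normal fragment
analysis.

Eight STR loci (NR27, NR21, NR24, BAT26, BAT25, D5S346, D2S123, D17S250)
are assayed by fluorescent PCR + capillary electrophoresis; each marker
yields an allele-length histogram (fragment length in bp -> peak height)
for tumor and matched normal tissue.  A marker is *unstable* when the
tumor trace contains a dominant allele absent from the normal trace — the
deterministic surrogate implemented here for expert electropherogram
reading is the dominant-allele shift rule: any tumor peak reaching
``rel_peak_frac`` of the tallest tumor peak whose length differs from every
dominant normal allele by more than ``shift_tol`` bp marks the marker
unstable.  A sample is MSI-High when at least 30% of evaluable markers are
unstable (>= 3 of 8); markers whose total signal falls below ``min_signal``
are *failed* and shrink the denominator, and a sample with fewer than
``min_evaluable`` evaluable markers is indeterminate rather than MSS.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

logger = logging.getLogger(__name__)

DEFAULT_MARKERS: tuple[str, ...] = (
    "NR27", "NR21", "NR24", "BAT26", "BAT25", "D5S346", "D2S123", "D17S250",
)

MarkerCall = Literal["stable", "unstable", "failed"]
MsiStatus = Literal["MSI-H", "MSS", "indeterminate"]

Histogram = Mapping[int, float]  # fragment length (bp) -> peak height


@dataclass(frozen=True)
class MarkerSet:
    markers: tuple[str, ...] = DEFAULT_MARKERS

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("marker set must contain at least one locus")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")


@dataclass(frozen=True)
class MsiParams:
    """Tolerances of the dominant-allele shift rule (all configurable)."""

    shift_tol: int = 2          # bp; |tumor - normal| must exceed this
    rel_peak_frac: float = 0.2  # dominant-allele height threshold
    min_signal: float = 100.0   # total trace signal below which a marker fails
    threshold: float = 0.30     # unstable fraction for MSI-H
    min_evaluable: int = 5      # evaluable markers required for a call


@dataclass
class MsiProfile:
    """Per-sample marker calls plus derived sample-level status."""

    sample_id: str
    marker_calls: dict[str, MarkerCall] = field(default_factory=dict)
    tumor_histograms: dict[str, dict[int, float]] = field(default_factory=dict)
    normal_histograms: dict[str, dict[int, float]] = field(default_factory=dict)
    msi_status: MsiStatus = "indeterminate"
    unstable_fraction: float = 0.0

    @property
    def n_unstable(self) -> int:
        return sum(1 for c in self.marker_calls.values() if c == "unstable")

    @property
    def n_evaluable(self) -> int:
        return sum(1 for c in self.marker_calls.values() if c != "failed")


def _dominant_alleles(hist: Histogram, rel_peak_frac: float) -> set[int]:
    peak = max(hist.values())
    return {bp for bp, h in hist.items() if h >= rel_peak_frac * peak}


def call_marker_instability(
    tumor: Histogram,
    normal: Histogram,
    params: MsiParams | None = None,
) -> MarkerCall:
    """Call one marker from paired tumor/normal allele-length histograms.

    Deterministic for fixed params.  Degenerate traces (empty or with total
    signal below ``min_signal``) yield ``failed``, never an exception.
    """
    params = params or MsiParams()
    if any(h < 0 for h in tumor.values()) or any(h < 0 for h in normal.values()):
        raise ValueError("peak heights must be non-negative")
    if sum(tumor.values()) < params.min_signal or sum(normal.values()) < params.min_signal:
        return "failed"
    tumor_dom = _dominant_alleles(tumor, params.rel_peak_frac)
    normal_dom = _dominant_alleles(normal, params.rel_peak_frac)
    for bp in tumor_dom:
        if all(abs(bp - nb) > params.shift_tol for nb in normal_dom):
            return "unstable"
    return "stable"


def call_msi_status(
    profile: MsiProfile,
    threshold: float = 0.30,
    min_evaluable: int = 5,
) -> MsiStatus:
    """Sample-level status from per-marker calls (>= 30% rule).

    With 8 evaluable markers MSI-H requires >= 3 unstable (2/8 = 0.25 falls
    below the 0.30 threshold).  Updates and returns ``profile.msi_status``;
    ``unstable_fraction`` excludes failed markers from the denominator.
    """
    evaluable = profile.n_evaluable
    unstable = profile.n_unstable
    profile.unstable_fraction = unstable / evaluable if evaluable else 0.0
    if evaluable < min_evaluable:
        profile.msi_status = "indeterminate"
    elif profile.unstable_fraction >= threshold:
        profile.msi_status = "MSI-H"
    else:
        profile.msi_status = "MSS"
    return profile.msi_status


def call_sample(
    sample_id: str,
    tumor: Mapping[str, Histogram],
    normal: Mapping[str, Histogram],
    markers: MarkerSet | None = None,
    params: MsiParams | None = None,
) -> MsiProfile:
    """Run marker-level calling over a sample's full marker set and derive
    its MSI status.  Markers missing from either tissue are failed."""
    markers = markers or MarkerSet()
    params = params or MsiParams()
    profile = MsiProfile(
        sample_id=sample_id,
        tumor_histograms={m: dict(tumor.get(m, {})) for m in markers.markers},
        normal_histograms={m: dict(normal.get(m, {})) for m in markers.markers},
    )
    for m in markers.markers:
        profile.marker_calls[m] = call_marker_instability(
            profile.tumor_histograms[m], profile.normal_histograms[m], params
        )
    call_msi_status(profile, params.threshold, params.min_evaluable)
    return profile


def profile_from_calls(
    sample_id: str,
    calls: Mapping[str, MarkerCall],
    params: MsiParams | None = None,
) -> MsiProfile:
    """Build a profile from pre-made marker calls (labs that export calls
    only), bypassing histogram calling."""
    params = params or MsiParams()
    for m, c in calls.items():
        if c not in ("stable", "unstable", "failed"):
            raise ValueError(f"invalid marker call {c!r} for {m}")
    profile = MsiProfile(sample_id=sample_id, marker_calls=dict(calls))
    call_msi_status(profile, params.threshold, params.min_evaluable)
    return profile


def msi_cohort_summary(profiles: Iterable[MsiProfile]) -> dict:
    """Counts and fractions by MSI status across a cohort."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("msi_cohort_summary requires a non-empty cohort")
    n = len(profiles)
    counts = {"MSI-H": 0, "MSS": 0, "indeterminate": 0}
    for p in profiles:
        counts[p.msi_status] += 1
    return {
        "n": n,
        "counts": counts,
        "fractions": {k: v / n for k, v in counts.items()},
        "percent": {k: round(100.0 * v / n, 1) for k, v in counts.items()},
    }


def concordance(status_a: Sequence[str], status_b: Sequence[str]) -> float:
    """Fraction of samples on which two binary status columns agree (e.g.
    fragment-analysis MSI vs an external MMR-IHC column)."""
    if len(status_a) != len(status_b) or not status_a:
        raise ValueError("status vectors must be equal-length and non-empty")
    return sum(a == b for a, b in zip(status_a, status_b)) / len(status_a)


# ---------------------------------------------------------------------------
# I/O

def read_marker_table(path: str | Path) -> dict[str, dict[str, dict[str, dict[int, float]]]]:
    """Read the long-format fragment table
    (sample_id, marker, tissue in {tumor, normal}, length_bp, height).

    Returns sample_id -> tissue -> marker -> histogram.
    """
    out: dict[str, dict[str, dict[str, dict[int, float]]]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "marker", "tissue", "length_bp", "height"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            tissue = row["tissue"].strip().lower()
            if tissue not in ("tumor", "normal"):
                raise ValueError(f"{path}:{i}: tissue must be tumor/normal")
            sample = out.setdefault(row["sample_id"], {"tumor": {}, "normal": {}})
            hist = sample[tissue].setdefault(row["marker"], {})
            hist[int(row["length_bp"])] = hist.get(int(row["length_bp"]), 0.0) + float(row["height"])
    return out


def call_cohort(
    path: str | Path,
    markers: MarkerSet | None = None,
    params: MsiParams | None = None,
) -> dict[str, MsiProfile]:
    """Read a long-format fragment table and call every sample."""
    table = read_marker_table(path)
    return {
        sid: call_sample(sid, tissues["tumor"], tissues["normal"], markers, params)
        for sid, tissues in table.items()
    }


def write_msi_table(profiles: Mapping[str, MsiProfile], path: str | Path,
                    markers: MarkerSet | None = None) -> None:
    markers = markers or MarkerSet()
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", *markers.markers, "unstable_fraction", "msi_status"])
        for sid in sorted(profiles):
            p = profiles[sid]
            w.writerow([
                sid,
                *(p.marker_calls.get(m, "failed") for m in markers.markers),
                f"{p.unstable_fraction:.4f}", p.msi_status,
            ])


__all__ = [
    "DEFAULT_MARKERS", "MarkerSet", "MsiParams", "MsiProfile",
    "call_marker_instability", "call_msi_status", "call_sample",
    "profile_from_calls", "msi_cohort_summary", "concordance",
    "read_marker_table", "call_cohort", "write_msi_table",
]
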