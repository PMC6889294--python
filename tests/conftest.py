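import pytest

from ecsubtype.fixture import build_reference_fixture
from ecsubtype.panel import apply_quality_filters, dichotomize_genes


@pytest.fixture(scope="session")
def reference_cohort():
    """The deterministic 96-sample reference cohort (in memory)."""
    cohort, manifest = build_reference_fixture(seed=0)
    return cohort, manifest


@pytest.fixture(scope="session")
def reference_profiles(reference_cohort):
    """Filter-and-dichotomize run over the reference cohort."""
    from collections import Counter

    cohort, _ = reference_cohort
    raw = Counter(v.sample_id for v in cohort.variants)
    retained = apply_quality_filters(cohort.variants)
    return dichotomize_genes(retained, raw_counts=dict(raw))


@pytest.fixture(scope="session")
def reference_msi(reference_cohort):
    """Marker-level MSI calls over the reference cohort."""
    from ecsubtype.msi import call_sample

    cohort, _ = reference_cohort
    statuses = {}
    for sid, sub in cohort.msi_rows.groupby("sample_id"):
        tissues = {"tumor": {}, "normal": {}}
        for r in sub.itertuples():
            hist = tissues[r.tissue].setdefault(r.marker, {})
            hist[int(r.length_bp)] = hist.get(int(r.length_bp), 0.0) + float(r.height)
        statuses[str(sid)] = call_sample(str(sid), tissues["tumor"], tissues["normal"])
    return statuses
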