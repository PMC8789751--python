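from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from gcrep import ContigRecord, default_profile, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_contig(
    barcode="AAAC-1",
    donor="donor1",
    chain="IGH",
    v_gene="IGHV3-23",
    d_gene="IGHD3-10",
    j_gene="IGHJ4",
    c_gene="IGHG1",
    cdr3_nt="TGTGCGAGAGAT",
    productive=True,
    full_length=True,
    high_confidence=True,
    umis=12,
    v_identity_pct=95.8,
) -> ContigRecord:
    if chain != "IGH":
        d_gene = ""
        c_gene = "" if c_gene == "IGHG1" else c_gene
        if v_gene == "IGHV3-23":
            v_gene = "IGKV1-39" if chain == "IGK" else "IGLV2-14"
        if j_gene == "IGHJ4":
            j_gene = "IGKJ2" if chain == "IGK" else "IGLJ3"
    return ContigRecord(
        barcode=barcode,
        donor=donor,
        chain=chain,
        v_gene=v_gene,
        d_gene=d_gene,
        j_gene=j_gene,
        c_gene=c_gene,
        cdr3_nt=cdr3_nt,
        productive=productive,
        full_length=full_length,
        high_confidence=high_confidence,
        umis=umis,
        v_identity_pct=v_identity_pct,
    )


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A 6,000-cell cohort at the default calibration, for pipeline-level tests."""
    out = tmp_path_factory.mktemp("small_cohort")
    profile = default_profile()
    profile.n_cells = 6_000
    profile.seed = 11
    truth = generate_cohort(profile, out)
    return out, truth
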