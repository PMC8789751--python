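"""Secondary cell filter, isotype assignment, identity binning, cluster groups."""

from __future__ import annotations

import pytest
from hypothesis import given, strategies as st

from gcrep import (
    assign_cluster_groups,
    assign_isotype_class,
    annotate_cells,
    bin_germline_identity,
    combined_germline_identity,
    filter_paired_cells,
)
from gcrep.qc import (
    AUDIT_REASONS,
    CLUSTER_GROUPS,
    CLUSTERS,
    IsotypeError,
    ClusterError,
)

from conftest import make_contig


class TestFilterPairedCells:
    def test_clean_pair_is_kept(self):
        contigs = [make_contig(), make_contig(chain="IGK", umis=8)]
        cells, audit = filter_paired_cells(contigs, {"AAAC-1"})
        assert len(cells) == 1
        assert audit["kept"] == 1
        cell = cells[0]
        assert cell.isotype_subclass == "IGHG1"
        assert cell.isotype_class == "IGHG"

    @pytest.mark.parametrize(
        "contigs, reason",
        [
            # two eligible heavy chains -> ambiguous pairing
            (
                [make_contig(), make_contig(cdr3_nt="TGTAAA"), make_contig(chain="IGK")],
                "multiple_eligible_heavy",
            ),
            # IGHD constant gene -> naive phenotype, removed
            (
                [make_contig(c_gene="IGHD"), make_contig(chain="IGK")],
                "heavy_ighd",
            ),
            # UMI threshold is strict: 3 UMIs is not "more than 3"
            (
                [make_contig(umis=3), make_contig(chain="IGK")],
                "no_eligible_heavy",
            ),
            # non-productive heavy is ineligible
            (
                [make_contig(productive=False), make_contig(chain="IGK")],
                "no_eligible_heavy",
            ),
            # two light chains
            (
                [make_contig(), make_contig(chain="IGK"), make_contig(chain="IGL")],
                "multiple_eligible_light",
            ),
            # no light at all
            ([make_contig()], "no_eligible_light"),
            # heavy without a constant-gene call cannot be isotyped
            (
                [make_contig(c_gene=""), make_contig(chain="IGK")],
                "heavy_missing_c_gene",
            ),
        ],
    )
    def test_drop_rules(self, contigs, reason):
        cells, audit = filter_paired_cells(contigs, {"AAAC-1"})
        assert cells == []
        assert audit[reason] == 1
        assert audit["kept"] == 0

    def test_barcode_missing_from_expression_is_dropped(self):
        contigs = [make_contig(), make_contig(chain="IGK")]
        cells, audit = filter_paired_cells(contigs, set())
        assert cells == []
        assert audit["not_in_expression"] == 1

    def test_expression_membership_can_be_per_donor(self):
        contigs = [make_contig(), make_contig(chain="IGK")]
        cells, _ = filter_paired_cells(contigs, {"donor2": {"AAAC-1"}})
        assert cells == []
        cells, _ = filter_paired_cells(contigs, {"donor1": {"AAAC-1"}})
        assert len(cells) == 1

    def test_audit_counters_sum_to_distinct_barcodes(self):
        contigs = [
            make_contig(barcode="A"), make_contig(barcode="A", chain="IGK"),
            make_contig(barcode="B", umis=2), make_contig(barcode="B", chain="IGL"),
            make_contig(barcode="C"),
        ]
        cells, audit = filter_paired_cells(contigs, {"A", "B", "C", "D"})
        assert sum(audit[r] for r in AUDIT_REASONS) + audit["kept"] == 3

    def test_filter_is_idempotent(self):
        contigs = []
        for i, umi in enumerate([10, 3, 7]):
            contigs.append(make_contig(barcode=f"bc{i}", umis=umi))
            contigs.append(make_contig(barcode=f"bc{i}", chain="IGK"))
        expressed = {f"bc{i}" for i in range(3)}
        cells, _ = filter_paired_cells(contigs, expressed)
        kept_contigs = [c for cell in cells for c in (cell.heavy, cell.light)]
        cells2, audit2 = filter_paired_cells(kept_contigs, expressed)
        assert [(c.donor, c.barcode) for c in cells] == [
            (c.donor, c.barcode) for c in cells2
        ]
        assert audit2["kept"] == len(cells)


class TestIsotype:
    @pytest.mark.parametrize(
        "c_gene, expected",
        [
            ("IGHG1", "IGHG"), ("IGHG2", "IGHG"), ("IGHG3", "IGHG"), ("IGHG4", "IGHG"),
            ("IGHA1", "IGHA"), ("IGHA2", "IGHA"),
            ("IGHM", "IGHM"), ("IGHE", "IGHE"),
        ],
    )
    def test_subclass_collapse(self, c_gene, expected):
        assert assign_isotype_class(c_gene) == expected

    @pytest.mark.parametrize("bad", ["IGHD", "IGKC", "IGHZ9", ""])
    def test_unknown_constant_gene_rejected(self, bad):
        with pytest.raises(IsotypeError):
            assign_isotype_class(bad)


class TestCombinedIdentity:
    @pytest.mark.parametrize(
        "heavy, light, expected",
        [(100, 100, 100), (94, 98, 96), (95.8, 97.2, 96.5)],
    )
    def test_unweighted_mean(self, heavy, light, expected):
        assert combined_germline_identity(heavy, light) == pytest.approx(expected)

    @given(
        st.floats(0, 100, allow_nan=False),
        st.floats(0, 100, allow_nan=False),
    )
    def test_symmetric_and_bounded(self, h, l):
        combined = combined_germline_identity(h, l)
        assert combined == pytest.approx(combined_germline_identity(l, h))
        assert min(h, l) - 1e-9 <= combined <= max(h, l) + 1e-9

    def test_heavy_only_mode(self):
        assert combined_germline_identity(90.0, 100.0, heavy_weight=1.0) == 90.0

    @pytest.mark.parametrize("bad", [-0.1, 100.1])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            combined_germline_identity(bad, 50.0)


class TestIdentityBins:
    @pytest.mark.parametrize(
        "pct, expected",
        [
            (100.0, "B100"),
            (99.99, "B98"),
            (98.0, "B98"),   # left-closed boundary
            (97.9, "B96"),
            (96.0, "B96"),
            (94.0, "B94"),
            (93.9, "B_LT94"),
            (0.0, "B_LT94"),
        ],
    )
    def test_bin_boundaries(self, pct, expected):
        assert bin_germline_identity(pct) == expected

    @given(st.floats(0, 100, allow_nan=False))
    def test_bins_partition_the_range(self, pct):
        assert bin_germline_identity(pct) in ("B100", "B98", "B96", "B94", "B_LT94")

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_germline_identity(100.5)


class TestClusterGroups:
    @pytest.mark.parametrize(
        "cluster, group",
        [("INT-1", "DZ"), ("FCRL2/3", "MP"), ("PBL-2", "PBL"), ("INT-2", "LZ"),
         ("LZ-3", "LZ"), ("PreM", "MP"), ("DZ-3", "DZ")],
    )
    def test_mapping(self, cluster, group):
        assert assign_cluster_groups(cluster) == group

    def test_every_cluster_has_a_group(self):
        assert set(CLUSTERS) == set(CLUSTER_GROUPS)

    def test_unknown_cluster_rejected(self):
        with pytest.raises(ClusterError):
            assign_cluster_groups("DZ-9")


def test_annotate_cells_attaches_cluster_and_group():
    import pandas as pd

    contigs = [make_contig(), make_contig(chain="IGK")]
    cells, _ = filter_paired_cells(contigs, {"AAAC-1"})
    ann = pd.DataFrame(
        {"barcode": ["AAAC-1"], "donor": ["donor1"], "cluster": ["LZ-2"]}
    )
    annotate_cells(cells, ann)
    assert cells[0].cluster == "LZ-2"
    assert cells[0].group == "LZ"
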