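"""Cell-level quality filtering, heavy/light pairing and isotype assignment.

A cell passes QC when it has both gene-expression data and V(D)J data for
exactly one heavy and one light chain, each productive, full length, called
with high confidence and supported by more than 3 UMIs, and its heavy-chain
constant gene is neither missing nor IGHD (naive phenotype).  Passing cells
carry a combined heavy+light V-region germline identity, a five-way identity
bin, an isotype class, and cluster/group labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ContigRecord

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

ISOTYPE_CLASSES = ("IGHM", "IGHG", "IGHA", "IGHE")

_SUBCLASS_TO_CLASS = {
    "IGHM": "IGHM",
    "IGHE": "IGHE",
    "IGHG": "IGHG",
    "IGHG1": "IGHG",
    "IGHG2": "IGHG",
    "IGHG3": "IGHG",
    "IGHG4": "IGHG",
    "IGHA": "IGHA",
    "IGHA1": "IGHA",
    "IGHA2": "IGHA",
}

IDENTITY_BINS = ("B100", "B98", "B96", "B94", "B_LT94")

#: 14 germinal-center clusters, in dark-zone -> plasmablast order.
CLUSTERS = (
    "DZ-1", "DZ-2", "DZ-3",
    "INT-1", "INT-2", "INT-3", "INT-4",
    "LZ-1", "LZ-2", "LZ-3",
    "FCRL2/3", "PreM",
    "PBL-1", "PBL-2",
)

#: Coarse cluster groups: DZ-like, LZ-like, memory precursors, plasmablasts.
CLUSTER_GROUPS: dict[str, str] = {
    "DZ-1": "DZ", "DZ-2": "DZ", "DZ-3": "DZ", "INT-1": "DZ",
    "INT-2": "LZ", "INT-4": "LZ", "LZ-1": "LZ", "LZ-2": "LZ", "LZ-3": "LZ",
    "INT-3": "MP", "PreM": "MP", "FCRL2/3": "MP",
    "PBL-1": "PBL", "PBL-2": "PBL",
}

GROUPS = ("DZ", "LZ", "MP", "PBL")

#: Columns of the per-cell output table written by the qc stage.
CELL_TABLE_COLUMNS = [
    "barcode", "donor", "cluster", "group",
    "isotype_subclass", "isotype_class",
    "heavy_v", "heavy_d", "heavy_j", "light_v", "light_j",
    "cdr3_nt_heavy", "cdr3_nt_light",
    "identity_heavy", "identity_light",
    "germline_identity_pct", "identity_bin",
]


class IsotypeError(ValueError):
    """Constant-gene call cannot be mapped to an isotype class."""


class ClusterError(ValueError):
    """Unknown cluster label."""


@dataclass
class PairedCell:
    """A QC-passing cell with exactly one heavy and one light chain."""

    barcode: str
    donor: str
    heavy: ContigRecord
    light: ContigRecord
    isotype_subclass: str
    isotype_class: str
    germline_identity_pct: float
    identity_bin: str
    cluster: str | None = None
    group: str | None = None


# ---------------------------------------------------------------------------
# Elementary assignments
# ---------------------------------------------------------------------------

def assign_isotype_class(c_gene: str) -> str:
    """Collapse a heavy-chain constant-gene call to its isotype class.

    IGHG1–4 -> IGHG, IGHA1–2 -> IGHA; IGHM and IGHE map to themselves.
    IGHD is rejected (such cells are removed upstream).
    """
    if c_gene == "IGHD":
        raise IsotypeError("IGHD cells are excluded upstream of isotype assignment")
    try:
        return _SUBCLASS_TO_CLASS[c_gene]
    except KeyError:
        raise IsotypeError(f"unknown heavy-chain constant gene {c_gene!r}") from None


def combined_germline_identity(
    heavy_pct: float,
    light_pct: float,
    heavy_weight: float = 0.5,
) -> float:
    """Combine heavy- and light-chain V germline identities into one per-cell value.

    The default is the unweighted arithmetic mean of the two chains.
    ``heavy_weight`` exposes alternative convex combinations (1.0 =
    heavy-chain only).
    """
    for value in (heavy_pct, light_pct):
        if not 0.0 <= value <= 100.0:
            raise ValueError(f"identity {value} outside [0, 100]")
    if not 0.0 <= heavy_weight <= 1.0:
        raise ValueError(f"heavy_weight {heavy_weight} outside [0, 1]")
    return heavy_weight * heavy_pct + (1.0 - heavy_weight) * light_pct


def bin_germline_identity(pct: float) -> str:
    """Assign a combined germline identity to one of five left-closed bins.

    B100 is the exact-100% (unmutated) point mass; B98/B96/B94 are the
    half-open intervals [98,100), [96,98), [94,96); B_LT94 is everything
    below 94%.  The five bins partition [0, 100].
    """
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"identity {pct} outside [0, 100]")
    if pct == 100.0:
        return "B100"
    if pct >= 98.0:
        return "B98"
    if pct >= 96.0:
        return "B96"
    if pct >= 94.0:
        return "B94"
    return "B_LT94"


#: Coarse strata over the five bins used in reporting.
IDENTITY_STRATA = {
    "unmutated": ("B100",),
    "high_identity_ge98": ("B100", "B98"),
    "mutated_lt98": ("B96", "B94", "B_LT94"),
    "heavily_mutated_lt94": ("B_LT94",),
}


def assign_cluster_groups(
    cluster: str, mapping: Mapping[str, str] | None = None
) -> str:
    """Map a cluster label to its coarse group (DZ, LZ, MP or PBL)."""
    table = CLUSTER_GROUPS if mapping is None else mapping
    try:
        return table[cluster]
    except KeyError:
        raise ClusterError(f"unknown cluster label {cluster!r}") from None


# ---------------------------------------------------------------------------
# The secondary filter
# ---------------------------------------------------------------------------

#: Drop-reason keys of the QC audit, in the order the rules are applied.
AUDIT_REASONS = (
    "not_in_expression",
    "no_eligible_heavy",
    "multiple_eligible_heavy",
    "no_eligible_light",
    "multiple_eligible_light",
    "heavy_missing_c_gene",
    "heavy_ighd",
)


def _contig_eligible(contig: ContigRecord, umi_min: int) -> bool:
    return (
        contig.productive
        and contig.full_length
        and contig.high_confidence
        and contig.umis >= umi_min
    )


def filter_paired_cells(
    contigs: Iterable[ContigRecord],
    expressed_barcodes: set[str] | Mapping[str, set[str]],
    umi_min: int = 4,
    heavy_weight: float = 0.5,
) -> tuple[list[PairedCell], dict[str, int]]:
    """Apply the secondary cell filter and pair heavy with light chains.

    Parameters
    ----------
    contigs
        All assembled contigs, any number of donors; grouped internally by
        (donor, barcode).
    expressed_barcodes
        Barcodes present in the gene-expression data — either one pooled set,
        or a mapping donor -> set for cohorts where barcodes are only unique
        within a donor.
    umi_min
        Minimum UMI count for a contig to be eligible; the default 4
        implements the strict "more than 3 UMIs" rule.
    heavy_weight
        Weight of the heavy chain in the combined germline identity.

    Returns
    -------
    (cells, audit)
        QC-passing cells in input barcode order, and a counter of kept cells
        plus per-rule drop reasons.  Cells failing a rule are silently
        dropped; nothing raises.
    """
    by_cell: dict[tuple[str, str], list[ContigRecord]] = {}
    order: list[tuple[str, str]] = []
    for contig in contigs:
        key = (contig.donor, contig.barcode)
        if key not in by_cell:
            by_cell[key] = []
            order.append(key)
        by_cell[key].append(contig)

    audit = {reason: 0 for reason in AUDIT_REASONS}
    audit["kept"] = 0
    cells: list[PairedCell] = []
    for donor, barcode in order:
        if isinstance(expressed_barcodes, Mapping):
            expressed = barcode in expressed_barcodes.get(donor, ())
        else:
            expressed = barcode in expressed_barcodes
        if not expressed:
            audit["not_in_expression"] += 1
            continue
        eligible = [c for c in by_cell[(donor, barcode)] if _contig_eligible(c, umi_min)]
        heavies = [c for c in eligible if c.chain == "IGH"]
        lights = [c for c in eligible if c.chain in ("IGK", "IGL")]
        if len(heavies) == 0:
            audit["no_eligible_heavy"] += 1
            continue
        if len(heavies) > 1:
            audit["multiple_eligible_heavy"] += 1
            continue
        if len(lights) == 0:
            audit["no_eligible_light"] += 1
            continue
        if len(lights) > 1:
            audit["multiple_eligible_light"] += 1
            continue
        heavy, light = heavies[0], lights[0]
        if heavy.c_gene == "":
            audit["heavy_missing_c_gene"] += 1
            continue
        if heavy.c_gene == "IGHD":
            audit["heavy_ighd"] += 1
            continue
        identity = combined_germline_identity(
            heavy.v_identity_pct, light.v_identity_pct, heavy_weight
        )
        cells.append(
            PairedCell(
                barcode=barcode,
                donor=donor,
                heavy=heavy,
                light=light,
                isotype_subclass=heavy.c_gene,
                isotype_class=assign_isotype_class(heavy.c_gene),
                germline_identity_pct=identity,
                identity_bin=bin_germline_identity(identity),
            )
        )
        audit["kept"] += 1
    return cells, audit


def annotate_cells(
    cells: Sequence[PairedCell],
    annotations: pd.DataFrame,
    group_mapping: Mapping[str, str] | None = None,
) -> list[PairedCell]:
    """Attach cluster and group labels from an annotation table, in place.

    Cells without an annotation row (or with an empty cluster field) keep
    ``cluster=None``; annotated cells must carry a known cluster label.
    """
    lookup: dict[tuple[str, str], str] = {}
    if "cluster" in annotations.columns:
        for donor, barcode, cluster in zip(
            annotations["donor"], annotations["barcode"], annotations["cluster"]
        ):
            if cluster:
                lookup[(donor, barcode)] = cluster
    for cell in cells:
        cluster = lookup.get((cell.donor, cell.barcode))
        cell.cluster = cluster
        cell.group = (
            assign_cluster_groups(cluster, group_mapping) if cluster else None
        )
    return list(cells)


# ---------------------------------------------------------------------------
# Tabular round trip (for the staged CLI)
# ---------------------------------------------------------------------------

def cells_to_table(cells: Sequence[PairedCell]) -> pd.DataFrame:
    rows = []
    for c in cells:
        rows.append(
            {
                "barcode": c.barcode,
                "donor": c.donor,
                "cluster": c.cluster or "",
                "group": c.group or "",
                "isotype_subclass": c.isotype_subclass,
                "isotype_class": c.isotype_class,
                "heavy_v": c.heavy.v_gene,
                "heavy_d": c.heavy.d_gene,
                "heavy_j": c.heavy.j_gene,
                "light_v": c.light.v_gene,
                "light_j": c.light.j_gene,
                "cdr3_nt_heavy": c.heavy.cdr3_nt,
                "cdr3_nt_light": c.light.cdr3_nt,
                "identity_heavy": c.heavy.v_identity_pct,
                "identity_light": c.light.v_identity_pct,
                "germline_identity_pct": c.germline_identity_pct,
                "identity_bin": c.identity_bin,
            }
        )
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)


def cells_from_table(df: pd.DataFrame) -> list[PairedCell]:
    """Rebuild :class:`PairedCell` objects from a qc-stage output table.

    Chain-level QC flags and UMI counts are not stored in the table; the
    reconstructed contigs carry pass-through values for them (the cells
    already passed QC).
    """
    cells = []
    for row in df.itertuples(index=False):
        heavy = ContigRecord(
            barcode=row.barcode, donor=row.donor, chain="IGH",
            v_gene=row.heavy_v, d_gene=str(row.heavy_d) if str(row.heavy_d) != "nan" else "",
            j_gene=row.heavy_j, c_gene=row.isotype_subclass,
            cdr3_nt=row.cdr3_nt_heavy, productive=True, full_length=True,
            high_confidence=True, umis=4, v_identity_pct=float(row.identity_heavy),
        )
        locus = row.light_v[:3] if isinstance(row.light_v, str) else "IGK"
        light = ContigRecord(
            barcode=row.barcode, donor=row.donor,
            chain=locus if locus in ("IGK", "IGL") else "IGK",
            v_gene=row.light_v, d_gene="", j_gene=row.light_j, c_gene="",
            cdr3_nt=row.cdr3_nt_light, productive=True, full_length=True,
            high_confidence=True, umis=4, v_identity_pct=float(row.identity_light),
        )
        cluster = row.cluster if row.cluster else None
        cells.append(
            PairedCell(
                barcode=row.barcode, donor=row.donor, heavy=heavy, light=light,
                isotype_subclass=row.isotype_subclass,
                isotype_class=row.isotype_class,
                germline_identity_pct=float(row.germline_identity_pct),
                identity_bin=row.identity_bin,
                cluster=cluster,
                group=(row.group if row.group else None),
            )
        )
    return cells
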