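"""Clonotype calling and intraclonal isotype-heterogeneity scoring.

Cells descend from the same B-cell precursor when they share (i) the same
called V(D)J gene segments on both chains and (ii) identical concatenated
heavy+light CDR3 nucleotide sequences; clonotype analysis is performed on
each donor separately.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .qc import PairedCell

#: (heavy V, heavy D, heavy J, light V, light J, heavy CDR3 + light CDR3)
CloneKey = tuple[str, str, str, str, str, str]


@dataclass
class Clonotype:
    id: str
    donor: str
    key: CloneKey
    members: list[str]
    isotype_classes: set[str]
    isotype_subclasses: set[str]
    cluster_composition: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.members)


def clone_key(cell: PairedCell) -> CloneKey:
    """Clonal fingerprint: gene-level segment calls plus exact CDR3 nt join."""
    return (
        cell.heavy.v_gene,
        cell.heavy.d_gene,
        cell.heavy.j_gene,
        cell.light.v_gene,
        cell.light.j_gene,
        cell.heavy.cdr3_nt + cell.light.cdr3_nt,
    )


def call_clonotypes(cells: Sequence[PairedCell]) -> list[Clonotype]:
    """Group cells into clonotypes by exact key equality, per donor.

    Clone ids are assigned deterministically as ``<donor>_clone<k>`` with k
    ordered by descending size, then lexicographic key; input order does not
    affect the result.  Every cell belongs to exactly one clonotype.
    """
    grouped: dict[tuple[str, CloneKey], list[PairedCell]] = {}
    for cell in cells:
        grouped.setdefault((cell.donor, clone_key(cell)), []).append(cell)

    per_donor: dict[str, list[tuple[CloneKey, list[PairedCell]]]] = {}
    for (donor, key), members in grouped.items():
        per_donor.setdefault(donor, []).append((key, members))

    clones: list[Clonotype] = []
    for donor in sorted(per_donor):
        entries = sorted(per_donor[donor], key=lambda kv: (-len(kv[1]), kv[0]))
        for rank, (key, members) in enumerate(entries, start=1):
            members = sorted(members, key=lambda c: c.barcode)
            clones.append(
                Clonotype(
                    id=f"{donor}_clone{rank}",
                    donor=donor,
                    key=key,
                    members=[c.barcode for c in members],
                    isotype_classes={c.isotype_class for c in members},
                    isotype_subclasses={c.isotype_subclass for c in members},
                    cluster_composition=dict(
                        Counter(c.cluster for c in members if c.cluster)
                    ),
                )
            )
    return clones


def clone_size_summary(
    clonotypes: Sequence[Clonotype],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-donor clone-size statistics.

    Returns
    -------
    (summary, histogram)
        ``summary``: one row per donor with the number of clonotypes, number
        of cells, fraction of cells in singleton clonotypes, and maximum
        clone size.  ``histogram``: (donor, size, n_clones) rows.
    """
    if not clonotypes:
        raise ValueError("empty clonotype list")
    rows = []
    hist_rows = []
    donors = sorted({c.donor for c in clonotypes})
    for donor in donors:
        sizes = [c.size for c in clonotypes if c.donor == donor]
        n_cells = sum(sizes)
        singleton_cells = sum(1 for s in sizes if s == 1)
        rows.append(
            {
                "donor": donor,
                "n_clonotypes": len(sizes),
                "n_cells": n_cells,
                "singleton_cell_fraction": singleton_cells / n_cells,
                "max_clone_size": max(sizes),
            }
        )
        for size, count in sorted(Counter(sizes).items()):
            hist_rows.append({"donor": donor, "size": size, "n_clones": count})
    return pd.DataFrame(rows), pd.DataFrame(hist_rows)


@dataclass
class HeterogeneityResult:
    """Intraclonal isotype heterogeneity among clones of at least ``min_size`` cells.

    ``fraction`` is NaN when no clone reaches ``min_size`` (zero denominator).
    """

    fraction: float
    n_eligible: int
    n_heterogeneous: int
    flags: dict[str, bool]


def clone_isotype_heterogeneity(
    clonotypes: Sequence[Clonotype],
    min_size: int = 5,
    level: str = "class",
) -> HeterogeneityResult:
    """Fraction of clones (size >= min_size) whose members span >= 2 isotypes.

    At the default ``level="class"`` heterogeneity is judged on the four
    isotype classes, so a clone mixing IGHG1 and IGHG2 is homogeneous —
    the statistic measures class switching within clones.  ``level=
    "subclass"`` distinguishes constant-gene subclasses instead.
    """
    if min_size < 2:
        raise ValueError("min_size must be at least 2")
    if level not in ("class", "subclass"):
        raise ValueError(f"unknown level {level!r}")
    flags: dict[str, bool] = {}
    n_het = 0
    for clone in clonotypes:
        if clone.size < min_size:
            continue
        observed = (
            clone.isotype_classes if level == "class" else clone.isotype_subclasses
        )
        flags[clone.id] = len(observed) >= 2
        n_het += flags[clone.id]
    n_eligible = len(flags)
    fraction = n_het / n_eligible if n_eligible else math.nan
    return HeterogeneityResult(
        fraction=fraction,
        n_eligible=n_eligible,
        n_heterogeneous=n_het,
        flags=flags,
    )


def clonotypes_to_table(clonotypes: Sequence[Clonotype], min_size: int = 5) -> pd.DataFrame:
    het = clone_isotype_heterogeneity(clonotypes, min_size=min_size) if clonotypes else None
    rows = []
    for c in clonotypes:
        rows.append(
            {
                "clone_id": c.id,
                "donor": c.donor,
                "size": c.size,
                "n_isotype_classes": len(c.isotype_classes),
                "heterogeneous": het.flags.get(c.id, "") if het else "",
                "isotype_classes": ",".join(sorted(c.isotype_classes)),
                "heavy_v": c.key[0],
                "heavy_d": c.key[1],
                "heavy_j": c.key[2],
                "light_v": c.key[3],
                "light_j": c.key[4],
                "cdr3_nt_concat": c.key[5],
            }
        )
    return pd.DataFrame(rows)
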