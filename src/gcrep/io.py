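"""Readers and writers for the pipeline's external file formats.

Covers 10x-style V(D)J contig annotation tables (CSV), sparse UMI count
matrices (MatrixMarket + barcode/feature sidecars), per-cell annotation
tables (TSV) and gene-set collections (GMT), mapped onto the pipeline's
in-memory types.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """An input file violates the expected dialect."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

VALID_CHAINS = ("IGH", "IGK", "IGL")


@dataclass(frozen=True)
class ContigRecord:
    """One assembled V(D)J contig.

    ``v_identity_pct`` is the percent nucleotide identity of the rearranged
    V region to its inferred germline segment (100 = unmutated), supplied as
    an input column; it is not recomputed from sequence.
    """

    barcode: str
    donor: str
    chain: str
    v_gene: str
    d_gene: str
    j_gene: str
    c_gene: str
    cdr3_nt: str
    productive: bool
    full_length: bool
    high_confidence: bool
    umis: int
    v_identity_pct: float

    def __post_init__(self) -> None:
        if self.chain not in VALID_CHAINS:
            raise ValueError(f"unknown chain {self.chain!r}")
        if self.umis < 0:
            raise ValueError(f"negative UMI count {self.umis}")
        if not 0.0 <= self.v_identity_pct <= 100.0:
            raise ValueError(
                f"v_identity_pct {self.v_identity_pct} outside [0, 100]"
            )


@dataclass
class CountMatrix:
    """Cells x genes sparse UMI count matrix."""

    cells: list[str]
    genes: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        if len(set(self.cells)) != len(self.cells):
            raise FormatError("duplicate cell barcodes in count matrix")
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene symbols in count matrix")
        if self.counts.shape != (len(self.cells), len(self.genes)):
            raise FormatError(
                f"matrix shape {self.counts.shape} does not match "
                f"{len(self.cells)} cells x {len(self.genes)} genes"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts in matrix")


@dataclass
class GeneSetCollection:
    """Named gene sets read from a GMT file."""

    sets: dict[str, list[str]]
    source: str = ""


# ---------------------------------------------------------------------------
# Contig tables
# ---------------------------------------------------------------------------

#: Default column mapping for the 10x ``filtered_contig_annotations.csv``
#: dialect.  ``v_identity`` is an extension column (10x does not emit one).
DEFAULT_CONTIG_COLUMNS: dict[str, str] = {
    "barcode": "barcode",
    "chain": "chain",
    "v_gene": "v_gene",
    "d_gene": "d_gene",
    "j_gene": "j_gene",
    "c_gene": "c_gene",
    "cdr3_nt": "cdr3_nt",
    "productive": "productive",
    "full_length": "full_length",
    "high_confidence": "high_confidence",
    "umis": "umis",
    "v_identity_pct": "v_identity",
}

_TRUE = {"true"}
_FALSE = {"false"}
_MISSING_GENE = {"", "none", "nan"}


def _parse_bool(value: object, column: str, row: int) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise FormatError(f"row {row}: cannot parse boolean {value!r} in column {column!r}")


def _parse_gene(value: object) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    text = str(value).strip()
    return "" if text.lower() in _MISSING_GENE else text


def read_contig_table(
    path: str | Path,
    donor: str,
    column_map: Mapping[str, str] | None = None,
    identity_table: str | Path | None = None,
) -> list[ContigRecord]:
    """Read a contig annotation CSV into :class:`ContigRecord` rows.

    Parameters
    ----------
    path
        Contig annotation CSV (one row per assembled contig).
    donor
        Donor label attached to every record; never inferred from barcodes.
    column_map
        Mapping from record fields to CSV column names; defaults to the 10x
        ``filtered_contig_annotations.csv`` dialect with a ``v_identity``
        extension column.
    identity_table
        Optional separate CSV with columns ``barcode, chain, v_identity``
        keyed by (barcode, chain), for workflows where germline identity was
        computed outside the contig caller.  When given, the main table does
        not need an identity column.
    """
    columns = dict(DEFAULT_CONTIG_COLUMNS)
    if column_map:
        columns.update(column_map)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)

    identity_lookup: dict[tuple[str, str], float] | None = None
    if identity_table is not None:
        ident = pd.read_csv(identity_table, dtype=str, keep_default_na=False)
        for col in ("barcode", "chain", "v_identity"):
            if col not in ident.columns:
                raise FormatError(f"identity table missing required column {col!r}")
        identity_lookup = {
            (b, c): float(v)
            for b, c, v in zip(ident["barcode"], ident["chain"], ident["v_identity"])
        }

    required = [
        name
        for fieldname, name in columns.items()
        if not (fieldname == "v_identity_pct" and identity_lookup is not None)
        and fieldname != "d_gene"  # light chains have no D segment
    ]
    for name in required:
        if name not in df.columns:
            raise FormatError(f"contig table missing required column {name!r}")
    has_d = columns["d_gene"] in df.columns

    records: list[ContigRecord] = []
    for row_idx, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        barcode = row_d[columns["barcode"]]
        chain = row_d[columns["chain"]]
        try:
            umis = int(row_d[columns["umis"]])
        except ValueError as exc:
            raise FormatError(
                f"row {row_idx}: unparsable UMI count "
                f"{row_d[columns['umis']]!r}"
            ) from exc
        if identity_lookup is not None:
            try:
                v_identity = identity_lookup[(barcode, chain)]
            except KeyError as exc:
                raise FormatError(
                    f"row {row_idx}: no identity entry for "
                    f"({barcode!r}, {chain!r})"
                ) from exc
        else:
            v_identity = float(row_d[columns["v_identity_pct"]])
        records.append(
            ContigRecord(
                barcode=barcode,
                donor=donor,
                chain=chain,
                v_gene=_parse_gene(row_d[columns["v_gene"]]),
                d_gene=_parse_gene(row_d.get(columns["d_gene"], "")) if has_d else "",
                j_gene=_parse_gene(row_d[columns["j_gene"]]),
                c_gene=_parse_gene(row_d[columns["c_gene"]]),
                cdr3_nt=str(row_d[columns["cdr3_nt"]]).strip(),
                productive=_parse_bool(row_d[columns["productive"]], "productive", row_idx),
                full_length=_parse_bool(row_d[columns["full_length"]], "full_length", row_idx),
                high_confidence=_parse_bool(
                    row_d[columns["high_confidence"]], "high_confidence", row_idx
                ),
                umis=umis,
                v_identity_pct=v_identity,
            )
        )
    return records


def write_contig_table(records: Sequence[ContigRecord], path: str | Path) -> None:
    """Write records in the canonical contig CSV dialect (round-trippable)."""
    df = pd.DataFrame(
        {
            "barcode": [r.barcode for r in records],
            "chain": [r.chain for r in records],
            "v_gene": [r.v_gene for r in records],
            "d_gene": [r.d_gene for r in records],
            "j_gene": [r.j_gene for r in records],
            "c_gene": [r.c_gene for r in records],
            "cdr3_nt": [r.cdr3_nt for r in records],
            "productive": [r.productive for r in records],
            "full_length": [r.full_length for r in records],
            "high_confidence": [r.high_confidence for r in records],
            "umis": [r.umis for r in records],
            "v_identity": [repr(r.v_identity_pct) for r in records],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def _read_lines(path: str | Path) -> list[str]:
    with open(path) as handle:
        return [line.rstrip("\n") for line in handle if line.strip()]


def _dedup_symbols(symbols: list[str]) -> list[str]:
    """Disambiguate duplicate symbols with numeric suffixes (.1, .2, ...)."""
    seen: dict[str, int] = {}
    out = []
    for sym in symbols:
        if sym in seen:
            seen[sym] += 1
            out.append(f"{sym}.{seen[sym]}")
        else:
            seen[sym] = 0
            out.append(sym)
    return out


def read_expression_matrix(
    mtx_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
) -> CountMatrix:
    """Read a MatrixMarket UMI matrix with barcode/feature sidecars.

    The on-disk orientation (cells x genes or the 10x genes x cells
    convention) is inferred from the sidecar lengths; the returned matrix is
    always cells x genes.
    """
    mat = sp.coo_matrix(scipy.io.mmread(str(mtx_path)))
    barcodes = _read_lines(barcodes_path)
    feature_rows = [line.split("\t") for line in _read_lines(features_path)]
    # 10x features.tsv: id, symbol[, type]; single-column files carry the
    # symbol directly.
    symbols = [row[1] if len(row) >= 2 else row[0] for row in feature_rows]
    symbols = _dedup_symbols(symbols)

    n_cells, n_genes = len(barcodes), len(symbols)
    if mat.shape == (n_genes, n_cells) and mat.shape != (n_cells, n_genes):
        mat = mat.T
    elif mat.shape == (n_cells, n_genes):
        if n_cells == n_genes:
            # ambiguous square case: assume the 10x genes x cells convention
            mat = mat.T
    else:
        raise FormatError(
            f"matrix shape {mat.shape} matches neither "
            f"(cells={n_cells}, genes={n_genes}) nor its transpose"
        )
    counts = sp.csr_matrix(mat)
    if counts.nnz:
        data = counts.data
        if not np.allclose(data, np.round(data)) or data.min() < 0:
            raise FormatError("expression matrix must hold non-negative integers")
        counts.data = np.round(data).astype(np.int64)
    else:
        counts = counts.astype(np.int64)
    return CountMatrix(cells=barcodes, genes=symbols, counts=counts)


def write_expression_matrix(
    matrix: CountMatrix,
    mtx_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
) -> None:
    """Write a :class:`CountMatrix` in the genes x cells 10x convention."""
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(matrix.counts.T), field="integer")
    Path(barcodes_path).write_text("".join(b + "\n" for b in matrix.cells))
    Path(features_path).write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in matrix.genes)
    )


# ---------------------------------------------------------------------------
# Annotations, gene sets, result tables
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a per-cell annotation TSV (barcode, donor[, sorted_fraction], cluster)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("barcode", "donor"):
        if col not in df.columns:
            raise FormatError(f"annotation table missing required column {col!r}")
    dup = df.duplicated(subset=["donor", "barcode"])
    if dup.any():
        raise FormatError("duplicate (donor, barcode) in annotation table")
    return df


def read_gene_sets(path: str | Path, source: str | None = None) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, tab-separated symbols)."""
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise FormatError(f"duplicate gene set name {name!r}")
            genes: list[str] = []
            seen: set[str] = set()
            for gene in fields[2:]:
                gene = gene.strip()
                if gene and gene not in seen:
                    seen.add(gene)
                    genes.append(gene)
            if not genes:
                raise FormatError(f"line {lineno}: gene set {name!r} is empty")
            sets[name] = genes
    return GeneSetCollection(sets=sets, source=source or str(Path(path).name))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with header."""
    df.to_csv(path, sep="\t", index=False)


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
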