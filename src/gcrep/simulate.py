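"""Synthetic paired expression + V(D)J cohort generator.

Emulates the statistical structure of a sorted germinal-center B-cell
cohort: 14 transcriptional clusters (dark zone, intermediate, light zone,
FCRL2/3, memory precursors, plasmablasts), per-cluster V-region
germline-identity mixtures (including the bimodal memory-precursor
pattern), per-cluster isotype-class probabilities, donor-scoped clonal
structure with irreversible intraclonal class switching, and
negative-binomial UMI counts with hallmark-gene fold-ups.  Output is
written in exactly the input formats the pipeline reads, so every stage is
testable without external data.

The default calibration is anchored on pooled repertoire marginals of a
tonsillar GC cohort: median combined germline identity 95.5%, 2% unmutated
cells, 15% at >=98% identity, 32% below 94%; isotype classes 43% IGHG,
33% IGHA, 24% IGHM; a bimodal memory-precursor cluster (36% unmutated, 51%
below 98%, 54% IGHM) and IGHG-dominated plasmablasts (71%).  Free bulk
(DZ/LZ) weights are solved in closed form from these pooled constraints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as gio
from .qc import CLUSTERS, CLUSTER_GROUPS, IDENTITY_BINS, ISOTYPE_CLASSES

# ---------------------------------------------------------------------------
# Profile
# ---------------------------------------------------------------------------

#: Identity-bin labels in mixture order (point mass at 100, then the
#: half-open bins [98,100), [96,98), [94,96), [71,94)).
BIN_ORDER = IDENTITY_BINS
_BIN_RANGES = {"B98": (98.0, 100.0), "B96": (96.0, 98.0), "B94": (94.0, 96.0),
               "B_LT94": (71.0, 94.0)}

_SUBCLASSES = {
    "IGHM": ("IGHM",),
    "IGHG": ("IGHG1", "IGHG2", "IGHG3", "IGHG4"),
    "IGHA": ("IGHA1", "IGHA2"),
    "IGHE": ("IGHE",),
}

#: Hallmark genes and the clusters where they are induced.
HALLMARK_GENES: dict[str, tuple[str, ...]] = {
    "CXCR4": ("DZ-1", "DZ-2", "DZ-3", "INT-1"),
    "AICDA": ("DZ-1", "DZ-2", "DZ-3", "INT-1"),
    "CD83": ("INT-2", "INT-4", "LZ-1", "LZ-2", "LZ-3"),
    "BCL2A1": ("INT-2", "INT-4", "LZ-1", "LZ-2", "LZ-3"),
    "CCR6": ("PreM",),
    "CELF2": ("PreM",),
    "PRDM1": ("PBL-1", "PBL-2"),
    "FKBP11": ("PBL-1", "PBL-2"),
    "FCRL2": ("FCRL2/3",),
    "FCRL3": ("FCRL2/3",),
}

_HEAVY_V = tuple(f"IGHV{f}-{n}" for f, n in
                 [(1, 2), (1, 18), (1, 69), (2, 5), (3, 7), (3, 15), (3, 21),
                  (3, 23), (3, 30), (3, 48), (4, 4), (4, 34), (4, 39), (4, 59),
                  (5, 51), (6, 1)])
_HEAVY_D = tuple(f"IGHD{f}-{n}" for f, n in
                 [(1, 1), (1, 26), (2, 2), (2, 15), (3, 3), (3, 10), (3, 22),
                  (4, 17), (5, 12), (6, 13), (6, 19), (7, 27)])
_HEAVY_J = tuple(f"IGHJ{i}" for i in range(1, 7))
_KAPPA_V = tuple(f"IGKV{f}-{n}" for f, n in
                 [(1, 5), (1, 33), (1, 39), (2, 28), (2, 30), (3, 11), (3, 15),
                  (3, 20), (4, 1)])
_KAPPA_J = tuple(f"IGKJ{i}" for i in range(1, 6))
_LAMBDA_V = tuple(f"IGLV{f}-{n}" for f, n in
                  [(1, 40), (1, 44), (1, 51), (2, 8), (2, 14), (2, 23), (3, 1),
                   (3, 19), (3, 21)])
_LAMBDA_J = tuple(f"IGLJ{i}" for i in (1, 2, 3, 7))


@dataclass
class CohortProfile:
    """Full parameterization of the synthetic cohort generator."""

    n_cells: int = 40_000
    n_donors: int = 3
    seed: int = 0
    cluster_proportions: dict[str, float] = field(default_factory=dict)
    #: per cluster: weights over (B100, B98, B96, B94, B_LT94)
    identity_model: dict[str, dict[str, float]] = field(default_factory=dict)
    #: per cluster: probabilities over (IGHM, IGHG, IGHA, IGHE)
    isotype_probs: dict[str, dict[str, float]] = field(default_factory=dict)
    clonal_model: dict[str, float] = field(default_factory=dict)
    expression_model: dict[str, float] = field(default_factory=dict)
    contaminant_rate: float = 0.02

    def validate(self) -> None:
        if abs(sum(self.cluster_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("cluster proportions must sum to 1")
        for cluster in CLUSTERS:
            for name, vec, keys in (
                ("identity", self.identity_model[cluster], BIN_ORDER),
                ("isotype", self.isotype_probs[cluster], ISOTYPE_CLASSES),
            ):
                total = sum(vec[k] for k in keys)
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(f"{name} weights for {cluster} sum to {total}")
                if any(vec[k] < 0 for k in keys):
                    raise ValueError(f"negative {name} weight for {cluster}")

    def to_json(self, path: str | Path) -> None:
        gio.write_json(self.__dict__, path)

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortProfile":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def _solve_bulk(pooled: dict[str, float],
                fixed: dict[str, dict[str, float]],
                proportions: dict[str, float],
                bulk_clusters: Sequence[str],
                keys: Sequence[str]) -> dict[str, float]:
    """Solve the shared bulk weight vector from pooled-marginal constraints.

    Given pooled targets m_k = p_bulk * b_k + sum_c p_c * w_ck over the
    fixed (non-bulk) clusters c, returns b.  Raises if the solution is not a
    probability vector.
    """
    p_bulk = sum(proportions[c] for c in bulk_clusters)
    bulk = {}
    for k in keys:
        fixed_mass = sum(proportions[c] * fixed[c][k] for c in fixed)
        bulk[k] = (pooled[k] - fixed_mass) / p_bulk
        if bulk[k] < 0:
            raise ValueError(f"bulk weight for {k} is negative: {bulk[k]}")
    total = sum(bulk.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"bulk weights sum to {total}")
    return bulk


def default_profile() -> CohortProfile:
    """The shipped cohort calibration (see module docstring for the anchors)."""
    proportions = {
        "DZ-1": 0.12, "DZ-2": 0.10, "DZ-3": 0.08,
        "INT-1": 0.10, "INT-2": 0.09, "INT-3": 0.02, "INT-4": 0.08,
        "LZ-1": 0.13, "LZ-2": 0.10, "LZ-3": 0.07,
        "FCRL2/3": 0.02, "PreM": 0.04, "PBL-1": 0.03, "PBL-2": 0.02,
    }
    bulk_clusters = [c for c in CLUSTERS if CLUSTER_GROUPS[c] in ("DZ", "LZ")]

    # Pooled identity-bin marginals.  B100 = 2% unmutated; B100+B98 = 15%
    # high-identity; B_LT94 = 32% heavily mutated; B94 = 24% places the
    # pooled median at 94 + 2*(0.50-0.32)/0.24 = 95.5%.
    pooled_bins = {"B100": 0.02, "B98": 0.13, "B96": 0.29, "B94": 0.24,
                   "B_LT94": 0.32}
    fixed_identity = {
        # bimodal memory precursors: 36% unmutated, 51% below 98%, 18% below 94%
        "PreM": {"B100": 0.36, "B98": 0.13, "B96": 0.18, "B94": 0.15,
                 "B_LT94": 0.18},
        # almost exclusively high-identity
        "INT-3": {"B100": 0.08, "B98": 0.84, "B96": 0.05, "B94": 0.02,
                  "B_LT94": 0.01},
        "FCRL2/3": {"B100": 0.06, "B98": 0.40, "B96": 0.28, "B94": 0.16,
                    "B_LT94": 0.10},
        # plasmablasts: mostly mutated but depleted below 94% (17%)
        "PBL-1": {"B100": 0.02, "B98": 0.21, "B96": 0.33, "B94": 0.27,
                  "B_LT94": 0.17},
        "PBL-2": {"B100": 0.02, "B98": 0.21, "B96": 0.33, "B94": 0.27,
                  "B_LT94": 0.17},
    }
    bulk_identity = _solve_bulk(pooled_bins, fixed_identity, proportions,
                                bulk_clusters, BIN_ORDER)
    identity_model = {
        c: dict(fixed_identity.get(c, bulk_identity)) for c in CLUSTERS
    }

    # Pooled isotype-class marginals: IGHG 43%, IGHA 33%, IGHM 24%, IGHE ~0.
    pooled_iso = {"IGHM": 0.24, "IGHG": 0.43, "IGHA": 0.33, "IGHE": 0.0}
    fixed_iso = {
        "PreM": {"IGHM": 0.54, "IGHG": 0.30, "IGHA": 0.16, "IGHE": 0.0},
        "INT-3": {"IGHM": 0.78, "IGHG": 0.13, "IGHA": 0.09, "IGHE": 0.0},
        "FCRL2/3": {"IGHM": 0.78, "IGHG": 0.13, "IGHA": 0.09, "IGHE": 0.0},
        "PBL-1": {"IGHM": 0.08, "IGHG": 0.71, "IGHA": 0.21, "IGHE": 0.0},
        "PBL-2": {"IGHM": 0.08, "IGHG": 0.71, "IGHA": 0.21, "IGHE": 0.0},
    }
    bulk_iso = _solve_bulk(pooled_iso, fixed_iso, proportions, bulk_clusters,
                           ISOTYPE_CLASSES)
    isotype_probs = {c: dict(fixed_iso.get(c, bulk_iso)) for c in CLUSTERS}

    profile = CohortProfile(
        cluster_proportions=proportions,
        identity_model=identity_model,
        isotype_probs=isotype_probs,
        clonal_model={
            # cell fraction in singleton clones s**2 = 0.74 under a
            # geometric size law with success probability s
            "singleton_cell_fraction": 0.74,
            "max_clone_size": 30,
            # one switch event per non-founder member with probability
            # p_switch; 1-(1-p)^4 ~ 0.33 makes ~21% of size-5 clones
            # heterogeneous once IGHA founders (which cannot switch
            # further) are accounted for
            "p_switch": 0.09,
        },
        expression_model={
            "n_genes": 400,
            "baseline_mean": 0.3,
            "dispersion": 0.5,
            "hallmark_fold": 6.0,
        },
        contaminant_rate=0.02,
    )
    profile.validate()
    return profile


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

#: Contaminant classes injected to exercise the QC audit, with the QC drop
#: reason each one must trigger.
CONTAMINANT_REASONS = {
    "extra_heavy": "multiple_eligible_heavy",
    "low_umi": "no_eligible_heavy",
    "ighd": "heavy_ighd",
    "nonproductive": "no_eligible_heavy",
    "no_expression": "not_in_expression",
}


@dataclass
class CohortTruth:
    """Ground truth and file handles of one generated cohort."""

    profile: CohortProfile
    cells: pd.DataFrame        # barcode, donor, cluster, clone_id, isotype, identity, contaminant
    contaminants: pd.DataFrame  # barcode, donor, type, expected_audit_reason
    donor_dirs: dict[str, Path]
    annotations_path: Path
    profile_path: Path

    @property
    def expected_kept(self) -> pd.DataFrame:
        return self.cells[self.cells["contaminant"] == ""]


def _random_cdr3(rng: np.random.Generator, codons_lo: int, codons_hi: int) -> str:
    length = 3 * int(rng.integers(codons_lo, codons_hi + 1))
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _draw_identity(rng: np.random.Generator, weights: dict[str, float]) -> float:
    bin_label = BIN_ORDER[rng.choice(len(BIN_ORDER),
                                     p=[weights[b] for b in BIN_ORDER])]
    if bin_label == "B100":
        return 100.0
    lo, hi = _BIN_RANGES[bin_label]
    return float(rng.uniform(lo, hi))


def _split_identity(rng: np.random.Generator, target: float) -> tuple[float, float]:
    """Decompose a per-cell identity into heavy/light values whose mean is the target."""
    half_span = min(0.5, 100.0 - target, target)
    delta = float(rng.uniform(-half_span, half_span)) if half_span > 0 else 0.0
    return target + delta, target - delta


#: When an IGHM cell switches, it picks IGHG with this probability (else IGHA).
_SWITCH_TO_G = 0.6


def _switch_class(rng: np.random.Generator, founder: str) -> str:
    """One irreversible class-switch event (IGHM -> IGHG/IGHA, IGHG -> IGHA)."""
    if founder == "IGHM":
        return "IGHG" if rng.random() < _SWITCH_TO_G else "IGHA"
    if founder == "IGHG":
        return "IGHA"
    return founder  # IGHA / IGHE cannot switch further


def _founder_probs(marginal: dict[str, float], alpha: float) -> list[float]:
    """Founder-class distribution whose post-switch marginal equals ``marginal``.

    ``alpha`` is the per-cell probability of having undergone one switch
    event (non-founder fraction x p_switch).  Inverts the switch kernel
    M -> {G, A}, G -> A so the realized per-cluster isotype fractions match
    the profile's probabilities in expectation; infeasible corrections
    (possible for extreme p_switch) are clipped and renormalized.
    """
    f_m = marginal["IGHM"] / (1.0 - alpha)
    f_g = (marginal["IGHG"] - f_m * alpha * _SWITCH_TO_G) / (1.0 - alpha)
    f_a = marginal["IGHA"] - f_g * alpha - f_m * alpha * (1.0 - _SWITCH_TO_G)
    f = np.clip([f_m, f_g, f_a, marginal["IGHE"]], 0.0, None)
    return list(f / f.sum())


def _clone_sizes(rng: np.random.Generator, n: int, singleton_cell_fraction: float,
                 max_size: int) -> list[int]:
    """Partition n cells into clone sizes from a truncated geometric law."""
    s = float(np.sqrt(singleton_cell_fraction))
    sizes: list[int] = []
    remaining = n
    while remaining > 0:
        size = min(int(rng.geometric(s)), max_size, remaining)
        sizes.append(size)
        remaining -= size
    return sizes


def generate_cohort(profile: CohortProfile, out_dir: str | Path) -> CohortTruth:
    """Generate a cohort and write it in the pipeline's input formats.

    Per donor: a contig CSV (two contigs per cell, plus injected
    contaminants), a MatrixMarket UMI matrix with barcode/feature sidecars,
    and a shared top-level annotation TSV and profile JSON.  Runs are
    bit-reproducible for a fixed profile (including its seed).
    """
    profile.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(profile.seed)

    cluster_list = list(CLUSTERS)
    props = np.array([profile.cluster_proportions[c] for c in cluster_list])
    expr = profile.expression_model
    n_genes = int(expr["n_genes"])
    hallmark = [g for g in HALLMARK_GENES if g != ""]
    genes = hallmark + [f"GENE{i:04d}" for i in range(1, n_genes - len(hallmark) + 1)]
    gene_cluster_fold = np.ones((len(cluster_list), len(genes)))
    for j, gene in enumerate(genes):
        for cluster in HALLMARK_GENES.get(gene, ()):
            gene_cluster_fold[cluster_list.index(cluster), j] = expr["hallmark_fold"]

    base = profile.n_cells // profile.n_donors
    remainder = profile.n_cells - base * profile.n_donors

    # founder-class distributions compensated for intraclonal switching
    singleton_frac = profile.clonal_model["singleton_cell_fraction"]
    nonfounder_frac = 1.0 - float(np.sqrt(singleton_frac))
    alpha = nonfounder_frac * profile.clonal_model["p_switch"]
    founder_probs = {
        cluster: _founder_probs(profile.isotype_probs[cluster], alpha)
        for cluster in cluster_list
    }

    cell_rows: list[dict] = []
    contaminant_rows: list[dict] = []
    donor_dirs: dict[str, Path] = {}
    contaminant_types = list(CONTAMINANT_REASONS)

    for d in range(profile.n_donors):
        donor = f"donor{d + 1}"
        donor_dir = out / donor
        donor_dir.mkdir(exist_ok=True)
        donor_dirs[donor] = donor_dir
        n_d = base + (1 if d < remainder else 0)
        barcodes = [f"{donor}-{i:06d}" for i in range(n_d)]

        cluster_idx = rng.choice(len(cluster_list), size=n_d, p=props)

        # clonal structure within each (donor, cluster) stratum
        clone_of = np.empty(n_d, dtype=object)
        founder_class: dict[str, str] = {}
        clone_genes: dict[str, tuple] = {}
        clone_counter = 0
        for ci, cluster in enumerate(cluster_list):
            members = np.flatnonzero(cluster_idx == ci)
            pos = 0
            for size in _clone_sizes(
                rng, len(members),
                profile.clonal_model["singleton_cell_fraction"],
                int(profile.clonal_model["max_clone_size"]),
            ):
                clone_id = f"{donor}:c{clone_counter}"
                clone_counter += 1
                locus_kappa = rng.random() < 0.6
                clone_genes[clone_id] = (
                    _HEAVY_V[rng.integers(len(_HEAVY_V))],
                    _HEAVY_D[rng.integers(len(_HEAVY_D))],
                    _HEAVY_J[rng.integers(len(_HEAVY_J))],
                    (_KAPPA_V if locus_kappa else _LAMBDA_V)[
                        rng.integers(len(_KAPPA_V if locus_kappa else _LAMBDA_V))],
                    (_KAPPA_J if locus_kappa else _LAMBDA_J)[
                        rng.integers(len(_KAPPA_J if locus_kappa else _LAMBDA_J))],
                    "IGK" if locus_kappa else "IGL",
                    _random_cdr3(rng, 13, 20),
                    _random_cdr3(rng, 9, 13),
                )
                founder_class[clone_id] = ISOTYPE_CLASSES[
                    rng.choice(len(ISOTYPE_CLASSES), p=founder_probs[cluster])
                ]
                for rank, m in enumerate(members[pos:pos + size]):
                    clone_of[m] = (clone_id, rank)
                pos += size

        # per-cell repertoire attributes
        p_switch = profile.clonal_model["p_switch"]
        contigs: list[gio.ContigRecord] = []
        n_cont = int(round(profile.contaminant_rate * n_d))
        cont_cells = rng.choice(n_d, size=n_cont, replace=False)
        cont_type = {int(c): contaminant_types[i % len(contaminant_types)]
                     for i, c in enumerate(cont_cells)}

        no_expr_barcodes: set[str] = set()
        for i in range(n_d):
            cluster = cluster_list[cluster_idx[i]]
            clone_id, rank = clone_of[i]
            hv, hd, hj, lv, lj, locus, cdr3_h, cdr3_l = clone_genes[clone_id]
            iso_class = founder_class[clone_id]
            if rank > 0 and rng.random() < p_switch:
                iso_class = _switch_class(rng, iso_class)
            subclasses = _SUBCLASSES[iso_class]
            subclass = subclasses[rng.integers(len(subclasses))]

            target = _draw_identity(rng, profile.identity_model[cluster])
            ident_h, ident_l = _split_identity(rng, target)
            umi_h = int(rng.integers(4, 61))
            umi_l = int(rng.integers(4, 61))
            ctype = cont_type.get(i, "")

            heavy_kwargs = dict(
                barcode=barcodes[i], donor=donor, chain="IGH",
                v_gene=hv, d_gene=hd, j_gene=hj, c_gene=subclass,
                cdr3_nt=cdr3_h, productive=True, full_length=True,
                high_confidence=True, umis=umi_h, v_identity_pct=ident_h,
            )
            if ctype == "low_umi":
                heavy_kwargs["umis"] = int(rng.integers(1, 4))
            elif ctype == "ighd":
                heavy_kwargs["c_gene"] = "IGHD"
            elif ctype == "nonproductive":
                heavy_kwargs["productive"] = False
            elif ctype == "no_expression":
                no_expr_barcodes.add(barcodes[i])
            contigs.append(gio.ContigRecord(**heavy_kwargs))
            if ctype == "extra_heavy":
                extra = dict(heavy_kwargs)
                extra["cdr3_nt"] = _random_cdr3(rng, 13, 20)
                extra["umis"] = int(rng.integers(4, 61))
                contigs.append(gio.ContigRecord(**extra))
            contigs.append(
                gio.ContigRecord(
                    barcode=barcodes[i], donor=donor, chain=locus,
                    v_gene=lv, d_gene="", j_gene=lj, c_gene="",
                    cdr3_nt=cdr3_l, productive=True, full_length=True,
                    high_confidence=True, umis=umi_l, v_identity_pct=ident_l,
                )
            )
            cell_rows.append(
                {
                    "barcode": barcodes[i], "donor": donor, "cluster": cluster,
                    "clone_id": clone_id, "isotype_class": iso_class,
                    "isotype_subclass": subclass, "identity": target,
                    "contaminant": ctype,
                }
            )
            if ctype:
                contaminant_rows.append(
                    {
                        "barcode": barcodes[i], "donor": donor, "type": ctype,
                        "expected_audit_reason": CONTAMINANT_REASONS[ctype],
                    }
                )

        gio.write_contig_table(contigs, donor_dir / "contigs.csv")

        # expression: gamma-Poisson (negative binomial) counts
        disp = expr["dispersion"]
        means = expr["baseline_mean"] * gene_cluster_fold[cluster_idx]
        lam = rng.gamma(1.0 / disp, scale=means * disp)
        counts = rng.poisson(lam).astype(np.int64)
        expr_barcodes = [b for b in barcodes if b not in no_expr_barcodes]
        keep_rows = np.array([b not in no_expr_barcodes for b in barcodes])
        matrix = gio.CountMatrix(
            cells=expr_barcodes,
            genes=list(genes),
            counts=sp.csr_matrix(counts[keep_rows]),
        )
        gio.write_expression_matrix(
            matrix,
            donor_dir / "matrix.mtx",
            donor_dir / "barcodes.tsv",
            donor_dir / "features.tsv",
        )

    cells = pd.DataFrame(cell_rows)
    annotations = pd.DataFrame(
        {
            "barcode": cells["barcode"],
            "donor": cells["donor"],
            "sorted_fraction": "GC",
            "cluster": cells["cluster"],
        }
    )
    annotations_path = out / "annotations.tsv"
    gio.write_table(annotations, annotations_path)
    profile_path = out / "profile.json"
    profile.to_json(profile_path)

    return CohortTruth(
        profile=profile,
        cells=cells,
        contaminants=pd.DataFrame(
            contaminant_rows,
            columns=["barcode", "donor", "type", "expected_audit_reason"],
        ),
        donor_dirs=donor_dirs,
        annotations_path=annotations_path,
        profile_path=profile_path,
    )


def load_cohort(out_dir: str | Path):
    """Read a generated cohort back through the pipeline's own readers.

    Returns (contigs, expressed_barcodes_by_donor, annotations, matrices),
    where ``matrices`` maps donor -> CountMatrix.
    """
    out = Path(out_dir)
    contigs = []
    expressed: dict[str, set[str]] = {}
    matrices: dict[str, gio.CountMatrix] = {}
    donor_dirs = sorted(p for p in out.iterdir() if p.is_dir())
    for donor_dir in donor_dirs:
        donor = donor_dir.name
        contigs.extend(gio.read_contig_table(donor_dir / "contigs.csv", donor=donor))
        matrix = gio.read_expression_matrix(
            donor_dir / "matrix.mtx",
            donor_dir / "barcodes.tsv",
            donor_dir / "features.tsv",
        )
        matrices[donor] = matrix
        expressed[donor] = set(matrix.cells)
    annotations = gio.read_annotations(out / "annotations.tsv")
    return contigs, expressed, annotations, matrices
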