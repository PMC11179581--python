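"""Bulk-expression normalization, DEG set logic, enrichment, and qPCR folds.

Covers the descriptive transcriptomic arithmetic around the injury studies:
RPKM normalization of a count matrix, control-relative scaling ("made relative
to 0"), a simple documented stand-in for upstream differential-expression
calls, the perturbation-specific DEG set subtraction (genes responsive to the
first RNAi but not altered by the second), hypergeometric over-representation
of categories, and ΔΔCt relative quantification with multi-melt-peak well
exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "compute_rpkm",
    "control_relative",
    "call_deg",
    "deg_gene_set",
    "cat1_specific_set",
    "hypergeometric_enrichment",
    "delta_delta_ct",
    "read_gmt",
    "DEFAULT_REFERENCE_GENES",
]

DEFAULT_REFERENCE_GENES = ("tba-1", "Y45F10D.4")


@dataclass
class ExpressionMatrix:
    """Gene-level counts with lengths and sample condition labels.

    ``counts`` is genes x samples; ``gene_length_bp`` indexed by gene;
    ``sample_conditions`` maps sample name to condition label. ``rpkm`` is
    computed lazily: counts * 1e9 / (gene length * library size).
    """

    counts: pd.DataFrame
    gene_length_bp: pd.Series
    sample_conditions: Mapping[str, str]
    _rpkm: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.gene_length_bp <= 0).any():
            raise ValueError("gene lengths must be positive")
        if not self.counts.index.equals(self.gene_length_bp.index):
            self.gene_length_bp = self.gene_length_bp.reindex(self.counts.index)
            if self.gene_length_bp.isna().any():
                raise ValueError("gene_length_bp missing entries for some genes")
        if (self.counts < 0).any().any():
            raise ValueError("counts must be nonnegative")

    @property
    def rpkm(self) -> pd.DataFrame:
        if self._rpkm is None:
            self._rpkm = compute_rpkm(self)
        return self._rpkm

    def samples_of(self, condition: str) -> list[str]:
        return [s for s, c in self.sample_conditions.items() if c == condition]


def compute_rpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads."""
    lib = matrix.counts.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0][0]
        raise ValueError(f"zero library size for sample {bad!r}")
    return matrix.counts * 1e9 / np.outer(matrix.gene_length_bp.to_numpy(), lib.to_numpy())


def control_relative(
    expr: ExpressionMatrix,
    gene: str,
    treated_samples: Sequence[str],
    control_samples: Sequence[str],
) -> float:
    """Mean treated RPKM over mean control RPKM, made relative to 0.

    Control maps to 0 (a value of 2.0 means 3x the control level)."""
    rpkm = expr.rpkm
    control_mean = float(rpkm.loc[gene, list(control_samples)].mean())
    if control_mean <= 0:
        raise ValueError(f"control mean RPKM for {gene!r} is not positive")
    treated_mean = float(rpkm.loc[gene, list(treated_samples)].mean())
    return treated_mean / control_mean - 1.0


def call_deg(
    expr: ExpressionMatrix,
    condition_pair: tuple[str, str],
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene differential-expression calls between two conditions.

    A deliberately simple, documented stand-in for a full DE pipeline: a
    pooled-variance two-sample t on log2(RPKM + pseudocount) per gene (groups
    are small and equal-sized, and the count model shares one dispersion, so
    the equal-variance form keeps its degrees of freedom), BH adjustment
    across genes, and
    up/down/ns flags at the given adjusted-p and |log2FC| thresholds. Any
    externally produced table with the same columns (gene, log2fc, p, adj_p,
    flag) can be used interchangeably by the set-logic operations.
    """
    treated, control = condition_pair
    t_samples = expr.samples_of(treated)
    c_samples = expr.samples_of(control)
    if len(t_samples) < 2 or len(c_samples) < 2:
        raise ValueError("need at least 2 replicates per condition")
    log_rpkm = np.log2(expr.rpkm + pseudocount)
    t_mat = log_rpkm[t_samples].to_numpy()
    c_mat = log_rpkm[c_samples].to_numpy()
    log2fc = t_mat.mean(axis=1) - c_mat.mean(axis=1)
    res = stats.ttest_ind(t_mat, c_mat, axis=1, equal_var=True)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    adj_p = multipletests(p, method="fdr_bh")[1]
    flag = np.where(
        (adj_p <= alpha) & (np.abs(log2fc) >= min_abs_log2fc),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    table = pd.DataFrame(
        {"gene": expr.counts.index, "log2fc": log2fc, "p": p, "adj_p": adj_p, "flag": flag}
    ).reset_index(drop=True)
    table.attrs["alpha"] = alpha
    table.attrs["min_abs_log2fc"] = min_abs_log2fc
    table.attrs["pseudocount"] = pseudocount
    table.attrs["condition_pair"] = condition_pair
    return table


def deg_gene_set(deg: pd.DataFrame) -> set[str]:
    """Genes flagged differentially expressed (up or down) in a DEG table."""
    return set(deg.loc[deg["flag"] != "ns", "gene"])


def cat1_specific_set(deg_cat1: pd.DataFrame, deg_cat2: pd.DataFrame) -> set[str]:
    """Genes DE under the first perturbation, excluding any altered by the second.

    Exact set arithmetic: {flagged in table 1} minus {flagged in table 2}. The
    two tables must share a gene universe.
    """
    u1, u2 = set(deg_cat1["gene"]), set(deg_cat2["gene"])
    if u1 != u2:
        raise ValueError("DEG tables do not share a gene universe")
    return deg_gene_set(deg_cat1) - deg_gene_set(deg_cat2)


def hypergeometric_enrichment(
    query: Iterable[str],
    categories: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each category.

    p = P[overlap >= k] under sampling |query| genes without replacement from
    the universe; BH across categories. Returned sorted by adjusted p.
    """
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        raise ValueError("query contains genes outside the universe")
    n, N = len(query), len(universe)
    rows = []
    for label, members in categories.items():
        cat = set(members) & universe
        if set(members) - universe:
            raise ValueError(f"category {label!r} contains genes outside the universe")
        k = len(cat & query)
        K = len(cat)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"category": label, "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    if len(table):
        table["adj_p"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values(["adj_p", "p", "category"]).reset_index(drop=True)
    return table


def delta_delta_ct(
    plate: pd.DataFrame,
    target_genes: Sequence[str],
    reference_genes: Sequence[str] = DEFAULT_REFERENCE_GENES,
    treated: str = "treated",
    control: str = "control",
) -> pd.DataFrame:
    """ΔΔCt relative quantification with multi-melt-peak well exclusion.

    Wells with more than one melt peak never contribute. Per sample, the
    reference Ct is the arithmetic mean of the reference genes' mean Cts
    (equivalently the geometric mean of their expression); ΔCt = Ct(target) -
    Ct(ref); ΔΔCt = ΔCt(treated) - ΔCt(control); fold = 2^(-ΔΔCt).
    """
    required = {"sample", "gene", "ct", "melt_peaks"}
    if not required <= set(plate.columns):
        raise ValueError(f"plate table must have columns {sorted(required)}")
    valid = plate[plate["melt_peaks"] <= 1]

    def mean_ct(sample: str, gene: str) -> float:
        wells = valid[(valid["sample"] == sample) & (valid["gene"] == gene)]
        if len(wells) == 0:
            raise ValueError(f"no valid wells for sample {sample!r}, gene {gene!r}")
        return float(wells["ct"].mean())

    for ref in reference_genes:
        if ref not in set(plate["gene"]):
            raise ValueError(f"missing reference gene {ref!r}")

    rows = []
    for sample in (treated, control):
        ref_ct = float(np.mean([mean_ct(sample, r) for r in reference_genes]))
        for gene in target_genes:
            rows.append({"sample": sample, "gene": gene, "dct": mean_ct(sample, gene) - ref_ct})
    dct = pd.DataFrame(rows).pivot(index="gene", columns="sample", values="dct")
    out = pd.DataFrame(
        {
            "gene": dct.index,
            "ddct": dct[treated] - dct[control],
        }
    ).reset_index(drop=True)
    out["fold_change"] = 2.0 ** (-out["ddct"])
    out.attrs["reference_genes"] = tuple(reference_genes)
    return out


def read_gmt(path) -> dict[str, set[str]]:
    """Read category gene sets from GMT text (name, description, genes...)."""
    categories: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            categories[parts[0]] = {g for g in parts[2:] if g}
    return categories
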