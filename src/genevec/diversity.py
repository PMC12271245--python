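"""Departures from SNP independence, between-gene association, prominent patterns.

The headline quantity is the *dependence ratio*: the total number of distinct
genotypic patterns observed across genes divided by the total expected under
cross-SNP independence at the same sample size and the same per-SNP marginal
genotype frequencies.  Positive within-gene dependence (LD) pushes the ratio
below 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .vectors import (
    MISSING,
    GenotypeTable,
    GeneVectorMatrix,
    PatternCatalog,
    diversity_index,
    expected_distinct_count,
)

__all__ = [
    "DiversityReport",
    "expected_distinct_independent",
    "dependence_ratio",
    "between_gene_association",
    "prominent_patterns",
    "diversity_summary",
]


class UndefinedAssociationError(ValueError):
    """Association is undefined (fewer than two pattern categories after pooling)."""


@dataclass
class DiversityReport:
    per_gene_d: dict[str, int]
    mean_d: float
    range_d: tuple[int, int]
    observed_total: int
    expected_total: float
    dependence_ratio: float
    pairwise_association_mean: float | None = None
    pairwise_association_sd: float | None = None

    def to_json(self) -> str:
        d = asdict(self)
        d["range_d"] = list(d["range_d"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DiversityReport":
        d = json.loads(text)
        d["range_d"] = tuple(d["range_d"])
        return cls(**d)


def _observed_marginals(table: GenotypeTable, snp_ids: list[str]) -> np.ndarray:
    """(m, 3) per-SNP genotype-state frequencies from non-missing calls."""
    sub = table.snp_columns(snp_ids)
    marg = np.empty((len(snp_ids), 3))
    for k in range(len(snp_ids)):
        col = sub[:, k]
        col = col[col != MISSING]
        if col.size == 0:
            marg[k] = 1.0 / 3.0  # uninformative fallback for an all-missing SNP
        else:
            marg[k] = np.bincount(col, minlength=3) / col.size
    return marg


def expected_distinct_independent(gene, marginals, n: int) -> float:
    """Expected distinct-pattern count for one gene under SNP independence.

    ``marginals``: (m, 3) observed per-SNP genotype frequencies; exact
    enumeration over the 3^m patterns (refused for m > 15).
    """
    marginals = np.asarray(marginals, dtype=float)
    m = marginals.shape[0] if marginals.ndim == 2 else getattr(gene, "m")
    return expected_distinct_count(m, n, marginals)


def dependence_ratio(
    matrix: GeneVectorMatrix, table: GenotypeTable
) -> tuple[float, pd.DataFrame]:
    """Observed total distinct patterns / expected total under independence.

    Per gene, the expectation uses the observed per-SNP marginals and the
    number of subjects with a complete (non-missing) vector for that gene.
    Returns the ratio and a per-gene report frame.
    """
    if not matrix.genes:
        raise ValueError("need at least one gene")
    rows = []
    for g in matrix.genes:
        codes = matrix.gene_codes(g.gene)
        n_complete = int((codes != MISSING).sum())
        d = diversity_index(matrix, g.gene)
        marg = _observed_marginals(table, g.snp_ids)
        exp = expected_distinct_count(g.m, n_complete, marg)
        rows.append((g.gene, g.m, n_complete, d, exp))
    rep = pd.DataFrame(rows, columns=["gene", "m", "n_complete", "observed_d", "expected_d"])
    observed = rep["observed_d"].sum()
    expected = rep["expected_d"].sum()
    return float(observed / expected), rep


def _pool_rare(codes: np.ndarray, min_count: int) -> np.ndarray:
    """Relabel codes, pooling patterns with count < min_count into one category."""
    vals, inv, counts = np.unique(codes, return_inverse=True, return_counts=True)
    keep = counts >= min_count
    labels = np.where(keep, np.arange(vals.size), -1)
    return labels[inv]


def between_gene_association(
    matrix: GeneVectorMatrix,
    gene_a: str,
    gene_b: str,
    min_count: int = 5,
    bias_correction: bool = True,
) -> float:
    """Cramér's V between the pattern categories of two genes.

    Subjects with either vector missing are dropped pairwise; patterns with
    fewer than ``min_count`` carriers are pooled into one rare category per
    gene.  With ``bias_correction`` the Bergsma small-sample correction is
    applied.  Raises :class:`UndefinedAssociationError` if either gene has
    fewer than two categories after pooling.
    """
    a = matrix.gene_codes(gene_a)
    b = matrix.gene_codes(gene_b)
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if a.size == 0:
        raise UndefinedAssociationError("no pairwise-complete subjects")
    a = _pool_rare(a, min_count)
    b = _pool_rare(b, min_count)
    tab = pd.crosstab(a, b).to_numpy()
    r, c = tab.shape
    if r < 2 or c < 2:
        raise UndefinedAssociationError(
            f"association undefined: {gene_a} x {gene_b} has a constant gene after pooling"
        )
    n = tab.sum()
    from scipy.stats import chi2_contingency

    chi2 = chi2_contingency(tab, correction=False)[0]
    phi2 = chi2 / n
    if bias_correction:
        phi2 = max(0.0, phi2 - (r - 1) * (c - 1) / (n - 1))
        r = r - (r - 1) ** 2 / (n - 1)
        c = c - (c - 1) ** 2 / (n - 1)
    denom = min(r - 1, c - 1)
    if denom <= 0:
        return 0.0
    return float(np.sqrt(phi2 / denom))


def prominent_patterns(
    catalog: PatternCatalog, coverage: float = 0.80
) -> tuple[list[int], int]:
    """Smallest prefix of patterns (by descending count, ties ascending code)
    whose cumulative share of non-missing subjects reaches ``coverage``."""
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    if catalog.d == 0:
        raise ValueError("empty catalog")
    rows = catalog.rows.sort_values(
        ["count", "code"], ascending=[False, True], ignore_index=True
    )
    cum = rows["count"].cumsum() / catalog.n_complete
    k = int(np.searchsorted(cum.to_numpy(), coverage - 1e-12) + 1)
    k = min(k, len(rows))
    return rows["code"].head(k).tolist(), k


def diversity_summary(
    matrix: GeneVectorMatrix,
    table: GenotypeTable | None = None,
    n_pairs: int | None = 200,
    min_count: int = 5,
    seed: int = 0,
) -> DiversityReport:
    """Aggregate per-gene diversity, the dependence ratio and pairwise association.

    Pairwise Cramér's V is averaged over all gene pairs, or a random subsample
    of ``n_pairs`` pairs when there are more (study-sized cohorts have ~5,000
    pairs).  Pairs whose association is undefined after pooling are skipped.
    """
    per_d = {g.gene: diversity_index(matrix, g.gene) for g in matrix.genes}
    ds = np.array(list(per_d.values()))
    if table is not None:
        ratio, rep = dependence_ratio(matrix, table)
        expected = float(rep["expected_d"].sum())
    else:
        ratio, expected = float("nan"), float("nan")
    # pairwise association
    mean_v = sd_v = None
    genes = [g.gene for g in matrix.genes]
    if len(genes) >= 2:
        pairs = [(i, j) for i in range(len(genes)) for j in range(i + 1, len(genes))]
        if n_pairs is not None and len(pairs) > n_pairs:
            rng = np.random.default_rng(seed)
            pairs = [pairs[i] for i in rng.choice(len(pairs), n_pairs, replace=False)]
        vs = []
        for i, j in pairs:
            try:
                vs.append(between_gene_association(matrix, genes[i], genes[j], min_count))
            except UndefinedAssociationError:
                continue
        if vs:
            mean_v = float(np.mean(vs))
            sd_v = float(np.std(vs, ddof=1)) if len(vs) > 1 else 0.0
    return DiversityReport(
        per_gene_d={k: int(v) for k, v in per_d.items()},
        mean_d=float(ds.mean()) if ds.size else 0.0,
        range_d=(int(ds.min()), int(ds.max())) if ds.size else (0, 0),
        observed_total=int(ds.sum()),
        expected_total=expected,
        dependence_ratio=ratio,
        pairwise_association_mean=mean_v,
        pairwise_association_sd=sd_v,
    )
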