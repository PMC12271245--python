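"""Base-3 gene vectors: encoding, pattern catalogs and coverage expectations.

A *gene vector* summarises the genotypes of the ``m`` SNPs located within one
gene as a single base-3 integer

.. math::

    v = \\sum_{k=1}^{m} s_k \\, 3^{k-1}, \\qquad s_k \\in \\{0, 1, 2\\},

where ``s_k`` counts copies of one allele at the k-th SNP (digit order =
ascending physical position within the gene).  With ``m`` SNPs at most
``3**m`` distinct *genotypic patterns* exist; the number actually observed in
a sample is the gene's *diversity index* ``d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  #: sentinel for a missing genotype / gene-vector code
MAX_SNPS_PER_GENE = 15

__all__ = [
    "MISSING",
    "MAX_SNPS_PER_GENE",
    "GenotypeTable",
    "GeneDefinition",
    "GeneVectorMatrix",
    "PatternCatalog",
    "encode_gene_vector",
    "decode_gene_vector",
    "n_possible_patterns",
    "build_gene_vector_matrix",
    "diversity_index",
    "pattern_catalog",
    "expected_pattern_coverage",
    "simulate_pattern_coverage",
]


class MissingGenotypeError(ValueError):
    """A gene vector cannot be formed because a constituent genotype is missing."""


@dataclass
class GenotypeTable:
    """Subjects x SNPs genotype matrix with per-SNP metadata.

    Parameters
    ----------
    subjects
        Subject identifiers (rows).
    snps
        DataFrame with columns ``snp_id``, ``gene`` (may be None), ``chrom``,
        ``pos`` (1-based bp), one row per SNP (columns of the matrix).
    genotypes
        ``(n_subjects, n_snps)`` int8 array with values in {0, 1, 2} or
        :data:`MISSING`.
    """

    subjects: list[str]
    snps: pd.DataFrame
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.subjects), len(self.snps)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.snps)} SNPs"
            )
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("duplicate snp_id in SNP metadata")
        if len(self.snps) and (self.snps["pos"] < 1).any():
            raise ValueError("SNP positions must be >= 1 (1-based)")
        ok = (self.genotypes >= MISSING) & (self.genotypes <= 2)
        if not ok.all():
            raise ValueError("genotype values must be in {0,1,2} or MISSING")
        self._snp_index = {s: i for i, s in enumerate(self.snps["snp_id"])}
        self._subject_index = {s: i for i, s in enumerate(self.subjects)}

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_columns(self, snp_ids: list[str]) -> np.ndarray:
        """Genotype sub-matrix for the given SNPs, in the given order."""
        try:
            idx = [self._snp_index[s] for s in snp_ids]
        except KeyError as exc:
            raise KeyError(f"unknown snp_id {exc.args[0]!r}") from None
        return self.genotypes[:, idx]

    def missing_rate_per_subject(self) -> np.ndarray:
        if self.n_snps == 0:
            return np.zeros(self.n_subjects)
        return (self.genotypes == MISSING).mean(axis=1)

    def copy(self) -> "GenotypeTable":
        return GenotypeTable(list(self.subjects), self.snps.copy(), self.genotypes.copy())


@dataclass
class GeneDefinition:
    """A gene: chromosome, physical span and its member SNPs (ascending position)."""

    gene: str
    chrom: str
    start: int
    end: int
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = len(self.snp_ids)
        if not 2 <= m <= MAX_SNPS_PER_GENE:
            raise ValueError(f"gene {self.gene}: needs 2..{MAX_SNPS_PER_GENE} SNPs, got {m}")
        if self.start > self.end:
            raise ValueError(f"gene {self.gene}: start > end")

    @property
    def m(self) -> int:
        return len(self.snp_ids)


@dataclass
class GeneVectorMatrix:
    """Subjects x genes matrix of base-3 pattern codes (:data:`MISSING` = undefined)."""

    subjects: list[str]
    genes: list[GeneDefinition]
    codes: np.ndarray  # (n_subjects, n_genes) int32

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int32)
        if self.codes.shape != (len(self.subjects), len(self.genes)):
            raise ValueError("code matrix shape mismatch")
        self._gene_index = {g.gene: i for i, g in enumerate(self.genes)}
        self._subject_index = {s: i for i, s in enumerate(self.subjects)}

    def gene_codes(self, gene: str) -> np.ndarray:
        return self.codes[:, self.gene_column(gene)]

    def gene_column(self, gene: str) -> int:
        if gene not in self._gene_index:
            raise KeyError(f"unknown gene {gene!r}")
        return self._gene_index[gene]

    def gene_def(self, gene: str) -> GeneDefinition:
        return self.genes[self.gene_column(gene)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, g in enumerate(self.genes):
            for i, s in enumerate(self.subjects):
                c = self.codes[i, j]
                rows.append((s, g.gene, int(c) if c != MISSING else None, g.m))
        return pd.DataFrame(rows, columns=["subject_id", "gene", "code", "m"])


@dataclass
class PatternCatalog:
    """Distinct genotypic patterns of one gene with overall and subgroup counts.

    ``rows`` has columns ``code``, ``count`` and one column per subgroup,
    sorted ascending by code.  The number of rows is the diversity index d.
    """

    gene: str
    m: int
    rows: pd.DataFrame
    n_complete: int  # subjects with a non-missing vector
    subgroup_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def d(self) -> int:
        return len(self.rows)


def encode_gene_vector(genotypes) -> int:
    """Encode an ordered genotype list (values in {0,1,2}) as a base-3 code.

    Digit k (1-based, ascending SNP position) contributes ``s_k * 3**(k-1)``.
    """
    s = np.asarray(genotypes)
    m = s.size
    if not 1 <= m <= MAX_SNPS_PER_GENE:
        raise ValueError(f"gene vector length must be 1..{MAX_SNPS_PER_GENE}, got {m}")
    if np.any(s == MISSING):
        raise MissingGenotypeError("cannot encode a gene vector with missing genotypes")
    if not np.isin(s, (0, 1, 2)).all():
        raise ValueError("genotype values must be in {0, 1, 2}")
    return int(np.dot(s, 3 ** np.arange(m)))


def decode_gene_vector(code: int, m: int) -> list[int]:
    """Inverse of :func:`encode_gene_vector`: code -> ordered genotype list."""
    if not 1 <= m <= MAX_SNPS_PER_GENE:
        raise ValueError(f"m must be 1..{MAX_SNPS_PER_GENE}")
    if not 0 <= code < 3**m:
        raise ValueError(f"code {code} out of range [0, 3^{m})")
    out = []
    for _ in range(m):
        out.append(code % 3)
        code //= 3
    return out


def n_possible_patterns(m: int) -> int:
    """Number of theoretically possible genotypic patterns for m SNPs: 3^m."""
    if not 1 <= m <= MAX_SNPS_PER_GENE:
        raise ValueError(f"m must be 1..{MAX_SNPS_PER_GENE}")
    return 3**m


def build_gene_vector_matrix(
    table: GenotypeTable, genes: list[GeneDefinition]
) -> GeneVectorMatrix:
    """Compute one base-3 code per (subject, gene).

    A vector is :data:`MISSING` whenever any constituent genotype is missing:
    a base-3 code with an unknown digit is undefined.
    """
    n = table.n_subjects
    codes = np.full((n, len(genes)), MISSING, dtype=np.int32)
    for j, g in enumerate(genes):
        sub = table.snp_columns(g.snp_ids).astype(np.int32)  # (n, m)
        complete = (sub != MISSING).all(axis=1)
        weights = 3 ** np.arange(g.m, dtype=np.int32)
        codes[complete, j] = sub[complete] @ weights
    return GeneVectorMatrix(list(table.subjects), list(genes), codes)


def diversity_index(matrix: GeneVectorMatrix, gene: str) -> int:
    """Number of distinct non-missing codes observed for ``gene``."""
    c = matrix.gene_codes(gene)
    return int(np.unique(c[c != MISSING]).size)


def pattern_catalog(
    matrix: GeneVectorMatrix,
    gene: str,
    subgroups: dict[str, list[str]] | None = None,
) -> PatternCatalog:
    """Tabulate distinct patterns of ``gene`` with overall and subgroup counts."""
    subgroups = subgroups or {}
    col = matrix.gene_column(gene)
    codes = matrix.codes[:, col]
    complete = codes != MISSING
    vals, counts = np.unique(codes[complete], return_counts=True)
    rows = pd.DataFrame({"code": vals.astype(int), "count": counts.astype(int)})
    sizes: dict[str, int] = {}
    for name, members in subgroups.items():
        unknown = set(members) - set(matrix.subjects)
        if unknown:
            raise KeyError(f"subgroup {name!r} contains unknown subjects: {sorted(unknown)[:3]}")
        idx = np.array([matrix._subject_index[s] for s in members], dtype=int)
        sub_codes = codes[idx] if idx.size else np.empty(0, dtype=codes.dtype)
        sub_codes = sub_codes[sub_codes != MISSING]
        sizes[name] = int(sub_codes.size)
        counter = pd.Series(sub_codes).value_counts()
        rows[name] = rows["code"].map(counter).fillna(0).astype(int)
    rows = rows.sort_values("code", ignore_index=True)
    return PatternCatalog(
        gene=gene,
        m=matrix.gene_def(gene).m,
        rows=rows,
        n_complete=int(complete.sum()),
        subgroup_sizes=sizes,
    )


def _pattern_probabilities(m: int, genotype_distribution=None) -> np.ndarray:
    """Probability of each of the 3^m patterns under cross-SNP independence.

    ``genotype_distribution`` is either a length-3 state distribution shared by
    all SNPs, or an (m, 3) array of per-SNP marginals; default uniform.
    """
    if m > MAX_SNPS_PER_GENE:
        raise ValueError(f"m={m} exceeds the 3^m enumeration bound (m <= {MAX_SNPS_PER_GENE})")
    if genotype_distribution is None:
        marg = np.full((m, 3), 1.0 / 3.0)
    else:
        marg = np.asarray(genotype_distribution, dtype=float)
        if marg.ndim == 1:
            marg = np.tile(marg, (m, 1))
        if marg.shape != (m, 3):
            raise ValueError("genotype_distribution must be length-3 or shape (m, 3)")
        if not np.allclose(marg.sum(axis=1), 1.0):
            raise ValueError("per-SNP state probabilities must sum to 1")
    # pattern code = sum_k s_k 3^(k-1): digit k varies fastest for SNP 1
    p = np.ones(1)
    for k in range(m):
        p = (marg[k][:, None] * p[None, :]).ravel(order="C")
        # after this step index = s_k * 3^k + previous-code; consistent weighting
    return p


def expected_pattern_coverage(m: int, n: int, genotype_distribution=None) -> float:
    """Expected fraction of the 3^m patterns observed in a sample of n subjects.

    Exact closed form under cross-SNP independence:
    ``(1/3^m) * sum_patterns [1 - (1 - p_pattern)^n]``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return 0.0
    p = _pattern_probabilities(m, genotype_distribution)
    return float(np.mean(1.0 - (1.0 - p) ** n))


def expected_distinct_count(m: int, n: int, genotype_distribution=None) -> float:
    """Expected number of distinct patterns observed (coverage x 3^m)."""
    return expected_pattern_coverage(m, n, genotype_distribution) * 3**m


def simulate_pattern_coverage(
    m: int,
    n: int,
    reps: int,
    seed: int | np.random.Generator = 0,
    genotype_distribution=None,
) -> float:
    """Monte-Carlo mean of the distinct-pattern fraction over ``reps`` samples."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if n == 0:
        return 0.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = _pattern_probabilities(m, genotype_distribution)
    total = 3**m
    fracs = np.empty(reps)
    for r in range(reps):
        draws = rng.choice(total, size=n, p=p)
        fracs[r] = np.unique(draws).size / total
    return float(fracs.mean())
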