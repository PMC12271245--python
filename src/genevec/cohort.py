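"""Synthetic genotype-phenotype cohorts with the structure the analysis assumes.

No patient-level data from naturalistic psychopharmacology studies of this
kind are publicly deposited, so every downstream stage is exercised on
simulated cohorts.  The generator emulates:

* ~100 candidate genes carrying 4-8 SNPs each, genotypes drawn per
  Hardy-Weinberg at per-SNP allele frequencies, with *within-gene* dependence
  induced by a Gaussian copula on latent allele dosages (this is what
  suppresses pattern diversity below the independence expectation);
* cross-gene pattern co-occurrence for designated gene pairs;
* embedded "response genes" whose designated multi-SNP pattern is common in
  treatment responders and rare (<10%) in non-responders;
* trigger-model score trajectories: improvement starts at a random trigger
  day and then follows its own course — full decline (responders), partial
  decline followed by a plateau ("stuck"), or no improvement at all;
* ~2% missing genotypes with a planted tail of high-missingness subjects;
* chronically elevated IgM flags with configurable genotype association.

Ground truth (which genes carry planted signal, and the planted patterns) is
recorded so parameter-recovery tests can score the analysis pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm

from .clinical import ClinicalTrajectory, OutcomeLabels, label_cohort
from .vectors import (
    MISSING,
    GeneDefinition,
    GenotypeTable,
    GeneVectorMatrix,
    build_gene_vector_matrix,
    encode_gene_vector,
)

__all__ = [
    "CohortConfig",
    "TrajectoryConfig",
    "IgmConfig",
    "SyntheticCohort",
    "simulate_genotypes",
    "plant_response_patterns",
    "simulate_trajectories",
    "apply_missingness",
    "simulate_igm",
    "generate_cohort",
]

#: assessment schedule: 8 visits over the 42-day observation period
VISIT_SCHEDULE = (0, 3, 7, 10, 14, 21, 28, 42)


class ConfigurationError(ValueError):
    pass


@dataclass
class TrajectoryConfig:
    """Trigger-model parameters for simulated score trajectories."""

    n_visits: int = 8
    horizon_days: int = 42
    visit_days: tuple[int, ...] = VISIT_SCHEDULE
    #: responders/stuck draw their trigger day geometrically with this p
    trigger_geom_p: float = 0.18
    #: responders shed this fraction of baseline by end of decline (uniform range)
    responder_shed: tuple[float, float] = (0.60, 0.85)
    #: "stuck" subjects shed this fraction before plateauing (uniform range)
    stuck_shed: tuple[float, float] = (0.20, 0.50)
    #: per-visit i.i.d. Gaussian noise sd (score points)
    noise_sd: float = 1.0
    #: fraction of non-responders that improve partially before getting stuck
    stuck_fraction: float = 0.60
    #: per-day linear drift of non-improvers (0 = flat; >0 worsens)
    nonimprover_drift: float = 0.0

    def __post_init__(self) -> None:
        if self.horizon_days < 14:
            raise ConfigurationError(
                "horizon < 14 days: early-improvement window undefined"
            )
        if self.n_visits < 3:
            raise ConfigurationError("need at least 3 visits")


@dataclass
class IgmConfig:
    """Marginal prevalence of chronically elevated IgM and its genotype link."""

    prevalence: float = 0.261
    associated_genes: tuple[str, ...] = ()
    strength: float = 0.5  # 0 = independent of genotype

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ConfigurationError("IgM prevalence must be in [0,1]")


# Baseline severity distributions (truncated normals, calibrated so the
# mild/moderate/severe proportions approximate the study bands:
# F3 HAM-D17 >=15: <20 / 20-24 / >24  ~ 24.3 / 38.6 / 37.1 %
# F2 PANSS-G >=21: <30 / 30-40 / >40  ~  6.9 / 30.0 / 63.1 %
SEVERITY_BASELINE = {
    "F3": {"mean": 22.6, "sd": 4.0, "min": 15.0},
    "F2": {"mean": 43.0, "sd": 9.5, "min": 21.0},
}
#: F2 response-scale (PANSS-P) baseline distribution
PANSS_P_BASELINE = {"mean": 22.0, "sd": 5.0, "min": 8.0}


@dataclass
class CohortConfig:
    """Full recipe for one synthetic cohort.

    Defaults reproduce the study conditions: 264 F2 + 638 F3 subjects, 100
    genes with 4-8 SNPs each, responder fractions 29.5% (F2) / 35.6% (F3),
    early-improver fractions 52.3% / 57.1%, ~2% missing genotypes with a
    14.5% tail of high-missingness subjects, 26.1% elevated-IgM prevalence,
    and ten embedded response genes whose planted pattern occurs in 30% of
    responders but only 5% of non-responders.
    """

    n_f2: int = 264
    n_f3: int = 638
    n_genes: int = 100
    snps_per_gene: tuple[int, int] = (4, 8)
    allele_freq_range: tuple[float, float] = (0.10, 0.90)
    #: latent pairwise correlation of within-gene allele dosages; the default
    #: is calibrated so the study-sized cohort's observed/expected distinct-
    #: pattern ratio lands near one third
    within_gene_ld: float = 0.80
    #: (geneA, geneB, strength): geneB copies geneA's pattern w.p. strength
    cross_gene_link: list[tuple[str, str, float]] = field(default_factory=list)
    #: (gene, freq in responders, freq in non-responders)
    response_genes: list[tuple[str, float, float]] = field(
        default_factory=lambda: [(f"g{i:03d}", 0.30, 0.05) for i in range(10)]
    )
    responder_fraction: dict[str, float] = field(
        default_factory=lambda: {"F2": 0.295, "F3": 0.356}
    )
    early_improver_fraction: dict[str, float] = field(
        default_factory=lambda: {"F2": 0.523, "F3": 0.571}
    )
    missing_rate: float = 0.02
    high_missing_subject_fraction: float = 0.145
    high_missing_rate: float = 0.10
    trajectory: TrajectoryConfig = field(default_factory=TrajectoryConfig)
    igm: IgmConfig = field(default_factory=IgmConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.allele_freq_range
        if not (0 < lo <= hi < 1):
            raise ConfigurationError("allele_freq_range must satisfy 0 < lo <= hi < 1")
        lo, hi = self.snps_per_gene
        if not (2 <= lo <= hi <= 15):
            raise ConfigurationError("snps_per_gene must lie within [2, 15]")
        for frac in (
            self.missing_rate,
            self.high_missing_subject_fraction,
            self.within_gene_ld,
            *self.responder_fraction.values(),
            *self.early_improver_fraction.values(),
        ):
            if not 0 <= frac <= 1:
                raise ConfigurationError(f"fraction {frac} outside [0,1]")

    @property
    def n_subjects(self) -> int:
        return self.n_f2 + self.n_f3


@dataclass
class SyntheticCohort:
    """A fully generated cohort plus the ground truth used to build it."""

    config: CohortConfig
    genotypes: GenotypeTable
    genes: list[GeneDefinition]
    trajectories: list[ClinicalTrajectory]
    severity_baselines: dict[str, float]
    true_labels: OutcomeLabels
    igm_flags: dict[str, bool]
    #: gene -> planted base-3 pattern code for embedded response genes
    truth: dict[str, int]

    def gene_vectors(self) -> GeneVectorMatrix:
        return build_gene_vector_matrix(self.genotypes, self.genes)

    def serialize(self) -> bytes:
        """Canonical byte serialization (for determinism checks)."""
        parts = [repr(sorted(asdict(self.config).items())).encode()]
        parts.append(self.genotypes.genotypes.tobytes())
        parts.append("\n".join(self.genotypes.subjects).encode())
        parts.append(self.genotypes.snps.to_csv(sep="\t", index=False).encode())
        for t in self.trajectories:
            parts.append(
                f"{t.subject_id}\t{t.diagnosis}\t{t.scale}\t{t.visits!r}".encode()
            )
        parts.append(repr(sorted(self.severity_baselines.items())).encode())
        parts.append(self.true_labels.table.to_csv(sep="\t").encode())
        parts.append(repr(sorted(self.igm_flags.items())).encode())
        parts.append(repr(sorted(self.truth.items())).encode())
        return b"\x00".join(parts)


def _make_gene_definitions(config: CohortConfig, rng: np.random.Generator) -> list[GeneDefinition]:
    genes = []
    for j in range(config.n_genes):
        lo, hi = config.snps_per_gene
        m = int(rng.integers(lo, hi + 1))
        chrom = str(j % 22 + 1)
        start = 1_000_000 + j * 1_000_000
        positions = np.sort(rng.choice(np.arange(1000, 200_000), size=m, replace=False))
        snp_ids = [f"g{j:03d}_s{k}" for k in range(m)]
        genes.append(
            GeneDefinition(
                gene=f"g{j:03d}",
                chrom=chrom,
                start=start,
                end=start + 250_000,
                snp_ids=snp_ids,
            )
        )
        genes[-1]._positions = (start + positions).tolist()  # kept for metadata
    return genes


def simulate_genotypes(
    config: CohortConfig, rng: np.random.Generator | None = None, genes=None
) -> tuple[GenotypeTable, list[GeneDefinition]]:
    """Draw genotypes per Hardy-Weinberg with copula-induced within-gene LD.

    Per SNP an allele frequency f is drawn uniformly from
    ``allele_freq_range``; genotype state probabilities are the HWE triple
    ((1-f)^2, 2f(1-f), f^2).  Within a gene, latent standard-normal dosages
    share pairwise correlation ``within_gene_ld`` and are discretized through
    the HWE cumulative thresholds, so ld=0 recovers independent SNPs.
    """
    rng = rng or np.random.default_rng(config.seed)
    genes = genes or _make_gene_definitions(config, rng)
    n = config.n_subjects
    subjects = [f"S{i:04d}" for i in range(n)]
    cols, meta_rows = [], []
    lo, hi = config.allele_freq_range
    rho = config.within_gene_ld
    for g in genes:
        m = g.m
        freqs = rng.uniform(lo, hi, size=m)
        if n == 0:
            block = np.empty((0, m), dtype=np.int8)
        else:
            if rho > 0 and m > 1:
                cov = np.full((m, m), rho)
                np.fill_diagonal(cov, 1.0)
                z = rng.multivariate_normal(np.zeros(m), cov, size=n, method="cholesky")
            else:
                z = rng.standard_normal((n, m))
            u = norm.cdf(z)
            p0 = (1 - freqs) ** 2
            p1 = 2 * freqs * (1 - freqs)
            block = np.where(u < p0, 0, np.where(u < p0 + p1, 1, 2)).astype(np.int8)
        cols.append(block)
        positions = getattr(g, "_positions", [g.start + 1000 * (k + 1) for k in range(m)])
        for k, sid in enumerate(g.snp_ids):
            meta_rows.append((sid, g.gene, g.chrom, int(positions[k])))
    import pandas as pd

    snps = pd.DataFrame(meta_rows, columns=["snp_id", "gene", "chrom", "pos"])
    geno = np.hstack(cols) if cols else np.empty((n, 0), dtype=np.int8)
    table = GenotypeTable(subjects, snps, geno)
    _apply_cross_gene_links(table, genes, config, rng)
    return table, genes


def _apply_cross_gene_links(table, genes, config, rng) -> None:
    """Copy the source gene's pattern digits into the linked gene w.p. strength."""
    gene_by_id = {g.gene: g for g in genes}
    for ga, gb, strength in config.cross_gene_link:
        if ga not in gene_by_id or gb not in gene_by_id:
            raise ConfigurationError(f"cross_gene_link names unknown gene: {ga}, {gb}")
        a, b = gene_by_id[ga], gene_by_id[gb]
        src = table.snp_columns(a.snp_ids)
        hit = rng.random(table.n_subjects) < strength
        digits = np.zeros((table.n_subjects, b.m), dtype=np.int8)
        mcopy = min(a.m, b.m)
        digits[:, :mcopy] = src[:, :mcopy]
        idx = [table._snp_index[s] for s in b.snp_ids]
        table.genotypes[np.ix_(hit, idx)] = digits[hit]


def plant_response_patterns(
    table: GenotypeTable,
    config: CohortConfig,
    labels: OutcomeLabels,
    genes: list[GeneDefinition],
    rng: np.random.Generator | None = None,
) -> dict[str, int]:
    """Overwrite designated multi-SNP patterns into responders/non-responders.

    For each configured response gene one random pattern is designated and
    written into responders with the configured responder frequency and into
    non-responders with the (rare) non-responder frequency.  Returns the
    gene -> planted pattern code ground truth; the table is modified in place.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    gene_by_id = {g.gene: g for g in genes}
    responders = set(labels.subjects_where("responder", True))
    truth: dict[str, int] = {}
    for gene_id, f_resp, f_non in config.response_genes:
        if gene_id not in gene_by_id:
            raise ConfigurationError(f"response gene {gene_id!r} not in cohort")
        g = gene_by_id[gene_id]
        pattern = [int(x) for x in rng.integers(0, 3, size=g.m)]
        truth[gene_id] = encode_gene_vector(pattern)
        idx = [table._snp_index[s] for s in g.snp_ids]
        for i, sid in enumerate(table.subjects):
            f = f_resp if sid in responders else f_non
            if f > 0 and rng.random() < f:
                table.genotypes[i, idx] = pattern
    return truth


def _truncnorm(rng, mean, sd, lower, size):
    """Truncated normal via inverse-CDF (deterministic given rng)."""
    a = norm.cdf((lower - mean) / sd)
    u = rng.uniform(a, 1.0, size=size)
    return mean + sd * norm.ppf(u)


def simulate_trajectories(
    subjects: list[str],
    diagnoses: dict[str, str],
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ClinicalTrajectory], dict[str, float], dict[str, str]]:
    """Generate trigger-model response-scale trajectories for every subject.

    Each subject is first assigned a target course class — ``responder``
    (full sustained decline), ``stuck`` (partial decline then plateau) or
    ``nonimprover`` (no trigger) — per the configured per-diagnosis
    fractions.  Returns (trajectories, F2 severity-scale baselines, target
    class per subject).  Realized outcome labels are re-derived downstream by
    applying the clinical criteria to the noisy trajectories.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    tcfg = config.trajectory
    days = [d for d in tcfg.visit_days if d <= tcfg.horizon_days][: tcfg.n_visits]
    trajs, sev_baselines, classes = [], {}, {}
    for sid in subjects:
        dx = diagnoses[sid]
        sev = SEVERITY_BASELINE[dx]
        sev_base = float(np.round(_truncnorm(rng, sev["mean"], sev["sd"], sev["min"], None), 1))
        sev_baselines[sid] = sev_base
        if dx == "F3":
            base = sev_base
            scale = "HAM-D17"
        else:
            p = PANSS_P_BASELINE
            base = float(np.round(_truncnorm(rng, p["mean"], p["sd"], p["min"], None), 1))
            scale = "PANSS-P"
        u = rng.random()
        rf = config.responder_fraction[dx]
        if u < rf:
            cls = "responder"
        elif rng.random() < tcfg.stuck_fraction:
            cls = "stuck"
        else:
            cls = "nonimprover"
        classes[sid] = cls
        scores = _one_trajectory(rng, base, cls, dx, days, config)
        trajs.append(
            ClinicalTrajectory(
                subject_id=sid, diagnosis=dx, scale=scale,
                visits=list(zip(days, scores)),
            )
        )
    return trajs, sev_baselines, classes


def _one_trajectory(rng, base, cls, dx, days, config: CohortConfig) -> list[float]:
    tcfg = config.trajectory
    horizon = tcfg.horizon_days
    if cls == "nonimprover":
        mean = [base + tcfg.nonimprover_drift * d for d in days]
        trigger = None
    else:
        # trigger day: the early-improver fraction is a marginal target over
        # *all* subjects, so the conditional early-trigger probability is
        # rescaled by the improver fraction of this diagnosis
        rf = config.responder_fraction[dx]
        improver_frac = rf + (1.0 - rf) * tcfg.stuck_fraction
        # 0.85: attenuation correction for visit-noise failures of the
        # sustained condition among early-triggered subjects
        p_early = min(1.0, config.early_improver_fraction[dx]
                      / max(improver_frac * 0.85, 1e-9))
        early = rng.random() < p_early
        if early:
            trigger = int(rng.integers(1, 7))
        else:
            trigger = int(min(horizon - 7, 14 + rng.geometric(tcfg.trigger_geom_p)))
        if cls == "responder":
            shed = rng.uniform(*tcfg.responder_shed)
            decline_end = min(horizon, trigger + int(rng.integers(10, 25)))
        else:  # stuck
            # a plateau at or beyond the response threshold would *be* a
            # response by definition, so the shed range is clipped below it
            from .clinical import RESPONSE_THRESHOLD

            lo, hi = tcfg.stuck_shed
            hi = min(hi, RESPONSE_THRESHOLD[dx] - 0.04)
            shed = rng.uniform(lo, max(lo + 1e-6, hi))
            decline_end = min(horizon, trigger + int(rng.integers(5, 13)))
        target = base * (1.0 - shed)
        mean = []
        for d in days:
            if d <= trigger:
                mean.append(base)
            elif d >= decline_end:
                mean.append(target)
            else:
                frac = (d - trigger) / (decline_end - trigger)
                mean.append(base + (target - base) * frac)
    scores = []
    for i, (d, mu) in enumerate(zip(days, mean)):
        noise = 0.0 if d == 0 else rng.normal(0.0, tcfg.noise_sd)
        scores.append(float(np.round(max(0.0, mu + noise), 1)))
    return scores


def apply_missingness(
    table: GenotypeTable, config: CohortConfig, rng: np.random.Generator | None = None
) -> GenotypeTable:
    """Mask genotypes at ``missing_rate``; a designated subject fraction gets
    an elevated (> 5%) missing rate.  Returns a new table."""
    rng = rng or np.random.default_rng(config.seed + 3)
    out = table.copy()
    n, p = out.genotypes.shape
    if p == 0 or n == 0:
        return out
    if config.missing_rate > 0:
        mask = rng.random((n, p)) < config.missing_rate
        out.genotypes[mask] = MISSING
    if config.high_missing_subject_fraction > 0:
        n_high = int(round(config.high_missing_subject_fraction * n))
        which = rng.choice(n, size=n_high, replace=False)
        extra = rng.random((n_high, p)) < config.high_missing_rate
        rows = out.genotypes[which]
        rows[extra] = MISSING
        out.genotypes[which] = rows
    return out


def simulate_igm(
    table: GenotypeTable,
    config: CohortConfig,
    genes: list[GeneDefinition],
    rng: np.random.Generator | None = None,
) -> dict[str, bool]:
    """Elevated-IgM flags with marginal prevalence ~ configured value.

    Carriers of the modal genotypic pattern of any associated gene get an
    elevated probability scaled by ``strength``; the non-carrier probability
    is solved so that the marginal prevalence is preserved.  strength=0 makes
    the flags independent of genotype.
    """
    rng = rng or np.random.default_rng(config.seed + 4)
    prev = config.igm.prevalence
    n = table.n_subjects
    if prev == 0 or n == 0:
        return {s: False for s in table.subjects}
    carrier = np.zeros(n, dtype=bool)
    if config.igm.associated_genes and config.igm.strength > 0:
        gene_by_id = {g.gene: g for g in genes}
        matrix = build_gene_vector_matrix(table, [gene_by_id[g] for g in config.igm.associated_genes])
        for g in config.igm.associated_genes:
            codes = matrix.gene_codes(g)
            ok = codes[codes != MISSING]
            if ok.size == 0:
                continue
            vals, counts = np.unique(ok, return_counts=True)
            modal = vals[np.argmax(counts)]
            carrier |= codes == modal
    c = carrier.mean()
    p_carr = min(0.95, prev * (1.0 + config.igm.strength))
    if c in (0.0, 1.0):
        p_carr = p_non = prev
    else:
        p_non = np.clip((prev - c * p_carr) / (1.0 - c), 0.0, 1.0)
    probs = np.where(carrier, p_carr, p_non)
    flags = rng.random(n) < probs
    return dict(zip(table.subjects, (bool(f) for f in flags)))


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Compose the full synthetic cohort; byte-identical for identical config."""
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rngs = [np.random.default_rng(s) for s in streams]
    table, genes = simulate_genotypes(config, rngs[0])
    diagnoses = {
        s: ("F2" if i < config.n_f2 else "F3") for i, s in enumerate(table.subjects)
    }
    trajs, sev_baselines, classes = simulate_trajectories(
        table.subjects, diagnoses, config, rngs[1]
    )
    labels = label_cohort(trajs, severity_baselines=sev_baselines)
    truth = plant_response_patterns(table, config, labels, genes, rngs[2])
    table = apply_missingness(table, config, rngs[3])
    igm = simulate_igm(table, config, genes, rngs[4])
    labels.table["igm_elevated"] = [igm[s] for s in labels.table.index]
    return SyntheticCohort(
        config=config,
        genotypes=table,
        genes=genes,
        trajectories=trajs,
        severity_baselines=sev_baselines,
        true_labels=labels,
        igm_flags=igm,
        truth=truth,
    )
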