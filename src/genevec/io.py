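"""Readers/writers for the pipeline's formats, QC and end-to-end orchestration.

Genotypes interchange as VCF (GT field; ``./.`` = missing; multi-allelic
sites rejected) or as a long TSV (subject_id, snp_id, genotype in
{0,1,2,NA}).  All coordinates are 1-based inclusive.  Genotypes are
strand-agnostic allele-state counts; no strand flipping is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical import ClinicalTrajectory, OutcomeLabels, label_cohort
from .cohort import CohortConfig, SyntheticCohort, generate_cohort
from .diversity import diversity_summary
from .nn import (
    TrainConfig,
    cross_cohort_overlap,
    exclude_high_missing,
    kfold_cv,
    one_hot_encode,
    random_walk_search,
)
from .screen import ScreenParams, screen_cohort
from .vectors import (
    MISSING,
    GeneDefinition,
    GenotypeTable,
    build_gene_vector_matrix,
)

__all__ = [
    "read_genotypes",
    "write_genotypes_vcf",
    "write_genotypes_tsv",
    "write_gene_definitions",
    "read_gene_definitions",
    "write_trajectories",
    "read_trajectories",
    "write_labels",
    "read_labels",
    "qc_filter",
    "PipelineConfig",
    "run_pipeline",
]


# --------------------------------------------------------------------------
# genotypes

_GT_TO_CODE = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
               "1/1": 2, "1|1": 2}


def write_genotypes_vcf(table: GenotypeTable, path) -> None:
    """Write genotypes as an uncompressed VCF (synthetic REF=A, ALT=G alleles)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(table.snps.sort_values(["chrom", "pos"])["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.subjects) + "\n")
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        order = table.snps.sort_values(["chrom", "pos"]).index
        for row_i in order:
            rec = table.snps.loc[row_i]
            gene = rec["gene"] if rec["gene"] is not None else "."
            calls = "\t".join(
                gt_strings[int(g)] for g in table.genotypes[:, row_i]
            )
            fh.write(f"{rec['chrom']}\t{rec['pos']}\t{rec['snp_id']}\tA\tG\t.\t.\t"
                     f"GENE={gene}\tGT\t{calls}\n")


def _read_vcf(path) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    meta, cols = [], []
    for i, var in enumerate(vcf):
        if var.ALT and len(var.ALT) > 1:
            raise ValueError(f"multi-allelic site unsupported: {var.ID} (record {i + 1})")
        # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = var.gt_types
        code = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        cols.append(code.astype(np.int8))
        gene = var.INFO.get("GENE")
        meta.append((var.ID, gene if gene not in (None, ".") else None,
                     var.CHROM, var.POS))
    snps = pd.DataFrame(meta, columns=["snp_id", "gene", "chrom", "pos"])
    geno = (np.column_stack(cols) if cols
            else np.empty((len(subjects), 0), dtype=np.int8))
    return GenotypeTable(subjects, snps, geno)


def write_genotypes_tsv(table: GenotypeTable, geno_path, snp_path) -> None:
    """Long-format genotype TSV plus SNP metadata TSV."""
    n, p = table.genotypes.shape
    subj = np.repeat(table.subjects, p)
    snp = np.tile(table.snps["snp_id"].to_numpy(), n)
    g = table.genotypes.ravel().astype(object)
    g[g == MISSING] = "NA"
    pd.DataFrame({"subject_id": subj, "snp_id": snp, "genotype": g}).to_csv(
        geno_path, sep="\t", index=False
    )
    table.snps.to_csv(snp_path, sep="\t", index=False)


def _read_tsv(geno_path, snp_path) -> GenotypeTable:
    long = pd.read_csv(geno_path, sep="\t", dtype={"genotype": str},
                       keep_default_na=False)
    snps = pd.read_csv(snp_path, sep="\t")
    snps["gene"] = snps["gene"].where(pd.notna(snps["gene"]), None)
    wide = long.pivot(index="subject_id", columns="snp_id", values="genotype")
    subjects = sorted(long["subject_id"].unique(), key=list(long["subject_id"]).index)
    wide = wide.loc[subjects, snps["snp_id"]]
    geno = wide.replace("NA", MISSING).astype(np.int8).to_numpy()
    return GenotypeTable(list(wide.index), snps, geno)


def read_genotypes(path, dialect: str = "vcf", snp_metadata=None) -> GenotypeTable:
    """Read a genotype table; ``dialect`` is 'vcf' or 'tsv'.

    The TSV dialect needs the companion SNP-metadata file (``snp_metadata``).
    """
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "tsv":
        if snp_metadata is None:
            raise ValueError("tsv dialect requires snp_metadata path")
        return _read_tsv(path, snp_metadata)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_gene_definitions(genes: list[GeneDefinition], path) -> None:
    rows = [(g.gene, g.chrom, g.start, g.end, ",".join(g.snp_ids)) for g in genes]
    pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "snp_ids"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_definitions(path) -> list[GeneDefinition]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        GeneDefinition(r["gene"], r["chrom"], int(r["start"]), int(r["end"]),
                       r["snp_ids"].split(","))
        for _, r in df.iterrows()
    ]


# --------------------------------------------------------------------------
# clinical

def write_trajectories(trajs: list[ClinicalTrajectory], path) -> None:
    rows = [
        (t.subject_id, t.diagnosis, d, t.scale, s)
        for t in trajs
        for d, s in t.visits
    ]
    pd.DataFrame(rows, columns=["subject_id", "diagnosis", "day", "scale", "score"]).to_csv(
        path, sep="\t", index=False
    )


def read_trajectories(path) -> list[ClinicalTrajectory]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (sid, dx, scale), grp in df.groupby(["subject_id", "diagnosis", "scale"], sort=False):
        grp = grp.sort_values("day")
        out.append(
            ClinicalTrajectory(sid, dx, scale,
                               list(zip(grp["day"].astype(int), grp["score"].astype(float))))
        )
    return out


def write_labels(labels: OutcomeLabels, path) -> None:
    labels.table.to_csv(path, sep="\t")


def read_labels(path) -> OutcomeLabels:
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    return OutcomeLabels(df)


# --------------------------------------------------------------------------
# QC

def qc_filter(
    table: GenotypeTable, snp_call_rate: float = 0.95, sample_call_rate: float = 0.80
) -> tuple[GenotypeTable, dict]:
    """Drop SNPs with call rate < 95%, then subjects with call rate < 80%."""
    for r in (snp_call_rate, sample_call_rate):
        if not 0 < r <= 1:
            raise ValueError("call-rate thresholds must be in (0, 1]")
    geno = table.genotypes
    snp_cr = 1.0 - (geno == MISSING).mean(axis=0) if len(table.subjects) else np.ones(table.n_snps)
    keep_snps = snp_cr >= snp_call_rate
    geno2 = geno[:, keep_snps]
    sample_cr = 1.0 - (geno2 == MISSING).mean(axis=1) if keep_snps.any() else np.ones(len(table.subjects))
    keep_subj = sample_cr >= sample_call_rate
    dropped_snps = table.snps.loc[~keep_snps, "snp_id"].tolist()
    dropped_subj = [s for s, k in zip(table.subjects, keep_subj) if not k]
    filtered = GenotypeTable(
        [s for s, k in zip(table.subjects, keep_subj) if k],
        table.snps.loc[keep_snps].reset_index(drop=True),
        geno2[keep_subj],
    )
    report = {
        "dropped_snps": dropped_snps,
        "dropped_subjects": dropped_subj,
        "snp_call_rate": snp_call_rate,
        "sample_call_rate": sample_call_rate,
    }
    return filtered, report


# --------------------------------------------------------------------------
# pipeline

@dataclass
class PipelineConfig:
    """End-to-end run: simulate (or load), QC, vectors, diversity, labels,
    screen, NN cross-validation and cross-diagnosis overlap."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    screen: ScreenParams = field(default_factory=ScreenParams)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0
    missing_cutoff: float = 0.05
    max_screen_genes: int = 12  # cap on the NN candidate pool (best first)
    out_dir: str | None = None
    association_pairs: int | None = 50  # gene pairs sampled for the report

    def __post_init__(self) -> None:
        # one seed drives every stochastic stage
        self.cohort.seed = self.seed
        self.train.seed = self.seed


def _screen_pool(result, cap: int) -> list[str]:
    """Response genes ranked by their strongest pattern (largest target/contrast gap)."""
    if result.qualifying.empty:
        return []
    q = result.qualifying.copy()
    q["gap"] = (q[["f_target", "f_contrast"]].max(axis=1)
                - q[["f_target", "f_contrast"]].min(axis=1))
    ranked = (q.groupby("gene")["gap"].max().sort_values(ascending=False))
    return ranked.index[:cap].tolist()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis on a synthetic cohort; returns the summary dict.

    Deterministic under ``config.seed``; when ``out_dir`` is set, all stage
    outputs (VCF, TSVs, summary JSON) are written there.
    """
    cohort = generate_cohort(config.cohort)
    table, qc_report = qc_filter(cohort.genotypes)
    kept = exclude_high_missing(table, config.missing_cutoff)
    # QC may drop SNPs: gene vectors are built from each gene's surviving
    # SNPs; genes reduced below 2 SNPs are excluded
    surviving = set(table.snps["snp_id"])
    genes = []
    for g in cohort.genes:
        snp_ids = [s for s in g.snp_ids if s in surviving]
        if len(snp_ids) >= 2:
            genes.append(GeneDefinition(g.gene, g.chrom, g.start, g.end, snp_ids))
    matrix = build_gene_vector_matrix(table, genes)
    div = diversity_summary(matrix, table, n_pairs=config.association_pairs,
                            seed=config.seed)
    labels = cohort.true_labels
    analysis_subjects = [s for s in kept if s in set(labels.table.index)]
    screen_res = screen_cohort(matrix, labels, config.screen,
                               subjects=analysis_subjects)
    pool = _screen_pool(screen_res, config.max_screen_genes)
    summary: dict = {
        "seed": config.seed,
        "config": {
            "cohort": asdict(config.cohort),
            "screen": asdict(config.screen),
            "train": asdict(config.train),
            "missing_cutoff": config.missing_cutoff,
        },
        "n_subjects": len(cohort.genotypes.subjects),
        "n_analysis_subjects": len(analysis_subjects),
        "qc": {"n_dropped_snps": len(qc_report["dropped_snps"]),
               "n_dropped_subjects": len(qc_report["dropped_subjects"])},
        "diversity": json.loads(div.to_json()),
        "screen": {
            "n_response_genes": int(screen_res.genes["response_gene"].sum()),
            "response_genes": screen_res.response_genes,
            "nn_pool": pool,
        },
        "nn": {},
    }
    if pool:
        features = one_hot_encode(matrix, pool, min_count=config.screen.min_count)
        sub_index = {s: i for i, s in enumerate(features.subjects)}
        lab = labels.table.loc[analysis_subjects]
        for dx in ("F2", "F3"):
            dx_subjects = [s for s in analysis_subjects if lab.loc[s, "diagnosis"] == dx]
            other = [s for s in analysis_subjects if lab.loc[s, "diagnosis"] != dx]
            y = lab.loc[dx_subjects, "responder"].astype(int).to_numpy()
            if len(dx_subjects) < config.train.k or np.unique(y).size < 2:
                continue
            idx = np.array([sub_index[s] for s in dx_subjects])
            X = features.X[idx]
            model, cv = random_walk_search(X, y, config.train)
            entry = {
                "cv_sensitivity": cv.sensitivity,
                "cv_constraint_accuracy": cv.constraint_accuracy,
                "cv_fp_count": cv.fp_count,
                "cv_fp_rate": cv.fp_rate,
                "n_responders": int(y.sum()),
                "n_non_responders": int((1 - y).sum()),
            }
            if other:
                o_idx = np.array([sub_index[s] for s in other])
                entry["cross_diagnosis_overlap"] = cross_cohort_overlap(
                    model, features.X[o_idx]
                )
            summary["nn"][dx] = entry
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genotypes_vcf(cohort.genotypes, out / "genotypes.vcf")
        write_genotypes_tsv(cohort.genotypes, out / "genotypes.tsv", out / "snps.tsv")
        write_gene_definitions(cohort.genes, out / "genes.tsv")
        write_trajectories(cohort.trajectories, out / "trajectories.tsv")
        write_labels(labels, out / "labels.tsv")
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
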