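"""Synthetic cohort generator: HWE marginals, planting, missingness, determinism."""

import numpy as np
import pytest
from scipy import stats

from genevec.clinical import classify_response
from genevec.cohort import (
    CohortConfig,
    ConfigurationError,
    TrajectoryConfig,
    apply_missingness,
    generate_cohort,
    plant_response_patterns,
    simulate_genotypes,
    simulate_igm,
    simulate_trajectories,
)
from genevec.vectors import MISSING, build_gene_vector_matrix, decode_gene_vector


def test_config_validation():
    with pytest.raises(ConfigurationError):
        CohortConfig(allele_freq_range=(0.0, 0.5))
    with pytest.raises(ConfigurationError):
        CohortConfig(snps_per_gene=(1, 4))
    with pytest.raises(ConfigurationError):
        CohortConfig(missing_rate=1.5)
    with pytest.raises(ConfigurationError):
        TrajectoryConfig(horizon_days=10)


def test_hwe_marginals_without_ld():
    """With ld=0 and f=0.5 the genotype states follow (0.25, 0.5, 0.25)."""
    cfg = CohortConfig(n_f2=0, n_f3=10000, n_genes=2, within_gene_ld=0.0,
                       allele_freq_range=(0.5, 0.5), response_genes=[],
                       missing_rate=0, high_missing_subject_fraction=0, seed=5)
    table, _ = simulate_genotypes(cfg)
    n = table.n_subjects
    for k in range(table.n_snps):
        col = table.genotypes[:, k]
        for state, p in ((0, 0.25), (1, 0.5), (2, 0.25)):
            obs = (col == state).mean()
            se = np.sqrt(p * (1 - p) / n)
            assert abs(obs - p) < 3 * se + 1e-12, (k, state, obs)


def test_independent_coverage_matches_closed_form():
    from genevec.vectors import expected_pattern_coverage, diversity_index

    cfg = CohortConfig(n_f2=0, n_f3=324, n_genes=6, within_gene_ld=0.0,
                       snps_per_gene=(4, 4), allele_freq_range=(0.5, 0.5),
                       response_genes=[], missing_rate=0,
                       high_missing_subject_fraction=0, seed=3)
    table, genes = simulate_genotypes(cfg)
    matrix = build_gene_vector_matrix(table, genes)
    # f=0.5 HWE marginals (0.25, 0.5, 0.25) per SNP
    expected = expected_pattern_coverage(4, 324, [0.25, 0.5, 0.25]) * 81
    observed = np.mean([diversity_index(matrix, g.gene) for g in genes])
    sd = np.std([diversity_index(matrix, g.gene) for g in genes], ddof=1)
    assert abs(observed - expected) < 3 * sd / np.sqrt(len(genes)) + 3


def test_empty_cohort():
    cfg = CohortConfig(n_f2=0, n_f3=0, n_genes=4, response_genes=[])
    table, genes = simulate_genotypes(cfg)
    assert table.n_subjects == 0
    assert table.n_snps == sum(g.m for g in genes)


class TestPlanting:
    def _setup(self, f_resp, f_non, seed=0):
        cfg = CohortConfig(n_f2=0, n_f3=600, n_genes=5, seed=seed,
                           response_genes=[("g000", f_resp, f_non)],
                           missing_rate=0, high_missing_subject_fraction=0)
        return cfg, generate_cohort(cfg)

    def test_planting_frequencies_binomial(self):
        cfg, cohort = self._setup(0.30, 0.05)
        matrix = cohort.gene_vectors()
        codes = matrix.gene_codes("g000")
        planted = cohort.truth["g000"]
        resp = cohort.true_labels.table["responder"].to_numpy()
        subj = np.array(matrix.subjects)
        labelled = cohort.true_labels.table.loc[subj, "responder"].to_numpy()
        n_r, n_n = labelled.sum(), (~labelled).sum()
        hit_r = (codes[labelled] == planted).sum()
        hit_n = (codes[~labelled] == planted).sum()
        # planting is a lower bound; natural carriage can add a few
        assert hit_r >= 0.30 * n_r - 3 * np.sqrt(n_r * 0.3 * 0.7)
        assert hit_n >= 0.05 * n_n - 3 * np.sqrt(n_n * 0.05 * 0.95)
        # and the responder excess is unmistakable
        assert hit_r / n_r > hit_n / n_n + 0.1

    def test_null_planting_leaves_table_unchanged(self):
        cfg = CohortConfig(n_f2=0, n_f3=100, n_genes=3, seed=1,
                           response_genes=[("g001", 0.0, 0.0)],
                           missing_rate=0, high_missing_subject_fraction=0)
        rng = np.random.default_rng(0)
        table, genes = simulate_genotypes(cfg, rng)
        before = table.genotypes.copy()
        from genevec.cohort import simulate_trajectories
        diag = {s: "F3" for s in table.subjects}
        trajs, sev, _ = simulate_trajectories(table.subjects, diag, cfg)
        from genevec.clinical import label_cohort
        labels = label_cohort(trajs, severity_baselines=sev)
        plant_response_patterns(table, cfg, labels, genes)
        assert np.array_equal(before, table.genotypes)

    def test_deterministic_planting(self):
        cfg, cohort = self._setup(1.0, 0.0, seed=2)
        matrix = cohort.gene_vectors()
        codes = matrix.gene_codes("g000")
        planted = cohort.truth["g000"]
        labelled = cohort.true_labels.table.loc[matrix.subjects, "responder"].to_numpy()
        assert (codes[labelled] == planted).all()

    def test_unknown_gene_rejected(self):
        cfg = CohortConfig(n_f2=0, n_f3=50, n_genes=2, seed=0,
                           response_genes=[("g999", 0.3, 0.05)])
        with pytest.raises(ConfigurationError):
            generate_cohort(cfg)


class TestTrajectories:
    def test_no_trigger_means_no_responders(self):
        cfg = CohortConfig(n_f2=0, n_f3=200, n_genes=2, seed=0, response_genes=[],
                           responder_fraction={"F2": 0.0, "F3": 0.0},
                           trajectory=TrajectoryConfig(stuck_fraction=0.0,
                                                       noise_sd=0.2))
        cohort = generate_cohort(cfg)
        assert not cohort.true_labels.table["responder"].any()

    def test_responder_fraction_recovered(self):
        fracs = []
        for seed in range(4):
            cfg = CohortConfig(
                n_f2=0, n_f3=500, n_genes=2, seed=seed, response_genes=[],
                responder_fraction={"F2": 0.4, "F3": 0.4},
                trajectory=TrajectoryConfig(noise_sd=0.3,
                                            responder_shed=(0.70, 0.85)),
            )
            cohort = generate_cohort(cfg)
            fracs.append(cohort.true_labels.table["responder"].mean())
        assert abs(np.mean(fracs) - 0.4) < 0.05

    def test_noiseless_decline_is_responder(self):
        traj = simulate_trajectories(
            ["s"], {"s": "F3"},
            CohortConfig(n_f2=0, n_f3=1, n_genes=2, seed=0, response_genes=[],
                         responder_fraction={"F2": 1.0, "F3": 1.0},
                         trajectory=TrajectoryConfig(noise_sd=0.0)),
        )[0][0]
        assert classify_response(traj)

    def test_visit_schedule(self, small_cohort):
        for t in small_cohort.trajectories:
            assert t.days == [0, 3, 7, 10, 14, 21, 28, 42]


class TestMissingness:
    def test_zero_rate_unchanged(self, small_cohort):
        cfg = CohortConfig(n_f2=0, n_f3=10, n_genes=2, missing_rate=0.0,
                           high_missing_subject_fraction=0.0, response_genes=[])
        table, _ = simulate_genotypes(cfg)
        out = apply_missingness(table, cfg)
        assert np.array_equal(out.genotypes, table.genotypes)

    def test_masked_fraction_binomial(self):
        cfg = CohortConfig(n_f2=0, n_f3=100, n_genes=100, missing_rate=0.02,
                           high_missing_subject_fraction=0.0, response_genes=[],
                           seed=9)
        table, _ = simulate_genotypes(cfg)
        out = apply_missingness(table, cfg)
        cells = out.genotypes.size
        frac = (out.genotypes == MISSING).mean()
        se = np.sqrt(0.02 * 0.98 / cells)
        assert abs(frac - 0.02) < 3 * se

    def test_high_missing_tail(self):
        cfg = CohortConfig(n_f2=0, n_f3=100, n_genes=100, missing_rate=0.02,
                           high_missing_subject_fraction=0.10,
                           high_missing_rate=0.12, response_genes=[], seed=9)
        table, _ = simulate_genotypes(cfg)
        out = apply_missingness(table, cfg)
        n_high = (out.missing_rate_per_subject() > 0.05).sum()
        assert 5 <= n_high <= 16  # ~10 planted high-missing subjects


class TestIgm:
    def test_zero_prevalence(self, small_cohort):
        from genevec.cohort import IgmConfig

        cfg = CohortConfig(n_f2=0, n_f3=50, n_genes=2, response_genes=[],
                           igm=IgmConfig(prevalence=0.0))
        table, genes = simulate_genotypes(cfg)
        flags = simulate_igm(table, cfg, genes)
        assert not any(flags.values())

    def test_marginal_prevalence(self):
        from genevec.cohort import IgmConfig

        cfg = CohortConfig(n_f2=0, n_f3=900, n_genes=4, response_genes=[],
                           igm=IgmConfig(prevalence=0.26,
                                         associated_genes=("g000",),
                                         strength=0.5),
                           seed=4)
        table, genes = simulate_genotypes(cfg)
        flags = simulate_igm(table, cfg, genes)
        count = sum(flags.values())
        se = np.sqrt(900 * 0.26 * 0.74)
        assert abs(count - 234) < 3 * se

    def test_zero_strength_independence(self):
        """With strength 0 the flags are independent of carrier status."""
        from genevec.cohort import IgmConfig

        pvals = []
        for seed in range(100):
            cfg = CohortConfig(n_f2=0, n_f3=300, n_genes=2, response_genes=[],
                               igm=IgmConfig(prevalence=0.3,
                                             associated_genes=("g000",),
                                             strength=0.0),
                               seed=seed, missing_rate=0,
                               high_missing_subject_fraction=0)
            table, genes = simulate_genotypes(cfg)
            flags = simulate_igm(table, cfg, genes)
            matrix = build_gene_vector_matrix(table, genes)
            codes = matrix.gene_codes("g000")
            vals, counts = np.unique(codes, return_counts=True)
            modal = vals[np.argmax(counts)]
            carrier = codes == modal
            flag = np.array([flags[s] for s in table.subjects])
            tab = np.array([
                [(carrier & flag).sum(), (carrier & ~flag).sum()],
                [(~carrier & flag).sum(), (~carrier & ~flag).sum()],
            ])
            if (tab.sum(axis=1) > 0).all() and (tab.sum(axis=0) > 0).all():
                pvals.append(stats.chi2_contingency(tab, correction=False)[1])
        # at alpha = 0.01 the null should survive in >= 95% of seeds
        assert np.mean(np.array(pvals) >= 0.01) >= 0.95


class TestDeterminism:
    @staticmethod
    def _cfg(seed):
        return CohortConfig(n_f2=10, n_f3=40, n_genes=6, seed=seed,
                            response_genes=[("g001", 0.3, 0.05)])

    def test_same_seed_identical_bytes(self):
        assert generate_cohort(self._cfg(77)).serialize() == \
            generate_cohort(self._cfg(77)).serialize()

    def test_different_seed_differs(self):
        assert generate_cohort(self._cfg(1)).serialize() != \
            generate_cohort(self._cfg(2)).serialize()


def test_study_sized_cohort_fast_and_calibrated():
    """The full 902-subject, 100-gene default cohort builds in seconds and
    reproduces the headline structure: ~2% base missingness and a dependence
    ratio in the vicinity of one third."""
    import time

    from genevec.diversity import dependence_ratio

    t0 = time.time()
    cohort = generate_cohort(CohortConfig(seed=1))
    assert time.time() - t0 < 60
    assert cohort.genotypes.n_subjects == 902
    matrix = cohort.gene_vectors()
    ratio, _ = dependence_ratio(matrix, cohort.genotypes)
    assert 0.2 < ratio < 0.55
    lab = cohort.true_labels.table
    igm = lab["igm_elevated"].mean()
    assert 0.18 < igm < 0.34
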