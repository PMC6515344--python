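"""Synthetic cohort generator: determinism, planted effects, covariates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from circlin.simulate import (
    SimulationConfig,
    SplicingEventSpec,
    simulate_cohort,
    simulate_ct_matrix,
    simulate_splicing_table,
)


class TestConfigValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_cases=-1)

    def test_too_many_true_positives_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=3, n_true_positive=4)

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(ratio_fold=0.0)

    def test_unordered_lib_range_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(lib_size_range=(10, 5))


class TestDeterminism:
    def test_identical_tables_for_fixed_seed(self):
        cfg = SimulationConfig(seed=11, n_genes=10, n_cases=4, n_controls=4,
                               n_true_positive=3)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a[0].counts, b[0].counts)
        pd.testing.assert_frame_equal(a[1], b[1])
        pd.testing.assert_frame_equal(a[2], b[2])
        ct_a = simulate_ct_matrix(cfg, a[3], sorted(a[3].true_positive_ids))
        ct_b = simulate_ct_matrix(cfg, b[3], sorted(b[3].true_positive_ids))
        pd.testing.assert_frame_equal(ct_a, ct_b)

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimulationConfig(seed=1, n_genes=5, n_cases=3, n_controls=3))
        b = simulate_cohort(SimulationConfig(seed=2, n_genes=5, n_cases=3, n_controls=3))
        assert not a[0].counts.equals(b[0].counts)


class TestCohortStructure:
    def test_empty_gene_set(self):
        cfg = SimulationConfig(n_genes=0, n_true_positive=0, n_cases=3, n_controls=3)
        table, linear, metadata, truth = simulate_cohort(cfg)
        assert table.counts.empty and linear.empty
        assert len(metadata) == 6 and not truth.true_positive_ids

    def test_truth_invariants(self):
        cfg = SimulationConfig(seed=3, n_genes=20, n_cases=6, n_controls=5,
                               n_true_positive=4)
        _, _, metadata, truth = simulate_cohort(cfg)
        cases = set(metadata.loc[metadata["group"] == "case", "sample_id"])
        assert set(truth.severity.index) == cases
        assert truth.severity.between(0, 1).all()
        f = truth.per_gene_baseline_fraction
        assert ((f > 0) & (f < 1)).all()
        assert truth.true_positive_ids <= set(f.index)

    def test_linear_junctions_share_event_sites(self):
        cfg = SimulationConfig(seed=3, n_genes=6, n_cases=2, n_controls=2)
        table, linear, _, _ = simulate_cohort(cfg)
        for _, ev in table.events.iterrows():
            sub = linear[linear["chrom"] == ev["chrom"]]
            touches = (sub["donor_pos"].isin([ev["start"], ev["end"]])
                       | sub["acceptor_pos"].isin([ev["start"], ev["end"]]))
            assert touches.all()
            assert sub["donor_pos"].nunique() + sub["acceptor_pos"].nunique() >= 2

    def test_mrc_decreases_with_severity_noise_free(self):
        cfg = SimulationConfig(seed=9, n_cases=20, n_controls=5, n_genes=2,
                               n_true_positive=0, mrc_noise_sd=0.0)
        _, _, metadata, truth = simulate_cohort(cfg)
        meta = metadata.set_index("sample_id")
        ordered = truth.severity.sort_values()
        mrc = meta.loc[ordered.index, "mrc_megascore"]
        assert (np.diff(mrc.to_numpy()) <= 1e-9).all()
        assert (meta.loc[meta["group"] == "control", "mrc_megascore"]
                == cfg.mrc_baseline).all()

    def test_mirs_quartile_mapping(self):
        cfg = SimulationConfig(seed=9, n_cases=40, n_controls=4, n_genes=2,
                               n_true_positive=0)
        _, _, metadata, truth = simulate_cohort(cfg)
        meta = metadata.set_index("sample_id")
        for sid, s in truth.severity.items():
            assert meta.loc[sid, "mirs_stage"] == min(3, int(s * 4)) + 2
        assert meta.loc[meta["group"] == "control", "mirs_stage"].isna().all()


class TestPlantedEffect:
    def test_null_groups_identical_in_law(self):
        """theta = 1: pooled case and control ratios from one gene agree (KS)."""
        cfg = SimulationConfig(seed=21, n_genes=10, n_true_positive=10, ratio_fold=1.0,
                               n_cases=150, n_controls=150, dispersion=0.05)
        table, linear, metadata, _ = simulate_cohort(cfg)
        best = linear.groupby(["chrom", "sample_id"])["count"].max().unstack()
        groups = metadata.set_index("sample_id")["group"]
        case_cols = [s for s in table.samples if groups[s] == "case"]
        ctrl_cols = [s for s in table.samples if groups[s] == "control"]
        ratios = table.counts.to_numpy() / best.reindex(
            index=table.events["chrom"], columns=table.samples).to_numpy()
        case_r = ratios[:, [table.samples.index(s) for s in case_cols]].ravel()
        ctrl_r = ratios[:, [table.samples.index(s) for s in ctrl_cols]].ravel()
        assert sps.ks_2samp(case_r, ctrl_r).pvalue > 0.001

    def test_ratio_fold_recovered(self):
        """theta = 2, c = 0: case/control mean-ratio quotient within [1.8, 2.2].

        The planted multiplier acts on the circular-to-linear odds,
        which equal the ratio, so the quotient of group mean ratios
        estimates theta directly (Monte-Carlo over 20 seeds).
        """
        per_gene = {}
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, n_genes=4, n_true_positive=4,
                                   ratio_fold=2.0, severity_coupling=0.0,
                                   n_cases=200, n_controls=200, dispersion=0.01)
            table, linear, metadata, truth = simulate_cohort(cfg)
            best = linear.groupby(["chrom", "sample_id"])["count"].max().unstack()
            groups = metadata.set_index("sample_id")["group"]
            ratios = pd.DataFrame(
                table.counts.to_numpy()
                / best.reindex(index=table.events["chrom"], columns=table.samples).to_numpy(),
                index=table.events["gene_id"], columns=table.samples,
            )
            case_cols = [s for s in table.samples if groups[s] == "case"]
            ctrl_cols = [s for s in table.samples if groups[s] == "control"]
            for gene in truth.true_positive_ids:
                q = ratios.loc[gene, case_cols].mean() / ratios.loc[gene, ctrl_cols].mean()
                per_gene.setdefault(gene, []).append(q)
        for gene, quotients in per_gene.items():
            assert 1.8 <= np.mean(quotients) <= 2.2, (gene, np.mean(quotients))

    def test_expected_read_share_conserved(self):
        """Circular + linear means sum to lib_size * e_g * 1e-6 (low noise)."""
        cfg = SimulationConfig(seed=5, n_genes=3, n_true_positive=0, dispersion=0.0,
                               n_cases=100, n_controls=100,
                               expression_log_mean=np.log(500.0), expression_log_sd=0.0)
        table, linear, _, truth = simulate_cohort(cfg)
        lin_sum = linear.groupby(["chrom", "sample_id"])["count"].sum().unstack()
        total = table.counts.to_numpy() + lin_sum.reindex(
            index=table.events["chrom"], columns=table.samples).to_numpy()
        expected = (truth.baseline_expression.to_numpy()[:, None]
                    * table.lib_sizes.reindex(table.samples).to_numpy()[None, :] * 1e-6)
        np.testing.assert_allclose(total.mean(axis=1) / expected.mean(axis=1), 1.0, atol=0.02)


class TestCtMatrix:
    def test_noise_free_ct_difference_equals_log2_odds(self):
        cfg = SimulationConfig(seed=13, n_genes=5, n_true_positive=0, ct_noise_sd=0.0,
                               n_cases=2, n_controls=2)
        _, _, _, truth = simulate_cohort(cfg)
        ct = simulate_ct_matrix(cfg, truth, list(truth.baseline_expression.index))
        wide = ct.pivot_table(index=["target_id", "sample_id"], columns="isoform",
                              values="ct")
        for (gene, sid), row in wide.dropna().iterrows():
            f = truth.per_gene_baseline_fraction[gene]
            # Ct_circ - Ct_lin = log2((1-f)/f); half-abundance circ -> +1 cycle
            assert row["circular"] - row["linear"] == pytest.approx(
                np.log2((1 - f) / f), abs=1e-9
            )

    def test_planted_fold_shifts_group_mean_by_log2_theta(self):
        cfg = SimulationConfig(seed=13, n_genes=4, n_true_positive=4, ratio_fold=4.0,
                               severity_coupling=0.0, ct_noise_sd=0.0,
                               n_cases=5, n_controls=5)
        _, _, metadata, truth = simulate_cohort(cfg)
        ct = simulate_ct_matrix(cfg, truth, sorted(truth.true_positive_ids))
        wide = ct.pivot_table(index=["target_id", "sample_id"], columns="isoform",
                              values="ct").dropna(subset=["circular", "linear"]).reset_index()
        wide["neg_dct"] = wide["linear"] - wide["circular"]
        groups = metadata.set_index("sample_id")["group"]
        wide["group"] = wide["sample_id"].map(groups)
        for gene, sub in wide.groupby("target_id"):
            diff = (sub.loc[sub["group"] == "case", "neg_dct"].mean()
                    - sub.loc[sub["group"] == "control", "neg_dct"].mean())
            assert diff == pytest.approx(2.0, abs=1e-9)  # log2(4)

    def test_reference_normalized_dct_removes_size_factor(self):
        cfg = SimulationConfig(seed=13, n_genes=3, n_true_positive=0, ct_noise_sd=0.0,
                               n_cases=3, n_controls=3)
        _, _, _, truth = simulate_cohort(cfg)
        gene = truth.baseline_expression.index[0]
        ct = simulate_ct_matrix(cfg, truth, [gene])
        flat = ct.pivot_table(index="sample_id", columns=["target_id", "isoform"],
                              values="ct")
        refs = flat[[c for c in flat.columns if c[1] == "reference"]].mean(axis=1)
        dct = flat[(gene, "circular")] - refs
        # identical across samples: size factor cancels, f_g and e_g fixed
        assert dct.std() == pytest.approx(0.0, abs=1e-9)

    def test_unknown_target_rejected(self):
        cfg = SimulationConfig(seed=13, n_genes=2, n_true_positive=0)
        _, _, _, truth = simulate_cohort(cfg)
        with pytest.raises(ValueError, match="unknown target"):
            simulate_ct_matrix(cfg, truth, ["NOT_A_GENE"])

    def test_empty_target_list(self):
        cfg = SimulationConfig(seed=13, n_genes=2, n_true_positive=0, n_cases=2,
                               n_controls=2)
        _, _, _, truth = simulate_cohort(cfg)
        ct = simulate_ct_matrix(cfg, truth, [], reference_genes=[])
        assert ct.empty and list(ct.columns) == ["target_id", "isoform", "sample_id",
                                                 "replicate", "ct"]


class TestSplicingTable:
    def test_noise_free_flat_event(self):
        cfg = SimulationConfig(seed=17, n_genes=2, n_true_positive=0, n_cases=4,
                               n_controls=4)
        _, _, _, truth = simulate_cohort(cfg)
        spec = SplicingEventSpec("E", "exclusion", baseline=40.0, slope=0.0, noise_sd=0.0)
        table = simulate_splicing_table(cfg, truth, (spec,))
        assert (table["percent"] == 40.0).all()

    def test_band_pair_round_trip(self):
        from circlin.biomarker import exon_exclusion_percent

        cfg = SimulationConfig(seed=17, n_genes=2, n_true_positive=0, n_cases=4,
                               n_controls=4)
        _, _, _, truth = simulate_cohort(cfg)
        table = simulate_splicing_table(cfg, truth)
        stated = table["percent"].copy()
        table = table.assign(percent=np.nan)
        recovered = exon_exclusion_percent(table)["percent"]
        np.testing.assert_allclose(recovered, stated, atol=1e-9)

    def test_severity_drives_percentage(self):
        spec = SplicingEventSpec("E", "exclusion", baseline=10.0, slope=30.0, noise_sd=2.0)
        hits = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, n_genes=2, n_true_positive=0,
                                   n_cases=30, n_controls=5)
            _, _, _, truth = simulate_cohort(cfg)
            table = simulate_splicing_table(cfg, truth, (spec,))
            cases = table[table["sample_id"].isin(truth.severity.index)]
            r = np.corrcoef(truth.severity[cases["sample_id"]].to_numpy(),
                            cases["percent"].to_numpy())[0, 1]
            hits += r > 0.9
        assert hits >= 9

    def test_bad_baseline_rejected(self):
        with pytest.raises(ValueError):
            SplicingEventSpec("E", "exclusion", baseline=120.0, slope=0.0)
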