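import filecmp

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from seqsig import pipeline
from seqsig.kmer_spectrum import N_KMERS, count_weighted_kmers, estimate_spectrum
from seqsig.synthetic_data import (
    CELL_A,
    CELL_B,
    GeneratorConfig,
    config_from_json,
    config_to_json,
    generate,
    truth_eval,
)


def null_config(**kw):
    return GeneratorConfig(
        emission_log_sd=0.0, driver_delta=0.0, expression_independent=True, **kw
    )


class TestConfig:
    def test_unidentifiable_coverage_is_error(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            GeneratorConfig(lambda_peak=1.0, lambda_dip=5.0)

    def test_transition_matrix_rows_sum_to_one(self):
        cfg = GeneratorConfig()
        np.testing.assert_allclose(cfg.transition_matrix.sum(axis=1), 1.0)
        pi = cfg.stationary
        np.testing.assert_allclose(pi @ cfg.transition_matrix, pi)

    def test_json_roundtrip(self, tmp_path):
        cfg = GeneratorConfig(n_genes=17, seed=4, shared_fraction=0.4)
        config_to_json(cfg, tmp_path / "c.json")
        assert config_from_json(tmp_path / "c.json") == cfg


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        cfg = GeneratorConfig(n_genes=20, seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate(cfg).write(d1)
        generate(cfg).write(d2)
        names = sorted(p.name for p in d1.iterdir())
        assert names == sorted(p.name for p in d2.iterdir())
        match, mismatch, errors = filecmp.cmpfiles(d1, d2, names, shallow=False)
        assert mismatch == [] and errors == []
        assert len(match) == len(names) > 0

    def test_different_seeds_differ(self):
        a = generate(GeneratorConfig(n_genes=5, seed=1))
        b = generate(GeneratorConfig(n_genes=5, seed=2))
        assert a.genome != b.genome


class TestStructure:
    def test_genome_layout_and_windows(self):
        ds = generate(GeneratorConfig(n_genes=15, seed=3))
        windows = ds.windows()
        assert len(windows) == 15
        # every window's oriented sequence reproduces the planted segments
        for g, w in enumerate(windows):
            assert len(w.segments) == 334
            assert w.gene_id == ds.truth.gene_ids[g]

    def test_transition_frequencies_converge(self, small_dataset):
        states = small_dataset.truth.states[CELL_A]
        cur, nxt = states[:, :-1].ravel(), states[:, 1:].ravel()
        a_mm = (cur & nxt).sum() / cur.sum()
        a_dd = (~cur & ~nxt).sum() / (~cur).sum()
        A = small_dataset.truth.transition_matrix
        assert abs(a_mm - A[0, 0]) < 0.02
        assert abs(a_dd - A[1, 1]) < 0.02

    def test_peak_kmer_frequencies_match_marginal(self, small_dataset):
        """Chi-squared goodness of fit of peak-segment 6-mer draws against
        the planted marginal peak distribution (cells pooled to keep
        expected counts >= 5)."""
        ds = small_dataset
        wins = ds.windows()
        states = ds.truth.states[CELL_A]
        segs, heights = [w.segments for w in wins], [s.astype(float) for s in states]
        pc, _ = count_weighted_kmers(segs, heights, dip_source="residual_everywhere")
        n = pc.sum()
        expected = n * ds.truth.p_peak
        order = np.argsort(expected)
        obs_pool, exp_pool = [], []
        o_acc = e_acc = 0.0
        for i in order:
            o_acc += pc[i]
            e_acc += expected[i]
            if e_acc >= 5:
                obs_pool.append(o_acc)
                exp_pool.append(e_acc)
                o_acc = e_acc = 0.0
        obs_pool[-1] += o_acc
        exp_pool[-1] += e_acc
        res = stats.chisquare(obs_pool, exp_pool)
        assert res.pvalue > 0.01

    def test_shared_fraction_extremes(self):
        full = generate(GeneratorConfig(n_genes=30, seed=5, shared_fraction=1.0))
        sa, sb = full.truth.states[CELL_A], full.truth.states[CELL_B]
        assert (sa & ~sb).sum() == 0  # every A peak present in B
        none = generate(GeneratorConfig(n_genes=30, seed=5, shared_fraction=0.0))
        sa, sb = none.truth.states[CELL_A], none.truth.states[CELL_B]
        overlap = (sa & sb).mean() / max(sa.mean() * sb.mean(), 1e-9)
        assert overlap < 2.0  # only chance-level co-occurrence remains


class TestCoverage:
    def test_enriched_mask_recovers_peak_bases(self, small_dataset):
        """lambda 20 vs 1 with the 5-read threshold recovers >= 95% of
        planted peak bases."""
        ds = small_dataset
        heights, enriched = pipeline.chip_segment_heights(
            ds.genome, ds.windows(), ds.reads[CELL_A]
        )
        states = ds.truth.states[CELL_A]
        assert enriched[states].mean() >= 0.95

    def test_dip_bases_mostly_unenriched(self, small_dataset):
        ds = small_dataset
        heights, enriched = pipeline.chip_segment_heights(
            ds.genome, ds.windows(), ds.reads[CELL_A]
        )
        states = ds.truth.states[CELL_A]
        # read extension blurs 150 bp past run edges; interior dips stay clean
        assert enriched[~states].mean() < 0.5
        assert heights[~states].mean() < 0.2


class TestNegativeControl:
    def test_delta_zero_removes_sequence_signal(self):
        """With no planted k-mer preference the spectrum is flat and the
        decoded signatures are uninformative out of sample.

        The model is fit on half the genes and decoded on the other half:
        with ~12 counts per 6-mer cell a within-sample decode would partly
        memorize which 6-mers happened to land in this dataset's peaks.
        """
        from seqsig import hmm_signature

        ds = generate(null_config(n_genes=200, seed=13))
        np.testing.assert_allclose(ds.truth.log_ratio, 0.0, atol=1e-12)
        windows = ds.windows()
        heights, enriched = pipeline.chip_segment_heights(
            ds.genome, windows, ds.reads[CELL_A]
        )
        half = len(windows) // 2
        model = pipeline.fit_signature_model(
            windows[:half], heights[:half], enriched=enriched[:half]
        )
        assert np.abs(model.spectrum.log_ratio).mean() < 0.5
        profiles = hmm_signature.posterior_batch(
            model, [w.segments for w in windows[half:]]
        )
        gamma = np.stack([p.gamma for p in profiles])
        auc = roc_auc_score(
            ds.truth.states[CELL_A][half:].ravel(), gamma.ravel()
        )
        assert abs(auc - 0.5) < 0.05


class TestTruthEval:
    def test_ground_truth_scores_at_ceiling(self, small_dataset):
        ds = small_dataset
        states = ds.truth.states[CELL_A]
        report = truth_eval(
            {
                "gene_ids": ds.truth.gene_ids,
                "gamma": states.astype(float),
                "log_ratio": ds.truth.log_ratio,
                "transition_matrix": ds.truth.transition_matrix,
                "expression_pred": np.log2(ds.truth.fpkm[CELL_A] + 1.0),
                "locus_classes": ds.truth.locus_classes(),
            },
            ds.truth,
        )
        assert report["state_auc"] == 1.0
        assert report["spectrum_logratio_pearson"] == pytest.approx(1.0)
        assert report["transition_max_abs_error"] == 0.0
        assert report["expression_spearman"] == pytest.approx(1.0)
        assert report["expression_auc"] == 1.0
        assert report["recall_typeA_specific"] == 1.0

    def test_shuffled_predictions_score_at_chance(self, small_dataset):
        ds = small_dataset
        rng = np.random.default_rng(0)
        states = ds.truth.states[CELL_A]
        report = truth_eval(
            {
                "gamma": rng.permuted(states.astype(float), axis=None).reshape(
                    states.shape
                ),
                "expression_pred": rng.permutation(
                    np.log2(ds.truth.fpkm[CELL_A] + 1.0)
                ),
            },
            ds.truth,
        )
        assert abs(report["state_auc"] - 0.5) < 0.02
        assert abs(report["expression_spearman"]) < 0.15

    def test_gene_id_mismatch_is_error(self, small_dataset):
        with pytest.raises(ValueError, match="id mismatch"):
            truth_eval({"gene_ids": ["nope"]}, small_dataset.truth)
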