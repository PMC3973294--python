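import numpy as np
import pandas as pd
import pytest

from promethyl.annotation import read_probes, read_promoters, write_probes, write_promoters
from promethyl.benchmarks import run_methylation_pipeline
from promethyl.simulate import (
    ConfigError,
    ConsistencyError,
    SimulationConfig,
    generate_annotation,
    generate_expression_truth,
    generate_ground_truth,
    simulate_expression_arrays,
    simulate_map_arrays,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_promoters": 0},
            {"n_promoters": -5},
            {"probes_per_window": 0},
            {"effect_log2": 0.0},
            {"frac_early": 0.6, "frac_late": 0.5},
            {"frac_early": 1.2},
            {"replicate_count": 1},
            {"expr_fold": (0.5, 2.0)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)

    def test_scalar_fold_promoted_to_range(self):
        cfg = SimulationConfig(expr_fold=4)
        assert cfg.expr_fold == (4.0, 4.0)


class TestAnnotationGeneration:
    def test_minimal_case_has_expected_probe_counts(self):
        cfg = SimulationConfig(n_promoters=1, probes_per_window=12, seed=0)
        promoters, probes = generate_annotation(cfg)
        assert len(promoters) == 1
        core = probes[probes["window"] == "core"]
        upstream = probes[probes["window"] == "upstream"]
        assert len(core) == 12 and len(upstream) == 12

    def test_minus_strand_probes_reflect_around_tss(self):
        cfg = SimulationConfig(n_promoters=40, probes_per_window=12, seed=3)
        promoters, probes = generate_annotation(cfg)
        minus = promoters[promoters["strand"] == "-"]
        assert len(minus) > 0
        for _, pr in minus.iterrows():
            mine = probes[probes["gene_id"] == pr["gene_id"]]
            mids = (mine["start"] + mine["end"]) / 2.0
            t = pr["tss"] - mids  # transcription-axis position
            core = mine["window"] == "core"
            # hand-derived reflection: core probes sit in genomic
            # (tss-500, tss+500], upstream in (tss+500, tss+1500]
            assert ((t[core] >= -500) & (t[core] < 500)).all()
            assert (mids[core] > pr["tss"] - 500).all()
            assert (mids[core] <= pr["tss"] + 500).all()
            assert (mids[~core] > pr["tss"] + 500).all()
            assert (mids[~core] <= pr["tss"] + 1500).all()

    def test_same_seed_gives_identical_files(self, tmp_path):
        cfg = SimulationConfig(n_promoters=30, seed=11)
        for run in ("a", "b"):
            promoters, probes = generate_annotation(cfg)
            write_promoters(promoters, tmp_path / f"{run}.bed")
            write_probes(probes, tmp_path / f"{run}.tsv")
        assert (tmp_path / "a.bed").read_bytes() == (tmp_path / "b.bed").read_bytes()
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_distinct_seeds_differ(self):
        a = simulate_map_arrays(
            *_annotation_and_truth(seed=1), SimulationConfig(n_promoters=20, seed=1)
        )
        b = simulate_map_arrays(
            *_annotation_and_truth(seed=2), SimulationConfig(n_promoters=20, seed=2)
        )
        assert not np.allclose(a["parent"]["ch1"], b["parent"]["ch1"])

    def test_roundtrip_through_io_readers(self, tmp_path):
        cfg = SimulationConfig(n_promoters=25, seed=4)
        promoters, probes = generate_annotation(cfg)
        write_promoters(promoters, tmp_path / "p.bed")
        write_probes(probes, tmp_path / "pr.tsv")
        pd.testing.assert_frame_equal(read_promoters(tmp_path / "p.bed"), promoters)
        pd.testing.assert_frame_equal(
            read_probes(tmp_path / "pr.tsv"), probes[["probe_id", "chrom", "start", "end"]]
        )


def _annotation_and_truth(seed, **kw):
    cfg = SimulationConfig(n_promoters=20, seed=seed, **kw)
    promoters, probes = generate_annotation(cfg)
    return probes, generate_ground_truth(promoters, cfg)


class TestMapArraySimulation:
    @staticmethod
    def noise_free_config(**kw):
        return dict(
            probe_noise_sd=0.0, intensity_bias=(), array_spread=(1, 1, 1, 1, 1), **kw
        )

    def test_stable_promoters_have_zero_m_everywhere(self):
        cfg = SimulationConfig(
            n_promoters=30, seed=6, frac_early=0, frac_late=0, frac_loss=0,
            **self.noise_free_config(),
        )
        promoters, probes = generate_annotation(cfg)
        truth = generate_ground_truth(promoters, cfg)
        arrays = simulate_map_arrays(probes, truth, cfg)
        for tbl in arrays.values():
            m = np.log2(tbl["ch2"] / tbl["ch1"])
            assert np.allclose(m, 0.0, atol=1e-9)

    def test_early_promoter_window_median_equals_effect(self):
        cfg = SimulationConfig(
            n_promoters=50, seed=8, frac_early=0.2, frac_late=0, frac_loss=0,
            effect_log2=1.5, **self.noise_free_config(),
        )
        promoters, probes = generate_annotation(cfg)
        truth = generate_ground_truth(promoters, cfg)
        arrays = simulate_map_arrays(probes, truth, cfg)
        early = truth.promoters.index[truth.promoters["hTERT"] == "early"]
        assert len(early) == 10
        for g in early[:3]:
            members = probes["gene_id"] == g
            for sample, expected in [
                ("parent", 0.0), ("hTERT_50", 1.5), ("hTERT_100", 1.5),
                ("TSR_50", 1.5), ("TSR_100", 1.5),
            ]:
                tbl = arrays[sample][members.to_numpy()]
                m = np.log2(tbl["ch2"] / tbl["ch1"])
                assert np.median(m) == pytest.approx(expected, abs=1e-9)

    def test_truth_mismatch_raises(self):
        cfg = SimulationConfig(n_promoters=10, seed=1)
        promoters, probes = generate_annotation(cfg)
        truth = generate_ground_truth(promoters.iloc[:5], cfg)
        with pytest.raises(ConsistencyError):
            simulate_map_arrays(probes, truth, cfg)

    def test_dye_bias_induces_then_loess_removes_ma_trend(self, rng):
        from promethyl.normalization import loess_normalize, compute_ma

        cfg = SimulationConfig(
            n_promoters=150, seed=9, frac_early=0, frac_late=0, frac_loss=0,
            probe_noise_sd=0.0, intensity_bias=(0.5,), array_spread=(1, 1, 1, 1, 1),
        )
        promoters, probes = generate_annotation(cfg)
        truth = generate_ground_truth(promoters, cfg)
        tbl = simulate_map_arrays(probes, truth, cfg)["parent"]
        ma, _ = compute_ma(tbl)
        raw_corr = np.corrcoef(ma["M"], ma["A"])[0, 1]
        assert raw_corr > 0.9
        out = loess_normalize(tbl, rng=rng)
        deciles = pd.qcut(out.data["A"], 10)
        assert out.data.groupby(deciles, observed=True)["M"].median().abs().max() < 0.05

    def test_noise_free_pipeline_recovers_all_labels(self):
        r = run_methylation_pipeline(
            SimulationConfig(
                n_promoters=400, seed=12, probe_noise_sd=0.0, intensity_bias=(),
                array_spread=(1, 1, 1, 1, 1),
            )
        )
        assert r.sensitivity == 1.0
        assert r.fdp == 0.0
        assert r.timing_accuracy == 1.0
        assert r.n_inconsistent == 0


class TestExpressionSimulation:
    def test_same_seed_identical_and_different_seed_not(self):
        cfg = SimulationConfig(n_transcripts=30, n_promoters=30, seed=3)
        a1, *_ = simulate_expression_arrays(cfg)
        a2, *_ = simulate_expression_arrays(cfg)
        pd.testing.assert_frame_equal(a1["parent_r1"], a2["parent_r1"])
        b, *_ = simulate_expression_arrays(
            SimulationConfig(n_transcripts=30, n_promoters=30, seed=4)
        )
        assert not np.allclose(a1["parent_r1"]["intensity"], b["parent_r1"]["intensity"])

    def test_all_null_data_yield_no_group_calls(self):
        from promethyl.benchmarks import run_expression_pipeline

        cfg = SimulationConfig(
            n_transcripts=300, seed=21,
            expr_frac_up=0, expr_frac_activated=0, expr_frac_down=0,
            expr_frac_g4=0, expr_frac_g5=0, expr_frac_g6=0,
        )
        r = run_expression_pipeline(cfg)
        assert r.n_true_labelled == 0
        assert r.spurious <= 0.01

    def test_group_proportions_respected(self):
        cfg = SimulationConfig(n_transcripts=1000, seed=5)
        truth = generate_expression_truth(cfg)
        counts = truth["group"].value_counts()
        for g in ("1", "2", "3", "4", "5", "6"):
            assert counts[g] == 50
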