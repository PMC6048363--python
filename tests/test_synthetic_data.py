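"""Ground-truth simulators: determinism, planted structure, marginals."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from saspkit import synthetic_data as sim
from saspkit.exceptions import CapacityError, ParameterError


class TestScreenSim:
    def test_same_seed_identical_tables(self):
        a, _ = sim.simulate_screen(60, replicate_count=2, seed=9)
        b, _ = sim.simulate_screen(60, replicate_count=2, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            sim.simulate_screen(100, n_plates=1)

    def test_pure_noise_sample_sd_matches_noise_sd(self):
        plates, truth = sim.simulate_screen(
            50 * 88, n_plates=50, replicate_count=1,
            row_artifact_sd=0.0, col_artifact_sd=0.0, noise_sd=1.0, seed=3,
        )
        sample = plates[plates["well_role"] == "sample"]
        sds = sample.groupby("plate_id")["IL8"].std(ddof=1)
        # closed form: per-plate SD concentrates around noise_sd
        assert abs(sds.mean() - 1.0) < 0.1

    def test_strong_inhibitor_is_plate_minimum(self):
        genes = [f"GENE{g:06d}" for g in range(88)]
        effects = pd.DataFrame(0.0, index=genes, columns=list(sim.SCREEN_READOUTS))
        effects.loc["GENE000040", "IL8"] = -4.0
        n_min = 0
        for seed in range(40):
            plates, _ = sim.simulate_screen(
                88, replicate_count=1, effect_table=effects,
                row_artifact_sd=0.0, col_artifact_sd=0.0, seed=seed,
            )
            sample = plates[plates["well_role"] == "sample"]
            n_min += sample.loc[sample["IL8"].idxmin(), "gene_id"] == "GENE000040"
        # closed form: P(target is the minimum of 88 wells) =
        # E[(1-Phi(T))^87], T ~ N(-4,1) = 0.92; 40 trials, 99.9% band >= 31
        assert n_min >= 31

    def test_truth_lists_planted_hits(self):
        genes = [f"GENE{g:06d}" for g in range(30)]
        effects = pd.DataFrame(0.0, index=genes, columns=list(sim.SCREEN_READOUTS))
        effects.loc["GENE000003", ["IL8", "IL6"]] = -4.0
        effects.loc["GENE000007", ["IL8", "IL6"]] = 4.0
        _, truth = sim.simulate_screen(30, effect_table=effects, seed=0)
        assert truth.down_hits == ["GENE000003"]
        assert truth.up_hits == ["GENE000007"]


class TestSpliceSim:
    def test_same_seed_identical_fasta_and_counts(self):
        a = sim.simulate_splicing(n_events=30, seed=4)
        b = sim.simulate_splicing(n_events=30, seed=4)
        assert a[2] == b[2]
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_unchanged_only_has_no_motifs(self):
        _, _, flanks, truth = sim.simulate_splicing(
            n_events=40, class_proportions={"unchanged": 1.0}, seed=2
        )
        assert (truth.events["regulation_class"] == "unchanged").all()
        assert truth.events["motif_offset"].isna().all()

    def test_empirical_delta_psi_concentrates_at_high_coverage(self):
        from saspkit import splicing

        _, junctions, _, truth = sim.simulate_splicing(
            n_events=30, coverage=10**6, delta_psi=0.3, n_replicates=1, seed=8
        )
        recs = splicing.delta_psi_table(junctions, "control", "knockdown")
        merged = recs.merge(truth.events, on="event_id")
        true_delta = merged["psi_knockdown"] - merged["psi_control"]
        assert (merged["delta_psi"] - true_delta).abs().max() < 0.01

    def test_motifs_embedded_in_placement_window(self):
        _, _, flanks, truth = sim.simulate_splicing(n_events=60, seed=6)
        rep = truth.events.dropna(subset=["motif_offset"])
        assert (truth.events["regulation_class"] == "repressed").sum() == len(rep)
        w0, w1 = truth.placement_window
        for _, r in rep.iterrows():
            off = int(r["motif_offset"])
            assert w0 <= off <= w1 - len(truth.motif)
            up = flanks[f"{r['event_id']}|upstream_intron"]
            local = off + 300
            assert up[local:local + len(truth.motif)] == truth.motif

    def test_motif_longer_than_window_rejected(self):
        with pytest.raises(ParameterError):
            sim.simulate_splicing(n_events=5, motif="T" * 50,
                                  placement_window=(-60, -20))

    def test_junction_counts_binomial_marginals(self):
        """inc1 of repeated events matches Binomial(coverage, psi) (KS test)."""
        _, junctions, _, truth = sim.simulate_splicing(
            n_events=400, class_proportions={"unchanged": 1.0},
            coverage=100, n_replicates=5, seed=12,
        )
        ev = truth.events.iloc[0]
        one = junctions[junctions["event_id"] == ev["event_id"]]
        # pooled z-scores over all events/samples should be ~N(0,1)
        merged = junctions.merge(truth.events, on="event_id")
        p = merged["psi_control"]
        z = (merged["inc1"] - 100 * p) / np.sqrt(100 * p * (1 - p))
        assert stats.kstest(z, "norm").pvalue > 0.01


class TestTissueSim:
    def test_same_seed_identical_matrix(self):
        a, pa, _ = sim.simulate_tissue_matrix(n_genes=100, n_samples=40, seed=5)
        b, pb, _ = sim.simulate_tissue_matrix(n_genes=100, n_samples=40, seed=5)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_series_equal(pa, pb)

    def test_regulator_psi_anticorrelated(self):
        counts, psi, truth = sim.simulate_tissue_matrix(
            n_genes=400, n_samples=200, seed=1
        )
        r = np.corrcoef(counts.loc[truth.regulator_gene], psi)[0, 1]
        assert r < -0.5

    def test_empty_enriched_set(self):
        _, _, truth = sim.simulate_tissue_matrix(
            n_genes=100, n_samples=30, enriched_set_size=0, seed=0
        )
        assert len(truth.enriched_set) == 0

    def test_planted_genes_upshifted_in_high_skipping_samples(self):
        counts, _, truth = sim.simulate_tissue_matrix(
            n_genes=300, n_samples=200, seed=3
        )
        high = truth.sample_high_regulator
        sub = counts.loc[truth.enriched_set.genes]
        ratio = sub.loc[:, high].mean(axis=1) / sub.loc[:, ~high].mean(axis=1)
        assert (ratio > 1.5).mean() > 0.9  # ~2-fold planted shift

    def test_nonpositive_library_rejected(self):
        with pytest.raises(ParameterError):
            sim.simulate_tissue_matrix(n_genes=10, n_samples=5,
                                       mean_library_size=0)

    def test_decoy_sets_exclude_planted(self):
        genes = [f"G{i:05d}" for i in range(200)]
        decoys = sim.decoy_gene_sets(genes, exclude=genes[:50], n_sets=10,
                                     size=20, seed=0)
        assert len(decoys) == 10
        for d in decoys:
            assert not set(d.genes) & set(genes[:50])
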