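"""End-to-end orchestration: simulate -> screen -> splice -> rnamap -> gsea
-> tissue, with a shared config, seed fan-out and a run manifest.

Each stage writes its tables under the configured output directory; a
manifest (JSON) records the config snapshot, seeds, per-stage status and
wall-clock, and the files written, so a run can be reproduced and audited.
Stages run in dependency order and a failure stops everything downstream.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cross_tissue, enrichment, plate_stats, rna_map, screen_calls, splicing
from . import synthetic_data as sim
from .io_formats import (
    RunConfig,
    write_counts_tsv,
    write_events_bed,
    write_fasta,
    write_gmt,
    write_plate_table,
    write_results_tsv,
)

log = logging.getLogger("saspkit")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on simulated inputs; returns the manifest dict."""
    config.log_all()
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    _kids = np.random.SeedSequence(seed).spawn(5)
    seed_screen, seed_splice, seed_splice_ref, seed_tissue, seed_gsea = (
        int(k.generate_state(1)[0] % 2**31) for k in _kids
    )

    manifest: dict = {"config": config.values, "seed": seed, "stages": {}}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                files = fn()
                manifest["stages"][name] = {
                    "status": "ok",
                    "wall_s": round(time.perf_counter() - t0, 3),
                    "files": files,
                }
            except Exception as exc:
                manifest["stages"][name] = {
                    "status": f"failed: {exc}",
                    "wall_s": round(time.perf_counter() - t0, 3),
                    "files": [],
                }
                raise
            return fn

        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        sc = config["screen_sim"]
        genes = [f"GENE{g:06d}" for g in range(sc["n_genes"])]
        effects = pd.DataFrame(0.0, index=genes, columns=list(sim.SCREEN_READOUTS))
        # planted hits scattered over the layout, as in a real library
        planted = np.random.default_rng(seed_screen).choice(
            sc["n_genes"], sc["n_down_hits"] + sc["n_up_hits"], replace=False
        )
        effects.iloc[planted[: sc["n_down_hits"]], 0:2] = sc["down_effect"]
        effects.iloc[planted[sc["n_down_hits"]:], 0:2] = sc["up_effect"]
        plates, screen_truth = sim.simulate_screen(
            n_genes=sc["n_genes"], replicate_count=sc["replicate_count"],
            effect_table=effects, row_artifact_sd=sc["row_artifact_sd"],
            col_artifact_sd=sc["col_artifact_sd"], noise_sd=sc["noise_sd"],
            seed=seed_screen,
        )
        sp = config["splice_sim"]
        props = {
            "repressed": sp["prop_repressed"],
            "enhanced": sp["prop_enhanced"],
            "unchanged": 1 - sp["prop_repressed"] - sp["prop_enhanced"],
        }
        events, junctions, flanks, splice_truth = sim.simulate_splicing(
            n_events=sp["n_events"], class_proportions=props,
            coverage=sp["coverage"], delta_psi=sp["delta_psi"],
            flank_len=sp["flank_len"], exon_len=sp["exon_len"],
            n_replicates=sp["n_replicates"],
            seed=seed_splice,
        )
        # an independent contrast (senescence-like) over the same event universe
        _, junctions_ref, _, splice_truth_ref = sim.simulate_splicing(
            n_events=sp["n_events"], class_proportions=props,
            coverage=sp["coverage"], delta_psi=sp["delta_psi"],
            flank_len=sp["flank_len"], exon_len=sp["exon_len"],
            n_replicates=sp["n_replicates"],
            seed=seed_splice_ref,
        )
        ti = config["tissue_sim"]
        counts, psi, tissue_truth = sim.simulate_tissue_matrix(
            n_genes=ti["n_genes"], n_samples=ti["n_samples"],
            enriched_set_size=ti["enriched_set_size"],
            seed=seed_tissue,
        )
        state.update(
            plates=plates, screen_truth=screen_truth, events=events,
            junctions=junctions, flanks=flanks, splice_truth=splice_truth,
            junctions_ref=junctions_ref, counts=counts, psi=psi,
            tissue_truth=tissue_truth,
        )
        write_plate_table(plates, outdir / "plates.csv")
        write_events_bed(events, outdir / "events.tsv")
        write_results_tsv(junctions, outdir / "junctions.tsv")
        write_fasta(flanks, outdir / "flanks.fa")
        write_counts_tsv(counts, outdir / "tissue_counts.tsv")
        psi.to_frame().to_csv(outdir / "tissue_psi.tsv", sep="\t")
        return ["plates.csv", "events.tsv", "junctions.tsv", "flanks.fa",
                "tissue_counts.tsv", "tissue_psi.tsv"]

    @stage("screen")
    def _screen():
        cc = config["screen_calls"]
        plates = state["plates"]
        bsc = plate_stats.b_score_run(plates, ["IL8", "IL6", "p16", "p21", "BrdU"])
        hits = screen_calls.call_primary_hits(
            bsc[bsc["well_role"] == "sample"],
            down_cutoff=cc["down_cutoff"], up_cutoff=cc["up_cutoff"],
            min_replicates=cc["min_replicates"], n_replicates=cc["n_replicates"],
            as_printed=cc["as_printed"],
        )
        npi_long = plate_stats.npi_run(plates, ["IL8", "IL6"])
        sample_npi = npi_long[npi_long["well_role"] == "sample"].rename(
            columns={"sirna_id": "sirna_id"}
        )
        scrambles = {
            r: npi_long[(npi_long["well_role"] == "negative_control")
                        & (npi_long["readout"] == r)]["npi"].to_numpy()
            for r in ("IL8", "IL6")
        }
        per_sirna, per_gene = screen_calls.secondary_validation(
            sample_npi, scrambles, npi_cutoff=cc["npi_cutoff"],
            alpha=cc["alpha"], min_sirnas=1,
        )
        # phenotype triage of the down-hits
        down_genes = hits.loc[hits["direction"] == "down", "gene_id"]
        prof = bsc[(bsc["gene_id"].isin(down_genes))
                   & (bsc["readout"].isin(["p16", "p21", "BrdU"]))]
        profiles = prof.pivot_table(
            index="gene_id", columns=["readout", "replicate"], values="b"
        )
        profiles.columns = [f"{r}_r{rep}" for r, rep in profiles.columns]
        feats = list(profiles.columns)
        clusters = None
        if len(profiles) >= cc["k"]:
            clustered, centroids = screen_calls.kmeans_cluster(
                profiles.reset_index(), feats, k=cc["k"], n_init=cc["n_init"],
                seed=seed,
            )
            roles = screen_calls.label_clusters(
                centroids, feats, reversion_margin=cc["reversion_margin"]
            )
            clustered["cluster_role"] = [roles[i - 1] for i in clustered["cluster_id"]]
            clusters = clustered
        write_results_tsv(bsc, outdir / "bscores.tsv")
        write_results_tsv(hits, outdir / "primary_hits.tsv")
        write_results_tsv(per_sirna, outdir / "secondary_sirna.tsv")
        write_results_tsv(per_gene, outdir / "secondary_genes.tsv")
        files = ["bscores.tsv", "primary_hits.tsv", "secondary_sirna.tsv",
                 "secondary_genes.tsv"]
        if clusters is not None:
            write_results_tsv(clusters, outdir / "phenotype_clusters.tsv")
            files.append("phenotype_clusters.tsv")
        state["hits"] = hits
        return files

    @stage("splice")
    def _splice():
        sc = config["splicing"]
        recs = splicing.delta_psi_table(state["junctions"], "control", "knockdown")
        recs["fdr"] = enrichment.bh_fdr(recs["p"])
        recs = splicing.classify_regulation(
            recs, delta_cutoff=sc["delta_cutoff"], fdr_cutoff=sc["fdr_cutoff"]
        )
        recs_ref = splicing.delta_psi_table(state["junctions_ref"], "control",
                                            "knockdown")
        recs_ref["fdr"] = enrichment.bh_fdr(recs_ref["p"])
        recs_ref = splicing.classify_regulation(
            recs_ref, delta_cutoff=sc["delta_cutoff"], fdr_cutoff=sc["fdr_cutoff"]
        )
        short = splicing.shortlist_events(
            recs, recs_ref, base_cutoff=sc["delta_cutoff"],
            strict_cutoff=sc["strict_cutoff"],
        )
        types = splicing.summarize_event_types(state["events"])
        write_results_tsv(recs, outdir / "delta_psi.tsv")
        write_results_tsv(short, outdir / "shortlist.tsv")
        write_results_tsv(types, outdir / "event_types.tsv")
        state["splice_records"] = recs
        return ["delta_psi.tsv", "shortlist.tsv", "event_types.tsv"]

    @stage("rnamap")
    def _rnamap():
        rc = config["rna_map"]
        spec = rna_map.RegionSpec(
            upstream_flank=rc["upstream_flank"], exon_window=rc["exon_window"],
            downstream_flank=rc["downstream_flank"],
        )
        pwm = rna_map.cu_rich_example_pwm()
        events = state["events"].set_index("event_id", drop=False)
        flanks = state["flanks"]
        anchored_all = []
        for event_id, ev in events.iterrows():
            for region in ("upstream_intron", "exon", "downstream_intron"):
                seq = flanks[f"{event_id}|{region}"]
                occ = rna_map.pwm_scan(seq, pwm, p_threshold=rc["p_threshold"],
                                       sequence_id=f"{event_id}|{region}")
                if occ.empty:
                    continue
                flank_len = config["splice_sim"]["flank_len"]
                g = [rna_map.local_to_genomic(ev, region, s, e, flank_len)
                     for s, e in zip(occ["start"], occ["end"])]
                occ = occ.assign(start=[a for a, _ in g], end=[b for _, b in g])
                anc, _ = rna_map.anchor_occurrences(ev, occ, spec)
                anchored_all.append(anc)
        anchored = (
            pd.concat(anchored_all, ignore_index=True)
            if anchored_all
            else pd.DataFrame(columns=["event_id", "anchor", "offset_start",
                                       "offset_end", "score", "p"])
        )
        groups = dict(zip(state["splice_records"]["event_id"],
                          state["splice_records"]["regulation_class"]))
        result = rna_map.build_rna_map(
            groups, anchored, window=rc["window"], step=rc["step"],
            region_spec=spec, anchor="acceptor",
        )
        windows = rna_map.window_significance(result.windows)
        dens = pd.DataFrame({"offset": result.offsets, **result.densities})
        write_results_tsv(windows, outdir / "rna_map_windows.tsv")
        write_results_tsv(dens, outdir / "rna_map_density.tsv")
        return ["rna_map_windows.tsv", "rna_map_density.tsv"]

    @stage("tissue_gsea")
    def _tissue():
        ct = config["cross_tissue"]
        gs = config["gsea"]
        counts, psi = state["counts"], state["psi"]
        truth = state["tissue_truth"]
        filtered = cross_tissue.cpm_filter(counts, threshold=ct["cpm_threshold"])
        norm = cross_tissue.quantile_normalize(filtered)
        # orient the split by exon skipping: high = low inclusion (PSI)
        dich = cross_tissue.dichotomize_by_density_minimum(
            psi, grid_points=ct["grid_points"]
        ).inverted()
        ranks = cross_tissue.rank_genes_by_t(norm, dich)
        ranked = enrichment.ranked_list(ranks["gene"], ranks["t"])
        decoys = sim.decoy_gene_sets(
            list(norm.index.astype(str)),
            truth.enriched_set.genes + [truth.regulator_gene],
            n_sets=20, size=len(truth.enriched_set), seed=seed,
        )
        sets = [truth.enriched_set] + decoys
        results = enrichment.gsea_preranked_sets(
            ranked, sets, weight_exponent=gs["weight_exponent"],
            n_perm=gs["n_perm"],
            seed=seed_gsea,
        )
        table = enrichment.results_table(results)
        write_gmt(sets, outdir / "gene_sets.gmt")
        write_results_tsv(ranks, outdir / "tissue_ranks.tsv")
        write_results_tsv(table, outdir / "gsea_results.tsv")
        return ["gene_sets.gmt", "tissue_ranks.tsv", "gsea_results.tsv"]

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("pipeline complete: %s", outdir / "manifest.json")
    return manifest
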