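"""End-to-end orchestration of the analysis stages on one dataset.

Stages mirror the analysis narrative: domain assignment, intra/inter
pair similarity with duplicate filtering and rank-sum comparison, the
GESS–function correlation, FSN communities vs random baselines, GGSI /
TAD-GGSI construction with repeated autoencoder link prediction,
neighbour-voting function inference, and long-range region detection.
All randomness derives from the master seed via per-stage seeds.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tadfunc import fsn_community, function_inference, pair_analysis
from tadfunc.genome_model import write_assignment
from tadfunc.ggsi_networks import (
    build_hic_ggsi,
    build_hic_tad_ggsi,
    gene_pair_contacts,
)
from tadfunc.go_similarity import (
    TermSimConfig,
    filter_annotations,
    pairwise_similarity_table,
)
from tadfunc.graph_autoencoder import (
    LinearGraphAutoencoder,
    graph_to_adjacency,
    run_repeats,
)
from tadfunc.longrange_regions import classify_region_pairs, report_similar_pairs
from tadfunc.synthetic_data import SimConfig, SyntheticDataset, derive_seed, simulate

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""


@dataclass
class RunConfig:
    """Thresholds and sizes for one end-to-end run."""

    sim: SimConfig = field(default_factory=SimConfig)
    ontology: str = "BPO"
    fsn_thresholds: tuple[float, ...] = (0.5, 0.7, 1.0)
    fsn_max_genes: int = 120
    max_scored_pairs: int = 300
    sim_threshold_corr: float = 0.2
    contact_min: float = 20.0
    dist_min: int = 1_000_000
    tad_dist_min: int = 100_000
    conf_min: float = 0.6
    strong_min: float = 10.0
    weak_max: float = 0.2
    sim_min: float = 0.5
    longrange_dist_min: int = 3_200_000
    n_repeats: int = 10
    embedding_dim: int = 128
    term_config: TermSimConfig = field(default_factory=TermSimConfig)


def intra_inter_scores(
    data: SyntheticDataset, cfg: RunConfig, kind: str = "tad"
) -> tuple[list[float], list[float]]:
    """Matched intra- vs inter-domain functional similarity samples:
    enumerate intra pairs, filter duplicates on both sets, rebalance to
    equal size (capped), score within the chosen ontology."""
    seed = derive_seed(data.config.seed, f"pairs-{kind}")
    rng = np.random.default_rng(seed)
    intra = pair_analysis.enumerate_intra_pairs(data.partition, kind)
    inter = pair_analysis.sample_inter_pairs(
        data.partition, kind, min(len(intra) * 2, 4000), rng
    )
    intra = pair_analysis.filter_duplicates(intra, data.identity_table)
    inter = pair_analysis.filter_duplicates(inter, data.identity_table)
    intra, inter = pair_analysis.rebalance(intra, inter, rng)
    cap = cfg.max_scored_pairs
    if len(intra) > cap:
        idx = rng.choice(len(intra), size=cap, replace=False)
        intra = [intra[i] for i in sorted(idx)]
        inter = [inter[i] for i in sorted(idx)]
    ann = filter_annotations(data.annotations, data.dag)
    sims_intra = pairwise_similarity_table(
        data.dag, ann, [p.key for p in intra], cfg.ontology, cfg.term_config
    )
    sims_inter = pairwise_similarity_table(
        data.dag, ann, [p.key for p in inter], cfg.ontology, cfg.term_config
    )
    return list(sims_intra.values()), list(sims_inter.values())


def build_networks(data: SyntheticDataset, cfg: RunConfig):
    """HiC-GGSI and HiC-TAD-GGSI from the raw contact matrix."""
    genes = {g.id: g for g in data.genome.genes}
    table = gene_pair_contacts(data.raw_contacts, data.genome.genes)
    ggsi = build_hic_ggsi(table, genes, cfg.contact_min, cfg.dist_min)
    tad_ggsi = build_hic_tad_ggsi(ggsi, data.partition, cfg.tad_dist_min)
    return table, ggsi, tad_ggsi


def run_all(config: RunConfig | None = None, out_dir=None, seed: int | None = None) -> dict:
    """Run every stage; returns a dict of stage summaries and, when
    *out_dir* is given, writes the per-stage TSVs there."""
    cfg = config or RunConfig()
    if seed is not None:
        from dataclasses import replace

        cfg.sim = replace(cfg.sim, seed=seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def stage(name):
        logger.info("stage %s", name)
        return time.time()

    try:
        t0 = stage("simulate")
        data = simulate(cfg.sim)
        if out is not None:
            data.write(out / "inputs")
        results["simulate"] = {"n_genes": len(data.genome.genes),
                               "n_tads": len(data.genome.tads),
                               "seconds": round(time.time() - t0, 2)}

        t0 = stage("domains")
        n_assigned = len(data.partition.assigned_genes())
        if out is not None:
            write_assignment(data.partition, out / "assignment.tsv")
        results["domains"] = {
            "assigned": n_assigned,
            "excluded": len(data.partition.assignment) - n_assigned,
            "gaps": len(data.partition.gaps),
            "dropped_zero_gaps": data.partition.dropped_zero_gaps,
            "seconds": round(time.time() - t0, 2),
        }

        t0 = stage("pairs")
        intra, inter = intra_inter_scores(data, cfg, "tad")
        p, tier = pair_analysis.compare_distributions(intra, inter)
        results["pairs"] = {
            "n_pairs_per_set": len(intra),
            "intra_mean": float(np.mean(intra)),
            "inter_mean": float(np.mean(inter)),
            "wilcoxon_p": p,
            "tier": tier,
            "seconds": round(time.time() - t0, 2),
        }
        if out is not None:
            pd.DataFrame(
                {"intra_sim": intra, "inter_sim": inter}
            ).to_csv(out / "pair_similarities.tsv", sep="\t", index=False)

        t0 = stage("gess")
        ecs = data.expression
        ec_max, ec_min = max(ecs.values()), min(ecs.values())
        ann = filter_annotations(data.annotations, data.dag)
        rng = np.random.default_rng(derive_seed(cfg.sim.seed, "gess"))
        pairs = pair_analysis.sample_baseline_pairs(
            data.partition, min(cfg.max_scored_pairs * 2, 500), rng
        )
        sims = pairwise_similarity_table(
            data.dag, ann, [pr.key for pr in pairs], cfg.ontology, cfg.term_config
        )
        keys = sorted(sims)
        gvals = [
            pair_analysis.gess(ecs[a], ecs[b], ec_max, ec_min) for a, b in keys
        ]
        svals = [sims[k] for k in keys]
        try:
            r, rp = pair_analysis.correlate_scores(svals, gvals, cfg.sim_threshold_corr)
            results["gess"] = {"pearson_r": r, "p": rp, "n": len(keys),
                               "seconds": round(time.time() - t0, 2)}
        except pair_analysis.InsufficientDataError as e:
            results["gess"] = {"error": str(e)}

        t0 = stage("fsn")
        tad_genes = sorted(data.partition.assigned_genes("tad"))[: cfg.fsn_max_genes]
        all_pairs = [
            (a, b) for i, a in enumerate(tad_genes) for b in tad_genes[i + 1:]
        ]
        sim_table = pairwise_similarity_table(
            data.dag, ann, all_pairs, cfg.ontology, cfg.term_config
        )
        fsn_rows = []
        for thr in cfg.fsn_thresholds:
            fsn = fsn_community.build_fsn(sim_table, thr)
            if fsn.number_of_nodes() == 0:
                continue
            comms = [
                c for c in fsn_community.detect_communities(fsn) if c.size >= 2
            ]
            if not comms:
                continue
            rng = np.random.default_rng(derive_seed(cfg.sim.seed, f"fsn-{thr}"))
            rand = fsn_community.random_communities(
                fsn, [c.size for c in comms], rng
            )
            real_ratios = [
                fsn_community.same_tad_ratio(c, data.partition) for c in comms
            ]
            rand_ratios = [
                fsn_community.same_tad_ratio(c, data.partition) for c in rand
            ]
            row = {
                "threshold": thr,
                "n_communities": len(comms),
                "mean_ratio": float(np.mean(real_ratios)),
                "mean_ratio_random": float(np.mean(rand_ratios)),
            }
            if len(real_ratios) >= 2:
                wp, _ = pair_analysis.compare_distributions(real_ratios, rand_ratios)
                row["wilcoxon_p"] = wp
            fsn_rows.append(row)
        results["fsn"] = {"rows": fsn_rows, "seconds": round(time.time() - t0, 2)}
        if out is not None:
            pd.DataFrame(fsn_rows).to_csv(out / "fsn_ratios.tsv", sep="\t", index=False)

        t0 = stage("ggsi")
        table, ggsi, tad_ggsi = build_networks(data, cfg)
        results["ggsi"] = {
            "ggsi_nodes": len(ggsi.nodes), "ggsi_edges": len(ggsi.edges),
            "tad_ggsi_nodes": len(tad_ggsi.nodes),
            "tad_ggsi_edges": len(tad_ggsi.edges),
            "seconds": round(time.time() - t0, 2),
        }
        if out is not None:
            ggsi.to_edgelist(out / "hic_ggsi.tsv")
            tad_ggsi.to_edgelist(out / "hic_tad_ggsi.tsv")

        t0 = stage("gae")
        gae_rows = []
        gae_summary = {}
        for name, net in (("HiC-GGSI", ggsi), ("HiC-TAD-GGSI", tad_ggsi)):
            df, auc_ci, ap_ci = run_repeats(
                net.graph,
                n_repeats=cfg.n_repeats,
                seed=derive_seed(cfg.sim.seed, f"gae-{name}"),
                n_components=cfg.embedding_dim,
            )
            df.insert(0, "network", name)
            gae_rows.append(df)
            gae_summary[name] = {
                "auc_mean": auc_ci.mean, "auc_ci": auc_ci.half_width,
                "ap_mean": ap_ci.mean, "ap_ci": ap_ci.half_width,
            }
        results["gae"] = {**gae_summary, "seconds": round(time.time() - t0, 2)}
        if out is not None:
            pd.concat(gae_rows).to_csv(out / "gae_metrics.tsv", sep="\t", index=False)

        t0 = stage("inference")
        ann_by_gene = {
            g: ann.terms(g, data.dag, cfg.ontology) for g in ann.genes()
        }
        inference = {}
        for name, net in (("HiC-GGSI", ggsi), ("HiC-TAD-GGSI", tad_ggsi)):
            A, nodes = graph_to_adjacency(net.graph)
            model = LinearGraphAutoencoder(
                n_components=cfg.embedding_dim,
                random_state=derive_seed(cfg.sim.seed, f"infer-{name}"),
            ).fit(A)
            recon = function_inference.threshold_reconstruction(
                model.A_hat_, nodes, cfg.conf_min
            )
            union = function_inference.union_network(net, recon)
            scores = {}
            for net_name, target in (
                ("original", net), ("reconstructed", recon), ("union", union)
            ):
                for k in (1, 4):
                    try:
                        scores[f"{net_name}_top{k}"] = function_inference.evaluate_topk(
                            target, ann_by_gene, data.dag, k, cfg.term_config
                        )
                    except ValueError:
                        scores[f"{net_name}_top{k}"] = None
            inference[name] = scores
        results["inference"] = {**inference, "seconds": round(time.time() - t0, 2)}

        t0 = stage("longrange")
        region_pairs = classify_region_pairs(
            data.norm_contacts, cfg.longrange_dist_min, cfg.strong_min, cfg.weak_max
        )
        strong = [rp for rp in region_pairs if rp.label == "strong"]
        report = report_similar_pairs(
            strong, data.genome.genes, data.dag, ann, cfg.ontology,
            cfg.sim_min, cfg.term_config,
        )
        results["longrange"] = {
            "n_strong": len(strong),
            "n_weak": sum(rp.label == "weak" for rp in region_pairs),
            "n_similar": len(report),
            "seconds": round(time.time() - t0, 2),
        }
        if out is not None:
            report.to_csv(out / "longrange_similar.tsv", sep="\t", index=False)
    except StageError:
        raise
    except Exception as exc:  # tag the failing stage
        raise StageError(f"stage failed: {exc}") from exc
    return results
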