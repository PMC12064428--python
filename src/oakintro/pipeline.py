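"""End-to-end orchestration: simulate -> admixture -> classify ->
diversity / barriers / haplotypes / environmental GLM.

Driven by a YAML config with stage toggles; every stage writes its
artifacts plus a manifest recording inputs, parameters, seed and package
version so a rerun with the same config is reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from oakintro import __version__
from oakintro import admixture as adx
from oakintro import classify as clf
from oakintro import diversity as dv
from oakintro import envglm
from oakintro import haplotypes as hap
from oakintro.barriers import bootstrap_support, build_graph, extract_barriers
from oakintro.genotype_io import (
    PopulationTable,
    read_population_table,
    read_structure,
    write_qmatrix,
    write_structure,
)
from oakintro.simulate import PopSpec, SimConfig, simulate_dataset

logger = logging.getLogger("oakintro.pipeline")

STAGES = ("simulate", "admixture", "classify", "diversity", "barriers", "haplotypes", "glm")
TOP_KEYS = {"seed", "out_dir", "stages"} | set(STAGES)


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    unknown = set(config) - TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for stage in config.get("stages", []):
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")


def _sim_config(section: dict, seed: int) -> SimConfig:
    pops = [
        PopSpec(str(p["pop_id"]), str(p.get("region", "all")),
                (float(p["x"]), float(p["y"])), int(p["n"]))
        for p in section.get("pops", [])
    ]
    kwargs = {k: v for k, v in section.items() if k not in ("pops", "lineages")}
    return SimConfig(pops=pops, seed=seed, **kwargs)


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the enabled stages in dependency order; returns artifact map."""
    validate_config(config)
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "oakintro_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(STAGES))
    artifacts: dict[str, str] = {}
    manifest = {
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": {s: config.get(s, {}) for s in stages},
    }

    G = truth = env = pop_table = None

    if "simulate" in stages:
        section = dict(config.get("simulate", {}))
        lineages = section.pop("lineages", None)
        sim = _sim_config(section, seed)
        lineage_map = None
        if lineages:
            lineage_map = {
                str(k): (v["lineage"], tuple(v["founder"])) for k, v in lineages.items()
            }
        G, truth, env = simulate_dataset(sim, lineage_map)
        write_structure(G, out / "genotypes.str")
        pop_rows = pd.DataFrame(
            [
                {"pop_id": p.pop_id, "x": p.coordinate[0], "y": p.coordinate[1],
                 "n": p.n_individuals, "region": p.region}
                for p in sim.pops
            ]
        )
        pop_rows.to_csv(out / "populations.csv", index=False)
        env.to_csv(out / "environment.csv", index=False)
        write_qmatrix(out / "true_q.tsv", G.individual_ids, G.pop_ids, truth.true_q)
        truth.true_introgression.to_csv(out / "truth_introgression.csv", index=False)
        if truth.true_haplotype is not None:
            truth.true_haplotype.to_csv(out / "haplotypes.csv", index=False)
        pop_table = PopulationTable(pop_rows)
        artifacts["genotypes"] = str(out / "genotypes.str")
        logger.info("simulate: %d individuals, %d loci", G.n_individuals, G.n_loci)

    if G is None and any(s in stages for s in STAGES[1:]):
        inputs = config.get("admixture", {})
        gpath = inputs.get("genotypes") or config.get("diversity", {}).get("genotypes")
        if not gpath:
            raise ValueError("no genotypes: enable the simulate stage or point "
                             "a stage at a genotype file")
        G = read_structure(gpath, inputs.get("dialect", "one-row"))
        ppath = config.get("barriers", {}).get("pops")
        if ppath:
            pop_table = read_population_table(ppath)

    runs = None
    if "admixture" in stages:
        sec = config.get("admixture", {})
        K = int(sec.get("K", 3))
        reps = int(sec.get("replicates", 3))
        runs = [
            adx.fit_admixture(
                G, K,
                burnin=int(sec.get("burnin", 500)),
                iters=int(sec.get("iters", 1000)),
                thin=int(sec.get("thin", 10)),
                prior_model=sec.get("prior_model", "independent"),
                locprior_pops=G.pop_ids if sec.get("locprior") else None,
                seed=seed + r,
            )
            for r in range(reps)
        ]
        aligned, _ = adx.align_runs(runs)
        modes = adx.detect_modes(aligned)
        q_mean = modes[0].mean_q
        write_qmatrix(out / "qmatrix.tsv", G.individual_ids, G.pop_ids, q_mean)
        mode_report = {
            "K": K,
            "n_runs": reps,
            "lnP_mean": float(np.mean([r.lnP for r in runs])),
            "n_modes": len(modes),
            "major_mode_similarity": modes[0].similarity,
        }
        with open(out / "mode_report.json", "w") as fh:
            json.dump(mode_report, fh, indent=2)
        artifacts["qmatrix"] = str(out / "qmatrix.tsv")
    elif truth is not None:
        q_mean = truth.true_q  # MCMC bypass: classify on the simulated truth
    else:
        q_mean = None

    assignments = None
    if "classify" in stages:
        if q_mean is None:
            raise ValueError("classify stage needs the admixture or simulate stage upstream")
        sec = config.get("classify", {})
        if truth is not None and "cluster_species" not in sec:
            cmap = {int(k): v for k, v in truth.cluster_species.items()}
        else:
            cmap = {int(k): str(v) for k, v in sec.get("cluster_species", {}).items()}
        focal = sec.get("focal_species", "focal")
        assignments = clf.classify_all(q_mean, cmap, G.individual_ids)
        summary = clf.population_summary(assignments, G.pop_ids, focal)
        taxa = pd.DataFrame(
            {
                "individual_id": [a.individual_id for a in assignments],
                "pop_id": G.pop_ids,
                "category": [a.category for a in assignments],
                "max_species_q": [max(a.species_q.values()) for a in assignments],
            }
        )
        taxa.to_csv(out / "taxa.csv", index=False)
        summary.to_csv(out / "introgression.csv", index=False)
        artifacts["introgression"] = str(out / "introgression.csv")

    if "diversity" in stages:
        sec = config.get("diversity", {})
        groups = sec.get("groups") or {"all": sorted(set(G.pop_ids))}
        g_copies = 2 * int(sec.get("rarefaction_individuals", 8))
        report = dv.diversity_report(G, groups, g_copies)
        report.to_csv(out / "diversity.csv", index=False)
        dv.pairwise_fst_nei(G).to_csv(out / "pairwise_fst.csv")
        artifacts["diversity"] = str(out / "diversity.csv")

    if "barriers" in stages and pop_table is not None:
        sec = config.get("barriers", {})
        D = dv.pairwise_fst_nei(G)
        order = [D.index.get_loc(p) for p in pop_table.pop_ids]
        graph = build_graph(pop_table, D.to_numpy()[np.ix_(order, order)])
        bars = extract_barriers(graph, int(sec.get("n_barriers", 1)))
        support = bootstrap_support(
            G, graph, n_boot=int(sec.get("bootstrap", 100)), seed=seed,
            n_barriers=int(sec.get("n_barriers", 1)),
        )
        records = [
            {
                "barrier": bi,
                "segments": [
                    {"pop_a": graph.pop_ids[i], "pop_b": graph.pop_ids[j], "distance": d}
                    for (i, j), d in zip(b.pairs, b.distances)
                ],
            }
            for bi, b in enumerate(bars)
        ]
        with open(out / "barriers.json", "w") as fh:
            json.dump(records, fh, indent=2)
        support.to_csv(out / "barrier_support.csv", index=False)
        artifacts["barriers"] = str(out / "barriers.json")

    if "haplotypes" in stages:
        sec = config.get("haplotypes", {})
        if truth is not None and truth.true_haplotype is not None:
            hap_in = truth.true_haplotype
        elif sec.get("table"):
            hap_in = pd.read_csv(sec["table"])
        else:
            hap_in = None
        if hap_in is not None:
            called = hap.call_haplotypes(hap_in)
            net = hap.msn(called)
            stats = hap.pons_petit(called)
            called.to_csv(out / "haplotypes_called.csv", index=False)
            edges = pd.DataFrame(
                [{"a": u, "b": v, "weight": d["weight"]} for u, v, d in net.edges(data=True)]
            )
            edges.to_csv(out / "msn_edges.csv", index=False)
            with open(out / "haplotype_stats.json", "w") as fh:
                json.dump(
                    {k: v for k, v in stats.items() if k != "per_population"}, fh, indent=2
                )
            stats["per_population"].to_csv(out / "haplotype_hs.csv")
            artifacts["haplotypes"] = str(out / "haplotypes_called.csv")

    if "glm" in stages:
        sec = config.get("glm", {})
        if env is None and sec.get("env"):
            env = pd.read_csv(sec["env"])
        if env is not None:
            response = sec.get("response", "introgression_index")
            if response not in env.columns and assignments is not None:
                summary = clf.population_summary(assignments, G.pop_ids,
                                                 sec.get("focal_species", "focal"))
                env = env.merge(summary[["pop_id", "introgression_index"]], on="pop_id")
                response = "introgression_index"
            covs = sec.get("covariates") or [
                c for c in env.columns if c.startswith("env")
            ]
            result = envglm.run_env_model(
                env, response, covs,
                r_max=float(sec.get("r_max", 0.7)),
                vif_max=float(sec.get("vif_max", 3.0)),
            )
            coef = pd.DataFrame(
                {
                    "term": result["final"].params.index,
                    "estimate": result["final"].params.values,
                    "se": result["final"].bse.values,
                    "p": result["final"].pvalues.values,
                }
            )
            coef.to_csv(out / "glm_coefficients.csv", index=False)
            with open(out / "glm_report.json", "w") as fh:
                json.dump(
                    {
                        "retained_after_corr": result["retained_after_corr"],
                        "retained_after_vif": result["retained_after_vif"],
                        "selected_terms": result["final"].terms,
                        "aic": result["final"].aic,
                        "generalized_r2": result["generalized_r2"],
                    },
                    fh, indent=2,
                )
            artifacts["glm"] = str(out / "glm_coefficients.csv")

    manifest["artifacts"] = artifacts
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"out_dir": str(out), "artifacts": artifacts, "manifest": manifest}
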