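"""Pipeline orchestration: run the analysis stages in dependency order.

A configuration dictionary (typically loaded from YAML) names the
inputs, the stages to run, their parameters and a global seed.  Each
stage writes its outputs under ``out_dir`` and a manifest records the
package version, seed, parameters and completed stages so a run is
reproducible bit for bit from config + seed.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from . import assembly as asm
from . import diversity as dv
from . import network as net
from . import neutral as nt
from . import simulate as sim
from . import tables as tb
from . import titan as tt
from . import trees as tr
from . import varpart as vp
from .results import write_results

log = logging.getLogger("ecoassembly")

STAGES = (
    "simulate",
    "preprocess",
    "diversity",
    "assembly",
    "neutral",
    "varpart",
    "titan",
    "network",
)

__all__ = ["run_pipeline", "STAGES"]


def _load_inputs(config, ctx):
    inputs = config.get("inputs", {})
    if "otu_table" in inputs:
        ctx["table"] = tb.read_otu_table(
            inputs["otu_table"], orientation=inputs.get("orientation", "samples")
        )
    if "tree" in inputs:
        ctx["tree"] = tr.read_newick(inputs["tree"])
    if "metadata" in inputs:
        ctx["metadata"] = tb.read_metadata(inputs["metadata"])


def _stage_simulate(config, ctx, out):
    p = dict(config.get("simulate", {}))
    p.setdefault("seed", config.get("seed", 0))
    cfg = sim.SimulationConfig(**p)
    tree = sim.simulate_tree(cfg.n_taxa, seed=cfg.seed)
    sites = sim.simulate_sites(
        cfg.n_sites, extent_km=cfg.extent_km, n_env=cfg.n_env,
        spatial_autocorr=cfg.spatial_autocorr, seed=cfg.seed,
    )
    table, truth = sim.simulate_regime(cfg, tree=tree, sites=sites)
    ctx.update(table=table, tree=tree, metadata=sites, truth=truth)
    table.to_tsv(out / "otu_table.tsv")
    tr.write_newick(tree, out / "tree.nwk")
    sites.to_csv(out / "metadata.csv")
    write_results(
        {"regime": truth.regime, "gamma": truth.gamma, "optima": truth.optima},
        out / "truth.json",
    )


def _stage_preprocess(config, ctx, out):
    p = config.get("preprocess", {})
    table = ctx["table"]
    table = tb.filter_min_total_count(table, p.get("min_total", 10))
    depth = p.get("rarefy_depth")
    if depth is None:
        depth = int(table.sample_totals().min())
    table = tb.rarefy(table, depth, seed=config.get("seed", 0))
    if p.get("min_rel") is not None:
        table = tb.filter_rare_relative(table, p["min_rel"])
    table = table.drop_empty_taxa()
    ctx["table"] = table
    table.to_tsv(out / "otu_table_preprocessed.tsv")


def _stage_diversity(config, ctx, out):
    table = ctx["table"]
    alpha = dv.alpha_diversity(table)
    write_results(alpha, out / "alpha_diversity.tsv")
    bc = dv.bray_curtis(table)
    write_results(bc, out / "bray_curtis.tsv")
    ctx["bray_curtis"] = bc
    if "metadata" in ctx and "latitude" in ctx["metadata"]:
        geo = dv.geographic_distance_matrix(ctx["metadata"])
        ctx["geo"] = geo
        ddr = dv.distance_decay(1 - bc, geo, seed=config.get("seed", 0))
        write_results(ddr, out / "distance_decay.json")


def _stage_assembly(config, ctx, out):
    p = config.get("assembly", {})
    table, tree = ctx["table"], ctx["tree"]
    D = tr.cophenetic_matrix(tree)
    n_null = p.get("n_null", 999)
    seed = config.get("seed", 0)
    z, bm, deg = asm.bnti(table, D, n_null=n_null, seed=seed)
    rc = asm.raup_crick_bray(table, n_null=n_null, seed=seed)
    pairs = asm.pair_table(z, bm, rc, deg)
    summary = asm.process_summary(pairs["process"], rc_df=rc)
    write_results(pairs, out / "pair_assembly.tsv")
    write_results(summary, out / "process_summary.json")
    ctx.update(bnti=z, rc=rc, pairs=pairs, process_summary=summary)


def _stage_neutral(config, ctx, out):
    table = ctx["table"]
    fit = nt.fit_sloan(table)
    write_results(fit.per_taxon, out / "sloan_per_taxon.tsv")
    write_results(
        {
            "m": fit.m,
            "N": fit.N,
            "d": fit.d,
            "r_squared": fit.r_squared,
            "aic_neutral": fit.aic_neutral,
            "aic_binomial": fit.aic_binomial,
        },
        out / "sloan_fit.json",
    )
    bcom = nt.community_niche_breadth(table)
    _, disp = nt.dispersal_ability(table)
    write_results(bcom.to_frame(), out / "community_niche_breadth.tsv")
    write_results({"dispersal_ability": disp}, out / "dispersal_ability.json")
    ctx["sloan"] = fit


def _env_variable_names(metadata):
    return [c for c in metadata.columns if c not in ("latitude", "longitude")]


def _stage_varpart(config, ctx, out):
    p = config.get("varpart", {})
    bc = ctx.get("bray_curtis")
    if bc is None:
        bc = dv.bray_curtis(ctx["table"])
    md = ctx["metadata"]
    geo = ctx.get("geo")
    if geo is None:
        geo = dv.geographic_distance_matrix(md)
    env_vars = p.get("env_vars") or _env_variable_names(md)
    half = max(1, len(env_vars) // 2)
    soil_vars = p.get("soil_vars", env_vars[:half])
    climate_vars = p.get("climate_vars", env_vars[half:]) or env_vars[:1]
    basis = vp.pcnm(geo)
    seed = config.get("seed", 0)
    sel_soil = vp.forward_select(bc, md[soil_vars], seed=seed)
    sel_clim = vp.forward_select(bc, md[climate_vars], seed=seed)
    sel_space = vp.forward_select(bc, basis.vectors, seed=seed)
    result = vp.variation_partition(
        bc,
        {
            "soil": md[sel_soil] if sel_soil else md[soil_vars[:0]],
            "climate": md[sel_clim] if sel_clim else md[climate_vars[:0]],
            "space": basis.vectors[sel_space] if sel_space else basis.vectors.iloc[:, :0],
        },
    )
    write_results(result, out / "variation_partition.json")
    fit = vp.nmds_envfit(bc, md, variables=env_vars, seed=seed)
    write_results(fit.coordinates, out / "nmds_coordinates.tsv")
    if fit.envfit is not None and len(fit.envfit):
        write_results(fit.envfit, out / "envfit.tsv")
    ctx.update(varpart=result, ordination=fit)


def _stage_titan(config, ctx, out):
    p = config.get("titan", {})
    md = ctx["metadata"]
    variable = p.get("variable") or _env_variable_names(md)[0]
    gradient = md.loc[ctx["table"].counts.index, variable].to_numpy(dtype=float)
    results = tt.titan_all_taxa(
        ctx["table"],
        gradient,
        n_perm=p.get("n_perm", 250),
        n_boot=p.get("n_boot", 500),
        seed=config.get("seed", 0),
        min_side=p.get("min_side", 5),
    )
    cands = tt.candidate_change_points(gradient, min_side=p.get("min_side", 5))
    comm = tt.community_thresholds(results, cands)
    per_taxon = pd.DataFrame([vars(r) for r in results])
    write_results(per_taxon, out / f"titan_{variable}.tsv")
    write_results(
        pd.DataFrame(
            {
                "candidate": comm.candidates,
                "sum_z_minus": comm.sum_z_minus,
                "sum_z_plus": comm.sum_z_plus,
                "cp_count_minus": comm.cp_counts_minus,
                "cp_count_plus": comm.cp_counts_plus,
            }
        ),
        out / f"titan_{variable}_community.tsv",
    )
    ctx["titan"] = comm


def _stage_network(config, ctx, out):
    p = config.get("network", {})
    table = ctx["table"]
    if p.get("min_rel") is not None:
        table = tb.filter_rare_relative(table, p["min_rel"])
    counts = table.counts
    edges = net.infer_edges(
        counts,
        n_perm=p.get("n_perm", 1000),
        n_boot=p.get("n_boot", 1000),
        seed=config.get("seed", 0),
        candidate_min_abs_rho=p.get("candidate_min_abs_rho", 0.0),
    )
    write_results(edges, out / "edges.tsv")
    rho_min = p.get("rho_min")
    if rho_min is None:
        rho_m, _ = net.pairwise_scores(tb.to_relative_abundance(table))
        try:
            rho_min = net.rmt_threshold(rho_m)
        except ValueError:
            rho_min = 0.74
    graph = net.build_network(
        edges, q_max=p.get("q_max", 0.05), rho_min=rho_min, domain=table.domain
    )
    modules, q = net.fast_greedy_modules(graph)
    nx_attrs = {n: int(m) for n, m in modules.items()}
    import networkx as nx

    nx.set_node_attributes(graph, nx_attrs, "module")
    write_results(graph, out / "network.graphml")
    write_results(graph, out / "network_edges.tsv", format="edge-list")
    write_results(
        {"modularity": q, "rho_min": rho_min, "n_nodes": graph.number_of_nodes(),
         "n_edges": graph.number_of_edges(),
         "modules": {int(m): int((modules == m).sum()) for m in modules.unique()}},
        out / "network_summary.json",
    )
    ctx.update(network=graph, modules=modules, modularity=q)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "diversity": _stage_diversity,
    "assembly": _stage_assembly,
    "neutral": _stage_neutral,
    "varpart": _stage_varpart,
    "titan": _stage_titan,
    "network": _stage_network,
}

_REQUIRES = {
    "preprocess": ("table",),
    "diversity": ("table",),
    "assembly": ("table", "tree"),
    "neutral": ("table",),
    "varpart": ("table", "metadata"),
    "titan": ("table", "metadata"),
    "network": ("table",),
}


def run_pipeline(config: dict) -> dict:
    """Execute the configured stages in dependency order.

    ``config['stages']`` may name any subset of the stages (or
    ``['all']``); inputs may come from files (``config['inputs']``) or
    from the ``simulate`` stage.  Returns the context dictionary with
    all in-memory results.
    """
    out = Path(config.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", ["all"]))
    if stages == ["all"]:
        stages = [s for s in STAGES if s != "simulate" or "simulate" in config or
                  "otu_table" not in config.get("inputs", {})]
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]  # dependency order
    ctx: dict = {}
    _load_inputs(config, ctx)
    manifest = {
        "version": __version__,
        "seed": config.get("seed", 0),
        "config": {k: v for k, v in config.items() if k != "inputs"},
        "stages": [],
    }
    for s in stages:
        missing = [r for r in _REQUIRES.get(s, ()) if r not in ctx]
        if missing:
            raise ValueError(f"stage {s!r} is missing inputs: {missing}")
        t0 = time.time()
        log.info("running stage %s", s)
        _STAGE_FN[s](config, ctx, out)
        manifest["stages"].append({"name": s, "seconds": round(time.time() - t0, 2)})
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    ctx["manifest"] = manifest
    return ctx
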