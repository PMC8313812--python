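"""Config-driven orchestration of the analysis stages.

Every stage is a plain function taking a :class:`PipelineConfig`; the
command-line interface in :mod:`coresponse.cli` is a thin wrapper around
these.  All outputs are TSV/GraphML/Newick/JSON files in the configured
output directory, and every run logs its seed and config hash so networks
are exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diversity as dv
from .metrics import enrich_taxa, find_hubs, summarize
from .network import MEASURES, CoResponseNetwork, NetworkConfig, build_network
from .ratios import compute_ratios
from .synthetic import ModuleSpec, generate_study
from .tables import (OtuTable, SampleDesign, TaxonomyMap, filter_prevalence,
                     read_design, read_otu_table, read_taxonomy, to_relative,
                     write_design, write_otu_table, write_taxonomy)

log = logging.getLogger("coresponse")

__all__ = ["PipelineConfig", "default_config", "run_stage", "STAGES"]


DEFAULTS: dict = {
    "seed": None,
    "paths": {
        "otu_table": "table.tsv",
        "taxonomy": "taxonomy.tsv",
        "design": "design.tsv",
        "output_dir": "coresponse_out",
    },
    "compartments": ["BS", "SRz", "TRz"],
    "simulate": {
        "n_bacteria": 120, "n_fungi": 30, "n_reps": 3,
        "zero_rate": 0.3, "modules": [[6, 1, 0.95], [6, -1, 0.95]],
    },
    "prevalence": {"community_min_present": 2, "network_min_present": 4},
    # networks use relative abundances computed on the full table, then
    # restricted to the prevalence-filtered OTUs (configurable)
    "relative_before_filter": True,
    "zero_replacement": 1.0,
    "ratio_scale": "relative",  # "relative" or "counts"
    "rarefaction": {"increment": 1000, "iterations": 10, "max_depth": None,
                    "shannon_base": 2},
    "diversity_rank": "phylum",
    "network": {
        "measures": list(MEASURES), "n_perm": 1000, "n_boot": 1000,
        "p_method": "perm_z", "merge_method": "brown", "min_support": 2,
        "alpha_edge": 0.05, "prefilter_quantile": None, "renormalize": False,
    },
    "enrichment": {"rank": "phylum", "alpha": 0.01},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


@dataclass
class PipelineConfig:
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raw = _merge(DEFAULTS, self.raw)
        if self.raw.get("seed") is None:
            raise ValueError("config error: 'seed' is mandatory")
        if self.raw["ratio_scale"] not in ("relative", "counts"):
            raise ValueError("ratio_scale must be 'relative' or 'counts'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.raw, sort_keys=False))

    # convenience accessors -------------------------------------------------
    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    def path(self, key: str) -> Path:
        return Path(self.raw["paths"][key])

    @property
    def outdir(self) -> Path:
        out = self.path("output_dir")
        out.mkdir(parents=True, exist_ok=True)
        return out

    def network_config(self) -> NetworkConfig:
        n = self.raw["network"]
        return NetworkConfig(
            seed=self.seed, measures=tuple(n["measures"]),
            n_perm=int(n["n_perm"]), n_boot=int(n["n_boot"]),
            p_method=n["p_method"], merge_method=n["merge_method"],
            min_support=int(n["min_support"]), alpha_edge=float(n["alpha_edge"]),
            prefilter_quantile=n["prefilter_quantile"],
            renormalize=bool(n["renormalize"]),
        )

    def validate_inputs(self) -> None:
        """Check referenced input files exist before any compute."""
        for key in ("otu_table", "taxonomy", "design"):
            p = self.path(key)
            if not p.exists():
                raise FileNotFoundError(f"config error: missing {key} file {p}")


def default_config(seed: int = 1) -> PipelineConfig:
    return PipelineConfig({"seed": seed})


def _load_inputs(cfg: PipelineConfig) -> tuple[OtuTable, TaxonomyMap, SampleDesign]:
    cfg.validate_inputs()
    table = read_otu_table(cfg.path("otu_table"))
    taxonomy = read_taxonomy(cfg.path("taxonomy"))
    design = read_design(cfg.path("design"))
    return table, taxonomy, design


def _network_ratios(cfg: PipelineConfig, table, design, compartment):
    """Relative (or raw-count) ratios restricted to 4-of-6-prevalent OTUs."""
    if cfg.raw["ratio_scale"] == "counts":
        source = table
    elif cfg.raw["relative_before_filter"]:
        source = to_relative(table)
    else:  # normalize within the compartment's samples only
        source = to_relative(table.subset_samples(design.samples(compartment)))
    filtered = filter_prevalence(
        source, design, group_by="compartment",
        min_present=int(cfg.raw["prevalence"]["network_min_present"]),
        compartment=compartment,
    )[compartment]
    return compute_ratios(filtered, design, compartment,
                          zero_replacement=float(cfg.raw["zero_replacement"]))


def _build_networks(cfg: PipelineConfig) -> dict[str, CoResponseNetwork]:
    table, taxonomy, design = _load_inputs(cfg)
    ncfg = cfg.network_config()
    nets = {}
    for comp in cfg.raw["compartments"]:
        ratios = _network_ratios(cfg, table, design, comp)
        net = build_network(ratios, taxonomy, ncfg)
        log.info("network: %s %d nodes, %d edges (of %d pairs tested; config %s)",
                 comp, net.graph.number_of_nodes(), len(net.edges),
                 net.n_pairs_tested, ncfg.hash())
        nets[comp] = net
    return nets


# ---------------------------------------------------------------------------
# Stages


def stage_simulate(cfg: PipelineConfig) -> None:
    sim = cfg.raw["simulate"]
    modules = [ModuleSpec(*m) for m in sim["modules"]]
    table, taxonomy, design, truths = generate_study(
        compartments=tuple(cfg.raw["compartments"]), seed=cfg.seed,
        n_bacteria=int(sim["n_bacteria"]), n_fungi=int(sim["n_fungi"]),
        n_reps=int(sim["n_reps"]), module_spec=modules,
        zero_rate=float(sim["zero_rate"]),
    )
    write_otu_table(table, cfg.path("otu_table"))
    write_taxonomy(taxonomy, cfg.path("taxonomy"))
    write_design(design, cfg.path("design"))
    for comp, truth in truths.items():
        truth.to_json(cfg.outdir / f"truth_{comp}.json")
    log.info("simulate: %d OTUs x %d samples (seed %d)", *table.shape, cfg.seed)


def stage_filter(cfg: PipelineConfig) -> None:
    table, _, design = _load_inputs(cfg)
    community = filter_prevalence(
        table, design, group_by="compartment_treatment",
        min_present=int(cfg.raw["prevalence"]["community_min_present"]),
    )
    for comp, sub in community.items():
        write_otu_table(sub, cfg.outdir / f"community_{comp}.tsv")
        log.info("filter: %s community %d OTUs", comp, sub.shape[0])
    network = filter_prevalence(
        table, design, group_by="compartment",
        min_present=int(cfg.raw["prevalence"]["network_min_present"]),
    )
    for comp, sub in network.items():
        write_otu_table(sub, cfg.outdir / f"network_input_{comp}.tsv")
        log.info("filter: %s network input %d OTUs", comp, sub.shape[0])


def stage_diversity(cfg: PipelineConfig) -> None:
    table, taxonomy, design = _load_inputs(cfg)
    r = cfg.raw["rarefaction"]
    series = dv.rarefaction_series(
        table, increment=int(r["increment"]), iterations=int(r["iterations"]),
        max_depth=r["max_depth"] and int(r["max_depth"]), seed=cfg.seed,
        shannon_base=float(r["shannon_base"]),
    )
    series.to_tsv(cfg.outdir / "rarefaction.tsv")
    for metric in ("richness", "shannon"):
        cmp_res = dv.compare_alpha(series, design, metric=metric)
        cmp_res.dunn.assign(
            kruskal_h=cmp_res.kruskal_h, kruskal_p=cmp_res.kruskal_p,
            letters_a=[cmp_res.letters[g] for g in cmp_res.dunn["group_a"]],
            letters_b=[cmp_res.letters[g] for g in cmp_res.dunn["group_b"]],
        ).to_csv(cfg.outdir / f"alpha_{metric}.tsv", sep="\t", index=False)
    rank = cfg.raw["diversity_rank"]
    agg = dv.aggregate_to_rank(to_relative(table), taxonomy, rank)
    dm = dv.bray_curtis(agg)
    dm.to_tsv(cfg.outdir / f"braycurtis_{rank}.tsv")
    ord_res = dv.pcoa(dm)
    ord_res.coordinates.to_csv(cfg.outdir / f"pcoa_{rank}.tsv", sep="\t")
    (cfg.outdir / f"upgma_{rank}.nwk").write_text(dv.upgma(dm) + "\n")
    rel = to_relative(table)
    for comp in cfg.raw["compartments"]:
        diff = dv.differential_taxa(rel, design, comp)
        diff.to_csv(cfg.outdir / f"differential_{comp}.tsv", sep="\t", index=False)
    log.info("diversity: standardized depth %d", series.max_depth)


def stage_ratios(cfg: PipelineConfig) -> None:
    table, _, design = _load_inputs(cfg)
    for comp in cfg.raw["compartments"]:
        ratios = _network_ratios(cfg, table, design, comp)
        ratios.to_tsv(cfg.outdir / f"ratios_{comp}.tsv")
        log.info("ratios: %s %d OTUs x %d pairs (zero_replacement=%g; pair order %s)",
                 comp, *ratios.values().shape, ratios.zero_replacement,
                 " ".join(ratios.pair_labels[:3]) + " ...")


def stage_network(cfg: PipelineConfig,
                  nets: dict[str, CoResponseNetwork] | None = None) -> None:
    nets = nets if nets is not None else _build_networks(cfg)
    for comp, net in nets.items():
        net.write_edge_list(cfg.outdir / f"edges_{comp}.tsv")
        net.write_graphml(cfg.outdir / f"network_{comp}.graphml")


def stage_summarize(cfg: PipelineConfig,
                    nets: dict[str, CoResponseNetwork] | None = None) -> None:
    _, taxonomy, _ = _load_inputs(cfg)
    nets = nets if nets is not None else _build_networks(cfg)
    for comp, net in nets.items():
        summary = summarize(net, taxonomy)
        series = summary.as_series()
        series.index.name = "Parameter"
        series.to_frame(comp).to_csv(cfg.outdir / f"summary_{comp}.tsv", sep="\t")
        if net.graph.number_of_nodes():
            hubs = find_hubs(net)
            degrees = dict(net.graph.degree())
            pd.DataFrame([(h, degrees[h]) for h in hubs.hubs],
                         columns=["otu_id", "degree"]).to_csv(
                cfg.outdir / f"hubs_{comp}.tsv", sep="\t", index=False)
        log.info("summarize: %s components=%d nodes=%d edges=%d",
                 comp, summary.n_components, summary.n_nodes, summary.n_edges)


def stage_enrich(cfg: PipelineConfig,
                 nets: dict[str, CoResponseNetwork] | None = None) -> None:
    table, taxonomy, design = _load_inputs(cfg)
    nets = nets if nets is not None else _build_networks(cfg)
    e = cfg.raw["enrichment"]
    for comp, net in nets.items():
        filtered = filter_prevalence(
            table, design, group_by="compartment",
            min_present=int(cfg.raw["prevalence"]["network_min_present"]),
            compartment=comp,
        )[comp]
        results = enrich_taxa(net, filtered, taxonomy,
                              rank=e["rank"], alpha=float(e["alpha"]))
        pd.DataFrame([r.__dict__ for r in results]).to_csv(
            cfg.outdir / f"enrichment_{comp}.tsv", sep="\t", index=False)
        log.info("enrich: %s %d taxa, %d enriched", comp, len(results),
                 sum(r.enriched for r in results))


STAGES = {
    "simulate": stage_simulate,
    "filter": stage_filter,
    "diversity": stage_diversity,
    "ratios": stage_ratios,
    "network": stage_network,
    "summarize": stage_summarize,
    "enrich": stage_enrich,
}


def run_stage(name: str, cfg: PipelineConfig) -> None:
    if name == "all":
        stage_simulate(cfg)
        stage_filter(cfg)
        stage_diversity(cfg)
        stage_ratios(cfg)
        nets = _build_networks(cfg)  # built once, reused by three stages
        stage_network(cfg, nets)
        stage_summarize(cfg, nets)
        stage_enrich(cfg, nets)
        return
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; expected one of {list(STAGES)} or 'all'")
    STAGES[name](cfg)
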