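"""Seeded synthetic pathway graphs and three-omics datasets.

The generator emulates the structure of level-3 tumor/normal multi-omics
exports: RPKM-like continuous expression (log-normal background),
methylation beta-values in (0, 1) (logit-normal latent), and sparse
GISTIC2-style integer copy-number calls.  A connected gene module with
induced diameter <= 3 is planted on the first pathway graph and carries a
layer-specific standardized mean shift between tumor and normal samples,
so every pipeline stage is exercisable without any data download.

Copy-number signal is simulated as a call-linked expression shift, because
the method's p_cnv is an expression contrast between call groups.
Methylation signal is applied on the logit-latent scale so beta-values
stay strictly inside (0, 1).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import IcdsError
from .omics_io import OmicsLayer, SampleDesign, write_design, write_matrix
from .pathway_io import PathwayGraph, PathwayGraphSet, induced_diameter, write_edgelist

TOPOLOGIES = ("scale-free", "small-world", "grid", "chain")
ALL_LAYERS = ("expression", "methylation", "cnv")

# fixed shape constants of the background model
_EXPR_LOG_MEAN_RANGE = (1.0, 3.0)   # per-gene log-RPKM location, uniform
_EXPR_LOG_SD = 0.5                  # log-scale noise sd (scaled by noise_sd)
_METHY_BASE_RANGE = (0.2, 0.8)      # per-gene baseline beta, uniform
_METHY_LATENT_SD = 0.4              # logit-latent noise sd (scaled by noise_sd)
_CNV_CALL_PROBS = {-2: 0.1, -1: 0.4, 1: 0.4, 2: 0.1}     # background calls
_CNV_EVENT_PROBS = {1: 0.7, 2: 0.3}                      # planted tumor events


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic dataset."""

    n_pathways: int = 1
    genes_per_pathway: int = 100
    topology: str = "scale-free"
    n_tumor: int = 50
    n_normal: int = 50
    planted_module_size: int = 10
    effect_layers: tuple[str, ...] = ALL_LAYERS  # layers carrying signal per planted gene
    effect_size: float = 1.5                     # standardized mean difference
    cnv_event_rate: float = 0.3                  # tumor samples carrying a planted call
    background_cnv_rate: float = 0.25            # GISTIC2-like call density off-module
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.topology not in TOPOLOGIES:
            raise IcdsError(f"unknown topology {self.topology!r}; expected one of {TOPOLOGIES}")
        if self.planted_module_size > self.genes_per_pathway:
            raise IcdsError("planted_module_size exceeds genes_per_pathway")
        if self.effect_size < 0:
            raise IcdsError("effect_size must be >= 0")
        for name in ("cnv_event_rate", "background_cnv_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise IcdsError(f"{name} must lie in [0, 1]")
        bad = set(self.effect_layers) - set(ALL_LAYERS)
        if bad:
            raise IcdsError(f"unknown effect layers {sorted(bad)}")


@dataclass
class SyntheticDataset:
    """A generated dataset bundled with its ground truth."""

    expression: OmicsLayer
    methylation: OmicsLayer
    cnv: OmicsLayer
    design: SampleDesign
    graphs: PathwayGraphSet
    planted_genes: tuple[str, ...]
    effect_layers_by_gene: dict[str, tuple[str, ...]]


def _derived_seed(seed: int, *keys) -> list[int]:
    return [int(seed) & 0x7FFFFFFF] + [zlib.crc32(str(k).encode()) for k in keys]


def _topology_graph(spec: SimulationSpec, index: int) -> nx.Graph:
    n = spec.genes_per_pathway
    seed = int(np.random.SeedSequence(
        _derived_seed(spec.rng_seed, "graph", index)).generate_state(1)[0] & 0x7FFFFFFF)
    if spec.topology == "scale-free":
        return nx.barabasi_albert_graph(n, m=min(2, n - 1), seed=seed)
    if spec.topology == "small-world":
        return nx.connected_watts_strogatz_graph(n, k=min(4, n - 1), p=0.1, seed=seed)
    if spec.topology == "grid":
        side = int(np.ceil(np.sqrt(n)))
        g = nx.grid_2d_graph(side, side)
        nodes = sorted(g.nodes)[:n]
        g = g.subgraph(nodes).copy()
        return nx.convert_node_labels_to_integers(g, ordering="sorted")
    return nx.path_graph(n)


def generate_graphs(spec: SimulationSpec) -> PathwayGraphSet:
    """Seeded random pathway graphs of the requested topology.

    The planted module (see :func:`select_planted_module`) is guaranteed to
    exist on the first pathway; generation fails if no connected subgraph
    of the requested size with induced diameter <= 3 can be found there.
    """
    graphs = PathwayGraphSet()
    for p in range(1, spec.n_pathways + 1):
        g = _topology_graph(spec, p)
        mapping = {i: f"P{p:02d}G{i:03d}" for i in g.nodes}
        pg = PathwayGraph(f"path:s{p:02d}", f"synthetic pathway {p}",
                          nx.relabel_nodes(g, mapping))
        graphs.add(pg)
    select_planted_module(next(iter(graphs)), spec.planted_module_size)  # fail early
    return graphs


def select_planted_module(graph: PathwayGraph, size: int) -> tuple[str, ...]:
    """Deterministic connected subgraph of ``size`` genes, induced diameter <= 3.

    Grows greedily from high-degree start nodes, adding at each step the
    highest-degree neighbor that keeps the induced diameter within 3.
    """
    if size < 1:
        raise IcdsError("module size must be >= 1")
    deg = dict(graph.graph.degree())
    order = sorted(graph.graph.nodes, key=lambda v: (-deg[v], v))
    for start in order:
        module = {start}
        while len(module) < size:
            frontier = set()
            for v in module:
                frontier |= set(graph.graph.neighbors(v))
            frontier -= module
            added = False
            for cand in sorted(frontier, key=lambda v: (-deg[v], v)):
                if induced_diameter(graph, module | {cand}) <= 3:
                    module.add(cand)
                    added = True
                    break
            if not added:
                break
        if len(module) == size:
            return tuple(sorted(module))
    raise IcdsError(
        f"{graph.pathway_id}: no connected subgraph of {size} genes with "
        "induced diameter <= 3; reduce the module size or change topology"
    )


def _sample_design(spec: SimulationSpec) -> SampleDesign:
    if min(spec.n_tumor, spec.n_normal) < 3:
        raise IcdsError("need at least 3 samples per group for two-group tests")
    tumor = [f"T{i:03d}" for i in range(1, spec.n_tumor + 1)]
    normal = [f"N{i:03d}" for i in range(1, spec.n_normal + 1)]
    return SampleDesign(tuple(tumor + normal),
                        tuple(["tumor"] * spec.n_tumor + ["normal"] * spec.n_normal))


def generate_omics(spec: SimulationSpec, graphs: PathwayGraphSet,
                   effect_layers_by_gene: dict[str, tuple[str, ...]] | None = None,
                   ) -> tuple[OmicsLayer, OmicsLayer, OmicsLayer, SampleDesign]:
    """Three omics layers plus the design, with the planted signal applied.

    By default every planted-module gene carries ``spec.effect_layers``;
    an explicit per-gene layout overrides this (used by the complementary
    fixture).
    """
    rng = np.random.default_rng(_derived_seed(spec.rng_seed, "omics"))
    design = _sample_design(spec)
    genes: list[str] = []
    for pg in graphs:
        genes.extend(sorted(pg.nodes))
    n_genes, n_samples = len(genes), len(design.samples)
    tumor_mask = np.array([g == "tumor" for g in design.groups])

    if effect_layers_by_gene is None:
        planted = select_planted_module(next(iter(graphs)), spec.planted_module_size)
        effect_layers_by_gene = {g: tuple(spec.effect_layers) for g in planted}
    gene_pos = {g: i for i, g in enumerate(genes)}
    eff = spec.effect_size

    # expression: log-normal background; planted shift on the raw scale
    log_mu = rng.uniform(*_EXPR_LOG_MEAN_RANGE, size=n_genes)
    sigma = _EXPR_LOG_SD * spec.noise_sd
    expr = np.exp(log_mu[:, None] + sigma * rng.standard_normal((n_genes, n_samples)))
    raw_sd = np.exp(log_mu + sigma ** 2 / 2.0) * np.sqrt(np.expm1(sigma ** 2))
    for g, layers in effect_layers_by_gene.items():
        if "expression" in layers:
            i = gene_pos[g]
            expr[i, tumor_mask] += eff * raw_sd[i]

    # methylation: logit-normal; planted shift on the latent scale
    base = rng.uniform(*_METHY_BASE_RANGE, size=n_genes)
    latent_sd = _METHY_LATENT_SD * spec.noise_sd
    latent = (np.log(base / (1.0 - base))[:, None]
              + latent_sd * rng.standard_normal((n_genes, n_samples)))
    for g, layers in effect_layers_by_gene.items():
        if "methylation" in layers:
            latent[gene_pos[g], tumor_mask] += eff * latent_sd
    methy = 1.0 / (1.0 + np.exp(-latent))

    # cnv: sparse background calls; planted tumor events with linked expression shift
    calls = np.zeros((n_genes, n_samples))
    bg = rng.random((n_genes, n_samples)) < spec.background_cnv_rate
    bg_values = rng.choice(list(_CNV_CALL_PROBS), size=(n_genes, n_samples),
                           p=list(_CNV_CALL_PROBS.values()))
    calls[bg] = bg_values[bg]
    for g, layers in effect_layers_by_gene.items():
        if "cnv" in layers:
            i = gene_pos[g]
            event = tumor_mask & (rng.random(n_samples) < spec.cnv_event_rate)
            values = rng.choice(list(_CNV_EVENT_PROBS), size=n_samples,
                                p=list(_CNV_EVENT_PROBS.values()))
            calls[i, event] = values[event]
            expr[i, calls[i] != 0] += eff * raw_sd[i]

    index = pd.Index(genes, name="gene")
    cols = list(design.samples)
    return (
        OmicsLayer(pd.DataFrame(expr, index=index, columns=cols), "expression"),
        OmicsLayer(pd.DataFrame(methy, index=index, columns=cols), "methylation"),
        OmicsLayer(pd.DataFrame(calls, index=index, columns=cols), "cnv"),
        design,
    )


def simulate(spec: SimulationSpec = SimulationSpec()) -> SyntheticDataset:
    """Generate graphs and omics for one dataset, bundled with ground truth."""
    graphs = generate_graphs(spec)
    planted = select_planted_module(next(iter(graphs)), spec.planted_module_size)
    layout = {g: tuple(spec.effect_layers) for g in planted}
    expr, methy, cnv, design = generate_omics(spec, graphs, layout)
    return SyntheticDataset(expr, methy, cnv, design, graphs, planted, layout)


def make_complementary_fixture(spec: SimulationSpec = SimulationSpec()) -> SyntheticDataset:
    """Dataset whose planted module splits into an expression-only half and a
    methylation-only half.

    Single-layer pipeline modes can see at most their own half of the
    module's signal; integrating the layers is required to recover the
    whole module.  Requires an even module size.
    """
    if spec.planted_module_size % 2:
        raise IcdsError("complementary fixture requires an even planted_module_size")
    graphs = generate_graphs(spec)
    planted = select_planted_module(next(iter(graphs)), spec.planted_module_size)
    layout = {g: (("expression",) if i % 2 == 0 else ("methylation",))
              for i, g in enumerate(sorted(planted))}
    expr, methy, cnv, design = generate_omics(spec, graphs, layout)
    return SyntheticDataset(expr, methy, cnv, design, graphs, planted, layout)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Materialize the TSV fixture suite in the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "methylation": outdir / "methylation.tsv",
        "cnv": outdir / "cnv.tsv",
        "design": outdir / "design.tsv",
        "pathways": outdir / "pathways.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_matrix(ds.expression, paths["expression"])
    write_matrix(ds.methylation, paths["methylation"])
    write_matrix(ds.cnv, paths["cnv"])
    write_design(ds.design, paths["design"])
    write_edgelist(ds.graphs, paths["pathways"])
    with open(paths["truth"], "w") as fh:
        fh.write("gene\teffect_layers\n")
        for g in ds.planted_genes:
            fh.write(f"{g}\t{','.join(ds.effect_layers_by_gene.get(g, ()))}\n")
    return paths
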