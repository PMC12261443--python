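"""Self-contained synthetic fixtures for every stage of the pipeline.

The generator emulates the study conditions end to end: a physical PPI
graph in which the true regulators of a target gene form a planted
proximal set (a clique by default), expression obeying the linear model
``y = X beta* + eps`` with i.i.d. standard-normal TF columns, an optional
decoy TF whose expression is correlated with y but which sits far from the
true regulators in the network, and toy peak / motif-hit / promoter-link
tables consistent with the planted structure. It deliberately does not
mimic single-cell count distributions (dropout, overdispersion); it
targets the model's assumptions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from grip.core import RegulationProblem
from grip.evaluate import PCHiCLinkSet
from grip.genomic import GeneAnnotation, GenomicRegion
from grip.ppi import PPINetwork, dsd_matrix, distance_submatrix

TG_NAME = "TG1"
DECOY_NAME = "DECOY"


@dataclass
class DecoySpec:
    """A TF correlated with y but distant from the true regulators."""

    enabled: bool = True
    correlation: float = 0.9
    network_distance: int = 4


@dataclass
class SyntheticSpec:
    """Study conditions for one planted inference instance.

    Defaults: 30 candidate TFs, 200 cells, 3 true regulators forming a
    clique, noise sd 0.5, Erdős–Rényi background graph with edge
    probability 0.15. The true effect sizes default to one dominant
    regulator, one moderate, and weaker co-regulators (1.2, 0.8, 0.3, then
    geometrically decaying) — a regulon profile in which the decoy's
    expression advantage is real but bounded, so proximity information is
    genuinely informative rather than redundant with expression.
    """

    n_tfs: int = 30
    m_cells: int = 200
    k_true: int = 3
    graph_model: str = "erdos_renyi"
    graph_params: dict = field(default_factory=lambda: {"p": 0.15})
    beta_star: np.ndarray | None = None
    noise_sd: float = 0.5
    decoy: DecoySpec = field(default_factory=DecoySpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true > self.n_tfs:
            raise ValueError("k_true must be <= n_tfs")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if isinstance(self.decoy, dict):
            self.decoy = DecoySpec(**self.decoy)
        if self.beta_star is None:
            base = [1.2, 0.8, 0.3]
            while len(base) < self.k_true:
                base.append(base[-1] * 0.7)
            self.beta_star = np.array(base[: self.k_true])
        else:
            self.beta_star = np.asarray(self.beta_star, dtype=float)
            if self.beta_star.size != self.k_true or np.any(self.beta_star == 0):
                raise ValueError("beta_star must have k_true nonzero entries")
        if self.decoy.enabled and not abs(self.decoy.correlation) < 1.0:
            raise ValueError("decoy correlation must satisfy |r| < 1")


@dataclass
class SyntheticInstance:
    """A planted problem with full ground truth and toy genomic tables."""

    problem: RegulationProblem
    true_support: tuple[int, ...]
    network: PPINetwork
    expression: pd.DataFrame
    gene: GeneAnnotation
    peaks: list[GenomicRegion]
    motif_hits: pd.DataFrame
    links: PCHiCLinkSet
    spec: SyntheticSpec

    @property
    def true_tfs(self) -> list[str]:
        return [self.problem.tf_ids[i] for i in self.true_support]

    @property
    def decoy_index(self) -> int | None:
        ids = self.problem.tf_ids
        return ids.index(DECOY_NAME) if DECOY_NAME in ids else None


def _tf_names(n: int, with_decoy: bool) -> list[str]:
    names = [f"TF{i + 1:03d}" for i in range(n - int(with_decoy))]
    if with_decoy:
        names.append(DECOY_NAME)
    return names


def _background_graph(model: str, names: Sequence[str], params: dict,
                      rng: np.random.Generator) -> nx.Graph:
    n = len(names)
    seed = int(rng.integers(2 ** 31))
    if model == "erdos_renyi":
        g = nx.gnp_random_graph(n, params.get("p", 0.15), seed=seed)
    elif model == "barabasi_albert":
        g = nx.barabasi_albert_graph(n, params.get("m", 2), seed=seed)
    elif model == "geometric":
        g = nx.random_geometric_graph(n, params.get("radius", 0.3), seed=seed)
    else:
        raise ValueError(f"unknown graph_model {model!r}")
    return nx.relabel_nodes(g, dict(enumerate(names)))


def generate_network(spec: SyntheticSpec, max_retries: int = 200
                     ) -> tuple[PPINetwork, list[str], list[str]]:
    """Background graph with a planted regulator clique and a distant decoy.

    Returns ``(network, tf_names, true_tf_names)``. The true TFs are made
    mutually adjacent (clique). When a decoy is requested it is connected
    to the rest of the graph only through a chain of bridge proteins, which
    guarantees its hop distance to every true TF is at least the spec's
    ``network_distance``; bridge proteins are network nodes but not TF
    candidates. Regeneration (bounded retries) handles disconnected draws.
    """
    rng = np.random.default_rng(spec.seed)
    names = _tf_names(spec.n_tfs, spec.decoy.enabled)
    core = [nm for nm in names if nm != DECOY_NAME]

    for _ in range(max_retries):
        g = _background_graph(spec.graph_model, core, spec.graph_params, rng)
        true_tfs = [core[i] for i in
                    sorted(rng.choice(len(core), spec.k_true, replace=False))]
        for i, a in enumerate(true_tfs):
            for b in true_tfs[i + 1:]:
                g.add_edge(a, b)
        if not nx.is_connected(g):
            continue
        if spec.decoy.enabled:
            non_true = [nm for nm in core if nm not in true_tfs]
            anchor = non_true[int(rng.integers(len(non_true)))]
            n_bridge = max(0, spec.decoy.network_distance - 2)
            chain = [DECOY_NAME] + [f"BRIDGE{i + 1}" for i in range(n_bridge)]
            chain.append(anchor)
            for a, b in zip(chain[:-1], chain[1:]):
                g.add_edge(a, b)
            dists = nx.single_source_shortest_path_length(g, DECOY_NAME)
            if min(dists[t] for t in true_tfs) < spec.decoy.network_distance:
                continue
        nx.set_edge_attributes(g, "physical", "interaction_type")
        return PPINetwork(graph=g), names, true_tfs
    raise RuntimeError("could not generate a connected planted network")


def generate_instance(spec: SyntheticSpec, n_dsd_steps: int = 7
                      ) -> SyntheticInstance:
    """Draw a complete planted instance under the spec's conditions.

    Expression: TF columns are i.i.d. standard normal (then standardized);
    ``y = X_true beta* + eps`` with ``eps ~ N(0, noise_sd^2)``, centered.
    The decoy column is rebuilt as
    ``r * (y/||y||) * ||z|| + sqrt(1 - r^2) * z`` with z standard normal,
    giving correlation ~r with y while carrying no causal effect. The toy
    genomic tables give every TF one distal peak with a motif hit in it;
    the promoter-interaction links cover exactly the true TFs' peaks, so a
    perfect top-k call scores F1 = 1.
    """
    net, names, true_tfs = generate_network(spec)
    rng = np.random.default_rng(spec.seed + 1)
    m, n = spec.m_cells, spec.n_tfs
    X = rng.standard_normal((m, n))
    true_idx = [names.index(t) for t in true_tfs]
    eps = rng.standard_normal(m) * spec.noise_sd
    y = X[:, true_idx] @ spec.beta_star + eps

    if spec.decoy.enabled:
        j = names.index(DECOY_NAME)
        z = rng.standard_normal(m)
        r = spec.decoy.correlation
        d = r * (y / np.linalg.norm(y)) * np.linalg.norm(z) \
            + np.sqrt(1.0 - r * r) * z
        X[:, j] = d
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    y = y - y.mean()

    dsd = dsd_matrix(net, n_steps=n_dsd_steps)
    S, kept, _ = distance_submatrix(dsd, names, missing_policy="error")
    problem = RegulationProblem(y=y, X=X, tf_ids=list(names), S=S,
                                rho=1.0, lam=0.0, k=spec.k_true)

    expr = pd.DataFrame(X, columns=names,
                        index=[f"cell{i + 1}" for i in range(m)])
    expr[TG_NAME] = y

    gene = GeneAnnotation(TG_NAME, "chr1", 500_000, "+")
    peaks = [GenomicRegion("chr1", gene.tss - 400, gene.tss - 200)]
    hits = []
    tf_peak: dict[str, GenomicRegion] = {}
    for i, tf in enumerate(names):
        start = gene.tss + 10_000 + 1_000 * i
        region = GenomicRegion("chr1", start, start + 500)
        peaks.append(region)
        tf_peak[tf] = region
        hits.append({"tf_id": tf, "chrom": "chr1",
                     "start": start + 100, "end": start + 120})
    motif_hits = pd.DataFrame(hits)
    links = PCHiCLinkSet(tg=TG_NAME,
                         linked_regions=[tf_peak[t] for t in true_tfs])
    return SyntheticInstance(
        problem=problem, true_support=tuple(sorted(true_idx)), network=net,
        expression=expr, gene=gene, peaks=peaks, motif_hits=motif_hits,
        links=links, spec=spec)


def degree_preserving_randomization(net: PPINetwork, seed: int = 0,
                                    n_swaps: int | None = None) -> PPINetwork:
    """Null network with the exact degree sequence of the input.

    Seeded double-edge swaps; default 10 x |E| swap attempts.
    """
    g = net.graph.copy()
    e = g.number_of_edges()
    if e < 2:
        return PPINetwork(graph=g)
    n_swaps = 10 * e if n_swaps is None else n_swaps
    nx.double_edge_swap(g, nswap=n_swaps, max_tries=100 * n_swaps + 100,
                        seed=int(seed) % (2 ** 31))
    nx.set_edge_attributes(g, "physical", "interaction_type")
    return PPINetwork(graph=g)


def support_recovery_f1(predicted: Sequence[int], truth: Sequence[int]) -> float:
    """Set-overlap F1 between a predicted and the planted support."""
    p, t = set(predicted), set(truth)
    if not p and not t:
        return 1.0
    if not p or not t:
        return 0.0
    tp = len(p & t)
    prec, rec = tp / len(p), tp / len(t)
    return 0.0 if tp == 0 else 2 * prec * rec / (prec + rec)


def write_instance(inst: SyntheticInstance, out_dir: str | Path) -> dict[str, Path]:
    """Write the instance as plain-text fixtures (TSV/BED/JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["expression"] = out / "expression.tsv"
    inst.expression.to_csv(paths["expression"], sep="\t", index_label="cell")

    paths["edges"] = out / "edges.tsv"
    rows = [{"symbol_a": a, "symbol_b": b, "interaction_type": "physical"}
            for a, b in sorted(map(sorted, inst.network.graph.edges))]
    pd.DataFrame(rows).to_csv(paths["edges"], sep="\t", index=False)

    paths["peaks"] = out / "peaks.bed"
    with open(paths["peaks"], "w") as fh:
        for p in inst.peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")

    paths["tss"] = out / "tss.tsv"
    pd.DataFrame([{"gene_id": inst.gene.gene_id, "chrom": inst.gene.chrom,
                   "tss": inst.gene.tss, "strand": inst.gene.strand}]
                 ).to_csv(paths["tss"], sep="\t", index=False)

    paths["motif_hits"] = out / "motif_hits.tsv"
    inst.motif_hits.to_csv(paths["motif_hits"], sep="\t", index=False)

    paths["links"] = out / "links.tsv"
    pd.DataFrame([{"tg": inst.links.tg, "chrom": r.chrom, "start": r.start,
                   "end": r.end} for r in inst.links.linked_regions]
                 ).to_csv(paths["links"], sep="\t", index=False)

    paths["truth"] = out / "truth.json"
    truth = {"tg": TG_NAME,
             "true_tfs": inst.true_tfs,
             "true_support": list(inst.true_support),
             "beta_star": list(map(float, inst.spec.beta_star)),
             "noise_sd": inst.spec.noise_sd,
             "seed": inst.spec.seed}
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return paths
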