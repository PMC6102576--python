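"""Girvan–Newman planted-partition benchmark for multi-view module discovery.

The classical GN benchmark is a random graph of 128 nodes split into 4 planted
communities of 32 nodes each, with an average node degree of 16.  The mixing
parameter ``z_out`` is the expected number of a node's edges that leave its
own community; as ``z_out`` grows from 1 to 8 the community structure fades
(at ``z_out = 8`` half of each node's edges point outside).

The multi-view construction couples three such graphs drawn independently
over one shared planted partition: the first two become the data views (each
node's adjacency-indicator column is its feature vector, giving a 128 x 128
data matrix per view), and the third serves as the structural regularization
network.  The difficulty of the views and of the regularization network are
controlled by separate ``z_out`` parameters.

Edges are sampled as independent Bernoulli draws with within-community
probability ``p_in = (deg - z_out)/(size - 1)`` and between-community
probability ``p_out = z_out/(n - size)``, which reproduces the stated
expected degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ExpressionView, ModulePartition, Network

__all__ = ["GNBenchmark", "generate_gn_network", "build_benchmark"]

N_NODES = 128
N_CLUSTERS = 4
AVG_DEGREE = 16.0
DEFAULT_ZOUT_REG = 6


@dataclass
class GNBenchmark:
    """A three-graph benchmark instance sharing one planted partition."""

    views: list[ExpressionView]
    reg_network: Network
    truth: ModulePartition
    z_out_views: float
    z_out_reg: float
    seed: int


def generate_gn_network(
    n_nodes: int = N_NODES,
    n_clusters: int = N_CLUSTERS,
    avg_degree: float = AVG_DEGREE,
    z_out: float = 1.0,
    seed: int = 0,
) -> tuple[Network, ModulePartition]:
    """Sample one planted-partition graph and its ground-truth labels.

    Nodes ``0..n-1`` are split into ``n_clusters`` equal consecutive blocks.
    Each unordered pair is connected independently with probability ``p_in``
    inside a block and ``p_out`` across blocks, chosen so a node expects
    ``avg_degree - z_out`` within-community and ``z_out`` cross-community
    neighbors.  Deterministic for a fixed seed.
    """
    if n_nodes % n_clusters != 0:
        raise ValueError("n_nodes must be divisible by n_clusters")
    if not 0 <= z_out <= avg_degree:
        raise ValueError("z_out must lie in [0, avg_degree]")
    size = n_nodes // n_clusters
    p_in = (avg_degree - z_out) / (size - 1)
    p_out = z_out / (n_nodes - size)
    if p_in > 1 or p_out > 1:
        raise ValueError(
            f"infeasible edge probabilities p_in={p_in:.3f}, p_out={p_out:.3f}"
        )
    labels = np.repeat(np.arange(1, n_clusters + 1), size)
    rng = np.random.default_rng(seed)
    same = labels[:, None] == labels[None, :]
    probs = np.where(same, p_in, p_out)
    draws = rng.random((n_nodes, n_nodes)) < probs
    A = np.triu(draws, k=1).astype(float)
    A = A + A.T
    gene_ids = [f"g{i:03d}" for i in range(n_nodes)]
    network = Network(adjacency=A, gene_ids=gene_ids)
    truth = ModulePartition(labels=labels, k=n_clusters)
    return network, truth


def build_benchmark(
    z_out_views: float = 1.0,
    z_out_reg: float = DEFAULT_ZOUT_REG,
    seed: int = 0,
) -> GNBenchmark:
    """Build the coupled three-graph benchmark.

    Draws three independent GN graphs over the same planted 4 x 32 partition
    using sub-seeds ``seed``, ``seed + 1``, ``seed + 2``.  Graphs 1–2 become
    expression-like views whose column ``j`` is node ``j``'s binary adjacency
    profile; graph 3 is the regularization network.
    """
    nets = []
    truth = None
    for offset, z in enumerate((z_out_views, z_out_views, z_out_reg)):
        net, t = generate_gn_network(z_out=z, seed=seed + offset)
        nets.append(net)
        truth = t
    gene_ids = nets[0].gene_ids
    views = [
        ExpressionView(
            stage_id=s + 1,
            values=net.adjacency.copy(),
            gene_ids=list(gene_ids),
            sample_ids=[f"s{s + 1}_{i:03d}" for i in range(net.n_genes)],
        )
        for s, net in enumerate(nets[:2])
    ]
    return GNBenchmark(
        views=views,
        reg_network=nets[2],
        truth=truth,
        z_out_views=z_out_views,
        z_out_reg=z_out_reg,
        seed=seed,
    )
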