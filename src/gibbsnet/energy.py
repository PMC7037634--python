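"""Network Gibbs free energy of an expression-weighted interaction graph.

The statistic treats rescaled expression values as protein "concentrations"
c_i in [0, 1] placed on the nodes of a PPI graph. Each node gets a chemical
potential

    mu_i = ln( c_i / sum_{j in Adj(i) ∪ {i}} c_j ),

the log-ratio of its own concentration to the concentration mass of its
closed neighborhood (a degree-entropy-like denominator), and contributes

    G_i = c_i * mu_i  <=  0.

The per-sample score is the network total G = sum_i G_i, a non-positive
scalar: 0 for an edgeless graph, increasingly negative the more concentration
mass sits inside connected neighborhoods.

Conventions (analytically forced limits): 0·ln(0) := 0, so mu_i := 0 when
c_i = 0; when the denominator equals c_i (isolated node, or all neighbors at
zero concentration) the log argument is exactly 1 and mu_i = 0. Natural
logarithm throughout — the log2 scale of the input expression refers only to
upstream normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .scorer import GibbsNetworkScorer

logger = logging.getLogger(__name__)


@dataclass
class GibbsResult:
    """Per-sample scoring result.

    Attributes
    ----------
    sample_id:
        Column label of the scored sample.
    total_G:
        Network total Gibbs free energy (dimensionless, ≤ 0).
    per_node:
        DataFrame indexed by gene symbol with columns ``concentration``,
        ``chemical_potential`` and ``contribution`` (= c_i · mu_i), covering
        the network nodes in sorted order.
    """

    sample_id: str
    total_G: float
    per_node: pd.DataFrame


def rescale_concentrations(sample: Mapping[str, float] | pd.Series) -> pd.Series:
    """Min–max rescale one sample's log2 expression into [0, 1].

    c_i = (e_i − e_min) / (e_max − e_min), with e_min and e_max taken over
    the genes of this sample, so the lowest-expressed gene maps to exactly 0
    and the highest to exactly 1. A constant sample (e_max = e_min) maps to
    all zeros with a degenerate-sample warning.
    """
    series = pd.Series(sample, dtype=float)
    if series.empty:
        raise ValueError("cannot rescale an empty sample")
    if not np.isfinite(series.to_numpy()).all():
        raise ValueError("sample contains non-finite expression values")
    e_min, e_max = series.min(), series.max()
    if e_max == e_min:
        logger.warning("degenerate sample: constant expression, all concentrations set to 0")
        return pd.Series(0.0, index=series.index)
    return (series - e_min) / (e_max - e_min)


def chemical_potential(
    network: nx.Graph, concentrations: Mapping[str, float], node: str
) -> float:
    """Chemical potential mu_i = ln(c_i / Σ_{j∈Adj(i)∪{i}} c_j) of one node.

    Genes absent from ``concentrations`` default to c = 0. Returns 0.0 when
    the node is isolated or its whole neighborhood carries zero concentration
    (log argument 1), and 0.0 by the 0·ln(0) convention when c_i = 0.
    """
    if node not in network:
        raise KeyError(f"node {node!r} not in network")
    c_i = float(concentrations.get(node, 0.0))
    if c_i == 0.0:
        return 0.0
    denom = c_i + sum(float(concentrations.get(j, 0.0)) for j in network.adj[node])
    if denom == c_i:
        return 0.0
    return float(np.log(c_i / denom))


def node_gibbs(network: nx.Graph, concentrations: Mapping[str, float], node: str) -> float:
    """Per-node contribution G_i = c_i · mu_i (≤ 0; 0 for c_i = 0 or isolated)."""
    c_i = float(concentrations.get(node, 0.0)) if node in network else 0.0
    return c_i * chemical_potential(network, concentrations, node)


def total_gibbs(network: nx.Graph, concentrations: Mapping[str, float]) -> float:
    """Network total G = Σ_i c_i · mu_i over the nodes of ``network``.

    Genes present in ``concentrations`` but absent from the network
    contribute nothing; network nodes absent from ``concentrations`` are
    treated as c = 0. Summation runs in sorted-node order for run-to-run
    determinism.
    """
    if network.number_of_nodes() == 0:
        return 0.0
    scorer = GibbsNetworkScorer(network=network, rescale=False).fit()
    c = pd.Series(dict(concentrations), dtype=float)
    return float(scorer.score_samples(pd.DataFrame([c]))[0])


def gibbs_per_sample(
    network: nx.Graph,
    expression: pd.DataFrame,
    rescale_scope: str = "sample",
    rescale_over: str = "all",
    keep_per_node: bool = False,
) -> list[GibbsResult]:
    """Score every sample column of a genes × samples expression matrix.

    Each column is min–max rescaled (per sample by default, or with a global
    matrix-wide min/max when ``rescale_scope="global"``), overlaid on the
    network, and summed into a total G. With ``rescale_over="network"`` the
    min/max is taken over network-overlapping genes only instead of the full
    transcriptome.

    Returns one :class:`GibbsResult` per sample, in column order. Raises
    ``ValueError`` when the expression genes and network nodes do not
    overlap at all.
    """
    scorer = GibbsNetworkScorer(
        network=network, rescale_scope=rescale_scope, rescale_over=rescale_over
    )
    X = expression.T  # samples × genes, the estimator's orientation
    scorer.fit(X)
    logger.info(
        "expression/network overlap: %d of %d genes on %d network nodes",
        scorer.n_overlap_, expression.shape[0], network.number_of_nodes(),
    )
    totals = scorer.score_samples(X)
    results: list[GibbsResult] = []
    for k, sample_id in enumerate(expression.columns):
        per_node = (
            scorer.per_node_table(X.iloc[[k]]) if keep_per_node else pd.DataFrame()
        )
        results.append(GibbsResult(str(sample_id), float(totals[k]), per_node))
    return results


def results_table(results: list[GibbsResult], n_overlap: int | None = None) -> pd.DataFrame:
    """Tidy per-sample table (sample_id, total_G, n_nodes_scored, n_overlap)."""
    rows = []
    for r in results:
        rows.append(
            {
                "sample_id": r.sample_id,
                "total_G": r.total_G,
                "n_nodes_scored": len(r.per_node) if len(r.per_node) else np.nan,
                "n_overlap": n_overlap,
            }
        )
    return pd.DataFrame(rows)
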