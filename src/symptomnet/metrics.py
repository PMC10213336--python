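"""Node centrality and outcome-flow summaries of an estimated network.

Strength — the sum of the absolute weights of the edges incident to a node —
is the sole centrality index here.  The flow layout extracts, for one target
node (typically global QOL), its direct edges ranked by absolute weight, and
assigns every node to a layer: 0 the target, 1 its direct neighbours, 2 the
remainder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import EDGE_EPS, SymptomNetworkResult

__all__ = ["strength_centrality", "FlowLayout", "flow_edges"]


def _weights(network) -> tuple[np.ndarray, list[str]]:
    if isinstance(network, SymptomNetworkResult):
        W = network.weights.to_numpy()
        nodes = network.nodes
    elif isinstance(network, pd.DataFrame):
        W = network.to_numpy()
        nodes = list(network.columns)
    else:
        W = np.asarray(network, dtype=float)
        nodes = [f"V{i + 1}" for i in range(W.shape[0])]
    return W, nodes


def strength_centrality(network) -> pd.DataFrame:
    """Strength centrality per node: strength, rank, z-scored strength.

    strength_i = sum_j |w_ij|.  Ranks are 1 (largest) .. p, ties broken by
    node order.  The handshake identity — total strength equals twice the sum
    of absolute upper-triangle weights — is asserted on every call.
    """
    W, nodes = _weights(network)
    strength = np.sum(np.abs(W), axis=1)
    iu = np.triu_indices(len(nodes), 1)
    assert np.isclose(strength.sum(), 2.0 * np.sum(np.abs(W[iu])), atol=1e-10), (
        "handshake identity violated: asymmetric or nonzero-diagonal weights"
    )
    order = np.argsort(-strength, kind="stable")
    rank = np.empty(len(nodes), dtype=int)
    rank[order] = np.arange(1, len(nodes) + 1)
    sd = strength.std()
    z = (strength - strength.mean()) / sd if sd > 0 else np.zeros_like(strength)
    return pd.DataFrame(
        {"strength": strength, "rank": rank, "z_strength": z}, index=nodes
    )


@dataclass(frozen=True)
class FlowLayout:
    """Direct-edge extraction around one target node.

    ``direct`` lists (neighbor, weight) for the target's nonzero edges,
    ranked by |weight| descending (ties by node order); ``layers`` maps each
    node to 0 (target), 1 (direct neighbour) or 2 (remainder).
    """

    target: str
    direct: list[tuple[str, float]]
    layers: dict[str, int]

    def top(self, k: int) -> list[str]:
        return [name for name, _ in self.direct[:k]]

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "direct": [{"node": n, "weight": w} for n, w in self.direct],
            "layers": dict(self.layers),
        }


def flow_edges(network, target: str) -> FlowLayout:
    """Extract and rank the direct edges between ``target`` and other nodes."""
    W, nodes = _weights(network)
    if target not in nodes:
        raise KeyError(f"unknown target node {target!r}; nodes are {nodes}")
    ti = nodes.index(target)
    pairs = [
        (nodes[j], float(W[ti, j]))
        for j in range(len(nodes))
        if j != ti and abs(W[ti, j]) > EDGE_EPS
    ]
    pairs.sort(key=lambda nw: -abs(nw[1]))  # stable: ties keep node order
    neighbours = {n for n, _ in pairs}
    layers = {
        n: 0 if n == target else (1 if n in neighbours else 2) for n in nodes
    }
    return FlowLayout(target=target, direct=pairs, layers=layers)
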