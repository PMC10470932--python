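"""Seeded synthetic generators for every pipeline input.

The generators plant a block structure: circRNAs and diseases are each
partitioned into ``blocks`` groups, associations are dense within matched
groups and sparse across, and circRNAs of one block share a latent
expression profile.  The planted signal is what the end-to-end pipeline is
expected to recover; defaults are sized so the whole pipeline runs at desk
scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AssociationMatrix, DiseaseDAG, ExpressionTable, LabeledPairSet


@dataclass
class SyntheticConfig:
    """Study conditions for the planted-structure generator.

    Defaults give an 80 x 30 association matrix with four co-association
    blocks (within-block association probability 0.3, between 0.02),
    32-sample expression profiles, and a 4-layer random disease ontology.
    """

    m: int = 80
    n: int = 30
    blocks: int = 4
    density_in: float = 0.3
    density_out: float = 0.02
    p: int = 32
    noise_sd: float = 0.5
    dag_depth: int = 4
    dag_branching: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.density_out < self.density_in <= 1):
            raise ValueError("need 0 <= density_out < density_in <= 1")
        for name in ("m", "n", "blocks", "p", "dag_depth", "dag_branching"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.blocks > min(self.m, self.n):
            raise ValueError("more blocks than rows or columns")


def _block_assignment(count: int, blocks: int) -> np.ndarray:
    """Deterministic contiguous partition of ``count`` items into blocks."""
    return np.array_split(np.arange(count), blocks)


def block_labels(count: int, blocks: int) -> np.ndarray:
    lab = np.empty(count, dtype=int)
    for b, idx in enumerate(_block_assignment(count, blocks)):
        lab[idx] = b
    return lab


def simulate_associations(cfg: SyntheticConfig) -> AssociationMatrix:
    """Bernoulli block model over an m x n circRNA-disease grid."""
    rng = np.random.default_rng(cfg.seed)
    cb = block_labels(cfg.m, cfg.blocks)
    db = block_labels(cfg.n, cfg.blocks)
    same = cb[:, None] == db[None, :]
    prob = np.where(same, cfg.density_in, cfg.density_out)
    if prob.sum() == 0:
        raise ValueError("expected positive count is zero; raise densities")
    am = (rng.random((cfg.m, cfg.n)) < prob).astype(np.int8)
    circ_ids = [f"circ_{i:04d}" for i in range(cfg.m)]
    disease_ids = [f"disease_{j:03d}" for j in range(cfg.n)]
    return AssociationMatrix(circ_ids, disease_ids, am)


def simulate_dag(cfg: SyntheticConfig) -> DiseaseDAG:
    """Layered random DAG over the n disease ids plus a synthetic root.

    Diseases of the same planted block form one ontology family: within a
    block the diseases are spread over ``dag_depth`` layers and every
    non-root node draws 1..dag_branching parents from strictly shallower
    layers of its own family (the synthetic root backs the first layer), so
    the graph is acyclic by construction and same-block diseases share
    ancestors — emulating how related diseases cluster into subtrees of a
    real ontology.  Edges point child -> parent.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    ids = [f"disease_{j:03d}" for j in range(cfg.n)]
    root = "disease_root"
    lab = block_labels(cfg.n, cfg.blocks)
    edges: list[tuple[str, str]] = []
    for b in range(cfg.blocks):
        members = [ids[j] for j in range(cfg.n) if lab[j] == b]
        layers: list[list[str]] = [[root]]
        for part in np.array_split(np.arange(len(members)), min(cfg.dag_depth, len(members))):
            layers.append([members[j] for j in part])
        for depth in range(1, len(layers)):
            shallower = [x for layer in layers[1:depth] for x in layer] or [root]
            for node in layers[depth]:
                k = min(int(rng.integers(1, cfg.dag_branching + 1)), len(shallower))
                parents = rng.choice(len(shallower), size=k, replace=False)
                edges.extend((node, shallower[p]) for p in parents)
    return DiseaseDAG([root] + ids, edges)


def simulate_expression(cfg: SyntheticConfig) -> ExpressionTable:
    """Block-correlated expression: shared latent profile + Gaussian noise."""
    rng = np.random.default_rng(cfg.seed + 2)
    lab = block_labels(cfg.m, cfg.blocks)
    latent = rng.normal(0.0, 2.0, size=(cfg.blocks, cfg.p))
    profiles = latent[lab] + rng.normal(0.0, cfg.noise_sd, size=(cfg.m, cfg.p))
    circ_ids = [f"circ_{i:04d}" for i in range(cfg.m)]
    return ExpressionTable(circ_ids, profiles)


def sample_negatives(am: AssociationMatrix, n_neg: int, seed: int) -> LabeledPairSet:
    """All positive cells plus a uniform sample of ``n_neg`` zero cells.

    Mirrors the balanced construction used on the curated association
    tables: unknown (zero) cells stand in for negatives, sampled without
    replacement.  A balanced set results when ``n_neg`` equals the positive
    count.
    """
    zeros = np.argwhere(am.AM == 0)
    if n_neg > len(zeros):
        raise ValueError(f"requested {n_neg} negatives but only {len(zeros)} zero cells")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(zeros), size=n_neg, replace=False)
    pos = np.argwhere(am.AM == 1)
    pairs = [(int(i), int(j), 1) for i, j in pos]
    pairs += [(int(zeros[k, 0]), int(zeros[k, 1]), 0) for k in pick]
    return LabeledPairSet(pairs)
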