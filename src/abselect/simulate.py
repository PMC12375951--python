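"""Sequence evolution simulation under the mutation-selection model.

Children are drawn per codon site independently from the site's
mutation-selection transition distribution (WT codon as remainder mass), so a
branch is a single transition step rather than a continuous-time chain —
exactly the structure of the fitted model.  Stop codons have probability 0 by
construction, so no simulated child can contain one.

Simulation cascades down a tree: the child sequence drawn on one edge is the
parent of its daughter edges.  Randomness is derived counter-style per
(tree, edge) from one master seed, so results are byte-identical regardless
of traversal or parallel execution order.
"""

from __future__ import annotations

import numpy as np

from .fitting import mutsel_probs
from .neutral import NeutralProvider, neutral_codon_probs
from .seqcodec import CODONS, PCP, AnnotatedTree, CodonSequence
from .selection import SelectionModel


def _as_generator(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.Generator(np.random.Philox(np.random.SeedSequence(rng)))


def sample_child(
    parent: CodonSequence,
    model: SelectionModel,
    provider: NeutralProvider,
    t: float,
    rng,
    counters: dict | None = None,
) -> CodonSequence:
    """Draw a child sequence from the per-site transition distributions.

    Masked (ambiguous) sites are copied through unchanged.  Sites where the
    probability clamp was active increment ``counters["clamped_sites"]`` when
    a counter dict is supplied.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    rng = _as_generator(rng)
    if t == 0:
        return CodonSequence(parent.nucleotides)
    probs = neutral_codon_probs(parent, provider, t)
    f = model.factors(parent.aa)
    ms = mutsel_probs(probs, parent, f)
    if counters is not None:
        counters["clamped_sites"] = counters.get("clamped_sites", 0) + int(ms.clamped.sum())
    child_codons = list(parent.codons)
    if ms.mask.any():
        rows = np.flatnonzero(ms.mask)
        cum = np.cumsum(ms.codon_probs[rows], axis=1)
        # guard against round-off so the final bin always catches the draw
        cum[:, -1] = np.maximum(cum[:, -1], 1.0)
        u = rng.random(rows.size)
        picks = (cum > u[:, None]).argmax(axis=1)
        for r, c in zip(rows, picks):
            child_codons[r] = CODONS[c]
    return CodonSequence("".join(child_codons))


def simulate_down_tree(
    tree: AnnotatedTree,
    naive: CodonSequence,
    model: SelectionModel,
    provider: NeutralProvider,
    rng,
    drop_naive: bool = True,
    drop_identical: bool = True,
    clone_id: str = "",
    counters: dict | None = None,
) -> list[PCP]:
    """Cascade simulation down one tree rooted at the naive sequence.

    One PCP per edge; the child drawn on an edge becomes the parent of its
    daughter edges.  Filtering then applies the real-data criteria: naive
    edges and identical parent/child pairs are excluded by default.  The
    naive sequence must be unambiguous and in frame.
    """
    if "N" in naive.nucleotides:
        raise ValueError("naive sequence must be unambiguous")
    if naive.has_stop():
        raise ValueError("naive sequence contains a stop codon")
    # An explicit Generator is consumed sequentially; an integer seed derives
    # an independent Philox stream per edge index (parallel-safe determinism).
    seq_rng = rng if isinstance(rng, np.random.Generator) else None

    root = tree.tree.seed_node
    seqs = {id(root): naive}
    pcps = []
    edge_index = 0
    for node in tree.tree.preorder_node_iter():
        for child in node.child_nodes():
            t = child.edge.length
            if t is None:
                raise ValueError("every edge needs a branch length for simulation")
            if seq_rng is not None:
                edge_rng = seq_rng
            else:
                edge_rng = np.random.Generator(
                    np.random.Philox(np.random.SeedSequence(rng, spawn_key=(edge_index,)))
                )
            parent_seq = seqs[id(node)]
            child_seq = sample_child(parent_seq, model, provider, float(t), edge_rng,
                                     counters=counters)
            seqs[id(child)] = child_seq
            pcp = PCP(
                parent=parent_seq,
                child=child_seq,
                branch_length=float(t),
                clone_id=clone_id or tree.naive_label,
                is_naive_edge=(node is root),
            )
            edge_index += 1
            if drop_naive and pcp.is_naive_edge:
                continue
            if drop_identical and pcp.identical:
                continue
            pcps.append(pcp)
    return pcps
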