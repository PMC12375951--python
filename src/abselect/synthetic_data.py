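"""Synthetic fixtures: naive sequences, trees, rate tables, ground truths.

Everything every stage of the pipeline consumes can be generated here from a
single master seed, so simulation, fitting and evaluation are testable with
no external data.  The ground-truth selection functions are simple analytic
families rather than a pre-trained network; the ``context`` family keeps the
essential property of the real problem — factors depend on sequence content,
not just position — by keying on the amino acid currently occupying a site.

Default study conditions (chosen once, a realistic desk-scale emulation of
affinity-maturation data): 60-codon naive sequences at balanced base
composition, clonal trees of 50 leaves with exponential branch lengths of
mean 0.05 expected substitutions per site per unit rate, and 5-mer neutral
rate tables with log-normal rate heterogeneity emulating SHM hotspot bias.
"""

from __future__ import annotations

import dataclasses
import itertools

import dendropy
import numpy as np

from ._nn import Tensor
from .neutral import KmerNeutralProvider, NucleotideRates, TableNeutralProvider
from .seqcodec import AMINO_ACIDS, NUCLEOTIDES, AnnotatedTree, CodonSequence, PCP, translate
from .selection import PAD, SelectionModel, SelectionModelConfig
from .simulate import simulate_down_tree

#: Amino acids treated as hydrophobic by the ``context`` ground-truth family.
HYDROPHOBIC = frozenset("AVILMFWC")

#: Bounds every ground-truth family clips its factors into.
FACTOR_BOUNDS = (0.05, 3.0)


def _as_generator(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


# ---------------------------------------------------------------------------
# Naive sequences and trees
# ---------------------------------------------------------------------------

def gen_naive(n_codons: int, gc_bias: float = 0.5, rng=0) -> CodonSequence:
    """Random in-frame sequence with no stop codons (rejection-sampled)."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = _as_generator(rng)
    p = np.array([(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2])
    codons = []
    while len(codons) < n_codons:
        codon = "".join(rng.choice(list(NUCLEOTIDES), p=p, size=3))
        if translate(codon) != "*":
            codons.append(codon)
    return CodonSequence("".join(codons))


def gen_tree(n_leaves: int, mean_branch: float = 0.05, rng=0) -> AnnotatedTree:
    """Random rooted binary topology with exponential branch lengths.

    The root is the naive outgroup (named ``naive``); a rooted binary tree
    with n leaves has 2n - 2 edges.  Topology is grown by splitting a
    uniformly chosen current leaf until n leaves exist.
    """
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    rng = _as_generator(rng)
    tree = dendropy.Tree()
    tree.seed_node.label = "naive"
    counter = itertools.count(1)
    leaves = []
    for _ in range(2):
        child = tree.seed_node.new_child(edge_length=0.0)
        child.label = f"n{next(counter)}"
        leaves.append(child)
    while len(leaves) < n_leaves:
        node = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            child = node.new_child(edge_length=0.0)
            child.label = f"n{next(counter)}"
            leaves.append(child)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = float(rng.exponential(mean_branch))
    # leaves need taxa (not just labels) to survive a newick round trip
    for node in tree.leaf_node_iter():
        node.taxon = tree.taxon_namespace.new_taxon(label=node.label)
        node.label = None
    return AnnotatedTree(tree, sequences=None, naive_label="naive")


# ---------------------------------------------------------------------------
# Neutral rate tables
# ---------------------------------------------------------------------------

def gen_rate_table(n_sites: int, rate_sigma: float = 0.5, rng=0) -> TableNeutralProvider:
    """Positional rate table: log-normal rates (mean 1), Dirichlet biases."""
    rng = _as_generator(rng)
    lam = rng.lognormal(mean=-rate_sigma**2 / 2, sigma=rate_sigma, size=n_sites)
    sub = rng.dirichlet(np.full(4, 2.0), size=n_sites)
    return TableNeutralProvider(NucleotideRates(lam, sub))


def gen_kmer_table(k: int = 5, rate_sigma: float = 1.0, rng=0) -> KmerNeutralProvider:
    """Complete k-mer context table with hotspot-like rate heterogeneity.

    Rates are log-normal with unit mean and sigma ~1 (a heavy right tail, as
    for SHM hotspots); substitution biases are Dirichlet over the three
    alternates of the central base.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    rng = _as_generator(rng)
    table = {}
    for kmer_tuple in itertools.product(NUCLEOTIDES, repeat=k):
        kmer = "".join(kmer_tuple)
        rate = float(rng.lognormal(mean=-rate_sigma**2 / 2, sigma=rate_sigma))
        s = np.zeros(4)
        alternates = [i for i, b in enumerate(NUCLEOTIDES) if b != kmer[k // 2]]
        s[alternates] = rng.dirichlet(np.full(3, 2.0))
        table[kmer] = (rate, s)
    rates = np.array([r for r, _ in table.values()])
    default_sub = np.mean([s for _, s in table.values()], axis=0)
    return KmerNeutralProvider(table, k, float(rates.mean()),
                               default_sub / default_sub.sum())


# ---------------------------------------------------------------------------
# Ground-truth selection functions
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GroundTruthSpec:
    """Parameters of an analytic ground-truth selection function.

    ``constant``: every factor equals ``baseline``.
    ``sinusoid``: position-only modulation ``baseline * (1 + amplitude *
    sin(2 pi j / period))``.
    ``context``: the sinusoid multiplied by ``hydrophobic_penalty`` wherever
    the *current* amino acid is hydrophobic — factors depend on sequence
    content, so two sequences differing at one position get different
    profiles there (by exactly the penalty ratio).
    """

    family: str = "context"  # constant | sinusoid | context
    baseline: float = 1.0
    amplitude: float = 0.5
    hydrophobic_penalty: float = 0.5
    period: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("constant", "sinusoid", "context"):
            raise ValueError(f"unknown ground-truth family {self.family!r}")
        if self.baseline <= 0 or self.hydrophobic_penalty <= 0:
            raise ValueError("parameters implying factor <= 0")
        if not 0 <= self.amplitude < 1:
            raise ValueError("amplitude must be in [0, 1) to keep factors positive")


class AnalyticSelectionModel(SelectionModel):
    """Deterministic, bounded selection model defined by a GroundTruthSpec.

    Implements the same surface as the trainable models (so it can drive the
    simulator and every evaluation path) but holds no trainable parameters.
    """

    def __init__(self, spec: GroundTruthSpec, max_len: int = 512):
        self.spec = spec
        self.config = SelectionModelConfig(family="single", max_len=max_len, beta=0.3)
        self._params = {}
        self._hydrophobic_tokens = np.zeros(PAD + 1, dtype=bool)
        for i, a in enumerate(AMINO_ACIDS):
            self._hydrophobic_tokens[i] = a in HYDROPHOBIC

    def forward(self, tokens, key_mask, train=False, rng=None) -> Tensor:
        spec = self.spec
        B, L = tokens.shape
        pos = np.arange(L, dtype=float)
        if spec.family == "constant":
            f = np.full((B, L), spec.baseline)
        else:
            f = np.broadcast_to(
                spec.baseline * (1.0 + spec.amplitude * np.sin(2 * np.pi * pos / spec.period)),
                (B, L),
            ).copy()
            if spec.family == "context":
                f = np.where(self._hydrophobic_tokens[tokens],
                             f * spec.hydrophobic_penalty, f)
        lo, hi = FACTOR_BOUNDS
        return Tensor(np.clip(f, lo, hi))


def gen_ground_truth(spec: GroundTruthSpec, max_len: int = 512) -> AnalyticSelectionModel:
    """Build the analytic selection model for a spec (validated on entry)."""
    return AnalyticSelectionModel(spec, max_len=max_len)


# ---------------------------------------------------------------------------
# Whole synthetic PCP datasets
# ---------------------------------------------------------------------------

def gen_pcp_dataset(
    n_pcps: int,
    truth: SelectionModel,
    provider,
    seed: int = 0,
    n_codons: int = 60,
    n_leaves: int = 50,
    mean_branch: float = 0.05,
    shared_naive: CodonSequence | None = None,
    drop_naive: bool = True,
    drop_identical: bool = True,
) -> list[PCP]:
    """Simulate clonal trees until at least ``n_pcps`` PCPs survive filtering.

    Each tree gets its own naive sequence (unless ``shared_naive`` is given),
    topology and branch lengths; PCP randomness is derived per tree from the
    master seed.  Returns exactly ``n_pcps`` pairs.
    """
    pcps: list[PCP] = []
    tree_i = 0
    while len(pcps) < n_pcps:
        tree_ss = np.random.SeedSequence(seed, spawn_key=(tree_i,))
        r_naive, r_tree, r_seqs = (np.random.default_rng(s) for s in tree_ss.spawn(3))
        naive = shared_naive or gen_naive(n_codons, rng=r_naive)
        tree = gen_tree(n_leaves, mean_branch=mean_branch, rng=r_tree)
        pcps.extend(
            simulate_down_tree(
                tree, naive, truth, provider, r_seqs,
                drop_naive=drop_naive, drop_identical=drop_identical,
                clone_id=f"clone{tree_i}",
            )
        )
        tree_i += 1
    return pcps[:n_pcps]
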