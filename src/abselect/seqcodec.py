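"""Codon sequences, parent-child pairs, and annotated clonal-family trees.

Sequences are in-frame nucleotide strings over ``{A, C, G, T, N}``; codon site
``j`` covers nucleotides ``[3j, 3j+3)`` (0-based, half-open).  The unit of
training data is the parent-child pair (PCP): the two sequences at the ends of
one edge of a clonal-family phylogenetic tree, together with an evolutionary
time (branch length) that is typically re-optimized downstream rather than
taken from the tree.

Trees are plain newick with *named* internal nodes; per-node sequences live in
a companion FASTA keyed by node name.  Inputs are assumed gap-free (indels are
reversed upstream); gapped input is rejected, not repaired.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
NT_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}

#: 20 canonical amino acids, alphabetical one-letter order (model vocabulary).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

STOP = "*"
AMBIGUOUS = "X"

# Standard nuclear genetic code (NCBI table 1), via biopython.
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = STOP

#: All 64 codons in lexicographic ACGT order; codon index = 16*i0 + 4*i1 + i2.
CODONS = [a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
STOP_CODON_INDICES = frozenset(CODON_INDEX[c] for c in _STANDARD_TABLE.stop_codons)

#: Amino acid (or ``*``) per codon index, aligned with :data:`CODONS`.
CODON_AA = [CODON_TO_AA[c] for c in CODONS]


def translate(codon: str) -> str:
    """Translate one codon under the standard nuclear genetic code.

    Returns the one-letter amino acid, ``"*"`` for TAA/TAG/TGA, or ``"X"``
    when the codon contains an ambiguous base ``N`` (never silently an amino
    acid).  Any other character raises ``ValueError``.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    codon = codon.upper()
    if "N" in codon:
        if any(ch not in "ACGTN" for ch in codon):
            raise ValueError(f"invalid nucleotide in codon {codon!r}")
        return AMBIGUOUS
    try:
        return CODON_TO_AA[codon]
    except KeyError:
        raise ValueError(f"invalid nucleotide in codon {codon!r}") from None


def translate_sequence(nt: str) -> str:
    """Translate an in-frame nucleotide string codon by codon."""
    if len(nt) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    return "".join(translate(nt[i : i + 3]) for i in range(0, len(nt), 3))


@dataclasses.dataclass(frozen=True)
class CodonSequence:
    """An in-frame nucleotide sequence and its derived amino-acid sequence."""

    nucleotides: str

    def __post_init__(self):
        nt = self.nucleotides.upper()
        object.__setattr__(self, "nucleotides", nt)
        if len(nt) % 3:
            raise ValueError(
                f"sequence length {len(nt)} is not a multiple of 3"
            )
        if "-" in nt:
            raise ValueError("gapped input is rejected; remove indels upstream")
        bad = set(nt) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.nucleotides)

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    @property
    def codons(self) -> list[str]:
        nt = self.nucleotides
        return [nt[i : i + 3] for i in range(0, len(nt), 3)]

    @property
    def aa(self) -> str:
        """Amino-acid sequence; ``*`` marks stops, ``X`` ambiguous codons."""
        return translate_sequence(self.nucleotides)

    def has_stop(self) -> bool:
        """True if any fully unambiguous codon is a stop codon."""
        return STOP in self.aa


def is_productive(seq: CodonSequence, flank: tuple[int, int]) -> bool:
    """Productive-sequence filter for BCR variable regions.

    ``flank`` gives the nucleotide start positions of the conserved cysteine
    and tryptophan codons flanking the CDR3.  A sequence is productive iff
    both flank codons sit in the frame starting at position 0 (start position
    divisible by 3) and no unambiguous codon is a stop codon.  The flank
    residues themselves may be mutated.
    """
    cys, trp = flank
    for pos in (cys, trp):
        if pos < 0 or pos + 3 > len(seq):
            raise ValueError(f"flank position {pos} outside sequence of length {len(seq)}")
    if cys % 3 or trp % 3:
        return False
    return not seq.has_stop()


@dataclasses.dataclass
class PCP:
    """One tree edge: parent codon sequence, child codon sequence, time t."""

    parent: CodonSequence
    child: CodonSequence
    branch_length: float | None = None
    clone_id: str = ""
    is_naive_edge: bool = False

    def __post_init__(self):
        if isinstance(self.parent, str):
            self.parent = CodonSequence(self.parent)
        if isinstance(self.child, str):
            self.child = CodonSequence(self.child)
        if len(self.parent) != len(self.child):
            raise ValueError(
                f"parent length {len(self.parent)} != child length {len(self.child)}"
            )
        if self.branch_length is not None and self.branch_length < 0:
            raise ValueError("branch length must be nonnegative")

    @property
    def identical(self) -> bool:
        return self.parent.nucleotides == self.child.nucleotides


class AnnotatedTree:
    """A rooted tree with branch lengths and a nucleotide sequence per node.

    The root node is the inferred naive (unmutated ancestor) sequence and
    doubles as the outgroup label; edges incident to it are "naive edges".
    Every node must be named, and every name must key into ``sequences``.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        sequences: dict[str, str] | None = None,
        naive_label: str | None = None,
    ):
        self.tree = tree
        self.sequences = dict(sequences) if sequences else {}
        root = tree.seed_node
        self.naive_label = naive_label or _node_name(root)
        if self.naive_label is None:
            raise ValueError("root/naive node must be named")
        if self.sequences:
            self.validate()

    def validate(self) -> None:
        lengths = set()
        for node in self.tree.preorder_node_iter():
            name = _node_name(node)
            if name is None:
                raise ValueError("every node must be named")
            if name not in self.sequences:
                raise ValueError(f"node {name!r} has no sequence")
            lengths.add(len(self.sequences[name]))
        if len(lengths) > 1:
            raise ValueError(f"node sequences differ in length: {sorted(lengths)}")

    @classmethod
    def from_files(cls, newick_path, fasta_path, naive_label=None) -> "AnnotatedTree":
        tree = dendropy.Tree.get(
            path=str(newick_path), schema="newick", suppress_internal_node_taxa=False
        )
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
        return cls(tree, seqs, naive_label=naive_label)

    def edges(self):
        """Yield (parent_name, child_name, branch_length) in preorder."""
        for node in self.tree.preorder_node_iter():
            for child in node.child_nodes():
                yield _node_name(node), _node_name(child), child.edge.length


def _node_name(node) -> str | None:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label


def extract_pcps(
    tree: AnnotatedTree,
    drop_naive: bool = True,
    drop_identical: bool = True,
    clone_id: str = "",
) -> list[PCP]:
    """One PCP per directed edge parent->child of an annotated tree.

    ``drop_naive`` excludes edges incident to the naive/root node and
    ``drop_identical`` excludes pairs with identical sequences — the two
    filters applied to training data.
    """
    pcps = []
    for parent_name, child_name, length in tree.edges():
        for name in (parent_name, child_name):
            if name not in tree.sequences:
                raise ValueError(f"node {name!r} has no sequence")
        pcp = PCP(
            parent=CodonSequence(tree.sequences[parent_name]),
            child=CodonSequence(tree.sequences[child_name]),
            branch_length=length,
            clone_id=clone_id or tree.naive_label,
            is_naive_edge=(parent_name == tree.naive_label or child_name == tree.naive_label),
        )
        if drop_naive and pcp.is_naive_edge:
            continue
        if drop_identical and pcp.identical:
            continue
        pcps.append(pcp)
    return pcps


PCP_COLUMNS = ["parent", "child", "clone_id", "is_naive_edge", "branch_length"]


def write_pcp_table(pcps: Iterable[PCP], path) -> None:
    """Write PCPs as UTF-8 TSV; missing branch_length means "to be optimized"."""
    rows = [
        {
            "parent": p.parent.nucleotides,
            "child": p.child.nucleotides,
            "clone_id": p.clone_id,
            "is_naive_edge": p.is_naive_edge,
            "branch_length": "" if p.branch_length is None else repr(p.branch_length),
        }
        for p in pcps
    ]
    pd.DataFrame(rows, columns=PCP_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pcp_table(
    path, drop_naive: bool = False, drop_identical: bool = False
) -> list[PCP]:
    """Read a PCP TSV; per-row validation errors name the offending row."""
    df = pd.read_csv(path, sep="\t", dtype={"parent": str, "child": str}, keep_default_na=False)
    missing = {"parent", "child"} - set(df.columns)
    if missing:
        raise ValueError(f"PCP table missing columns: {sorted(missing)}")
    pcps = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            bl = getattr(row, "branch_length", "")
            branch_length = None if bl in ("", None) else float(bl)
            naive = getattr(row, "is_naive_edge", False)
            if isinstance(naive, str):
                naive = naive.strip().lower() in ("true", "1", "yes")
            pcp = PCP(
                parent=CodonSequence(row.parent),
                child=CodonSequence(row.child),
                branch_length=branch_length,
                clone_id=str(getattr(row, "clone_id", "")),
                is_naive_edge=bool(naive),
            )
        except ValueError as err:
            raise ValueError(f"row {i}: {err}") from err
        if drop_naive and pcp.is_naive_edge:
            continue
        if drop_identical and pcp.identical:
            continue
        pcps.append(pcp)
    return pcps


def aa_substitution_indicators(pcp: PCP) -> tuple[list[int], list[bool]]:
    """Per codon site: (y_j, mask_j).

    ``y_j`` is 1 when parent and child amino acids differ; ``mask_j`` is True
    for usable sites — sites whose parent or child codon contains an ambiguous
    base are masked out of all likelihood sums.
    """
    pa, ca = pcp.parent.aa, pcp.child.aa
    y, mask = [], []
    for a, b in zip(pa, ca):
        usable = AMBIGUOUS not in (a, b)
        mask.append(usable)
        y.append(int(usable and a != b))
    return y, mask


def warn_all_masked(mask: Sequence[bool]) -> None:
    if not any(mask):
        warnings.warn("all codon sites are ambiguous; profile fully masked", stacklevel=3)
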