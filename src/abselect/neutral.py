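"""Neutral somatic-hypermutation (SHM) probability machinery.

The neutral model is an independent Poisson mutation process at each
nucleotide site ``i`` with rate ``lambda_i``, plus a conditional substitution
distribution ``s_{i,b}`` over the three non-parent bases.  Over a branch of
length ``t`` the probability that site ``i`` keeps its base is
``exp(-lambda_i t)`` and the probability it ends as base ``b != parent`` is
``(1 - exp(-lambda_i t)) * s_{i,b}``.  Codon-level transition probabilities
are products of the three per-position terms, so a multi-nucleotide change is
just co-occurring independent single-site events; no clustered-mutation model
is used.  Only the product ``lambda_i * t`` is identified — rates and branch
lengths share one arbitrary unit.

Two neutral-rate providers are shipped: a per-site table (rates keyed by
position in a fixed-length sequence) and a k-mer context table (rates keyed by
the centered k-mer around each site, the usual parameterization of SHM hotspot
bias).  Both are deterministic functions of the parent sequence alone.
"""

from __future__ import annotations

import dataclasses
import math
from collections import defaultdict
from typing import Protocol

import numpy as np
import pandas as pd

from .seqcodec import (
    CODON_AA,
    CODON_INDEX,
    NT_INDEX,
    NUCLEOTIDES,
    STOP,
    CodonSequence,
    warn_all_masked,
)

#: Probabilities below this are flushed to zero to avoid underflow in products.
PROB_FLOOR = 1e-300

_AA_OF_CODON = np.array(CODON_AA)
#: STOP_MASK[c] — codon index c is a stop codon.
STOP_MASK = _AA_OF_CODON == STOP
#: NONSYN_MASK[w, c] — c codes an amino acid different from codon w's, not a stop.
NONSYN_MASK = (_AA_OF_CODON[None, :] != _AA_OF_CODON[:, None]) & ~STOP_MASK[None, :]
#: SYN_NONWT_MASK[w, c] — c is synonymous with w but a different codon.
SYN_NONWT_MASK = (_AA_OF_CODON[None, :] == _AA_OF_CODON[:, None]) & ~np.eye(64, dtype=bool)
NONSYN_MASK[STOP_MASK, :] = False
SYN_NONWT_MASK[STOP_MASK, :] = False


@dataclasses.dataclass
class NucleotideRates:
    """Per-site neutral rates for one parent sequence.

    ``lam[i]`` is the mutation rate at nucleotide site ``i`` (events per unit
    branch length); ``sub[i, b]`` the probability of substituting to base
    ``b`` given a mutation at ``i``, with ``sub[i, parent base] == 0`` and the
    three alternates summing to 1.
    """

    lam: np.ndarray
    sub: np.ndarray

    def __post_init__(self):
        self.lam = np.asarray(self.lam, dtype=float)
        self.sub = np.asarray(self.sub, dtype=float)
        if self.lam.ndim != 1 or self.sub.shape != (self.lam.size, 4):
            raise ValueError("lam must be (L,), sub must be (L, 4)")
        if np.any(self.lam < 0):
            raise ValueError("rates must be nonnegative")
        rowsum = self.sub.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-8):
            raise ValueError("substitution rows must sum to 1 over the three alternates")

    def validate_for(self, parent_nt: str) -> None:
        idx = np.array([NT_INDEX.get(b, -1) for b in parent_nt])
        ok = idx >= 0
        if np.any(np.abs(self.sub[np.arange(len(parent_nt))[ok], idx[ok]]) > 1e-12):
            raise ValueError("substitution probability to the parent base must be 0")


class NeutralProvider(Protocol):
    """Contract: parent nucleotide sequence -> :class:`NucleotideRates`."""

    def rates(self, parent_nt: str) -> NucleotideRates: ...


class TableNeutralProvider:
    """Rates supplied per nucleotide position of a fixed-length sequence."""

    def __init__(self, rates: NucleotideRates):
        self._rates = rates

    def rates(self, parent_nt: str) -> NucleotideRates:
        if len(parent_nt) != self._rates.lam.size:
            raise ValueError(
                f"rate table covers {self._rates.lam.size} sites, sequence has {len(parent_nt)}"
            )
        # Re-zero the parent-base column: the table's distribution is over
        # alternates of the *table's* reference, which may differ by position.
        sub = self._rates.sub.copy()
        for i, b in enumerate(parent_nt):
            bi = NT_INDEX.get(b)
            if bi is not None and sub[i, bi] > 0:
                sub[i, bi] = 0.0
                tot = sub[i].sum()
                sub[i] = sub[i] / tot if tot > 0 else _uniform_alternates(bi)
        return NucleotideRates(self._rates.lam.copy(), sub)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "site": np.arange(self._rates.lam.size),
                "lambda": self._rates.lam,
                **{f"s_{b}": self._rates.sub[:, i] for b, i in NT_INDEX.items()},
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TableNeutralProvider":
        df = pd.read_csv(path, sep="\t").sort_values("site")
        lam = df["lambda"].to_numpy(float)
        sub = df[[f"s_{b}" for b in NUCLEOTIDES]].to_numpy(float)
        return cls(NucleotideRates(lam, sub))


def _uniform_alternates(parent_base_idx: int) -> np.ndarray:
    s = np.full(4, 1.0 / 3.0)
    s[parent_base_idx] = 0.0
    return s


class KmerNeutralProvider:
    """Rates keyed by the centered k-mer context of each site.

    ``table`` maps k-mer -> (rate, substitution distribution over ACGT).
    Sites whose context is not in the table (including contexts truncated at
    sequence ends or containing N) fall back to the global average rate and
    distribution.  Deterministic: the same sequence always yields the same
    rates, independent of any child sequence.
    """

    def __init__(self, table: dict[str, tuple[float, np.ndarray]], k: int,
                 default_rate: float, default_sub: np.ndarray):
        if k % 2 == 0:
            raise ValueError("k must be odd")
        self.k = k
        self.table = {kmer: (float(r), np.asarray(s, float)) for kmer, (r, s) in table.items()}
        self.default_rate = float(default_rate)
        self.default_sub = np.asarray(default_sub, float)

    def rates(self, parent_nt: str) -> NucleotideRates:
        h = self.k // 2
        padded = "N" * h + parent_nt + "N" * h
        L = len(parent_nt)
        lam = np.empty(L)
        sub = np.empty((L, 4))
        for i in range(L):
            context = padded[i : i + self.k]
            rate, s = self.table.get(context, (self.default_rate, self.default_sub))
            lam[i] = rate
            s = s.copy()
            bi = NT_INDEX.get(parent_nt[i])
            if bi is not None:
                s[bi] = 0.0
            tot = s.sum()
            sub[i] = s / tot if tot > 0 else _uniform_alternates(bi if bi is not None else 0)
        return NucleotideRates(lam, sub)

    def to_tsv(self, path) -> None:
        rows = [
            {"kmer": "default", "rate": self.default_rate,
             **{f"s_{b}": self.default_sub[i] for b, i in NT_INDEX.items()}}
        ]
        for kmer in sorted(self.table):
            rate, s = self.table[kmer]
            rows.append({"kmer": kmer, "rate": rate, **{f"s_{b}": s[i] for b, i in NT_INDEX.items()}})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "KmerNeutralProvider":
        df = pd.read_csv(path, sep="\t", dtype={"kmer": str})
        subcols = [f"s_{b}" for b in NUCLEOTIDES]
        table = {}
        default_rate, default_sub = None, None
        for row in df.itertuples(index=False):
            s = np.array([getattr(row, c) for c in subcols], float)
            if row.kmer == "default":
                default_rate, default_sub = float(row.rate), s
            else:
                table[row.kmer] = (float(row.rate), s)
        if default_rate is None:
            rates = np.array([r for r, _ in table.values()])
            default_rate = float(rates.mean())
            default_sub = np.mean([s for _, s in table.values()], axis=0)
        k = len(next(iter(table)))
        return cls(table, k, default_rate, default_sub)


# ---------------------------------------------------------------------------
# Codon-level transition probabilities (product of per-position Poisson terms)
# ---------------------------------------------------------------------------

def site_rate_arrays(parent: CodonSequence, rates: NucleotideRates):
    """Reshape per-nucleotide rates into per-codon-site arrays.

    Returns ``(lam3, sub3, parent_idx, mask)`` with shapes ``(J, 3)``,
    ``(J, 3, 4)``, ``(J,)`` parent codon indices (-1 where masked) and a
    ``(J,)`` boolean mask that is False for codons containing ``N``.
    """
    nt = parent.nucleotides
    J = parent.n_codons
    lam3 = rates.lam.reshape(J, 3)
    sub3 = rates.sub.reshape(J, 3, 4)
    parent_idx = np.empty(J, dtype=int)
    mask = np.empty(J, dtype=bool)
    for j, codon in enumerate(parent.codons):
        if "N" in codon:
            parent_idx[j] = -1
            mask[j] = False
        else:
            parent_idx[j] = CODON_INDEX[codon]
            mask[j] = True
    return lam3, sub3, parent_idx, mask


def per_position_vectors(lam3, sub3, parent_codon: str, t: float) -> np.ndarray:
    """(3, 4) matrix: probability of each base at each codon position after t."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    stay = np.exp(-np.asarray(lam3, float) * t)  # (3,)
    v = (1.0 - stay)[:, None] * np.asarray(sub3, float)  # (3, 4)
    for k, b in enumerate(parent_codon):
        v[k, NT_INDEX[b]] = stay[k]
    v[v < PROB_FLOOR] = 0.0
    return v


def codon_probs(lam3, sub3, t: float, parent_codon: str) -> np.ndarray:
    """Distribution over the 64 codons for one site after time ``t``.

    The probability of a target codon is the product over the three
    nucleotide positions of ``exp(-lambda_i t)`` where the base is unchanged
    and ``(1 - exp(-lambda_i t)) * s_{i,b}`` where it changes to ``b``.
    """
    lam3 = np.asarray(lam3, float).reshape(3)
    sub3 = np.asarray(sub3, float).reshape(3, 4)
    if any(b not in NT_INDEX for b in parent_codon):
        raise ValueError(f"parent codon {parent_codon!r} must be unambiguous")
    v = per_position_vectors(lam3, sub3, parent_codon, t)
    return np.einsum("a,b,c->abc", v[0], v[1], v[2]).reshape(64)


def neutral_codon_probs(
    parent: CodonSequence, provider: NeutralProvider, t: float
) -> np.ndarray:
    """(J, 64) neutral codon distribution per site; NaN rows at masked sites."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    rates = provider.rates(parent.nucleotides)
    lam3, sub3, parent_idx, mask = site_rate_arrays(parent, rates)
    stay = np.exp(-lam3 * t)  # (J, 3)
    v = (1.0 - stay)[..., None] * sub3  # (J, 3, 4)
    J = parent.n_codons
    rows = np.arange(J)
    for k in range(3):
        bases = np.array([NT_INDEX.get(c[k], -1) for c in parent.codons])
        ok = bases >= 0
        v[rows[ok], k, bases[ok]] = stay[rows[ok], k]
    probs = np.einsum("ja,jb,jc->jabc", v[:, 0], v[:, 1], v[:, 2]).reshape(J, 64)
    probs[probs < PROB_FLOOR] = 0.0
    probs[~mask] = np.nan
    return probs


def nonsyn_profile(
    parent: CodonSequence, provider: NeutralProvider, t: float
) -> np.ndarray:
    """Per-site neutral probability of a nonsynonymous substitution.

    ``p_j`` sums the codon distribution over codons coding a non-parent amino
    acid, excluding stops.  Codons containing N yield NaN (masked).
    """
    probs = neutral_codon_probs(parent, provider, t)
    _, _, parent_idx, mask = site_rate_arrays(parent, provider.rates(parent.nucleotides))
    p = np.full(parent.n_codons, np.nan)
    if mask.any():
        w = parent_idx[mask]
        p[mask] = np.einsum("jc,jc->j", probs[mask], NONSYN_MASK[w].astype(float))
    warn_all_masked(list(mask))
    return p


# ---------------------------------------------------------------------------
# k-mer rate estimation from out-of-frame (nonfunctional) sequence pairs
# ---------------------------------------------------------------------------

def estimate_kmer_rates(out_of_frame_pcps, k: int = 5) -> KmerNeutralProvider:
    """Estimate a k-mer context rate table from out-of-frame parent/child pairs.

    Out-of-frame rearrangements evolve without protein-level selection, so
    their substitutions estimate the neutral SHM process.  Under the unit
    branch-length convention (t = 1 per input pair) the per-context rate is
    ``-log(1 - mutated/occurrences)``; the substitution distribution over the
    three alternate bases uses add-one smoothing.  Unseen contexts fall back
    to the global average.  Contexts touching N or sequence ends are skipped.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    pcps = list(out_of_frame_pcps)
    if not pcps:
        raise ValueError("no input pairs")
    h = k // 2
    occ = defaultdict(int)
    mut = defaultdict(int)
    subcounts = defaultdict(lambda: np.zeros(4))
    for pcp in pcps:
        pnt, cnt = pcp.parent.nucleotides, pcp.child.nucleotides
        for i in range(h, len(pnt) - h):
            context = pnt[i - h : i + h + 1]
            if "N" in context or cnt[i] == "N":
                continue
            occ[context] += 1
            if cnt[i] != pnt[i]:
                mut[context] += 1
                subcounts[context][NT_INDEX[cnt[i]]] += 1
    if not occ:
        raise ValueError("no usable contexts in input pairs")

    table = {}
    for context, n in occ.items():
        m = mut[context]
        frac = min(m / n, 1.0 - 0.5 / n)  # guard: all-mutated context has finite rate
        rate = -math.log(1.0 - frac)
        center = NT_INDEX[context[h]]
        counts = subcounts[context].copy()
        counts += 1.0  # add-one smoothing over the three alternates
        counts[center] = 0.0
        table[context] = (rate, counts / counts.sum())

    rates = np.array([r for r, _ in table.values()])
    default_rate = float(rates.mean())
    default_sub = np.mean([s for _, s in table.values()], axis=0)
    default_sub = default_sub / default_sub.sum()
    return KmerNeutralProvider(table, k, default_rate, default_sub)
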