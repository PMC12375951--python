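"""Mutation-selection composition, losses, and joint fitting.

The mutation-selection transition probability at codon site ``j`` scales the
neutral codon distribution by the per-site selection factor:

* codons coding a non-parent amino acid: ``m_{j,c} = p_{j,c} * f_j``;
* synonymous non-parent codons: ``m_{j,c} = p_{j,c}`` (synonymous factors
  are fixed at 1);
* stop codons: ``m_{j,c} = 0``;
* the parent (WT) codon takes the remainder ``1 - sum`` of the others.

Because ``f_j`` is unbounded above, the scaled probabilities can exceed 1 in
rare cases; the total non-WT mass is then clamped to a little less than 1
(``1 - 1e-6``) and the event is counted, never silently ignored.

Two likelihoods coexist by design.  The neural network trains on a per-site
binary cross-entropy over nonsynonymous-substitution indicators (``m_j = f_j
* p_j`` with ``p_j`` the neutral nonsynonymous sum, precomputed and cached
after every branch-length round).  Branch lengths are optimized against the
full codon-level negative log likelihood, which sees synonymous substitutions
— this is what makes ``t`` and ``f`` jointly identifiable: a sequence rich in
synonymous change pulls ``t`` up and pushes the factors down.
"""

from __future__ import annotations

import dataclasses
from collections import namedtuple

import numpy as np
from scipy.optimize import minimize_scalar

from . import _nn
from ._nn import RMSprop, Tensor
from .neutral import (
    NONSYN_MASK,
    STOP_MASK,
    SYN_NONWT_MASK,
    NeutralProvider,
    neutral_codon_probs,
    nonsyn_profile,
)
from .seqcodec import (
    CODON_AA,
    PCP,
    STOP,
    CodonSequence,
    aa_substitution_indicators,
)
from .selection import PAD, SelectionModel, pad_token_batch

CLAMP = 1.0 - 1e-6
PROB_EPS = 1e-12
T_MIN, T_MAX = 1e-6, 5.0

# byte -> base index lookup (A,C,G,T -> 0..3; anything else -> -1)
_NT_LUT = np.full(256, -1, dtype=np.int64)
for _b, _i in zip(b"ACGT", range(4)):
    _NT_LUT[_b] = _i

_AA_OF_CODON = np.array(CODON_AA)
# codon -> amino-acid-class indicator matrix (64 x 21): columns 0..19 are the
# amino acids in vocabulary order, column 20 the stop class.  One matmul with
# it yields every per-site class mass, from which the nonsynonymous /
# synonymous splits follow without any per-WT-codon gather.
_AA_LIST = sorted(set(CODON_AA) - {STOP})
_AA_CODE = {a: i for i, a in enumerate(_AA_LIST)}
_CLASS64 = np.zeros((64, 21), dtype=np.float32)
for _c, _a in enumerate(CODON_AA):
    _CLASS64[_c, 20 if _a == STOP else _AA_CODE[_a]] = 1.0
_WT_CLASS = np.array([20 if a == STOP else _AA_CODE[a] for a in CODON_AA])


def _nt_indices(nt: str) -> np.ndarray:
    return _NT_LUT[np.frombuffer(nt.encode(), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# Mutation-selection probabilities
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MutSelProbs:
    """Per-site codon transition distribution under mutation + selection."""

    codon_probs: np.ndarray  # (J, 64), NaN rows at masked sites
    nonsyn: np.ndarray  # (J,) aggregate nonsynonymous probability m_j
    wt_idx: np.ndarray  # (J,) parent codon index, -1 at masked sites
    mask: np.ndarray  # (J,) usable sites
    clamped: np.ndarray  # (J,) True where the clamp activated


def mutsel_probs(
    neutral_probs: np.ndarray,
    parent: CodonSequence,
    profile: np.ndarray,
    clamp: float = CLAMP,
) -> MutSelProbs:
    """Compose neutral codon probabilities with a selection profile.

    ``neutral_probs`` is the (J, 64) per-site neutral codon distribution for
    ``parent``; ``profile`` the (J,) selection factors.  Sites masked in
    either input stay masked.
    """
    profile = np.asarray(profile, dtype=float)
    J = parent.n_codons
    if neutral_probs.shape != (J, 64) or profile.shape != (J,):
        raise ValueError("neutral probabilities and profile must match the parent length")

    wt_idx = np.full(J, -1, dtype=int)
    for j, codon in enumerate(parent.codons):
        if "N" not in codon:
            wt_idx[j] = (
                _NT_LUT[ord(codon[0])] * 16 + _NT_LUT[ord(codon[1])] * 4 + _NT_LUT[ord(codon[2])]
            )
    mask = (wt_idx >= 0) & ~np.isnan(profile) & ~np.isnan(neutral_probs).any(axis=1)

    m = np.full((J, 64), np.nan)
    nonsyn = np.full(J, np.nan)
    clamped = np.zeros(J, dtype=bool)
    if mask.any():
        w = wt_idx[mask]
        p = neutral_probs[mask]
        f = profile[mask][:, None]
        block = p * (NONSYN_MASK[w] * f + SYN_NONWT_MASK[w])
        total = block.sum(axis=1)
        over = total > clamp
        if over.any():
            block[over] *= (clamp / total[over])[:, None]
            total[over] = clamp
        block[np.arange(w.size), w] = 1.0 - total
        m[mask] = block
        nonsyn[mask] = (block * NONSYN_MASK[w]).sum(axis=1)
        clamped[mask] = over
    return MutSelProbs(m, nonsyn, wt_idx, mask, clamped)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def bce_terms(m: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Elementwise Bernoulli negative log likelihood; infinite where m
    contradicts an observed substitution (surfaced, not clipped)."""
    with np.errstate(divide="ignore"):
        return -np.where(y > 0, np.log(m), np.log1p(-m))


def pcp_loss(pcp: PCP, model: SelectionModel, provider: NeutralProvider, t: float) -> float:
    """Binary cross-entropy of one PCP's nonsynonymous indicators.

    ``loss = -sum_j [y_j log m_j + (1-y_j) log(1-m_j)]`` with ``m_j =
    min(f_j p_j, clamp)`` and ``y_j`` the amino-acid difference indicator;
    ambiguous sites are excluded.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    p = nonsyn_profile(pcp.parent, provider, t)
    f = model.factors(pcp.parent.aa)
    y, mask = aa_substitution_indicators(pcp)
    y = np.asarray(y, dtype=float)
    mask = np.asarray(mask) & ~np.isnan(p) & ~np.isnan(f)
    m = np.minimum(f * p, CLAMP)
    return float(bce_terms(m[mask], y[mask]).sum())


def codon_nll(pcp: PCP, model: SelectionModel, provider: NeutralProvider, t: float) -> float:
    """Full codon-level negative log likelihood of one PCP (used for t)."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    probs = neutral_codon_probs(pcp.parent, provider, t)
    f = model.factors(pcp.parent.aa)
    ms = mutsel_probs(probs, pcp.parent, f)
    nll = 0.0
    for j, (pc, cc) in enumerate(zip(pcp.parent.codons, pcp.child.codons)):
        if not ms.mask[j] or "N" in cc:
            continue
        ci = _NT_LUT[ord(cc[0])] * 16 + _NT_LUT[ord(cc[1])] * 4 + _NT_LUT[ord(cc[2])]
        with np.errstate(divide="ignore"):
            nll -= float(np.log(max(ms.codon_probs[j, ci], 0.0)))
    return nll


def initial_branch_length(pcp: PCP, provider: NeutralProvider) -> float:
    """Moment guess: observed nucleotide difference fraction over mean rate."""
    pa, ca = _nt_indices(pcp.parent.nucleotides), _nt_indices(pcp.child.nucleotides)
    ok = (pa >= 0) & (ca >= 0)
    frac = float((pa[ok] != ca[ok]).mean()) if ok.any() else 0.0
    mean_lam = float(provider.rates(pcp.parent.nucleotides).lam.mean())
    if mean_lam <= 0:
        return T_MIN
    return float(np.clip(frac / mean_lam, T_MIN, T_MAX))


BranchLengthResult = namedtuple("BranchLengthResult", ["t", "pinned", "nll"])


def optimize_branch_length(
    pcp: PCP,
    model: SelectionModel,
    provider: NeutralProvider,
    t_min: float = T_MIN,
    t_max: float = T_MAX,
    xatol: float = 1e-8,
) -> BranchLengthResult:
    """Maximum-likelihood branch length for one PCP, selection profile fixed.

    Scalar Brent minimization of the codon negative log likelihood on log t
    over ``[t_min, t_max]``; any branch length carried on the input tree is
    ignored.  If the pair carries no substitutions the optimum is pinned at
    ``t_min`` and flagged.
    """
    f = model.factors(pcp.parent.aa)
    probs_cache: dict[float, float] = {}

    def objective(log_t: float) -> float:
        t = float(np.exp(log_t))
        if t not in probs_cache:
            probs = neutral_codon_probs(pcp.parent, provider, t)
            ms = mutsel_probs(probs, pcp.parent, f)
            nll = 0.0
            for j, cc in enumerate(pcp.child.codons):
                if not ms.mask[j] or "N" in cc:
                    continue
                ci = (_NT_LUT[ord(cc[0])] * 16 + _NT_LUT[ord(cc[1])] * 4
                      + _NT_LUT[ord(cc[2])])
                with np.errstate(divide="ignore"):
                    nll -= float(np.log(max(ms.codon_probs[j, ci], PROB_EPS)))
            probs_cache[t] = nll
        return probs_cache[t]

    res = minimize_scalar(
        objective,
        bounds=(np.log(t_min), np.log(t_max)),
        method="bounded",
        options={"xatol": xatol},
    )
    t_star = float(np.exp(res.x))
    pinned = t_star <= t_min * (1.0 + 1e-3)
    return BranchLengthResult(t_star, pinned, float(res.fun))


# ---------------------------------------------------------------------------
# Vectorized dataset: stacked per-codon arrays grouped by sequence length
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class _Group:
    """All PCPs of one codon length J, stacked for vectorized evaluation."""

    idx: np.ndarray  # (N,) indices into the original PCP list
    J: int
    lam: np.ndarray  # (N, J, 3) float32 per-position rates
    sub: np.ndarray  # (N, J, 3, 4) float32 substitution distributions
    pos_base: np.ndarray  # (N, J, 3) parent base index (0 where masked)
    wt: np.ndarray  # (N, J) parent codon index (0 where masked)
    child: np.ndarray  # (N, J) child codon index (0 where masked)
    mask: np.ndarray  # (N, J) usable sites
    y: np.ndarray  # (N, J) nonsynonymous substitution indicator
    tokens: np.ndarray  # (U, J) amino-acid tokens of unique parents
    expand: np.ndarray  # (N,) PCP row -> unique-parent row
    parent_aa: list  # (U,) unique parent amino-acid strings

    @property
    def n(self) -> int:
        return self.idx.size


class PCPDataset:
    """Vectorized view of a PCP list for one neutral provider.

    Rates are looked up once per unique parent sequence; everything else is
    plain array arithmetic, chunked to bound memory.
    """

    chunk = 2048

    def __init__(self, groups: list[_Group], n: int):
        self.groups = groups
        self.n = n

    @classmethod
    def build(cls, pcps: list[PCP], provider: NeutralProvider) -> "PCPDataset":
        if not pcps:
            raise ValueError("empty PCP list")
        by_len: dict[int, list[int]] = {}
        for i, p in enumerate(pcps):
            by_len.setdefault(p.parent.n_codons, []).append(i)
        rate_cache: dict[str, tuple] = {}
        groups = []
        for J, idxs in sorted(by_len.items()):
            groups.append(cls._build_group(pcps, idxs, J, provider, rate_cache))
        return cls(groups, len(pcps))

    @staticmethod
    def _build_group(pcps, idxs, J, provider, rate_cache) -> _Group:
        N = len(idxs)
        lam = np.empty((N, J, 3), dtype=np.float32)
        sub = np.empty((N, J, 3, 4), dtype=np.float32)
        pos_base = np.zeros((N, J, 3), dtype=np.int64)
        wt = np.zeros((N, J), dtype=np.int64)
        child = np.zeros((N, J), dtype=np.int64)
        mask = np.zeros((N, J), dtype=bool)
        y = np.zeros((N, J), dtype=np.float32)
        uniq: dict[str, int] = {}
        expand = np.empty(N, dtype=np.int64)
        parent_aa: list[str] = []
        for r, i in enumerate(idxs):
            pcp = pcps[i]
            pnt = pcp.parent.nucleotides
            if pnt not in rate_cache:
                rates = provider.rates(pnt)
                rate_cache[pnt] = (
                    rates.lam.astype(np.float32).reshape(J, 3),
                    rates.sub.astype(np.float32).reshape(J, 3, 4),
                )
            lam[r], sub[r] = rate_cache[pnt]
            pi = _nt_indices(pnt).reshape(J, 3)
            ci = _nt_indices(pcp.child.nucleotides).reshape(J, 3)
            ok = (pi >= 0).all(axis=1) & (ci >= 0).all(axis=1)
            pos_base[r] = np.where(pi >= 0, pi, 0)
            wt_r = pos_base[r, :, 0] * 16 + pos_base[r, :, 1] * 4 + pos_base[r, :, 2]
            ci0 = np.where(ci >= 0, ci, 0)
            child_r = ci0[:, 0] * 16 + ci0[:, 1] * 4 + ci0[:, 2]
            # child stop codons carry probability 0; treat as unusable sites
            ok &= ~STOP_MASK[child_r] & ~STOP_MASK[wt_r]
            wt[r], child[r], mask[r] = wt_r, child_r, ok
            y[r] = ok & (_AA_OF_CODON[wt_r] != _AA_OF_CODON[child_r])
            aa = pcp.parent.aa
            if aa not in uniq:
                uniq[aa] = len(parent_aa)
                parent_aa.append(aa)
            expand[r] = uniq[aa]
        tokens, _ = pad_token_batch(parent_aa, max_len=max(J, 1))
        return _Group(np.array(idxs), J, lam, sub, pos_base, wt, child, mask, y,
                      tokens, expand, parent_aa)

    # -- factors ------------------------------------------------------------

    def factors(self, model: SelectionModel, batch: int = 1024) -> list[np.ndarray]:
        """Evaluation-mode selection factors expanded to PCP rows, per group."""
        out = []
        with _nn.no_grad():
            for g in self.groups:
                U = len(g.parent_aa)
                f_u = np.empty((U, g.J), dtype=np.float64)
                for s in range(0, U, batch):
                    tok = g.tokens[s : s + batch]
                    f_u[s : s + batch] = model.forward(tok, tok != PAD, train=False).data
                out.append(f_u[g.expand])
        return out

    # -- codon-level NLL and neutral sums ------------------------------------

    def _site_quantities(self, g: _Group, sl: slice, t: np.ndarray):
        """(p_ns, p_syn, p_child) neutral quantities for rows ``sl`` at ``t``.

        Built from amino-acid-class masses: with ``cm`` the probability mass
        of the WT amino-acid class and ``p_stop`` the stop-class mass,
        ``p_ns = 1 - cm - p_stop`` and ``p_syn = cm - p_wt``.
        """
        lam, sub = g.lam[sl], g.sub[sl]
        stay = np.exp(-lam * t[:, None, None].astype(np.float32))
        v = (1.0 - stay)[..., None] * sub
        np.put_along_axis(v, g.pos_base[sl][..., None], stay[..., None], axis=3)
        n = v.shape[0]
        pq = np.einsum("nja,njb->njab", v[:, :, 0], v[:, :, 1]).reshape(n, g.J, 16)
        probs = np.einsum("njk,njc->njkc", pq, v[:, :, 2]).reshape(n, g.J, 64)
        class_mass = probs.reshape(n * g.J, 64) @ _CLASS64  # (n*J, 21)
        class_mass = class_mass.reshape(n, g.J, 21)
        wt = g.wt[sl]
        cm_wt = np.take_along_axis(class_mass, _WT_CLASS[wt][..., None], axis=2)[..., 0]
        p_stop = class_mass[..., 20]
        p_wt = np.take_along_axis(probs, wt[..., None], axis=2)[..., 0]
        p_child = np.take_along_axis(probs, g.child[sl][..., None], axis=2)[..., 0]
        p_ns = np.maximum(1.0 - cm_wt - p_stop, 0.0)
        p_syn = np.maximum(cm_wt - p_wt, 0.0)
        return p_ns, p_syn, p_child

    def _group_nll(self, g: _Group, f: np.ndarray, t: np.ndarray) -> np.ndarray:
        """(N,) codon NLL for one group at per-PCP times ``t``."""
        nll = np.empty(g.n, dtype=np.float64)
        for s in range(0, g.n, self.chunk):
            sl = slice(s, min(s + self.chunk, g.n))
            p_ns, p_syn, p_child = self._site_quantities(g, sl, t[sl])
            fs = f[sl].astype(np.float32)
            total = fs * p_ns + p_syn
            scale = np.where(total > CLAMP, CLAMP / np.maximum(total, PROB_EPS), 1.0)
            is_wt = g.child[sl] == g.wt[sl]
            child_ns = _AA_OF_CODON[g.wt[sl]] != _AA_OF_CODON[g.child[sl]]
            m = np.where(
                is_wt,
                1.0 - np.minimum(total, CLAMP),
                scale * p_child * np.where(child_ns, fs, 1.0),
            )
            terms = np.log(np.maximum(m, PROB_EPS)) * g.mask[sl]
            nll[sl] = -terms.sum(axis=1)
        return nll

    def optimize_branch_lengths(
        self,
        model: SelectionModel,
        t_min: float = T_MIN,
        t_max: float = T_MAX,
        iters: int = 28,
    ):
        """Golden-section search on log t, vectorized over all PCPs.

        Returns ``(t, p_ns, clamp_fraction)``: per-PCP optimal times in
        original order, the neutral nonsynonymous sums at those times (per
        group, for caching), and the fraction of sites where the clamp is
        active at the optimum.
        """
        factors = self.factors(model)
        t_out = np.empty(self.n)
        p_ns_groups = []
        clamped, total_sites = 0, 0
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        invphi2 = 1.0 - invphi  # (3 - sqrt 5) / 2
        for g, f in zip(self.groups, factors):
            lo = np.full(g.n, np.log(t_min))
            hi = np.full(g.n, np.log(t_max))
            x1 = lo + invphi2 * (hi - lo)
            x2 = lo + invphi * (hi - lo)
            f1 = self._group_nll(g, f, np.exp(x1))
            f2 = self._group_nll(g, f, np.exp(x2))
            for _ in range(iters):
                take1 = f1 < f2
                lo = np.where(take1, lo, x1)
                hi = np.where(take1, x2, hi)
                h = hi - lo
                cand = np.where(take1, lo + invphi2 * h, lo + invphi * h)
                fcand = self._group_nll(g, f, np.exp(cand))
                x1, f1, x2, f2 = (
                    np.where(take1, cand, x2),
                    np.where(take1, fcand, f2),
                    np.where(take1, x1, cand),
                    np.where(take1, f1, fcand),
                )
            t_g = np.exp((lo + hi) / 2.0)
            t_out[g.idx] = t_g
            p_ns = np.empty((g.n, g.J), dtype=np.float64)
            for s in range(0, g.n, self.chunk):
                sl = slice(s, min(s + self.chunk, g.n))
                pn, psn, _ = self._site_quantities(g, sl, t_g[sl])
                p_ns[sl] = pn
                tot = f[sl] * pn + psn
                clamped += int(((tot > CLAMP) & g.mask[sl]).sum())
                total_sites += int(g.mask[sl].sum())
            p_ns_groups.append(p_ns)
        clamp_fraction = clamped / max(total_sites, 1)
        return t_out, p_ns_groups, clamp_fraction

    def nonsyn_expectations(self, model: SelectionModel, t: np.ndarray):
        """Per-site m_j = min(f_j p_j, clamp) at given per-PCP times.

        Returns per-group ``(rows, m, y, mask)`` with ``rows`` the original
        PCP indices — the expected/observed inputs of the site aggregation.
        """
        factors = self.factors(model)
        out = []
        for g, f in zip(self.groups, factors):
            m = np.empty((g.n, g.J))
            for s in range(0, g.n, self.chunk):
                sl = slice(s, min(s + self.chunk, g.n))
                p_ns, _, _ = self._site_quantities(g, sl, t[g.idx][sl])
                m[sl] = np.minimum(f[sl] * p_ns, CLAMP)
            out.append((g.idx, m, g.y.copy(), g.mask.copy()))
        return out


# ---------------------------------------------------------------------------
# Training loop: alternate branch-length rounds and RMSprop epochs
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainState:
    """Outcome of a fit: model, per-PCP branch lengths, cache, loss trace."""

    model: SelectionModel
    branch_lengths: np.ndarray
    nonsyn_cache: list  # per group, (N, J) neutral nonsynonymous sums
    loss_trace: list  # one record per cycle: train/val BCE per site
    cycles_done: int
    clamp_fraction: float
    val_idx: np.ndarray


def fit(
    pcps: list[PCP],
    model: SelectionModel,
    provider: NeutralProvider,
    cycles: int = 4,
    epochs_per_cycle: int = 2,
    batch_size: int = 512,
    lr: float = 1e-3,
    clip_norm: float | None = None,
    seed: int = 0,
    val_fraction: float = 0.1,
    dataset: PCPDataset | None = None,
    progress=None,
) -> TrainState:
    """Joint fit: alternate branch-length optimization and RMSprop training.

    Each cycle first re-optimizes every PCP's branch length under the current
    selection model, recomputes and caches the neutral nonsynonymous sums,
    then runs ``epochs_per_cycle`` epochs of RMSprop on the binary
    cross-entropy.  ``cycles=0`` returns the untouched model with branch
    lengths from a single optimization round.
    """
    if not pcps:
        raise ValueError("empty training set")
    ds = dataset or PCPDataset.build(pcps, provider)
    ss = np.random.SeedSequence(seed)
    rng_shuffle, rng_drop, rng_split = (np.random.default_rng(s) for s in ss.spawn(3))

    # deterministic validation split over unique parents of each group
    val_sel = []
    for g in ds.groups:
        U = len(g.parent_aa)
        n_val = int(round(val_fraction * U))
        val_u = np.zeros(U, dtype=bool)
        if n_val:
            val_u[rng_split.choice(U, size=n_val, replace=False)] = True
        val_sel.append(val_u)
    val_idx = np.concatenate(
        [g.idx[val_u[g.expand]] for g, val_u in zip(ds.groups, val_sel)]
    ) if ds.groups else np.array([], dtype=int)

    t, p_ns_groups, clamp_frac = ds.optimize_branch_lengths(model)
    if cycles == 0:
        return TrainState(model, t, p_ns_groups, [], 0, clamp_frac, val_idx)

    opt = RMSprop(model.parameters(), lr=lr, clip_norm=clip_norm)
    trace = []
    for cycle in range(cycles):
        if cycle > 0:
            t, p_ns_groups, clamp_frac = ds.optimize_branch_lengths(model)
        for epoch in range(epochs_per_cycle):
            train_loss = _train_epoch(ds, model, opt, p_ns_groups, val_sel,
                                      batch_size, rng_shuffle, rng_drop)
            if not np.isfinite(train_loss):
                raise RuntimeError(
                    f"divergent loss at cycle {cycle} epoch {epoch}: {train_loss}"
                )
        record = {
            "cycle": cycle,
            "train_loss": _eval_loss(ds, model, p_ns_groups, val_sel, want_val=False),
            "val_loss": _eval_loss(ds, model, p_ns_groups, val_sel, want_val=True),
            "clamp_fraction": clamp_frac,
        }
        trace.append(record)
        if progress:
            progress(record)
    return TrainState(model, t, p_ns_groups, trace, cycles, clamp_frac, val_idx)


def _batched_bce(model, tokens, expand, p, y, mask, train, rng):
    """Differentiable mean BCE for one batch of unique parents."""
    f_u = model.forward(tokens, tokens != PAD, train=train, rng=rng)
    f = _nn.take_rows(f_u, expand)
    m = _nn.clamp(_nn.mul(f, Tensor(p)), PROB_EPS, CLAMP)
    one = Tensor(np.float32(1.0))
    pos = _nn.mul(Tensor(y), _nn.log(m))
    neg = _nn.mul(Tensor(1.0 - y), _nn.log(_nn.sub(one, m)))
    nll = _nn.mul(_nn.add(pos, neg), Tensor(-mask.astype(np.float32)))
    denom = max(float(mask.sum()), 1.0)
    # keep the scale in float32: a float64 scalar here would upcast every
    # gradient in the backward pass
    return _nn.mul(_nn.sum_all(nll), Tensor(np.float32(1.0 / denom)))


def _train_epoch(ds, model, opt, p_ns_groups, val_sel, batch_size, rng_shuffle, rng_drop):
    total, count = 0.0, 0.0
    plan = []
    for gi, g in enumerate(ds.groups):
        train_u = np.flatnonzero(~val_sel[gi])
        rng_shuffle.shuffle(train_u)
        for s in range(0, train_u.size, batch_size):
            plan.append((gi, train_u[s : s + batch_size]))
    order = rng_shuffle.permutation(len(plan))
    for bi in order:
        gi, u_rows = plan[bi]
        g = ds.groups[gi]
        in_batch = np.isin(g.expand, u_rows)
        rows = np.flatnonzero(in_batch)
        if rows.size == 0:
            continue
        remap = -np.ones(len(g.parent_aa), dtype=np.int64)
        remap[u_rows] = np.arange(u_rows.size)
        expand = remap[g.expand[rows]]
        p = np.nan_to_num(p_ns_groups[gi][rows], nan=0.5).astype(np.float32)
        loss = _batched_bce(model, g.tokens[u_rows], expand, p,
                            g.y[rows], g.mask[rows], train=True, rng=rng_drop)
        opt.zero_grad()
        loss.backward()
        opt.step()
        total += float(loss.data) * g.mask[rows].sum()
        count += g.mask[rows].sum()
    return total / max(count, 1.0)


def _eval_loss(ds, model, p_ns_groups, val_sel, want_val: bool, batch: int = 1024):
    total, count = 0.0, 0.0
    for gi, g in enumerate(ds.groups):
        u_rows = np.flatnonzero(val_sel[gi] if want_val else ~val_sel[gi])
        for s in range(0, u_rows.size, batch):
            ub = u_rows[s : s + batch]
            rows = np.flatnonzero(np.isin(g.expand, ub))
            if rows.size == 0:
                continue
            remap = -np.ones(len(g.parent_aa), dtype=np.int64)
            remap[ub] = np.arange(ub.size)
            expand = remap[g.expand[rows]]
            p = np.nan_to_num(p_ns_groups[gi][rows], nan=0.5).astype(np.float32)
            with _nn.no_grad():
                loss = _batched_bce(model, g.tokens[ub], expand, p,
                                    g.y[rows], g.mask[rows], train=False, rng=None)
            total += float(loss.data) * g.mask[rows].sum()
            count += g.mask[rows].sum()
    return total / max(count, 1.0) if count else float("nan")
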