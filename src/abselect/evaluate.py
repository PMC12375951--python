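"""Goodness-of-fit and model-comparison metrics.

The central check aggregates, per aligned site, the *observed* number of
amino-acid substitutions across a PCP set against the *expected* number —
the sum of per-PCP substitution probabilities ``m_j`` — with a Bernoulli-sum
standard deviation ``sqrt(sum m_j (1 - m_j))``.  Agreement between the two
count histograms is summarized by the overlap statistic: the intersection of
the histograms divided by their average area (1 = identical, 0 = disjoint).

Model-vs-model agreement of selection factors is summarized on the log scale
by a coefficient of determination against the identity line y = x (not a
refitted regression line), in a symmetric form so the two models enter
interchangeably.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon

from .fitting import PCPDataset
from .neutral import NeutralProvider
from .seqcodec import PCP
from .selection import SelectionModel


def overlap(observed, expected) -> float:
    """Histogram overlap: sum of minima over the average total area."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape:
        raise ValueError("observed and expected must have equal length")
    if np.any(obs < 0) or np.any(exp < 0):
        raise ValueError("histograms must be nonnegative")
    denom = 0.5 * (obs.sum() + exp.sum())
    if denom == 0:
        raise ValueError("overlap undefined for two all-zero histograms")
    return float(np.minimum(obs, exp).sum() / denom)


def site_obs_exp(
    pcps: list[PCP],
    model: SelectionModel,
    provider: NeutralProvider,
    site_map: dict | None = None,
    grouping=None,
    dataset: PCPDataset | None = None,
) -> pd.DataFrame:
    """Observed vs expected substitution counts per aligned site per group.

    Every PCP must carry a branch length.  ``site_map`` maps ``(clone_id,
    site)`` to an aligned position label (e.g. an IMGT position supplied
    externally); sites it does not cover are dropped and counted in
    ``df.attrs["n_unmapped"]``.  ``grouping`` is a callable ``PCP -> label``
    (default: one pooled group).  Returns a tidy frame with columns
    ``group, site, observed, expected, sd``.
    """
    for i, p in enumerate(pcps):
        if p.branch_length is None:
            raise ValueError(f"PCP {i} has no branch length")
    ds = dataset or PCPDataset.build(pcps, provider)
    t = np.array([p.branch_length for p in pcps], dtype=float)

    glabels = [grouping(p) if grouping else "all" for p in pcps]
    label_codes = {g: c for c, g in enumerate(dict.fromkeys(glabels))}
    codes = np.array([label_codes[g] for g in glabels])
    inv_labels = list(label_codes)

    acc: dict[tuple, np.ndarray] = {}
    n_unmapped = 0
    for rows, m, y, mask in ds.nonsyn_expectations(model, t):
        if site_map is None:
            # fast path: bincount over (group code, site) cells
            J = m.shape[1]
            cell = codes[rows][:, None] * J + np.arange(J)[None, :]
            keep = mask.ravel()
            flat_cell = cell.ravel()[keep]
            nbins = len(inv_labels) * J
            obs = np.bincount(flat_cell, weights=y.ravel()[keep], minlength=nbins)
            exp_ = np.bincount(flat_cell, weights=m.ravel()[keep], minlength=nbins)
            var = np.bincount(flat_cell, weights=(m * (1.0 - m)).ravel()[keep],
                              minlength=nbins)
            touched = np.bincount(flat_cell, minlength=nbins)
            for cell_i in np.flatnonzero(touched):
                key = (inv_labels[cell_i // J], int(cell_i % J))
                slot = acc.setdefault(key, np.zeros(3))
                slot += (obs[cell_i], exp_[cell_i], var[cell_i])
        else:
            for r, pcp_i in enumerate(rows):
                pcp = pcps[pcp_i]
                for j in np.flatnonzero(mask[r]):
                    key = site_map.get((pcp.clone_id, int(j)))
                    if key is None:
                        n_unmapped += 1
                        continue
                    slot = acc.setdefault((glabels[pcp_i], key), np.zeros(3))
                    mj = m[r, j]
                    slot += (y[r, j], mj, mj * (1.0 - mj))
    records = [
        {"group": g, "site": s, "observed": v[0], "expected": v[1], "sd": np.sqrt(v[2])}
        for (g, s), v in sorted(acc.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1])))
    ]
    df = pd.DataFrame.from_records(records, columns=["group", "site", "observed", "expected", "sd"])
    df.attrs["n_unmapped"] = n_unmapped
    return df


def pooled_overlap(df: pd.DataFrame) -> float:
    """Headline overlap: all groups' sites pooled into one histogram pair."""
    return overlap(df["observed"].to_numpy(), df["expected"].to_numpy())


def per_group_overlap(df: pd.DataFrame) -> pd.Series:
    """Overlap within each group (secondary report alongside the pooled one)."""
    return df.groupby("group").apply(
        lambda d: overlap(d["observed"].to_numpy(), d["expected"].to_numpy()),
        include_groups=False,
    )


def log_factor_r2(model_a: SelectionModel, model_b: SelectionModel,
                  panel: list[str]) -> float:
    """Agreement of log selection factors with the identity line, pooled over
    every site of every panel sequence.

    Symmetric in the two models: residuals are taken to y = x and the total
    sum of squares pools both models' deviations from the grand mean.  Sites
    where either factor is 0 (log undefined) or masked are excluded; their
    count is reported in ``log_factor_r2.last_excluded``.
    """
    la_parts, lb_parts, excluded = [], [], 0
    for seq in panel:
        fa = model_a.factors(seq)
        fb = model_b.factors(seq)
        ok = np.isfinite(fa) & np.isfinite(fb) & (fa > 0) & (fb > 0)
        excluded += int((~ok).sum())
        la_parts.append(np.log(fa[ok]))
        lb_parts.append(np.log(fb[ok]))
    la = np.concatenate(la_parts)
    lb = np.concatenate(lb_parts)
    if la.size == 0:
        raise ValueError("no usable sites in panel")
    log_factor_r2.last_excluded = excluded
    ss_res = float(((la - lb) ** 2).sum())
    grand = float(np.concatenate([la, lb]).mean())
    ss_tot = float(((la - grand) ** 2).sum() + ((lb - grand) ** 2).sum())
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - 2.0 * ss_res / ss_tot


log_factor_r2.last_excluded = 0


def weighted_entropy(aa_counts, weights=None) -> np.ndarray:
    """Per-site Shannon entropy (bits) of weighted amino-acid counts.

    ``aa_counts`` is (sites, 20); optional ``weights`` multiply the counts
    elementwise (broadcastable).  All-zero sites yield NaN (masked).
    """
    counts = np.atleast_2d(np.asarray(aa_counts, dtype=float))
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if weights is not None:
        counts = counts * np.asarray(weights, dtype=float)
        if np.any(counts < 0):
            raise ValueError("weighted counts must be nonnegative")
    totals = counts.sum(axis=1)
    out = np.full(counts.shape[0], np.nan)
    live = totals > 0
    if live.any():
        out[live] = _shannon(counts[live], base=2, axis=1)
    return out
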