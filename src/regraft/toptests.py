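"""Topology tests from a site log-likelihood matrix: BP, KH, SH and AU.

All tests resample estimated log-likelihoods (RELL): bootstrap replicates
are drawn by resampling alignment columns of the precomputed site-wise
log-likelihood matrix rather than refitting trees.  The AU
(approximately unbiased) test extends this to a multiscale bootstrap:
replicates of size round(r * n_sites) are drawn at several scales r, the
per-scale bootstrap proportion BP(r) of each topology is converted to
z(r) = Phi^-1(1 - BP(r)), and a weighted least-squares fit of

    z(r) ~ d * sqrt(r) + c / sqrt(r)

estimates a signed distance d and curvature c, giving the p-value
p_AU = 1 - Phi(d - c).  The weights are the asymptotic inverse variances
B * phi(z)^2 / (BP * (1 - BP)).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from math import comb, factorial

import numpy as np
import pandas as pd
from scipy.stats import norm

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 10))
DEFAULT_REPLICATES = 10_000


class TopologyTestError(ValueError):
    pass


def _check_matrix(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise TopologyTestError("need a (topologies x sites) matrix with >= 2 rows")
    if not np.all(np.isfinite(M)):
        raise TopologyTestError("site log-likelihoods must be finite")
    return M


def _resample_counts(rng: np.random.Generator, n_sites: int, size: int, B: int) -> np.ndarray:
    """B multinomial column-count vectors for resamples of the given size."""
    return rng.multinomial(size, np.full(n_sites, 1.0 / n_sites), size=B)


def rell_bootstrap(
    M: np.ndarray,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    B: int = DEFAULT_REPLICATES,
    seed: int = 0,
    exhaustive: bool = False,
) -> np.ndarray:
    """Per-scale bootstrap proportions, shape (n_scales, n_topologies).

    At scale r, round(r * n_sites) columns are drawn with replacement and
    each topology's resampled log-likelihood is summed; BP_k(r) is the
    fraction of replicates in which topology k attains the maximum (ties
    going to the lowest row index).  With ``exhaustive=True`` every
    resample of the given size is enumerated with its multinomial weight
    instead of being sampled (for small matrices only).
    """
    M = _check_matrix(M)
    scales = tuple(scales)
    if any(r <= 0 for r in scales):
        raise TopologyTestError("scales must be positive")
    if not exhaustive and B < 100:
        raise TopologyTestError("B must be >= 100")
    K, n = M.shape
    out = np.zeros((len(scales), K))
    rng = np.random.default_rng(seed)
    for si, r in enumerate(scales):
        size = max(1, round(r * n))
        if exhaustive:
            total = 0.0
            probs = np.zeros(K)
            for combo in combinations_with_replacement(range(n), size):
                counts = np.bincount(combo, minlength=n)
                weight = factorial(size)
                for c in counts:
                    weight //= factorial(int(c))
                sums = M @ counts
                probs[int(np.argmax(sums))] += weight
                total += weight
            out[si] = probs / total
        else:
            counts = _resample_counts(rng, n, size, B)
            sums = counts @ M.T  # (B, K)
            win = np.argmax(sums, axis=1)
            out[si] = np.bincount(win, minlength=K) / B
    return out


@dataclass
class AUFit:
    """Result of the multiscale fit for one topology."""

    p: float
    d: float
    c: float
    rss: float
    n_used: int
    untestable: bool


def au_pvalues(
    bp_table: np.ndarray,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    B: int = DEFAULT_REPLICATES,
) -> list[AUFit]:
    """AU p-values from a per-scale BP table (n_scales x n_topologies).

    BP values are clamped to [1/(2B), 1 - 1/(2B)] as a continuity
    correction; a topology whose BP curve sits entirely on one boundary
    after clamping gets the corresponding boundary p-value (0 or 1).
    Topologies with fewer than two off-boundary scales are flagged
    untestable and also get the boundary value of their majority side.
    """
    bp_table = np.asarray(bp_table, float)
    scales_arr = np.asarray(scales, float)
    if bp_table.shape[0] != len(scales_arr):
        raise TopologyTestError("bp_table rows must match scales")
    lo, hi = 1.0 / (2 * B), 1.0 - 1.0 / (2 * B)
    results = []
    for k in range(bp_table.shape[1]):
        bp = bp_table[:, k]
        usable = (bp > lo) & (bp < hi)
        if usable.sum() < 2:
            p = 1.0 if bp.mean() >= 0.5 else 0.0
            results.append(AUFit(p=p, d=np.nan, c=np.nan, rss=np.nan,
                                 n_used=int(usable.sum()), untestable=True))
            continue
        bpc = np.clip(bp, lo, hi)
        z = norm.ppf(1.0 - bpc)
        wts = B * norm.pdf(z) ** 2 / (bpc * (1.0 - bpc))
        X = np.column_stack([np.sqrt(scales_arr), 1.0 / np.sqrt(scales_arr)])
        W = np.sqrt(wts)
        coef, res_, *_ = np.linalg.lstsq(X * W[:, None], z * W, rcond=None)
        d, c = float(coef[0]), float(coef[1])
        resid = z - X @ coef
        rss = float(np.sum(wts * resid**2))
        p = float(1.0 - norm.cdf(d - c))
        results.append(AUFit(p=p, d=d, c=c, rss=rss,
                             n_used=int(usable.sum()), untestable=False))
    return results


def kh_test(M: np.ndarray, i: int, j: int, B: int = DEFAULT_REPLICATES, seed: int = 0) -> float:
    """Kishino–Hasegawa RELL test of topology i against topology j.

    The per-site log-likelihood difference d = l_i - l_j is centred at its
    mean and bootstrap-resampled; the one-sided p-value is the fraction of
    centred replicate sums at least as large as the observed total
    difference.
    """
    M = _check_matrix(M)
    if i == j:
        raise TopologyTestError("need two distinct topologies")
    d = M[i] - M[j]
    obs = float(d.sum())
    n = d.size
    rng = np.random.default_rng(seed)
    counts = _resample_counts(rng, n, n, B)
    reps = counts @ (d - d.mean())
    # mid-p handling of ties so two identical site vectors give exactly 0.5
    return float(np.mean(reps > obs) + 0.5 * np.mean(reps == obs))


def sh_test(M: np.ndarray, B: int = DEFAULT_REPLICATES, seed: int = 0) -> np.ndarray:
    """Shimodaira–Hasegawa test: per-topology p-values against the ML tree.

    Replicate sums are centred per topology at their own mean; the
    observed lnL deficit of each topology to the best is compared with the
    distribution of max-over-topologies centred replicate deviations.
    """
    M = _check_matrix(M)
    K, n = M.shape
    totals = M.sum(axis=1)
    delta = totals.max() - totals  # >= 0, 0 for the best topology
    rng = np.random.default_rng(seed)
    counts = _resample_counts(rng, n, n, B)
    sums = counts @ M.T  # (B, K)
    centred = sums - sums.mean(axis=0)
    dmax = centred.max(axis=1)  # (B,)
    # deviation of topology k in each replicate: dmax - centred_k
    p = np.mean(dmax[:, None] - centred >= delta[None, :], axis=0)
    return p


def topology_test_report(
    M: np.ndarray,
    labels: list[str] | None = None,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    B: int = DEFAULT_REPLICATES,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full per-topology report: lnL, dlnL, BP, KH, SH, AU and rejection flag.

    KH p-values are computed against the maximum-likelihood topology; the
    ML topology's own KH entry is its test against the runner-up.
    """
    M = _check_matrix(M)
    K = M.shape[0]
    if labels is None:
        labels = [f"topo{k}" for k in range(K)]
    totals = M.sum(axis=1)
    best = int(np.argmax(totals))
    order = np.argsort(-totals, kind="stable")
    runner = int(order[1])
    bp = rell_bootstrap(M, scales=scales, B=B, seed=seed)
    scale1 = int(np.argmin(np.abs(np.asarray(scales) - 1.0)))
    fits = au_pvalues(bp, scales=scales, B=B)
    sh = sh_test(M, B=B, seed=seed + 1)
    kh = np.array([
        kh_test(M, best, k, B=B, seed=seed + 2) if k != best
        else kh_test(M, runner, best, B=B, seed=seed + 2)
        for k in range(K)
    ])
    df = pd.DataFrame(
        {
            "topology": labels,
            "lnL": totals,
            "delta_lnL": totals.max() - totals,
            "bp": bp[scale1],
            "kh": kh,
            "sh": sh,
            "au": [f.p for f in fits],
            "au_d": [f.d for f in fits],
            "au_c": [f.c for f in fits],
            "au_untestable": [f.untestable for f in fits],
        }
    )
    df["rejected"] = df["au"] < alpha
    return df


# ------------------------------------------------------- matrix file formats


def write_site_lnl_matrix(M: np.ndarray, path, labels: list[str] | None = None) -> None:
    """Write the (topologies x sites) matrix in the puzzle-style text layout
    consumed by multiscale-bootstrap tools: a header line ``n_topologies
    n_sites`` then one labelled row of site log-likelihoods per topology."""
    M = _check_matrix(M)
    K, n = M.shape
    if labels is None:
        labels = [f"topo{k}" for k in range(K)]
    with open(path, "w") as fh:
        fh.write(f"{K} {n}\n")
        for lab, row in zip(labels, M):
            fh.write(lab.replace(" ", "_") + " " + " ".join(f"{v:.8f}" for v in row) + "\n")


def read_site_lnl_matrix(path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        header = fh.readline().split()
        K, n = int(header[0]), int(header[1])
        labels, rows = [], []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    M = np.array(rows)
    if M.shape != (K, n):
        raise TopologyTestError(f"matrix shape {M.shape} does not match header {(K, n)}")
    return M, labels
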