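"""WAG(+F)+I+Gamma amino-acid substitution model.

The model is a general time-reversible CTMC on the 20 residues: a
symmetric exchangeability matrix S (the published WAG values, bundled as
data) combined with stationary frequencies pi gives the generator
Q_ij = S_ij * pi_j, normalised to one expected substitution per unit
branch length.  Among-site rate heterogeneity is the usual mixture of a
proportion ``p_inv`` of invariant sites (rate 0) with ``n_cat``
equal-weight discrete-gamma classes (class rate = conditional mean of a
Gamma(alpha, alpha) within each inter-quantile slice), rescaled so the
mixture mean rate is one.

Transition probabilities come from a symmetric eigendecomposition of Q in
the pi^{1/2} inner product, so a single decomposition serves every branch
length and rate class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
from scipy.stats import gamma as gamma_dist

from .alignment import AA_INDEX, AMINO_ACIDS, Alignment

N_STATES = 20


class ModelError(ValueError):
    """Raised for invalid model parameters."""


def load_wag() -> tuple[np.ndarray, np.ndarray]:
    """Return the WAG exchangeability matrix and stationary frequencies."""
    text = resources.files("regraft.data").joinpath("wag.txt").read_text()
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    order = lines[0].strip()
    S = np.zeros((N_STATES, N_STATES))
    for row, line in enumerate(lines[1:20], start=1):
        for col, val in enumerate(line.split()):
            S[row, col] = S[col, row] = float(val)
    pi = np.array([float(v) for v in lines[20].split()])
    # re-index from the file's residue order to ours (they coincide, but be safe)
    perm = [order.index(aa) for aa in AMINO_ACIDS]
    S = S[np.ix_(perm, perm)]
    pi = pi[perm]
    return S, pi / pi.sum()


def build_rate_matrix(S: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Normalised reversible generator Q from exchangeabilities and frequencies."""
    S = np.asarray(S, float)
    pi = np.asarray(pi, float)
    if S.shape != (N_STATES, N_STATES) or not np.allclose(S, S.T):
        raise ModelError("S must be a symmetric 20x20 matrix")
    off = S[~np.eye(N_STATES, dtype=bool)]
    if np.any(off < 0):
        raise ModelError("S off-diagonals must be non-negative")
    if pi.shape != (N_STATES,) or np.any(pi <= 0) or abs(pi.sum() - 1) > 1e-8:
        raise ModelError("pi must be a positive frequency vector summing to 1")
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(Q)))
    return Q / mu


def discretize_gamma(alpha: float, n_cat: int = 4) -> np.ndarray:
    """Mean-of-slice discrete gamma rates (equal weights, mean 1)."""
    if alpha <= 0:
        raise ModelError("gamma shape alpha must be > 0")
    if n_cat < 1:
        raise ModelError("n_cat must be >= 1")
    if n_cat == 1:
        return np.array([1.0])
    g = gamma_dist(a=alpha, scale=1.0 / alpha)
    cuts = g.ppf(np.linspace(0.0, 1.0, n_cat + 1))
    # conditional mean of each slice via the incomplete-gamma identity:
    # E[X; X<x] = P(alpha+1, alpha*x) / ... expressed with the cdf of shape+1
    g1 = gamma_dist(a=alpha + 1.0, scale=1.0 / alpha)
    upper = g1.cdf(cuts[1:])
    lower = g1.cdf(cuts[:-1])
    rates = (upper - lower) * n_cat  # each slice has probability 1/n_cat
    rates = np.maximum(rates, 0.0)
    return rates / (rates.mean())


@dataclass(frozen=True)
class RateClasses:
    """Relative rates and weights of the +I+Gamma mixture (mean rate 1)."""

    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        if abs(self.weights.sum() - 1) > 1e-9:
            raise ModelError("rate-class weights must sum to 1")


@dataclass(frozen=True)
class SubstitutionModel:
    """Exchangeabilities, frequencies and rate-heterogeneity parameters."""

    S: np.ndarray
    pi: np.ndarray
    alpha: float = 1.0
    p_inv: float = 0.0
    n_cat: int = 4

    def __post_init__(self):
        if not (0.0 <= self.p_inv < 1.0):
            raise ModelError("p_inv must lie in [0, 1)")
        if self.alpha <= 0:
            raise ModelError("alpha must be > 0")

    @classmethod
    def wag(cls, alpha: float = 1.0, p_inv: float = 0.0, n_cat: int = 4,
            pi: np.ndarray | None = None) -> "SubstitutionModel":
        S, pi_wag = load_wag()
        return cls(S=S, pi=pi_wag if pi is None else np.asarray(pi, float),
                   alpha=alpha, p_inv=p_inv, n_cat=n_cat)

    def with_params(self, **kw) -> "SubstitutionModel":
        return replace(self, **kw)

    # -------------------------------------------------------------- mixture
    def rate_classes(self) -> RateClasses:
        """Invariant class first (rate 0, weight p_inv), then gamma classes
        rescaled by 1/(1-p_inv) so the mixture mean rate is exactly 1."""
        grates = discretize_gamma(self.alpha, self.n_cat)
        if self.p_inv > 0.0:
            rates = np.concatenate([[0.0], grates / (1.0 - self.p_inv)])
            weights = np.concatenate(
                [[self.p_inv], np.full(self.n_cat, (1.0 - self.p_inv) / self.n_cat)]
            )
        else:
            rates = grates
            weights = np.full(self.n_cat, 1.0 / self.n_cat)
        return RateClasses(rates=rates, weights=weights)

    # ---------------------------------------------------------- CTMC algebra
    @property
    def Q(self) -> np.ndarray:
        return build_rate_matrix(self.S, self.pi)

    def eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eigenvalues, left factor, right factor) with
        P(t) = left @ diag(exp(lam t)) @ right."""
        pi = self.pi
        sq = np.sqrt(pi)
        A = (sq[:, None] * self.Q) / sq[None, :]
        A = 0.5 * (A + A.T)  # symmetrise away rounding
        lam, V = np.linalg.eigh(A)
        left = V / sq[:, None]
        right = V.T * sq[None, :]
        return lam, left, right

    def transition_matrix(self, t: float, eig=None) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, entries clipped to [0, 1]."""
        if t < 0:
            raise ModelError("branch length t must be >= 0")
        lam, left, right = eig if eig is not None else self.eigensystem()
        P = (left * np.exp(lam * t)[None, :]) @ right
        return np.clip(P, 0.0, 1.0)

    def transition_matrices(self, t: float, rates: np.ndarray, eig=None) -> np.ndarray:
        """Stack of P(t * r_k) over rate classes, shape (n_class, 20, 20)."""
        if t < 0:
            raise ModelError("branch length t must be >= 0")
        lam, left, right = eig if eig is not None else self.eigensystem()
        E = np.exp(np.outer(rates, lam) * t)  # (K, 20)
        P = np.einsum("ij,kj,jl->kil", left, E, right, optimize=True)
        return np.clip(P, 0.0, 1.0)


def empirical_frequencies(aln: Alignment, pseudocount: float = 1.0) -> np.ndarray:
    """Observed residue proportions (+F), with add-one smoothing so every
    frequency is strictly positive."""
    counts = np.zeros(N_STATES)
    for row in aln.rows:
        for ch in row:
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
    if counts.sum() == 0:
        raise ModelError("alignment has no unambiguous residues")
    counts += pseudocount
    return counts / counts.sum()
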