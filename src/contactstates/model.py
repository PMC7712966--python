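"""Bernoulli mixture model with a category-uniqueness prior.

Each frame i picks a latent conformational state z_i = k with probability
π_k and then sets each binary contact feature j independently with
probability μ_kj, so

    P(x, z | θ) = ∏_k π_k^{N_k} ∏_j μ_kj^{N_kj} (1 − μ_kj)^{N_k − N_kj},

with N_k the size of category k and N_kj its per-feature contact count.
The prior factorizes as a symmetric Dirichlet(α) on π (α = M + 1 by
default, M the pruned feature count), a flat Beta(1, 1) on every μ_kj, and
a uniqueness factor ∏_{k<l} (1 − B(μ_k, μ_l)) built from the Bhattacharyya
coefficient, which zeroes the density of any parameter set containing two
identical category prototypes.

All probability arithmetic is in log space; −inf is a value, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln, logsumexp, xlogy


@dataclass
class ModelParams:
    """Mixture parameters θ = (K, π, μ) plus the Dirichlet concentration α."""

    pi: np.ndarray
    mu: np.ndarray
    alpha: float

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float).ravel()
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        if self.mu.shape[0] != self.pi.size:
            raise ValueError("pi and mu disagree on the number of categories")
        if abs(self.pi.sum() - 1.0) > 1e-12 or (self.pi < 0).any():
            raise ValueError("pi must be a probability vector")
        if ((self.mu < 0) | (self.mu > 1)).any():
            raise ValueError("mu entries must lie in [0, 1]")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")

    @property
    def n_categories(self) -> int:
        return self.pi.size

    @property
    def n_features(self) -> int:
        return self.mu.shape[1]


def default_alpha(n_features: int) -> float:
    """α = M + 1: keeps the split/merge likelihood asymptotically
    insensitive to the number of features."""
    return float(n_features + 1)


def _as_x(fm) -> np.ndarray:
    """Accept a FeatureMatrix or a bare 0/1 array."""
    return fm.x if hasattr(fm, "x") else np.asarray(fm)


def suff_stats(fm, z, K: int):
    """Category sizes N_k and per-category contact counts N_kj.

    Labels are 0-based in {0, ..., K−1}; empty categories get N_k = 0.
    """
    x = _as_x(fm)
    z = np.asarray(z)
    if z.size and (z.min() < 0 or z.max() >= K):
        raise ValueError("assignment labels out of range")
    Nk = np.bincount(z, minlength=K).astype(np.int64)
    Nkj = np.zeros((K, x.shape[1]), dtype=np.int64)
    np.add.at(Nkj, z, x.astype(np.int64))
    return Nk, Nkj


def log_joint(fm, z, theta: ModelParams) -> float:
    """log P(x, z | θ), with the 0·log 0 = 0 convention.

    −inf when a zero-probability event (μ ∈ {0,1} against the data) has a
    positive count.
    """
    x = _as_x(fm)
    Nk, Nkj = suff_stats(x, z, theta.n_categories)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = xlogy(Nk, theta.pi).sum()
        term += xlogy(Nkj, theta.mu).sum()
        term += xlogy(Nk[:, None] - Nkj, 1.0 - theta.mu).sum()
    return float(term) if np.isfinite(term) else -np.inf


def log_resp_matrix(fm, theta: ModelParams, include_pi: bool = True) -> np.ndarray:
    """Unnormalized log responsibilities, shape (N, K).

    Row i holds log π_k + Σ_j [x_ij log μ_kj + (1−x_ij) log(1−μ_kj)].
    ``include_pi=False`` drops the mixture-weight factor (classification by
    prototypes alone), exposed for comparison.
    """
    x = _as_x(fm).astype(float)
    mu = theta.mu
    interior = (mu > 0).all() and (mu < 1).all()
    if interior:
        lmu, lmu0 = np.log(mu), np.log1p(-mu)
        ll = x @ lmu.T + (1.0 - x) @ lmu0.T
    else:
        # safe path for boundary prototypes: avoid 0·(−inf) inside matmul
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = (xlogy(x[:, None, :], mu[None]).sum(-1)
                  + xlogy(1.0 - x[:, None, :], 1.0 - mu[None]).sum(-1))
    if include_pi:
        with np.errstate(divide="ignore"):
            ll = ll + np.log(theta.pi)[None, :]
    return ll


def responsibilities(xi, theta: ModelParams, include_pi: bool = True) -> np.ndarray:
    """Posterior P(z_i = k | x_i, θ) over categories for one frame."""
    ll = log_resp_matrix(np.atleast_2d(xi), theta, include_pi=include_pi)[0]
    norm = logsumexp(ll)
    if not np.isfinite(norm):
        raise ValueError("datum impossible under every category")
    return np.exp(ll - norm)


def bhattacharyya(p, q) -> float:
    """B(p, q) = ∏_j [√(p_j q_j) + √((1−p_j)(1−q_j))] ∈ [0, 1].

    Per-feature this is the Bhattacharyya coefficient between two Bernoulli
    distributions; B(p, p) = 1 and B = 0 for disjoint support.
    """
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    if p.shape != q.shape:
        raise ValueError("vectors must have equal length")
    fac = np.sqrt(p * q) + np.sqrt((1.0 - p) * (1.0 - q))
    with np.errstate(divide="ignore"):
        return float(np.exp(np.sum(np.log(fac)))) if (fac > 0).all() else 0.0


def bhattacharyya_matrix(mu: np.ndarray) -> np.ndarray:
    """Pairwise B(μ_k, μ_l) for all category rows; shape (K, K)."""
    mu = np.atleast_2d(mu)
    a = np.sqrt(mu)[:, None, :] * np.sqrt(mu)[None, :, :]
    b = np.sqrt(1.0 - mu)[:, None, :] * np.sqrt(1.0 - mu)[None, :, :]
    with np.errstate(divide="ignore"):
        return np.exp(np.sum(np.log(a + b), axis=-1))


def log_uniqueness(mu: np.ndarray) -> float:
    """Σ_{k<l} log(1 − B_kl); −inf when two prototypes coincide."""
    K = np.atleast_2d(mu).shape[0]
    if K < 2:
        return 0.0
    B = bhattacharyya_matrix(mu)
    gap = 1.0 - B[np.triu_indices(K, k=1)]
    if (gap <= 0).any():  # duplicate prototypes (or fp rounding past 1)
        return -np.inf
    return float(np.sum(np.log(gap)))


def log_prior(theta: ModelParams) -> float:
    """log P(θ | I) up to a constant: Dirichlet(α) on π (flat Beta on μ
    contributes 0) plus the uniqueness factor."""
    K, a = theta.n_categories, theta.alpha
    with np.errstate(divide="ignore"):
        dir_term = gammaln(K * a) - K * gammaln(a) + (a - 1.0) * np.sum(np.log(theta.pi))
    if np.isnan(dir_term):  # pi_k = 0 with alpha < 1: density diverges; treat as -inf
        dir_term = -np.inf
    return float(dir_term + log_uniqueness(theta.mu))


def sample_theta_given_z(fm, z, K: int, rng, alpha: float = None) -> ModelParams:
    """Conjugate draw θ ~ P(θ | z, x, U): Dirichlet(N_k + α) weights and
    Beta(N_kj + 1, N_k − N_kj + 1) prototypes."""
    x = _as_x(fm)
    if alpha is None:
        alpha = default_alpha(x.shape[1])
    Nk, Nkj = suff_stats(x, z, K)
    return _sample_theta(Nk, Nkj, rng, alpha)


def _sample_theta(Nk, Nkj, rng, alpha: float) -> ModelParams:
    pi = rng.dirichlet(Nk + alpha)
    mu = rng.beta(Nkj + 1.0, (Nk[:, None] - Nkj) + 1.0)
    return ModelParams(pi=pi, mu=np.atleast_2d(mu), alpha=alpha)


def log_marginal(fm, z, K: int, alpha: float = None) -> float:
    """Collapsed log P(x, z | K, U): π and μ integrated out analytically.

    log Γ(Kα) − log Γ(N + Kα) + Σ_k [log Γ(N_k + α) − log Γ(α)]
        + Σ_{k,j} log Beta(N_kj + 1, N_k − N_kj + 1).

    This is the quantity whose ratios drive split/join acceptance.
    """
    x = _as_x(fm)
    if alpha is None:
        alpha = default_alpha(x.shape[1])
    Nk, Nkj = suff_stats(x, z, K)
    return log_marginal_from_stats(Nk, Nkj, alpha)


def log_marginal_from_stats(Nk, Nkj, alpha: float) -> float:
    Nk = np.asarray(Nk)
    K, N = Nk.size, int(Nk.sum())
    out = gammaln(K * alpha) - gammaln(N + K * alpha)
    out += np.sum(gammaln(Nk + alpha)) - K * gammaln(alpha)
    out += np.sum(betaln(Nkj + 1.0, (Nk[:, None] - Nkj) + 1.0))
    return float(out)


# ---------------------------------------------------------------------------
# serialization helpers

def export_prototypes_csv(path, theta: ModelParams, fm=None) -> None:
    """CSV of μ (categories × contact pairs) for inspection."""
    header = "category," + ",".join(
        f"{u}-{v}" for u, v in (fm.pairs if fm is not None
                                else [(j, j) for j in range(theta.n_features)])
    )
    rows = np.column_stack([np.arange(theta.n_categories), theta.mu])
    np.savetxt(path, rows, delimiter=",", header=header, comments="",
               fmt=["%d"] + ["%.6f"] * theta.n_features)
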