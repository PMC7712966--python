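"""Four-move MCMC over categorizations and mixture parameters.

Each sweep applies, in order:

1. **recategorize** — every frame's label z_i is redrawn from its
   responsibilities P(z_i = k | x_i, θ): an exact Gibbs step at fixed θ.
2. **reclassify** — θ is proposed from the conjugate posterior
   P(θ | z, x, U) and accepted with probability ∏_{k<l}(1 − B_kl), which
   leaves P(θ | z, x, I) invariant (the proposal density times the
   acceptance weight is symmetric in old and new θ).
3. **split or join** (50/50 when both exist) — a reversible-jump pair that
   changes K by ±1, accepted by a Metropolis ratio of collapsed marginals
   P(x, z | K, U) times the move-generation probabilities.  Splits pick a
   splittable category k and one of its non-constant features j, then send
   each member to the new category L with probability η^{x_ij}(1−η)^{1−x_ij}
   (degenerate all-L/all-R partitions are redrawn); the new category label
   is inserted at a uniformly chosen slot, and the matching join draws an
   ordered (keep, remove) label pair, so every join is the exact labeled
   inverse of a split and detailed balance holds.  An accepted dimension
   move is followed immediately by a reclassification at the new K.

The chain is restricted to surjective labelings: a recategorization draw
that would leave a category empty is rejected (see ``recategorize``), so K
always equals the number of occupied categories, 1 <= K <= N, and the
collapsed target of the dimension moves is P(x, z | K, U) over surjective
labeled states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .model import (ModelParams, _sample_theta, default_alpha, log_uniqueness,
                    log_marginal_from_stats)

_MU_EPS = 1e-15  # keep conjugate draws strictly interior for log-space matmuls


@dataclass
class SamplerConfig:
    """Chain protocol; the defaults are the reference protocol
    (5 chains × 1000 steps, burn-in 500, thin 10, η = 0.9, α = M + 1)."""

    n_steps: int = 1000
    n_chains: int = 5
    burn_in: int = 500
    thin: int = 10
    eta: float = 0.9
    split_join_prob: float = 0.5
    seed: int = 0
    alpha_override: float = None
    include_pi: bool = True
    uniqueness: bool = True

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_steps):
            raise ValueError("need 0 <= burn_in < n_steps")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (0.5 < self.eta < 1.0):
            raise ValueError("eta must lie in (0.5, 1.0)")


@dataclass
class PosteriorSample:
    """One retained posterior draw."""

    theta: ModelParams
    z: np.ndarray
    log_post: float
    chain_id: int
    step: int

    @property
    def k_nonempty(self) -> int:
        return int(np.unique(self.z).size)


@dataclass
class ChainState:
    """Current (θ, z) with cached sufficient statistics and log terms."""

    z: np.ndarray
    pi: np.ndarray
    mu: np.ndarray
    alpha: float
    Nk: np.ndarray
    Nkj: np.ndarray
    log_joint: float = -np.inf
    log_prior: float = -np.inf
    step: int = 0

    @property
    def K(self) -> int:
        return self.Nk.size

    @property
    def log_post(self) -> float:
        return self.log_joint + self.log_prior

    def theta(self) -> ModelParams:
        return ModelParams(pi=self.pi.copy(), mu=self.mu.copy(), alpha=self.alpha)


def _stats_from_z(xf: np.ndarray, z: np.ndarray, K: int):
    onehot = np.zeros((z.size, K))
    onehot[np.arange(z.size), z] = 1.0
    Nk = np.bincount(z, minlength=K).astype(np.int64)
    Nkj = np.rint(onehot.T @ xf).astype(np.int64)
    return Nk, Nkj


def _refresh_logs(state: ChainState) -> None:
    with np.errstate(divide="ignore"):
        lpi = np.log(state.pi)
        lmu, lmu0 = np.log(state.mu), np.log1p(-state.mu)
    lj = float(state.Nk @ lpi
               + np.sum(state.Nkj * lmu)
               + np.sum((state.Nk[:, None] - state.Nkj) * lmu0))
    K, a = state.K, state.alpha
    lp = float(gammaln(K * a) - K * gammaln(a) + (a - 1.0) * lpi.sum()
               + log_uniqueness(state.mu))
    state.log_joint = lj if np.isfinite(lj) else -np.inf
    state.log_prior = lp if np.isfinite(lp) else -np.inf


def _draw_theta(state: ChainState, rng) -> ModelParams:
    th = _sample_theta(state.Nk, state.Nkj, rng, state.alpha)
    th.mu = np.clip(th.mu, _MU_EPS, 1.0 - _MU_EPS)
    th.pi = np.clip(th.pi, 1e-300, None)
    th.pi = th.pi / th.pi.sum()
    return th


# ---------------------------------------------------------------------------
# moves

def recategorize(state: ChainState, xf: np.ndarray, rng,
                 include_pi: bool = True) -> bool:
    """Redraw every label from its responsibilities (in place).

    The chain lives on surjective labelings (every one of the K categories
    occupied), so K always counts real categories and split/join moves stay
    exactly reversible.  The joint draw from P(z | θ, x) is an independence
    proposal whose acceptance on that support is 1 if every category is
    occupied and 0 otherwise; a draw that would empty a category is
    therefore rejected and the previous z retained.
    """
    lmu, lmu0 = np.log(state.mu), np.log1p(-state.mu)
    ll = xf @ lmu.T + (1.0 - xf) @ lmu0.T
    if include_pi:
        ll += np.log(state.pi)[None, :]
    ll -= ll.max(axis=1, keepdims=True)
    p = np.exp(ll)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random((p.shape[0], 1))
    z = (np.cumsum(p, axis=1) < u).sum(axis=1)
    z = np.minimum(z, state.K - 1).astype(np.int64)
    if np.unique(z).size < state.K:
        return False
    state.z = z
    state.Nk, state.Nkj = _stats_from_z(xf, state.z, state.K)
    _refresh_logs(state)
    return True


def reclassify(state: ChainState, rng, uniqueness: bool = True) -> bool:
    """Propose θ' ~ P(θ | z, x, U); accept with probability ∏(1 − B_kl)."""
    th = _draw_theta(state, rng)
    if uniqueness and state.K >= 2:
        if rng.random() >= math.exp(log_uniqueness(th.mu)):
            return False
    state.pi, state.mu = th.pi, th.mu
    _refresh_logs(state)
    return True


def _splittable(Nk: np.ndarray, Nkj: np.ndarray) -> np.ndarray:
    """Categories with >= 2 members and at least one non-constant feature."""
    varies = ((Nkj > 0) & (Nkj < Nk[:, None])).any(axis=1)
    return np.nonzero((Nk >= 2) & varies)[0]


def _log_partition_prob(a1, a0, b1, b0, Nkj_nc, Nk_k, eta):
    """log Σ_j P̃_j(A, B): the probability that the η-Bernoulli rule with a
    uniformly chosen non-constant feature produces the ordered partition
    (A, B), each term renormalized for the degenerate-partition redraw."""
    leta, lneta = math.log(eta), math.log1p(-eta)
    logp = (a1 + b0) * leta + (a0 + b1) * lneta
    log_all_L = Nkj_nc * leta + (Nk_k - Nkj_nc) * lneta
    log_all_R = (Nk_k - Nkj_nc) * leta + Nkj_nc * lneta
    renorm = -np.log1p(-(np.exp(log_all_L) + np.exp(log_all_R)))
    return logsumexp(logp + renorm) - math.log(len(logp))


def _dirichlet_delta(N: int, K_old: int, K_new: int, alpha: float) -> float:
    return float(gammaln(K_new * alpha) - gammaln(N + K_new * alpha)
                 - gammaln(K_old * alpha) + gammaln(N + K_old * alpha))


def _betaln_rows(nj, n):
    from scipy.special import betaln
    return np.sum(betaln(nj + 1.0, (n - nj) + 1.0))


def propose_split(state: ChainState, x: np.ndarray, eta: float, rng):
    """Draw a split candidate; returns None when no category is splittable.

    The new category (the R set) takes label k+1, higher labels shift up,
    so the labeled outcome identifies the generating (category, partition)
    uniquely and the matching adjacent join is its exact inverse.  Returns
    (z', Nk', Nkj', info, log_gen) where log_gen is the log probability of
    generating exactly this outcome: category choice × Σ over feature
    choices of the η-Bernoulli partition probability, renormalized for the
    degenerate-partition redraw.
    """
    splittable = _splittable(state.Nk, state.Nkj)
    if splittable.size == 0:
        return None
    k = int(splittable[rng.integers(splittable.size)])
    nc = np.nonzero((state.Nkj[k] > 0) & (state.Nkj[k] < state.Nk[k]))[0]
    j = int(nc[rng.integers(nc.size)])
    members = np.nonzero(state.z == k)[0]
    xkj = x[members, j]
    p_left = np.where(xkj == 1, eta, 1.0 - eta)
    while True:
        left = rng.random(members.size) < p_left
        if left.any() and not left.all():
            break

    xk_nc = x[members][:, nc].astype(np.int64)
    a1 = xk_nc[left].sum(axis=0)
    b1 = xk_nc[~left].sum(axis=0)
    nA, nB = int(left.sum()), int(members.size - left.sum())
    log_gen = (-math.log(splittable.size)
               + _log_partition_prob(a1, nA - a1, b1, nB - b1,
                                     state.Nkj[k, nc], state.Nk[k], eta))

    # candidate labeling: R becomes k+1, labels above k shift up
    z_new = state.z + (state.z > k)
    z_new[members[~left]] = k + 1
    xA = x[members[left]].sum(axis=0, dtype=np.int64)
    xB = state.Nkj[k] - xA
    Nk_new = np.insert(state.Nk, k + 1, nB)
    Nk_new[k] = nA
    Nkj_new = np.insert(state.Nkj, k + 1, xB, axis=0)
    Nkj_new[k] = xA
    return z_new, Nk_new, Nkj_new, (k, nA, nB, xA, xB), log_gen


def propose_join(state: ChainState, rng):
    """Draw a join candidate: an adjacent label pair (k, k+1), k uniform on
    the K−1 choices; members of k+1 are relabeled to k and higher labels
    close the gap.  The exact inverse of a split at k.  None at K = 1."""
    K = state.K
    if K < 2:
        return None
    keep = int(rng.integers(K - 1))
    remove = keep + 1
    z_new = state.z.copy()
    z_new[z_new == remove] = keep
    z_new[z_new > remove] -= 1
    Nk_new = np.delete(state.Nk, remove)
    Nkj_new = np.delete(state.Nkj, remove, axis=0)
    Nk_new[keep] += state.Nk[remove]
    Nkj_new[keep] += state.Nkj[remove]
    log_gen = -math.log(K - 1)
    return z_new, Nk_new, Nkj_new, (keep, remove), log_gen


def split_join_step(state: ChainState, x: np.ndarray, xf: np.ndarray,
                    cfg: SamplerConfig, rng, diag: dict = None) -> bool:
    """One dimension-move attempt; returns True on an accepted K change."""
    diag = diag if diag is not None else {}
    N, alpha = state.z.size, state.alpha
    want_split = rng.random() < cfg.split_join_prob
    accepted = False

    if want_split:
        diag["split_attempts"] = diag.get("split_attempts", 0) + 1
        prop = propose_split(state, x, cfg.eta, rng)
        if prop is not None:
            z_new, Nk_new, Nkj_new, (k, nA, nB, xA, xB), log_gen = prop
            d_lm = (_dirichlet_delta(N, state.K, state.K + 1, alpha)
                    + gammaln(nA + alpha) + gammaln(nB + alpha)
                    - gammaln(state.Nk[k] + alpha) - gammaln(alpha)
                    + _betaln_rows(xA, nA) + _betaln_rows(xB, nB)
                    - _betaln_rows(state.Nkj[k], state.Nk[k]))
            log_gen_rev = -math.log(state.K)  # adjacent join choice at K+1
            log_r = d_lm + log_gen_rev - log_gen
            if math.log(rng.random()) < log_r:
                state.z, state.Nk, state.Nkj = z_new, Nk_new, Nkj_new
                accepted = True
                diag["split_accepts"] = diag.get("split_accepts", 0) + 1
    else:
        diag["join_attempts"] = diag.get("join_attempts", 0) + 1
        prop = propose_join(state, rng)
        if prop is not None:
            z_new, Nk_new, Nkj_new, (keep, remove), log_gen = prop
            nA, nB = int(state.Nk[keep]), int(state.Nk[remove])
            nc = np.nonzero((Nkj_new[keep] > 0)
                            & (Nkj_new[keep] < Nk_new[keep]))[0]
            if nA > 0 and nB > 0 and nc.size > 0:
                d_lm = (_dirichlet_delta(N, state.K, state.K - 1, alpha)
                        + gammaln(nA + nB + alpha) + gammaln(alpha)
                        - gammaln(nA + alpha) - gammaln(nB + alpha)
                        + _betaln_rows(Nkj_new[keep], nA + nB)
                        - _betaln_rows(state.Nkj[keep], nA)
                        - _betaln_rows(state.Nkj[remove], nB))
                splittable_new = _splittable(Nk_new, Nkj_new)
                a1 = state.Nkj[keep, nc]
                b1 = state.Nkj[remove, nc]
                log_gen_rev = (-math.log(splittable_new.size)
                               + _log_partition_prob(a1, nA - a1, b1, nB - b1,
                                                     Nkj_new[keep, nc],
                                                     nA + nB, cfg.eta))
                log_r = d_lm + log_gen_rev - log_gen
                if math.log(rng.random()) < log_r:
                    state.z, state.Nk, state.Nkj = z_new, Nk_new, Nkj_new
                    accepted = True
                    diag["join_accepts"] = diag.get("join_accepts", 0) + 1

    if accepted:
        # dimension changed: θ must be re-drawn at the new K, then a
        # standard reclassification is applied on top of the fresh draw
        th = _draw_theta(state, rng)
        state.pi, state.mu = th.pi, th.mu
        reclassify(state, rng, uniqueness=cfg.uniqueness)
    _refresh_logs(state)
    return accepted


# ---------------------------------------------------------------------------
# chain drivers

def init_state(fm, cfg: SamplerConfig, rng) -> ChainState:
    """All frames in one category, θ drawn from its conjugate posterior."""
    x = fm.x if hasattr(fm, "x") else np.asarray(fm)
    xf = np.ascontiguousarray(x, dtype=float)
    alpha = (cfg.alpha_override if cfg.alpha_override is not None
             else default_alpha(x.shape[1]))
    z = np.zeros(x.shape[0], dtype=np.int64)
    Nk, Nkj = _stats_from_z(xf, z, 1)
    state = ChainState(z=z, pi=np.ones(1), mu=np.zeros((1, x.shape[1])),
                       alpha=alpha, Nk=Nk, Nkj=Nkj)
    th = _draw_theta(state, rng)
    state.pi, state.mu = th.pi, th.mu
    _refresh_logs(state)
    return state


def run_chain(fm, cfg: SamplerConfig, chain_id: int = 0):
    """One chain; returns (samples, diagnostics).

    Fully reproducible from (cfg.seed, chain_id): each chain owns an
    independent generator seeded by the pair, so ensembles are identical
    under any execution order.
    """
    x = fm.x if hasattr(fm, "x") else np.asarray(fm)
    if x.shape[1] < 1:
        raise ValueError("feature matrix must have at least one column")
    xf = np.ascontiguousarray(x, dtype=float)
    rng = np.random.default_rng([int(cfg.seed), int(chain_id)])
    state = init_state(fm, cfg, rng)
    samples = []
    diag = {"k_trace": np.empty(cfg.n_steps, dtype=np.int64),
            "log_post_trace": np.empty(cfg.n_steps),
            "split_attempts": 0, "split_accepts": 0,
            "join_attempts": 0, "join_accepts": 0}
    for step in range(cfg.n_steps):
        state.step = step
        recategorize(state, xf, rng, include_pi=cfg.include_pi)
        reclassify(state, rng, uniqueness=cfg.uniqueness)
        split_join_step(state, x, xf, cfg, rng, diag)
        diag["k_trace"][step] = np.unique(state.z).size
        diag["log_post_trace"][step] = state.log_post
        if step >= cfg.burn_in and step % cfg.thin == 0:
            samples.append(PosteriorSample(theta=state.theta(),
                                           z=state.z.copy(),
                                           log_post=state.log_post,
                                           chain_id=chain_id, step=step))
    att = diag["split_attempts"] + diag["join_attempts"]
    acc = diag["split_accepts"] + diag["join_accepts"]
    diag["dimension_move_acceptance"] = acc / att if att else 0.0
    return samples, diag


def run_ensemble(fm, cfg: SamplerConfig):
    """Independent chains 0..n_chains−1; pooled samples tagged by chain."""
    samples, diags = [], []
    for cid in range(cfg.n_chains):
        s, d = run_chain(fm, cfg, chain_id=cid)
        samples.extend(s)
        diags.append(d)
    return samples, diags


# ---------------------------------------------------------------------------
# posterior container I/O (.npz with per-sample offsets; K varies by sample)

def write_posterior(path, samples) -> None:
    K = np.array([s.theta.n_categories for s in samples], dtype=np.int64)
    np.savez_compressed(
        path,
        z=np.array([s.z for s in samples], dtype=np.int64),
        K=K,
        pi=np.concatenate([s.theta.pi for s in samples]),
        mu=np.concatenate([s.theta.mu.ravel() for s in samples]),
        n_features=np.int64(samples[0].theta.n_features),
        alpha=np.float64(samples[0].theta.alpha),
        log_post=np.array([s.log_post for s in samples]),
        chain_id=np.array([s.chain_id for s in samples], dtype=np.int64),
        step=np.array([s.step for s in samples], dtype=np.int64),
    )


def read_posterior(path):
    with np.load(path, allow_pickle=False) as zf:
        K, M = zf["K"], int(zf["n_features"])
        off = np.concatenate([[0], np.cumsum(K)])
        out = []
        for i in range(K.size):
            pi = zf["pi"][off[i]:off[i + 1]]
            mu = zf["mu"][off[i] * M:off[i + 1] * M].reshape(K[i], M)
            out.append(PosteriorSample(
                theta=ModelParams(pi=pi, mu=mu, alpha=float(zf["alpha"])),
                z=zf["z"][i], log_post=float(zf["log_post"][i]),
                chain_id=int(zf["chain_id"][i]), step=int(zf["step"][i])))
        return out
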