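"""Bayesian inference of diffusive mobility states from pooled steps.

A molecule switching between K diffusive states emits, in state k, 2D
frame-to-frame displacements with independent Gaussian components of
per-axis variance 2*D_k*tau. The hidden state sequence of each
trajectory is a Markov chain with row-stochastic transition matrix T.
The sampler is a blocked Gibbs scheme on an overfitted finite hidden
Markov mixture (a weak-limit stand-in for the nonparametric sampler):

* per-trajectory state labels by forward-filtering backward-sampling,
  vectorized across trajectories of equal length;
* per-state variances (hence D_k) from a conjugate inverse-gamma update
  on pooled squared displacements;
* transition rows from sparse Dirichlet(1/K_init) posteriors, which
  lets redundant states empty out;
* state death by occupancy pruning (states holding fewer than
  ``min_occupancy`` of steps — default 2%, below which a mobility state
  is not meaningfully resolved at the recommended step counts — for
  ``patience`` consecutive sweeps are removed) plus a resolvability floor: adjacent states whose diffusion
  coefficients stay within a factor ``merge_ratio`` of each other for a
  patience window are treated as one mobility state and merged.
  Overfitted mixtures otherwise sustain satellite states that carve off
  the tail of a real state at a slightly offset D; physically distinct
  mobility states in this regime differ by well over 2x in D.

Samples are canonicalized by ascending D so summaries are free of label
switching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from nucleotrack.models import StepSeries

__all__ = [
    "GibbsPriors",
    "PosteriorSample",
    "GibbsChain",
    "PosteriorSummary",
    "gibbs_infer",
    "summarize",
    "classify_steps",
]

#: Below this many pooled steps the posterior is considered under-resolved
#: for multi-state inference and a warning is issued.
MIN_RECOMMENDED_STEPS = 45_000


@dataclass
class GibbsPriors:
    """Hyperparameters of the conjugate priors.

    ``sigma2_shape`` is the inverse-gamma shape on the per-axis emission
    variance 2*D*tau; the scale is set from the global mean squared
    displacement so the prior mean matches a one-state fit.
    ``dirichlet_conc`` is the per-entry concentration of the transition
    rows; the default 1/K_init is filled in at run time.
    """

    sigma2_shape: float = 2.0
    dirichlet_conc: float | None = None


@dataclass
class PosteriorSample:
    iteration: int
    K: int
    D: np.ndarray       # ascending
    pi: np.ndarray      # occupancy fractions, aligned with D
    T: np.ndarray       # (K, K), aligned with D
    sd_D: np.ndarray    # conditional posterior SD of each D


@dataclass
class GibbsChain:
    samples: list[PosteriorSample]
    n_iter: int
    burn_in: int
    tau: float
    label_counts: dict[int, np.ndarray] = field(default_factory=dict)
    degenerate: bool = False

    def post_burn_in(self) -> list[PosteriorSample]:
        return [s for s in self.samples if s.iteration >= self.burn_in]


@dataclass
class PosteriorSummary:
    K: int
    modal_fraction: float           # fraction of post-burn-in samples at modal K
    n_samples: int
    D_mean: np.ndarray
    D_sd: np.ndarray
    pi_mean: np.ndarray
    pi_sd: np.ndarray
    T_mean: np.ndarray
    T_sd: np.ndarray

    def to_dict(self) -> dict:
        return {
            "K": int(self.K),
            "modal_fraction": float(self.modal_fraction),
            "n_samples": int(self.n_samples),
            "D_mean": self.D_mean.tolist(),
            "D_sd": self.D_sd.tolist(),
            "pi_mean": self.pi_mean.tolist(),
            "pi_sd": self.pi_sd.tolist(),
            "T_mean": self.T_mean.tolist(),
            "T_sd": self.T_sd.tolist(),
        }


# ---------------------------------------------------------------------------


def _group_by_trajectory(steps: StepSeries) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group flat step indices by trajectory and by equal track length.

    Returns a list of (index_matrix, sq) pairs where index_matrix has
    shape (n_traj, L) of positions into the flat step arrays.
    """
    ids = steps.traj_id
    # contiguous runs of equal id
    change = np.flatnonzero(np.diff(ids)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(ids)]])
    lengths = ends - starts
    groups = []
    for L in np.unique(lengths):
        sel = lengths == L
        idx = starts[sel][:, None] + np.arange(L)[None, :]
        groups.append(idx)
    return groups


def _sample_rows(rng: np.random.Generator, p: np.ndarray) -> np.ndarray:
    """Sample one category per row of an unnormalized probability matrix."""
    c = np.cumsum(p, axis=1)
    u = rng.random(len(p)) * c[:, -1]
    return (u[:, None] > c).sum(axis=1)


def gibbs_infer(
    steps: StepSeries,
    n_iter: int = 10_000,
    k_init: int = 5,
    priors: GibbsPriors | None = None,
    seed: int | np.random.Generator = 0,
    burn_in_frac: float = 0.5,
    min_occupancy: float = 0.02,
    patience: int = 50,
    merge_ratio: float = 1.6,
    merge_warmup: int = 100,
    loc_noise_var: float = 0.0,
) -> GibbsChain:
    """Run the blocked Gibbs sampler on pooled step observations.

    Parameters
    ----------
    steps : StepSeries
        Pooled displacements (um) grouped by trajectory; tau in seconds.
    n_iter : int
        Total sweeps (burn-in included).
    k_init : int
        Overfitted initial state count; states can only die.
    loc_noise_var : float
        Optional fixed static localization-noise variance added to the
        per-axis emission variance, um^2. Default 0.

    Returns
    -------
    GibbsChain with one canonicalized sample per sweep and per-step
    marginal label counts accumulated post burn-in.
    """
    if len(steps) < 1000:
        raise ValueError("need at least 1000 steps for state inference")
    if len(steps) < MIN_RECOMMENDED_STEPS:
        warnings.warn(
            f"only {len(steps)} steps; at least {MIN_RECOMMENDED_STEPS} "
            "are recommended for stable multi-state inference",
            stacklevel=2,
        )
    priors = priors or GibbsPriors()
    rng = np.random.default_rng(seed)
    tau = steps.tau
    sq = steps.squared_displacements
    N = len(sq)
    burn_in = int(round(burn_in_frac * n_iter))
    conc = priors.dirichlet_conc if priors.dirichlet_conc is not None else 1.0 / k_init

    mean_sq = float(sq.mean())
    degenerate = mean_sq <= 0.0
    if degenerate:
        warnings.warn("all steps are zero; returning a prior-only posterior",
                      stacklevel=2)
        mean_sq = 1e-12
    a0 = priors.sigma2_shape
    b0 = (a0 - 1.0) * mean_sq / 2.0  # prior mean sigma^2 = global mean sq / 2

    groups = _group_by_trajectory(steps)

    # --- initialization: spread states over step-size quantiles
    K = k_init
    qs = np.quantile(sq, np.linspace(0, 1, K + 1))
    qs[-1] = np.inf
    z0 = np.clip(np.searchsorted(qs, sq, side="right") - 1, 0, K - 1)
    sigma2 = np.array([
        max(sq[z0 == k].mean() / 2.0 if np.any(z0 == k) else mean_sq / 2.0, 1e-12)
        for k in range(K)
    ])
    T = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(T, 0.9)
    init_dist = np.full(K, 1.0 / K)

    prune_counter = np.zeros(K, dtype=int)
    merge_counter: dict[frozenset[int], int] = {}

    samples: list[PosteriorSample] = []
    label_counts: dict[int, np.ndarray] = {}

    for sweep in range(n_iter):
        # --- emission log-likelihoods (N, K)
        var = sigma2[None, :]
        ll = -np.log(2.0 * np.pi * var) - sq[:, None] / (2.0 * var)
        lik = np.exp(ll - ll.max(axis=1, keepdims=True))

        # --- FFBS per length group, vectorized across trajectories
        z_flat = np.empty(N, dtype=np.int64)
        trans_counts = np.zeros((K, K))
        init_counts = np.zeros(K)
        for idx in groups:
            n_tr, L = idx.shape
            likg = lik[idx]                       # (n_tr, L, K)
            filt = np.empty_like(likg)
            alpha = init_dist[None, :] * likg[:, 0, :]
            alpha /= alpha.sum(axis=1, keepdims=True).clip(1e-300)
            filt[:, 0, :] = alpha
            for t in range(1, L):
                alpha = (alpha @ T) * likg[:, t, :]
                alpha /= alpha.sum(axis=1, keepdims=True).clip(1e-300)
                filt[:, t, :] = alpha
            z = np.empty((n_tr, L), dtype=np.int64)
            z[:, -1] = _sample_rows(rng, filt[:, -1, :])
            for t in range(L - 2, -1, -1):
                p = filt[:, t, :] * T[:, z[:, t + 1]].T
                z[:, t] = _sample_rows(rng, p)
            z_flat[idx.ravel()] = z.ravel()
            pair = z[:, :-1] * K + z[:, 1:]
            trans_counts += np.bincount(pair.ravel(), minlength=K * K).reshape(K, K)
            init_counts += np.bincount(z[:, 0], minlength=K)

        occ = np.bincount(z_flat, minlength=K).astype(float)
        S = np.bincount(z_flat, weights=sq, minlength=K)

        # --- conjugate updates
        a = a0 + occ
        b = b0 + S / 2.0
        sigma2 = b / rng.gamma(a)
        sigma2 = np.maximum(sigma2, 1e-14)
        sd_sigma2 = b / ((a - 1.0) * np.sqrt(np.maximum(a - 2.0, 1.0)))
        D = np.maximum((sigma2 - loc_noise_var), 1e-14) / (2.0 * tau)
        sd_D = sd_sigma2 / (2.0 * tau)

        T = np.vstack([rng.dirichlet(conc + trans_counts[k]) for k in range(K)])
        init_dist = rng.dirichlet(conc + init_counts)

        # --- record canonicalized sample
        order = np.argsort(D, kind="stable")
        pi_occ = occ / N
        sample = PosteriorSample(
            iteration=sweep, K=K,
            D=D[order].copy(), pi=pi_occ[order].copy(),
            T=T[np.ix_(order, order)].copy(), sd_D=sd_D[order].copy(),
        )
        samples.append(sample)

        if sweep >= burn_in:
            lc = label_counts.setdefault(K, np.zeros((N, K), dtype=np.int64))
            inv = np.empty(K, dtype=int)
            inv[order] = np.arange(K)
            np.add.at(lc, (np.arange(N), inv[z_flat]), 1)

        # --- state death: occupancy pruning
        if K > 1:
            low = pi_occ < min_occupancy
            prune_counter = np.where(low, prune_counter + 1, 0)
            kill = np.flatnonzero(prune_counter > patience)
            if len(kill):
                keep = np.setdiff1d(np.arange(K), kill)
                sigma2, prune_counter = sigma2[keep], prune_counter[keep]
                T = T[np.ix_(keep, keep)]
                T /= T.sum(axis=1, keepdims=True)
                init_dist = init_dist[keep] / init_dist[keep].sum()
                K = len(keep)
                merge_counter.clear()
                continue

        # --- state death: duplicate merging (adjacent in D)
        if K > 1 and sweep >= merge_warmup:
            order2 = np.argsort(D)
            merged = False
            for r in range(K - 1):
                i, j = int(order2[r]), int(order2[r + 1])
                key = frozenset((i, j))
                close = D[j] < merge_ratio * D[i] or abs(D[i] - D[j]) < 3.0 * float(
                    np.hypot(sd_D[i], sd_D[j])
                )
                c = merge_counter.get(key, 0)
                merge_counter[key] = c + 1 if close else max(0, c - 2)
                if merge_counter[key] > patience and not merged:
                    wi, wj = max(occ[i], 1.0), max(occ[j], 1.0)
                    sigma2[i] = (wi * sigma2[i] + wj * sigma2[j]) / (wi + wj)
                    T[:, i] += T[:, j]
                    T[i] = (wi * T[i] + wj * T[j]) / (wi + wj)
                    keep = np.setdiff1d(np.arange(K), [j])
                    sigma2 = sigma2[keep]
                    T = T[np.ix_(keep, keep)]
                    T /= T.sum(axis=1, keepdims=True)
                    init_dist[i] += init_dist[j]
                    init_dist = init_dist[keep]
                    prune_counter = prune_counter[keep]
                    K = len(keep)
                    merge_counter.clear()
                    merged = True
                    break

    return GibbsChain(
        samples=samples, n_iter=n_iter, burn_in=burn_in, tau=tau,
        label_counts=label_counts, degenerate=degenerate,
    )


def summarize(chain: GibbsChain, max_samples: int = 500) -> PosteriorSummary:
    """Posterior means/SDs over post-burn-in samples at the modal K.

    When more than ``max_samples`` post-burn-in samples exist at the
    modal K, an evenly thinned subset of that size is used.
    """
    post = chain.post_burn_in()
    if not post:
        raise ValueError("chain has no post-burn-in samples")
    ks = np.array([s.K for s in post])
    modal = int(np.bincount(ks).argmax())
    at_modal = [s for s in post if s.K == modal]
    frac = len(at_modal) / len(post)
    if len(at_modal) > max_samples:
        sel = np.linspace(0, len(at_modal) - 1, max_samples).astype(int)
        at_modal = [at_modal[i] for i in sel]
    D = np.stack([s.D for s in at_modal])
    pi = np.stack([s.pi for s in at_modal])
    T = np.stack([s.T for s in at_modal])
    return PosteriorSummary(
        K=modal, modal_fraction=frac, n_samples=len(at_modal),
        D_mean=D.mean(0), D_sd=D.std(0),
        pi_mean=pi.mean(0), pi_sd=pi.std(0),
        T_mean=T.mean(0), T_sd=T.std(0),
    )


def classify_steps(chain: GibbsChain, steps: StepSeries) -> np.ndarray:
    """Marginal posterior state probabilities per step at the modal K.

    Rows sum to 1; column order matches the ascending-D state order of
    the chain's summary.
    """
    post = chain.post_burn_in()
    ks = np.array([s.K for s in post])
    modal = int(np.bincount(ks).argmax())
    if modal not in chain.label_counts:
        raise ValueError("no accumulated labels at the modal state count")
    counts = chain.label_counts[modal].astype(float)
    if counts.shape[0] != len(steps):
        raise ValueError("step count does not match the chain's data")
    return counts / counts.sum(axis=1, keepdims=True)
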