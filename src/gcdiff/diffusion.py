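"""Variance-preserving joint diffusion over atom coordinates and features.

The forward process adds Gaussian noise to the joint state
``z = [z^(x), z^(h)]``; coordinate noise lives on the zero center-of-mass
subspace so the model's likelihood is translation invariant.  The reverse
process is ε-parametrized: a denoising network predicts the injected
noise, the clean state is recovered algebraically, and the true Gaussian
posterior of the transitions is used for each reverse step.

Schedules are variance preserving (α_t² + σ_t² = 1).  Note on the
transition variance: σ_{t|s}² = σ_t² − α_{t|s}² σ_s², the unique form
under which composing q(z_s|z_0) with q(z_t|z_s) reproduces the closed
form q(z_t|z_0) (checked by the Gaussian-composition oracle test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.stats import norm as _norm

from .mol import (Molecule, SizeDistribution, remove_com, sample_size,
                  ONEHOT_SCALE, CHARGE_SCALE)

__all__ = [
    "NoiseSchedule", "NoisySample", "TransitionCoeffs", "make_schedule",
    "transition_coeffs", "forward_sample", "posterior_params",
    "predict_clean", "reverse_step", "diffusion_loss", "sample_molecules",
    "nll",
]


@dataclass
class NoiseSchedule:
    """α_t / σ_t tables over T steps, variance preserving by construction."""

    T: int
    alphas: np.ndarray     # (T+1,)
    sigmas: np.ndarray     # (T+1,)
    kind: str = "polynomial"
    precision: float = 1e-5

    def snr(self, t: int) -> float:
        return float(self.alphas[t] ** 2 / self.sigmas[t] ** 2)


@dataclass
class NoisySample:
    """Joint latent at a time step; coordinates on the zero-CoM subspace."""

    zx: np.ndarray          # (N, 3)
    zh: np.ndarray          # (N, f)
    t: int

    def __post_init__(self):
        self.zx = np.asarray(self.zx, dtype=np.float64)
        self.zh = np.asarray(self.zh, dtype=np.float64)
        com = np.abs(self.zx.mean(axis=0)).max()
        if com > 1e-8:
            raise ValueError(f"coordinates are off the zero-CoM subspace "
                             f"(|mean| = {com:.2e})")


@dataclass
class TransitionCoeffs:
    alpha_ts: float
    sigma_ts: float


def _clip_ratio(alphas2: np.ndarray, clip_value: float = 0.001) -> np.ndarray:
    """Clamp stepwise α² ratios away from zero for numerical stability."""
    ratios = alphas2[1:] / alphas2[:-1]
    ratios = np.clip(ratios, clip_value, 1.0)
    return np.concatenate([[alphas2[0]], alphas2[0] * np.cumprod(ratios)])


def make_schedule(kind: str = "polynomial", T: int = 1000,
                  precision: float = 1e-5) -> NoiseSchedule:
    """Build a variance-preserving noise schedule.

    ``polynomial`` (default): α_t² ∝ (1 − (t/T)²)²; ``cosine``: the
    squared-cosine schedule.  Endpoints are clamped by ``precision`` so
    α never reaches 0 or 1 exactly.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    t = np.arange(T + 1, dtype=np.float64)
    if kind == "polynomial":
        alphas2 = (1.0 - (t / T) ** 2) ** 2
    elif kind == "cosine":
        s = 0.008
        f = np.cos(((t / T) + s) / (1 + s) * math.pi / 2) ** 2
        alphas2 = f / f[0]
    else:
        raise ValueError(f"unknown schedule kind {kind!r}")
    alphas2 = _clip_ratio(alphas2)
    alphas2 = (1.0 - 2.0 * precision) * alphas2 + precision
    alphas = np.sqrt(alphas2)
    sigmas = np.sqrt(1.0 - alphas2)
    return NoiseSchedule(T=T, alphas=alphas, sigmas=sigmas, kind=kind,
                         precision=precision)


def transition_coeffs(schedule: NoiseSchedule, s: int, t: int) -> TransitionCoeffs:
    """Coefficients of q(z_t | z_s): α_{t|s} = α_t/α_s, σ_{t|s}² = σ_t² − α_{t|s}² σ_s²."""
    if not 0 <= s < t <= schedule.T:
        raise ValueError(f"need 0 <= s < t <= T, got s={s}, t={t}")
    a = schedule.alphas[t] / schedule.alphas[s]
    var = schedule.sigmas[t] ** 2 - a**2 * schedule.sigmas[s] ** 2
    return TransitionCoeffs(alpha_ts=float(a),
                            sigma_ts=float(np.sqrt(max(var, 0.0))))


def forward_sample(z0: NoisySample, t: int, schedule: NoiseSchedule,
                   rng: np.random.Generator):
    """Draw z_t ~ q(z_t | z_0) in closed form; returns (z_t, ε).

    Coordinate noise is standard normal projected onto the zero-CoM
    subspace, so z_t^(x) stays on the subspace.
    """
    c = transition_coeffs(schedule, 0, t)
    eps_x = remove_com(rng.standard_normal(z0.zx.shape))
    eps_h = rng.standard_normal(z0.zh.shape)
    zt = NoisySample(
        zx=c.alpha_ts * z0.zx + c.sigma_ts * eps_x,
        zh=c.alpha_ts * z0.zh + c.sigma_ts * eps_h,
        t=t,
    )
    return zt, (eps_x, eps_h)


def posterior_params(zt: NoisySample, z0: NoisySample, s: int, t: int,
                     schedule: NoiseSchedule):
    """Moments of the true denoising posterior q(z_s | z_t, z_0)."""
    if not 0 <= s < t:
        raise ValueError(f"need s < t, got s={s}, t={t}")
    w0, wt, sigma = _posterior_weights(schedule, s, t)
    mu_x = w0 * z0.zx + wt * zt.zx
    mu_h = w0 * z0.zh + wt * zt.zh
    return (mu_x, mu_h), float(sigma)


def _posterior_weights(schedule: NoiseSchedule, s: int, t: int):
    """z0/zt weights and the posterior std of q(z_s | z_t, z_0).

    All quantities are relative to the t=0 latent (the σ_s, σ_t of the
    posterior formula are the s|0 and t|0 transition widths), keeping the
    Bayes inversion exact under the precision-clamped schedule where
    α_0 is slightly below 1.
    """
    cst = transition_coeffs(schedule, s, t)
    c0t = transition_coeffs(schedule, 0, t)
    if s == 0:
        a_s0, sig_s0 = 1.0, 0.0
    else:
        c0s = transition_coeffs(schedule, 0, s)
        a_s0, sig_s0 = c0s.alpha_ts, c0s.sigma_ts
    w0 = a_s0 * cst.sigma_ts**2 / c0t.sigma_ts**2
    wt = cst.alpha_ts * sig_s0**2 / c0t.sigma_ts**2
    sigma = cst.sigma_ts * sig_s0 / c0t.sigma_ts
    return w0, wt, sigma


def predict_clean(zt: NoisySample, eps_hat, t: int,
                  schedule: NoiseSchedule) -> NoisySample:
    """Invert the closed-form forward draw: z̃_0 = z_t/α_{t|0} − ε̂ σ_{t|0}/α_{t|0}.

    Uses the same (t|0) transition coefficients as :func:`forward_sample`,
    so feeding the true noise recovers z_0 to machine precision.
    """
    if t < 1:
        raise ValueError("predict_clean needs t >= 1")
    c = transition_coeffs(schedule, 0, t)
    if c.alpha_ts < 1e-12:
        raise FloatingPointError("alpha_t underflow in predict_clean")
    eps_x, eps_h = eps_hat
    return NoisySample(
        zx=zt.zx / c.alpha_ts - eps_x * (c.sigma_ts / c.alpha_ts),
        zh=zt.zh / c.alpha_ts - eps_h * (c.sigma_ts / c.alpha_ts),
        t=0,
    )


def reverse_step(zt: NoisySample, eps_hat, s: int, t: int,
                 schedule: NoiseSchedule, rng: np.random.Generator,
                 add_noise: bool = True) -> NoisySample:
    """One learned reverse transition p(z_s | z_t) with the ε̂ plug-in.

    Works for any s < t, including the strided grids used by time-scaled
    generation.  When ``add_noise`` is off (final decode), returns the
    posterior mean.
    """
    eps_x, eps_h = eps_hat
    if np.abs(eps_x.mean(axis=0)).max() > 1e-8:
        raise ValueError("predicted coordinate noise must be CoM-free")
    z0_tilde = predict_clean(zt, eps_hat, t, schedule)
    (mu_x, mu_h), sigma = posterior_params(zt, z0_tilde, s, t, schedule)
    if add_noise and sigma > 0:
        xi_x = remove_com(rng.standard_normal(mu_x.shape))
        xi_h = rng.standard_normal(mu_h.shape)
        mu_x = mu_x + sigma * xi_x
        mu_h = mu_h + sigma * xi_h
    return NoisySample(zx=remove_com(mu_x), zh=mu_h, t=s)


def diffusion_loss(eps, eps_hat, t: Optional[int] = None,
                   weight: float = 1.0) -> float:
    """Training objective ℒ_t = ½ w(t) ‖ε − ε̂‖²  (default w(t) = 1)."""
    eps_x, eps_h = eps
    ehat_x, ehat_h = eps_hat
    sq = np.sum((eps_x - ehat_x) ** 2) + np.sum((eps_h - ehat_h) ** 2)
    return 0.5 * weight * float(sq)


# -- batched sampling ---------------------------------------------------------

def _flat_remove_com(x: np.ndarray, seg: np.ndarray, n_mols: int) -> np.ndarray:
    counts = np.bincount(seg, minlength=n_mols).astype(np.float64)
    means = np.zeros((n_mols, x.shape[1]))
    np.add.at(means, seg, x)
    means /= counts[:, None]
    return x - means[seg]


def sample_molecules(model, n_mols: int, schedule: NoiseSchedule,
                     rng: np.random.Generator,
                     sizes: Optional[Sequence[int]] = None,
                     size_dist: Optional[SizeDistribution] = None,
                     condition: Optional[np.ndarray] = None,
                     n_steps: Optional[int] = None,
                     callback=None) -> List[Molecule]:
    """Generate molecules by iterating the learned reverse process.

    Starts from 𝒩(0, I) noise (coordinate part on the zero-CoM subspace)
    and runs T → 0; the final step decodes from the predicted clean state
    without added noise (argmax atom types, rounded charges).  A uniform
    subsampled time grid of ``n_steps`` points gives time-scaled
    generation.  All molecules are denoised in one flattened batch.
    """
    if sizes is None:
        if size_dist is None:
            raise ValueError("provide sizes or size_dist")
        sizes = [sample_size(size_dist, rng) for _ in range(n_mols)]
    sizes = [int(n) for n in sizes]
    if len(sizes) != n_mols:
        raise ValueError("len(sizes) must equal n_mols")
    if any(n < 1 for n in sizes):
        raise ValueError("molecule sizes must be >= 1")

    vocab = model.vocab
    f = len(vocab) + 1
    seg = np.repeat(np.arange(n_mols), sizes)
    n_tot = int(np.sum(sizes))

    zx = _flat_remove_com(rng.standard_normal((n_tot, 3)), seg, n_mols)
    zh = rng.standard_normal((n_tot, f))

    T = schedule.T
    if n_steps is None or n_steps >= T:
        grid = list(range(T, 0, -1))
    else:
        if n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        stride = math.ceil(T / n_steps)
        grid = list(range(T, 0, -stride))
    cond = None
    if condition is not None:
        cond = np.asarray(condition, dtype=np.float64)
        if cond.ndim == 1:
            cond = cond[:, None]

    for k, t in enumerate(grid):
        t_frac = np.full(n_mols, t / T)
        eps_x, eps_h = model.predict(zx, zh, seg, t_frac, cond=cond)
        s = grid[k + 1] if k + 1 < len(grid) else 0
        c_t = transition_coeffs(schedule, 0, t)
        z0x = zx / c_t.alpha_ts - eps_x * (c_t.sigma_ts / c_t.alpha_ts)
        z0h = zh / c_t.alpha_ts - eps_h * (c_t.sigma_ts / c_t.alpha_ts)
        if s == 0:
            zx, zh = z0x, z0h       # mean-only decode, no added noise
        else:
            w0, wt, sigma = _posterior_weights(schedule, s, t)
            zx = w0 * z0x + wt * zx + sigma * _flat_remove_com(
                rng.standard_normal(zx.shape), seg, n_mols)
            zh = w0 * z0h + wt * zh + sigma * rng.standard_normal(zh.shape)
        zx = _flat_remove_com(zx, seg, n_mols)
        if callback is not None:
            callback(t, zx, seg)

    mols = []
    offset = 0
    for n in sizes:
        sl = slice(offset, offset + n)
        mols.append(Molecule.from_features(zx[sl], zh[sl], vocab=vocab))
        offset += n
    return mols


# -- variational negative log-likelihood --------------------------------------

def _canonical_axes(x: np.ndarray) -> np.ndarray:
    """Equivariant canonical frame of a centered point cloud.

    Principal axes of the gyration tensor, ordered by eigenvalue, signs
    fixed by third moments, handedness fixed by the cross product.  Noise
    drawn in this frame makes the Monte-Carlo NLL estimate exactly
    rotation invariant while remaining N(0, I) distributed.
    """
    g = x.T @ x
    w, v = np.linalg.eigh(g)
    order = np.argsort(w)[::-1]
    v = v[:, order]
    for k in range(2):
        sk = np.sum((x @ v[:, k]) ** 3)
        if sk == 0.0:
            sk = np.sum((x @ v[:, k]))
        if sk < 0:
            v[:, k] = -v[:, k]
    v[:, 2] = np.cross(v[:, 0], v[:, 1])
    return v


def _gaussian_kl(mean_sq: float, sigma: float, d: int) -> float:
    """KL( N(μ, σ²I_d) ‖ N(0, I_d) ) with ‖μ‖² = mean_sq."""
    return 0.5 * (d * sigma**2 + mean_sq - d - d * np.log(sigma**2))


def nll(model, mol: Molecule, schedule: NoiseSchedule,
        size_dist: SizeDistribution, n_mc: int = 1,
        rng: Optional[np.random.Generator] = None,
        full_sum: bool = False,
        condition: Optional[np.ndarray] = None) -> float:
    """Variational bound on −log p(x, h, N).

    Terms: prior KL at T, diffusion terms for t in 1..T (Monte-Carlo over
    uniformly drawn t unless ``full_sum``), a reconstruction
    term at t = 0 (Gaussian for coordinates on the 3(N−1)-dimensional
    zero-CoM subspace, discretized Gaussian for one-hot types and integer
    charges), and −log p(N) from the size distribution.
    """
    rng = rng or np.random.default_rng(0)
    n = mol.n_atoms
    x = remove_com(mol.coords)
    h = mol.features()
    f = h.shape[1]
    d_x = 3 * (n - 1)
    d_h = n * f
    seg = np.zeros(n, dtype=np.int64)
    axes = _canonical_axes(x) if n > 2 else np.eye(3)

    def draw_eps():
        eps_x = remove_com(rng.standard_normal((n, 3)) @ axes.T)
        eps_h = rng.standard_normal((n, f))
        return eps_x, eps_h

    def model_eps(zx, zh, t):
        return model.predict(zx, zh, seg, np.array([t / schedule.T]),
                             cond=condition)

    total = -size_dist.log_prob(n)
    if not np.isfinite(total):
        return float("inf")

    T = schedule.T
    cT = transition_coeffs(schedule, 0, T)
    total += _gaussian_kl(cT.alpha_ts**2 * float(np.sum(x**2)),
                          cT.sigma_ts, d_x)
    total += _gaussian_kl(cT.alpha_ts**2 * float(np.sum(h**2)),
                          cT.sigma_ts, d_h)

    # diffusion terms, t = 2..T (t = 1 is covered by the reconstruction)
    def loss_term(t):
        c_t = transition_coeffs(schedule, 0, t)
        eps_x, eps_h = draw_eps()
        zx = c_t.alpha_ts * x + c_t.sigma_ts * eps_x
        zh = c_t.alpha_ts * h + c_t.sigma_ts * eps_h
        ehat_x, ehat_h = model_eps(zx, zh, t)
        sq = np.sum((eps_x - ehat_x) ** 2) + np.sum((eps_h - ehat_h) ** 2)
        w = schedule.snr(t - 1) / schedule.snr(t) - 1.0
        return 0.5 * w * sq

    if full_sum:
        total += sum(loss_term(t) for t in range(2, T + 1))
    else:
        acc = 0.0
        for _ in range(n_mc):
            t = int(rng.integers(2, T + 1))
            acc += (T - 1) * loss_term(t)
        total += acc / n_mc

    # reconstruction −log p(x, h | z_1)
    c1 = transition_coeffs(schedule, 0, 1)
    eps_x, eps_h = draw_eps()
    zx = c1.alpha_ts * x + c1.sigma_ts * eps_x
    zh = c1.alpha_ts * h + c1.sigma_ts * eps_h
    ehat_x, ehat_h = model_eps(zx, zh, 1)
    sig0 = c1.sigma_ts / c1.alpha_ts
    total += 0.5 * d_x * np.log(2 * np.pi * sig0**2) \
        + 0.5 * float(np.sum((eps_x - ehat_x) ** 2))
    h_est = (zh - c1.sigma_ts * ehat_h) / c1.alpha_ts

    # integer charges: discretized Gaussian around the predicted value
    q_est = h_est[:, -1] / CHARGE_SCALE
    sig_q = sig0 / CHARGE_SCALE
    p_int = (_norm.cdf((mol.charges + 0.5 - q_est) / sig_q)
             - _norm.cdf((mol.charges - 0.5 - q_est) / sig_q))
    total += -float(np.sum(np.log(np.clip(p_int, 1e-300, None))))

    # one-hot types: per-channel discretized Gaussian, normalized over classes
    oh_est = h_est[:, :-1] / ONEHOT_SCALE
    sig_o = sig0 / ONEHOT_SCALE
    centered = oh_est - 1.0
    logp_un = np.log(np.clip(
        _norm.cdf((centered + 0.5) / sig_o) - _norm.cdf((centered - 0.5) / sig_o),
        1e-300, None))
    log_z = _logsumexp(logp_un, axis=1)
    true_idx = np.argmax(mol.atom_types, axis=1)
    total += -float(np.sum(logp_un[np.arange(n), true_idx] - log_z))
    return float(total)


def _logsumexp(a, axis):
    amax = a.max(axis=axis, keepdims=True)
    return (amax + np.log(np.exp(a - amax).sum(axis=axis, keepdims=True))).squeeze(axis)
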