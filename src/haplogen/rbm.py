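"""Restricted Boltzmann machine with persistent contrastive divergence.

The model is the joint distribution ``P(v, h) ∝ exp(-E(v, h))`` over binary
visible units ``v`` (one per SNP) and hidden units ``h``, with

    E(v, h) = - Σ_ij W_ij v_i h_j - Σ_i a_i v_i - Σ_j b_j h_j,

so that a larger ``W_ij v_i h_j`` raises probability.  Hidden units are
either sigmoid (binary, Bernoulli conditionals) or ReLU (non-negative
continuous; conditioned on the visibles they follow a unit-variance
Gaussian truncated to [0, ∞)).  Training maximizes the visible likelihood
by PCD-k: the positive gradient term comes from the data batch, the
negative term from persistent Gibbs chains advanced ``k`` sweeps per
update (defaults: k = 10, 100 chains, batch size 32, learning rate in
[1e-4, 1e-3]).

For tiny models the module also provides the exact log-likelihood gradient
and visible marginal by full enumeration — the oracle PCD is tested
against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Optional

import numpy as np
from scipy.special import expit, log_ndtr, ndtr, ndtri
from scipy.stats import norm

from .haplotypes import HaplotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "RBMParams",
    "RBMConfig",
    "PCDState",
    "sample_hidden_given_visible",
    "sample_visible_given_hidden",
    "hidden_conditional_mean",
    "pcd_update",
    "exact_loglik_gradient",
    "exact_visible_marginal",
    "partition_function",
    "train_rbm",
    "sample_rbm",
    "hidden_encoding",
    "svd_axes",
    "project_hidden",
]


@dataclass
class RBMParams:
    """Weights ``W`` (N_v × N_h), visible/hidden biases, hidden-unit type."""

    W: np.ndarray
    visible_bias: np.ndarray
    hidden_bias: np.ndarray
    hidden_type: str = "relu"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.visible_bias = np.asarray(self.visible_bias, dtype=float)
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=float)
        if self.W.shape != (self.visible_bias.size, self.hidden_bias.size):
            raise ValueError("W shape inconsistent with bias lengths")
        if not (
            np.isfinite(self.W).all()
            and np.isfinite(self.visible_bias).all()
            and np.isfinite(self.hidden_bias).all()
        ):
            raise ValueError("parameters must be finite")
        if self.hidden_type not in ("sigmoid", "relu"):
            raise ValueError("hidden_type must be 'sigmoid' or 'relu'")

    @property
    def n_visible(self) -> int:
        return self.visible_bias.size

    @property
    def n_hidden(self) -> int:
        return self.hidden_bias.size

    @classmethod
    def initialize(
        cls,
        n_visible: int,
        n_hidden: int,
        hidden_type: str = "relu",
        seed: int = 0,
        weight_scale: float = 0.01,
    ) -> "RBMParams":
        rng = np.random.default_rng(seed)
        return cls(
            W=rng.normal(0.0, weight_scale, size=(n_visible, n_hidden)),
            visible_bias=np.zeros(n_visible),
            hidden_bias=np.zeros(n_hidden),
            hidden_type=hidden_type,
        )


@dataclass
class RBMConfig:
    n_hidden: int = 100
    hidden_type: str = "relu"
    learning_rate: float = 5e-4
    batch_size: int = 32
    pcd_k: int = 10
    n_chains: int = 100
    epochs: int = 100
    weight_scale: float = 0.01  # init sd of W; raise to speed symmetry breaking
    probe_interval: int = 0  # 0 disables the AA_TS probe
    stop_at_aats: bool = False
    aats_band: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hidden", "batch_size", "pcd_k", "n_chains", "epochs"):
            if getattr(self, name) < 1 and not (name == "epochs" and self.epochs == 0):
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 1e-4 <= self.learning_rate <= 1e-3:
            logger.warning(
                "learning_rate %g outside the usual [1e-4, 1e-3] range",
                self.learning_rate,
            )


@dataclass
class PCDState:
    """Visible states of the persistent Gibbs chains (n_chains × N_v, 0/1)."""

    visible: np.ndarray

    def __post_init__(self) -> None:
        self.visible = np.asarray(self.visible, dtype=np.int8)
        if not np.isin(self.visible, (0, 1)).all():
            raise ValueError("chain states must be binary")


def _hidden_input(params: RBMParams, v: np.ndarray) -> np.ndarray:
    return v @ params.W + params.hidden_bias


def hidden_conditional_mean(params: RBMParams, v: np.ndarray) -> np.ndarray:
    """E[h | v]: sigmoid probability, or the truncated-normal mean for ReLU."""
    mu = _hidden_input(params, v.astype(float))
    if params.hidden_type == "sigmoid":
        return expit(mu)
    # mean of N(mu, 1) truncated to [0, inf): mu + phi(mu)/Phi(mu)
    return mu + np.exp(norm.logpdf(mu) - log_ndtr(mu))


def sample_hidden_given_visible(
    params: RBMParams, v: np.ndarray, seed: int | np.random.Generator = 0
) -> np.ndarray:
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mu = _hidden_input(params, v.astype(float))
    if params.hidden_type == "sigmoid":
        return (rng.random(mu.shape) < expit(mu)).astype(np.int8)
    # N(mu, 1) truncated to [0, inf) by inverse-CDF: fast and exact for the
    # moderate |mu| reached in training
    lo = ndtr(-mu)
    u = rng.random(mu.shape)
    x = mu + ndtri(np.clip(lo + u * (1.0 - lo), 1e-16, 1.0 - 1e-16))
    return np.maximum(x, 0.0)


def sample_visible_given_hidden(
    params: RBMParams, h: np.ndarray, seed: int | np.random.Generator = 0
) -> np.ndarray:
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = expit(h @ params.W.T + params.visible_bias)
    return (rng.random(p.shape) < p).astype(np.int8)


def _gibbs_sweeps(
    params: RBMParams, v: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    for _ in range(k):
        h = sample_hidden_given_visible(params, v, rng)
        v = sample_visible_given_hidden(params, h, rng)
    return v


def pcd_update(
    params: RBMParams,
    state: PCDState,
    batch: np.ndarray,
    cfg: RBMConfig,
    rng: np.random.Generator | int = 0,
) -> tuple[RBMParams, PCDState]:
    """One PCD-k gradient-ascent step.

    Positive statistics use the data batch with Rao-Blackwellized hidden
    means; negative statistics use the persistent chains advanced ``k``
    alternating Gibbs sweeps.  Chains persist across calls.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    vd = batch.astype(float)
    hd = hidden_conditional_mean(params, vd)

    vc = _gibbs_sweeps(params, state.visible, cfg.pcd_k, rng)
    hc = hidden_conditional_mean(params, vc.astype(float))

    n, m = vd.shape[0], vc.shape[0]
    gW = vd.T @ hd / n - vc.T.astype(float) @ hc / m
    ga = vd.mean(axis=0) - vc.mean(axis=0)
    gb = hd.mean(axis=0) - hc.mean(axis=0)
    if not (np.isfinite(gW).all() and np.isfinite(ga).all() and np.isfinite(gb).all()):
        raise FloatingPointError("non-finite PCD gradient")

    lr = cfg.learning_rate
    new = RBMParams(
        W=params.W + lr * gW,
        visible_bias=params.visible_bias + lr * ga,
        hidden_bias=params.hidden_bias + lr * gb,
        hidden_type=params.hidden_type,
    )
    return new, PCDState(visible=vc)


def _free_energy(params: RBMParams, V: np.ndarray) -> np.ndarray:
    """-log Σ_h exp(-E(v, h)) for each row of V (sigmoid hidden units)."""
    mu = _hidden_input(params, V.astype(float))
    return -V @ params.visible_bias - np.logaddexp(0.0, mu).sum(axis=1)


def _enumerate_visible(n_visible: int) -> np.ndarray:
    return np.array(list(product((0, 1), repeat=n_visible)), dtype=float)


def _check_enumerable(params: RBMParams) -> None:
    if params.hidden_type != "sigmoid":
        raise ValueError("exact enumeration requires sigmoid (binary) hidden units")
    if params.n_visible + params.n_hidden > 20:
        raise ValueError("model too large for exact enumeration (N_v + N_h > 20)")


def partition_function(params: RBMParams) -> float:
    """Z = Σ_{v,h} exp(-E(v,h)), by enumerating visible states."""
    _check_enumerable(params)
    V = _enumerate_visible(params.n_visible)
    return float(np.exp(-_free_energy(params, V)).sum())


def exact_visible_marginal(params: RBMParams) -> np.ndarray:
    """P(v) for every visible state, in lexicographic enumeration order."""
    _check_enumerable(params)
    V = _enumerate_visible(params.n_visible)
    logp = -_free_energy(params, V)
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


def exact_loglik_gradient(
    params: RBMParams, data: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact gradient of the mean visible log-likelihood (enumeration).

    Returns ``(dW, d_visible_bias, d_hidden_bias)``.  Only feasible for
    sigmoid hidden units and ``N_v + N_h <= 20``.
    """
    _check_enumerable(params)
    data = np.asarray(data, dtype=float)
    V = _enumerate_visible(params.n_visible)
    p = exact_visible_marginal(params)

    hd = hidden_conditional_mean(params, data)
    hm = hidden_conditional_mean(params, V)
    dW = data.T @ hd / data.shape[0] - (V * p[:, None]).T @ hm
    da = data.mean(axis=0) - p @ V
    db = hd.mean(axis=0) - p @ hm
    return dW, da, db


def train_rbm(
    M: HaplotypeMatrix,
    cfg: RBMConfig,
    probe: Optional[Callable[[int, RBMParams, float], None]] = None,
) -> tuple[RBMParams, dict]:
    """Minibatch PCD training; returns the parameters and a history dict.

    If ``cfg.probe_interval`` > 0 the AA_TS score between the persistent
    chains (the model's running sample) and an equal-sized random subset of
    the training data is recorded every interval; with ``stop_at_aats`` the
    run halts once two consecutive probes land within ``aats_band`` of the
    optimum 0.5.
    """
    from .metrics import adversarial_accuracy, nearest_neighbor_profile

    rng = np.random.default_rng(cfg.seed)
    X = M.values
    n = X.shape[0]
    if cfg.batch_size > n:
        raise ValueError("batch larger than dataset")
    params = RBMParams.initialize(
        M.n_snps, cfg.n_hidden, hidden_type=cfg.hidden_type, seed=cfg.seed,
        weight_scale=cfg.weight_scale,
    )
    state = PCDState(visible=X[rng.integers(n, size=cfg.n_chains)])
    history = {"epoch": [], "grad_norm": [], "probe_epoch": [], "aats": []}
    ok_probes = 0

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n - cfg.batch_size + 1, cfg.batch_size):
            batch = X[order[start:start + cfg.batch_size]]
            params, state = pcd_update(params, state, batch, cfg, rng)
        history["epoch"].append(epoch)
        history["grad_norm"].append(float(np.abs(params.W).mean()))

        if cfg.probe_interval and epoch % cfg.probe_interval == 0:
            size = min(cfg.n_chains, n)
            ref = HaplotypeMatrix(values=X[rng.choice(n, size=size, replace=False)])
            art = HaplotypeMatrix(values=state.visible[:size])
            aats = adversarial_accuracy(nearest_neighbor_profile(ref, art))[2]
            history["probe_epoch"].append(epoch)
            history["aats"].append(aats)
            if probe is not None:
                probe(epoch, params, aats)
            if cfg.stop_at_aats:
                ok_probes = ok_probes + 1 if abs(aats - 0.5) <= cfg.aats_band else 0
                if ok_probes >= 2:
                    break
    return params, history


def sample_rbm(
    params: RBMParams,
    n: int,
    init: str = "random",
    init_data: Optional[HaplotypeMatrix] = None,
    n_gibbs: int = 100,
    seed: int = 0,
) -> HaplotypeMatrix:
    """Sample ``n`` visible states after ``n_gibbs`` alternating Gibbs sweeps.

    ``init`` chooses the chain start: ``random`` (fair-coin visibles),
    ``train_set`` or ``sampling_set`` (rows of ``init_data``; starting from
    an independent sampling set rather than the training set reduces the
    overfitting the training-set start exacerbates).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if init == "random":
        v = rng.integers(2, size=(n, params.n_visible)).astype(np.int8)
    elif init in ("train_set", "sampling_set"):
        if init_data is None:
            raise ValueError(f"init={init!r} requires init_data")
        rows = np.resize(np.arange(init_data.n_haplotypes), n)
        v = init_data.values[rows].copy()
    else:
        raise ValueError(f"unknown init scheme {init!r}")
    v = _gibbs_sweeps(params, v, n_gibbs, rng)
    return HaplotypeMatrix(values=v)


def hidden_encoding(params: RBMParams, M: HaplotypeMatrix) -> np.ndarray:
    """Noise-free latent code: E[h | v] per haplotype (n_haplotypes × N_h)."""
    return hidden_conditional_mean(params, M.values.astype(float))


def svd_axes(params: RBMParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of W: (visible axes U, hidden axes V, singular values).

    Columns of U live in SNP space; columns of V span the hidden
    representation.  Dominant visible axes resemble principal components,
    while projections onto dominant hidden axes can separate structure
    more cleanly thanks to the non-linear hidden activations.
    """
    U, s, Vt = np.linalg.svd(params.W, full_matrices=False)
    return U, Vt.T, s


def project_hidden(params: RBMParams, M: HaplotypeMatrix, n_axes: int = 2) -> np.ndarray:
    """Project haplotypes onto the top hidden axes (non-linear reduction)."""
    _, V, _ = svd_axes(params)
    return hidden_encoding(params, M) @ V[:, :n_axes]
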