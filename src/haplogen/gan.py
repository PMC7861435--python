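"""Fully connected GAN for artificial genomes.

Generator: latent(600) -> round(L/1.2) -> round(L/1.1) -> L with LeakyReLU
(alpha 0.01) hidden activations and tanh output.  Discriminator:
L -> round(L/2) -> round(L/3) -> 1 with LeakyReLU hidden activations and a
sigmoid output.  Both train with Adam on binary cross-entropy; L2 weight
decay 1e-4; batch size 32; discriminator learning rate 8e-4 and combined
(generator) learning rate 1e-4, dropping tenfold for panels of 5000+ SNPs.
During discriminator updates the real labels are smoothed into [0.9, 1.0]
by a uniform draw.  Generated outputs are rounded to {0, 1}.

An adversarial-accuracy probe (AA_TS between a fresh artificial sample and
a held-out quarter of the data) is recorded every ``probe_interval`` epochs;
by default training runs to ``max_epochs``, with an optional early-stop
policy that halts once the probe sits within a band around the optimum 0.5
for two consecutive probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .haplotypes import HaplotypeMatrix
from .nn import Adam, DenseNet, bce_grad, bce_loss

__all__ = ["GANConfig", "GANModel", "build_gan", "train_gan", "generate_gan", "hidden_widths"]

LARGE_PANEL_SNPS = 5000  # learning rates drop tenfold at this panel size


def _round_half_away(x: float) -> int:
    """round() with exact halves going away from zero (805/2 -> 403)."""
    return int(np.floor(x + 0.5))


def hidden_widths(n_snps: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """(generator, discriminator) hidden-layer widths for an ``n_snps`` panel."""
    gen = (_round_half_away(n_snps / 1.2), _round_half_away(n_snps / 1.1))
    disc = (_round_half_away(n_snps / 2), _round_half_away(n_snps / 3))
    return gen, disc


@dataclass
class GANConfig:
    n_snps: int = 0
    latent_dim: int = 600
    leaky_alpha: float = 0.01
    l2: float = 1e-4
    lr_disc: Optional[float] = None  # default 8e-4, or 8e-5 for >=5000 SNPs
    lr_gan: Optional[float] = None  # default 1e-4, or 1e-5 for >=5000 SNPs
    batch_size: int = 32
    max_epochs: int = 20000
    smoothing_range: tuple[float, float] = (0.0, 0.1)
    probe_interval: int = 200
    train_fraction: float = 0.75  # 3:1 train:test split
    data_mode: str = "unit"  # "unit": 0/1 data, threshold 0.5; "signed": ±1, threshold 0
    stop_at_aats: bool = False
    aats_band: float = 0.05
    restore_best_probe: bool = True  # return the checkpoint whose probe is nearest 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.batch_size < 1 or self.max_epochs < 0:
            raise ValueError("counts must be positive")
        if self.n_snps > 0:
            # resolve learning-rate defaults once the panel size is known
            if self.lr_disc is None:
                self.lr_disc = 8e-5 if self.n_snps >= LARGE_PANEL_SNPS else 8e-4
            if self.lr_gan is None:
                self.lr_gan = 1e-5 if self.n_snps >= LARGE_PANEL_SNPS else 1e-4
        for lr in (self.lr_disc, self.lr_gan):
            if lr is not None and lr <= 0:
                raise ValueError("learning rates must be positive")
        lo, hi = self.smoothing_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("smoothing_range must lie within [0, 1]")
        if self.data_mode not in ("unit", "signed"):
            raise ValueError("data_mode must be 'unit' or 'signed'")

    @property
    def gen_hidden(self) -> tuple[int, int]:
        return hidden_widths(self.n_snps)[0]

    @property
    def disc_hidden(self) -> tuple[int, int]:
        return hidden_widths(self.n_snps)[1]


@dataclass
class GANModel:
    config: GANConfig
    generator: DenseNet
    discriminator: DenseNet
    history: dict = field(default_factory=dict)


def build_gan(cfg: GANConfig) -> GANModel:
    """Construct generator and discriminator with seeded initialization."""
    if cfg.n_snps < 4:
        raise ValueError("n_snps must be >= 4 (hidden sizes degenerate below)")
    gen_h, disc_h = hidden_widths(cfg.n_snps)
    # L2 weight decay applies to the hidden layers only, not the outputs
    gen = DenseNet(
        sizes=(cfg.latent_dim, gen_h[0], gen_h[1], cfg.n_snps),
        activations=("leaky_relu", "leaky_relu", "tanh"),
        leaky_alpha=cfg.leaky_alpha,
        l2=cfg.l2,
        l2_layers=(0, 1),
    )
    disc = DenseNet(
        sizes=(cfg.n_snps, disc_h[0], disc_h[1], 1),
        activations=("leaky_relu", "leaky_relu", "sigmoid"),
        leaky_alpha=cfg.leaky_alpha,
        l2=cfg.l2,
        l2_layers=(0, 1),
    )
    rng = np.random.default_rng(cfg.seed)
    gen.init_params(rng)
    disc.init_params(rng)
    return GANModel(config=cfg, generator=gen, discriminator=disc)


def _threshold(raw: np.ndarray, mode: str) -> np.ndarray:
    cut = 0.5 if mode == "unit" else 0.0
    return (raw > cut).astype(np.int8)


def generate_gan(model: GANModel, n: int, seed: int = 0) -> HaplotypeMatrix:
    """Sample ``n`` artificial haplotypes: N(0,1) latents, rounded outputs."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, model.config.latent_dim))
    raw = model.generator.forward(z)
    return HaplotypeMatrix(values=_threshold(raw, model.config.data_mode))


def train_gan(
    M: HaplotypeMatrix,
    cfg: GANConfig,
    callbacks: Optional[list[Callable[[int, "GANModel"], None]]] = None,
) -> GANModel:
    """Adversarial training with label smoothing and the AA_TS probe.

    The data are split haplotype-wise 3:1 (seeded); training uses the first
    split, the probe compares fresh artificial samples against the held-out
    split every ``probe_interval`` epochs.  Adversarial quality oscillates
    between epochs, so by default the returned model is the recorded
    checkpoint whose probe score sits closest to the optimum 0.5
    (``restore_best_probe=False`` returns the final epoch instead);
    training itself always runs to ``max_epochs`` unless ``stop_at_aats``
    halts it.  Deterministic given ``cfg.seed``.
    """
    from .metrics import (
        adversarial_accuracy,
        joint_pca,
        nearest_neighbor_profile,
        wasserstein_2d,
    )

    cfg = GANConfig(**{**cfg.__dict__, "n_snps": M.n_snps})
    model = build_gan(cfg)
    # the split permutation is drawn from cfg.seed alone so an external 3:1
    # split made with the same seed selects exactly the same rows
    perm = np.random.default_rng(cfg.seed).permutation(M.n_haplotypes)
    rng = np.random.default_rng(cfg.seed + 1)
    n_train = max(cfg.batch_size, int(round(cfg.train_fraction * M.n_haplotypes)))
    if n_train > M.n_haplotypes:
        raise ValueError("dataset smaller than one batch")
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    train_binary = M.values[train_idx].copy()
    X = train_binary.astype(float)
    if cfg.data_mode == "signed":
        X = 2.0 * X - 1.0
    held_out = M.values[test_idx].copy()

    gen, disc = model.generator, model.discriminator
    opt_d = Adam(disc.params, lr=cfg.lr_disc)
    opt_g = Adam(gen.params, lr=cfg.lr_gan)
    bs = cfg.batch_size
    lo, hi = cfg.smoothing_range
    history = {
        "epoch": [], "d_loss": [], "g_loss": [],
        "probe_epoch": [], "aats": [], "probe_w2": [],
    }
    ok_probes = 0
    best = None  # (probe score, generator params, discriminator params)

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n_train)
        d_losses, g_losses = [], []
        for start in range(0, n_train - bs + 1, bs):
            real = X[order[start:start + bs]]
            z = rng.standard_normal((bs, cfg.latent_dim))
            fake = gen.forward(z)

            # --- discriminator: one step on real (smoothed labels), one on fake ---
            d_loss = 0.0
            for batch, labels in (
                (real, 0.9 + rng.uniform(lo, hi, size=(bs, 1))),
                (fake, np.zeros((bs, 1))),
            ):
                pred, zs, acts = disc.forward(batch, cache=True)
                d_loss += 0.5 * bce_loss(pred, labels)
                grads, _ = disc.backward(zs, acts, bce_grad(pred, labels))
                opt_d.step(grads)

            # --- generator step through the frozen discriminator ---
            z = rng.standard_normal((bs, cfg.latent_dim))
            fake, g_zs, g_acts = gen.forward(z, cache=True)
            pred, d_zs, d_acts = disc.forward(fake, cache=True)
            ones = np.ones((bs, 1))
            g_loss = bce_loss(pred, ones)
            _, grad_fake = disc.backward(d_zs, d_acts, bce_grad(pred, ones))
            g_grads, _ = gen.backward(g_zs, g_acts, grad_fake)
            opt_g.step(g_grads)

            if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} (d={d_loss}, g={g_loss})"
                )
            d_losses.append(d_loss)
            g_losses.append(g_loss)

        history["epoch"].append(epoch)
        history["d_loss"].append(float(np.mean(d_losses)))
        history["g_loss"].append(float(np.mean(g_losses)))

        if cfg.probe_interval and epoch % cfg.probe_interval == 0 and len(held_out):
            model.history = history
            sample = generate_gan(model, len(held_out), seed=cfg.seed + 7919 + epoch)
            nd = nearest_neighbor_profile(
                HaplotypeMatrix(values=held_out), sample
            )
            aats = adversarial_accuracy(nd)[2]
            # checkpoint score: PCA-cloud coherence with the training split;
            # the AA probe at held-out sizes is too noisy to rank checkpoints,
            # and adversarial quality cycles rather than converging
            big = generate_gan(model, train_binary.shape[0],
                               seed=cfg.seed + 104729 + epoch)
            pca_train, pca_sample = joint_pca(
                [HaplotypeMatrix(values=train_binary), big], n_components=2
            )
            probe_w2 = wasserstein_2d(pca_train[:, :2], pca_sample[:, :2])
            history["probe_epoch"].append(epoch)
            history["aats"].append(aats)
            history["probe_w2"].append(probe_w2)
            score = probe_w2
            if best is None or score < best[0]:
                best = (
                    score,
                    [w.copy() for w in gen.weights] + [b.copy() for b in gen.biases],
                    [w.copy() for w in disc.weights] + [b.copy() for b in disc.biases],
                )
            if cfg.stop_at_aats:
                ok_probes = ok_probes + 1 if abs(aats - 0.5) <= cfg.aats_band else 0
                if ok_probes >= 2:
                    break
        if callbacks:
            for cb in callbacks:
                cb(epoch, model)

    if cfg.restore_best_probe and best is not None:
        k = len(gen.weights)
        gen.weights, gen.biases = best[1][:k], best[1][k:]
        k = len(disc.weights)
        disc.weights, disc.biases = best[2][:k], best[2][k:]
    model.history = history
    return model
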