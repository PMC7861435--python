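"""Synthetic structured haplotype data with known ground truth.

Two generators provide test beds for the generative models and the
evaluation metrics:

* :func:`simulate_structured` — a Balding–Nichols-style model: each site has
  an ancestral frequency ``p``; each population draws its own frequency from
  a Beta distribution with mean ``p`` and variance ``p (1 - p) * F`` where
  ``F`` is the differentiation parameter (an F_ST analogue); alleles are
  then drawn independently per haplotype.  Produces population structure
  but no linkage.
* :func:`simulate_mosaic` — a copying process: each output haplotype copies
  a founder template left to right, switching template with a per-SNP
  probability and flipping alleles at a per-site mutation rate.  Produces
  the decaying linkage disequilibrium that the LD and 3-point metrics
  measure.

Both are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .haplotypes import HaplotypeMatrix

__all__ = [
    "PopStructureConfig",
    "MosaicConfig",
    "simulate_structured",
    "simulate_mosaic",
    "structured_mosaic_dataset",
]


@dataclass
class PopStructureConfig:
    """Parameters of the structured-population allele-frequency model.

    ``differentiation`` plays the role of F_ST: the Beta draw for each
    population has mean ``p`` and variance ``p (1 - p) * differentiation``.
    ``ancestral_freq_law`` is ``("uniform", lo, hi)`` or
    ``("beta", alpha, beta)``; the default Uniform(0.05, 0.95) avoids sites
    that start out fixed.  ``rare_fraction`` replaces that fraction of sites
    with draws from Beta(0.2, 2), a low-frequency spike exercising the
    rare-allele behaviour of the generative models.
    """

    n_pops: int = 2
    haplotypes_per_pop: int = 250
    n_snps: int = 100
    differentiation: float = 0.2
    ancestral_freq_law: tuple = ("uniform", 0.05, 0.95)
    rare_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1 or self.haplotypes_per_pop < 1 or self.n_snps < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 < self.differentiation < 1.0:
            raise ValueError("differentiation must lie strictly in (0, 1)")
        if not 0.0 <= self.rare_fraction <= 1.0:
            raise ValueError("rare_fraction must lie in [0, 1]")


@dataclass
class MosaicConfig:
    """Copying-process parameters: template switch rate and mutation rate."""

    switch_rate: float = 0.05
    template_pool: int = 20
    mutation_rate: float = 0.01

    def __post_init__(self) -> None:
        for name in ("switch_rate", "mutation_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.template_pool < 1:
            raise ValueError("template_pool must be >= 1")


def _draw_ancestral(cfg: PopStructureConfig, rng: np.random.Generator) -> np.ndarray:
    law = cfg.ancestral_freq_law
    if law[0] == "uniform":
        p = rng.uniform(law[1], law[2], size=cfg.n_snps)
    elif law[0] == "beta":
        p = rng.beta(law[1], law[2], size=cfg.n_snps)
    else:
        raise ValueError(f"unknown ancestral_freq_law {law[0]!r}")
    if cfg.rare_fraction > 0:
        rare = rng.random(cfg.n_snps) < cfg.rare_fraction
        p[rare] = rng.beta(0.2, 2.0, size=int(rare.sum()))
    # keep Beta parameters below non-degenerate
    return np.clip(p, 1e-3, 1.0 - 1e-3)


def simulate_structured(cfg: PopStructureConfig) -> HaplotypeMatrix:
    """Draw a structured haplotype matrix under the Balding–Nichols model.

    Per site, population frequencies are Beta(p (1-F)/F, (1-p)(1-F)/F) —
    mean ``p``, variance ``p(1-p) F``.  Rows are grouped by population and
    labelled ``pop0, pop1, ...``.
    """
    rng = np.random.default_rng(cfg.seed)
    p = _draw_ancestral(cfg, rng)
    F = cfg.differentiation
    scale = (1.0 - F) / F
    a, b = p * scale, (1.0 - p) * scale
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("degenerate Beta parameters (ancestral frequency at 0 or 1)")
    blocks = []
    labels = []
    for k in range(cfg.n_pops):
        pop_freq = rng.beta(a, b)
        draws = rng.random((cfg.haplotypes_per_pop, cfg.n_snps)) < pop_freq
        blocks.append(draws.astype(np.int8))
        labels.extend([f"pop{k}"] * cfg.haplotypes_per_pop)
    return HaplotypeMatrix(values=np.concatenate(blocks, axis=0), labels=tuple(labels))


def simulate_mosaic(
    founders: HaplotypeMatrix,
    n_out: int,
    cfg: MosaicConfig,
    seed: int = 0,
) -> HaplotypeMatrix:
    """Generate ``n_out`` haplotypes by mosaic copying of founder rows.

    Each output row starts on a uniformly chosen founder; at every SNP step
    it switches to a (uniformly re-drawn) founder with probability
    ``cfg.switch_rate``, then each emitted allele is flipped independently
    with probability ``cfg.mutation_rate``.
    """
    if n_out < 1:
        raise ValueError("n_out must be >= 1")
    if founders.n_haplotypes < 1:
        raise ValueError("founders must be non-empty")
    rng = np.random.default_rng(seed)
    nf, L = founders.shape
    pool = min(cfg.template_pool, nf)
    founder_idx = rng.choice(nf, size=pool, replace=False)
    fv = founders.values[founder_idx]

    # vectorized template paths: switch events then cumulative re-draws
    template = np.empty((n_out, L), dtype=np.int64)
    template[:, 0] = rng.integers(pool, size=n_out)
    switches = rng.random((n_out, L - 1)) < cfg.switch_rate if L > 1 else None
    new_templates = rng.integers(pool, size=(n_out, L - 1)) if L > 1 else None
    for t in range(1, L):
        template[:, t] = np.where(
            switches[:, t - 1], new_templates[:, t - 1], template[:, t - 1]
        )
    out = fv[template, np.arange(L)]
    if cfg.mutation_rate > 0:
        flips = rng.random((n_out, L)) < cfg.mutation_rate
        out = np.where(flips, 1 - out, out)
    labels = None
    if founders.labels is not None:
        labels = tuple(founders.labels[founder_idx[t]] for t in template[:, 0])
    return HaplotypeMatrix(
        values=out.astype(np.int8), positions=founders.positions, labels=labels
    )


def structured_mosaic_dataset(
    cfg: PopStructureConfig,
    mosaic: MosaicConfig | None = None,
    founders_per_pop: int = 20,
) -> HaplotypeMatrix:
    """Structured populations with within-population mosaic LD.

    Draws ``founders_per_pop`` founders per population from the
    Balding–Nichols model, then expands each population to its target size
    by mosaic copying — giving datasets with both population structure and
    decaying LD, the two signals the evaluation suite measures.
    """
    mosaic = mosaic or MosaicConfig()
    founder_cfg = PopStructureConfig(
        n_pops=cfg.n_pops,
        haplotypes_per_pop=founders_per_pop,
        n_snps=cfg.n_snps,
        differentiation=cfg.differentiation,
        ancestral_freq_law=cfg.ancestral_freq_law,
        rare_fraction=cfg.rare_fraction,
        seed=cfg.seed,
    )
    founders = simulate_structured(founder_cfg)
    blocks = []
    labels: list[str] = []
    for k in range(cfg.n_pops):
        sel = np.arange(k * founders_per_pop, (k + 1) * founders_per_pop)
        pop_founders = founders.subset_rows(sel)
        pop = simulate_mosaic(
            pop_founders, cfg.haplotypes_per_pop, mosaic, seed=cfg.seed + 1 + k
        )
        blocks.append(pop.values)
        labels.extend([f"pop{k}"] * cfg.haplotypes_per_pop)
    return HaplotypeMatrix(values=np.concatenate(blocks, axis=0), labels=tuple(labels))
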