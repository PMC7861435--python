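"""Simple generative baselines: per-site Bernoulli and windowed Markov chain.

The Bernoulli model draws each allele independently from the training
allele frequency at that site.  The Markov model draws alleles left to
right; position 0 uses the marginal frequency, and position ``p`` uses the
empirical conditional ``P(h_p | h_{p-w}, ..., h_{p-1})`` with the context
window growing incrementally up to ``w`` SNPs (typical windows: 5 or 10).
Conditional probabilities are raw observed frequencies with no smoothing;
a context never seen in training is resolved by truncating it one allele
at a time (oldest first) until a seen context is found, falling back to
the position's marginal frequency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .haplotypes import HaplotypeMatrix

__all__ = [
    "fit_bernoulli",
    "generate_bernoulli",
    "MarkovModel",
    "fit_markov",
    "generate_markov",
]


def fit_bernoulli(train: HaplotypeMatrix) -> np.ndarray:
    """Per-site allele-1 frequencies (column means) of the training data."""
    return train.allele_frequencies()


def generate_bernoulli(freqs: np.ndarray, n: int, seed: int = 0) -> HaplotypeMatrix:
    """Draw ``n`` haplotypes with independent per-site Bernoulli alleles."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    values = (rng.random((n, freqs.size)) < freqs).astype(np.int8)
    return HaplotypeMatrix(values=values)


@dataclass
class MarkovModel:
    """Empirical left-to-right haplotype Markov model with window ``w``.

    ``context_counts[p]`` maps the context tuple (the up-to-``w`` alleles
    preceding position ``p``) to an array ``[count0, count1]`` of observed
    continuations.
    """

    window: int
    n_snps: int
    initial_freq: float
    context_counts: list[dict[tuple[int, ...], np.ndarray]] = field(repr=False)

    def conditional(self, p: int, context: tuple[int, ...]) -> float:
        """P(allele 1 at position p | context), with truncation backoff.

        ``context`` holds the immediately preceding alleles, oldest first;
        an unseen context is shortened from the left until a match exists.
        """
        if p == 0:
            return self.initial_freq
        ctx = context[-min(len(context), self.window, p):]
        table = self.context_counts[p]
        while True:
            counts = table.get(ctx)
            if counts is not None and counts.sum() > 0:
                return float(counts[1] / counts.sum())
            if not ctx:
                return self.initial_freq
            ctx = ctx[1:]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "window": self.window,
            "n_snps": self.n_snps,
            "initial_freq": self.initial_freq,
            "context_counts": [
                {"".join(map(str, k)): v.tolist() for k, v in table.items()}
                for table in self.context_counts
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkovModel":
        payload = json.loads(Path(path).read_text())
        tables = [
            {
                tuple(int(c) for c in k): np.asarray(v, dtype=np.int64)
                for k, v in table.items()
            }
            for table in payload["context_counts"]
        ]
        return cls(
            window=payload["window"],
            n_snps=payload["n_snps"],
            initial_freq=payload["initial_freq"],
            context_counts=tables,
        )


def fit_markov(train: HaplotypeMatrix, window: int) -> MarkovModel:
    """Count context/continuation pairs at every position of the training set."""
    if window < 1:
        raise ValueError("window must be >= 1")
    X = train.values
    n, L = X.shape
    tables: list[dict[tuple[int, ...], np.ndarray]] = [dict() for _ in range(L)]
    for p in range(1, L):
        w = min(window, p)
        contexts = X[:, p - w:p]
        outcomes = X[:, p]
        table = tables[p]
        for ctx_row, out in zip(map(tuple, contexts.tolist()), outcomes):
            counts = table.get(ctx_row)
            if counts is None:
                counts = np.zeros(2, dtype=np.int64)
                table[ctx_row] = counts
            counts[out] += 1
    return MarkovModel(
        window=window,
        n_snps=L,
        initial_freq=float(X[:, 0].mean()),
        context_counts=tables,
    )


def generate_markov(model: MarkovModel, n: int, seed: int = 0) -> HaplotypeMatrix:
    """Sample ``n`` haplotypes left to right from the fitted model."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    L = model.n_snps
    out = np.zeros((n, L), dtype=np.int8)
    out[:, 0] = rng.random(n) < model.initial_freq
    for p in range(1, L):
        w = min(model.window, p)
        u = rng.random(n)
        for i in range(n):
            ctx = tuple(int(a) for a in out[i, p - w:p])
            out[i, p] = u[i] < model.conditional(p, ctx)
    return HaplotypeMatrix(values=out)
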