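"""Fidelity and privacy metrics for (real, artificial) haplotype dataset pairs.

Covers the full audit of an artificial-genome set against the real data it
was trained on: per-site allele-frequency agreement, pairwise linkage
disequilibrium (r²) matrices and binned decay curves, 3-point (connected
third-moment) correlations, pairwise Hamming-distance distributions,
nearest-neighbour distance profiles, the nearest-neighbour adversarial
accuracy AA_TS and privacy loss, a spike-in sensitivity protocol, joint PCA
embeddings, an entropic-regularized 2-D Wasserstein distance between PCA
clouds, and fixed-site bookkeeping.  :func:`evaluate_pair` assembles
everything into one report.

Conventions: distances are raw Hamming counts (number of differing sites);
nearest-neighbour self-distances are excluded (leave-one-out); the AA
indicators use the strict inequality, so a tie contributes 0.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.special import logsumexp
from scipy.stats import pearsonr, wasserstein_distance
from sklearn.decomposition import PCA

from .haplotypes import HaplotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborDistances",
    "FrequencyTables",
    "EvaluationReport",
    "allele_freq_comparison",
    "ld_matrix",
    "ld_decay",
    "ld_correlation",
    "three_point_corr",
    "pairwise_distance_distributions",
    "nearest_neighbor_profile",
    "adversarial_accuracy",
    "privacy_loss",
    "spike_in_sensitivity",
    "joint_pca",
    "wasserstein_2d",
    "fixed_site_report",
    "evaluate_pair",
]


# --------------------------------------------------------------------------
# frequency tables and 3-point correlations


class FrequencyTables:
    """Single-, pair- and triple-site allele frequency accessors."""

    def __init__(self, M: HaplotypeMatrix):
        self._X = M.values
        self._n = M.n_haplotypes

    def f1(self, i: int, a: int) -> float:
        """Frequency of allele ``a`` at SNP ``i``."""
        return float(np.mean(self._X[:, i] == a))

    def f2(self, i: int, j: int, a: int, b: int) -> float:
        return float(np.mean((self._X[:, i] == a) & (self._X[:, j] == b)))

    def f3(self, i: int, j: int, k: int, a: int, b: int, c: int) -> float:
        return float(
            np.mean((self._X[:, i] == a) & (self._X[:, j] == b) & (self._X[:, k] == c))
        )

    def c3(self, i: int, j: int, k: int, a: int, b: int, c: int) -> float:
        """Connected 3-point correlation c_ijk(a, b, c).

        c = f_ijk - f_ij f_k - f_ik f_j - f_jk f_i + 2 f_i f_j f_k;
        it vanishes whenever one of the three sites is fixed.
        """
        return (
            self.f3(i, j, k, a, b, c)
            - self.f2(i, j, a, b) * self.f1(k, c)
            - self.f2(i, k, a, c) * self.f1(j, b)
            - self.f2(j, k, b, c) * self.f1(i, a)
            + 2.0 * self.f1(i, a) * self.f1(j, b) * self.f1(k, c)
        )


def three_point_corr(
    M: HaplotypeMatrix,
    separations: Sequence = (1, 4, 16, 64, 256, 512, 1024, "random"),
    n_triplets: int = 8000,
    seed: int = 0,
    alleles: tuple[int, int, int] = (1, 1, 1),
) -> dict:
    """3-point correlations for randomly picked SNP triplets.

    For integer separation ``s`` triplets are (i, i+s, i+2s); ``"random"``
    picks three distinct sites uniformly.  Returns, per separation, the
    sampled values plus mean/std summaries.  Separations that do not fit in
    the panel are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    X = M.values.astype(float)
    n, L = X.shape
    a, b, c = alleles
    # indicator columns for the requested alleles
    A = X if a == 1 else 1.0 - X
    B = X if b == 1 else 1.0 - X
    C = X if c == 1 else 1.0 - X
    out: dict = {}
    for sep in separations:
        if sep == "random":
            if L < 3:
                warnings.warn("panel too small for random triplets")
                continue
            trip = np.array(
                [rng.choice(L, size=3, replace=False) for _ in range(n_triplets)]
            )
            i_idx, j_idx, k_idx = trip[:, 0], trip[:, 1], trip[:, 2]
        else:
            if 2 * sep >= L:
                warnings.warn(f"separation {sep} does not fit in {L} SNPs; skipped")
                continue
            i_idx = rng.integers(0, L - 2 * sep, size=n_triplets)
            j_idx = i_idx + sep
            k_idx = i_idx + 2 * sep
        Ai, Bj, Ck = A[:, i_idx], B[:, j_idx], C[:, k_idx]
        fi, fj, fk = Ai.mean(0), Bj.mean(0), Ck.mean(0)
        fij = (Ai * Bj).mean(0)
        fik = (Ai * Ck).mean(0)
        fjk = (Bj * Ck).mean(0)
        fijk = (Ai * Bj * Ck).mean(0)
        c3 = fijk - fij * fk - fik * fj - fjk * fi + 2.0 * fi * fj * fk
        out[sep] = {
            "values": c3,
            "mean": float(c3.mean()),
            "std": float(c3.std()),
            "mean_abs": float(np.abs(c3).mean()),
        }
    return out


# --------------------------------------------------------------------------
# frequency and LD


def allele_freq_comparison(
    real: HaplotypeMatrix, art: HaplotypeMatrix
) -> tuple[np.ndarray, float]:
    """Per-site (real, artificial) frequency pairs and their Pearson r."""
    if real.n_snps != art.n_snps:
        raise ValueError("datasets must share the SNP panel")
    fr, fa = real.allele_frequencies(), art.allele_frequencies()
    pairs = np.column_stack([fr, fa])
    if fr.std() == 0 or fa.std() == 0:
        warnings.warn("zero-variance frequency vector; correlation undefined")
        return pairs, float("nan")
    return pairs, float(pearsonr(fr, fa)[0])


def ld_matrix(M: HaplotypeMatrix) -> np.ndarray:
    """Pairwise r² between SNP columns (NaN rows/cols at fixed sites)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(M.values.astype(float), rowvar=False)
    r2 = r * r
    np.fill_diagonal(r2, 1.0)
    fixed = M.allele_frequencies() % 1 == 0
    r2[fixed, :] = np.nan
    r2[:, fixed] = np.nan
    return r2


def _segregating_mask(*datasets: HaplotypeMatrix) -> np.ndarray:
    """Sites polymorphic in every dataset (fixed-in-any removed)."""
    mask = np.ones(datasets[0].n_snps, dtype=bool)
    for d in datasets:
        f = d.allele_frequencies()
        mask &= (f > 0) & (f < 1)
    return mask


def ld_decay(
    real: HaplotypeMatrix,
    art: HaplotypeMatrix,
    n_bins: int = 50,
) -> dict:
    """Binned LD-decay curves for both datasets on a shared site filter.

    Sites fixed in at least one dataset are removed first; r² for every
    remaining pair is stratified into ``n_bins`` equal-width distance bins
    (SNP-index distance, or bp when positions are available) and averaged
    per bin.
    """
    mask = _segregating_mask(real, art)
    idx = np.flatnonzero(mask)
    if idx.size < 2:
        raise ValueError("fewer than 2 jointly segregating sites")
    if real.positions is not None:
        coord = real.positions[idx].astype(float)
    else:
        coord = idx.astype(float)
    iu = np.triu_indices(idx.size, k=1)
    dist = np.abs(coord[iu[0]] - coord[iu[1]])
    edges = np.linspace(dist.min(), dist.max(), n_bins + 1)
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    curves = {}
    for name, d in (("real", real), ("art", art)):
        sub = HaplotypeMatrix(values=d.values[:, idx])
        r2 = ld_matrix(sub)[iu]
        sums = np.bincount(which, weights=r2, minlength=n_bins)
        counts = np.bincount(which, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            curves[name] = sums / counts
    centers = 0.5 * (edges[:-1] + edges[1:])
    return {"bin_centers": centers, "real": curves["real"], "art": curves["art"],
            "n_sites": idx.size}


def ld_correlation(real: HaplotypeMatrix, art: HaplotypeMatrix) -> float:
    """Pearson r between real and artificial r² across all retained pairs."""
    mask = _segregating_mask(real, art)
    idx = np.flatnonzero(mask)
    if idx.size < 2:
        raise ValueError("fewer than 2 jointly segregating sites")
    iu = np.triu_indices(idx.size, k=1)
    r2_real = ld_matrix(HaplotypeMatrix(values=real.values[:, idx]))[iu]
    r2_art = ld_matrix(HaplotypeMatrix(values=art.values[:, idx]))[iu]
    return float(pearsonr(r2_real, r2_art)[0])


# --------------------------------------------------------------------------
# distances, adversarial accuracy, privacy


@dataclass
class NeighborDistances:
    """The four nearest-neighbour distance vectors behind AA_TS.

    ``d_TS[i]``: real haplotype i to its nearest artificial neighbour;
    ``d_TT[i]``: real i to its nearest *other* real haplotype;
    ``d_ST``/``d_SS``: the artificial-side analogues.
    """

    d_TS: np.ndarray
    d_ST: np.ndarray
    d_TT: np.ndarray
    d_SS: np.ndarray
    metric: str = "hamming"


def _hamming_counts(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return cdist(A.astype(float), B.astype(float), metric="cityblock")


def pairwise_distance_distributions(
    real: HaplotypeMatrix, art: HaplotypeMatrix
) -> dict:
    """Within- and between-set Hamming distance distributions.

    Returns the three distance vectors, the 1-D Wasserstein distance
    between the two within-set distributions, and the number of exact
    (zero-distance) real/artificial pairs — a direct copy detector.
    """
    within_real = pdist(real.values.astype(float), metric="cityblock")
    within_art = pdist(art.values.astype(float), metric="cityblock")
    between = _hamming_counts(real.values, art.values).ravel()
    return {
        "within_real": within_real,
        "within_art": within_art,
        "between": between,
        "wasserstein_within": float(wasserstein_distance(within_real, within_art)),
        "n_identical_pairs": int(np.sum(between == 0)),
    }


def nearest_neighbor_profile(
    real: HaplotypeMatrix, art: HaplotypeMatrix
) -> NeighborDistances:
    """Compute the four nearest-neighbour vectors (leave-self-out within)."""
    D = _hamming_counts(real.values, art.values)
    d_TS = D.min(axis=1)
    d_ST = D.min(axis=0)
    DT = _hamming_counts(real.values, real.values)
    np.fill_diagonal(DT, np.inf)
    d_TT = DT.min(axis=1)
    DS = _hamming_counts(art.values, art.values)
    np.fill_diagonal(DS, np.inf)
    d_SS = DS.min(axis=1)
    return NeighborDistances(d_TS=d_TS, d_ST=d_ST, d_TT=d_TT, d_SS=d_SS)


def adversarial_accuracy(nd: NeighborDistances) -> tuple[float, float, float]:
    """(AA_truth, AA_syn, AA_TS) from the nearest-neighbour vectors.

    AA_truth = mean 1(d_TS > d_TT); AA_syn = mean 1(d_ST > d_SS);
    AA_TS = (AA_truth + AA_syn) / 2.  0.5 is optimal; below 0.5 the
    artificial set sits too close to the real points (overfitting), above
    0.5 too far (underfitting).  AA_truth and AA_syn are reported
    separately: AA_TS = 0.5 with AA_truth = 0 and AA_syn = 1 still signals
    a generator collapsing onto clusters of real genomes.
    """
    if nd.d_TS.size < 2 or nd.d_ST.size < 2:
        raise ValueError("need at least 2 haplotypes per set (d_TT/d_SS undefined)")
    if nd.d_TS.size != nd.d_ST.size:
        logger.warning(
            "unequal set sizes (%d real vs %d artificial); AA equations assume equal n",
            nd.d_TS.size,
            nd.d_ST.size,
        )
    aa_truth = float(np.mean(nd.d_TS > nd.d_TT))
    aa_syn = float(np.mean(nd.d_ST > nd.d_SS))
    return aa_truth, aa_syn, 0.5 * (aa_truth + aa_syn)


def _aats(real: HaplotypeMatrix, art: HaplotypeMatrix) -> float:
    return adversarial_accuracy(nearest_neighbor_profile(real, art))[2]


def privacy_loss(
    train: HaplotypeMatrix, test: HaplotypeMatrix, art: HaplotypeMatrix
) -> float:
    """Test-set AA_TS minus training-set AA_TS.

    Positive values indicate leakage of training information into the
    artificial set; the score ranges approximately over [-0.5, 0.5].
    """
    value = _aats(test, art) - _aats(train, art)
    if abs(value) > 0.5:
        logger.warning("privacy loss %.3f outside the typical [-0.5, 0.5] range", value)
    return value


def spike_in_sensitivity(
    train: HaplotypeMatrix,
    test: HaplotypeMatrix,
    art: HaplotypeMatrix,
    spike_counts: Sequence[int] = (0, 1, 10, 50),
    seed: int = 0,
) -> list[dict]:
    """Sensitivity of AA_TS / privacy loss to real rows hidden in the AGs.

    For each k, k random artificial rows are replaced by k random training
    rows and the scores recomputed — emulating an adversarial release that
    smuggles real genomes into an artificial set.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for k in spike_counts:
        if k > art.n_haplotypes or k > train.n_haplotypes:
            raise ValueError(f"spike count {k} exceeds dataset size")
        values = art.values.copy()
        if k > 0:
            dst = rng.choice(art.n_haplotypes, size=k, replace=False)
            src = rng.choice(train.n_haplotypes, size=k, replace=False)
            values[dst] = train.values[src]
        spiked = HaplotypeMatrix(values=values)
        aats_train = _aats(train, spiked)
        aats_test = _aats(test, spiked)
        rows.append(
            {
                "spiked": int(k),
                "aats_train": aats_train,
                "aats_test": aats_test,
                "privacy_loss": aats_test - aats_train,
            }
        )
    return rows


# --------------------------------------------------------------------------
# embeddings and optimal transport


def joint_pca(
    datasets: Sequence[HaplotypeMatrix],
    n_components: int = 6,
    scale: str = "unit_norm",
) -> list[np.ndarray]:
    """One PCA fitted on the row-concatenation of all datasets.

    Returns the coordinates of each dataset in the shared component space,
    in input order.  With ``scale="unit_norm"`` (default) each component's
    coordinate vector over the combined rows is normalized to unit Euclidean
    norm — the plotting convention of population-genetics PCA tools, which
    puts coordinates at the O(1/sqrt(n)) scale the entropic-transport
    distances are calibrated for.  ``scale="raw"`` keeps the untouched
    principal-component scores.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    if scale not in ("unit_norm", "raw"):
        raise ValueError("scale must be 'unit_norm' or 'raw'")
    X = np.concatenate([d.values.astype(float) for d in datasets], axis=0)
    n_components = min(n_components, *X.shape)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    if scale == "unit_norm":
        norms = np.linalg.norm(coords, axis=0)
        coords = coords / np.where(norms > 0, norms, 1.0)
    out, start = [], 0
    for d in datasets:
        out.append(coords[start:start + d.n_haplotypes])
        start += d.n_haplotypes
    return out


def wasserstein_2d(
    cloud_a: np.ndarray,
    cloud_b: np.ndarray,
    reg: float = 0.001,
    max_iter: int = 20000,
    tol: float = 1e-6,
) -> float:
    """Entropic-regularized optimal transport cost between two point clouds.

    Squared-Euclidean ground cost, uniform weights, log-domain Sinkhorn
    scaling with epsilon annealing (warm-started stages down to ``reg``).
    Returns the transport cost <P, C> of the converged plan.
    """
    A = np.atleast_2d(np.asarray(cloud_a, dtype=float))
    B = np.atleast_2d(np.asarray(cloud_b, dtype=float))
    if A.size == 0 or B.size == 0:
        raise ValueError("clouds must be non-empty")
    n, m = A.shape[0], B.shape[0]
    C = cdist(A, B, metric="sqeuclidean")
    loga = np.full(n, -np.log(n))
    logb = np.full(m, -np.log(m))
    f = np.zeros(n)
    g = np.zeros(m)
    # roundoff in the log-domain updates floors the marginal error at
    # roughly (n+m) * machine-epsilon * (C_max / reg); don't demand less
    tol = max(tol, (n + m) * 5e-8)
    # anneal epsilon from the cost scale down to the target regularization
    eps_start = max(C.max(), reg)
    n_stages = max(1, int(np.ceil(np.log(eps_start / reg) / np.log(2.0))))
    schedule = list(eps_start / 2.0 ** np.arange(n_stages)) + [reg]
    it_total = 0
    err = np.inf
    for stage, eps in enumerate(schedule):
        last = stage == len(schedule) - 1
        budget = max_iter if last else min(200, max_iter)
        for it in range(budget):
            it_total += 1
            Mx = (-C + f[:, None] + g[None, :]) / eps
            f = f + eps * (loga - logsumexp(Mx, axis=1))
            Mx = (-C + f[:, None] + g[None, :]) / eps
            g = g + eps * (logb - logsumexp(Mx, axis=0))
            if it % 10 == 0 or it == budget - 1:
                # row marginal error of the current plan (columns are exact
                # right after the g-update)
                Mx = (-C + f[:, None] + g[None, :]) / eps
                err = np.abs(np.exp(logsumexp(Mx, axis=1)) - np.exp(loga)).sum()
                if err < tol:
                    break
        else:
            if last and err > 100 * tol:
                raise RuntimeError(
                    f"Sinkhorn did not converge (marginal error {err:.2e} "
                    f"after {it_total} iterations, reg={reg})"
                )
            if last:
                logger.warning(
                    "Sinkhorn stopped at marginal error %.2e (tol %.2e); "
                    "cost error is bounded by err * max cost", err, tol
                )
    P = np.exp((-C + f[:, None] + g[None, :]) / reg)
    return float((P * C).sum())


# --------------------------------------------------------------------------
# fixed sites and the aggregate report


def fixed_site_report(real: HaplotypeMatrix, art: HaplotypeMatrix) -> dict:
    """Counts of sites fixed in one dataset but polymorphic in the other."""
    fr, fa = real.allele_frequencies(), art.allele_frequencies()
    poly_real = (fr > 0) & (fr < 1)
    poly_art = (fa > 0) & (fa < 1)
    return {
        "art_fixed_0_real_poly": int(np.sum(poly_real & (fa == 0))),
        "art_fixed_1_real_poly": int(np.sum(poly_real & (fa == 1))),
        "real_fixed_0_art_poly": int(np.sum(poly_art & (fr == 0))),
        "real_fixed_1_art_poly": int(np.sum(poly_art & (fr == 1))),
    }


@dataclass
class EvaluationReport:
    """All fidelity/privacy summaries for one (real, artificial) pair."""

    n_real: int
    n_art: int
    n_snps: int
    seed: int
    allele_freq_corr: float
    ld_corr: Optional[float]
    ld_decay: Optional[dict]
    three_point: Optional[dict]
    pairwise: dict
    neighbors: Optional[NeighborDistances]
    aa_truth: float
    aa_syn: float
    aa_ts: float
    privacy_loss: Optional[float]
    pca_wasserstein_2d: float
    fixed_sites: dict

    def summary(self) -> dict:
        """Scalar metrics only, JSON-serializable."""
        out = {
            "n_real": self.n_real,
            "n_art": self.n_art,
            "n_snps": self.n_snps,
            "seed": self.seed,
            "allele_freq_corr": self.allele_freq_corr,
            "ld_corr": self.ld_corr,
            "wasserstein_pairwise": self.pairwise["wasserstein_within"],
            "n_identical_pairs": self.pairwise["n_identical_pairs"],
            "aa_truth": self.aa_truth,
            "aa_syn": self.aa_syn,
            "aa_ts": self.aa_ts,
            "privacy_loss": self.privacy_loss,
            "pca_wasserstein_2d": self.pca_wasserstein_2d,
            **self.fixed_sites,
        }
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def evaluate_pair(
    real: HaplotypeMatrix,
    art: HaplotypeMatrix,
    train: Optional[HaplotypeMatrix] = None,
    test: Optional[HaplotypeMatrix] = None,
    seed: int = 0,
    with_ld: bool = True,
    with_three_point: bool = True,
    three_point_separations: Sequence = (1, 4, 16, "random"),
    n_triplets: int = 2000,
    sinkhorn_reg: float = 0.001,
) -> EvaluationReport:
    """Run the full evaluation suite on a (real, artificial) dataset pair.

    ``train``/``test`` enable the privacy loss (both required; when absent
    the field is None and a log line says why).  All stochastic pieces
    (triplet sampling) derive from ``seed``.
    """
    _, freq_corr = allele_freq_comparison(real, art)
    ld_c = decay = None
    if with_ld:
        try:
            ld_c = ld_correlation(real, art)
            decay = ld_decay(real, art)
        except ValueError as exc:
            logger.warning("LD metrics skipped: %s", exc)
    three = None
    if with_three_point:
        three = {
            "real": three_point_corr(
                real, three_point_separations, n_triplets, seed=seed
            ),
            "art": three_point_corr(
                art, three_point_separations, n_triplets, seed=seed
            ),
        }
    pw = pairwise_distance_distributions(real, art)
    nd = nearest_neighbor_profile(real, art)
    aa_truth, aa_syn, aa_ts = adversarial_accuracy(nd)
    ploss = None
    if train is not None and test is not None:
        ploss = privacy_loss(train, test, art)
    else:
        logger.info("privacy loss disabled: needs both train and test splits")
    pca_real, pca_art = joint_pca([real, art], n_components=2)
    w2d = wasserstein_2d(pca_real[:, :2], pca_art[:, :2], reg=sinkhorn_reg)
    return EvaluationReport(
        n_real=real.n_haplotypes,
        n_art=art.n_haplotypes,
        n_snps=real.n_snps,
        seed=seed,
        allele_freq_corr=freq_corr,
        ld_corr=ld_c,
        ld_decay=decay,
        three_point=three,
        pairwise=pw,
        neighbors=nd,
        aa_truth=aa_truth,
        aa_syn=aa_syn,
        aa_ts=aa_ts,
        privacy_loss=ploss,
        pca_wasserstein_2d=w2d,
        fixed_sites=fixed_site_report(real, art),
    )
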