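"""Binary haplotype matrices and their on-disk formats.

The universal data container of the package is :class:`HaplotypeMatrix`:
a ``(n_haplotypes, n_snps)`` matrix of 0/1 allele codes (0 = reference,
1 = alternative), with optional genomic positions, SNP identifiers and
per-row population labels.  Two on-disk representations are supported:

* the ``hapt`` text dialect — whitespace-separated, one haplotype per row,
  each row starting with a group-label token and a sample-id token followed
  by one 0/1 token per SNP; an optional ``#``-prefixed header line carries
  SNP ids;
* phased VCF (``GT`` fields separated by ``|``), read via :mod:`cyvcf2`.

Phased data keep one column per site; the unphased ("genotype") layout packs
the two alleles of an individual into adjacent columns, two columns per site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypeMatrix",
    "HaptFormatError",
    "PhasingError",
    "read_hapt",
    "write_hapt",
    "read_vcf_haplotypes",
    "to_genotype_layout",
    "from_genotype_layout",
]


class HaptFormatError(ValueError):
    """Malformed hapt file (bad token, ragged row, empty file)."""


class PhasingError(ValueError):
    """VCF record is not phased where phased data were required."""


@dataclass(frozen=True)
class HaplotypeMatrix:
    """A binary haplotype-by-SNP matrix.

    Parameters
    ----------
    values
        ``(n_haplotypes, n_snps)`` array with entries in ``{0, 1}``.
    positions
        Optional 1-based genomic coordinates (bp), one per SNP, strictly
        increasing.
    snp_ids
        Optional SNP identifiers, one per SNP.
    labels
        Optional per-haplotype population/group tags.
    phased
        ``True`` (default) means one column per site.  ``False`` marks the
        genotype layout where columns ``(2t, 2t+1)`` hold the two alleles of
        site ``t``.
    """

    values: np.ndarray
    positions: Optional[np.ndarray] = None
    snp_ids: Optional[tuple[str, ...]] = None
    labels: Optional[tuple[str, ...]] = None
    phased: bool = True

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.int8)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("need at least one haplotype and one SNP")
        if not np.isin(values, (0, 1)).all():
            bad = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise ValueError(
                f"allele codes must be 0 or 1; found {values[tuple(bad)]} "
                f"at row {bad[0]}, column {bad[1]}"
            )
        object.__setattr__(self, "values", values)
        if self.positions is not None:
            pos = np.asarray(self.positions, dtype=np.int64)
            if pos.shape != (values.shape[1],):
                raise ValueError(
                    f"positions length {pos.shape} does not match n_snps {values.shape[1]}"
                )
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing")
            object.__setattr__(self, "positions", pos)
        if self.snp_ids is not None:
            ids = tuple(str(s) for s in self.snp_ids)
            if len(ids) != values.shape[1]:
                raise ValueError("snp_ids length does not match n_snps")
            object.__setattr__(self, "snp_ids", ids)
        if self.labels is not None:
            lab = tuple(str(s) for s in self.labels)
            if len(lab) != values.shape[0]:
                raise ValueError("labels length does not match n_haplotypes")
            object.__setattr__(self, "labels", lab)
        if not self.phased and values.shape[1] % 2 != 0:
            raise ValueError("unphased layout requires an even number of columns")

    @property
    def n_haplotypes(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def allele_frequencies(self) -> np.ndarray:
        """Per-site frequency of allele 1."""
        return self.values.mean(axis=0)

    def subset_rows(self, index: Sequence[int] | np.ndarray) -> "HaplotypeMatrix":
        index = np.asarray(index)
        labels = None
        if self.labels is not None:
            labels = tuple(self.labels[i] for i in index)
        return replace(self, values=self.values[index], labels=labels)

    def with_labels(self, labels: Sequence[str]) -> "HaplotypeMatrix":
        return replace(self, labels=tuple(labels))


def read_hapt(path: str | Path) -> HaplotypeMatrix:
    """Read a hapt file.

    Each data row is ``<group> <sample-id> <a_1> ... <a_L>`` with alleles in
    ``{0, 1}``.  A leading line starting with ``#`` lists SNP ids.

    Raises
    ------
    HaptFormatError
        On ragged rows or non-0/1 allele tokens (the message names the
        offending line and column).
    """
    path = Path(path)
    snp_ids: Optional[tuple[str, ...]] = None
    labels: list[str] = []
    rows: list[list[int]] = []
    width: Optional[int] = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if rows:
                    raise HaptFormatError(
                        f"{path}:{lineno}: header line after data rows"
                    )
                snp_ids = tuple(line[1:].split())
                continue
            tokens = line.split()
            if len(tokens) < 3:
                raise HaptFormatError(
                    f"{path}:{lineno}: expected group, id and >=1 allele tokens"
                )
            if width is None:
                width = len(tokens)
            elif len(tokens) != width:
                raise HaptFormatError(
                    f"{path}:{lineno}: ragged row ({len(tokens)} tokens, expected {width})"
                )
            alleles = []
            for col, tok in enumerate(tokens[2:], start=1):
                if tok == "0":
                    alleles.append(0)
                elif tok == "1":
                    alleles.append(1)
                else:
                    raise HaptFormatError(
                        f"{path}:{lineno}: allele token {tok!r} at SNP column {col} "
                        "is not 0 or 1"
                    )
            labels.append(tokens[0])
            rows.append(alleles)
    if not rows:
        raise HaptFormatError(f"{path}: no data rows")
    values = np.array(rows, dtype=np.int8)
    if snp_ids is not None and len(snp_ids) != values.shape[1]:
        raise HaptFormatError(
            f"{path}: header lists {len(snp_ids)} SNP ids for {values.shape[1]} columns"
        )
    return HaplotypeMatrix(values=values, snp_ids=snp_ids, labels=tuple(labels))


def write_hapt(matrix: HaplotypeMatrix, path: str | Path) -> None:
    """Write a matrix in the hapt dialect (Unix line endings)."""
    path = Path(path)
    labels = matrix.labels or tuple("POP" for _ in range(matrix.n_haplotypes))
    with path.open("w", newline="\n") as fh:
        if matrix.snp_ids is not None:
            fh.write("# " + " ".join(matrix.snp_ids) + "\n")
        for i in range(matrix.n_haplotypes):
            alleles = " ".join(str(int(a)) for a in matrix.values[i])
            fh.write(f"{labels[i]} h{i} {alleles}\n")


def read_vcf_haplotypes(
    path: str | Path,
    region: Optional[str] = None,
    strict: bool = True,
    force_genotype: bool = False,
) -> HaplotypeMatrix:
    """Extract phased haplotypes from a VCF.

    Each sample contributes two rows (left haplotype then right haplotype).
    REF maps to 0, ALT to 1; positions are the 1-based VCF ``POS`` values.
    Multiallelic sites are skipped with a logged count (or raise when
    ``strict``); unphased genotypes raise :class:`PhasingError` unless
    ``force_genotype`` accepts them as written.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: list[np.ndarray] = []
    positions: list[int] = []
    snp_ids: list[str] = []
    n_multi = 0
    window = None
    if region:
        # stream-and-filter so plain-text VCFs work without a tabix index
        chrom, _, span = region.partition(":")
        if span:
            lo, _, hi = span.partition("-")
            window = (chrom, int(lo), int(hi) if hi else np.inf)
        else:
            window = (chrom, 1, np.inf)
    for rec in vcf:
        if window is not None and not (
            rec.CHROM == window[0] and window[1] <= rec.POS <= window[2]
        ):
            continue
        if len(rec.ALT) != 1:
            if strict:
                raise ValueError(
                    f"multiallelic site at {rec.CHROM}:{rec.POS} (strict mode)"
                )
            n_multi += 1
            continue
        gts = rec.genotypes  # [allele_a, allele_b, phased_flag] per sample
        col = np.empty(2 * len(samples), dtype=np.int8)
        for s, gt in enumerate(gts):
            a, b, phased = gt[0], gt[1], gt[2]
            if a < 0 or b < 0:
                raise ValueError(
                    f"missing genotype at {rec.CHROM}:{rec.POS} sample {samples[s]}"
                )
            if not phased and not force_genotype:
                raise PhasingError(
                    f"unphased genotype at {rec.CHROM}:{rec.POS} sample {samples[s]}"
                )
            col[2 * s] = a
            col[2 * s + 1] = b
        columns.append(col)
        positions.append(rec.POS)
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
    if n_multi:
        logger.info("skipped %d multiallelic sites", n_multi)
    if not columns:
        raise ValueError("no sites in region" if region else "no biallelic sites in VCF")
    values = np.stack(columns, axis=1)
    labels = tuple(f"{s}.{h}" for s in samples for h in ("L", "R"))
    return HaplotypeMatrix(
        values=values,
        positions=np.array(positions, dtype=np.int64),
        snp_ids=tuple(snp_ids),
        labels=labels,
    )


def to_genotype_layout(matrix: HaplotypeMatrix) -> HaplotypeMatrix:
    """Pack consecutive haplotype row pairs into genotype rows.

    Rows ``(2i, 2i+1)`` form individual ``i``; the output row interleaves
    site-major: site ``t`` contributes columns ``(2t, 2t+1)`` holding the
    alleles of chromosomes A and B.
    """
    if matrix.n_haplotypes % 2 != 0:
        raise ValueError(
            f"cannot pair {matrix.n_haplotypes} haplotypes into individuals"
        )
    n_ind = matrix.n_haplotypes // 2
    a = matrix.values[0::2]  # chromosome A per individual
    b = matrix.values[1::2]
    values = np.empty((n_ind, 2 * matrix.n_snps), dtype=np.int8)
    values[:, 0::2] = a
    values[:, 1::2] = b
    labels = None
    if matrix.labels is not None:
        labels = tuple(matrix.labels[2 * i] for i in range(n_ind))
    return HaplotypeMatrix(values=values, labels=labels, phased=False)


def from_genotype_layout(matrix: HaplotypeMatrix) -> HaplotypeMatrix:
    """Inverse of :func:`to_genotype_layout`."""
    if matrix.n_snps % 2 != 0:
        raise ValueError("genotype layout requires an even number of columns")
    n_sites = matrix.n_snps // 2
    a = matrix.values[:, 0::2]
    b = matrix.values[:, 1::2]
    values = np.empty((2 * matrix.n_haplotypes, n_sites), dtype=np.int8)
    values[0::2] = a
    values[1::2] = b
    labels = None
    if matrix.labels is not None:
        labels = tuple(lab for lab in matrix.labels for _ in range(2))
    return HaplotypeMatrix(values=values, labels=labels, phased=True)
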