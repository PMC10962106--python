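"""Canonical indexing of the pairwise-interaction design Z = X * X.

Z is the partial face-splitting (transposed Khatri-Rao) product of the
genotype matrix with itself: one column per unordered SNP pair (i, j),
i < j, holding the elementwise dosage product; self-products are excluded.
For p SNPs Z has p(p-1)/2 columns, laid out in row-major upper-triangle
order: (0,1), (0,2), ..., (0,p-1), (1,2), ...

Also provides minor allele frequency (MAF) filtering and the analogous
minor *interaction* allele frequency (MIAF) of a product column, plus
plain-text genotype readers/writers.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering
from math import isqrt

import numpy as np

from .simdata import GenotypeMatrix, Marker

__all__ = [
    "TermKey",
    "MafReport",
    "pair_to_index",
    "index_to_pair",
    "n_pairs",
    "interaction_column",
    "compute_maf",
    "filter_by_maf",
    "compute_miaf",
    "read_genotype_tsv",
    "read_vcf",
    "write_maf_report",
]


@total_ordering
@dataclass(frozen=True)
class TermKey:
    """A model term: a single SNP i, or an unordered pair (i, j) with i < j."""

    kind: str  # "single" | "pair"
    i: int
    j: int | None = None

    def __post_init__(self) -> None:
        if self.kind == "single":
            if self.j is not None:
                raise ValueError("single terms carry no second index")
            if self.i < 0:
                raise ValueError("negative SNP index")
        elif self.kind == "pair":
            if self.j is None or not 0 <= self.i < self.j:
                raise ValueError(f"pair keys need 0 <= i < j, got ({self.i},{self.j})")
        else:
            raise ValueError(f"unknown term kind {self.kind!r}")

    @classmethod
    def single(cls, i: int) -> "TermKey":
        return cls("single", int(i))

    @classmethod
    def pair(cls, i: int, j: int) -> "TermKey":
        return cls("pair", int(i), int(j))

    def sort_key(self) -> tuple:
        # deterministic tie-break order: (kind, i, j), "pair" < "single"
        return (self.kind, self.i, -1 if self.j is None else self.j)

    def __lt__(self, other: "TermKey") -> bool:
        return self.sort_key() < other.sort_key()

    def linear_index(self, p: int) -> int:
        """Position in the concatenated [singles | pairs] column layout."""
        if self.kind == "single":
            if self.i >= p:
                raise ValueError(f"index {self.i} outside p={p}")
            return self.i
        return p + pair_to_index(self.i, self.j, p)

    @classmethod
    def from_linear(cls, k: int, p: int) -> "TermKey":
        if k < p:
            return cls.single(k)
        return cls.pair(*index_to_pair(k - p, p))


def n_pairs(p: int) -> int:
    """Number of unordered SNP pairs, p(p-1)/2, exact for any p."""
    if p < 0:
        raise ValueError("p must be non-negative")
    return p * (p - 1) // 2


def pair_to_index(i: int, j: int, p: int) -> int:
    """Linear column index of pair (i, j) in row-major upper-triangle order."""
    if not 0 <= i < j < p:
        raise ValueError(f"need 0 <= i < j < p, got ({i}, {j}, {p})")
    return i * p - i * (i + 1) // 2 + (j - i - 1)


def index_to_pair(k: int, p: int) -> tuple[int, int]:
    """Inverse of :func:`pair_to_index` (closed form via triangular root)."""
    total = n_pairs(p)
    if not 0 <= k < total:
        raise ValueError(f"pair index {k} outside [0, {total})")
    # remaining pairs strictly below row i: total - k; row i is the smallest i
    # with rem(i) = (p-1-i)(p-i)/2 <= total - k - ... use the triangular root.
    rem = total - k
    t = (isqrt(8 * rem - 7) + 1) // 2  # largest t with t(t-1)/2 < rem, then +1 checks
    while t * (t + 1) // 2 < rem:
        t += 1
    while t * (t - 1) // 2 >= rem:
        t -= 1
    i = p - 1 - t
    j = i + 1 + (k - (i * p - i * (i + 1) // 2))
    return i, j


def interaction_column(X: GenotypeMatrix, i: int, j: int) -> np.ndarray:
    """Elementwise product of raw dosage columns i and j (i < j)."""
    if not 0 <= i < j < X.p:
        raise ValueError(
            f"need 0 <= i < j < p (self-products are excluded), got ({i}, {j})"
        )
    return X.values[:, i].astype(np.int64) * X.values[:, j].astype(np.int64)


def compute_maf(X: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency min(f, 1-f), f = mean dosage / ploidy."""
    f = X.values.mean(axis=0) / X.ploidy
    return np.minimum(f, 1.0 - f)


@dataclass
class MafReport:
    maf: np.ndarray
    threshold: float
    kept: np.ndarray  # original indices surviving the filter
    index_map: dict[int, int]  # original -> filtered position


def filter_by_maf(
    X: GenotypeMatrix, threshold: float = 0.3
) -> tuple[GenotypeMatrix, MafReport]:
    """Keep SNPs with MAF strictly greater than ``threshold``; order preserved."""
    if not 0.0 <= threshold < 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5)")
    maf = compute_maf(X)
    kept = np.flatnonzero(maf > threshold)
    if kept.size == 0:
        raise ValueError(f"no SNP passes MAF > {threshold}")
    report = MafReport(
        maf=maf,
        threshold=threshold,
        kept=kept,
        index_map={int(orig): new for new, orig in enumerate(kept)},
    )
    return X.subset_snps(kept), report


def compute_miaf(X: GenotypeMatrix, i: int, j: int) -> float:
    """Minor interaction allele frequency of the product column (i, j).

    f is the mean of the product column scaled by its maximum attainable
    value (ploidy^2); MIAF = min(f, 1-f).  In inbred coding f is simply the
    frequency of 1 in the product column.
    """
    z = interaction_column(X, i, j)
    f = z.mean() / (X.ploidy ** 2)
    return float(min(f, 1.0 - f))


# ---------------------------------------------------------------------------
# readers / writers

def read_genotype_tsv(path, ploidy: int = 1) -> GenotypeMatrix:
    """Read the delimited matrix written by :func:`simdata.write_genotype_tsv`."""
    chroms = pos = ids = None
    individuals: list[str] = []
    rows: list[list[int]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "#chrom":
                chroms = parts[1:]
            elif parts[0] == "#pos":
                pos = [int(x) for x in parts[1:]]
            elif parts[0] == "#id":
                ids = parts[1:]
            elif parts[0].startswith("#"):
                continue
            else:
                individuals.append(parts[0])
                rows.append([int(x) for x in parts[1:]])
    if chroms is None or pos is None or ids is None:
        raise ValueError(f"{path}: missing #chrom/#pos/#id header rows")
    markers = [Marker(c, q, s) for c, q, s in zip(chroms, pos, ids)]
    return GenotypeMatrix(
        np.asarray(rows, dtype=np.int8), markers, individuals, ploidy=ploidy
    )


def read_vcf(path, ploidy: int = 1) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix (ALT allele count per individual).

    Multiallelic sites are rejected; missing genotypes are mean-imputed to
    the nearest integer dosage.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    individuals = list(vcf.samples)
    markers: list[Marker] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic site {var.CHROM}:{var.POS} is not supported"
            )
        gt = np.asarray(var.gt_types, dtype=float)  # 0,1,2; 3 = unknown
        miss = gt == 3
        if miss.any():
            fill = np.round(gt[~miss].mean()) if (~miss).any() else 0.0
            gt[miss] = fill
        markers.append(Marker(var.CHROM, var.POS, var.ID or f"{var.CHROM}:{var.POS}"))
        cols.append(gt)
    vcf.close()
    values = np.column_stack(cols).astype(np.int8)
    if ploidy == 1:
        # homozygous-calls convention: 1/1 (gt_types 2) is dosage 1
        values = (values >= 1).astype(np.int8)
    return GenotypeMatrix(values, markers, individuals, ploidy=ploidy)


def write_maf_report(report: MafReport, markers: list[Marker], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tid\tmaf\tkept\n")
        keptset = set(int(i) for i in report.kept)
        for idx, (m, f) in enumerate(zip(markers, report.maf)):
            fh.write(f"{m.chrom}\t{m.pos}\t{m.id}\t{f:.6g}\t{int(idx in keptset)}\n")
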