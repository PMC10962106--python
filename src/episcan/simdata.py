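"""Genotype/phenotype simulation with a known sparse genetic architecture.

Genotypes are drawn marker-by-marker from a binomial model: in ``inbred``
mode (highly homozygous lines, e.g. Arabidopsis accessions) each dosage is
Bernoulli(freq) coded {0,1}; in ``outbred`` mode dosages are Binomial(2,
freq) coded {0,1,2}.  Phenotypes are built from a sparse architecture of
simple (additive), pairwise-epistatic and pure-quadratic effects, and
Gaussian noise is added so that the realized narrow-sense heritability
``var(g)/var(Y)`` matches a target h2.

Pairwise effects come in four flavours: ``product`` (the coefficient
multiplies the raw dosage product x_i * x_j) and three classical two-locus
penetrance models (Marchini et al. 2005): type 1 multiplicative within and
between loci, type 2 two-locus multiplicative interaction, and type 3
two-locus threshold interaction.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Marker",
    "GenotypeMatrix",
    "PhenotypeVector",
    "Architecture",
    "MarchiniTable",
    "sample_genotypes",
    "sample_architecture",
    "marchini_table",
    "genetic_value",
    "add_noise_for_h2",
    "simulate_phenotype",
    "write_genotype_tsv",
    "write_vcf",
    "write_phenotype_tsv",
]

Mode = Literal["inbred", "outbred"]

PAIR_TYPES = ("product", "marchini1", "marchini2", "marchini3")


@dataclass(frozen=True)
class Marker:
    chrom: str
    pos: int  # 1-based
    id: str


@dataclass
class GenotypeMatrix:
    """n individuals x p SNPs of integer allele dosages plus metadata."""

    values: np.ndarray
    markers: list[Marker]
    individuals: list[str]
    ploidy: int = 1  # 1 -> {0,1} inbred coding, 2 -> {0,1,2} outbred coding

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.markers) != p:
            raise ValueError(f"{len(self.markers)} markers for {p} SNP columns")
        if len(self.individuals) != n:
            raise ValueError(f"{len(self.individuals)} ids for {n} rows")
        lo, hi = self.values.min(initial=0), self.values.max(initial=0)
        if lo < 0 or hi > self.ploidy:
            raise ValueError(
                f"dosages outside coding set [0, {self.ploidy}]: saw [{lo}, {hi}]"
            )
        if any(m.pos < 0 for m in self.markers):
            raise ValueError("marker positions must be non-negative")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset_snps(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            values=self.values[:, idx],
            markers=[self.markers[i] for i in idx],
            individuals=list(self.individuals),
            ploidy=self.ploidy,
        )


@dataclass
class PhenotypeVector:
    values: np.ndarray
    name: str = "trait"
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        obs = self.values[~self.missing]
        if obs.size and obs.var() == 0.0:
            raise ValueError("phenotype has zero variance over observed entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def observed(self) -> np.ndarray:
        return self.values[~self.missing]


@dataclass
class Architecture:
    """The simulated truth: sparse term sets with signed effect sizes.

    ``pair_effects`` entries are (i, j, theta, interaction_type) with i < j;
    ``simple_effects`` / ``quad_effects`` entries are (snp, theta).
    """

    simple_effects: list[tuple[int, float]] = field(default_factory=list)
    pair_effects: list[tuple[int, int, float, str]] = field(default_factory=list)
    quad_effects: list[tuple[int, float]] = field(default_factory=list)
    target_h2: float = 0.5
    noise_mode: Literal["fixed", "random"] = "fixed"
    seed: int = 0
    marchini_mu: float = 1.0
    marchini_theta: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_h2 <= 1.0):
            raise ValueError("target_h2 must lie in [0, 1]")
        for i, j, _, t in self.pair_effects:
            if not i < j:
                raise ValueError(f"pair indices must satisfy i<j, got ({i},{j})")
            if t not in PAIR_TYPES:
                raise ValueError(f"unknown interaction type {t!r}")
        seen: set = set()
        for key in self.term_keys():
            if key in seen:
                raise ValueError(f"duplicate term {key}")
            seen.add(key)
        if not seen:
            raise ValueError("architecture must contain at least one non-null term")

    def term_keys(self) -> list[tuple]:
        """Canonical term identifiers: ('single', i) and ('pair', i, j).

        Quadratic terms are identified with their SNP ('single', i): the scan
        dictionary has no self-product column, so x_i^2 signal is discovered
        (if at all) through the x_i column.
        """
        keys: list[tuple] = [("single", i) for i, _ in self.simple_effects]
        keys += [("pair", i, j) for i, j, _, _ in self.pair_effects]
        keys += [
            ("single", i)
            for i, _ in self.quad_effects
            if ("single", i) not in keys
        ]
        return keys

    def n_terms(self) -> int:
        return len(self.simple_effects) + len(self.pair_effects) + len(self.quad_effects)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Architecture":
        with open(path) as fh:
            d = json.load(fh)
        d["simple_effects"] = [tuple(t) for t in d["simple_effects"]]
        d["pair_effects"] = [tuple(t) for t in d["pair_effects"]]
        d["quad_effects"] = [tuple(t) for t in d["quad_effects"]]
        return cls(**d)


@dataclass
class MarchiniTable:
    """3x3 table of genetic values indexed by the two dosages."""

    type_id: int
    mu: float
    theta: float
    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (3, 3):
            raise ValueError("penetrance table must be 3x3")
        if not np.all(np.isfinite(self.table)):
            raise ValueError("penetrance table entries must be finite")


def marchini_table(type_id: int, mu: float = 1.0, theta: float = 1.0) -> MarchiniTable:
    """Two-locus penetrance table for interaction model ``type_id``.

    type 1: mu*(1+theta)^(i+j)   (multiplicative within and between loci)
    type 2: mu*(1+theta)^(i*j)   (two-locus multiplicative interaction)
    type 3: mu*(1+theta) if i>=1 and j>=1 else mu   (threshold)
    """
    if type_id not in (1, 2, 3):
        raise ValueError(f"type_id must be 1, 2 or 3, got {type_id}")
    i = np.arange(3)[:, None]
    j = np.arange(3)[None, :]
    if type_id == 1:
        tab = mu * (1.0 + theta) ** (i + j)
    elif type_id == 2:
        tab = mu * (1.0 + theta) ** (i * j)
    else:
        tab = np.where((i >= 1) & (j >= 1), mu * (1.0 + theta), mu)
    return MarchiniTable(type_id=type_id, mu=mu, theta=theta, table=tab)


def sample_genotypes(
    n: int,
    p: int,
    allele_freq: float | np.ndarray = 0.5,
    mode: Mode = "inbred",
    seed: int = 0,
    chrom: str = "1",
) -> GenotypeMatrix:
    """Draw an n x p dosage matrix from independent binomial markers."""
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    freq = np.broadcast_to(np.asarray(allele_freq, dtype=float), (p,))
    if np.any(freq <= 0.0) or np.any(freq >= 1.0):
        raise ValueError("allele_freq must lie strictly in (0, 1)")
    if mode not in ("inbred", "outbred"):
        raise ValueError(f"unknown mode {mode!r}")
    ploidy = 1 if mode == "inbred" else 2
    rng = np.random.default_rng(seed)
    values = rng.binomial(ploidy, freq, size=(n, p)).astype(np.int8)
    markers = [Marker(chrom, i + 1, f"snp{i}") for i in range(p)]
    individuals = [f"ind{i}" for i in range(n)]
    return GenotypeMatrix(values, markers, individuals, ploidy=ploidy)


def sample_architecture(
    p: int,
    k_simple: int,
    k_pair: int,
    k_quad: int = 0,
    effect_range: tuple[float, float] = (0.5, 1.5),
    types: Sequence[str] = ("product",),
    target_h2: float = 0.5,
    noise_mode: Literal["fixed", "random"] = "fixed",
    seed: int = 0,
    marchini_mu: float = 1.0,
    marchini_theta: float = 1.0,
) -> Architecture:
    """Dispatch non-null coordinates between simple, pair and quadratic terms.

    Effect magnitudes are uniform on ``effect_range`` with random sign.
    Interaction types are cycled through ``types`` in order.
    """
    if k_simple + k_pair + k_quad < 1:
        raise ValueError("need at least one non-null term")
    max_pairs = p * (p - 1) // 2
    if k_pair > max_pairs:
        raise ValueError(f"k_pair={k_pair} exceeds the {max_pairs} available pairs")
    if k_simple + k_quad > p:
        raise ValueError("more single-SNP terms requested than SNPs")
    for t in types:
        if t not in PAIR_TYPES:
            raise ValueError(f"unknown interaction type {t!r}")
    rng = np.random.default_rng(seed)

    def draw(k: int) -> np.ndarray:
        return rng.uniform(*effect_range, size=k) * rng.choice([-1.0, 1.0], size=k)

    singles = rng.choice(p, size=k_simple + k_quad, replace=False)
    simple_idx, quad_idx = singles[:k_simple], singles[k_simple:]
    pairs: set[tuple[int, int]] = set()
    while len(pairs) < k_pair:
        i, j = rng.choice(p, size=2, replace=False)
        pairs.add((int(min(i, j)), int(max(i, j))))
    pair_list = sorted(pairs)
    return Architecture(
        simple_effects=[(int(i), float(t)) for i, t in zip(simple_idx, draw(k_simple))],
        pair_effects=[
            (i, j, float(t), types[c % len(types)])
            for c, ((i, j), t) in enumerate(zip(pair_list, draw(k_pair)))
        ],
        quad_effects=[(int(i), float(t)) for i, t in zip(quad_idx, draw(k_quad))],
        target_h2=target_h2,
        noise_mode=noise_mode,
        seed=seed,
        marchini_mu=marchini_mu,
        marchini_theta=marchini_theta,
    )


def _marchini_contribution(
    xi: np.ndarray, xj: np.ndarray, type_id: int, theta: float, mu: float, mtheta: float
) -> np.ndarray:
    """Centered, variance-matched penetrance lookup for one pair term.

    The realized lookup vector is centered and scaled to unit standard
    deviation, then multiplied by the signed effect size, so every Marchini
    term contributes variance theta^2 regardless of its type.  A degenerate
    (constant) lookup — e.g. mtheta = 0 — contributes nothing.
    """
    tab = marchini_table(type_id, mu=mu, theta=mtheta).table
    vals = tab[xi.astype(np.intp), xj.astype(np.intp)]
    vals = vals - vals.mean()
    sd = vals.std()
    if sd == 0.0:
        return np.zeros_like(vals, dtype=float)
    return theta * vals / sd


def genetic_value(X: GenotypeMatrix, arch: Architecture) -> np.ndarray:
    """Genetic value g for each individual under the architecture.

    g = sum theta*x_i (simple) + sum theta*x_i^2 (quadratic, outbred)
      + sum pair contributions (raw product, or centered Marchini lookup).
    In inbred coding x^2 == x, so quadratic terms alias with simple effects;
    they are merged (with a warning) rather than double-coded.
    """
    V = X.values.astype(float)
    p = X.p
    g = np.zeros(X.n)
    for i, t in arch.simple_effects:
        _check_idx(i, p)
        g += t * V[:, i]
    quads = arch.quad_effects
    if quads and X.ploidy == 1:
        warnings.warn(
            "quadratic effects alias with simple effects in inbred coding "
            "(x^2 == x); merging them into the additive part",
            stacklevel=2,
        )
    for i, t in quads:
        _check_idx(i, p)
        g += t * (V[:, i] if X.ploidy == 1 else V[:, i] ** 2)
    for i, j, t, kind in arch.pair_effects:
        _check_idx(i, p)
        _check_idx(j, p)
        if kind == "product":
            g += t * V[:, i] * V[:, j]
        else:
            g += _marchini_contribution(
                X.values[:, i], X.values[:, j], int(kind[-1]), t,
                arch.marchini_mu, arch.marchini_theta,
            )
    return g


def _check_idx(i: int, p: int) -> None:
    if not 0 <= i < p:
        raise IndexError(f"SNP index {i} outside [0, {p})")


def add_noise_for_h2(
    g: np.ndarray,
    target_h2: float,
    noise_mode: Literal["fixed", "random"] = "fixed",
    seed: int = 0,
    name: str = "trait",
) -> PhenotypeVector:
    """Add Gaussian noise so that var(g)/var(Y) converges to ``target_h2``.

    sigma_eps^2 = var(g) * (1 - h2) / h2, computed from the realized var(g).
    ``random`` mode additionally jitters sigma uniformly in [0.8, 1.2]*sigma0
    per call, emulating replicate-to-replicate noise-level variation.
    """
    g = np.asarray(g, dtype=float)
    if not 0.0 < target_h2 <= 1.0:
        raise ValueError("target_h2 must lie in (0, 1]")
    vg = g.var()
    if vg == 0.0:
        raise ValueError("degenerate signal: var(g) = 0")
    if target_h2 == 1.0:
        return PhenotypeVector(g.copy(), name=name)
    sigma = np.sqrt(vg * (1.0 - target_h2) / target_h2)
    rng = np.random.default_rng(seed)
    if noise_mode == "random":
        sigma *= rng.uniform(0.8, 1.2)
    elif noise_mode != "fixed":
        raise ValueError(f"unknown noise_mode {noise_mode!r}")
    return PhenotypeVector(g + sigma * rng.standard_normal(g.shape[0]), name=name)


def simulate_phenotype(
    X: GenotypeMatrix, arch: Architecture, seed: int | None = None, name: str = "trait"
) -> PhenotypeVector:
    """Convenience: genetic value + calibrated noise in one call."""
    g = genetic_value(X, arch)
    return add_noise_for_h2(
        g, arch.target_h2, arch.noise_mode,
        seed=arch.seed + 1 if seed is None else seed, name=name,
    )


# ---------------------------------------------------------------------------
# writers

def write_genotype_tsv(X: GenotypeMatrix, path) -> None:
    """Delimited integer matrix with marker header rows (chrom, pos, id)."""
    with open(path, "w") as fh:
        fh.write("#chrom\t" + "\t".join(m.chrom for m in X.markers) + "\n")
        fh.write("#pos\t" + "\t".join(str(m.pos) for m in X.markers) + "\n")
        fh.write("#id\t" + "\t".join(m.id for m in X.markers) + "\n")
        for ind, row in zip(X.individuals, X.values):
            fh.write(ind + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def write_vcf(X: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2: one ALT per site, GT-only FORMAT.

    Inbred dosages are written as homozygous calls (0 -> 0/0, 1 -> 1/1);
    outbred dosage counts ALT alleles.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"} if X.ploidy == 2 else {0: "0/0", 1: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = []
        for m in X.markers:
            if m.chrom not in chroms:
                chroms.append(m.chrom)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(X.individuals) + "\n"
        )
        for k, m in enumerate(X.markers):
            calls = "\t".join(gt_map[int(v)] for v in X.values[:, k])
            fh.write(f"{m.chrom}\t{m.pos}\t{m.id}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def write_phenotype_tsv(Y: PhenotypeVector, individuals: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        fh.write(f"individual\t{Y.name}\n")
        for ind, v in zip(individuals, Y.values):
            fh.write(f"{ind}\t{'NA' if not np.isfinite(v) else repr(float(v))}\n")
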