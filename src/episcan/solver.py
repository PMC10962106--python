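"""Sketch-compressed sparse effect estimation over implicit interaction terms.

The estimator works piece by piece on blocks of model terms (single-SNP
columns and pairwise product columns).  Within a piece with standardized
design M (n x d) and centered phenotype Y the compressed ridge estimate is

    c      = (A M' M A' + lambda I_m)^-1  A M' Y        (m-dimensional)
    theta  = A' c                                        (decompressed)

with A an m x d random sketch (gaussian or rademacher entries, scale
1/sqrt(m)).  When the sketch dimension reaches the piece dimension the
sketch is dropped (A = I) and the solve is an exact ridge.  Estimates can be
averaged over several independent sketches, which suppresses the zero-mean
decompression noise.

The scan estimate is a screening statistic: with the default strong ridge
it behaves like a stabilized, partially decorrelated marginal correlation
and is robust in the very-high-dimensional regime (d >> n).  Final effect
sizes and the reported support come from a debiasing refit: orthogonal
matching pursuit over the pooled top scan candidates, followed by ordinary
least squares on the selected support (``n_star`` terms at most).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .interactions import TermKey
from .simdata import GenotypeMatrix

__all__ = [
    "SolverConfig",
    "SketchMatrix",
    "EffectMap",
    "make_sketch",
    "sketch_gram",
    "default_sketch_dim",
    "term_design",
    "solve_compressed_ridge",
    "average_over_sketches",
    "solve_block",
    "top_n_support",
    "omp_refit",
    "select_ridge_cv",
    "permutation_threshold",
    "seed_for",
]

# sketch-dimension rule m = ceil(C_SKETCH * K_MAX * ln d), capped at d
C_SKETCH = 8.0
K_MAX = 50


def seed_for(root: int, *ids) -> int:
    """Deterministic sub-seed derived from a root seed and a path of ids.

    String ids are folded in via a stable digest (Python's ``hash`` is
    salted per process and would break cross-run reproducibility).
    """
    import hashlib

    ent = [int(root)]
    for x in ids:
        if isinstance(x, str):
            ent.append(int.from_bytes(hashlib.sha256(x.encode()).digest()[:4], "little"))
        else:
            ent.append(int(x))
    return int(np.random.SeedSequence(ent).generate_state(1)[0] % (2**31))


def default_sketch_dim(d: int, c: float = C_SKETCH, k_max: int = K_MAX) -> int:
    """m = ceil(c * k_max * ln d), capped at d (no sketch below that size)."""
    if d <= 1:
        return max(d, 1)
    return min(d, int(math.ceil(c * k_max * math.log(d))))


@dataclass
class SolverConfig:
    """Knobs of the piecewise sketched-ridge scan.

    block_size
        SNPs per block axis of the piece plan; ``None`` selects
        clip(round(sqrt(2 n)), 32, 500) so that a piece holds ~2n terms.
    sketch_dim / sketch_c / k_max
        Explicit sketch dimension, or the c*k_max*ln(d) rule when ``None``.
    n_sketches
        Independent sketches averaged per piece (ignored on the exact path).
    ridge / ridge_mult
        Absolute ridge lambda, or lambda = ridge_mult * trace(G)/dim(G).
    n_star
        Retained support size (sparsity budget of the selection step).
    pool_factor
        The debiasing refit pools pool_factor * n_star scan candidates.
    """

    block_size: int | None = None
    sketch_kind: str = "gaussian"  # gaussian | rademacher | identity
    sketch_dim: int | None = None
    sketch_c: float = C_SKETCH
    k_max: int = K_MAX
    n_sketches: int = 1
    ridge: float | None = None
    ridge_mult: float = 10.0
    n_star: int = 50
    pool_factor: int = 10
    debias: bool = False
    standardize: bool = True
    dtype: str = "float64"
    seed: int = 0
    memory_limit_bytes: float = 4.0e9

    def __post_init__(self) -> None:
        if self.n_sketches < 1 or self.n_star < 1:
            raise ValueError("n_sketches and n_star must be >= 1")
        if self.block_size is not None and self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.ridge is not None and self.ridge < 0:
            raise ValueError("ridge must be >= 0")

    def sketch_dim_for(self, d: int) -> int:
        if self.sketch_dim is not None:
            return min(self.sketch_dim, d)
        return default_sketch_dim(d, self.sketch_c, self.k_max)

    def with_seed(self, seed: int) -> "SolverConfig":
        return replace(self, seed=seed)


@dataclass
class SketchMatrix:
    """Seeded random projection A (m x d), rows scaled to unit expected norm."""

    m: int
    d: int
    kind: str = "gaussian"
    seed: int = 0
    values: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not 1 <= self.m <= self.d:
            raise ValueError(f"need 1 <= m <= d, got m={self.m}, d={self.d}")
        if self.m * self.d > 3e8:
            raise MemoryError(
                f"sketch of {self.m} x {self.d} entries is too large to materialize; "
                "use a smaller piece (block_size) or sketch_dim"
            )
        rng = np.random.default_rng(self.seed)
        if self.kind == "gaussian":
            self.values = rng.standard_normal((self.m, self.d)) / math.sqrt(self.m)
        elif self.kind == "rademacher":
            self.values = (
                rng.integers(0, 2, size=(self.m, self.d)).astype(float) * 2.0 - 1.0
            ) / math.sqrt(self.m)
        elif self.kind == "identity":
            if self.m != self.d:
                raise ValueError("identity sketch requires m == d")
            self.values = np.eye(self.d)
        else:
            raise ValueError(f"unknown sketch kind {self.kind!r}")


def make_sketch(m: int, d: int, kind: str = "gaussian", seed: int = 0) -> SketchMatrix:
    return SketchMatrix(m=m, d=d, kind=kind, seed=seed)


def sketch_gram(A: SketchMatrix | np.ndarray, M: np.ndarray) -> np.ndarray:
    """A (M'M) A' without materializing M'M: via B = M A' in O(n d m)."""
    Av = A.values if isinstance(A, SketchMatrix) else np.asarray(A)
    if Av.shape[1] != M.shape[1]:
        raise ValueError(
            f"sketch is for d={Av.shape[1]} columns but design has {M.shape[1]}"
        )
    B = M @ Av.T
    return B.T @ B


def term_design(
    X: GenotypeMatrix,
    keys: Sequence[TermKey],
    dtype: str = "float64",
    standardize: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Materialize (standardized) columns for a set of terms.

    Returns (M, mean, sd).  Constant columns get sd = inf so their
    standardized column is identically zero (and their estimate 0).
    """
    V = X.values.astype(dtype)
    n, d = X.n, len(keys)
    M = np.empty((n, d), dtype=dtype, order="F")
    for c, key in enumerate(keys):
        if key.kind == "single":
            M[:, c] = V[:, key.i]
        else:
            np.multiply(V[:, key.i], V[:, key.j], out=M[:, c])
    mean = M.mean(axis=0)
    sd = M.std(axis=0)
    if standardize:
        safe = np.where(sd == 0.0, np.inf, sd)
        M -= mean
        M /= safe.astype(dtype)
        return M, mean, np.where(sd == 0.0, np.inf, sd)
    return M, mean, sd


def _ridge_solve(B: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """argmin ||B c - y||^2 + lam ||c||^2, primal or dual by aspect ratio."""
    n, m = B.shape
    if lam <= 0.0:
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        return coef
    if m <= n:
        G = (B.T @ B).astype(B.dtype)
        G[np.diag_indices_from(G)] += B.dtype.type(lam)
        return cho_solve(cho_factor(G, lower=True, check_finite=False),
                         B.T @ y, check_finite=False)
    K = (B @ B.T).astype(B.dtype)
    K[np.diag_indices_from(K)] += B.dtype.type(lam)
    alpha = cho_solve(cho_factor(K, lower=True, check_finite=False), y,
                      check_finite=False)
    return B.T @ alpha


def _resolve_lambda(B: np.ndarray, config: SolverConfig) -> float:
    if config.ridge is not None:
        return config.ridge
    # trace of the (sketched) Gram = squared Frobenius norm of B
    m = B.shape[1]
    return config.ridge_mult * float(np.square(B).sum()) / m


def solve_compressed_ridge(
    M: np.ndarray,
    Y: np.ndarray,
    A: SketchMatrix | np.ndarray | None,
    lam: float | None = None,
    config: SolverConfig | None = None,
) -> np.ndarray:
    """Compressed ridge estimate theta = A' (A M'M A' + lam I)^-1 A M' Y.

    ``A=None`` means the exact (uncompressed) path, algebraically A = I.
    """
    config = config or SolverConfig()
    y = np.asarray(Y, dtype=M.dtype)
    if y.shape[0] != M.shape[0]:
        raise ValueError("Y length does not match the design row count")
    if A is None:
        B = M
    else:
        Av = (A.values if isinstance(A, SketchMatrix) else np.asarray(A)).astype(M.dtype)
        if Av.shape[1] != M.shape[1]:
            raise ValueError("sketch dimension mismatch with design columns")
        B = M @ Av.T
    if lam is None:
        lam = _resolve_lambda(B, config)
    if lam == 0.0 and B.shape[1] >= B.shape[0]:
        warnings.warn("lambda = 0 on an underdetermined system; using least norm")
    c = _ridge_solve(B, y, float(lam))
    theta = c if A is None else Av.T @ c
    return np.asarray(theta, dtype=np.float64)


def average_over_sketches(
    M: np.ndarray,
    Y: np.ndarray,
    config: SolverConfig,
    seed: int | None = None,
) -> np.ndarray:
    """Mean of compressed-ridge estimates over n_sketches independent sketches."""
    d = M.shape[1]
    m = config.sketch_dim_for(d)
    root = config.seed if seed is None else seed
    if m >= d or config.sketch_kind == "identity":
        return solve_compressed_ridge(M, Y, None, config=config)
    total = np.zeros(d)
    for s in range(config.n_sketches):
        A = make_sketch(m, d, config.sketch_kind, seed_for(root, "sketch", s))
        total += solve_compressed_ridge(M, Y, A, config=config)
    return total / config.n_sketches


@dataclass
class EffectMap:
    """Sparse mapping term -> signed effect estimate, with optional support.

    ``theta`` is on the raw-dosage scale (effect per dosage unit relative to
    the reference coding); ``theta_std`` is on the standardized-column scale
    used for ranking (comparable across terms of different frequency).
    ``support_score`` is |debiased theta_std| on selected terms, 0 elsewhere.
    """

    p: int
    theta: dict[TermKey, float] = field(default_factory=dict)
    theta_std: dict[TermKey, float] = field(default_factory=dict)
    support_score: dict[TermKey, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def set(self, key: TermKey, theta_std: float, theta_raw: float) -> None:
        self.theta_std[key] = float(theta_std)
        self.theta[key] = float(theta_raw)

    def __len__(self) -> int:
        return len(self.theta_std)

    def keys(self) -> Iterable[TermKey]:
        return self.theta_std.keys()

    def _rank_value(self, key: TermKey) -> tuple:
        return (
            -self.support_score.get(key, 0.0),
            -abs(self.theta_std.get(key, 0.0)),
            key.sort_key(),
        )

    def top(self, k: int) -> list[TermKey]:
        """Top-k terms: selected support first (by debiased magnitude), then
        the scan ranking; deterministic lexicographic tie-breaking."""
        return sorted(self.theta_std, key=self._rank_value)[:k]

    def pairs_only(self) -> "EffectMap":
        """The interaction (2D) landscape: pair terms without the diagonal."""
        return self.restrict([k for k in self.theta_std if k.kind == "pair"])

    def restrict(self, keys: Sequence[TermKey]) -> "EffectMap":
        sub = EffectMap(p=self.p, provenance=dict(self.provenance))
        for key in keys:
            sub.set(key, self.theta_std[key], self.theta[key])
            if key in self.support_score:
                sub.support_score[key] = self.support_score[key]
        return sub

    # -- serialization -----------------------------------------------------
    def to_tsv(self, path, markers=None) -> None:
        def loc(i):
            if markers is None:
                return ("1", i + 1)
            m = markers[i]
            return (m.chrom, m.pos)

        rows = []
        for key in sorted(self.theta_std, key=self._rank_value):
            ci, pi = loc(key.i)
            cj, pj = loc(key.j) if key.kind == "pair" else (".", 0)
            rows.append(
                f"{key.kind}\t{ci}\t{pi}\t{cj}\t{pj}\t{key.i}\t"
                f"{'.' if key.j is None else key.j}\t{self.theta[key]!r}\t"
                f"{self.theta_std[key]!r}\t{self.support_score.get(key, 0.0)!r}"
            )
        with open(path, "w") as fh:
            fh.write(
                "kind\tchrom_i\tpos_i\tchrom_j\tpos_j\tidx_i\tidx_j\t"
                "theta\ttheta_std\tsupport_score\n"
            )
            fh.write("\n".join(rows) + ("\n" if rows else ""))

    @classmethod
    def from_tsv(cls, path, p: int) -> "EffectMap":
        em = cls(p=p)
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("kind\t")
            for line in fh:
                f = line.rstrip("\n").split("\t")
                key = (
                    TermKey.single(int(f[5]))
                    if f[0] == "single"
                    else TermKey.pair(int(f[5]), int(f[6]))
                )
                em.set(key, float(f[8]), float(f[7]))
                if float(f[9]) > 0:
                    em.support_score[key] = float(f[9])
        return em

    def to_hdf5(self, path, group: str = "effects") -> None:
        import h5py

        keys = sorted(self.theta_std, key=self._rank_value)
        kind = np.array([0 if k.kind == "single" else 1 for k in keys], dtype=np.int8)
        ii = np.array([k.i for k in keys], dtype=np.int64)
        jj = np.array([-1 if k.j is None else k.j for k in keys], dtype=np.int64)
        with h5py.File(path, "a") as fh:
            if group in fh:
                del fh[group]
            g = fh.create_group(group)
            g.attrs["p"] = self.p
            g.create_dataset("kind", data=kind)
            g.create_dataset("i", data=ii)
            g.create_dataset("j", data=jj)
            g.create_dataset("theta", data=np.array([self.theta[k] for k in keys]))
            g.create_dataset(
                "theta_std", data=np.array([self.theta_std[k] for k in keys])
            )
            g.create_dataset(
                "support_score",
                data=np.array([self.support_score.get(k, 0.0) for k in keys]),
            )

    @classmethod
    def from_hdf5(cls, path, group: str = "effects") -> "EffectMap":
        import h5py

        with h5py.File(path, "r") as fh:
            g = fh[group]
            em = cls(p=int(g.attrs["p"]))
            for kd, i, j, th, ts, sc in zip(
                g["kind"][:], g["i"][:], g["j"][:], g["theta"][:],
                g["theta_std"][:], g["support_score"][:],
            ):
                key = TermKey.single(int(i)) if kd == 0 else TermKey.pair(int(i), int(j))
                em.set(key, float(ts), float(th))
                if sc > 0:
                    em.support_score[key] = float(sc)
        return em


def solve_block(
    X: GenotypeMatrix,
    keys: Sequence[TermKey],
    Y: np.ndarray,
    config: SolverConfig,
    seed: int | None = None,
    report_keys: Sequence[TermKey] | None = None,
) -> EffectMap:
    """Scan one piece: standardize term columns, sketch-solve, rescale.

    ``report_keys`` restricts which estimates enter the returned map
    (covariate terms — e.g. singles inside an off-diagonal pair piece — are
    solved for but not reported).  Constant columns are excluded (theta 0).
    """
    if len(keys) == 0:
        raise ValueError("empty term set")
    y = np.asarray(Y, dtype=float)
    if y.shape[0] != X.n:
        raise ValueError("phenotype length does not match genotype rows")
    est_bytes = X.n * len(keys) * (4 if config.dtype == "float32" else 8)
    if est_bytes > config.memory_limit_bytes:
        raise MemoryError(
            f"piece of {len(keys)} terms x {X.n} rows needs ~{est_bytes/1e9:.1f} GB; "
            "lower block_size or raise memory_limit_bytes"
        )
    yc = (y - y.mean()).astype(config.dtype)
    M, _, sd = term_design(X, keys, dtype=config.dtype, standardize=config.standardize)
    theta_std = average_over_sketches(
        M, yc, config, seed=config.seed if seed is None else seed
    )
    em = EffectMap(p=X.p)
    report = set(report_keys) if report_keys is not None else None
    for c, key in enumerate(keys):
        if report is not None and key not in report:
            continue
        if np.isinf(sd[c]):
            em.set(key, 0.0, 0.0)  # constant column: no information
        else:
            em.set(key, theta_std[c], theta_std[c] / sd[c])
    return em


def top_n_support(em: EffectMap, n_star: int) -> EffectMap:
    """Restrict to the N* largest effects; support_score = |theta_std| there."""
    if n_star < 1:
        raise ValueError("n_star must be >= 1")
    if n_star > len(em):
        warnings.warn(
            f"n_star={n_star} exceeds the {len(em)} available terms; returning all"
        )
    top = em.top(min(n_star, len(em)))
    sub = em.restrict(top)
    for key in top:
        sub.support_score[key] = abs(sub.theta_std[key])
    return sub


def omp_refit(
    X: GenotypeMatrix,
    Y: np.ndarray,
    candidates: Sequence[TermKey],
    n_select: int,
) -> tuple[list[TermKey], dict[TermKey, float], dict[TermKey, float]]:
    """Greedy orthogonal matching pursuit over pooled candidates + OLS refit.

    Selects up to ``n_select`` terms by largest residual correlation,
    orthogonalizing after each pick (this is what removes the correlated
    "relative" terms that a marginal ranking cannot separate), then refits
    the selected support jointly by least squares.

    Returns (selected keys in pick order, theta_std, theta_raw).
    """
    y = np.asarray(Y, dtype=float)
    yc = y - y.mean()
    M, _, sd = term_design(X, list(candidates), dtype="float64", standardize=True)
    finite = ~np.isinf(sd)
    n_select = min(n_select, int(finite.sum()), X.n - 1)
    sel: list[int] = []
    resid = yc.copy()
    Q = np.empty((X.n, 0))
    for _ in range(n_select):
        score = np.abs(M.T @ resid)
        score[~finite] = -np.inf
        score[sel] = -np.inf
        j = int(np.argmax(score))
        if not np.isfinite(score[j]) or score[j] <= 1e-12:
            break
        sel.append(j)
        q = M[:, j] - Q @ (Q.T @ M[:, j])
        nq = np.linalg.norm(q)
        if nq <= 1e-10 * np.linalg.norm(M[:, j]):
            sel.pop()
            finite[j] = False  # numerically inside the selected span
            continue
        q /= nq
        Q = np.column_stack([Q, q])
        resid = resid - q * (q @ resid)
    coef, *_ = np.linalg.lstsq(M[:, sel], yc, rcond=None)
    keys = [list(candidates)[j] for j in sel]
    theta_std = {k: float(c) for k, c in zip(keys, coef)}
    theta_raw = {k: float(c / sd[j]) for k, c, j in zip(keys, coef, sel)}
    return keys, theta_std, theta_raw


def apply_debias(
    X: GenotypeMatrix, Y: np.ndarray, em: EffectMap, config: SolverConfig
) -> EffectMap:
    """Pool the top pool_factor*N* scan candidates, OMP-select N*, refit.

    Selected terms get their debiased estimates and a positive
    support_score; everything else keeps its scan estimate with score 0.
    """
    pool = em.top(min(config.pool_factor * config.n_star, len(em)))
    keys, t_std, t_raw = omp_refit(X, Y, pool, config.n_star)
    for k in keys:
        em.set(k, t_std[k], t_raw[k])
        em.support_score[k] = abs(t_std[k])
    return em


def select_ridge_cv(
    X: GenotypeMatrix,
    keys: Sequence[TermKey],
    Y: np.ndarray,
    grid: Sequence[float] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Optional ridge selection: lambda minimizing k-fold prediction error.

    The grid defaults to trace-scaled multipliers {0.1, 1, 10, 100}.  The
    per-fold solves reuse one design materialization; intended for
    moderate piece sizes (the scan default remains the trace-scaled rule).
    """
    y = np.asarray(Y, dtype=float)
    yc = y - y.mean()
    M, _, _ = term_design(X, list(keys), dtype="float64", standardize=True)
    n, d = M.shape
    if grid is None:
        # trace(G)/dim = n on standardized columns
        grid = [mult * n for mult in (0.1, 1.0, 10.0, 100.0)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    errs = np.zeros(len(grid))
    for f in range(folds):
        test = order[f::folds]
        train = np.setdiff1d(order, test)
        Mt, Me = M[train], M[test]
        for g, lam in enumerate(grid):
            coef = _ridge_solve(Mt, yc[train], float(lam))
            errs[g] += float(np.square(yc[test] - Me @ coef).sum())
    return float(grid[int(np.argmin(errs))])


def permutation_threshold(
    X: GenotypeMatrix,
    keys: Sequence[TermKey],
    Y: np.ndarray,
    config: SolverConfig,
    n_perm: int = 20,
    quantile: float = 0.95,
    seed: int | None = None,
) -> float:
    """Null threshold on |theta_std|: quantile of per-permutation maxima.

    Permutes the phenotype ``n_perm`` times (breaking genotype-phenotype
    links while keeping both marginals), rescans, and records the maximum
    absolute standardized estimate of each permutation.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations for a stable threshold")
    root = config.seed if seed is None else seed
    y = np.asarray(Y, dtype=float)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        rng = np.random.default_rng(seed_for(root, "perm", b))
        yp = rng.permutation(y)
        em = solve_block(X, keys, yp, config, seed=seed_for(root, "permsolve", b))
        maxima[b] = max(abs(v) for v in em.theta_std.values())
    if quantile >= 1.0:
        return float(maxima.max())
    return float(np.quantile(maxima, quantile))
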