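"""Genome-scale orchestration: block plans, 1D and full 2D scans, pyramids.

A scan partitions the p SNPs into blocks of ``B`` along each axis.  Singles
are estimated in per-block singles-only pieces (this IS the 1D scan, and it
is what the diagonal of a 2D map reports).  Intra-block pairs are estimated
in diagonal pieces and cross-block pairs in off-diagonal pieces; in pair
pieces the parent blocks' single columns are included as covariates but
their estimates are only reported from the singles pieces, so every term is
reported exactly once.

The |theta| map over the upper triangle can be exported as a max-pooled
tile pyramid: level-l pixels each cover a 2^l x 2^l square of level-0
cells, so a level-11 pixel summarizes 4,194,304 SNP-pair cells.
"""

from __future__ import annotations

import json
import math
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np

from .interactions import TermKey, n_pairs
from .simdata import GenotypeMatrix
from .solver import EffectMap, SolverConfig, apply_debias, seed_for, solve_block

__all__ = [
    "BlockPlan",
    "Pyramid",
    "auto_block_size",
    "plan_blocks",
    "run_1d",
    "run_2d",
    "build_pyramid",
    "write_json_atomic",
]


def auto_block_size(n: int) -> int:
    """Block axis sized so a piece holds ~2n terms: clip(round(sqrt(2n)), 32, 500)."""
    return int(np.clip(round(math.sqrt(2 * n)), 32, 500))


@dataclass
class BlockPlan:
    p: int
    block_size: int
    blocks: list[tuple[int, int]] = field(init=False)  # [start, stop) per block
    diagonal: list[int] = field(init=False)
    off_diagonal: list[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        B = self.block_size
        nb = max(1, (self.p + B - 1) // B)
        self.blocks = [(b * B, min((b + 1) * B, self.p)) for b in range(nb)]
        self.diagonal = list(range(nb))
        self.off_diagonal = [(a, b) for a in range(nb) for b in range(a + 1, nb)]

    def n_blocks(self) -> int:
        return len(self.blocks)

    def singles_of(self, b: int) -> list[TermKey]:
        lo, hi = self.blocks[b]
        return [TermKey.single(i) for i in range(lo, hi)]

    def intra_pairs_of(self, b: int) -> list[TermKey]:
        lo, hi = self.blocks[b]
        return [TermKey.pair(i, j) for i in range(lo, hi) for j in range(i + 1, hi)]

    def cross_pairs_of(self, a: int, b: int) -> list[TermKey]:
        la, ha = self.blocks[a]
        lb, hb = self.blocks[b]
        return [TermKey.pair(i, j) for i in range(la, ha) for j in range(lb, hb)]


def plan_blocks(p: int, block_size: int) -> BlockPlan:
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    return BlockPlan(p=p, block_size=block_size)


def _check_inputs(X: GenotypeMatrix, Y: np.ndarray) -> np.ndarray:
    y = np.asarray(Y, dtype=float)
    if y.ndim != 1 or y.shape[0] != X.n:
        raise ValueError(
            f"phenotype has {y.shape[0] if y.ndim == 1 else '?'} values "
            f"for {X.n} individuals"
        )
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains missing/non-finite values")
    if y.var() == 0.0:
        raise ValueError("phenotype is constant")
    return y


def _scan_singles(
    X: GenotypeMatrix, y: np.ndarray, config: SolverConfig, plan: BlockPlan
) -> EffectMap:
    em = EffectMap(p=X.p)
    for b in plan.diagonal:
        keys = plan.singles_of(b)
        frag = solve_block(X, keys, y, config, seed=seed_for(config.seed, "diag1d", b))
        em.theta_std.update(frag.theta_std)
        em.theta.update(frag.theta)
    return em


def run_1d(X: GenotypeMatrix, Y: np.ndarray, config: SolverConfig | None = None) -> EffectMap:
    """Per-SNP scan: signed effect estimates for all p single terms."""
    config = config or SolverConfig()
    y = _check_inputs(X, Y)
    B = config.block_size or auto_block_size(X.n)
    plan = plan_blocks(X.p, B)
    em = _scan_singles(X, y, config, plan)
    if config.debias:
        em = apply_debias(X, y, em, config)
    em.provenance = {"scan": "1d", "block_size": B, "seed": config.seed}
    return em


def run_2d(
    X: GenotypeMatrix,
    Y: np.ndarray,
    config: SolverConfig | None = None,
    max_map_terms: int = 1_000_000,
) -> EffectMap:
    """Full 2D scan: all p singles and all p(p-1)/2 pairwise product terms.

    Returns an EffectMap whose keys are exactly {singles} + {pairs i<j}
    when that fits in ``max_map_terms``; beyond that floor only the
    largest-|theta| terms are retained in the sparse map (full maps at
    genome scale run to hundreds of gigabytes).  With ``config.debias``
    the top-N* support carries debiased estimates and positive scores.
    """
    config = config or SolverConfig()
    y = _check_inputs(X, Y)
    B = config.block_size or auto_block_size(X.n)
    plan = plan_blocks(X.p, B)
    em = _scan_singles(X, y, config, plan)
    for b in plan.diagonal:
        pairs = plan.intra_pairs_of(b)
        if not pairs:
            continue
        keys = plan.singles_of(b) + pairs
        frag = solve_block(
            X, keys, y, config,
            seed=seed_for(config.seed, "diag2d", b), report_keys=pairs,
        )
        em.theta_std.update(frag.theta_std)
        em.theta.update(frag.theta)
    for a, b in plan.off_diagonal:
        pairs = plan.cross_pairs_of(a, b)
        keys = plan.singles_of(a) + plan.singles_of(b) + pairs
        frag = solve_block(
            X, keys, y, config,
            seed=seed_for(config.seed, "off2d", a, b), report_keys=pairs,
        )
        em.theta_std.update(frag.theta_std)
        em.theta.update(frag.theta)
    assert len(em) == X.p + n_pairs(X.p)
    if config.debias:
        em = apply_debias(X, y, em, config)
    if len(em) > max_map_terms:
        em = em.restrict(em.top(max_map_terms))
    em.provenance = {"scan": "2d", "block_size": B, "seed": config.seed}
    return em


@dataclass
class Pyramid:
    """Max-pooled multiresolution tiling of the |theta| upper-triangle map."""

    levels: list[np.ndarray]  # levels[0] is the full-resolution map

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @staticmethod
    def cells_per_pixel(level: int) -> int:
        return 4 ** level

    @property
    def apex(self) -> float:
        return float(self.levels[-1].max()) if self.levels else 0.0

    def to_hdf5(self, path, group: str = "pyramid") -> None:
        import h5py

        with h5py.File(path, "a") as fh:
            if group in fh:
                del fh[group]
            g = fh.create_group(group)
            for lv, arr in enumerate(self.levels):
                g.create_dataset(f"level{lv}", data=arr)


def _pool2(a: np.ndarray) -> np.ndarray:
    r = (a.shape[0] + 1) // 2 * 2
    c = (a.shape[1] + 1) // 2 * 2
    padded = np.zeros((r, c), dtype=a.dtype)
    padded[: a.shape[0], : a.shape[1]] = a
    return padded.reshape(r // 2, 2, c // 2, 2).max(axis=(1, 3))


def build_pyramid(source: EffectMap | np.ndarray, levels: int) -> Pyramid:
    """Factor-2 max pooling per level over the dense |theta_std| map.

    From an EffectMap, level 0 is the p x p grid with |theta_std| of pair
    (i, j) at [i, j] (upper triangle) and of single i on the diagonal;
    absent cells are 0.  ``levels`` additional pooled levels are built.
    """
    if levels < 1:
        raise ValueError("need at least one pooled level")
    if isinstance(source, EffectMap):
        base = np.zeros((source.p, source.p))
        for key, v in source.theta_std.items():
            if key.kind == "single":
                base[key.i, key.i] = abs(v)
            else:
                base[key.i, key.j] = abs(v)
    else:
        base = np.abs(np.asarray(source, dtype=float))
        if base.ndim != 2:
            raise ValueError("dense pyramid source must be 2-D")
    out = [base]
    for _ in range(levels):
        out.append(_pool2(out[-1]))
    return Pyramid(levels=out)


def write_json_atomic(obj, path) -> None:
    """Write JSON via a temp file + rename so readers never see partial output."""
    d = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(obj, fh, indent=1)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
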