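"""Truth-based evaluation of scans and small-instance brute-force oracles."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .interactions import TermKey
from .simdata import Architecture, GenotypeMatrix
from .solver import EffectMap, term_design

__all__ = [
    "TruthSet",
    "truth_from_architecture",
    "recall_top_k",
    "recovery_percent",
    "brute_force_rank",
]


@dataclass(frozen=True)
class TruthSet:
    """The set of term keys carrying non-null simulated effects."""

    keys: frozenset[TermKey]
    p: int

    def __post_init__(self) -> None:
        if not self.keys:
            raise ValueError("truth set is empty")
        for k in self.keys:
            top = k.i if k.j is None else k.j
            if top >= self.p:
                raise ValueError(f"truth key {k} outside p={self.p}")

    def __len__(self) -> int:
        return len(self.keys)


def truth_from_architecture(arch: Architecture, p: int) -> TruthSet:
    keys = []
    for t in arch.term_keys():
        keys.append(TermKey.single(t[1]) if t[0] == "single" else TermKey.pair(t[1], t[2]))
    return TruthSet(keys=frozenset(keys), p=p)


def _matches(found: TermKey, true: TermKey, window: int) -> bool:
    if found.kind != true.kind:
        return False
    if found.kind == "single":
        return abs(found.i - true.i) <= window
    return abs(found.i - true.i) <= window and abs(found.j - true.j) <= window


def recall_top_k(em: EffectMap, truth: TruthSet, k: int = 10, window: int = 0) -> float:
    """|top-k terms intersected with truth| / |truth|.

    ``window`` relaxes matching to within +-window SNPs per index (for
    real-data-style evaluation where hits land on neighbours of the causal
    marker); the default is an exact (i, j) match.  Each true term can be
    claimed by at most one top-k term.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    top = em.top(k)
    if window == 0:
        return len(set(top) & truth.keys) / len(truth)
    remaining = set(truth.keys)
    hit = 0
    for f in top:
        for t in remaining:
            if _matches(f, t, window):
                remaining.discard(t)
                hit += 1
                break
    return hit / len(truth)


def recovery_percent(em: EffectMap, truth: TruthSet, k: int = 100) -> float:
    """Percent of true signals found in the top-k ranked estimates."""
    return 100.0 * recall_top_k(em, truth, k)


def brute_force_rank(
    X: GenotypeMatrix,
    Y: np.ndarray,
    term_set: Sequence[TermKey],
    ridge: float = 0.0,
) -> tuple[list[TermKey], dict[TermKey, float]]:
    """Exact reference ranking on the fully materialized design.

    OLS (``ridge=0``, least-norm if underdetermined) or exact ridge on the
    standardized columns; ranking by |coefficient| with the same
    deterministic tie-breaking used by EffectMap.  Intended as an
    independent oracle for small instances (|term_set| <= 1e5).
    """
    if len(term_set) > 10**5:
        raise ValueError("brute force is limited to 1e5 terms")
    if X.n < 2:
        raise ValueError("need at least 2 individuals")
    y = np.asarray(Y, dtype=float)
    yc = y - y.mean()
    M, _, sd = term_design(X, list(term_set), dtype="float64", standardize=True)
    if ridge > 0.0:
        G = M.T @ M + ridge * np.eye(M.shape[1])
        coef = np.linalg.solve(G, M.T @ yc)
    else:
        coef, *_ = np.linalg.lstsq(M, yc, rcond=None)
    coef = np.where(np.isinf(sd), 0.0, coef)
    values = {k: float(c) for k, c in zip(term_set, coef)}
    order = sorted(term_set, key=lambda k: (-abs(values[k]), k.sort_key()))
    return order, values
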