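"""Deterministic simulation scenarios binding all modules end to end.

Each scenario is a fully serializable :class:`ScenarioSpec`; replicate r of
a scenario regenerates byte-identically from (root_seed, r).  The stock
scenarios mirror the validation designs the method is built around:

``mixed_small``
    100 SNPs, 5000 individuals, five planted terms (2 simple + 3 pairwise)
    at h2 = 0.5 — the dense small landscape where a full 2D scan should
    place all five terms at the top.
``pair_landscape``
    1000 SNPs (500,500 candidate terms), 10 planted pair effects, h2 grid
    around 0.2, n from 1000 to 10,000 — the sparse very-high-dimensional
    landscape where top-10 recall is the figure of merit.
``marchini``
    Outbred coding with two-locus penetrance interactions of types 1-3 at
    matched per-term variance.
``split_h2``
    A trait with a fixed additive h2 plus a fixed pairwise-epistatic h2,
    used for heritability-recovery analyses.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evalmetrics import TruthSet, truth_from_architecture
from .simdata import (
    Architecture,
    GenotypeMatrix,
    PhenotypeVector,
    add_noise_for_h2,
    genetic_value,
    sample_architecture,
    sample_genotypes,
)
from .solver import SolverConfig, seed_for

__all__ = [
    "ScenarioSpec",
    "scenario_mixed_small",
    "scenario_pair_landscape",
    "scenario_marchini",
    "scenario_split_h2",
    "realize",
]


@dataclass
class ScenarioSpec:
    name: str
    n: int
    p: int
    mode: str = "inbred"
    allele_freq: float = 0.5
    k_simple: int = 0
    k_pair: int = 0
    k_quad: int = 0
    types: tuple[str, ...] = ("product",)
    h2: float = 0.5
    h2_pair: float | None = None  # split-h2 scenarios: additive h2 is ``h2``
    effect_range: tuple[float, float] = (0.5, 1.5)
    marchini_theta: float = 1.0
    noise_mode: str = "fixed"
    replicates: int = 20
    root_seed: int = 20240101
    solver: dict = field(default_factory=dict)

    def solver_config(self, seed: int | None = None) -> SolverConfig:
        cfg = SolverConfig(**self.solver)
        if seed is not None:
            cfg = cfg.with_seed(seed)
        return cfg

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            d = json.load(fh)
        d["types"] = tuple(d["types"])
        d["effect_range"] = tuple(d["effect_range"])
        return cls(**d)


def scenario_mixed_small(h2: float = 0.5, replicates: int = 20) -> ScenarioSpec:
    """Dense small landscape: p=100, n=5000, 2 simple + 3 pair effects."""
    return ScenarioSpec(
        name="mixed_small",
        n=5000,
        p=100,
        k_simple=2,
        k_pair=3,
        h2=h2,
        replicates=replicates,
        solver={"dtype": "float32", "debias": True},
    )


def scenario_pair_landscape(
    n: int = 1000, h2: float = 0.2, replicates: int = 20
) -> ScenarioSpec:
    """Sparse VHD landscape: p=1000 (500,500 terms), 10 planted pairs.

    One solver configuration covers the whole n grid (1000 ... 10,000):
    45-SNP blocks keep every piece at ~2000 terms.
    """
    if n not in (1000, 2500, 5000, 10000):
        raise ValueError("n must be one of 1000, 2500, 5000, 10000")
    return ScenarioSpec(
        name=f"pair_landscape_n{n}",
        n=n,
        p=1000,
        k_pair=10,
        h2=h2,
        replicates=replicates,
        solver={"dtype": "float32", "block_size": 45},
    )


def scenario_marchini(
    types: Sequence[int] = (1, 2, 3),
    k_pair: int = 5,
    n: int = 2000,
    p: int = 100,
    h2: float = 0.4,
    marchini_theta: float = 1.0,
    replicates: int = 20,
) -> ScenarioSpec:
    """Outbred two-locus penetrance interactions at matched per-term variance."""
    for t in types:
        if t not in (1, 2, 3):
            raise ValueError("types must be drawn from {1, 2, 3}")
    return ScenarioSpec(
        name="marchini_" + "".join(str(t) for t in types),
        n=n,
        p=p,
        mode="outbred",
        k_pair=k_pair,
        types=tuple(f"marchini{t}" for t in types),
        h2=h2,
        marchini_theta=marchini_theta,
        replicates=replicates,
        solver={"dtype": "float32"},
    )


def scenario_split_h2(
    h2_additive: float = 0.20,
    h2_pair: float = 0.15,
    n: int = 4000,
    p: int = 200,
    k_simple: int = 8,
    k_pair: int = 5,
) -> ScenarioSpec:
    """Trait with separately controlled additive and pairwise h2 components."""
    return ScenarioSpec(
        name="split_h2",
        n=n,
        p=p,
        k_simple=k_simple,
        k_pair=k_pair,
        h2=h2_additive,
        h2_pair=h2_pair,
        solver={"dtype": "float32", "debias": True},
    )


def realize(
    spec: ScenarioSpec, replicate: int = 0
) -> tuple[GenotypeMatrix, PhenotypeVector, Architecture, TruthSet]:
    """Regenerate replicate ``replicate`` of a scenario deterministically."""
    gseed = seed_for(spec.root_seed, spec.name, "geno", replicate)
    aseed = seed_for(spec.root_seed, spec.name, "arch", replicate)
    nseed = seed_for(spec.root_seed, spec.name, "noise", replicate)
    X = sample_genotypes(
        spec.n, spec.p, spec.allele_freq, mode=spec.mode, seed=gseed
    )
    arch = sample_architecture(
        spec.p,
        spec.k_simple,
        spec.k_pair,
        spec.k_quad,
        effect_range=spec.effect_range,
        types=spec.types,
        target_h2=spec.h2,
        noise_mode=spec.noise_mode,
        seed=aseed,
        marchini_theta=spec.marchini_theta,
    )
    if spec.h2_pair is None:
        if spec.marchini_theta == 0.0 and all(
            t.startswith("marchini") for t in spec.types
        ) and spec.k_simple + spec.k_quad == 0:
            # null interaction tables: the trait is pure noise
            rng = np.random.default_rng(nseed)
            Y = PhenotypeVector(rng.standard_normal(spec.n), name=spec.name)
        else:
            g = genetic_value(X, arch)
            Y = add_noise_for_h2(
                g, spec.h2, spec.noise_mode, seed=nseed, name=spec.name
            )
    else:
        # split-h2 construction: rescale the additive and pairwise genetic
        # components separately so each contributes its target variance share
        add_arch = dataclasses.replace(arch, pair_effects=[], target_h2=1.0)
        pair_arch = dataclasses.replace(
            arch, simple_effects=[], quad_effects=[], target_h2=1.0
        )
        g_add = genetic_value(X, add_arch)
        g_pair = genetic_value(X, pair_arch)
        h_a, h_p = spec.h2, spec.h2_pair
        if h_a + h_p >= 1.0:
            raise ValueError("h2 components must sum below 1")
        rng = np.random.default_rng(nseed)
        y = (
            np.sqrt(h_a) * (g_add - g_add.mean()) / g_add.std()
            + np.sqrt(h_p) * (g_pair - g_pair.mean()) / g_pair.std()
            + np.sqrt(1.0 - h_a - h_p) * rng.standard_normal(spec.n)
        )
        Y = PhenotypeVector(y, name=spec.name)
    truth = truth_from_architecture(arch, spec.p)
    return X, Y, arch, truth
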