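"""The spatial population: toroidal grid, initialization, Monte Carlo updates.

Two equivalent surfaces are exposed.  The reference operators
(:func:`death_probability`, :func:`moore_neighbors`,
:func:`candidate_parents`, :func:`fill_empty_site`,
:func:`elementary_update`, :func:`diffusion_step`, :func:`run_generation`)
are plain Python/NumPy, convenient for unit tests and small-case
enumeration.  Whole runs go through :func:`run` / :func:`advance`, which
drive the compiled generation loop in :mod:`senesim._kernel` on the same
array state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import _kernel
from .environment import (
    MODE_DIRECTIONAL,
    PHASE_ASCENDING,
    PHASE_DESCENDING,
    TargetPhenotype,
    advance_target,
    init_directional,
    init_stabilizing,
)
from .genome import Genome, LocusLayout, make_layout, mutate, recombine
from .params import ALPHA_PER_ALLELE, SimParams

METRIC_COLUMNS = [
    "t",
    "occupancy",
    "mean_alpha",
    "mean_age",
    "mean_delta",
    "mean_norm_fecundity",
    "corr_alpha_fecundity",
    "mean_match",
    "tag_frequency",
    "deaths",
    "births",
    "swaps",
    "target_flips",
]

_DIFFUSION_OFFSETS = [
    (-1, -1),
    (-1, 0),
    (-1, 1),
    (0, -1),
    (0, 1),
    (1, -1),
    (1, 0),
    (1, 1),
]


@dataclass(frozen=True)
class Individual:
    """One agent: a genome plus its integer age in generations."""

    genome: Genome
    age: int

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be non-negative")


@dataclass
class Lattice:
    """N x N torus whose sites are empty or hold one individual.

    State is stored as dense arrays shared with the compiled kernel:
    occupancy flags, ages, genomes (one chromosome row per site), the cached
    senescence-allele sums and target-match counts, and a neutral lineage
    tag used by the invasion protocols.
    """

    layout: LocusLayout
    occupied: np.ndarray
    age: np.ndarray
    genomes: np.ndarray
    sum_a: np.ndarray
    match: np.ndarray
    tag: np.ndarray

    @classmethod
    def empty(cls, N: int, layout: LocusLayout) -> "Lattice":
        if N < 1:
            raise ValueError("N must be >= 1")
        L = layout.length
        return cls(
            layout=layout,
            occupied=np.zeros((N, N), dtype=np.uint8),
            age=np.zeros((N, N), dtype=np.int32),
            genomes=np.zeros((N, N, L), dtype=np.uint8),
            sum_a=np.zeros((N, N), dtype=np.int16),
            match=np.zeros((N, N), dtype=np.int16),
            tag=np.zeros((N, N), dtype=np.uint8),
        )

    @property
    def N(self) -> int:
        return int(self.occupied.shape[0])

    @property
    def population(self) -> int:
        return int(self.occupied.sum())

    @property
    def occupancy(self) -> float:
        return self.population / (self.N * self.N)

    def occupied_sites(self) -> np.ndarray:
        """Array of (x, y) coordinates of occupied sites."""
        return np.argwhere(self.occupied == 1)

    def is_occupied(self, site: tuple[int, int]) -> bool:
        return bool(self.occupied[site] == 1)

    def get_individual(self, site: tuple[int, int]) -> Individual:
        if not self.is_occupied(site):
            raise ValueError(f"site {site} is empty")
        return Individual(
            Genome(self.genomes[site].copy(), self.layout), int(self.age[site])
        )

    def set_individual(
        self,
        site: tuple[int, int],
        individual: Individual,
        target: Optional[TargetPhenotype] = None,
        tag: int = 0,
    ) -> None:
        g = individual.genome
        if g.layout.length != self.layout.length or not np.array_equal(
            g.layout.roles, self.layout.roles
        ):
            raise ValueError("individual's layout does not match the lattice layout")
        self.occupied[site] = 1
        self.age[site] = individual.age
        self.genomes[site] = g.alleles
        self.sum_a[site] = g.senescence_alleles.sum()
        self.tag[site] = tag
        if target is not None:
            self.match[site] = (g.fecundity_alleles == target.phi).sum()
        else:
            self.match[site] = 0

    def clear_site(self, site: tuple[int, int]) -> None:
        self.occupied[site] = 0

    def refresh_caches(self, target: Optional[TargetPhenotype] = None) -> None:
        """Recompute the senescence sums and target-match counts."""
        fpos = self.layout.fecundity_positions
        spos = self.layout.senescence_positions
        self.sum_a[:] = self.genomes[:, :, spos].sum(axis=2)
        if target is not None:
            self.match[:] = (self.genomes[:, :, fpos] == target.phi).sum(axis=2)
        mask = self.occupied == 0
        self.sum_a[mask] = 0
        self.match[mask] = 0

    def alpha(self) -> np.ndarray:
        """Per-site rate of aging (NaN on empty sites)."""
        a = ALPHA_PER_ALLELE * self.sum_a.astype(np.float64)
        a[self.occupied == 0] = np.nan
        return a

    def copy(self) -> "Lattice":
        return Lattice(
            layout=self.layout,
            occupied=self.occupied.copy(),
            age=self.age.copy(),
            genomes=self.genomes.copy(),
            sum_a=self.sum_a.copy(),
            match=self.match.copy(),
            tag=self.tag.copy(),
        )


# ---------------------------------------------------------------------------
# construction

def make_target(params: SimParams, rng: np.random.Generator) -> TargetPhenotype:
    if params.selection == MODE_DIRECTIONAL:
        return init_directional(params.L_f, params.T)
    return init_stabilizing(params.L_f, rng, T=params.T)


def initialize(
    params: SimParams,
    rng: np.random.Generator,
    layout: Optional[LocusLayout] = None,
    target: Optional[TargetPhenotype] = None,
) -> tuple[Lattice, TargetPhenotype]:
    """Fully occupied starting lattice.

    Ages are ``floor(U(0, 1/delta0))``; senescence alleles start 0 (a
    non-aging population) and fecundity alleles are i.i.d. fair coins.
    The ``fixed_alpha`` variant presets the corresponding number of
    senescence alleles; ``monomorphic_fertility`` gives every individual
    the target's own fecundity pattern (a perfectly adapted monomorphic
    population).
    """
    if layout is None:
        layout = make_layout(params.L_f, params.L_a, rng)
    if target is None:
        target = make_target(params, rng)
    N = params.N
    lat = Lattice.empty(N, layout)
    lat.occupied[:] = 1
    lat.age[:] = np.floor(
        rng.uniform(0.0, 1.0 / params.delta0, size=(N, N))
    ).astype(np.int32)
    fpos = layout.fecundity_positions
    if params.monomorphic_fertility:
        lat.genomes[:, :, fpos] = target.phi
    else:
        lat.genomes[:, :, fpos] = rng.integers(
            0, 2, size=(N, N, params.L_f), dtype=np.uint8
        )
    if params.fixed_alpha is not None and params.fixed_alpha_alleles > 0:
        on = layout.senescence_positions[: params.fixed_alpha_alleles]
        lat.genomes[:, :, on] = 1
    lat.refresh_caches(target)
    return lat, target


# ---------------------------------------------------------------------------
# reference operators (pure Python surface)

def death_probability(individual: Individual, delta0: float) -> float:
    """Linear-age-ramp hazard ``delta0 + alpha * tau`` capped at 1.

    ``tau_max = floor((1 - delta0) / alpha)`` is the maximum lifespan; a
    non-aging individual (alpha = 0) keeps the baseline hazard at any age.
    """
    if not 0.0 < delta0 < 1.0:
        raise ValueError("delta0 must lie in (0, 1)")
    suma = int(individual.genome.senescence_alleles.sum())
    return float(_kernel.hazard(suma, individual.age, delta0, False))


def moore_neighbors(
    site: tuple[int, int], n: int, N: int
) -> list[tuple[int, int]]:
    """The (2n+1)^2 - 1 sites within Chebyshev distance n, torus-wrapped."""
    if n < 1:
        raise ValueError("Moore radius must be >= 1")
    x, y = site
    out = []
    for dx in range(-n, n + 1):
        for dy in range(-n, n + 1):
            if dx == 0 and dy == 0:
                continue
            out.append(((x + dx) % N, (y + dy) % N))
    return out


def candidate_parents(
    lattice: Lattice,
    site: tuple[int, int],
    params: SimParams,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Occupied sites eligible to parent an offspring at ``site``.

    Normal mode: the occupied sites of the n-Moore neighborhood.  In the
    configuration-field limit: the occupied ones among 8 distinct sites
    drawn uniformly from the whole lattice (excluding the focal site),
    which destroys relatedness between candidates and the focal site.
    """
    N = lattice.N
    if params.config_field:
        drawn: list[tuple[int, int]] = []
        while len(drawn) < 8:
            c = (int(rng.integers(N)), int(rng.integers(N)))
            if c == tuple(site) or c in drawn:
                continue
            drawn.append(c)
        return [c for c in drawn if lattice.is_occupied(c)]
    return [
        c for c in moore_neighbors(site, params.n, N) if lattice.is_occupied(c)
    ]


def _pick_weighted(
    rng: np.random.Generator, weights: np.ndarray
) -> int:
    return int(rng.choice(len(weights), p=weights / weights.sum()))


def fill_empty_site(
    lattice: Lattice,
    site: tuple[int, int],
    target: TargetPhenotype,
    params: SimParams,
    rng: np.random.Generator,
) -> Optional[Individual]:
    """Try to populate an empty site; returns the newborn or ``None``.

    Parents are drawn proportionally to their raw fecundity ``b ** s``
    (normalization cancels).  Sexual reproduction needs two distinct
    parents (dioecy, drawn without replacement); with fewer candidates the
    site stays empty.  The newborn is the (recombined) mutated offspring at
    age 0; its lineage tag is copied from the first-drawn parent.
    """
    if lattice.is_occupied(site):
        raise ValueError(f"site {site} is not empty")
    cands = candidate_parents(lattice, site, params, rng)
    p_f = params.effective_p_f
    if params.reproduction == "sexual":
        if len(cands) < 2:
            return None
        weights = np.array(
            [float(params.b) ** int(lattice.match[c]) for c in cands]
        )
        i1 = _pick_weighted(rng, weights)
        rest = [c for j, c in enumerate(cands) if j != i1]
        wrest = np.delete(weights, i1)
        i2 = _pick_weighted(rng, wrest)
        c1, c2 = cands[i1], rest[i2]
        g1 = Genome(lattice.genomes[c1].copy(), lattice.layout)
        g2 = Genome(lattice.genomes[c2].copy(), lattice.layout)
        child = mutate(recombine(g1, g2, params.p_rec, rng), p_f, params.p_a, rng)
        parent_tag = int(lattice.tag[c1])
    else:
        if len(cands) < 1:
            return None
        weights = np.array(
            [float(params.b) ** int(lattice.match[c]) for c in cands]
        )
        i1 = _pick_weighted(rng, weights)
        c1 = cands[i1]
        g1 = Genome(lattice.genomes[c1].copy(), lattice.layout)
        child = mutate(g1, p_f, params.p_a, rng)
        parent_tag = int(lattice.tag[c1])
    newborn = Individual(child, 0)
    lattice.set_individual(site, newborn, target, tag=parent_tag)
    return newborn


def diffusion_step(
    lattice: Lattice, D: float, rng: np.random.Generator
) -> bool:
    """One diffusion trial: with probability D swap a random adjacent pair.

    The pair is a uniformly random site and a uniformly random one of its 8
    orthogonal/diagonal neighbors; empty sites participate.  Returns whether
    a swap happened.
    """
    if not 0.0 <= D <= 1.0:
        raise ValueError("diffusion_step expects D in [0, 1]")
    if D == 0.0 or rng.random() >= D:
        return False
    N = lattice.N
    sx, sy = int(rng.integers(N)), int(rng.integers(N))
    dx, dy = _DIFFUSION_OFFSETS[int(rng.integers(8))]
    tx, ty = (sx + dx) % N, (sy + dy) % N
    for arr in (
        lattice.occupied,
        lattice.age,
        lattice.sum_a,
        lattice.match,
        lattice.tag,
    ):
        arr[sx, sy], arr[tx, ty] = arr[tx, ty], arr[sx, sy]
    tmp = lattice.genomes[sx, sy].copy()
    lattice.genomes[sx, sy] = lattice.genomes[tx, ty]
    lattice.genomes[tx, ty] = tmp
    return True


def elementary_update(
    lattice: Lattice,
    target: TargetPhenotype,
    params: SimParams,
    rng: np.random.Generator,
) -> None:
    """One asynchronous Monte Carlo step.

    A uniformly random site is processed: an occupant faces a Bernoulli
    death trial at its hazard, and a site freed by death is immediately
    exposed to the repopulation rule within the same step (this keeps the
    grid saturated); an empty site may be populated.  Afterwards the
    diffusion trials (expected number ``D``) are appended, independent of
    the focal site.
    """
    N = lattice.N
    site = (int(rng.integers(N)), int(rng.integers(N)))
    if lattice.is_occupied(site):
        ind = lattice.get_individual(site)
        if params.evolvable_baseline:
            d = float(
                _kernel.hazard(int(lattice.sum_a[site]), ind.age, params.delta0, True)
            )
        else:
            d = death_probability(ind, params.delta0)
        if rng.random() < d:
            lattice.clear_site(site)
            fill_empty_site(lattice, site, target, params, rng)
    else:
        fill_empty_site(lattice, site, target, params, rng)
    ntrials = int(params.D)
    frac = params.D - ntrials
    for _ in range(ntrials):
        diffusion_step(lattice, 1.0, rng)
    if frac > 0.0:
        diffusion_step(lattice, frac, rng)


def run_generation(
    lattice: Lattice,
    target: TargetPhenotype,
    params: SimParams,
    t: int,
    rng: np.random.Generator,
) -> TargetPhenotype:
    """Reference (non-compiled) generation: target advance, N*N updates,
    age increment.  Returns the possibly advanced target."""
    new_target = advance_target(target, t, rng)
    if new_target is not target:
        lattice.refresh_caches(new_target)
    for _ in range(params.N * params.N):
        elementary_update(lattice, new_target, params, rng)
    lattice.age[lattice.occupied == 1] += 1
    return new_target


# ---------------------------------------------------------------------------
# compiled driver

def _phase_code(target: TargetPhenotype) -> int:
    return 0 if target.phase == PHASE_ASCENDING else 1


def advance(
    lattice: Lattice,
    target: TargetPhenotype,
    params: SimParams,
    n_gens: int,
    t0: int = 0,
    kernel_seed: Optional[int] = None,
) -> tuple[pd.DataFrame, TargetPhenotype]:
    """Advance ``n_gens`` generations with the compiled kernel (in place).

    ``kernel_seed`` reseeds the kernel RNG stream; omit it to continue the
    current stream (used by multi-phase protocols).  Returns the
    per-generation metrics and the updated target.
    """
    if n_gens < 0:
        raise ValueError("n_gens must be >= 0")
    if lattice.N != params.N:
        raise ValueError("lattice size does not match params.N")
    if kernel_seed is not None:
        _kernel.seed_kernel(int(kernel_seed))
    out = np.full((n_gens, _kernel.N_METRICS), np.nan)
    phi = np.ascontiguousarray(target.phi.copy())
    phase = np.array([_phase_code(target)], dtype=np.int64)
    b_pow = float(params.b) ** np.arange(params.L_f + 1, dtype=np.float64)
    if n_gens > 0:
        _kernel.run_generations(
            lattice.occupied,
            lattice.age,
            lattice.genomes,
            lattice.sum_a,
            lattice.match,
            lattice.tag,
            np.ascontiguousarray(lattice.layout.fecundity_positions),
            np.ascontiguousarray(lattice.layout.senescence_positions),
            phi,
            phase,
            t0,
            n_gens,
            params.delta0,
            b_pow,
            params.n,
            params.T,
            params.p_rec,
            params.effective_p_f,
            params.p_a,
            params.D,
            params.reproduction == "sexual",
            params.selection == MODE_DIRECTIONAL,
            params.config_field,
            params.evolvable_baseline,
            out,
        )
    metrics = pd.DataFrame(out, columns=METRIC_COLUMNS)
    for col in ("t", "deaths", "births", "swaps", "target_flips"):
        metrics[col] = metrics[col].astype(np.int64)
    metrics["hamming_to_target"] = params.L_f - metrics["mean_match"]
    new_phase = PHASE_ASCENDING if phase[0] == 0 else PHASE_DESCENDING
    new_target = replace(target, phi=phi, phase=new_phase)
    return metrics, new_target


@dataclass
class RunResult:
    """Outcome of a full run: metrics time series plus the final state."""

    params: SimParams
    metrics: pd.DataFrame
    lattice: Lattice
    target: TargetPhenotype
    layout: LocusLayout
    seed: int


def derive_seeds(seed: int) -> tuple[np.random.Generator, int]:
    """Split one master seed into the init Generator and the kernel seed."""
    ss = np.random.SeedSequence(seed)
    s_init, s_kernel = ss.spawn(2)
    rng = np.random.default_rng(s_init)
    kernel_seed = int(s_kernel.generate_state(1)[0] % 2**31)
    return rng, kernel_seed


def run(
    params: SimParams,
    snapshot_callback: Optional[Callable[[int, Lattice], None]] = None,
) -> RunResult:
    """Seeded, reproducible full simulation.

    ``snapshot_callback(t, lattice)`` is invoked every
    ``params.snapshot_every`` generations (and at the end) when set.
    """
    rng, kernel_seed = derive_seeds(params.seed)
    layout = make_layout(params.L_f, params.L_a, rng)
    lattice, target = initialize(params, rng, layout=layout)
    cadence = params.snapshot_every if params.snapshot_every > 0 else 0
    chunks = []
    t = 0
    first = True
    while t < params.generations:
        step = min(cadence or params.generations, params.generations - t)
        metrics, target = advance(
            lattice,
            target,
            params,
            step,
            t0=t,
            kernel_seed=kernel_seed if first else None,
        )
        first = False
        t += step
        chunks.append(metrics)
        if cadence and snapshot_callback is not None:
            snapshot_callback(t, lattice)
    if params.generations == 0:
        metrics = pd.DataFrame(columns=METRIC_COLUMNS + ["hamming_to_target"])
        chunks.append(metrics)
    all_metrics = pd.concat(chunks, ignore_index=True)
    return RunResult(params, all_metrics, lattice, target, layout, params.seed)
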