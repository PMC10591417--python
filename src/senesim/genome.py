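"""Binary genomes and the genetic operators.

A genome is a single haploid chromosome of ``L_f`` fecundity loci and
``L_a`` senescence loci interleaved in a random, run-fixed order (the
:class:`LocusLayout`).  Fecundity loci are compared against the current
target phenotype; senescence loci additively set the rate of aging
(0.01 per ON allele).  All operators here have value semantics: inputs are
never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .params import ALPHA_PER_ALLELE

if TYPE_CHECKING:  # pragma: no cover
    from .environment import TargetPhenotype

ROLE_FECUNDITY = 0
ROLE_SENESCENCE = 1


@dataclass(frozen=True)
class LocusLayout:
    """Run-fixed random arrangement of fecundity and senescence loci.

    ``roles[pos]`` is 0 for a fecundity locus and 1 for a senescence locus.
    ``fecundity_positions[k]`` is the chromosome position of fecundity locus
    ``k`` (ordered by locus index), similarly ``senescence_positions``.
    """

    roles: np.ndarray
    fecundity_positions: np.ndarray = field(init=False)
    senescence_positions: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        roles = np.asarray(self.roles, dtype=np.int8)
        if roles.ndim != 1:
            raise ValueError("roles must be a 1-d array")
        if not np.isin(roles, (ROLE_FECUNDITY, ROLE_SENESCENCE)).all():
            raise ValueError("roles must contain only 0 (fecundity) and 1 (senescence)")
        object.__setattr__(self, "roles", roles)
        object.__setattr__(
            self, "fecundity_positions", np.flatnonzero(roles == ROLE_FECUNDITY)
        )
        object.__setattr__(
            self, "senescence_positions", np.flatnonzero(roles == ROLE_SENESCENCE)
        )
        if self.n_fecundity < 1 or self.n_senescence < 1:
            raise ValueError("layout needs at least one locus of each role")

    @property
    def n_fecundity(self) -> int:
        return int(self.fecundity_positions.size)

    @property
    def n_senescence(self) -> int:
        return int(self.senescence_positions.size)

    @property
    def length(self) -> int:
        return int(self.roles.size)


def make_layout(L_f: int, L_a: int, rng: np.random.Generator) -> LocusLayout:
    """Draw the uniformly random locus arrangement used for a whole run."""
    if L_f < 1 or L_a < 1:
        raise ValueError("locus counts must be positive")
    roles = np.concatenate(
        [
            np.full(L_f, ROLE_FECUNDITY, dtype=np.int8),
            np.full(L_a, ROLE_SENESCENCE, dtype=np.int8),
        ]
    )
    rng.shuffle(roles)
    return LocusLayout(roles)


@dataclass(frozen=True)
class Genome:
    """Binary allele vector in chromosome order plus its layout."""

    alleles: np.ndarray
    layout: LocusLayout

    def __post_init__(self) -> None:
        alleles = np.asarray(self.alleles, dtype=np.uint8)
        if alleles.shape != (self.layout.length,):
            raise ValueError(
                f"allele vector length {alleles.size} does not match layout "
                f"length {self.layout.length}"
            )
        if not np.isin(alleles, (0, 1)).all():
            raise ValueError("alleles must be 0 or 1")
        object.__setattr__(self, "alleles", alleles)

    @property
    def fecundity_alleles(self) -> np.ndarray:
        """Fecundity alleles ordered by locus index k = 1..L_f."""
        return self.alleles[self.layout.fecundity_positions]

    @property
    def senescence_alleles(self) -> np.ndarray:
        return self.alleles[self.layout.senescence_positions]


def aging_rate(genome: Genome) -> float:
    """Rate of aging: 0.01 per ON senescence allele (units 1/generation^2)."""
    return ALPHA_PER_ALLELE * int(genome.senescence_alleles.sum())


def match_count(genome: Genome, target: "TargetPhenotype") -> int:
    """Number of fecundity loci matching the current target phenotype."""
    if target.phi.size != genome.layout.n_fecundity:
        raise ValueError(
            f"target length {target.phi.size} does not match the genome's "
            f"{genome.layout.n_fecundity} fecundity loci"
        )
    return int((genome.fecundity_alleles == target.phi).sum())


def fecundity(
    genome: Genome,
    target: "TargetPhenotype",
    b: float,
    normalized: bool = False,
) -> float:
    """Multiplicative fecundity ``b ** s``.

    With ``normalized=True`` the value is divided by the maximum attainable
    fecundity ``b ** L_f`` so that it lies in ``(0, 1]``.
    """
    if b <= 1.0:
        raise ValueError("fitness base b must exceed 1")
    s = match_count(genome, target)
    if normalized:
        return float(b ** (s - genome.layout.n_fecundity))
    return float(b**s)


def mutate(genome: Genome, p_f: float, p_a: float, rng: np.random.Generator) -> Genome:
    """Independent per-bit flips at role-specific rates; returns a new genome."""
    if not 0.0 <= p_f <= 1.0 or not 0.0 <= p_a <= 1.0:
        raise ValueError("mutation probabilities must lie in [0, 1]")
    alleles = genome.alleles.copy()
    layout = genome.layout
    if p_f > 0.0:
        flips = rng.random(layout.n_fecundity) < p_f
        pos = layout.fecundity_positions[flips]
        alleles[pos] = 1 - alleles[pos]
    if p_a > 0.0:
        flips = rng.random(layout.n_senescence) < p_a
        pos = layout.senescence_positions[flips]
        alleles[pos] = 1 - alleles[pos]
    return Genome(alleles, layout)


def recombine(
    g1: Genome, g2: Genome, p_rec: float, rng: np.random.Generator
) -> Genome:
    """Single-point crossover between two parental chromosomes.

    With probability ``p_rec`` a crossover point is drawn uniformly from the
    ``L - 1`` internal inter-locus positions, so the offspring inherits at
    least one gene from each parent; which parent contributes the left
    segment is decided by a fair coin.  With probability ``1 - p_rec`` the
    offspring is an exact copy of one uniformly chosen parent.  Mutation is
    not applied here.
    """
    if g1.layout is not g2.layout and not np.array_equal(
        g1.layout.roles, g2.layout.roles
    ):
        raise ValueError("parents must share the same locus layout")
    if not 0.0 <= p_rec <= 1.0:
        raise ValueError("p_rec must lie in [0, 1]")
    L = g1.layout.length
    if rng.random() < p_rec:
        cut = int(rng.integers(1, L))  # internal positions 1..L-1
        left, right = (g1, g2) if rng.random() < 0.5 else (g2, g1)
        alleles = np.concatenate([left.alleles[:cut], right.alleles[cut:]])
    else:
        parent = g1 if rng.random() < 0.5 else g2
        alleles = parent.alleles.copy()
    return Genome(alleles, g1.layout)
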