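"""Simulation parameters and their validation.

The defaults are the standard parameter set of the model: a 200x200 torus,
50 fecundity and 50 senescence loci, baseline mortality 0.05, fitness base
1.2, Moore radius 1, one target flip every 10 generations, obligate
single-point recombination, per-bit mutation rate 0.01 and no diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

#: mortality contributed by one ON senescence allele, per generation of age
ALPHA_PER_ALLELE = 0.01

#: age-independent floor of the evolvable-baseline-mortality variant
EVOLVABLE_BASELINE_FLOOR = 0.002

REPRODUCTION_MODES = ("sexual", "asexual")
SELECTION_MODES = ("directional", "stabilizing")


@dataclass(frozen=True)
class SimParams:
    """Full configuration of a single run.

    Attributes
    ----------
    N : lattice side; the torus has ``N * N`` sites.
    L_f, L_a : number of fecundity / senescence loci.
    delta0 : baseline (extrinsic) per-generation death probability.
    b : base of the multiplicative fecundity function ``b ** s``.
    n : Moore-neighborhood radius used to collect parent candidates.
    T : generations between single-locus flips of the directional target
        ("fitness period dilution").
    p_rec : probability of single-point crossover in sexual reproduction.
    p_f, p_a : per-bit flip probability of fecundity / senescence alleles.
    D : expected number of random adjacent-pair swaps appended to each
        elementary update (values above 1 mean several swaps per update).
    reproduction : "sexual" or "asexual".
    selection : "directional" (moving target) or "stabilizing" (static
        random target).
    config_field : draw the 8 parent candidates from random lattice-wide
        sites instead of the local neighborhood (destroys relatedness).
    monomorphic_fertility : freeze fecundity loci (identical in all
        individuals, no fecundity mutation); only senescence alleles evolve.
    evolvable_baseline : age-independent but evolvable baseline mortality
        ``0.002 + 0.01 * sum(a_j)`` replaces the age-ramp hazard;
        the age-dependent term is switched off.
    fixed_alpha : clamp the aging rate at this value (senescence alleles
        preset accordingly, ``p_a`` must be 0).
    generations : run length.
    seed : master seed; all randomness in the run derives from it.
    snapshot_every : cadence (generations) of lattice snapshots, 0 = none.
    """

    N: int = 200
    L_f: int = 50
    L_a: int = 50
    delta0: float = 0.05
    b: float = 1.2
    n: int = 1
    T: int = 10
    p_rec: float = 1.0
    p_f: float = 0.01
    p_a: float = 0.01
    D: float = 0.0
    reproduction: str = "sexual"
    selection: str = "directional"
    config_field: bool = False
    monomorphic_fertility: bool = False
    evolvable_baseline: bool = False
    fixed_alpha: Optional[float] = None
    generations: int = 10_000
    seed: int = 0
    snapshot_every: int = 0

    def __post_init__(self) -> None:
        if self.L_f < 1:
            raise ValueError(f"L_f must be >= 1, got {self.L_f}")
        if self.L_a < 1:
            raise ValueError(f"L_a must be >= 1, got {self.L_a}")
        if self.n < 1:
            raise ValueError(f"Moore radius n must be >= 1, got {self.n}")
        if self.N < 2 * self.n + 1:
            raise ValueError(
                f"lattice side N={self.N} too small for Moore radius n={self.n}; "
                f"need N >= {2 * self.n + 1}"
            )
        if not 0.0 < self.delta0 < 1.0:
            raise ValueError(f"delta0 must lie in (0, 1), got {self.delta0}")
        if self.b <= 1.0:
            raise ValueError(f"fitness base b must exceed 1, got {self.b}")
        if self.T < 1:
            raise ValueError(f"fitness period dilution T must be >= 1, got {self.T}")
        for name in ("p_rec", "p_f", "p_a"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.D < 0.0:
            raise ValueError(f"diffusion parameter D must be >= 0, got {self.D}")
        if self.reproduction not in REPRODUCTION_MODES:
            raise ValueError(
                f"reproduction must be one of {REPRODUCTION_MODES}, got "
                f"{self.reproduction!r}"
            )
        if self.selection not in SELECTION_MODES:
            raise ValueError(
                f"selection must be one of {SELECTION_MODES}, got {self.selection!r}"
            )
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.snapshot_every < 0:
            raise ValueError("snapshot_every must be >= 0")
        if self.config_field and self.N * self.N < 9:
            raise ValueError("config_field mode needs at least 9 lattice sites")
        if self.fixed_alpha is not None:
            if self.evolvable_baseline:
                raise ValueError(
                    "fixed_alpha cannot be combined with evolvable_baseline"
                )
            if self.p_a > 0.0:
                raise ValueError(
                    "fixed_alpha requires p_a = 0 (senescence alleles are clamped)"
                )
            k = round(self.fixed_alpha / ALPHA_PER_ALLELE)
            if abs(self.fixed_alpha - k * ALPHA_PER_ALLELE) > 1e-9:
                raise ValueError(
                    f"fixed_alpha must be a multiple of {ALPHA_PER_ALLELE}, got "
                    f"{self.fixed_alpha}"
                )
            if not 0 <= k <= self.L_a:
                raise ValueError(
                    f"fixed_alpha must lie in [0, {ALPHA_PER_ALLELE * self.L_a}]"
                )

    @property
    def chromosome_length(self) -> int:
        return self.L_f + self.L_a

    @property
    def fixed_alpha_alleles(self) -> int:
        """Number of ON senescence alleles implementing ``fixed_alpha``."""
        if self.fixed_alpha is None:
            return 0
        return round(self.fixed_alpha / ALPHA_PER_ALLELE)

    @property
    def effective_p_f(self) -> float:
        """Fecundity mutation rate actually applied (0 when monomorphic)."""
        return 0.0 if self.monomorphic_fertility else self.p_f

    def to_dict(self) -> dict:
        return asdict(self)
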