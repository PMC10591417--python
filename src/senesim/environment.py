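"""The selective environment: the optimal fecundity pattern and its dynamics.

Directional selection is a moving genomic target: starting from the all-zero
pattern, every ``T`` generations one randomly chosen element flips towards
the current phase (ascending: 0 -> 1) until the pattern saturates, after
which the direction reverses.  The trajectory is therefore periodic with
period ``2 * T * L_f`` generations and consecutive states differ at exactly
one position.  Stabilizing selection keeps a random static pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

MODE_DIRECTIONAL = "directional"
MODE_STABILIZING = "stabilizing"

PHASE_ASCENDING = "ascending"
PHASE_DESCENDING = "descending"


@dataclass(frozen=True)
class TargetPhenotype:
    """Binary optimal fecundity pattern of length ``L_f``."""

    phi: np.ndarray
    mode: str
    T: int
    phase: str = PHASE_ASCENDING

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=np.uint8)
        if phi.ndim != 1 or phi.size < 1:
            raise ValueError("phi must be a non-empty 1-d vector")
        if not np.isin(phi, (0, 1)).all():
            raise ValueError("phi must be binary")
        object.__setattr__(self, "phi", phi)
        if self.mode not in (MODE_DIRECTIONAL, MODE_STABILIZING):
            raise ValueError(f"unknown target mode {self.mode!r}")
        if self.phase not in (PHASE_ASCENDING, PHASE_DESCENDING):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.T < 1:
            raise ValueError("T must be >= 1")

    @property
    def L_f(self) -> int:
        return int(self.phi.size)

    @property
    def period(self) -> int:
        """Full period of the directional trajectory, in generations."""
        return 2 * self.T * self.L_f


def init_directional(L_f: int, T: int) -> TargetPhenotype:
    """All-zero initial target in the ascending phase."""
    if L_f < 1:
        raise ValueError("L_f must be >= 1")
    if T < 1:
        raise ValueError("T must be >= 1")
    return TargetPhenotype(np.zeros(L_f, dtype=np.uint8), MODE_DIRECTIONAL, T)


def init_stabilizing(
    L_f: int, rng: np.random.Generator, T: int = 1
) -> TargetPhenotype:
    """Static target with i.i.d. fair-coin elements."""
    if L_f < 1:
        raise ValueError("L_f must be >= 1")
    phi = rng.integers(0, 2, size=L_f, dtype=np.uint8)
    return TargetPhenotype(phi, MODE_STABILIZING, T)


def advance_target(
    target: TargetPhenotype, t: int, rng: np.random.Generator
) -> TargetPhenotype:
    """Target state at the start of generation ``t``.

    A flip occurs when ``t % T == 0`` and ``t > 0``, before the generation's
    Monte Carlo updates.  One uniformly chosen element opposite to the phase
    flips; the flip that reaches saturation also reverses the phase (the next
    flip starts the reverse sweep, with no double flip at the turning point).
    Stabilizing targets are returned unchanged.
    """
    if target.mode == MODE_STABILIZING or t <= 0 or t % target.T != 0:
        return target
    phase = target.phase
    want = 0 if phase == PHASE_ASCENDING else 1
    candidates = np.flatnonzero(target.phi == want)
    # by construction the pattern is never saturated at flip time
    idx = int(candidates[rng.integers(candidates.size)])
    phi = target.phi.copy()
    phi[idx] = 1 - phi[idx]
    if candidates.size == 1:  # saturated: reverse direction
        phase = PHASE_DESCENDING if phase == PHASE_ASCENDING else PHASE_ASCENDING
    return replace(target, phi=phi, phase=phase)
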