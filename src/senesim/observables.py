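"""Per-generation and spatial summary statistics.

All lattice means are taken over occupied sites only; degenerate quantities
(empty lattice, zero-variance correlation) are reported as NaN, never as a
silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .environment import TargetPhenotype
from .lattice import METRIC_COLUMNS, Lattice
from .params import ALPHA_PER_ALLELE, EVOLVABLE_BASELINE_FLOOR, SimParams

__all__ = [
    "METRIC_COLUMNS",
    "MetricsRecord",
    "summarize",
    "mean_hamming_to_target",
    "aging_gradient_profile",
]


@dataclass(frozen=True)
class MetricsRecord:
    """Lattice summary of one generation."""

    t: int
    occupancy: float
    mean_alpha: float
    mean_age: float
    mean_delta: float
    mean_norm_fecundity: float
    corr_alpha_fecundity: float
    mean_match: float
    hamming_to_target: float
    tag_frequency: float
    age_histogram: np.ndarray

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        return d


def _hazard_array(
    sum_a: np.ndarray, age: np.ndarray, delta0: float, evolvable_baseline: bool
) -> np.ndarray:
    if evolvable_baseline:
        return EVOLVABLE_BASELINE_FLOOR + ALPHA_PER_ALLELE * sum_a
    alpha = ALPHA_PER_ALLELE * sum_a
    with np.errstate(divide="ignore"):
        tau_max = np.floor((1.0 - delta0) / np.where(alpha > 0, alpha, np.inf))
    d = delta0 + alpha * age
    return np.where(age > tau_max, 1.0, d)


def summarize(
    lattice: Lattice,
    target: TargetPhenotype,
    params: SimParams,
    t: int = 0,
) -> MetricsRecord:
    """Pure lattice summary (does not modify state).

    The correlation between normalized fecundity and the rate of aging uses
    the population formula and is NaN when either variance vanishes.
    """
    mask = lattice.occupied == 1
    cnt = int(mask.sum())
    nn = lattice.N * lattice.N
    if cnt == 0:
        nanhist = np.zeros(0, dtype=np.int64)
        return MetricsRecord(
            t, 0.0, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
            np.nan, nanhist,
        )
    sum_a = lattice.sum_a[mask].astype(np.float64)
    age = lattice.age[mask].astype(np.float64)
    s = lattice.match[mask].astype(np.float64)
    alpha = ALPHA_PER_ALLELE * sum_a
    delta = _hazard_array(sum_a, age, params.delta0, params.evolvable_baseline)
    phi_norm = float(params.b) ** (s - params.L_f)
    vx = phi_norm.var()
    vy = alpha.var()
    if vx > 1e-15 and vy > 1e-15:
        corr = float(
            ((phi_norm * alpha).mean() - phi_norm.mean() * alpha.mean())
            / np.sqrt(vx * vy)
        )
    else:
        corr = np.nan
    hist = np.bincount(lattice.age[mask])
    return MetricsRecord(
        t=t,
        occupancy=cnt / nn,
        mean_alpha=float(alpha.mean()),
        mean_age=float(age.mean()),
        mean_delta=float(delta.mean()),
        mean_norm_fecundity=float(phi_norm.mean()),
        corr_alpha_fecundity=corr,
        mean_match=float(s.mean()),
        hamming_to_target=float(params.L_f - s.mean()),
        tag_frequency=float(lattice.tag[mask].mean()),
        age_histogram=hist,
    )


def mean_hamming_to_target(lattice: Lattice, target: TargetPhenotype) -> float:
    """Lattice mean of ``L_f - s_i`` over occupants (NaN when empty)."""
    mask = lattice.occupied == 1
    if not mask.any():
        return float("nan")
    fpos = lattice.layout.fecundity_positions
    s = (lattice.genomes[:, :, fpos][mask] == target.phi).sum(axis=1)
    return float(target.L_f - s.mean())


def _ring_offsets(d: int, N: int) -> list[tuple[int, int]]:
    """Distinct torus displacements at Chebyshev distance exactly d.

    Offsets are deduplicated modulo N (at d = N/2 the offsets o and -o act
    identically on the torus), so every unordered pair is enumerated exactly
    twice by iterating the returned list.
    """
    seen = set()
    out = []
    for dx in range(-d, d + 1):
        for dy in range(-d, d + 1):
            if max(abs(dx), abs(dy)) != d:
                continue
            key = (dx % N, dy % N)
            if key in seen:
                continue
            seen.add(key)
            out.append((dx, dy))
    return out


def aging_gradient_profile(
    lattice: Lattice,
    d_max: int,
    rng: Optional[np.random.Generator] = None,
    max_pairs: int = 100_000,
    exhaustive_below: int = 65,
) -> pd.DataFrame:
    """Mean |alpha_i - alpha_j| over occupied pairs at Chebyshev distance d.

    Exhaustive pair enumeration for lattices up to ``exhaustive_below - 1``
    on a side; larger lattices are sampled with ``max_pairs`` random pairs
    per distance.  Returns one row per d with the mean, standard deviation
    and number of pairs.
    """
    N = lattice.N
    if not 1 <= d_max <= N // 2:
        raise ValueError(f"d_max must lie in [1, N//2] = [1, {N // 2}]")
    alpha = ALPHA_PER_ALLELE * lattice.sum_a.astype(np.float64)
    occ = lattice.occupied == 1
    rows = []
    if N < exhaustive_below:
        for d in range(1, d_max + 1):
            diffs = []
            for dx, dy in _ring_offsets(d, N):
                shifted_occ = np.roll(occ, (dx, dy), axis=(0, 1))
                shifted_alpha = np.roll(alpha, (dx, dy), axis=(0, 1))
                both = occ & shifted_occ
                diffs.append(np.abs(alpha[both] - shifted_alpha[both]))
            diffs = np.concatenate(diffs) if diffs else np.zeros(0)
            # every unordered pair appears twice (once per direction);
            # means and dispersions are unaffected
            rows.append(_profile_row(d, diffs, len(diffs) // 2))
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        for d in range(1, d_max + 1):
            offsets = _ring_offsets(d, N)
            xs = rng.integers(0, N, size=max_pairs)
            ys = rng.integers(0, N, size=max_pairs)
            oi = rng.integers(0, len(offsets), size=max_pairs)
            offs = np.array(offsets)
            x2 = (xs + offs[oi, 0]) % N
            y2 = (ys + offs[oi, 1]) % N
            keep = occ[xs, ys] & occ[x2, y2]
            diffs = np.abs(alpha[xs[keep], ys[keep]] - alpha[x2[keep], y2[keep]])
            rows.append(_profile_row(d, diffs, int(keep.sum())))
    return pd.DataFrame(rows)


def _profile_row(d: int, diffs: np.ndarray, n_pairs: int) -> dict:
    if diffs.size == 0:
        return {
            "distance": d,
            "mean_abs_diff": np.nan,
            "std_abs_diff": np.nan,
            "n_pairs": 0,
        }
    return {
        "distance": d,
        "mean_abs_diff": float(diffs.mean()),
        "std_abs_diff": float(diffs.std()),
        "n_pairs": n_pairs,
    }
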