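"""Reproducible experiment protocols: sweeps, invasions, model variants.

Every protocol is a pure function of its spec (all randomness derives from
the spec's base seed).  Replicates reuse the same seed offsets across swept
values, giving a paired design that sharpens across-value comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .lattice import RunResult, advance, derive_seeds, initialize, make_layout, run
from .params import ALPHA_PER_ALLELE, SimParams

#: metrics averaged over the equilibrium window by the sweep protocols
EQ_COLUMNS = [
    "occupancy",
    "mean_alpha",
    "mean_age",
    "mean_delta",
    "mean_norm_fecundity",
    "mean_match",
    "hamming_to_target",
]

#: default equilibrium window as run fractions (after the transient)
DEFAULT_WINDOW = (0.4, 1.0)


def equilibrium_window(generations: int, window: tuple[float, float]) -> slice:
    lo = int(np.floor(window[0] * generations))
    hi = int(np.ceil(window[1] * generations))
    if not 0 <= lo < hi <= generations:
        raise ValueError(f"equilibrium window {window} lies outside the run")
    return slice(lo, hi)


def window_means(metrics: pd.DataFrame, window: tuple[float, float]) -> dict:
    sl = equilibrium_window(len(metrics), window)
    sub = metrics.iloc[sl]
    out = {f"eq_{c}": float(sub[c].mean()) for c in EQ_COLUMNS if c in sub}
    out["min_occupancy"] = float(sub["occupancy"].min())
    return out


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep with replicates and a stabilizing-style control.

    ``parameter`` is any :class:`SimParams` field name; ``values`` the
    swept values.  ``generations`` overrides the base run length;
    ``window`` is the equilibrium time-averaging window as run fractions.
    Replicate seeds are ``base_seed + replicate index``.
    """

    parameter: str
    values: Sequence
    replicates: int
    base: SimParams
    generations: Optional[int] = None
    window: tuple[float, float] = DEFAULT_WINDOW
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(self.values) < 1:
            raise ValueError("values must be non-empty")
        if self.parameter not in SimParams.__dataclass_fields__:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        gens = self.run_generations
        equilibrium_window(gens, self.window)  # validates

    @property
    def run_generations(self) -> int:
        return self.generations if self.generations is not None else self.base.generations


def _sweep_run(base: SimParams, parameter: str, value, gens: int, seed: int) -> RunResult:
    params = replace(base, **{parameter: value}, generations=gens, seed=seed)
    return run(params)


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """One full run per value x replicate; returns a tidy table of
    equilibrium-window means (one row per run)."""
    gens = spec.run_generations
    rows = []
    for value in spec.values:
        for rep in range(spec.replicates):
            seed = spec.base_seed + rep
            result = _sweep_run(spec.base, spec.parameter, value, gens, seed)
            row = {
                "parameter": spec.parameter,
                "value": value,
                "replicate": rep,
                "seed": seed,
            }
            row.update(window_means(result.metrics, spec.window))
            rows.append(row)
    return pd.DataFrame(rows)


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Across-replicate mean and standard deviation per swept value."""
    grouped = table.groupby("value", sort=False)
    agg = {}
    for col in table.columns:
        if col.startswith("eq_") or col == "min_occupancy":
            agg[col] = ["mean", "std"]
    out = grouped.agg(agg)
    out.columns = [f"{c}_{stat}" for c, stat in out.columns]
    return out.reset_index()


def equilibrium_alphas(
    params: SimParams,
    replicates: int,
    generations: int,
    window: tuple[float, float] = DEFAULT_WINDOW,
    base_seed: int = 0,
    column: str = "mean_alpha",
) -> np.ndarray:
    """Per-replicate equilibrium-window means of one metric column."""
    vals = []
    for rep in range(replicates):
        result = run(replace(params, generations=generations, seed=base_seed + rep))
        sl = equilibrium_window(generations, window)
        vals.append(float(result.metrics.iloc[sl][column].mean()))
    return np.array(vals)


def transition_value(
    values: Sequence,
    sweep_means: Sequence[float],
    control_values: np.ndarray,
    n_sd: float = 2.0,
):
    """Smallest swept value whose mean minus the control mean falls below
    ``n_sd`` control standard deviations; ``None`` if none qualifies."""
    mu = float(np.mean(control_values))
    sd = float(np.std(control_values, ddof=1))
    for v, m in zip(values, sweep_means):
        if m - mu < n_sd * sd:
            return v
    return None


# ---------------------------------------------------------------------------
# invasibility

@dataclass(frozen=True)
class InvasionSpec:
    """Introduce invaders into an equilibrated resident population.

    Invaders replace residents at uniformly random occupied sites: each
    keeps the fecundity genotype of the resident it replaces (isolating the
    aging-rate effect), carries ``round(invader_alpha / 0.01)`` ON
    senescence alleles, starts at age 0 and bears the lineage tag.
    """

    resident: SimParams
    invader_alpha: float
    fraction: float
    introduction_generation: int
    horizon: int
    threshold: float = 0.05
    window: tuple[float, float] = (0.75, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction < 1.0:
            raise ValueError("invader fraction must lie in [0, 1)")
        if self.introduction_generation < 0 or self.horizon < 1:
            raise ValueError("invalid invasion timing")
        k = round(self.invader_alpha / ALPHA_PER_ALLELE)
        if abs(self.invader_alpha - k * ALPHA_PER_ALLELE) > 1e-9:
            raise ValueError("invader_alpha must be a multiple of 0.01")
        if not 0 <= k <= self.resident.L_a:
            raise ValueError("invader_alpha out of range")


@dataclass
class InvasionResult:
    spec: InvasionSpec
    pre_metrics: pd.DataFrame
    post_metrics: pd.DataFrame
    pre_alpha_mean: float
    pre_alpha_sd: float
    final_carrier_frequency: float
    final_tag_frequency: float
    post_alpha_mean: float

    @property
    def established(self) -> bool:
        """Did the invading aging lineage persist above the threshold?

        Measured as the final frequency of individuals carrying any
        senescence allele (exact when the resident has ``p_a = 0``).
        """
        return self.final_carrier_frequency > self.spec.threshold

    @property
    def relaxed(self) -> bool:
        """Did the mean aging rate return to the pre-invasion equilibrium
        (within 2 temporal standard deviations of the pre-invasion window)?
        """
        return abs(self.post_alpha_mean - self.pre_alpha_mean) <= 2.0 * self.pre_alpha_sd


def introduce_invaders(
    lattice,
    fraction: float,
    invader_alpha: float,
    rng: np.random.Generator,
) -> int:
    """Replace a random ``fraction`` of occupants by invaders (in place).

    Returns the number of invaders placed.  Residents keep tag 0; invaders
    (and, through the first-parent rule, their matriline) carry tag 1.
    """
    k = round(invader_alpha / ALPHA_PER_ALLELE)
    sites = lattice.occupied_sites()
    n_inv = int(np.floor(fraction * len(sites)))
    if n_inv == 0:
        return 0
    chosen = sites[rng.choice(len(sites), size=n_inv, replace=False)]
    spos = lattice.layout.senescence_positions
    for x, y in chosen:
        lattice.genomes[x, y, spos] = 0
        if k > 0:
            lattice.genomes[x, y, spos[:k]] = 1
        lattice.sum_a[x, y] = k
        lattice.age[x, y] = 0
        lattice.tag[x, y] = 1
    return n_inv


def run_invasion(spec: InvasionSpec) -> InvasionResult:
    """Equilibrate the resident, introduce invaders, run out the horizon."""
    params = spec.resident
    rng, kernel_seed = derive_seeds(spec.seed)
    lattice, target = initialize(params, rng)
    pre_metrics, target = advance(
        lattice, target, params, spec.introduction_generation,
        t0=0, kernel_seed=kernel_seed,
    )
    pre_window = pre_metrics.iloc[
        equilibrium_window(len(pre_metrics), (0.5, 1.0))
    ] if len(pre_metrics) else pre_metrics
    pre_mean = float(pre_window["mean_alpha"].mean()) if len(pre_window) else float("nan")
    pre_sd = float(pre_window["mean_alpha"].std(ddof=1)) if len(pre_window) > 1 else float("nan")
    introduce_invaders(lattice, spec.fraction, spec.invader_alpha, rng)
    post_metrics, target = advance(
        lattice, target, params, spec.horizon,
        t0=spec.introduction_generation, kernel_seed=None,
    )
    mask = lattice.occupied == 1
    carrier = float((lattice.sum_a[mask] > 0).mean()) if mask.any() else 0.0
    tagf = float(lattice.tag[mask].mean()) if mask.any() else 0.0
    post_window = post_metrics.iloc[equilibrium_window(len(post_metrics), spec.window)]
    return InvasionResult(
        spec=spec,
        pre_metrics=pre_metrics,
        post_metrics=post_metrics,
        pre_alpha_mean=pre_mean,
        pre_alpha_sd=pre_sd,
        final_carrier_frequency=carrier,
        final_tag_frequency=tagf,
        post_alpha_mean=float(post_window["mean_alpha"].mean()),
    )


# ---------------------------------------------------------------------------
# model variants

VARIANTS = ("monomorphic_fertility", "evolvable_baseline", "fixed_alpha", "config_field")


def run_variant(
    name: str,
    params: SimParams,
    fixed_alpha: Optional[float] = None,
) -> RunResult:
    """Run one of the model variants with its rule substitutions active."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {VARIANTS}")
    if name == "fixed_alpha":
        if fixed_alpha is None:
            raise ValueError("fixed_alpha variant needs a fixed_alpha value")
        params = replace(params, fixed_alpha=fixed_alpha, p_a=0.0)
    elif name == "evolvable_baseline":
        params = replace(params, evolvable_baseline=True)
    elif name == "monomorphic_fertility":
        params = replace(params, monomorphic_fertility=True)
    elif name == "config_field":
        params = replace(params, config_field=True)
    return run(params)
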