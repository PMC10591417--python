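"""Configuration files, snapshots, metrics and run manifests.

Everything is delimited text: configs are flat ``key = value`` files whose
keys mirror the standard parameter symbols (N, Lf, La, delta0, b, n, T,
prec, pf, pa, D) plus mode switches; metrics are tab-separated with one row
per generation; snapshots are one row per occupied site.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .genome import LocusLayout, ROLE_FECUNDITY, ROLE_SENESCENCE
from .lattice import Lattice
from .params import SimParams

PathLike = Union[str, Path]


class ConfigError(ValueError):
    pass


#: config key -> SimParams field
CONFIG_KEYS = {
    "N": "N",
    "Lf": "L_f",
    "La": "L_a",
    "delta0": "delta0",
    "b": "b",
    "n": "n",
    "T": "T",
    "prec": "p_rec",
    "pf": "p_f",
    "pa": "p_a",
    "D": "D",
    "reproduction": "reproduction",
    "selection": "selection",
    "config_field": "config_field",
    "monomorphic_fertility": "monomorphic_fertility",
    "evolvable_baseline": "evolvable_baseline",
    "fixed_alpha": "fixed_alpha",
    "generations": "generations",
    "seed": "seed",
    "snapshot_every": "snapshot_every",
}

_INT_FIELDS = {"N", "L_f", "L_a", "n", "T", "generations", "seed", "snapshot_every"}
_FLOAT_FIELDS = {"delta0", "b", "p_rec", "p_f", "p_a", "D"}
_BOOL_FIELDS = {"config_field", "monomorphic_fertility", "evolvable_baseline"}
_TRUE = {"yes", "true", "1", "on"}
_FALSE = {"no", "false", "0", "off"}


def _parse_value(field: str, raw: str, key: str):
    raw = raw.strip()
    if field in _INT_FIELDS:
        try:
            return int(raw)
        except ValueError:
            raise ConfigError(f"key {key!r}: expected an integer, got {raw!r}")
    if field in _FLOAT_FIELDS:
        try:
            return float(raw)
        except ValueError:
            raise ConfigError(f"key {key!r}: expected a number, got {raw!r}")
    if field in _BOOL_FIELDS:
        low = raw.lower()
        if low in _TRUE:
            return True
        if low in _FALSE:
            return False
        raise ConfigError(f"key {key!r}: expected yes/no, got {raw!r}")
    if field == "fixed_alpha":
        if raw.lower() in {"none", ""}:
            return None
        try:
            return float(raw)
        except ValueError:
            raise ConfigError(f"key {key!r}: expected a number or 'none', got {raw!r}")
    return raw  # string fields (reproduction, selection)


def load_config(path: PathLike, **overrides) -> SimParams:
    """Parse a flat key-value config; missing keys take the standard defaults.

    Unknown keys and out-of-range values raise :class:`ConfigError` naming
    the offending key.  Keyword overrides (e.g. from CLI flags) are applied
    after the file.
    """
    path = Path(path)
    fields: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, raw = (part.strip() for part in stripped.split("=", 1))
        if key not in CONFIG_KEYS:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        field = CONFIG_KEYS[key]
        fields[field] = _parse_value(field, raw, key)
    fields.update(overrides)
    try:
        return SimParams(**fields)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(params: SimParams, path: PathLike) -> None:
    inverse = {v: k for k, v in CONFIG_KEYS.items()}
    lines = []
    for field, value in params.to_dict().items():
        key = inverse[field]
        if isinstance(value, bool):
            value = "yes" if value else "no"
        if value is None:
            value = "none"
        lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")


def params_hash(params: SimParams) -> str:
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# snapshots

def write_snapshot(
    lattice: Lattice,
    path: PathLike,
    generation: int = 0,
    params: Optional[SimParams] = None,
    seed: Optional[int] = None,
) -> None:
    """One row per occupied site: x, y, age, lineage tag and the 0/1 allele
    string in chromosome order; header comments record provenance and the
    locus layout (needed to rebuild the lattice exactly)."""
    layout_str = "".join(
        "f" if r == ROLE_FECUNDITY else "a" for r in lattice.layout.roles
    )
    lines = [
        f"# generation = {generation}",
        f"# seed = {'' if seed is None else seed}",
        f"# params_hash = {'' if params is None else params_hash(params)}",
        f"# N = {lattice.N}",
        f"# layout = {layout_str}",
        "x\ty\tage\ttag\talleles",
    ]
    for x, y in lattice.occupied_sites():
        alleles = "".join(str(int(v)) for v in lattice.genomes[x, y])
        lines.append(f"{x}\t{y}\t{int(lattice.age[x, y])}\t{int(lattice.tag[x, y])}\t{alleles}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_snapshot(path: PathLike) -> tuple[Lattice, dict]:
    """Rebuild a lattice from a snapshot file.

    The target-match cache is left at 0; call
    ``lattice.refresh_caches(target)`` with the run's target to restore it.
    """
    meta: dict = {}
    rows = []
    header_seen = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
            continue
        if not header_seen:
            header_seen = True  # column header
            continue
        if line.strip():
            rows.append(line.split("\t"))
    if "N" not in meta or "layout" not in meta:
        raise ValueError(f"{path}: snapshot header is missing N or layout")
    N = int(meta["N"])
    roles = np.array(
        [ROLE_FECUNDITY if c == "f" else ROLE_SENESCENCE for c in meta["layout"]],
        dtype=np.int8,
    )
    layout = LocusLayout(roles)
    lattice = Lattice.empty(N, layout)
    for x, y, age, tag, alleles in rows:
        xi, yi = int(x), int(y)
        lattice.occupied[xi, yi] = 1
        lattice.age[xi, yi] = int(age)
        lattice.tag[xi, yi] = int(tag)
        lattice.genomes[xi, yi] = np.frombuffer(alleles.encode(), dtype=np.uint8) - ord("0")
    lattice.refresh_caches()
    return lattice, meta


# ---------------------------------------------------------------------------
# metrics and manifests

def write_metrics(metrics: pd.DataFrame, path: PathLike) -> None:
    metrics.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def read_metrics(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")


@dataclass
class RunManifest:
    """Everything needed to bit-reproduce a run and find its outputs."""

    params: dict
    seed: int
    code_version: str
    generations: int
    outputs: list
    status: str = "running"
    started: str = ""
    finished: str = ""

    @classmethod
    def start(cls, params: SimParams, path: PathLike) -> "RunManifest":
        manifest = cls(
            params=params.to_dict(),
            seed=params.seed,
            code_version=__version__,
            generations=params.generations,
            outputs=[],
            started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        )
        manifest.write(path)
        return manifest

    def finish(self, outputs: list, path: PathLike) -> None:
        self.outputs = [str(o) for o in outputs]
        self.status = "finished"
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        self.write(path)

    def write(self, path: PathLike) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")
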