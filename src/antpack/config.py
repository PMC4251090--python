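"""Run configuration: TOML loading, validation and round-trip saving.

An empty file yields the full defaults (eight colonies, standard colony
parameters).  Unknown keys anywhere are rejected with an error naming them;
value constraints are enforced by the underlying config dataclasses.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field

from .aco import ColonyConfig, TAU0_DEFAULT
from .energy import PAIR_CUTOFF, REP_CAP
from .subrot import MinimisationConfig

__all__ = ["RunConfig", "load_config", "save_config"]

_MINIMIZE_CHOICES = ("off", "model1", "model2", "model3")


@dataclass(frozen=True)
class RunConfig:
    """Everything a packing run needs besides the input files."""

    k: int = 8
    seed: int = 0
    mode: str = "serial"
    reference_colony: int = 0
    minimize: str = "off"
    colony: ColonyConfig = field(default_factory=ColonyConfig)
    minimisation: MinimisationConfig = field(default_factory=MinimisationConfig)
    pair_cutoff: float = PAIR_CUTOFF
    rep_cap: float = REP_CAP
    prob_cutoff: float = 0.98
    tau0: float = TAU0_DEFAULT
    thresholds: tuple = (20.0, 40.0)
    alphas_betas: tuple | None = None

    def __post_init__(self):
        if not 1 <= self.k <= 8:
            raise ValueError("k must lie in [1, 8]")
        if self.mode not in ("serial", "threaded"):
            raise ValueError("mode must be 'serial' or 'threaded'")
        if self.minimize not in _MINIMIZE_CHOICES:
            raise ValueError(f"minimize must be one of {_MINIMIZE_CHOICES}")
        if not 0 <= self.reference_colony < self.k:
            raise ValueError("reference_colony must lie in [0, k)")
        if not 0.0 < self.prob_cutoff <= 1.0:
            raise ValueError("prob_cutoff must lie in (0, 1]")
        if self.tau0 <= 0:
            raise ValueError("tau0 must be positive")

    @property
    def model(self) -> int | None:
        return None if self.minimize == "off" else int(self.minimize[-1])


_RUN_KEYS = {"k", "seed", "mode", "reference_colony", "minimize"}
_COLONY_KEYS = {
    "alpha", "beta", "q0", "rho", "n_ants", "max_iters",
    "stagnation_iters", "seed", "explore", "eq4_variant", "alphas_betas",
}
_MIN_KEYS = {"max_deviation", "max_subrotamers", "accept_tol", "max_fun_evals"}
_ENERGY_KEYS = {"pair_cutoff", "rep_cap", "prob_cutoff", "tau0"}
_EVAL_KEYS = {"thresholds"}
_SECTIONS = {
    "run": _RUN_KEYS,
    "colony": _COLONY_KEYS,
    "minimisation": _MIN_KEYS,
    "energy": _ENERGY_KEYS,
    "evaluation": _EVAL_KEYS,
}


def _check_keys(section: str, data: dict, allowed: set) -> None:
    unknown = sorted(set(data) - allowed)
    if unknown:
        raise ValueError(f"unknown keys in [{section}]: {', '.join(unknown)}")


def load_config(path) -> RunConfig:
    """Load and validate a TOML run configuration; absent keys default."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    unknown = sorted(set(data) - set(_SECTIONS))
    if unknown:
        raise ValueError(f"unknown config sections: {', '.join(unknown)}")
    for sec, allowed in _SECTIONS.items():
        if sec in data:
            if not isinstance(data[sec], dict):
                raise ValueError(f"[{sec}] must be a table")
            _check_keys(sec, data[sec], allowed)

    run = data.get("run", {})
    colony_raw = dict(data.get("colony", {}))
    alphas_betas = colony_raw.pop("alphas_betas", None)
    if alphas_betas is not None:
        alphas_betas = tuple(tuple(float(v) for v in ab) for ab in alphas_betas)
        if any(len(ab) != 2 for ab in alphas_betas):
            raise ValueError("alphas_betas entries must be [alpha, beta] pairs")
    colony = ColonyConfig(**colony_raw)
    minimisation = MinimisationConfig(**data.get("minimisation", {}))
    energy = data.get("energy", {})
    ev = data.get("evaluation", {})
    thresholds = tuple(float(t) for t in ev.get("thresholds", (20.0, 40.0)))
    return RunConfig(
        k=int(run.get("k", 8)),
        seed=int(run.get("seed", 0)),
        mode=run.get("mode", "serial"),
        reference_colony=int(run.get("reference_colony", 0)),
        minimize=run.get("minimize", "off"),
        colony=colony,
        minimisation=minimisation,
        pair_cutoff=float(energy.get("pair_cutoff", PAIR_CUTOFF)),
        rep_cap=float(energy.get("rep_cap", REP_CAP)),
        prob_cutoff=float(energy.get("prob_cutoff", 0.98)),
        tau0=float(energy.get("tau0", TAU0_DEFAULT)),
        thresholds=thresholds,
        alphas_betas=alphas_betas,
    )


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    return repr(float(v)) if isinstance(v, float) else repr(v)


def save_config(config: RunConfig, path) -> None:
    """Write a configuration as TOML; ``load_config`` round-trips it."""
    lines = ["[run]"]
    for key in ("k", "seed", "mode", "reference_colony", "minimize"):
        lines.append(f"{key} = {_toml_value(getattr(config, key))}")
    lines.append("\n[colony]")
    for key, val in asdict(config.colony).items():
        lines.append(f"{key} = {_toml_value(val)}")
    if config.alphas_betas is not None:
        lines.append(f"alphas_betas = {_toml_value(config.alphas_betas)}")
    lines.append("\n[minimisation]")
    for key, val in asdict(config.minimisation).items():
        lines.append(f"{key} = {_toml_value(val)}")
    lines.append("\n[energy]")
    for key in ("pair_cutoff", "rep_cap", "prob_cutoff", "tau0"):
        lines.append(f"{key} = {_toml_value(getattr(config, key))}")
    lines.append("\n[evaluation]")
    lines.append(f"thresholds = {_toml_value(config.thresholds)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
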