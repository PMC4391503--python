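"""Scenario parameter sets for the gametophore branching model.

A scenario bundles every constant of the model: the clamped auxin levels of
the terminal apex (``H_apex``) and of lateral branch apices (``H``), the
branching threshold (``T``) — each as the (mu, sigma) of a per-gametophore
normal draw — the per-step transport constants ``K_A`` (acropetal) and
``K_B`` (basipetal), the decay rate ``v``, the integration cadence, the
basal-inhibitor geometry and the growth/stop bookkeeping.

Note on units: ``K_A``, ``K_B`` and ``v`` are increments *per simulation
step*.  ``dt`` expresses the fraction of a plastochron covered by one step,
so ``round(plastochron / dt)`` integration steps make up one plastochron
(200 at the standard dt = 0.005).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from importlib import resources

import yaml

__all__ = ["ScenarioParams", "load_presets", "get_scenario", "preset_names"]


@dataclass(frozen=True)
class ScenarioParams:
    """All model constants for one named scenario."""

    name: str
    H_apex_mu: float
    H_apex_sigma: float
    H_mu: float
    H_sigma: float
    T_mu: float
    T_sigma: float
    v: float
    K_A: float
    K_B: float
    dt: float = 0.005
    plastochron: float = 1.0
    basal_zone_depth: int = 5
    basal_T_factor: float = 0.1
    growth_delay_max: int = 4000
    total_steps: int = 8000
    length_range: tuple[int, int] = (20, 40)

    def __post_init__(self) -> None:
        if not (self.H_apex_mu > 0 and self.H_mu > 0 and self.T_mu > 0):
            raise ValueError("H_apex_mu, H_mu and T_mu must be positive")
        if min(self.H_apex_sigma, self.H_sigma, self.T_sigma) < 0:
            raise ValueError("sigmas must be non-negative")
        if self.v < 0 or self.K_A < 0 or self.K_B < 0:
            raise ValueError("v, K_A and K_B must be non-negative")
        if self.dt <= 0 or self.plastochron <= 0:
            raise ValueError("dt and plastochron must be positive")
        # Explicit-Euler safety: the per-step loss of a metamer must stay
        # below its content.  A branch metamer carries one extra basipetal
        # edge to its lateral apex, hence the 2*K_B.
        if self.K_A + 2 * self.K_B + self.v >= 1:
            raise ValueError(
                "unstable configuration: K_A + 2*K_B + v must be < 1 per step"
            )
        if not (0 < self.basal_T_factor <= 1):
            raise ValueError("basal_T_factor must be in (0, 1]")
        if self.basal_zone_depth < 0 or self.growth_delay_max < 0:
            raise ValueError("basal_zone_depth and growth_delay_max must be >= 0")
        if self.total_steps < 1:
            raise ValueError("total_steps must be >= 1")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("length_range must satisfy 1 <= min <= max")
        object.__setattr__(self, "length_range", (int(lo), int(hi)))

    @property
    def steps_per_plastochron(self) -> int:
        return round(self.plastochron / self.dt)

    def with_overrides(self, **kwargs) -> "ScenarioParams":
        """A copy with the given fields replaced (re-validated)."""
        return replace(self, **kwargs)


def _load_raw() -> dict:
    text = resources.files("mossbranch").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


_FIELDS = {f.name for f in fields(ScenarioParams)} - {"name"}


def load_presets() -> dict[str, ScenarioParams]:
    """All shipped scenario presets, keyed by name."""
    raw = _load_raw()
    out = {}
    for name, params in raw["scenarios"].items():
        unknown = set(params) - _FIELDS
        if unknown:
            raise ValueError(f"preset {name!r} has unknown keys {sorted(unknown)}")
        if "length_range" in params:
            params = {**params, "length_range": tuple(params["length_range"])}
        out[name] = ScenarioParams(name=name, **params)
    return out


def preset_names() -> list[str]:
    return list(_load_raw()["scenarios"])


def get_scenario(name: str, **overrides) -> ScenarioParams:
    """Look up a preset by name, optionally overriding fields."""
    presets = load_presets()
    if name not in presets:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(presets)}"
        )
    sc = presets[name]
    return sc.with_overrides(**overrides) if overrides else sc
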