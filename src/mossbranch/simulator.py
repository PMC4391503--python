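"""Mechanistic simulator of gametophore growth and branch initiation.

The gametophore is a growing 1-D file of metamers with a terminal apex
held at a fixed auxin level ``H_apex``.  Auxin moves between neighbouring
metamers with acropetal and basipetal transport constants ``K_A`` and
``K_B`` and decays at rate ``v``; all three are per-simulation-step
increments (see :mod:`mossbranch.scenarios`).  Once per step, every
metamer whose concentration has fallen below its effective branching
threshold is irreversibly re-specified as a branch.  A branch carries a
lateral apex — a separate vertex held at the lateral source level ``H`` —
so from that step on the insertion metamer receives one extra basipetal
influx ``K_B * (H - c)`` while continuing to obey the transport equation.

The basal inhibitor multiplies the threshold by ``basal_T_factor`` inside
the ``basal_zone_depth`` most basal metamers, suppressing the otherwise
constitutive branching of the oldest, auxin-poorest metamers.

Update rule for a non-source metamer i (synchronous, forward Euler)::

    c_i += K_B * (c_above - c_i) + K_A * (c_below - c_i) - v * c_i

with the terminal apex (at ``H_apex``) as the neighbour above the topmost
metamer and a no-flux mirror below metamer 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patterns import BranchingPattern, PatternDataset
from .scenarios import ScenarioParams

__all__ = [
    "GametophoreParams",
    "GametophoreState",
    "draw_parameters",
    "steps_per_plastochron",
    "euler_step",
    "add_metamer",
    "effective_threshold",
    "apply_branch_rule",
    "simulate_gametophore",
    "simulate_dataset",
]

_MAX_REDRAWS = 200


@dataclass(frozen=True)
class GametophoreParams:
    """Per-gametophore stochastic draws, constant for its whole life."""

    H_apex: float
    H: float
    T: float

    def __post_init__(self) -> None:
        if min(self.H_apex, self.H, self.T) <= 0:
            raise ValueError("H_apex, H and T must be strictly positive")


class GametophoreState:
    """The live metamer file during one simulation.

    Arrays run basal to apical; metamer ``i`` (1-based) is slot ``i - 1``.
    ``apex_level`` is the clamped concentration of the terminal apex; it
    may be set to ``None`` to detach the apex (a source-free file, used
    for conservation checks).
    """

    def __init__(
        self,
        params: GametophoreParams,
        apex_level: float | None = None,
        c: np.ndarray | None = None,
        is_branch: np.ndarray | None = None,
    ) -> None:
        self.params = params
        self.apex_level = params.H_apex if apex_level is None else apex_level
        self.c = np.array([0.0] if c is None else c, dtype=float)
        n = len(self.c)
        self.is_branch = (
            np.zeros(n, dtype=bool) if is_branch is None else np.asarray(is_branch, bool).copy()
        )
        self.birth_step = np.zeros(n, dtype=int)
        self.step = 0
        if len(self.is_branch) != n:
            raise ValueError("c and is_branch must have equal length")

    @property
    def n_metamers(self) -> int:
        return len(self.c)

    def detach_apex(self) -> None:
        """Remove the terminal apex source (no-flux at the apical end)."""
        self.apex_level = None

    def pattern(self) -> BranchingPattern:
        positions = tuple(int(i) + 1 for i in np.nonzero(self.is_branch)[0])
        return BranchingPattern(L=self.n_metamers, branch_positions=positions)


def draw_parameters(
    scenario: ScenarioParams, rng: np.random.Generator
) -> GametophoreParams:
    """Draw (H_apex, H, T) for one gametophore.

    Each value is normal with the scenario's (mu, sigma), truncated at
    zero by resampling; sigma = 0 returns the mean exactly.
    """

    def draw(mu: float, sigma: float) -> float:
        if sigma == 0:
            return mu
        while True:
            x = rng.normal(mu, sigma)
            if x > 0:
                return x

    return GametophoreParams(
        H_apex=draw(scenario.H_apex_mu, scenario.H_apex_sigma),
        H=draw(scenario.H_mu, scenario.H_sigma),
        T=draw(scenario.T_mu, scenario.T_sigma),
    )


def steps_per_plastochron(scenario: ScenarioParams) -> int:
    """Number of integration steps between metamer additions."""
    return scenario.steps_per_plastochron


def euler_step(state: GametophoreState, scenario: ScenarioParams) -> GametophoreState:
    """Advance concentrations by one synchronous forward-Euler step.

    Mutates ``state`` in place and returns it.  Branch metamers receive
    the extra lateral-apex influx; the terminal apex (if attached) is the
    fixed neighbour above the topmost metamer; the basal boundary is a
    no-flux mirror.
    """
    c = state.c
    n = len(c)
    up = np.empty(n)
    down = np.empty(n)
    up[:-1] = c[1:]
    up[-1] = state.apex_level if state.apex_level is not None else c[-1]
    down[1:] = c[:-1]
    down[0] = c[0]
    delta = (
        scenario.K_B * (up - c)
        + scenario.K_A * (down - c)
        - scenario.v * c
    )
    flagged = state.is_branch
    if flagged.any():
        delta[flagged] += scenario.K_B * (state.params.H - c[flagged])
    state.c = c + delta
    state.step += 1
    return state


def add_metamer(state: GametophoreState) -> GametophoreState:
    """Insert a new metamer just below the apex, at concentration zero."""
    state.c = np.append(state.c, 0.0)
    state.is_branch = np.append(state.is_branch, False)
    state.birth_step = np.append(state.birth_step, state.step)
    return state


def effective_threshold(
    i: int, N: int, params: GametophoreParams, scenario: ScenarioParams
) -> float:
    """Branching threshold at metamer i (1-based), with basal reduction."""
    if not 1 <= i <= N:
        raise ValueError(f"metamer index {i} outside 1..{N}")
    if i <= scenario.basal_zone_depth:
        return params.T * scenario.basal_T_factor
    return params.T


def apply_branch_rule(
    state: GametophoreState, scenario: ScenarioParams
) -> GametophoreState:
    """Flag every non-branch metamer whose concentration fell below its
    effective threshold (strict inequality).  Flags are permanent."""
    n = state.n_metamers
    thr = np.full(n, state.params.T)
    k = min(scenario.basal_zone_depth, n)
    if k:
        thr[:k] *= scenario.basal_T_factor
    state.is_branch |= (~state.is_branch) & (state.c < thr)
    return state


def _run(
    scenario: ScenarioParams, gparams: GametophoreParams, delay: int
) -> GametophoreState:
    """One gametophore's full life: delay, then per-step transport and
    branch rule, with a metamer added every plastochron."""
    state = GametophoreState(gparams)
    spp = scenario.steps_per_plastochron
    next_add = delay + spp
    while state.step < scenario.total_steps:
        euler_step(state, scenario)
        apply_branch_rule(state, scenario)
        if state.step >= next_add:
            add_metamer(state)
            next_add += spp
    return state


def simulate_gametophore(
    scenario: ScenarioParams,
    rng: np.random.Generator,
    return_state: bool = False,
):
    """Simulate one gametophore; redraw until its final length lands in
    the scenario's admissible range.

    Returns the :class:`BranchingPattern` (and the final state if
    ``return_state``).  Raises ``RuntimeError`` if no admissible length is
    produced within the redraw budget.
    """
    lo, hi = scenario.length_range
    for _ in range(_MAX_REDRAWS):
        gparams = draw_parameters(scenario, rng)
        delay = int(rng.integers(0, scenario.growth_delay_max + 1))
        state = _run(scenario, gparams, delay)
        if lo <= state.n_metamers <= hi:
            pattern = state.pattern()
            return (pattern, state) if return_state else pattern
    raise RuntimeError(
        f"scenario {scenario.name!r} produced no gametophore with length in "
        f"[{lo}, {hi}] after {_MAX_REDRAWS} attempts"
    )


def simulate_dataset(
    scenario: ScenarioParams, n: int, seed: int
) -> PatternDataset:
    """Simulate ``n`` independent gametophores under one scenario.

    Each gametophore uses its own deterministic substream derived from
    (seed, index), so the dataset is reproducible and order-independent.
    Per-gametophore draws are recorded in the dataset metadata.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    patterns = []
    draws = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        pattern, state = simulate_gametophore(scenario, rng, return_state=True)
        patterns.append(pattern)
        p = state.params
        draws.append({"H_apex": p.H_apex, "H": p.H, "T": p.T})
    return PatternDataset(
        patterns,
        label=scenario.name,
        seed=seed,
        metadata={"scenario": scenario.name, "n": n, "draws": draws},
    )
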