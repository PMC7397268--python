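"""Baseline stave-selection methods: the cooperage's *current* practice and Monte Carlo.

* ``current`` — what a Master Cooper does today: pick staves that satisfy
  the size rules only, ignoring OTR entirely. Implemented as a single run
  of the part's random feasible initializer.
* ``mc`` — Monte-Carlo search: random feasible elements, keep the best.
  Implemented *by configuration* of the GA engine (population of two, new
  solutions with probability 100%, every other procedure at 0%), so the
  reduction is literal: an MC run is bit-identical to a GA run with the
  degenerate configuration and the same seed.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .bodies import BodyToolkit
from .engine import EvolutionTrace, GAConfig, MC_PROCEDURES, evolve
from .geometry import BarrelSpec, DEFAULT_SPEC
from .heads import HeadToolkit
from .production import ConstructionOutcome, Constructor
from .staves import PART_BODY, PART_HEAD, Stave

METHODS = ("current", "mc", "ga")


def make_toolkit(staves: Sequence[Stave], part: str, spec: BarrelSpec = DEFAULT_SPEC):
    if part == PART_HEAD:
        return HeadToolkit(staves, spec)
    if part == PART_BODY:
        return BodyToolkit(staves, spec)
    raise ValueError(f"unknown part {part!r}")


def monte_carlo_config(config: GAConfig) -> GAConfig:
    """The degenerate GA configuration implementing the MC baseline."""
    return replace(config, population_size=2, procedures=dict(MC_PROCEDURES))


def current_select(idle_staves: Sequence[Stave], part: str,
                   spec: BarrelSpec = DEFAULT_SPEC,
                   rng: np.random.Generator | None = None) -> list[Stave]:
    """Select an element the way a cooperage does today: sizes only, OTR ignored."""
    rng = rng if rng is not None else np.random.default_rng()
    tk = make_toolkit(idle_staves, part, spec)
    return tk.staves_of(tk.new(rng))


def mc_construct(idle_staves: Sequence[Stave], part: str, config: GAConfig,
                 spec: BarrelSpec = DEFAULT_SPEC,
                 rng: np.random.Generator | None = None) -> tuple[list[Stave], EvolutionTrace]:
    """Monte-Carlo construction: best of repeated random feasible elements."""
    tk = make_toolkit(idle_staves, part, spec)
    best, trace = evolve(tk, monte_carlo_config(config), rng)
    return tk.staves_of(best), trace


def ga_construct(idle_staves: Sequence[Stave], part: str, config: GAConfig,
                 spec: BarrelSpec = DEFAULT_SPEC,
                 rng: np.random.Generator | None = None) -> tuple[list[Stave], EvolutionTrace]:
    """GA construction of one head or body from the idle pool."""
    tk = make_toolkit(idle_staves, part, spec)
    best, trace = evolve(tk, config, rng)
    return tk.staves_of(best), trace


def element_constructor(part: str, method: str, config: GAConfig | None,
                        spec: BarrelSpec = DEFAULT_SPEC) -> Constructor:
    """A production-line constructor for the given part and selection method.

    ``config`` may be None for the ``current`` method, which needs no target.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if method != "current" and config is None:
        raise ValueError(f"method {method!r} needs a GAConfig")

    def construct(method_staves: list[Stave], rng: np.random.Generator) -> ConstructionOutcome:
        tk = make_toolkit(method_staves, part, spec)
        if method == "current":
            ind = tk.new(rng)
            return ConstructionOutcome(indices=ind, otr=tk.otr(ind), trace=None)
        cfg = monte_carlo_config(config) if method == "mc" else config
        best, trace = evolve(tk, cfg, rng)
        return ConstructionOutcome(indices=best, otr=tk.otr(best), trace=trace)

    return construct
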