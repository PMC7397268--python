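"""Production-line queue simulation: idle / method / used stave datasets.

The cooperage production line is modelled as three disjoint datasets. All
staves start in the **idle** queue (a seeded random permutation). Each
construction step moves the first ``S_m`` idle staves into the **method**
dataset, runs a constructor (current / MC / GA) on them, moves the selected
staves (``S_c(n)`` of them at step ``n``) to the **used** dataset and
returns the unselected staves to the tail of the idle queue in their
method-dataset order.

The dataset sizes obey, at every step boundary,

    idle before step n  = S_i - S_m - sum_{k=2..n} S_c(k-1)      (n >= 2)
    used before step n  =             sum_{k=2..n} S_c(k-1)      (n >= 2)

where ``S_i`` is the initial stave count. The idle count above follows the
ledger convention that the next step's method dataset is already held out.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .engine import EvolutionTrace
from .errors import ExhaustedQueueError, InfeasiblePoolError
from .geometry import BarrelSpec, DEFAULT_SPEC, barrel_otr
from .staves import Stave


@dataclass
class ConstructionOutcome:
    """What a constructor returns for one element: indices into the method
    dataset (in element order), the element OTR, and the GA trace if any."""

    indices: tuple[int, ...]
    otr: float
    trace: EvolutionTrace | None = None


#: A constructor builds one element from a method dataset.
Constructor = Callable[[list[Stave], np.random.Generator], ConstructionOutcome]


@dataclass
class StaveQueues:
    """Idle/used bookkeeping for one part's production queue."""

    idle: deque
    used: list
    s_i: int
    s_m: int
    consumed: list[int] = field(default_factory=list)

    @property
    def steps_done(self) -> int:
        return len(self.consumed)

    def eq_idle_count(self, n: int) -> int:
        """Idle-dataset size before step n (method dataset held out), n >= 1."""
        return self.s_i - self.s_m - sum(self.consumed[: n - 1])

    def eq_used_count(self, n: int) -> int:
        """Used-dataset size before step n, n >= 1."""
        return sum(self.consumed[: n - 1])

    def check_conservation(self) -> None:
        """Assert disjointness and stave conservation at a step boundary."""
        idle_ids = {s.id for s in self.idle}
        used_ids = {s.id for s in self.used}
        if idle_ids & used_ids:
            raise AssertionError("idle and used datasets overlap")
        if len(self.idle) + len(self.used) != self.s_i:
            raise AssertionError("stave count not conserved")


def init_queues(staves: Sequence[Stave], s_m: int,
                rng: np.random.Generator | None = None) -> StaveQueues:
    """Randomly order a stave population into an idle queue.

    ``s_m`` is the constant method-dataset size drawn from the head of the
    queue at each step.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if s_m < 1:
        raise ValueError("method dataset size must be at least 1")
    if s_m > len(staves):
        raise ValueError(f"method dataset size {s_m} exceeds population size {len(staves)}")
    order = rng.permutation(len(staves))
    return StaveQueues(
        idle=deque(staves[i] for i in order),
        used=[],
        s_i=len(staves),
        s_m=s_m,
    )


def production_step(queues: StaveQueues, constructor: Constructor,
                    rng: np.random.Generator) -> tuple[list[Stave], ConstructionOutcome]:
    """Run one construction step on the queue.

    The first ``S_m`` idle staves form the method dataset; the constructor's
    selected staves move to the used dataset and the rest return to the tail
    of the idle queue in method-dataset order. A method dataset from which no
    feasible element can be seeded at all (e.g. no bung-capable stave among
    the drawn body staves) is itself returned to the tail and the next
    ``S_m`` staves are drawn, for at most one full pass of the queue.
    """
    requeues = 0
    max_requeues = max(1, len(queues.idle) // queues.s_m)
    while True:
        if len(queues.idle) < queues.s_m:
            raise ExhaustedQueueError(
                f"idle queue holds {len(queues.idle)} staves but the method dataset needs "
                f"{queues.s_m}", elements_completed=queues.steps_done,
            )
        method = [queues.idle.popleft() for _ in range(queues.s_m)]
        try:
            outcome = constructor(method, rng)
        except InfeasiblePoolError:
            queues.idle.extend(method)
            requeues += 1
            if requeues > max_requeues:
                raise
            continue
        selected = set(outcome.indices)
        element = [method[i] for i in outcome.indices]
        for i, stave in enumerate(method):
            if i in selected:
                queues.used.append(stave)
            else:
                queues.idle.append(stave)
        queues.consumed.append(len(selected))
        return element, outcome


@dataclass
class ProductionReport:
    """Per-barrel OTRs and homogeneity summary of one production run."""

    barrels: pd.DataFrame  # barrel_id, body_otr, head1_otr, head2_otr, barrel_otr
    mean: float
    sd: float
    cov_pct: float
    min: float
    max: float
    range_pct: float  # 100 * (max - min) / mean
    error_rate: float  # fraction of elements that hit the budget
    mean_generations: float
    mean_elapsed_seconds: float

    def summary(self) -> dict:
        return {
            "n_barrels": int(len(self.barrels)),
            "mean": self.mean,
            "sd": self.sd,
            "cov_pct": self.cov_pct,
            "min": self.min,
            "max": self.max,
            "range_pct": self.range_pct,
            "error_rate": self.error_rate,
            "mean_generations": self.mean_generations,
            "mean_elapsed_seconds": self.mean_elapsed_seconds,
        }


def run_production(head_staves: Sequence[Stave], body_staves: Sequence[Stave],
                   head_constructor: Constructor, body_constructor: Constructor,
                   n_barrels: int, s_m_head: int, s_m_body: int,
                   queue_rng: np.random.Generator,
                   method_rng: np.random.Generator,
                   spec: BarrelSpec = DEFAULT_SPEC) -> ProductionReport:
    """Build ``2·n_barrels`` heads and ``n_barrels`` bodies through the queues
    and assemble barrels strictly in completion order (barrel i gets body i
    and heads 2i-1, 2i).

    ``queue_rng`` only permutes the initial queues, so two methods compared
    with the same queue seed see identical initial idle queues; ``method_rng``
    drives the constructors.
    """
    head_q = init_queues(head_staves, s_m_head, queue_rng)
    body_q = init_queues(body_staves, s_m_body, queue_rng)

    head_otrs, traces = [], []
    for _ in range(2 * n_barrels):
        _, outcome = production_step(head_q, head_constructor, method_rng)
        head_otrs.append(outcome.otr)
        traces.append(outcome.trace)
    body_otrs = []
    for _ in range(n_barrels):
        _, outcome = production_step(body_q, body_constructor, method_rng)
        body_otrs.append(outcome.otr)
        traces.append(outcome.trace)

    rows = []
    for i in range(n_barrels):
        h1, h2 = head_otrs[2 * i], head_otrs[2 * i + 1]
        rows.append({
            "barrel_id": i + 1,
            "body_otr": body_otrs[i],
            "head1_otr": h1,
            "head2_otr": h2,
            "barrel_otr": barrel_otr(body_otrs[i], h1, h2, spec),
        })
    df = pd.DataFrame(rows)
    otrs = df["barrel_otr"].to_numpy()
    mean = float(otrs.mean())
    sd = float(otrs.std(ddof=1)) if len(otrs) > 1 else 0.0
    real_traces = [t for t in traces if t is not None]
    return ProductionReport(
        barrels=df,
        mean=mean,
        sd=sd,
        cov_pct=100.0 * sd / mean if mean else float("nan"),
        min=float(otrs.min()),
        max=float(otrs.max()),
        range_pct=100.0 * (otrs.max() - otrs.min()) / mean if mean else float("nan"),
        error_rate=(sum(t.termination == "budget_exhausted" for t in real_traces) / len(real_traces))
        if real_traces else float("nan"),
        mean_generations=float(np.mean([t.generations for t in real_traces])) if real_traces else float("nan"),
        mean_elapsed_seconds=float(np.mean([t.elapsed_seconds for t in real_traces])) if real_traces else float("nan"),
    )
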