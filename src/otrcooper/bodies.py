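"""Body-specific initializer and genetic operators.

A body individual is a tuple of stave indices with the bung-capable stave
first. Order beyond that is irrelevant to the body OTR (a width-weighted
mean), so there is no internal crossing for bodies. Every operator output
satisfies the body rules: summed width inside the window around 218 cm and
a first stave strictly wider than the bung minimum; when no feasible
variation can be built within the bounded repair budget, the original
individual is returned.

Construction machinery: a randomized greedy fill adds staves while the
total stays under the window's upper bound, and a single-swap repair
(exchange one selected non-bung stave for an unused one, found by binary
search over sorted widths) lands the total inside the window when the
greedy fill stalls below it.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import InfeasiblePoolError
from .geometry import BarrelSpec, DEFAULT_SPEC
from .staves import PART_BODY, Stave

INIT_ATTEMPTS = 200
REPAIR_ATTEMPTS = 50
#: Number of non-bung staves the mutation operator removes.
MUTATION_REMOVALS = 3


def _greedy_fill(chosen: list[int], total: float, order: Sequence[int],
                 widths: Sequence[float], lo: float, hi: float) -> float:
    """Append staves from *order* while the total stays <= hi, stopping at >= lo."""
    for j in order:
        if total >= lo:
            break
        w = widths[j]
        if total + w <= hi:
            chosen.append(j)
            total += w
    return total


def _swap_repair(chosen: list[int], total: float, unused: Sequence[int],
                 widths: Sequence[float], lo: float, hi: float,
                 rng: np.random.Generator) -> float | None:
    """Swap one non-bung chosen stave for an unused one to land in [lo, hi].

    Returns the new total on success (mutating *chosen*), else None.
    """
    if not unused or len(chosen) < 2:
        return None
    uw = np.array([widths[j] for j in unused], dtype=float)
    order_u = np.argsort(uw, kind="stable")
    uw_sorted = uw[order_u]
    for i in rng.permutation(len(chosen) - 1) + 1:  # never position 0 (bung)
        wi = widths[chosen[i]]
        left = int(np.searchsorted(uw_sorted, lo - total + wi, side="left"))
        right = int(np.searchsorted(uw_sorted, hi - total + wi, side="right"))
        if right > left:
            pick = int(order_u[int(rng.integers(left, right))])
            j = unused[pick]
            total += widths[j] - wi
            chosen[i] = j
            return total
    return None


def _init(pool: Sequence[int], widths: Sequence[float], spec: BarrelSpec,
          rng: np.random.Generator, attempts: int = INIT_ATTEMPTS) -> tuple[int, ...]:
    lo, hi = spec.body_width_window
    bungs = [i for i in pool if widths[i] > spec.bung_min_width]
    if not bungs:
        raise InfeasiblePoolError(
            f"no stave wider than the bung minimum {spec.bung_min_width} mm in the pool"
        )
    for _ in range(attempts):
        bung = bungs[int(rng.integers(len(bungs)))]
        others = [i for i in pool if i != bung]
        rng.shuffle(others)
        chosen = [bung]
        total = _greedy_fill(chosen, widths[bung], others, widths, lo, hi)
        if lo <= total <= hi:
            return tuple(chosen)
        in_body = set(chosen)
        unused = [j for j in others if j not in in_body]
        if _swap_repair(chosen, total, unused, widths, lo, hi, rng) is not None:
            return tuple(chosen)
    raise InfeasiblePoolError(
        f"no stave subset meeting the width window [{lo}, {hi}] mm found in {attempts} attempts"
    )


def _mutate(ind: tuple[int, ...], idle: Sequence[int], widths: Sequence[float],
            spec: BarrelSpec, rng: np.random.Generator,
            attempts: int = REPAIR_ATTEMPTS, n_remove: int = MUTATION_REMOVALS) -> tuple[int, ...]:
    """Remove ``n_remove`` random non-bung staves and refill from the idle pool.

    The bung stave (position 0) is never touched. Unchanged original when no
    feasible refill is found within the attempt budget.
    """
    if not idle or len(ind) < 2:
        return ind
    lo, hi = spec.body_width_window
    removable = list(ind[1:])
    k = min(n_remove, len(removable))
    for _ in range(attempts):
        removed = set(int(i) for i in rng.choice(len(removable), size=k, replace=False))
        kept = [ind[0]] + [s for i, s in enumerate(removable) if i not in removed]
        total = sum(widths[i] for i in kept)
        candidates = [j for j in idle]
        rng.shuffle(candidates)
        chosen = list(kept)
        total = _greedy_fill(chosen, total, candidates, widths, lo, hi)
        if lo <= total <= hi:
            return tuple(chosen)
        in_body = set(chosen)
        unused = [j for j in candidates if j not in in_body]
        if _swap_repair(chosen, total, unused, widths, lo, hi, rng) is not None:
            return tuple(chosen)
    return ind


def _external_cross(a: tuple[int, ...], b: tuple[int, ...], idle: Sequence[int],
                    widths: Sequence[float], spec: BarrelSpec,
                    rng: np.random.Generator,
                    attempts: int = REPAIR_ATTEMPTS) -> tuple[int, ...]:
    """Bung of a random parent first; pooled de-duplicated parent staves are
    appended in random order until the window's lower bound is reached; an
    overshoot is repaired by the mutation mechanism with idle staves."""
    lo, hi = spec.body_width_window
    bung = a[0] if rng.random() < 0.5 else b[0]
    pooled = list(dict.fromkeys(list(a) + list(b)))  # order-stable de-dup
    pooled.remove(bung)
    rng.shuffle(pooled)
    chosen = [bung]
    total = widths[bung]
    taken = 0
    for j in pooled:
        if total >= lo:
            break
        chosen.append(j)
        total += widths[j]
        taken += 1
    if lo <= total <= hi:
        return tuple(chosen)
    # Overshoot (or stalled below the window): repair with extra staves.
    leftover = pooled[taken:]
    extra = list(idle) + leftover
    repaired = _mutate(tuple(chosen), extra, widths, spec, rng, attempts=attempts)
    lo_ok = lo <= sum(widths[i] for i in repaired) <= hi
    if lo_ok:
        return repaired
    return tuple(a) if rng.random() < 0.5 else tuple(b)


class BodyToolkit:
    """Constructor toolkit over a fixed pool of body staves."""

    part = PART_BODY

    def __init__(self, staves: Sequence[Stave], spec: BarrelSpec = DEFAULT_SPEC,
                 init_attempts: int = INIT_ATTEMPTS):
        bad = [s.id for s in staves if s.part != PART_BODY]
        if bad:
            raise ValueError(f"non-body staves in body pool: {bad[:5]}")
        self.staves = list(staves)
        self.widths = [s.width for s in staves]
        self.otrs = [s.otr for s in staves]
        self.spec = spec
        self.init_attempts = init_attempts
        self._all = list(range(len(staves)))

    def new(self, rng: np.random.Generator) -> tuple[int, ...]:
        return _init(self._all, self.widths, self.spec, rng, self.init_attempts)

    def mutate(self, ind: tuple[int, ...], rng: np.random.Generator) -> tuple[int, ...]:
        in_use = set(ind)
        idle = [i for i in self._all if i not in in_use]
        return _mutate(ind, idle, self.widths, self.spec, rng)

    def internal_cross(self, ind: tuple[int, ...], rng: np.random.Generator) -> tuple[int, ...]:
        # Stave order does not affect a body's OTR; internal crossing is a no-op
        # and its procedure probability is 0 for bodies.
        return ind

    def external_cross(self, a, b, rng: np.random.Generator) -> tuple[int, ...]:
        in_use = set(a) | set(b)
        idle = [i for i in self._all if i not in in_use]
        return _external_cross(a, b, idle, self.widths, self.spec, rng)

    def otr(self, ind: tuple[int, ...]) -> float:
        total = 0.0
        acc = 0.0
        for i in ind:
            w = self.widths[i]
            total += w
            acc += w * self.otrs[i]
        return acc / total

    def staves_of(self, ind: Sequence[int]) -> list[Stave]:
        return [self.staves[i] for i in ind]


# ---------------------------------------------------------------------------
# Stave-level convenience API


def body_init(idle_staves: Sequence[Stave], spec: BarrelSpec = DEFAULT_SPEC,
              rng: np.random.Generator | None = None) -> list[Stave]:
    """Build one feasible body (bung stave first) from the idle pool."""
    rng = rng if rng is not None else np.random.default_rng()
    tk = BodyToolkit(idle_staves, spec)
    return tk.staves_of(tk.new(rng))


def body_mutate(body: Sequence[Stave], idle_staves: Sequence[Stave],
                spec: BarrelSpec = DEFAULT_SPEC,
                rng: np.random.Generator | None = None) -> list[Stave]:
    """Replace three non-bung staves of *body* from the idle pool when feasible."""
    rng = rng if rng is not None else np.random.default_rng()
    body_ids = {s.id for s in body}
    pool = list(body) + [s for s in idle_staves if s.id not in body_ids]
    tk = BodyToolkit(pool, spec)
    ind = tuple(range(len(body)))
    idle = list(range(len(body), len(pool)))
    return tk.staves_of(_mutate(ind, idle, tk.widths, spec, rng))


def body_external_cross(body_a: Sequence[Stave], body_b: Sequence[Stave],
                        idle_staves: Sequence[Stave],
                        spec: BarrelSpec = DEFAULT_SPEC,
                        rng: np.random.Generator | None = None) -> list[Stave]:
    """Combine two bodies into a new feasible body, with idle-stave repair."""
    rng = rng if rng is not None else np.random.default_rng()
    ids_a = {s.id for s in body_a}
    ids_ab = ids_a | {s.id for s in body_b}
    pool = (list(body_a) + [s for s in body_b if s.id not in ids_a]
            + [s for s in idle_staves if s.id not in ids_ab])
    tk = BodyToolkit(pool, spec)
    index_of = {s.id: i for i, s in enumerate(pool)}
    a = tuple(index_of[s.id] for s in body_a)
    b = tuple(index_of[s.id] for s in body_b)
    return tk.staves_of(tk.external_cross(a, b, rng))
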