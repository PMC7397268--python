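"""Head-specific genetic operators and initializer.

A head individual is an ordered tuple of stave indices into a fixed pool
(the method dataset). Order is part of the genotype: it determines each
stave's position across the disc, hence its in-circle area weight and its
required length. All operators are *feasibility preserving*: their output
always satisfies the head rules, falling back to (one of) the original
individual(s) when no feasible variation exists.

The public functions (:func:`head_init`, :func:`head_mutate`, ...) operate
on lists of :class:`~otrcooper.staves.Stave`; :class:`HeadToolkit` exposes
the same operators over integer indices for the GA engine.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np

from .errors import InfeasiblePoolError
from .geometry import BarrelSpec, DEFAULT_SPEC, _head_strips, head_dims_feasible
from .staves import PART_HEAD, Stave

#: Random-draw attempts before head_init declares the pool infeasible.
INIT_ATTEMPTS = 200


def _feasible(ind: Sequence[int], widths: Sequence[float], lengths: Sequence[float],
              spec: BarrelSpec) -> bool:
    return head_dims_feasible([widths[i] for i in ind], [lengths[i] for i in ind], spec)[0]


def _centre_out(subset: Sequence[int], lengths, rng: np.random.Generator) -> tuple[int, ...]:
    """Arrange a stave subset with the longest staves at the most demanding
    positions: centre first, then alternating outward. The required-length
    profile of any head is maximal at the centre and non-increasing toward
    the edges, so this is the ordering most likely to be feasible."""
    k = len(subset)
    mid = k // 2
    positions = [mid]
    for step in range(1, mid + 1):
        pair = [mid - step, mid + step]
        if rng.random() < 0.5:
            pair.reverse()
        positions.extend(pair)
    by_length = sorted(subset, key=lambda i: -lengths[i])
    out = [0] * k
    for pos, stave in zip(positions, by_length):
        out[pos] = stave
    return tuple(out)


def _init(widths: Sequence[float], lengths: Sequence[float], spec: BarrelSpec,
          rng: np.random.Generator, attempts: int = INIT_ATTEMPTS) -> tuple[int, ...]:
    """Draw random stave subsets until one forms a feasible head.

    Each attempt draws a random allowed count and a random subset in random
    order; if that order is infeasible, the same subset is retried in the
    centre-out arrangement before the subset is abandoned. Stave *choice*
    therefore stays uniformly random; only the placement is repaired.
    """
    n = len(widths)
    counts = [k for k in sorted(spec.head_count_allowed) if k <= n]
    if not counts:
        raise InfeasiblePoolError(
            f"pool of {n} staves cannot reach any allowed head count {sorted(spec.head_count_allowed)}"
        )
    failures: Counter[str] = Counter()
    for _ in range(attempts):
        k = counts[rng.integers(len(counts))]
        ind = tuple(int(i) for i in rng.choice(n, size=k, replace=False))
        ok, why = head_dims_feasible([widths[i] for i in ind], [lengths[i] for i in ind], spec)
        if ok:
            return ind
        arranged = _centre_out(ind, lengths, rng)
        if head_dims_feasible([widths[i] for i in arranged],
                              [lengths[i] for i in arranged], spec)[0]:
            return arranged
        failures[why.split(":")[0]] += 1
    top = failures.most_common(1)[0][0] if failures else "unknown"
    raise InfeasiblePoolError(
        f"no feasible head found in {attempts} random draws; most frequent violation: {top}"
    )


def _mutate(ind: tuple[int, ...], idle: Sequence[int], widths, lengths,
            spec: BarrelSpec, rng: np.random.Generator) -> tuple[int, ...]:
    """Replace exactly one stave in place, scanning (position, idle stave)
    pairs in randomized order; unchanged original if no pair is feasible."""
    if not idle:
        return ind
    positions = rng.permutation(len(ind))
    idle_order = [idle[i] for i in rng.permutation(len(idle))]
    lst = list(ind)
    ws = [widths[i] for i in lst]
    ls = [lengths[i] for i in lst]
    for p in positions:
        keep_w, keep_l = ws[p], ls[p]
        for j in idle_order:
            ws[p], ls[p] = widths[j], lengths[j]
            if head_dims_feasible(ws, ls, spec)[0]:
                lst[p] = j
                return tuple(lst)
        ws[p], ls[p] = keep_w, keep_l
    return ind


def _internal_cross(ind: tuple[int, ...], widths, lengths,
                    spec: BarrelSpec, rng: np.random.Generator) -> tuple[int, ...]:
    """Swap two positions; the first candidate pair is random and the scan is
    exhaustive over all pairs, returning the original if none is feasible."""
    k = len(ind)
    if k < 2:
        return ind
    pairs = [(i, j) for i in range(k - 1) for j in range(i + 1, k)]
    ws = [widths[i] for i in ind]
    ls = [lengths[i] for i in ind]
    for p in rng.permutation(len(pairs)):
        i, j = pairs[p]
        ws[i], ws[j] = ws[j], ws[i]
        ls[i], ls[j] = ls[j], ls[i]
        if head_dims_feasible(ws, ls, spec)[0]:
            lst = list(ind)
            lst[i], lst[j] = lst[j], lst[i]
            return tuple(lst)
        ws[i], ws[j] = ws[j], ws[i]
        ls[i], ls[j] = ls[j], ls[i]
    return ind


def _external_cross(a: tuple[int, ...], b: tuple[int, ...], widths, lengths,
                    spec: BarrelSpec, rng: np.random.Generator) -> tuple[int, ...]:
    """Prefix of *a* up to a random cut, extended with *b*'s staves in order
    (skipping duplicates), then *a*'s remaining staves; the shortest feasible
    allowed count wins. Falls back to one of the originals at random."""
    cut = int(rng.integers(0, len(a) + 1))  # 0 = empty prefix is allowed
    child = list(a[:cut])
    used = set(child)
    for j in b:
        if j not in used:
            child.append(j)
            used.add(j)
    for j in a[cut:]:
        if j not in used:
            child.append(j)
            used.add(j)
    ws = [widths[i] for i in child]
    ls = [lengths[i] for i in child]
    for k in sorted(spec.head_count_allowed):
        if k <= len(child) and head_dims_feasible(ws[:k], ls[:k], spec)[0]:
            return tuple(child[:k])
    return a if rng.random() < 0.5 else b


class HeadToolkit:
    """Constructor toolkit over a fixed pool of head staves.

    Individuals are tuples of pool indices in head order. ``idle`` staves
    for mutation are the pool members not used by the individual.
    """

    part = PART_HEAD

    def __init__(self, staves: Sequence[Stave], spec: BarrelSpec = DEFAULT_SPEC,
                 init_attempts: int = INIT_ATTEMPTS):
        bad = [s.id for s in staves if s.part != PART_HEAD]
        if bad:
            raise ValueError(f"non-head staves in head pool: {bad[:5]}")
        self.staves = list(staves)
        self.widths = [s.width for s in staves]
        self.lengths = [s.length for s in staves]
        self.otrs = [s.otr for s in staves]
        self.spec = spec
        self.init_attempts = init_attempts
        self._n = len(staves)

    def new(self, rng: np.random.Generator) -> tuple[int, ...]:
        return _init(self.widths, self.lengths, self.spec, rng, self.init_attempts)

    def mutate(self, ind: tuple[int, ...], rng: np.random.Generator) -> tuple[int, ...]:
        in_use = set(ind)
        idle = [i for i in range(self._n) if i not in in_use]
        return _mutate(ind, idle, self.widths, self.lengths, self.spec, rng)

    def internal_cross(self, ind: tuple[int, ...], rng: np.random.Generator) -> tuple[int, ...]:
        return _internal_cross(ind, self.widths, self.lengths, self.spec, rng)

    def external_cross(self, a, b, rng: np.random.Generator) -> tuple[int, ...]:
        return _external_cross(a, b, self.widths, self.lengths, self.spec, rng)

    def otr(self, ind: tuple[int, ...]) -> float:
        strips = _head_strips([self.widths[i] for i in ind], self.spec)
        total = 0.0
        acc = 0.0
        for (_, _, area, _), i in zip(strips, ind):
            total += area
            acc += area * self.otrs[i]
        return acc / total

    def staves_of(self, ind: Sequence[int]) -> list[Stave]:
        return [self.staves[i] for i in ind]


# ---------------------------------------------------------------------------
# Stave-level convenience API


def head_init(idle_staves: Sequence[Stave], spec: BarrelSpec = DEFAULT_SPEC,
              rng: np.random.Generator | None = None) -> list[Stave]:
    """Build one feasible head from randomly drawn idle staves (bounded retries)."""
    rng = rng if rng is not None else np.random.default_rng()
    tk = HeadToolkit(idle_staves, spec)
    return tk.staves_of(tk.new(rng))


def _combined(head: Sequence[Stave], idle_staves: Sequence[Stave], spec: BarrelSpec):
    pool = list(head) + [s for s in idle_staves if s.id not in {h.id for h in head}]
    tk = HeadToolkit(pool, spec)
    ind = tuple(range(len(head)))
    idle = list(range(len(head), len(pool)))
    return tk, ind, idle


def head_mutate(head: Sequence[Stave], idle_staves: Sequence[Stave],
                spec: BarrelSpec = DEFAULT_SPEC,
                rng: np.random.Generator | None = None) -> list[Stave]:
    """Replace one stave of *head* with an idle stave when feasible, else return it unchanged."""
    rng = rng if rng is not None else np.random.default_rng()
    tk, ind, idle = _combined(head, idle_staves, spec)
    return tk.staves_of(_mutate(ind, idle, tk.widths, tk.lengths, spec, rng))


def head_internal_cross(head: Sequence[Stave], spec: BarrelSpec = DEFAULT_SPEC,
                        rng: np.random.Generator | None = None) -> list[Stave]:
    """Exchange the positions of two staves of *head* when feasible."""
    rng = rng if rng is not None else np.random.default_rng()
    tk = HeadToolkit(list(head), spec)
    return tk.staves_of(tk.internal_cross(tuple(range(len(head))), rng))


def head_external_cross(head_a: Sequence[Stave], head_b: Sequence[Stave],
                        spec: BarrelSpec = DEFAULT_SPEC,
                        rng: np.random.Generator | None = None) -> list[Stave]:
    """Combine two heads into a new feasible head, or return one of the originals."""
    rng = rng if rng is not None else np.random.default_rng()
    ids_a = {s.id for s in head_a}
    pool = list(head_a) + [s for s in head_b if s.id not in ids_a]
    tk = HeadToolkit(pool, spec)
    index_of = {s.id: i for i, s in enumerate(pool)}
    a = tuple(index_of[s.id] for s in head_a)
    b = tuple(index_of[s.id] for s in head_b)
    return tk.staves_of(tk.external_cross(a, b, rng))
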