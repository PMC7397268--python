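"""Body operators: initializer, mutation and external crossing.

The brute-force oracle enumerates every stave subset of a small pool and
checks the width window and bung rule, so operator outputs can be verified
against the complete feasible set.
"""

import itertools

import numpy as np
import pytest

from otrcooper import (InfeasiblePoolError, body_external_cross, body_feasible, body_init,
                       body_mutate, element_otr)
from otrcooper.bodies import BodyToolkit

from conftest import make_body_stave


def feasible_subsets(staves, spec):
    """All feasible bodies of a small pool, as frozensets of ids (brute force)."""
    lo, hi = spec.body_width_window
    out = []
    for r in range(1, len(staves) + 1):
        for combo in itertools.combinations(staves, r):
            total = sum(s.width for s in combo)
            if lo <= total <= hi and any(s.width > spec.bung_min_width for s in combo):
                out.append(frozenset(s.id for s in combo))
    return out


class TestInit:
    def test_toy_pool_produces_feasible_body(self, toy_body_spec, rng):
        pool = [make_body_stave(i, w) for i, w in enumerate([110.0, 100.0, 90.0, 95.0, 105.0])]
        body = body_init(pool, toy_body_spec, rng)
        assert body_feasible(body, toy_body_spec)[0]
        assert body[0].width > toy_body_spec.bung_min_width

    def test_no_bung_capable_stave_errors(self, toy_body_spec, rng):
        pool = [make_body_stave(i, 95.0) for i in range(10)]
        with pytest.raises(InfeasiblePoolError, match="bung"):
            body_init(pool, toy_body_spec, rng)

    def test_unique_window_subset_is_found(self, toy_body_spec, rng):
        # widths chosen so exactly one subset sums into [299.5, 300.5]
        widths = [120.0, 97.3, 82.7, 55.0, 61.0, 73.0, 131.0, 47.0]
        pool = [make_body_stave(i, w) for i, w in enumerate(widths)]
        oracle = feasible_subsets(pool, toy_body_spec)
        assert len(oracle) == 1
        body = body_init(pool, toy_body_spec, rng)
        assert frozenset(s.id for s in body) == oracle[0]

    def test_seeded_determinism(self, toy_body_spec):
        pool = [make_body_stave(i, w) for i, w in enumerate([110.0, 100.0, 90.0, 95.0, 105.0])]
        b1 = body_init(pool, toy_body_spec, np.random.default_rng(4))
        b2 = body_init(pool, toy_body_spec, np.random.default_rng(4))
        assert [s.id for s in b1] == [s.id for s in b2]


class TestMutate:
    def test_empty_idle_returns_original(self, toy_body_spec, rng):
        body = [make_body_stave(i, w) for i, w in enumerate([110.0, 100.0, 90.0])]
        assert [s.id for s in body_mutate(body, [], toy_body_spec, rng)] == ["b0", "b1", "b2"]

    def test_exact_copy_idle_pool_changes_at_most_three(self, toy_body_spec, rng):
        body = [make_body_stave(i, w) for i, w in enumerate([110.0, 100.0, 90.0])]
        idle = [make_body_stave(10 + i, w) for i, w in enumerate([100.0, 90.0, 95.0, 105.0])]
        mutated = body_mutate(body, idle, toy_body_spec, rng)
        assert body_feasible(mutated, toy_body_spec)[0]
        assert mutated[0].id == "b0"  # the bung stave is never replaced
        changed = len(set(s.id for s in mutated) - {"b0", "b1", "b2"})
        assert changed <= 3

    def test_four_stave_body_keeps_bung(self, rng):
        from otrcooper import BarrelSpec
        spec = BarrelSpec(body_total_width=400.0, body_width_tolerance=0.5,
                          bung_min_width=100.0)
        body = [make_body_stave(0, 103.0), make_body_stave(1, 99.0),
                make_body_stave(2, 99.0), make_body_stave(3, 99.0)]
        idle = [make_body_stave(10 + i, 99.0) for i in range(6)]
        mutated = body_mutate(body, idle, spec, rng)
        assert mutated[0].id == "b0"
        assert body_feasible(mutated, spec)[0]


class TestExternalCross:
    def test_identical_parents_keep_id_set(self, toy_body_spec, rng):
        body = [make_body_stave(i, w) for i, w in enumerate([110.0, 100.0, 90.0])]
        child = body_external_cross(body, body, [], toy_body_spec, rng)
        assert set(s.id for s in child) == {"b0", "b1", "b2"}

    def test_disjoint_parents_mix_feasibly(self, toy_body_spec, rng):
        a = [make_body_stave(i, w) for i, w in enumerate([110.0, 100.0, 90.0])]
        b = [make_body_stave(10 + i, w) for i, w in enumerate([105.0, 95.0, 100.0])]
        for _ in range(20):
            child = body_external_cross(a, b, [], toy_body_spec, rng)
            assert body_feasible(child, toy_body_spec)[0]
            ids = [s.id for s in child]
            assert len(set(ids)) == len(ids)
            assert set(ids) <= {s.id for s in a + b}

    def test_idle_assisted_repair_or_fallback(self, toy_body_spec, rng):
        # parents whose pooled widths cannot reach the window without help
        a = [make_body_stave(i, w) for i, w in enumerate([160.0, 140.0])]
        b = [make_body_stave(10 + i, w) for i, w in enumerate([150.0, 150.0])]
        assert body_feasible(a, toy_body_spec)[0] and body_feasible(b, toy_body_spec)[0]
        idle = [make_body_stave(20 + i, w) for i, w in enumerate([50.0, 60.0, 70.0, 90.3, 110.0])]
        oracle = feasible_subsets(a + b + idle, toy_body_spec)
        for _ in range(20):
            child = body_external_cross(a, b, idle, toy_body_spec, rng)
            assert frozenset(s.id for s in child) in oracle


class TestFuzzClosure:
    def test_operators_stay_in_window_and_conserve_ids(self, rng):
        from otrcooper import DEFAULT_SPEC
        widths = np.concatenate([rng.uniform(40, 130, size=45), rng.uniform(101, 130, size=5)])
        pool = [make_body_stave(i, float(w), otr=float(o))
                for i, (w, o) in enumerate(zip(widths, rng.uniform(0.01, 0.06, size=50)))]
        tk = BodyToolkit(pool)
        lo, hi = DEFAULT_SPEC.body_width_window
        ind = tk.new(rng)
        for _ in range(150):
            op = rng.choice(["mutate", "external", "new"])
            if op == "mutate":
                ind = tk.mutate(ind, rng)
            elif op == "external":
                ind = tk.external_cross(ind, tk.new(rng), rng)
            else:
                ind = tk.new(rng)
            total = sum(tk.widths[i] for i in ind)
            assert lo <= total <= hi
            assert tk.widths[ind[0]] > DEFAULT_SPEC.bung_min_width
            assert len(set(ind)) == len(ind)

    def test_body_otr_is_order_independent(self, rng):
        pool = [make_body_stave(i, float(w), otr=float(o))
                for i, (w, o) in enumerate(zip(rng.uniform(40, 130, size=30),
                                               rng.uniform(0.01, 0.06, size=30)))]
        shuffled = [pool[i] for i in rng.permutation(30)]
        assert element_otr(shuffled) == pytest.approx(element_otr(pool), rel=1e-12)
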