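"""Head operators: initializer, mutation, internal and external crossing.

Closure (outputs stay feasible), conservation (no ids invented, none
duplicated) and fallback totality (worst case returns an original) are the
contracts every operator must keep.
"""

import itertools

import numpy as np
import pytest

from otrcooper import (InfeasiblePoolError, head_external_cross, head_feasible, head_init,
                       head_internal_cross, head_mutate)
from otrcooper.heads import HeadToolkit

from conftest import make_head_stave


def interchangeable_pool(n, width=67.0, length=600.0):
    return [make_head_stave(i, width, length, otr=0.02 + 0.0005 * i) for i in range(n)]


class TestInit:
    def test_returns_feasible_head(self, rng):
        head = head_init(interchangeable_pool(11), rng=rng)
        ok, why = head_feasible(head)
        assert ok, why
        assert len(head) == 9  # only 9 of {7, 9, 11} works at 67 mm widths

    def test_pool_too_small_for_any_odd_count(self, rng):
        with pytest.raises(InfeasiblePoolError, match="allowed head count"):
            head_init(interchangeable_pool(6), rng=rng)

    def test_seeded_determinism(self):
        pool = interchangeable_pool(15)
        h1 = head_init(pool, rng=np.random.default_rng(3))
        h2 = head_init(pool, rng=np.random.default_rng(3))
        assert [s.id for s in h1] == [s.id for s in h2]

    def test_hard_pool_uses_centre_out_arrangement(self, rng):
        # exactly one stave long enough for the centre (597 mm required) and
        # two for the flanking positions (~592.9 mm at 70 mm widths): any
        # feasible 9-stave head must centre h0, which random ordering alone
        # essentially never produces
        pool = ([make_head_stave(0, 70.0, 600.0)]
                + [make_head_stave(i, 70.0, 594.0) for i in (1, 2)]
                + [make_head_stave(i, 70.0, 560.0) for i in range(3, 12)])
        head = head_init(pool, rng=rng)
        assert head[len(head) // 2].id == "h0"


class TestMutate:
    def test_empty_idle_pool_returns_original(self, rng):
        head = interchangeable_pool(9)
        assert [s.id for s in head_mutate(head, [], rng=rng)] == [s.id for s in head]

    def test_replacement_changes_exactly_one_stave(self, rng):
        head = interchangeable_pool(9)
        idle = [make_head_stave(100, 67.0, 600.0)]
        mutated = head_mutate(head, idle, rng=rng)
        changed = [a.id != b.id for a, b in zip(head, mutated)]
        assert sum(changed) == 1
        assert "h100" in {s.id for s in mutated}

    def test_exhaustive_scan_finds_single_feasible_slot(self, rng):
        # Cross-check against brute force over all (position, idle) pairs:
        # the scan must land on one of the genuinely feasible replacements.
        head = [make_head_stave(i, 67.0, 372.0 if i in (0, 8) else 600.0) for i in range(9)]
        assert head_feasible(head)[0]
        idle = [make_head_stave(50, 67.0, 597.0)]
        # brute force: which (position, idle) replacements are feasible?
        feasible_positions = []
        for p in range(9):
            trial = head.copy()
            trial[p] = idle[0]
            if head_feasible(trial)[0]:
                feasible_positions.append(p)
        mutated = head_mutate(head, idle, rng=rng)
        changed = [i for i, (a, b) in enumerate(zip(head, mutated)) if a.id != b.id]
        if feasible_positions:
            assert changed and changed[0] in feasible_positions
        else:
            assert not changed


class TestInternalCross:
    def test_swap_of_interchangeable_staves(self, rng):
        head = interchangeable_pool(9)
        crossed = head_internal_cross(head, rng=rng)
        assert sorted(s.id for s in crossed) == sorted(s.id for s in head)
        assert sum(a.id != b.id for a, b in zip(head, crossed)) == 2

    def test_planted_single_feasible_swap_is_found(self, rng):
        # centre stave is the only long one; edge staves have matching lengths
        # so the only feasible swaps exchange two equal-requirement positions.
        lengths = [370.0, 500.0, 570.0, 595.0, 600.0, 595.0, 570.0, 500.0, 370.0]
        head = [make_head_stave(i, 67.0, l) for i, l in enumerate(lengths)]
        assert head_feasible(head)[0]
        feasible_swaps = set()
        for i, j in itertools.combinations(range(9), 2):
            trial = head.copy()
            trial[i], trial[j] = trial[j], trial[i]
            if head_feasible(trial)[0]:
                feasible_swaps.add((i, j))
        crossed = head_internal_cross(head, rng=rng)
        changed = tuple(i for i, (a, b) in enumerate(zip(head, crossed)) if a.id != b.id)
        if feasible_swaps:
            assert changed in feasible_swaps
        else:
            assert changed == ()


class TestExternalCross:
    def test_identical_parents_reproduce_parent(self, rng):
        head = interchangeable_pool(9)
        child = head_external_cross(head, head, rng=rng)
        assert [s.id for s in child] == [s.id for s in head]

    def test_disjoint_interchangeable_parents_mix(self, rng):
        a = interchangeable_pool(9)
        b = [make_head_stave(100 + i, 67.0, 600.0) for i in range(9)]
        child = head_external_cross(a, b, rng=rng)
        assert head_feasible(child)[0]
        assert len(child) % 2 == 1
        ids = [s.id for s in child]
        assert len(set(ids)) == len(ids)
        assert set(ids) <= {s.id for s in a} | {s.id for s in b}

    def test_incompatible_parents_fall_back_to_original(self, rng):
        # two barely-feasible heads of short staves: any mixture that shifts
        # the long stave off-centre fails, so most cuts are infeasible
        def head_with_lengths(base):
            lengths = [370.0, 500.0, 570.0, 595.0, 600.0, 595.0, 570.0, 500.0, 370.0]
            return [make_head_stave(base + i, 67.0, l) for i, l in enumerate(lengths)]

        a, b = head_with_lengths(0), head_with_lengths(100)
        for _ in range(20):
            child = head_external_cross(a, b, rng=rng)
            assert head_feasible(child)[0]
            ids = [s.id for s in child]
            assert len(set(ids)) == len(ids)


class TestOperatorClosureFuzz:
    def test_operators_preserve_feasibility_and_conserve_ids(self, rng):
        pool = [make_head_stave(i, float(w), float(l), otr=float(o))
                for i, (w, l, o) in enumerate(zip(
                    rng.uniform(55, 95, size=30),
                    rng.uniform(420, 730, size=30),
                    rng.uniform(0.01, 0.06, size=30)))]
        tk = HeadToolkit(pool)
        try:
            ind = tk.new(rng)
        except InfeasiblePoolError:
            pytest.skip("random pool cannot seed a head")
        all_ids = set(range(30))
        for _ in range(200):
            op = rng.choice(["mutate", "internal", "external", "new"])
            if op == "mutate":
                ind = tk.mutate(ind, rng)
            elif op == "internal":
                ind = tk.internal_cross(ind, rng)
            elif op == "external":
                other = tk.new(rng)
                ind = tk.external_cross(ind, other, rng)
            else:
                ind = tk.new(rng)
            widths = [tk.widths[i] for i in ind]
            lengths = [tk.lengths[i] for i in ind]
            from otrcooper.geometry import head_dims_feasible
            ok, why = head_dims_feasible(widths, lengths, tk.spec)
            assert ok, why
            assert len(set(ind)) == len(ind)
            assert set(ind) <= all_ids
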