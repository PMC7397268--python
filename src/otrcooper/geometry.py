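"""Barrel geometry: feasibility rules and OTR aggregation for heads and bodies.

The model follows the 225-litre *Bordelaise* barrel. A head is a disc of
597 mm diameter covered by an ordered row of staves; the in-circle area of
each head stave is a closed-form difference of circular-segment integrals.
A body is a set of staves whose widths must total 218 cm within a small
tolerance, including at least one stave wide enough (> 10 cm) to host the
bung hole.

The barrel OTR is the stave OTRs weighted by the printed area shares: the
body accounts for 74.77% of the barrel surface and each head for 12.61%.
Those shares (which sum to 99.99% as printed) and the 0.28 m² head-area
normalizer are taken verbatim rather than recomputed from the underlying
area assumptions; see docs/methods.md for the discussion of that choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InfeasibleLayoutError
from .staves import PART_BODY, Stave

MM2_PER_M2 = 1e6
_LENGTH_EPS = 1e-9  # slack for length >= required-length comparisons (mm)


@dataclass(frozen=True)
class BarrelSpec:
    """All geometry constants of the barrel model.

    Lengths and widths are millimetres; areas m²; area shares are fractions
    of the total barrel surface.
    """

    body_area_share: float = 0.7477
    head_area_share: float = 0.1261
    head_diameter: float = 597.0
    head_area_norm: float = 0.28
    body_total_width: float = 2180.0
    body_width_tolerance: float = 0.5
    bung_min_width: float = 100.0
    head_count_allowed: frozenset[int] = field(default_factory=lambda: frozenset({7, 9, 11}))

    def __post_init__(self):
        if abs(self.body_area_share + 2 * self.head_area_share - 1.0) > 1e-3:
            raise ValueError("body and head area shares must sum to 1 within 0.001")
        if any(k % 2 == 0 or k < 1 for k in self.head_count_allowed):
            raise ValueError("head_count_allowed must contain only positive odd integers")
        if self.head_diameter <= 0 or self.body_total_width <= 0:
            raise ValueError("head_diameter and body_total_width must be positive")
        if self.body_width_tolerance < 0:
            raise ValueError("body_width_tolerance must be non-negative")

    @property
    def head_radius(self) -> float:
        return self.head_diameter / 2.0

    @property
    def body_width_window(self) -> tuple[float, float]:
        """Inclusive (low, high) bounds on the summed body stave width, mm."""
        return (self.body_total_width - self.body_width_tolerance,
                self.body_total_width + self.body_width_tolerance)


DEFAULT_SPEC = BarrelSpec()


def _disc_antiderivative(x: float, r: float) -> float:
    """Antiderivative of the full chord 2*sqrt(r^2 - x^2): x*sqrt(r^2-x^2) + r^2*asin(x/r)."""
    u = min(1.0, max(-1.0, x / r))
    return x * math.sqrt(max(r * r - x * x, 0.0)) + r * r * math.asin(u)


def segment_area(a: float, b: float, radius: float) -> float:
    """In-circle area (mm²) of the vertical strip between x=a and x=b.

    a and b must already be clipped to [-radius, radius].
    """
    return _disc_antiderivative(b, radius) - _disc_antiderivative(a, radius)


def _required_length(a: float, b: float, r: float) -> float:
    """Longest chord covered by the (clipped) strip [a, b]: the required stave length."""
    if a <= 0.0 <= b:
        return 2.0 * r
    d = a if a > 0.0 else -b
    return 2.0 * math.sqrt(max(r * r - d * d, 0.0))


def _head_strips(widths: Sequence[float], spec: BarrelSpec):
    """Clipped interval, area (mm²) and required length per stave, or raise.

    The layout is centred: the midpoint of the total stave width sits on the
    circle centre, so any overhang beyond the disc splits equally between the
    two outermost staves and is clipped away.
    """
    r = spec.head_radius
    total = math.fsum(widths)
    if total < spec.head_diameter - _LENGTH_EPS:
        raise InfeasibleLayoutError(
            f"total stave width {total:.3f} mm is below the head diameter {spec.head_diameter} mm"
        )
    x = -total / 2.0
    strips = []
    for i, w in enumerate(widths):
        a, b = x, x + w
        x = b
        ca = -r if a < -r else a
        cb = r if b > r else b
        if cb - ca <= 1e-12:
            raise InfeasibleLayoutError(f"stave at position {i} lies entirely outside the head disc")
        strips.append((ca, cb, segment_area(ca, cb, r), _required_length(ca, cb, r)))
    return strips


def head_dims_feasible(widths: Sequence[float], lengths: Sequence[float], spec: BarrelSpec) -> tuple[bool, str | None]:
    """Fast feasibility check on raw head dimensions.

    Returns ``(ok, reason)``; *reason* names the first violated rule.
    """
    k = len(widths)
    if k not in spec.head_count_allowed:
        return False, f"stave count {k} not in allowed head counts {sorted(spec.head_count_allowed)}"
    r = spec.head_radius
    total = math.fsum(widths)
    if total < spec.head_diameter - _LENGTH_EPS:
        return False, f"total width {total:.3f} mm below head diameter {spec.head_diameter} mm"
    x = -total / 2.0
    for i in range(k):
        a = x
        b = x + widths[i]
        x = b
        if a < -r:
            a = -r
        if b > r:
            b = r
        if b - a <= 1e-12:
            return False, f"stave at position {i} lies entirely outside the head disc"
        if a <= 0.0 <= b:
            req = 2.0 * r
        else:
            d = a if a > 0.0 else -b
            req = 2.0 * math.sqrt(r * r - d * d)
        if lengths[i] < req - _LENGTH_EPS:
            return False, (
                f"stave at position {i} is too short: length {lengths[i]:.3f} mm "
                f"< required {req:.3f} mm"
            )
    return True, None


@dataclass
class HeadLayout:
    """Geometric layout of an ordered head: intervals, areas, required lengths.

    ``intervals`` are the clipped [a, b] bounds across the disc in mm
    (|x| <= radius); ``areas_m2`` are the in-circle areas 2·I_i of each stave
    in m²; ``required_lengths`` the minimum stave length (mm) at each position.
    """

    ids: list[str]
    intervals: list[tuple[float, float]]
    areas_m2: list[float]
    required_lengths: list[float]
    spec: BarrelSpec

    @property
    def total_area_m2(self) -> float:
        return math.fsum(self.areas_m2)


def layout_head(ordered_staves: Sequence[Stave], spec: BarrelSpec = DEFAULT_SPEC) -> HeadLayout:
    """Lay an ordered row of head staves over the disc, centred.

    Raises :class:`InfeasibleLayoutError` when the staves cannot cover the
    disc (total width below the diameter, or a stave clipped away entirely).
    """
    if not ordered_staves:
        raise InfeasibleLayoutError("a head needs at least one stave")
    strips = _head_strips([s.width for s in ordered_staves], spec)
    return HeadLayout(
        ids=[s.id for s in ordered_staves],
        intervals=[(a, b) for a, b, _, _ in strips],
        areas_m2=[area / MM2_PER_M2 for _, _, area, _ in strips],
        required_lengths=[req for _, _, _, req in strips],
        spec=spec,
    )


def head_feasible(ordered_staves: Sequence[Stave], spec: BarrelSpec = DEFAULT_SPEC) -> tuple[bool, str | None]:
    """Whether the ordered staves form a buildable head; reports the first violated rule."""
    return head_dims_feasible([s.width for s in ordered_staves], [s.length for s in ordered_staves], spec)


def body_feasible(staves: Sequence[Stave], spec: BarrelSpec = DEFAULT_SPEC) -> tuple[bool, str | None]:
    """Whether the staves form a buildable body.

    The summed width must fall in the body width window and at least one
    stave must be strictly wider than the bung minimum.
    """
    lo, hi = spec.body_width_window
    total = math.fsum(s.width for s in staves)
    if not (lo <= total <= hi):
        return False, f"total width {total:.3f} mm outside window [{lo}, {hi}] mm"
    if not any(s.width > spec.bung_min_width for s in staves):
        return False, f"no stave strictly wider than the bung minimum {spec.bung_min_width} mm"
    return True, None


def body_ratios(body: Sequence[Stave] | Sequence[float], spec: BarrelSpec = DEFAULT_SPEC) -> np.ndarray:
    """Per-stave area ratios of a body, as fractions of the total barrel area.

    ratio_i = body_area_share * w_i / sum(w); the ratios sum to the body
    area share (74.77% by default).
    """
    widths = np.asarray([s.width if isinstance(s, Stave) else float(s) for s in body], dtype=float)
    if widths.size == 0:
        raise ValueError("body has no staves")
    return spec.body_area_share * widths / widths.sum()


def head_ratios(layout: HeadLayout, spec: BarrelSpec | None = None) -> np.ndarray:
    """Per-stave area ratios of a head: head_area_share * (2·I_i) / head_area_norm.

    Note: the ratios of a full head sum to head_area_share * πR² / 0.28,
    which is ≈ 12.607% rather than exactly 12.61%, because the printed
    0.28 m² normalizer slightly exceeds the disc area π·(0.2985 m)².
    """
    spec = spec or layout.spec
    return spec.head_area_share * np.asarray(layout.areas_m2) / spec.head_area_norm


def body_element_otr(widths: Sequence[float], otrs: Sequence[float]) -> float:
    """Width-weighted mean OTR of a body, on the stave scale (hPa/h)."""
    wsum = math.fsum(widths)
    return math.fsum(w * o for w, o in zip(widths, otrs)) / wsum


def head_element_otr(widths: Sequence[float], otrs: Sequence[float], spec: BarrelSpec = DEFAULT_SPEC) -> float:
    """In-circle-area-weighted mean OTR of an ordered head, on the stave scale (hPa/h)."""
    strips = _head_strips(widths, spec)
    asum = math.fsum(s[2] for s in strips)
    return math.fsum(s[2] * o for s, o in zip(strips, otrs)) / asum


def element_otr(staves: Sequence[Stave], spec: BarrelSpec = DEFAULT_SPEC) -> float:
    """Area-weighted mean OTR of a head or body element, on the stave scale.

    Weights are normalized within the element (widths for a body, in-circle
    areas for a head), so a perfectly homogeneous element matches a target
    defined as a stave-level mean OTR. The barrel-level combination of
    elements applies the printed area shares separately via
    :func:`barrel_otr`.
    """
    if not staves:
        raise ValueError("element has no staves")
    parts = {s.part for s in staves}
    if len(parts) != 1:
        raise ValueError(f"element mixes parts {sorted(parts)}")
    otrs = [s.otr for s in staves]
    if parts == {PART_BODY}:
        return body_element_otr([s.width for s in staves], otrs)
    return head_element_otr([s.width for s in staves], otrs, spec)


def barrel_otr(body_otr: float, head1_otr: float, head2_otr: float, spec: BarrelSpec = DEFAULT_SPEC) -> float:
    """Whole-barrel OTR from the element OTRs via the printed area shares.

    body_area_share·body + head_area_share·(head1 + head2). With the printed
    shares the coefficients sum to 0.9999, so three identical elements of
    OTR c give 0.9999·c, reproducing the published arithmetic.
    """
    return (spec.body_area_share * body_otr + spec.head_area_share * (head1_otr + head2_otr))
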