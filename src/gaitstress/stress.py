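"""Beam-mechanics bone stress analysis.

Limb long bones are treated as irregular beams loaded at mid-shaft.  The normal
stress at a point (x, y) of the cross-section is the sum of the uniform
compressive/tensile term and the asymmetric-bending term

    sigma = F/A + [(Mx*Iy + My*Ixy) * y - (My*Ix + Mx*Ixy) * x] / (Ix*Iy - Ixy^2)

with F the longitudinal force (tension positive), Mx and My the bending moments
about the centroidal section axes, and Ix, Iy, Ixy the second and product
moments of area.  Shear stress is deliberately ignored: bending and axial
compression dominate mid-shaft long-bone loading.

Cross-sections are described by a closed outer outline; hollow (tubular)
sections are built by offsetting the outline inward by the cortical wall
thickness, expressed as a fraction of the mean external radius.

Peak stress traces produced during simulation are low-pass filtered with a
causal 2nd-order Butterworth filter (5 Hz default) before being tested against
the stress limit, compensating for the absence of soft-tissue cushioning in a
rigid-body model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from shapely.geometry import Polygon as _ShapelyPolygon

from .geometry import ensure_ccw, is_simple, polygon_moments, regular_polygon


@dataclass(eq=False)
class SectionProperties:
    """Geometric properties of a (possibly hollow) beam cross-section.

    All moments are about axes through the area centroid; boundary vertex
    coordinates are stored centroid-relative.
    """

    area: float
    ix: float
    iy: float
    ixy: float
    centroid: np.ndarray
    outer_boundary: np.ndarray
    inner_boundary: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("section area must be positive")
        if self.ix <= 0 or self.iy <= 0:
            raise ValueError("second moments must be positive")
        if self.ix * self.iy - self.ixy**2 <= 0:
            raise ValueError("Ix*Iy - Ixy^2 must be positive")


@dataclass
class LoadState:
    """Mid-shaft load: longitudinal force (tension positive) and bending moments."""

    axial_force: float = 0.0  # N, tension positive
    moment_x: float = 0.0  # N m, about the section x-axis
    moment_y: float = 0.0  # N m, about the section y-axis


def polygon_section_properties(boundary) -> SectionProperties:
    """Exact section properties (A, centroid, Ix, Iy, Ixy) of a solid polygon."""
    v = ensure_ccw(boundary)
    a, c, ix, iy, ixy = polygon_moments(v)
    return SectionProperties(
        area=a, ix=ix, iy=iy, ixy=ixy, centroid=c, outer_boundary=v - c
    )


def _composite_properties(outer: np.ndarray, inner: np.ndarray) -> SectionProperties:
    """Properties of outer polygon minus inner polygon (hole)."""
    ao, co, ixo, iyo, ixyo = polygon_moments(outer)
    ai, ci, ixi, iyi, ixyi = polygon_moments(inner)
    a = ao - ai
    if a <= 0:
        raise ValueError("inner boundary swallows the section")
    c = (ao * co - ai * ci) / a
    # move each part's centroidal moments to the composite centroid
    do, di = co - c, ci - c
    ix = (ixo + ao * do[1] ** 2) - (ixi + ai * di[1] ** 2)
    iy = (iyo + ao * do[0] ** 2) - (iyi + ai * di[0] ** 2)
    ixy = (ixyo + ao * do[0] * do[1]) - (ixyi + ai * di[0] * di[1])
    return SectionProperties(
        area=a,
        ix=ix,
        iy=iy,
        ixy=ixy,
        centroid=c,
        outer_boundary=outer - c,
        inner_boundary=inner - c,
    )


def hollow_section_from_outline(
    outline, cortical_fraction: float, min_vertices: int = 128
) -> SectionProperties:
    """Build a hollow-bone section from an external outline and wall fraction.

    The cortical wall thickness is ``cortical_fraction`` times the mean external
    radius (mean distance of the outer boundary from its centroid).  The inner
    (endosteal) boundary is the outer boundary offset inward by that thickness;
    a fraction of 1 yields a solid section.  The outer boundary is densified to
    at least ``min_vertices`` vertices so that boundary peak-stress searches
    resolve the extreme fibre.
    """
    if not 0.0 < cortical_fraction <= 1.0:
        raise ValueError("cortical_fraction must be in (0, 1]")
    outer = ensure_ccw(outline)
    if not is_simple(outer):
        raise ValueError("outline is self-intersecting")
    outer = _densify(outer, min_vertices)
    _, c, *_ = polygon_moments(outer)
    mean_radius = float(np.mean(np.hypot(*(outer - c).T)))
    if cortical_fraction >= 1.0:
        return polygon_section_properties(outer)
    t = cortical_fraction * mean_radius
    inner_poly = _ShapelyPolygon(outer).buffer(-t, quad_segs=16)
    if inner_poly.is_empty or inner_poly.area <= 0:
        # wall thickness consumed the whole interior: effectively solid
        return polygon_section_properties(outer)
    if inner_poly.geom_type == "MultiPolygon":  # keep the dominant lobe
        inner_poly = max(inner_poly.geoms, key=lambda g: g.area)
    inner = ensure_ccw(np.asarray(inner_poly.exterior.coords)[:-1])
    return _composite_properties(outer, inner)


def circular_section(
    radius: float, cortical_fraction: float = 1.0, n: int = 256
) -> SectionProperties:
    """Convenience constructor: hollow circular section from an n-gon outline."""
    return hollow_section_from_outline(
        regular_polygon(n, radius), cortical_fraction, min_vertices=n
    )


def _densify(v: np.ndarray, min_vertices: int) -> np.ndarray:
    if len(v) >= min_vertices:
        return v
    per_edge = int(np.ceil(min_vertices / len(v)))
    out = []
    for i in range(len(v)):
        a, b = v[i], v[(i + 1) % len(v)]
        ts = np.linspace(0.0, 1.0, per_edge, endpoint=False)
        out.append(a + ts[:, None] * (b - a))
    return np.vstack(out)


def compressive_stress(load: LoadState, section: SectionProperties) -> float:
    """Uniform normal stress F/A (Pa, tension positive)."""
    return load.axial_force / section.area


def bending_stress(load: LoadState, section: SectionProperties, point) -> float:
    """Normal bending stress (Pa) at centroid-relative point (x, y).

    Valid for arbitrary asymmetric sections via the product moment of area.
    """
    d = section.ix * section.iy - section.ixy**2
    if d <= 0:
        raise ValueError("singular section (Ix*Iy - Ixy^2 <= 0)")
    x, y = np.asarray(point, dtype=float).T
    mx, my = load.moment_x, load.moment_y
    return (
        (mx * section.iy + my * section.ixy) / d * y
        - (my * section.ix + mx * section.ixy) / d * x
    )


def peak_boundary_stress(
    load: LoadState, section: SectionProperties
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Extremes of axial + bending stress over the outer boundary vertices.

    Returns ``(sigma_max, sigma_min, point_max, point_min)``.  For a combined
    axial + bending field the extreme fibre lies on the outer boundary, so
    vertex evaluation suffices once the boundary is densified.
    """
    sig = compressive_stress(load, section) + bending_stress(
        load, section, section.outer_boundary
    )
    imax, imin = int(np.argmax(sig)), int(np.argmin(sig))
    return (
        float(sig[imax]),
        float(sig[imin]),
        section.outer_boundary[imax],
        section.outer_boundary[imin],
    )


# ---------------------------------------------------------------------------
# filtering and the hard stress-fail monitor
# ---------------------------------------------------------------------------


def butterworth_sos(sample_rate: float, cutoff: float = 5.0, order: int = 2):
    if cutoff >= 0.5 * sample_rate:
        raise ValueError("cutoff must be below the Nyquist frequency")
    return signal.butter(order, cutoff, btype="low", fs=sample_rate, output="sos")


def butterworth_lowpass(
    series,
    sample_rate: float,
    cutoff: float = 5.0,
    order: int = 2,
    zero_phase: bool = False,
) -> np.ndarray:
    """Low-pass Butterworth filter of a uniformly sampled series.

    The default is causal (as used online in the simulator's fail test) with
    the filter state initialised to the first sample so a constant series
    passes through unchanged.  ``zero_phase=True`` gives forward-backward
    filtering for post-hoc analysis.
    """
    x = np.asarray(series, dtype=float)
    sos = butterworth_sos(sample_rate, cutoff, order)
    if zero_phase:
        return signal.sosfiltfilt(sos, x)
    zi = signal.sosfilt_zi(sos) * x[0]
    y, _ = signal.sosfilt(sos, x, zi=zi)
    return y


class StreamingLowpass:
    """Causal Butterworth filter applied sample by sample (online monitoring).

    Accepts scalars or vectors (one independent channel per element).  The
    biquad cascade is evaluated directly (transposed direct form II), with the
    state initialised on the first sample so a constant input passes through
    unchanged from the start.
    """

    def __init__(self, sample_rate: float, cutoff: float = 5.0, order: int = 2):
        self.sos = butterworth_sos(sample_rate, cutoff, order)
        self._zi_unit = signal.sosfilt_zi(self.sos)  # steady state for unit input
        self._z = None

    def __call__(self, x):
        arr = np.asarray(x, dtype=float)
        scalar = arr.ndim == 0
        v = arr.reshape(-1)
        if self._z is None:
            self._z = self._zi_unit[:, :, None] * v[None, None, :]
        y = v
        for k, (b0, b1, b2, _, a1, a2) in enumerate(self.sos):
            z1, z2 = self._z[k]
            out = b0 * y + z1
            self._z[k, 0] = b1 * y - a1 * out + z2
            self._z[k, 1] = b2 * y - a2 * out
            y = out
        return float(y[0]) if scalar else y


@dataclass(eq=False)
class StressTrace:
    """Raw and filtered peak-stress series for one monitored bone."""

    name: str
    time: np.ndarray
    raw_max: np.ndarray
    raw_min: np.ndarray
    filtered_max: np.ndarray
    filtered_min: np.ndarray
    limit: float = np.inf

    @property
    def peak_magnitude(self) -> np.ndarray:
        return np.maximum(np.abs(self.filtered_max), np.abs(self.filtered_min))


@dataclass
class StressFailure:
    bone: str
    time: float
    stress: float


def stress_fail_monitor(
    traces: list[StressTrace], limit: float
) -> StressFailure | None:
    """First instant at which any bone's filtered peak |stress| exceeds the limit.

    Returns None if every trace stays below the limit (pass).
    """
    first: StressFailure | None = None
    for tr in traces:
        mag = tr.peak_magnitude
        over = np.nonzero(mag > limit)[0]
        if len(over):
            i = int(over[0])
            cand = StressFailure(tr.name, float(tr.time[i]), float(mag[i]))
            if first is None or cand.time < first.time:
                first = cand
    return first
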