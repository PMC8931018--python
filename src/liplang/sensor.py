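"""Parametric simulator of a contact-separation triboelectric sensor.

The sensor is two dielectric layers (PVC / nylon) on copper electrodes kept
apart by a sponge spacer.  One mouth open-close event presses and releases the
stack, driving charge back and forth between the electrodes: a positive
current/voltage lobe while pressing, a negative lobe while releasing, and zero
transfer at the fully-closed and fully-open turning points.

The simulator is calibrated against the reported characterisation of a square
sensor of side ``D`` (mm) and thickness ``T`` (mm) driven at force ``F`` (N)
and frequency ``f`` (Hz):

* force sensitivity of the open-circuit voltage: 0.376 V/N above 1 N;
* open-circuit voltage flat across 1-5 Hz;
* short-circuit current 1.88 nA at 1 Hz rising to 9.66 nA at 5 Hz (5 N);
* a 2.8x voltage gain and 2.9x current gain from D = 20 mm to D = 50 mm;
* thickness response saturating at T = 2 mm;
* matched-load power 3.50 nW at an external resistance of 97.1 MOhm;
* amplitude decay to 1.38/1.40 of the initial value after 2000 press cycles.

One-axis-at-a-time characterisation composes multiplicatively relative to the
reference condition (20 x 20 x 5 mm sensor, 5 N, 1 Hz).  Note the reported
series are not mutually consistent in absolute volts (the stated 0.376 V/N
slope over 1-5 N spans more than the reported 5 N values of other series), so
the force/frequency series anchors the absolute scale and the area and
thickness series contribute relative factors only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .waveform import Waveform


class CombinationMode(str, Enum):
    SINGLE = "single"
    SERIES = "series"
    PARALLEL = "parallel"


class RangeError(ValueError):
    """Query outside the calibrated range without extrapolation enabled."""


class AliasingError(ValueError):
    """Sampling rate too low for the requested pressing frequency."""


class ShapeError(ValueError):
    """Mismatched waveform shapes for combination."""


@dataclass
class SensorSpec:
    """Square sensor geometry: side length ``D`` and thickness ``T`` in mm."""

    side_length_mm: float = 20.0
    thickness_mm: float = 5.0
    n_units: int = 1
    combination: CombinationMode = CombinationMode.SINGLE

    def __post_init__(self) -> None:
        if not (10.0 <= self.side_length_mm <= 100.0):
            raise ValueError("side length must be within [10, 100] mm")
        if not (0.5 <= self.thickness_mm <= 10.0):
            raise ValueError("thickness must be within [0.5, 10] mm")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        self.combination = CombinationMode(self.combination)


@dataclass
class Excitation:
    """Mechanical drive: pressing force (N) and frequency (Hz)."""

    force_n: float = 5.0
    frequency_hz: float = 1.0
    n_cycles: int = 3
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        if self.force_n < 0:
            raise ValueError("force must be >= 0")
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be > 0")
        if self.sampling_rate < 20 * self.frequency_hz:
            raise AliasingError("sampling rate must be >= 20x the pressing frequency")


def _interp_monotone(anchors: dict, x: float, extrapolate: bool) -> float:
    """Piecewise-linear interpolation through sorted anchors; clamp outside."""
    xs = np.array(sorted(anchors))
    ys = np.array([anchors[k] for k in xs])
    if not extrapolate and (x < xs[0] - 1e-12 or x > xs[-1] + 1e-12):
        raise RangeError(f"{x} outside calibrated range [{xs[0]}, {xs[-1]}]")
    return float(np.interp(x, xs, ys))


@dataclass
class CalibrationTable:
    """Anchor points from the reported characterisation series.

    ``force_anchors_v`` carry the absolute voltage scale of the reference
    sensor (slope 0.376 V/N through the origin, linear below 1 N by design);
    the frequency, area and thickness series are stored as reported but used
    as ratios relative to the reference condition.
    """

    #: V_oc (V) vs force (N) at 1 Hz, 20x20x5 mm. Slope 0.376 V/N.
    force_anchors_v: dict = field(default_factory=lambda: {
        0.0: 0.0, 1.0: 0.376, 2.0: 0.752, 3.0: 1.128, 4.0: 1.504, 5.0: 1.880})
    #: V_oc frequency factor (dimensionless) at 5 N: flat across 1-5 Hz.
    freq_factor_v: dict = field(default_factory=lambda: {
        1.0: 1.0, 2.0: 1.0, 3.0: 1.0, 4.0: 1.0, 5.0: 1.0})
    #: I_sc (nA) vs frequency (Hz) at 5 N, 20x20x5 mm.
    freq_anchors_na: dict = field(default_factory=lambda: {
        1.0: 1.88, 2.0: 3.825, 3.0: 5.77, 4.0: 7.715, 5.0: 9.66})
    #: V_oc (V) vs side length (mm) at 5 N, 1 Hz, T=2 mm (ratio use only).
    area_anchors_v: dict = field(default_factory=lambda: {20.0: 1.10, 50.0: 3.08})
    #: I_sc (nA) vs side length (mm), same conditions (ratio use only).
    area_anchors_na: dict = field(default_factory=lambda: {20.0: 1.52, 50.0: 4.39})
    #: thickness factor, saturating at 2 mm (fully saturated above).
    thickness_factor: dict = field(default_factory=lambda: {
        0.5: 0.55, 1.0: 0.80, 2.0: 1.0, 5.0: 1.0, 10.0: 1.0})
    #: durability endpoints: peak voltage at cycle 0 and cycle 2000.
    durability_v: dict = field(default_factory=lambda: {0: 1.40, 2000: 1.38})

    REF_SIDE_MM = 20.0
    REF_THICKNESS_MM = 5.0
    REF_FORCE_N = 5.0
    REF_FREQ_HZ = 1.0

    def __post_init__(self) -> None:
        for name in ("freq_anchors_na", "area_anchors_v", "area_anchors_na",
                     "thickness_factor", "durability_v"):
            if any(v <= 0 for v in getattr(self, name).values()):
                raise ValueError(f"{name} anchors must be strictly positive")


class LoadCircuit:
    """Thevenin model of the sensor driving an external resistance."""

    def __init__(self, r_internal_ohm: float = 97.1e6,
                 v_source_peak: float | None = None,
                 p_max_w: float = 3.50e-9):
        if r_internal_ohm <= 0:
            raise ValueError("internal resistance must be > 0")
        self.r_internal_ohm = r_internal_ohm
        if v_source_peak is None:
            # choose the source amplitude reproducing the stated matched-load
            # power: P_max = V^2 / (4 R_int)
            v_source_peak = float(np.sqrt(4.0 * r_internal_ohm * p_max_w))
        if v_source_peak <= 0:
            raise ValueError("source peak must be > 0")
        self.v_source_peak = v_source_peak


# ---------------------------------------------------------------------------
# operations

def cycle_shape(phase) -> np.ndarray | float:
    """Unit-amplitude biphasic template for one press-release cycle.

    Raised-cosine lobes: positive during pressing (first half of the cycle),
    mirrored negative during releasing.  Zero with zero slope at the stage
    boundaries (mouth fully closed / fully open), and zero net area over a
    full cycle, as required by charge conservation.
    """
    p = np.asarray(phase, dtype=float)
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("phase must lie in [0, 1)")
    lobe = 0.5 * (1.0 - np.cos(4.0 * np.pi * p))
    out = np.where(p < 0.5, lobe, -lobe)
    return float(out) if np.isscalar(phase) else out


def _force_factor(cal: CalibrationTable, force_n: float, extrapolate: bool) -> float:
    v = _interp_monotone(cal.force_anchors_v, force_n, extrapolate)
    return v / cal.force_anchors_v[cal.REF_FORCE_N]


def _geometry_factors(cal: CalibrationTable, spec: SensorSpec,
                      anchors_area: dict, extrapolate: bool) -> float:
    g_area = (_interp_monotone(anchors_area, spec.side_length_mm, extrapolate)
              / anchors_area[cal.REF_SIDE_MM])
    g_thick = (_interp_monotone(cal.thickness_factor, spec.thickness_mm, extrapolate)
               / cal.thickness_factor[cal.REF_THICKNESS_MM])
    return g_area * g_thick


def peak_voltage(spec: SensorSpec, exc: Excitation,
                 cal: CalibrationTable | None = None,
                 extrapolate: bool = False) -> float:
    """Peak open-circuit voltage (V) for a single sensor unit."""
    cal = cal or CalibrationTable()
    if exc.force_n == 0:
        return 0.0
    v_ref = _interp_monotone(cal.force_anchors_v, exc.force_n, extrapolate)
    g_f = _interp_monotone(cal.freq_factor_v, exc.frequency_hz, extrapolate)
    g_geom = _geometry_factors(cal, spec, cal.area_anchors_v, extrapolate)
    return v_ref * g_f * g_geom


def peak_current(spec: SensorSpec, exc: Excitation,
                 cal: CalibrationTable | None = None,
                 extrapolate: bool = False) -> float:
    """Peak short-circuit current (nA) for a single sensor unit."""
    cal = cal or CalibrationTable()
    if exc.force_n == 0:
        return 0.0
    i_ref = _interp_monotone(cal.freq_anchors_na, exc.frequency_hz, extrapolate)
    g_force = _force_factor(cal, exc.force_n, extrapolate)
    g_geom = _geometry_factors(cal, spec, cal.area_anchors_na, extrapolate)
    return i_ref * g_force * g_geom


def simulate_waveform(spec: SensorSpec, exc: Excitation,
                      cal: CalibrationTable | None = None,
                      kind: str = "voc", extrapolate: bool = False) -> Waveform:
    """Simulate ``n_cycles`` press-release cycles of V_oc or I_sc.

    Deterministic: the waveform is ``peak * cycle_shape(phase)`` on a uniform
    grid, so identical inputs give bit-identical output.
    """
    cal = cal or CalibrationTable()
    if kind not in ("voc", "isc"):
        raise ValueError("kind must be 'voc' or 'isc'")
    if exc.sampling_rate < 20 * exc.frequency_hz:
        raise AliasingError("sampling rate must be >= 20x the pressing frequency")
    peak = (peak_voltage if kind == "voc" else peak_current)(spec, exc, cal, extrapolate)
    n = int(round(exc.n_cycles * exc.sampling_rate / exc.frequency_hz))
    t = np.arange(n) / exc.sampling_rate
    phase = np.mod(t * exc.frequency_hz, 1.0)
    samples = peak * cycle_shape(phase)
    units = "V" if kind == "voc" else "nA"
    meta = {"side_length_mm": spec.side_length_mm, "thickness_mm": spec.thickness_mm,
            "force_n": exc.force_n, "frequency_hz": exc.frequency_hz,
            "n_cycles": exc.n_cycles}
    return Waveform(samples=samples, rate=exc.sampling_rate, kind=kind,
                    units=units, meta=meta)


def combine_sensors(waveforms: list, mode: str = "series") -> Waveform:
    """Ideal superposition of identical-condition units.

    Series connection adds voltages (the series stack behaves as one larger
    contact area); parallel connection adds currents.  In the non-additive
    direction identical ideal sources simply coexist, so the amplitude equals
    the single-unit amplitude (implemented as the elementwise mean).
    """
    mode = CombinationMode(mode)
    if not waveforms:
        raise ValueError("need at least one waveform")
    w0 = waveforms[0]
    for w in waveforms[1:]:
        if w.rate != w0.rate or len(w) != len(w0):
            raise ShapeError("waveforms must share sampling rate and length")
        if w.kind != w0.kind:
            raise ShapeError("cannot combine voc with isc waveforms")
    stack = np.stack([w.samples for w in waveforms])
    adds = (mode is CombinationMode.SERIES) == (w0.kind == "voc")
    samples = stack.sum(axis=0) if adds else stack.mean(axis=0)
    return w0.copy(samples=samples,
                   meta={**w0.meta, "combination": mode.value, "n_units": len(waveforms)})


def load_sweep(circ: LoadCircuit, r_values) -> tuple[np.ndarray, np.ndarray]:
    """Power and voltage across a sweep of external load resistances.

    Returns ``(power_w, voltage_v)`` arrays for the Thevenin model:
    ``V(R) = Vp R/(R+Ri)`` and ``P(R) = Vp^2 R/(R+Ri)^2``, whose power peaks
    exactly at the matched load ``R = Ri``.
    """
    r = np.asarray(r_values, dtype=float)
    if np.any(r <= 0):
        raise ValueError("load resistances must be > 0")
    v = circ.v_source_peak * r / (r + circ.r_internal_ohm)
    p = circ.v_source_peak ** 2 * r / (r + circ.r_internal_ohm) ** 2
    return p, v


def durability_decay(cycle_index: int, cal: CalibrationTable | None = None) -> float:
    """Amplitude scale factor after ``cycle_index`` press cycles.

    Linear decay between the measured endpoints (1.0 at cycle 0 down to
    1.38/1.40 at cycle 2000), clamped beyond the tested range.
    """
    cal = cal or CalibrationTable()
    if cycle_index < 0:
        raise ValueError("cycle index must be >= 0")
    cycles = sorted(cal.durability_v)
    c0, c1 = cycles[0], cycles[-1]
    end_scale = cal.durability_v[c1] / cal.durability_v[c0]
    frac = min(max((cycle_index - c0) / (c1 - c0), 0.0), 1.0)
    return 1.0 + frac * (end_scale - 1.0)
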