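"""Forward simulation of an automatic tube current modulation (ATCM) system.

The scanner is modelled with the same lookahead-window response class that
the fitting module estimates: at each table position z the simulator takes
the WED profile samples starting at z and extending ``lookahead_mm`` towards
the scanning direction, summarizes them with a convex combination of order
statistics

    f(z) = w1*max + w2*Q3 + w3*median + w4*min     (w >= 0, sum w = 1)

and sets the effective mAs exponentially in f relative to a reference size:

    eff_mAs(z) = reference_mas * exp(strength * beta * (f(z) - wed_ref))

clamped to the tube-current limits, with CTDIvol = k_dose * eff_mAs. A real
scanner's algorithm is proprietary; this generator deliberately realises the
model class so that the downstream fit can be validated by exact parameter
recovery, while reproducing the qualitative behaviours seen on hardware:
direction-dependent curves, mirror-image asymmetry on symmetric phantoms,
pitch-dependent lookahead depth, and under-compensated noise (strength < 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .phantoms import PhantomSpec, rasterize_slice
from .wed import WEDProfile

DIRECTIONS = ("HF", "FH")
#: Convex window weights (max, Q3, median, min) used by default; all four
#: non-zero, as the fitted scanner behaviour requires.
DEFAULT_WEIGHTS = (0.40, 0.25, 0.20, 0.15)
#: Effective lookahead window length (mm) per helical pitch, as deduced from
#: grid-search fits on scanner data: the window grows with pitch.
LOOKAHEAD_BY_PITCH = {0.6: 32.0, 0.8: 40.0, 1.0: 50.0, 1.2: 52.0}


def default_lookahead_mm(pitch: float) -> float:
    """Lookahead window length for a pitch, interpolating the known points."""
    pitches = np.array(sorted(LOOKAHEAD_BY_PITCH))
    windows = np.array([LOOKAHEAD_BY_PITCH[p] for p in pitches])
    return float(np.interp(pitch, pitches, windows))


@dataclass(frozen=True)
class Protocol:
    """Acquisition protocol settings and ATCM response parameters.

    ``modulation_strength`` in [0, 1] is the exponent applied to the ideal
    (noise-constant) size compensation: 1 compensates fully, smaller values
    under-compensate as clinical systems do. ``k_dose`` converts effective
    mAs to CTDIvol (mGy per effective mAs at the set kVp); ``wed_ref`` is
    the water-equivalent size (mm) at which the effective mAs equals
    ``reference_mas`` and ``beta`` (1/mm) sets the exponential size scaling.
    """

    name: str
    reference_mas: float
    rotation_time: float = 0.5
    collimation_rows: int = 64
    row_width: float = 0.6
    pitch: float = 0.8
    recon_thickness: float = 2.0
    kvp: float = 120.0
    mode: str = "helical"
    min_ma: float = 10.0
    max_ma: float = 650.0
    modulation_strength: float = 0.7
    k_dose: float = 0.075
    wed_ref: float = 300.0
    beta: float = 0.012

    def __post_init__(self) -> None:
        if self.reference_mas <= 0 or self.rotation_time <= 0:
            raise ValueError("reference_mas and rotation_time must be"
                             " positive")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if not 0 <= self.min_ma <= self.max_ma:
            raise ValueError("need 0 <= min_ma <= max_ma")
        if self.recon_thickness <= 0:
            raise ValueError("recon_thickness must be positive")
        if not 0 <= self.modulation_strength <= 1:
            raise ValueError("modulation_strength must lie in [0, 1]")
        if self.mode not in ("helical", "axial"):
            raise ValueError("mode must be 'helical' or 'axial'")

    @property
    def beam_width(self) -> float:
        """Total collimated beam width (mm) = rows x row width."""
        return self.collimation_rows * self.row_width


THORAX_PLAIN = Protocol("Thorax Plain", reference_mas=66.0, pitch=0.8)
ABDOMEN = Protocol("Abdomen", reference_mas=210.0, pitch=0.8)
ABD_SEQ = Protocol("AbdSeq", reference_mas=210.0, pitch=0.9, mode="axial")
PROTOCOLS = {"thorax": THORAX_PLAIN, "abdomen": ABDOMEN, "abdseq": ABD_SEQ}


@dataclass(frozen=True)
class ModulationCurve:
    """Ordered per-slice (table position, CTDIvol, mA) series in scan order.

    Table positions run with the Head at positive values, so they decrease
    along a head-to-feet (HF) scan and increase along feet-to-head (FH).
    ``f_window`` keeps the generator's window statistic per slice when the
    curve was simulated (used for noise rendering and diagnostics).
    """

    z: np.ndarray
    ctdi_vol: np.ndarray
    ma: np.ndarray
    direction: str
    protocol: Protocol
    phantom_name: str = ""
    f_window: np.ndarray | None = None
    lookahead_mm: float | None = None
    weights: tuple[float, ...] | None = None
    table_offset: float | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        c = np.asarray(self.ctdi_vol, dtype=float)
        m = np.asarray(self.ma, dtype=float)
        if not (z.shape == c.shape == m.shape) or z.ndim != 1 or z.size == 0:
            raise ValueError("z, ctdi_vol and ma must be matching 1-D arrays")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if (c < 0).any():
            raise ValueError("ctdi_vol must be non-negative")
        dz = np.diff(z)
        if z.size > 1:
            ok = np.all(dz < 0) if self.direction == "HF" else np.all(dz > 0)
            if not ok:
                raise ValueError("table positions must be monotone along the"
                                 " scanning direction")
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "ctdi_vol", c)
        object.__setattr__(self, "ma", m)

    def __len__(self) -> int:
        return self.z.size

    @property
    def scan_length_mm(self) -> float:
        return len(self) * self.protocol.recon_thickness


@dataclass(frozen=True)
class SliceRecord:
    """One reconstructed slice with its acquisition metadata."""

    table_position: float
    image: np.ndarray
    ma: float
    exposure_time: float          # ms
    ctdi_vol: float | None
    recon_thickness: float
    pixel_size: float
    instance_number: int | None = None

    def __post_init__(self) -> None:
        if self.ctdi_vol is not None and self.ctdi_vol < 0:
            raise ValueError("ctdi_vol must be non-negative")


def window_stat_matrix(wed_scan_order: np.ndarray, d: int) -> np.ndarray:
    """(n, 4) matrix of (max, Q3, median, min) over the lookahead window.

    Row i summarizes the ``d`` samples starting at slice i towards the
    scanning direction (the current slice plus d-1 ahead); positions beyond
    the end of the series are padded with air (WED = 0). Quartiles use
    linear interpolation between order statistics.
    """
    if d < 1:
        raise ValueError("window depth d must be at least 1")
    w = np.asarray(wed_scan_order, dtype=float)
    n = w.size
    padded = np.concatenate([w, np.zeros(d - 1)]) if d > 1 else w
    win = sliding_window_view(padded, d)[:n]
    return np.column_stack([
        win.max(axis=1),
        np.quantile(win, 0.75, axis=1),
        np.median(win, axis=1),
        win.min(axis=1),
    ])


def lookahead_stats(t: np.ndarray, profile: WEDProfile, d: int,
                    direction: str, slice_spacing: float) -> np.ndarray:
    """Window order statistics for slices at table positions ``t`` (scan
    order), reading the profile beyond the last slice so a scan that stops
    inside the phantom still sees the true attenuation ahead; only
    positions beyond the profile itself count as air."""
    t = np.asarray(t, dtype=float)
    if t.size > 1:
        step = t[1] - t[0]
    else:
        step = -slice_spacing if direction == "HF" else slice_spacing
    ext = t[-1] + step * np.arange(1, d)
    wed = profile.interp(np.concatenate([t, ext]))
    return window_stat_matrix(wed, d)[:t.size]


def _check_weights(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (4,):
        raise ValueError("need exactly four window weights")
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    return w


def planned_positions(profile: WEDProfile, protocol: Protocol,
                      direction: str, scan_margin_mm: float = 40.0
                      ) -> np.ndarray:
    """Slice table positions in scan order, covering the phantom extent plus
    ``scan_margin_mm`` of air at both ends."""
    lo, hi = profile.support()
    lo -= scan_margin_mm
    hi += scan_margin_mm
    n = max(int(round((hi - lo) / protocol.recon_thickness)), 1)
    t = lo + protocol.recon_thickness * np.arange(n + 1)
    return t[::-1] if direction == "HF" else t


def _dose_response(f: np.ndarray, protocol: Protocol
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(ctdi_vol, ma) for window statistic f, with tube-current clamping."""
    expo = protocol.modulation_strength * protocol.beta * (f - protocol.wed_ref)
    eff = protocol.reference_mas * np.exp(np.clip(expo, -50.0, 50.0))
    lo = protocol.min_ma * protocol.rotation_time / protocol.pitch
    hi = protocol.max_ma * protocol.rotation_time / protocol.pitch
    eff = np.clip(eff, lo, hi)
    ma = eff * protocol.pitch / protocol.rotation_time
    return protocol.k_dose * eff, ma


def simulate_modulation(profile: WEDProfile, protocol: Protocol,
                        direction: str = "HF",
                        lookahead_mm: float | None = None,
                        weights=DEFAULT_WEIGHTS, seed: int = 0,
                        scan_margin_mm: float = 40.0,
                        angular_jitter: float = 0.0,
                        table_positions: np.ndarray | None = None
                        ) -> ModulationCurve:
    """Simulate a helical acquisition's per-slice CTDIvol/mA series.

    ``profile`` must be in table coordinates (Head positive). The lookahead
    window defaults to the pitch-dependent length; ``seed`` only drives the
    optional per-slice angular-modulation jitter (off by default), so the
    default output is fully deterministic.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if len(profile) == 0:
        raise ValueError("empty WED profile")
    w = _check_weights(weights)
    if lookahead_mm is None:
        lookahead_mm = default_lookahead_mm(protocol.pitch)
    if lookahead_mm <= 0:
        raise ValueError("lookahead_mm must be positive")
    d = max(int(round(lookahead_mm / protocol.recon_thickness)), 1)
    if table_positions is None:
        t = planned_positions(profile, protocol, direction, scan_margin_mm)
    else:
        t = np.asarray(table_positions, dtype=float)
    f = lookahead_stats(t, profile, d, direction,
                        protocol.recon_thickness) @ w
    if angular_jitter > 0:
        rng = np.random.default_rng(seed)
        f = f * (1.0 + angular_jitter * rng.standard_normal(f.size))
    ctdi, ma = _dose_response(f, protocol)
    return ModulationCurve(z=t, ctdi_vol=ctdi, ma=ma, direction=direction,
                           protocol=protocol, phantom_name=profile.label,
                           f_window=f, lookahead_mm=float(lookahead_mm),
                           weights=tuple(w))


def simulate_axial(profile: WEDProfile, protocol: Protocol,
                   direction: str = "HF",
                   lookahead_mm: float | None = None,
                   weights=DEFAULT_WEIGHTS, step_mm: float | None = None,
                   seed: int = 0, scan_margin_mm: float = 40.0,
                   table_positions: np.ndarray | None = None
                   ) -> ModulationCurve:
    """Simulate a sequential (axial) acquisition.

    The tube current is selected once per table step (default step: beam
    width x pitch) from the lookahead window at the step's leading slice, so
    the CTDIvol curve is piecewise constant with step edges preceding the
    WED ramps in the scanning direction.
    """
    if step_mm is None:
        step_mm = protocol.beam_width * protocol.pitch
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    axial = replace(protocol, mode="axial")
    curve = simulate_modulation(profile, axial, direction, lookahead_mm,
                                weights, seed=seed,
                                scan_margin_mm=scan_margin_mm,
                                table_positions=table_positions)
    idx = np.floor_divide(np.arange(len(curve)) * axial.recon_thickness,
                          step_mm).astype(int)
    first = np.searchsorted(idx, np.unique(idx), side="left")
    lead = first[idx]                       # leading slice of each step
    return replace(curve, ctdi_vol=curve.ctdi_vol[lead], ma=curve.ma[lead],
                   f_window=curve.f_window[lead])


def full_compensation_ctdi(curve: ModulationCurve) -> np.ndarray:
    """Per-slice CTDIvol that would hold image noise constant (strength=1)
    for the same lookahead attenuation, without tube-current clamping."""
    if curve.f_window is None:
        raise ValueError("curve carries no window statistics (not simulated)")
    p = curve.protocol
    expo = np.clip(p.beta * (curve.f_window - p.wed_ref), -50.0, 50.0)
    return p.k_dose * p.reference_mas * np.exp(expo)


def render_series(curve: ModulationCurve, phantom: PhantomSpec,
                  noise_sigma_ref: float = 12.0, seed: int = 0,
                  pixel_size: float = 3.0, matrix: int = 128,
                  sigma_max: float = 100.0,
                  table_offset: float | None = None) -> list[SliceRecord]:
    """Render noisy HU slice images for a simulated acquisition.

    Gaussian noise is added with sigma(z) = noise_sigma_ref *
    sqrt(ctdi_ref(z) / ctdi_vol(z)), where ctdi_ref(z) is the per-slice
    full-compensation dose; with modulation_strength < 1 the noise therefore
    rises with WED, as observed on real ATCM systems. Deterministic under
    ``seed``.
    """
    if noise_sigma_ref <= 0:
        raise ValueError("noise_sigma_ref must be positive")
    offset = (phantom.total_length / 2.0 if table_offset is None
              else table_offset)
    ref = full_compensation_ctdi(curve)
    with np.errstate(divide="ignore"):
        sigma = noise_sigma_ref * np.sqrt(
            np.divide(ref, curve.ctdi_vol,
                      out=np.full_like(ref, np.inf),
                      where=curve.ctdi_vol > 0))
    sigma = np.clip(sigma, 0.0, sigma_max)
    rng = np.random.default_rng(seed)
    records = []
    exposure_ms = curve.protocol.rotation_time * 1000.0
    for i, t in enumerate(curve.z):
        img = rasterize_slice(phantom, offset - t, pixel_size=pixel_size,
                              matrix=matrix)
        img = img + rng.normal(0.0, sigma[i], size=img.shape)
        records.append(SliceRecord(
            table_position=float(t), image=img, ma=float(curve.ma[i]),
            exposure_time=exposure_ms, ctdi_vol=float(curve.ctdi_vol[i]),
            recon_thickness=curve.protocol.recon_thickness,
            pixel_size=pixel_size, instance_number=i + 1))
    return records


def dlp(curve: ModulationCurve) -> float:
    """Dose-length product (mGy*cm) = mean CTDIvol x irradiated length."""
    return float(curve.ctdi_vol.mean()) * curve.scan_length_mm / 10.0
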