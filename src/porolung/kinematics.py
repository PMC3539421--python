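"""Motion analysis of simulated breathing: landmark traces, hysteresis lags,
cycle stability, trajectory-loop closure and the target-deformation-error
(TDE) metric.

Hysteresis is quantified per landmark and per displacement component as the
time by which the within-cycle peak of |displacement| lags the mid-cycle peak
of the inlet-pressure drive.  A linear (homogeneous isotropic) lung tracks
the drive nearly in phase; spatially varying anisotropic elasticity produces
component-dependent lags, cycle-to-cycle loop non-closure and slower settling
— the signatures this module measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fsi import SimulationResult, Waveform
from .phantom import ZonedMesh

logger = logging.getLogger("porolung")

__all__ = [
    "Landmark",
    "HysteresisReport",
    "TDEReport",
    "default_landmarks",
    "landmark_series",
    "hysteresis_lag",
    "cross_correlation_lag",
    "cycle_stability",
    "trajectory_loop_gap",
    "long_periodicity",
    "compute_tde",
    "build_hysteresis_report",
]

_COMPONENTS = ("x", "y", "z")


@dataclass(frozen=True)
class Landmark:
    """A monitored mesh node on the lung surface."""

    id: str
    node_index: int
    description: str = ""


@dataclass
class TDEReport:
    """Mean / max Euclidean landmark displacement error (mm) per breathing phase."""

    phase: str
    mean_tde: float
    max_tde: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_tde <= self.max_tde:
            raise ValueError("need 0 <= mean_tde <= max_tde")


@dataclass
class HysteresisReport:
    """Per landmark x component x cycle hysteresis summary.

    ``lags`` maps (landmark id, component, cycle) -> lag in seconds (None for
    flat traces); ``peaks`` the corresponding peak |displacement| in metres;
    ``loop_gaps`` maps (landmark id, cycle pair index) -> maximum 3D distance
    between phase-matched consecutive-cycle trajectories; ``stabilization``
    maps (landmark id, component) -> 1-based stabilized cycle index (or None);
    ``long_period`` maps (landmark id, component) -> dominant super-cycle
    period in seconds (or None).
    """

    landmarks: list[Landmark]
    waveform: Waveform
    lags: dict
    peaks: dict
    loop_gaps: dict
    stabilization: dict
    long_period: dict

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (lid, comp, cycle), lag in sorted(self.lags.items()):
            rows.append(
                {
                    "landmark": lid,
                    "component": comp,
                    "cycle": cycle,
                    "lag_s": np.nan if lag is None else lag,
                    "peak_displacement_m": self.peaks[(lid, comp, cycle)],
                }
            )
        return pd.DataFrame(rows)


def default_landmarks(mesh: ZonedMesh) -> list[Landmark]:
    """Three monitored surface nodes mirroring an apex / lateral / medial layout.

    A: the surface node farthest from the inlet patch centre (distal pole);
    B: the most lateral (max x) surface node near mid-height;
    C: the most medial (min x) surface node near mid-height.
    Nodes in the inlet or fixed patches are excluded.
    """
    surf = mesh.surface_nodes()
    excluded = np.concatenate(
        [mesh.boundary_tags.get(k, np.empty(0, dtype=int)) for k in ("inlet", "fixed")]
    )
    candidates = np.setdiff1d(surf, excluded)
    if candidates.size < 3:
        raise ValueError("mesh too coarse to place three landmarks")
    pts = mesh.nodes[candidates]
    inlet_nodes = mesh.boundary_tags.get("inlet")
    ref = (mesh.nodes[inlet_nodes].mean(axis=0) if inlet_nodes is not None
           and inlet_nodes.size else pts.mean(axis=0))
    a_idx = candidates[np.argmax(np.linalg.norm(pts - ref, axis=1))]
    z_span = pts[:, 2].max() - pts[:, 2].min()
    mid = (pts[:, 2].max() + pts[:, 2].min()) / 2.0
    near_mid = np.abs(pts[:, 2] - mid) < 0.25 * z_span
    if not np.any(near_mid):
        near_mid = np.ones(len(pts), dtype=bool)
    b_idx = candidates[near_mid][np.argmax(pts[near_mid, 0])]
    c_idx = candidates[near_mid][np.argmin(pts[near_mid, 0])]
    return [
        Landmark("A", int(a_idx), "distal pole (far from inlet)"),
        Landmark("B", int(b_idx), "lateral surface, mid-height"),
        Landmark("C", int(c_idx), "medial surface, mid-height"),
    ]


def landmark_series(result: SimulationResult, landmarks: list[Landmark]) -> dict:
    """Extract per-landmark (t, x, y, z) displacement traces (exact copies).

    Returns {landmark id: (times, displacement (n_times, 3))}.  A landmark on
    a Dirichlet (fixed) node yields an identically zero trace (warning logged).
    """
    out = {}
    for lm in landmarks:
        if not 0 <= lm.node_index < result.n_nodes:
            raise ValueError(f"landmark '{lm.id}' node {lm.node_index} not in mesh")
        trace = result.displacement[:, lm.node_index, :].copy()
        if np.all(trace == 0.0) and result.times.shape[0] > 1:
            logger.warning(
                "landmark '%s' (node %d) has an identically zero trace "
                "(fixed node or zero drive)", lm.id, lm.node_index,
            )
        out[lm.id] = (result.times.copy(), trace)
    return out


# ---------------------------------------------------------------------------
# per-cycle peak timing
# ---------------------------------------------------------------------------

def _cycle_slice(times: np.ndarray, w: Waveform, cycle: int) -> np.ndarray:
    """Indices of samples inside the 1-based breathing cycle ``cycle``."""
    t0 = w.phase_offset + (cycle - 1) * w.period
    t1 = t0 + w.period
    idx = np.flatnonzero((times >= t0 - 1e-12) & (times <= t1 + 1e-12))
    if idx.size < 3:
        raise ValueError(f"trace does not cover cycle {cycle}")
    return idx


def _interpolated_peak_time(times: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Peak time of |values| refined by a local quadratic fit; ties -> earliest."""
    mag = np.abs(values)
    k = int(np.argmax(mag))  # argmax takes the earliest maximum
    if 0 < k < len(mag) - 1:
        y0, y1, y2 = mag[k - 1], mag[k], mag[k + 2 - 1]
        denom = y0 - 2.0 * y1 + y2
        if abs(denom) > 1e-300:
            delta = 0.5 * (y0 - y2) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            dt = times[k + 1] - times[k]
            peak = y1 - 0.25 * (y0 - y2) * delta
            return float(times[k] + delta * dt), float(peak)
    return float(times[k]), float(mag[k])


def hysteresis_lag(trace: tuple[np.ndarray, np.ndarray], w: Waveform,
                   cycle: int = 1) -> float | None:
    """Lag (s) of the within-cycle displacement peak behind the drive peak.

    ``trace`` is (times, values) for one scalar component.  The discrete peak
    of |value| inside the requested 1-based cycle is refined by a local
    quadratic fit, then compared with the drive's mid-cycle peak time.
    Positive lag = peak after the drive peak; wrapped into [-period/2,
    period/2].  Returns None for an identically flat (zero) trace.
    """
    times, values = np.asarray(trace[0], float), np.asarray(trace[1], float)
    idx = _cycle_slice(times, w, cycle)
    if times[1] - times[0] > w.period / 40.0 + 1e-12:
        raise ValueError("trace sampling step must be <= period/40 for lag estimation")
    seg_t, seg_v = times[idx], values[idx]
    if np.all(seg_v == 0.0):
        return None
    t_peak, _ = _interpolated_peak_time(seg_t, seg_v)
    drive_peak = w.phase_offset + (cycle - 1) * w.period + w.period / 2.0
    lag = t_peak - drive_peak
    half = w.period / 2.0
    return float((lag + half) % w.period - half)


def cross_correlation_lag(trace: tuple[np.ndarray, np.ndarray], w: Waveform,
                          cycle: int = 1) -> float | None:
    """Secondary lag estimate: argmax of the circular cross-correlation of the
    within-cycle |trace| against the drive waveform (robust to peak shape)."""
    times, values = np.asarray(trace[0], float), np.asarray(trace[1], float)
    idx = _cycle_slice(times, w, cycle)
    seg_t, seg_v = times[idx[:-1]], np.abs(values[idx[:-1]])
    if np.all(seg_v == 0.0):
        return None
    drive = w.value(seg_t)
    a = seg_v - seg_v.mean()
    b = drive - drive.mean()
    n = len(a)
    corr = np.array([np.dot(a, np.roll(b, s)) for s in range(n)])
    s_best = int(np.argmax(corr))
    dt = seg_t[1] - seg_t[0]
    lag = s_best * dt
    half = w.period / 2.0
    return float((lag + half) % w.period - half)


def cycle_stability(trace: tuple[np.ndarray, np.ndarray], w: Waveform,
                    rel_tol: float = 0.05) -> int | None:
    """Smallest 1-based cycle whose peak all later cycles match within rel_tol.

    A trace that is periodic from the start returns 1; a decaying transient
    returns the cycle where the peak sequence has settled.  Requires at least
    3 full cycles; returns None if the peaks never settle.
    """
    times, values = np.asarray(trace[0], float), np.asarray(trace[1], float)
    n_cycles = int(np.floor((times[-1] - w.phase_offset) / w.period + 1e-9))
    if n_cycles < 3:
        raise ValueError(f"need >= 3 full cycles, got {n_cycles}")
    peaks = []
    for c in range(1, n_cycles + 1):
        idx = _cycle_slice(times, w, c)
        _, pk = _interpolated_peak_time(times[idx], values[idx])
        peaks.append(pk)
    peaks = np.asarray(peaks)
    scale = max(float(peaks.max()), 1e-300)
    for c in range(n_cycles):
        ref = peaks[c]
        if np.all(np.abs(peaks[c:] - ref) < rel_tol * max(ref, 1e-300 * scale)):
            return c + 1
    return None


def trajectory_loop_gap(trace3d: tuple[np.ndarray, np.ndarray], w: Waveform,
                        n_phase: int = 64) -> np.ndarray:
    """Maximum phase-matched distance between consecutive-cycle 3D loops.

    ``trace3d`` is (times, displacement (n_times, 3)).  Each cycle's
    trajectory is resampled at ``n_phase`` matched cycle phases (linear
    interpolation) and the maximum point-wise Euclidean distance between
    cycle c and cycle c+1 is returned, one value per consecutive pair.
    """
    times, disp = np.asarray(trace3d[0], float), np.asarray(trace3d[1], float)
    n_cycles = int(np.floor((times[-1] - w.phase_offset) / w.period + 1e-9))
    if n_cycles < 2:
        raise ValueError("need >= 2 full cycles for loop-gap analysis")
    phases = np.linspace(0.0, w.period, n_phase, endpoint=False)
    loops = []
    for c in range(n_cycles):
        t0 = w.phase_offset + c * w.period
        resampled = np.column_stack(
            [np.interp(t0 + phases, times, disp[:, a]) for a in range(3)]
        )
        loops.append(resampled)
    gaps = [
        float(np.max(np.linalg.norm(loops[c + 1] - loops[c], axis=1)))
        for c in range(n_cycles - 1)
    ]
    return np.asarray(gaps)


def long_periodicity(trace: tuple[np.ndarray, np.ndarray], w: Waveform,
                     min_autocorr: float = 0.3) -> float | None:
    """Dominant super-cycle period (s) of the per-cycle peak-magnitude sequence.

    The per-cycle peak |value| sequence is autocorrelated; the lag (in whole
    cycles, >= 2) with the largest autocorrelation above ``min_autocorr``
    defines the long period.  Returns None for constant peak sequences or
    when no lag is significant.  Requires >= 8 cycles.
    """
    times, values = np.asarray(trace[0], float), np.asarray(trace[1], float)
    n_cycles = int(np.floor((times[-1] - w.phase_offset) / w.period + 1e-9))
    if n_cycles < 8:
        raise ValueError(f"need >= 8 full cycles, got {n_cycles}")
    peaks = []
    for c in range(1, n_cycles + 1):
        idx = _cycle_slice(times, w, c)
        _, pk = _interpolated_peak_time(times[idx], values[idx])
        peaks.append(pk)
    x = np.asarray(peaks)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom < 1e-300 * max(1.0, float(np.max(np.abs(peaks))) ** 2):
        return None
    best_lag, best_ac = None, min_autocorr
    for lag in range(2, n_cycles // 2 + 1):
        ac = float(np.dot(x[:-lag], x[lag:])) / denom
        if ac > best_ac:
            best_lag, best_ac = lag, ac
    if best_lag is None:
        return None
    return float(best_lag * w.period)


def compute_tde(predicted: np.ndarray, reference: np.ndarray,
                phase: str = "") -> TDEReport:
    """Target deformation error: mean and max Euclidean distance (mm) between
    predicted and reference landmark displacement vectors at one phase."""
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape or predicted.ndim != 2 or predicted.shape[1] != 3:
        raise ValueError(
            f"predicted/reference must both be (n_landmarks, 3), got "
            f"{predicted.shape} vs {reference.shape}"
        )
    err = np.linalg.norm(predicted - reference, axis=1)
    return TDEReport(phase=phase, mean_tde=float(err.mean()), max_tde=float(err.max()))


def build_hysteresis_report(result: SimulationResult, landmarks: list[Landmark],
                            stability_tol: float = 0.05) -> HysteresisReport:
    """Full hysteresis analysis of a run: lags and peaks for every landmark,
    component and cycle, loop gaps per cycle pair, stabilization cycle, and
    (when >= 8 cycles are available) the super-cycle period."""
    w = result.waveform
    traces = landmark_series(result, landmarks)
    n_cycles = int(np.floor((result.times[-1] - w.phase_offset) / w.period + 1e-9))
    lags, peaks, loop_gaps, stab, long_p = {}, {}, {}, {}, {}
    for lm in landmarks:
        times, disp = traces[lm.id]
        for a, comp in enumerate(_COMPONENTS):
            trace = (times, disp[:, a])
            for c in range(1, n_cycles + 1):
                idx = _cycle_slice(times, w, c)
                lag = hysteresis_lag(trace, w, c)
                _, pk = _interpolated_peak_time(times[idx], disp[idx, a])
                lags[(lm.id, comp, c)] = lag
                peaks[(lm.id, comp, c)] = pk
            if n_cycles >= 3:
                stab[(lm.id, comp)] = cycle_stability(trace, w, stability_tol)
            if n_cycles >= 8:
                long_p[(lm.id, comp)] = long_periodicity(trace, w)
        if n_cycles >= 2:
            gaps = trajectory_loop_gap((times, disp), w)
            for c, g in enumerate(gaps, start=1):
                loop_gaps[(lm.id, c)] = g
    return HysteresisReport(
        landmarks=landmarks, waveform=w, lags=lags, peaks=peaks,
        loop_gaps=loop_gaps, stabilization=stab, long_period=long_p,
    )
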