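"""AP waveform metrics, the renormalising fitness function, and signal
conditioning for optically mapped action potentials.

The fitness is designed for optical recordings, where only the normalised
waveform is known: before each comparison the reference (input) trace is
shifted in time to superimpose half-maximum upstrokes, affinely rescaled
(V -> alpha*V + beta, least squares) onto the model trace, and the model's
initial depolarisation phase below -20 mV is excluded (photon scattering
distorts the experimental upstroke).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

__all__ = [
    "APTrace", "BaselineSet", "AlignmentResult",
    "align_half_max", "lsq_rescale", "rmse", "fitness", "biomarkers",
    "add_noise", "notch_60hz", "ensemble_average", "PENALTY_RMSE",
]

# Penalty assigned to sub-threshold or failed APs; any value far above
# physiological RMSE works.
PENALTY_RMSE = 1.0e3
AMPLITUDE_THRESHOLD = 30.0   # mV; smaller depolarisations are discarded
UPSTROKE_MASK_LEVEL = -20.0  # mV, on the model trace
# The amplitude check must not count the stimulus artifact (a -80 A/F x
# 0.5 ms pulse alone depolarises a quiescent cell by ~40 mV): the peak is
# taken after the artifact has decayed, so sub-threshold stimulus
# responses are discarded as intended while any real AP is still on its
# plateau at that time.
ARTIFACT_WINDOW_MS = 30.0


@dataclass
class APTrace:
    """Uniformly sampled voltage-vs-time record for one pacing cycle length."""

    time: np.ndarray            # ms, uniform
    v: np.ndarray               # mV (or arbitrary units if normalized)
    pcl: float                  # ms
    normalized: bool = False    # True for unit-scale optical data

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.time.shape != self.v.shape or self.time.ndim != 1:
            raise ValueError("time and v must be 1-D arrays of equal length")
        if self.time.size < 2:
            raise ValueError("trace too short")
        dt = np.diff(self.time)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trace must be uniformly sampled")
        if self.pcl <= 0:
            raise ValueError("PCL must be positive")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def fs(self) -> float:
        """Sampling rate in Hz (time is in ms)."""
        return 1000.0 / self.dt

    def copy(self) -> "APTrace":
        return APTrace(self.time.copy(), self.v.copy(), self.pcl,
                       self.normalized)


@dataclass
class BaselineSet:
    """GA input: one reference trace per PCL plus per-PCL weights."""

    traces: dict            # pcl -> APTrace
    weights: dict = None    # pcl -> float, default all equal to 1
    mode: str = "optical"   # 'optical' or 'absolute'

    def __post_init__(self):
        if not self.traces:
            raise ValueError("empty baseline set")
        if self.weights is None:
            self.weights = {pcl: 1.0 for pcl in self.traces}
        if set(self.weights) != set(self.traces):
            raise ValueError("weights and traces must cover the same PCLs")
        w = np.array([self.weights[p] for p in self.traces])
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be >= 0 and not all zero")
        if self.mode not in ("optical", "absolute"):
            raise ValueError("mode must be 'optical' or 'absolute'")

    @property
    def pcls(self):
        return sorted(self.traces)


@dataclass
class AlignmentResult:
    shift: float                 # ms; candidate + shift superimposes reference
    time: np.ndarray             # common grid (reference timebase)
    v_ref: np.ndarray
    v_cand: np.ndarray
    ok: bool = True


def _half_max_crossing(trace: APTrace) -> float:
    """Time of the first upward crossing of half-maximum depolarisation."""
    v = trace.v
    lo, hi = v.min(), v.max()
    if hi - lo <= 0:
        raise ValueError("trace has no upstroke")
    level = 0.5 * (lo + hi)
    above = v >= level
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        if above[0]:
            return trace.time[0]
        raise ValueError("no half-maximum crossing found")
    i = idx[0]
    w = (level - v[i]) / (v[i + 1] - v[i])
    return trace.time[i] + w * (trace.time[i + 1] - trace.time[i])


def align_half_max(reference: APTrace, candidate: APTrace) -> AlignmentResult:
    """Shift the candidate so both half-maximum upstrokes superimpose.

    The candidate is linearly resampled onto the reference grid over the
    overlapping support.
    """
    try:
        t_ref = _half_max_crossing(reference)
        t_cand = _half_max_crossing(candidate)
    except ValueError:
        n = min(reference.v.size, candidate.v.size)
        return AlignmentResult(0.0, reference.time[:n], reference.v[:n],
                               candidate.v[:n], ok=False)
    shift = t_ref - t_cand
    t_cand_shifted = candidate.time + shift
    lo = max(reference.time[0], t_cand_shifted[0])
    hi = min(reference.time[-1], t_cand_shifted[-1])
    sel = (reference.time >= lo - 1e-9) & (reference.time <= hi + 1e-9)
    t_common = reference.time[sel]
    v_cand = np.interp(t_common, t_cand_shifted, candidate.v)
    return AlignmentResult(shift, t_common, reference.v[sel], v_cand)


def lsq_rescale(v_ref, v_cand):
    """Affine map alpha*v_ref + beta minimising the distance to v_cand.

    Returns (alpha, beta, rescaled reference).  Closed-form simple
    regression; the *reference* (input data) is rescaled onto the model.
    """
    v_ref = np.asarray(v_ref, dtype=float)
    v_cand = np.asarray(v_cand, dtype=float)
    if v_ref.shape != v_cand.shape:
        raise ValueError("length mismatch")
    var = np.var(v_ref)
    if var <= 0:
        raise ValueError("zero-variance reference")
    alpha = np.cov(v_ref, v_cand, bias=True)[0, 1] / var
    beta = v_cand.mean() - alpha * v_ref.mean()
    return alpha, beta, alpha * v_ref + beta


def rmse(a, b) -> float:
    """Root-mean-square difference of two equal-length sample vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _ap_amplitude(trace: APTrace) -> float:
    """AP amplitude excluding the stimulus artifact: peak after the
    artifact window minus the trace minimum."""
    late = trace.time >= trace.time[0] + ARTIFACT_WINDOW_MS
    if not np.any(late):
        late = slice(None)
    return float(trace.v[late].max() - trace.v.min())


def _single_pcl_error(ref: APTrace, cand: APTrace, mode: str) -> float:
    if _ap_amplitude(cand) < AMPLITUDE_THRESHOLD:
        return PENALTY_RMSE
    if mode == "absolute":
        n = min(ref.v.size, cand.v.size)
        return rmse(ref.v[:n], cand.v[:n])
    aligned = align_half_max(ref, cand)
    if not aligned.ok or aligned.time.size < 10:
        return PENALTY_RMSE
    try:
        _, _, v_ref_scaled = lsq_rescale(aligned.v_ref, aligned.v_cand)
    except ValueError:
        return PENALTY_RMSE
    # exclude the reference's initial depolarisation below -20 mV (the part
    # photon scattering distorts in optical recordings): a single
    # contiguous prefix ending at the reference's first upward crossing.
    # Masking on the reference side keeps a candidate with a slow or absent
    # upstroke fully exposed to the comparison.
    above = np.flatnonzero(v_ref_scaled >= UPSTROKE_MASK_LEVEL)
    start = above[0] if above.size else 0
    if aligned.v_cand.size - start < 10:
        return PENALTY_RMSE
    return rmse(v_ref_scaled[start:], aligned.v_cand[start:])


def fitness(baselines: BaselineSet, candidates: dict,
            mode: str | None = None) -> tuple[float, dict]:
    """Weighted total RMSE of candidate traces against the baseline set.

    ``candidates`` maps PCL -> APTrace or None (None marks an integration
    failure and draws the penalty).  Returns (RMSE_tot, per-PCL RMSE).
    Weights are applied as given (not normalised): RMSE_tot = sum w_i R_i.
    """
    mode = mode or baselines.mode
    per_pcl = {}
    failed = False
    for pcl, ref in baselines.traces.items():
        cand = candidates.get(pcl)
        if cand is None:
            per_pcl[pcl] = PENALTY_RMSE
            failed = True
            continue
        per_pcl[pcl] = _single_pcl_error(ref, cand, mode)
        if per_pcl[pcl] >= PENALTY_RMSE:
            failed = True
    if failed:
        return PENALTY_RMSE, per_pcl
    total = sum(baselines.weights[p] * r for p, r in per_pcl.items())
    return float(total), per_pcl


def biomarkers(trace: APTrace, level: float = 0.8) -> dict:
    """APD at the given repolarisation level, amplitude, RMP, (dV/dt)max.

    Activation time is the half-maximum upstroke crossing; APD runs from
    activation to ``level`` (fraction of amplitude) repolarisation.  RMP is
    the mean of the pre-upstroke diastolic segment when one exists,
    otherwise the trace minimum.  APD is None when the trace does not
    repolarise to the requested level (undefined-marker flag).
    """
    t_act = _half_max_crossing(trace)
    v = trace.v
    t = trace.time
    pre = t < t_act - 5.0
    rmp = float(v[pre].mean()) if pre.sum() >= 3 else float(v.min())
    peak_idx = int(np.argmax(v))
    peak = float(v[peak_idx])
    amplitude = peak - rmp
    dvdt = np.gradient(v, t)
    vd = peak - level * amplitude
    below = v[peak_idx:] <= vd
    apd = None
    idx = np.flatnonzero(below)
    if idx.size:
        i = peak_idx + idx[0]
        if i > 0 and v[i] != v[i - 1]:
            w = (vd - v[i - 1]) / (v[i] - v[i - 1])
            t_rep = t[i - 1] + w * (t[i] - t[i - 1])
        else:
            t_rep = t[i]
        apd = float(t_rep - t_act)
    return {
        "APD": apd,
        "amplitude": float(amplitude),
        "RMP": rmp,
        "dVdt_max": float(dvdt.max()),
        "level": level,
    }


def add_noise(trace: APTrace, snr_db: float, seed=None) -> APTrace:
    """Additive white Gaussian noise at the requested SNR (signal power is
    measured on the mean-removed trace)."""
    if np.isinf(snr_db):
        return trace.copy()
    rng = np.random.default_rng(seed)
    p_signal = np.mean((trace.v - trace.v.mean()) ** 2)
    sigma = np.sqrt(p_signal / 10.0 ** (snr_db / 10.0))
    noisy = trace.copy()
    noisy.v = trace.v + rng.normal(0.0, sigma, size=trace.v.size)
    return noisy


def notch_60hz(trace: APTrace, band: tuple = (58.0, 62.0),
               order: int = 2) -> APTrace:
    """Zero-phase band-stop Butterworth filter centred on 60-Hz hum."""
    fs = trace.fs
    if fs < 200.0:
        raise ValueError("sampling rate too low for a 60-Hz notch")
    sos = _signal.butter(order, band, btype="bandstop", fs=fs, output="sos")
    out = trace.copy()
    out.v = _signal.sosfiltfilt(sos, trace.v)
    return out


def ensemble_average(traces) -> APTrace:
    """Average several beats after aligning each to the first's upstroke."""
    traces = list(traces)
    if len(traces) < 1:
        raise ValueError("need at least one trace")
    ref = traces[0]
    acc = np.zeros_like(ref.v)
    counts = np.zeros_like(ref.v)
    for tr in traces:
        al = align_half_max(ref, tr)
        if not al.ok:
            raise ValueError("trace without an upstroke in ensemble")
        sel = np.searchsorted(ref.time, al.time[0])
        acc[sel:sel + al.v_cand.size] += al.v_cand
        counts[sel:sel + al.v_cand.size] += 1
    good = counts > 0
    out = ref.copy()
    out.v = np.where(good, acc / np.maximum(counts, 1), ref.v)
    sel = np.flatnonzero(good)
    return APTrace(ref.time[sel[0]:sel[-1] + 1], out.v[sel[0]:sel[-1] + 1],
                   ref.pcl, ref.normalized)
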