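"""Forward single-cell electrophysiology.

Wraps the O'Hara-Rudy endocardial ventricular model (see
:mod:`cardiofit._ord`) with multiplicative scaling factors on thirteen
conductances/fluxes, an adaptive Rush-Larsen integrator, and a cheap
closed-form "toy" action potential used to exercise the optimisation
machinery in milliseconds instead of minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import _ord
from ._ord import (
    CURRENT_NAMES,
    GATE_SLICE,
    N_SCALING,
    N_STATES,
    SCALING_NAMES,
    STATE_NAMES,
)

__all__ = [
    "STATE_NAMES", "SCALING_NAMES", "CURRENT_NAMES",
    "ScalingFactors", "PacingProtocol", "IntegrationResult",
    "ord_initial_state", "ord_rhs", "nernst", "integrate",
    "pace_to_steady_state", "ord_steady_state", "toy_ap", "toy_apd",
    "TOY_BASELINE_PARAMS",
    "state_to_json", "state_from_json",
]

MULTIPLIER_LO = 0.01
MULTIPLIER_HI = 4.0


@dataclass
class ScalingFactors:
    """Dimensionless multipliers on the baseline model, all 1.0 by default.

    Order and names follow ``SCALING_NAMES``: gNa, gKr, gK1, gKs, PCaL,
    gto, gNaK, gNCX, gpCa, Jrel, Jup, CMDN, CaMKII.
    """

    gNa: float = 1.0
    gKr: float = 1.0
    gK1: float = 1.0
    gKs: float = 1.0
    PCaL: float = 1.0
    gto: float = 1.0
    gNaK: float = 1.0
    gNCX: float = 1.0
    gpCa: float = 1.0
    Jrel: float = 1.0
    Jup: float = 1.0
    CMDN: float = 1.0
    CaMKII: float = 1.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SCALING_NAMES])

    @classmethod
    def from_array(cls, arr) -> "ScalingFactors":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_SCALING,):
            raise ValueError(f"expected {N_SCALING} multipliers, got {arr.shape}")
        return cls(**dict(zip(SCALING_NAMES, arr)))

    def validate(self, lo: float = MULTIPLIER_LO, hi: float = MULTIPLIER_HI):
        a = self.to_array()
        if np.any(a < lo) or np.any(a > hi):
            bad = [n for n, v in zip(SCALING_NAMES, a) if not lo <= v <= hi]
            raise ValueError(f"multipliers out of [{lo}, {hi}]: {bad}")
        return self


@dataclass
class PacingProtocol:
    """Stimulation protocol: periodic current pulses.

    Stimulus amplitude/duration default to the -80 A/F x 0.5 ms convention
    of the baseline model's own pacing protocol.
    """

    pcl: float = 1000.0           # ms
    n_beats: int = 1
    stim_amplitude: float = -80.0  # A/F
    stim_duration: float = 0.5     # ms

    def __post_init__(self):
        if not self.pcl > self.stim_duration > 0:
            raise ValueError("require PCL > stimulus duration > 0")
        if self.n_beats < 1:
            raise ValueError("need at least one beat")


@dataclass
class IntegrationResult:
    """Voltage trace plus final state; ``ok`` is False on a blow-up.

    A failed integration is a *result*, not an exception, so a fitness
    evaluation can assign the penalty value and carry on.
    """

    trace: "APTrace | None"
    state: np.ndarray
    ok: bool
    apd_delta: float | None = None   # final two-beat APD90 difference, ms


def ord_initial_state(**overrides) -> np.ndarray:
    """Published resting initial conditions; keyword overrides by state name.

    ``ord_initial_state(ki=120.0, nai=8.0, cansr=4.0)`` also propagates the
    override to the paired subspace/junctional component (kss, nass, cajsr)
    unless that component is itself overridden.
    """
    y = _ord.initial_state()
    pairs = {"ki": "kss", "nai": "nass", "cansr": "cajsr"}
    for name, value in overrides.items():
        if name not in STATE_NAMES:
            raise KeyError(f"unknown state component {name!r}")
        y[STATE_NAMES.index(name)] = value
        partner = pairs.get(name)
        if partner and partner not in overrides:
            y[STATE_NAMES.index(partner)] = value
    return y


_STEADY_CACHE: dict = {}


def ord_steady_state(pcl: float = 1000.0, settle: float = 1000.0,
                     **overrides) -> np.ndarray:
    """Baseline-model state after long pacing at the given PCL (cached).

    This is the conventional starting point for simulations: the published
    resting initial conditions advanced to the paced limit cycle.
    """
    key = (pcl, settle)
    if key not in _STEADY_CACHE:
        res = pace_to_steady_state(pcl=pcl, settle=settle,
                                   dt_max=1.0, dv_max=0.2)
        if not res.ok:
            raise RuntimeError("baseline steady-state pacing failed")
        _STEADY_CACHE[key] = res.state
    y = _STEADY_CACHE[key].copy()
    pairs = {"ki": "kss", "nai": "nass", "cansr": "cajsr"}
    for name, value in overrides.items():
        y[STATE_NAMES.index(name)] = value
        partner = pairs.get(name)
        if partner and partner not in overrides:
            y[STATE_NAMES.index(partner)] = value
    return y


def _check_state(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.shape != (N_STATES,):
        raise ValueError(f"state must have {N_STATES} components")
    if not np.all(np.isfinite(y)):
        bad = [STATE_NAMES[i] for i in np.flatnonzero(~np.isfinite(y))]
        raise ValueError(f"non-finite state component(s): {bad}")
    return y


def ord_rhs(state, scaling: ScalingFactors | np.ndarray | None = None,
            stim: float = 0.0):
    """Time derivative of the full state and the ionic currents by name.

    Currents are in A/F; SR fluxes (Jrel, Jup) in mM/ms.
    """
    y = _check_state(state)
    s = _as_scaling_array(scaling)
    xinf = np.empty(N_STATES)
    xtau = np.empty(N_STATES)
    dy = np.empty(N_STATES)
    cur = np.empty(_ord.N_CURRENTS)
    _ord._rates(y, s, stim, xinf, xtau, dy, cur)
    return dy, dict(zip(CURRENT_NAMES, cur))


def _as_scaling_array(scaling) -> np.ndarray:
    if scaling is None:
        return np.ones(N_SCALING)
    if isinstance(scaling, ScalingFactors):
        return scaling.to_array()
    arr = np.asarray(scaling, dtype=float)
    if arr.shape != (N_SCALING,):
        raise ValueError(f"expected {N_SCALING} multipliers")
    return arr


def nernst(valence: int, conc_in: float, conc_out: float,
           temperature: float = 310.0) -> float:
    """Nernst reversal potential (mV) = (RT/zF) ln(out/in)."""
    if conc_in <= 0 or conc_out <= 0:
        raise ValueError("concentrations must be positive")
    return (_ord.R_GAS * temperature / (valence * _ord.FARADAY)
            * np.log(conc_out / conc_in))


# Integrator defaults: 5e-3 ms floor, 0.5 ms cap, step chosen so V moves
# at most DV_MAX per step (smallest steps land on the upstroke).  Halving
# both caps moves steady-paced APD90 by ~0.5 ms (first-order convergence).
DT_MIN = 5e-3
DT_MAX = 0.5
DV_MAX = 0.1


def integrate(state, scaling=None, duration: float = 1000.0,
              protocol: PacingProtocol | None = None,
              dt_min: float = DT_MIN, dt_max: float = DT_MAX,
              dv_max: float = DV_MAX,
              record_from: float = 0.0) -> IntegrationResult:
    """Integrate the cell for ``duration`` ms under periodic stimulation.

    The voltage trace is resampled to a uniform 1-ms grid (1-kHz optical
    sampling) from ``record_from`` ms onward; the final state is returned
    for persistence.
    """
    from .waveform import APTrace

    if duration <= 0:
        raise ValueError("duration must be positive")
    proto = protocol or PacingProtocol(pcl=max(duration, 1.0))
    y = _check_state(state).copy()
    s = _as_scaling_array(scaling)
    n_rec = int(np.floor(duration - record_from)) + 1
    rec = np.empty(n_rec)
    status = _ord._cell_run(y, s, duration, proto.pcl,
                            proto.stim_amplitude, proto.stim_duration,
                            dt_min, dt_max, dv_max, rec, record_from)
    trace = None
    if status == 0:
        t = record_from + np.arange(n_rec, dtype=float)
        trace = APTrace(time=t - record_from, v=rec, pcl=proto.pcl)
    return IntegrationResult(trace=trace, state=y, ok=(status == 0))


def pace_to_steady_state(scaling=None, initial=None, pcl: float = 1000.0,
                         settle: float = 1000.0,
                         protocol_kwargs: dict | None = None,
                         dt_min: float = DT_MIN, dt_max: float = DT_MAX,
                         dv_max: float = DV_MAX) -> IntegrationResult:
    """Pace at fixed PCL for ``settle`` seconds; return the last beat.

    ``apd_delta`` on the result is the APD90 difference of the final two
    beats, a convergence measure (small at steady state).
    """
    from .waveform import APTrace, biomarkers

    y = _check_state(initial if initial is not None else ord_initial_state())
    y = y.copy()
    s = _as_scaling_array(scaling)
    kw = dict(protocol_kwargs or {})
    proto = PacingProtocol(pcl=pcl, n_beats=max(
        1, int(np.ceil(settle * 1000.0 / pcl))), **kw)
    n_beats = proto.n_beats
    n_last = min(2, n_beats)
    rec_t0 = (n_beats - n_last) * pcl
    duration = n_beats * pcl
    n_rec = int(round(duration - rec_t0)) + 1
    rec = np.empty(n_rec)
    status = _ord._cell_run(y, s, duration, pcl,
                            proto.stim_amplitude, proto.stim_duration,
                            dt_min, dt_max, dv_max, rec, rec_t0)
    if status != 0:
        return IntegrationResult(trace=None, state=y, ok=False)
    npcl = int(round(pcl))
    last = APTrace(time=np.arange(npcl + 1, dtype=float),
                   v=rec[-(npcl + 1):], pcl=pcl)
    apd_delta = None
    if n_last == 2:
        prev = APTrace(time=np.arange(npcl + 1, dtype=float),
                       v=rec[:npcl + 1], pcl=pcl)
        try:
            a1 = biomarkers(prev, level=0.9)["APD"]
            a2 = biomarkers(last, level=0.9)["APD"]
            if a1 is not None and a2 is not None:
                apd_delta = abs(a2 - a1)
        except ValueError:
            apd_delta = None
    return IntegrationResult(trace=last, state=y, ok=True,
                             apd_delta=apd_delta)


# ---------------------------------------------------------------------------
# Toy action-potential surrogate
# ---------------------------------------------------------------------------

# rest depth (mV below 0), amplitude (mV), long-PCL APD (ms), short-PCL
# APD (ms): values chosen to mimic a human ventricular AP.
TOY_BASELINE_PARAMS = np.array([85.0, 125.0, 290.0, 180.0])

# fixed shape constants of the toy waveform (not searched over)
_TOY_PIVOT_PCL = 200.0     # ms; restitution pivot, below the studied PCLs
_TOY_REST_TAU = 350.0      # ms; restitution relaxation constant
_TOY_T_UP = 5.0            # ms; upstroke latency
_TOY_EDGE = 0.06           # repolarisation edge width, fraction of APD


def toy_apd(params, pcl: float) -> float:
    """Closed-form APD of the toy waveform at the given PCL."""
    rest, amp, apd_long, apd_short = np.asarray(params, dtype=float)
    return apd_long - (apd_long - apd_short) * np.exp(
        -(pcl - _TOY_PIVOT_PCL) / _TOY_REST_TAU)


def toy_ap(params, pcl: float):
    """Closed-form AP-like waveform with one parameter per feature.

    params = (rest, amp, apd_long, apd_short):

    * resting level is ``-rest`` mV,
    * amplitude is ``amp`` mV,
    * ``apd_long`` is the action-potential duration at slow pacing,
    * ``apd_short`` sets the duration at the fastest studied rate, so it
      alone controls the PCL-dependent restitution term
      ``(apd_long - apd_short) * exp(-(pcl - 200)/350)``.

    Deterministic, smooth, and strictly monotone in each parameter's own
    feature, which makes recovery experiments interpretable.
    """
    from .waveform import APTrace

    p = np.asarray(params, dtype=float)
    if p.shape != (4,) or np.any(p <= 0):
        raise ValueError("toy_ap needs 4 positive shape parameters")
    rest, amp = p[0], p[1]
    apd = toy_apd(p, pcl)
    t = np.arange(int(round(pcl)) + 1, dtype=float)
    upstroke = 1.0 / (1.0 + np.exp(
        np.clip(-(t - _TOY_T_UP) / 0.8, -700, 700)))
    repol = 1.0 / (1.0 + np.exp(
        np.clip((t - _TOY_T_UP - apd) / (_TOY_EDGE * apd), -700, 700)))
    v = -rest + amp * upstroke * repol
    return APTrace(time=t, v=v, pcl=pcl)


# ---------------------------------------------------------------------------
# State (de)serialisation: flat named-vector JSON
# ---------------------------------------------------------------------------

def state_to_json(state, path=None) -> str:
    y = _check_state(state)
    text = json.dumps(dict(zip(STATE_NAMES, map(float, y))), indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def state_from_json(source) -> np.ndarray:
    if hasattr(source, "read"):
        data = json.load(source)
    else:
        text = str(source)
        if text.lstrip().startswith("{"):
            data = json.loads(text)
        else:
            with open(text) as fh:
                data = json.load(fh)
    return np.array([data[name] for name in STATE_NAMES])


def check_invariants(state) -> None:
    """Raise if gates leave [0,1] or any concentration is non-positive."""
    y = _check_state(state)
    gates = y[GATE_SLICE]
    if np.any(gates < -1e-9) or np.any(gates > 1.0 + 1e-9):
        raise ValueError("gating variable outside [0, 1]")
    conc_idx = [STATE_NAMES.index(n) for n in
                ("nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr")]
    if np.any(y[conc_idx] <= 0):
        raise ValueError("non-positive concentration")
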