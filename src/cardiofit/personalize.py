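"""Synthetic baselines for verification experiments and mRNA-based
rescaling of a fitted model onto a second subject.

The rescaling assumes each ionic conductance/flux is proportional to the
normalised mRNA expression of its pore-forming subunit gene: a fitted
multiplier set is mapped to another subject by multiplying each entry by
the target/reference expression ratio of the mapped gene.  Slow-variable
genes are dropped — the new subject's concentrations must re-equilibrate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._ord import SCALING_NAMES
from .cellmodel import (
    ScalingFactors, TOY_BASELINE_PARAMS, pace_to_steady_state, toy_ap,
)
from .waveform import APTrace, BaselineSet, add_noise, biomarkers

__all__ = [
    "GENE_PARAMETER_MAP", "ExpressionTable", "make_baselines",
    "rescale_by_expression", "restitution_curve", "SyntheticTruth",
]

# gene symbol of the pore-forming subunit -> model multiplier
GENE_PARAMETER_MAP = {
    "SCN5A": "gNa",
    "KCNH2": "gKr",
    "KCNJ2": "gK1",
    "KCNQ1": "gKs",
    "CACNA1C": "PCaL",
    "KCNA4": "gto",
    "ATP1A1": "gNaK",
    "SLC8A1": "gNCX",
    "ATP2B4": "gpCa",
    "RYR2": "Jrel",
    "ATP2A2": "Jup",
    "CALM1": "CMDN",
    "CAMK2D": "CaMKII",
}

# PCLs at which synthetic steady-state baselines are generated by default
DEFAULT_PCLS = (217.0, 225.0, 250.0, 300.0, 500.0, 1000.0, 2000.0)


class ExpressionTable:
    """Gene-by-sample table of normalised expression (TPM or similar).

    One row per gene symbol; promoter/transcript aggregation is the
    caller's responsibility.
    """

    def __init__(self, frame: pd.DataFrame):
        if (frame.values < 0).any():
            raise ValueError("expression values must be non-negative")
        self.frame = frame

    @classmethod
    def from_tsv(cls, path) -> "ExpressionTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path):
        self.frame.to_csv(path, sep="\t")

    @property
    def samples(self):
        return list(self.frame.columns)

    def value(self, gene: str, sample: str) -> float:
        if gene not in self.frame.index:
            raise KeyError(f"gene {gene!r} missing from expression table")
        if sample not in self.frame.columns:
            raise KeyError(f"sample {sample!r} missing from expression table")
        return float(self.frame.at[gene, sample])


@dataclass
class SyntheticTruth:
    """Hidden record of a synthetic experiment: what the GA should find."""

    scaling: np.ndarray               # true multipliers
    concentrations: dict              # pcl -> (nai, cansr) at steady state
    states: dict                      # pcl -> full steady state vector


def make_baselines(scaling=None, pcls=DEFAULT_PCLS, settle: float = 1000.0,
                   snr_db: float | None = None, seed=None,
                   mode: str = "optical", model: str = "ord",
                   toy_params=None, dt_max: float | None = None,
                   dv_max: float | None = None):
    """Generate steady-state reference traces by pacing the forward model.

    Returns (BaselineSet, SyntheticTruth).  In optical mode the traces are
    min-max normalised, stripping the absolute voltage scale so the
    renormalising fitness is exercised.  Noise, if requested, is Gaussian
    at ``snr_db``.  A PCL at which the model fails to capture 1:1 is
    dropped with a warning.
    """
    if len(set(pcls)) != len(pcls):
        raise ValueError("PCLs must be distinct")
    rng = np.random.default_rng(seed)
    traces = {}
    concentrations = {}
    states = {}
    if model == "toy":
        params = np.asarray(toy_params if toy_params is not None
                            else TOY_BASELINE_PARAMS, dtype=float)
        truth_scaling = params / TOY_BASELINE_PARAMS
        for pcl in pcls:
            traces[pcl] = toy_ap(params, pcl)
    elif model == "ord":
        truth_scaling = (np.ones(len(SCALING_NAMES)) if scaling is None
                         else np.asarray(
                             scaling.to_array()
                             if isinstance(scaling, ScalingFactors)
                             else scaling, dtype=float))
        # default to the genetic algorithm's forward-model step caps so a
        # truth organism scores (near) zero against its own baselines
        from .ga import GA_DT_MAX, GA_DV_MAX
        kw = {"dt_max": GA_DT_MAX if dt_max is None else dt_max,
              "dv_max": GA_DV_MAX if dv_max is None else dv_max}
        for pcl in pcls:
            res = pace_to_steady_state(truth_scaling, pcl=pcl, settle=settle,
                                       **kw)
            # 1:1 capture requires a healthy amplitude, a measurable APD
            # and negligible beat-to-beat APD change (2:1 block and
            # alternans both fail at least one of these)
            captured = res.ok
            if captured:
                from .waveform import AMPLITUDE_THRESHOLD, _ap_amplitude
                captured = _ap_amplitude(res.trace) >= AMPLITUDE_THRESHOLD
            if captured:
                apd = biomarkers(res.trace, level=0.9)["APD"]
                captured = (apd is not None
                            and res.apd_delta is not None
                            and res.apd_delta < 5.0)
            if not captured:
                warnings.warn(f"PCL {pcl:g} ms dropped: no 1:1 capture")
                continue
            traces[pcl] = res.trace
            concentrations[pcl] = (float(res.state[1]), float(res.state[7]))
            states[pcl] = res.state
    else:
        raise ValueError("model must be 'ord' or 'toy'")
    if not traces:
        raise ValueError("no capturing PCL: baseline set would be empty")
    for pcl, tr in traces.items():
        if snr_db is not None and np.isfinite(snr_db):
            tr = add_noise(tr, snr_db, seed=rng.integers(2 ** 31))
        if mode == "optical":
            lo, hi = tr.v.min(), tr.v.max()
            tr = APTrace(tr.time, (tr.v - lo) / (hi - lo), pcl,
                         normalized=True)
        traces[pcl] = tr
    baselines = BaselineSet(traces=traces, mode=mode)
    return baselines, SyntheticTruth(truth_scaling, concentrations, states)


def rescale_by_expression(fitted, expr: ExpressionTable, reference: str,
                          target: str, gene_map=None,
                          clip: tuple | None = None) -> ScalingFactors:
    """Rescale fitted multipliers by target/reference mRNA expression ratios.

    ``fitted`` may be a ScalingFactors, a 13-vector, or a longer GA genome
    (slow-variable genes are dropped).  Rescaled values may leave the GA
    search box: bounds are a property of the optimiser, not of the model,
    so clipping is applied only when ``clip`` limits are given (with a
    warning).
    """
    gene_map = gene_map or GENE_PARAMETER_MAP
    if isinstance(fitted, ScalingFactors):
        vec = fitted.to_array()
    else:
        vec = np.asarray(fitted, dtype=float)[:len(SCALING_NAMES)]
    out = vec.copy()
    by_param = {p: g for g, p in gene_map.items()}
    for i, pname in enumerate(SCALING_NAMES):
        gene = by_param[pname]
        ref_val = expr.value(gene, reference)
        tgt_val = expr.value(gene, target)
        if ref_val <= 0:
            raise ValueError(
                f"zero reference expression for {gene} ({pname})")
        out[i] = vec[i] * tgt_val / ref_val
    if clip is not None:
        lo, hi = clip
        clipped = np.clip(out, lo, hi)
        if np.any(clipped != out):
            warnings.warn("rescaled multipliers clipped to validity bounds")
        out = clipped
    return ScalingFactors.from_array(out)


def restitution_curve(scaling=None, pcls=DEFAULT_PCLS, settle: float = 1000.0,
                      level: float = 0.9, model: str = "ord",
                      toy_params=None) -> pd.DataFrame:
    """Steady-state APD-vs-PCL pairs (the restitution curve)."""
    baselines, _ = make_baselines(scaling, pcls=pcls, settle=settle,
                                  mode="absolute", model=model,
                                  toy_params=toy_params)
    rows = []
    for pcl in baselines.pcls:
        bm = biomarkers(baselines.traces[pcl], level=level)
        rows.append({"pcl_ms": pcl, "apd_ms": bm["APD"]})
    return pd.DataFrame(rows)
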