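"""Synthetic-data generators with attached ground truth.

Every input the characterization pipeline consumes can be generated here
with known generating parameters, so each downstream fit is testable as a
parameter-recovery problem.  Generation starts at the initial-velocity
level (no absorbance traces).  The noise model is multiplicative Gaussian
on rates -- velocities are positive and measurement error in chromogenic
assays scales with signal -- with negative draws truncated at zero.
Replicate count defaults to 8, the usual replication of this assay format.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import ProfileDataset, RateDataset, ResidualActivityTable
from .exceptions import (
    EmptyInputError,
    InfeasibleFixtureError,
    InvalidParameterError,
    InvalidSelectorError,
)
from .mm import MichaelisMentenParams
from .ph import PHProfileModel, predict_eq1
from .seqfeatures import SequenceRecord, count_axxxa, scan_pentapeptide
from .temperature import ElementaryRates, predict_temperature_model


@dataclass(frozen=True)
class SimulationSpec:
    """Reproducible simulation settings.

    seed : RNG seed (identical spec => byte-identical output).
    noise_rel_sd : relative SD of the multiplicative Gaussian noise (>= 0);
        zero gives exact model predictions.
    n_replicates : replicate measurements per grid point (>= 1).
    grid : condition values -- substrate mM, pH units or degC depending on
        the generator.
    """

    seed: int
    grid: Sequence[float]
    noise_rel_sd: float = 0.03
    n_replicates: int = 8

    def __post_init__(self):
        if self.noise_rel_sd < 0:
            raise InvalidParameterError("noise_rel_sd must be >= 0")
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")
        if len(self.grid) == 0:
            raise EmptyInputError("simulation grid is empty")
        object.__setattr__(self, "grid", tuple(float(g) for g in self.grid))


def _noisy(values: np.ndarray, spec: SimulationSpec) -> np.ndarray:
    """Replicate and apply truncated multiplicative Gaussian noise.

    Returns an array of shape (n_points * n_replicates,), replicate-major
    within each grid point.
    """
    rng = np.random.default_rng(spec.seed)
    tiled = np.repeat(values, spec.n_replicates)
    if spec.noise_rel_sd == 0:
        return tiled.copy()
    eps = rng.normal(0.0, spec.noise_rel_sd, size=tiled.shape)
    return np.clip(tiled * (1.0 + eps), 0.0, None)


def simulate_velocity_curve(params: MichaelisMentenParams,
                            enzyme_conc_nM: float,
                            spec: SimulationSpec,
                            pH: float = 8.0,
                            temperature_C: float = 40.0) -> RateDataset:
    """Hyperbolic velocity-vs-[S] data: v = kcat.[E].[S]/(Km+[S]) + noise."""
    if enzyme_conc_nM <= 0:
        raise InvalidParameterError("enzyme_conc_nM must be positive")
    s = np.asarray(spec.grid, dtype=float)
    if (s < 0).any():
        raise InvalidParameterError("substrate concentrations must be >= 0")
    v_true = params.velocity(s, enzyme_conc_nM)
    v = _noisy(v_true, spec)
    n = spec.n_replicates
    frame = pd.DataFrame({
        "substrate_name": params.substrate_name,
        "substrate_conc_mM": np.repeat(s, n),
        "pH": pH,
        "temperature_C": temperature_C,
        "enzyme_conc_nM": float(enzyme_conc_nM),
        "replicate": np.tile(np.arange(1, n + 1), len(s)),
        "velocity": v,
    })
    truth = {"kcat": params.kcat, "km_mM": params.km_mM,
             "kcat_over_km": params.kcat_over_km,
             "substrate_name": params.substrate_name,
             "enzyme_conc_nM": float(enzyme_conc_nM)}
    return RateDataset(frame[["substrate_name", "substrate_conc_mM", "pH",
                              "temperature_C", "enzyme_conc_nM", "replicate",
                              "velocity"]], ground_truth=truth)


def simulate_ph_profile(model: PHProfileModel,
                        spec: SimulationSpec) -> ProfileDataset:
    """k_obs-vs-pH data from the two-pKa bell, with noise and ground truth."""
    ph = np.asarray(spec.grid, dtype=float)
    if ph.min() < 2.0 or ph.max() > 12.0:
        raise InvalidParameterError("pH grid must lie within [2, 12]")
    k_true = predict_eq1(model, ph)
    k = _noisy(k_true, spec)
    n = spec.n_replicates
    frame = pd.DataFrame({
        "x_name": "pH",
        "x": np.repeat(ph, n),
        "replicate": np.tile(np.arange(1, n + 1), len(ph)),
        "value": k,
    })
    truth = {"k_lim": model.k_lim, "pka1": model.pka1, "pka2": model.pka2,
             "parameter_kind": model.parameter_kind}
    return ProfileDataset(frame, parameter_kind=model.parameter_kind,
                          ground_truth=truth)


_TEMP_SELECTORS = {"kcatKm_2a": ("eq2a", "kcatKm"),
                   "kcatKm_2b": ("eq2b", "kcatKm"),
                   "kcat_3": ("eq3", "kcat")}


def simulate_temperature_profile(rates, which: str,
                                 spec: SimulationSpec,
                                 pH: float = 8.0) -> ProfileDataset:
    """Temperature profile (grid in degC) from one of the three rate laws.

    ``which``: 'kcatKm_2a' (inactivation x Arrhenius), 'kcatKm_2b'
    (elementary-rate kcat/Km) or 'kcat_3' (elementary-rate kcat).
    """
    if which not in _TEMP_SELECTORS:
        raise InvalidSelectorError(
            f"unknown selector {which!r}; expected one of {sorted(_TEMP_SELECTORS)}"
        )
    eq, kind = _TEMP_SELECTORS[which]
    t_c = np.asarray(spec.grid, dtype=float)
    t_k = t_c + 273.15
    if (t_k <= 0).any():
        raise InvalidParameterError("temperatures not convertible to positive K")
    y_true = predict_temperature_model(rates, eq, t_k)
    y = _noisy(y_true, spec)
    n = spec.n_replicates
    frame = pd.DataFrame({
        "x_name": "temperature_C",
        "x": np.repeat(t_c, n),
        "replicate": np.tile(np.arange(1, n + 1), len(t_c)),
        "value": y,
    })
    truth = {"which": which, **{f: getattr(rates, f) for f in
                                rates.__dataclass_fields__}}
    return ProfileDataset(frame, parameter_kind=kind, pH=pH,
                          ground_truth=truth)


def simulate_thermostability(t50_C: float, steepness: float,
                             spec: SimulationSpec) -> ResidualActivityTable:
    """Residual activity after preincubation: a falling sigmoid in T.

    r(T) = 1/(1 + exp(steepness (T - t50))), noisy values clipped to [0, 1].
    """
    if steepness <= 0:
        raise InvalidParameterError("steepness must be positive")
    t = np.asarray(spec.grid, dtype=float)
    if t.min() < 0 or t.max() > 100:
        raise InvalidParameterError("temperature grid must lie within [0, 100] degC")
    r_true = 1.0 / (1.0 + np.exp(steepness * (t - t50_C)))
    rng = np.random.default_rng(spec.seed)
    if spec.noise_rel_sd == 0:
        r = r_true.copy()
    else:
        eps = rng.normal(0.0, spec.noise_rel_sd, size=r_true.shape)
        r = np.clip(r_true * (1.0 + eps), 0.0, 1.0)
    frame = pd.DataFrame({"preincubation_temp_C": t, "residual_activity": r})
    return ResidualActivityTable(frame, ground_truth={"t50_C": t50_C,
                                                      "steepness": steepness})


_NON_A_BACKGROUND = "CDEFGHIKLMNPQRSTVWY"
_NO_MOTIF_BACKGROUND = "CDEFIKLMNPQRTVWY"  # lacks A, G, S entirely


def simulate_protein(length: int, spec: SimulationSpec,
                     ala_fraction: float | None = None,
                     n_axxxa: int = 0, plant_elbow: bool = False,
                     identifier: str = "synthetic",
                     max_tries: int = 5000) -> SequenceRecord:
    """Random protein with a planted, re-scan-verified motif inventory.

    The planter samples candidates and verifies by re-scanning: a candidate
    is accepted only when count_axxxa == n_axxxa and the G-X-S-X-G match
    count equals plant_elbow.  When ``ala_fraction`` is given the alanine
    count is exact (round(ala_fraction * length)); otherwise alanines are
    laid down deterministically as a chain of n_axxxa+1 residues spaced four
    apart, which yields the requested motif count by construction.
    """
    if length < 10:
        raise InvalidParameterError("length must be >= 10")
    if n_axxxa < 0 or n_axxxa > length // 2:
        raise InfeasibleFixtureError(f"cannot plant {n_axxxa} AXXXA motifs in "
                                     f"{length} residues")
    rng = np.random.default_rng(spec.seed)
    elbow = "GHSQG"

    for _ in range(max_tries):
        if ala_fraction is None:
            seq = _plant_chain(length, n_axxxa, plant_elbow, elbow, rng)
        else:
            seq = _plant_rejection(length, ala_fraction, plant_elbow, elbow, rng)
        if seq is None:
            continue
        rec = SequenceRecord(identifier=identifier, residues=seq)
        if count_axxxa(rec) != n_axxxa:
            continue
        if len(scan_pentapeptide(rec)) != (1 if plant_elbow else 0):
            continue
        return rec
    raise InfeasibleFixtureError(
        f"could not realize n_axxxa={n_axxxa}, ala_fraction={ala_fraction}, "
        f"plant_elbow={plant_elbow} at length {length} within {max_tries} tries"
    )


def _plant_chain(length, n_axxxa, plant_elbow, elbow, rng):
    """Alanine-free background; A's planted as a chain i, i+4, ..., giving
    exactly n_axxxa overlapping motifs."""
    bg = _NO_MOTIF_BACKGROUND
    seq = list(rng.choice(list(bg), size=length))
    pos = 0
    if plant_elbow:
        start = int(rng.integers(0, length - 5 + 1))
        seq[start:start + 5] = list(elbow)
        pos = start + 5  # keep the alanine chain clear of the elbow
    if n_axxxa > 0:
        span = 4 * n_axxxa + 1
        if pos + span > length:
            if span > length:
                return None
            pos = 0 if not plant_elbow else None
            if pos is None:
                return None
        start = int(rng.integers(pos, length - span + 1))
        for j in range(n_axxxa + 1):
            seq[start + 4 * j] = "A"
    return "".join(seq)


def _plant_rejection(length, ala_fraction, plant_elbow, elbow, rng):
    """Exact alanine count at random positions over a G/S-free background;
    motif counts left to the accept/re-scan loop."""
    n_ala = int(round(ala_fraction * length))
    if n_ala > length:
        return None
    reserved = 0
    seq = list(rng.choice(list(_NO_MOTIF_BACKGROUND), size=length))
    if plant_elbow:
        start = int(rng.integers(0, length - 5 + 1))
        seq[start:start + 5] = list(elbow)
        free = [i for i in range(length) if i < start or i >= start + 5]
        reserved = 5
    else:
        free = list(range(length))
    if n_ala > length - reserved:
        return None
    ala_pos = rng.choice(free, size=n_ala, replace=False)
    for i in ala_pos:
        seq[i] = "A"
    return "".join(seq)


def attach_spec(dataset, spec: SimulationSpec):
    """Record the generating SimulationSpec inside the ground-truth bundle."""
    truth = dict(dataset.ground_truth or {})
    truth.update({"seed": spec.seed, "noise_rel_sd": spec.noise_rel_sd,
                  "n_replicates": spec.n_replicates})
    return replace(dataset, ground_truth=truth) if hasattr(dataset, "__dataclass_fields__") else dataset


__all__ = [
    "SimulationSpec", "simulate_velocity_curve", "simulate_ph_profile",
    "simulate_temperature_profile", "simulate_thermostability",
    "simulate_protein",
]
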