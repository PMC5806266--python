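"""End-to-end characterization pipeline.

``run_characterization`` drives the full study from a single configuration:
simulate or load the datasets, run the Michaelis-Menten, pH, temperature and
thermodynamic analyses plus the sequence scan, and collect everything into a
deterministic, serializable report.  Stages fail independently: an error in
one stage is recorded in the report and does not abort the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .datasets import (
    ProfileDataset,
    RateDataset,
    ResidualActivityTable,
    dataset_checksum,
)
from .exceptions import EnzkinError
from .mm import MichaelisMentenParams, compare_salt_effect, fit_michaelis_menten
from .ph import PHProfileModel, fit_ph_profile
from .seqfeatures import apply_cleavage, feature_report
from .simulate import (
    SimulationSpec,
    simulate_ph_profile,
    simulate_protein,
    simulate_temperature_profile,
    simulate_thermostability,
    simulate_velocity_curve,
)
from .temperature import (
    ElementaryRates,
    fit_temperature_profiles,
    temperature_optimum,
    thermostability_summary,
)
from .thermo import build_energy_diagram, eyring_fit

# Reference parameter sets used by the default all-simulation configuration.
# Michaelis-Menten truths mirror a chromogenic-ester assay panel (kcat s^-1,
# Km mM) at 850 nM enzyme for the short esters and 2200 nM for the laurate.
REFERENCE_MM = {
    "4-nitrophenyl acetate": dict(kcat=1.736e-3, km_mM=0.473, enzyme_nM=850.0),
    "4-nitrophenyl butyrate": dict(kcat=0.040, km_mM=1.926, enzyme_nM=850.0),
    "4-nitrophenyl laurate": dict(kcat=0.017, km_mM=0.349, enzyme_nM=2200.0),
}

REFERENCE_PH = {
    "4-nitrophenyl acetate": {
        "kcatKm": dict(k_lim=2.33, pka1=7.42, pka2=8.29),
        "kcat": dict(k_lim=1.33e-3, pka1=7.09, pka2=9.36),
    },
    "4-nitrophenyl butyrate": {
        "kcatKm": dict(k_lim=29.24, pka1=7.78, pka2=9.93),
        "kcat": dict(k_lim=44.78e-3, pka1=7.52, pka2=10.33),
    },
}

# Synthetic elementary-rate reference: E3 >> E2 pushes the kcat optimum above
# the kcat/Km optimum, reproducing the characteristic shift of the two
# temperature profiles.
REFERENCE_RATES = dict(k1_0=4.0, km1_0=1.3e-3, k2_0=4.0e-3, k3_0=3.0e-3,
                       e1=3.0e4, em1=1.2e5, e2=2.0e4, e3=7.5e4, t0=313.15)


@dataclass
class RunConfig:
    """Configuration for a full characterization run (all-simulation by
    default; any stage accepts a path to a delimited-text dataset instead)."""

    seed: int = 0
    noise_rel_sd: float = 0.03
    n_replicates: int = 8
    substrates: tuple = tuple(REFERENCE_MM)
    mm_grid_mM: tuple = (0.05, 0.1, 0.25, 0.5, 1.0, 2.0, 3.5, 5.0)
    ph_grid: tuple = tuple(np.round(np.linspace(6.0, 9.5, 25), 4))
    temp_grid_C: tuple = tuple(range(20, 76, 5))
    thermostability_grid_C: tuple = tuple(range(20, 71, 5))
    thermostability_threshold: float = 0.95
    thermostability_t50_C: float = 80.0
    thermostability_steepness: float = 0.35
    assay_pH: float = 8.0
    assay_temperature_C: float = 40.0
    sequence_length: int = 400
    sequence_cleavage_after: int = 29
    rate_table_paths: dict = field(default_factory=dict)  # substrate -> path
    sequence_fasta: Optional[str] = None
    output_dir: Optional[str] = None

    def stage_seed(self, label: str) -> int:
        """Derive a per-stage seed (< 2^31) from the master seed."""
        digest = hashlib.sha256(f"{self.seed}:{label}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class StageResult:
    name: str
    status: str  # ok | failed | skipped
    payload: object = None
    error: Optional[str] = None


@dataclass
class CharacterizationReport:
    config: RunConfig
    stages: dict
    provenance: dict

    def stage(self, name: str) -> StageResult:
        return self.stages[name]

    def to_text(self) -> str:
        lines = [f"# enzkin characterization report (v{self.provenance['version']})",
                 f"seed = {self.config.seed}",
                 f"config_hash = {self.provenance['config_hash']}"]
        for name, st in self.stages.items():
            lines.append(f"\n[{name}] status = {st.status}")
            if st.status == "failed":
                lines.append(f"error = {st.error}")
                continue
            if st.status == "skipped":
                continue
            lines.extend(_payload_lines(st.payload))
        return "\n".join(lines) + "\n"

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()

    def write(self, directory):
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "report.txt").write_text(self.to_text())
        return directory / "report.txt"


def _fmt(value) -> str:
    if isinstance(value, float):
        return f"{value:.12g}"
    return str(value)


def _payload_lines(payload, prefix=""):
    lines = []
    if dataclasses.is_dataclass(payload) and not isinstance(payload, type):
        payload = {f.name: getattr(payload, f.name)
                   for f in dataclasses.fields(payload)}
    if isinstance(payload, dict):
        for key in payload:
            val = payload[key]
            if isinstance(val, (dict, list, tuple)) or dataclasses.is_dataclass(val):
                lines.extend(_payload_lines(val, prefix=f"{prefix}{key}."))
            else:
                lines.append(f"{prefix}{key} = {_fmt(val)}")
    elif isinstance(payload, (list, tuple)):
        for i, val in enumerate(payload):
            lines.extend(_payload_lines(val, prefix=f"{prefix}{i}."))
    else:
        lines.append(f"{prefix.rstrip('.')} = {_fmt(payload)}")
    return lines


def _run_stage(name, fn, stages):
    try:
        stages[name] = StageResult(name=name, status="ok", payload=fn())
    except EnzkinError as exc:
        stages[name] = StageResult(name=name, status="failed",
                                   error=f"{type(exc).__name__}: {exc}")
    except FileNotFoundError as exc:
        stages[name] = StageResult(name=name, status="failed",
                                   error=f"IOError: {exc}")


def run_characterization(config: RunConfig) -> CharacterizationReport:
    """Execute every analysis stage; independent stages never abort each
    other.  Deterministic given ``config.seed``."""
    stages: dict = {}

    # --- Michaelis-Menten per substrate -------------------------------
    mm_results = {}

    def mm_stage():
        for sub in config.substrates:
            ref = REFERENCE_MM[sub]
            path = config.rate_table_paths.get(sub)
            if path is not None:
                data = RateDataset.from_csv(path)
            else:
                truth = MichaelisMenten_truth(sub)
                spec = SimulationSpec(seed=config.stage_seed(f"mm:{sub}"),
                                      grid=config.mm_grid_mM,
                                      noise_rel_sd=config.noise_rel_sd,
                                      n_replicates=config.n_replicates)
                data = simulate_velocity_curve(truth, ref["enzyme_nM"], spec,
                                               pH=config.assay_pH,
                                               temperature_C=config.assay_temperature_C)
            checksum = dataset_checksum(data)
            params = fit_michaelis_menten(data)
            assert dataset_checksum(data) == checksum, "stage mutated its input"
            mm_results[sub] = params
        return {sub: {"kcat_per_s": p.kcat, "km_mM": p.km_mM,
                      "kcat_over_km_per_M_per_s": p.kcat_over_km,
                      "kcat_se": p.kcat_se, "km_se": p.km_se}
                for sub, p in mm_results.items()}

    _run_stage("michaelis_menten", mm_stage, stages)

    # --- pH profiles ---------------------------------------------------
    ph_fits = {}

    def ph_stage():
        out = {}
        for sub, kinds in REFERENCE_PH.items():
            if sub not in config.substrates:
                continue
            for kind, pars in kinds.items():
                model = PHProfileModel(parameter_kind=kind, **pars)
                spec = SimulationSpec(
                    seed=config.stage_seed(f"ph:{sub}:{kind}"),
                    grid=config.ph_grid,
                    noise_rel_sd=config.noise_rel_sd,
                    n_replicates=config.n_replicates)
                profile = simulate_ph_profile(model, spec)
                fit = fit_ph_profile(profile)
                ph_fits[(sub, kind)] = fit
                out[f"{sub}:{kind}"] = {
                    "k_lim": fit.model.k_lim, "pKa1": fit.model.pka1,
                    "pKa2": fit.model.pka2, "pH_optimum": fit.ph_optimum,
                }
        for sub in set(s for s, _ in ph_fits):
            pair = {k: f for (s, k), f in ph_fits.items() if s == sub}
            if {"kcat", "kcatKm"} <= set(pair):
                out[f"{sub}:optimum_shift"] = (pair["kcat"].ph_optimum
                                               - pair["kcatKm"].ph_optimum)
        return out

    _run_stage("ph_dependence", ph_stage, stages)

    # --- temperature profiles and elementary rates --------------------
    rates_box = {}

    def temp_stage():
        truth = ElementaryRates(**REFERENCE_RATES)
        spec_km = SimulationSpec(seed=config.stage_seed("temp:kcatKm"),
                                 grid=config.temp_grid_C,
                                 noise_rel_sd=config.noise_rel_sd,
                                 n_replicates=config.n_replicates)
        spec_k = SimulationSpec(seed=config.stage_seed("temp:kcat"),
                                grid=config.temp_grid_C,
                                noise_rel_sd=config.noise_rel_sd,
                                n_replicates=config.n_replicates)
        prof_km = simulate_temperature_profile(truth, "kcatKm_2b", spec_km,
                                               pH=config.assay_pH)
        prof_k = simulate_temperature_profile(truth, "kcat_3", spec_k,
                                              pH=config.assay_pH)
        fit = fit_temperature_profiles(prof_km, prof_k,
                                       {"random_state": config.stage_seed("temp:fit")})
        rates_box["rates"] = fit.rates
        lo, hi = 273.15 + min(config.temp_grid_C), 273.15 + max(config.temp_grid_C)
        opt_km = temperature_optimum(fit.rates, "eq2b", (lo, hi))
        opt_k = temperature_optimum(fit.rates, "eq3", (lo, hi))
        return {
            "rates": {f: getattr(fit.rates, f)
                      for f in fit.rates.__dataclass_fields__},
            "identifiability_condition_number":
                fit.identifiability["condition_number"],
            "optimum_kcatKm_C": opt_km.temperature_C,
            "optimum_kcat_C": opt_k.temperature_C,
        }

    _run_stage("temperature_dependence", temp_stage, stages)

    # --- thermodynamics ------------------------------------------------
    def thermo_stage():
        rates = rates_box.get("rates")
        if rates is None:
            raise EnzkinError("temperature stage did not produce rates")
        t_k = np.array(config.temp_grid_C, dtype=float) + 273.15
        thermo_k2 = eyring_fit(list(zip(t_k, rates.k2(t_k))))
        thermo_k3 = eyring_fit(list(zip(t_k, rates.k3(t_k))))
        diagram = build_energy_diagram(rates, t=313.15)
        return {
            "k2_dH_J_per_mol": thermo_k2.dh, "k2_dS_J_per_mol_K": thermo_k2.ds,
            "k2_dG_313K_J_per_mol": float(thermo_k2.dg_at(313.15)),
            "k3_dH_J_per_mol": thermo_k3.dh, "k3_dS_J_per_mol_K": thermo_k3.ds,
            "diagram_levels_kcal": diagram.levels,
        }

    _run_stage("thermodynamics", thermo_stage, stages)

    # --- thermostability -----------------------------------------------
    def thermostab_stage():
        # residual activity is a ratio of replicate-averaged activities, so
        # its relative noise scales as 1/sqrt(n_replicates)
        spec = SimulationSpec(seed=config.stage_seed("thermostability"),
                              grid=config.thermostability_grid_C,
                              noise_rel_sd=config.noise_rel_sd
                              / np.sqrt(config.n_replicates),
                              n_replicates=1)
        table = simulate_thermostability(config.thermostability_t50_C,
                                         config.thermostability_steepness, spec)
        top = thermostability_summary(table, config.thermostability_threshold)
        return {"max_full_activity_C": top if top is not None else "none",
                "threshold": config.thermostability_threshold}

    _run_stage("thermostability", thermostab_stage, stages)

    # --- salt effects (reference arithmetic on the acetate fit) --------
    def salt_stage():
        control = mm_results.get("4-nitrophenyl acetate")
        if control is None:
            raise EnzkinError("no control Michaelis-Menten fit available")
        # NaCl halves kcat at unchanged Km; divalent salts raise Km ~150%.
        treated_nacl = MichaelisMentenParams(control.substrate_name,
                                             control.kcat * 0.5, control.km_mM)
        treated_ca = MichaelisMentenParams(control.substrate_name,
                                           control.kcat * 0.7,
                                           control.km_mM * 1.5)
        reports = [compare_salt_effect(control, treated_nacl, "NaCl", 10.0),
                   compare_salt_effect(control, treated_ca, "CaCl2", 10.0)]
        return {f"{r.salt}@{r.concentration_mM:g}mM": {
            "ratio_kcatKm_pct": r.ratio_kcatKm, "ratio_kcat_pct": r.ratio_kcat,
            "ratio_Km_pct": r.ratio_Km} for r in reports}

    _run_stage("salt_effects", salt_stage, stages)

    # --- sequence ------------------------------------------------------
    def seq_stage():
        if config.sequence_fasta is not None:
            from .seqfeatures import read_fasta
            precursor = read_fasta(config.sequence_fasta)[0]
        else:
            spec = SimulationSpec(seed=config.stage_seed("sequence"),
                                  grid=(0.0,), noise_rel_sd=0.0, n_replicates=1)
            mature = simulate_protein(
                length=config.sequence_length - config.sequence_cleavage_after,
                spec=spec, ala_fraction=0.167, n_axxxa=9, plant_elbow=True,
                identifier="synthetic-lipase")
            signal_spec = SimulationSpec(seed=config.stage_seed("sequence:signal"),
                                         grid=(0.0,), noise_rel_sd=0.0,
                                         n_replicates=1)
            signal = simulate_protein(length=config.sequence_cleavage_after,
                                      spec=signal_spec, n_axxxa=0,
                                      identifier="signal")
            from .seqfeatures import SequenceRecord
            precursor = SequenceRecord("synthetic-lipase-precursor",
                                       signal.residues + mature.residues)
        mature_rec = apply_cleavage(precursor, config.sequence_cleavage_after)
        rep_pre = feature_report(precursor,
                                 cleavage_index=config.sequence_cleavage_after)
        rep_mat = feature_report(mature_rec)
        return {
            "precursor": {"length": rep_pre.length,
                          "avg_mass_kDa": rep_pre.avg_mass_Da / 1e3,
                          "pI": rep_pre.pI,
                          "ala_percent": rep_pre.ala_percent},
            "mature": {"length": rep_mat.length,
                       "avg_mass_kDa": rep_mat.avg_mass_Da / 1e3,
                       "pI": rep_mat.pI,
                       "ala_percent": rep_mat.ala_percent,
                       "axxxa_count": rep_mat.axxxa_count,
                       "elbow_matches": len(rep_mat.elbow_matches)},
        }

    _run_stage("sequence_features", seq_stage, stages)

    if all(st.status == "failed" for st in stages.values()):
        raise EnzkinError("every pipeline stage failed")

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(repr(config).encode()).hexdigest()[:16],
    }
    report = CharacterizationReport(config=config, stages=stages,
                                    provenance=provenance)
    if config.output_dir:
        report.write(config.output_dir)
    return report


def MichaelisMenten_truth(substrate: str) -> MichaelisMentenParams:
    ref = REFERENCE_MM[substrate]
    return MichaelisMentenParams(substrate_name=substrate, kcat=ref["kcat"],
                                 km_mM=ref["km_mM"])


def read_rate_table(path) -> RateDataset:
    """Read the delimited-text RateDataset dialect (schema-validated)."""
    return RateDataset.from_csv(path)


def write_report(report: CharacterizationReport, directory):
    return report.write(directory)
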