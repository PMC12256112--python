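"""Packaged default parameter sets for every experimental condition."""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .kinetics import ConditionSpec, KineticParams
from .simulate import AcquisitionParams, BulkAssayParams, FretLevels, ProcessingParams


@lru_cache(maxsize=1)
def load_defaults() -> dict:
    """The raw packaged default table (parsed JSON)."""
    with resources.files("proteofret.data").joinpath("paper_defaults.json").open() as fh:
        return json.load(fh)


def default_acquisition() -> AcquisitionParams:
    a = load_defaults()["acquisition"]
    return AcquisitionParams(
        frame_interval=a["frame_interval_s"], n_frames=a["n_frames"],
        total_intensity=a["total_intensity"], noise_sd=a["noise_sd"],
        background=a["background"], donor_bleach_mean=a["donor_bleach_mean_s"],
        acceptor_bleach_mean=a["acceptor_bleach_mean_s"],
    )


def default_fret_levels() -> FretLevels:
    f = load_defaults()["fret_levels"]
    return FretLevels(E_s1=f["E_s1"], E_ns1=f["E_ns1"])


def dynamics_condition(name: str) -> ConditionSpec:
    d = load_defaults()["dynamics"]
    if name not in d:
        raise KeyError(f"unknown dynamics condition {name!r}; have {sorted(d)}")
    c = d[name]
    return ConditionSpec(label=name, ligand_conc=c["ligand_conc_uM"],
                         k_f=c["k_f"], k_b=c["k_b"])


def titration_params() -> KineticParams:
    t = load_defaults()["titration"]
    return KineticParams(k_f_apo=t["k_f_apo"], k_f_sat=t["k_f_sat"],
                         k_b=load_defaults()["dynamics"]["WT"]["k_b"],
                         K_D_app=t["K_D_app_uM"])


def processing_condition(name: str) -> ProcessingParams:
    d = load_defaults()["processing"]
    if name not in d:
        raise KeyError(f"unknown processing condition {name!r}; have {sorted(d)}")
    c = d[name]
    return ProcessingParams(p_success=c["p_success"],
                            tau_ins_mean=c["tau_ins_mean_s"])


def bulk_condition(name: str, assay: str = "bulk_degradation") -> BulkAssayParams:
    block = load_defaults()[assay]
    conds = block["conditions"]
    if name not in conds:
        raise KeyError(f"unknown {assay} condition {name!r}; have {sorted(conds)}")
    return BulkAssayParams(
        enzyme_conc=block["enzyme_conc_nM"],
        substrate_conc=block["substrate_conc_uM"],
        rate_per_enzyme=conds[name]["rate_per_enzyme"],
        fp_intact=block["fp_intact_mP"], fp_degraded=block["fp_degraded_mP"],
        fp_noise_sd=block["fp_noise_sd_mP"],
        sample_interval=block["sample_interval_min"],
        duration=block["duration_min"],
    )
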