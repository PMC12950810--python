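"""Run configuration for the ventricular myocyte simulations."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .model import CELLTYPE_ENDO, CELLTYPE_EPI, CELLTYPE_M, pack_params

__all__ = ["OrdConfig", "load_config", "validate_config"]

_CELLTYPES = {"endo": CELLTYPE_ENDO, "epi": CELLTYPE_EPI, "mid": CELLTYPE_M}


@dataclass(frozen=True)
class OrdConfig:
    """Configuration of one myocyte simulation.

    Defaults are this study's baseline: midmyocardial cell, cycle
    length 1000 ms, normokalemia (5.4 mM), L-type Ca2+ permeability
    scaled to 0.8, full I_Kr conductance, no beta-adrenergic tone.
    """

    cell_type: str = "mid"
    cycle_length: float = 1000.0    # ms
    n_beats: int = 1000             # pre-pacing cap
    k_o: float = 5.4                # mM extracellular K+
    g_kr_scale: float = 1.0         # 0.31 emulates the variant channels
    p_ca_scale: float = 0.8         # study baseline calibration
    beta_as: bool = False           # 1 uM isoproterenol effect set
    i_ca_act_shift: float = -3.0    # mV, I_CaL activation shift under beta-AS
    i_ca_inact_shift: float = -2.8  # mV, I_CaL inactivation shift under beta-AS
    iso_ical_factor: float = 2.5
    iso_gks_factor: float = 3.2
    iso_inak_factor: float = 1.3
    iso_kmup_factor: float = 0.54
    iso_kmtrpn_factor: float = 1.6
    stim_amplitude: float = -80.0   # uA/uF
    stim_duration: float = 0.5      # ms
    dt: float = 0.005               # ms integration step
    record_interval: float = 0.5    # ms output sampling
    convergence_tol: float = 1e-6   # beat-to-beat relative L2 state change
    ead_delta_mv: float = 1.0       # EAD detection threshold
    ead_floor_mv: float = -40.0     # repolarization level ending EAD search
    ead_blank_ms: float = 100.0     # skip upstroke/notch/dome at beat start

    def __post_init__(self):
        if self.cell_type not in _CELLTYPES:
            raise ValueError(f"cell_type must be one of {list(_CELLTYPES)}")
        for name in ("g_kr_scale", "p_ca_scale"):
            val = getattr(self, name)
            if not (0.0 <= val <= 2.0):
                raise ValueError(f"{name}={val} outside (0, 2]")
        if self.k_o <= 0:
            raise ValueError("k_o must be positive")
        if self.cycle_length <= self.stim_duration:
            raise ValueError("cycle_length must exceed stimulus duration")
        if self.dt <= 0 or self.record_interval < self.dt:
            raise ValueError("need dt > 0 and record_interval >= dt")

    def params(self) -> np.ndarray:
        return pack_params(
            ko=self.k_o, gkr_scale=self.g_kr_scale, pca_scale=self.p_ca_scale,
            iso=self.beta_as, d_shift=self.i_ca_act_shift,
            f_shift=self.i_ca_inact_shift, iso_ical=self.iso_ical_factor,
            iso_gks=self.iso_gks_factor, iso_inak=self.iso_inak_factor,
            iso_kmup=self.iso_kmup_factor, iso_kmtrpn=self.iso_kmtrpn_factor,
            stim_amplitude=self.stim_amplitude,
            stim_duration=self.stim_duration,
            celltype=_CELLTYPES[self.cell_type])

    def replace(self, **kw) -> "OrdConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


def validate_config(data: dict | None) -> OrdConfig:
    """Build a config from a plain mapping, reporting every unknown or
    invalid field by name.  An empty mapping yields the full defaults."""
    data = dict(data or {})
    known = set(OrdConfig.__dataclass_fields__)
    errors = [f"unknown field: {k}" for k in data if k not in known]
    if errors:
        raise ValueError("; ".join(errors))
    try:
        return OrdConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(str(exc)) from exc


def load_config(path) -> OrdConfig:
    """Load a YAML config file; missing fields take defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return validate_config(data)
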