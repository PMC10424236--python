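"""Run configuration: validated YAML blocks covering every stage.

Defaults encode the production protocol: umbrella force constant
5000 kJ/mol/nm^2, window centres 2-7 nm at 0.1 nm spacing, reference
separation 7.0 nm, 300 K, a 15.0 nm cubic box and 0.1 M salt.  Presets
name the four studied systems (L24Na, L24Ca, R65Na, R65Ca), a
desk-scale smoke variant and the two-charged-bead analytic oracle.
Unknown keys are rejected at load time.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "SystemBlock", "SamplingBlock", "WhamBlock",
           "AnalysisBlock", "ForceFieldBlock", "ConfigError", "load_config",
           "save_config", "preset", "PRESETS"]


class ConfigError(ValueError):
    """Configuration violates the schema; the message names the key."""


def _from_dict(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"{context}: unknown key(s) {sorted(unknown)}; allowed: {sorted(known)}"
        )
    return cls(**data)


@dataclass
class SystemBlock:
    topology: str = "linear"  # linear | ring | point
    n_bp: int = 24
    counterion_valence: int = 1
    salt_molar: float = 0.1
    box_edge_nm: float = 15.0
    rise_nm: float = 0.338
    bead_radius_nm: float = 1.0
    point_charge: float = -2.0  # only for topology == "point"
    include_ions: bool = True

    def validate(self) -> None:
        if self.topology not in ("linear", "ring", "point"):
            raise ConfigError(
                f"system.topology: {self.topology!r} not in linear|ring|point"
            )
        if self.counterion_valence not in (1, 2):
            raise ConfigError("system.counterion_valence: must be 1 or 2")
        if self.salt_molar < 0:
            raise ConfigError("system.salt_molar: must be >= 0")
        if self.box_edge_nm <= 0:
            raise ConfigError("system.box_edge_nm: must be > 0")


@dataclass
class SamplingBlock:
    r_min: float = 2.0
    r_max: float = 7.0
    spacing: float = 0.1
    force_k: float = 5000.0
    n_equil_sweeps: int = 5_000
    n_prod_sweeps: int = 50_000
    sample_stride: int = 10
    frame_stride: int = 0  # 0 = no frames
    seed: int = 2024

    def validate(self) -> None:
        from .simulate import make_schedule

        try:
            make_schedule(self.r_min, self.r_max, self.spacing,
                          max(self.force_k, 1e-9))
        except ValueError as exc:
            raise ConfigError(f"sampling: {exc}") from exc
        if self.n_prod_sweeps % self.sample_stride:
            raise ConfigError(
                "sampling.sample_stride: must divide n_prod_sweeps"
            )


@dataclass
class WhamBlock:
    bin_width: float = 0.05
    bin_min: float = 1.8
    bin_max: float = 7.2
    tol: float = 1e-7
    max_iter: int = 100_000
    reference_r: float = 7.0
    temperature: float = 300.0
    n_boot: int = 0  # 0 = no bootstrap errors

    def validate(self) -> None:
        if self.bin_min >= self.bin_max or self.bin_width <= 0:
            raise ConfigError("wham: bins must satisfy bin_min < bin_max, width > 0")
        if not (self.bin_min <= self.reference_r < self.bin_max):
            raise ConfigError("wham.reference_r: outside the binned range")


@dataclass
class AnalysisBlock:
    rdf_bin_width: float = 0.05
    rdf_r_max: float = 5.0
    kde_grid_r: int = 101
    kde_grid_theta: int = 91

    def validate(self) -> None:
        if self.rdf_bin_width <= 0 or self.rdf_r_max <= 0:
            raise ConfigError("analysis: rdf bins must be positive")


@dataclass
class ForceFieldBlock:
    bond_k: float = 50_000.0
    bend_k: float = 369.0
    wca_sigma: float = 0.3
    wca_epsilon: float = 2.494
    bjerrum_length: float = 0.7
    debye_length: float = 0.0
    temperature: float = 300.0
    coulomb_cutoff: float | None = None

    def validate(self) -> None:
        from .simulate import ForceFieldParams

        try:
            self.to_params()
        except ValueError as exc:
            raise ConfigError(f"forcefield: {exc}") from exc

    def to_params(self):
        from .simulate import ForceFieldParams

        cutoff = self.coulomb_cutoff
        if isinstance(cutoff, str):
            cutoff = float(cutoff)
        return ForceFieldParams(
            bond_k=self.bond_k, bend_k=self.bend_k, wca_sigma=self.wca_sigma,
            wca_epsilon=self.wca_epsilon, bjerrum_length=self.bjerrum_length,
            debye_length=self.debye_length, temperature=self.temperature,
            coulomb_cutoff=cutoff,
        )


@dataclass
class RunConfig:
    system: SystemBlock = field(default_factory=SystemBlock)
    sampling: SamplingBlock = field(default_factory=SamplingBlock)
    wham: WhamBlock = field(default_factory=WhamBlock)
    analysis: AnalysisBlock = field(default_factory=AnalysisBlock)
    forcefield: ForceFieldBlock = field(default_factory=ForceFieldBlock)

    def validate(self) -> "RunConfig":
        for block in (self.system, self.sampling, self.wham, self.analysis,
                      self.forcefield):
            block.validate()
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError("top level: expected a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(
                f"top level: unknown key(s) {sorted(unknown)}; "
                f"allowed: {sorted(known)}"
            )
        cfg = cls(
            system=_from_dict(SystemBlock, data.get("system", {}), "system"),
            sampling=_from_dict(SamplingBlock, data.get("sampling", {}), "sampling"),
            wham=_from_dict(WhamBlock, data.get("wham", {}), "wham"),
            analysis=_from_dict(AnalysisBlock, data.get("analysis", {}), "analysis"),
            forcefield=_from_dict(ForceFieldBlock, data.get("forcefield", {}),
                                  "forcefield"),
        )
        return cfg.validate()


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML config; an empty file yields the
    full default configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def _table1_system(topology: str, n_bp: int, valence: int) -> dict:
    return {"system": {"topology": topology, "n_bp": n_bp,
                       "counterion_valence": valence}}


PRESETS: dict[str, dict] = {
    # the four studied 0.1 M systems at the production protocol
    "L24Na": _table1_system("linear", 24, 1),
    "L24Ca": _table1_system("linear", 24, 2),
    "R65Na": _table1_system("ring", 65, 1),
    "R65Ca": _table1_system("ring", 65, 2),
    # desk-scale smoke variant: 3 closely spaced windows, short chains;
    # half the production spacing so the thin k = 5000 histograms still
    # overlap at this tiny sample count
    "L24Na-smoke": {
        "system": {"topology": "linear", "n_bp": 24, "counterion_valence": 1},
        "sampling": {"r_min": 2.0, "r_max": 2.1, "spacing": 0.05,
                     "n_equil_sweeps": 80, "n_prod_sweeps": 240,
                     "sample_stride": 4, "frame_stride": 40},
        "wham": {"bin_width": 0.025, "bin_min": 1.85, "bin_max": 2.35,
                 "reference_r": 2.1},
    },
    # two isolated charged beads: the analytic pair-potential oracle
    "two-bead-oracle": {
        "system": {"topology": "point", "include_ions": False,
                   "salt_molar": 0.0, "point_charge": -2.0,
                   "box_edge_nm": 30.0},
        # soft k = 250 restraints: adjacent windows overlap by ~60 %,
        # which keeps the WHAM stitching error well below the analytic
        # tolerance for this two-particle toy
        "sampling": {"r_min": 2.0, "r_max": 7.0, "spacing": 0.1,
                     "force_k": 250.0, "n_equil_sweeps": 300,
                     "n_prod_sweeps": 10_000, "sample_stride": 5},
        "forcefield": {"coulomb_cutoff": float("inf")},
        # wider bins than the production ladder: the softer k = 1000
        # restraint spreads each window over ~0.05 nm
        "wham": {"reference_r": 7.0, "bin_min": 1.6, "bin_max": 7.4},
    },
}


def preset(name: str) -> RunConfig:
    """Named configuration preset (see :data:`PRESETS`)."""
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return RunConfig.from_dict(PRESETS[name])
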