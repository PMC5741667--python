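"""Pipeline configuration: flat key = value files with strict validation.

Unknown keys are rejected by name (catching typos like ``kmer`` for
``k``), defaults follow the module-level conventions (k = 25, consensus
floor 1000 nt), and every referenced input path must resolve at
validation time, before any stage runs.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

from .errors import ConfigError
from .io import read_flat_config


def _bool(v: str) -> bool:
    s = str(v).strip().lower()
    if s in ("1", "true", "yes", "on"):
        return True
    if s in ("0", "false", "no", "off"):
        return False
    raise ValueError(f"not a boolean: {v!r}")


@dataclass
class PipelineConfig:
    outdir: str = "repeatburst_run"
    seed: int = 0
    # stage toggles
    run_simulate: bool = True
    run_assemble: bool = True
    run_landscape: bool = True
    run_tau: bool = True
    run_mirna: bool = True
    run_genomesize: bool = True
    # optional external inputs (simulated when absent)
    genome: str = ""
    reference_library: str = ""
    expression: str = ""
    # repeat assembly
    k: int = 25
    min_count: int = 10
    min_length: int = 1000
    max_length: int = 20000
    # landscape
    min_identity: float = 0.7
    min_mutual_coverage: float = 0.8
    mixture_margin: float = 10.0
    # expression
    tau_floor: float = 1.0
    # miRNA
    max_mismatches: int = 1
    # simulation scale
    background_length: int = 250000
    te_master_length: int = 2000
    te_rate: float = 0.15
    te_burst_ages: str = "0.1,0.6"
    te_copies_per_burst: str = "20,20"
    continuous_family: bool = True
    continuous_copies: int = 16
    n_genes: int = 300
    n_tissues: int = 9
    frac_specific: float = 0.2
    fold_effect: float = 8.0
    dispersion: float = 0.3
    true_2c_pg: float = 39.64
    cytometry_noise_sd: float = 0.0

    def burst_ages(self) -> list[float]:
        return [float(x) for x in self.te_burst_ages.split(",") if x.strip()]

    def copies_per_burst(self) -> list[int]:
        return [int(x) for x in self.te_copies_per_burst.split(",") if x.strip()]


_PATH_KEYS = ("genome", "reference_library", "expression")


def validate_config(path) -> PipelineConfig:
    """Parse and validate a flat config file into a PipelineConfig."""
    path = Path(path)
    if not path.is_file():
        raise ConfigError(f"config file not found: {path}")
    raw = read_flat_config(path)
    known = {f.name: f.type for f in fields(PipelineConfig)}
    cfg = PipelineConfig()
    for key, value in raw.items():
        if key not in known:
            raise ConfigError(f"unknown config key '{key}'")
        current = getattr(cfg, key)
        try:
            if isinstance(current, bool):
                parsed = _bool(value)
            elif isinstance(current, int):
                parsed = int(value)
            elif isinstance(current, float):
                parsed = float(value)
            else:
                parsed = value
        except ValueError as exc:
            raise ConfigError(f"config key '{key}': {exc}") from exc
        setattr(cfg, key, parsed)

    if cfg.k % 2 == 0:
        raise ConfigError(f"config key 'k': must be odd (got {cfg.k})")
    if not 11 <= cfg.k <= 31:
        raise ConfigError(f"config key 'k': must lie in [11, 31] (got {cfg.k})")
    if cfg.min_count < 2:
        raise ConfigError("config key 'min_count': must be >= 2")
    if len(cfg.burst_ages()) != len(cfg.copies_per_burst()):
        raise ConfigError(
            "config keys 'te_burst_ages'/'te_copies_per_burst': lengths differ"
        )
    base = path.parent
    for key in _PATH_KEYS:
        value = getattr(cfg, key)
        if value:
            p = (base / value).resolve() if not Path(value).is_absolute() else Path(value)
            if not p.is_file():
                raise ConfigError(f"config key '{key}': path not found: {value}")
            setattr(cfg, key, str(p))
    out = Path(cfg.outdir)
    if not out.is_absolute():
        cfg.outdir = str((base / out).resolve())
    return cfg
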