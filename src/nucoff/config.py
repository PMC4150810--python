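"""Flat key-value run configuration and reproducible TSV emission.

A run config is a flat YAML mapping whose keys carry their units
(``target_off_per_s``, ``kd_full_nM``, ``ddg_min_kBT``, ...).  ``run_config``
resolves the defaults, executes the requested scan and writes a TSV whose
``#``-prefixed header embeds the package version, the seed and every
resolved key, so any output file is reproducible from its own header.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dimeric import ddg_scan, fit_naked_dimeric
from .landscape import FreeEnergyLandscape, load_landscape, synthetic_landscape
from .nonspecific import default_K_grid, default_k1_grid, scan_nonspecific

__all__ = ["RunConfig", "load_config", "run_config", "write_tsv_with_header"]


@dataclass
class RunConfig:
    """Resolved configuration for a dimeric or non-specific scan."""

    model: str = "dimeric"
    seed: int = 0
    # naked-DNA fit inputs
    target_off_per_s: float = 0.0034
    ratio: float = 1000.0
    kd_full_nM: float = 0.07
    # dimeric scan grid
    ddg_min_kBT: float = 5.0
    ddg_max_kBT: float = 7.0
    ddg_step_kBT: float = 0.25
    n_full_bp: int = 34
    n_part_bp: int = 19
    conc_nM: float = 0.0
    # non-specific scan
    K_values: list | None = None
    k1_values_per_s: list | None = None
    d_min_bp: int = 0
    d_max_bp: int = 21
    conc_values_nM: list = field(default_factory=lambda: [0.0])
    L_bp: int = 147
    site_start_bp: int = 8
    site_end_bp: int = 27
    # landscape source: a file, or synthetic parameters
    landscape_file: str | None = None
    landscape_total_kBT: float = 35.0
    landscape_n_max_bp: int = 147
    landscape_shape: str = "linear"
    k0_per_s: float = 1e5

    def landscape(self) -> FreeEnergyLandscape:
        if self.landscape_file:
            return load_landscape(self.landscape_file)
        return synthetic_landscape(
            n_max=self.landscape_n_max_bp,
            total_dG=self.landscape_total_kBT,
            shape=self.landscape_shape,
        )


def load_config(path) -> RunConfig:
    """Read a flat YAML mapping; unknown keys are an error listing them."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    return RunConfig(**raw)


def _header_lines(cfg: RunConfig) -> list[str]:
    lines = [f"# nucoff {__version__}"]
    for f in dataclasses.fields(RunConfig):
        lines.append(f"# {f.name} = {getattr(cfg, f.name)!r}")
    return lines


def write_tsv_with_header(df: pd.DataFrame, cfg: RunConfig, path_or_buf) -> None:
    buf = io.StringIO()
    for line in _header_lines(cfg):
        buf.write(line + "\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.10g")
    text = buf.getvalue()
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def run_config(cfg: RunConfig, out=None) -> pd.DataFrame:
    """Execute the configured scan; optionally write the headered TSV."""
    if cfg.model == "dimeric":
        params = fit_naked_dimeric(
            target_off=cfg.target_off_per_s, ratio=cfg.ratio, kd_full=cfg.kd_full_nM
        )
        ddg = np.arange(cfg.ddg_min_kBT, cfg.ddg_max_kBT + 1e-9, cfg.ddg_step_kBT)
        df = ddg_scan(
            params,
            ddg_values=ddg,
            n_full=cfg.n_full_bp,
            n_part=cfg.n_part_bp,
            conc=cfg.conc_nM,
            k0=cfg.k0_per_s,
        )
    elif cfg.model == "nonspecific":
        K_values = (
            default_K_grid() if cfg.K_values is None else np.asarray(cfg.K_values, float)
        )
        k1_values = (
            default_k1_grid()
            if cfg.k1_values_per_s is None
            else np.asarray(cfg.k1_values_per_s, float)
        )
        df = scan_nonspecific(
            cfg.landscape(),
            K_values=K_values,
            k1_values=k1_values,
            d_values=range(cfg.d_min_bp, cfg.d_max_bp + 1),
            conc_values=tuple(cfg.conc_values_nM),
            L=cfg.L_bp,
            site_start=cfg.site_start_bp,
            site_end=cfg.site_end_bp,
            target_off=cfg.target_off_per_s,
            k0=cfg.k0_per_s,
        )
    else:
        raise ValueError(f"unknown model {cfg.model!r}; use 'dimeric' or 'nonspecific'")
    if out is not None:
        write_tsv_with_header(df, cfg, out)
    return df
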