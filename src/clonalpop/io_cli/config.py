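"""YAML run configuration with strict key validation."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

from ..synthetic_data import (
    GeneModel,
    SimulationConfig,
    default_config,
    default_gene_models,
    default_schedule,
)

logger = logging.getLogger(__name__)

__all__ = ["load_config", "build_simulation_config"]

_TOP_KEYS = {"seed", "log_level", "paths", "simulation", "entropy", "clades", "abundance"}
_SIM_KEYS = {
    "genes",
    "n_clades",
    "founder_divergence_nt",
    "mu",
    "generations_per_interval",
    "schedule",
    "n_years",
    "trough_log10",
    "sample_sizes",
    "effective_size_cap",
    "lod",
    "founder_weights",
    "allow_extinction",
    "abundance_replicate_sd",
    "abundance_n_replicates",
}
_ENTROPY_KEYS = {"base", "test", "alternative", "group_map"}
_CLADES_KEYS = {"cut_identity", "linkage"}
_ABUNDANCE_KEYS = {"lod", "high_margin", "intermediate_threshold"}


def _check_keys(block: Mapping[str, Any], allowed: set[str], name: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")


def load_config(path: str | Path) -> dict[str, Any]:
    """Load and validate a YAML run configuration; unknown keys reject."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top-level")
    for key, allowed in (
        ("simulation", _SIM_KEYS),
        ("entropy", _ENTROPY_KEYS),
        ("clades", _CLADES_KEYS),
        ("abundance", _ABUNDANCE_KEYS),
    ):
        block = raw.get(key) or {}
        if not isinstance(block, dict):
            raise ValueError(f"{path}: {key} block must be a mapping")
        _check_keys(block, allowed, key)
    logger.info("effective config from %s: %s", path, raw)
    return raw


def build_simulation_config(block: Mapping[str, Any], seed: int) -> SimulationConfig:
    """Turn the `simulation` config block into a SimulationConfig.

    Omitted fields fall back to the packaged default population (default
    gene roster, 8 founder clades, 12-year two-season schedule).
    """
    base = default_config(seed=seed, n_years=int(block.get("n_years", 12)))
    genes = base.genes
    if "genes" in block:
        genes = tuple(
            GeneModel(g["name"], int(g["cds_length_nt"]), float(g["constrained_fraction"]))
            for g in block["genes"]
        )
    if "schedule" in block:
        schedule = tuple((str(lbl), float(lvl)) for lbl, lvl in block["schedule"])
    else:
        schedule = base.seasonal_log10_peaks
    sample_sizes = dict(block.get("sample_sizes", base.sample_sizes))
    weights = block.get("founder_weights")
    return SimulationConfig(
        genes=genes,
        n_clades=int(block.get("n_clades", base.n_clades)),
        founder_divergence_nt=int(block.get("founder_divergence_nt", base.founder_divergence_nt)),
        mu=float(block.get("mu", base.mu)),
        generations_per_interval=int(
            block.get("generations_per_interval", base.generations_per_interval)
        ),
        seasonal_log10_peaks=schedule,
        trough_log10=float(block.get("trough_log10", base.trough_log10)),
        sample_sizes={str(k): int(v) for k, v in sample_sizes.items()},
        effective_size_cap=int(block.get("effective_size_cap", base.effective_size_cap)),
        lod=float(block.get("lod", base.lod)),
        seed=seed,
        founder_weights=tuple(float(w) for w in weights) if weights else None,
        allow_extinction=bool(block.get("allow_extinction", False)),
    )
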