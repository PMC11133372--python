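"""Loading and saving of simulator / experiment configurations.

Two frozen configurations ship with the package under ``data/``:

* ``staining.yaml`` — the calibrated single-clone FCM configuration
  used for affinity-panel blocking readouts;
* ``experiment.yaml`` — the 14-clone binning experiment (0.1 nM and
  10 nM staining for both reference antibodies).
"""

from __future__ import annotations

from dataclasses import asdict
from importlib import resources
from pathlib import Path

import yaml

from .cytometry import SimConfig
from .workflow import Condition, ExperimentConfig

__all__ = [
    "load_sim_config",
    "load_experiment_config",
    "staining_sim_config",
    "default_experiment_config",
    "save_sim_config",
]


def _data_text(name: str) -> str:
    return (resources.files("epibinseq") / "data" / name).read_text()


def sim_config_from_dict(d: dict) -> SimConfig:
    return SimConfig(**d)


def load_sim_config(path) -> SimConfig:
    return sim_config_from_dict(yaml.safe_load(Path(path).read_text()))


def save_sim_config(config: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def staining_sim_config() -> SimConfig:
    """The frozen calibrated single-clone staining configuration."""
    return sim_config_from_dict(yaml.safe_load(_data_text("staining.yaml")))


def experiment_config_from_dict(d: dict) -> ExperimentConfig:
    conditions = tuple(
        Condition(c["sample_id"], c["rab"], float(c["concentration"]))
        for c in d.get("conditions", [])
    )
    return ExperimentConfig(
        sim=sim_config_from_dict(d.get("sim", {})),
        conditions=conditions,
        binning_samples=tuple(d.get("binning_samples", [])),
        library_sample=d.get("library_sample", "library"),
        n_reads=int(d.get("n_reads", 100_000)),
        negative_control=d.get("negative_control", "Niv"),
        threshold=float(d.get("threshold", 3.0)),
    )


def load_experiment_config(path) -> ExperimentConfig:
    return experiment_config_from_dict(yaml.safe_load(Path(path).read_text()))


def default_experiment_config() -> ExperimentConfig:
    """The shipped 14-clone binning experiment."""
    return experiment_config_from_dict(yaml.safe_load(_data_text("experiment.yaml")))
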