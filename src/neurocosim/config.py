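"""Run configuration: YAML schema, defaults, seeding and provenance.

A run configuration is a nested mapping with sections ``neuron``,
``micro``, ``macro``, ``coupling``, ``analysis`` and ``io``; every field
has a default taken from the corresponding dataclass, so an empty file is
a valid configuration.  One global seed is split into independent
per-module seeds through :func:`numpy.random.SeedSequence` spawning, so
sub-runs are reproducible in isolation.

Every command echoes the fully resolved configuration (plus derived seeds
and the package version) into the output directory as ``provenance.yaml``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .connectome import SyntheticConnectomeSpec
from .coupling import CalciumParams, TranslationConfig
from .ion_neuron import ClassifierConfig, IonNeuronParams
from .macro_rww import RwwParams
from .micro_net import NetworkSpec, SynapseParams
from .seizure import OnsetConfig

_MODULES = ("neuron", "micro", "macro", "coupling", "analysis")


@dataclass
class IoConfig:
    output_dir: str = "out"
    log_level: str = "INFO"


@dataclass
class SimConfig:
    """Integration/run controls not owned by any model dataclass."""

    dt_micro: float = 0.05
    dt_macro: float = 0.1
    duration: float = 10_000.0        # ms
    kbath: float = 9.5
    kbath_grid: list = field(default_factory=lambda: [
        4.0, 7.5, 9.5, 12.5, 17.0, 17.5, 22.5])
    spike_threshold: float = 0.0
    sample_every: int = 20
    connectome_path: str | None = None
    synthetic_connectome: bool = True
    seed_region: str = "l CA1"


@dataclass
class RunConfig:
    neuron: IonNeuronParams = field(default_factory=IonNeuronParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    micro: NetworkSpec = field(default_factory=NetworkSpec)
    macro: RwwParams = field(default_factory=RwwParams)
    coupling: TranslationConfig = field(default_factory=TranslationConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    onset: OnsetConfig = field(default_factory=OnsetConfig)
    connectome: SyntheticConnectomeSpec = field(
        default_factory=SyntheticConnectomeSpec)
    sim: SimConfig = field(default_factory=SimConfig)
    io: IoConfig = field(default_factory=IoConfig)
    seed: int = 0

    def module_seed(self, module: str) -> int:
        """Deterministic per-module seed derived from the global seed."""
        if module not in _MODULES:
            raise KeyError(f"unknown module {module!r}")
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(_MODULES))
        idx = _MODULES.index(module)
        return int(children[idx].generate_state(1, np.uint32)[0])

    def resolve_seeds(self) -> "RunConfig":
        """Propagate derived seeds into the module configs."""
        self.micro.seed = self.module_seed("micro")
        self.coupling.seed = self.module_seed("coupling")
        self.connectome.seed = self.module_seed("macro")
        return self


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ValueError(f"unknown config key {path}.{key}")
        ftype = fields[key].type
        current = getattr(cls(), key) if False else None
        if isinstance(value, dict):
            sub_cls = _SECTION_TYPES.get((cls, key))
            if sub_cls is None:
                raise ValueError(f"{path}.{key} does not take a mapping")
            kwargs[key] = _build(sub_cls, value, f"{path}.{key}")
        else:
            if isinstance(value, str) and value.lower() in ("none", "null"):
                value = None
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config section {path}: {exc}") from exc


_SECTION_TYPES = {
    (RunConfig, "neuron"): IonNeuronParams,
    (RunConfig, "synapse"): SynapseParams,
    (RunConfig, "micro"): NetworkSpec,
    (RunConfig, "macro"): RwwParams,
    (RunConfig, "coupling"): TranslationConfig,
    (RunConfig, "classifier"): ClassifierConfig,
    (RunConfig, "onset"): OnsetConfig,
    (RunConfig, "connectome"): SyntheticConnectomeSpec,
    (RunConfig, "sim"): SimConfig,
    (RunConfig, "io"): IoConfig,
    (TranslationConfig, "calcium"): CalciumParams,
}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration; missing keys take defaults.

    ``overrides`` is a flat mapping of dotted keys
    (e.g. ``{"sim.kbath": 12.5}``) applied after the file.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping, got "
                             f"{type(loaded).__name__}")
        data = loaded
    for key, value in (overrides or {}).items():
        node = data
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    cfg = _build(RunConfig, data, "config")
    return cfg


def to_dict(obj) -> dict:
    if dataclasses.is_dataclass(obj):
        out = {}
        for f in dataclasses.fields(obj):
            v = getattr(obj, f.name)
            if dataclasses.is_dataclass(v):
                out[f.name] = to_dict(v)
            elif isinstance(v, np.ndarray):
                out[f.name] = v.tolist()
            elif isinstance(v, tuple):
                out[f.name] = list(v)
            else:
                out[f.name] = v
        return out
    return dict(obj)


def write_provenance(cfg: RunConfig, out_dir: str | Path,
                     extra: dict | None = None) -> Path:
    """Echo the resolved configuration and seeds for reproducibility."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "package_version": __version__,
        "config": to_dict(cfg),
        "derived_seeds": {m: cfg.module_seed(m) for m in _MODULES},
    }
    if extra:
        payload["run"] = extra
    path = out_dir / "provenance.yaml"
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path
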