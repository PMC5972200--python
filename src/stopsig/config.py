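"""Study-wide configuration: one object bundling every stage's settings plus
a master seed that fans out deterministically to the stages."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from ._seeds import stage_rng, stage_seed
from .cohort import CohortConfig
from .connectivity import ConfoundAmplitudes
from .cv import CVConfig
from .first_level import AcquisitionSpec
from .group_level import ClusterConfig
from .task import TaskConfig


@dataclass
class StudyConfig:
    n_patients: int = 38
    n_controls: int = 30
    cohort: CohortConfig = field(default_factory=CohortConfig)
    task: TaskConfig = field(default_factory=TaskConfig)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    cv: CVConfig = field(default_factory=CVConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    confounds: ConfoundAmplitudes = field(default_factory=ConfoundAmplitudes)
    band_hz: tuple[float, float] = (0.01, 0.1)
    drop_initial_volumes: int = 4
    fc_coupling_control: float = 0.6
    fc_coupling_patient: float = 0.3
    task_noise_sd: float = 1.0
    voxel_noise_sd: float = 0.5
    contrast_mean: float = 0.5  # group-mean inhibition effect at the block (beta units)
    master_seed: int = 0
    out_dir: str = "results/pipeline"

    def seed_for(self, stage: str, index: int = 0) -> int:
        return stage_seed(self.master_seed, stage, index)

    def rng_for(self, stage: str, index: int = 0):
        return stage_rng(self.master_seed, stage, index)

    def to_yaml(self, path) -> None:
        def conv(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {f.name: conv(getattr(obj, f.name))
                        for f in fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        Path(path).write_text(yaml.safe_dump(conv(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs = {}
        sub = {"cohort": CohortConfig, "task": TaskConfig,
               "acquisition": AcquisitionSpec, "cv": CVConfig,
               "cluster": ClusterConfig, "confounds": ConfoundAmplitudes}
        for key, val in raw.items():
            if key in sub:
                val = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in val.items()}
                kwargs[key] = sub[key](**val)
            elif isinstance(val, list):
                kwargs[key] = tuple(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)
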