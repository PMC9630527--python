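"""Run configuration: one YAML document with sections flow, labeling,
features, classifier, postprocess.  Defaults are chosen so the pipeline is
parameter-free for the user."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .flow import FlowParams
from .labeling import ThresholdPolicy


@dataclass(frozen=True)
class FeatureConfig:
    names: tuple[str, ...] = ("entropy", "gradient")
    entropy_radius: int = 5
    entropy_bins: int = 32
    gradient_sigma: float = 1.0

    def options(self) -> dict:
        return {
            "entropy_radius": self.entropy_radius,
            "entropy_bins": self.entropy_bins,
            "gradient_sigma": self.gradient_sigma,
        }


@dataclass(frozen=True)
class ClassifierConfig:
    variance_floor: float = 1e-6
    priors: str = "empirical"  # or "uniform"


@dataclass(frozen=True)
class PostprocessConfig:
    fill_radius: int = 5
    min_fraction: float = 0.1
    size_filter_enabled: bool = True


def _seed_erosion(window_size: int) -> int:
    # the displacement halo spans the finest-level half-window plus the
    # upsampled coarse-level contributions; 2/3 of the window covers it
    return max(window_size * 2 // 3, 1)


def _default_policy() -> ThresholdPolicy:
    # the pipeline hardens CELL seeds by eroding away the flow halo
    # (see labeling.label_from_flow)
    return ThresholdPolicy(cell_erosion_radius=_seed_erosion(FlowParams().window_size))


@dataclass(frozen=True)
class PipelineConfig:
    flow: FlowParams = field(default_factory=FlowParams)
    labeling: ThresholdPolicy = field(default_factory=_default_policy)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["features"]["names"] = list(d["features"]["names"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        feats = dict(d.get("features", {}))
        if "names" in feats:
            feats["names"] = tuple(feats["names"])
        flow = FlowParams(**d.get("flow", {}))
        labeling = {"cell_erosion_radius": _seed_erosion(flow.window_size), **d.get("labeling", {})}
        return cls(
            flow=flow,
            labeling=ThresholdPolicy(**labeling),
            features=FeatureConfig(**feats),
            classifier=ClassifierConfig(**d.get("classifier", {})),
            postprocess=PostprocessConfig(**d.get("postprocess", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(Path(path)) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(Path(path), "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
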