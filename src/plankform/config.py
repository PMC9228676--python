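"""YAML run configuration for the CLI pipeline.

One file drives every stage; unknown keys are rejected so typos fail fast.
Sections: data (synthetic-study generator), preprocessing (window),
features (max-feature mode), filter, forest, tree, evaluation, seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .cascade import DEFAULT_ORDER, ForestConfig
from .errors import ValidationError
from .evaluate import PipelineConfig, SplitSpec
from .preprocess import WindowSpec

CONFIG_VERSION = 1


@dataclass
class DataSection:
    n_subjects_per_technique: int = 19
    T: int = 600
    separation_sds: float = 4.0
    hd_overlap: bool = True
    subject_sd: float = 0.5
    noise_sd: float = 2.0
    transient_amp: float = 5.0
    ar1_phi: float = 0.0


@dataclass
class PreprocessingSection:
    window_mode: str = "fixed"
    window_start: int = 181
    window_end: int = 420
    fraction_lo: float = 0.3
    fraction_hi: float = 0.7

    def window(self) -> WindowSpec:
        return WindowSpec(
            mode=self.window_mode,
            start=self.window_start,
            end=self.window_end,
            fraction_lo=self.fraction_lo,
            fraction_hi=self.fraction_hi,
        )


@dataclass
class FeaturesSection:
    max_features: str = "reference"  # reference | none

    def __post_init__(self) -> None:
        if self.max_features not in ("reference", "none"):
            raise ValidationError("features.max_features must be 'reference' or 'none'")


@dataclass
class FilterSection:
    mode: str = "reference"  # reference | auto | none
    alpha: float = 0.05
    sidedness: str = "two_sided"
    correction: str = "none"

    def spec(self):
        return {"reference": "reference", "auto": "auto", "none": None}[self.mode]

    def __post_init__(self) -> None:
        if self.mode not in ("reference", "auto", "none"):
            raise ValidationError("filter.mode must be reference, auto or none")


@dataclass
class ForestSection:
    n_estimators: int = 500
    max_features: str = "sqrt"
    max_depth: int | None = None
    min_samples_leaf: int = 1

    def forest_config(self) -> ForestConfig:
        return ForestConfig(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
        )


@dataclass
class TreeSection:
    order: object = "default"  # default | greedy | explicit list
    threshold_first: object = "auto"  # auto | none | [variable, technique]
    exclude_flagged: bool = True

    def order_arg(self):
        if self.order == "default":
            return DEFAULT_ORDER
        if self.order == "greedy":
            return "greedy"
        return list(self.order)

    def threshold_arg(self):
        if self.threshold_first == "auto":
            return "auto"
        if self.threshold_first in ("none", None):
            return None
        return tuple(self.threshold_first)


@dataclass
class EvaluationSection:
    train_fraction: float = 0.8
    n_repetitions: int = 50
    routed_metrics: bool = False

    def split_spec(self, seed: int) -> SplitSpec:
        return SplitSpec(self.train_fraction, self.n_repetitions, seed)


@dataclass
class RunConfig:
    seed: int = 0
    version: int = CONFIG_VERSION
    data: DataSection = field(default_factory=DataSection)
    preprocessing: PreprocessingSection = field(default_factory=PreprocessingSection)
    features: FeaturesSection = field(default_factory=FeaturesSection)
    filter: FilterSection = field(default_factory=FilterSection)
    forest: ForestSection = field(default_factory=ForestSection)
    tree: TreeSection = field(default_factory=TreeSection)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(
            threshold_first=self.tree.threshold_arg(),
            order=self.tree.order_arg(),
            filter_specs=self.filter.spec(),
            forest=self.forest.forest_config(),
            alpha=self.filter.alpha,
            sidedness=self.filter.sidedness,
            correction=self.filter.correction,
            exclude_flagged=self.tree.exclude_flagged,
            routed_metrics=self.evaluation.routed_metrics,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _build_section(cls, obj, path: str):
    if obj is None:
        return cls()
    if not isinstance(obj, dict):
        raise ValidationError(f"config section {path!r} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(obj) - known
    if unknown:
        raise ValidationError(f"unknown keys in config section {path!r}: {sorted(unknown)}")
    return cls(**obj)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config file must contain a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown top-level config keys: {sorted(unknown)}")
    version = raw.get("version", CONFIG_VERSION)
    if version != CONFIG_VERSION:
        raise ValidationError(f"unsupported config version {version}")
    kwargs = {"seed": int(raw.get("seed", 0)), "version": version}
    for name, cls in [
        ("data", DataSection),
        ("preprocessing", PreprocessingSection),
        ("features", FeaturesSection),
        ("filter", FilterSection),
        ("forest", ForestSection),
        ("tree", TreeSection),
        ("evaluation", EvaluationSection),
    ]:
        kwargs[name] = _build_section(cls, raw.get(name), name)
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
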