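"""Canonical channel naming, raw-trial and feature-table I/O, model persistence.

A recording session yields 60 signal channels: 4 measurement types (Euler
angles, acceleration, gyroscope, magnetometer) x 3 axes x 5 body-worn sensors
(occiput, C7, T3, sacrum, right radius).  Channel names follow the
``Measurement-Axis-Sensor`` convention, e.g. ``"Euler-Y-S1"``.  The canonical
column order is sensor-major (S1..S5), then measurement (Euler, Acc, Gyr,
Mag), then axis (X, Y, Z) — arbitrary but fixed.

Seven technique labels are recognised; ``PC`` (proper/acceptable plank) is the
unique acceptable one, the other six are named deviations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    MalformedInputError,
    ModelVersionError,
    UnknownTechniqueError,
    ValidationError,
)

MODEL_FORMAT = "plankform-tree-model"
MODEL_FORMAT_VERSION = 1

MEASUREMENTS = ("Euler", "Acc", "Gyr", "Mag")
AXES = ("X", "Y", "Z")
SENSORS = ("S1", "S2", "S3", "S4", "S5")

TECHNIQUES = ("PC", "HTFN", "HTBN", "HC", "HTB", "HD", "BC")
ACCEPTABLE_TECHNIQUE = "PC"

#: Full descriptions of the seven plank techniques.
TECHNIQUE_DESCRIPTIONS = {
    "PC": "acceptable plank technique",
    "HTFN": "head tilted forward at the neck",
    "HTBN": "head tilted back at the neck",
    "HC": "hands too close",
    "HTB": "pelvis tilted back",
    "HD": "hip dropped",
    "BC": "back convex",
}


@dataclass(frozen=True)
class ChannelID:
    """One of the 60 IMU signal channels."""

    measurement: str
    axis: str
    sensor: str

    def __post_init__(self) -> None:
        if self.measurement not in MEASUREMENTS:
            raise ValidationError(f"unknown measurement {self.measurement!r}")
        if self.axis not in AXES:
            raise ValidationError(f"unknown axis {self.axis!r}")
        if self.sensor not in SENSORS:
            raise ValidationError(f"unknown sensor {self.sensor!r}")

    def __str__(self) -> str:
        return f"{self.measurement}-{self.axis}-{self.sensor}"

    @classmethod
    def parse(cls, name: str) -> "ChannelID":
        parts = name.split("-")
        if len(parts) != 3:
            raise ValidationError(f"channel name {name!r} is not Measurement-Axis-Sensor")
        return cls(*parts)


#: All 60 channels in canonical order (sensor-major, then measurement, then axis).
CHANNELS: tuple[str, ...] = tuple(
    str(ChannelID(m, a, s)) for s in SENSORS for m in MEASUREMENTS for a in AXES
)
CHANNEL_INDEX = {name: i for i, name in enumerate(CHANNELS)}


def check_technique(code: str) -> str:
    if code not in TECHNIQUES:
        raise UnknownTechniqueError(
            f"unknown technique code {code!r}; expected one of {TECHNIQUES}"
        )
    return code


# ---------------------------------------------------------------------------
# Raw trials
# ---------------------------------------------------------------------------

@dataclass
class RawTrial:
    """One subject x technique recording: a T x 60 sample matrix.

    Rows are timestamps (1-based t = 1..T when indexing mathematically),
    columns follow the canonical :data:`CHANNELS` order.
    """

    subject_id: str
    technique: str
    samples: np.ndarray
    sample_rate: float = 60.0

    def __post_init__(self) -> None:
        check_technique(self.technique)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(CHANNELS):
            raise MalformedInputError(
                f"trial ({self.subject_id}, {self.technique}): samples must be "
                f"T x {len(CHANNELS)}, got shape {self.samples.shape}"
            )
        if np.isnan(self.samples).any():
            raise MalformedInputError(
                f"trial ({self.subject_id}, {self.technique}) contains missing values"
            )

    @property
    def n_timestamps(self) -> int:
        return self.samples.shape[0]


def read_raw_trials(path, schema: str = "long") -> list[RawTrial]:
    """Read raw trials from CSV in ``long`` or ``wide`` schema.

    long:  columns subject, technique, timestamp, channel, value
    wide:  columns subject, technique, timestamp, then the 60 channel columns
    """
    if schema not in ("long", "wide"):
        raise ValidationError(f"schema must be 'long' or 'wide', got {schema!r}")
    df = pd.read_csv(path)
    if schema == "long":
        required = {"subject", "technique", "timestamp", "channel", "value"}
        if not required.issubset(df.columns):
            raise MalformedInputError(
                f"long schema requires columns {sorted(required)}, got {list(df.columns)}"
            )
        trials = []
        for (subj, tech), grp in df.groupby(["subject", "technique"], sort=True):
            check_technique(str(tech))
            wide = grp.pivot_table(
                index="timestamp", columns="channel", values="value", aggfunc="first"
            )
            trials.append(_trial_from_wide(str(subj), str(tech), wide))
        return trials
    # wide schema
    meta = ["subject", "technique", "timestamp"]
    if not set(meta).issubset(df.columns):
        raise MalformedInputError(f"wide schema requires columns {meta}")
    trials = []
    for (subj, tech), grp in df.groupby(["subject", "technique"], sort=True):
        check_technique(str(tech))
        wide = grp.set_index("timestamp")[[c for c in df.columns if c not in meta]]
        trials.append(_trial_from_wide(str(subj), str(tech), wide))
    return trials


def _trial_from_wide(subject: str, technique: str, wide: pd.DataFrame) -> RawTrial:
    tag = f"trial ({subject}, {technique})"
    missing = [c for c in CHANNELS if c not in wide.columns]
    if missing:
        raise MalformedInputError(f"{tag}: missing channels {missing[:5]}"
                                  + ("..." if len(missing) > 5 else ""))
    extra = [c for c in wide.columns if c not in CHANNEL_INDEX]
    if extra:
        raise MalformedInputError(f"{tag}: unknown channels {extra[:5]}")
    wide = wide.sort_index()
    ts = wide.index.to_numpy()
    if len(ts) == 0:
        raise MalformedInputError(f"{tag}: no timestamps")
    # Timestamps must be an unbroken run; they are re-indexed 1..T afterwards.
    if not np.array_equal(ts, np.arange(ts[0], ts[0] + len(ts))):
        raise MalformedInputError(f"{tag}: gaps or duplicates in timestamps")
    values = wide[list(CHANNELS)].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise MalformedInputError(f"{tag}: missing values in samples")
    return RawTrial(subject, technique, values)


def write_raw_trials(trials, path, schema: str = "long") -> None:
    """Write trials to CSV (inverse of :func:`read_raw_trials`)."""
    frames = []
    for tr in trials:
        t = np.arange(1, tr.n_timestamps + 1)
        if schema == "wide":
            df = pd.DataFrame(tr.samples, columns=list(CHANNELS))
            df.insert(0, "timestamp", t)
            df.insert(0, "technique", tr.technique)
            df.insert(0, "subject", tr.subject_id)
        elif schema == "long":
            df = pd.DataFrame(
                {
                    "subject": np.repeat(tr.subject_id, tr.n_timestamps * len(CHANNELS)),
                    "technique": tr.technique,
                    "timestamp": np.repeat(t, len(CHANNELS)),
                    "channel": np.tile(np.array(CHANNELS), tr.n_timestamps),
                    "value": tr.samples.ravel(),
                }
            )
        else:
            raise ValidationError(f"schema must be 'long' or 'wide', got {schema!r}")
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Subjects x features matrix of stable-window means (plus engineered columns).

    Backed by a DataFrame whose first two columns are ``subject`` and
    ``technique``; the remaining columns are feature values.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        cols = list(self.frame.columns)
        if cols[:2] != ["subject", "technique"]:
            raise ValidationError("first two columns must be 'subject' and 'technique'")
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ValidationError(f"duplicate column names: {dupes}")
        pairs = list(zip(self.frame["subject"], self.frame["technique"]))
        if len(set(pairs)) != len(pairs):
            raise MalformedInputError("duplicate (subject, technique) rows in feature table")
        for tech in self.frame["technique"]:
            check_technique(str(tech))
        self.frame = self.frame.reset_index(drop=True)

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns[2:])

    @property
    def subjects(self) -> pd.Series:
        return self.frame["subject"]

    @property
    def techniques(self) -> pd.Series:
        return self.frame["technique"]

    @property
    def values(self) -> np.ndarray:
        return self.frame.iloc[:, 2:].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.frame)

    def select(self, mask) -> "FeatureTable":
        return FeatureTable(self.frame.loc[mask].reset_index(drop=True))

    def matrix(self, feature_names) -> np.ndarray:
        missing = [f for f in feature_names if f not in self.frame.columns]
        if missing:
            raise DataError(f"feature table lacks columns: {missing}")
        return self.frame[list(feature_names)].to_numpy(dtype=float)


def write_feature_table(table: FeatureTable, path) -> None:
    table.frame.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise MalformedInputError("feature table CSV must start with subject, technique")
    df["subject"] = df["subject"].astype(str)
    df["technique"] = df["technique"].astype(str)
    return FeatureTable(df)


# ---------------------------------------------------------------------------
# Model persistence (single-file JSON, version-stamped)
# ---------------------------------------------------------------------------

def _tree_state_to_json(tree) -> dict:
    state = tree.__getstate__()
    nodes = state["nodes"]
    return {
        "max_depth": int(state["max_depth"]),
        "node_count": int(state["node_count"]),
        "node_fields": list(nodes.dtype.names),
        "nodes": [[float(row[f]) for f in nodes.dtype.names] for row in nodes],
        "values": np.asarray(state["values"]).tolist(),
    }


def _tree_state_from_json(obj: dict, n_features: int, n_classes: int):
    from sklearn.tree._tree import Tree

    dummy_dtype = _node_dtype()
    if list(dummy_dtype.names) != obj["node_fields"]:
        raise ModelVersionError(
            "decision-tree node layout in file does not match installed scikit-learn"
        )
    nodes = np.array([tuple(row) for row in obj["nodes"]], dtype=dummy_dtype)
    tree = Tree(n_features, np.array([n_classes], dtype=np.intp), 1)
    tree.__setstate__(
        {
            "max_depth": obj["max_depth"],
            "node_count": obj["node_count"],
            "nodes": nodes,
            "values": np.asarray(obj["values"], dtype=float),
        }
    )
    return tree


_NODE_DTYPE = None


def _node_dtype():
    # Obtained from a minimal fitted tree so it always matches the installed
    # scikit-learn, whose private node dtype is not part of the public API.
    global _NODE_DTYPE
    if _NODE_DTYPE is None:
        from sklearn.tree import DecisionTreeClassifier

        toy = DecisionTreeClassifier(max_depth=1).fit([[0.0], [1.0]], [0, 1])
        _NODE_DTYPE = toy.tree_.__getstate__()["nodes"].dtype
    return _NODE_DTYPE


def _forest_to_json(forest) -> dict:
    return {
        "params": {
            "n_estimators": forest.n_estimators,
            "max_features": forest.max_features,
            "max_depth": forest.max_depth,
            "min_samples_leaf": forest.min_samples_leaf,
            "random_state": forest.random_state,
            "class_weight": forest.class_weight,
        },
        "classes": [int(c) for c in forest.classes_],
        "n_features": int(forest.n_features_in_),
        "trees": [_tree_state_to_json(est.tree_) for est in forest.estimators_],
    }


def _forest_from_json(obj: dict):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.tree import DecisionTreeClassifier

    classes = np.asarray(obj["classes"])
    n_features = obj["n_features"]
    forest = RandomForestClassifier(**obj["params"])
    forest.classes_ = classes
    forest.n_classes_ = len(classes)
    forest.n_features_in_ = n_features
    forest.n_outputs_ = 1
    estimators = []
    for tree_obj in obj["trees"]:
        est = DecisionTreeClassifier()
        est.tree_ = _tree_state_from_json(tree_obj, n_features, len(classes))
        est.classes_ = classes
        est.n_classes_ = len(classes)
        est.n_features_in_ = n_features
        est.n_outputs_ = 1
        estimators.append(est)
    forest.estimators_ = estimators
    return forest


def save_model(model, path) -> None:
    """Persist a fitted TreeModel as a single JSON file."""
    import sklearn

    from . import cascade

    if not isinstance(model, cascade.TreeModel):
        raise ValidationError("save_model expects a fitted TreeModel")
    doc = {
        "format": MODEL_FORMAT,
        "format_version": MODEL_FORMAT_VERSION,
        "sklearn_version": sklearn.__version__,
        "seed": model.seed,
        "config": model.config,
        "terminal_acceptable": model.terminal_acceptable,
        "root": None
        if model.root is None
        else {
            "variable": model.root.variable,
            "threshold": model.root.threshold,
            "direction": model.root.direction,
            "d1": model.root.d1,
        },
        "nodes": [
            {
                "node_index": n.node_index,
                "d1": n.d1,
                "d2_set": list(n.d2_set),
                "feature_names": list(n.feature_names),
                "filter": None
                if n.filter is None
                else {
                    "node_index": n.filter.node_index,
                    "variables": list(n.filter.variables),
                    "reference_values": {
                        v: [float(x) for x in vals]
                        for v, vals in n.filter.reference_values.items()
                    },
                    "alpha": n.filter.alpha,
                    "sidedness": n.filter.sidedness,
                    "correction": n.filter.correction,
                },
                "forest": _forest_to_json(n.forest),
            }
            for n in model.nodes
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path):
    """Load a TreeModel saved by :func:`save_model`.

    Raises :class:`ModelVersionError` for truncated/foreign files or a
    scikit-learn version whose tree layout differs from the one that wrote
    the file.
    """
    import sklearn

    from . import cascade

    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelVersionError(f"cannot parse model file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise ModelVersionError(f"{path} is not a {MODEL_FORMAT} file")
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ModelVersionError(
            f"model format version {doc.get('format_version')} unsupported "
            f"(library writes version {MODEL_FORMAT_VERSION})"
        )
    if doc.get("sklearn_version") != sklearn.__version__:
        raise ModelVersionError(
            f"model was written with scikit-learn {doc.get('sklearn_version')}, "
            f"installed is {sklearn.__version__}"
        )
    root_obj = doc["root"]
    root = None
    if root_obj is not None:
        root = cascade.ThresholdNode(
            variable=root_obj["variable"],
            threshold=root_obj["threshold"],
            direction=root_obj["direction"],
            d1=root_obj["d1"],
        )
    nodes = []
    for n in doc["nodes"]:
        filt = None
        if n["filter"] is not None:
            f = n["filter"]
            filt = cascade.AberranceFilter(
                node_index=f["node_index"],
                variables=tuple(f["variables"]),
                reference_values={
                    v: np.asarray(vals, dtype=float)
                    for v, vals in f["reference_values"].items()
                },
                alpha=f["alpha"],
                sidedness=f["sidedness"],
                correction=f["correction"],
            )
        nodes.append(
            cascade.NodeModel(
                node_index=n["node_index"],
                d1=n["d1"],
                d2_set=tuple(n["d2_set"]),
                filter=filt,
                forest=_forest_from_json(n["forest"]),
                feature_names=tuple(n["feature_names"]),
            )
        )
    return cascade.TreeModel(
        root=root,
        nodes=nodes,
        terminal_acceptable=doc["terminal_acceptable"],
        config=doc.get("config", {}),
        seed=doc.get("seed"),
    )
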