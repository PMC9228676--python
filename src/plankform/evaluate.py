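"""Repeated stratified hold-out evaluation of the cascade.

Protocol: per technique, floor(train_fraction * n) subjects form the
training set (default 0.8, so 19 subjects -> 15 train / 4 test) and the rest
the test set; the whole pipeline is refitted on each of ``n_repetitions``
independent splits (default 50) and per-node accuracy, sensitivity and
specificity are aggregated as mean (SD) over repetitions — the familiar
two-table layout (training and test) of repeated hold-out studies.

At node i the positive class D1 is the technique the node separates and D2
the union of the techniques still in play at that node.  n_ij counts
observations classified as D_i whose true category is D_j, giving

    accuracy    = (n11 + n22) / (n11 + n12 + n21 + n22)
    sensitivity = n11 / (n11 + n21)
    specificity = n22 / (n12 + n22)

Undefined metrics (zero denominator) are reported as missing, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import cascade
from .cascade import ForestConfig, TreeModel, apply_filter, greedy_build_tree
from .errors import DataError, ValidationError
from .io import FeatureTable


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    n_repetitions: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must lie in (0, 1)")
        if self.n_repetitions < 1:
            raise ValidationError("n_repetitions must be >= 1")


def _rep_rng(seed: int, repetition_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, repetition_index)))


def stratified_split(
    table: FeatureTable, spec: SplitSpec, repetition_index: int = 0
) -> tuple[FeatureTable, FeatureTable]:
    """Per-class subject split: floor(train_fraction * n) train, rest test."""
    rng = _rep_rng(spec.seed, repetition_index)
    train_idx: list[int] = []
    for cls in sorted(set(table.techniques)):
        idx = np.flatnonzero((table.techniques == cls).to_numpy())
        if idx.size < 2:
            raise DataError(f"class {cls!r} has fewer than 2 subjects; cannot split")
        n_train = int(np.floor(spec.train_fraction * idx.size))
        train_idx.extend(rng.choice(idx, size=n_train, replace=False))
    mask = np.zeros(len(table), dtype=bool)
    mask[np.asarray(train_idx, dtype=int)] = True
    return table.select(mask), table.select(~mask)


# ---------------------------------------------------------------------------
# Confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """n_ij = #observations classified as D_i with true category D_j."""

    n11: int
    n12: int
    n21: int
    n22: int

    def __post_init__(self) -> None:
        if min(self.n11, self.n12, self.n21, self.n22) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22


class Metrics(NamedTuple):
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None


def metrics(counts: ConfusionCounts) -> Metrics:
    if counts.total == 0:
        raise ValidationError("cannot compute metrics from all-zero counts")
    acc = (counts.n11 + counts.n22) / counts.total
    sens_den = counts.n11 + counts.n21
    spec_den = counts.n12 + counts.n22
    return Metrics(
        accuracy=acc,
        sensitivity=counts.n11 / sens_den if sens_den else None,
        specificity=counts.n22 / spec_den if spec_den else None,
    )


def _node_entry(model: TreeModel, node_index: int):
    """The root ThresholdNode or NodeModel carrying this 1-based index."""
    if model.root is not None and node_index == 1:
        return model.root
    for node in model.nodes:
        if node.node_index == node_index:
            return node
    raise ValidationError(f"model has no node with index {node_index}")


def node_indices(model: TreeModel) -> list[int]:
    out = [1] if model.root is not None else []
    return out + [n.node_index for n in model.nodes]


def _node_claims(model: TreeModel, node, table: FeatureTable) -> np.ndarray:
    """Boolean claim vector of one node over all rows of ``table``."""
    if isinstance(node, cascade.ThresholdNode):
        col = table.frame[node.variable].to_numpy(dtype=float)
        return col < node.threshold if node.direction == "below_is_d1" else col > node.threshold
    flagged = np.array(
        [apply_filter(node.filter, row) for _, row in table.frame.iterrows()], dtype=bool
    )
    forest_votes = node.forest_claims(table.matrix(node.feature_names))
    return flagged | forest_votes


def _node_membership(model: TreeModel, node, table: FeatureTable, routed: bool) -> np.ndarray:
    """Rows that count at this node: C_i chain by true label, or actually routed."""
    if not routed:
        if isinstance(node, cascade.ThresholdNode):
            return np.ones(len(table), dtype=bool)
        member = table.techniques.isin((node.d1, *node.d2_set)).to_numpy()
        return member
    reach = np.ones(len(table), dtype=bool)
    for idx in node_indices(model):
        entry = _node_entry(model, idx)
        if entry is node:
            return reach
        reach &= ~_node_claims(model, entry, table)
    raise ValidationError("node not part of the model")


def confusion_at_node(
    model: TreeModel, node_index: int, table: FeatureTable, routed: bool = False
) -> ConfusionCounts:
    """n_ij counts at one node.

    By default D2 membership follows the C_i chain by true labels (fixed
    per-node n1/n2); ``routed=True`` instead scores only the rows the fitted
    cascade actually routes to the node.
    """
    node = _node_entry(model, node_index)
    member = _node_membership(model, node, table, routed)
    sub = table.select(member)
    truth_d1 = (sub.techniques == node.d1).to_numpy()
    if truth_d1.sum() == 0 or (~truth_d1).sum() == 0:
        raise DataError(
            f"node {node_index} ({node.d1}): empty D1 or D2 among the scored rows"
        )
    claimed = _node_claims(model, node, sub)
    return ConfusionCounts(
        n11=int(np.sum(claimed & truth_d1)),
        n12=int(np.sum(claimed & ~truth_d1)),
        n21=int(np.sum(~claimed & truth_d1)),
        n22=int(np.sum(~claimed & ~truth_d1)),
    )


# ---------------------------------------------------------------------------
# Repeated evaluation
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything needed to refit the cascade inside each repetition."""

    threshold_first: object = "auto"
    order: object = cascade.DEFAULT_ORDER
    filter_specs: object = "reference"
    forest: ForestConfig = field(default_factory=ForestConfig)
    alpha: float = 0.05
    sidedness: str = "two_sided"
    correction: str = "none"
    exclude_flagged: bool = True
    routed_metrics: bool = False

    def fit(self, table: FeatureTable, seed: int | None) -> TreeModel:
        return greedy_build_tree(
            table,
            threshold_first=self.threshold_first,
            filter_specs=self.filter_specs,
            order=self.order,
            forest_config=self.forest,
            seed=seed,
            alpha=self.alpha,
            sidedness=self.sidedness,
            correction=self.correction,
            exclude_flagged=self.exclude_flagged,
        )


@dataclass
class EvalReport:
    per_repetition: pd.DataFrame
    train_summary: pd.DataFrame
    test_summary: pd.DataFrame
    failures: list = field(default_factory=list)
    complete: bool = True
    single_repetition: bool = False

    def node_summary(self, split: str, node_index: int) -> pd.Series:
        table = self.train_summary if split == "train" else self.test_summary
        return table.set_index("node_index").loc[node_index]


_METRIC_COLS = ["accuracy", "sensitivity", "specificity"]


def repeat_evaluation(
    table: FeatureTable,
    pipeline: PipelineConfig | None = None,
    spec: SplitSpec | None = None,
) -> EvalReport:
    """Split / fit / score ``n_repetitions`` times and aggregate mean (SD)."""
    pipeline = pipeline or PipelineConfig()
    spec = spec or SplitSpec()
    records, failures = [], []
    for rep in range(spec.n_repetitions):
        train, test = stratified_split(table, spec, rep)
        fit_seed = int(_rep_rng(spec.seed, rep).integers(2**31))
        try:
            model = pipeline.fit(train, fit_seed)
        except Exception as exc:  # recorded, not raised: the report stays usable
            failures.append((rep, f"{type(exc).__name__}: {exc}"))
            continue
        for split_name, part in (("train", train), ("test", test)):
            for idx in node_indices(model):
                node = _node_entry(model, idx)
                counts = confusion_at_node(model, idx, part, routed=pipeline.routed_metrics)
                m = metrics(counts)
                records.append(
                    {
                        "repetition": rep,
                        "split": split_name,
                        "node_index": idx,
                        "d1": node.d1,
                        "n1": counts.n11 + counts.n21,
                        "n2": counts.n12 + counts.n22,
                        "accuracy": m.accuracy,
                        "sensitivity": m.sensitivity,
                        "specificity": m.specificity,
                    }
                )
    per_rep = pd.DataFrame.from_records(records)
    if per_rep.empty:
        raise DataError("every repetition failed to fit; see report failures")

    def summarise(split_name: str) -> pd.DataFrame:
        part = per_rep[per_rep["split"] == split_name]
        rows = []
        for idx, grp in part.groupby("node_index"):
            row = {
                "node_index": idx,
                "d1": grp["d1"].iloc[0],
                "n1": grp["n1"].mean(),
                "n2": grp["n2"].mean(),
            }
            for met in _METRIC_COLS:
                vals = grp[met].dropna()
                row[f"{met}_mean"] = vals.mean() if len(vals) else np.nan
                row[f"{met}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
                row[f"{met}_undefined"] = int(grp[met].isna().sum())
            rows.append(row)
        return pd.DataFrame(rows).sort_values("node_index").reset_index(drop=True)

    return EvalReport(
        per_repetition=per_rep,
        train_summary=summarise("train"),
        test_summary=summarise("test"),
        failures=failures,
        complete=not failures,
        single_repetition=spec.n_repetitions == 1,
    )


def variable_importance(model: TreeModel, node_index: int, top_k: int = 20):
    """Mean-decrease-Gini importance ranking of one node's forest."""
    node = _node_entry(model, node_index)
    if isinstance(node, cascade.ThresholdNode):
        raise ValidationError("the threshold root has no forest to rank")
    imp = node.forest.feature_importances_
    order = np.argsort(imp)[::-1][: min(top_k, len(imp))]
    return [(node.feature_names[i], float(imp[i])) for i in order]
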