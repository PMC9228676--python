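"""Binary-tree cascade classifier: threshold root, aberrance filters, forests.

The cascade separates one technique per node.  The root is a univariate
threshold: on the study-like data the head-tilted-back technique (HTBN) is
perfectly separated by Euler-Y-S1, and the fitted cut is the midpoint
between the extreme of the separated class and the nearest point of the
rest.  Every later node N_i runs a two-stage procedure:

1. An aberrance filter F_i computes, for each of a small set of "filtered
   variables", an empirical p-value of the incoming observation against the
   node's D2 training values; any p below alpha flags the observation as an
   extreme aberrant execution of the node's technique, which short-circuits
   the forest.
2. A binary random forest RF_i votes d1-vs-rest over all available features
   (base channels plus engineered maxima).

Node order is either supplied explicitly or chosen greedily: at each node,
every remaining technique is tried as the separated class and the one whose
combined two-stage node scores highest out-of-bag accuracy on the training
rows is kept.  The final node separates the last deviation from the
acceptable technique, which is the terminal leaf.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import DataError, FitError, SeparabilityError, ValidationError
from .io import ACCEPTABLE_TECHNIQUE, FeatureTable
from .preprocess import parse_max_feature_name, reference_filter_variables

logger = logging.getLogger(__name__)

#: Reference node order after the threshold root (the study-like cascade).
DEFAULT_ORDER = ("HTFN", "HTB", "BC", "HC", "HD")


# ---------------------------------------------------------------------------
# Empirical p-values
# ---------------------------------------------------------------------------

def empirical_p_value(
    x: float,
    reference,
    sidedness: str = "two_sided",
    correction: str = "add_one",
) -> float:
    """Empirical-distribution p-value of ``x`` against ``reference`` values.

    With the add-one correction (default), p_left = (#{v <= x} + 1) / (m + 1)
    and p_right = (#{v >= x} + 1) / (m + 1), so the result is never exactly 0;
    two-sided is min(1, 2 * min(p_left, p_right)).  ``correction="none"``
    uses the plain empirical proportions #{...} / m, which can reach 0 for a
    value beyond the whole reference — the behaviour a tail filter needs when
    the reference is small.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.size < 2:
        raise ValidationError("reference must contain at least 2 values")
    if sidedness not in ("two_sided", "left", "right"):
        raise ValidationError(f"unknown sidedness {sidedness!r}")
    if correction not in ("add_one", "none"):
        raise ValidationError(f"unknown correction {correction!r}")
    m = ref.size
    n_le = int(np.sum(ref <= x))
    n_ge = int(np.sum(ref >= x))
    if correction == "add_one":
        p_left = (n_le + 1) / (m + 1)
        p_right = (n_ge + 1) / (m + 1)
    else:
        p_left = n_le / m
        p_right = n_ge / m
    if sidedness == "left":
        return min(1.0, p_left)
    if sidedness == "right":
        return min(1.0, p_right)
    return min(1.0, 2.0 * min(p_left, p_right))


# ---------------------------------------------------------------------------
# Threshold node
# ---------------------------------------------------------------------------

@dataclass
class ThresholdNode:
    variable: str
    threshold: float
    direction: str  # below_is_d1 | above_is_d1
    d1: str

    def claims(self, value: float) -> bool:
        if self.direction == "below_is_d1":
            return value < self.threshold
        return value > self.threshold


def fit_threshold_node(
    table: FeatureTable, d1: str, variable: str, direction: str = "below_is_d1"
) -> ThresholdNode:
    """Midpoint threshold between the separated class and the rest.

    With ``below_is_d1`` the cut is (max over D1 + min over D2) / 2 and the
    training classes must satisfy max(D1) < min(D2); fitting fails loudly on
    overlap rather than producing a bad threshold.
    """
    if direction not in ("below_is_d1", "above_is_d1"):
        raise ValidationError(f"unknown direction {direction!r}")
    if variable not in table.frame.columns:
        raise DataError(f"variable {variable!r} not in feature table")
    mask = (table.techniques == d1).to_numpy()
    v1 = table.frame.loc[mask, variable].to_numpy(dtype=float)
    v2 = table.frame.loc[~mask, variable].to_numpy(dtype=float)
    if v1.size == 0 or v2.size == 0:
        raise DataError(f"need rows for {d1} and at least one other class")
    if direction == "below_is_d1":
        lo, hi = v1.max(), v2.min()
        if not lo < hi:
            raise SeparabilityError(
                f"{d1} not separated below the rest on {variable}: "
                f"max(D1)={lo:.4g} >= min(D2)={hi:.4g}"
            )
    else:
        lo, hi = v2.max(), v1.min()
        if not lo < hi:
            raise SeparabilityError(
                f"{d1} not separated above the rest on {variable}: "
                f"min(D1)={hi:.4g} <= max(D2)={lo:.4g}"
            )
    return ThresholdNode(variable, (lo + hi) / 2.0, direction, d1)


# ---------------------------------------------------------------------------
# Aberrance filter
# ---------------------------------------------------------------------------

@dataclass
class AberranceFilter:
    """Flags observations extreme w.r.t. the node's D2 training distribution."""

    node_index: int
    variables: tuple[str, ...]
    reference_values: dict[str, np.ndarray]
    alpha: float = 0.05
    sidedness: str = "two_sided"
    correction: str = "none"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        for v in self.variables:
            if v not in self.reference_values:
                raise ValidationError(f"no reference values stored for {v!r}")
            if np.asarray(self.reference_values[v]).size < 2:
                raise ValidationError(f"reference for {v!r} needs >= 2 values")

    def p_values(self, row) -> dict[str, float]:
        return {
            v: empirical_p_value(
                _row_value(row, v), self.reference_values[v], self.sidedness, self.correction
            )
            for v in self.variables
        }

    def flags(self, row) -> bool:
        """ANY-variable rule: flagged iff some variable's p-value < alpha."""
        return any(p < self.alpha for p in self.p_values(row).values())


def apply_filter(filt: AberranceFilter | None, row) -> bool:
    """True means: classify as the node's d1 now, skip the forest."""
    return False if filt is None else filt.flags(row)


def fit_filter(
    table: FeatureTable,
    d1: str,
    d2_set,
    variables="auto",
    alpha: float = 0.05,
    sidedness: str = "two_sided",
    correction: str = "none",
    node_index: int = 0,
) -> AberranceFilter | None:
    """Store D2 training values per filtered variable.

    ``variables`` may be an explicit list (used verbatim), "auto" (keep a
    candidate iff it flags at least one D1 training row while flagging no
    more than floor(alpha * |D2|) D2 rows), or None/() for no filter.
    """
    d2_set = tuple(d2_set)
    d2_mask = table.techniques.isin(d2_set).to_numpy()
    if d2_mask.sum() < 2:
        raise DataError("need at least 2 D2 training rows to build a reference")
    make = lambda names: AberranceFilter(
        node_index=node_index,
        variables=tuple(names),
        reference_values={
            v: table.frame.loc[d2_mask, v].to_numpy(dtype=float) for v in names
        },
        alpha=alpha,
        sidedness=sidedness,
        correction=correction,
    )
    if variables is None:
        return None
    if variables != "auto":
        names = list(variables)
        if not names:
            return None
        missing = [v for v in names if v not in table.frame.columns]
        if missing:
            raise DataError(f"filter variables not in table: {missing}")
        return make(names)
    # auto selection
    d1_rows = table.frame.loc[(table.techniques == d1).to_numpy()]
    d2_rows = table.frame.loc[d2_mask]
    budget = int(np.floor(alpha * d2_mask.sum()))
    kept = []
    for v in table.feature_names:
        ref = table.frame.loc[d2_mask, v].to_numpy(dtype=float)
        p = lambda x: empirical_p_value(x, ref, sidedness, correction)
        d1_hits = sum(p(x) < alpha for x in d1_rows[v])
        if d1_hits == 0:
            continue
        d2_hits = sum(p(x) < alpha for x in d2_rows[v])
        if d2_hits <= budget:
            kept.append(v)
    if not kept:
        logger.info("aberrance filter (node %d, d1=%s): auto mode retained no "
                    "variables; node degrades to forest only", node_index, d1)
        return None
    return make(kept)


# ---------------------------------------------------------------------------
# Node model (filter + forest)
# ---------------------------------------------------------------------------

@dataclass
class ForestConfig:
    """Random-forest hyperparameters (defaults: 500 trees, sqrt(p) features)."""

    n_estimators: int = 500
    max_features: str | float | None = "sqrt"
    max_depth: int | None = None
    min_samples_leaf: int = 1
    class_weight: str | dict | None = None

    def build(self, seed, oob: bool = False) -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            class_weight=self.class_weight,
            oob_score=oob,
            random_state=None if seed is None else int(seed) % (2**31),
        )


@dataclass
class NodeModel:
    node_index: int
    d1: str
    d2_set: tuple[str, ...]
    filter: AberranceFilter | None
    forest: RandomForestClassifier
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.d1 in self.d2_set or not self.d2_set:
            raise ValidationError("d1 must not be in the (nonempty) d2_set")

    def forest_claims(self, X: np.ndarray) -> np.ndarray:
        """Boolean vector: forest votes d1 (class 1)."""
        return self.forest.predict(X).astype(bool)

    def claims_row(self, row) -> tuple[bool, str]:
        """(claims d1?, decided_by in {'filter', 'forest'}) for one observation."""
        if apply_filter(self.filter, row):
            return True, "filter"
        x = np.array([[_row_value(row, f) for f in self.feature_names]])
        return bool(self.forest.predict(x)[0]), "forest"


def fit_node(
    table: FeatureTable,
    d1: str,
    d2_set,
    filter_spec="auto",
    forest_config: ForestConfig | None = None,
    seed: int | None = 0,
    node_index: int = 0,
    alpha: float = 0.05,
    sidedness: str = "two_sided",
    correction: str = "none",
    exclude_flagged: bool = True,
    oob: bool = False,
) -> NodeModel:
    """Fit the two-stage node: aberrance filter, then a d1-vs-rest forest.

    Training rows flagged by the filter are excluded from the forest's
    training set by default (they would sit in awkward regions of feature
    space and are already handled by the short-circuit); set
    ``exclude_flagged=False`` to keep them.
    """
    forest_config = forest_config or ForestConfig()
    d2_set = tuple(d2_set)
    for cls in (d1, *d2_set):
        if not (table.techniques == cls).any():
            raise DataError(f"no training rows for class {cls!r} at node {node_index}")
    node_mask = table.techniques.isin((d1, *d2_set)).to_numpy()
    sub = table.select(node_mask)
    filt = fit_filter(
        sub, d1, d2_set, variables=filter_spec, alpha=alpha,
        sidedness=sidedness, correction=correction, node_index=node_index,
    )
    feature_names = tuple(sub.feature_names)
    flagged = np.array(
        [apply_filter(filt, row) for _, row in sub.frame.iterrows()], dtype=bool
    )
    y = (sub.techniques == d1).to_numpy().astype(int)
    train_mask = ~flagged if exclude_flagged else np.ones(len(sub), dtype=bool)
    if len(np.unique(y[train_mask])) < 2:
        logger.info("node %d (%s): excluding flagged rows would leave one class; "
                    "training forest on all rows", node_index, d1)
        train_mask = np.ones(len(sub), dtype=bool)
    forest = forest_config.build(seed, oob=oob)
    forest.fit(sub.matrix(feature_names)[train_mask], y[train_mask])
    return NodeModel(node_index, d1, d2_set, filt, forest, feature_names)


def _node_training_score(node: NodeModel, table: FeatureTable) -> float:
    """Combined two-stage accuracy on the node's training rows.

    Filter-flagged rows are scored as claimed-d1; rows the forest was trained
    on are scored by their out-of-bag vote, so the score is an internal
    estimate of generalisation rather than a degenerate resubstitution one.
    """
    sub = table.select(table.techniques.isin((node.d1, *node.d2_set)).to_numpy())
    y = (sub.techniques == node.d1).to_numpy().astype(int)
    flagged = np.array(
        [apply_filter(node.filter, row) for _, row in sub.frame.iterrows()], dtype=bool
    )
    pred = np.zeros(len(sub), dtype=int)
    pred[flagged] = 1
    X = sub.matrix(node.feature_names)
    if (~flagged).any():
        oob = getattr(node.forest, "oob_decision_function_", None)
        if oob is not None and len(oob) == int((~flagged).sum()):
            votes = np.argmax(oob, axis=1)
            bad = np.isnan(oob).any(axis=1)
            if bad.any():  # rows never out-of-bag fall back to a refit vote
                votes[bad] = node.forest.predict(X[~flagged][bad])
            pred[~flagged] = node.forest.classes_[votes]
        else:
            pred[~flagged] = node.forest.predict(X[~flagged])
    return float(np.mean(pred == y))


# ---------------------------------------------------------------------------
# Tree building
# ---------------------------------------------------------------------------

@dataclass
class TreeModel:
    root: ThresholdNode | None
    nodes: list[NodeModel]
    terminal_acceptable: str = ACCEPTABLE_TECHNIQUE
    config: dict = field(default_factory=dict)
    seed: int | None = None

    def class_chain(self) -> list[str]:
        """All classes in separation order, terminal last."""
        chain = [] if self.root is None else [self.root.d1]
        chain += [n.d1 for n in self.nodes]
        chain.append(self.terminal_acceptable)
        return chain

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.nodes[0].feature_names if self.nodes else ()


def find_perfect_separator(table: FeatureTable, classes=None):
    """Scan (feature, class) pairs for perfect univariate separation.

    Returns (variable, d1, direction) with the largest standardized margin,
    or None if no pair separates perfectly on the training data.
    """
    classes = list(classes) if classes is not None else sorted(set(table.techniques))
    labels = table.techniques.to_numpy()
    best, best_key = None, (-np.inf, -np.inf)
    for var in table.feature_names:
        col = table.frame[var].to_numpy(dtype=float)
        # pooled within-class spread: the natural scale for a separation margin
        within = np.sqrt(
            np.mean([col[labels == c].var() for c in np.unique(labels)])
        )
        for cls in classes:
            mask = labels == cls
            v1, v2 = col[mask], col[~mask]
            if v1.size == 0 or v2.size == 0:
                continue
            if v1.max() < v2.min():
                gap, direction = v2.min() - v1.max(), "below_is_d1"
            elif v1.min() > v2.max():
                gap, direction = v1.min() - v2.max(), "above_is_d1"
            else:
                continue
            margin = gap / within if within > 0 else np.inf
            if (margin, gap) > best_key:  # gap breaks exact-margin ties
                best, best_key = (var, cls, direction), (margin, gap)
    return best


def greedy_build_tree(
    table: FeatureTable,
    threshold_first="auto",
    filter_specs="reference",
    order="greedy",
    forest_config: ForestConfig | None = None,
    seed: int | None = 0,
    terminal_acceptable: str = ACCEPTABLE_TECHNIQUE,
    alpha: float = 0.05,
    sidedness: str = "two_sided",
    correction: str = "none",
    exclude_flagged: bool = True,
) -> TreeModel:
    """Fit the full cascade.

    ``threshold_first``: "auto" (scan for a perfectly separating
    (feature, class) pair), an explicit ``(variable, d1)`` pair, or None for
    no threshold root.  ``filter_specs``: "reference" (the study-like filtered
    variables, by technique), "auto", None, or a mapping d1 -> variable list.
    ``order``: "greedy" (pick the out-of-bag best candidate at every node) or
    an explicit list of techniques.
    """
    forest_config = forest_config or ForestConfig()
    classes = sorted(set(table.techniques))
    if len(classes) < 3:
        raise ValidationError("need at least 3 classes to build a cascade")
    if terminal_acceptable not in classes:
        raise DataError(f"terminal class {terminal_acceptable!r} has no rows")
    rng = np.random.default_rng(None if seed is None else seed)

    root = None
    if threshold_first == "auto":
        found = find_perfect_separator(
            table, [c for c in classes if c != terminal_acceptable]
        )
        if found is None:
            logger.info("no perfectly separating (feature, class) pair; "
                        "building the cascade without a threshold root")
        else:
            var, d1, direction = found
            root = fit_threshold_node(table, d1, var, direction)
    elif threshold_first is not None:
        var, d1 = threshold_first
        # honour the requested variable; infer the direction from the data
        col = table.frame[var].to_numpy(dtype=float)
        mask = (table.techniques == d1).to_numpy()
        direction = "below_is_d1" if col[mask].mean() < col[~mask].mean() else "above_is_d1"
        root = fit_threshold_node(table, d1, var, direction)

    remaining = [c for c in classes if root is None or c != root.d1]

    def filter_spec_for(d1: str):
        if filter_specs == "reference":
            return reference_filter_variables().get(d1, None) or None
        if filter_specs in ("auto", None):
            return filter_specs
        return filter_specs.get(d1, None)

    nodes: list[NodeModel] = []
    node_index = 2 if root is not None else 1
    if order != "greedy":
        explicit = list(order)
        expected = [c for c in remaining if c != terminal_acceptable]
        if sorted(explicit) != sorted(expected):
            raise ValidationError(
                f"explicit order {explicit} must be a permutation of {sorted(expected)}"
            )
    while len(remaining) > 1:
        if order != "greedy":
            d1 = explicit[node_index - (2 if root is not None else 1)]
            node = fit_node(
                table, d1, [c for c in remaining if c != d1],
                filter_spec=filter_spec_for(d1), forest_config=forest_config,
                seed=rng.integers(2**31), node_index=node_index, alpha=alpha,
                sidedness=sidedness, correction=correction,
                exclude_flagged=exclude_flagged,
            )
        else:
            candidates = [c for c in remaining if c != terminal_acceptable]
            best_node, best_score = None, -np.inf
            for cand in candidates:
                trial_node = fit_node(
                    table, cand, [c for c in remaining if c != cand],
                    filter_spec=filter_spec_for(cand), forest_config=forest_config,
                    seed=rng.integers(2**31), node_index=node_index, alpha=alpha,
                    sidedness=sidedness, correction=correction,
                    exclude_flagged=exclude_flagged, oob=True,
                )
                score = _node_training_score(trial_node, table)
                if score > best_score:
                    best_node, best_score = trial_node, score
            node = best_node
        nodes.append(node)
        remaining = [c for c in remaining if c != node.d1]
        node_index += 1
    if remaining != [terminal_acceptable]:
        raise FitError(f"cascade did not terminate at {terminal_acceptable!r}")
    return TreeModel(
        root=root,
        nodes=nodes,
        terminal_acceptable=terminal_acceptable,
        config={
            "filter_specs": filter_specs if isinstance(filter_specs, str) else "explicit",
            "order": "greedy" if order == "greedy" else list(order),
            "alpha": alpha,
            "sidedness": sidedness,
            "correction": correction,
            "exclude_flagged": exclude_flagged,
            "forest": vars(forest_config).copy(),
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _row_value(row, name: str) -> float:
    """Feature value from a row mapping, deriving max-features when absent."""
    try:
        val = row[name]
    except (KeyError, IndexError):
        val = None
    if val is not None and not (isinstance(val, float) and np.isnan(val)):
        return float(val)
    parsed = parse_max_feature_name(name)
    if parsed is not None:
        a, b = parsed
        try:
            return float(max(row[a], row[b]))
        except (KeyError, IndexError):
            pass
    raise DataError(f"missing feature(s) for prediction: {name!r}")


def predict_row(model: TreeModel, row) -> tuple[str, int, str]:
    """Traverse the cascade for one observation.

    Returns (label, decision_node, decided_by) where decided_by is
    'threshold', 'filter' or 'forest'.
    """
    node_idx = 1
    if model.root is not None:
        if model.root.claims(_row_value(row, model.root.variable)):
            return model.root.d1, 1, "threshold"
        node_idx = 2
    for node in model.nodes:
        claimed, how = node.claims_row(row)
        if claimed:
            return node.d1, node.node_index, how
    last = model.nodes[-1].node_index if model.nodes else node_idx
    return model.terminal_acceptable, last, "forest"


def predict(model: TreeModel, table: FeatureTable):
    """Predict every row of a feature table.

    Returns a DataFrame with columns subject, technique_predicted,
    decision_node, decided_by.
    """
    import pandas as pd

    records = []
    for _, row in table.frame.iterrows():
        label, node, how = predict_row(model, row)
        records.append((row["subject"], label, node, how))
    return pd.DataFrame(
        records, columns=["subject", "technique_predicted", "decision_node", "decided_by"]
    )
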