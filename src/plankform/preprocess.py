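"""Stable-window feature extraction and engineered cross-sensor max-features.

Each raw trial is reduced to a single 60-vector by averaging every channel
over the stable middle portion of the recording,

    X_{k,j} = (1 / W) * sum_{t=start}^{end} x_{t,j}^{(k)},

with the default closed window t in [181, 420] (the 4th to 7th second at
60 Hz, W = 240 timestamps), chosen because the transients of getting into
and out of position live at the edges of a 10-s trial.  A fractional window
mode generalises to other trial lengths.

On top of the base features, pairwise maxima across sensors within the same
(measurement, axis) — e.g. ``max(Euler-Z-S5, Euler-Z-S1)`` — capture
relative sensor relationships that single channels miss.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, MalformedInputError, ValidationError
from .io import CHANNELS, ChannelID, FeatureTable, RawTrial

_MAX_NAME_RE = re.compile(r"^max\((?P<a>[^,()]+), (?P<b>[^,()]+)\)$")


@dataclass(frozen=True)
class WindowSpec:
    """Averaging window; timestamps are 1-based and both endpoints inclusive."""

    mode: str = "fixed"
    start: int = 181
    end: int = 420
    fraction_lo: float = 0.3
    fraction_hi: float = 0.7

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "fractional"):
            raise ValidationError("window mode must be 'fixed' or 'fractional'")
        if self.mode == "fixed" and not 1 <= self.start <= self.end:
            raise ValidationError("fixed window requires 1 <= start <= end")
        if self.mode == "fractional" and not 0 <= self.fraction_lo < self.fraction_hi <= 1:
            raise ValidationError("fractional window requires 0 <= lo < hi <= 1")

    def resolve(self, n_timestamps: int) -> tuple[int, int]:
        """Realized (start, end), 1-based inclusive, for a trial of length T."""
        if self.mode == "fixed":
            start, end = self.start, self.end
        else:
            start = math.floor(self.fraction_lo * n_timestamps) + 1
            end = math.floor(self.fraction_hi * n_timestamps)
        if end > n_timestamps:
            raise ValidationError(
                f"window [{start}, {end}] exceeds trial length {n_timestamps}"
            )
        return start, end


DEFAULT_WINDOW = WindowSpec()


def stable_window_mean(trial: RawTrial, window: WindowSpec = DEFAULT_WINDOW) -> np.ndarray:
    """Per-channel mean over the window: one 60-vector per trial."""
    try:
        start, end = window.resolve(trial.n_timestamps)
    except ValidationError as exc:
        raise ValidationError(
            f"trial ({trial.subject_id}, {trial.technique}): {exc}"
        ) from exc
    return trial.samples[start - 1 : end].mean(axis=0)


def build_feature_table(trials, window: WindowSpec = DEFAULT_WINDOW) -> FeatureTable:
    """One row of stable-window means per trial, 60 canonical columns."""
    trials = list(trials)
    seen = set()
    for tr in trials:
        key = (tr.subject_id, tr.technique)
        if key in seen:
            raise MalformedInputError(f"duplicate trial for {key}: row identity ambiguous")
        seen.add(key)
    rows = np.array([stable_window_mean(tr, window) for tr in trials]).reshape(
        len(trials), len(CHANNELS)
    )
    df = pd.DataFrame(rows, columns=list(CHANNELS))
    df.insert(0, "technique", [tr.technique for tr in trials])
    df.insert(0, "subject", [tr.subject_id for tr in trials])
    return FeatureTable(df)


# ---------------------------------------------------------------------------
# Engineered max-features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaxFeatureSpec:
    """Pairwise max of a base channel with same-measurement/axis partners."""

    base: str
    partners: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "partners", tuple(self.partners))
        b = ChannelID.parse(self.base)
        for p in self.partners:
            pid = ChannelID.parse(p)
            if (pid.measurement, pid.axis) != (b.measurement, b.axis):
                raise ValidationError(
                    f"partner {p} does not share measurement/axis with base {self.base}"
                )
            if pid.sensor == b.sensor:
                raise ValidationError(f"partner {p} has the same sensor as base {self.base}")

    def names(self) -> list[str]:
        return [max_feature_name(self.base, p) for p in self.partners]


def max_feature_name(base: str, partner: str) -> str:
    return f"max({base}, {partner})"


def parse_max_feature_name(name: str) -> tuple[str, str] | None:
    """Return (base, partner) if ``name`` is a max-feature name, else None."""
    m = _MAX_NAME_RE.match(name)
    return (m.group("a"), m.group("b")) if m else None


def add_max_features(table: FeatureTable, specs) -> FeatureTable:
    """Append one max(base, partner) column per spec partner; base columns untouched."""
    df = table.frame.copy()
    for spec in specs:
        if spec.base not in df.columns:
            raise DataError(f"base channel {spec.base} not in table")
        for partner in spec.partners:
            if partner not in df.columns:
                raise DataError(f"partner channel {partner} not in table")
            name = max_feature_name(spec.base, partner)
            if name in df.columns:
                raise ValidationError(f"column {name!r} already exists")
            df[name] = np.maximum(df[spec.base], df[partner])
    return FeatureTable(df)


def reference_max_feature_specs() -> list[MaxFeatureSpec]:
    """The nine engineered max-features used by the reference cascade filters."""
    return [
        MaxFeatureSpec("Euler-Z-S5", ("Euler-Z-S1", "Euler-Z-S2", "Euler-Z-S3", "Euler-Z-S4")),
        MaxFeatureSpec("Acc-X-S3", ("Acc-X-S2", "Acc-X-S4", "Acc-X-S5")),
        MaxFeatureSpec("Mag-Z-S3", ("Mag-Z-S2", "Mag-Z-S4")),
    ]


def reference_filter_variables() -> dict[str, tuple[str, ...]]:
    """Filtered variables of the reference cascade, keyed by the technique the
    node separates.  The HTFN node uses no filter; the hands-close node uses
    the four Euler-Z-S5 maxima; the hip-dropped node uses Euler-Z-S3 plus five
    cross-sensor maxima of Acc-X-S3 and Mag-Z-S3."""
    return {
        "HTFN": (),
        "HTB": ("Gyr-Z-S3",),
        "BC": ("Euler-Z-S3", "Acc-X-S4"),
        "HC": (
            "max(Euler-Z-S5, Euler-Z-S1)",
            "max(Euler-Z-S5, Euler-Z-S2)",
            "max(Euler-Z-S5, Euler-Z-S3)",
            "max(Euler-Z-S5, Euler-Z-S4)",
        ),
        "HD": (
            "Euler-Z-S3",
            "max(Acc-X-S3, Acc-X-S2)",
            "max(Acc-X-S3, Acc-X-S4)",
            "max(Acc-X-S3, Acc-X-S5)",
            "max(Mag-Z-S3, Mag-Z-S2)",
            "max(Mag-Z-S3, Mag-Z-S4)",
        ),
    }
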