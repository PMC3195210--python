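"""Correlation-based redundancy filtering of the feature set.

Several of the 11 features are near-duplicates by construction (e.g. entropy
and uniformity are tightly anti-correlated, EBI is essentially −b_i), so a
greedy rule keeps a feature only if its absolute Pearson correlation with
every feature already kept is below a threshold (default 0.7). Which member
of a correlated group survives is set by an explicit priority order, making
the reduced set reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DegenerateColumn
from .features import FEATURE_NAMES

#: Priority order under which the bundled reference correlation matrix yields
#: the six-feature set {r_i, RBI, EBI, W, WDR, U_t}.
DEFAULT_PRIORITY = ["r_i", "RBI", "EBI", "W", "WDR", "U_t", "g_i", "b_i", "ERI", "EGI", "E_t"]


@dataclass
class SelectionResult:
    """Outcome of the greedy low-correlation filter.

    ``dropped`` maps each discarded feature to the kept feature it was
    absorbed into (the first kept feature it correlated with at or above the
    threshold).
    """

    kept: list[str]
    dropped: dict[str, str] = field(default_factory=dict)
    threshold: float = 0.7

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"kept": self.kept, "dropped": self.dropped, "threshold": self.threshold},
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        return cls(kept=d["kept"], dropped=d["dropped"], threshold=d["threshold"])


def correlation_matrix(table: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlation matrix of the feature columns.

    Raises :class:`DegenerateColumn` if any feature is constant (its
    correlations are undefined).
    """
    features = features or [c for c in FEATURE_NAMES if c in table.columns]
    if len(table) < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    sub = table[features].astype(float)
    stds = sub.std(ddof=1)
    dead = stds[stds == 0].index.tolist()
    if dead:
        raise DegenerateColumn(f"zero-variance feature(s): {dead}")
    return sub.corr(method="pearson")


def select_features(
    corr: pd.DataFrame,
    threshold: float = 0.7,
    priority: list[str] | None = None,
) -> SelectionResult:
    """Greedy scan in priority order keeping only low-correlation features.

    A feature is kept iff its |r| with every already-kept feature is strictly
    below ``threshold``; otherwise it is recorded as absorbed into the first
    kept feature that conflicts with it.
    """
    labels = list(corr.columns)
    priority = priority or [f for f in DEFAULT_PRIORITY if f in labels]
    missing = set(labels) - set(priority)
    if missing:
        raise ValueError(f"priority order does not cover features: {sorted(missing)}")
    kept: list[str] = []
    dropped: dict[str, str] = {}
    for name in priority:
        if name not in labels:
            continue
        conflict = next(
            (k for k in kept if abs(float(corr.loc[name, k])) >= threshold), None
        )
        if conflict is None:
            kept.append(name)
        else:
            dropped[name] = conflict
    return SelectionResult(kept=kept, dropped=dropped, threshold=threshold)
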