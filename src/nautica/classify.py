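"""Decision rules for TF-pair interaction classification and threshold fitting.

A candidate TF pair carries three features: a boolean positional-interaction
label from an upstream predictor (TICA or equivalent), a boolean direct-edge
flag from the PPI network, and the shared-interactor count N12. The
classifier is a fixed four-branch decision tree over the two booleans, with
two fitted integer thresholds on N12:

==========  ===========  ==============================================
predictor   direct edge  rule
==========  ===========  ==============================================
yes         yes          COOP
yes         no           COOP if N12 >= tau_L else COMP (subclass COMP+)
no          yes          COOP if N12 >= tau_L else NINT
no          no           COMP (subclass COMP-) if N12 >= tau_H else NINT
==========  ===========  ==============================================

tau_L separates NINT from COOP for pairs supported by the network only, and
COOP from COMP for pairs supported by the positional predictor only; tau_H
separates NINT from COMP when neither source reports a direct interaction.
Thresholds are inclusive on the high-N12 side (N12 >= tau yields the
high-N12 label). The tree is table-driven (:data:`TREE_RULES`) so an
alternative topology is a configuration change rather than a rewrite.

COMP predictions are sub-classed: COMP+ pairs have positional co-binding
support (likely direct competition for a spot or partner), COMP- pairs have
none and are interpreted as members of rival complexes.

A one-feature baseline tree over N12 alone (NINT below ``L``, COMP in
``[L, H)``, COOP at ``H`` and above) serves as the network-only comparison
point; its published operating point is L=1, H=10, versus tau_L=5, tau_H=8
for the full tree.

Both trees are fitted by exhaustive grid search maximising per-class recall
on a curated training set, with the full per-grid-point recall table
returned for sensitivity inspection.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING, Iterable, NamedTuple, Sequence

import pandas as pd

from .errors import ConfigError

if TYPE_CHECKING:  # pragma: no cover
    from .candidates import CandidatePair

logger = logging.getLogger(__name__)


class InteractionLabel(str, Enum):
    """The three interaction classes."""

    COOP = "COOP"  # bind DNA together, or one recruits the other
    COMP = "COMP"  # mutually exclusive binding to a spot or shared partner
    NINT = "NINT"  # no physical interaction of any kind

    def __str__(self) -> str:
        return self.value


class CompSubclass(str, Enum):
    """Sub-classes of COMP predictions."""

    COMP_PLUS = "COMP+"   # positional support: likely direct spot competition
    COMP_MINUS = "COMP-"  # no positional support: rival-complex membership

    def __str__(self) -> str:
        return self.value


class Prediction(NamedTuple):
    """A class label plus an optional COMP subclass."""

    label: InteractionLabel
    subclass: CompSubclass | None = None


@dataclass(frozen=True)
class NauticaThresholds:
    """The two N12 thresholds of the full tree (defaults: fitted optimum)."""

    tau_l: int = 5
    tau_h: int = 8

    def __post_init__(self):
        if self.tau_l < 1 or self.tau_h < 1:
            raise ConfigError("thresholds must be positive integers")


@dataclass(frozen=True)
class BaselineThresholds:
    """The two band edges of the network-only baseline tree."""

    low: int = 1
    high: int = 10

    def __post_init__(self):
        if self.low < 1 or self.high < 1:
            raise ConfigError("thresholds must be positive integers")
        if not self.low < self.high:
            raise ConfigError("baseline requires L < H")


class BranchRule(NamedTuple):
    """One row of the decision table: which threshold applies and which
    (label, subclass) to emit below / at-or-above it."""

    threshold: str | None  # "tau_l", "tau_h", or None (no N12 test)
    below: Prediction
    at_or_above: Prediction


#: Decision table keyed by (predictor label, direct edge).
TREE_RULES: dict[tuple[bool, bool], BranchRule] = {
    (True, True): BranchRule(None,
                             Prediction(InteractionLabel.COOP),
                             Prediction(InteractionLabel.COOP)),
    (True, False): BranchRule("tau_l",
                              Prediction(InteractionLabel.COMP,
                                         CompSubclass.COMP_PLUS),
                              Prediction(InteractionLabel.COOP)),
    (False, True): BranchRule("tau_l",
                              Prediction(InteractionLabel.NINT),
                              Prediction(InteractionLabel.COOP)),
    (False, False): BranchRule("tau_h",
                               Prediction(InteractionLabel.NINT),
                               Prediction(InteractionLabel.COMP,
                                          CompSubclass.COMP_MINUS)),
}


def classify_features(
    tica_label: bool,
    direct_edge: bool,
    n12: int,
    thresholds: NauticaThresholds = NauticaThresholds(),
) -> Prediction:
    """Classify one feature triple with the full decision tree."""
    if n12 < 0:
        raise ValueError("n12 must be non-negative")
    rule = TREE_RULES[(bool(tica_label), bool(direct_edge))]
    if rule.threshold is None:
        return rule.at_or_above
    tau = getattr(thresholds, rule.threshold)
    return rule.at_or_above if n12 >= tau else rule.below


def classify_nautica(
    pair: "CandidatePair", thresholds: NauticaThresholds = NauticaThresholds()
) -> Prediction:
    """Classify a candidate pair with the full decision tree."""
    f = pair.features
    return classify_features(pair.tica_label, f.direct_edge, f.n12, thresholds)


def classify_baseline(
    n12: int, thresholds: BaselineThresholds = BaselineThresholds()
) -> Prediction:
    """Network-only baseline: NINT below L, COMP in [L, H), COOP at >= H."""
    if n12 < 0:
        raise ValueError("n12 must be non-negative")
    if n12 < thresholds.low:
        return Prediction(InteractionLabel.NINT)
    if n12 < thresholds.high:
        return Prediction(InteractionLabel.COMP)
    return Prediction(InteractionLabel.COOP)


# ---------------------------------------------------------------------------
# threshold fitting


def _per_class_recall(
    actual: Sequence[InteractionLabel], predicted: Sequence[InteractionLabel]
) -> dict[InteractionLabel, float]:
    recall = {}
    for cls in InteractionLabel:
        total = sum(1 for a in actual if a is cls)
        if total:
            hit = sum(1 for a, p in zip(actual, predicted) if a is cls and p is cls)
            recall[cls] = hit / total
    return recall


def _scalarise(recalls: dict[InteractionLabel, float], objective: str) -> float:
    if not recalls:
        return float("nan")
    if objective == "macro_recall":
        return sum(recalls.values()) / len(recalls)
    if objective == "min_class_recall":
        return min(recalls.values())
    raise ConfigError(f"unknown objective: {objective!r}")


def _check_classes(labels: Iterable[InteractionLabel]) -> None:
    present = set(labels)
    missing = [c.value for c in InteractionLabel if c not in present]
    if missing:
        logger.warning(
            "training set lacks class(es) %s; objective degenerates to the "
            "recall of the represented classes", ", ".join(missing),
        )


def fit_thresholds(
    train: Sequence[tuple["CandidatePair", InteractionLabel]],
    tau_l_grid: Iterable[int] = range(1, 13),
    tau_h_grid: Iterable[int] = range(1, 13),
    objective: str = "macro_recall",
) -> tuple[NauticaThresholds, pd.DataFrame]:
    """Grid-fit (tau_L, tau_H) by maximising per-class recall on ``train``.

    Every grid point is evaluated; the returned sensitivity table holds one
    row per point with per-class recalls and both scalarisations, so the
    recall trade-off between classes remains inspectable (the objective
    collapses it to one number only for the argmax). Ties are broken by the
    smallest (tau_H, tau_L) lexicographically.
    """
    if not train:
        raise ValueError("training set must be non-empty")
    points = list(itertools.product(tau_l_grid, tau_h_grid))
    if not points:
        raise ValueError("empty threshold grid")
    _check_classes(lbl for _, lbl in train)
    actual = [lbl for _, lbl in train]

    rows = []
    for tau_l, tau_h in points:
        th = NauticaThresholds(tau_l, tau_h)
        predicted = [classify_nautica(pair, th).label for pair, _ in train]
        recalls = _per_class_recall(actual, predicted)
        rows.append({
            "tau_l": tau_l,
            "tau_h": tau_h,
            **{f"recall_{c.value}": recalls.get(c) for c in InteractionLabel},
            "macro_recall": _scalarise(recalls, "macro_recall"),
            "min_class_recall": _scalarise(recalls, "min_class_recall"),
        })
    table = pd.DataFrame(rows)
    best = max(
        rows, key=lambda r: (r[objective], -r["tau_h"], -r["tau_l"])
    )
    return NauticaThresholds(best["tau_l"], best["tau_h"]), table


def fit_baseline_thresholds(
    train: Sequence[tuple[int, InteractionLabel]],
    low_grid: Iterable[int] = range(1, 9),
    high_grid: Iterable[int] = range(2, 13),
    objective: str = "macro_recall",
) -> tuple[BaselineThresholds, pd.DataFrame]:
    """Grid-fit the baseline band edges (L, H) on (n12, label) pairs.

    Accepts either raw N12 integers or objects exposing ``features.n12``.
    Grid points with L >= H are skipped. Ties are broken by the smallest
    (H, L) lexicographically.
    """
    if not train:
        raise ValueError("training set must be non-empty")
    n12s = [
        x if isinstance(x, int) else x.features.n12 for x, _ in train
    ]
    actual = [lbl for _, lbl in train]
    _check_classes(actual)
    points = [
        (lo, hi)
        for lo, hi in itertools.product(low_grid, high_grid)
        if lo < hi
    ]
    if not points:
        raise ValueError("empty threshold grid")
    rows = []
    for lo, hi in points:
        th = BaselineThresholds(lo, hi)
        predicted = [classify_baseline(n, th).label for n in n12s]
        recalls = _per_class_recall(actual, predicted)
        rows.append({
            "low": lo,
            "high": hi,
            **{f"recall_{c.value}": recalls.get(c) for c in InteractionLabel},
            "macro_recall": _scalarise(recalls, "macro_recall"),
            "min_class_recall": _scalarise(recalls, "min_class_recall"),
        })
    table = pd.DataFrame(rows)
    best = max(rows, key=lambda r: (r[objective], -r["high"], -r["low"]))
    return BaselineThresholds(best["low"], best["high"]), table
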