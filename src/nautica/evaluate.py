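"""Recall calibration, theoretical precision, and per-bin association stats.

Curated training/test sets of TF pairs are sampled roughly uniformly across
N12 bins, whereas the real candidate population is heavily skewed towards
low N12 (most random TF pairs share no partner). Raw recall on such a test
set therefore misrepresents performance on real data. Calibration reweights
each test pair by the relative population size of its N12 bin in a null
distribution: the bin with the fewest candidates is the base bin with weight
1, and every other bin gets ``floor(count / base count)``. A test pair
curated as NINT or COMP takes its weight from the NINT null (built over all
candidate pairs, which are predominantly non-interacting; too few curated
competitions exist to form a COMP null, and competing TFs are expected to
share few partners, like NINTs); a pair curated as COOP takes it from the
COOP null (built over curated co-operations). Each prediction then counts as
``m`` (its weight) predictions in the confusion matrix.

Precision cannot be read off a calibrated confusion matrix because the
weights are class-specific. Instead a closed-form estimate is used: assuming
a NINT:COMP:COOP population split (y, x_comp, x_coop) and per-class recalls
R_i, the precision of "interaction" (COOP or COMP) predictions is

    P_INT = (x_coop R_COOP + x_comp R_COMP)
            / (x_coop R_COOP + x_comp R_COMP + y (1 - R_NINT))

under the approximation that every missed non-interaction becomes a false
positive interaction. At the reference split 0.8/0.1/0.1 this evaluates to
0.46 with the full tree's recalls and 0.45 with the network-only baseline's.
For a symmetric split y:x:x, P_INT / 2x measures the fold improvement over
random guessing.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .classify import InteractionLabel
from .network import N_BINS, bin_index

logger = logging.getLogger(__name__)

_LABELS = [InteractionLabel.NINT, InteractionLabel.COMP, InteractionLabel.COOP]


def _as_bin(item) -> int:
    """Accept a raw bin/N12 integer, PairFeatures, or CandidatePair."""
    if isinstance(item, (int, np.integer)):
        return bin_index(int(item))
    if hasattr(item, "features"):
        return item.features.bin
    if hasattr(item, "bin"):
        return item.bin
    raise TypeError(f"cannot extract an N12 bin from {item!r}")


@dataclass
class NullDistribution:
    """Binned N12 counts of a reference pair population with floor-ratio
    calibration weights relative to the smallest non-empty bin."""

    bin_counts: dict[int, int]
    base_bin: int = field(init=False)
    weights: dict[int, int] = field(init=False)

    def __post_init__(self):
        positive = {b: c for b, c in self.bin_counts.items() if c > 0}
        if not positive:
            raise ValueError("null distribution has no non-empty bin")
        base_count = min(positive.values())
        # tie on the minimal count -> smallest bin index
        self.base_bin = min(b for b, c in positive.items() if c == base_count)
        self.weights = {b: c // base_count for b, c in positive.items()}

    def weight(self, bin_: int, fallback: int = 1) -> int:
        """Weight of a bin; empty bins fall back (with a warning) to 1."""
        if bin_ not in self.weights:
            logger.warning(
                "bin %d is empty in the null distribution; using fallback "
                "weight %d", bin_, fallback,
            )
            return fallback
        return self.weights[bin_]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"bin": b, "count": self.bin_counts.get(b, 0),
             "weight": self.weights.get(b)}
            for b in range(N_BINS)
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NullDistribution":
        df = pd.read_csv(path, sep="\t")
        return cls({int(r["bin"]): int(r["count"]) for _, r in df.iterrows()})


def build_null(pairs: Iterable) -> NullDistribution:
    """Bin a reference pair population into the eleven N12 bins.

    Accepts candidate pairs, feature objects, or raw N12/bin integers.
    """
    counts = {b: 0 for b in range(N_BINS)}
    n = 0
    for item in pairs:
        counts[_as_bin(item)] += 1
        n += 1
    if n == 0:
        raise ValueError("cannot build a null distribution from zero pairs")
    return NullDistribution(counts)


@dataclass
class WeightedConfusion:
    """A 3x3 confusion matrix (rows: actual, columns: predicted) whose cells
    are weighted prediction counts, plus the per-class recalls it implies."""

    cells: pd.DataFrame
    recalls: dict[InteractionLabel, float] = field(init=False)

    def __post_init__(self):
        self.recalls = {}
        for cls in _LABELS:
            row = self.cells.loc[cls.value]
            total = float(row.sum())
            if total > 0:
                self.recalls[cls] = float(row[cls.value]) / total


def confusion(
    test: Sequence[tuple],
    nint_null: NullDistribution | None = None,
    coop_null: NullDistribution | None = None,
    fallback_weight: int = 1,
) -> WeightedConfusion:
    """Tally (pair, actual, predicted) triples into a confusion matrix.

    Without nulls every pair counts once (raw confusion). With nulls, each
    pair contributes the weight of its N12 bin: the COOP null's weight if the
    curated label is COOP, the NINT null's otherwise (NINT and COMP alike).
    """
    cells = pd.DataFrame(
        0.0,
        index=[c.value for c in _LABELS],
        columns=[c.value for c in _LABELS],
    )
    for item, actual, predicted in test:
        actual = InteractionLabel(actual)
        predicted = getattr(predicted, "label", predicted)
        predicted = InteractionLabel(predicted)
        if nint_null is None and coop_null is None:
            w = 1
        else:
            null = coop_null if actual is InteractionLabel.COOP else nint_null
            w = null.weight(_as_bin(item), fallback_weight)
        cells.loc[actual.value, predicted.value] += w
    return WeightedConfusion(cells)


def calibrated_confusion(
    test: Sequence[tuple],
    nint_null: NullDistribution,
    coop_null: NullDistribution,
    fallback_weight: int = 1,
) -> WeightedConfusion:
    """Bin-weighted confusion matrix (see :func:`confusion`)."""
    if not test:
        raise ValueError("test set must be non-empty")
    return confusion(test, nint_null, coop_null, fallback_weight)


# ---------------------------------------------------------------------------
# theoretical precision


@dataclass
class PrecisionModel:
    """Population split and per-class recalls feeding the closed-form
    precision estimate.

    ``split`` is (y, x_coop, x_comp) = fractions of NINT, COOP and COMP
    pairs in the candidate population, summing to 1. ``m`` is the total
    candidate count; it cancels in the precision formula and is kept only to
    report absolute expected counts.
    """

    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    r_nint: float = 0.83
    r_comp: float = 0.39
    r_coop: float = 0.75
    m: int = 1

    def __post_init__(self):
        y, xc, xp = self.split
        if min(y, xc, xp) < 0 or abs(y + xc + xp - 1.0) > 1e-9:
            raise ValueError("split fractions must be non-negative and sum to 1")
        for r in (self.r_nint, self.r_comp, self.r_coop):
            if not 0.0 <= r <= 1.0:
                raise ValueError("recalls must lie in [0, 1]")
        if self.m < 1:
            raise ValueError("m must be a positive integer")


def precision_interaction(model: PrecisionModel) -> float:
    """Closed-form precision of "interaction" (COOP or COMP) predictions.

    Returns NaN when both the expected true positives and the expected false
    positives are zero (the estimate is undefined, not an error).
    """
    y, x_coop, x_comp = model.split
    tp = x_coop * model.r_coop + x_comp * model.r_comp
    fp = y * (1.0 - model.r_nint)
    if tp + fp == 0.0:
        return float("nan")
    return tp / (tp + fp)


def fold_over_random(
    x: float, recalls: tuple[float, float, float] = (0.83, 0.39, 0.75)
) -> float:
    """Fold improvement of P_INT over random guessing at a y:x:x split.

    With a fraction ``x`` each of COOP and COMP (and y = 1 - 2x of NINT), a
    random guesser's interaction precision is 2x; the fold is P_INT / 2x.
    ``recalls`` is (R_NINT, R_COMP, R_COOP).
    """
    if not 0.0 < x < 0.5:
        raise ValueError("x must lie strictly between 0 and 0.5")
    r_nint, r_comp, r_coop = recalls
    model = PrecisionModel(
        split=(1.0 - 2.0 * x, x, x),
        r_nint=r_nint, r_comp=r_comp, r_coop=r_coop,
    )
    return precision_interaction(model) / (2.0 * x)


# ---------------------------------------------------------------------------
# per-bin association statistics


def bin_association_stats(
    labelled_bins: Iterable[tuple[InteractionLabel, int]],
    class_a: InteractionLabel = InteractionLabel.COOP,
    class_b: InteractionLabel = InteractionLabel.NINT,
    yates: bool = False,
) -> pd.DataFrame:
    """Per-bin 2x2 association between two classes and bin membership.

    For every bin b the table (class_a vs class_b) x (in bin b vs not) is
    formed with cells (a, b, c, d) = (class_a in-bin, class_a out,
    class_b in-bin, class_b out); relative risk, odds ratio and a Pearson
    chi-squared p-value (Yates continuity correction off by default) are
    reported. Cells whose margins are zero yield NaN statistics.
    """
    items = [(InteractionLabel(lbl), _as_bin(b)) for lbl, b in labelled_bins]
    bins_a = [b for lbl, b in items if lbl is class_a]
    bins_b = [b for lbl, b in items if lbl is class_b]
    if not bins_a or not bins_b:
        raise ValueError("both classes must be present")
    rows = []
    for b in range(N_BINS):
        a_in = sum(1 for x in bins_a if x == b)
        a_out = len(bins_a) - a_in
        b_in = sum(1 for x in bins_b if x == b)
        b_out = len(bins_b) - b_in
        rr, or_ = contingency_stats(a_in, a_out, b_in, b_out)
        p = float("nan")
        table = np.array([[a_in, a_out], [b_in, b_out]])
        if table.sum(axis=0).min() > 0 and table.sum(axis=1).min() > 0:
            p = float(chi2_contingency(table, correction=yates)[1])
        rows.append({
            "bin": b, "a_in": a_in, "a_out": a_out,
            "b_in": b_in, "b_out": b_out,
            "chi2_p": p, "relative_risk": rr, "odds_ratio": or_,
        })
    return pd.DataFrame(rows)


def contingency_stats(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Relative risk and odds ratio of one 2x2 table, rows (a, b) / (c, d).

    RR = (a/(a+b)) / (c/(c+d)); OR = ad / (bc). Tables with a zero margin or
    a zero divisor yield NaN rather than raising.
    """
    rr = (a / (a + b)) / (c / (c + d)) if (a + b) and (c + d) and c else float("nan")
    or_ = (a * d) / (b * c) if b and c else float("nan")
    return rr, or_
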