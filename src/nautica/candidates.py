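"""Reading prediction and curated-label tables; assembling candidate pairs.

The upstream positional predictor (TICA or any ChIP-seq co-binding tool)
emits one boolean per TF pair per cell-line context. Contexts are aggregated
with a logical OR — a pair predicted to interact in any context counts as a
positive, and additional supporting contexts add nothing. Curated label
tables carry literature-derived COOP/COMP/NINT labels; pairs with
conflicting labels are ambiguous and are dropped before any fitting.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._util import canonical_pair
from .classify import InteractionLabel
from .errors import FormatError
from .network import PPINetwork, PairFeatures, pair_features

logger = logging.getLogger(__name__)

_TRUE_TOKENS = {"1", "true", "t", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n"}


def _parse_bool(token: str, where: str) -> bool:
    t = str(token).strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise FormatError(f"{where}: unparseable boolean {token!r}")


@dataclass
class PredictionTable:
    """Canonicalised per-(pair, context) boolean predictions."""

    df: pd.DataFrame  # columns: tf_a, tf_b, context, predicted

    def aggregate(self) -> dict[tuple[str, str], tuple[bool, list[str]]]:
        """OR-aggregate contexts: pair -> (label, supporting contexts)."""
        out: dict[tuple[str, str], tuple[bool, list[str]]] = {}
        for (a, b), grp in self.df.groupby(["tf_a", "tf_b"], sort=True):
            supporting = sorted(grp.loc[grp["predicted"], "context"])
            out[(a, b)] = (bool(supporting), supporting)
        return out

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class CuratedPair:
    """A literature-curated TF pair with its interaction label."""

    tf_a: str
    tf_b: str
    label: InteractionLabel
    source: str = ""


@dataclass
class CandidatePair:
    """A classifier-ready pair: network features plus the aggregated
    positional-prediction label and its supporting contexts."""

    features: PairFeatures
    tica_label: bool
    contexts_supporting: list[str] = field(default_factory=list)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.features.tf_a, self.features.tf_b)


def read_predictions(path: str | Path) -> PredictionTable:
    """Read a predictions TSV (header: tf_a, tf_b, context, predicted).

    Pairs are canonicalised; exact duplicate (pair, context) rows collapse;
    duplicates that disagree on the predicted value are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["tf_a", "tf_b", "context", "predicted"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    records = []
    for i, row in df.iterrows():
        a, b = canonical_pair(row["tf_a"], row["tf_b"])
        pred = _parse_bool(row["predicted"], f"{path}:{i + 2}")
        records.append((a, b, str(row["context"]).strip(), pred))
    out = pd.DataFrame(records, columns=["tf_a", "tf_b", "context", "predicted"])
    out = out.drop_duplicates()
    conflicted = out.duplicated(subset=["tf_a", "tf_b", "context"], keep=False)
    if conflicted.any():
        bad = out.loc[conflicted, ["tf_a", "tf_b", "context"]].drop_duplicates()
        raise FormatError(
            f"{path}: conflicting predictions for "
            + "; ".join(f"{a}/{b} in {c}" for a, b, c in bad.itertuples(index=False))
        )
    out = out.sort_values(["tf_a", "tf_b", "context"]).reset_index(drop=True)
    return PredictionTable(out)


def read_curated(path: str | Path) -> list[CuratedPair]:
    """Read a curated-label TSV (header: tf_a, tf_b, label[, source]).

    Labels are parsed case-insensitively into COOP/COMP/NINT. A pair appearing
    with more than one distinct label is ambiguous and every occurrence of it
    is dropped with a warning, mirroring the exclusion of multi-category pairs
    from threshold fitting.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        logger.warning("read_curated(%s): empty file", path)
        return []
    for col in ("tf_a", "tf_b", "label"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    by_pair: dict[tuple[str, str], list[tuple[InteractionLabel, str]]] = {}
    for i, row in df.iterrows():
        a, b = canonical_pair(row["tf_a"], row["tf_b"])
        token = str(row["label"]).strip().upper()
        try:
            label = InteractionLabel(token)
        except ValueError:
            raise FormatError(f"{path}:{i + 2}: unknown label token {row['label']!r}")
        source = str(row["source"]).strip() if "source" in df.columns and pd.notna(row.get("source")) else ""
        by_pair.setdefault((a, b), []).append((label, source))
    out: list[CuratedPair] = []
    for (a, b), entries in sorted(by_pair.items()):
        labels = {lbl for lbl, _ in entries}
        if len(labels) > 1:
            logger.warning(
                "read_curated(%s): pair %s/%s has conflicting labels %s; dropped",
                path, a, b, sorted(l.value for l in labels),
            )
            continue
        label, source = entries[0]
        out.append(CuratedPair(a, b, label, source))
    return out


@dataclass
class SkipReport:
    """Pairs excluded from candidate assembly, by reason."""

    ineligible: list[tuple[str, str]] = field(default_factory=list)
    missing_from_network: list[tuple[str, str]] = field(default_factory=list)

    def total(self) -> int:
        return len(self.ineligible) + len(self.missing_from_network)


def assemble_candidates(
    net: PPINetwork,
    preds: PredictionTable,
    eligible: frozenset[str] | set[str] | None = None,
    min_degree: int = 3,
) -> tuple[list[CandidatePair], SkipReport]:
    """One classifier-ready candidate per predicted pair of eligible TFs.

    ``eligible`` is the eligible-TF set from
    :func:`nautica.network.filter_network`; when omitted it is recomputed
    from the network's TF flags and ``min_degree``. Pairs whose members are
    not both eligible are skipped, not failed, and reported. Output is sorted
    by canonical pair, so assembly is deterministic and order-stable.
    """
    if eligible is None:
        eligible = {
            t for t, is_tf in net.tf_flags.items()
            if is_tf and net.graph.degree[t] >= min_degree
        }
    skip = SkipReport()
    candidates: list[CandidatePair] = []
    for (a, b), (label, contexts) in sorted(preds.aggregate().items()):
        if a not in net.graph.nodes or b not in net.graph.nodes:
            skip.missing_from_network.append((a, b))
            continue
        if a not in eligible or b not in eligible:
            skip.ineligible.append((a, b))
            continue
        candidates.append(
            CandidatePair(pair_features(net, a, b), label, contexts)
        )
    if skip.total():
        logger.info(
            "assemble_candidates: %d candidates, %d skipped "
            "(%d ineligible, %d absent from network)",
            len(candidates), skip.total(),
            len(skip.ineligible), len(skip.missing_from_network),
        )
    return candidates, skip
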