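"""Protein-complex co-membership enrichment of predicted classes.

Co-operating TFs bind DNA as (or via recruitment into) a shared unit, so
they should appear together in curated complex databases such as CORUM far
more often than competing or non-interacting pairs; competitors may still
co-occur occasionally (same complex in one context, mutually exclusive in
another). The analysis checks, for each predicted pair, whether at least one
complex contains both members, reports the percentage per predicted class,
and the fold-increase (ratio of percentages) between classes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._util import normalize_symbol
from .classify import InteractionLabel
from .errors import FormatError

logger = logging.getLogger(__name__)

#: Default column names for a CORUM allComplexes-style file.
CORUM_COLUMNS = {"complex_id": "ComplexID", "subunits": "subunits(Gene name)"}


@dataclass
class ComplexDB:
    """Map of complex id -> set of member gene symbols."""

    complexes: dict[str, frozenset[str]]

    def __len__(self) -> int:
        return len(self.complexes)

    def members(self, complex_id: str) -> frozenset[str]:
        return self.complexes[complex_id]


def read_complexes(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> ComplexDB:
    """Read a tab-delimited complex table (CORUM allComplexes style).

    Requires a complex-id column and a subunit gene-name column whose members
    are semicolon-separated. Duplicate complex ids have their members
    unioned; complexes with no members are dropped. Both cases are warned.
    """
    cols = dict(CORUM_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for key in ("complex_id", "subunits"):
        if cols[key] not in df.columns:
            raise FormatError(f"missing required column {cols[key]!r} in {path}")
    complexes: dict[str, set[str]] = {}
    n_dup = n_empty = 0
    for _, row in df.iterrows():
        cid = str(row[cols["complex_id"]]).strip()
        raw = row[cols["subunits"]]
        members = {
            normalize_symbol(m)
            for m in (str(raw).split(";") if pd.notna(raw) else [])
            if m.strip()
        }
        if not members:
            n_empty += 1
            continue
        if cid in complexes:
            n_dup += 1
            complexes[cid] |= members
        else:
            complexes[cid] = members
    if n_dup or n_empty:
        logger.warning(
            "read_complexes(%s): unioned %d duplicate ids, dropped %d empty "
            "member lists", path, n_dup, n_empty,
        )
    return ComplexDB({cid: frozenset(m) for cid, m in complexes.items()})


def co_complex(db: ComplexDB, a: str, b: str) -> bool:
    """True iff at least one complex contains both symbols."""
    a, b = normalize_symbol(a), normalize_symbol(b)
    if a == b:
        raise ValueError("co_complex requires two distinct symbols")
    return any(a in members and b in members for members in db.complexes.values())


def fold_increase(pct_a: float, pct_b: float) -> float:
    """Ratio of two class co-complex percentages; NaN when pct_b is zero."""
    if pct_b == 0:
        return float("nan")
    return pct_a / pct_b


def class_enrichment(
    predictions: Iterable[tuple[tuple[str, str], InteractionLabel]],
    db: ComplexDB,
    restrict_to_db: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class co-complex membership and pairwise fold-increases.

    ``predictions`` yields ((tf_a, tf_b), label). The percentage denominator
    is, by default, every prediction of the class; with ``restrict_to_db``
    it is restricted to pairs whose both members occur somewhere in the
    database (a sensitivity mode for symbol-coverage effects).

    Returns (per-class table, fold matrix). The fold matrix cell (r, c) is
    percentage(r) / percentage(c); undefined ratios are NaN.
    """
    all_members: set[str] = set().union(*db.complexes.values()) if db.complexes else set()
    totals = {c: 0 for c in InteractionLabel}
    in_db = {c: 0 for c in InteractionLabel}
    for (a, b), label in predictions:
        label = InteractionLabel(label)
        a, b = normalize_symbol(a), normalize_symbol(b)
        if restrict_to_db and not (a in all_members and b in all_members):
            continue
        totals[label] += 1
        if co_complex(db, a, b):
            in_db[label] += 1
    order = [InteractionLabel.COOP, InteractionLabel.COMP, InteractionLabel.NINT]
    rows = []
    pct = {}
    for c in order:
        p = 100.0 * in_db[c] / totals[c] if totals[c] else float("nan")
        pct[c] = p
        rows.append({
            "label": c.value, "n_total": totals[c],
            "n_in_db": in_db[c], "percentage": p,
        })
    table = pd.DataFrame(rows)
    folds = pd.DataFrame(
        [[fold_increase(pct[r], pct[c]) for c in order] for r in order],
        index=[c.value for c in order],
        columns=[c.value for c in order],
    )
    return table, folds
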