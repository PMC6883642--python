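"""Core inference: KO sets → producible compound sets → origin categories.

A source (e.g. a predicted gut-microbiome metagenome, or the host genome) is
a labelled KO set.  Its *producible* compound set is the union of
right-hand-side compounds over every reaction reachable from those KOs —
reaction direction is assumed left-to-right, so substrate-only compounds are
never called producible.  Given one producible set per source and an
optional detected-metabolome compound list, each compound is assigned an
origin category: which sources could have produced it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError
from .kegg_db import KeggDatabase

logger = logging.getLogger(__name__)


def kos_to_reactions(ko_ids: Iterable[str], db: KeggDatabase) -> set[str]:
    """Union of reaction ids linked to the given KOs (unknown KOs skipped)."""
    reactions: set[str] = set()
    unknown = 0
    for ko_id in ko_ids:
        ko = db.orthologs.get(ko_id)
        if ko is None:
            unknown += 1
            logger.debug("KO %s not in database", ko_id)
            continue
        reactions.update(ko.reaction_ids)
    if unknown:
        logger.info("%d KO ids not found in the database", unknown)
    return reactions


def reactions_to_products(
    reaction_ids: Iterable[str],
    db: KeggDatabase,
    include_reverse: bool = False,
) -> set[str]:
    """Union of product compound ids over the given reactions.

    Products are the right-hand side of each equation.  With
    ``include_reverse`` the substrates of reversible (``<=>``) reactions are
    added too — an explicit opt-out from the left-to-right assumption.
    Reactions missing from the database or lacking an equation are skipped
    with a log entry.
    """
    products: set[str] = set()
    for rid in reaction_ids:
        reaction = db.reactions.get(rid)
        if reaction is None:
            logger.debug("reaction %s not in database", rid)
            continue
        if reaction.equation is None:
            logger.debug("reaction %s has no equation; skipped", rid)
            continue
        products.update(reaction.equation.product_ids)
        if include_reverse and reaction.equation.arrow == "reversible":
            products.update(reaction.equation.substrate_ids)
    return products


@dataclass
class SourceSet:
    """A labelled KO set with its derived reaction and producible-compound closure."""

    label: str
    ko_ids: set[str]
    reaction_ids: set[str] = field(default_factory=set)
    producible_compounds: set[str] = field(default_factory=set)
    n_kos_with_reactions: int = 0


def build_source(
    label: str,
    ko_ids: Iterable[str],
    db: KeggDatabase,
    include_reverse: bool = False,
) -> SourceSet:
    """Derive a source's reaction set and producible-compound closure."""
    ko_ids = set(ko_ids)
    if not ko_ids:
        logger.warning("source %r has an empty KO set", label)
    reaction_ids = kos_to_reactions(ko_ids, db)
    n_with = sum(
        1
        for k in ko_ids
        if k in db.orthologs and db.orthologs[k].reaction_ids
    )
    producible = reactions_to_products(reaction_ids, db, include_reverse=include_reverse)
    logger.info(
        "source %r: %d KOs, %d with reactions, %d reactions, %d producible compounds",
        label, len(ko_ids), n_with, len(reaction_ids), len(producible),
    )
    return SourceSet(
        label=label,
        ko_ids=ko_ids,
        reaction_ids=reaction_ids,
        producible_compounds=producible,
        n_kos_with_reactions=n_with,
    )


@dataclass
class OriginRow:
    compound_id: str
    detected: bool
    producible_by: dict[str, bool]
    category: str
    in_database: bool = True


@dataclass
class OriginTable:
    """Per-compound producibility flags per source plus the derived category.

    For exactly two sources the category is one of ``{<label1>_only,
    <label2>_only, both, neither}``; for N sources it is the ``+``-joined
    subset of producing labels (or ``neither``).  Those categories partition
    the compound rows by construction.
    """

    source_labels: list[str]
    rows: dict[str, OriginRow]

    def category_counts(self, detected_only: bool = False) -> dict[str, int]:
        counts: dict[str, int] = {}
        for row in self.rows.values():
            if detected_only and not row.detected:
                continue
            counts[row.category] = counts.get(row.category, 0) + 1
        return counts

    def compounds_in_category(self, category: str, detected_only: bool = False) -> set[str]:
        return {
            cid
            for cid, row in self.rows.items()
            if row.category == category and (row.detected or not detected_only)
        }

    def categories(self) -> list[str]:
        """All category labels possible for this table's sources, in emit order."""
        if len(self.source_labels) == 2:
            a, b = self.source_labels
            return [f"{a}_only", f"{b}_only", "both", "neither"]
        seen = sorted({row.category for row in self.rows.values()})
        return seen

    def to_frame(self, db: KeggDatabase | None = None) -> pd.DataFrame:
        records = []
        for cid in sorted(self.rows):
            row = self.rows[cid]
            rec = {
                "compound_id": cid,
                "compound_name": db.compound_name(cid) if db else cid,
                "detected": row.detected,
            }
            for label in self.source_labels:
                rec[label] = row.producible_by[label]
            rec["category"] = row.category
            rec["in_database"] = row.in_database
            records.append(rec)
        columns = (
            ["compound_id", "compound_name", "detected"]
            + list(self.source_labels)
            + ["category", "in_database"]
        )
        return pd.DataFrame.from_records(records, columns=columns)


def _category(producible_by: dict[str, bool], source_labels: Sequence[str]) -> str:
    producing = [label for label in source_labels if producible_by[label]]
    if not producing:
        return "neither"
    if len(producing) == 1:
        return f"{producing[0]}_only"
    if len(source_labels) == 2:
        return "both"
    return "+".join(producing)


def classify_origins(
    sources: Sequence[SourceSet],
    detected: set[str] | None = None,
    db: KeggDatabase | None = None,
) -> OriginTable:
    """Classify each compound's putative origin across sources.

    Rows cover the union of all sources' producible compounds plus every
    detected compound; detected compounds that no source can produce (or
    that are absent from the database entirely) stay in the table as
    ``neither`` rather than being dropped — they are the interesting
    "unexplained" fraction of a metabolome.
    """
    if not sources:
        raise ConfigError("at least one source is required")
    labels = [s.label for s in sources]
    if len(set(labels)) != len(labels):
        raise ConfigError(f"duplicate source labels: {labels}")
    detected = set(detected) if detected else set()

    all_compounds = set().union(*(s.producible_compounds for s in sources)) | detected
    rows: dict[str, OriginRow] = {}
    for cid in all_compounds:
        producible_by = {s.label: cid in s.producible_compounds for s in sources}
        rows[cid] = OriginRow(
            compound_id=cid,
            detected=cid in detected,
            producible_by=producible_by,
            category=_category(producible_by, labels),
            in_database=(db is None) or (cid in db.compounds),
        )
    table = OriginTable(source_labels=labels, rows=rows)
    logger.info(
        "origin table: %d compounds, %d detected, categories %s",
        len(rows), sum(r.detected for r in rows.values()),
        table.category_counts(detected_only=bool(detected)),
    )
    return table
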