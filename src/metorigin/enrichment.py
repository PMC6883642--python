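"""Hypergeometric pathway enrichment with Benjamini-Hochberg FDR control.

For a query compound set (e.g. the detected metabolites attributable to one
source) drawn from a background universe of N compounds, a pathway holding K
universe compounds is tested with the upper-tail hypergeometric probability
P[X >= k] of seeing k or more pathway members in a query of size n.  The
survival function is exact (log-space combinatorials via scipy), never a
normal or chi-square approximation — enrichment calls live at small k where
approximations are worst.  BH adjustment is applied across exactly the
pathways tested, i.e. those with at least one query member.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DomainError
from .kegg_db import KeggDatabase

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["pathway_id", "pathway_name", "k", "K", "n", "N", "p_raw", "p_adj"]


def hypergeom_sf(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail probability P[X >= k], X ~ Hypergeometric(N, K, n).

    N is the universe size, K the number of marked items (pathway members),
    n the draw (query) size and k the observed overlap.
    """
    for name, value in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(value) != value or value < 0:
            raise DomainError(f"{name}={value} must be a non-negative integer")
    if K > N:
        raise DomainError(f"K <= N violated: K={K}, N={N}")
    if n > N:
        raise DomainError(f"n <= N violated: n={n}, N={N}")
    if k > min(K, n):
        raise DomainError(f"k <= min(K, n) violated: k={k}, K={K}, n={n}")
    # sf(k-1) = P[X > k-1] = P[X >= k]; exact for the hypergeometric
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p_values = list(p_values)
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise DomainError(f"p-value {p} outside [0, 1]")
    if not p_values:
        return []
    return list(multipletests(p_values, method="fdr_bh")[1])


def pathway_universe(
    db: KeggDatabase,
    mode: str = "pathway-annotated",
    detected: Iterable[str] | None = None,
) -> set[str]:
    """The background compound universe for enrichment.

    ``pathway-annotated`` (default): every database compound belonging to at
    least one pathway — the least-biased background that can actually join
    against pathway membership.  ``all``: every database compound.
    ``detected``: the detected-metabolome compounds.
    """
    if mode == "pathway-annotated":
        return {
            cid for cid, c in db.compounds.items() if c.pathway_ids
        } | {cid for p in db.pathways.values() for cid in p.compound_ids if cid in db.compounds}
    if mode == "all":
        return set(db.compounds)
    if mode == "detected":
        if detected is None:
            raise ConfigError("universe mode 'detected' requires a detected-compound set")
        return set(detected)
    raise ConfigError(f"unknown universe mode: {mode!r}")


def _pathway_members(db: KeggDatabase, pathway_id: str) -> set[str]:
    # pathway->compound and compound->pathway links are unioned so either
    # direction of annotation in the source files suffices
    members = set(db.pathways[pathway_id].compound_ids)
    members.update(
        cid for cid, c in db.compounds.items() if pathway_id in c.pathway_ids
    )
    return members


def pathway_enrichment(
    query_compounds: set[str],
    db: KeggDatabase,
    universe: set[str],
) -> pd.DataFrame:
    """Test every pathway with >= 1 query member for enrichment.

    Query compounds outside the universe are dropped (logged).  Returns one
    row per tested pathway, sorted by raw p ascending with ties broken by
    pathway id; BH adjustment spans exactly the emitted rows.
    """
    if not universe:
        raise ConfigError("enrichment universe is empty")
    query = set(query_compounds) & universe
    dropped = len(set(query_compounds)) - len(query)
    if dropped:
        logger.info("%d query compounds outside the universe dropped", dropped)
    if not query:
        logger.warning("empty query after universe intersection; no enrichment rows")
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)

    n = len(query)
    N = len(universe)
    records = []
    for pathway_id in sorted(db.pathways):
        members = _pathway_members(db, pathway_id) & universe
        k = len(query & members)
        if k == 0:
            continue
        K = len(members)
        records.append(
            {
                "pathway_id": pathway_id,
                "pathway_name": db.pathways[pathway_id].name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_raw": hypergeom_sf(k, K, n, N),
            }
        )
    frame = pd.DataFrame.from_records(records, columns=ENRICHMENT_COLUMNS[:-1])
    frame["p_adj"] = bh_adjust(list(frame["p_raw"]))
    frame = frame.sort_values(
        ["p_raw", "pathway_id"], kind="mergesort"
    ).reset_index(drop=True)
    return frame[ENRICHMENT_COLUMNS]
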