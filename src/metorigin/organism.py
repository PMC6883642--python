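"""Derive the unique KO set encoded by a KEGG organism.

The input is a gene-to-KO link table (the ``/link/ko/<org>`` REST dialect):
two tab-separated columns, ``<org>:<gene>\\tko:K#####`` per line.  The bare
``K#####`` form in column two is also accepted, since FTP dumps omit the
namespace prefix.  The resulting KO set is what the pipeline consumes as a
host "source" (e.g. the human genome's KO content).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable

from .errors import KeggParseError
from .kegg_db import KO_ID_RE, RestClient

logger = logging.getLogger(__name__)

_LINK_LINE_RE = re.compile(r"^(?P<gene>\S+:\S+)\t(?:ko:)?(?P<ko>K\d{5})\s*$")


@dataclass
class OrganismKoSet:
    """The unique KOs encoded by one organism, with gene-mapping counts."""

    org_code: str
    ko_ids: set[str] = field(default_factory=set)
    n_genes_mapped: int = 0
    n_genes_unmapped: int = 0

    def to_lines(self) -> list[str]:
        """One KO per line, sorted lexicographically (deterministic output)."""
        return sorted(self.ko_ids)


def parse_gene_ko_links(
    lines: Iterable[str],
    org_code: str = "",
    gene_universe: set[str] | None = None,
) -> OrganismKoSet:
    """Parse a two-column gene→KO link table into an :class:`OrganismKoSet`.

    Gene→KO is many-to-one and many genes can map to the same KO, so
    ``n_genes_mapped`` may exceed the KO-set size.  Genes in
    ``gene_universe`` with no KO line are counted as unmapped; without a
    universe the unmapped count is 0 (the link table only lists mapped
    genes).  A line not matching the dialect raises a parse error with its
    line number.
    """
    ko_ids: set[str] = set()
    mapped_genes: set[str] = set()
    n_lines = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        m = _LINK_LINE_RE.match(line.rstrip("\n"))
        if not m:
            raise KeggParseError(
                f"line {lineno}: not a '<org>:<gene>\\tko:K#####' link line: {line.rstrip()!r}"
            )
        ko_ids.add(m.group("ko"))
        mapped_genes.add(m.group("gene"))
        n_lines += 1
    if n_lines == 0:
        logger.warning("empty gene->KO link table for %r", org_code or "<unknown>")
    n_unmapped = len(gene_universe - mapped_genes) if gene_universe else 0
    return OrganismKoSet(
        org_code=org_code,
        ko_ids=ko_ids,
        n_genes_mapped=len(mapped_genes),
        n_genes_unmapped=n_unmapped,
    )


def extract_organism_kos(
    org_code: str = "",
    stream=None,
    client: RestClient | None = None,
    gene_universe: set[str] | None = None,
) -> OrganismKoSet:
    """Extract an organism's KO set from a link-table stream or the REST API.

    Exactly one of ``stream`` (text or file-like) and ``client`` must be
    given; with a client, ``org_code`` selects the ``/link/ko/<org>`` table.
    """
    if (stream is None) == (client is None):
        raise ValueError("provide exactly one of stream or client")
    if stream is not None:
        text = stream if isinstance(stream, str) else stream.read()
    else:
        if not org_code:
            raise ValueError("org_code is required when fetching via the API")
        text = client.get_link_table("ko", org_code)
    result = parse_gene_ko_links(
        text.splitlines(), org_code=org_code, gene_universe=gene_universe
    )
    assert all(KO_ID_RE.fullmatch(k) for k in result.ko_ids)
    return result
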