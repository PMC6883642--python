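"""KEGG record model, flat-file parsing, REST client and database assembly.

The flat-file dialect handled here is the classic KEGG one: records are
terminated by a ``///`` line, field labels occupy a fixed 12-character
left-justified column, and continuation lines are indented past that column.
Only the fields this pipeline needs (ENTRY, NAME, EQUATION, ORTHOLOGY,
PATHWAY, REACTION, COMPOUND) are captured; everything else is ignored.

Reaction equations are directed left-to-right: the right-hand side of the
equation is taken as the product set.  The flat files do not encode
reversibility beyond the arrow token, so ``<=>`` is recorded as reversible and
``=>`` as forward; a ``<=`` arrow is normalized by swapping sides.
"""

from __future__ import annotations

import logging
import re
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .errors import EquationParseError, FetchError, KeggParseError, UnknownIdError

logger = logging.getLogger(__name__)

KO_ID_RE = re.compile(r"K\d{5}")
REACTION_ID_RE = re.compile(r"R\d{5}")
COMPOUND_ID_RE = re.compile(r"[CG]\d{5}")
PATHWAY_ID_RE = re.compile(r"(?:[a-z]{2,4})?(\d{5})")

LABEL_WIDTH = 12
RECORD_KINDS = ("ko", "reaction", "compound", "pathway")

Coefficient = int | str  # ints, or symbolic text like "n" / "(n+1)"


def normalize_pathway_id(token: str) -> str:
    """Map any per-namespace pathway id (ko00650, hsa00650, 00650) to map00650.

    KEGG prefixes pathway ids with an organism or database namespace; origin
    and enrichment need a single key space so KO-linked and compound-linked
    references join.
    """
    m = PATHWAY_ID_RE.fullmatch(token.strip())
    if not m:
        raise KeggParseError(f"not a pathway identifier: {token!r}")
    return "map" + m.group(1)


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------

@dataclass
class ReactionEquation:
    """A parsed, directed reaction equation.

    ``substrates`` and ``products`` are (compound_id, coefficient) pairs;
    coefficients are positive ints, or the original symbolic text (e.g.
    ``"(n+1)"``) which counts as presence for product-set purposes.
    ``raw`` preserves the input string byte-for-byte.
    """

    substrates: tuple[tuple[str, Coefficient], ...]
    products: tuple[tuple[str, Coefficient], ...]
    arrow: str  # "reversible" | "forward"
    raw: str

    @property
    def substrate_ids(self) -> set[str]:
        return {cid for cid, _ in self.substrates}

    @property
    def product_ids(self) -> set[str]:
        return {cid for cid, _ in self.products}


@dataclass
class KeggOrtholog:
    ko_id: str
    name: str = ""
    reaction_ids: set[str] = field(default_factory=set)
    pathway_ids: set[str] = field(default_factory=set)


@dataclass
class KeggReaction:
    reaction_id: str
    name: str = ""
    equation: ReactionEquation | None = None  # None: record lacked EQUATION
    orthology_ids: set[str] = field(default_factory=set)


@dataclass
class KeggCompound:
    compound_id: str
    names: list[str] = field(default_factory=list)
    pathway_ids: set[str] = field(default_factory=set)

    @property
    def display_name(self) -> str:
        return self.names[0] if self.names else self.compound_id


@dataclass
class KeggPathway:
    pathway_id: str
    name: str = ""
    compound_ids: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# Equation grammar
# ---------------------------------------------------------------------------

_ARROW_RE = re.compile(r"<=>|=>|<=")
_TERM_RE = re.compile(
    r"^(?:(?P<coef>\d+|\(?\d*n(?:\s*[+-]\s*\d+)?\)?)\s+)?(?P<cid>[CG]\d{5})$"
)


def _parse_side(side: str, raw: str) -> tuple[tuple[str, Coefficient], ...]:
    terms = [t.strip() for t in side.strip().split(" + ")]
    if terms == [""]:
        raise EquationParseError(f"empty equation side in {raw!r}")
    parsed: list[tuple[str, Coefficient]] = []
    for term in terms:
        m = _TERM_RE.match(term)
        if not m:
            raise EquationParseError(f"unrecognized term {term!r} in {raw!r}")
        coef_text = m.group("coef")
        coef: Coefficient
        if coef_text is None:
            coef = 1
        elif coef_text.isdigit():
            coef = int(coef_text)
        else:
            coef = coef_text  # symbolic, kept verbatim
        parsed.append((m.group("cid"), coef))
    return tuple(parsed)


def parse_equation(text: str) -> ReactionEquation:
    """Parse a KEGG reaction equation into directed substrate/product lists.

    Exactly one arrow token (``<=>``, ``=>`` or ``<=``) must be present.
    ``<=`` equations are normalized by swapping sides so that downstream
    logic only ever sees left-to-right direction.
    """
    arrows = _ARROW_RE.findall(text)
    if len(arrows) != 1:
        raise EquationParseError(
            f"expected exactly one arrow token, found {len(arrows)} in {text!r}"
        )
    left, right = _ARROW_RE.split(text)
    arrow_token = arrows[0]
    if arrow_token == "<=":
        left, right = right, left
        arrow = "forward"
    else:
        arrow = "reversible" if arrow_token == "<=>" else "forward"
    return ReactionEquation(
        substrates=_parse_side(left, text),
        products=_parse_side(right, text),
        arrow=arrow,
        raw=text,
    )


# ---------------------------------------------------------------------------
# Flat-file parsing
# ---------------------------------------------------------------------------

def _iter_blocks(text: str) -> Iterable[list[str]]:
    block: list[str] = []
    for line in text.splitlines():
        if line.strip() == "///":
            if any(l.strip() for l in block):
                yield block
            block = []
        else:
            block.append(line)
    if any(l.strip() for l in block):
        yield block


def _block_fields(block: list[str], index: int) -> dict[str, list[str]]:
    fields: dict[str, list[str]] = {}
    current: str | None = None
    for line in block:
        if not line.strip():
            continue
        label = line[:LABEL_WIDTH].strip()
        value = line[LABEL_WIDTH:].rstrip()
        if label:
            current = label
            fields.setdefault(label, []).append(value)
        elif current is not None:
            fields[current].append(value.strip() or line.strip())
        # indented line before any label: ignored (comment junk)
    if "ENTRY" not in fields:
        raise KeggParseError(f"record {index}: no ENTRY line")
    return fields


def _entry_id(fields: dict[str, list[str]]) -> str:
    tokens = fields["ENTRY"][0].split()
    if not tokens:
        raise KeggParseError("empty ENTRY line")
    return tokens[0]


def _first_tokens(lines: list[str], pattern: re.Pattern[str]) -> set[str]:
    out: set[str] = set()
    for line in lines:
        tokens = line.split()
        if tokens and pattern.fullmatch(tokens[0]):
            out.add(tokens[0])
    return out


def _build_ko(fields: dict[str, list[str]]) -> KeggOrtholog:
    reaction_ids: set[str] = set()
    for line in fields.get("REACTION", []):
        reaction_ids.update(REACTION_ID_RE.findall(line))
    pathway_ids = {
        normalize_pathway_id(line.split()[0])
        for line in fields.get("PATHWAY", [])
        if line.split()
    }
    return KeggOrtholog(
        ko_id=_entry_id(fields),
        name=" ".join(fields.get("NAME", [])).strip(),
        reaction_ids=reaction_ids,
        pathway_ids=pathway_ids,
    )


def _build_reaction(fields: dict[str, list[str]]) -> KeggReaction:
    rid = _entry_id(fields)
    equation = None
    if "EQUATION" in fields:
        equation = parse_equation(" ".join(fields["EQUATION"]).strip())
    else:
        logger.warning(
            "reaction %s has no EQUATION field; excluded from product inference",
            rid,
        )
    return KeggReaction(
        reaction_id=rid,
        name=" ".join(fields.get("NAME", [])).strip(),
        equation=equation,
        orthology_ids=_first_tokens(fields.get("ORTHOLOGY", []), KO_ID_RE),
    )


def _build_compound(fields: dict[str, list[str]]) -> KeggCompound:
    names = [
        n.strip()
        for n in " ".join(fields.get("NAME", [])).split(";")
        if n.strip()
    ]
    pathway_ids = {
        normalize_pathway_id(line.split()[0])
        for line in fields.get("PATHWAY", [])
        if line.split()
    }
    return KeggCompound(
        compound_id=_entry_id(fields), names=names, pathway_ids=pathway_ids
    )


def _build_pathway(fields: dict[str, list[str]]) -> KeggPathway:
    return KeggPathway(
        pathway_id=normalize_pathway_id(_entry_id(fields)),
        name=" ".join(fields.get("NAME", [])).strip(),
        compound_ids=_first_tokens(fields.get("COMPOUND", []), COMPOUND_ID_RE),
    )


_BUILDERS: dict[str, Callable[[dict[str, list[str]]], object]] = {
    "ko": _build_ko,
    "reaction": _build_reaction,
    "compound": _build_compound,
    "pathway": _build_pathway,
}


def parse_flat_file(stream, record_kind: str) -> list:
    """Parse a KEGG flat-file stream into record objects of one kind.

    ``stream`` may be a text string or a file-like object.  Records are
    delimited by ``///``; an empty stream yields an empty list; a block
    without an ENTRY line raises :class:`KeggParseError` naming the record
    index.
    """
    if record_kind not in _BUILDERS:
        raise ValueError(f"record_kind must be one of {RECORD_KINDS}")
    text = stream if isinstance(stream, str) else stream.read()
    builder = _BUILDERS[record_kind]
    records = []
    for index, block in enumerate(_iter_blocks(text)):
        records.append(builder(_block_fields(block, index)))
    return records


# ---------------------------------------------------------------------------
# Flat-file writing (round-trip support; also backs the fixture generator)
# ---------------------------------------------------------------------------

def _fmt(label: str, value: str) -> str:
    return f"{label:<{LABEL_WIDTH}}{value}"


def _write_ko(r: KeggOrtholog) -> list[str]:
    lines = [_fmt("ENTRY", f"{r.ko_id}            KO")]
    if r.name:
        lines.append(_fmt("NAME", r.name))
    for i, pid in enumerate(sorted(r.pathway_ids)):
        lines.append(_fmt("PATHWAY" if i == 0 else "", pid))
    for i, rid in enumerate(sorted(r.reaction_ids)):
        lines.append(_fmt("REACTION" if i == 0 else "", rid))
    return lines


def _write_reaction(r: KeggReaction) -> list[str]:
    lines = [_fmt("ENTRY", f"{r.reaction_id}            Reaction")]
    if r.name:
        lines.append(_fmt("NAME", r.name))
    if r.equation is not None:
        lines.append(_fmt("EQUATION", r.equation.raw))
    for i, ko in enumerate(sorted(r.orthology_ids)):
        lines.append(_fmt("ORTHOLOGY" if i == 0 else "", ko))
    return lines


def _write_compound(r: KeggCompound) -> list[str]:
    lines = [_fmt("ENTRY", f"{r.compound_id}            Compound")]
    for i, name in enumerate(r.names):
        suffix = ";" if i < len(r.names) - 1 else ""
        lines.append(_fmt("NAME" if i == 0 else "", name + suffix))
    for i, pid in enumerate(sorted(r.pathway_ids)):
        lines.append(_fmt("PATHWAY" if i == 0 else "", pid))
    return lines


def _write_pathway(r: KeggPathway) -> list[str]:
    lines = [_fmt("ENTRY", f"{r.pathway_id}          Pathway")]
    if r.name:
        lines.append(_fmt("NAME", r.name))
    for i, cid in enumerate(sorted(r.compound_ids)):
        lines.append(_fmt("COMPOUND" if i == 0 else "", cid))
    return lines


_WRITERS = {
    "ko": _write_ko,
    "reaction": _write_reaction,
    "compound": _write_compound,
    "pathway": _write_pathway,
}


def write_flat_file(records: Sequence, record_kind: str) -> str:
    """Serialize records back to the flat-file dialect (inverse of parsing)."""
    if record_kind not in _WRITERS:
        raise ValueError(f"record_kind must be one of {RECORD_KINDS}")
    writer = _WRITERS[record_kind]
    chunks = []
    for record in records:
        chunks.append("\n".join(writer(record)) + "\n///\n")
    return "".join(chunks)


# ---------------------------------------------------------------------------
# REST client
# ---------------------------------------------------------------------------

def _default_transport(url: str) -> str:
    with urllib.request.urlopen(url, timeout=60) as resp:
        return resp.read().decode()


class RestClient:
    """Throttled, caching client for the KEGG REST endpoints.

    The public KEGG API limits request volume, so at most one request is
    issued per ``throttle`` seconds and every raw response record is cached
    on disk keyed by (kind, id); warm-cache calls make zero network requests.
    ``transport`` is injectable so tests never touch the network.
    """

    def __init__(
        self,
        cache_dir: str | Path,
        base_url: str = "https://rest.kegg.jp",
        throttle: float = 1.0,
        batch_size: int = 10,
        max_retries: int = 3,
        transport: Callable[[str], str] | None = None,
        sleep: Callable[[float], None] = time.sleep,
        clock: Callable[[], float] = time.monotonic,
    ) -> None:
        self.cache_dir = Path(cache_dir)
        self.base_url = base_url.rstrip("/")
        self.throttle = throttle
        self.batch_size = batch_size
        self.max_retries = max_retries
        self._transport = transport or _default_transport
        self._sleep = sleep
        self._clock = clock
        self._last_request: float | None = None
        self.requests_made = 0
        self.missing_ids: set[str] = set()

    # -- plumbing ---------------------------------------------------------

    def _wait_for_slot(self) -> None:
        if self._last_request is not None:
            elapsed = self._clock() - self._last_request
            if elapsed < self.throttle:
                self._sleep(self.throttle - elapsed)

    def _request(self, url: str) -> str | None:
        """GET with throttling and exponential-backoff retries; None on 404."""
        for attempt in range(self.max_retries):
            self._wait_for_slot()
            self._last_request = self._clock()
            self.requests_made += 1
            try:
                return self._transport(url)
            except urllib.error.HTTPError as exc:
                if exc.code == 404:
                    return None
                last_error: Exception = exc
            except (urllib.error.URLError, OSError, TimeoutError) as exc:
                last_error = exc
            if attempt < self.max_retries - 1:
                self._sleep(self.throttle * 2**attempt)
        raise FetchError(f"giving up on {url} after {self.max_retries} attempts: {last_error}")

    def _cache_path(self, kind: str, identifier: str) -> Path:
        return self.cache_dir / kind / f"{identifier}.txt"

    # -- API --------------------------------------------------------------

    def get_records(self, ids: Sequence[str], kind: str) -> dict[str, str]:
        """Fetch raw flat-file record text for each id, via cache when warm.

        Ids the server does not return are recorded in ``missing_ids`` and
        absent from the result, never fatal.
        """
        texts: dict[str, str] = {}
        to_fetch: list[str] = []
        for identifier in dict.fromkeys(ids):  # dedupe, keep order
            path = self._cache_path(kind, identifier)
            if path.exists():
                texts[identifier] = path.read_text()
            else:
                to_fetch.append(identifier)
        for start in range(0, len(to_fetch), self.batch_size):
            batch = to_fetch[start : start + self.batch_size]
            response = self._request(f"{self.base_url}/get/{'+'.join(batch)}")
            returned: dict[str, str] = {}
            if response:
                for block in _iter_blocks(response):
                    fields = _block_fields(block, 0)
                    returned[_entry_id(fields)] = "\n".join(block) + "\n///\n"
            for identifier in batch:
                if identifier in returned:
                    text = returned[identifier]
                    path = self._cache_path(kind, identifier)
                    path.parent.mkdir(parents=True, exist_ok=True)
                    path.write_text(text)
                    texts[identifier] = text
                else:
                    logger.warning("%s %s not returned by server", kind, identifier)
                    self.missing_ids.add(identifier)
        return texts

    def get_link_table(self, target: str, source: str) -> str:
        """Fetch a /link/<target>/<source> two-column table (cached)."""
        path = self._cache_path("link", f"{target}_{source}")
        if path.exists():
            return path.read_text()
        response = self._request(f"{self.base_url}/link/{target}/{source}")
        if response is None:
            raise FetchError(f"no link table for {target}/{source}")
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(response)
        return response


def fetch_records(ids: Sequence[str], record_kind: str, client: RestClient) -> list:
    """Fetch and parse KEGG records by id; missing ids are skipped (logged)."""
    if not ids:
        return []
    texts = client.get_records(list(ids), record_kind)
    records = []
    for identifier in dict.fromkeys(ids):
        if identifier in texts:
            records.extend(parse_flat_file(texts[identifier], record_kind))
    return records


# ---------------------------------------------------------------------------
# Database assembly
# ---------------------------------------------------------------------------

@dataclass
class KeggDatabase:
    """Indexed KO/reaction/compound/pathway collection with total lookups.

    Unknown ids raise :class:`UnknownIdError` rather than returning an empty
    result; cross-reference integrity is summarized in ``dangling`` (counts
    of references that do not resolve — logged, never silently dropped).
    """

    orthologs: dict[str, KeggOrtholog] = field(default_factory=dict)
    reactions: dict[str, KeggReaction] = field(default_factory=dict)
    compounds: dict[str, KeggCompound] = field(default_factory=dict)
    pathways: dict[str, KeggPathway] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    dangling: dict[str, int] = field(default_factory=dict)

    def _lookup(self, table: dict, identifier: str, kind: str):
        try:
            return table[identifier]
        except KeyError:
            raise UnknownIdError(f"unknown {kind} id: {identifier}") from None

    def ortholog(self, ko_id: str) -> KeggOrtholog:
        return self._lookup(self.orthologs, ko_id, "KO")

    def reaction(self, reaction_id: str) -> KeggReaction:
        return self._lookup(self.reactions, reaction_id, "reaction")

    def compound(self, compound_id: str) -> KeggCompound:
        return self._lookup(self.compounds, compound_id, "compound")

    def pathway(self, pathway_id: str) -> KeggPathway:
        return self._lookup(self.pathways, pathway_id, "pathway")

    def compound_name(self, compound_id: str) -> str:
        if compound_id in self.compounds:
            return self.compounds[compound_id].display_name
        return compound_id


def _check_duplicates(records: Sequence, key: Callable, kind: str) -> None:
    seen: set[str] = set()
    dupes: set[str] = set()
    for record in records:
        identifier = key(record)
        if identifier in seen:
            dupes.add(identifier)
        seen.add(identifier)
    if dupes:
        raise KeggParseError(f"duplicate {kind} ENTRY ids: {sorted(dupes)}")


def build_database(
    ko_records: Sequence[KeggOrtholog] = (),
    reaction_records: Sequence[KeggReaction] = (),
    compound_records: Sequence[KeggCompound] = (),
    pathway_records: Sequence[KeggPathway] = (),
    provenance: dict | None = None,
) -> KeggDatabase:
    """Index parsed records into a cross-referenced database.

    Duplicate ENTRY ids within one kind are an error; dangling
    cross-references are counted per link kind and logged at DEBUG.
    """
    _check_duplicates(ko_records, lambda r: r.ko_id, "KO")
    _check_duplicates(reaction_records, lambda r: r.reaction_id, "reaction")
    _check_duplicates(compound_records, lambda r: r.compound_id, "compound")
    _check_duplicates(pathway_records, lambda r: r.pathway_id, "pathway")

    db = KeggDatabase(
        orthologs={r.ko_id: r for r in ko_records},
        reactions={r.reaction_id: r for r in reaction_records},
        compounds={r.compound_id: r for r in compound_records},
        pathways={r.pathway_id: r for r in pathway_records},
        provenance=provenance or {},
    )

    def count_dangling(name: str, refs: Iterable[tuple[str, str]], table: dict) -> None:
        n = 0
        for owner, ref in refs:
            if ref not in table:
                n += 1
                logger.debug("dangling %s: %s -> %s", name, owner, ref)
        db.dangling[name] = n

    count_dangling(
        "ko->reaction",
        ((k.ko_id, r) for k in db.orthologs.values() for r in k.reaction_ids),
        db.reactions,
    )
    count_dangling(
        "reaction->ko",
        ((r.reaction_id, k) for r in db.reactions.values() for k in r.orthology_ids),
        db.orthologs,
    )
    count_dangling(
        "equation->compound",
        (
            (r.reaction_id, c)
            for r in db.reactions.values()
            if r.equation is not None
            for c in (r.equation.substrate_ids | r.equation.product_ids)
        ),
        db.compounds,
    )
    count_dangling(
        "compound->pathway",
        ((c.compound_id, p) for c in db.compounds.values() for p in c.pathway_ids),
        db.pathways,
    )
    count_dangling(
        "pathway->compound",
        ((p.pathway_id, c) for p in db.pathways.values() for c in p.compound_ids),
        db.compounds,
    )
    total = sum(db.dangling.values())
    if total:
        logger.info("database built with %d dangling cross-references: %s", total, db.dangling)
    return db


def load_database_from_dir(directory: str | Path) -> KeggDatabase:
    """Load a database from a directory of flat files named <kind>[.txt|.keg]."""
    directory = Path(directory)
    parsed: dict[str, list] = {}
    for kind in RECORD_KINDS:
        for candidate in (kind, f"{kind}.txt", f"{kind}.keg"):
            path = directory / candidate
            if path.exists():
                parsed[kind] = parse_flat_file(path.read_text(), kind)
                break
        else:
            parsed[kind] = []
            logger.warning("no %s flat file found in %s", kind, directory)
    return build_database(
        ko_records=parsed["ko"],
        reaction_records=parsed["reaction"],
        compound_records=parsed["compound"],
        pathway_records=parsed["pathway"],
        provenance={"source": "flat-files", "directory": str(directory)},
    )


def load_database_from_api(ko_ids: Iterable[str], client: RestClient) -> KeggDatabase:
    """Build a database reachable from a KO set via the REST API.

    Fetches the KO records, follows their reaction links, then the compounds
    appearing in those reactions' equations, then the pathways those
    compounds belong to.  Everything lands in the client's cache so repeat
    runs are network-free.
    """
    kos = fetch_records(sorted(set(ko_ids)), "ko", client)
    reaction_ids = sorted({rid for ko in kos for rid in ko.reaction_ids})
    reactions = fetch_records(reaction_ids, "reaction", client)
    compound_ids = sorted(
        {
            cid
            for r in reactions
            if r.equation is not None
            for cid in (r.equation.substrate_ids | r.equation.product_ids)
        }
    )
    compounds = fetch_records(compound_ids, "compound", client)
    pathway_ids = sorted({pid for c in compounds for pid in c.pathway_ids})
    pathways = fetch_records(pathway_ids, "pathway", client)
    return build_database(
        ko_records=kos,
        reaction_records=reactions,
        compound_records=compounds,
        pathway_records=pathways,
        provenance={"source": "kegg-api", "base_url": client.base_url},
    )
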