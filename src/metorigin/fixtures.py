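"""Deterministic synthetic-KEGG generator with recorded ground truth.

Real KEGG flat files are license-encumbered and network access to the REST
API is slow and rate-limited, so every stage of the pipeline is exercised
against internally consistent synthetic KO/reaction/compound/pathway flat
files instead.  The generator records the ground-truth link structure it
built (KO→reaction, reaction→substrates/products, pathway membership, any
planted enrichment signal) so tests can compare pipeline output against an
oracle that never goes through the parser.

Structural edge cases are present by construction under the default spec:
an orphan KO with no reactions, at least one reversible and one forward
reaction, a compound that only ever appears as a substrate, a compound
produced by reactions of two different KOs, and one symbolic-coefficient
("n") equation when there are at least five reactions.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

from .kegg_db import (
    KeggCompound,
    KeggOrtholog,
    KeggPathway,
    KeggReaction,
    parse_equation,
    write_flat_file,
)


@dataclass
class SynthSpec:
    """Parameters of the synthetic KEGG universe.

    Defaults give a small but structurally complete network: enough
    reactions to include the symbolic-coefficient branch, a realistic share
    of non-metabolic (reaction-less) KOs, and a mix of reversible and
    directed reactions.  Identical specs produce byte-identical files.
    """

    n_kos: int = 30
    n_reactions: int = 40
    n_compounds: int = 60
    n_pathways: int = 8
    reversible_fraction: float = 0.5
    orphan_ko_fraction: float = 0.2
    planted_enrichment: tuple[int, int] | None = None  # (pathway index, query size)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_kos", "n_reactions", "n_compounds", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("reversible_fraction", "orphan_ko_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_reactions > 0 and self.n_compounds < 2:
            raise ValueError("reactions need at least 2 compounds")
        if self.planted_enrichment is not None:
            index, size = self.planted_enrichment
            if not 0 <= index < self.n_pathways:
                raise ValueError("planted pathway index out of range")
            if self.n_pathways < 2:
                raise ValueError("planted enrichment needs >= 2 pathways")
            if not 1 <= size <= self.n_compounds - 2:
                raise ValueError("planted query size must leave >= 2 other compounds")


@dataclass
class GroundTruth:
    """The generator's own record of every link the pipeline should recover."""

    ko_reactions: dict[str, list[str]]
    reaction_substrates: dict[str, list[str]]
    reaction_products: dict[str, list[str]]
    reaction_arrow: dict[str, str]
    pathway_compounds: dict[str, list[str]]
    substrate_only_compound: str
    shared_product: str | None
    orphan_kos: list[str]
    planted: dict | None = None
    gene_ko_links: dict[str, str] = field(default_factory=dict)

    def expected_reactions(self, ko_ids: Iterable[str]) -> set[str]:
        return {r for k in ko_ids for r in self.ko_reactions.get(k, [])}

    def expected_closure(self, ko_ids: Iterable[str]) -> set[str]:
        """Producible-compound oracle straight from the link bookkeeping."""
        return {
            cid
            for rid in self.expected_reactions(ko_ids)
            for cid in self.reaction_products[rid]
        }

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _cid(i: int) -> str:
    return f"C{i:05d}"


def _rid(i: int) -> str:
    return f"R{i:05d}"


def _kid(i: int) -> str:
    return f"K{i:05d}"


def _pid(i: int) -> str:
    return f"map{i:05d}"


def _equation_raw(
    substrates: list[tuple[str, int]], products: list[tuple[str, int]], arrow: str
) -> str:
    def side(terms):
        return " + ".join(f"{c} {cid}" if c != 1 else cid for cid, c in terms)

    return f"{side(substrates)} {arrow} {side(products)}"


def synth_kegg(spec: SynthSpec) -> tuple[dict[str, str], GroundTruth]:
    """Generate the four flat files plus their ground truth.

    Returns ``(files, truth)`` where ``files`` maps record kind to flat-file
    text in the exact dialect :mod:`metorigin.kegg_db` parses.
    """
    spec.validate()
    rng = random.Random(spec.seed)

    compounds = [_cid(i + 1) for i in range(spec.n_compounds)]
    substrate_only = compounds[0]
    planted_cids: list[str] = []
    planted_pid: str | None = None
    if spec.planted_enrichment is not None:
        index, size = spec.planted_enrichment
        planted_pid = _pid(index + 1)
        planted_cids = compounds[1 : 1 + size]

    # pathway membership; planted pathway holds exactly the planted compounds
    pathway_ids = [_pid(i + 1) for i in range(spec.n_pathways)]
    open_pathways = [p for p in pathway_ids if p != planted_pid]
    membership: dict[str, list[str]] = {p: [] for p in pathway_ids}
    for cid in compounds:
        if cid in planted_cids:
            membership[planted_pid].append(cid)
            continue
        for pid in rng.sample(open_pathways, k=min(rng.randint(1, 2), len(open_pathways))):
            membership[pid].append(cid)
    free_cids = [c for c in compounds if c not in planted_cids]
    for pid in open_pathways:
        if not membership[pid]:
            membership[pid].append(rng.choice(free_cids))

    # general reactions
    product_pool = [c for c in compounds if c != substrate_only]
    reactions: dict[str, dict] = {}
    shared_product = rng.choice(product_pool) if spec.n_reactions >= 2 else None
    for i in range(spec.n_reactions):
        rid = _rid(i + 1)
        if i == 4 and spec.n_reactions >= 5:
            # symbolic-coefficient polymerisation-style equation
            a, b = rng.sample(product_pool, 2)
            raw = f"(n+1) {a} <=> n {a} + {b}"
            eq = parse_equation(raw)
            reactions[rid] = {
                "substrates": sorted(eq.substrate_ids),
                "products": sorted(eq.product_ids),
                "arrow": "reversible",
                "raw": raw,
            }
            continue
        n_sub = rng.randint(1, 3)
        n_prod = rng.randint(1, 3)
        substrates = rng.sample(compounds, n_sub)
        if i == 0 and substrate_only not in substrates:
            substrates[0] = substrate_only
        prod_candidates = [c for c in product_pool if c not in substrates]
        products = rng.sample(prod_candidates, min(n_prod, len(prod_candidates)))
        if i in (0, 1) and shared_product is not None:
            if shared_product in substrates:
                substrates = [s for s in substrates if s != shared_product] or [
                    rng.choice([c for c in compounds if c != shared_product])
                ]
            if shared_product not in products:
                products.append(shared_product)
        if i == 0:
            arrow = "<=>"
        elif i == 1:
            arrow = "=>"
        else:
            arrow = "<=>" if rng.random() < spec.reversible_fraction else "=>"
        sub_terms = [(c, rng.choice([1, 1, 2])) for c in substrates]
        prod_terms = [(c, rng.choice([1, 1, 2])) for c in products]
        reactions[rid] = {
            "substrates": sorted(substrates),
            "products": sorted(products),
            "arrow": "reversible" if arrow == "<=>" else "forward",
            "raw": _equation_raw(sub_terms, prod_terms, arrow),
        }

    # KO -> reaction assignment; a fixed fraction of KOs are orphans
    n_orphans = round(spec.orphan_ko_fraction * spec.n_kos)
    ko_ids = [_kid(i + 1) for i in range(spec.n_kos)]
    linked_kos = ko_ids[: spec.n_kos - n_orphans]
    orphan_kos = ko_ids[spec.n_kos - n_orphans :]
    general_rids = list(reactions)
    ko_reactions: dict[str, list[str]] = {k: [] for k in ko_ids}
    for j, ko in enumerate(linked_kos):
        picks = rng.sample(general_rids, k=min(rng.randint(1, 3), len(general_rids)))
        ko_reactions[ko] = sorted(set(picks))
    # the shared product must be reachable from two different KOs
    if len(linked_kos) >= 2 and spec.n_reactions >= 2:
        if _rid(1) not in ko_reactions[linked_kos[0]]:
            ko_reactions[linked_kos[0]] = sorted(set(ko_reactions[linked_kos[0]]) | {_rid(1)})
        if _rid(2) not in ko_reactions[linked_kos[1]]:
            ko_reactions[linked_kos[1]] = sorted(set(ko_reactions[linked_kos[1]]) | {_rid(2)})

    # planted enrichment: one dedicated KO whose reactions produce exactly
    # the planted pathway's compounds
    planted: dict | None = None
    if planted_pid is not None:
        planted_ko = _kid(spec.n_kos + 1)
        ko_reactions[planted_ko] = []
        chunks = [planted_cids[i : i + 3] for i in range(0, len(planted_cids), 3)]
        for j, chunk in enumerate(chunks):
            rid = _rid(spec.n_reactions + j + 1)
            substrates = rng.sample(free_cids, k=min(2, len(free_cids)))
            reactions[rid] = {
                "substrates": sorted(substrates),
                "products": sorted(chunk),
                "arrow": "forward",
                "raw": _equation_raw(
                    [(c, 1) for c in substrates], [(c, 1) for c in chunk], "=>"
                ),
            }
            ko_reactions[planted_ko].append(rid)
        planted = {
            "pathway_id": planted_pid,
            "query_compounds": sorted(planted_cids),
            "source_kos": [planted_ko],
        }
        ko_ids.append(planted_ko)

    # inverse link + record assembly
    reaction_kos: dict[str, set[str]] = {r: set() for r in reactions}
    for ko, rids in ko_reactions.items():
        for rid in rids:
            reaction_kos[rid].add(ko)
    compound_pathways: dict[str, set[str]] = {c: set() for c in compounds}
    for pid, members in membership.items():
        for cid in members:
            compound_pathways[cid].add(pid)

    ko_records = []
    for i, ko in enumerate(ko_ids):
        product_cids = {
            c for rid in ko_reactions[ko] for c in reactions[rid]["products"]
        }
        ko_pathways = {p for c in product_cids for p in compound_pathways[c]}
        ko_records.append(
            KeggOrtholog(
                ko_id=ko,
                name=f"synthetic ortholog {i + 1}",
                reaction_ids=set(ko_reactions[ko]),
                pathway_ids=ko_pathways,
            )
        )
    reaction_records = [
        KeggReaction(
            reaction_id=rid,
            name=f"synthetic reaction {int(rid[1:])}",
            equation=parse_equation(info["raw"]),
            orthology_ids=set(reaction_kos[rid]),
        )
        for rid, info in reactions.items()
    ]
    compound_records = []
    for i, cid in enumerate(compounds):
        names = [f"synthetic compound {i + 1}"]
        if i % 5 == 0:
            names.append(f"synonym {i + 1}")
        compound_records.append(
            KeggCompound(compound_id=cid, names=names, pathway_ids=compound_pathways[cid])
        )
    pathway_records = [
        KeggPathway(
            pathway_id=pid,
            name=f"synthetic pathway {int(pid[3:])}",
            compound_ids=set(membership[pid]),
        )
        for pid in pathway_ids
    ]

    files = {
        "ko": write_flat_file(ko_records, "ko"),
        "reaction": write_flat_file(reaction_records, "reaction"),
        "compound": write_flat_file(compound_records, "compound"),
        "pathway": write_flat_file(pathway_records, "pathway"),
    }

    # a synthetic gene->KO link table (two genes map to the first KO, one to
    # each of the rest) for the organism-extraction stage
    gene_ko: dict[str, str] = {}
    gene_counter = 1
    for ko in ko_ids:
        copies = 2 if ko == ko_ids[0] else 1
        for _ in range(copies):
            gene_ko[f"syn:g{gene_counter:04d}"] = ko
            gene_counter += 1

    truth = GroundTruth(
        ko_reactions={k: sorted(v) for k, v in ko_reactions.items()},
        reaction_substrates={r: info["substrates"] for r, info in reactions.items()},
        reaction_products={r: info["products"] for r, info in reactions.items()},
        reaction_arrow={r: info["arrow"] for r, info in reactions.items()},
        pathway_compounds={p: sorted(m) for p, m in membership.items()},
        substrate_only_compound=substrate_only,
        shared_product=shared_product,
        orphan_kos=orphan_kos,
        planted=planted,
        gene_ko_links=gene_ko,
    )
    return files, truth


def write_synth(spec: SynthSpec, outdir: str | Path) -> GroundTruth:
    """Write the synthetic flat files, link table and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files, truth = synth_kegg(spec)
    for kind, text in files.items():
        (outdir / f"{kind}.txt").write_text(text)
    (outdir / "gene_ko_links.tsv").write_text(
        "".join(f"{gene}\tko:{ko}\n" for gene, ko in truth.gene_ko_links.items())
    )
    (outdir / "ground_truth.json").write_text(truth.to_json() + "\n")
    return truth


# ---------------------------------------------------------------------------
# Hand-written minimal fixture: butyrate kinase
# ---------------------------------------------------------------------------

_WORKED_KO = """\
ENTRY       K00929            KO
NAME        buk; butyrate kinase
PATHWAY     map00650
REACTION    R01688
///
"""

_WORKED_REACTION = """\
ENTRY       R01688            Reaction
NAME        butanoyl-phosphate phosphotransferase
EQUATION    C02527 <=> C00246
ORTHOLOGY   K00929
///
"""

_WORKED_COMPOUND = """\
ENTRY       C02527            Compound
NAME        Butanoyl phosphate
PATHWAY     map00650
///
ENTRY       C00246            Compound
NAME        Butanoate;
            Butyrate
PATHWAY     map00650
///
"""

_WORKED_PATHWAY = """\
ENTRY       map00650          Pathway
NAME        Butanoate metabolism
COMPOUND    C02527
            C00246
///
"""


def worked_example_fixture() -> dict[str, str]:
    """Minimal butyrate-kinase fixture: K00929 -> R01688 -> butyrate.

    Butyrate kinase (K00929) performs reaction R01688, whose equation
    ``C02527 <=> C00246`` makes butyrate (C00246) the sole product; butanoyl
    phosphate (C02527) is substrate-only and must never appear in a
    producible set under the left-to-right direction rule.
    """
    return {
        "ko": _WORKED_KO,
        "reaction": _WORKED_REACTION,
        "compound": _WORKED_COMPOUND,
        "pathway": _WORKED_PATHWAY,
    }


def write_worked_example(outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for kind, text in worked_example_fixture().items():
        (outdir / f"{kind}.txt").write_text(text)
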