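"""Report emission: KEGG Mapper color file, Venn summary, output bundle.

The mapper file uses the KEGG Mapper "Color" dialect — one object per line,
``<id> <bgcolor>[,<fgcolor>]`` — so the origin annotation can be painted
onto KEGG pathway diagrams.  The default palette follows the convention of
blue for the microbial-style first source, yellow for the host-style second
source, with detected compounds outlined in orange; the two-source blend is
green.  Venn region counts are always written as machine-readable text next
to the rendered figure, because figures are not a test surface.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Circle

from .errors import ConfigError
from .kegg_db import KeggDatabase
from .origin import OriginTable, SourceSet

logger = logging.getLogger(__name__)

DEFAULT_PALETTE = {
    "source1": "blue",
    "source2": "yellow",
    "both": "green",
    "detected": "orange",
}


def make_mapper_file(
    origin_table: OriginTable,
    sources: Sequence[SourceSet],
    palette: Mapping[str, str] | None = None,
) -> list[str]:
    """Color compounds by origin category and KOs by source membership.

    Defined for exactly two sources (the colored-map semantics are a
    two-source convention); compounds producible by neither source are
    omitted — there is no origin to color.  Detected compounds get the
    detected foreground color.  Line order is deterministic: compounds then
    KOs, each sorted by id.
    """
    if len(sources) != 2:
        raise ConfigError(
            "the mapper color file is defined for exactly two sources; "
            "use the tabular origin output for other source counts"
        )
    colors = dict(DEFAULT_PALETTE)
    colors.update(palette or {})
    label1, label2 = (s.label for s in sources)
    bg_for_category = {
        f"{label1}_only": colors["source1"],
        f"{label2}_only": colors["source2"],
        "both": colors["both"],
    }
    lines = []
    for cid in sorted(origin_table.rows):
        row = origin_table.rows[cid]
        bg = bg_for_category.get(row.category)
        if bg is None:
            continue
        if row.detected:
            lines.append(f"{cid} {bg},{colors['detected']}")
        else:
            lines.append(f"{cid} {bg}")
    ko1, ko2 = sources[0].ko_ids, sources[1].ko_ids
    for ko in sorted(ko1 | ko2):
        if ko in ko1 and ko in ko2:
            lines.append(f"{ko} {colors['both']}")
        elif ko in ko1:
            lines.append(f"{ko} {colors['source1']}")
        else:
            lines.append(f"{ko} {colors['source2']}")
    return lines


# ---------------------------------------------------------------------------
# Venn summary
# ---------------------------------------------------------------------------

@dataclass
class VennSummary:
    """Exact disjoint region counts over 2-3 labelled sets.

    ``region_counts`` keys are ``&``-joined subsets of labels (in the given
    label order); each element of the union is counted in exactly one
    region, so the counts sum to the union size.
    """

    labels: list[str]
    set_sizes: dict[str, int]
    region_counts: dict[str, int]

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def to_lines(self) -> list[str]:
        lines = ["region\tcount"]
        for key in self.region_counts:
            lines.append(f"{key}\t{self.region_counts[key]}")
        return lines


def _region_counts(named_sets: dict[str, set[str]]) -> dict[str, int]:
    labels = list(named_sets)
    counts: dict[str, int] = {}
    # enumerate nonempty label subsets in a stable order
    for mask in range(1, 2 ** len(labels)):
        included = [l for i, l in enumerate(labels) if mask >> i & 1]
        excluded = [l for l in labels if l not in included]
        region = set.intersection(*(named_sets[l] for l in included))
        for l in excluded:
            region -= named_sets[l]
        counts["&".join(included)] = len(region)
    return counts


def make_venn(
    origin_table: OriginTable | None,
    sources: Sequence[SourceSet],
    detected: set[str] | None = None,
    figure_path: str | Path | None = None,
) -> VennSummary:
    """Compute Venn region counts over producible sets and the detected set.

    With more than three sets in play only the count table is produced (no
    figure, with a warning); the counts themselves are exact for any N.
    """
    named: dict[str, set[str]] = {}
    if detected is not None:
        named["detected"] = set(detected)
    for source in sources:
        named[source.label] = set(source.producible_compounds)
    summary = VennSummary(
        labels=list(named),
        set_sizes={label: len(s) for label, s in named.items()},
        region_counts=_region_counts(named),
    )
    if figure_path is not None:
        if len(named) > 3:
            logger.warning(
                "%d sets: Venn figure only defined for 2-3 sets; "
                "emitting region counts only", len(named),
            )
        elif len(named) >= 2:
            _render_venn(summary, Path(figure_path))
    return summary


_LAYOUTS = {
    2: {
        "centers": [(-0.45, 0.0), (0.45, 0.0)],
        "radius": 1.0,
        "regions": {(0,): (-1.0, 0.0), (1,): (1.0, 0.0), (0, 1): (0.0, 0.0)},
    },
    3: {
        "centers": [(0.0, 0.55), (-0.5, -0.3), (0.5, -0.3)],
        "radius": 1.0,
        "regions": {
            (0,): (0.0, 1.1),
            (1,): (-1.0, -0.7),
            (2,): (1.0, -0.7),
            (0, 1): (-0.6, 0.35),
            (0, 2): (0.6, 0.35),
            (1, 2): (0.0, -0.75),
            (0, 1, 2): (0.0, 0.0),
        },
    },
}

_FILL_COLORS = ["tab:red", "tab:green", "tab:purple"]


def _render_venn(summary: VennSummary, path: Path) -> None:
    """Draw 2-3 overlapping circles with the exact region counts as labels."""
    layout = _LAYOUTS[len(summary.labels)]
    fig, ax = plt.subplots(figsize=(5, 5))
    for (cx, cy), label, color in zip(layout["centers"], summary.labels, _FILL_COLORS):
        ax.add_patch(
            Circle((cx, cy), layout["radius"], alpha=0.3, color=color, ec="black")
        )
        ax.annotate(
            f"{label} ({summary.set_sizes[label]})",
            (cx, cy + layout["radius"] * 1.05),
            ha="center", fontsize=9,
        )
    for indices, (tx, ty) in layout["regions"].items():
        key = "&".join(summary.labels[i] for i in indices)
        ax.annotate(str(summary.region_counts[key]), (tx, ty), ha="center", fontsize=11)
    ax.set_xlim(-2.1, 2.1)
    ax.set_ylim(-2.1, 2.3)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Output bundle
# ---------------------------------------------------------------------------

def write_bundle(
    outdir: str | Path,
    origin_table: OriginTable,
    enrichment_tables: Mapping[str, "pd.DataFrame"],
    sources: Sequence[SourceSet],
    detected: set[str] | None = None,
    db: KeggDatabase | None = None,
    run_metadata: Mapping | None = None,
    palette: Mapping[str, str] | None = None,
) -> dict:
    """Write the consolidated output bundle and return its manifest.

    Produces the origin TSV, one enrichment TSV per query set, the mapper
    color file (two-source runs only), the Venn counts + figure, and a JSON
    manifest recording inputs, provenance and the file list.  TSV content is
    deterministic so identical runs produce byte-identical tables.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc

    files: list[str] = []

    origin_path = outdir / "origin_table.tsv"
    origin_table.to_frame(db).to_csv(origin_path, sep="\t", index=False)
    files.append(origin_path.name)

    for name in sorted(enrichment_tables):
        path = outdir / f"enrichment_{name}.tsv"
        enrichment_tables[name].to_csv(path, sep="\t", index=False)
        files.append(path.name)

    if len(sources) == 2:
        mapper_path = outdir / "kegg_mapper.txt"
        mapper_path.write_text(
            "\n".join(make_mapper_file(origin_table, sources, palette)) + "\n"
        )
        files.append(mapper_path.name)

    n_sets = len(sources) + (1 if detected is not None else 0)
    venn_figure = outdir / "venn.png" if 2 <= n_sets <= 3 else None
    venn = make_venn(origin_table, sources, detected, figure_path=venn_figure)
    venn_counts_path = outdir / "venn_counts.tsv"
    venn_counts_path.write_text("\n".join(venn.to_lines()) + "\n")
    files.append(venn_counts_path.name)
    if venn_figure is not None and venn_figure.exists():
        files.append(venn_figure.name)

    manifest = {
        "files": sorted(files),
        "sources": {s.label: sorted(s.ko_ids) for s in sources},
        "n_detected": len(detected) if detected is not None else None,
        "detection_supplied": detected is not None,
        "category_counts": origin_table.category_counts(
            detected_only=detected is not None and bool(detected)
        ),
        "database_provenance": dict(db.provenance) if db else None,
        "metadata": dict(run_metadata or {}),
    }
    if detected is None:
        manifest["note"] = "no detected-compound list supplied; detection-dependent outputs omitted"
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
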