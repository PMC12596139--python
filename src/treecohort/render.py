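"""Static SVG renderings of trees, cohort grids, distance heatmaps and
2-D embeddings, plus camera-ready PDF export.

All renderers emit plain SVG text built deterministically: the same
inputs and options always produce byte-identical documents.  Layouts use
equal branch lengths per depth level; node radii scale with the square
root of the subclone fraction when sizes are present.  Gene highlighting
follows the copy-number convention red = amplification, blue = deletion,
violet = any other event type; subclones affected by a selected drug get
a square marker at the node center.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np

from .annotations import InteractionTable, highlight_category, nodes_affected_by_drug
from .cohort import matching_groups
from .errors import TreecohortError
from .treecore import DistanceMatrix, MutationTree, TreeCohort
from .treeops import edge_label, subclone_fractions

__all__ = [
    "render_tree",
    "render_cohort_grid",
    "render_heatmap",
    "render_embedding",
    "export_pdf",
    "PALETTE",
    "HIGHLIGHT_COLORS",
    "label_colors",
]

logger = logging.getLogger(__name__)

#: Fixed 12-color categorical palette, cycled deterministically.
PALETTE = (
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
)

HIGHLIGHT_COLORS = {
    "amplification": "#d62728",  # red
    "deletion": "#1f77b4",       # blue
    "other": "#9467bd",          # violet
    "none": "#d9d9d9",
}

_DEFAULT_FILL = "#d9d9d9"


def _fmt(x: float) -> str:
    return f"{x:.2f}".rstrip("0").rstrip(".")


def _esc(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def label_colors(labels: Sequence[str]) -> dict[str, str]:
    """Deterministic label→color map: pure function of the sorted label set."""
    return {lbl: PALETTE[i % len(PALETTE)] for i, lbl in enumerate(sorted(set(labels)))}


def _tree_layout(
    tree: MutationTree, h_spacing: float, level_height: float
) -> dict[str, tuple[float, float]]:
    """Leaves evenly spaced, internal nodes centered over their children;
    y = depth * level_height (equal branch lengths per level)."""
    pos: dict[str, tuple[float, float]] = {}
    next_x = [0.0]

    def place(nid: str) -> float:
        kids = tree.children(nid)
        if not kids:
            x = next_x[0]
            next_x[0] += h_spacing
        else:
            x = sum(place(c) for c in kids) / len(kids)
        pos[nid] = (x, tree.depth(nid) * level_height)
        return x

    place(tree.root_id)
    return pos


def _node_radii(tree: MutationTree, base_radius: float) -> dict[str, float]:
    if not tree.has_sizes():
        return {nid: base_radius for nid in tree.nodes}
    fracs = subclone_fractions(tree)
    mx = max(fracs.values())
    radii = {tree.root_id: base_radius * 0.6}
    for nid, f in fracs.items():
        radii[nid] = base_radius * (0.35 + 0.65 * (f / mx) ** 0.5)
    return radii


def _tree_svg_elements(
    tree: MutationTree,
    offset: tuple[float, float],
    *,
    base_radius: float = 14.0,
    h_spacing: float = 80.0,
    level_height: float = 70.0,
    fills: Mapping[str, str] | None = None,
    highlight_gene: str | None = None,
    drug_nodes: frozenset[str] = frozenset(),
    show_edge_labels: bool = True,
) -> tuple[list[str], float, float]:
    pos = _tree_layout(tree, h_spacing, level_height)
    radii = _node_radii(tree, base_radius)
    ox, oy = offset
    parts: list[str] = []
    for nid in sorted(tree.nodes):
        n = tree.nodes[nid]
        if n.parent_id is None:
            continue
        x1, y1 = pos[n.parent_id]
        x2, y2 = pos[nid]
        parts.append(
            f'<line x1="{_fmt(ox + x1)}" y1="{_fmt(oy + y1)}" '
            f'x2="{_fmt(ox + x2)}" y2="{_fmt(oy + y2)}" '
            'stroke="#555555" stroke-width="1.5"/>'
        )
        if show_edge_labels:
            mx, my = (x1 + x2) / 2, (y1 + y2) / 2
            parts.append(
                f'<text x="{_fmt(ox + mx + 6)}" y="{_fmt(oy + my)}" '
                'font-size="10" font-family="sans-serif" fill="#333333">'
                f"{_esc(edge_label(n))}</text>"
            )
    for nid in sorted(tree.nodes):
        n = tree.nodes[nid]
        x, y = pos[nid]
        if n.is_root:
            fill = "#ffffff"
        elif highlight_gene is not None:
            fill = HIGHLIGHT_COLORS[highlight_category(n.events, highlight_gene)]
        elif fills is not None and n.matching_label in fills:
            fill = fills[n.matching_label]
        else:
            fill = _DEFAULT_FILL
        r = radii[nid]
        parts.append(
            f'<circle cx="{_fmt(ox + x)}" cy="{_fmt(oy + y)}" r="{_fmt(r)}" '
            f'fill="{fill}" stroke="#333333" stroke-width="1"/>'
        )
        if nid in drug_nodes:
            s = r * 0.7
            parts.append(
                f'<rect x="{_fmt(ox + x - s / 2)}" y="{_fmt(oy + y - s / 2)}" '
                f'width="{_fmt(s)}" height="{_fmt(s)}" '
                'fill="#111111" stroke="none"/>'
            )
    width = max(x for x, _ in pos.values()) + h_spacing
    height = max(y for _, y in pos.values()) + level_height
    return parts, width, height


def _svg_document(parts: list[str], width: float, height: float) -> str:
    head = (
        '<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">'
    )
    return "\n".join([head, *parts, "</svg>"]) + "\n"


def render_tree(
    tree: MutationTree,
    *,
    highlight_gene: str | None = None,
    drug: str | None = None,
    interactions: InteractionTable | None = None,
    show_edge_labels: bool = True,
    base_radius: float = 14.0,
) -> str:
    """One mutation tree as SVG; see module docstring for conventions."""
    drug_nodes: frozenset[str] = frozenset()
    if drug is not None:
        if interactions is None:
            raise TreecohortError("drug highlighting requires an interaction table")
        drug_nodes = frozenset(nodes_affected_by_drug(tree, interactions, drug))
    parts, w, h = _tree_svg_elements(
        tree, (40.0, 40.0),
        highlight_gene=highlight_gene,
        drug_nodes=drug_nodes,
        show_edge_labels=show_edge_labels,
        base_radius=base_radius,
    )
    title = (
        f'<text x="40" y="20" font-size="12" font-family="sans-serif" '
        f'font-weight="bold">{_esc(tree.sample_id)}</text>'
    )
    return _svg_document([title, *parts], w + 80, h + 60)


def render_cohort_grid(
    cohort: TreeCohort,
    ordering: Sequence[str] | None = None,
    *,
    columns: int = 4,
    show_edge_labels: bool = False,
    cell_width: float = 320.0,
    cell_height: float = 300.0,
) -> str:
    """Trees side by side in the given order.

    Cluster membership tints each cell's background from the fixed
    palette (15% opacity); nodes in cohort-wide matching groups share a
    fill color (same label ⇒ same color across the whole document).
    """
    order = list(ordering) if ordering is not None else cohort.sample_ids()
    try:
        groups = matching_groups(cohort, "whole-cohort")
        fills = label_colors([g.label for g in groups])
    except TreecohortError:
        fills = {}
    parts: list[str] = []
    for idx, sid in enumerate(order):
        row, col = divmod(idx, columns)
        x0, y0 = col * cell_width, row * cell_height
        ci = cohort.cluster_of(sid)
        if ci is not None:
            tint = PALETTE[ci % len(PALETTE)]
            parts.append(
                f'<rect x="{_fmt(x0)}" y="{_fmt(y0)}" width="{_fmt(cell_width)}" '
                f'height="{_fmt(cell_height)}" fill="{tint}" fill-opacity="0.15"/>'
            )
        parts.append(
            f'<text x="{_fmt(x0 + 10)}" y="{_fmt(y0 + 16)}" font-size="12" '
            f'font-family="sans-serif" font-weight="bold">{_esc(sid)}</text>'
        )
        tree_parts, _, _ = _tree_svg_elements(
            cohort.trees[sid], (x0 + 30, y0 + 40),
            base_radius=10.0, h_spacing=46.0, level_height=44.0,
            fills=fills, show_edge_labels=show_edge_labels,
        )
        parts.extend(tree_parts)
    n_rows = (len(order) + columns - 1) // columns if order else 1
    return _svg_document(parts, columns * cell_width, n_rows * cell_height)


def _heat_color(v: float, vmax: float) -> str:
    """White→dark blue linear ramp."""
    t = 0.0 if vmax <= 0 else min(max(v / vmax, 0.0), 1.0)
    r = round(255 + (31 - 255) * t)
    g = round(255 + (71 - 255) * t)
    b = round(255 + (140 - 255) * t)
    return f"#{r:02x}{g:02x}{b:02x}"


def render_heatmap(
    dm: DistanceMatrix,
    clusters: Sequence[Sequence[str]] | None = None,
    *,
    cell: float = 22.0,
    margin: float = 90.0,
) -> str:
    """Distance heatmap; rows/columns follow cluster order with separators."""
    if clusters:
        order = [sid for grp in clusters for sid in sorted(grp)]
        order += sorted(set(dm.sample_ids) - set(order))
        dm = dm.reorder(order)
    n = len(dm.sample_ids)
    vmax = float(np.max(dm.values)) if n else 0.0
    parts: list[str] = []
    for i in range(n):
        for j in range(n):
            parts.append(
                f'<rect x="{_fmt(margin + j * cell)}" y="{_fmt(margin + i * cell)}" '
                f'width="{_fmt(cell)}" height="{_fmt(cell)}" '
                f'fill="{_heat_color(float(dm.values[i, j]), vmax)}" '
                'stroke="#eeeeee" stroke-width="0.5"/>'
            )
    for i, sid in enumerate(dm.sample_ids):
        y = margin + i * cell + cell / 2 + 3
        parts.append(
            f'<text x="{_fmt(margin - 6)}" y="{_fmt(y)}" font-size="9" '
            f'font-family="sans-serif" text-anchor="end">{_esc(sid)}</text>'
        )
        parts.append(
            f'<text x="{_fmt(margin + i * cell + cell / 2)}" y="{_fmt(margin - 6)}" '
            'font-size="9" font-family="sans-serif" text-anchor="start" '
            f'transform="rotate(-60 {_fmt(margin + i * cell + cell / 2)} '
            f'{_fmt(margin - 6)})">{_esc(sid)}</text>'
        )
    if clusters:
        pos = 0
        for grp in clusters[:-1]:
            pos += len(grp)
            c = margin + pos * cell
            end = margin + n * cell
            parts.append(
                f'<line x1="{_fmt(c)}" y1="{_fmt(margin)}" x2="{_fmt(c)}" '
                f'y2="{_fmt(end)}" stroke="#000000" stroke-width="1.5"/>'
            )
            parts.append(
                f'<line x1="{_fmt(margin)}" y1="{_fmt(c)}" x2="{_fmt(end)}" '
                f'y2="{_fmt(c)}" stroke="#000000" stroke-width="1.5"/>'
            )
    size = margin + n * cell + 20
    return _svg_document(parts, size, size)


def render_embedding(
    coords: Mapping[str, tuple[float, float]],
    clusters: Sequence[Sequence[str]] | None = None,
    *,
    size: float = 420.0,
    margin: float = 40.0,
    point_radius: float = 5.0,
) -> str:
    """2-D latent-space scatter of trees; points colored by cluster."""
    ids = sorted(coords)
    xs = np.array([coords[s][0] for s in ids])
    ys = np.array([coords[s][1] for s in ids])
    span = max(float(np.ptp(xs)), float(np.ptp(ys)), 1e-12)
    scale = (size - 2 * margin) / span

    def cluster_of(sid: str) -> int | None:
        if clusters is None:
            return None
        for i, grp in enumerate(clusters):
            if sid in grp:
                return i
        return None

    parts: list[str] = []
    for sid in ids:
        x = margin + (coords[sid][0] - float(xs.min())) * scale
        y = margin + (coords[sid][1] - float(ys.min())) * scale
        ci = cluster_of(sid)
        color = PALETTE[ci % len(PALETTE)] if ci is not None else "#555555"
        parts.append(
            f'<circle cx="{_fmt(x)}" cy="{_fmt(y)}" r="{_fmt(point_radius)}" '
            f'fill="{color}" stroke="#333333" stroke-width="0.8"/>'
        )
        parts.append(
            f'<text x="{_fmt(x + 7)}" y="{_fmt(y + 3)}" font-size="9" '
            f'font-family="sans-serif">{_esc(sid)}</text>'
        )
    return _svg_document(parts, size, size)


def export_pdf(svg_document: str, path: str | Path) -> Path:
    """Write an SVG document as a vector PDF.

    Uses the optional ``cairosvg`` backend when importable; otherwise
    degrades to writing the SVG next to the requested path (``.svg``
    suffix) with a warning, and returns the path actually written.
    """
    path = Path(path)
    try:
        import cairosvg  # type: ignore[import-not-found]
    except ImportError:
        out = path.with_suffix(".svg")
        logger.warning(
            "PDF backend (cairosvg) unavailable; writing SVG to %s instead", out
        )
        out.write_text(svg_document, encoding="utf-8")
        return out
    cairosvg.svg2pdf(bytestring=svg_document.encode("utf-8"), write_to=str(path))
    return path
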