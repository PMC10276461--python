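"""Report-ready figures: annotated MS2 spectra and fragment cartoons.

Spectra are drawn as stick plots of relative abundance (% of base peak);
annotations — text labels (m/z, charge, adduct) or SNFG-style glyph
cartoons — are placed above their peaks with greedy vertical staggering to
avoid overlaps.  Cartoons use the standard symbol nomenclature shapes
keyed by monosaccharide code (filled square = HexNAc class, circle = Hex
class, triangle = fucose, diamond = sialic acids, star = xylose).

Figures are deterministic for fixed input: write SVG with empty metadata
for byte-stable output.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import matplotlib

matplotlib.use("Agg", force=False)
# byte-stable SVG: fixed element-id salt, text kept as text
matplotlib.rcParams["svg.hashsalt"] = "glyscreen"
matplotlib.rcParams["svg.fonttype"] = "none"
import matplotlib.pyplot as plt
from matplotlib.lines import Line2D
from matplotlib.patches import Circle, Polygon, Rectangle

from .fragments import Fragment, FragmentSet, GlycanTopology
from .masses import MONOSACCHARIDES
from .ms2 import MS2Result, PeakAnnotation

__all__ = [
    "render_annotated_spectrum",
    "render_fragment_cartoon",
    "render_fragment_repository",
]

_SAVE_KW = dict(metadata={"Date": None, "Creator": None})


def _glyph(ax, x: float, y: float, code: str, size: float = 0.32) -> None:
    shape, color = MONOSACCHARIDES[code].snfg
    kw = dict(facecolor=color, edgecolor="black", linewidth=1.0, zorder=3)
    if shape == "circle":
        ax.add_patch(Circle((x, y), size, **kw))
    elif shape == "square":
        ax.add_patch(Rectangle((x - size, y - size), 2 * size, 2 * size, **kw))
    elif shape == "triangle":
        pts = [(x, y + size), (x - size, y - size), (x + size, y - size)]
        ax.add_patch(Polygon(pts, closed=True, **kw))
    elif shape == "diamond":
        pts = [(x, y + size), (x + size, y), (x, y - size), (x - size, y)]
        ax.add_patch(Polygon(pts, closed=True, **kw))
    elif shape == "star":
        import numpy as np

        ang = np.linspace(0.5 * np.pi, 2.5 * np.pi, 11)[:-1]
        r = [size if i % 2 == 0 else 0.45 * size for i in range(10)]
        pts = [(x + ri * np.cos(a), y + ri * np.sin(a)) for ri, a in zip(r, ang)]
        ax.add_patch(Polygon(pts, closed=True, **kw))
    else:
        ax.add_patch(Circle((x, y), size, **kw))


def _layout_tree(fragment_nodes: Sequence[int], topology: GlycanTopology):
    """Simple left-to-right tree layout restricted to a retained node set."""
    retained = set(fragment_nodes)
    pos: Dict[int, Tuple[float, float]] = {}
    next_row = [0.0]

    def place(node: int, depth: float) -> float:
        kids = [c for c in topology.children(node) if c in retained]
        if not kids:
            y = next_row[0]
            next_row[0] += 1.0
        else:
            ys = [place(c, depth + 1.0) for c in kids]
            y = sum(ys) / len(ys)
        pos[node] = (depth, y)
        return y

    heads = [n for n in sorted(retained) if not any(
        p in retained for p in topology.graph.predecessors(n)
    )]
    for head in heads:
        place(head, 0.0)
    return pos


def render_fragment_cartoon(
    fragment_or_topology: Union[Fragment, GlycanTopology],
    path: Union[str, Path],
    topology: Optional[GlycanTopology] = None,
) -> Path:
    """Draw one fragment (or a whole glycan) as connected SNFG glyphs.

    Y-ion fragments get a tag mark (a line to "T") at the reducing end.
    Pass the parent topology alongside a Fragment so node positions and
    codes can be resolved.
    """
    if isinstance(fragment_or_topology, GlycanTopology):
        topo = fragment_or_topology
        nodes = sorted(topo.codes)
        tagged = True
    else:
        frag = fragment_or_topology
        if topology is None:
            raise ValueError("rendering a Fragment requires its parent topology")
        topo = topology
        nodes = sorted(frag.retained)
        tagged = frag.contains_tag

    pos = _layout_tree(nodes, topo)
    fig, ax = plt.subplots(figsize=(2 + 0.7 * len(nodes), 2.2))
    retained = set(nodes)
    for parent, child in topo.edges:
        if parent in retained and child in retained:
            (x1, y1), (x2, y2) = pos[parent], pos[child]
            ax.add_line(Line2D([x1, x2], [y1, y2], color="black", linewidth=1.2, zorder=1))
    for node in nodes:
        x, y = pos[node]
        _glyph(ax, x, y, topo.codes[node])
    if tagged and nodes:
        root = min(nodes)
        x, y = pos[root]
        ax.add_line(Line2D([x, x - 0.8], [y, y], color="black", linewidth=1.2, zorder=1))
        ax.text(x - 1.0, y, "T", ha="center", va="center", fontsize=10, weight="bold")
    ax.set_aspect("equal")
    ax.axis("off")
    ax.autoscale_view()
    ax.margins(0.25)
    path = Path(path)
    fig.savefig(path, **(_SAVE_KW if path.suffix == ".svg" else {}))
    plt.close(fig)
    return path


def render_fragment_repository(
    fragment_set: FragmentSet,
    topology: GlycanTopology,
    directory: Union[str, Path],
    fmt: str = "svg",
) -> List[Path]:
    """One cartoon file per fragment, named by fragment id."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for frag in fragment_set:
        safe = frag.fragment_id.replace("/", "_").replace("(", "").replace(")", "")
        paths.append(
            render_fragment_cartoon(frag, directory / f"{safe}.{fmt}", topology)
        )
    return paths


def render_annotated_spectrum(
    result: MS2Result,
    path: Union[str, Path],
    mode: str = "labels",
    topology: Optional[GlycanTopology] = None,
    fragment_set: Optional[FragmentSet] = None,
) -> Path:
    """Render the annotated MS2 stick spectrum of a confirmation result.

    ``mode="labels"`` writes m/z + charge + adduct text at each annotated
    peak; ``mode="cartoons"`` draws the matched fragment's glyph chain
    instead (requires the parent topology and fragment set).  Labels are
    staggered vertically so they never overlap one another or their peak
    sticks.
    """
    if mode not in ("labels", "cartoons"):
        raise ValueError("mode must be 'labels' or 'cartoons'")
    if mode == "cartoons" and (topology is None or fragment_set is None):
        raise ValueError("cartoon mode requires the parent topology and fragment set")

    fig, ax = plt.subplots(figsize=(11, 5))
    anns = result.annotations
    for ann in anns:
        ax.vlines(ann.mz, 0, ann.relative_intensity, color="#333333", linewidth=1.2)

    frag_by_id = {f.fragment_id: f for f in fragment_set} if fragment_set else {}
    # greedy vertical staggering: successive labels near one m/z step upward
    last_x = -1e9
    tier = 0
    for ann in sorted(anns, key=lambda a: a.mz):
        if not ann.matches:
            continue
        tier = tier + 1 if ann.mz - last_x < 80 else 0
        last_x = ann.mz
        y = min(ann.relative_intensity + 4 + 9 * tier, 132)
        if mode == "labels":
            parts = []
            for m in ann.matches:
                txt = f"{m.theoretical_mz:.3f} ({m.charge}+)"
                if m.adduct:
                    txt += f" {m.adduct}"
                parts.append(txt)
            ax.annotate(
                "\n".join(parts),
                xy=(ann.mz, ann.relative_intensity),
                xytext=(ann.mz, y),
                ha="center",
                fontsize=6.5,
                arrowprops=dict(arrowstyle="-", linewidth=0.5, color="#999999"),
            )
        else:
            match = ann.matches[0]
            frag = frag_by_id.get(match.fragment_id)
            ax.annotate(
                f"{ann.mz:.2f}",
                xy=(ann.mz, ann.relative_intensity),
                xytext=(ann.mz, y),
                ha="center",
                fontsize=6.5,
                arrowprops=dict(arrowstyle="-", linewidth=0.5, color="#999999"),
            )
            if frag is not None and topology is not None:
                _inset_cartoon(ax, fig, ann.mz, y, frag, topology)

    title = result.name
    if result.rt is not None:
        title += f"  RT {result.rt:.2f} min"
    if result.precursor_mz is not None:
        title += f"  precursor m/z {result.precursor_mz:.3f}"
        if result.charge:
            title += f" ({result.charge}+)"
    ax.set_title(title)
    ax.set_xlabel("m/z")
    ax.set_ylabel("Relative abundance (%)")
    ax.set_ylim(0, 145)
    path = Path(path)
    fig.savefig(path, **(_SAVE_KW if path.suffix == ".svg" else {}))
    plt.close(fig)
    return path


def _inset_cartoon(ax, fig, x: float, y: float, frag: Fragment, topo: GlycanTopology):
    """Tiny glyph row above a cartoon-mode label (composition only)."""
    dx = 0.0
    for code, count in frag.composition:
        for _ in range(count):
            trans = ax.transData
            _glyph_data(ax, x + dx, y + 8, code)
            dx += 18.0


def _glyph_data(ax, x: float, y: float, code: str):
    shape, color = MONOSACCHARIDES[code].snfg
    marker = {"circle": "o", "square": "s", "triangle": "^", "diamond": "D", "star": "*"}[
        shape
    ]
    ax.plot(
        [x],
        [y],
        marker=marker,
        markersize=5,
        markerfacecolor=color,
        markeredgecolor="black",
        markeredgewidth=0.7,
        linestyle="none",
        zorder=4,
    )
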