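"""Static rendering of layouts (SVG, optional PNG) and layout file I/O.

Nodes are drawn as fixed-size glyphs centered on their grid cell and edges
as straight lines beneath them. Visual styles resolve per node through a
module -> class -> default precedence, so functional modules can be drawn
in identical shapes and colors. Grid coordinates are stored y-up; the
conversion to the y-down SVG document frame happens only at render time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping

import yaml

from .network import UNASSIGNED, Network, _open_text
from .optimize import Placement

SHAPES = ("square", "rectangle", "round-rectangle", "ellipse", "circle", "diamond")


@dataclass(frozen=True)
class NodeStyle:
    shape: str = "circle"
    fill: str = "#9ecae1"

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; choose from {SHAPES}")


@dataclass
class VisualStyleMap:
    """Per-module / per-class glyph styles plus global drawing parameters."""

    modules: dict[str, NodeStyle] = field(default_factory=dict)
    classes: dict[str, NodeStyle] = field(default_factory=dict)
    default: NodeStyle = field(default_factory=NodeStyle)
    edge_color: str = "#b0b0b0"
    edge_width: float = 1.0
    cell_size: float = 18.0
    label_mode: str = "none"  # none | all | listed
    labeled_nodes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label_mode not in {"none", "all", "listed"}:
            raise ValueError("label_mode must be 'none', 'all' or 'listed'")

    def resolve(self, node: str, net: Network) -> NodeStyle:
        """Style for one node: module entry, else class entry, else default."""
        if net.node_module and net.node_module.get(node) in self.modules:
            return self.modules[net.node_module[node]]
        if net.node_class and net.node_class.get(node) in self.classes:
            return self.classes[net.node_class[node]]
        return self.default

    @classmethod
    def from_dict(cls, raw: Mapping) -> "VisualStyleMap":
        def parse(entry) -> NodeStyle:
            return NodeStyle(
                shape=entry.get("shape", "circle"), fill=entry.get("fill", "#9ecae1")
            )

        kwargs: dict = {}
        if "modules" in raw:
            kwargs["modules"] = {k: parse(v) for k, v in raw["modules"].items()}
        if "classes" in raw:
            kwargs["classes"] = {k: parse(v) for k, v in raw["classes"].items()}
        if "default" in raw:
            kwargs["default"] = parse(raw["default"])
        for key in ("edge_color", "edge_width", "cell_size", "label_mode"):
            if key in raw:
                kwargs[key] = raw[key]
        if "labeled_nodes" in raw:
            kwargs["labeled_nodes"] = tuple(raw["labeled_nodes"])
        unknown = set(raw) - {
            "modules", "classes", "default", "edge_color", "edge_width",
            "cell_size", "label_mode", "labeled_nodes",
        }
        if unknown:
            raise ValueError(f"unknown style keys: {sorted(unknown)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, source: str | Path | IO[str]) -> "VisualStyleMap":
        with _open_text(source) as handle:
            raw = yaml.safe_load(handle)
        return cls.from_dict(raw or {})


def _fmt(value: float) -> str:
    return f"{value:.2f}".rstrip("0").rstrip(".")


def _glyph(shape: str, cx: float, cy: float, s: float, fill: str) -> str:
    half = s / 2
    attrs = f'fill="{fill}" stroke="#404040" stroke-width="0.5"'
    if shape == "square":
        return (
            f'<rect x="{_fmt(cx - half)}" y="{_fmt(cy - half)}" '
            f'width="{_fmt(s)}" height="{_fmt(s)}" {attrs}/>'
        )
    if shape == "rectangle":
        return (
            f'<rect x="{_fmt(cx - 0.7 * s)}" y="{_fmt(cy - 0.4 * s)}" '
            f'width="{_fmt(1.4 * s)}" height="{_fmt(0.8 * s)}" {attrs}/>'
        )
    if shape == "round-rectangle":
        return (
            f'<rect x="{_fmt(cx - 0.7 * s)}" y="{_fmt(cy - 0.4 * s)}" '
            f'width="{_fmt(1.4 * s)}" height="{_fmt(0.8 * s)}" '
            f'rx="{_fmt(0.25 * s)}" {attrs}/>'
        )
    if shape == "ellipse":
        return (
            f'<ellipse cx="{_fmt(cx)}" cy="{_fmt(cy)}" '
            f'rx="{_fmt(0.7 * s)}" ry="{_fmt(0.45 * s)}" {attrs}/>'
        )
    if shape == "circle":
        return f'<circle cx="{_fmt(cx)}" cy="{_fmt(cy)}" r="{_fmt(half)}" {attrs}/>'
    if shape == "diamond":
        pts = (
            f"{_fmt(cx)},{_fmt(cy - half)} {_fmt(cx + half)},{_fmt(cy)} "
            f"{_fmt(cx)},{_fmt(cy + half)} {_fmt(cx - half)},{_fmt(cy)}"
        )
        return f'<polygon points="{pts}" {attrs}/>'
    raise ValueError(f"unknown shape {shape!r}")


def render_svg(
    net: Network, placement: Placement, style: VisualStyleMap | None = None
) -> str:
    """Render a layout as an SVG 1.1 document string.

    Exactly one glyph per node and one straight line per edge; output is
    byte-identical for identical inputs. Raises if any network node has no
    coordinates.
    """
    style = style or VisualStyleMap()
    coords = placement.as_dict()
    missing = [v for v in net.nodes if v not in coords]
    if missing:
        raise ValueError(f"nodes without coordinates: {missing[:5]}")
    s = style.cell_size
    margin = s

    def to_doc(x: int, y: int) -> tuple[float, float]:
        # grid y points up; SVG y points down
        return margin + x * s, margin + (placement.height - 1 - y) * s

    width = 2 * margin + (placement.width - 1) * s
    height = 2 * margin + (placement.height - 1) * s
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(width)}" height="{_fmt(height)}" '
        f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">',
        '<g class="edges">',
    ]
    for a, b in sorted(net.edges):
        x1, y1 = to_doc(*coords[a])
        x2, y2 = to_doc(*coords[b])
        lines.append(
            f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" y2="{_fmt(y2)}" '
            f'stroke="{style.edge_color}" stroke-width="{_fmt(style.edge_width)}"/>'
        )
    lines.append("</g>")
    lines.append('<g class="nodes">')
    glyph_size = 0.55 * s
    for v in net.nodes:
        cx, cy = to_doc(*coords[v])
        ns = style.resolve(v, net)
        lines.append(_glyph(ns.shape, cx, cy, glyph_size, ns.fill))
    lines.append("</g>")
    labeled: Iterable[str] = ()
    if style.label_mode == "all":
        labeled = net.nodes
    elif style.label_mode == "listed":
        labeled = [v for v in net.nodes if v in set(style.labeled_nodes)]
    label_lines = []
    for v in labeled:
        cx, cy = to_doc(*coords[v])
        label_lines.append(
            f'<text x="{_fmt(cx)}" y="{_fmt(cy - 0.45 * s)}" '
            f'font-size="{_fmt(0.45 * s)}" text-anchor="middle" '
            f'font-family="sans-serif">{v}</text>'
        )
    if label_lines:
        lines.append('<g class="labels">')
        lines.extend(label_lines)
        lines.append("</g>")
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


def render_png(
    net: Network,
    placement: Placement,
    path: str | Path,
    style: VisualStyleMap | None = None,
    dpi: int = 150,
) -> None:
    """Rasterize a layout to PNG via matplotlib (same geometry as the SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    style = style or VisualStyleMap()
    coords = placement.as_dict()
    fig, ax = plt.subplots(
        figsize=(placement.width * 0.2 + 1, placement.height * 0.2 + 1)
    )
    for a, b in sorted(net.edges):
        (x1, y1), (x2, y2) = coords[a], coords[b]
        ax.plot([x1, x2], [y1, y2], color=style.edge_color,
                linewidth=style.edge_width, zorder=1)
    for v in net.nodes:
        x, y = coords[v]
        ns = style.resolve(v, net)
        marker = {"square": "s", "rectangle": "s", "round-rectangle": "s",
                  "ellipse": "o", "circle": "o", "diamond": "D"}[ns.shape]
        ax.scatter([x], [y], marker=marker, c=ns.fill, edgecolors="#404040",
                   s=40, zorder=2)
    ax.set_xlim(-1, placement.width)
    ax.set_ylim(-1, placement.height)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)


def write_layout(placement: Placement, sink: str | Path | IO[str]) -> None:
    """Write a layout as TSV ``node<TAB>x<TAB>y`` with a grid-size header."""
    with _open_text(sink, "w") as handle:
        handle.write(f"#grid\t{placement.width}\t{placement.height}\n")
        for v, (x, y) in zip(placement.nodes, placement.coords):
            handle.write(f"{v}\t{int(x)}\t{int(y)}\n")


def read_layout(source: str | Path | IO[str]) -> Placement:
    """Read a layout TSV written by :func:`write_layout`.

    Malformed lines raise with their line number; duplicate cells raise;
    an empty file raises ``"no nodes"``. Without a grid header the grid is
    the tight bounding box of the coordinates.
    """
    nodes: list[str] = []
    coords: list[tuple[int, int]] = []
    width = height = None
    with _open_text(source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#grid"):
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ValueError(f"line {lineno}: malformed grid header")
                width, height = int(fields[1]), int(fields[2])
                continue
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 3:
                raise ValueError(f"line {lineno}: expected 'node<TAB>x<TAB>y'")
            try:
                x, y = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"line {lineno}: coordinates must be integers") from None
            if (x, y) in coords:
                raise ValueError(f"line {lineno}: cell ({x}, {y}) already occupied")
            if fields[0] in nodes:
                raise ValueError(f"line {lineno}: duplicate node {fields[0]!r}")
            nodes.append(fields[0])
            coords.append((x, y))
    if not nodes:
        raise ValueError("no nodes")
    import numpy as np

    arr = np.array(coords, dtype=np.int64)
    if width is None or height is None:
        width = int(arr[:, 0].max()) + 1
        height = int(arr[:, 1].max()) + 1
    return Placement(nodes, arr, width, height)
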