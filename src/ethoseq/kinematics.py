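"""Kinematic diagrams: significant-transition graphs exported as DOT.

Node symbol size encodes each behavior's relative frequency (five
classes: <1%, 1-5%, 5-10%, 10-15%, >15%); node shape encodes category
(square for aggressive, circle for interactive/non-aggressive, triangle
for non-interactive); edges are the significant transitions, colored by
Freeman-Tukey deviate band (1-5 black, 5-10 orange, >10 red).
"""

from __future__ import annotations

from dataclasses import dataclass

from .ethogram import Category, Ethogram
from .quasi_independence import QuasiIndependenceResults

#: node-frequency class boundaries (%), half-open with the boundary in the upper class
_SIZE_BOUNDS = (1.0, 5.0, 10.0, 15.0)

#: deviate bands; the lower edge of "low" is the significance criterion
_BAND_BOUNDS = (5.0, 10.0)
BANDS = ("low", "intermediate", "high")
_BAND_COLOR = {"low": "black", "intermediate": "orange", "high": "red"}
_BAND_PENWIDTH = {"low": 1.0, "intermediate": 2.5, "high": 4.0}

_CATEGORY_SHAPE = {
    Category.HIGH_INTENSITY_AGGRESSION: "square",
    Category.LOW_INTENSITY_AGGRESSION: "square",
    Category.INTERACTIVE_NONAGGRESSIVE: "circle",
    Category.NON_INTERACTIVE: "triangle",
}
# closed (filled) squares mark high-intensity aggression, open squares low-intensity
_CATEGORY_FILL = {Category.HIGH_INTENSITY_AGGRESSION: "gray25"}

_SIZE_INCHES = {1: 0.3, 2: 0.5, 3: 0.7, 4: 0.9, 5: 1.1}


def node_size_class(freq_pct: float) -> int:
    """Map a relative frequency (%) to symbol size class 1..5."""
    if freq_pct < 0:
        raise ValueError(f"negative frequency: {freq_pct}")
    for cls, bound in enumerate(_SIZE_BOUNDS, start=1):
        if freq_pct < bound:
            return cls
    return 5


def edge_band(deviate: float, criterion: float = 1.0) -> str:
    """Band of a significant deviate: low, intermediate, or high."""
    if deviate <= criterion:
        raise ValueError(
            f"deviate {deviate} does not exceed the significance criterion {criterion}; "
            "non-significant transitions are not drawn"
        )
    if deviate < _BAND_BOUNDS[0]:
        return "low"
    if deviate < _BAND_BOUNDS[1]:
        return "intermediate"
    return "high"


@dataclass
class KinematicDiagram:
    nodes: dict[str, dict]
    edges: dict[tuple[str, str], dict]


def build_diagram(fit: QuasiIndependenceResults, ethogram: Ethogram) -> KinematicDiagram:
    """Node/edge description of the kinematic diagram for one fit.

    Node frequency is the first-position (row-margin) count as a
    percentage of all transitions.
    """
    tc = fit.counts
    total = tc.total
    nodes = {}
    for code in tc.labels:
        freq_pct = 100.0 * tc.row_sums[tc.index(code)] / total if total else 0.0
        category = ethogram.category_of(code)
        nodes[code] = {
            "frequency_pct": freq_pct,
            "size_class": node_size_class(freq_pct),
            "shape": _CATEGORY_SHAPE[category],
            "category": category.value,
        }
    edges = {}
    for a, b in sorted(fit.significant_transitions()):
        z = fit.deviate(a, b)
        edges[(a, b)] = {"deviate": z, "band": edge_band(z, fit.criterion)}
    return KinematicDiagram(nodes=nodes, edges=edges)


def export_dot(fit: QuasiIndependenceResults, ethogram: Ethogram, name: str = "kinematic") -> str:
    """Deterministic DOT text for the kinematic diagram of ``fit``."""
    diagram = build_diagram(fit, ethogram)
    lines = [f"digraph {name} {{", "  layout=neato;", "  overlap=false;"]
    for code in fit.counts.labels:  # ethogram/matrix order, stable
        node = diagram.nodes[code]
        size = _SIZE_INCHES[node["size_class"]]
        category = Category(node["category"])
        attrs = [
            f'label="{code}"',
            f"shape={node['shape']}",
            f"width={size:.1f}",
            f"height={size:.1f}",
            "fixedsize=true",
        ]
        if category in _CATEGORY_FILL:
            attrs.append("style=filled")
            attrs.append(f"fillcolor={_CATEGORY_FILL[category]}")
        lines.append(f'  "{code}" [{", ".join(attrs)}];')
    for (a, b), edge in sorted(diagram.edges.items()):
        band = edge["band"]
        lines.append(
            f'  "{a}" -> "{b}" [color={_BAND_COLOR[band]}, '
            f"penwidth={_BAND_PENWIDTH[band]:.1f}];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
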