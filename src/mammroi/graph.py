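"""Node-level dataflow-graph simulator for the two streaming kernels.

The streaming kernels of :mod:`mammroi.stream` are re-expressed here as
explicit graphs of typed operator nodes — the form in which they would be
laid out on a streaming accelerator — and evaluated one tick per pixel.
This gives a second, structurally faithful implementation used to
cross-validate the direct kernels bit-exactly.

Node inventory (32-bit unsigned data paths, 1-bit control):

``stream_in`` / ``stream_out``
    pixel-rate ports.
``scalar_in``
    run-constant parameters ("black", "threshold").
``const``
    build-time constant.
``counter``
    wrapping counter; counts 0 .. max-1 with the given step, advancing each
    tick (or only on ticks where its optional ``enable`` input is 1).
``cmp_lt``/``cmp_gt``/``cmp_ge``/``cmp_le``/``cmp_eq``
    32-bit comparators with 1-bit output.
``and_gate``
    1-bit AND.
``div``
    unsigned 32-bit integer division (floor).
``mux2``
    2-to-1 multiplexer, 32-bit data, 1-bit select (output = ``b`` when the
    select is 1, else ``a``).
``first_run_detect``
    stateful: 1 while the current pixel lies in the row's leftmost maximal
    run of values >= "black"; resets when the column input is 0.
``line_buffer``
    one-row delay: outputs the value written ``cols`` ticks ago (0 for the
    first row).

State crosses ticks only through ``counter``, ``line_buffer`` and
``first_run_detect``; within a tick the graph is acyclic and nodes fire in
topological order, so evaluation is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from graphlib import TopologicalSorter

import numpy as np

from .params import SegParams, resolve_threshold
from .raster_io import as_gray_image

__all__ = [
    "Node",
    "KernelGraph",
    "build_background_graph",
    "build_pectoral_graph",
    "evaluate_graph",
    "graph_to_text",
    "run_graph_on_image",
]

_MASK32 = 2**32 - 1

NODE_KINDS = frozenset(
    {
        "stream_in",
        "scalar_in",
        "const",
        "counter",
        "cmp_lt",
        "cmp_gt",
        "cmp_ge",
        "cmp_le",
        "cmp_eq",
        "and_gate",
        "div",
        "mux2",
        "first_run_detect",
        "line_buffer",
        "stream_out",
    }
)

#: node kinds whose output may be read before their same-tick inputs settle
_STATEFUL = frozenset({"counter", "line_buffer", "first_run_detect"})

#: kinds whose outputs are 1-bit control signals
_ONE_BIT = frozenset({"cmp_lt", "cmp_gt", "cmp_ge", "cmp_le", "cmp_eq", "and_gate", "first_run_detect"})

_INPUT_PORTS = {
    "stream_in": (),
    "scalar_in": (),
    "const": (),
    "counter": (),  # optional "enable" port
    "cmp_lt": ("a", "b"),
    "cmp_gt": ("a", "b"),
    "cmp_ge": ("a", "b"),
    "cmp_le": ("a", "b"),
    "cmp_eq": ("a", "b"),
    "and_gate": ("a", "b"),
    "div": ("a", "b"),
    "mux2": ("a", "b", "sel"),
    "first_run_detect": ("pixel", "black", "col"),
    "line_buffer": ("value",),
    "stream_out": ("value",),
}


@dataclass(frozen=True)
class Node:
    id: int
    kind: str
    name: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")


@dataclass
class KernelGraph:
    """Typed-node graph: nodes plus (producer_id -> (consumer_id, port)) edges."""

    nodes: dict[int, Node] = field(default_factory=dict)
    edges: list[tuple[int, int, str]] = field(default_factory=list)

    def add(self, node_id: int, kind: str, name: str = "", **params) -> int:
        if node_id in self.nodes:
            raise ValueError(f"duplicate node id {node_id}")
        self.nodes[node_id] = Node(node_id, kind, name or kind, dict(params))
        return node_id

    def connect(self, producer: int, consumer: int, port: str) -> None:
        for p, c, pt in self.edges:
            if c == consumer and pt == port:
                raise ValueError(f"port {port!r} of node {consumer} already driven by {p}")
        self.edges.append((producer, consumer, port))

    def nodes_of_kind(self, kind: str) -> list[Node]:
        return [n for n in self.nodes.values() if n.kind == kind]

    def producer_of(self, consumer: int, port: str) -> int:
        for p, c, pt in self.edges:
            if c == consumer and pt == port:
                return p
        raise KeyError(f"port {port!r} of node {consumer} is unbound")

    def same_tick_order(self) -> list[int]:
        """Topological order of the combinational (same-tick) subgraph.

        Stateful nodes read last-tick state, so edges INTO them do not
        constrain same-tick ordering; raises if a combinational cycle exists.
        """
        ts = TopologicalSorter({nid: set() for nid in self.nodes})
        for p, c, _ in self.edges:
            if self.nodes[c].kind not in _STATEFUL:
                ts.add(c, p)
        return list(ts.static_order())

    def stream_inputs(self) -> list[Node]:
        return self.nodes_of_kind("stream_in")

    def scalar_inputs(self) -> list[Node]:
        return self.nodes_of_kind("scalar_in")

    def stream_outputs(self) -> list[Node]:
        return self.nodes_of_kind("stream_out")


# ---------------------------------------------------------------------------
# graph builders

def _add_raster_counters(g: KernelGraph, rows: int, cols: int, base: int) -> tuple[int, int]:
    """Column counter (wraps at cols) driving the row counter (0..rows-1, step 1).

    Returns (col_node_id, row_node_id).  The row counter advances when the
    column counter sits on its last value, i.e. once per completed row.
    """
    col = g.add(base, "counter", "col_counter", start=0, max=cols, step=1)
    last = g.add(base + 1, "const", "cols_minus_1", value=cols - 1)
    wrap = g.add(base + 2, "cmp_eq", "row_done")
    g.connect(col, wrap, "a")
    g.connect(last, wrap, "b")
    row = g.add(base + 3, "counter", "row_counter", start=0, max=rows, step=1)
    g.connect(wrap, row, "enable")
    return col, row


def build_background_graph(rows: int, cols: int) -> KernelGraph:
    """Kernel K_A as a dataflow graph (muxes 22 and 37).

    Mux 22 zeroes a first-row pixel outside the first non-black run; mux 37
    zeroes a later-row pixel that is outside its row's first run while the
    above (line-buffer) pixel is black.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    g = KernelGraph()
    pixel = g.add(1, "stream_in", "pixel")
    black = g.add(2, "scalar_in", "black")
    zero = g.add(3, "const", "zero", value=0)
    col, row = _add_raster_counters(g, rows, cols, base=4)

    frd = g.add(10, "first_run_detect", "first_run")
    g.connect(pixel, frd, "pixel")
    g.connect(black, frd, "black")
    g.connect(col, frd, "col")
    not_in_run = g.add(11, "cmp_eq", "not_in_first_run")
    g.connect(frd, not_in_run, "a")
    g.connect(zero, not_in_run, "b")

    is_row0 = g.add(12, "cmp_eq", "is_first_row")
    g.connect(row, is_row0, "a")
    g.connect(zero, is_row0, "b")
    not_row0 = g.add(13, "cmp_eq", "not_first_row")
    g.connect(is_row0, not_row0, "a")
    g.connect(zero, not_row0, "b")

    lbuf = g.add(14, "line_buffer", "above_pixel", cols=cols)
    above_black = g.add(15, "cmp_lt", "above_is_black")
    g.connect(lbuf, above_black, "a")
    g.connect(black, above_black, "b")

    sel22 = g.add(16, "and_gate", "row0_background")
    g.connect(is_row0, sel22, "a")
    g.connect(not_in_run, sel22, "b")
    mux22 = g.add(22, "mux2", "mux_22")
    g.connect(pixel, mux22, "a")
    g.connect(zero, mux22, "b")
    g.connect(sel22, mux22, "sel")

    and2 = g.add(17, "and_gate", "later_row_outside_run")
    g.connect(not_row0, and2, "a")
    g.connect(not_in_run, and2, "b")
    sel37 = g.add(18, "and_gate", "background_propagate")
    g.connect(and2, sel37, "a")
    g.connect(above_black, sel37, "b")
    mux37 = g.add(37, "mux2", "mux_37")
    g.connect(mux22, mux37, "a")
    g.connect(zero, mux37, "b")
    g.connect(sel37, mux37, "sel")

    out = g.add(40, "stream_out", "roi")
    g.connect(mux37, out, "value")
    g.connect(mux37, lbuf, "value")  # line buffer taps the kernel OUTPUT
    return g


def build_pectoral_graph(rows: int, cols: int, pectoral_fraction=None) -> KernelGraph:
    """Kernel K_B as a dataflow graph (muxes 19 and 35).

    The boundary row count is computed on-graph by an unsigned division
    (rows/10 by default).  Mux 19 zeroes a pixel >= T inside the boundary
    band; mux 35 zeroes a pixel >= T below it when the above pixel is black.
    The line buffer starts at 0 (< B), which makes a boundary of 0 and of 1
    behave identically on the first row, so no explicit max(1, .) is wired.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    from fractions import Fraction

    frac = Fraction(1, 10) if pectoral_fraction is None else Fraction(pectoral_fraction).limit_denominator(1_000_000)
    g = KernelGraph()
    pixel = g.add(1, "stream_in", "pixel")
    threshold = g.add(2, "scalar_in", "threshold")
    black = g.add(3, "scalar_in", "black")
    zero = g.add(4, "const", "zero", value=0)
    col, row = _add_raster_counters(g, rows, cols, base=5)

    numer = g.add(10, "const", "rows_scaled", value=rows * frac.numerator)
    denom = g.add(11, "const", "tenth_divisor", value=frac.denominator)
    div = g.add(12, "div", "boundary_row")
    g.connect(numer, div, "a")
    g.connect(denom, div, "b")

    in_band = g.add(13, "cmp_lt", "in_first_tenth")
    g.connect(row, in_band, "a")
    g.connect(div, in_band, "b")
    below_band = g.add(14, "cmp_ge", "below_first_tenth")
    g.connect(row, below_band, "a")
    g.connect(div, below_band, "b")
    hot = g.add(15, "cmp_ge", "at_least_threshold")
    g.connect(pixel, hot, "a")
    g.connect(threshold, hot, "b")

    lbuf = g.add(16, "line_buffer", "above_pixel", cols=cols)
    above_black = g.add(17, "cmp_lt", "above_is_black")
    g.connect(lbuf, above_black, "a")
    g.connect(black, above_black, "b")

    sel19 = g.add(18, "and_gate", "pectoral_band")
    g.connect(in_band, sel19, "a")
    g.connect(hot, sel19, "b")
    mux19 = g.add(19, "mux2", "mux_19")
    g.connect(pixel, mux19, "a")
    g.connect(zero, mux19, "b")
    g.connect(sel19, mux19, "sel")

    and2 = g.add(20, "and_gate", "hot_below_band")
    g.connect(below_band, and2, "a")
    g.connect(hot, and2, "b")
    sel35 = g.add(21, "and_gate", "pectoral_propagate")
    g.connect(and2, sel35, "a")
    g.connect(above_black, sel35, "b")
    mux35 = g.add(35, "mux2", "mux_35")
    g.connect(mux19, mux35, "a")
    g.connect(zero, mux35, "b")
    g.connect(sel35, mux35, "sel")

    out = g.add(40, "stream_out", "roi")
    g.connect(mux35, out, "value")
    g.connect(mux35, lbuf, "value")
    return g


# ---------------------------------------------------------------------------
# evaluation

class _CounterState:
    def __init__(self, node: Node):
        self.value = int(node.params.get("start", 0))
        self.max = int(node.params["max"])
        self.step = int(node.params.get("step", 1))


class _LineBufferState:
    def __init__(self, node: Node):
        self.buf = [0] * int(node.params["cols"])
        self.pos = 0


class _FirstRunState:
    def __init__(self):
        self.seen = False
        self.ended = False


def evaluate_graph(graph: KernelGraph, streams: dict, scalars: dict) -> dict:
    """Run *graph* one tick per stream element; returns output streams by name.

    ``streams`` maps stream_in names to equal-length sequences; ``scalars``
    maps scalar_in names to values.  Unbound ports, unknown bindings and
    mismatched stream lengths raise ``ValueError``.
    """
    order = graph.same_tick_order()
    producers: dict[tuple[int, str], int] = {}
    for p, c, pt in graph.edges:
        producers[(c, pt)] = p

    stream_nodes = graph.stream_inputs()
    lengths = set()
    stream_data = {}
    for node in stream_nodes:
        if node.name not in streams:
            raise ValueError(f"stream input port {node.name!r} is unbound")
        seq = np.asarray(streams[node.name]).ravel()
        stream_data[node.id] = seq
        lengths.add(len(seq))
    if len(lengths) > 1:
        raise ValueError(f"stream length mismatch: {sorted(lengths)}")
    n_ticks = lengths.pop() if lengths else 0

    scalar_vals = {}
    for node in graph.scalar_inputs():
        if node.name not in scalars:
            raise ValueError(f"scalar input port {node.name!r} is unbound")
        scalar_vals[node.id] = int(scalars[node.name]) & _MASK32

    state: dict[int, object] = {}
    for node in graph.nodes.values():
        if node.kind == "counter":
            state[node.id] = _CounterState(node)
        elif node.kind == "line_buffer":
            state[node.id] = _LineBufferState(node)
        elif node.kind == "first_run_detect":
            state[node.id] = _FirstRunState()

    def inp(values, nid, port):
        key = (nid, port)
        if key not in producers:
            raise ValueError(f"port {port!r} of node {nid} is unbound")
        return values[producers[key]]

    outputs = {node.name: [] for node in graph.stream_outputs()}
    for t in range(n_ticks):
        values: dict[int, int] = {}
        pending = []  # (node, same-tick input values) for post-tick updates
        for nid in order:
            node = graph.nodes[nid]
            k = node.kind
            if k == "stream_in":
                values[nid] = int(stream_data[nid][t]) & _MASK32
            elif k == "scalar_in":
                values[nid] = scalar_vals[nid]
            elif k == "const":
                values[nid] = int(node.params["value"]) & _MASK32
            elif k == "counter":
                values[nid] = state[nid].value
            elif k == "line_buffer":
                st = state[nid]
                values[nid] = st.buf[st.pos]
            elif k == "first_run_detect":
                st = state[nid]
                pix = inp(values, nid, "pixel")
                blk = inp(values, nid, "black")
                c = inp(values, nid, "col")
                if c == 0:
                    st.seen = False
                    st.ended = False
                nonblack = pix >= blk
                if nonblack and not st.ended:
                    st.seen = True
                    fire = 1
                else:
                    if not nonblack and st.seen:
                        st.ended = True
                    fire = 0
                values[nid] = fire
            elif k in ("cmp_lt", "cmp_gt", "cmp_ge", "cmp_le", "cmp_eq"):
                a, b = inp(values, nid, "a"), inp(values, nid, "b")
                op = {
                    "cmp_lt": a < b,
                    "cmp_gt": a > b,
                    "cmp_ge": a >= b,
                    "cmp_le": a <= b,
                    "cmp_eq": a == b,
                }[k]
                values[nid] = int(op)
            elif k == "and_gate":
                values[nid] = inp(values, nid, "a") & inp(values, nid, "b") & 1
            elif k == "div":
                b = inp(values, nid, "b")
                if b == 0:
                    raise ZeroDivisionError(f"div node {nid} divided by zero")
                values[nid] = (inp(values, nid, "a") // b) & _MASK32
            elif k == "mux2":
                sel = inp(values, nid, "sel")
                values[nid] = inp(values, nid, "b") if sel else inp(values, nid, "a")
            elif k == "stream_out":
                v = inp(values, nid, "value")
                values[nid] = v
                outputs[node.name].append(v)
            if k in ("counter", "line_buffer"):
                pending.append(node)
        for node in pending:  # state updates commit after the tick
            st = state[node.id]
            if node.kind == "counter":
                key = (node.id, "enable")
                enabled = values[producers[key]] if key in producers else 1
                if enabled:
                    st.value = (st.value + st.step) % st.max
            else:  # line_buffer: store this tick's input, advance ring
                st.buf[st.pos] = inp(values, node.id, "value")
                st.pos = (st.pos + 1) % len(st.buf)
    return {name: np.asarray(vals, dtype=np.uint64) for name, vals in outputs.items()}


def run_graph_on_image(kind: str, image, params: SegParams | None = None) -> np.ndarray:
    """Evaluate the named kernel graph ("background" or "pectoral") on an image."""
    params = params or SegParams()
    image = as_gray_image(image)
    rows, cols = image.shape
    if kind == "background":
        g = build_background_graph(rows, cols)
        scalars = {"black": params.black}
    elif kind == "pectoral":
        g = build_pectoral_graph(rows, cols, params.fraction)
        scalars = {"black": params.black, "threshold": resolve_threshold(params, image)}
    else:
        raise ValueError(f"kind must be 'background' or 'pectoral', got {kind!r}")
    out = evaluate_graph(g, {"pixel": image.ravel()}, scalars)["roi"]
    return out.reshape(rows, cols).astype(np.uint32)


def graph_to_text(graph: KernelGraph) -> str:
    """Serialize a graph as a plain node-list + edge-list text block."""
    lines = ["# nodes: id kind name params"]
    for nid in sorted(graph.nodes):
        n = graph.nodes[nid]
        ps = " ".join(f"{k}={v}" for k, v in sorted(n.params.items()))
        lines.append(f"node {n.id} {n.kind} {n.name}" + (f" {ps}" if ps else ""))
    lines.append("# edges: producer -> consumer.port")
    for p, c, pt in graph.edges:
        lines.append(f"edge {p} -> {c}.{pt}")
    return "\n".join(lines) + "\n"
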