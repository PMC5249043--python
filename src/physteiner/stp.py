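"""SteinLib STP reading/writing for prize-collecting instances.

The on-disk dialect follows SteinLib conventions: a ``SECTION Graph`` with
``Nodes``/``Edges`` counts and ``E i j cost`` lines (1-based indices), and a
``SECTION Terminals`` with a ``Terminals`` count, ``T i`` lines for the
terminal set and ``TP i prize`` lines carrying the vertex prizes. A sidecar
TSV (``<path>.map.tsv``) maps the 1-based indices back to drug ids; without
it, vertices are named by their index.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx

from physteiner.dsn import DrugNetwork
from physteiner.errors import FormatError

__all__ = ["write_stp", "read_stp", "sidecar_path"]

_HEADER = "33D32945 STP File, STP Format Version 1.0"


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".map.tsv")


def write_stp(network: DrugNetwork, path: str | Path, name: str = "DSN") -> None:
    """Write a network (costs, prizes, terminals) as an STP file plus id sidecar."""
    path = Path(path)
    ids = network.vertex_ids
    index = {v: k + 1 for k, v in enumerate(ids)}
    lines = [
        _HEADER,
        "",
        "SECTION Comment",
        f'Name "{name}"',
        'Creator "physteiner"',
        'Problem "Prize-Collecting Steiner Problem in Graphs"',
        "END",
        "",
        "SECTION Graph",
        f"Nodes {len(ids)}",
        f"Edges {network.n_edges}",
    ]
    for (u, v), c in sorted(network.costs.items()):
        lines.append(f"E {index[u]} {index[v]} {c!r}")
    lines += ["END", "", "SECTION Terminals", f"Terminals {len(network.terminals)}"]
    for t in sorted(network.terminals):
        lines.append(f"T {index[t]}")
    for v in ids:
        lines.append(f"TP {index[v]} {network.prize(v)!r}")
    lines += ["END", "", "EOF", ""]
    path.write_text("\n".join(lines))
    with sidecar_path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["index", "drug_id"])
        for v in ids:
            writer.writerow([index[v], v])


def read_stp(path: str | Path) -> DrugNetwork:
    """Read an STP file written by :func:`write_stp` (sidecar optional).

    Raises
    ------
    FormatError
        On malformed lines (with line number), terminal-count mismatches, or
        non-positive edge costs.
    """
    path = Path(path)
    id_of: dict[int, str] = {}
    side = sidecar_path(path)
    if side.exists():
        with side.open(newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            next(reader, None)
            for record in reader:
                if len(record) == 2:
                    id_of[int(record[0])] = record[1]

    g = nx.Graph()
    terminals: set[int] = set()
    prizes: dict[int, float] = {}
    edges: list[tuple[int, int, float]] = []
    n_nodes = n_edges = n_terminals = None
    section = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line == _HEADER or line == "EOF":
            continue
        upper = line.upper()
        if upper.startswith("SECTION"):
            section = upper.split()[1] if len(upper.split()) > 1 else None
            continue
        if upper == "END":
            section = None
            continue
        try:
            if section == "GRAPH":
                tok = line.split()
                if tok[0] == "Nodes":
                    n_nodes = int(tok[1])
                elif tok[0] == "Edges":
                    n_edges = int(tok[1])
                elif tok[0] == "E":
                    i, j, c = int(tok[1]), int(tok[2]), float(tok[3])
                    if c <= 0:
                        raise FormatError(
                            f"{path}:{lineno}: non-positive edge cost {c}"
                        )
                    edges.append((i, j, c))
            elif section == "TERMINALS":
                tok = line.split()
                if tok[0] == "Terminals":
                    n_terminals = int(tok[1])
                elif tok[0] == "T":
                    terminals.add(int(tok[1]))
                elif tok[0] == "TP":
                    prizes[int(tok[1])] = float(tok[2])
        except FormatError:
            raise
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: malformed line {line!r}") from exc

    if n_nodes is None or n_edges is None:
        raise FormatError(f"{path}: missing Nodes/Edges declaration")
    if n_edges != len(edges):
        raise FormatError(f"{path}: declared {n_edges} edges, found {len(edges)}")
    if n_terminals is not None and n_terminals != len(terminals):
        raise FormatError(
            f"{path}: declared {n_terminals} terminals, found {len(terminals)}"
        )

    def name(k: int) -> str:
        return id_of.get(k, str(k))

    for k in range(1, n_nodes + 1):
        g.add_node(name(k), prize=float(prizes.get(k, 0.0)))
    for i, j, c in edges:
        g.add_edge(name(i), name(j), cost=c)
    return DrugNetwork(graph=g, terminals=frozenset(name(t) for t in terminals))
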