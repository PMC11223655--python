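"""Edge-list readers/writers and flat run configuration.

Edge lists are plain delimited text: one edge per line, "i j" or "i j t",
whitespace- or comma-separated, with '#' comment lines skipped.  Arbitrary
string node labels are mapped to contiguous integer IDs in order of first
appearance and the mapping is retained on the stream.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import yaml

from .streams import EdgeStream


def read_edge_list(path, sort_by_time: bool = False) -> EdgeStream:
    """Read a delimited edge list into an :class:`EdgeStream`.

    Lines carry 2 tokens ("i j") or 3 ("i j t"); all data lines must agree.
    With ``sort_by_time=True`` (requires timestamps) edges are stably
    sorted by t; otherwise file order is preserved.
    """
    path = Path(path)
    label_to_id: dict[str, int] = {}
    labels: list[str] = []
    rows: list[tuple[int, int]] = []
    times: list[float] = []
    n_tokens: int | None = None

    def node_id(label: str) -> int:
        if label not in label_to_id:
            label_to_id[label] = len(labels)
            labels.append(label)
        return label_to_id[label]

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.replace(",", " ").split()
            if len(tokens) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 'i j' or 'i j t', got {line!r}"
                )
            if n_tokens is None:
                n_tokens = len(tokens)
            elif len(tokens) != n_tokens:
                raise ValueError(
                    f"{path}:{lineno}: inconsistent column count "
                    f"(expected {n_tokens}, got {len(tokens)})"
                )
            if n_tokens == 3:
                try:
                    times.append(float(tokens[2]))
                except ValueError as err:
                    raise ValueError(
                        f"{path}:{lineno}: bad timestamp {tokens[2]!r}"
                    ) from err
            rows.append((node_id(tokens[0]), node_id(tokens[1])))
    if not rows:
        raise ValueError(f"{path}: no edges found")
    edges = np.asarray(rows, dtype=np.int64)
    t_arr = np.asarray(times) if times else None
    if sort_by_time:
        if t_arr is None:
            raise ValueError(f"{path}: sort_by_time requires a timestamp column")
        order = np.argsort(t_arr, kind="stable")
        edges, t_arr = edges[order], t_arr[order]
    return EdgeStream(edges=edges, n_total=len(labels), labels=labels, times=t_arr)


def write_edge_list(stream: EdgeStream, path, header: str | None = None) -> None:
    """Write a stream back to delimited text, using original labels when
    present, with the optional header emitted as '#' comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for idx, (i, j) in enumerate(stream.edges):
            a = stream.labels[i] if stream.labels else str(int(i))
            b = stream.labels[j] if stream.labels else str(int(j))
            if stream.times is not None:
                fh.write(f"{a} {b} {stream.times[idx]:g}\n")
            else:
                fh.write(f"{a} {b}\n")


@dataclass
class RunConfig:
    """Flat key-value run configuration, loadable from YAML and overridable
    by CLI flags.  Field names mirror the CLI options."""

    n_nodes: int = 20_000
    n_edges: int = 1_000
    p: float = 0.5
    f: float = 1.0
    allow_multiedges: bool = True
    allow_self_loops: bool = True
    local_info: bool = False
    updates: int = 10
    seed: int = 0
    kmax: int = 1000
    snapshot_edges: int = 1_000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def merged(self, **overrides) -> "RunConfig":
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)
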