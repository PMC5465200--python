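"""Haplogroup assignment from binary markers and frequency-table building.

Assignment walks the typed-marker hierarchy: a sample gets the label of the
deepest node whose marker is derived while every typed ancestor is derived.
When a child marker was typed and found ancestral, the paragroup notation
``X*-M(xY)`` is emitted (e.g. ``C2*-M217(xM48)``); untyped markers carry no
evidence and never trigger the exclusion notation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ystr.data_io import SampleRecord

UNRESOLVED = "unresolved"


class InconsistentCallsError(ValueError):
    """A derived marker sits below a marker typed ancestral."""


@dataclass(frozen=True)
class MarkerNode:
    label: str
    marker: str
    parent: Optional[str]  # parent marker, None for top-level


@dataclass
class MarkerTree:
    """Rooted hierarchy of the typed binary markers."""

    nodes: dict[str, MarkerNode] = field(default_factory=dict)  # by marker

    def __post_init__(self) -> None:
        for node in self.nodes.values():
            if node.parent is not None and node.parent not in self.nodes:
                raise ValueError(
                    f"parent marker {node.parent!r} of {node.marker!r} "
                    "not in tree"
                )
        # cycle check via depth computation
        for marker in self.nodes:
            self.depth(marker)

    @classmethod
    def from_json(cls, path: Optional[str | Path] = None) -> "MarkerTree":
        """Load the tree; defaults to the packaged 35-marker panel file."""
        if path is None:
            text = (
                resources.files("ystr") / "data" / "marker_tree.json"
            ).read_text()
        else:
            text = Path(path).read_text()
        raw = json.loads(text)
        nodes = {}
        for entry in raw["nodes"]:
            marker = entry["marker"]
            if marker in nodes:
                raise ValueError(f"marker {marker!r} appears twice")
            nodes[marker] = MarkerNode(
                label=entry["label"], marker=marker, parent=entry["parent"]
            )
        return cls(nodes=nodes)

    def ancestors(self, marker: str) -> list[str]:
        """Marker chain from the node's parent up to a top-level node."""
        chain, cur = [], self.nodes[marker].parent
        seen = set()
        while cur is not None:
            if cur in seen:
                raise ValueError(f"cycle in marker tree at {cur!r}")
            seen.add(cur)
            chain.append(cur)
            cur = self.nodes[cur].parent
        return chain

    def depth(self, marker: str) -> int:
        return len(self.ancestors(marker)) + 1

    def children(self, marker: str) -> list[str]:
        return sorted(
            m for m, n in self.nodes.items() if n.parent == marker
        )


_DEFAULT_TREE: Optional[MarkerTree] = None


def default_tree() -> MarkerTree:
    global _DEFAULT_TREE
    if _DEFAULT_TREE is None:
        _DEFAULT_TREE = MarkerTree.from_json()
    return _DEFAULT_TREE


def _paragroup_label(node: MarkerNode, excluded: Sequence[str]) -> str:
    prefix = node.label.rsplit("-", 1)[0]
    return f"{prefix}*-{node.marker}(x{','.join(excluded)})"


def assign_haplogroup(
    snp_calls: Mapping[str, str],
    tree: Optional[MarkerTree] = None,
) -> str:
    """Assign a haplogroup label from derived/ancestral marker calls.

    Returns :data:`UNRESOLVED` when no tree marker is derived.  Raises
    :class:`InconsistentCallsError` when a derived marker has an ancestor
    typed ancestral.
    """
    tree = tree or default_tree()
    derived = {m for m, c in snp_calls.items()
               if c == "derived" and m in tree.nodes}
    ancestral = {m for m, c in snp_calls.items()
                 if c == "ancestral" and m in tree.nodes}
    for marker in sorted(derived):
        bad = [a for a in tree.ancestors(marker) if a in ancestral]
        if bad:
            raise InconsistentCallsError(
                f"marker {marker} derived but ancestor {bad[0]} ancestral"
            )
    if not derived:
        return UNRESOLVED
    best = max(sorted(derived), key=lambda m: (tree.depth(m), m))
    node = tree.nodes[best]
    excluded = [c for c in tree.children(best) if c in ancestral]
    if excluded:
        return _paragroup_label(node, excluded)
    return node.label


@dataclass
class FrequencyTable:
    """Population-by-haplogroup proportions with per-population sizes."""

    populations: list[str]
    haplogroups: list[str]
    p: np.ndarray  # shape (n_pops, n_haplogroups), rows sum to 1
    n: np.ndarray  # sample sizes, shape (n_pops,)

    def validate(self) -> None:
        if self.p.shape != (len(self.populations), len(self.haplogroups)):
            raise ValueError("frequency matrix shape mismatch")
        if np.any(self.p < 0):
            raise ValueError("negative proportion")
        if not np.allclose(self.p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows must sum to 1")
        if np.any(self.n < 1):
            raise ValueError("sample sizes must be >= 1")

    def row(self, population: str) -> np.ndarray:
        return self.p[self.populations.index(population)]


def frequency_table(
    records: Iterable[SampleRecord],
    by: str = "population",
) -> FrequencyTable:
    """Count haplogroup proportions per population (or per clan).

    The haplogroup set is the union over all groups, zero-filled; records
    without an assigned haplogroup raise.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    if by not in ("population", "clan"):
        raise ValueError(f"unknown grouping {by!r}")
    groups: dict[str, list[str]] = {}
    for rec in records:
        if rec.haplogroup is None:
            raise ValueError(f"{rec.sample_id}: haplogroup not assigned")
        key = rec.population_code if by == "population" else (rec.clan or "")
        if not key:
            continue  # clanless samples drop out of clan tables
        groups.setdefault(key, []).append(rec.haplogroup)
    if not groups:
        raise ValueError("no groups after filtering")
    pops = sorted(groups)
    hgs = sorted({h for labels in groups.values() for h in labels})
    p = np.zeros((len(pops), len(hgs)))
    n = np.zeros(len(pops), dtype=int)
    for i, pop in enumerate(pops):
        labels = groups[pop]
        n[i] = len(labels)
        for h in labels:
            p[i, hgs.index(h)] += 1
        p[i] /= n[i]
    table = FrequencyTable(populations=pops, haplogroups=hgs, p=p, n=n)
    table.validate()
    return table


def haplogroup_diversity(p: Sequence[float], n: int) -> float:
    """Nei's unbiased gene diversity HD = n(1 - sum p_i^2)/(n - 1)."""
    if n < 2:
        raise ValueError("diversity undefined for n < 2")
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("frequencies must sum to 1")
    return float(n * (1.0 - np.sum(p**2)) / (n - 1))
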