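"""Gene duplication/loss histories along a species tree.

A history assigns to every branch (parent, child) an ordered list of
duplication events (source gene -> new copy) and loss events (gene).
Replaying the events from the root gene set induces the gene content at
every node; :meth:`DupLossHistory.replay` performs that replay and
:meth:`validate` checks it against stored contents.

Serialized as JSON:
``{"root_content": [...], "branches": [{"branch": [parent, child],
"duplications": [[source|null, new], ...], "losses": [...]}, ...]}``
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .trees import Phylogeny

__all__ = ["BranchEvents", "DupLossHistory", "GeneContent"]

#: Mapping from node label to the set of genes present at that node.
GeneContent = dict[str, frozenset[str]]


@dataclass
class BranchEvents:
    """Events on one tree branch, applied duplications-first."""

    duplications: list[tuple[str | None, str]] = field(default_factory=list)
    losses: list[str] = field(default_factory=list)

    @property
    def n_events(self) -> int:
        return len(self.duplications) + len(self.losses)


@dataclass
class DupLossHistory:
    """Per-branch duplication/loss events plus induced node gene contents."""

    root_content: frozenset[str]
    branches: dict[tuple[str, str], BranchEvents]
    contents: GeneContent = field(default_factory=dict)

    @property
    def n_duplications(self) -> int:
        return sum(len(b.duplications) for b in self.branches.values())

    @property
    def n_losses(self) -> int:
        return sum(len(b.losses) for b in self.branches.values())

    def replay(self, tree: Phylogeny) -> GeneContent:
        """Apply the events from the root down; returns content per node."""
        contents: GeneContent = {tree.root.label: frozenset(self.root_content)}
        for parent, child in tree.branches():
            genes = set(contents[parent.label])
            ev = self.branches.get((parent.label, child.label), BranchEvents())
            for source, new in ev.duplications:
                if source is not None and source not in genes:
                    raise ValueError(
                        f"duplication source {source!r} absent at start of branch "
                        f"{parent.label}->{child.label}"
                    )
                if new in genes:
                    raise ValueError(f"duplicate gene id {new!r} on replay")
                genes.add(new)
            for lost in ev.losses:
                if lost not in genes:
                    raise ValueError(
                        f"loss of {lost!r} not present on branch "
                        f"{parent.label}->{child.label}"
                    )
                genes.discard(lost)
            contents[child.label] = frozenset(genes)
        return contents

    def validate(self, tree: Phylogeny) -> None:
        """Check that replaying the events reproduces the stored contents."""
        replayed = self.replay(tree)
        if self.contents and replayed != dict(self.contents):
            diff = {
                k for k in replayed
                if replayed[k] != self.contents.get(k)
            }
            raise ValueError(f"history replay disagrees with contents at {sorted(diff)}")
        self.contents = replayed

    # -- serialization --------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "root_content": sorted(self.root_content),
            "branches": [
                {
                    "branch": [p, c],
                    "duplications": [[s, n] for s, n in ev.duplications],
                    "losses": list(ev.losses),
                }
                for (p, c), ev in self.branches.items()
            ],
        }
        return json.dumps(payload, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "DupLossHistory":
        payload = json.loads(text)
        try:
            root = frozenset(payload["root_content"])
            branches = {}
            for rec in payload["branches"]:
                p, c = rec["branch"]
                branches[(p, c)] = BranchEvents(
                    duplications=[(s, n) for s, n in rec.get("duplications", [])],
                    losses=list(rec.get("losses", [])),
                )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"malformed history JSON: {exc}") from exc
        return cls(root_content=root, branches=branches)

    @classmethod
    def load(cls, path: str | Path, tree: Phylogeny | None = None) -> "DupLossHistory":
        """Read a history file; when a tree is given, validate and replay it."""
        hist = cls.from_json(Path(path).read_text())
        if tree is not None:
            labels = {n.label for n in tree.preorder()}
            for p, c in hist.branches:
                if p not in labels or c not in labels:
                    raise ValueError(f"history branch ({p}, {c}) not in tree")
            hist.validate(tree)
        return hist
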