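"""Rooted taxonomy trees, in the NCBI taxdump dialect or JSON.

``nodes.dmp`` lines are pipe-tab delimited (``taxid | parent | rank |``);
``names.dmp`` carries scientific names.  The JSON form is one object with
``root`` and a ``nodes`` map ``taxid -> [parent, rank, name]``.  Trees are
validated on load: a unique root, no cycles, every node reaching the root.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .errors import FormatError, InputError

__all__ = ["TaxonomyTree", "load_taxonomy", "write_taxdump", "write_taxonomy_json"]


@dataclass
class TaxonomyTree:
    """taxid -> (parent taxid, rank, scientific name), plus the root id."""

    nodes: dict[int, tuple[int, str, str]]
    root: int

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        roots = [t for t, (p, _, _) in self.nodes.items() if p == t]
        if self.root not in self.nodes:
            raise FormatError(f"taxonomy: root taxid {self.root} missing from nodes")
        if roots and roots != [self.root]:
            raise FormatError(f"taxonomy: multiple roots {sorted(roots)}")
        for taxid in self.nodes:
            seen = set()
            cur = taxid
            while cur != self.root:
                if cur in seen:
                    raise FormatError(f"taxonomy: cycle through taxid {cur}")
                seen.add(cur)
                parent = self.nodes[cur][0]
                if parent not in self.nodes:
                    raise FormatError(f"taxonomy: orphan taxid {cur} (parent {parent} unknown)")
                cur = parent

    def parent(self, taxid: int) -> int:
        self._require(taxid)
        return self.nodes[taxid][0]

    def name(self, taxid: int) -> str:
        self._require(taxid)
        return self.nodes[taxid][2]

    def taxid_of(self, name: str) -> int:
        hits = [t for t, (_, _, n) in self.nodes.items() if n == name]
        if not hits:
            raise InputError(f"taxonomy: no node named {name!r}")
        if len(hits) > 1:
            raise InputError(f"taxonomy: name {name!r} is not unique ({sorted(hits)})")
        return hits[0]

    def ancestors(self, taxid: int) -> list[int]:
        """Ancestor chain of ``taxid``, root first, inclusive of ``taxid``."""
        self._require(taxid)
        chain = [taxid]
        while chain[-1] != self.root:
            chain.append(self.nodes[chain[-1]][0])
        return chain[::-1]

    def is_ancestor(self, ancestor: int, taxid: int) -> bool:
        """True iff ``ancestor`` is an ancestor-or-self of ``taxid``."""
        return ancestor in self.ancestors(taxid)

    def leaves(self) -> list[int]:
        parents = {p for t, (p, _, _) in self.nodes.items() if p != t}
        return sorted(t for t in self.nodes if t not in parents)

    def checksum(self) -> str:
        """Version pin: SHA-256 of the canonical serialization."""
        canon = json.dumps(
            {"root": self.root,
             "nodes": {str(t): list(self.nodes[t]) for t in sorted(self.nodes)}},
            sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()

    def _require(self, taxid: int) -> None:
        if taxid not in self.nodes:
            raise InputError(f"taxonomy: taxid {taxid} not in tree")


def _parse_dmp_line(line: str) -> list[str]:
    return [f.strip() for f in line.rstrip("\n").rstrip("\t|").split("\t|\t")]


def load_taxonomy(nodes_source: str | Path, names_source: Optional[str | Path] = None) -> TaxonomyTree:
    """Load a taxonomy from taxdump ``nodes.dmp``/``names.dmp`` or JSON.

    A single ``.json`` argument loads the JSON encoding; otherwise both dmp
    files are required.
    """
    nodes_source = Path(nodes_source)
    if nodes_source.suffix == ".json":
        payload = json.loads(nodes_source.read_text(encoding="utf-8"))
        nodes = {int(t): (int(v[0]), str(v[1]), str(v[2]))
                 for t, v in payload["nodes"].items()}
        return TaxonomyTree(nodes=nodes, root=int(payload["root"]))
    if names_source is None:
        raise FormatError("taxonomy: names.dmp required alongside nodes.dmp")
    parents: dict[int, tuple[int, str]] = {}
    for line in Path(nodes_source).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        fields = _parse_dmp_line(line)
        if len(fields) < 3:
            raise FormatError(f"nodes.dmp: short line {line!r}")
        parents[int(fields[0])] = (int(fields[1]), fields[2])
    names: dict[int, str] = {}
    for line in Path(names_source).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        fields = _parse_dmp_line(line)
        if len(fields) < 4:
            raise FormatError(f"names.dmp: short line {line!r}")
        taxid, name_txt, _, name_class = fields[:4]
        if name_class == "scientific name":
            names[int(taxid)] = name_txt
    nodes = {}
    for taxid, (parent, rank) in parents.items():
        nodes[taxid] = (parent, rank, names.get(taxid, str(taxid)))
    roots = [t for t, (p, _, _) in nodes.items() if p == t]
    if len(roots) != 1:
        raise FormatError(f"taxonomy: expected one self-parent root, found {sorted(roots)}")
    return TaxonomyTree(nodes=nodes, root=roots[0])


def write_taxdump(tree: TaxonomyTree, directory: str | Path) -> tuple[Path, Path]:
    """Write ``nodes.dmp`` and ``names.dmp`` in the pipe-tab dialect."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    nodes_path = directory / "nodes.dmp"
    names_path = directory / "names.dmp"
    with open(nodes_path, "w", encoding="utf-8", newline="\n") as fh:
        for taxid in sorted(tree.nodes):
            parent, rank, _ = tree.nodes[taxid]
            fh.write(f"{taxid}\t|\t{parent}\t|\t{rank}\t|\n")
    with open(names_path, "w", encoding="utf-8", newline="\n") as fh:
        for taxid in sorted(tree.nodes):
            name = tree.nodes[taxid][2]
            fh.write(f"{taxid}\t|\t{name}\t|\t\t|\tscientific name\t|\n")
    return nodes_path, names_path


def write_taxonomy_json(tree: TaxonomyTree, path: str | Path) -> Path:
    path = Path(path)
    payload = {"root": tree.root,
               "nodes": {str(t): list(tree.nodes[t]) for t in sorted(tree.nodes)}}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    return path
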