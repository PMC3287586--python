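"""Access to packaged data: stop-words, the default interaction lexicon,
the demo edge list and the KGML DTD.  Also the TSV dialects for
user-supplied gene dictionaries and lexica.

Gene dictionary TSV: ``canonical_symbol<TAB>synonym1<TAB>synonym2...``
(the canonical symbol itself always counts as a synonym).
Lexicon TSV: ``word<TAB>polarity`` with polarity in
{activation, repression, neutral}.  Lines starting with ``#`` are comments.
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources as _ilr
from pathlib import Path

from .errors import FormatError

__all__ = [
    "stopwords",
    "default_lexicon",
    "demo_edge_list",
    "kgml_dtd_path",
    "read_gene_dictionary",
    "read_lexicon",
    "write_gene_dictionary",
    "write_lexicon",
]

_POLARITIES = {"activation", "repression", "neutral"}


def _data(name: str) -> Path:
    return Path(str(_ilr.files("litpath").joinpath("data", name)))


@lru_cache(maxsize=1)
def stopwords() -> frozenset[str]:
    """The packaged stop-word list (lower-case)."""
    words = set()
    for line in _data("stopwords.txt").read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line.lower())
    return frozenset(words)


def read_lexicon(path: str | Path) -> dict[str, str]:
    """Read a ``word<TAB>polarity`` lexicon TSV."""
    lexicon: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"lexicon line {lineno}: expected 'word<TAB>polarity'")
        word, polarity = parts[0].strip(), parts[1].strip()
        if polarity not in _POLARITIES:
            raise FormatError(f"lexicon line {lineno}: unknown polarity {polarity!r}")
        lexicon[word.lower()] = polarity
    return lexicon


def write_lexicon(lexicon: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for word in sorted(lexicon):
            fh.write(f"{word}\t{lexicon[word]}\n")


@lru_cache(maxsize=1)
def default_lexicon() -> dict[str, str]:
    """The packaged ~60-verb interaction lexicon with polarity."""
    return dict(read_lexicon(_data("lexicon.tsv")))


def read_gene_dictionary(path: str | Path) -> dict[str, list[str]]:
    """Read a gene-name dictionary TSV: symbol followed by its synonyms."""
    dictionary: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = [p for p in line.split("\t") if p.strip()]
        if not parts:
            continue
        symbol, *synonyms = (p.strip() for p in parts)
        if symbol in dictionary:
            raise FormatError(f"gene dictionary line {lineno}: duplicate symbol {symbol}")
        dictionary[symbol] = list(dict.fromkeys([symbol, *synonyms]))
    return dictionary


def write_gene_dictionary(dictionary: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for symbol in sorted(dictionary):
            synonyms = [s for s in dictionary[symbol] if s != symbol]
            fh.write("\t".join([symbol, *synonyms]) + "\n")


def demo_edge_list() -> list[tuple[str, str, str, str]]:
    """The packaged hand-encoded preimplantation demo edges.

    Returns ``(source, subtype, target, evidence_id)`` tuples.
    """
    edges = []
    for line in _data("preimplantation_demo_edges.tsv").read_text(encoding="utf-8").splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        src, subtype, tgt, evidence = line.split("\t")
        edges.append((src, subtype, tgt, evidence))
    return edges


def kgml_dtd_path() -> Path:
    """Filesystem path of the packaged KGML DTD."""
    return _data("KGML_v0.7.2.dtd")
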