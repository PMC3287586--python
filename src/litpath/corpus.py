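"""Abstract corpora: the PMID-keyed record type and its Medline-like TSV format.

A corpus is a flat TSV, one record per line::

    pmid<TAB>title<TAB>abstract

UTF-8, no internal tabs or newlines inside fields.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import FormatError

__all__ = ["AbstractRecord", "read_corpus_tsv", "write_corpus_tsv"]


@dataclass(frozen=True)
class AbstractRecord:
    """One abstract: a PMID-keyed title plus body text."""

    pmid: str
    title: str
    body: str

    @property
    def text(self) -> str:
        """Title and body joined the way downstream tagging sees them."""
        if not self.title:
            return self.body
        if not self.body:
            return self.title
        return f"{self.title} {self.body}"

    def sentences(self):
        """Sentence segmentation of the full text (title is one sentence)."""
        from .extract import segment_sentences

        return segment_sentences(self.text)


def read_corpus_tsv(source: str | Path | io.TextIOBase) -> list[AbstractRecord]:
    """Read a ``pmid<TAB>title<TAB>abstract`` TSV into records."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return read_corpus_tsv(fh)
    records = []
    for lineno, line in enumerate(source, 1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(
                f"corpus line {lineno}: expected 3 tab-separated fields, got {len(parts)}"
            )
        records.append(AbstractRecord(*parts))
    return records


def write_corpus_tsv(records: Iterable[AbstractRecord], dest: str | Path | io.TextIOBase) -> None:
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8", newline="\n") as fh:
            write_corpus_tsv(records, fh)
        return
    for rec in records:
        for name, value in (("pmid", rec.pmid), ("title", rec.title), ("abstract", rec.body)):
            if "\t" in value or "\n" in value:
                raise FormatError(f"record {rec.pmid}: field {name} contains a tab or newline")
        dest.write(f"{rec.pmid}\t{rec.title}\t{rec.body}\n")
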