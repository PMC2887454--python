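"""Provenance metadata attached to NeuroML documents and cells."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Person:
    name: str
    institution: str = ""


@dataclass
class Metadata:
    """Background information tracked alongside a model component.

    Every field is optional; serialization preserves populated fields
    verbatim.  ``status`` records model stability ("stable",
    "in_progress", "known_issues") with free-text detail in
    ``status_comment``.
    """

    authors: list[Person] = field(default_factory=list)
    translators: list[Person] = field(default_factory=list)
    publications: list[str] = field(default_factory=list)
    database_refs: list[tuple[str, str]] = field(default_factory=list)
    comments: str = ""
    status: str = ""
    status_comment: str = ""

    def is_empty(self) -> bool:
        return not (self.authors or self.translators or self.publications
                    or self.database_refs or self.comments or self.status
                    or self.status_comment)
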