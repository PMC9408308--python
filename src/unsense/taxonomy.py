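"""Controlled vocabulary: molecular levels, mechanism tags, effect tags and
the registry of RNA substitution-type terms."""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, asdict
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional


class Level(str, Enum):
    DNA = "DNA"
    RNA = "RNA"
    PROTEIN = "PROTEIN"


class MechanismTag(str, Enum):
    """Mechanism through which a codon-synonymous change exerts an effect."""

    TF_BINDING = "TF_BINDING"
    SPLICE_SITE = "SPLICE_SITE"
    ESE = "ESE"
    ESS = "ESS"
    MRNA_STRUCTURE_STABILITY = "MRNA_STRUCTURE_STABILITY"
    MIRNA_BINDING = "MIRNA_BINDING"
    CODON_USAGE_TRANSLATION = "CODON_USAGE_TRANSLATION"
    COTRANSLATIONAL_FOLDING = "COTRANSLATIONAL_FOLDING"
    PTM = "PTM"
    NONE_OBSERVED = "NONE_OBSERVED"

    @property
    def level(self) -> Optional[Level]:
        return _MECHANISM_LEVEL.get(self)


_MECHANISM_LEVEL: dict[MechanismTag, Level] = {
    MechanismTag.TF_BINDING: Level.DNA,
    MechanismTag.SPLICE_SITE: Level.RNA,
    MechanismTag.ESE: Level.RNA,
    MechanismTag.ESS: Level.RNA,
    MechanismTag.MRNA_STRUCTURE_STABILITY: Level.RNA,
    MechanismTag.MIRNA_BINDING: Level.RNA,
    MechanismTag.CODON_USAGE_TRANSLATION: Level.PROTEIN,
    MechanismTag.COTRANSLATIONAL_FOLDING: Level.PROTEIN,
    MechanismTag.PTM: Level.PROTEIN,
}

#: RNA-level mechanisms that make a codon-synonymous variant an unsense one
#: (splicing, splicing regulation, or miRNA-mediated expression regulation).
UNSENSE_MECHANISMS = frozenset(
    {
        MechanismTag.SPLICE_SITE,
        MechanismTag.ESE,
        MechanismTag.ESS,
        MechanismTag.MIRNA_BINDING,
    }
)


class EffectTag(str, Enum):
    MISSING_RNA = "MISSING_RNA"
    EXON_SKIPPING = "EXON_SKIPPING"
    EXON_INCLUSION = "EXON_INCLUSION"
    ABERRANT_SPLICING = "ABERRANT_SPLICING"
    PREMATURE_STOP = "PREMATURE_STOP"
    FRAMESHIFT = "FRAMESHIFT"
    EXPRESSION_CHANGE = "EXPRESSION_CHANGE"
    PROTEIN_ABUNDANCE_CHANGE = "PROTEIN_ABUNDANCE_CHANGE"
    CONFORMATION_CHANGE = "CONFORMATION_CHANGE"
    ACTIVITY_CHANGE = "ACTIVITY_CHANGE"
    PTM_LOSS = "PTM_LOSS"
    NO_EFFECT = "NO_EFFECT"


def mechanisms_for_level(level: Level | str) -> list[MechanismTag]:
    """All mechanism tags operating at the given molecular level."""
    level = Level(level)
    return [m for m, lv in _MECHANISM_LEVEL.items() if lv == level]


class TermLookupError(KeyError):
    def __init__(self, query: str, suggestions: list[str]):
        self.query = query
        self.suggestions = suggestions
        hint = f"; did you mean: {', '.join(suggestions)}?" if suggestions else ""
        super().__init__(f"unknown term {query!r}{hint}")


@dataclass(frozen=True)
class Term:
    """One vocabulary entry.

    ``provenance`` records where the definition text comes from;
    ``external_code`` carries a cross-reference code when one is known
    (None where the source figure could not be transcribed).
    """

    term_id: str
    name: str
    definition: str
    level: str
    parent: Optional[str] = None
    provenance: str = "artifact"
    external_code: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)


class TermRegistry:
    """Queryable, serialisable collection of Terms."""

    def __init__(self, terms: Iterable[Term]):
        self._by_id: dict[str, Term] = {}
        self._by_name: dict[str, Term] = {}
        for t in terms:
            if t.term_id in self._by_id:
                raise ValueError(f"duplicate term_id {t.term_id!r}")
            if t.name.lower() in self._by_name:
                raise ValueError(f"duplicate term name {t.name!r}")
            self._by_id[t.term_id] = t
            self._by_name[t.name.lower()] = t
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        for t in self._by_id.values():
            seen = {t.term_id}
            cur = t
            while cur.parent is not None:
                if cur.parent not in self._by_id:
                    raise ValueError(
                        f"term {cur.term_id!r} has unknown parent {cur.parent!r}"
                    )
                if cur.parent in seen:
                    raise ValueError(f"parent cycle at {cur.parent!r}")
                seen.add(cur.parent)
                cur = self._by_id[cur.parent]

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self):
        return iter(self._by_id.values())

    def lookup(self, term_id_or_name: str) -> Term:
        """Exact-match lookup by id, or case-insensitively by name."""
        if term_id_or_name in self._by_id:
            return self._by_id[term_id_or_name]
        key = term_id_or_name.lower()
        if key in self._by_name:
            return self._by_name[key]
        candidates = list(self._by_id) + [t.name for t in self._by_id.values()]
        suggestions = difflib.get_close_matches(term_id_or_name, candidates, n=3)
        raise TermLookupError(term_id_or_name, suggestions)

    def children(self, term_id: str) -> list[Term]:
        return [t for t in self._by_id.values() if t.parent == term_id]

    def to_json(self) -> str:
        return json.dumps([t.to_dict() for t in self._by_id.values()], indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TermRegistry":
        return cls(Term(**obj) for obj in json.loads(text))

    @classmethod
    def from_file(cls, path: str | Path) -> "TermRegistry":
        return cls.from_json(Path(path).read_text())


def load_default_registry() -> TermRegistry:
    """Load the packaged term registry (data/terms.json)."""
    text = resources.files("unsense").joinpath("data/terms.json").read_text()
    return TermRegistry.from_json(text)
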