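"""Codon tables and exhaustive enumeration of the single-nucleotide
substitution space.

Counting is *directed*: each ordered ``ref -> alt`` single-base change is one
record, so a table of 64 codons yields exactly 64 x 9 = 576 records.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping

BASES = "ACGT"
PURINES = frozenset("AG")
STOP = "*"

#: Three-letter names for one-letter amino-acid codes (plus the stop marker).
AA_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    STOP: "Stop",
}
_THREE_TO_ONE = {v.upper(): k for k, v in AA_THREE.items()}

# Standard genetic code, spelled out rather than imported so that tests can
# cross-check it against an independent source.
_STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": STOP, "TAG": STOP,
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": STOP, "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class CodonTableError(ValueError):
    """Raised for invalid codons, amino acids, or malformed table files."""


class Category(str, Enum):
    """Outcome of a single-base codon change at translation level."""

    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    STOP_LOSS = "stop_loss"
    STOP_TO_STOP = "stop_to_stop"


class Chemistry(str, Enum):
    TRANSITION = "transition"
    TRANSVERSION = "transversion"


def _normalize_codon(codon: str) -> str:
    """Uppercase and map U->T; reject anything that is not a trinucleotide."""
    if not isinstance(codon, str) or len(codon) != 3:
        raise CodonTableError(f"not a trinucleotide: {codon!r}")
    norm = codon.upper().replace("U", "T")
    bad = set(norm) - set(BASES)
    if bad:
        raise CodonTableError(
            f"codon {codon!r} contains invalid characters: {sorted(bad)}"
        )
    return norm


@dataclass(frozen=True)
class CodonTable:
    """A complete codon -> amino-acid map over the DNA alphabet.

    ``codon_to_aa`` maps each of the 64 trinucleotides to a one-letter
    amino-acid code, with ``"*"`` marking stop codons.
    """

    table_id: str = "standard"
    codon_to_aa: Mapping[str, str] = field(
        default_factory=lambda: dict(_STANDARD_CODE)
    )

    def __post_init__(self) -> None:
        expected = {"".join(p) for p in product(BASES, repeat=3)}
        keys = set(self.codon_to_aa)
        if keys != expected:
            missing = sorted(expected - keys)[:3]
            extra = sorted(keys - expected)[:3]
            raise CodonTableError(
                f"codon table {self.table_id!r} must map exactly the 64 codons"
                f" (missing e.g. {missing}, unexpected e.g. {extra})"
            )

    @property
    def codons(self) -> list[str]:
        return sorted(self.codon_to_aa)

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(
            c for c, a in self.codon_to_aa.items() if a == STOP
        )

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[_normalize_codon(codon)] == STOP

    @classmethod
    def standard(cls) -> "CodonTable":
        return cls()

    @classmethod
    def from_tsv(cls, path: str | Path, table_id: str | None = None) -> "CodonTable":
        """Read a two-column TSV (codon, amino_acid) with 64 data rows.

        The amino-acid column accepts one-letter codes, three-letter names,
        or "Stop"/"*" for stop codons.  A header row is allowed.
        """
        path = Path(path)
        mapping: dict[str, str] = {}
        with path.open() as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise CodonTableError(
                        f"{path}:{lineno}: expected 2 tab-separated columns"
                    )
                codon_raw, aa_raw = parts[0].strip(), parts[1].strip()
                if lineno == 1 and codon_raw.lower() in ("codon",):
                    continue
                codon = _normalize_codon(codon_raw)
                aa = _parse_aa(aa_raw)
                if codon in mapping:
                    raise CodonTableError(f"{path}:{lineno}: duplicate codon {codon}")
                mapping[codon] = aa
        return cls(table_id=table_id or path.stem, codon_to_aa=mapping)


def _parse_aa(token: str) -> str:
    if token in ("*", "Stop", "stop", "STOP", "Ter"):
        return STOP
    if len(token) == 1 and token.upper() in AA_THREE:
        return token.upper()
    if token.upper() in _THREE_TO_ONE:
        return _THREE_TO_ONE[token.upper()]
    raise CodonTableError(f"unknown amino-acid code: {token!r}")


def translate_codon(codon: str, table: CodonTable | None = None) -> str:
    """Translate one codon; returns a one-letter code or ``"*"`` for stop.

    Accepts RNA spelling (U normalised to T) and lowercase input.
    """
    table = table or CodonTable.standard()
    return table.codon_to_aa[_normalize_codon(codon)]


def chemistry(ref_base: str, alt_base: str) -> Chemistry:
    """Transition (purine<->purine or pyrimidine<->pyrimidine) vs transversion."""
    ref = _normalize_codon(ref_base * 3)[0]
    alt = _normalize_codon(alt_base * 3)[0]
    if ref == alt:
        raise CodonTableError(f"identical bases {ref!r}: not a substitution")
    if (ref in PURINES) == (alt in PURINES):
        return Chemistry.TRANSITION
    return Chemistry.TRANSVERSION


def classify_codon_substitution(
    ref_codon: str, alt_codon: str, table: CodonTable | None = None
) -> Category:
    """Category of a single-base codon change.

    Requires Hamming distance exactly 1; distance 0 and distance >= 2 raise
    distinct errors.
    """
    table = table or CodonTable.standard()
    ref = _normalize_codon(ref_codon)
    alt = _normalize_codon(alt_codon)
    dist = sum(a != b for a, b in zip(ref, alt))
    if dist == 0:
        raise CodonTableError(f"{ref} -> {alt}: not a substitution (identical codons)")
    if dist > 1:
        raise CodonTableError(
            f"{ref} -> {alt}: multi-nucleotide change out of scope"
        )
    ref_aa = table.codon_to_aa[ref]
    alt_aa = table.codon_to_aa[alt]
    if ref_aa == STOP and alt_aa == STOP:
        return Category.STOP_TO_STOP
    if ref_aa == STOP:
        return Category.STOP_LOSS
    if alt_aa == STOP:
        return Category.NONSENSE
    if ref_aa == alt_aa:
        return Category.SYNONYMOUS
    return Category.MISSENSE


@dataclass(frozen=True)
class SubstitutionRecord:
    """One ordered single-base codon change with its category and chemistry."""

    ref_codon: str
    alt_codon: str
    position: int  # codon position, 1..3
    ref_base: str
    alt_base: str
    category: Category
    chemistry: Chemistry

    def __post_init__(self) -> None:
        diffs = [i + 1 for i, (a, b) in
                 enumerate(zip(self.ref_codon, self.alt_codon)) if a != b]
        if diffs != [self.position]:
            raise CodonTableError(
                f"{self.ref_codon} -> {self.alt_codon}: codons must differ "
                f"exactly at position {self.position}, differ at {diffs}"
            )


def enumerate_substitution_space(
    table: CodonTable | None = None,
) -> list[SubstitutionRecord]:
    """All ordered single-base codon changes, 9 per codon.

    Deterministic order: ref codon lexicographic, then position, then alt
    base lexicographic.
    """
    table = table or CodonTable.standard()
    records: list[SubstitutionRecord] = []
    for codon in table.codons:
        for pos in (1, 2, 3):
            ref_base = codon[pos - 1]
            for alt_base in BASES:
                if alt_base == ref_base:
                    continue
                alt_codon = codon[: pos - 1] + alt_base + codon[pos:]
                records.append(
                    SubstitutionRecord(
                        ref_codon=codon,
                        alt_codon=alt_codon,
                        position=pos,
                        ref_base=ref_base,
                        alt_base=alt_base,
                        category=classify_codon_substitution(codon, alt_codon, table),
                        chemistry=chemistry(ref_base, alt_base),
                    )
                )
    return records


def round_percent(count: int, total: int) -> float:
    """100*count/total rounded half-up to one decimal."""
    pct = Decimal(100 * count) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SpaceSummary:
    """Counts, percentages and wobble structure of a full enumeration.

    ``syn_off_wobble`` counts synonymous records whose changed base is not at
    the third codon position; ``syn_off_wobble_by_position`` breaks those down
    per position.  ``wobble_groups`` flags, per two-base prefix, whether all
    third-position changes within the group are synonymous coding changes.
    """

    total: int
    by_category: dict[str, int]
    by_position_category: dict[int, dict[str, int]]
    percent_by_category: dict[str, float]
    transitions: int
    transversions: int
    syn_off_wobble: int
    syn_off_wobble_by_position: dict[int, int]
    syn_off_wobble_percent: float
    wobble_groups: dict[str, bool]
    wobble_groups_full: int
    fold_stop_to_stop: bool = False

    def to_dict(self) -> dict:
        d = {
            "total": self.total,
            "synonymous": self.by_category.get(Category.SYNONYMOUS.value, 0),
            "missense": self.by_category.get(Category.MISSENSE.value, 0),
            "nonsense": self.by_category.get(Category.NONSENSE.value, 0),
            "stop_loss": self.by_category.get(Category.STOP_LOSS.value, 0),
            "stop_to_stop": self.by_category.get(Category.STOP_TO_STOP.value, 0),
            "syn_off_wobble": self.syn_off_wobble,
            "transitions": self.transitions,
            "transversions": self.transversions,
            "wobble_groups_full": self.wobble_groups_full,
            "percent": dict(self.percent_by_category),
            "syn_off_wobble_percent": self.syn_off_wobble_percent,
            "syn_off_wobble_by_position": {
                str(k): v for k, v in self.syn_off_wobble_by_position.items()
            },
            "by_position": {
                str(p): dict(c) for p, c in self.by_position_category.items()
            },
            "wobble_groups": dict(self.wobble_groups),
            "fold_stop_to_stop": self.fold_stop_to_stop,
        }
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_tsv(self) -> str:
        flat = self.to_dict()
        rows = [
            ("total", flat["total"]),
            ("synonymous", flat["synonymous"]),
            ("missense", flat["missense"]),
            ("nonsense", flat["nonsense"]),
            ("stop_loss", flat["stop_loss"]),
            ("stop_to_stop", flat["stop_to_stop"]),
            ("syn_off_wobble", flat["syn_off_wobble"]),
            ("transitions", flat["transitions"]),
            ("transversions", flat["transversions"]),
            ("wobble_groups_full", flat["wobble_groups_full"]),
        ]
        lines = ["key\tvalue"]
        lines += [f"{k}\t{v}" for k, v in rows]
        return "\n".join(lines) + "\n"


def summarize_space(
    records: Iterable[SubstitutionRecord],
    table: CodonTable | None = None,
    fold_stop_to_stop: bool = False,
) -> SpaceSummary:
    """Summarise a complete enumeration.

    With ``fold_stop_to_stop=True``, stop<->stop records are counted inside
    the synonymous tally (they change no amino acid), matching presentations
    that first count them as synonymous before excluding them.
    """
    table = table or CodonTable.standard()
    records = list(records)
    n_codons = len(table.codons)
    if len(records) != 9 * n_codons:
        raise CodonTableError(
            f"incomplete enumeration: {len(records)} records, "
            f"expected {9 * n_codons}"
        )
    by_cat: Counter[str] = Counter()
    by_pos_cat: dict[int, Counter[str]] = {1: Counter(), 2: Counter(), 3: Counter()}
    chem: Counter[Chemistry] = Counter()
    syn_off: Counter[int] = Counter()
    for rec in records:
        cat = rec.category
        if fold_stop_to_stop and cat == Category.STOP_TO_STOP:
            cat = Category.SYNONYMOUS
        by_cat[cat.value] += 1
        by_pos_cat[rec.position][cat.value] += 1
        chem[rec.chemistry] += 1
        if cat == Category.SYNONYMOUS and rec.position != 3:
            syn_off[rec.position] += 1
    total = len(records)
    groups = wobble_group_analysis(table)
    return SpaceSummary(
        total=total,
        by_category=dict(by_cat),
        by_position_category={p: dict(c) for p, c in by_pos_cat.items()},
        percent_by_category={
            cat: round_percent(n, total) for cat, n in sorted(by_cat.items())
        },
        transitions=chem[Chemistry.TRANSITION],
        transversions=chem[Chemistry.TRANSVERSION],
        syn_off_wobble=sum(syn_off.values()),
        syn_off_wobble_by_position=dict(syn_off),
        syn_off_wobble_percent=round_percent(sum(syn_off.values()), total),
        wobble_groups=groups,
        wobble_groups_full=sum(groups.values()),
        fold_stop_to_stop=fold_stop_to_stop,
    )


def degeneracy(amino_acid: str, table: CodonTable | None = None) -> int:
    """Number of codons translating to the given amino acid.

    Accepts one-letter or three-letter codes and "Stop"/"*".
    """
    table = table or CodonTable.standard()
    aa = _parse_aa(amino_acid)
    count = sum(1 for a in table.codon_to_aa.values() if a == aa)
    if count == 0:
        raise CodonTableError(
            f"amino acid {amino_acid!r} not present in table {table.table_id!r}"
        )
    return count


def wobble_group_analysis(table: CodonTable | None = None) -> dict[str, bool]:
    """Per two-base codon group, is the third position fully interchangeable?

    A group (e.g. ``"CT"`` for CTA/CTC/CTG/CTT) is flagged True iff all six
    unordered third-position pairs are synonymous changes between coding
    codons.
    """
    table = table or CodonTable.standard()
    flags: dict[str, bool] = {}
    for prefix in ("".join(p) for p in product(BASES, repeat=2)):
        aas = {table.codon_to_aa[prefix + b] for b in BASES}
        flags[prefix] = len(aas) == 1 and STOP not in aas
    return flags
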