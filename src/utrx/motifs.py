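"""Gapped IUPAC motif grammar (Transterm style) and seed-site counting.

A pattern is a whitespace-separated list of elements:

* an IUPAC word, optionally with parenthesised alternations — ``A(A|U)UAAA``;
* a bounded gap ``a...b`` (also written ``a.b``), matching any ``a``–``b``
  bases;
* a bounded repeat ``X{a,b}`` of one IUPAC symbol;
* a mismatch triple ``[s,i,d]`` — substitution / insertion / deletion
  allowances applied to the word immediately before it.

The four built-in 3'UTR elements::

    c_rich          YCCA 0...5 CCCW Y{0,4} TCYCC
    au_rich         UAUUUAUWW
    cyto_polyA      UUUUAU 1.100 AAUAAA
    mammalian_polyA A(A|U)UAAA 12.40 KKKKKKKKKK [5,0,0]

Sequences are DNA or RNA; T and U are equivalent.  An ``N`` in the scanned
sequence is matched only by the IUPAC code N (and by gaps).

MicroRNA seed sites are counted TargetScan-style from the 7-base seed
(miRNA positions 2–8): 8mer (perfect seed match plus A opposite position 1),
7mer-m8 (perfect seed match), 7mer-A1 (positions 2–7 match plus A); each
genomic occurrence is assigned to exactly one type (8mer > 7mer-m8 >
7mer-A1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

from .errors import MotifParseError, ValidationError

# IUPAC nucleotide codes over the DNA alphabet (U folded onto T).
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),  # N in a pattern matches anything, incl. seq N
}

_GAP_RE = re.compile(r"^(\d+)\.{1,3}(\d+)$")
_REPEAT_RE = re.compile(r"^([A-Za-z])\{(\d+),(\d+)\}$")
_MISMATCH_RE = re.compile(r"^\[(\d+),(\d+),(\d+)\]$")


@dataclass(frozen=True)
class Word:
    """An IUPAC word; alternations are expanded into literal variants."""

    variants: tuple[tuple[frozenset, ...], ...]
    mismatch: tuple[int, int, int] = (0, 0, 0)
    text: str = ""


@dataclass(frozen=True)
class Gap:
    min: int
    max: int


@dataclass(frozen=True)
class Repeat:
    allowed: frozenset
    min: int
    max: int
    symbol: str = ""


Element = Union[Word, Gap, Repeat]


@dataclass(frozen=True)
class MotifPattern:
    elements: tuple[Element, ...]
    text: str = ""
    name: str = ""


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _parse_word(token: str, offset: int) -> Word:
    """Parse one word token; cross-product of parenthesised alternations."""
    variants: list[list[frozenset]] = [[]]
    i = 0
    while i < len(token):
        ch = token[i]
        if ch == "(":
            j = token.find(")", i)
            if j < 0:
                raise MotifParseError("unclosed '('", offset + i)
            alts = token[i + 1 : j].split("|")
            if not all(alts):
                raise MotifParseError("empty alternation branch", offset + i)
            expanded: list[list[frozenset]] = []
            for prefix in variants:
                for alt in alts:
                    sets = []
                    for k, c in enumerate(alt.upper()):
                        if c not in IUPAC:
                            raise MotifParseError(
                                f"unknown symbol {c!r}", offset + i + 1 + k
                            )
                        sets.append(IUPAC[c])
                    expanded.append(prefix + sets)
            variants = expanded
            i = j + 1
        else:
            cu = ch.upper()
            if cu not in IUPAC:
                raise MotifParseError(f"unknown symbol {ch!r}", offset + i)
            for v in variants:
                v.append(IUPAC[cu])
            i += 1
    if not variants[0]:
        raise MotifParseError("empty word", offset)
    return Word(variants=tuple(tuple(v) for v in variants), text=token)


def parse_motif_pattern(text: str, name: str = "") -> MotifPattern:
    """Parse Transterm-style pattern text into a structured MotifPattern."""
    elements: list[Element] = []
    pos = 0
    for token in text.split():
        offset = text.index(token, pos)
        pos = offset + len(token)
        m = _MISMATCH_RE.match(token)
        if m:
            if not elements or not isinstance(elements[-1], Word):
                raise MotifParseError(
                    "mismatch triple must follow a word", offset
                )
            prev = elements[-1]
            elements[-1] = Word(
                variants=prev.variants,
                mismatch=(int(m.group(1)), int(m.group(2)), int(m.group(3))),
                text=prev.text,
            )
            continue
        m = _GAP_RE.match(token)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            if lo > hi:
                raise MotifParseError(f"gap min {lo} > max {hi}", offset)
            elements.append(Gap(lo, hi))
            continue
        m = _REPEAT_RE.match(token)
        if m:
            sym = m.group(1).upper()
            if sym not in IUPAC:
                raise MotifParseError(f"unknown symbol {sym!r}", offset)
            lo, hi = int(m.group(2)), int(m.group(3))
            if lo > hi:
                raise MotifParseError(f"repeat min {lo} > max {hi}", offset)
            elements.append(Repeat(IUPAC[sym], lo, hi, symbol=sym))
            continue
        elements.append(_parse_word(token, offset))
    if not elements:
        raise MotifParseError("empty pattern", 0)
    return MotifPattern(elements=tuple(elements), text=text, name=name)


BUILTIN_MOTIFS: dict[str, MotifPattern] = {
    name: parse_motif_pattern(text, name)
    for name, text in {
        "c_rich": "YCCA 0...5 CCCW Y{0,4} TCYCC",
        "au_rich": "UAUUUAUWW",
        "cyto_polyA": "UUUUAU 1.100 AAUAAA",
        "mammalian_polyA": "A(A|U)UAAA 12.40 KKKKKKKKKK [5,0,0]",
    }.items()
}


def _word_ends(seq: str, pos: int, word: Word) -> list[int]:
    """All end positions where ``word`` can match starting at ``pos``."""
    s_max, i_max, d_max = word.mismatch
    ends: set[int] = set()
    for variant in word.variants:
        if i_max == 0 and d_max == 0:
            # substitutions only: fixed length, count mismatches
            end = pos + len(variant)
            if end > len(seq):
                continue
            mism = sum(
                1 for k, allowed in enumerate(variant) if seq[pos + k] not in allowed
            )
            if mism <= s_max:
                ends.add(end)
        else:
            stack = [(pos, 0, s_max, i_max, d_max)]
            seen = set()
            while stack:
                p, k, s, i, d = stack.pop()
                if (p, k, s, i, d) in seen:
                    continue
                seen.add((p, k, s, i, d))
                if k == len(variant):
                    ends.add(p)
                    continue
                if p < len(seq):
                    if seq[p] in variant[k]:
                        stack.append((p + 1, k + 1, s, i, d))
                    elif s > 0:
                        stack.append((p + 1, k + 1, s - 1, i, d))
                    if i > 0:  # extra sequence base
                        stack.append((p + 1, k, s, i - 1, d))
                if d > 0:  # skipped motif symbol
                    stack.append((p, k + 1, s, i, d - 1))
    return sorted(ends)


def _element_ends(seq: str, pos: int, elem: Element) -> Iterable[int]:
    if isinstance(elem, Word):
        return _word_ends(seq, pos, elem)
    if isinstance(elem, Gap):
        hi = min(elem.max, len(seq) - pos)
        return range(pos + elem.min, pos + hi + 1) if hi >= elem.min else ()
    # Repeat: maximal run of allowed symbols, any count within bounds
    run = 0
    while pos + run < len(seq) and run < elem.max and seq[pos + run] in elem.allowed:
        run += 1
    if run < elem.min:
        return ()
    return range(pos + elem.min, pos + run + 1)


def _match_at(seq: str, pos: int, elements: Sequence[Element]) -> int | None:
    """Smallest-consumption match end, trying shorter element spans first."""
    if not elements:
        return pos
    for end in _element_ends(seq, pos, elements[0]):
        rest = _match_at(seq, end, elements[1:])
        if rest is not None:
            return rest
    return None


def scan_motif(seq: str, pattern: MotifPattern) -> list[tuple[int, int]]:
    """All matches of ``pattern`` in ``seq``, one per matching start position.

    Returns (start, end) half-open coordinates; the end reported for each
    start is the shortest-gap assignment.
    """
    s = _normalize(seq)
    hits: list[tuple[int, int]] = []
    for start in range(len(s)):
        end = _match_at(s, start, pattern.elements)
        if end is not None:
            hits.append((start, end))
    return hits


@dataclass
class MotifCountTable:
    """Hit counts per motif for one or more region sets."""

    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    total_bp: dict[str, int] = field(default_factory=dict)

    def per_kbp(self, set_name: str, motif: str) -> float:
        bp = self.total_bp[set_name]
        if bp == 0:
            raise ValidationError(f"region set {set_name!r} has no sequence")
        return 1000.0 * self.counts[set_name][motif] / bp


def count_motifs(
    sequences_by_set: Mapping[str, Sequence[str]],
    patterns: Mapping[str, MotifPattern] | None = None,
) -> MotifCountTable:
    """Scan every sequence in every named set with every pattern."""
    patterns = dict(patterns) if patterns is not None else dict(BUILTIN_MOTIFS)
    table = MotifCountTable()
    for set_name, seqs in sequences_by_set.items():
        table.counts[set_name] = {}
        table.total_bp[set_name] = sum(len(s) for s in seqs)
        for motif_name, pattern in patterns.items():
            table.counts[set_name][motif_name] = sum(
                len(scan_motif(s, pattern)) for s in seqs
            )
    return table


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def count_seed_sites(
    utr_seq: str,
    seeds: Sequence[str],
) -> dict[str, dict[str, int]]:
    """Count 8mer / 7mer-m8 / 7mer-A1 sites per seed in a target sequence.

    ``seeds`` are 7-base miRNA seeds (positions 2–8, 5'→3', RNA or DNA
    alphabet).  Conservation is not considered.
    """
    target = _normalize(utr_seq)
    out: dict[str, dict[str, int]] = {}
    for seed in seeds:
        s = _normalize(seed)
        if len(s) != 7 or any(c not in "ACGT" for c in s):
            raise ValidationError(f"seed must be 7 bases over A/C/G/U, got {seed!r}")
        m8_site = _revcomp(s)              # match to positions 2-8
        a1_site = _revcomp(s[:6]) + "A"    # match to positions 2-7, then A
        counts = {"8mer": 0, "7mer-m8": 0, "7mer-A1": 0}
        # occurrences of the full seed match, split by the position-1 A
        i = target.find(m8_site)
        while i >= 0:
            if target[i + 7 : i + 8] == "A":
                counts["8mer"] += 1
            else:
                counts["7mer-m8"] += 1
            i = target.find(m8_site, i + 1)
        # 7mer-A1 occurrences not embedded in an 8mer
        i = target.find(a1_site)
        while i >= 0:
            embedded = i >= 1 and target[i - 1 : i + 6] == m8_site
            if not embedded:
                counts["7mer-A1"] += 1
            i = target.find(a1_site, i + 1)
        out[seed] = counts
    return out
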