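"""Degenerate TCF/LEF (WRE) motif expansion and strand-aware promoter scanning.

The Wnt response element bound by beta-catenin/TCF/LEF factors is the
degenerate 7-mer 5'-(A/T)(A/T)CAAAG-3', written ``WWCAAAG`` in IUPAC code.
It expands to four literal 7-mers; together with their reverse complements
that gives eight distinct strings to search, four per strand (the two
strand sets are disjoint for this motif).

Hit coordinates follow one convention throughout the package: a hit's
``position`` is the TSS-relative coordinate of the *leftmost sense-strand
base* of the 7-mer, on both strands.  Windows containing N never match.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .promoter_io import (
    PromoterIOError,
    PromoterRecord,
    index_to_pos,
    reverse_complement,
)

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

WRE_PATTERN = "WWCAAAG"


def expand_motif(pattern: str, both_strands: bool = False) -> frozenset[str]:
    """All literal expansions of an IUPAC pattern, optionally plus reverse complements."""
    if not pattern:
        raise ValueError("empty pattern")
    pattern = pattern.upper()
    try:
        choices = [IUPAC_CODES[c] for c in pattern]
    except KeyError as exc:
        raise ValueError(f"illegal IUPAC code {exc.args[0]!r} in pattern {pattern!r}") from None
    forward = frozenset("".join(p) for p in itertools.product(*choices))
    if not both_strands:
        return forward
    return forward | frozenset(reverse_complement(s) for s in forward)


@dataclass(frozen=True)
class DegenerateMotif:
    """A degenerate motif with its literal forward and reverse-strand expansions."""

    pattern: str = WRE_PATTERN

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def forward_variants(self) -> frozenset[str]:
        return expand_motif(self.pattern)

    @property
    def reverse_variants(self) -> frozenset[str]:
        return frozenset(reverse_complement(s) for s in self.forward_variants)

    @property
    def palindromic_overlap(self) -> frozenset[str]:
        """Variants matching on both strands (empty for the WRE)."""
        return self.forward_variants & self.reverse_variants

    @property
    def all_variants(self) -> frozenset[str]:
        return self.forward_variants | self.reverse_variants

    def matches(self, kmer: str) -> bool:
        """Whether a literal k-mer matches the pattern on either strand."""
        kmer = kmer.upper()
        return kmer in self.forward_variants or kmer in self.reverse_variants


@dataclass(frozen=True, order=True)
class MotifHit:
    """One strand-aware motif match, TSS-relative.

    ``position`` anchors the leftmost sense-strand base of the match;
    ``matched_seq`` is the literal k-mer as read on the matching strand.
    """

    position: int
    strand: str
    matched_seq: str
    species: str = ""
    isoform_id: str = ""
    pattern_id: str = WRE_PATTERN

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


def scan_sequence(seq: str, motif: DegenerateMotif, upstream: int,
                  species: str = "", isoform_id: str = "") -> list[MotifHit]:
    """Scan a sense-oriented sequence on both strands.

    ``upstream`` fixes the TSS anchor: 0-based index i maps to position
    i - upstream (skipping 0).  Every k-window is tested literally, so
    overlapping and nested matches are all reported; windows with N never
    match (N is not in any expansion).
    """
    k = motif.length
    fwd = motif.forward_variants
    hits: list[MotifHit] = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        pos = index_to_pos(i, upstream)
        if w in fwd:
            hits.append(MotifHit(pos, "+", w, species, isoform_id, motif.pattern))
        if reverse_complement(w) in fwd:
            hits.append(MotifHit(pos, "-", reverse_complement(w), species, isoform_id, motif.pattern))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def scan_promoter(record: PromoterRecord, motif: DegenerateMotif | None = None) -> list[MotifHit]:
    """All WRE hits in one promoter record, sorted by (position, strand)."""
    motif = motif or DegenerateMotif()
    return scan_sequence(
        record.sequence, motif, record.upstream,
        species=record.species, isoform_id=record.isoform_id,
    )


@dataclass(frozen=True)
class SpeciesHit:
    """A per-species hit deduplicated over isoforms, with isoform provenance."""

    species: str
    position: int
    strand: str
    matched_seq: str
    pattern_id: str
    isoforms: tuple[str, ...]


def scan_species(
    records: Sequence[PromoterRecord], motif: DegenerateMotif | None = None
) -> dict[str, list[SpeciesHit]]:
    """Scan all isoforms of each species; dedupe hits by (position, strand).

    The union of hits over isoform variants is reported once per species
    with the contributing isoforms recorded as provenance.
    """
    if not records:
        raise ValueError("empty record set")
    motif = motif or DegenerateMotif()
    tables: dict[str, dict[tuple[int, str], tuple[str, list[str]]]] = {}
    for rec in records:
        per = tables.setdefault(rec.species, {})
        for h in scan_promoter(rec, motif):
            key = (h.position, h.strand)
            if key in per:
                per[key][1].append(rec.isoform_id)
            else:
                per[key] = (h.matched_seq, [rec.isoform_id])
    out: dict[str, list[SpeciesHit]] = {}
    for sp, per in tables.items():
        out[sp] = [
            SpeciesHit(sp, pos, strand, seq, motif.pattern, tuple(isos))
            for (pos, strand), (seq, isos) in sorted(per.items())
        ]
    return out


def hits_to_table(hits: Iterable[MotifHit | SpeciesHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        row = {
            "species": h.species,
            "position": h.position,
            "strand": h.strand,
            "matched_seq": h.matched_seq,
            "pattern_id": h.pattern_id,
        }
        if isinstance(h, SpeciesHit):
            row["isoform_id"] = ",".join(h.isoforms)
        else:
            row["isoform_id"] = h.isoform_id
        rows.append(row)
    cols = ["species", "isoform_id", "position", "strand", "matched_seq", "pattern_id"]
    return pd.DataFrame(rows, columns=cols)


def write_hit_table(tables: Mapping[str, Sequence[SpeciesHit]], path: str | Path) -> None:
    frames = [hits_to_table(hits) for hits in tables.values()]
    df = pd.concat(frames, ignore_index=True) if frames else hits_to_table([])
    df.to_csv(path, sep="\t", index=False)


def read_hit_table(path: str | Path) -> dict[str, list[SpeciesHit]]:
    df = pd.read_csv(path, sep="\t", dtype={"isoform_id": str})
    out: dict[str, list[SpeciesHit]] = {}
    for _, row in df.iterrows():
        isoforms = tuple(str(row["isoform_id"]).split(",")) if pd.notna(row["isoform_id"]) else ()
        out.setdefault(row["species"], []).append(
            SpeciesHit(row["species"], int(row["position"]), row["strand"],
                       row["matched_seq"], row["pattern_id"], isoforms)
        )
    return out
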