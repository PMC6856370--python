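"""Promoter sequence I/O and the TSS-relative coordinate model.

Every downstream stage (motif scanning, conservation calling, reporter
design) speaks the same coordinate language defined here:

* Promoters are stored 5'->3' in the gene's sense orientation.
* Positions are 1-based and TSS-relative with **no position 0**: a record
  with ``upstream = U`` and ``downstream = D`` has length ``U + D``, where
  string index ``1..U`` (1-based) maps to positions ``-U..-1`` and index
  ``U+1..U+D`` maps to ``+1..+D``.  Position -1 abuts +1.
* Bounds are inclusive, so the span -1635..+86 has length 1721.

Genomic strand extraction happens upstream of this package; the assembly
label is carried as metadata only, which keeps every stage
strand-unambiguous.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
GAP = "-"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class PromoterIOError(ValueError):
    """Malformed sequence data, metadata, or coordinates."""


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise PromoterIOError(f"illegal character(s) in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def pos_to_index(pos: int, upstream: int) -> int:
    """Convert a signed TSS-relative position to a 0-based string index."""
    if pos == 0:
        raise PromoterIOError("position 0 does not exist (-1 abuts +1)")
    return upstream + pos if pos < 0 else upstream + pos - 1


def index_to_pos(idx: int, upstream: int) -> int:
    """Convert a 0-based string index back to a signed TSS-relative position."""
    return idx - upstream if idx < upstream else idx - upstream + 1


def span_length(from_pos: int, to_pos: int) -> int:
    """Inclusive length of from_pos..to_pos under the no-zero convention."""
    if from_pos == 0 or to_pos == 0:
        raise PromoterIOError("position 0 does not exist (-1 abuts +1)")
    if from_pos > to_pos:
        raise PromoterIOError(f"empty window: {from_pos}..{to_pos}")
    if (from_pos < 0) == (to_pos < 0):
        return to_pos - from_pos + 1
    return to_pos - from_pos  # zero skipped


@dataclass(frozen=True)
class PromoterRecord:
    """One species/isoform promoter window anchored at a TSS.

    ``sequence`` is written 5'->3' in the gene's sense orientation and must
    have length ``upstream + downstream``.
    """

    species: str
    gene: str
    isoform_id: str
    upstream: int
    downstream: int
    sequence: str
    assembly: str = ""

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise PromoterIOError("upstream and downstream must be >= 0")
        if self.upstream + self.downstream < 1:
            raise PromoterIOError("upstream + downstream must be >= 1")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise PromoterIOError(
                f"illegal character(s) in {self.species}/{self.isoform_id}: {sorted(bad)}"
            )
        expected = self.upstream + self.downstream
        if len(seq) != expected:
            raise PromoterIOError(
                f"length mismatch for {self.species}/{self.isoform_id}: "
                f"sequence has {len(seq)} nt but U+D = {expected}"
            )

    @property
    def record_id(self) -> str:
        return f"{self.species}|{self.gene}|{self.isoform_id}"

    def window(self, from_pos: int, to_pos: int) -> str:
        return extract_window(self, from_pos, to_pos)


def extract_window(record: PromoterRecord, from_pos: int, to_pos: int) -> str:
    """Inclusive TSS-relative slice of a promoter record.

    Both bounds are signed positions (never 0); the returned length is
    ``to_pos - from_pos + 1`` when the bounds share a sign and
    ``to_pos - from_pos`` when the window spans the TSS.
    """
    n = span_length(from_pos, to_pos)  # validates ordering and no-zero
    if from_pos < -record.upstream or to_pos > record.downstream:
        raise PromoterIOError(
            f"window {from_pos}..{to_pos} outside record "
            f"(-{record.upstream}..+{record.downstream})"
        )
    start = pos_to_index(from_pos, record.upstream)
    return record.sequence[start : start + n]


@dataclass(frozen=True)
class AlignedPromoterSet:
    """A gapped alignment of one promoter per species.

    ``members`` maps species -> gapped string over {A,C,G,T,N,-}; all
    members share the same number of columns.  ``upstream`` optionally maps
    species -> U so TSS-relative hit positions can be projected into
    alignment columns; when absent, D = 0 is assumed (U = ungapped length).
    """

    members: Mapping[str, str]
    upstream: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise PromoterIOError("alignment has no members")
        members = {sp: s.upper() for sp, s in self.members.items()}
        object.__setattr__(self, "members", members)
        lengths = {len(s) for s in members.values()}
        if len(lengths) != 1:
            raise PromoterIOError(f"unequal alignment lengths: {sorted(lengths)}")
        allowed = DNA_ALPHABET | {GAP}
        for sp, s in members.items():
            bad = set(s) - allowed
            if bad:
                raise PromoterIOError(f"illegal character(s) in {sp}: {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.members.values())))

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.members)

    def degapped(self, species: str) -> str:
        return self.members[species].replace(GAP, "")

    def upstream_of(self, species: str) -> int:
        if self.upstream is not None and species in self.upstream:
            return self.upstream[species]
        return len(self.degapped(species))

    @classmethod
    def from_fasta(cls, path: str | Path, upstream: Mapping[str, int] | None = None) -> "AlignedPromoterSet":
        members = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            species = rec.id.split("|")[0]
            members[species] = str(rec.seq).upper()
        if not members:
            raise PromoterIOError(f"no records in alignment {path}")
        return cls(members=members, upstream=upstream)

    def to_fasta(self, path: str | Path) -> None:
        recs = [
            SeqRecord(Seq(s), id=sp, description="")
            for sp, s in self.members.items()
        ]
        SeqIO.write(recs, str(path), "fasta")


MANIFEST_FIELDS = ("record_id", "species", "gene", "assembly", "isoform_id", "upstream", "downstream")


def read_manifest(path: str | Path) -> dict[str, dict]:
    """Read the TSV metadata sidecar, keyed by FASTA record id."""
    out: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(MANIFEST_FIELDS) - set(reader.fieldnames or ())
        if missing:
            raise PromoterIOError(f"manifest missing columns: {sorted(missing)}")
        for row in reader:
            out[row["record_id"]] = {
                "species": row["species"],
                "gene": row["gene"],
                "assembly": row["assembly"],
                "isoform_id": row["isoform_id"],
                "upstream": int(row["upstream"]),
                "downstream": int(row["downstream"]),
            }
    return out


def _parse_header(header: str) -> dict:
    """Parse 'species|gene|isoform[|assembly]|U=5000|D=0' style headers."""
    positional: list[str] = []
    kv: dict[str, str] = {}
    for tok in header.split("|"):
        if "=" in tok:
            k, v = tok.split("=", 1)
            kv[k.strip().upper()] = v.strip()
        else:
            positional.append(tok.strip())
    if len(positional) < 3 or "U" not in kv or "D" not in kv:
        raise PromoterIOError(
            f"cannot parse header {header!r}: expected species|gene|isoform[|assembly]|U=..|D=.."
        )
    return {
        "species": positional[0],
        "gene": positional[1],
        "isoform_id": positional[2],
        "assembly": positional[3] if len(positional) > 3 else "",
        "upstream": int(kv["U"]),
        "downstream": int(kv["D"]),
    }


def read_promoter_fasta(
    path: str | Path, manifest: str | Path | Mapping[str, dict] | None = None
) -> list[PromoterRecord]:
    """Read promoters from FASTA with metadata in headers or a TSV manifest.

    With no manifest, headers must encode the metadata
    (``species|gene|isoform[|assembly]|U=..|D=..``); with a manifest, FASTA
    record ids are looked up in it.  Records whose length differs from
    U + D are rejected.
    """
    if manifest is not None and not isinstance(manifest, Mapping):
        manifest = read_manifest(manifest)
    records: list[PromoterRecord] = []
    seen_any = False
    for rec in SeqIO.parse(str(path), "fasta"):
        seen_any = True
        if manifest is not None:
            if rec.id not in manifest:
                raise PromoterIOError(f"record {rec.id!r} absent from manifest")
            meta = manifest[rec.id]
        else:
            meta = _parse_header(rec.description or rec.id)
        records.append(PromoterRecord(sequence=str(rec.seq), **meta))
    if not seen_any:
        raise PromoterIOError(f"no FASTA records in {path}")
    return records


def write_promoter_fasta(
    records: Sequence[PromoterRecord],
    path: str | Path,
    manifest_path: str | Path | None = None,
) -> None:
    """Write promoters as FASTA (metadata-encoding headers) plus optional manifest."""
    seqs = []
    for r in records:
        header = f"{r.species}|{r.gene}|{r.isoform_id}"
        if r.assembly:
            header += f"|{r.assembly}"
        header += f"|U={r.upstream}|D={r.downstream}"
        seqs.append(SeqRecord(Seq(r.sequence), id=header, description=""))
    SeqIO.write(seqs, str(path), "fasta")
    if manifest_path is not None:
        with open(manifest_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(MANIFEST_FIELDS)
            for r in records:
                rid = f"{r.species}|{r.gene}|{r.isoform_id}"
                if r.assembly:
                    rid += f"|{r.assembly}"
                rid += f"|U={r.upstream}|D={r.downstream}"
                w.writerow([rid, r.species, r.gene, r.assembly, r.isoform_id, r.upstream, r.downstream])


def group_by_species(records: Iterable[PromoterRecord]) -> dict[str, list[PromoterRecord]]:
    out: dict[str, list[PromoterRecord]] = {}
    for r in records:
        out.setdefault(r.species, []).append(r)
    return out
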