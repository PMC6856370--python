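"""WT / site-mutant promoter reporter insert design.

Models the sequence side of a dual-luciferase promoter assay: a promoter
fragment (e.g. -1635..+86 of a TSS, 1721 bases) is extracted as the
wild-type insert, and a mutant insert is produced by replacing one
TCF/LEF 7-mer (e.g. TTCAAAG at -1587) with a non-binding 7-mer (CCGCGGT).
Both inserts are re-scanned so the design carries proof that the edit
removes exactly the intended site and nothing else.  Site positions anchor
the 7-mer's leftmost base, the same convention the scanner uses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .promoter_io import (
    PromoterIOError,
    PromoterRecord,
    extract_window,
    reverse_complement,
    span_length,
)
from .wre_scan import DegenerateMotif, MotifHit, scan_sequence


class ReporterDesignError(ValueError):
    pass


def window_offset(from_pos: int, pos: int) -> int:
    """0-based offset of TSS-relative ``pos`` within a window starting at ``from_pos``."""
    if from_pos == 0 or pos == 0:
        raise PromoterIOError("position 0 does not exist")
    if pos < from_pos:
        raise ReporterDesignError(f"position {pos} upstream of window start {from_pos}")
    return span_length(from_pos, pos) - 1


@dataclass(frozen=True)
class ReporterConstruct:
    """A WT + mutant reporter insert pair with the edit record and hit lists."""

    name: str
    window: tuple[int, int]
    wt_seq: str
    mut_seq: str
    edit: tuple[int, str, str]  # (site_pos, wt_7mer, replacement_7mer)
    wt_hits: tuple[MotifHit, ...] = ()
    mut_hits: tuple[MotifHit, ...] = ()

    @property
    def window_length(self) -> int:
        return span_length(*self.window)


def design_reporter(
    record: PromoterRecord,
    window: tuple[int, int],
    site_pos: int,
    replacement: str,
    motif: DegenerateMotif | None = None,
    name: str | None = None,
) -> ReporterConstruct:
    """Extract the WT insert and substitute the motif 7-mer at ``site_pos``.

    Refuses to "mutate" a position that does not carry a motif match on
    either strand, and refuses a no-op replacement; a replacement that
    itself matches the motif triggers a warning (the mutant would still
    bind).  Both inserts are scanned and the hits attached.
    """
    motif = motif or DegenerateMotif()
    k = motif.length
    replacement = replacement.upper()
    if len(replacement) != k:
        raise ReporterDesignError(f"replacement must be {k} nt, got {len(replacement)}")
    wt_seq = extract_window(record, *window)
    off = window_offset(window[0], site_pos)
    if off + k > len(wt_seq):
        raise ReporterDesignError(
            f"site at {site_pos} extends past window end {window[1]}"
        )
    wt_7mer = wt_seq[off : off + k]
    if not motif.matches(wt_7mer):
        raise ReporterDesignError(
            f"no motif match at {site_pos}: found {wt_7mer!r}, refusing to mutate a non-site"
        )
    if replacement == wt_7mer:
        raise ReporterDesignError("no-op replacement (mutant identical to WT)")
    if motif.matches(replacement):
        warnings.warn(
            f"replacement {replacement} still matches {motif.pattern} on one strand",
            stacklevel=2,
        )
    mut_seq = wt_seq[:off] + replacement + wt_seq[off + k :]
    # scan both inserts in window coordinates (upstream part of the window)
    ups = -window[0] if window[0] < 0 else 0
    wt_hits = tuple(scan_sequence(wt_seq, motif, ups, species=record.species))
    mut_hits = tuple(scan_sequence(mut_seq, motif, ups, species=record.species))
    return ReporterConstruct(
        name=name or f"{record.gene}_{record.species}_{site_pos}",
        window=tuple(window),
        wt_seq=wt_seq,
        mut_seq=mut_seq,
        edit=(site_pos, wt_7mer, replacement),
        wt_hits=wt_hits,
        mut_hits=mut_hits,
    )


@dataclass
class ValidationReport:
    ok: bool
    hits_lost_at: list[int]
    hits_gained_at: list[int]
    hamming: int
    failures: list[str] = field(default_factory=list)


def validate_construct(c: ReporterConstruct, motif: DegenerateMotif | None = None) -> ValidationReport:
    """Check the WT/mutant pair invariants; failures become report entries.

    Verifies equal lengths, that the two inserts differ only inside the
    edited 7-mer, that the WT 7-mer matches the motif while the replacement
    does not, and that the Hamming distance equals the positions changed
    within the 7-mer.  Hit differences between WT and mutant are listed.
    """
    motif = motif or DegenerateMotif()
    k = motif.length
    failures: list[str] = []
    site_pos, wt_7mer, repl = c.edit
    if len(c.wt_seq) != len(c.mut_seq):
        failures.append("wt and mut inserts differ in length")
    expected_len = span_length(*c.window)
    if len(c.wt_seq) != expected_len:
        failures.append(f"insert length {len(c.wt_seq)} != window length {expected_len}")
    try:
        off = window_offset(c.window[0], site_pos)
    except (ReporterDesignError, PromoterIOError):
        off = None
        failures.append(f"edit site {site_pos} outside window {c.window}")
    hamming = 0
    if off is not None and len(c.wt_seq) == len(c.mut_seq):
        if off + k > len(c.wt_seq):
            failures.append(f"edit site {site_pos} extends past window end")
        else:
            diffs_outside = [
                i for i, (a, b) in enumerate(zip(c.wt_seq, c.mut_seq))
                if a != b and not (off <= i < off + k)
            ]
            if diffs_outside:
                failures.append(f"wt/mut differ outside the edited 7-mer at offsets {diffs_outside}")
            hamming = sum(a != b for a, b in zip(c.wt_seq[off:off + k], c.mut_seq[off:off + k]))
            if hamming == 0:
                failures.append("wt and mut identical at the edit site (no-op)")
            if c.wt_seq[off:off + k] != wt_7mer:
                failures.append("recorded wt 7-mer does not match insert")
            if c.mut_seq[off:off + k] != repl:
                failures.append("recorded replacement does not match mutant insert")
    if not motif.matches(wt_7mer):
        failures.append(f"wt 7-mer {wt_7mer} does not match motif {motif.pattern}")
    if motif.matches(repl):
        failures.append(f"replacement {repl} still matches motif {motif.pattern}")
    wt_keys = {(h.position, h.strand) for h in c.wt_hits}
    mut_keys = {(h.position, h.strand) for h in c.mut_hits}
    lost = sorted({p for p, _ in wt_keys - mut_keys})
    gained = sorted({p for p, _ in mut_keys - wt_keys})
    return ValidationReport(
        ok=not failures,
        hits_lost_at=lost,
        hits_gained_at=gained,
        hamming=hamming,
        failures=failures,
    )


def write_construct(c: ReporterConstruct, fasta_path: str | Path, edit_json_path: str | Path) -> None:
    """Write the WT/mut inserts as FASTA and the edit record as JSON."""
    recs = [
        SeqRecord(Seq(c.wt_seq), id=f"{c.name}|WT", description=""),
        SeqRecord(Seq(c.mut_seq), id=f"{c.name}|Mut", description=""),
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")
    payload = {
        "name": c.name,
        "window": list(c.window),
        "window_length": c.window_length,
        "site_pos": c.edit[0],
        "wt_7mer": c.edit[1],
        "replacement_7mer": c.edit[2],
        "wt_hit_positions": [h.position for h in c.wt_hits],
        "mut_hit_positions": [h.position for h in c.mut_hits],
    }
    Path(edit_json_path).write_text(json.dumps(payload, indent=2) + "\n")
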