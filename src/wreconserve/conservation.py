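"""Cross-species conserved-site calling in alignment (or position) space.

Per-species motif hits are projected into the columns of a supplied gapped
promoter alignment and clustered by single linkage on overlapping column
intervals; a cluster is called *conserved* when at least ``m`` species
contribute a hit (default: all but one, the criterion under which a site
retained in four of five vertebrates — e.g. lost only in rat — is still
conserved).  Strand is ignored for the conservation call itself (a site may
sit on opposite strands in different species) but is recorded per member.

When no alignment is available, :func:`positional_fallback` clusters hits
whose TSS-relative positions agree within a tolerance instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .promoter_io import AlignedPromoterSet, GAP, PromoterIOError, pos_to_index
from .wre_scan import SpeciesHit


@dataclass(frozen=True)
class ClusterMember:
    hit: SpeciesHit
    start_col: int
    end_col: int


@dataclass(frozen=True)
class ConservedSiteCluster:
    """One connected component of overlapping cross-species site intervals."""

    cluster_id: int
    start_col: int
    end_col: int
    members: Mapping[str, ClusterMember]  # at most one per species
    present_species: frozenset[str]
    absent_species: frozenset[str]
    conserved: bool
    all_hits: tuple[ClusterMember, ...]  # every hit assigned to this component

    @property
    def n_species_present(self) -> int:
        return len(self.present_species)

    @property
    def representative_position(self) -> dict[str, int]:
        return {sp: m.hit.position for sp, m in self.members.items()}


def map_hit_to_columns(hit: SpeciesHit, aligned: AlignedPromoterSet) -> tuple[int, int]:
    """Columns (1-based) of a hit's first and last ungapped bases.

    The hit's TSS-relative position is converted to an ungapped base index
    using the species' upstream length, then walked through the gapped
    member string.  With internal gaps the interval is wider than the motif.
    """
    if hit.species not in aligned.members:
        raise PromoterIOError(f"species {hit.species!r} not in alignment")
    gapped = aligned.members[hit.species]
    upstream = aligned.upstream_of(hit.species)
    k = len(hit.matched_seq)
    first_idx = pos_to_index(hit.position, upstream)  # 0-based ungapped
    last_idx = first_idx + k - 1
    ungapped_len = len(gapped) - gapped.count(GAP)
    if first_idx < 0 or last_idx >= ungapped_len:
        raise PromoterIOError(
            f"hit at {hit.position} ({hit.species}) outside aligned span"
        )
    start_col = end_col = None
    seen = -1
    for col0, ch in enumerate(gapped):
        if ch == GAP:
            continue
        seen += 1
        if seen == first_idx:
            start_col = col0 + 1
        if seen == last_idx:
            end_col = col0 + 1
            break
    assert start_col is not None and end_col is not None
    return start_col, end_col


def _connected_components(intervals: list[tuple[int, int]]) -> list[list[int]]:
    """Single-linkage components of inclusive-overlapping intervals."""
    order = sorted(range(len(intervals)), key=lambda i: intervals[i])
    components: list[list[int]] = []
    cur: list[int] = []
    cur_end = None
    for i in order:
        s, e = intervals[i]
        if cur and s <= cur_end:
            cur.append(i)
            cur_end = max(cur_end, e)
        else:
            if cur:
                components.append(cur)
            cur, cur_end = [i], e
    if cur:
        components.append(cur)
    return components


def _build_clusters(
    flat: list[tuple[SpeciesHit, int, int]],
    all_species: Sequence[str],
    m: int,
) -> list[ConservedSiteCluster]:
    intervals = [(s, e) for _, s, e in flat]
    clusters: list[ConservedSiteCluster] = []
    for cid, comp in enumerate(_connected_components(intervals), start=1):
        members_all = tuple(ClusterMember(flat[i][0], flat[i][1], flat[i][2]) for i in sorted(comp))
        start_col = min(cm.start_col for cm in members_all)
        end_col = max(cm.end_col for cm in members_all)
        # one hit per species: largest column overlap with the other species'
        # intervals wins; ties broken by smaller position
        by_species: dict[str, list[ClusterMember]] = {}
        for cm in members_all:
            by_species.setdefault(cm.hit.species, []).append(cm)
        chosen: dict[str, ClusterMember] = {}
        for sp, cms in by_species.items():
            if len(cms) == 1:
                chosen[sp] = cms[0]
                continue
            other_cols: set[int] = set()
            for cm in members_all:
                if cm.hit.species != sp:
                    other_cols.update(range(cm.start_col, cm.end_col + 1))
            def overlap(cm: ClusterMember) -> int:
                return len(other_cols & set(range(cm.start_col, cm.end_col + 1)))
            chosen[sp] = min(cms, key=lambda cm: (-overlap(cm), cm.hit.position))
        present = frozenset(chosen)
        absent = frozenset(all_species) - present
        clusters.append(
            ConservedSiteCluster(
                cluster_id=cid,
                start_col=start_col,
                end_col=end_col,
                members=chosen,
                present_species=present,
                absent_species=absent,
                conserved=len(present) >= m,
                all_hits=members_all,
            )
        )
    clusters.sort(key=lambda c: c.start_col)
    return [
        ConservedSiteCluster(cluster_id=i + 1, start_col=c.start_col, end_col=c.end_col,
                             members=c.members, present_species=c.present_species,
                             absent_species=c.absent_species, conserved=c.conserved,
                             all_hits=c.all_hits)
        for i, c in enumerate(clusters)
    ]


def call_conserved(
    hit_tables: Mapping[str, Sequence[SpeciesHit]],
    aligned: AlignedPromoterSet,
    m: int | None = None,
) -> list[ConservedSiteCluster]:
    """Cluster per-species hits by overlapping alignment-column intervals.

    ``m`` is the minimum number of species required for the conserved flag;
    the default is ``n_species - 1``.
    """
    all_species = aligned.species
    unknown = set(hit_tables) - set(all_species)
    if unknown:
        raise PromoterIOError(f"hit tables name species absent from alignment: {sorted(unknown)}")
    if m is None:
        m = len(all_species) - 1
    if m < 2:
        raise ValueError("minimum species m must be >= 2")
    flat: list[tuple[SpeciesHit, int, int]] = []
    for sp, hits in hit_tables.items():
        for h in hits:
            s, e = map_hit_to_columns(h, aligned)
            flat.append((h, s, e))
    return _build_clusters(flat, all_species, m)


def positional_fallback(
    hit_tables: Mapping[str, Sequence[SpeciesHit]],
    tolerance_w: int,
    m: int | None = None,
    all_species: Sequence[str] | None = None,
) -> list[ConservedSiteCluster]:
    """Alignment-free clustering: hits within ``tolerance_w`` bases are linked.

    Column fields hold TSS-relative positions instead of alignment columns.
    Single linkage is applied on |pos_i - pos_j| <= w, realized by padding
    each hit's position interval by w/2 on each side (w even) or by
    clustering positions whose gaps are <= w (exact for point positions).
    """
    if tolerance_w < 0:
        raise ValueError("tolerance must be >= 0")
    if all_species is None:
        all_species = sorted(hit_tables)
    if m is None:
        m = len(all_species) - 1
    if m < 2:
        raise ValueError("minimum species m must be >= 2")
    flat: list[tuple[SpeciesHit, int, int]] = []
    for sp, hits in hit_tables.items():
        for h in hits:
            flat.append((h, h.position, h.position))
    # link positions p, q when |p - q| <= w: widen right ends by w
    widened = [(h, s, e + tolerance_w) for h, s, e in flat]
    clusters = _build_clusters(widened, all_species, m)
    # report un-widened position extents
    fixed = []
    for c in clusters:
        members = {sp: ClusterMember(cm.hit, cm.hit.position, cm.hit.position)
                   for sp, cm in c.members.items()}
        all_hits = tuple(ClusterMember(cm.hit, cm.hit.position, cm.hit.position)
                         for cm in c.all_hits)
        fixed.append(ConservedSiteCluster(
            cluster_id=c.cluster_id,
            start_col=min(cm.start_col for cm in all_hits),
            end_col=max(cm.end_col for cm in all_hits),
            members=members, present_species=c.present_species,
            absent_species=c.absent_species, conserved=c.conserved,
            all_hits=all_hits,
        ))
    return fixed


def clusters_to_table(clusters: Sequence[ConservedSiteCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        for sp in sorted(c.present_species | c.absent_species):
            cm = c.members.get(sp)
            rows.append({
                "cluster_id": c.cluster_id,
                "start_col": c.start_col,
                "end_col": c.end_col,
                "n_species_present": c.n_species_present,
                "conserved": c.conserved,
                "species": sp,
                "present": sp in c.present_species,
                "position": cm.hit.position if cm else "",
                "strand": cm.hit.strand if cm else "",
                "matched_seq": cm.hit.matched_seq if cm else "",
            })
    cols = ["cluster_id", "start_col", "end_col", "n_species_present", "conserved",
            "species", "present", "position", "strand", "matched_seq"]
    return pd.DataFrame(rows, columns=cols)


def write_cluster_table(clusters: Sequence[ConservedSiteCluster], path: str | Path) -> None:
    clusters_to_table(clusters).to_csv(path, sep="\t", index=False)
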