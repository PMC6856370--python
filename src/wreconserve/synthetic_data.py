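"""Synthetic promoter/exon evolution with known ground truth.

Generates the inputs the pipeline normally gets from genome browsers:
TSS-anchored promoter windows for a set of species related by a known tree,
with TCF/LEF (WRE) sites planted at orthologous TSS-relative positions and
retained or lost per species.  Because the simulation is indel-free, the
true alignment is the identity alignment and is emitted alongside, so every
stage (scan, conservation call, distances, NJ) can be tested against an
exact truth without any downloads.

The process: the root sequence is drawn iid uniform over {A,C,G,T}; each
site evolves independently down the tree under a reversible substitution
model (JC or TN93) with per-branch transition matrices ``expm(Q t)``;
planted sites are then overwritten — a WRE 7-mer in retaining species, a
non-matching 7-mer (default CCGCGGT) in losing species — so ground-truth
recovery is deterministic ("frozen" sites).  A decaying mode (no overwrite
in retaining species) is available for power exploration.  By default,
chance WRE matches arising in the background are scrubbed (one core base
mutated) so the planted registry is the complete truth; keep them to study
false-cluster rates.

Defaults model the five-vertebrate study design: human, mouse, rat,
chicken, zebrafish; 5-kb upstream windows (U=5000, D=0); one TTCAAAG site
at -1413 retained everywhere except rat.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from scipy.linalg import expm

from .phylo import BASES, PhyloTree, parse_newick, tn93_rate_matrix
from .promoter_io import AlignedPromoterSet, PromoterRecord
from .wre_scan import DegenerateMotif, scan_sequence

DEFAULT_SPECIES = ("human", "mouse", "rat", "chicken", "zebrafish")

# Fixed five-vertebrate working topology with promoter-scale divergences
# (substitutions/site): mammals close, chicken farther, zebrafish outgroup.
DEFAULT_TREE_NEWICK = (
    "(((human:0.08,(mouse:0.06,rat:0.06):0.04):0.12,chicken:0.35):0.15,"
    "zebrafish:0.50);"
)

NONBINDING_7MER = "CCGCGGT"


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible nucleotide model: JC or TN93(kappa1, kappa2, freqs)."""

    name: str = "JC"
    kappa1: float = 1.0
    kappa2: float = 1.0
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def rate_matrix(self) -> np.ndarray:
        if self.name.upper() == "JC":
            return tn93_rate_matrix(1.0, 1.0, (0.25, 0.25, 0.25, 0.25))
        if self.name.upper() == "TN93":
            return tn93_rate_matrix(self.kappa1, self.kappa2, self.freqs)
        raise ValueError(f"unknown substitution model {self.name!r}")

    def stationary(self) -> np.ndarray:
        if self.name.upper() == "JC":
            return np.full(4, 0.25)
        f = np.asarray(self.freqs, dtype=float)
        return f / f.sum()

    def describe(self) -> dict:
        return {"name": self.name, "kappa1": self.kappa1, "kappa2": self.kappa2,
                "freqs": list(self.stationary())}


@dataclass(frozen=True)
class PlantedSite:
    """One orthologous site: position of its leftmost base (TSS-relative),
    which species retain a motif 7-mer and which carry the non-binding one."""

    position: int
    retained: frozenset[str]
    lost: frozenset[str]
    motif_7mer: str = "TTCAAAG"
    loss_7mer: str = NONBINDING_7MER


@dataclass
class SimulationTruth:
    """Ground-truth registry for one simulated data set."""

    tree_newick: str
    seed: int
    planted_sites: list[PlantedSite]
    model: dict
    length: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tree_newick": self.tree_newick,
            "seed": self.seed,
            "length": self.length,
            "model": self.model,
            "planted_sites": [
                {
                    "position": s.position,
                    "retained": sorted(s.retained),
                    "lost": sorted(s.lost),
                    "motif_7mer": s.motif_7mer,
                    "loss_7mer": s.loss_7mer,
                }
                for s in self.planted_sites
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _as_tree(tree: PhyloTree | str | None) -> PhyloTree:
    if tree is None:
        return parse_newick(DEFAULT_TREE_NEWICK)
    if isinstance(tree, str):
        return parse_newick(tree)
    return tree


def _evolve(ptree: PhyloTree, length: int, model: SubstitutionModel,
            rng: np.random.Generator,
            root_plant: dict[int, str] | None = None) -> dict[str, np.ndarray]:
    """Evolve iid sites from the seed node down; returns leaf base-index arrays.

    ``root_plant`` maps 0-based offsets to literal strings written into the
    root before evolution (used by the decaying-site mode).
    """
    Q = model.rate_matrix()
    pi = model.stationary()
    root_seq = rng.choice(4, size=length, p=pi)
    if root_plant:
        for off, lit in root_plant.items():
            root_seq[off : off + len(lit)] = [BASES.index(c) for c in lit]
    leaf_seqs: dict[str, np.ndarray] = {}
    stack = [(ptree.tree.seed_node, root_seq)]
    while stack:
        node, seq = stack.pop()
        if node.is_leaf():
            leaf_seqs[node.taxon.label] = seq
            continue
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            if t == 0.0:
                child_seq = seq.copy()
            else:
                P = expm(Q * t)
                # cumulative inverse sampling per parent base
                cum = np.cumsum(P, axis=1)
                u = rng.random(length)
                child_seq = (u[:, None] > cum[seq]).sum(axis=1)
            stack.append((child, child_seq))
    return leaf_seqs


def _indices_to_str(arr: np.ndarray) -> str:
    return "".join(BASES[i] for i in arr)


def _scrub_background(seq: str, motif: DegenerateMotif, protected: set[int],
                      upstream: int, rng: np.random.Generator) -> str:
    """Destroy chance motif matches outside protected offsets.

    For each non-protected match, an invariant core base (the C of WWCAAAG
    on the forward strand, the G of its reverse complement) is replaced by
    a random different base; rescanned until no background match remains.
    The random choice avoids deterministic flip cycles in which destroying
    a match on one strand keeps re-creating one on the other.
    """
    s = list(seq)
    k = motif.length
    for _ in range(100 * (len(seq) // k + 1)):
        hits = scan_sequence("".join(s), motif, upstream)
        background = [h for h in hits
                      if not any(off - k < _off_of(h.position, upstream) < off + k
                                 for off in protected)]
        if not background:
            return "".join(s)
        h = background[0]
        i = _off_of(h.position, upstream)
        core = i + 2 if h.strand == "+" else i + 4
        choices = [b for b in BASES if b != s[core]]
        s[core] = choices[rng.integers(3)]
    raise RuntimeError("background scrubbing did not converge")


def _off_of(position: int, upstream: int) -> int:
    return upstream + position if position < 0 else upstream + position - 1


def simulate_promoters(
    tree: PhyloTree | str | None = None,
    length: int = 5000,
    model: SubstitutionModel | None = None,
    planted_sites: Sequence[PlantedSite] | None = None,
    seed: int = 0,
    gene: str = "WNT3A",
    n_isoforms: int = 1,
    freeze_planted: bool = True,
    scrub_background: bool = True,
) -> tuple[list[PromoterRecord], AlignedPromoterSet, SimulationTruth]:
    """Simulate TSS-anchored promoters for all leaves of a species tree.

    Returns the promoter records (``n_isoforms`` duplicates per species),
    the identity alignment (indel-free simulation), and the ground-truth
    registry.  Fully reproducible from ``seed``.
    """
    ptree = _as_tree(tree)
    model = model or SubstitutionModel("JC")
    rng = np.random.default_rng(seed)
    species = ptree.taxa
    if planted_sites is None:
        planted_sites = [PlantedSite(
            position=-1413,
            retained=frozenset(sp for sp in species if sp != "rat"),
            lost=frozenset({"rat"} if "rat" in species else {species[-1]}),
        )]
    upstream = length  # windows are upstream-only (D = 0)
    k = 7
    offsets = sorted(_off_of(s.position, upstream) for s in planted_sites)
    for a, b in zip(offsets, offsets[1:]):
        if b - a < k:
            raise ValueError("planted sites overlap (must be >= 7 bases apart)")
    for s in planted_sites:
        off = _off_of(s.position, upstream)
        if off < 0 or off + k > length:
            raise ValueError(f"planted site at {s.position} outside the window")
        union = s.retained | s.lost
        if union != set(species) or (s.retained & s.lost):
            raise ValueError("retained/lost must partition the species set")

    root_plant = None
    if not freeze_planted:
        # decaying mode: the site exists at the root and erodes down the tree
        root_plant = {_off_of(s.position, upstream): s.motif_7mer
                      for s in planted_sites}
    leaf_idx = _evolve(ptree, length, model, rng, root_plant=root_plant)
    motif = DegenerateMotif()
    protected = {_off_of(s.position, upstream) for s in planted_sites}
    sequences: dict[str, str] = {}
    for sp in species:
        seq = _indices_to_str(leaf_idx[sp])
        if scrub_background:
            seq = _scrub_background(seq, motif, protected, upstream, rng)
        s = list(seq)
        for site in planted_sites:
            off = _off_of(site.position, upstream)
            if sp in site.lost:
                s[off : off + k] = site.loss_7mer
            elif freeze_planted:
                s[off : off + k] = site.motif_7mer
        sequences[sp] = "".join(s)

    records = [
        PromoterRecord(species=sp, gene=gene, isoform_id=f"iso{i + 1}",
                       upstream=upstream, downstream=0, sequence=sequences[sp])
        for sp in species
        for i in range(n_isoforms)
    ]
    aligned = AlignedPromoterSet(members=sequences,
                                 upstream={sp: upstream for sp in species})
    truth = SimulationTruth(
        tree_newick=ptree.tree.as_string(schema="newick").strip(),
        seed=seed,
        planted_sites=list(planted_sites),
        model=model.describe(),
        length=length,
    )
    return records, aligned, truth


def simulate_exons(
    tree: PhyloTree | str | None = None,
    length: int = 2000,
    model: SubstitutionModel | None = None,
    seed: int = 0,
    mask_n_fraction: float = 0.0,
    gap_column_fraction: float = 0.0,
) -> tuple[AlignedPromoterSet, SimulationTruth]:
    """Simulate an aligned exon set (no planting) for tree-building tests.

    ``mask_n_fraction`` masks random cells to N; ``gap_column_fraction``
    turns random columns into gap-containing columns (one random species
    gapped), exercising complete deletion.
    """
    ptree = _as_tree(tree)
    model = model or SubstitutionModel("JC")
    rng = np.random.default_rng(seed)
    leaf_idx = _evolve(ptree, length, model, rng)
    species = ptree.taxa
    seqs = {sp: list(_indices_to_str(leaf_idx[sp])) for sp in species}
    n_gap_cols = int(round(gap_column_fraction * length))
    gap_cols = rng.choice(length, size=n_gap_cols, replace=False) if n_gap_cols else []
    for col in gap_cols:
        sp = species[rng.integers(len(species))]
        seqs[sp][col] = "-"
    if mask_n_fraction > 0:
        for sp in species:
            n_mask = int(round(mask_n_fraction * length))
            cols = rng.choice(length, size=n_mask, replace=False)
            for col in cols:
                if seqs[sp][col] != "-":
                    seqs[sp][col] = "N"
    aligned = AlignedPromoterSet(members={sp: "".join(s) for sp, s in seqs.items()})
    truth = SimulationTruth(
        tree_newick=ptree.tree.as_string(schema="newick").strip(),
        seed=seed,
        planted_sites=[],
        model=model.describe(),
        length=length,
    )
    return aligned, truth
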