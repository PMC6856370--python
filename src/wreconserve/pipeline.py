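"""End-to-end orchestration: scan -> conserve -> tree -> design.

A run is a pure function of (inputs, config, seed).  Each stage writes a
plain-text artifact into the run directory and the run manifest records a
hash over the config and every output, so re-running the same configuration
yields the identical manifest hash.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__
from .conservation import call_conserved, positional_fallback, write_cluster_table
from .phylo import complete_deletion, nj_tree, pairwise_distances, write_newick
from .promoter_io import AlignedPromoterSet, read_promoter_fasta, write_promoter_fasta
from .reporter_design import design_reporter, validate_construct, write_construct
from .synthetic_data import (
    DEFAULT_TREE_NEWICK,
    PlantedSite,
    SubstitutionModel,
    simulate_exons,
    simulate_promoters,
)
from .wre_scan import DegenerateMotif, scan_species, write_hit_table


class SpeciesSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    species: str
    gene: str = "WNT3A"
    assembly: str = ""


class ReporterSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    species: str = "human"
    window: tuple[int, int] = (-1635, 86)
    site_pos: int = -1587
    replacement: str = "CCGCGGT"


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    species: list[SpeciesSpec]
    pattern: str = "WWCAAAG"
    upstream: int = 5000
    downstream: int = 0
    min_species: Optional[int] = None  # default: n_species - 1
    distance_model: str = "mcl-tn93"
    deletion: str = "complete"
    tolerance_w: int = 50  # positional fallback tolerance, bases
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if not self.species:
            raise ValueError("species table is empty")
        n = len(self.species)
        m = self.min_species if self.min_species is not None else n - 1
        if m > n:
            raise ValueError(f"min_species {m} exceeds n_species {n}")
        if m < 2:
            raise ValueError("min_species must be >= 2")
        if self.deletion != "complete":
            raise ValueError("only complete deletion is supported")
        return self

    @property
    def m(self) -> int:
        return self.min_species if self.min_species is not None else len(self.species) - 1

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    promoter_fasta: str | Path | None = None,
    manifest: str | Path | None = None,
    alignment: str | Path | None = None,
    exon_alignment: str | Path | None = None,
    reporter: ReporterSpec | None = None,
) -> Path:
    """Execute all stages; returns the run directory.

    With no promoter input, a synthetic data set (with its true alignment
    and exon set) is generated from ``config.seed``, so the pipeline is
    runnable end to end with zero external files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}
    stage = "inputs"
    try:
        t0 = time.perf_counter()
        synthetic = promoter_fasta is None
        if synthetic:
            records, aligned, truth = simulate_promoters(
                length=config.upstream, seed=config.seed,
                gene=config.species[0].gene,
            )
            write_promoter_fasta(records, out / "promoters.fasta",
                                 manifest_path=out / "promoters.manifest.tsv")
            aligned.to_fasta(out / "promoters.aligned.fasta")
            truth.to_json(out / "truth.json")
            exons, _ = simulate_exons(seed=config.seed + 1)
            exons.to_fasta(out / "exons.aligned.fasta")
        else:
            records = read_promoter_fasta(promoter_fasta, manifest)
            aligned = (AlignedPromoterSet.from_fasta(alignment)
                       if alignment is not None else None)
            exons = (AlignedPromoterSet.from_fasta(exon_alignment)
                     if exon_alignment is not None else None)
        counts["promoter_records"] = len(records)
        timings[stage] = time.perf_counter() - t0

        stage = "scan"
        t0 = time.perf_counter()
        motif = DegenerateMotif(config.pattern)
        tables = scan_species(records, motif)
        write_hit_table(tables, out / "hits.tsv")
        counts["hits"] = sum(len(v) for v in tables.values())
        timings[stage] = time.perf_counter() - t0

        stage = "conserve"
        t0 = time.perf_counter()
        if aligned is not None:
            clusters = call_conserved(tables, aligned, m=config.m)
        else:
            clusters = positional_fallback(tables, config.tolerance_w, m=config.m,
                                           all_species=[s.species for s in config.species])
        write_cluster_table(clusters, out / "conserved_sites.tsv")
        counts["clusters"] = len(clusters)
        counts["conserved_clusters"] = sum(c.conserved for c in clusters)
        timings[stage] = time.perf_counter() - t0

        stage = "tree"
        t0 = time.perf_counter()
        if exons is not None:
            filtered, usable = complete_deletion(exons)
            dm = pairwise_distances(filtered, model=config.distance_model)
            dm = type(dm)(taxa=dm.taxa, d=dm.d, usable_sites=usable,
                          saturated=dm.saturated)
            dm.to_tsv(out / "distances.tsv")
            ptree = nj_tree(dm)
            write_newick(ptree, out / "tree.nwk")
            counts["usable_sites"] = usable
            counts["sum_branch_lengths_millis"] = int(round(ptree.sum_branch_lengths * 1000))
        timings[stage] = time.perf_counter() - t0

        stage = "design"
        t0 = time.perf_counter()
        if reporter is None and synthetic:
            # mutate the planted site in the first retaining species
            site = truth.planted_sites[0]
            sp = sorted(site.retained)[0]
            lo = max(-config.upstream, site.position - 222)
            hi = min(-1, site.position + 140)
            reporter = ReporterSpec(species=sp, window=(lo, hi),
                                    site_pos=site.position)
        if reporter is not None:
            rec = next(r for r in records if r.species == reporter.species)
            construct = design_reporter(rec, reporter.window, reporter.site_pos,
                                        reporter.replacement,
                                        motif=motif)
            report = validate_construct(construct, motif)
            write_construct(construct, out / "reporter.fasta", out / "reporter_edit.json")
            counts["reporter_ok"] = int(report.ok)
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    outputs = sorted(p for p in out.iterdir()
                     if p.is_file() and p.name != "manifest.json")
    file_hashes = {p.name: _sha256(p) for p in outputs}
    run_hash = hashlib.sha256(
        json.dumps({"config": config.config_hash(), "files": file_hashes},
                   sort_keys=True).encode()
    ).hexdigest()
    manifest_doc = {
        "package_version": __version__,
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": counts,
        "file_hashes": file_hashes,
        "run_hash": run_hash,
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest_doc, indent=2) + "\n")
    return out
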