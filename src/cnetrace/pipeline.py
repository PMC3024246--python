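"""End-to-end orchestration: simulate/align/detect/integrate/reconstruct.

Library-level driver behind the command line.  Every run directory gets a
manifest recording package version, parameters, seed and input checksums;
all artifacts are deterministic for a fixed seed, so re-running a manifest
reproduces them byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .align import PairwiseAlignment, Scoring, align_global
from .detect import (
    ConservedInterval,
    call_conserved_intervals,
    windowed_identity,
)
from .dollo import annotated_newick, dollo_reconstruct, event_report
from .integrate import CNE, assign_names, integrate_pairs, presence_matrix
from .io import (
    CharacterMatrix,
    RegionSequence,
    SpeciesTree,
    write_bed,
    write_region_fasta,
)

__all__ = ["RunConfig", "run_all", "detect_pairs", "reference_coverage", "integrate_group"]

DEFAULT_REFERENCE = "stickleback"


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one pipeline run (defaults: W=100, threshold=70,
    reference=stickleback)."""

    reference: str = DEFAULT_REFERENCE
    window: int = 100
    threshold: float = 70.0
    scoring: Scoring = field(default_factory=Scoring)
    model: str = "dollo"
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.threshold <= 100):
            raise ValueError(f"threshold must lie in (0, 100], got {self.threshold}")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.model not in ("dollo", "fitch"):
            raise ValueError("model must be 'dollo' or 'fitch'")
        self.scoring.validate()


def _log(stage: str, started: float, quiet: bool) -> None:
    if not quiet:
        print(f"[cnetrace] {stage}: {time.perf_counter() - started:.2f}s", file=sys.stderr)


def reference_coverage(aln: PairwiseAlignment) -> list[tuple[int, int]]:
    """Reference intervals across which the query is scorable (not ``N``).

    A deletion in the query is an observation (sequenced absence) and
    counts as covered; only ``N`` columns are unscorable.
    """
    col_of_ref = aln.column_of_ref()
    q = np.frombuffer(aln.qry_row.encode(), dtype=np.uint8)
    covered = q[col_of_ref] != ord("N")
    intervals: list[tuple[int, int]] = []
    start = None
    for i, ok in enumerate(covered):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            intervals.append((start, i))
            start = None
    if start is not None:
        intervals.append((start, covered.size))
    return intervals


def detect_pairs(
    regions: Sequence[RegionSequence],
    config: RunConfig,
) -> tuple[dict[str, PairwiseAlignment], list[ConservedInterval]]:
    """Align every query region to the reference and call conserved intervals.

    All regions must share one (cluster, region_class); the reference
    species' region anchors the comparison.
    """
    groups = {(r.cluster_id, r.region_class) for r in regions}
    if len(groups) != 1:
        raise ValueError(f"regions span multiple (cluster, region_class): {sorted(groups)}")
    by_species = {r.species_id: r for r in regions}
    if config.reference not in by_species:
        raise ValueError(f"reference species {config.reference!r} has no region")
    ref = by_species[config.reference]
    alignments: dict[str, PairwiseAlignment] = {}
    intervals: list[ConservedInterval] = []
    for species in sorted(by_species):
        if species == config.reference:
            continue
        aln = align_global(ref, by_species[species], scoring=config.scoring)
        alignments[species] = aln
        profile = windowed_identity(aln, window=config.window)
        intervals.extend(call_conserved_intervals(profile, threshold=config.threshold))
    return alignments, intervals


def integrate_group(
    regions: Sequence[RegionSequence],
    config: RunConfig,
) -> tuple[list[CNE], CharacterMatrix, dict[str, PairwiseAlignment]]:
    """Full detection + integration for one region group."""
    alignments, intervals = detect_pairs(regions, config)
    cluster_id = regions[0].cluster_id
    region_class = regions[0].region_class
    elements = assign_names(integrate_pairs(intervals), cluster_id, region_class)
    ref_len = len([r for r in regions if r.species_id == config.reference][0].seq)
    availability = {config.reference: [(0, ref_len)]}
    for species, aln in alignments.items():
        availability[species] = reference_coverage(aln)
    species_universe = sorted(availability)
    matrix = presence_matrix(
        elements, species_universe, availability, min_sub_length=config.window
    )
    return elements, matrix, alignments


def run_all(
    regions: Sequence[RegionSequence],
    tree: SpeciesTree,
    config: RunConfig,
    outdir: str | Path,
    inputs_checksums: Mapping[str, str] | None = None,
    quiet: bool = False,
) -> Path:
    """Run detect -> integrate -> reconstruct, writing every artifact.

    Writes per-pair interval BED, named-CNE BED (sub-elements included),
    presence matrix TSV, per-branch event report TSV, annotated newick and
    a JSON manifest.  Returns the run directory.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    groups: dict[tuple[str, str], list[RegionSequence]] = {}
    for r in regions:
        groups.setdefault((r.cluster_id, r.region_class), []).append(r)

    all_elements: list[CNE] = []
    matrices: list[CharacterMatrix] = []
    for key in sorted(groups):
        group = groups[key]
        elements, matrix, alignments = integrate_group(group, config)
        all_elements.extend(elements)
        matrices.append(matrix)
        pair_intervals = []
        for species, aln in sorted(alignments.items()):
            profile = windowed_identity(aln, window=config.window)
            pair_intervals.extend(
                call_conserved_intervals(profile, threshold=config.threshold)
            )
        pair_bed = _pair_bed(pair_intervals, config.reference)
        (outdir / f"pairs_{key[0]}_{key[1]}.bed").write_text(pair_bed)
    _log("detect+integrate", t0, quiet)

    t0 = time.perf_counter()
    cne_bed = write_bed(all_elements, config.reference, include_sub_elements=True)
    (outdir / "cnes.bed").write_text(cne_bed)

    frames = [m.frame for m in matrices]
    import pandas as pd

    merged = CharacterMatrix(pd.concat(frames, axis=1).fillna("?"))
    merged.to_tsv(outdir / "matrix.tsv")
    _log("matrix", t0, quiet)

    t0 = time.perf_counter()
    if config.model == "dollo":
        rec = dollo_reconstruct(merged, tree)
        report = event_report(rec)
        report.to_csv(outdir / "events.tsv", sep="\t", index=False)
        (outdir / "annotated_tree.nwk").write_text(annotated_newick(rec) + "\n")
    else:
        from .dollo import fitch_events

        counts = fitch_events(merged, tree)
        pd.Series(counts, name="n_changes").to_csv(outdir / "events.tsv", sep="\t")
    _log("reconstruct", t0, quiet)

    manifest = {
        "tool": "cnetrace",
        "version": __version__,
        "parameters": {
            "reference": config.reference,
            "window": config.window,
            "threshold": config.threshold,
            "scoring": dataclasses.asdict(config.scoring),
            "model": config.model,
            "seed": config.seed,
        },
        "inputs": dict(inputs_checksums or {}),
        "outputs": {
            p.name: sha256_file(p)
            for p in sorted(outdir.iterdir())
            if p.name != "manifest.json" and p.is_file()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir


def _pair_bed(intervals: Sequence[ConservedInterval], reference: str) -> str:
    lines = [f"# per-pair conserved intervals on reference {reference}"]
    for iv in sorted(intervals, key=lambda x: (x.start, x.end, x.qry_species)):
        lines.append(
            f"chrRegion\t{iv.start}\t{iv.end}\t{iv.qry_species}\t"
            f"{round(iv.mean_identity * 10)}\t+"
        )
    return "\n".join(lines) + "\n"


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
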