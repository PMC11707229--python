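"""Thin composition helpers wiring the modules into the standard pipeline.

These functions orchestrate the per-genome steps -- read annotations and hit
tables, filter, resolve, label -- so examples and downstream analyses can go
from a directory of inputs to :class:`~quinrep.annotation.AnnotatedGenome`
objects in one call.  All the science lives in the individual modules.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

from Bio import SeqIO

from .annotation import (
    AnnotatedGenome,
    HitFilterPolicy,
    build_annotated_genome,
    filter_hits,
    read_gff3,
    read_hit_table,
    resolve_best_profile,
)
from .motifs import UpstreamRegion, extract_upstream

__all__ = ["annotate_genome", "annotate_directory", "load_replicons", "triplet_upstream_regions"]


def annotate_genome(
    gff_path: str | Path,
    hits_path: str | Path,
    genome_id: str | None = None,
    policy: HitFilterPolicy | None = None,
    ga_thresholds: Mapping[str, float] | None = None,
) -> AnnotatedGenome:
    """GFF3 + hit table -> labelled AnnotatedGenome for one genome."""
    gff_path = Path(gff_path)
    genome_id = genome_id or gff_path.stem
    features = read_gff3(gff_path, genome_id=genome_id)
    hits = read_hit_table(hits_path, genome_id=genome_id, ga_thresholds=ga_thresholds)
    kept = filter_hits(hits, policy)
    best = resolve_best_profile(kept)
    assignments = {protein: hit.profile_name for protein, hit in best.items()}
    known = {f.locus_tag for f in features}
    assignments = {k: v for k, v in assignments.items() if k in known}
    return build_annotated_genome(features, assignments)


def annotate_directory(
    gff_dir: str | Path,
    hits_dir: str | Path,
    genome_ids: Sequence[str],
    policy: HitFilterPolicy | None = None,
    ga_thresholds: Mapping[str, float] | None = None,
    gff_suffix: str = ".gff",
    hits_suffix: str = ".domtbl",
) -> list[AnnotatedGenome]:
    """Annotate every genome id from per-genome GFF3 and hit-table files."""
    gff_dir, hits_dir = Path(gff_dir), Path(hits_dir)
    return [
        annotate_genome(
            gff_dir / f"{gid}{gff_suffix}",
            hits_dir / f"{gid}{hits_suffix}",
            genome_id=gid,
            policy=policy,
            ga_thresholds=ga_thresholds,
        )
        for gid in genome_ids
    ]


def load_replicons(fasta_path: str | Path) -> dict[str, str]:
    """Replicon id -> sequence for one genome FASTA."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}


def triplet_upstream_regions(
    architectures,
    fasta_dir: str | Path,
    window: int = 450,
    fasta_suffix: str = ".fna",
) -> list[UpstreamRegion]:
    """Upstream windows of every gene of every classified ubiTUV occurrence."""
    fasta_dir = Path(fasta_dir)
    cache: dict[str, dict[str, str]] = {}
    regions: list[UpstreamRegion] = []
    for arch in architectures:
        occ = arch.occurrence
        if occ.genome_id not in cache:
            cache[occ.genome_id] = load_replicons(fasta_dir / f"{occ.genome_id}{fasta_suffix}")
        replicons = cache[occ.genome_id]
        for feat in (occ.t, occ.u, occ.v):
            regions.append(extract_upstream(feat, replicons[feat.replicon_id], window))
    return regions
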