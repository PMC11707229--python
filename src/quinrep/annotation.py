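"""Reading and filtering of genome annotations, profile-search hit tables and
genome metadata.

This module turns the raw inputs of a quinone-pathway survey -- per-genome GFF3
annotations, HMMER3 ``--domtblout`` hit tables from profile searches, and a
genome metadata table -- into :class:`AnnotatedGenome` objects whose genes
carry pathway-gene labels (``ubiU``, ``menB``, ``rquA``, ...).

The hit-selection rule mirrors standard practice for curated HMM profile
collections: a hit is trusted when it reaches the profile's gathering (GA)
bit-score cutoff, or, for profiles without a GA cutoff, when its independent
domain e-value and its coverage of the query sequence are both good enough.
When several profiles match one protein, the hit with the lowest i-evalue
wins.  Genome bookkeeping follows MIMAG quality criteria (completeness > 90%,
contamination < 5%) and a one-genome-per-species selection that prefers NCBI
"reference" over "representative" assemblies, falling back to a seeded random
draw.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SearchIO
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

__all__ = [
    "GeneFeature",
    "ProfileHit",
    "HitFilterPolicy",
    "GenomeMetadata",
    "AnnotatedGenome",
    "read_gff3",
    "read_hit_table",
    "read_metadata",
    "read_ga_thresholds",
    "filter_hits",
    "resolve_best_profile",
    "select_one_genome_per_species",
    "mimag_filter",
    "build_annotated_genome",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    """One gene/CDS with 1-based inclusive coordinates on a replicon."""

    genome_id: str
    replicon_id: str
    replicon_length: int
    start: int
    end: int
    strand: str
    locus_tag: str
    gene_label: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.start <= self.end <= self.replicon_length):
            raise ValueError(
                f"feature {self.locus_tag!r}: coordinates [{self.start}, {self.end}] "
                f"outside replicon {self.replicon_id!r} of length {self.replicon_length}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def with_label(self, label: str) -> "GeneFeature":
        return replace(self, gene_label=label)


@dataclass(frozen=True)
class ProfileHit:
    """One domain hit of an HMM profile against a protein sequence.

    ``aln_from``/``aln_to`` are 1-based inclusive alignment coordinates on the
    query sequence; coverage is alignment length over sequence length.
    """

    protein_id: str
    genome_id: str
    profile_name: str
    bit_score: float
    i_evalue: float
    aln_from: int
    aln_to: int
    seq_length: int
    ga_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.i_evalue < 0:
            raise ValueError(
                f"hit {self.protein_id}/{self.profile_name}: negative i-evalue"
            )
        if not (1 <= self.aln_from <= self.aln_to <= self.seq_length):
            raise ValueError(
                f"hit {self.protein_id}/{self.profile_name}: alignment span "
                f"[{self.aln_from}, {self.aln_to}] invalid for length {self.seq_length}"
            )

    @property
    def coverage(self) -> float:
        return (self.aln_to - self.aln_from + 1) / self.seq_length


@dataclass(frozen=True)
class HitFilterPolicy:
    """Hit-retention rule.

    With ``use_ga`` set, a hit whose profile defines a GA cutoff is retained
    iff its bit score reaches the cutoff; other hits fall through to the
    e-value + coverage rule.  ``quinone()`` is the default policy used for the
    quinone-protein profiles; ``reductase()`` is the stricter e-value-only
    policy used for O2-reductase profiles.
    """

    use_ga: bool = True
    ievalue_max: float = 1e-3
    coverage_min: float = 0.5

    def __post_init__(self) -> None:
        if self.ievalue_max <= 0:
            raise ValueError("ievalue_max must be > 0")
        if not (0 < self.coverage_min <= 1):
            raise ValueError("coverage_min must be in (0, 1]")

    @classmethod
    def quinone(cls) -> "HitFilterPolicy":
        return cls(use_ga=True, ievalue_max=1e-3, coverage_min=0.5)

    @classmethod
    def reductase(cls) -> "HitFilterPolicy":
        return cls(use_ga=False, ievalue_max=1e-5, coverage_min=0.5)

    def retains(self, hit: ProfileHit) -> bool:
        if self.use_ga and hit.ga_threshold is not None:
            return hit.bit_score >= hit.ga_threshold
        return hit.i_evalue < self.ievalue_max and hit.coverage > self.coverage_min


@dataclass(frozen=True)
class GenomeMetadata:
    genome_id: str
    species_id: str
    assembly_category: str = "other"  # reference | representative | other
    completeness: float | None = None  # percent
    contamination: float | None = None  # percent
    taxonomy: Mapping[str, str] = field(default_factory=dict)
    metabolism: str | None = None

    def __post_init__(self) -> None:
        for name, v in (("completeness", self.completeness),
                        ("contamination", self.contamination)):
            if v is not None and not (0 <= v <= 100):
                raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")


@dataclass
class AnnotatedGenome:
    """Gene features of one genome, some carrying pathway-gene labels."""

    genome_id: str
    features: list[GeneFeature]
    multi_copy_labels: set[str] = field(default_factory=set)

    @property
    def labels(self) -> set[str]:
        return {f.gene_label for f in self.features if f.gene_label}

    def genes_with_label(self, label: str) -> list[GeneFeature]:
        return [f for f in self.features if f.gene_label == label]

    def label_counts(self) -> dict[str, int]:
        counts: dict[str, int] = defaultdict(int)
        for f in self.features:
            if f.gene_label:
                counts[f.gene_label] += 1
        return dict(counts)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_CDS_TYPES = {"CDS", "gene"}


def read_gff3(path: str | Path, genome_id: str | None = None) -> list[GeneFeature]:
    """Read CDS/gene records of a GFF3 file into :class:`GeneFeature` objects.

    Replicon lengths are taken from ``##sequence-region`` pragmas; a feature
    extending past the declared length is a validation error.  Coordinates are
    kept 1-based inclusive, exactly as in the file.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    lengths: dict[str, int] = {}
    features: list[GeneFeature] = []
    seen_tags: dict[str, int] = defaultdict(int)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ValueError(
                    f"{path}:{lineno}: malformed GFF3 line: expected 9 tab-separated "
                    f"columns, got {len(line.split(chr(9)))}"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # noqa: BLE001 - re-raise with location
                raise ValueError(f"{path}:{lineno}: malformed GFF3 line: {exc}") from exc
            if feat.featuretype not in _CDS_TYPES:
                continue
            if feat.seqid not in lengths:
                raise ValueError(
                    f"{path}:{lineno}: no ##sequence-region pragma for replicon "
                    f"{feat.seqid!r}"
                )
            attrs = feat.attributes
            locus = (attrs.get("locus_tag") or attrs.get("ID") or [""])[0]
            if not locus:
                locus = f"{feat.seqid}_{lineno}"
            label = (attrs.get("gene") or [""])[0]
            seen_tags[locus] += 1
            try:
                features.append(
                    GeneFeature(
                        genome_id=genome_id,
                        replicon_id=feat.seqid,
                        replicon_length=lengths[feat.seqid],
                        start=feat.start,
                        end=feat.end,
                        strand=feat.strand,
                        locus_tag=locus,
                        gene_label=label,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    dupes = {t for t, n in seen_tags.items() if n > 1}
    if dupes:
        logger.warning("%s: %d duplicated locus_tags (kept all)", path, len(dupes))
    return features


def read_hit_table(
    path: str | Path,
    genome_id: str | None = None,
    ga_thresholds: Mapping[str, float] | None = None,
) -> list[ProfileHit]:
    """Read an HMMER3 ``--domtblout`` table (hmmscan layout) into hits.

    One :class:`ProfileHit` per domain row.  The query is the protein, the
    target the profile; coverage is computed from the ``ali`` span and the
    query length.  ``ga_thresholds`` maps profile names to their GA bit-score
    cutoffs (GA values are a profile property and are not part of the tabular
    format).
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    ga_thresholds = ga_thresholds or {}
    hits: list[ProfileHit] = []
    try:
        for qresult in SearchIO.parse(str(path), "hmmscan3-domtab"):
            for hit in qresult:
                for hsp in hit:
                    hits.append(
                        ProfileHit(
                            protein_id=qresult.id,
                            genome_id=genome_id,
                            profile_name=hit.id,
                            bit_score=float(hsp.bitscore),
                            i_evalue=float(hsp.evalue),
                            aln_from=hsp.query_start + 1,
                            aln_to=hsp.query_end,
                            seq_length=qresult.seq_len,
                            ga_threshold=ga_thresholds.get(hit.id),
                        )
                    )
    except ValueError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"{path}: malformed domtblout table: {exc}") from exc
    return hits


def read_metadata(path: str | Path) -> list[GenomeMetadata]:
    """Read a tab-separated genome metadata table.

    Required columns: genome_id, species_id.  Recognized optional columns:
    assembly_category, completeness, contamination, metabolism; any other
    column is kept as a taxonomy rank.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"genome_id", "species_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    known = required | {"assembly_category", "completeness", "contamination", "metabolism"}
    tax_cols = [c for c in df.columns if c not in known]
    records = []
    for d in df.to_dict(orient="records"):

        def _num(key: str) -> float | None:
            v = d.get(key)
            if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
                return None
            return float(v)

        records.append(
            GenomeMetadata(
                genome_id=d["genome_id"],
                species_id=d["species_id"],
                assembly_category=d.get("assembly_category") or "other",
                completeness=_num("completeness"),
                contamination=_num("contamination"),
                taxonomy={c: d[c] for c in tax_cols if isinstance(d[c], str)},
                metabolism=d.get("metabolism") if isinstance(d.get("metabolism"), str) else None,
            )
        )
    return records


def read_ga_thresholds(path: str | Path) -> dict[str, float]:
    """Read a two-column (profile, GA bit score) tab-separated table."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("profile\t"):
                continue
            name, value = line.split("\t")[:2]
            out[name] = float(value)
    return out


# ---------------------------------------------------------------------------
# filtering and resolution
# ---------------------------------------------------------------------------

def filter_hits(
    hits: Iterable[ProfileHit], policy: HitFilterPolicy | None = None
) -> list[ProfileHit]:
    """Retain hits per the policy, preserving input order.

    Default policy: GA cutoff when the profile defines one, otherwise
    i-evalue < 1e-3 and coverage > 0.5.  Idempotent.
    """
    policy = policy or HitFilterPolicy.quinone()
    return [h for h in hits if policy.retains(h)]


def resolve_best_profile(hits: Iterable[ProfileHit]) -> dict[str, ProfileHit]:
    """Pick, per protein, the surviving hit with the lowest i-evalue.

    Ties on i-evalue break to the lexicographically smallest profile name, so
    the result is independent of input order.
    """
    best: dict[str, ProfileHit] = {}
    for hit in hits:
        cur = best.get(hit.protein_id)
        if (
            cur is None
            or hit.i_evalue < cur.i_evalue
            or (hit.i_evalue == cur.i_evalue and hit.profile_name < cur.profile_name)
        ):
            best[hit.protein_id] = hit
    return best


def select_one_genome_per_species(
    metadata: Sequence[GenomeMetadata], seed: int
) -> dict[str, str]:
    """Choose one genome per species: reference > representative > random.

    Within the winning assembly category the choice is a seeded uniform draw
    over the lexicographically sorted genome ids, so a fixed seed reproduces
    the selection regardless of input order.
    """
    rng = np.random.default_rng(seed)
    by_species: dict[str, list[GenomeMetadata]] = defaultdict(list)
    for m in metadata:
        by_species[m.species_id].append(m)
    priority = {"reference": 0, "representative": 1, "other": 2}
    chosen: dict[str, str] = {}
    for species in sorted(by_species):
        group = by_species[species]
        best_rank = min(priority.get(m.assembly_category, 2) for m in group)
        pool = sorted(
            m.genome_id
            for m in group
            if priority.get(m.assembly_category, 2) == best_rank
        )
        chosen[species] = pool[int(rng.integers(len(pool)))]
    return chosen


def mimag_filter(metadata: Sequence[GenomeMetadata]) -> list[str]:
    """Genome ids passing MIMAG quality: completeness > 90 and contamination < 5.

    Both inequalities are strict; records with missing values are rejected
    with a logged warning.
    """
    kept: list[str] = []
    for m in metadata:
        if m.completeness is None or m.contamination is None:
            logger.warning(
                "genome %s: missing completeness/contamination, rejected", m.genome_id
            )
            continue
        if m.completeness > 90 and m.contamination < 5:
            kept.append(m.genome_id)
    return kept


def build_annotated_genome(
    features: Sequence[GeneFeature], assignments: Mapping[str, str]
) -> AnnotatedGenome:
    """Attach gene labels (locus_tag -> label) to features.

    Labels on a locus_tag absent from the features are an error listing the
    offenders.  A label carried by several features (paralogs) is kept on all
    of them and flagged multi-copy.
    """
    if not features:
        raise ValueError("cannot build an annotated genome without features")
    genome_ids = {f.genome_id for f in features}
    if len(genome_ids) != 1:
        raise ValueError(f"features span several genomes: {sorted(genome_ids)}")
    tags = {f.locus_tag for f in features}
    unknown = sorted(set(assignments) - tags)
    if unknown:
        raise ValueError(
            f"assignments reference locus_tags absent from the genome: {unknown}"
        )
    labelled = [
        f.with_label(assignments[f.locus_tag]) if f.locus_tag in assignments else f
        for f in features
    ]
    counts: dict[str, int] = defaultdict(int)
    for f in labelled:
        if f.gene_label:
            counts[f.gene_label] += 1
    multi = {lab for lab, n in counts.items() if n > 1}
    return AnnotatedGenome(
        genome_id=next(iter(genome_ids)), features=labelled, multi_copy_labels=multi
    )
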