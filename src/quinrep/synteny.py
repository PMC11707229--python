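"""Gene-neighbourhood statistics: contiguity, degree of synteny, and ubiTUV
locus architectures.

Two genes of a genome are *contiguous* when their intergenic gap is strictly
below 500 bp.  Across genomes, the contiguity score of a gene pair is the
number of genomes where they are contiguous divided by the number of
occurrences of the rarer gene, giving a value in [0, 1].

The *degree of synteny* compares the observed frequency ``f`` at which two
genes sit close together with the probability ``p`` of such proximity under
random gene placement, as the relative entropy (Bernoulli Kullback-Leibler
divergence)::

    D = f ln(f/p) + (1 - f) ln((1 - f)/(1 - p))

Proximity on a replicon of length ``L`` means an intergenic distance below
``d = p * L / 2``; with the default ``p = 0.02`` this is 50 kb for a 5 Mb
chromosome and 5 kb for a 500 kb one.  ``D = 0`` iff ``f = p``; strong synteny
(``f`` near 1) gives ``D`` near ``ln(1/p)``.

The ubiTUV locus classifier canonicalizes each triplet occurrence into the
transcription frame of the conserved ubiU-ubiV pair and assigns one of four
architecture classes (or ``other``):

* ``1`` - ubiT immediately upstream of ubiUV, same strand;
* ``2`` - ubiT immediately downstream of ubiUV, same strand;
* ``3`` - ubiT adjacent but on the opposite strand, divergent from ubiU;
* ``4`` - ubiUV adjacent but ubiT farther than the contiguity cutoff
  (or on another replicon).

Classification is invariant under coordinate translation and reverse
complement of the replicon.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import math

import networkx as nx
import numpy as np
import pandas as pd

from .annotation import AnnotatedGenome, GeneFeature

__all__ = [
    "SyntenyParams",
    "TripletOccurrence",
    "LocusArchitecture",
    "intergenic_distance",
    "proximity_threshold",
    "bernoulli_relative_entropy",
    "contiguity_score",
    "contiguity_graph",
    "export_contiguity_edgelist",
    "synteny_degree_matrix",
    "classify_ubiTUV_architecture",
    "enumerate_triplet_occurrences",
]


@dataclass(frozen=True)
class SyntenyParams:
    """Parameters of the proximity statistics.

    ``p`` is the random-placement proximity probability defining the distance
    threshold ``d = p*L/2`` per replicon; ``contiguity_gap_max`` is the strict
    intergenic-gap cutoff for contiguity; ``circular`` enables wrap-around
    distances; ``copresence_denominator`` restricts the ``f`` denominator to
    genomes containing both genes (set to False to divide by all genomes).
    """

    p: float = 0.02
    contiguity_gap_max: int = 500
    circular: bool = False
    copresence_denominator: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.p < 1):
            raise ValueError("p must be in (0, 1)")
        if self.contiguity_gap_max <= 0:
            raise ValueError("contiguity_gap_max must be positive")


def intergenic_distance(
    a: GeneFeature, b: GeneFeature, circular: bool = False
) -> int | None:
    """Gap in bp between two features on the same replicon; ``None`` otherwise.

    The gap counts the bases strictly between the nearest feature ends;
    overlapping or book-ended features give 0.  With ``circular``, the smaller
    of the linear and wrap-around gaps is returned.
    """
    if a.genome_id != b.genome_id or a.replicon_id != b.replicon_id:
        return None
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    linear = max(0, hi.start - lo.end - 1)
    if not circular:
        return linear
    wrap = max(0, a.replicon_length - hi.end + lo.start - 1)
    return min(linear, wrap)


def proximity_threshold(replicon_length: float, p: float = 0.02) -> float:
    """Distance ``d = p * L / 2`` below which two genes count as proximal.

    Chosen so that two genes placed uniformly at random on a replicon of
    length ``L`` fall within ``d`` of each other with probability ``p``.
    """
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    if replicon_length <= 0:
        raise ValueError("replicon length must be positive")
    return p * replicon_length / 2


def bernoulli_relative_entropy(f: float, p: float) -> float:
    """KL divergence of Bernoulli(f) from Bernoulli(p), with 0 ln 0 = 0."""
    if not (0 <= f <= 1):
        raise ValueError("f must be in [0, 1]")
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    d = 0.0
    if f > 0:
        d += f * math.log(f / p)
    if f < 1:
        d += (1 - f) * math.log((1 - f) / (1 - p))
    return d


# ---------------------------------------------------------------------------
# contiguity
# ---------------------------------------------------------------------------

def _min_pair_distance(
    gi: Sequence[GeneFeature], gj: Sequence[GeneFeature], circular: bool
) -> int | None:
    """Minimum intergenic distance over all copy pairs; None if never comparable."""
    best: int | None = None
    for a, b in itertools.product(gi, gj):
        d = intergenic_distance(a, b, circular=circular)
        if d is not None and (best is None or d < best):
            best = d
    return best


def contiguity_score(
    gene_i: str,
    gene_j: str,
    genomes: Iterable[AnnotatedGenome],
    gap_max: int = 500,
    circular: bool = False,
) -> float | None:
    """(#genomes with a contiguous copy pair) / min(occurrences of i, of j).

    Occurrences are counted as genomes containing the gene.  Returns ``None``
    when either gene never occurs.
    """
    n_i = n_j = n_adj = 0
    for g in genomes:
        gi = g.genes_with_label(gene_i)
        gj = g.genes_with_label(gene_j)
        if gi:
            n_i += 1
        if gj:
            n_j += 1
        if gi and gj:
            d = _min_pair_distance(gi, gj, circular)
            if d is not None and d < gap_max:
                n_adj += 1
    if n_i == 0 or n_j == 0:
        return None
    return n_adj / min(n_i, n_j)


def contiguity_graph(
    genomes: Sequence[AnnotatedGenome],
    labels: Sequence[str] | None = None,
    gap_max: int = 500,
    circular: bool = False,
) -> nx.Graph:
    """Weighted graph of pairwise contiguity scores over gene labels.

    Nodes carry the per-gene occurrence count (genomes containing the gene);
    edges carry ``score`` in [0, 1]; pairs never contiguous get no edge.
    """
    if labels is None:
        labels = sorted({lab for g in genomes for lab in g.labels})
    graph = nx.Graph()
    occurrences = {
        lab: sum(1 for g in genomes if g.genes_with_label(lab)) for lab in labels
    }
    for lab in labels:
        graph.add_node(lab, occurrences=occurrences[lab])
    for i, j in itertools.combinations(labels, 2):
        score = contiguity_score(i, j, genomes, gap_max=gap_max, circular=circular)
        if score is not None and score > 0:
            graph.add_edge(i, j, score=score)
    return graph


def export_contiguity_edgelist(graph: nx.Graph, path) -> None:
    """Write the contiguity graph as a (node, node, score) TSV edge list."""
    with open(path, "w") as fh:
        fh.write("gene_i\tgene_j\tscore\n")
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['score']:.6g}\n")


# ---------------------------------------------------------------------------
# degree of synteny
# ---------------------------------------------------------------------------

def synteny_degree_matrix(
    genomes: Sequence[AnnotatedGenome],
    params: SyntenyParams | None = None,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Pairwise proximity frequencies ``f`` and synteny degrees ``D``.

    For each ordered-independent pair of gene labels, a genome counts as
    *proximal* when some copy pair on a shared replicon lies within
    ``d = p*L/2`` of that replicon's length ``L``; copies on different
    replicons are never proximal.  ``f`` divides proximal genomes by genomes
    containing both genes (or all genomes, per ``params``).  Rows with an
    empty denominator carry ``n = 0`` and ``NaN`` for ``f`` and ``D``.
    """
    params = params or SyntenyParams()
    if labels is None:
        labels = sorted({lab for g in genomes for lab in g.labels})
    rows = []
    for i, j in itertools.combinations(labels, 2):
        n_both = n_prox = 0
        for g in genomes:
            gi = g.genes_with_label(i)
            gj = g.genes_with_label(j)
            if gi and gj:
                n_both += 1
                if _is_proximal(gi, gj, params):
                    n_prox += 1
        denom = n_both if params.copresence_denominator else len(genomes)
        if denom == 0:
            rows.append({"gene_i": i, "gene_j": j, "n": 0, "f": np.nan, "D": np.nan})
        else:
            f = n_prox / denom
            rows.append(
                {
                    "gene_i": i,
                    "gene_j": j,
                    "n": denom,
                    "f": f,
                    "D": bernoulli_relative_entropy(f, params.p),
                }
            )
    return pd.DataFrame(rows)


def _is_proximal(
    gi: Sequence[GeneFeature], gj: Sequence[GeneFeature], params: SyntenyParams
) -> bool:
    for a, b in itertools.product(gi, gj):
        d = intergenic_distance(a, b, circular=params.circular)
        if d is None:
            continue
        if d < proximity_threshold(a.replicon_length, params.p):
            return True
    return False


# ---------------------------------------------------------------------------
# ubiTUV locus architectures
# ---------------------------------------------------------------------------

#: stable geometry names; the numeric labels are the conventional shorthand
GEOMETRY_NAMES = {
    "1": "T_upstream_same_strand",
    "2": "T_downstream_same_strand",
    "3": "T_divergent_opposite_strand",
    "4": "T_distant",
    "other": "other",
}


@dataclass(frozen=True)
class TripletOccurrence:
    """One grouped (ubiT, ubiU, ubiV) copy set in a genome."""

    genome_id: str
    t: GeneFeature
    u: GeneFeature
    v: GeneFeature


@dataclass
class LocusArchitecture:
    """Classified geometry of a ubiTUV occurrence."""

    occurrence: TripletOccurrence
    class_label: str  # "1" | "2" | "3" | "4" | "other"
    geometry: str
    gap_uv: int | None
    gap_t_uv: int | None  # min gap between T and the UV pair; None if unknown
    fnr_sites: list = field(default_factory=list)


def classify_ubiTUV_architecture(
    occ: TripletOccurrence, gap_max: int = 500, circular: bool = False
) -> LocusArchitecture:
    """Assign an architecture class to a complete ubiTUV occurrence.

    The U-V pair is first canonicalized so it reads U then V along its
    transcription direction; classes 1-3 additionally require every gap inside
    the triplet below ``gap_max``, class 4 requires U-V adjacent with T beyond
    the cutoff.  Anything else (U-V not adjacent, U-V on opposite strands,
    convergent T, T between U and V) is ``other``.
    """
    t, u, v = occ.t, occ.u, occ.v
    gap_uv = intergenic_distance(u, v, circular=circular)
    d_tu = intergenic_distance(t, u, circular=circular)
    d_tv = intergenic_distance(t, v, circular=circular)
    gaps_t = [d for d in (d_tu, d_tv) if d is not None]
    gap_t_uv = min(gaps_t) if gaps_t else None

    def arch(label: str) -> LocusArchitecture:
        return LocusArchitecture(occ, label, GEOMETRY_NAMES[label], gap_uv, gap_t_uv)

    # the conserved UV pair must be adjacent, same strand, V following U
    if gap_uv is None or gap_uv >= gap_max or u.strand != v.strand:
        return arch("other")
    uv_forward = u.strand == "+"
    v_follows_u = (u.start < v.start) if uv_forward else (v.start < u.start)
    if not v_follows_u:
        return arch("other")

    if gap_t_uv is None or gap_t_uv >= gap_max:
        return arch("4")

    # position of T relative to the UV block, in the UV transcription frame
    block_lo = min(u.start, v.start)
    block_hi = max(u.end, v.end)
    if t.end < block_lo:
        t_side = "upstream" if uv_forward else "downstream"
    elif t.start > block_hi:
        t_side = "downstream" if uv_forward else "upstream"
    else:
        return arch("other")  # T overlaps or sits inside the UV block

    same_strand = t.strand == u.strand
    if t_side == "upstream" and same_strand:
        return arch("1")
    if t_side == "downstream" and same_strand:
        return arch("2")
    if t_side == "upstream" and not same_strand:
        # T transcribed away from U: divergent promoters share the T-U gap
        return arch("3")
    return arch("other")  # downstream, convergent with V


def enumerate_triplet_occurrences(
    genomes: Iterable[AnnotatedGenome],
    gap_max: int = 500,
    circular: bool = False,
    labels: tuple[str, str, str] = ("ubiT", "ubiU", "ubiV"),
) -> tuple[list[LocusArchitecture], pd.DataFrame]:
    """Group T/U/V copies into occurrences and classify each one.

    A genome with ``k = min(#T, #U, #V)`` copies yields ``k`` occurrences;
    copies are assigned to occurrences so as to minimize the total genomic
    span (brute force over assignments, which stay tiny in practice).  Returns
    the classified occurrences plus a per-genome report with class labels,
    U-V gaps and an ``incomplete`` flag for genomes carrying only a subset of
    the three genes.
    """
    lab_t, lab_u, lab_v = labels
    architectures: list[LocusArchitecture] = []
    report_rows = []
    for g in genomes:
        ts = g.genes_with_label(lab_t)
        us = g.genes_with_label(lab_u)
        vs = g.genes_with_label(lab_v)
        k = min(len(ts), len(us), len(vs))
        present = [bool(ts), bool(us), bool(vs)]
        if k == 0:
            if any(present):
                report_rows.append(
                    {
                        "genome_id": g.genome_id,
                        "class": "incomplete",
                        "gap_uv": np.nan,
                        "n_occurrences": 0,
                    }
                )
            continue
        for t, u, v in _group_triplets(ts, us, vs, k):
            arch = classify_ubiTUV_architecture(
                TripletOccurrence(g.genome_id, t, u, v), gap_max=gap_max, circular=circular
            )
            architectures.append(arch)
            report_rows.append(
                {
                    "genome_id": g.genome_id,
                    "class": arch.class_label,
                    "gap_uv": arch.gap_uv if arch.gap_uv is not None else np.nan,
                    "n_occurrences": k,
                }
            )
    return architectures, pd.DataFrame(report_rows)


def _span(*feats: GeneFeature) -> float:
    if len({(f.genome_id, f.replicon_id) for f in feats}) != 1:
        return math.inf
    return max(f.end for f in feats) - min(f.start for f in feats)


def _group_triplets(
    ts: Sequence[GeneFeature],
    us: Sequence[GeneFeature],
    vs: Sequence[GeneFeature],
    k: int,
) -> list[tuple[GeneFeature, GeneFeature, GeneFeature]]:
    """Pick k disjoint (T, U, V) triplets minimizing the summed span.

    Cross-replicon triplets contribute the span of their same-replicon UV
    pair plus a large constant, so same-replicon groupings always win when
    available.  Exhaustive over copy subsets -- copy numbers above three per
    gene are biologically implausible and would be reported upstream.
    """
    big = 10 ** 9

    def cost(t: GeneFeature, u: GeneFeature, v: GeneFeature) -> float:
        s = _span(t, u, v)
        if s != math.inf:
            return s
        s_uv = _span(u, v)
        return (s_uv if s_uv != math.inf else 0) + big

    best_cost = math.inf
    best: list[tuple[GeneFeature, GeneFeature, GeneFeature]] = []
    for t_sel in itertools.permutations(range(len(ts)), k):
        for u_sel in itertools.permutations(range(len(us)), k):
            for v_sel in itertools.permutations(range(len(vs)), k):
                total = 0.0
                combo = []
                for a, b, c in zip(t_sel, u_sel, v_sel):
                    t, u, v = ts[a], us[b], vs[c]
                    total += cost(t, u, v)
                    combo.append((t, u, v))
                if total < best_cost:
                    best_cost = total
                    best = combo
    return best


def class_counts(architectures: Sequence[LocusArchitecture]) -> dict[str, int]:
    """Occurrence counts per architecture class label."""
    counts: dict[str, int] = defaultdict(int)
    for a in architectures:
        counts[a.class_label] += 1
    return dict(counts)
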