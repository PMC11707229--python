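"""Presence/absence calling of quinone biosynthetic pathways.

A pathway is declared present in a genome when the number of *distinct*
pathway genes annotated in that genome reaches the pathway's threshold.  Two
pathways have hard definitions: the O2-independent ubiquinone pathway requires
all three of ``ubiT``, ``ubiU``, ``ubiV``; rhodoquinone requires ``rquA``.
For the larger pathways the threshold defaults to ``"auto"`` and is inferred
from the bimodality of the per-genome gene-count distribution: genomes either
carry essentially the whole pathway or almost none of it, so the count
histogram shows two modes and the threshold is placed just above the deepest
valley (antimode) between them.

The default gene memberships are an editable convention, not ground truth;
callers with curated profile collections should supply their own
:class:`PathwayDefinition` objects.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotatedGenome

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayDefinition",
    "PathwayPresenceMatrix",
    "DEFAULT_PATHWAYS",
    "load_pathway_definitions",
    "count_pathway_genes",
    "infer_presence_threshold",
    "call_pathway_presence",
    "copresence_combinations",
    "repertoire_by_taxon",
    "cooccurrence_covariance",
]


@dataclass(frozen=True)
class PathwayDefinition:
    """A named pathway: its gene labels and its presence threshold.

    ``min_genes`` may be an explicit integer in ``[1, len(gene_set)]`` or the
    string ``"auto"`` to infer it from count bimodality at call time.
    """

    name: str
    gene_set: frozenset[str]
    min_genes: int | str = "auto"

    def __post_init__(self) -> None:
        if not self.gene_set:
            raise ValueError(f"pathway {self.name!r} has an empty gene set")
        if isinstance(self.min_genes, int):
            if not (1 <= self.min_genes <= len(self.gene_set)):
                raise ValueError(
                    f"pathway {self.name!r}: min_genes={self.min_genes} outside "
                    f"[1, {len(self.gene_set)}]"
                )
        elif self.min_genes != "auto":
            raise ValueError("min_genes must be an int or 'auto'")


_UQ_CORE = {"ubiA", "ubiB", "ubiC", "ubiD", "ubiE", "ubiG"}
_UQ_O2_HYDROXYLASES = {"ubiF", "ubiH", "ubiI", "ubiL", "ubiM", "ubiN", "coq7"}

#: Default pathway definitions.  The O2-dependent UQ pathway is the core Ubi
#: enzymes plus the O2-dependent hydroxylases; the O2-independent pathway is
#: strictly ubiTUV; rhodoquinone is the single-gene rquA conversion of UQ.
DEFAULT_PATHWAYS: dict[str, PathwayDefinition] = {
    p.name: p
    for p in (
        PathwayDefinition("UQ_O2_dependent", frozenset(_UQ_CORE | _UQ_O2_HYDROXYLASES)),
        PathwayDefinition("UQ_O2_independent", frozenset({"ubiT", "ubiU", "ubiV"}), 3),
        PathwayDefinition(
            "Men",
            frozenset(
                {"menF", "menD", "menH", "menC", "menE", "menB", "menI", "menA", "ubiE"}
            ),
        ),
        PathwayDefinition("futalosine", frozenset({"mqnA", "mqnB", "mqnC", "mqnD", "mqnE"})),
        PathwayDefinition("RQ", frozenset({"rquA"}), 1),
    )
}


def load_pathway_definitions(path) -> dict[str, PathwayDefinition]:
    """Read pathway definitions from a YAML config file.

    Format: a mapping of pathway name to ``{genes: [...], min_genes: <int>}``
    (``min_genes`` optional, default ``"auto"``), e.g.::

        RQ:
          genes: [rquA]
          min_genes: 1
        UQ_O2_independent:
          genes: [ubiT, ubiU, ubiV]
          min_genes: 3
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of pathway definitions")
    out = {}
    for name, spec in raw.items():
        genes = spec.get("genes")
        if not genes:
            raise ValueError(f"{path}: pathway {name!r} lists no genes")
        out[name] = PathwayDefinition(
            name=name,
            gene_set=frozenset(genes),
            min_genes=spec.get("min_genes", "auto"),
        )
    return out


@dataclass
class PathwayPresenceMatrix:
    """Boolean genome x pathway calls plus the underlying gene counts."""

    presence: pd.DataFrame  # bool, genomes x pathways
    counts: pd.DataFrame  # int, same shape
    thresholds: dict[str, int]
    demethyl_mk_only: pd.Series  # bool per genome: Men present but ubiE absent

    def combinations(self) -> pd.Series:
        """Per genome, the tuple of present pathway names (sorted)."""
        cols = list(self.presence.columns)
        return self.presence.apply(
            lambda row: tuple(c for c in cols if row[c]), axis=1
        )


def count_pathway_genes(
    genomes: Iterable[AnnotatedGenome],
    definitions: Mapping[str, PathwayDefinition] | None = None,
) -> pd.DataFrame:
    """Count distinct pathway genes per genome (multi-copy genes count once)."""
    definitions = definitions or DEFAULT_PATHWAYS
    rows = {}
    for g in genomes:
        labels = g.labels
        rows[g.genome_id] = {
            name: len(labels & d.gene_set) for name, d in definitions.items()
        }
    df = pd.DataFrame.from_dict(rows, orient="index").astype(int)
    return df[list(definitions)]


def infer_presence_threshold(counts: Sequence[int] | np.ndarray, gene_set_size: int) -> int:
    """Presence threshold from the bimodality of a gene-count distribution.

    Histogram the integer counts, locate the two highest local maxima (modes),
    and return one plus the deepest valley strictly between them (leftmost bin
    on ties).  A unimodal distribution falls back to ``ceil(gene_set_size/2)``
    with a logged warning.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.size == 0:
        raise ValueError("cannot infer a threshold from an empty count vector")
    fallback = math.ceil(gene_set_size / 2)
    hist = np.bincount(counts, minlength=gene_set_size + 1)
    # local maxima of the histogram (plateau-aware: >= neighbours, > one side)
    maxima = []
    for k in range(len(hist)):
        left = hist[k - 1] if k > 0 else -1
        right = hist[k + 1] if k < len(hist) - 1 else -1
        if hist[k] > 0 and hist[k] >= left and hist[k] >= right and (hist[k] > left or hist[k] > right or (k == 0 and k == len(hist) - 1)):
            maxima.append(k)
    if len(maxima) < 2:
        logger.warning(
            "count distribution is unimodal; falling back to ceil(|genes|/2) = %d",
            fallback,
        )
        return fallback
    # two highest modes, ties broken toward the outermost bins
    modes = sorted(maxima, key=lambda k: (-hist[k], k))[:2]
    lo, hi = sorted(modes)
    if hi - lo < 2:
        logger.warning(
            "modes are adjacent bins (%d, %d); falling back to ceil(|genes|/2) = %d",
            lo, hi, fallback,
        )
        return fallback
    between = hist[lo + 1 : hi]
    valley = lo + 1 + int(np.argmin(between))
    return valley + 1


def call_pathway_presence(
    counts: pd.DataFrame,
    definitions: Mapping[str, PathwayDefinition] | None = None,
    genome_labels: Mapping[str, set[str]] | None = None,
) -> PathwayPresenceMatrix:
    """Apply per-pathway thresholds to a count matrix.

    ``genome_labels`` (genome id -> set of gene labels) is only needed to flag
    Men-positive genomes lacking ``ubiE``, which can produce demethyl-MK but
    not MK itself.
    """
    definitions = definitions or DEFAULT_PATHWAYS
    thresholds: dict[str, int] = {}
    presence = pd.DataFrame(index=counts.index)
    for name, d in definitions.items():
        if name not in counts.columns:
            raise KeyError(f"count matrix lacks pathway {name!r}")
        if d.min_genes == "auto":
            thresholds[name] = infer_presence_threshold(
                counts[name].to_numpy(), len(d.gene_set)
            )
        else:
            thresholds[name] = int(d.min_genes)
        presence[name] = counts[name] >= thresholds[name]
    demethyl = pd.Series(False, index=counts.index)
    if "Men" in presence.columns and genome_labels is not None:
        for gid in counts.index:
            if presence.at[gid, "Men"] and "ubiE" not in genome_labels.get(gid, set()):
                demethyl.at[gid] = True
    return PathwayPresenceMatrix(
        presence=presence,
        counts=counts[list(definitions)].copy(),
        thresholds=thresholds,
        demethyl_mk_only=demethyl,
    )


def copresence_combinations(presence: pd.DataFrame) -> pd.DataFrame:
    """Count genomes per observed pathway combination (empty set included).

    Counts sum to the number of genomes; combinations partition the dataset.
    """
    cols = list(presence.columns)
    combos = presence.apply(lambda row: tuple(c for c in cols if row[c]), axis=1)
    vc = combos.value_counts()
    df = pd.DataFrame(
        {
            "combination": ["+".join(c) if c else "(none)" for c in vc.index],
            "pathways": list(vc.index),
            "n_genomes": vc.to_numpy(),
        }
    )
    return df.sort_values("n_genomes", ascending=False, ignore_index=True)


def repertoire_by_taxon(
    presence: pd.DataFrame, taxonomy: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-taxon pathway presence counts and proportions.

    ``taxonomy`` maps genome id to its taxon at the rank of interest (order,
    class, ...).  Genomes without a taxon are dropped; empty taxa are never
    emitted.
    """
    tax = pd.Series(dict(taxonomy) if not isinstance(taxonomy, pd.Series) else taxonomy)
    shared = presence.index.intersection(tax.index)
    rows = []
    for taxon, idx in presence.loc[shared].groupby(tax.loc[shared]).groups.items():
        sub = presence.loc[idx]
        for pw in presence.columns:
            n_present = int(sub[pw].sum())
            rows.append(
                {
                    "taxon": taxon,
                    "n_genomes": len(sub),
                    "pathway": pw,
                    "n_present": n_present,
                    "proportion": n_present / len(sub),
                }
            )
    return pd.DataFrame(rows)


def cooccurrence_covariance(indicators: pd.DataFrame) -> pd.DataFrame:
    """Population covariance matrix of 0/1 indicator columns across genomes.

    Works for pathway presence columns or per-gene indicator columns.  With
    the population normalization (ddof=0) every diagonal entry is a Bernoulli
    variance, bounded by 0.25.
    """
    x = indicators.astype(float).to_numpy()
    cov = np.cov(x, rowvar=False, ddof=0)
    cov = np.atleast_2d(cov)
    return pd.DataFrame(cov, index=indicators.columns, columns=indicators.columns)
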