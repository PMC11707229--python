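"""Upstream-window extraction and PWM scanning for FNR-box motifs.

FNR, the O2-sensing master regulator of anaerobiosis, binds a ~14 bp
palindromic box.  This module extracts the 450 bp upstream of annotated genes
(strand-aware, truncated only at replicon edges), builds position-weight
matrices from aligned example sites or a consensus, and scans the windows
with FIMO-style thresholds: an exact p-value per position from a dynamic
program over the discretized log-odds score distribution, and
Benjamini-Hochberg q-values pooled over every scanned position of the run.
Matches are reported when ``p < 1e-5`` and ``q <= 0.05``.

Because the motif is palindromic, scanning the given strand suffices: the
reverse strand carries the same score at every informative column.

Score discretization uses 1e-3-bit bins with rounding *down* of both the
observed score and the distribution support, which keeps the reported
p-values conservative.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .annotation import GeneFeature
from .synteny import LocusArchitecture

logger = logging.getLogger(__name__)

__all__ = [
    "ALPHABET",
    "UpstreamRegion",
    "PWM",
    "MotifMatch",
    "ScanResult",
    "DEFAULT_FNR_CONSENSUS",
    "extract_upstream",
    "pwm_from_sites",
    "pwm_from_consensus",
    "write_meme_motif",
    "read_meme_motif",
    "score_distribution",
    "pwm_scan",
    "fnr_triplet_summary",
]

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(ALPHABET):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i

#: The canonical FNR-box consensus used as the default scanning motif
#: (a configuration default, not a claim about any particular dataset).
DEFAULT_FNR_CONSENSUS = "TTGATNNNNATCAA"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# upstream windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UpstreamRegion:
    """Sequence 5'->3' on the gene's coding strand, ending just before the
    translation start.

    ``start_offset`` is the signed offset of the first base of ``sequence``
    from the translation start (-450 for a full window); the last base is at
    offset -1.  Truncation happens only at replicon boundaries.
    """

    gene: GeneFeature
    sequence: str
    start_offset: int

    def __post_init__(self) -> None:
        if len(self.sequence) != -self.start_offset:
            raise ValueError("sequence length inconsistent with start_offset")

    @property
    def truncated(self) -> bool:
        return len(self.sequence) < 450


def extract_upstream(
    gene: GeneFeature, replicon_seq: str, window: int = 450
) -> UpstreamRegion:
    """Extract up to ``window`` bp upstream of the start codon, strand-aware.

    For a + strand gene starting at ``s`` the window covers replicon positions
    ``[s-window, s-1]``; for a - strand gene ending at ``e`` it covers
    ``[e+1, e+window]`` reverse-complemented.  Zero-length windows (gene at
    the replicon edge) yield an empty region.
    """
    if len(replicon_seq) != gene.replicon_length:
        raise ValueError(
            f"replicon sequence length {len(replicon_seq)} does not match "
            f"declared length {gene.replicon_length} for {gene.replicon_id}"
        )
    if gene.strand == "+":
        lo = max(1, gene.start - window)
        seq = replicon_seq[lo - 1 : gene.start - 1]
    else:
        hi = min(gene.replicon_length, gene.end + window)
        seq = revcomp(replicon_seq[gene.end : hi])
    if not seq:
        logger.warning(
            "gene %s at replicon edge: empty upstream window", gene.locus_tag
        )
    return UpstreamRegion(gene=gene, sequence=seq.upper(), start_offset=-len(seq))


# ---------------------------------------------------------------------------
# position-weight matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PWM:
    """Per-position base probabilities of a fixed-width motif."""

    probs: np.ndarray  # (width, 4), rows sum to 1
    name: str = "motif"

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("probs must have shape (width, 4)")
        if np.any(p < 0) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM column must be a probability vector")
        object.__setattr__(self, "probs", p)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1].copy(), name=self.name)

    def is_palindromic(self, tol: float = 1e-12) -> bool:
        return bool(np.allclose(self.probs, self.probs[::-1, ::-1], atol=tol))

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=1))

    def log_odds(self, background: np.ndarray) -> np.ndarray:
        """Log2 odds matrix (bits) against a 0-order background."""
        bg = np.asarray(background, dtype=float)
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must be a length-4 probability vector")
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / bg)


def pwm_from_sites(
    sites: Sequence[str], pseudocount: float = 0.25, palindromize: bool = False,
    name: str = "motif",
) -> PWM:
    """Build a PWM from equal-length aligned site sequences.

    Counts plus a per-base pseudocount, column-normalized.  With
    ``palindromize`` the matrix is averaged with its reverse complement,
    restoring exact palindromic symmetry.
    """
    if not sites:
        raise ValueError("need at least one site")
    w = len(sites[0])
    if any(len(s) != w for s in sites):
        raise ValueError("sites must have equal length")
    counts = np.full((w, 4), pseudocount, dtype=float)
    for s in sites:
        idx = _BASE_INDEX[np.frombuffer(s.upper().encode(), dtype=np.uint8)]
        if np.any(idx < 0):
            raise ValueError(f"non-ACGT character in site {s!r}")
        counts[np.arange(w), idx] += 1
    probs = counts / counts.sum(axis=1, keepdims=True)
    if palindromize:
        probs = (probs + probs[::-1, ::-1]) / 2
    return PWM(probs, name=name)


def pwm_from_consensus(
    consensus: str = DEFAULT_FNR_CONSENSUS,
    match_prob: float = 0.97,
    name: str = "consensus",
) -> PWM:
    """PWM from a consensus string; ``N`` columns are uniform.

    Non-N columns put ``match_prob`` on the consensus base and split the rest
    evenly, so a full match to the informative columns scores
    ``k * log2(match_prob/bg)`` bits.
    """
    rows = []
    off = (1 - match_prob) / 3
    for ch in consensus.upper():
        if ch == "N":
            rows.append([0.25] * 4)
        elif ch in ALPHABET:
            row = [off] * 4
            row[ALPHABET.index(ch)] = match_prob
            rows.append(row)
        else:
            raise ValueError(f"unsupported consensus character {ch!r}")
    return PWM(np.array(rows), name=name)


def write_meme_motif(pwm: PWM, path, background: np.ndarray | None = None) -> None:
    """Write a PWM in MEME minimal text format."""
    bg = np.asarray(background if background is not None else [0.25] * 4)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[i]:.5f}" for i, b in enumerate(ALPHABET)) + "\n\n")
        fh.write(f"MOTIF {pwm.name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= 20 E= 0\n"
        )
        for row in pwm.probs:
            fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")


def read_meme_motif(path) -> PWM:
    """Read the first motif of a MEME minimal text file."""
    name = "motif"
    rows: list[list[float]] = []
    width = None
    with open(path) as fh:
        lines = iter(fh)
        for line in lines:
            if line.startswith("MOTIF"):
                parts = line.split()
                if len(parts) > 1:
                    name = parts[1]
            elif line.startswith("letter-probability matrix"):
                m = re.search(r"w=\s*(\d+)", line)
                if not m:
                    raise ValueError(f"{path}: missing motif width")
                width = int(m.group(1))
                for _ in range(width):
                    rows.append([float(x) for x in next(lines).split()])
                break
    if width is None:
        raise ValueError(f"{path}: no letter-probability matrix found")
    probs = np.array(rows)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return PWM(probs, name=name)


# ---------------------------------------------------------------------------
# exact p-values and scanning
# ---------------------------------------------------------------------------

DEFAULT_SCORE_BIN = 1e-3  # bits


def _discretize(logodds: np.ndarray, bin_size: float) -> np.ndarray:
    finite = np.where(np.isfinite(logodds), logodds, -1e4)
    return np.floor(finite / bin_size).astype(np.int64)


def score_distribution(
    pwm: PWM, background: np.ndarray, bin_size: float = DEFAULT_SCORE_BIN
) -> tuple[int, np.ndarray]:
    """Exact distribution of the discretized log-odds score under background.

    Returns ``(offset, probs)`` where ``probs[k]`` is the probability that the
    integer (floored) score equals ``offset + k`` for a random word drawn from
    the 0-order background.  Dynamic program over motif columns; cost is
    width x 4 x (score range / bin).
    """
    bg = np.asarray(background, dtype=float)
    ints = _discretize(pwm.log_odds(bg), bin_size)
    lo = int(ints.min(axis=1).sum())
    hi = int(ints.max(axis=1).sum())
    dist = np.zeros(hi - lo + 1)
    # start with an empty prefix at score 0, tracked relative to running lo
    cur = np.array([1.0])
    cur_lo = 0
    for i in range(pwm.width):
        col = ints[i]
        new_lo = cur_lo + int(col.min())
        new_hi = cur_lo + len(cur) - 1 + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            if bg[b] == 0:
                continue
            shift = cur_lo + int(col[b]) - new_lo
            new[shift : shift + len(cur)] += cur * bg[b]
        cur, cur_lo = new, new_lo
    dist[cur_lo - lo : cur_lo - lo + len(cur)] = cur
    return lo, dist


def exact_pvalue_lookup(
    pwm: PWM, background: np.ndarray, bin_size: float = DEFAULT_SCORE_BIN
) -> tuple[int, np.ndarray]:
    """Survival function of the discretized score: ``sf[k] = P(S >= lo + k)``."""
    lo, dist = score_distribution(pwm, background, bin_size)
    sf = np.cumsum(dist[::-1])[::-1]
    return lo, np.minimum(sf, 1.0)


@dataclass(frozen=True)
class MotifMatch:
    """A PWM hit in an upstream window, located by its signed start offset."""

    gene: GeneFeature
    offset: int  # offset of the match's first base from the translation start
    score: float  # bits
    p_value: float
    q_value: float


@dataclass
class ScanResult:
    matches: list[MotifMatch]
    n_positions_scanned: int
    n_positions_skipped: int
    background: np.ndarray


def estimate_background(regions: Iterable[UpstreamRegion]) -> np.ndarray:
    """0-order base frequencies over a region set (ACGT only)."""
    counts = np.zeros(4)
    for r in regions:
        idx = _BASE_INDEX[np.frombuffer(r.sequence.encode(), dtype=np.uint8)]
        counts += np.bincount(idx[idx >= 0], minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def pwm_scan(
    regions: Sequence[UpstreamRegion],
    pwm: PWM,
    background: np.ndarray | None = None,
    p_max: float = 1e-5,
    q_max: float = 0.05,
    bin_size: float = DEFAULT_SCORE_BIN,
) -> ScanResult:
    """Scan upstream windows with a PWM and report significant matches.

    Scores are computed at every start position on the coding strand (a
    palindromic PWM makes the reverse strand redundant); exact p-values come
    from the score-distribution dynamic program; q-values are
    Benjamini-Hochberg over *all* scanned positions of the run.  A match needs
    ``p < p_max`` and ``q <= q_max``.  Windows shorter than the motif are
    skipped, as are start positions whose word contains a non-ACGT character.
    """
    if background is None:
        background = estimate_background(regions)
    background = np.asarray(background, dtype=float)
    lo, sf = exact_pvalue_lookup(pwm, background, bin_size)
    lod = pwm.log_odds(background)
    ints = _discretize(lod, bin_size)
    w = pwm.width

    cand: list[tuple[int, int, float, float]] = []  # (region idx, pos, score, p)
    n_scanned = n_skipped = 0
    for ri, region in enumerate(regions):
        n = len(region.sequence)
        if n < w:
            continue
        idx = _BASE_INDEX[np.frombuffer(region.sequence.encode(), dtype=np.uint8)]
        n_pos = n - w + 1
        scores_int = np.zeros(n_pos, dtype=np.int64)
        scores = np.zeros(n_pos)
        valid = np.ones(n_pos, dtype=bool)
        for j in range(w):
            col = idx[j : j + n_pos]
            bad = col < 0
            if bad.any():
                valid &= ~bad
                col = np.where(bad, 0, col)
            scores_int += ints[j, col]
            scores += lod[j, col]
        n_scanned += int(valid.sum())
        n_skipped += int((~valid).sum())
        ps = sf[np.clip(scores_int - lo, 0, len(sf) - 1)]
        ps = np.where(scores_int - lo >= len(sf), 0.0, ps)
        for pos in np.nonzero(valid)[0]:
            cand.append((ri, int(pos), float(scores[pos]), float(ps[pos])))
    if n_skipped:
        logger.warning("skipped %d window positions with non-ACGT bases", n_skipped)

    if not cand:
        return ScanResult([], n_scanned, n_skipped, background)
    pvals = np.array([c[3] for c in cand])
    qvals = false_discovery_control(pvals, method="bh")
    matches = []
    for (ri, pos, score, p), q in zip(cand, qvals):
        if p < p_max and q <= q_max:
            region = regions[ri]
            matches.append(
                MotifMatch(
                    gene=region.gene,
                    offset=region.start_offset + pos,
                    score=score,
                    p_value=p,
                    q_value=float(q),
                )
            )
    matches.sort(key=lambda m: (m.gene.genome_id, m.gene.locus_tag, m.offset))
    return ScanResult(matches, n_scanned, n_skipped, background)


# ---------------------------------------------------------------------------
# per-triplet summaries
# ---------------------------------------------------------------------------

def fnr_triplet_summary(
    matches: Sequence[MotifMatch],
    architectures: Sequence[LocusArchitecture],
) -> dict[str, pd.DataFrame]:
    """Summarize candidate FNR-site placement per ubiTUV triplet.

    Returns three tables: ``per_triplet`` (has-site flags upstream of ubiT /
    ubiU / ubiV and either-of-T-or-U), ``per_class`` (fraction of occurrences
    with a site and median signed offsets per architecture class) and
    ``per_gene`` (how many triplets have at least one site upstream of each
    gene).
    """
    by_gene: dict[tuple[str, str], list[MotifMatch]] = {}
    for m in matches:
        by_gene.setdefault((m.gene.genome_id, m.gene.locus_tag), []).append(m)

    def sites(feat: GeneFeature) -> list[MotifMatch]:
        return by_gene.get((feat.genome_id, feat.locus_tag), [])

    trip_rows = []
    for i, arch in enumerate(architectures):
        occ = arch.occurrence
        st, su, sv = sites(occ.t), sites(occ.u), sites(occ.v)
        arch.fnr_sites = [m.offset for m in st + su + sv]
        trip_rows.append(
            {
                "genome_id": occ.genome_id,
                "triplet": i,
                "class": arch.class_label,
                "has_site_ubiT": bool(st),
                "has_site_ubiU": bool(su),
                "has_site_ubiV": bool(sv),
                "has_site_either": bool(st or su),
                "offsets_ubiT": [m.offset for m in st],
                "offsets_ubiU": [m.offset for m in su],
            }
        )
    per_triplet = pd.DataFrame(trip_rows)

    cls_rows = []
    if not per_triplet.empty:
        for cls, sub in per_triplet.groupby("class"):
            off_t = [o for lst in sub["offsets_ubiT"] for o in lst]
            off_u = [o for lst in sub["offsets_ubiU"] for o in lst]
            cls_rows.append(
                {
                    "class": cls,
                    "n_occurrences": len(sub),
                    "frac_with_site": sub["has_site_either"].mean(),
                    "frac_site_ubiT": sub["has_site_ubiT"].mean(),
                    "frac_site_ubiU": sub["has_site_ubiU"].mean(),
                    "median_offset_ubiT": float(np.median(off_t)) if off_t else np.nan,
                    "median_offset_ubiU": float(np.median(off_u)) if off_u else np.nan,
                }
            )
    per_class = pd.DataFrame(cls_rows)

    gene_rows = []
    if not per_triplet.empty:
        for gene, col in (
            ("ubiT", "has_site_ubiT"),
            ("ubiU", "has_site_ubiU"),
            ("ubiV", "has_site_ubiV"),
            ("either_T_or_U", "has_site_either"),
        ):
            gene_rows.append(
                {
                    "gene": gene,
                    "n_with_site": int(per_triplet[col].sum()),
                    "n_triplets": len(per_triplet),
                    "fraction": per_triplet[col].mean(),
                }
            )
    per_gene = pd.DataFrame(gene_rows)
    return {"per_triplet": per_triplet, "per_class": per_class, "per_gene": per_gene}
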