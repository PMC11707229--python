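"""Ground-truthed synthetic datasets for the whole pipeline.

The generator emits, per genome, a GFF3 annotation, a FASTA replicon
sequence and an HMMER-style domtblout hit table, plus a metadata table, a
Newick species tree and ground-truth tables -- everything the analysis
modules consume, with the planted truth recorded alongside:

* pathway gene complements drawn per genome (all-or-none by default, so
  gene-count distributions are cleanly bimodal);
* one ubiTUV locus per O2-independent genome, laid out in one of the four
  architecture classes with geometric intergenic gaps;
* palindromic FNR-box instances planted at known offsets inside the 450 bp
  upstream windows of ubiU/ubiT;
* true profile hits that pass the hit filter and decoy hits that each fail
  exactly one recorded criterion;
* a Yule species tree, and discrete traits evolved under independent or
  dependent continuous-time Markov models for calibrating the association
  tests.

Everything is driven by a single seed: identical scenario + seed gives
byte-identical output files.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .annotation import GeneFeature
from .motifs import DEFAULT_FNR_CONSENSUS, revcomp
from .pathways import DEFAULT_PATHWAYS, PathwayDefinition

__all__ = [
    "SimulationScenario",
    "GroundTruth",
    "SyntheticDataset",
    "scenario_from_yaml",
    "make_yule_tree",
    "simulate_discrete_trait",
    "synthesize_genome_set",
    "write_hit_table",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: default metabolism mix conditional on (O2-independent UQ present,
#: low-potential quinone present): aerobes dominate plain-UQ repertoires,
#: facultative metabolism grows with the O2-independent pathway and again
#: with a low-potential quinone.
DEFAULT_METABOLISM_GIVEN_REPERTOIRE: dict[tuple[bool, bool], tuple[float, ...]] = {
    (False, False): (0.90, 0.07, 0.02, 0.01),
    (True, False): (0.70, 0.21, 0.05, 0.04),
    (False, True): (0.55, 0.35, 0.05, 0.05),
    (True, True): (0.40, 0.51, 0.06, 0.03),
}

METABOLISMS = ("aerobic", "facultative", "microaerophilic", "anaerobic")


@dataclass
class SimulationScenario:
    """Knobs of the generator; the defaults are the reference study design.

    Pathway presence probabilities follow the frequencies reported for the
    surveyed phylum (O2-dependent UQ nearly universal, O2-independent in
    ~39% of genomes, Men in ~20%, RQ rare).  ``architecture_freqs`` are the
    ubiTUV locus class frequencies; ``motif_rate_*`` are the probabilities of
    planting an FNR box upstream of ubiU / ubiT.  Probabilities may be a
    single float or a per-clade mapping (clades are the taxonomy orders cut
    from the species tree).
    """

    seed: int = 0
    n_genomes: int = 200
    replicon_length: int = 500_000
    n_clades: int = 4
    pathway_presence: Mapping[str, object] = dc_field(
        default_factory=lambda: {
            "UQ_O2_dependent": 0.98,
            "UQ_O2_independent": 0.39,
            "Men": 0.20,
            "futalosine": 0.0,
            "RQ": 0.02,
        }
    )
    architecture_freqs: Mapping[str, float] = dc_field(
        default_factory=lambda: {"1": 0.5, "2": 0.3, "3": 0.15, "4": 0.05}
    )
    gap_mean: float = 120.0  # geometric intra-operon gap, bp (< 500)
    distant_t_range: tuple[int, int] = (10_000, 40_000)  # class-4 T placement
    motif_consensus: str = DEFAULT_FNR_CONSENSUS
    motif_rate_ubiU: float = 0.75
    motif_rate_ubiT: float = 0.64
    motif_offset_range: tuple[int, int] = (-200, -40)
    multi_copy_rate: float = 0.0  # probability of a second ubiTUV copy set
    decoy_mean: float = 5.0  # mean decoy hits per genome (Poisson)
    n_filler_genes: int = 10
    gene_length_range: tuple[int, int] = (600, 1800)
    gc_content: float = 0.5
    yule_birth_rate: float = 1.0
    metabolism_given_repertoire: Mapping[tuple[bool, bool], tuple[float, ...]] = dc_field(
        default_factory=lambda: dict(DEFAULT_METABOLISM_GIVEN_REPERTOIRE)
    )
    completeness_range: tuple[float, float] = (92.0, 100.0)
    contamination_range: tuple[float, float] = (0.0, 4.0)
    pathways: Mapping[str, PathwayDefinition] = dc_field(
        default_factory=lambda: dict(DEFAULT_PATHWAYS)
    )

    def __post_init__(self) -> None:
        freqs = np.array(list(self.architecture_freqs.values()), dtype=float)
        if not math.isclose(freqs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("architecture class frequencies must sum to 1")
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0, 1)")


@dataclass
class GroundTruth:
    """Planted truth emitted next to the synthetic files."""

    presence: pd.DataFrame  # genomes x pathways, bool
    architectures: pd.DataFrame  # genome_id, occurrence, class, coordinates
    motif_sites: pd.DataFrame  # genome_id, locus_tag, gene_label, offset
    hits: pd.DataFrame  # per emitted hit: protein, profile, is_true, fail_reason
    metadata: pd.DataFrame
    metabolism: pd.Series


@dataclass
class SyntheticDataset:
    root: Path
    gff_dir: Path
    fasta_dir: Path
    hits_dir: Path
    metadata_path: Path
    tree_path: Path
    ga_thresholds_path: Path
    genome_ids: list[str]
    truth: GroundTruth


def scenario_from_yaml(path: str | Path) -> SimulationScenario:
    """Build a scenario from a YAML file of :class:`SimulationScenario` fields.

    List values for tuple-typed fields (ranges) are converted; mapping keys of
    ``metabolism_given_repertoire`` are written as two-flag strings such as
    ``"uq_indep+low_potential"``, ``"uq_indep"``, ``"low_potential"`` or
    ``"neither"``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    tuple_fields = {
        "distant_t_range", "motif_offset_range", "gene_length_range",
        "completeness_range", "contamination_range",
    }
    for key in tuple_fields & set(raw):
        raw[key] = tuple(raw[key])
    if "metabolism_given_repertoire" in raw:
        decoded = {}
        for key, probs in raw["metabolism_given_repertoire"].items():
            flags = set() if key == "neither" else set(key.split("+"))
            unknown = flags - {"uq_indep", "low_potential"}
            if unknown:
                raise ValueError(f"unknown repertoire flags {sorted(unknown)}")
            decoded[("uq_indep" in flags, "low_potential" in flags)] = tuple(probs)
        raw["metabolism_given_repertoire"] = decoded
    return SimulationScenario(**raw)


# ---------------------------------------------------------------------------
# trees and traits
# ---------------------------------------------------------------------------

def make_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int | None = None,
    labels: Sequence[str] | None = None,
) -> dendropy.Tree:
    """Rooted binary pure-birth (Yule) tree with ``n_tips`` extant tips."""
    if n_tips < 2:
        raise ValueError("a Yule tree needs at least two tips")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
        repeat_until_success=True,
    )
    leaves = sorted(tree.leaf_node_iter(), key=lambda nd: nd.taxon.label)
    # the simulator stops exactly at the n-th birth, leaving two zero-length
    # pendant edges; sample the tree a random time later (before the next
    # birth) so every branch length is strictly positive
    delta = rng.expovariate(n_tips * birth_rate)
    for leaf in leaves:
        leaf.edge.length = (leaf.edge.length or 0.0) + delta
    tree.seed_node.edge.length = None  # no root edge: depths start at the root
    if labels is None:
        labels = [f"g{i:04d}" for i in range(len(leaves))]
    for leaf, label in zip(leaves, labels):
        leaf.taxon.label = label
    return tree


def simulate_discrete_trait(
    tree: dendropy.Tree,
    rates: tuple[float, float] | None = None,
    q_matrix: np.ndarray | None = None,
    seed: int | None = None,
    root_state: int | None = None,
) -> tuple[dict[str, int], int]:
    """Simulate a discrete character along the tree by a CTMC.

    Either 2-state ``rates = (q01, q10)`` or an arbitrary ``q_matrix`` (e.g.
    the dependent 4-state matrix from :func:`build_dependent_q`).  Returns
    tip states and the total number of simulated changes.  The root state is
    drawn uniformly unless given.
    """
    if (rates is None) == (q_matrix is None):
        raise ValueError("give exactly one of rates or q_matrix")
    if q_matrix is None:
        q01, q10 = rates
        Q = np.array([[-q01, q01], [q10, -q10]], dtype=float)
    else:
        Q = np.asarray(q_matrix, dtype=float)
    n_states = Q.shape[0]
    rng = np.random.default_rng(seed)
    root = tree.seed_node
    states: dict[int, int] = {
        id(root): int(rng.integers(n_states)) if root_state is None else int(root_state)
    }
    n_changes = 0
    tip_states: dict[str, int] = {}
    for nd in tree.preorder_node_iter():
        if nd is root:
            pass
        else:
            s = states[id(nd.parent_node)]
            t = nd.edge.length or 0.0
            pos = 0.0
            while True:
                out = -Q[s, s]
                if out <= 0:
                    break
                wait = rng.exponential(1.0 / out)
                if pos + wait > t:
                    break
                pos += wait
                probs = np.clip(Q[s], 0, None)
                probs[s] = 0.0
                probs = probs / probs.sum()
                s = int(rng.choice(n_states, p=probs))
                n_changes += 1
            states[id(nd)] = s
        if nd.is_leaf():
            tip_states[nd.taxon.label] = states[id(nd)]
    return tip_states, n_changes


# ---------------------------------------------------------------------------
# genome synthesis
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _geom_gap(rng: np.random.Generator, mean: float, lo: int = 20, hi: int = 499) -> int:
    g = lo + int(rng.geometric(1.0 / max(mean - lo, 1.0))) - 1
    return min(g, hi)


@dataclass
class _Gene:
    locus_tag: str
    label: str  # "" for filler
    start: int
    end: int
    strand: str


class _Layout:
    """Sequential gene placement along one replicon."""

    def __init__(self, rng: np.random.Generator, scenario: SimulationScenario):
        self.rng = rng
        self.sc = scenario
        self.genes: list[_Gene] = []
        self.cursor = int(rng.integers(1_000, 3_000))
        self._tag = 0

    def next_tag(self, genome_id: str) -> str:
        self._tag += 1
        return f"{genome_id}_{self._tag:05d}"

    def place(self, genome_id: str, label: str, strand: str, gap: int) -> _Gene:
        lo, hi = self.sc.gene_length_range
        length = int(self.rng.integers(lo, hi + 1))
        start = self.cursor + gap
        gene = _Gene(self.next_tag(genome_id), label, start, start + length - 1, strand)
        if gene.end > self.sc.replicon_length:
            raise ValueError(
                "gene placement exceeds replicon; increase replicon_length"
            )
        self.genes.append(gene)
        self.cursor = gene.end
        return gene

    def jump(self, lo: int = 3_000, hi: int = 8_000) -> None:
        self.cursor += int(self.rng.integers(lo, hi))


def _clade_prob(value, clade: str) -> float:
    if isinstance(value, Mapping):
        return float(value[clade])
    return float(value)


def _plant_triplet(
    layout: _Layout, genome_id: str, cls: str, rng: np.random.Generator,
    scenario: SimulationScenario,
) -> dict[str, _Gene]:
    """Lay out one ubiTUV occurrence in the requested architecture class.

    Geometries are written in the UV transcription frame and the whole
    cassette is placed on a random strand, exercising the classifier's
    reverse-complement invariance.
    """
    flip = bool(rng.integers(2))  # place cassette on the minus strand
    gm = scenario.gap_mean

    def gap() -> int:
        return _geom_gap(rng, gm)

    genes: dict[str, _Gene] = {}
    layout.jump()
    if flip:
        # minus-strand cassette: genomic order is the reverse of the
        # transcription order, so emit the frame right-to-left
        if cls == "1":  # T upstream of UV, same strand -> genomic V, U, T
            genes["ubiV"] = layout.place(genome_id, "ubiV", "-", gap())
            genes["ubiU"] = layout.place(genome_id, "ubiU", "-", gap())
            genes["ubiT"] = layout.place(genome_id, "ubiT", "-", gap())
        elif cls == "2":  # T downstream -> genomic T, V, U
            genes["ubiT"] = layout.place(genome_id, "ubiT", "-", gap())
            genes["ubiV"] = layout.place(genome_id, "ubiV", "-", gap())
            genes["ubiU"] = layout.place(genome_id, "ubiU", "-", gap())
        elif cls == "3":  # T adjacent, opposite strand, divergent from U
            genes["ubiV"] = layout.place(genome_id, "ubiV", "-", gap())
            genes["ubiU"] = layout.place(genome_id, "ubiU", "-", gap())
            genes["ubiT"] = layout.place(genome_id, "ubiT", "+", max(gap(), 60))
        elif cls == "4":
            genes["ubiV"] = layout.place(genome_id, "ubiV", "-", gap())
            genes["ubiU"] = layout.place(genome_id, "ubiU", "-", gap())
            d_lo, d_hi = scenario.distant_t_range
            genes["ubiT"] = layout.place(
                genome_id, "ubiT", "-" if rng.integers(2) else "+",
                int(rng.integers(d_lo, d_hi)),
            )
        else:  # pragma: no cover - scenario validation forbids this
            raise ValueError(f"unknown architecture class {cls!r}")
    else:
        if cls == "1":
            genes["ubiT"] = layout.place(genome_id, "ubiT", "+", gap())
            genes["ubiU"] = layout.place(genome_id, "ubiU", "+", gap())
            genes["ubiV"] = layout.place(genome_id, "ubiV", "+", gap())
        elif cls == "2":
            genes["ubiU"] = layout.place(genome_id, "ubiU", "+", gap())
            genes["ubiV"] = layout.place(genome_id, "ubiV", "+", gap())
            genes["ubiT"] = layout.place(genome_id, "ubiT", "+", gap())
        elif cls == "3":
            genes["ubiT"] = layout.place(genome_id, "ubiT", "-", gap())
            genes["ubiU"] = layout.place(genome_id, "ubiU", "+", max(gap(), 60))
            genes["ubiV"] = layout.place(genome_id, "ubiV", "+", gap())
        elif cls == "4":
            d_lo, d_hi = scenario.distant_t_range
            genes["ubiT"] = layout.place(
                genome_id, "ubiT", "-" if rng.integers(2) else "+", gap()
            )
            genes["ubiU"] = layout.place(
                genome_id, "ubiU", "+", int(rng.integers(d_lo, d_hi))
            )
            genes["ubiV"] = layout.place(genome_id, "ubiV", "+", gap())
        else:  # pragma: no cover
            raise ValueError(f"unknown architecture class {cls!r}")
    return genes


def _motif_instance(rng: np.random.Generator, consensus: str) -> str:
    return "".join(
        "ACGT"[rng.integers(4)] if ch == "N" else ch for ch in consensus.upper()
    )


def _plant_motif(
    seq: np.ndarray,
    gene: _Gene,
    offset: int,
    instance: str,
    planted: list[tuple[int, int]],
) -> bool:
    """Write a motif instance at a signed offset upstream of a gene.

    Returns False (and leaves the sequence untouched) when the absolute
    interval leaves the replicon or collides with an earlier instance.
    """
    w = len(instance)
    if gene.strand == "+":
        a = gene.start + offset  # 1-based start of the instance
        b = a + w - 1
        written = instance
    else:
        b = gene.end - offset
        a = b - w + 1
        written = revcomp(instance)
    if a < 1 or b > len(seq):
        return False
    if any(not (b < x or a > y) for x, y in planted):
        return False
    seq[a - 1 : b] = np.frombuffer(written.encode(), dtype=np.uint8)
    planted.append((a, b))
    return True


def _window(gene: _Gene, window: int, replicon_length: int) -> tuple[int, int]:
    """Absolute 1-based interval of the upstream window of a gene."""
    if gene.strand == "+":
        return max(1, gene.start - window), gene.start - 1
    return gene.end + 1, min(replicon_length, gene.end + window)


def _offset_in_window(gene: _Gene, a: int, b: int) -> int:
    """Signed start offset of an absolute interval in a gene's coding frame."""
    if gene.strand == "+":
        return a - gene.start
    return -(b - gene.end)


def synthesize_genome_set(
    scenario: SimulationScenario, out_dir: str | Path
) -> SyntheticDataset:
    """Generate the full synthetic dataset under ``out_dir``.

    Writes ``gff/``, ``fasta/``, ``hits/`` (one file per genome),
    ``metadata.tsv``, ``tree.nwk``, ``ga_thresholds.tsv`` and a
    ``truth/`` directory with the planted presence matrix, architectures,
    motif offsets and per-hit filter expectations.
    """
    out = Path(out_dir)
    gff_dir, fasta_dir, hits_dir, truth_dir = (
        out / "gff", out / "fasta", out / "hits", out / "truth"
    )
    for d in (gff_dir, fasta_dir, hits_dir, truth_dir):
        d.mkdir(parents=True, exist_ok=True)

    master = np.random.default_rng(scenario.seed)
    genome_ids = [f"g{i:04d}" for i in range(scenario.n_genomes)]
    tree = make_yule_tree(
        scenario.n_genomes,
        scenario.yule_birth_rate,
        seed=int(master.integers(2**31)),
        labels=genome_ids,
    )
    tree.write(path=str(out / "tree.nwk"), schema="newick")

    # clades = contiguous blocks of the tree's leaf order, named like orders
    leaf_order = [nd.taxon.label for nd in tree.leaf_node_iter()]
    clade_of: dict[str, str] = {}
    block = math.ceil(len(leaf_order) / scenario.n_clades)
    for i, gid in enumerate(leaf_order):
        clade_of[gid] = f"order_{i // block + 1}"

    arch_labels = list(scenario.architecture_freqs)
    arch_probs = np.array([scenario.architecture_freqs[a] for a in arch_labels])
    pathway_names = list(scenario.pathways)

    # GA cutoffs: ubi/rqu profiles ship GA scores, men/mqn profiles do not,
    # exercising both branches of the hit filter
    all_genes = sorted({g for d in scenario.pathways.values() for g in d.gene_set})
    ga_thresholds = {g: 25.0 for g in all_genes if g.startswith(("ubi", "rqu", "coq"))}
    with open(out / "ga_thresholds.tsv", "w") as fh:
        fh.write("profile\tga\n")
        for name, ga in sorted(ga_thresholds.items()):
            fh.write(f"{name}\t{ga}\n")

    presence_rows: dict[str, dict[str, bool]] = {}
    arch_rows = []
    motif_rows = []
    hit_rows = []
    meta_rows = []
    metabolism: dict[str, str] = {}

    for gid in genome_ids:
        rng = np.random.default_rng(master.integers(2**31))
        clade = clade_of[gid]
        presence = {
            name: bool(rng.random() < _clade_prob(scenario.pathway_presence.get(name, 0.0), clade))
            for name in pathway_names
        }
        presence_rows[gid] = presence

        layout = _Layout(rng, scenario)
        triplets: list[dict[str, _Gene]] = []
        planted_classes: list[str] = []
        for name in pathway_names:
            if not presence[name]:
                continue
            definition = scenario.pathways[name]
            if name == "UQ_O2_independent":
                n_copies = 1 + (rng.random() < scenario.multi_copy_rate)
                for _ in range(n_copies):
                    cls = str(rng.choice(arch_labels, p=arch_probs))
                    triplets.append(_plant_triplet(layout, gid, cls, rng, scenario))
                    planted_classes.append(cls)
            else:
                layout.jump()
                strand = "+" if rng.integers(2) else "-"
                for gene_label in sorted(definition.gene_set):
                    layout.place(gid, gene_label, strand, _geom_gap(rng, scenario.gap_mean))
        for _ in range(scenario.n_filler_genes):
            layout.jump()
            layout.place(gid, "", "+" if rng.integers(2) else "-", 0)

        seq = _random_dna(rng, scenario.replicon_length, scenario.gc_content)

        # FNR boxes upstream of ubiU / ubiT; truth records every window of the
        # triplet that fully contains the planted instance
        planted_intervals: list[tuple[int, int]] = []
        for trip_idx, trip in enumerate(triplets):
            for target, rate in (("ubiU", scenario.motif_rate_ubiU),
                                 ("ubiT", scenario.motif_rate_ubiT)):
                if rng.random() >= rate:
                    continue
                gene = trip[target]
                instance = _motif_instance(rng, scenario.motif_consensus)
                lo_off, hi_off = scenario.motif_offset_range
                for _attempt in range(20):
                    offset = int(rng.integers(lo_off, hi_off + 1))
                    if _plant_motif(seq, gene, offset, instance, planted_intervals):
                        a, b = planted_intervals[-1]
                        for lab, g2 in trip.items():
                            wa, wb = _window(g2, 450, scenario.replicon_length)
                            if wa <= a and b <= wb:
                                motif_rows.append(
                                    {
                                        "genome_id": gid,
                                        "locus_tag": g2.locus_tag,
                                        "gene_label": lab,
                                        "offset": _offset_in_window(g2, a, b),
                                        "triplet": trip_idx,
                                    }
                                )
                        break

        replicon = f"{gid}_r1"
        _write_fasta(fasta_dir / f"{gid}.fna", replicon, seq)
        _write_gff(gff_dir / f"{gid}.gff", replicon, scenario.replicon_length, layout.genes)

        genome_hits = _make_hits(rng, gid, layout.genes, ga_thresholds, scenario)
        hit_rows.extend(genome_hits)
        write_hit_table(hits_dir / f"{gid}.domtbl", genome_hits)

        for occ_idx, cls in enumerate(planted_classes):
            trip = triplets[occ_idx]
            arch_rows.append(
                {
                    "genome_id": gid,
                    "occurrence": occ_idx,
                    "class": cls,
                    **{
                        f"{lab}_{fieldname}": getattr(trip[lab], fieldname)
                        for lab in ("ubiT", "ubiU", "ubiV")
                        for fieldname in ("start", "end", "strand")
                    },
                }
            )

        uq_indep = presence["UQ_O2_independent"]
        low_pot = presence.get("Men", False) or presence.get("RQ", False) or presence.get("futalosine", False)
        probs = scenario.metabolism_given_repertoire[(uq_indep, bool(low_pot))]
        metabolism[gid] = METABOLISMS[int(rng.choice(4, p=np.asarray(probs)))]
        meta_rows.append(
            {
                "genome_id": gid,
                "species_id": f"sp{gid[1:]}",
                "assembly_category": str(rng.choice(
                    ["reference", "representative", "other"], p=[0.5, 0.3, 0.2]
                )),
                "completeness": round(float(rng.uniform(*scenario.completeness_range)), 2),
                "contamination": round(float(rng.uniform(*scenario.contamination_range)), 2),
                "class": "synthetic_class",
                "order": clade,
                "metabolism": metabolism[gid],
            }
        )

    presence_df = pd.DataFrame.from_dict(presence_rows, orient="index")[pathway_names]
    arch_df = pd.DataFrame(arch_rows)
    motif_df = pd.DataFrame(motif_rows)
    hits_df = pd.DataFrame(hit_rows)
    meta_df = pd.DataFrame(meta_rows)

    meta_df.to_csv(out / "metadata.tsv", sep="\t", index=False)
    presence_df.to_csv(truth_dir / "presence.tsv", sep="\t")
    arch_df.to_csv(truth_dir / "architectures.tsv", sep="\t", index=False)
    motif_df.to_csv(truth_dir / "motif_sites.tsv", sep="\t", index=False)
    hits_df.to_csv(truth_dir / "hits.tsv", sep="\t", index=False)

    truth = GroundTruth(
        presence=presence_df,
        architectures=arch_df,
        motif_sites=motif_df,
        hits=hits_df,
        metadata=meta_df,
        metabolism=pd.Series(metabolism),
    )
    return SyntheticDataset(
        root=out,
        gff_dir=gff_dir,
        fasta_dir=fasta_dir,
        hits_dir=hits_dir,
        metadata_path=out / "metadata.tsv",
        tree_path=out / "tree.nwk",
        ga_thresholds_path=out / "ga_thresholds.tsv",
        genome_ids=genome_ids,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

_FAIL_MODES = ("ga", "ievalue", "coverage")


def _make_hits(
    rng: np.random.Generator,
    genome_id: str,
    genes: Sequence[_Gene],
    ga_thresholds: Mapping[str, float],
    scenario: SimulationScenario,
) -> list[dict]:
    """True hits for labelled genes, decoys (each failing one criterion) on fillers."""
    rows = []
    fillers = [g for g in genes if not g.label]
    for g in genes:
        if not g.label:
            continue
        seq_len = (g.end - g.start + 1) // 3
        cov = rng.uniform(0.9, 1.0)
        aln_len = max(1, int(round(cov * seq_len)))
        aln_from = int(rng.integers(1, seq_len - aln_len + 2))
        rows.append(
            {
                "genome_id": genome_id,
                "protein_id": g.locus_tag,
                "profile_name": g.label,
                "bit_score": round(float(rng.uniform(150, 600)), 1),
                "i_evalue": float(10.0 ** rng.uniform(-60, -20)),
                "aln_from": aln_from,
                "aln_to": aln_from + aln_len - 1,
                "seq_length": seq_len,
                "is_true": True,
                "fail_reason": "",
            }
        )
    n_decoys = int(rng.poisson(scenario.decoy_mean))
    profiles = sorted(ga_thresholds) + ["menB", "menD", "mqnA"]
    for k in range(n_decoys):
        if not fillers:
            break
        g = fillers[int(rng.integers(len(fillers)))]
        profile = profiles[int(rng.integers(len(profiles)))]
        has_ga = profile in ga_thresholds
        mode = _FAIL_MODES[0] if has_ga else _FAIL_MODES[1 + int(rng.integers(2))]
        seq_len = (g.end - g.start + 1) // 3
        if mode == "ga":
            bit, iev, cov = rng.uniform(2, 20), 10.0 ** rng.uniform(-4, -1), rng.uniform(0.6, 0.9)
        elif mode == "ievalue":
            bit, iev, cov = rng.uniform(10, 30), 10.0 ** rng.uniform(-2.5, -0.5), rng.uniform(0.6, 0.9)
        else:  # coverage failure with a seductive e-value
            bit, iev, cov = rng.uniform(10, 30), 5e-4, rng.uniform(0.1, 0.45)
        aln_len = max(1, int(round(cov * seq_len)))
        aln_from = int(rng.integers(1, max(2, seq_len - aln_len + 2)))
        rows.append(
            {
                "genome_id": genome_id,
                "protein_id": g.locus_tag,
                "profile_name": profile,
                "bit_score": round(float(bit), 1),
                "i_evalue": float(iev),
                "aln_from": aln_from,
                "aln_to": aln_from + aln_len - 1,
                "seq_length": seq_len,
                "is_true": False,
                "fail_reason": mode,
            }
        )
    return rows


def write_hit_table(path: str | Path, rows: Sequence[Mapping]) -> None:
    """Write hits as an HMMER3 hmmscan ``--domtblout`` table."""
    with open(path, "w") as fh:
        fh.write(
            "#" + " " * 31 + "--- full sequence --- "
            "-------------- this domain -------------\n"
        )
        fh.write(
            "# target name        accession   tlen query name           accession  "
            " qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias"
            "  from    to  from    to  from    to  acc description of target\n"
        )
        fh.write("#" + "-" * 140 + "\n")
        for r in rows:
            fh.write(
                f"{r['profile_name']:<20} -          "
                f"{int(r['seq_length']):>5} {r['protein_id']:<20} -          "
                f"{int(r['seq_length']):>5} "
                f"{r['i_evalue']:9.2g} {r['bit_score']:6.1f}   0.0   1   1 "
                f"{r['i_evalue']:9.2g} {r['i_evalue']:9.2g} {r['bit_score']:6.1f}"
                f"   0.0     1 {int(r['seq_length']):>5} "
                f"{int(r['aln_from']):>5} {int(r['aln_to']):>5} "
                f"{int(r['aln_from']):>5} {int(r['aln_to']):>5} 0.99 -\n"
            )


def _write_fasta(path: Path, replicon: str, seq: np.ndarray) -> None:
    text = seq.tobytes().decode("ascii")
    with open(path, "w") as fh:
        fh.write(f">{replicon}\n")
        for i in range(0, len(text), 80):
            fh.write(text[i : i + 80] + "\n")


def _write_gff(path: Path, replicon: str, length: int, genes: Sequence[_Gene]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {replicon} 1 {length}\n")
        for g in sorted(genes, key=lambda x: x.start):
            fh.write(
                f"{replicon}\tquinrep_sim\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t"
                f"ID={g.locus_tag};locus_tag={g.locus_tag}\n"
            )


def features_from_genes(
    genome_id: str, replicon: str, length: int, genes: Sequence[_Gene]
) -> list[GeneFeature]:
    """In-memory view of planted genes as labelled GeneFeatures (tests)."""
    return [
        GeneFeature(
            genome_id=genome_id,
            replicon_id=replicon,
            replicon_length=length,
            start=g.start,
            end=g.end,
            strand=g.strand,
            locus_tag=g.locus_tag,
            gene_label=g.label,
        )
        for g in genes
    ]
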