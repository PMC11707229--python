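"""Call quinone pathway presence and tabulate repertoire combinations.

Counts distinct pathway genes per genome, infers thresholds from the
bimodality of the count distribution where no hard threshold exists
(ubiTUV requires all three genes; rquA alone defines RQ), and prints the
co-presence table.
"""

import tempfile
from pathlib import Path

from quinrep.annotation import read_ga_thresholds
from quinrep.pathways import call_pathway_presence, copresence_combinations, count_pathway_genes
from quinrep.simulate import SimulationScenario, synthesize_genome_set
from quinrep.workflow import annotate_directory

with tempfile.TemporaryDirectory() as tmp:
    ds = synthesize_genome_set(SimulationScenario(seed=2, n_genomes=60), Path(tmp))
    ga = read_ga_thresholds(ds.ga_thresholds_path)
    genomes = annotate_directory(ds.gff_dir, ds.hits_dir, ds.genome_ids,
                                 ga_thresholds=ga)

    counts = count_pathway_genes(genomes)
    called = call_pathway_presence(
        counts, genome_labels={g.genome_id: g.labels for g in genomes}
    )
    print("inferred presence thresholds:", called.thresholds)
    print("\ngenomes per pathway:")
    print(called.presence.sum().to_string())
    print("\npathway combinations (counts sum to the number of genomes):")
    print(copresence_combinations(called.presence)[["combination", "n_genomes"]]
          .to_string(index=False))

# Present pathways carry (nearly) their full gene complement, absent ones
# almost none, so the count histogram is bimodal and the antimode threshold
# separates the two modes; the combination counts partition the genomes.
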