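"""Generate the synthetic litter-moss-soil study system.

Writes a 75-sample (5 sites x 5 plots x 3 habitats) count table with planted
SU / ES / EC core taxa, habitat specialists and background generalists, plus
sample metadata (pH, elevation, a predicted-pathway proxy), a random
phylogeny, and the ground-truth labels every later script scores against.
"""

from pathlib import Path

from phyllocore import io_prep as io
from phyllocore.pipeline import stage_seed
from phyllocore.synthetic_data import StratifiedScenario, simulate_stratified_system, simulate_tree

SEED = 20240
OUT = Path(__file__).resolve().parent.parent / "results" / "fixture"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scn = StratifiedScenario(seed=SEED)
    tab, meta, truth = simulate_stratified_system(scn)
    io.write_abundance_table(tab, OUT / "counts.tsv")
    meta.data.to_csv(OUT / "meta.tsv", sep="\t")
    simulate_tree(tab.taxon_ids, seed=stage_seed(SEED, "tree")).write(
        str(OUT / "tree.nwk"), format="newick"
    )
    truth.taxon_labels.to_frame().to_csv(OUT / "truth.tsv", sep="\t")
    print(f"system: {tab.n_samples} samples x {tab.n_taxa} taxa")
    print(f"planted classes: {truth.taxon_labels.value_counts().to_dict()}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
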