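"""Community assembly partitioning of the synthetic communities.

Computes betaMNTD/betaNTI (taxa-shuffle null) and RC_bray (pool null) for
every within-group sample pair, classifies pairs into the five ecological
processes, and runs the three-regime parameter-recovery experiment
(selection / dispersal-limited / homogenizing). Writes results/assembly/.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from casingsoil import recovery_design, simulate_dataset
from casingsoil.assembly import assembly_profile
from casingsoil.io import align, read_count_table, read_metadata, read_tree

OUT = ROOT / "results" / "assembly"

SIGNATURES = {
    "selection": "variable_selection",
    "limited": "dispersal_limitation",
    "homogenizing": "homogenizing_dispersal",
}

def main():
    table = read_count_table(ROOT / "results/data/counts.tsv")
    meta = read_metadata(ROOT / "results/data/metadata.tsv")
    tree = read_tree(ROOT / "results/data/tree.nwk")
    table, meta = align(table, meta)
    OUT.mkdir(parents=True, exist_ok=True)

    pairs, fractions = assembly_profile(table, tree, meta, n_null=199, seed=7)
    pairs.to_csv(OUT / "assembly_pairs.tsv", sep="\t", index=False)
    fractions.to_csv(OUT / "assembly_fractions.tsv", sep="\t")
    print("per-group process fractions (study emulation):")
    print(fractions.round(3).to_string())

    print("\nthree-regime recovery (2 groups x 18 samples x 300 taxa):")
    recovery = {}
    for regime, signature in SIGNATURES.items():
        hits = 0
        for rep in range(5):
            design = recovery_design(regime, seed=100 + rep)
            t, tr, m, _ = simulate_dataset(design)
            _, fr = assembly_profile(t, tr, m, n_null=199, seed=500 + rep)
            hits += fr.mean(axis=0).idxmax() == signature
        recovery[regime] = {"signature": signature, "modal_replicates": f"{hits}/5"}
        print(f"  {regime:13s} -> {signature:22s} modal in {hits}/5 replicates")
    (OUT / "recovery.json").write_text(json.dumps(recovery, indent=2))

if __name__ == "__main__":
    main()
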