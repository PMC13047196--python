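"""Beta structure of the synthetic casing-soil communities.

Bray-Curtis dissimilarity, PCoA ordination, three group-dissimilarity
tests (PERMANOVA, ANOSIM, MRPP), and per-group core-taxon screening
(occupancy > 80%, abundance >= 0.1%). Writes results/beta/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from casingsoil.beta import anosim, bray_curtis, core_taxa, mrpp, pcoa, permanova
from casingsoil.io import align, read_count_table, read_metadata

OUT = ROOT / "results" / "beta"

def main():
    table = read_count_table(ROOT / "results/data/counts.tsv")
    meta = read_metadata(ROOT / "results/data/metadata.tsv")
    table, meta = align(table, meta)
    OUT.mkdir(parents=True, exist_ok=True)

    dm = bray_curtis(table)
    ordn = pcoa(dm)
    ordn["coordinates"].iloc[:, :5].to_csv(OUT / "pcoa_coordinates.tsv", sep="\t")
    prop = ordn["proportion_explained"]
    print(f"PCoA: axis 1 explains {prop[0]:.1%}, axis 2 {prop[1]:.1%}")

    groups = meta.frame["group"].to_numpy()
    tests = {
        "permanova": permanova(dm, groups, n_perm=999, seed=1),
        "anosim": anosim(dm, groups, n_perm=999, seed=1),
        "mrpp": mrpp(dm, groups, n_perm=999, seed=1),
    }
    (OUT / "beta_tests.json").write_text(json.dumps(tests, indent=2))
    for name, res in tests.items():
        print(f"{name}: {res}")

    cores = {}
    for group in meta.groups():
        sub = table.restrict_samples(meta.samples_in_group(group))
        core = core_taxa(sub, group)
        cores[str(group)] = sorted(core.taxa)
        print(f"group {group}: {len(core.taxa)} core taxa")
    (OUT / "core_taxa.json").write_text(json.dumps(cores, indent=2))

if __name__ == "__main__":
    main()
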