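"""Alpha diversity of the synthetic casing-soil communities.

Computes richness, Chao1, Shannon, evenness and inverse Simpson per sample
and tests for differences across peat groups (one-way ANOVA + Tukey HSD).
Writes results/alpha/alpha.tsv and alpha_tests.json.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from casingsoil.diversity import alpha_indices, group_anova
from casingsoil.io import align, read_count_table, read_metadata

OUT = ROOT / "results" / "alpha"

def main():
    table = read_count_table(ROOT / "results/data/counts.tsv")
    meta = read_metadata(ROOT / "results/data/metadata.tsv")
    table, meta = align(table, meta)
    OUT.mkdir(parents=True, exist_ok=True)

    alpha = alpha_indices(table)
    alpha.to_csv(OUT / "alpha.tsv", sep="\t")

    groups = meta.frame["group"].to_numpy()
    tests = {}
    for index in alpha.columns:
        res = group_anova(alpha[index].to_numpy(), groups)
        tests[index] = {
            "F": res["F"], "p": res["p"],
            "tukey_pairs": {f"{a}|{b}": p for (a, b), p in res["tukey_pairs"].items()},
        }
        print(f"{index:12s} F = {res['F']:8.2f}   p = {res['p']:.3g}")
    (OUT / "alpha_tests.json").write_text(json.dumps(tests, indent=2))

    by_group = alpha.join(meta.frame["group"]).groupby("group").mean()
    print("\ngroup means:")
    print(by_group.round(3).to_string())

if __name__ == "__main__":
    main()
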