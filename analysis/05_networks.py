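"""Co-occurrence networks of the synthetic casing-soil communities.

Per peat group: node filter (occupancy > 80%), Pearson correlation network
at St = 0.75, topology vs degree-preserving random nulls, robustness to
random removal of 50% of nodes, vulnerability, and Zi-Pi node roles.
Writes results/network/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from casingsoil.io import align, read_count_table, read_metadata
from casingsoil.network import (
    correlation_network,
    filter_for_network,
    random_null,
    robustness,
    roles_frame,
    topology,
    vulnerability,
    zi_pi,
)

OUT = ROOT / "results" / "network"

def main():
    table = read_count_table(ROOT / "results/data/counts.tsv")
    meta = read_metadata(ROOT / "results/data/metadata.tsv")
    table, meta = align(table, meta)
    OUT.mkdir(parents=True, exist_ok=True)

    summary = {}
    for group in meta.groups():
        sub = table.restrict_samples(meta.samples_in_group(group))
        net = correlation_network(filter_for_network(sub), st=0.75)
        stats = topology(net)
        nulls = random_null(net, n_rand=10, seed=3)
        rob = robustness(net, 0.5, n_rep=100, seed=3)
        vuln = vulnerability(net) if net.n_nodes >= 3 else None
        roles = roles_frame(zi_pi(net))
        roles.to_csv(OUT / f"roles_{group}.tsv", sep="\t")
        keystones = roles[roles["role"] != "peripheral"]
        summary[str(group)] = {
            "stats": stats.to_dict(),
            "random": {k: {"mean": v[0], "sd": v[1]} for k, v in nulls.items()},
            "robustness_50pct": rob,
            "vulnerability": vuln,
            "n_keystones": int(len(keystones)),
        }
        print(
            f"group {group}: {stats.n_nodes} nodes, {stats.n_links} links, "
            f"connectivity {stats.avg_connectivity:.2f}, "
            f"modularity {stats.modularity:.2f} "
            f"(random {nulls['modularity'][0]:.2f}±{nulls['modularity'][1]:.2f}), "
            f"robustness {rob:.2f}, keystones {len(keystones)}"
        )
    (OUT / "network_summary.json").write_text(json.dumps(summary, indent=2))

if __name__ == "__main__":
    main()
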