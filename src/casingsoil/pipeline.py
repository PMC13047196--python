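"""End-to-end orchestration: simulate or load, then run every stage.

``run_all`` executes the full analysis (alpha diversity, beta structure,
core screening, assembly partitioning, networks, environmental drivers)
per group, writes every result file under the configured output directory
and returns a manifest mapping each file to its SHA-256 content hash.
Identical configuration and seed give identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import assembly as asm
from . import beta as beta_mod
from . import diversity as div
from . import env as env_mod
from . import network as net_mod
from .io import (
    align,
    read_count_table,
    read_metadata,
    read_tree,
    write_count_table,
    write_metadata,
    write_tree,
)
from .synth import SimDesign, simulate_dataset


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Inputs, thresholds, permutation counts and seeds for one run."""

    design: SimDesign | None = None
    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    outdir: str = "scratch/run"
    occupancy: float = 0.8
    core_abundance: float = 0.001
    st: float = 0.75
    n_perm: int = 999
    n_null: int = 199
    n_rand: int = 20
    n_rep: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.st < 1:
            raise ConfigError(f"st must be in (0, 1), got {self.st}")
        if not 0 < self.occupancy < 1:
            raise ConfigError("occupancy must be in (0, 1)")
        if not 0 <= self.core_abundance < 1:
            raise ConfigError("core_abundance must be in [0, 1)")
        if self.n_perm < 99 or self.n_null < 99:
            raise ConfigError("n_perm and n_null must be >= 99")
        if self.design is None and not (
            self.table_path and self.tree_path and self.metadata_path
        ):
            raise ConfigError("provide either a SimDesign or all three input paths")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))


def run_all(config: RunConfig) -> dict:
    """Execute all stages; return {'outputs': {path: sha256}, 'stages': [...]}."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    stages: list[dict] = []

    def finish(stage: str, t0: float, *paths: Path) -> None:
        for p in paths:
            outputs[str(p.relative_to(out))] = _sha256(p)
        stages.append({"stage": stage, "seconds": round(time.time() - t0, 3)})

    # ---- inputs -----------------------------------------------------------
    t0 = time.time()
    try:
        if config.design is not None:
            table, tree, meta, _ = simulate_dataset(config.design)
            data_dir = out / "data"
            data_dir.mkdir(exist_ok=True)
            write_count_table(table, data_dir / "counts.tsv")
            write_metadata(meta, data_dir / "metadata.tsv")
            write_tree(tree, data_dir / "tree.nwk")
            finish(
                "simulate", t0,
                data_dir / "counts.tsv", data_dir / "metadata.tsv",
                data_dir / "tree.nwk",
            )
        else:
            table = read_count_table(config.table_path)
            tree = read_tree(config.tree_path)
            meta = read_metadata(config.metadata_path)
            table, meta = align(table, meta)
            stages.append({"stage": "load", "seconds": round(time.time() - t0, 3)})
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'inputs' failed: {exc}") from exc

    groups = meta.groups()
    group_col = meta.frame["group"].to_numpy()

    # ---- alpha diversity --------------------------------------------------
    t0 = time.time()
    try:
        alpha = div.alpha_indices(table)
        alpha.to_csv(out / "alpha.tsv", sep="\t")
        tests = {}
        for index in alpha.columns:
            res = div.group_anova(alpha[index].to_numpy(), group_col)
            tests[index] = {
                "F": res["F"],
                "p": res["p"],
                "tukey_pairs": {
                    f"{a}|{b}": p for (a, b), p in res["tukey_pairs"].items()
                },
            }
        _write_json(tests, out / "alpha_tests.json")
        finish("alpha", t0, out / "alpha.tsv", out / "alpha_tests.json")
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'alpha' failed: {exc}") from exc

    # ---- beta structure ---------------------------------------------------
    t0 = time.time()
    try:
        dm = beta_mod.bray_curtis(table)
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            out / "bray_curtis.tsv", sep="\t"
        )
        ordn = beta_mod.pcoa(dm)
        ordn["coordinates"].to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        _write_json(
            {
                "eigenvalues": list(ordn["eigenvalues"]),
                "proportion_explained": list(ordn["proportion_explained"]),
            },
            out / "pcoa_eigen.json",
        )
        tests = {
            "permanova": beta_mod.permanova(dm, group_col, config.n_perm, config.seed),
            "anosim": beta_mod.anosim(dm, group_col, config.n_perm, config.seed),
            "mrpp": beta_mod.mrpp(dm, group_col, config.n_perm, config.seed),
        }
        _write_json(tests, out / "beta_tests.json")
        finish(
            "beta", t0,
            out / "bray_curtis.tsv", out / "pcoa_coordinates.tsv",
            out / "pcoa_eigen.json", out / "beta_tests.json",
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'beta' failed: {exc}") from exc

    # ---- core taxa --------------------------------------------------------
    t0 = time.time()
    try:
        cores = {}
        for group in groups:
            sub = table.restrict_samples(meta.samples_in_group(group))
            core = beta_mod.core_taxa(
                sub, group,
                occupancy_threshold=config.occupancy,
                abundance_threshold=config.core_abundance,
            )
            cores[str(group)] = sorted(core.taxa)
        _write_json(cores, out / "core_taxa.json")
        finish("core", t0, out / "core_taxa.json")
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'core' failed: {exc}") from exc

    # ---- assembly ---------------------------------------------------------
    t0 = time.time()
    try:
        pairs, fractions = asm.assembly_profile(
            table, tree, meta, n_null=config.n_null, seed=config.seed
        )
        pairs.to_csv(out / "assembly_pairs.tsv", sep="\t", index=False)
        _write_json(
            {str(g): fractions.loc[g].to_dict() for g in fractions.index},
            out / "assembly_fractions.json",
        )
        finish(
            "assembly", t0,
            out / "assembly_pairs.tsv", out / "assembly_fractions.json",
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'assembly' failed: {exc}") from exc

    # ---- networks ---------------------------------------------------------
    t0 = time.time()
    try:
        net_stats = {}
        for group in groups:
            sub = table.restrict_samples(meta.samples_in_group(group))
            filtered = net_mod.filter_for_network(sub, config.occupancy)
            net = net_mod.correlation_network(filtered, st=config.st)
            if net.n_nodes == 0:
                warnings.warn(
                    f"group {group}: no edges at St={config.st}", RuntimeWarning
                )
                net_stats[str(group)] = None
                continue
            stats = net_mod.topology(net).to_dict()
            stats["random"] = {
                k: {"mean": v[0], "sd": v[1]}
                for k, v in net_mod.random_null(
                    net, n_rand=config.n_rand, seed=config.seed
                ).items()
            }
            stats["robustness_50pct"] = net_mod.robustness(
                net, 0.5, n_rep=config.n_rep, seed=config.seed
            )
            if net.n_nodes >= 3:
                stats["vulnerability"] = net_mod.vulnerability(net)
            edges = pd.DataFrame(
                [
                    {"node1": u, "node2": v, "r": d["r"], "sign": d["sign"]}
                    for u, v, d in net.graph.edges(data=True)
                ]
            )
            edges.to_csv(out / f"network_edges_{group}.tsv", sep="\t", index=False)
            net_mod.roles_frame(net_mod.zi_pi(net)).to_csv(
                out / f"network_roles_{group}.tsv", sep="\t"
            )
            outputs[f"network_edges_{group}.tsv"] = _sha256(
                out / f"network_edges_{group}.tsv"
            )
            outputs[f"network_roles_{group}.tsv"] = _sha256(
                out / f"network_roles_{group}.tsv"
            )
            net_stats[str(group)] = stats
        _write_json(net_stats, out / "network_stats.json")
        finish("network", t0, out / "network_stats.json")
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'network' failed: {exc}") from exc

    # ---- environmental drivers -------------------------------------------
    t0 = time.time()
    try:
        driver_out = {}
        mantel_frames = []
        for group in groups:
            sids = meta.samples_in_group(group)
            sub = table.restrict_samples(sids)
            env = meta.frame.loc[sids, list(meta.env_vars)].astype(float)
            dm_g = beta_mod.bray_curtis(sub)
            screen = env_mod.mantel_screen(
                dm_g, env, n_perm=config.n_perm, seed=config.seed
            )
            screen.insert(0, "group", group)
            mantel_frames.append(screen)
            phys = env[[v for v in env_mod.PHYSICAL_VARS if v in env.columns]]
            chem = env[[v for v in env_mod.CHEMICAL_VARS if v in env.columns]]
            driver_out[str(group)] = env_mod.vpa(dm_g, phys, chem).to_dict()
        pd.concat(mantel_frames).to_csv(out / "mantel.tsv", sep="\t")
        _write_json(driver_out, out / "vpa.json")
        finish("drivers", t0, out / "mantel.tsv", out / "vpa.json")
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"stage 'drivers' failed: {exc}") from exc

    manifest = {
        "config": _config_dict(config),
        "outputs": outputs,
        "stages": stages,
    }
    _write_json(manifest, out / "manifest.json")
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    if config.design is not None:
        d["design"] = asdict(config.design)
    return d
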