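"""Pipeline orchestration: configuration, seeding, stage wiring, manifests.

A run executes simulate -> (EC filter) -> structure -> ancestry -> gwas from
a single YAML config and a single global seed.  Every stochastic stage gets
a stable sub-seed derived from (global seed, stage tag), so the 50-iteration
designs are reproducible yet use distinct streams.  Stages communicate only
through serialized artifacts (VCF/TSV/JSON/newick/BED) under the output
directory; the manifest records config hash, seeds and per-stage outputs and
is written atomically at the end of the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, ancestry, gwas, simpop, structure, vcfio
from .errors import ConfigurationError

__all__ = ["RunConfig", "RunManifest", "load_config", "save_config", "run_pipeline"]

log = logging.getLogger("sebpop")

_STAGES = ("simulate", "structure", "ancestry", "gwas")


@dataclass
class RunConfig:
    """Validated run configuration with all defaults materialized."""

    out_dir: str
    seed: int = 0
    log_level: str = "INFO"
    ec_filter: bool = False
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    # simulate block: either a generator preset or imported files
    sim: dict = field(default_factory=dict)
    import_paths: dict | None = None
    structure_params: dict = field(default_factory=dict)
    ancestry_params: dict = field(default_factory=dict)
    gwas_params: dict = field(default_factory=dict)

    _SIM_KEYS = {
        "n_scale", "L", "groups", "missing_rate", "mismatch_rate",
        "n_autosomes", "include_x", "F_anc", "drift",
    }
    _STRUCTURE_KEYS = {"n_pcs", "ld_r2", "ld_window", "ld_step", "mantel_perms"}
    _ANCESTRY_KEYS = {
        "n_boot", "subsample", "posterior_min", "sd_mult", "min_snps",
        "excl_bp", "fold_min", "afs_subsample",
    }
    _GWAS_KEYS = {"scenarios", "n_iter", "n_pcs", "maf_min", "suggestive"}

    def __post_init__(self):
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ConfigurationError(f"unknown stages: {unknown}")
        for block, allowed in (
            (self.sim, self._SIM_KEYS),
            (self.structure_params, self._STRUCTURE_KEYS),
            (self.ancestry_params, self._ANCESTRY_KEYS),
            (self.gwas_params, self._GWAS_KEYS),
        ):
            bad = set(block) - allowed
            if bad:
                raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        if self.import_paths is not None:
            for key in ("vcf", "samples"):
                if key not in self.import_paths:
                    raise ConfigurationError(f"import_paths needs {key!r}")
                if not os.path.exists(self.import_paths[key]):
                    raise ConfigurationError(
                        f"import path does not exist: {self.import_paths[key]}"
                    )

    def stage_seed(self, tag: str) -> int:
        """Stable sub-seed for one stage, below 2**31."""
        return int(
            np.random.SeedSequence(
                (self.seed, zlib.crc32(tag.encode()))
            ).generate_state(1)[0]
            & 0x7FFFFFFF
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seeds: dict
    outputs: dict
    status: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_TOP_KEYS = {
    "out_dir", "seed", "log_level", "ec_filter", "stages", "sim",
    "import_paths", "structure_params", "ancestry_params", "gwas_params",
}


def load_config(path: str | os.PathLike) -> RunConfig:
    """Parse, default-fill and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if "out_dir" not in raw:
        raise ConfigurationError("config requires out_dir")
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, out: Path):
    if config.import_paths is not None:
        dataset, la = vcfio.import_dataset(
            config.import_paths["vcf"],
            config.import_paths["samples"],
            config.import_paths.get("local_ancestry"),
        )
        sim_cfg = None
        truth = None
    else:
        p = dict(config.sim)
        chroms = simpop.default_chromosomes(
            n_autosomes=p.pop("n_autosomes", 4), include_x=p.pop("include_x", True)
        )
        drift = p.pop("drift", 0.003)
        groups_spec = p.pop("groups", None)
        if groups_spec is None:
            groups = simpop.default_groups(n_scale=p.pop("n_scale", 0.05), drift=drift)
        else:
            p.pop("n_scale", None)
            groups = [simpop.GroupSpec(**g) for g in groups_spec]
        sim_cfg = simpop.SimConfig(
            groups=groups,
            chroms=chroms,
            L=p.pop("L", 5000),
            F_anc=p.pop("F_anc", simpop.DEFAULT_F_ANC),
            seed=config.stage_seed("simulate"),
            **p,
        )
        dataset, la, truth = simpop.simulate_genotypes(sim_cfg)
    paths = vcfio.export_dataset(dataset, la, out / "simulate")
    return dataset, la, truth, paths


def _stage_structure(config: RunConfig, dataset, out: Path, groups_geo):
    p = config.structure_params
    out_dir = out / "structure"
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = dataset.samples["group"].to_numpy()
    kept = structure.ld_prune(
        dataset.G,
        r2_threshold=p.get("ld_r2", 0.5),
        window=p.get("ld_window", 50),
        step=p.get("ld_step", 5),
        chrom=dataset.variants.chrom,
    )
    auto = kept[~dataset.variants.is_x[kept]]
    pca = structure.genotype_pca(dataset.G[:, auto], n_pcs=p.get("n_pcs", 10))
    pd.DataFrame(
        pca.coords, columns=[f"PC{i+1}" for i in range(pca.coords.shape[1])]
    ).assign(id=dataset.samples["id"], group=labels).to_csv(
        out_dir / "pcs.tsv", sep="\t", index=False
    )
    names = [g for g in dict.fromkeys(labels.tolist())]
    outputs = {"pcs": str(out_dir / "pcs.tsv")}
    results = {}
    if len(names) >= 2:
        dm = structure.pairwise_fst_matrix(dataset.G[:, auto], labels, names)
        pd.DataFrame(dm.D, index=names, columns=names).to_csv(
            out_dir / "fst.tsv", sep="\t"
        )
        tree = structure.upgma_tree(dm.floored())
        (out_dir / "upgma.nwk").write_text(tree.newick() + "\n")
        outputs["fst"] = str(out_dir / "fst.tsv")
        outputs["upgma"] = str(out_dir / "upgma.nwk")
        if len(names) >= 3 and groups_geo:
            geo = [groups_geo[g] for g in names if g in groups_geo]
            if len(geo) == len(names):
                gd = np.zeros((len(names), len(names)))
                for i in range(len(names)):
                    for j in range(i + 1, len(names)):
                        gd[i, j] = gd[j, i] = structure.great_circle_distance(
                            structure.GeoPoint(*geo[i]), structure.GeoPoint(*geo[j])
                        )
                n_perm = p.get("mantel_perms", 9999)
                mres = structure.mantel_test(
                    dm.floored(),
                    structure.DistanceMatrix(labels=names, D=gd),
                    n_perm=n_perm,
                    seed=config.stage_seed("mantel"),
                )
                group_pc = np.vstack(
                    [pca.coords[labels == g, :2].mean(axis=0) for g in names]
                )
                pres = structure.procrustes_test(
                    np.array([[lon, lat] for lat, lon in geo]),
                    group_pc,
                    n_perm=n_perm,
                    seed=config.stage_seed("procrustes"),
                )
                results = {
                    "mantel": {"r": mres.r, "p": mres.p, "n_perm": mres.n_perm},
                    "procrustes": {
                        "m2": pres.m2, "r": pres.r, "r2": pres.r2,
                        "p": pres.p, "n_perm": pres.n_perm,
                    },
                    "seed": {
                        "mantel": config.stage_seed("mantel"),
                        "procrustes": config.stage_seed("procrustes"),
                    },
                }
                (out_dir / "geography.json").write_text(json.dumps(results, indent=2))
                outputs["geography"] = str(out_dir / "geography.json")
    return outputs


def _stage_ancestry(config: RunConfig, dataset, la, anc_freqs, out: Path):
    p = config.ancestry_params
    out_dir = out / "ancestry"
    out_dir.mkdir(parents=True, exist_ok=True)
    auto = ~dataset.variants.is_x
    xsel = dataset.variants.is_x
    ploidy_x = np.where(dataset.samples["sex"].to_numpy() == "M", 1, 2)
    sub_auto = simpop.AncestralFrequencies(
        freq=anc_freqs.freq[:, auto], ancestries=anc_freqs.ancestries
    )
    Q_auto = ancestry.estimate_ancestry_supervised(dataset.G[:, auto], sub_auto)
    outputs = {}
    qdf = pd.DataFrame(Q_auto.Q, columns=list(anc_freqs.ancestries or []) or None)
    qdf.insert(0, "id", dataset.samples["id"])
    qdf.to_csv(out_dir / "q_autosomal.tsv", sep="\t", index=False)
    outputs["q_autosomal"] = str(out_dir / "q_autosomal.tsv")
    stats_block = {}
    if xsel.any():
        sub_x = simpop.AncestralFrequencies(
            freq=anc_freqs.freq[:, xsel], ancestries=anc_freqs.ancestries
        )
        Q_x = ancestry.estimate_ancestry_supervised(
            dataset.G[:, xsel], sub_x, ploidy=ploidy_x, scope="X"
        )
        groups = dataset.samples["group"].to_numpy()
        rows = {}
        for g in dict.fromkeys(groups.tolist()):
            idx = np.flatnonzero(groups == g)
            if len(idx) < p.get("subsample", 20):
                continue
            res = ancestry.bootstrap_delta_admix(
                Q_auto, Q_x, idx,
                n_boot=p.get("n_boot", 50),
                subsample=p.get("subsample", 20),
                seed=config.stage_seed(f"delta_admix:{g}"),
            )
            rows[g] = {
                "ancestries": res.ancestries,
                "point": [None if np.isnan(v) else float(v) for v in res.point],
                "se": [float(v) for v in res.se],
                "n_boot": res.n_boot,
                "subsample": res.subsample,
            }
        stats_block["delta_admix"] = rows
    if la is not None:
        regions = ancestry.khoesan_enrichment_scan(
            la,
            ancestry_index=1,
            posterior_min=p.get("posterior_min", 0.8),
            sd_mult=p.get("sd_mult", 3.0),
            min_snps=p.get("min_snps", 3),
            excl_bp=p.get("excl_bp", 2_000_000),
        )
        (out_dir / "ks_enrichment.bed").write_text(ancestry.regions_to_bed(regions))
        outputs["ks_enrichment"] = str(out_dir / "ks_enrichment.bed")
        stats_block["n_enrichment_regions"] = len(regions)
    (out_dir / "ancestry_stats.json").write_text(json.dumps(stats_block, indent=2))
    outputs["stats"] = str(out_dir / "ancestry_stats.json")
    return outputs


def _stage_gwas(config: RunConfig, dataset, out: Path):
    p = config.gwas_params
    out_dir = out / "gwas"
    out_dir.mkdir(parents=True, exist_ok=True)
    scenarios = p.get("scenarios")
    if scenarios is None:
        site = dataset.samples["site"].mode().iat[0]
        n_site = int((dataset.samples["site"] == site).sum())
        n_half = max(2, n_site // 2 - 1)
        scenarios = [
            {
                "name": "random-labels",
                "scheme": "category4",
                "params": {"site": site, "n_case": n_half, "n_control": n_half},
            }
        ]
    reports, summary, qq = gwas.run_gwas_suite(
        dataset,
        scenarios,
        n_iter=p.get("n_iter", 5),
        seed=config.stage_seed("gwas"),
        n_pcs=p.get("n_pcs", 3),
        maf_min=p.get("maf_min", 0.05),
        collect_qq=True,
    )
    summary.to_csv(out_dir / "inflation_summary.tsv", sep="\t", index=False)
    (out_dir / "inflation_reports.json").write_text(
        json.dumps([dataclasses.asdict(r) for r in reports], indent=2, default=float)
    )
    for name, frame in qq.items():
        frame.to_csv(out_dir / f"qq_{name}.tsv", sep="\t")
    return {
        "summary": str(out_dir / "inflation_summary.tsv"),
        "reports": str(out_dir / "inflation_reports.json"),
    }


def run_pipeline(config: RunConfig, dry_run: bool = False) -> RunManifest:
    """Execute the enabled stages in order and write the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    seeds = {s: config.stage_seed(s) for s in config.stages}
    if dry_run:
        log.info("dry run: stages %s", config.stages)
        return RunManifest(
            config_hash=config_hash(config),
            version=__version__,
            seeds=seeds,
            outputs={"planned_stages": list(config.stages)},
            status={s: "planned" for s in config.stages},
        )
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    outputs: dict = {}
    status: dict = {}
    dataset = la = truth = None
    anc_freqs = None
    for stage in _STAGES:
        if stage not in config.stages:
            status[stage] = "disabled"
            continue
        try:
            if stage == "simulate":
                dataset, la, truth, paths = _stage_simulate(config, out)
                anc_freqs = _rebuild_ancestral_frequencies(config, dataset)
                if config.ec_filter:
                    mask = simpop.ec_mask(dataset.samples)
                    keep = np.flatnonzero(mask)
                    dataset = dataset.subset_samples(keep)
                    if la is not None:
                        hap = np.sort(np.concatenate([2 * keep, 2 * keep + 1]))
                        la = simpop.LocalAncestryMatrix(
                            A=la.A[hap], P=la.P[hap], K=la.K, variants=la.variants
                        )
                    log.info("EC filter retained %d samples", dataset.n)
                outputs[stage] = paths
            elif stage == "structure":
                if dataset is None:
                    raise ConfigurationError("structure stage needs simulate outputs")
                geo = _group_geo(config)
                outputs[stage] = _stage_structure(config, dataset, out, geo)
            elif stage == "ancestry":
                if dataset is None or anc_freqs is None:
                    raise ConfigurationError("ancestry stage needs simulate outputs")
                outputs[stage] = _stage_ancestry(config, dataset, la, anc_freqs, out)
            elif stage == "gwas":
                if dataset is None:
                    raise ConfigurationError("gwas stage needs simulate outputs")
                outputs[stage] = _stage_gwas(config, dataset, out)
            status[stage] = "ok"
        except Exception as exc:  # stage failure: record, skip dependents
            log.error("stage %s failed: %s", stage, exc)
            status[stage] = f"failed: {exc}"
            break
    manifest = RunManifest(
        config_hash=config_hash(config),
        version=__version__,
        seeds=seeds,
        outputs=outputs,
        status=status,
    )
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest.to_dict(), indent=2))
    tmp.replace(out / "manifest.json")
    return manifest


def _rebuild_ancestral_frequencies(config: RunConfig, dataset):
    """Re-derive the truth ancestral frequency panel used by the simulator.

    The supervised estimator needs the ancestral panel; for simulated runs it
    is reproducible from the simulate-stage seed.  Imported datasets carry no
    truth panel, so ancestry estimation is skipped for them.
    """
    if config.import_paths is not None:
        return None
    p = dict(config.sim)
    K = len(p.get("F_anc", simpop.DEFAULT_F_ANC))
    ss = np.random.SeedSequence(config.stage_seed("simulate"))
    rng_freq = np.random.default_rng(ss.spawn(5)[0])
    return simpop.draw_ancestral_frequencies(
        K,
        dataset.L,
        p.get("F_anc", simpop.DEFAULT_F_ANC),
        tuple(p.get("base_freq_range", (0.05, 0.95))),
        variant_map=dataset.variants,
        seed=rng_freq,
    )


def _group_geo(config: RunConfig) -> dict:
    groups_spec = config.sim.get("groups")
    if groups_spec:
        return {
            g["name"]: tuple(g["geo"]) for g in groups_spec if g.get("geo") is not None
        }
    return {g.name: g.geo for g in simpop.default_groups()}
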