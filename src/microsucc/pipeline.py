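"""End-to-end orchestration: simulate/load -> validate -> beta diversity ->
succession -> cluster/assign -> project -> select, with a machine-readable
run manifest.

Configuration is a single flat ``key = value`` text file (``#`` comments
allowed); every key has a documented default in :data:`CONFIG_DEFAULTS`, and
the manifest records resolved parameters, seeds, input digests and headline
numbers, which together suffice to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as msio
from . import matching, metrics, projection, selection, simulate, succession
from .errors import SchemaError

logger = logging.getLogger("microsucc.pipeline")

CONFIG_DEFAULTS: dict[str, object] = {
    # inputs: leave blank to simulate
    "counts": "",
    "meta": "",
    "asv_fasta": "",
    "genomes_fasta": "",
    "pathways": "",
    "subsystems": "",
    # synthetic generator
    "seed": 0,
    "n_taxa": 80,
    "n_pathways": 100,
    "depth": 20000,
    "n_replicates": 5,
    "effect_size": 0.6,
    "base_p": 0.3,
    "overdispersion": 200.0,
    # analysis
    "substrate": "polyp",
    "metric": "bray_curtis",
    "permutations": 999,
    "identity_threshold": 0.97,
    "min_abund": 5e-5,
    "subsystem_threshold": 0.5,
    "n_repeats": 10,
    "n_trees": 500,
    "max_iter": 100,
    "alpha": 0.01,
    "cv_k": 5,
    # output
    "outdir": "pipeline_out",
}


@dataclass
class RunConfig:
    values: dict[str, object] = field(default_factory=dict)

    def __getitem__(self, key: str):
        return self.values[key]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        values = dict(CONFIG_DEFAULTS)
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise SchemaError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in CONFIG_DEFAULTS:
                raise SchemaError(f"{path}:{lineno}: unknown config key {key!r}")
            default = CONFIG_DEFAULTS[key]
            if isinstance(default, bool):
                values[key] = val.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                values[key] = int(val)
            elif isinstance(default, float):
                values[key] = float(val)
            else:
                values[key] = val
        return cls(values=values).validate()

    @classmethod
    def from_dict(cls, overrides: dict[str, object] | None = None) -> "RunConfig":
        values = dict(CONFIG_DEFAULTS)
        for key, val in (overrides or {}).items():
            if key not in CONFIG_DEFAULTS:
                raise SchemaError(f"unknown config key {key!r}")
            values[key] = val
        return cls(values=values).validate()

    def validate(self) -> "RunConfig":
        v = self.values
        if not 0.5 < float(v["identity_threshold"]) <= 1.0:
            raise SchemaError("identity_threshold must be in (0.5, 1]")
        if not 0.0 <= float(v["min_abund"]) < 1.0:
            raise SchemaError("min_abund must be in [0, 1)")
        if float(v["subsystem_threshold"]) < 0:
            raise SchemaError("subsystem_threshold must be >= 0")
        if int(v["permutations"]) < 1:
            raise SchemaError("permutations must be >= 1")
        if v["metric"] not in metrics.METRICS:
            raise SchemaError(f"metric must be one of {metrics.METRICS}")
        if v["substrate"] not in msio.SUBSTRATES:
            raise SchemaError(f"substrate must be one of {msio.SUBSTRATES}")
        return self


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _StageTimer:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage %s: done in %.1fs", self.name, dt)
        else:
            logger.error("stage %s: FAILED after %.1fs: %s", self.name, dt, exc)
        return False


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order and write a manifest.

    Returns the manifest dict; every stage's outputs land under
    ``config["outdir"]``.  Errors abort with the stage name attached.
    """
    cfg = config.validate().values
    outdir = Path(str(cfg["outdir"]))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "parameters": {k: cfg[k] for k in CONFIG_DEFAULTS},
        "seeds": {"master": seed},
        "stages": {},
        "headline": {},
    }

    def record(stage: str, **paths):
        manifest["stages"][stage] = {k: str(p) for k, p in paths.items()}

    try:
        stage = "simulate"
        with _StageTimer(stage):
            if cfg["counts"]:
                table = msio.read_community_table(cfg["counts"], cfg["meta"])
                asv_seqs = msio.read_fasta(cfg["asv_fasta"])
                genome_seqs = msio.read_fasta(cfg["genomes_fasta"])
                pp = msio.read_pathway_presence(
                    cfg["pathways"], cfg["subsystems"] or None
                )
                truth = None
                manifest["inputs"] = {
                    k: {"path": str(cfg[k]), "sha256": _digest(Path(str(cfg[k])))}
                    for k in ("counts", "meta", "asv_fasta", "genomes_fasta", "pathways")
                    if cfg[k]
                }
                record(stage)
            else:
                spec = simulate.default_truth(
                    seed=seed,
                    n_taxa=int(cfg["n_taxa"]),
                    n_pathways=int(cfg["n_pathways"]),
                    effect_size=float(cfg["effect_size"]),
                    base_p=float(cfg["base_p"]),
                    overdispersion=float(cfg["overdispersion"]),
                )
                exp = simulate.generate_experiment(
                    spec,
                    n_replicates=int(cfg["n_replicates"]),
                    depth=int(cfg["depth"]),
                )
                paths = simulate.write_experiment(exp, outdir / "synthetic")
                table, pp = exp.table, exp.pathways
                asv_seqs, genome_seqs = exp.asv_seqs, exp.genome_seqs
                truth = exp.truth
                record(stage, **paths)

        stage = "validate"
        with _StageTimer(stage):
            table.validate()
            pp.validate()
            record(stage)

        stage = "betadiv"
        with _StageTimer(stage):
            sub = table.subset_substrate(str(cfg["substrate"]), keep_inoculum=False)
            rel = metrics.relative_abundance(sub)
            dm = metrics.distance_matrix(rel, str(cfg["metric"]))
            dm.to_frame().to_csv(outdir / "distance_matrix.tsv", sep="\t")
            ord_res = metrics.pcoa(dm, n_axes=min(2, dm.n - 1))
            ord_res.coordinates.to_csv(outdir / "ordination.tsv", sep="\t")
            m = sub.meta.loc[rel.index]
            stats_rows = []
            for factor, groups in (
                ("dpr", m["timepoint"].astype(str).to_numpy()),
                ("inoculum", m["inoculum"].to_numpy()),
            ):
                per = metrics.permanova(
                    dm, groups, n_permutations=int(cfg["permutations"]), seed=seed
                )
                ano = metrics.anosim(
                    dm, groups, n_permutations=int(cfg["permutations"]), seed=seed
                )
                stats_rows.append(
                    (factor, per.statistic, per.effect, per.p_value,
                     ano.statistic, ano.p_value)
                )
                manifest["headline"][f"permanova_r2_{factor}"] = per.effect
            pd.DataFrame(
                stats_rows,
                columns=["factor", "pseudo_f", "r2", "p", "anosim_r", "anosim_p"],
            ).to_csv(outdir / "stats.tsv", sep="\t", index=False)
            pw = metrics.pairwise_permanova(
                dm, m["inoculum"].to_numpy(),
                n_permutations=int(cfg["permutations"]), seed=seed,
            )
            pw.to_csv(outdir / "pairwise_permanova.tsv", sep="\t", index=False)
            record(
                stage,
                distance_matrix=outdir / "distance_matrix.tsv",
                ordination=outdir / "ordination.tsv",
                stats=outdir / "stats.tsv",
                pairwise=outdir / "pairwise_permanova.tsv",
            )

        stage = "succession"
        with _StageTimer(stage):
            wtab = table.subset_substrate(str(cfg["substrate"]), keep_inoculum=True)
            wrel = metrics.relative_abundance(wtab)
            prof = succession.succession_profile(
                wrel, wtab.meta, min_abund=float(cfg["min_abund"])
            )
            (outdir / "filtered_asvs.txt").write_text("\n".join(prof.asv_ids) + "\n")
            prof.scaled.to_csv(outdir / "scaled_matrix.tsv", sep="\t")
            (outdir / "row_order.txt").write_text("\n".join(prof.order) + "\n")
            pd.Series(prof.class_of, name="class").rename_axis("asv").to_csv(
                outdir / "classes.tsv", sep="\t"
            )
            manifest["headline"]["n_core_asvs"] = len(prof.asv_ids)
            manifest["headline"]["n_early"] = sum(
                1 for c in prof.class_of.values() if c == "early"
            )
            manifest["headline"]["n_late"] = sum(
                1 for c in prof.class_of.values() if c == "late"
            )
            record(
                stage,
                filtered=outdir / "filtered_asvs.txt",
                scaled=outdir / "scaled_matrix.tsv",
                order=outdir / "row_order.txt",
                classes=outdir / "classes.tsv",
            )

        stage = "cluster"
        with _StageTimer(stage):
            cmap = matching.greedy_cluster(
                asv_seqs, threshold=float(cfg["identity_threshold"])
            )
            cmap = matching.assign_genomes(genome_seqs, cmap)
            pd.Series(cmap.cluster_of_asv, name="cluster").rename_axis("asv").to_csv(
                outdir / "clusters.tsv", sep="\t"
            )
            rows = [
                (g, c) for c, gs in cmap.genomes_of.items() for g in gs
            ] + [(g, "") for g in cmap.unassigned_genomes]
            pd.DataFrame(rows, columns=["genome", "cluster"]).to_csv(
                outdir / "genome_clusters.tsv", sep="\t", index=False
            )
            manifest["headline"]["n_clusters"] = len(cmap.clusters)
            record(
                stage,
                clusters=outdir / "clusters.tsv",
                genome_clusters=outdir / "genome_clusters.tsv",
            )

        stage = "project"
        with _StageTimer(stage):
            crel = projection.aggregate_to_clusters(rel, cmap)
            pa = projection.project_pathways(crel, pp, cmap)
            pa.A.to_csv(outdir / "pathway_abundance.tsv", sep="\t")
            pa.coverage.to_csv(outdir / "coverage.tsv", sep="\t")
            tc = projection.pathway_timecourse(
                pa, sub.meta, list(pa.A.index[: min(20, pa.A.shape[0])])
            )
            tc.to_csv(outdir / "timecourse.tsv", sep="\t", index=False)
            manifest["headline"]["mean_coverage"] = float(pa.coverage.mean())
            record(
                stage,
                abundance=outdir / "pathway_abundance.tsv",
                coverage=outdir / "coverage.tsv",
                timecourse=outdir / "timecourse.tsv",
            )

        stage = "select"
        with _StageTimer(stage):
            res = selection.select_pathways(
                pa.A,
                sub.meta,
                pp.subsystem_of,
                n_repeats=int(cfg["n_repeats"]),
                seed=seed,
                n_trees=int(cfg["n_trees"]),
                max_iter=int(cfg["max_iter"]),
                alpha=float(cfg["alpha"]),
                k=int(cfg["cv_k"]),
                subsystem_threshold=float(cfg["subsystem_threshold"]),
            )
            sel = pd.DataFrame(
                {
                    "decision": pd.Series(res.decision),
                    "importance": pd.Series(res.importance),
                    "lfc_late_vs_early": pd.Series(res.lfc),
                }
            ).rename_axis("pathway")
            sel.to_csv(outdir / "selection.tsv", sep="\t")
            pd.Series(res.subsystem_score, name="score").rename_axis(
                "subsystem"
            ).to_csv(outdir / "subsystem_scores.tsv", sep="\t")
            report = {
                "n_repeats": res.n_repeats,
                "seed": res.seed,
                "repeat_seeds": [r.seed for r in res.per_repeat],
                "n_consistent": len(res.consistent_set),
                "consistent_set": res.consistent_set,
                "cv_accuracy": res.cv_accuracy,
                "importance_scale": "impurity importance, per-repeat max = 1",
                "lfc_sign": "log2(mean_late / mean_early); early-enriched < 0",
            }
            (outdir / "selection_report.json").write_text(json.dumps(report, indent=1))
            manifest["headline"]["n_consistent_pathways"] = len(res.consistent_set)
            manifest["headline"]["cv_accuracy"] = res.cv_accuracy
            record(
                stage,
                selection=outdir / "selection.tsv",
                subsystem_scores=outdir / "subsystem_scores.tsv",
                report=outdir / "selection_report.json",
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
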