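"""End-to-end orchestration: simulate -> DE -> DM -> dominant -> integrate
-> enrich -> classify, with reproducible, checksummed artifacts.

Every table written by the pipeline carries a comment header recording the
package version, the seed and a hash of the configuration, and a run
manifest (JSON) lists every artifact with its SHA-256 checksum so a rerun
can be verified bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import build_views, incremental_selection, rank_importance
from .diffexpr import call_degs, fit_moderated_de
from .enrichment import GeneSetCollection, ora_hypergeometric
from .integration import intersect_groups, region_distribution
from .methylation import (
    DOMINANT_TOL,
    aggregate_gene_beta,
    aggregate_region_beta,
    call_dmgs,
    find_dominant_regions,
    region_delta_beta,
)
from .synthetic import INTERGENIC, CohortConfig, generate_cohort, write_study

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class ChecksumMismatchError(RuntimeError):
    """An artifact's checksum does not match the run manifest."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and classifier settings for one pipeline run."""

    outdir: str = "methdx_run"
    expression: str | None = None
    beta: str | None = None
    annotation: str | None = None
    samples: str | None = None
    gmt: str | None = None
    simulate: dict | None = None  # CohortConfig fields; triggers simulation
    alpha_de: float = 0.05
    lfc: float = 0.2
    alpha_dm: float = 0.05
    deciles: tuple[float, float] = (0.1, 0.9)
    tol: float = DOMINANT_TOL
    n_trees: int = 500
    max_k: int | None = None
    nested: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.alpha_de <= 1 and 0 <= self.alpha_dm <= 1):
            raise ValueError("alpha thresholds must lie in [0, 1]")
        if not (0 <= self.deciles[0] < self.deciles[1] <= 1):
            raise ValueError("deciles must satisfy 0 <= lo < hi <= 1")
        if self.lfc < 0 or self.tol <= 0:
            raise ValueError("lfc must be >= 0 and tol > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "deciles" in raw:
            raw["deciles"] = tuple(raw["deciles"])
        return cls(**raw)

    def snapshot(self) -> dict:
        snap = dataclasses.asdict(self)
        snap["deciles"] = list(self.deciles)
        return snap

    def digest(self) -> str:
        # outdir is excluded so reruns into different directories remain
        # bit-identical and checksum-comparable.
        snap = {k: v for k, v in self.snapshot().items() if k != "outdir"}
        return hashlib.sha256(json.dumps(snap, sort_keys=True).encode()).hexdigest()[:12]


def _header(config: PipelineConfig) -> str:
    return f"# methdx {__version__} seed={config.seed} config={config.digest()}\n"


def write_table(df: pd.DataFrame, path: Path, config: PipelineConfig, **to_csv) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep=to_csv.pop("sep", "\t"), **to_csv)


def read_table(path: str | Path, **kw) -> pd.DataFrame:
    kw.setdefault("sep", "\t")
    kw.setdefault("comment", "#")
    return pd.read_csv(path, **kw)


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def verify_manifest(manifest_path: str | Path) -> None:
    """Re-hash every artifact listed in a run manifest; raise on mismatch."""
    manifest = json.loads(Path(manifest_path).read_text())
    base = Path(manifest_path).parent
    for name, entry in manifest["artifacts"].items():
        path = base / entry["path"]
        digest = sha256_file(path)
        if digest != entry["sha256"]:
            raise ChecksumMismatchError(
                f"{name} ({path}): sha256 {digest} != manifest {entry['sha256']}"
            )


def _read_inputs(config: PipelineConfig, outdir: Path):
    if config.simulate is not None:
        cohort_cfg = CohortConfig(**{**config.simulate, "seed": config.seed})
        study = generate_cohort(cohort_cfg)
        write_study(study, outdir / "simulated")
        expr = study.expression
        beta = study.beta
        annot = study.annotation
        labels = study.samples
        meth_labels = study.meth_samples
    else:
        for name in ("expression", "beta", "annotation", "samples"):
            if getattr(config, name) is None:
                raise StageError(f"inputs: missing required path {name!r}")
        expr = read_table(config.expression, index_col=0)
        beta = read_table(config.beta, index_col=0)
        annot = read_table(config.annotation, keep_default_na=False)
        sheet = pd.read_csv(config.samples, comment="#")
        labels = sheet.set_index("sample_id")["group"]
        meth_labels = labels
    return expr, beta, annot, labels, meth_labels


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; write artifacts + run manifest; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def record(name: str, path: Path) -> None:
        artifacts[name] = path

    stage = "inputs"
    try:
        expr, beta, annot, labels, meth_labels = _read_inputs(config, outdir)

        stage = "de"
        de_table = fit_moderated_de(expr, labels)
        up, down = call_degs(de_table, config.alpha_de, config.lfc)
        de_table["direction"] = "none"
        de_table.loc[sorted(up), "direction"] = "up"
        de_table.loc[sorted(down), "direction"] = "down"
        de_path = outdir / "de_table.tsv"
        write_table(de_table, de_path, config)
        record("de_table", de_path)

        stage = "dm"
        gene_beta = aggregate_gene_beta(beta, annot)
        region_beta = aggregate_region_beta(beta, annot)
        intergenic_probes = annot.loc[annot["region"] == INTERGENIC, "probe_id"]
        intergenic_beta = beta.loc[beta.index.intersection(intergenic_probes)]
        dm_table = call_dmgs(
            gene_beta, intergenic_beta, meth_labels, config.alpha_dm, config.deciles
        )
        hypo = set(dm_table.index[dm_table["call"] == "hypo"])
        hyper = set(dm_table.index[dm_table["call"] == "hyper"])
        dm_path = outdir / "dm_table.tsv"
        write_table(dm_table, dm_path, config)
        record("dm_table", dm_path)

        stage = "dominant"
        region_delta = region_delta_beta(region_beta, meth_labels)["delta_beta"]
        dominant: dict[str, tuple[str, ...]] = {}
        for direction, gene_set in (("hypo", hypo), ("hyper", hyper)):
            sub = region_delta.loc[region_delta.index.get_level_values(0).isin(gene_set)]
            if len(sub):
                dominant.update(find_dominant_regions(sub, direction, config.tol))
        dom_rows = [
            {"gene": g, "regions": ";".join(r),
             "extreme_delta_beta": float(region_delta.loc[g].min() if g in hypo
                                         else region_delta.loc[g].max())}
            for g, r in sorted(dominant.items())
        ]
        dom_path = outdir / "dominant_regions.tsv"
        write_table(pd.DataFrame(dom_rows, columns=["gene", "regions", "extreme_delta_beta"]),
                    dom_path, config, index=False)
        record("dominant_regions", dom_path)

        stage = "integrate"
        groups = intersect_groups(up, down, hypo, hyper)
        groups_path = outdir / "groups.json"
        groups_path.write_text(json.dumps(
            {k: sorted(v) for k, v in groups.as_dict().items()}, indent=1))
        record("groups", groups_path)
        q_lo, q_hi = dm_table.attrs["thresholds"]
        region_calls = {
            gene: {r for r, v in region_delta.loc[gene].items()
                   if v < q_lo or v > q_hi}
            for gene in set().union(*groups.as_dict().values())
            if gene in region_delta.index.get_level_values(0)
        }
        grouped_genes = set().union(*groups.as_dict().values())
        if grouped_genes:
            dist = region_distribution(groups, region_calls)
            dist_path = outdir / "region_distribution.tsv"
            write_table(dist, dist_path, config)
            record("region_distribution", dist_path)

        stage = "enrich"
        if config.gmt is not None:
            collection = GeneSetCollection.from_gmt(config.gmt, set(de_table.index))
            for name, genes in (("hypo_up", groups.hypo_up),
                                ("hyper_down", groups.hyper_down)):
                enr = ora_hypergeometric(set(genes), collection, config.alpha_dm)
                enr_path = outdir / f"enrichment_{name}.tsv"
                write_table(enr, enr_path, config)
                record(f"enrichment_{name}", enr_path)

        stage = "classify"
        for name, genes in (("hypo_up", sorted(groups.hypo_up)),
                            ("hyper_down", sorted(groups.hyper_down))):
            if not genes:
                logger.warning("classify: %s group is empty, stage skipped", name)
                continue
            views = build_views(expr, gene_beta, region_beta, dominant, genes)
            for kind, view in views.items():
                if view.matrix.empty:
                    logger.warning("classify: %s/%s view empty, skipped", name, kind)
                    continue
                view_labels = labels if kind == "expression" else meth_labels
                ranking = rank_importance(view, view_labels, config.seed, config.n_trees)
                ranked_genes = list(ranking.index)
                if config.max_k is not None:
                    ranked_genes = ranked_genes[: config.max_k]
                report = incremental_selection(
                    view, ranked_genes, view_labels, config.seed, config.n_trees,
                    nested=config.nested, raw_importance=ranking,
                )
                payload = {
                    "group": name,
                    "kind": kind,
                    "best_k": report.best_k,
                    "auc": report.auc,
                    "auc_p": report.auc_p,
                    "auc_by_k": {str(k): v for k, v in report.auc_by_k.items()},
                    "ranked": report.ranked.reset_index().to_dict(orient="records"),
                    "loo_scores": report.loo_scores.to_dict(),
                }
                rep_path = outdir / f"classifier_{name}_{kind}.json"
                rep_path.write_text(json.dumps(payload, indent=1))
                record(f"classifier_{name}_{kind}", rep_path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the stage name
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.snapshot(),
        "config_hash": config.digest(),
        "artifacts": {
            name: {"path": path.name, "sha256": sha256_file(path)}
            for name, path in artifacts.items()
        },
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), outdir)
    return manifest
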