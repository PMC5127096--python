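"""End-to-end cohort analysis: ingest or simulate, then collapse, diversity,
distances, dendrogram, ordination, cluster validation (whole cohort and per
stratum), group comparisons, correlation network, and the BMI stratification.

Every output file carries a run-metadata header (package version, seed,
config hash) and the run writes a ``manifest.json`` listing everything it
produced; re-running against an unchanged config is a no-op unless forced.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import (
    AbundanceTable,
    TaxonomyMap,
    collapse_to_level,
    prevalence,
    read_metadata,
    read_table,
    to_relative,
    write_metadata,
    write_table,
)
from .clustering import jsd_distance, pam, select_and_validate, upgma
from .diversity import diversity_profile, write_profile
from .ordination import pca_biplot, pcoa
from .simulate import (
    QuestionnaireCoupling,
    SyntheticCohortConfig,
    archetype_composition,
    EnterotypeArchetype,
    default_config,
    generate_cohort,
    study_families,
)
from .stats import bmi_strata_compare, build_network, group_abundance_report

log = logging.getLogger("guttype.pipeline")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "stratify"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    outdir: str = "guttype_out"
    seed: int = 0
    # either synthetic generation ...
    synthetic: SyntheticCohortConfig | None = None
    # ... or files on disk
    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    level: str = "family"
    k_min: int = 2
    k_max: int = 10
    ps_repeats: int = 100
    strata: tuple[str, ...] = ("gender", "region")
    p_threshold: float = 0.001
    tau_threshold: float = 0.2
    alpha: float = 0.05
    bmi_item: str = "Q7"
    network_items: tuple[str, ...] = ()
    compare_by: str | None = "region"
    compare_taxa: tuple[str, ...] | None = None

    def validate(self) -> None:
        if self.synthetic is None and self.counts_path is None:
            raise PipelineError("config: provide either a synthetic block or counts_path")
        for path in (self.counts_path, self.metadata_path, self.taxonomy_path):
            if path is not None and not Path(path).exists():
                raise PipelineError(f"config: input file does not exist: {path}")

    def config_hash(self) -> str:
        doc = self.to_dict()
        doc.pop("outdir", None)  # analytic identity, not output location
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        doc: dict = {
            "outdir": self.outdir,
            "seed": self.seed,
            "level": self.level,
            "k_min": self.k_min,
            "k_max": self.k_max,
            "ps_repeats": self.ps_repeats,
            "strata": list(self.strata),
            "p_threshold": self.p_threshold,
            "tau_threshold": self.tau_threshold,
            "alpha": self.alpha,
            "bmi_item": self.bmi_item,
            "network_items": list(self.network_items),
            "compare_by": self.compare_by,
            "compare_taxa": list(self.compare_taxa) if self.compare_taxa else None,
            "counts_path": self.counts_path,
            "metadata_path": self.metadata_path,
            "taxonomy_path": self.taxonomy_path,
        }
        if self.synthetic is not None:
            sc = self.synthetic
            doc["synthetic"] = {
                "n_samples": sc.n_samples,
                "n_taxa": sc.n_taxa,
                "depth_mean": sc.depth_mean,
                "depth_sd": sc.depth_sd,
                "seed": sc.seed,
                "mixing_proportions": [float(p) for p in sc.mixing_proportions],
                "archetypes": [
                    {
                        "name": a.name,
                        "concentration": a.concentration,
                        "mean_composition": [float(v) for v in a.mean_composition],
                    }
                    for a in sc.archetypes
                ],
                "questionnaire_couplings": [
                    {
                        "item": c.item,
                        "taxa": list(c.taxa),
                        "target_tau": c.target_tau,
                        "levels": c.levels,
                    }
                    for c in sc.questionnaire_couplings
                ],
            }
        return doc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "PipelineConfig":
        doc = dict(doc)
        synthetic = None
        syn = doc.pop("synthetic", None)
        if syn is not None:
            synthetic = _synthetic_from_dict(syn, seed=doc.get("seed", 0))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        for key in ("strata", "network_items", "compare_taxa"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(synthetic=synthetic, **doc)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _synthetic_from_dict(doc, seed: int = 0) -> SyntheticCohortConfig:
    if doc in ("default", True):
        return default_config(seed=seed)
    doc = dict(doc)
    n_taxa = int(doc.get("n_taxa", 66))
    taxa = study_families(n_taxa)
    base = default_config(seed=int(doc.get("seed", seed)))
    archetypes = base.archetypes
    if "archetypes" in doc:
        archetypes = []
        for spec in doc["archetypes"]:
            if "mean_composition" in spec:
                mean = np.asarray(spec["mean_composition"], dtype=float)
            else:
                mean = archetype_composition(spec["dominant"], taxa)
            archetypes.append(
                EnterotypeArchetype(spec["name"], mean, float(spec["concentration"]))
            )
    couplings = base.questionnaire_couplings
    if "questionnaire_couplings" in doc:
        couplings = [
            QuestionnaireCoupling(
                c["item"], tuple(c["taxa"]), float(c["target_tau"]), int(c.get("levels", 5))
            )
            for c in doc["questionnaire_couplings"]
        ]
    mixing = doc.get("mixing_proportions")
    return SyntheticCohortConfig(
        n_samples=int(doc.get("n_samples", base.n_samples)),
        archetypes=archetypes,
        mixing_proportions=np.asarray(mixing, dtype=float) if mixing is not None else None,
        depth_mean=float(doc.get("depth_mean", base.depth_mean)),
        depth_sd=float(doc.get("depth_sd", base.depth_sd)),
        n_taxa=n_taxa,
        metadata_strata=doc.get("metadata_strata", base.metadata_strata),
        questionnaire_couplings=couplings,
        seed=int(doc.get("seed", seed)),
    )


def stratify(metadata: pd.DataFrame, by: str) -> dict[str, list[str]]:
    """Disjoint, exhaustive subsets of samples by a metadata variable.

    Samples with a missing value are placed in no subset (and logged).
    """
    if by not in metadata.columns:
        raise ValueError(f"metadata has no column {by!r}")
    col = metadata[by]
    missing = metadata.index[col.isna()].tolist()
    if missing:
        log.info("stratify(%s): %d samples with missing values excluded", by, len(missing))
    out: dict[str, list[str]] = {}
    for value in pd.unique(col.dropna()):
        out[str(value)] = metadata.index[col == value].tolist()
    return out


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute all stages and return the output manifest (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    cfg_hash = config.config_hash()
    if manifest_path.exists() and not force:
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            previous = None
        if previous and previous.get("config_hash") == cfg_hash:
            log.info("manifest up to date (hash %s); skipping (use force=True to re-run)", cfg_hash)
            return previous

    header = [
        f"guttype {__version__}",
        f"seed {config.seed}",
        f"config {cfg_hash}",
    ]
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": cfg_hash,
        "files": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["files"][name] = str(path)

    def stage(name: str):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                log.info("stage %s done in %.2fs", name, time.perf_counter() - self_inner.t0)

        return _Stage()

    config.to_yaml(outdir / "config.yaml")
    record("config", outdir / "config.yaml")

    with stage("ingest"):
        if config.synthetic is not None:
            cohort = generate_cohort(config.synthetic)
            counts, metadata = cohort.counts, cohort.metadata
            labels_path = outdir / "true_labels.tsv"
            pd.Series(
                cohort.true_labels, index=counts.sample_ids, name="archetype"
            ).to_csv(labels_path, sep="\t")
            record("true_labels", labels_path)
        else:
            counts = read_table(config.counts_path)
            metadata = (
                read_metadata(config.metadata_path)
                if config.metadata_path
                else pd.DataFrame(index=counts.data.index)
            )
        if config.taxonomy_path:
            taxonomy = TaxonomyMap.from_tsv(config.taxonomy_path)
            counts = collapse_to_level(counts, taxonomy, config.level)
        write_table(counts, outdir / "counts.tsv", header_lines=header)
        write_metadata(metadata, outdir / "metadata.tsv", header_lines=header)
        record("counts", outdir / "counts.tsv")
        record("metadata", outdir / "metadata.tsv")

    with stage("relative_abundance"):
        rel = to_relative(counts)
        write_table(rel, outdir / "relative.tsv", header_lines=header)
        record("relative", outdir / "relative.tsv")
        prev = prevalence(counts)
        with open(outdir / "prevalence.tsv", "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            prev.rename("prevalence").to_csv(fh, sep="\t")
        record("prevalence", outdir / "prevalence.tsv")

    with stage("diversity"):
        profile = diversity_profile(counts)
        write_profile(profile, outdir / "diversity.tsv", header_lines=header)
        record("diversity", outdir / "diversity.tsv")

    with stage("distances"):
        dist = jsd_distance(rel)
        dist.to_tsv(outdir / "distance.tsv", header_lines=header)
        record("distance", outdir / "distance.tsv")
        dendro = upgma(dist)
        dendro.write_newick(outdir / "dendrogram.nwk")
        record("dendrogram", outdir / "dendrogram.nwk")

    with stage("ordination"):
        pca = pca_biplot(rel)
        pca.write_coords(outdir / "pca_coords.tsv", header_lines=header)
        pca.write_loadings(outdir / "pca_loadings.tsv", header_lines=header)
        record("pca_coords", outdir / "pca_coords.tsv")
        record("pca_loadings", outdir / "pca_loadings.tsv")
        ord_pcoa = pcoa(dist)
        ord_pcoa.write_coords(outdir / "pcoa_coords.tsv", header_lines=header)
        record("pcoa_coords", outdir / "pcoa_coords.tsv")

    with stage("cluster_validation"):
        def usable_k(n: int) -> list[int]:
            # split-half prediction strength needs k <= n/2
            return [k for k in range(config.k_min, config.k_max + 1) if k <= n // 2]

        k_range = usable_k(dist.n)
        reports = {"whole": select_and_validate(
            dist, k_range, repeats=config.ps_repeats, seed=config.seed
        )}
        part = pam(dist, reports["whole"].best_k)
        partition_path = outdir / "partition.tsv"
        with open(partition_path, "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            pd.Series(part.labels + 1, index=dist.sample_ids, name="cluster").to_csv(
                fh, sep="\t"
            )
        record("partition", partition_path)
        for var in config.strata:
            if var not in metadata.columns:
                continue
            for value, ids in sorted(stratify(metadata, var).items()):
                sub_range = usable_k(len(ids))
                if not sub_range:
                    log.info("stratum %s=%s too small (n=%d); skipped", var, value, len(ids))
                    continue
                sub = dist.subset(ids)
                reports[f"{var}={value}"] = select_and_validate(
                    sub, sub_range, repeats=config.ps_repeats, seed=config.seed
                )
        frames = []
        for name, report in reports.items():
            frame = report.to_frame().rename(columns={"value": name})
            frames.append(frame)
        validation = pd.concat(frames, axis=1)
        with open(outdir / "cluster_validation.tsv", "w") as fh:
            for line in header:
                fh.write(f"# {line}\n")
            validation.to_csv(fh, sep="\t")
        record("cluster_validation", outdir / "cluster_validation.tsv")

    if config.compare_by and config.compare_by in metadata.columns:
        with stage("group_comparison"):
            report = group_abundance_report(
                rel, metadata, by=config.compare_by,
                taxa=list(config.compare_taxa) if config.compare_taxa else None,
                alpha=config.alpha,
            )
            with open(outdir / "group_comparison.tsv", "w") as fh:
                for line in header:
                    fh.write(f"# {line}\n")
                report.to_csv(fh, sep="\t")
            record("group_comparison", outdir / "group_comparison.tsv")

    with stage("correlation_network"):
        items = None
        item_cols = [c for c in config.network_items if c in metadata.columns]
        if not item_cols:
            item_cols = [c for c in metadata.columns if c.startswith("Q")]
        if item_cols:
            items = metadata[item_cols]
        network = build_network(
            rel, items=items,
            p_threshold=config.p_threshold, tau_threshold=config.tau_threshold,
        )
        network.write_tsv(outdir / "network_edges.tsv", header_lines=header)
        record("network_edges", outdir / "network_edges.tsv")

    if "bmi" in metadata.columns:
        with stage("bmi_strata"):
            try:
                report = bmi_strata_compare(rel, metadata, item=config.bmi_item)
            except Exception as exc:  # empty stratum on small runs is not fatal
                log.warning("bmi stratification skipped: %s", exc)
            else:
                with open(outdir / "bmi_comparison.tsv", "w") as fh:
                    for line in header:
                        fh.write(f"# {line}\n")
                    fh.write(
                        f"# lean n={report.attrs['n_lean']}, obese n={report.attrs['n_obese']}\n"
                    )
                    report.to_csv(fh, sep="\t")
                record("bmi_comparison", outdir / "bmi_comparison.tsv")

    record("manifest", manifest_path)
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
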