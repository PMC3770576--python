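"""End-to-end pipeline: genotypes -> network -> scan -> haplogroup calls.

A run is driven by a YAML configuration (see :class:`RunConfig`), executes
missingness handling, haplotype collapsing, network estimation and
resolution, contrast enumeration, the permutation scan per phenotype under
both APOE models, second-round conditional scans for significant contrasts,
and haplogroup classification.  Every output lands in the run directory
together with a machine-readable manifest (seed, config echo, versions) and
a plain-text log; a single global seed fans out to per-stage seeds by
stable hashing so stages are individually reproducible.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genotype_io import (
    collapse_haplotypes,
    handle_missing,
    read_genotype_table,
    read_site_map,
    read_vcf,
)
from .haplogroup import classify_significant_clades, read_rule_table, write_call_report
from .network import (
    build_network,
    enumerate_contrasts,
    resolve_ambiguities,
    score_ancestry,
    write_contrast_table,
    write_dot,
    write_graphml,
)
from .phenotypes import read_subject_table
from .treescan import (
    ScanConfig,
    scan_both_models,
    second_round_scan,
    write_scan_table,
)

logger = logging.getLogger("mtscan")


@dataclass
class RunConfig:
    genotypes: str  # .tsv (with site_map) or .vcf
    subjects: str
    out_dir: str
    site_map: str | None = None
    haplogroup_rules: str | None = None
    phenotypes: list[str] = field(default_factory=lambda: ["y"])
    covariates: tuple[str, ...] = ("age", "sex")
    apoe_column: str = "apoe4"
    n_permutations: int = 10_000
    min_group: int = 5
    alpha: float = 0.05
    max_missing_rate: float = 0.05
    max_connection_steps: int = 10
    nominal_p: str = "analytic"
    permute: str = "freedman_lane"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        for name in ("genotypes", "subjects"):
            p = getattr(cfg, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory.

    Any stage error aborts with the stage name; a partial-results marker is
    left in the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    (out / "PARTIAL").write_text("run in progress\n")
    stage = "setup"
    try:
        stage = "read_inputs"
        if config.genotypes.endswith(".vcf"):
            matrix = read_vcf(config.genotypes)
        else:
            if not config.site_map:
                raise ValueError("tabular genotypes require a site_map path")
            matrix = read_genotype_table(config.genotypes, read_site_map(config.site_map))
        subjects = read_subject_table(config.subjects)

        stage = "handle_missing"
        matrix, missing_report = handle_missing(matrix, config.max_missing_rate)

        stage = "collapse_haplotypes"
        haplotypes = collapse_haplotypes(matrix)
        logger.info(
            "%d individuals collapsed to %d haplotypes",
            matrix.n_individuals,
            len(haplotypes),
        )

        stage = "build_network"
        net = build_network(
            haplotypes, config.max_connection_steps, variants=matrix.variants
        )
        score_ancestry(net)
        resolve_ambiguities(net)
        write_graphml(net, out / "network.graphml", matrix.variants)
        write_dot(net, out / "network.dot", matrix.variants)

        stage = "enumerate_contrasts"
        contrasts = enumerate_contrasts(net, haplotypes)
        write_contrast_table(contrasts, out / "contrasts.tsv")

        stage = "scan"
        summary: dict[str, dict] = {}
        for k, phen in enumerate(config.phenotypes):
            scan_cfg = ScanConfig(
                phenotype=phen,
                covariates=config.covariates,
                n_permutations=config.n_permutations,
                min_group=config.min_group,
                alpha=config.alpha,
                seed=stage_seed(config.seed, f"scan:{phen}"),
                nominal_p=config.nominal_p,
                permute=config.permute,
            )
            reports = scan_both_models(
                contrasts,
                subjects,
                scan_cfg,
                base_covariates=config.covariates,
                apoe_column=config.apoe_column,
            )
            write_scan_table(reports, out / f"scan_{phen}.tsv")
            sig = {
                r.contrast_id for rep in reports.values() for r in rep.significant
            }
            summary[phen] = {"significant_contrasts": sorted(sig)}

            stage = f"second_round:{phen}"
            by_id = {c.contrast_id: c for c in contrasts}
            round2_rows = []
            for cid in sorted(sig):
                rep2 = second_round_scan(by_id[cid], contrasts, subjects, scan_cfg)
                round2_rows.extend(
                    {
                        "contrast": r.contrast_id,
                        "model": r.model_tag,
                        "f": r.f_statistic,
                        "nominal_p": r.nominal_p,
                        "corrected_p": r.corrected_p,
                        "n_a": r.n_a,
                        "n_b": r.n_b,
                    }
                    for r in rep2.results
                )
                round2_rows.extend(
                    {"contrast": cid2, "model": "skipped:" + reason}
                    for cid2, reason in rep2.skipped
                )
            if round2_rows:
                pd.DataFrame(round2_rows).to_csv(
                    out / f"scan2_{phen}.tsv", sep="\t", index=False
                )

            stage = f"haplogroup:{phen}"
            if config.haplogroup_rules:
                rules = read_rule_table(config.haplogroup_rules)
                calls = classify_significant_clades(
                    reports["with_apoe"], contrasts, haplotypes, matrix.variants, rules
                )
                write_call_report(calls, out / f"haplogroups_{phen}.tsv")
                summary[phen]["haplogroup_calls"] = {
                    c.clade_id: sorted(c.candidates) for c in calls
                }

        stage = "manifest"
        manifest = {
            "mtscan_version": __version__,
            "seed": config.seed,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(config).items()
            },
            "n_individuals": matrix.n_individuals,
            "n_sites": matrix.n_sites,
            "n_haplotypes": len(haplotypes),
            "n_dropped": len(missing_report.dropped_ids),
            "n_imputed": missing_report.n_imputed,
            "n_contrasts": len(contrasts),
            "n_ambiguity_loops": len(net.ambiguity_loops),
            "n_unresolved_loops": len(net.unresolved_loops()),
            "phenotypes": summary,
        }
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
        (out / "PARTIAL").unlink()
    except Exception as exc:
        logger.error("pipeline aborted in stage %r: %s", stage, exc)
        (out / "PARTIAL").write_text(f"aborted in stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
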