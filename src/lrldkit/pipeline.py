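"""End-to-end pipeline: filters, APOE strata, association, LD analyses,
structure diagnostics and meta-analysis, driven by one YAML config."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

import lrldkit
from lrldkit.apoe_strata import call_dataset, is_e2_carrier
from lrldkit.association import allelic_assoc_marker, stratified_assoc
from lrldkit.errors import ConfigurationError, LrldkitError
from lrldkit.genotype_io import read_plink
from lrldkit.ld_core import ld_pair
from lrldkit.lrld_scan import (
    bootstrap_null_pvalue,
    e2_association_scan,
    lrld_decision,
    sliding_window_ld,
)
from lrldkit.meta_analysis import meta_analyze, se_from_ci
from lrldkit.population_structure import principal_components, wrights_f

log = logging.getLogger("lrldkit.pipeline")


@dataclass
class PipelineConfig:
    bfile: str
    out_dir: str
    apoe: dict[str, str] | None = None  # {"rs429358": id, "rs7412": id}
    ld_pairs: list[list[str]] = field(default_factory=list)
    scan: dict[str, Any] | None = None
    bootstrap: dict[str, Any] | None = None
    assoc: dict[str, Any] | None = None
    meta_input: str | None = None
    inbreeding: dict[str, Any] | None = None
    pca: dict[str, Any] | None = None

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(PipelineConfig.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "bfile" not in raw or "out_dir" not in raw:
            raise ConfigurationError("config requires 'bfile' and 'out_dir'")
        return PipelineConfig(**raw)


def _write_tsv(df: pd.DataFrame, path: Path, written: list[Path]) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    written.append(path)
    log.info("wrote %s (%d rows)", path, len(df))


def run_pipeline(config: PipelineConfig) -> list[Path]:
    """Run every configured stage; returns the list of written files.

    Any stage error aborts the run with the stage name, after removing
    partial outputs. Identical configs produce identical outputs.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "load"
    try:
        log.info("lrldkit %s", lrldkit.__version__)
        ds = read_plink(config.bfile)
        log.info("loaded %d samples x %d markers", ds.n_samples, ds.n_markers)

        referenced = [m for pair in config.ld_pairs for m in pair]
        if config.apoe:
            referenced += list(config.apoe.values())
        if config.bootstrap:
            referenced += [config.bootstrap["anchor"], config.bootstrap["target"]]
        if config.assoc:
            referenced.append(config.assoc["marker"])
        known = {m.id for m in ds.markers}
        for mid in referenced:
            if mid not in known:
                raise ConfigurationError(f"marker {mid!r} not found in {config.bfile}")

        strata = None
        if config.apoe:
            stage = "apoe"
            diplos, strata = call_dataset(
                ds, config.apoe["rs429358"], config.apoe["rs7412"]
            )
            _write_tsv(
                pd.DataFrame(
                    {
                        "sample_id": [s.id for s in ds.samples],
                        "diplotype": [d.value for d in diplos],
                        "stratum": [s.value for s in strata],
                    }
                ),
                out_dir / "apoe_calls.tsv",
                written,
            )

        if config.ld_pairs:
            stage = "ld_pairs"
            rows = []
            for m1, m2 in config.ld_pairs:
                ld = ld_pair(ds, m1, m2)
                rows.append(
                    {
                        "snp1": m1, "snp2": m2, "n": ld.n_samples, "D": ld.D,
                        "Dprime": ld.dprime, "r2": ld.r2, "chi2": ld.chi2,
                        "p": ld.p, "lrld": lrld_decision(ld),
                    }
                )
            _write_tsv(pd.DataFrame(rows), out_dir / "ld_pairs.tsv", written)

        if config.scan:
            stage = "ld_scan"
            windows = sliding_window_ld(
                ds,
                chrom=str(config.scan["chrom"]),
                window_bp=int(config.scan.get("window_bp", 1_700_000)),
                step_bp=int(config.scan.get("step_bp", 100_000)),
                min_sep_bp=int(config.scan.get("min_sep_bp", 50_000)),
                max_sep_bp=int(config.scan.get("max_sep_bp", 500_000)),
                maf_min=float(config.scan.get("maf_min", 0.2)),
            )
            _write_tsv(
                pd.DataFrame(
                    [
                        {
                            "chrom": w.chrom, "start": w.start_bp, "end": w.end_bp,
                            "n_pairs": w.n_pairs,
                            "mean_abs_dprime": w.mean_abs_dprime,
                            "mean_r2": w.mean_r2,
                        }
                        for w in windows
                    ]
                ),
                out_dir / "ld_scan.tsv",
                written,
            )

        if config.bootstrap:
            stage = "bootstrap_null"
            b = config.bootstrap
            log.info("bootstrap null seed = %s", b.get("seed", 0))
            res = bootstrap_null_pvalue(
                ds,
                anchor=b["anchor"],
                target=b["target"],
                B=int(b.get("B", 10_000)),
                maf_min=float(b.get("maf_min", 0.20)),
                maf_max=float(b.get("maf_max", 0.40)),
                seed=int(b.get("seed", 0)),
            )
            _write_tsv(
                pd.DataFrame([vars(res)]), out_dir / "bootstrap_null.tsv", written
            )

        if config.apoe:
            stage = "e2_scan"
            carrier = np.array([is_e2_carrier(d) for d in diplos])
            if carrier.any() and not carrier.all():
                hits = e2_association_scan(ds, carrier)
                _write_tsv(
                    pd.DataFrame([vars(h) for h in hits]),
                    out_dir / "e2_scan.tsv",
                    written,
                )
            else:
                log.warning("e2 scan skipped: single carrier class")

        if config.assoc:
            stage = "association"
            marker = config.assoc["marker"]
            rows = []
            res = allelic_assoc_marker(ds, marker)
            rows.append({"stratum": "ALL", **vars(res)})
            if config.assoc.get("stratify") and strata is not None:
                for stratum, r in stratified_assoc(ds, marker, strata).items():
                    rows.append({"stratum": stratum.value, **vars(r)})
            _write_tsv(pd.DataFrame(rows), out_dir / "association.tsv", written)

        if config.meta_input:
            stage = "meta_analysis"
            studies = pd.read_csv(config.meta_input, sep="\t")
            effects = [
                se_from_ci(
                    float(row["or"]), float(row["ci_low"]), float(row["ci_high"]),
                    label=str(row["label"]),
                )
                for _, row in studies.iterrows()
            ]
            res = meta_analyze(effects)
            _write_tsv(pd.DataFrame([vars(res)]), out_dir / "meta.tsv", written)

        if config.inbreeding is not None:
            stage = "inbreeding"
            inb = wrights_f(
                ds,
                maf_min=float(config.inbreeding.get("maf_min", 0.2)),
                hwe_p_min=float(config.inbreeding.get("hwe_min", 0.001)),
                sample_call_rate_min=float(
                    config.inbreeding.get("call_rate_min", 0.99)
                ),
            )
            df = pd.DataFrame(inb.per_marker_f, columns=["marker_id", "f"])
            _write_tsv(df, out_dir / "inbreeding_per_marker.tsv", written)
            _write_tsv(
                pd.DataFrame(
                    [
                        {
                            "f_mean": inb.f_mean,
                            "n_markers": inb.n_markers,
                            "n_samples": inb.n_samples,
                        }
                    ]
                ),
                out_dir / "inbreeding.tsv",
                written,
            )

        if config.pca is not None:
            stage = "pca"
            pcs = principal_components(
                ds,
                n_components=int(config.pca.get("n_components", 10)),
                prune_r2=float(config.pca.get("prune_r2", 0.3)),
            )
            df = pd.DataFrame(
                pcs, columns=[f"PC{k + 1}" for k in range(pcs.shape[1])]
            )
            df.insert(0, "sample_id", [s.id for s in ds.samples])
            _write_tsv(df, out_dir / "pca.tsv", written)

        log.info("pipeline complete: %d output files", len(written))
        return written
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise LrldkitError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
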