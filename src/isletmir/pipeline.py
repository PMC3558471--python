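"""End-to-end orchestration: ingest -> preprocess -> SAM -> targets.

``run_pipeline`` executes the stages on one configuration and writes four
artifacts to the output directory:

* ``global_fc_table.tsv``  -- fold change and category for every detected miRNA
* ``sam_table.tsv``        -- significant miRNAs at the selected delta
* ``sam_diagnostics.tsv``  -- per-miRNA mean z, se, d, q, fold change
* ``delta_scan.tsv``       -- the delta grid vs call count and estimated FDR
* ``target_report.tsv``    -- gene-group intersection (optional stage)
* ``manifest.json``        -- config echo, seed, versions, per-stage counts

Counts in the manifest are recomputed from the written artifact files by
:func:`summarize_counts`, so the manifest doubles as a self-audit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from isletmir import __version__, io_ct, preprocess, targets as tg
from isletmir.sam import SamConfig, run_sam

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class PipelineConfig:
    ct_path: str | None = None
    metadata_path: str | None = None
    out_dir: str = "results"
    control_assay: str = "RNU48"
    cutoff_ct: float = preprocess.DEFAULT_CUTOFF_CT
    detection_min: int = 4
    detection_scope: str = "either"
    fc_aggregation: str = "geometric"
    equal_band: tuple[float, float] = preprocess.DEFAULT_EQUAL_BAND
    sam: SamConfig = field(default_factory=SamConfig)
    min_fc: float = 3.0
    db_paths: dict = field(default_factory=dict)  # source name -> path
    db_dialects: dict = field(default_factory=dict)  # source name -> dialect
    groups_dir: str | None = None
    alias_path: str | None = None
    run_targets: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sam_raw = raw.pop("sam", {})
        cfg = cls(**raw)
        cfg.sam = SamConfig(**sam_raw)
        return cfg


@dataclass
class PipelineResult:
    artifacts: dict[str, Path]
    counts: dict[str, int]
    sam_delta: float
    sam_s0: float


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(cfg: PipelineConfig, ct_matrix=None) -> PipelineResult:
    """Run the full analysis; ``ct_matrix`` may be passed directly (e.g. a
    simulated matrix) instead of being read from ``cfg.ct_path``."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if ct_matrix is None:
        if not cfg.ct_path or not cfg.metadata_path:
            raise PipelineError("stage 'ingest' failed: no Ct matrix or paths given")
        ct_matrix = _stage(
            "ingest",
            io_ct.read_ct_table,
            cfg.ct_path,
            cfg.metadata_path,
            control_assays=(cfg.control_assay,),
        )
    n_panel = len(ct_matrix.mirna_assays())
    logger.info("ingest: %d assays x %d samples", len(ct_matrix.assay_ids),
                len(ct_matrix.sample_ids))

    censored = _stage("censor", preprocess.censor_cts, ct_matrix, cfg.cutoff_ct)
    detected = _stage(
        "detection_filter",
        preprocess.detection_filter,
        censored,
        cutoff=cfg.cutoff_ct,
        min_detected=cfg.detection_min,
        scope=cfg.detection_scope,
    )
    logger.info("detection_filter: %d of %d assays retained", len(detected), n_panel)

    dct = _stage("delta_ct", preprocess.delta_ct, censored, cfg.control_assay)
    dct.values = dct.values.loc[detected]
    z = _stage("paired_differences", preprocess.paired_differences, dct)
    fc = _stage(
        "fold_change", preprocess.fold_change, z, cfg.equal_band, cfg.fc_aggregation
    )

    artifacts: dict[str, Path] = {}
    global_path = out_dir / "global_fc_table.tsv"
    _stage("write_global", io_ct.write_global_table, fc, global_path)
    artifacts["global_fc_table"] = global_path

    sam_result = _stage("sam", run_sam, z, fc, cfg.sam)
    logger.info(
        "sam: delta=%.4f s0=%.4f pi0=%.3f -> %d significant",
        sam_result.delta, sam_result.s0, sam_result.null.pi0, len(sam_result.table),
    )
    diag_path = out_dir / "sam_diagnostics.tsv"
    sam_result.diagnostics.to_csv(diag_path, sep="\t", index=False)
    artifacts["sam_diagnostics"] = diag_path
    scan_path = out_dir / "delta_scan.tsv"
    sam_result.delta_scan.to_csv(scan_path, sep="\t", index=False)
    artifacts["delta_scan"] = scan_path
    sam_path = out_dir / "sam_table.tsv"
    if len(sam_result.table):
        _stage("write_sam", io_ct.write_sam_table, sam_result.table, sam_path)
    else:
        sam_path.write_text(
            "\t".join(io_ct.SAM_TABLE_COLUMNS) + "\n", encoding="utf-8"
        )
    artifacts["sam_table"] = sam_path

    if cfg.run_targets and cfg.db_paths:
        aliases = (
            tg.read_alias_table(cfg.alias_path) if cfg.alias_path else None
        )
        dbs = [
            _stage(
                f"read_predictions[{name}]",
                tg.read_predictions,
                path,
                dialect=cfg.db_dialects.get(name, name),
                source=name,
                aliases=aliases,
            )
            for name, path in cfg.db_paths.items()
        ]
        if cfg.groups_dir is None:
            raise PipelineError("stage 'targets' failed: groups_dir not set")
        group_paths = {
            g: str(Path(cfg.groups_dir) / f"{g}.txt") for g in tg.GROUP_NAMES
        }
        groups = _stage("read_gene_groups", tg.read_gene_groups, group_paths)
        beta_ids = tg.filter_beta_mirnas(sam_result.table, cfg.min_fc)
        report = _stage(
            "intersect_targets", tg.intersect_targets, beta_ids, dbs, groups,
            aliases=aliases,
        )
        report_path = out_dir / "target_report.tsv"
        if len(report.rows):
            _stage("write_targets", io_ct.write_target_report, report.rows, report_path)
        else:
            report_path.write_text(
                "\t".join(io_ct.TARGET_REPORT_COLUMNS) + "\n", encoding="utf-8"
            )
        artifacts["target_report"] = report_path

    counts = summarize_counts(artifacts, n_panel=n_panel)
    manifest = {
        "version": __version__,
        "seed": cfg.sam.seed,
        "config": _jsonable(cfg),
        "counts": counts,
        "sam": {
            "delta": sam_result.delta,
            "s0": sam_result.s0,
            "pi0": sam_result.null.pi0,
            "achieved_fdr_percent": sam_result.achieved_fdr_percent,
            "exhaustive_null": sam_result.null.exhaustive,
            "target_unmet": sam_result.target_unmet,
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    artifacts["manifest"] = manifest_path
    return PipelineResult(
        artifacts=artifacts,
        counts=counts,
        sam_delta=sam_result.delta,
        sam_s0=sam_result.s0,
    )


def _jsonable(cfg: PipelineConfig) -> dict:
    raw = asdict(cfg)
    raw["sam"] = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in asdict(cfg.sam).items()
    }
    return raw


def summarize_counts(artifacts: dict[str, Path], n_panel: int | None = None) -> dict:
    """Stage counts recomputed from the written artifact files.

    Reading the files back (rather than trusting in-memory state) makes
    the manifest an independent audit of what was actually written.
    """
    counts: dict[str, int] = {}
    if n_panel is not None:
        counts["n_panel"] = int(n_panel)
    gpath = artifacts.get("global_fc_table")
    if gpath is None or not Path(gpath).exists():
        raise PipelineError("stage 'summarize' failed: global FC table missing")
    gtab = io_ct.read_global_table(gpath)
    counts["n_detected"] = len(gtab)
    counts["n_equal_band"] = int((gtab["category"] == "equal").sum())
    counts["n_alpha_band"] = int((gtab["category"] == "alpha_enriched").sum())
    counts["n_beta_band"] = int((gtab["category"] == "beta_enriched").sum())

    spath = artifacts.get("sam_table")
    if spath is None or not Path(spath).exists():
        raise PipelineError("stage 'summarize' failed: SAM table missing")
    stab = pd.read_csv(spath, sep="\t")
    counts["n_significant"] = len(stab)
    if len(stab):
        counts["n_beta"] = int((stab["direction"] == "beta").sum())
        counts["n_alpha"] = int((stab["direction"] == "alpha").sum())
    else:
        counts["n_beta"] = counts["n_alpha"] = 0

    tpath = artifacts.get("target_report")
    if tpath is not None and Path(tpath).exists():
        ttab = pd.read_csv(tpath, sep="\t")
        counts["n_target_rows"] = len(ttab)
    return counts
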