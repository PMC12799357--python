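"""End-to-end orchestration: QC -> signatures -> calls -> composition -> DEG -> ORA.

A single YAML config drives every stage; one global seed fans out to
per-stage seeds through a counter-based derivation so any stage can be rerun
in isolation with the same stream.  Every output is a TSV (plus a JSON run
manifest with config hash and per-file checksums), and reruns with identical
config and inputs are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composition, differential, preprocessing, senescence, synthetic

logger = logging.getLogger("senskin")

STAGES = ("qc", "signatures", "call", "compose", "correlate", "deg", "ora")


@dataclass
class PipelineConfig:
    input_dir: str = "."
    out_dir: str = "senskin_out"
    mito_prefix: str = "MT-"
    exclude_barcodes_file: str | None = None  # e.g. an external doublet list
    qc: preprocessing.QCThresholds = field(default_factory=preprocessing.QCThresholds)
    target_sum: float = 10_000.0
    signature: senescence.SignatureCriteria = field(default_factory=senescence.SignatureCriteria)
    gmm_k_candidates: tuple[int, ...] = (2, 3)
    gmm_n_init: int = 10
    gmm_min_scores: int = 50
    deg: differential.DEGCriteria = field(default_factory=differential.DEGCriteria)
    deg_subsets: tuple[str, ...] = synthetic.T_SUBSETS
    ora_gmt: str | None = None
    ora_min_size: int = 10
    ora_max_size: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "qc" in kwargs:
            kwargs["qc"] = preprocessing.QCThresholds(**kwargs["qc"])
        if "signature" in kwargs:
            kwargs["signature"] = senescence.SignatureCriteria(**kwargs["signature"])
        if "deg" in kwargs:
            kwargs["deg"] = differential.DEGCriteria(**kwargs["deg"])
        for key in ("gmm_k_candidates", "deg_subsets"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def stage_seed(global_seed: int, stage: str) -> int:
    """Counter-based per-stage seed, stable across runs and stage reordering."""
    idx = STAGES.index(stage) if stage in STAGES else len(STAGES)
    return int(np.random.SeedSequence([int(global_seed), idx]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seeds: dict[str, int]
    outputs: dict[str, str]  # file -> sha256
    warnings: list[str]

    def to_json(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage on the bundle in ``config.input_dir``.

    Writes qc_report.tsv, kept_barcodes.tsv, signatures.tsv, calls.tsv,
    composition.tsv, correlations.tsv, degs.tsv, enrichment.tsv (when a GMT is
    configured) and manifest.json under ``config.out_dir``.  A stage failure
    aborts the run with the stage name; partial outputs are kept next to a
    FAILED marker naming the stage and cause.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []
    outputs: dict[str, str] = {}
    stage_seeds = {s: stage_seed(config.seed, s) for s in STAGES}
    stage = "load"
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")

            adata = synthetic.read_tenx_bundle(config.input_dir)
            logger.info("loaded %d cells x %d genes", adata.n_obs, adata.n_vars)

            stage = "qc"
            qc = preprocessing.compute_qc_metrics(adata, mito_prefix=config.mito_prefix)
            keep = preprocessing.filter_cells(qc, config.qc)
            if config.exclude_barcodes_file:
                excl = set(
                    pd.read_csv(config.exclude_barcodes_file, sep="\t", header=None)[0].astype(str)
                )
                keep &= ~keep.index.isin(excl)
            report = qc.copy()
            report["keep"] = keep
            _write(report.reset_index(names="barcode"), out / "qc_report.tsv")
            adata = adata[keep.to_numpy()].copy()
            preprocessing.normalize_log(adata, target_sum=config.target_sum)
            pd.Series(adata.obs_names).to_csv(
                out / "kept_barcodes.tsv", sep="\t", index=False, header=False
            )

            stage = "signatures"
            signatures, callsets = senescence.run_senescence(
                adata,
                criteria=config.signature,
                seed=stage_seeds["call"],
                min_scores=config.gmm_min_scores,
            )
            sig_table = pd.concat([s.table for s in signatures], ignore_index=True)
            _write(sig_table, out / "signatures.tsv")

            stage = "call"
            calls = senescence.calls_frame(callsets)
            _write(calls, out / "calls.tsv")

            stage = "compose"
            comp = composition.subset_proportions(adata.obs, calls if len(calls) else None)
            _write(comp.reset_index(), out / "composition.tsv")

            stage = "correlate"
            scans = [composition.scan_tprops_vs_age(comp)]
            if "sen_frac_pooled" in comp.columns:
                scans.insert(0, composition.scan_fractions_vs_age(comp, adata.obs))
                scans.append(composition.scan_tprops_vs_burden(comp))
            corr = pd.concat(scans, ignore_index=True)
            corr["excluded"] = corr["excluded"].map(lambda t: ";".join(t))
            _write(corr, out / "correlations.tsv")

            stage = "deg"
            deg_tables = []
            for subset in config.deg_subsets:
                if (adata.obs["cell_type"] == subset).sum() == 0:
                    caught.append(f"deg: no cells of subset {subset!r}; skipped")
                    continue
                deg_tables.append(differential.find_degs(adata, subset, config.deg))
            degs = (
                pd.concat(deg_tables, ignore_index=True)
                if deg_tables
                else pd.DataFrame()
            )
            _write(degs, out / "degs.tsv")

            stage = "ora"
            if config.ora_gmt and len(degs):
                gene_sets = differential.read_gmt(config.ora_gmt)
                universe = list(adata.var_names)
                ora_tables = []
                for subset in degs["subset"].unique():
                    sub = degs[degs["subset"] == subset]
                    for target in ("old", "young"):
                        query = differential.degs_passing(sub, target)
                        if not query:
                            continue
                        tab = differential.ora_hypergeometric(
                            query, universe, gene_sets,
                            min_size=config.ora_min_size, max_size=config.ora_max_size,
                        )
                        tab.insert(0, "subset", subset)
                        tab.insert(1, "target", target)
                        ora_tables.append(tab)
                if ora_tables:
                    _write(pd.concat(ora_tables, ignore_index=True), out / "enrichment.tsv")

            caught.extend(str(w.message) for w in wlist)
    except Exception as err:
        (out / "FAILED").write_text(f"stage={stage}\nerror={err}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    for f in sorted(out.glob("*.tsv")):
        outputs[f.name] = _sha256(f)
    cfg_dict = config.to_dict()
    cfg_dict.pop("out_dir")  # where results land does not identify the analysis
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = RunManifest(
        config_hash=cfg_hash,
        seed=config.seed,
        stage_seeds=stage_seeds,
        outputs=outputs,
        warnings=caught,
    )
    manifest.to_json(out / "manifest.json")
    return manifest
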