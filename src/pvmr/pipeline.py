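"""Orchestration of the two analysis arms.

``run_pv`` runs the pharmacovigilance arm end to end — ingest, dedup,
disproportionality for every PT co-reported with the target drug, priority
scoring of the target pair, volcano statistics, logistic regression — and
``run_mr`` the Mendelian-randomization arm — instrument selection,
harmonization, the five-estimator bundle, heterogeneity/pleiotropy/
MR-PRESSO/leave-one-out diagnostics, optionally repeated against a positive-
control outcome.  Outputs are TSV/JSON files in the configured directory;
every threshold, exclusion and count is echoed into a run log, and a single
seed drives all stochastic steps so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, mr
from .disproportionality import contingency_table, signal_table, volcano_stats
from .priority import PriorityInput, score_priority
from .regression import prepare_regression_frame, regression_report
from .reports import CANONICAL_SCHEMA, deduplicate, parse_reports

log = logging.getLogger(__name__)


@dataclass(slots=True)
class PipelineConfig:
    arm: str = "both"                       # pharmacovigilance | mendelian_randomization | both
    outdir: str = "pvmr-out"
    seed: int = 0
    # pharmacovigilance arm
    reports_path: str | None = None
    schema: dict = field(default_factory=dict)
    drug: str = "somatropin"
    pt_code: int = 10061019
    clinical_relevance: str = "IME"
    yates: bool = False
    scoring_gate: int = 1                   # min positive methods for priority scoring
    alpha: float = 0.05
    # MR arm
    exposure_path: str | None = None
    outcome_path: str | None = None
    control_outcome_path: str | None = None
    ld_path: str | None = None
    p_thresh: float = 5e-6
    r2_max: float = 0.001
    window_kb: float = 10_000
    f_min: float = 10.0
    ambiguous_eaf: tuple[float, float] = (0.42, 0.58)
    n_boot: int = 1000
    n_sim: int = 1000
    bandwidth_factor: float = 1.0
    random_effects: bool = True
    select: bool = True                     # apply instrument selection before harmonizing
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.ambiguous_eaf, list):
            cfg.ambiguous_eaf = tuple(cfg.ambiguous_eaf)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _setup_run_log(outdir: Path, cfg: PipelineConfig) -> logging.Logger:
    outdir.mkdir(parents=True, exist_ok=True)
    # attach to the package logger so module-level exclusion/skip messages
    # land in the run log too
    pkg_log = logging.getLogger("pvmr")
    pkg_log.setLevel(logging.INFO)
    for h in [h for h in pkg_log.handlers if isinstance(h, logging.FileHandler)]:
        pkg_log.removeHandler(h)
        h.close()
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    pkg_log.addHandler(fh)
    run_log = logging.getLogger("pvmr.run")
    run_log.info("pvmr version %s", __version__)
    run_log.info("config hash %s", cfg.config_hash())
    for key, value in sorted(asdict(cfg).items()):
        run_log.info("config %s = %r", key, value)
    return run_log


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pv(cfg: PipelineConfig) -> dict[str, Path]:
    """Pharmacovigilance arm; returns the paths of the written outputs."""
    outdir = Path(cfg.outdir)
    run_log = _setup_run_log(outdir, cfg)
    if not cfg.reports_path:
        raise ValueError("reports_path not set")

    try:
        rs = parse_reports(cfg.reports_path, cfg.schema or CANONICAL_SCHEMA,
                           provenance="pipeline")
    except Exception as exc:
        raise RuntimeError(f"ingest stage failed: {exc}") from exc
    if len(rs) == 0:
        raise RuntimeError("ingest stage failed: no parseable reports")
    rs = deduplicate(rs)
    run_log.info("reports: %s", rs.counts)

    outputs: dict[str, Path] = {}
    signals = signal_table(rs, cfg.drug, yates=cfg.yates)
    outputs["signals"] = outdir / "signals.tsv"
    _write_tsv(signals, outputs["signals"])

    target = signals[signals.pt_code == cfg.pt_code]
    if target.empty:
        raise RuntimeError(f"target PT {cfg.pt_code} not co-reported with {cfg.drug}")
    row = target.iloc[0]
    t = contingency_table(rs, cfg.drug, cfg.pt_code)
    deaths = sum(
        1 for r in rs
        if r.has_drug(cfg.drug) and r.has_pt(cfg.pt_code) and "death" in r.outcome
    )
    n_pos = int(row.n_positive_methods)
    priority_payload: dict = {
        "drug": cfg.drug,
        "pt_code": cfg.pt_code,
        "eligible": n_pos >= cfg.scoring_gate,
    }
    if priority_payload["eligible"]:
        pin = PriorityInput(
            clinical_relevance=cfg.clinical_relevance,
            reporting_rate=t.a / (t.a + t.b) if t.a + t.b else 0.0,
            fatality_rate=deaths / t.a if t.a else 0.0,
            stability=n_pos,
        )
        score = score_priority(pin)
        priority_payload.update(
            {
                "inputs": {
                    "clinical_relevance": pin.clinical_relevance,
                    "reporting_rate": pin.reporting_rate,
                    "fatality_rate": pin.fatality_rate,
                    "stability": pin.stability,
                },
                "components": score.component_points,
                "total": score.total,
                "category": score.category,
            }
        )
        run_log.info("priority: total %d (%s)", score.total, score.category)
    outputs["priority"] = outdir / "priority.json"
    outputs["priority"].write_text(json.dumps(priority_payload, indent=2, sort_keys=True))

    volcano = volcano_stats(rs, cfg.drug)
    outputs["volcano"] = outdir / "volcano.tsv"
    _write_tsv(volcano, outputs["volcano"])

    try:
        design, y = prepare_regression_frame(rs, cfg.drug, cfg.pt_code)
        reg = regression_report(design, y, {"age_band": "<18", "sex": "female"},
                                alpha=cfg.alpha)
        outputs["regression"] = outdir / "regression.tsv"
        _write_tsv(reg, outputs["regression"])
    except ValueError as exc:
        run_log.warning("regression stage skipped: %s", exc)

    if cfg.plots:
        _plot_volcano(volcano, outdir / "volcano.png")
    run_log.info("pv arm complete")
    return outputs


def _mr_bundle(
    h: mr.HarmonizedSet, cfg: PipelineConfig, rng: np.random.Generator, run_log
) -> tuple[pd.DataFrame, dict, pd.DataFrame | None]:
    estimates = mr.all_estimates(
        h, n_boot=cfg.n_boot, bandwidth_factor=cfg.bandwidth_factor,
        seed=rng, random_effects=cfg.random_effects,
    )
    table = mr.estimates_table(estimates)
    diag: dict = {"k_snps": h.k, "exclusions": h.exclusions}
    for model in ("ivw", "egger"):
        try:
            het = mr.cochran_q(h, model)
            diag[f"q_{model}"] = {"Q": het.Q, "df": het.df, "p": het.p}
        except ValueError as exc:
            run_log.info("cochran_q(%s) skipped: %s", model, exc)
    for e in estimates:
        if e.method == "egger":
            diag["egger_intercept"] = {
                "intercept": e.extras["intercept"],
                "se": e.extras["intercept_se"],
                "p": e.extras["intercept_p"],
            }
    try:
        presso = mr.mr_presso(h, n_sim=cfg.n_sim, seed=rng, alpha=cfg.alpha)
        diag["mr_presso"] = {
            "global_rss": presso.global_rss,
            "global_p": presso.global_p,
            "outlier_p": presso.outlier_p.tolist(),
            "outliers": [s for s, f in zip(h.snp_ids, presso.outlier_flags) if f],
        }
    except ValueError as exc:
        run_log.info("mr_presso skipped: %s", exc)
    loo_df = None
    try:
        loo = mr.leave_one_out(h, random_effects=cfg.random_effects)
        diag["leave_one_out_influential"] = bool(loo.influential)
        loo_df = loo.rows
    except ValueError as exc:
        run_log.info("leave_one_out skipped: %s", exc)
    return table, diag, loo_df


def run_mr(cfg: PipelineConfig) -> dict[str, Path]:
    """Mendelian-randomization arm; returns the paths of the written outputs."""
    outdir = Path(cfg.outdir)
    run_log = _setup_run_log(outdir, cfg)
    if not cfg.exposure_path or not cfg.outcome_path:
        raise ValueError("exposure_path and outcome_path must be set")

    exposure = mr.read_gwas(cfg.exposure_path)
    ld = mr.LdMatrix.from_tsv(cfg.ld_path) if cfg.ld_path else mr.LdMatrix()
    if cfg.select:
        exposure, exclusions = mr.select_instruments(
            exposure, p_thresh=cfg.p_thresh, ld=ld, r2_max=cfg.r2_max,
            window_kb=cfg.window_kb, f_min=cfg.f_min,
        )
    else:
        exclusions = []
    exclusion_rows = [{"snp_id": s, "stage": "selection", "reason": r} for s, r in exclusions]

    rng = np.random.default_rng(cfg.seed)
    outputs: dict[str, Path] = {}
    runs = [("primary", cfg.outcome_path)]
    if cfg.control_outcome_path:
        runs.append(("control", cfg.control_outcome_path))
    for label, out_path in runs:
        outcome = mr.read_gwas(out_path)
        h = mr.harmonize(exposure, outcome, ambiguous_eaf=cfg.ambiguous_eaf)
        exclusion_rows += [
            {"snp_id": s, "stage": f"harmonize-{label}", "reason": r}
            for s, r in h.exclusions
        ]
        run_log.info("%s: k = %d instruments after harmonization", label, h.k)
        table, diag, loo_df = _mr_bundle(h, cfg, rng, run_log)
        diag["label"] = label
        outputs[f"estimates_{label}"] = outdir / f"estimates_{label}.tsv"
        _write_tsv(table, outputs[f"estimates_{label}"])
        outputs[f"diagnostics_{label}"] = outdir / f"diagnostics_{label}.json"
        outputs[f"diagnostics_{label}"].write_text(
            json.dumps(diag, indent=2, sort_keys=True)
        )
        if loo_df is not None:
            outputs[f"leave_one_out_{label}"] = outdir / f"leave_one_out_{label}.tsv"
            _write_tsv(loo_df, outputs[f"leave_one_out_{label}"])

    outputs["exclusions"] = outdir / "exclusions.tsv"
    _write_tsv(pd.DataFrame(exclusion_rows, columns=["snp_id", "stage", "reason"]),
               outputs["exclusions"])
    run_log.info("mr arm complete")
    return outputs


def _plot_volcano(volcano: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    sc = ax.scatter(volcano.log_ror, volcano.neg_log10_p, c=volcano.n, cmap="Reds")
    ax.axhline(-np.log10(0.05), ls="--", c="grey")
    ax.set_xlabel("log10 ROR")
    ax.set_ylabel("-log10 adjusted p")
    fig.colorbar(sc, label="reports")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
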