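"""End-to-end pipeline driver: ingest -> screen -> contingency -> score ->
describe -> report, configured from a YAML file.

The configuration has nested sections mirroring the library objects::

    output_dir: out
    dialect: faers_dollar
    input: {demo: demo.txt, drug: drug.txt, reac: reac.txt, outc: outc.txt}
    meddra_map: pt_soc_map.csv
    # or, instead of input:, generate a synthetic corpus:
    simulate: {n_target_reports: 2000, planted_signals: [[PT_001, 5.0]], seed: 7}
    screening: {drug_synonyms: [TABRECTA, CAPMATINIB], date_window: [2020Q2, 2023Q4]}
    thresholds: {min_a: 3}
    priors: {alpha1: 1.0}
    counting: {unit: pair}
    top_n: 30

All outputs are deterministic functions of the configuration (plus the seed
for synthetic input): a re-run writes byte-identical files. The metadata
file records the package and library versions, the configuration hash, the
counting policy, the prior constants and the two methodological notes that
matter when comparing against other implementations (EBGM is the
observed/expected form without gamma-Poisson shrinkage; the IC variance is
the Bate-1998 expression).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import faers_io, preprocess, synthetic
from .contingency import CountingPolicy, build_pt_tables, build_soc_tables
from .report import describe, signal_report
from .signal_stats import BcpnnPriors, Thresholds, score_all, scores_frame


class PipelineError(RuntimeError):
    """A stage failure with a machine-readable stage name and error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


def _section(cfg: dict, name: str, cls):
    params = dict(cfg.get(name) or {})
    try:
        if name == "screening" and "drug_synonyms" in params:
            params["drug_synonyms"] = tuple(params["drug_synonyms"])
        if name == "screening" and "date_window" in params:
            params["date_window"] = tuple(params["date_window"])
        return cls(**params)
    except (TypeError, ValueError) as exc:
        raise PipelineError("configure", "bad_section", f"invalid {name!r} section: {exc}") from exc


def _sim_config(cfg: dict, seed: Optional[int]) -> synthetic.SimConfig:
    params = dict(cfg.get("simulate") or {})
    if "planted_signals" in params:
        params["planted_signals"] = [tuple(p) for p in params["planted_signals"]]
    if "pt_catalog" in params:
        params["pt_catalog"] = [tuple(p) for p in params["pt_catalog"]]
    if seed is not None:
        params["seed"] = seed
    try:
        sim = synthetic.SimConfig(**params)
        sim.validate()
        return sim
    except (TypeError, ValueError) as exc:
        raise PipelineError("configure", "bad_simulate", str(exc)) from exc


def _config_hash(cfg: dict, seed: Optional[int]) -> str:
    canonical = json.dumps({"config": cfg, "seed": seed}, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def run_pipeline(config_path: str | Path, out_dir: Optional[str | Path] = None, seed: Optional[int] = None) -> Path:
    """Execute the full pipeline described by a config file.

    Returns the output directory. Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise PipelineError("configure", "missing_config", f"config file not found: {config_path}")
    cfg = yaml.safe_load(config_path.read_text()) or {}
    out = Path(out_dir) if out_dir is not None else Path(cfg.get("output_dir", "pvsignals_out"))
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    # --- ingest -----------------------------------------------------------
    dialect = cfg.get("dialect", "faers_dollar")
    truth = None
    if "simulate" in cfg:
        sim = _sim_config(cfg, seed)
        raw, truth = synthetic.generate(sim)
        sim_dir = out / "sim"
        faers_io.write_quarter(raw, sim_dir, dialect=dialect)
        truth.pair_counts.to_csv(out / "truth_pairs.csv", index=False)
        log(f"simulated {len(raw.demo)} demo rows (seed {sim.seed})")
    elif "input" in cfg:
        try:
            raw = faers_io.read_quarter(cfg["input"], dialect=dialect)
        except (OSError, faers_io.FormatError) as exc:
            raise PipelineError("ingest", "read_failed", str(exc)) from exc
        log(f"read {len(raw.demo)} demo rows")
    else:
        raise PipelineError("configure", "no_input", "config needs an 'input' or 'simulate' section")

    # --- PT->SOC map ------------------------------------------------------
    if "meddra_map" in cfg:
        try:
            meddra = faers_io.read_meddra_map(cfg["meddra_map"])
        except (OSError, faers_io.FormatError) as exc:
            raise PipelineError("annotate", "bad_map", str(exc)) from exc
    elif truth is not None:
        frame = synthetic.meddra_map_frame(truth.config)
        map_path = out / "sim" / "pt_soc_map.csv"
        frame.to_csv(map_path, index=False)
        meddra = faers_io.read_meddra_map(map_path)
    else:
        raise PipelineError("annotate", "no_map", "config needs a 'meddra_map' path for real input")

    # --- assemble & screen ------------------------------------------------
    cases, assembly_log = faers_io.assemble_cases(raw)
    log(f"assembled {assembly_log.n_cases} cases "
        f"(orphan reac rows: {assembly_log.orphan_reac_rows}, collapsed: {assembly_log.collapsed_reactions})")
    screening_cfg = _section(cfg, "screening", preprocess.ScreeningConfig)
    try:
        screened = preprocess.screen(cases, screening_cfg)
    except preprocess.ConfigError as exc:
        raise PipelineError("screen", "bad_config", str(exc)) from exc
    pd.DataFrame(
        [{"step": k, "count": v} for k, v in screened.screening_log.items()]
    ).to_csv(out / "screening_log.csv", index=False)

    target, unmapped_t = preprocess.annotate_soc(screened.target_reports, meddra)
    background, unmapped_b = preprocess.annotate_soc(screened.background_reports, meddra)
    screened.target_reports, screened.background_reports = target, background
    n_unmapped = sum(unmapped_t.values()) + sum(unmapped_b.values())
    log(f"annotated SOCs; {n_unmapped} unmapped PT occurrences")

    # --- contingency & scores ---------------------------------------------
    policy = _section(cfg, "counting", CountingPolicy)
    pt_tables = build_pt_tables(screened, policy)
    soc_tables = build_soc_tables(screened, policy)
    for name, tables in (("contingency_pt", pt_tables), ("contingency_soc", soc_tables)):
        pd.DataFrame(
            [{"event_id": t.event_id, "level": t.level, "a": t.a, "b": t.b, "c": t.c, "d": t.d} for t in tables]
        ).to_csv(out / f"{name}.csv", index=False)

    priors = _section(cfg, "priors", BcpnnPriors)
    thresholds = _section(cfg, "thresholds", Thresholds)
    if "min_a" not in (cfg.get("thresholds") or {}):
        thresholds = dataclasses.replace(thresholds, min_a=screening_cfg.min_pair_count)
    pt_rows = score_all(pt_tables, priors=priors, thresholds=thresholds)
    soc_rows = score_all(soc_tables, priors=priors, thresholds=thresholds)
    scores_frame(pt_rows).to_csv(out / "signals_pt.csv", index=False, float_format="%.10g")
    scores_frame(soc_rows).to_csv(out / "signals_soc.csv", index=False, float_format="%.10g")
    log(f"scored {len(pt_rows)} PTs and {len(soc_rows)} SOCs")

    # --- descriptive & report ---------------------------------------------
    summary = describe(screened.target_reports)
    summary.to_frame().to_csv(out / "descriptive.csv", index=False)
    top_n = int(cfg.get("top_n", 30))
    try:
        signal_report(pt_rows, top_n=top_n, level="PT").to_csv(out / "top_signals_pt.csv", index=False)
        signal_report(soc_rows, top_n=max(top_n, len(soc_rows) or 1), level="SOC").to_csv(
            out / "signals_report_soc.csv", index=False
        )
    except ValueError as exc:
        raise PipelineError("report", "bad_top_n", str(exc)) from exc

    metadata = {
        "package": "pvsignals",
        "package_version": __import__("pvsignals").__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config_hash_sha256": _config_hash(cfg, seed),
        "counting_policy": dataclasses.asdict(policy),
        "bcpnn_priors": dataclasses.asdict(priors),
        "thresholds": dataclasses.asdict(thresholds),
        "notes": [
            "EBGM is the observed/expected relative reporting ratio aN/((a+b)(a+c)) "
            "with a Woolf-type interval; no gamma-Poisson (MGPS) hyperparameter fitting.",
            "IC variance follows Bate (1998); IC025 = E(IC) - 2*sqrt(V(IC)).",
            "counting unit 'pair' counts (report, PT) occurrences, so SOC counts can "
            "exceed the number of reports.",
        ],
    }
    (out / "run_metadata.json").write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")
    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return out
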