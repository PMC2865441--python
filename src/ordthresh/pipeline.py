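"""Seeded end-to-end pipeline: cases → risks → responses → thresholds → population.

A single global seed is expanded into per-stage substreams (via
``numpy.random.SeedSequence``) so any stage can be rerun independently
yet reproducibly.  Every artifact is written with a manifest recording
the seeds and config hashes; rerunning with an identical config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from . import io as tio
from .cases import simulate_cases
from .physicians import simulate_physician_panel, simulate_responses
from .population import fit_beta_mle, summarize_population
from .risk import compute_risks


def _stage_seeds(seed: int, n: int = 3) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def run_pipeline(
    population_config_path,
    risk_config_path,
    panel_config_path,
    seed: int,
    outdir,
    percent: bool = False,
) -> dict:
    """Execute all stages, writing artifacts plus ``manifest.json`` to
    ``outdir``; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    case_seed, panel_seed, response_seed = _stage_seeds(seed)

    stage = "simulate-cases"
    try:
        pop_cfg = tio.load_population_config(population_config_path, seed=case_seed)
        cases = simulate_cases(pop_cfg)
        tio.write_case_table(cases, outdir / "cases.csv")

        stage = "compute-risk"
        risk_cfg = tio.load_risk_config(risk_config_path)
        risks = compute_risks(cases, risk_cfg)
        tio.write_risk_table(cases["case_id"], risks, outdir / "risks.csv", percent=percent)

        stage = "simulate-responses"
        panel_cfg = tio.load_panel_config(panel_config_path)
        panel = simulate_physician_panel(
            panel_cfg["n_physicians"],
            threshold_beta_shapes=panel_cfg["threshold_beta_shapes"],
            discrimination_range=panel_cfg["discrimination_range"],
            spacing=panel_cfg["spacing"],
            seed=panel_seed,
        )
        responses = simulate_responses(
            panel, risks, case_ids=cases["case_id"].tolist(), seed=response_seed
        )
        tio.write_response_table(responses, outdir / "responses.csv")

        stage = "estimate-thresholds"
        from .population import estimate_all_thresholds

        risk_df = tio.read_risk_table(outdir / "risks.csv", percent=percent)
        estimates = estimate_all_thresholds(responses, risk_df)
        tio.write_threshold_table(estimates, outdir / "thresholds.csv")

        stage = "fit-population"
        numeric = [e.threshold for e in estimates if e.threshold is not None]
        beta_fit = fit_beta_mle(numeric)
        summary = summarize_population(estimates)
        report = {
            "beta_fit": dataclasses.asdict(beta_fit),
            "summary": dataclasses.asdict(summary),
        }
        (outdir / "population.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": int(seed),
        "stage_seeds": {
            "cases": case_seed,
            "panel": panel_seed,
            "responses": response_seed,
        },
        "config_hashes": {
            "population": _sha256_text(Path(population_config_path).read_text()),
            "risk_model": _sha256_text(Path(risk_config_path).read_text()),
            "panel": _sha256_text(Path(panel_config_path).read_text()),
        },
        "artifacts": {
            name: _sha256_file(outdir / name)
            for name in ("cases.csv", "risks.csv", "responses.csv", "thresholds.csv", "population.json")
        },
        "risk_unit": "percent" if percent else "proportion",
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
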