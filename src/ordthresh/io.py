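"""Delimited-table and YAML-config input/output with validation.

All tabular artifacts are plain CSV with headers; every reader validates
the header and the row values, reporting 1-based data-row numbers in
errors.  Risks are serialized as proportions with 6 decimal places; a
percent flag converts at the boundary only.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cases import CASE_COLUMNS, FactorSpec, PopulationConfig, CONTINUOUS_FACTORS
from .estimate import ThresholdEstimate
from .physicians import DEFAULT_SPACING, LEVELS3, LEVELS7
from .risk import RiskModelConfig

_VALID_RESPONSES = set(LEVELS7) | set(LEVELS3)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


# ---------------------------------------------------------------------------
# case tables


def read_case_table(path) -> pd.DataFrame:
    """Typed, validated case table (see :data:`~ordthresh.cases.CASE_COLUMNS`)."""
    df = pd.read_csv(path)
    _require_columns(df, CASE_COLUMNS, path)
    df = df[list(CASE_COLUMNS)]
    for col in CONTINUOUS_FACTORS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[~np.isfinite(vals)]
        if len(bad):
            raise ValueError(f"{path}: row {bad[0] + 1}: non-numeric {col!r}")
        df[col] = vals.astype(float)
    for i, v in enumerate(df["cdr"]):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{path}: row {i + 1}: cdr={v} outside [0, 1]")
    for col in ("age", "iop", "psd", "cct"):
        neg = df.index[df[col] <= 0]
        if len(neg):
            raise ValueError(f"{path}: row {neg[0] + 1}: {col} must be positive")
    bad_dm = df.index[~df["diabetes"].isin([0, 1])]
    if len(bad_dm):
        raise ValueError(f"{path}: row {bad_dm[0] + 1}: diabetes must be 0 or 1")
    bad_g = df.index[~df["gender"].isin(["female", "male"])]
    if len(bad_g):
        raise ValueError(f"{path}: row {bad_g[0] + 1}: gender must be female or male")
    df["diabetes"] = df["diabetes"].astype(int)
    return df


def write_case_table(cases: pd.DataFrame, path) -> None:
    out = cases.copy()
    for col in CONTINUOUS_FACTORS:
        out[col] = out[col].map(lambda v: f"{v:.6f}")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# risk tables


def read_risk_table(path, percent: bool = False) -> pd.DataFrame:
    """Table with ``case_id`` and ``risk`` columns; risks strictly in (0, 1)
    as proportions (or (0, 100) with ``percent=True``, converted on read)."""
    df = pd.read_csv(path)
    _require_columns(df, ("case_id", "risk"), path)
    vals = pd.to_numeric(df["risk"], errors="coerce")
    bad = vals.index[~np.isfinite(vals)]
    if len(bad):
        raise ValueError(f"{path}: row {bad[0] + 1}: non-numeric risk")
    if percent:
        vals = vals / 100.0
    out_of_range = vals.index[(vals <= 0) | (vals >= 1)]
    if len(out_of_range):
        raise ValueError(
            f"{path}: row {out_of_range[0] + 1}: risk outside (0, 1)"
        )
    df["risk"] = vals.astype(float)
    return df[["case_id", "risk"]]


def write_risk_table(case_ids: Sequence[str], risks, path, percent: bool = False) -> None:
    r = np.asarray(risks, dtype=float)
    if percent:
        r = r * 100.0
    pd.DataFrame({"case_id": list(case_ids), "risk": [f"{v:.6f}" for v in r]}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# response tables


def read_response_table(path) -> pd.DataFrame:
    """Recommendation table ``physician_id,case_id,response`` using the
    canonical 7-point (or collapsed 3-point) level strings."""
    df = pd.read_csv(path)
    _require_columns(df, ("physician_id", "case_id", "response"), path)
    bad = df.index[~df["response"].isin(_VALID_RESPONSES)]
    if len(bad):
        tok = df.loc[bad[0], "response"]
        raise ValueError(f"{path}: row {bad[0] + 1}: unknown response level {tok!r}")
    dup = df.duplicated(subset=["physician_id", "case_id"])
    if dup.any():
        i = int(df.index[dup][0])
        raise ValueError(
            f"{path}: row {i + 1}: duplicate (physician_id, case_id) pair "
            f"({df.loc[i, 'physician_id']!r}, {df.loc[i, 'case_id']!r})"
        )
    return df[["physician_id", "case_id", "response"]]


def write_response_table(responses: pd.DataFrame, path) -> None:
    responses[["physician_id", "case_id", "response"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# threshold tables


def write_threshold_table(estimates: Sequence[ThresholdEstimate], path) -> None:
    rows = []
    for e in estimates:
        rows.append(
            {
                "physician_id": e.physician_id,
                "threshold": "" if e.threshold is None else f"{e.threshold:.6f}",
                "method": e.method,
                "r2_nagelkerke": "" if e.r2_nagelkerke is None else f"{e.r2_nagelkerke:.6f}",
                "concordance": "" if e.concordance is None else f"{e.concordance:.6f}",
                "warnings": "; ".join(e.warnings),
            }
        )
    pd.DataFrame(
        rows,
        columns=["physician_id", "threshold", "method", "r2_nagelkerke", "concordance", "warnings"],
    ).to_csv(path, index=False)


def read_threshold_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("physician_id", "threshold", "method"), path)
    df["threshold"] = pd.to_numeric(df["threshold"], errors="coerce")
    return df


# ---------------------------------------------------------------------------
# YAML configs


def load_population_config(path, n_cases: int | None = None, seed: int | None = None) -> PopulationConfig:
    """Population config from YAML.

    Schema: ``factors: {age: {mean, sd, lower?, upper?}, ...}``,
    ``p_diabetes``, ``p_female``, ``n_cases``, ``seed`` (the latter two
    overridable by keyword, e.g. from CLI flags).
    """
    raw = yaml.safe_load(Path(path).read_text())
    factors = {}
    for name, spec in raw["factors"].items():
        factors[name] = FactorSpec(
            mean=float(spec["mean"]),
            sd=float(spec["sd"]),
            lower=float(spec.get("lower", -math.inf)),
            upper=float(spec.get("upper", math.inf)),
        )
    return PopulationConfig(
        factors=factors,
        p_diabetes=float(raw["p_diabetes"]),
        p_female=float(raw["p_female"]),
        n_cases=int(raw["n_cases"] if n_cases is None else n_cases),
        seed=int(raw.get("seed", 0) if seed is None else seed),
        max_attempts=int(raw.get("max_attempts", 10_000)),
    )


def load_risk_config(path) -> RiskModelConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return RiskModelConfig(
        coefficients={k: float(v) for k, v in raw["coefficients"].items()},
        intercept=float(raw.get("intercept", 0.0)),
        link=raw.get("link", "logistic"),
        baseline_survival=(
            float(raw["baseline_survival"]) if "baseline_survival" in raw else None
        ),
        risk_horizon_years=float(raw.get("risk_horizon_years", 5.0)),
    )


def load_panel_config(path) -> dict:
    """Panel config: n_physicians, threshold beta shapes, discrimination
    range and optional cutpoint spacing."""
    raw = yaml.safe_load(Path(path).read_text())
    return {
        "n_physicians": int(raw["n_physicians"]),
        "threshold_beta_shapes": tuple(float(x) for x in raw["threshold_beta_shapes"]),
        "discrimination_range": tuple(float(x) for x in raw["discrimination_range"]),
        "spacing": tuple(float(x) for x in raw.get("spacing", DEFAULT_SPACING)),
    }
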