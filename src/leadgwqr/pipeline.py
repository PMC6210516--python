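"""End-to-end analysis pipeline.

Stages, in order: data preparation (rate from counts, log-transformed
taxable value, exclusion of untested blocks) -> global quantile regression
at each requested quantile with bootstrap inference and standardized
coefficients -> Moran's I on the observed rate and the per-quantile
residuals -> bandwidth selection (fixed value, quantile-AIC grid search, or
variogram practical range) -> geographically weighted quantile regression
per quantile with local bootstrap t surfaces -> nonstationarity summaries
-> CSV tables and GeoJSON coefficient/significance layers.

All randomness descends from one master seed, split per stage and per
quantile, so a run is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .diagnostics import (assess_nonstationarity, build_weights,
                          residual_autocorrelation_report)
from .gwqr import (GWQuantileRegressor, KernelSpec, fit_gwqr,
                   local_inference, select_bandwidth_aic)
from .quantreg import LinearQuantileRegressor
from .synthetic import SyntheticConfig, generate_block_table
from .variogram import select_bandwidth_variogram

__all__ = ["PipelineConfig", "RunReport", "prepare_data", "run_analysis",
           "export_maps", "COVARIATES"]

COVARIATES = ("building_year", "log_tax", "soil_lead")
COEF_NAMES = ("intercept",) + COVARIATES

logger = logging.getLogger("leadgwqr")

T_CRITICAL = 1.96  # local |t| significance cutoff


@dataclass
class PipelineConfig:
    """Everything a full run needs; see module docstring for the stages.

    ``bandwidth`` is either a number (meters), "aic" (grid search with
    ``bandwidth_grid``), or "variogram" (practical range of the AIC-best
    variogram model fitted to the observed rate).
    """

    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    taus: tuple[float, ...] = (0.25, 0.50, 0.75, 0.90)
    kernel: str = "gaussian"
    bandwidth: float | str = "variogram"
    bandwidth_grid: tuple[float, ...] = (1000., 1600., 2400., 3600., 5400.,
                                         8000., 12000.)
    bandwidth_per_tau: bool = False
    n_boot_global: int = 200
    n_boot_local: int = 99
    seed: int = 0
    weights_scheme: str = "knn"
    weights_parameter: float = 8
    output_dir: str | None = None

    def validate(self) -> "PipelineConfig":
        taus = tuple(float(t) for t in self.taus)
        if not taus or any(not 0 < t < 1 for t in taus):
            raise ValueError("taus must lie strictly in (0, 1)")
        if tuple(sorted(set(taus))) != taus:
            raise ValueError("taus must be strictly increasing")
        if self.input_path is None and self.synthetic is None:
            raise ValueError("either input_path or a synthetic config "
                             "is required")
        if isinstance(self.bandwidth, str) and \
                self.bandwidth not in ("aic", "variogram"):
            raise ValueError("bandwidth must be a number, 'aic' or "
                             "'variogram'")
        return self

    def hash(self) -> str:
        # output_dir is excluded: where artifacts land must not change
        # what they contain
        payload = {k: v for k, v in self.__dict__.items()
                   if k != "output_dir"}
        if self.synthetic is not None:
            payload["synthetic"] = {
                k: v for k, v in self.synthetic.__dict__.items()
                if k != "coefficient_surfaces"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All artifacts of one pipeline run."""

    config_hash: str
    seed: int
    data: pd.DataFrame
    n_dropped: int
    global_fits: dict
    global_table: pd.DataFrame
    moran_table: pd.DataFrame
    bandwidths: dict
    bandwidth_audit: dict
    gwqr_fits: dict
    nonstationarity: dict
    provenance: dict = field(default_factory=dict)


# -- data preparation --------------------------------------------------------

def prepare_data(raw: pd.DataFrame, max_invalid_frac: float = 0.05
                 ) -> tuple[pd.DataFrame, int]:
    """Build the analysis table from raw counts/covariates.

    The rate is n_elevated / n_tested where counts are present (0 when no
    child tested elevated); blocks with no tested children are dropped and
    counted.  ``log_tax`` is ln(taxable value in K$).  Rows with negative
    counts, n_elevated > n_tested, or non-positive taxable value are
    invalid; more than ``max_invalid_frac`` of them aborts the run.

    Returns (table, number of dropped zero-tested blocks).
    """
    df = raw.copy()
    problems = np.zeros(len(df), dtype=bool)
    if {"n_tested", "n_elevated"}.issubset(df.columns):
        problems |= (df["n_tested"] < 0) | (df["n_elevated"] < 0)
        problems |= df["n_elevated"] > df["n_tested"]
    elif "rate" not in df.columns:
        raise ValueError("raw table needs counts (n_tested, n_elevated) "
                         "or a rate column")
    if "tax_value" in df.columns:
        problems |= ~(df["tax_value"] > 0)
    if problems.mean() > max_invalid_frac:
        bad = df.index[problems].tolist()[:20]
        raise ValueError(f"{problems.sum()} invalid rows (e.g. index {bad}); "
                         f"more than {max_invalid_frac:.0%} of the table")
    df = df.loc[~problems].copy()
    n_dropped = 0
    if "n_tested" in df.columns:
        zero = df["n_tested"] == 0
        n_dropped = int(zero.sum())
        df = df.loc[~zero].copy()
        df["rate"] = df["n_elevated"] / df["n_tested"]
    if "tax_value" in df.columns:
        df["log_tax"] = np.log(df["tax_value"].astype(float))
    if df[list({"rate", *COVARIATES} & set(df.columns))].isna().any().any():
        raise ValueError("missing values in analysis columns")
    return df.reset_index(drop=True), n_dropped


# -- orchestration -----------------------------------------------------------

def _stage_seed(master: int, stage: str, tau: float | None = None) -> int:
    """Deterministic 31-bit seed for a named stage (and quantile)."""
    key = f"{master}:{stage}" + ("" if tau is None else f":{tau:g}")
    return int.from_bytes(hashlib.sha256(key.encode()).digest()[:4],
                          "big") % (2**31)


def run_analysis(config: PipelineConfig) -> RunReport:
    """Run every stage; returns the full report and writes artifacts when
    ``config.output_dir`` is set."""
    config.validate()
    t0 = time.time()
    stage = "prepare"
    try:
        if config.input_path is not None:
            raw = _io.read_block_table(config.input_path)
        else:
            raw = generate_block_table(config.synthetic)
        data, n_dropped = prepare_data(raw)
        coords = data[["u", "v"]].to_numpy(float)
        X = data.loc[:, list(COVARIATES)]
        y = data["rate"].to_numpy(float)

        stage = "global_qr"
        global_fits: dict[float, LinearQuantileRegressor] = {}
        rows = []
        for tau in config.taus:
            fit = LinearQuantileRegressor(tau=tau).fit(X, y)
            fit.bootstrap_inference(
                X, y, n_boot=config.n_boot_global,
                random_state=_stage_seed(config.seed, "global_boot", tau))
            stb = fit.standardized_coefficients(X, y)
            global_fits[tau] = fit
            for j, name in enumerate(COEF_NAMES):
                rows.append({
                    "tau": tau, "coefficient": name,
                    "estimate": fit.beta_[j],
                    "ci_lower": fit.ci_lower_[j],
                    "ci_upper": fit.ci_upper_[j],
                    "p_value": fit.p_values_[j],
                    "stb": np.nan if j == 0 else stb[j - 1],
                })
        global_table = pd.DataFrame(rows)

        stage = "moran"
        weights = build_weights(coords, config.weights_scheme,
                                config.weights_parameter)
        moran_table = residual_autocorrelation_report(data, global_fits,
                                                      weights)

        stage = "bandwidth"
        bandwidths: dict[float, float] = {}
        audit: dict = {"method": config.bandwidth}
        if isinstance(config.bandwidth, (int, float)):
            bandwidths = {tau: float(config.bandwidth)
                          for tau in config.taus}
        elif config.bandwidth == "variogram":
            vg = select_bandwidth_variogram(y, coords)
            audit.update(model=vg.model, practical_range=vg.practical_range,
                         reliable=vg.range_reliable,
                         model_aic=dict(vg.model_aic))
            bandwidths = {tau: float(vg.practical_range)
                          for tau in config.taus}
        else:  # aic grid
            if config.bandwidth_per_tau:
                for tau in config.taus:
                    sel = select_bandwidth_aic(X, y, coords, tau,
                                               config.bandwidth_grid,
                                               kernel=config.kernel)
                    bandwidths[tau] = sel.chosen_h
                    audit[f"tau_{tau:g}"] = {
                        "grid": sel.grid.tolist(),
                        "criterion": sel.criterion.tolist()}
            else:
                mid_tau = config.taus[len(config.taus) // 2]
                sel = select_bandwidth_aic(X, y, coords, mid_tau,
                                           config.bandwidth_grid,
                                           kernel=config.kernel)
                bandwidths = {tau: sel.chosen_h for tau in config.taus}
                audit["shared"] = {"tau": mid_tau,
                                   "grid": sel.grid.tolist(),
                                   "criterion": sel.criterion.tolist()}

        stage = "gwqr"
        gwqr_fits: dict[float, GWQuantileRegressor] = {}
        nonstat: dict[float, pd.DataFrame] = {}
        for tau in config.taus:
            spec = KernelSpec(config.kernel, bandwidths[tau])
            gfit = fit_gwqr(data, tau, spec)
            local_inference(gfit, data, n_boot=config.n_boot_local,
                            seed=_stage_seed(config.seed, "local_boot", tau))
            gwqr_fits[tau] = gfit
            nonstat[tau] = assess_nonstationarity(
                gfit, global_fits[tau], names=list(COEF_NAMES))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = RunReport(
        config_hash=config.hash(), seed=config.seed, data=data,
        n_dropped=n_dropped, global_fits=global_fits,
        global_table=global_table, moran_table=moran_table,
        bandwidths=bandwidths, bandwidth_audit=audit, gwqr_fits=gwqr_fits,
        nonstationarity=nonstat,
        provenance={
            "config_hash": config.hash(), "seed": config.seed,
            "n_blocks": int(len(data)), "n_dropped": n_dropped,
            "elapsed_s": round(time.time() - t0, 2),
        })
    if config.output_dir is not None:
        write_artifacts(report, config)
    return report


def write_artifacts(report: RunReport, config: PipelineConfig) -> None:
    """CSV tables, GeoJSON layers, run log and provenance block."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = report.config_hash
    gt = report.global_table.copy()
    gt["config_hash"] = h
    gt.to_csv(out / "global_qr_coefficients.csv", index=False)
    mt = report.moran_table.copy()
    mt["config_hash"] = h
    mt.to_csv(out / "moran.csv", index=False)
    ns = pd.concat([df.assign(tau=tau)
                    for tau, df in report.nonstationarity.items()])
    ns["config_hash"] = h
    ns.to_csv(out / "nonstationarity.csv", index=False)
    _io.write_block_table(report.data, out / "block_table.csv")
    export_maps(report, out)
    (out / "provenance.json").write_text(
        json.dumps({**report.provenance,
                    "bandwidths": {f"{t:g}": b
                                   for t, b in report.bandwidths.items()},
                    "bandwidth_audit": report.bandwidth_audit},
                   indent=2, default=str))
    with open(out / "run.log", "a") as fh:
        fh.write(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} INFO run "
                 f"config={h} seed={report.seed} "
                 f"n={len(report.data)}\n")


def export_maps(report: RunReport, out_dir) -> list[Path]:
    """GeoJSON point layers per (tau, coefficient) and per-tau predictions.

    Each coefficient layer carries estimate, se, t and the boolean
    ``significant`` = |t| > 1.96 (strictly); the prediction layer carries
    the locally fitted quantile.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for tau, gfit in report.gwqr_fits.items():
        base = report.data[["block_id", "u", "v"]].copy()
        for j, name in enumerate(COEF_NAMES):
            layer = base.copy()
            layer["estimate"] = gfit.local_beta_[:, j]
            if hasattr(gfit, "local_se_"):
                layer["se"] = gfit.local_se_[:, j]
                layer["t"] = gfit.local_t_[:, j]
                layer["significant"] = np.abs(gfit.local_t_[:, j]) > T_CRITICAL
            path = out / f"gwqr_tau{int(round(tau * 100))}_{name}.geojson"
            _io.write_geojson_points(layer, path)
            written.append(path)
        pred = base.copy()
        pred["fitted_quantile"] = gfit.fitted_quantile_
        path = out / f"gwqr_tau{int(round(tau * 100))}_prediction.geojson"
        _io.write_geojson_points(pred, path)
        written.append(path)
    return written
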