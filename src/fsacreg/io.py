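"""Configuration, file formats, and the batch entry point.

Formats: wide curves CSV (first column ``unit``, remaining columns named by
grid value), two-column response CSV (``unit,value``), GAL or edge-list
weights, YAML/JSON run configuration with a versioned schema, JSON fit
reports.  Every artifact written carries the configuration hash and root
seed so any output can be regenerated from its own metadata.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, estimator, functional, simulation, weights as weights_mod
from .functional import FunctionalSample
from .weights import SpatialWeights

__all__ = [
    "RunConfig",
    "load_config",
    "read_response",
    "read_curves",
    "write_curves",
    "write_response",
    "fit_report",
    "run",
    "ConfigError",
]

SCHEMA_VERSION = 1

logger = logging.getLogger("fsacreg")


class ConfigError(ValueError):
    """Run configuration is malformed or references missing inputs."""


@dataclass
class RunConfig:
    """One batch run: what to do, on which inputs, with which knobs."""

    mode: str
    out_dir: str = "fsacreg-out"
    seed: int = 0
    # inputs for fit / diagnose
    curves: str | None = None
    response: str | None = None
    weights: str | None = None
    weights_format: str = "gal"
    lattice: tuple[int, int] | None = None
    contiguity: str = "rook"
    # model knobs
    variant: str = "fsac"
    threshold: float = 0.85
    include_intercept: bool = False
    alpha: float = 0.05
    optimizer_box: float = 0.99
    optimizer_starts: int = 3
    stat: str = "moran"
    # DGP knobs for simulate / mc-study
    rho: float = 0.1
    lam: float = 0.9
    reps: int = 500
    p: int = 100
    beta_variant: str = "A"
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "fit", "diagnose", "mc-study"):
            raise ConfigError(f"unknown mode: {self.mode!r}")
        if not 0.0 < self.threshold <= 1.0:
            raise ConfigError("threshold must be in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported schema_version {self.schema_version}")
        if self.mode in ("fit", "diagnose"):
            for name in ("curves", "response") if self.mode == "fit" else ("response",):
                path = getattr(self, name)
                if path is None:
                    raise ConfigError(f"mode {self.mode!r} requires {name!r}")
                if not Path(path).exists():
                    raise ConfigError(f"{name} path does not exist: {path}")
            if self.weights is None and self.lattice is None:
                raise ConfigError("need either a weights file or a lattice spec")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Read a YAML or JSON run configuration; unknown keys are errors."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "lattice" in data and data["lattice"] is not None:
        data["lattice"] = tuple(data["lattice"])
    return RunConfig(**data)


def read_response(path, weights: SpatialWeights | None = None) -> pd.Series:
    """Two-column (unit, value) CSV as a labeled series, aligned to weights.

    Alignment is a label join, not positional: shuffled rows give the same
    vector.  Duplicate labels, non-numeric values, or labels missing from the
    weights raise.
    """
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ConfigError(f"response file {path} needs (unit, value) columns")
    units = df.iloc[:, 0].astype(str)
    if units.duplicated().any():
        dups = sorted(units[units.duplicated()].unique())
        raise ConfigError(f"duplicate unit labels in {path}: {dups}")
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    if vals.isna().any():
        bad = units[vals.isna()].tolist()
        raise ConfigError(f"non-numeric response values for units {bad}")
    series = pd.Series(vals.to_numpy(), index=units.to_numpy(), name="response")
    if weights is not None and weights.labels is not None:
        missing = [lab for lab in weights.labels if lab not in series.index]
        if missing:
            raise ConfigError(f"units in weights but absent from response: {missing}")
        series = series.loc[list(weights.labels)]
    return series


def read_curves(path) -> tuple[list[str], FunctionalSample]:
    """Wide curves CSV: first column unit label, headers are grid values."""
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    labels = df.iloc[:, 0].astype(str).tolist()
    grid = np.array([float(c) for c in df.columns[1:]])
    values = np.ascontiguousarray(df.iloc[:, 1:].to_numpy(dtype=float))
    return labels, FunctionalSample(grid, values)


def write_curves(path, labels, sample: FunctionalSample) -> None:
    df = pd.DataFrame(sample.values, columns=[repr(float(g)) for g in sample.grid])
    df.insert(0, "unit", list(labels))
    df.to_csv(path, index=False, float_format="%.17g")


def write_response(path, labels, y: np.ndarray) -> None:
    pd.DataFrame({"unit": list(labels), "value": y}).to_csv(
        path, index=False, float_format="%.17g"
    )


def fit_report(f: estimator.FSACFit, spec: estimator.FSACSpec, alpha: float) -> dict:
    """JSON-serializable fit summary including the slope band."""
    basis = spec.scores.basis_ref
    lo, hi = estimator.confidence_band(f, basis, alpha)
    return {
        "variant": f.variant,
        "n": spec.n,
        "m": spec.m,
        "rho_hat": f.rho_hat,
        "lambda_hat": f.lambda_hat,
        "beta_m_hat": f.beta_m_hat.tolist(),
        "intercept_hat": f.intercept_hat,
        "sigma2_hat": f.sigma2_hat,
        "loglik": f.loglik,
        "cov_hat": f.cov_hat.tolist(),
        "grid": basis.grid.tolist(),
        "beta_curve": f.beta_curve.tolist(),
        "band_lower": lo.tolist(),
        "band_upper": hi.tolist(),
        "alpha": alpha,
        "converged": f.converged,
        "at_boundary": f.at_boundary,
        "cov_repaired": f.cov_repaired,
        "n_eval": f.n_eval,
    }


def _load_weights(config: RunConfig, n_hint: int | None = None) -> SpatialWeights:
    if config.weights is not None:
        w = weights_mod.read_weights(config.weights, config.weights_format)
        return weights_mod.row_standardize(w)
    R, T = config.lattice
    return weights_mod.build_lattice_weights(R, T, config.contiguity)


def _write_json(path: Path, payload: dict, config: RunConfig) -> None:
    payload = dict(payload)
    payload["_meta"] = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "schema_version": SCHEMA_VERSION,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def run(config: RunConfig) -> dict:
    """Execute one configured run; returns a manifest of written artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info(
        "mode=%s seed=%d config=%s variant=%s threshold=%s contiguity=%s "
        "intercept=%s alpha=%s",
        config.mode, config.seed, config.hash(), config.variant, config.threshold,
        config.contiguity, config.include_intercept, config.alpha,
    )
    written: dict[str, str] = {}

    if config.mode == "simulate":
        cfg = simulation.SimulationConfig(
            R=config.lattice[0] if config.lattice else 20,
            T=config.lattice[1] if config.lattice else 20,
            rho=config.rho,
            lam=config.lam,
            reps=1,
            seed=config.seed,
            p=config.p,
            beta_variant=config.beta_variant,
            threshold=config.threshold,
            contiguity=config.contiguity,
        )
        y, curves, w = simulation.generate_dataset(cfg, cfg.rep_seed(0))
        labels = w.labels
        write_curves(out / "curves.csv", labels, curves)
        write_response(out / "response.csv", labels, y)
        weights_mod.write_weights(w, out / "weights.gal", "gal")
        _write_json(out / "simulate_meta.json", {"dgp": asdict(cfg)}, config)
        written = {k: str(out / v) for k, v in {
            "curves": "curves.csv", "response": "response.csv",
            "weights": "weights.gal", "meta": "simulate_meta.json"}.items()}

    elif config.mode == "fit":
        w = _load_weights(config)
        y = read_response(config.response, w)
        labels, curves = read_curves(config.curves)
        if w.labels is not None and labels != list(w.labels):
            index = {lab: i for i, lab in enumerate(labels)}
            missing = [lab for lab in w.labels if lab not in index]
            if missing:
                raise ConfigError(f"curves missing units: {missing}")
            curves = FunctionalSample(
                curves.grid, curves.values[[index[lab] for lab in w.labels]]
            )
        basis = functional.fpca(curves, threshold=config.threshold)
        sc = functional.scores(curves, basis)
        spec = estimator.FSACSpec(
            y.to_numpy(), sc, w, variant=config.variant,
            include_intercept=config.include_intercept,
        )
        f = estimator.fit(
            spec,
            estimator.OptimizerConfig(box=config.optimizer_box, n_starts=config.optimizer_starts),
        )
        _write_json(out / "fit.json", fit_report(f, spec, config.alpha), config)
        written = {"fit": str(out / "fit.json")}

    elif config.mode == "diagnose":
        w = _load_weights(config)
        y = read_response(config.response, w)
        if config.stat == "moran":
            res = diagnostics.morans_i(y.to_numpy(), w, seed=config.seed)
            payload = {
                "statistic": "morans_i", "I": res.I, "expectation": res.expectation,
                "variance": res.variance, "z": res.z, "p_value": res.p_value,
                "method": res.method, "n_perm": res.n_perm,
                "interpretation": res.interpretation(),
            }
        elif config.stat == "residual-lm":
            labels, curves = read_curves(config.curves)
            basis = functional.fpca(curves, threshold=config.threshold)
            sc = functional.scores(curves, basis)
            spec = estimator.FSACSpec(y.to_numpy(), sc, w, variant="fsar_lag")
            f = estimator.fit(spec)
            res = diagnostics.residual_spatial_test(f, spec)
            payload = {
                "statistic": "residual_lm", "T": res.T, "df": res.df,
                "p_value": res.p_value, "T1": res.T1, "T2": res.T2,
                "var_rho": res.var_rho,
            }
        else:
            raise ConfigError(f"unknown diagnostic stat: {config.stat!r}")
        _write_json(out / "diagnose.json", payload, config)
        written = {"diagnose": str(out / "diagnose.json")}

    elif config.mode == "mc-study":
        cfg = simulation.SimulationConfig(
            R=config.lattice[0] if config.lattice else 20,
            T=config.lattice[1] if config.lattice else 20,
            rho=config.rho, lam=config.lam, reps=config.reps, seed=config.seed,
            p=config.p, beta_variant=config.beta_variant,
            threshold=config.threshold, contiguity=config.contiguity,
        )
        res = simulation.run_monte_carlo(cfg)
        table = pd.DataFrame(
            [{
                "n": cfg.n, "rho": cfg.rho, "rho_hat": res.mean_rho,
                "lambda": cfg.lam, "lambda_hat": res.mean_lambda,
                "sigma2_hat": res.mean_sigma2, "mse_rho": res.mse_rho,
                "mse_lambda": res.mse_lambda, "mse_sigma2": res.mse_sigma2,
                "mse_beta": res.mse_beta,
            }]
        )
        table.to_csv(out / "mc_table.csv", index=False)
        res.per_rep.to_csv(out / "mc_per_rep.csv", index=False)
        _write_json(
            out / "mc_meta.json",
            {"dgp": asdict(cfg), "n_failed": res.n_failed},
            config,
        )
        written = {k: str(out / v) for k, v in {
            "table": "mc_table.csv", "per_rep": "mc_per_rep.csv",
            "meta": "mc_meta.json"}.items()}

    return written
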