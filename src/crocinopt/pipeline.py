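"""End-to-end workflow: design -> simulate -> resolve -> dataset ->
train -> surface -> optimize -> diagnostics -> quantify.

Every stage writes a plain CSV or JSON artifact into the run directory
and is importable as a library function; the command-line interface in
:mod:`crocinopt.cli` is a thin wrapper.  All randomness flows from the
master seed, so a rerun with the same configuration reproduces every
artifact hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import crocinopt.ann as ann
import crocinopt.diagnostics as diagnostics
import crocinopt.doe as doe
import crocinopt.encoding as encoding
import crocinopt.quantification as quantification
import crocinopt.resolution as resolution
import crocinopt.simulate as simulate
import crocinopt.surface as surface

__all__ = ["RunConfig", "run_all", "load_config"]


@dataclass
class RunConfig:
    """Configuration of one optimization campaign."""

    master_seed: int = 0
    center_replicates: int = 2  # 27 + 2 -> 29 calibration runs
    rt_noise_sd: float = 0.005
    width_noise_cv: float = 0.02
    n_train: int = 486
    n_hidden: int = 8
    activation: str = "tanh"
    select_grid: bool = False  # scan the architecture grid before training
    restarts: int = 100
    max_epochs: int = 1000
    patience: int = 30
    retained_pairs: tuple = surface.DEFAULT_RETAINED_PAIRS
    surface_tg_levels: tuple = (8.0, 10.0, 12.0)
    surface_step_T: float = 0.25
    surface_step_phi: float = 0.01
    optimum_tg_step: float = 0.1
    coloring_strength: float = 254.0  # E1%1cm(440 nm) of the quantified sample
    crrn_draws: int = 20_000

    def sim_config(self) -> simulate.SimulationConfig:
        return simulate.SimulationConfig(
            seed=self.master_seed,
            rt_noise_sd=self.rt_noise_sd,
            width_noise_cv=self.width_noise_cv,
        )

    def train_config(self) -> ann.TrainConfig:
        return ann.TrainConfig(
            max_epochs=self.max_epochs,
            patience=self.patience,
            restarts=self.restarts,
            seed=self.master_seed,
        )


def load_config(path) -> RunConfig:
    """Read a RunConfig from a YAML file (unknown keys are rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "retained_pairs" in raw:
        raw["retained_pairs"] = tuple(tuple(p) for p in raw["retained_pairs"])
    for key in ("surface_tg_levels",):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, outdir, resume: bool = False) -> dict:
    """Execute the full pipeline; returns the run manifest (also written).

    With ``resume=True`` stages whose artifact already exists are
    loaded instead of recomputed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    factors = doe.default_factors()
    timings: dict[str, float] = {}
    artifacts: dict[str, str] = {}

    def stage(name, path, compute, write, read):
        t0 = time.perf_counter()
        path = outdir / path
        if resume and path.exists():
            value = read(path)
        else:
            value = compute()
            write(value, path)
        artifacts[name] = str(path)
        timings[name] = time.perf_counter() - t0
        return value

    # 1. design
    design = stage(
        "design", "design.csv",
        lambda: doe.campaign_design(factors, config.center_replicates),
        lambda v, p: doe.design_to_frame(v).to_csv(p, index=False),
        lambda p: doe.design_from_frame(pd.read_csv(p)),
    )

    # 2. simulate (ground-truth analyte parameters travel with the run)
    sim_config = config.sim_config()
    params = simulate.sample_analyte_params(sim_config)
    chroms = stage(
        "peaks", "peaks.csv",
        lambda: simulate.simulate_campaign(params, design, sim_config),
        lambda v, p: simulate.peaks_to_frame(v).to_csv(p, index=False),
        lambda p: _chroms_from_frame(pd.read_csv(p), design),
    )

    # 3. resolutions
    records = stage(
        "resolutions", "resolutions.csv",
        lambda: [r for c in chroms for r in resolution.adjacent_resolutions(c)],
        lambda v, p: resolution.records_to_frame(v).to_csv(p, index=False),
        lambda p: _records_from_frame(pd.read_csv(p)),
    )

    # 4. dataset
    calibration, external = encoding.assemble(chroms)
    split = encoding.split_dataset(calibration, n_train=config.n_train)
    X_cal, y_cal = encoding.samples_to_arrays(calibration)
    X_ext, y_ext = encoding.samples_to_arrays(external)
    tr, vl = list(split.training), list(split.validation)
    X_tr, y_tr = X_cal[tr], y_cal[tr]
    X_vl, y_vl = X_cal[vl], y_cal[vl]
    stage(
        "dataset", "dataset.csv",
        lambda: _dataset_frame(calibration, external, split),
        lambda v, p: v.to_csv(p, index=False),
        lambda p: pd.read_csv(p),
    )

    # 5. train
    train_config = config.train_config()
    if config.select_grid:
        n_hidden, activation, _ = ann.select_architecture(
            X_tr, y_tr, X_vl, y_vl, train_config
        )
    else:
        n_hidden, activation = config.n_hidden, config.activation

    def _train():
        return ann.train_ensemble(
            n_hidden, activation, X_tr, y_tr, X_vl, y_vl, train_config
        )

    ensemble = stage(
        "model", "model.json",
        _train,
        lambda v, p: v.to_json(p),
        lambda p: ann.EnsembleModel.from_json(p),
    )

    r2_tr, se_tr = ann.metrics(ann.predict(ensemble, X_tr), y_tr)
    r2_vl, se_vl = ann.metrics(ann.predict(ensemble, X_vl), y_vl)
    r2_ex, se_ex = ann.metrics(ann.predict(ensemble, X_ext), y_ext)

    # 6. surfaces at the three design t_g levels
    surfaces = stage(
        "surfaces", "surfaces.csv",
        lambda: [
            surface.evaluate_surface(
                ensemble, tg, factors, config.retained_pairs,
                step_T=config.surface_step_T, step_phi=config.surface_step_phi,
            )
            for tg in config.surface_tg_levels
        ],
        lambda v, p: surface.surfaces_to_frame(v).to_csv(p, index=False),
        lambda p: _surfaces_from_frame(pd.read_csv(p)),
    )

    # 7. optimum over a fine t_g grid
    ftg = factors[1]
    tg_fine = np.round(
        np.arange(ftg.low, ftg.high + config.optimum_tg_step / 2,
                  config.optimum_tg_step),
        6,
    )
    fine_surfaces = [
        surface.evaluate_surface(
            ensemble, float(tg), factors, config.retained_pairs,
            step_T=config.surface_step_T, step_phi=config.surface_step_phi,
        )
        for tg in tg_fine
    ]
    optimum = surface.locate_optimum(fine_surfaces)
    stage(
        "optimum", "optimum.json",
        lambda: {
            "T": optimum.argmax[0], "tg": optimum.argmax[1],
            "phi": optimum.argmax[2], "RG": optimum.rg_max,
            "on_boundary": optimum.on_boundary,
            "alternatives": [list(a) for a in optimum.alternatives],
        },
        _write_json,
        _read_json,
    )

    # 8. sensitivity
    derivs = diagnostics.partial_derivatives(ensemble, X_cal)
    sens = diagnostics.factor_importance(derivs)
    stage(
        "sensitivity", "sensitivity.json",
        lambda: {
            "mean_abs_derivative": sens.mean_abs_derivative,
            "importance": sens.importance,
        },
        _write_json,
        _read_json,
    )

    # 9. SRD of residuals across DOE points
    resid_matrix, cond_ids, ref_col = _residual_matrix(
        ensemble, calibration, design
    )
    srd_result = diagnostics.srd(
        resid_matrix, ref_col, n_draws=config.crrn_draws, seed=config.master_seed
    )
    stage(
        "srd", "srd.json",
        lambda: {
            "condition_ids": cond_ids,
            "srd": srd_result.srd.tolist(),
            "srd_normalized": srd_result.srd_normalized.tolist(),
            "reference": cond_ids[ref_col],
            "crrn": {
                "mean": srd_result.crrn_mean, "sd": srd_result.crrn_sd,
                "lower": srd_result.crrn_lower, "upper": srd_result.crrn_upper,
                "pct_2_5": srd_result.crrn_pct_2_5,
                "pct_97_5": srd_result.crrn_pct_97_5,
            },
            "inside_interval": srd_result.inside_interval.tolist(),
        },
        _write_json,
        _read_json,
    )

    # 10. quantification of the center-point chromatogram
    center = next(c for c in chroms if c.condition.coded == (0.0, 0.0, 0.0))
    quant_frame = pd.DataFrame(
        {
            "abbreviation": [p.label for p in params],
            "area": [pk.area for pk in center.peaks],
        }
    )
    stage(
        "quantification", "quantification.csv",
        lambda: pd.DataFrame(
            [
                {"abbreviation": r.abbreviation, "conc_mg_per_g": r.concentration}
                for r in quantification.quantify_table(
                    quant_frame, config.coloring_strength
                )
            ]
        ),
        lambda v, p: v.to_csv(p, index=False),
        lambda p: pd.read_csv(p),
    )

    manifest = {
        "master_seed": config.master_seed,
        "package_version": __import__("crocinopt").__version__,
        "architecture": {"n_hidden": n_hidden, "activation": activation},
        "counts": {
            "design_rows": len(design),
            "calibration_samples": len(calibration),
            "external_samples": len(external),
            "training_samples": len(tr),
            "validation_samples": len(vl),
        },
        "metrics": {
            "r2_train": r2_tr, "r2_validation": r2_vl, "r2_external": r2_ex,
            "se_train": se_tr, "se_validation": se_vl, "se_external": se_ex,
        },
        "optimum": {
            "T": optimum.argmax[0], "tg": optimum.argmax[1],
            "phi": optimum.argmax[2], "RG": optimum.rg_max,
        },
        "artifacts": {
            name: {"path": path, "sha256": _sha256(Path(path))}
            for name, path in artifacts.items()
        },
        "timings_s": timings,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


# --- artifact (de)serialization helpers ---


def _write_json(value, path) -> None:
    with open(path, "w") as fh:
        json.dump(value, fh, indent=2)


def _read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _dataset_frame(calibration, external, split) -> pd.DataFrame:
    role = np.empty(len(calibration), dtype=object)
    role[list(split.training)] = "train"
    role[list(split.validation)] = "val"
    rows = []
    for samples, roles in ((calibration, role), (external, None)):
        for k, s in enumerate(samples):
            row = {f"x{i+1:02d}": v for i, v in enumerate(s.x)}
            row["y"] = s.y
            row["role"] = roles[k] if roles is not None else "external"
            row["condition_id"] = s.condition_id
            row["i"], row["j"] = s.pair
            rows.append(row)
    return pd.DataFrame(rows)


def _chroms_from_frame(df: pd.DataFrame, design) -> list:
    by_id = {p.id: p for p in design}
    chroms = []
    for cond_id, group in df.groupby("condition_id", sort=False):
        peaks = tuple(
            simulate.Peak(
                analyte_id=int(r.analyte_id), rt=float(r.rt_min),
                w_half=float(r.whalf_min), area=float(r.area),
            )
            for r in group.sort_values("analyte_id").itertuples()
        )
        chroms.append(
            simulate.Chromatogram(condition=by_id[cond_id], peaks=peaks, seed=0)
        )
    order = {p.id: k for k, p in enumerate(design)}
    chroms.sort(key=lambda c: order[c.condition.id])
    return chroms


def _records_from_frame(df: pd.DataFrame) -> list:
    return [
        resolution.ResolutionRecord(
            condition_id=str(r.condition_id), pair=(int(r.i), int(r.j)),
            R=float(r.R), y=float(r.y),
        )
        for r in df.itertuples()
    ]


def _surfaces_from_frame(df: pd.DataFrame) -> list:
    out = []
    for tg, group in df.groupby("tg", sort=True):
        piv = group.pivot(index="T", columns="phi", values="RG")
        out.append(
            surface.SurfaceGrid(
                t_g=float(tg),
                T_axis=piv.index.to_numpy(dtype=float),
                phi_axis=piv.columns.to_numpy(dtype=float),
                R_G=piv.to_numpy(dtype=float),
            )
        )
    return out


def _residual_matrix(ensemble, calibration, design):
    """Absolute residuals per pair (rows) x calibration DOE point (columns).

    Center replicates are averaged into the center column; the center
    point is the SRD reference.
    """
    key_of = {}
    for p in design:
        if p.role != "calibration":
            continue
        key_of[p.id] = "center" if p.coded == (0.0, 0.0, 0.0) else p.id

    X, y = encoding.samples_to_arrays(calibration)
    resid = np.abs(ann.predict(ensemble, X) - y)
    acc: dict[str, dict[tuple, list]] = {}
    for s, r in zip(calibration, resid):
        col = key_of[s.condition_id]
        acc.setdefault(col, {}).setdefault(s.pair, []).append(r)

    cols = sorted(acc)
    pairs = sorted({pair for d in acc.values() for pair in d})
    matrix = np.array(
        [[float(np.mean(acc[c][p])) for c in cols] for p in pairs]
    )
    return matrix, cols, cols.index("center")
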