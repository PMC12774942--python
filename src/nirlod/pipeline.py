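"""End-to-end pipeline: data -> pretreatment -> PLS -> validation -> LOD.

``run_pipeline`` reproduces the full study workflow on either simulated
or loaded spectra: replicate averaging, calibration/test split, the
standardized pretreatment chain with and/or without OSC, LOOCV-based
latent-variable selection, external test-set validation, both LOD/LOQ
frameworks, the latent-structure diagnostics and, optionally, an
LV-truncation contrast table.  Identical config and seed give identical
outputs; every written file embeds the config hash and seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ReferenceTable, SpectraSet
from .diagnostics import (
    explained_y_variance_per_lv,
    project_pure_spectrum,
    truncation_study,
)
from .instruments import get_profile
from .io import (
    read_concentrations_csv,
    read_spectra_csv,
    write_concentrations_csv,
    write_spectra_csv,
)
from .lod import LOD_TABLE_COLUMNS, lod_report
from .pls import evaluate, loocv, pls_fit
from .preprocess import PreprocessOptions, preprocess_chain
from .synthetic import SyntheticConfig, average_replicates, simulate_dataset

METRICS_COLUMNS = ["analyte", "osc", "LVs", "R2C", "RMSEC", "R2CV", "RMSECV",
                   "R2TSV", "RMSEP"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "simulate"              # "simulate" | "load"
    instrument: str = "n500"
    analyte: str = "vitexin"            # "vitexin" | "isovitexin" | "sum"
    sample_state: str = "milled"        # "milled" | "intact"
    osc: str = "off"                    # "on" | "off" | "both"
    A_max: int = 10
    n_test: int = 10
    n_samples: int = 50                 # calibration size (simulate mode)
    seed: int = 0
    spectra_path: str | None = None     # load mode
    concentrations_path: str | None = None
    truncation_lvs: tuple = ()          # e.g. (3, 5); empty = skip
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.A_max < 1:
            raise ValueError("A_max must be >= 1")
        if self.osc not in ("on", "off", "both"):
            raise ValueError("osc must be 'on', 'off' or 'both'")
        if self.mode not in ("simulate", "load"):
            raise ValueError("mode must be 'simulate' or 'load'")

    def hash(self) -> str:
        # output_dir is where results land, not what they are
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclass
class RunResult:
    """Everything one pipeline run produced, keyed by OSC setting."""

    config: RunConfig
    metrics: pd.DataFrame               # R2/RMSE per model (METRICS_COLUMNS)
    lod_table: pd.DataFrame             # both LOD frameworks (+ osc column)
    truncation: pd.DataFrame | None     # LV-truncation contrast, when requested
    diagnostics: dict                   # per-LV y variance, pure projection
    models: dict                        # osc flag -> fitted PLSModel
    calibration: tuple                  # (SpectraSet averaged cal, y_cal)
    test: tuple                         # (SpectraSet averaged test, y_test)


def _acquire(config: RunConfig) -> tuple[SpectraSet, ReferenceTable]:
    if config.mode == "simulate":
        profile = get_profile(config.instrument)
        syn = SyntheticConfig(
            n_samples=config.n_samples + config.n_test,
            sample_state=config.sample_state,
            seed=config.seed,
        )
        return simulate_dataset(syn, profile)
    spectra = read_spectra_csv(config.spectra_path, instrument=config.instrument)
    table = read_concentrations_csv(config.concentrations_path)
    ids = spectra.replicate_of if spectra.replicate_of is not None else spectra.sample_ids
    missing = sorted(set(ids) - set(table.sample_ids))
    orphans = sorted(set(table.sample_ids) - set(ids))
    if missing or orphans:
        raise ValueError(
            f"sample-id mismatch between spectra and reference table: "
            f"spectra-only={missing}, table-only={orphans}"
        )
    return spectra, table


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the complete calibration + LOD workflow for one configuration."""
    spectra, table = _acquire(config)
    averaged = (
        average_replicates(spectra) if spectra.replicate_of is not None else spectra
    )
    # align reference rows to averaged spectra order
    order = [table.sample_ids.index(s) for s in averaged.sample_ids]
    table = table.subset(order)
    y_all = table.y(config.analyte)

    n = averaged.n_samples
    n_test = min(config.n_test, max(n - 3, 0))
    cal_idx = np.arange(n - n_test)
    test_idx = np.arange(n - n_test, n)
    cal, test = averaged.subset(cal_idx), averaged.subset(test_idx)
    y_cal, y_test = y_all[cal_idx], y_all[test_idx]

    osc_flags = {"on": [True], "off": [False], "both": [False, True]}[config.osc]

    metrics_rows, lod_rows, models, diagnostics = [], [], {}, {}
    truncation_frames = []
    for use_osc in osc_flags:
        opts = PreprocessOptions(osc=use_osc)
        cv = loocv(cal.absorbance, y_cal, config.A_max, opts)
        X_cal, record = preprocess_chain(cal.absorbance, y_cal, opts)
        model = pls_fit(X_cal, y_cal, cv.chosen_A)
        model.pretreatment = record
        X_test = record.transform(test.absorbance)

        m_cal = evaluate(model, X_cal, y_cal, "calibration")
        m_tsv = evaluate(model, X_test, y_test, "testset") if len(y_test) >= 2 else None
        metrics_rows.append({
            "analyte": config.analyte,
            "osc": use_osc,
            "LVs": model.A,
            "R2C": m_cal.r2,
            "RMSEC": m_cal.rmse,
            "R2CV": cv.r2cv(),
            "RMSECV": cv.rmsecv(),
            "R2TSV": m_tsv.r2 if m_tsv else np.nan,
            "RMSEP": m_tsv.rmse if m_tsv else np.nan,
        })

        rep = lod_report(
            model, X_cal, y_cal, cv,
            replicate_variance=cal.replicate_variance,
            osc_used=use_osc,
        )
        row = {"analyte": config.analyte, "osc": use_osc}
        row.update(rep.to_row())
        lod_rows.append(row)

        diag = {"explained_y_variance_per_lv":
                explained_y_variance_per_lv(model, y_cal).tolist()}
        if cal.pure_spectra is not None and config.analyte in cal.pure_spectra:
            proj = project_pure_spectrum(
                model, cal.pure_spectra[config.analyte], record
            )
            diag["pure_projection"] = proj.coefficients.tolist()
            diag["pure_projection_normalized"] = proj.normalized.tolist()
            diag["pure_projection_residual_fraction"] = proj.residual_norm_fraction
        diagnostics["osc" if use_osc else "no_osc"] = diag
        models[use_osc] = model

        if config.truncation_lvs:
            tab = truncation_study(
                cal.absorbance, y_cal, config.truncation_lvs, opts,
                replicate_variance=cal.replicate_variance,
            )
            tab.insert(0, "osc", use_osc)
            truncation_frames.append(tab)

    result = RunResult(
        config=config,
        metrics=pd.DataFrame(metrics_rows, columns=METRICS_COLUMNS),
        lod_table=pd.DataFrame(
            lod_rows, columns=["analyte", "osc"] + LOD_TABLE_COLUMNS
        ),
        truncation=(
            pd.concat(truncation_frames, ignore_index=True)
            if truncation_frames else None
        ),
        diagnostics=diagnostics,
        models=models,
        calibration=(cal, y_cal),
        test=(test, y_test),
    )
    if config.output_dir is not None:
        _write_outputs(result, spectra, table)
    return result


def _write_outputs(result: RunResult, spectra: SpectraSet, table: ReferenceTable) -> None:
    cfg = result.config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": cfg.hash(), "seed": cfg.seed}

    def dump(df: pd.DataFrame, name: str) -> None:
        with open(out / name, "w") as fh:
            for k, v in prov.items():
                fh.write(f"# {k}={v}\n")
            df.to_csv(fh, index=False)

    dump(result.metrics, "metrics.csv")
    dump(result.lod_table, "lod.csv")
    if result.truncation is not None:
        dump(result.truncation, "truncation.csv")
    if cfg.mode == "simulate":
        write_spectra_csv(out / "spectra.csv", spectra, provenance=prov)
        write_concentrations_csv(out / "concentrations.csv", table, provenance=prov)
    with open(out / "diagnostics.json", "w") as fh:
        json.dump({**prov, "diagnostics": result.diagnostics}, fh, indent=2)
    with open(out / "run_log.json", "w") as fh:
        json.dump({**prov, "config": asdict(cfg)}, fh, indent=2, default=str)
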