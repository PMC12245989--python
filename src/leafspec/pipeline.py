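"""End-to-end campaign analysis: data in, report out.

The pipeline runs, in order: data acquisition (simulate or load a manifest)
-> integrated reflectance and vegetation indices -> mixed models -> PCA and
per-PC mixed models -> PLS-DA tuning with held-out evaluation and
wavelength importance.  All inter-stage exchange happens through in-memory
objects; rendered CSV/JSON files are terminal artifacts only.  A single
seed fixes the simulation and the PLS-DA split/folds, so the entire report
is reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chemometrics import SpectraMatrix, pca_fit, tune_plsda
from .indices import INDEX_NAMES, INTEGRATED, index_table
from .io import load_set, read_panel_csv
from .mixed import fit_all_indices, fit_lmm, fit_pcs
from .simulate import LeafSimConfig, simulate_campaign
from .spectra import SpectrumSet

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "simulate"                  # "simulate" | "manifest"
    sim: LeafSimConfig | None = None
    manifest_path: str | None = None
    panel_path: str | None = None
    seed: int = 0
    pca_components: int = 10
    n_pc_models: int = 4
    plsda_max_components: int = 60
    plsda_folds: int = 10
    plsda_train_fraction: float = 0.7
    indices: tuple[str, ...] = INDEX_NAMES
    output_dir: str | None = None
    stitch_policy: str = "cut"
    pca_standardize: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "manifest"):
            raise ValueError(f"unknown input mode {self.mode!r}")
        if self.mode == "manifest" and not self.manifest_path:
            raise ValueError("manifest mode requires manifest_path")
        if self.mode == "simulate" and self.sim is None:
            self.sim = LeafSimConfig(seed=self.seed)


@dataclass
class RunReport:
    """Aggregate results of a pipeline run (JSON-serialisable)."""

    dataset: dict
    integrated_lmm: dict
    pca_variance: list
    pc_lmms: dict
    index_lmm_table: list
    plsda: dict
    provenance: dict
    index_summary: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "integrated_reflectance_lmm": self.integrated_lmm,
            "pca_variance": self.pca_variance,
            "pc_lmms": self.pc_lmms,
            "index_lmm_table": self.index_lmm_table,
            "plsda": self.plsda,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True,
                          default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def _acquire(config: RunConfig) -> SpectrumSet:
    if config.mode == "simulate":
        sim = dataclasses.replace(config.sim, seed=config.seed)
        logger.info("stage=simulate seed=%d", config.seed)
        return simulate_campaign(sim)
    panel = read_panel_csv(config.panel_path) if config.panel_path else None
    logger.info("stage=load manifest=%s", config.manifest_path)
    return load_set(config.manifest_path, panel=panel,
                    policy=config.stitch_policy)


def run(config: RunConfig) -> RunReport:
    """Execute every stage and return the aggregate report.

    With ``config.output_dir`` set, each stage also renders its artifact
    (wide spectra CSV, index CSV, PCA CSVs, PLS-DA CSV/JSON, rendered index-summary
    CSV, report JSON); partial outputs persist if a later stage fails.
    """
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    stage = "acquire"
    try:
        sset = _acquire(config)
        meta = sset.meta_frame()
        dataset = {
            "n_spectra": len(sset),
            "per_treatment": sset.treatment_counts(),
            "n_trees": int(meta["tree_id"].nunique()),
            "n_dates": int(meta["date"].nunique()),
            "design": sset.design().to_dict(orient="records"),
        }
        logger.info("stage=acquire n_spectra=%d", len(sset))
        if outdir:
            sset.to_csv(outdir / "spectra_wide.csv")

        stage = "indices"
        idx_df = index_table(sset, names=tuple(config.indices) + (INTEGRATED,))
        if outdir:
            idx_df.to_csv(outdir / "indices.csv", index=False)
        logger.info("stage=indices rows=%d", len(idx_df))

        stage = "integrated_lmm"
        integ = idx_df[idx_df["index_name"] == INTEGRATED]
        integ_res = fit_lmm(integ, "value")
        by_trt = integ.groupby("treatment")["value"].mean()
        integrated_lmm = {
            "group_means": by_trt.to_dict(),
            **integ_res.report_row(),
            "eco2_effect_pct": 100.0 * integ_res.params[1] / integ_res.params[0],
        }
        logger.info("stage=integrated_lmm effect=%.3f", integ_res.params[1])

        stage = "index_lmms"
        veg = idx_df[idx_df["index_name"] != INTEGRATED]
        index_models = fit_all_indices(veg)
        if outdir:
            index_models.to_csv(outdir / "index_lmms.csv", index=False)
            render_index_summary(index_models).to_csv(
                outdir / "index_lmm_summary.csv", index=False)
        logger.info("stage=index_lmms indices=%d", len(index_models))

        stage = "pca"
        matrix = SpectraMatrix.from_spectrum_set(sset)
        pca = pca_fit(matrix, n_components=config.pca_components,
                      standardize=config.pca_standardize)
        pca_var = pca.variance_table()
        if outdir:
            pca_var.to_csv(outdir / "pca_variance.csv", index=False)
            pd.DataFrame(
                pca.scores,
                columns=[f"PC{k+1}" for k in range(pca.n_components)],
            ).to_csv(outdir / "pca_scores.csv", index=False)
            pd.DataFrame(
                pca.loadings, index=pca.wavelengths,
                columns=[f"PC{k+1}" for k in range(pca.n_components)],
            ).to_csv(outdir / "pca_loadings.csv", index_label="wavelength_nm")
        logger.info("stage=pca pc1=%.2f%%",
                    100 * pca.explained_variance_ratio[0])

        stage = "pc_lmms"
        scores_df = pd.DataFrame(
            pca.scores[:, : config.n_pc_models],
            columns=[f"PC{k+1}" for k in range(config.n_pc_models)],
        )
        pc_fits = fit_pcs(scores_df, meta, n_pcs=config.n_pc_models)
        pc_lmms = {
            name: res.report_row() for name, res in pc_fits["per_pc"].items()
        }
        pc_lmms["pooled"] = pc_fits["pooled"].report_row()
        logger.info("stage=pc_lmms pooled_effect=%.4f",
                    pc_fits["pooled"].params[1])

        stage = "plsda"
        plsda_seed = int(
            np.random.SeedSequence([config.seed, 11]).generate_state(1)[0]
            % (2**31)
        )
        tuning = tune_plsda(
            matrix.X, matrix.labels,
            max_components=config.plsda_max_components,
            folds=config.plsda_folds,
            train_fraction=config.plsda_train_fraction,
            seed=plsda_seed,
            wavelengths=matrix.wavelengths,
        )
        importance = tuning.results.wavelength_importance()
        plsda = {
            "best_n_components": tuning.best_n_components,
            "cv_best_accuracy": float(
                tuning.cv_curve["cv_accuracy"].iloc[tuning.best_n_components - 1]
            ),
            "test": tuning.test_stats.as_dict(),
            "n_train": int(tuning.train_indices.size),
            "n_test": int(tuning.test_indices.size),
        }
        if outdir:
            tuning.cv_curve.to_csv(outdir / "plsda_cv_curve.csv", index=False)
            importance.to_csv(outdir / "plsda_importance.csv", index=False)
            (outdir / "plsda_report.json").write_text(
                json.dumps(plsda, indent=2, sort_keys=True,
                           default=_json_default)
            )
        logger.info("stage=plsda best_k=%d test_acc=%.3f",
                    tuning.best_n_components, tuning.test_stats.accuracy)

        report = RunReport(
            dataset=dataset,
            integrated_lmm=integrated_lmm,
            pca_variance=pca_var.to_dict(orient="records"),
            pc_lmms=pc_lmms,
            index_lmm_table=index_models.to_dict(orient="records"),
            plsda=plsda,
            provenance={
                "package": "leafspec",
                "version": __version__,
                "seed": config.seed,
                "mode": config.mode,
                "pca_standardize": config.pca_standardize,
                "stitch_policy": config.stitch_policy,
            },
            index_summary=index_models,
        )
        if outdir:
            (outdir / "report.json").write_text(report.to_json())
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _two_sig(x: float) -> str:
    if not np.isfinite(x):
        return ""
    return f"{x:.2g}"


def render_index_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Render the per-index mixed-model table at two significant figures,
    with a significance star at alpha = 0.05 (full precision lives in the
    JSON report)."""
    out = pd.DataFrame()
    out["index"] = table["index"]
    out["aco2_mean"] = table["aco2_mean"].map(_two_sig)
    out["aco2_se"] = table["aco2_se"].map(_two_sig)
    out["eco2_effect"] = table["eco2_effect"].map(_two_sig)
    out["eco2_se"] = table["eco2_se"].map(_two_sig)
    out["t_value"] = table["t_value"].map(_two_sig)
    out["p_value"] = [
        _two_sig(p) + ("*" if sig else "")
        for p, sig in zip(table["p_value"], table["significant"])
    ]
    for col in ("tree_variance", "tree_sd", "date_variance", "date_sd",
                "residual_variance", "residual_sd"):
        out[col] = table[col].map(_two_sig)
    return out
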