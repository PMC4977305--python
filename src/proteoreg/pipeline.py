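"""End-to-end orchestration: screening -> clustering -> profiling -> modeling.

Runs the full analysis in stage order on a design table plus abundance
matrix, writing every artifact (screening report, dendrogram, cluster
assignments, PCA, VIP, correlation, ANCOVA divergence tables, per-variable
models with cross-validation, beta-weight table) under an output directory,
and returns a run report.  All randomness flows from named seeds in the
configuration; identical configurations produce byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import coassign, cut, impute_missing, standardize, ward_cluster
from .design import (
    DesignTable,
    builtin_design,
    collinearity,
    load_design,
    pure_error_df,
    write_design,
)
from .profiles import ancova, correlation_matrix, in_cluster_plsr, pca
from .response_surface import effect_significance_table, fit_all, kfold_cv
from .screening import DEFAULT_CRITERIA, ScreeningCriteria, screen
from .simulate import AbundanceMatrix, make_truth, read_matrix, simulate, write_matrix

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "make_demo", "load_config"]


@dataclass
class PipelineConfig:
    """All pipeline inputs, thresholds and seeds, with paper-default values."""

    design_path: str | None = None  # None -> packaged 32-run design
    matrix_path: str | None = None
    folds_path: str | None = None
    out_dir: str = "proteoreg_out"
    k_clusters: int = 8
    cv_folds: int = 4
    seed_cv: int = 0
    seed_randomization: int = 0
    vip_cutoff: float = 1.0
    divergence_p: float = 0.05
    vdv_alpha: float = 0.10
    criteria: dict[str, dict] = field(default_factory=dict)
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.k_clusters < 1:
            raise ValueError("k_clusters must be >= 1")
        for name in ("seed_cv", "seed_randomization"):
            if not isinstance(getattr(self, name), int):
                raise ValueError(f"{name} must be an integer")

    def screening_criteria(self) -> dict[str, ScreeningCriteria]:
        crit = {}
        for var_class, default in DEFAULT_CRITERIA.items():
            overrides = self.criteria.get(var_class, {})
            crit[var_class] = ScreeningCriteria(**{**asdict(default), **overrides})
        return crit


@dataclass
class RunReport:
    version: str
    config: dict
    stages: dict[str, dict]
    warnings: list[str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config": self.config,
                "stages": self.stages,
                "warnings": self.warnings,
            },
            indent=1,
            sort_keys=True,
        )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        doc = json.load(fh)
    return PipelineConfig(**doc)


def _fmt_float(x) -> float | None:
    return None if x is None or not np.isfinite(x) else float(x)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages and write artifacts under ``config.out_dir``."""
    if config.matrix_path is None:
        raise ValueError("config.matrix_path is required")
    if not Path(config.matrix_path).exists():
        raise FileNotFoundError(config.matrix_path)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    caught: list[str] = []
    stages: dict[str, dict] = {}

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        design = (
            load_design(config.design_path) if config.design_path else builtin_design()
        )
        matrix = read_matrix(config.matrix_path)
        R, P = collinearity(design)
        off = R.to_numpy()[~np.eye(len(R), dtype=bool)]
        stages["design"] = {
            "n_runs": design.n_runs,
            "n_factors": len(design.factors),
            "max_abs_correlation": float(np.max(np.abs(off))),
            "pure_error_df": pure_error_df(design),
        }
        R.to_csv(out / "design_collinearity_r.tsv", sep="\t")
        P.to_csv(out / "design_collinearity_p.tsv", sep="\t")

        # -- screening ----------------------------------------------------
        criteria = config.screening_criteria()
        report = screen(matrix, design, criteria)
        report.to_csv(out / "screening_report.tsv", sep="\t", index=False)
        selected_ids = list(report.loc[report["selected"], "variable"])
        by_class = report.groupby("class")["selected"]
        stages["screening"] = {
            "n_variables": len(report),
            "n_selected": int(report["selected"].sum()),
            "selected_by_class": {c: int(s.sum()) for c, s in by_class},
        }
        if len(selected_ids) < 2:
            raise RuntimeError("screening selected fewer than 2 variables")
        selected = matrix.subset(selected_ids)

        # -- clustering ---------------------------------------------------
        spots = selected.of_class("spot") if "spot" in set(
            selected.var_class.values()
        ) else selected
        k = min(config.k_clusters, len(spots.variables))
        prepared = impute_missing(standardize(spots))
        dendro = ward_cluster(prepared)
        (out / "dendrogram_spots.nwk").write_text(dendro.to_newick() + "\n")
        spot_assign = cut(dendro, k)
        joint = coassign(selected, k)
        joint.to_frame(selected.var_class).to_csv(
            out / "cluster_assignments.tsv", sep="\t", index=False
        )
        sizes = {
            str(c): len(joint.members(c)) for c in range(1, joint.k + 1)
        }
        stages["clustering"] = {
            "k": joint.k,
            "cluster_sizes": sizes,
            "n_spots_clustered": len(spot_assign.labels),
        }

        # -- cluster profiling -------------------------------------------
        pca_res = pca(selected)
        pd.DataFrame({
            "component": [f"PC{i+1}" for i in range(len(pca_res.eigenvalues))],
            "eigenvalue": pca_res.eigenvalues,
            "percent_variability": pca_res.proportions,
        }).to_csv(out / "pca_variance.tsv", sep="\t", index=False)
        pca_res.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
        pca_res.scores.to_csv(out / "pca_scores.tsv", sep="\t")

        vip_rows, div_rows, ancova_summ = [], [], []
        for c in range(1, joint.k + 1):
            members = joint.members(c)
            cluster_matrix = selected.subset(members)
            try:
                vip_table = in_cluster_plsr(
                    cluster_matrix, design, alpha=config.vdv_alpha,
                    seed=config.seed_randomization, vip_cutoff=config.vip_cutoff,
                )
                for factor, row in vip_table.iterrows():
                    vip_rows.append({
                        "cluster": c, "factor": factor,
                        "vip": row["vip"], "sign": int(row["sign"]),
                        "n_factors": int(row["n_factors"]),
                    })
            except ValueError as exc:
                caught.append(f"cluster {c} PLSR skipped: {exc}")
            Rc, Pc = correlation_matrix(cluster_matrix)
            Rc.to_csv(out / f"correlation_cluster{c}.tsv", sep="\t")
            if len(members) >= 1:
                try:
                    amod = ancova(
                        cluster_matrix, design, cluster_id=c,
                        p_cutoff=config.divergence_p,
                    )
                    ancova_summ.append({
                        "cluster": c, "r2": amod.r2,
                        "r2_adjusted": amod.r2_adjusted,
                        "rmse_f": amod.rmse_f, "p": amod.p_whole_model,
                        "n": amod.n, "k": amod.k,
                    })
                    for _, row in amod.divergence.iterrows():
                        div_rows.append({"cluster": c, **row.to_dict()})
                except (ValueError, np.linalg.LinAlgError) as exc:
                    caught.append(f"cluster {c} ANCOVA skipped: {exc}")
        pd.DataFrame(vip_rows).to_csv(out / "vip_table.tsv", sep="\t", index=False)
        pd.DataFrame(
            div_rows,
            columns=["cluster", "variable", "factor", "beta_weight", "p", "divergent"],
        ).to_csv(out / "ancova_divergence.tsv", sep="\t", index=False)
        stages["profiling"] = {
            "pc1_percent": float(pca_res.proportions[0]),
            "pc2_percent": float(pca_res.proportions[1]),
            "n_divergent_flags": int(sum(bool(r["divergent"]) for r in div_rows)),
            "ancova_mean_r2_adjusted": _fmt_float(
                np.mean([s["r2_adjusted"] for s in ancova_summ])
                if ancova_summ else np.nan
            ),
        }

        # -- per-variable response-surface models ------------------------
        folds = None
        if config.folds_path:
            fold_table = pd.read_csv(config.folds_path, sep="\t",
                                     dtype={"run_id": str})
            folds = dict(zip(fold_table["run_id"], fold_table["fold"].astype(int)))
        models = fit_all(selected, design)
        cv_results = {}
        for m in models:
            y = selected.data.loc[m.response_id]
            y.index = selected.run_ids
            try:
                cv_results[m.response_id] = kfold_cv(
                    y, design, m.terms, k=config.cv_folds,
                    seed=config.seed_cv, folds=folds, response_id=m.response_id,
                )
            except ValueError as exc:
                caught.append(f"CV skipped for {m.response_id}: {exc}")
        models_doc = {
            m.response_id: {
                **m.to_dict(),
                "cv": (
                    {
                        "per_fold_rmse_cv": cv_results[m.response_id].per_fold_rmse_cv,
                        "pooled_rmse_cv": cv_results[m.response_id].pooled_rmse_cv,
                        "per_fold_train_r2": cv_results[m.response_id].per_fold_train_r2,
                    }
                    if m.response_id in cv_results else None
                ),
            }
            for m in models
        }
        (out / "models.json").write_text(json.dumps(models_doc, indent=1, sort_keys=True))
        beta = effect_significance_table(models, design)
        beta.to_csv(out / "beta_table.tsv", sep="\t")
        stages["modeling"] = {
            "n_models": len(models),
            "mean_r2_adjusted": float(np.mean([m.r2_adjusted for m in models])),
            "mean_rmse_f_over_scale": float(np.mean([
                m.rmse_f / m.response_average_scale
                for m in models if m.response_average_scale > 0
            ])),
            "mean_pooled_rmse_cv": _fmt_float(
                np.mean([c.pooled_rmse_cv for c in cv_results.values()])
                if cv_results else np.nan
            ),
        }

        caught.extend(str(w.message) for w in wrec)

    report = RunReport(
        version=__version__,
        config=asdict(config),
        stages=stages,
        warnings=caught,
    )
    (out / "run_report.json").write_text(report.to_json())
    return report


def make_demo(outdir, seed: int = 0, n_spots: int = 135, n_assays: int = 19):
    """Write a ready-to-run demo data set over the packaged design.

    Generates a truth model with 8 co-regulated clusters for
    ``n_spots + n_assays`` variables (mirroring the 135 identified protein
    spots and 19 physiological assays of the built-in experiment), simulates
    the abundance matrix, and writes design, matrix, truth sidecar and a
    pipeline configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = builtin_design()
    truth = make_truth(
        n_vars=n_spots + n_assays, n_clusters=8,
        effect_size_range=(0.5, 2.0), noise_sd=0.25, missing_rate=0.0,
        seed=seed, design=design, n_assays=n_assays,
    )
    matrix = simulate(design, truth, seed=seed + 1)
    # missingness mirrors the real data sets: spots complete, a handful of
    # assay cells absent, concentrated in a few runs (incl. a center point)
    assays = [v.var_id for v in truth.variables if v.var_class == "assay"]
    if len(assays) >= 5:
        rng = np.random.default_rng(seed + 2)
        center = "42" if "42" in design.run_ids else design.run_ids[-1]
        others = [r for r in design.run_ids if r != center]
        extra = list(rng.choice(others, size=2, replace=False))
        hit = list(rng.choice(assays, size=5, replace=False))
        masked_cells = (
            [(hit[0], center), (hit[1], center), (hit[2], center)]
            + [(hit[3], center), (hit[3], extra[0])]
            + [(hit[4], center), (hit[4], extra[0]), (hit[4], extra[1])]
        )
        for var, run in masked_cells:
            matrix.data.loc[var, run] = np.nan
    write_design(design, outdir / "design.tsv")
    write_matrix(matrix, outdir / "matrix.tsv")
    (outdir / "truth.json").write_text(truth.to_json())
    config = PipelineConfig(
        design_path=str(outdir / "design.tsv"),
        matrix_path=str(outdir / "matrix.tsv"),
        out_dir=str(outdir / "results"),
        seed_cv=seed, seed_randomization=seed,
    )
    (outdir / "config.json").write_text(json.dumps(asdict(config), indent=1))
    return config, truth, matrix
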