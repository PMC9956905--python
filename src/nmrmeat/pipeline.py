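"""End-to-end orchestration: simulate → preprocess → model → screen → ORA.

``run_pipeline`` executes the whole analysis for one seed and returns a
JSON-serializable summary; ``run_study`` is the library-level core that
returns the intermediate objects as well (used by the CLI, the test suite
and the acceptance script).  Identical config + seed reproduces identical
summaries.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemometrics as chem
from . import screening as screen_mod
from .config import DEFAULT_CONFIG, config_hash, scheme_from_config
from .ora import bundled_library, load_library, overrepresent
from .panel import INCREASING_METABOLITES, default_panel, default_signal_table
from .preprocess import assemble_bucket_table, univariate_scale
from .qnmr import default_standard, quantify_spectra
from .simdesign import AcquisitionSettings, generate_design, simulate_dataset
from .spectra import normalize_to_standard

__all__ = ["run_study", "run_pipeline", "StudyArtifacts"]

log = logging.getLogger("nmrmeat")


class StudyArtifacts(dict):
    """Dict of every intermediate object produced by one pipeline run."""


def _stage(name: str, t0: float, **info) -> float:
    dt = time.perf_counter() - t0
    log.info("stage=%s elapsed=%.2fs %s", name, dt, " ".join(f"{k}={v}" for k, v in info.items()))
    return time.perf_counter()


def run_study(config: dict | None = None, seed: int | None = None) -> StudyArtifacts:
    """Run the full analysis; returns intermediates plus a 'summary' entry."""
    cfg = config if config is not None else DEFAULT_CONFIG
    gen = cfg["generator"]
    seed = int(seed if seed is not None else gen["seed"])
    mdl = cfg["models"]
    alpha = cfg["screening"]["alpha"]

    t0 = time.perf_counter()
    design = generate_design(
        n_heifers=gen["n_heifers"],
        n_cows=gen["n_cows"],
        days=list(gen["days"]),
        n_runs=gen["n_runs"],
        seed=seed,
        n_replicates=gen.get("n_replicates", 1),
    )
    panel = default_panel(
        cattle_effect_scale=gen["cattle_effect_scale"],
        agingtype_effect_scale=gen["agingtype_effect_scale"],
        animal_re_scale=gen["animal_re_scale"],
        run_re_scale=gen["run_re_scale"],
        max_day=design.max_day,
    )
    acq = AcquisitionSettings(
        n_points=gen["n_points"],
        linewidth=gen["linewidth"],
        noise_sd=gen["noise_sd"],
        sample_mass_mg=gen["sample_mass_mg"],
        extract_fraction=gen["extract_fraction"],
    )
    design, conc_true, spectra = simulate_dataset(design, panel, acq, seed=seed)
    t0 = _stage("simulate", t0, samples=design.n_samples, metabolites=len(panel))

    std_region = tuple(cfg["preprocess"]["standard_region"])
    target = cfg["preprocess"]["standard_target_integral"]
    spectra = [normalize_to_standard(s, std_region, target) for s in spectra]
    scheme_time = scheme_from_config(cfg, "aging_time")
    scheme_type = scheme_from_config(cfg, "aging_type")
    bt_time = assemble_bucket_table(spectra, scheme_time)
    bt_type = assemble_bucket_table(spectra, scheme_type)
    t0 = _stage("preprocess", t0, buckets_time=bt_time.values.shape[1],
                buckets_type=bt_type.values.shape[1])

    meta = design.samples
    day = meta["aging_day"].to_numpy(dtype=float)
    X_time = bt_time.matrix
    cv_seed = int(mdl["seed"]) + seed

    # PCA on the autoscaled aging-time table
    scaled_time = univariate_scale(bt_time)
    pca_model = chem.pca(scaled_time.matrix, n_components=int(mdl["pca_components"]))

    # PLS-R aging day, component count by CV Q²
    n_comp, pls_metrics = chem.select_pls_components(
        X_time, day, max_components=int(mdl["pls_max_components"]),
        k=int(mdl["pls_folds"]), seed=cv_seed,
    )
    pls_model, _ = chem.pls_fit(X_time, day, n_comp)
    vip_scores = chem.vip(pls_model)
    t0 = _stage("pls", t0, components=n_comp, q2=round(pls_metrics.q2, 4))

    # OPLS-DA cow vs heifer: day-0 subset and all samples
    cattle = meta["cattle_type"].to_numpy()
    mask_d0 = day == 0
    _, opls_d0 = chem.oplsda_fit_cv(
        X_time[mask_d0], cattle[mask_d0], n_orthogonal=int(mdl["oplsda_orthogonal"]),
        k=int(mdl["oplsda_folds"]), seed=cv_seed,
    )
    _, opls_all = chem.oplsda_fit_cv(
        X_time, cattle, n_orthogonal=int(mdl["oplsda_orthogonal"]),
        k=int(mdl["oplsda_folds"]), seed=cv_seed,
    )
    t0 = _stage("oplsda", t0, acc_day0=round(opls_d0.accuracy, 4),
                acc_all=round(opls_all.accuracy, 4))

    # PCA-LDA dry vs wet on late aging days
    lda_days = set(int(d) for d in mdl["lda_days"])
    mask_late = meta["aging_day"].astype(int).isin(lda_days).to_numpy()
    lda_metrics, _ = chem.pca_lda_fit_cv(
        bt_type.matrix[mask_late], meta["aging_type"].to_numpy()[mask_late],
        variance_kept=float(mdl["lda_variance_kept"]), k=int(mdl["lda_folds"]),
        seed=cv_seed,
    )
    t0 = _stage("pca_lda", t0, accuracy=round(lda_metrics.accuracy, 4))

    # qNMR quantification and screening
    signals = default_signal_table(panel)
    conc_q = quantify_spectra(
        spectra, signals, default_standard(), gen["sample_mass_mg"], gen["extract_fraction"]
    )
    conc_table = meta.merge(conc_q, left_on="sample_id", right_index=True)
    t0 = _stage("quantify", t0, metabolites=conc_q.shape[1])

    names = [m.name for m in panel]
    results, summary_df = screen_mod.screen_table(
        conc_table, names, model=cfg["screening"]["model"], alpha=alpha
    )
    sig_day = summary_df.loc[summary_df["sig_day"], "metabolite"].tolist()
    sig_cattle = summary_df.loc[summary_df["sig_cattle"], "metabolite"].tolist()
    sig_aging = summary_df.loc[summary_df["sig_aging"], "metabolite"].tolist()
    t0 = _stage("screen", t0, day=len(sig_day), cattle=len(sig_cattle), aging=len(sig_aging))

    lib_path = cfg["ora"]["library"]
    library = load_library(lib_path) if lib_path else bundled_library()
    ora_df = overrepresent(sig_cattle, library) if sig_cattle else None
    t0 = _stage("ora", t0, query=len(sig_cattle))

    spearman_incr = {
        m: float(summary_df.set_index("metabolite").loc[m, "spearman_r"])
        for m in INCREASING_METABOLITES
    }

    summary = {
        "seed": seed,
        "config_hash": config_hash(cfg),
        "n_samples": int(design.n_samples),
        "pls": {**pls_metrics.as_dict()},
        "oplsda_day0": {**opls_d0.as_dict()},
        "oplsda_all": {**opls_all.as_dict()},
        "pca_lda": {**lda_metrics.as_dict()},
        "pca_explained_variance": [float(v) for v in pca_model.explained_variance],
        "significant": {
            "aging_time": sorted(sig_day),
            "cattle_type": sorted(sig_cattle),
            "aging_type": sorted(sig_aging),
            "n_aging_time": len(sig_day),
            "n_cattle_type": len(sig_cattle),
            "n_aging_type": len(sig_aging),
        },
        "spearman_increasing": spearman_incr,
        "ora_top": ora_df.head(5)["pathway"].tolist() if ora_df is not None else [],
    }

    return StudyArtifacts(
        config=cfg,
        design=design,
        panel=panel,
        concentrations_true=conc_true,
        spectra=spectra,
        bucket_table_time=bt_time,
        bucket_table_type=bt_type,
        pca=pca_model,
        pls_model=pls_model,
        pls_metrics=pls_metrics,
        vip=vip_scores,
        oplsda_day0=opls_d0,
        oplsda_all=opls_all,
        pca_lda=lda_metrics,
        concentrations_quantified=conc_table,
        screen_results=results,
        screen_summary=summary_df,
        ora=ora_df,
        summary=summary,
    )


def run_pipeline(config: dict | None = None, seed: int | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Run the pipeline and (optionally) write all artifacts; returns the summary."""
    art = run_study(config, seed)
    summary = art["summary"]
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        art["design"].samples.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        art["concentrations_true"].to_csv(outdir / "concentrations_true.tsv", sep="\t", index=False)
        art["concentrations_quantified"].to_csv(
            outdir / "concentrations_quantified.tsv", sep="\t", index=False
        )
        art["bucket_table_time"].to_tsv(outdir / "buckets_aging_time.tsv")
        art["bucket_table_type"].to_tsv(outdir / "buckets_aging_type.tsv")
        art["screen_summary"].to_csv(outdir / "screening.tsv", sep="\t", index=False)
        if art["ora"] is not None:
            art["ora"].to_csv(outdir / "ora.tsv", sep="\t", index=False)
        vip_df = pd.DataFrame(
            {"bucket": art["bucket_table_time"].values.columns, "vip": art["vip"]}
        )
        vip_df.to_csv(outdir / "vip.tsv", sep="\t", index=False)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
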