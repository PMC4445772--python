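"""End-to-end orchestration: reconstruct -> preprocess -> fit -> QC ->
quantify -> tissue merge -> cohort statistics.

The per-voxel outputs are written as one long-format CSV row per voxel per
metabolite (subject, voxel_x, voxel_y, metabolite, area, fwhm_hz,
ppm_offset, iu_level, qc_stage, tissue fractions and contrast), plus a
per-subject attrition JSON.  Every downstream table and report is
regenerable from the long CSV alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import container
from .params import PipelineConfig
from .phantom import MRSIAcquisition
from .preprocess import preprocess_fid
from .presets import METABOLITES, get_relaxation
from .qc import run_cascade, subject_inclusion
from .quantify import ratios, to_institutional_units
from .recon import reconstruct
from .spectral_fit import default_priors, fit_voxel
from .stats import correlate, fit_tissue_model
from .tissue import TissueFractions, tissue_contrast, tissue_difference

log = logging.getLogger("bgmrsi")

LEVEL_RESPONSES = {"NAA": "naa_iu", "Cho": "cho_iu", "Cre": "cre_iu"}
RATIO_RESPONSES = ("naa_cre", "cho_cre", "naa_cho",
                   "area_naa_cre", "area_cho_cre", "area_naa_cho")


def process_subject(
    acq: MRSIAcquisition,
    fractions: TissueFractions,
    config: PipelineConfig | None = None,
    subject_id: str = "sub",
):
    """Run the voxel-level pipeline for one subject.

    Voxels already failing the tissue stages (background/CSF) are not
    fitted; the cascade charges them to their stage from the fractions
    alone.
    """
    config = config or PipelineConfig()
    params = acq.params
    if config.psf_weighted_fractions:
        from .tissue import psf_weight_fractions

        fractions = psf_weight_fractions(fractions, params)
    grid = reconstruct(acq, apodise=True)
    priors = default_priors()
    relax = get_relaxation(config.relaxation_preset)
    qc_thr = config.qc

    fits, spectra = {}, {}
    for ix, iy in grid.voxels(interior_only=True):
        brain_pct = 100.0 - fractions.f_bgnd[ix, iy]
        if brain_pct < qc_thr.brain_min_pct:
            continue
        if fractions.f_csf[ix, iy] > qc_thr.csf_max_pct:
            continue
        fid, _ref = preprocess_fid(
            grid.fids[ix, iy], params,
            hlsvd_rank=config.hlsvd_rank,
            water_window_hz=config.water_window_hz,
            water_lowpass_hz=config.water_lowpass_hz,
        )
        fits[(ix, iy)] = fit_voxel(
            fid, priors, params,
            downweight_first_points=config.downweight_first_points,
        )
        spectra[(ix, iy)] = fid

    records, attrition = run_cascade(
        fits, fractions, grid.press_mask, grid.edge_mask,
        config=config, spectra=spectra, params=params,
    )

    x = tissue_contrast(fractions)
    dx = tissue_difference(fractions)
    rows = []
    for rec in records:
        ix, iy = rec.voxel
        fit = fits.get(rec.voxel)
        levels, areas = {}, {}
        if fit is not None:
            for m in METABOLITES:
                pk = fit.peaks[m]
                areas[m] = pk.amplitude
                levels[m] = to_institutional_units(
                    pk.amplitude, m, relax, params, scale=config.iu_scale
                )
        rat = ratios(levels, areas) if fit is not None else {}
        # refer levels to the parenchyma (GM+WM) volume: the CSF/background
        # share of a voxel carries no metabolite signal, and the tissue
        # regressor x is normalised the same way, so the pure-tissue
        # extrapolation is insensitive to CSF partial volume
        paren = (fractions.f_gm[ix, iy] + fractions.f_wm[ix, iy]) / 100.0
        for m in METABOLITES:
            pk = fit.peaks[m] if fit is not None else None
            rows.append({
                "subject": subject_id,
                "voxel_x": ix,
                "voxel_y": iy,
                "metabolite": m,
                "area": areas.get(m, np.nan),
                "fwhm_hz": pk.fwhm_hz if pk else np.nan,
                "ppm_offset": pk.offset_ppm if pk else np.nan,
                "iu_level": levels.get(m, np.nan),
                "iu_level_pv": (levels[m] / paren
                                if m in levels and paren > 0 else np.nan),
                "qc_stage": rec.stage_failed,
                "f_gm": fractions.f_gm[ix, iy],
                "f_wm": fractions.f_wm[ix, iy],
                "f_csf": fractions.f_csf[ix, iy],
                "f_bgnd": fractions.f_bgnd[ix, iy],
                "x": x[ix, iy],
                "wm_minus_gm_pct": dx[ix, iy],
                **{k: (v if v is not None else np.nan) for k, v in rat.items()},
            })
        if rec.stage_failed != "none":
            log.info("%s voxel (%d,%d) rejected at stage %s",
                     subject_id, ix, iy, rec.stage_failed)
    return pd.DataFrame(rows), records, attrition


def process_cohort(in_dir, out_dir, config: PipelineConfig | None = None) -> Path:
    """Process every subject container found in ``in_dir``."""
    config = config or PipelineConfig()
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    if not in_dir.is_dir():
        raise FileNotFoundError(f"input directory {in_dir} does not exist")
    subject_ids = container.cohort_subject_ids(in_dir)
    if not subject_ids:
        raise FileNotFoundError(f"no subject containers (*.h5) in {in_dir}")
    out_dir.mkdir(parents=True, exist_ok=True)

    tables, attritions = [], {}
    for sid in subject_ids:
        acq = container.load_subject(in_dir / f"{sid}.h5")
        maps = container.load_tissue_maps(in_dir, sid)
        from .tissue import voxel_fractions

        fr = voxel_fractions(maps["gm"], maps["wm"], maps["csf"], acq.params)
        df, _records, att = process_subject(acq, fr, config, subject_id=sid)
        tables.append(df)
        attritions[sid] = att.to_dict()
        log.info("%s: %d/%d voxels valid", sid, att.n_valid_all, att.n_total)

    long_df = pd.concat(tables, ignore_index=True)
    long_df.to_csv(out_dir / "voxels_long.csv", index=False, float_format="%.8g")
    with open(out_dir / "attrition.json", "w") as fh:
        totals = {
            "n_total": sum(a["n_total"] for a in attritions.values()),
            "n_valid_naa": sum(a["n_valid_naa"] for a in attritions.values()),
            "n_valid_all": sum(a["n_valid_all"] for a in attritions.values()),
            "counts": {
                s: sum(a["counts"][s] for a in attritions.values())
                for s in ("BGND", "CSF", "NAA", "Vis", "ChoCre")
            },
        }
        json.dump({"subjects": attritions, "cohort": totals}, fh, indent=2)
    cov_src = in_dir / "covariates.csv"
    if cov_src.exists():
        (out_dir / "covariates.csv").write_text(cov_src.read_text())
    return out_dir


def _valid_wide(long_df: pd.DataFrame) -> pd.DataFrame:
    """Pivot the all-valid voxels to one row per voxel."""
    ok = long_df[long_df["qc_stage"] == "none"]
    keys = ["subject", "voxel_x", "voxel_y"]
    base = ok[keys + ["x", "wm_minus_gm_pct", "f_gm", "f_wm", "f_csf",
                      "naa_cre", "cho_cre", "naa_cho",
                      "area_naa_cre", "area_cho_cre", "area_naa_cho"]
              ].drop_duplicates(keys)
    lv = ok.pivot_table(index=keys, columns="metabolite",
                        values="iu_level_pv").reset_index()
    lv = lv.rename(columns={m: f"{m.lower()}_iu" for m in METABOLITES})
    raw = ok.pivot_table(index=keys, columns="metabolite",
                         values="iu_level").reset_index()
    raw = raw.rename(columns={m: f"{m.lower()}_iu_raw" for m in METABOLITES})
    return base.merge(lv, on=keys).merge(raw, on=keys)


def run_stats(proc_dir, out_dir, config: PipelineConfig | None = None) -> dict:
    """Cohort statistics from the processed long table.

    Applies the minimum-valid-voxel subject inclusion rule, fits the
    mixed model for each level and ratio response, and computes
    subject-level correlations with the covariates when present.
    """
    config = config or PipelineConfig()
    proc_dir, out_dir = Path(proc_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    long_df = pd.read_csv(proc_dir / "voxels_long.csv")
    with open(proc_dir / "attrition.json") as fh:
        attrition = json.load(fh)

    wide = _valid_wide(long_df)
    n_valid = wide.groupby("subject").size()
    included = [s for s, n in n_valid.items()
                if subject_inclusion(int(n), config.qc.min_voxels_per_subject)]
    excluded = {s: int(n) for s, n in n_valid.items() if s not in included}
    wide = wide[wide["subject"].isin(included)]

    results = {}
    for met, col in LEVEL_RESPONSES.items():
        fit = fit_tissue_model(wide, col, method=config.stats_method)
        results[col] = fit.to_dict()
    for col in RATIO_RESPONSES:
        fit = fit_tissue_model(wide, col, method=config.stats_method)
        results[col] = fit.to_dict()

    # subject summaries + correlations
    summaries = wide.groupby("subject")[
        ["naa_iu", "cho_iu", "cre_iu", "naa_cre", "cho_cre", "naa_cho"]
    ].mean()
    summaries["n_valid"] = n_valid
    naa_rows = long_df[
        (long_df["metabolite"] == "NAA")
        & (long_df["qc_stage"].isin(["none", "ChoCre"]))
    ].rename(columns={"fwhm_hz": "naa_fwhm_hz"})
    summaries["mean_naa_fwhm_hz"] = naa_rows.groupby("subject")["naa_fwhm_hz"].mean()
    pct = {
        s: 100.0 * a["n_valid_all"] / a["n_total"]
        for s, a in attrition["subjects"].items() if a["n_total"]
    }
    summaries["percent_valid"] = pd.Series(pct)
    summaries = summaries.loc[summaries.index.isin(included)].reset_index()

    cov_path = proc_dir / "covariates.csv"
    correlations = []
    pairs = [("cho_iu", "cre_iu"), ("cre_iu", "naa_iu"),
             ("percent_valid", "mean_naa_fwhm_hz")]
    if cov_path.exists():
        cov = pd.read_csv(cov_path).rename(columns={"subject_id": "subject"})
        summaries = summaries.merge(cov, on="subject", how="left")
        pairs += [("cre_iu", "fluid_g"), ("naa_iu", "memory_g"),
                  ("cho_iu", "wml_score"), ("naa_iu", "atrophy_score"),
                  ("cre_iu", "iron_score")]
    for a, b in pairs:
        if a in summaries and b in summaries and summaries[[a, b]].dropna().shape[0] >= 3:
            c = correlate(summaries, a, b)
            correlations.append({
                "var_a": a, "var_b": b, "r": c.r, "p": c.p, "n": c.n,
                "defined": c.defined,
            })

    report = {
        "results": results,
        "included_subjects": included,
        "excluded_subjects": excluded,
        "correlations": correlations,
        "attrition": attrition["cohort"],
        "stats_method": config.stats_method,
    }
    with open(out_dir / "cohort_stats.json", "w") as fh:
        json.dump(report, fh, indent=2)
    summaries.to_csv(out_dir / "subject_summaries.csv", index=False)
    (out_dir / "table1.txt").write_text(format_table(results))
    return report


def format_table(results: dict) -> str:
    """Human-readable pure-tissue table (WM, GM, p columns)."""
    lines = [f"{'response':>14} {'WM':>8} {'GM':>8} {'p (GM vs WM)':>12}"]

    def row(name, key):
        r = results[key]
        lines.append(
            f"{name:>14} {r['wm_estimate']:8.2f} {r['gm_estimate']:8.2f} "
            f"{r['p_tissue']:12.3g}"
        )

    lines.append("Metabolites (IU)")
    for met, key in LEVEL_RESPONSES.items():
        row(met, key)
    lines.append("Metabolite ratios (IU)")
    for key in ("naa_cho", "naa_cre", "cho_cre"):
        row(key, key)
    lines.append("Spectral peak area ratios")
    for key in ("area_naa_cho", "area_naa_cre", "area_cho_cre"):
        row(key, key)
    return "\n".join(lines) + "\n"


def run_full_study(work_dir, seed: int, n_subjects: int = 10,
                   config: PipelineConfig | None = None,
                   **phantom_kwargs) -> dict:
    """Simulate, process and analyse a cohort in one call.

    Convenience wrapper running the three pipeline stages under
    ``work_dir`` and returning the cohort-statistics report.
    """
    config = config or PipelineConfig()
    config.seed = seed
    config.n_subjects = n_subjects
    work_dir = Path(work_dir)
    simulate_cohort(work_dir / "cohort", config, **phantom_kwargs)
    process_cohort(work_dir / "cohort", work_dir / "proc", config)
    return run_stats(work_dir / "proc", work_dir / "stats", config)


def simulate_cohort(out_dir, config: PipelineConfig | None = None,
                    **phantom_kwargs) -> Path:
    """Generate and write the default synthetic cohort."""
    from .phantom import make_default_phantom

    config = config or PipelineConfig()
    specs = make_default_phantom(
        seed=config.seed,
        n_subjects=config.n_subjects,
        params=config.acquisition,
        concentration_preset=config.concentration_preset,
        relaxation_preset=config.relaxation_preset,
        **phantom_kwargs,
    )
    return container.write_cohort(specs, config.acquisition, out_dir,
                                  seed=config.seed)
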