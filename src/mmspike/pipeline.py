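"""End-to-end orchestration: ingest -> preprocess -> kinematics -> MMS ->
cohort cells -> bootstrap ensembles -> signatures -> comparisons.

``run_pipeline`` consumes a config (see :mod:`mmspike.config`) naming a cohort
table and motion-file directory and writes a deterministic results bundle:
excursion and spike CSVs, the ensemble signature table, the three
comparison-matrix sets (within-TD, within-ASD, TD-vs-ASD) for each selector,
effect-size tables, log-log Gamma-plane fits, and a run manifest.  Reruns
with the same config and master seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

import mmspike
from mmspike.bootstrap import Ensemble, child_seed, ensemble_signatures
from mmspike.cohort import assign_cells
from mmspike.compare import (
    cohen_d,
    effect_size_report,
    glass_delta,
    kruskal_wallis_matrix,
    ks_matrix,
    star,
)
from mmspike.config import bins_from_config, default_config
from mmspike.errors import MMSpikeError, ValidationError
from mmspike.kinematics import angular_speed, head_excursion, linear_speed
from mmspike.mms import extract_mms
from mmspike.motion_io import read_cohort_table, read_motion_file
from mmspike.preprocess import resample_uniform, truncate_common
from mmspike.signatures import loglog_plane_fit

__all__ = ["run_pipeline", "summarize_run"]

logger = logging.getLogger(__name__)

KINDS = ("linear", "angular")

BUNDLE_FILES = (
    "manifest.json",
    "cells.csv",
    "excursions.csv",
    "spikes_linear.csv",
    "spikes_angular.csv",
    "signatures.csv",
    "effect_sizes.csv",
    "loglog_fits.csv",
)


def _config_hash(cfg: dict) -> str:
    # Hash the analysis parameters only; input file locations are incidental
    # to the run's identity and would break reproducibility comparisons.
    params = {k: v for k, v in cfg.items() if k != "io"}
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()


def _write_matrix(mat, path_stem: Path) -> None:
    mat.values.to_csv(path_stem.with_suffix(".csv"))
    path_stem.with_suffix(".txt").write_text(mat.render_text())


def run_pipeline(cfg: dict, out_dir: str | Path, seed: int | None = None) -> Path:
    """Run the full analysis and write the results bundle under ``out_dir``.

    ``seed`` overrides ``cfg["bootstrap"]["seed"]`` as the master seed from
    which every cell's resampling stream is derived.  Returns the bundle path.
    """
    from mmspike.config import merge_config

    cfg = merge_config(default_config(), cfg or {})
    io_cfg = cfg["io"]
    if not io_cfg.get("cohort_table") or not io_cfg.get("motion_dir"):
        raise ValidationError("config must name io.cohort_table and io.motion_dir")
    cohort_path = Path(io_cfg["cohort_table"])
    motion_dir = Path(io_cfg["motion_dir"])
    if not cohort_path.exists():
        raise ValidationError(f"cohort table not found: {cohort_path}")
    if not motion_dir.is_dir():
        raise ValidationError(f"motion directory not found: {motion_dir}")
    master_seed = int(seed if seed is not None else cfg["bootstrap"]["seed"])

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mat_dir = out_dir / "matrices"
    mat_dir.mkdir(exist_ok=True)

    records = read_cohort_table(cohort_path)
    records.sort(key=lambda r: r.subject_id)

    # ingest + kinematics
    speeds: dict[str, dict[str, np.ndarray]] = {k: {} for k in KINDS}
    dts: dict[str, float] = {}
    for rec in records:
        trace = read_motion_file(
            motion_dir / f"{rec.subject_id}.1D",
            dt=rec.dt,
            subject_id=rec.subject_id,
            column_order=io_cfg.get("column_order", "rot_first"),
        )
        lin = linear_speed(trace, combine=cfg["speed"]["combine"])
        ang = angular_speed(
            trace, combine=cfg["speed"]["combine"], unit=cfg["speed"]["angular_unit"]
        )
        per_site = cfg["resample"].get("per_site") or {}
        pq = per_site.get(rec.site, {"p": cfg["resample"]["p"], "q": cfg["resample"]["q"]})
        speeds["linear"][rec.subject_id] = resample_uniform(lin.values, pq["p"], pq["q"])
        speeds["angular"][rec.subject_id] = resample_uniform(ang.values, pq["p"], pq["q"])
        dts[rec.subject_id] = rec.dt * pq["q"] / pq["p"]

    # common length per kind
    for kind in KINDS:
        speeds[kind] = truncate_common(speeds[kind], cfg["truncate"]["length"])

    # excursions on the standardized series
    from mmspike.kinematics import SpeedSeries

    excursion_rows = []
    speed_series: dict[str, dict[str, SpeedSeries]] = {k: {} for k in KINDS}
    for rec in records:
        sid = rec.subject_id
        for kind in KINDS:
            speed_series[kind][sid] = SpeedSeries(sid, kind, dts[sid], speeds[kind][sid])
        excursion_rows.append(
            {
                "subject_id": sid,
                "linear_pathlength_mm": head_excursion(speed_series["linear"][sid]),
                "angular_pathlength_deg": head_excursion(speed_series["angular"][sid]),
            }
        )
    excursions = pd.DataFrame(excursion_rows)
    excursions.to_csv(out_dir / "excursions.csv", index=False)

    # micro-movement spikes
    trains = {k: {} for k in KINDS}
    for kind in KINDS:
        spike_rows = []
        for rec in records:
            train = extract_mms(
                speed_series[kind][rec.subject_id],
                source=cfg["mms"]["source"],
                window=cfg["mms"]["window"],
            )
            trains[kind][rec.subject_id] = train
            for idx, amp in zip(train.peak_indices, train.amplitudes):
                spike_rows.append(
                    {
                        "subject_id": rec.subject_id,
                        "kind": kind,
                        "peak_index": int(idx),
                        "amplitude": amp,
                    }
                )
        pd.DataFrame(
            spike_rows, columns=["subject_id", "kind", "peak_index", "amplitude"]
        ).to_csv(out_dir / f"spikes_{kind}.csv", index=False)

    # cohort cells
    bins = bins_from_config(cfg)
    cells = assign_cells(records, bins)
    cell_rows = [
        {"age_bin": bin_label, "diagnosis": diag, "n_subjects": len(members)}
        for (bin_label, diag), members in sorted(cells.items())
    ]
    pd.DataFrame(cell_rows).to_csv(out_dir / "cells.csv", index=False)

    # bootstrap ensembles + signature table
    bcfg = cfg["bootstrap"]
    ensembles: dict[tuple[str, str, str], Ensemble] = {}
    sig_rows = []
    for (bin_label, diag), members in sorted(cells.items()):
        for kind in KINDS:
            cell_key = (bin_label, diag, kind)
            cell_trains = {r.subject_id: trains[kind][r.subject_id] for r in members}
            try:
                ens = ensemble_signatures(
                    cell_trains,
                    cell=cell_key,
                    k=bcfg["k"],
                    m=bcfg["m"],
                    replacement=bcfg["replacement"],
                    seed=child_seed(master_seed, bin_label, diag, kind),
                )
            except MMSpikeError as exc:
                logger.error("cell %s failed: %s; continuing", cell_key, exc)
                continue
            ensembles[cell_key] = ens
            for i, sig in enumerate(ens.members):
                sig_rows.append(
                    {
                        "age_bin": bin_label,
                        "diagnosis": diag,
                        "kind": kind,
                        "member": i,
                        "shape": sig.shape,
                        "scale": sig.scale,
                        "ci_shape_lo": sig.ci_shape[0],
                        "ci_shape_hi": sig.ci_shape[1],
                        "ci_scale_lo": sig.ci_scale[0],
                        "ci_scale_hi": sig.ci_scale[1],
                        "mean": sig.mean,
                        "sd": sig.sd,
                        "skewness": sig.skewness,
                        "kurtosis": sig.kurtosis,
                        "nsr": sig.nsr,
                        "best_family": sig.best_family,
                        "n_obs": sig.n_obs,
                        "loglik_gamma": sig.loglik_by_family["gamma"],
                        "loglik_exponential": sig.loglik_by_family["exponential"],
                        "loglik_lognormal": sig.loglik_by_family["lognormal"],
                        "loglik_gaussian": sig.loglik_by_family["gaussian"],
                    }
                )
    pd.DataFrame(sig_rows).to_csv(out_dir / "signatures.csv", index=False)

    # comparison matrices: within-TD, within-ASD, TD-vs-ASD (rows ASD, cols TD)
    ccfg = cfg["compare"]
    bin_labels = [b.label for b in bins]
    for kind in KINDS:
        per_diag = {}
        for diag in ("TD", "ASD"):
            per_diag[diag] = {
                lbl: ensembles[(lbl, diag, kind)]
                for lbl in bin_labels
                if (lbl, diag, kind) in ensembles
            }
        for selector in ccfg["selectors"]:
            sets = {
                "td": (
                    {l: e.values(selector) for l, e in per_diag["TD"].items()},
                    None,
                ),
                "asd": (
                    {l: e.values(selector) for l, e in per_diag["ASD"].items()},
                    None,
                ),
                "cross": (
                    {l: e.values(selector) for l, e in per_diag["ASD"].items()},
                    {l: e.values(selector) for l, e in per_diag["TD"].items()},
                ),
            }
            for set_name, (groups, columns) in sets.items():
                if len(groups) < (1 if columns else 2) or (columns is not None and not columns):
                    continue
                kw = kruskal_wallis_matrix(
                    groups,
                    columns=columns,
                    statistic_name=f"Kruskal-Wallis p | {kind} {selector} | {set_name}",
                    alpha1=ccfg["alpha1"],
                    alpha2=ccfg["alpha2"],
                )
                _write_matrix(kw, mat_dir / f"kw_{kind}_{selector}_{set_name}")
                if selector == "nsr":
                    ks = ks_matrix(
                        groups,
                        columns=columns,
                        statistic_name=f"Kolmogorov-Smirnov p | {kind} {selector} | {set_name}",
                        alpha1=ccfg["alpha1"],
                        alpha2=ccfg["alpha2"],
                    )
                    _write_matrix(ks, mat_dir / f"ks_{kind}_{selector}_{set_name}")

    # effect sizes on excursions: ASD vs TD per age bin, TD as control
    exc_by_subject = excursions.set_index("subject_id")
    param_cols = {
        "linear_excursion": "linear_pathlength_mm",
        "angular_excursion": "angular_pathlength_deg",
    }
    effect_rows = []
    for bin_label in bin_labels:
        asd = cells.get((bin_label, "ASD"), [])
        td = cells.get((bin_label, "TD"), [])
        if len(asd) < 2 or len(td) < 2:
            continue
        for param, col in param_cols.items():
            rep = effect_size_report(
                cell=bin_label,
                parameter=param,
                treatment=exc_by_subject.loc[[r.subject_id for r in asd], col].to_numpy(),
                control=exc_by_subject.loc[[r.subject_id for r in td], col].to_numpy(),
                ttest_variant=ccfg["ttest"],
            )
            effect_rows.append(
                {
                    "age_bin": bin_label,
                    "parameter": param,
                    "cohen_d": rep.cohen_d,
                    "cohen_label": rep.cohen_label,
                    "glass_delta": rep.glass_delta,
                    "glass_label": rep.glass_label,
                    "ttest_p": rep.p_value,
                    "stars": star(rep.p_value, ccfg["alpha1"], ccfg["alpha2"]),
                }
            )
    pd.DataFrame(effect_rows).to_csv(out_dir / "effect_sizes.csv", index=False)

    # age-effect pairwise effect-size matrices per diagnosis and parameter
    for diag in ("TD", "ASD"):
        for param, col in param_cols.items():
            groups = {
                lbl: exc_by_subject.loc[
                    [r.subject_id for r in cells[(lbl, diag)]], col
                ].to_numpy()
                for lbl in bin_labels
                if (lbl, diag) in cells and len(cells[(lbl, diag)]) >= 2
            }
            if len(groups) < 2:
                continue
            labels = list(groups)
            dmat = pd.DataFrame(0.0, index=labels, columns=labels)
            gmat = pd.DataFrame(0.0, index=labels, columns=labels)
            for i in labels:
                for j in labels:
                    if i != j:
                        dmat.loc[i, j] = cohen_d(groups[i], groups[j])
                        gmat.loc[i, j] = glass_delta(groups[i], groups[j])
            dmat.to_csv(mat_dir / f"age_effect_cohen_{param}_{diag.lower()}.csv")
            gmat.to_csv(mat_dir / f"age_effect_glass_{param}_{diag.lower()}.csv")

    # log-log Gamma-plane power-law fits per diagnosis and kind
    loglog_rows = []
    for kind in KINDS:
        for diag in ("TD", "ASD"):
            sigs = [
                m
                for (lbl, d, kd), ens in sorted(ensembles.items())
                if d == diag and kd == kind
                for m in ens.members
            ]
            if len(sigs) < 3:
                continue
            fit = loglog_plane_fit(sigs)
            loglog_rows.append(
                {
                    "kind": kind,
                    "diagnosis": diag,
                    "slope": fit["slope"],
                    "intercept": fit["intercept"],
                    "ci_slope_lo": fit["ci_slope"][0],
                    "ci_slope_hi": fit["ci_slope"][1],
                    "ci_intercept_lo": fit["ci_intercept"][0],
                    "ci_intercept_hi": fit["ci_intercept"][1],
                    "residual_norm": fit["residual_norm"],
                    "n": fit["n"],
                }
            )
    pd.DataFrame(loglog_rows).to_csv(out_dir / "loglog_fits.csv", index=False)

    manifest = {
        "config_sha256": _config_hash(cfg),
        "seed": master_seed,
        "n_subjects": len(records),
        "n_cells": len(cells),
        "versions": {
            "mmspike": mmspike.__version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out_dir


def summarize_run(bundle_dir: str | Path) -> str:
    """Render a results bundle as a human-readable markdown report."""
    bundle_dir = Path(bundle_dir)
    missing = [f for f in BUNDLE_FILES if not (bundle_dir / f).exists()]
    if missing:
        raise ValidationError(f"incomplete bundle, missing: {missing}")
    manifest = json.loads((bundle_dir / "manifest.json").read_text())
    cells = pd.read_csv(bundle_dir / "cells.csv")
    sigs = pd.read_csv(bundle_dir / "signatures.csv")
    effects = pd.read_csv(bundle_dir / "effect_sizes.csv")

    lines = ["# Head-motion stochastic-signature run report", ""]
    lines.append(f"Master seed: {manifest['seed']}; config {manifest['config_sha256'][:12]}...")
    lines.append(f"{manifest['n_subjects']} subjects in {manifest['n_cells']} cells.")
    lines.append("")
    lines.append("## Cell counts")
    for row in cells.itertuples(index=False):
        lines.append(f"- {row.age_bin} {row.diagnosis}: {row.n_subjects} subjects")
    lines.append("")
    lines.append("## Best-family tally over ensemble signatures")
    tally = sigs.groupby(["kind", "best_family"]).size()
    for (kind, family), count in tally.items():
        lines.append(f"- {kind}: {family} x {count}")
    lines.append("")
    lines.append("## Ensemble-mean NSR per cell")
    nsr = sigs.groupby(["kind", "age_bin", "diagnosis"])["nsr"].mean()
    for (kind, bin_label, diag), value in nsr.items():
        lines.append(f"- {kind} {bin_label} {diag}: {value:.4f}")
    lines.append("")
    lines.append("## Effect sizes (ASD vs TD, TD control)")
    for row in effects.itertuples(index=False):
        lines.append(
            f"- {row.age_bin} {row.parameter}: Cohen d = {row.cohen_d:.2f} "
            f"({row.cohen_label}), Glass Delta = {row.glass_delta:.2f} "
            f"({row.glass_label}), t-test p = {row.ttest_p:.2e}{row.stars}"
        )
    lines.append("")
    mat_dir = bundle_dir / "matrices"
    if mat_dir.is_dir():
        lines.append("## Comparison matrices")
        for txt in sorted(mat_dir.glob("*.txt")):
            lines.append("```")
            lines.append(txt.read_text().rstrip())
            lines.append("```")
    return "\n".join(lines) + "\n"
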