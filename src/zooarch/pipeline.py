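"""End-to-end orchestration: curation → chronology → diversity → ordination → prey choice.

The pipeline is a thin composition of the analysis modules with file
I/O around them. Every stage writes its own CSV/JSON artifacts; a
single machine-readable ``summary.json`` collects the headline numbers
(totals, per-site group-level Simpson D, ordination eigenvalues,
prey-choice statistics, slice tests). Floats are serialized at fixed
precision so re-running an identical configuration reproduces
byte-identical summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assemblage as asm
from . import chronology as chrono
from . import diversity as div
from . import feri
from . import prey_choice as pcm

__all__ = ["PipelineConfig", "StageError", "run_full_pipeline"]

_ROUND = 6


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage '{stage}' failed: {exc}")
        self.stage = stage
        self.cause = exc


@dataclass
class PipelineConfig:
    """Input paths, thresholds, and knobs for one pipeline run."""

    assemblage_csv: str
    outdir: str
    c14_csv: str | None = None
    curve_path: str | None = None
    trait_map_path: str | None = None
    nutrition_csv: str | None = None
    min_nisp: int = 30
    curate: bool = True
    feri_min_fish_nisp: int = 15
    abundance_threshold: float = 0.025
    k: int = 4
    seed: int = 0
    detrend_segments: int = 26

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(open(path)) or {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else round(f, _ROUND)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage available for the configured inputs.

    Stages without inputs (e.g. no nutrition table) are skipped and
    recorded in the summary; a stage that *has* inputs but fails raises
    :class:`StageError` naming the stage, with earlier artifacts preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"schema_version": 1, "config": _jsonable(asdict(config)), "stages": {}}

    # -- curation --------------------------------------------------------
    try:
        table = asm.read_assemblage_table(config.assemblage_csv)
        if config.curate:
            table = asm.curate_sites(table, config.min_nisp)
        table = asm.apply_fish_mni_convention(table)
        asm.write_assemblage_table(table, outdir / "curated_assemblage.csv", log_path=outdir / "curation_log.json")
        summary["stages"]["curation"] = {
            "n_sites": len(table.sites),
            "total_nisp": table.total("NISP"),
            "total_mni": table.total("MNI"),
        }
    except Exception as exc:  # noqa: BLE001 - stage boundary
        _dump(summary, outdir)
        raise StageError("curation", exc) from exc

    # -- chronology ------------------------------------------------------
    grouping = None
    site_slices: dict[str, str] = {}
    if config.c14_csv and config.curve_path:
        try:
            curve = chrono.read_calibration_curve(config.curve_path)
            dates = chrono.read_radiocarbon_dates(config.c14_csv)
            per_site: dict[str, list] = {}
            rows = []
            for d in dates:
                dens = chrono.calibrate_date(d, curve)
                per_site.setdefault(d.site_id, []).append(dens)
                rows.append({"lab_id": d.lab_id, "site_id": d.site_id, "median_bp": dens.median_cal})
            medians = {s: chrono.site_median(v) for s, v in per_site.items() if s in table.sites}
            if medians:
                k = min(config.k, len(medians))
                grouping = chrono.kmeans_1d(medians, k=k, seed=config.seed)
                site_slices = {
                    s: chrono.assign_time_slice(chrono.bp_to_bce(m)) for s, m in medians.items()
                }
            pd.DataFrame(rows).to_csv(outdir / "date_medians.csv", index=False)
            out = {
                s: {
                    "median_bp": medians[s],
                    "median_bce": chrono.bp_to_bce(medians[s]),
                    "group": grouping.labels[s] if grouping else None,
                    "slice": site_slices.get(s),
                }
                for s in medians
            }
            (outdir / "site_chronology.json").write_text(json.dumps(_jsonable(out), indent=2, sort_keys=True))
            summary["stages"]["chronology"] = {"n_sites_dated": len(medians), "k": grouping.k if grouping else 0}
        except Exception as exc:  # noqa: BLE001
            _dump(summary, outdir)
            raise StageError("chronology", exc) from exc
    else:
        summary["stages"]["chronology"] = "skipped: no 14C input configured"

    # -- diversity -------------------------------------------------------
    try:
        profile = div.diversity_profile(table, grouping, median_unit="BP")
        profile.to_csv(outdir / "diversity.csv", index=False)
        d_group = {
            r.site_id: r.D
            for r in profile[(profile["level"] == "group") & (profile["basis"] == "NISP")].itertuples()
        }
        div_summary: dict = {"d_group_nisp": d_group}
        for basis in ("NISP", "MNI"):
            try:
                fit = div.fit_family_class_regression(profile, basis)
                div_summary[f"regression_{basis.lower()}"] = {
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "outside_band": [s for s, o in zip(fit.sites, fit.outside) if o],
                }
            except ValueError as exc:
                div_summary[f"regression_{basis.lower()}"] = f"skipped: {exc}"
        slices_d = profile[(profile["level"] == "family") & (profile["basis"] == "NISP")]
        groups = {sl: sub["D"].to_numpy() for sl, sub in slices_d.groupby("slice") if sl not in ("unplaced", "outside")}
        tests = {}
        names = [s for s, _, _ in chrono.TIME_SLICES if s in groups]
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if len(groups[a]) >= 2 and len(groups[b]) >= 2:
                    t = div.welch_ttest(groups[a], groups[b])
                    tests[f"{a} vs {b}"] = {"t": t.statistic, "df": t.df, "p": t.p_value}
        div_summary["slice_tests_family_nisp"] = tests
        summary["stages"]["diversity"] = div_summary
    except Exception as exc:  # noqa: BLE001
        _dump(summary, outdir)
        raise StageError("diversity", exc) from exc

    # -- trait ordination ------------------------------------------------
    if config.trait_map_path:
        try:
            tm = feri.TraitMap.from_yaml(config.trait_map_path)
            results = {}
            for axis in ("salinity", "sediment", "combined"):
                try:
                    m = feri.build_trait_matrix(table, tm, axis, config.feri_min_fish_nisp)
                    ca = feri.correspondence_analysis(m)
                    dca = feri.detrend(ca, config.detrend_segments) if ca.row_scores.shape[1] >= 2 else ca
                    results[axis] = dca
                    dca.row_scores.to_csv(outdir / f"feri_{axis}_scores.csv")
                except ValueError as exc:
                    summary["stages"].setdefault("feri_skipped", {})[axis] = str(exc)
            report = feri.feri_report(results)
            (outdir / "feri.json").write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
            summary["stages"]["feri"] = {
                axis: {"eigenvalues": [round(float(e), _ROUND) for e in r.eigenvalues[:2]]}
                for axis, r in results.items()
            }
        except Exception as exc:  # noqa: BLE001
            _dump(summary, outdir)
            raise StageError("feri", exc) from exc
    else:
        summary["stages"]["feri"] = "skipped: no trait map configured"

    # -- prey choice + energetics ---------------------------------------
    if config.nutrition_csv:
        try:
            nutrition = pcm.read_nutrition_table(config.nutrition_csv)
            pcm_rows = []
            for site in table.sites:
                sub = table.for_site(site)
                if len(sub.records) < 3:
                    continue
                try:
                    rep = pcm.pcm_site_report(sub, nutrition)
                except ValueError:
                    continue
                pcm_rows.append(
                    {
                        "site_id": site,
                        "d_group": rep["d_group"],
                        "model_a_r": rep["model_a"].correlation,
                        "model_a_p": rep["model_a"].p_value,
                        "model_b_rho": rep["model_b"].correlation,
                        "model_b_p": rep["model_b"].p_value,
                        "n_taxa": rep["n_taxa"],
                        **{f"share_{k}": v for k, v in rep["habitat_shares"].items()},
                    }
                )
            pcm_df = pd.DataFrame(pcm_rows)
            pcm_df.to_csv(outdir / "pcm_results.csv", index=False)
            summary["stages"]["prey_choice"] = {
                r["site_id"]: {"model_b_rho": r["model_b_rho"], "model_b_p": r["model_b_p"]} for r in pcm_rows
            }
            if site_slices:
                energy = pcm.energy_by_slice(table, nutrition, site_slices, [s for s, _, _ in chrono.TIME_SLICES])
                summary["stages"]["energetics"] = {
                    "summaries": energy["summaries"],
                    "pairwise": {
                        k: (v if isinstance(v, str) else {"t": v.statistic, "df": v.df, "p": v.p_value})
                        for k, v in energy["pairwise_tests"].items()
                    },
                }
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            _dump(summary, outdir)
            raise StageError("prey_choice", exc) from exc
    else:
        summary["stages"]["prey_choice"] = "skipped: no nutrition table configured"

    _dump(summary, outdir)
    return summary


def _dump(summary: dict, outdir: Path) -> None:
    (outdir / "summary.json").write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True))
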