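"""Prey-choice models: profitability, abundance, and habitat structure.

Optimal-foraging theory predicts that, when prey are equally
encountered, foragers preferentially take the most profitable taxa. We
score profitability as the post-encounter return rate

    PERR = e / h × 60   [kcal per hour]

with e the caloric return of one individual (kcal) and h its handling
time (minutes); pursuit failure is deliberately excluded, so PERR is an
upper bound on realized returns. Two site-level models relate
profitability to archaeological abundance: model a correlates the
continuous PERR with %NISP (Pearson), model b correlates their ranks
(Spearman with average ties), which is robust to outliers and monotone
re-scaling of either variable. Domesticated taxa are ranked alongside
wild ones by default — husbandry breaks the encounter logic, which is
exactly the deviation the correlation is meant to expose — and a flag
restricts the analysis to wild taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assemblage import AssemblageTable
from .diversity import TestResult, simpson_index, welch_ttest

__all__ = [
    "HABITAT_CLASSES",
    "compute_perr",
    "classify_habitat",
    "build_prey_profiles",
    "PCMResult",
    "model_a",
    "model_b",
    "pcm_site_report",
    "energy_by_slice",
    "read_nutrition_table",
]

#: Biome label → broad habitat class.
HABITAT_CLASSES: dict[str, str] = {
    "Marine": "marine",
    "Mixed water": "marine",
    "Mixed saltwater": "marine",
    "Coastal": "coastal",
    "Freshwater": "coastal",
    "Wetland": "coastal",
    "Forest": "terrestrial",
    "Mixed Land": "terrestrial",
    "Land": "terrestrial",
}


def compute_perr(e, h):
    """Post-encounter return rate in kcal/hour: e / h × 60.

    Accepts scalars or arrays; every element of e and h must be positive.
    """
    e_arr = np.asarray(e, dtype=float)
    h_arr = np.asarray(h, dtype=float)
    if (e_arr <= 0).any() or (h_arr <= 0).any():
        raise ValueError("caloric return e and handling time h must be positive")
    out = e_arr * 60.0 / h_arr
    return float(out) if np.isscalar(e) or (e_arr.ndim == 0 and h_arr.ndim == 0) else out


def classify_habitat(biome: str) -> str:
    """Map a biome label to marine / coastal / terrestrial.

    Unknown labels return "unknown" with a warning — never silently
    dropped, so habitat shares still sum to one.
    """
    label = " ".join(str(biome).split())
    for known, cls in HABITAT_CLASSES.items():
        if known.casefold() == label.casefold():
            return cls
    warnings.warn(f"biome {biome!r} not in the controlled vocabulary; classed as 'unknown'")
    return "unknown"


def read_nutrition_table(path) -> pd.DataFrame:
    """Nutrition CSV: taxon, e_kcal, h_minutes and optional biome/source."""
    df = pd.read_csv(path)
    missing = [c for c in ("taxon", "e_kcal", "h_minutes") if c not in df.columns]
    if missing:
        raise ValueError(f"nutrition table missing column(s) {missing}")
    return df


def _norm(s: object) -> str:
    return " ".join(str(s).split()).casefold()


def build_prey_profiles(
    site_table: AssemblageTable,
    nutrition: pd.DataFrame,
    *,
    wild_only: bool = False,
    domesticates: set[str] | None = None,
) -> pd.DataFrame:
    """Per-taxon prey profiles for one site.

    Joins the site's counts with the nutrition table, computes PERR,
    %NISP, average-tie ranks of both, and the habitat class from the
    biome. Taxa without a nutrition entry are excluded (listed in the
    ``missing_nutrition`` DataFrame attr); if nothing is covered an error
    names every missing taxon.
    """
    rec = site_table.records[site_table.records["nisp"] > 0].copy()
    if wild_only:
        dom = {_norm(t) for t in (domesticates or set())}
        rec = rec[~rec["taxon"].map(_norm).isin(dom)]
    nut = nutrition.copy()
    nut["_key"] = nut["taxon"].map(_norm)
    rec["_key"] = rec["taxon"].map(_norm)
    merged = rec.merge(nut.drop(columns=["taxon"]), on="_key", how="left", suffixes=("", "_nut"))
    missing = merged[merged["e_kcal"].isna()]["taxon"].tolist()
    prof = merged.dropna(subset=["e_kcal", "h_minutes"]).copy()
    if prof.empty:
        raise ValueError(f"no nutrition coverage for site; missing taxa: {missing}")

    prof["e"] = prof["e_kcal"].astype(float)
    prof["h"] = prof["h_minutes"].astype(float)
    prof["perr"] = compute_perr(prof["e"].to_numpy(), prof["h"].to_numpy())
    prof["pct_nisp"] = prof["nisp"] / prof["nisp"].sum()
    prof["perr_rank"] = stats.rankdata(prof["perr"])
    prof["nisp_rank"] = stats.rankdata(prof["nisp"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # unknown biomes already logged at ingest
        prof["habitat_class"] = prof["biome"].map(classify_habitat)
    out = prof[
        ["taxon", "tax_group", "e", "h", "perr", "nisp", "pct_nisp", "perr_rank", "nisp_rank", "biome", "habitat_class"]
    ].reset_index(drop=True)
    out.attrs["missing_nutrition"] = missing
    return out


@dataclass
class PCMResult:
    """One prey-choice correlation at one site."""

    site_id: str
    model: str  # "a" | "b"
    correlation: float
    p_value: float
    n_taxa: int
    undefined: bool = False
    d_group: float | None = None
    profiles: pd.DataFrame | None = field(default=None, repr=False)


def model_a(profiles: pd.DataFrame, site_id: str = "") -> PCMResult:
    """Continuous model: Pearson correlation of PERR with %NISP."""
    if len(profiles) < 3:
        raise ValueError("model a needs ≥3 taxa")
    x = profiles["perr"].to_numpy(dtype=float)
    y = profiles["pct_nisp"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PCMResult(site_id, "a", float("nan"), float("nan"), len(profiles), undefined=True)
    r, p = stats.pearsonr(x, y)
    return PCMResult(site_id, "a", float(r), float(p), len(profiles))


def model_b(profiles: pd.DataFrame, site_id: str = "", method: str = "spearman") -> PCMResult:
    """Rank model: Spearman (default) or Kendall correlation of PERR and NISP ranks."""
    if len(profiles) < 3:
        raise ValueError("model b needs ≥3 taxa")
    x = profiles["perr"].to_numpy(dtype=float)
    y = profiles["nisp"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return PCMResult(site_id, "b", float("nan"), float("nan"), len(profiles), undefined=True)
    if method == "kendall":
        rho, p = stats.kendalltau(x, y)
    else:
        rho, p = stats.spearmanr(x, y)
    return PCMResult(site_id, "b", float(rho), float(p), len(profiles))


def habitat_shares(profiles: pd.DataFrame) -> dict[str, float]:
    """NISP share per habitat class; always sums to 1 (includes 'unknown')."""
    total = profiles["nisp"].sum()
    shares = {k: 0.0 for k in ("marine", "coastal", "terrestrial", "unknown")}
    for cls, sub in profiles.groupby("habitat_class"):
        shares[str(cls)] = float(sub["nisp"].sum() / total)
    return shares


def pcm_site_report(
    site_table: AssemblageTable,
    nutrition: pd.DataFrame,
    model: str = "both",
    **profile_kwargs,
) -> dict:
    """Full prey-choice workup for one site.

    Returns the per-taxon profile table, both correlation models (or one),
    the species-group Simpson D, and marine/coastal/terrestrial NISP shares.
    """
    sites = site_table.sites
    site_id = sites[0] if len(sites) == 1 else ",".join(sites)
    profiles = build_prey_profiles(site_table, nutrition, **profile_kwargs)
    group_counts = profiles.groupby("tax_group")["nisp"].sum()
    d_group = simpson_index(group_counts.to_numpy())
    report: dict = {
        "site_id": site_id,
        "n_taxa": len(profiles),
        "d_group": d_group,
        "habitat_shares": habitat_shares(profiles),
        "missing_nutrition": profiles.attrs.get("missing_nutrition", []),
        "profiles": profiles,
    }
    if model in ("a", "both"):
        res = model_a(profiles, site_id)
        res.d_group = d_group
        report["model_a"] = res
    if model in ("b", "both"):
        res = model_b(profiles, site_id)
        res.d_group = d_group
        report["model_b"] = res
    return report


def energy_by_slice(
    table: AssemblageTable,
    nutrition: pd.DataFrame,
    site_slices: dict[str, str],
    slice_order: list[str] | None = None,
) -> dict:
    """Diachronic energetics of the fish catch (MNI basis).

    Each fish taxon present at a site contributes its per-individual
    caloric value e once per individual; with the fish-MNI=1 convention
    this is the distribution of e over the fish taxa caught in each
    chronological slice. Adjacent slices are compared with Welch's
    t-test; slices with fewer than two fish taxa are flagged and skipped.
    """
    nut = nutrition.copy()
    nut["_key"] = nut["taxon"].map(_norm)
    fish = table.records[(table.records["tax_class"].map(_norm) == "fish") & (table.records["nisp"] > 0)].copy()
    fish["_key"] = fish["taxon"].map(_norm)
    fish = fish.merge(nut[["_key", "e_kcal"]], on="_key", how="left")
    fish = fish.dropna(subset=["e_kcal"])
    fish["slice"] = fish["site_id"].map(site_slices)
    fish = fish.dropna(subset=["slice"])
    fish["mni_eff"] = np.maximum(fish["mni"], 1)

    per_slice: dict[str, np.ndarray] = {}
    for sl, sub in fish.groupby("slice"):
        per_slice[str(sl)] = np.repeat(sub["e_kcal"].to_numpy(dtype=float), sub["mni_eff"].to_numpy(dtype=int))

    if slice_order is None:
        from .chronology import TIME_SLICES

        canonical = [name for name, _, _ in TIME_SLICES]
        slice_order = [s for s in canonical if s in per_slice] + sorted(
            s for s in per_slice if s not in canonical
        )
    order = [s for s in slice_order if s in per_slice]
    summaries = {
        sl: {"n": len(v), "mean_kcal": float(v.mean()), "sd_kcal": float(v.std(ddof=1)) if len(v) > 1 else float("nan")}
        for sl, v in per_slice.items()
    }
    pairwise: dict[str, TestResult | str] = {}
    for a, b in zip(order[:-1], order[1:]):
        key = f"{a} vs {b}"
        if len(per_slice[a]) < 2 or len(per_slice[b]) < 2:
            pairwise[key] = "skipped: <2 fish individuals in a slice"
            continue
        pairwise[key] = welch_ttest(per_slice[a], per_slice[b])
    return {"values": per_slice, "summaries": summaries, "pairwise_tests": pairwise, "order": order}
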