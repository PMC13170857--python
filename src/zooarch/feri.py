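"""Fish-ecology trait ordination for salinity and sediment reconstruction.

Fish taxa carry habitat-preference categories on two ecological axes —
salinity (marine, brackish, freshwater, …) and bottom sediment (rock,
mud, sand, vegetation, …). Translating each assemblage's fish taxa into
the categories they carry yields a binary site × category incidence
matrix; correspondence analysis (CA) of that matrix places assemblages
along latent environmental gradients, with an optional detrending step
that removes the arch artefact from higher axes. Because the category
vocabulary is an ecological convention rather than a measurement, the
taxon → category map is an external config with a shipped default, and
all results are relative to the supplied map.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .assemblage import AssemblageTable

__all__ = [
    "TraitMap",
    "BinaryTraitMatrix",
    "OrdinationResult",
    "build_trait_matrix",
    "correspondence_analysis",
    "detrend",
    "feri_report",
]

TRAIT_AXES = ("salinity", "sediment")


def _norm(s: object) -> str:
    return " ".join(str(s).split()).casefold()


@dataclass
class TraitMap:
    """taxon → habitat categories on the salinity and sediment axes."""

    salinity: dict[str, frozenset[str]] = field(default_factory=dict)
    sediment: dict[str, frozenset[str]] = field(default_factory=dict)

    def categories(self, taxon: str, axis: str) -> frozenset[str]:
        table = self._axis_table(axis)
        return table.get(_norm(taxon), frozenset())

    def covers(self, taxon: str, axis: str) -> bool:
        return _norm(taxon) in self._axis_table(axis)

    def _axis_table(self, axis: str) -> dict[str, frozenset[str]]:
        if axis not in TRAIT_AXES:
            raise ValueError(f"unknown trait axis {axis!r}; expected one of {TRAIT_AXES}")
        return getattr(self, axis)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TraitMap":
        """Load ``{taxon: {salinity: [...], sediment: [...]}}`` YAML."""
        data = yaml.safe_load(Path(path).read_text())
        tm = cls()
        for taxon, axes in (data or {}).items():
            for axis in TRAIT_AXES:
                cats = (axes or {}).get(axis)
                if cats:
                    tm._axis_table(axis)[_norm(taxon)] = frozenset(_norm(c) for c in cats)
        return tm

    @classmethod
    def from_csv(cls, path: str | Path) -> "TraitMap":
        """Load long-format CSV with columns taxon, axis, category."""
        tm = cls()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                axis = _norm(row["axis"])
                table = tm._axis_table(axis)
                key = _norm(row["taxon"])
                table[key] = table.get(key, frozenset()) | {_norm(row["category"])}
        return tm


@dataclass
class BinaryTraitMatrix:
    """Assemblage × category incidence matrix (0/1) on one trait axis."""

    values: pd.DataFrame  # index: site ids; columns: categories; ints in {0,1}
    axis: str
    excluded_taxa: list[str] = field(default_factory=list)
    pruned: dict = field(default_factory=dict)


def build_trait_matrix(
    table: AssemblageTable,
    traits: TraitMap,
    axis: str,
    min_fish_nisp: int = 15,
) -> BinaryTraitMatrix:
    """Binary site × category matrix from an assemblage's fish taxa.

    Only assemblages whose fish NISP reaches ``min_fish_nisp`` enter
    (i.e. fish NISP > 14 with the default — small fish assemblages are
    too sparse to carry an environmental signal). A cell is 1 iff any
    retained fish taxon at the site carries the category. Taxa without a
    trait entry are collected in ``excluded_taxa``; empty rows/columns
    are pruned and recorded.

    ``axis="combined"`` concatenates salinity and sediment columns
    (prefixed) into one matrix.
    """
    axes = TRAIT_AXES if axis == "combined" else (axis,)
    fish = table.records[table.records["tax_class"].map(_norm) == "fish"]
    if fish.empty:
        raise ValueError("assemblage table contains no fish records")
    fish_totals = fish.groupby("site_id", sort=False)["nisp"].sum()
    kept_sites = [s for s in fish_totals.index if fish_totals[s] >= min_fish_nisp]
    if not kept_sites:
        raise ValueError(
            f"no assemblage reaches fish NISP ≥ {min_fish_nisp}; "
            f"max observed {int(fish_totals.max())}"
        )

    excluded: set[str] = set()
    all_cats: dict[str, set[str]] = {ax: set() for ax in axes}
    cells: dict[tuple[str, str], int] = {}
    for site in kept_sites:
        sub = fish[(fish["site_id"] == site) & (fish["nisp"] > 0)]
        for taxon in sub["taxon"]:
            covered_any = False
            for ax in axes:
                cats = traits.categories(taxon, ax)
                if cats:
                    covered_any = True
                for c in cats:
                    col = f"{ax}:{c}" if axis == "combined" else c
                    all_cats[ax].add(col)
                    cells[(site, col)] = 1
            if not covered_any:
                excluded.add(taxon)

    columns = sorted(set().union(*all_cats.values()))
    mat = pd.DataFrame(0, index=kept_sites, columns=columns, dtype=int)
    for (site, col), v in cells.items():
        mat.loc[site, col] = v

    pruned_rows = [s for s in mat.index if mat.loc[s].sum() == 0]
    pruned_cols = [c for c in mat.columns if mat[c].sum() == 0]
    mat = mat.drop(index=pruned_rows, columns=pruned_cols)
    mat.index.name = "site_id"
    return BinaryTraitMatrix(
        values=mat,
        axis=axis,
        excluded_taxa=sorted(excluded),
        pruned={"rows": pruned_rows, "cols": pruned_cols},
    )


@dataclass
class OrdinationResult:
    """CA/DCA output: eigenvalues plus row and column scores."""

    eigenvalues: np.ndarray  # descending
    row_scores: pd.DataFrame  # principal coordinates, axes CA1, CA2, …
    col_scores: pd.DataFrame
    method: str  # "CA" | "DCA"
    total_inertia: float
    segments: int | None = None


def correspondence_analysis(m: BinaryTraitMatrix | pd.DataFrame) -> OrdinationResult:
    """Correspondence analysis of an incidence (or count) matrix.

    The correspondence matrix P = N/n is centred by its rank-one margin
    expectation and standardized by the chi-square metric,
    S = D_r^{-1/2} (P − r cᵀ) D_c^{-1/2}; singular values of S squared are
    the eigenvalues (inertia per axis), and row/column principal
    coordinates are the margin-weighted singular vectors scaled by the
    singular values. Signs are fixed by making the first nonzero row
    score on each axis positive.
    """
    df = m.values if isinstance(m, BinaryTraitMatrix) else m
    N = df.to_numpy(dtype=float)
    if N.shape[0] < 2 or N.shape[1] < 2:
        raise ValueError("correspondence analysis needs ≥2 rows and ≥2 columns")
    n = N.sum()
    if n <= 0:
        raise ValueError("matrix grand total must be positive")
    if (N.sum(axis=1) == 0).any() or (N.sum(axis=0) == 0).any():
        raise ValueError("all-zero rows/columns must be pruned before ordination")

    P = N / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)

    max_axes = min(N.shape) - 1
    keep = np.flatnonzero(sv > 1e-10)[:max_axes]
    sv = sv[keep]
    U = U[:, keep]
    V = Vt[keep].T

    # principal coordinates
    F = (U * sv) / np.sqrt(r)[:, None]
    G = (V * sv) / np.sqrt(c)[:, None]
    # deterministic sign: first row score with |.| > tol positive per axis
    for a in range(F.shape[1]):
        col = F[:, a]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            F[:, a] *= -1
            G[:, a] *= -1

    axes = [f"CA{i + 1}" for i in range(F.shape[1])]
    return OrdinationResult(
        eigenvalues=sv**2,
        row_scores=pd.DataFrame(F, index=df.index, columns=axes),
        col_scores=pd.DataFrame(G, index=df.columns, columns=axes),
        method="CA",
        total_inertia=float((S**2).sum()),
    )


def detrend(ca: OrdinationResult, segments: int = 26) -> OrdinationResult:
    """Detrend higher CA axes by segment-wise centering along axis 1.

    Axis-1 scores are split into ``segments`` equal-width windows; within
    each window the mean of every higher axis is subtracted, removing the
    quadratic "arch" dependence of axis 2 on axis 1 that CA produces on
    single-gradient data. The axis-1 scores and eigenvalue are taken over
    from the CA solution unchanged; no nonlinear axis rescaling is applied.
    """
    if segments < 2:
        raise ValueError("segments must be ≥ 2")
    if ca.row_scores.shape[1] < 2:
        raise ValueError("detrending needs at least 2 ordination axes")
    scores = ca.row_scores.to_numpy().copy()
    ax1 = scores[:, 0]
    lo, hi = ax1.min(), ax1.max()
    width = (hi - lo) or 1.0
    bins = np.minimum(((ax1 - lo) / width * segments).astype(int), segments - 1)
    for a in range(1, scores.shape[1]):
        for b in np.unique(bins):
            sel = bins == b
            scores[sel, a] -= scores[sel, a].mean()
    return OrdinationResult(
        eigenvalues=ca.eigenvalues.copy(),
        row_scores=pd.DataFrame(scores, index=ca.row_scores.index, columns=ca.row_scores.columns),
        col_scores=ca.col_scores.copy(),
        method="DCA",
        total_inertia=ca.total_inertia,
        segments=segments,
    )


def feri_report(
    results: Mapping[str, OrdinationResult],
    context: Mapping[str, str] | None = None,
) -> dict:
    """Serialize ordinations (eigenvalues, site scores) to plain dicts.

    ``context`` optionally annotates each site (e.g. settlement vs fjord)
    so score clusters can be read against depositional setting.
    """
    out: dict = {"axes": {}}
    for axis, res in results.items():
        sites = {}
        for site, row in res.row_scores.iterrows():
            entry = {k: round(float(v), 6) for k, v in row.items()}
            if context and site in context:
                entry["context"] = context[site]
            sites[str(site)] = entry
        out["axes"][axis] = {
            "method": res.method,
            "eigenvalues": [round(float(e), 6) for e in res.eigenvalues],
            "total_inertia": round(res.total_inertia, 6),
            "site_scores": sites,
        }
    return out
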