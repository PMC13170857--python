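"""Faunal assemblage data model, I/O, curation and aggregation.

The universal input is a long-format table of taxon counts per site:
one record per (site, taxon) with the number of identified specimens
(NISP), the minimum number of individuals (MNI), taxonomic annotations
at three levels (class, family, species group), and a habitat ("biome")
label from a controlled vocabulary. Everything downstream — chronology
joins, diversity indices, trait ordination, prey-choice models —
consumes the outputs of this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BIOME_VOCABULARY",
    "COLUMNS",
    "AssemblageTable",
    "CountMatrix",
    "ProportionVector",
    "SchemaError",
    "ValidationError",
    "read_assemblage_table",
    "write_assemblage_table",
    "table_from_records",
    "apply_fish_mni_convention",
    "curate_sites",
    "aggregate_counts",
    "proportions",
    "abundance_filter",
]

#: Controlled habitat vocabulary; anything else is normalized to "unknown".
BIOME_VOCABULARY = frozenset(
    {
        "Marine",
        "Mixed water",
        "Mixed saltwater",
        "Coastal",
        "Freshwater",
        "Wetland",
        "Forest",
        "Mixed Land",
        "Land",
    }
)

COLUMNS = [
    "site_id",
    "site_name",
    "taxon",
    "tax_class",
    "tax_family",
    "tax_group",
    "nisp",
    "mni",
    "biome",
]

_LEVEL_COLUMN = {"group": "tax_group", "family": "tax_family", "class": "tax_class"}
_BASES = ("NISP", "MNI")

#: Taxon labels treated as unidentifiable material when the schema flag
#: ``drop_unidentified`` is set (case-folded comparison).
UNIDENTIFIED_LABELS = frozenset({"unidentified", "indet", "indet.", "indeterminate"})


class SchemaError(ValueError):
    """An input file does not expose a required column."""


class ValidationError(ValueError):
    """A record violates a count or vocabulary invariant."""


def _norm_text(value: object) -> str:
    s = "" if value is None or (isinstance(value, float) and np.isnan(value)) else str(value)
    return " ".join(s.split())


def _norm_key(value: object) -> str:
    return _norm_text(value).casefold()


@dataclass
class AssemblageTable:
    """Long-format faunal count table plus its curation history.

    ``records`` is a DataFrame with :data:`COLUMNS`; (site_id, taxon) pairs
    are unique after name normalization. ``curation_log`` accumulates one
    entry per transformation so that no row is ever silently dropped.
    """

    records: pd.DataFrame
    provenance: str = "<memory>"
    curation_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = self.records.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def sites(self) -> list[str]:
        return list(dict.fromkeys(self.records["site_id"]))

    def total(self, basis: str = "NISP") -> int:
        return int(self.records[_basis_column(basis)].sum())

    def site_totals(self, basis: str = "NISP") -> pd.Series:
        col = _basis_column(basis)
        return self.records.groupby("site_id", sort=False)[col].sum()

    def for_site(self, site_id: str) -> "AssemblageTable":
        sub = self.records[self.records["site_id"] == site_id]
        return AssemblageTable(sub.copy(), self.provenance, list(self.curation_log))

    def log(self, action: str, **details) -> None:
        self.curation_log.append({"action": action, **details})

    def copy(self) -> "AssemblageTable":
        return AssemblageTable(self.records.copy(), self.provenance, list(self.curation_log))

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CountMatrix:
    """Site × taxon-label count matrix at one taxonomic level and basis."""

    values: pd.DataFrame  # index: site ids, columns: labels
    level: str
    basis: str

    def row(self, site_id: str) -> pd.Series:
        return self.values.loc[site_id]

    @property
    def grand_total(self) -> int:
        return int(self.values.to_numpy().sum())


@dataclass
class ProportionVector:
    """Relative abundances of one assemblage: p_i = count_i / total."""

    labels: list[str]
    p: np.ndarray
    S: int  # number of nonzero categories


def _basis_column(basis: str) -> str:
    b = basis.upper()
    if b not in _BASES:
        raise ValueError(f"unknown basis {basis!r}; expected one of {_BASES}")
    return b.lower()


def _level_column(level: str) -> str:
    try:
        return _LEVEL_COLUMN[level.lower()]
    except KeyError:
        raise ValueError(
            f"unknown level {level!r}; expected one of {tuple(_LEVEL_COLUMN)}"
        ) from None


def _validate_and_normalize(df: pd.DataFrame, *, source: str) -> tuple[pd.DataFrame, list[dict]]:
    """Coerce counts to int, normalize text, merge duplicate (site, taxon) rows."""
    log: list[dict] = []
    df = df.copy()
    for col in ("site_id", "site_name", "taxon", "tax_class", "tax_family", "tax_group"):
        df[col] = df[col].map(_norm_text)
    for col in ("nisp", "mni"):
        raw = pd.to_numeric(df[col], errors="coerce")
        bad = raw.index[raw.isna()].tolist()
        if bad:
            raise ValidationError(f"{source}: non-numeric {col} at rows {bad}")
        neg = raw.index[raw < 0].tolist()
        if neg:
            raise ValidationError(f"{source}: negative {col} at rows {neg}")
        df[col] = raw.round().astype(int)

    biome = df["biome"].map(_norm_text)
    known = {b.casefold(): b for b in BIOME_VOCABULARY}
    fixed = biome.map(lambda s: known.get(s.casefold(), "unknown"))
    n_unknown = int(((fixed == "unknown") & (biome.str.casefold() != "unknown")).sum())
    if n_unknown > 0:
        log.append({"action": "biome_normalized_to_unknown", "n": n_unknown})
    df["biome"] = fixed

    # mni <= nisp whenever both positive: repair impossible MNIs, log them
    both = (df["nisp"] > 0) & (df["mni"] > 0) & (df["mni"] > df["nisp"])
    if both.any():
        log.append({"action": "mni_capped_at_nisp", "rows": df.index[both].tolist()})
        df.loc[both, "mni"] = df.loc[both, "nisp"]

    # merge duplicates under case-folded taxon keys, summing counts
    key = df["site_id"].map(_norm_key) + "\x00" + df["taxon"].map(_norm_key)
    if key.duplicated().any():
        n_dup = int(key.duplicated().sum())
        agg = {c: "first" for c in COLUMNS}
        agg["nisp"] = "sum"
        agg["mni"] = "sum"
        df = df.groupby(key, sort=False).agg(agg).reset_index(drop=True)
        log.append({"action": "merged_duplicate_records", "n": n_dup})
    return df.reset_index(drop=True)[COLUMNS], log


def table_from_records(records: Iterable[Mapping] | pd.DataFrame, provenance: str = "<memory>") -> AssemblageTable:
    """Build a validated table from dict records or a DataFrame."""
    df = pd.DataFrame(records)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df, log = _validate_and_normalize(df[COLUMNS], source=provenance)
    table = AssemblageTable(df, provenance)
    table.curation_log.extend(log)
    return table


def read_assemblage_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    drop_unidentified: bool = True,
) -> AssemblageTable:
    """Read a long-format assemblage CSV.

    Parameters
    ----------
    path:
        CSV with a header row; UTF-8, comma separated.
    schema:
        Optional mapping ``{canonical column -> file column}`` for files whose
        headers differ from :data:`COLUMNS`.
    drop_unidentified:
        Exclude rows whose taxon is an unidentifiable-material label
        (recorded in the curation log, never silently).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    schema = dict(schema or {})
    rename = {schema.get(c, c): c for c in COLUMNS}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    df = raw.rename(columns=rename)[COLUMNS]

    dropped = pd.Series(False, index=df.index)
    if drop_unidentified:
        dropped = df["taxon"].map(_norm_key).isin(UNIDENTIFIED_LABELS)
    df, log = _validate_and_normalize(df[~dropped], source=path.name)
    table = AssemblageTable(df, provenance=str(path))
    if int(dropped.sum()):
        table.log("dropped_unidentified", n=int(dropped.sum()))
    table.curation_log.extend(log)
    return table


def write_assemblage_table(table: AssemblageTable, path: str | Path, *, log_path: str | Path | None = None) -> None:
    """Write the records as CSV and, optionally, the curation log as JSON."""
    table.records.to_csv(path, index=False)
    if log_path is not None:
        Path(log_path).write_text(json.dumps(table.curation_log, indent=2, default=str))


# -- curation operations ------------------------------------------------


def apply_fish_mni_convention(table: AssemblageTable) -> AssemblageTable:
    """Force MNI = 1 for every fish record with NISP > 0.

    Fish skeletons are massively redundant (dozens of near-identical
    vertebrae per individual), so element-based MNI estimates are
    unreliable; the convention collapses every represented fish taxon to a
    single individual per site. Non-fish records are untouched and the
    operation is idempotent.
    """
    out = table.copy()
    mask = (out.records["tax_class"].map(_norm_key) == "fish") & (out.records["nisp"] > 0)
    changed = int((out.records.loc[mask, "mni"] != 1).sum())
    out.records.loc[mask, "mni"] = 1
    out.log("fish_mni_convention", records_changed=changed)
    return out


def curate_sites(table: AssemblageTable, min_nisp: int = 30) -> AssemblageTable:
    """Drop sites whose total NISP falls strictly below ``min_nisp``.

    Small assemblages give unstable proportions and diversity values. The
    threshold is inclusive: a site totalling exactly ``min_nisp`` is kept.
    Removals are recorded in the curation log; removing every site yields an
    empty table with a warning entry rather than an exception.
    """
    out = table.copy()
    totals = out.site_totals("NISP")
    removed = totals.index[totals < min_nisp].tolist()
    out.records = out.records[~out.records["site_id"].isin(removed)].reset_index(drop=True)
    out.log("curate_sites", min_nisp=min_nisp, removed_sites=removed)
    if len(out.records) == 0 and len(table.records) > 0:
        out.log("warning", message="all sites removed by NISP curation")
    return out


def aggregate_counts(table: AssemblageTable, level: str, basis: str = "NISP") -> CountMatrix:
    """Sum counts into a site × label matrix at a taxonomic level.

    ``level`` ∈ {group, family, class}; ``basis`` ∈ {NISP, MNI}. Marginal
    sums are conserved: row sums equal site totals on that basis.
    """
    lcol = _level_column(level)
    bcol = _basis_column(basis)
    pivot = table.records.pivot_table(
        index="site_id", columns=lcol, values=bcol, aggfunc="sum", fill_value=0, sort=False
    ).astype(int)
    pivot.columns.name = None
    pivot.index.name = "site_id"
    return CountMatrix(pivot, level=level.lower(), basis=basis.upper())


def proportions(counts: pd.Series | Sequence[float]) -> ProportionVector:
    """Convert one assemblage's counts to relative abundances."""
    if isinstance(counts, pd.Series):
        labels = [str(c) for c in counts.index]
        values = counts.to_numpy(dtype=float)
    else:
        values = np.asarray(counts, dtype=float)
        labels = [str(i) for i in range(len(values))]
    if (values < 0).any():
        raise ValidationError("negative counts")
    total = values.sum()
    if total <= 0:
        raise ValidationError("cannot form proportions of an all-zero count vector")
    p = values / total
    return ProportionVector(labels=labels, p=p, S=int((p > 0).sum()))


def abundance_filter(matrix: CountMatrix, threshold: float = 0.025) -> CountMatrix:
    """Pool rare columns into "other".

    A column is retained when its share of the grand total is ≥ ``threshold``
    (inclusive); everything below is summed into a trailing "other" column,
    so totals are conserved. Used for display-level composition plots where
    a long tail of singleton taxa would drown the signal.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    values = matrix.values
    total = values.to_numpy().sum()
    if total == 0 or threshold == 0:
        return CountMatrix(values.copy(), matrix.level, matrix.basis)
    share = values.sum(axis=0) / total
    keep = share.index[share >= threshold]
    pool = share.index.difference(keep)
    out = values[list(keep)].copy()
    if len(pool) and "other" not in out.columns:
        out["other"] = values[list(pool)].sum(axis=1)
    elif len(pool):
        out["other"] = out["other"] + values[list(pool)].sum(axis=1)
    return CountMatrix(out, matrix.level, matrix.basis)
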