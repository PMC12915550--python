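"""Reading, validation and writing of GWAS/QTL summary-statistics tables.

The canonical in-memory container is :class:`TraitTable`, a thin wrapper
around a :class:`pandas.DataFrame` with one row per variant and a fixed
column schema.  Individual rows materialise as :class:`VariantAssoc`
records.  All positions are 1-based inclusive; the genome build is carried
as free text in run manifests and never used computationally.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariantAssoc",
    "TraitTable",
    "GeneLocus",
    "SumstatsError",
    "ConfigError",
    "EmptyTableError",
    "read_sumstats",
    "read_multi_sumstats",
    "read_locus_table",
    "write_results",
    "CANONICAL_COLUMNS",
    "IDENTITY_COLUMN_MAP",
]

VALID_BASES = frozenset("ACGT")

#: Canonical column order of a TraitTable frame.
CANONICAL_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

#: Column map for files already written in the canonical schema.
IDENTITY_COLUMN_MAP = {c: c for c in CANONICAL_COLUMNS}

MANDATORY_FIELDS = ("variant_id", "effect_allele", "other_allele", "beta", "se")


class SumstatsError(Exception):
    """Base error for summary-statistics I/O."""


class ConfigError(SumstatsError):
    """A column mapping or configuration value is missing or invalid."""


class EmptyTableError(SumstatsError):
    """No valid rows survived validation."""


@dataclass(frozen=True)
class VariantAssoc:
    """One variant's association record for one trait.

    ``beta`` is the per-effect-allele estimate: log-odds for a binary
    trait, SD units for a quantitative trait.  ``eaf`` and ``n`` may be
    missing (``None``).
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: identical alleles")
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.variant_id}: eaf outside (0,1)")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"{self.variant_id}: pval outside (0,1]")

    @property
    def zscore(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class GeneLocus:
    """Gene/protein-coding region (1-based, inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")

    def cis_window(self, window_bp: int) -> tuple[int, int]:
        """Closed interval [start - window, end + window], floored at 1."""
        return max(1, self.start - window_bp), self.end + window_bp


class TraitTable:
    """Per-trait collection of variant association records.

    Variant keys are unique by construction; duplicate keys must be
    resolved before instantiation (``read_sumstats`` keeps the lowest-p
    row, ties broken by first occurrence).
    """

    def __init__(
        self,
        trait_id: str,
        trait_type: str,
        platform_or_tissue: str,
        df: pd.DataFrame,
        tally: Mapping[str, int] | None = None,
    ):
        if trait_type not in ("protein", "transcript", "outcome"):
            raise ValueError(f"unknown trait_type {trait_type!r}")
        if df["variant_id"].duplicated().any():
            raise ValueError("duplicate variant keys in TraitTable")
        self.trait_id = trait_id
        self.trait_type = trait_type
        self.platform_or_tissue = platform_or_tissue
        self.df = df.reset_index(drop=True)[list(CANONICAL_COLUMNS)]
        self.tally: dict[str, int] = dict(tally or {})
        self._index = pd.Index(self.df["variant_id"])

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def variant_ids(self) -> list[str]:
        return list(self.df["variant_id"])

    def get(self, variant_id: str) -> VariantAssoc:
        loc = self._index.get_loc(variant_id)
        return self._row_to_record(self.df.iloc[loc])

    def records(self) -> Iterable[VariantAssoc]:
        for _, row in self.df.iterrows():
            yield self._row_to_record(row)

    @staticmethod
    def _row_to_record(row: pd.Series) -> VariantAssoc:
        eaf = row["eaf"]
        n = row["n"]
        return VariantAssoc(
            variant_id=str(row["variant_id"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            effect_allele=str(row["effect_allele"]),
            other_allele=str(row["other_allele"]),
            beta=float(row["beta"]),
            se=float(row["se"]),
            pval=float(row["pval"]),
            eaf=None if pd.isna(eaf) else float(eaf),
            n=None if pd.isna(n) else int(n),
        )

    @classmethod
    def from_records(
        cls,
        trait_id: str,
        trait_type: str,
        platform_or_tissue: str,
        records: Iterable[VariantAssoc],
    ) -> "TraitTable":
        rows = [dataclasses.asdict(r) for r in records]
        df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
        if df.empty:
            df = _empty_frame()
        return cls(trait_id, trait_type, platform_or_tissue, df)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in CANONICAL_COLUMNS})


def _validate_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Row-wise validation; every dropped row maps to exactly one reason."""
    tally: dict[str, int] = {}
    reason = pd.Series("", index=df.index)

    def mark(mask: pd.Series, name: str) -> None:
        mask = mask & (reason == "")
        if mask.any():
            reason[mask] = name

    mark(~np.isfinite(df["beta"].astype(float)), "nonfinite_beta")
    mark(~(df["se"].astype(float) > 0), "nonpositive_se")
    allele_ok = df["effect_allele"].map(_allele_valid) & df["other_allele"].map(
        _allele_valid
    )
    mark(~allele_ok, "invalid_alleles")
    mark(df["effect_allele"] == df["other_allele"], "identical_alleles")
    p = df["pval"].astype(float)
    mark(p.notna() & ~((p > 0) & (p <= 1)), "bad_pval")
    eaf = df["eaf"].astype(float)
    mark(eaf.notna() & ~((eaf > 0) & (eaf < 1)), "bad_eaf")
    pos = df["pos"]
    mark(pos.notna() & (pos.astype(float) < 1), "bad_pos")

    dropped = reason != ""
    for name, count in reason[dropped].value_counts().items():
        tally[f"drop_reason[{name}]"] = int(count)
    kept = df.loc[~dropped].copy()

    # Duplicate variant keys: keep the lowest-p row, tie -> first occurrence.
    if kept["variant_id"].duplicated().any():
        order = kept["pval"].astype(float).fillna(1.0)
        kept = kept.assign(_p=order, _i=np.arange(len(kept)))
        kept = kept.sort_values(["_p", "_i"], kind="stable")
        ndup = int(kept["variant_id"].duplicated().sum())
        kept = kept.drop_duplicates("variant_id", keep="first")
        kept = kept.sort_values("_i").drop(columns=["_p", "_i"])
        tally["duplicates"] = ndup
    return kept, tally


def _allele_valid(a: object) -> bool:
    return isinstance(a, str) and len(a) > 0 and set(a) <= VALID_BASES


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str],
    trait_meta: Mapping[str, str],
) -> TraitTable:
    """Read one trait's summary statistics from a delimited text file.

    ``column_map`` maps canonical field names (``variant_id``, ``chrom``,
    ``pos``, ``effect_allele``, ``other_allele``, ``eaf``, ``beta``,
    ``se``, ``pval``, ``n``) to the file's column headers.  Only the
    variant key, alleles, beta and se are mandatory; a missing ``pval``
    is derived from the Wald z score.  Rows violating record invariants
    are dropped and tallied on the returned table's ``tally``.
    """
    path = Path(path)
    for field in MANDATORY_FIELDS:
        if field not in column_map:
            raise ConfigError(f"column_map is missing mandatory field {field!r}")
    try:
        raw = pd.read_csv(path, sep=None, engine="python")
    except OSError as exc:
        raise SumstatsError(f"cannot read {path}: {exc}") from exc
    return _build_trait_table(raw, column_map, trait_meta, origin=str(path))


def _build_trait_table(
    raw: pd.DataFrame,
    column_map: Mapping[str, str],
    trait_meta: Mapping[str, str],
    origin: str,
) -> TraitTable:
    missing_cols = [c for c in column_map.values() if c not in raw.columns]
    if missing_cols:
        raise ConfigError(f"{origin}: mapped column(s) not in file: {missing_cols}")

    df = pd.DataFrame(index=raw.index)
    for field in CANONICAL_COLUMNS:
        if field in column_map:
            df[field] = raw[column_map[field]]
        else:
            df[field] = np.nan
    for field in ("variant_id", "chrom", "effect_allele", "other_allele"):
        df[field] = df[field].astype(str)
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    for field in ("eaf", "beta", "se", "pval"):
        df[field] = pd.to_numeric(df[field], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")
    # n must be a positive integer or missing
    bad_n = df["n"].notna() & (df["n"] <= 0)
    df.loc[bad_n, "n"] = np.nan

    kept, tally = _validate_frame(df)
    if kept.empty:
        raise EmptyTableError(f"{origin}: zero valid rows after validation")
    # Derive missing p-values from the Wald z (two-sided normal).
    missing_p = kept["pval"].isna()
    if missing_p.any():
        z = kept.loc[missing_p, "beta"] / kept.loc[missing_p, "se"]
        kept.loc[missing_p, "pval"] = np.maximum(
            2.0 * stats.norm.sf(np.abs(z)), np.nextafter(0.0, 1.0)
        )
    tally["kept"] = len(kept)
    return TraitTable(
        trait_id=str(trait_meta["trait_id"]),
        trait_type=str(trait_meta.get("trait_type", "protein")),
        platform_or_tissue=str(trait_meta.get("platform_or_tissue", "")),
        df=kept,
        tally=tally,
    )


def read_multi_sumstats(
    path: str | Path,
    column_map: Mapping[str, str],
    trait_column: str,
    trait_type: str,
    platform_or_tissue: str,
) -> dict[str, TraitTable]:
    """Split a combined file carrying a trait-id column into TraitTables."""
    path = Path(path)
    raw = pd.read_csv(path, sep=None, engine="python")
    if trait_column not in raw.columns:
        raise ConfigError(f"{path}: trait column {trait_column!r} not in file")
    out: dict[str, TraitTable] = {}
    for trait_id, sub in raw.groupby(trait_column, sort=True):
        try:
            out[str(trait_id)] = _build_trait_table(
                sub.drop(columns=[trait_column]).reset_index(drop=True),
                column_map,
                {
                    "trait_id": str(trait_id),
                    "trait_type": trait_type,
                    "platform_or_tissue": platform_or_tissue,
                },
                origin=f"{path}[{trait_id}]",
            )
        except EmptyTableError:
            continue
    return out


def read_locus_table(path: str | Path) -> list[GeneLocus]:
    """4-column TSV: gene_id, chrom, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = {"gene_id", "chrom", "start", "end"}
    if not needed <= set(df.columns):
        raise ConfigError(f"locus table must have columns {sorted(needed)}")
    return [
        GeneLocus(str(r.gene_id), str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    ]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict:
    """Write one TSV per result class plus a JSON reproducibility manifest.

    Re-reading a written table reproduces it to full float precision
    (pandas emits shortest round-trip float repr).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise SumstatsError(f"output directory not writable: {out_dir}: {exc}") from exc

    import cismr

    manifest: dict = {
        "package": "cismr",
        "version": getattr(cismr, "__version__", "unknown"),
        "seed": seed,
        "config": _jsonable(config) if config is not None else None,
        "tables": {},
    }
    for name in sorted(tables):
        df = tables[name]
        fname = f"{name}.tsv"
        df.to_csv(out_dir / fname, sep="\t", index=False)
        manifest["tables"][name] = {"file": fname, "rows": int(len(df))}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj
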