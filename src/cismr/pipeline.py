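"""End-to-end scan orchestration: instruments -> harmonization -> MR ->
FDR -> colocalization -> triangulation, driven by one RunConfig.

Per-trait failures (no cis instrument, no harmonizable outcome data,
insufficient instruments for a sensitivity method) are recorded in the
result tables and manifest counts and never abort the scan.  Multiple
testing is corrected within each platform/tissue separately (the
per-dataset reporting convention); a pooled universe is configurable.
Given the same config and seed, repeated runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import harmonize as harm_mod
from . import instruments as ins_mod
from . import mr as mr_mod
from . import sumstats as ss
from . import triangulate as tri_mod
from . import validation as val_mod

__all__ = ["RunConfig", "run_scan", "run_validate", "load_config"]


@dataclass
class RunConfig:
    exposure_paths: dict[str, str]  # platform/tissue -> combined TSV
    outcome_path: str
    locus_path: str
    out_dir: str
    exposure_types: dict[str, str] = field(default_factory=dict)  # -> protein|transcript
    ld_dir: str | None = None
    column_map: dict[str, str] = field(
        default_factory=lambda: dict(ss.IDENTITY_COLUMN_MAP)
    )
    trait_column: str = "trait_id"
    cis_window: int = ins_mod.DEFAULT_CIS_WINDOW
    p_threshold: float = ins_mod.DEFAULT_P_THRESHOLD
    f_min: float = ins_mod.DEFAULT_F_MIN
    r2_max: float = ins_mod.DEFAULT_R2_MAX
    palindrome_policy: str = "infer_by_eaf"
    eaf_window: float = 0.08
    p1: float = coloc_mod.DEFAULT_PRIORS[0]
    p2: float = coloc_mod.DEFAULT_PRIORS[1]
    p12: float = coloc_mod.DEFAULT_PRIORS[2]
    coloc_threshold: float = tri_mod.DEFAULT_COLOC_THRESHOLD
    q_level: float = 0.05
    n_boot: int = 2000
    fdr_universe: str = "per_dataset"  # per_dataset | pooled
    genome_build: str = "unspecified"
    seed: int = 0

    def validate(self) -> None:
        for name, path in {
            "outcome_path": self.outcome_path,
            "locus_path": self.locus_path,
            **{f"exposure_paths[{k}]": v for k, v in self.exposure_paths.items()},
        }.items():
            if not Path(path).exists():
                raise ss.ConfigError(f"{name}: path does not exist: {path}")
        if not self.exposure_paths:
            raise ss.ConfigError("exposure_paths: at least one platform required")
        for name, val, lo, hi in (
            ("p_threshold", self.p_threshold, 0.0, 1.0),
            ("r2_max", self.r2_max, 0.0, 1.0),
            ("coloc_threshold", self.coloc_threshold, 0.0, 1.0),
            ("q_level", self.q_level, 0.0, 1.0),
            ("eaf_window", self.eaf_window, 0.0, 0.5),
        ):
            if not (lo <= val <= hi):
                raise ss.ConfigError(f"{name}: {val} outside [{lo}, {hi}]")
        if self.cis_window < 0:
            raise ss.ConfigError("cis_window must be >= 0")
        if self.fdr_universe not in ("per_dataset", "pooled"):
            raise ss.ConfigError(f"fdr_universe: unknown value {self.fdr_universe!r}")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ss.ConfigError(f"unknown config field(s): {sorted(unknown)}")
    return RunConfig(**raw)


def _mr_row(platform: str, res: mr_mod.MRResult) -> dict:
    return {
        "trait_id": res.trait_id,
        "dataset": platform,
        "method": res.method,
        "n_snp": res.n_snp,
        "estimate": res.estimate,
        "se": res.se,
        "pval": res.pval,
        "p_adj": np.nan,
        "or_point": res.or_point,
        "or_lo95": res.or_lo95,
        "or_hi95": res.or_hi95,
        "egger_intercept": res.egger_intercept,
        "egger_intercept_p": res.egger_intercept_p,
        "status": res.status,
        "reason": res.reason or "",
    }


def _unavailable_row(trait_id: str, platform: str, reason: str) -> dict:
    row = {
        "trait_id": trait_id,
        "dataset": platform,
        "method": "",
        "n_snp": 0,
        "estimate": np.nan,
        "se": np.nan,
        "pval": np.nan,
        "p_adj": np.nan,
        "or_point": np.nan,
        "or_lo95": np.nan,
        "or_hi95": np.nan,
        "egger_intercept": np.nan,
        "egger_intercept_p": np.nan,
        "status": "unavailable",
        "reason": reason,
    }
    return row


def _load_ld(config: RunConfig, gene_id: str) -> pd.DataFrame | None:
    if config.ld_dir is None:
        return None
    path = Path(config.ld_dir) / f"{gene_id}.tsv"
    if not path.exists():
        return None
    return pd.read_csv(path, sep="\t", index_col=0)


def _coloc_for_trait(
    exp_table: ss.TraitTable,
    outcome: ss.TraitTable,
    locus: ss.GeneLocus,
    config: RunConfig,
) -> coloc_mod.ColocResult | None:
    """Colocalize the full cis region (no p-value filtering) of a trait
    against the outcome, using only harmonizable shared variants."""
    lo, hi = locus.cis_window(config.cis_window)
    df = exp_table.df
    in_region = (
        (df["chrom"].astype(str) == str(locus.chrom))
        & (pd.to_numeric(df["pos"]) >= lo)
        & (pd.to_numeric(df["pos"]) <= hi)
    )
    sub = ss.TraitTable(
        exp_table.trait_id,
        exp_table.trait_type,
        exp_table.platform_or_tissue,
        df.loc[in_region],
    )
    pairs, _ = harm_mod.harmonize_tables(
        sub, outcome, config.palindrome_policy, config.eaf_window
    )
    usable = [p for p in pairs if p.usable]
    if not usable:
        return None
    ids = tuple(p.variant_id for p in usable)
    exp_type = "quant"  # protein/transcript levels are quantitative
    r1 = coloc_mod.ColocInputRegion(
        trait_id=exp_table.trait_id,
        variant_ids=ids,
        beta=np.array([p.beta_exp for p in usable]),
        se=np.array([p.se_exp for p in usable]),
        trait_type=exp_type,
    )
    r2 = coloc_mod.ColocInputRegion(
        trait_id=outcome.trait_id,
        variant_ids=ids,
        beta=np.array([p.beta_out for p in usable]),
        se=np.array([p.se_out for p in usable]),
        trait_type="binary",
    )
    return coloc_mod.coloc_abf(r1, r2, config.p1, config.p2, config.p12)


def run_scan(config: RunConfig) -> dict:
    """Execute the full discovery scan; returns the manifest dict."""
    config.validate()
    outcome_tables = ss.read_multi_sumstats(
        config.outcome_path, config.column_map, config.trait_column, "outcome", "gwas"
    ) if _has_trait_column(config.outcome_path, config.trait_column) else None
    if outcome_tables:
        if len(outcome_tables) != 1:
            raise ss.ConfigError("outcome file must contain exactly one trait")
        outcome = next(iter(outcome_tables.values()))
    else:
        outcome = ss.read_sumstats(
            config.outcome_path,
            config.column_map,
            {"trait_id": "outcome", "trait_type": "outcome", "platform_or_tissue": "gwas"},
        )
    loci = {g.gene_id: g for g in ss.read_locus_table(config.locus_path)}

    mr_rows: list[dict] = []
    sens_rows: list[dict] = []
    coloc_rows: list[dict] = []
    counts: dict[str, dict] = {}

    for platform in sorted(config.exposure_paths):
        trait_type = config.exposure_types.get(platform, "protein")
        tables = ss.read_multi_sumstats(
            config.exposure_paths[platform],
            config.column_map,
            config.trait_column,
            trait_type,
            platform,
        )
        n_total = len(tables)
        n_analyzable = 0
        for ti, trait_id in enumerate(sorted(tables)):
            exp_table = tables[trait_id]
            locus = loci.get(trait_id)
            if locus is None:
                mr_rows.append(_unavailable_row(trait_id, platform, "no_locus"))
                continue
            selected = ins_mod.select_cis_instruments(
                exp_table, locus, config.cis_window, config.p_threshold, config.f_min
            )
            if not selected:
                mr_rows.append(_unavailable_row(trait_id, platform, "no_cis_instrument"))
                continue
            ld = _load_ld(config, trait_id)
            clumped = ins_mod.ld_clump(selected, ld, config.r2_max)
            ins_table = ss.TraitTable.from_records(
                trait_id, trait_type, platform, [i.variant for i in clumped]
            )
            pairs, _ = harm_mod.harmonize_tables(
                ins_table, outcome, config.palindrome_policy, config.eaf_window
            )
            usable = [p for p in pairs if p.usable]
            if not usable:
                mr_rows.append(
                    _unavailable_row(trait_id, platform, "no_harmonized_instrument")
                )
                continue
            n_analyzable += 1
            k = len(usable)
            if k == 1:
                primary = mr_mod.wald_ratio(usable[0], trait_id)
            else:
                primary = mr_mod.ivw(usable, "multiplicative_random", trait_id)
            mr_rows.append(_mr_row(platform, primary))
            # sensitivity estimators (NotEstimable below 3 instruments)
            boot_seed = (config.seed * 100_003 + ti) % (2**31 - 1)
            sens_rows.append(_mr_row(platform, mr_mod.egger(usable, trait_id)))
            sens_rows.append(
                _mr_row(
                    platform,
                    mr_mod.weighted_median(usable, config.n_boot, boot_seed, trait_id),
                )
            )
            cres = _coloc_for_trait(exp_table, outcome, locus, config)
            if cres is not None:
                coloc_rows.append(
                    {
                        "trait_id": trait_id,
                        "dataset": platform,
                        "n_variants": cres.n_variants,
                        "pp_h0": cres.pp_h0,
                        "pp_h1": cres.pp_h1,
                        "pp_h2": cres.pp_h2,
                        "pp_h3": cres.pp_h3,
                        "pp_h4": cres.pp_h4,
                        "conditional_pp": cres.conditional_pp,
                        "p1": cres.p1,
                        "p2": cres.p2,
                        "p12": cres.p12,
                    }
                )
        counts[platform] = {"traits_total": n_total, "traits_analyzable": n_analyzable}

    mr_df = pd.DataFrame(mr_rows)
    if not mr_df.empty:
        ok = mr_df["status"] == "ok"
        if config.fdr_universe == "pooled":
            if ok.any():
                mr_df.loc[ok, "p_adj"] = mr_mod.bh_adjust(mr_df.loc[ok, "pval"])
        else:
            for platform in mr_df["dataset"].unique():
                mask = ok & (mr_df["dataset"] == platform)
                if mask.any():
                    mr_df.loc[mask, "p_adj"] = mr_mod.bh_adjust(mr_df.loc[mask, "pval"])
    sens_df = pd.DataFrame(sens_rows)
    coloc_df = pd.DataFrame(coloc_rows)

    # triangulation: evidence matrix over protein platforms + tiers
    protein_platforms = sorted(
        pl
        for pl in config.exposure_paths
        if config.exposure_types.get(pl, "protein") == "protein"
    )
    tissue_sets = sorted(set(config.exposure_paths) - set(protein_platforms))
    prot_df = (
        mr_df[mr_df["dataset"].isin(protein_platforms)] if not mr_df.empty else mr_df
    )
    cells, evidence_wide = tri_mod.build_evidence_matrix(
        prot_df, datasets=protein_platforms
    )
    tier_rows = []
    if not prot_df.empty:
        for trait_id in sorted(prot_df["trait_id"].unique()):
            sub = prot_df[prot_df["trait_id"] == trait_id]
            csub = (
                coloc_df[
                    (coloc_df["trait_id"] == trait_id)
                    & (coloc_df["dataset"].isin(protein_platforms))
                ]
                if not coloc_df.empty
                else None
            )
            esub = None
            if tissue_sets and not mr_df.empty:
                esub = mr_df[
                    (mr_df["trait_id"] == trait_id)
                    & (mr_df["dataset"].isin(tissue_sets))
                ].rename(columns={"dataset": "tissue"})
            tier = tri_mod.classify_support(
                trait_id,
                sub,
                csub,
                esub,
                q_level=config.q_level,
                coloc_threshold=config.coloc_threshold,
            )
            tier_rows.append(
                {
                    "trait_id": tier.trait_id,
                    "mr_significant_datasets": tier.mr_significant_datasets,
                    "directionally_consistent": tier.directionally_consistent,
                    "coloc_supported_datasets": ",".join(tier.coloc_supported_datasets),
                    "eqtl_corroborated_tissues": ",".join(
                        tier.eqtl_corroborated_tissues
                    ),
                    "tier": tier.tier or "",
                }
            )
    tiers_df = pd.DataFrame(tier_rows)

    tables = {
        "mr": mr_df,
        "mr_sensitivity": sens_df,
        "coloc": coloc_df,
        "evidence_matrix": evidence_wide.reset_index()
        if not evidence_wide.empty
        else evidence_wide,
        "tiers": tiers_df,
    }
    manifest = ss.write_results(
        tables,
        config.out_dir,
        config=dataclasses.asdict(config) | {"counts": counts},
        seed=config.seed,
    )
    manifest["counts"] = counts
    return manifest


def _has_trait_column(path: str, trait_column: str) -> bool:
    head = pd.read_csv(path, sep=None, engine="python", nrows=0)
    return trait_column in head.columns


def run_validate(
    intensities_path: str,
    clinical_path: str,
    covariate_types: dict[str, str],
    out_dir: str,
    min_detect_frac: float = 0.5,
    seed: int | None = None,
) -> dict:
    """Case-control validation: differential abundance + baseline table."""
    intensities = pd.read_csv(intensities_path, sep="\t", index_col=0)
    clinical = pd.read_csv(clinical_path, sep="\t")
    if "group" not in clinical.columns:
        raise ss.ConfigError("clinical table lacks required column 'group'")
    sample_col = clinical.columns[0]
    groups = pd.Series(
        clinical["group"].astype(str).values, index=clinical[sample_col].astype(str)
    )
    de = val_mod.de_test(intensities, groups, min_detect_frac=min_detect_frac)
    baseline = val_mod.baseline_compare(clinical, covariate_types)
    return ss.write_results({"de": de, "baseline": baseline}, out_dir, seed=seed)
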