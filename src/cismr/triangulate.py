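"""Cross-platform/tissue triangulation of MR and colocalization evidence.

A protein association earns corroboration two ways: a Bayesian
colocalization posterior PP.H4 above threshold in some dataset, or a
directionally consistent, FDR-significant transcript (eQTL) association
in some tissue.  The evidence matrix mirrors the familiar
protein-by-dataset heatmap (gray = not available for analysis;
significance stars on FDR-adjusted p), and the support tiers rank
traits by how many independent lines of evidence agree:

- T1: MR-significant in >= 1 platform, colocalization-supported AND
  eQTL-corroborated;
- T2: MR-significant plus exactly one of the two corroborations;
- T3: MR-significant only.

The tiering is an interpretive layer: thresholds (q level, PP.H4 cut,
FDR vs nominal eQTL significance) are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EvidenceCell",
    "SupportTier",
    "significance_stars",
    "directional_consistency",
    "build_evidence_matrix",
    "classify_support",
    "DEFAULT_COLOC_THRESHOLD",
]

DEFAULT_COLOC_THRESHOLD = 0.8
STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


class IntegrityError(Exception):
    """Duplicate (trait, dataset) results in an evidence table."""


def significance_stars(p_adj: float | None) -> str:
    if p_adj is None or (isinstance(p_adj, float) and math.isnan(p_adj)):
        return ""
    for thresh, stars in STAR_THRESHOLDS:
        if p_adj < thresh:
            return stars
    return ""


@dataclass(frozen=True)
class EvidenceCell:
    trait_id: str
    dataset_or_tissue: str
    available: bool
    estimate: float | None = None
    or_point: float | None = None
    p_adj: float | None = None
    stars: str = ""


@dataclass(frozen=True)
class SupportTier:
    trait_id: str
    mr_significant_datasets: int
    directionally_consistent: bool | None
    coloc_supported_datasets: tuple[str, ...]
    eqtl_corroborated_tissues: tuple[str, ...]
    tier: str | None  # T1 | T2 | T3 | None


def directional_consistency(estimates) -> bool | None:
    """True iff all point estimates share a strict sign.

    An estimate of exactly 0 counts as inconsistent.  Fewer than two
    estimable values -> None (consistency undefined).
    """
    vals = [e for e in estimates if e is not None and not math.isnan(e)]
    if len(vals) < 2:
        return None
    signs = {1 if v > 0 else (-1 if v < 0 else 0) for v in vals}
    return signs in ({1}, {-1})


def build_evidence_matrix(
    mr_results: pd.DataFrame,
    datasets: list[str] | None = None,
    traits: list[str] | None = None,
) -> tuple[list[EvidenceCell], pd.DataFrame]:
    """Trait x dataset evidence cells from a long-format MR result frame.

    ``mr_results`` needs columns trait_id, dataset, estimate, or_point,
    p_adj, status.  Every (trait, dataset) combination appears exactly
    once in the output, populated or explicitly unavailable.  A wide
    display frame (stars appended to the OR) is returned alongside.
    """
    required = {"trait_id", "dataset", "estimate", "p_adj", "status"}
    if not mr_results.empty and not required <= set(mr_results.columns):
        raise ValueError(f"mr_results must have columns {sorted(required)}")
    if mr_results.empty:
        return [], pd.DataFrame()
    dup = mr_results.duplicated(subset=["trait_id", "dataset"])
    if dup.any():
        bad = mr_results.loc[dup, ["trait_id", "dataset"]].values.tolist()
        raise IntegrityError(f"duplicate (trait, dataset) results: {bad}")

    traits = traits or sorted(mr_results["trait_id"].unique())
    datasets = datasets or sorted(mr_results["dataset"].unique())
    keyed = mr_results.set_index(["trait_id", "dataset"])

    cells: list[EvidenceCell] = []
    display = pd.DataFrame(index=traits, columns=datasets, dtype=object)
    for t in traits:
        for d in datasets:
            try:
                row = keyed.loc[(t, d)]
                ok = row["status"] == "ok"
            except KeyError:
                ok = False
            if not ok:
                cells.append(EvidenceCell(t, d, available=False))
                display.loc[t, d] = "NA"
                continue
            p_adj = None if pd.isna(row["p_adj"]) else float(row["p_adj"])
            stars = significance_stars(p_adj)
            orp = float(row["or_point"]) if "or_point" in row else math.exp(row["estimate"])
            cells.append(
                EvidenceCell(
                    t,
                    d,
                    available=True,
                    estimate=float(row["estimate"]),
                    or_point=orp,
                    p_adj=p_adj,
                    stars=stars,
                )
            )
            display.loc[t, d] = f"{orp:.2f}{stars}"
    display.index.name = "trait_id"
    return cells, display


def classify_support(
    trait_id: str,
    mr_results: pd.DataFrame,
    coloc_results: pd.DataFrame | None = None,
    eqtl_results: pd.DataFrame | None = None,
    q_level: float = 0.05,
    coloc_threshold: float = DEFAULT_COLOC_THRESHOLD,
    eqtl_use_fdr: bool = True,
) -> SupportTier:
    """Assign the trait a support tier from MR, coloc and eQTL evidence.

    ``mr_results``: long frame (dataset, estimate, p_adj, status) of the
    trait's protein-platform MR results.  ``coloc_results``: (dataset,
    pp_h4).  ``eqtl_results``: (tissue, estimate, pval, p_adj, status)
    of transcript MR results for the same gene.  eQTL corroboration
    requires significance in that tissue (FDR by default) *and* sign
    consistency with the protein-platform MR estimates.
    """
    if not mr_results.empty and "status" in mr_results.columns:
        mine = mr_results[mr_results["status"] == "ok"]
    else:
        mine = mr_results
    sig = mine[mine["p_adj"] < q_level] if not mine.empty else mine
    n_sig = int(len(sig))

    ests = list(mine["estimate"]) if not mine.empty else []
    consistent = directional_consistency(ests)

    coloc_supported: tuple[str, ...] = ()
    if coloc_results is not None and not coloc_results.empty:
        hits = coloc_results[coloc_results["pp_h4"] >= coloc_threshold]
        coloc_supported = tuple(sorted(hits["dataset"].astype(str)))

    eqtl_tissues: tuple[str, ...] = ()
    if eqtl_results is not None and not eqtl_results.empty and ests:
        pcol = "p_adj" if eqtl_use_fdr else "pval"
        if "status" in eqtl_results.columns:
            ok = eqtl_results[eqtl_results["status"] == "ok"]
        else:
            ok = eqtl_results
        sig_e = ok[ok[pcol] < q_level]
        protein_sign = np.sign(np.mean(np.sign(ests)))
        corr = [
            str(r["tissue"])
            for _, r in sig_e.iterrows()
            if protein_sign != 0 and np.sign(r["estimate"]) == protein_sign
        ]
        eqtl_tissues = tuple(sorted(corr))

    if n_sig == 0:
        tier = None
    else:
        corroborations = int(bool(coloc_supported)) + int(bool(eqtl_tissues))
        tier = {2: "T1", 1: "T2", 0: "T3"}[corroborations]
    return SupportTier(
        trait_id=trait_id,
        mr_significant_datasets=n_sig,
        directionally_consistent=consistent,
        coloc_supported_datasets=coloc_supported,
        eqtl_corroborated_tissues=eqtl_tissues,
        tier=tier,
    )
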