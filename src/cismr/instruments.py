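"""Cis instrument selection and instrument-strength quantification.

An instrument is a variant lying within a window of the gene body
(default gene body ± 1 Mb) whose exposure association passes a p-value
threshold (default genome-wide significance, 5e-8) and whose strength,
summarized by the F statistic (beta/se)^2, exceeds a minimum (default
10, the conventional weak-instrument bound).  Approximate independence
among instruments is enforced by greedy LD clumping; with no LD matrix
available the single lowest-p variant is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sumstats import ConfigError, GeneLocus, TraitTable, VariantAssoc

__all__ = ["Instrument", "f_statistic", "select_cis_instruments", "ld_clump"]

DEFAULT_CIS_WINDOW = 1_000_000
DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_F_MIN = 10.0
DEFAULT_R2_MAX = 0.01


@dataclass(frozen=True)
class Instrument:
    variant: VariantAssoc
    gene: GeneLocus
    f_stat: float
    in_cis: bool = True


def f_statistic(beta: float, se: float) -> float:
    """Single-variant instrument-strength F statistic, (beta/se)^2."""
    if not se > 0:
        raise ValueError("se must be > 0")
    return (beta / se) ** 2


def select_cis_instruments(
    exp: TraitTable,
    locus: GeneLocus,
    window_bp: int = DEFAULT_CIS_WINDOW,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    f_min: float = DEFAULT_F_MIN,
) -> list[Instrument]:
    """Variants in the closed cis window passing the p and F thresholds.

    Sorted by ascending p, ties broken by position then variant id, so
    the result is deterministic and independent of input row order.  An
    empty list is a valid outcome (trait "not available for analysis").
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    lo, hi = locus.cis_window(window_bp)
    df = exp.df
    pos = pd.to_numeric(df["pos"], errors="coerce")
    pval = pd.to_numeric(df["pval"], errors="coerce")
    fstat = (
        pd.to_numeric(df["beta"], errors="coerce")
        / pd.to_numeric(df["se"], errors="coerce")
    ) ** 2
    mask = (
        (df["chrom"].astype(str) == str(locus.chrom))
        & (pos >= lo)
        & (pos <= hi)
        & (pval <= p_threshold)
        & (fstat >= f_min)
    )
    sel = df.loc[mask.fillna(False)].copy()
    sel = sel.sort_values(
        ["pval", "pos", "variant_id"], kind="stable"
    )
    return [
        Instrument(
            variant=TraitTable._row_to_record(row),
            gene=locus,
            f_stat=float((row["beta"] / row["se"]) ** 2),
            in_cis=True,
        )
        for _, row in sel.iterrows()
    ]


def ld_clump(
    instruments: list[Instrument],
    ld: pd.DataFrame | None = None,
    r2_max: float = DEFAULT_R2_MAX,
) -> list[Instrument]:
    """Greedy LD clumping by ascending p.

    A candidate is kept iff its squared correlation with every already
    kept variant is <= ``r2_max``.  With ``ld`` absent only the single
    lowest-p instrument is returned (conservative: independence cannot
    be verified).  ``ld`` must be a square symmetric unit-diagonal frame
    indexed by variant id in both axes, covering all instruments.
    """
    if not instruments:
        return []
    ordered = sorted(
        instruments,
        key=lambda ins: (ins.variant.pval, ins.variant.pos, ins.variant.variant_id),
    )
    if ld is None:
        return [ordered[0]]

    ids = [ins.variant.variant_id for ins in ordered]
    if ld.shape[0] != ld.shape[1]:
        raise ConfigError("LD matrix is not square")
    missing = [v for v in ids if v not in ld.index or v not in ld.columns]
    if missing:
        raise ConfigError(f"LD matrix missing variants: {missing}")
    sub = ld.loc[ids, ids].to_numpy(dtype=float)
    if not np.allclose(sub, sub.T, atol=1e-8):
        raise ConfigError("LD matrix is not symmetric")
    if not np.allclose(np.diag(sub), 1.0, atol=1e-6):
        raise ConfigError("LD matrix diagonal is not 1")

    kept_idx: list[int] = []
    for i in range(len(ordered)):
        if all(sub[i, j] ** 2 <= r2_max for j in kept_idx):
            kept_idx.append(i)
    return [ordered[i] for i in kept_idx]
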