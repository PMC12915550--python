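"""Case-control statistics for the proteomic validation cohort.

``de_test`` performs differential-abundance testing on a protein x
sample intensity matrix (mass-spectrometry convention: zero/missing
intensity means not detected).  Proteins detected in enough samples of
both groups are log2-transformed and compared by a two-sided Welch
t-test; the effect size is the log2 fold change, mean(log2 case) -
mean(log2 control).  Benjamini-Hochberg adjustment runs across the
tested proteins.  Proteins below the detection threshold are reported
with ``detected=False`` rather than silently dropped.

``baseline_compare`` builds the usual Table-1-style group comparison:
two-sample t-test for continuous covariates, Pearson chi-square without
continuity correction for categorical ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .mr import bh_adjust

__all__ = ["de_test", "baseline_compare"]


def _group_masks(groups: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    labels = set(groups.unique())
    if not labels <= {"case", "control"}:
        raise ValueError(f"group labels must be 'case'/'control', got {sorted(labels)}")
    return (groups == "case").to_numpy(), (groups == "control").to_numpy()


def de_test(
    intensities: pd.DataFrame,
    groups: pd.Series,
    min_detect_frac: float = 0.5,
    zeros_as_missing: bool = True,
    pseudo_intensity: float = 0.0,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Differential-abundance test per protein (rows) across samples (cols).

    Parameters
    ----------
    groups
        Sample -> {'case','control'}, indexed compatibly with the
        matrix's columns.
    min_detect_frac
        A protein is "detected" when its non-missing fraction reaches
        this threshold in *each* group; others carry detected=False and
        no statistics.
    zeros_as_missing
        Treat zero intensity as missing (default).  When False, zeros
        are offset by ``pseudo_intensity`` before log2.
    equal_var
        False (default) = Welch; True = pooled-variance t-test.
    """
    if intensities.empty:
        raise ValueError("intensity matrix is empty")
    groups = groups.reindex(intensities.columns)
    if groups.isna().any():
        missing = list(intensities.columns[groups.isna()])
        raise ValueError(f"samples without group label: {missing}")
    case_mask, ctrl_mask = _group_masks(groups)
    if case_mask.sum() < 2 or ctrl_mask.sum() < 2:
        raise ValueError("need >= 2 samples per group")

    mat = intensities.to_numpy(dtype=float)
    if zeros_as_missing:
        mat = np.where(mat == 0, np.nan, mat)
    else:
        mat = np.where(mat == 0, pseudo_intensity, mat)
    if np.nanmin(mat) <= 0:
        raise ValueError("nonpositive intensities cannot be log2-transformed")

    rows = []
    for i, protein in enumerate(intensities.index):
        case_vals = mat[i, case_mask]
        ctrl_vals = mat[i, ctrl_mask]
        case_vals = case_vals[~np.isnan(case_vals)]
        ctrl_vals = ctrl_vals[~np.isnan(ctrl_vals)]
        n_case, n_ctrl = len(case_vals), len(ctrl_vals)
        detected = (
            n_case >= min_detect_frac * case_mask.sum()
            and n_ctrl >= min_detect_frac * ctrl_mask.sum()
        )
        row = {
            "protein_id": protein,
            "detected": detected,
            "n_case_detected": n_case,
            "n_control_detected": n_ctrl,
            "log2fc": np.nan,
            "pval": np.nan,
            "testable": False,
        }
        if detected and n_case >= 2 and n_ctrl >= 2:
            lc = np.log2(case_vals)
            lo = np.log2(ctrl_vals)
            row["log2fc"] = float(lc.mean() - lo.mean())
            if lc.std(ddof=1) == 0 and lo.std(ddof=1) == 0:
                row["pval"] = 1.0 if row["log2fc"] == 0 else np.nan
            else:
                row["pval"] = float(
                    stats.ttest_ind(lc, lo, equal_var=equal_var).pvalue
                )
            row["testable"] = np.isfinite(row["pval"])
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    tested = out["testable"] & out["pval"].notna()
    if tested.any():
        out.loc[tested, "p_adj"] = bh_adjust(
            np.clip(out.loc[tested, "pval"].to_numpy(), 5e-324, 1.0)
        )
    return out


def baseline_compare(
    clinical: pd.DataFrame,
    covariate_types: dict[str, str],
    group_column: str = "group",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Baseline characteristics comparison between case and control groups.

    Continuous covariates: two-sided two-sample t-test on means (Welch
    by default).  Categorical covariates: Pearson chi-square on the
    contingency table without continuity correction — the variant that
    reproduces printed baseline-table p-values from recoverable counts.
    Constant covariates yield a missing p.
    """
    if group_column not in clinical.columns:
        raise ValueError(f"clinical table lacks group column {group_column!r}")
    groups = clinical[group_column].astype(str)
    case_mask, ctrl_mask = _group_masks(groups)

    rows = []
    for cov, ctype in covariate_types.items():
        if cov not in clinical.columns:
            raise ValueError(f"clinical table lacks covariate {cov!r}")
        col = clinical[cov]
        if ctype == "continuous":
            x = pd.to_numeric(col[case_mask], errors="coerce").dropna()
            y = pd.to_numeric(col[ctrl_mask], errors="coerce").dropna()
            if x.nunique() <= 1 and y.nunique() <= 1:
                stat, p = np.nan, np.nan
            else:
                res = stats.ttest_ind(x, y, equal_var=equal_var)
                stat, p = float(res.statistic), float(res.pvalue)
            rows.append(
                {
                    "covariate": cov,
                    "type": ctype,
                    "test": "welch_t" if not equal_var else "pooled_t",
                    "case_summary": f"{x.mean():.3g} ± {x.std(ddof=1):.3g}",
                    "control_summary": f"{y.mean():.3g} ± {y.std(ddof=1):.3g}",
                    "statistic": stat,
                    "pval": p,
                }
            )
        elif ctype == "categorical":
            table = pd.crosstab(col, groups)
            if table.shape[0] < 2:
                stat, p = np.nan, np.nan
            else:
                res = stats.chi2_contingency(table.to_numpy(), correction=False)
                stat, p = float(res.statistic), float(res.pvalue)
            counts_case = col[case_mask].value_counts().to_dict()
            counts_ctrl = col[ctrl_mask].value_counts().to_dict()
            rows.append(
                {
                    "covariate": cov,
                    "type": ctype,
                    "test": "chi2_no_correction",
                    "case_summary": str(counts_case),
                    "control_summary": str(counts_ctrl),
                    "statistic": stat,
                    "pval": p,
                }
            )
        else:
            raise ValueError(f"covariate {cov!r}: unknown type {ctype!r}")
    return pd.DataFrame(rows)
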