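"""Synthetic summary statistics and intensity matrices for desk-scale runs.

Real pQTL/eQTL and disease-GWAS inputs are consortium-scale and not
redistributable, so every pipeline stage is exercised on simulated data
that reproduces the statistical structure the methods assume:

- regional summary statistics under an AR1 LD model, drawn directly
  from the multivariate-normal sampling distribution of marginal GWAS
  estimates (no individual-level genotypes are simulated — the pipeline
  only ever consumes the marginal estimates);
- multi-instrument MR studies with optional balanced or directional
  pleiotropy and randomized allele orientation, to exercise
  harmonization;
- log-normal protein intensity matrices with group shifts on the log2
  scale and optional detection masking.

For a standardized quantitative trait the sampling variance of a
marginal per-allele estimate is approximately 1/(n * 2 * maf * (1-maf));
for a binary (log-odds) trait it is inflated by 1/(phi*(1-phi)) for
case fraction phi.  Default sample sizes mirror a large pQTL cohort
(n = 35 000) against a modest disease GWAS (1917 cases / 9292 controls).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import ColocInputRegion
from .sumstats import GeneLocus, TraitTable, VariantAssoc

__all__ = [
    "SimScenario",
    "simulate_ld",
    "simulate_region_pair",
    "simulate_mr_study",
    "simulate_proteomics",
    "simulate_scan_dataset",
    "write_scan_inputs",
    "sampling_variance",
    "DEFAULT_CASE_FRACTION",
]

#: 1917 cases / (1917 + 9292) controls — the outcome GWAS design.
DEFAULT_CASE_FRACTION = 1917 / (1917 + 9292)

# non-palindromic SNP allele pairs used when randomizing orientations
_SAFE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_PALINDROMIC_PAIRS = [("A", "T"), ("C", "G")]


def sampling_variance(
    n: float, maf, binary: bool = False, case_fraction: float = DEFAULT_CASE_FRACTION
):
    """Approximate variance of a marginal per-allele GWAS estimate."""
    maf = np.asarray(maf, dtype=float)
    v = 1.0 / (n * 2.0 * maf * (1.0 - maf))
    if binary:
        v = v / (case_fraction * (1.0 - case_fraction))
    return v


@dataclass
class SimScenario:
    """Generative parameters for one pair of regional association studies.

    ``hypothesis`` fixes the causal configuration: H0 no causal variant,
    H1/H2 one trait only, H3 distinct variants, H4 one shared variant.
    Unset causal indices default to well-separated positions (center for
    H4; quarter points for H3, far enough apart that LD r^2 < 0.05 at
    the default decay).  Unset effect sizes are chosen to put the causal
    variant's expected |z| at ``target_z`` (default 10) given the drawn
    allele frequency — i.e. a clearly detectable but not overwhelming
    regional signal.
    """

    hypothesis: str = "H4"
    n_variants: int = 500
    ld_rho: float = 0.9
    causal_index_1: int | None = None
    causal_index_2: int | None = None
    effect_size_1: float | None = None
    effect_size_2: float | None = None
    n_trait1: int = 20_000
    n_trait2: int = 20_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    trait1_type: str = "quant"
    trait2_type: str = "binary"
    case_fraction: float = DEFAULT_CASE_FRACTION
    target_z: float = 10.0

    def __post_init__(self) -> None:
        if self.hypothesis not in ("H0", "H1", "H2", "H3", "H4"):
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        n = self.n_variants
        if self.hypothesis == "H4":
            if self.causal_index_1 is None and self.causal_index_2 is None:
                self.causal_index_1 = self.causal_index_2 = n // 2
            elif self.causal_index_1 is None:
                self.causal_index_1 = self.causal_index_2
            elif self.causal_index_2 is None:
                self.causal_index_2 = self.causal_index_1
            if self.causal_index_1 != self.causal_index_2:
                raise ValueError("H4 requires a shared causal index")
        elif self.hypothesis == "H3":
            if self.causal_index_1 is None:
                self.causal_index_1 = n // 4
            if self.causal_index_2 is None:
                self.causal_index_2 = (3 * n) // 4
            if self.causal_index_1 == self.causal_index_2:
                raise ValueError("H3 requires distinct causal indices")
        elif self.hypothesis == "H1":
            if self.causal_index_1 is None:
                self.causal_index_1 = n // 2
            self.causal_index_2 = None
        elif self.hypothesis == "H2":
            if self.causal_index_2 is None:
                self.causal_index_2 = n // 2
            self.causal_index_1 = None
        else:  # H0
            if self.causal_index_1 is not None or self.causal_index_2 is not None:
                raise ValueError("H0 admits no causal indices")
        for idx in (self.causal_index_1, self.causal_index_2):
            if idx is not None and not (0 <= idx < n):
                raise ValueError("causal index out of range")


def simulate_ld(n_variants: int, ld_rho: float) -> np.ndarray:
    """AR1 LD correlation matrix R[i,j] = ld_rho^|i-j| (positive definite)."""
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError("ld_rho must lie in [0, 1)")
    idx = np.arange(n_variants)
    return ld_rho ** np.abs(idx[:, None] - idx[None, :])


def _ar1_cholesky(n: int, rho: float) -> np.ndarray:
    """Lower Cholesky factor of the AR1 matrix, built in closed form."""
    L = np.zeros((n, n))
    L[:, 0] = rho ** np.arange(n)
    s = np.sqrt(1.0 - rho**2)
    for j in range(1, n):
        L[j:, j] = s * rho ** np.arange(n - j)
    return L


def _simulate_marginals(
    rng: np.random.Generator,
    R: np.ndarray,
    L: np.ndarray,
    gamma: np.ndarray,
    variances: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw marginal estimates ~ MVN(R @ gamma, D R D), D = diag(sqrt(v))."""
    mean = R @ gamma
    sd = np.sqrt(variances)
    draw = mean + sd * (L @ rng.standard_normal(len(gamma)))
    return draw, sd


def simulate_region_pair(s: SimScenario) -> tuple[ColocInputRegion, ColocInputRegion]:
    """Regional summary statistics for two traits under one LD panel."""
    rng = np.random.default_rng(s.seed)
    n = s.n_variants
    R = simulate_ld(n, s.ld_rho)
    L = _ar1_cholesky(n, s.ld_rho)
    maf = rng.uniform(*s.maf_range, size=n)
    ids = tuple(f"v{i}" for i in range(n))

    regions = []
    for which in (1, 2):
        trait_type = s.trait1_type if which == 1 else s.trait2_type
        n_samples = s.n_trait1 if which == 1 else s.n_trait2
        idx = s.causal_index_1 if which == 1 else s.causal_index_2
        eff = s.effect_size_1 if which == 1 else s.effect_size_2
        v = sampling_variance(
            n_samples, maf, binary=(trait_type == "binary"), case_fraction=s.case_fraction
        )
        gamma = np.zeros(n)
        if idx is not None:
            if eff is None:
                eff = s.target_z * float(np.sqrt(v[idx]))
            gamma[idx] = eff
        beta, se = _simulate_marginals(rng, R, L, gamma, v)
        regions.append(
            ColocInputRegion(
                trait_id=f"trait{which}",
                variant_ids=ids,
                beta=beta,
                se=se,
                trait_type=trait_type,
            )
        )
    return regions[0], regions[1]


def _random_alleles(rng: np.random.Generator, include_palindromic: bool):
    pool = _SAFE_PAIRS + (_PALINDROMIC_PAIRS if include_palindromic else [])
    return pool[rng.integers(len(pool))]


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def simulate_mr_study(
    k_instruments: int,
    beta_true: float,
    pleiotropy: str = "none",
    alpha_pleio: float = 0.0,
    n_exp: int = 35_000,
    n_out: int = 11_209,
    seed: int = 0,
    f_band: tuple[float, float] = (30.0, 300.0),
    case_fraction: float = DEFAULT_CASE_FRACTION,
    maf_range: tuple[float, float] = (0.1, 0.5),
    include_palindromic: bool = False,
    chrom: str = "1",
    start_pos: int = 1_000_000,
    trait_id: str = "exposure",
    outcome_id: str = "outcome",
    randomize_orientation: bool = True,
) -> tuple[TraitTable, TraitTable]:
    """Independent-instrument two-sample MR study.

    Exposure effect magnitudes are set so each variant's expected F
    statistic falls uniformly in ``f_band`` (signs randomized; a
    degenerate band like ``(100, 100)`` fixes F); outcome effects are
    ``beta_true * beta_exp`` plus a pleiotropic term (``none``: 0;
    ``balanced``: N(0, alpha_pleio^2); ``directional``: N(alpha_pleio,
    (alpha_pleio/2)^2), independent of instrument strength so the InSIDE
    condition holds) plus sampling noise on the binary-outcome scale.
    Outcome allele orientations are randomized (swap / strand flip) to
    exercise harmonization.
    """
    if k_instruments < 1:
        raise ValueError("k_instruments must be >= 1")
    if pleiotropy not in ("none", "balanced", "directional"):
        raise ValueError(f"unknown pleiotropy mode {pleiotropy!r}")
    rng = np.random.default_rng(seed)
    k = k_instruments
    maf = rng.uniform(*maf_range, size=k)
    se_exp = np.sqrt(sampling_variance(n_exp, maf))
    sign = rng.choice([-1.0, 1.0], size=k)
    f_true = rng.uniform(f_band[0], f_band[1], size=k)
    bx_true = sign * np.sqrt(f_true) * se_exp
    bx_hat = bx_true + rng.normal(0.0, se_exp)

    se_out = np.sqrt(
        sampling_variance(n_out, maf, binary=True, case_fraction=case_fraction)
    )
    if pleiotropy == "none":
        pleio = np.zeros(k)
    elif pleiotropy == "balanced":
        pleio = rng.normal(0.0, abs(alpha_pleio), size=k)
    else:
        pleio = rng.normal(alpha_pleio, abs(alpha_pleio) / 2.0, size=k)
    # Pleiotropy is defined relative to the exposure-increasing allele
    # (the orientation Egger regression uses); the arbitrary allele
    # coding of each variant must not flip its sign.
    by_true = beta_true * bx_true + sign * pleio
    by_hat = by_true + rng.normal(0.0, se_out)

    exp_records, out_records = [], []
    for j in range(k):
        ea, oa = _random_alleles(rng, include_palindromic)
        eaf = float(maf[j]) if rng.random() < 0.5 else float(1.0 - maf[j])
        vid = f"{trait_id}_v{j}"
        pos = start_pos + j * 1000
        p_exp = float(max(2.0 * stats.norm.sf(abs(bx_hat[j] / se_exp[j])), 5e-324))
        exp_records.append(
            VariantAssoc(
                variant_id=vid,
                chrom=chrom,
                pos=pos,
                effect_allele=ea,
                other_allele=oa,
                beta=float(bx_hat[j]),
                se=float(se_exp[j]),
                pval=p_exp,
                eaf=eaf,
                n=n_exp,
            )
        )
        # outcome reported in a random but recoverable orientation
        o_ea, o_oa, o_beta, o_eaf = ea, oa, float(by_hat[j]), eaf
        if randomize_orientation:
            if rng.random() < 0.5:  # swap alleles
                o_ea, o_oa = o_oa, o_ea
                o_beta = -o_beta
                o_eaf = 1.0 - o_eaf
            if rng.random() < 0.5:  # report opposite strand
                o_ea = o_ea.translate(_COMPLEMENT)
                o_oa = o_oa.translate(_COMPLEMENT)
        p_out = float(max(2.0 * stats.norm.sf(abs(by_hat[j] / se_out[j])), 5e-324))
        out_records.append(
            VariantAssoc(
                variant_id=vid,
                chrom=chrom,
                pos=pos,
                effect_allele=o_ea,
                other_allele=o_oa,
                beta=o_beta,
                se=float(se_out[j]),
                pval=p_out,
                eaf=o_eaf,
                n=n_out,
            )
        )
    exp_table = TraitTable.from_records(trait_id, "protein", "synthetic", exp_records)
    out_table = TraitTable.from_records(outcome_id, "outcome", "synthetic", out_records)
    return exp_table, out_table


def simulate_proteomics(
    n_case: int,
    n_control: int,
    n_proteins: int,
    effect_map: dict[str, float] | None = None,
    sigma: float = 1.0,
    seed: int = 0,
    masked_proteins: tuple[str, ...] = (),
    base_log2: float = 20.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Log-normal intensity matrix with case-group log2 shifts.

    Protein names are P000, P001, ...; ``effect_map`` assigns selected
    proteins a log2-scale mean shift in cases; ``masked_proteins`` are
    set entirely missing (below detection in every sample).  Returns the
    (proteins x samples) matrix and the sample -> group labels.
    """
    if min(n_case, n_control, n_proteins) < 2:
        raise ValueError("need >= 2 cases, controls and proteins")
    rng = np.random.default_rng(seed)
    effect_map = effect_map or {}
    proteins = [f"P{i:03d}" for i in range(n_proteins)]
    samples = [f"case{i}" for i in range(n_case)] + [
        f"ctrl{i}" for i in range(n_control)
    ]
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=samples, name="group"
    )
    log2_mat = rng.normal(base_log2, sigma, size=(n_proteins, n_case + n_control))
    for name, shift in effect_map.items():
        if name not in proteins:
            raise ValueError(f"unknown protein {name!r} in effect_map")
        log2_mat[proteins.index(name), :n_case] += shift
    mat = np.power(2.0, log2_mat)
    df = pd.DataFrame(mat, index=proteins, columns=samples)
    for name in masked_proteins:
        df.loc[name] = np.nan
    return df, groups


def simulate_scan_dataset(
    n_proteins: int = 20,
    platforms: tuple[str, ...] = ("platformA", "platformB"),
    seed: int = 0,
    k_range: tuple[int, int] = (1, 5),
    frac_causal: float = 0.25,
    causal_beta: float = 0.4,
    missing_fraction: float = 0.15,
    n_exp: int = 35_000,
    n_out: int = 11_209,
) -> dict:
    """Multi-platform proteome-scan fixture.

    Each protein gets a gene locus, per-platform cis instruments (some
    proteins are absent from a platform, emulating assay coverage gaps)
    and outcome associations at the same variants; a ``frac_causal``
    subset carries a true log-odds effect ``causal_beta`` shared across
    platforms.  Returns exposures (platform -> trait -> TraitTable), the
    pooled outcome TraitTable, loci, and the true effect map.
    """
    rng = np.random.default_rng(seed)
    proteins = [f"PROT{i:02d}" for i in range(n_proteins)]
    causal = {
        p: (causal_beta if rng.random() < frac_causal else 0.0) for p in proteins
    }
    loci = []
    exposures: dict[str, dict[str, TraitTable]] = {pl: {} for pl in platforms}
    outcome_records: list[VariantAssoc] = []
    for i, prot in enumerate(proteins):
        chrom = str(1 + i % 22)
        start = 1_000_000 + (i // 22) * 10_000_000
        loci.append(GeneLocus(prot, chrom, start, start + 50_000))
        for pj, platform in enumerate(platforms):
            if rng.random() < missing_fraction:
                continue  # protein not assayed on this platform
            k = int(rng.integers(k_range[0], k_range[1] + 1))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            exp_t, out_t = simulate_mr_study(
                k_instruments=k,
                beta_true=causal[prot],
                seed=sub_seed,
                n_exp=n_exp,
                n_out=n_out,
                chrom=chrom,
                start_pos=start + 1000,
                trait_id=f"{prot}@{platform}",
                f_band=(50.0, 300.0),
            )
            exp_t.trait_id = prot
            exp_t.platform_or_tissue = platform
            exposures[platform][prot] = exp_t
            outcome_records.extend(out_t.records())
    outcome = TraitTable.from_records(
        "disease", "outcome", "synthetic-gwas", outcome_records
    )
    return {
        "exposures": exposures,
        "outcome": outcome,
        "loci": loci,
        "true_effects": causal,
    }


def write_scan_inputs(dataset: dict, out_dir) -> dict:
    """Write a simulate_scan_dataset result as pipeline-readable TSVs.

    One combined exposure TSV per platform (with a trait_id column), one
    outcome TSV and one locus TSV; returns the path mapping a RunConfig
    needs.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict = {"exposure_paths": {}}
    for platform, traits in dataset["exposures"].items():
        frames = []
        for trait_id in sorted(traits):
            df = traits[trait_id].df.copy()
            df.insert(0, "trait_id", trait_id)
            frames.append(df)
        path = out_dir / f"exposure_{platform}.tsv"
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
        paths["exposure_paths"][platform] = str(path)
    outcome_path = out_dir / "outcome.tsv"
    dataset["outcome"].to_tsv(outcome_path)
    paths["outcome_path"] = str(outcome_path)
    locus_path = out_dir / "loci.tsv"
    pd.DataFrame(
        [
            {"gene_id": g.gene_id, "chrom": g.chrom, "start": g.start, "end": g.end}
            for g in dataset["loci"]
        ]
    ).to_csv(locus_path, sep="\t", index=False)
    paths["locus_path"] = str(locus_path)
    return paths
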