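"""Clade-phenotype association scanning over haplotype-network contrasts.

Every branch cut of the haplotype network bipartitions the individuals into
two allelic classes; the scan tests each bipartition for a covariate-adjusted
shift in a quantitative phenotype.

Statistic
    Partial F (1 numerator df) for the group indicator in an ordinary
    least-squares model ``y ~ intercept + covariates + group`` (ANCOVA).
    With a binary group this equals the squared adjusted two-sample t.

Permutation null
    Freedman-Lane: y is regressed on the covariates only; the residuals are
    permuted with a seeded generator, the fitted values are added back, and
    all contrast statistics are recomputed per permutation.  One shared
    permutation stream is used across contrasts (and across the with/without
    APOE models) because the step-down correction needs the joint
    distribution.  Plain phenotype shuffling is available as a fallback.

Multiplicity
    Westfall-Young step-down minP over the shared permutation matrix, with
    monotonicity enforcement; corrected p is never below nominal p.  The
    nominal p itself is analytic (from the F reference distribution) by
    default, or the +1/+1-corrected permutation estimate
    ``(1 + #{F_perm >= F_obs}) / (1 + B)`` when configured.

Contrasts with fewer than ``min_group`` analyzable individuals on either
side are reported as skipped, not silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import ALT, GenotypeMatrix, Haplotype
from .network import Contrast

__all__ = [
    "ScanConfig",
    "ContrastResult",
    "ScanReport",
    "partition_individuals",
    "adjusted_group_test",
    "permutation_scan",
    "scan_both_models",
    "second_round_scan",
    "single_variant_scan",
    "bonferroni_per_test_alpha",
    "write_scan_table",
]


@dataclass(frozen=True)
class ScanConfig:
    phenotype: str = "y"
    covariates: tuple[str, ...] = ("age", "sex")
    n_permutations: int = 10_000
    min_group: int = 5
    alpha: float = 0.05
    seed: int = 0
    nominal_p: str = "analytic"  # "analytic" | "permutation"
    permute: str = "freedman_lane"  # "freedman_lane" | "phenotype"

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.min_group < 1:
            raise ValueError("min_group must be >= 1")
        if self.nominal_p not in ("analytic", "permutation"):
            raise ValueError(f"unknown nominal_p mode {self.nominal_p!r}")
        if self.permute not in ("freedman_lane", "phenotype"):
            raise ValueError(f"unknown permutation scheme {self.permute!r}")


@dataclass
class ContrastResult:
    contrast_id: str
    branch_ids: list[int]
    resolution_id: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    f_statistic: float
    nominal_p: float
    corrected_p: float
    model_tag: str = ""


@dataclass
class ScanReport:
    phenotype: str
    model_tag: str
    results: list[ContrastResult]
    skipped: list[tuple[str, str]]  # (contrast_id, reason)
    config: ScanConfig
    alpha: float = 0.05

    @property
    def significant(self) -> list[ContrastResult]:
        return [r for r in self.results if r.corrected_p <= self.alpha]

    def result(self, contrast_id: str) -> ContrastResult:
        for r in self.results:
            if r.contrast_id == contrast_id:
                return r
        raise KeyError(contrast_id)


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def _encode_covariates(
    subjects: pd.DataFrame, covariates: Sequence[str]
) -> pd.DataFrame:
    """Numeric covariate frame; 'sex' becomes 1=male/0=female."""
    out = pd.DataFrame(index=subjects.index)
    for c in covariates:
        if c not in subjects.columns:
            raise KeyError(f"covariate {c!r} not in subject table")
        col = subjects[c]
        if c == "sex" or col.dtype == object:
            col = col.map({"male": 1.0, "female": 0.0}).astype(float) \
                if set(col.dropna().unique()) <= {"male", "female"} \
                else pd.to_numeric(col)
        out[c] = pd.to_numeric(col)
    return out


def partition_individuals(
    contrast: Contrast,
    haplotypes: Sequence[Haplotype],
    subjects: pd.DataFrame,
    phenotype: str,
    covariates: Sequence[str],
) -> tuple[list[str], list[str]]:
    """Analysis sets per side: complete phenotype + covariates only."""
    cov = _encode_covariates(subjects, covariates)
    ok = subjects[phenotype].notna() & cov.notna().all(axis=1)
    usable = set(subjects.index[ok])
    ids_a = sorted(contrast.individuals_a & usable)
    ids_b = sorted(contrast.individuals_b & usable)
    return ids_a, ids_b


def adjusted_group_test(
    y: np.ndarray, group_indicator: np.ndarray, covariate_matrix: np.ndarray | None
) -> tuple[float, float]:
    """Partial F (1 df) for the group term in OLS of y on covariates + group.

    ``covariate_matrix`` excludes the intercept (pass None for none).
    Returns (F, analytic p).  Raises on rank-deficient designs, naming the
    collinearity.
    """
    y = np.asarray(y, float)
    g = np.asarray(group_indicator, float)
    n = len(y)
    if covariate_matrix is None:
        X = np.ones((n, 1))
    else:
        C = np.atleast_2d(np.asarray(covariate_matrix, float))
        if C.shape[0] != n:
            C = C.T
        X = np.column_stack([np.ones(n), C])
    p = X.shape[1]
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p - 1} covariates plus group")
    if len(set(g)) < 2:
        raise ValueError("group indicator is constant")
    Q, _ = np.linalg.qr(X)
    gt = g - Q @ (Q.T @ g)
    gnorm2 = float(gt @ gt)
    if gnorm2 < 1e-10 * float(g @ g):
        raise ValueError(
            "rank-deficient design: the group indicator is collinear with "
            "the covariates/intercept"
        )
    yt = y - Q @ (Q.T @ y)
    rss0 = float(yt @ yt)
    if rss0 <= 1e-12 * max(float(y @ y), 1e-30):
        return 0.0, 1.0  # y perfectly explained by the covariates alone
    num = float(gt @ yt) ** 2 / gnorm2
    rss1 = rss0 - num
    df_resid = n - p - 1
    if rss1 <= 1e-12 * rss0:
        return np.inf, 0.0
    f = num / (rss1 / df_resid)
    return float(f), float(stats.f.sf(f, 1, df_resid))


# ---------------------------------------------------------------------------
# vectorized scan engine
# ---------------------------------------------------------------------------

def _f_matrix(Yres: np.ndarray, Gt: np.ndarray, gnorm2: np.ndarray, df_resid: int) -> np.ndarray:
    """Partial F for every contrast (rows) x permutation column of Yres."""
    rss0 = np.einsum("ij,ij->j", Yres, Yres)
    A = Gt.T @ Yres  # C x B
    num = A**2 / gnorm2[:, None]
    rss1 = np.maximum(rss0[None, :] - num, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = num / (rss1 / df_resid)
    # degenerate columns: no group signal -> 0; perfect group fit -> inf
    F = np.where(num <= 1e-12 * np.maximum(rss0[None, :], 1e-30), 0.0, F)
    F[np.isnan(F)] = 0.0
    F[np.isinf(F)] = np.inf
    return F


def _stepdown_minp(
    p_obs: np.ndarray, p_perm: np.ndarray, n_perm: int
) -> np.ndarray:
    """Westfall-Young free step-down minP with monotonicity enforcement."""
    order = np.argsort(p_obs, kind="stable")
    Q = p_perm[order]
    # suffix minima over the ordered (ascending-p) contrasts
    m = np.minimum.accumulate(Q[::-1], axis=0)[::-1]
    cnt = (m <= p_obs[order][:, None] + 1e-12).sum(axis=1)
    corr = (1.0 + cnt) / (1.0 + n_perm)
    corr = np.maximum.accumulate(corr)
    corr = np.minimum(np.maximum(corr, p_obs[order]), 1.0)
    out = np.empty_like(corr)
    out[order] = corr
    return out


def _scan_engine(
    y: np.ndarray,
    X: np.ndarray,
    G: np.ndarray,
    config: ScanConfig,
    perm_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observed F, nominal p and corrected p for contrast indicators G.

    ``X`` includes the intercept; ``perm_idx`` is the shared (B x n)
    permutation index matrix.
    """
    n, p = X.shape
    df_resid = n - p - 1
    Q, _ = np.linalg.qr(X)

    def residualize(M: np.ndarray) -> np.ndarray:
        return M - Q @ (Q.T @ M)

    Gt = residualize(G)
    gnorm2 = np.einsum("ij,ij->j", Gt, Gt)
    gg = np.einsum("ij,ij->j", G, G)
    bad = gnorm2 < 1e-10 * np.maximum(gg, 1e-30)
    if bad.any():
        raise ValueError(
            f"rank-deficient design for contrast column(s) {np.flatnonzero(bad)}: "
            "group indicator collinear with covariates"
        )
    ytil = residualize(y)
    F_obs = _f_matrix(ytil[:, None], Gt, gnorm2, df_resid)[:, 0]

    source = ytil if config.permute == "freedman_lane" else y
    P = residualize(source[perm_idx.T])  # n x B
    F_perm = _f_matrix(P, Gt, gnorm2, df_resid)

    B = perm_idx.shape[0]
    if config.nominal_p == "analytic":
        p_obs = stats.f.sf(F_obs, 1, df_resid)
        p_perm = stats.f.sf(F_perm, 1, df_resid)
    else:
        p_obs = (1.0 + (F_perm >= F_obs[:, None] - 1e-12).sum(axis=1)) / (1.0 + B)
        # per-contrast rank of each permutation value within its own row
        ranks = np.empty_like(F_perm)
        for c in range(F_perm.shape[0]):
            row = F_perm[c]
            srt = np.sort(row)
            ranks[c] = len(row) - np.searchsorted(srt, row - 1e-12, side="left")
        p_perm = ranks / B
    p_corr = _stepdown_minp(p_obs, p_perm, B)
    return F_obs, p_obs, p_corr


def _permutation_indices(n: int, B: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.permuted(np.tile(np.arange(n), (B, 1)), axis=1)


def permutation_scan(
    contrasts: Sequence[Contrast],
    subjects: pd.DataFrame,
    config: ScanConfig,
    model_tag: str = "",
) -> ScanReport:
    """First-round scan of every contrast for one phenotype and model.

    Contrast families are scanned per network resolution; within a family
    all testable contrasts share one seeded permutation stream.
    """
    tag = model_tag or ("with_apoe" if "apoe4" in config.covariates else "no_apoe")
    cov = _encode_covariates(subjects, config.covariates)
    ok = subjects[config.phenotype].notna() & cov.notna().all(axis=1)
    sample = subjects.index[ok]
    results: list[ContrastResult] = []
    skipped: list[tuple[str, str]] = []

    by_res: dict[str, list[Contrast]] = {}
    for c in contrasts:
        by_res.setdefault(c.resolution_id, []).append(c)

    for res_id in sorted(by_res):
        # every contrast bipartitions the same genotyped universe
        universe = by_res[res_id][0].individuals_a | by_res[res_id][0].individuals_b
        res_sample = [i for i in sample if i in universe]
        family = []
        for c in by_res[res_id]:
            ids_a = [i for i in res_sample if i in c.individuals_a]
            ids_b = [i for i in res_sample if i in c.individuals_b]
            if len(ids_a) < config.min_group or len(ids_b) < config.min_group:
                skipped.append(
                    (
                        c.contrast_id,
                        f"min-group failure: {len(ids_a)} vs {len(ids_b)} "
                        f"analyzable (need {config.min_group})",
                    )
                )
                continue
            family.append((c, set(ids_a)))
        if not family:
            continue
        y = subjects.loc[res_sample, config.phenotype].to_numpy(float)
        X = np.column_stack(
            [np.ones(len(res_sample)), cov.loc[res_sample].to_numpy(float)]
        )
        G = np.column_stack(
            [[1.0 if i in in_a else 0.0 for i in res_sample] for _, in_a in family]
        )
        perm_idx = _permutation_indices(
            len(res_sample), config.n_permutations, config.seed
        )
        F_obs, p_obs, p_corr = _scan_engine(y, X, G, config, perm_idx)
        for k, (c, in_a) in enumerate(family):
            mask_a = G[:, k] == 1.0
            ya, yb = y[mask_a], y[~mask_a]
            results.append(
                ContrastResult(
                    contrast_id=c.contrast_id,
                    branch_ids=c.branch_ids,
                    resolution_id=c.resolution_id,
                    n_a=int(mask_a.sum()),
                    n_b=int((~mask_a).sum()),
                    mean_a=float(ya.mean()),
                    sd_a=float(ya.std(ddof=1)) if len(ya) > 1 else 0.0,
                    mean_b=float(yb.mean()),
                    sd_b=float(yb.std(ddof=1)) if len(yb) > 1 else 0.0,
                    f_statistic=float(F_obs[k]),
                    nominal_p=float(p_obs[k]),
                    corrected_p=float(p_corr[k]),
                    model_tag=tag,
                )
            )
    if not results and not skipped:
        skipped.append(("-", "no contrasts supplied"))
    return ScanReport(
        phenotype=config.phenotype,
        model_tag=tag,
        results=results,
        skipped=skipped,
        config=config,
        alpha=config.alpha,
    )


def scan_both_models(
    contrasts: Sequence[Contrast],
    subjects: pd.DataFrame,
    config: ScanConfig,
    base_covariates: tuple[str, ...] = ("age", "sex"),
    apoe_column: str = "apoe4",
) -> dict[str, ScanReport]:
    """Run the scan without and with the APOE e4 covariate, shared stream."""
    no_apoe = replace(config, covariates=base_covariates)
    with_apoe = replace(config, covariates=base_covariates + (apoe_column,))
    return {
        "no_apoe": permutation_scan(contrasts, subjects, no_apoe, "no_apoe"),
        "with_apoe": permutation_scan(contrasts, subjects, with_apoe, "with_apoe"),
    }


# ---------------------------------------------------------------------------
# second round: conditional scan within a significant clade
# ---------------------------------------------------------------------------

def second_round_scan(
    significant_contrast: Contrast,
    contrasts: Sequence[Contrast],
    subjects: pd.DataFrame,
    config: ScanConfig,
) -> ScanReport:
    """Conditional scan inside each side of a significant branch.

    Three-allele system: the other side of the significant cut is held
    constant; sub-branches subdivide the focal side into two alleles, and
    residual permutations shuffle only within the focal side.  Both sides
    are examined; sides that cannot be split under ``min_group`` are
    reported as unsplittable.
    """
    cov_all = _encode_covariates(subjects, config.covariates)
    ok = subjects[config.phenotype].notna() & cov_all.notna().all(axis=1)
    results: list[ContrastResult] = []
    skipped: list[tuple[str, str]] = []
    sig = significant_contrast
    for side_name, side_haps, side_inds in (
        ("A", sig.side_a, sig.individuals_a),
        ("B", sig.side_b, sig.individuals_b),
    ):
        sample = [i for i in subjects.index if i in side_inds and ok.loc[i]]
        # sub-contrasts: network cuts that split this side's haplotypes
        family: list[tuple[Contrast, frozenset[str]]] = []
        seen: set[frozenset[frozenset[str]]] = set()
        for c in contrasts:
            if c.resolution_id != sig.resolution_id or c.contrast_id == sig.contrast_id:
                continue
            part1 = c.side_a & side_haps
            part2 = side_haps - part1
            if not part1 or not part2:
                continue
            key = frozenset((frozenset(part1), frozenset(part2)))
            if key in seen:
                continue
            seen.add(key)
            sub_a = c.individuals_a & frozenset(sample)
            sub_b = frozenset(sample) - sub_a
            if len(sub_a) < config.min_group or len(sub_b) < config.min_group:
                skipped.append(
                    (
                        f"{sig.contrast_id}/{side_name}/{c.contrast_id}",
                        f"min-group failure within side {side_name}",
                    )
                )
                continue
            family.append((c, sub_a))
        if not family:
            if len(side_haps) <= 1:
                skipped.append(
                    (f"{sig.contrast_id}/{side_name}", "unsplittable: single haplotype")
                )
            elif not any(
                s[0].startswith(f"{sig.contrast_id}/{side_name}/") for s in skipped
            ):
                skipped.append(
                    (f"{sig.contrast_id}/{side_name}", "unsplittable under min_group")
                )
            continue
        y = subjects.loc[sample, config.phenotype].to_numpy(float)
        X = np.column_stack(
            [np.ones(len(sample)), cov_all.loc[sample].to_numpy(float)]
        )
        G = np.column_stack(
            [[1.0 if i in sub_a else 0.0 for i in sample] for _, sub_a in family]
        )
        perm_idx = _permutation_indices(
            len(sample), config.n_permutations, config.seed
        )
        F_obs, p_obs, p_corr = _scan_engine(y, X, G, config, perm_idx)
        for k, (c, sub_a) in enumerate(family):
            mask_a = G[:, k] == 1.0
            ya, yb = y[mask_a], y[~mask_a]
            results.append(
                ContrastResult(
                    contrast_id=f"{sig.contrast_id}/{side_name}/{c.contrast_id}",
                    branch_ids=c.branch_ids,
                    resolution_id=c.resolution_id,
                    n_a=int(mask_a.sum()),
                    n_b=int((~mask_a).sum()),
                    mean_a=float(ya.mean()),
                    sd_a=float(ya.std(ddof=1)) if len(ya) > 1 else 0.0,
                    mean_b=float(yb.mean()),
                    sd_b=float(yb.std(ddof=1)) if len(yb) > 1 else 0.0,
                    f_statistic=float(F_obs[k]),
                    nominal_p=float(p_obs[k]),
                    corrected_p=float(p_corr[k]),
                    model_tag=f"conditional_{side_name}",
                )
            )
    return ScanReport(
        phenotype=config.phenotype,
        model_tag="second_round",
        results=results,
        skipped=skipped,
        config=config,
        alpha=config.alpha,
    )


# ---------------------------------------------------------------------------
# single-variant ANCOVA screen
# ---------------------------------------------------------------------------

def bonferroni_per_test_alpha(n_tests: int, family_alpha: float = 0.05) -> float:
    """Per-test threshold family_alpha / n_tests, truncated to one
    significant figure (the convention used when the threshold is printed,
    e.g. 0.05/138 -> 0.0003)."""
    import math

    x = family_alpha / n_tests
    e = math.floor(math.log10(x))
    return math.floor(x / 10**e) * 10**e


def single_variant_scan(
    matrix: GenotypeMatrix,
    subjects: pd.DataFrame,
    phenotype: str,
    covariates: tuple[str, ...] = ("age", "sex", "apoe4_count"),
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-site ANCOVA: partial F for each SNP given the covariates.

    Monomorphic sites get an absent p with a reason.  The Bonferroni
    per-test alpha (family alpha / number of sites, truncated to the printed
    precision) is attached as ``df.attrs['per_test_alpha']``.
    """
    cov = _encode_covariates(subjects, covariates)
    common = [i for i in matrix.individual_ids if i in subjects.index]
    ok = subjects.loc[common, phenotype].notna() & cov.loc[common].notna().all(axis=1)
    sample = [i for i, o in zip(common, ok) if o]
    pos_of = {ind: k for k, ind in enumerate(matrix.individual_ids)}
    rows_idx = [pos_of[i] for i in sample]
    y = subjects.loc[sample, phenotype].to_numpy(float)
    C = cov.loc[sample].to_numpy(float)
    per_alpha = bonferroni_per_test_alpha(matrix.n_sites, family_alpha)
    out = []
    for j, v in enumerate(matrix.variants):
        g = (matrix.calls[rows_idx, j] == ALT).astype(float)
        if len(set(g)) < 2:
            out.append(
                {
                    "rcrs_position": v.rcrs_position,
                    "variant": v.label,
                    "n": len(sample),
                    "f_statistic": np.nan,
                    "p_value": np.nan,
                    "significant": False,
                    "note": "monomorphic in analysis sample",
                }
            )
            continue
        f, p = adjusted_group_test(y, g, C)
        out.append(
            {
                "rcrs_position": v.rcrs_position,
                "variant": v.label,
                "n": len(sample),
                "f_statistic": f,
                "p_value": p,
                "significant": bool(p < per_alpha),
                "note": "",
            }
        )
    df = pd.DataFrame(out)
    df.attrs["per_test_alpha"] = per_alpha
    df.attrs["family_alpha"] = family_alpha
    return df


def write_scan_table(
    reports: dict[str, ScanReport], path, top: int | None = None
) -> pd.DataFrame:
    """TSV mirroring the published layout: one row per contrast, nominal and
    corrected p under both APOE models, group/network means (SD)."""
    no_apoe = {r.contrast_id: r for r in reports["no_apoe"].results}
    with_apoe = {r.contrast_id: r for r in reports.get("with_apoe", reports["no_apoe"]).results}
    rows = []
    for cid, r in no_apoe.items():
        w = with_apoe.get(cid)
        rows.append(
            {
                "contrast": cid,
                "branches": ";".join(map(str, r.branch_ids)),
                "nominal_p_no_apoe": r.nominal_p,
                "corrected_p_no_apoe": r.corrected_p,
                "nominal_p_with_apoe": w.nominal_p if w else np.nan,
                "corrected_p_with_apoe": w.corrected_p if w else np.nan,
                "group_mean_sd": f"{r.mean_a:.6g} ({r.sd_a:.6g})",
                "network_mean_sd": f"{r.mean_b:.6g} ({r.sd_b:.6g})",
                "n_group": r.n_a,
                "n_network": r.n_b,
            }
        )
    df = pd.DataFrame(rows).sort_values("nominal_p_no_apoe")
    if top:
        df = df.head(top)
    df.to_csv(path, sep="\t", index=False)
    return df
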