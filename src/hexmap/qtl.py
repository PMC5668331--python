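"""Multi-allelic QTL analysis on IBD probabilities.

At every grid locus the block-corrected phenotype is regressed on the
IBD probabilities of the parental homologues with the additive model

    Y = mu + a2*X2 + ... + a6*X6 + a8*X8 + ... + a12*X12

(for a hexaploid; one homologue per parent — h1 and h7 — is the
reference class and omitted, because each parent always transmits
ploidy/2 homologues so the probabilities are linearly dependent within a
parent).  The locus p-value is the overall F test of this model against
the intercept-only model.  Genome-wide significance comes from a
permutation test: phenotypes are shuffled across individuals, the scan
re-run, and the 5th percentile of the minimum p-values over permutations
is the threshold.  Per-allele effects come from twelve separate simple
regressions Y = mu + a_i*X_i, estimating the effect of full presence
versus full absence of each homologue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dosage import HexmapError
from .ibd import IBDArray

_RANK_TOL = 1e-8


def _design_loci(
    grids: list[IBDArray], individuals: list[str]
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack the per-locus design tensors of several CLGs.

    Returns (X, loci): X has shape (n_loci, n_ind, 2*ploidy - 2) with the
    two reference homologues dropped; ``loci`` records CLG and position.
    """
    blocks = []
    recs = []
    for arr in grids:
        ploidy = arr.ploidy
        keep = [h for h in range(2 * ploidy) if h not in (0, ploidy)]
        sel = [arr.individual_ids.index(i) for i in individuals]
        blocks.append(arr.prob[:, sel][:, :, keep])
        for p in arr.positions:
            recs.append((arr.clg, float(p)))
    x = np.concatenate(blocks, axis=0)
    loci = pd.DataFrame(recs, columns=["CLG", "position_cM"])
    return x, loci


def _orthobases(x: np.ndarray) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Per-locus orthonormal bases of [1 | X] via SVD (rank-deficient
    loci keep their effective rank and are flagged)."""
    n_loci, n_ind, k = x.shape
    bases = []
    ranks = np.empty(n_loci, dtype=int)
    flagged = np.zeros(n_loci, dtype=bool)
    ones = np.ones((n_ind, 1))
    for l in range(n_loci):
        m = np.concatenate([ones, x[l]], axis=1)
        u, s, _ = np.linalg.svd(m, full_matrices=False)
        r = int((s > s[0] * _RANK_TOL).sum())
        bases.append(np.ascontiguousarray(u[:, :r]))
        ranks[l] = r
        flagged[l] = r < k + 1
    return bases, ranks, flagged


def _f_pvalues(
    bases: list[np.ndarray], ranks: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Overall model-vs-intercept F-test p-values per locus.

    ``y`` may be (n_ind,) or (n_ind, n_perm); returns matching shape
    (n_loci[, n_perm]).
    """
    y = np.asarray(y, dtype=float)
    squeeze = y.ndim == 1
    yy = y[:, None] if squeeze else y
    n = yy.shape[0]
    yc = yy - yy.mean(axis=0)
    tss = (yc**2).sum(axis=0)
    out = np.empty((len(bases), yy.shape[1]))
    for l, u in enumerate(bases):
        proj = u.T @ yy
        rss = (yy**2).sum(axis=0) - (proj**2).sum(axis=0)
        rss = np.maximum(rss, 0.0)
        q = ranks[l] - 1
        dfe = n - ranks[l]
        if q <= 0 or dfe <= 0 or (tss <= 0).all():
            out[l] = np.nan
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((tss - rss) / q) / (rss / dfe)
            out[l] = stats.f.sf(f, q, dfe)
        out[l, tss <= 0] = np.nan
    return out[:, 0] if squeeze else out


@dataclass
class QTLScan:
    """Genome-scan result: per-locus p-values plus permutation threshold."""

    table: pd.DataFrame
    threshold: float | None = None
    perm_minima: np.ndarray | None = None
    flagged_loci: np.ndarray | None = None

    def significant(self) -> pd.DataFrame:
        if self.threshold is None:
            raise HexmapError("no permutation threshold computed")
        return self.table[self.table["p"] <= self.threshold]


def _complete_cases(
    grids: list[IBDArray], phenotype: pd.Series
) -> tuple[list[str], np.ndarray]:
    pheno = phenotype.dropna()
    shared = [i for i in grids[0].individual_ids if i in set(pheno.index)]
    if len(shared) < 30:
        raise HexmapError(
            f"only {len(shared)} individuals shared between map and phenotype"
        )
    return shared, pheno.loc[shared].to_numpy(dtype=float)


def scan(grids: list[IBDArray], phenotype: pd.Series) -> QTLScan:
    """Additive multi-allelic genome scan over all gridded CLGs.

    ``phenotype`` is indexed by individual id; missing values are dropped
    (complete-case).  Rank-deficient loci (e.g. an unrepresented
    homologue) are fitted with their reduced column space and flagged.
    Degenerate (constant) phenotypes give NaN p-values.
    """
    shared, y = _complete_cases(grids, phenotype)
    x, loci = _design_loci(grids, shared)
    bases, ranks, flagged = _orthobases(x)
    p = _f_pvalues(bases, ranks, y)
    table = loci.copy()
    table["p"] = p
    with np.errstate(divide="ignore"):
        table["neg_log10_p"] = -np.log10(p)
    return QTLScan(table=table, flagged_loci=flagged)


def permutation_threshold(
    grids: list[IBDArray],
    phenotype: pd.Series,
    n_perm: int = 1000,
    percentile: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> tuple[float, np.ndarray]:
    """Genome-wide p-value threshold from phenotype permutations.

    Phenotypes are shuffled across individuals ``n_perm`` times, the full
    scan re-run and the minimum p recorded; the threshold is the
    ``percentile``-th percentile of the ordered minima.
    """
    if n_perm < 100:
        warnings.warn(
            f"{n_perm} permutations give an unstable percentile estimate",
            stacklevel=2,
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shared, y = _complete_cases(grids, phenotype)
    x, _ = _design_loci(grids, shared)
    bases, ranks, _ = _orthobases(x)
    perms = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    pvals = _f_pvalues(bases, ranks, perms)  # (n_loci, n_perm)
    minima = np.nanmin(pvals, axis=0)
    return float(np.percentile(np.sort(minima), percentile)), minima


def scan_with_threshold(
    grids: list[IBDArray],
    phenotype: pd.Series,
    n_perm: int = 1000,
    percentile: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> QTLScan:
    """Scan plus permutation threshold, sharing the design setup."""
    result = scan(grids, phenotype)
    thr, minima = permutation_threshold(
        grids, phenotype, n_perm=n_perm, percentile=percentile, seed=seed
    )
    result.threshold = thr
    result.perm_minima = minima
    result.table["significant"] = result.table["p"] <= thr
    return result


def per_allele_effects(
    arr: IBDArray, locus_index: int, phenotype: pd.Series
) -> pd.DataFrame:
    """Simple per-homologue regressions at one grid locus.

    For each homologue i fits Y = mu + a_i * X_i and reports the effect
    of full presence versus full absence with its p-value.  Homologues
    with (near-)constant probabilities have no estimable effect and are
    flagged with NaN.
    """
    pheno = phenotype.dropna()
    shared = [i for i in arr.individual_ids if i in set(pheno.index)]
    y = pheno.loc[shared].to_numpy(dtype=float)
    sel = [arr.individual_ids.index(i) for i in shared]
    rows = []
    for h, name in enumerate(arr.homologue_names):
        xh = arr.prob[locus_index, sel, h]
        sx = xh.std()
        if sx < 1e-9 or y.std() < 1e-12:
            rows.append((name, np.nan, np.nan))
            continue
        res = stats.linregress(xh, y)
        rows.append((name, float(res.slope), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["homologue", "effect", "p"])
    out.insert(0, "position_cM", arr.positions[locus_index])
    out.insert(0, "CLG", arr.clg)
    return out


def variance_explained(predictors: np.ndarray, phenotype: np.ndarray) -> float:
    """Coefficient of determination of the least-squares fit of the
    phenotype on the given predictor columns (markers or IBD columns)."""
    x = np.asarray(predictors, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(phenotype, dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(x).any(axis=1)
    x, y = x[ok], y[ok]
    m = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(m, y, rcond=None)
    resid = y - m @ beta
    tss = ((y - y.mean()) ** 2).sum()
    if tss <= 0:
        return np.nan
    return float(1.0 - (resid**2).sum() / tss)


def heritability(data: pd.DataFrame) -> float:
    """Broad-sense heritability from a trial x genotype fixed-effects
    ANOVA.

    ``data`` needs columns genotype, trial, value with >= 2 replicates
    per genotype.  H^2 = sigma2_G / (sigma2_G + sigma2_E) with
    sigma2_G = (MS_genotype - MS_error) / r (r = mean replicates per
    genotype), clipped to [0, 1].
    """
    d = data.dropna(subset=["value"])
    reps = d.groupby("genotype")["value"].size()
    if (reps < 2).all():
        raise HexmapError("heritability undefined with a single replicate")
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("value ~ C(trial) + C(genotype)", data=d).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    ms_g = anova.loc["C(genotype)", "sum_sq"] / anova.loc["C(genotype)", "df"]
    ms_e = anova.loc["Residual", "sum_sq"] / anova.loc["Residual", "df"]
    r = float(reps.mean())
    sigma_g = max(0.0, (ms_g - ms_e) / r)
    total = sigma_g + ms_e
    if total <= 0:
        return 1.0 if sigma_g > 0 else 0.0
    return float(np.clip(sigma_g / total, 0.0, 1.0))


def two_locus_interaction(
    x_a: np.ndarray, x_b: np.ndarray, phenotype: np.ndarray
) -> pd.DataFrame:
    """ANOVA of the interaction between two allele predictors (e.g. the
    closest simplex markers to two detected QTL): Y ~ A + B + A:B."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    d = pd.DataFrame({"A": x_a, "B": x_b, "value": phenotype}).dropna()
    model = smf.ols("value ~ A * B", data=d).fit()
    return sm.stats.anova_lm(model, typ=2)
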