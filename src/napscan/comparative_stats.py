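"""Cross-species statistics linking NAP investment to growth temperature.

Covers the comparative layer of the analysis: Spearman correlations
(exact permutation null at small n), a domain-wide correlation screen
against optimal growth temperature, ordinary least squares with mean and
new-observation intervals for predicting investment in an unseen species,
phylogenetic generalized least squares under Brownian motion, reciprocal
best-hit abundance correlations, and mean genes per transcription unit.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .io_formats import OperonMap, ValidationError
from .quantification import FractionalProteome

__all__ = [
    "OlsFit",
    "PglsFit",
    "ScreenResult",
    "spearman",
    "domain_ogt_screen",
    "ols_predict",
    "bm_covariance",
    "pgls_bm",
    "rbh_abundance_correlation",
    "genes_per_tu",
]


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


def spearman(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 9
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks. For n <= ``exact_max_n`` the p-value is the
    exact permutation probability of |rho| at least as large as observed;
    for larger n the usual t approximation is used. Constant input leaves
    rho undefined and raises.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = xa.size
    if n < 3:
        raise ValidationError("need n >= 3 for a Spearman correlation")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValidationError("Spearman rho undefined for a constant vector")
    rx = stats.rankdata(xa, method="average")
    ry = stats.rankdata(ya, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= exact_max_n:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt(float((rx_c**2).sum() * (ry_c**2).sum()))
        obs = abs(float(rx_c @ ry_c))
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(float(rx_c @ ry_c[list(perm)])) >= obs - 1e-9 * denom:
                count += 1
        return rho, count / total
    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return rho, min(1.0, p)


# ---------------------------------------------------------------------------
# Domain-vs-OGT correlation screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    """Per-feature correlation with OGT and the NAP aggregate's rank.

    ``table`` has one row per retained feature with columns ``rho``, ``p``
    and ``n``; ``nap_rank`` is 1 + the number of features whose rho exceeds
    the NAP aggregate's (rank 1 = strongest positive correlation).
    """

    table: pd.DataFrame
    nap_feature: str
    nap_rank: int | None


def domain_ogt_screen(
    abundances: pd.DataFrame,
    ogt: pd.Series,
    min_species: int = 10,
    nap_feature: str = "NAP",
) -> ScreenResult:
    """Correlate every feature's relative abundance with OGT across species.

    ``abundances`` is features x species (percent of proteome); features
    are retained only when quantified (positive abundance) in at least
    ``min_species`` species. The NAP aggregate is screened alongside every
    other feature and its rank by descending rho is reported.
    """
    species = [s for s in abundances.columns if s in ogt.index]
    rows = []
    for feat, vals in abundances.loc[:, species].iterrows():
        mask = vals.notna() & (vals > 0)
        if int(mask.sum()) < min_species:
            continue
        sub = vals[mask]
        rho, p = spearman(ogt.loc[sub.index].to_numpy(), sub.to_numpy())
        rows.append({"feature": feat, "rho": rho, "p": p, "n": int(mask.sum())})
    table = pd.DataFrame(rows, columns=["feature", "rho", "p", "n"]).set_index("feature")
    nap_rank = None
    if nap_feature in table.index:
        nap_rho = table.loc[nap_feature, "rho"]
        nap_rank = int((table["rho"] > nap_rho).sum()) + 1
    return ScreenResult(table=table, nap_feature=nap_feature, nap_rank=nap_rank)


# ---------------------------------------------------------------------------
# Ordinary least squares with intervals
# ---------------------------------------------------------------------------


@dataclass
class OlsFit:
    """Simple linear regression y = intercept + slope * x.

    ``predict`` returns the point estimate together with the 95% confidence
    interval of the mean response and the 95% prediction interval for a
    new observation at x0.
    """

    slope: float
    intercept: float
    residual_se: float
    n: int
    df: int
    x_mean: float
    sxx: float

    def predict(
        self, x0: float, level: float = 0.95
    ) -> tuple[float, tuple[float, float], tuple[float, float]]:
        point = self.intercept + self.slope * x0
        if self.df <= 0:
            raise ValidationError("intervals undefined with zero residual df")
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.df)
        lever = 1.0 / self.n + (x0 - self.x_mean) ** 2 / self.sxx
        half_mean = tcrit * self.residual_se * math.sqrt(lever)
        half_pred = tcrit * self.residual_se * math.sqrt(1.0 + lever)
        return (
            point,
            (point - half_mean, point + half_mean),
            (point - half_pred, point + half_pred),
        )


def ols_predict(x: Sequence[float], y: Sequence[float]) -> OlsFit:
    """Fit a simple linear regression by least squares."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    n = xa.size
    if n < 2:
        raise ValidationError("need n >= 2 to fit a line")
    sxx = float(((xa - xa.mean()) ** 2).sum())
    if sxx == 0:
        raise ValidationError("x is constant; slope undefined")
    slope = float(((xa - xa.mean()) * (ya - ya.mean())).sum() / sxx)
    intercept = float(ya.mean() - slope * xa.mean())
    resid = ya - intercept - slope * xa
    df = n - 2
    residual_se = math.sqrt(float((resid**2).sum()) / df) if df > 0 else 0.0
    return OlsFit(
        slope=slope,
        intercept=intercept,
        residual_se=residual_se,
        n=n,
        df=df,
        x_mean=float(xa.mean()),
        sxx=sxx,
    )


# ---------------------------------------------------------------------------
# Phylogenetic generalized least squares (Brownian motion)
# ---------------------------------------------------------------------------


def bm_covariance(tree: dendropy.Tree, taxa: Sequence[str]) -> np.ndarray:
    """Brownian-motion covariance: C_ij = shared root-to-tip path length.

    The diagonal holds root-to-tip depths; off-diagonals the depth of the
    most recent common ancestor of the two tips.
    """
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    missing = [t for t in taxa if t not in leaves]
    extra = sorted(set(leaves) - set(taxa))
    if missing or extra:
        raise ValidationError(
            f"tree/tip mismatch: missing from tree {missing}, unmatched tips {extra}"
        )
    depth = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        edge = node.edge.length or 0.0
        depth[node] = edge + (depth[parent] if parent is not None else 0.0)
    pdm = tree.phylogenetic_distance_matrix()
    n = len(taxa)
    C = np.empty((n, n))
    for i, ti in enumerate(taxa):
        C[i, i] = depth[leaves[ti]]
        for j in range(i + 1, n):
            tj = taxa[j]
            d = pdm.patristic_distance(leaves[ti].taxon, leaves[tj].taxon)
            C[i, j] = C[j, i] = 0.5 * (depth[leaves[ti]] + depth[leaves[tj]] - d)
    return C


@dataclass
class PglsFit:
    """GLS regression fit with Brownian-motion residual covariance."""

    slope: float
    intercept: float
    sigma2_bm: float
    loglik: float
    slope_se: float
    slope_p: float
    n: int
    bootstrap_ci: tuple[float, float] | None = None
    bootstrap_level: float = 0.95
    n_boot: int = 0
    covariance: np.ndarray | None = field(default=None, repr=False)


def pgls_bm(
    tree: dendropy.Tree,
    x: Mapping[str, float],
    y: Mapping[str, float],
    log_transform: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
    bootstrap: bool = False,
    level: float = 0.95,
) -> PglsFit:
    """Phylogenetic regression of y on x under a Brownian-motion model.

    beta = (X' C^-1 X)^-1 X' C^-1 y with C the shared-path-length matrix;
    sigma^2 is the maximum-likelihood rate. The slope p-value is a t-test
    on n - 2 df using the unbiased residual variance. With ``bootstrap``,
    residuals are re-simulated as multivariate normal with covariance
    sigma^2 C (parametric bootstrap, seeded) and a percentile CI for the
    slope is returned. ``log_transform`` takes natural logs of both
    variables; non-positive values are excluded with a warning.
    """
    if set(x) != set(y):
        raise ValidationError("x and y must cover the same species")
    taxa = sorted(x)
    if log_transform:
        bad = [t for t in taxa if x[t] <= 0 or y[t] <= 0]
        if bad:
            warnings.warn(f"excluding non-positive values before log transform: {bad}")
            taxa = [t for t in taxa if t not in set(bad)]
        tree = tree.clone(depth=1)
        tree.retain_taxa_with_labels(taxa)
    n = len(taxa)
    if n < 3:
        raise ValidationError("need >= 3 species for PGLS")
    xv = np.array([x[t] for t in taxa], dtype=float)
    yv = np.array([y[t] for t in taxa], dtype=float)
    if log_transform:
        xv = np.log(xv)
        yv = np.log(yv)
    C = bm_covariance(tree, taxa)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(f"singular BM covariance matrix: {exc}") from exc
    X = np.column_stack([np.ones(n), xv])
    # whiten with the Cholesky factor: solve L a = v
    Xw = solve_triangular(L, X, lower=True)
    yw = solve_triangular(L, yv, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    sigma2_ml = rss / n
    logdetC = 2.0 * float(np.log(np.diag(L)).sum())
    loglik = -0.5 * (n * math.log(2.0 * math.pi * sigma2_ml) + logdetC + n)
    sigma2_unbiased = rss / (n - 2)
    cov_beta = sigma2_unbiased * np.linalg.inv(XtX)
    slope_se = math.sqrt(cov_beta[1, 1])
    tstat = beta[1] / slope_se if slope_se > 0 else math.inf
    slope_p = 2.0 * stats.t.sf(abs(tstat), n - 2)
    ci = None
    if bootstrap and n_boot > 0:
        rng = np.random.default_rng(seed)
        fitted = X @ beta
        slopes = np.empty(n_boot)
        scale = math.sqrt(sigma2_ml)
        for b in range(n_boot):
            y_star = fitted + scale * (L @ rng.standard_normal(n))
            yw_star = solve_triangular(L, y_star, lower=True)
            beta_star = np.linalg.solve(XtX, Xw.T @ yw_star)
            slopes[b] = beta_star[1]
        lo, hi = np.quantile(slopes, [(1 - level) / 2.0, 0.5 + level / 2.0])
        ci = (float(lo), float(hi))
    return PglsFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        sigma2_bm=float(sigma2_ml),
        loglik=float(loglik),
        slope_se=float(slope_se),
        slope_p=float(min(1.0, slope_p)),
        n=n,
        bootstrap_ci=ci,
        bootstrap_level=level,
        n_boot=n_boot if bootstrap else 0,
        covariance=C,
    )


# ---------------------------------------------------------------------------
# Cross-species homolog abundance and operon structure
# ---------------------------------------------------------------------------


def rbh_abundance_correlation(
    fpA: FractionalProteome,
    fpB: FractionalProteome,
    pairs: Sequence[tuple[str, str]],
) -> tuple[float, int]:
    """Spearman correlation of log10 abundances over reciprocal-best-hit pairs.

    Pairs whose member is undetected in either species are dropped;
    returns (rho, number of usable pairs). Fewer than 3 usable pairs is an
    error.
    """
    xs, ys = [], []
    for ida, idb in pairs:
        fa, fb = fpA.fraction_of(ida), fpB.fraction_of(idb)
        if fa > 0 and fb > 0:
            xs.append(math.log10(fa))
            ys.append(math.log10(fb))
    if len(xs) < 3:
        raise ValidationError(f"only {len(xs)} usable RBH pairs; need >= 3")
    rho, _ = spearman(xs, ys, exact_max_n=0)
    return rho, len(xs)


def genes_per_tu(om: OperonMap) -> float:
    """Arithmetic mean number of genes per transcription unit."""
    if not om.operons:
        raise ValidationError("operon map is empty")
    sizes = [len(genes) for genes in om.operons.values()]
    return float(np.mean(sizes))
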