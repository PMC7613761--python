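"""Differential abundance between nucleoid and top sucrose-gradient fractions.

Replicated log2 intensities from the nucleoid fraction are compared
against the top (soluble) fraction as control. Missing values — typical
left-censored missingness of label-free proteomics — are imputed from a
down-shifted narrow normal per sample. Per-protein variances are
moderated with an empirical-Bayes prior fitted by moment-matching the
log sample variances, and positive log2 fold changes mean
nucleoid-enriched. A rank-sum test then asks whether DNA-binding-domain
proteins are collectively enriched.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq
from statsmodels.stats.multitest import multipletests

from .io_formats import ValidationError

__all__ = [
    "EnrichmentTable",
    "impute_missing",
    "moderated_test",
    "domain_class_enrichment",
    "matrices_from_tables",
]


def matrices_from_tables(nucleoid_tables, top_tables) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble aligned log2 intensity matrices from per-replicate tables.

    Rows are the union of proteins seen in any replicate of either
    fraction; absent values are NaN (to be imputed). Zero intensities are
    treated as missing, as log-undefined.
    """

    def _collect(tables) -> pd.DataFrame:
        cols = {}
        for qt in tables:
            vals = qt.data.set_index("protein_id")["raw_intensity"]
            vals = np.log2(vals[vals > 0])
            cols[qt.replicate_id] = vals
        return pd.DataFrame(cols)

    nuc = _collect(nucleoid_tables)
    top = _collect(top_tables)
    index = nuc.index.union(top.index)
    return nuc.reindex(index), top.reindex(index)


@dataclass
class EnrichmentTable:
    """Per-protein enrichment statistics plus the fitted prior.

    ``table`` columns: mean_log2_nucleoid, mean_log2_top, log2fc
    (nucleoid - top), t (moderated), p_value, q_value (Benjamini-Hochberg).
    ``d0``/``s0_sq`` are the prior degrees of freedom and prior variance
    (d0 may be ``inf`` when sample variances are exchangeable).
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float


def impute_missing(
    matrix: pd.DataFrame,
    shift: float = 1.8,
    width: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Impute missing log2 intensities from a down-shifted normal.

    For each sample (column) with observed mean m and standard deviation s,
    missing cells are drawn from Normal(m - shift * s, (width * s)^2) — the
    standard left-censored convention for label-free data. Deterministic
    given the seed. A sample with fewer than two observed values has no
    usable spread and raises.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = matrix.copy()
    for col in out.columns:
        vals = out[col]
        observed = vals.dropna()
        if len(observed) < 2:
            raise ValidationError(
                f"sample {col!r} has {len(observed)} observed values; need >= 2"
            )
        n_missing = int(vals.isna().sum())
        if n_missing == 0:
            continue
        m, s = float(observed.mean()), float(observed.std(ddof=1))
        draws = rng.normal(m - shift * s, width * s, size=n_missing)
        out.loc[vals.isna(), col] = draws
    return out


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match log sample variances to a scaled F marginal.

    Under the hierarchical model s_g^2 ~ s0^2 * F(df, d0), the log sample
    variance has variance psi'(df/2) + psi'(d0/2); solving for d0 and
    back-substituting gives s0^2. Returns (d0, s0_sq), with d0 = inf when
    the observed spread is no larger than the chi-square sampling noise.
    """
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return math.inf, float(np.mean(s2)) if s2.size else 0.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    evar = float(np.var(e, ddof=1))
    target = evar - float(special.polygamma(1, df / 2.0))
    if target <= 0:
        return math.inf, float(np.exp(np.mean(e)))
    lo, hi = 1e-2, 1e8
    if special.polygamma(1, lo / 2.0) < target:
        d0 = lo
    else:
        d0 = float(
            brentq(lambda d: float(special.polygamma(1, d / 2.0)) - target, lo, hi)
        )
    s0_sq = float(
        np.exp(np.mean(e) + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    )
    return d0, s0_sq


def moderated_test(
    nucleoid: pd.DataFrame,
    top: pd.DataFrame,
    d0: float | None = None,
    s0_sq: float | None = None,
) -> EnrichmentTable:
    """Moderated two-sample t-test of nucleoid versus top, per protein.

    Inputs are complete (imputed) log2 intensity matrices, proteins by
    replicates, sharing an index. The pooled per-protein variance s_g^2
    with d_g = n1 + n2 - 2 residual df is shrunk towards the fitted prior:

        s_tilde^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

    and the statistic log2fc / sqrt(s_tilde^2 (1/n1 + 1/n2)) is referred
    to t with d0 + d_g df. ``d0``/``s0_sq`` can be supplied to override
    the fit (d0 = 0 recovers the ordinary two-sample t exactly).
    Benjamini-Hochberg q-values are computed across proteins.
    """
    if not nucleoid.index.equals(top.index):
        raise ValidationError("nucleoid and top matrices must share an index")
    n1, n2 = nucleoid.shape[1], top.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("need >= 2 replicates per fraction")
    dg = n1 + n2 - 2
    if dg <= 0:
        raise ValidationError("zero residual degrees of freedom")
    a = nucleoid.to_numpy(dtype=float)
    b = top.to_numpy(dtype=float)
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("matrices must be imputed (no missing values)")
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / dg
    if d0 is None or s0_sq is None:
        fit_d0, fit_s0 = _fit_variance_prior(s2, dg)
        d0 = fit_d0 if d0 is None else d0
        s0_sq = fit_s0 if s0_sq is None else s0_sq
    if math.isinf(d0):
        s_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s_tilde = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    log2fc = mean_a - mean_b
    se = np.sqrt(s_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, log2fc / se, 0.0)
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    p = np.clip(p, 0.0, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "mean_log2_nucleoid": mean_a,
            "mean_log2_top": mean_b,
            "log2fc": log2fc,
            "t": tstat,
            "p_value": p,
            "q_value": q,
        },
        index=nucleoid.index,
    )
    return EnrichmentTable(table=table, d0=float(d0), s0_sq=float(s0_sq))


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def domain_class_enrichment(
    log2fc: pd.Series, members: set[str], exact_max: int = 10
) -> tuple[float, float]:
    """Rank-sum test: are DNA-binding-domain proteins collectively enriched?

    Compares the log2 fold changes of ``members`` against all other
    proteins. Returns (W, p) where W is the member rank sum (midranks for
    ties). When both groups have at most ``exact_max`` elements the
    two-sided p-value is computed by exhaustive enumeration of all
    C(n, n_members) label assignments; otherwise the normal approximation
    with tie correction (Mann-Whitney) is used.
    """
    member_mask = np.array([pid in members for pid in log2fc.index])
    x = log2fc.to_numpy(dtype=float)
    n_members = int(member_mask.sum())
    n_others = int((~member_mask).sum())
    if n_members == 0 or n_others == 0:
        raise ValidationError("both member and non-member groups must be non-empty")
    ranks = _midranks(x)
    w = float(ranks[member_mask].sum())
    if n_members <= exact_max and n_others <= exact_max:
        n = n_members + n_others
        total_le = total_ge = count = 0
        for combo in itertools.combinations(range(n), n_members):
            s = ranks[list(combo)].sum()
            count += 1
            if s <= w + 1e-9:
                total_le += 1
            if s >= w - 1e-9:
                total_ge += 1
        p = min(1.0, 2.0 * min(total_le, total_ge) / count)
        return w, p
    res = stats.mannwhitneyu(
        x[member_mask], x[~member_mask], alternative="two-sided", method="asymptotic"
    )
    return w, float(res.pvalue)
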