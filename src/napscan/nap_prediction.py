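"""Candidate NAP prediction from a quantified proteome.

A detected protein qualifies as a candidate NAP when it passes four
successive filters and is not a known NAP:

1. size: shorter than 290 amino acids (strict; 110% the size of TrmBL2,
   the largest protein with a characterized global chromatin role);
2. DNA binding: carries a known DNA-binding domain OR has a positive
   DNA-binding SVM score (strict OR);
3. abundance: a high-side abundance outlier relative to predicted
   transcription factors, judged by the generalized extreme studentized
   deviate (Rosner) test;
4. operon: encoded as a single-gene operon.

The generalized ESD test iteratively removes the most extreme studentized
deviate R_i and compares it to a t-based critical value lambda_i, allowing
up to k_max outliers without masking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import (
    DomainClassification,
    DomainHit,
    OperonMap,
    ValidationError,
    proteins_with_domain,
)
from .quantification import FractionalProteome, compute_isoelectric_point

__all__ = [
    "EsdResult",
    "CandidateNAP",
    "PredictionParams",
    "size_filter",
    "dna_binding_filter",
    "esd_outliers",
    "default_k_max",
    "abundance_outlier_filter",
    "single_operon_filter",
    "predict_candidates",
]


@dataclass
class EsdResult:
    """Internals of one generalized ESD (Rosner) run.

    ``stats`` holds one (R_i, lambda_i, removed_index) triple per step,
    i = 1..k_max; ``n_outliers`` is the largest i with R_i > lambda_i and
    ``flagged`` the original indices of the first ``n_outliers`` removals.
    """

    n: int
    k_max: int
    alpha: float
    stats: list[tuple[float, float, int | None]]
    n_outliers: int
    flagged: set[int]

    def __post_init__(self) -> None:
        assert len(self.stats) == self.k_max
        assert self.n_outliers <= self.k_max
        assert len(self.flagged) == self.n_outliers


def esd_outliers(values: Sequence[float], k_max: int, alpha: float = 0.05) -> EsdResult:
    """Generalized ESD test for up to ``k_max`` outliers in ``values``.

    At step i the studentized extreme deviate R_i = max_j |x_j - mean| / sd
    over the remaining points is compared with

        lambda_i = (n - i) * t / sqrt((n - i - 1 + t^2) * (n - i + 1)),

    where t is the 1 - alpha / (2 (n - i + 1)) quantile of Student's t with
    n - i - 1 degrees of freedom. The argmax is removed (ties broken by
    lowest index) and the declared outlier count is the largest i with
    R_i > lambda_i. If the remaining points become constant, remaining
    steps record R_i = 0.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite values in ESD input")
    n = len(x)
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    if n < k_max + 2:
        raise ValidationError(f"need n >= k_max + 2 (n={n}, k_max={k_max})")
    remaining = x.copy()
    orig_idx = np.arange(n)
    stats_list: list[tuple[float, float, int | None]] = []
    removed: list[int] = []
    degenerate = False
    for i in range(1, k_max + 1):
        m = n - i + 1  # points remaining before this removal
        p = 1.0 - alpha / (2.0 * m)
        df = m - 2  # = n - i - 1
        t = stats.t.ppf(p, df)
        lam = (m - 1) * t / math.sqrt((df + t * t) * m)
        if degenerate:
            stats_list.append((0.0, lam, None))
            continue
        mean = remaining.mean()
        sd = remaining.std(ddof=1)
        if sd <= 0:
            degenerate = True
            stats_list.append((0.0, lam, None))
            continue
        dev = np.abs(remaining - mean)
        j = int(np.argmax(dev))  # first maximum: lowest-index tie-break
        r = float(dev[j] / sd)
        stats_list.append((r, lam, int(orig_idx[j])))
        removed.append(int(orig_idx[j]))
        keep = np.ones(len(remaining), dtype=bool)
        keep[j] = False
        remaining = remaining[keep]
        orig_idx = orig_idx[keep]
    n_outliers = 0
    for i, (r, lam, _) in enumerate(stats_list, start=1):
        if r > lam:
            n_outliers = i
    return EsdResult(
        n=n,
        k_max=k_max,
        alpha=alpha,
        stats=stats_list,
        n_outliers=n_outliers,
        flagged=set(removed[:n_outliers]),
    )


def default_k_max(n: int) -> int:
    """Default outlier allowance: max(5, ceil(0.05 n))."""
    return max(5, math.ceil(0.05 * n))


def size_filter(length: int, max_len: int = 290) -> bool:
    """True iff the protein is strictly shorter than ``max_len`` residues."""
    if length < 1:
        raise ValidationError("length must be >= 1")
    return length < max_len


def dna_binding_filter(
    protein_id: str,
    hits: Sequence[DomainHit],
    cls: DomainClassification,
    scores: Mapping[str, float],
) -> bool:
    """True iff the protein has a DNA-binding domain hit OR an SVM score > 0."""
    if protein_id in proteins_with_domain(hits, cls.dna_binding_domains):
        return True
    score = scores.get(protein_id)
    return score is not None and score > 0.0


def abundance_outlier_filter(
    candidate_fractions: Mapping[str, float],
    tf_fractions: Sequence[float],
    k_max: int | None = None,
    alpha: float = 0.05,
    log_transform: bool = True,
    mode: str = "leave-one-in",
) -> set[str]:
    """Candidates that are ESD-flagged high-abundance outliers versus TFs.

    The reference population is the fractional abundances of predicted
    transcription factors. In ``leave-one-in`` mode (default) each
    candidate is appended to the TF vector on its own, so one extreme
    candidate cannot mask another; ``pooled`` appends all candidates at
    once. Only candidates flagged by the ESD test AND lying above the TF
    median are returned (high side only).
    """
    tf = np.asarray([v for v in tf_fractions], dtype=float)
    if tf.size == 0:
        raise ValidationError("transcription-factor abundance vector is empty")
    if log_transform:
        tf = tf[tf > 0]
        if tf.size == 0:
            raise ValidationError("no positive TF abundances to log-transform")
    tf_vals = np.log10(tf) if log_transform else tf
    tf_median = float(np.median(tf))

    def _flag(pool_candidates: list[tuple[str, float]]) -> set[str]:
        raw = [v for _, v in pool_candidates]
        if log_transform:
            usable = [(c, v) for c, v in pool_candidates if v > 0]
        else:
            usable = pool_candidates
        if not usable:
            return set()
        vals = np.array([v for _, v in usable], dtype=float)
        pooled = np.concatenate([tf_vals, np.log10(vals) if log_transform else vals])
        n = pooled.size
        k = default_k_max(n) if k_max is None else k_max
        if n < k + 2:
            raise ValidationError(f"pool too small for ESD (n={n}, k_max={k})")
        res = esd_outliers(pooled, k_max=k, alpha=alpha)
        out = set()
        for offset, (cand, value) in enumerate(usable):
            idx = tf_vals.size + offset
            if idx in res.flagged and value > tf_median:
                out.add(cand)
        return out

    items = list(candidate_fractions.items())
    if mode == "pooled":
        return _flag(items)
    if mode != "leave-one-in":
        raise ValueError(f"unknown mode {mode!r}")
    flagged: set[str] = set()
    for cand, value in items:
        flagged |= _flag([(cand, value)])
    return flagged


def single_operon_filter(protein_id: str, om: OperonMap) -> bool:
    """True iff the protein's operon contains exactly one gene.

    Proteins absent from the operon map fail conservatively, with a warning.
    """
    size = om.operon_size(protein_id)
    if size is None:
        warnings.warn(f"protein {protein_id!r} not assigned to any operon")
        return False
    return size == 1


@dataclass
class PredictionParams:
    max_len: int = 290
    alpha: float = 0.05
    k_max: int | None = None  # None -> max(5, ceil(0.05 n))
    log_transform: bool = True
    mode: str = "leave-one-in"
    relax_operon: bool = False


@dataclass
class CandidateNAP:
    protein_id: str
    length: int
    fraction: float  # percent of proteome
    passes: dict[str, bool]
    rank: int
    pI: float | None = None


def predict_candidates(
    fp: FractionalProteome,
    lengths: Mapping[str, int],
    hits: Sequence[DomainHit],
    cls: DomainClassification,
    scores: Mapping[str, float],
    om: OperonMap,
    known_nap_ids: set[str],
    params: PredictionParams | None = None,
    sequences: Mapping[str, str] | None = None,
) -> list[CandidateNAP]:
    """Run the four-filter candidate-NAP pipeline on one proteome.

    Known NAPs are excluded up front. The transcription-factor population
    for the abundance filter is every detected protein with a tf-domain
    hit that is not itself a known NAP. Candidates are ranked by
    fractional abundance, descending. ``params.relax_operon`` drops the
    single-gene-operon requirement.
    """
    params = params or PredictionParams()
    detected = [p for p in fp.fractions.index if fp.fractions[p] > 0]
    dna_binders = proteins_with_domain(hits, cls.dna_binding_domains)
    tf_ids = proteins_with_domain(hits, cls.tf_domains) - known_nap_ids
    tf_fractions = [fp.fraction_of(p) for p in sorted(tf_ids) if fp.fraction_of(p) > 0]

    survivors: list[str] = []
    passes: dict[str, dict[str, bool]] = {}
    for pid in detected:
        if pid in known_nap_ids:
            continue
        length = lengths.get(pid)
        if length is None:
            warnings.warn(f"no length for detected protein {pid!r}; skipped")
            continue
        ok_size = size_filter(length, params.max_len)
        ok_dna = pid in dna_binders or (scores.get(pid) is not None and scores[pid] > 0)
        passes[pid] = {"size": ok_size, "dna_binding": ok_dna}
        if ok_size and ok_dna:
            survivors.append(pid)

    outliers = abundance_outlier_filter(
        {p: fp.fraction_of(p) for p in survivors},
        tf_fractions,
        k_max=params.k_max,
        alpha=params.alpha,
        log_transform=params.log_transform,
        mode=params.mode,
    )

    finalists: list[str] = []
    for pid in survivors:
        ok_abund = pid in outliers
        ok_operon = True if params.relax_operon else single_operon_filter(pid, om)
        passes[pid]["abundance_outlier"] = ok_abund
        passes[pid]["single_operon"] = ok_operon
        if ok_abund and ok_operon:
            finalists.append(pid)

    finalists.sort(key=lambda p: (-fp.fraction_of(p), p))
    out = []
    for rank, pid in enumerate(finalists, start=1):
        pI = None
        if sequences is not None and pid in sequences:
            pI = compute_isoelectric_point(sequences[pid])
        out.append(
            CandidateNAP(
                protein_id=pid,
                length=int(lengths[pid]),
                fraction=fp.fraction_of(pid),
                passes=passes[pid],
                rank=rank,
                pI=pI,
            )
        )
    return out
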