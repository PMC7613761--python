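"""Fractional protein abundances and the aggregate NAP-investment metric.

A proteome's intensities are converted to fractional abundances (percent
of total intensity). NAP investment is the summed fractional abundance of
all detected NAPs; variants normalize by housekeeping references (tRNA
synthetases, RNA polymerase largest subunits) instead of the full
proteome, which controls for ploidy-like scaling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import (
    DomainClassification,
    DomainHit,
    QuantTable,
    SpeciesMeta,
    ValidationError,
    proteins_with_domain,
)

logger = logging.getLogger("napscan")

__all__ = [
    "FractionalProteome",
    "InvestmentRecord",
    "QcResult",
    "fractional_abundances",
    "qc_filter",
    "investment",
    "reference_normalize",
    "aggregate_by_class",
    "compute_isoelectric_point",
    "EMBOSS_PKA",
]


@dataclass
class FractionalProteome:
    """Per-protein fractional abundances for one sample, in percent.

    Invariant: fractions sum to 100 within 1e-6; every fraction >= 0.
    ``n_detected`` counts proteins with a positive intensity on the chosen
    basis (zero-intensity rows keep a 0% fraction but are not "detected").
    """

    species_id: str
    condition: str
    fractions: pd.Series  # protein_id -> percent
    n_detected: int
    intensity_basis: str  # "raw" or "lfq"

    def __post_init__(self) -> None:
        if (self.fractions < 0).any():
            raise ValidationError("negative fractional abundance")
        total = float(self.fractions.sum())
        if not math.isclose(total, 100.0, abs_tol=1e-6):
            raise ValidationError(f"fractions sum to {total}, expected 100")

    def fraction_of(self, protein_id: str) -> float:
        return float(self.fractions.get(protein_id, 0.0))


@dataclass
class InvestmentRecord:
    """Aggregate NAP investment for one species with its normalizations."""

    species_id: str
    nap_percent: float
    nap_percent_known_only: float
    normalized_by_trna_synth: float | None
    normalized_by_rnap: float | None
    coverage: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.nap_percent_known_only <= self.nap_percent <= 100.0 + 1e-9):
            raise ValidationError(
                "expected 0 <= known-only <= total NAP percent <= 100"
            )
        if not (0.0 < self.coverage <= 1.0):
            raise ValidationError("coverage must lie in (0, 1]")


@dataclass
class QcResult:
    passed: bool
    reasons: list[str]


def fractional_abundances(q: QuantTable, prefer_lfq: bool = True) -> FractionalProteome:
    """Normalize intensities to percent of total.

    With ``prefer_lfq`` and any LFQ value present, LFQ intensities form the
    basis and rows lacking an LFQ value are dropped from it (logged);
    otherwise raw intensities are used for all rows.
    """
    data = q.data
    use_lfq = prefer_lfq and data["lfq_intensity"].notna().any()
    if use_lfq:
        basis = data["lfq_intensity"]
        n_dropped = int(basis.isna().sum())
        if n_dropped:
            logger.info(
                "%s: dropping %d rows without LFQ intensity", q.species_id, n_dropped
            )
        kept = data.loc[basis.notna()]
        values = kept["lfq_intensity"]
    else:
        kept = data
        values = kept["raw_intensity"]
    total = float(values.sum())
    if total <= 0:
        raise ValidationError(f"{q.species_id}: total intensity is zero")
    fractions = pd.Series(
        (values / total * 100.0).values, index=kept["protein_id"].values
    )
    return FractionalProteome(
        species_id=q.species_id,
        condition=q.condition,
        fractions=fractions,
        n_detected=int((values > 0).sum()),
        intensity_basis="lfq" if use_lfq else "raw",
    )


def qc_filter(q: QuantTable, meta: SpeciesMeta) -> QcResult:
    """Sample-level QC: whole-cell extract, no size selection, >500 proteins."""
    reasons = []
    if not meta.whole_cell_extract:
        reasons.append("not derived from whole cell extract")
    if meta.size_selected:
        reasons.append("sample was size selected")
    if q.n_proteins <= 500:
        reasons.append(f"only {q.n_proteins} identified proteins (need > 500)")
    return QcResult(passed=not reasons, reasons=reasons)


def investment(fp: FractionalProteome, nap_ids: Iterable[str]) -> float:
    """Summed fractional abundance (percent) of the detected members of ``nap_ids``.

    Proteins in ``nap_ids`` absent from the proteome contribute 0: they are
    treated as not detected.
    """
    idx = fp.fractions.index.intersection(set(nap_ids))
    return float(fp.fractions.loc[idx].sum())


def reference_normalize(
    fp: FractionalProteome,
    nap_ids: Iterable[str],
    hits: Sequence[DomainHit],
    cls: DomainClassification,
    reference: str,
) -> float:
    """NAP investment divided by the investment in a housekeeping reference.

    ``reference`` is one of ``trna_synth``, ``rnap_rpb1``, ``rnap_rpb2``.
    """
    models = {
        "trna_synth": cls.trna_synth_models,
        "rnap_rpb1": cls.rnap_rpb1_models,
        "rnap_rpb2": cls.rnap_rpb2_models,
    }.get(reference)
    if models is None:
        raise ValueError(f"unknown reference {reference!r}")
    ref_ids = proteins_with_domain(hits, models)
    ref_sum = investment(fp, ref_ids)
    if ref_sum <= 0:
        raise ValidationError(
            f"{fp.species_id}: no detected protein carries a {reference} model"
        )
    return investment(fp, nap_ids) / ref_sum


def aggregate_by_class(
    fp: FractionalProteome,
    hits: Sequence[DomainHit],
    classes: Mapping[str, set[str]],
) -> dict[str, float]:
    """Aggregate fractional abundance by domain class.

    A protein matching several classes contributes its full fraction to
    each (no splitting); classes with no detected member map to 0.
    """
    out: dict[str, float] = {}
    for name, models in classes.items():
        out[name] = investment(fp, proteins_with_domain(hits, models))
    return out


# EMBOSS pKa values (iep); N-/C-terminus plus ionizable side chains.
EMBOSS_PKA: dict[str, float] = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def _net_charge(seq_counts: Mapping[str, int], ph: float, pka: Mapping[str, float]) -> float:
    # Henderson-Hasselbalch: positive groups protonated below their pKa,
    # negative groups deprotonated above; monotone decreasing in pH.
    def pos(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pk))

    def neg(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pk - ph))

    charge = pos(pka["Nterm"]) - neg(pka["Cterm"])
    for aa in ("K", "R", "H"):
        charge += seq_counts.get(aa, 0) * pos(pka[aa])
    for aa in ("D", "E", "C", "Y"):
        charge -= seq_counts.get(aa, 0) * neg(pka[aa])
    return charge


def compute_isoelectric_point(
    sequence: str, pka: Mapping[str, float] = EMBOSS_PKA, tol: float = 1e-6
) -> float:
    """Isoelectric point: the pH of zero net charge, found by bisection.

    Uses the EMBOSS pKa set by default (configurable). Raises on empty
    sequences or non-standard residues.
    """
    seq = sequence.upper()
    if not seq:
        raise ValidationError("empty sequence")
    bad = set(seq) - _STANDARD_AA
    if bad:
        raise ValidationError(f"non-standard residues: {sorted(bad)}")
    counts = {aa: seq.count(aa) for aa in _STANDARD_AA}
    lo, hi = 0.0, 14.0
    # net charge is monotone decreasing in pH
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if _net_charge(counts, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0
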