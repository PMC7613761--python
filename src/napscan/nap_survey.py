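"""Presence/absence of known NAP families across genomes and their co-occurrence.

Presence is called from HMM hit tables produced with model gathering
thresholds, so any hit to a family model counts as presence; an optional
stricter e-value cutoff can be layered on top. CC1 has no curated model
and is detected via jackhmmer, whose hits require an explicit e-value
threshold (default 1e-5).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import pandas as pd

from .io_formats import DomainClassification, DomainHit, ModelSource

__all__ = [
    "DEFAULT_NAP_FAMILY_MODELS",
    "call_presence",
    "cooccurrence",
    "naps_per_genome",
]

# Curated default model lists for the previously characterized NAP families.
# These are editable configuration, not a canonical registry: accession sets
# evolve with PFAM/TIGRFAM releases and jackhmmer-based families (CC1) have
# no stable accession at all.
DEFAULT_NAP_FAMILY_MODELS: dict[str, set[str]] = {
    "Alba": {"PF01918"},
    "CC1": {"CC1_jackhmmer"},
    "Cren7": {"PF11520"},
    "Histone": {"PF00808"},
    "HU": {"PF00216"},
    "MC1": {"PF02582"},
    "Sul7": {"PF01984"},
}


def _hit_qualifies(
    hit: DomainHit, evalue_cutoff: float | None, jackhmmer_cutoff: float
) -> bool:
    if hit.model_source is ModelSource.JACKHMMER:
        if hit.e_value > jackhmmer_cutoff:
            return False
    if evalue_cutoff is not None and hit.e_value > evalue_cutoff:
        return False
    return True


def call_presence(
    hits_by_genome: Mapping[str, Sequence[DomainHit]],
    cls: DomainClassification,
    evalue_cutoff: float | None = None,
    jackhmmer_cutoff: float = 1e-5,
    genomes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Genome x family boolean presence/absence matrix.

    A family is present in a genome iff at least one qualifying hit matches
    any of its models anywhere in the proteome (no synteny or copy-number
    logic). Genomes listed in ``genomes`` but missing from
    ``hits_by_genome`` yield an all-absent row with a warning.
    """
    families = sorted(cls.nap_family_models)
    genome_list = list(genomes) if genomes is not None else sorted(hits_by_genome)
    model_to_family = {
        m: fam for fam, models in cls.nap_family_models.items() for m in models
    }
    pa = pd.DataFrame(False, index=genome_list, columns=families)
    for genome in genome_list:
        hits = hits_by_genome.get(genome)
        if hits is None:
            warnings.warn(f"no hit table for genome {genome!r}; calling all families absent")
            continue
        for hit in hits:
            fam = model_to_family.get(hit.model_accession)
            if fam is None:
                continue
            if _hit_qualifies(hit, evalue_cutoff, jackhmmer_cutoff):
                pa.loc[genome, fam] = True
    return pa


def cooccurrence(pa: pd.DataFrame) -> pd.DataFrame:
    """Family x family counts of genomes containing both.

    Symmetric; the diagonal is per-family prevalence and every off-diagonal
    entry is bounded by the smaller of the two diagonals.
    """
    m = pa.astype(int)
    return m.T @ m


def naps_per_genome(pa: pd.DataFrame) -> pd.Series:
    """Number of distinct NAP families present in each genome."""
    return pa.sum(axis=1).astype(int)
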