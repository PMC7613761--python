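"""Synthetic archaeal proteomics studies with known ground truth.

Generates everything the pipeline consumes — a species tree, optimal
growth temperatures (OGT) evolving on it, per-species quantified
proteomes with long-tailed abundances, domain annotations, operon
structures, DNA-binding scores, and two-fraction nucleoid-enrichment
replicates — so every stage is testable without downloads.

The study-level signal is the linear relationship the comparative
analysis estimates: each species' summed NAP fractional abundance is
``beta0 + beta1 * OGT`` plus truncated Gaussian noise. Defaults are
calibrated so a 37 degC species carries ~0.75% NAP investment and the
hottest species ~5.4%, the regime the method is designed to detect.
Every proteome also contains decoy proteins that each fail exactly one
prediction filter, so the filters have discriminating work to do.

The generator is a pure function of (params, seed).
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .io_formats import (
    DomainClassification,
    DomainHit,
    ModelSource,
    OperonMap,
    QuantTable,
    SpeciesMeta,
    ValidationError,
    read_dnabinding_scores,
    read_hmm_tblout,
    read_operon_table,
    read_quant_table,
    read_species_meta,
    read_tree,
    write_dnabinding_scores,
    write_hmm_tblout,
    write_operon_table,
    write_quant_table,
    write_species_meta,
    write_tree,
)
from .nap_survey import DEFAULT_NAP_FAMILY_MODELS

__all__ = [
    "StudyParams",
    "StudyTruth",
    "SpeciesData",
    "EnrichmentSim",
    "Study",
    "build_default_classification",
    "simulate_tree",
    "simulate_ogt",
    "simulate_truth",
    "simulate_proteome",
    "simulate_enrichment",
    "simulate_study",
    "write_study",
    "load_study",
    "LoadedStudy",
]


@dataclass(frozen=True)
class StudyParams:
    """Generator defaults define the study conditions.

    ``beta0``/``beta1``/``noise_sd`` set the linear NAP-investment model
    (percent, percent per degC, percent); ``bm_rate`` is the Brownian OGT
    rate in degC^2 per unit branch on a unit-depth tree. Abundances are
    log10-normal with spread ``abundance_log_sd``; ``tf_log10_percent``
    centres the (deliberately tight) transcription-factor abundance
    background. Enrichment replicates shift true NAPs by
    ``enrichment_effect`` log2 units with replicate noise ``rep_sd`` and
    missing-at-low-abundance censoring at overall rate ``missing_rate``.
    """

    n_species: int = 19
    beta0: float = -2.0
    beta1: float = 0.075
    noise_sd: float = 0.6
    min_nap_percent: float = 0.01
    root_ogt: float = 70.0
    bm_rate: float = 3600.0
    ogt_bounds: tuple[float, float] = (24.0, 98.0)
    proteome_size: int = 2000
    abundance_log_sd: float = 1.2
    tf_fraction: float = 0.05
    tf_log10_percent: float = -2.7
    tf_log10_sd: float = 0.15
    enrichment_effect: float = 2.5
    rep_sd: float = 0.5
    n_reps: int = 3
    missing_rate: float = 0.1


# Shared domain-model pool for background proteins; shared across species so
# the domain screen has cross-species features to rank the NAP class against.
BACKGROUND_DOMAIN_POOL = [f"PFX{i:04d}" for i in range(1, 151)]

_DNA_BINDING_MODELS = {f"DBD{i:04d}" for i in range(1, 9)}
_TF_GO_MODELS = {f"TFGO{i:03d}" for i in range(1, 5)}


def build_default_classification() -> DomainClassification:
    """Domain classification matching the generator's synthetic annotation."""
    return DomainClassification(
        dna_binding_domains=set(_DNA_BINDING_MODELS),
        tf_domains=set(_DNA_BINDING_MODELS) | set(_TF_GO_MODELS),
        nap_family_models={k: set(v) for k, v in DEFAULT_NAP_FAMILY_MODELS.items()},
        trna_synth_models={"tRNA-synt_1", "tRNA-synt_2"},
        rnap_rpb1_models={"RNA_pol_Rpb1_3"},
        rnap_rpb2_models={"RNA_pol_Rpb2_3"},
    )


def simulate_tree(n_tips: int, seed: int = 0) -> dendropy.Tree:
    """Yule (pure-birth) tree scaled to unit depth, tips sp1..spN.

    Speciation waiting times are exponential with rate equal to the number
    of extant lineages; a final waiting interval after the last split
    keeps every terminal branch strictly positive (the tree is ultrametric
    with all tips at depth 1). Pure function of the seed.
    """
    if n_tips < 3:
        raise ValidationError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.is_rooted = True
    root = tree.seed_node
    t = 0.0
    # active lineages as (node, birth_time)
    left, right = dendropy.Node(), dendropy.Node()
    root.add_child(left)
    root.add_child(right)
    active: list[tuple[dendropy.Node, float]] = [(left, 0.0), (right, 0.0)]
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node, birth = active.pop(i)
        node.edge.length = t - birth
        a, b = dendropy.Node(), dendropy.Node()
        node.add_child(a)
        node.add_child(b)
        active.extend([(a, t), (b, t)])
    t += rng.exponential(1.0 / n_tips)
    for i, (node, birth) in enumerate(active, start=1):
        node.edge.length = t - birth
        node.taxon = taxon_namespace.new_taxon(label=f"sp{i}")
    root.edge.length = None
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / t
    return tree


def _reflect(v: float, lo: float, hi: float) -> float:
    period = 2.0 * (hi - lo)
    t = (v - lo) % period
    return lo + (t if t <= hi - lo else period - t)


def simulate_ogt(
    tree: dendropy.Tree,
    root_ogt: float = 70.0,
    bm_rate: float = 400.0,
    bounds: tuple[float, float] = (24.0, 98.0),
    seed: int = 0,
) -> dict[str, float]:
    """Brownian motion of OGT along the tree, reflected into ``bounds``."""
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    value: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            value[node] = _reflect(root_ogt, lo, hi)
            continue
        edge = node.edge.length or 0.0
        step = rng.normal(0.0, math.sqrt(bm_rate * edge)) if edge > 0 else 0.0
        value[node] = _reflect(value[parent] + step, lo, hi)
    return {leaf.taxon.label: value[leaf] for leaf in tree.leaf_node_iter()}


@dataclass
class StudyTruth:
    """Ground truth of one synthetic study."""

    params: StudyParams
    seed: int
    ogt: dict[str, float]
    true_nap_ids: dict[str, set[str]]
    known_nap_ids: dict[str, set[str]]
    true_nap_total_percent: dict[str, float]


def simulate_truth(
    n_species: int = 19, params: StudyParams | None = None, seed: int = 0
) -> tuple[dendropy.Tree, dict[str, float], dict[str, float]]:
    """Tree, per-species OGT and per-species total NAP percent.

    The total is ``beta0 + beta1 * OGT + N(0, noise_sd)`` truncated below
    at ``min_nap_percent``. This is the study-level signal; proteome
    generation distributes each total over 1-3 NAP proteins.
    """
    params = params or StudyParams()
    rng = np.random.default_rng(seed)
    tree_seed = int(rng.integers(2**31))
    ogt_seed = int(rng.integers(2**31))
    tree = simulate_tree(n_species, seed=tree_seed)
    ogt = simulate_ogt(
        tree, params.root_ogt, params.bm_rate, params.ogt_bounds, seed=ogt_seed
    )
    totals = {}
    for sp in sorted(ogt):
        raw = params.beta0 + params.beta1 * ogt[sp] + rng.normal(0.0, params.noise_sd)
        total = max(params.min_nap_percent, raw)
        if total >= 100.0:
            raise ValidationError(f"{sp}: NAP total percent {total} >= 100")
        totals[sp] = float(total)
    return tree, ogt, totals


@dataclass
class SpeciesData:
    """All generated tables for one species, plus its ground truth."""

    species_id: str
    ogt: float
    quant: QuantTable
    lengths: dict[str, int]
    hits: list[DomainHit]
    operons: OperonMap
    dnabind_scores: dict[str, float]
    known_nap_ids: set[str]
    true_nap_ids: set[str]
    nap_total_percent: float
    percents: pd.Series = field(repr=False)  # truth fractional abundances (%)
    meta: SpeciesMeta | None = None


def _hit(pid: str, model: str, rng: np.random.Generator) -> DomainHit:
    source = ModelSource.JACKHMMER if model == "CC1_jackhmmer" else ModelSource.PFAM
    return DomainHit(
        protein_id=pid,
        model_accession=model,
        model_source=source,
        e_value=float(10.0 ** rng.uniform(-30.0, -6.0)),
        bit_score=float(rng.uniform(50.0, 300.0)),
    )


def simulate_proteome(
    species_id: str,
    ogt: float,
    params: StudyParams | None = None,
    seed: int = 0,
    classification: DomainClassification | None = None,
    nap_total_percent: float | None = None,
) -> SpeciesData:
    """Generate one species' proteome-scale tables.

    True NAPs (1-3 small DNA-binding single-operon proteins; the count
    drops to 1 when the total is below 0.1% so no single NAP falls under
    the detectable range) sum exactly to the target percent. Half of the
    NAPs are labelled "known" and additionally hit a NAP family model.
    Four decoys each fail exactly one prediction filter; transcription
    factors form a tight low-abundance background for the outlier test;
    fixed-abundance tRNA-synthetase and RNA-polymerase proteins provide
    the housekeeping references.
    """
    params = params or StudyParams()
    cls = classification or build_default_classification()
    rng = np.random.default_rng(seed)
    if nap_total_percent is None:
        nap_total_percent = max(
            params.min_nap_percent,
            params.beta0 + params.beta1 * ogt + rng.normal(0.0, params.noise_sd),
        )
    if nap_total_percent >= 100.0:
        raise ValidationError(f"NAP target percent {nap_total_percent} >= 100")

    ids: list[str] = []
    percents: list[float] = []
    lengths: dict[str, int] = {}
    hits: list[DomainHit] = []
    scores: dict[str, float] = {}

    # --- true NAPs -------------------------------------------------------
    k = 1 if nap_total_percent < 0.1 else int(rng.integers(1, 4))
    shares = (
        np.array([1.0])
        if k == 1
        else 0.15 + (1.0 - 0.15 * k) * rng.dirichlet(np.ones(k))
    )
    true_nap_ids: set[str] = set()
    known_nap_ids: set[str] = set()
    family_names = sorted(DEFAULT_NAP_FAMILY_MODELS)
    dbd_list = sorted(_DNA_BINDING_MODELS)
    for i in range(k):
        pid = f"{species_id}_nap{i + 1}"
        true_nap_ids.add(pid)
        ids.append(pid)
        percents.append(float(nap_total_percent * shares[i]))
        lengths[pid] = int(rng.integers(60, 121))
        hits.append(_hit(pid, dbd_list[int(rng.integers(len(dbd_list)))], rng))
        scores[pid] = float(rng.normal(1.0, 0.5))
        if rng.random() < 0.5:
            known_nap_ids.add(pid)
            fam = family_names[int(rng.integers(len(family_names)))]
            model = sorted(DEFAULT_NAP_FAMILY_MODELS[fam])[0]
            hits.append(_hit(pid, model, rng))

    # --- decoys: each engineered to fail exactly one filter --------------
    def _add(pid: str, percent: float, length: int, dbd: bool, score: float) -> None:
        ids.append(pid)
        percents.append(percent)
        lengths[pid] = length
        scores[pid] = score
        if dbd:
            hits.append(_hit(pid, dbd_list[int(rng.integers(len(dbd_list)))], rng))

    jitter = lambda: float(10.0 ** rng.normal(0.0, 0.1))
    _add(f"{species_id}_decoy_operon", 0.3 * jitter(), 80, True, 1.0)
    _add(f"{species_id}_decoy_nodna", 0.3 * jitter(), 75, False, -1.5)
    _add(f"{species_id}_decoy_large", 0.3 * jitter(), 420, True, 1.0)
    _add(
        f"{species_id}_decoy_lowab",
        float(10.0 ** rng.normal(params.tf_log10_percent, params.tf_log10_sd)),
        90,
        True,
        1.0,
    )

    # --- transcription factors -------------------------------------------
    n_tf = round(params.tf_fraction * params.proteome_size)
    tfgo_list = sorted(_TF_GO_MODELS)
    for i in range(n_tf):
        pid = f"{species_id}_tf{i + 1:03d}"
        ids.append(pid)
        percents.append(
            float(10.0 ** rng.normal(params.tf_log10_percent, params.tf_log10_sd))
        )
        lengths[pid] = int(rng.integers(150, 401))
        hits.append(_hit(pid, tfgo_list[int(rng.integers(len(tfgo_list)))], rng))
        scores[pid] = float(rng.normal(-2.0, 0.5))

    # --- housekeeping references (fixed abundance across species) --------
    ref_specs = (
        [("aars", "tRNA-synt_1", 0.075)] * 10
        + [("aars", "tRNA-synt_2", 0.075)] * 10
        + [("rpb1", "RNA_pol_Rpb1_3", 0.25)] * 2
        + [("rpb2", "RNA_pol_Rpb2_3", 0.25)] * 2
    )
    for i, (stub, model, pct) in enumerate(ref_specs, 1):
        pid = f"{species_id}_{stub}{i:02d}"
        ids.append(pid)
        percents.append(pct)
        lengths[pid] = int(rng.integers(400, 1001))
        hits.append(_hit(pid, model, rng))
        scores[pid] = float(rng.normal(-2.0, 0.5))

    # --- background -------------------------------------------------------
    n_bg = params.proteome_size - len(ids)
    if n_bg <= 0:
        raise ValidationError("proteome_size too small for the fixed components")
    remaining = 100.0 - float(np.sum(percents))
    if remaining <= 0:
        raise ValidationError("fixed components exceed 100% of the proteome")
    weights = 10.0 ** rng.normal(0.0, params.abundance_log_sd, size=n_bg)
    bg_percents = weights / weights.sum() * remaining
    bg_ids = [f"{species_id}_bg{i + 1:04d}" for i in range(n_bg)]
    bg_lengths = np.clip(
        rng.lognormal(math.log(250.0), 0.45, size=n_bg), 50, 1500
    ).astype(int)
    n_domains = rng.integers(0, 3, size=n_bg)
    pool = BACKGROUND_DOMAIN_POOL
    for i, pid in enumerate(bg_ids):
        ids.append(pid)
        percents.append(float(bg_percents[i]))
        lengths[pid] = int(bg_lengths[i])
        scores[pid] = float(rng.normal(-2.0, 0.5))
        for j in range(int(n_domains[i])):
            hits.append(_hit(pid, pool[int(rng.integers(len(pool)))], rng))

    percent_series = pd.Series(percents, index=ids, dtype=float)

    # --- operons ----------------------------------------------------------
    operons: dict[str, list[str]] = {}
    op_i = 0

    def _new_operon(genes: list[str]) -> None:
        nonlocal op_i
        op_i += 1
        operons[f"{species_id}_op{op_i:04d}"] = genes

    singletons = sorted(true_nap_ids) + [
        f"{species_id}_decoy_nodna",
        f"{species_id}_decoy_large",
        f"{species_id}_decoy_lowab",
    ]
    for pid in singletons:
        _new_operon([pid])
    _new_operon([f"{species_id}_decoy_operon", bg_ids[0]])
    rest = [
        pid
        for pid in ids
        if pid not in set(singletons)
        and pid not in {f"{species_id}_decoy_operon", bg_ids[0]}
    ]
    pos = 0
    while pos < len(rest):
        size = int(rng.integers(1, 6))
        _new_operon(rest[pos : pos + size])
        pos += size

    # --- quantification table --------------------------------------------
    total_intensity = 10.0 ** rng.uniform(9.0, 10.0)
    lfq = percent_series.to_numpy() / 100.0 * total_intensity
    raw = lfq * 10.0 ** rng.normal(0.0, 0.05, size=len(lfq))
    quant = QuantTable(
        species_id=species_id,
        condition="whole_cell",
        replicate_id="rep1",
        data=pd.DataFrame(
            {
                "protein_id": ids,
                "raw_intensity": raw,
                "lfq_intensity": lfq,
                "aliases": "",
            }
        ),
    )
    meta = SpeciesMeta(
        species_id=species_id,
        ogt=float(ogt),
        predicted_proteome_size=int(round(params.proteome_size / 0.7)),
        ph=float(rng.uniform(5.0, 8.5)),
        doubling_time=float(10.0 ** rng.uniform(0.0, 1.5)),
        genome_size=float((3.5e6 - 1.5e4 * ogt) * 10.0 ** rng.normal(0.0, 0.11)),
        whole_cell_extract=True,
        size_selected=False,
    )
    return SpeciesData(
        species_id=species_id,
        ogt=float(ogt),
        quant=quant,
        lengths=lengths,
        hits=hits,
        operons=OperonMap(operons),
        dnabind_scores=scores,
        known_nap_ids=known_nap_ids,
        true_nap_ids=true_nap_ids,
        nap_total_percent=float(nap_total_percent),
        percents=percent_series,
        meta=meta,
    )


@dataclass
class EnrichmentSim:
    """Replicated two-fraction log2 intensities for one species."""

    species_id: str
    nucleoid: pd.DataFrame  # proteins x replicates, NaN = missing
    top: pd.DataFrame
    nucleoid_tables: list[QuantTable]
    top_tables: list[QuantTable]


def simulate_enrichment(
    sp: SpeciesData,
    true_nap_ids: set[str] | None = None,
    effect: float | None = None,
    n_reps: int | None = None,
    missing_rate: float | None = None,
    rep_sd: float = 0.5,
    seed: int = 0,
    params: StudyParams | None = None,
) -> EnrichmentSim:
    """Simulate nucleoid/top replicate intensities with censored missingness.

    Each cell is the protein's base log2 abundance plus N(effect, rep_sd^2)
    for true NAPs in the nucleoid fraction and N(0, rep_sd^2) otherwise.
    Cells go missing preferentially at low abundance, with overall rate
    ``missing_rate``.
    """
    params = params or StudyParams()
    true_nap_ids = sp.true_nap_ids if true_nap_ids is None else true_nap_ids
    effect = params.enrichment_effect if effect is None else effect
    n_reps = params.n_reps if n_reps is None else n_reps
    missing_rate = params.missing_rate if missing_rate is None else missing_rate
    if not math.isfinite(effect):
        raise ValidationError("enrichment effect must be finite")
    rng = np.random.default_rng(seed)
    base = np.log2(sp.percents.to_numpy() * 1e7)
    n = base.size
    is_nap = np.array([pid in true_nap_ids for pid in sp.percents.index])
    shift = np.where(is_nap, effect, 0.0)
    nuc = base[:, None] + shift[:, None] + rng.normal(0.0, rep_sd, size=(n, n_reps))
    top = base[:, None] + rng.normal(0.0, rep_sd, size=(n, n_reps))
    if missing_rate > 0:
        rank = base.argsort().argsort()  # 0 = lowest abundance
        frac = rank / max(1, n - 1)
        p_missing = np.clip(missing_rate * 2.0 * (1.0 - frac), 0.0, 1.0)
        for mat in (nuc, top):
            mask = rng.random(size=mat.shape) < p_missing[:, None]
            mat[mask] = np.nan
    cols = [f"rep{r + 1}" for r in range(n_reps)]
    nuc_df = pd.DataFrame(nuc, index=sp.percents.index, columns=cols)
    top_df = pd.DataFrame(top, index=sp.percents.index, columns=cols)

    def _tables(df: pd.DataFrame, condition: str) -> list[QuantTable]:
        out = []
        for col in df.columns:
            vals = df[col].dropna()
            intensity = np.exp2(vals.to_numpy())
            out.append(
                QuantTable(
                    species_id=sp.species_id,
                    condition=condition,
                    replicate_id=col,
                    data=pd.DataFrame(
                        {
                            "protein_id": vals.index,
                            "raw_intensity": intensity,
                            "lfq_intensity": intensity,
                            "aliases": "",
                        }
                    ),
                )
            )
        return out

    return EnrichmentSim(
        species_id=sp.species_id,
        nucleoid=nuc_df,
        top=top_df,
        nucleoid_tables=_tables(nuc_df, "nucleoid"),
        top_tables=_tables(top_df, "top"),
    )


@dataclass
class Study:
    """A complete synthetic study bundle."""

    params: StudyParams
    seed: int
    tree: dendropy.Tree
    classification: DomainClassification
    species: dict[str, SpeciesData]
    enrichment: dict[str, EnrichmentSim]
    truth: StudyTruth

    @property
    def meta(self) -> list[SpeciesMeta]:
        return [self.species[sp].meta for sp in sorted(self.species)]


def simulate_study(
    n_species: int = 19,
    params: StudyParams | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_enrichment_species: int = 2,
) -> Study:
    """Compose a full study: tree, OGTs, proteomes, enrichment, metadata.

    Nucleoid-enrichment replicates are generated for the first
    ``n_enrichment_species`` species (alphabetically), mirroring an assay
    run on a few species rather than the whole panel. With ``out_dir`` the
    bundle is also written to disk in the exact formats the readers parse.
    """
    params = params or StudyParams()
    if n_species != params.n_species:
        params = StudyParams(**{**asdict(params), "n_species": n_species})
    tree, ogt, totals = simulate_truth(n_species, params, seed)
    cls = build_default_classification()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(2 * n_species)
    species: dict[str, SpeciesData] = {}
    enrichment: dict[str, EnrichmentSim] = {}
    names = sorted(ogt)
    for i, sp in enumerate(names):
        sp_seed = int(np.random.default_rng(child_seeds[i]).integers(2**31))
        species[sp] = simulate_proteome(
            sp, ogt[sp], params, seed=sp_seed, classification=cls,
            nap_total_percent=totals[sp],
        )
    for i, sp in enumerate(names[:n_enrichment_species]):
        e_seed = int(
            np.random.default_rng(child_seeds[n_species + i]).integers(2**31)
        )
        enrichment[sp] = simulate_enrichment(species[sp], seed=e_seed, params=params,
                                             rep_sd=params.rep_sd)
    truth = StudyTruth(
        params=params,
        seed=seed,
        ogt=ogt,
        true_nap_ids={sp: species[sp].true_nap_ids for sp in names},
        known_nap_ids={sp: species[sp].known_nap_ids for sp in names},
        true_nap_total_percent=totals,
    )
    study = Study(
        params=params,
        seed=seed,
        tree=tree,
        classification=cls,
        species=species,
        enrichment=enrichment,
        truth=truth,
    )
    if out_dir is not None:
        write_study(study, out_dir)
    return study


# ---------------------------------------------------------------------------
# Disk layout
# ---------------------------------------------------------------------------


def write_study(study: Study, out_dir: str | Path) -> Path:
    """Write a study bundle to ``out_dir`` in the pipeline's input formats."""
    out = Path(out_dir)
    (out / "species").mkdir(parents=True, exist_ok=True)
    write_species_meta(study.meta, out / "meta.tsv")
    write_tree(study.tree, out / "tree.nwk")
    study.classification.to_json(out / "classification.json")
    truth_payload = {
        "seed": study.seed,
        "params": asdict(study.params),
        "species": {
            sp: {
                "ogt": study.truth.ogt[sp],
                "nap_total_percent": study.truth.true_nap_total_percent[sp],
                "true_nap_ids": sorted(study.truth.true_nap_ids[sp]),
                "known_nap_ids": sorted(study.truth.known_nap_ids[sp]),
            }
            for sp in sorted(study.species)
        },
    }
    (out / "truth.json").write_text(json.dumps(truth_payload, indent=1))
    for sp, data in study.species.items():
        base = out / "species"
        write_quant_table(data.quant, base / f"{sp}.quant.tsv")
        write_hmm_tblout(data.hits, base / f"{sp}.hits.tblout")
        write_operon_table(data.operons, base / f"{sp}.operons.tsv")
        write_dnabinding_scores(data.dnabind_scores, base / f"{sp}.dnabind.tsv")
        (base / f"{sp}.known_naps.txt").write_text(
            "\n".join(sorted(data.known_nap_ids)) + "\n"
        )
        pd.DataFrame(
            {"protein_id": list(data.lengths), "length": list(data.lengths.values())}
        ).to_csv(base / f"{sp}.lengths.tsv", sep="\t", index=False)
    if study.enrichment:
        (out / "enrichment").mkdir(exist_ok=True)
        for sp, sim in study.enrichment.items():
            for qt in sim.nucleoid_tables + sim.top_tables:
                write_quant_table(
                    qt, out / "enrichment" / f"{sp}.{qt.condition}.{qt.replicate_id}.tsv"
                )
    return out


@dataclass
class LoadedStudy:
    """A study bundle re-read from disk through the io layer."""

    meta: list[SpeciesMeta]
    tree: dendropy.Tree
    classification: DomainClassification
    quant: dict[str, QuantTable]
    hits: dict[str, list[DomainHit]]
    operons: dict[str, OperonMap]
    dnabind_scores: dict[str, dict[str, float]]
    lengths: dict[str, dict[str, int]]
    known_nap_ids: dict[str, set[str]]
    truth: dict | None
    enrichment_tables: dict[str, dict[str, list[QuantTable]]]


def load_study(study_dir: str | Path) -> LoadedStudy:
    """Load a study directory written by :func:`write_study`."""
    root = Path(study_dir)
    meta = read_species_meta(root / "meta.tsv")
    tree = read_tree(root / "tree.nwk")
    cls = DomainClassification.from_json(root / "classification.json")
    truth = None
    if (root / "truth.json").exists():
        truth = json.loads((root / "truth.json").read_text())
    quant, hits, operons, scores, lengths, known = {}, {}, {}, {}, {}, {}
    for m in meta:
        sp = m.species_id
        base = root / "species"
        quant[sp] = read_quant_table(base / f"{sp}.quant.tsv", sp, "whole_cell", "rep1")
        hits[sp] = _read_mixed_tblout(base / f"{sp}.hits.tblout")
        operons[sp] = read_operon_table(base / f"{sp}.operons.tsv")
        scores[sp] = read_dnabinding_scores(base / f"{sp}.dnabind.tsv")
        ldf = pd.read_csv(base / f"{sp}.lengths.tsv", sep="\t")
        lengths[sp] = dict(zip(ldf["protein_id"].astype(str), ldf["length"].astype(int)))
        known_path = base / f"{sp}.known_naps.txt"
        known[sp] = {
            line.strip()
            for line in known_path.read_text().splitlines()
            if line.strip()
        }
    enrichment: dict[str, dict[str, list[QuantTable]]] = {}
    enr_dir = root / "enrichment"
    if enr_dir.exists():
        for path in sorted(enr_dir.glob("*.tsv")):
            sp, condition, rep = path.stem.split(".")
            qt = read_quant_table(path, sp, condition, rep)
            enrichment.setdefault(sp, {}).setdefault(condition, []).append(qt)
    return LoadedStudy(
        meta=meta,
        tree=tree,
        classification=cls,
        quant=quant,
        hits=hits,
        operons=operons,
        dnabind_scores=scores,
        lengths=lengths,
        known_nap_ids=known,
        truth=truth,
        enrichment_tables=enrichment,
    )


def _read_mixed_tblout(path: Path) -> list[DomainHit]:
    # jackhmmer-sourced hits are recognizable by the CC1 model name; the
    # generator writes one combined tblout per species.
    hits = read_hmm_tblout(path, ModelSource.PFAM)
    out = []
    for h in hits:
        if h.model_accession == "CC1_jackhmmer":
            out.append(
                DomainHit(h.protein_id, h.model_accession, ModelSource.JACKHMMER,
                          h.e_value, h.bit_score)
            )
        else:
            out.append(h)
    return out
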