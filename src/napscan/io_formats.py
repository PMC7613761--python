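"""Readers and writers for the external formats the pipeline consumes.

Every downstream stage works on the in-memory types defined here:
MaxQuant-style protein quantification tables, hmmer3 ``--tblout`` domain
hit tables, operon membership tables, DNA-binding SVM score tables,
species metadata, and Newick species trees (held as :class:`dendropy.Tree`).

All identifiers are treated case-sensitively. Parsers validate on read and
raise :class:`FormatError` (malformed file) or :class:`ValidationError`
(well-formed file violating a domain invariant).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

logger = logging.getLogger("napscan")

__all__ = [
    "FormatError",
    "ValidationError",
    "QuantDialect",
    "QuantTable",
    "ModelSource",
    "DomainHit",
    "DomainClassification",
    "OperonMap",
    "SpeciesMeta",
    "read_quant_table",
    "write_quant_table",
    "read_hmm_tblout",
    "write_hmm_tblout",
    "read_operon_table",
    "write_operon_table",
    "read_species_meta",
    "write_species_meta",
    "read_tree",
    "write_tree",
    "read_fasta",
    "read_dnabinding_scores",
    "write_dnabinding_scores",
    "hits_by_protein",
    "proteins_with_domain",
]


class FormatError(ValueError):
    """A file does not follow the expected layout."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


# ---------------------------------------------------------------------------
# Quantification tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuantDialect:
    """Column names of a protein quantification table.

    Defaults match MaxQuant ``proteinGroups.txt`` conventions. Upstream
    tools vary (iBAQ vs Intensity, localized headers), so the mapping is
    configurable rather than hard-coded.
    """

    protein_col: str = "Protein IDs"
    intensity_col: str = "Intensity"
    lfq_col: str | None = "LFQ intensity"
    id_separator: str = ";"


DEFAULT_DIALECT = QuantDialect()


def _float_series(s: pd.Series) -> pd.Series:
    # python float() is correctly rounded; pandas' csv float path is not,
    # and the round-trip invariant demands full precision
    return s.map(
        lambda v: float("nan")
        if v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == ""
        else float(v)
    )


@dataclass
class QuantTable:
    """Per-sample protein intensities for one species/condition/replicate.

    ``data`` columns: ``protein_id`` (unique), ``raw_intensity`` (>= 0),
    ``lfq_intensity`` (>= 0 or NaN when the table carries no LFQ values),
    ``aliases`` (secondary ids of a protein group, ';'-joined, may be '').
    Zero-intensity rows are retained; negative intensities are rejected.
    """

    species_id: str
    condition: str
    replicate_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"protein_id", "raw_intensity", "lfq_intensity"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"QuantTable missing columns: {sorted(missing)}")
        if len(self.data) == 0:
            raise ValidationError("QuantTable must contain at least one row")
        if self.data["protein_id"].duplicated().any():
            dups = self.data.loc[self.data["protein_id"].duplicated(), "protein_id"]
            raise ValidationError(f"duplicate protein ids: {sorted(set(dups))[:5]}")
        if (self.data["raw_intensity"] < 0).any():
            raise ValidationError("negative raw intensity")
        lfq = self.data["lfq_intensity"]
        if (lfq.dropna() < 0).any():
            raise ValidationError("negative LFQ intensity")
        if "aliases" not in self.data.columns:
            self.data = self.data.assign(aliases="")

    @property
    def n_proteins(self) -> int:
        return len(self.data)


def read_quant_table(
    path: str | Path,
    species_id: str,
    condition: str = "",
    replicate_id: str = "",
    dialect: QuantDialect = DEFAULT_DIALECT,
) -> QuantTable:
    """Read a tab-separated MaxQuant-style protein quantification table.

    Protein-group rows listing multiple ids keep the first id as canonical
    and the remainder as aliases.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (dialect.protein_col, dialect.intensity_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    ids = df[dialect.protein_col].astype(str).str.split(dialect.id_separator)
    protein_id = ids.str[0].str.strip()
    aliases = ids.str[1:].map(lambda rest: ";".join(s.strip() for s in rest))
    try:
        raw = _float_series(df[dialect.intensity_col])
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric intensity: {exc}") from exc
    if dialect.lfq_col is not None and dialect.lfq_col in df.columns:
        try:
            lfq = _float_series(df[dialect.lfq_col])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric LFQ intensity: {exc}") from exc
    else:
        lfq = pd.Series(float("nan"), index=df.index)
    data = pd.DataFrame(
        {
            "protein_id": protein_id,
            "raw_intensity": raw.astype(float),
            "lfq_intensity": lfq.astype(float),
            "aliases": aliases,
        }
    )
    return QuantTable(species_id, condition, replicate_id, data)


def write_quant_table(
    qt: QuantTable, path: str | Path, dialect: QuantDialect = DEFAULT_DIALECT
) -> None:
    ids = [
        pid if not al else dialect.id_separator.join([pid, *al.split(";")])
        for pid, al in zip(qt.data["protein_id"], qt.data["aliases"])
    ]
    out = pd.DataFrame({dialect.protein_col: ids})
    out[dialect.intensity_col] = qt.data["raw_intensity"].map(repr).values
    if dialect.lfq_col is not None:
        out[dialect.lfq_col] = [
            "" if pd.isna(v) else repr(v) for v in qt.data["lfq_intensity"]
        ]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# hmmer3 --tblout domain hits
# ---------------------------------------------------------------------------


class ModelSource(str, Enum):
    PFAM = "PFAM"
    TIGR = "TIGR"
    JACKHMMER = "JACKHMMER"


@dataclass(frozen=True)
class DomainHit:
    """One full-sequence hit of an HMM model against a protein."""

    protein_id: str
    model_accession: str
    model_source: ModelSource
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if not self.e_value > 0:
            raise ValidationError(
                f"e-value must be > 0 (got {self.e_value} for {self.protein_id})"
            )


# hmmer3 --tblout: 18 whitespace-delimited fields, then free-text description
_TBLOUT_FIELDS = 18


def read_hmm_tblout(path: str | Path, source: ModelSource) -> list[DomainHit]:
    """Parse an hmmsearch/jackhmmer ``--tblout`` file.

    Target name -> protein_id; query accession (or query name when the
    accession field is '-') -> model_accession; full-sequence e-value and
    bit score are captured. The trailing description may contain spaces.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split(None, _TBLOUT_FIELDS)
            if len(parts) < _TBLOUT_FIELDS:
                raise FormatError(
                    f"{path}:{lineno}: expected >= {_TBLOUT_FIELDS} fields, got {len(parts)}"
                )
            target_name, _target_acc, query_name, query_acc = parts[:4]
            model = query_name if query_acc == "-" else query_acc
            try:
                e_value = float(parts[4])
                score = float(parts[5])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad numeric field: {exc}") from exc
            hits.append(DomainHit(target_name, model, source, e_value, score))
    return hits


def write_hmm_tblout(hits: Sequence[DomainHit], path: str | Path) -> None:
    """Write hits in a minimal hmmer3 ``--tblout``-compatible layout."""
    with open(path, "w") as fh:
        fh.write("# target name  accession  query name  accession  E-value  score"
                 "  bias  E-value  score  bias  exp  reg  clu  ov  env  dom  rep  inc"
                 "  description of target\n")
        for h in hits:
            rest = "0.0 " + " ".join(["0.0"] * 2 + ["1.0"] + ["1"] * 7)
            fh.write(
                f"{h.protein_id} - {h.model_accession} {h.model_accession} "
                f"{h.e_value!r} {h.bit_score!r} {rest} synthetic hit\n"
            )


def hits_by_protein(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    out: dict[str, list[DomainHit]] = {}
    for h in hits:
        out.setdefault(h.protein_id, []).append(h)
    return out


def proteins_with_domain(hits: Iterable[DomainHit], models: set[str]) -> set[str]:
    """Protein ids with at least one hit to any model in ``models``."""
    return {h.protein_id for h in hits if h.model_accession in models}


# ---------------------------------------------------------------------------
# Curated domain classification
# ---------------------------------------------------------------------------


@dataclass
class DomainClassification:
    """Curated domain sets driving annotation-dependent steps.

    ``tf_domains`` is the transcription-factor set: the DNA-binding domain
    list plus the domains of the sequence-specific DNA-binding GO category
    (pfam2go GO:0003700). ``nap_family_models`` maps each previously
    characterized NAP family (Alba, CC1, Cren7, Histone, HU, MC1, Sul7) to
    its model accessions. The reference sets back the housekeeping
    normalizations (tRNA synthetases; RNA polymerase largest subunits).
    """

    dna_binding_domains: set[str]
    tf_domains: set[str]
    nap_family_models: dict[str, set[str]]
    trna_synth_models: set[str]
    rnap_rpb1_models: set[str]
    rnap_rpb2_models: set[str]

    def __post_init__(self) -> None:
        for name, models in [
            ("dna_binding_domains", self.dna_binding_domains),
            ("tf_domains", self.tf_domains),
            ("trna_synth_models", self.trna_synth_models),
            ("rnap_rpb1_models", self.rnap_rpb1_models),
            ("rnap_rpb2_models", self.rnap_rpb2_models),
        ]:
            if not models:
                raise ValidationError(f"{name} must be non-empty")
        for fam, models in self.nap_family_models.items():
            if not models:
                raise ValidationError(f"NAP family {fam!r} has no models")

    @property
    def rnap_models(self) -> set[str]:
        return self.rnap_rpb1_models | self.rnap_rpb2_models

    @property
    def all_nap_models(self) -> set[str]:
        out: set[str] = set()
        for models in self.nap_family_models.values():
            out |= models
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dna_binding_domains": sorted(self.dna_binding_domains),
            "tf_domains": sorted(self.tf_domains),
            "nap_family_models": {k: sorted(v) for k, v in self.nap_family_models.items()},
            "trna_synth_models": sorted(self.trna_synth_models),
            "rnap_rpb1_models": sorted(self.rnap_rpb1_models),
            "rnap_rpb2_models": sorted(self.rnap_rpb2_models),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DomainClassification":
        payload = json.loads(Path(path).read_text())
        return cls(
            dna_binding_domains=set(payload["dna_binding_domains"]),
            tf_domains=set(payload["tf_domains"]),
            nap_family_models={k: set(v) for k, v in payload["nap_family_models"].items()},
            trna_synth_models=set(payload["trna_synth_models"]),
            rnap_rpb1_models=set(payload["rnap_rpb1_models"]),
            rnap_rpb2_models=set(payload["rnap_rpb2_models"]),
        )


# ---------------------------------------------------------------------------
# Operon membership
# ---------------------------------------------------------------------------


@dataclass
class OperonMap:
    """Transcription-unit membership from an external operon predictor."""

    operons: dict[str, list[str]]
    index: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            index: dict[str, str] = {}
            for op_id, genes in self.operons.items():
                if not genes:
                    raise ValidationError(f"operon {op_id!r} is empty")
                for g in genes:
                    if g in index:
                        raise ValidationError(
                            f"protein {g!r} assigned to operons {index[g]!r} and {op_id!r}"
                        )
                    index[g] = op_id
            self.index = index

    def operon_size(self, protein_id: str) -> int | None:
        op = self.index.get(protein_id)
        return None if op is None else len(self.operons[op])


def read_operon_table(path: str | Path) -> OperonMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("operon_id", "position", "protein_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df = df.assign(position=pd.to_numeric(df["position"]))
    operons: dict[str, list[str]] = {}
    for op_id, group in df.sort_values("position").groupby("operon_id", sort=True):
        operons[str(op_id)] = list(group["protein_id"])
    return OperonMap(operons)


def write_operon_table(om: OperonMap, path: str | Path) -> None:
    rows = [
        {"operon_id": op_id, "position": pos, "protein_id": pid}
        for op_id, genes in om.operons.items()
        for pos, pid in enumerate(genes, start=1)
    ]
    pd.DataFrame(rows, columns=["operon_id", "position", "protein_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Species metadata
# ---------------------------------------------------------------------------


@dataclass
class SpeciesMeta:
    species_id: str
    ogt: float | None
    predicted_proteome_size: int
    ph: float | None = None
    doubling_time: float | None = None
    genome_size: float | None = None
    whole_cell_extract: bool = True
    size_selected: bool = False

    def __post_init__(self) -> None:
        if self.ogt is not None and not (0.0 <= self.ogt <= 130.0):
            raise ValidationError(
                f"{self.species_id}: OGT {self.ogt} outside [0, 130] degC"
            )
        if not self.predicted_proteome_size > 0:
            raise ValidationError(
                f"{self.species_id}: predicted_proteome_size must be > 0"
            )


_META_COLS = [
    "species_id",
    "ogt",
    "ph",
    "doubling_time",
    "genome_size",
    "predicted_proteome_size",
    "whole_cell_extract",
    "size_selected",
]


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == "":
        return None
    try:
        return float(v)
    except ValueError as exc:
        raise ValidationError(f"non-numeric value {v!r}") from exc


def read_species_meta(path: str | Path) -> list[SpeciesMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"species_id", "ogt", "predicted_proteome_size"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SpeciesMeta(
                species_id=str(row["species_id"]),
                ogt=_opt_float(row["ogt"]),
                ph=_opt_float(row.get("ph")),
                doubling_time=_opt_float(row.get("doubling_time")),
                genome_size=_opt_float(row.get("genome_size")),
                predicted_proteome_size=int(float(row["predicted_proteome_size"])),
                whole_cell_extract=str(row.get("whole_cell_extract", "True")) == "True",
                size_selected=str(row.get("size_selected", "False")) == "True",
            )
        )
    return out


def write_species_meta(metas: Sequence[SpeciesMeta], path: str | Path) -> None:
    rows = []
    for m in metas:
        rows.append(
            {
                "species_id": m.species_id,
                "ogt": "" if m.ogt is None else repr(m.ogt),
                "ph": "" if m.ph is None else repr(m.ph),
                "doubling_time": "" if m.doubling_time is None else repr(m.doubling_time),
                "genome_size": "" if m.genome_size is None else repr(m.genome_size),
                "predicted_proteome_size": m.predicted_proteome_size,
                "whole_cell_extract": str(m.whole_cell_extract),
                "size_selected": str(m.size_selected),
            }
        )
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees and score tables
# ---------------------------------------------------------------------------


def validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate tip labels in tree")
    n_zero = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            continue
        if edge.length < 0:
            raise ValidationError("negative branch length in tree")
        if edge.length == 0 and edge.head_node.parent_node is not None:
            n_zero += 1
    if n_zero:
        logger.info("tree contains %d zero-length branches", n_zero)
    return tree


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree; polytomies and zero-length branches allowed."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise FormatError(f"{path}: unparseable Newick: {exc}") from exc
    tree.is_rooted = True
    return validate_tree(tree)


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by record id (first token of the header)."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in out:
            raise ValidationError(f"{path}: duplicate sequence id {record.id!r}")
        out[record.id] = str(record.seq)
    return out


def read_dnabinding_scores(path: str | Path) -> dict[str, float]:
    """Read a DNA-binding SVM score table (scores may be any reals)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_id", "score"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    try:
        scores = _float_series(df["score"])
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-numeric score: {exc}") from exc
    return dict(zip(df["protein_id"].astype(str), scores.astype(float)))


def write_dnabinding_scores(scores: Mapping[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"protein_id": list(scores), "score": [repr(v) for v in scores.values()]}
    ).to_csv(path, sep="\t", index=False)
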