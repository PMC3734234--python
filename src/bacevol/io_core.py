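"""Readers/writers and external-feature ingestion.

Coordinates are 0-based half-open everywhere in this package. FASTA headers
carry optional positional metadata as whitespace-separated fields after the
gene ID: ``>geneX <start> <end> <strand>``; records without them default to
``start=0, end=len(cds), strand='+'``.

Missing feature-table cells are written as empty strings and read back as
NaN; they are never coerced to zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetics import translate_cds

logger = logging.getLogger("bacevol")

#: Feature-table columns: response (ER) plus the 16 per-gene features.
FEATURE_COLUMNS: tuple[str, ...] = (
    "ER", "CAI", "EL", "ESS", "PPA", "MFS", "HS", "AS", "LEN", "RSB", "TMH",
    "SLC", "SLM", "SLP", "SLO", "SLE", "SLW",
)

#: PSORTb-style localization labels per Gram stain. Gram-negative bacteria
#: have five predictable compartments; Gram-positive ones have four (no
#: periplasm or outer membrane, but a cell wall).
LOCALIZATION_COLUMNS: dict[str, dict[str, str]] = {
    "negative": {
        "cytoplasmic": "SLC",
        "cytoplasmic membrane": "SLM",
        "periplasmic": "SLP",
        "outer membrane": "SLO",
        "extracellular": "SLE",
    },
    "positive": {
        "cytoplasmic": "SLC",
        "cytoplasmic membrane": "SLM",
        "cell wall": "SLW",
        "extracellular": "SLE",
    },
}


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene: in-frame CDS plus genomic context."""

    gene_id: str
    cds: str
    protein: str
    start: int = 0
    end: int = 0
    strand: str = "+"
    is_ribosomal: bool = False
    valid: bool = True
    problems: tuple[str, ...] = ()

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def flagged(self, *problems: str) -> "GeneRecord":
        return replace(self, valid=False, problems=self.problems + problems)


@dataclass
class SpeciesConfig:
    """Per-species inputs and the pipeline's tunable thresholds.

    Defaults follow the analysis this package implements: 150-nt folding
    windows slid by 10 nt, a 0.4 association-score cutoff, ln(Ka + 0.001)
    for the evolutionary rate, ortholog filters of >30 aa, 80% coverage and
    30% identity, and a 1.64-SD (two-sided 90%) reference box for CUS.
    """

    species_id: str = "species"
    cds_fasta: str | None = None
    partner_fasta: str | None = None
    ribosomal_ids: tuple[str, ...] = ()
    ori_position: int = 0
    ter_position: int = 1
    genome_length: int = 0
    gram: str = "negative"
    window: int = 150
    step: int = 10
    ppa_cutoff: float = 0.4
    ka_constant: float = 0.001
    min_protein_aa: int = 30
    min_coverage: float = 0.80
    min_identity: float = 0.30
    z_quantile: float = 1.64
    log_base: float = math.e

    def __post_init__(self) -> None:
        for name in ("window", "step", "ppa_cutoff", "ka_constant",
                     "min_protein_aa", "min_coverage", "min_identity",
                     "z_quantile"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name!r} must be positive")
        if self.ori_position == self.ter_position:
            raise ValueError("ori_position and ter_position must differ")
        if self.gram not in ("positive", "negative"):
            raise ValueError("gram must be 'positive' or 'negative'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpeciesConfig":
        import dataclasses

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        data = {k: v for k, v in data.items() if k in known}
        if "ribosomal_ids" in data:
            data["ribosomal_ids"] = tuple(data["ribosomal_ids"])
        return cls(**data)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _record_from_seq(seq_record: SeqRecord) -> GeneRecord:
    cds = str(seq_record.seq).upper()
    fields = seq_record.description.split()
    start, end, strand = 0, len(cds), "+"
    if len(fields) >= 4 and fields[3] in "+-":
        try:
            start, end, strand = int(fields[1]), int(fields[2]), fields[3]
        except ValueError:
            pass
    protein = translate_cds(cds)
    rec = GeneRecord(seq_record.id, cds, protein, start, end, strand)
    if len(cds) == 0 or len(cds) % 3 != 0:
        rec = rec.flagged("frame")
    stop_at = protein.find("*")
    if 0 <= stop_at < len(protein) - 1:
        # internal stop: keep the truncated translation, flag the record
        rec = replace(rec, protein=protein[:stop_at]).flagged("internal_stop")
    elif protein.endswith("*"):
        rec = replace(rec, protein=protein[:-1])
    return rec


def read_fasta(path: str | Path) -> list[GeneRecord]:
    """Read a CDS FASTA into GeneRecords (file order preserved).

    Records failing the frame or translation checks are returned flagged
    (``valid=False``) rather than dropped. Duplicate IDs and empty files
    raise ``ValueError``.
    """
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for seq_record in SeqIO.parse(str(path), "fasta"):
        if seq_record.id in seen:
            raise ValueError(f"duplicate gene ID in {path}: {seq_record.id!r}")
        seen.add(seq_record.id)
        records.append(_record_from_seq(seq_record))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GeneRecord], path: str | Path,
                width: int = 60) -> None:
    """Write GeneRecords as FASTA; inverse of :func:`read_fasta` for valid
    records (IDs and sequences round-trip byte-identically)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id} {rec.start} {rec.end} {rec.strand}\n")
            for i in range(0, len(rec.cds), width):
                fh.write(rec.cds[i : i + width] + "\n")


def mark_ribosomal(records: Sequence[GeneRecord],
                   ribosomal_ids: Iterable[str]) -> list[GeneRecord]:
    ribo = set(ribosomal_ids)
    return [replace(r, is_ribosomal=r.gene_id in ribo) for r in records]


def read_id_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def new_feature_table(gene_ids: Sequence[str]) -> pd.DataFrame:
    """An all-missing feature table indexed by gene ID."""
    return pd.DataFrame(np.nan, index=pd.Index(gene_ids, name="gene_id"),
                        columns=list(FEATURE_COLUMNS))


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id",
                     na_values=[""], keep_default_na=True)
    return df.astype(float)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", na_rep="", index_label="gene_id",
                 float_format="%.10g")


def validate_feature_table(table: pd.DataFrame) -> list[str]:
    """Return human-readable violations of the feature-table invariants."""
    issues: list[str] = []
    for col in ("AS", "MFS"):
        if col in table:
            vals = table[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                issues.append(f"{col}: values outside [0, 1]")
    if "CAI" in table:
        vals = table["CAI"].dropna()
        if ((vals <= 0) | (vals > 1)).any():
            issues.append("CAI: values outside (0, 1]")
    for col in ("ESS", "RSB"):
        if col in table:
            vals = table[col].dropna()
            if (~vals.isin([0.0, 1.0])).any():
                issues.append(f"{col}: non-binary values")
    for col in ("PPA", "TMH", "LEN"):
        if col in table:
            vals = table[col].dropna()
            if (vals < 0).any() or (vals != vals.round()).any():
                issues.append(f"{col}: negative or non-integer values")
    return issues


# ---------------------------------------------------------------------------
# External-feature transforms
# ---------------------------------------------------------------------------

def ppa_from_links(link_table: pd.DataFrame, cutoff: float = 0.4,
                   gene_ids: Sequence[str] | None = None) -> pd.Series:
    """Count each gene's distinct association partners at score >= cutoff.

    ``link_table`` has columns (gene_a, gene_b, score); links are undirected,
    duplicate rows and (a,b)/(b,a) mirrors count once, self-links are
    ignored. The cutoff is inclusive, so a 0.4-confidence link is retained
    under the default 0.4 cutoff.
    """
    cols = list(link_table.columns[:3])
    scores = link_table[cols[2]].astype(float)
    if ((scores < 0) | (scores > 1)).any():
        bad = scores[(scores < 0) | (scores > 1)].iloc[0]
        raise ValueError(f"association score outside [0, 1]: {bad}")
    partners: dict[str, set[str]] = {}
    for a, b, s in zip(link_table[cols[0]], link_table[cols[1]], scores):
        if s < cutoff or a == b:
            continue
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)
    ids = list(gene_ids) if gene_ids is not None else sorted(
        set(link_table[cols[0]]) | set(link_table[cols[1]]))
    return pd.Series({g: len(partners.get(g, ())) for g in ids},
                     name="PPA", dtype=float)


def localization_scores(psortb_table: pd.DataFrame,
                        gram: str = "negative") -> pd.DataFrame:
    """Spread PSORTb-style (gene, predicted_type, score) rows into SL* columns.

    A gene receives its prediction score in the column matching its predicted
    compartment and 0 in the other compartments predictable for that Gram
    stain; genes absent from the table stay missing in every SL* column.
    """
    try:
        allowed = LOCALIZATION_COLUMNS[gram]
    except KeyError:
        raise ValueError("gram must be 'positive' or 'negative'") from None
    cols = list(psortb_table.columns[:3])
    out = pd.DataFrame(index=pd.Index(psortb_table[cols[0]].unique(),
                                      name="gene_id"),
                       columns=list(allowed.values()), dtype=float)
    out[:] = 0.0
    for gene, loc_type, score in zip(psortb_table[cols[0]],
                                     psortb_table[cols[1]],
                                     psortb_table[cols[2]]):
        key = str(loc_type).strip().lower()
        if key not in allowed:
            raise ValueError(
                f"unknown localization type {loc_type!r} for Gram-{gram}; "
                f"allowed: {sorted(allowed)}")
        out.loc[gene, allowed[key]] = float(score)
    return out


def scale_expression(raw_levels: pd.Series | pd.DataFrame,
                     base: float = math.e,
                     aggregate: str = "mean") -> pd.Series:
    """Log-scale raw expression levels into the EL column.

    A DataFrame is treated as genes x samples and aggregated (mean of the
    per-sample log values by default, or ``median``). Zeros are replaced by
    half the smallest positive value before taking logs; negative values
    raise ``ValueError``.
    """
    if isinstance(raw_levels, pd.Series):
        frame = raw_levels.to_frame()
    else:
        frame = raw_levels.copy()
    values = frame.to_numpy(dtype=float)
    if np.nanmin(values) < 0:
        raise ValueError("negative expression level")
    positive = values[np.isfinite(values) & (values > 0)]
    if positive.size and (values == 0).any():
        n_zero = int((values == 0).sum())
        logger.warning("replacing %d zero expression values with half the "
                       "smallest positive value", n_zero)
        values[values == 0] = positive.min() / 2.0
    logged = np.log(values) / math.log(base)
    if aggregate == "mean":
        el = np.nanmean(logged, axis=1)
    elif aggregate == "median":
        el = np.nanmedian(logged, axis=1)
    else:
        raise ValueError("aggregate must be 'mean' or 'median'")
    return pd.Series(el, index=frame.index, name="EL")


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """Read a 12-column tabular hit file (blast outfmt 6 dialect)."""
    names = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
             "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    return pd.read_csv(path, sep="\t", names=names, comment="#")
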