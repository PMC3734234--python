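"""End-to-end assembly: sequence-derived features, per-gene ER, and the
full feature table the statistical layer consumes."""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import codonstats, evorate, mfs, seqprops
from .io_core import FEATURE_COLUMNS, GeneRecord, SpeciesConfig, new_feature_table
from .synthetic import SpeciesBundle

logger = logging.getLogger("bacevol")


def sequence_features(records: Sequence[GeneRecord], config: SpeciesConfig,
                      include_mfs: bool = True,
                      engine: mfs.FoldingEngine | None = None) -> pd.DataFrame:
    """CAI, HS, AS, LEN, RSB (and optionally MFS) from gene sequences.

    CAI weights come from the ribosomal reference genes named in the
    species config; replication strand bias uses its ori/ter coordinates.
    Invalid records are excluded with a warning.
    """
    valid = [r for r in records if r.valid]
    if len(valid) < len(records):
        logger.warning("excluding %d invalid gene records from feature "
                       "computation", len(records) - len(valid))
    counts = {r.gene_id: codonstats.count_codons(r.cds, r.gene_id)
              for r in valid}
    ribo_ids = [g for g in config.ribosomal_ids if g in counts]
    if not ribo_ids:
        raise ValueError("no ribosomal reference genes found among records")
    weights = codonstats.cai_weights([counts[g] for g in ribo_ids])
    rep_map = None
    if config.genome_length > 0:
        rep_map = seqprops.ReplichoreMap(config.ori_position,
                                         config.ter_position,
                                         config.genome_length)
    rows = {}
    for r in valid:
        row = {
            "CAI": codonstats.cai(counts[r.gene_id], weights),
            "HS": seqprops.gravy(r.protein),
            "AS": seqprops.aromaticity(r.protein),
            "LEN": seqprops.protein_length(r.protein),
        }
        if rep_map is not None:
            row["RSB"] = seqprops.replication_strand(r, rep_map)
        if include_mfs:
            profile = mfs.pairing_profile(r.cds, engine, config.window,
                                          config.step, gene_id=r.gene_id)
            row["MFS"] = mfs.mfs_score(profile)
        rows[r.gene_id] = row
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id")


def paired_er(ancestral: Sequence[GeneRecord], derived: Sequence[GeneRecord],
              config: SpeciesConfig) -> pd.DataFrame:
    """Ka and ER for genes paired by identical ID across two CDS sets.

    Suited to simulated ancestor/descendant genomes where orthology is
    known; unpaired or saturated genes come back missing.
    """
    by_id = {r.gene_id: r for r in derived if r.valid}
    rows = {}
    for rec in ancestral:
        if not rec.valid or rec.gene_id not in by_id:
            continue
        other = by_id[rec.gene_id]
        if len(rec.cds) != len(other.cds):
            logger.warning("length mismatch for %s; skipping", rec.gene_id)
            continue
        ng = evorate.ka_ng86(rec.cds, other.cds)
        er = (evorate.er_transform(ng.ka, config.ka_constant)
              if ng.ka is not None else np.nan)
        rows[rec.gene_id] = {"ka": ng.ka if ng.ka is not None else np.nan,
                             "ks": ng.ks if ng.ks is not None else np.nan,
                             "ER": er}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id")


def rbh_er(genes_a: Sequence[GeneRecord], genes_b: Sequence[GeneRecord],
           config: SpeciesConfig,
           hgt_exclusion: Iterable[str] = ()) -> pd.DataFrame:
    """Reciprocal-best-hit orthologs between two proteomes, with Ka/ER.

    Quadratic in the number of genes — intended for modest gene sets or
    for use with imported tabular hits.
    """
    valid_a = [r for r in genes_a if r.valid]
    valid_b = [r for r in genes_b if r.valid]
    scores_ab = {(a.gene_id, b.gene_id):
                 evorate.alignment_score(a.protein, b.protein)
                 for a in valid_a for b in valid_b}
    scores_ba = {(b, a): s for (a, b), s in scores_ab.items()}
    pairs = evorate.reciprocal_best_hits(scores_ab, scores_ba)
    rec_a = {r.gene_id: r for r in valid_a}
    rec_b = {r.gene_id: r for r in valid_b}
    rows = []
    for a, b in pairs:
        result = evorate.ortholog_ka(
            rec_a[a], rec_b[b], min_identity=config.min_identity,
            min_coverage=config.min_coverage, min_aa=config.min_protein_aa,
            hgt_exclusion=hgt_exclusion, ka_constant=config.ka_constant)
        rows.append({
            "gene_a": a, "gene_b": b,
            "identity": result.alignment.identity,
            "coverage": result.alignment.coverage,
            "keep": result.keep,
            "reasons": ",".join(result.filter_reasons),
            "ka": result.ng.ka if result.ng and result.ng.ka is not None else np.nan,
            "ks": result.ng.ks if result.ng and result.ng.ks is not None else np.nan,
            "ER": result.er if result.er is not None else np.nan,
        })
    return pd.DataFrame(rows)


#: generative coefficient sets used by the recovery experiments
SINGLE_BETA = {"CAI": -0.8}
MIXED_BETA = {"CAI": -1.5, "ESS": -0.5, "PPA": -0.25, "SLM": 0.1}


def recovery_features(beta_map: dict[str, float], seed: int,
                      n_genes: int = 500, n_codons_mean: int = 200,
                      include_mfs: bool = True) -> pd.DataFrame:
    """Feature table of one simulated species for a recovery experiment.

    The simulated species carries no expression measurements (the EL column
    is left blank, as it is for several real species): the
    squared-loading PCR attribution splits the variance shared by a
    correlated pair evenly between its members, so recovery of a
    codon-bias-driven signal is only interpretable without a collinear
    expression proxy in the table. Columns entirely missing are dropped.
    """
    from . import synthetic

    bundle = synthetic.simulate_species(
        n_genes=n_genes, n_codons_mean=n_codons_mean, beta_map=beta_map,
        seed=seed)
    table = assemble_features(bundle, include_mfs=include_mfs)
    return table.drop(columns="EL").dropna(axis=1, how="all")


def recovery_proportions(beta_map: dict[str, float],
                         seeds: Sequence[int],
                         n_genes: int = 500, n_codons_mean: int = 200,
                         include_mfs: bool = True) -> pd.Series:
    """Mean PCR contribution proportions over replicate simulations.

    Averaging over replicates damps the rotation noise that near-degenerate
    correlation-matrix eigenvalues induce in the per-feature attribution.
    """
    from .inference import pcr_contributions

    props = []
    for seed in seeds:
        table = recovery_features(beta_map, seed, n_genes=n_genes,
                                  n_codons_mean=n_codons_mean,
                                  include_mfs=include_mfs)
        res = pcr_contributions(table.drop(columns="ER"), table["ER"])
        props.append(res.proportions)
    return pd.concat(props, axis=1).mean(axis=1)


def assemble_features(bundle: SpeciesBundle, include_mfs: bool = True,
                      engine: mfs.FoldingEngine | None = None) -> pd.DataFrame:
    """Full feature table (ER plus the 16 features) for a simulated bundle.

    Sequence-derived columns are computed from the ancestral genome,
    externally-styled columns come from the bundle's feature table, and ER
    comes from NG86 on the ancestral/derived gene pairs.
    """
    table = new_feature_table([r.gene_id for r in bundle.ancestral])
    seq = sequence_features(bundle.ancestral, bundle.config,
                            include_mfs=include_mfs, engine=engine)
    for col in seq.columns:
        table.loc[seq.index, col] = seq[col]
    for col in bundle.features.columns:
        if col in FEATURE_COLUMNS:
            table.loc[bundle.features.index, col] = bundle.features[col]
    er = paired_er(bundle.ancestral, bundle.derived, bundle.config)
    table.loc[er.index, "ER"] = er["ER"]
    return table
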