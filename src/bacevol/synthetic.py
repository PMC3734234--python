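"""Synthetic species bundles with known generative structure.

The generator emulates the joint structure the analysis assumes in real
bacterial data: a lognormal expression latent, codon bias coupled to
expression (strength ``alpha``), a ribosomal subset drawn from the most
highly expressed genes with an extra bias boost, binary essentiality,
overdispersed association counts, a hydrophobic membrane-gene subset with
transmembrane helices, leading/lagging strand assignment consistent with an
oriC/ter replichore map, and a per-gene divergence parameter generated from
a known log-linear model on (z-scored) latent features:

    d_g = exp(beta0 + sum_j beta_j * z(feature_j) + eps),  eps ~ N(0, sigma)

A derived genome is produced by sprinkling Poisson-distributed synonymous
and nonsynonymous point substitutions over each ancestral CDS, so the whole
pipeline — codon statistics, CA/CUS, folding, NG86 Ka, Spearman and PCR —
runs end to end against exported ground truth.

Substitutions are placed without enforcing reversibility or excluding
multiple hits; the NG86 Jukes-Cantor correction absorbs multiple hits
approximately, which is why ``d_g`` is capped at 0.3. Stop codons are never
introduced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evorate import _codon_sites
from .genetics import CODON_TO_AA, STOP_CODONS, SYNONYMOUS_FAMILIES, translate_cds
from .io_core import GeneRecord, SpeciesConfig, write_fasta, write_feature_table
from .seqprops import KYTE_DOOLITTLE, ReplichoreMap, aromaticity, gravy

#: Latent features the divergence model may draw on, in fixed order.
BETA_FEATURES = ("CAI", "EL", "ESS", "PPA", "SLM", "TMH", "RSB", "LEN",
                 "HS", "AS")

# background amino-acid frequencies, roughly bacterial averages
_BG_AA = {
    "A": 0.089, "R": 0.055, "N": 0.039, "D": 0.054, "C": 0.011,
    "Q": 0.039, "E": 0.061, "G": 0.074, "H": 0.022, "I": 0.059,
    "L": 0.103, "K": 0.047, "M": 0.024, "F": 0.039, "P": 0.043,
    "S": 0.058, "T": 0.054, "W": 0.013, "Y": 0.029, "V": 0.068,
}

#: per synonymous family, the codon treated as translationally optimal
#: (highest-GC member, alphabetical tie-break) — fixed across simulations
OPTIMAL_CODON = {
    aa: max(codons, key=lambda c: (c.count("G") + c.count("C"), c))
    for aa, codons in SYNONYMOUS_FAMILIES.items() if aa != "*"
}


def _membrane_aa_freqs() -> dict[str, float]:
    # tilt the background toward hydrophobic residues
    w = {aa: f * math.exp(0.35 * KYTE_DOOLITTLE[aa]) for aa, f in _BG_AA.items()}
    total = sum(w.values())
    return {aa: v / total for aa, v in w.items()}


_MEM_AA = _membrane_aa_freqs()


@dataclass
class SpeciesBundle:
    """Everything one simulated species produces."""

    config: SpeciesConfig
    ancestral: list[GeneRecord]
    derived: list[GeneRecord]
    features: pd.DataFrame   # externally-derived feature columns per gene
    truth: pd.DataFrame      # per-gene latents and divergence parameters
    beta: dict[str, float]
    seed: int

    @property
    def ribosomal_ids(self) -> tuple[str, ...]:
        return self.config.ribosomal_ids

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.ancestral, outdir / "ancestral.fasta")
        write_fasta(self.derived, outdir / "derived.fasta")
        write_feature_table(self.features, outdir / "features.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t",
                          index_label="gene_id", float_format="%.10g")
        (outdir / "ribosomal_ids.txt").write_text(
            "".join(f"{g}\n" for g in self.ribosomal_ids))
        cfg = {
            "species_id": self.config.species_id,
            "ori_position": self.config.ori_position,
            "ter_position": self.config.ter_position,
            "genome_length": self.config.genome_length,
            "gram": self.config.gram,
            "ribosomal_ids": list(self.config.ribosomal_ids),
            "beta": self.beta,
            "seed": self.seed,
        }
        (outdir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))


def _draw_protein(rng: np.random.Generator, length: int,
                  membrane: bool) -> str:
    freqs = _MEM_AA if membrane else _BG_AA
    aas = list(freqs)
    p = np.array([freqs[a] for a in aas])
    body = rng.choice(aas, size=length - 1, p=p / p.sum())
    return "M" + "".join(body)


def _encode_protein(rng: np.random.Generator, protein: str,
                    bias: float) -> str:
    """Choose codons: the optimal codon with probability 1/k + b(1 - 1/k)."""
    codons = []
    for aa in protein:
        family = SYNONYMOUS_FAMILIES[aa]
        k = len(family)
        if k == 1:
            codons.append(family[0])
            continue
        p_opt = 1.0 / k + bias * (1.0 - 1.0 / k)
        opt = OPTIMAL_CODON[aa]
        others = [c for c in family if c != opt]
        if rng.random() < p_opt:
            codons.append(opt)
        else:
            codons.append(others[rng.integers(len(others))])
    return "".join(codons)


def _mutation_candidates(codon: str, synonymous: bool) -> list[str]:
    """Single-nucleotide neighbours of the required class, stop-free."""
    out = []
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            same = CODON_TO_AA[alt] == CODON_TO_AA[codon]
            if same == synonymous:
                out.append(alt)
    return out


def _mutate_cds(rng: np.random.Generator, cds: str, n_nonsyn: int,
                n_syn: int) -> str:
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    jobs = [False] * n_nonsyn + [True] * n_syn
    for synonymous in jobs:
        for _ in range(200):  # resample codons without a legal move
            idx = int(rng.integers(len(codons)))
            cands = _mutation_candidates(codons[idx], synonymous)
            if cands:
                codons[idx] = cands[int(rng.integers(len(cands)))]
                break
    return "".join(codons)


def simulate_species(n_genes: int = 200, n_codons_mean: int = 300,
                     alpha: float = 1.0,
                     beta_map: dict[str, float] | None = None,
                     ribo_fraction: float = 0.05, seed: int = 0,
                     membrane_fraction: float = 0.15,
                     ess_prob: float = 0.3, leading_prob: float = 0.7,
                     kappa: float = 4.0, sigma_eps: float = 0.3,
                     beta0: float = math.log(0.05),
                     ribo_bias_boost: float = 1.5, bias_noise: float = 1.0,
                     el_noise: float = 0.5, ess_expression_coupling: float = 0.5,
                     species_id: str = "synthetic") -> SpeciesBundle:
    """Simulate one species bundle; byte-identical outputs per seed.

    ``beta_map`` maps latent feature names (subset of ``BETA_FEATURES``) to
    generative coefficients on the z-scored latents. Divergence values are
    capped at 0.3 so the counting estimator's multiple-hit correction stays
    adequate.
    """
    beta_map = dict(beta_map or {})
    unknown = set(beta_map) - set(BETA_FEATURES)
    if unknown:
        raise ValueError(f"unknown beta features: {sorted(unknown)}; "
                         f"allowed: {BETA_FEATURES}")
    n_ribo = int(round(ribo_fraction * n_genes))
    if n_ribo < 5:
        raise ValueError("ribo_fraction * n_genes must be at least 5")
    if not (0 <= alpha):
        raise ValueError("alpha must be non-negative")
    rng = np.random.default_rng(seed)

    gene_ids = [f"g{str(i).zfill(len(str(n_genes)))}" for i in range(n_genes)]

    # expression latent and codon-bias strength
    log_e = rng.normal(0.0, 1.0, n_genes)
    z_e = (log_e - log_e.mean()) / log_e.std()
    ribo = np.zeros(n_genes, dtype=bool)
    ribo[np.argsort(log_e)[::-1][:n_ribo]] = True
    # codon bias tracks expression only partially: real genomes leave much
    # of the bias variance unexplained by expression, so the coupling gets
    # an idiosyncratic noise term
    bias = 1.0 / (1.0 + np.exp(-(alpha * z_e
                                 + bias_noise * rng.normal(0.0, 1.0, n_genes)
                                 + ribo_bias_boost * ribo)))

    lengths = np.maximum(
        50, rng.gamma(shape=20.0, scale=n_codons_mean / 20.0,
                      size=n_genes).astype(int))
    membrane = (rng.random(n_genes) < membrane_fraction) & ~ribo
    # essential genes are enriched among highly expressed ones, so the
    # Bernoulli probability tilts with the expression latent
    logit_ess = math.log(ess_prob / (1 - ess_prob))
    p_ess = 1.0 / (1.0 + np.exp(-(logit_ess + ess_expression_coupling * z_e)))
    ess = (rng.random(n_genes) < p_ess).astype(int)
    ppa_mean = 5.0 + 15.0 * ess
    ppa_r = 2.0
    ppa = rng.negative_binomial(ppa_r, ppa_r / (ppa_r + ppa_mean))
    tmh = np.where(membrane, 1 + rng.poisson(3.0, n_genes), 0)
    rsb = (rng.random(n_genes) < leading_prob).astype(int)
    extracellular = (rng.random(n_genes) < 0.05) & ~membrane & ~ribo
    loc_score = np.round(rng.uniform(7.5, 10.0, n_genes), 2)
    slm = np.where(membrane, loc_score, 0.0)
    sle = np.where(extracellular, loc_score, 0.0)
    slc = np.where(~membrane & ~extracellular, loc_score, 0.0)

    proteins = [_draw_protein(rng, int(L), bool(m))
                for L, m in zip(lengths, membrane)]
    cds = [_encode_protein(rng, prot, float(b))
           for prot, b in zip(proteins, bias)]
    hs = np.array([gravy(p) for p in proteins])
    a_s = np.array([aromaticity(p) for p in proteins])

    # genome layout: genes laid end to end with intergenic gaps; ter at the
    # midpoint so both replichores are populated
    starts = np.zeros(n_genes, dtype=int)
    pos = 0
    for i in range(n_genes):
        starts[i] = pos
        pos += 3 * int(lengths[i]) + int(rng.integers(20, 200))
    genome_length = pos
    rep_map = ReplichoreMap(ori=0, ter=genome_length // 2,
                            genome_length=genome_length)
    midpoints = starts + 1.5 * lengths
    first_replichore = np.array([rep_map.in_first_replichore(m)
                                 for m in midpoints])
    # choose the strand so that the gene's leading/lagging status equals RSB
    strand = np.where(first_replichore == rsb.astype(bool), "+", "-")

    # divergence model on z-scored latents
    latents = {
        "CAI": bias, "EL": log_e, "ESS": ess.astype(float),
        "PPA": np.log1p(ppa.astype(float)), "SLM": slm,
        "TMH": tmh.astype(float), "RSB": rsb.astype(float),
        "LEN": np.log(lengths.astype(float)), "HS": hs, "AS": a_s,
    }
    eta = np.full(n_genes, beta0)
    for name, b in beta_map.items():
        v = latents[name]
        sd = v.std()
        if sd == 0:
            raise ValueError(f"latent {name} has zero variance; cannot apply "
                             "a generative coefficient to it")
        eta += b * (v - v.mean()) / sd
    eta += rng.normal(0.0, sigma_eps, n_genes)
    d = np.clip(np.exp(eta), 1e-4, 0.3)

    # derived genome: Poisson numbers of substitutions per class
    derived_cds = []
    for i in range(n_genes):
        s_sites = sum(_codon_sites(cds[i][j : j + 3])[0]
                      for j in range(0, len(cds[i]), 3))
        n_sites = sum(_codon_sites(cds[i][j : j + 3])[1]
                      for j in range(0, len(cds[i]), 3))
        n_nonsyn = int(rng.poisson(d[i] * n_sites))
        n_syn = int(rng.poisson(kappa * d[i] * s_sites))
        derived_cds.append(_mutate_cds(rng, cds[i], n_nonsyn, n_syn))

    ends = starts + 3 * lengths
    ancestral = [
        GeneRecord(gene_ids[i], cds[i], proteins[i], int(starts[i]),
                   int(ends[i]), str(strand[i]), bool(ribo[i]))
        for i in range(n_genes)
    ]
    derived = [
        GeneRecord(gene_ids[i], derived_cds[i], translate_cds(derived_cds[i]),
                   int(starts[i]), int(ends[i]), str(strand[i]), bool(ribo[i]))
        for i in range(n_genes)
    ]

    index = pd.Index(gene_ids, name="gene_id")
    # measured expression: log latent plus microarray-scale noise
    el = log_e + rng.normal(0.0, el_noise, n_genes)
    features = pd.DataFrame({
        "EL": el, "ESS": ess.astype(float), "PPA": ppa.astype(float),
        "TMH": tmh.astype(float), "RSB": rsb.astype(float),
        "SLC": slc, "SLM": slm, "SLP": 0.0, "SLO": 0.0, "SLE": sle,
    }, index=index)
    truth = pd.DataFrame({
        "expression_latent": np.exp(log_e), "bias": bias,
        "essential": ess, "ppa": ppa, "membrane": membrane.astype(int),
        "strand_leading": rsb, "divergence": d, "ribosomal": ribo.astype(int),
        "length_codons": lengths,
    }, index=index)
    config = SpeciesConfig(
        species_id=species_id,
        ribosomal_ids=tuple(g for g, r in zip(gene_ids, ribo) if r),
        ori_position=0, ter_position=genome_length // 2,
        genome_length=genome_length)
    return SpeciesBundle(config, ancestral, derived, features, truth,
                         beta_map, seed)


def simulate_ca_fixture(n_nonribo: int = 200, n_ribo: int = 20,
                        separation: float = 0.0, seed: int = 0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Labeled 2-D coordinates for exercising the CUS statistic.

    Non-ribosomal points are standard bivariate normal; ribosomal points
    are standard normal shifted by ``(separation, 0)``. Returns
    ``(coords, ribosomal_flags)``.
    """
    if n_nonribo < 10:
        raise ValueError("need at least 10 non-ribosomal points")
    rng = np.random.default_rng(seed)
    non = rng.standard_normal((n_nonribo, 2))
    rib = rng.standard_normal((n_ribo, 2))
    rib[:, 0] += separation
    coords = np.vstack([non, rib])
    flags = np.zeros(len(coords), dtype=bool)
    flags[n_nonribo:] = True
    return coords, flags
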