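"""Synthetic inputs with known ground truth for every pipeline stage.

Real inputs to this pipeline are genome annotations, FASTA files,
pre-computed co-expression z-score tables and pathway annotations.  The
generators here emulate each of them with controlled, recorded truth:

* :func:`simulate_genome` — gene models with a chosen intron-count
  distribution, emitted as GFF3 + CDS/protein FASTA plus a truth table.
* :func:`simulate_family` — duplicated protein/CDS families descended
  from labeled clade ancestors at controlled divergence.
* :func:`simulate_paralog_pair` — CDS pairs with a target number of
  synonymous events per synonymous site (the bookkept "true Ks").
* :func:`simulate_expression` — expression matrices in which paralog
  correlation decays as ``exp(-lambda * Ks)``.
* :func:`simulate_coexpression` — co-expression z-score tables with a
  pathway enrichment planted at a configured odds ratio.

All generators are pure functions of :class:`SimConfig` (a fixed seed
yields byte-identical output) and every emitted file parses with the
corresponding pipeline reader.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .expression_divergence import (
    GENETIC_CODE,
    ExpressionMatrix,
    codon_sites,
)
from .pathway_prediction import CoexpressionTable, PathwayAnnotation

__all__ = [
    "SimConfig",
    "GenomeSim",
    "FamilySim",
    "CoexpressionSim",
    "simulate_genome",
    "simulate_family",
    "simulate_paralog_pair",
    "simulate_expression",
    "simulate_coexpression",
]

_NONSTOP_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")
_BASES = "TCAG"


@dataclass
class SimConfig:
    """Study conditions for all generators; the seed fixes every byte."""

    seed: int = 0

    # genome structure
    n_species: int = 3
    genes_per_species: int = 40
    # seed-plant-like family: mostly 0-1 introns per gene
    intron_count_distribution: dict[int, float] = field(
        default_factory=lambda: {0: 0.45, 1: 0.40, 2: 0.10, 3: 0.05}
    )
    intron_length_mean: float = 200.0  # geometric, >= 20 bp
    min_exon_length: int = 30
    n_codons: int = 410  # near the land-plant family average protein length

    # family / divergence
    clade_labels: tuple[str, ...] = ("1", "2", "4", "5", "6")
    descendants_per_clade: int = 8
    protein_divergence: float = 0.10  # fraction of residues substituted
    target_ks_grid: tuple[float, ...] = (0.05, 0.1, 0.2, 0.4)
    ka_ks_ratio: float = 0.3  # nonsynonymous events relative to synonymous

    # expression model: corr = base_correlation * exp(-decay_lambda * Ks)
    n_samples: int = 60
    base_correlation: float = 1.0
    decay_lambda: float = 2.5
    noise_sd: float = 0.1

    # co-expression / pathway model
    n_background_genes: int = 600
    n_pathways: int = 30
    planted_pathway_size: int = 15
    planted_odds_ratio: float = 8.0
    baseline_coexp_rate: float = 0.15
    excluded_rate: float = 0.05

    def __post_init__(self):
        dist = self.intron_count_distribution
        total = sum(dist.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("intron_count_distribution must sum to 1")
        if any(v < 0 for v in dist.values()):
            raise ValueError("negative probability in intron distribution")
        if self.protein_divergence > 0.95:
            raise ValueError("requested divergence > 95%")
        if self.n_samples < 10:
            raise ValueError("n_samples < 10")
        if self.planted_odds_ratio < 1:
            raise ValueError("planted odds ratio must be >= 1")
        if self.planted_pathway_size >= self.n_background_genes:
            raise ValueError("planted pathway larger than annotated universe")
        if self.intron_length_mean <= 0 or self.noise_sd < 0 \
                or self.decay_lambda < 0:
            raise ValueError("rates and standard deviations must be positive")


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
    return "".join(_NONSTOP_CODONS[i] for i in idx)


def _translate(cds: str) -> str:
    return "".join(GENETIC_CODE[cds[i:i + 3]] for i in range(0, len(cds), 3))


def _fasta(records: Sequence[tuple[str, str]], wrap: int = 60) -> str:
    lines = []
    for name, seq in records:
        lines.append(f">{name}")
        for i in range(0, len(seq), wrap):
            lines.append(seq[i:i + wrap])
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Genome


@dataclass
class GenomeSim:
    gff3_text: str
    protein_fasta: str
    cds_fasta: str
    truth: pd.DataFrame  # gene_id, species, n_introns, intron_lengths, ...


def simulate_genome(config: SimConfig) -> GenomeSim:
    """Gene models with sampled intron structure, as GFF3 + FASTA + truth.

    Each gene's CDS covers its exons completely (single transcript); the
    CDS is split across ``n_introns + 1`` exons at random in-frame-free
    boundaries, with intron lengths geometric around the configured mean.
    """
    rng = np.random.default_rng(config.seed)
    counts = sorted(config.intron_count_distribution)
    probs = [config.intron_count_distribution[c] for c in counts]
    cds_len = 3 * config.n_codons
    if cds_len < (max(counts) + 1) * config.min_exon_length:
        raise ValueError("CDS too short for requested exon count")

    gff = ["##gff-version 3"]
    prot_recs, cds_recs, rows = [], [], []
    for sp_i in range(config.n_species):
        species = f"species{sp_i + 1}"
        cursor = 1000
        for g_i in range(config.genes_per_species):
            gid = f"{species}_g{g_i + 1:04d}"
            n_introns = int(rng.choice(counts, p=probs))
            # split CDS into n_introns+1 exon chunks, each >= min_exon_length
            free = cds_len - (n_introns + 1) * config.min_exon_length
            cuts = np.sort(rng.integers(0, free + 1, size=n_introns))
            chunks = np.diff(np.concatenate(([0], cuts, [free]))) \
                + config.min_exon_length
            intron_lens = (
                rng.geometric(1.0 / config.intron_length_mean,
                              size=n_introns) + 19
            )
            start = cursor
            exons = []
            pos = start
            for k, chunk in enumerate(chunks):
                exons.append((pos, pos + int(chunk) - 1))
                pos = exons[-1][1] + 1
                if k < n_introns:
                    pos += int(intron_lens[k])
            end = exons[-1][1]
            strand = "+" if (g_i % 2 == 0) else "-"
            chrom = f"chr{sp_i + 1}"
            gff.append(f"{chrom}\tsim\tgene\t{start}\t{end}\t.\t{strand}\t."
                       f"\tID={gid}")
            mrna = f"{gid}.t1"
            gff.append(f"{chrom}\tsim\tmRNA\t{start}\t{end}\t.\t{strand}\t."
                       f"\tID={mrna};Parent={gid}")
            for s, e in exons:
                gff.append(f"{chrom}\tsim\texon\t{s}\t{e}\t.\t{strand}\t."
                           f"\tParent={mrna}")
                gff.append(f"{chrom}\tsim\tCDS\t{s}\t{e}\t.\t{strand}\t0"
                           f"\tParent={mrna}")
            cds = _random_cds(rng, config.n_codons)
            cds_recs.append((gid, cds))
            prot_recs.append((gid, _translate(cds)))
            rows.append({
                "gene_id": gid,
                "species": species,
                "n_introns": n_introns,
                "intron_lengths": ",".join(map(str, intron_lens)),
                "locus_length": end - start + 1,
                "cds_length": cds_len,
            })
            cursor = end + int(rng.integers(500, 2000))
    return GenomeSim(
        gff3_text="\n".join(gff) + "\n",
        protein_fasta=_fasta(prot_recs),
        cds_fasta=_fasta(cds_recs),
        truth=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Family divergence


@dataclass
class FamilySim:
    protein_fasta: str  # ancestors + descendants
    cds_fasta: str
    truth: pd.DataFrame  # gene_id, clade, role, divergence
    panel: list[tuple[str, str, str]]  # (ref_id, clade, protein) ancestors


def _mutate_protein_cds(rng: np.random.Generator, cds: str,
                        divergence: float) -> str:
    """Substitute amino acids at a fraction of codon positions by swapping
    whole codons for random codons of a different residue."""
    n = len(cds) // 3
    k = int(round(divergence * n))
    positions = rng.choice(n, size=k, replace=False)
    codons = [cds[3 * i:3 * i + 3] for i in range(n)]
    for pos in positions:
        aa_old = GENETIC_CODE[codons[pos]]
        while True:
            new = _NONSTOP_CODONS[rng.integers(0, len(_NONSTOP_CODONS))]
            if GENETIC_CODE[new] != aa_old:
                codons[pos] = new
                break
    return "".join(codons)


def simulate_family(config: SimConfig) -> FamilySim:
    """Labeled clade ancestors plus descendants at controlled divergence.

    Ancestors are independent random CDS (so inter-clade similarity is
    background-level); each descendant substitutes ``protein_divergence``
    of its residues.  The ancestors double as the characterized reference
    panel; descendants are the queries with known true clade.
    """
    rng = np.random.default_rng(config.seed)
    prot_recs, cds_recs, rows = [], [], []
    panel = []
    for clade in config.clade_labels:
        anc_cds = _random_cds(rng, config.n_codons)
        anc_id = f"ref_clade{clade}"
        panel.append((anc_id, clade, _translate(anc_cds)))
        prot_recs.append((anc_id, _translate(anc_cds)))
        cds_recs.append((anc_id, anc_cds))
        rows.append({"gene_id": anc_id, "clade": clade,
                     "role": "ancestor", "divergence": 0.0})
        for d_i in range(config.descendants_per_clade):
            did = f"clade{clade}_d{d_i + 1:02d}"
            dcds = _mutate_protein_cds(rng, anc_cds,
                                       config.protein_divergence)
            prot_recs.append((did, _translate(dcds)))
            cds_recs.append((did, dcds))
            rows.append({"gene_id": did, "clade": clade,
                         "role": "descendant",
                         "divergence": config.protein_divergence})
    return FamilySim(
        protein_fasta=_fasta(prot_recs),
        cds_fasta=_fasta(cds_recs),
        truth=pd.DataFrame(rows),
        panel=panel,
    )


def _total_syn_sites(cds: str) -> float:
    return sum(codon_sites(cds[i:i + 3])[0] for i in range(0, len(cds), 3))


def _total_nonsyn_sites(cds: str) -> float:
    return sum(codon_sites(cds[i:i + 3])[1] for i in range(0, len(cds), 3))


def _apply_events(rng: np.random.Generator, cds: str, n_events: int,
                  synonymous: bool) -> str:
    """Apply single-nucleotide events classified post hoc against the
    standard code; repeated hits on one site are allowed (multiple hits
    are what the Jukes-Cantor correction later undoes)."""
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    applied = 0
    while applied < n_events:
        ci = int(rng.integers(0, len(codons)))
        pos = int(rng.integers(0, 3))
        base = _BASES[rng.integers(0, 4)]
        cod = codons[ci]
        if base == cod[pos]:
            continue
        new = cod[:pos] + base + cod[pos + 1:]
        if GENETIC_CODE[new] == "*":
            continue
        if (GENETIC_CODE[new] == GENETIC_CODE[cod]) != synonymous:
            continue
        codons[ci] = new
        applied += 1
    return "".join(codons)


def simulate_paralog_pair(
    config: SimConfig,
    target_ks: float,
    n_codons: int = 500,
    rng: np.random.Generator | None = None,
) -> tuple[str, str, float, float]:
    """One CDS pair with a bookkept true Ks (and Ka).

    ``round(target_ks * S)`` synonymous events (S = ancestor synonymous
    sites) and ``round(ka_ks_ratio * target_ks * N)`` nonsynonymous events
    are applied to one copy; the truth is events per corresponding site.
    Returns ``(cds_a, cds_b, true_ks, true_ka)``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    anc = _random_cds(rng, n_codons)
    s_sites = _total_syn_sites(anc)
    n_sites = _total_nonsyn_sites(anc)
    m_syn = int(round(target_ks * s_sites))
    m_non = int(round(config.ka_ks_ratio * target_ks * n_sites))
    derived = _apply_events(rng, anc, m_syn, synonymous=True)
    derived = _apply_events(rng, derived, m_non, synonymous=False)
    return anc, derived, m_syn / s_sites, m_non / n_sites


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    config: SimConfig,
    pair_ks: Sequence[float],
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, list[float]]:
    """Expression matrix of paralog pairs whose population correlation is
    ``base_correlation * exp(-decay_lambda * Ks)`` plus independent
    measurement noise.  Returns the matrix (two rows per pair) and the
    realized sample correlation of each pair.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_samples
    gene_ids, rows, realized = [], [], []
    for i, ks in enumerate(pair_ks):
        r = config.base_correlation * math.exp(-config.decay_lambda * ks)
        r = min(max(r, 0.0), 1.0)
        shared = rng.standard_normal(n)
        x = math.sqrt(r) * shared + math.sqrt(1 - r) * rng.standard_normal(n)
        y = math.sqrt(r) * shared + math.sqrt(1 - r) * rng.standard_normal(n)
        x = x + config.noise_sd * rng.standard_normal(n)
        y = y + config.noise_sd * rng.standard_normal(n)
        a, b = f"pair{i + 1:03d}a", f"pair{i + 1:03d}b"
        gene_ids += [a, b]
        rows += [x, y]
        realized.append(float(np.corrcoef(x, y)[0, 1]))
    matrix = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=[f"sample{j + 1:03d}" for j in range(n)],
        values=np.vstack(rows),
    )
    return matrix, realized


# ---------------------------------------------------------------------------
# Co-expression with planted pathway enrichment


@dataclass
class CoexpressionSim:
    table: CoexpressionTable
    annotation: PathwayAnnotation
    truth: pd.DataFrame  # focal, pathway, target OR, realized counts/OR
    focal_gene: str = "FOCAL"


def simulate_coexpression(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> CoexpressionSim:
    """Co-expression z-scores for a focal gene with one planted pathway.

    Background partner genes are co-expressed (z drawn above 3) at the
    baseline rate, not-co-expressed (z below 1) otherwise, with a small
    excluded band in between.  The planted pathway's membership among
    co-expressed genes is set deterministically so that the realized 2x2
    odds ratio is as close as possible to ``planted_odds_ratio``; an odds
    ratio of 1 plants nothing beyond the baseline.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_background_genes
    size = config.planted_pathway_size
    genes = [f"G{i + 1:05d}" for i in range(n)]
    planted_genes = genes[:size]
    background = genes[size:]
    planted_pid = "PWY-PLANTED"

    # pathway annotation: planted pathway + uniform assignment of the rest
    gene_pathways: dict[str, set[tuple[str, str]]] = {
        g: {(planted_pid, "planted pathway")} for g in planted_genes
    }
    other_pids = [f"PWY{i + 1:04d}" for i in range(config.n_pathways - 1)]
    assign = rng.integers(0, len(other_pids), size=len(background))
    for g, k in zip(background, assign):
        gene_pathways[g] = {(other_pids[k], f"pathway {other_pids[k]}")}

    # background co-expression status
    u = rng.random(len(background))
    status = np.where(
        u < config.baseline_coexp_rate, "co",
        np.where(u < config.baseline_coexp_rate + config.excluded_rate,
                 "ex", "not"),
    )
    n_co = int((status == "co").sum())
    n_not = int((status == "not").sum())

    # deterministic planting to hit the target odds ratio
    odds_bg = n_co / n_not
    target = config.planted_odds_ratio * odds_bg
    a = int(round(size * target / (1 + target)))
    if config.planted_odds_ratio > 1:
        a = max(1, min(size - 1, a))

    def z_co() -> float:
        return 3.0 + abs(rng.standard_normal())

    def z_not() -> float:
        return 1.0 - abs(rng.standard_normal())

    records = []
    for g in planted_genes[:a]:
        records.append(("FOCAL", g, z_co()))
    for g in planted_genes[a:]:
        records.append(("FOCAL", g, z_not()))
    for g, st in zip(background, status):
        if st == "co":
            z = z_co()
        elif st == "not":
            z = z_not()
        else:
            z = float(rng.uniform(1.01, 2.99))
        records.append(("FOCAL", g, z))

    c, d = n_co, n_not
    realized_or = (a / (size - a)) / (c / d) if 0 < a < size else float("inf")
    truth = pd.DataFrame([{
        "focal_gene": "FOCAL",
        "pathway_id": planted_pid,
        "target_odds_ratio": config.planted_odds_ratio,
        "a": a, "b": c, "c": size - a, "d": d,
        "realized_odds_ratio": realized_or,
    }])
    return CoexpressionSim(
        table=CoexpressionTable(records),
        annotation=PathwayAnnotation(gene_pathways),
        truth=truth,
    )
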