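"""Co-expression-based pathway enrichment and combined functional calls.

For each focal family member, partner genes are partitioned by their
pre-computed co-expression z-score (ATTED-style): z >= 3 co-expressed,
z <= 1 not co-expressed, the band in between excluded.  Restricting to
partners with pathway annotation (PMN-style), each pathway is tested for
over-representation among the co-expressed partners with a one-sided
Fisher exact test; q-values (Benjamini-Hochberg by default, optional
Storey) are computed per focal gene across its tested pathways.  Enriched
pathways are then merged with an orthology-based substrate-class
prediction into a per-gene agreement verdict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .motif_enrichment import fisher_greater

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionTable",
    "PathwayAnnotation",
    "EnrichmentResult",
    "FunctionalPrediction",
    "partition_by_z",
    "pathway_enrichment",
    "combine_predictions",
    "storey_qvalues",
    "write_enrichment_table",
    "write_prediction_table",
]

AGREEMENT_LABELS = (
    "both-consistent", "coexpression-only", "orthology-only",
    "none", "conflicting",
)


@dataclass
class CoexpressionTable:
    """Pairwise co-expression z-scores; pairs unordered and unique."""

    records: list[tuple[str, str, float]]
    _partners: dict[str, dict[str, float]] = field(init=False, repr=False)

    def __post_init__(self):
        self._partners = {}
        seen = set()
        for a, b, z in self.records:
            if not np.isfinite(z):
                raise ValueError(f"non-finite z for pair ({a}, {b})")
            key = tuple(sorted((a, b)))
            if key in seen:
                raise ValueError(f"duplicate pair {key}")
            seen.add(key)
            self._partners.setdefault(a, {})[b] = z
            self._partners.setdefault(b, {})[a] = z

    def partners_of(self, gene: str) -> dict[str, float]:
        return dict(self._partners.get(gene, {}))

    def __contains__(self, gene: str) -> bool:
        return gene in self._partners


@dataclass
class PathwayAnnotation:
    """gene_id -> set of (pathway_id, pathway_name)."""

    gene_pathways: dict[str, set[tuple[str, str]]]

    def __post_init__(self):
        for gene, pws in self.gene_pathways.items():
            for pid, _ in pws:
                if not pid:
                    raise ValueError(f"empty pathway id for gene {gene}")

    def annotated(self) -> set[str]:
        return set(self.gene_pathways)

    def genes_in(self, pathway_id: str) -> set[str]:
        return {g for g, pws in self.gene_pathways.items()
                if any(pid == pathway_id for pid, _ in pws)}

    def pathways(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for pws in self.gene_pathways.values():
            for pid, name in pws:
                out.setdefault(pid, name)
        return out


@dataclass
class EnrichmentResult:
    focal_gene: str
    pathway_id: str
    pathway_name: str
    table: tuple[int, int, int, int]  # (a, b, c, d)
    p_value: float
    q_value: float = float("nan")
    enriched: bool = False


@dataclass
class FunctionalPrediction:
    focal_gene: str
    enriched_pathways: list[str]
    orthology_substrate_class: str | None
    agreement: str

    def __post_init__(self):
        if self.agreement not in AGREEMENT_LABELS:
            raise ValueError(f"bad agreement label {self.agreement!r}")


def partition_by_z(
    table: CoexpressionTable,
    focal_gene: str,
    z_coexp: float = 3.0,
    z_not: float = 1.0,
) -> tuple[set[str], set[str]]:
    """Split the focal gene's partners into co-expressed (z >= z_coexp)
    and not-co-expressed (z <= z_not); the band in between joins neither
    set.  Boundary values are inclusive on both sides.
    """
    if z_not > z_coexp:
        raise ValueError("z_not must not exceed z_coexp")
    if focal_gene not in table:
        logger.warning("focal gene %s absent from co-expression table",
                       focal_gene)
        return set(), set()
    partners = table.partners_of(focal_gene)
    coexp = {g for g, z in partners.items() if z >= z_coexp}
    not_coexp = {g for g, z in partners.items() if z <= z_not}
    return coexp, not_coexp


def storey_qvalues(p_values: Sequence[float],
                   lambdas: np.ndarray | None = None) -> np.ndarray:
    """Storey q-values with smoother pi0 estimation over a lambda grid.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is smoothed with a
    cubic spline and evaluated at the largest lambda; q = pi0 * BH.
    """
    p = np.asarray(p_values, float)
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_grid = np.array(
        [(p > lam).sum() / (m * (1 - lam)) for lam in lambdas]
    )
    if m < 2 * lambdas.size:
        pi0 = 1.0  # too few tests to estimate pi0 stably
    else:
        from scipy.interpolate import UnivariateSpline

        spline = UnivariateSpline(lambdas, pi0_grid, k=3)
        pi0 = float(np.clip(spline(lambdas[-1]), 0.0, 1.0)) or 1.0
    _, bh, _, _ = multipletests(p, method="fdr_bh")
    return np.minimum(pi0 * bh, 1.0)


def pathway_enrichment(
    coexp: set[str],
    not_coexp: set[str],
    annotation: PathwayAnnotation,
    focal_gene: str = "focal",
    min_pathway_genes: int = 2,
    alpha: float = 0.05,
    qvalue_method: str = "bh",
) -> list[EnrichmentResult]:
    """One-sided Fisher enrichment of each pathway among co-expressed genes.

    The universe of each 2x2 table is the *annotated* genes among the
    focal gene's co-expressed and not-co-expressed partners.  Pathways
    with fewer than ``min_pathway_genes`` annotated genes in that universe
    are not tested.  ``enriched`` requires q < alpha and a co-expressed
    pathway fraction exceeding the not-co-expressed one.
    """
    annotated = annotation.annotated()
    co_ann = sorted(coexp & annotated)
    not_ann = sorted(not_coexp & annotated)
    if not co_ann:
        logger.warning("focal %s: no annotated co-expressed partners; "
                       "no tests performed", focal_gene)
        return []
    universe = set(co_ann) | set(not_ann)
    names = annotation.pathways()
    results = []
    for pid in sorted(names):
        members = annotation.genes_in(pid) & universe
        if len(members) < min_pathway_genes:
            continue
        a = len(members & set(co_ann))
        b = len(co_ann) - a
        c = len(members & set(not_ann))
        d = len(not_ann) - c
        p = fisher_greater(a, b, c, d)
        results.append(EnrichmentResult(
            focal_gene=focal_gene, pathway_id=pid, pathway_name=names[pid],
            table=(a, b, c, d), p_value=p,
        ))
    if results:
        pvals = [r.p_value for r in results]
        if qvalue_method == "storey":
            q = storey_qvalues(pvals)
        elif qvalue_method == "bh":
            _, q, _, _ = multipletests(pvals, method="fdr_bh")
        else:
            raise ValueError(f"unknown q-value method {qvalue_method!r}")
        for r, qv in zip(results, q):
            a, b, c, d = r.table
            frac_co = a / (a + b) if a + b else 0.0
            frac_not = c / (c + d) if c + d else 0.0
            r.q_value = float(qv)
            r.enriched = bool(qv < alpha and frac_co > frac_not)
    return results


def combine_predictions(
    enrichment: Sequence[EnrichmentResult],
    ortho_calls: Mapping[str, str],
    class_pathway_map: Mapping[str, set[str]],
    focal_genes: Sequence[str] | None = None,
) -> list[FunctionalPrediction]:
    """Merge enriched pathways with orthology substrate-class calls.

    ``class_pathway_map`` maps pathway_id -> substrate classes compatible
    with that pathway.  Agreement per focal gene:

    * both signals, some enriched pathway compatible -> ``both-consistent``
    * both signals, no compatible pathway -> ``conflicting``
    * orthology class unmapped in the table -> ``orthology-only`` (warned,
      never silently called conflicting)
    * one signal -> ``coexpression-only`` / ``orthology-only``
    * neither -> ``none``
    """
    by_gene: dict[str, list[EnrichmentResult]] = {}
    for r in enrichment:
        by_gene.setdefault(r.focal_gene, []).append(r)
    genes = list(focal_genes) if focal_genes is not None else sorted(
        set(by_gene) | set(ortho_calls)
    )
    mapped_classes = set().union(*class_pathway_map.values()) \
        if class_pathway_map else set()
    out = []
    for gene in genes:
        enriched = sorted(r.pathway_id for r in by_gene.get(gene, [])
                          if r.enriched)
        ortho = ortho_calls.get(gene)
        if enriched and ortho:
            if ortho not in mapped_classes:
                logger.warning(
                    "substrate class %r absent from class map; %s labeled "
                    "orthology-only, not conflicting", ortho, gene)
                label = "orthology-only"
            elif any(ortho in class_pathway_map.get(pid, set())
                     for pid in enriched):
                label = "both-consistent"
            else:
                label = "conflicting"
        elif enriched:
            label = "coexpression-only"
        elif ortho:
            label = "orthology-only"
        else:
            label = "none"
        out.append(FunctionalPrediction(
            focal_gene=gene, enriched_pathways=enriched,
            orthology_substrate_class=ortho, agreement=label,
        ))
    return out


def write_enrichment_table(results: Sequence[EnrichmentResult],
                           path: str) -> None:
    with open(path, "w") as fh:
        fh.write("focal_gene\tpathway_id\tpathway_name\ta\tb\tc\td\t"
                 "p_value\tq_value\tenriched\n")
        for r in results:
            a, b, c, d = r.table
            fh.write(f"{r.focal_gene}\t{r.pathway_id}\t{r.pathway_name}\t"
                     f"{a}\t{b}\t{c}\t{d}\t{r.p_value:.6g}\t"
                     f"{r.q_value:.6g}\t{int(r.enriched)}\n")


def write_prediction_table(predictions: Sequence[FunctionalPrediction],
                           path: str) -> None:
    with open(path, "w") as fh:
        fh.write("focal_gene\tenriched_pathways\torthology_substrate_class\t"
                 "agreement\n")
        for p in predictions:
            pws = ",".join(p.enriched_pathways)
            fh.write(f"{p.focal_gene}\t{pws}\t"
                     f"{p.orthology_substrate_class or ''}\t{p.agreement}\n")
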