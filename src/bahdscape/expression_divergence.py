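"""Expression divergence of family paralogs: PCC, Ka/Ks (NG86), Ks bins.

After a gene duplication the two copies initially share their regulatory
context, so their expression profiles correlate; the correlation decays as
the copies diverge.  This module quantifies that decay for an enzyme
family: all-pairs Pearson correlation across expression samples,
percentile-based co-expression calls (>95th / <5th percentile of the
pairwise PCC distribution), synonymous and nonsynonymous substitution
rates per paralog pair, and statistics across Ks bins (Kruskal-Wallis,
pairwise two-sample Kolmogorov-Smirnov with BH-FDR, and a linear fit of
PCC on Ks).

Ka/Ks uses the Nei-Gojobori (1986) counting method: synonymous and
nonsynonymous site counts per codon averaged over both sequences,
differences per codon averaged over all minimal mutational pathways that
avoid stop codons, and Jukes-Cantor correction
``d = -(3/4) ln(1 - (4/3) p)``.  Ks here is used ordinally (binning and
regression), for which NG86 is an adequate, exactly specifiable estimator.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ParalogPair",
    "CoexpressionCallSet",
    "DivergenceSummary",
    "KaKsResult",
    "pairwise_pcc",
    "call_coexpression",
    "ng86_ka_ks",
    "codon_sites",
    "align_codons",
    "ks_bin_label",
    "bin_and_test",
    "build_paralog_pairs",
    "GENETIC_CODE",
]

# Standard genetic code, DNA alphabet; '*' marks stop codons.
_BASES = "TCAG"
_AA64 = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
GENETIC_CODE: dict[str, str] = {
    a + b + c: _AA64[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


# ---------------------------------------------------------------------------
# Expression matrix and correlation


@dataclass
class ExpressionMatrix:
    """Normalized expression values, genes x samples."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("expression matrix dimensions inconsistent")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in expression matrix")

    @classmethod
    def from_tsv(cls, path: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), list(df.columns), df.to_numpy(float))

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(self.values, index=self.gene_ids,
                     columns=self.sample_ids).to_csv(path, sep="\t")

    def subset(self, ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in ids if g not in pos]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]!r}")
        idx = [pos[g] for g in ids]
        return ExpressionMatrix(list(ids), self.sample_ids, self.values[idx])


def pairwise_pcc(matrix: ExpressionMatrix,
                 ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix over the selected genes.

    Rows with zero variance yield NaN correlations (logged), never silent
    zeros; the diagonal is exactly 1 for usable rows.
    """
    sub = matrix.subset(ids) if ids is not None else matrix
    if len(sub.sample_ids) < 3:
        raise ValueError("need >= 3 samples for correlation")
    x = sub.values
    sd = x.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        logger.warning("%d zero-variance gene row(s) -> NaN PCC: %s",
                       flat.size, [sub.gene_ids[i] for i in flat[:5]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(x)
    corr[flat, :] = np.nan
    corr[:, flat] = np.nan
    np.fill_diagonal(corr, [np.nan if i in set(flat) else 1.0
                            for i in range(len(sub.gene_ids))])
    return pd.DataFrame(corr, index=sub.gene_ids, columns=sub.gene_ids)


@dataclass
class CoexpressionCallSet:
    positive_threshold: float
    negative_threshold: float
    positive_pairs: list[tuple[str, str]]
    negative_pairs: list[tuple[str, str]]


def call_coexpression(pcc_matrix: pd.DataFrame) -> CoexpressionCallSet:
    """Flag pairs beyond the 95th / 5th percentile of the PCC distribution.

    The distribution is the unordered upper triangle excluding the
    diagonal (each pair once, self-correlations excluded); percentiles use
    linear interpolation between order statistics; flags are strict
    (> 95th, < 5th).
    """
    genes = list(pcc_matrix.index)
    vals, pairs = [], []
    arr = pcc_matrix.to_numpy(float)
    for i, j in itertools.combinations(range(len(genes)), 2):
        pairs.append(tuple(sorted((genes[i], genes[j]))))
        vals.append(arr[i, j])
    vals = np.asarray(vals)
    ok = ~np.isnan(vals)
    if not ok.any():
        raise ValueError("all pairwise correlations are NA")
    if ok.sum() < 20:
        raise ValueError("need >= 20 usable off-diagonal pairs")
    pos_t = float(np.percentile(vals[ok], 95))
    neg_t = float(np.percentile(vals[ok], 5))
    positive = [p for p, v in zip(pairs, vals) if not np.isnan(v) and v > pos_t]
    negative = [p for p, v in zip(pairs, vals) if not np.isnan(v) and v < neg_t]
    return CoexpressionCallSet(pos_t, neg_t, sorted(positive), sorted(negative))


# ---------------------------------------------------------------------------
# NG86 Ka/Ks


@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float  # NaN when saturated
    ka_ks: float  # NaN when ks is 0 or NaN
    s_sites: float
    n_sites: float
    s_diffs: float
    n_diffs: float
    saturated_s: bool = False
    saturated_n: bool = False


def codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one codon.

    Each position contributes the fraction of its three possible
    nucleotide changes that preserve the amino acid; changes creating a
    stop codon count as nonsynonymous.
    """
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if GENETIC_CODE[alt] == aa:
                s += 1 / 3
    return s, 3.0 - s


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences between two codons, averaged
    over all minimal mutational pathways that avoid stop intermediates.

    If every pathway passes through a stop, all pathways are used (rare
    fallback; endpoints are guaranteed stop-free by the caller).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order):
        steps = []
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            steps.append((cur, nxt))
            cur = nxt
        return steps

    all_paths = [walk(order) for order in itertools.permutations(diff_pos)]
    valid = [
        p for p in all_paths
        if all(GENETIC_CODE[b] != "*" for _, b in p[:-1])
    ]
    use = valid or all_paths
    s_tot = n_tot = 0.0
    for path in use:
        for a, b in path:
            if GENETIC_CODE[a] == GENETIC_CODE[b]:
                s_tot += 1
            else:
                n_tot += 1
    return s_tot / len(use), n_tot / len(use)


def _jc(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return float("nan"), True
    if p == 0.0:
        return 0.0, False
    return -0.75 * math.log(1 - 4 * p / 3), False


def _codon_list(cds: str, name: str) -> list[str]:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise ValueError(f"{name}: CDS length {len(cds)} not a multiple of 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    bad = [c for c in codons if c not in GENETIC_CODE]
    if bad:
        raise ValueError(f"{name}: unrecognized codon(s) {bad[:3]!r}")
    stops = [i for i, c in enumerate(codons[:-1]) if GENETIC_CODE[c] == "*"]
    if stops:
        raise ValueError(f"{name}: internal stop codon at {stops[:3]}")
    if GENETIC_CODE[codons[-1]] == "*":
        codons = codons[:-1]  # trailing stop is not a comparable site
    if not codons:
        raise ValueError(f"{name}: no coding codons")
    return codons


def align_codons(
    cds_a: str,
    cds_b: str,
    protein_alignment: tuple[str, str] | None = None,
) -> list[tuple[str, str]]:
    """Back-translate a protein alignment into paired codons.

    ``protein_alignment`` is the pair of aligned protein strings ('-' for
    gaps); columns with a gap in either sequence are dropped.  When no
    alignment is supplied a Needleman-Wunsch global protein alignment
    (BLOSUM62, gap -10/-0.5) is computed internally.
    """
    ca = _codon_list(cds_a, "cds_a")
    cb = _codon_list(cds_b, "cds_b")
    if protein_alignment is None:
        from Bio import Align
        from Bio.Align import substitution_matrices

        pa = "".join(GENETIC_CODE[c] for c in ca)
        pb = "".join(GENETIC_CODE[c] for c in cb)
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        aln = next(iter(aligner.align(pa, pb)))
        aligned_a, aligned_b = aln[0], aln[1]
    else:
        aligned_a, aligned_b = protein_alignment
        if len(aligned_a) != len(aligned_b):
            raise ValueError("protein alignment rows differ in length")
    ia = ib = 0
    pairs = []
    for cha, chb in zip(aligned_a, aligned_b):
        if cha != "-" and chb != "-":
            pairs.append((ca[ia], cb[ib]))
        if cha != "-":
            ia += 1
        if chb != "-":
            ib += 1
    if ia != len(ca) or ib != len(cb):
        raise ValueError("protein alignment inconsistent with CDS lengths")
    return pairs


def ng86_ka_ks(
    cds_a: str,
    cds_b: str,
    protein_alignment: tuple[str, str] | None = None,
) -> KaKsResult:
    """Nei-Gojobori (1986) Ka and Ks for one in-frame CDS pair.

    Symmetric in its arguments (the pair is canonicalized internally, so
    ``ng86_ka_ks(a, b)`` and ``ng86_ka_ks(b, a)`` are bitwise equal).
    Saturated proportions (p >= 3/4) yield NaN with the corresponding
    ``saturated_*`` flag.
    """
    if cds_b < cds_a:
        cds_a, cds_b = cds_b, cds_a
        if protein_alignment is not None:
            protein_alignment = (protein_alignment[1], protein_alignment[0])
    pairs = align_codons(cds_a, cds_b, protein_alignment)
    if not pairs:
        raise ValueError("no aligned codons")
    s_sites = n_sites = s_diffs = n_diffs = 0.0
    for c1, c2 in pairs:
        s1, n1 = codon_sites(c1)
        s2, n2 = codon_sites(c2)
        s_sites += (s1 + s2) / 2
        n_sites += (n1 + n2) / 2
        sd, nd = _pathway_diffs(c1, c2)
        s_diffs += sd
        n_diffs += nd
    p_s = s_diffs / s_sites if s_sites > 0 else 0.0
    p_n = n_diffs / n_sites if n_sites > 0 else 0.0
    ks, sat_s = _jc(p_s)
    ka, sat_n = _jc(p_n)
    if math.isnan(ks) or ks == 0.0:
        ka_ks = float("nan")
    else:
        ka_ks = ka / ks
    return KaKsResult(ka=ka, ks=ks, ka_ks=ka_ks,
                      s_sites=s_sites, n_sites=n_sites,
                      s_diffs=s_diffs, n_diffs=n_diffs,
                      saturated_s=sat_s, saturated_n=sat_n)


# ---------------------------------------------------------------------------
# Paralog pairs, Ks bins and tests


def ks_bin_label(ks: float, bin_width: float = 0.2) -> str:
    """Half-open bin label "[x, x+w)" for a Ks value; NaN -> "NA"."""
    if ks is None or math.isnan(ks):
        return "NA"
    lo = math.floor(ks / bin_width) * bin_width
    return f"[{lo:.1f}, {lo + bin_width:.1f})"


@dataclass(frozen=True)
class ParalogPair:
    """Unordered within-species gene pair (gene_a < gene_b)."""

    gene_a: str
    gene_b: str
    pcc: float
    ka: float
    ks: float
    ka_ks: float
    ks_bin: str

    def __post_init__(self):
        if self.gene_a >= self.gene_b:
            raise ValueError("ParalogPair requires gene_a < gene_b")


def build_paralog_pairs(
    pcc_matrix: pd.DataFrame,
    cds: Mapping[str, str],
    bin_width: float = 0.2,
) -> list[ParalogPair]:
    """All unordered pairs with PCC and NG86 Ka/Ks (Ks bin attached)."""
    genes = sorted(set(pcc_matrix.index) & set(cds))
    skipped = set(pcc_matrix.index) - set(genes)
    if skipped:
        logger.warning("%d gene(s) lack CDS, skipped from Ka/Ks: %s",
                       len(skipped), sorted(skipped)[:5])
    out = []
    for a, b in itertools.combinations(genes, 2):
        res = ng86_ka_ks(cds[a], cds[b])
        out.append(ParalogPair(
            gene_a=a, gene_b=b,
            pcc=float(pcc_matrix.loc[a, b]),
            ka=res.ka, ks=res.ks, ka_ks=res.ka_ks,
            ks_bin=ks_bin_label(res.ks, bin_width),
        ))
    return out


@dataclass
class DivergenceSummary:
    slope: float
    intercept: float
    r_squared: float
    kruskal_wallis_H: float
    kruskal_wallis_p: float
    pairwise_ks: pd.DataFrame  # bin_a, bin_b, D, p_value, p_adjusted
    bin_counts: dict[str, int]


def bin_and_test(
    pairs: Sequence[ParalogPair],
    bin_width: float = 0.2,
    min_bin_size: int = 3,
) -> DivergenceSummary:
    """Ks-binned divergence statistics for a set of paralog pairs.

    PCC ~ Ks linear fit (unbinned, saturated/NA-Ks pairs excluded),
    Kruskal-Wallis across usable bins, and all pairwise two-sample KS
    tests between bins with BH-FDR adjustment.  With fewer than two
    usable bins the rank tests are skipped (NaN) and the fit is still
    reported.
    """
    usable = [p for p in pairs
              if not math.isnan(p.ks) and not math.isnan(p.pcc)]
    if len(usable) < 2:
        raise ValueError("need >= 2 pairs with defined Ks and PCC")
    ks_vals = np.array([p.ks for p in usable])
    pcc_vals = np.array([p.pcc for p in usable])
    if np.ptp(ks_vals) > 0:
        fit = stats.linregress(ks_vals, pcc_vals)
        slope, intercept, r2 = fit.slope, fit.intercept, fit.rvalue ** 2
    else:  # all Ks identical: regression undefined
        slope = intercept = r2 = float("nan")

    groups: dict[str, list[float]] = {}
    for p in usable:
        groups.setdefault(ks_bin_label(p.ks, bin_width), []).append(p.pcc)
    bins = sorted(groups, key=lambda b: float(b[1:].split(",")[0]))
    big = [b for b in bins if len(groups[b]) >= min_bin_size]
    bin_counts = {b: len(groups[b]) for b in bins}

    if len(big) >= 2:
        kw_h, kw_p = stats.kruskal(*[groups[b] for b in big])
        rows = []
        for ba, bb in itertools.combinations(big, 2):
            res = stats.ks_2samp(groups[ba], groups[bb])
            rows.append({"bin_a": ba, "bin_b": bb,
                         "D": float(res.statistic),
                         "p_value": float(res.pvalue)})
        pw = pd.DataFrame(rows)
        _, adj, _, _ = multipletests(pw["p_value"], method="fdr_bh")
        pw["p_adjusted"] = adj
    else:
        logger.warning("fewer than 2 bins with >= %d pairs; rank tests "
                       "skipped", min_bin_size)
        kw_h = kw_p = float("nan")
        pw = pd.DataFrame(
            columns=["bin_a", "bin_b", "D", "p_value", "p_adjusted"]
        )
    return DivergenceSummary(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        kruskal_wallis_H=float(kw_h),
        kruskal_wallis_p=float(kw_p),
        pairwise_ks=pw,
        bin_counts=bin_counts,
    )
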