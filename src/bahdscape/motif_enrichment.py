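"""Clade-discriminative fixed-width motif enrichment.

Finds short ungapped motifs (consensus strings over the amino-acid
alphabet, optionally with 'X' wildcard positions) that are over-represented
in one clade's protein sequences (foreground) relative to all other family
sequences (background).  Canonical family motifs like DFGWG and HXXXD, and
clade markers like TFFDXXW, are of exactly this form.

The finder enumerates every foreground substring in a width range together
with its wildcard generalizations, scores each candidate by per-sequence
presence/absence with a one-sided Fisher exact test (foreground
over-representation), adjusts with Benjamini-Hochberg across the full
candidate set, and reports the top motifs after greedy redundancy removal.
This is a deliberately simple, exactly testable consensus-enumeration
method — no PWM refinement or probabilistic seeding.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "MotifModel",
    "MotifEnrichmentResult",
    "enumerate_candidate_motifs",
    "score_motif",
    "score_all",
    "top_motifs",
    "find_motifs",
    "fisher_greater",
    "write_motif_table",
    "write_meme_minimal",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
MIN_WIDTH, MAX_WIDTH = 3, 15


@dataclass(frozen=True)
class MotifModel:
    """Fixed-width consensus motif; 'X' matches any residue."""

    consensus: str

    def __post_init__(self):
        c = self.consensus
        if len(c) < MIN_WIDTH:
            raise ValueError(f"motif {c!r}: width < {MIN_WIDTH}")
        if c.startswith("X") or c.endswith("X"):
            raise ValueError(f"motif {c!r}: leading/trailing wildcard")
        bad = set(c) - set(_AA + "X")
        if bad:
            raise ValueError(f"motif {c!r}: bad characters {sorted(bad)!r}")

    @property
    def width(self) -> int:
        return len(self.consensus)

    @property
    def n_wildcards(self) -> int:
        return self.consensus.count("X")

    def pattern(self) -> re.Pattern:
        return re.compile(self.consensus.replace("X", "."))

    def matches(self, seq: str) -> bool:
        return self.pattern().search(seq) is not None

    def match_offsets(self, seq: str) -> tuple[int, ...]:
        """0-based start offsets of all (possibly overlapping) matches."""
        pat = re.compile("(?=" + self.consensus.replace("X", ".") + ")")
        return tuple(m.start() for m in pat.finditer(seq))


@dataclass
class MotifEnrichmentResult:
    motif: MotifModel
    fg_with: int
    fg_total: int
    bg_with: int
    bg_total: int
    p_value: float
    q_value: float = float("nan")
    fg_offsets: dict[str, tuple[int, ...]] = field(default_factory=dict)

    @property
    def fraction_fg(self) -> float:
        """Percent of foreground sequences carrying the motif."""
        return 100.0 * self.fg_with / self.fg_total


def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided Fisher exact p for over-representation in the first row.

    Table [[a, b], [c, d]]; p = P(X >= a) under the hypergeometric null
    with population a+b+c+d, a+c successes, draws a+b.
    """
    return float(hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))


def _generalize(word: str, max_x: int) -> set[str]:
    # All wildcard generalizations with <= max_x interior X positions.
    out = {word}
    interior = range(1, len(word) - 1)
    for k in range(1, min(max_x, len(word) - 2) + 1):
        for pos in itertools.combinations(interior, k):
            chars = list(word)
            for p in pos:
                chars[p] = "X"
            out.add("".join(chars))
    return out


def enumerate_candidate_motifs(
    fg_sequences: Mapping[str, str] | Sequence[str],
    width_range: tuple[int, int] = (5, 8),
    allow_wildcards: int = 2,
) -> list[MotifModel]:
    """All foreground substrings in the width range plus their wildcard
    generalizations (up to ``allow_wildcards`` interior 'X'), deduplicated
    and sorted."""
    lo, hi = width_range
    if lo < MIN_WIDTH or hi > MAX_WIDTH or lo > hi:
        raise ValueError(
            f"width_range {width_range} outside [{MIN_WIDTH}, {MAX_WIDTH}]"
        )
    seqs = list(fg_sequences.values()) if isinstance(fg_sequences, Mapping) \
        else list(fg_sequences)
    if len(seqs) < 2:
        raise ValueError("need >= 2 foreground sequences")
    words: set[str] = set()
    for seq in seqs:
        seq = seq.upper()
        for w in range(lo, hi + 1):
            for i in range(len(seq) - w + 1):
                word = seq[i:i + w]
                if set(word) <= set(_AA):
                    words |= _generalize(word, allow_wildcards)
    return [MotifModel(w) for w in sorted(words)]


def score_motif(
    motif: MotifModel,
    fg_sequences: Mapping[str, str],
    bg_sequences: Mapping[str, str],
    record_offsets: bool = True,
) -> MotifEnrichmentResult:
    """Presence/absence enrichment of one motif, foreground vs background.

    A sequence counts once no matter how many matches it has; sequences
    shorter than the motif count as absent (warning logged).
    """
    if not fg_sequences or not bg_sequences:
        raise ValueError("foreground and background must be non-empty")
    shared = set(fg_sequences) & set(bg_sequences)
    if shared:
        raise ValueError(f"fg and bg overlap: {sorted(shared)[:5]!r}")
    short = [sid for sid, s in {**fg_sequences, **bg_sequences}.items()
             if len(s) < motif.width]
    if short:
        logger.warning("motif %s wider than %d sequence(s); counted absent",
                       motif.consensus, len(short))
    pat = motif.pattern()
    fg_hit = {sid for sid, s in fg_sequences.items() if pat.search(s.upper())}
    bg_with = sum(1 for s in bg_sequences.values() if pat.search(s.upper()))
    a, n_fg = len(fg_hit), len(fg_sequences)
    n_bg = len(bg_sequences)
    p = fisher_greater(a, n_fg - a, bg_with, n_bg - bg_with)
    offsets = {}
    if record_offsets:
        offsets = {sid: motif.match_offsets(fg_sequences[sid].upper())
                   for sid in sorted(fg_hit)}
    return MotifEnrichmentResult(
        motif=motif, fg_with=a, fg_total=n_fg,
        bg_with=bg_with, bg_total=n_bg, p_value=p, fg_offsets=offsets,
    )


def score_all(
    candidates: Iterable[MotifModel],
    fg_sequences: Mapping[str, str],
    bg_sequences: Mapping[str, str],
) -> list[MotifEnrichmentResult]:
    """Score every candidate and attach BH q-values over the full set.

    Presence is computed from a word-occurrence index built in one pass
    over the sequences, so the cost is near-linear in total sequence
    length rather than candidates x sequences.
    """
    candidates = list(candidates)
    widths = {m.width for m in candidates}
    max_x = max((m.n_wildcards for m in candidates), default=0)

    def index(seqs: Mapping[str, str]) -> dict[str, set[str]]:
        idx: dict[str, set[str]] = {}
        for sid, seq in seqs.items():
            seq = seq.upper()
            for w in widths:
                for i in range(len(seq) - w + 1):
                    word = seq[i:i + w]
                    if set(word) <= set(_AA):
                        for gen in _generalize(word, max_x):
                            idx.setdefault(gen, set()).add(sid)
        return idx

    fg_idx, bg_idx = index(fg_sequences), index(bg_sequences)
    n_fg, n_bg = len(fg_sequences), len(bg_sequences)
    results = []
    for motif in candidates:
        fg_hit = fg_idx.get(motif.consensus, set())
        a = len(fg_hit)
        bg_with = len(bg_idx.get(motif.consensus, set()))
        p = fisher_greater(a, n_fg - a, bg_with, n_bg - bg_with)
        offsets = {sid: motif.match_offsets(fg_sequences[sid].upper())
                   for sid in sorted(fg_hit)}
        results.append(MotifEnrichmentResult(
            motif=motif, fg_with=a, fg_total=n_fg,
            bg_with=bg_with, bg_total=n_bg, p_value=p, fg_offsets=offsets,
        ))
    if results:
        _, q, _, _ = multipletests([r.p_value for r in results],
                                   method="fdr_bh")
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    return results


def _offsets_overlap(a: tuple[int, ...], wa: int,
                     b: tuple[int, ...], wb: int) -> bool:
    return any(oa < ob + wb and ob < oa + wa for oa in a for ob in b)


def top_motifs(
    results: Sequence[MotifEnrichmentResult],
    n: int = 5,
) -> list[MotifEnrichmentResult]:
    """The ``n`` best motifs by p-value after greedy redundancy removal.

    A candidate is skipped when, for more than 80% of its matched
    foreground sequences, its matches overlap an already selected motif's
    matches at the sequence level (overlapping offset windows).  Ties in p
    break toward more matched foreground sequences, then wider motifs,
    then lexicographic consensus, so a fully specified motif outranks its
    own wildcard generalizations.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    ranked = sorted(
        results,
        key=lambda r: (r.p_value, -r.fg_with, -r.motif.width,
                       r.motif.consensus),
    )
    selected: list[MotifEnrichmentResult] = []
    for cand in ranked:
        if len(selected) == n:
            break
        redundant = False
        for sel in selected:
            common = set(cand.fg_offsets) & set(sel.fg_offsets)
            overlapping = sum(
                1 for sid in common
                if _offsets_overlap(cand.fg_offsets[sid], cand.motif.width,
                                    sel.fg_offsets[sid], sel.motif.width)
            )
            if cand.fg_with and overlapping > 0.8 * cand.fg_with:
                redundant = True
                break
        if not redundant:
            selected.append(cand)
    return selected


def find_motifs(
    fg_sequences: Mapping[str, str],
    bg_sequences: Mapping[str, str],
    width_range: tuple[int, int] = (5, 8),
    allow_wildcards: int = 2,
    n_motifs: int = 5,
) -> list[MotifEnrichmentResult]:
    """End-to-end: enumerate, score, adjust, select top motifs."""
    candidates = enumerate_candidate_motifs(
        fg_sequences, width_range, allow_wildcards
    )
    results = score_all(candidates, fg_sequences, bg_sequences)
    return top_motifs(results, n_motifs)


def write_motif_table(results: Sequence[MotifEnrichmentResult],
                      path: str) -> None:
    with open(path, "w") as fh:
        fh.write("motif\twidth\tfg_with\tfg_total\tfraction_fg_pct\t"
                 "bg_with\tbg_total\tp_value\tq_value\n")
        for r in results:
            fh.write(
                f"{r.motif.consensus}\t{r.motif.width}\t{r.fg_with}\t"
                f"{r.fg_total}\t{r.fraction_fg:.2f}\t{r.bg_with}\t"
                f"{r.bg_total}\t{r.p_value:.6g}\t{r.q_value:.6g}\n"
            )


def write_meme_minimal(results: Sequence[MotifEnrichmentResult],
                       path: str) -> None:
    """MEME minimal motif format (consensus positions as 0/1 frequencies;
    'X' positions uniform), for downstream scanning tools."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= " + _AA + "\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{aa} {1 / len(_AA):.5f}" for aa in _AA) + "\n\n")
        for r in results:
            m = r.motif
            fh.write(f"MOTIF {m.consensus}\n")
            fh.write(f"letter-probability matrix: alength= {len(_AA)} "
                     f"w= {m.width} nsites= {r.fg_with} "
                     f"E= {r.p_value:.3g}\n")
            for ch in m.consensus:
                if ch == "X":
                    row = [1 / len(_AA)] * len(_AA)
                else:
                    row = [1.0 if aa == ch else 0.0 for aa in _AA]
                fh.write(" ".join(f"{v:.5f}" for v in row) + "\n")
            fh.write("\n")
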