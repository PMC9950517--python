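"""Clade assignment of family members by best hit against a reference panel.

Family members are placed into previously defined clades (0-7 plus
subclades such as "1a/b" or "5a") by their best similarity hit against a
panel of biochemically characterized reference enzymes.  Two call sets are
produced per query:

* **Relaxed** — the clade of the best hit, unconditionally.  Every query
  with at least one hit receives a clade.
* **Conservative** — the same clade only if the best hit survives a filter
  (alignment engine: >= 40% identity and >= 200 aligned columns; profile
  engine: e-value <= 1e-50); otherwise "unassigned".  Unassigned members
  flag lineage-specific divergence: candidate novel clades.

Two hit "engines" share one filter contract: an internal Smith-Waterman
local aligner (BLOSUM62, blastp-style affine gaps), or imported BLAST
outfmt-6 / phmmer tabular hits.  Boundary values pass: identity exactly
40.0, match length exactly 200, e-value exactly 1e-50 are all kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ReferencePanel",
    "SimilarityHit",
    "CladeCall",
    "AssignmentThresholds",
    "AlignmentScoring",
    "local_align",
    "align_all",
    "best_hits",
    "assign_clades",
    "clade_census",
]

# Residues representable under BLOSUM62 (includes ambiguity codes and stop).
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZX*")


@dataclass(frozen=True)
class AlignmentScoring:
    """Scoring scheme of the internal local aligner.

    Gap costs follow the blastp convention (open 11, extend 1): a gap of
    length L costs 11 + L, i.e. the first gapped column costs 12.  Bit
    scores use Karlin-Altschul scaling with the standard gapped BLOSUM62
    constants; e-values use a fixed effective search-space parameter.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    ka_lambda: float = 0.267
    ka_k: float = 0.041
    search_space: float = 1e7  # fixed m*n stand-in for a database search

    def bit_score(self, raw: float) -> float:
        return (self.ka_lambda * raw - math.log(self.ka_k)) / math.log(2.0)

    def e_value(self, raw: float) -> float:
        return self.search_space * 2.0 ** (-self.bit_score(raw))


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    target_id: str
    pct_identity: float  # over alignment columns, gaps included
    match_length: int  # alignment columns
    bit_score: float
    e_value: float
    engine: str = "alignment"  # {"alignment", "profile"}


@dataclass(frozen=True)
class AssignmentThresholds:
    min_identity: float = 40.0
    min_match_length: int = 200
    max_evalue_profile: float = 1e-50

    def __post_init__(self):
        if min(self.min_identity, self.min_match_length,
               self.max_evalue_profile) <= 0:
            raise ValueError("thresholds must be positive")

    def passes(self, hit: SimilarityHit) -> bool:
        if hit.engine == "profile":
            return hit.e_value <= self.max_evalue_profile
        return (hit.pct_identity >= self.min_identity
                and hit.match_length >= self.min_match_length)


@dataclass(frozen=True)
class CladeCall:
    query_id: str
    clade: str  # clade label or "unassigned"
    mode: str  # {"relaxed", "conservative"}
    supporting_hit: SimilarityHit | None = None


@dataclass
class ReferencePanel:
    """Characterized reference enzymes with clade labels."""

    entries: list[tuple[str, str, str]]  # (ref_id, clade_label, protein seq)
    _clades: dict[str, str] = field(init=False, repr=False)
    _seqs: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self):
        ids = [rid for rid, _, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("reference panel ids are not unique")
        for rid, _, seq in self.entries:
            if not seq:
                raise ValueError(f"reference {rid}: empty sequence")
            _check_protein(seq, rid)
        self._clades = {rid: clade for rid, clade, _ in self.entries}
        self._seqs = {rid: seq for rid, _, seq in self.entries}

    def clade_of(self, ref_id: str) -> str:
        return self._clades[ref_id]

    def sequence_of(self, ref_id: str) -> str:
        return self._seqs[ref_id]

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._clades

    def ids(self) -> list[str]:
        return [rid for rid, _, _ in self.entries]


def _check_protein(seq: str, name: str) -> None:
    bad = set(seq.upper()) - _AA_ALPHABET
    if bad:
        raise ValueError(
            f"sequence {name}: non-amino-acid characters {sorted(bad)!r}"
        )


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(
        scoring.matrix_name
    )
    # blastp open cost 11 applies before the first gapped column, so the
    # first column of a gap costs open+extend.
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def local_align(
    query: str,
    target: str,
    query_id: str = "query",
    target_id: str = "target",
    scoring: AlignmentScoring = AlignmentScoring(),
) -> SimilarityHit:
    """Smith-Waterman optimal local alignment of two protein sequences.

    Percent identity is identical aligned positions over alignment columns
    (gap columns included, matching BLAST's reporting over alignment
    length); ``match_length`` is the number of alignment columns.  A pair
    with no positive-scoring local alignment yields a zero hit.
    """
    query, target = query.upper(), target.upper()
    if not query or not target:
        raise ValueError("local_align: empty sequence")
    _check_protein(query, query_id)
    _check_protein(target, target_id)
    aligner = _make_aligner(scoring)
    score = aligner.score(query, target)
    if score <= 0:
        return SimilarityHit(query_id, target_id, 0.0, 0, 0.0,
                             float("inf"), "alignment")
    alignment = next(iter(aligner.align(query, target)))
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    return SimilarityHit(
        query_id=query_id,
        target_id=target_id,
        pct_identity=identity,
        match_length=columns,
        bit_score=scoring.bit_score(score),
        e_value=scoring.e_value(score),
        engine="alignment",
    )


def align_all(
    queries: Mapping[str, str],
    panel: ReferencePanel,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> list[SimilarityHit]:
    """Align every query against every panel reference, dropping zero hits."""
    hits = []
    for qid, qseq in queries.items():
        for rid in panel.ids():
            hit = local_align(qseq, panel.sequence_of(rid), qid, rid, scoring)
            if hit.match_length > 0:
                hits.append(hit)
    return hits


def _hit_rank_key(hit: SimilarityHit):
    # Better first: primary criterion per engine, then identity, then
    # match length, then lexicographic target id (deterministic ties).
    primary = (-hit.bit_score if hit.engine == "alignment" else hit.e_value)
    return (primary, -hit.pct_identity, -hit.match_length, hit.target_id)


def best_hits(hits: Sequence[SimilarityHit]) -> dict[str, SimilarityHit]:
    """Best hit per query: max bit score (alignment) or min e-value (profile)."""
    engines = {h.engine for h in hits}
    if len(engines) > 1:
        raise ValueError(f"mixed engines in one best-hit call: {engines}")
    best: dict[str, SimilarityHit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None or _hit_rank_key(hit) < _hit_rank_key(cur):
            best[hit.query_id] = hit
    return best


def assign_clades(
    best: Mapping[str, SimilarityHit],
    panel: ReferencePanel,
    thresholds: AssignmentThresholds = AssignmentThresholds(),
) -> list[CladeCall]:
    """Emit the relaxed and conservative clade call for every query.

    The relaxed call adopts the best hit's clade unconditionally; the
    conservative call keeps it only if the hit passes the engine's filter,
    otherwise "unassigned".
    """
    calls = []
    for qid in sorted(best):
        hit = best[qid]
        if hit.target_id not in panel:
            raise KeyError(
                f"best-hit target {hit.target_id!r} for query {qid!r} "
                "absent from reference panel"
            )
        clade = panel.clade_of(hit.target_id)
        calls.append(CladeCall(qid, clade, "relaxed", hit))
        conservative = clade if thresholds.passes(hit) else "unassigned"
        calls.append(CladeCall(qid, conservative, "conservative", hit))
    return calls


def clade_census(
    calls: Sequence[CladeCall],
    species_map: Mapping[str, str],
    clade_order: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-species x per-clade count table for calls of a single mode.

    Rows are species, columns clades (plus "unassigned" where present);
    row sums equal the per-species family size.  ``clade_order`` (e.g.
    taken from a reference tree) fixes column order; remaining clades
    follow alphabetically.
    """
    modes = {c.mode for c in calls}
    if len(modes) > 1:
        raise ValueError(f"census requires calls of a single mode, got {modes}")
    rows = [
        {"species": species_map.get(c.query_id, "unknown"), "clade": c.clade}
        for c in calls
    ]
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["species", "clade"]).size().unstack(fill_value=0)
        .sort_index()
    )
    if clade_order is not None:
        ordered = [c for c in clade_order if c in table.columns]
        rest = sorted(set(table.columns) - set(ordered))
        table = table[ordered + rest]
    else:
        table = table[sorted(table.columns)]
    table.columns.name = "clade"
    return table
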