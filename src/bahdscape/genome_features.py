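"""Per-gene structural features of family members from genome annotation.

Large enzyme families such as the BAHD acyltransferases show marked shifts
in gene architecture across plant lineages: algal members carry several
(often long) introns while most seed-plant members have none or one.  This
module extracts the four features that summarize that architecture —
intron count, intron lengths, locus length and coding-sequence length —
from a GFF3 annotation, one record per family member, and aggregates them
per species with a cross-species grand mean.

Coordinates follow the GFF3 convention: 1-based, inclusive on both ends,
so every interval length is ``end - start + 1`` and the intron between an
exon ending at ``e`` and the next exon starting at ``s`` spans ``s - e - 1``
bases.  Features are computed on a single representative transcript per
gene: the one with the longest total CDS, ties broken by transcript id.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gffutils

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "Transcript",
    "GeneFeatureRecord",
    "FeatureStats",
    "SpeciesFeatureSummary",
    "GFFParseError",
    "GeneModelError",
    "load_gene_models",
    "select_transcript",
    "compute_features",
    "summarize_species",
    "write_feature_table",
    "write_summary_table",
]

FEATURE_NAMES = ("n_introns", "intron_length", "locus_length", "cds_length")


class GFFParseError(ValueError):
    """A GFF3 line could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class GeneModelError(ValueError):
    """A gene model violates a structural invariant (names the gene)."""


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene locus with its transcripts (1-based, inclusive)."""

    gene_id: str
    species: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: tuple[Transcript, ...]

    def __post_init__(self):
        if self.start > self.end:
            raise GeneModelError(f"gene {self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise GeneModelError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        for tx in self.transcripts:
            for s, e in tx.exons:
                if s < self.start or e > self.end:
                    raise GeneModelError(
                        f"gene {self.gene_id}: exon {s}-{e} outside gene span "
                        f"{self.start}-{self.end}"
                    )


@dataclass(frozen=True)
class GeneFeatureRecord:
    gene_id: str
    species: str
    n_introns: int
    intron_lengths: tuple[int, ...]
    locus_length: int
    cds_length: int


@dataclass(frozen=True)
class FeatureStats:
    mean: float
    median: float
    n: int


@dataclass
class SpeciesFeatureSummary:
    """Per-species feature statistics plus the cross-species grand mean.

    ``grand_means`` maps each feature to the mean of per-species means —
    the "average across all analyzed species" reference line.
    """

    species: str
    features: dict[str, FeatureStats]
    grand_means: dict[str, float] = field(default_factory=dict)


def _prescan_gff(path: str) -> None:
    # gffutils swallows line numbers; validate column structure up front so
    # malformed lines are reported with their position.
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFFParseError(
                    f"expected 9 tab-separated fields, got {len(fields)}", i
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise GFFParseError("non-integer start/end coordinate", i) from None
            if start > end:
                raise GFFParseError(f"start {start} > end {end}", i)


def load_gene_models(
    gff3_path: str,
    id_list: Iterable[str],
    species: str = "unknown",
) -> tuple[list[GeneModel], list[str]]:
    """Load the requested gene models from a GFF3 file.

    Returns ``(models, missing_ids)``: one :class:`GeneModel` per requested
    id found, plus the ids absent from the annotation (reported, never
    silently dropped).
    """
    wanted = list(dict.fromkeys(id_list))
    _prescan_gff(gff3_path)
    db = gffutils.create_db(
        gff3_path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    missing: list[str] = []
    for gid in wanted:
        try:
            gene = db[gid]
        except gffutils.FeatureNotFoundError:
            missing.append(gid)
            continue
        transcripts = []
        for tx in db.children(gene, level=1):
            if tx.featuretype not in {"mRNA", "transcript"}:
                continue
            exons = tuple(
                sorted(
                    (f.start, f.end)
                    for f in db.children(tx, featuretype="exon")
                )
            )
            cds = tuple(
                sorted(
                    (f.start, f.end)
                    for f in db.children(tx, featuretype="CDS")
                )
            )
            transcripts.append(Transcript(tx.id, exons, cds))
        transcripts.sort(key=lambda t: t.transcript_id)
        models.append(
            GeneModel(
                gene_id=gid,
                species=species,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                transcripts=tuple(transcripts),
            )
        )
    if missing:
        logger.warning("%d requested ids absent from %s: %s",
                       len(missing), gff3_path, ", ".join(missing))
    return models, missing


def select_transcript(model: GeneModel) -> Transcript:
    """Representative isoform: longest total CDS, ties by transcript id."""
    coding = [t for t in model.transcripts if t.cds]
    if not coding:
        raise GeneModelError(f"gene {model.gene_id}: no transcript with CDS")
    return min(coding, key=lambda t: (-t.cds_length, t.transcript_id))


def compute_features(model: GeneModel) -> GeneFeatureRecord:
    """Intron count/lengths, locus length and CDS length of one gene.

    Introns are the gaps between consecutive exons of the representative
    transcript; overlapping exons within that transcript are a validation
    error.
    """
    tx = select_transcript(model)
    if not tx.exons:
        raise GeneModelError(f"gene {model.gene_id}: transcript has no exons")
    exons = sorted(tx.exons)
    introns = []
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 <= e1:
            raise GeneModelError(
                f"gene {model.gene_id}: overlapping exons "
                f"{s1}-{e1} and {s2}-{e2} in transcript {tx.transcript_id}"
            )
        introns.append(s2 - e1 - 1)
    return GeneFeatureRecord(
        gene_id=model.gene_id,
        species=model.species,
        n_introns=len(introns),
        intron_lengths=tuple(introns),
        locus_length=model.end - model.start + 1,
        cds_length=tx.cds_length,
    )


def _stats(values: Sequence[float]) -> FeatureStats:
    return FeatureStats(
        mean=float(statistics.fmean(values)) if values else float("nan"),
        median=float(statistics.median(values)) if values else float("nan"),
        n=len(values),
    )


def summarize_species(
    records: Sequence[GeneFeatureRecord],
) -> list[SpeciesFeatureSummary]:
    """Per-species mean/median/n per feature plus the cross-species grand mean.

    Intron lengths are pooled over all introns of a species' family members;
    the other three features contribute one value per gene.  Output is
    ordered by species name.
    """
    if not records:
        raise ValueError("summarize_species: no records")
    by_species: dict[str, list[GeneFeatureRecord]] = {}
    for rec in records:
        by_species.setdefault(rec.species, []).append(rec)

    summaries = []
    for sp in sorted(by_species):
        recs = by_species[sp]
        feats = {
            "n_introns": _stats([r.n_introns for r in recs]),
            "intron_length": _stats(
                [l for r in recs for l in r.intron_lengths]
            ),
            "locus_length": _stats([r.locus_length for r in recs]),
            "cds_length": _stats([r.cds_length for r in recs]),
        }
        summaries.append(SpeciesFeatureSummary(species=sp, features=feats))

    for feat in FEATURE_NAMES:
        means = [s.features[feat].mean for s in summaries
                 if s.features[feat].n > 0]
        grand = float(statistics.fmean(means)) if means else float("nan")
        for s in summaries:
            s.grand_means[feat] = grand
    return summaries


def write_feature_table(records: Sequence[GeneFeatureRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tspecies\tn_introns\tintron_lengths\t"
                 "locus_length\tcds_length\n")
        for r in records:
            lens = ",".join(map(str, r.intron_lengths))
            fh.write(f"{r.gene_id}\t{r.species}\t{r.n_introns}\t{lens}\t"
                     f"{r.locus_length}\t{r.cds_length}\n")


def write_summary_table(summaries: Sequence[SpeciesFeatureSummary], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("species\tfeature\tmean\tmedian\tn\tgrand_mean\n")
        for s in summaries:
            for feat in FEATURE_NAMES:
                st = s.features[feat]
                fh.write(f"{s.species}\t{feat}\t{st.mean:.6g}\t{st.median:.6g}\t"
                         f"{st.n}\t{s.grand_means[feat]:.6g}\n")
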