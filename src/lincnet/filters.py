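"""Candidate lincRNA filtering and genomic feature summaries.

A candidate transcript is kept as a lincRNA iff it is

* at least 200 nt long,
* assembled from an intergenic locus (class code ``u``),
* expressed (RPKM >= 0.5 in at least one sample),
* not similar to a known protein (similarity coverage > 50% AND
  e-value < 1e-5 rejects),
* and flagged non-coding by both coding-potential tools.

The rejection table records the first failed rule per transcript in
that order.  Feature summaries (exon lengths, exon-count proportions,
GC content) operate on a GTF and FASTA with 1-based closed intervals.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

from .errors import CoordinateError, FormatError

logger = logging.getLogger(__name__)

REASONS = ("length", "intergenic", "expression", "protein_similarity",
           "coding_potential")


@dataclass(frozen=True)
class CandidateTranscript:
    transcript_id: str
    locus_id: str
    length: int
    class_code: str
    rpkm: tuple[float, ...]
    similarity: tuple[float, float] | None = None  # (coverage, e-value)
    coding_cpat: bool = False
    coding_cpc: bool = False
    exons: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self):
        if any(v < 0 for v in self.rpkm):
            raise FormatError(f"{self.transcript_id}: negative RPKM")
        if self.similarity is not None:
            cov, ev = self.similarity
            if not 0.0 <= cov <= 1.0:
                raise FormatError(f"{self.transcript_id}: coverage {cov} outside [0,1]")
            if ev < 0:
                raise FormatError(f"{self.transcript_id}: negative e-value")
        if self.exons is not None:
            exon_len = sum(e - s + 1 for s, e in self.exons)
            if exon_len != self.length:
                raise FormatError(
                    f"{self.transcript_id}: length {self.length} != exon sum {exon_len}")


@dataclass(frozen=True)
class FilterThresholds:
    min_length: int = 200
    min_rpkm: float = 0.5
    sim_coverage: float = 0.5
    sim_evalue: float = 1e-5
    intergenic_classes: frozenset[str] = frozenset({"u"})


def rejection_reason(t: CandidateTranscript,
                     th: FilterThresholds = FilterThresholds()) -> str | None:
    """First failed rule, or None if the transcript passes all filters."""
    if t.length < th.min_length:
        return "length"
    if t.class_code not in th.intergenic_classes:
        return "intergenic"
    if not t.rpkm or max(t.rpkm) < th.min_rpkm:
        return "expression"
    if t.similarity is not None:
        cov, ev = t.similarity
        if cov > th.sim_coverage and ev < th.sim_evalue:
            return "protein_similarity"
    if t.coding_cpat or t.coding_cpc:
        return "coding_potential"
    return None


def filter_candidates(records: Sequence[CandidateTranscript],
                      thresholds: FilterThresholds = FilterThresholds(),
                      ) -> tuple[list[CandidateTranscript], pd.DataFrame]:
    """Split candidates into kept lincRNAs and a rejection table
    (columns: transcript_id, reason)."""
    kept, rejected = [], []
    for t in records:
        reason = rejection_reason(t, thresholds)
        if reason is None:
            kept.append(t)
        else:
            rejected.append((t.transcript_id, reason))
    logger.info("filter_candidates: kept %d / %d transcripts",
                len(kept), len(records))
    return kept, pd.DataFrame(rejected, columns=["transcript_id", "reason"])


# ---------------------------------------------------------------------------
# GTF / FASTA feature summaries
# ---------------------------------------------------------------------------

def _gtf_db(gtf_path: str | Path) -> gffutils.FeatureDB:
    return gffutils.create_db(str(gtf_path), dbfn=":memory:", force=True,
                              keep_order=True, merge_strategy="create_unique",
                              disable_infer_genes=True,
                              disable_infer_transcripts=True)


def _transcript_biotype(feature) -> str:
    for key in ("transcript_biotype", "gene_biotype", "biotype"):
        if key in feature.attributes:
            return feature.attributes[key][0]
    return "unknown"


def exon_summaries(gtf_path: str | Path,
                   ) -> tuple[dict[str, list[int]], pd.DataFrame]:
    """Per biotype: every exon's length (end - start + 1) and the
    proportion of transcripts with k exons (k = 1, 2, 3, ...)."""
    db = _gtf_db(gtf_path)
    lengths: dict[str, list[int]] = defaultdict(list)
    exon_counts: dict[str, list[int]] = defaultdict(list)
    for tx in db.features_of_type("transcript"):
        exons = list(db.children(tx, featuretype="exon"))
        if not exons:
            logger.warning("exon_summaries: transcript %s has no exon lines; skipped",
                           tx.id)
            continue
        biotype = _transcript_biotype(tx)
        lengths[biotype].extend(e.end - e.start + 1 for e in exons)
        exon_counts[biotype].append(len(exons))
    rows = []
    for biotype, counts in exon_counts.items():
        total = len(counts)
        for k in sorted(set(counts)):
            rows.append((biotype, k, counts.count(k) / total))
    props = pd.DataFrame(rows, columns=["biotype", "n_exons", "proportion"])
    return dict(lengths), props


def gc_content(fasta_path: str | Path, gtf_path: str | Path) -> dict[str, float]:
    """GC fraction (G+C)/(A+C+G+T) of each transcript's concatenated
    exonic sequence; ambiguous bases are excluded from both counts.
    GC is strand-symmetric, so no reverse complementing is performed."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = _gtf_db(gtf_path)
    out: dict[str, float] = {}
    for tx in db.features_of_type("transcript"):
        parts = []
        for e in db.children(tx, featuretype="exon", order_by="start"):
            seq = seqs.get(e.seqid)
            if seq is None or e.start < 1 or e.end > len(seq):
                raise CoordinateError(
                    f"transcript {tx.id}: exon {e.seqid}:{e.start}-{e.end} "
                    f"outside sequence bounds")
            parts.append(seq[e.start - 1:e.end])
        exonic = "".join(parts)
        gc = sum(exonic.count(b) for b in "GC")
        at = sum(exonic.count(b) for b in "AT")
        out[tx.id] = gc / (gc + at) if gc + at else 0.0
    return out
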