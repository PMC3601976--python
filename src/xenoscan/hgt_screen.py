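"""Taxon-aware four-stage screening cascade for HGT candidate contigs.

The cascade reproduces a translated-homology screen of a parasite
transcriptome against a reference panel containing close nonparasitic
relatives and distantly related donor-candidate (host-lineage) taxa:

1. the contig's top hit must come from a donor-candidate taxon;
2. the contig must be longer than 500 nt, the top donor hit 60-95%
   identical, and its aligned query span at least half the contig;
3. no close relative may appear among the 10 best hits;
4. a contig with any close-relative hit at all is rescued only if its best
   donor bitscore exceeds the best close-relative bitscore by a configurable
   ratio (default 1.2).

Stages 1+2 together correspond to the "initial" screening count in the
funnel report. The module also provides a small translated-search engine —
six-frame translation plus affine-gap local alignment under BLOSUM62 with
Karlin-Altschul bitscores — adequate for fixture-scale databases; it makes
no attempt to replicate a production search tool's heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq
from Bio.Align import substitution_matrices

from xenoscan.io_core import (
    PipelineConfig,
    ScreenThresholds,
    SequenceRecord,
    TaxonGroupMap,
    logger,
    write_hit_table,
)

__all__ = [
    "HitRecord",
    "ScreenReport",
    "ScoringParams",
    "sixframe_translate",
    "translated_search",
    "apply_screen_cascade",
    "run_screen",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class HitRecord:
    """One pairwise translated-search match (outfmt-6 dialect row).

    Query coordinates are 1-based inclusive on the nucleotide contig,
    normalized so q_start <= q_end regardless of strand.
    """

    query_id: str
    subject_id: str
    subject_species: str
    subject_group: str
    percent_identity: float
    align_length_aa: int
    q_start: int
    q_end: int
    evalue: float
    bitscore: float
    mismatches: int = 0
    gap_opens: int = 0
    s_start: int = 1
    s_end: int = 1
    query_frame: int = 0
    subject_frame: int = 0

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: q_start > q_end")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent_identity must be within [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    @property
    def query_span_nt(self) -> int:
        return self.q_end - self.q_start + 1


@dataclass
class ScreenReport:
    """Per-contig cascade outcomes plus funnel totals."""

    per_contig: pd.DataFrame
    funnel: dict[str, int]
    candidates: list[str]

    def __post_init__(self) -> None:
        f = self.funnel
        seq = [f["input"], f["after_initial"], f["after_stage3"], f["after_stage4"]]
        if any(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError(f"funnel counts must be non-increasing: {seq}")

    def to_tsv(self, path) -> None:
        out = self.per_contig.copy()
        out.index.name = "contig_id"
        with Path(path).open("w") as fh:
            for key, val in self.funnel.items():
                fh.write(f"# funnel\t{key}\t{val}\n")
            out.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Translated search engine
# ---------------------------------------------------------------------------


@dataclass
class ScoringParams:
    """Scoring for the internal translated search.

    ``gap_open``/``gap_extend`` follow the convention that a gap of length k
    costs gap_open + (k - 1) * gap_extend. ``lam`` and ``k`` are the
    Karlin-Altschul parameters for gapped BLOSUM62 scoring; the e-values they
    produce are a ranking and cutoff device, not calibrated significance.
    ``word_size`` > 0 enables a shared-word prefilter between frame pairs
    before running the alignment (0 disables it).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    k: float = 0.041
    evalue_cutoff: float = 1e-10
    word_size: int = 5

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix_name)
        aligner.open_gap_score = -float(self.gap_open)
        aligner.extend_gap_score = -float(self.gap_extend)
        return aligner

    def bitscore(self, raw_score: float) -> float:
        return (self.lam * raw_score - log(self.k)) / log(2.0)

    def evalue(self, bitscore: float, m: int, n: int) -> float:
        return float(m) * float(n) * 2.0 ** (-bitscore)


def sixframe_translate(record: SequenceRecord | str) -> dict[int, str]:
    """Translate a nucleotide sequence in all six reading frames.

    Frames +1..+3 read the forward strand with offsets 0..2; frames -1..-3
    read the reverse complement the same way. Standard genetic code, stops
    as '*', trailing partial codons dropped.
    """
    nt = record.residues if isinstance(record, SequenceRecord) else record.upper()
    if len(nt) < 3:
        raise ValueError("sequence shorter than one codon cannot be translated")
    fwd = Seq(nt)
    rev = fwd.reverse_complement()
    frames: dict[int, str] = {}
    for off in range(3):
        for sign, strand in ((1, fwd), (-1, rev)):
            sub = strand[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames[sign * (off + 1)] = str(sub.translate())
    return {f: s for f, s in frames.items() if s}


def _words(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _alignment_stats(alignment) -> tuple[int, int, int, tuple[int, int], tuple[int, int]]:
    """(identities, align_length, gap_opens, q_aa_range, s_aa_range) of a local alignment."""
    qseg, sseg = alignment.aligned
    q = alignment.sequences[0]
    s = alignment.sequences[1]
    identities = 0
    aligned_cols = 0
    for (qs, qe), (ss, se) in zip(qseg, sseg):
        aligned_cols += qe - qs
        identities += sum(1 for a, b in zip(q[qs:qe], s[ss:se]) if a == b)
    gap_cols = 0
    gap_opens = 0
    for i in range(1, len(qseg)):
        dq = qseg[i][0] - qseg[i - 1][1]
        ds = sseg[i][0] - sseg[i - 1][1]
        gap_cols += dq + ds
        gap_opens += (dq > 0) + (ds > 0)
    length = aligned_cols + gap_cols
    q_range = (int(qseg[0][0]), int(qseg[-1][1]))
    s_range = (int(sseg[0][0]), int(sseg[-1][1]))
    return identities, length, gap_opens, q_range, s_range


def _frame_aa_to_nt(frame: int, aa_start: int, aa_end: int, nt_len: int) -> tuple[int, int]:
    """Map an aa interval [aa_start, aa_end) in a frame to 1-based inclusive
    nt coordinates on the forward strand, normalized so start <= end."""
    off = abs(frame) - 1
    lo = off + 3 * aa_start
    hi = off + 3 * aa_end - 1
    if frame < 0:
        lo, hi = nt_len - 1 - hi, nt_len - 1 - lo
    return lo + 1, hi + 1


def translated_search(
    query: SequenceRecord,
    subject_db: Sequence[SequenceRecord],
    scoring: ScoringParams | None = None,
    taxon_map: TaxonGroupMap | None = None,
    _subject_frames: Mapping[str, dict[int, str]] | None = None,
    _subject_words: Mapping[str, dict[int, set[str]]] | None = None,
    _db_aa_length: int | None = None,
) -> list[HitRecord]:
    """Best-scoring translated hit of one query against each subject.

    For every query x subject pair the best local alignment score over all
    36 frame pairs is found; bitscore = (lambda*S - ln K)/ln 2 and
    evalue = m*n*2^(-bitscore) with m the query and n the whole-database
    amino-acid search-space lengths. Hits above the e-value cutoff are
    dropped; output is sorted by bitscore desc, evalue asc, subject id.
    """
    scoring = scoring or ScoringParams()
    if not subject_db:
        return []
    aligner = scoring.make_aligner()
    try:
        q_frames = sixframe_translate(query)
    except ValueError:
        return []
    m = len(query.residues) // 3
    n_db = _db_aa_length
    if n_db is None:
        n_db = sum(len(s.residues) // 3 for s in subject_db)
    q_words = (
        {f: _words(aa, scoring.word_size) for f, aa in q_frames.items()}
        if scoring.word_size > 0
        else None
    )

    hits: list[HitRecord] = []
    for subject in subject_db:
        if _subject_frames is not None and subject.id in _subject_frames:
            s_frames = _subject_frames[subject.id]
        else:
            s_frames = sixframe_translate(subject)
        if scoring.word_size > 0:
            if _subject_words is not None and subject.id in _subject_words:
                s_words = _subject_words[subject.id]
            else:
                s_words = {f: _words(aa, scoring.word_size) for f, aa in s_frames.items()}
        else:
            s_words = None
        best = None  # (score, qf, sf)
        for qf, q_aa in q_frames.items():
            for sf, s_aa in s_frames.items():
                if q_words is not None and not (q_words[qf] & s_words[sf]):
                    continue
                score = aligner.score(q_aa, s_aa)
                if best is None or score > best[0]:
                    best = (score, qf, sf)
        if best is None or best[0] <= 0:
            continue
        score, qf, sf = best
        bit = scoring.bitscore(score)
        evalue = scoring.evalue(bit, m, n_db)
        if evalue > scoring.evalue_cutoff:
            continue
        alignment = aligner.align(q_frames[qf], s_frames[sf])[0]
        identities, alen, gap_opens, q_rng, s_rng = _alignment_stats(alignment)
        q_start, q_end = _frame_aa_to_nt(qf, q_rng[0], q_rng[1], len(query.residues))
        s_start, s_end = _frame_aa_to_nt(sf, s_rng[0], s_rng[1], len(subject.residues))
        species = subject.species or subject.id.split("|", 1)[0]
        group = subject.group
        if taxon_map is not None:
            group = taxon_map.group_of(species)
        hits.append(
            HitRecord(
                query_id=query.id,
                subject_id=subject.id,
                subject_species=species,
                subject_group=group,
                percent_identity=100.0 * identities / alen,
                align_length_aa=alen,
                q_start=q_start,
                q_end=q_end,
                evalue=evalue,
                bitscore=bit,
                mismatches=alen - identities,
                gap_opens=gap_opens,
                s_start=s_start,
                s_end=s_end,
                query_frame=qf,
                subject_frame=sf,
            )
        )
    hits.sort(key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
    return hits


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------

_HIT_SORT_KEY = lambda h: (-h.bitscore, h.evalue, h.subject_id)  # noqa: E731


def apply_screen_cascade(
    hits_by_contig: Mapping[str, Sequence[HitRecord]],
    contig_lengths: Mapping[str, int],
    taxon_map: TaxonGroupMap,
    thresholds: ScreenThresholds | None = None,
) -> ScreenReport:
    """Apply the four-stage cascade to per-contig hit lists.

    A pure function of its inputs: permuting contig order permutes rows but
    never changes per-contig outcomes. Every subject species must resolve in
    the taxon map.
    """
    thr = thresholds or ScreenThresholds()
    thr.validate()
    rows = []
    candidates = []
    n_initial = n_s3 = n_s4 = 0
    for contig_id in sorted(contig_lengths):
        length = contig_lengths[contig_id]
        hits = sorted(hits_by_contig.get(contig_id, ()), key=_HIT_SORT_KEY)
        groups = [taxon_map.group_of(h.subject_species) for h in hits]

        stage = dict.fromkeys(("stage1", "stage2", "stage3", "stage4"), False)
        reason = ""
        rescued = False
        while True:
            # Stage 1: donor-candidate taxon must be the single top hit.
            if not hits:
                reason = "stage1: no hits"
                break
            if groups[0] != "donor_candidate":
                reason = f"stage1: top hit {hits[0].subject_species} is {groups[0]}"
                break
            stage["stage1"] = True

            # Stage 2: length, identity window and aligned-span filters on
            # the top donor hit.
            top = hits[0]
            if length <= thr.min_contig_length:
                reason = f"stage2: contig length {length} <= {thr.min_contig_length}"
                break
            if not (thr.min_identity <= top.percent_identity <= thr.max_identity):
                reason = (
                    f"stage2: identity {top.percent_identity:.1f}% outside "
                    f"[{thr.min_identity:g}, {thr.max_identity:g}]"
                )
                break
            if top.query_span_nt < thr.min_span_fraction * length:
                reason = (
                    f"stage2: aligned span {top.query_span_nt} nt < "
                    f"{thr.min_span_fraction:.0%} of contig"
                )
                break
            stage["stage2"] = True

            # Stage 3: close relatives must be absent from the best hits.
            top_n = groups[: thr.top_n_exclusion]
            if "close_relative" in top_n:
                reason = "stage3: close relative among top hits"
                break
            stage["stage3"] = True

            # Stage 4: any close-relative hit anywhere must be much weaker
            # than the best donor hit.
            close_bits = [h.bitscore for h, g in zip(hits, groups) if g == "close_relative"]
            if close_bits:
                donor_bits = [h.bitscore for h, g in zip(hits, groups) if g == "donor_candidate"]
                ratio = max(donor_bits) / max(close_bits)
                if ratio < thr.stage4_bitscore_ratio:
                    reason = (
                        f"stage4: donor/close bitscore ratio {ratio:.2f} < "
                        f"{thr.stage4_bitscore_ratio:g}"
                    )
                    break
                rescued = True
            stage["stage4"] = True
            break

        is_candidate = all(stage.values())
        if stage["stage1"] and stage["stage2"]:
            n_initial += 1
        if stage["stage3"]:
            n_s3 += 1
        if stage["stage4"]:
            n_s4 += 1
        if is_candidate:
            candidates.append(contig_id)
        rows.append(
            {
                "contig_id": contig_id,
                **stage,
                "candidate": is_candidate,
                "stage4_rescued": rescued,
                "failure_reason": reason,
            }
        )

    if rows:
        per_contig = pd.DataFrame(rows).set_index("contig_id")
    else:
        per_contig = pd.DataFrame(
            columns=["stage1", "stage2", "stage3", "stage4", "candidate",
                     "stage4_rescued", "failure_reason"]
        ).rename_axis("contig_id")
    funnel = {
        "input": len(contig_lengths),
        "after_initial": n_initial,
        "after_stage3": n_s3,
        "after_stage4": n_s4,
    }
    return ScreenReport(per_contig=per_contig, funnel=funnel, candidates=candidates)


def run_screen(
    contigs: Sequence[SequenceRecord],
    reference_db: Sequence[SequenceRecord],
    taxon_map: TaxonGroupMap,
    config: PipelineConfig | None = None,
    hits_by_contig: Mapping[str, Sequence[HitRecord]] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[ScreenReport, dict[str, list[HitRecord]]]:
    """Run the translated search plus cascade over a contig set.

    Externally produced outfmt-6 hit tables may be supplied through
    ``hits_by_contig``, in which case the internal engine is skipped and the
    cascade runs on the imported hits. When ``out_dir`` is given, the hit
    tables and the cascade report are persisted there.
    """
    config = config or PipelineConfig()
    scoring = ScoringParams(evalue_cutoff=config.thresholds.evalue_cutoff)
    contig_lengths = {c.id: len(c.residues) for c in contigs}

    if hits_by_contig is None:
        frames = {s.id: sixframe_translate(s) for s in reference_db if len(s.residues) >= 3}
        words = (
            {
                sid: {f: _words(aa, scoring.word_size) for f, aa in fr.items()}
                for sid, fr in frames.items()
            }
            if scoring.word_size > 0
            else None
        )
        db_aa = sum(len(s.residues) // 3 for s in reference_db)
        hits_by_contig = {}
        for contig in contigs:
            hits_by_contig[contig.id] = translated_search(
                contig,
                reference_db,
                scoring=scoring,
                taxon_map=taxon_map,
                _subject_frames=frames,
                _subject_words=words,
                _db_aa_length=db_aa,
            )
        logger.info("translated search done: %d contigs vs %d references", len(contigs), len(reference_db))

    report = apply_screen_cascade(hits_by_contig, contig_lengths, taxon_map, config.thresholds)
    logger.info(
        "screen funnel: %s -> candidates %s", report.funnel, report.candidates
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        all_hits = [h for cid in sorted(hits_by_contig) for h in hits_by_contig[cid]]
        write_hit_table(all_hits, out / "hits.outfmt6.tsv")
        report.to_tsv(out / "screen_report.tsv")
    return report, dict(hits_by_contig)
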