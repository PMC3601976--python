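"""Structural validation of candidate xenogenes.

Covers ORF finding, single-intron inference by genomic-vs-CDS comparison,
canonical GT..AG splice-site checks, cross-species intron-position
conservation, protein identity/similarity over ungapped alignment columns,
and a rule-based cysteine-scaffold score for the six-cysteine KNOTTIN fold
of albumin-1-like proteins. The scaffold score is an original sequence-level
statistic: it checks the cysteine count and the inter-cysteine loop lengths
against windows derived from a packaged profile alignment, and is calibrated
so profile-like sequences pass while shuffled controls fail.

Intervals are 0-based half-open internally; GFF3 output is 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from xenoscan.io_core import SequenceRecord, read_fasta

__all__ = [
    "GeneStructure",
    "ScaffoldScore",
    "ScaffoldProfile",
    "find_orf",
    "infer_intron",
    "check_splice_sites",
    "intron_conservation",
    "alignment_identity_similarity",
    "cysteine_scaffold_score",
    "write_gff3",
]


@dataclass
class GeneStructure:
    """Exon/intron layout of a single-intron gene on its genomic sequence."""

    gene_id: str
    exons: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int], ...]
    donor_dinucleotide: str = ""
    acceptor_dinucleotide: str = ""
    phase: int = 0

    def __post_init__(self) -> None:
        ivs = sorted(self.exons + self.introns)
        for (a, b) in ivs:
            if a >= b:
                raise ValueError("empty or inverted interval in gene structure")
        for (_, b), (c, _) in zip(ivs, ivs[1:]):
            if c < b:
                raise ValueError("overlapping intervals in gene structure")
        if self.phase not in (0, 1, 2):
            raise ValueError("intron phase must be 0, 1 or 2")

    def spliced(self, genomic: str) -> str:
        return "".join(genomic[a:b] for a, b in self.exons)

    def intron_seq(self, genomic: str, index: int = 0) -> str:
        a, b = self.introns[index]
        return genomic[a:b]


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------


def find_orf(nt: str, min_codons: int = 30) -> dict:
    """Longest ATG-initiated open reading frame over all six frames.

    The ORF runs from an ATG to the first in-frame stop (included) or the
    frame end. Ties are broken by the earliest start on the forward-mapped
    coordinate, then by forward strand. Returns the CDS, frame, strand and
    0-based half-open coordinates on the input sequence.
    """
    nt = nt.upper()
    if len(nt) < 6:
        raise ValueError("sequence too short for ORF finding")
    candidates = []
    for strand, seq in ((1, nt), (-1, str(Seq(nt).reverse_complement()))):
        for off in range(3):
            frame = seq[off:]
            frame = frame[: len(frame) - len(frame) % 3]
            aa = str(Seq(frame).translate())
            i = 0
            while i < len(aa):
                if aa[i] == "M":
                    stop = aa.find("*", i)
                    end_codon = stop + 1 if stop != -1 else len(aa)
                    n_sense = (stop if stop != -1 else len(aa)) - i
                    cds = frame[3 * i : 3 * end_codon]
                    start_nt = off + 3 * i
                    end_nt = off + 3 * end_codon
                    if strand == 1:
                        coords = (start_nt, end_nt)
                    else:
                        coords = (len(nt) - end_nt, len(nt) - start_nt)
                    if n_sense >= min_codons:
                        candidates.append(
                            {
                                "cds": cds,
                                "n_codons": n_sense,
                                "frame": (1 if strand == 1 else -1) * (off + 1),
                                "strand": strand,
                                "start": coords[0],
                                "end": coords[1],
                            }
                        )
                    i = end_codon if stop != -1 else len(aa)
                else:
                    i += 1
    if not candidates:
        raise ValueError(f"no ATG-initiated ORF of >= {min_codons} codons found")
    candidates.sort(key=lambda c: (-c["n_codons"], c["start"], 0 if c["strand"] == 1 else 1))
    return candidates[0]


# ---------------------------------------------------------------------------
# Intron inference
# ---------------------------------------------------------------------------


def _prefix_mismatches(a: str, b: str) -> list[int]:
    """Cumulative mismatch count of a[:i] vs b[:i] for i in 0..min length."""
    out = [0]
    for x, y in zip(a, b):
        out.append(out[-1] + (x != y))
    return out


def infer_intron(genomic: str, cds: str, max_mismatch: int = 0, gene_id: str = "gene") -> GeneStructure:
    """Infer the single intron separating a CDS from its genomic sequence.

    Finds splits cds = prefix + suffix with genomic = prefix·intron·suffix,
    allowing up to ``max_mismatch`` exonic mismatches. Among valid splits the
    one whose intron starts GT and ends AG is preferred, then the longest
    prefix. Raises when no single-intron decomposition exists.
    """
    genomic, cds = genomic.upper(), cds.upper()
    intron_len = len(genomic) - len(cds)
    if intron_len < 1:
        raise ValueError("structure not single-intron: genomic not longer than cds")
    pref = _prefix_mismatches(genomic, cds)
    suff = _prefix_mismatches(genomic[::-1], cds[::-1])
    solutions = []
    for k in range(len(cds) + 1):
        mism = pref[k] + suff[len(cds) - k]
        if mism <= max_mismatch:
            intron = genomic[k : k + intron_len]
            canonical = intron.startswith("GT") and intron.endswith("AG")
            solutions.append((k, canonical, mism))
    if not solutions:
        raise ValueError("structure not single-intron: no valid decomposition")
    solutions.sort(key=lambda s: (not s[1], -s[0]))
    k, _, _ = solutions[0]
    intron = genomic[k : k + intron_len]
    return GeneStructure(
        gene_id=gene_id,
        exons=tuple(
            iv
            for iv in ((0, k), (k + intron_len, len(genomic)))
            if iv[0] < iv[1]
        ),
        introns=((k, k + intron_len),),
        donor_dinucleotide=intron[:2],
        acceptor_dinucleotide=intron[-2:],
        phase=k % 3,
    )


def check_splice_sites(structure: GeneStructure, genomic: str) -> dict[str, bool]:
    """Canonical GT (donor) / AG (acceptor) flags for each intron."""
    intron = structure.intron_seq(genomic)
    return {
        "donor_canonical": intron.startswith("GT"),
        "acceptor_canonical": intron.endswith("AG"),
    }


def intron_conservation(
    structure_a: GeneStructure,
    genomic_a: str,
    structure_b: GeneStructure,
    genomic_b: str,
    cds_alignment: Mapping[str, str],
) -> dict:
    """Compare intron positions of two genes through a CDS alignment.

    ``same_start`` is true when both introns interrupt the coding sequence at
    the same alignment column with equal phase; ``shared_prefix_len`` is the
    identical run length from the two introns' 5' ends.
    """
    try:
        aln_a = cds_alignment[structure_a.gene_id]
        aln_b = cds_alignment[structure_b.gene_id]
    except KeyError as exc:
        raise KeyError(f"CDS {exc.args[0]!r} absent from alignment") from None

    def insertion_column(structure: GeneStructure, aligned: str) -> int:
        k = structure.exons[0][1] - structure.exons[0][0]
        count = 0
        for col, ch in enumerate(aligned):
            if ch != "-":
                count += 1
            if count == k:
                return col + 1
        raise ValueError("intron position beyond aligned CDS length")

    col_a = insertion_column(structure_a, aln_a)
    col_b = insertion_column(structure_b, aln_b)
    same_start = col_a == col_b and structure_a.phase == structure_b.phase

    ia = structure_a.intron_seq(genomic_a)
    ib = structure_b.intron_seq(genomic_b)
    shared = 0
    for x, y in zip(ia, ib):
        if x != y:
            break
        shared += 1
    return {"same_start": same_start, "shared_prefix_len": shared}


# ---------------------------------------------------------------------------
# Identity / similarity
# ---------------------------------------------------------------------------


def alignment_identity_similarity(
    aligned_a: str, aligned_b: str, matrix_name: str = "BLOSUM62"
) -> dict[str, float]:
    """Percent identity and similarity over ungapped alignment columns.

    Similarity counts identities plus conservative substitutions, defined as
    residue pairs with a positive substitution-matrix score.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    matrix = substitution_matrices.load(matrix_name)
    ident = simil = total = 0
    for a, b in zip(aligned_a.upper(), aligned_b.upper()):
        if a == "-" or b == "-":
            continue
        total += 1
        if a == b:
            ident += 1
            simil += 1
        elif matrix[a, b] > 0:
            simil += 1
    if total == 0:
        raise ValueError("no ungapped columns to compare")
    return {
        "percent_identity": 100.0 * ident / total,
        "percent_similarity": 100.0 * simil / total,
        "ungapped_columns": total,
    }


# ---------------------------------------------------------------------------
# Cysteine scaffold scoring
# ---------------------------------------------------------------------------


@dataclass
class ScaffoldScore:
    """Outcome of the cysteine-scaffold screen for one protein."""

    cysteine_count: int
    cysteine_positions: tuple[int, ...]
    loop_lengths: tuple[int, ...]
    subscores: dict[str, float] = field(default_factory=dict)
    total: float = 0.0
    threshold: float = 0.0
    passed: bool = False


@dataclass
class ScaffoldProfile:
    """Expected cysteine scaffold: count, loop-length windows and weights.

    Loop windows are derived from a profile alignment as the min/max loop
    length per inter-cysteine segment, widened by ``slack`` residues on each
    side. The default weights make the pass threshold reachable only by
    sequences with the full cysteine count and most loops inside their
    windows, which shuffled controls essentially never achieve.
    """

    expected_count: int = 6
    loop_windows: tuple[tuple[int, int], ...] = ()
    count_weight: float = 10.0
    loop_weight: float = 2.0
    terminal_weight: float = 1.0
    threshold: float = 18.0

    @classmethod
    def from_alignment(
        cls, records: Sequence[SequenceRecord], slack: int = 2, **kwargs
    ) -> "ScaffoldProfile":
        loops_per_seq = []
        counts = set()
        for rec in records:
            seq = rec.residues.replace("-", "")
            pos = [i for i, ch in enumerate(seq) if ch == "C"]
            counts.add(len(pos))
            loops_per_seq.append([b - a - 1 for a, b in zip(pos, pos[1:])])
        if len(counts) != 1:
            raise ValueError(f"profile sequences disagree on cysteine count: {sorted(counts)}")
        count = counts.pop()
        windows = tuple(
            (max(0, min(l[i] for l in loops_per_seq) - slack), max(l[i] for l in loops_per_seq) + slack)
            for i in range(count - 1)
        )
        return cls(expected_count=count, loop_windows=windows, **kwargs)

    @classmethod
    def default(cls) -> "ScaffoldProfile":
        """Profile from the packaged synthetic albumin-1-like sequence set
        (six-cysteine knottin-style spacing; synthetic, not curated data)."""
        path = resources.files("xenoscan.data") / "albumin1_synthetic.faa"
        with resources.as_file(path) as p:
            return cls.from_alignment(read_fasta(p, alphabet="aa"))


def cysteine_scaffold_score(
    protein: str | SequenceRecord, profile: ScaffoldProfile | None = None
) -> ScaffoldScore:
    """Score a protein against the six-cysteine scaffold profile.

    Subscores: full expected cysteine count (count_weight); each
    inter-cysteine loop length inside its profiled window (loop_weight each);
    no cysteine within the final two residues (terminal_weight). The protein
    passes when the subscore total reaches the profile threshold.
    """
    seq = protein.residues if isinstance(protein, SequenceRecord) else protein.upper()
    if len(seq) < 30:
        raise ValueError("protein shorter than 30 aa cannot be scored")
    profile = profile or ScaffoldProfile.default()
    positions = tuple(i for i, ch in enumerate(seq) if ch == "C")
    loops = tuple(b - a - 1 for a, b in zip(positions, positions[1:]))

    subscores: dict[str, float] = {}
    subscores["cysteine_count"] = (
        profile.count_weight if len(positions) == profile.expected_count else 0.0
    )
    n_loop_ok = 0
    if len(positions) == profile.expected_count:
        for i, (lo, hi) in enumerate(profile.loop_windows):
            ok = lo <= loops[i] <= hi
            subscores[f"loop_{i + 1}"] = profile.loop_weight if ok else 0.0
            n_loop_ok += ok
    subscores["terminal"] = (
        profile.terminal_weight if not any(p >= len(seq) - 2 for p in positions) else 0.0
    )
    total = sum(subscores.values())
    return ScaffoldScore(
        cysteine_count=len(positions),
        cysteine_positions=positions,
        loop_lengths=loops,
        subscores=subscores,
        total=total,
        threshold=profile.threshold,
        passed=total >= profile.threshold,
    )


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def write_gff3(structure: GeneStructure, seq_id: str, path: str | Path) -> None:
    """Write the gene structure as GFF3 (1-based inclusive, CDS phase)."""
    lines = ["##gff-version 3"]
    gid = structure.gene_id
    start = min(a for a, _ in structure.exons) + 1
    end = max(b for _, b in structure.exons)
    lines.append(f"{seq_id}\txenoscan\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}")
    consumed = 0
    for i, (a, b) in enumerate(structure.exons, start=1):
        phase = (3 - consumed % 3) % 3
        lines.append(
            f"{seq_id}\txenoscan\tCDS\t{a + 1}\t{b}\t.\t+\t{phase}\tID={gid}.cds{i};Parent={gid}"
        )
        consumed += b - a
    for i, (a, b) in enumerate(structure.introns, start=1):
        lines.append(
            f"{seq_id}\txenoscan\tintron\t{a + 1}\t{b}\t.\t+\t.\tID={gid}.intron{i};Parent={gid}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
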