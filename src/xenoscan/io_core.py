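"""Core domain types, file formats and reproducibility plumbing.

Sequences travel as :class:`SequenceRecord`, translated-search matches as
:class:`~xenoscan.hgt_screen.HitRecord` rows in BLAST tabular (outfmt-6)
dialect, and trees as :mod:`dendropy` ``Tree`` objects read/written as newick.
All randomness in the pipeline flows from a single integer seed through
:func:`substream`, which derives an independent named stream per module.

Coordinates are 0-based half-open internally; every emitted table uses
1-based inclusive coordinates, matching the external formats.
"""

from __future__ import annotations

import logging
import sys
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal, Sequence

import dendropy
import numpy as np
import yaml
from Bio import SeqIO

logger = logging.getLogger("xenoscan")

NT_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZJUOX*")

GROUPS = ("self", "close_relative", "donor_candidate", "other", "unknown")

Group = Literal["self", "close_relative", "donor_candidate", "other", "unknown"]


def setup_logging(level: int = logging.INFO) -> None:
    """Route pipeline logging to standard error with level prefixes."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(levelname)s] %(name)s: %(message)s"))
    root = logging.getLogger("xenoscan")
    root.handlers[:] = [handler]
    root.setLevel(level)


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a named, independent random stream derived from a single seed.

    The stream key mixes the seed with a CRC32 of the name, so modules that
    draw in different orders cannot perturb one another and the whole pipeline
    is reproducible from one integer.
    """
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


# ---------------------------------------------------------------------------
# Sequence records
# ---------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    """A named nucleotide or protein sequence with a taxon-group role.

    ``group`` classifies the source species relative to the focal parasite:
    ``self`` (the parasite itself), ``close_relative`` (nonparasitic sister
    taxa whose presence among hits argues for vertical inheritance),
    ``donor_candidate`` (the distantly related host-lineage taxa a transfer
    would come from), ``other``, or ``unknown``.
    """

    id: str
    residues: str
    alphabet: Literal["nt", "aa"] = "nt"
    species: str = ""
    group: Group = "unknown"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        self.residues = self.residues.upper()
        allowed = NT_ALPHABET if self.alphabet == "nt" else AA_ALPHABET
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: residues {sorted(bad)} invalid for "
                f"alphabet {self.alphabet!r}"
            )
        if self.group not in GROUPS:
            raise ValueError(f"sequence {self.id!r}: unknown group {self.group!r}")

    def __len__(self) -> int:
        return len(self.residues)


def _guess_alphabet(residues: str) -> str:
    return "nt" if set(residues.upper()) <= NT_ALPHABET else "aa"


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased; records keep file order; the taxon group is
    ``unknown`` until annotated through a :class:`TaxonGroupMap`. Duplicate
    ids and empty files are rejected rather than repaired.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        records.append(
            SequenceRecord(
                id=rec.id,
                residues=residues,
                alphabet=alphabet or _guess_alphabet(residues),
            )
        )
    if not records:
        raise ValueError(f"{path}: no sequences")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Taxon-group map
# ---------------------------------------------------------------------------


@dataclass
class TaxonGroupMap:
    """Maps reference species names to their taxon-group role.

    The screen needs at least one close relative (to argue against transfer)
    and one donor-candidate species (to argue for it); the constructor
    enforces that. ``donor_labels`` optionally names the donor families for
    reports.
    """

    species_to_group: dict[str, str]
    donor_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for sp, grp in self.species_to_group.items():
            if grp not in GROUPS:
                raise ValueError(f"species {sp!r}: unknown group {grp!r}")
        groups = set(self.species_to_group.values())
        if "close_relative" not in groups or "donor_candidate" not in groups:
            raise ValueError(
                "taxon map must include at least one close_relative and one "
                "donor_candidate species"
            )

    def group_of(self, species: str) -> str:
        try:
            return self.species_to_group[species]
        except KeyError:
            raise KeyError(f"species {species!r} not present in taxon-group map") from None

    def annotate(self, records: Sequence[SequenceRecord]) -> None:
        """Set species and group on records whose id encodes the species.

        Reference ids follow the ``Species|gene`` convention used throughout
        the pipeline; a bare id is treated as the species name itself.
        """
        for rec in records:
            species = rec.id.split("|", 1)[0] if "|" in rec.id else rec.id
            if species in self.species_to_group:
                rec.species = species
                rec.group = self.species_to_group[species]  # type: ignore[assignment]

    @classmethod
    def from_dict(cls, data: dict) -> "TaxonGroupMap":
        return cls(
            species_to_group=dict(data["species_to_group"]),
            donor_labels=tuple(data.get("donor_labels", ())),
        )


def species_of_subject(subject_id: str) -> str:
    """Species encoded in a reference sequence id (``Species|gene``)."""
    return subject_id.split("|", 1)[0] if "|" in subject_id else subject_id


# ---------------------------------------------------------------------------
# Hit tables (BLAST tabular, outfmt-6 dialect)
# ---------------------------------------------------------------------------

OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_hit_table(path: str | Path):
    """Read a 12-column BLAST tabular (outfmt-6) file into HitRecords.

    Rows are kept in file order. Query coordinates are 1-based inclusive on
    the nucleotide contig. Extra columns beyond 12 are ignored with a warning;
    short rows are an error naming the offending line.
    """
    from xenoscan.hgt_screen import HitRecord

    path = Path(path)
    hits: list[HitRecord] = []
    warned = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            if len(fields) > 12 and not warned:
                logger.warning("%s: extra columns beyond 12 ignored", path)
                warned = True
            try:
                hits.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        subject_species=species_of_subject(fields[1]),
                        subject_group="unknown",
                        percent_identity=float(fields[2]),
                        align_length_aa=int(fields[3]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                    )
                )
            except (ValueError, TypeError) as exc:
                if "expected 12" in str(exc):
                    raise
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
    return hits


def write_hit_table(hits, path: str | Path) -> None:
    """Write HitRecords as 12-column outfmt-6 (1-based inclusive coords)."""
    path = Path(path)
    with path.open("w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        str(h.align_length_aa),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.evalue:.2e}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a newick tree; raises on syntax errors rather than repairing."""
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"{path}: newick parse error: {exc}") from exc


def parse_tree(newick: str) -> dendropy.Tree:
    """Parse a newick string (same semantics as :func:`read_tree`)."""
    try:
        return dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as exc:
        raise ValueError(f"newick parse error: {exc}") from exc


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    """Write newick preserving branch lengths to better than 1e-9."""
    Path(path).write_text(tree_to_newick(tree))


def tree_to_newick(tree: dendropy.Tree) -> str:
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".10g",
        ).strip()
        + "\n"
    )


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class ScreenThresholds:
    """Cascade thresholds.

    Defaults mirror the published screen: contigs longer than 500 nt, top
    donor-hit identity within [60, 95] percent, aligned query span at least
    half the contig, e-value cutoffs of 1e-10, and a stage-4 rescue requiring
    the best donor bitscore to exceed the best close-relative bitscore by a
    configurable ratio.
    """

    evalue_cutoff: float = 1e-10
    min_contig_length: int = 500       # strictly greater than
    min_identity: float = 60.0         # inclusive
    max_identity: float = 95.0         # inclusive
    min_span_fraction: float = 0.5
    top_n_exclusion: int = 10
    stage4_bitscore_ratio: float = 1.2

    def validate(self) -> None:
        if not (0 <= self.min_identity <= self.max_identity <= 100):
            raise ValueError("identity bounds must satisfy 0 <= min <= max <= 100")
        if not (0 < self.min_span_fraction <= 1):
            raise ValueError("min_span_fraction must be in (0, 1]")
        if self.stage4_bitscore_ratio < 1:
            raise ValueError("stage4_bitscore_ratio must be >= 1")
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")


@dataclass
class PipelineConfig:
    """All pipeline thresholds and paths, loadable from a YAML config."""

    seed: int = 0
    out_dir: str = "xenoscan_out"
    thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    scenario: dict = field(default_factory=dict)
    taxon_map: dict = field(default_factory=dict)
    scaffold_threshold: float = 18.0
    n_bootstrap: int = 1000
    n_rell: int = 1000
    calibration_age: float = 39.0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise ValueError("seed must be an integer")
        self.thresholds.validate()

    def run(self, stages: tuple[str, ...] = ("all",)):
        """Execute the pipeline for this configuration (see
        :func:`xenoscan.pipeline.run_pipeline`)."""
        from xenoscan.pipeline import run_pipeline

        return run_pipeline(self, stages=stages)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        thr = ScreenThresholds(**data.pop("thresholds", {}))
        return cls(thresholds=thr, **data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
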