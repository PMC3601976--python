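"""Synthetic host/parasite datasets with planted horizontal transfers.

The generator emulates the study system behind the pipeline: a donor (host)
clade of papilionoid-legume-like taxa, a parasite clade, and a single
horizontal transfer of a gene into the parasite stem lineage followed by one
gene duplication inside a parasite subclade. Around that planted xenolog it
emits a background of vertically inherited gene families (each with a
close-relative ortholog at small divergence, so the screening cascade rejects
them), single-intron gene structures with canonical GT..AG splice sites, a
six-cysteine codon-level constraint, and stage-structured expression with a
>1000-fold dynamic range across eight developmental stages.

Everything is deterministic given (scenario, seed): sequence evolution uses
per-branch transition matrices (matrix exponentials) rather than event
sampling, and reads are exact substrings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm

from xenoscan._codons import (
    CODON_INDEX,
    NUC_INDEX,
    NUCS,
    SENSE_CODONS,
    STOP_CODONS,
    is_transition,
    translate_codon,
)
from xenoscan.io_core import SequenceRecord, TaxonGroupMap, substream

__all__ = [
    "SimScenario",
    "TruthTable",
    "simulate_gene_tree_with_hgt",
    "evolve_nt",
    "evolve_codon",
    "make_transcriptome_fixture",
    "make_genomic_with_intron",
    "simulate_stage_reads",
]

STAGE_NAMES = ("stg0", "stg1", "stg2", "stg3", "stg4", "stg5", "stg6_1", "stg6_2")

# Per-stage mean RPKM for the planted xenolog: lowest at the haustorial
# attachment stage (stg3), highest in reproductive tissue (stg6_2), with a
# >1000-fold range between them.
DEFAULT_EXPRESSION_PROFILE = (40.0, 60.0, 25.0, 0.5, 15.0, 90.0, 250.0, 520.0)


@dataclass
class SimScenario:
    """Parameters of the simulated transfer history.

    Ages are in millions of years (My); the transfer at 16 My into the
    parasite stem, the parasite crown split at 11 My and the duplication at
    5 My mirror the dated history the pipeline is meant to recover, with the
    donor-clade crown at 39 My serving as the calibration node.
    ``subst_rate`` is in substitutions/site/My.
    """

    n_host_taxa: int = 6
    n_parasite_taxa: int = 4
    root_age: float = 39.0
    transfer_age: float = 16.0
    split_age: float = 11.0
    duplication_age: float = 5.0
    outgroup_age: float = 50.0
    subst_rate: float = 0.006
    kappa: float = 2.0
    pi: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    omega_classes: tuple[tuple[float, float], ...] = ((0.1, 0.6), (0.5, 0.3), (1.0, 0.1))
    intron_length: int = 120
    xenolog_n_codons: int = 200
    n_background: int = 50
    background_length_range: tuple[int, int] = (240, 1500)
    expression_profile: tuple[float, ...] = DEFAULT_EXPRESSION_PROFILE
    # Flat expression level of every background gene. Large relative to the
    # xenolog's peak share so the xenolog stays a minor library fraction at
    # all stages, as a 2-gene family is in a whole-transcriptome library.
    background_rpkm: float = 100.0
    library_size: int = 50000
    read_length: int = 50
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.transfer_age < self.root_age):
            raise ValueError("require 0 < transfer_age < root_age")
        if not (self.duplication_age < self.transfer_age):
            raise ValueError("require duplication_age < transfer_age")
        if not (0 < self.split_age < self.transfer_age):
            raise ValueError("require 0 < split_age < transfer_age")
        if self.duplication_age and not (self.duplication_age > 0):
            raise ValueError("duplication_age must be >= 0")
        if self.outgroup_age <= self.root_age:
            raise ValueError("outgroup_age must exceed root_age")
        props = [p for _, p in self.omega_classes]
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("omega class proportions must sum to 1")
        if abs(sum(self.pi) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if self.n_host_taxa < 2 or self.n_parasite_taxa < 2:
            raise ValueError("need at least 2 host and 2 parasite taxa")
        if self.intron_length < 4:
            raise ValueError("intron_length must be >= 4")

    @property
    def host_taxa(self) -> list[str]:
        return [f"Donor{i + 1}" for i in range(self.n_host_taxa)]

    @property
    def parasite_taxa(self) -> list[str]:
        return [f"Parasite{i + 1}" for i in range(self.n_parasite_taxa)]


@dataclass
class TruthTable:
    """Ground truth for a generated dataset.

    ``contigs`` has one row per emitted parasite contig (is_xenolog flag,
    family, donor lineage); ``gene_tree`` is the true xenolog gene tree;
    intron coordinates and per-stage read counts are attached by the
    generators that produce them.
    """

    contigs: pd.DataFrame
    gene_tree: dendropy.Tree | None = None
    events: dict = field(default_factory=dict)
    xenolog_alignment: dict = field(default_factory=dict)
    intron_truth: dict = field(default_factory=dict)
    stage_counts: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def _random_ultrametric_clade(
    taxa: Sequence[str], crown_age: float, rng: np.random.Generator, tns: dendropy.TaxonNamespace
) -> dendropy.Node:
    """Random ultrametric clade (pure-birth shape) with its crown at crown_age.

    Internal-node ages are ordered uniforms below the crown; lineages are
    merged backwards in time in random pairs, which gives labelled topologies
    the uniform (Yule-consistent) distribution.
    """
    nodes = []
    for name in taxa:
        nd = dendropy.Node(taxon=tns.require_taxon(label=name))
        nd.age = 0.0
        nodes.append(nd)
    if len(nodes) == 1:
        return nodes[0]
    inner_ages = sorted(rng.uniform(0.0, crown_age, size=len(taxa) - 2)) + [crown_age]
    for age in inner_ages:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = dendropy.Node()
        parent.age = age
        for child in (a, b):
            parent.add_child(child)
            child.edge.length = age - child.age
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return nodes[0]


def simulate_gene_tree_with_hgt(scenario: SimScenario) -> tuple[dendropy.Tree, dict]:
    """Gene tree for the transferred family, with event annotations.

    The parasite gene clade attaches inside the host (donor) clade on the
    lineage of Donor1 at ``transfer_age``; if ``duplication_age`` > 0 the
    first parasite subclade carries two gene copies (suffixes ``alb1``,
    ``alb2``) that diverged at the duplication. An outgroup leaf roots the
    tree. Branch lengths are in time units (My).
    """
    scenario.validate()
    rng = substream(scenario.seed, "gene_tree")
    tns = dendropy.TaxonNamespace()

    host_root = _random_ultrametric_clade(
        [f"{t}|alb" for t in scenario.host_taxa], scenario.root_age, rng, tns
    )

    parasite_root = _build_parasite_gene_clade(scenario, rng, tns)

    # Attach the parasite clade on the edge of Donor1's lineage spanning
    # transfer_age.
    donor_leaf = _find_leaf(host_root, f"{scenario.host_taxa[0]}|alb")
    edge_child = donor_leaf
    while edge_child.parent_node is not None and edge_child.parent_node.age < scenario.transfer_age:
        edge_child = edge_child.parent_node
    attach_parent = edge_child.parent_node
    transfer_node = dendropy.Node()
    transfer_node.age = scenario.transfer_age
    if attach_parent is None:
        raise ValueError("transfer_age must be younger than the host crown age")
    attach_parent.remove_child(edge_child)
    attach_parent.add_child(transfer_node)
    transfer_node.edge.length = attach_parent.age - scenario.transfer_age
    transfer_node.add_child(edge_child)
    edge_child.edge.length = scenario.transfer_age - edge_child.age
    transfer_node.add_child(parasite_root)
    parasite_root.edge.length = scenario.transfer_age - parasite_root.age
    transfer_node.label = "transfer"

    # Root with the outgroup.
    root = dendropy.Node()
    root.age = scenario.outgroup_age
    og = dendropy.Node(taxon=tns.require_taxon(label="Outgroup|alb"))
    og.age = 0.0
    root.add_child(host_root)
    host_root.edge.length = scenario.outgroup_age - host_root.age
    root.add_child(og)
    og.edge.length = scenario.outgroup_age

    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True

    dup = [nd for nd in tree.preorder_node_iter() if nd.label == "duplication"]
    events = {
        "transfer_node": transfer_node,
        "transfer_age": scenario.transfer_age,
        "duplication_node": dup[0] if dup else None,
        "duplication_age": scenario.duplication_age if dup else None,
        "donor_lineage": scenario.host_taxa[0],
    }
    return tree, events


def _build_parasite_gene_clade(
    scenario: SimScenario, rng: np.random.Generator, tns: dendropy.TaxonNamespace
) -> dendropy.Node:
    taxa = scenario.parasite_taxa
    n_a = max(1, (len(taxa) + 1) // 2)
    clade_a_taxa, clade_b_taxa = taxa[:n_a], taxa[n_a:]

    if scenario.duplication_age > 0:
        # Two copies of the first subclade, diverging at the duplication.
        copy_age = min(scenario.duplication_age * 0.6, scenario.split_age * 0.5)
        dup_node = dendropy.Node()
        dup_node.age = scenario.duplication_age
        dup_node.label = "duplication"
        for copy in ("alb1", "alb2"):
            sub = _random_ultrametric_clade(
                [f"{t}|{copy}" for t in clade_a_taxa], copy_age, rng, tns
            )
            dup_node.add_child(sub)
            sub.edge.length = scenario.duplication_age - sub.age
        clade_a = dup_node
    else:
        clade_a = _random_ultrametric_clade(
            [f"{t}|alb1" for t in clade_a_taxa], scenario.split_age * 0.5, rng, tns
        )

    if not clade_b_taxa:
        return clade_a
    clade_b = _random_ultrametric_clade(
        [f"{t}|alb1" for t in clade_b_taxa], scenario.split_age * 0.5, rng, tns
    )
    root = dendropy.Node()
    root.age = scenario.split_age
    for child in (clade_a, clade_b):
        root.add_child(child)
        child.edge.length = scenario.split_age - child.age
    return root


def _find_leaf(subtree_root: dendropy.Node, label: str) -> dendropy.Node:
    for nd in subtree_root.leaf_iter():
        if nd.taxon is not None and nd.taxon.label == label:
            return nd
    raise KeyError(label)


# ---------------------------------------------------------------------------
# Nucleotide (HKY) evolution
# ---------------------------------------------------------------------------


def hky_rate_matrix(kappa: float, pi: Sequence[float]) -> np.ndarray:
    """HKY rate matrix normalized to one expected substitution per unit time."""
    pi = np.asarray(pi, dtype=float)
    q = np.zeros((4, 4))
    for i, a in enumerate(NUCS):
        for j, b in enumerate(NUCS):
            if i == j:
                continue
            q[i, j] = pi[j] * (kappa if is_transition(a, b) else 1.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    flux = -(pi * np.diag(q)).sum()
    return q / flux


def _sample_children(
    parent_states: np.ndarray, p: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample child states site-wise from transition matrix rows."""
    u = rng.random(parent_states.shape[0])
    cum = np.cumsum(p, axis=1)
    return (u[:, None] > cum[parent_states]).sum(axis=1)


def evolve_nt(
    tree: dendropy.Tree,
    root_seq: str,
    rate: float,
    kappa: float = 2.0,
    pi: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> dict[str, str]:
    """Evolve a nucleotide sequence down a tree under HKY.

    Branch lengths are multiplied by ``rate`` to give expected substitutions
    per site; substitutions are sampled per site from the branch transition
    probability matrix. Returns one gapless sequence per leaf, keyed by leaf
    label. Deterministic given the seed.
    """
    if not root_seq:
        raise ValueError("root sequence must be non-empty")
    bad = set(root_seq.upper()) - set(NUCS)
    if bad:
        raise ValueError(f"root sequence has non-ACGT characters: {sorted(bad)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    q = hky_rate_matrix(kappa, pi)
    root_states = np.array([NUC_INDEX[b] for b in root_seq.upper()])
    states = {id(tree.seed_node): root_states}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = (node.edge.length or 0.0) * rate
        p = expm(q * t) if t > 0 else np.eye(4)
        p = np.clip(p, 0.0, None)
        p /= p.sum(axis=1, keepdims=True)
        child = _sample_children(states[id(node.parent_node)], p, rng)
        states[id(node)] = child
        if node.is_leaf():
            out[node.taxon.label] = "".join(NUCS[s] for s in child)
    return out


# ---------------------------------------------------------------------------
# Codon (MG94-style) evolution
# ---------------------------------------------------------------------------


def mg94_rate_matrix(kappa: float, omega: float, pi: Sequence[float]) -> np.ndarray:
    """MG94-style codon rate matrix over the 61 sense codons (unscaled).

    Instantaneous rate is zero for multi-nucleotide codon changes and
    proportional to pi_target * kappa^[transition] * omega^[nonsynonymous]
    otherwise. Stops are unreachable, so simulated CDSs never gain internal
    stop codons.
    """
    pi = np.asarray(pi, dtype=float)
    n = len(SENSE_CODONS)
    q = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for pos in range(3):
            for b in NUCS:
                if b == ci[pos]:
                    continue
                cj = ci[:pos] + b + ci[pos + 1 :]
                if cj in STOP_CODONS:
                    continue
                j = CODON_INDEX[cj]
                r = pi[NUC_INDEX[b]]
                if is_transition(ci[pos], b):
                    r *= kappa
                if translate_codon(ci) != translate_codon(cj):
                    r *= omega
                q[i, j] = r
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def codon_stationary(pi: Sequence[float]) -> np.ndarray:
    """Stationary codon frequencies: products of nt frequencies over sense codons."""
    pi = np.asarray(pi, dtype=float)
    w = np.array(
        [pi[NUC_INDEX[c[0]]] * pi[NUC_INDEX[c[1]]] * pi[NUC_INDEX[c[2]]] for c in SENSE_CODONS]
    )
    return w / w.sum()


def _mg94_neutral_scale(kappa: float, pi: Sequence[float]) -> float:
    """Scale factor putting the neutral (omega=1) matrix at 3 subs/codon/unit.

    All omega classes share this scale, so constrained classes genuinely
    evolve more slowly instead of being renormalized to the neutral pace.
    """
    q1 = mg94_rate_matrix(kappa, 1.0, pi)
    pc = codon_stationary(pi)
    flux = -(pc * np.diag(q1)).sum()
    return 3.0 / flux


def evolve_codon(
    tree: dendropy.Tree,
    root_cds: str,
    kappa: float = 2.0,
    omega_classes: Sequence[tuple[float, float]] = ((0.2, 1.0),),
    pi: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    rate: float = 1.0,
    site_classes: Sequence[int] | None = None,
) -> tuple[dict[str, str], np.ndarray]:
    """Evolve a CDS down a tree under an MG94-style codon model.

    Sites are assigned i.i.d. to omega classes by proportion unless
    ``site_classes`` pins them explicitly (used to hold e.g. cysteine codons
    under omega=0). Branch lengths x ``rate`` are in expected substitutions
    per nucleotide site for neutral sites. Returns (leaf CDSs keyed by leaf
    label, per-site true class indices).
    """
    root_cds = root_cds.upper()
    if len(root_cds) % 3 != 0:
        raise ValueError("root CDS length must be divisible by 3")
    codons = [root_cds[i : i + 3] for i in range(0, len(root_cds), 3)]
    for c in codons:
        if c in STOP_CODONS:
            raise ValueError(f"root CDS contains internal stop codon {c}")
        if c not in CODON_INDEX:
            raise ValueError(f"root CDS contains invalid codon {c!r}")
    props = np.array([p for _, p in omega_classes], dtype=float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("omega class proportions must sum to 1")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_sites = len(codons)
    if site_classes is None:
        classes = rng.choice(len(omega_classes), size=n_sites, p=props)
    else:
        classes = np.asarray(site_classes, dtype=int)
        if classes.shape != (n_sites,):
            raise ValueError("site_classes length must equal the codon count")

    scale = _mg94_neutral_scale(kappa, pi)
    qs = [mg94_rate_matrix(kappa, om, pi) * scale for om, _ in omega_classes]

    root_states = np.array([CODON_INDEX[c] for c in codons])
    states = {id(tree.seed_node): root_states}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        # Branch lengths are per nt site; the matrices are scaled to 3
        # neutral substitutions per codon per unit, so the units agree.
        t = (node.edge.length or 0.0) * rate
        child = states[id(node.parent_node)].copy()
        for k, q in enumerate(qs):
            mask = classes == k
            if not mask.any():
                continue
            p = expm(q * t) if t > 0 else np.eye(q.shape[0])
            p = np.clip(p, 0.0, None)
            p /= p.sum(axis=1, keepdims=True)
            child[mask] = _sample_children(states[id(node.parent_node)][mask], p, rng)
        states[id(node)] = child
        if node.is_leaf():
            out[node.taxon.label] = "".join(SENSE_CODONS[s] for s in child)
    return out, classes


# ---------------------------------------------------------------------------
# Transcriptome fixture
# ---------------------------------------------------------------------------

# Six-cysteine scaffold: codon indices (0-based) of the cysteines in the
# simulated xenolog CDS, chosen to match the packaged scaffold profile.
CYSTEINE_CODON_POSITIONS = (40, 47, 58, 64, 66, 79)


def random_cds(n_codons: int, rng: np.random.Generator, cys_positions: Sequence[int] = ()) -> str:
    """Random sense-codon CDS starting with ATG, with optional fixed cysteines.

    When cysteine positions are designated, all other positions avoid
    cysteine codons so the designated scaffold is the only one present.
    """
    sense = [c for c in SENSE_CODONS if c != "ATG"]
    if cys_positions:
        sense = [c for c in sense if translate_codon(c) != "C"]
    codons = ["ATG"] + [sense[rng.integers(len(sense))] for _ in range(n_codons - 1)]
    for pos in cys_positions:
        codons[pos] = "TGT" if rng.random() < 0.5 else "TGC"
    return "".join(codons)


def _mutate(seq: str, fraction: float, rng: np.random.Generator) -> str:
    """Mutate a stated fraction of positions to a different random base."""
    seq = list(seq)
    n_mut = int(round(fraction * len(seq)))
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    for p in pos:
        choices = [b for b in NUCS if b != seq[p]]
        seq[p] = choices[rng.integers(3)]
    return "".join(seq)


def make_transcriptome_fixture(
    scenario: SimScenario,
) -> tuple[list[SequenceRecord], list[SequenceRecord], TaxonGroupMap, TruthTable]:
    """Build parasite contigs, a reference database and the truth table.

    Emits ``n_background`` vertically inherited gene families — each parasite
    contig has a close-relative ortholog at ~5% divergence and a distant
    donor-clade homolog, so the cascade rejects it — plus the planted
    xenolog family, which is present in the donor taxa and the parasite but
    absent from the close relatives. Background contig lengths span a range
    that includes contigs shorter than 500 nt, exercising the length filter.

    Returns (contigs, references, taxon_map, truth).
    """
    scenario.validate()
    rng = substream(scenario.seed, "fixture")
    focal = scenario.parasite_taxa[0]

    contigs: list[SequenceRecord] = []
    refs: list[SequenceRecord] = []
    rows = []

    close_rels = ["CloseRel1", "CloseRel2"]
    lo, hi = scenario.background_length_range
    for i in range(scenario.n_background):
        length = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
        base = random_cds(length // 3, rng)
        cid = f"bg{i + 1:03d}_c1"
        contigs.append(
            SequenceRecord(
                id=cid, residues=_mutate(base, 0.02, rng), species=focal, group="self"
            )
        )
        cr = close_rels[i % 2]
        refs.append(
            SequenceRecord(
                id=f"{cr}|bg{i + 1:03d}",
                residues=_mutate(base, 0.05, rng),
                species=cr,
                group="close_relative",
            )
        )
        donor = scenario.host_taxa[i % scenario.n_host_taxa]
        refs.append(
            SequenceRecord(
                id=f"{donor}|bg{i + 1:03d}",
                residues=_mutate(base, 0.35, rng),
                species=donor,
                group="donor_candidate",
            )
        )
        rows.append(
            {"contig_id": cid, "family": f"bg{i + 1:03d}", "is_xenolog": False, "donor_lineage": ""}
        )

    # Planted xenolog family: evolve a codon alignment along the HGT gene tree.
    gene_tree, events = simulate_gene_tree_with_hgt(scenario)
    root_cds = random_cds(scenario.xenolog_n_codons, rng, CYSTEINE_CODON_POSITIONS)
    site_classes = _xenolog_site_classes(scenario, rng)
    omega_classes = tuple(scenario.omega_classes) + ((0.0, 0.0),)
    leaf_cds, _ = evolve_codon(
        gene_tree,
        root_cds,
        kappa=scenario.kappa,
        omega_classes=omega_classes,
        pi=scenario.pi,
        seed=int(substream(scenario.seed, "xenolog_cds").integers(2**31)),
        rate=scenario.subst_rate,
        site_classes=site_classes,
    )
    xeno_contigs = []
    for label, cds in sorted(leaf_cds.items()):
        species = label.split("|", 1)[0]
        if species == focal:
            copy = label.split("|", 1)[1]
            cid = f"xeno_{copy}"
            contigs.append(SequenceRecord(id=cid, residues=cds, species=focal, group="self"))
            xeno_contigs.append(cid)
            rows.append(
                {
                    "contig_id": cid,
                    "family": "xenolog",
                    "is_xenolog": True,
                    "donor_lineage": events["donor_lineage"],
                }
            )
        elif species.startswith("Donor"):
            refs.append(
                SequenceRecord(
                    id=f"{species}|alb", residues=cds, species=species, group="donor_candidate"
                )
            )
        # Other parasite species and the outgroup stay out of the reference
        # database, as in a screen of a parasite transcriptome against
        # non-parasite references.

    mapping = {sp: "donor_candidate" for sp in scenario.host_taxa}
    mapping.update({cr: "close_relative" for cr in close_rels})
    mapping[focal] = "self"
    mapping["Outgroup"] = "other"
    taxon_map = TaxonGroupMap(
        species_to_group=mapping, donor_labels=tuple(scenario.host_taxa)
    )

    truth = TruthTable(
        contigs=pd.DataFrame(rows).set_index("contig_id"),
        gene_tree=gene_tree,
        events={
            "transfer_age": events["transfer_age"],
            "duplication_age": events["duplication_age"],
            "donor_lineage": events["donor_lineage"],
            "xenolog_contigs": sorted(xeno_contigs),
        },
        xenolog_alignment=dict(sorted(leaf_cds.items())),
    )
    return contigs, refs, taxon_map, truth


def _xenolog_site_classes(scenario: SimScenario, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. omega classes with cysteine codons pinned to an omega=0 class.

    The omega=0 class is appended after the scenario's classes, so its index
    is len(omega_classes).
    """
    props = np.array([p for _, p in scenario.omega_classes])
    classes = rng.choice(len(scenario.omega_classes), size=scenario.xenolog_n_codons, p=props)
    classes[list(CYSTEINE_CODON_POSITIONS)] = len(scenario.omega_classes)
    return classes


# ---------------------------------------------------------------------------
# Gene structure
# ---------------------------------------------------------------------------


def make_genomic_with_intron(
    cds: str, intron_length: int, seed: int = 0, position: int | None = None
):
    """Insert one intron with canonical GT..AG ends into a CDS.

    ``position`` is the number of coding nucleotides before the intron
    (default: mid-CDS on a codon boundary). Returns the genomic record and
    the true gene structure; concatenating the exons recovers the CDS.
    """
    from xenoscan.gene_structure import GeneStructure

    if intron_length < 4:
        raise ValueError("intron_length must be >= 4 to hold the GT..AG dinucleotides")
    cds = cds.upper()
    if position is None:
        position = (len(cds) // 6) * 3
    if not (0 < position < len(cds)):
        raise ValueError("intron position must be strictly inside the CDS")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    middle = "".join(NUCS[i] for i in rng.integers(0, 4, size=intron_length - 4))
    intron = "GT" + middle + "AG"
    genomic = cds[:position] + intron + cds[position:]
    structure = GeneStructure(
        gene_id="synthetic",
        exons=((0, position), (position + intron_length, len(genomic))),
        introns=((position, position + intron_length),),
        donor_dinucleotide="GT",
        acceptor_dinucleotide="AG",
        phase=position % 3,
    )
    record = SequenceRecord(id="synthetic_genomic", residues=genomic, alphabet="nt")
    return record, structure


# ---------------------------------------------------------------------------
# Stage-structured reads
# ---------------------------------------------------------------------------


def simulate_stage_reads(
    genes: Sequence[SequenceRecord],
    expression_profile: np.ndarray | Sequence[Sequence[float]],
    read_length: int = 50,
    library_sizes: Sequence[int] | None = None,
    seed: int = 0,
    stage_names: Sequence[str] = STAGE_NAMES,
    mutate_fraction: float = 0.0,
) -> tuple[dict[str, list[SequenceRecord]], pd.DataFrame]:
    """Simulate per-stage read sets from target expression profiles.

    ``expression_profile`` is genes x stages of target RPKM. Per-stage gene
    counts are multinomial with probabilities proportional to RPKM x gene
    length; reads are exact substrings at uniform positions (optionally a
    stated fraction of reads carries one random mismatch). Returns
    (reads per stage, true counts genes x stages).
    """
    profile = np.asarray(expression_profile, dtype=float)
    if profile.ndim != 2 or profile.shape[0] != len(genes):
        raise ValueError("expression_profile must be genes x stages")
    n_stages = profile.shape[1]
    if library_sizes is None:
        library_sizes = [20000] * n_stages
    if len(library_sizes) != n_stages:
        raise ValueError("one library size per stage required")
    if any(s <= 0 for s in library_sizes):
        raise ValueError("library sizes must be positive")
    lengths = np.array([len(g) for g in genes], dtype=float)
    if read_length > lengths.min():
        raise ValueError("read_length must not exceed the shortest gene")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    reads: dict[str, list[SequenceRecord]] = {}
    counts = np.zeros((len(genes), n_stages), dtype=int)
    for s in range(n_stages):
        weights = profile[:, s] * lengths
        total = weights.sum()
        if total <= 0:
            raise ValueError(f"stage {stage_names[s]}: all-zero expression profile")
        gene_counts = rng.multinomial(library_sizes[s], weights / total)
        counts[:, s] = gene_counts
        stage_reads: list[SequenceRecord] = []
        for g, n_reads in enumerate(gene_counts):
            if n_reads == 0:
                continue
            starts = rng.integers(0, len(genes[g]) - read_length + 1, size=n_reads)
            for k, st in enumerate(starts):
                seq = genes[g].residues[st : st + read_length]
                if mutate_fraction > 0 and rng.random() < mutate_fraction:
                    seq = _mutate(seq, 1.0 / read_length, rng)
                stage_reads.append(
                    SequenceRecord(
                        id=f"{stage_names[s]}_r{len(stage_reads) + 1:06d}",
                        residues=seq,
                    )
                )
        reads[stage_names[s]] = stage_reads
    truth = pd.DataFrame(counts, index=[g.id for g in genes], columns=list(stage_names)[:n_stages])
    return reads, truth
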