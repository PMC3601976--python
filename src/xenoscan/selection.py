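"""Evolutionary-constraint analysis of codon alignments.

Pairwise rates use Nei-Gojobori (1986) counting: per-codon synonymous and
nonsynonymous site fractions, averaging over all minimal mutational pathways
for multi-difference codons (pathways through stop codons excluded), and a
Jukes-Cantor correction of the resulting proportions. Per-branch substitution
counts come from parsimony reconstruction of ancestral states on a rooted
tree, with equally parsimonious reconstructions averaged exactly; branch
counts can be pooled into user-defined lineages to stabilize the dN/dS signal
on short branches. A per-site scan compares each codon column's observed
nonsynonymous changes with its opportunity-scaled expectation, flagging
cysteine columns, as a counting analogue of site-wise constraint analysis.

Conventions fixed here: mutations to stop codons are excluded from both the
site-count denominators and the pathway numerators; codon columns containing
gaps or ambiguous bases are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations, product
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from xenoscan._codons import (
    NUCS,
    STOP_CODONS,
    single_nt_neighbors,
    translate_codon,
)
from xenoscan.io_core import logger

__all__ = [
    "CodonChangeSummary",
    "codon_site_counts",
    "ng86_pairwise",
    "parsimony_branch_counts",
    "pool_lineages",
    "site_constraint_scan",
]


@dataclass
class CodonChangeSummary:
    """Synonymous/nonsynonymous change summary for a pair, branch or pool."""

    scope: str
    Nd: float
    Sd: float
    N_sites: float
    S_sites: float
    pN: float | None = None
    pS: float | None = None
    dN: float | None = None
    dS: float | None = None
    omega: float | None = None
    saturated: bool = False
    omega_undefined: bool = False

    def __post_init__(self) -> None:
        if self.Nd < 0 or self.Sd < 0:
            raise ValueError("substitution counts must be non-negative")


def jc_correct(p: float) -> float | None:
    """Jukes-Cantor distance -(3/4) ln(1 - 4p/3); None when saturated."""
    if p >= 0.75:
        return None
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# Site and pathway counting
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (S, N) of one sense codon.

    At each of the three positions the site's synonymous fraction is the
    fraction of its non-stop single-nucleotide mutations that preserve the
    amino acid; mutations to stops are excluded from the denominator, so each
    position still contributes one full site and S + N = 3.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in NUCS for b in codon):
        raise ValueError(f"invalid or ambiguous codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = translate_codon(codon)
    s_total = 0.0
    for pos in range(3):
        syn = 0
        non_stop = 0
        for b in NUCS:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            non_stop += 1
            if translate_codon(mut) == aa:
                syn += 1
        s_total += syn / non_stop if non_stop else 0.0
    return s_total, 3.0 - s_total


@lru_cache(maxsize=None)
def codon_path_counts(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """(Nd, Sd) between two sense codons, averaged over minimal pathways.

    Pathways that traverse a stop codon are excluded; returns None when every
    pathway does (the codon pair is then skipped by callers).
    """
    for c in (codon_a, codon_b):
        if c in STOP_CODONS or any(b not in NUCS for b in c):
            raise ValueError(f"invalid codon {c!r}")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    totals = []
    for order in permutations(diff):
        cur = codon_a
        nd = sd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate_codon(cur) == translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((nd, sd))
    if not totals:
        return None
    nd = float(np.mean([t[0] for t in totals]))
    sd = float(np.mean([t[1] for t in totals]))
    return nd, sd


def _codons_of(seq: str) -> list[str]:
    seq = seq.upper()
    if len(seq) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def _codon_ok(codon: str) -> bool:
    return all(b in NUCS for b in codon) and codon not in STOP_CODONS


def ng86_pairwise(cds_a: str, cds_b: str, scope: str = "pair") -> CodonChangeSummary:
    """Nei-Gojobori pairwise dN, dS and omega for two aligned CDSs.

    Codons with gaps, ambiguity or stops in either sequence are skipped
    pairwise; site counts are averaged over the two sequences; proportions
    are Jukes-Cantor corrected. Symmetric in its arguments. ``omega`` is None
    (flagged undefined) when dS is zero or either proportion is saturated.
    """
    ca, cb = _codons_of(cds_a), _codons_of(cds_b)
    if len(ca) != len(cb):
        raise ValueError("aligned CDS lengths differ")
    nd = sd = 0.0
    s_sites = n_sites = 0.0
    skipped = 0
    for a, b in zip(ca, cb):
        if not (_codon_ok(a) and _codon_ok(b)):
            continue
        path = codon_path_counts(a, b)
        if path is None:
            skipped += 1
            continue
        sa, na = codon_site_counts(a)
        sb, nb = codon_site_counts(b)
        s_sites += (sa + sb) / 2.0
        n_sites += (na + nb) / 2.0
        nd += path[0]
        sd += path[1]
    if skipped:
        logger.warning("ng86_pairwise: skipped %d codon pairs (all pathways hit stops)", skipped)
    if s_sites == 0 and n_sites == 0:
        raise ValueError("no comparable codons between the two sequences")
    p_n = nd / n_sites if n_sites else 0.0
    p_s = sd / s_sites if s_sites else 0.0
    d_n, d_s = jc_correct(p_n), jc_correct(p_s)
    saturated = d_n is None or d_s is None
    omega = None
    undefined = True
    if not saturated and d_s is not None and d_s > 0 and d_n is not None:
        omega = d_n / d_s
        undefined = False
    return CodonChangeSummary(
        scope=scope,
        Nd=nd,
        Sd=sd,
        N_sites=n_sites,
        S_sites=s_sites,
        pN=p_n,
        pS=p_s,
        dN=d_n,
        dS=d_s,
        omega=omega,
        saturated=saturated,
        omega_undefined=undefined,
    )


# ---------------------------------------------------------------------------
# Parsimony branch counts
# ---------------------------------------------------------------------------

_INF = float("inf")


def _sankoff_edge_joint(tree: dendropy.Tree, leaf_states: Mapping[str, int | None]):
    """Per-edge joint distribution of (parent, child) states under uniform
    weighting of all maximally parsimonious reconstructions.

    Unit substitution costs on the four nucleotide states. Returns
    {child-node id: 4x4 probability matrix}. ``None`` leaf states are treated
    as missing (any state, cost 0).
    """
    n_states = 4
    c_in: dict[int, np.ndarray] = {}
    w_in: dict[int, np.ndarray] = {}
    c_edge: dict[int, np.ndarray] = {}
    w_edge: dict[int, np.ndarray] = {}

    for node in tree.postorder_node_iter():
        nid = id(node)
        if node.is_leaf():
            state = leaf_states[node.taxon.label]
            cost = np.full(n_states, _INF)
            wt = np.zeros(n_states)
            if state is None:
                cost[:] = 0.0
                wt[:] = 1.0
            else:
                cost[state] = 0.0
                wt[state] = 1.0
            c_in[nid], w_in[nid] = cost, wt
        else:
            cost = np.zeros(n_states)
            wt = np.ones(n_states)
            for child in node.child_nodes():
                cost += c_edge[id(child)]
                wt *= w_edge[id(child)]
            c_in[nid], w_in[nid] = cost, wt
        if node.parent_node is not None:
            ce = np.empty(n_states)
            we = np.empty(n_states)
            for a in range(n_states):
                tot = c_in[nid] + (np.arange(n_states) != a)
                m = tot.min()
                ce[a] = m
                we[a] = w_in[nid][np.isclose(tot, m)].sum()
            c_edge[nid], w_edge[nid] = ce, we

    root = tree.seed_node
    g_min = c_in[id(root)].min()

    c_out: dict[int, np.ndarray] = {id(root): np.zeros(n_states)}
    w_out: dict[int, np.ndarray] = {id(root): np.ones(n_states)}
    joint: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        children = node.child_nodes()
        for child in children:
            cid = id(child)
            g = c_out[id(node)].copy()
            wg = w_out[id(node)].copy()
            for sib in children:
                if sib is child:
                    continue
                g += c_edge[id(sib)]
                wg *= w_edge[id(sib)]
            # Joint cost/weight over (parent state a, child state b).
            total = g[:, None] + (np.arange(n_states)[:, None] != np.arange(n_states)[None, :]) + c_in[cid][None, :]
            weight = wg[:, None] * w_in[cid][None, :]
            opt = np.isclose(total, g_min)
            jm = np.where(opt, weight, 0.0)
            z = jm.sum()
            joint[cid] = jm / z if z > 0 else jm
            # Outside quantities for the child.
            co = np.empty(n_states)
            wo = np.empty(n_states)
            for b in range(n_states):
                col = g + (np.arange(n_states) != b)
                m = col.min()
                co[b] = m
                wo[b] = wg[np.isclose(col, m)].sum()
            c_out[cid], w_out[cid] = co, wo
    return joint


def _branch_labels(tree: dendropy.Tree) -> dict[int, str]:
    """Deterministic branch naming: a branch is named by its child node."""
    labels = {}
    counter = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.taxon is not None:
            labels[id(node)] = node.taxon.label
        elif node.label:
            labels[id(node)] = node.label
        else:
            counter += 1
            labels[id(node)] = f"inode{counter}"
            node.label = labels[id(node)]
    return labels


def _per_column_branch_counts(
    codon_alignment: Mapping[str, str], tree: dendropy.Tree
) -> tuple[np.ndarray, np.ndarray, list[str], list[int]]:
    """(Nd, Sd) per codon column x branch by averaged-parsimony reconstruction.

    Returns (nd_matrix, sd_matrix, branch_labels, used_columns); columns with
    gaps/ambiguity/stops in any sequence are skipped.
    """
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    if leaves != set(codon_alignment):
        diff = leaves.symmetric_difference(codon_alignment)
        raise ValueError(f"tree/alignment leaf mismatch: {sorted(diff)}")
    codons = {lab: _codons_of(seq) for lab, seq in codon_alignment.items()}
    n_col = len(next(iter(codons.values())))
    if any(len(c) != n_col for c in codons.values()):
        raise ValueError("aligned CDS lengths differ")

    labels_by_id = _branch_labels(tree)
    branch_ids = [id(nd) for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    branch_names = [labels_by_id[b] for b in branch_ids]
    nuc_index = {b: i for i, b in enumerate(NUCS)}

    nd_mat = np.zeros((n_col, len(branch_ids)))
    sd_mat = np.zeros((n_col, len(branch_ids)))
    used: list[int] = []
    for col in range(n_col):
        col_codons = {lab: codons[lab][col] for lab in codons}
        if not all(_codon_ok(c) for c in col_codons.values()):
            continue
        used.append(col)
        joints = []
        for pos in range(3):
            states = {lab: nuc_index[c[pos]] for lab, c in col_codons.items()}
            joints.append(_sankoff_edge_joint(tree, states))
        for b_idx, bid in enumerate(branch_ids):
            j0, j1, j2 = (j[bid] for j in joints)
            nd, sd = _expected_codon_change(j0, j1, j2)
            nd_mat[col, b_idx] = nd
            sd_mat[col, b_idx] = sd
    return nd_mat, sd_mat, branch_names, used


def _expected_codon_change(j0: np.ndarray, j1: np.ndarray, j2: np.ndarray) -> tuple[float, float]:
    """Expected (Nd, Sd) on one branch for one codon column.

    The three positions' (parent, child) joint distributions are independent
    under uniform weighting of optimal reconstructions, so the codon-level
    expectation is a sum over the product support, classifying multi-hit
    codon changes by stop-avoiding pathway averaging.
    """
    nd = sd = 0.0
    supports = [np.argwhere(j > 0) for j in (j0, j1, j2)]
    for (a0, b0) in supports[0]:
        for (a1, b1) in supports[1]:
            for (a2, b2) in supports[2]:
                w = j0[a0, b0] * j1[a1, b1] * j2[a2, b2]
                parent = NUCS[a0] + NUCS[a1] + NUCS[a2]
                child = NUCS[b0] + NUCS[b1] + NUCS[b2]
                if parent == child:
                    continue
                if parent in STOP_CODONS or child in STOP_CODONS:
                    continue
                path = codon_path_counts(parent, child)
                if path is None:
                    continue
                nd += w * path[0]
                sd += w * path[1]
    return nd, sd


def parsimony_branch_counts(
    codon_alignment: Mapping[str, str], tree: dendropy.Tree
) -> pd.DataFrame:
    """Per-branch (Nd, Sd) substitution counts on a rooted tree.

    Ancestral states are reconstructed position-wise by parsimony with exact
    averaging over all equally parsimonious reconstructions; each branch's
    implied codon changes are classified synonymous/nonsynonymous with
    pathway averaging. Branches are named by their child node.
    """
    nd_mat, sd_mat, branch_names, _ = _per_column_branch_counts(codon_alignment, tree)
    return pd.DataFrame(
        {"Nd": nd_mat.sum(axis=0), "Sd": sd_mat.sum(axis=0)}, index=branch_names
    ).rename_axis("branch")


def pool_lineages(
    branch_counts: pd.DataFrame,
    lineage_definitions: Mapping[str, Sequence[str]],
    codon_alignment: Mapping[str, str] | None = None,
) -> list[CodonChangeSummary]:
    """Pool per-branch counts into named lineages and report pooled dN/dS.

    Raises if a branch is assigned to more than one pool. Site counts (needed
    for rates) are the alignment-wide mean NG86 site counts when the
    alignment is supplied; otherwise only counts are reported. Pools with
    zero synonymous changes are flagged omega-undefined.
    """
    seen: dict[str, str] = {}
    for pool, branches in lineage_definitions.items():
        for b in branches:
            if b in seen:
                raise ValueError(f"branch {b!r} assigned to both {seen[b]!r} and {pool!r}")
            if b not in branch_counts.index:
                raise KeyError(f"branch {b!r} not present in branch counts")
            seen[b] = pool

    s_sites = n_sites = 0.0
    if codon_alignment is not None:
        per_seq = []
        for seq in codon_alignment.values():
            s = n = 0.0
            for codon in _codons_of(seq):
                if _codon_ok(codon):
                    cs, cn = codon_site_counts(codon)
                    s += cs
                    n += cn
            per_seq.append((s, n))
        s_sites = float(np.mean([p[0] for p in per_seq]))
        n_sites = float(np.mean([p[1] for p in per_seq]))

    out = []
    for pool, branches in lineage_definitions.items():
        nd = float(branch_counts.loc[list(branches), "Nd"].sum())
        sd = float(branch_counts.loc[list(branches), "Sd"].sum())
        p_n = nd / n_sites if n_sites else None
        p_s = sd / s_sites if s_sites else None
        d_n = jc_correct(p_n) if p_n is not None else None
        d_s = jc_correct(p_s) if p_s is not None else None
        omega = None
        undefined = True
        if d_n is not None and d_s is not None and d_s > 0:
            omega = d_n / d_s
            undefined = False
        out.append(
            CodonChangeSummary(
                scope=pool,
                Nd=nd,
                Sd=sd,
                N_sites=n_sites,
                S_sites=s_sites,
                pN=p_n,
                pS=p_s,
                dN=d_n,
                dS=d_s,
                omega=omega,
                saturated=(p_n is not None and p_n >= 0.75)
                or (p_s is not None and p_s >= 0.75),
                omega_undefined=undefined,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Per-site constraint scan
# ---------------------------------------------------------------------------


def site_constraint_scan(
    codon_alignment: Mapping[str, str], tree: dendropy.Tree, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-codon-column nonsynonymous constraint scores.

    For each column the observed parsimony nonsynonymous changes are compared
    with an expectation proportional to the column's nonsynonymous
    opportunity and the tree-wide nonsynonymous rate:
    ``score = ln(expected_N / (observed_N + pseudocount))``. High scores mark
    constrained columns. Columns whose consensus amino acid is cysteine are
    flagged. Columns skipped from counting get NaN scores.
    """
    nd_mat, sd_mat, _, used = _per_column_branch_counts(codon_alignment, tree)
    codons = {lab: _codons_of(seq) for lab, seq in codon_alignment.items()}
    n_col = nd_mat.shape[0]

    opportunity = np.full(n_col, np.nan)
    consensus_cys = np.zeros(n_col, dtype=bool)
    for col in used:
        n_opp = []
        aas = []
        for lab in codons:
            c = codons[lab][col]
            _, n = codon_site_counts(c)
            n_opp.append(n)
            aas.append(translate_codon(c))
        opportunity[col] = float(np.mean(n_opp))
        vals, counts = np.unique(aas, return_counts=True)
        consensus_cys[col] = vals[counts.argmax()] == "C"

    observed = nd_mat.sum(axis=1)
    total_obs = observed[used].sum()
    total_opp = np.nansum(opportunity[used])
    rate = total_obs / total_opp if total_opp > 0 else 0.0

    score = np.full(n_col, np.nan)
    for col in used:
        expected = rate * opportunity[col]
        if expected <= 0:
            expected = pseudocount  # degenerate: no nonsynonymous change anywhere
        score[col] = np.log(expected / (observed[col] + pseudocount))

    obs_s = sd_mat.sum(axis=1)
    return pd.DataFrame(
        {
            "column": np.arange(n_col),
            "observed_N": observed,
            "observed_S": obs_s,
            "opportunity_N": opportunity,
            "constraint_score": score,
            "is_cysteine": consensus_cys,
            "used": np.isin(np.arange(n_col), used),
        }
    ).set_index("column")
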