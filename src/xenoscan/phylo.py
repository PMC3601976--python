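"""Phylogenetic confirmation and dating of horizontal transfer.

Tree building is neighbor-joining on JC/K2P distances; likelihood scoring is
Felsenstein pruning under GTR (optionally with discrete-gamma rate
heterogeneity); topology comparison uses RELL resampling of per-site log
likelihoods to give Kishino-Hasegawa and Shimodaira-Hasegawa p-values; and
node dating is strict-clock mean-path-length (MPL) against a single
calibrated node. These are deterministic, desk-scale counterparts of full
ML tree search and Bayesian relaxed-clock dating: the topology is supplied
or comes from NJ, likelihoods are evaluated rather than optimized, and the
calibration is used as a point value.

Alignments are passed as ``{label: sequence}`` mappings of equal-length
nucleotide strings; gaps (``-``) and ``N`` are treated as missing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm

from xenoscan.io_core import TaxonGroupMap, logger

__all__ = [
    "GTRParams",
    "SiteLikelihoods",
    "distance_matrix",
    "nj_tree",
    "felsenstein_loglik",
    "rell_topology_test",
    "hgt_placement_support",
    "mpl_dates",
]

_NUCS = "ACGT"
_NUC_INDEX = {b: i for i, b in enumerate(_NUCS)}


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------


def _seq_matrix(alignment: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    labels = list(alignment)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must have equal length")
    arr = np.array([list(alignment[l].upper()) for l in labels])
    return labels, arr


def distance_matrix(
    alignment: Mapping[str, str], model: str = "JC"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise JC or K2P distances with pairwise deletion of gap/N columns.

    Returns (distances, saturated) as label-indexed DataFrames; an entry is
    flagged saturated (distance NaN) when the mismatch proportion reaches the
    model's domain bound (p >= 3/4 for JC; log argument <= 0 for K2P). A pair
    with zero overlapping columns is an error.
    """
    if model not in ("JC", "K2P"):
        raise ValueError(f"unknown distance model {model!r}")
    labels, arr = _seq_matrix(alignment)
    valid = np.isin(arr, list(_NUCS))
    n = len(labels)
    d = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no overlapping columns between {labels[i]!r} and {labels[j]!r}"
                )
            a, b = arr[i][ok], arr[j][ok]
            if model == "JC":
                p = float((a != b).sum()) / m
                if p >= 0.75:
                    sat[i, j] = sat[j, i] = True
                    d[i, j] = d[j, i] = np.nan
                else:
                    d[i, j] = d[j, i] = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            else:
                diff = a != b
                ts = (
                    ((a == "A") & (b == "G")) | ((a == "G") & (b == "A"))
                    | ((a == "C") & (b == "T")) | ((a == "T") & (b == "C"))
                )
                p = float(ts.sum()) / m
                q = float((diff & ~ts).sum()) / m
                w1 = 1.0 - 2.0 * p - q
                w2 = 1.0 - 2.0 * q
                if w1 <= 0 or w2 <= 0:
                    sat[i, j] = sat[j, i] = True
                    d[i, j] = d[j, i] = np.nan
                else:
                    d[i, j] = d[j, i] = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    return (
        pd.DataFrame(d, index=labels, columns=labels),
        pd.DataFrame(sat, index=labels, columns=labels),
    )


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(distances: pd.DataFrame) -> dendropy.Tree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative branch-length estimates are clamped to zero; joins are
    tie-broken by the lexicographically smallest label pair, so reruns are
    identical. Returns an unrooted tree (trifurcating root).
    """
    labels = list(distances.index)
    if len(labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = distances.to_numpy(dtype=float).copy()
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN (saturated?) entries")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")

    tns = dendropy.TaxonNamespace()
    nodes = [dendropy.Node(taxon=tns.require_taxon(label=l)) for l in labels]
    names = labels[:]
    active = list(range(len(labels)))

    while len(active) > 2:
        n = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        best = min(
            ((i, j) for i, j in ties if i < j),
            key=lambda ij: tuple(sorted((names[active[ij[0]]], names[active[ij[1]]]))),
        )
        ai, aj = active[best[0]], active[best[1]]
        dij = d[ai, aj]
        li = 0.5 * dij + (r[best[0]] - r[best[1]]) / (2.0 * (n - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        for child, bl in ((nodes[ai], li), (nodes[aj], lj)):
            parent.add_child(child)
            child.edge.length = bl
        # Distances from the new node to the remaining taxa.
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (ai, aj):
                continue
            new_row[k] = 0.5 * (d[ai, k] + d[aj, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        names.append(min(names[ai], names[aj]))
        active = [k for k in active if k not in (ai, aj)] + [d.shape[0] - 1]

    ai, aj = active
    root = dendropy.Node()
    bl = max(d[ai, aj], 0.0)
    ni, nj_ = nodes[ai], nodes[aj]
    # Attach the simpler node under the other to form an unrooted tree.
    if ni.is_leaf():
        root.add_child(ni)
        ni.edge.length = bl
        for ch in list(nj_.child_nodes()):
            nj_.remove_child(ch)
            root.add_child(ch)
    else:
        root.add_child(nj_)
        nj_.edge.length = bl
        for ch in list(ni.child_nodes()):
            ni.remove_child(ch)
            root.add_child(ch)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# GTR likelihood
# ---------------------------------------------------------------------------


@dataclass
class GTRParams:
    """GTR model: symmetric exchangeabilities (AC, AG, AT, CG, CT, GT) and
    base frequencies in ACGT order; optional discrete-gamma heterogeneity."""

    exchangeabilities: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    frequencies: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = None
    n_gamma_categories: int = 4

    def rate_matrix(self) -> np.ndarray:
        ex = self.exchangeabilities
        pi = np.asarray(self.frequencies, dtype=float)
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        q = np.zeros((4, 4))
        for (i, j), s in zip(pairs, ex):
            q[i, j] = s * pi[j]
            q[j, i] = s * pi[i]
        np.fill_diagonal(q, -q.sum(axis=1))
        flux = -(pi * np.diag(q)).sum()
        return q / flux

    def rate_categories(self) -> np.ndarray:
        """Mean-normalized discrete-gamma category rates (equal weights)."""
        if self.gamma_shape is None:
            return np.array([1.0])
        from scipy.stats import gamma as gamma_dist

        k = self.n_gamma_categories
        a = self.gamma_shape
        # Category means between equal-probability quantile boundaries.
        edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        rates = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            lo_c = gamma_dist.cdf(lo * a, a + 1)
            hi_c = gamma_dist.cdf(hi * a, a + 1) if np.isfinite(hi) else 1.0
            rates.append((hi_c - lo_c) * k)
        rates = np.array(rates)
        return rates / rates.mean()


@dataclass
class SiteLikelihoods:
    """Per-site log-likelihoods for one or more topologies (rows)."""

    loglik: np.ndarray  # topologies x sites
    topology_names: tuple[str, ...]
    params: GTRParams = field(default_factory=GTRParams)

    def __post_init__(self) -> None:
        self.loglik = np.atleast_2d(np.asarray(self.loglik, dtype=float))
        if not np.all(np.isfinite(self.loglik)):
            raise ValueError("site log-likelihoods must be finite")

    @property
    def totals(self) -> np.ndarray:
        return self.loglik.sum(axis=1)


_MISSING = {"-", "N", "?"}


def _leaf_partials(seq: str) -> np.ndarray:
    """sites x 4 indicator partials; gap/N columns are all-ones (missing)."""
    n = len(seq)
    p = np.zeros((n, 4))
    for i, b in enumerate(seq):
        if b in _MISSING:
            p[i] = 1.0
        else:
            try:
                p[i, _NUC_INDEX[b]] = 1.0
            except KeyError:
                p[i] = 1.0
    return p


def felsenstein_loglik(
    alignment: Mapping[str, str],
    tree: dendropy.Tree,
    gtr_params: GTRParams | None = None,
) -> SiteLikelihoods:
    """Per-site log-likelihood of an alignment on a tree by pruning.

    Tree leaf labels must equal the alignment ids (a mismatch error lists the
    symmetric difference). Branch lengths are expected substitutions/site.
    With ``gamma_shape`` set, the likelihood is averaged over equal-weight
    discrete-gamma rate categories.
    """
    params = gtr_params or GTRParams()
    leaf_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    if leaf_labels != set(alignment):
        diff = leaf_labels.symmetric_difference(alignment)
        raise ValueError(f"tree/alignment leaf mismatch: {sorted(diff)}")
    _, arr = _seq_matrix(alignment)
    n_sites = arr.shape[1]

    q = params.rate_matrix()
    pi = np.asarray(params.frequencies, dtype=float)
    rates = params.rate_categories()

    site_lik = np.zeros(n_sites)
    for rate in rates:
        partials: dict[int, np.ndarray] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                partials[id(node)] = _leaf_partials(alignment[node.taxon.label].upper())
            else:
                p_node = np.ones((n_sites, 4))
                for child in node.child_nodes():
                    t = (child.edge.length or 0.0) * rate
                    pmat = expm(q * t)
                    p_node *= partials[id(child)] @ pmat.T
                partials[id(node)] = p_node
        site_lik += (partials[id(tree.seed_node)] @ pi) / len(rates)
    if np.any(site_lik <= 0):
        raise ValueError("zero site likelihood encountered")
    return SiteLikelihoods(loglik=np.log(site_lik), topology_names=("tree",), params=params)


def brute_force_loglik(
    alignment: Mapping[str, str], tree: dendropy.Tree, gtr_params: GTRParams | None = None
) -> np.ndarray:
    """Exhaustive-enumeration likelihood oracle for tiny trees.

    Sums over all interior-node state assignments explicitly; exponential in
    the number of internal nodes, so only usable on toy cases. Kept in the
    package (not the tests) so the pruning implementation and its oracle can
    be compared anywhere.
    """
    params = gtr_params or GTRParams()
    q = params.rate_matrix()
    pi = np.asarray(params.frequencies, dtype=float)
    if params.gamma_shape is not None:
        raise NotImplementedError("oracle supports the homogeneous-rate model only")

    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    leaves = [nd for nd in tree.leaf_node_iter()]
    pmats = {
        id(nd): expm(q * (nd.edge.length or 0.0))
        for nd in tree.preorder_node_iter()
        if nd is not tree.seed_node
    }
    _, arr = _seq_matrix(alignment)
    seqs = {nd.taxon.label: alignment[nd.taxon.label].upper() for nd in leaves}
    n_sites = len(next(iter(seqs.values())))

    out = np.zeros(n_sites)
    for site in range(n_sites):
        total = 0.0
        for states in product(range(4), repeat=len(internal)):
            assign = {id(nd): s for nd, s in zip(internal, states)}
            prob = pi[assign[id(tree.seed_node)]]
            for nd in tree.preorder_node_iter():
                if nd is tree.seed_node:
                    continue
                parent_state = assign[id(nd.parent_node)]
                if nd.is_leaf():
                    base = seqs[nd.taxon.label][site]
                    if base in _MISSING:
                        prob *= 1.0
                    else:
                        prob *= pmats[id(nd)][parent_state, _NUC_INDEX[base]]
                else:
                    prob *= pmats[id(nd)][parent_state, assign[id(nd)]]
            total += prob
        out[site] = np.log(total)
    return out


# ---------------------------------------------------------------------------
# RELL topology tests
# ---------------------------------------------------------------------------


def rell_topology_test(
    site_likelihoods: SiteLikelihoods | np.ndarray,
    topology_names: Sequence[str] | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """KH and SH p-values by RELL resampling of per-site log-likelihoods.

    Sites are resampled with replacement without re-optimizing branch
    lengths. KH compares each topology against the ML topology through the
    centered bootstrap distribution of their log-likelihood difference; SH
    compares simultaneously against each replicate's maximum over
    per-topology centered sums. p-values are in [0, 1]; identical site
    vectors give p = 1.
    """
    if isinstance(site_likelihoods, SiteLikelihoods):
        mat = site_likelihoods.loglik
        names = list(site_likelihoods.topology_names)
    else:
        mat = np.atleast_2d(np.asarray(site_likelihoods, dtype=float))
        names = list(topology_names or (f"T{i + 1}" for i in range(mat.shape[0])))
    n_topo, n_sites = mat.shape
    if n_topo < 2:
        raise ValueError("topology tests need at least 2 topologies")
    if n_reps < 100:
        logger.warning("rell_topology_test: n_reps=%d is very small", n_reps)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    totals = mat.sum(axis=1)
    best = int(np.argmax(totals))

    # canonical column order makes the resampling, and hence the p-values,
    # exactly invariant to the input site order
    mat = mat[:, np.lexsort(mat)]
    idx = rng.integers(0, n_sites, size=(n_reps, n_sites))
    # replicate sums per topology: n_topo x n_reps
    reps = np.stack([mat[t][idx].sum(axis=1) for t in range(n_topo)])

    kh = np.ones(n_topo)
    for t in range(n_topo):
        if t == best:
            kh[t] = 1.0
            continue
        d_obs = totals[best] - totals[t]
        d_rep = reps[best] - reps[t]
        centered = d_rep - d_rep.mean()
        kh[t] = float((centered >= d_obs).mean())

    centered_reps = reps - reps.mean(axis=1, keepdims=True)
    rep_max = centered_reps.max(axis=0)
    sh = np.ones(n_topo)
    for t in range(n_topo):
        d_obs = totals[best] - totals[t]
        sh[t] = float((rep_max - centered_reps[t] >= d_obs).mean())

    return pd.DataFrame(
        {"loglik": totals, "kh_p": kh, "sh_p": sh, "is_ml": np.arange(n_topo) == best},
        index=names,
    )


# ---------------------------------------------------------------------------
# Placement support
# ---------------------------------------------------------------------------


def _leafset(node) -> frozenset:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def _nesting_outcome(
    tree: dendropy.Tree,
    parasite: set[str],
    donor: set[str],
    outgroup: set[str],
) -> tuple[bool, bool]:
    """(parasite_monophyly, nested_in_donor) on a tree rooted at the outgroup."""
    tree = tree.clone(depth=1)
    og = [l for l in tree.leaf_node_iter() if l.taxon.label in outgroup]
    if not og:
        raise ValueError("outgroup leaf missing from tree")
    tree.reroot_at_edge(og[0].edge, update_bipartitions=False)
    mrca = tree.mrca(taxon_labels=sorted(parasite))
    mono = _leafset(mrca) == frozenset(parasite)
    node = mrca
    while node is not None:
        others = _leafset(node) - parasite
        if others:
            break
        node = node.parent_node
    nested = bool(others) and others <= donor
    return mono, mono and nested


def hgt_placement_support(
    alignment: Mapping[str, str],
    taxon_map_or_groups: TaxonGroupMap | Mapping[str, str],
    n_bootstrap: int = 100,
    seed: int = 0,
) -> dict:
    """NJ-based test that the parasite sequences nest inside the donor clade.

    The alignment labels are classified (via a taxon-group map applied to the
    ``Species|gene`` convention, or a direct label->group mapping) into
    parasite (``self``), donor (``donor_candidate``) and outgroup (``other``)
    sets. An NJ tree is built on JC distances and rooted on the outgroup;
    support is the percentage of column-bootstrap NJ trees showing the same
    parasite-inside-donor nesting.
    """
    groups: dict[str, str] = {}
    for label in alignment:
        if isinstance(taxon_map_or_groups, TaxonGroupMap):
            species = label.split("|", 1)[0]
            groups[label] = taxon_map_or_groups.group_of(species)
        else:
            groups[label] = taxon_map_or_groups[label]
    parasite = {l for l, g in groups.items() if g == "self"}
    donor = {l for l, g in groups.items() if g == "donor_candidate"}
    outgroup = {l for l, g in groups.items() if g == "other"}
    if not parasite or len(donor) < 2:
        raise ValueError("need at least 1 parasite and 2 donor-group sequences")
    if not outgroup:
        raise ValueError("an outgroup sequence is required for rooting")

    d, _ = distance_matrix(alignment, model="JC")
    tree = nj_tree(d)
    mono, nested = _nesting_outcome(tree, parasite, donor, outgroup)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    labels, arr = _seq_matrix(alignment)
    n_sites = arr.shape[1]
    agree = 0
    for _ in range(n_bootstrap):
        cols = rng.integers(0, n_sites, size=n_sites)
        boot = {l: "".join(arr[i][cols]) for i, l in enumerate(labels)}
        try:
            bd, _ = distance_matrix(boot, model="JC")
            btree = nj_tree(bd)
            _, bnested = _nesting_outcome(btree, parasite, donor, outgroup)
        except ValueError:
            continue
        if bnested == nested:
            agree += 1
    return {
        "parasite_monophyly": mono,
        "nested_in_donor": nested,
        "support": 100.0 * agree / n_bootstrap,
        "tree": tree,
    }


# ---------------------------------------------------------------------------
# Strict-clock MPL dating
# ---------------------------------------------------------------------------


def mpl_dates(
    tree: dendropy.Tree,
    calibration_taxa: Sequence[str],
    calibration_age: float,
) -> pd.DataFrame:
    """Strict-clock mean-path-length node ages from one calibrated node.

    Each node's depth is the mean path length to its descendant tips; the
    global rate is calibration-node depth / calibration age. Returns a table
    of node depths and ages plus a clocklikeness diagnostic (the coefficient
    of variation of root-to-tip distances, reported as ``tip_depth_cv`` on
    the root row). Parent-younger-than-child impossibilities are clamped to
    the child's age with a warning.
    """
    depths: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        depths[id(node)] = 0.0 if node.is_leaf() else float(np.mean(_tip_path_list(node)))

    cal = tree.mrca(taxon_labels=list(calibration_taxa))
    cal_depth = depths[id(cal)]
    if cal_depth <= 0:
        raise ValueError("calibration node has zero depth; cannot set a rate")
    rate = cal_depth / calibration_age

    rows = []
    ages: dict[int, float] = {}
    for node in tree.postorder_node_iter():
        age = depths[id(node)] / rate
        child_ages = [ages[id(c)] for c in node.child_nodes()]
        if child_ages and age < max(child_ages):
            logger.warning("mpl_dates: clamping node age %.3f below child age", age)
            age = max(child_ages)
        ages[id(node)] = age
        label = (
            node.taxon.label
            if node.taxon is not None
            else (node.label or f"node{len(rows)}")
        )
        rows.append(
            {
                "node": label,
                "is_leaf": node.is_leaf(),
                "depth_subs": depths[id(node)],
                "age": age,
                "leafset": ",".join(sorted(l.taxon.label for l in node.leaf_iter())),
            }
        )
    root_paths = _tip_path_list(tree.seed_node)
    cv = float(np.std(root_paths) / np.mean(root_paths)) if np.mean(root_paths) > 0 else np.nan
    df = pd.DataFrame(rows)
    df["tip_depth_cv"] = cv
    df.attrs["rate"] = rate
    df.attrs["tip_depth_cv"] = cv
    return df


def _tip_path_list(node) -> list[float]:
    """Path lengths from a node to each of its descendant tips."""
    if node.is_leaf():
        return [0.0]
    out = []
    for child in node.child_nodes():
        bl = child.edge.length or 0.0
        out.extend(bl + p for p in _tip_path_list(child))
    return out
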