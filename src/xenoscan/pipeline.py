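"""End-to-end orchestration of the simulate/screen/phylo/selection/structure/
expression stages over the synthetic fixture, producing machine-readable
reports. All stage outputs are deterministic functions of the configured
seed; rerunning with the same seed reproduces the reports byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from xenoscan import io_core
from xenoscan.io_core import PipelineConfig, SequenceRecord, logger, substream, write_fasta, write_tree
from xenoscan.synthetic_data import (
    SimScenario,
    make_genomic_with_intron,
    make_transcriptome_fixture,
    simulate_stage_reads,
)

STAGES = ("simulate", "screen", "phylo", "selection", "structure", "expression")


def xenolog_label_groups(labels) -> dict[str, str]:
    """Taxon-group roles for gene-tree leaf labels (``Species|gene``)."""
    groups = {}
    for label in labels:
        sp = label.split("|", 1)[0]
        if sp.startswith("Parasite"):
            groups[label] = "self"
        elif sp.startswith("Donor"):
            groups[label] = "donor_candidate"
        elif sp.startswith("CloseRel"):
            groups[label] = "close_relative"
        else:
            groups[label] = "other"
    return groups


def no_hgt_topology(gene_tree: dendropy.Tree) -> dendropy.Tree:
    """Alternative hypothesis tree: parasite clade sister to the donor clade.

    Moves the parasite gene clade from its nested position inside the donor
    clade to a position outside it, mirroring the hypothesis that the gene
    was not horizontally acquired from within the donors. Branch lengths are
    preserved where possible; the moved clade keeps its stem length.
    """
    tree = gene_tree.clone(depth=1)
    groups = xenolog_label_groups(l.taxon.label for l in tree.leaf_node_iter())
    parasite = {l for l, g in groups.items() if g == "self"}
    donors = {l for l, g in groups.items() if g == "donor_candidate"}

    mrca_par = tree.mrca(taxon_labels=sorted(parasite))
    stem = mrca_par.edge.length or 0.0
    parent = mrca_par.parent_node
    parent.remove_child(mrca_par)
    # suppress the now-degree-2 node
    if len(parent.child_nodes()) == 1 and parent.parent_node is not None:
        only = parent.child_nodes()[0]
        grand = parent.parent_node
        extra = parent.edge.length or 0.0
        grand.remove_child(parent)
        grand.add_child(only)
        only.edge.length = (only.edge.length or 0.0) + extra

    mrca_donor = tree.mrca(taxon_labels=sorted(donors))
    dparent = mrca_donor.parent_node
    dlen = mrca_donor.edge.length or 0.0
    new = dendropy.Node()
    dparent.remove_child(mrca_donor)
    dparent.add_child(new)
    new.edge.length = dlen / 2.0
    new.add_child(mrca_donor)
    mrca_donor.edge.length = dlen / 2.0
    new.add_child(mrca_par)
    mrca_par.edge.length = stem
    return tree


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = ("all",)) -> Path:
    """Execute the requested pipeline stages and write reports.

    Stages form a dependency chain rooted at ``simulate`` (the synthetic
    fixture); requesting a later stage runs the generators it needs in
    memory. Reports land under ``config.out_dir``; identical seeds give
    byte-identical reports.
    """
    wanted = set(STAGES) if "all" in stages else set(stages)
    unknown = wanted - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}; choose from {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    scenario = SimScenario(**{**config.scenario, "seed": config.seed})
    contigs, refs, taxon_map, truth = make_transcriptome_fixture(scenario)
    summary: dict = {"seed": config.seed}

    if "simulate" in wanted:
        write_fasta(contigs, out / "contigs.fasta")
        write_fasta(refs, out / "references.fasta")
        write_tree(truth.gene_tree, out / "true_gene_tree.nwk")
        truth.contigs.to_csv(out / "truth_contigs.tsv", sep="\t")
        summary["simulate"] = {
            "n_contigs": len(contigs),
            "n_references": len(refs),
            "xenolog_contigs": truth.events["xenolog_contigs"],
        }
        logger.info("simulate: %d contigs, %d references", len(contigs), len(refs))

    if "screen" in wanted:
        from xenoscan.hgt_screen import run_screen

        report, _ = run_screen(contigs, refs, taxon_map, config, out_dir=out)
        truth_set = set(truth.events["xenolog_contigs"])
        found = set(report.candidates)
        sensitivity = len(found & truth_set) / len(truth_set) if truth_set else float("nan")
        n_neg = len(contigs) - len(truth_set)
        fpr = len(found - truth_set) / n_neg if n_neg else 0.0
        summary["screen"] = {
            "funnel": report.funnel,
            "candidates": sorted(found),
            "sensitivity": sensitivity,
            "false_positive_rate": fpr,
        }

    alignment = dict(truth.xenolog_alignment)
    rate = scenario.subst_rate

    if "phylo" in wanted:
        from xenoscan.phylo import (
            felsenstein_loglik,
            hgt_placement_support,
            mpl_dates,
            rell_topology_test,
            SiteLikelihoods,
        )

        groups = xenolog_label_groups(alignment)
        placement = hgt_placement_support(
            alignment,
            groups,
            n_bootstrap=config.n_bootstrap,
            seed=int(substream(config.seed, "placement_bootstrap").integers(2**31)),
        )
        write_tree(placement["tree"], out / "nj_gene_tree.nwk")

        scaled_true = truth.gene_tree.clone(depth=1)
        for edge in scaled_true.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= rate
        scaled_alt = no_hgt_topology(truth.gene_tree)
        for edge in scaled_alt.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= rate
        sl_true = felsenstein_loglik(alignment, scaled_true)
        sl_alt = felsenstein_loglik(alignment, scaled_alt)
        sl = SiteLikelihoods(
            loglik=np.vstack([sl_true.loglik, sl_alt.loglik]),
            topology_names=("hgt_nested", "no_hgt_sister"),
        )
        rell = rell_topology_test(
            sl,
            n_reps=config.n_rell,
            seed=int(substream(config.seed, "rell").integers(2**31)),
        )
        rell.to_csv(out / "topology_tests.tsv", sep="\t")

        donors = sorted(l for l, g in groups.items() if g == "donor_candidate")
        parasites = sorted(l for l, g in groups.items() if g == "self")
        outgroup = [l for l, g in groups.items() if g == "other"]
        dated_tree = placement["tree"].clone(depth=1)
        og_leaf = [l for l in dated_tree.leaf_node_iter() if l.taxon.label in outgroup][0]
        dated_tree.reroot_at_edge(og_leaf.edge, update_bipartitions=False)
        dates = mpl_dates(dated_tree, donors, config.calibration_age)
        dates.to_csv(out / "node_ages.tsv", sep="\t", index=False)
        transfer_node = dated_tree.mrca(
            taxon_labels=parasites + [f"{truth.events['donor_lineage']}|alb"]
        )
        transfer_leafset = ",".join(sorted(l.taxon.label for l in transfer_node.leaf_iter()))
        transfer_rows = dates[dates.leafset == transfer_leafset]
        transfer_age = float(transfer_rows.age.iloc[0]) if len(transfer_rows) else float("nan")
        summary["phylo"] = {
            "parasite_monophyly": bool(placement["parasite_monophyly"]),
            "nested_in_donor": bool(placement["nested_in_donor"]),
            "support": placement["support"],
            "kh_p_no_hgt": float(rell.loc["no_hgt_sister", "kh_p"]),
            "sh_p_no_hgt": float(rell.loc["no_hgt_sister", "sh_p"]),
            "transfer_age_estimate": transfer_age,
        }

    if "selection" in wanted:
        from xenoscan.selection import parsimony_branch_counts, pool_lineages, site_constraint_scan

        groups = xenolog_label_groups(alignment)
        ingroup = {l: s for l, s in alignment.items() if groups[l] != "other"}
        sub_tree = truth.gene_tree.clone(depth=1)
        sub_tree.retain_taxa_with_labels(sorted(ingroup))
        branch_counts = parsimony_branch_counts(ingroup, sub_tree)
        branch_counts.to_csv(out / "branch_counts.tsv", sep="\t")

        pools = _clade_pools(sub_tree, groups)
        pooled = pool_lineages(branch_counts, pools, ingroup)
        pd.DataFrame([vars(p) for p in pooled]).to_csv(out / "pooled_dnds.tsv", sep="\t", index=False)

        scan = site_constraint_scan(ingroup, sub_tree)
        scan.to_csv(out / "site_constraint.tsv", sep="\t")
        summary["selection"] = {
            "pooled": {
                p.scope: {
                    "Nd": p.Nd,
                    "Sd": p.Sd,
                    "omega": p.omega,
                    "ds_dn_ratio": (p.dS / p.dN) if p.dN and p.dS is not None else None,
                }
                for p in pooled
            },
            "cysteine_score_mean_percentile": _cysteine_percentile(scan),
        }

    if "structure" in wanted:
        from xenoscan.gene_structure import (
            check_splice_sites,
            cysteine_scaffold_score,
            infer_intron,
            intron_conservation,
            write_gff3,
        )

        focal = scenario.parasite_taxa[0]
        cds_a = alignment[f"{focal}|alb1"]
        cds_b = alignment[f"{truth.events['donor_lineage']}|alb"]
        seed_a = int(substream(config.seed, "genomic_a").integers(2**31))
        gen_a, truth_a = make_genomic_with_intron(cds_a, scenario.intron_length, seed=seed_a)
        # The donor copy shares the intron position and (initially) sequence,
        # emulating transfer of a genomic segment.
        gen_b_res = cds_b[: truth_a.introns[0][0]] + truth_a.intron_seq(gen_a.residues) + cds_b[truth_a.introns[0][0]:]
        st_a = infer_intron(gen_a.residues, cds_a, gene_id=f"{focal}|alb1")
        st_b = infer_intron(gen_b_res, cds_b, gene_id=f"{truth.events['donor_lineage']}|alb")
        cons = intron_conservation(
            st_a, gen_a.residues, st_b, gen_b_res,
            {st_a.gene_id: cds_a, st_b.gene_id: cds_b},
        )
        write_gff3(st_a, "xeno_alb1_genomic", out / "xeno_alb1.gff3")
        protein = str(Seq(cds_a).translate()).rstrip("*")
        scaffold = cysteine_scaffold_score(protein)
        summary["structure"] = {
            "intron_recovered": st_a.introns == truth_a.introns,
            "splice_sites": check_splice_sites(st_a, gen_a.residues),
            "intron_conservation": cons,
            "scaffold_total": scaffold.total,
            "scaffold_passed": bool(scaffold.passed),
            "cysteine_count": scaffold.cysteine_count,
        }

    if "expression" in wanted:
        from xenoscan.expression import naive_map_counts, rpkm_table, stage_summary

        # The read pool contains the xenolog genes (stage-structured target
        # profile) plus the flat-expressed background transcriptome, so the
        # xenologs' per-stage share of the library varies as their profile.
        xeno_ids = truth.events["xenolog_contigs"]
        genes = [c for c in contigs if c.id in xeno_ids] + [
            c for c in contigs if c.id not in xeno_ids
        ]
        n_stages = len(scenario.expression_profile)
        profile = np.full((len(genes), n_stages), scenario.background_rpkm)
        for i in range(len(xeno_ids)):
            profile[i] = scenario.expression_profile
        reads, true_counts = simulate_stage_reads(
            genes,
            profile,
            read_length=scenario.read_length,
            library_sizes=[scenario.library_size] * n_stages,
            seed=int(substream(config.seed, "reads").integers(2**31)),
        )
        ambiguous_total = 0
        count_cols = {}
        for stage, stage_reads in reads.items():
            col, amb = naive_map_counts(stage_reads, genes)
            count_cols[stage] = col
            ambiguous_total += amb
        counts = pd.DataFrame(count_cols)
        libs = {stage: int(counts[stage].sum()) for stage in counts.columns}
        table = rpkm_table(counts, {g.id: len(g.residues) for g in genes}, libs)
        table.rpkm.to_csv(out / "rpkm.tsv", sep="\t")
        summ = stage_summary(table)
        summ.to_csv(out / "stage_summary.tsv", sep="\t")
        first = summ.loc[xeno_ids[0]]
        background_exact = bool(
            (counts.loc[~counts.index.isin(xeno_ids)] == true_counts.loc[~true_counts.index.isin(xeno_ids)])
            .all()
            .all()
        )
        summary["expression"] = {
            "background_counts_match_truth": background_exact,
            "ambiguous_reads": ambiguous_total,
            "min_stage": str(first.min_stage),
            "max_stage": str(first.max_stage),
            "max_fold": float(first.fold),
        }

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return out


def _clade_pools(tree: dendropy.Tree, groups: dict[str, str]) -> dict[str, list[str]]:
    """Pool branch names into parasite-clade vs donor-clade lineages."""
    from xenoscan.selection import _branch_labels

    labels = _branch_labels(tree)
    parasite = {l for l, g in groups.items() if g == "self"}
    pools: dict[str, list[str]] = {"broomrape": [], "legume": []}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        leafset = {l.taxon.label for l in node.leaf_iter()}
        name = labels[id(node)]
        if leafset <= parasite:
            pools["broomrape"].append(name)
        elif not (leafset & parasite):
            pools["legume"].append(name)
    return pools


def _cysteine_percentile(scan: pd.DataFrame) -> float:
    """Mean percentile rank of cysteine columns' constraint scores."""
    used = scan[scan.used]
    if not used.is_cysteine.any():
        return float("nan")
    ranks = used.constraint_score.rank(pct=True)
    return float(ranks[used.is_cysteine].mean())
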