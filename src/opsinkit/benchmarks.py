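"""End-to-end benchmark experiments on synthetic data with known truth.

Each function runs one self-contained experiment — simulation, inference,
scoring — and returns plain numbers. They power both the validation test
suite and the reproduction script, so every reported quantity is recomputed
from scratch at call time.
"""

from __future__ import annotations

import numpy as np

from opsinkit.config import SimulationConfig, PlantedEvent


def truth_recovery(n_seeds: int = 20, base_seed: int = 1) -> dict:
    """Planted-event recovery through the full inference chain.

    For each seed: a 12-species tree with five planted events spanning all
    duplication mechanisms; annotation, gene trees (true and NJ-estimated),
    LCA reconciliation and mechanistic classification; events scored for
    exact branch and exact mechanism.
    """
    from opsinkit.pipeline import run_truth_recovery_modes
    tot = {"true": [0, 0, 0], "nj": [0, 0, 0]}
    n_events = 0
    n_count_exact = {"true": 0, "nj": 0}
    recalls = []
    for k in range(n_seeds):
        reports = run_truth_recovery_modes(base_seed + k)
        n_events += reports["true"].n_true
        recalls.append(reports["true"].annotation_recall)
        for mode, rep in reports.items():
            tot[mode][0] += rep.branch_exact
            tot[mode][1] += rep.event_exact
            n_count_exact[mode] += rep.count_exact
    return {
        "n_seeds": n_seeds,
        "n_events": n_events,
        "branch_exact_true_pct": 100.0 * tot["true"][0] / n_events,
        "event_exact_true_pct": 100.0 * tot["true"][1] / n_events,
        "count_exact_true_pct": 100.0 * n_count_exact["true"] / n_seeds,
        "branch_exact_nj_pct": 100.0 * tot["nj"][0] / n_events,
        "event_exact_nj_pct": 100.0 * tot["nj"][1] / n_events,
        "count_exact_nj_pct": 100.0 * n_count_exact["nj"] / n_seeds,
        "annotation_recall_pct": 100.0 * float(np.mean(recalls)),
    }


def ng86_hand_examples() -> dict:
    """The two fixed NG86 worked examples (lysine-run codon rows)."""
    from opsinkit.selection import ng86_dnds
    syn = ng86_dnds("AAA" * 9, "AAA" * 8 + "AAG")
    non = ng86_dnds("AAA" * 9, "AAA" * 8 + "ACA")
    return {"dS_synonymous_example": syn.dS, "dN_nonsynonymous_example": non.dN}


def estimator_recovery(omega: float, n_rep: int = 100, n_codons: int = 500,
                       divergence: float = 0.4, seed: int = 0) -> float:
    """Mean NG86 ω-hat over replicate pairs simulated at a known ω (κ=1)."""
    from opsinkit.selection import ng86_dnds
    from opsinkit.simul import simulate_codon_pair
    est = []
    for i in range(n_rep):
        a, b = simulate_codon_pair(n_codons, divergence, omega, 1.0,
                                   seed * 100_003 + 17 * i + 1)
        est.append(ng86_dnds(a, b).omega)
    return float(np.nanmean(est))


def group_test_type1(n_datasets: int = 100, n_per_group: int = 10,
                     n_perm: int = 199, seed: int = 0) -> float:
    """Type-I error of the permutation group test under a common null."""
    from opsinkit.selection import compare_groups_dnds
    rng = np.random.default_rng(seed)
    rej = 0
    for i in range(n_datasets):
        vals = {g: rng.lognormal(-2.0, 0.5, n_per_group)
                for g in ("nocturnal", "diurnal", "both")}
        p = compare_groups_dnds(vals, n_perm=n_perm, seed=int(rng.integers(2**31)))
        rej += p["p_value"] <= 0.05
    return rej / n_datasets


def trait_test_type1(n_datasets: int = 100, n_species: int = 20,
                     n_boot: int = 49, seed: int = 0) -> float:
    """Type-I error of the trait-association bootstrap under independence."""
    from opsinkit.simul import simulate_species_tree
    from opsinkit.selection import trait_association_test, TraitVector
    from opsinkit.selection.pagel import _TreeArrays, _simulate_trait
    tree = simulate_species_tree(n_species, 1.0, 0.0, seed=seed * 7 + 77)
    ta = _TreeArrays(tree, [lf.taxon.label for lf in tree.leaf_node_iter()])
    rate = 1.0 / ta.height
    rej = done = 0
    i = 0
    while done < n_datasets:
        i += 1
        rng = np.random.default_rng([seed % (2**31), i])
        a = _simulate_trait(ta, rate, rate, rng)
        b = _simulate_trait(ta, rate, rate, rng)
        if len(set(a.values())) < 2 or len(set(b.values())) < 2:
            continue
        tv = TraitVector({sp: ("diurnal" if v else "nocturnal")
                          for sp, v in a.items()}, b)
        p = trait_association_test(tree, tv, n_boot=n_boot,
                                   seed=int(rng.integers(2**31)))["p_value"]
        done += 1
        rej += p <= 0.05
    return rej / n_datasets


def two_clade_alignment(omega_fg: float, omega_bg: float, seed: int,
                        n_per_side: int = 10, n_codons: int = 300):
    """A family with a relaxed foreground clade and purifying background,
    the parent/retrocopy configuration."""
    from opsinkit.simul.codon_evolve import evolve_branch, random_root_cds
    from opsinkit.codons import cds_to_indices, indices_to_cds
    rng = np.random.default_rng(seed)
    root = cds_to_indices(random_root_cds(n_codons, rng, start_codon=False))
    anc_fg = evolve_branch(root, 0.05, omega_bg, 2.0, rng)
    anc_bg = evolve_branch(root, 0.05, omega_bg, 2.0, rng)
    aln = {}
    for i in range(n_per_side):
        aln[f"fg{i}"] = indices_to_cds(
            evolve_branch(anc_fg, 0.15, omega_fg, 2.0, rng))
        aln[f"bg{i}"] = indices_to_cds(
            evolve_branch(anc_bg, 0.15, omega_bg, 2.0, rng))
    return aln, [k for k in aln if k.startswith("fg")]


def relaxation_power(n_rep: int = 100, omega_fg: float = 0.8,
                     omega_bg: float = 0.1, n_per_side: int = 10,
                     n_codons: int = 300, n_perm: int = 199,
                     seed: int = 0) -> float:
    """Power of the clade ω-ratio permutation test at the stated effect."""
    from opsinkit.selection import relaxation_test
    sig = 0
    for i in range(n_rep):
        aln, fg = two_clade_alignment(omega_fg, omega_bg,
                                      seed * 100_003 + 31 * i + 7,
                                      n_per_side, n_codons)
        res = relaxation_test(aln, fg, n_perm=n_perm, seed=seed + i)
        sig += res.p_value < 0.05
    return sig / n_rep


def linkage_emulation(n_seeds: int = 200, n_background: int = 1000,
                      seed: int = 0) -> dict:
    """Tandem pairs (~6 kb) against a ~16 kb-median paralog background."""
    from opsinkit.linkage import linkage_percentile
    from opsinkit.simul import simulate_paralog_background
    below = 0
    percentiles = []
    for i in range(n_seeds):
        rng = np.random.default_rng([seed % (2**31), 5, i])
        focal = float(rng.uniform(3000, 13_000))
        bg = simulate_paralog_background(n_background,
                                         seed=(seed * 9973 + i) % (2**31))
        out = linkage_percentile(focal, bg)
        percentiles.append(out["percentile"])
        below += out["percentile"] < 50.0
    return {
        "below_median_pct": 100.0 * below / n_seeds,
        "median_focal_percentile": float(np.median(percentiles)),
    }


def retro_fusion_accuracy(n_seeds: int = 10, seed: int = 0) -> dict:
    """Mechanism and translocation-mode accuracy on simulator fixtures."""
    from opsinkit.simul import (simulate_species_tree,
                                simulate_gene_family_history,
                                evolve_codon_sequences, emit_genomes)
    from opsinkit.pipeline import normalize_tree_height, _evaluation_genome
    from opsinkit.characterize import classify_duplicate
    mech_ok = mech_n = mode_ok = mode_n = 0
    for k in range(n_seeds):
        s = seed + 50 + k
        tree = simulate_species_tree(6, 1.0, 0.0, s)
        normalize_tree_height(tree)
        # the retro copy is pinned away from chr6 so the fusion (of chr6)
        # cannot coincidentally sweep it along
        cfg = SimulationConfig(seed=s, n_species=6, planted_events=[
            PlantedEvent("duplication_retro", "n2", family="LW",
                         dest_chrom="chr2"),
            PlantedEvent("duplication_dispersed", "n3", family="RH7",
                         dest_chrom="chr6"),
            PlantedEvent("chromosome_fusion", "n3", dest_chrom="chr6"),
        ])
        ledger = simulate_gene_family_history(tree, cfg)
        seqs = evolve_codon_sequences(ledger, tree, cfg)
        genomes = emit_genomes(ledger, seqs, cfg)
        for fam, want_mech, want_mode in (("LW", "retro", "single_gene"),
                                          ("RH7", "dna", "fusion")):
            two = [sp for sp in ledger.extant
                   if ledger.copy_number(sp, fam) == 2]
            one = [sp for sp in ledger.extant
                   if ledger.copy_number(sp, fam) == 1]
            if not two or not one:
                continue
            focal = genomes[two[0]]
            comp = genomes[one[0]]
            copies = sorted(
                (g for g in focal.genes.values()
                 if g.attributes.get("family") == fam),
                key=lambda g: -g.exon_count)
            parent, dup = copies[0], copies[-1]
            if fam == "RH7":   # both 8-exon; parent is the non-Z copy
                parent = next(g for g in copies if g.chrom != "chrZ")
                dup = next(g for g in copies if g.chrom == "chrZ")
            cls = classify_duplicate(dup, parent, focal,
                                     comparator_genome=comp)
            mech_n += 1
            mech_ok += cls.mechanism == want_mech
            if cls.location == "translocated":
                mode_n += 1
                mode_ok += cls.translocation_mode == want_mode
    return {
        "mechanism_accuracy_pct": 100.0 * mech_ok / mech_n,
        "translocation_mode_accuracy_pct": 100.0 * mode_ok / mode_n,
        "n_mechanism": mech_n,
        "n_mode": mode_n,
    }


def expression_roundtrip(n_seeds: int = 200, fold: float = 50.0,
                         seed: int = 0) -> dict:
    """TPM normalization and recovery of planted reciprocal stage bias."""
    from opsinkit.expression import compute_tpm, paralog_expression_divergence
    from opsinkit.simul import simulate_expression
    from opsinkit.simul.expression_sim import biased_profiles
    stages3 = ["larva_instar1", "adult_male_head", "adult_female_head"]
    genes = ["LWS1", "LWS2"] + [f"bg{i}" for i in range(20)]
    ok = 0
    max_colsum_err = 0.0
    for i in range(n_seeds):
        prof = biased_profiles(genes, stages3, base_mean=50.0,
                               bias={"LWS2": "larva_instar1"}, fold=fold)
        prof["LWS1"]["adult_male_head"] = 50.0 * fold
        prof["LWS1"]["adult_female_head"] = 50.0 * fold
        counts, lengths, stages = simulate_expression(
            genes, prof, seed=(seed * 99_991 + i) % (2**31))
        stages = stages.replace({"adult_male_head": "adult",
                                 "adult_female_head": "adult"})
        tpm = compute_tpm(counts, lengths)
        err = float(np.abs(tpm.sum(axis=0) / 1e6 - 1.0).max())
        max_colsum_err = max(max_colsum_err, err)
        out = paralog_expression_divergence(tpm, "LWS1", "LWS2", stages)
        ok += out["classification"] == "reciprocal stage bias"
    return {
        "reciprocal_bias_recovery_pct": 100.0 * ok / n_seeds,
        "max_tpm_colsum_rel_error": max_colsum_err,
    }


def format_fidelity(seed: int = 0, tmp_dir=None) -> dict:
    """Byte-level round trips of the emitted FASTA/GFF3/newick files."""
    import tempfile
    from pathlib import Path
    import dendropy
    from opsinkit.genome import (load_genome, write_fasta, write_gff3,
                                 write_chromosome_table)
    from opsinkit.simul import (simulate_species_tree,
                                simulate_gene_family_history,
                                evolve_codon_sequences, emit_genomes)
    tree = simulate_species_tree(4, 1.0, 0.0, seed + 3)
    cfg = SimulationConfig(seed=seed + 3, n_species=4, planted_events=[
        PlantedEvent("duplication_tandem", "n2", family="blue")])
    ledger = simulate_gene_family_history(tree, cfg)
    seqs = evolve_codon_sequences(ledger, tree, cfg)
    ctx = tempfile.TemporaryDirectory() if tmp_dir is None else None
    out = Path(tmp_dir or ctx.name)
    emit_genomes(ledger, seqs, cfg, out_dir=out)
    ok = True
    for sp in sorted(ledger.extant):
        genome = load_genome(sp, out / f"{sp}.fa", out / f"{sp}.gff3",
                             out / f"{sp}.chroms.tsv")
        sub = Path(out / "rt")
        sub.mkdir(exist_ok=True)
        write_fasta(genome.sequences, sub / f"{sp}.fa")
        write_gff3(genome, sub / f"{sp}.gff3")
        write_chromosome_table(genome, sub / f"{sp}.chroms.tsv")
        for name in (f"{sp}.fa", f"{sp}.gff3", f"{sp}.chroms.tsv"):
            ok &= (out / name).read_bytes() == (sub / name).read_bytes()
    t1 = dendropy.Tree.get(path=str(out / "species_tree.nwk"),
                           schema="newick", preserve_underscores=True)
    t1.write(path=str(out / "rt" / "species_tree.nwk"), schema="newick",
             suppress_rooting=True)
    ok &= ((out / "species_tree.nwk").read_bytes()
           == (out / "rt" / "species_tree.nwk").read_bytes())
    if ctx is not None:
        ctx.cleanup()
    return {"round_trip_identical": bool(ok)}
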