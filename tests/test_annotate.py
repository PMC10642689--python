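import numpy as np
import pytest
from Bio.Seq import Seq

from opsinkit.annotate import (
    translated_search,
    merge_hits_to_loci,
    reconstruct_orf,
    classify_opsin,
    iterative_annotation,
    AnnotationThresholds,
)
from opsinkit.simul.codon_evolve import random_root_cds
from tests.conftest import rooted


def _random_genome(rng, length=20_000):
    return {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, length))}


@pytest.fixture(scope="module")
def protein_and_cds():
    rng = np.random.default_rng(42)
    cds = random_root_cds(300, rng)
    return str(Seq(cds).translate()), cds


class TestTranslatedSearch:
    def test_exact_forward_encoding(self, protein_and_cds, rng):
        prot, cds = protein_and_cds
        genome = _random_genome(rng)
        # frame +1: insert at a codon-aligned position
        seq = genome["chr1"]
        genome["chr1"] = seq[:9000] + cds + seq[9000:]
        hits = translated_search(prot, genome, min_score=100)
        assert hits
        best = hits[0]
        assert best.strand == "+"
        assert best.identity == 100.0
        assert best.coverage == 1.0
        assert best.interval == (9000, 9000 + len(cds))

    def test_reverse_strand_symmetry(self, protein_and_cds, rng):
        prot, cds = protein_and_cds
        genome = _random_genome(rng)
        rc = str(Seq(cds).reverse_complement())
        seq = genome["chr1"]
        genome["chr1"] = seq[:9000] + rc + seq[9000:]
        hits = translated_search(prot, genome, min_score=100)
        assert hits and hits[0].strand == "-"
        assert hits[0].identity == 100.0

    def test_no_shared_kmers_gives_empty(self, rng):
        # construct genome guaranteed to share no 5-mer with the query:
        # query uses only {M, W} amino acids (codons ATG/TGG) while the
        # genome is built from codons of other residues; verified by scan
        query = "MW" * 30
        genome = {"chr1": "GCTGCCGCAGCG" * 500}  # alanine codons only
        for strand_seq in (genome["chr1"],
                           str(Seq(genome["chr1"]).reverse_complement())):
            for f in range(3):
                aa = str(Seq(strand_seq[f:f + 3 * ((6000 - f) // 3)]).translate())
                assert not any(aa[i:i + 5] in {"MWMWM", "WMWMW"}
                               for i in range(len(aa) - 4))
        assert translated_search(query, genome, min_score=30) == []

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            translated_search("MKV", {}, 10)


class TestReconstructOrf:
    def test_single_exon_exact(self, protein_and_cds, rng):
        prot, cds = protein_and_cds
        genome = _random_genome(rng)
        seq = genome["chr1"]
        genome["chr1"] = seq[:9000] + cds + "TAA" + seq[9000:]
        hits = translated_search(prot, genome, min_score=100)
        model = reconstruct_orf(hits[0], genome, prot)
        assert model is not None
        assert model.exon_count == 1
        assert model.exons == [(9000, 9000 + len(cds) + 3)]
        assert model.complete
        assert model.protein == prot

    def test_intron_insertion_recovered(self, protein_and_cds, rng):
        # build the fixture by inserting one 100-bp GT..AG intron; the
        # construction itself is the oracle for the expected exon structure
        prot, cds = protein_and_cds
        intron = "GT" + "".join("ACGT"[i] for i in rng.integers(0, 4, 96)) + "AG"
        split = 150  # codon boundary: 50 codons in exon 1
        gene = cds[:split] + intron + cds[split:] + "TAA"
        genome = _random_genome(rng)
        seq = genome["chr1"]
        genome["chr1"] = seq[:9000] + gene + seq[9000:]
        hits = translated_search(prot, genome, min_score=80)
        loci = merge_hits_to_loci(hits)
        model = reconstruct_orf(loci[0], genome, prot)
        assert model is not None
        assert model.exon_count == 2
        assert model.exons == [(9000, 9000 + split),
                               (9000 + split + 100,
                                9000 + len(gene))]
        assert model.protein == prot

    def test_missing_start_codon_flagged(self, protein_and_cds, rng):
        prot, cds = protein_and_cds
        # remove the start codon from both gene and query
        genome = _random_genome(rng)
        seq = genome["chr1"]
        genome["chr1"] = seq[:9000] + cds[3:] + "TAA" + seq[9000:]
        hits = translated_search(prot[1:], genome, min_score=100)
        model = reconstruct_orf(hits[0], genome, prot[1:])
        assert model is not None
        assert not model.has_start
        assert model.has_stop
        assert not model.complete


@pytest.fixture(scope="module")
def references():
    rng = np.random.default_rng(7)
    refs = {}
    for fam in ("UV", "blue", "LW", "RH7", "c-opsin"):
        refs[f"ref_{fam}"] = (fam, str(Seq(random_root_cds(300, rng)).translate()))
    return refs


class TestClassify:
    def test_identical_to_reference(self, references):
        label, ev = classify_opsin(references["ref_LW"][1], references)
        assert label == "LW"

    def test_exact_tie_is_unassigned(self, references):
        refs = dict(references)
        # make blue and UV references identical: any query ties
        refs["ref_blue"] = ("blue", refs["ref_UV"][1])
        label, ev = classify_opsin(refs["ref_UV"][1], refs)
        assert label == "unassigned"

    def test_reference_order_invariance(self, references):
        q = references["ref_blue"][1]
        l1, _ = classify_opsin(q, dict(sorted(references.items())))
        l2, _ = classify_opsin(q, dict(sorted(references.items(), reverse=True)))
        assert l1 == l2 == "blue"

    def test_missing_class_rejected(self, references):
        refs = {k: v for k, v in references.items() if v[0] != "RH7"}
        with pytest.raises(ValueError):
            classify_opsin("MKV" * 50, refs)

    def test_tree_clade_rule(self, references):
        tree = rooted("((gene_x:1,ref_LW:1):1,(ref_UV:1,(ref_blue:1,"
                      "(ref_RH7:1,ref_c-opsin:1):1):1):1);")
        label, ev = classify_opsin("gene_x", references, gene_tree=tree)
        assert label == "LW"


class TestIterativeAnnotation:
    def test_empty_genomes_fixed_point(self, rng):
        seeds = {"q": "MKVLWAYTSIRNMKVLWAYTSIRN" * 12}
        genomes = {"sp1": _random_genome(rng, 10_000)}
        out = iterative_annotation(seeds, genomes, max_rounds=3)
        assert out == {"sp1": []}

    def test_transitive_homolog_needs_second_round(self):
        """Seed Q detects gene H (~75% identity) but not the doubly
        divergent gene T (~57%); H detects T, so T appears only with a
        second annotation round."""
        rng = np.random.default_rng(11)
        from opsinkit.codons import SENSE_CODONS, AA_OF
        by_aa = {}
        for c in SENSE_CODONS:
            by_aa.setdefault(AA_OF[c], c)
        aas = sorted(by_aa)

        def mutate(prot, p):
            out = []
            for ch in prot:
                if rng.random() < p:
                    out.append(aas[int(rng.integers(len(aas)))])
                else:
                    out.append(ch)
            return "".join(out)

        cds_h = random_root_cds(300, rng)
        prot_h = str(Seq(cds_h).translate())
        q = mutate(prot_h, 0.25)              # Q ~75% identical to H
        prot_t = mutate(prot_h, 0.25)         # T ~75% to H, ~57% to Q
        cds_t = "ATG" + "".join(by_aa[a] for a in prot_t[1:])
        genome = _random_genome(rng, 30_000)
        seq = genome["chr1"]
        genome["chr1"] = (seq[:9000] + cds_h + "TAA" + seq[9000:20000]
                          + cds_t + "TAA" + seq[20000:])
        thr = AnnotationThresholds(min_hit_score=60, min_model_score=950)
        one_round = iterative_annotation({"q": q}, {"sp": genome},
                                         max_rounds=1, thresholds=thr)
        two_rounds = iterative_annotation({"q": q}, {"sp": genome},
                                          max_rounds=3, thresholds=thr)
        assert len(one_round["sp"]) == 1
        assert len(two_rounds["sp"]) == 2

    def test_rounds_monotone_and_seeds_complete(self, small_dataset):
        seqs = small_dataset["seqs"]
        cfg = small_dataset["cfg"]
        root_prot = {fam: str(Seq(seqs[f"__root__{fam}"]).translate())
                     for fam in cfg.families}
        genomes = {sp: g.sequences
                   for sp, g in list(small_dataset["genomes"].items())[:2]}
        r1 = iterative_annotation(dict(root_prot), genomes, max_rounds=1)
        r2 = iterative_annotation(dict(root_prot), genomes, max_rounds=2)
        for sp in genomes:
            assert len(r2[sp]) >= len(r1[sp])
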