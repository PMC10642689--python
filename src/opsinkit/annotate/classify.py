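"""Opsin class assignment against labeled reference proteins.

A gene is assigned the class (UV, blue, LW, RH7, c-opsin) of its
best-scoring reference only when the margin over the best other class
exceeds a threshold; exact ties are never silently resolved. When a gene
tree is supplied, the clade rule applies instead: the label is the class of
the smallest reference-containing clade around the gene, provided that clade
is class-pure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from opsinkit.annotate.search import make_protein_aligner
from opsinkit.genome import GeneModel

OPSIN_CLASSES = ("UV", "blue", "LW", "RH7", "c-opsin")
UNASSIGNED = "unassigned"


@dataclass
class OpsinGene:
    model: GeneModel
    opsin_class: str
    evidence: dict = field(default_factory=dict)
    lambda_max: str | None = None  # free-text metadata, never computed

    @property
    def gene_id(self) -> str:
        return self.model.gene_id


def classify_opsin(gene: GeneModel | str,
                   references: dict[str, tuple[str, str]],
                   gene_tree=None, margin: float = 0.05) -> tuple[str, dict]:
    """Classify a gene model (or raw protein) against labeled references.

    Parameters
    ----------
    references : reference id -> (class label, protein sequence); must cover
        all five opsin classes.
    gene_tree : optional rooted dendropy tree containing the gene and the
        references as leaves; activates the monophyletic-clade rule.
    margin : required relative score margin of the best class over the
        runner-up class; ties or sub-margin calls return "unassigned".

    Returns (label, evidence dict).
    """
    classes = {cls for cls, _ in references.values()}
    missing = set(OPSIN_CLASSES) - classes
    if missing:
        raise ValueError(f"reference set missing classes: {sorted(missing)}")
    protein = gene if isinstance(gene, str) else gene.protein

    if gene_tree is not None:
        return _classify_by_clade(gene, references, gene_tree)

    aligner = make_protein_aligner("local")
    best_by_class: dict[str, tuple[float, str]] = {}
    for rid, (cls, ref_seq) in sorted(references.items()):
        score = float(aligner.score(protein, ref_seq))
        if cls not in best_by_class or score > best_by_class[cls][0]:
            best_by_class[cls] = (score, rid)
    ranked = sorted(best_by_class.items(), key=lambda kv: -kv[1][0])
    (cls1, (s1, rid1)), (cls2, (s2, _)) = ranked[0], ranked[1]
    evidence = {"best_reference": rid1, "best_score": s1,
                "runner_up_class": cls2, "runner_up_score": s2}
    if s1 <= 0 or (s1 - s2) / abs(s1) < margin:
        return UNASSIGNED, evidence
    return cls1, evidence


def _classify_by_clade(gene, references, gene_tree) -> tuple[str, dict]:
    gene_id = gene if isinstance(gene, str) else gene.gene_id
    leaf = None
    for lf in gene_tree.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == gene_id:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"gene {gene_id} not in gene tree")
    node = leaf.parent_node
    while node is not None:
        ref_classes = {
            references[lf.taxon.label][0]
            for lf in node.leaf_iter()
            if lf.taxon is not None and lf.taxon.label in references
        }
        if ref_classes:
            evidence = {"clade_classes": sorted(ref_classes)}
            if len(ref_classes) == 1:
                return next(iter(ref_classes)), evidence
            return UNASSIGNED, evidence
        node = node.parent_node
    return UNASSIGNED, {"clade_classes": []}
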