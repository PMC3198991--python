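"""Synthetic data with recorded ground truth.

Two generators drive every planted-truth test in the package:

* :func:`evolve_family` grows a rhodopsin-like protein family from the
  packaged anchor sequence along a known tree, planting class-diagnostic
  residues that are held invariant while the rest of the sequence accrues
  Poisson substitutions and short indels.  The returned truth records the
  class label of every taxon, the generating tree, and the exact residue
  correspondence of each leaf back to the anchor.

* :func:`generate_genome` writes a genome of iid background nucleotides
  containing non-overlapping genes drawn from a codon model consistent with
  the background G+C, plus planted "foreign" genes with shifted G+C and
  sharpened codon bias.

The substitution process is deliberately simple (uniform replacement among
the 19 alternatives, no rate heterogeneity, no empirical exchangeabilities):
these generators exercise anchoring, rule recovery and compositional
screening, and make no claim of evolutionary realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .composition import GENETIC_CODE, STOP_CODONS, SYNONYMOUS_FAMILIES
from .fingerprint import FingerprintConfig, RhodopsinClass, default_config, load_reference
from .seqio import GeneAnnotation, GenomeRecord, ProteinRecord, AlignedSet

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# residues planted at (acceptor, donor, helixG, schiff_lysine) per class
CLASS_PLANTS: dict[RhodopsinClass, tuple[str, str, str, str]] = {
    RhodopsinClass.PROTON_PUMP: ("D", "D", "D", "K"),
    RhodopsinClass.CHLORIDE_PUMP: ("T", "A", "D", "K"),
    RhodopsinClass.SENSORY: ("D", "Y", "D", "K"),
    RhodopsinClass.XENORHODOPSIN: ("D", "S", "P", "K"),
    RhodopsinClass.UNCLASSIFIED: ("D", "D", "D", "L"),  # no Schiff-base lysine
}


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def simulate_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    divergence: float | None = None,
    prefix: str = "t",
) -> TreeNode:
    """Yule (pure-birth) tree on ``n_taxa`` labelled tips.

    When ``divergence`` is given, branch lengths are rescaled so the mean
    root-to-tip path length equals it (substitutions per site).
    """
    if n_taxa < 3:
        raise SimulationError("need >= 3 taxa")
    if birth_rate <= 0:
        raise SimulationError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    active = [root]
    while len(active) < n_taxa:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        for node in active:
            node.length = (node.length or 0.0) + wait
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        children = [TreeNode(length=0.0), TreeNode(length=0.0)]
        parent.extend(children)
        active.extend(children)
    # terminal stretch so tips have non-zero pendant branches
    wait = rng.exponential(1.0 / (birth_rate * len(active)))
    for node in active:
        node.length = (node.length or 0.0) + wait
    order = rng.permutation(n_taxa)
    for i, tip in enumerate(active):
        tip.name = f"{prefix}{order[i]:03d}"
    root.length = None
    if divergence is not None:
        depths = [sum(a.length or 0.0 for a in tip.ancestors() if a.length) + tip.length
                  for tip in root.tips()]
        mean_depth = float(np.mean(depths))
        if mean_depth > 0:
            factor = divergence / mean_depth
            for node in root.traverse(include_self=False):
                if node.length is not None:
                    node.length *= factor
    return root


# ---------------------------------------------------------------------------
# Protein families
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one synthetic rhodopsin family.

    ``n_taxa`` gives the number of taxa per class; every class becomes a
    clade on its own Yule subtree (root-to-tip divergence ``divergence``),
    and subtrees hang off the family root on stems of length
    ``class_separation`` so classes are cleanly separated.
    """

    n_taxa: dict[RhodopsinClass, int] = field(
        default_factory=lambda: {
            RhodopsinClass.XENORHODOPSIN: 10,
            RhodopsinClass.PROTON_PUMP: 8,
            RhodopsinClass.CHLORIDE_PUMP: 8,
            RhodopsinClass.SENSORY: 8,
        }
    )
    divergence: float = 0.25
    class_separation: float = 0.5
    birth_rate: float = 1.0
    indel_rate: float = 0.01  # indel events per site per substitution/site
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 3 for n in self.n_taxa.values()):
            raise SimulationError("each class needs >= 3 taxa")
        if self.divergence < 0:
            raise SimulationError("divergence must be >= 0")
        if self.divergence > 1.0:
            raise SimulationError(
                "divergence > 1.0 substitutions/site would defeat anchoring; "
                "use <= 1.0"
            )


@dataclass
class FamilyTruth:
    """Ground truth for a generated family."""

    labels: dict[str, RhodopsinClass]
    tree: TreeNode
    # per taxon: reference precursor position -> 1-based position in the taxon
    correspondence: dict[str, dict[int, int]]
    alignment: AlignedSet  # reference-anchored true alignment (insertions dropped)


_ABBREV = {
    RhodopsinClass.XENORHODOPSIN: "xeno",
    RhodopsinClass.PROTON_PUMP: "bprot",
    RhodopsinClass.CHLORIDE_PUMP: "chlor",
    RhodopsinClass.SENSORY: "sens",
    RhodopsinClass.UNCLASSIFIED: "uncl",
}


INDEL_BUFFER = 2  # indels keep this distance from anchored sites


def _anchored_indices(cfg: FingerprintConfig) -> set[int]:
    """0-based mature-sequence indices held invariant during evolution."""
    positions = {
        cfg.acceptor_pos,
        cfg.donor_pos,
        cfg.schiff_lysine_pos,
        cfg.helixG_diag_pos,
        cfg.inward_pump_pos,
        *cfg.pocket_positions,
    }
    return {p - cfg.numbering_offset - 1 for p in positions}


def _indel_exclusion_zone(anchored: set[int]) -> set[int]:
    """Anchored indices plus a small buffer; indels are kept out of this zone
    so the recorded residue correspondence stays unambiguous under pairwise
    realignment (a gap abutting an anchor can shift by a column at no cost)."""
    return {i + d for i in anchored for d in range(-INDEL_BUFFER, INDEL_BUFFER + 1)}


def _evolve_branch(
    sites: list[tuple[int | None, str]],
    branch: float,
    anchored: set[int],
    indel_rate: float,
    rng: np.random.Generator,
) -> list[tuple[int | None, str]]:
    """Evolve one branch: Poisson substitutions + geometric indels.

    ``sites`` is a list of (origin, residue) where origin is the 0-based
    index in the ancestor reference or None for inserted material.  Anchored
    origins are never substituted or deleted.
    """
    sites = list(sites)
    if branch <= 0:
        return sites
    # substitutions
    n_subs = rng.poisson(branch, size=len(sites))
    for i, (origin, res) in enumerate(sites):
        if origin in anchored:
            continue
        for _ in range(int(n_subs[i])):
            choices = AMINO_ACIDS.replace(res, "")
            res = choices[int(rng.integers(len(choices)))]
        sites[i] = (sites[i][0], res)
    # indels, kept clear of anchored sites (plus buffer) so the recorded
    # correspondence stays recoverable by realignment
    zone = _indel_exclusion_zone(anchored)
    n_events = rng.poisson(indel_rate * branch * len(sites))
    for _ in range(int(n_events)):
        length = int(rng.geometric(0.5))
        if rng.random() < 0.5 and len(sites) > length:  # deletion
            start = int(rng.integers(len(sites)))
            kept, removed = [], 0
            for j, site in enumerate(sites):
                if (
                    start <= j < start + length
                    and site[0] not in zone
                    and removed < length
                ):
                    removed += 1
                    continue
                kept.append(site)
            sites = kept
        else:  # insertion
            at = int(rng.integers(len(sites) + 1))
            near = [
                s[0]
                for s in sites[max(at - 1, 0) : at + 1]
                if s[0] is not None
            ]
            if any(o in zone for o in near):
                continue  # skip insertions that would abut an anchor
            insert = [
                (None, AMINO_ACIDS[int(rng.integers(20))]) for _ in range(length)
            ]
            sites = sites[:at] + insert + sites[at:]
    return sites


def evolve_family(
    spec: FamilySpec,
    cfg: FingerprintConfig | None = None,
    reference: ProteinRecord | None = None,
) -> tuple[list[ProteinRecord], FamilyTruth]:
    """Generate a protein family with planted class-diagnostic residues."""
    cfg = cfg or default_config()
    reference = reference or load_reference()
    rng = np.random.default_rng(spec.seed)
    anchored = _anchored_indices(cfg)
    off = cfg.numbering_offset

    root = TreeNode()
    labels: dict[str, RhodopsinClass] = {}
    subtrees = []
    for ci, (cls, n) in enumerate(sorted(spec.n_taxa.items(), key=lambda kv: kv[0].value)):
        sub = simulate_tree(
            n,
            birth_rate=spec.birth_rate,
            seed=int(rng.integers(2**31)),
            divergence=spec.divergence,
            prefix=f"{_ABBREV[cls]}_",
        )
        sub.length = spec.class_separation
        for tip in sub.tips():
            labels[tip.name] = cls
        subtrees.append((cls, sub))
        root.append(sub)

    # ancestral sequence per class: reference with diagnostics planted
    def class_root_sites(cls: RhodopsinClass) -> list[tuple[int | None, str]]:
        seq = list(reference.residues)
        acc, don, hg, lys = CLASS_PLANTS[cls]
        seq[cfg.acceptor_pos - off - 1] = acc
        seq[cfg.donor_pos - off - 1] = don
        seq[cfg.helixG_diag_pos - off - 1] = hg
        seq[cfg.schiff_lysine_pos - off - 1] = lys
        return [(i, r) for i, r in enumerate(seq)]

    records: list[ProteinRecord] = []
    correspondence: dict[str, dict[int, int]] = {}

    def recurse(node: TreeNode, sites: list[tuple[int | None, str]]) -> None:
        for child in node.children:
            evolved = _evolve_branch(
                sites, child.length or 0.0, anchored, spec.indel_rate, rng
            )
            if child.is_tip():
                residues = "".join(r for _, r in evolved)
                records.append(ProteinRecord(id=child.name, residues=residues))
                correspondence[child.name] = {
                    origin + off + 1: i + 1
                    for i, (origin, _) in enumerate(evolved)
                    if origin is not None
                }
            else:
                recurse(child, evolved)

    for cls, sub in subtrees:
        start = class_root_sites(cls)
        # evolve the class stem before descending into the subtree
        stem_sites = _evolve_branch(
            start, sub.length or 0.0, anchored, spec.indel_rate, rng
        )
        if sub.is_tip():
            records.append(
                ProteinRecord(id=sub.name, residues="".join(r for _, r in stem_sites))
            )
        else:
            recurse(sub, stem_sites)

    records.sort(key=lambda r: r.id)
    rows = []
    ref_len = len(reference)
    for rec in records:
        cmap = correspondence[rec.id]
        row = "".join(
            rec.residues[cmap[p + off + 1] - 1] if (p + off + 1) in cmap else "-"
            for p in range(ref_len)
        )
        rows.append((rec.id, row))
    truth = FamilyTruth(
        labels=labels,
        tree=root,
        correspondence=correspondence,
        alignment=AlignedSet(records=tuple(rows)),
    )
    return records, truth


# ---------------------------------------------------------------------------
# Genomes with planted foreign genes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSpec:
    """Recipe for one synthetic genome with planted foreign genes."""

    background_gc: float = 0.45
    n_genes: int = 200
    n_foreign: int = 1
    delta_gc: float = 0.15
    sharpening: float = 2.0  # exponent on within-family codon probabilities
    gene_codons: tuple[int, int] = (100, 400)  # uniform range, inclusive
    intergenic_mean: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.background_gc < 1.0:
            raise SimulationError("background GC must be in (0, 1)")
        if not 0.0 < self.background_gc + self.delta_gc < 1.0:
            raise SimulationError("foreign GC out of range")
        if self.n_foreign > self.n_genes:
            raise SimulationError("more foreign genes than genes")


@dataclass
class GenomeTruth:
    foreign: set[str]
    spec: GenomeSpec


def codon_distribution(gc: float, sharpening: float = 1.0) -> dict[str, float]:
    """Codon probabilities from iid base frequencies at the given G+C,
    stop codons excluded, optionally sharpened within synonymous families.

    Sharpening raises each within-family codon probability to the given
    exponent and renormalizes within the family, leaving family (amino
    acid) probabilities unchanged.
    """
    base_p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}
    weight = {
        c: base_p[c[0]] * base_p[c[1]] * base_p[c[2]]
        for c in GENETIC_CODE
        if c not in STOP_CODONS
    }
    total = sum(weight.values())
    probs = {c: w / total for c, w in weight.items()}
    if sharpening != 1.0:
        out: dict[str, float] = {}
        for family in SYNONYMOUS_FAMILIES.values():
            fam_p = sum(probs[c] for c in family)
            sharp = {c: probs[c] ** sharpening for c in family}
            z = sum(sharp.values())
            for c in family:
                out[c] = fam_p * sharp[c] / z
        probs = out
    return probs


def _draw_gene(n_codons: int, dist: dict[str, float], rng: np.random.Generator) -> str:
    codons = list(dist)
    p = np.array([dist[c] for c in codons])
    p = p / p.sum()
    picks = rng.choice(len(codons), size=n_codons, p=p)
    return "".join(codons[i] for i in picks)


def generate_genome(
    spec: GenomeSpec,
) -> tuple[GenomeRecord, list[GeneAnnotation], GenomeTruth]:
    """Generate a genome with ``n_genes`` non-overlapping genes, the last
    ``n_foreign`` of which (by label, positions shuffled) carry shifted G+C
    and sharpened codon bias."""
    rng = np.random.default_rng(spec.seed)
    native_dist = codon_distribution(spec.background_gc)
    foreign_dist = codon_distribution(
        spec.background_gc + spec.delta_gc, spec.sharpening
    )
    is_foreign = np.zeros(spec.n_genes, dtype=bool)
    if spec.n_foreign:
        is_foreign[
            rng.choice(spec.n_genes, size=spec.n_foreign, replace=False)
        ] = True

    gc = spec.background_gc
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    bases = np.array(list("ACGT"))

    def intergenic(length: int) -> str:
        return "".join(bases[rng.choice(4, size=length, p=base_p)])

    parts: list[str] = []
    annotations: list[GeneAnnotation] = []
    foreign_ids: set[str] = set()
    pos = 0
    genome_id = "synth_genome"
    for i in range(spec.n_genes):
        gap = int(rng.poisson(spec.intergenic_mean)) + 1
        parts.append(intergenic(gap))
        pos += gap
        n_codons = int(rng.integers(spec.gene_codons[0], spec.gene_codons[1] + 1))
        dist = foreign_dist if is_foreign[i] else native_dist
        cds = _draw_gene(n_codons, dist, rng)
        gid = f"gene_{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            from Bio.Seq import Seq

            parts.append(str(Seq(cds).reverse_complement()))
        else:
            parts.append(cds)
        annotations.append(
            GeneAnnotation(
                gene_id=gid,
                genome_id=genome_id,
                start=pos,
                end=pos + 3 * n_codons,
                strand=strand,
            )
        )
        pos += 3 * n_codons
        if is_foreign[i]:
            foreign_ids.add(gid)
    parts.append(intergenic(int(rng.poisson(spec.intergenic_mean)) + 1))
    genome = GenomeRecord(id=genome_id, sequence="".join(parts))
    return genome, annotations, GenomeTruth(foreign=foreign_ids, spec=spec)
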