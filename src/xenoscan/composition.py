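"""Compositional signatures of genes against their host genome.

Three signatures of foreign origin, in the spirit of classical alien-gene
screens: percent G+C, relative synonymous codon usage (RSCU) distance, and a
per-nucleotide log-odds under interpolated variable-order Markov models
(gene self-model versus genome background model).  Genes are flagged
atypical when robust z-scores of the RSCU distance or the Markov log-odds
against the genome's own gene population exceed a cutoff.

A recently transferred gene retains the donor's composition (shifted G+C,
different codon bias); amelioration erodes these signals over time, so a
native-looking gene does not rule out ancient transfer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqio import GenomeRecord

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Standard genetic code, codon -> amino acid (stop = '*')
from Bio.Data.CodonTable import unambiguous_dna_by_id as _tables

GENETIC_CODE: dict[str, str] = dict(_tables[1].forward_table)
for _stop in _tables[1].stop_codons:
    GENETIC_CODE[_stop] = "*"

# Synonymous families with >= 2 codons, stops excluded (59 informative codons)
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in GENETIC_CODE.items():
    if _aa == "*":
        continue
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)
INFORMATIVE_CODONS = tuple(
    c
    for aa, codons in sorted(SYNONYMOUS_FAMILIES.items())
    for c in sorted(codons)
    if len(codons) > 1
)


class CompositionError(ValueError):
    pass


def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T); 'N' excluded from numerator and denominator."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGTN"}
    denom = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    if denom == 0:
        raise CompositionError("sequence has no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


@dataclass(frozen=True)
class CodonUsageProfile:
    """RSCU values per codon; family means equal 1 where the family was seen."""

    rscu: dict[str, float]
    n_codons: int
    families_observed: frozenset[str]

    def vector(self, codons: tuple[str, ...] = INFORMATIVE_CODONS) -> np.ndarray:
        return np.array([self.rscu.get(c, 0.0) for c in codons])


def rscu(cds: str, warn_internal_stop: bool = True) -> CodonUsageProfile:
    """Relative synonymous codon usage of an in-frame coding sequence.

    RSCU(c) = count(c) * degeneracy / family total.  Codons containing N are
    skipped; stop codons are excluded; families never observed get RSCU 0
    for all members and are excluded from distances downstream.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise CompositionError(f"CDS length {len(cds)} not divisible by 3")
    counts: dict[str, int] = {}
    n_codons = 0
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, codon in enumerate(codons):
        if "N" in codon:
            continue
        if codon in STOP_CODONS:
            if warn_internal_stop and i < len(codons) - 1:
                warnings.warn(f"in-frame stop codon at codon {i}", stacklevel=2)
            continue
        counts[codon] = counts.get(codon, 0) + 1
        n_codons += 1
    values: dict[str, float] = {}
    observed: set[str] = set()
    for aa, family in SYNONYMOUS_FAMILIES.items():
        total = sum(counts.get(c, 0) for c in family)
        if total == 0:
            for c in family:
                values[c] = 0.0
            continue
        observed.add(aa)
        deg = len(family)
        for c in family:
            values[c] = counts.get(c, 0) * deg / total
    return CodonUsageProfile(
        rscu=values, n_codons=n_codons, families_observed=frozenset(observed)
    )


MIN_CODONS_FOR_DISTANCE = 100


def codon_usage_distance(
    gene: CodonUsageProfile, background: CodonUsageProfile
) -> tuple[float, bool]:
    """Mean |RSCU difference| over informative codons seen in both profiles.

    Returns ``(distance, low_power)``; ``low_power`` is set when either
    profile rests on fewer than 100 codons.
    """
    shared_aas = gene.families_observed & background.families_observed
    codons = [
        c
        for c in INFORMATIVE_CODONS
        if GENETIC_CODE[c] in shared_aas
    ]
    if not codons:
        raise CompositionError("profiles share no informative codon families")
    diffs = [abs(gene.rscu[c] - background.rscu[c]) for c in codons]
    low_power = gene.n_codons < MIN_CODONS_FOR_DISTANCE or (
        background.n_codons < MIN_CODONS_FOR_DISTANCE
    )
    return float(np.mean(diffs)), low_power


# ---------------------------------------------------------------------------
# Interpolated variable-order Markov model
# ---------------------------------------------------------------------------

IMM_DAMPING = 400.0  # w = n / (n + 400), classic interpolated-model damping


@dataclass
class InterpolatedMarkovModel:
    """Context-conditional nucleotide distributions for orders 0..k_max,
    blended per position with count-dependent interpolation weights."""

    k_max: int
    pseudocount: float
    # per order k: conditional probabilities, shape (4**k, 4)
    conditionals: list[np.ndarray] = field(repr=False)
    # per order k: context counts, shape (4**k,)
    context_counts: list[np.ndarray] = field(repr=False)

    def interpolated_probs(self, encoded: np.ndarray) -> np.ndarray:
        """P(x_i | context) for every position of an encoded (0-3) sequence,
        blending orders k_max..0 with weights w(c) = n(c) / (n(c) + damping)."""
        n = encoded.size
        probs = self.conditionals[0][0][encoded]  # order-0 baseline
        for k in range(1, self.k_max + 1):
            # context id of length k ending just before position i
            ctx = np.zeros(n, dtype=np.int64)
            valid = np.zeros(n, dtype=bool)
            if n > k:
                ids = np.zeros(n - k, dtype=np.int64)
                for off in range(k):
                    ids = ids * 4 + encoded[off : off + n - k]
                ctx[k:] = ids
                valid[k:] = True
            counts = self.context_counts[k][ctx]
            w = np.where(valid, counts / (counts + IMM_DAMPING), 0.0)
            pk = self.conditionals[k][ctx, encoded]
            probs = np.where(valid, w * pk + (1.0 - w) * probs, probs)
        return probs

    def log_likelihood(self, seq: str) -> float:
        """Total log-likelihood of a sequence (N splits it into chunks)."""
        total = 0.0
        for chunk in _encode_chunks(seq):
            total += float(np.log(self.interpolated_probs(chunk)).sum())
        return total


def _encode_chunks(seq: str) -> list[np.ndarray]:
    """Encode A/C/G/T as 0-3; runs containing N are split out."""
    out: list[np.ndarray] = []
    current: list[int] = []
    for ch in seq.upper():
        idx = _BASE_INDEX.get(ch)
        if idx is None:
            if current:
                out.append(np.array(current, dtype=np.int64))
                current = []
        else:
            current.append(idx)
    if current:
        out.append(np.array(current, dtype=np.int64))
    return out


def train_imm(
    sequence: str | GenomeRecord,
    k_max: int = 5,
    pseudocount: float = 1.0,
    both_strands: bool = True,
) -> InterpolatedMarkovModel:
    """Train an interpolated Markov model on a sequence, both strands pooled
    by default (a genome background has no preferred strand).

    Order-k conditionals get an additive pseudocount; interpolation weights
    are derived from raw context counts.
    """
    if k_max < 0:
        raise CompositionError("k_max must be >= 0")
    if isinstance(sequence, GenomeRecord):
        sequence = sequence.sequence
    from Bio.Seq import Seq

    strands = [sequence]
    if both_strands:
        strands.append(str(Seq(sequence).reverse_complement()))
    chunks = [c for s in strands for c in _encode_chunks(s)]
    if not chunks:
        raise CompositionError("no unambiguous sequence to train on")
    conditionals: list[np.ndarray] = []
    context_counts: list[np.ndarray] = []
    for k in range(k_max + 1):
        counts = np.zeros(4 ** (k + 1))
        for enc in chunks:
            n = enc.size
            if n <= k:
                continue
            ids = np.zeros(n - k, dtype=np.int64)
            for off in range(k):
                ids = ids * 4 + enc[off : off + n - k]
            counts += np.bincount(ids * 4 + enc[k:], minlength=4 ** (k + 1))
        counts = counts.reshape(4**k, 4)
        ctx_n = counts.sum(axis=1)
        cond = (counts + pseudocount) / (ctx_n + 4.0 * pseudocount)[:, None]
        conditionals.append(cond)
        context_counts.append(ctx_n)
    return InterpolatedMarkovModel(
        k_max=k_max,
        pseudocount=pseudocount,
        conditionals=conditionals,
        context_counts=context_counts,
    )


def ivom_logodds(
    gene: str,
    self_model: InterpolatedMarkovModel,
    genome_model: InterpolatedMarkovModel,
) -> float:
    """(log L(gene | self) - log L(gene | genome)) / length.

    Positive values mean the gene looks more like itself than like its host
    genome -- i.e. more foreign.
    """
    n = sum(c.size for c in _encode_chunks(gene))
    if n == 0:
        raise CompositionError("gene has no unambiguous bases")
    return (self_model.log_likelihood(gene) - genome_model.log_likelihood(gene)) / n


# ---------------------------------------------------------------------------
# Per-gene reports and outlier flagging
# ---------------------------------------------------------------------------


@dataclass
class GeneCompositionReport:
    """One Table-S1-style row: a gene's signatures versus its host genome."""

    gene_id: str
    gene_length: int
    gene_gc: float
    genome_gc: float
    gc_delta: float
    rscu_distance: float
    ivom_logodds: float
    low_power: bool = False
    z_gc: float | None = None
    z_rscu: float | None = None
    z_ivom: float | None = None
    atypical: bool | None = None


MIN_GENES_FOR_FLAGS = 20
MAD_SCALE = 1.4826  # MAD -> sigma under normality


def gene_reports(
    genome: GenomeRecord,
    genes: dict[str, str],
    k_max: int = 5,
    pseudocount: float = 1.0,
) -> list[GeneCompositionReport]:
    """Compute the three signatures for every gene of a genome.

    ``genes`` maps gene_id to its coding-strand CDS.  The RSCU background
    is the pooled codon usage of all genes; the Markov background is trained
    on the whole genome.
    """
    if not genes:
        raise CompositionError("no genes supplied")
    genome_gc = gc_content(genome.sequence)
    genome_model = train_imm(genome, k_max=k_max, pseudocount=pseudocount)
    background = rscu("".join(genes.values()), warn_internal_stop=False)
    reports = []
    for gid, cds in genes.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            profile = rscu(cds)
        dist, low_power = codon_usage_distance(profile, background)
        self_model = train_imm(cds, k_max=k_max, pseudocount=pseudocount)
        reports.append(
            GeneCompositionReport(
                gene_id=gid,
                gene_length=len(cds),
                gene_gc=gc_content(cds),
                genome_gc=genome_gc,
                gc_delta=gc_content(cds) - genome_gc,
                rscu_distance=dist,
                ivom_logodds=ivom_logodds(cds, self_model, genome_model),
                low_power=low_power,
            )
        )
    return reports


def _robust_z(values: np.ndarray) -> tuple[np.ndarray, bool]:
    center = float(np.median(values))
    mad = float(np.median(np.abs(values - center)))
    scale = mad * MAD_SCALE
    if scale == 0.0:
        return np.zeros_like(values), True
    return (values - center) / scale, False


def _log_clip(values: np.ndarray) -> np.ndarray:
    """log of a non-negative metric; zeros/negatives clipped to the smallest
    positive value (monotone, affects only the most native-looking genes)."""
    pos = values[values > 0]
    if pos.size == 0:
        return values.copy()
    return np.log(np.maximum(values, pos.min()))


def _length_adjusted_z(
    metric: np.ndarray, lengths: np.ndarray, log_transform: bool
) -> tuple[np.ndarray, bool]:
    """Robust z-scores of a metric after removing its gene-length trend.

    Both signatures shrink with gene length under the null (sampling noise
    of RSCU ~ 1/sqrt(codons); self-model overfit of the Markov log-odds
    ~ 1/length), so short genes would otherwise dominate the flag set.  The
    trend is removed by a Theil-Sen fit of the (log-transformed) metric on
    log length -- robust, because the population contains true outliers by
    hypothesis -- and residuals are standardized by median and MAD * 1.4826.
    """
    from scipy.stats import theilslopes

    y = _log_clip(metric) if log_transform else metric.astype(float)
    x = np.log(lengths.astype(float))
    if np.ptp(x) > 0 and y.size >= 3:
        slope, intercept, *_ = theilslopes(y, x)
        resid = y - (intercept + slope * x)
    else:
        resid = y - np.median(y)
    return _robust_z(resid)


def flag_atypical(
    reports: list[GeneCompositionReport], z_cutoff: float = 2.0
) -> list[GeneCompositionReport]:
    """Annotate reports with robust z-scores and the atypical flag.

    z-scores are computed against the genome's own gene population: each
    metric is log-transformed, its gene-length trend removed by a robust
    Theil-Sen fit, and the residuals standardized by median and MAD * 1.4826
    (see :func:`_length_adjusted_z`).  A gene is atypical when the z-score
    of its RSCU distance or Markov log-odds reaches the cutoff.  With fewer
    than 20 genes, or a degenerate (MAD = 0) background, flags are
    suppressed with a warning.
    """
    if not reports:
        raise CompositionError("no reports to flag")
    suppress = False
    if len(reports) < MIN_GENES_FOR_FLAGS:
        warnings.warn(
            f"only {len(reports)} genes; background unstable, flags suppressed",
            stacklevel=2,
        )
        suppress = True
    lengths = np.array([r.gene_length for r in reports])
    z_gc, _ = _robust_z(np.array([r.gc_delta for r in reports]))
    z_rscu, deg_rscu = _length_adjusted_z(
        np.array([r.rscu_distance for r in reports]), lengths, log_transform=True
    )
    z_ivom, deg_ivom = _length_adjusted_z(
        np.array([r.ivom_logodds for r in reports]), lengths, log_transform=True
    )
    if not suppress and (deg_rscu or deg_ivom):
        warnings.warn("degenerate (MAD=0) background; flags suppressed", stacklevel=2)
        suppress = True
    for i, rep in enumerate(reports):
        rep.z_gc = float(z_gc[i])
        rep.z_rscu = float(z_rscu[i])
        rep.z_ivom = float(z_ivom[i])
        rep.atypical = (
            False
            if suppress
            else bool(rep.z_rscu >= z_cutoff or rep.z_ivom >= z_cutoff)
        )
    return reports


def reports_to_frame(reports: list[GeneCompositionReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in reports],
            "gene_length": [r.gene_length for r in reports],
            "gene_gc": [round(r.gene_gc, 4) for r in reports],
            "genome_gc": [round(r.genome_gc, 4) for r in reports],
            "gc_delta": [round(r.gc_delta, 4) for r in reports],
            "rscu_distance": [round(r.rscu_distance, 4) for r in reports],
            "ivom_logodds": [round(r.ivom_logodds, 5) for r in reports],
            "z_gc": [None if r.z_gc is None else round(r.z_gc, 3) for r in reports],
            "z_rscu": [None if r.z_rscu is None else round(r.z_rscu, 3) for r in reports],
            "z_ivom": [None if r.z_ivom is None else round(r.z_ivom, 3) for r in reports],
            "low_power": [r.low_power for r in reports],
            "atypical": [r.atypical for r in reports],
        }
    )
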