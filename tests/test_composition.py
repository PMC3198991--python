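import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xenoscan.composition import (
    CompositionError,
    SYNONYMOUS_FAMILIES,
    codon_usage_distance,
    flag_atypical,
    gc_content,
    gene_reports,
    ivom_logodds,
    rscu,
    train_imm,
)
from xenoscan.seqio import GenomeRecord, extract_gene
from xenoscan.simulate import GenomeSpec, codon_distribution, generate_genome


class TestGC:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGCC", 1.0), ("ATAT", 0.0), ("GCAT", 0.5), ("GCNNAT", 0.5)],
    )
    def test_closed_form(self, seq, expected):
        assert gc_content(seq) == expected

    def test_all_n_rejected(self):
        with pytest.raises(CompositionError):
            gc_content("NNNN")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=200))
    def test_bounds_and_revcomp_invariance(self, seq):
        from Bio.Seq import Seq

        if set(seq) <= {"N"}:
            return
        g = gc_content(seq)
        assert 0.0 <= g <= 1.0
        assert g == pytest.approx(gc_content(str(Seq(seq).reverse_complement())))


class TestRSCU:
    def test_single_codon_six_fold_family(self):
        prof = rscu("CTGCTG")
        assert prof.rscu["CTG"] == pytest.approx(6.0)  # Leu: 6-fold degenerate
        for c in ("CTA", "CTC", "CTT", "TTA", "TTG"):
            assert prof.rscu[c] == 0.0

    def test_uniform_usage_gives_all_ones(self):
        cds = "".join(
            "".join(family) for family in SYNONYMOUS_FAMILIES.values()
        )
        prof = rscu(cds)
        informative = [c for f in SYNONYMOUS_FAMILIES.values() if len(f) > 1 for c in f]
        assert all(prof.rscu[c] == pytest.approx(1.0) for c in informative)

    def test_family_means_equal_one(self, rng):
        bases = np.array(list("ACGT"))
        cds = "".join(bases[rng.integers(0, 4, 3000)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = rscu(cds)
        for family in SYNONYMOUS_FAMILIES.values():
            vals = [prof.rscu[c] for c in family]
            if any(v > 0 for v in vals):
                assert np.mean(vals) == pytest.approx(1.0, abs=1e-9)

    def test_simulated_distribution_recovered(self, rng):
        dist = codon_distribution(0.5)
        codons = list(dist)
        p = np.array([dist[c] for c in codons])
        cds = "".join(
            codons[i] for i in rng.choice(len(codons), 10_000, p=p / p.sum())
        )
        prof = rscu(cds)
        # expected RSCU from the generating distribution, binomial tolerance
        for family in SYNONYMOUS_FAMILIES.values():
            if len(family) == 1:
                continue
            fam_p = sum(dist[c] for c in family)
            for c in family:
                expected = dist[c] * len(family) / fam_p
                n_fam = 10_000 * fam_p
                se = len(family) * np.sqrt(
                    (dist[c] / fam_p) * (1 - dist[c] / fam_p) / n_fam
                )
                assert prof.rscu[c] == pytest.approx(expected, abs=4 * se + 1e-6)

    def test_frame_violation_rejected(self):
        with pytest.raises(CompositionError):
            rscu("ATGC")

    def test_internal_stop_warns(self):
        with pytest.warns(UserWarning, match="stop"):
            rscu("ATGTAAATG")


class TestCodonDistance:
    def test_self_distance_zero(self):
        prof = rscu("ATGGCTGCCGCA" * 30, warn_internal_stop=False)
        d, low = codon_usage_distance(prof, prof)
        assert d == 0.0 and not low

    def test_two_fold_opposition_closed_form(self):
        # Lys (AAA/AAG) and Glu (GAA/GAG): fully opposed 2-fold families
        a = rscu("AAAGAA" * 60)
        b = rscu("AAGGAG" * 60)
        d, _ = codon_usage_distance(a, b)
        assert d == pytest.approx(2.0)  # |2-0| at every shared informative codon

    def test_low_power_flagged(self):
        small = rscu("AAAGAA" * 3)
        big = rscu("AAAGAA" * 60)
        _, low = codon_usage_distance(small, big)
        assert low


class TestIMM:
    def test_homopolymer_limit(self):
        model = train_imm("A" * 500, k_max=2, pseudocount=1e-9, both_strands=False)
        enc = np.zeros(10, dtype=np.int64)
        probs = model.interpolated_probs(enc)
        assert probs[-1] == pytest.approx(1.0, abs=1e-6)

    def test_order0_uniform_on_acgt_repeat(self):
        model = train_imm("ACGT" * 200, k_max=0)
        assert np.allclose(model.conditionals[0][0], 0.25, atol=1e-3)

    def test_conditionals_are_distributions(self):
        model = train_imm("ACGTTGCAAC" * 100, k_max=3)
        for cond in model.conditionals:
            assert np.allclose(cond.sum(axis=1), 1.0, atol=1e-9)

    def test_order2_chain_recovered(self, rng):
        # simulate a known order-2 chain; forward-strand training must
        # recover the generating conditionals within 3 SE at high coverage
        probs = rng.dirichlet(np.ones(4) * 5, size=16)  # 16 contexts
        seq = [0, 1]
        for _ in range(60_000):
            ctx = seq[-2] * 4 + seq[-1]
            seq.append(int(rng.choice(4, p=probs[ctx])))
        s = "".join("ACGT"[i] for i in seq)
        model = train_imm(s, k_max=2, both_strands=False)
        for ctx in range(16):
            n = model.context_counts[2][ctx]
            if n < 1000:
                continue
            est = model.conditionals[2][ctx]
            se = np.sqrt(probs[ctx] * (1 - probs[ctx]) / n)
            assert np.all(np.abs(est - probs[ctx]) <= 3 * se + 0.01)

    def test_self_consistency_near_zero_logodds(self, rng):
        bases = np.array(list("ACGT"))
        genome_seq = "".join(bases[rng.integers(0, 4, 60_000)])
        gene = genome_seq[1000:2200]
        genome_model = train_imm(genome_seq)
        self_model = train_imm(gene)
        lo = ivom_logodds(gene, self_model, genome_model)
        assert abs(lo) < 0.2

    def test_foreign_chain_positive_logodds(self, rng):
        bases = np.array(list("ACGT"))

        def iid(gc, n):
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            return "".join(bases[rng.choice(4, size=n, p=p)])

        genome_model = train_imm(iid(0.60, 60_000))
        wins = 0
        for _ in range(10):
            gene = iid(0.30, 1500)
            lo = ivom_logodds(gene, train_imm(gene), genome_model)
            wins += lo > 0
        assert wins == 10  # sign test: every AT-rich gene looks foreign

    def test_deterministic(self):
        gene = "ATGGCTAAAGGGCCC" * 40
        genome = GenomeRecord(id="g", sequence="ACGT" * 5000)
        m1, m2 = train_imm(genome), train_imm(genome)
        s = train_imm(gene)
        assert ivom_logodds(gene, s, m1) == ivom_logodds(gene, s, m2)

    def test_negative_order_rejected(self):
        with pytest.raises(CompositionError):
            train_imm("ACGT", k_max=-1)


class TestFlagging:
    @pytest.fixture(scope="class")
    def screened(self):
        spec = GenomeSpec(seed=42, n_genes=120, n_foreign=2)
        genome, genes, truth = generate_genome(spec)
        cds = {g.gene_id: extract_gene(genome, g) for g in genes}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports = flag_atypical(gene_reports(genome, cds))
        return reports, truth

    def test_planted_foreign_genes_flagged(self, screened):
        reports, truth = screened
        flagged = {r.gene_id for r in reports if r.atypical}
        assert truth.foreign <= flagged

    def test_flags_deterministic_function_of_inputs(self, screened):
        reports, truth = screened
        for r in reports:
            assert r.atypical == bool(r.z_rscu >= 2.0 or r.z_ivom >= 2.0)

    def test_few_genes_suppresses_flags(self):
        spec = GenomeSpec(seed=5, n_genes=10, n_foreign=1)
        genome, genes, _ = generate_genome(spec)
        cds = {g.gene_id: extract_gene(genome, g) for g in genes}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports = gene_reports(genome, cds)
        with pytest.warns(UserWarning, match="suppressed"):
            reports = flag_atypical(reports)
        assert not any(r.atypical for r in reports)

    def test_degenerate_background_suppresses_flags(self):
        genome = GenomeRecord(id="g", sequence="ACGT" * 30_000)
        gene = "ATGGCTAAAGGG" * 30
        cds = {f"g{i}": gene for i in range(25)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports = gene_reports(genome, cds, k_max=2)
        with pytest.warns(UserWarning, match="MAD=0|suppressed"):
            reports = flag_atypical(reports)
        assert not any(r.atypical for r in reports)
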