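import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from amatox import msdin_miner as mm
from amatox import synthdata as sd
from amatox.msdin_miner import (GeneModel, NoCoreFound, NoModel,
                                build_leader_profile, extract_core, scan_orfs,
                                spliced_align, toxin_gene_distance, translate)
from amatox.seqio import GenomicInterval, SeqRecord


class TestExtractCore:
    def test_printed_lepiota_precursor(self):
        prec = extract_core("MDANATRLPIWGIGCNPWTPESVNDTLTKDLS")
        assert prec.leader == "MDANATRLP"
        assert prec.core == "IWGIGCNP"
        assert prec.core_span == (10, 17)
        assert prec.follower == "WTPESVNDTLTKDLS"

    def test_no_downstream_p(self):
        with pytest.raises(NoCoreFound):
            extract_core("MXXPAAAAAAAA")

    def test_decomposition_concatenates_back(self):
        for seed in range(10):
            _, truth = sd.plant_msdin_contig(
                300, 0.5, "GFVLAAFP", "MSDIN", 0, seed=seed)
            prec = extract_core(truth["precursor"])
            assert prec.leader + prec.core + prec.follower == truth["precursor"]
            assert prec.core == truth["core"]

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_generator_round_trip(self, seed):
        _, truth = sd.plant_msdin_contig(
            300, 0.5, "IWGIGCNP", "MFDTN", 0, seed=seed)
        assert extract_core(truth["precursor"]).core == "IWGIGCNP"


class TestLeaderProfile:
    def test_identical_leaders_concentrate_weight(self):
        prof = build_leader_profile(["MSDINATRLP"] * 3, leader_len=9)
        for pos, aa in enumerate("MSDINATRL"):
            assert prof.pwm[pos].argmax() == mm.AA_INDEX[aa]

    def test_training_set_scores_above_threshold(self, mdan_profile):
        for t in mdan_profile.training:
            assert mdan_profile.score(t) >= mdan_profile.threshold

    def test_true_leader_beats_shuffled(self, mdan_profile):
        rng = np.random.default_rng(0)
        true_score = mdan_profile.score("MDANATRLP")
        shuffled = [
            "".join(rng.permutation(list("MDANATRLP")))
            for _ in range(200)
        ]
        beaten = sum(true_score > mdan_profile.score(s) for s in shuffled
                     if s != "MDANATRLP")
        assert beaten >= 0.95 * len(shuffled)

    def test_too_few_sequences(self):
        with pytest.raises(ValueError):
            build_leader_profile(["MSDINATRLP"], 9)


class TestScanOrfs:
    def test_planted_gene_exact_coordinates(self, mdan_profile):
        contig, truth = sd.plant_msdin_contig(
            3000, 0.49, "IWGIGCNP", "MDAN", 0, seed=42)
        hits = scan_orfs(contig, mdan_profile)
        assert len(hits) == 1
        model = hits[0].gene_model
        assert model.interval.strand == truth["strand"]
        assert [(e.start, e.end) for e in model.exons] == truth["exons"]
        assert hits[0].precursor.core == "IWGIGCNP"

    def test_planted_intron_gene_recovered(self, mdan_profile):
        contig, truth = sd.plant_msdin_contig(
            3000, 0.49, "IWGIGCNP", "MDAN", 1, seed=43)
        hits = scan_orfs(contig, mdan_profile)
        exon_sets = [
            (h.gene_model.interval.strand,
             tuple((e.start, e.end) for e in h.gene_model.exons))
            for h in hits]
        assert (truth["strand"], tuple(truth["exons"])) in exon_sets

    def test_gene_model_invariant(self, mdan_profile):
        contig, _ = sd.plant_msdin_contig(
            3000, 0.49, "IWGIGCNP", "MDAN", 1, seed=44)
        for h in scan_orfs(contig, mdan_profile):
            h.gene_model.check_invariant()

    def test_random_contig_no_hits(self, mdan_profile):
        rng = np.random.default_rng(9)
        seq = "".join(np.array(list("ACGT"))[
            rng.choice(4, 2000, p=[0.255, 0.245, 0.245, 0.255])])
        assert scan_orfs(SeqRecord("rand", seq), mdan_profile) == []


class TestSplicedAlign:
    def test_identity_single_exon(self):
        gene, cds, _ = sd.plant_multiexon_gene(80, 0, 0, seed=1)
        model = spliced_align(gene, cds)
        assert [(e.start, e.end) for e in model.exons] == [(0, len(cds))]

    def test_planted_introns_exact(self):
        gene, cds, truth = sd.plant_multiexon_gene(
            120, 2, 120, seed=5)
        model = spliced_align(gene, cds)
        assert [(e.start, e.end) for e in model.exons] == truth["exons"]
        assert model.protein == truth["protein"]

    def test_score_floor_raises(self):
        rng = np.random.default_rng(2)
        junk = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        _, cds, _ = sd.plant_multiexon_gene(60, 0, 0, seed=3)
        with pytest.raises(NoModel):
            spliced_align(junk, cds)

    @pytest.mark.parametrize("seed", range(6))
    def test_brute_force_intron_placement_oracle(self, seed):
        """Optimal score equals exhaustive enumeration of <=2 intron
        placements followed by plain affine alignment (inputs <=300 bp)."""
        rng = np.random.default_rng(seed)
        n_introns = seed % 3
        gene, cds, _ = sd.plant_multiexon_gene(
            40, n_introns, 44 * max(n_introns, 1) * (n_introns > 0),
            seed=100 + seed, min_intron=42)
        got = _best_score(gene, cds)
        expect = _brute_best_score(gene, cds, max_introns=2)
        assert got == pytest.approx(expect, abs=1e-9)


MATCH, MISMATCH, GAP_OPEN, GAP_EXT, INTRON_OPEN = 2.0, -3.0, -8.0, -2.0, -10.0


def _best_score(gene, cds):
    model = spliced_align(gene, cds)
    # recompute the alignment score of the returned model (no indels case)
    score = 0.0
    spliced = "".join(gene[e.start:e.end] for e in model.exons)
    assert len(spliced) == len(cds)
    for a, b in zip(spliced, cds):
        score += MATCH if a == b else MISMATCH
    score += INTRON_OPEN * (len(model.exons) - 1)
    return score


def _nw_fit(g, c):
    """Plain affine-gap fit alignment score (free genomic flanks)."""
    n, m = len(g), len(c)
    NEG = -1e18
    M = np.full(m + 1, NEG)
    X = np.full(m + 1, NEG)
    Y = np.full(m + 1, NEG)
    M[0] = 0.0
    for j in range(1, m + 1):
        Y[j] = max(M[0] + GAP_OPEN + GAP_EXT * (j - 1), NEG)
    best = max(M[m], Y[m])
    for i in range(1, n + 1):
        newM = np.full(m + 1, NEG)
        newX = np.full(m + 1, NEG)
        newY = np.full(m + 1, NEG)
        newM[0] = 0.0
        for j in range(1, m + 1):
            s = MATCH if g[i - 1] == c[j - 1] else MISMATCH
            newM[j] = s + max(M[j - 1], X[j - 1], Y[j - 1])
            newX[j] = max(M[j] + GAP_OPEN, X[j] + GAP_EXT)
            newY[j] = max(newM[j - 1] + GAP_OPEN, newY[j - 1] + GAP_EXT)
        M, X, Y = newM, newX, newY
        best = max(best, M[m], Y[m])
    return best


def _brute_best_score(gene, cds, max_introns=2, min_len=40):
    gts = [i for i in range(len(gene) - 1) if gene[i:i + 2] == "GT"]
    ags = [i + 2 for i in range(len(gene) - 1) if gene[i:i + 2] == "AG"]
    best = _nw_fit(gene, cds)
    singles = [(p, q) for p in gts for q in ags if q - p >= min_len]
    for p, q in singles:
        best = max(best, INTRON_OPEN + _nw_fit(gene[:p] + gene[q:], cds))
    if max_introns >= 2:
        for (p1, q1), (p2, q2) in itertools.combinations(singles, 2):
            if q1 <= p2:
                cut = gene[:p1] + gene[q1:p2] + gene[q2:]
                best = max(best, 2 * INTRON_OPEN + _nw_fit(cut, cds))
    return best


class TestToxinGeneDistance:
    def _model(self, contig, start, end):
        return GeneModel(
            interval=GenomicInterval(contig, start, end, "+"),
            exons=[GenomicInterval(contig, start, end, "+")],
            protein="M" * ((end - start) // 3 - 1),
        )

    def test_close_pair_clustered(self):
        r = toxin_gene_distance(
            [self._model("c1", 0, 300), self._model("c1", 1300, 1600)])
        assert r["verdict"] == "clustered"
        assert r["pairs"][0]["gap_bp"] == 1000

    def test_cross_contig_unlinked(self):
        r = toxin_gene_distance(
            [self._model("contig4", 0, 300), self._model("contig27", 0, 300)])
        assert r["verdict"] == "not clustered"
        assert r["pairs"][0]["note"] == "unlinked at assembly level"

    def test_exact_threshold_not_clustered(self):
        r = toxin_gene_distance(
            [self._model("c", 0, 100), self._model("c", 50_100, 50_200)],
            cluster_threshold=50_000)
        assert r["pairs"][0]["gap_bp"] == 50_000
        assert r["verdict"] == "not clustered"

    def test_single_gene(self):
        assert toxin_gene_distance([self._model("c", 0, 99)])[
            "verdict"] == "single gene"


def test_translate_standard_code():
    assert translate("ATGGGATAA") == "MG*"
    assert translate("atggga") == "MG"
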