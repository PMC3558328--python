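import math
import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from microdelim.distances import (
    build_distance_matrix,
    collapse_haplotypes,
    k2p_distance,
    write_phylip,
)
from microdelim.errors import InputError, UndefinedDistanceError
from microdelim.io import Alignment

seq_pairs = st.integers(0, 2**31 - 1).map(
    lambda seed: tuple(
        "".join(np.random.default_rng(seed + k).choice(list("ACGTN-"), 50))
        for k in range(2)
    )
)


class TestK2pPair:
    def test_identical_sequences(self):
        d, P, Q, n = k2p_distance("ACGT" * 25, "ACGT" * 25)
        assert (d, P, Q, n) == (0.0, 0.0, 0.0, 100)

    def test_ten_transitions_in_hundred(self):
        # P = 0.1, Q = 0 -> d = -1/2 ln(0.8)
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        d, P, Q, n = k2p_distance(a, b)
        assert P == pytest.approx(0.1) and Q == 0.0
        assert d == pytest.approx(0.111572, abs=1e-6)

    def test_equal_transition_transversion_quarters(self):
        # P = Q = 0.25 -> d = -1/2 ln(0.25 * sqrt(0.5)) = 0.866434
        a = "A" * 100
        b = "G" * 25 + "C" * 25 + "A" * 50
        d, P, Q, _ = k2p_distance(a, b)
        assert (P, Q) == (0.25, 0.25)
        assert d == pytest.approx(0.866434, abs=1e-6)

    def test_pairwise_deletion_excludes_gaps_missing_ambiguity(self):
        d, P, Q, n = k2p_distance("ACGT-NRA", "ACGTAAAG")
        assert n == 5  # '-', 'N' and IUPAC 'R' sites dropped
        assert P == pytest.approx(1 / 5)

    def test_no_overlap_is_an_error(self):
        with pytest.raises(UndefinedDistanceError):
            k2p_distance("NNNN", "ACGT")

    def test_saturation_gives_inf(self):
        d, P, Q, _ = k2p_distance("A" * 10, "G" * 10)
        assert P == 1.0 and math.isinf(d)

    @given(seq_pairs)
    def test_swap_symmetry(self, pair):
        a, b = pair
        try:
            ra = k2p_distance(a, b)
        except UndefinedDistanceError:
            return
        assert ra == k2p_distance(b, a)

    @given(seq_pairs)
    def test_correction_dominates_p_distance(self, pair):
        a, b = pair
        try:
            d, P, Q, n = k2p_distance(a, b)
        except UndefinedDistanceError:
            return
        assert d >= P + Q - 1e-12
        if P + Q > 0:
            assert d > P + Q or math.isinf(d)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_independent_count_and_formula(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), 50))
        b = "".join(rng.choice(list("ACGT"), 50))
        ts = {frozenset("AG"), frozenset("CT")}
        P = sum(x != y and frozenset((x, y)) in ts for x, y in zip(a, b)) / 50
        Q = sum(x != y and frozenset((x, y)) not in ts for x, y in zip(a, b)) / 50
        d, Pg, Qg, n = k2p_distance(a, b)
        assert (Pg, Qg, n) == (pytest.approx(P), pytest.approx(Q), 50)
        w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
        expected = math.inf if w1 <= 0 or w2 <= 0 else -0.5 * math.log(w1 * math.sqrt(w2))
        assert d == pytest.approx(expected)


class TestDistanceMatrix:
    def test_identical_sequences_give_zero_matrix(self):
        aln = Alignment(ids=("a", "b", "c"), seqs=("ACGT",) * 3)
        dm = build_distance_matrix(aln)
        assert np.all(dm.matrix == 0)

    def test_matrix_matches_pairwise_calls(self, toy_alignment):
        dm = build_distance_matrix(toy_alignment)
        for i, a in enumerate(toy_alignment.seqs):
            for j, b in enumerate(toy_alignment.seqs):
                if i < j:
                    assert dm.matrix[i, j] == pytest.approx(k2p_distance(a, b)[0])
        assert np.array_equal(dm.matrix, dm.matrix.T)

    def test_hamming_counts_steps(self):
        aln = Alignment(ids=("a", "b"), seqs=("AAAA", "AAAT"))
        dm = build_distance_matrix(aln, model="HAMMING")
        assert dm.matrix[0, 1] == 1.0

    def test_unknown_model_rejected(self, toy_alignment):
        with pytest.raises(InputError):
            build_distance_matrix(toy_alignment, model="GTR")

    def test_agrees_with_ape_dist_dna(self, tmp_path):
        """Independent oracle: ape's dist.dna K80 with pairwise deletion."""
        from microdelim.io import write_fasta_alignment
        from microdelim.simulate import SimSpec, sim_sequences_k80, sim_tree

        tree = sim_tree(SimSpec(process="yule", n_tips=6, r1=1.0, seed=3))
        aln = sim_sequences_k80(tree, 300, kappa=3.0, scale=0.05, seed=4)
        seqs = list(aln.seqs)
        seqs[0] = "N" * 8 + seqs[0][8:]
        aln = Alignment(ids=aln.ids, seqs=tuple(seqs))
        fasta = tmp_path / "k.fasta"
        write_fasta_alignment(aln, fasta)
        out = subprocess.run(
            [
                "Rscript", "-e",
                "suppressMessages(library(ape));"
                f"a <- read.dna('{fasta}', format='fasta');"
                "d <- dist.dna(a, model='K80', pairwise.deletion=TRUE);"
                "cat(sprintf('%.10f', as.vector(d)), sep='\\n')",
            ],
            capture_output=True, text=True, check=True,
        )
        theirs = list(map(float, out.stdout.split()))
        dm = build_distance_matrix(aln)
        mine = [dm.matrix[i, j] for i in range(6) for j in range(i + 1, 6)]
        assert mine == pytest.approx(theirs, abs=1e-8)


class TestHaplotypes:
    def test_copies_collapse(self):
        aln = Alignment(ids=tuple("abcde"), seqs=("ACGT",) * 5)
        hap, members = collapse_haplotypes(aln)
        assert hap.n_sequences == 1
        assert members == {"a": ["a", "b", "c", "d", "e"]}

    def test_distinct_stay_distinct(self, toy_alignment):
        hap, members = collapse_haplotypes(toy_alignment)
        assert hap.n_sequences == 3
        assert sum(len(m) for m in members.values()) == 4

    def test_missing_data_does_not_merge(self):
        aln = Alignment(ids=("a", "b"), seqs=("ACGT", "ACGN"))
        hap, _ = collapse_haplotypes(aln)
        assert hap.n_sequences == 2


def test_phylip_export(tmp_path, toy_alignment):
    dm = build_distance_matrix(toy_alignment)
    path = tmp_path / "m.phy"
    write_phylip(dm, path)
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "4" and len(lines) == 5
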