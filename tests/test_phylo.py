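"""Binary encoding, Dice/TN93 distances, UPGMA and bootstrap support."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from fescuecp import (
    AlignedSequenceSet,
    bootstrap_support,
    call_variants,
    dice_distance,
    encode_binary,
    tamura_nei_distance,
    to_newick,
    upgma,
)
from fescuecp.errors import SaturationError
from fescuecp.phylo import Clade

from conftest import MED_MAIREI_TAXA


class TestEncodeBinary:
    def test_monomorphic_input_gives_zero_columns(self):
        aln = AlignedSequenceSet(
            taxa=["a", "b"],
            group_of={"a": "A", "b": "B"},
            sequences={"a": "ACGT", "b": "ACGT"},
        )
        assert encode_binary([], aln, "a").shape == (2, 0)

    def test_panel_profile_all_biallelic_gives_167_columns(
        self, panel_alignment, panel_loci
    ):
        aln, _ = panel_alignment
        matrix = encode_binary(panel_loci, aln, "KY31")
        assert matrix.shape == (12, 167)

    def test_triallelic_snp_gives_two_columns(self):
        aln = AlignedSequenceSet(
            taxa=["a", "b", "c"],
            group_of={t: t for t in "abc"},
            sequences={"a": "AA", "b": "CA", "c": "GA"},
        )
        loci = call_variants(aln)
        assert encode_binary(loci, aln, "a").shape == (3, 2)

    def test_column_sums_equal_planted_carrier_counts(
        self, panel_alignment, panel_loci, panel_profile
    ):
        aln, truth = panel_alignment
        matrix = encode_binary(panel_loci, aln, "KY31")
        taxa_per_group = {}
        for t, g in panel_profile.group_of.items():
            taxa_per_group.setdefault(g, []).append(t)
        by_start = {rec.start: rec for rec in truth.itertuples()}
        for col in matrix.columns:
            start = int(col.split("_")[0])
            rec = by_start[start]
            carriers = sum(
                len(taxa_per_group[g]) for g in rec.carriers.split(";")
            )
            assert matrix[col].sum() == carriers


class TestDice:
    def test_identical_rows_have_zero_distance(self):
        m = pd.DataFrame([[1, 0, 1], [1, 0, 1]], index=["a", "b"])
        assert dice_distance(m).loc["a", "b"] == 0

    def test_disjoint_presence_sets_have_distance_one(self):
        m = pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1]], index=["a", "b"])
        assert dice_distance(m).loc["a", "b"] == 1

    def test_hand_computed_coefficient(self):
        # a=2 shared, b=1, c=1 unique -> similarity 2*2/(2*2+1+1) = 2/3
        m = pd.DataFrame([[1, 1, 1, 0], [1, 1, 0, 1]], index=["a", "b"])
        assert dice_distance(m).loc["a", "b"] == pytest.approx(1 / 3)

    def test_empty_rows_are_defined_identical(self):
        m = pd.DataFrame([[0, 0], [0, 0], [1, 0]], index=["a", "b", "c"])
        d = dice_distance(m)
        assert d.loc["a", "b"] == 0
        assert d.loc["a", "c"] == 1

    def test_bounds_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = pd.DataFrame(
                rng.integers(0, 2, size=(6, 30)), index=[f"t{i}" for i in range(6)]
            )
            d = dice_distance(m).to_numpy()
            assert (d >= 0).all() and (d <= 1).all()
            assert np.allclose(d, d.T)
            assert np.diag(d).sum() == 0


class TestTamuraNei:
    def test_identical_sequences_give_zero(self):
        aln = AlignedSequenceSet(
            taxa=["a", "b"],
            group_of={"a": "A", "b": "B"},
            sequences={"a": "ACGTACGT" * 5, "b": "ACGTACGT" * 5},
        )
        assert tamura_nei_distance(aln).loc["a", "b"] == 0

    def test_gap_only_differences_give_zero(self):
        aln = AlignedSequenceSet(
            taxa=["a", "b"],
            group_of={"a": "A", "b": "B"},
            sequences={"a": "ACGT--GTAC" * 4, "b": "ACGTCAGTAC" * 4},
        )
        assert tamura_nei_distance(aln).loc["a", "b"] == 0

    def test_saturation_names_the_pair(self):
        aln = AlignedSequenceSet(
            taxa=["a", "b"],
            group_of={"a": "A", "b": "B"},
            sequences={"a": "AG" * 30, "b": "GA" * 30},
        )
        with pytest.raises(SaturationError):
            tamura_nei_distance(aln)

    def test_simulation_consistency(self):
        """Estimate within 5% of the true distance for a pair simulated
        under the TN93 Markov model at 100 kb."""
        d_true = 0.15
        aln = _simulate_tn93_pair(
            d_true,
            freqs=np.array([0.3, 0.2, 0.2, 0.3]),
            kappa1=4.0,
            kappa2=6.0,
            length=100_000,
            seed=7,
        )
        d_hat = tamura_nei_distance(aln).loc["x", "y"]
        assert abs(d_hat - d_true) / d_true < 0.05

    def test_matches_r_ape_reference(self, tmp_path):
        """Cross-check against ape::dist.dna(model='TN93') on a small pair."""
        aln = _simulate_tn93_pair(
            0.1,
            freqs=np.array([0.25, 0.25, 0.25, 0.25]),
            kappa1=3.0,
            kappa2=3.0,
            length=5_000,
            seed=3,
        )
        ours = tamura_nei_distance(aln).loc["x", "y"]
        fasta = tmp_path / "pair.fasta"
        fasta.write_text(
            f">x\n{aln.sequences['x']}\n>y\n{aln.sequences['y']}\n"
        )
        script = textwrap.dedent(
            f"""
            suppressMessages(library(ape))
            aln <- read.dna("{fasta}", format = "fasta")
            cat(dist.dna(aln, model = "TN93", pairwise.deletion = TRUE))
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        theirs = float(out.stdout.strip().split()[-1])
        assert ours == pytest.approx(theirs, rel=1e-6)


def _simulate_tn93_pair(distance, freqs, kappa1, kappa2, length, seed):
    """Evolve one sequence from another under the TN93 rate matrix so the
    expected substitutions per site equal ``distance``."""
    from scipy.linalg import expm

    gA, gC, gG, gT = freqs
    # rate matrix: alpha1 A<->G, alpha2 C<->T, beta transversions
    Q = np.zeros((4, 4))
    for i, bi in enumerate("ACGT"):
        for j, bj in enumerate("ACGT"):
            if i == j:
                continue
            purine = {bi, bj} <= {"A", "G"}
            pyrimidine = {bi, bj} <= {"C", "T"}
            rate = kappa1 if purine else kappa2 if pyrimidine else 1.0
            Q[i, j] = rate * freqs[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -np.sum(freqs * np.diag(Q))  # expected substitutions per unit time
    P = expm(Q * distance / mu)
    rng = np.random.default_rng(seed)
    x = rng.choice(4, size=length, p=freqs)
    y = np.array([rng.choice(4, p=P[b]) for b in x])
    bases = np.array(list("ACGT"))
    return AlignedSequenceSet(
        taxa=["x", "y"],
        group_of={"x": "X", "y": "Y"},
        sequences={"x": "".join(bases[x]), "y": "".join(bases[y])},
    )


class TestUpgma:
    def test_two_taxa_cherry(self):
        d = pd.DataFrame([[0, 4], [4, 0]], index=["a", "b"], columns=["a", "b"])
        tree = upgma(d)
        assert tree.height == 2
        assert {c.name for c in tree.children} == {"a", "b"}

    def test_hand_computed_three_taxon_case(self):
        d = pd.DataFrame(
            [[0, 2, 6], [2, 0, 6], [6, 6, 0]],
            index=list("ABC"),
            columns=list("ABC"),
        )
        tree = upgma(d)
        assert tree.height == 3
        inner = [c for c in tree.children if not c.is_leaf][0]
        assert inner.height == 1
        assert inner.leaves() == frozenset("AB")

    def test_ultrametricity_on_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            a = rng.random((n, n)) * 10
            d = pd.DataFrame(
                (a + a.T) / 2, index=[f"t{i}" for i in range(n)],
                columns=[f"t{i}" for i in range(n)],
            )
            np.fill_diagonal(d.values, 0)
            tree = upgma(d)
            depths = _leaf_depths(tree)
            assert max(depths) - min(depths) < 1e-9 * max(1.0, max(depths))

    def test_planted_ultrametric_matrix_recovered_exactly(self):
        # tree ((a,b):1,(c,d):2):0 -> heights 1, 2, root 3
        labels = list("abcd")
        d = pd.DataFrame(0.0, index=labels, columns=labels)
        d.loc["a", "b"] = d.loc["b", "a"] = 2.0
        d.loc["c", "d"] = d.loc["d", "c"] = 4.0
        for x in "ab":
            for y in "cd":
                d.loc[x, y] = d.loc[y, x] = 6.0
        tree = upgma(d)
        clades = {n.leaves(): n.height for n in tree.walk() if not n.is_leaf}
        assert clades[frozenset("ab")] == 1.0
        assert clades[frozenset("cd")] == 2.0
        assert clades[frozenset("abcd")] == 3.0

    def test_heights_match_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(9)
        a = rng.random((7, 7)) * 5
        dm = (a + a.T) / 2
        np.fill_diagonal(dm, 0)
        labels = [f"t{i}" for i in range(7)]
        tree = upgma(pd.DataFrame(dm, index=labels, columns=labels))
        ours = sorted(
            n.height * 2 for n in tree.walk() if not n.is_leaf
        )
        theirs = sorted(average(squareform(dm))[:, 2])
        assert np.allclose(ours, theirs)


def _leaf_depths(tree: Clade, acc=0.0):
    if tree.is_leaf:
        return [acc]
    out = []
    for c in tree.children:
        out.extend(_leaf_depths(c, acc + tree.height - c.height))
    return out


class TestBootstrap:
    def test_clean_split_gets_full_support(self):
        m = pd.DataFrame(
            [[1] * 6, [1] * 6, [0] * 6, [0] * 6],
            index=["a1", "a2", "b1", "b2"],
        )
        tree = bootstrap_support(m, builder="dice", n_replicates=50, seed=2)
        for node in tree.walk():
            if node.leaves() in ({"a1", "a2"}, {"b1", "b2"}):
                assert node.support == 100

    def test_trivial_all_taxa_bipartition_is_100(self, panel_alignment, panel_loci):
        aln, _ = panel_alignment
        m = encode_binary(panel_loci, aln, "KY31")
        tree = bootstrap_support(m, builder="dice", n_replicates=20, seed=5)
        assert tree.support == 100

    def test_med_mairei_bipartition_supported_at_100(self, panel_alignment, panel_loci):
        aln, _ = panel_alignment
        m = encode_binary(panel_loci, aln, "KY31")
        tree = bootstrap_support(m, builder="dice", n_replicates=100, seed=6)
        supports = {
            n.leaves(): n.support for n in tree.walk() if not n.is_leaf
        }
        assert supports[MED_MAIREI_TAXA] == 100

    def test_support_invariant_to_taxon_input_order(self):
        rng = np.random.default_rng(12)
        m = pd.DataFrame(
            rng.integers(0, 2, size=(5, 40)),
            index=[f"t{i}" for i in range(5)],
        )
        t1 = bootstrap_support(m, builder="dice", n_replicates=30, seed=3)
        perm = m.iloc[[3, 1, 4, 0, 2]]
        t2 = bootstrap_support(perm, builder="dice", n_replicates=30, seed=3)
        s1 = {n.leaves(): n.support for n in t1.walk() if not n.is_leaf}
        s2 = {n.leaves(): n.support for n in t2.walk() if not n.is_leaf}
        assert s1 == s2


def test_newick_output_contains_supports_and_lengths():
    d = pd.DataFrame(
        [[0, 2, 6], [2, 0, 6], [6, 6, 0]], index=list("ABC"), columns=list("ABC")
    )
    tree = upgma(d)
    for n in tree.walk():
        if not n.is_leaf:
            n.support = 87.0
    nwk = to_newick(tree)
    assert nwk.endswith(";")
    assert "87" in nwk and ":" in nwk
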