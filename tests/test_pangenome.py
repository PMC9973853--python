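import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from bgcnovelty import (
    PangenomeSimConfig,
    ProteinRecord,
    ValidationError,
    cluster_proteins,
    fit_heaps,
    pairwise_identity,
    partition,
    rarefaction,
    simulate_pangenome,
)
from bgcnovelty.pangenome import matrix_from_planted, read_protein_fasta, write_protein_fasta


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("MKTAYIAKQR", "MKTAYIAKQR") == 1.0

    def test_fully_different(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_single_substitution(self):
        assert pairwise_identity("ACGTACGT", "ACGAACGT") == pytest.approx(7 / 8)

    def test_symmetric(self, rng):
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            a = "".join(aa[i] for i in rng.integers(20, size=rng.integers(5, 40)))
            b = "".join(aa[i] for i in rng.integers(20, size=rng.integers(5, 40)))
            assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_agrees_with_biopython_score(self, rng):
        """The DP optimum must equal Biopython's global aligner score
        under the same scoring (independent oracle for the alignment
        stage; identity additionally depends on our fixed traceback)."""
        from Bio import Align

        from bgcnovelty.pangenome import _encode, _nw_align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = 0
        aligner.open_gap_score = -1
        aligner.extend_gap_score = -1
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(15):
            a = "".join(aa[i] for i in rng.integers(20, size=rng.integers(3, 30)))
            b = "".join(aa[i] for i in rng.integers(20, size=rng.integers(3, 30)))
            matches, alen = _nw_align(_encode(a), _encode(b))
            gaps = 2 * alen - len(a) - len(b)
            our_score = matches - gaps
            assert our_score == aligner.score(a, b)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_identity("", "AA")


class TestClusterProteins:
    def test_identical_across_genomes_one_family(self):
        recs = [
            ProteinRecord("g1", "p1", "MKTAYIAKQRMKTAYIAKQR"),
            ProteinRecord("g2", "p1", "MKTAYIAKQRMKTAYIAKQR"),
        ]
        m = cluster_proteins(recs)
        assert m.n_families == 1
        assert m.presence.all()

    def test_unrelated_sequences_two_families(self):
        recs = [
            ProteinRecord("g1", "p1", "MKTAYIAKQRLVHEWDNSGC"),
            ProteinRecord("g2", "p1", "WWWWFFFFPPPPGGGGHHHH"),
        ]
        assert cluster_proteins(recs).n_families == 2

    def test_duplicate_protein_ids_rejected(self):
        recs = [ProteinRecord("g1", "p1", "AAAA"), ProteinRecord("g1", "p1", "CCCC")]
        with pytest.raises(ValidationError):
            cluster_proteins(recs)

    def test_recovers_planted_families(self):
        recs = simulate_pangenome(PangenomeSimConfig(seed=1))
        m = cluster_proteins(recs)
        fam_of = {}
        for f, members in m.family_members.items():
            for key in members:
                fam_of[key] = f
        truth = [r.planted_family for r in recs]
        pred = [fam_of[r.key] for r in recs]
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_deterministic_under_shuffle(self, rng):
        recs = simulate_pangenome(
            PangenomeSimConfig(seed=3, n_genomes=3, core_families=5, accessory_families=3,
                               unique_per_genome=2, protein_length=60)
        )
        base = cluster_proteins(recs)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        again = cluster_proteins(shuffled)
        assert base.families == again.families
        assert base.family_members == again.family_members


class TestPartition:
    def _matrix(self, presence, genomes=None):
        presence = np.asarray(presence, dtype=bool)
        genomes = genomes or [f"g{i}" for i in range(presence.shape[1])]
        fams = [f"f{i}" for i in range(presence.shape[0])]
        return matrix_from_planted(
            [
                ProteinRecord(genomes[g], f"p{f}_{g}", "AAAA", planted_family=fams[f])
                for f in range(presence.shape[0])
                for g in range(presence.shape[1])
                if presence[f, g]
            ]
        )

    def test_core_unique_accessory(self):
        m = self._matrix([[1, 1, 1], [1, 0, 0], [1, 1, 0]])
        p = partition(m)
        assert p.counts == {"core": 1, "accessory": 1, "unique": 1}
        assert p.per_genome_unique == {"g0": 1, "g1": 0, "g2": 0}

    def test_single_genome_rejected(self):
        m = self._matrix([[1], [1]])
        with pytest.raises(ValidationError):
            partition(m)

    def test_planted_counts_recovered_exactly(self):
        cfg = PangenomeSimConfig(seed=5, n_genomes=4, core_families=50, accessory_families=30,
                                 unique_per_genome=5, protein_length=60)
        recs = simulate_pangenome(cfg)
        p = partition(cluster_proteins(recs))
        assert p.counts == {"core": 50, "accessory": 30, "unique": 20}
        assert sum(p.per_genome_unique.values()) == 20


@pytest.fixture(scope="module")
def matrix():
    return matrix_from_planted(
        simulate_pangenome(PangenomeSimConfig(seed=2, n_genomes=6, protein_length=30))
    )


class TestRarefaction:

    def test_monotone_curves_every_permutation(self, matrix):
        r = rarefaction(matrix, iterations=50, seed=1)
        assert (np.diff(r.pan_curves, axis=1) >= 0).all()
        assert (np.diff(r.core_curves, axis=1) <= 0).all()

    def test_endpoints(self, matrix):
        r = rarefaction(matrix, iterations=50, seed=1)
        assert (r.pan_curves[:, -1] == matrix.n_families).all()
        assert (r.pan_curves[:, 0] == r.core_curves[:, 0]).all()

    def test_reproducible_for_seed(self, matrix):
        a = rarefaction(matrix, iterations=20, seed=9)
        b = rarefaction(matrix, iterations=20, seed=9)
        assert np.array_equal(a.pan_curves, b.pan_curves)

    def test_bad_iterations_rejected(self, matrix):
        with pytest.raises(ValidationError):
            rarefaction(matrix, iterations=0)


class TestHeapsFit:
    def test_noiseless_power_law_recovered(self):
        n = np.arange(1, 13)
        fit = fit_heaps(100.0 * n**0.4)
        assert fit.kappa == pytest.approx(100.0, abs=1e-6)
        assert fit.gamma == pytest.approx(0.4, abs=1e-6)

    def test_constant_curve_is_closed(self):
        fit = fit_heaps(np.full(8, 250.0))
        assert fit.gamma == pytest.approx(0.0, abs=1e-12)
        assert not fit.open

    def test_nonpositive_curve_rejected(self):
        with pytest.raises(ValidationError):
            fit_heaps(np.array([10.0, 0.0, 30.0]))

    def test_planted_open_pangenome_called_open(self):
        for seed in (1, 2):
            recs = simulate_pangenome(
                PangenomeSimConfig(seed=seed, n_genomes=12, unique_per_genome=20)
            )
            m = matrix_from_planted(recs)
            fit = fit_heaps(rarefaction(m, iterations=200, seed=seed))
            assert fit.open and fit.gamma_ci[0] > 0.02


def test_protein_fasta_round_trip(tmp_path):
    recs = simulate_pangenome(
        PangenomeSimConfig(seed=4, n_genomes=2, core_families=3, accessory_families=0,
                           unique_per_genome=1, protein_length=40)
    )
    p = tmp_path / "prot.fa"
    write_protein_fasta(recs, p)
    back = read_protein_fasta(p)
    assert [(r.genome_id, r.protein_id, r.sequence) for r in back] == [
        (r.genome_id, r.protein_id, r.sequence) for r in recs
    ]
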