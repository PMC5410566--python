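"""Distribution, tandem-candidate detection and global alignment."""

import itertools
from functools import lru_cache

import numpy as np
import pytest
from Bio import Align

from dnajsurvey.family_pipeline import members_from_catalog
from dnajsurvey.formats_io import GeneRecord
from dnajsurvey.genome_organization import (
    DuplicationCriteria,
    Scoring,
    call_tandem,
    chromosome_distribution,
    global_align,
    read_segmental_pairs,
    tandem_candidates,
)


class FakeMember:
    def __init__(self, name, chrom, start, end, locus=None):
        self.gene_name = name
        self.locus = locus or name
        self.gene = GeneRecord(
            gene_id=name, chromosome=chrom, start=start, end=end, strand="+",
            exons=(), protein_id=name,
        )
        self.group = "C"


class TestDistribution:
    def test_fixture_distribution(self, catalog):
        dist = chromosome_distribution(members_from_catalog(catalog))
        assert dist["8"] == 11 and dist["5"] == 9
        assert dist["6"] == 3 and dist["10"] == 3
        assert dist["00"] == 5
        assert sum(dist.values()) == 76

    def test_empty(self):
        assert chromosome_distribution([]) == {}


class TestTandemCandidates:
    def test_fixture_yields_single_chr7_pair(self, catalog):
        pairs = tandem_candidates(members_from_catalog(catalog))
        assert [(a.gene_name, b.gene_name) for a, b in pairs] == [
            ("CaDnaJ41", "CaDnaJ42")
        ]
        a, b = pairs[0]
        assert b.gene.start - a.gene.end == 3931

    def test_far_pair_excluded(self):
        members = [
            FakeMember("g1", "1", 1000, 2000),
            FakeMember("g2", "1", 202001, 203000),  # 200 kb gap
        ]
        assert tandem_candidates(members) == []

    def test_overlapping_genes_have_zero_gap(self):
        members = [
            FakeMember("g1", "1", 1000, 5000),
            FakeMember("g2", "1", 4000, 9000),
        ]
        assert len(tandem_candidates(members)) == 1

    def test_intervening_gene_limit(self):
        members = [
            FakeMember("g1", "1", 1_000, 2_000),
            FakeMember("g2", "1", 10_000, 11_000),
            FakeMember("g3", "1", 20_000, 21_000),
            FakeMember("g4", "1", 30_000, 31_000),
        ]
        pairs = tandem_candidates(members, DuplicationCriteria(max_intervening_genes=1))
        names = {(a.gene_name, b.gene_name) for a, b in pairs}
        assert ("g1", "g4") not in names  # two intervening members
        assert ("g1", "g3") in names

    def test_matches_quadratic_oracle_on_random_genes(self):
        rng = np.random.default_rng(5)
        members = []
        # 30 random genes; 3 planted close pairs
        pos = 0
        for i in range(30):
            pos += int(rng.integers(150_000, 400_000))
            members.append(FakeMember(f"g{i:02d}", str(rng.integers(1, 4)), pos, pos + 1000))
        for k in range(3):
            anchor = members[k * 7]
            g = anchor.gene
            members.append(
                FakeMember(f"p{k}", g.chromosome, g.end + 4000, g.end + 5000)
            )
        crit = DuplicationCriteria(max_intervening_genes=None)
        got = {
            (a.gene_name, b.gene_name) for a, b in tandem_candidates(members, crit)
        }
        oracle = set()
        for a, b in itertools.combinations(members, 2):
            if a.gene.chromosome != b.gene.chromosome:
                continue
            lo, hi = sorted((a, b), key=lambda m: m.gene.start)
            gap = max(0, hi.gene.start - lo.gene.end)
            if gap <= crit.max_distance_bp:
                oracle.add(tuple(sorted((a.gene_name, b.gene_name))))
        assert got == oracle and len(got) >= 3

    def test_permutation_invariance(self, catalog):
        members = members_from_catalog(catalog)
        ref = tandem_candidates(members)
        rev = tandem_candidates(list(reversed(members)))
        assert [(a.gene_name, b.gene_name) for a, b in ref] == [
            (a.gene_name, b.gene_name) for a, b in rev
        ]


def brute_force_score(a, b, scoring=Scoring()):
    """Memoized recursion oracle for the global alignment score."""

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0:
            return j * scoring.gap
        if j == 0:
            return i * scoring.gap
        return max(
            rec(i - 1, j - 1) + scoring.score(a[i - 1], b[j - 1]),
            rec(i - 1, j) + scoring.gap,
            rec(i, j - 1) + scoring.gap,
        )

    return rec(len(a), len(b))


class TestGlobalAlign:
    def test_identical_sequences(self):
        r = global_align("M" * 50, "M" * 50)
        assert r.coverage_of_longer == 1.0 and r.identity_of_aligned == 1.0

    def test_single_mismatch_identity(self):
        r = global_align("ACGT", "ACGA")
        assert r.identity_of_aligned == pytest.approx(0.75)
        assert r.score == pytest.approx(2.0)  # 3 matches - 1 mismatch

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")

    def test_score_matches_recursion_oracle(self):
        rng = np.random.default_rng(6)
        alpha = np.array(list("ACGT"))
        for _ in range(40):
            a = "".join(alpha[rng.integers(0, 4, rng.integers(1, 13))])
            b = "".join(alpha[rng.integers(0, 4, rng.integers(1, 13))])
            assert global_align(a, b).score == pytest.approx(brute_force_score(a, b))

    def test_score_matches_biopython_aligner(self):
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        rng = np.random.default_rng(7)
        alpha = np.array(list("ACGT"))
        for _ in range(20):
            a = "".join(alpha[rng.integers(0, 4, rng.integers(5, 40))])
            b = "".join(alpha[rng.integers(0, 4, rng.integers(5, 40))])
            assert global_align(a, b).score == pytest.approx(aligner.score(a, b))

    def test_fraction_bounds(self):
        rng = np.random.default_rng(8)
        alpha = np.array(list("ACGT"))
        for _ in range(20):
            a = "".join(alpha[rng.integers(0, 4, rng.integers(1, 30))])
            b = "".join(alpha[rng.integers(0, 4, rng.integers(1, 30))])
            r = global_align(a, b)
            assert 0 <= r.coverage_of_longer <= 1
            assert 0 <= r.identity_of_aligned <= 1


class TestCallTandem:
    def test_planted_pair_called_with_true_identity(self, study_bundle):
        members = _bundle_members(study_bundle)
        seqs = {m.gene_name: s for m, s in zip_members_seqs(members, study_bundle)}
        calls = call_tandem(members, seqs)
        truth = study_bundle.tandem_truth.iloc[0]
        assert [(c.gene_a, c.gene_b) for c in calls] == [
            tuple(sorted((truth.gene_a, truth.gene_b)))
        ]
        assert calls[0].alignment.identity_of_aligned == pytest.approx(
            truth.true_identity, abs=1e-3
        )
        assert calls[0].alignment.coverage_of_longer == pytest.approx(1.0)

    def test_identity_exactly_70_percent_not_called(self):
        members = [
            FakeMember("g1", "1", 1000, 2000),
            FakeMember("g2", "1", 6000, 7000),
        ]
        base = "ACDEFGHIKL" * 10
        # substitute exactly 30 positions -> identity exactly 0.70
        mutated = list(base)
        for i in range(30):
            mutated[i] = "W" if base[i] != "W" else "Y"
        seqs = {"g1": base, "g2": "".join(mutated)}
        assert call_tandem(members, seqs) == []

    def test_identity_above_threshold_called(self):
        members = [
            FakeMember("g1", "1", 1000, 2000),
            FakeMember("g2", "1", 6000, 7000),
        ]
        base = "ACDEFGHIKL" * 10
        mutated = list(base)
        for i in range(15):  # 85% identity
            mutated[i] = "W" if base[i] != "W" else "Y"
        calls = call_tandem(members, {"g1": base, "g2": "".join(mutated)})
        assert len(calls) == 1
        assert calls[0].alignment.identity_of_aligned == pytest.approx(0.85)
        assert calls[0].distance_bp == 4000

    def test_missing_sequence_names_gene(self):
        members = [
            FakeMember("g1", "1", 1000, 2000),
            FakeMember("g2", "1", 6000, 7000),
        ]
        with pytest.raises(KeyError, match="g2"):
            call_tandem(members, {"g1": "MKT"})


class TestPlantedDuplicationRecovery:
    def test_exact_recovery_over_twenty_simulated_genomes(self):
        """Sensitivity 1.0 on planted pairs, zero calls among random neighbors."""
        from dnajsurvey.synthetic_data import SimulationDesign, simulate

        for seed in range(20):
            design = SimulationDesign(
                seed=100 + seed, n_family_genes=8, n_decoys=0,
                n_chromosomes=2, n_tandem_pairs=1, tandem_identity=0.85,
            )
            bundle = simulate(design)
            truth_pair = tuple(
                sorted(bundle.tandem_truth.iloc[0][["gene_a", "gene_b"]])
            )
            members = _bundle_members(bundle)
            seqs = {m.gene_name: s for m, s in zip_members_seqs(members, bundle)}
            calls = call_tandem(members, seqs)
            assert [(c.gene_a, c.gene_b) for c in calls] == [truth_pair]


def _bundle_members(bundle):
    import tempfile

    from dnajsurvey.domain_annotation import ArchitectureConfig
    from dnajsurvey.formats_io import read_gff3
    from dnajsurvey.report import build_members

    with tempfile.NamedTemporaryFile("w", suffix=".gff3", delete=False) as fh:
        fh.write(bundle.gff3)
        path = fh.name
    genes = read_gff3(path)
    members, _, _ = build_members(
        bundle.proteome, genes, bundle.domain_hits, ArchitectureConfig()
    )
    # keep original locus ids as names for truth comparison
    class Named:
        def __init__(self, m):
            self.gene_name = m.locus
            self.locus = m.locus
            self.gene = m.gene
            self.group = m.group

    return [Named(m) for m in members]


def zip_members_seqs(members, bundle):
    seqs = {r.id: r.residues for r in bundle.proteome}
    return [(m, seqs[m.locus]) for m in members]


class TestSegmentalPairs:
    def test_pairs_mapped_to_member_names(self, tmp_path, catalog):
        members = members_from_catalog(catalog)
        p = tmp_path / "seg.tsv"
        p.write_text("CA01g22020\tCA08g04550\nCA04g03850\tCA12g07660\n")
        calls = read_segmental_pairs(p, members)
        assert [(c.gene_a, c.gene_b, c.kind) for c in calls] == [
            ("CaDnaJ04", "CaDnaJ44", "segmental"),
            ("CaDnaJ19", "CaDnaJ67", "segmental"),
        ]

    def test_unknown_locus_skipped_with_warning(self, tmp_path, catalog, caplog):
        members = members_from_catalog(catalog)
        p = tmp_path / "seg.tsv"
        p.write_text("CA01g22020\tCAXXg99999\n")
        with caplog.at_level("WARNING"):
            calls = read_segmental_pairs(p, members)
        assert calls == []
        assert "unknown locus" in caplog.text

    def test_empty_file(self, tmp_path, catalog):
        p = tmp_path / "seg.tsv"
        p.write_text("")
        assert read_segmental_pairs(p, members_from_catalog(catalog)) == []
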