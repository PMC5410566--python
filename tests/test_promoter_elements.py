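"""Upstream-window extraction and IUPAC cis-element scanning."""

import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from dnajsurvey.formats_io import FormatError, GeneRecord, SequenceRecord
from dnajsurvey.promoter_elements import (
    IUPAC,
    MotifDefinition,
    PromoterConfig,
    element_census,
    extract_promoters,
    load_default_motifs,
    scan_motifs,
)


def gene(gid="g1", chrom="c1", start=2001, end=3000, strand="+"):
    return GeneRecord(
        gene_id=gid, chromosome=chrom, start=start, end=end, strand=strand,
        exons=(), protein_id=gid,
    )


def contig(seq, cid="c1"):
    return SequenceRecord(id=cid, residues=seq)


class TestExtractPromoters:
    def test_plus_strand_window(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 5000)])
        (win,) = extract_promoters([contig(seq)], [gene(start=2001, end=3000)])
        assert win.residues == seq[500:2000]
        assert len(win.residues) == 1500

    def test_plus_strand_truncated_at_contig_edge(self):
        seq = "A" * 5000
        (win,) = extract_promoters([contig(seq)], [gene(start=1001, end=2000)])
        assert len(win.residues) == 1000
        assert "truncated" in win.description

    def test_minus_strand_is_reverse_complement_of_downstream(self):
        seq = "ACGTACGTACGTACGTACGTACGTACGTGG"  # 30 bp toy contig
        g = gene(start=5, end=10, strand="-")
        (win,) = extract_promoters(
            [contig(seq)], [g], PromoterConfig(upstream_bp=8)
        )
        expected = str(Seq(seq[10:18]).reverse_complement())
        assert win.residues == expected

    def test_missing_contig_is_error(self):
        with pytest.raises(FormatError, match="contig"):
            extract_promoters([contig("ACGT", cid="other")], [gene()])

    def test_round_trip_with_simulator(self, small_bundle, gff_loader):
        genes = gff_loader(small_bundle.gff3)
        fam = {p.id for p in small_bundle.promoters}
        fam_genes = [g for g in genes if g.gene_id in fam]
        extracted = {
            w.id: w.residues
            for w in extract_promoters(small_bundle.genome, fam_genes)
        }
        for p in small_bundle.promoters:
            assert extracted[p.id] == p.residues


HSE = MotifDefinition(name="HSE", sequence="AAAAAATTTC", category="stress", response="heat")


class TestScanMotifs:
    def test_forward_hit(self):
        pro = SequenceRecord(id="p", residues="G" * 20 + "AAAAAATTTC" + "G" * 20)
        hits = scan_motifs(pro, [HSE])
        assert [(h.start, h.end, h.strand) for h in hits] == [(21, 30, "+")]
        assert hits[0].matched_seq == "AAAAAATTTC"

    def test_reverse_complement_hit(self):
        pro = SequenceRecord(id="p", residues="G" * 20 + "GAAATTTTTT" + "G" * 20)
        hits = scan_motifs(pro, [HSE])
        assert [(h.start, h.end, h.strand) for h in hits] == [(21, 30, "-")]

    def test_all_g_promoter_has_no_hits(self):
        pro = SequenceRecord(id="p", residues="G" * 300)
        assert scan_motifs(pro, load_default_motifs()) == []

    def test_degenerate_code_matching(self):
        m = MotifDefinition(name="d", sequence="RYN", category="stress")
        pro = SequenceRecord(id="p", residues="GTA")  # R=G, Y=T, N=A
        hits = scan_motifs(pro, [m], PromoterConfig(scan_both_strands=False))
        assert [(h.start, h.end) for h in hits] == [(1, 3)]

    def test_overlapping_occurrences_counted(self):
        m = MotifDefinition(name="aa", sequence="AAA", category="stress")
        pro = SequenceRecord(id="p", residues="AAAAA")
        hits = scan_motifs(pro, [m], PromoterConfig(scan_both_strands=False))
        assert [(h.start, h.end) for h in hits] == [(1, 3), (2, 4), (3, 5)]

    @settings(derandomize=True, max_examples=150)
    @given(
        seq=st.text(alphabet="ACGT", min_size=0, max_size=80),
        motif=st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=6),
    )
    def test_matches_naive_iupac_oracle(self, seq, motif):
        m = MotifDefinition(name="m", sequence=motif, category="stress")
        pro = SequenceRecord(id="p", residues=seq) if seq else None
        if pro is None:
            return
        got = {
            (h.start, h.end)
            for h in scan_motifs(pro, [m], PromoterConfig(scan_both_strands=False))
        }
        naive = set()
        for i in range(len(seq) - len(motif) + 1):
            if all(seq[i + k] in IUPAC[c] for k, c in enumerate(motif)):
                naive.add((i + 1, i + len(motif)))
        assert got == naive

    def test_strand_symmetry(self):
        rng = np.random.default_rng(4)
        motifs = load_default_motifs()
        for _ in range(10):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
            rc = str(Seq(seq).reverse_complement())
            h_fwd = scan_motifs(SequenceRecord(id="a", residues=seq), motifs)
            h_rc = scan_motifs(SequenceRecord(id="a", residues=rc), motifs)
            assert len(h_fwd) == len(h_rc)


class TestCensus:
    def test_conservation(self, small_bundle):
        motifs = load_default_motifs()
        hits = []
        for p in small_bundle.promoters:
            hits.extend(scan_motifs(p, motifs))
        per_motif, per_gene = element_census(hits, [p.id for p in small_bundle.promoters])
        assert per_motif.total_hits.sum() == len(hits)
        assert per_gene.n_elements.sum() == len(hits)
        assert (per_motif.genes_with_hit <= len(small_bundle.promoters)).all()

    def test_planted_counts_recovered_exactly(self, small_bundle):
        """Scanning simulator promoters returns exactly the planted copies."""
        motifs = load_default_motifs()
        truth = small_bundle.gene_truth.set_index("gene_id")
        for p in small_bundle.promoters:
            hits = scan_motifs(p, motifs)
            counts = {}
            for h in hits:
                counts[h.motif] = counts.get(h.motif, 0) + 1
            for m in motifs:
                assert counts.get(m.name, 0) == truth.loc[p.id, f"motif_{m.name}"]

    def test_max_types_matches_brute_force(self, small_bundle):
        motifs = load_default_motifs()
        all_hits = []
        for p in small_bundle.promoters:
            all_hits.extend(scan_motifs(p, motifs))
        _, per_gene = element_census(all_hits, [p.id for p in small_bundle.promoters])
        brute = {}
        for h in all_hits:
            brute.setdefault(h.gene, set()).add(h.motif)
        top_gene = per_gene.sort_values(["n_types", "gene"], ascending=[False, True]).iloc[0]
        assert top_gene.n_types == max(len(v) for v in brute.values())

    def test_no_hits_gives_zeros(self):
        per_motif, per_gene = element_census([], ["g1", "g2"])
        assert per_motif.empty
        assert per_gene.n_elements.sum() == 0
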