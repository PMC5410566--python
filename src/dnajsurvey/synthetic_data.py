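"""Self-contained toy dataset generator with machine-readable ground truth.

The simulator emulates the statistical structure the survey pipeline
assumes: a small multi-chromosome genome carrying family genes whose
proteins have planted domain architectures (one per group A-E), decoy
genes whose J-domain evidence is truncated below the completeness cut-off,
tandem duplicate pairs placed a few kb apart with controlled protein
identity, promoter windows with planted cis-element copies, an RPKM matrix
drawn from three expression archetypes, and a qPCR Ct table with known
log2 fold changes. Every file parses with ``formats_io`` and every planted
quantity is recorded in the ground truth, so pipeline-vs-truth agreement
can be asserted exactly on noise-free designs.

All randomness flows from a single seed through one numpy Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .domain_annotation import (
    AMINO_ACIDS,
    HPD,
    J_DOMAIN_ID,
    ZINC_FINGER,
    default_j_profile,
    find_pattern,
)
from .formats_io import DomainHit, SequenceRecord, write_domain_table, write_fasta, write_tsv
from .promoter_elements import (
    MotifDefinition,
    PromoterConfig,
    load_default_motifs,
    scan_motifs,
)

NUCLEOTIDES = np.array(list("ACGT"))
_RC = str.maketrans("ACGT", "TGCA")

DEFAULT_TISSUES = (
    "root", "stem", "leaf", "PC-6DPA", "PC-16DPA", "PC-25DPA", "MG", "B", "B5", "B10",
)

#: the study's group sizes, as proportions of 76
DEFAULT_GROUP_PROPORTIONS = {"A": 9 / 76, "B": 8 / 76, "C": 53 / 76, "D": 1 / 76, "E": 5 / 76}

#: archetype mix: 29/76 barely expressed, 10/76 constitutive, a few
#: tissue-specific, remainder intermediate
DEFAULT_EXPRESSION_ARCHETYPES = {
    "barely_expressed": 29 / 76,
    "constitutive": 10 / 76,
    "tissue_specific": 3 / 76,
    "other": 34 / 76,
}

DEFAULT_MOTIF_RATES = {
    "HSE": 1.0, "TC-rich": 1.4, "MBS": 1.3, "LTR": 0.45, "TCA-element": 1.0,
    "TGA-element": 0.5, "GARE-motif": 1.1, "CGTCA-motif": 1.8, "ERE": 0.5, "ABRE": 0.7,
}


@dataclass(frozen=True)
class SimulationDesign:
    seed: int = 0
    n_chromosomes: int = 12
    n_family_genes: int = 76
    group_proportions: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_PROPORTIONS))
    n_decoys: int = 9
    n_tandem_pairs: int = 1
    tandem_identity: float = 0.85
    motif_plant_rates: dict = field(default_factory=lambda: dict(DEFAULT_MOTIF_RATES))
    expression_archetypes: dict = field(
        default_factory=lambda: dict(DEFAULT_EXPRESSION_ARCHETYPES)
    )
    qpcr_log2fold_range: tuple = (-3.0, 3.0)
    ct_noise_sd: float = 0.2
    n_replicates: int = 3
    tissues: tuple = DEFAULT_TISSUES
    upstream_bp: int = 1500
    intergene_gap_bp: int = 150_000
    tandem_gap_bp: int = 4_000
    max_chromosome_bp: int = 20_000_000

    def __post_init__(self) -> None:
        if abs(sum(self.group_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        if abs(sum(self.expression_archetypes.values()) - 1.0) > 1e-9:
            raise ValueError("expression archetype proportions must sum to 1")
        if not 0.7 < self.tandem_identity <= 1.0:
            raise ValueError("tandem_identity must lie in (0.7, 1]")
        if self.n_tandem_pairs * 2 > self.n_family_genes:
            raise ValueError("too many tandem pairs for family size")


@dataclass
class SimulatedBundle:
    """In-memory dataset plus truth tables; ``write`` emits the file tree."""

    genome: list[SequenceRecord]
    gff3: str
    proteome: list[SequenceRecord]
    domain_hits: list[DomainHit]
    promoters: list[SequenceRecord]
    expression: pd.DataFrame
    qpcr: pd.DataFrame
    gene_truth: pd.DataFrame
    tandem_truth: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fasta",
            "gff3": outdir / "genes.gff3",
            "proteome": outdir / "proteome.fasta",
            "domain_hits": outdir / "domain_hits.tsv",
            "promoters": outdir / "promoters.fasta",
            "expression": outdir / "expression.tsv",
            "qpcr": outdir / "qpcr_ct.tsv",
            "gene_truth": outdir / "truth_genes.tsv",
            "tandem_truth": outdir / "truth_tandem.tsv",
        }
        write_fasta(self.genome, paths["genome"])
        paths["gff3"].write_text(self.gff3)
        write_fasta(self.proteome, paths["proteome"])
        write_domain_table(self.domain_hits, paths["domain_hits"], hmm_len=63)
        write_fasta(self.promoters, paths["promoters"])
        expr = self.expression.reset_index().rename(columns={"index": "gene"})
        write_tsv(expr, paths["expression"])
        write_tsv(self.qpcr, paths["qpcr"])
        write_tsv(self.gene_truth, paths["gene_truth"])
        write_tsv(self.tandem_truth, paths["tandem_truth"])
        return paths


def _counts_from_proportions(props: dict, n: int) -> dict:
    """Largest-remainder apportionment of n items over the proportion map."""
    keys = sorted(props)
    raw = {k: props[k] * n for k in keys}
    counts = {k: int(np.floor(raw[k])) for k in keys}
    short = n - sum(counts.values())
    by_frac = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_frac[:short]:
        counts[k] += 1
    return counts


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float, protect: set[int] = frozenset()) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in protect:
            continue
        if rng.random() < rate:
            choices = [aa for aa in AMINO_ACIDS if aa != out[i]]
            out[i] = choices[rng.integers(0, 19)]
    return "".join(out)


def _zf_block(rng: np.random.Generator, repeats: int = 2) -> str:
    """Concatenated CxxCxGxG repeats with random spacer residues (no C/G at x)."""
    safe = [aa for aa in AMINO_ACIDS if aa not in "CG"]
    parts = []
    for _ in range(repeats):
        x = lambda: safe[rng.integers(0, len(safe))]
        parts.append(f"C{x()}{x()}C{x()}G{x()}G")
        parts.append("".join(safe[rng.integers(0, len(safe))] for _ in range(4)))
    return "".join(parts)


def _build_family_protein(rng: np.random.Generator, group: str, j_consensus: str) -> tuple[str, tuple[int, int]]:
    """A protein with the architecture its group requires; returns (seq, J span)."""
    hpd_at = j_consensus.index(HPD)  # 0-based within the J-domain
    for _ in range(200):
        protect = set(range(hpd_at, hpd_at + 3))
        j_seq = _mutate(rng, j_consensus, 0.05, protect=protect)
        if group == "E":
            j_seq = j_seq[:hpd_at + 1] + "A" + j_seq[hpd_at + 2:]  # HPD -> HAD
        lead = _random_protein(rng, 20)
        if group == "A":
            seq = lead + j_seq + _random_protein(rng, 15) + _zf_block(rng) + _random_protein(rng, 50)
            want_zf = 2
        elif group == "B" or group == "E":
            seq = lead + j_seq + _random_protein(rng, 60)
            want_zf = 0
        elif group == "C":
            seq = lead + j_seq + _random_protein(rng, 10)
            want_zf = 0
        elif group == "D":
            seq = lead + _zf_block(rng) + _random_protein(rng, 5) + j_seq + _random_protein(rng, 10)
            want_zf = 2
        else:
            raise ValueError(f"unknown group {group}")
        if group == "D":
            j_start = len(seq) - 10 - len(j_seq) + 1
        else:
            j_start = len(lead) + 1
        j_span = (j_start, j_start + len(j_seq) - 1)
        # reject chance zinc fingers / HPD artefacts so planted truth is exact
        if len(find_pattern(seq, ZINC_FINGER)) != want_zf:
            continue
        j_window = seq[j_span[0] - 1 : j_span[1]]
        if group == "E" and HPD in j_window:
            continue
        if group != "E" and HPD not in j_window:
            continue
        return seq, j_span
    raise RuntimeError("could not realise requested architecture")


def _mutate_copy_exact(rng: np.random.Generator, seq: str, identity: float, protect: set[int]) -> str:
    """Copy with exactly round((1-identity)*len) substitutions outside protected sites."""
    n_sub = round((1.0 - identity) * len(seq))
    free = [i for i in range(len(seq)) if i not in protect]
    sites = rng.choice(len(free), size=min(n_sub, len(free)), replace=False)
    out = list(seq)
    for si in sites:
        i = free[si]
        choices = [aa for aa in AMINO_ACIDS if aa != out[i]]
        out[i] = choices[rng.integers(0, 19)]
    return "".join(out)


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return NUCLEOTIDES[rng.integers(0, 4, size=n)]


def _plant_promoter(
    rng: np.random.Generator,
    motifs: list[MotifDefinition],
    rates: dict,
    length: int,
) -> tuple[str, dict]:
    """A promoter window whose complete motif-hit set equals the planted set."""
    config = PromoterConfig(upstream_bp=length)
    for _ in range(60):
        seq = _random_dna(rng, length)
        planted: list[tuple[str, int, int, str]] = []
        occupied: list[tuple[int, int]] = []
        counts = {m.name: 0 for m in motifs}
        for m in motifs:
            k = rng.poisson(rates.get(m.name, 0.0))
            for _ in range(k):
                mlen = len(m.sequence)
                for _try in range(50):
                    pos = int(rng.integers(0, length - mlen + 1))
                    if all(pos + mlen <= s or pos >= e for s, e in occupied):
                        break
                else:
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                ins = m.sequence if strand == "+" else m.sequence.translate(_RC)[::-1]
                seq[pos : pos + mlen] = list(ins)
                occupied.append((pos, pos + mlen))
                planted.append((m.name, pos + 1, pos + mlen, strand))
                counts[m.name] += 1
        # scrub chance hits until the scan reports exactly the planted set
        planted_set = {(n, s, e, st) for n, s, e, st in planted}
        ok = False
        for _scrub in range(200):
            rec = SequenceRecord(id="p", residues="".join(seq))
            hits = {
                (h.motif, h.start, h.end, h.strand)
                for h in scan_motifs(rec, motifs, config)
            }
            extra = hits - planted_set
            if not extra and planted_set <= hits:
                ok = True
                break
            if planted_set - hits:
                break  # a plant was damaged; regenerate
            name, s, e, _st = sorted(extra)[0]
            mutable = [
                i for i in range(s - 1, e)
                if all(not (ps - 1 <= i < pe) for _, ps, pe, _ in planted)
            ]
            if not mutable:
                break
            i = mutable[int(rng.integers(0, len(mutable)))]
            current = seq[i]
            seq[i] = rng.choice([b for b in "ACGT" if b != current])
        if ok:
            return "".join(seq), counts
    raise RuntimeError("could not realise clean promoter")


def _make_exons(rng: np.random.Generator, start: int, end: int) -> list[tuple[int, int]]:
    """Partition [start,end] into 1-8 exons separated by >=1 bp introns."""
    span = end - start + 1
    n_exons = int(rng.integers(1, 9))
    n_exons = min(n_exons, max(1, span // 40))
    if n_exons == 1:
        return [(start, end)]
    cuts = sorted(rng.choice(np.arange(1, span - 1), size=2 * (n_exons - 1), replace=False))
    bounds = [0] + [int(c) for c in cuts] + [span]
    exons = []
    for k in range(n_exons):
        s = start + bounds[2 * k]
        e = start + bounds[2 * k + 1] - (0 if k == n_exons - 1 else 1)
        if e < s:
            e = s
        exons.append((s, min(e, end)))
    # enforce strictly increasing, disjoint spans
    fixed = []
    prev_end = start - 2
    for s, e in exons:
        s = max(s, prev_end + 2)
        e = max(e, s)
        if e > end:
            break
        fixed.append((s, e))
        prev_end = e
    return fixed or [(start, end)]


def simulate(design: SimulationDesign) -> SimulatedBundle:
    """Generate the full dataset bundle; deterministic for a fixed seed."""
    rng = np.random.default_rng(design.seed)
    profile = default_j_profile()
    j_consensus = profile.consensus
    motifs = load_default_motifs()

    # -- group labels ------------------------------------------------------
    counts = _counts_from_proportions(design.group_proportions, design.n_family_genes)
    groups: list[str] = []
    for g in sorted(counts):
        groups.extend([g] * counts[g])
    rng.shuffle(groups)

    # -- tandem pairing: donor/partner indices among group-C genes ---------
    c_indices = [i for i, g in enumerate(groups) if g == "C"]
    if len(c_indices) < 2 * design.n_tandem_pairs:
        raise ValueError("not enough group-C genes for requested tandem pairs")
    tandem_partner: dict[int, int] = {}  # partner index -> donor index
    for p in range(design.n_tandem_pairs):
        donor, partner = c_indices[2 * p], c_indices[2 * p + 1]
        tandem_partner[partner] = donor

    # -- proteins ----------------------------------------------------------
    n_total = design.n_family_genes + design.n_decoys
    gene_ids = [f"SIMg{i + 1:03d}" for i in range(n_total)]
    proteins: dict[int, str] = {}
    j_spans: dict[int, tuple[int, int]] = {}
    tandem_true_identity: dict[int, float] = {}
    for i in range(design.n_family_genes):
        if i in tandem_partner:
            continue
        seq, span = _build_family_protein(rng, groups[i], j_consensus)
        proteins[i], j_spans[i] = seq, span
    for partner, donor in tandem_partner.items():
        donor_seq, span = proteins[donor], j_spans[donor]
        hpd_at = donor_seq.find(HPD, span[0] - 1, span[1])
        protect = set(range(hpd_at, hpd_at + 3))
        for _ in range(100):
            copy = _mutate_copy_exact(rng, donor_seq, design.tandem_identity, protect)
            if len(find_pattern(copy, ZINC_FINGER)) == 0:
                break
        proteins[partner], j_spans[partner] = copy, span
        n_sub = round((1.0 - design.tandem_identity) * len(donor_seq))
        tandem_true_identity[partner] = 1.0 - n_sub / len(donor_seq)
    # decoys: half-length J evidence (hit table carries the truncation)
    for d in range(design.n_decoys):
        i = design.n_family_genes + d
        half = len(j_consensus) // 2
        j_seq = _mutate(rng, j_consensus[:half], 0.05)
        seq = _random_protein(rng, 20) + j_seq + _random_protein(rng, 40)
        proteins[i] = seq
        j_spans[i] = (21, 20 + half)

    proteome = [
        SequenceRecord(id=gene_ids[i], residues=proteins[i], description="")
        for i in range(n_total)
    ]

    # -- domain-hit table --------------------------------------------------
    domain_hits = []
    half_cov = (len(j_consensus) // 2) / len(j_consensus)
    for i in range(n_total):
        is_decoy = i >= design.n_family_genes
        s, e = j_spans[i]
        domain_hits.append(
            DomainHit(
                protein_id=gene_ids[i],
                domain_id=J_DOMAIN_ID,
                ali_start=s,
                ali_end=e,
                profile_cov=half_cov if is_decoy else 1.0,
                e_value=1e-20,
            )
        )

    # -- placement ---------------------------------------------------------
    order = list(range(n_total))  # placement order = id order
    per_chrom: dict[int, list[int]] = {c: [] for c in range(design.n_chromosomes)}
    c = 0
    k = 0
    while k < len(order):
        i = order[k]
        per_chrom[c].append(i)
        if i in tandem_partner.values():
            # keep the partner adjacent on the same chromosome
            partner = next(p for p, d in tandem_partner.items() if d == i)
            if partner in order[k + 1 :]:
                order.remove(partner)
                order.insert(k + 1, partner)
                per_chrom[c].append(partner)
                k += 1
        c = (c + 1) % design.n_chromosomes
        k += 1

    chrom_names = [f"chr{c + 1:02d}" for c in range(design.n_chromosomes)]
    gene_meta: dict[int, dict] = {}
    chrom_seqs: dict[str, np.ndarray] = {}
    for c in range(design.n_chromosomes):
        pos = design.upstream_bp + 1000
        for idx, i in enumerate(per_chrom[c]):
            gene_len = int(rng.integers(1500, 4001))
            if i in tandem_partner:  # place close to its donor (previous gene)
                donor_meta = gene_meta[tandem_partner[i]]
                pos = donor_meta["end"] + design.tandem_gap_bp
            start, end = pos, pos + gene_len - 1
            strand = "+" if rng.random() < 0.8 else "-"
            gene_meta[i] = {
                "chrom": chrom_names[c], "start": start, "end": end,
                "strand": strand, "exons": _make_exons(rng, start, end),
            }
            pos = end + design.intergene_gap_bp
        length = pos + design.upstream_bp + 1000
        if length > design.max_chromosome_bp:
            raise ValueError(
                f"design infeasible: {chrom_names[c]} would need {length} bp "
                f"(> {design.max_chromosome_bp})"
            )
        chrom_seqs[chrom_names[c]] = _random_dna(rng, length)

    # -- promoters (family genes only) with planted motifs ------------------
    promoters = []
    motif_counts: dict[int, dict] = {}
    for i in range(design.n_family_genes):
        window, counts_i = _plant_promoter(
            rng, motifs, design.motif_plant_rates, design.upstream_bp
        )
        motif_counts[i] = counts_i
        meta = gene_meta[i]
        arr = chrom_seqs[meta["chrom"]]
        if meta["strand"] == "+":
            lo = meta["start"] - design.upstream_bp - 1  # 0-based
            arr[lo : lo + design.upstream_bp] = list(window)
        else:
            rc = window.translate(_RC)[::-1]
            lo = meta["end"]  # 0-based position of end+1
            arr[lo : lo + design.upstream_bp] = list(rc)
        promoters.append(SequenceRecord(id=gene_ids[i], residues=window, description="promoter"))

    genome = [
        SequenceRecord(id=name, residues="".join(chrom_seqs[name]), description="")
        for name in chrom_names
    ]

    # -- GFF3 --------------------------------------------------------------
    lines = ["##gff-version 3"]
    for c in range(design.n_chromosomes):
        for i in per_chrom[c]:
            meta = gene_meta[i]
            gid = gene_ids[i]
            lines.append(
                f"{meta['chrom']}\tsim\tgene\t{meta['start']}\t{meta['end']}\t.\t"
                f"{meta['strand']}\t.\tID={gid}"
            )
            lines.append(
                f"{meta['chrom']}\tsim\tmRNA\t{meta['start']}\t{meta['end']}\t.\t"
                f"{meta['strand']}\t.\tID={gid}.m1;Parent={gid};protein_id={gid}"
            )
            for n_ex, (s, e) in enumerate(meta["exons"], start=1):
                lines.append(
                    f"{meta['chrom']}\tsim\texon\t{s}\t{e}\t.\t{meta['strand']}\t.\t"
                    f"ID={gid}.m1.exon{n_ex};Parent={gid}.m1"
                )
    gff3 = "\n".join(lines) + "\n"

    # -- expression matrix -------------------------------------------------
    arch_counts = _counts_from_proportions(
        design.expression_archetypes, design.n_family_genes
    )
    patterns: list[str] = []
    for p in sorted(arch_counts):
        patterns.extend([p] * arch_counts[p])
    rng.shuffle(patterns)
    n_tissues = len(design.tissues)
    expr = np.zeros((design.n_family_genes, n_tissues))
    for i, pat in enumerate(patterns):
        if pat == "barely_expressed":
            expr[i] = rng.uniform(0.0, 0.5, n_tissues)
        elif pat == "constitutive":
            expr[i] = rng.uniform(2.0, 100.0, n_tissues)
        elif pat == "tissue_specific":
            expr[i] = rng.uniform(0.0, 0.5, n_tissues)
            k = int(rng.integers(1, 3))
            on = rng.choice(n_tissues, size=k, replace=False)
            expr[i, on] = rng.uniform(20.0, 100.0, k)
        else:  # other: expressed in 3 .. n-1 tissues
            expr[i] = rng.uniform(0.0, 0.5, n_tissues)
            k = int(rng.integers(3, n_tissues))
            on = rng.choice(n_tissues, size=k, replace=False)
            expr[i, on] = rng.uniform(2.0, 50.0, k)
    expression = pd.DataFrame(
        expr, index=gene_ids[: design.n_family_genes], columns=list(design.tissues)
    ).round(3)

    # -- qPCR Ct table ------------------------------------------------------
    lo, hi = design.qpcr_log2fold_range
    log2_folds = rng.uniform(lo, hi, design.n_family_genes)
    qpcr_rows = []
    for rep in range(1, design.n_replicates + 1):
        for cond in ("control", "treatment"):
            qpcr_rows.append(
                {"gene": "UBI", "condition": cond, "replicate": rep,
                 "ct": round(20.0 + rng.normal(0, design.ct_noise_sd), 3)}
            )
    base_ct = rng.uniform(22.0, 30.0, design.n_family_genes)
    for i in range(design.n_family_genes):
        for rep in range(1, design.n_replicates + 1):
            for cond in ("control", "treatment"):
                mu = base_ct[i] - (log2_folds[i] if cond == "treatment" else 0.0)
                qpcr_rows.append(
                    {"gene": gene_ids[i], "condition": cond, "replicate": rep,
                     "ct": round(mu + rng.normal(0, design.ct_noise_sd), 3)}
                )
    qpcr = pd.DataFrame(qpcr_rows, columns=["gene", "condition", "replicate", "ct"])

    # -- ground truth -------------------------------------------------------
    truth_rows = []
    for i in range(n_total):
        family = i < design.n_family_genes
        row = {
            "gene_id": gene_ids[i],
            "role": "family" if family else "decoy",
            "true_group": groups[i] if family else "",
            "j_complete": family,
            "expression_pattern": patterns[i] if family else "",
            "log2_fold": round(float(log2_folds[i]), 4) if family else np.nan,
            "n_introns": len(gene_meta[i]["exons"]) - 1,
        }
        for m in motifs:
            row[f"motif_{m.name}"] = motif_counts.get(i, {}).get(m.name, 0)
        truth_rows.append(row)
    gene_truth = pd.DataFrame(truth_rows)
    tandem_rows = [
        {
            "gene_a": gene_ids[donor], "gene_b": gene_ids[partner],
            "true_identity": round(tandem_true_identity[partner], 4),
            "true_coverage": 1.0,
            "gap_bp": design.tandem_gap_bp,
        }
        for partner, donor in sorted(tandem_partner.items())
    ]
    tandem_truth = pd.DataFrame(
        tandem_rows, columns=["gene_a", "gene_b", "true_identity", "true_coverage", "gap_bp"]
    )

    return SimulatedBundle(
        genome=genome,
        gff3=gff3,
        proteome=proteome,
        domain_hits=domain_hits,
        promoters=promoters,
        expression=expression,
        qpcr=qpcr,
        gene_truth=gene_truth,
        tandem_truth=tandem_truth,
    )
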