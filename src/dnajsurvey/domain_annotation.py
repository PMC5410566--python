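"""J-domain, HPD-tripeptide and zinc-finger detection.

The J-domain is the ~70-residue co-chaperone domain whose invariant HPD
tripeptide stimulates Hsp70 ATPase activity; type-I family members
additionally carry CxxCxGxG zinc-finger repeats and a less conserved
C-terminal region. This module locates that evidence and condenses it into
one :class:`DomainArchitecture` per protein.

Domain hits may come from an external profile search (via
``formats_io.read_domain_table``) or from the bundled ungapped log-odds
scanner, which is deliberately simple: no insert/delete states, one score
per profile column per residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .formats_io import DomainHit, FormatError, SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

J_DOMAIN_ID = "PF00226"

#: HPD tripeptide — the J-domain hallmark
HPD = "HPD"
#: zinc-finger repeat of type-I DnaJ proteins
ZINC_FINGER = "CxxCxGxG"


@dataclass(frozen=True)
class MotifPattern:
    """A short protein motif where 'x' matches any residue."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        for ch in self.pattern:
            if ch != "x" and ch not in AMINO_ACIDS:
                raise ValueError(f"motif {self.name}: illegal character {ch!r}")


def find_pattern(seq: str, pattern: MotifPattern | str) -> list[tuple[int, int]]:
    """All non-overlapping left-to-right matches of a motif, 1-based inclusive."""
    pat = pattern.pattern if isinstance(pattern, MotifPattern) else pattern
    regex = re.compile(pat.replace("x", "."))
    return [(m.start() + 1, m.end()) for m in regex.finditer(seq)]


@dataclass
class ProfileModel:
    """Ungapped per-column log-odds profile for sliding-window scanning.

    ``scores[i]`` maps each of the 20 residues to a log2-odds score for
    column ``i``. Placements scoring at or above ``score_threshold`` are
    reported; the threshold default of 0 bits keeps the false-positive rate
    on random background far below 1% per 200 residues for profiles of this
    length (random windows score strongly negative).
    """

    name: str
    scores: np.ndarray  # shape (length, 20)
    score_threshold: float = 0.0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("scores must be (length, 20)")
        if self.scores.shape[0] < 1:
            raise ValueError("profile must have at least one column")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in self.scores.argmax(axis=1))

    @classmethod
    def from_consensus(
        cls,
        name: str,
        consensus: str,
        match_prob: float = 0.6,
        score_threshold: float = 0.0,
    ) -> "ProfileModel":
        """Build a profile emitting the consensus residue with ``match_prob``
        per column (remaining mass uniform), scored against a uniform
        background."""
        if not 0 < match_prob < 1:
            raise ValueError("match_prob must be in (0,1)")
        bg = 1.0 / 20.0
        other = (1.0 - match_prob) / 19.0
        scores = np.full((len(consensus), 20), np.log2(other / bg))
        for i, aa in enumerate(consensus):
            scores[i, _AA_INDEX[aa]] = np.log2(match_prob / bg)
        return cls(name=name, scores=scores, score_threshold=score_threshold)

    def window_score(self, window: str) -> float:
        idx = [_AA_INDEX.get(ch, -1) for ch in window]
        # unknown residues (X) score as the column minimum
        return float(
            sum(
                self.scores[i].min() if j < 0 else self.scores[i, j]
                for i, j in enumerate(idx)
            )
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# profile {self.name} threshold {self.score_threshold}\n")
            fh.write("#col\t" + "\t".join(AMINO_ACIDS) + "\n")
            for i, row in enumerate(self.scores, start=1):
                fh.write(f"{i}\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileModel":
        name, threshold = "profile", 0.0
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("# profile"):
                    parts = line.split()
                    name, threshold = parts[2], float(parts[4])
                    continue
                if not line or line.startswith("#"):
                    continue
                rows.append([float(v) for v in line.split("\t")[1:]])
        return cls(name=name, scores=np.array(rows), score_threshold=threshold)


# Bundled stand-in J-domain profile. The consensus is an idealised ~63-residue
# J-domain: helix-II/III core with the invariant HPD at its centre.
_J_CONSENSUS = (
    "DYYKILGVSKGASEDEIKKAYRKLALKY" + "HPD" + "KNPGDKEAEEKFKEIAEAYEVLSDPEKRELYD"
)


def default_j_profile(score_threshold: float = 0.0) -> ProfileModel:
    """The bundled J-domain profile used by the internal scanner and simulator."""
    return ProfileModel.from_consensus(
        J_DOMAIN_ID, _J_CONSENSUS, match_prob=0.6, score_threshold=score_threshold
    )


def scan_profile(seq: str, model: ProfileModel) -> list[DomainHit]:
    """Slide the profile over the sequence and report high-scoring placements.

    Overlapping placements are merged keeping the best-scoring one. The
    reported e-value is the naive bit-score transform 2^-score (adequate for
    thresholding synthetic data; calibrated statistics are out of scope).
    A sequence shorter than the profile yields no hits.
    """
    L = model.length
    if len(seq) < L:
        return []
    # vectorised scoring: unknown residues (X) take the column minimum
    idx = np.array([_AA_INDEX.get(ch, -1) for ch in seq])
    col_min = model.scores.min(axis=1)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    cols = np.arange(L)
    per_col = np.where(
        windows >= 0, model.scores[cols, windows.clip(min=0)], col_min[cols]
    )
    scores = per_col.sum(axis=1)
    placements = [(i + 1, i + L, float(s)) for i, s in enumerate(scores)]
    passing = [p for p in placements if p[2] >= model.score_threshold]
    passing.sort(key=lambda p: -p[2])
    kept: list[tuple[int, int, float]] = []
    for s, e, sc in passing:
        if all(e < ks or s > ke for ks, ke, _ in kept):
            kept.append((s, e, sc))
    kept.sort()
    return [
        DomainHit(
            protein_id="",
            domain_id=model.name,
            ali_start=s,
            ali_end=e,
            profile_cov=1.0,
            e_value=max(float(2.0 ** (-sc)), 1e-300),
        )
        for s, e, sc in kept
    ]


@dataclass(frozen=True)
class ArchitectureConfig:
    """Thresholds governing what counts as a complete architecture.

    e_threshold: profile-search e-value cut-off for accepting a J hit.
    cov_complete: minimum fraction of the J profile matched for the domain
        to count as complete (truncated hits fall below it).
    zf_min_repeats: CxxCxGxG repeats needed to call a zinc-finger domain
        (type-I proteins carry a repeat pair).
    cterm_min: residues required downstream of the last domain to call a
        distinct C-terminal region.
    """

    e_threshold: float = 1e-5
    cov_complete: float = 0.8
    zf_min_repeats: int = 2
    cterm_min: int = 40


@dataclass(frozen=True)
class DomainArchitecture:
    """Condensed per-protein domain evidence."""

    protein_id: str
    j_domains: tuple[tuple[int, int], ...]
    has_hpd: bool
    zf_repeats: int
    has_zinc_finger: bool
    has_cterm: bool
    j_complete: bool

    def __post_init__(self) -> None:
        if self.has_hpd and not self.j_domains:
            raise ValueError(f"{self.protein_id}: has_hpd requires a J-domain")
        if self.zf_repeats < 0:
            raise ValueError(f"{self.protein_id}: negative zinc-finger count")


def assemble_architecture(
    protein: SequenceRecord,
    hits: list[DomainHit],
    config: ArchitectureConfig = ArchitectureConfig(),
) -> DomainArchitecture:
    """Combine motif scans and J-domain hits into one architecture record.

    Only J-domain hits below the e-value threshold are retained; the domain
    is complete when at least one retained hit covers ``cov_complete`` of the
    profile. HPD counts only when it lies inside a retained J span.
    """
    n = len(protein.residues)
    j_spans: list[tuple[int, int]] = []
    j_complete = False
    for h in hits:
        if h.protein_id and h.protein_id != protein.id:
            raise ValueError(f"hit for {h.protein_id} applied to {protein.id}")
        if h.ali_end > n:
            raise ValueError(
                f"{protein.id}: hit end {h.ali_end} beyond protein length {n}"
            )
        if h.domain_id == J_DOMAIN_ID and h.e_value < config.e_threshold:
            j_spans.append((h.ali_start, h.ali_end))
            if h.profile_cov >= config.cov_complete:
                j_complete = True
    j_spans.sort()

    hpd_sites = find_pattern(protein.residues, HPD)
    has_hpd = any(
        s >= js and e <= je for s, e in hpd_sites for js, je in j_spans
    )
    zf_repeats = len(find_pattern(protein.residues, ZINC_FINGER))
    max_end = max((je for _, je in j_spans), default=0)
    has_cterm = bool(j_spans) and (n - max_end) >= config.cterm_min
    return DomainArchitecture(
        protein_id=protein.id,
        j_domains=tuple(j_spans),
        has_hpd=has_hpd,
        zf_repeats=zf_repeats,
        has_zinc_finger=zf_repeats >= config.zf_min_repeats,
        has_cterm=has_cterm,
        j_complete=j_complete,
    )
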