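"""Gene-family identification by position-specific scoring profiles.

The family scan follows the iterative species-specific profile strategy
used for large plant families such as the UDP-glycosyltransferases: a seed
alignment of the conserved domain is turned into a log-odds profile, each
proteome is scanned, high-confidence hits are realigned and rebuilt into a
species-specific profile, and the final profile defines the family set.

The scorer is a gapless position-specific score matrix (PSSM), not a full
profile HMM: no insert/delete states and no E-value calibration. Scores are
bits (log2 odds against a background amino-acid distribution); thresholds
are therefore bit scores. Results from an external HMMER run can be
ingested instead through ``read_domtblout``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}

DEFAULT_INCLUSION_BITS = 15.0
DEFAULT_CONFIDENT_BITS = 25.0


@dataclass
class ProfileModel:
    """Per-position log2-odds scores over the 20 amino acids."""

    columns: np.ndarray           # (length, 20) bit scores
    background: np.ndarray       # (20,) frequencies summing to 1
    score_threshold: float = DEFAULT_INCLUSION_BITS

    def __post_init__(self):
        self.columns = np.asarray(self.columns, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    @property
    def length(self) -> int:
        return self.columns.shape[0]

    def consensus(self) -> str:
        if self.length == 0:
            return ""
        return "".join(AA_ALPHABET[i] for i in self.columns.argmax(axis=1))


def uniform_background() -> np.ndarray:
    return np.full(20, 1.0 / 20.0)


def build_profile(
    alignment: list[str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
) -> ProfileModel:
    """Build a log-odds profile from a gapped protein alignment.

    Columns with more than ``max_gap_fraction`` gaps are dropped (the
    trimming step). Column scores are log2((count + pc*bg) / (n + pc) / bg)
    where n counts the non-gap residues of the column.
    """
    if len(alignment) < 2:
        raise ValueError("profile needs at least 2 sequences")
    L = len(alignment[0])
    if any(len(s) != L for s in alignment):
        raise ValueError("ragged alignment")
    bg = uniform_background() if background is None else np.asarray(background, float)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    cols = []
    for j in range(L):
        column = [s[j].upper() for s in alignment]
        residues = [c for c in column if c in AA_INDEX]
        gap_fraction = 1.0 - len(residues) / len(column)
        if gap_fraction > max_gap_fraction:
            continue
        counts = np.zeros(20)
        for c in residues:
            counts[AA_INDEX[c]] += 1
        n = len(residues)
        freqs = (counts + pseudocount * bg) / (n + pseudocount)
        cols.append(np.log2(freqs / bg))
    if not cols:
        raise ValueError("all columns gapped beyond threshold: empty profile")
    return ProfileModel(np.array(cols), bg)


def _window_scores(profile: ProfileModel, protein: str) -> np.ndarray:
    """Score of every alignment offset of the profile against the sequence.

    Offset o aligns profile column i with sequence position o+i; columns
    falling off either sequence end score 0. Unknown characters score 0.
    """
    L = profile.length
    n = len(protein)
    if L == 0 or n == 0:
        return np.zeros(1)
    idx = np.array([AA_INDEX.get(c, -1) for c in protein.upper()])
    known = idx >= 0
    if not known.all():
        logger.warning("non-amino-acid characters scored 0 in sequence scan")
    # per (column, position) score matrix, unknowns 0
    M = np.where(known[None, :], profile.columns[:, np.where(known, idx, 0)], 0.0)
    offsets = np.arange(-(L - 1), n)
    scores = np.zeros(len(offsets))
    for k, o in enumerate(offsets):
        i0 = max(0, -o)
        i1 = min(L, n - o)
        if i1 <= i0:
            continue
        cols = np.arange(i0, i1)
        scores[k] = M[cols, o + cols].sum()
    return scores


def score_sequence(profile: ProfileModel, protein: str) -> float:
    """Best gapless-window bit score of the profile against a protein."""
    if len(protein) < 1:
        raise ValueError("empty protein")
    if profile.length == 0:
        return 0.0
    return float(_window_scores(profile, protein).max())


def best_window_offset(profile: ProfileModel, protein: str) -> int:
    """Offset of the best-scoring window (profile column 0 at this position)."""
    scores = _window_scores(profile, protein)
    return int(scores.argmax()) - (profile.length - 1)


def extract_window(profile: ProfileModel, protein: str) -> str:
    """Residues of the best window, padded with gaps at sequence ends."""
    o = best_window_offset(profile, protein)
    out = []
    for i in range(profile.length):
        p = o + i
        out.append(protein[p] if 0 <= p < len(protein) else "-")
    return "".join(out)


def iterative_scan(
    seed_profile: ProfileModel,
    proteome: dict[str, str],
    rounds: int = 2,
    inclusion_threshold: float = DEFAULT_INCLUSION_BITS,
    confident_threshold: float = DEFAULT_CONFIDENT_BITS,
    pseudocount: float = 1.0,
) -> tuple[dict[str, float], ProfileModel]:
    """Iteratively refine a species-specific profile and report family hits.

    Round 1 scans with the seed profile; sequences at or above the
    confident threshold are realigned (gapless, anchored at their best
    window) and rebuilt into a species-specific profile used for the next
    round. The final round reports every sequence at or above the inclusion
    threshold with its bit score.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if confident_threshold < inclusion_threshold:
        raise ValueError("confident_threshold must be >= inclusion_threshold")
    profile = seed_profile
    scores = {gid: score_sequence(profile, seq) for gid, seq in sorted(proteome.items())}
    if not any(s >= inclusion_threshold for s in scores.values()):
        logger.warning("no hits above inclusion threshold in round 1; no rebuild")
        return {}, profile
    for _ in range(rounds - 1):
        confident = [gid for gid, s in scores.items() if s >= confident_threshold]
        if len(confident) < 2:
            logger.warning("fewer than 2 confident hits; keeping current profile")
            break
        realigned = [extract_window(profile, proteome[gid]) for gid in confident]
        profile = build_profile(realigned, pseudocount=pseudocount,
                                background=seed_profile.background)
        scores = {gid: score_sequence(profile, seq)
                  for gid, seq in sorted(proteome.items())}
    hits = {gid: s for gid, s in scores.items() if s >= inclusion_threshold}
    return hits, profile


@dataclass(frozen=True)
class SubfamilyReference:
    label: str
    sequences: tuple[str, ...]


_ALIGNER = None


def _aligner():
    global _ALIGNER
    if _ALIGNER is None:
        from Bio.Align import PairwiseAligner, substitution_matrices
        a = PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11
        a.extend_gap_score = -1
        _ALIGNER = a
    return _ALIGNER


def global_identity(a: str, b: str) -> float:
    """Identity of the best global alignment: identities / alignment columns."""
    aligner = _aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def assign_subfamily(
    protein: str,
    references: list[SubfamilyReference],
    min_identity: float = 0.4,
) -> str:
    """Label of the most similar reference, or "species-specific".

    The query is globally aligned against every reference sequence; the
    label of the best identity wins if it reaches ``min_identity``. Ties go
    to the lexicographically first label (logged).
    """
    if not protein:
        raise ValueError("empty protein")
    if not references:
        raise ValueError("empty reference set")
    best: tuple[float, str] | None = None
    tied = False
    for ref in sorted(references, key=lambda r: r.label):
        ident = max(global_identity(protein, s) for s in ref.sequences)
        if best is None or ident > best[0] + 1e-12:
            best = (ident, ref.label)
            tied = False
        elif abs(ident - best[0]) <= 1e-12 and ref.label != best[1]:
            tied = True
    assert best is not None
    if tied:
        logger.info("subfamily tie broken lexicographically: %s", best[1])
    return best[1] if best[0] >= min_identity else "species-specific"


def read_domtblout(path) -> dict[str, float]:
    """Best per-sequence bit scores from a HMMER domtblout file."""
    scores: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            if len(fields) < 8:
                raise ValueError("malformed domtblout line")
            gid, bits = fields[0], float(fields[7])
            scores[gid] = max(scores.get(gid, float("-inf")), bits)
    return scores


def apply_keep_list(hits: dict[str, float], keep_list_path) -> dict[str, float]:
    """Optional external validation filter: retain only whitelisted ids."""
    with open(keep_list_path) as fh:
        keep = {line.strip() for line in fh if line.strip()}
    return {gid: s for gid, s in hits.items() if gid in keep}
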