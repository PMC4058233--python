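"""Translated homology search with BLAST-style filtering.

Emulates a protein-query versus nucleotide-subject (TBLASTN-style) search:
each subject is translated in all six reading frames, the protein query is
aligned against every frame with an affine-gap Smith-Waterman aligner, and
the best-scoring frame per query-subject pair is kept. Hits are filtered on
three criteria, all strict inequalities:

* E-value < ``evalue_max`` (default 1.0e-6),
* percent identity > ``identity_min_pct`` (default 50),
* query coverage > ``query_cov_min_pct`` (default 80, computed on the
  protein query).

E-values follow the Karlin-Altschul form ``E = K * m * n * exp(-lambda * S)``
with gapped BLOSUM62 constants by default. The module also reads and writes
BLAST tabular (outfmt 6) files so precomputed hits from a real TBLASTN run
can be substituted for the built-in aligner.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

#: Score of a translated stop codon against any residue. Local alignments
#: never extend through a stop, mirroring TBLASTN behaviour.
STOP_SCORE = -10000.0

#: The 12 standard BLAST outfmt 6 columns, in file order.
BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

#: Columns of the in-memory hit table: outfmt 6 plus subject frame and
#: query coverage.
HIT_COLUMNS = BLAST6_COLUMNS + ["frame", "qcovpct"]

_NT_ALPHABET = frozenset("ACGTN")

# Standard genetic code; stop codons map to '*', anything unresolvable
# (e.g. containing N) to 'X'.
_TABLE1 = unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_TABLE1.forward_table)
for _stop in _TABLE1.stop_codons:
    _CODON_TO_AA[_stop] = "*"


@dataclass(frozen=True)
class HomologyThresholds:
    """Hit acceptance criteria; every comparison is a strict inequality."""

    evalue_max: float = 1.0e-6
    identity_min_pct: float = 50.0
    query_cov_min_pct: float = 80.0

    def __post_init__(self) -> None:
        if not self.evalue_max > 0:
            raise ValueError("evalue_max must be positive")
        if not 0 <= self.identity_min_pct <= 100:
            raise ValueError("identity_min_pct must be in [0, 100]")
        if not 0 < self.query_cov_min_pct <= 100:
            raise ValueError("query_cov_min_pct must be in (0, 100]")


@dataclass(frozen=True)
class AlignerConfig:
    """Scoring parameters for the built-in translated aligner.

    ``gap_open``/``gap_extend`` follow the BLAST convention: a gap of
    length L costs ``gap_open + gap_extend * L``. ``lambda_`` and ``k``
    are the Karlin-Altschul statistical parameters for the chosen scoring
    scheme (defaults are the standard gapped BLOSUM62/11/1 constants).
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lambda_: float = 0.267
    k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lambda_ <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")


@dataclass(frozen=True)
class LocalAlignment:
    """A local alignment summary; coordinates are 1-based inclusive."""

    score: float
    n_identical: int
    aln_len: int
    mismatch: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.n_identical / self.aln_len


def translate_six_frames(nt_seq: str) -> dict[int, str]:
    """Translate a nucleotide sequence in all six reading frames.

    Frames +1..+3 read the forward strand starting at offsets 0..2;
    frames -1..-3 read the reverse complement likewise. Trailing partial
    codons are dropped; codons containing N translate to ``X`` and stop
    codons to ``*``.
    """
    seq = nt_seq.upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    bad = set(seq) - _NT_ALPHABET
    if bad:
        raise ValueError(f"non-IUPAC nucleotide characters: {sorted(bad)}")
    rc = reverse_complement(seq)
    frames: dict[int, str] = {}
    for off in (0, 1, 2):
        frames[off + 1] = _translate(seq[off:])
        frames[-(off + 1)] = _translate(rc[off:])
    return frames


def _translate(seq: str) -> str:
    return "".join(
        _CODON_TO_AA.get(seq[i:i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


def make_aligner(config: AlignerConfig | None = None) -> PairwiseAligner:
    """Build a local affine-gap aligner with stop-breaking scores."""
    config = config or AlignerConfig()
    matrix = substitution_matrices.load(config.matrix)
    if "*" in matrix.alphabet:
        for ch in matrix.alphabet:
            matrix[ch, "*"] = STOP_SCORE
            matrix["*", ch] = STOP_SCORE
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # Biopython charges open_gap_score for the first gap position, so the
    # BLAST cost open + extend*L maps onto open+extend / extend.
    aligner.open_gap_score = -(config.gap_open + config.gap_extend)
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def local_align(
    query_aa: str,
    subject_aa: str,
    config: AlignerConfig | None = None,
    aligner: PairwiseAligner | None = None,
) -> LocalAlignment | None:
    """Optimal Smith-Waterman local alignment of two protein sequences.

    Returns ``None`` when no alignment scores above zero (e.g. all
    substitution scores negative). Ties between co-optimal alignments are
    broken deterministically by the aligner's fixed traceback order.
    """
    if not query_aa or not subject_aa:
        raise ValueError("empty sequence")
    if aligner is None:
        aligner = make_aligner(config)
    score = aligner.score(query_aa, subject_aa)
    if score <= 0:
        return None
    aln = aligner.align(query_aa, subject_aa)[0]
    q_blocks, s_blocks = (b.tolist() for b in aln.aligned)
    matches = 0
    aligned_cols = 0
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        aligned_cols += qe - qs
        matches += sum(
            1 for a, b in zip(query_aa[qs:qe], subject_aa[ss:se]) if a == b
        )
    gap_cols = 0
    gap_opens = 0
    for (q_prev, s_prev), (q_next, s_next) in zip(
        zip(q_blocks, s_blocks), zip(q_blocks[1:], s_blocks[1:])
    ):
        dq = q_next[0] - q_prev[1]
        ds = s_next[0] - s_prev[1]
        gap_cols += dq + ds
        gap_opens += (dq > 0) + (ds > 0)
    return LocalAlignment(
        score=float(score),
        n_identical=matches,
        aln_len=aligned_cols + gap_cols,
        mismatch=aligned_cols - matches,
        gap_opens=gap_opens,
        q_start=q_blocks[0][0] + 1,
        q_end=q_blocks[-1][1],
        s_start=s_blocks[0][0] + 1,
        s_end=s_blocks[-1][1],
    )


def estimate_evalue(
    score: float,
    query_len: int,
    db_len: int,
    lambda_: float = 0.267,
    k: float = 0.041,
) -> float:
    """Karlin-Altschul expected hit count ``E = K*m*n*exp(-lambda*S)``."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence lengths must be positive")
    if lambda_ <= 0 or k <= 0:
        raise ValueError("lambda and K must be positive")
    if score < 0:
        raise ValueError("score must be non-negative")
    return k * query_len * db_len * math.exp(-lambda_ * score)


def bit_score(score: float, lambda_: float = 0.267, k: float = 0.041) -> float:
    """Normalised (bit) score ``S' = (lambda*S - ln K) / ln 2``."""
    return (lambda_ * score - math.log(k)) / math.log(2)


def _frame_to_nt_coords(
    aa_start: int, aa_end: int, frame: int, subject_len: int
) -> tuple[int, int]:
    """Map 1-based residue coords on a frame translation to 1-based
    nucleotide coords on the forward strand of the subject.

    Minus frames follow the BLAST convention ``s_start > s_end``.
    """
    off = abs(frame)
    nt_start = 3 * (aa_start - 1) + off
    nt_end = 3 * (aa_end - 1) + off + 2
    if frame > 0:
        return nt_start, nt_end
    return subject_len - nt_start + 1, subject_len - nt_end + 1


def search_homologs(
    queries: Mapping[str, str],
    subjects: Mapping[str, str],
    thresholds: HomologyThresholds | None = None,
    config: AlignerConfig | None = None,
) -> pd.DataFrame:
    """Search every protein query against every nucleotide subject.

    For each pair, the query is aligned against all six frame translations
    and the best-scoring frame wins (ties to the first frame in the order
    +1, +2, +3, -1, -2, -3). A row is emitted only when the hit passes all
    three thresholds. The search database size for E-values is the total
    nucleotide length of ``subjects``.

    Returns a hit table with :data:`HIT_COLUMNS`.
    """
    if not queries or not subjects:
        raise ValueError("queries and subjects must be non-empty")
    thresholds = thresholds or HomologyThresholds()
    config = config or AlignerConfig()
    aligner = make_aligner(config)
    db_len = sum(len(s) for s in subjects.values())
    frame_cache = {
        sid: translate_six_frames(nt) for sid, nt in subjects.items()
    }
    frame_order = (1, 2, 3, -1, -2, -3)
    rows = []
    for qid, q_aa in queries.items():
        m = len(q_aa)
        for sid, nt in subjects.items():
            frames = frame_cache[sid]
            best_frame, best_score = 0, 0.0
            for f in frame_order:
                aa = frames[f]
                if len(aa) == 0:
                    continue
                sc = aligner.score(q_aa, aa)
                if sc > best_score:
                    best_frame, best_score = f, sc
            if best_frame == 0:
                continue
            evalue = estimate_evalue(
                best_score, m, db_len, config.lambda_, config.k
            )
            if not evalue < thresholds.evalue_max:
                continue
            aln = local_align(
                q_aa, frames[best_frame], aligner=aligner
            )
            qcov = 100.0 * (aln.q_end - aln.q_start + 1) / m
            if not (
                aln.identity_pct > thresholds.identity_min_pct
                and qcov > thresholds.query_cov_min_pct
            ):
                continue
            s_start, s_end = _frame_to_nt_coords(
                aln.s_start, aln.s_end, best_frame, len(nt)
            )
            rows.append(
                (
                    qid, sid, round(aln.identity_pct, 2), aln.aln_len,
                    aln.mismatch, aln.gap_opens, aln.q_start, aln.q_end,
                    s_start, s_end, evalue,
                    round(bit_score(best_score, config.lambda_, config.k), 1),
                    best_frame, round(qcov, 2),
                )
            )
    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    logger.info(
        "homology search: %d queries x %d subjects -> %d hits",
        len(queries), len(subjects), len(hits),
    )
    return hits


def filter_hits(
    hits: pd.DataFrame, thresholds: HomologyThresholds | None = None
) -> pd.DataFrame:
    """Keep hits passing all three criteria (strict inequalities).

    Row order is preserved; the result is always a subset of the input,
    and the operation is idempotent.
    """
    thresholds = thresholds or HomologyThresholds()
    required = ("pident", "qcovpct", "evalue")
    for col in required:
        if col not in hits.columns:
            raise ValueError(f"hit table lacks required column '{col}'")
    for col in required:
        na = hits[col].isna()
        if na.any():
            idx = hits.index[na][0]
            raise ValueError(f"hit row {idx} has missing '{col}'")
    if hits.empty:
        return hits.copy()
    mask = (
        (hits["evalue"] < thresholds.evalue_max)
        & (hits["pident"] > thresholds.identity_min_pct)
        & (hits["qcovpct"] > thresholds.query_cov_min_pct)
    )
    return hits[mask].copy()


def _infer_frame(sstart: int, send: int, subject_len: int | None) -> int:
    if subject_len is None:
        return 1 if sstart <= send else -1
    if sstart <= send:
        return (sstart - 1) % 3 + 1
    rc_pos = subject_len - sstart + 1
    return -((rc_pos - 1) % 3 + 1)


def read_blast6(
    path,
    query_lengths: Mapping[str, int],
    subject_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Read a BLAST outfmt 6 TSV into the internal hit-table layout.

    ``query_lengths`` (protein residues) is needed to compute query
    coverage, which outfmt 6 does not carry. Frames are recovered from
    subject coordinates when ``subject_lengths`` is given; otherwise only
    the strand sign is recorded (+1/-1).
    """
    df = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS)
    missing = sorted(set(df["qseqid"]) - set(query_lengths))
    if missing:
        raise ValueError(f"no query length for ids: {missing[:5]}")
    qlen = df["qseqid"].map(query_lengths)
    df["frame"] = [
        _infer_frame(
            ss, se,
            None if subject_lengths is None else subject_lengths.get(sid),
        )
        for sid, ss, se in zip(df["sseqid"], df["sstart"], df["send"])
    ]
    df["qcovpct"] = (
        100.0 * (df["qend"] - df["qstart"] + 1) / qlen
    ).round(2)
    return df


def write_blast6(hits: pd.DataFrame, path) -> None:
    """Write the 12 standard outfmt 6 columns, tab-separated, no header."""
    hits[BLAST6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
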