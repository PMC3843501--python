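"""Spaced k-mer extraction, integer k-mer coding, and branch-and-bound
generation of similar-k-mer lists.

The central primitive of the prefilter is the *similar k-mer list*: for a
query k-mer x, the set of all k-mers y over the 20-letter amino-acid
alphabet whose substitution score sum(S(x_j, y_j)) reaches a threshold
S_min, together with those scores.  Lists are produced by a depth-first
branch-and-bound that extends prefixes position by position (or two
positions at a time using pre-sorted dimer lists) and prunes a prefix as
soon as its score falls below the position-wise minimum still compatible
with reaching S_min.  Because candidate extensions are visited in
descending score order, no complete k-mer below threshold is ever emitted.

All scores are integers in half-bit units (BLOSUM62 entries are half-bit
log-odds), so accumulation is exact; thresholds may be fractional (the
default 6-mer threshold is 4.3 half-bits per column).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import ALPHABET_SIZE, AMINO_ACIDS, WILDCARD, EncodedSequence

# Robinson & Robinson amino-acid background frequencies, in the code order
# A R N D C Q E G H I L K M F P S T W Y V (the standard BLAST background).
ROBINSON_BACKGROUND = np.array(
    [
        0.07805, 0.05129, 0.04487, 0.05364, 0.01925,
        0.04264, 0.06295, 0.07377, 0.02199, 0.05142,
        0.09019, 0.05744, 0.02243, 0.03856, 0.05203,
        0.07120, 0.05841, 0.01330, 0.03216, 0.06441,
    ]
)
ROBINSON_BACKGROUND /= ROBINSON_BACKGROUND.sum()


class ScoringModel:
    """A 21x21 integer substitution-score table in half-bits plus amino-acid
    background frequencies.

    The wildcard row/column (code 20) scores 0 against everything.  The
    table must be symmetric over the 20 amino-acid codes with row maxima on
    the diagonal (true for the BLOSUM series).
    """

    def __init__(self, matrix: np.ndarray, background: np.ndarray | None = None):
        matrix = np.asarray(matrix, dtype=np.int64)
        if matrix.shape != (ALPHABET_SIZE, ALPHABET_SIZE):
            raise ValueError(f"matrix must be {ALPHABET_SIZE}x{ALPHABET_SIZE}")
        aa = matrix[:20, :20]
        if not np.array_equal(aa, aa.T):
            raise ValueError("substitution scores must be symmetric")
        if not np.all(np.diag(aa) == aa.max(axis=1)):
            raise ValueError("diagonal entries must be row maxima")
        if background is None:
            background = ROBINSON_BACKGROUND
        background = np.asarray(background, dtype=float)
        if background.shape != (20,) or not np.isclose(background.sum(), 1.0):
            raise ValueError("background must be 20 probabilities summing to 1")
        self.matrix = matrix
        self.background = background
        self._dimer_cache: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    @classmethod
    def blosum62(cls) -> "ScoringModel":
        return _blosum62()

    @classmethod
    def from_ncbi_file(cls, path) -> "ScoringModel":
        """Load a substitution matrix from NCBI-format matrix text."""
        return cls(_expand_matrix(substitution_matrices.read(str(path))))

    def rows_for(self, codes: np.ndarray) -> np.ndarray:
        """Position-specific score rows for a sequence: shape (L, 21)."""
        return self.matrix[codes]

    def sorted_dimer_list(self, a: int, b: int) -> tuple[np.ndarray, np.ndarray]:
        """All 400 amino-acid dimers scored against query dimer (a, b),
        sorted by descending score.  Returns (dimer codes y1*21+y2, scores)."""
        key = (a, b)
        cached = self._dimer_cache.get(key)
        if cached is not None:
            return cached
        scores = (self.matrix[a, :20][:, None] + self.matrix[b, :20][None, :]).ravel()
        codes = (np.arange(20)[:, None] * ALPHABET_SIZE + np.arange(20)[None, :]).ravel()
        order = np.argsort(-scores, kind="stable")
        result = (codes[order], scores[order])
        self._dimer_cache[key] = result
        return result


def _expand_matrix(mat) -> np.ndarray:
    """Map a Biopython substitution matrix onto the 21-code table."""
    full = np.zeros((ALPHABET_SIZE, ALPHABET_SIZE), dtype=np.int64)
    alpha = mat.alphabet
    idx = {c: alpha.index(c) for c in AMINO_ACIDS}
    for i, x in enumerate(AMINO_ACIDS):
        for j, y in enumerate(AMINO_ACIDS):
            full[i, j] = int(mat[idx[x], idx[y]])
    return full


@lru_cache(maxsize=None)
def _blosum62() -> ScoringModel:
    return ScoringModel(_expand_matrix(substitution_matrices.load("BLOSUM62")))


#: Default spaced patterns (weight 6 / span 9 and weight 4 / span 5); both
#: begin and end with match positions, spreading matches to decorrelate
#: neighboring window scores.
DEFAULT_PATTERN_6 = "110101011"
DEFAULT_PATTERN_4 = "11011"

#: Default 6-mer list threshold: 4.3 half-bits per column.
DEFAULT_SMIN_PER_COLUMN_6 = 4.3


@dataclass(frozen=True)
class KmerSpec:
    """A spaced-seed pattern together with the similar-k-mer threshold.

    ``pattern`` is a '1'/'0' string whose '1' positions are the k match
    positions; ``s_min_total`` is the list threshold in half-bits summed
    over the k match positions.
    """

    pattern: str
    s_min_total: float

    def __post_init__(self):
        if set(self.pattern) - {"0", "1"} or not self.pattern:
            raise ValueError("pattern must be a non-empty string of '0'/'1'")
        if self.pattern[0] != "1" or self.pattern[-1] != "1":
            raise ValueError("pattern must begin and end with a match position")

    @property
    def k(self) -> int:
        return self.pattern.count("1")

    @property
    def span(self) -> int:
        return len(self.pattern)

    @property
    def offsets(self) -> np.ndarray:
        return np.flatnonzero(np.frombuffer(self.pattern.encode(), dtype=np.uint8) == ord("1"))

    @property
    def per_column_threshold(self) -> float:
        return self.s_min_total / self.k

    @classmethod
    def spaced_6mer(cls, s_min_per_column: float = DEFAULT_SMIN_PER_COLUMN_6) -> "KmerSpec":
        return cls(DEFAULT_PATTERN_6, s_min_per_column * 6)

    @classmethod
    def spaced_4mer(cls, s_min_total: float | None = None) -> "KmerSpec":
        if s_min_total is None:
            s_min_total = DEFAULT_SMIN_4MER
        return cls(DEFAULT_PATTERN_4, s_min_total)


def kmer_code(codes) -> int:
    """Integer code of a k-mer: sum_j x_j * 21**(k-1-j); bijective on [0, 21**k)."""
    code = 0
    for x in codes:
        if not 0 <= x <= WILDCARD:
            raise ValueError(f"residue code out of range: {x}")
        code = code * ALPHABET_SIZE + int(x)
    return code


def kmer_decode(code: int, k: int) -> tuple[int, ...]:
    """Inverse of :func:`kmer_code` for known k."""
    out = []
    for _ in range(k):
        out.append(code % ALPHABET_SIZE)
        code //= ALPHABET_SIZE
    return tuple(reversed(out))


def extract_spaced_kmers(seq: EncodedSequence, spec: KmerSpec) -> list[tuple[int, np.ndarray]]:
    """All wildcard-free spaced k-mers of a sequence.

    Returns (start position, array of k residue codes) for every window
    start p in [0, L - span]; windows whose match positions include the
    wildcard are omitted.
    """
    L = len(seq)
    span = spec.span
    if L < span:
        return []
    offs = spec.offsets
    starts = np.arange(L - span + 1)
    windows = seq.codes[starts[:, None] + offs[None, :]]
    keep = ~(windows == WILDCARD).any(axis=1)
    return [(int(p), windows[i]) for i, p in enumerate(starts) if keep[i]]


def position_min_scores(query_kmer, spec: KmerSpec, scoring: ScoringModel) -> np.ndarray:
    """Per-position minimum prefix scores still compatible with S_min.

    S_min,j = S_min - sum_{i>j} S(x_i, x_i): the highest score attainable
    by the remaining positions is the self score, so a prefix scoring below
    S_min,j can never reach S_min.  The last threshold equals S_min.
    """
    q = np.asarray(query_kmer)
    diag = scoring.matrix[q, q]
    suffix_max = np.concatenate([np.cumsum(diag[::-1])[::-1][1:], [0]])
    return spec.s_min_total - suffix_max


def _row_min_scores(rows: np.ndarray, s_min: float) -> np.ndarray:
    """Generalized position thresholds from per-position score rows."""
    best = rows[:, :20].max(axis=1)
    suffix_max = np.concatenate([np.cumsum(best[::-1])[::-1][1:], [0]])
    return s_min - suffix_max


@dataclass
class SimilarKmerList:
    """All k-mers scoring >= s_min against the query, with their scores.

    ``codes``/``scores`` are parallel arrays sorted by k-mer code.
    """

    query_code: int
    codes: np.ndarray
    scores: np.ndarray

    def __len__(self) -> int:
        return int(self.codes.shape[0])

    def as_dict(self) -> dict[int, int]:
        return dict(zip(self.codes.tolist(), self.scores.tolist()))


def _similar_from_rows_single(rows: np.ndarray, s_min: float, counter=None):
    """Single-letter branch-and-bound over per-position score rows."""
    k = rows.shape[0]
    smin_j = _row_min_scores(rows, s_min)
    orders = [np.argsort(-rows[j, :20], kind="stable") for j in range(k)]
    out_codes: list[int] = []
    out_scores: list[int] = []
    stack = [(0, 0, 0)]  # depth-first via explicit recursion

    def extend(j: int, code: int, score: float):
        row = rows[j]
        thr = smin_j[j]
        last = j == k - 1
        for a in orders[j]:
            s = score + row[a]
            if s < thr:
                break
            c = code * ALPHABET_SIZE + int(a)
            if last:
                out_codes.append(c)
                out_scores.append(int(s))
                if counter is not None:
                    counter["emitted"] += 1
            else:
                extend(j + 1, c, s)

    del stack
    extend(0, 0, 0.0)
    return out_codes, out_scores


def _similar_from_rows_dimer(rows: np.ndarray, s_min: float, counter=None,
                             dimer_lists=None):
    """Dimer-list branch-and-bound: append two positions per step, walking
    each pre-sorted 400-dimer list until the prefix falls below threshold."""
    k = rows.shape[0]
    smin_j = _row_min_scores(rows, s_min)
    steps = []  # (codes array, scores array, threshold after step)
    j = 0
    while j + 1 < k:
        if dimer_lists is not None:
            codes, scores = dimer_lists[j // 2]
        else:
            dscores = (rows[j, :20][:, None] + rows[j + 1, :20][None, :]).ravel()
            dcodes = (np.arange(20)[:, None] * ALPHABET_SIZE + np.arange(20)[None, :]).ravel()
            order = np.argsort(-dscores, kind="stable")
            codes, scores = dcodes[order], dscores[order]
        steps.append((codes.tolist(), scores.tolist(), smin_j[j + 1]))
        j += 2
    tail = None
    if j < k:  # odd k: final single position
        order = np.argsort(-rows[j, :20], kind="stable")
        tail = (order.tolist(), rows[j, :20][order].tolist(), smin_j[j])

    out_codes: list[int] = []
    out_scores: list[int] = []
    n_steps = len(steps)

    def extend(step: int, code: int, score: float):
        if step < n_steps:
            codes, scores, thr = steps[step]
            last = step == n_steps - 1 and tail is None
            base = code * (ALPHABET_SIZE * ALPHABET_SIZE)
            for c, s in zip(codes, scores):
                tot = score + s
                if tot < thr:
                    break
                if last:
                    out_codes.append(base + c)
                    out_scores.append(int(tot))
                    if counter is not None:
                        counter["emitted"] += 1
                else:
                    extend(step + 1, base + c, tot)
        else:  # final single letter
            letters, scores, thr = tail
            base = code * ALPHABET_SIZE
            for a, s in zip(letters, scores):
                tot = score + s
                if tot < thr:
                    break
                out_codes.append(base + a)
                out_scores.append(int(tot))
                if counter is not None:
                    counter["emitted"] += 1

    extend(0, 0, 0.0)
    return out_codes, out_scores


def similar_kmers_from_rows(
    query_code: int,
    rows: np.ndarray,
    s_min: float,
    method: str = "dimer",
    counter=None,
    dimer_lists=None,
) -> SimilarKmerList:
    """Similar-k-mer list for arbitrary per-position score rows (used both
    for plain sequences and for profile columns in iterative mode)."""
    if method == "dimer":
        codes, scores = _similar_from_rows_dimer(rows, s_min, counter, dimer_lists)
    elif method == "single":
        codes, scores = _similar_from_rows_single(rows, s_min, counter)
    else:
        raise ValueError(f"unknown method {method!r}")
    codes_arr = np.asarray(codes, dtype=np.int64)
    scores_arr = np.asarray(scores, dtype=np.int64)
    order = np.argsort(codes_arr, kind="stable")
    return SimilarKmerList(query_code, codes_arr[order], scores_arr[order])


def similar_kmers(
    query_kmer,
    spec: KmerSpec,
    scoring: ScoringModel,
    method: str = "dimer",
    counter=None,
) -> SimilarKmerList:
    """The set { y : sum_j S(x_j, y_j) >= S_min } with scores.

    Query k-mers containing the wildcard produce an empty list (the
    wildcard has no meaningful similarity score).
    """
    q = np.asarray(query_kmer, dtype=np.int64)
    if q.shape[0] != spec.k:
        raise ValueError("query k-mer length does not match spec weight")
    qcode = kmer_code(q)
    if (q == WILDCARD).any():
        empty = np.empty(0, dtype=np.int64)
        return SimilarKmerList(qcode, empty, empty.copy())
    rows = scoring.rows_for(q)
    dimer_lists = None
    if method == "dimer":
        dimer_lists = [
            scoring.sorted_dimer_list(int(q[j]), int(q[j + 1]))
            for j in range(0, spec.k - 1, 2)
        ]
    return similar_kmers_from_rows(qcode, rows, spec.s_min_total, method, counter, dimer_lists)


def count_similar_kmers(query_kmer, k: int, s_min: float, scoring: ScoringModel) -> int:
    """List length only, via the same pruning (cheaper than materializing)."""
    q = np.asarray(query_kmer, dtype=np.int64)
    rows = scoring.rows_for(q)
    smin_j = _row_min_scores(rows, s_min)
    sorted_rows = [np.sort(rows[j, :20])[::-1] for j in range(k)]

    def count(j: int, score: float) -> int:
        thr = smin_j[j]
        row = sorted_rows[j]
        n = 0
        if j == k - 1:
            for s in row:
                if score + s < thr:
                    break
                n += 1
            return n
        for s in row:
            if score + s < thr:
                break
            n += count(j + 1, score + s)
        return n

    return count(0, 0.0)


def sample_background_kmers(k: int, n: int, scoring: ScoringModel, seed: int) -> np.ndarray:
    """n query k-mers drawn i.i.d. from the background composition."""
    rng = np.random.default_rng(seed)
    return rng.choice(20, size=(n, k), p=scoring.background)


def calibrate_threshold(
    target_r: float,
    k: int,
    scoring: ScoringModel,
    sample: np.ndarray,
    seed: int = 0,
) -> float:
    """Integer half-bit threshold whose mean similar-list length over the
    sample is closest to ``target_r``.

    Walks the threshold down from the maximum attainable self score until
    the mean list length first reaches ``target_r`` (list length is
    monotone non-increasing in the threshold), then returns the bracket
    endpoint closest to the target.  Deterministic given the sample.
    """
    sample = np.asarray(sample)
    if sample.ndim != 2 or sample.shape[0] == 0 or sample.shape[1] != k:
        raise ValueError("sample must be a non-empty (n, k) array of residue codes")
    if target_r > 20.0**k:
        raise ValueError(f"target list length {target_r} exceeds 20^{k}")

    def mean_len(th: float) -> float:
        return float(
            np.mean([count_similar_kmers(q, k, th, scoring) for q in sample])
        )

    hi = int(max(scoring.matrix[q, q].sum() for q in sample))
    th = hi
    prev_mean = mean_len(th)
    if prev_mean >= target_r:
        return float(th)
    while True:
        th -= 1
        m = mean_len(th)
        if m >= target_r:
            # bracket [th, th+1]: mean(th) >= target_r > mean(th+1)
            return float(th if m - target_r <= target_r - prev_mean else th + 1)
        prev_mean = m
        if th < -int(abs(scoring.matrix).max()) * k:  # pragma: no cover
            raise RuntimeError("calibration failed to bracket the target")


#: Default 4-mer threshold, calibrated once with ``calibrate_threshold`` to a
#: mean similar-list length of about 200 over background-composition 4-mers
#: (2000 k-mers, seed 42; mean length 189 at this threshold); see
#: docs/methods.md.
DEFAULT_SMIN_4MER = 13.0
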