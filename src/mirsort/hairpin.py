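"""Hairpin folding and guide/star duplex signatures.

Folding uses the Nussinov maximum-base-pair dynamic program (Watson-Crick
plus G:U wobble, minimum loop of 3 unpaired nt) with a fully deterministic
traceback, so a fold can serve as a reproducible stand-in for the duplex
topology of a pre-miRNA.  A pre-computed pairing map may be attached to a
:class:`Hairpin` to override folding entirely.

Duplex-level statistics implemented here: hybridized-nucleotide count,
per-position guide/star mismatch profiles, central-mismatch calls
(guide positions 10–12 by default), 5'-nucleotide signatures, and guide
length comparisons between sorting classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NoDuplexError, ValidationError
from .sequence import can_pair, clean_rna, is_wc, is_wobble

MIN_LOOP = 3

# Pair classes for guide positions in a duplex.
WC = "WC"
GU = "GU"
MISMATCH = "mismatch"
UNCOVERED = "uncovered"

UNPAIRED = -1


def fold_hairpin(seq: str, *, min_loop: int = MIN_LOOP) -> np.ndarray:
    """Maximum base-pair secondary structure of an RNA sequence.

    Returns an integer array ``fold`` with ``fold[i]`` the 0-based partner
    of position ``i``, or ``-1`` if unpaired.  The structure is non-crossing,
    uses AU/GC/GU pairs, keeps at least ``min_loop`` unpaired nt inside any
    pair, and ties are resolved deterministically (pairing of the interval
    ends preferred over bifurcation, then smaller split index).
    """
    s = clean_rna(seq)
    n = len(s)
    fold = np.full(n, UNPAIRED, dtype=np.int64)
    if n < min_loop + 2:
        return fold

    pairable = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            pairable[i, j] = can_pair(s[i], s[j])

    N = np.zeros((n, n), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = N[i + 1, j]
            v = N[i, j - 1]
            if v > best:
                best = v
            if pairable[i, j]:
                v = N[i + 1, j - 1] + 1
                if v > best:
                    best = v
            if j - i > 1:
                # bifurcation: split into [i,k] and [k+1,j]
                v = int((N[i, i + 1 : j] + N[i + 2 : j + 1, j]).max())
                if v > best:
                    best = v
            N[i, j] = best

    # deterministic traceback
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or N[i, j] == 0:
            continue
        if pairable[i, j] and N[i, j] == N[i + 1, j - 1] + 1:
            fold[i] = j
            fold[j] = i
            stack.append((i + 1, j - 1))
        elif N[i, j] == N[i + 1, j]:
            stack.append((i + 1, j))
        elif N[i, j] == N[i, j - 1]:
            stack.append((i, j - 1))
        else:
            for k in range(i + 1, j):
                if N[i, k] + N[k + 1, j] == N[i, j]:
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
    return fold


def parse_dot_bracket(structure: str) -> np.ndarray:
    """Partner array from a dot-bracket string (inverse of :func:`dot_bracket`)."""
    fold = np.full(len(structure), UNPAIRED, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValidationError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            fold[i] = j
            fold[j] = i
        elif c != ".":
            raise ValidationError(f"invalid dot-bracket character {c!r} at position {i}")
    if stack:
        raise ValidationError(f"unclosed '(' at position {stack[-1]}")
    return fold


def dot_bracket(fold: np.ndarray) -> str:
    out = []
    for i, p in enumerate(fold):
        if p == UNPAIRED:
            out.append(".")
        elif p > i:
            out.append("(")
        else:
            out.append(")")
    return "".join(out)


@dataclass
class Hairpin:
    """A pre-miRNA precursor with its fold and guide/star placement.

    Spans are 0-based half-open intervals on ``precursor_seq``; ``fold`` is
    a partner array as produced by :func:`fold_hairpin` (computed lazily if
    not supplied).  ``guide_arm`` says which precursor arm carries the guide.
    """

    id: str
    precursor_seq: str
    guide_span: tuple[int, int]
    star_span: tuple[int, int] | None = None
    guide_arm: str = "5p"  # {5p, 3p}
    fold: np.ndarray | None = None
    locus: tuple[str, int, int, str] | None = None  # (chrom, start, end, strand)

    def __post_init__(self) -> None:
        self.precursor_seq = clean_rna(self.precursor_seq, name=f"precursor {self.id}")
        n = len(self.precursor_seq)
        gs, ge = self.guide_span
        if not (0 <= gs < ge <= n):
            raise ValidationError(f"{self.id}: guide span {self.guide_span} outside precursor")
        if self.star_span is not None:
            ss, se = self.star_span
            if not (0 <= ss < se <= n):
                raise ValidationError(f"{self.id}: star span {self.star_span} outside precursor")
            if max(gs, ss) < min(ge, se):
                raise ValidationError(f"{self.id}: guide and star spans overlap")
        if self.guide_arm not in ("5p", "3p"):
            raise ValidationError(f"{self.id}: guide_arm must be 5p or 3p")

    @property
    def guide_seq(self) -> str:
        gs, ge = self.guide_span
        return self.precursor_seq[gs:ge]

    def get_fold(self) -> np.ndarray:
        if self.fold is None:
            self.fold = fold_hairpin(self.precursor_seq)
        return self.fold


@dataclass
class Duplex:
    """Guide/star pairing map; ``pairs[i]`` classifies guide position i+1.

    Guide positions are numbered 1..len(guide) from the guide 5' end.
    Classes: WC, GU (wobble, counted as hybridized), mismatch (a star base
    faces the guide position but cannot pair), uncovered (no star base
    faces it, e.g. the 2-nt 3' overhang).
    """

    guide_seq: str
    star_seq: str
    pairs: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.guide_seq):
            raise ValidationError("duplex classifies a wrong number of guide positions")

    def __len__(self) -> int:
        return len(self.guide_seq)


def extract_duplex(
    hairpin: Hairpin,
    guide_span: tuple[int, int] | None = None,
    star_span: tuple[int, int] | None = None,
    *,
    overhang: int = 2,
) -> Duplex:
    """Derive the guide/star duplex of a hairpin from its fold.

    When ``star_span`` is not given (e.g. no star reads were observed) it is
    inferred from the fold as the region pairing with the guide, extended at
    its 3' end by ``overhang`` nt so that the canonical Dicer 2-nt 3'
    overhangs are represented as uncovered rather than out-of-span.  When
    star reads define the span, pass it explicitly and the fold is only used
    for per-position pair classes.
    """
    seq = hairpin.precursor_seq
    fold = hairpin.get_fold()
    gs, ge = guide_span if guide_span is not None else hairpin.guide_span

    if star_span is None:
        star_span = hairpin.star_span
    if star_span is None:
        partners = [int(fold[i]) for i in range(gs, ge) if fold[i] != UNPAIRED]
        partners = [p for p in partners if p < gs or p >= ge]
        if not partners:
            raise NoDuplexError(f"{hairpin.id}: guide span pairs nowhere in the fold")
        lo, hi = min(partners), max(partners) + 1
        hi = min(hi + overhang, len(seq))  # star 3' end is its high coordinate
        star_span = (lo, hi)
    ss, se = star_span

    # anchors: guide positions paired into the star span
    anchors = [
        (i, int(fold[i]))
        for i in range(gs, ge)
        if fold[i] != UNPAIRED and ss <= fold[i] < se
    ]
    if not anchors:
        raise NoDuplexError(f"{hairpin.id}: guide span pairs nowhere within the star span")

    classes: list[str] = []
    anchor_pos = [a for a, _ in anchors]
    for i in range(gs, ge):
        p = int(fold[i])
        if fold[i] != UNPAIRED and ss <= p < se:
            a, b = seq[i], seq[p]
            classes.append(WC if is_wc(a, b) else GU if is_wobble(a, b) else MISMATCH)
            continue
        # unpaired (or paired outside the star): facing a star base, or uncovered?
        left = [a for a in anchor_pos if a < i]
        right = [a for a in anchor_pos if a > i]
        if left and right:
            classes.append(MISMATCH)
        else:
            a0 = max(left) if left else min(right)
            proj = int(fold[a0]) - (i - a0)  # antiparallel register
            classes.append(MISMATCH if ss <= proj < se else UNCOVERED)

    return Duplex(guide_seq=seq[gs:ge], star_seq=seq[ss:se], pairs=classes)


def _is_mismatch(cls: str, *, gu_is_mismatch: bool, uncovered_is_mismatch: bool) -> bool:
    if cls == MISMATCH:
        return True
    if cls == GU and gu_is_mismatch:
        return True
    if cls == UNCOVERED and uncovered_is_mismatch:
        return True
    return False


def hybridized_count(duplex: Duplex, *, gu_is_mismatch: bool = False) -> int:
    """Number of guide positions hybridized to the star (WC, plus G:U unless
    wobbles are configured to count as mismatches)."""
    ok = {WC} if gu_is_mismatch else {WC, GU}
    return sum(1 for c in duplex.pairs if c in ok)


def mismatch_profile(
    duplexes: Iterable[Duplex],
    *,
    gu_is_mismatch: bool = False,
    uncovered_is_mismatch: bool = False,
) -> pd.DataFrame:
    """Per-guide-position mismatch frequency across a set of duplexes.

    Frequency at position i = mismatching duplexes / duplexes whose star
    covers i.  Positions never covered get frequency NaN.  Index is the
    1-based guide position.
    """
    duplexes = list(duplexes)
    if not duplexes:
        raise ValidationError("mismatch_profile needs a non-empty duplex set")
    max_len = max(len(d) for d in duplexes)
    n_cov = np.zeros(max_len, dtype=int)
    n_mm = np.zeros(max_len, dtype=int)
    for d in duplexes:
        for idx, cls in enumerate(d.pairs):
            covered = cls != UNCOVERED or uncovered_is_mismatch
            if covered:
                n_cov[idx] += 1
                if _is_mismatch(
                    cls,
                    gu_is_mismatch=gu_is_mismatch,
                    uncovered_is_mismatch=uncovered_is_mismatch,
                ):
                    n_mm[idx] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_cov > 0, n_mm / np.maximum(n_cov, 1), np.nan)
    return pd.DataFrame(
        {"n_covered": n_cov, "n_mismatch": n_mm, "frequency": freq},
        index=pd.RangeIndex(1, max_len + 1, name="guide_position"),
    )


def has_central_mismatch(
    duplex: Duplex,
    region: tuple[int, int] = (10, 12),
    *,
    gu_is_mismatch: bool = False,
    uncovered_is_mismatch: bool = False,
) -> bool:
    """True iff at least one guide position in ``region`` (1-based, inclusive)
    is a mismatch.  ``region=(9, 11)`` reproduces the fly convention."""
    lo, hi = region
    if len(duplex) < hi:
        raise ValidationError(
            f"guide of {len(duplex)} nt is shorter than the central region end {hi}"
        )
    return any(
        _is_mismatch(
            duplex.pairs[p - 1],
            gu_is_mismatch=gu_is_mismatch,
            uncovered_is_mismatch=uncovered_is_mismatch,
        )
        for p in range(lo, hi + 1)
    )


def five_prime_signature(guides: Iterable[str]) -> tuple[pd.DataFrame, pd.Series]:
    """Position-wise nucleotide frequency matrix for 5'-aligned guides.

    Returns ``(matrix, first_nt)``: the matrix has one row per 1-based guide
    position and columns A/C/G/U summing to 1 over the sequences observed at
    that position; ``first_nt`` is row 1 (the 5'-terminal identity).
    """
    seqs = [clean_rna(g) for g in guides]
    if not seqs:
        raise ValidationError("five_prime_signature needs a non-empty guide set")
    max_len = max(len(s) for s in seqs)
    counts = pd.DataFrame(
        0,
        index=pd.RangeIndex(1, max_len + 1, name="position"),
        columns=list("ACGU"),
        dtype=float,
    )
    for s in seqs:
        for idx, base in enumerate(s):
            counts.loc[idx + 1, base] += 1
    totals = counts.sum(axis=1)
    matrix = counts.div(totals, axis=0)
    return matrix, matrix.iloc[0]


@dataclass
class LengthStats:
    means: dict[str, float]
    n: dict[str, int]
    compared: tuple[str, str] | None
    t: float | None
    p: float | None


def length_stats(
    groups: Mapping[str, Sequence],
    compare: tuple[str, str] = ("AGO1", "AGO2"),
) -> LengthStats:
    """Mean guide length per sorting class plus a two-sample Student t-test.

    ``groups`` maps a class label to guide sequences (or integer lengths).
    The t statistic compares the two classes named in ``compare``; if either
    has fewer than two members the statistic is omitted with a warning.
    """
    lengths = {
        k: [len(v) if isinstance(v, str) else int(v) for v in vals]
        for k, vals in groups.items()
    }
    means = {k: float(np.mean(v)) if v else float("nan") for k, v in lengths.items()}
    ns = {k: len(v) for k, v in lengths.items()}
    a, b = compare
    if ns.get(a, 0) < 2 or ns.get(b, 0) < 2:
        warnings.warn(
            f"length_stats: classes {compare} need >=2 members each; t-test omitted",
            stacklevel=2,
        )
        return LengthStats(means=means, n=ns, compared=None, t=None, p=None)
    t, p = stats.ttest_ind(lengths[a], lengths[b], equal_var=True)
    return LengthStats(means=means, n=ns, compared=compare, t=float(t), p=float(p))
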