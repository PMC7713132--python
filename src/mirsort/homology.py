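"""Plant-style target prediction and origin-from-target signature detection.

Target sites are scored with an Allen-type expectation penalty (perfect
complement 0, G:U wobble 0.5, mismatch 1.0, penalties in the seed region
weighted 1.5×; no gaps) and reported below a cutoff of 2.5.

An "origin from target" signature is sequence identity extending from a
predicted target site into the regions flanking the guide on its precursor:
the guide is extracted with 7 nt of stem-side and 6 nt of loop-side flank,
locally aligned (Smith-Waterman, affine gaps) against the reverse complement
of the target transcript, and a signature requires >=6 consecutive matched
columns inside a flank plus overlap of the alignment footprint with a
predicted site.  Significance comes from a permutation null: 50 lists with
the flank letters shuffled (guide fixed, composition preserved), re-counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import hairpin as hp
from .errors import ValidationError
from .sequence import clean_rna, is_wc, is_wobble, revcomp

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def _jit(func):
        return _njit(cache=False)(func)

except ImportError:  # pragma: no cover
    def _jit(func):
        return func


_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_CODE[c] for c in seq), dtype=np.int8, count=len(seq))


# ---------------------------------------------------------------------------
# Smith-Waterman, affine gaps
# ---------------------------------------------------------------------------

NEG_INF = -1e18


def _sw_fill_py(a, b, match, mismatch, gap_open, gap_extend):
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG_INF)
    F = np.full((n + 1, m + 1), NEG_INF)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] - gap_open
            e2 = E[i, j - 1] - gap_extend
            if e2 > e:
                e = e2
            E[i, j] = e
            f = H[i - 1, j] - gap_open
            f2 = F[i - 1, j] - gap_extend
            if f2 > f:
                f = f2
            F[i, j] = f
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


_sw_fill = _jit(_sw_fill_py)


@dataclass
class Alignment:
    """A local alignment; columns are (a_char, b_char) with '-' for gaps.
    Coordinates are 0-based half-open on the input sequences."""

    score: float
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    columns: list[tuple[str, str]] = field(default_factory=list)

    def column_score(self, match=5.0, mismatch=-4.0, gap_open=15.0, gap_extend=2.0) -> float:
        """Recompute the score from the traceback columns (consistency check)."""
        total, in_gap = 0.0, False
        for x, y in self.columns:
            if x == "-" or y == "-":
                total -= gap_extend if in_gap else gap_open
                in_gap = True
            else:
                total += match if x == y else mismatch
                in_gap = False
        return total


def smith_waterman(
    a: str,
    b: str,
    gap_open: float = 15.0,
    gap_extend: float = 2.0,
    match: float = 5.0,
    mismatch: float = -4.0,
) -> Alignment:
    """Optimal local alignment under affine gap costs.

    A gap of length g costs ``gap_open + (g-1) * gap_extend``.  Tie-breaking
    is deterministic: the best cell with the lowest end coordinates wins, and
    traceback prefers diagonal over up (gap in ``b``) over left.
    """
    sa = clean_rna(a, name="a")
    sb = clean_rna(b, name="b")
    if not sa or not sb:
        raise ValidationError("smith_waterman: sequences must be non-empty")
    ca, cb = _encode(sa), _encode(sb)
    H, E, F, best, bi, bj = _sw_fill(
        ca, cb, float(match), float(mismatch), float(gap_open), float(gap_extend)
    )
    if best <= 0.0:
        return Alignment(score=0.0, a_start=0, a_end=0, b_start=0, b_end=0, columns=[])

    cols: list[tuple[str, str]] = []
    i, j = int(bi), int(bj)
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0.0:
                break
            s = match if ca[i - 1] == cb[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                cols.append((sa[i - 1], sb[j - 1]))
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            cols.append((sa[i - 1], "-"))
            if F[i, j] == H[i - 1, j] - gap_open:
                state = "H"
            i -= 1
        else:  # E
            cols.append(("-", sb[j - 1]))
            if E[i, j] == H[i, j - 1] - gap_open:
                state = "H"
            j -= 1
    cols.reverse()
    return Alignment(
        score=float(best),
        a_start=i,
        a_end=int(bi),
        b_start=j,
        b_end=int(bj),
        columns=cols,
    )


# ---------------------------------------------------------------------------
# Expectation scoring / target prediction
# ---------------------------------------------------------------------------

SEED_RANGE = (2, 13)
SEED_FACTOR = 1.5
GU_PENALTY = 0.5
MISMATCH_PENALTY = 1.0


def expectation_score(
    guide: str,
    site_window: str,
    seed_range: tuple[int, int] = SEED_RANGE,
    seed_factor: float = SEED_FACTOR,
    gu_penalty: float = GU_PENALTY,
    mismatch_penalty: float = MISMATCH_PENALTY,
) -> float:
    """Complementarity penalty of a gap-free guide/site duplex.

    The guide (5'->3') pairs antiparallel with the site window (transcript
    5'->3'): guide position i faces window base L-i.  Lower is better; 0 is
    a perfect complement.
    """
    g = clean_rna(guide, name="guide")
    w = clean_rna(site_window, name="site window")
    if len(g) != len(w):
        raise ValidationError(
            f"guide ({len(g)} nt) and site window ({len(w)} nt) differ in length"
        )
    L = len(g)
    total = 0.0
    for i in range(1, L + 1):
        t = w[L - i]
        if is_wc(g[i - 1], t):
            pen = 0.0
        elif is_wobble(g[i - 1], t):
            pen = gu_penalty
        else:
            pen = mismatch_penalty
        if seed_range[0] <= i <= seed_range[1]:
            pen *= seed_factor
        total += pen
    return total


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    span: tuple[int, int]  # 0-based half-open on the transcript
    score: float

    def pairing_string(self, guide: str, transcript: str) -> str:
        """Per guide-position pairing ('|' WC, 'o' G:U, '.' mismatch)."""
        w = transcript[self.span[0] : self.span[1]]
        L = len(guide)
        out = []
        for i in range(1, L + 1):
            t = w[L - i]
            out.append("|" if is_wc(guide[i - 1], t) else "o" if is_wobble(guide[i - 1], t) else ".")
        return "".join(out)


def _penalty_matrix(
    guide: str, seed_range, seed_factor, gu_penalty, mismatch_penalty
) -> np.ndarray:
    """W[k, base] = penalty of window column k (facing guide position L-k)."""
    L = len(guide)
    W = np.empty((L, 4))
    for k in range(L):
        i = L - k  # 1-based guide position facing window column k
        gbase = guide[i - 1]
        for tbase, code in _CODE.items():
            if is_wc(gbase, tbase):
                pen = 0.0
            elif is_wobble(gbase, tbase):
                pen = gu_penalty
            else:
                pen = mismatch_penalty
            if seed_range[0] <= i <= seed_range[1]:
                pen *= seed_factor
            W[k, code] = pen
    return W


def predict_targets(
    guides: Mapping[str, str],
    transcripts: Mapping[str, str],
    cutoff: float = 2.5,
    seed_range: tuple[int, int] = SEED_RANGE,
    seed_factor: float = SEED_FACTOR,
    gu_penalty: float = GU_PENALTY,
    mismatch_penalty: float = MISMATCH_PENALTY,
) -> list[TargetSite]:
    """Slide each guide over each transcript (antisense) and report windows
    with expectation score <= cutoff, ordered by (miRNA, transcript, start)."""
    if not transcripts:
        raise ValidationError("predict_targets: empty transcript set")
    t_codes = {tid: _encode(clean_rna(s, name=tid)) for tid, s in transcripts.items()}
    sites: list[TargetSite] = []
    for mid in sorted(guides):
        g = clean_rna(guides[mid], name=mid)
        L = len(g)
        W = _penalty_matrix(g, seed_range, seed_factor, gu_penalty, mismatch_penalty)
        for tid in sorted(t_codes):
            codes = t_codes[tid]
            if len(codes) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(codes, L)
            scores = np.zeros(len(windows))
            for k in range(L):
                scores += W[k, windows[:, k]]
            for pos in np.nonzero(scores <= cutoff)[0]:
                sites.append(
                    TargetSite(
                        mirna_id=mid,
                        transcript_id=tid,
                        span=(int(pos), int(pos) + L),
                        score=float(scores[pos]),
                    )
                )
    return sites


def load_target_sites(path) -> list[TargetSite]:
    """Import externally predicted target sites (TSV: mirna_id,
    transcript_id, start, end, score; 0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    required = ["mirna_id", "transcript_id", "start", "end", "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: target table missing column(s) {missing}")
    return [
        TargetSite(
            mirna_id=str(r.mirna_id),
            transcript_id=str(r.transcript_id),
            span=(int(r.start), int(r.end)),
            score=float(r.score),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Extended guides and signatures
# ---------------------------------------------------------------------------

STEM_FLANK = 7
LOOP_FLANK = 6


@dataclass
class ExtendedGuide:
    """Guide plus precursor flanks: 7 nt from the stem side, 6 from the loop
    side (mirrored for a 3p-arm guide).  ``up_side`` names which flank sits
    5' of the guide; ``truncated`` flags flanks cut short by the precursor
    edge."""

    mirna_id: str
    seq: str
    up_len: int
    guide_len: int
    down_len: int
    up_side: str  # stem / loop
    truncated: tuple[bool, bool] = (False, False)

    @property
    def down_side(self) -> str:
        return "loop" if self.up_side == "stem" else "stem"

    def flank_range(self, side: str) -> tuple[int, int]:
        """Coordinates of a flank on the extended-guide sequence."""
        if side == self.up_side:
            return (0, self.up_len)
        return (self.up_len + self.guide_len, len(self.seq))

    @property
    def guide_seq(self) -> str:
        return self.seq[self.up_len : self.up_len + self.guide_len]


def extended_guide(
    hairpin: hp.Hairpin,
    stem_flank: int = STEM_FLANK,
    loop_flank: int = LOOP_FLANK,
) -> ExtendedGuide:
    """Extract the guide with its precursor flanks for the homology scan."""
    gs, ge = hairpin.guide_span
    n = len(hairpin.precursor_seq)
    if hairpin.guide_arm == "5p":
        up_want, down_want, up_side = stem_flank, loop_flank, "stem"
    else:
        up_want, down_want, up_side = loop_flank, stem_flank, "loop"
    up_lo = max(0, gs - up_want)
    down_hi = min(n, ge + down_want)
    return ExtendedGuide(
        mirna_id=hairpin.id,
        seq=hairpin.precursor_seq[up_lo:down_hi],
        up_len=gs - up_lo,
        guide_len=ge - gs,
        down_len=down_hi - ge,
        up_side=up_side,
        truncated=(gs - up_lo < up_want, down_hi - ge < down_want),
    )


@dataclass
class HomologySignature:
    mirna_id: str
    transcript_id: str
    run_length: int
    flank_side: str  # stem / loop
    overlaps_predicted_site: bool
    footprint: tuple[int, int]  # on the transcript
    alignment: Alignment


def _flank_runs(ext: ExtendedGuide, alignment: Alignment) -> dict[str, int]:
    """Flank-resident length of matched runs extending from the target site.

    Maximal runs of consecutive matched columns are scanned (gap or
    mismatch columns break a run).  A run qualifies only if it crosses the
    guide/flank boundary — homology detached from the site (e.g. re-matching
    after a gap) is not an extension of it — and contributes only its
    columns with extended-guide coordinates inside a flank.  Returns the
    best count per flank side."""
    guide_lo = ext.up_len
    guide_hi = ext.up_len + ext.guide_len
    ranges = {side: ext.flank_range(side) for side in ("stem", "loop")}
    best = {"stem": 0, "loop": 0}
    run_a: list[int] = []

    def _flush() -> None:
        if run_a and any(guide_lo <= a < guide_hi for a in run_a):
            for side, (lo, hi) in ranges.items():
                n = sum(1 for a in run_a if lo <= a < hi)
                best[side] = max(best[side], n)
        run_a.clear()

    a_pos = alignment.a_start
    for x, y in alignment.columns:
        if x != "-" and y != "-" and x == y:
            run_a.append(a_pos)
        else:
            _flush()
        if x != "-":
            a_pos += 1
    _flush()
    return best


def detect_signature(
    ext: ExtendedGuide,
    transcript_id: str,
    transcript_seq: str,
    sites: Sequence[TargetSite],
    min_run: int = 6,
    *,
    gap_open: float = 15.0,
    gap_extend: float = 2.0,
    match: float = 5.0,
    mismatch: float = -4.0,
) -> HomologySignature | None:
    """Scan one miRNA/transcript pair for an extended-homology signature.

    The extended guide is aligned against the reverse complement of the
    transcript so that target complementarity appears as alignment identity.
    A signature requires (i) the alignment footprint on the transcript to
    overlap one of the pair's predicted target sites and (ii) at least
    ``min_run`` consecutive matched columns inside a flank region.
    """
    if not sites:
        raise ValidationError(
            f"{ext.mirna_id}/{transcript_id}: no predicted site for this pair"
        )
    tseq = clean_rna(transcript_seq, name=transcript_id)
    aln = smith_waterman(
        ext.seq, revcomp(tseq),
        gap_open=gap_open, gap_extend=gap_extend, match=match, mismatch=mismatch,
    )
    if not aln.columns:
        return None
    T = len(tseq)
    footprint = (T - aln.b_end, T - aln.b_start)
    overlap = any(
        max(footprint[0], s.span[0]) < min(footprint[1], s.span[1]) for s in sites
    )
    if not overlap:
        return None
    runs = _flank_runs(ext, aln)
    side = max(runs, key=lambda s: runs[s])
    if runs[side] < min_run:
        return None
    return HomologySignature(
        mirna_id=ext.mirna_id,
        transcript_id=transcript_id,
        run_length=runs[side],
        flank_side=side,
        overlaps_predicted_site=True,
        footprint=footprint,
        alignment=aln,
    )


def count_signatures(
    ext_guides: Mapping[str, ExtendedGuide],
    transcripts: Mapping[str, str],
    sites: Iterable[TargetSite],
    min_run: int = 6,
    **align_kwargs,
) -> tuple[int, pd.DataFrame]:
    """Distinct miRNAs with at least one signature (a miRNA homologous to
    several targets counts once), plus the full per-pair evidence table."""
    pairs: dict[tuple[str, str], list[TargetSite]] = {}
    for s in sites:
        pairs.setdefault((s.mirna_id, s.transcript_id), []).append(s)
    rows = []
    hit_mirnas: set[str] = set()
    for (mid, tid) in sorted(pairs):
        if mid not in ext_guides or tid not in transcripts:
            continue
        sig = detect_signature(
            ext_guides[mid], tid, transcripts[tid], pairs[(mid, tid)],
            min_run=min_run, **align_kwargs,
        )
        if sig is not None:
            hit_mirnas.add(mid)
            rows.append(
                {
                    "mirna_id": mid,
                    "transcript_id": tid,
                    "run_length": sig.run_length,
                    "flank_side": sig.flank_side,
                    "score": sig.alignment.score,
                    "footprint_start": sig.footprint[0],
                    "footprint_end": sig.footprint[1],
                }
            )
    return len(hit_mirnas), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Shuffled-flank permutation null
# ---------------------------------------------------------------------------

@dataclass
class ShuffleNullResult:
    n_lists: int
    per_list_counts: list[int]
    mean: float
    se: float
    max: int
    observed: int
    rng_seed: int


def shuffle_flanks(
    ext: ExtendedGuide,
    rng: np.random.Generator,
    *,
    dinucleotide: bool = False,
    max_tries: int = 200,
) -> ExtendedGuide:
    """Permute the flank letters of an extended guide (guide untouched).

    Each flank is shuffled independently, preserving its nucleotide
    composition exactly; ``dinucleotide=True`` additionally requires the
    shuffled flank to preserve the dinucleotide multiset (rejection-sampled;
    falls back to the original flank when no alternative arrangement is
    found).
    """
    up = ext.seq[: ext.up_len]
    guide = ext.guide_seq
    down = ext.seq[ext.up_len + ext.guide_len :]

    def _shuf(s: str) -> str:
        if len(s) < 2:
            return s
        if not dinucleotide:
            return "".join(rng.permutation(list(s)))
        target = sorted(s[i : i + 2] for i in range(len(s) - 1))
        for _ in range(max_tries):
            cand = "".join(rng.permutation(list(s)))
            if sorted(cand[i : i + 2] for i in range(len(cand) - 1)) == target:
                return cand
        return s

    new_up, new_down = _shuf(up), _shuf(down)
    assert sorted(new_up) == sorted(up) and sorted(new_down) == sorted(down)
    return ExtendedGuide(
        mirna_id=ext.mirna_id,
        seq=new_up + guide + new_down,
        up_len=ext.up_len,
        guide_len=ext.guide_len,
        down_len=ext.down_len,
        up_side=ext.up_side,
        truncated=ext.truncated,
    )


def shuffle_null(
    ext_guides: Mapping[str, ExtendedGuide],
    transcripts: Mapping[str, str],
    sites: Iterable[TargetSite],
    n_lists: int = 50,
    seed: int = 0,
    min_run: int = 6,
    *,
    dinucleotide: bool = False,
    **align_kwargs,
) -> ShuffleNullResult:
    """Signature counts expected by chance: ``n_lists`` miRNA lists with
    shuffled guide flanks, each re-counted with the same detection rules."""
    sites = list(sites)
    observed, _ = count_signatures(
        ext_guides, transcripts, sites, min_run=min_run, **align_kwargs
    )
    rng = np.random.default_rng(seed)
    counts = []
    for _ in range(n_lists):
        shuffled = {
            mid: shuffle_flanks(ext, rng, dinucleotide=dinucleotide)
            for mid, ext in ext_guides.items()
        }
        c, _ = count_signatures(
            shuffled, transcripts, sites, min_run=min_run, **align_kwargs
        )
        counts.append(int(c))
    arr = np.array(counts, dtype=float)
    se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return ShuffleNullResult(
        n_lists=n_lists,
        per_list_counts=counts,
        mean=float(arr.mean()),
        se=se,
        max=int(arr.max()),
        observed=int(observed),
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# Repetitive-element origin flags
# ---------------------------------------------------------------------------

def re_origin_flags(
    precursor_families: Mapping[str, str | None],
    sites: Iterable[TargetSite],
    transcript_repeats: pd.DataFrame,
) -> pd.DataFrame:
    """Flag (miRNA, target) pairs whose target site overlaps a repeat of the
    same family as the repeat hosting the miRNA precursor.

    ``transcript_repeats`` is a GFF3-style table with transcript ids in
    ``seqid`` (1-based inclusive coordinates) and the repeat family in the
    ``attributes`` ``family=`` tag.
    """
    from .io import gff3_attr

    rows = []
    for s in sites:
        fam = precursor_families.get(s.mirna_id)
        if fam is None:
            continue
        for row in transcript_repeats.itertuples():
            if str(row.seqid) != s.transcript_id:
                continue
            if gff3_attr(row.attributes, "family") != fam:
                continue
            if max(s.span[0], row.start - 1) < min(s.span[1], row.end):
                rows.append(
                    {
                        "mirna_id": s.mirna_id,
                        "transcript_id": s.transcript_id,
                        "family": fam,
                        "site_start": s.span[0],
                        "site_end": s.span[1],
                    }
                )
                break
    return pd.DataFrame(rows)
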