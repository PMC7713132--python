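"""Synthetic AGO-IP small-RNA data with planted ground truth.

The generator emulates the experimental design this pipeline targets: ~21-23
nt guides excised from fold-back precursors with 2-nt 3' overhangs, imperfect
strand selection, 5'-end read heterogeneity, IP enrichment over a flat IgG
background, two biological replicates per pulldown per stage, four spike-in
miRNAs for knockdown normalization, and transcripts carrying inverted-
duplication homology to precursor loci.  Every stochastic step is driven by
a seeded :class:`numpy.random.Generator`, so outputs are bit-reproducible.

Planted-failure hairpins (used to validate the annotation filters) receive
deterministic read counts at their defining margins, so the planted failure
label is unambiguous rather than a coin-flip against count noise; bona-fide
hairpins get the full negative-binomial noise model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import hairpin as hp
from .errors import ConstructionError, NoDuplexError, ValidationError
from .io import (
    DEFAULT_SPIKEIN_IDS,
    N_SPIKEINS,
    ReadStack,
    STACK_COLUMNS,
    SmallRNALibrary,
)
from .sequence import can_pair, clean_rna, complement, pairing_partners, revcomp

# guide-length distributions per planted sorting class; means 22.2 / 21.0 /
# 21.5 nt, matching the reported class averages this pipeline should recover
GUIDE_LENGTH_PMF = {
    "AGO1": {21: 0.10, 22: 0.60, 23: 0.30},
    "AGO2": {20: 0.25, 21: 0.50, 22: 0.25},
    "none": {21: 0.50, 22: 0.50},
}

#: probability that a planted duplex carries >=1 central (10-12) mismatch,
#: per sorting class (26/40 for the miRNA-dedicated AGO, 11/60 for the other)
CENTRAL_MISMATCH_PROB = {"AGO1": 26 / 40, "AGO2": 11 / 60, "none": 0.30}

FAILURE_MODES = ("enrichment", "homogeneity", "ratio", "reads", "duplex")


@dataclass
class SimulationDesign:
    """Study conditions for the synthetic dataset."""

    n_hairpins: int = 100
    stages: tuple[str, ...] = ("planula", "primary_polyp", "adult")
    replicates: int = 2
    guide_length_range: tuple[int, int] = (20, 23)
    #: per-hairpin guide:star count ratio, drawn log-uniformly from this range
    strand_selection: tuple[float, float] = (4.0, 50.0)
    five_prime_homogeneity: float = 0.9
    igg_background_rpm: float = 2.0
    ip_depth: int = 2_000_000
    dispersion: float = 0.1  # negative-binomial: var = m + dispersion * m^2
    expression_rpm_range: tuple[float, float] = (150.0, 10_000.0)
    kd_effect: float = 0.5  # fold change in the KD of a miRNA's preferred AGO
    spikein_mean_counts: tuple[int, ...] = (2000, 2400, 1600, 2000)
    n_transcripts: int = 100
    transcript_length: int = 400
    frac_ago1: float = 0.4
    frac_ago2: float = 0.4  # remainder: no AGO preference
    frac_strong: float = 0.5  # fraction of preferring miRNAs in the >90% band
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_hairpins < 1:
            raise ValidationError("n_hairpins must be >= 1")
        if not (0.0 <= self.five_prime_homogeneity <= 1.0):
            raise ValidationError("five_prime_homogeneity must lie in [0, 1]")
        for name in ("frac_ago1", "frac_ago2", "frac_strong"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.frac_ago1 + self.frac_ago2 > 1.0:
            raise ValidationError("frac_ago1 + frac_ago2 must be <= 1")
        if self.ip_depth <= 0:
            raise ValidationError("ip_depth must be positive")
        if self.igg_background_rpm < 0 or self.dispersion < 0:
            raise ValidationError("rates must be >= 0")
        if len(self.spikein_mean_counts) != N_SPIKEINS:
            raise ValidationError(f"exactly {N_SPIKEINS} spike-in species are required")
        if any(c <= 0 for c in self.spikein_mean_counts):
            raise ValidationError("spike-in counts must be positive")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")


@dataclass
class HairpinTruth:
    hairpin_id: str
    guide_span: tuple[int, int]
    star_span: tuple[int, int]
    guide_arm: str
    class_label: str  # AGO1 / AGO2 / none
    preference_ago1: float
    central_mismatch: bool
    mismatch_positions: tuple[int, ...]
    expression_counts: float  # expected guide counts summed over both AGO IPs
    strand_ratio: float
    five_prime_homogeneity: float
    starless: bool = False
    planted_failure: str | None = None
    igg_counts: float | None = None  # override of the flat background
    deterministic_counts: bool = False


@dataclass
class TranscriptTruth:
    transcript_id: str
    mirna_id: str
    site_span: tuple[int, int]
    homology_run: int
    side: str | None  # stem / loop
    planted: bool


@dataclass
class GroundTruth:
    hairpins: dict[str, HairpinTruth] = field(default_factory=dict)
    transcripts: dict[str, TranscriptTruth] = field(default_factory=dict)
    kd_effects: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Hairpin construction
# ---------------------------------------------------------------------------

def make_hairpin(
    guide_seq: str,
    mismatch_positions: Sequence[int] = (),
    loop_len: int = 8,
    seed: int = 0,
    *,
    guide_arm: str = "5p",
    hairpin_id: str = "hp",
    pad_len: int = 10,
    verify: str | None = "duplex",
    use_planted_fold: bool = False,
) -> hp.Hairpin:
    """Build a precursor whose fold yields the requested guide/star duplex.

    The precursor is pad + 5'arm + loop + 3'arm + pad, with the two arms
    pairing antiparallel and 2-nt 3' overhangs on both duplex ends; a
    mismatch is planted at each requested 1-based guide position by
    replacing the facing star base with the guide base itself (purine-
    purine / pyrimidine-pyrimidine, never pairable).  The ``pad_len``-nt
    pads emulate precursor sequence beyond the Dicer-excised duplex (the
    stem-side flank used by the origin scan); pad and loop letters are
    restricted so they cannot form pairs that would displace the planted
    stem in a maximum-base-pair structure.

    ``verify`` re-derives the structure with the folding module:
    ``"duplex"`` (default) requires the planted per-position pair classes to
    be recovered, ``"fold"`` requires the exact planted pairing map, and
    ``None`` skips the check.  Failure raises :class:`ConstructionError`.

    ``use_planted_fold`` attaches the planted pairing map to the hairpin as
    a supplied fold instead of refolding it.  Needed for heavily mismatched
    duplexes, where the maximum-pair structure is legitimately different
    from the planted stem.
    """
    guide = clean_rna(guide_seq, name="guide")
    L = len(guide)
    if not (18 <= L <= 26):
        raise ConstructionError(f"guide must be 18-26 nt, got {L}")
    if loop_len < hp.MIN_LOOP:
        raise ConstructionError(f"loop_len must be >= {hp.MIN_LOOP}")
    if guide_arm not in ("5p", "3p"):
        raise ConstructionError("guide_arm must be 5p or 3p")
    positions = sorted(set(int(p) for p in mismatch_positions))
    for p in positions:
        if not 1 <= p <= L:
            raise ConstructionError(f"mismatch position {p} outside guide 1..{L}")
        if p >= L - 1:
            raise ConstructionError(
                f"mismatch position {p} falls on the guide 3' overhang "
                f"(positions {L - 1}-{L}); no star base faces it"
            )

    rng = np.random.default_rng(seed)

    # paired register: arm5[i] pairs arm3[L-3-i] for i in 0..L-3; the last
    # two bases of each arm are the 3' overhangs (arm5's loop-side, arm3's
    # at the precursor 3' end)
    arm5 = ["N"] * L
    arm3 = ["N"] * L
    mism = set(positions)

    def _bubble_base(g_idx: int) -> str:
        # a star base facing a planted mismatch must never pair the guide
        # base it faces, and should avoid the neighbours too (a +/-1
        # register shift could otherwise zip the bubble and beat or tie the
        # planted stem); minimize neighbour conflicts when unavoidable
        neighbours = guide[max(0, g_idx - 1) : g_idx + 2]
        centre = guide[g_idx]

        def conflicts(c: str) -> int:
            return sum(can_pair(c, g) or can_pair(g, c) for g in neighbours)

        cands = [c for c in "ACGU" if not (can_pair(c, centre) or can_pair(centre, c))]
        fewest = min(conflicts(c) for c in cands)
        pool = [c for c in cands if conflicts(c) == fewest]
        return str(rng.choice(pool))

    if guide_arm == "5p":
        for i, base in enumerate(guide):
            arm5[i] = base
        for i in range(L - 2):  # i = guide index, partner index on arm3
            g_pos = i + 1
            arm3[L - 3 - i] = _bubble_base(i) if g_pos in mism else complement(guide[i])
        # the star 3' overhang closes the folded core; letters pairing with
        # the guide 5' end would create an equal-count shifted structure
        free = [c for c in "ACGU" if not can_pair(guide[0], c) and not can_pair(c, guide[0])]
        arm3[L - 2] = str(rng.choice(free))
        arm3[L - 1] = str(rng.choice(free))
    else:
        for i, base in enumerate(guide):
            arm3[i] = base
        for g_idx in range(L - 2):  # guide index pairs arm5[L-3-g_idx]
            g_pos = g_idx + 1
            arm5[L - 3 - g_idx] = (
                _bubble_base(g_idx) if g_pos in mism else complement(guide[g_idx])
            )
        # arm5's last two bases are the star's 3' overhang (loop-adjacent)
        arm5[L - 2] = str(rng.choice(["A", "C"]))
        arm5[L - 1] = str(rng.choice(["A", "C"]))

    # pads emulate transcript sequence beyond the excised hairpin; they are
    # not part of the folded core, so they carry ordinary random sequence
    pad5 = "".join(rng.choice(list("ACGU"), size=pad_len)) if pad_len else ""
    pad3 = "".join(rng.choice(list("ACGU"), size=pad_len)) if pad_len else ""

    loop = _build_loop((arm5[L - 2], arm5[L - 1]), loop_len, rng)

    precursor = pad5 + "".join(arm5) + loop + "".join(arm3) + pad3
    n = len(precursor)
    if guide_arm == "5p":
        guide_span = (pad_len, pad_len + L)
        star_span = (pad_len + L + loop_len, pad_len + 2 * L + loop_len)
    else:
        guide_span = (pad_len + L + loop_len, pad_len + 2 * L + loop_len)
        star_span = (pad_len, pad_len + L)

    # The stored fold describes the excised hairpin (arms + loop); the pads
    # emulate transcript sequence beyond the processed precursor and stay
    # unpaired.  Folding the core with the Nussinov module must recover the
    # planted structure; heavily mismatched plants carry the planted map
    # directly (their stem is legitimately not the maximum-pair structure).
    core = "".join(arm5) + loop + "".join(arm3)
    planted_core = planted_fold(L, loop_len, positions, guide_arm, 0)
    if use_planted_fold:
        core_fold = planted_core
    else:
        core_fold = hp.fold_hairpin(core)
        if verify == "fold" and not np.array_equal(core_fold, planted_core):
            raise ConstructionError(
                f"{hairpin_id}: fold does not recover the planted pairing map"
            )

    full_fold = np.full(len(precursor), hp.UNPAIRED, dtype=np.int64)
    paired = core_fold != hp.UNPAIRED
    full_fold[pad_len : pad_len + len(core)][paired] = core_fold[paired] + pad_len

    hairpin = hp.Hairpin(
        id=hairpin_id,
        precursor_seq=precursor,
        guide_span=guide_span,
        star_span=star_span,
        guide_arm=guide_arm,
        fold=full_fold,
    )

    if verify is not None:
        planted = planted_duplex_classes(L, positions)
        try:
            duplex = hp.extract_duplex(hairpin)
        except NoDuplexError as err:
            raise ConstructionError(
                f"{hairpin_id}: fold lost the planted duplex ({err})"
            ) from err
        if duplex.pairs != planted:
            raise ConstructionError(
                f"{hairpin_id}: fold does not recover the planted duplex classes"
            )
    return hairpin


#: candidate two-letter loop alphabets whose members pair with nothing in the set
_OUTSIDE_ALPHABETS = (("A", "C"), ("C", "U"), ("A", "G"))


def _build_loop(
    overhang: tuple[str, str], loop_len: int, rng: np.random.Generator
) -> str:
    """A loop drawn from a mutually non-pairing alphabet that also avoids
    the partners of the loop-reachable 3'-overhang bases of the 5' arm, so
    no structure can pair into the loop."""
    forbidden: set[str] = set()
    if loop_len >= 3:
        forbidden |= pairing_partners(overhang[0])
    if loop_len >= 4:
        forbidden |= pairing_partners(overhang[1])
    for alpha in _OUTSIDE_ALPHABETS:
        if not (set(alpha) & forbidden):
            return "".join(rng.choice(list(alpha), size=loop_len))
    for c in "CAGU":
        if c not in forbidden:
            return c * loop_len
    raise ConstructionError(
        f"no loop alphabet avoids pairing with overhang bases {overhang!r}"
    )


def planted_fold(
    guide_len: int,
    loop_len: int,
    mismatch_positions: Iterable[int],
    guide_arm: str = "5p",
    pad_len: int = 0,
) -> np.ndarray:
    """The pairing map a constructed hairpin is planted with: arm positions
    pad+i and pad+2L+loop-3-i pair for i in 0..L-3, except at mismatches."""
    L = guide_len
    core = 2 * L + loop_len
    n = core + 2 * pad_len
    fold = np.full(n, hp.UNPAIRED, dtype=np.int64)
    mism = set(int(p) for p in mismatch_positions)
    for i in range(L - 2):
        # guide position (1-based) that this stem pair involves
        g_pos = i + 1 if guide_arm == "5p" else (L - 2) - i
        if g_pos in mism:
            continue
        fold[pad_len + i] = pad_len + core - 3 - i
        fold[pad_len + core - 3 - i] = pad_len + i
    return fold


def planted_duplex_classes(guide_len: int, mismatch_positions: Iterable[int]) -> list[str]:
    """Expected per-position duplex classes for a constructed hairpin."""
    mism = set(mismatch_positions)
    classes = []
    for p in range(1, guide_len + 1):
        if p >= guide_len - 1:
            classes.append(hp.UNCOVERED)
        elif p in mism:
            classes.append(hp.MISMATCH)
        else:
            classes.append(hp.WC)
    return classes


def _random_guide(rng: np.random.Generator, length: int) -> str:
    # 5'-terminal U dominates real guides in this system
    first = "U" if rng.random() < 0.9 else rng.choice(list("ACG"))
    rest = rng.choice(list("ACGU"), size=length - 1)
    return first + "".join(rest)


def _draw_length(rng: np.random.Generator, class_label: str) -> int:
    pmf = GUIDE_LENGTH_PMF[class_label]
    lengths = sorted(pmf)
    return int(rng.choice(lengths, p=[pmf[l] for l in lengths]))


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _draw_preference(rng: np.random.Generator, class_label: str, frac_strong: float) -> float:
    if class_label == "none":
        return float(rng.uniform(0.35, 0.65))
    if rng.random() < frac_strong:
        f = rng.uniform(0.95, 0.995)
    else:
        f = rng.uniform(0.75, 0.88)
    return float(f) if class_label == "AGO1" else float(1.0 - f)


def _central_positions(rng: np.random.Generator, guide_len: int) -> tuple[int, ...]:
    # single positions or adjacent pairs; an isolated paired base between
    # two bubbles folds ambiguously and cannot be planted reliably
    region = [p for p in (10, 11, 12) if p < guide_len - 1]
    options: list[tuple[int, ...]] = [(p,) for p in region]
    options += [(a, a + 1) for a in region if a + 1 in region]
    return options[int(rng.integers(0, len(options)))]


def generate_hairpins(
    design: SimulationDesign,
    rng: np.random.Generator,
    *,
    n_failures: int = 0,
    n_starless: int = 0,
) -> tuple[list[hp.Hairpin], GroundTruth]:
    """Draw hairpins with planted sorting classes, duplex mismatches,
    expression, and (optionally) single-criterion annotation failures.

    The first ``n_hairpins - n_failures`` hairpins are planted bona fide
    (the last ``n_starless`` of those with no star reads); the remaining
    ``n_failures`` cycle through the failure modes in :data:`FAILURE_MODES`.
    """
    design.validate()
    n_true = design.n_hairpins - n_failures
    if n_true < 0:
        raise ValidationError("n_failures exceeds n_hairpins")
    if n_starless > n_true:
        raise ValidationError("n_starless exceeds the number of bona-fide hairpins")

    hairpins: list[hp.Hairpin] = []
    truth = GroundTruth()
    depth_scale = design.ip_depth / 1e6

    for idx in range(design.n_hairpins):
        hid = f"mir-s{idx + 1:03d}"
        is_failure = idx >= n_true
        mode = FAILURE_MODES[(idx - n_true) % len(FAILURE_MODES)] if is_failure else None

        u = rng.random()
        if is_failure:
            class_label = "none"
        elif u < design.frac_ago1:
            class_label = "AGO1"
        elif u < design.frac_ago1 + design.frac_ago2:
            class_label = "AGO2"
        else:
            class_label = "none"

        length = _draw_length(rng, class_label)
        central = rng.random() < CENTRAL_MISMATCH_PROB[class_label]
        positions: tuple[int, ...] = ()
        if mode == "duplex":
            # enough mismatches to drop the hybridized count below 16,
            # placed away from 10-12 so only the duplex criterion fails
            length = max(length, 22)
            positions = (3, 6, 9, 14, 17)
            central = False
        elif central:
            positions = _central_positions(rng, length)

        base_arm = "5p" if rng.random() < 0.5 else "3p"
        hairpin = None
        for attempt in range(120):
            guide = _random_guide(rng, length)
            arm = base_arm if attempt % 2 == 0 else ("3p" if base_arm == "5p" else "5p")
            try:
                hairpin = make_hairpin(
                    guide,
                    positions,
                    loop_len=int(rng.integers(6, 13)),
                    seed=int(rng.integers(0, 2**31 - 1)),
                    guide_arm=arm,
                    hairpin_id=hid,
                    # a 5-mismatch stem is not the max-pair structure; carry
                    # the planted pairing map as a supplied fold
                    use_planted_fold=(mode == "duplex"),
                )
                break
            except ConstructionError:
                continue
        if hairpin is None:
            raise ConstructionError(f"{hid}: could not construct a verifiable hairpin")
        hairpins.append(hairpin)

        pref = 0.5 if is_failure else _draw_preference(rng, class_label, design.frac_strong)
        expr = _loguniform(rng, *design.expression_rpm_range) * depth_scale
        ratio = _loguniform(rng, *design.strand_selection)
        homog = design.five_prime_homogeneity
        igg = None
        starless = (not is_failure) and (idx >= n_true - n_starless)

        if mode == "enrichment":
            expr, igg = 600.0, 150.0  # IP/IgG fold ~2, below the >3 cut
        elif mode == "homogeneity":
            expr, homog = 600.0, 0.5
        elif mode == "ratio":
            expr, ratio = 800.0, 1.3
        elif mode == "reads":
            expr, ratio = 125.0, 5.0  # replicate counts 60/65, both below 70
        elif mode == "duplex":
            expr = 600.0

        truth.hairpins[hid] = HairpinTruth(
            hairpin_id=hid,
            guide_span=hairpin.guide_span,
            star_span=hairpin.star_span,
            guide_arm=hairpin.guide_arm,
            class_label=class_label,
            preference_ago1=pref,
            central_mismatch=central,
            mismatch_positions=positions,
            expression_counts=expr,
            strand_ratio=ratio,
            five_prime_homogeneity=homog,
            starless=starless,
            planted_failure=mode,
            igg_counts=igg,
            deterministic_counts=is_failure,
        )
    return hairpins, truth


# ---------------------------------------------------------------------------
# Read-stack simulation
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    r = 1.0 / dispersion
    return int(rng.negative_binomial(r, r / (r + mean)))


def _five_prime_offsets(span: tuple[int, int], seq_len: int) -> list[int]:
    """Modal 5' offset plus two alternative starts (within the precursor)."""
    lo, _hi = span
    alts = [o for o in (lo - 1, lo + 1, lo + 2) if 0 <= o < seq_len]
    return [lo] + alts[:2]


def _emit_span_reads(
    precursor: str,
    span: tuple[int, int],
    total: int,
    homogeneity: float,
    rng: np.random.Generator,
    *,
    deterministic: bool,
) -> list[tuple[str, int, int]]:
    """Distribute ``total`` counts over 5' offsets of a span; the modal
    offset carries ``homogeneity`` of the mass.  Reads keep the span 3' end."""
    if total <= 0:
        return []
    offsets = _five_prime_offsets(span, len(precursor))
    n_alt = len(offsets) - 1
    probs = [homogeneity] + [(1.0 - homogeneity) / n_alt] * n_alt if n_alt else [1.0]
    if deterministic:
        counts = [int(round(total * p)) for p in probs]
        counts[0] += total - sum(counts)
    else:
        counts = rng.multinomial(total, probs).tolist()
    out = []
    for off, c in zip(offsets, counts):
        if c > 0:
            read = precursor[off : span[1]]
            out.append((read, off, int(c)))
    return out


def simulate_ip_libraries(
    design: SimulationDesign,
    hairpins: Sequence[hp.Hairpin],
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[list[SmallRNALibrary], dict[str, ReadStack]]:
    """Emit AGO1/AGO2/IgG IP libraries (``replicates`` each per stage) with
    read stacks on the given hairpins.

    Expected guide counts follow expression × AGO preference in the AGO
    libraries and the flat ``igg_background_rpm`` in IgG; star counts follow
    the per-hairpin strand-selection ratio; counts are negative-binomial
    draws unless the hairpin is planted with deterministic counts.
    """
    design.validate()
    if not hairpins:
        raise ValidationError("simulate_ip_libraries: empty hairpin set")
    if rng is None:
        rng = np.random.default_rng(design.rng_seed)

    libraries: list[SmallRNALibrary] = []
    rows: dict[str, list] = {h.id: [] for h in hairpins}

    for stage in design.stages:
        for pulldown in ("AGO1_IP", "AGO2_IP", "IgG_IP"):
            for rep in range(1, design.replicates + 1):
                lib_id = f"{stage}_{pulldown}_rep{rep}"
                libraries.append(
                    SmallRNALibrary(
                        library_id=lib_id,
                        stage=stage,
                        pulldown=pulldown,
                        replicate=rep,
                        genome_mapped_total=design.ip_depth,
                    )
                )
                for h in hairpins:
                    t = truth.hairpins[h.id]
                    det = t.deterministic_counts
                    if pulldown == "IgG_IP":
                        mean = (
                            t.igg_counts
                            if t.igg_counts is not None
                            else design.igg_background_rpm * design.ip_depth / 1e6
                        )
                        g_total = int(round(mean)) if det else _nb_draw(rng, mean, design.dispersion)
                        s_total = 0
                    else:
                        pref = t.preference_ago1 if pulldown == "AGO1_IP" else 1.0 - t.preference_ago1
                        mean = t.expression_counts * pref
                        if t.planted_failure == "reads":
                            # spec'd margin: replicate counts straddle 60-65
                            g_total = 60 if rep == 1 else 65
                        elif det:
                            g_total = int(round(mean))
                        else:
                            g_total = _nb_draw(rng, mean, design.dispersion)
                        if t.starless:
                            s_total = 0
                        else:
                            s_mean = mean / t.strand_ratio
                            s_total = (
                                int(round(s_mean)) if det else _nb_draw(rng, s_mean, design.dispersion)
                            )
                    homog = t.five_prime_homogeneity if pulldown != "IgG_IP" else 0.5
                    for read, off, c in _emit_span_reads(
                        h.precursor_seq, t.guide_span, g_total, homog, rng, deterministic=det
                    ):
                        rows[h.id].append((lib_id, read, off, c, False))
                    for read, off, c in _emit_span_reads(
                        h.precursor_seq, t.star_span, s_total, 1.0, rng, deterministic=det
                    ):
                        rows[h.id].append((lib_id, read, off, c, False))

    stacks = {
        pid: ReadStack(
            precursor_id=pid, records=pd.DataFrame(recs, columns=STACK_COLUMNS[1:])
        )
        for pid, recs in rows.items()
        if recs
    }
    _check_depth(stacks, libraries)
    return libraries, stacks


def _check_depth(stacks: Mapping[str, ReadStack], libraries: Iterable[SmallRNALibrary]) -> None:
    totals: dict[str, int] = {}
    for stack in stacks.values():
        for lib_id, c in stack.records.groupby("library_id")["count"].sum().items():
            totals[lib_id] = totals.get(lib_id, 0) + int(c)
    for lib in libraries:
        if totals.get(lib.library_id, 0) > lib.genome_mapped_total:
            raise ValidationError(
                f"{lib.library_id}: simulated stack counts exceed the genome-mapped total"
            )


def default_kd_effects(design: SimulationDesign, truth: GroundTruth) -> dict[str, dict[str, float]]:
    """Per-miRNA fold changes in each knockdown: a miRNA drops by
    ``design.kd_effect`` in the KD of its preferred AGO and is unchanged in
    the other."""
    effects = {}
    for hid, t in truth.hairpins.items():
        f1 = design.kd_effect if t.class_label == "AGO1" else 1.0
        f2 = design.kd_effect if t.class_label == "AGO2" else 1.0
        effects[hid] = {"KD_AGO1": f1, "KD_AGO2": f2, "KD_control": 1.0}
    return effects


def simulate_kd_libraries(
    design: SimulationDesign,
    hairpins: Sequence[hp.Hairpin],
    truth: GroundTruth,
    kd_effects: Mapping[str, Mapping[str, float]] | None = None,
    star_effects: Mapping[str, Mapping[str, float]] | None = None,
    rng: np.random.Generator | None = None,
    *,
    stage: str = "planula",
) -> tuple[list[SmallRNALibrary], dict[str, ReadStack]]:
    """Control and AGO-knockdown libraries with spike-in counts.

    Guide counts scale by the per-miRNA knockdown fold change; star counts
    scale by ``star_effects`` when given (defaults to the guide effect, i.e.
    no strand-selection shift); spike-in counts are drawn independently of
    treatment.  Fold changes recorded in the returned ground truth feed the
    direction and strand-selection statistics downstream.
    """
    design.validate()
    if rng is None:
        rng = np.random.default_rng(design.rng_seed + 1)
    if kd_effects is None:
        kd_effects = default_kd_effects(design, truth)
    missing = [h.id for h in hairpins if h.id not in kd_effects]
    if missing:
        raise ValidationError(f"kd_effects missing for miRNA(s): {missing[:5]}")
    if not all(c > 0 for c in design.spikein_mean_counts):
        raise ValidationError("spike-in counts are required for KD simulation")

    libraries: list[SmallRNALibrary] = []
    rows: dict[str, list] = {h.id: [] for h in hairpins}
    for pulldown in ("KD_control", "KD_AGO1", "KD_AGO2"):
        for rep in range(1, design.replicates + 1):
            lib_id = f"{stage}_{pulldown}_rep{rep}"
            spikes = {
                sid: max(1, _nb_draw(rng, m, design.dispersion))
                for sid, m in zip(DEFAULT_SPIKEIN_IDS, design.spikein_mean_counts)
            }
            libraries.append(
                SmallRNALibrary(
                    library_id=lib_id,
                    stage=stage,
                    pulldown=pulldown,
                    replicate=rep,
                    genome_mapped_total=design.ip_depth,
                    spikein_counts=spikes,
                )
            )
            for h in hairpins:
                t = truth.hairpins[h.id]
                fc = float(kd_effects[h.id].get(pulldown, 1.0))
                star_fc = fc
                if star_effects is not None and h.id in star_effects:
                    star_fc = float(star_effects[h.id].get(pulldown, fc))
                truth.kd_effects[h.id] = float(kd_effects[h.id].get("KD_AGO1", 1.0))
                g_mean = t.expression_counts * fc
                s_mean = 0.0 if t.starless else t.expression_counts * star_fc / t.strand_ratio
                g_total = _nb_draw(rng, g_mean, design.dispersion)
                s_total = _nb_draw(rng, s_mean, design.dispersion)
                for read, off, c in _emit_span_reads(
                    h.precursor_seq, t.guide_span, g_total,
                    t.five_prime_homogeneity, rng, deterministic=False,
                ):
                    rows[h.id].append((lib_id, read, off, c, False))
                for read, off, c in _emit_span_reads(
                    h.precursor_seq, t.star_span, s_total, 1.0, rng, deterministic=False
                ):
                    rows[h.id].append((lib_id, read, off, c, False))

    stacks = {
        pid: ReadStack(
            precursor_id=pid, records=pd.DataFrame(recs, columns=STACK_COLUMNS[1:])
        )
        for pid, recs in rows.items()
        if recs
    }
    _check_depth(stacks, libraries)
    return libraries, stacks


# ---------------------------------------------------------------------------
# Origin-from-target transcripts
# ---------------------------------------------------------------------------

def _flank_regions(
    hairpin: hp.Hairpin, stem_flank: int, loop_flank: int
) -> dict[str, tuple[int, int]]:
    """Precursor spans of the stem-side and loop-side guide flanks."""
    gs, ge = hairpin.guide_span
    n = len(hairpin.precursor_seq)
    if hairpin.guide_arm == "5p":
        stem = (max(0, gs - stem_flank), gs)
        loop = (ge, min(n, ge + loop_flank))
    else:
        loop = (max(0, gs - loop_flank), gs)
        stem = (ge, min(n, ge + stem_flank))
    return {"stem": stem, "loop": loop}


def _positionwise_run(a: str, b: str) -> int:
    best = cur = 0
    for x, y in zip(a, b):
        cur = cur + 1 if x == y else 0
        best = max(best, cur)
    return best


def plant_origin_transcripts(
    hairpins: Sequence[hp.Hairpin],
    homology_runs: Mapping[str, tuple[int, str]] | Mapping[str, int],
    n_decoys: int | None = None,
    seed: int = 0,
    *,
    transcript_length: int = 400,
    stem_flank: int = 7,
    loop_flank: int = 6,
    min_run: int = 6,
    decoy_context: str = "random",
) -> tuple[dict[str, str], GroundTruth]:
    """Transcripts carrying (or lacking) inverted-duplication homology.

    For each flagged hairpin the transcript embeds the reverse complement of
    the guide plus a contiguous ``run``-nt stretch of flank, i.e. the
    signature left by origin of the precursor from its own target.  Decoy
    transcripts (for unflagged hairpins, up to ``n_decoys``) embed only the
    guide-complementary site: with ``decoy_context="random"`` (default) the
    flanking positions are random transcript backbone; ``"shuffled"``
    instead places composition-preserving shuffles of the true flanks next
    to the site.  Constructed precursor flanks use a reduced pad/loop
    alphabet, so a composition-preserving decoy context shares letters with
    the true flank far more often than natural sequence would; the random
    default keeps "decoy" meaning "no extended homology".

    ``homology_runs`` maps hairpin id → run length, or → ``(run, side)``
    with side in {"stem", "loop"}; run lengths above the flank length of the
    chosen side are rejected.
    """
    if decoy_context not in ("random", "shuffled"):
        raise ValidationError(f"unknown decoy_context {decoy_context!r}")
    rng = np.random.default_rng(seed)
    flank_len = {"stem": stem_flank, "loop": loop_flank}
    transcripts: dict[str, str] = {}
    truth = GroundTruth()

    decoys_made = 0
    for h in hairpins:
        spec_entry = homology_runs.get(h.id)
        if isinstance(spec_entry, tuple):
            run, side = int(spec_entry[0]), str(spec_entry[1])
        elif spec_entry is None:
            run, side = 0, "loop"
        else:
            run, side = int(spec_entry), "loop"
        planted = run > 0
        if planted and run > flank_len[side]:
            raise ValidationError(
                f"{h.id}: homology run {run} exceeds the {side}-side flank "
                f"({flank_len[side]} nt)"
            )
        if not planted:
            if n_decoys is not None and decoys_made >= n_decoys:
                continue
            decoys_made += 1

        gs, ge = h.guide_span
        regions = _flank_regions(h, stem_flank, loop_flank)
        # the homologous (or decoy) insert on the transcript, 5'->3'
        up = h.precursor_seq[regions["stem"][0] : gs] if h.guide_arm == "5p" else \
            h.precursor_seq[regions["loop"][0] : gs]
        down = h.precursor_seq[ge : regions["loop"][1]] if h.guide_arm == "5p" else \
            h.precursor_seq[ge : regions["stem"][1]]
        up_side = "stem" if h.guide_arm == "5p" else "loop"
        down_side = "loop" if h.guide_arm == "5p" else "stem"

        def _context(flank: str, flank_side: str) -> str:
            if planted and flank_side == side:
                # keep `run` nt contiguous with the guide identical
                if flank_side == up_side:
                    return flank[len(flank) - run :]
                return flank[:run]
            if decoy_context == "shuffled":
                return _shuffled_away(flank, rng, min_run)
            return ""  # random backbone supplies the context

        ctx_up = _context(up, up_side)
        ctx_down = _context(down, down_side)
        insert = revcomp(ctx_up + h.guide_seq + ctx_down)

        tid = f"t-{h.id}"
        backbone = "".join(rng.choice(list("ACGU"), size=transcript_length))
        pos = int(rng.integers(20, transcript_length - len(insert) - 20))
        tseq = backbone[:pos] + insert + backbone[pos + len(insert) :]
        # site span = location of the guide-complementary part on the transcript
        site_lo = pos + len(ctx_down)
        site_span = (site_lo, site_lo + len(h.guide_seq))
        transcripts[tid] = tseq
        truth.transcripts[tid] = TranscriptTruth(
            transcript_id=tid,
            mirna_id=h.id,
            site_span=site_span,
            homology_run=run if planted else 0,
            side=side if planted else None,
            planted=planted,
        )
    return transcripts, truth


def _shuffled(s: str, rng: np.random.Generator) -> str:
    return "".join(rng.permutation(list(s))) if len(s) > 1 else s


def _shuffled_away(s: str, rng: np.random.Generator, min_run: int) -> str:
    """Composition-preserving shuffle re-drawn until no positionwise identity
    run of ``min_run``+ nt survives against the original (decoy semantics)."""
    if len(s) < min_run:
        return _shuffled(s, rng)
    for _ in range(200):
        cand = _shuffled(s, rng)
        if _positionwise_run(cand, s) < min_run:
            return cand
    raise ConstructionError("could not shuffle flank away from its own sequence")


# ---------------------------------------------------------------------------
# Scenario orchestration
# ---------------------------------------------------------------------------

def simulate_annotation_scenario(
    design: SimulationDesign | None = None,
    *,
    seed: int | None = None,
    n_failures: int = 20,
    n_starless: int = 10,
):
    """The annotation-validation study: bona-fide hairpins (some starless)
    plus single-criterion failures, with full IP/IgG libraries."""
    if design is None:
        design = SimulationDesign()
    if seed is not None:
        design = replace(design, rng_seed=seed)
    rng = np.random.default_rng(design.rng_seed)
    hairpins, truth = generate_hairpins(
        design, rng, n_failures=n_failures, n_starless=n_starless
    )
    libraries, stacks = simulate_ip_libraries(design, hairpins, truth, rng)
    return hairpins, libraries, stacks, truth


def simulate_origin_scenario(
    design: SimulationDesign | None = None,
    *,
    seed: int | None = None,
    n_planted: int = 10,
):
    """Hairpin set plus transcripts, ``n_planted`` of which carry extended
    flank homology (full-flank runs, alternating stem/loop side); the rest
    are shuffled-context decoys."""
    if design is None:
        design = SimulationDesign()
    if seed is not None:
        design = replace(design, rng_seed=seed)
    rng = np.random.default_rng(design.rng_seed)
    hairpins, truth = generate_hairpins(design, rng)
    runs: dict[str, tuple[int, str]] = {}
    for i, h in enumerate(hairpins[:n_planted]):
        side = "stem" if i % 2 == 0 else "loop"
        runs[h.id] = (7 if side == "stem" else 6, side)
    transcripts, t_truth = plant_origin_transcripts(
        hairpins,
        runs,
        seed=int(rng.integers(0, 2**31 - 1)),
        transcript_length=design.transcript_length,
    )
    truth.transcripts = t_truth.transcripts
    return hairpins, transcripts, truth
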