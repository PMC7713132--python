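"""Argonaute occupancy, knockdown direction statistics, and methylation.

The relative preference of a miRNA for AGO1 is its replicate-averaged RPM
in the AGO1 IP divided by the summed RPM in both AGO IPs.  Classes use
strict thresholds: >0.7 of the signal in one AGO is a preference, >0.9 a
strong preference; exactly 0.7 or 0.9 falls to the weaker class.

Knockdown responses are judged by an exact sign (binomial) test on the
direction of spike-in-normalized fold changes, strand-selection shifts by a
paired test on log(guide FC / star FC), and 2'-O-methylation by comparing
periodate-oxidized to untreated libraries with a paired t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import ReadStack, SmallRNALibrary, normalize_spikein

logger = logging.getLogger("mirsort")

AGO1_STRONG = "AGO1_strong"
AGO1 = "AGO1"
NONE = "none"
AGO2 = "AGO2"
AGO2_STRONG = "AGO2_strong"


def classify_preference(
    fraction: float, thresholds: tuple[float, float] = (0.7, 0.9)
) -> str:
    """Map an AGO1-preference fraction to its class (strict inequalities)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError(f"preference fraction {fraction} outside [0, 1]")
    weak, strong = thresholds
    # canonicalize to the preferred side so the classification is exactly
    # antisymmetric under f -> 1-f (1-(1-f) is exact in IEEE for f >= 0.5)
    toward_ago1 = fraction >= 0.5
    m = fraction if toward_ago1 else 1.0 - fraction
    if m > strong:
        return AGO1_STRONG if toward_ago1 else AGO2_STRONG
    if m > weak:
        return AGO1 if toward_ago1 else AGO2
    return NONE


@dataclass
class PreferenceRecord:
    mirna_id: str
    stage: str
    mean_ago1_rpm: float
    mean_ago2_rpm: float
    preference_ago1: float
    class_label: str


def preference_table(
    rpm: pd.DataFrame,
    libraries: Sequence[SmallRNALibrary],
    min_norm_reads: float = 20.0,
    thresholds: tuple[float, float] = (0.7, 0.9),
) -> pd.DataFrame:
    """Per-stage AGO preference for every sufficiently expressed miRNA.

    ``rpm`` is a miRNA × library RPM matrix.  miRNAs below ``min_norm_reads``
    in every library are omitted (with a logged reason); replicates are
    averaged within each AGO IP per stage.
    """
    by_cond: dict[tuple[str, str], list[str]] = {}
    for lib in libraries:
        if lib.pulldown in ("AGO1_IP", "AGO2_IP") and lib.library_id in rpm.columns:
            by_cond.setdefault((lib.stage, lib.pulldown), []).append(lib.library_id)
    stages = sorted({s for s, _ in by_cond})
    for stage in stages:
        if (stage, "AGO1_IP") not in by_cond or (stage, "AGO2_IP") not in by_cond:
            raise ValidationError(f"stage {stage}: missing an AGO IP arm")

    records: list[PreferenceRecord] = []
    for mid, row in rpm.iterrows():
        if row.max() < min_norm_reads:
            logger.info(
                "preference_table: %s below %.0f RPM in every library; omitted",
                mid,
                min_norm_reads,
            )
            continue
        for stage in stages:
            a1 = float(row[by_cond[(stage, "AGO1_IP")]].mean())
            a2 = float(row[by_cond[(stage, "AGO2_IP")]].mean())
            if a1 + a2 == 0:
                continue
            f = a1 / (a1 + a2)
            records.append(
                PreferenceRecord(
                    mirna_id=str(mid),
                    stage=stage,
                    mean_ago1_rpm=a1,
                    mean_ago2_rpm=a2,
                    preference_ago1=f,
                    class_label=classify_preference(f, thresholds),
                )
            )
    return pd.DataFrame([r.__dict__ for r in records])


def overall_preference(stage_classes: Iterable[str]) -> str:
    """Collapse per-stage classes to one label: a miRNA with no preference in
    any stage is "none"; consistent direction keeps the strongest class seen;
    opposite directions across stages are flagged "mixed"."""
    classes = list(stage_classes)
    if not classes:
        raise ValidationError("overall_preference: empty class list")
    toward1 = [c for c in classes if c in (AGO1, AGO1_STRONG)]
    toward2 = [c for c in classes if c in (AGO2, AGO2_STRONG)]
    if not toward1 and not toward2:
        return NONE
    if toward1 and toward2:
        return "mixed"
    side = toward1 or toward2
    strong = AGO1_STRONG if toward1 else AGO2_STRONG
    return strong if strong in side else side[0]


# ---------------------------------------------------------------------------
# Knockdown statistics
# ---------------------------------------------------------------------------

def binomial_direction_p(n_down: int, n_up: int, tail: str = "two_tailed") -> float | None:
    """Exact sign-test p-value under P(down) = 0.5.

    One-tailed: probability of an imbalance at least as large in the observed
    direction; two-tailed: twice that, capped at 1.  Returns None when there
    are no informative (non-tied) observations.
    """
    n = n_down + n_up
    if n == 0:
        return None
    k = max(n_down, n_up)
    upper = sum(comb(n, i) for i in range(k, n + 1)) / 2.0**n
    if tail == "one_tailed":
        return float(upper)
    if tail == "two_tailed":
        return float(min(1.0, 2.0 * upper))
    raise ValidationError(f"unknown tail {tail!r}")


@dataclass
class KDResult:
    subset: list[str]
    n_down: int
    n_up: int
    n_ties: int
    tail: str
    p: float | None
    fold_changes: pd.Series


def kd_direction_test(
    control_norm: pd.Series,
    kd_norm: pd.Series,
    subset: Iterable[str] | None = None,
    tail: str = "two_tailed",
) -> KDResult:
    """Do miRNAs move down (or up) after an AGO knockdown?

    ``control_norm`` / ``kd_norm`` are spike-in-normalized guide counts per
    miRNA.  Each miRNA is classed by its fold change; exact ties are
    uninformative and excluded from the binomial n.
    """
    ids = list(subset) if subset is not None else list(control_norm.index)
    if not ids:
        raise ValidationError("kd_direction_test: empty miRNA subset")
    missing = [i for i in ids if i not in control_norm.index or i not in kd_norm.index]
    if missing:
        raise ValidationError(f"kd_direction_test: missing values for {missing[:5]}")
    fc = (kd_norm[ids] / control_norm[ids]).astype(float)
    n_down = int((fc < 1.0).sum())
    n_up = int((fc > 1.0).sum())
    n_ties = len(ids) - n_down - n_up
    p = binomial_direction_p(n_down, n_up, tail)
    if p is None:
        logger.warning("kd_direction_test: all fold changes tied; p undefined")
    return KDResult(
        subset=ids,
        n_down=n_down,
        n_up=n_up,
        n_ties=n_ties,
        tail=tail,
        p=p,
        fold_changes=fc.rename("fold_change"),
    )


def spikein_normalized_counts(
    stacks: Mapping[str, ReadStack],
    spans: Mapping[str, tuple[int, int]],
    libraries: Sequence[SmallRNALibrary],
) -> pd.DataFrame:
    """miRNA × library matrix of span read counts divided by each library's
    mean spike-in count."""
    mat = pd.DataFrame(
        0.0, index=sorted(spans), columns=[l.library_id for l in libraries]
    )
    for mid in mat.index:
        if mid not in stacks:
            continue
        df = stacks[mid].span_records(spans[mid])
        for lib_id, c in df.groupby("library_id")["count"].sum().items():
            if lib_id in mat.columns:
                mat.loc[mid, lib_id] = float(c)
    for lib in libraries:
        mat[lib.library_id] = normalize_spikein(mat[lib.library_id].to_numpy(), lib)
    return mat


def condition_means(
    norm: pd.DataFrame, libraries: Sequence[SmallRNALibrary], pulldown: str
) -> pd.Series:
    ids = [l.library_id for l in libraries if l.pulldown == pulldown]
    if not ids:
        raise ValidationError(f"no libraries with pulldown {pulldown!r}")
    return norm[ids].mean(axis=1)


@dataclass
class StrandShiftResult:
    ratios: pd.Series  # guide FC / star FC per miRNA
    test_name: str
    statistic: float | None
    p: float | None
    n: int


def strand_selection_shift(
    guide_fc: pd.Series,
    star_fc: pd.Series,
    test: str = "wilcoxon",
) -> StrandShiftResult:
    """Ratio of guide to star fold changes per miRNA, with a paired two-tailed
    test of log-ratio against zero (Wilcoxon signed-rank by default; ``test=
    "ttest"`` switches to a paired t)."""
    common = guide_fc.index.intersection(star_fc.index)
    g = guide_fc[common].astype(float)
    s = star_fc[common].astype(float)
    keep = (s > 0) & np.isfinite(s) & (g > 0) & np.isfinite(g)
    ratios = (g[keep] / s[keep]).rename("guide_fc_over_star_fc")
    logr = np.log(ratios.to_numpy())
    if len(logr) < 2 or np.allclose(logr, 0.0):
        return StrandShiftResult(ratios, test, None, None, len(logr))
    if test == "wilcoxon":
        res = stats.wilcoxon(logr, alternative="two-sided")
        return StrandShiftResult(ratios, "wilcoxon", float(res.statistic), float(res.pvalue), len(logr))
    if test == "ttest":
        t, p = stats.ttest_1samp(logr, 0.0)
        return StrandShiftResult(ratios, "paired_t", float(t), float(p), len(logr))
    raise ValidationError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# Methylation (oxidized vs non-oxidized libraries)
# ---------------------------------------------------------------------------

@dataclass
class MethylationResult:
    retention: pd.Series  # oxidized / non-oxidized normalized ratio per miRNA
    class_means: dict[str, float]
    t: float
    p: float
    n: int


def methylation_comparison(
    ox_norm: pd.Series,
    nonox_norm: pd.Series,
    raw_nonox: pd.Series,
    classes: Mapping[str, str],
    min_raw_reads: int = 50,
) -> MethylationResult:
    """Retention of each miRNA after periodate oxidation.

    miRNAs with fewer than ``min_raw_reads`` raw reads in the untreated
    library are removed; the paired two-tailed t-test compares normalized
    oxidized vs non-oxidized levels across the survivors, and per-class mean
    retention ratios summarize which sorting class stays methylated.
    """
    ids = [
        i
        for i in nonox_norm.index
        if i in ox_norm.index
        and i in raw_nonox.index
        and raw_nonox[i] >= min_raw_reads
        and nonox_norm[i] > 0
    ]
    if not ids:
        raise ValidationError(
            f"methylation_comparison: no miRNA with >= {min_raw_reads} raw reads"
        )
    retention = (ox_norm[ids] / nonox_norm[ids]).rename("retention")
    class_means: dict[str, float] = {}
    labels = {classes.get(i, "unclassified") for i in ids}
    for lab in sorted(labels):
        members = [i for i in ids if classes.get(i, "unclassified") == lab]
        class_means[lab] = float(retention[members].mean())
    diffs = ox_norm[ids].to_numpy(dtype=float) - nonox_norm[ids].to_numpy(dtype=float)
    if np.allclose(diffs, 0.0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(ox_norm[ids].astype(float), nonox_norm[ids].astype(float))
    return MethylationResult(
        retention=retention,
        class_means=class_means,
        t=float(t),
        p=float(p),
        n=len(ids),
    )
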