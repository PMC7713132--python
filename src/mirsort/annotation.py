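"""Stringent AGO-IP miRNA annotation.

A candidate hairpin with its read stack is tested against five criteria:
(a) >3-fold enrichment of the IP signal over the IgG negative control,
(b) a homogeneous guide 5' end (modal-offset fraction of guide reads),
(c) guide/star read ratio strictly above two,
(d) guide reads present in both biological replicates with at least 70 raw
    reads in at least one of them,
(e) at least 16 hybridized nucleotides in the predicted guide/star duplex,
plus an expression floor of 20 RPM in at least one library.  Candidates
passing everything with zero star reads anywhere are kept as the separate
"starless" category.  Every measured value is retained for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import hairpin as hp
from .errors import NoDuplexError, ValidationError
from .io import ReadStack, SmallRNALibrary, gff3_attr, normalize_rpm

logger = logging.getLogger("mirsort")

BONA_FIDE = "bona_fide"
STARLESS = "starless"
REJECTED = "rejected"

#: criterion keys, in report order
CRITERIA_KEYS = ("enrichment", "homogeneity", "ratio", "reads", "duplex", "expression")


@dataclass
class AnnotationCriteria:
    """Thresholds for the bona-fide criteria; comparisons as documented."""

    min_fold_enrichment: float = 3.0  # strict >
    min_5p_homogeneity: float = 0.75  # >=
    min_guide_star_ratio: float = 2.0  # strict >
    min_guide_reads: int = 70  # raw counts, >=, in at least one replicate
    require_both_replicates: bool = True
    min_hybridized_nt: int = 16  # >=
    min_norm_reads: float = 20.0  # RPM, >=, in at least one library
    gu_is_mismatch: bool = False

    def __post_init__(self) -> None:
        for name in (
            "min_fold_enrichment",
            "min_5p_homogeneity",
            "min_guide_star_ratio",
            "min_guide_reads",
            "min_hybridized_nt",
            "min_norm_reads",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"criterion threshold {name} must be positive")


@dataclass
class CriterionResult:
    passed: bool
    value: float
    threshold: float


@dataclass
class CatalogEntry:
    mirna_id: str
    hairpin: hp.Hairpin
    guide_seq: str
    star_seq: str
    guide_arm: str
    class_label: str  # bona_fide / starless / rejected
    criteria: dict[str, CriterionResult]
    rpm: pd.Series  # guide RPM per library
    star_raw_total: int
    best_condition: tuple[str, str]  # (stage, pulldown)

    @property
    def failed_criteria(self) -> list[str]:
        return [k for k, r in self.criteria.items() if not r.passed]


def enrichment_fold(ip_rpm: float, igg_rpm: float, pseudocount_rpm: float = 0.0) -> float:
    """IP/IgG fold enrichment with an additive IgG pseudocount (typically
    the RPM of a single raw read in the IgG library, so an empty control
    still yields a finite fold)."""
    if ip_rpm < 0 or igg_rpm < 0 or pseudocount_rpm < 0:
        raise ValidationError("RPM values must be >= 0")
    denom = igg_rpm + pseudocount_rpm
    if denom == 0:
        return float("inf") if ip_rpm > 0 else 0.0
    return ip_rpm / denom


def five_prime_homogeneity(
    stack: ReadStack,
    guide_span: tuple[int, int],
    library_ids: Iterable[str] | None = None,
) -> float:
    """Fraction of guide-strand read counts starting at the modal 5' offset."""
    df = stack.span_records(guide_span, library_ids)
    if df.empty:
        raise ValidationError(
            f"{stack.precursor_id}: no guide-strand reads for 5' homogeneity"
        )
    by_offset = df.groupby("offset")["count"].sum()
    return float(by_offset.max() / by_offset.sum())


def _replicate_guide_counts(
    stack: ReadStack,
    guide_span: tuple[int, int],
    libs: Sequence[SmallRNALibrary],
) -> dict[int, int]:
    return {
        lib.replicate: int(
            stack.span_records(guide_span, [lib.library_id])["count"].sum()
        )
        for lib in libs
    }


def evaluate_candidate(
    hairpin: hp.Hairpin,
    stack: ReadStack,
    libraries: Sequence[SmallRNALibrary],
    criteria: AnnotationCriteria | None = None,
) -> CatalogEntry:
    """Apply all annotation criteria to one candidate.

    The observed guide arm is the arm with the higher summed IP read counts
    (ties broken toward the more homogeneous 5' end); enrichment compares
    replicate-averaged RPM between the best-supporting IP condition and its
    stage-matched IgG controls.
    """
    if criteria is None:
        criteria = AnnotationCriteria()
    ago_libs = [l for l in libraries if l.pulldown in ("AGO1_IP", "AGO2_IP")]
    igg_libs = [l for l in libraries if l.pulldown == "IgG_IP"]
    if not ago_libs:
        raise ValidationError("evaluate_candidate: no AGO IP libraries supplied")
    if not igg_libs:
        raise ValidationError("evaluate_candidate: missing IgG control libraries")
    ip_ids = [l.library_id for l in ago_libs]

    # --- observed guide arm -------------------------------------------------
    span_a = hairpin.guide_span
    span_b = hairpin.star_span
    if span_b is None:
        # infer the partner span from the fold (2-nt 3' overhang included)
        fold = hairpin.get_fold()
        partners = [
            int(fold[i])
            for i in range(*span_a)
            if fold[i] != hp.UNPAIRED and not (span_a[0] <= fold[i] < span_a[1])
        ]
        if not partners:
            raise NoDuplexError(f"{hairpin.id}: guide span pairs nowhere in the fold")
        lo, hi = min(partners), max(partners) + 1
        span_b = (lo, min(hi + 2, len(hairpin.precursor_seq)))
    count_a = int(stack.span_records(span_a, ip_ids)["count"].sum())
    count_b = int(stack.span_records(span_b, ip_ids)["count"].sum())
    if count_a > count_b:
        guide_span, star_span = span_a, span_b
    elif count_b > count_a:
        guide_span, star_span = span_b, span_a
    else:
        try:
            h_a = five_prime_homogeneity(stack, span_a, ip_ids)
        except ValidationError:
            h_a = -1.0
        try:
            h_b = five_prime_homogeneity(stack, span_b, ip_ids)
        except ValidationError:
            h_b = -1.0
        guide_span, star_span = (span_a, span_b) if h_a >= h_b else (span_b, span_a)
    arm = "5p" if guide_span[0] < star_span[0] else "3p"

    # --- best-supporting IP condition ---------------------------------------
    conditions: dict[tuple[str, str], list[SmallRNALibrary]] = {}
    for lib in ago_libs:
        conditions.setdefault((lib.stage, lib.pulldown), []).append(lib)
    best_cond, best_libs, best_total = None, None, -1
    for cond in sorted(conditions):
        libs = conditions[cond]
        total = int(
            stack.span_records(guide_span, [l.library_id for l in libs])["count"].sum()
        )
        if total > best_total:
            best_cond, best_libs, best_total = cond, libs, total

    results: dict[str, CriterionResult] = {}

    # (a) enrichment: best-condition mean RPM vs stage-matched IgG mean RPM
    stage = best_cond[0]
    stage_igg = [l for l in igg_libs if l.stage == stage] or igg_libs
    ip_rpms = [
        normalize_rpm(stack.span_records(guide_span, [l.library_id])["count"].sum(), l)
        for l in best_libs
    ]
    igg_rpms = [
        normalize_rpm(stack.span_records(guide_span, [l.library_id])["count"].sum(), l)
        for l in stage_igg
    ]
    pseudo = float(np.mean([1e6 / l.genome_mapped_total for l in stage_igg]))
    fold = enrichment_fold(float(np.mean(ip_rpms)), float(np.mean(igg_rpms)), pseudo)
    results["enrichment"] = CriterionResult(
        fold > criteria.min_fold_enrichment, fold, criteria.min_fold_enrichment
    )

    # (b) 5' homogeneity over the best condition's libraries
    try:
        homog = five_prime_homogeneity(
            stack, guide_span, [l.library_id for l in best_libs]
        )
    except ValidationError:
        homog = 0.0
    results["homogeneity"] = CriterionResult(
        homog >= criteria.min_5p_homogeneity, homog, criteria.min_5p_homogeneity
    )

    # (c) guide/star ratio (summed counts, best condition); star-free passes
    best_ids = [l.library_id for l in best_libs]
    guide_total = int(stack.span_records(guide_span, best_ids)["count"].sum())
    star_total = int(stack.span_records(star_span, best_ids)["count"].sum())
    ratio = float("inf") if star_total == 0 else guide_total / star_total
    results["ratio"] = CriterionResult(
        ratio > criteria.min_guide_star_ratio, ratio, criteria.min_guide_star_ratio
    )

    # (d) both replicates, >=70 raw guide reads in at least one
    rep_counts = _replicate_guide_counts(stack, guide_span, best_libs)
    present = all(c > 0 for c in rep_counts.values()) if criteria.require_both_replicates else any(
        c > 0 for c in rep_counts.values()
    )
    enough = any(c >= criteria.min_guide_reads for c in rep_counts.values())
    results["reads"] = CriterionResult(
        bool(present and enough),
        float(max(rep_counts.values(), default=0)),
        float(criteria.min_guide_reads),
    )

    # (e) hybridized nucleotides in the predicted duplex
    try:
        duplex = hp.extract_duplex(hairpin, guide_span, star_span)
        hyb = hp.hybridized_count(duplex, gu_is_mismatch=criteria.gu_is_mismatch)
    except NoDuplexError:
        duplex = None
        hyb = 0
    results["duplex"] = CriterionResult(
        hyb >= criteria.min_hybridized_nt, float(hyb), float(criteria.min_hybridized_nt)
    )

    # expression floor: >=20 RPM in at least one library
    rpm = pd.Series(
        {
            l.library_id: float(
                normalize_rpm(
                    stack.span_records(guide_span, [l.library_id])["count"].sum(), l
                )
            )
            for l in libraries
        },
        name=hairpin.id,
    )
    ip_igg_rpm = rpm[[l.library_id for l in ago_libs + igg_libs]]
    results["expression"] = CriterionResult(
        float(ip_igg_rpm.max()) >= criteria.min_norm_reads,
        float(ip_igg_rpm.max()),
        criteria.min_norm_reads,
    )

    star_raw_total = int(stack.span_records(star_span, ip_ids)["count"].sum())
    all_pass = all(r.passed for r in results.values())
    if all_pass and star_raw_total > 0:
        label = BONA_FIDE
    elif all_pass:
        label = STARLESS
    else:
        label = REJECTED

    gs, ge = guide_span
    ss, se = star_span
    return CatalogEntry(
        mirna_id=hairpin.id,
        hairpin=hairpin,
        guide_seq=hairpin.precursor_seq[gs:ge],
        star_seq=hairpin.precursor_seq[ss:se],
        guide_arm=arm,
        class_label=label,
        criteria=results,
        rpm=rpm,
        star_raw_total=star_raw_total,
        best_condition=best_cond,
    )


def annotate_catalog(
    hairpins: Sequence[hp.Hairpin],
    stacks: Mapping[str, ReadStack],
    libraries: Sequence[SmallRNALibrary],
    criteria: AnnotationCriteria | None = None,
) -> tuple[pd.DataFrame, dict, list[CatalogEntry]]:
    """Evaluate every candidate; return the audit table, summary counts,
    and the accepted/rejected entries themselves."""
    if criteria is None:
        criteria = AnnotationCriteria()
    entries: list[CatalogEntry] = []
    rows = []
    for hairpin in sorted(hairpins, key=lambda h: h.id):
        if hairpin.id not in stacks:
            logger.info("annotate_catalog: no reads for %s; skipped", hairpin.id)
            continue
        entry = evaluate_candidate(hairpin, stacks[hairpin.id], libraries, criteria)
        entries.append(entry)
        row: dict = {
            "mirna_id": entry.mirna_id,
            "class": entry.class_label,
            "guide_arm": entry.guide_arm,
            "guide_seq": entry.guide_seq,
            "star_seq": entry.star_seq,
            "star_raw_total": entry.star_raw_total,
            "best_stage": entry.best_condition[0],
            "best_pulldown": entry.best_condition[1],
            "failed_criteria": ",".join(entry.failed_criteria),
        }
        for key in CRITERIA_KEYS:
            r = entry.criteria[key]
            row[f"{key}_value"] = r.value
            row[f"{key}_pass"] = r.passed
        rows.append(row)
    catalog = pd.DataFrame(rows)
    summary = {
        "n_candidates": len(entries),
        "n_bona_fide": sum(e.class_label == BONA_FIDE for e in entries),
        "n_starless": sum(e.class_label == STARLESS for e in entries),
        "n_rejected": sum(e.class_label == REJECTED for e in entries),
        "rejections_per_criterion": {
            key: sum(
                1
                for e in entries
                if e.class_label == REJECTED and key in e.failed_criteria
            )
            for key in CRITERIA_KEYS
        },
    }
    return catalog, summary, entries


def guide_count_matrix(
    stacks: Mapping[str, ReadStack],
    spans: Mapping[str, tuple[int, int]],
    libraries: Sequence[SmallRNALibrary],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Raw and RPM guide-read count matrices (miRNA × library)."""
    lib_ids = [l.library_id for l in libraries]
    raw = pd.DataFrame(0.0, index=sorted(spans), columns=lib_ids)
    for mid in raw.index:
        if mid not in stacks:
            continue
        df = stacks[mid].span_records(spans[mid])
        for lib_id, c in df.groupby("library_id")["count"].sum().items():
            if lib_id in raw.columns:
                raw.loc[mid, lib_id] = float(c)
    rpm = raw.copy()
    for lib in libraries:
        rpm[lib.library_id] = normalize_rpm(raw[lib.library_id].to_numpy(), lib)
    return raw, rpm


def mirna_read_fraction(
    stacks: Mapping[str, ReadStack],
    libraries: Sequence[SmallRNALibrary],
    catalog_ids: Iterable[str],
) -> pd.DataFrame:
    """Percentage of each library's genome-mapped reads assigned to catalog
    miRNAs, and the IP enrichment of that percentage over stage-matched IgG."""
    ids = set(catalog_ids)
    if not ids:
        raise ValidationError("mirna_read_fraction: empty catalog")
    assigned = {l.library_id: 0 for l in libraries}
    for pid, stack in stacks.items():
        if pid not in ids:
            continue
        for lib_id, c in stack.records.groupby("library_id")["count"].sum().items():
            if lib_id in assigned:
                assigned[lib_id] += int(c)
    rows = []
    for lib in libraries:
        pct = 100.0 * assigned[lib.library_id] / lib.genome_mapped_total
        rows.append(
            {
                "library_id": lib.library_id,
                "stage": lib.stage,
                "pulldown": lib.pulldown,
                "pct_mirna_reads": pct,
            }
        )
    df = pd.DataFrame(rows).set_index("library_id")
    igg = df[df["pulldown"] == "IgG_IP"].groupby("stage")["pct_mirna_reads"].mean()
    enr = []
    for _, row in df.iterrows():
        if row["pulldown"] in ("AGO1_IP", "AGO2_IP") and row["stage"] in igg.index:
            base = igg[row["stage"]]
            enr.append(row["pct_mirna_reads"] / base if base > 0 else np.nan)
        else:
            enr.append(np.nan)
    df["enrichment_vs_igg"] = enr
    return df


# ---------------------------------------------------------------------------
# Genomic context
# ---------------------------------------------------------------------------

def _overlaps(locus: tuple[str, int, int], row) -> bool:
    """Overlap between a 0-based half-open locus and a 1-based inclusive
    GFF3 feature row on the same chromosome."""
    chrom, lo, hi = locus
    return str(row.seqid) == chrom and not (hi <= row.start - 1 or lo >= row.end)


def classify_genomic_context(
    locus: tuple[str, int, int, str],
    gene_models: pd.DataFrame,
    repeats: pd.DataFrame | None = None,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[str, bool, str | None]:
    """Classify a precursor locus as exonic / intronic / intergenic, with an
    independent repetitive-element flag.

    Exon overlap wins over intron; a locus inside a gene but outside its
    exons is intronic.  Any >=1 bp overlap with a repeat feature sets the RE
    flag and returns the repeat family (``family`` or ``Name`` attribute).
    """
    chrom, lo, hi, _strand = locus
    if lo < 0 or hi <= lo:
        raise ValidationError(f"invalid locus interval {locus}")
    if chrom_sizes is not None:
        size = chrom_sizes.get(chrom)
        if size is None or hi > size:
            raise ValidationError(f"locus {locus} beyond chromosome bounds")
    key = (chrom, lo, hi)

    context = "intergenic"
    if not gene_models.empty:
        exon_hit = any(
            _overlaps(key, row)
            for row in gene_models[gene_models["type"] == "exon"].itertuples()
        )
        gene_hit = any(
            _overlaps(key, row)
            for row in gene_models[
                gene_models["type"].isin(["gene", "mRNA", "intron"])
            ].itertuples()
        )
        if exon_hit:
            context = "exonic"
        elif gene_hit:
            context = "intronic"

    re_flag, family = False, None
    if repeats is not None and not repeats.empty:
        for row in repeats.itertuples():
            if _overlaps(key, row):
                re_flag = True
                family = gff3_attr(row.attributes, "family") or gff3_attr(
                    row.attributes, "Name"
                )
                break
    return context, re_flag, family
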