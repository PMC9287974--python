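"""Differentially methylated position (DMP) calling with copy-number filtering.

A probe is a DMP for a sample pair when it survives the homozygous-deletion
filter, is measured in both samples, and its β-values differ by strictly more
than the Δβ threshold (0.3 by default). Per-tumour burden is reported as the
union over all biopsy pairs (with per-pair counts and the pair-multiplicity
histogram alongside, since burden is sometimes quoted as a per-pair maximum).
"""
from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_formats import BetaMatrix, CnaSegmentSet, ProbeManifest


@dataclass
class DmpPairResult:
    """DMPs between two samples.

    ``delta`` holds the signed β difference (sample_b − sample_a) at each DMP.
    ``hypo_count`` / ``hyper_count`` are populated only for ordered
    primary→relapse comparisons (hypo: lower β in the relapse).
    """

    sample_a: str
    sample_b: str
    retained_probe_count: int
    dmp_probe_ids: frozenset
    delta: pd.Series
    hypo_count: int | None = None
    hyper_count: int | None = None
    majority_direction: str | None = None

    @property
    def count(self) -> int:
        return len(self.dmp_probe_ids)


@dataclass
class PatientDmpSummary:
    """All-pairs DMP structure of one multi-biopsy tumour."""

    patient_id: str
    pair_results: list[DmpPairResult]
    union_dmp_ids: frozenset
    retained_probe_count: int  # retained and measured in every biopsy
    multiplicity: Counter  # probe -> number of pairs calling it

    @property
    def union_count(self) -> int:
        return len(self.union_dmp_ids)

    @property
    def max_pair_count(self) -> int:
        return max((r.count for r in self.pair_results), default=0)

    @property
    def union_fraction_pct(self) -> float:
        """Union burden as % of retained probes, one decimal place."""
        return as_percent(self.union_count, self.retained_probe_count, 1)

    def multiplicity_histogram(self) -> dict[int, int]:
        hist = Counter(self.multiplicity.values())
        return dict(sorted(hist.items()))


def as_percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage helper used for burden reporting (e.g. 17100/728898 → 2.3)."""
    if denominator == 0:
        raise ValidationError("percentage denominator is zero")
    return round(100.0 * numerator / denominator, decimals)


# ---------------------------------------------------------------------------


def apply_cna_filter(
    manifest: ProbeManifest,
    segments: CnaSegmentSet,
    samples: Sequence[str],
    threshold: float = -0.4,
) -> frozenset:
    """Probes retained after removing homozygous deletions and SNP probes.

    A probe is removed when its position falls inside a segment with
    seg_mean strictly below ``threshold`` in ANY of ``samples`` — a deletion
    in either member of a pair invalidates its Δβ. Samples without segments
    contribute no removals. SNP probes are always removed.
    """
    if threshold >= 0:
        raise ValidationError("CNA deletion threshold must be negative")
    removed: set[str] = set()
    table = manifest.table
    for sample in samples:
        segs = segments.for_sample(sample)
        for _, seg in segs.iterrows():
            if seg["seg_mean"] < threshold:
                hit = table.index[
                    (table["chrom"] == seg["chrom"])
                    & (table["pos"] >= seg["start"])
                    & (table["pos"] <= seg["end"])
                ]
                removed.update(hit)
    retained = frozenset(set(manifest.non_snp_probe_ids) - removed)
    if not retained:
        raise ValidationError("CNA filter removed every probe; nothing to analyse")
    return retained


def call_dmps(
    beta: BetaMatrix,
    sample_a: str,
    sample_b: str,
    retained: Iterable[str],
    threshold: float = 0.3,
) -> DmpPairResult:
    """Pairwise DMP call: retained, measured in both, |β_b − β_a| > threshold.

    The inequality is strict, so a difference of exactly the threshold is not
    a DMP. ``retained_probe_count`` counts probes retained AND non-missing in
    both samples (the denominator for burden fractions).
    """
    va = beta.column(sample_a)
    vb = beta.column(sample_b)
    keep = beta.probe_ids.intersection(pd.Index(retained), sort=False)
    va, vb = va.loc[keep], vb.loc[keep]
    measured = va.notna() & vb.notna()
    delta = (vb - va)[measured]
    is_dmp = delta.abs() > threshold
    return DmpPairResult(
        sample_a=sample_a,
        sample_b=sample_b,
        retained_probe_count=int(measured.sum()),
        dmp_probe_ids=frozenset(delta.index[is_dmp]),
        delta=delta[is_dmp],
    )


def summarize_temporal(
    beta: BetaMatrix,
    primary: str,
    relapse: str,
    retained: Iterable[str],
    threshold: float = 0.3,
) -> DmpPairResult:
    """Ordered primary→relapse DMP call with the hypo/hyper split.

    hypo_count: DMPs with lower β in the relapse (delta < −threshold);
    hyper_count: higher β in the relapse. They always sum to the DMP total.
    """
    res = call_dmps(beta, primary, relapse, retained, threshold)
    hypo = int((res.delta < -threshold).sum())
    hyper = int((res.delta > threshold).sum())
    res.hypo_count, res.hyper_count = hypo, hyper
    res.majority_direction = (
        "hypo" if hypo > hyper else "hyper" if hyper > hypo else "tie"
    )
    return res


def summarize_patient_spatial(
    beta: BetaMatrix,
    samples: Sequence[str],
    retained: Iterable[str],
    threshold: float = 0.3,
    patient_id: str = "",
) -> PatientDmpSummary:
    """All unordered biopsy pairs of one tumour, with union and multiplicity.

    The burden denominator is the per-patient retained set: probes surviving
    the CNA filter and measured in every biopsy of the patient.
    """
    if len(samples) < 2:
        raise ValidationError("spatial summary needs at least 2 samples")
    retained_idx = beta.probe_ids.intersection(pd.Index(retained), sort=False)
    sub = beta.values.loc[retained_idx, list(samples)]
    all_measured = int(sub.notna().all(axis=1).sum())
    pair_results = [
        call_dmps(beta, a, b, retained_idx, threshold)
        for a, b in itertools.combinations(samples, 2)
    ]
    multiplicity: Counter = Counter()
    for res in pair_results:
        multiplicity.update(res.dmp_probe_ids)
    return PatientDmpSummary(
        patient_id=patient_id,
        pair_results=pair_results,
        union_dmp_ids=frozenset(multiplicity),
        retained_probe_count=all_measured,
        multiplicity=multiplicity,
    )


def cross_patient_sharing(
    summaries: Mapping[str, PatientDmpSummary] | Mapping[str, Iterable[str]],
) -> tuple[pd.Series, dict[int, int]]:
    """How many patients share each DMP.

    Accepts per-patient summaries (union sets used) or raw probe-id sets.
    Returns (probe → patient multiplicity, histogram over multiplicities).
    """
    if len(summaries) < 2:
        raise ValidationError("cross-patient sharing needs at least 2 patients")
    counts: Counter = Counter()
    for value in summaries.values():
        ids = value.union_dmp_ids if isinstance(value, PatientDmpSummary) else value
        counts.update(set(ids))
    series = pd.Series(dict(counts), dtype=int).sort_index()
    hist = dict(sorted(Counter(series.to_numpy()).items()))
    return series, {int(k): int(v) for k, v in hist.items()}


def hypo_majority_fraction(results: Iterable[DmpPairResult]) -> float:
    """Fraction of primary→relapse pairs whose DMPs are mostly hypomethylated."""
    results = [r for r in results if r.count > 0]
    if not results:
        raise ValidationError("no pairs with DMPs")
    n_hypo = sum(1 for r in results if r.majority_direction == "hypo")
    return n_hypo / len(results)
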