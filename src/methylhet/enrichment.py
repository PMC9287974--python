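"""Genomic-region enrichment of DMPs against the array background.

For each annotation category (CpG-island relation: Island / Shore / Shelf /
OpenSea; gene region: TSS200, TSS1500, 5'UTR, 1st exon, exon boundary, body,
3'UTR, plus IGR for probes with no gene annotation) we compare each patient's
DMP proportion with the background proportion of the retained probe set, and
test the per-patient differences with a two-sided one-sample Wilcoxon
signed-rank test (exact null for n ≤ 25 patients, normal approximation with
continuity correction above). A category is flagged enriched or depleted at
p < alpha with the sign of the median difference.

A pooled-count binomial test is available as an alternative (``method=
"binomial"``) but is not the default: the per-patient construction matches
per-patient bar representations and is robust to one patient dominating the
pooled DMP count.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .io_formats import CGI_CATEGORIES, GENE_REGION_CATEGORIES, IGR, ProbeManifest

logger = logging.getLogger(__name__)

EXACT_WILCOXON_MAX_N = 25


@dataclass
class EnrichmentResult:
    axis: str  # "cgi" or "gene_region"
    category: str
    array_proportion: float
    patient_proportions: dict[str, float]
    median_difference: float
    p_value: float
    q_value: float | None
    flag: str  # "enriched" | "depleted" | "ns"


def category_distribution(
    manifest: ProbeManifest, probe_set: Iterable[str]
) -> dict[str, dict[str, float]]:
    """Annotation proportions of a probe set.

    CGI proportions partition the set (sum to 1). Gene-region proportions are
    membership fractions and may sum to more than 1 for multi-annotated
    probes; IGR is the fraction of probes with no gene annotation.
    """
    probes = list(probe_set)
    if not probes:
        raise ValidationError("category_distribution of an empty probe set")
    sub = manifest.table.loc[probes]
    n = len(sub)
    cgi_counts = sub["cgi_relation"].value_counts()
    cgi = {c: float(cgi_counts.get(c, 0)) / n for c in CGI_CATEGORIES}
    regions = sub["gene_regions"]
    gene: dict[str, float] = {}
    for c in GENE_REGION_CATEGORIES:
        gene[c] = sum(1 for r in regions if c in r) / n
    gene[IGR] = sum(1 for r in regions if len(r) == 0) / n
    return {"cgi": cgi, "gene_region": gene}


def _signed_rank_p(diffs: np.ndarray) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p for differences vs zero.

    Zeros are dropped before ranking (standard signed-rank practice); if all
    differences are zero the test is degenerate and p = 1.
    """
    diffs = diffs[diffs != 0]
    if len(diffs) == 0:
        return 1.0
    if len(diffs) <= EXACT_WILCOXON_MAX_N:
        res = stats.wilcoxon(diffs, alternative="two-sided", method="exact")
    else:
        res = stats.wilcoxon(
            diffs, alternative="two-sided", method="approx", correction=True
        )
    return float(res.pvalue)


def _bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (supplementary output only)."""
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(ranked, 0, 1)
    return q


def enrichment_test(
    manifest: ProbeManifest,
    retained: Iterable[str],
    patient_dmp_sets: Mapping[str, Iterable[str]],
    alpha: float = 0.01,
    method: str = "wilcoxon",
) -> list[EnrichmentResult]:
    """Per-category enrichment of per-patient DMP sets vs the retained set.

    Patients with empty DMP sets are excluded (logged); at least two
    contributing patients are required. No multiple-testing correction is
    applied to the flags; BH q-values are attached as supplementary output.
    """
    retained = list(retained)
    background = category_distribution(manifest, retained)

    usable: dict[str, dict[str, dict[str, float]]] = {}
    for patient, probes in patient_dmp_sets.items():
        probes = list(probes)
        if not probes:
            logger.info("enrichment: patient %s has 0 DMPs, excluded", patient)
            continue
        usable[patient] = category_distribution(manifest, probes)
    if len(usable) < 2:
        raise ValidationError(
            "enrichment requires >= 2 patients with non-empty DMP sets"
        )

    results: list[EnrichmentResult] = []
    for axis in ("cgi", "gene_region"):
        for category, array_prop in background[axis].items():
            props = {p: usable[p][axis][category] for p in sorted(usable)}
            diffs = np.array([v - array_prop for v in props.values()])
            if method == "wilcoxon":
                p = _signed_rank_p(diffs)
            elif method == "binomial":
                pooled_n = sum(len(list(patient_dmp_sets[p])) for p in usable)
                pooled_k = int(round(sum(
                    usable[p][axis][category] * len(list(patient_dmp_sets[p]))
                    for p in usable)))
                p = float(stats.binomtest(
                    pooled_k, pooled_n, array_prop, alternative="two-sided"
                ).pvalue)
            else:
                raise ValidationError(f"unknown enrichment method {method!r}")
            med = float(np.median(diffs))
            if p < alpha and med > 0:
                flag = "enriched"
            elif p < alpha and med < 0:
                flag = "depleted"
            else:
                flag = "ns"
            results.append(EnrichmentResult(
                axis=axis, category=category, array_proportion=float(array_prop),
                patient_proportions={k: float(v) for k, v in props.items()},
                median_difference=med, p_value=p, q_value=None, flag=flag,
            ))

    qvals = _bh_qvalues(np.array([r.p_value for r in results]))
    for r, q in zip(results, qvals):
        r.q_value = float(q)
    return results


def flags(results: Iterable[EnrichmentResult]) -> dict[str, str]:
    """category → flag shorthand, e.g. {"OpenSea": "enriched", ...}."""
    return {r.category: r.flag for r in results}
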