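"""EPIC-like cohort simulator with known ground truth.

The generator emulates the statistical structure a multi-region / paired
primary-relapse methylation study assumes:

* per-probe β baselines drawn from a bimodal mixture (modes near 0.1 and 0.9
  with a minor intermediate component), independently per patient;
* biopsy-private, site-specific alterations of fixed magnitude Δ whose sign
  points toward the opposite mode, so shifted values stay inside [0, 1];
* for relapse samples, alteration counts that grow as Poisson(λ · interval)
  with a hypomethylation excess (``hypo_fraction``);
* alteration sites sampled with categorical weights favouring OpenSea and
  intergenic probes (non-regulatory regions);
* purity mixing: observed β = purity · tumour + (1 − purity) · normal,
  truncated, plus Normal(0, σ) noise, re-truncated;
* homozygous deletions (SEG mean < −0.4) whose probes carry Uniform(0, 1)
  noise instead of signal, so the copy-number filter matters;
* tri-modal SNP-probe genotypes (≈0.05 / 0.5 / 0.95) constant within a
  patient, for identity verification.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io_formats import (
    IGR,
    BetaMatrix,
    CnaSegmentSet,
    GENE_REGION_CATEGORIES,
    ProbeManifest,
    SampleSheet,
)

N_SYNTHETIC_CHROMOSOMES = 22
PROBE_SPACING = 1000  # bp between adjacent synthetic probes

#: Default annotation frequencies, loosely EPIC-like.
DEFAULT_CGI_FREQUENCIES: dict[str, float] = {
    "Island": 0.20, "Shore": 0.20, "Shelf": 0.10, "OpenSea": 0.50,
}
DEFAULT_GENE_REGION_FREQUENCIES: dict[str, float] = {
    "TSS200": 0.05, "TSS1500": 0.07, "5UTR": 0.08, "1stExon": 0.03,
    "ExonBnd": 0.02, "Body": 0.35, "3UTR": 0.03, IGR: 0.37,
}

#: Default cohort composition: (n_patients, alteration-rate multiplier).
#: Spatial: 7 low-grade gliomas, 3 medulloblastomas, 1 ependymoma;
#: temporal groups span low- to high-grade entities with increasing rates.
DEFAULT_SPATIAL_GROUPS: dict[str, tuple[int, float]] = {
    "LGG": (7, 1.0), "MB": (3, 2.25), "EPN": (1, 1.2),
}
DEFAULT_TEMPORAL_GROUPS: dict[str, tuple[int, float]] = {
    "LGG": (11, 0.4), "EPN": (5, 0.8), "MB": (8, 1.2),
    "HGG": (5, 2.0), "Embryonal": (4, 2.8),
}


@dataclass
class SimulationDesign:
    """Parameters of a synthetic cohort. Defaults give a desk-scale study:
    20,000 probes, 11 multi-biopsy patients and 33 primary/relapse pairs."""

    n_probes: int = 20000
    n_snp_probes: int = 59
    cgi_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CGI_FREQUENCIES))
    gene_region_frequencies: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_REGION_FREQUENCIES))
    second_region_prob: float = 0.05  # chance of a second gene-region label

    # cohort composition
    spatial_groups: Mapping[str, tuple[int, float]] | None = field(
        default_factory=lambda: dict(DEFAULT_SPATIAL_GROUPS))
    temporal_groups: Mapping[str, tuple[int, float]] | None = field(
        default_factory=lambda: dict(DEFAULT_TEMPORAL_GROUPS))
    n_spatial_patients: int = 11      # used when spatial_groups is None
    n_temporal_patients: int = 33     # used when temporal_groups is None
    biopsies_range: tuple[int, int] = (3, 7)

    # alteration model
    spatial_dmps_per_biopsy: tuple[int, int] = (30, 250)
    dmp_rate_per_day: float = 0.3     # λ, expected relapse DMPs per day
    relapse_interval_range: tuple[int, int] = (100, 1500)  # days
    hypo_fraction: float = 0.6
    dmp_effect_size: float = 0.5      # Δ
    region_bias: float = 3.0          # weight multiplier for OpenSea / IGR sites

    # measurement model
    noise_sd: float = 0.02            # σ
    purity_range: tuple[float, float] = (0.65, 0.95)
    missing_rate: float = 0.0
    shared_baseline: bool = False     # all patients share the normal profile

    # copy number
    deletion_prob: float = 0.3        # per tumour sample
    deletion_n_probes: int = 40
    deletion_seg_mean: float = -1.0

    seed: int | None = None

    def validate(self, dmp_delta_threshold: float = 0.3) -> None:
        for name, freqs in (
            ("cgi_frequencies", self.cgi_frequencies),
            ("gene_region_frequencies", self.gene_region_frequencies),
        ):
            total = sum(freqs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValidationError(f"{name} must sum to 1 (got {total})")
        if not 0 <= self.hypo_fraction <= 1:
            raise ValidationError("hypo_fraction must lie in [0, 1]")
        if self.dmp_effect_size <= dmp_delta_threshold + 3 * self.noise_sd:
            raise ValidationError(
                "dmp_effect_size must exceed the DMP threshold by at least "
                "3 noise standard deviations for injected sites to be recoverable"
            )
        if not self.deletion_seg_mean < -0.4:
            raise ValidationError("deletion_seg_mean must be < -0.4")
        lo, hi = self.purity_range
        if not (0 <= lo <= hi <= 1):
            raise ValidationError("purity_range must satisfy 0 <= lo <= hi <= 1")

    def spatial_plan(self) -> list[tuple[str, float]]:
        """(group_label, multiplier) per spatial patient, deterministic order."""
        if self.spatial_groups is None:
            return [("tumour", 1.0)] * self.n_spatial_patients
        plan = []
        for label, (n, mult) in self.spatial_groups.items():
            plan.extend([(label, mult)] * n)
        return plan

    def temporal_plan(self) -> list[tuple[str, float]]:
        if self.temporal_groups is None:
            return [("tumour", 1.0)] * self.n_temporal_patients
        plan = []
        for label, (n, mult) in self.temporal_groups.items():
            plan.extend([(label, mult)] * n)
        return plan


@dataclass
class GroundTruth:
    """What the generator actually injected, keyed for direct comparison with
    pipeline output.

    injected[patient][sample] maps altered probe ids to their signed shift;
    samples without private alterations map to an empty dict. Injected sites
    are disjoint between samples of a patient, from SNP probes and from the
    patient's deleted regions, so every pairwise truth is a clean set union.
    """

    injected: dict[str, dict[str, dict[str, float]]]
    deleted: dict[str, frozenset]
    purity: dict[str, float]
    relapse_interval: dict[str, int]
    snp_genotypes: dict[str, dict[str, float]]
    truncation_events: list[tuple[str, str]] = field(default_factory=list)

    def pair_truth(self, patient_id: str, sample_a: str, sample_b: str) -> frozenset:
        """True DMP set for a sample pair: symmetric difference of injections."""
        inj = self.injected.get(patient_id, {})
        a = set(inj.get(sample_a, {}))
        b = set(inj.get(sample_b, {}))
        return frozenset(a ^ b)

    def patient_union(self, patient_id: str) -> frozenset:
        inj = self.injected.get(patient_id, {})
        out: set[str] = set()
        for sites in inj.values():
            out |= set(sites)
        return frozenset(out)

    def to_jsonable(self) -> dict:
        return {
            "injected": {
                p: {s: dict(sites) for s, sites in by_sample.items()}
                for p, by_sample in self.injected.items()
            },
            "deleted": {s: sorted(v) for s, v in self.deleted.items()},
            "purity": self.purity,
            "relapse_interval": self.relapse_interval,
            "snp_genotypes": self.snp_genotypes,
            "truncation_events": [list(t) for t in self.truncation_events],
        }


# ---------------------------------------------------------------------------


def simulate_manifest(design: SimulationDesign, rng: np.random.Generator) -> ProbeManifest:
    """Draw a synthetic probe manifest.

    Regular probes are laid out contiguously across 22 synthetic chromosomes
    with 1 kb spacing and i.i.d. annotation draws; SNP probes are appended at
    the high-coordinate end of each chromosome.
    """
    design.validate()
    cgi_cats = list(design.cgi_frequencies)
    cgi_p = np.array([design.cgi_frequencies[c] for c in cgi_cats])
    reg_cats = list(design.gene_region_frequencies)
    reg_p = np.array([design.gene_region_frequencies[c] for c in reg_cats])

    n = design.n_probes
    records = []
    per_chrom = -(-n // N_SYNTHETIC_CHROMOSOMES)  # ceil
    cgi_draw = rng.choice(len(cgi_cats), size=n, p=cgi_p)
    reg_draw = rng.choice(len(reg_cats), size=n, p=reg_p)
    second = rng.random(n) < design.second_region_prob
    chrom_fill: dict[str, int] = {}
    for i in range(n):
        chrom = f"chr{i // per_chrom + 1}"
        offset = i % per_chrom
        pos = (offset + 1) * PROBE_SPACING
        chrom_fill[chrom] = pos
        regions: set[str] = set()
        primary = reg_cats[reg_draw[i]]
        if primary != IGR:
            regions.add(primary)
            if second[i]:
                others = [c for c in GENE_REGION_CATEGORIES if c != primary]
                regions.add(others[rng.integers(len(others))])
        records.append(
            (f"cg{i:07d}", chrom, pos, regions, cgi_cats[cgi_draw[i]], False)
        )
    chroms = sorted(chrom_fill, key=lambda c: int(c[3:]))
    for j in range(design.n_snp_probes):
        chrom = chroms[j % len(chroms)]
        chrom_fill[chrom] += PROBE_SPACING
        records.append((f"rs{j:07d}", chrom, chrom_fill[chrom], set(), "OpenSea", True))
    return ProbeManifest.from_records(records)


def _bimodal_baseline(n: int, rng: np.random.Generator) -> np.ndarray:
    comp = rng.choice(3, size=n, p=[0.45, 0.45, 0.10])
    out = np.empty(n)
    low = comp == 0
    high = comp == 1
    mid = comp == 2
    out[low] = rng.beta(2, 18, size=low.sum())
    out[high] = rng.beta(18, 2, size=high.sum())
    out[mid] = rng.beta(8, 8, size=mid.sum())
    return out


def _site_weights(manifest: ProbeManifest, probe_ids: np.ndarray, bias: float) -> np.ndarray:
    sub = manifest.table.loc[probe_ids]
    w = np.ones(len(sub))
    w *= np.where(sub["cgi_relation"].to_numpy() == "OpenSea", bias, 1.0)
    w *= np.array([bias if len(r) == 0 else 1.0 for r in sub["gene_regions"]])
    return w


def _sample_sites(
    pool: np.ndarray, weights: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    if n == 0:
        return np.array([], dtype=pool.dtype)
    if n > len(pool):
        raise ValidationError(
            f"requested {n} alteration sites but only {len(pool)} eligible probes"
        )
    p = weights / weights.sum()
    return rng.choice(pool, size=n, replace=False, p=p)


def simulate_cohort(
    design: SimulationDesign,
    rng: np.random.Generator,
    manifest: ProbeManifest | None = None,
) -> tuple[BetaMatrix, SampleSheet, CnaSegmentSet, GroundTruth]:
    """Generate a full cohort (β matrix, sample sheet, CNA segments, truth).

    Equal seeds give bit-identical output. When ``manifest`` is omitted it is
    drawn first from the same stream (so ``simulate`` below reproduces it).
    """
    design.validate()
    if manifest is None:
        manifest = simulate_manifest(design, rng)

    regular_ids = np.array(manifest.non_snp_probe_ids)
    snp_ids = np.array(manifest.snp_probe_ids)
    n_reg = len(regular_ids)
    delta = design.dmp_effect_size
    pos = manifest.table["pos"]
    chrom = manifest.table["chrom"]
    regular_index = pd.Index(regular_ids)

    normal_profile = _bimodal_baseline(n_reg, rng)

    columns: dict[str, np.ndarray] = {}
    sheet_rows: list[dict] = []
    segments: dict[str, pd.DataFrame] = {}
    truth = GroundTruth(
        injected={}, deleted={}, purity={}, relapse_interval={}, snp_genotypes={}
    )

    def draw_deletion(sample_id: str) -> frozenset:
        """Maybe assign one homozygously deleted run of regular probes."""
        if rng.random() >= design.deletion_prob:
            return frozenset()
        k = design.deletion_n_probes
        start_idx = int(rng.integers(0, n_reg - k))
        run = regular_ids[start_idx : start_idx + k]
        run_chrom = chrom.loc[run[0]]
        run = run[chrom.loc[run].to_numpy() == run_chrom]  # clip at chromosome edge
        segments[sample_id] = pd.DataFrame(
            {
                "chrom": [run_chrom],
                "start": [int(pos.loc[run[0]])],
                "end": [int(pos.loc[run[-1]])],
                "seg_mean": [design.deletion_seg_mean],
            }
        )
        return frozenset(run)

    def observe(
        sample_id: str,
        tumour: np.ndarray,
        purity: float,
        genotypes: np.ndarray,
        deleted: frozenset,
    ) -> None:
        mixed = purity * tumour + (1 - purity) * normal_profile
        mixed = np.clip(mixed, 0.0, 1.0)
        if design.noise_sd > 0:
            mixed = mixed + rng.normal(0.0, design.noise_sd, size=n_reg)
        mixed = np.clip(mixed, 0.0, 1.0)
        if deleted:
            idx = regular_index.get_indexer(sorted(deleted))
            mixed[idx] = rng.random(len(idx))
        snp_vals = genotypes.copy()
        if design.noise_sd > 0:
            snp_vals = snp_vals + rng.normal(0.0, design.noise_sd, size=len(snp_ids))
        snp_vals = np.clip(snp_vals, 0.0, 1.0)
        columns[sample_id] = np.concatenate([mixed, snp_vals])

    def inject(
        baseline: np.ndarray, sites: np.ndarray, signs: np.ndarray, sample_id: str
    ) -> tuple[np.ndarray, dict[str, float]]:
        tumour = baseline.copy()
        idx = regular_index.get_indexer(sites)
        shifted = tumour[idx] + signs * delta
        for s, val in zip(sites, shifted):
            if val < 0 or val > 1:
                truth.truncation_events.append((sample_id, s))
        tumour[idx] = np.clip(shifted, 0.0, 1.0)
        return tumour, {s: float(sg * delta) for s, sg in zip(sites, signs)}

    # ---- normal reference sample -----------------------------------------
    norm_geno_pool = np.array([0.05, 0.5, 0.95])
    norm_geno = norm_geno_pool[rng.integers(0, 3, size=len(snp_ids))]
    truth.snp_genotypes["NORM"] = dict(zip(snp_ids, norm_geno.tolist()))
    truth.purity["NORM-1"] = float("nan")
    observe("NORM-1", normal_profile, 1.0, norm_geno, frozenset())
    sheet_rows.append(
        dict(sample_id="NORM-1", patient_id="NORM", role="normal_reference",
             biopsy_index=1, purity=np.nan, relapse_interval=np.nan,
             group_label="normal")
    )

    def new_patient(pid: str) -> tuple[np.ndarray, np.ndarray]:
        baseline = (
            normal_profile.copy() if design.shared_baseline
            else _bimodal_baseline(n_reg, rng)
        )
        geno = norm_geno_pool[rng.integers(0, 3, size=len(snp_ids))]
        truth.snp_genotypes[pid] = dict(zip(snp_ids, geno.tolist()))
        truth.injected[pid] = {}
        return baseline, geno

    # ---- spatial patients -------------------------------------------------
    for p_i, (label, mult) in enumerate(design.spatial_plan(), start=1):
        pid = f"SP{p_i:02d}"
        baseline, geno = new_patient(pid)
        n_biopsies = int(rng.integers(design.biopsies_range[0],
                                      design.biopsies_range[1] + 1))
        sample_ids = [f"{pid}-{b}" for b in range(1, n_biopsies + 1)]
        patient_deleted: set[str] = set()
        for sid in sample_ids:
            d = draw_deletion(sid)
            truth.deleted[sid] = d
            patient_deleted |= d
        pool = np.array(sorted(set(regular_ids) - patient_deleted))
        weights = _site_weights(manifest, pool, design.region_bias)
        for sid in sample_ids:
            lo, hi = design.spatial_dmps_per_biopsy
            count = int(round(rng.integers(lo, hi + 1) * mult)) if hi > 0 else 0
            sites = _sample_sites(pool, weights, count, rng)
            if len(sites):
                keep = ~np.isin(pool, sites)
                pool, weights = pool[keep], weights[keep]
            base_at = baseline[regular_index.get_indexer(sites)]
            signs = np.where(base_at >= 0.5, -1.0, 1.0)  # toward opposite mode
            tumour, inj = inject(baseline, sites, signs, sid)
            truth.injected[pid][sid] = inj
            purity = float(rng.uniform(*design.purity_range))
            truth.purity[sid] = purity
            observe(sid, tumour, purity, geno, truth.deleted[sid])
            sheet_rows.append(
                dict(sample_id=sid, patient_id=pid, role="spatial",
                     biopsy_index=int(sid.rsplit("-", 1)[1]), purity=purity,
                     relapse_interval=np.nan, group_label=label)
            )

    # ---- temporal patients ------------------------------------------------
    for p_i, (label, mult) in enumerate(design.temporal_plan(), start=1):
        pid = f"TP{p_i:02d}"
        baseline, geno = new_patient(pid)
        prim, rel = f"{pid}-P", f"{pid}-R"
        patient_deleted = set()
        for sid in (prim, rel):
            d = draw_deletion(sid)
            truth.deleted[sid] = d
            patient_deleted |= d
        interval = int(rng.integers(*design.relapse_interval_range))
        truth.relapse_interval[pid] = interval
        lam = design.dmp_rate_per_day * mult
        n_dmps = int(rng.poisson(lam * interval))
        n_hypo = int(rng.binomial(n_dmps, design.hypo_fraction))

        eligible = np.array(sorted(set(regular_ids) - patient_deleted))
        base_at = baseline[regular_index.get_indexer(eligible)]
        hypo_pool = eligible[base_at >= delta]          # can move down by Δ
        hyper_pool = eligible[base_at <= 1 - delta]     # can move up by Δ
        if n_hypo > len(hypo_pool) or (n_dmps - n_hypo) > len(hyper_pool):
            raise ValidationError(
                f"patient {pid}: λ·interval requests {n_dmps} DMPs but the "
                "eligible probe pools are smaller"
            )
        hypo_sites = _sample_sites(
            hypo_pool, _site_weights(manifest, hypo_pool, design.region_bias),
            n_hypo, rng)
        hyper_pool = hyper_pool[~np.isin(hyper_pool, hypo_sites)]
        hyper_sites = _sample_sites(
            hyper_pool, _site_weights(manifest, hyper_pool, design.region_bias),
            n_dmps - n_hypo, rng)
        sites = np.concatenate([hypo_sites, hyper_sites])
        signs = np.concatenate([-np.ones(len(hypo_sites)), np.ones(len(hyper_sites))])

        truth.injected[pid][prim] = {}
        tumour_rel, inj = inject(baseline, sites, signs, rel)
        truth.injected[pid][rel] = inj
        for sid, tumour in ((prim, baseline), (rel, tumour_rel)):
            purity = float(rng.uniform(*design.purity_range))
            truth.purity[sid] = purity
            observe(sid, tumour, purity, geno, truth.deleted[sid])
            sheet_rows.append(
                dict(sample_id=sid, patient_id=pid,
                     role="primary" if sid == prim else "relapse",
                     biopsy_index=1, purity=purity,
                     relapse_interval=interval if sid == rel else np.nan,
                     group_label=label)
            )

    all_probe_ids = np.concatenate([regular_ids, snp_ids])
    values = pd.DataFrame(columns, index=pd.Index(all_probe_ids, name="probe_id"))
    if design.missing_rate > 0:
        mask = rng.random(values.shape) < design.missing_rate
        values = values.mask(mask)
    beta = BetaMatrix(values)
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    return beta, sheet, CnaSegmentSet(segments), truth


@dataclass
class SimulatedStudy:
    manifest: ProbeManifest
    beta: BetaMatrix
    sheet: SampleSheet
    segments: CnaSegmentSet
    truth: GroundTruth


def simulate(design: SimulationDesign, seed: int | None = None) -> SimulatedStudy:
    """Convenience wrapper: manifest + cohort from one seed."""
    if seed is None:
        seed = design.seed if design.seed is not None else 0
    rng = np.random.default_rng(seed)
    manifest = simulate_manifest(design, rng)
    beta, sheet, segments, truth = simulate_cohort(design, rng, manifest)
    return SimulatedStudy(manifest, beta, sheet, segments, truth)
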